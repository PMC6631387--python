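"""Result serialization for estimation runs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimator import DLayout, EstimationRun
from .model import MultiBodyModel


def write_run(out_dir, model: MultiBodyModel, run: EstimationRun,
              config: dict | None = None) -> None:
    """Write per-sample estimates (CSV) and a JSON run log.

    ``torques.csv`` holds tau and its posterior std per joint;
    ``estimates.csv`` the per-link accelerations/external wrenches and
    per-joint accelerations; ``run_log.json`` the contact decisions and
    configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = DLayout(model)
    joint_names = [j.name for j in model.joints]

    data = {"time": run.times}
    for k, name in enumerate(joint_names):
        data[f"tau_{name}"] = run.tau[:, k]
        data[f"tau_std_{name}"] = np.sqrt(run.tau_variance[:, k])
    pd.DataFrame(data).to_csv(out / "torques.csv", index=False)

    cols = {"time": run.times}
    for i, link in enumerate(model.links):
        for k, c in enumerate(("ax", "ay", "az", "wx", "wy", "wz")):
            cols[f"alpha_{link.name}_{c}"] = run.d_mean[:, layout.alpha(i)][:, k]
        for k, c in enumerate(("fx", "fy", "fz", "mx", "my", "mz")):
            cols[f"ext_{link.name}_{c}"] = \
                run.d_mean[:, layout.ext_wrench(i)][:, k]
    for j, name in enumerate(joint_names, start=1):
        cols[f"sddot_{name}"] = run.d_mean[:, layout.s_ddot(j)]
    pd.DataFrame(cols).to_csv(out / "estimates.csv", index=False)

    log = {
        "n_samples": int(len(run.times)),
        "joints": joint_names,
        "contact_frames_per_sample": run.contact_log,
        "config": config or {},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
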