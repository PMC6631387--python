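"""Rigid multi-body tree model, system state, and a URDF-subset reader.

A model is a tree of ``N_B`` links connected by ``n = N_B - 1`` one-DoF
joints, with link 0 the floating base (no parent joint).  Joint ``i``
(1-based, ``1..n``) is the joint whose child is link ``i``; the stacked
estimation vector relies on this numbering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from lxml import etree

from .spatial import (SpatialInertia, SpatialTransform, check_rotation,
                      rotation_about_axis, skew)


def rpy_to_matrix(r: float, p: float, y: float) -> np.ndarray:
    """URDF fixed-axis roll-pitch-yaw to a rotation matrix (Rz Ry Rx)."""
    cr, sr = np.cos(r), np.sin(r)
    cp, sp = np.cos(p), np.sin(p)
    cy, sy = np.cos(y), np.sin(y)
    Rx = np.array([[1, 0, 0], [0, cr, -sr], [0, sr, cr]])
    Ry = np.array([[cp, 0, sp], [0, 1, 0], [-sp, 0, cp]])
    Rz = np.array([[cy, -sy, 0], [sy, cy, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def matrix_to_rpy(R: np.ndarray) -> tuple[float, float, float]:
    p = -np.arcsin(np.clip(R[2, 0], -1.0, 1.0))
    r = np.arctan2(R[2, 1], R[2, 2])
    y = np.arctan2(R[1, 0], R[0, 0])
    return float(r), float(p), float(y)


@dataclass(frozen=True)
class Link:
    name: str
    inertia: SpatialInertia


@dataclass(frozen=True)
class Joint:
    """One-DoF joint coupling a parent link to a child link.

    ``origin`` is the pose of the joint frame in the parent link frame at
    zero displacement; the child link frame coincides with the joint frame
    displaced by the joint motion.  ``axis`` is expressed in the child
    frame.
    """

    name: str
    parent: str
    child: str
    kind: str  # "revolute" | "prismatic"
    axis: np.ndarray
    origin: SpatialTransform = field(default_factory=SpatialTransform.identity)
    limits: tuple[float, float] = (-np.inf, np.inf)

    def __post_init__(self):
        object.__setattr__(self, "axis",
                           np.asarray(self.axis, dtype=float).reshape(3))
        n = np.linalg.norm(self.axis)
        if not np.isclose(n, 1.0, atol=1e-8):
            raise ValueError(f"joint {self.name!r}: axis must be unit norm")
        if self.kind not in ("revolute", "prismatic"):
            raise ValueError(f"joint {self.name!r}: unsupported kind "
                             f"{self.kind!r}")
        if not self.limits[0] < self.limits[1]:
            raise ValueError(f"joint {self.name!r}: s_min must be < s_max")

    @property
    def motion_subspace(self) -> np.ndarray:
        """6-vector S mapping the joint rate to the child-relative twist
        expressed in the child frame (linear block first)."""
        S = np.zeros(6)
        if self.kind == "prismatic":
            S[:3] = self.axis
        else:
            S[3:] = self.axis
        return S

    def child_pose(self, s: float) -> SpatialTransform:
        """Pose of the child link frame in the parent link frame."""
        if self.kind == "revolute":
            motion = SpatialTransform(rotation_about_axis(self.axis, s),
                                      np.zeros(3))
        else:
            motion = SpatialTransform(np.eye(3), self.axis * s)
        return self.origin.compose(motion)


class ModelError(ValueError):
    """Raised for malformed model descriptions (bad topology, URDF, ...)."""


class MultiBodyModel:
    """Tree of links and one-DoF joints with a designated floating base.

    Links are re-indexed topologically on construction: index 0 is the
    base and every parent precedes its children, so forward passes can
    iterate ``1..N_B-1`` in order.  Joint ``i`` is the parent joint of
    link ``i``.
    """

    def __init__(self, links: list[Link], joints: list[Joint],
                 base: str | None = None,
                 frames: dict[str, tuple[str, SpatialTransform]] | None = None):
        by_name = {l.name: l for l in links}
        if len(by_name) != len(links):
            raise ModelError("duplicate link names")
        for j in joints:
            if j.parent not in by_name or j.child not in by_name:
                raise ModelError(f"joint {j.name!r} references unknown link")
            if j.parent == j.child:
                raise ModelError(f"joint {j.name!r}: child equals parent")
        children_of: dict[str, list[Joint]] = {l.name: [] for l in links}
        has_parent: dict[str, bool] = {l.name: False for l in links}
        for j in joints:
            if has_parent[j.child]:
                raise ModelError(f"link {j.child!r} has two parent joints")
            has_parent[j.child] = True
            children_of[j.parent].append(j)
        roots = [n for n, p in has_parent.items() if not p]
        if base is None:
            if len(roots) != 1:
                raise ModelError(f"topology has {len(roots)} roots; "
                                 "expected a single tree")
            base = roots[0]
        elif base not in by_name:
            raise ModelError(f"unknown base link {base!r}")
        elif has_parent[base]:
            raise ModelError(f"base link {base!r} has a parent joint")

        # breadth-first re-index; detects cycles/disconnection by count
        order: list[str] = [base]
        joint_order: list[Joint] = []
        cursor = 0
        while cursor < len(order):
            for j in children_of[order[cursor]]:
                order.append(j.child)
                joint_order.append(j)
            cursor += 1
        if len(order) != len(links):
            raise ModelError("topology is not a tree rooted at the base "
                             "(cycle or disconnected link)")

        self.links: list[Link] = [by_name[n] for n in order]
        self.joints: list[Joint] = joint_order
        self._index = {n: i for i, n in enumerate(order)}
        self._parent = [-1] + [self._index[j.parent] for j in joint_order]
        self._children: list[list[int]] = [[] for _ in order]
        for i, p in enumerate(self._parent):
            if p >= 0:
                self._children[p].append(i)
        self.frames: dict[str, tuple[int, SpatialTransform]] = {}
        for name, (link_name, T) in (frames or {}).items():
            self.add_frame(name, link_name, T)

    # -- topology ----------------------------------------------------
    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def n_joints(self) -> int:
        return len(self.joints)

    def link_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ModelError(f"unknown link {name!r}") from None

    def parent(self, link: int) -> int:
        """Parent link index; -1 for the base."""
        return self._parent[link]

    def children(self, link: int) -> list[int]:
        return list(self._children[link])

    def joint_of(self, link: int) -> Joint:
        """The parent joint of link ``link`` (1-based link index)."""
        if link == 0:
            raise ModelError("the floating base has no parent joint")
        return self.joints[link - 1]

    def path_to_base(self, link: int) -> list[int]:
        """Link indices from ``link`` up to (and including) the base."""
        path = [link]
        while path[-1] != 0:
            path.append(self._parent[path[-1]])
        return path

    def add_frame(self, name: str, link: str,
                  T: SpatialTransform | None = None) -> None:
        """Attach a named frame rigidly to a link."""
        if name in self._index or name in self.frames:
            raise ModelError(f"frame name {name!r} already in use")
        self.frames[name] = (self.link_index(link),
                             T or SpatialTransform.identity())

    def resolve_frame(self, name: str) -> tuple[int, SpatialTransform]:
        """Return (host link index, fixed link-to-frame transform)."""
        if name in self._index:
            return self._index[name], SpatialTransform.identity()
        if name in self.frames:
            return self.frames[name]
        raise ModelError(f"unknown frame {name!r}")

    def joint_limits(self) -> np.ndarray:
        return np.array([j.limits for j in self.joints])

    # -- serialization ----------------------------------------------
    def to_json(self) -> str:
        def tf(T: SpatialTransform):
            return {"rotation": T.rotation.tolist(),
                    "origin": T.origin.tolist()}

        obj = {
            "base": self.links[0].name,
            "links": [{
                "name": l.name,
                "mass": l.inertia.mass,
                "first_moment": l.inertia.first_moment.tolist(),
                "inertia": l.inertia.inertia.tolist(),
            } for l in self.links],
            "joints": [{
                "name": j.name, "parent": j.parent, "child": j.child,
                "kind": j.kind, "axis": j.axis.tolist(),
                "origin": tf(j.origin),
                "limits": [j.limits[0], j.limits[1]],
            } for j in self.joints],
            "frames": {name: {"link": self.links[i].name, **tf(T)}
                       for name, (i, T) in self.frames.items()},
        }
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MultiBodyModel":
        obj = json.loads(text)
        links = [Link(d["name"],
                      SpatialInertia(d["mass"], d["first_moment"],
                                     np.asarray(d["inertia"])))
                 for d in obj["links"]]
        joints = [Joint(d["name"], d["parent"], d["child"], d["kind"],
                        d["axis"],
                        SpatialTransform(np.asarray(d["origin"]["rotation"]),
                                         d["origin"]["origin"]),
                        (d["limits"][0], d["limits"][1]))
                  for d in obj["joints"]]
        frames = {name: (d["link"],
                         SpatialTransform(np.asarray(d["rotation"]),
                                          d["origin"]))
                  for name, d in obj.get("frames", {}).items()}
        return cls(links, joints, base=obj.get("base"), frames=frames)


# ---------------------------------------------------------------------------
# URDF subset I/O
# ---------------------------------------------------------------------------

_SUPPORTED_JOINTS = {"revolute", "prismatic", "continuous"}


def _parse_origin(el) -> SpatialTransform:
    if el is None:
        return SpatialTransform.identity()
    xyz = [float(v) for v in el.get("xyz", "0 0 0").split()]
    rpy = [float(v) for v in el.get("rpy", "0 0 0").split()]
    return SpatialTransform(rpy_to_matrix(*rpy), xyz)


def parse_urdf(text: str | bytes) -> MultiBodyModel:
    """Parse a URDF document covering the supported subset.

    Supported: ``<link>`` with a full ``<inertial>`` block; ``<joint>`` of
    type revolute, prismatic or continuous (continuous becomes revolute
    with infinite limits).  Anything else raises :class:`ModelError`
    naming the offending element.
    """
    if isinstance(text, str):
        text = text.encode()
    root = etree.fromstring(text)
    if root.tag != "robot":
        raise ModelError(f"expected <robot> root element, got <{root.tag}>")

    links = []
    for el in root.findall("link"):
        name = el.get("name")
        if name is None:
            raise ModelError("<link> without a name attribute")
        inertial = el.find("inertial")
        if inertial is None:
            raise ModelError(f"link {name!r}: missing <inertial> block")
        mass_el = inertial.find("mass")
        inertia_el = inertial.find("inertia")
        if mass_el is None or inertia_el is None:
            raise ModelError(f"link {name!r}: incomplete <inertial> block")
        mass = float(mass_el.get("value"))
        T = _parse_origin(inertial.find("origin"))
        vals = {k: float(inertia_el.get(k, "0"))
                for k in ("ixx", "ixy", "ixz", "iyy", "iyz", "izz")}
        I_local = np.array([
            [vals["ixx"], vals["ixy"], vals["ixz"]],
            [vals["ixy"], vals["iyy"], vals["iyz"]],
            [vals["ixz"], vals["iyz"], vals["izz"]],
        ])
        I_com = T.rotation @ I_local @ T.rotation.T
        links.append(Link(name, SpatialInertia.from_com(mass, T.origin, I_com)))

    joints = []
    for el in root.findall("joint"):
        name = el.get("name", "<unnamed>")
        kind = el.get("type")
        if kind not in _SUPPORTED_JOINTS:
            raise ModelError(f"joint {name!r}: unsupported type {kind!r}")
        parent_el, child_el = el.find("parent"), el.find("child")
        if parent_el is None or child_el is None:
            raise ModelError(f"joint {name!r}: missing parent/child element")
        axis_el = el.find("axis")
        axis = ([float(v) for v in axis_el.get("xyz").split()]
                if axis_el is not None else [1.0, 0.0, 0.0])
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        limits = (-np.inf, np.inf)
        limit_el = el.find("limit")
        if kind != "continuous" and limit_el is not None:
            limits = (float(limit_el.get("lower", "-inf")),
                      float(limit_el.get("upper", "inf")))
        joints.append(Joint(name, parent_el.get("link"), child_el.get("link"),
                            "revolute" if kind == "continuous" else kind,
                            axis, _parse_origin(el.find("origin")), limits))

    return MultiBodyModel(links, joints)


def to_urdf(model: MultiBodyModel, name: str = "model") -> str:
    """Serialize the supported subset back to URDF XML."""
    robot = etree.Element("robot", name=name)
    for link in model.links:
        el = etree.SubElement(robot, "link", name=link.name)
        inertial = etree.SubElement(el, "inertial")
        com = link.inertia.com
        etree.SubElement(inertial, "origin",
                         xyz=" ".join(f"{v:.17g}" for v in com), rpy="0 0 0")
        etree.SubElement(inertial, "mass",
                         value=f"{link.inertia.mass:.17g}")
        I = link.inertia.inertia_at_com()
        etree.SubElement(inertial, "inertia",
                         ixx=f"{I[0, 0]:.17g}", ixy=f"{I[0, 1]:.17g}",
                         ixz=f"{I[0, 2]:.17g}", iyy=f"{I[1, 1]:.17g}",
                         iyz=f"{I[1, 2]:.17g}", izz=f"{I[2, 2]:.17g}")
    for j in model.joints:
        el = etree.SubElement(robot, "joint", name=j.name, type=j.kind)
        r, p, y = matrix_to_rpy(j.origin.rotation)
        etree.SubElement(el, "origin",
                         xyz=" ".join(f"{v:.17g}" for v in j.origin.origin),
                         rpy=f"{r:.17g} {p:.17g} {y:.17g}")
        etree.SubElement(el, "parent", link=j.parent)
        etree.SubElement(el, "child", link=j.child)
        etree.SubElement(el, "axis",
                         xyz=" ".join(f"{v:.17g}" for v in j.axis))
        if np.isfinite(j.limits).all():
            etree.SubElement(el, "limit", lower=f"{j.limits[0]:.17g}",
                             upper=f"{j.limits[1]:.17g}",
                             effort="1000", velocity="100")
    return etree.tostring(robot, pretty_print=True).decode()


@dataclass
class SystemState:
    """Configuration and velocity of the floating-base system.

    ``base_velocity`` is the *mixed* base velocity ``(I_odot_B, I_w_B)``:
    linear velocity of the base origin and angular velocity, both in
    inertial coordinates.  ``base_acceleration`` stacks their time
    derivatives ``(I_oddot_B, I_wdot_B)``.
    """

    base_position: np.ndarray
    base_rotation: np.ndarray
    s: np.ndarray
    base_velocity: np.ndarray = None
    s_dot: np.ndarray = None
    base_acceleration: np.ndarray = None
    s_ddot: np.ndarray = None

    def __post_init__(self):
        self.base_position = np.asarray(self.base_position, float).reshape(3)
        self.base_rotation = check_rotation(np.asarray(self.base_rotation,
                                                       float))
        self.s = np.atleast_1d(np.asarray(self.s, float))
        n = self.s.size
        if self.base_velocity is None:
            self.base_velocity = np.zeros(6)
        if self.s_dot is None:
            self.s_dot = np.zeros(n)
        self.base_velocity = np.asarray(self.base_velocity, float).reshape(6)
        self.s_dot = np.asarray(self.s_dot, float).reshape(n)
        if self.base_acceleration is not None:
            self.base_acceleration = np.asarray(self.base_acceleration,
                                                float).reshape(6)
        if self.s_ddot is not None:
            self.s_ddot = np.asarray(self.s_ddot, float).reshape(n)

    def check_dims(self, model: MultiBodyModel) -> None:
        if self.s.size != model.n_joints:
            raise ModelError(f"state has {self.s.size} joint positions, "
                             f"model has {model.n_joints} joints")

    @property
    def nu(self) -> np.ndarray:
        return np.concatenate([self.base_velocity, self.s_dot])

    @property
    def nu_dot(self) -> np.ndarray:
        if self.base_acceleration is None or self.s_ddot is None:
            raise ModelError("state has no acceleration information")
        return np.concatenate([self.base_acceleration, self.s_ddot])
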