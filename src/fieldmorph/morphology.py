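"""Neuronal morphologies: SWC I/O, discretization, rotation and geometry.

A :class:`Morphology` is a tree of typed neurite sections (soma, axon, basal
and apical dendrites) with 3-D points and per-point diameters, in µm.  The
soma is a single spherical section at the tree root and, by convention, sits
at the coordinate origin; "upright" means the dendritic arbor extends toward
+z.  :func:`discretize` reduces a morphology to a
:class:`CompartmentalModel`, the electrical graph used by the cable solver
and by all morphometrics.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "MorphologyError",
    "Section",
    "Morphology",
    "Compartment",
    "CompartmentalModel",
    "read_swc",
    "write_swc",
    "discretize",
    "rotate",
    "compartment_angle",
    "morphologies_equal",
]

NEURITE_TYPES = ("soma", "axon", "basal_dendrite", "apical_dendrite")
DENDRITIC_TYPES = ("basal_dendrite", "apical_dendrite")
SWC_CODE_TO_TYPE = {1: "soma", 2: "axon", 3: "basal_dendrite", 4: "apical_dendrite"}
TYPE_TO_SWC_CODE = {v: k for k, v in SWC_CODE_TO_TYPE.items()}
# integer codes used in CompartmentalModel arrays (== SWC codes)
TYPE_CODE = {t: c for c, t in SWC_CODE_TO_TYPE.items()}


class MorphologyError(ValueError):
    """Structural or validation failure of a morphology or SWC file."""


@dataclass
class Section:
    """An unbranched neurite piece: an ordered 3-D polyline with diameters.

    The polyline does not include the junction point on the parent section;
    the attachment is purely topological (``parent_id``).
    """

    id: int
    neurite_type: str
    points: np.ndarray  # (n, 3) µm
    diameters: np.ndarray  # (n,) µm
    parent_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.diameters = np.asarray(self.diameters, dtype=float).reshape(-1)

    @property
    def length(self) -> float:
        """Arc length of the polyline, µm (0 for a single point)."""
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def validate(self) -> None:
        if self.neurite_type not in NEURITE_TYPES:
            raise MorphologyError(f"unknown neurite type {self.neurite_type!r}")
        if len(self.points) < 1 or len(self.points) != len(self.diameters):
            raise MorphologyError(f"section {self.id}: empty or mismatched points/diameters")
        if np.any(self.diameters <= 0):
            raise MorphologyError(f"section {self.id}: non-positive diameter")
        if len(self.points) >= 2:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            if np.any(seg <= 0):
                raise MorphologyError(f"section {self.id}: repeated consecutive points")


@dataclass
class Morphology:
    sections: list[Section]
    class_label: Optional[str] = None  # "PC" | "PV"
    layer_label: Optional[str] = None  # "L23" | "L4" | "L5"

    @property
    def soma(self) -> Section:
        roots = [s for s in self.sections if s.parent_id is None]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root section, found {len(roots)}")
        return roots[0]

    def section_by_id(self, sid: int) -> Section:
        for s in self.sections:
            if s.id == sid:
                return s
        raise MorphologyError(f"no section with id {sid}")

    def children_map(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {s.id: [] for s in self.sections}
        for s in self.sections:
            if s.parent_id is not None:
                ch[s.parent_id].append(s.id)
        return ch

    @property
    def soma_center(self) -> np.ndarray:
        return self.soma.points.mean(axis=0)

    def all_points(self) -> np.ndarray:
        """All morphology points, (M, 3)."""
        return np.concatenate([s.points for s in self.sections], axis=0)

    def point_types(self) -> np.ndarray:
        """Integer type code per point, aligned with :meth:`all_points`."""
        return np.concatenate(
            [np.full(len(s.points), TYPE_CODE[s.neurite_type]) for s in self.sections]
        )

    def translate(self, offset: np.ndarray) -> "Morphology":
        offset = np.asarray(offset, dtype=float)
        secs = [replace(s, points=s.points + offset) for s in self.sections]
        return Morphology(secs, self.class_label, self.layer_label)

    def validate(self) -> None:
        ids = [s.id for s in self.sections]
        if len(set(ids)) != len(ids):
            raise MorphologyError("duplicate section ids")
        roots = [s for s in self.sections if s.parent_id is None]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root section, found {len(roots)}")
        if roots[0].neurite_type != "soma":
            raise MorphologyError("root section must be the soma")
        n_soma = sum(1 for s in self.sections if s.neurite_type == "soma")
        if n_soma != 1:
            raise MorphologyError(f"expected exactly one soma section, found {n_soma}")
        by_id = {s.id: s for s in self.sections}
        for s in self.sections:
            s.validate()
            if s.parent_id is not None and s.parent_id not in by_id:
                raise MorphologyError(f"section {s.id}: missing parent {s.parent_id}")
        # cycle / reachability check: every section must reach the root
        for s in self.sections:
            seen = set()
            cur: Optional[Section] = s
            while cur.parent_id is not None:
                if cur.id in seen:
                    raise MorphologyError(f"cycle detected through section {s.id}")
                seen.add(cur.id)
                cur = by_id[cur.parent_id]


@dataclass(frozen=True)
class Compartment:
    """View of a single compartment of a :class:`CompartmentalModel`."""

    index: int
    section_id: int
    neurite_type: str
    midpoint: np.ndarray  # (3,) µm, arc-length center
    length: float  # µm
    diameter: float  # µm
    parent_index: Optional[int]


@dataclass
class CompartmentalModel:
    """Discretized electrical graph of a morphology.

    Compartment 0 is always the (spherical) soma.  ``parent[i] < i`` for all
    i > 0, so root-to-leaf array order is also a valid elimination order for
    the tree solver.  ``point_cloud`` keeps the raw morphology points so that
    coordinate extents do not depend on discretization granularity.
    """

    midpoints: np.ndarray  # (N, 3) µm
    lengths: np.ndarray  # (N,) µm (soma: its diameter)
    diameters: np.ndarray  # (N,) µm
    neurite_codes: np.ndarray  # (N,) int, SWC type codes
    section_ids: np.ndarray  # (N,) int
    parent: np.ndarray  # (N,) int, -1 for the soma root
    axes: np.ndarray  # (N, 3) unit tangent at the midpoint (soma: +z)
    point_cloud: np.ndarray  # (M, 3) µm
    point_codes: np.ndarray  # (M,) int
    class_label: Optional[str] = None
    layer_label: Optional[str] = None
    # per-section children counts, for branch counting / recording targets
    section_children: dict[int, list[int]] = field(default_factory=dict)
    section_types: dict[int, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.lengths)

    @property
    def areas(self) -> np.ndarray:
        """Membrane area per compartment, µm².  Soma: sphere 4πr² = πd²;
        neurites: cylinder lateral surface πdΔx."""
        a = math.pi * self.diameters * self.lengths
        soma = self.neurite_codes == TYPE_CODE["soma"]
        a[soma] = math.pi * self.diameters[soma] ** 2
        return a

    def compartment(self, i: int) -> Compartment:
        p = int(self.parent[i])
        return Compartment(
            index=i,
            section_id=int(self.section_ids[i]),
            neurite_type=SWC_CODE_TO_TYPE[int(self.neurite_codes[i])],
            midpoint=self.midpoints[i].copy(),
            length=float(self.lengths[i]),
            diameter=float(self.diameters[i]),
            parent_index=None if p < 0 else p,
        )

    def type_mask(self, *types: str) -> np.ndarray:
        codes = [TYPE_CODE[t] for t in types]
        return np.isin(self.neurite_codes, codes)

    def rotated(self, theta_deg: float) -> "CompartmentalModel":
        """Rotate midpoints, axes and point cloud about +y (see :func:`rotate`)."""
        R = _rotation_matrix_y(theta_deg)
        return replace(
            self,
            midpoints=self.midpoints @ R.T,
            axes=self.axes @ R.T,
            point_cloud=self.point_cloud @ R.T,
        )

    def section_compartments(self, sid: int) -> np.ndarray:
        return np.flatnonzero(self.section_ids == sid)


# ---------------------------------------------------------------------------
# SWC I/O


def read_swc(path) -> Morphology:
    """Read a 7-column SWC file and recenter the soma at the origin.

    Type codes 1/2/3/4 map to soma/axon/basal/apical; any other code is
    treated as basal dendrite with a warning.  Sections are maximal
    unbranched chains of same-type points.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise MorphologyError(f"{path}:{ln}: expected 7 columns, got {len(parts)}")
            rows.append(
                (
                    int(parts[0]),
                    int(parts[1]),
                    float(parts[2]),
                    float(parts[3]),
                    float(parts[4]),
                    float(parts[5]),
                    int(parts[6]),
                )
            )
    if not rows:
        raise MorphologyError(f"{path}: empty SWC file")

    ids = {r[0] for r in rows}
    by_id = {}
    roots = []
    for pid, code, x, y, z, r, parent in rows:
        if r <= 0:
            raise MorphologyError(f"point {pid}: non-positive radius")
        if code not in SWC_CODE_TO_TYPE:
            warnings.warn(f"point {pid}: unknown SWC type {code}, treating as basal dendrite")
            code = 3
        if parent == -1:
            roots.append(pid)
        elif parent not in ids:
            raise MorphologyError(f"point {pid}: missing parent {parent}")
        by_id[pid] = (code, np.array([x, y, z]), r, parent)
    if len(roots) != 1:
        raise MorphologyError(f"expected a single root point, found {len(roots)}")

    children: dict[int, list[int]] = {pid: [] for pid in by_id}
    for pid, (_, _, _, parent) in by_id.items():
        if parent != -1:
            children[parent].append(pid)

    soma_ids = [pid for pid, v in by_id.items() if v[0] == 1]
    if not soma_ids:
        raise MorphologyError("no soma points (SWC type 1)")
    if by_id[roots[0]][0] != 1:
        raise MorphologyError("root point is not a soma point")

    sections: list[Section] = []
    soma_pts = np.array([by_id[pid][1] for pid in soma_ids])
    soma_diam = np.array([2.0 * by_id[pid][2] for pid in soma_ids])
    sections.append(Section(0, "soma", soma_pts, soma_diam, None))
    soma_set = set(soma_ids)

    # section starts: non-soma points whose parent is soma, a branch point,
    # or a point of a different type
    def is_start(pid: int) -> bool:
        code, _, _, parent = by_id[pid]
        if code == 1:
            return False
        if parent in soma_set:
            return True
        pcode = by_id[parent][0]
        return pcode != code or len(children[parent]) >= 2

    next_sid = 1
    sec_of_start: dict[int, int] = {}
    starts = [pid for pid in by_id if is_start(pid)]
    starts.sort()
    chains: dict[int, list[int]] = {}
    for start in starts:
        chain = [start]
        cur = start
        while True:
            ch = [c for c in children[cur] if by_id[c][0] == by_id[cur][0]]
            if len(children[cur]) != 1 or len(ch) != 1:
                break
            cur = ch[0]
            chain.append(cur)
        sec_of_start[start] = next_sid
        chains[next_sid] = chain
        next_sid += 1

    last_point_section: dict[int, int] = {pid: 0 for pid in soma_ids}
    for sid, chain in chains.items():
        for pid in chain:
            last_point_section[pid] = sid
    for sid, chain in chains.items():
        code = by_id[chain[0]][0]
        parent_pt = by_id[chain[0]][3]
        parent_sid = last_point_section[parent_pt]
        pts = np.array([by_id[pid][1] for pid in chain])
        dia = np.array([2.0 * by_id[pid][2] for pid in chain])
        sections.append(Section(sid, SWC_CODE_TO_TYPE[code], pts, dia, parent_sid))

    morph = Morphology(sections)
    morph = morph.translate(-morph.soma_center)
    morph.validate()
    return morph


def write_swc(morph: Morphology, path) -> None:
    """Write standard 7-column SWC (radii = diameter/2, '#' header)."""
    morph.validate()
    lines = ["# id type x y z radius parent", "# written by fieldmorph"]
    next_id = 1
    last_id_of_section: dict[int, int] = {}

    def emit(sec: Section, parent_point: int) -> None:
        nonlocal next_id
        code = TYPE_TO_SWC_CODE[sec.neurite_type]
        prev = parent_point
        for (x, y, z), d in zip(sec.points, sec.diameters):
            lines.append(
                f"{next_id} {code} {x:.6g} {y:.6g} {z:.6g} {d / 2.0:.6g} {prev}"
            )
            prev = next_id
            next_id += 1
        last_id_of_section[sec.id] = prev

    soma = morph.soma
    emit(soma, -1)
    ch = morph.children_map()

    def walk(sid: int) -> None:
        for cid in sorted(ch[sid]):
            sec = morph.section_by_id(cid)
            emit(sec, last_id_of_section[sid])
            walk(cid)

    walk(soma.id)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def morphologies_equal(a: Morphology, b: Morphology, tol: float = 1e-4) -> bool:
    """Topology-aware equality (coordinates and radii to ``tol`` µm)."""
    if len(a.sections) != len(b.sections):
        return False
    for sa, sb in zip(a.sections, b.sections):
        if sa.neurite_type != sb.neurite_type or sa.parent_id != sb.parent_id:
            return False
        if sa.points.shape != sb.points.shape:
            return False
        if not np.allclose(sa.points, sb.points, atol=tol):
            return False
        if not np.allclose(sa.diameters, sb.diameters, atol=tol):
            return False
    return True


# ---------------------------------------------------------------------------
# discretization


def discretize(morph: Morphology, max_compartment_length: float) -> CompartmentalModel:
    """Cut every section into ⌈L/max_len⌉ equal compartments.

    The soma becomes a single spherical compartment at the tree root whose
    cable "length" is its diameter.  Total neurite arc length is conserved
    exactly.  Compartment midpoints and diameters are interpolated along the
    section polyline at arc-length centers.
    """
    if max_compartment_length <= 0:
        raise ValueError("max_compartment_length must be positive")
    morph.validate()
    soma = morph.soma
    r_soma = float(np.mean(soma.diameters)) / 2.0
    center = morph.soma_center

    mid = [center]
    length = [2.0 * r_soma]
    diam = [2.0 * r_soma]
    codes = [TYPE_CODE["soma"]]
    sids = [soma.id]
    parent = [-1]
    axes = [np.array([0.0, 0.0, 1.0])]

    last_comp_of_section: dict[int, int] = {soma.id: 0}
    ch = morph.children_map()

    def do_section(sec: Section) -> None:
        pts, dia = sec.points, sec.diameters
        if len(pts) < 2:
            raise MorphologyError(f"section {sec.id}: single point, zero length")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        L = float(seg.sum())
        if L <= 0:
            raise MorphologyError(f"section {sec.id}: zero arc length")
        s = np.concatenate([[0.0], np.cumsum(seg)])
        ncomp = max(1, math.ceil(L / max_compartment_length))
        dx = L / ncomp
        prev = last_comp_of_section[sec.parent_id]
        for k in range(ncomp):
            sc = (k + 0.5) * dx
            j = min(np.searchsorted(s, sc, side="right") - 1, len(seg) - 1)
            f = (sc - s[j]) / seg[j]
            mid.append(pts[j] + f * (pts[j + 1] - pts[j]))
            diam.append(float(dia[j] + f * (dia[j + 1] - dia[j])))
            axes.append((pts[j + 1] - pts[j]) / seg[j])
            length.append(dx)
            codes.append(TYPE_CODE[sec.neurite_type])
            sids.append(sec.id)
            parent.append(prev)
            prev = len(mid) - 1
        last_comp_of_section[sec.id] = prev

    def walk(sid: int) -> None:
        for cid in sorted(ch[sid]):
            do_section(morph.section_by_id(cid))
            walk(cid)

    walk(soma.id)

    return CompartmentalModel(
        midpoints=np.array(mid),
        lengths=np.array(length),
        diameters=np.array(diam),
        neurite_codes=np.array(codes, dtype=np.int64),
        section_ids=np.array(sids, dtype=np.int64),
        parent=np.array(parent, dtype=np.int64),
        axes=np.array(axes),
        point_cloud=morph.all_points(),
        point_codes=morph.point_types(),
        class_label=morph.class_label,
        layer_label=morph.layer_label,
        section_children={s.id: ch[s.id] for s in morph.sections},
        section_types={s.id: s.neurite_type for s in morph.sections},
    )


# ---------------------------------------------------------------------------
# geometry


def _rotation_matrix_y(theta_deg: float) -> np.ndarray:
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    # right-handed rotation about +y: (x, y, z) -> (x c + z s, y, -x s + z c)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotate(morph: Morphology, theta_deg: float) -> Morphology:
    """Rotate every point about the +y axis; topology and diameters unchanged."""
    R = _rotation_matrix_y(theta_deg)
    secs = [replace(s, points=s.points @ R.T) for s in morph.sections]
    return Morphology(secs, morph.class_label, morph.layer_label)


def compartment_angle(comp, mode: str = "midpoint") -> float:
    """Polar angle φ of a compartment relative to the +z axis, in [0, π].

    ``midpoint`` (default): angle of the midpoint position vector (soma at
    the origin), so a compartment straight above the soma has φ = 0 and one
    exactly at the origin returns 0 by convention.  ``axis``: angle of the
    compartment's own tangent direction (an alternative reading of how a
    compartment is oriented within the field), also in [0, π].
    """
    if mode == "midpoint":
        v = np.asarray(comp.midpoint if hasattr(comp, "midpoint") else comp, dtype=float)
    elif mode == "axis":
        v = np.asarray(comp.axis if hasattr(comp, "axis") else comp, dtype=float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    nrm = np.linalg.norm(v)
    if nrm == 0:
        return 0.0
    return float(np.arccos(np.clip(v[2] / nrm, -1.0, 1.0)))


def midpoint_cosines(model: CompartmentalModel, mode: str = "midpoint") -> np.ndarray:
    """cos φ_j for every compartment (vectorized :func:`compartment_angle`).

    Midpoints at the origin (the soma, by convention) get cos φ = 1.
    """
    if mode == "midpoint":
        v = model.midpoints
    elif mode == "axis":
        v = model.axes
    else:
        raise ValueError(f"unknown mode {mode!r}")
    nrm = np.linalg.norm(v, axis=1)
    cos = np.ones(model.n)
    nz = nrm > 0
    cos[nz] = np.clip(v[nz, 2] / nrm[nz], -1.0, 1.0)
    return cos
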