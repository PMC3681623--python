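"""Cavity desolvation and fenestration transit-event analysis.

Regions (central cavity, the four lateral fenestrations, lipid slab,
intracellular/extracellular aqueous compartments) are declared as unions of
geometric primitives — z-slabs, spheres and capped cylinders — optionally
anchored to a protein selection's center of mass per frame. Per-frame
molecule counts inside regions feed two analyses:

* the water-displacement regression of cavity water counts on cavity
  ligand counts, whose negative slope is the number of waters each bound
  ligand displaces; and
* transit-event detection, which turns each molecule's per-frame region
  trace into entry/exit events via declared routes (for example
  lipid → fenestration → cavity is a fenestration entry). A dwell filter
  removes boundary flicker: a molecule must stay at least ``dwell`` frames
  in a region for the visit to count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_model import Frame, Topology, Trajectory, group_com, minimum_image, molecule_groups

__all__ = [
    "Slab",
    "Sphere",
    "Cylinder",
    "RegionSpec",
    "TransitEvent",
    "DEFAULT_ROUTES",
    "count_in_region",
    "water_displacement_fit",
    "region_trace",
    "detect_transit_events",
]


@dataclass(frozen=True)
class Slab:
    """All points with z in [z_lo, z_hi] (anchor-relative coordinates)."""

    z_lo: float
    z_hi: float

    def __post_init__(self) -> None:
        if self.z_hi <= self.z_lo:
            raise ValueError("slab interval is degenerate")

    def contains(self, points: np.ndarray, box: np.ndarray, offset: np.ndarray) -> np.ndarray:
        zc = offset[2] + 0.5 * (self.z_lo + self.z_hi)
        dz = minimum_image(points[:, 2] - zc, box[2])
        half = 0.5 * (self.z_hi - self.z_lo)
        return np.abs(dz) <= half


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")

    def contains(self, points: np.ndarray, box: np.ndarray, offset: np.ndarray) -> np.ndarray:
        d = minimum_image(points - (offset + np.asarray(self.center)), box)
        return (d * d).sum(axis=1) <= self.radius**2


@dataclass(frozen=True)
class Cylinder:
    """Capped cylinder: axis point, direction, radius, half-length."""

    point: tuple[float, float, float]
    axis: tuple[float, float, float]
    radius: float
    half_length: float

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.half_length <= 0:
            raise ValueError("cylinder radius and half-length must be positive")
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("cylinder axis must be non-zero")
        object.__setattr__(self, "axis", tuple(a / n))

    def contains(self, points: np.ndarray, box: np.ndarray, offset: np.ndarray) -> np.ndarray:
        d = minimum_image(points - (offset + np.asarray(self.point)), box)
        a = np.asarray(self.axis)
        along = d @ a
        perp = d - along[:, None] * a
        return (np.abs(along) <= self.half_length) & (
            (perp * perp).sum(axis=1) <= self.radius**2
        )


@dataclass(frozen=True)
class RegionSpec:
    """Named union of primitives, optionally anchored to a selection COM.

    With ``anchor_selection`` set, primitive coordinates are interpreted
    relative to that selection's per-frame center of mass (drift-proof);
    otherwise they are absolute box coordinates. Every primitive tests
    membership through the minimum-image displacement from its own
    reference point, so regions work across periodic boundaries.
    """

    name: str
    primitives: tuple[Slab | Sphere | Cylinder, ...]
    anchor_selection: str | None = None

    def __post_init__(self) -> None:
        if not self.primitives:
            raise ValueError(f"region {self.name!r} has no primitives")

    def contains(
        self, points: np.ndarray, frame: Frame, top: Topology | None = None
    ) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.anchor_selection is not None:
            if top is None:
                raise ValueError("anchored region needs a topology")
            offset = group_com(frame, top.select(self.anchor_selection), top)
        else:
            offset = np.zeros(3)
        mask = np.zeros(points.shape[0], dtype=bool)
        for prim in self.primitives:
            mask |= prim.contains(points, frame.box, offset)
        return mask


@dataclass(frozen=True)
class TransitEvent:
    """A molecule crossing into or out of the cavity via a labeled pathway."""

    molecule_index: int
    direction: str  # "entry" | "exit"
    pathway: str  # "fenestration_i" | "intracellular_gate" | ... | "unresolved"
    frame_start: int
    frame_end: int


#: Route table: (region sequence) -> pathway label. Sequences end (entry)
#: or start (exit) at the cavity; ``fenestration_*`` matches any declared
#: fenestration copy and labels the event with the copy actually used.
DEFAULT_ROUTES: dict[tuple[str, ...], str] = {
    ("lipid", "fenestration_*", "cavity"): "fenestration",
    ("aqueous_intracellular", "cavity"): "intracellular_gate",
    ("aqueous_extracellular", "cavity"): "selectivity_filter",
}


def count_in_region(
    traj: Trajectory,
    selection: str,
    region: RegionSpec,
) -> np.ndarray:
    """Per-frame count of molecules whose COM lies inside the region."""
    groups = molecule_groups(traj.topology, selection)
    counts = np.zeros(traj.n_frames, dtype=int)
    if not groups:
        return counts
    for fi, frame in enumerate(traj.frames):
        coms = np.array([group_com(frame, g, traj.topology) for g in groups])
        counts[fi] = int(region.contains(coms, frame, traj.topology).sum())
    return counts


def water_displacement_fit(
    n_water: Sequence[float], n_ligand: Sequence[float]
) -> dict:
    """OLS of cavity water count on cavity ligand count.

    The displacement ratio (waters removed per bound ligand) is the
    negative of the fitted slope. Returns slope, intercept, the ratio and
    fit diagnostics (r², residual SD, n).
    """
    w = np.asarray(n_water, dtype=float)
    l = np.asarray(n_ligand, dtype=float)
    if w.shape != l.shape or w.ndim != 1:
        raise ValueError("series must be aligned 1-D arrays")
    if w.size < 3:
        raise ValueError("need at least 3 paired frames")
    if np.ptp(l) == 0:
        raise ValueError("cannot fit: ligand counts have zero variance")
    slope, intercept = np.polyfit(l, w, 1)
    pred = slope * l + intercept
    ss_res = float(((w - pred) ** 2).sum())
    ss_tot = float(((w - w.mean()) ** 2).sum())
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "displacement_ratio": float(-slope),
        "r_squared": 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        "residual_sd": float(np.sqrt(ss_res / (w.size - 2))),
        "n": int(w.size),
    }


def region_trace(
    traj: Trajectory,
    selection: str,
    regions: Sequence[RegionSpec],
) -> list[list[str]]:
    """Per-molecule, per-frame region label ("none" when in no region).

    Regions are tested in declaration order; the first match wins, so
    declaration order is the precedence rule. Cavity/fenestration overlap
    is rejected because events would then be ambiguous.
    """
    _check_disjoint_cavity_fenestrations(traj, regions)
    groups = molecule_groups(traj.topology, selection)
    traces: list[list[str]] = [[] for _ in groups]
    for frame in traj.frames:
        coms = np.array([group_com(frame, g, traj.topology) for g in groups])
        masks = [r.contains(coms, frame, traj.topology) for r in regions]
        for mi in range(len(groups)):
            label = "none"
            for r, mask in zip(regions, masks):
                if mask[mi]:
                    label = r.name
                    break
            traces[mi].append(label)
    return traces


def _check_disjoint_cavity_fenestrations(
    traj: Trajectory, regions: Sequence[RegionSpec]
) -> None:
    cavity = [r for r in regions if r.name == "cavity"]
    fens = [r for r in regions if r.name.startswith("fenestration")]
    if not cavity or not fens:
        return
    frame = traj.frames[0]
    # probe on a coarse grid of the box; an overlap anywhere is a config error
    box = frame.box
    axes = [np.linspace(0.5, b - 0.5, 24) for b in box]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    cav = cavity[0].contains(pts, frame, traj.topology)
    for f in fens:
        if np.any(cav & f.contains(pts, frame, traj.topology)):
            raise ValueError(
                f"region {f.name!r} overlaps the cavity; declarations must be disjoint"
            )


def _confirmed_visits(labels: Sequence[str], dwell: int) -> list[tuple[str, int, int]]:
    """Collapse a label trace to visits lasting >= dwell frames.

    Shorter excursions (boundary flicker) are discarded; "none" spans never
    form visits of their own and do not interrupt a region visit shorter
    than the dwell requirement on either side.
    """
    runs: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i))
            start = i
    visits = [(lab, a, b) for lab, a, b in runs if lab != "none" and b - a >= dwell]
    # merge consecutive confirmed visits to the same region
    merged: list[tuple[str, int, int]] = []
    for lab, a, b in visits:
        if merged and merged[-1][0] == lab:
            merged[-1] = (lab, merged[-1][1], b)
        else:
            merged.append((lab, a, b))
    return merged


def _match_route(
    sequence: tuple[str, ...], routes: Mapping[tuple[str, ...], str]
) -> str | None:
    for pattern, label in routes.items():
        if len(pattern) > len(sequence):
            continue
        tail = sequence[-len(pattern):]
        ok = True
        fen_used = None
        for pat, got in zip(pattern, tail):
            if pat.endswith("*"):
                if not got.startswith(pat[:-1]):
                    ok = False
                    break
                fen_used = got
            elif pat != got:
                ok = False
                break
        if ok:
            return fen_used if fen_used is not None else label
    return None


def detect_transit_events(
    traj: Trajectory,
    selection: str,
    regions: Sequence[RegionSpec],
    routes: Mapping[tuple[str, ...], str] | None = None,
    dwell: int = 2,
) -> tuple[list[TransitEvent], dict[str, dict[str, int]]]:
    """Detect cavity entry/exit events and how each pathway was used.

    Each molecule's confirmed visit sequence (dwell-filtered) is scanned:
    every transition into a visit of the ``cavity`` region is an entry
    event and every transition out of it an exit event. The pathway label
    comes from matching the preceding (entry) or following (exit) visit
    sequence against ``routes``; transitions matching no route are labeled
    ``"unresolved"``, never dropped. Returns the events plus a per-pathway
    usage summary with entry and exit counts.
    """
    routes = dict(DEFAULT_ROUTES if routes is None else routes)
    traces = region_trace(traj, selection, regions)
    events: list[TransitEvent] = []
    for mi, labels in enumerate(traces):
        visits = _confirmed_visits(labels, dwell)
        names = tuple(v[0] for v in visits)
        for vi, (lab, a, b) in enumerate(visits):
            if lab != "cavity":
                continue
            if vi > 0:
                pathway = _match_route(names[: vi + 1], routes) or "unresolved"
                events.append(
                    TransitEvent(mi, "entry", pathway, visits[vi - 1][2] - 1, a)
                )
            if vi < len(visits) - 1:
                # exit route = entry route read backwards
                rev = tuple(reversed(names[vi:]))
                pathway = _match_route(rev, routes) or "unresolved"
                events.append(
                    TransitEvent(mi, "exit", pathway, b - 1, visits[vi + 1][1])
                )
    usage: dict[str, dict[str, int]] = {}
    for ev in events:
        slot = usage.setdefault(ev.pathway, {"entry": 0, "exit": 0})
        slot[ev.direction] += 1
    return events, usage
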