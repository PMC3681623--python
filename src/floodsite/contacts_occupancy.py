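"""Contact tables, site occupancy, subunit symmetry and RMSD diagnostics.

A residue is "in contact" with the ligand in a frame when any ligand atom
sits within a cutoff (default 5 Å, minimum image) of any residue atom.
Contact frequencies (% of frames) are classified into three interaction
classes; the numeric thresholds are package conventions (the underlying
classification scheme is usually reported as colors, without numbers).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core_model import Frame, Trajectory, group_com, molecule_groups

__all__ = [
    "InteractionClass",
    "Episode",
    "OccupancySeries",
    "residue_contact_frequencies",
    "classify_interaction",
    "site_occupancy_series",
    "subunit_symmetry_table",
    "backbone_rmsd_series",
]


class InteractionClass(str, Enum):
    NON = "non"
    POSSIBLY = "possibly"
    LIKELY = "likely"


@dataclass(frozen=True)
class Episode:
    """One residence episode of one molecule inside a region: [enter, leave)."""

    molecule_index: int
    enter_frame: int
    leave_frame: int


@dataclass(frozen=True)
class OccupancySeries:
    """Per-frame count of molecules inside a region, plus residence episodes."""

    times: np.ndarray
    counts: np.ndarray
    episodes: tuple[Episode, ...]
    region_name: str

    def mean_occupancy(self) -> float:
        return float(self.counts.mean())


def _capped_contacts(
    lig_pos: np.ndarray, res_pos: np.ndarray, box: np.ndarray, cutoff: float
) -> bool:
    """Any ligand-residue atom pair within cutoff (minimum image)?

    Uses MDAnalysis's cell-list capped distance search, which guarantees
    all pairs below the cutoff are found.
    """
    from MDAnalysis.lib.distances import capped_distance

    dims = np.array([box[0], box[1], box[2], 90.0, 90.0, 90.0], dtype=np.float32)
    pairs = capped_distance(
        lig_pos.astype(np.float32),
        res_pos.astype(np.float32),
        max_cutoff=cutoff,
        box=dims,
        return_distances=False,
    )
    return len(pairs) > 0


def residue_contact_frequencies(
    traj: Trajectory,
    ligand_selection: str = "ligand",
    residues: Sequence[tuple[str, int]] | None = None,
    cutoff: float = 5.0,
    window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Contact frequency (% of frames) of each residue with any ligand atom.

    ``residues`` is a list of (subunit_id, residue_seq) pairs; by default
    every residue of the ``"protein"`` selection is scored. A frame counts
    as a contact frame for a residue when at least one ligand atom lies
    within ``cutoff`` of at least one residue atom (minimum image). The
    returned table has one row per residue with its frequency and
    interaction class.
    """
    top = traj.topology
    lig_ids = top.select(ligand_selection)
    if lig_ids.size == 0:
        raise ValueError("ligand selection is empty")
    if residues is None:
        prot = top.select("protein")
        if prot.size == 0:
            raise ValueError("no residues given and the protein selection is empty")
        seen: list[tuple[str, int]] = []
        for i in prot:
            key = (top.subunit_ids[i], int(top.residue_seq[i]))
            if key not in seen:
                seen.append(key)
        residues = seen
    if not residues:
        raise ValueError("residue set is empty")

    res_atoms = []
    for sub, seq in residues:
        ids = np.flatnonzero(
            (np.asarray(top.subunit_ids) == sub) & (top.residue_seq == seq)
        )
        if ids.size == 0:
            raise ValueError(f"residue ({sub}, {seq}) not found in topology")
        res_atoms.append(ids)

    lo, hi = window if window is not None else (0, traj.n_frames)
    if not (0 <= lo < hi <= traj.n_frames):
        raise ValueError("window outside trajectory")
    hits = np.zeros(len(residues), dtype=int)
    for frame in traj.frames[lo:hi]:
        lig_pos = frame.positions[lig_ids]
        for ri, ids in enumerate(res_atoms):
            if _capped_contacts(lig_pos, frame.positions[ids], frame.box, cutoff):
                hits[ri] += 1
    freq = 100.0 * hits / (hi - lo)
    rows = []
    for (sub, seq), ids, f in zip(residues, res_atoms, freq):
        rows.append(
            {
                "subunit_id": sub,
                "residue_seq": seq,
                "residue_name": top.residue_names[ids[0]],
                "contact_frequency_pct": f,
                "interaction": classify_interaction(f).value,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["cutoff"] = cutoff
    df.attrs["window"] = (lo, hi)
    return df


def classify_interaction(
    frequency: float, thresholds: tuple[float, float] = (10.0, 50.0)
) -> InteractionClass:
    """Three-way interaction class from a contact frequency in percent.

    non if f < f_low; possibly if f_low ≤ f < f_high; likely if f ≥ f_high.
    The defaults (10%, 50%) are package conventions, mandatory config in
    the pipeline.
    """
    f_low, f_high = thresholds
    if f_low >= f_high:
        raise ValueError("thresholds must satisfy f_low < f_high")
    if not 0.0 <= frequency <= 100.0:
        raise ValueError("frequency must be a percentage in [0, 100]")
    if frequency < f_low:
        return InteractionClass.NON
    if frequency < f_high:
        return InteractionClass.POSSIBLY
    return InteractionClass.LIKELY


def site_occupancy_series(
    traj: Trajectory,
    ligand_selection: str,
    site,
    debounce: int = 0,
) -> OccupancySeries:
    """Per-frame molecule count inside a site region plus residence episodes.

    Membership is by molecule COM. Episodes are maximal [enter, leave)
    frame spans per molecule; a molecule that re-enters within ``debounce``
    frames of leaving continues its previous episode.
    """
    from .cavity_pathway import RegionSpec  # local import to avoid a cycle

    if not isinstance(site, RegionSpec):
        raise TypeError("site must be a RegionSpec")
    groups = molecule_groups(traj.topology, ligand_selection)
    if not groups:
        raise ValueError("ligand selection has no molecules")
    inside = np.zeros((traj.n_frames, len(groups)), dtype=bool)
    for fi, frame in enumerate(traj.frames):
        coms = np.array([group_com(frame, g, traj.topology) for g in groups])
        inside[fi] = site.contains(coms, frame, traj.topology)
    episodes: list[Episode] = []
    for mi in range(len(groups)):
        col = inside[:, mi]
        spans = _runs(col)
        merged: list[list[int]] = []
        for a, b in spans:
            if merged and a - merged[-1][1] <= debounce:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        episodes.extend(Episode(mi, a, b) for a, b in merged)
    return OccupancySeries(
        times=traj.times,
        counts=inside.sum(axis=1),
        episodes=tuple(sorted(episodes, key=lambda e: (e.molecule_index, e.enter_frame))),
        region_name=site.name,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) spans of True runs."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def subunit_symmetry_table(
    occupancy_by_copy: Mapping[str, float],
    asymmetry_factor: float = 5.0,
    min_occupancy: float = 0.0,
) -> pd.DataFrame:
    """Compare mean occupancy across equivalent site copies.

    Flags the site "asymmetric" when the ratio of the largest to the
    smallest per-copy mean occupancy exceeds ``asymmetry_factor``.
    ``min_occupancy`` suppresses the flag for sites that are essentially
    empty everywhere (max below the floor). A pure ratio is used, so
    rescaling all occupancies together never changes the flag.
    """
    if len(occupancy_by_copy) < 2:
        raise ValueError("need at least two equivalent copies to compare")
    copies = sorted(occupancy_by_copy)
    values = np.array([occupancy_by_copy[c] for c in copies], dtype=float)
    if np.any(values < 0):
        raise ValueError("occupancies must be non-negative")
    vmax, vmin = values.max(), values.min()
    if vmax <= min_occupancy:
        asymmetric = False
        ratio = 1.0
    else:
        ratio = np.inf if vmin == 0 else vmax / vmin
        asymmetric = ratio > asymmetry_factor
    df = pd.DataFrame({"copy": copies, "mean_occupancy": values})
    df.attrs["asymmetric"] = bool(asymmetric)
    df.attrs["max_min_ratio"] = float(ratio)
    return df


def backbone_rmsd_series(
    traj: Trajectory,
    reference: Frame,
    selections: Sequence[str],
) -> pd.DataFrame:
    """RMSD of each selection vs a reference frame after optimal superposition.

    Each selection is least-squares superposed (Kabsch) onto its reference
    coordinates per frame, so global rigid motion contributes nothing.
    Returns a table with one column per selection label, times in ns.
    """
    if not selections:
        raise ValueError("no selections given")
    top = traj.topology
    out = {"time_ns": traj.times}
    for label in selections:
        ids = top.select(label)
        if ids.size == 0:
            raise ValueError(f"selection {label!r} is empty")
        ref = reference.positions[ids]
        if ref.shape[0] != ids.size:
            raise ValueError("reference frame does not match topology")
        ref_c = ref - ref.mean(axis=0)
        vals = []
        for frame in traj.frames:
            mob = frame.positions[ids]
            mob_c = mob - mob.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref_c, mob_c)
            aligned = rot.apply(mob_c)
            vals.append(float(np.sqrt(((aligned - ref_c) ** 2).sum(axis=1).mean())))
        out[label] = np.array(vals)
    return pd.DataFrame(out)
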