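"""Membrane-partitioning diagnostics and concentration accounting.

A flooding run starts with all ligand copies in the aqueous phase; the
analyses here quantify how they partition into the bilayer: the number
density profile of ligand centers of mass along the bilayer normal (z),
per-frame aqueous/membrane phase counts, equilibration detection, and the
conversion between mean solute counts and molar concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import Trajectory, group_com, minimum_image, molecule_groups

__all__ = [
    "DensityProfile",
    "PhaseSeries",
    "WATER_MOLARITY",
    "z_density_profile",
    "phase_count_series",
    "concentration_from_counts",
    "detect_equilibration",
]

#: Molarity of pure water (mol/L); used to convert count ratios to molar
#: concentration. Exposed so a different solvent convention can be used.
WATER_MOLARITY = 55.5


@dataclass(frozen=True)
class DensityProfile:
    """COM number density along z: counts/Å per bin, per-frame normalized."""

    edges: np.ndarray  # (n_bins + 1,) Å, in bilayer-centered coordinates
    density: np.ndarray  # (n_bins,) counts/Å averaged over the window
    window: tuple[int, int]  # [start, stop) frame indices averaged

    @property
    def integral(self) -> float:
        """∫ density dz — equals the mean molecule count in the window."""
        return float(np.sum(self.density * np.diff(self.edges)))


@dataclass(frozen=True)
class PhaseSeries:
    """Per-frame aqueous/membrane molecule counts."""

    times: np.ndarray  # ns
    n_aqueous: np.ndarray
    n_membrane: np.ndarray
    membrane_z: tuple[float, float]  # bilayer-centered interval

    def mean_aqueous(self, window: tuple[int, int] | None = None) -> float:
        lo, hi = window if window is not None else (0, len(self.times))
        if hi <= lo:
            raise ValueError("empty averaging window")
        return float(self.n_aqueous[lo:hi].mean())


def _com_z_per_frame(
    traj: Trajectory, selection: str, center_on: str | None
) -> np.ndarray:
    """(n_frames, n_molecules) COM z in bilayer-centered coordinates.

    The bilayer midplane is taken from the COM of ``center_on`` (e.g. a
    lipid selection) when given; otherwise the box z-midpoint is used, and
    z coordinates are reported relative to it via the minimum image.
    """
    groups = molecule_groups(traj.topology, selection)
    if not groups:
        raise ValueError(f"selection {selection!r} contains no molecules")
    center_groups = (
        [traj.topology.select(center_on)] if center_on else None
    )
    out = np.empty((traj.n_frames, len(groups)))
    for fi, frame in enumerate(traj.frames):
        lz = frame.box[2]
        if center_groups is not None:
            mid = group_com(frame, center_groups[0], traj.topology)[2]
        else:
            mid = lz / 2.0
        for mi, g in enumerate(groups):
            z = group_com(frame, g, traj.topology)[2]
            out[fi, mi] = minimum_image(np.array([0.0, 0.0, z - mid]), frame.box)[2]
    return out


def z_density_profile(
    traj: Trajectory,
    selection: str = "ligand",
    bin_width: float = 1.0,
    window: tuple[int, int] | None = None,
    center_on: str | None = None,
) -> DensityProfile:
    """Histogram of molecule-COM z positions, averaged over a frame window.

    The profile is normalized per frame, so its integral over z equals the
    mean molecule count (conservation). z is bilayer-centered: the midplane
    sits at z = 0.
    """
    lo, hi = window if window is not None else (0, traj.n_frames)
    if hi <= lo:
        raise ValueError("empty frame window")
    zs = _com_z_per_frame(traj, selection, center_on)[lo:hi]
    lz = traj.frames[lo].box[2]
    n_bins = max(1, int(np.ceil(lz / bin_width)))
    edges = np.linspace(-lz / 2, lz / 2, n_bins + 1)
    counts, _ = np.histogram(zs.ravel(), bins=edges)
    n_frames = hi - lo
    density = counts / n_frames / np.diff(edges)
    return DensityProfile(edges=edges, density=density, window=(lo, hi))


def phase_count_series(
    traj: Trajectory,
    selection: str = "ligand",
    membrane_z: tuple[float, float] = (-15.0, 15.0),
    center_on: str | None = None,
) -> PhaseSeries:
    """Classify each molecule's COM per frame as membrane or aqueous.

    ``membrane_z`` is the slab interval in bilayer-centered coordinates;
    everything outside it counts as aqueous, so the two phases tile the box
    and the counts sum to the number of molecules.
    """
    z_lo, z_hi = membrane_z
    if z_hi <= z_lo:
        raise ValueError("membrane interval is degenerate")
    lz = traj.frames[0].box[2]
    if z_lo < -lz / 2 or z_hi > lz / 2:
        raise ValueError("membrane interval must lie inside the box")
    zs = _com_z_per_frame(traj, selection, center_on)
    in_mem = (zs >= z_lo) & (zs <= z_hi)
    n_mem = in_mem.sum(axis=1)
    n_aq = zs.shape[1] - n_mem
    return PhaseSeries(
        times=traj.times,
        n_aqueous=n_aq.astype(int),
        n_membrane=n_mem.astype(int),
        membrane_z=membrane_z,
    )


def concentration_from_counts(
    n_solute: float,
    n_water: float,
    water_molarity: float = WATER_MOLARITY,
) -> float:
    """Molar concentration from mean solute count per water count.

    Uses the count convention: c = (n_solute / n_water) × [water].
    For 145 solute copies among 25310 waters this gives 0.318 M, and a
    mean of 0.4 copies gives 0.88 mM.
    """
    if n_water <= 0:
        raise ValueError("water count must be positive")
    if n_solute < 0:
        raise ValueError("solute count must be non-negative")
    return n_solute / n_water * water_molarity


def detect_equilibration(
    series: PhaseSeries,
    window_frames: int | None = None,
    tolerance: float = 1.0,
    fixed_fraction: float | None = None,
) -> int | None:
    """First frame after which the aqueous count has stopped drifting.

    Compares means of consecutive windows of ``window_frames`` frames and
    returns the first start index where successive window means differ by
    less than ``tolerance`` (in molecules). With ``fixed_fraction`` set, a
    fixed cut of that fraction of frames is returned instead (the common
    discard-the-first-portion convention). Returns ``None`` when the series
    never settles, rather than a silent guess.
    """
    n = len(series.times)
    if n < 10:
        raise ValueError("need at least 10 frames to judge equilibration")
    if fixed_fraction is not None:
        if not 0 <= fixed_fraction < 1:
            raise ValueError("fixed_fraction must lie in [0, 1)")
        return int(np.floor(fixed_fraction * n))
    w = window_frames if window_frames is not None else max(2, n // 10)
    x = series.n_aqueous.astype(float)
    starts = range(0, n - 2 * w + 1)
    diffs = np.array(
        [abs(x[s + w : s + 2 * w].mean() - x[s : s + w].mean()) for s in starts]
    )
    settled = diffs < tolerance
    if not settled.any():
        return None
    # first start from which every later window pair is also settled
    unsettled = np.flatnonzero(~settled)
    first = 0 if unsettled.size == 0 else int(unsettled[-1]) + 1
    if first >= len(diffs):
        return None
    return first
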