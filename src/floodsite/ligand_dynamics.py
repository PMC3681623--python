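"""Translational diffusion and rotational relaxation of ligand molecules.

Translational diffusion coefficients come from the mean-squared
displacement averaged over molecules and time origins, D = slope/6 in
three dimensions. Rotational relaxation times come from the Legendre
autocorrelation C_ℓ(τ) = ⟨P_ℓ(u(t)·u(t+τ))⟩ of a fixed molecular axis,
fit to a single exponential over the decay range C_ℓ ∈ [0.8, 0.1]
(ℓ = 2 by default, the order probed by most spectroscopies). For
isotropic rotational diffusion C_ℓ(τ) = exp(−ℓ(ℓ+1) D_r τ), so
τ_ℓ = 1/(ℓ(ℓ+1) D_r).

All MSD input traces must be unwrapped (no periodic jumps); a jump larger
than half a box edge is detected and rejected with advice to unwrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_model import Trajectory, group_com, molecule_groups, unwrap_traces

__all__ = [
    "MsdCurve",
    "DiffusionFit",
    "RotationalResult",
    "com_traces",
    "compute_msd",
    "msd_over_segments",
    "site_msd",
    "fit_diffusion",
    "rotational_relaxation",
    "simulate_rotational_diffusion",
]


@dataclass(frozen=True)
class MsdCurve:
    lags: np.ndarray  # ns
    msd: np.ndarray  # Å²
    n_pairs: np.ndarray  # samples averaged per lag


@dataclass(frozen=True)
class DiffusionFit:
    d: float  # Å²/ns
    intercept: float  # Å², diagnostic
    window: tuple[float, float]  # ns
    clipped_negative: bool  # True when the raw slope was negative


@dataclass(frozen=True)
class RotationalResult:
    tau: float | None  # ps-equivalent of the lag unit; None if not relaxed
    relaxed: bool
    order: int
    lags: np.ndarray
    acf: np.ndarray


def com_traces(
    traj: Trajectory, selection: str = "ligand", unwrap: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """(traces, times): per-molecule COM series (n_mol, n_frames, 3).

    Wrapped trajectory coordinates are unwrapped by minimum-image
    accumulation so MSD can be computed on them.
    """
    groups = molecule_groups(traj.topology, selection)
    if not groups:
        raise ValueError(f"selection {selection!r} has no molecules")
    traces = np.empty((len(groups), traj.n_frames, 3))
    for fi, frame in enumerate(traj.frames):
        for mi, g in enumerate(groups):
            traces[mi, fi] = group_com(frame, g, traj.topology)
    if unwrap:
        traces = unwrap_traces(traces, traj.frames[0].box)
    return traces, traj.times


def compute_msd(
    traces: np.ndarray,
    lags: Sequence[int],
    dt: float = 1.0,
    box: np.ndarray | None = None,
) -> MsdCurve:
    """MSD(τ) averaged over molecules and all time origins.

    ``traces`` is (n_mol, n_frames, 3) of unwrapped positions; ``lags``
    are frame offsets and ``dt`` the frame spacing in ns. When a box is
    supplied, traces are checked for wrap-around jumps first.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim == 2:
        traces = traces[None]
    n_mol, n_frames, _ = traces.shape
    if n_frames < 2:
        raise ValueError("need at least two frames")
    if box is not None:
        jumps = np.abs(np.diff(traces, axis=1))
        if np.any(jumps > np.asarray(box) / 2):
            raise ValueError(
                "traces contain jumps larger than half a box edge; "
                "unwrap them (see unwrap_traces) before computing the MSD"
            )
    lags = np.asarray(sorted(set(int(l) for l in lags)))
    if np.any(lags < 0) or np.any(lags >= n_frames):
        raise ValueError("lags must lie in [0, n_frames)")
    msd = np.empty(lags.size)
    n_pairs = np.empty(lags.size, dtype=int)
    for i, lag in enumerate(lags):
        if lag == 0:
            msd[i] = 0.0
            n_pairs[i] = n_mol * n_frames
            continue
        disp = traces[:, lag:, :] - traces[:, :-lag, :]
        msd[i] = float((disp**2).sum(axis=2).mean())
        n_pairs[i] = disp.shape[0] * disp.shape[1]
    return MsdCurve(lags=lags * dt, msd=msd, n_pairs=n_pairs)


def msd_over_segments(
    segments: Sequence[np.ndarray],
    lags: Sequence[int],
    dt: float = 1.0,
) -> MsdCurve:
    """MSD averaged over independent trace segments of unequal length.

    Used for per-site dynamics: each segment is one residence episode of
    one molecule inside the site, so displacement origins never cross an
    episode boundary. Lags longer than a segment simply draw no samples
    from it.
    """
    lags = np.asarray(sorted(set(int(l) for l in lags)))
    if np.any(lags < 0):
        raise ValueError("lags must be non-negative")
    sums = np.zeros(lags.size)
    counts = np.zeros(lags.size, dtype=int)
    for seg in segments:
        seg = np.asarray(seg, dtype=float)
        if seg.ndim != 2 or seg.shape[1] != 3:
            raise ValueError("each segment must be (n_frames, 3)")
        for i, lag in enumerate(lags):
            if lag == 0:
                counts[i] += seg.shape[0]
                continue
            if lag >= seg.shape[0]:
                continue
            disp = seg[lag:] - seg[:-lag]
            sums[i] += float((disp**2).sum())
            counts[i] += disp.shape[0]
    if not np.any(counts[lags > 0] > 0):
        raise ValueError("no segment is longer than the shortest positive lag")
    msd = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    return MsdCurve(lags=lags * dt, msd=msd, n_pairs=counts)


def site_msd(
    traj: Trajectory,
    selection: str,
    site,
    lags: Sequence[int],
    debounce: int = 0,
) -> MsdCurve:
    """MSD of molecules while resident inside a site region.

    Residence episodes come from the occupancy analysis; each episode's
    unwrapped COM trace is one segment for :func:`msd_over_segments`.
    """
    from .contacts_occupancy import site_occupancy_series

    occ = site_occupancy_series(traj, selection, site, debounce=debounce)
    traces, times = com_traces(traj, selection)
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    segments = [
        traces[ep.molecule_index, ep.enter_frame : ep.leave_frame]
        for ep in occ.episodes
        if ep.leave_frame - ep.enter_frame >= 2
    ]
    if not segments:
        raise ValueError(f"no residence episodes in region {occ.region_name!r}")
    return msd_over_segments(segments, lags, dt=dt)


def fit_diffusion(
    curve: MsdCurve, window: tuple[float, float] | None = None
) -> DiffusionFit:
    """D = slope/6 from a least-squares line through an MSD lag window.

    Default window: lags between 10% and 50% of the longest lag (short
    lags are noise-dominated, long lags origin-starved). A negative fitted
    slope yields D = 0 with ``clipped_negative`` set, never a negative D.
    """
    if window is None:
        tmax = curve.lags.max()
        window = (0.1 * tmax, 0.5 * tmax)
    lo, hi = window
    mask = (curve.lags >= lo) & (curve.lags <= hi)
    if mask.sum() < 3:
        raise ValueError("fit window must contain at least 3 lag points")
    slope, intercept = np.polyfit(curve.lags[mask], curve.msd[mask], 1)
    clipped = slope < 0
    return DiffusionFit(
        d=0.0 if clipped else float(slope / 6.0),
        intercept=float(intercept),
        window=(float(lo), float(hi)),
        clipped_negative=bool(clipped),
    )


def _legendre(order: int, x: np.ndarray) -> np.ndarray:
    if order == 1:
        return x
    if order == 2:
        return 1.5 * x**2 - 0.5
    raise ValueError("legendre order must be 1 or 2")


def rotational_relaxation(
    orientations: np.ndarray,
    order: int = 2,
    dt: float = 1.0,
    fit_range: tuple[float, float] = (0.1, 0.8),
    max_lag: int | None = None,
) -> RotationalResult:
    """Rotational relaxation time from the Legendre orientation ACF.

    ``orientations`` is (n_frames, 3) or (n_mol, n_frames, 3) of unit
    vectors. C_ℓ(τ) is averaged over molecules and time origins; τ comes
    from a log-linear single-exponential fit restricted to lags where
    C_ℓ lies inside ``fit_range``. A frozen axis (C ≡ 1) returns the
    not-relaxed sentinel instead of a number.
    """
    u = np.asarray(orientations, dtype=float)
    if u.ndim == 2:
        u = u[None]
    norms = np.linalg.norm(u, axis=-1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("orientations must be unit vectors")
    n_mol, n_frames, _ = u.shape
    max_lag = max_lag if max_lag is not None else n_frames - 1
    lags = np.arange(0, max_lag + 1)
    acf = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag == 0:
            acf[i] = float(_legendre(order, np.ones(1))[0])
            continue
        dots = np.einsum("mtk,mtk->mt", u[:, lag:], u[:, :-lag])
        acf[i] = float(_legendre(order, np.clip(dots, -1.0, 1.0)).mean())
    c_lo, c_hi = fit_range
    mask = (acf <= c_hi) & (acf >= c_lo) & (lags > 0)
    if mask.sum() < 2:
        # never decayed into the fit range: the axis is (effectively) frozen
        return RotationalResult(
            tau=None, relaxed=False, order=order, lags=lags * dt, acf=acf
        )
    t = lags[mask] * dt
    slope, _ = np.polyfit(t, np.log(acf[mask]), 1)
    if slope >= 0:
        return RotationalResult(
            tau=None, relaxed=False, order=order, lags=lags * dt, acf=acf
        )
    return RotationalResult(
        tau=float(-1.0 / slope),
        relaxed=True,
        order=order,
        lags=lags * dt,
        acf=acf,
    )


def simulate_rotational_diffusion(
    d_rot: float,
    dt: float,
    n_frames: int,
    n_mol: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Unit-vector traces under isotropic rotational diffusion.

    Small-step tangent-kick propagation on the sphere: each step adds a
    Gaussian kick of variance 2·D_r·dt in the tangent plane and
    renormalizes; exact in the dt → 0 limit. Used both by tests (closed
    form τ_ℓ = 1/(ℓ(ℓ+1)D_r)) and by the 3-atom synthetic ligand.
    """
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n_mol, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    amp = np.sqrt(2.0 * d_rot * dt)
    out = np.empty((n_mol, n_frames, 3))
    out[:, 0] = u
    for t in range(1, n_frames):
        kick = amp * rng.standard_normal((n_mol, 3))
        kick -= (kick * u).sum(axis=1, keepdims=True) * u
        u = u + kick
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        out[:, t] = u
    return out
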