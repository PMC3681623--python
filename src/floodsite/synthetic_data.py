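"""Synthetic trajectories, cavity series and FEP samples with known truth.

The generator produces the three kinds of data every downstream stage
consumes, each with a planted ground truth so recovery can be tested:

* **Flooding trajectories** — ligand pseudo-particles evolved by overdamped
  (Brownian) Langevin dynamics in a potential composed of a membrane slab
  well plus isotropic Gaussian binding-site wells, in a periodic
  orthorhombic box. All ligands start in the aqueous phase and partition
  into the slab, emulating a flooding simulation of a membrane protein.
* **Cavity occupancy series** — paired (water count, ligand count) traces in
  which each bound ligand displaces a fixed number of waters, plus noise.
* **FEP window samples** — per-window energy-difference samples from models
  (Gaussian or harmonic) whose total free-energy difference is analytic.

Energies are in units of kT (kT = 1) inside the trajectory generator;
FEP samples are in kcal/mol since that is the bookkeeping unit downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import trapezoid

from .core_model import Frame, Topology, Trajectory, minimum_image, wrap_positions
from .free_energy import GAS_CONSTANT_KCAL, FepWindow

__all__ = [
    "SiteSpec",
    "FloodingConfig",
    "GroundTruth",
    "generate_flooding_trajectory",
    "generate_cavity_series",
    "generate_fep_windows",
    "slab_potential",
    "aqueous_fraction_boltzmann",
]


@dataclass(frozen=True)
class SiteSpec:
    """A planted binding site: isotropic Gaussian well."""

    center: tuple[float, float, float]
    width: float  # Å, Gaussian sigma of the well
    depth: float  # kT, well depth (>= 0)


@dataclass(frozen=True)
class FloodingConfig:
    """Parameters of the synthetic flooding run.

    Defaults emulate the study conditions this package targets: 145 ligand
    copies flooding a membrane-bound system, near-complete partitioning into
    a central membrane slab, and a handful of localized high-affinity sites.
    The box is smaller than an all-atom system (the ligands are single
    pseudo-particles) so equilibration happens within the generated window.
    """

    n_ligands: int = 145
    n_frames: int = 500
    dt: float = 0.005  # ns, integration step
    save_every: int = 10  # frames saved every save_every steps
    box: tuple[float, float, float] = (60.0, 60.0, 90.0)
    membrane_z: tuple[float, float] = (-15.0, 15.0)  # slab, box-centered coords
    eps_mem: float = 6.6  # kT, slab depth: near-complete membrane partitioning
    # (Boltzmann aqueous fraction ~0.3% -> ~0.4 of 145 ligands in water)
    slab_edge_width: float = 2.0  # Å, smoothness of the slab edges
    sites: tuple[SiteSpec, ...] = ()
    d_free: float = 100.0  # Å²/ns, free (aqueous) diffusion coefficient
    ligand_atoms: Literal[1, 3] = 1
    bond_length: float = 1.5  # Å, arm length of the rigid 3-atom ligand
    d_rot: float = 50.0  # rad²/ns, rotational diffusion of the 3-atom ligand
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if any(s.depth < 0 for s in self.sites):
            raise ValueError("site depths must be >= 0")
        if any(s.width <= 0 for s in self.sites):
            raise ValueError("site widths must be > 0")
        half = np.asarray(self.box) / 2
        for s in self.sites:
            if np.any(np.abs(np.asarray(s.center)) > half):
                raise ValueError(f"site center {s.center} lies outside the box")
        if self.eps_mem < 0:
            raise ValueError("membrane well depth must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters of a synthetic run, for recovery tests."""

    site_centers: tuple[tuple[float, float, float], ...]
    site_depths: tuple[float, ...]
    site_widths: tuple[float, ...]
    d_free: float
    expected_aqueous_fraction: float
    displacement_ratio: float | None
    seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def slab_potential(
    z: np.ndarray, membrane_z: tuple[float, float], eps: float, edge: float
) -> np.ndarray:
    """Smooth membrane slab well, −eps inside [z_lo, z_hi], 0 outside (kT)."""
    z_lo, z_hi = membrane_z
    return -0.5 * eps * (np.tanh((z - z_lo) / edge) - np.tanh((z - z_hi) / edge))


def _slab_gradient(
    z: np.ndarray, membrane_z: tuple[float, float], eps: float, edge: float
) -> np.ndarray:
    z_lo, z_hi = membrane_z
    return (
        -0.5
        * eps
        / edge
        * (np.cosh((z - z_lo) / edge) ** -2 - np.cosh((z - z_hi) / edge) ** -2)
    )


def _total_gradient(pos: np.ndarray, cfg: FloodingConfig) -> np.ndarray:
    """∇U (kT/Å) at box-centered positions, slab + Gaussian wells, periodic."""
    box = np.asarray(cfg.box)
    grad = np.zeros_like(pos)
    zc = minimum_image(pos[:, 2], box[2])
    grad[:, 2] += _slab_gradient(zc, cfg.membrane_z, cfg.eps_mem, cfg.slab_edge_width)
    for s in cfg.sites:
        d = minimum_image(pos - np.asarray(s.center), box)
        r2 = (d * d).sum(axis=1)
        u = -s.depth * np.exp(-0.5 * r2 / s.width**2)
        grad += (-u / s.width**2)[:, None] * d
    return grad


def _max_gradient(cfg: FloodingConfig) -> float:
    g = cfg.eps_mem / (2 * cfg.slab_edge_width)
    for s in cfg.sites:
        g = max(g, s.depth * np.exp(-0.5) / s.width)
    return g


def aqueous_fraction_boltzmann(cfg: FloodingConfig, n_grid: int = 20001) -> float:
    """Equilibrium aqueous fraction from 1-D Boltzmann integration over z.

    Exact for the slab-only potential; site wells are localized and carry
    negligible volume relative to the slab, so they are omitted here (the
    configurations used for partitioning oracles plant no sites).
    """
    lz = cfg.box[2]
    z = np.linspace(-lz / 2, lz / 2, n_grid)
    w = np.exp(-slab_potential(z, cfg.membrane_z, cfg.eps_mem, cfg.slab_edge_width))
    in_slab = (z >= cfg.membrane_z[0]) & (z <= cfg.membrane_z[1])
    total = trapezoid(w, z)
    membrane = trapezoid(np.where(in_slab, w, 0.0), z)
    return float((total - membrane) / total)


def _ligand_topology(cfg: FloodingConfig) -> Topology:
    names: list[str] = []
    res_seq: list[int] = []
    res_names: list[str] = []
    per = cfg.ligand_atoms
    atom_names = ["X1"] if per == 1 else ["X1", "X2", "X3"]
    for mol in range(cfg.n_ligands):
        for nm in atom_names:
            names.append(nm)
            res_seq.append(mol + 1)
            res_names.append("LIG")
    n = len(names)
    return Topology(
        names=tuple(names),
        masses=np.ones(n),
        residue_seq=np.array(res_seq),
        residue_names=tuple(res_names),
        subunit_ids=tuple("L" for _ in range(n)),
        selections={
            "ligand": np.arange(n),
            "protein": np.array([], dtype=int),
            "water_oxygen": np.array([], dtype=int),
        },
    )


def generate_flooding_trajectory(
    cfg: FloodingConfig,
) -> tuple[Trajectory, GroundTruth]:
    """Evolve ligand pseudo-particles by Brownian dynamics in the box.

    Update rule per step: ``x ← x − D ∇U dt / kT + sqrt(2 D dt) ξ`` with
    kT = 1 and ξ standard normal. Noise is drawn from one independent,
    counter-based stream per molecule (spawned from the config seed), so
    the output is bit-identical for identical (config, seed) regardless of
    how the generation is batched.

    Ligands start uniformly distributed in the aqueous region. Saved frame
    positions are wrapped into the primary image ``[0, L)``; the slab and
    all site centers are specified in box-centered coordinates and are
    reported in the ground truth wrapped to the same primary image.
    """
    max_step = cfg.d_free * cfg.dt * _max_gradient(cfg)
    min_width = min(
        [cfg.slab_edge_width] + [s.width for s in cfg.sites]
    )
    if max_step > min_width / 2:
        raise ValueError(
            f"dt={cfg.dt} ns is too large for stability: drift per step "
            f"{max_step:.3g} Å exceeds half the narrowest feature width "
            f"{min_width / 2:.3g} Å; reduce dt"
        )

    box = np.asarray(cfg.box, dtype=float)
    ss = np.random.SeedSequence(cfg.seed)
    mol_streams = [np.random.Generator(np.random.Philox(s)) for s in ss.spawn(cfg.n_ligands + 1)]
    init_rng = mol_streams[-1]

    # start in the aqueous phase: z uniform outside the slab (box-centered)
    lz = box[2]
    z_lo, z_hi = cfg.membrane_z
    aq_len_low = z_lo - (-lz / 2)
    aq_len_high = lz / 2 - z_hi
    pos = np.empty((cfg.n_ligands, 3))
    pos[:, 0] = init_rng.uniform(-box[0] / 2, box[0] / 2, cfg.n_ligands)
    pos[:, 1] = init_rng.uniform(-box[1] / 2, box[1] / 2, cfg.n_ligands)
    u = init_rng.uniform(0, aq_len_low + aq_len_high, cfg.n_ligands)
    pos[:, 2] = np.where(u < aq_len_low, -lz / 2 + u, z_hi + (u - aq_len_low))

    n_steps = cfg.n_frames * cfg.save_every
    # per-molecule translational noise, pre-drawn from independent streams
    noise = np.empty((n_steps, cfg.n_ligands, 3))
    for m in range(cfg.n_ligands):
        noise[:, m, :] = mol_streams[m].standard_normal((n_steps, 3))

    orient = None
    rot_noise = None
    if cfg.ligand_atoms == 3:
        orient = _random_unit(init_rng, cfg.n_ligands)
        rot_noise = np.empty((n_steps, cfg.n_ligands, 3))
        for m in range(cfg.n_ligands):
            rot_noise[:, m, :] = mol_streams[m].standard_normal((n_steps, 3))

    amp = np.sqrt(2 * cfg.d_free * cfg.dt)
    rot_amp = np.sqrt(2 * cfg.d_rot * cfg.dt)
    frames: list[Frame] = []
    step = 0
    for frame_idx in range(cfg.n_frames):
        for _ in range(cfg.save_every):
            grad = _total_gradient(pos, cfg)
            pos = pos - cfg.d_free * cfg.dt * grad + amp * noise[step]
            pos = minimum_image(pos, box)  # keep box-centered
            if orient is not None:
                kick = rot_amp * rot_noise[step]
                kick -= (kick * orient).sum(axis=1, keepdims=True) * orient
                orient = orient + kick
                orient /= np.linalg.norm(orient, axis=1, keepdims=True)
            step += 1
        frames.append(
            Frame(
                time=(frame_idx + 1) * cfg.dt * cfg.save_every,
                box=box.copy(),
                positions=_assemble_positions(pos, orient, cfg, box),
            )
        )

    top = _ligand_topology(cfg)
    truth = GroundTruth(
        site_centers=tuple(
            tuple(np.round(wrap_positions(np.asarray(s.center) + box / 2, box), 6))
            for s in cfg.sites
        ),
        site_depths=tuple(s.depth for s in cfg.sites),
        site_widths=tuple(s.width for s in cfg.sites),
        d_free=cfg.d_free,
        expected_aqueous_fraction=aqueous_fraction_boltzmann(cfg),
        displacement_ratio=None,
        seed=cfg.seed,
    )
    return Trajectory(topology=top, frames=frames), truth


def _random_unit(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _assemble_positions(
    com: np.ndarray, orient: np.ndarray | None, cfg: FloodingConfig, box: np.ndarray
) -> np.ndarray:
    """Box-centered COMs → saved atom positions wrapped into [0, L).

    The generator's internal frame puts the slab midplane at z = 0; saved
    coordinates shift it to z = L/2, the convention the analyses expect
    (midplane at the box z-midpoint).
    """
    if orient is None:
        return wrap_positions(com + box / 2, box)
    arms = cfg.bond_length * orient
    atoms = np.stack([com - arms, com, com + arms], axis=1)  # (n, 3 atoms, 3)
    return wrap_positions(atoms.reshape(-1, 3) + box / 2, box)


# ---------------------------------------------------------------------------
# cavity desolvation series
# ---------------------------------------------------------------------------

def generate_cavity_series(
    baseline_waters: float,
    displacement_ratio: float,
    ligand_trace: Sequence[int],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (n_water, n_ligand) per-frame counts for a closed cavity.

    ``n_water(t) = round(baseline − ratio · n_ligand(t) + ε)`` with
    ε ~ Normal(0, noise_sd), clipped at zero.
    """
    if baseline_waters < 0 or displacement_ratio < 0:
        raise ValueError("baseline and displacement ratio must be non-negative")
    trace = np.asarray(ligand_trace, dtype=float)
    if baseline_waters < displacement_ratio * trace.max():
        raise ValueError(
            "baseline must cover ratio * max(ligand trace); the cavity "
            "cannot hold negative mean water counts"
        )
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, trace.shape) if noise_sd > 0 else 0.0
    waters = np.round(baseline_waters - displacement_ratio * trace + noise)
    return np.clip(waters, 0, None), trace.astype(int)


# ---------------------------------------------------------------------------
# FEP window samples
# ---------------------------------------------------------------------------

def generate_fep_windows(
    schedule: Sequence[float],
    n_samples: int,
    temperature: float = 300.0,
    system: Literal["gaussian", "harmonic"] = "gaussian",
    mu: float | Sequence[float] = 0.0,
    sigma: float | Sequence[float] = 0.5,
    k_start: float = 1.0,
    k_end: float = 4.0,
    seed: int = 0,
) -> tuple[list[FepWindow], float]:
    """Per-window ΔU samples with an analytic total free-energy difference.

    ``gaussian``: window *i* draws ΔU ~ Normal(mu_i, sigma_i) (kcal/mol);
    its exact free energy is ``mu_i − sigma_i² / (2 RT)``.

    ``harmonic``: the coupling interpolates a harmonic spring constant
    geometrically from ``k_start`` to ``k_end`` (kcal/mol/Å²); window *i*
    samples x ~ Normal(0, RT/k_i) and ΔU = ½(k_{i+1} − k_i) x², with exact
    window free energy ``(RT/2) ln(k_{i+1}/k_i)``.
    """
    schedule = list(schedule)
    if schedule[0] != 0.0 or schedule[-1] != 1.0 or np.any(np.diff(schedule) <= 0):
        raise ValueError("schedule must increase strictly from 0 to 1")
    n_windows = len(schedule) - 1
    rt = GAS_CONSTANT_KCAL * temperature
    rng = np.random.default_rng(seed)
    windows: list[FepWindow] = []

    if system == "gaussian":
        mu_arr = np.broadcast_to(np.asarray(mu, dtype=float), (n_windows,))
        sig_arr = np.broadcast_to(np.asarray(sigma, dtype=float), (n_windows,))
        if np.any(sig_arr < 0):
            raise ValueError("sigma must be >= 0")
        total = float(np.sum(mu_arr - sig_arr**2 / (2 * rt)))
        for i in range(n_windows):
            du = rng.normal(mu_arr[i], sig_arr[i], n_samples)
            windows.append(
                FepWindow(schedule[i], schedule[i + 1], du, temperature)
            )
    elif system == "harmonic":
        if k_start <= 0 or k_end <= 0:
            raise ValueError("spring constants must be positive")
        lam = np.asarray(schedule)
        k = k_start * (k_end / k_start) ** lam
        total = float(0.5 * rt * np.log(k_end / k_start))
        for i in range(n_windows):
            x = rng.normal(0.0, np.sqrt(rt / k[i]), n_samples)
            du = 0.5 * (k[i + 1] - k[i]) * x**2
            windows.append(
                FepWindow(schedule[i], schedule[i + 1], du, temperature)
            )
    else:
        raise ValueError(f"unknown system {system!r}")
    return windows, total
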