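"""Free-energy perturbation (FEP) bookkeeping for ligand binding.

Implements the binding free-energy decomposition used in flooding studies
of anesthetic binding:

    ΔG_bind = ΔG_gas→prot − (ΔG_solv + ΔG_rstr)
    ΔG_rstr = RT ln(V_rstr / V_1M)

where ΔG_gas→prot is the gas-phase → protein-site transfer free energy,
ΔG_solv the ligand solvation free energy, and ΔG_rstr the entropic cost of
confining the ligand from the 1 M standard-state volume V_1M to the
restraint volume V_rstr used during decoupling. The per-window estimator
is forward exponential averaging (Zwanzig): ΔG_i = −RT ln⟨exp(−ΔU/RT)⟩.

Units: energies in kcal/mol, volumes in Å³, temperature in K.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "GAS_CONSTANT_KCAL",
    "STANDARD_STATE_VOLUME",
    "WATER_TO_DODECANE_TRANSFER_DG",
    "FepWindow",
    "FepEstimate",
    "FreeEnergyComponents",
    "lambda_schedule",
    "fep_exponential_estimate",
    "restraint_correction",
    "combine_binding_dg",
    "kd_from_dg",
    "read_windows_csv",
]

#: Gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL = 1.98720e-3

#: Volume per molecule at a 1 M concentration (Å³): 1e27 / N_A.
STANDARD_STATE_VOLUME = 1660.5

#: Transfer free energy of the reference anesthetic from water to dodecane
#: (kcal/mol). Documented constant used in the lipid-partitioning argument:
#: a hydrophobic-phase affinity this weak relative to the protein sites means
#: membrane partitioning has only a marginal effect on the apparent Kd.
#: It is a recorded literature value, not something this package computes.
WATER_TO_DODECANE_TRANSFER_DG = 3.0


@dataclass(frozen=True)
class FepWindow:
    """Energy-difference samples for one coupling window λ_from → λ_to."""

    lam_from: float
    lam_to: float
    delta_u: np.ndarray  # kcal/mol
    temperature: float = 300.0

    def __post_init__(self) -> None:
        du = np.atleast_1d(np.asarray(self.delta_u, dtype=float))
        if du.size < 1:
            raise ValueError("a window needs at least one ΔU sample")
        if self.lam_from == self.lam_to:
            raise ValueError("λ_from and λ_to must differ")
        object.__setattr__(self, "delta_u", du)


@dataclass(frozen=True)
class FepEstimate:
    """Total ΔG with per-window contributions and sampling diagnostics."""

    dg_total: float
    per_window: tuple[float, ...]
    n_samples: tuple[int, ...]
    mean_du: tuple[float, ...]
    std_du: tuple[float, ...]


@dataclass(frozen=True)
class FreeEnergyComponents:
    """Audit record of a binding free-energy combination."""

    dg_gas_to_prot: float
    dg_solv: float
    dg_rstr: float
    dg_bind: float
    v_rstr: float | None = None
    v_1m: float = STANDARD_STATE_VOLUME
    temperature: float = 300.0

    def to_dict(self) -> dict:
        return {
            "dg_gas_to_prot_kcal_mol": self.dg_gas_to_prot,
            "dg_solv_kcal_mol": self.dg_solv,
            "dg_rstr_kcal_mol": self.dg_rstr,
            "dg_bind_kcal_mol": self.dg_bind,
            "v_rstr_A3": self.v_rstr,
            "v_1m_A3": self.v_1m,
            "temperature_K": self.temperature,
        }


def lambda_schedule(
    fine_step: float = 0.025,
    coarse_step: float = 0.05,
    fine_zone: float = 0.1,
) -> list[float]:
    """Coupling-parameter grid: fine steps near the end points.

    The schedule runs from 0 to 1 with step ``fine_step`` inside
    ``[0, fine_zone]`` and ``[1 − fine_zone, 1]`` and ``coarse_step``
    in the middle. Steps must divide their zones exactly.
    """
    def _divides(step: float, length: float) -> bool:
        if step <= 0:
            return False
        k = length / step
        return abs(k - round(k)) < 1e-9

    if fine_zone < 0 or fine_zone > 0.5:
        raise ValueError("fine_zone must lie in [0, 0.5]")
    middle = 1.0 - 2.0 * fine_zone
    if fine_zone > 0 and not _divides(fine_step, fine_zone):
        raise ValueError(f"fine_step {fine_step} does not divide zone {fine_zone}")
    if middle > 0 and not _divides(coarse_step, middle):
        raise ValueError(f"coarse_step {coarse_step} does not divide the middle zone")

    lams: list[float] = [0.0]
    if fine_zone > 0:
        n = round(fine_zone / fine_step)
        lams += [round(i * fine_step, 10) for i in range(1, n + 1)]
    if middle > 0:
        n = round(middle / coarse_step)
        lams += [round(fine_zone + i * coarse_step, 10) for i in range(1, n + 1)]
    if fine_zone > 0:
        n = round(fine_zone / fine_step)
        lams += [round(1.0 - fine_zone + i * fine_step, 10) for i in range(1, n + 1)]
    lams[-1] = 1.0
    return lams


def fep_exponential_estimate(windows: Sequence[FepWindow]) -> FepEstimate:
    """Forward exponential-averaging (Zwanzig) estimate over a λ path.

    Windows must tile [0, 1] contiguously. The per-window estimate
    ``−RT ln⟨exp(−ΔU/RT)⟩`` is computed with a log-sum-exp so large ΔU
    samples cannot overflow.
    """
    if not windows:
        raise ValueError("no windows supplied")
    ws = sorted(windows, key=lambda w: w.lam_from)
    if abs(ws[0].lam_from) > 1e-9 or abs(ws[-1].lam_to - 1.0) > 1e-9:
        raise ValueError("λ path must start at 0 and end at 1")
    for a, b in zip(ws, ws[1:]):
        if abs(a.lam_to - b.lam_from) > 1e-9:
            raise ValueError(
                f"λ coverage has a gap or overlap between {a.lam_to} and {b.lam_from}"
            )
    per, ns, means, stds = [], [], [], []
    for w in ws:
        rt = GAS_CONSTANT_KCAL * w.temperature
        du = w.delta_u
        dg = -rt * (logsumexp(-du / rt) - np.log(du.size))
        per.append(float(dg))
        ns.append(int(du.size))
        means.append(float(du.mean()))
        stds.append(float(du.std(ddof=0)))
    return FepEstimate(
        dg_total=float(sum(per)),
        per_window=tuple(per),
        n_samples=tuple(ns),
        mean_du=tuple(means),
        std_du=tuple(stds),
    )


def restraint_correction(
    v_rstr: float,
    temperature: float = 300.0,
    v_1m: float = STANDARD_STATE_VOLUME,
) -> float:
    """Standard-state correction ΔG_rstr = RT ln(V_rstr / V_1M), kcal/mol."""
    if v_rstr <= 0 or v_1m <= 0:
        raise ValueError("volumes must be strictly positive")
    return GAS_CONSTANT_KCAL * temperature * float(np.log(v_rstr / v_1m))


def combine_binding_dg(
    dg_gas_to_prot: float,
    dg_solv: float,
    dg_rstr: float,
    v_rstr: float | None = None,
    temperature: float = 300.0,
) -> FreeEnergyComponents:
    """Combine the three legs into ΔG_bind = ΔG_gas→prot − (ΔG_solv + ΔG_rstr)."""
    dg_bind = dg_gas_to_prot - (dg_solv + dg_rstr)
    return FreeEnergyComponents(
        dg_gas_to_prot=dg_gas_to_prot,
        dg_solv=dg_solv,
        dg_rstr=dg_rstr,
        dg_bind=dg_bind,
        v_rstr=v_rstr,
        temperature=temperature,
    )


def kd_from_dg(dg_bind: float, temperature: float = 300.0) -> float:
    """Dissociation constant Kd = C° exp(ΔG_bind / RT), C° = 1 M."""
    rt = GAS_CONSTANT_KCAL * temperature
    return float(np.exp(dg_bind / rt))


def read_windows_csv(path: str | Path, temperature: float = 300.0) -> list[FepWindow]:
    """Read windows from CSV with columns lam_from, lam_to, delta_u."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"lam_from", "lam_to", "delta_u"}
    if not required.issubset(df.columns):
        raise ValueError(f"windows CSV needs columns {sorted(required)}")
    windows = []
    for (lf, lt), grp in df.groupby(["lam_from", "lam_to"], sort=True):
        windows.append(
            FepWindow(float(lf), float(lt), grp["delta_u"].to_numpy(), temperature)
        )
    return windows
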