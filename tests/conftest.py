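"""Shared fixtures: small synthetic systems built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from floodsite.core_model import Frame, Topology, Trajectory
from floodsite.pipeline import quickstart_config, run_pipeline


def make_point_topology(n_molecules: int, label: str = "ligand") -> Topology:
    """One unit-mass pseudo-atom per molecule."""
    return Topology(
        names=tuple("X" for _ in range(n_molecules)),
        masses=np.ones(n_molecules),
        residue_seq=np.arange(1, n_molecules + 1),
        residue_names=tuple("LIG" for _ in range(n_molecules)),
        subunit_ids=tuple("L" for _ in range(n_molecules)),
        selections={
            label: np.arange(n_molecules),
            "protein": np.array([], dtype=int),
            "water_oxygen": np.array([], dtype=int),
        },
    )


def make_trajectory(
    positions: np.ndarray,
    box=(50.0, 50.0, 50.0),
    dt: float = 1.0,
    top: Topology | None = None,
) -> Trajectory:
    """Trajectory from a (n_frames, n_atoms, 3) position array."""
    positions = np.asarray(positions, dtype=float)
    top = top if top is not None else make_point_topology(positions.shape[1])
    frames = [
        Frame(time=(i + 1) * dt, box=np.asarray(box, dtype=float), positions=p)
        for i, p in enumerate(positions)
    ]
    return Trajectory(topology=top, frames=frames)


@pytest.fixture(scope="session")
def quickstart_report(tmp_path_factory):
    """The bundled three-site synthetic demo, run once per session."""
    out = tmp_path_factory.mktemp("quickstart")
    summary = run_pipeline(quickstart_config(seed=1), out)
    return summary, out
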