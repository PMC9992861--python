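"""Shared fixtures: small programmatically-built ensembles and helpers."""

import numpy as np
import pytest

from motorscape.io import Ensemble, Topology


def build_topology(
    n_residues: int,
    atoms_per_residue: tuple[str, ...] = ("N", "CA", "C", "O"),
    chain: str = "A",
    elements: tuple[str, ...] | None = None,
) -> Topology:
    """A linear peptide-like topology for tests."""
    names, resnums, els = [], [], []
    if elements is None:
        elements = tuple(a[0] for a in atoms_per_residue)
    for r in range(1, n_residues + 1):
        for a, e in zip(atoms_per_residue, elements):
            names.append(a)
            resnums.append(r)
            els.append(e)
    n = len(names)
    return Topology(
        atom_serial=np.arange(1, n + 1),
        atom_name=np.array(names, dtype=object),
        residue_name=np.array(["ALA"] * n, dtype=object),
        residue_number=np.array(resnums, dtype=int),
        chain_id=np.array([chain] * n, dtype=object),
        element=np.array(els, dtype=object),
        occupancy=np.ones(n),
    )


def random_ensemble(
    n_frames: int = 4,
    n_residues: int = 5,
    seed: int = 0,
    scale: float = 10.0,
) -> Ensemble:
    top = build_topology(n_residues)
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-scale, scale, (n_frames, top.n_atoms, 3))
    return Ensemble(topology=top, coordinates=coords)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture
def peptide_ensemble() -> Ensemble:
    return random_ensemble(n_frames=4, n_residues=5, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
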