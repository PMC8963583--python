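import numpy as np
import pytest

from crossflex import FluctuationSpec, Structure, Trajectory, make_toy_protein, simulate_fluctuation


@pytest.fixture
def toy3() -> Structure:
    """3-residue toy backbone: 12 atoms (N, CA, C, O per residue)."""
    return make_toy_protein(3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def random_trajectory(base: Structure, sigma: float, n_frames: int, seed: int) -> Trajectory:
    return simulate_fluctuation(FluctuationSpec(base=base, sigma=sigma, n_frames=n_frames, seed=seed))


# a tiny handwritten fixed-column PDB: 3 residues x (N, CA, C, O)
TOY_PDB_TEXT = "".join(
    f"ATOM  {serial:>5} {name:<4}ALA A{res:>4}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           {name[0]}\n"
    for serial, (res, name, x, y, z) in enumerate(
        [
            (res, name, (res - 1) * 3.8 + dx, dy, 0.0)
            for res in (1, 2, 3)
            for name, dx, dy in (("N", -1.46, 0.0), ("CA", 0.0, 0.0), ("C", 1.52, 0.0), ("O", 1.52, 1.23))
        ],
        start=1,
    )
) + "END\n"


ALTLOC_PDB_TEXT = (
    "ATOM      1  N   ALA A   1      -1.460   0.000   0.000  1.00  0.00           N\n"
    "ATOM      2  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C\n"
    "ATOM      3  CA BALA A   1       0.500   0.000   0.000  0.40  0.00           C\n"
    "ATOM      4  C   ALA A   1       1.520   0.000   0.000  1.00  0.00           C\n"
    "ATOM      5  O   ALA A   1       1.520   1.230   0.000  1.00  0.00           O\n"
    "END\n"
)
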