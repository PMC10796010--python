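import numpy as np
import pytest

from histonefold.structio import ChainRecord, Structure
from histonefold.synthetic_data import make_two_helix_dimer


def _pdb_line(serial, resname, chain, resseq, x, y, z, altloc=" ", occ=1.00):
    return (
        f"ATOM  {serial:5d}  CA {altloc}{resname:>3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          C"
    )


@pytest.fixture
def two_residue_pdb(tmp_path):
    lines = [
        _pdb_line(1, "ALA", "A", 1, 1.0, 2.0, 3.0),
        _pdb_line(2, "GLY", "A", 2, 4.0, 5.0, 6.0),
        "END",
    ]
    p = tmp_path / "two.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def multimodel_pdb(tmp_path):
    lines = []
    for m in range(1, 4):
        lines.append(f"MODEL     {m:4d}")
        for i in range(1, 4):
            lines.append(_pdb_line(i, "ALA", "A", i, float(i + m), 0.0, 0.0))
        lines.append("ENDMDL")
    lines.append("END")
    p = tmp_path / "multi.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    # residue 1 has two CA conformers: B with higher occupancy must win
    lines = [
        _pdb_line(1, "ALA", "A", 1, 1.0, 0.0, 0.0, altloc="A", occ=0.4),
        _pdb_line(2, "ALA", "A", 1, 2.0, 0.0, 0.0, altloc="B", occ=0.6),
        _pdb_line(3, "GLY", "A", 2, 3.0, 0.0, 0.0),
        "END",
    ]
    p = tmp_path / "altloc.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def altloc_tie_pdb(tmp_path):
    # equal occupancies: altloc 'A' must win
    lines = [
        _pdb_line(1, "ALA", "A", 1, 1.0, 0.0, 0.0, altloc="B", occ=0.5),
        _pdb_line(2, "ALA", "A", 1, 2.0, 0.0, 0.0, altloc="A", occ=0.5),
        _pdb_line(3, "GLY", "A", 2, 3.0, 0.0, 0.0),
        "END",
    ]
    p = tmp_path / "altloc_tie.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def offset_pdb(tmp_path):
    # author numbering starts at 28 (offset 27 from 1-based)
    lines = [
        _pdb_line(i, "LEU", "A", 27 + i, 3.8 * i, 0.0, 0.0) for i in range(1, 9)
    ] + ["END"]
    p = tmp_path / "offset.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p


def random_structure(n_per_chain=(8, 8), seed=0, name="random") -> Structure:
    rng = np.random.default_rng(seed)
    chains = []
    for cid, n in zip("ABCDEF", n_per_chain):
        chains.append(
            ChainRecord(cid, ["A"] * n, rng.normal(scale=5.0, size=(n, 3)),
                        list(range(1, n + 1)))
        )
    return Structure(chains, name=name)


@pytest.fixture
def native_dimer() -> Structure:
    """A compact two-chain reference with a real interface (crossing 140°)."""
    return make_two_helix_dimer(140.0, n_res=16, separation=10.0)
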