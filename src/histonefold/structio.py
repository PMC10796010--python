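"""Reading and writing Cα-level protein structures and sequences.

Every analysis in this package operates on the :class:`Structure` container:
an ordered list of chains, each holding one Cα coordinate and one-letter code
per residue.  PDB files are parsed with Biopython; only Cα atoms are kept,
because all implemented statistics (Q, RMSD/RMSF, radius of gyration, helix
axes) are defined at the Cα level.

Two numbering systems coexist.  *Author* numbering is whatever the PDB file
says (possibly with gaps or offsets) and is preserved for reporting.
*Internal* numbering is 0-based and contiguous within a chain and is what
sequence separations (for the Q order parameter) are computed on; gaps in
author numbering do not create placeholder residues.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.Atom import DisorderedAtom
from Bio.Data.PDBData import protein_letters_3to1_extended
from Bio.SeqUtils import seq1

__all__ = [
    "ChainRecord",
    "Structure",
    "SegmentSpec",
    "PDBFormatError",
    "EmptyStructureError",
    "read_structure",
    "write_structure",
    "read_fasta",
    "write_fasta",
    "extract_sequence",
    "select_segment",
    "enumerate_chain_pairings",
]

# extended IUPAC table maps modified residues (MSE -> M etc.);
# anything unknown falls back to X
_THREE_TO_ONE_KWARGS = {
    "custom_map": protein_letters_3to1_extended,
    "undef_code": "X",
}


class PDBFormatError(ValueError):
    """A coordinate record could not be parsed; the message names the line."""


class EmptyStructureError(ValueError):
    """The file contained no CA atoms."""


@dataclass
class ChainRecord:
    """One chain: parallel lists of one-letter codes, Cα coordinates (Å) and
    the original author residue numbers (which may be non-contiguous)."""

    chain_id: str
    residue_codes: list[str]
    ca_coords: np.ndarray  # (n, 3) float64, Å
    author_numbers: list[int]

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float).reshape(-1, 3)
        n = len(self.residue_codes)
        if not (len(self.ca_coords) == n == len(self.author_numbers)):
            raise ValueError(
                f"chain {self.chain_id!r}: residue_codes/ca_coords/author_numbers "
                f"lengths differ ({n}, {len(self.ca_coords)}, {len(self.author_numbers)})"
            )
        if n == 0:
            raise ValueError(f"chain {self.chain_id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residue_codes)

    @property
    def sequence(self) -> str:
        return "".join(self.residue_codes)


@dataclass
class Structure:
    """An ordered set of chains from one model of a (possibly multi-model)
    coordinate file."""

    chains: list[ChainRecord]
    name: str = ""
    frame_index: int = 0

    def __post_init__(self) -> None:
        if not self.chains:
            raise EmptyStructureError(f"structure {self.name!r} has no chains")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids in {self.name!r}: {ids}")

    def chain(self, chain_id: str) -> ChainRecord:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(
            f"chain {chain_id!r} not found; available: "
            f"{[c.chain_id for c in self.chains]}"
        )

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def coords(self) -> np.ndarray:
        """All Cα coordinates, chains concatenated in order, shape (n, 3)."""
        return np.concatenate([c.ca_coords for c in self.chains], axis=0)


@dataclass(frozen=True)
class SegmentSpec:
    """A declared residue range on one chain, e.g. an α2 helix.

    ``indexing='author'`` interprets ``start``/``end`` (inclusive) in the
    file's own residue numbering; ``'internal'`` in the 0-based contiguous
    index.  Helix ranges are deliberately explicit user input: structures
    differ in where their helices start, and the choice should be visible in
    any report.
    """

    chain_id: str
    start: int
    end: int
    indexing: str = "author"

    def __post_init__(self) -> None:
        if self.indexing not in ("author", "internal"):
            raise ValueError(f"indexing must be 'author' or 'internal', got {self.indexing!r}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")


# ---------------------------------------------------------------------------
# PDB reading


def _validate_coordinate_fields(path: Path) -> None:
    """Pre-scan: raise PDBFormatError naming the first malformed ATOM line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBFormatError(f"{path}:{lineno}: truncated coordinate record")
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBFormatError(
                        f"{path}:{lineno}: malformed {what} coordinate field "
                        f"{line[lo:hi]!r}"
                    ) from None


def _pick_ca(residue) -> "np.ndarray | None":
    """Return the Cα coordinate of a residue, resolving altlocs.

    Highest occupancy wins; exact ties are broken alphabetically by altloc
    identifier (so 'A' beats 'B'), which keeps parsing deterministic.
    """
    if "CA" not in residue:
        return None
    atom = residue["CA"]
    if isinstance(atom, DisorderedAtom):
        children = atom.disordered_get_list()
        best = min(children, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()))
        return np.asarray(best.get_coord(), dtype=float)
    return np.asarray(atom.get_coord(), dtype=float)


def read_structure(path: str | Path, model: int | None = None) -> list[Structure]:
    """Read a PDB file into one :class:`Structure` per MODEL.

    Only residues with a CA atom are retained (this includes HETATM residues
    such as MSE, translated to one-letter codes via the extended IUPAC table,
    unknowns becoming ``X``).  ``model`` selects a single model by 0-based
    position in the file; ``None`` returns all.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_coordinate_fields(path)

    parser = PDBParser(QUIET=True)
    bio_structure = parser.get_structure(path.stem, str(path))

    structures: list[Structure] = []
    for frame_index, bio_model in enumerate(bio_structure):
        chains: list[ChainRecord] = []
        for bio_chain in bio_model:
            codes: list[str] = []
            coords: list[np.ndarray] = []
            numbers: list[int] = []
            for residue in bio_chain:
                ca = _pick_ca(residue)
                if ca is None:
                    continue
                three = residue.get_resname().strip()
                one = seq1(three, **_THREE_TO_ONE_KWARGS)
                codes.append(one if len(one) == 1 else "X")
                coords.append(ca)
                numbers.append(residue.id[1])
            if codes:
                chains.append(
                    ChainRecord(bio_chain.id, codes, np.array(coords), numbers)
                )
        if chains:
            structures.append(Structure(chains, name=path.stem, frame_index=frame_index))

    if not structures:
        raise EmptyStructureError(f"{path}: no CA atoms found")
    if model is not None:
        if not 0 <= model < len(structures):
            raise IndexError(f"model {model} out of range (file has {len(structures)})")
        return [structures[model]]
    return structures


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


def write_structure(structures: "Structure | Sequence[Structure]",
                    path: str | Path,
                    header_comment: str | None = None) -> None:
    """Write one or more Structures as a Cα-only (multi-MODEL) PDB file."""
    if isinstance(structures, Structure):
        structures = [structures]
    multi = len(structures) > 1
    lines: list[str] = []
    if header_comment:
        for chunk in header_comment.splitlines():
            lines.append(f"REMARK   1 {chunk}")
    for k, s in enumerate(structures, start=1):
        if multi:
            lines.append(f"MODEL     {k:4d}")
        serial = 1
        for chain in s.chains:
            for code, xyz, num in zip(chain.residue_codes, chain.ca_coords,
                                      chain.author_numbers):
                res3 = _ONE_TO_THREE.get(code, "UNK")
                lines.append(
                    f"ATOM  {serial:5d}  CA  {res3:>3s} {chain.chain_id[:1]}"
                    f"{num:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {'C':>2s}"
                )
                serial += 1
            lines.append(f"TER   {serial:5d}")
            serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sequences


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def extract_sequence(s: Structure, chain_id: str) -> str:
    """One-letter sequence of a chain (length equals its residue count)."""
    return s.chain(chain_id).sequence


# ---------------------------------------------------------------------------
# Segment selection and chain pairing


def resolve_segment(s: Structure, spec: SegmentSpec) -> np.ndarray:
    """Internal (0-based) indices covered by a SegmentSpec, in N→C order."""
    chain = s.chain(spec.chain_id)
    if spec.indexing == "internal":
        if spec.start < 0 or spec.end >= len(chain):
            raise IndexError(
                f"internal range {spec.start}..{spec.end} out of bounds for chain "
                f"{spec.chain_id!r} with {len(chain)} residues"
            )
        idx = np.arange(spec.start, spec.end + 1)
    else:
        nums = np.asarray(chain.author_numbers)
        mask = (nums >= spec.start) & (nums <= spec.end)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise IndexError(
                f"author range {spec.start}..{spec.end} selects no residues on chain "
                f"{spec.chain_id!r} (available numbering {nums.min()}..{nums.max()})"
            )
    if idx.size < 3:
        raise ValueError(
            f"segment {spec} resolves to {idx.size} residue(s); "
            "at least 3 are required for axis fitting"
        )
    return idx


def select_segment(s: Structure, spec: SegmentSpec) -> tuple[np.ndarray, str]:
    """Cα coordinates and sequence of a declared segment, N→C order."""
    chain = s.chain(spec.chain_id)
    idx = resolve_segment(s, spec)
    coords = chain.ca_coords[idx]
    seq = "".join(chain.residue_codes[i] for i in idx)
    return coords, seq


def enumerate_chain_pairings(a: Structure, b: Structure) -> list[dict[str, str]]:
    """All chain-label bijections a→b that preserve per-chain residue counts.

    For a homodimer (two equal-length chains) both orderings are returned;
    downstream scores that depend on chain identity should be maximized over
    these pairings.
    """
    if len(a.chains) != len(b.chains):
        raise ValueError(
            f"chain counts differ: {len(a.chains)} vs {len(b.chains)}"
        )
    a_ids = a.chain_ids
    b_ids = b.chain_ids
    a_len = {c.chain_id: len(c) for c in a.chains}
    b_len = {c.chain_id: len(c) for c in b.chains}
    pairings = []
    for perm in itertools.permutations(b_ids):
        if all(a_len[ai] == b_len[bi] for ai, bi in zip(a_ids, perm)):
            pairings.append(dict(zip(a_ids, perm)))
    if not pairings:
        raise ValueError(
            f"no length-preserving chain correspondence between {a.name!r} "
            f"({[a_len[i] for i in a_ids]}) and {b.name!r} ({[b_len[i] for i in b_ids]})"
        )
    return pairings
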