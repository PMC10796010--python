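"""Head-tail hydrophobic sequence symmetry.

The histone fold is thought to descend from a duplicated primordial
helix-strand-helix motif, which leaves a cryptic signature in modern
sequences: the hydrophobic positions of a histone tend to reappear at the
mirrored positions of its partner read C→N.  This module formalizes that
observation as a statistic.  A sequence ``a`` is globally aligned against the
reversal of its partner ``b``; the symmetry score is the fraction of aligned
columns involving at least one hydrophobic residue in which *both* sides are
hydrophobic.  Significance comes from a composition-preserving permutation
null: residues of ``b`` are shuffled, destroying positional structure while
keeping the amino-acid multiset, and the score is recomputed.

Alignment is Needleman–Wunsch with affine gaps (via Biopython's
PairwiseAligner); a gap of length L costs gap_open + (L−1)·gap_extend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

__all__ = [
    "HYDROPHOBIC_DEFAULT",
    "AMINO_ALPHABET",
    "SubstitutionScheme",
    "AlignmentResult",
    "SymmetryReport",
    "reverse_sequence",
    "align_global",
    "symmetry_score",
    "permutation_pvalue",
]

#: Default hydrophobic residue set (aliphatic + aromatic F/W + M/C; tyrosine
#: excluded by default because of its polar hydroxyl — toggle by passing an
#: explicit set).
HYDROPHOBIC_DEFAULT = frozenset("AVLIMFWC")

AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class SubstitutionScheme:
    """Scoring scheme for global alignment.

    If ``matrix_name`` is set (e.g. "BLOSUM62"), that published matrix is
    loaded and overrides match/mismatch.  Gap penalties are scores (≤ 0).
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0
    matrix_name: str | None = None

    def __post_init__(self):
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0 (they are scores)")
        if self.match < self.mismatch:
            raise ValueError("match score must be >= mismatch score")

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        if self.matrix_name is not None:
            aligner.substitution_matrix = Align.substitution_matrices.load(
                self.matrix_name
            )
        else:
            aligner.match_score = self.match
            aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        return aligner


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    columns: list[tuple[int | None, int | None]]

    def recompute_score(self, scheme: SubstitutionScheme) -> float:
        """Column-wise score recomputation (consistency check)."""
        if scheme.matrix_name is not None:
            matrix = Align.substitution_matrices.load(scheme.matrix_name)
        else:
            matrix = None
        total = 0.0
        in_gap_a = in_gap_b = False
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca == "-":
                total += scheme.gap_extend if in_gap_a else scheme.gap_open
                in_gap_a, in_gap_b = True, False
            elif cb == "-":
                total += scheme.gap_extend if in_gap_b else scheme.gap_open
                in_gap_a, in_gap_b = False, True
            else:
                in_gap_a = in_gap_b = False
                if matrix is not None:
                    total += matrix[ca, cb]
                else:
                    total += scheme.match if ca == cb else scheme.mismatch
        return total


@dataclass
class SymmetryReport:
    symmetry_score: float
    hydrophobic_columns: list[int]
    n_scored_columns: int
    hydrophobic_set: frozenset[str]
    alignment: AlignmentResult | None = None
    p_value: float | None = None
    n_permutations: int | None = None
    null_scores: np.ndarray | None = field(default=None, repr=False)


def reverse_sequence(s: str) -> str:
    """Reverse a sequence C→N (character-wise reversal)."""
    if not s:
        raise ValueError("sequence is empty")
    return s[::-1]


def _check_alphabet(s: str, name: str) -> None:
    bad = set(s.upper()) - AMINO_ALPHABET
    if bad:
        raise ValueError(
            f"{name} contains characters outside the amino-acid alphabet: "
            f"{sorted(bad)}"
        )


def align_global(a: str, b: str,
                 scheme: SubstitutionScheme = SubstitutionScheme()) -> AlignmentResult:
    """Optimal global (Needleman–Wunsch, affine-gap) alignment of a and b."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    _check_alphabet(a, "first sequence")
    _check_alphabet(b, "second sequence")
    aligner = scheme.make_aligner()
    alignment = aligner.align(a, b)[0]  # first alignment: deterministic
    ga, gb = str(alignment[0]), str(alignment[1])
    columns: list[tuple[int | None, int | None]] = []
    ia = ib = 0
    for ca, cb in zip(ga, gb):
        pa = pb = None
        if ca != "-":
            pa, ia = ia, ia + 1
        if cb != "-":
            pb, ib = ib, ib + 1
        columns.append((pa, pb))
    return AlignmentResult(aligned_a=ga, aligned_b=gb,
                           score=float(alignment.score), columns=columns)


def symmetry_score(a: str, b_reversed: str,
                   scheme: SubstitutionScheme = SubstitutionScheme(),
                   hydrophobic_set=HYDROPHOBIC_DEFAULT) -> SymmetryReport:
    """Hydrophobic-symmetry score of ``a`` against an already-reversed
    partner sequence.

    Score = (# residue–residue columns where both sides are hydrophobic) /
            (# residue–residue columns where at least one side is hydrophobic).

    Gap columns do not enter the ratio: they reflect length mismatch, not
    positional asymmetry, and excluding them keeps the score at exactly 1 for
    any pair of all-hydrophobic sequences however they align.  If no column
    involves a hydrophobic residue the score is 0.
    """
    hset = frozenset(str(h).upper() for h in hydrophobic_set)
    aln = align_global(a, b_reversed, scheme)
    both: list[int] = []
    either = 0
    for k, (ca, cb) in enumerate(zip(aln.aligned_a, aln.aligned_b)):
        if ca == "-" or cb == "-":
            continue
        ha = ca in hset
        hb = cb in hset
        if ha or hb:
            either += 1
            if ha and hb:
                both.append(k)
    score = len(both) / either if either else 0.0
    return SymmetryReport(symmetry_score=score, hydrophobic_columns=both,
                          n_scored_columns=either, hydrophobic_set=hset,
                          alignment=aln)


def permutation_pvalue(a: str, b: str,
                       scheme: SubstitutionScheme = SubstitutionScheme(),
                       hydrophobic_set=HYDROPHOBIC_DEFAULT,
                       n_perm: int = 999, seed: int = 0) -> SymmetryReport:
    """Symmetry score of a vs reverse(b) with a permutation p-value.

    The null shuffles the residue order of ``b`` (composition preserved)
    ``n_perm`` times; p = (1 + #{null ≥ observed}) / (n_perm + 1), the
    add-one estimator, which never returns 0.
    """
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99 for usable resolution, got {n_perm}")
    rng = np.random.default_rng(seed)
    observed = symmetry_score(a, reverse_sequence(b), scheme, hydrophobic_set)
    b_chars = np.array(list(b.upper()))
    null = np.empty(n_perm)
    for k in range(n_perm):
        shuffled = "".join(rng.permutation(b_chars))
        null[k] = symmetry_score(a, reverse_sequence(shuffled),
                                 scheme, hydrophobic_set).symmetry_score
    p = (1 + int(np.count_nonzero(null >= observed.symmetry_score))) / (n_perm + 1)
    observed.p_value = p
    observed.n_permutations = n_perm
    observed.null_scores = null
    return observed
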