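"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the code paths they check: the superposition oracle
searches rotation space on a refining grid instead of solving the Kabsch
SVD, and the alignment oracle enumerates every global alignment instead of
running dynamic programming.
"""

import itertools

import numpy as np
from scipy.spatial.transform import Rotation


def _rmsd_after_translation(P, Q, R):
    """Best-translation RMSD of R·P onto Q (centroids superposed)."""
    Pr = P @ R.transpose(0, 2, 1) if R.ndim == 3 else P @ R.T
    if R.ndim == 3:
        diff = Pr - (Pr.mean(axis=1, keepdims=True) - Q.mean(0)) - Q
        return np.sqrt((diff ** 2).sum(axis=(1, 2)) / len(Q))
    diff = (Pr - Pr.mean(0)) - (Q - Q.mean(0))
    return float(np.sqrt((diff ** 2).sum() / len(Q)))


def grid_search_rmsd(mobile, target, n_coarse=20, n_refine=16, shrink=2.0):
    """Minimum RMSD over proper rotations by hierarchical grid search.

    Coarse Euler-angle grid over the whole rotation group, then successively
    shrunken local rotation-vector grids around the incumbent (the local
    parameterization avoids Euler gimbal degeneracies); returns the best
    RMSD found, accurate to well below 1e-3 Å for small point sets.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    grid = np.linspace(-np.pi, np.pi, n_coarse, endpoint=False)
    half = np.linspace(0.0, np.pi, n_coarse)  # zyz middle angle lives in [0, π]
    angles = np.array(list(itertools.product(grid, half, grid)))
    R = Rotation.from_euler("zyz", angles).as_matrix()
    r = _rmsd_after_translation(P, Q, R)
    k = int(np.argmin(r))
    best_R, best_rmsd = R[k], float(r[k])

    width = 2 * np.pi / n_coarse
    for _ in range(n_refine):
        local = np.linspace(-width, width, 9)
        offsets = np.array(list(itertools.product(local, local, local)))
        R = best_R @ Rotation.from_rotvec(offsets).as_matrix()
        r = _rmsd_after_translation(P, Q, R)
        k = int(np.argmin(r))
        if r[k] < best_rmsd:
            best_rmsd, best_R = float(r[k]), R[k]
        width /= shrink
    return best_rmsd


def enumerate_global_alignments(a, b):
    """Yield every global alignment of a and b as (aligned_a, aligned_b).

    An alignment is a monotone path of match/insert/delete moves; adjacent
    insert-then-delete orderings are both produced (they score identically
    under column-wise affine scoring as used here).
    """

    def rec(i, j):
        if i == len(a) and j == len(b):
            yield "", ""
            return
        if i < len(a) and j < len(b):
            for ra, rb in rec(i + 1, j + 1):
                yield a[i] + ra, b[j] + rb
        if i < len(a):
            for ra, rb in rec(i + 1, j):
                yield a[i] + ra, "-" + rb
        if j < len(b):
            for ra, rb in rec(i, j + 1):
                yield "-" + ra, b[j] + rb

    yield from rec(0, 0)


def score_alignment(aligned_a, aligned_b, match, mismatch, gap_open, gap_extend):
    """Affine column-wise score: a gap run of length L costs
    gap_open + (L−1)·gap_extend."""
    total = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-":
            total += gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            total += gap_extend if in_gap_b else gap_open
            in_gap_a, in_gap_b = False, True
        else:
            total += match if ca == cb else mismatch
            in_gap_a = in_gap_b = False
    return total


def best_alignment_score_bruteforce(a, b, match, mismatch, gap_open, gap_extend):
    return max(
        score_alignment(ra, rb, match, mismatch, gap_open, gap_extend)
        for ra, rb in enumerate_global_alignments(a, b)
    )
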