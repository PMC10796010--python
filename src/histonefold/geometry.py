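"""Rigid-body geometry: Kabsch superposition, RMSD/RMSF, radius of gyration,
helix-axis fitting, the inter-helix crossing angle, and pairwise-RMSD
conformational clustering.

The crossing angle is the package's geometric discriminant between the native
handshake dimer and its inverted alternative: with both helix axes oriented
N→C, the inverted arrangement flips one axis, so its angle is close to
180° minus the native one.  The angle is therefore reported on [0, 180°] and
never folded onto [0, 90°].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from .structio import SegmentSpec, Structure, select_segment

__all__ = [
    "Superposition",
    "HelixAxis",
    "ClusterResult",
    "superpose_kabsch",
    "apply_superposition",
    "rmsd_series",
    "rmsf_profile",
    "radius_of_gyration",
    "fit_helix_axis",
    "helix_axis_from_structure",
    "interhelix_angle",
    "crossing_angle",
    "pairwise_rmsd_matrix",
    "cluster_conformations",
]


@dataclass
class Superposition:
    """Proper rigid transform x ↦ R x + t minimizing weighted RMSD."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float


@dataclass
class HelixAxis:
    """A fitted helix axis: centroid + unit direction oriented N→C."""

    centroid: np.ndarray
    direction: np.ndarray
    segment: SegmentSpec | None
    fit_rms: float


@dataclass
class ClusterResult:
    labels: np.ndarray  # one integer label per conformation (1-based)
    medoids: dict[int, int]  # cluster label -> medoid frame index
    linkage_cutoff: float


def _as_points(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"{name} must be an (n, 3) array, got shape {arr.shape}")
    return arr


def superpose_kabsch(mobile, target, weights=None) -> Superposition:
    """Optimal proper rigid superposition of ``mobile`` onto ``target``.

    Kabsch algorithm via SVD, with the sign of the smallest singular vector
    corrected so the rotation is always proper (det = +1): mirror solutions
    are never returned, so superposing a structure onto its mirror image
    yields a strictly positive RMSD.  For degenerate (collinear) point sets
    the rotation about the line is undetermined; the minimal-angle rotation
    aligning the principal directions is returned, which keeps results
    deterministic.
    """
    P = _as_points(mobile, "mobile")
    Q = _as_points(target, "target")
    if P.shape != Q.shape:
        raise ValueError(f"point counts differ: {P.shape} vs {Q.shape}")
    n = len(P)
    if n < 3:
        raise ValueError(f"need at least 3 points for superposition, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError(f"weights must have shape ({n},)")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative and not all zero")
    wsum = w.sum()
    p0 = (w[:, None] * P).sum(0) / wsum
    q0 = (w[:, None] * Q).sum(0) / wsum
    Pc, Qc = P - p0, Q - q0

    H = (w[:, None] * Pc).T @ Qc
    U, S, Vt = np.linalg.svd(H)
    rank2 = S[1] > 1e-9 * max(S[0], 1e-300)
    if rank2:
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    else:
        # collinear or coincident: minimal rotation taking the mobile
        # principal direction onto the target's (identity if coincident)
        if S[0] <= 1e-12:
            R = np.eye(3)
        else:
            u = U[:, 0]
            v = Vt[0]
            # flip together so u·v >= 0, then minimal rotation u -> v
            if np.dot(u, v) < 0:
                v = -v
            R = Rotation.align_vectors(v[None, :], u[None, :])[0].as_matrix()
    t = q0 - R @ p0
    diff = (Pc @ R.T) - Qc
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum() / wsum))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def apply_superposition(coords, sup: Superposition) -> np.ndarray:
    return _as_points(coords, "coords") @ sup.rotation.T + sup.translation


def rmsd_series(frames, reference) -> np.ndarray:
    """Superposed Cα RMSD of every frame against one reference (Å)."""
    ref = _as_points(reference, "reference")
    out = np.empty(len(frames))
    for k, frame in enumerate(frames):
        f = _as_points(frame, f"frame {k}")
        if f.shape != ref.shape:
            raise ValueError(
                f"frame {k} has shape {f.shape}, reference {ref.shape}"
            )
        out[k] = superpose_kabsch(f, ref).rmsd
    return out


def rmsf_profile(frames, align_to: str = "mean") -> np.ndarray:
    """Per-residue root-mean-square fluctuation over an aligned ensemble.

    ``align_to='mean'`` performs two passes of alignment to the running mean
    structure (first pass seeded by the first frame); ``'first'`` aligns every
    frame to the first one, reproducing single-reference analyses.  Rigid
    overall motion is removed by the alignment, so a rigidly tumbling but
    internally static body has RMSF 0 everywhere.
    """
    if align_to not in ("mean", "first"):
        raise ValueError("align_to must be 'mean' or 'first'")
    frames = [_as_points(f, f"frame {k}") for k, f in enumerate(frames)]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames for RMSF")

    def _aligned(reference):
        return np.stack(
            [apply_superposition(f, superpose_kabsch(f, reference)) for f in frames]
        )

    if align_to == "first":
        stack = _aligned(frames[0])
    else:
        stack = _aligned(frames[0])
        for _ in range(2):
            stack = _aligned(stack.mean(axis=0))
    mean = stack.mean(axis=0)
    return np.sqrt(((stack - mean) ** 2).sum(axis=2).mean(axis=0))


def radius_of_gyration(coords, masses=None) -> float:
    """Mass-weighted radius of gyration (Å); unit weights by default."""
    X = _as_points(coords, "coords")
    if masses is None:
        w = np.ones(len(X))
    else:
        w = np.asarray(masses, dtype=float)
        if np.any(w < 0):
            raise ValueError("masses must be non-negative")
        if not np.any(w > 0):
            raise ValueError("masses must not be all zero")
    com = (w[:, None] * X).sum(0) / w.sum()
    return float(np.sqrt((w * ((X - com) ** 2).sum(1)).sum() / w.sum()))


def fit_helix_axis(coords, segment: SegmentSpec | None = None) -> HelixAxis:
    """Fit a helix axis as the dominant principal component of the Cα cloud.

    The direction is sign-fixed to point N→C (positive projection of the
    last-minus-first Cα vector).  ``fit_rms`` is the RMS perpendicular
    distance of the points from the fitted line — large values flag segments
    that are not actually helical/straight.
    """
    X = _as_points(coords, "coords")
    if len(X) < 3:
        raise ValueError("need at least 3 points to fit an axis")
    centroid = X.mean(axis=0)
    Xc = X - centroid
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    if S[0] <= 1e-12:
        raise ValueError("all points coincide; axis undefined")
    direction = Vt[0]
    if np.dot(direction, X[-1] - X[0]) < 0:
        direction = -direction
    proj = Xc @ direction
    perp = Xc - proj[:, None] * direction
    fit_rms = float(np.sqrt((perp ** 2).sum(1).mean()))
    return HelixAxis(centroid=centroid, direction=direction,
                     segment=segment, fit_rms=fit_rms)


def helix_axis_from_structure(s: Structure, spec: SegmentSpec,
                              mode: str = "axis") -> HelixAxis:
    """Fit the axis of a declared helix segment of a Structure.

    ``mode='axis'`` (default) fits the principal axis; ``mode='endpoints'``
    uses the normalized last-minus-first Cα difference vector instead, for
    reproducing analyses defined that way.
    """
    coords, _ = select_segment(s, spec)
    if mode == "axis":
        return fit_helix_axis(coords, segment=spec)
    if mode == "endpoints":
        d = coords[-1] - coords[0]
        nrm = np.linalg.norm(d)
        if nrm <= 1e-12:
            raise ValueError("segment endpoints coincide; axis undefined")
        return HelixAxis(centroid=coords.mean(0), direction=d / nrm,
                         segment=spec, fit_rms=float("nan"))
    raise ValueError("mode must be 'axis' or 'endpoints'")


def interhelix_angle(a: HelixAxis, b: HelixAxis) -> float:
    """Angle between two oriented helix axes, degrees in [0, 180].

    Because both directions are N→C oriented, parallel helices give 0° and
    antiparallel ones 180°; flipping one axis maps θ to 180° − θ (the
    native/inverted complementarity).
    """
    c = float(np.clip(np.dot(a.direction, b.direction), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def crossing_angle(s: Structure, seg_a: SegmentSpec, seg_b: SegmentSpec,
                   mode: str = "axis") -> float:
    """The α2–α2 style crossing angle between two declared helix segments."""
    return interhelix_angle(helix_axis_from_structure(s, seg_a, mode=mode),
                            helix_axis_from_structure(s, seg_b, mode=mode))


def pairwise_rmsd_matrix(frames) -> np.ndarray:
    """Symmetric matrix of superposed RMSDs between all frame pairs (Å)."""
    frames = [_as_points(f, f"frame {k}") for k, f in enumerate(frames)]
    n = len(frames)
    if n < 2:
        raise ValueError("need at least 2 frames")
    shape = frames[0].shape
    for k, f in enumerate(frames):
        if f.shape != shape:
            raise ValueError(f"frame {k} has shape {f.shape}, expected {shape}")
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = superpose_kabsch(frames[i], frames[j]).rmsd
    return M


def cluster_conformations(M: np.ndarray, cutoff: float = 4.0) -> ClusterResult:
    """Average-linkage agglomerative clustering of a pairwise-RMSD matrix,
    cut at ``cutoff`` Å; each cluster reports the medoid frame (minimum mean
    intra-cluster distance, ties to the lowest frame index)."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"matrix must be square, got {M.shape}")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    if np.any(M < 0):
        raise ValueError("matrix entries must be non-negative")
    if np.any(np.abs(np.diag(M)) > 1e-8):
        raise ValueError("diagonal must be zero")
    n = M.shape[0]
    if n == 1:
        return ClusterResult(np.array([1]), {1: 0}, cutoff)
    Z = linkage(squareform(M, checks=False), method="average")
    labels = fcluster(Z, t=cutoff, criterion="distance")
    medoids: dict[int, int] = {}
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        mean_d = M[np.ix_(members, members)].mean(axis=1)
        medoids[int(lab)] = int(members[int(np.argmin(mean_d))])
    return ClusterResult(labels=labels, medoids=medoids, linkage_cutoff=cutoff)
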