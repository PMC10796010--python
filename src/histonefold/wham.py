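"""Weighted histogram analysis method (WHAM) for umbrella-sampled windows.

Umbrella sampling runs a ladder of biased simulations, window k feeling the
harmonic bias

    U_k(q) = ½ k_spring (q − q_k)²

on top of the unknown free-energy profile F(q).  WHAM removes the bias by
solving the self-consistent equations for the per-window free-energy
constants f_k and the unbiased bin probabilities p_i:

    p_i ∝ M_i / Σ_k N_k exp[−β (U_k(x_i) − f_k)]
    exp(−β f_k) = Σ_i p_i exp(−β U_k(x_i))

where M_i is the total count in bin i and N_k the sample count of window k.
The profile is F_i = −kT ln p_i, anchored so its sampled minimum is 0.

Note the ½ in the bias convention: the spring constant is the physical k of
½ k x², matching the common MD definition of a harmonic restraint.  Window
files that were generated under the k x² convention must double their spring
before being fed in.

After the 1D solve, the same window constants let every sample be reweighted
onto a second, unbiased coordinate recorded alongside the first (e.g. a
crossing angle logged during Q-biased sampling), giving 2D surfaces
F(q, y) without a 2D umbrella.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "KT_300K",
    "UmbrellaWindow",
    "WhamConfig",
    "FreeEnergyProfile",
    "FreeEnergySurface",
    "bias_energy",
    "solve_wham_1d",
    "reweight_2d",
    "barrier_height",
    "read_windows",
    "write_windows",
]

#: kT in kcal/mol at 300 K.
KT_300K = 0.593


@dataclass
class UmbrellaWindow:
    """Biased samples of the reaction coordinate from one umbrella window.

    ``aux_samples`` optionally records a second coordinate measured on the
    same frames (same length), used for 2D reweighting.
    """

    center: float
    spring: float  # energy / coordinate², bias = ½·spring·(q−center)² + offset
    samples: np.ndarray
    aux_samples: np.ndarray | None = None
    bias_offset: float = 0.0  # additive constant; absorbed by the window
    # free-energy constants, so it never changes the recovered profile

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.spring < 0:
            raise ValueError("spring must be >= 0")
        if self.samples.size == 0:
            raise ValueError("window has no samples")
        if self.aux_samples is not None:
            self.aux_samples = np.asarray(self.aux_samples, dtype=float).ravel()
            if self.aux_samples.size != self.samples.size:
                raise ValueError(
                    f"aux_samples length {self.aux_samples.size} != "
                    f"samples length {self.samples.size}"
                )


@dataclass(frozen=True)
class WhamConfig:
    kT: float = KT_300K  # kcal/mol
    n_bins: int = 50
    range: tuple[float, float] = (0.0, 1.0)
    tol: float = 1e-7  # kcal/mol, max |Δf_k| between iterations
    max_iter: int = 100_000

    def __post_init__(self):
        lo, hi = self.range
        if not lo < hi:
            raise ValueError(f"range must satisfy lo < hi, got {self.range}")
        if self.n_bins < 10:
            raise ValueError("n_bins must be >= 10")
        if self.kT <= 0:
            raise ValueError("kT must be > 0")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(self.range[0], self.range[1], self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        return 0.5 * (e[:-1] + e[1:])


@dataclass
class FreeEnergyProfile:
    bin_centers: np.ndarray
    F: np.ndarray  # kcal/mol; +inf where no counts
    counts: np.ndarray
    converged: bool
    iterations: int
    kT: float
    window_free_energies: np.ndarray = field(default=None, repr=False)
    warnings: list[str] = field(default_factory=list)
    n_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers,
                             "F_kcal_mol": self.F, "counts": self.counts})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class FreeEnergySurface:
    x_centers: np.ndarray
    y_centers: np.ndarray
    F: np.ndarray  # (nx, ny), +inf where empty
    weights: np.ndarray  # reweighted (unbiased) histogram mass per cell
    raw_counts: np.ndarray  # unweighted sample counts per cell
    kT: float

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        return pd.DataFrame({"x": xx.ravel(), "y": yy.ravel(),
                             "F_kcal_mol": self.F.ravel()})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def bias_energy(window: UmbrellaWindow, q) -> np.ndarray:
    """½·spring·(q − center)² + bias_offset for this window."""
    q = np.asarray(q, dtype=float)
    return 0.5 * window.spring * (q - window.center) ** 2 + window.bias_offset


def _histogram(samples: np.ndarray, cfg: WhamConfig) -> tuple[np.ndarray, int]:
    """Left-closed right-open binning; samples outside the range are dropped."""
    lo, hi = cfg.range
    width = (hi - lo) / cfg.n_bins
    idx = np.floor((samples - lo) / width).astype(int)
    inside = (idx >= 0) & (idx < cfg.n_bins)
    counts = np.bincount(idx[inside], minlength=cfg.n_bins).astype(float)
    return counts, int(np.count_nonzero(~inside))


def solve_wham_1d(windows: list[UmbrellaWindow],
                  config: WhamConfig = WhamConfig()) -> FreeEnergyProfile:
    """Self-consistent 1D WHAM solve over a set of umbrella windows.

    Iterates the window free-energy constants until their maximum absolute
    change falls below ``config.tol``; if ``max_iter`` is exhausted first the
    partial result is returned with ``converged=False``.  A run of empty
    bins splitting the sampled range attaches a connectivity warning, since
    the two sides are then only anchored to each other through the (possibly
    poor) tails.
    """
    if not windows:
        raise ValueError("need at least 1 window")
    beta = 1.0 / config.kT
    centers = config.bin_centers
    K, B = len(windows), config.n_bins

    counts_per_window = np.empty((K, B))
    n_dropped = 0
    for k, w in enumerate(windows):
        counts_per_window[k], dropped = _histogram(w.samples, config)
        n_dropped += dropped
        if counts_per_window[k].sum() == 0:
            raise ValueError(
                f"window {k} (center {w.center}) has no samples inside "
                f"range {config.range}"
            )
    M = counts_per_window.sum(axis=0)  # total counts per bin
    N = counts_per_window.sum(axis=1)  # samples per window

    # bias energies at bin centers: (K, B)
    U = np.stack([bias_energy(w, centers) for w in windows])

    sampled = M > 0
    log_M = np.where(sampled, np.log(np.maximum(M, 1)), -np.inf)
    log_N = np.log(N)

    f = np.zeros(K)  # window free-energy constants, kcal/mol
    iterations = 0
    converged = False
    for iterations in range(1, config.max_iter + 1):
        # log denominator per bin: logsumexp_k [ log N_k + beta f_k - beta U_ki ]
        log_denom = logsumexp(log_N[:, None] + beta * (f[:, None] - U), axis=0)
        log_p = np.where(sampled, log_M - log_denom, -np.inf)
        # normalize (not required for convergence, keeps numbers tame)
        log_p -= logsumexp(log_p[sampled])
        # update f_k: exp(-beta f_k) = sum_i p_i exp(-beta U_ki)
        f_new = -config.kT * logsumexp(log_p[None, :] - beta * U, axis=1,
                                       b=None)
        f_new -= f_new[0]  # gauge: fix first window constant to 0
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < config.tol:
            converged = True
            break

    log_denom = logsumexp(log_N[:, None] + beta * (f[:, None] - U), axis=0)
    log_p = np.where(sampled, log_M - log_denom, -np.inf)
    F = np.full(B, np.inf)
    F[sampled] = -config.kT * log_p[sampled]
    F -= F[sampled].min()

    warnings: list[str] = []
    if not converged:
        warnings.append(
            f"WHAM did not converge in {config.max_iter} iterations "
            f"(last max |Δf| above tol {config.tol})"
        )
    idx = np.flatnonzero(sampled)
    if idx.size and np.any(np.diff(idx) > 1):
        warnings.append(
            "sampled range is split by empty bins; windows may not overlap "
            "and relative free energies across the gap are unreliable"
        )
    if n_dropped:
        warnings.append(f"{n_dropped} sample(s) outside histogram range dropped")

    return FreeEnergyProfile(bin_centers=centers, F=F, counts=M,
                             converged=converged, iterations=iterations,
                             kT=config.kT, window_free_energies=f,
                             warnings=warnings, n_dropped=n_dropped)


def reweight_2d(windows: list[UmbrellaWindow], profile: FreeEnergyProfile,
                config: WhamConfig, bins2: int,
                range2: tuple[float, float]) -> FreeEnergySurface:
    """Reweight biased samples onto (primary, auxiliary) coordinate bins.

    Each sample s from window k carries the unbiasing weight
    1 / Σ_k' N_k' exp[β (f_k' − U_k'(q_s))]; the weighted 2D histogram gives
    F(q, y) = −kT ln p(q, y), anchored to minimum 0.
    """
    for k, w in enumerate(windows):
        if w.aux_samples is None:
            raise ValueError(f"window {k} (center {w.center}) has no aux_samples")
    if profile.window_free_energies is None or len(
            profile.window_free_energies) != len(windows):
        raise ValueError("profile does not match the window set")
    if not profile.converged:
        raise ValueError("profile must be converged before reweighting")
    beta = 1.0 / config.kT
    f = profile.window_free_energies
    log_N = np.log([w.samples.size for w in windows])

    q_all = np.concatenate([w.samples for w in windows])
    y_all = np.concatenate([w.aux_samples for w in windows])
    # log denominator per sample over all windows
    log_denom = logsumexp(
        np.stack([log_N[k] + beta * (f[k] - bias_energy(windows[k], q_all))
                  for k in range(len(windows))]),
        axis=0,
    )
    log_w = -log_denom
    weights = np.exp(log_w - log_w.max())

    x_edges = config.bin_edges
    lo2, hi2 = range2
    if not lo2 < hi2:
        raise ValueError(f"range2 must satisfy lo < hi, got {range2}")
    y_edges = np.linspace(lo2, hi2, bins2 + 1)
    H, _, _ = np.histogram2d(q_all, y_all, bins=[x_edges, y_edges],
                             weights=weights)
    raw, _, _ = np.histogram2d(q_all, y_all, bins=[x_edges, y_edges])
    F = np.full_like(H, np.inf)
    filled = H > 0
    F[filled] = -config.kT * np.log(H[filled])
    F -= F[filled].min()
    return FreeEnergySurface(
        x_centers=config.bin_centers,
        y_centers=0.5 * (y_edges[:-1] + y_edges[1:]),
        F=F, weights=H, raw_counts=raw, kT=config.kT,
    )


def barrier_height(profile: FreeEnergyProfile,
                   basin_a: tuple[float, float],
                   basin_b: tuple[float, float]) -> float:
    """Free-energy barrier from basin_a's minimum to basin_b along the 1D
    profile: the maximum F between the two basin minima, minus F at basin_a's
    minimum (kcal/mol)."""

    def _basin_argmin(basin):
        lo, hi = basin
        mask = (profile.bin_centers >= lo) & (profile.bin_centers <= hi) \
            & np.isfinite(profile.F)
        if not np.any(mask):
            raise ValueError(f"basin {basin} contains no sampled bins")
        idx = np.flatnonzero(mask)
        return idx[int(np.argmin(profile.F[idx]))]

    ia = _basin_argmin(basin_a)
    ib = _basin_argmin(basin_b)
    if ia == ib:
        return 0.0
    lo, hi = min(ia, ib), max(ia, ib)
    path = profile.F[lo:hi + 1]
    if not np.all(np.isfinite(path)):
        raise ValueError(
            "unsampled gap between basins; barrier undefined "
            f"(empty bins between coordinates {profile.bin_centers[lo]:.4g} "
            f"and {profile.bin_centers[hi]:.4g})"
        )
    return float(path.max() - profile.F[ia])


# ---------------------------------------------------------------------------
# Window file I/O: one plain-text file per window (1 or 2 columns), plus a
# TSV metadata file with columns path, center, spring.


def read_windows(meta_path: str | Path,
                 stride: int = 1) -> list[UmbrellaWindow]:
    """Load umbrella windows from a metadata TSV + per-window sample files.

    ``stride`` subsamples every file (a decorrelation stride; no estimator
    is applied).  Relative paths in the metadata are resolved against the
    metadata file's directory.
    """
    meta_path = Path(meta_path)
    meta = pd.read_csv(meta_path, sep="\t", comment="#")
    for col in ("path", "center", "spring"):
        if col not in meta.columns:
            raise ValueError(f"metadata file lacks required column {col!r}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    windows = []
    for _, row in meta.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = meta_path.parent / p
        data = np.loadtxt(p, comments="#", ndmin=2)[::stride]
        aux = data[:, 1] if data.shape[1] > 1 else None
        windows.append(UmbrellaWindow(center=float(row["center"]),
                                      spring=float(row["spring"]),
                                      samples=data[:, 0], aux_samples=aux))
    return windows


def write_windows(windows: list[UmbrellaWindow], out_dir: str | Path,
                  header_comment: str | None = None) -> Path:
    """Write windows in the on-disk format read_windows expects; returns the
    metadata file path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, w in enumerate(windows):
        fname = f"window_{k:03d}.dat"
        cols = (w.samples if w.aux_samples is None
                else np.column_stack([w.samples, w.aux_samples]))
        header = "bias = 0.5 * spring * (q - center)^2"
        if header_comment:
            header = header_comment + "\n" + header
        np.savetxt(out_dir / fname, cols, header=header)
        rows.append({"path": fname, "center": w.center, "spring": w.spring})
    meta_path = out_dir / "windows.tsv"
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)
    return meta_path
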