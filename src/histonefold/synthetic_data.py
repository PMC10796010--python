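"""Synthetic inputs with known ground truth.

Real histone-folding trajectories come from expensive coarse-grained or
all-atom MD engines.  This module generates structurally faithful stand-ins
whose true answers are known by construction, so every analysis in the
package can be validated end to end:

* ideal α-helices and two-helix "dimers" built at a prescribed crossing
  angle (for axis fitting and the native-vs-inverted angle analysis);
* noisy conformational ensembles around a reference structure (for Q, RMSD,
  RMSF and clustering);
* Metropolis Boltzmann samples from analytic 1D/2D potentials under harmonic
  umbrella biases (for WHAM, with the analytic profile as ground truth);
* sequence pairs with head-tail hydrophobic symmetry planted at a stated
  strength (for the symmetry statistic and its permutation test).

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import ChainRecord, Structure
from .symmetry import HYDROPHOBIC_DEFAULT
from .wham import KT_300K, UmbrellaWindow, bias_energy

__all__ = [
    "HelixParams",
    "GeneratorConfig",
    "make_ideal_helix",
    "make_two_helix_dimer",
    "perturb_ensemble",
    "HarmonicPotential",
    "DoubleWellPotential",
    "Separable2DPotential",
    "TwoBasin2DPotential",
    "default_ladder",
    "sample_potential",
    "make_symmetric_pair",
]

AMINO20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class HelixParams:
    """Canonical α-helix geometry: 1.5 Å rise, 2.3 Å radius, 100°/residue."""

    rise: float = 1.5  # Å per residue
    radius: float = 2.3  # Å
    twist: float = 100.0  # degrees per residue


@dataclass(frozen=True)
class GeneratorConfig:
    """Bundled generator settings; the seed makes every output reproducible."""

    seed: int = 0
    helix: HelixParams = field(default_factory=HelixParams)
    noise_amplitude: float = 1.0  # Å, per-coordinate std
    symmetry_strength: float = 0.8

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def make_ideal_helix(n_res: int, axis=(0.0, 0.0, 1.0),
                     params: HelixParams = HelixParams()) -> np.ndarray:
    """Cα coordinates of an ideal α-helix whose N→C axis points along ``axis``.

    Residue i sits at (r cos(iτ), r sin(iτ), i·rise) before rotation, so
    consecutive Cα–Cα distances are ≈ 3.8 Å with canonical parameters.  For
    short helices an incomplete final turn tilts the principal axis slightly
    off the geometric screw axis, so the rotation is chosen to put the
    *fitted* (principal-component) axis exactly along ``axis``.
    """
    if n_res < 4:
        raise ValueError(f"need at least 4 residues for a helix, got {n_res}")
    i = np.arange(n_res)
    tau = np.radians(params.twist)
    local = np.column_stack([
        params.radius * np.cos(i * tau),
        params.radius * np.sin(i * tau),
        params.rise * i,
    ])
    local -= local.mean(axis=0)
    # principal axis of the local cloud, oriented N->C
    _, _, Vt = np.linalg.svd(local, full_matrices=False)
    pa = Vt[0]
    if np.dot(pa, local[-1] - local[0]) < 0:
        pa = -pa
    v = np.asarray(axis, dtype=float)
    nrm = np.linalg.norm(v)
    if nrm <= 1e-12:
        raise ValueError("axis must be a non-zero vector")
    R = Rotation.align_vectors((v / nrm)[None, :], pa[None, :])[0].as_matrix()
    return local @ R.T


def _poly_ala_chain(chain_id: str, coords: np.ndarray) -> ChainRecord:
    n = len(coords)
    return ChainRecord(chain_id, ["A"] * n, coords, list(range(1, n + 1)))


def make_two_helix_dimer(angle_deg: float, n_res: int = 20,
                         separation: float = 10.0,
                         params: HelixParams = HelixParams()) -> Structure:
    """Two ideal helices (chains A, B) whose N→C axes cross at ``angle_deg``.

    The helices are parallel-transported apart along the mutual perpendicular
    so the chains never clash (min inter-chain Cα distance ≥ 4 Å; the
    separation is widened automatically if the default is too tight).
    """
    if not 0.0 <= angle_deg <= 180.0:
        raise ValueError(f"angle must be in [0, 180], got {angle_deg}")
    half = math.radians(angle_deg) / 2.0
    d_a = np.array([math.sin(half), 0.0, math.cos(half)])
    d_b = np.array([-math.sin(half), 0.0, math.cos(half)])
    coords_a = make_ideal_helix(n_res, d_a, params)
    coords_b = make_ideal_helix(n_res, d_b, params)
    for sep in (separation, 1.5 * separation, 3.0 * separation):
        A = coords_a + np.array([0.0, -sep / 2.0, 0.0])
        B = coords_b + np.array([0.0, +sep / 2.0, 0.0])
        dmin = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2).min()
        if dmin >= 4.0:
            return Structure(
                [_poly_ala_chain("A", A), _poly_ala_chain("B", B)],
                name=f"two_helix_{angle_deg:g}deg",
            )
    raise RuntimeError(
        f"could not place helices without clashes at separation {separation}"
    )


def perturb_ensemble(reference: Structure, n_frames: int, amplitude: float,
                     seed: int = 0) -> list[Structure]:
    """I.i.d. isotropic Gaussian displacement of every Cα in every frame.

    ``amplitude`` is the per-coordinate standard deviation in Å (so the RMS
    displacement per atom is amplitude·√3).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    frames = []
    for k in range(n_frames):
        chains = [
            ChainRecord(c.chain_id, list(c.residue_codes),
                        c.ca_coords + rng.normal(0.0, amplitude,
                                                 c.ca_coords.shape),
                        list(c.author_numbers))
            for c in reference.chains
        ]
        frames.append(Structure(chains, name=f"{reference.name}_frame{k}",
                                frame_index=k))
    return frames


# ---------------------------------------------------------------------------
# Analytic potentials (energies in kcal/mol; coordinates dimensionless unless
# stated otherwise)


@dataclass(frozen=True)
class HarmonicPotential:
    """U(q) = k (q − center)²  — note no ½; k is the full curvature/2... i.e.
    the variance of the Boltzmann distribution is kT / (2k)."""

    k: float = 20.0  # kcal/mol per unit²
    center: float = 0.5

    def energy(self, q):
        q = np.asarray(q, dtype=float)
        return self.k * (q - self.center) ** 2

    def analytic_profile(self, q):
        """Free energy up to a constant: the potential itself."""
        return self.energy(q)


@dataclass(frozen=True)
class DoubleWellPotential:
    """Symmetric quartic double well U(q) = h·[((q−c)/w)² − 1]² with minima
    at c ± w and an analytic barrier of exactly h between them."""

    barrier: float = 3.0 * KT_300K  # kcal/mol
    center: float = 0.5
    halfwidth: float = 0.25

    def energy(self, q):
        q = np.asarray(q, dtype=float)
        u = ((q - self.center) / self.halfwidth) ** 2 - 1.0
        return self.barrier * u ** 2

    @property
    def minima(self) -> tuple[float, float]:
        return (self.center - self.halfwidth, self.center + self.halfwidth)

    def analytic_profile(self, q):
        return self.energy(q)


@dataclass(frozen=True)
class Separable2DPotential:
    """U(q, y) = U1(q) + ½ k_y (y − y0)²: the y-marginal is the same parabola
    in every q slice — the ground truth for conditional-profile checks."""

    base: HarmonicPotential = field(default_factory=HarmonicPotential)
    k_y: float = 0.005  # kcal/mol per unit² (y may span e.g. degrees)
    y0: float = 90.0

    def energy(self, q, y):
        return (self.base.energy(q)
                + 0.5 * self.k_y * (np.asarray(y, dtype=float) - self.y0) ** 2)


@dataclass(frozen=True)
class TwoBasin2DPotential:
    """Smooth two-basin surface built as −kT ln of a two-Gaussian mixture.

    The default basins sit at (0.8, 140) and (0.35, 40) in (Q-like, angle-
    like) coordinates — a fixture mimicking a native-plus-inverted dimer
    landscape, with the basin locations known exactly by construction.
    """

    minima: tuple[tuple[float, float], ...] = ((0.8, 140.0), (0.35, 40.0))
    widths: tuple[tuple[float, float], ...] = ((0.07, 15.0), (0.05, 12.0))
    weights: tuple[float, ...] = (1.0, 0.7)
    kT_ref: float = KT_300K

    def energy(self, q, y):
        q = np.asarray(q, dtype=float)
        y = np.asarray(y, dtype=float)
        total = np.zeros(np.broadcast(q, y).shape)
        for (q0, y0), (sq, sy), w in zip(self.minima, self.widths, self.weights):
            total = total + w * np.exp(
                -((q - q0) ** 2) / (2 * sq ** 2) - ((y - y0) ** 2) / (2 * sy ** 2)
            )
        return -self.kT_ref * np.log(total + 1e-300)


def default_ladder(n_windows: int = 12, lo: float = 0.0, hi: float = 1.0,
                   spring: float = 100.0) -> list[tuple[float, float]]:
    """Evenly spaced umbrella centers across [lo, hi] with one spring."""
    return [(float(c), spring) for c in np.linspace(lo, hi, n_windows)]


def _metropolis_1d(energy, q0, n_samples, kT, rng, burn_frac=0.1, thin=1):
    n_burn = max(200, int(burn_frac * n_samples * thin))
    step = 0.2
    q = q0
    e = float(energy(q))
    accepted = attempted = 0
    samples = np.empty(n_samples)
    total = n_burn + n_samples * thin
    out = 0
    for it in range(total):
        prop = q + rng.normal(0.0, step)
        e_prop = float(energy(prop))
        attempted += 1
        if e_prop <= e or rng.random() < math.exp(-(e_prop - e) / kT):
            q, e = prop, e_prop
            accepted += 1
        if it < n_burn:
            if attempted == 50:  # adapt toward 30–50% acceptance
                rate = accepted / attempted
                if rate < 0.3:
                    step *= 0.8
                elif rate > 0.5:
                    step *= 1.25
                accepted = attempted = 0
        elif (it - n_burn) % thin == 0:
            samples[out] = q
            out += 1
    if attempted and accepted / attempted < 0.01:
        raise RuntimeError(
            f"Metropolis acceptance rate {accepted / attempted:.3%} < 1%; "
            f"step size {step:.3g} unsuitable for this potential"
        )
    return samples[:out]


def _metropolis_2d(energy, start, n_samples, kT, rng, steps=(0.2, 10.0),
                   burn_frac=0.1, thin=1):
    n_burn = max(200, int(burn_frac * n_samples * thin))
    step = np.array(steps, dtype=float)
    x = np.array(start, dtype=float)
    e = float(energy(x[0], x[1]))
    accepted = attempted = 0
    samples = np.empty((n_samples, 2))
    total = n_burn + n_samples * thin
    out = 0
    for it in range(total):
        prop = x + rng.normal(0.0, step)
        e_prop = float(energy(prop[0], prop[1]))
        attempted += 1
        if e_prop <= e or rng.random() < math.exp(-(e_prop - e) / kT):
            x, e = prop, e_prop
            accepted += 1
        if it < n_burn:
            if attempted == 50:
                rate = accepted / attempted
                if rate < 0.3:
                    step *= 0.8
                elif rate > 0.5:
                    step *= 1.25
                accepted = attempted = 0
        elif (it - n_burn) % thin == 0:
            samples[out] = x
            out += 1
    if attempted and accepted / attempted < 0.01:
        raise RuntimeError(
            f"Metropolis acceptance rate {accepted / attempted:.3%} < 1%; "
            f"step sizes {step} unsuitable for this potential"
        )
    return samples[:out]


def sample_potential(potential, windows, n_samples: int,
                     kT: float = KT_300K, seed: int = 0, thin: int = 1,
                     aux_range: tuple[float, float] = (0.0, 180.0),
                     check_overlap: bool = True) -> list[UmbrellaWindow]:
    """Metropolis Boltzmann samples of a potential under umbrella biases.

    ``windows`` is a list of (center, spring) pairs; each window runs an
    independent Metropolis chain on U(q) + ½·spring·(q − center)², discards a
    10% burn-in (during which the step size is auto-tuned to 30–50%
    acceptance), and records ``n_samples`` values.  2D potentials (those
    whose ``energy`` takes two arguments) sample (q, y) jointly, with the
    bias acting on q only, and store y in ``aux_samples``.

    Adjacent windows whose sample ranges do not intersect make WHAM
    ill-posed; by default this is checked and raised at generation time.
    """
    if n_samples < 100:
        raise ValueError("need at least 100 samples per window")
    is_2d = _takes_two_args(potential.energy)
    result: list[UmbrellaWindow] = []
    for k, (center, spring) in enumerate(windows):
        rng = np.random.default_rng(np.random.SeedSequence((seed, k)))
        dummy = UmbrellaWindow(center=center, spring=spring,
                               samples=np.zeros(1))

        if is_2d:
            def biased(q, y, _w=dummy):
                return float(potential.energy(q, y) + bias_energy(_w, q))
            y0 = 0.5 * (aux_range[0] + aux_range[1])
            draws = _metropolis_2d(biased, (center, y0), n_samples, kT, rng,
                                   thin=thin)
            win = UmbrellaWindow(center=center, spring=spring,
                                 samples=draws[:, 0], aux_samples=draws[:, 1])
        else:
            def biased(q, _w=dummy):
                return float(potential.energy(q) + bias_energy(_w, q))
            draws = _metropolis_1d(biased, center, n_samples, kT, rng,
                                   thin=thin)
            win = UmbrellaWindow(center=center, spring=spring, samples=draws)
        result.append(win)

    if check_overlap and len(result) > 1:
        order = np.argsort([w.center for w in result])
        for a, b in zip(order[:-1], order[1:]):
            if result[a].samples.max() < result[b].samples.min():
                raise RuntimeError(
                    f"umbrella windows at centers {result[a].center} and "
                    f"{result[b].center} do not overlap; increase sampling "
                    "or soften the springs"
                )
    return result


def _takes_two_args(fn) -> bool:
    import inspect

    params = [p for p in inspect.signature(fn).parameters.values()
              if p.default is inspect.Parameter.empty
              and p.kind in (p.POSITIONAL_ONLY, p.POSITIONAL_OR_KEYWORD)]
    return len(params) >= 2


# ---------------------------------------------------------------------------
# Sequence pairs with planted head-tail hydrophobic symmetry


def make_symmetric_pair(length: int, strength: float, seed: int = 0,
                        hydrophobic_set=HYDROPHOBIC_DEFAULT) -> tuple[str, str]:
    """A sequence pair (a, b) whose hydropathy patterns mirror head-to-tail.

    With probability ``strength`` position i of ``a`` is "conserved" at the
    mirrored position (length−1−i) of ``b``: hydrophobic residues are copied
    verbatim (conserved hydrophobic positions are what anchor real
    reversed-sequence alignments), non-hydrophobic ones are replaced by a
    random non-hydrophobic residue.  With probability 1 − strength the
    mirrored residue is uniform over the 20-letter alphabet.  strength 1
    yields a perfect hydrophobic mirror (symmetry score 1 against
    reverse(b)); strength 0 an independent random partner.
    """
    if length < 10:
        raise ValueError("length must be >= 10")
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    hset = sorted(str(h).upper() for h in hydrophobic_set)
    nonh = sorted(set(AMINO20) - set(hset))
    a = "".join(rng.choice(list(AMINO20), size=length))
    b_rev = []
    for ch in a:
        if rng.random() < strength:
            b_rev.append(ch if ch in hset else str(rng.choice(nonh)))
        else:
            b_rev.append(str(rng.choice(list(AMINO20))))
    b = "".join(reversed(b_rev))
    return a, b
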