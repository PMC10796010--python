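# Methods

This note records the models, conventions, parameter choices and known
limitations behind each analysis, in enough detail to reproduce or audit the
numbers the package computes.

## Structures and numbering

All analyses operate at the Cα level: structures are ordered chains of
residues, each with one Cα coordinate (Å) and a one-letter code. PDB files
are parsed with Biopython; only residues with a CA atom are kept (including
HETATM residues such as selenomethionine, translated via the extended IUPAC
table, unknowns → X). Alternate locations are resolved to the highest
occupancy conformer, exact ties going to the alphabetically first altloc —
a deterministic rule matching common practice.

Two numbering systems coexist deliberately. *Author* numbering (the file's
own, possibly offset or gapped) is preserved for segment declarations and
reports. *Internal* numbering is 0-based and contiguous per chain and is
what sequence separations use: numbering gaps must not inflate |i − j| in
the Q formula, and missing residues do not create placeholders. Helix
segment ranges (e.g. which residues constitute α2 in a given histone) are
explicit user input via `SegmentSpec`, never guessed: helix boundaries vary
between structures and the choice belongs in the record of any reported
angle.

## Q order parameter

Q = (1/N) Σ exp[−(r_ij − r_ij^N)²/(2σ_ij²)] over a declared pair set, with
the intra-chain set restricted to sequence separation ≥ 3 (the literal
reading of the i < j−2 summation convention). The pair width grows weakly
with separation, σ_ij = σ0 (1 + |i−j|)^ε, with σ0 = 1 Å and ε = 0.15 — the
convention used by coarse-grained folding models, which is where this
flavor of Q originates. Separation is meaningless across chains, so
inter-chain pairs use the constant σ0 (1 + 3)^0.15 ≈ 1.23 Å. Both constants
are exposed in `QSpec` and echoed in serialized contact references, because
upstream uses of Q rarely print them.

Modes: `monomer` (intra-chain pairs), `dimer` (intra + all inter),
`interface` (inter-chain pairs only, restricted to pairs within 9.5 Å in
the native). The interface restriction exists because unrestricted
inter-chain Q is dominated by long, uninformative distances; passing
`interface_native_cutoff=inf` recovers the literal all-pairs variant.
Whether a "dimer Q" should include intra-chain pairs is genuinely
convention-dependent; here `dimer` includes them and `interface` answers
the pure cross-chain question, so both readings are available.

For homodimers the chain correspondence is ambiguous;
`enumerate_chain_pairings` returns every length-preserving bijection and
`q_score_best` maximizes over them, which is invariant to relabeling the
conformation's chains.

Fraction of native contacts uses a separate, binary definition: native
contacts are Cα pairs within 8 Å (separation ≥ 3 intra-chain; all pairs
inter-chain), and a contact is "formed" when the conformation distance is
within 1.2 × the cutoff. Both constants are arguments; the defaults are a
common Cα contact convention, not a published criterion.

## Superposition, RMSD, RMSF

Kabsch superposition via SVD of the weighted cross-covariance, with the
smallest singular vector's sign corrected so the rotation is always proper
(det = +1): mirror images of chiral sets therefore superpose with strictly
positive RMSD. Degenerate (collinear/coincident) point sets leave the
rotation underdetermined; the minimal-angle rotation aligning the principal
directions is returned to keep results deterministic.

RMSF_i = sqrt(mean_t |x_i(t) − ⟨x_i⟩|²) after removing rigid motion. The
default reference is the iterated mean structure (two passes, seeded by the
first frame); `align_to="first"` reproduces single-reference analyses.
A quantitative caveat encoded in the tests: the rigid-body fit absorbs 6 of
the 3N fluctuation degrees of freedom, so for i.i.d. isotropic noise of
per-coordinate std s the aligned-ensemble RMSF converges to
s·√3·√(1 − 2/N), not s·√3; the closed form is only reached as N grows.

Pairwise-RMSD conformational clustering is average-linkage agglomerative
(scipy), cut at a user cutoff (default 4 Å); the method is not dictated by
any upstream convention, and average linkage with an explicit cutoff is the
standard way to support "no consensus structure" statements. Each cluster
reports its medoid (minimum mean intra-cluster distance, ties to the lowest
frame index).

## Helix axes and the crossing angle

A helix axis is the dominant principal component of the segment's Cα cloud,
sign-fixed so it points N→C; `fit_rms` (RMS perpendicular scatter) flags
non-helical segments. A principal-component axis is robust for the 8–30
residue segments of interest and needs no local-axis machinery. Because
which vector definition is used affects reported angles, an alternative
`endpoints` mode (normalized last-minus-first Cα vector) is provided, and
reports should name the mode. The inter-axis angle is arccos of the dot
product, kept on [0°, 180°]: with N→C orientation the native handshake and
the inverted dimer sit at complementary angles (θ and 180° − θ), which is
the whole diagnostic.

The synthetic two-helix dimer generator builds ideal α-helices (rise 1.5
Å/residue, radius 2.3 Å, twist 100°/residue — textbook values) at a
prescribed crossing angle. For short helices the incomplete final turn
tilts the principal axis ~2° off the geometric screw axis, so the generator
aligns the *fitted* axis with the request; construction targets are then
met to well under a degree.

## WHAM

The bias convention is U_k(q) = ½ k_spring (q − q_k)², the common MD
definition of a harmonic restraint — fixed explicitly (and written into
window-file headers) because a silent factor-of-two in the spring is the
classic WHAM bug. kT defaults to 0.593 kcal/mol (300 K). Histogram bins are
left-closed right-open; out-of-range samples are dropped and counted.

The solver iterates the standard self-consistent equations on the window
free-energy constants f_k in log space (logsumexp throughout), gauge-fixed
to f_0 = 0, until max |Δf_k| < 10⁻⁷ kcal/mol (max 100 000 iterations;
non-convergence returns the partial result with a flag and warning).
Constant offsets added to any window's bias are absorbed exactly by the
f_k — tested as a gauge-invariance property. A run of empty bins splitting
the sampled range attaches a connectivity warning, since the two sides are
then anchored only through unsampled territory.

2D surfaces are built by reweighting, not 2D umbrellas: each sample from
window k carries weight 1/Σ_k' N_k' exp[β(f_k' − U_k'(q_s))] with the
converged constants, and the weighted 2D histogram gives
F(q, y) = −kT ln p. The surface stores both the reweighted mass and the raw
sample counts per cell; "adequately sampled" always means raw counts,
because the reweighted mass is on an arbitrary scale.

`barrier_height` is the 1D mini-max path: maximum F between the two basin
argmins minus F at the starting basin's minimum; an unsampled bin between
the basins makes the barrier undefined and raises.

Validation uses analytic potentials from the synthetic module: a harmonic
well (recovered parabola RMS error < 0.15 kcal/mol with 12 windows × 5 000
samples), a quartic double well with an exactly 3 kT barrier (recovered
within 0.3 kT averaged over seeds), a separable 2D potential whose
conditional y-profile must be the same parabola in every q slice, and a
two-Gaussian-basin surface mimicking a native-plus-inverted landscape with
basins at (0.8, 140°) and (0.35, 40°), both of which must reappear as local
minima of the reconstruction. The free-energy scale of real histone
landscapes (barriers of several kcal/mol from engine-level sampling) is not
reproducible here — the package validates the *procedure* on analytic
truth, which is the strongest claim desk-scale inputs support.

The Metropolis generator auto-tunes its step during a 10% burn-in toward
30–50% acceptance and errors out below 1% acceptance; chains are seeded per
window from (seed, window index) so window sets are reproducible and
windows are independent. Adjacent windows whose sample ranges fail to
intersect raise at generation time. No autocorrelation estimator is
applied; a decorrelation stride is available at file-read time but samples
are otherwise treated as given.

## Rg scaling

`fit_power_law` is least squares on (log N, log Rg) — exact on noiseless
power-law data, scale-equivariant, residuals summing to zero. Rg is
computed from Cα coordinates with unit weights by default (mass weighting
available); dimer N is the total residue count over both chains, stated in
output metadata. The bundled reference line (R0 = 2.2 Å, ν = 0.38) is a
stand-in of the right order for compact globular proteins, *not* a
published survey fit — it is mandatory-config-with-default precisely so no
invented constant is mistaken for a literature value.

## Head-tail hydrophobic symmetry

The statistic formalizes a qualitative observation: hydrophobic positions
of one histone reappear at mirrored positions of its partner read C→N, a
relic of descent from a duplicated helix-strand-helix motif. Sequence `a`
is globally aligned against reverse(`b`) with Needleman–Wunsch affine gaps
(Biopython PairwiseAligner; gap of length L costs open + (L−1)·extend;
defaults match +2 / mismatch −1 / open −5 / extend −1, or a published
matrix such as BLOSUM62 by name). The symmetry score is

    (# residue–residue columns with both sides hydrophobic) /
    (# residue–residue columns with at least one side hydrophobic).

Gap columns are excluded from the ratio: they reflect length mismatch
rather than positional asymmetry, and excluding them keeps the score at
exactly 1 for any two all-hydrophobic sequences however they align. The
hydrophobic set defaults to {A, V, L, I, M, F, W, C} (tyrosine excluded for
its polar hydroxyl, toggleable); the set is echoed in every report because
the choice moves the score.

Significance: the residues of `b` are shuffled (composition preserved — the
null must test positional structure, not composition bias) and the score
recomputed n_perm times; p = (1 + #{null ≥ observed})/(n_perm + 1), the
add-one estimator, which is never 0 and is exactly uniform under the null.
Calibration is tested by KS against uniform over replicated null pairs.
Multiple sequences are handled as all-pairs pairwise reports, not a true
MSA — a deliberate narrowing that keeps the statistic well-defined.

The generator plants symmetry by *conserving* residues across the mirror:
with probability `strength`, position i of `a` is mirrored at position
L−1−i of `b` — hydrophobic residues copied verbatim, non-hydrophobic ones
replaced by a random non-hydrophobic residue — otherwise the mirrored
residue is uniform over the 20-letter alphabet. Verbatim copying matters:
a planted signal carried only by hydropathy class, with random letters
within class, is invisible to letter-level alignment (verified during
development — the aligner gaps it into noise). Conserved-mostly-hydrophobic
positions are also exactly what real reversed-sequence alignments anchor
on. Expected score at strength s with a 8/20 hydrophobic alphabet is
s·0.4/(0.4 + 0.12(1−s)) + chance terms ≈ 0.79 at s = 0.8, matching the
±0.1 recovery tolerance used in tests.

## Synthetic data: what it does and does not emulate

The generators provide geometric fixtures (ideal helices, crossing-angle
dimers), statistical ensembles (i.i.d. isotropic Gaussian perturbations),
Boltzmann samples of analytic potentials, and planted sequence pairs. They
are ground-truth machines, not physics: perturbation ensembles have no
correlated motions, chain connectivity constraints or anharmonicity;
synthetic dimers are poly-alanine two-helix bundles, not histone folds;
analytic potentials have none of the orthogonal slow degrees of freedom
that make real umbrella sampling hard. Passing tests therefore demonstrate
correctness of the estimators and geometry under known truth — not that any
particular biological system behaves a certain way. Every generator is a
pure function of its arguments including the seed.

## Problem sizes and numerical choices

Default validation sizes — 12 windows × 5 000 Metropolis samples for WHAM
checks, 10 000 frames for RMSF closed-form checks, 500 replicates × 99
permutations for null calibration, 40 replicates × 999 permutations for
power, 100 random short pairs for the alignment oracle, 5 random 5-point
problems for the rotation-grid oracle — were chosen as the smallest sizes
at which the analytic expectations are sharp relative to Monte-Carlo noise;
the whole suite runs in about a minute on one CPU. Tolerances follow the
sharpest claim each check supports: machine precision for algebraic
identities (rigid invariance, complementarity, exact fits), 1e-3 Å against
the grid oracle (its own resolution), and analytic-noise-limited bounds
(0.15 kcal/mol, 0.3 kT, ±0.02 on the scaling exponent) for stochastic
reconstructions.

## Known limitations

- Cα-only throughout; no side-chain contacts, secondary-structure
  assignment, or all-atom anything.
- WHAM only (no MBAR), 1D bias coordinate only; 2D surfaces come from
  reweighting and inherit the 1D sampling's metastability in the auxiliary
  coordinate (visible as depth errors of order 1–2 kT for narrow secondary
  basins in the two-basin validation).
- Pairwise alignment only; tie-breaking among co-optimal alignments follows
  the aligner's deterministic first result.
- The Rg reference line is a labelled stand-in; conclusions about
  "monomer-like" dimers require a user-supplied calibrated reference.
- Helix ranges are user input; reported angles depend on them and on the
  axis mode (principal component vs endpoints), both of which are recorded
  in output manifests.
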