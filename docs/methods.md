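# Methods

This note documents the models and procedures motorscape implements,
the assumptions behind them, the numerical choices that matter, and
what the synthetic benchmarks do and do not establish about real data.

## Scope and data model

motorscape operates downstream of simulation: it consumes conformational
ensembles (multi-model PDB) and per-frame boost-potential logs, and
produces collective-variable series, free-energy profiles, cluster
reports, and distribution summaries. An `Ensemble` is a single topology
shared by a stack of coordinate frames; every frame must agree on the
(chain, residue number, atom name) sequence, which is the invariant all
per-frame analyses rely on. Residue numbers are taken verbatim from the
input (author numbering) so that anchors defined in a publication's
numbering select the intended atoms; insertion codes are rejected
rather than silently renumbered. Alternate locations resolve to the
highest-occupancy copy (ties to the lexicographically smallest altloc
id). Hydrogens are kept on read and excluded by the `heavy` filter.

Boost logs are per-replica files paired with per-replica coordinate
files; when multiple replicas are combined the frame order is the input
list order and each frame records its replica of origin. The
`amber_gamd` dialect requires the caller to name the column holding the
total boost energy — column layouts vary between engine versions, so
the package never guesses.

## Collective variables

**Distances.** Atom-pair distances (and the cleft width, a semantically
named Cα–Cα distance) are plain Euclidean norms per frame.

**Crossing angles.** Each secondary-structure element is reduced to the
principal axis of its Cα positions, sign-oriented from the first
residue toward the last (N→C). The angle between two elements is the
arccos of the directed axes' dot product, in [0°, 180°]. Directed axes
(rather than the undirected [0°, 90°] convention) preserve the
distinction between parallel and antiparallel packing, which is what
makes rigor-like (≈5–10°) and prepowerstroke-like (≈20–25°) geometries
distinguishable. A two-endpoint chord axis is available as an
alternative (`method="chord"`).

A caution on the principal-axis fit: the PCA axis of an *ideal* α-helix
is tilted from the true helix axis because the phase of the backbone
spiral correlates with position along the axis. The tilt is ≈2.3° for a
12-residue helix and falls below 1° only around 24 residues. Crossing
angles between two elements of similar internal geometry largely cancel
this tilt, but absolute axis directions of short elements should be
read with that bias in mind. The synthetic generator therefore defines
its planted angles on the fitted axes (rotating the second element
about an axis perpendicular to the first element's fitted axis), which
makes the planted value exact by the equivariance of PCA under rigid
rotation.

**SASA and contact areas.** Solvent-accessible surface area uses
Shrake–Rupley quadrature with a deterministic golden-angle (Fibonacci)
lattice, default 960 points, probe 1.4 Å, Bondi-style radii
(C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å; unlisted elements
default to 1.70, all overridable). The quadrature is evaluated in the
system's principal-axes frame with a deterministic sign convention, so
areas are exactly invariant under rigid-body motion of the input (up to
frame-computation round-off; systems with degenerate inertia may show
quadrature-level noise instead). Against closed forms, an isolated
sphere is exact to well under 1% at 960 points, and two-sphere
occlusion matches the spherical-cap formula within 2%; doubling the
lattice from 1920 points changes areas by <0.5% on the test systems.

The contact area between groups A and B is half the buried area,

    area = (SASA_A,alone + SASA_B,alone − SASA_AB) / 2.

By default "alone" means the group in isolation and the complex is
A∪B only (pairwise mode): symmetric, nonnegative, zero beyond the
geometric cutoff 2·(r_max + probe), and independent of everything else
in the structure. A `context=True` mode includes all other atoms as
occluders in every term; which convention a given publication used for
its motif–actin areas is usually unstated, so both are provided and
reports should name the mode.

**Superposition and RMSD.** Kabsch's SVD solution with reflection
correction (determinant +1), optional weights, and a degenerate-geometry
error when the covariance is rank-deficient (collinear or coincident
points leave the rotation undetermined). RMSD series superpose each
frame on a fit selection and report RMSD over a measure selection,
matched to the reference by (chain, residue number, atom name); heavy
atoms by default, `CA` for backbone-level comparisons.

## Reweighting

GaMD samples the biased density p*(ξ) ∝ p(ξ)·exp(−βΔV) pointwise, so
the equilibrium density is p(ξ) ∝ p*(ξ)·⟨exp(βΔV)⟩_ξ. The exponential
average is evaluated per histogram bin through its Maclaurin/cumulant
expansion

    ln⟨e^{βΔV}⟩ ≈ β C₁ + β² C₂/2! + β³ C₃/3!

with C₁ the bin mean of ΔV, C₂ the bin variance, C₃ the third central
moment, truncated at a configurable order (default 2; orders 1–3
implemented). Second order is exact when ΔV is Gaussian within the bin,
which is the operating regime GaMD's harmonic boost is designed for;
`anharmonicity_check` flags bins whose |skewness| exceeds a threshold
(default 0.5) as unreliable under that truncation. The PMF is
F_j = −k_BT [ln p*_j + correction_j], anchored so the minimum over
adequately sampled bins is zero. Cumulants are *local* (per bin): a
single global reweighting factor would cancel on anchoring and could
not reshape the landscape.

Defaults: k_B = 0.0019872041 kcal/(mol·K); temperature 300 K
(configurable — the package takes the simulation temperature as input
rather than assuming one); 50 bins in 1D, 40×40 in 2D; bins with fewer
than 20 frames are masked (NaN) rather than reported. Two identities
pin the estimator down and are tested exactly: ΔV ≡ 0 reduces to the
plain histogram PMF to floating precision, and adding any constant to
all ΔV leaves the anchored profile unchanged.

**Basins.** Local minima over the unmasked-bin graph (2-neighborhood in
1D, 4-neighborhood in 2D) found by an ascending sweep with union-find:
when two catchments meet, the shallower minimum is merged into the
deeper one if its depth below the connecting saddle (its persistence)
is less than `depth_threshold` (default 0.5 kcal/mol). Survivors are
labeled m1, m2, … by ascending free energy. This lowest-saddle flood
criterion is simpler than a full watershed; it labels well-separated
minima reliably but does not delineate basin boundaries.

## Ensemble analysis

**Clustering.** GROMOS leader algorithm on a pairwise superposition
RMSD matrix: the frame with the most neighbors within the cutoff
(default 2.0 Å) becomes a cluster center, it and its neighbors are
removed, repeat; ties break to the lowest frame index. Clusters are
renumbered by descending population and each cluster's centroid is the
member minimizing mean RMSD to the rest. Clustering is permutation
equivariant and the cutoff is always recorded in reports, since cluster
counts are meaningless without it.

**Densities and peaks.** Gaussian-kernel density on a 512-point grid
spanning the data range padded by three bandwidths; Silverman's rule by
default (on the effective sample size when weights are given), fixed
bandwidths in CV units accepted. Weights can be the reweighting
module's per-frame factors, so a "most probable distance" refers to the
recovered equilibrium distribution rather than the biased one. Peaks
are local maxima with prominence at least a fraction (default 5%) of
the global mode, ordered by density. A zero-variance series yields a
degenerate single-delta report, not an error.

## Synthetic data: what it emulates and what it does not

The generator produces the two kinds of ground truth the pipeline
needs:

* **Toy motors** — two rigid Cα-only domains (an 18-residue ideal helix
  plus a 12-residue idealized strand each) with the cleft distance and
  helix/strand crossing angle planted exactly before Gaussian jitter,
  optional discrete conformers for cluster-recovery tests, and a
  per-frame truth ledger. A 100-frame, two-conformer benchmark
  (15 Å/5° vs 35 Å/25°, 0.1 Å jitter) separates the conformers by
  ≈10 Å RMSD.
* **Boosted samples** — draws from a known potential under the exact
  GaMD boost form. 1D potentials (harmonic; double well
  V = b((2(x−c)/s)² − 1)²) are sampled by inverse-CDF on a 40 001-point
  grid spanning the thermally occupied range; the 2D Gaussian basin
  (V = ½k_BT (x−μ)ᵀΣ⁻¹(x−μ), so the unbiased Boltzmann density has
  exactly the specified covariance) uses Metropolis with proposal SD =
  5 × grid spacing, 10⁴ burn-in, thinning 5. Per-sample ΔV is computed
  analytically, and the true PMF is returned on an analysis grid.

Sampling is at the distribution level by design: the reweighting
pipeline consumes (ξ, ΔV) pairs only, so simulating dynamics would add
correlation structure without adding verifiable truth. Consequently the
benchmarks do **not** probe: time-correlated frames (every synthetic
frame is independent, so masked-bin and error statistics are optimistic
relative to real trajectories), force-field realism, multi-chain
topology complexity, hydrogen placement, or boost distributions whose
bin-wise anharmonicity defeats the second-order truncation (that regime
is exactly what `anharmonicity_check` is for). Passing tests establish
the correctness of the estimators, not the sufficiency of any
particular simulation's sampling.

Determinism: one global seed expands to per-component streams via
`numpy.random.SeedSequence(seed, spawn_key=(component,))`; identical
spec + seed reproduces outputs bit for bit.

## Pipeline

Stages run in a fixed order (load → pair boosts → CVs →
densities/peaks → 1D/2D PMFs → basins → clustering → reference RMSD →
report); a failure aborts with the stage named. Config validation
collects *all* errors rather than stopping at the first. Reports are
JSON (sorted keys, full precision) with CSV side tables; the only
nondeterministic field is the timestamp, and reruns are verified
byte-stable apart from it. Input files are identified by SHA-256 in the
report's provenance block.

Problem sizes in the shipped benchmarks — 2×10⁵ reweighting samples,
100–200-frame clustering ensembles, 120-frame end-to-end runs — were
chosen so each recovery target is measured with comfortable statistical
margin while the whole suite stays interactive (seconds, not minutes).

## Known limitations

* No mmCIF or binary trajectory formats; the `Ensemble` contract is
  format-agnostic, so adding readers does not touch the analysis.
* No WHAM/MBAR multi-ensemble estimators and no block-bootstrap error
  bars on PMFs (a documented extension; the per-bin counts needed for
  it are already in the profile object).
* Basin merging is persistence-based only; no watershed boundaries.
* The principal-axis tilt of short helices (above) biases absolute axis
  directions; prefer elements of ≥ 20 residues or the chord method when
  the absolute direction matters.
* Insertion codes are rejected; structures using them must be
  renumbered upstream.
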