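# motorscape

Conformational-landscape analysis for molecular motors: collective
variables over structural ensembles, energetic reweighting of
Gaussian-accelerated MD (GaMD) trajectories into free-energy profiles,
RMSD clustering, and distribution analysis — with a synthetic-data
generator that makes every stage verifiable against exact ground truth.

## The problem

Enhanced-sampling studies of actomyosin-like systems characterize how a
motor's conformational states (e.g. prepowerstroke vs. rigor) differ
along a handful of geometric coordinates: the actin-binding cleft width
(a Cα–Cα distance between residues flanking the cleft), the crossing
angle between core secondary-structure elements (HF helix vs. the β5
strand of the transducer), salt-bridge distances, and buried contact
areas between surface motifs and the actin filament. GaMD adds a
harmonic boost

    ΔV(x) = ½ k (E − V(x))²    for V(x) < E,  else 0

to flatten barriers; equilibrium statistics must then be recovered by
reweighting. motorscape implements the full post-simulation chain:

1. **structure I/O** — multi-model PDB ensembles, per-frame boost logs,
   motif/anchor selections (author residue numbering, altloc handling);
2. **geometry** — distance CVs, cleft width, helix/strand crossing
   angles from principal-axis fits, Shrake–Rupley SASA on a
   deterministic Fibonacci lattice, pairwise buried contact areas,
   Kabsch superposition and RMSD series;
3. **reweighting** — the per-bin cumulant expansion
   `ln⟨e^{βΔV}⟩ ≈ βC₁ + β²C₂/2 + β³C₃/6` (orders 1–3, default 2) turning
   boosted histograms into 1D/2D potentials of mean force
   `F(ξ) = −k_BT ln p(ξ)` anchored at zero, with under-sampled bins
   masked, local-minimum basin labeling (m1, m2, …), and a per-bin
   anharmonicity diagnostic;
4. **ensemble analysis** — GROMOS leader clustering over pairwise RMSD
   with centroid extraction, weighted kernel densities, peak detection,
   and most-probable-value summaries;
5. **synthetic data** — toy two-domain motors with exactly planted
   cleft distances, crossing angles and conformational clusters, and
   boosted samples from known 1D/2D potentials with exact per-sample ΔV;
6. **pipeline** — a validated YAML config running the whole per-state
   analysis into a deterministic JSON + CSV report, plus state-to-state
   comparison.

## Worked example

Recover a known double-well free-energy profile from boosted samples
(`examples/02_reweighting_pmf.py`):

```python
from motorscape import find_basins, pmf_1d
from motorscape.synthetic import BoostedSampleSpec, sample_boosted

spec = BoostedSampleSpec(
    potential="double_well", params={"b": 3.0, "s": 4.0},
    k_boost=0.08, boost_E=3.5, temperature=300.0,
    n_samples=200_000, seed=1,
)
sample = sample_boosted(spec)
profile = pmf_1d(sample.samples, sample.dV, temperature=300.0,
                 bins=50, cumulant_order=2, min_count=20)
basins = find_basins(profile, depth_threshold=1.0)
```

Output:

```
samples: 200000, boost range [0.00, 0.49] kcal/mol
max |PMF − truth| over sampled bins: 0.282 kcal/mol
basin m1: x = +2.03, F = 0.00 kcal/mol
basin m2: x = -2.01, F = 0.01 kcal/mol
recovered barrier: 3.01 kcal/mol (planted 3.00)
```

The reweighted profile tracks the planted potential to well under
k_BT (0.6 kcal/mol at 300 K), both wells are labeled as basins with
near-degenerate free energy (they are symmetric by construction), and
the recovered barrier matches the planted 3 kcal/mol.

The other examples each exercise one capability with its own printed
recovery check: `01_collective_variables.py` (planted cleft/angle
through the CV chain), `03_clustering.py` (two planted conformers →
two pure clusters), `04_distribution_peaks.py` (bimodal distance modes
at 3.80/6.92 Å vs planted 3.8/6.9), and `05_full_pipeline.py` (two toy
states through the full pipeline; the report delta recovers the planted
5 Å cleft closure).

A thin CLI mirrors the library (`motorscape run --config cfg.yaml`,
`motorscape compare a.json b.json`, `motorscape cv distance ...`,
`motorscape pmf ...`, `motorscape cluster ...`, `motorscape peaks ...`,
`motorscape simulate toy-motor|boosted|bimodal ...`).

## Layout

```
src/motorscape/    io, geometry, reweighting, analysis, synthetic,
                   pipeline, cli
examples/          one narrative script per capability
tests/             pytest suite (unit, property, acceptance)
scripts/           acceptance.py
docs/methods.md    models, assumptions, numerical choices, limitations
```
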