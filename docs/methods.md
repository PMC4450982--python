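# Methods

This note documents the models, conventions and numerical choices behind
`enrichkit`, in the order the pipeline uses them.

## The pROC-AUC metric

The screening-performance metric is the area under the semi-logarithmic ROC
curve.  For a best-pose-reduced score table with N_a bioactives and N_d
decoys, each bioactive *i* contributes its decoy fraction
f_i = (#decoys ranked above *i*) / N_d, and

    pROC-AUC = (1/N_a) · Σ_i log10(1/f_i).

Conventions, all of which matter at the margins:

* **Floor.**  f_i is floored at 1/N_d, so a bioactive retrieved before
  every decoy contributes log10(N_d) rather than a divergent term.  This
  choice reproduces the analytic random baseline log10(e) ≈ 0.434 (verified
  by seeded Monte Carlo in the test suite and the acceptance script) and
  caps the metric at log10(N_d), attained exactly at perfect separation.
  The floor is configurable per call.
* **Ties.**  A decoy with exactly the same score as a bioactive counts half
  above / half below (average-rank convention) — unbiased in expectation
  and deterministic.  The pooled global rank (1..N_a+N_d) breaks exact ties
  by molecule id, so rank permutations are reproducible.
* **Other bioactives** are ignored when counting what is "above" a
  bioactive: only decoys enter the false-positive denominator.
* **Failed dockings** (missing scores) rank strictly worst, after every
  scored molecule, ties among them by id.  A benchmark molecule never
  leaves the denominator: a bioactive with no score contributes f = 1.
* **Orientation** (higher- vs lower-is-better) is an explicit per-table
  flag, never inferred from data.  Negating all scores and flipping the
  flag yields the identical ranking (tested).

## Preparation deltas and the safety margin

Differences between two conditions are plain AUC differences
(first − second).  A difference is called significant only outside a
symmetric safety margin (default ±0.05, the run-to-run spread of a
stochastic docking heuristic); the boundary is inclusive, so |Δ| = 0.05 is
non-significant.  Per-target delta columns are summarised as three counts
(favors-first / favors-second / non-significant).

## Attribution experiments

* **Match/mismatch grid.**  Eight score tables keyed by which of two
  schemes prepared (target, bioactives, decoys).  The marginal effect of a
  factor is the mean AUC change when toggling that factor with the other
  two fixed (equivalently, the difference of cell-average AUCs; the test
  suite checks both routes agree).
* **Protomer shuffling.**  Scores of a chosen id set (typically the
  molecules whose two preparations differ) are replaced by the donor
  scheme's scores; the list is re-ranked and the AUC delta reported.
  Shuffling back with the same ids restores the original AUC exactly.
* **Deletion** removes ids outright and recomputes the AUC with updated
  N_a/N_d and floor; it equals the AUC of a freshly built table without
  those ids (construction-path independence, tested).
* **Rank/score shifts.**  Per-molecule Δrank (pooled global ranks; the
  bioactive-only rank is also reported, since the two are easy to
  conflate), Δscore, preference fractions (ties split 0.5/0.5), five-number
  box statistics per role and side (linear-interpolation quartiles), and R²
  as the squared Pearson correlation of the paired values — not a
  through-origin regression.  Molecules with |Δrank| above a cutoff
  (default 500) are flagged and annotated with available causes
  (protonation / tautomer / ring-conformation difference, rotor count > 8,
  else "none").
* **Outlier isolation.**  The published procedure was visual ("red dots");
  the operationalisation here removes, k times, the point with the largest
  orthogonal residual from the slope-1 line (intercept refit as the mean
  offset after every removal; ties broken by id).  The remaining core's R²
  and the outlier subset's |Δscore|-vs-property R² are reported.  k is a
  user input, not estimated.

## Structure audits

All comparisons operate on heavy atoms only — the preparation schemes
differ precisely in the hydrogens they add, which would otherwise dominate.
Two variants must have isomorphic heavy-atom graphs (element +
connectivity); anything else is reported as an invalid pair, not scored.

* **Protonation difference**: total formal charge or total hydrogen count
  differs; or, when a bond-order-preserving mapping exists, formal charges
  moved between atoms (zwitterion shift).
* **Tautomer difference**: identical formula (same total H and charge) but
  the heavy-skeleton bond orders and/or hydrogen placement cannot be
  reconciled by any mapping.  A pure protonation difference never qualifies;
  a combined protonation-plus-skeleton change is reported as protonation.
  Bond orders are compared as perceived (aromatic = 1.5), so alternative
  kekulizations of the same aromatic system do not raise false tautomer
  calls.
* **Ring-conformation difference**: for each non-aromatic ring of size
  5–7, endocyclic torsions are compared under every heavy-atom mapping
  (circular differences); the pair is flagged when even the best mapping
  leaves a torsion more than the threshold apart.  Default threshold 30°,
  configurable — the published calls were qualitative, so this rule is this
  package's operationalisation.  Exocyclic torsions are out of scope.
* **Symmetry-aware RMSD**: minimum heavy-atom RMSD over all graph
  isomorphisms, with optimal rigid-body superposition (Kabsch, proper
  rotations only) per mapping; an in-place mode (no superposition) is also
  exposed since the reference tool's behaviour is not documented.  Above a
  mapping cap (default 10 000) the search falls back to a Hungarian
  assignment within canonical-rank symmetry classes, anchored to one seed
  mapping — an upper bound that can settle in a nearby local optimum; the
  cap and the fallback are documented at the call site and exercised in the
  tests.
* **Rotatable bonds**: acyclic single bonds between two non-terminal heavy
  atoms, excluding amide C–N.  The definition is fixed and documented here
  because descriptor vendors disagree; the test suite pins it against an
  independent SMARTS enumeration.

## The synthetic benchmark generator

Real inputs for these analyses come from commercial docking on curated
benchmark sets and cannot be redistributed, so the generator produces
score lists *of the same shape* with known ground truth:

    score_first  = base + bias_slope·NHA + affinity_offset·[bioactive] + ε,
                   ε ~ N(0, noise_sd²)
    score_second = score_first + jitter + shift·[flagged]
                   − coupling·n_rot·|ε′|·[flexible]

Defaults (the study conditions of the package's property tests):

| parameter | default | rationale |
|---|---|---|
| n_actives / n_decoys | 40 / 1200 | DEKOIS shape: 30 decoys per bioactive |
| NHA distribution | N(27.6, 5²), actives and decoys | bioactive-set mean NHA of a mid-size benchmark; decoys are property-matched |
| base_score / bias_slope | 0 / 2.725 per heavy atom | decoy scores ≈ 75 ± 16, the magnitude of reported decoy score statistics; base folded entirely into the size term so that removing the slope is a clean null (a large constant divided by √N would itself reorder the list) |
| affinity_offset | 15 | baseline pROC-AUC lands in the 0.3–2.0 band observed for real benchmarks |
| noise_sd / prep_noise_sd | 8 / 2 | score scatter vs run-to-run/preparation jitter |
| protomer_diff_fraction | 2/40, 435/1200 | observed protomer-difference census of a paired-preparation benchmark |
| protomer_shift_sd | 8 | score change of a re-protonated molecule, same scale as the noise |
| flexible subset | 10 bioactives, rotors 9–14, coupling 1.0 | the flexible-bioactive subset whose score diverges most between preparations |
| tautomer / ring diff counts | 1 / 2 decoys | the rarer structural causes |

`scripts/calibrate_generator.py` prints the diagnostics these defaults were
fixed with (baseline AUC band, decoy score statistics, normalization
recovery, null neutrality, shuffle-vs-full-delta).  The generator records
every random draw in a truth table sufficient to rebuild both score tables
exactly; `replay` regenerates bit-identically from the config and seed, and
a versioned YAML sidecar makes that durable.

With `with_structures=True` each molecule is additionally realised as a
small real template molecule (embedded with a seeded ETKDG): protomer pairs
differ only in formal charges/H counts (heavy coordinates copied, so their
pairwise RMSD is 0), tautomer pairs in H placement and bond orders, ring
pairs are two verified-distinct ring conformers of the same molecule, and
unflagged molecules are identical copies.  In this mode NHA and rotor
counts come from the template structures, not the configured Gaussian, so
SD files and score tables can never disagree; structure-backed benchmarks
are therefore meant for down-scaled audit runs, while score-level
experiments use the structure-free path at full size.

**What passing tests do and do not show.**  The generator is a linear
additive score model with planted structure — it emulates the *shape* of a
benchmark and the *mechanisms* under study (size bias, protomer swaps,
flexibility-coupled divergence), not any docking program's functional form,
pose geometry, or protein context.  Property tests on it validate the
pipeline's bookkeeping and the direction/magnitude-class of effects, not
absolute AUC values of real screens.

## Problem sizes and tolerances

Monte-Carlo checks use 1000 replicates for the random baseline (tolerance
±0.01 around log10 e) and 20 seeds for the generator-recovery properties
(≥ 90% success criteria; null median within the ±0.05 margin).  Geometric
identities (rigid-motion RMSD, automorphism minimization) are asserted at
1e-6 Å; analytic identities at 1e-9 or tighter.  Reports print two decimals
(the resolution at which the deltas are interpreted against the ±0.05
margin); TSV outputs keep full precision, and score tables round-trip
bit-exactly through their shortest-representation float format.

## Known limitations

* The AUC of a *set* is reported without a confidence interval; the safety
  margin stands in for run-to-run spread but not for benchmark-composition
  uncertainty.
* Combined protonation+tautomer changes are reported as protonation only.
* The ring-conformation rule compares torsion tuples, not puckering
  coordinates; near-threshold puckers depend on the 30° default.
* The class-fallback RMSD is an upper bound (see above).
* Mixed-sign score columns are refused for normalization unless forced,
  because dividing across zero reorders ambiguously; energy-like
  (all-negative) columns normalize toward zero, which is usually *not* what
  is wanted scientifically — the guideline flags exist for exactly this
  reason.
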