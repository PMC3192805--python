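# Methods

## Model

A contact potential is a symmetric 20×20 matrix `e_ij` of pair free
energies in a dimensionless RT-like scale.  Its 210 unique elements (upper
triangle including the diagonal) are treated as the observations; every fit
and summary in the package is unweighted over this set, so each unordered
pair counts exactly once.

The coarse-grained model combines a two-class hydrophobic/polar (HP)
description of side-chain interactions with a binary backbone
hydrogen-bonding (HB) capability in which every residue except proline can
donate the backbone amide hydrogen bond:

    e_ij = η₀ − (η_HH·HH_ij + η_HP·HP_ij + η_HB·HB_ij) + q_i + q_j + ε_ij

* `HH`, `HP`, `HB` are 0/1 symmetric indicator matrices; the polar–polar
  class is the implicit complement of `HH + HP`.
* The η coefficients are **positive stabilization magnitudes entering with
  a minus sign**.  This sign convention makes η_HB the free energy gained
  per backbone hydrogen bond and lets η₀ (the solvent–solvent constant)
  absorb any overall shift of the matrix: adding a constant `c` to every
  element changes η₀ by `c` and nothing else, so the ratio η_HB/η_HH is
  shift-invariant (verified by test).
* `q_i` is a residue-specific one-body term, interpreted as the free energy
  of forming hydrogen-bonded secondary structure plus a class-level
  solvation free energy.

Under the default hydropathy partition (hydrophobic C,F,L,W,V,I,M,Y,A,P;
hydrophilic H,G,N,T,S,R,Q,D,K,E) the unique-pair counts are |HH| = 55,
|HP| = 100, |PP| = 55 and |HB| = 190.

## Gauge

The full model is degenerate: per-class constants can be moved between `q`,
η_HH, η_HP and η₀ without changing any reconstructed element.  The gauge is
fixed by requiring Σq = 0 separately over the hydrophobic and hydrophilic
residues.  This choice is not arbitrary — the published fitted one-body
scales bundled with the package sum to zero within each class to the
printed precision, identifying the convention their authors used.  The
fit is parametrized directly in the gauge-reduced coordinates (9 + 9 free
q parameters), so the constraints hold exactly rather than to a solver
tolerance.

## Estimation: joint vs sequential

Two strategies are implemented for the full model and both are exposed:

* **joint** (default): one constrained least-squares problem in all 24
  parameters (via statsmodels OLS on the reduced design).  This is the
  statistically clean estimator; it recovers noiseless synthetic matrices
  exactly (≤ 1e-9 per parameter, tested) and its coefficient standard
  errors have ≈ 95% two-SE coverage under the generative model (tested over
  500 seeded replicates).
* **sequential**: fit the two-body model first, then fit `q` to its
  residuals under the gauge.  The two-body block then equals the
  two-body-only fit exactly.

The reason both exist is a near-degeneracy of the design: `1 − HB_ij` is
the indicator "proline is in the pair", which differs from the q-column of
proline only on the single Pro–Pro element.  η_HB and q_P are therefore
almost collinear, and the joint estimate of the two-body block can drift
far from the two-body-only fit while changing the residual sum of squares
very little.  Published one-body scales for the native-fold matrix match
the **sequential** estimates almost perfectly (r ≈ 0.9996, rms difference
≈ 0.015 RT on the bundled data) and published two-body tables match the
two-body-only fit, so reproduction analyses use `strategy="sequential"`;
statistical analyses (recovery, coverage) use `joint`.

Standard errors are ordinary OLS standard errors from the residual
variance.  The design-matrix rank is checked and a degenerate
classification (e.g. a single-class partition) raises an explicit error.

## Simulated-annealing refinement

`anneal_refine` minimises the same residual sum of squares stochastically,
as a solver-independent cross-check of the closed-form fit: single-
coordinate Gaussian proposals with Metropolis acceptance, geometric cooling
(T₀ = 1.0, factor 0.995 applied once per sweep over the parameters,
2×10⁵ steps), and best-seen tracking.  The proposal standard deviation
scales as 0.05·√T with a floor of 1e-3 so the late, effectively greedy
phase can still refine; cooling per sweep (rather than per step) keeps the
exploration phase long enough that a zeros-initialised run reaches the
closed-form optimum to well under 1e-3 in the objective (tested).  The
search runs in gauge-reduced coordinates, so the output satisfies the
constraints exactly.  Everything is deterministic under the seed.  Note
that along the near-degenerate η_HB/q_P direction the objective is almost
flat, so individual parameters converge more slowly than the objective;
parameter-level agreement with the closed form is asserted from a
closed-form initialisation.

## Distribution summaries

"Gaussian fit" means sample moments (the Gaussian MLE) of each class's
unique elements — deterministic and bin-free, rather than histogram least
squares.  Standard deviations use the population convention (divide by N),
fixed so the summaries are exactly reproducible.  Component weights follow
the element-count convention (class size / 210 = 26.2% / 47.6% / 26.2%
under the default partition).  Published decompositions of the native-fold
matrix quote contact *fractions* of 37% / 39% / 24% for the same three
components; those fractions do not equal element counts and their
convention (likely structure-derived contact frequencies, data not part of
this package) is surfaced here as unreconciled — the component means and
sds, which do match the class-sample convention, are the tested quantities.
Histograms anchor their bins at the smallest element, making the counts
exactly translation-invariant.

## Solvation correction and proline policy

`solvation_correct` subtracts each hydropathy class's mean from its
members and records the means as the solvation shifts (hydrophobic penalty
≈ 1.45 RT in magnitude, hydrophilic shift ≈ −0.07 RT for the bundled
q-value scale).  Published analyses of these scales imply different
effective treatments of proline in different panels, so the grouping of
proline is an explicit policy pinned per analysis: the native-fold
comparison reproduces r ≈ 0.98 with proline grouped hydrophilic; the
strand-potential comparisons reproduce r ≈ 0.96/0.97 with proline excluded
(19 residues).  The published β-sheet "removal costs" (+0.32 with −0.51,
and +0.34 with −0.25) are the *negated* class means of the bundled sheet
free-energy columns under the proline-excluded grouping; the package
reports the means and the examples print the costs.

## Sensitivity controls

* **Proline scaling**: "reduced k-fold" is interpreted multiplicatively —
  Pro–X free energies are divided by k (strand-pairing potentials have
  positive, destabilising Pro–X elements, so division moves them toward
  neutrality).  `find_pro_factor` bisects on k for a target η_HB/η_HH
  (tolerance 1e-3 on the ratio) after the monotonicity of the ratio in k
  has been checked on the bracket.
* **Reclassification battery**: the two-body model is refitted under
  alternative partitions (proline hydrophilic; proline and alanine
  hydrophilic).  On a strand-like potential the ratio stays above 1; on
  the bundled native-fold matrix the refit drives η_HB toward zero because
  proline's contacts there are *more* stabilising than its reclassified
  polar peers — the battery reports whatever the refit gives rather than
  forcing an expected sign.
* **Disulfide handling**: the Cys–Cys element mixes covalent chemistry
  into the statistics; either it is dropped from the fitted set (default)
  or absorbed by a dedicated binary regressor.  Metrics are computed over
  the fitted element set.

## Synthetic data

`generate_matrix` draws `ε` once per unique element and mirrors it,
matching the 210-independent-variables picture; it never perturbs the two
triangles independently.  Ground-truth `q` vectors are projected onto the
gauge on construction (scales transcribed from rounded tables can be off
by ~1e-4).  The default truth mimics a native-fold decomposition:
η = (3.64, 1.48, 1.76, 0.07) RT, the bundled fitted one-body scale as `q`,
and noise sd 0.23 RT — the residual scale of the full-model fit to the
real matrix — which reproduces the published fit quality (r ≈ 0.99).  What
the generator does *not* emulate: heavy-tailed residuals, correlated
errors from shared contact-counting statistics, and any structure beyond
the model itself — so passing recovery tests demonstrate the estimator is
correct and calibrated under the model's own assumptions, not that real
potentials satisfy them.

## Bundled data and problem sizes

The package ships two text fixtures: the Miyazawa–Jernigan (1996)
contact-energy matrix transcribed to two decimals, and a table of six
per-residue scales (fitted one-body terms of the native-fold and two
strand-pairing potentials, the Li–Tang–Wingreen q-values, and
Steward–Thornton-derived β-sheet free energies).  Strand-pairing and other
external matrices are consumed from user-supplied files with optional
SHA-256 validation.  All analyses run on 210-element fits in well under a
second; the acceptance script's heaviest step is the 500-replicate
coverage estimate (~3 s total on one CPU), and the default annealing
schedule takes ~2 s.

## Known limitations

* The energy scale is treated as uniform across matrices; no unit
  conversion is attempted.
* The reclassification control on the native-fold matrix does not
  reproduce published ratio values (0.55/0.61); see the discussion above —
  a plain refit cannot produce them from this matrix, and the original
  fitting procedure for that control is not documented in enough detail to
  reproduce.
* β-sheet propensity-to-free-energy conversion is out of scope; the
  already-converted scales are consumed as data.
* One-body standard errors are not reported (only the two-body block has
  OLS SEs attached).
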