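# Methods

`zbind` models the binding affinity of fixed-length peptides to MHC
molecules as a quantitative structure–activity relationship (QSAR) over
amino-acid principal-component descriptors.  This note records the models,
the defaults and the design choices that were genuinely open.

## Z-scale descriptors

Each of the 20 standard amino acids is described by its scores on the first
three principal components of a panel of physicochemical property scales:
z1 (polarity/hydrophobicity), z2 (molecular size), z3 (electronic
character).  `aa_properties.compute_zscales` derives such scores from any
property table by correlation-matrix PCA: property columns are standardized
to mean 0, variance 1 (sample sd, ddof = 1) over the 20 residues, the
correlation matrix is eigendecomposed, and scores are projections of the
standardized data onto unit eigenvectors.  Scores therefore carry the
eigenvalue weighting — component j has variance equal to its eigenvalue —
so downstream regressions need no further descriptor scaling.

PCA signs are arbitrary; they are fixed by anchoring z1(F) > 0, z2(G) > 0
and z3(P) > 0 (hydrophobic phenylalanine positive on the polarity axis,
tiny glycine positive on the size axis, rigid proline positive on the
electronic axis), which matches the orientation of the canonical table.
Beyond three components the largest-|loading| entry of each eigenvector is
made positive.  Exactly degenerate eigenvalues are ordered by a stable sort
of the eigendecomposition, which is deterministic for a fixed input.

`canonical_zscales()` ships the fixed three-component table used by every
other module (provenance `canonical_table1`).  Its three components jointly
capture about 90% of the variance of the 31-scale panel they were derived
from; the individual proportions were not retained and are reported as NaN.

A peptide of length L becomes a flat descriptor vector of 3L reals,
{z1(aa1), z2(aa1), z3(aa1), …, z3(aaL)}.  Groove positions are labelled
P1–P9 for class-I 9-mers and N-3…N-1, P1–P9, C+1…C+3 for class-II 15-mers
(open groove, three peptide-flanking residues on each side).  All
affinities are handled as natural logs of ic50 in nM; ic50 ≤ 0 is rejected
and no input capping is applied (censoring is modelled explicitly by the
generator instead).

## PLS regression and VIP

The linear predictor is single-response NIPALS PLS.  Descriptor columns are
centered but not unit-scaled (the z-scales already carry PC weighting); the
response is centered.  For a single response the NIPALS alternation
converges in one pass: each dimension has weight w_a ∝ X′y of the deflated
data, scores t_a = X w_a, and both X and y are deflated on t_a.  SSY_a is
the residual sum of squares of the centered response after a dimensions, so
SSY_{a−1} − SSY_a is the response SS explained by dimension a.  Regression
coefficients are W(P′W)⁻¹q; at A = rank(X) they coincide with ordinary
least squares (cross-checked in the tests against a normal-equations oracle
and against scikit-learn's NIPALS with scaling disabled).

Variable importance in projection:

    VIP_k = sqrt( K · Σ_a w_ak² (SSY_{a−1} − SSY_a) / (SSY_0 − SSY_A) )

normalized so Σ_k VIP_k² = K; descriptors with VIP > 1 are the most
relevant to the response.  Models that explain no response variance have no
defined VIP and are rejected.

The number of latent factors is chosen by 7-fold cross-validated PRESS.
The folds are contiguous blocks; when a seed is supplied the rows are
permuted once before the blocks are cut, because real binding compilations
arrive grouped by measurement subset and purely contiguous blocks would
confound fold and subset.  The selected A is the smallest whose PRESS is
within 2% of the global minimum (a parsimony rule; how many factors the
original analyses used for prediction, as opposed to detected, is not
documented anywhere we could follow).

Training sets smaller than 30 peptides are fitted but flagged
(`small_sample=True`) and warned about.

## Perceptron regression

The non-linear predictor is a three-layer perceptron whose geometry mirrors
the binding reaction: 3L inputs, a hidden layer of logistic units
(1/(1+e^{−x})) with as many nodes as binding-domain residues — 9 for
class I, 15 for class II — and one linear output, ln(ic50).  The logistic
is written with the conventional negative exponent; the opposite sign
convention is representationally identical because the weights absorb it.
The output node is linear since ln(ic50) is unbounded.

Training minimizes Σ(y − ŷ)² + λ·Σ(all weights²) by full-batch L-BFGS
(iteration cap 2000, gradient tolerance 1e-8) from uniform [−0.1, 0.1]
initial weights drawn from the seed; training is a pure function of
(data, hyperparameters, seed).  Inputs and the response are standardized
inside the wrapper and inverse-mapped on output — invisible at the
interface, but it conditions the optimizer.  The L2 formulation of the
overfitting penalty is our interpretation of a proprietary "overfitting
penalty coefficient"; its λ is tuned by log-space bisection until the
training r² lands within ±0.02 of the 0.9 target — 0.9 because the three
z-scales capture about 90% of the underlying property variance, so a
tighter training fit is memorization.  An unattainable target returns λ = 0
with a warning.

Two cross-validation schemes build prediction models:

* **Method 1** — multiple tours (seed-derived random holdback splits of
  1/3); each tour tunes λ on its training portion and the tour with the
  best holdback r² is returned (ties to the earlier tour).  Whether the
  original procedure kept one tour or averaged them is not documented;
  selection by validation is the simplest faithful reading.
* **Method 2** — nine independent uniform random subsets of 2/3 of the
  rows, one perceptron per subset (λ tuned once on the full set and
  shared).  Each peptide is used 9 × 2/3 = 6 times in expectation.
  Per-peptide predictions report the member mean, SEM = sd/√m and
  CV% = 100·sd/|mean|, all on the ln(ic50) scale (the modelling scale);
  per-allele summaries average the per-peptide CV%.  A mean within 1e-9 of
  zero yields a NaN CV sentinel.

## Evaluation

Predictors are benchmarked by (i) the squared Pearson correlation between
predicted and observed ln(ic50), and (ii) AROC after dichotomizing observed
affinities: strong binders at ic50 ≤ 50 nM, weak binders in (50, 500] nM,
non-binders above 500 nM.  AROC is the Mann–Whitney probability that a
random positive outranks a random negative with half-credit ties
(scikit-learn's `roc_auc_score`; an O(n²) pair-enumeration oracle guards it
in the tests).  Because predictions are ln(ic50) — lower is stronger —
ranking scores are negated predictions.  The WB column uses the nested
dichotomy binders (≤ 500 nM) vs non-binders; a one-vs-rest 3-class reading
would also be defensible, but the nested one matches common practice for
these datasets.  Degenerate inputs (one class only, zero variance) return
NaN sentinels rather than raising.

## Synthetic data

The generator reproduces the statistical structure documented in the public
binding compilations rather than any structural biology:

* **Subsets.**  Defaults: three subsets of 232, 167 and 49 peptides with
  mean ln(ic50) offsets 9.0, 6.8 and 4.9 — the two large subsets differ by
  2.2 ln units and the small high-affinity panel by 4.1, the documented
  between-subset gaps.  The 9.0 baseline (~8,100 nM) puts the bulk of the
  data in the weak/non-binder range, as observed.
* **Planted truth.**  ln(ic50) = subset offset + x·β + N(0, noise_sd²) with
  noise_sd = 2.0 by default (several e-folds of assay spread).  β defaults
  to a sparse planted effect (6 descriptors, 0.5 ln units per descriptor
  sd).  `generate_linear_truth` expresses effects per descriptor standard
  deviation so each planted position contributes equally to the response
  variance regardless of which principal component it sits on — this is
  what makes "high-effect position" well defined for VIP recovery checks.
* **Censoring.**  Values beyond an assay limit are snapped to the limit
  with a configured probability: deterministic snap-beyond-threshold rather
  than an additive spike mixture, matching the assay-limit interpretation.
  Limits below the grand mean offset act as detection floors (snap up),
  the rest as ceilings (snap down); each record is tested once against the
  nearest limit it lies beyond.  Defaults 1 / 20,000 / 78,125 nM with
  fractions 0.75 / 0.88 / 0.86, the fractions of the spiked histogram bins
  in the real compilations (124/166, 701/800, 168/195).
* **Composition.**  Residues are uniform over the 20 amino acids by
  default; an optional anchor-bias mode enriches hydrophobics at anchor
  pockets to mimic the highly non-random design of real training panels.
* Uncensored truth values and subset labels ride along as metadata
  (`ln_true`, `subset_tags`) and are never exposed through the standard
  TSV view used by models.

What passing tests on this generator do **not** show: real compilations
have correlated peptide panels (systematic single-position variants),
allele-specific anchor preferences and laboratory batch structure; the
generator's peptides are independent and its truth is exactly linear (or a
small planted network).  Recovery results here validate the machinery, not
field performance on IEDB-scale data.

## Visualization

VIP heat plots draw alleles × positions, one panel per PC, with a dot
marking cells above the VIP = 1 relevance threshold.  Three scalings:
`global_uniform` (one color range over all cells), `column_relative`
(per-position normalization) and `within_allele` (per-row).  The exact
palette and scaling arithmetic of the original figures is not documented,
so the palette is a perceptually uniform default and the modes implement
the captions' verbal descriptions.  Rendering never alters numbers: every
plot writes a sidecar TSV with the exact values (read it back with
`float_precision="round_trip"` for bit-equality).  Affinity histograms
overlay a normal fit and highlight bins holding > 20% of observations — our
operationalization of the "preponderance of identical measurements" spike.
Response surfaces evaluate any fitted model over a grid of two chosen
descriptors (observed training ranges) with the rest held at training
means; a static contour export stands in for interactive profiling.

## Problem sizes and numerics

Test and acceptance runs use synthetic datasets of 40–500 peptides for PLS
properties, 150–1,300 for perceptron training, 20 seed replicates for
censoring checks and 500 replicates for the subset-inclusion Monte-Carlo —
sizes at which every check is exact or statistically stable.  Numerical
tolerances: NIPALS rank guard 1e-10; VIP normalization asserted to 1e-6;
PLS/OLS agreement to 1e-6; AROC against enumeration to 1e-12.  Ties in
Method-1 tour selection go to the first tour; equal PRESS within 2%
resolves to the smaller factor count; zero-variance descriptor columns are
inert (coefficient 0) rather than errors.

## Known limitations

* The canonical z-scale table is shipped as printed; the 31-scale property
  panel behind it is not redistributed, so derived z-scales can be
  validated only against structural invariants, not against the canonical
  values.
* Long peptides are encoded whole; there is no 9-mer core/register
  alignment of the kind pan-allele tools perform.
* Method 1/Method 2 hyperparameters (tours, subsets, fractions) follow the
  documented defaults; no search over them is attempted.
* Published benchmark numbers against external web-server predictors are
  out of scope: they require third-party downloads and live comparator
  services.
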