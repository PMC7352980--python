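# Methods

## Problem and model

Chemocentric target prediction ("target fishing" or retro-virtual
screening) asks which protein target a query compound is most likely to
bind, given only its chemical similarity to ligands with known target
annotations.  Ranking single nearest neighbours is fragile; `targetkl`
instead performs a *one-to-group* comparison: it models the whole
distribution of similarities and scores a query against each target class
as a distance between distributions.

The raw input is a matrix of Jaccard–Tanimoto coefficients between ligand
conformers, with each conformer annotated to a target class.  Entries lie
in [0, 1] for a single similarity feature or [0, 2] for a combined
shape + pharmacophore-color score (the default).  The matrix is generally
asymmetric because the 3D overlay of a pair (A, B) is optimized
independently of (B, A); no symmetrization is applied by default.

Three estimation stages follow.

1. **Class Q-distribution.**  For class *n*, all intra-class ligand-pair
   similarities (self-pairs excluded, see below) form a sample whose
   density Φₙ is summarized by a histogram (1000 bins over the score
   range by default) and fitted by a K-component univariate Gaussian
   mixture

   Ξ(x) = Σₖ ωₖ g(x; mₖ, σₖ),

   with the weights, means and SDs estimated by
   expectation–maximization.  The mixture accommodates the right-skewed,
   non-Gaussian shapes real classes show; K = 1, 3 and 7 are the
   conventional panel.

2. **Query distribution.**  For a query ℓ of class *m* compared with
   class *n*, the column of similarities between the query and every
   ligand of class *n* is fitted by a single Gaussian using maximum
   likelihood: μ = sample mean, σ = divide-by-*n* SD.  A query-vector
   distribution is assumed unimodal — one compound against one coherent
   ligand set — which is why no mixture is fitted here.

3. **Divergence and discrimination.**  The relevance of query ℓ to class
   *n* is the Kullback–Leibler divergence D(query ‖ class).  For a K = 1
   class model the Gaussian–Gaussian closed form applies,

   D = ln(σⱼ/σᵢ) + (σᵢ² + (mᵢ − mⱼ)²) / (2σⱼ²) − ½,

   with the query as the first argument; for K > 1 the divergence is
   computed by numerical quadrature (below).  Each query is assigned the
   class ν minimizing its divergence; aggregating assignments by true
   class gives the M×M probability matrix P(ν = i | class m).  A class
   is *discriminable* when its diagonal entry is at least as large as
   every off-diagonal entry of its row (the necessary condition), and its
   feasibility index summarizes the self-assignment odds.

## Feasibility-index conventions

Two conventions are implemented for the feasibility index:

* `odds`: F = P/(1 − P), the plain odds of self-assignment;
* `sqrt-odds` (default): F = √(P/(1 − P)).

The odds form is the natural definition (F ≥ 1 iff P ≥ ½), but published
per-class feasibility values for the reference 4-target panel are
reproduced by the square-root form — every tabulated cell matches
√(P/(1−P)) to ≤ 5×10⁻⁴, e.g. √(0.9404/0.0596) = 3.9718 — and not by the
plain odds (0.9404/0.0596 = 15.78).  The default therefore follows the
square-root convention so that results are comparable with the published
panel; both modes are exposed and `sqrt-odds`² ≡ `odds` exactly.

## Numerical choices

* **EM.**  Initialization is deterministic quantile spread (component
  means at the (k+1)/(K+1) sample quantiles, equal weights, pooled SD)
  plus four seeded random restarts (component means drawn from the data);
  the best final log-likelihood wins.  Convergence when the
  log-likelihood increment drops below 1e−8, cap 500 iterations
  (non-convergence is flagged in the trace, not fatal).  Component SDs
  are floored at 1e−6 to prevent likelihood blow-up from collapsing
  components; flooring is flagged.  The per-iteration log-likelihood is
  recorded and is non-decreasing.  For K = 1 the first M-step lands
  exactly on the closed-form ML fit.
* **ML query fits** operate on the raw similarity vector by default.  A
  histogram-weighted variant (`fit_gaussian_ml_binned`, 100 bins by
  default) reproduces a fully binned pipeline; it differs from the raw
  fit by at most the binning error, of order one bin width.
* **Truncation is ignored in fitting**: Gaussians and mixtures are fitted
  and compared on ℝ although similarities live in a bounded range.  The
  fitted distributions sit well inside the range for realistic data, so
  the truncated-mass correction would be far below the other error terms.
* **Quadrature.**  K > 1 divergences use a 4096-point trapezoid rule over
  the score range padded by six times the largest component SD.  The
  integrand p·ln(p/q) is evaluated from *log*-densities, which keeps the
  tails exact where the plain densities underflow; against the
  Gaussian–Gaussian closed form the rule is accurate to ~1e−8, well
  inside the 1e−6 agreement asserted in the tests.  When only plain
  densities are available the denominator is floored at 1e−300 before
  the logarithm.  Tiny negative results from quadrature error are clipped
  to zero.
* **Histogram convention.**  Bins are half-open [xₖ, xₖ₊₁) with the last
  bin closed; masses (probability per bin) sum to one by construction and
  heights are recovered as mass/δx.  Class densities default to 1000
  bins, query densities to 100.
* **Self-pairs.**  Whether self-similarity pairs (score = range maximum
  by construction) belong in the class sample is genuinely open; since a
  point mass at the maximum would distort any smooth fit, the default
  excludes the diagonal, with `include_diagonal` to override.
* **Ties** in the assignment argmin break toward the lowest class
  number.  P = 1 yields an infinite feasibility index (flagged value, not
  an error).
* **Direction.**  D(query ‖ class) is the default; class-to-query and the
  symmetrized mean are options.  KL is asymmetric and the choice matters.

## Synthetic data: what it does and does not emulate

The generator draws matrix entries i.i.d. from per-block distributions —
intra-class blocks from a class mixture, cross-class blocks from a
single Gaussian — rejection-truncated to the score range, with the
diagonal set to the range maximum and opposite blocks drawn independently
(asymmetry).  Because every downstream statistic consumes only entry
distributions, i.i.d. blocks give *exact* ground truth for testing the
estimators.

Defaults emulate the empirical regime of ChEMBL-derived target-class
matrices: right-skewed intra-class mixtures with modes near 0.5 on the
[0, 2] combined score, and cross-class Gaussians with means ≈ 0.2–0.6 and
SDs ≈ 0.05–0.15.  An optional per-(column, block) mean jitter models
query heterogeneity — without it, all queries of a class are
statistically identical and assignment matrices collapse to near-0/1.

What the generator does **not** emulate: metric consistency (entries are
not derived from an embedding, so triangle-like constraints among entries
are absent), conformer duplication structure, and any dependence between
a query's vectors against different classes beyond the shared jitter.
Passing tests therefore demonstrate that the estimators and the
discrimination calculus are correct under known sampling distributions;
they do not certify performance on real overlay matrices, where
inter-entry correlations exist.

Problem sizes: reference experiments use 200–1000 queries per class with
class blocks of the same size (about 4×10⁴–10⁶ intra-class pairs per
class), which puts estimator noise well below the tested tolerances while
keeping the full suite fast.  Real panels are larger (≈1.4×10⁴ conformers
per class); all statistics here concentrate further with size, so the
scaled runs are the conservative case for the recovery tolerances.

Named scenario presets:

* `default_spec` — four classes with skewed mixtures as above (300
  ligands/class);
* `separated_spec` — four single-Gaussian classes at means
  0.30/0.45/0.60/0.75, σ = 0.05, with cross-class means `separation`
  below the lower intra mean of each pair (200 ligands/class).  Note the
  cross mean must sit below *both* intra means: anchoring it to the pair
  midpoint would make a distant pair's cross distribution coincide with
  the lower class's intra distribution and silently destroy separation;
* `null_spec` — four statistically identical classes (1000
  ligands/class), the no-signal control: assignment rows should be
  uniform to within sampling noise.

## Known limitations

* Gaussian tails cross the score boundaries; for distributions pressed
  against 0 or the range maximum the untruncated fit biases σ upward.
* EM finds local optima; the restart scheme is effective for the
  well-separated and moderately overlapping mixtures tested but offers
  no global guarantee, and K is not selected automatically.
* The divergence compares *fitted* forms, not raw histograms (a
  histogram-vs-model variant exists for diagnostics); model
  misspecification of a query (multi-modal vector) is not detected.
* Published worked divergence values for the reference panel are
  internally inconsistent across their own presentations and are not
  used as correctness fixtures; the closed-form/quadrature cross-check
  is the formula-level oracle.
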