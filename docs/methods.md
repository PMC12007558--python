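# Methods

## Study structure

The package operates on a *travelling-heads* design: `n_subjects` subjects
each scanned once (repeat index 0) on every one of `n_scanners` scanners,
with a subset of subjects completing extra within-scanner repeats on one
designated scanner each. The reference design is 10 subjects × 6 scanners
from 3 vendors at 5 sites, with 4 subjects contributing 5 extra repeats
each: 60 primary + 20 repeat = 80 sessions. Ages span 24–48 years and the
sex ratio is 8:2; in the generator these are assigned deterministically
(evenly spaced ages, fixed sex assignment) so that the design itself is not
a source of randomness.

## Generative model of the synthetic cohort

Each IDP value for subject *s*, scanner *b*, repeat *r*, feature *v* is

    y = α_v + x_s·β_v + u_sv + γ_bv + η_bsv + δ_bv · ε_sbrv

* `α_v` — baseline mean, drawn once per feature from
  `alpha_mean · U(1−spread, 1+spread)` (defaults 100 ± 30%);
* `β_v` — age (per-year) and sex covariate slopes, normal with sd 0.2% and
  2% of `α_v`;
* `u_sv ~ N(0, τ_v²)` — biological subject effect, τ = 5% of `α_v`;
* `γ_bv ~ N(0, σ_γ²)` — additive scanner effect, σ_γ = 4% of `α_v`, with a
  `vendor_share` (default 0.5) of its variance drawn at the vendor level so
  same-vendor scanners have correlated offsets;
* `δ_bv` — multiplicative noise scale, log-uniform on [0.8, 1.25];
* `ε ~ N(0, σ_v²)` — session noise, σ = 1% of `α_v`;
* `η_bsv` — a scanner×subject interaction (sd 0.5% of `α_v`), again with a
  vendor-shared variance fraction.

All dispersions are fractions of `α_v`, which makes coefficient-of-variation
statistics comparable across features whatever their units. The defaults
put the median between-scanner CoV near 4× the within-scanner CoV,
the regime in which harmonisation is clearly needed but the noise floor is
still visible.

Why the interaction term: a constant `γ_bv` added to every subject on a
scanner cannot change that scanner's subject *ordering*, so purely
additive/multiplicative scanner effects predict identical ranking
consistency within and across vendors. Real scanners disagree about
subjects, and more so across vendors; `η_bsv` models that disagreement, and
its vendor-shared component is what makes same-vendor scanner pairs rank
subjects more consistently. Setting `interaction_sd = 0` recovers the pure
location/scale model, which is exactly the model class ComBat assumes —
harmonisation "success" then has a well-defined truth.

One global seed feeds a named substream per random quantity (baselines,
covariate slopes, scanner offsets, scales, subject effects, interactions,
noise, IQMs), so identical configurations are bit-identical and changing
one quantity's dimensionality does not reshuffle the others.

What the generator does **not** emulate: non-affine scanner effects
(nonlinear compression, coil-profile geometry), longitudinal drift, motion
artefacts, heavy-tailed or missing data, realistic IQM distributions, and
correlation structure between IDPs beyond what the shared subject effects
induce. Passing tests therefore demonstrate the *statistics and the
harmonisation machinery* are correct under the stated model, not that
ComBat removes real scanner effects this completely; on real data the
between/within ratio after harmonisation should be expected to stay further
from 1.

## Evaluation statistics

**Between-session similarity.** For each IDP category *m*, the Spearman
correlation `R_ijm` between the category's feature vectors of sessions *i*
and *j*; the similarity `P_ij` is the median of `R_ijm` over categories, so
every category counts equally regardless of its feature count. Missing
categories for a pair are ignored (the count of contributing categories is
reported); the diagonal is 1 by definition. Session pairs are classified
into within/between-scanner × within/between-subject, and class-wise order
statistics are reported. For a connectivity-edge category, only the top
fraction of edges by absolute mean over the within-scanner repeat sessions
enters the correlations (default 5%, rounded half-up; an explicit `k`
override is available) — edges are signed partial correlations, so strength
is absolute value, with lexicographic tie-breaks for determinism.

**Coefficients of variation.** CoV = sd/|mean| with the sample (n−1)
divisor by default (`ddof` is configurable; with 6-session repeat sets the
divisor is material). Three classes per IDP: within-scanner within-subject
(each qualifying (subject, scanner) repeat set, averaged over sets);
between-scanner within-subject (each subject's repeat-0 sessions, one per
scanner, averaged over subjects); within-scanner between-subject (each
scanner's repeat-0 sessions across subjects, averaged over scanners).
Using only repeat-0 sessions in the between-scanner class keeps repeat
sessions from leaking in; a `mean-of-repeats` policy is available. A mean
within 1e-12 of zero (relative to the data's own scale) marks the CoV
missing instead of exploding. Relative difference is
`100·(between − within)/within`, missing where `within ≤ 0`.

**Scanner bias.** Per qualifying subject and IDP:
`100·(mean of the repeat-0 sessions across scanners − mean of the
within-scanner repeat set)/the latter`, plus a variant restricting the
between-scanner mean to scanners sharing the repeat scanner's vendor, and
group rows averaging over subjects.

**IQM z-scores.** Within-scanner repeats are excluded; each metric is
z-scored (sample sd) across scanners within a subject and averaged over
subjects (scanner × IQM), or the transpose construction (subject × IQM). An
exactly constant column has zero deviations, whose z-score limit is 0.

**Ranking consistency.** `v_ld` holds one value per subject for scanner *l*
(the repeat-0 session; repeats never contribute under the default policy).
`Q_lkd` is the Spearman correlation of `v_ld` and `v_kd` for every
unordered scanner pair — 15 pairs for 6 scanners, 3 for a single-vendor
triple. Pairs with fewer than 3 jointly observed subjects report a missing
Q. The null band is the IQR of the Spearman correlation between two
independent random rankings: exact enumeration of all n! orderings against
a fixed reference for n ≤ 8 (valid by exchangeability), Monte-Carlo
(default 10,000 seeded draws) otherwise.

**Missing data.** Every correlation uses pairwise-complete deletion, and
degenerate inputs (constant after dropping, fewer than two complete pairs)
propagate as missing rather than 0, so they can never masquerade as "no
association". Quartiles use linear interpolation throughout.

## ComBat

For feature *v* in batch *b*: least-squares fit of batch offsets (one-hot,
constrained so the sample-size-weighted offsets sum to zero — this
preserves the grand mean rather than privileging an arbitrary reference
batch) plus covariates (age centred for conditioning, sex coded 0/1);
pooled residual variance σ̂² with divisor N; standardisation
`z = (y − α̂ − x·β̂)/σ̂`; per-batch mean γ̂ and variance δ̂² of z; normal
prior on γ̂ and inverse-gamma prior on δ̂² with hyperparameters by method
of moments across features (`a = (2s₂ + m²)/s₂`, `b = (m·s₂ + m³)/s₂` from
the mean m and variance s₂ of the δ̂²); alternating conditional posterior
means

    γ* = (n_b τ̄² γ̂ + δ²* γ̄)/(n_b τ̄² + δ²*)
    δ²* = (b + ½ Σ (z − γ*)²)/(n_b/2 + a − 1)

iterated until the maximum relative change falls below 1e-4 (cap 100; both
configurable, iteration counts stored on the model). The adjustment is
`y* = σ̂·(z − γ*_b)/δ*_b + α̂ + x·β̂` — strictly increasing and affine per
(feature, batch), which is why within-batch subject orderings are exactly
preserved when no covariates are used.

Numerical conventions and their consequences:

* Per-batch variances use divisor `n_b`, matching the divisor-N pooled
  variance. This makes the degenerate cases exact: a single-batch fit is
  the identity, and the no-shrinkage (`empirical_bayes=False`) transform is
  exactly idempotent. (With the n−1 divisor every pass would shrink all
  deviations by √((n−1)/n).)
* Shrinkage is skipped for a batch when the across-feature variance of its
  δ̂² is ~0 (single batch, uniform constructions, tiny feature sets), where
  the inverse-gamma moment equations degenerate; the skip is recorded on
  the model.
* With shrinkage active the adjustment is *not* idempotent and the grand
  mean is preserved only approximately: the posterior mean leaves a
  residual batch offset proportional to `(γ̂ − γ̄)·δ²*/(n_b τ̄² + δ²*)`,
  which a second pass shrinks again but never to zero. The exact
  invariants are stated (and tested) for the no-shrinkage variant.
* Fitting defaults to the primary (repeat-0) sessions, a balanced
  subject × scanner grid, with the model then applied to all sessions. On
  an unbalanced fit a repeat set gives its subject several-fold weight on
  that one scanner, so that subject's biological deviation leaks into the
  estimated scanner offset; on the reference simulation this single choice
  moves the recovered scanner-effect correlation with truth from ≈ 0.94 to
  ≈ 0.995. Fitting on all sessions remains available.

Batch effects are only identified up to the zero-sum constraint, so
parameter-recovery comparisons correlate the estimates with the same
weighted-centred projection of the generative truth.

## CovBat

After ComBat, the covariate-adjusted residuals are decomposed by PCA across
features (all `min(N−1, p)` components); the smallest K components whose
cumulative explained variance reaches `variance_fraction` (default 0.95, as
in the reference implementation of the method) have their scores re-centred
and re-scaled per batch to the pooled mean and sd — a plain location/scale
adjustment with no covariates and no shrinkage — the remaining scores pass
through untouched, and the data are reconstructed under the fitted mean
structure. With no covariance differences between batches the output
equals the input up to the sampling error of the per-batch score estimates.

## Pipeline

`run_all` executes simulate/load → similarity → reliability → IQMs →
ranking → harmonise → evaluate under one configuration, writing every
artefact as TSV/JSON plus a manifest of SHA-256 hashes. Tables are written
with `%.17g` formatting and read back with round-trip float parsing, so
write→read is bit-exact and two runs with the same configuration and seed
are byte-identical. All randomness flows from the single config seed.

At the reference scale (80 sessions, 360 IDPs, 10,000 null draws) a full
run takes a few seconds on one CPU; the problem sizes used by the test
suite and the acceptance script are the reference design itself, with
smaller hand-built tables for the analytic oracles.

## Known limitations

* Parametric empirical Bayes only; the non-parametric prior variant is out
  of scope, as are longitudinal ComBat and GAM extensions.
* The generator's scanner effects are affine by construction (plus the
  documented interaction term); conclusions about non-affine real-world
  effects do not follow.
* `CovBat.transform` on unseen data adjusts only batches seen at fit time.
* The similarity and ranking statistics assume the session table indexes a
  complete IDP matrix; heavy missingness degrades them to pairwise-complete
  estimates with the reported counts.
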