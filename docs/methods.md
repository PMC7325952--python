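# Methods

## The model

`slongdina` implements a simplified longitudinal higher-order DINA model
(sLong-DINA) for tracking the mastery of fine-grained skills ("attributes")
across repeated diagnostic assessments, together with a simulation framework
for studying how monotone sample attrition degrades its estimates.

The model has three levels. At the measurement level, person *n*'s response
to item *i* at occasion *t* follows a DINA item response function

    logit P(y_nit = 1) = λ0_it + λ1_it · η_nit,
    η_nit = ∏_k α_nkt ^ q_ikt,

where the Q-matrix entry `q_ikt ∈ {0,1}` records whether the item requires
attribute *k*, and the conjunction indicator η is 1 only when every required
attribute is mastered. `expit(λ0)` is the guessing probability; `1 −
expit(λ0 + λ1)` the slipping probability; `λ1 > 0` enforces monotonicity.
At the attribute level, mastery is driven by a time-specific general ability

    logit P(α_nkt = 1) = ξ_k θ_nt − β_k,

with slope `ξ_k > 0` and difficulty `β_k` shared across occasions (the same
latent structure is measured throughout). At the growth level,
`θ_n = (θ_n1, …, θ_nT) ~ MVN(μ, Σ)` with `μ_1 = 0` and `Σ_11 = 1` fixed for
identification, so later occasions are expressed on the first occasion's
scale. The local-dependence ("testlet") dimensions sometimes attached to
anchor items in the full longitudinal DINA are deliberately omitted.

## What the generator emulates

`simulate.GeneratingConfig` encodes the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_persons` | 200 (also 400) | starting cohort size |
| `items_per_time` | 15 (also 30) | test length per occasion |
| `n_times`, `n_attributes` | 3, 4 | occasions and attributes |
| anchors | 4 of 15, 8 of 30 | items identical across occasions, fixed at λ0 = −2.197, λ1 = 4.394 (≈10% guessing/slipping) |
| non-anchor (λ0, λ1) | MVN((−2.197, 4.394), unit variances, r = −0.6) | negatively related guessing and slipping; λ1 ≤ 0 draws rejected (~10⁻⁵ per draw) |
| `xi`, `beta` | 1.5; (−1, −0.5, 0.5, 1) | attribute slopes and difficulties |
| `mean_growth` | 1.0 | μ = (0, 1, 2) |
| `scale_ratio` | 1.25 | SDs (1, 1.25, 1.5625); "scale" is read as the standard deviation, the usual convention in IRT scale linking |
| `rho` | 0.9 | cross-occasion ability correlation |
| `attrition_rate` | 0–0.6 | per-occasion monotone dropout fraction |

The Q-matrix is built deterministically: anchor blocks are stacked
single-attribute identity rows; non-anchor rows are one cycle of
single-attribute items plus two-attribute pairs in a fixed rotation, with
attribute labels cyclically permuted across occasions so occasion-specific
forms differ. The construction guarantees, per occasion, at least one
single-attribute item per attribute (completeness) and at least three items
per attribute. The exact published item-by-attribute layout underlying the
original study is not recoverable from text, so this constructor is an
explicit, constraint-equivalent stand-in; results that depend only on the
stated structural facts should transfer, item-level detail may not.

Attrition is individual-level and completely at random: at each occasion
from the second onward, `floor(rate × n_remaining)` of the students still in
the study are sampled uniformly and never return (fractional counts
truncated, matching proportional sampling with decimals deleted). The
generator does **not** emulate class-level or outcome-dependent
(nonrandom) dropout, non-monotone "returning" missingness, item-parameter
drift, or multilevel class/school structure — passing tests say nothing
about those regimes.

## Estimation

`SLongDINA` is a Metropolis-within-Gibbs sampler. Missing responses are
excluded from every likelihood sum; dropped students stay in the model, so
their post-dropout abilities and attributes are imputed from the structural
model (this is exactly the behaviour of a general-purpose Gibbs sampler
given NA responses). Blocks per sweep:

* **Attribute profiles** — exact Gibbs draw per person-occasion by
  enumerating all 2^K = 16 profiles; at unobserved person-times the draw is
  prior-only. Binary latents are not monitored for PSRF (their within-chain
  variance degenerates).
* **Abilities** — per-coordinate random-walk Metropolis, vectorized over
  persons, against the attribute Bernoulli terms times the MVN prior.
* **Item parameters** — joint (λ0, λ1) random-walk per item-occasion;
  proposals with λ1 ≤ 0 rejected. Anchor items are estimated like all
  others (fixing them at truth is not assumed).
* **Structural parameters** — random-walk updates for ξ_k (> 0), β_k, free
  means μ_2…μ_T, and the free elements of the Cholesky factor of Σ with the
  (1,1) element pinned at 1; non-positive-definite proposals are impossible
  by construction (diagonal elements kept positive).

Proposal scales adapt multiplicatively toward ~0.3 acceptance during
burn-in only, in windows of 50 sweeps, and are frozen afterwards so retained
draws come from a valid Markov chain. Chains start from dispersed random
points. Priors default to weakly-informative choices — λ0, λ1, ξ, β ~
Normal(0, 4) (λ1, ξ truncated positive), μ_t ~ Normal(0, 10), Normal(0, 1)
on free Cholesky elements — and are fully overridable through
`PriorConfig`; prior choice should always be revisited for real
applications, especially at small N.

Classification uses the EAP rule: attribute mastered iff its posterior
mastery probability is ≥ 0.5 (ties count as mastery). Convergence is
assessed with the classic two-chain PSRF (`diagnostics.psrf`); the split
variant is available but off by default.

## Evaluation

Parameter recovery: bias = mean(estimate − truth) and RMSE =
√mean((estimate − truth)²) across replications, Pearson correlations where a
parameter vector varies (person abilities per occasion are summarized within
replication first, then averaged). Classification: ACCR (per attribute),
PCCR (whole K-vector per occasion), Longitudinal PCCR (all T×K attributes).
Because dropped students remain in the model, every rate is reported for two
populations: **all** persons (post-dropout classifications come from the
structurally informed posterior) and **observed** persons (per-occasion
rates over students present at that occasion; the longitudinal rate over
completers). The thresholds quoted in the worked example use the completer
population, the natural one when later responses are simply absent; the
all-persons variant is always alongside it in `RecoveryReport`.

## Numerical and design choices

* Full-conditional enumeration for α uses the Gumbel-max trick on log
  posteriors; log-likelihoods are assembled as `y·z − softplus(z)`, which is
  stable for any finite logit.
* An all-zero Q-row yields η = 1 (empty-product convention); generated
  Q-matrices never contain one, but the primitive is total.
* A time point with no observed responses triggers an explicit warning and
  structural-only inference there — never a silent failure.
* Seeding is hierarchical and pure: `(master seed, condition, replication)`
  determines independent generation and sampling streams via
  `numpy.random.SeedSequence` spawn keys, so any study cell reproduces
  bit-exactly regardless of execution order or parallelism.
* Two protocols ship as presets: the full one (R = 30 replications, 2
  chains × 15,000 iterations, 10,000 burn-in) and a desk protocol (R = 3,
  2 × 5,000/2,500) used by the test suite and the acceptance script; at the
  desk protocol a fit of the largest cell (N = 400, 30 items) takes well
  under a minute on one core.

## Known limitations

* With weak priors and the smaller design cells (N = 200, 15 items) the
  posterior shows a mild ridge trading ξ against the free elements of μ and
  Σ — ξ shrinks toward the prior and μ/Σ inflate correspondingly, while
  mastery probabilities (and hence classifications) are nearly invariant
  along the ridge. The effect disappears at N = 400 with 30 items, where
  essentially all item and structural EAPs fall within 3 posterior SDs of
  truth. Informative priors on ξ remove it at small N if desired.
* PSRF is the only convergence diagnostic; no effective-sample-size or
  autocorrelation reporting.
* The evaluation assumes simulated data with known truth; there is no
  model-fit machinery (DIC/WAIC) for real-data use.
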