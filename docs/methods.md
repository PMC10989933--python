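# Methods

This note documents the models, estimators, generative scenarios, and
numerical choices behind `taxadyn`, in the order the pipeline uses them.

## Log-ratio dynamics and the three models

Amplicon data are compositional: total community size `N_T` is
unobservable, so all dynamics are modelled through the log abundance
ratio `Z_i = log(X_i/X_r)` against a fixed reference taxon `r`. The
reference is chosen as the taxon with top occupancy (fraction of
samples in which it is present), with mean relative abundance as the
tie-break; it must be present at every time point, since every
observation divides by `X_r`.

**Consumer–resource.** MacArthur-style exploitative competition gives
per-capita growth `Σ_j b_ij C_ij R_j − m_i` for taxon `i`
(`C` consumption rate, `b` conversion efficiency, `m` maintenance).
Log-ratio differencing removes `N_T` and leaves the linear model
`dZ_i/dt = k0 + Σ_j k1_j R_j` with `k1_j = b_ij C_ij − b_rj C_rj`: only
competition strength *relative to the reference* is identifiable, and
the intercept conflates maintenance costs (never decomposed). Fitted by
OLS with homoscedastic Gaussian errors; the error variance `σ²` is
estimated by ML (`RSS/n`) and counts as a parameter, so `n_params = J+2`.

**Neutral.** Relative abundance follows a Wright–Fisher diffusion with
immigration on scaled time `τ = t/a` (`a` = mean replacement time of an
individual, in days):

    dX_i = λ_i (p_i − X_i) dτ + sqrt(2 X_i (1 − X_i)) dW_i,

with cross-covariance `Σ_ij = −X_i X_j` between taxa. Ito's lemma on
`Z_i` gives, in real time,

    dZ_i/dt = k0 + k2 / X_i + k3 / X_r + ε,
    k0 = (λ_r − λ_i)/a,  k2 = (λ_i p_i − 1)/a,  k3 = −(λ_r p_r − 1)/a,

where `Var(ε_k) = (2/X_i + 2/X_r)/(a · dt_k)` per interval. The fit is
therefore weighted least squares with weights
`w_k = dt_k/(2/X_i + 2/X_r)`, and the weighted residuals `√w ε` have
variance `1/a`, giving `â = 1/mean((√w ε)²)` (ML convention, denominator
`n`; an `n − p` option exists). `n_params = 4` (`k0, k2, k3, a`).

**Combined.** The resource growth term is purely deterministic and adds
to the drift unchanged:
`dZ_i/dt = k0 + Σ_j k1_j R_j + k2/X_i + k3/X_r + ε`, same weights and
`â` construction, `n_params = J + 4`. Its intercept conflates
`(λ_r − λ_i)/a` with `m_r − m_i`; `λ_i` is still derived from `k2`.

**AIC comparability.** Each model's log-likelihood is the Gaussian
likelihood that model actually asserts on the *same* response values:
homoscedastic for CR, heteroscedastic (`Var = 1/(a w_k)`) for neutral
and combined. `AIC = −2 loglik + 2 n_params`, variance/scale parameters
included; ties break toward fewer parameters. `r²` for weighted fits is
`1 − RSS_w/TSS_w` with `TSS_w` about the weighted mean — under identical
weights the neutral model is the `k1 = 0` restriction of the combined
model, so combined `r² ≥` neutral `r²` holds exactly and is asserted in
the tests. A fit with zero residuals reports `â = ∞` and infinite
log-likelihood rather than failing.

## Interval construction

Responses are finite differences `(Z_{k+1} − Z_k)/dt` over consecutive
sample pairs within one replicate; regressors and weights are evaluated
at the **left** endpoint (the non-anticipating Euler/Ito convention —
the source data's convention is not stated, and the left endpoint is
the standard choice). Intervals where the focal or reference taxon has
a zero count at either endpoint are dropped (the log ratio is
undefined); an optional pseudo-abundance floor exists for sensitivity
analyses. Replicate series are pooled by concatenating interval
observations — differences never straddle replicate boundaries.
Resource values are matched to sample days exactly, with linear
interpolation inside a replicate's measured range and never
extrapolation. Each fit requires at least `n_params + 2` intervals
(two residual degrees of freedom).

## Derived quantities

- `λ_i p_i = k2 â + 1`; `p_i` is estimated by the taxon's mean relative
  abundance over all samples of the fitting unit (zeros included);
  `λ_i = (k2 â + 1)/p_i`. A non-positive `λ_i p_i` is reported as
  `λ_i = 0` with a non-neutral-compatible flag.
- Equilibrium prediction: `X_i ~ Beta(λ_i p_i, λ_i (1 − p_i))` — mean
  `p_i`, variance `p_i(1−p_i)/(λ_i+1)` — the large-community diffusion
  limit of the neutral model. Compared with observed histograms by the
  Kolmogorov–Smirnov distance; boundary observations (exactly 0 or 1)
  are excluded and counted.
- Taxon determinism (from the combined fit) is the inverse coefficient
  of variation of the SDE,
  `|k0 + Σ_j k1_j R_j + k2/X_i + k3/X_r| · sqrt(â/(2/X_i + 2/X_r))`
  on the real-time scale (default). The scaled-time convention
  (`× â/sqrt(2/X_i+2/X_r)`, differing by `√â`) is available via
  `time_scale="tau"`; the absolute value is taken since only drift
  magnitude relative to noise is meaningful. Community determinism is
  the mean over taxa with a defined value at that time point,
  optionally weighted by the taxon's relative abundance there
  (renormalised over contributing taxa).

## The simulator

The generator integrates, by Euler–Maruyama on `τ`,

    ΔX_i = [λ_i (p_i − X_i) + X_i (f_i − Σ_k X_k f_k)] dτ + η_i,

with selection coefficients `f_i = a (Σ_j bC_ij R_j(t) − m_i)` per unit
scaled time and Gaussian noise `η` of covariance `2Σ dτ`. Noise is
drawn on the simplex tangent space,
`η_i = sqrt(2dτ)(√X_i g_i − X_i Σ_k √X_k g_k)` with iid `g`, which
reproduces `Σ` exactly and conserves `Σ X_i` to machine precision. The
replicator form of selection makes the log-ratio drift against any
reference exactly `(f_i − f_r)/a` per day — the combined model's
resource term — so injected competition strengths are recoverable by
the fitters; with equal `f_i` the selection term cancels identically
and the dynamics are strictly neutral. After each step, states are
floored at 1e-12 and renormalised (Wright–Fisher paths do touch the
boundary; the fitting pipeline drops zero observations anyway). A
warning is issued if macroscopic abundances (above ~100·dτ, i.e. well
outside the diffusion boundary layer) overshoot below zero in more
than 1% of updates — boundary jitter of pinned taxa is intrinsic and
not warned. Observation days map to steps via `t = a τ`; counts are
multinomial samples of the configured depth at each observation day.
Per-replicate noise streams derive deterministically from one seed.

### Validity envelope

The log-ratio regression is a diffusion approximation; the generative
scenarios are designed to sit inside its envelope, and the limits are
worth stating because they apply to real data too:

- **Interval length vs relaxation.** Per-interval variance follows
  `(2/X_i + 2/X_r)·dt/a` only while `λ·dt/a ≪ 1`; for longer intervals
  the variance saturates at its stationary value and `â` is biased
  upward. Scenarios keep `λ·dt/a ≲ 0.1`.
- **Boundary layer.** The linearised noise model fails for abundances
  below `~2·dt/a` (one interval's diffusion spread exceeds the
  abundance itself), and conditioning on presence then biases the
  restoring-force coefficient toward zero. Taxa dwelling below that
  layer — those with `λp ≪ 1` — are fitted but their neutral
  coefficients carry little information; the model-selection benchmark
  therefore uses a source pool whose fitted taxa stay above the layer.
- **Read sampling.** Multinomial sampling adds variance
  `≈ a/(depth·dt)` relative to the diffusion term; scenarios keep this
  below ~5%.

## Generative scenarios (`scenario_library`)

All scenarios use 30 taxa and 50 000 reads per sample; parameter draws
are deterministic in the seed.

- **strict_neutral** — one replicate, 53 samples every 9.6 days
  (~500 days), `λ = 400`, `a = 40 000` d (immigration restores ~1% of
  any deviation per day), geometric source pool spanning 0.003–0.2, a
  stable resource background (sinusoid + slight trend around
  20 g/L) and no selection. Emulates a steadily fed control reactor
  whose fitted taxa all sit in the diffusion regime.
- **heterogeneous_lambda** — the parameter-recovery benchmark
  prescribed at `a = 1`: `λ` log-uniform on [2, 500], ~400 intervals of
  0.004 τ split across six replicate series, source abundances
  inversely proportional to `λ` (the abundance–immigration
  anticorrelation seen in real reactor communities) with a pinned
  fast-immigrating dominant reference (`p = 0.3`). Short independent
  replicate windows are what make the time-averaged abundance of
  slowly immigrating taxa estimable. `â` is summarised over the
  well-observed half of taxa (those within the diffusion envelope).
- **resource_selection** — three replicates, 11 samples every 10 days
  while the resource ramps 1→3 g/L; competition strengths
  `|k1| ∈ [0.1, 0.2]` per day per (g/L) with maintenance set so each
  taxon breaks even at the mid-ramp level. Selection therefore
  reverses sign mid-run: strong, detectable resource-driven drift
  (≥3× the interval noise SD at the ramp ends for abundant taxa)
  without driving anyone extinct. `λ = 200`, `a = 20 000` d.
- **combined** — resource_selection with heterogeneous immigration
  rates (`λ` log-uniform on [50, 500]).

## Phylogenetic signal

Pairwise sequence similarity is global-alignment identity (match +1,
mismatch −1, gap −2; matches / alignment length). Over taxon pairs
above a similarity threshold (default 0.70, sweepable), Spearman's rank
correlation (midrank ties, t-approximation p-value) is computed between
similarity and `|k1_i − k1_j|` (Euclidean distance for several
resources). A precomputed similarity matrix can be supplied to bypass
the aligner. The self-validation plants the signal explicitly: traits
drawn from a Gaussian process whose covariance decays with sequence
dissimilarity (`exp(−(1−S)/0.35)`) along a mutation chain.

## Numerical choices and degenerate inputs

- WLS/OLS solving is delegated to statsmodels; likelihoods, `â`, AIC
  and weighted `r²` are computed here. Rank-deficient designs raise an
  error naming the collinear column (e.g. a constant resource).
- Simulator step sizes satisfy `λ·dτ < 0.1` (warned otherwise) and
  `|f|·dτ < 0.1` by construction; observation days must land on the
  `τ` grid.
- Determinism is undefined where the focal or reference abundance is
  zero; such points are skipped and community averages use the
  renormalised weights of the remaining taxa.
- Boundary values 0.01% and 0.1% of the abundance classification both
  belong to the "moderate" class (closed interval).
- Bit-identical outputs for identical inputs: the fitting pipeline is
  deterministic; all simulation randomness flows through explicit
  seeds.

## Benchmark sizes

The self-validation studies (`taxadyn.validation`, exercised by the
acceptance script and test suite) use: selection rates averaged over 3
simulation repeats; immigration-rate recovery over 10–20 repeats of the
30-taxon scenario; the residual-scale identity on 2000 intervals; the
stationary law on 1e5 thinned states from 100 parallel chains (burn-in
2 τ, thinning 0.05 τ); determinism calibration on 1e6 Monte-Carlo
replicates. These sizes give sampling error comfortably below the
tolerances they are checked against.

## Known limitations

- Resource effects on growth are linear; saturating (Monod) kinetics
  are outside the model family.
- Only the difference in competition strength to the reference taxon is
  identifiable, and maintenance costs cannot be separated from
  immigration-rate differences in the combined intercept.
- `p̂_i` (mean observed abundance) is a biased estimator of the source
  abundance when the observation window is short relative to `a/λ_i`.
- The determinism index inherits the combined fit's coefficients;
  taxa whose dynamics the combined model fits poorly get a poorly
  calibrated determinism.
- The simulator emulates demographic drift, immigration, resource
  selection and read sampling — not PCR/primer bias, contamination,
  batch effects, or taxon-specific detection limits. Passing recovery
  tests demonstrate statistical soundness under the model's own
  assumptions, not robustness to those artefacts.
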