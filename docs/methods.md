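# Methods

## Model and procedure

`symentropy` treats an EEG segment as a realization of a stationary
amplitude process and asks how uniformly its binary threshold-crossing
patterns are distributed. The chain is symbolize → words → codes →
entropy:

* **Symbolization.** `s_i = 1` iff `T_i ≥ mean(T) + ξ`. The mean is the
  arithmetic mean over the full segment (not per-window, not the median);
  ties at the threshold symbolize to 1 exactly as the rule is written, with
  no epsilon. The offset ξ is the swept "threshold" parameter and carries
  the signal's units (µV). A second rule, `s_i = 1` iff `|T_i − mean| ≥ ξ`,
  is provided because both mean-crossing and deviation-band symbolizations
  are established in heart-rate and EEG symbolic dynamics; the default is
  the mean-plus-offset rule. Only `Ψ = 2` is implemented — the binary rules
  do not generalize to more symbols without choosing a binning scheme,
  which is out of scope.
* **Words and codes.** Overlapping windows of `L` symbols, advancing one
  sample at a time, give `N − L + 1` words; each is encoded positionally
  with the earliest symbol most significant. Orientation is an injective
  relabeling and cannot change any entropy value; it is fixed only so code
  series are reproducible. Default `L = 3`, where the 8-category word
  distribution is well estimated even for short segments.
* **Entropy.** `SE` is the Shannon entropy (bits) of the observed code
  distribution; `CSE = SE + (C_R − 1)/(2 M ln 2)` adds a finite-sample
  bias correction (`C_R` = number of observed distinct codes);
  `NCSE = CSE / CSE_max` with
  `CSE_max = log₂(Ψ^L) + (Ψ^L − 1)/(2 Ψ^L ln 2)`.

### The M convention

The correction denominator `M` is ambiguous in the literature this method
descends from: the classical bias correction uses the number of word
tokens (`N − L + 1`), while treating `M` as the alphabet size `Ψ^L` makes
`CSE_max` depend only on `(L, Ψ)`. The package defaults to the
**cardinality** convention (`M = Ψ^L` in the correction) because it is the
only choice under which long, highly irregular segments reach NCSE values
above the token-convention ceiling of ≈ 0.8265 (at `L = 3`, `N = 4097`),
as reference result tables for such data report. The **tokens** convention
is available behind a flag for comparison. The normalizer `CSE_max` always
uses `Ψ^L` — this keeps `NCSE ∈ [0, 1]` under both conventions (the
alternative, normalizing by a token-based maximum, would not bound the
ratio by 1 for short series).

Degenerate inputs are values, not errors: a constant segment symbolizes to
all ones, has a single code, `SE = 0`, a vanishing correction (`C_R = 1`)
and `NCSE = 0`.

## Multiscale entropy

The comparison method coarse-grains the signal into non-overlapping window
means of width τ (scales 1–20 by default) and computes sample entropy with
template length `m = 1` and tolerance `r = 0.25 ×` the population SD of the
**original** series, held fixed across scales. Fixing r from the scale-1
series is deliberate: re-estimating it per scale would mask the variance
loss that coarse-graining inflicts on uncorrelated noise, which is exactly
the signature MSE is meant to expose. Sample entropy uses Chebyshev
distance, excludes self-matches, and restricts both template lengths to the
first `N − m` positions so the two match counts are comparable. When either
match count is zero the estimate is undefined and reported as NaN — never
silently zero; the per-electrode comparison simply drops scales at which
any subject's estimate is undefined.

## Group statistics

Metric values across segments or subjects are compared with the two-sided
Mann–Whitney–Wilcoxon rank-sum test: exact (full enumeration, delegated to
scipy) when the combined sample size is ≤ 12 with no ties — enumeration
cost grows combinatorially beyond that — and the normal approximation with
tie and continuity corrections otherwise. Two identical samples return
`U = n_a n_b / 2, p = 1` rather than an error. p-values map to tiers:
strictly (`p < 10⁻⁴`), very (`< 0.01`), just (`< 0.05`), almost (`< 0.1`),
ns. The band `10⁻⁴ ≤ p < 10⁻³` is assigned to "very": the conventional
tier cut-offs leave it unnamed, and closing the gap downward would inflate
the top tier. Per electrode the pipeline reports each condition's maximum
median over the grid, the minimum p with its setting (argmin, ties broken
toward the smaller setting) and the maximal contiguous runs of settings
with `p < 0.05`. The maximum-median and minimum-p columns are computed
independently and need not come from the same setting. No multiple-testing
correction is applied across electrodes or thresholds; consumers needing
familywise control should correct downstream. A paired Wilcoxon
signed-rank mode exists for within-subject EC/EO designs, but the default
is the unpaired rank-sum test.

## Synthetic data

The generators produce the amplitude/rhythm structure the analysis is
sensitive to, nothing more:

| generator | model | defaults |
|---|---|---|
| `gen_resting_eeg` | alpha sinusoid + white Gaussian noise | 15 µV alpha at 10 Hz, 25 µV noise (EO-like scalp); EC-like: 45 µV alpha, 15 µV noise |
| `gen_interictal_like` | theta sinusoid + sparse 20 ms spikes + noise | 100 µV at 5 Hz, 300 µV spikes at 1 Hz, 20 µV noise (intracranial scale) |
| `gen_ictal_like` | periodic spike-wave template with timing jitter + noise | 1000 µV spikes at 3 Hz, 30 µV noise |
| `gen_multichannel_ec_eo` | per-channel alpha + noise, per-subject lognormal gains | 19 channels, 20 µV alpha, 15 µV noise, 500 Hz; EC occipital (O1/O2/P7/P8/Pz) alpha × `effect` (default 3) |
| `gen_bernoulli_symbols` / `gen_markov_symbols` | discrete sources with known entropies | — |

Single-channel defaults mirror the public corpus geometry (173.61 Hz,
23.6 s → 4097 samples) so threshold grids transfer; the multichannel
generator defaults to 10 s epochs at 500 Hz — resting-state entropy at
`L = 3` is stable well below the few-minute recordings it emulates. Setting
`effect = 1` makes EC and EO distributionally identical, a null
construction used for calibration. All generators are driven by
`numpy.random.default_rng(seed)` and are bit-reproducible.

What the surrogates deliberately lack: 1/f background spectra, non-
stationarity, artefacts, inter-channel correlation, and any fitted
correspondence to real patients. Passing tests on them shows the pipeline
orders *rhythm-dominated vs noise-dominated regimes* correctly and is
statistically calibrated — not that it reproduces clinical effect sizes on
real recordings.

## Problem sizes used in the checks

The statistical checks run at sizes chosen to estimate the relevant rates
tightly while staying desk-scale: type-I error from 2000 null replicates
(n = 10 per group); pipeline null calibration from 200 seeded 16-subject
runs at a single threshold (a min-p over a grid is not a 5% quantity, so
calibration is per-setting by construction); qualitative orderings over 20
seeds with an exact sign test; EC/EO power runs with 2 s, 250 Hz epochs,
where the occipital contrast is already near-certain at n = 16.

## Known limitations

* Only binary symbolization; quantile or multi-level binning is not
  implemented.
* The NCSE threshold sweep treats ξ as an absolute offset in signal units,
  so groups with very different amplitude scales are compared at the same
  absolute ξ (as the reference tables do), not at matched quantiles.
* Sample entropy is O(n²); multichannel MSE over many subjects and scales
  is the slow path of the pipeline.
* The exact rank-sum path requires tie-free data; entropy values are
  continuous so ties essentially never occur there, but heavily quantized
  metrics would silently fall back to the asymptotic test.
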