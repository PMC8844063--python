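# Methods

## The question and the estimand

The acoustic niche hypothesis predicts that species calling together
partition acoustic space, so the calls of an observed assemblage should be
less similar than those of a randomly assembled community drawn from the
same regional fauna. The estimand is, per similarity measure, the mean
standardized effect size (SES) across assemblages:

    SES_i = s · (obs_i − mean(null_i)) / sd(null_i)

where `obs_i` is the assemblage's mean pairwise similarity, the null
distribution comes from random matching-size assemblages drawn from the
assemblage's 50 km species pool, and the sign `s` is −1 for spectral
overlap (higher overlap = more similar) and +1 for the four distance-based
measures, so positive SES always indicates partitioning. Degenerate
assemblages (null sd = 0, possible when the pool's species all share call
parameters) are flagged and excluded from summaries rather than crashing.

## Call measurement

Single-call clips (mono PCM WAV, nominally 44.1 kHz) are measured as
follows:

* **Spectrum** — Welch average of Hann-windowed 512-sample segments with
  50% overlap. At 44.1 kHz this gives 86.13 Hz bins, the granularity quoted
  for all frequency tolerances. The analysis tools this emulates document
  only the window length; window type, overlap and averaging are this
  package's declared convention, matching the common default of an
  averaged selection spectrum.
* **Dominant frequency** — centre frequency of the maximum-energy bin
  (ties toward the lower bin), log10-transformed. All frequencies are kept
  as log10 Hz because frequency perception and production scale ratios,
  not differences.
* **5% / 95% frequency** — smallest bin centre at which cumulative spectral
  energy reaches the quantile (right-continuous), log10-transformed. Their
  span is the 90% bandwidth. A single-bin call may measure freq5 = freq95;
  downstream bandwidth use floors the width at one spectral bin (in log10
  units, evaluated at freq5) so overlap denominators are never zero.
* **Envelope** — rectified signal smoothed by a 5 ms moving average.
* **Call bounds** — first to last envelope sample above 10% of the peak
  (explicit bounds can be passed instead when calls are isolated manually).
* **Duration 90%** — time between the 5% and 95% cumulative-energy
  instants of the squared envelope. Envelope energy (not spectrogram
  energy) is the declared convention.
* **Peak time (relative)** — position of the (first) envelope maximum
  within the call bounds, scaled to [0, 1].
* **Notes / note rate** — notes are maximal supra-threshold envelope runs
  (threshold 10% of peak) with gaps shorter than 10 ms merged; note rate is
  the note count divided by the call duration. Threshold and minimum gap
  are configurable; the defaults are package conventions, since "separated
  by silence" fixes no numbers.

All six parameters are invariant to amplitude scaling (thresholds and
quantiles are relative), and measurement is deterministic. A species'
parameter vector is the mean over its measured calls on the stored scales.

## Similarity measures

PCAs are fitted once on the full analysis species set (species pairs are
scored in one common space, not per assemblage), on centred and scaled
parameters (sd with n−1). Exactly three components are retained; for the
three-parameter subsets this is the full space, so PC distances equal
standardized-parameter distances. Component signs are fixed by making each
component's largest-magnitude loading positive, so results are fully
deterministic.

Spectral overlap between two 90% bandwidths uses the symmetric convention
p = (L/bw_a + L/bw_b)/2, where L is the intersection length: it is bounded
in [0, 1], symmetric, and reduces to the obvious answer for equal
bandwidths. The denominator convention ("union", "smaller bandwidth", …)
is not fixed by the phrase "mean proportion of overlap"; this choice is
declared and used consistently.

Assemblage values are unweighted means over all C(n, 2) species pairs
(presence only; no abundance weighting).

## Null model

* **Pool** — all species of every assemblage whose location lies within
  50 km (inclusive; haversine distance on a sphere of radius 6371.0088 km)
  of the focal assemblage. Pools are built from the assemblages that
  survive the richness and parameter-coverage filters, so every pooled
  species can be scored in null draws.
* **Filters** — ≥ 4 species; call parameters available for every species
  present (all six for the PCA/overlap measures; dominant frequency alone
  suffices for a dominant-frequency-only run, which therefore retains more
  assemblages); ≥ 1 extra species in the pool (otherwise observed and null
  would coincide). Each dropped assemblage is logged with the first rule it
  violated.
* **Sampling** — uniform without replacement over the distinct pooled
  species (not occurrence-weighted), 1,000 draws by default; the focal
  composition is itself a possible draw, as is standard in null-model
  ecology. Null similarity values are read off precomputed species ×
  species pairwise matrices, which is exactly equivalent to re-running the
  observed-assemblage code path pair by pair (asserted in tests).
* **Reproducibility** — one master seed spawns a child generator per
  assemblage keyed by a CRC of its id, so results are bitwise reproducible
  and independent of processing order. Sample sd uses the n−1 denominator.

## Inference

* **BCa bootstrap** (implemented from scratch, as a core methodological
  step): n = 10,000 resamples of the mean SES; bias constant
  z0 = Φ⁻¹(fraction of bootstrap means below the observed mean, ties
  counted half); acceleration a from the jackknife skewness of
  leave-one-out means; endpoints at the BCa-adjusted percentiles of the
  bootstrap distribution. A constant input yields the degenerate interval
  [v, v]; a z0 proportion of exactly 0 or 1 is clipped to half a resample.
  With z0 = a = 0 the interval equals the plain percentile interval
  (asserted by injection). Known property: two-sided coverage of the mean
  has an O(1/n) deficit — about 93–94% at n = 50 for nominal 95%, matching
  the scipy reference implementation under identical conditions, and
  approaching nominal as n grows.
* **Verdict** — `partitioned` if the whole CI is above 0, `aggregated` if
  below, `indistinct` otherwise; plus the fraction of assemblages with
  SES > 0 ("less similar than the null mean").
* **Mixed model** — the statement "observed and null values were compared"
  admits two designs, both offered: the default *long* form models the
  similarity value with an observed/null indicator (the null row is the
  per-assemblage null mean, avoiding pseudo-replication of 1,000 draws)
  interacting with centred richness and centred 50 km pool surplus, with
  random intercepts for habitat, month, calendar day and assemblage
  (crossed, via variance components on a single top-level group); the
  *contrast* form models the per-assemblage observed-minus-null difference
  with the same covariates. Fitting is delegated to statsmodels MixedLM
  (REML); non-convergence, boundary estimates and all-singleton random
  groups are reported as structured warnings with whatever output exists.
  The five measures are modelled independently; no multiple-testing
  correction is applied.

## Synthetic data

The generator emulates the *structure* of a continental citizen-science
frog occurrence dataset at desk scale — it does not mimic any real fauna,
phylogeny, body-size allometry or sampling effort.

* **Calls** — a train of Hann-windowed FM notes; dominant frequency equals
  the carrier, note rate is n_notes over the call extent, and the peak-time
  ground truth is the exact argmax position of the constructed amplitude
  profile (a triangular note-level profile peaking at the requested
  position; the realized peak sits at the nearest note centre because the
  call is discrete in notes).
* **Traits** — log10 dominant frequency ~ Normal(3.30, 0.25) (≈ 2 kHz
  centre, spanning roughly 600 Hz–6 kHz across species); bandwidth placed
  symmetrically around it; duration and note rate log-normal; peak time
  Beta(2, 2). Temporal traits are independent of spectral traits by
  design, so frequency-based assembly mechanisms leave `PCA_Temporal`
  centred at SES 0 — a built-in negative control.
* **Sites** — cluster centres on a coarse grid spanning a continental
  extent (hundreds of km apart), sites scattered ~15 km around their
  centre, so 50 km pools are cluster-local by construction. Each cluster
  carries a regional pool of ~12 species (±2 between clusters, so pool
  surplus is not collinear with richness; neighbouring clusters share
  species). Richness is truncated Poisson (mean 6) with minimum 4,
  matching the analysis filter.
* **Assembly** — `random` draws uniformly without replacement via the same
  sampler as the null model, which guarantees SES calibration at 0 by
  construction; `repulsion` builds the community sequentially, each
  candidate joining with probability ∝ exp(+β · min dominant-frequency
  distance to current members); `attraction` uses −β. β = 0 reduces every
  mode to random. Repulsion acts on dominant frequency only, so the
  spectral measures respond and the temporal one does not.

## What the tests show (and don't)

Passing tests demonstrate: the measurement chain recovers known generator
parameters to within one spectral bin / 10% / 0.05; the five similarity
statistics equal brute-force pairwise computation exactly; the Monte-Carlo
null agrees with exhaustive enumeration on small pools; SES is calibrated
at 0 under the null assembly process and responds monotonically (and with
the correct sign) to repulsion/attraction strength; the BCa interval
reduces correctly and tracks the reference implementation; and the whole
pipeline is bitwise deterministic under a seed. They do not show anything
about real recordings (noise, overlapping callers, misidentification),
about real spatial occupancy patterns, or about the behaviour of the
measures when call parameters vary geographically within species.

## Problem sizes and numerical choices

Simulation-based checks use 500 assemblages × 200 nulls (30 species, 5
clusters) for calibration/recovery/monotonicity, 5,000 Monte-Carlo draws
against exhaustive enumeration, 100 random calls for measurement recovery,
and 5,000 replicates (n = 50, n_boot = 2,000) for bootstrap coverage —
sizes chosen to keep each check to seconds-to-minutes on one CPU while
leaving Monte-Carlo error well inside the asserted tolerances. Note that
the grand mean SES over 500 assemblages has a standard error of
1/√500 ≈ 0.045 by construction (SES is standardized), so calibration
checks at the ±0.05 level operate at ≈ 1 SE and are expectedly noisy from
seed to seed.

CSV output uses `%.17g` floats and reading uses round-trip parsing, so all
files round-trip losslessly. All-identical null values short-circuit the
mean/sd computation (summation rounding would otherwise produce a spurious
sd of ~1 ulp). Ties in argmax-style measurements always resolve to the
earliest/lowest candidate.
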