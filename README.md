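# acousticniche

Null-model tests of **acoustic niche partitioning** in frog assemblages.

Co-calling frogs compete for acoustic space: if partitioning is real, the
calls heard together in a chorus should be *less* similar than expected by
chance. This package implements the full analysis chain needed to test that
at scale:

1. **Call measurement** — six parameters per species from single-call WAV
   recordings: 5% frequency, 95% frequency and dominant frequency (log10 Hz,
   from an averaged Hann-windowed spectrum, window 512 at 44.1 kHz), and
   90%-energy duration, relative peak time and note rate from the amplitude
   envelope.
2. **Acoustic similarity** — five per-assemblage statistics, each the mean
   over all species pairs: Euclidean distance *d* on the first three
   principal components of a centred-and-scaled PCA over all six
   (`PCA_All`), the spectral (`PCA_Spectral`) or the temporal
   (`PCA_Temporal`) parameters; the proportion of overlap *p* between 90%
   log10 frequency bandwidths (`spectral_overlap`); and the distance between
   log10 dominant frequencies (`domfreq_distance`).
3. **Geographic null model** — each observed assemblage is compared with
   1,000 random assemblages of matching richness drawn uniformly from its
   50 km species pool (every species recorded in any assemblage within
   50 km). The standardized effect size is

       SES = (observed − mean(null)) / sd(null),

   with the sign reversed for spectral overlap so that SES > 0 always means
   partitioning and SES < 0 aggregation.
4. **Inference** — bias-corrected and accelerated (BCa) bootstrap CI
   (n = 10,000) of the mean SES per measure; the fraction of assemblages
   less similar than their null mean; and a linear mixed-effects check of
   observed vs null similarity with assemblage richness and 50 km pool
   surplus as fixed effects and habitat, month, recording day and
   assemblage as random effects.
5. **Synthetic data** — generators for call audio with known ground truth
   and for whole occurrence datasets (clustered sites, regional species
   pools, community assembly that is uniform, frequency-repulsive or
   frequency-attractive), so every stage is testable without any download.

Assemblages with fewer than four species, species lacking the required call
parameters, or no extra species within 50 km are filtered out before
analysis, and the exclusions are logged.

## Worked example

Generate a synthetic dataset whose communities repel each other in dominant
frequency (β = 5), then run the full analysis:

```bash
acousticniche simulate --mode repulsion --beta 5 --n-sites 200 --seed 0 --out-dir data
acousticniche run --calls data/calls.csv --assemblages data/assemblages.csv \
    --out-dir out --seed 1
```

`out/summary.json` then holds, per measure, the mean SES, its 95% BCa CI
and the verdict; this run prints:

| measure           | mean SES | verdict      |
|-------------------|---------:|--------------|
| PCA_All           |    0.278 | partitioned  |
| PCA_Spectral      |    0.420 | partitioned  |
| PCA_Temporal      |   -0.060 | indistinct   |
| spectral_overlap  |    0.483 | partitioned  |
| domfreq_distance  |    0.420 | partitioned  |

The frequency-based measures recover the partitioning that the generator
built in, while the temporal measure — untouched by the repulsion mechanism
— stays indistinguishable from random: the expected qualitative pattern.
Under `--mode random` all five verdicts come out indistinct.

The same stages are available programmatically (`measure_call`,
`assemblage_similarity`, `run_null_model`, `bca_ci`, `fit_lmm`,
`gen_dataset`, `analyze`), and individually as CLI subcommands
(`measure`, `similarity`, `null`, `bootstrap`, `lmm`).

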