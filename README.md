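# segmse

Sample entropy (SampEn) and multiscale entropy (MSE) estimation for
**sparse, discontinuous** time series — EEG epochs, fMRI block designs,
trial-based recordings — plus the simulation machinery to quantify how
accurate and precise those estimates are, and to turn that precision into
sample-size plans.

## The problem

SampEn measures the predictability of a signal: it counts how often
patterns of `m` successive samples reoccur (`B` matching template pairs)
versus patterns of `m + 1` samples (`A` pairs), two samples counting as
equal when they differ by at most `r · SD`. Then

```
SampEn(m, r) = ln(B / A)
```

MSE repeats this at coarser time scales: at scale `s` the signal is
replaced by averages of `s` successive non-overlapping samples, while the
tolerance `r · SD` stays fixed at its native-scale value. Conventional
wisdom requires hundreds of *continuous* samples per scale, which rules out
most epoch-based EEG and block-design fMRI data.

`segmse` removes that restriction by estimating SampEn/MSE **across
segments**: pattern counts are pooled over all segments of a recording,
under two constraints — coarse-graining never crosses a segment border, and
no template spans one. With `j` segments of `n` samples the data density is
`(n − m) · j` templates, and any scale up to `⌊n / (m + 1)⌋` is estimable —
including scales far beyond the reach of a single short segment. A
single-segment set reduces bit-for-bit to the classic continuous estimator.

## Worked example

Estimate MSE of one 1/f-noise recording split into 20 segments of 256
samples (250 Hz):

```python
from segmse import EntropyParams, mse, simulate_ensemble
from segmse.evaluate import draw_segments

series = simulate_ensemble("one_over_f", 20 * 256, 1, seed=0,
                           sampling_rate=250.0)[0]
segments = draw_segments(series, j=20, n=256)
profile = mse(segments, EntropyParams(m=2, r=0.5),
              scales=[1, 2, 5, 10, 20, 40])
print(profile.to_frame().to_string(index=False))
```

```
unit_id  scale  entropy       B      A  n_comparisons  tolerance  defined
   unit      1 0.920691 1383783 551083           5080   0.410531     True
   unit      2 0.862784  388269 163844           2520   0.410531     True
   unit      5 0.822379   66502  29220            980   0.410531     True
   unit     10 0.790410   16195   7347            460   0.410531     True
   unit     20 0.792031    3420   1549            200   0.410531     True
   unit     40 0.834933     643    279             80   0.410531     True
```

Entropy near 0.8–0.9 nats with a shallow decline across scales is the
signature of 1/f noise (white noise sits near 1.29 at scale 1 for
`r = 0.5` and falls quickly with scale). Note scale 40: a single 256-sample
segment could never support it, but pooling 20 segments leaves 80 templates
to compare. `tolerance` is the single `r · SD` value fixed from the native
data; `defined` flags scales where at least one `(m+1)`-pair matched.

From a shell, the same analysis runs off a segment manifest:

```sh
segmse mse --manifest data/manifest.tsv --m 2 --r 0.5 --scales 1:20 \
       --sd-policy pooled --out mse.tsv
segmse power --precision 0.09 --delta 0.05 --power 0.8
# required N per group: 51
```

Other subcommands: `simulate` (white/pink ensembles), `evaluate`
(accuracy/precision grids over segment counts and lengths), `compare`
(paired condition contrasts with sensitivity/specificity against a
benchmark map), `fixture` (seeded synthetic datasets). Every command writes
a `*.run.yaml` sidecar sufficient to re-run it bit-identically.

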