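# imepmap

Mapping and inference for **ipsilateral motor evoked potentials (iMEPs)**
recorded from a pre-activated muscle during transcranial magnetic stimulation
(TMS) of the same-side motor cortex.

iMEPs are small, late EMG bursts riding on voluntary background activity, so
they cannot be measured like ordinary contralateral MEPs. This package
implements the complete analysis chain used in iMEP grid-mapping studies:

1. **Burst detection on rectified EMG.** The onset is the first
   post-stimulus sample where rectified EMG exceeds the prestimulus mean plus
   one standard deviation for at least 5 ms; the offset is the first later
   sample where it stays below that threshold for more than 5 ms. The
   response size is the *relative iMEP area*

   `relative_area = area(rectified EMG, onset..offset) / (prestim mean x duration) x 100 [%]`,

   i.e. the burst expressed as a percentage of the ongoing background EMG.
2. **Amplitude-weighted map centre of gravity.** Over a 3x3 stimulation
   grid (2 cm spacing, centred on the contralateral-MEP hotspot), the map
   CoG is `x_CoG = sum_i a_i x_i / sum_i a_i` with `a_i` the mean relative
   area at site `i` and `x_i` its 3-D location in a common anatomical space.
3. **Bayesian two-group comparison** of iMEP CoG coordinates against the
   contralateral hotspot, axis by axis: a robust two-group model with
   Student-t likelihoods, broad priors and MCMC sampling
   (`BestModel(...).fit()` returns posterior draws, the difference of means
   with its 95% highest-density interval, and a separation "accuracy"
   `max(P(dmu>0), P(dmu<0))` that feeds a tiered significance rule:
   >= 80% `*`, >= 90% `**`, > 95% `***`).
4. **Task-modulation test** of iMEP area with a linear mixed model
   (TASK as categorical fixed effect, participant random intercept,
   background EMG covariate; likelihood-ratio omnibus test).
5. **A synthetic study generator** that simulates stimulus-locked EMG
   (band-limited noise background, multiplicative burst envelopes, Gaussian
   spatial tuning with a known true CoG) so every stage can be validated by
   parameter recovery.

Who this is for: TMS/EMG researchers who want a tested, scriptable version
of this analysis, and methodologists who want to probe how the threshold
rule, the CoG weighting and the Bayesian decision rule behave under known
ground truth.

## Worked example

```python
import numpy as np
from imepmap import (SyntheticConfig, MCMCConfig, simulate_dataset,
                     compare_centroids_by_axis)
from imepmap.pipeline import detect_study, map_study

# 8 participants, 3 tasks, 9 grid sites, 10 pulses per site; the true
# response centre is displaced antero-laterally from the hotspot
cfg = SyntheticConfig(n_participants=8, seed=1)
study, truth = simulate_dataset(cfg)

summaries = detect_study(study)          # burst detection per site
cogs, _ = map_study(study, summaries)    # CoG per participant x task

task = "iBB"
per_p = {p: c.location for (p, t), c in cogs.items() if t == task}
shift = np.mean([per_p[p] - study.hotspots[p] for p in per_p], axis=0)
print(f"{task}: n={len(per_p)} maps, mean CoG shift from hotspot "
      f"(dx, dy, dz) = ({shift[0]:+.1f}, {shift[1]:+.1f}, {shift[2]:+.1f}) mm")

res = compare_centroids_by_axis(
    per_p, {p: study.hotspots[p] for p in per_p},
    MCMCConfig(n_samples=20000, seed=2))
for ax, r in res.items():
    print(f"  axis {ax}: diff of means {r.mean_diff:+6.2f} mm, "
          f"95% HDI [{r.hdi[0]:+.2f}, {r.hdi[1]:+.2f}], "
          f"accuracy {r.accuracy:.1%} {r.tier}")
```

prints

```
iBB: n=6 maps, mean CoG shift from hotspot (dx, dy, dz) = (-0.8, +16.0, -0.0) mm
  axis x: diff of means  -0.84 mm, 95% HDI [-6.99, +5.17], accuracy 62.6% ns
  axis y: diff of means +16.09 mm, 95% HDI [+7.28, +24.23], accuracy 99.9% ***
  axis z: diff of means  -0.02 mm, 95% HDI [-3.38, +3.26], accuracy 50.1% ns
```

The generator planted the true iMEP centre 13.25 mm anterior (+y) and
2.3 mm lateral (-x) of the hotspot; the pipeline recovers an anterior shift
of the group CoG, the anterior axis separates the distributions decisively
(`***`), and the two undisplaced axes stay at chance-level accuracy. (Two
of the eight simulated participants had no detectable response for this
task and drop out of the map, as happens with weak responders in practice.)

The same chain is available from the shell:

```sh
imepmap run-all --seed 1 --out demo_out --mcmc-draws 10000
```

writes per-site summaries (`summary.tsv`), CoGs (`cogs.json`,
`group_cog.tsv`), per-task posterior comparisons (`comparison_<task>.json`),
the task-model report and a `report.json` embedding the seed and a
configuration hash. `simulate`, `detect`, `map`, `compare` and `taskmodel`
run the stages individually on studies stored in the documented TSV + JSON
sidecar format.

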