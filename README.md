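# contextdrift

Analysis pipeline linking **multivoxel fMRI pattern change** during
encoding of a continuous narrative to **retrospective duration estimates**
— the behavioral judgment of how much time passed between two moments of
the story — together with the surrogate- and permutation-based inference
that such slow signals require, searchlight mapping, autocorrelation
timescale profiling, a crossed-random-effects regression controlling for
stimulus similarity, and the accompanying behavioral statistics.

It is written for cognitive-neuroscience researchers who study episodic
memory and time perception with naturalistic stimuli, and for
methodologists interested in calibrated inference on slowly drifting BOLD
signals.

## The scientific problem

Theories of episodic memory posit a slowly changing *mental context*
signal that is bound to experienced events; the dissimilarity between the
context states at two events can serve as a clock for retrospective
duration judgments. With fMRI, mental context change between two narrative
events A and B is operationalised as the **pattern distance**

    d(A, B) = 1 − corr(p_A, p_B)

between the multivoxel activity patterns `p_A`, `p_B` of a region (each the
mean over a 5-TR window centred on the event's middle TR, TR = 1.5 s). The
central claim to test: across intervals of *equal objective duration*, a
participant's duration estimates correlate with `d(A, B)` in regions
carrying contextual information (entorhinal cortex being the canonical
candidate).

Because BOLD has long-range autocorrelation, the chance level of such a
correlation cannot be read from a textbook r distribution. The null is
built from **phase-randomized surrogates** of the lagged pattern-distance
time course (same amplitude spectrum, hence same autocorrelation, random
phases). With `r_emp` the empirical Fisher-transformed correlation and
`r_null` the surrogate set,

    z = (r_emp − mean(r_null)) / sd(r_null),

tested across participants with a right-tailed t-test and two-stage
Benjamini–Krieger–Yekutieli FDR over regions. A within-interval variant
scrambles estimates across participants instead; searchlight maps use
sign-flip cluster-mass family-wise-error control; a hierarchical model

    y ~ 1 + NaiveEstimates + NeuralPatternDistance
        + (1 + NaiveEstimates + NeuralPatternDistance | subject)
        + (1 + NeuralPatternDistance | interval)

(Box-Cox-transformed estimates, Wald 95% CIs) controls for the mere
stimulus similarity between events via the estimates of *naive* raters who
never heard the story.

Since raw scans of this paradigm are not publicly deposited, the package
ships a first-class **synthetic-data generator** that embeds a known
latent context-drift signal into BOLD-like data (plus stimulus-locked
shared signal, CSF/WM compartments, a global low-frequency artifact and
AR(1) voxel noise) and generates matching behavioral tables. Every stage
of the pipeline is verified against this ground truth.

## Worked example

```python
from contextdrift.synthgen import SynthConfig, generate_dataset
from contextdrift.datatypes import FilterSpec
from contextdrift.preprocess import highpass_run, nuisance_residualize
from contextdrift.drift import surrogate_z, group_roi_test
from contextdrift.behavior import confidence_filter
import pandas as pd

cfg = SynthConfig(seed=3)                  # 18 participants, 1040 TRs
ds = generate_dataset(cfg)

spec = FilterSpec(480.0)                   # gentle high-pass, sigma = 240 s
proc = [nuisance_residualize(highpass_run(r, spec)) for r in ds.runs]

two_min = set(ds.schedule.intervals.query("true_gap_s == 120").interval_id)
z = {}
for run, rep in zip(proc, ds.reports):
    keep = [i for i in confidence_filter(rep, ds.schedule) if i in two_min]
    z[run.participant_id] = {
        roi: surrogate_z(run, roi, ds.schedule, rep.estimates, keep,
                         n=1000, seed=7).z
        for roi in ("drift_roi", "null_roi")
    }
print(group_roi_test(pd.DataFrame(z).T).round(3))
```

Output (seed 3):

```
                  t      p     n      q  significant
drift_roi     0.790  0.220  18.0  0.462        False
null_roi      0.111  0.456  18.0  0.479        False
```

At the default (deliberately weak, physiologically plausible) effect size
neither region is detected in a single dataset — matching the reality that
these are small effects. The z-values are nonetheless higher in the region
that actually carries the planted drift signal (mean 0.22 vs 0.03), and at
the calibrated planted-effect strength used in the recovery suite
(`tests/test_acceptance.py::TestParameterRecovery`, where the latent
displacement–estimate correlation is ≈ 0.5) the drift region is flagged at
FDR q < 0.05 — and the matched null region is not — in well over 80% of
replicates.

A purely behavioral worked example, the combined CI for the difference
between two correlations computed from four printed summary numbers:

```python
from contextdrift.behavior import zou_difference_ci
ci = zou_difference_ci(0.49, 0.27, 0.57, 0.09, -0.05, 0.21)
print(round(ci.rdiff, 2), round(ci.lldiff, 2), round(ci.uldiff, 2))
# 0.4 0.15 0.56
```

meaning: the original group's estimates track event-boundary counts
(r = 0.49) significantly more strongly than the naive group's (r = 0.09);
the difference 0.40 has 95% CI [0.15, 0.56], excluding zero.

## Command line

```sh
contextdrift synth --out data/ --seed 1          # write a synthetic dataset
contextdrift run   --out results/ --seed 1       # full pipeline + manifest
contextdrift behavior --reports data/reports.tsv --schedule data/ \
                      --analysis gap-ttest
```

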