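# wearagree

Agreement analysis for multi-device wearable physiology: can a consumer
wristband's 30-second heart-rate and electrodermal summaries stand in for
what a research wearable or laboratory instrument measures?

The package is aimed at psychophysiologists and wearable-validation
researchers. It implements, as a tested and reusable pipeline, the analysis
chain such validation studies use — and a synthetic multi-device cohort
generator with ground truth so that every stage of the chain can be verified
end to end without access to any proprietary recording.

## What it computes

Three device classes observe the same underlying physiology over three
consecutive 90-s resting sessions per subject:

* a **laboratory device** (64 Hz raw PPG and EDA),
* a **research wearable** (64 Hz raw PPG, 4 Hz raw EDA),
* a **consumer wearable** that exposes no raw data — only one HR value and
  one "EDA responses" count per 30-s window.

From the raw devices the pipeline derives the same two features the consumer
device emits, on the same 30-s grid (9 points per subject):

1. **PPG conditioning and artifact rejection** — 5th-order Butterworth
   band-pass 1–15 Hz (zero-phase), polarity rectification by skewness, 2-s
   windowing, and two artifact criteria: a window is rejected if its local
   maximum exceeds 2× the median of all window maxima (or falls to ~0), or
   if the standardized, squared first derivative exceeds 9 — the 3σ point,
   below which 99.7% of physiological samples lie — after a 0.15-s
   convolution. Artefactual windows are removed, never repaired.
2. **Beat detection and HR** — a Pan–Tompkins-style detector (derivative,
   squaring, 0.15-s integration, adaptive dual thresholds, 0.25-s
   refractory) run on each contiguous clean segment; inter-beat intervals
   outside 0.25–2.0 s or spanning a rejected window are discarded;
   HR = mean of 60/IBI per 30-s window.
3. **EDA decomposition and SCL** — 1 Hz low-pass, then continuous
   decomposition analysis: skin conductance y(t) is modelled as a smooth
   tonic level (SCL) plus a nonnegative sudomotor driver convolved with a
   Bateman kernel `exp(-t/τ2) − exp(-t/τ1)`; SCL is averaged per 30-s
   window and driver bursts above an amplitude criterion emulate the
   consumer "EDA responses" count.
4. **Agreement statistics** — per-subject Pearson r (with the tally of
   subjects showing r > 0, p < 0.05) and the group repeated-measures
   correlation: a common-slope ANCOVA with subject intercepts, where
   `r_rm = sign(b)·√(SS_measure / (SS_measure + SS_error))` and
   `df = N_total − N_subjects − 1`.

## Worked example

```python
from wearagree.pipeline import RunConfig, run_pipeline

res = run_pipeline(RunConfig(seed=42, n_subjects=2))
print(res.features.head(9).to_string(index=False))
print(res.agreements[("scl_us", "empatica", "shimmer")].summary())
```

prints

```
subject  session   device  window_index    hr_bpm   scl_us  n_responses
    S01        1  shimmer             1 70.473441 3.717126            1
    S01        1  shimmer             2 73.359844 3.828448            0
    S01        1  shimmer             3 72.417192 3.938028            1
    S01        1 empatica             1 70.651031 3.709739            1
    S01        1 empatica             2 72.909787 3.823343            2
    S01        1 empatica             3 72.690164 3.938531            2
    S01        1   fitbit             1 74.000000      NaN            1
    S01        1   fitbit             2 76.000000      NaN            0
    S01        1   fitbit             3 73.000000      NaN            1

Agreement: scl_us  [empatica vs shimmer]
  subjects with r > 0 and p < 0.05: 2/2
  rmcorr: r_rm =  1.000, df = 15, p = 1.52e-25
  note: per-subject p-values are uncorrected for multiple testing
```

Each row is one 30-s window of one device's view of a session: the two raw
devices agree on SCL to ~0.01 µS and on HR to well under 1 bpm because they
watch the same simulated physiology through different sampling rates, noise
and artifacts; the consumer row carries only its integer HR and response
count. The rmcorr line says the two devices' SCL series share a common
within-subject slope almost perfectly once subject-level offsets are
removed.

A command-line interface mirrors the stages (`wearagree simulate`,
`ppg-clean`, `ppg-hr`, `eda`, `agree`, `run`); `wearagree run --seed 42
--n-subjects 12 --out-dir out/` writes `features.csv`, `truth.csv`,
`agreement.json` and a run manifest.

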