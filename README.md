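# eventshift

Detects **anticipatory temporal shifts in neural event structure** when
people experience the same naturalistic stimulus repeatedly. Given fMRI
responses to several viewings of a movie clip, the package fits an
ordered-event hidden Markov model jointly to all viewings, measures how
much earlier event transitions occur on repeated viewings (in seconds),
maps this across the brain with searchlights plus permutation/FDR
inference and a posterior→anterior gradient test, and relates the model's
event boundaries to human boundary annotations via HRF-convolved
cross-correlation with continuous lag estimation.

It is written for computational neuroimaging researchers working with
repeated naturalistic designs (movie or story stimuli, TR-resolution BOLD
data in NIfTI volumes).

## The model

A region's response is modeled as a traversal of K ordered events, each
with a fixed spatial pattern m_k. The latent state starts at event 0,
advances by at most one event per TR, and must reach event K−1 by the last
timepoint; emissions are isotropic Gaussians N(m_k, σ²I) on
feature-z-scored observations. Fitting the model jointly to all viewings
shares the event patterns while leaving each viewing its own posterior
γ_v[t, k] = P(event k at time t). The expected-event curve
e_v(t) = Σ_k k·γ_v[t, k] tracks each viewing's progress, and anticipation
is the upward shift of the repeated-viewing curves:

    anticipation (s) = (mean_v≥2 AUC_v − AUC_1) · TR / (K − 1)

so one TR of uniform shift equals one TR of anticipation. Whole-brain maps
run this inside spherical searchlights after shared-response-model (SRM)
hyperalignment into a 10-dimensional shared space; significance comes from
re-running the full pipeline on datasets with each subject's viewing order
shuffled (normal-fit one-tailed p, Benjamini–Hochberg FDR). The temporal
derivative of e_v(t) ("boundary strength") is cross-correlated with an
HRF-convolved human-annotation timecourse to estimate, per viewing, the
continuous lag between the brain's boundaries and subjective ones.

## Worked example

Recover a known two-TR anticipation from synthetic data (six viewings,
seven events, 60 TRs at TR = 1.5 s, noise SD 0.3):

```python
from eventshift import (make_ground_truth, generate_subject_viewings,
                        fit_event_model, expected_event_curve,
                        anticipation_seconds)

truth = make_ground_truth(n_events=7, n_timepoints=60, n_voxels=10,
                          shift_seconds=[0, 3, 3, 3, 3, 3],
                          noise_sd=0.3, seed=1)
subject = generate_subject_viewings(truth, n_subjects=1, mixing="none", seed=2)[0]
model, posteriors = fit_event_model(subject, n_events=7)
curves = [expected_event_curve(p, tr=1.5, viewing_index=v + 1)
          for v, p in enumerate(posteriors)]
print(f"anticipation: {anticipation_seconds(curves):.2f} s")
```

```
anticipation: 3.00 s
```

The repeated viewings were generated with boundaries 3 s (two TRs) earlier
than viewing 1, and the model recovers exactly that. The same analysis
runs end to end from the command line on a simulated volume:

```bash
eventshift run-all --out results/demo --seed 1
```

which simulates a gradient dataset, writes the anticipation/p/q maps, the
gradient-test table, per-searchlight boundary lags, and the
intrinsic-timescale (best-K) map, each stage alongside the exact config
used.

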