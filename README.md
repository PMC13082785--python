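# shhtrack

Analysis of single-cell morphogen-response dynamics from timelapse
fluorescent-reporter tracks, built for the zebrafish ventral neural tube:
neural progenitors respond to a Sonic hedgehog (Shh) gradient through Gli,
and a stable-protein transcriptional reporter (e.g. *ptch2:kaede*) records
that response as accumulating fluorescence. `shhtrack` turns raw intensity
tracks into inferred promoter-activity traces, estimates reporter mRNA
half-life from heat-shock pulse data, clusters response trajectories, and
quantifies how sharply per-cell response metrics predict fate choice.

## The model

For a stable fluorescent protein, measured intensity `I(t)` and reporter
mRNA `m(t)` obey

    dI/dt = c1 * m
    dm/dt = x - m * ln2 / t_half

where `x(t)` is the promoter transcription rate (the cell's signalling
response, in AU/hr²) and `t_half` the mRNA half-life. Eliminating `m` gives
the inversion used on every processed track:

    c * x(t) = I''(t) + I'(t) * ln2 / t_half

Half-life is estimated from a heat-shock pulse experiment: after a short
transcription pulse, `-ln(1 - I/I_max)` is linear in time with slope
`ln2 / t_half`.

Before inversion, tracks pass a fixed correction chain: saturated records
(saturated-pixel fraction > 5%) are masked, channel bleed-through is
estimated and subtracted, intensities are smoothed by a centered moving
average (default 6 time points = 36 min at 6-min sampling), and tracks are
trimmed to the 10–15 hpf analysis window.

Downstream, per-cell metrics (maximum transient response, average response,
response time above 0.05 AU/hr²) are ranked into a "French flag": cells
ordered by the metric are split by optimally placed ordered thresholds into
fate bands (LFP / pMN / more-dorsal), and the percentage of correctly
banded cells measures metric–fate correlation, against a label-permutation
chance baseline.

A synthetic-data module generates cohorts with known ground truth
(fate-dependent transcription programs, heterogeneous onsets, bleed-through,
saturation, measurement noise, fate-correlated LMDV positions) so the whole
chain is testable without microscopy data.

## Worked example

```sh
shhtrack halflife --seed 3 --out out-hs
# t_half = 1.684 hr (report in out-hs/halflife_fit.txt)
```

The heat-shock preset simulates 20 cells with a true half-life of 1.7 hr
and 2% measurement noise; the linearized fit recovers 1.68 hr (slope
≈ 0.41 hr⁻¹).

```sh
shhtrack all --preset anterior-like --seed 1 --out out-ant
# done: {'version': '0.1.0', 'seed': 1, 'n_tracks': 90,
#        'bleed_ratio': 0.223..., 'k': 6,
#        'flag': {'anterior:max_response': 100.0,
#                 'anterior:avg_response': 100.0,
#                 'anterior:response_time': 100.0}}
```

This runs simulate → preprocess → infer → metrics → cluster → flag on the
anterior-like preset (90 cells, 30 per fate). All three response metrics
predict fate perfectly on this well-separated cohort; `out-ant/` holds the
processed tracks, activity traces, per-cell metrics, cluster assignments,
the fate-contribution matrix and the flag summary with permutation
baselines. On the posterior-like preset (overlapping LFP/pMN amplitudes,
variable onset and duration) the duration-weighted metrics degrade while
the maximum transient response stays the best predictor:

```sh
shhtrack all --preset posterior-like --seed 1 --out out-post
# 'flag': {'posterior:max_response': 95.83, 'posterior:avg_response': 85.0,
#          'posterior:response_time': 74.17}
```

A YAML config can replace the flags (`shhtrack --config examples/anterior.yaml all`);
CLI options override config values. See `docs/methods.md` for the model
details, parameter meanings and limitations.

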