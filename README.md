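# gamblerp

Simulation and analysis of event-related potentials (ERPs) recorded during a
probabilistic gambling task — the kind of paradigm used to study risky
decision making in adult ADHD.  The package is aimed at EEG/ERP
methodologists who want a fully synthetic, seed-reproducible test bed for the
complete analysis chain: behavioural task simulation, multichannel EEG
synthesis with planted components, ERP preprocessing, peak-latency
extraction, and a difference-wave group analysis with nonparametric
statistics.

## The task and its endpoints

Each trial the agent holds an endowment of 20 points and stakes
x ∈ {0, 4, 8, 12, 16, 20}.  With probability P_win = 1/3 the stake returns
fourfold, otherwise it is lost:

    points_after = (20 − x) + 4x·[win]

so staking 8 leaves 12 on a loss and 44 on a win, and
E[points_after | x] = 20 + x/3.  Trials run in 10 alternating blocks of 16:
high-frequency feedback (HF, outcome shown each trial) vs low-frequency
(LF, outcome withheld) — 80 trials per condition.  Behaviour is summarised
by total gains TotG (and per-condition TG(HF), TG(LF)), response times
(cleaned by 250 ms / 10 s thresholds plus a Local-Outlier-Factor screen on
log RT), and the risk index

    RI = (HR − LR) / (HR + LR) ∈ [−1, +1]

where HR and LR are the fractions of high-stake (12/16/20) and low-stake
(0/4/8) trials.

## The ERP analysis

Two events delimit each trial: trial onset **S** (spacebar press) and gamble
selection **I** (mouse click).  Six midline sites (Fz, FCz, Cz, CPz, Pz,
POz) are band-passed 0.1–30 Hz (zero-phase 2-pole Butterworth), cut into
[−500, +1000) ms epochs around S and I (320 epochs/participant), baseline
corrected to the pre-trigger 500 ms, screened by peak-to-peak (100 µV) and
gradient (50 µV/ms) rules, and averaged per feedback condition (only when
more than 20 clean epochs remain).  Component peaks (N2 ~175 ms negative,
P3a ~250 ms and P3b ~340 ms positive, posterior C1 ~70 ms) are located as
windowed local extrema and pooled over frontocentral (Fz, FCz, Cz) and
centroparietal (CPz, Pz, POz) sites.

The difference-wave analysis subtracts each participant's LF average from
their HF average, forms group mean ± SEM envelopes, and quantifies group
contrasts by integrating the gap between non-overlapping envelope limit
lines over component windows (trial onset: 80, 260, 490 ms; choice: −450,
−140, +490, +850 ms), with permutation tests, per-electrode bootstrap
confidence intervals, and Wilcoxon signed-rank tests.

The synthetic EEG generator plants Gaussian-bump components whose mean
latencies carry the study's group × condition × ROI structure (e.g.
trial-onset frontocentral N2: controls 164.0 vs ADHD 173.5 ms under HF), on
top of 1/f noise, alpha rhythm, blinks, and muscle bursts — so every stage
can be validated by parameter recovery.

## Worked example

```sh
python examples/01_simulate_behavior.py
```

prints, for one seeded risk-neutral control session:

```
trials played: 160  (HF 80, LF 80)
TotG = 3860 points   TG(HF) = 1880   TG(LF) = 1980
RI(all) = -0.076  (HR 0.46, LR 0.54, n 145)
RI(HF) = +0.040  (HR 0.52, LR 0.48, n 75)
RI(LF) = -0.200  (HR 0.40, LR 0.60, n 70)
RT median = 1028 ms over 145 retained trials (0 outside 250 ms-10 s, 15 LOF outliers)
```

TotG ≈ 160·(20 + 10/3) ≈ 3733 in expectation for a uniform gambler; RI near
zero reflects the risk-neutral stake policy.  The other examples cover EEG
synthesis + preprocessing (`02`), planted-latency recovery (`03`), the
difference-wave contrast (`04`), the nonparametric statistics (`05`), and
the full report bundle (`06`).

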