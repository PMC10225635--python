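# Methods

`grf3d` estimates three-dimensional ground reaction force (GRF) waveforms
during treadmill running from the free (gravity-subtracted) accelerations
of three body-worn IMUs — one on the pelvis and one on each (proximal)
tibia — sampled at 240 Hz. Because no public dataset pairs such sensor
streams with force-plate recordings at this protocol, the package ships a
physics-consistent cohort simulator that stands in for the instrumented
treadmill; every claim the test suite makes is a claim about that stated
synthetic world, not about human subjects.

## Estimation models

**Physical model.** Newton's second law applied to a weighted sensor
combination gives the vertical GRF per sample:

    eGRF(t) = m_b·g + m_b · [ WF_p·ã_z,pelvis(t) + WF_t·ã_z,tibL(t) + WF_t·ã_z,tibR(t) ]

with body mass `m_b`, `g = 9.81 m/s²`, weight factors `WF_p = 0.55` and
`WF_t = 0.23` (per tibia), and per-sensor zero-phase Butterworth low-pass
filtering of the vertical free acceleration (pelvis: 2nd order, 5.97 Hz;
tibias: 1st order, 8.74 Hz). Outputs are reported in bodyweights (BW),
where the model is independent of `m_b`:
`eGRF_BW = 1 + Σ WF_i·ã_z,i/g`. There is no physical model for the
mediolateral (ML) or anterior-posterior (AP) axis; those columns are
marked unavailable (NaN). The estimate is not clipped at zero; during
flight it settles near `1 − (WF_p + 2·WF_t) ≈ −0.01 BW` because sensors in
free fall read `−g`.

**Direct neural estimator.** A feedforward network (two hidden layers of
100 ReLU units, linear 3-unit output) maps the nine acceleration channels
(3 sensors × 3 axes, 3rd-order bidirectional 10 Hz low-pass) at one time
sample to the 3-axis GRF in BW at that sample. Loss is the joint MSE over
the three axes; optimization is Adam (learning rate 1e-3, β₁ 0.9,
β₂ 0.999) with batch size 250 for at most 1000 epochs, stopping early once
the validation loss has not improved for 100 consecutive epochs and
restoring the weights of the best validation epoch. Inputs are z-scored
with statistics of the training rows only; targets stay in BW (dividing by
`m_b·g` removes body-mass scale from the regression). Training rows
include flight samples so the network learns to emit ≈0 there. An optional
symmetric context window `w` replicates each channel at lags −w..+w
(default `w = 0`, i.e. a per-sample map; the temporal extent of the input
is a free design axis, so it is exposed as configuration rather than
hard-coded).

**Hybrid estimator.** Identical to the direct estimator except that the
physical model's vertical estimate (BW) is appended as a tenth input
column — physics as a feature, letting the network spend capacity on the
residual and on the two axes the physics cannot see.

**Ensembles under LOSO-CV.** Evaluation is leave-one-subject-out: for each
held-out subject, seven networks are trained on randomly drawn,
pairwise-distinct partitions of the remaining subjects into 4 validation
subjects and the rest (7 of 12) for training; the ensemble prediction is
the arithmetic mean of the member predictions. By convexity of the squared
error the ensemble's MSE never exceeds the members' mean MSE, and this
identity is asserted on every run. Member dispersion (per-sample sd with
the n−1 denominator, min, max) is reported as an agreement/uncertainty
band; it is widest near the force peaks. Members that fail to train abort
the run — a silent 6-member ensemble would be unauditable. For cohorts of
other sizes the geometry generalizes to (n − 1 − 4) training subjects;
seven members and four validation subjects are kept. Distinctness of the
splits is enforced (duplicates would silently shrink ensemble diversity),
which requires C(n−1, 4) ≥ 7, i.e. at least 7 subjects.

The trainer is written directly on NumPy (float32 forward/backward,
seeded He initialization). Inside one LOSO fold the seven members are
optimized in a single batched pass (stacked weight tensors, one gather per
minibatch); per-member early stopping masks the update of members that
have stopped. A fixed random subset of validation rows (config
`max_val_rows`) may stand in for the full validation loss when cohorts are
large; the subset is drawn once before training, so the early-stopping
signal is consistent across epochs.

## Preprocessing

1. **Force conditioning** — the 2048 Hz treadmill force is filtered with a
   6th-order zero-phase 30 Hz Butterworth low-pass, then downsampled onto
   the 240 Hz sensor clock by linear interpolation (the 30 Hz filter is
   the anti-alias step; 2048/240 is non-integer).
2. **Synchronization** — the unknown inter-system offset is the argmax of
   the normalized cross-correlation between the summed tibia vertical free
   acceleration and the vertical GRF, searched over ±1.25 s. The discrete
   peak is refined parabolically and rounded back to an integer lag, which
   removes the ±1-sample bias that otherwise arises from cross-correlating
   two differently shaped waveforms. A weak peak (< 0.2) or non-contiguous
   near-peak lags (within 1%) raise an ambiguity warning; genuine running
   signals are unambiguous only because stride timing jitters — a
   perfectly periodic gait yields a correlation comb at the step period
   whose wrong teeth flip the ML axis sign (one-step misalignment swaps
   the feet) while leaving vertical and AP nearly unchanged.
3. **Gait events** — stance where the measured vertical GRF exceeds 25 N,
   flight where it does not, with runs lasting ≤ 0.05 s (strictly-greater
   rule) absorbed into the enclosing phase; labelling is done at 240 Hz.
   A stride is two consecutive steps: summed dual-belt force carries no
   foot identity, so left/right strides are not distinguishable.
4. **Stride window** — 40 strides (configurable) centred on the middle of
   the trial, snapped to stance onsets. All filtering happens on the full
   continuous trial before windowing to avoid per-stride edge artefacts.

## The synthetic cohort

The generator emulates the protocol of a 12-subject treadmill study
(body mass ~ N(73.7, 17.5²) kg truncated to (40, 120); 90 s trials at
10/12/14 km/h × stride-frequency conditions preferred and ±10%; preferred
stride frequency ~ N(1.40, 0.07) Hz).

**Vertical GRF** per step is the sum of two stance-limited Gaussian bumps
— an impact peak at 12.5% of stance (σ = 25 ms, 1.6 BW nominal) and an
active peak at 45% of stance (σ = 0.18·stance, 2.5 BW at 10 km/h +
0.05 BW per km/h) — shaped to zero at the stance edges by short cosine
ramps and rescaled per trial so the average vertical force over an
integer number of strides equals body weight (impulse balance). Duty
factor (stance / stride period) is 0.35 at 10 km/h, −0.015 per km/h.
**AP force** is a braking negative half-sine over the first 40% of stance
followed by a propulsive positive half-sine (peak ±0.40 BW). **ML force**
is a low-frequency half-sine of ±0.12 BW whose sign alternates with the
stance foot. Flight samples are exactly zero on all axes. Step onsets
jitter with sd 2% of the step period — real stride timing varies at this
order, and this jitter is what makes cross-correlation synchronization
well-posed (see above).

**Sensor synthesis** inverts the physical model so that the model is
near-valid on the synthetic data: with centre-of-mass acceleration
`a_com = F_v/m_b − g`, the pelvis carries `LP(a_com)` (2nd-order
bidirectional, 6 Hz) and each tibia carries the residual
`(a_com − 0.55·a_pelvis)/0.46`, so the weighted sensor sum reproduces
`a_com` identically. The striking tibia additionally rings with an
exponentially decaying 20 Hz transient (15 m/s², τ = 40 ms); both tibias
sway at the stride frequency (0.5 m/s², antiphase — note the antiphase
components cancel in the summed vertical). Horizontal channels couple to
the AP/ML force per unit mass through subject-specific gains
κ ~ N(1, 0.08); white noise (sd 0.5 m/s²) is added to all channels. The
force stream is the truth resampled to 2048 Hz and delayed by an integer
offset drawn uniformly from ±240 samples.

**What the generator does not emulate** — and hence what a green test
does not establish: soft-tissue artefact and skin motion, sensor
orientation drift, non-heel-strike patterns, dual-belt crossover, surface
gradient, fatigue drift, and ML force variance that is *not* visible in
the sensors. The last point matters: with the stated constants the ML
channel is a clean (if small) linear image of the ML force, so held-out
ML correlation reaches ≈0.99 — strictly the worst of the three axes (its
amplitude-to-noise ratio is the lowest), but far better than on real
runners, where much of the ML force is biomechanically unobservable from
three sensor sites. Conclusions about the *ordering* of axis difficulty
transfer; absolute ML performance does not.

**Physical-model consistency.** With noise, transients and sway off, the
end-to-end physical model achieves a vertical stance-only rRMSE of ≈7.8%
at the central condition (12 km/h, preferred cadence; range 7.2–9.3%
across the nine protocol cells, mean ≈8.0%). The residual error is
structural: given the exact linear sensor partition, the model's output
equals the truth filtered through a fixed transfer function
`H(f) = G_8.74(f) + 0.55·(G_5.97(f) − G_8.74(f))·G_6(f)` (zero-phase
gains), which attenuates genuine 4–9 Hz waveform content by 20–45%;
faster cadence shifts more energy into that band, which is why the
fastest cells are worst. No tibia/pelvis signal assignment satisfying the
linear partition can beat this floor.

## Evaluation

Per trial and axis: RMSE in BW; rRMSE = RMSE / (max − min of the
*measured* signal over the same evaluation domain) × 100; Pearson r; and
for the vertical axis the absolute active-peak error (mean over stance
intervals of |ê_peak − m_peak|/m_peak × 100). The default evaluation
domain is stance samples inside the stride window — including flight
(domain `full_signal`) flatters rRMSE because the zero force there is
trivially predicted, and the package asserts that direction on synthetic
data. Trial metrics average to per-subject values (averaging over trials,
not pooling samples), per-subject values to cohort mean ± sd; model pairs
are compared with a two-sided dependent t-test over per-subject means at
α = 0.05. Zero-variance difference vectors are reported explicitly
(identical models: t = 0, p = 1; constant non-zero shift: degenerate
flag) rather than dividing by zero.

## Numerical and design choices

- Axis conventions are fixed once: sensors (AP, ML, vertical), force
  (ML, AP, vertical), vertical positive up; `g = 9.81 m/s²` everywhere.
- Half-open, 0-based sample intervals; filtering precedes windowing.
- CSV output uses `%.17g` floats and fixed column order; reading uses
  round-trip float parsing, so write→read is bit-exact and repeated
  writes are byte-identical.
- One network with three outputs rather than three per-axis networks: a
  single joint MSE, no per-axis weighting.
- Early stopping counts epochs since the best validation epoch and stops
  when the gap reaches the patience (strictly increasing validation loss
  from epoch 1 stops after epoch 101 with epoch-1 weights restored).
- Seeding: one master seed fans out via `SeedSequence` to subjects,
  trials, and per-fold trainer seeds; identical seeds give byte-identical
  cohorts and bit-identical weights at a fixed thread count.
- The physical estimate feeding the hybrid features is computed on the
  full trial and sliced to the window, like every other channel.

## Known limitations

- The ≤8% physical-model consistency bound holds at the central protocol
  condition but not at 14 km/h / +10% cadence (see above); the bound is a
  property of the simulator+model pair, not of the estimators.
- Single-sample (w = 0) networks carry no temporal context; they cannot
  disambiguate states that coincide instantaneously in feature space.
- The trainer is CPU-bound NumPy; at the full published protocol scale
  (12 subjects × 9 trials × 40 strides × 1000 epochs × 2 model kinds) a
  LOSO sweep takes hours, so tests and the acceptance script run reduced
  cohorts (fewer trials, shorter windows, capped epochs) — scaled down,
  never gated.
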