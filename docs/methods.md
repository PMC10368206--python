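# Methods

## Task model

Both paradigms are encoded as `TaskVariant` objects with per-pattern pulse
counts and durations. Time is trial-relative: t = 0 at the onset of the
first intra-trial stimulus, and all windows (reward, response, time-out) are
expressed on that axis. A pattern is pulses alternating with gaps, starting
and ending with a pulse, so its duration obeys the closed form
`n·d + (n−1)·g`:

| variant | preferred | nonpreferred | gap | reward | response window |
|---|---|---|---|---|---|
| TPSD | 4 × 0.2 s = 1.4 s | 4 × 0.9 s = 4.2 s | 0.2 s | 1.2 s | 1–2 s |
| TPSD_mod | 3 × 0.733 s ≈ 2.6 s | 7 × 0.2 s = 2.6 s | 0.2 s | 2.3 s | 2–3.2 s |
| control | as TPSD, indicator forced off | | | | |

733 ms is stored exactly (0.733 s); the 2.6 s duration parity of the
modified variant holds at 0.01 s rounding (3·0.733 + 2·0.2 = 2.599 s). No
gap precedes the first pulse — the printed totals only come out with the
gap strictly interleaved. Binary stimulus indicators use half-open bins
`[t, t+Δ)` with membership decided by the bin midpoint; the indicator sum
therefore matches total on-time within one bin per epoch boundary for
non-aligned bin widths. Session schedules draw an exact round-half-up count
of preferred trials (245/105 at 7:3 and 350 trials) and permute the order
under the supplied seed.

## Synthetic sessions

The study's recordings are not deposited, so the generator produces
sessions with the structure the analysis assumes. It is first-class, tested
code: its planted ground truth is what makes recovery claims falsifiable.

**Licking** is a renewal point process on the 250 Hz lickport clock. The
instantaneous rate (licks/s) is piecewise per stage and trial kind, and the
tick-wise hazard is inflated to `r/(1 − r·t_ref)` with a refractory dead
time `t_ref = 70 ms`, so the requested rate is the mean rate while the
train is quasi-rhythmic like real licking (≤ ~14 Hz). Defaults (free
parameters of the generator, not measurements): base rate 4 licks/s;
learned engaged trials ramp ×2.5 from 0.3 s to the 0.7 s decision time and
hold through the response window; learned nonpreferred trials suppress to
×0.1 of base from 0.7 s unless the trial is "impulsive" (probability 0.15,
licking like a preferred trial — the false-alarm mechanism); preferred
trials lapse with probability 0.05 (×0.2 rate — the miss mechanism); naive
trials lick at base rate regardless of stimulus, with a ×1.5 consumption
bump after the chance-encountered 1.2 s reward on preferred trials.

**Spiking** is Bernoulli per 1/15 s frame (deconvolved-spike scale, binary
by construction). Baseline probability 0.06/frame (≈ 0.9 Hz). In the
learned stage, stimulus-locked cells (fraction 0.35) multiply their rate by
(1 + 2·indicator) during on-epochs of the *preferred* timeline — the
learned network is tuned to the preferred rhythm in both conditions — and
all non-lick cells on nonpreferred trials decay by `exp(−(t−t₀)/0.25 s)`
from onset t₀ = 0.7 s when the simulated animal withholds licking, or
t₀ = 1.4 s when it licks impulsively. This couples network suppression to
behavior the way the recorded data behave: correct rejections suppress
early, false alarms predictively code the preferred stimulus. Planted
lick-coupled cells (fraction 0.10) fire with probability
`p₀ + c·(0.95 − p₀)` in any frame containing a lick (coupling c = 1 in the
recovery fixtures). The naive stage has no drive and no suppression, so
per-bin activity is flat. Population size, when not fixed, is drawn from
the across-animal distribution N(108, 39.2) truncated at 10 cells.

One master seed spawns independent child streams (schedule, licks,
population), so stages are individually reproducible; fixtures serialize to
CSV + HDF5 + YAML with a full parameter echo and round-trip losslessly.

**What the generator does not emulate:** calcium-indicator kinetics and
deconvolution artifacts, slow drift and motion, running/arousal covariates,
cross-trial adaptation, correlated noise between cells, and graded (rather
than switch-like) per-trial engagement. Passing tests therefore show that
the *analysis machinery* behaves correctly on data with the assumed
structure — not that real V1 data have that structure.

## Behavioral metrics

d′ = Φ⁻¹(hit fraction) − Φ⁻¹(FA fraction); a fraction of exactly 1 (0) is
replaced by 0.99 (0.01) before the inverse normal — clipping applies only
at the exact corners, not as a continuity correction, so an all-correct
session caps at 2·Φ⁻¹(0.99) ≈ 4.653. Session performance is the maximum d′
over every contiguous 150-trial window (ties → earliest; windows missing a
stimulus class are skipped), with hit and CR rates reported on the same
window. The lick threshold is the final-pretrial mean rate minus one sample
SD (n−1 throughout), floored at zero; a trial counts as a response when its
mean lick rate over the full response window reaches the threshold — the
averaging window is a package choice, as only the rate criterion itself is
specified by the task. Lick probabilities are per-0.1 s fractions of trials
with ≥ 1 lick, computed per mouse and averaged across mice (never pooled
trials); empty groups (e.g. Miss) are dropped with a warning.

## Decoding

Features per 0.067 s bin are the lick count (one feature) or each cell's
binary frame value (population mode; 15 Hz frames map 1:1 onto the decoding
bins). Bin count is `floor(horizon/Δ)`; a final partial bin is dropped.
Each "machine" is an RBF-kernel C-SVM trained on a freshly resampled
stratified 80/20 split and scored on the held-out 20 % — the bootstrap
resamples the split, not the trials (a resample-with-replacement variant is
available via `resample_trials=True`). Defaults when untuned: box
constraint 1, kernel scale = median pairwise distance (so accuracy is
invariant to positive rescaling of the features). Controls permute the
labels independently per machine; bands are percentile (2.5–97.5 %). A bin
with constant features records chance (0.5) with a warning; single-class
labels are an error. Stratification, not reweighting, handles class
imbalance, so the 0.5 chance reference is only exact for balanced designs —
the synthetic decoding fixtures are balanced for that reason.
Hyperparameter tuning (used for full-network neural decoding only; lick
decoding is deliberately untuned) is a seeded log-space random search over
(C, kernel scale) around the median heuristic, scored by stratified 5-fold
CV; candidate 0 is the default pair, and insufficient data falls back to
the defaults with a warning.

Forward sequential selection of k cells evaluates, at each step, every
remaining cell by the held-out accuracy of the model on the
already-selected set plus that cell. Two numerical choices matter on small
test sets, where accuracies tie frequently: ties break by a seeded random
draw, and once no candidate strictly improves the objective the remaining
slots are filled by a random draw from the unused candidates (the greedy
objective is flat there, so any order is equally good; a deterministic
tie-break would spuriously concentrate selections on low-index cells).
Cells constant in the training split are never selectable. Selection maps
normalize per-cell counts by the k·n_machines available slots, so forced
selection (k = n cells) yields exactly 1/n per cell. The hot path calls
scikit-learn's low-level libsvm bindings directly (same solver as `SVC`,
verified prediction-identical) to keep per-fit overhead small; paper-scale
defaults are 10,000 machines/bin for licking and 1,000 for imaging, with
desk-scale presets used throughout the tests.

## Lick-modulated cells

Licked (Hit + FA) vs non-licked (CR + Miss) trials are decoded per
response-window bin; per machine, 20 cells are forward-selected (clamped
with a warning if the population is smaller; selection repeats per machine
— the once-per-bin reading is obtainable with `n_machines=1`) and every
selected cell accrues the machine's accuracy z-scored against that bin's
control distribution. The control runs the *same* selection procedure on
permuted labels, so the optimism of picking cells by held-out accuracy
cancels and an unstructured population scores near zero; the control SD is
floored at the binomial SD of a chance classifier on the test set so a
degenerate control cannot inflate z. Sessions are admitted when the Pearson
correlation between per-cell total score and selection count is positive
with p < 0.05; admitted sessions flag cells > 1 SD above the mean total
score (SD = 0 or a non-admitted session flags nothing — an empty flag set
is a legitimate outcome). Flagged cells are removed before sensory
analyses; scores accumulate within a session only.

## Dynamics

Mean network activity per condition is a trial bootstrap: 1000 iterations
of resampling trials with replacement (cells are never resampled) and
averaging the binary activity over cells and trials per bin; per-mouse
iteration sets pool into one grand distribution with percentile 95 % bands.
Stimulus correlation is Pearson r over pooled (iteration × bin) pairs
against the 0/1 indicator; zero-variance input is an error rather than
r = NaN. Peak times are per-cell argmax of the trial-averaged trace within
the stated period (ties → earliest bin, per-trial variant available);
condition pairs are compared with two-sample KS tests at
α_adj = family α / n_pairs (0.0083 for six pairs, 0.0167 for three), exact
p-values below n = 30 and asymptotic otherwise. Heatmap orderings group
cells by peak bin in ascending time with original order preserved within a
group (stable argsort). Trajectories: per-outcome cell × bin trial-averaged
matrices are concatenated over (outcome × bin) observations, centered per
cell without variance scaling (activity is already on a common binary-rate
scale), and projected onto the first three principal components; the
divergence between two outcomes is the mean Euclidean distance between
their component trajectories across bins.

## Problem sizes and numerical choices

The tests and the acceptance script run desk-scale configurations chosen as
this package's own defaults for development hardware: 50–200 trial
sessions, 40–50 cell populations, 100–200 machines per bin for decoding
curves, 10 selection machines per response-window bin (with 10
selection-based controls), 200-iteration bootstraps, and 5–20 seed
replicates. Paper-scale settings (10,000/1,000 machines, 1000-iteration
bootstraps, ~108-cell populations) remain the library defaults and are
exposed through the `paper-scale` CLI preset. Recovery fixtures use
balanced (1:1) schedules: with single-frame binary features, a 7:3 class
prior makes the majority-class baseline unbeatable for weakly informative
cells, which degrades the selection signal without changing the algorithm —
the biased-ratio schedules remain available for the behavioral analyses.

## Known limitations

- The Bernoulli spiking model has no temporal correlation within cells, so
  peak-time distributions are noisier than calcium-derived ones.
- The generator's outcome-coupled suppression builds in the direction of
  the trajectory-divergence effect; the corresponding checks validate the
  analysis chain end-to-end, not the biological claim.
- Multiclass outcome decoding is pairwise one-vs-one only.
- Percentile (not normal-theory) intervals everywhere; with few bootstrap
  iterations the bands are conservative at the edges.
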