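# Methods

## Scope

`oxyloop` simulates and evaluates an SpO2-targeted FiO2 controller in a
closed loop with a virtual patient. Three layers:

* **physiology** — delivered FiO2 → arterial saturation;
* **sensor** — arterial saturation → the displayed, quality-annotated SpO2
  stream;
* **controller / scenarios / evaluation** — decisions, disturbances, and
  the clinical time-in-range metrics.

## Gas-exchange model

The virtual patient is a single-compartment lung with venous admixture:

1. Alveolar gas equation (simplified):
   `PAO2 = FiO2·(Pb − 47) − PaCO2/R`.
2. Severinghaus (1979) dissociation curve
   `S(P) = 1/(1 + 23400/(P³ + 150P))`, accurate to about ±0.3% saturation
   over the clinical range and analytically invertible (Cardano), so the
   P50 (26.8 mm Hg) is exact by construction.
3. Oxygen content `C = 1.34·Hb·S + 0.003·P`.
4. Berggren shunt balance `CaO2 = Cc′O2 − s·avDO2/(1 − s)` with shunt
   fraction `s` and a fixed arteriovenous content difference.
5. PaO2 recovered from arterial content by inverting `C(P)` — monotone
   scalar root-find (warm-started Newton, bracketed-bisection fallback,
   root bracketed in (0, PAO2]).

Dynamics: the effective alveolar FiO2 relaxes to the set value with a
first-order time constant `tau_alveolar` (default 45 s), and the probe sees
the arterial saturation of `circ_delay` seconds ago (default 15 s, a pure
transport delay implemented as a ring buffer). These mid-range wash-in and
recirculation times produce the visibly dampened response the controller's
lockout and dampening are designed around.

Degenerate inputs: the pure steady-state API raises a model error when the
requested shunt/content combination is non-physical, but the dynamic
stepping path instead floors PaO2 at 20 mm Hg (SaO2 ≈ 32%). Overlapping
transient events can push the total shunt beyond what a fixed
arteriovenous difference can represent; a real patient there is profoundly
hypoxemic, not content-negative, and the simulation must remain total.

The model deliberately carries the clinical asymmetry that motivates the
two controller profiles: the higher the shunt, the smaller ∂SaO2/∂FiO2 at a
matched operating saturation, to the point that a total shunt above ≈0.4
cannot be compensated by 100% oxygen at all (refractory hypoxemia). A
property test asserts this ordering.

### Patient parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `shunt_fraction` | per stratum | – | sole severity dial |
| `hb` | 11 | g/dl | mildly anemic ventilated ICU adult |
| `paco2` | 40 | mm Hg | normocapnic ventilation |
| `barometric_pressure` | 760 | mm Hg | sea level |
| `resp_quotient` | 0.8 | – | mixed diet |
| `av_o2_diff` | 5 | ml O2/dl | normal extraction, stable hemodynamics |
| `tau_alveolar` | 45 | s | mid-range FiO2 wash-in |
| `circ_delay` | 15 | s | lung-to-finger recirculation |

Severity strata: severe patients draw shunt ~ U(0.20, 0.30) and start at
FiO2 0.40; moderate ~ U(0.05, 0.15) starting at FiO2 0.30. With the
defaults above the severe stratum's baseline PaO2/FiO2 spans ≈ 140–190
mm Hg (median ≈ 160, matching the intended severe group), while the
moderate stratum lands at ≈ 250–450 mm Hg — higher than the ≈ 239 a real
moderately hypoxemic cohort shows, because a single-shunt lung without V/Q
heterogeneity is too healthy at low shunt. The two strata still fall
cleanly on either side of the 200 mm Hg profile-selection threshold, which
is what the matched-profile logic needs. Patients were never assigned
shunt fractions in the clinical data this emulates; the strata are a
modeling stand-in, and the moderate-side PF mismatch is a known limitation.

## Sensor model

1-Hz sampling; the instrument averages the true saturation over a trailing
2-s window, adds Gaussian reading noise (default SD 0.5% SpO2), and rounds
half-up to whole percent, matching clinical displays and making the 92–96%
band well defined. Two Poisson event processes disturb the stream: complete
dropouts (no signal; default 0.5/h × 30 s) and low-SIQ episodes (SIQ drawn
below 0.30 and the displayed value unreliable; same default rate). The
defaults yield no-signal and low-SIQ fractions under ~0.5% of recorded
time, the order seen on well-monitored patients. Not modeled: motion
artifact waveforms, SpO2-vs-SaO2 calibration bias, probe-site differences.

## Controller

Decision tick and lockout are both 30 s; rescue (SpO2 < 85% → 100% FiO2)
is evaluated on every 1-Hz sample and bypasses the lockout. Signal
fall-back freezes FiO2 while the signal is absent or SIQ < 0.30 (strict,
matching the device's wording). Both the rescue and SIQ thresholds are
strict less-than comparisons.

The step tables (README) satisfy the constraints the device's description
fixes — zero step inside the band, monotone step magnitude, up-steps larger
than down-steps, severe-profile steps at least as large as moderate ones in
every bin — but the device's exact tables are unpublished, so the defaults
here are this package's own and are config-overridable. Bin edges sit at
half-integers in effect (deviations are integers), with the dead band
inclusive at ±2: SpO2 92 and 96 are in range, so the controller does not
titrate inside the band.

The PID internals are likewise unpublished and are this package's design:

* P term = the table step itself;
* I term: gain 0.002 FiO2-fraction per %·tick, accumulated only when a step
  is actually taken, clamped to ±0.05 (one maximal down-step — a standard
  anti-windup heuristic), and reset on re-entering the band. This gives
  sustained errors a gentle acceleration without hunting inside the band;
* D term: zero by default — the 30-s tick over a 2-s-averaged signal is
  already heavily filtered;
* dampening: the whole correction is multiplied by
  `max(0, 1 − |FiO2_set − FiO2_eff|/0.2)`, where `FiO2_eff` is a first-order
  estimate (tau 60 s) of what has reached the alveoli. While a previous
  change is still washing in, further corrections shrink; immediately after
  a rescue jump the factor reaches zero and recovery down-titration starts
  slowly. This is the intended behavior, not a bug: it trades a longer
  hyperoxemic tail for the absence of overshoot cycles.

Proposals are quantized to 0.01 FiO2 (ventilator setting granularity) and
clamped to [0.21, 1.0]. Rescue exits through normal table steps once
SpO2 ≥ 85; there is no special weaning rule. Profile selection uses the
classic 200 mm Hg PaO2/FiO2 threshold; exactly 200 takes the gentler MH
profile, since either choice is safe and MH is the conservative one.

In a noiseless static loop the controller reaches the band from any
admissible start within 15 min and never leaves it, with zero FiO2
direction reversals after settling (regression-tested).

## Scenario harness

Episodes run at 1 Hz: patient stepped with the applied FiO2 → sensor sample
→ policy decision → next second. Suctioning (default 2 per 3-h period)
forces FiO2 = 1.0 for 180 s (preoxygenation + suction), after which the
policy resumes and down-titrates; the evaluation masks 15 min from each
suction onset, so the forced-oxygen spike and its recovery are excluded
from profile comparisons. Desaturation events are transient shunt-fraction
increases (+0.10 to +0.25 for 2–10 min, Poisson ~1/h), emulating secretion
plugging or derecruitment. Everything derives from a seed; the same seed
regenerates an episode bit for bit.

The usual-care baseline is an explicit caricature of manual titration —
30-min checks, +0.10 on a low-SpO2 alarm sustained 30 s (with a 5-min
refractory period), −0.05 only at checks when SpO2 ≥ 98% — consistent with
care driven by a prescribed low alarm and no upper constraint. It is not
fitted to any recorded nurse behavior and outputs label it as such.

## Evaluation

Time-in-range percentages are *time*-weighted: each sample holds until the
next (the final sample holds one median inter-sample gap), so 1-Hz
controller traces and historical logs recorded every 1–2 min are treated
consistently. Bands on integer SpO2: hypoxemia ≤ 91, normoxemia 92–96,
hyperoxemia ≥ 97; non-integer inputs are rounded first. No-signal and
low-SIQ (≤ 0.3) time are reported as separate categories, excluded from the
three oxygenation bands; the five categories partition 100% of recorded
time exactly (asserted to 1e-9). Masked intervals (suction, aberrant,
custom) leave numerator and denominator alike. Audit mode additionally
drops aberrant readings (SpO2 < 80%, strict) — a monitor-artifact filter
for usual-care logs only, never for controller traces, where genuine
desaturations must count. Group comparisons delegate to scipy.stats
(Wilcoxon signed-rank for paired profile comparisons, Mann–Whitney U for
unpaired baselines, two-sample t for study-vs-historical); identical paired
groups are reported as statistic 0, p = 1 by convention.

## What passing tests do and do not show

The simulator reproduces the *mechanisms* the controller must handle —
shunt-blunted FiO2 response, measurement lag and quantization, signal
dropouts, suction spikes — not any real cohort's disturbance burden. Under
the default disturbance schedule the 20-patient crossover cohort holds the
band ≈ 83–88% of recorded time (seeded; the acceptance script prints the
exact value). The decomposition is: ≈ 6% hypoxemia during shunt events too
large for 100% oxygen to compensate, ≈ 6% post-event hyperoxemia while the
dampened tables titrate back down, ≈ 4% residual hyperoxemia from low-shunt
moderate patients pinned at the 0.21 FiO2 floor. A real trial population
with a milder event burden sits well above 95%; closing that gap here would
mean quieting the synthetic disturbances, not improving the controller.
Outside disturbance windows the controller holds the band > 99% of time.

## Problem sizes

Defaults: 3-h periods at 1 Hz (10 800 samples), 10 + 10 patients, two
periods each — 40 episodes per crossover, a few seconds of CPU per cohort.
The full test suite plus the acceptance script complete in well under a
minute on one core.

## Known limitations

* One shunt compartment: no V/Q heterogeneity, CO2 kinetics, hemodynamics
  or PEEP-recruitment effects; low-shunt patients are healthier than
  PF-matched real patients (see strata note above).
* The device's true step tables and PID constants are unpublished; the
  defaults here satisfy every stated constraint but are not claimed
  faithful.
* The usual-care policy is a labeled caricature.
* Alarm escalation and clinician notification are out of scope, as is any
  hardware/serial interfacing.
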