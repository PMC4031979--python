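# oxyloop

Automated SpO2-targeted FiO2 titration for mechanically ventilated adults,
simulated end to end: the controller, a shunt-based virtual patient, a
pulse-oximeter model, time-in-range outcome metrics, and a crossover-trial
harness. Everything runs at desk scale from a seed — no patient data, no
hardware.

## Who this is for

Researchers and engineers working on physiological closed-loop control who
need to exercise an oxygen-titration algorithm against reproducible virtual
patients: tune step tables, inject desaturations and suctioning, and score
the outcome with the clinical time-in-range metrics used in ICU studies.

## The algorithm

The controller keeps the displayed SpO2 inside a target band of 92–96% by
steering toward the band midpoint (94%). Every 30 s it computes the
deviation ΔSpO2 = SpO2 − 94 and proposes a step change ΔFiO2 taken from one
of two tables:

| ΔSpO2 bin      | ≤ −9 | −8..−7 | −6..−4 | −3 | −2..+2 | +3 | ≥ +4 |
|----------------|------|--------|--------|-----|--------|-----|------|
| **SH** (severe)   | +0.30 | +0.20 | +0.10 | +0.05 | 0 | −0.03 | −0.05 |
| **MH** (moderate) | +0.15 | +0.10 | +0.05 | +0.02 | 0 | −0.02 | −0.04 |

The SH table is for severely hypoxemic patients (PaO2/FiO2 < 200 mm Hg),
whose intrapulmonary shunt blunts the SaO2 response to FiO2 — they need
larger steps. Safety rules, in priority order:

1. **Rescue** — SpO2 < 85% on a valid sample ⇒ propose 100% FiO2
   immediately, bypassing the lockout;
2. **Signal-quality fall-back** — no signal or SIQ < 0.30 ⇒ keep the last
   FiO2;
3. **Lockout** — at least 30 s between consecutive non-rescue changes;
4. otherwise a dampened PID correction: P = the table step, a small clamped
   I term, and the whole correction scaled by how far the estimated
   effective (alveolar) FiO2 still lags the set value, which suppresses
   oscillation despite the physiological and technical delays.

The virtual patient composes the alveolar gas equation
`PAO2 = FiO2·(Pb − 47) − PaCO2/R`, the Severinghaus dissociation curve
`S = 1/(1 + 23400/(P³ + 150P))`, and the Berggren shunt balance
`CaO2 = Cc′O2 − s·avDO2/(1 − s)`, with a 45-s alveolar wash-in and a 15-s
lung-to-probe transport delay. See `docs/methods.md` for assumptions and
limitations.

## Worked example

```bash
oxyloop simulate-episode --seed 7 --out demo --stratum severe --profile SH --duration-h 3
```

prints

```
patient: severe (shunt 0.24, baseline PF 164 mm Hg) | policy: controller | profile: SH
                                                     episode
Time with no signal (%)                                  0.3
Time with SIQ <= 0.3 (%)                                 0.7
Time with hypoxemia (SpO2 <= 91%) (%)                    5.0
Time with normoxemia (SpO2 92% to 96%) (%)              87.6
Time with hyperoxemia (SpO2 >= 97%) (%)                  6.4
Recorded time (s)                                       9000
```

One 3-h closed-loop episode of a severely hypoxemic virtual patient
(baseline PaO2/FiO2 164 mm Hg): the controller held SpO2 in the 92–96% band
for 87.6% of the recorded 9000 s (the 15-min windows around the two
suctioning episodes are excluded, hence 9000 s rather than 10800 s). The
hypoxemic 5% is dominated by two transient desaturation events during which
the simulated shunt is briefly too large for any FiO2 to compensate; the
hyperoxemic 6.4% is mostly the down-titration tail after those events.
The log (`demo/episode.samples.csv`) holds the five 1-Hz signals — SpO2,
FiO2 set, FiO2 proposed, heart rate, perfusion index — with quality
annotations and an event table.

Other entry points:

```bash
oxyloop run-crossover --seed 1 --out results/     # two-profile crossover, 20 patients
oxyloop run-comparison --seed 1 --out results/    # controller vs usual-care caricature
oxyloop summarize demo/ --audit                   # audit mode: drops aberrant SpO2 <80%
```

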