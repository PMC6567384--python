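# poachmort

Poaching is a cryptic mortality source: the evidence is rarely observed
directly, carcasses are found haphazardly, and even a recovered carcass may
not yield a cause of death.  `poachmort` estimates **age- and sex-specific
annual mortality split into poaching and other causes** from
capture–mark–recapture data on animals carrying multiple mark types — the
setting of long-term red deer monitoring in an Alpine protected area,
where 141 deer carried ear tags, optical collars or GPS collars and were
followed by spring resightings and opportunistic dead recoveries.

It is written for quantitative ecologists and wildlife managers who have
individual-based monitoring data and need defensible cause-specific
mortality estimates in the presence of tag loss, mark-dependent detection
and cause-of-death uncertainty.

## The model

Encounter histories (one event code 0–10 per animal and year) are modelled
as a 9-state / 11-event hidden Markov (multievent) process.  Latent states
track mark status (working GPS / inactive GPS / optical collar / ear
tags), alive vs newly dead by cause (poached vs other), and an absorbing
dead state.  One annual transition is

> mark kernel (GPS signal loss λ_d, collar drop-off D) → survival
> (φ_a = 1 − m_a,poach − m_a,other by age class a),

and emissions cover certain GPS detection, mark-dependent resighting
p_t,mark, incomplete dead recovery r, and cause determination δ — so
unknown-cause recoveries are redistributed between poaching and other
causes by the likelihood itself.  Everything is fitted by maximum
likelihood (scaled forward algorithm, multinomial-logit links); candidate
mortality structures (interactive / additive / constant poaching over an
age partition) are compared by AICc with Akaike weights and combined by
model averaging with unconditional SEs.  A U-CARE-style
Cormack–Jolly–Seber goodness-of-fit suite (TEST3.SR/SM, TEST2.CT/CL) runs
on the live detections, and a full generative simulator provides
ground-truth datasets for calibration.  Details: `docs/methods.md`.

## Worked example

The published encounter-history file is not redistributable, so the
bundled analysis runs on a surrogate drawn from the generative process at
the study's own design (11 occasions, 56 males / 85 females, the study's
mark split) with the published averaged estimates as generating values:

```bash
python analysis/01_simulate_surrogate.py
python analysis/02_gof.py
```

prints

```
wrote 141 histories (56 M / 85 F), 36 recoveries (13 poached / 17 other / 6 unknown) -> results
pooled: chi2 = 3.85, df = 3, p = 0.28
time-dependent CJS description of the live detections: adequate
```

— the census of the simulated marking study, and the pooled CJS
goodness-of-fit statistic on the live-only detections (p > 0.05: the
time-dependent model describes the resighting data, so the multievent
analysis can proceed).  `analysis/03_model_selection.py` then runs the
sequential AICc ladder (age partition → recovery → resighting → the three
mortality hypotheses) and `analysis/04_averaged_estimates.py` refits the
hypothesis models on a 2000-per-sex surrogate, where the model-averaged
estimates land on the generating values, e.g. (truth in the presets:
male 8+ poaching mortality 0.255, male 4–7 survival 0.902):

```
=== M: averaged estimates (truth = generating preset) ===
           name level  estimate    se    lo    hi
       survival   1-3     0.746 0.012 0.721 0.769
poach_mortality   1-3     0.135 0.011 0.116 0.158
       survival   4-7     0.908 0.008 0.892 0.922
poach_mortality   4-7     0.055 0.007 0.042 0.071
       survival    8+     0.516 0.016 0.484 0.547
poach_mortality    8+     0.261 0.016 0.231 0.293
relative poaching share: 1-3: 53%, 4-7: 60%, 8+: 54%
```

Each row is the annual probability for one age class with its
unconditional SE and logit-Wald 95% interval; the relative share is
m_poach / (m_poach + m_other), the fraction of total mortality caused by
poaching.  Old males lose ~26% of their number to poaching each year,
females 3–4% at every age — the strongly male-biased pattern the model is
designed to expose.

`analysis/05_parameter_recovery.py` reports bias and 95% CI coverage of
every mortality probability over replicate simulate-and-refit runs.

In code, the same pipeline is three calls:

```python
import poachmort as pm

params = {s: pm.study_preset(s)[0] for s in "MF"}
data = pm.simulate_histories(pm.default_design(), params, seed=1)
bundle = pm.run_full_analysis(data.histories)
print(bundle.per_sex["M"].model_table)      # AICc table with Akaike weights
print(bundle.per_sex["M"].averaged)         # model-averaged estimates + CIs
```

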