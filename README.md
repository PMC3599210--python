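# tkburden

Toxicokinetic (TK) model fitting and dietary body-burden simulation for
mammalian pesticide risk assessment.

Acute risk to wild mammals is conventionally judged against an oral LD₅₀
measured by gavage — the whole dose forced in at once. A free-living animal
instead eats contaminated food over minutes to hours, and for rapidly
cleared compounds such as the neonicotinoid thiamethoxam the *peak internal
dose* that drives acute effects depends strongly on that feeding pattern.
`tkburden` provides the pieces needed to make that refinement from a
standard rat ADME (absorption, distribution, metabolism, excretion) study:

- **One-compartment kinetics** (`tkburden.model`): monoexponential i.v.
  decay `C(t) = (dose/V)·e^(−kₑt)` and the oral Bateman curve
  `C(t) = (dose/(V/F))·k_a/(k_a−k_e)·(e^(−k_e t) − e^(−k_a t))`, with
  half-lives, t_max, C_max and compartmental AUC.
- **Per-individual fitting** (`tkburden.fit`): Levenberg–Marquardt weighted
  nonlinear least squares with 1/C_obs weighting, asymptotic 95 % confidence
  intervals, AIC model ranking against a two-compartment comparator, and
  relative bioavailability `F = (AUC_po/dose_po)/(AUC_iv/dose_iv)`.
- **Body-burden simulation** (`tkburden.burden`): a discrete-time (1-min
  forward Euler) two-pool model,
  `ΔD_gut = I − k_a·D_gut·F`, `ΔD_int = k_a·D_gut·F − k_e·D_int`,
  driven by arbitrary feeding bouts, with an exact continuous-time solution
  as built-in oracle. The risk metric is max D_int, the peak
  body-weight-normalised internal dose (mg a.i. kg⁻¹ bw).
- **Synthetic study generation** (`tkburden.synth`): the underlying rat ADME
  study is unpublished, so a seeded generator emulates its design (3 M + 3 F
  per group, i.v. 0.5 and oral 0.5/100 mg kg⁻¹ bw, 9 samples over 48 h,
  proportional noise, LOQ censoring) from the published group summary
  statistics.

## Worked example

```python
from tkburden import PRESET_NAMES, preset_scenario, simulate

for name in PRESET_NAMES:
    trace = simulate(preset_scenario(name))
    print(name, round(trace.max_d_int, 1), "mg/kg at", trace.t_of_max_min, "min")
```

prints

```
bolus 1188.8 mg/kg at 67.0 min
2h 1097.3 mg/kg at 148.0 min
4h 933.9 mg/kg at 254.0 min
split 771.4 mg/kg at 395.0 min
```

All four runs deliver the same total dose — the rat oral LD₅₀ of
thiamethoxam, 1563 mg kg⁻¹ bw — under worst-case kinetics (k_a = 2.2 h⁻¹,
k_e = 0.25 h⁻¹, complete absorption). Eaten as a 1-minute bolus the body
burden peaks at ~1189 mg kg⁻¹ bw; spread over two hours the peak drops to
~1097; over four hours to ~934; and split into two one-hour bouts separated
by a four-hour break it reaches only ~771 (65 % of the bolus peak). The
slower the animal eats, the lower the internal dose — so risk inferred
directly from a bolus LD₅₀ overstates dietary risk.

More narrative scripts live in `examples/`: fitting a full synthetic study,
estimating bioavailability, and sweeping the (k_a, k_e) grid. A thin CLI
(`tkburden synth|fit|summarize|simulate|sweep|reproduce`) wraps the same
functions for shell pipelines; every run writes a manifest recording the
configuration hash, seed and outputs.

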