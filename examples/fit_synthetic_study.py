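"""Generate a synthetic rat ADME study and fit every individual.

The generator emulates the real study design (5 groups of 3 males + 3
females, 9 blood samples over 48 h, 10 % proportional measurement noise,
values below 5 ng/ml censored). Each subject is then fitted with the
one-compartment model under 1/C weighting and the group summary table is
printed: mean, SD, min, max of the rate constants per group.
"""

import pandas as pd

from tkburden import fit_one_compartment, generate_study, summarize_group

series = generate_study(seed=42)
fits = [fit_one_compartment(s) for s in series]

print(f"fitted {len(fits)} subjects; {sum(not f.converged for f in fits)} non-converged")
table = summarize_group(fits)
with pd.option_context("display.width", 160, "display.float_format", "{:.3f}".format):
    print(table[[c for c in table.columns if c[0] in ("k_a", "k_e")]])
print(
    "\nGroup-mean k_a and k_e should sit within ~2 population SDs of the "
    "generating values; k_a is the harder parameter at n = 3 per sex."
)
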