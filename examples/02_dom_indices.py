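"""DOM quality indices and a field-vs-incubation style set comparison.

Computes NOSC, DBE, aromaticity index and van Krevelen classes for two
compound libraries that share part of their inventory, the way a field
sample and its incubation share most — but not all — compounds.
"""

import pandas as pd

from peatdom.metrics import compare_sets, metrics_table, sample_summary
from peatdom.synthetic import HabitatProfile, generate_compound_library

field = generate_compound_library(
    HabitatProfile("bog", mean_oc=0.52, mean_hc=1.20, n_compounds=400, lability_index=0.5), seed=1
)
incubation = generate_compound_library(
    HabitatProfile("bog", mean_oc=0.50, mean_hc=1.28, n_compounds=400, lability_index=0.5), seed=2
) | set(list(field)[:250])  # incubations retain most field compounds

table = pd.concat(
    [metrics_table(field, sample_id="field"),
     metrics_table(incubation, sample_id="incubation")],
    ignore_index=True,
)
for sid in ("field", "incubation"):
    s = sample_summary(table, sid)
    print(f"{sid:11s} n={s.n_formulas:4d}  NOSC={s.mean_nosc:+.3f}  DBE={s.mean_dbe:.2f}"
          f"  AI={s.mean_ai:.3f}  O/C={s.mean_oc:.3f}  H/C={s.mean_hc:.3f}")

overlap = compare_sets(field, incubation)
print(f"compound overlap: {overlap.n_shared} shared; "
      f"{overlap.pct_a_in_b:.1f}% of field compounds also present in the incubation")
print("# lower NOSC in the more reduced library indicates lower remaining")
print("# oxidative energy yield, i.e. more degraded organic matter.")
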