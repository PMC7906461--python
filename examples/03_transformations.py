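"""Mass-difference transformation analysis of a compound library.

All pairwise exact-mass differences within a sample are matched against a
reference database of chemical moieties; counts per moiety indicate which
decomposition steps (decarboxylation, hydrogenation, dehydration, ...) can
connect the observed compounds.
"""

from peatdom.synthetic import HabitatProfile, generate_compound_library
from peatdom.transforms import (
    builtin_moieties,
    match_transforms,
    pairwise_differences,
    top_transforms,
)

library = generate_compound_library(
    HabitatProfile("fen", mean_oc=0.55, mean_hc=1.35, n_compounds=400, lability_index=0.7), seed=3
)
masses = sorted(f.mass for f in library)
counts = match_transforms(
    pairwise_differences(masses), builtin_moieties(), tol_da=0.001, sample_id="fen"
)

print(f"compounds: {len(masses)}  pairs examined: {len(masses) * (len(masses) - 1) // 2}")
print(f"total transform matches: {counts.total}")
print("top five transforms:")
for name, pct in top_transforms(counts, k=5):
    print(f"  {name:28s} {pct:5.2f}%")
print("# each match is a compound pair separated by exactly one moiety mass;")
print("# a compound can participate in many pairs, so totals exceed n_compounds.")
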