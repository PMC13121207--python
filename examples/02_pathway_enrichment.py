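"""Over-representation of a selection against gene sets: InTerm (count of
selected features in the term), RichFactor (fraction of the term covered),
hypergeometric p and BH q."""

import numpy as np

from asorescue import GeneSetCollection, ora

rng = np.random.default_rng(0)
universe = [f"GENE{i:03d}" for i in range(300)]

# an "ECM" term genuinely enriched in the selection, plus random terms
ecm = tuple(universe[:20])
sets = {"ECM_ORGANISATION": ("extracellular matrix organisation", ecm)}
for j in range(9):
    members = tuple(rng.choice(universe, size=25, replace=False))
    sets[f"RANDOM_{j}"] = (f"random pathway {j}", members)

selection = list(universe[:15]) + list(rng.choice(universe[50:], size=15,
                                                  replace=False))
result = ora(selection, GeneSetCollection(sets), universe)
print(result[["term", "in_term", "term_size", "rich_factor", "p", "q"]]
      .head(5).to_string(index=False))

# The ECM term should top the table: 15 of its 20 members are selected
# (RichFactor 0.75) against a 10% background selection rate.
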