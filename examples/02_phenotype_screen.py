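"""Sole-source utilization screening and agreement scoring.

Scores the packaged S. radiopugnans utilization table (the published
in-silico calls against the in-vivo plate results), then runs an actual
FBA-based screen on a synthetic model with 5 planted pathway gaps.
"""

import gsmm
from gsmm.datasets import load_substrate_utilization

# published table: 28 carbon and 6 nitrogen substrates
for role in ("carbon", "nitrogen"):
    records, published = load_substrate_utilization(role=role)
    res = gsmm.compare_predictions(records, published)
    print(f"{role}: {res.n_agree}/{res.n_total} agree -> {res.accuracy}% "
          f"(discordant: {', '.join(res.discordant)})")
# carbon: 23/28 -> 82.1%; nitrogen: 5/6 -> 83.3% (L-Cysteine)

# synthetic screen: 28 substrates, 5 planted in-vivo(+)/model(-) gaps
model, medium, table = gsmm.make_phenotype_fixture(28, 5, seed=1)
res = gsmm.screen_table(model, medium, table)
print(f"planted-gap screen: {res.accuracy}% "
      f"({res.n_agree}/{res.n_total} agree, as planted)")
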