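"""Generate a synthetic sociometric trust survey at study scale.

57 roster members (~75% respond) each name up to seven partners and rate
collaboration intensity plus seven 5-point trust items per partner; two
outside organizations can also be named, giving a 59-node universe.
"""

import numpy as np

from trustnet import GeneratorConfig, dyad_matrix, generate_survey, write_survey

cfg = GeneratorConfig(seed=42)
roster, records, truth = generate_survey(cfg)

n_dyads = sum(len(r.alters) for r in records)
print(f"roster + outside organizations : {len(roster.member_ids)} nodes")
print(f"respondents                    : {len(records)}")
print(f"rated dyads                    : {n_dyads}")
print(f"mean nominations per respondent: {n_dyads / len(records):.2f}")
print(f"mutually nominated dyad pairs  : {len(truth['mutual_dyads']) // 2}")

m = dyad_matrix(records)
share_agree = float((m.iloc[:, :7] >= 0.5).to_numpy().mean())
print(f"share of agree/strongly-agree  : {share_agree:.2f}")

path = write_survey(records, "synthetic_survey.csv")
print(f"wrote {path} — a long-format CSV, one row per (respondent, alter)")
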