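"""Is the observed structure explained by chance or by popularity?

Every measure of one observed trust layer is compared to 95% quantile
envelopes from 1,000 simulations of two null models: random survey
completion and preferential attachment.  An observed value outside an
envelope is inconsistent with that null at the 95% level.
"""

from trustnet import (
    GeneratorConfig,
    NullConfig,
    build_dimension_layer,
    envelope,
    generate_survey,
    node_universe,
)

roster, records, _ = generate_survey(GeneratorConfig(seed=42))
layer = build_dimension_layer(records, 5, universe=node_universe(roster, records))

cfg = NullConfig(iterations=1000, seed=7, n_nodes=layer.n_nodes,
                 n_respondents=len(records))
print(f"layer {layer.label}: {layer.n_nodes} nodes, {layer.n_edges} edges\n")
print(f"{'measure':<15}{'observed':>9} | {'model':<13}{'2.5%':>8}{'97.5%':>8}  verdict")
for model in ("random", "preferential"):
    for e in envelope(layer, model, cfg):
        if e.q_lo is None or e.observed is None:
            continue
        verdict = "OUTSIDE the null" if e.outside else "inside"
        print(f"{e.measure:<15}{e.observed:>9.3f} | {model:<13}"
              f"{e.q_lo:>8.3f}{e.q_hi:>8.3f}  {verdict}")
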