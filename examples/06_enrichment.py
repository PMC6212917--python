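"""Hypergeometric gene-set over-representation with BH FDR.

A toy term map over the simulated genes: one term is loaded with the study
genes and should surface with a small p; a background-sized term should not.
"""

import numpy as np

from macdiv import TermMap, demo_config, enrich, simulate

bundle = simulate(demo_config(seed=1))
background = sorted(bundle.genes.gene_spans)  # all simulated genes
rng = np.random.default_rng(0)

study = set(background[:8])  # pretend these hold outlier nsSNVs
terms = TermMap(
    terms={
        "path:loaded": set(background[:6]) | {background[10]},
        "path:random": set(rng.choice(background, size=12, replace=False)),
        "path:everything": set(background),
    },
    background=set(background),
    names={"path:loaded": "genes we planted the signal in",
           "path:random": "an unrelated set",
           "path:everything": "the whole background"},
)

res = enrich(study, terms, min_k=3, size_range=(5, 500))
print(res.drop(columns="genes").to_string(index=False))
# k of K term genes among n study genes from N background; p is the
# hypergeometric upper tail P(X >= k), q the BH-adjusted value.  The loaded
# term gets a small p; a term equal to the background is uninformative (p=1).
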