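"""Region and codon-level effect annotation with mutation spectra.

Each SNV gets one region category (exonic > splicing > UTR > intronic >
ncRNA > up/downstream > intergenic); exonic SNVs are classified by codon
translation into synonymous / nonsynonymous / stop-gain / stop-loss.
"""

from macdiv import (
    annotate_matrix,
    demo_config,
    merge_samples,
    region_table,
    simulate,
    spectra,
    tabulate_annotation,
)

bundle = simulate(demo_config(seed=1))
m = merge_samples(bundle.per_sample, roster=bundle.config.samples)
ann = annotate_matrix(m, bundle.genes, bundle.genome)

reg, eff = tabulate_annotation(ann)
print("region categories (percent of all SNVs):")
print(reg.to_string(index=False))
print("\nexonic effects (percent of exonic SNVs):")
print(eff.to_string(index=False))

exonic = ann[ann["region"] == "exonic"]
print(f"\nexample notation: {exonic['notation'].iloc[0]}")
# TRANSCRIPT:exonN:c.<ref><CDSpos><alt>:p.<aa><residue><aa>

sp = spectra(m.sites["ref"], m.sites["alt"], ann)
print("\ntop 5 base substitutions:")
print(sp.substitutions.head(5).to_string())
print("\ntop 5 codon changes (exonic):")
print(sp.codon_changes.head(5).to_string())
# C>T / G>A dominate, the transition bias every resequencing survey sees.
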