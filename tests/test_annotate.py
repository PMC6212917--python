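"""Region classification and codon-level effect annotation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from macdiv import (
    HET,
    GeneModelSet,
    ReferenceGenome,
    Transcript,
    annotate_matrix,
    classify_region,
    effect_table,
    exonic_effect,
    merge_samples,
    region_table,
    read_gene_models,
)
from macdiv.annotate import REGIONS
from macdiv.genemodels import revcomp

from conftest import make_matrix

BASES = "ACGT"
ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]


def oracle_effect(ref_codon: str, alt_codon: str) -> str:
    """Independent classification by direct translation of the two codons."""
    a = str(Seq(ref_codon).translate())
    b = str(Seq(alt_codon).translate())
    if a != "*" and b == "*":
        return "stopgain"
    if a == "*" and b != "*":
        return "stoploss"
    return "synonymous" if a == b else "nonsynonymous"


def _codon_transcript(codon: str, strand: str = "+"):
    """A 7-bp toy chromosome holding one complete single-codon CDS."""
    plus = "TT" + codon + "TT"
    if strand == "+":
        genome = ReferenceGenome.from_dict({"c": plus})
    else:
        genome = ReferenceGenome.from_dict({"c": revcomp(plus)})
    t = Transcript("TX", "G", "c", strand, exons=[(0, 7)], cds=[(2, 5)])
    return genome, t


def test_all_576_codon_changes_match_translation_oracle():
    """Every (codon, position, alt) single-base change classifies identically
    to the exhaustive translation lookup."""
    for codon in ALL_CODONS:
        genome, t = _codon_transcript(codon)
        for within in range(3):
            ref = codon[within]
            for alt in BASES.replace(ref, ""):
                ann = exonic_effect("c", 3 + within, ref, alt, t, genome)
                alt_codon = codon[:within] + alt + codon[within + 1:]
                assert ann.effect == oracle_effect(codon, alt_codon), (codon, within, alt)
                assert ann.ref_codon == codon and ann.alt_codon == alt_codon
                assert ann.cds_pos == within + 1 and ann.protein_pos == 1


def test_minus_strand_equals_reverse_complement_construction():
    """A minus-strand transcript on the reverse-complemented chromosome gives
    the same effect as the plus-strand original."""
    rng = np.random.default_rng(2)
    for codon in rng.choice(ALL_CODONS, size=16, replace=False):
        g_plus, t_plus = _codon_transcript(codon, "+")
        g_minus, t_minus = _codon_transcript(codon, "-")
        for within in range(3):
            ref = codon[within]
            for alt in BASES.replace(ref, ""):
                plus = exonic_effect("c", 3 + within, ref, alt, t_plus, g_plus)
                # the same biological change seen from the other strand
                pos_minus = 7 - (3 + within) + 1
                minus = exonic_effect("c", pos_minus, revcomp(ref), revcomp(alt),
                                      t_minus, g_minus)
                assert plus.effect == minus.effect
                assert plus.ref_codon == minus.ref_codon
                assert plus.alt_codon == minus.alt_codon


def test_notation_follows_cds_and_protein_coordinates():
    """A G->A change at c.391 turning codon 131 GTG into ATG reads p.V131M."""
    rng = np.random.default_rng(4)
    internal = []
    while len(internal) < 129:
        c = "".join(rng.choice(list(BASES), size=3))
        if str(Seq(c).translate()) != "*":
            internal.append(c)
    cds = "ATG" + "".join(internal) + "GTG" + "TAA"  # codon 131 = GTG
    genome = ReferenceGenome.from_dict({"c": cds})
    t = Transcript("TX1", "G", "c", "+", exons=[(0, len(cds))], cds=[(0, len(cds))])
    ann = exonic_effect("c", 391, "G", "A", t, genome)
    assert ann.effect == "nonsynonymous"
    assert ann.notation == "TX1:exon1:c.G391A:p.V131M"


def test_incomplete_transcript_yields_unknown_effect():
    genome = ReferenceGenome.from_dict({"c": "ATGAAAA"})
    t = Transcript("TX", "G", "c", "+", exons=[(0, 7)], cds=[(0, 7)])
    assert not t.complete
    ann = exonic_effect("c", 3, "G", "A", t, genome)
    assert ann.effect == "unknown"


def test_most_severe_effect_wins_across_transcripts():
    # overlapping frames: T_A sees TAT->TAA (stopgain), T_B sees ATG->AAG
    genome = ReferenceGenome.from_dict({"c": "TATGAAAAAA"})
    genes = GeneModelSet(transcripts={
        "T_A": Transcript("T_A", "GA", "c", "+", exons=[(0, 3)], cds=[(0, 3)]),
        "T_B": Transcript("T_B", "GB", "c", "+", exons=[(1, 4)], cds=[(1, 4)]),
    })
    m = make_matrix(["S"], [("c", 3, "T", "A", [HET])])
    ann = annotate_matrix(m, genes, genome, flank_bp=0)
    assert ann.at[0, "effect"] == "stopgain"
    assert ann.at[0, "transcript_id"] == "T_A"
    assert "T_B:" in ann.at[0, "notations"]


@pytest.fixture(scope="module")
def models(toy_gff3):
    return read_gene_models(toy_gff3)


class TestClassifyRegion:
    def test_cds_position_is_exonic(self, models):
        assert classify_region("chr1", 1200, models)[0] == "exonic"

    def test_two_bases_into_intron_is_splicing(self, models):
        # T1 first intron spans 0-based [1400, 1800)
        assert classify_region("chr1", 1401, models, splice_bp=2)[0] == "splicing"
        assert classify_region("chr1", 1402, models, splice_bp=2)[0] == "splicing"
        assert classify_region("chr1", 1403, models, splice_bp=2)[0] == "intronic"

    def test_utr_ncRNA_flank_and_intergenic(self, models):
        assert classify_region("chr1", 1050, models)[0] == "utr"
        assert classify_region("chr1", 8100, models)[0] == "ncRNA"
        assert classify_region("chr1", 950, models)[0] == "upstream_downstream"
        assert classify_region("chr1", 4000, models, flank_bp=100)[0] == "intergenic"

    def test_agrees_with_per_base_oracle(self, models):
        """200 random positions against a naive per-base category labeling."""
        flank_bp, splice_bp = 300, 2
        rank = {r: i for i, r in enumerate(REGIONS)}

        def naive(pos0):
            best = "intergenic"
            for t in models.transcripts.values():
                s, e = t.span
                if s <= pos0 < e:
                    if not t.coding:
                        cat = "ncRNA"
                    elif any(cs <= pos0 < ce for cs, ce in t.cds):
                        cat = "exonic"
                    elif any(es <= pos0 < ee for es, ee in t.exons):
                        cat = "utr"
                    else:
                        d = min(min(abs(pos0 - ee), abs(es - 1 - pos0))
                                for (_, ee), (es, _) in zip(t.exons, t.exons[1:])
                                if ee <= pos0 < es)
                        cat = "splicing" if d < splice_bp else "intronic"
                elif s - flank_bp <= pos0 < e + flank_bp:
                    cat = "upstream_downstream"
                else:
                    continue
                if rank[cat] < rank[best]:
                    best = cat
            return best

        rng = np.random.default_rng(8)
        for pos0 in rng.integers(0, 10_000, size=200):
            got = classify_region("chr1", int(pos0) + 1, models,
                                  flank_bp=flank_bp, splice_bp=splice_bp)[0]
            assert got == naive(int(pos0)), pos0


def test_annotation_partitions_and_tables_reconcile(demo_bundle):
    """Every variant gets exactly one region; genic subcategories sum to the
    genic total; exonic effects match the simulator's translation truth."""
    m = merge_samples(demo_bundle.per_sample, roster=demo_bundle.config.samples)
    ann = annotate_matrix(m, demo_bundle.genes, demo_bundle.genome)
    assert ann["region"].isin(REGIONS).all()
    assert (ann["effect"].notna() == (ann["region"] == "exonic")).all()

    reg, eff = region_table(ann["region"].value_counts().to_dict()), None
    counts = {r["category"]: r["count"] for _, r in reg.iterrows()}
    assert counts["total"] == m.n_sites
    assert counts["intergenic"] + counts["genic"] == counts["total"]
    subcats = ["upstream_downstream", "exonic", "splicing", "intronic", "utr", "ncRNA"]
    assert sum(counts[c] for c in subcats) == counts["genic"]

    truth = demo_bundle.truth.set_index(["chrom", "pos"])
    exonic = ann[ann["region"] == "exonic"]
    assert len(exonic) > 50
    for _, row in exonic.iterrows():
        t_eff = truth.loc[(row["chrom"], row["pos"]), "effect"]
        assert row["effect"] == t_eff, (row["chrom"], row["pos"])


def test_effect_table_percentages():
    eff = effect_table({"synonymous": 60, "nonsynonymous": 30,
                        "stopgain": 9, "stoploss": 1})
    assert eff.set_index("effect")["pct_of_exonic"].to_dict() == {
        "synonymous": 60.0, "nonsynonymous": 30.0,
        "stopgain": 9.0, "stoploss": 1.0,
    }
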