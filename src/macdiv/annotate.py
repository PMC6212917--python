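"""Region and codon-level effect annotation of SNVs.

Each variant receives exactly one region category (precedence: exonic >
splicing > UTR > intronic > ncRNA > upstream/downstream > intergenic) and,
when exonic, a coding effect from codon translation with the standard
genetic code: synonymous, nonsynonymous, stopgain (alt codon is a stop, ref
is not) or stoploss (ref codon is a stop, alt is not).  Variants hitting
several transcripts report the most severe effect, keeping every
transcript's notation.

Notation follows the ``TRANSCRIPT:exonN:c.R<pos>A:p.X<res>Y`` convention,
with CDS and protein positions 1-based and bases given on the coding strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .genemodels import GeneModelSet, Transcript, revcomp
from .io import ReferenceGenome
from .variants import GenotypeMatrix

REGIONS = ("exonic", "splicing", "utr", "intronic", "ncRNA",
           "upstream_downstream", "intergenic")
_REGION_RANK = {r: i for i, r in enumerate(REGIONS)}

EFFECTS = ("stoploss", "stopgain", "nonsynonymous", "synonymous", "unknown")
_EFFECT_RANK = {e: i for i, e in enumerate(EFFECTS)}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter residue, stops as '*'
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
CODON_TO_AA.update({c: "*" for c in _STANDARD.stop_codons})

DEFAULT_FLANK_BP = 1000
DEFAULT_SPLICE_BP = 2


def translate_codon(codon: str) -> str:
    return CODON_TO_AA[codon.upper()]


@dataclass(slots=True)
class EffectAnnotation:
    effect: str
    transcript_id: str
    notation: str
    ref_codon: str | None = None
    alt_codon: str | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    cds_pos: int | None = None
    protein_pos: int | None = None


def exonic_effect(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    t: Transcript,
    genome: ReferenceGenome,
) -> EffectAnnotation:
    """Codon-level effect of a CDS variant on one transcript.

    ``pos`` is 1-based genomic.  Incomplete transcripts (CDS length not a
    multiple of 3) yield effect ``unknown`` — the frame cannot be trusted.
    """
    pos0 = pos - 1
    if not t.in_cds(pos0):
        raise ValueError(f"{chrom}:{pos} not in CDS of {t.transcript_id}")
    if not t.complete:
        return EffectAnnotation(
            effect="unknown",
            transcript_id=t.transcript_id,
            notation=f"{t.transcript_id}:incomplete",
        )
    if genome.base(chrom, pos) != ref:
        raise ValueError(
            f"{chrom}:{pos}: reference base mismatch "
            f"(genome {genome.base(chrom, pos)!r}, variant {ref!r})")

    cpos = t.cds_coord(pos0)
    codon_idx = (cpos - 1) // 3  # 0-based codon number
    within = (cpos - 1) % 3
    codon_bases = [t.genomic_coord(codon_idx * 3 + k + 1) for k in range(3)]
    ref_codon = "".join(genome.base(t.chrom, p0 + 1) for p0 in codon_bases)
    if t.strand == "-":
        ref_codon = "".join(revcomp(b) for b in
                            (genome.base(t.chrom, p0 + 1) for p0 in codon_bases))
    # coding-strand ref/alt bases at the variant position
    c_ref = ref if t.strand == "+" else revcomp(ref)
    c_alt = alt if t.strand == "+" else revcomp(alt)
    assert ref_codon[within] == c_ref, (ref_codon, within, c_ref)
    alt_codon = ref_codon[:within] + c_alt + ref_codon[within + 1:]

    aa_ref = translate_codon(ref_codon)
    aa_alt = translate_codon(alt_codon)
    if aa_ref != "*" and aa_alt == "*":
        effect = "stopgain"
    elif aa_ref == "*" and aa_alt != "*":
        effect = "stoploss"
    elif aa_ref == aa_alt:
        effect = "synonymous"
    else:
        effect = "nonsynonymous"

    exon_n = t.exon_number(pos0)
    notation = (f"{t.transcript_id}:exon{exon_n}:c.{c_ref}{cpos}{c_alt}"
                f":p.{aa_ref}{codon_idx + 1}{aa_alt}")
    return EffectAnnotation(
        effect=effect,
        transcript_id=t.transcript_id,
        notation=notation,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        cds_pos=cpos,
        protein_pos=codon_idx + 1,
    )


def _tx_region(t: Transcript, pos0: int, splice_bp: int) -> str | None:
    span_s, span_e = t.span
    if not span_s <= pos0 < span_e:
        return None
    if not t.coding:
        return "ncRNA"
    if t.in_cds(pos0):
        return "exonic"
    if t.in_exon(pos0):
        return "utr"
    # intronic: distance into the intron from the nearest exon boundary
    for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
        if e1 <= pos0 < s2:
            if pos0 - e1 < splice_bp or s2 - 1 - pos0 < splice_bp:
                return "splicing"
            return "intronic"
    return "intronic"


def classify_region(
    chrom: str,
    pos: int,
    genes: GeneModelSet,
    flank_bp: int = DEFAULT_FLANK_BP,
    splice_bp: int = DEFAULT_SPLICE_BP,
) -> tuple[str, list[Transcript]]:
    """Region category of a 1-based position, with the transcripts backing it.

    Returns (region, transcripts-with-that-region); for intergenic and
    upstream/downstream the transcript list is the flank hits (empty for
    intergenic).
    """
    pos0 = pos - 1
    hits = genes.transcripts_near(chrom, pos0, flank=flank_bp)
    best = "intergenic"
    backing: list[Transcript] = []
    for t in hits:
        region = _tx_region(t, pos0, splice_bp)
        if region is None:
            region = "upstream_downstream"
        if _REGION_RANK[region] < _REGION_RANK[best]:
            best, backing = region, [t]
        elif region == best and best != "intergenic":
            backing.append(t)
    return best, backing


def annotate_matrix(
    m: GenotypeMatrix,
    genes: GeneModelSet,
    genome: ReferenceGenome,
    flank_bp: int = DEFAULT_FLANK_BP,
    splice_bp: int = DEFAULT_SPLICE_BP,
) -> pd.DataFrame:
    """Annotate every variant in the matrix.

    Returns a frame aligned with ``m.sites`` (one row per variant) with
    columns: region, effect, transcript_id, notation, notations (all
    transcripts, ';'-joined), gene_id, ref_codon, alt_codon, aa_ref, aa_alt.
    """
    rows = []
    sites = m.sites
    for chrom, pos, ref, alt in zip(
        sites["chrom"], sites["pos"], sites["ref"], sites["alt"]
    ):
        region, backing = classify_region(chrom, int(pos), genes, flank_bp, splice_bp)
        rec = {
            "chrom": chrom, "pos": int(pos), "region": region,
            "effect": None, "transcript_id": None, "notation": None,
            "notations": None, "gene_id": None,
            "ref_codon": None, "alt_codon": None, "aa_ref": None, "aa_alt": None,
        }
        if backing:
            rec["gene_id"] = backing[0].gene_id
        if region == "exonic":
            effects = [
                exonic_effect(chrom, int(pos), ref, alt, t, genome)
                for t in backing if t.in_cds(int(pos) - 1)
            ]
            effects.sort(key=lambda e: (_EFFECT_RANK[e.effect], e.transcript_id))
            top = effects[0]
            rec.update(
                effect=top.effect,
                transcript_id=top.transcript_id,
                notation=top.notation,
                notations=";".join(e.notation for e in effects),
                ref_codon=top.ref_codon,
                alt_codon=top.alt_codon,
                aa_ref=top.aa_ref,
                aa_alt=top.aa_alt,
            )
        rows.append(rec)
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "region", "effect", "transcript_id",
                 "notation", "notations", "gene_id", "ref_codon", "alt_codon",
                 "aa_ref", "aa_alt"],
    )


# ---------------------------------------------------------------------------
# tabulation

_GENIC_ORDER = ("upstream_downstream", "exonic", "splicing", "intronic",
                "utr", "ncRNA")


def region_table(region_counts: Mapping[str, int]) -> pd.DataFrame:
    """Region category counts with percentages (genic = all non-intergenic).

    Mirrors the survey layout: intergenic and genic as percent of total,
    exonic additionally as percent of total; genic subcategories sum to the
    genic total by construction.
    """
    total = sum(region_counts.values())
    intergenic = region_counts.get("intergenic", 0)
    genic = total - intergenic
    rows = [
        {"category": "total", "count": total, "pct_of_total": 100.0 if total else float("nan")},
        {"category": "intergenic", "count": intergenic,
         "pct_of_total": round(100 * intergenic / total, 2) if total else float("nan")},
        {"category": "genic", "count": genic,
         "pct_of_total": round(100 * genic / total, 2) if total else float("nan")},
    ]
    for cat in _GENIC_ORDER:
        n = region_counts.get(cat, 0)
        rows.append({
            "category": cat, "count": n,
            "pct_of_total": round(100 * n / total, 2) if total else float("nan"),
        })
    return pd.DataFrame(rows, columns=["category", "count", "pct_of_total"])


_EFFECT_ORDER = ("synonymous", "nonsynonymous", "stopgain", "stoploss")


def effect_table(effect_counts: Mapping[str, int]) -> pd.DataFrame:
    """Exonic effect counts with percent of the classified exonic total."""
    total = sum(effect_counts.get(e, 0) for e in _EFFECT_ORDER)
    rows = [
        {
            "effect": e,
            "count": effect_counts.get(e, 0),
            "pct_of_exonic": round(100 * effect_counts.get(e, 0) / total, 2)
            if total else float("nan"),
        }
        for e in _EFFECT_ORDER
    ]
    return pd.DataFrame(rows, columns=["effect", "count", "pct_of_exonic"])


def tabulate_annotation(
    records: pd.DataFrame,
    scope_idx: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region and exonic-effect tables for all records or a scoped subset."""
    sub = records if scope_idx is None else records.iloc[scope_idx]
    region_counts = sub["region"].value_counts().to_dict()
    effect_counts = sub["effect"].dropna().value_counts().to_dict()
    return region_table(region_counts), effect_table(effect_counts)
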