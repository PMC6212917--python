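"""Gene models: transcripts with strand-aware exon/CDS structure.

Built from GFF3 via gffutils; intervals are stored 0-based half-open in
genomic order.  CDS reading frame is anchored at the annotated CDS start
(first CDS base in transcript orientation), so codon k covers CDS positions
3k+1..3k+3 (1-based).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import gffutils
from intervaltree import IntervalTree

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: GFF3 feature types treated as non-coding transcripts
NONCODING_TYPES = {"ncRNA", "lnc_RNA", "lncRNA", "rRNA", "tRNA", "snoRNA",
                   "snRNA", "miRNA", "pseudogenic_transcript"}
TRANSCRIPT_TYPES = {"mRNA", "transcript"} | NONCODING_TYPES


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # sorted genomic 0-based half-open
    cds: list[tuple[int, int]]  # sorted genomic 0-based half-open

    def __post_init__(self) -> None:
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        self.cds = sorted((int(s), int(e)) for s, e in self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError(
                    f"{self.transcript_id}: CDS [{cs},{ce}) not inside an exon")

    # -- structure -------------------------------------------------------
    @property
    def coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def complete(self) -> bool:
        """Protein-coding with CDS length divisible by 3."""
        return self.coding and self.cds_len % 3 == 0

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def in_exon(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.exons)

    def in_cds(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.cds)

    def exon_number(self, pos0: int) -> int | None:
        """1-based exon index in transcript orientation containing pos0."""
        for i, (s, e) in enumerate(self.exons):
            if s <= pos0 < e:
                return i + 1 if self.strand == "+" else len(self.exons) - i
        return None

    # -- CDS coordinate mapping -------------------------------------------
    def cds_coord(self, pos0: int) -> int | None:
        """1-based CDS position of a genomic position, or None outside CDS."""
        if self.strand == "+":
            offset = 0
            for s, e in self.cds:
                if s <= pos0 < e:
                    return offset + (pos0 - s) + 1
                offset += e - s
        else:
            offset = 0
            for s, e in reversed(self.cds):
                if s <= pos0 < e:
                    return offset + (e - 1 - pos0) + 1
                offset += e - s
        return None

    def genomic_coord(self, cds_pos1: int) -> int:
        """Genomic 0-based position of a 1-based CDS position."""
        if not 1 <= cds_pos1 <= self.cds_len:
            raise ValueError(f"CDS position {cds_pos1} outside 1..{self.cds_len}")
        remaining = cds_pos1 - 1
        if self.strand == "+":
            for s, e in self.cds:
                if remaining < e - s:
                    return s + remaining
                remaining -= e - s
        else:
            for s, e in reversed(self.cds):
                if remaining < e - s:
                    return e - 1 - remaining
                remaining -= e - s
        raise AssertionError("unreachable")

    def cds_sequence(self, genome) -> str:
        """Coding-strand CDS sequence."""
        parts = [genome.fetch(self.chrom, s, e) for s, e in self.cds]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class GeneModelSet:
    """Indexed transcript collection supporting interval queries."""

    transcripts: dict[str, Transcript]
    _tx_trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _gene_trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    gene_spans: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._tx_trees = {}
        spans: dict[str, list] = {}
        for t in self.transcripts.values():
            s, e = t.span
            self._tx_trees.setdefault(t.chrom, IntervalTree()).addi(s, e, t.transcript_id)
            g = spans.setdefault(t.gene_id, [t.chrom, s, e])
            g[1], g[2] = min(g[1], s), max(g[2], e)
        self.gene_spans = {gid: (c, s, e) for gid, (c, s, e) in spans.items()}
        self._gene_trees = {}
        for gid, (chrom, s, e) in self.gene_spans.items():
            self._gene_trees.setdefault(chrom, IntervalTree()).addi(s, e, gid)

    def transcripts_near(self, chrom: str, pos0: int, flank: int = 0) -> list[Transcript]:
        tree = self._tx_trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(pos0 - flank, pos0 + flank + 1)
        return [self.transcripts[h.data] for h in sorted(hits, key=lambda h: h.data)]

    def genes_overlapping(self, chrom: str, start0: int, end0: int) -> set[str]:
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return set()
        return {h.data for h in tree.overlap(start0, end0)}

    def coding_transcripts(self) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.coding]

    def gene_of(self, transcript_id: str) -> str:
        return self.transcripts[transcript_id].gene_id


def read_gene_models(
    gff3: str | os.PathLike,
    genome=None,
) -> GeneModelSet:
    """Assemble a GeneModelSet from a GFF3 file.

    Transcripts without CDS features are treated as non-coding; coding
    transcripts with CDS length not divisible by 3 are retained and exposed
    through ``Transcript.complete`` as incomplete.  When a genome is given,
    features on chromosomes it does not cover raise an error.
    """
    db = gffutils.create_db(
        str(gff3), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts: dict[str, Transcript] = {}
    for ft in TRANSCRIPT_TYPES:
        for tx in db.features_of_type(ft):
            if genome is not None and tx.seqid not in genome:
                raise ValueError(f"{tx.id}: unknown chromosome {tx.seqid!r}")
            exons = [(f.start - 1, f.end) for f in db.children(tx, featuretype="exon")]
            cds = [(f.start - 1, f.end) for f in db.children(tx, featuretype="CDS")]
            if not exons:  # single-feature transcript: treat span as one exon
                exons = [(tx.start - 1, tx.end)]
            parents = list(db.parents(tx, featuretype="gene"))
            gene_id = parents[0].id if parents else tx.attributes.get("gene_id", [tx.id])[0]
            transcripts[tx.id] = Transcript(
                transcript_id=tx.id,
                gene_id=gene_id,
                chrom=tx.seqid,
                strand=tx.strand if tx.strand in "+-" else "+",
                exons=exons,
                cds=cds,
            )
    return GeneModelSet(transcripts=transcripts)
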