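"""Synthetic multi-species SNV dataset generator with per-variant truth.

Mutations are placed on the branches of a fixed rooted species tree: a
mutation on a branch is carried by every leaf below it, so carrier subsets
mirror clades (infinite-sites by default — every mutation gets its own
site).  Carriers are hom_alt with a per-sample heterozygous downgrade
probability, the alternate allele follows a transition/transversion bias
kappa, an outgroup lineage contributes a carrier-site set for specificity
exclusion, and optional per-sample window hotspots inflate local terminal
mutation rates.  The generator also emits a toy reference genome, gene
models (ATG-initiated, stop-terminated CDS without internal stops), a
duplication-mask BED, and a truth table recording each variant's branch,
intended carriers and genotypes, substitution class and — for CDS variants —
an effect class computed by direct whole-CDS translation, a code path
deliberately separate from the annotation module.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genemodels import GeneModelSet, Transcript, revcomp
from .io import (
    IntervalSet,
    ReferenceGenome,
    write_bed,
    write_fasta,
    write_site_list,
)
from .variants import BASES, HET, HOM_ALT, TRANSITIONS, Variant

_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}
_STOPS = ("TAA", "TAG", "TGA")
_EFFECT_SEVERITY = {"stoploss": 0, "stopgain": 1, "nonsynonymous": 2,
                    "synonymous": 3}


@dataclass(frozen=True)
class Branch:
    """A tree branch: mutations on it are carried by every leaf below."""

    name: str
    leaves: frozenset[str]
    intensity: float  # expected mutation count on this branch

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"branch {self.name}: negative intensity")
        if not self.leaves:
            raise ValueError(f"branch {self.name}: empty leaf set")


@dataclass(frozen=True)
class Hotspot:
    """Locally inflated terminal mutation rate for one sample.

    ``fold`` multiplies the sample's genome-average per-bp rate inside
    [start0, end0) on ``chrom``; the excess (fold - 1) is added as extra
    sample-private mutations.
    """

    sample: str
    chrom: str
    start0: int
    end0: int
    fold: float

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("hotspot fold must be >= 1")


@dataclass
class SimConfig:
    samples: list[str]
    branches: list[Branch]
    outgroup: str = "PP1"
    n_chroms: int = 2
    chrom_length: int = 500_000
    kappa: float = 2.2
    het_prob: float | dict[str, float] = 0.45
    gene_count: int = 30
    mean_cds_len: int = 900  # bp, multiple-of-3 enforced per gene
    hotspots: list[Hotspot] = field(default_factory=list)
    mask_n: int = 2
    mask_len: int = 5000
    allow_collisions: bool = False
    seed: int = 0

    def het_prob_of(self, sample: str) -> float:
        if isinstance(self.het_prob, Mapping):
            return float(self.het_prob.get(sample, 0.0))
        return float(self.het_prob)

    def __post_init__(self) -> None:
        for b in self.branches:
            unknown = b.leaves - set(self.samples) - {self.outgroup}
            if unknown:
                raise ValueError(f"branch {b.name}: unknown leaves {unknown}")
        probs = (self.het_prob.values() if isinstance(self.het_prob, Mapping)
                 else [self.het_prob])
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("het_prob must lie in [0, 1]")


def demo_config(seed: int = 0, scale: float = 1.0) -> SimConfig:
    """An eight-sample, six-species macaque-like study design.

    Topology: the pig-tailed sample (PM1) splits first; a rhesus/cynomolgus
    clade (CR1, (CE1, CE2)) and a sinica-group clade ((SM1, SM2), (TM1,
    AM1)); a baboon-like outgroup (PP1).  Branch intensities are scaled-down
    expected mutation counts chosen so per-sample totals, specific fractions
    and the het% spread qualitatively follow the published macaque survey;
    het probabilities are the observed per-sample heterozygosity levels.
    One 5-fold hotspot for AM1 on chr2 emulates the observed
    Assamese-specific SNV-dense region.
    """
    samples = ["CR1", "CE1", "CE2", "SM1", "SM2", "TM1", "AM1", "PM1"]
    out = "PP1"
    f = lambda leaves: frozenset(leaves)

    def b(name, leaves, mu):
        return Branch(name, f(leaves), mu * scale)

    branches = [
        b("ancestral", samples + [out], 500),
        b("macaca", samples, 1500),
        b("outgroup", [out], 1500),
        b("fascicularis_group", ["CR1", "CE1", "CE2"], 500),
        b("ce_pair", ["CE1", "CE2"], 600),
        b("sinica_group", ["SM1", "SM2", "TM1", "AM1"], 700),
        b("sm_pair", ["SM1", "SM2"], 1200),
        b("tm_am", ["TM1", "AM1"], 800),
        b("t_CR1", ["CR1"], 950),
        b("t_CE1", ["CE1"], 1000),
        b("t_CE2", ["CE2"], 1150),
        b("t_SM1", ["SM1"], 260),
        b("t_SM2", ["SM2"], 280),
        b("t_TM1", ["TM1"], 560),
        b("t_AM1", ["AM1"], 1010),
        b("t_PM1", ["PM1"], 2600),
    ]
    het = {"CR1": 0.63, "CE1": 0.57, "CE2": 0.60, "SM1": 0.29, "SM2": 0.29,
           "TM1": 0.17, "AM1": 0.45, "PM1": 0.45}
    return SimConfig(
        samples=samples,
        branches=branches,
        outgroup=out,
        n_chroms=2,
        chrom_length=500_000,
        kappa=2.2,
        het_prob=het,
        gene_count=30,
        mean_cds_len=900,
        hotspots=[Hotspot("AM1", "chr2", 100_000, 200_000, 5.0)],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# genome and gene models


def _random_genome(rng: np.random.Generator, n_chroms: int,
                   length: int) -> dict[str, list[str]]:
    return {
        f"chr{i + 1}": list(rng.choice(list(BASES), size=length))
        for i in range(n_chroms)
    }


def _random_cds_seq(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random internal non-stop codons + one stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list(BASES), size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def _build_genes(
    rng: np.random.Generator,
    genome: dict[str, list[str]],
    gene_count: int,
    mean_cds_len: int,
) -> tuple[GeneModelSet, str]:
    """Place non-overlapping genes and write their CDS into the genome.

    Returns the gene model set and the corresponding GFF3 text.  Each gene
    has one transcript of 1-3 exons with optional UTRs; the coding-strand
    CDS is ATG...stop with no internal stop codons.
    """
    chroms = list(genome)
    per_chrom = gene_count // len(chroms)
    gff: list[str] = ["##gff-version 3"]
    transcripts: dict[str, Transcript] = {}
    gi = 0
    for ci, chrom in enumerate(chroms):
        L = len(genome[chrom])
        cursor = 2000
        n_here = per_chrom + (1 if ci < gene_count % len(chroms) else 0)
        for _ in range(n_here):
            n_codons = max(10, int(rng.normal(mean_cds_len, mean_cds_len / 4)) // 3)
            cds_len = 3 * n_codons
            u5 = int(rng.integers(0, 150))
            u3 = int(rng.integers(0, 200))
            n_exons = int(rng.integers(1, 4))
            tx_len = u5 + cds_len + u3
            # split transcript length into exons with introns between
            cuts = sorted(rng.choice(np.arange(1, tx_len), size=n_exons - 1,
                                     replace=False)) if n_exons > 1 else []
            exon_lens = np.diff([0, *cuts, tx_len]).astype(int)
            intron_lens = rng.integers(100, 500, size=n_exons - 1)
            start = cursor + int(rng.integers(500, 3000))
            exons: list[tuple[int, int]] = []
            p = start
            for k, el in enumerate(exon_lens):
                exons.append((p, p + int(el)))
                p += int(el)
                if k < n_exons - 1:
                    p += int(intron_lens[k])
            gene_end = p
            if gene_end + 2000 > L:
                break
            cursor = gene_end
            strand = "+" if rng.random() < 0.5 else "-"

            # CDS occupies transcript positions [u5, u5+cds_len) in
            # transcript orientation; map to genomic intervals
            tx_positions: list[int] = []
            for s, e in exons:
                tx_positions.extend(range(s, e))
            if strand == "-":
                tx_positions = tx_positions[::-1]
            cds_genomic = sorted(tx_positions[u5:u5 + cds_len])
            cds_ivs: list[tuple[int, int]] = []
            for p0 in cds_genomic:
                if cds_ivs and p0 == cds_ivs[-1][1]:
                    cds_ivs[-1] = (cds_ivs[-1][0], p0 + 1)
                else:
                    cds_ivs.append((p0, p0 + 1))

            gi += 1
            gid, tid = f"GENE{gi:04d}", f"TX{gi:04d}"
            t = Transcript(transcript_id=tid, gene_id=gid, chrom=chrom,
                           strand=strand, exons=exons, cds=cds_ivs)
            transcripts[tid] = t

            # write a clean CDS into the genome (strand-aware)
            cds_seq = _random_cds_seq(rng, n_codons)
            coding_positions = tx_positions[u5:u5 + cds_len]  # tx orientation
            for base, p0 in zip(cds_seq, coding_positions):
                genome[chrom][p0] = base if strand == "+" else revcomp(base)

            gs, ge = t.span
            gff.append(f"{chrom}\tmacdiv\tgene\t{gs + 1}\t{ge}\t.\t{strand}\t.\tID={gid}")
            gff.append(f"{chrom}\tmacdiv\tmRNA\t{gs + 1}\t{ge}\t.\t{strand}\t.\t"
                       f"ID={tid};Parent={gid}")
            for k, (s, e) in enumerate(t.exons, 1):
                gff.append(f"{chrom}\tmacdiv\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                           f"ID={tid}.exon{k};Parent={tid}")
            for k, (s, e) in enumerate(t.cds, 1):
                gff.append(f"{chrom}\tmacdiv\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t"
                           f"ID={tid}.cds{k};Parent={tid}")
    return GeneModelSet(transcripts=transcripts), "\n".join(gff) + "\n"


# ---------------------------------------------------------------------------
# independent effect oracle (whole-CDS translation)


def effect_by_translation(
    genome: ReferenceGenome,
    t: Transcript,
    pos: int,
    alt: str,
) -> str | None:
    """Effect class by translating the whole CDS before and after mutation.

    Deliberately avoids codon-index arithmetic: the full coding sequence is
    mutated and both proteins compared at the affected residue.  Returns
    None outside the CDS or for incomplete transcripts.
    """
    pos0 = pos - 1
    if not t.complete or not t.in_cds(pos0):
        return None
    cds = t.cds_sequence(genome)
    cpos = t.cds_coord(pos0)
    c_alt = alt if t.strand == "+" else revcomp(alt)
    mutated = cds[:cpos - 1] + c_alt + cds[cpos:]
    prot_ref = str(Seq(cds).translate())
    prot_alt = str(Seq(mutated).translate())
    idx = (cpos - 1) // 3
    a, b = prot_ref[idx], prot_alt[idx]
    if a != "*" and b == "*":
        return "stopgain"
    if a == "*" and b != "*":
        return "stoploss"
    return "synonymous" if a == b else "nonsynonymous"


def _truth_effect(
    genome: ReferenceGenome,
    genes: GeneModelSet,
    chrom: str,
    pos: int,
    alt: str,
) -> tuple[str | None, str | None]:
    """Most severe translation-oracle effect over transcripts at a site."""
    best: tuple[int, str, str] | None = None
    for t in genes.transcripts_near(chrom, pos - 1):
        if t.chrom != chrom:
            continue
        eff = effect_by_translation(genome, t, pos, alt)
        if eff is None:
            continue
        key = (_EFFECT_SEVERITY[eff], t.transcript_id)
        if best is None or key < (best[0], best[2]):
            best = (key[0], eff, t.transcript_id)
    if best is None:
        return None, None
    return best[1], best[2]


# ---------------------------------------------------------------------------
# simulation


@dataclass
class SimBundle:
    """Everything one simulation run produced."""

    config: SimConfig
    genome_seqs: dict[str, str]
    genes: GeneModelSet
    gff3_text: str
    per_sample: dict[str, list[Variant]]
    outgroup_sites: set[tuple[str, int]]
    truth: pd.DataFrame
    mask: IntervalSet

    @property
    def genome(self) -> ReferenceGenome:
        return ReferenceGenome.from_dict(self.genome_seqs)

    @property
    def reference_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome_seqs.items()}

    def write(self, outdir: str | os.PathLike) -> dict[str, Path]:
        """Write FASTA, GFF3, per-sample VCFs, mask BED, outgroup and truth TSVs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["fasta"] = outdir / "reference.fa"
        write_fasta(self.genome_seqs, paths["fasta"])
        paths["gff3"] = outdir / "genes.gff3"
        paths["gff3"].write_text(self.gff3_text)
        paths["mask"] = outdir / "mask.bed"
        write_bed(self.mask, paths["mask"])
        paths["outgroup"] = outdir / "outgroup_sites.tsv"
        write_site_list(self.outgroup_sites, paths["outgroup"])
        paths["truth"] = outdir / "truth.tsv"
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        lengths = self.reference_lengths
        for sample, variants in self.per_sample.items():
            p = outdir / f"{sample}.vcf"
            _write_sample_vcf(variants, sample, lengths, p)
            paths[f"vcf:{sample}"] = p
        return paths


def _write_sample_vcf(variants: Sequence[Variant], sample: str,
                      lengths: Mapping[str, int], path: Path) -> None:
    gt = {HET: "0/1", HOM_ALT: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=macdiv-simulate\n")
        for chrom, length in lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\t"
                     f"GT\t{gt[v.genotype]}\n")


def _draw_alt(rng: np.random.Generator, ref: str, kappa: float) -> str:
    if rng.random() < kappa / (kappa + 1.0):
        return TRANSITIONS[ref]
    tv = _TRANSVERSIONS[ref]
    return tv[int(rng.integers(2))]


def simulate(cfg: SimConfig) -> SimBundle:
    """Run the generator; deterministic for a fixed config and seed."""
    rng = np.random.default_rng(cfg.seed)
    genome_lists = _random_genome(rng, cfg.n_chroms, cfg.chrom_length)
    genes, gff3_text = _build_genes(rng, genome_lists, cfg.gene_count,
                                    cfg.mean_cds_len)
    genome_seqs = {c: "".join(s) for c, s in genome_lists.items()}
    genome = ReferenceGenome.from_dict(genome_seqs)
    chroms = list(genome_seqs)
    L = cfg.chrom_length
    total_len = cfg.n_chroms * L

    # expected per-sample totals, for hotspot excess rates
    sample_rate = {
        s: sum(b.intensity for b in cfg.branches if s in b.leaves) / total_len
        for s in cfg.samples
    }

    # mutation plan: (branch_name, carriers) per mutation
    plan: list[tuple[str, frozenset[str]]] = []
    for b in cfg.branches:
        n = int(rng.poisson(b.intensity))
        plan.extend([(b.name, b.leaves)] * n)
    hotspot_slots: list[tuple[str, Hotspot]] = []
    for h in cfg.hotspots:
        if h.sample not in cfg.samples:
            raise ValueError(f"hotspot sample {h.sample!r} not in roster")
        excess = (h.fold - 1.0) * sample_rate[h.sample] * (h.end0 - h.start0)
        n = int(rng.poisson(excess))
        hotspot_slots.extend([(f"hotspot:{h.sample}", h)] * n)

    n_mut = len(plan)
    n_hot = len(hotspot_slots)
    if n_mut + n_hot > total_len:
        raise ValueError(
            f"{n_mut + n_hot} mutations exceed {total_len} available positions")

    flat = rng.choice(total_len, size=n_mut, replace=cfg.allow_collisions)
    used = set(int(i) for i in flat)

    records: list[dict] = []
    per_sample: dict[str, list[Variant]] = {s: [] for s in cfg.samples}
    outgroup_sites: set[tuple[str, int]] = set()

    def place(flat_idx: int, branch: str, carriers: frozenset[str]) -> None:
        chrom = chroms[flat_idx // L]
        pos = flat_idx % L + 1
        ref = genome.base(chrom, pos)
        alt = _draw_alt(rng, ref, cfg.kappa)
        gts: dict[str, int] = {}
        for s in cfg.samples:
            if s in carriers:
                gts[s] = HET if rng.random() < cfg.het_prob_of(s) else HOM_ALT
                per_sample[s].append(Variant(chrom, pos, ref, alt, gts[s]))
        if cfg.outgroup in carriers:
            outgroup_sites.add((chrom, pos))
        effect, tid = _truth_effect(genome, genes, chrom, pos, alt)
        ingroup = sorted(c for c in carriers if c != cfg.outgroup)
        records.append({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "branch": branch,
            "carriers": ",".join(ingroup),
            "genotypes": ",".join(f"{s}={g}" for s, g in sorted(gts.items())),
            "substitution": f"{ref}>{alt}",
            "is_transition": TRANSITIONS[ref] == alt,
            "in_outgroup": cfg.outgroup in carriers,
            "effect": effect,
            "transcript_id": tid,
        })

    for flat_idx, (branch, carriers) in zip(flat, plan):
        place(int(flat_idx), branch, carriers)

    for branch, h in hotspot_slots:
        ci = chroms.index(h.chrom)
        while True:
            flat_idx = ci * L + int(rng.integers(h.start0, h.end0))
            if cfg.allow_collisions or flat_idx not in used:
                used.add(flat_idx)
                break
        place(flat_idx, branch, frozenset([h.sample]))

    truth = pd.DataFrame(
        records,
        columns=["chrom", "pos", "ref", "alt", "branch", "carriers",
                 "genotypes", "substitution", "is_transition", "in_outgroup",
                 "effect", "transcript_id"],
    ).sort_values(["chrom", "pos"]).reset_index(drop=True)

    # duplication mask: random intervals
    mask_pairs = []
    for _ in range(cfg.mask_n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, L - cfg.mask_len))
        mask_pairs.append((chrom, start, start + cfg.mask_len))
    mask = IntervalSet.from_pairs(mask_pairs) if mask_pairs else IntervalSet()

    return SimBundle(
        config=cfg,
        genome_seqs=genome_seqs,
        genes=genes,
        gff3_text=gff3_text,
        per_sample=per_sample,
        outgroup_sites=outgroup_sites,
        truth=truth,
        mask=mask,
    )


# ---------------------------------------------------------------------------
# targeted fixture planting


def plant_effect_variant(
    genome: ReferenceGenome,
    genes: GeneModelSet,
    effect: str,
    rng: np.random.Generator,
    exclude: set[tuple[str, int]] | None = None,
) -> tuple[Variant, dict]:
    """Plant one CDS variant whose translation-oracle class equals ``effect``.

    Searches random CDS positions and alt alleles of complete transcripts;
    falls back to an exhaustive scan before declaring the class impossible
    on the given models.  ``exclude`` avoids reusing sites.
    """
    if effect not in _EFFECT_SEVERITY:
        raise ValueError(f"unknown effect class {effect!r}")
    exclude = exclude or set()
    txs = [t for t in genes.coding_transcripts() if t.complete]
    if not txs:
        raise ValueError("no complete coding transcripts to plant into")

    def try_site(t: Transcript, cds_pos1: int) -> tuple[Variant, dict] | None:
        pos0 = t.genomic_coord(cds_pos1)
        pos = pos0 + 1
        if (t.chrom, pos) in exclude:
            return None
        ref = genome.base(t.chrom, pos)
        alts = [b for b in BASES if b != ref]
        for alt in (alts[i] for i in rng.permutation(len(alts))):
            if effect_by_translation(genome, t, pos, alt) == effect:
                v = Variant(t.chrom, pos, ref, alt, HOM_ALT)
                return v, {"chrom": t.chrom, "pos": pos, "ref": ref,
                           "alt": alt, "effect": effect,
                           "transcript_id": t.transcript_id}
        return None

    for _ in range(2000):
        t = txs[int(rng.integers(len(txs)))]
        hit = try_site(t, int(rng.integers(1, t.cds_len + 1)))
        if hit is not None:
            return hit
    for t in txs:  # exhaustive fallback
        for cds_pos1 in range(1, t.cds_len + 1):
            hit = try_site(t, cds_pos1)
            if hit is not None:
                return hit
    raise ValueError(f"no CDS site admits effect class {effect!r}")
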