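"""Format I/O: VCF (pysam), BED masks, and indexed reference access.

All on-disk formats keep their native coordinate conventions (VCF/GFF3
1-based closed, BED 0-based half-open); internal interval structures are
0-based half-open throughout, with conversion at this boundary only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from pyfaidx import Fasta

from .variants import (
    BASES,
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    Variant,
    merge_samples,
)

_BASE_SET = frozenset(BASES)


# ---------------------------------------------------------------------------
# intervals


@dataclass
class IntervalSet:
    """Per-chromosome sorted, merged, non-empty 0-based half-open intervals."""

    intervals: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in pairs:
            if start >= end:
                raise ValueError(f"empty or inverted interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts, ends = [], []
            for s, e in ivs:
                if ends and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            merged[chrom] = (np.asarray(starts, dtype=np.int64),
                             np.asarray(ends, dtype=np.int64))
        return cls(merged)

    def contains(self, chrom: str, pos0: int) -> bool:
        iv = self.intervals.get(chrom)
        if iv is None:
            return False
        starts, ends = iv
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        return i >= 0 and pos0 < ends[i]

    def contains_positions(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Vectorized membership for an array of 0-based positions."""
        pos0 = np.asarray(pos0, dtype=np.int64)
        iv = self.intervals.get(chrom)
        if iv is None:
            return np.zeros(pos0.shape, dtype=bool)
        starts, ends = iv
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = idx >= 0
        out = np.zeros(pos0.shape, dtype=bool)
        out[ok] = pos0[ok] < ends[idx[ok]]
        return out

    def total_bp(self) -> int:
        return int(sum((e - s).sum() for s, e in self.intervals.values()))

    def __len__(self) -> int:
        return sum(len(s) for s, _ in self.intervals.values())

    def to_pairs(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self.intervals):
            starts, ends = self.intervals[chrom]
            out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
        return out


def read_bed_mask(path: str | os.PathLike) -> IntervalSet:
    """Read a 3+ column BED into a merged IntervalSet (0-based half-open)."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            pairs.append((chrom, start, end))
    return IntervalSet.from_pairs(pairs)


def write_bed(iset: IntervalSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in iset.to_pairs():
            fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# reference genome


class ReferenceGenome:
    """Uniform 0-based half-open fetch over a FASTA file or in-memory dict."""

    def __init__(self, seqs: Mapping[str, str] | Fasta):
        self._fasta = seqs if isinstance(seqs, Fasta) else None
        self._dict = None if self._fasta is not None else dict(seqs)

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "ReferenceGenome":
        return cls(Fasta(str(path), as_raw=True, sequence_always_upper=True))

    @classmethod
    def from_dict(cls, seqs: Mapping[str, str]) -> "ReferenceGenome":
        return cls({k: v.upper() for k, v in seqs.items()})

    @property
    def lengths(self) -> dict[str, int]:
        if self._dict is not None:
            return {k: len(v) for k, v in self._dict.items()}
        return {name: len(rec) for name, rec in self._fasta.records.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in (self._dict if self._dict is not None else self._fasta.records)

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        start0 = max(start0, 0)
        if self._dict is not None:
            return self._dict[chrom][start0:end0]
        return str(self._fasta[chrom][start0:end0])

    def base(self, chrom: str, pos1: int) -> str:
        """Single reference base at a 1-based position."""
        return self.fetch(chrom, pos1 - 1, pos1)


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF


def _gt_state(gt: tuple) -> int:
    """Map a pysam GT tuple to the four states (any non-ref allele = alt)."""
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return MISSING
    n_alt = sum(1 for a in gt if a != 0)
    if n_alt == 0:
        return HOM_REF
    if n_alt == len(gt):
        return HOM_ALT
    return HET


def read_vcf(path: str | os.PathLike, sample: str) -> list[Variant]:
    """Read single-nucleotide records for one sample from a VCF.

    Only records whose REF and first ALT are single bases are returned;
    records with extra ALT alleles are flagged multi-allelic (kept for the
    filter stage).  Non-SNV records (indels, symbolic alleles) are skipped.
    """
    out: list[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        if sample not in vcf.header.samples:
            raise KeyError(f"sample {sample!r} not in {path} "
                           f"(has {list(vcf.header.samples)})")
        for rec in vcf:
            try:
                alts = rec.alts or ()
                if not alts:
                    continue
                ref, alt = rec.ref.upper(), alts[0].upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in _BASE_SET or alt not in _BASE_SET:
                    continue
                state = _gt_state(rec.samples[sample].get("GT"))
                out.append(
                    Variant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=ref,
                        alt=alt,
                        genotype=state,
                        multiallelic=len(alts) > 1,
                        alt_other=tuple(a.upper() for a in alts[1:]),
                    )
                )
            except Exception as exc:  # noqa: BLE001 - rewrap with position
                raise ValueError(
                    f"malformed record at {path}:{rec.chrom}:{rec.pos}: {exc}"
                ) from exc
    return out


_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
_GT_CODE = {v: k for k, v in _GT_STRING.items()}
_GT_CODE["1/0"] = HET
_GT_CODE["1|0"] = HET
_GT_CODE["0|1"] = HET
_GT_CODE["0|0"] = HOM_REF
_GT_CODE["1|1"] = HOM_ALT


def write_merged_vcf(m: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write the merged matrix as a plain-text multi-sample VCF v4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=macdiv\n")
        for chrom, length in m.reference_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=TRIALLELIC,Number=0,Type=Flag,'
                 'Description="ALT disagrees across merged samples">\n')
        fh.write('##INFO=<ID=MULTIALLELIC,Number=0,Type=Flag,'
                 'Description="A source record had multiple ALT alleles">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(m.samples) + "\n")
        sites = m.sites
        for i in range(m.n_sites):
            info_flags = []
            if sites.at[i, "triallelic"]:
                info_flags.append("TRIALLELIC")
            if sites.at[i, "multiallelic"]:
                info_flags.append("MULTIALLELIC")
            info = ";".join(info_flags) or "."
            gts = "\t".join(_GT_STRING[int(g)] for g in m.genotypes[i])
            fh.write(f"{sites.at[i, 'chrom']}\t{sites.at[i, 'pos']}\t.\t"
                     f"{sites.at[i, 'ref']}\t{sites.at[i, 'alt']}\t.\t.\t"
                     f"{info}\tGT\t{gts}\n")


def read_merged_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a multi-sample VCF (as written by :func:`write_merged_vcf`)."""
    import pandas as pd

    samples: list[str] = []
    lengths: dict[str, int] = {}
    rows = {"chrom": [], "pos": [], "ref": [], "alt": [],
            "triallelic": [], "multiallelic": []}
    gts: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##contig"):
                inner = line.strip()[len("##contig=<"):-1]
                fields = dict(kv.split("=", 1) for kv in inner.split(","))
                lengths[fields["ID"]] = int(fields["length"])
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                continue
            f = line.rstrip("\n").split("\t")
            rows["chrom"].append(f[0])
            rows["pos"].append(int(f[1]))
            rows["ref"].append(f[3])
            rows["alt"].append(f[4].split(",")[0])
            rows["triallelic"].append("TRIALLELIC" in f[7])
            rows["multiallelic"].append("MULTIALLELIC" in f[7])
            gts.append([_GT_CODE[g.split(":")[0]] for g in f[9:]])
    sites = pd.DataFrame(rows)
    sites["pos"] = sites["pos"].astype(np.int64)
    g = np.asarray(gts, dtype=np.int8) if gts else np.zeros((0, len(samples)), np.int8)
    return GenotypeMatrix(samples=samples, sites=sites, genotypes=g,
                          reference_lengths=lengths)


def read_site_list(path: str | os.PathLike) -> set[tuple[str, int]]:
    """Read a two-column (chrom, 1-based pos) TSV into a site-key set.

    Used for precomputed outgroup carrier sites.
    """
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos = line.split("\t")[:2]
            out.add((chrom, int(pos)))
    return out


def write_site_list(sites: Iterable[tuple[str, int]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, pos in sorted(sites):
            fh.write(f"{chrom}\t{pos}\n")
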