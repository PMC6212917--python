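"""Core variant containers.

Single-nucleotide variants are represented per sample (as read from one VCF)
and, after merging, as a :class:`GenotypeMatrix` — the multi-sample table the
rest of the pipeline operates on.  Positions are 1-based on disk (VCF/GFF3)
and 0-based half-open internally; ``pos`` on these objects is the 1-based VCF
coordinate, conversion to internal coordinates happens where intervals are
built.

Genotype states are small ints so the matrix can live in a compact int8
array: ``HOM_REF=0, HET=1, HOM_ALT=2, MISSING=-1``.  Genotypes are unphased;
``0/1`` and ``1/0`` are the same het state.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

GT_NAMES: dict[int, str] = {
    HOM_REF: "hom_ref",
    HET: "het",
    HOM_ALT: "hom_alt",
    MISSING: "missing",
}

BASES = ("A", "C", "G", "T")
_BASE_SET = frozenset(BASES)

#: transition partner of each base (A<->G, C<->T)
TRANSITIONS: dict[str, str] = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(slots=True)
class Variant:
    """One biallelic SNV call for a single sample.

    ``alt`` holds the first ALT allele; records with more than one ALT are
    flagged ``multiallelic`` (with the remaining alleles kept in
    ``alt_other``) and passed through so the filter stage can drop them
    explicitly rather than losing them at read time.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype: int
    multiallelic: bool = False
    alt_other: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.ref not in _BASE_SET or self.alt not in _BASE_SET:
            raise ValueError(
                f"{self.chrom}:{self.pos}: ref/alt must be single upper-case "
                f"bases, got {self.ref!r}/{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref equals alt ({self.ref})")
        if self.genotype not in GT_NAMES:
            raise ValueError(f"unknown genotype code {self.genotype}")

    @property
    def is_transition(self) -> bool:
        return TRANSITIONS[self.ref] == self.alt


def _natural_chrom_key(name: str) -> tuple:
    """Sort chromosomes numerically where possible (chr2 before chr10)."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass
class GenotypeMatrix:
    """Merged, sorted, biallelic multi-sample SNV table.

    ``sites`` is a DataFrame with columns ``chrom, pos, ref, alt, triallelic,
    multiallelic`` (pos 1-based), strictly sorted by (chrom, pos) with no
    duplicate sites; ``genotypes`` is an int8 array of shape
    ``(n_sites, n_samples)`` in the order of ``samples``.
    """

    samples: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray
    reference_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not in roster {self.samples}") from None

    def carrier_matrix(self) -> np.ndarray:
        """Boolean (n_sites, n_samples): genotype is het or hom_alt."""
        return self.genotypes > HOM_REF

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[idx],
            reference_lengths=dict(self.reference_lengths),
        )

    def site_keys(self) -> set[tuple[str, int]]:
        return set(zip(self.sites["chrom"], self.sites["pos"].astype(int)))

    def validate(self) -> None:
        """Check the container invariants; raise ValueError on violation."""
        s = self.sites
        if s.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) in matrix")
        for chrom, grp in s.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"{chrom}: positions not strictly increasing")
            if self.reference_lengths:
                length = self.reference_lengths.get(chrom)
                if length is None:
                    raise ValueError(f"{chrom}: not in reference_lengths")
                if pos.size and pos.max() > length:
                    raise ValueError(f"{chrom}: position beyond chromosome end")


def _check_chrom_naming(per_sample: Mapping[str, Sequence[Variant]]) -> None:
    """Error if samples mix 'chrN' and bare 'N' styles for the same chromosome."""
    seen: dict[str, set[str]] = {}
    for sample, variants in per_sample.items():
        for v in variants:
            stripped = v.chrom[3:] if v.chrom.lower().startswith("chr") else v.chrom
            seen.setdefault(stripped, set()).add(v.chrom)
    offenders = {k: sorted(v) for k, v in seen.items() if len(v) > 1}
    if offenders:
        raise ValueError(f"inconsistent chromosome naming across inputs: {offenders}")


def merge_samples(
    per_sample: Mapping[str, Sequence[Variant]],
    roster: Sequence[str] | None = None,
    reference_lengths: Mapping[str, int] | None = None,
    callable_regions: Mapping[str, "object"] | None = None,
) -> GenotypeMatrix:
    """Merge per-sample SNV calls into one multi-sample matrix.

    The union of sites is taken.  A sample with no record at a site is
    hom_ref if the site is callable for that sample (always, when no
    callable_regions track is supplied for it), else missing.  Sites where
    the first ALT allele disagrees across samples are kept with the
    first-seen alt (roster order) and flagged ``triallelic``; a site where
    any contributing record was multi-allelic is flagged ``multiallelic``.

    Parameters
    ----------
    callable_regions:
        Optional ``{sample: IntervalSet}`` (0-based half-open) of callable
        regions; samples absent from the mapping are callable everywhere.
    """
    if roster is None:
        roster = list(per_sample)
    roster = list(roster)
    missing_samples = [s for s in roster if s not in per_sample]
    if missing_samples:
        raise KeyError(f"roster samples without input: {missing_samples}")
    _check_chrom_naming(per_sample)

    # site key -> [ref, alt, gts dict, triallelic, multiallelic]
    table: dict[tuple[str, int], list] = {}
    for si, sample in enumerate(roster):
        for v in per_sample[sample]:
            key = (v.chrom, v.pos)
            entry = table.get(key)
            if entry is None:
                table[key] = [v.ref, v.alt, {si: v.genotype}, False, v.multiallelic]
            else:
                if v.ref != entry[0]:
                    raise ValueError(
                        f"{v.chrom}:{v.pos}: REF disagrees across samples "
                        f"({entry[0]} vs {v.ref})"
                    )
                if v.alt != entry[1]:
                    entry[3] = True  # triallelic across samples
                entry[2][si] = v.genotype
                entry[4] = entry[4] or v.multiallelic

    if reference_lengths is not None:
        chrom_order = {c: i for i, c in enumerate(reference_lengths)}
        for chrom, pos in table:
            if chrom not in chrom_order:
                raise ValueError(f"chromosome {chrom!r} not in reference_lengths")
            if pos > reference_lengths[chrom]:
                raise ValueError(f"{chrom}:{pos} beyond chromosome length")
        sort_key = lambda kv: (chrom_order[kv[0][0]], kv[0][1])
    else:
        sort_key = lambda kv: (_natural_chrom_key(kv[0][0]), kv[0][1])

    items = sorted(table.items(), key=sort_key)
    n = len(items)
    gts = np.zeros((n, len(roster)), dtype=np.int8)
    rows = {
        "chrom": [], "pos": [], "ref": [], "alt": [],
        "triallelic": [], "multiallelic": [],
    }
    for i, ((chrom, pos), (ref, alt, gtmap, tri, multi)) in enumerate(items):
        rows["chrom"].append(chrom)
        rows["pos"].append(pos)
        rows["ref"].append(ref)
        rows["alt"].append(alt)
        rows["triallelic"].append(tri)
        rows["multiallelic"].append(multi)
        for si in range(len(roster)):
            gt = gtmap.get(si)
            if gt is None:
                regions = None if callable_regions is None else callable_regions.get(roster[si])
                if regions is not None and not regions.contains(chrom, pos - 1):
                    gt = MISSING
                else:
                    gt = HOM_REF
            gts[i, si] = gt

    sites = pd.DataFrame(rows)
    sites["pos"] = sites["pos"].astype(np.int64)
    m = GenotypeMatrix(
        samples=roster,
        sites=sites,
        genotypes=gts,
        reference_lengths=dict(reference_lengths or {}),
    )
    return m
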