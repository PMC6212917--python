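"""Per-sample diversity summaries and mutation spectra.

Reproduces the per-sample accounting of a multi-species SNV survey: total /
homozygous / heterozygous counts, heterozygosity percentage, per-kb SNV
density, transition/transversion ratio, and specific-SNV counts — plus
ranked substitution / codon-change / amino-acid-change spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variants import HET, HOM_ALT, TRANSITIONS, GenotypeMatrix


def _pct(num: int, den: int) -> float:
    """Percentage to 2 decimals; NaN when the denominator is zero."""
    return round(100.0 * num / den, 2) if den else math.nan


@dataclass
class SampleSummary:
    sample: str
    n_snvs: int
    n_hom: int
    n_het: int
    pct_het: float
    snv_density: float  # SNVs per kb of the density denominator
    titv: float
    n_specific: int
    pct_specific: float
    n_specific_het: int

    @classmethod
    def from_counts(
        cls,
        sample: str,
        n_snvs: int,
        n_het: int,
        n_specific: int = 0,
        n_specific_het: int = 0,
        n_ti: int = 0,
        n_tv: int = 0,
        denom_bp: int = 0,
    ) -> "SampleSummary":
        """Build a summary from raw counts (percentages to 2 decimals)."""
        return cls(
            sample=sample,
            n_snvs=n_snvs,
            n_hom=n_snvs - n_het,
            n_het=n_het,
            pct_het=_pct(n_het, n_snvs),
            snv_density=(n_snvs / (denom_bp / 1000.0)) if denom_bp else math.nan,
            titv=(n_ti / n_tv) if n_tv else math.nan,
            n_specific=n_specific,
            pct_specific=_pct(n_specific, n_snvs),
            n_specific_het=n_specific_het,
        )


def titv(ref: Sequence[str], alt: Sequence[str]) -> float:
    """Transition/transversion ratio of a variant set.

    Transitions are A<->G and C<->T; everything else is a transversion.
    Returns 0.0 with no transitions, NaN with no transversions.
    """
    ref = np.asarray(ref)
    alt = np.asarray(alt)
    if ref.size == 0:
        return math.nan
    ti = sum(1 for r, a in zip(ref, alt) if TRANSITIONS[r] == a)
    tv = ref.size - ti
    return ti / tv if tv else math.nan


def ti_tv_counts(ref: Sequence[str], alt: Sequence[str]) -> tuple[int, int]:
    ti = sum(1 for r, a in zip(ref, alt) if TRANSITIONS[r] == a)
    return ti, len(ref) - ti


def sample_summary(
    m: GenotypeMatrix,
    sample: str,
    specific_idx: np.ndarray | None = None,
    denom_bp: int | None = None,
) -> SampleSummary:
    """Summarize one sample over the variants it carries.

    ``denom_bp`` is the density denominator; defaults to the sum of the
    matrix's reference chromosome lengths.
    """
    si = m.sample_index(sample)
    g = m.genotypes[:, si]
    carrier = g > 0
    n_het = int((g == HET).sum())
    n_snvs = int(carrier.sum())
    ref = m.sites["ref"].to_numpy()[carrier]
    alt = m.sites["alt"].to_numpy()[carrier]
    n_ti, n_tv = ti_tv_counts(ref, alt)
    if specific_idx is None:
        n_specific = n_specific_het = 0
    else:
        n_specific = int(len(specific_idx))
        n_specific_het = int((m.genotypes[specific_idx, si] == HET).sum())
    if denom_bp is None:
        denom_bp = sum(m.reference_lengths.values())
    return SampleSummary.from_counts(
        sample=sample,
        n_snvs=n_snvs,
        n_het=n_het,
        n_specific=n_specific,
        n_specific_het=n_specific_het,
        n_ti=n_ti,
        n_tv=n_tv,
        denom_bp=denom_bp or 0,
    )


def summary_table(summaries: Iterable[SampleSummary]) -> pd.DataFrame:
    """Stack summaries into a frame mirroring the survey's per-sample table."""
    return pd.DataFrame(
        [
            {
                "sample": s.sample,
                "n_snvs": s.n_snvs,
                "snvs_per_kb": round(s.snv_density, 2),
                "n_hom": s.n_hom,
                "n_het": s.n_het,
                "pct_het": s.pct_het,
                "titv": round(s.titv, 2) if not math.isnan(s.titv) else math.nan,
                "n_specific": s.n_specific,
                "pct_specific": s.pct_specific,
                "n_specific_het": s.n_specific_het,
            }
            for s in summaries
        ]
    )


@dataclass
class SpectrumTable:
    """Ranked mutation spectra; ties broken lexicographically."""

    substitutions: pd.Series  # "X>Y" over the 12 ordered base changes
    codon_changes: pd.Series  # "CCG>CCA"
    aa_changes_ordered: pd.Series  # "P>L"
    aa_changes_unordered: pd.Series  # "A<->T" (symmetric pooling)


def _ranked(counter: dict[str, int]) -> pd.Series:
    s = pd.Series(counter, dtype=np.int64)
    if s.empty:
        return s
    order = sorted(s.index, key=lambda k: (-s[k], k))
    return s.loc[order]


def spectra(
    ref: Sequence[str],
    alt: Sequence[str],
    annotation: pd.DataFrame | None = None,
) -> SpectrumTable:
    """Mutation spectra of a variant set.

    ``annotation`` (optional) supplies exonic codon context with columns
    ``ref_codon, alt_codon, aa_ref, aa_alt`` for the same variants (rows with
    nulls are ignored), feeding the codon and amino-acid change tables.
    """
    subs: dict[str, int] = {}
    for r, a in zip(ref, alt):
        key = f"{r}>{a}"
        subs[key] = subs.get(key, 0) + 1

    codons: dict[str, int] = {}
    aa_ord: dict[str, int] = {}
    aa_unord: dict[str, int] = {}
    if annotation is not None and len(annotation):
        sub = annotation.dropna(subset=["ref_codon", "alt_codon"])
        for rc, ac, ar, aa in zip(
            sub["ref_codon"], sub["alt_codon"], sub["aa_ref"], sub["aa_alt"]
        ):
            k = f"{rc}>{ac}"
            codons[k] = codons.get(k, 0) + 1
            ko = f"{ar}>{aa}"
            aa_ord[ko] = aa_ord.get(ko, 0) + 1
            ku = "<->".join(sorted((ar, aa)))
            aa_unord[ku] = aa_unord.get(ku, 0) + 1

    return SpectrumTable(
        substitutions=_ranked(subs),
        codon_changes=_ranked(codons),
        aa_changes_ordered=_ranked(aa_ord),
        aa_changes_unordered=_ranked(aa_unord),
    )
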