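"""Carrier-set analysis: sharing counts, within-species shared SNVs, and
species/population-specific SNVs with outgroup exclusion.

A sample "carries" a variant when its genotype is het or hom_alt.  Sharing
counts are UpSet-style "distinct" intersections: each variant is counted
under its exact carrier subset.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import HET, HOM_ALT, GenotypeMatrix


def carrier_masks(m: GenotypeMatrix) -> np.ndarray:
    """Per-variant carrier bitmask over the roster (bit i = samples[i])."""
    carriers = m.carrier_matrix()
    weights = (1 << np.arange(len(m.samples), dtype=np.uint64))
    return carriers.astype(np.uint64) @ weights


def mask_to_subset(mask: int, samples: Sequence[str]) -> frozenset[str]:
    return frozenset(s for i, s in enumerate(samples) if mask >> i & 1)


def sharing_counts(m: GenotypeMatrix) -> dict[frozenset[str], int]:
    """UpSet 'distinct' intersection sizes: exact carrier subset -> count.

    Variants with no carrier (possible only before merging guarantees) are
    counted under the empty set so totals always reconcile.
    """
    masks = carrier_masks(m)
    values, counts = np.unique(masks, return_counts=True)
    return {
        mask_to_subset(int(v), m.samples): int(c) for v, c in zip(values, counts)
    }


def sharing_table(m: GenotypeMatrix) -> pd.DataFrame:
    """Sharing counts as a TSV-ready frame (subset column is '+'-joined)."""
    rows = [
        {"subset": "+".join(sorted(sub)), "degree": len(sub), "count": n}
        for sub, n in sharing_counts(m).items()
    ]
    return (pd.DataFrame(rows, columns=["subset", "degree", "count"])
            .sort_values(["count", "subset"], ascending=[False, True])
            .reset_index(drop=True))


def specific_snvs(
    m: GenotypeMatrix,
    unit: Iterable[str],
    outgroup_sites: set[tuple[str, int]] | None = None,
    outgroup_mode: str = "any",
) -> np.ndarray:
    """Indices of variants specific to ``unit`` after outgroup exclusion.

    A variant is specific when its carrier set equals the unit exactly: for a
    single sample every other sample is a non-carrier; for a conspecific pair
    both members carry it and nobody else does.  Sites present in the
    outgroup carrier set are then excluded — either any outgroup-carried site
    (``outgroup_mode='any'``, default) or only sites additionally carried by
    every ingroup sample (``'all'``).
    """
    unit = list(dict.fromkeys(unit))
    if not unit:
        raise ValueError("empty unit")
    bad = [s for s in unit if s not in m.samples]
    if bad:
        raise ValueError(f"unit samples not in roster: {bad}")
    if outgroup_mode not in ("any", "all"):
        raise ValueError(f"unknown outgroup_mode {outgroup_mode!r}")

    carriers = m.carrier_matrix()
    unit_idx = [m.sample_index(s) for s in unit]
    in_unit = np.zeros(len(m.samples), dtype=bool)
    in_unit[unit_idx] = True
    match = carriers[:, in_unit].all(axis=1) & ~carriers[:, ~in_unit].any(axis=1)

    if outgroup_sites:
        keys = list(zip(m.sites["chrom"], m.sites["pos"].astype(int)))
        in_outgroup = np.fromiter(
            (k in outgroup_sites for k in keys), dtype=bool, count=m.n_sites)
        if outgroup_mode == "all":
            in_outgroup &= carriers.all(axis=1)
        match &= ~in_outgroup
    return np.flatnonzero(match)


def shared_within_species(m: GenotypeMatrix, a: str, b: str) -> GenotypeMatrix:
    """Collapse two conspecific samples into one shared pseudo-sample.

    Keeps only sites carried by both; the merged genotype is hom_alt when
    both are hom_alt, else het.  Returns a one-sample matrix named "a+b";
    other samples are dropped (they are analyzed separately).
    """
    if a == b:
        raise ValueError("need two distinct samples")
    ia, ib = m.sample_index(a), m.sample_index(b)
    ga, gb = m.genotypes[:, ia], m.genotypes[:, ib]
    both = (ga > 0) & (gb > 0)
    merged = np.where((ga == HOM_ALT) & (gb == HOM_ALT), HOM_ALT, HET).astype(np.int8)
    sub = m.subset(both)
    return GenotypeMatrix(
        samples=[f"{a}+{b}"],
        sites=sub.sites,
        genotypes=merged[both][:, None],
        reference_lengths=dict(m.reference_lengths),
    )
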