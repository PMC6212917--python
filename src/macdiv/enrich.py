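"""Gene-set over-representation: hypergeometric test with BH FDR.

For a study set of n genes drawn from a background of N, a term with K
annotated genes and k study hits is scored with the upper-tail
hypergeometric probability P(X >= k).  Terms are filtered to a size range
before testing and to a minimum overlap after; surviving p-values get a
Benjamini-Hochberg step-up adjustment.  Raw p at 0.05 is the reported
significance convention (q is emitted alongside for transparency).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_MIN_K = 3
DEFAULT_SIZE_RANGE = (5, 500)


@dataclass
class TermMap:
    """term id -> gene set, with names and a background universe."""

    terms: dict[str, set[str]]
    background: set[str]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, genes in self.terms.items():
            extra = genes - self.background
            if extra:
                raise ValueError(
                    f"term {tid}: {len(extra)} genes outside background "
                    f"(e.g. {sorted(extra)[:3]})")

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        background: Iterable[str],
        names: Mapping[str, str] | None = None,
    ) -> "TermMap":
        """Build from (gene, term) pairs; genes outside background dropped."""
        background = set(background)
        terms: dict[str, set[str]] = {}
        for gene, term in pairs:
            if gene in background:
                terms.setdefault(term, set()).add(gene)
        return cls(terms=terms, background=background, names=dict(names or {}))


def read_term_map(
    gene_term_tsv: str | os.PathLike,
    background: Iterable[str] | None = None,
    term_names_tsv: str | os.PathLike | None = None,
) -> TermMap:
    """Read a 2-column (gene, term) TSV; background defaults to all genes seen."""
    pairs = []
    with open(gene_term_tsv) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            pairs.append((gene, term))
    if background is None:
        background = {g for g, _ in pairs}
    names = {}
    if term_names_tsv is not None:
        with open(term_names_tsv) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                term, name = line.split("\t")[:2]
                names[term] = name
    return TermMap.from_pairs(pairs, background, names)


def read_gmt(path: str | os.PathLike, background: Iterable[str] | None = None) -> TermMap:
    """Read GMT (term <tab> description <tab> gene...)."""
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            terms[fields[0]] = set(fields[2:])
            names[fields[0]] = fields[1]
    if background is None:
        background = set().union(*terms.values()) if terms else set()
    background = set(background)
    terms = {t: g & background for t, g in terms.items()}
    return TermMap(terms=terms, background=background, names=names)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    study: Iterable[str],
    terms: TermMap,
    min_k: int = DEFAULT_MIN_K,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of a study gene set against a term map.

    Returns a frame with columns term, name, k, K, n, N, p, q, significant,
    genes — sorted by (p, term).  Study genes outside the background are
    dropped with a warning; ``significant`` marks raw p < alpha (the q value
    is reported alongside).
    """
    study = set(study)
    outside = study - terms.background
    if outside:
        logger.warning("%d study genes outside background dropped", len(outside))
        study &= terms.background
    n = len(study)
    N = len(terms.background)
    if n == 0:
        logger.warning("empty study set after background intersection")
        return pd.DataFrame(
            columns=["term", "name", "k", "K", "n", "N", "p", "q",
                     "significant", "genes"])

    lo, hi = size_range
    rows = []
    for term in sorted(terms.terms):
        genes = terms.terms[term]
        K = len(genes)
        if not lo <= K <= hi:
            continue
        overlap = study & genes
        k = len(overlap)
        if k < min_k:
            continue
        rows.append({
            "term": term,
            "name": terms.names.get(term, ""),
            "k": k, "K": K, "n": n, "N": N,
            "p": hypergeom_upper_tail(k, N, K, n),
            "genes": ",".join(sorted(overlap)),
        })
    if not rows:
        return pd.DataFrame(
            columns=["term", "name", "k", "K", "n", "N", "p", "q",
                     "significant", "genes"])
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = df["p"] < alpha
    df = df.sort_values(["p", "term"]).reset_index(drop=True)
    return df[["term", "name", "k", "K", "n", "N", "p", "q", "significant", "genes"]]
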