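"""Conservative site filters applied to the merged matrix.

Filters run in a fixed order — missing genotype, triallelic/multi-allelic,
duplication mask, CpG context, proximity — each operating on the sites that
survived the previous stage, and each removed site is charged to the first
filter that failed it.  Running the whole battery twice therefore changes
nothing (idempotence), and enabling an extra filter can only shrink the
survivor set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import IntervalSet, ReferenceGenome
from .variants import MISSING, GenotypeMatrix

FILTER_ORDER = ("missing", "triallelic", "mask", "cpg", "proximity")


@dataclass
class FilterConfig:
    drop_missing: bool = True
    drop_triallelic: bool = True
    drop_cpg: bool = True
    proximity_bp: int = 5  # 0 disables; symmetric removal of both neighbors
    mask: IntervalSet | None = None

    def __post_init__(self) -> None:
        if self.proximity_bp < 0:
            raise ValueError("proximity_bp must be >= 0")


@dataclass
class FilterReport:
    input_sites: int
    output_sites: int
    removed: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.input_sites != self.output_sites + sum(self.removed.values()):
            raise ValueError("filter report does not reconcile")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("filter\tremoved\n")
            for name in FILTER_ORDER:
                fh.write(f"{name}\t{self.removed.get(name, 0)}\n")
            fh.write(f"input\t{self.input_sites}\n")
            fh.write(f"output\t{self.output_sites}\n")


def cpg_context(genome: ReferenceGenome, chrom: str, pos: int) -> bool:
    """True iff the 1-based position sits in a reference CpG dinucleotide.

    That is: the base is C followed by G, or G preceded by C.  Neighbors
    beyond the chromosome ends count as non-matching.
    """
    base = genome.base(chrom, pos)
    if base == "C":
        return genome.fetch(chrom, pos, pos + 1) == "G"
    if base == "G":
        return pos >= 2 and genome.fetch(chrom, pos - 2, pos - 1) == "C"
    return False


def _cpg_flags(genome: ReferenceGenome, chrom: str, pos: np.ndarray,
               ref: np.ndarray) -> np.ndarray:
    """Vectorized CpG context over sorted positions of one chromosome."""
    seq = genome.fetch(chrom, 0, genome.length(chrom))
    arr = np.frombuffer(seq.encode(), dtype="S1")
    p0 = pos - 1
    is_c = ref == "C"
    is_g = ref == "G"
    nxt = np.full(p0.shape, b"", dtype="S1")
    ok = p0 + 1 < len(arr)
    nxt[ok] = arr[(p0 + 1)[ok]]
    prv = np.full(p0.shape, b"", dtype="S1")
    ok = p0 - 1 >= 0
    prv[ok] = arr[(p0 - 1)[ok]]
    return (is_c & (nxt == b"G")) | (is_g & (prv == b"C"))


def _proximity_flags(pos: np.ndarray, proximity_bp: int) -> np.ndarray:
    """Flag sites within proximity_bp of another site (sorted positions)."""
    flags = np.zeros(pos.shape, dtype=bool)
    if pos.size < 2 or proximity_bp <= 0:
        return flags
    gap = np.diff(pos)
    close = gap <= proximity_bp
    flags[:-1] |= close
    flags[1:] |= close
    return flags


def apply_filters(
    m: GenotypeMatrix,
    genome: ReferenceGenome,
    cfg: FilterConfig,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the filter battery; returns the surviving matrix and a report."""
    sites = m.sites
    for chrom, grp in sites.groupby("chrom", sort=False):
        if chrom not in genome:
            raise ValueError(f"chromosome {chrom!r} absent from genome")
        if len(grp) and int(grp["pos"].max()) > genome.length(chrom):
            raise ValueError(f"{chrom}: variant position beyond chromosome end")

    alive = np.ones(m.n_sites, dtype=bool)
    removed: dict[str, int] = {name: 0 for name in FILTER_ORDER}

    def charge(name: str, bad: np.ndarray) -> None:
        bad = bad & alive
        removed[name] += int(bad.sum())
        alive[bad] = False

    if cfg.drop_missing:
        charge("missing", (m.genotypes == MISSING).any(axis=1))
    if cfg.drop_triallelic:
        charge("triallelic",
               sites["triallelic"].to_numpy() | sites["multiallelic"].to_numpy())
    if cfg.mask is not None and len(cfg.mask):
        bad = np.zeros(m.n_sites, dtype=bool)
        for chrom, grp in sites.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            bad[idx] = cfg.mask.contains_positions(
                chrom, grp["pos"].to_numpy() - 1)
        charge("mask", bad)
    if cfg.drop_cpg:
        bad = np.zeros(m.n_sites, dtype=bool)
        for chrom, grp in sites.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            sel = alive[idx]
            if sel.any():
                bad[idx[sel]] = _cpg_flags(
                    genome, chrom,
                    grp["pos"].to_numpy()[sel],
                    grp["ref"].to_numpy()[sel],
                )
        charge("cpg", bad)
    if cfg.proximity_bp > 0:
        bad = np.zeros(m.n_sites, dtype=bool)
        for chrom, grp in sites.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            sel = alive[idx]
            if sel.any():
                bad[idx[sel]] = _proximity_flags(
                    grp["pos"].to_numpy()[sel], cfg.proximity_bp)
        charge("proximity", bad)

    out = m.subset(alive)
    report = FilterReport(
        input_sites=m.n_sites,
        output_sites=out.n_sites,
        removed={k: v for k, v in removed.items() if v},
    )
    report.check()
    return out, report
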