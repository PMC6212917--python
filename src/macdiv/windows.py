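"""Non-overlapping window scans of SNV counts and influence-based outliers.

Counts are binned on a fixed per-chromosome grid (window k covers 1-based
positions k*W+1 .. (k+1)*W; default W = 50 kb).  Outlier windows are flagged
with a Cook's-distance rule: for each sample an ordinary least-squares fit of
its window counts on an intercept plus the leave-one-out mean of the other
samples' counts is computed, and a window is an outlier when its Cook's
distance in any fit exceeds ``multiplier`` times that fit's mean Cook's
distance (default multiplier 30).  The partial terminal window is excluded
from fitting (unequal exposure would fake influence) but kept in bin tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genemodels import GeneModelSet

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 50_000
DEFAULT_MULTIPLIER = 30.0


@dataclass
class WindowMatrix:
    """Per-chromosome (window x sample) variant counts on a fixed grid."""

    chrom: str
    window_size: int
    chrom_length: int
    samples: list[str]
    counts: np.ndarray  # (n_windows, n_samples) int64

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    @property
    def partial_last(self) -> bool:
        return self.chrom_length % self.window_size != 0

    @property
    def n_full(self) -> int:
        return self.chrom_length // self.window_size

    def effective_kb(self) -> np.ndarray:
        """Covered kilobases per window (shorter for the partial last one)."""
        kb = np.full(self.n_windows, self.window_size / 1000.0)
        if self.partial_last and self.n_windows:
            kb[-1] = (self.chrom_length - (self.n_windows - 1) * self.window_size) / 1000.0
        return kb

    def window_bounds(self, k: int) -> tuple[int, int]:
        """0-based half-open genomic bounds of window k."""
        return k * self.window_size, min((k + 1) * self.window_size, self.chrom_length)


def bin_counts(
    positions_by_sample: Mapping[str, Mapping[str, np.ndarray]],
    chrom_lengths: Mapping[str, int],
    window_size: int = DEFAULT_WINDOW_BP,
) -> dict[str, WindowMatrix]:
    """Bin per-sample 1-based positions into fixed windows per chromosome.

    ``positions_by_sample[sample][chrom]`` is an array of 1-based positions.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    samples = list(positions_by_sample)
    out: dict[str, WindowMatrix] = {}
    for chrom, length in chrom_lengths.items():
        n_windows = max(1, -(-length // window_size))
        counts = np.zeros((n_windows, len(samples)), dtype=np.int64)
        for j, sample in enumerate(samples):
            pos = np.asarray(positions_by_sample[sample].get(chrom, ()), dtype=np.int64)
            if pos.size == 0:
                continue
            if pos.min() < 1 or pos.max() > length:
                raise ValueError(f"{chrom}: position outside 1..{length}")
            counts[:, j] = np.bincount((pos - 1) // window_size, minlength=n_windows)
        out[chrom] = WindowMatrix(
            chrom=chrom, window_size=window_size, chrom_length=length,
            samples=samples, counts=counts,
        )
    return out


def density_outliers(
    wm: WindowMatrix,
    rate_per_kb: float,
) -> pd.DataFrame:
    """Windows whose per-kb SNV rate exceeds a threshold, per sample."""
    kb = wm.effective_kb()
    rates = wm.counts / kb[:, None]
    win, samp = np.nonzero(rates > rate_per_kb)
    return pd.DataFrame({
        "chrom": wm.chrom,
        "window": win,
        "sample": [wm.samples[j] for j in samp],
        "count": wm.counts[win, samp],
        "rate_per_kb": rates[win, samp],
    })


# ---------------------------------------------------------------------------
# Cook's distance


def cooks_distances(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Cook's distances of a simple linear regression y ~ 1 + x.

    Hat-matrix form: D_i = e_i^2 / (p * s^2) * h_ii / (1 - h_ii)^2 with
    p = 2 parameters and s^2 the residual mean square.  A perfect or
    degenerate fit (s^2 == 0) returns all zeros.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    X = np.column_stack([np.ones(n), x])
    # least squares via normal equations with pinv (x may be constant)
    XtX = X.T @ X
    beta = np.linalg.pinv(XtX) @ X.T @ y
    fitted = X @ beta
    e = y - fitted
    p = 2
    dof = n - p
    if dof <= 0:
        return np.zeros(n)
    s2 = float(e @ e) / dof
    # degenerate/perfect fit: residual variance at floating-point noise level
    if not np.isfinite(s2) or s2 <= 1e-12 * max(1.0, float(y @ y) / n):
        return np.zeros(n)
    h = np.einsum("ij,jk,ik->i", X, np.linalg.pinv(XtX), X)
    h = np.clip(h, 0.0, 1.0 - 1e-12)
    return (e**2 / (p * s2)) * h / (1.0 - h) ** 2


@dataclass
class OutlierResult:
    """Cook's-distance influence scan of one chromosome's window matrix."""

    chrom: str
    window_size: int
    multiplier: float
    windows: np.ndarray  # indices of the complete windows used in fits
    samples: list[str]
    distances: np.ndarray  # (n_used_windows, n_samples) D per sample fit
    mean_d: np.ndarray  # per-fit mean Cook's distance
    thresholds: np.ndarray  # multiplier * mean_d, per fit
    flags: np.ndarray  # (n_used_windows,) bool: exceeds threshold in any fit
    max_d: np.ndarray  # per-window max D over fits

    def flagged_windows(self) -> np.ndarray:
        return self.windows[self.flags]

    def to_bed(self) -> pd.DataFrame:
        """Flagged windows as BED-like rows with the max-distance score."""
        rows = []
        for i in np.flatnonzero(self.flags):
            k = int(self.windows[i])
            rows.append({
                "chrom": self.chrom,
                "start": k * self.window_size,
                "end": (k + 1) * self.window_size,
                "window": k,
                "max_d": float(self.max_d[i]),
            })
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "window", "max_d"])


def cooks_outliers(
    wm: WindowMatrix,
    multiplier: float = DEFAULT_MULTIPLIER,
) -> OutlierResult | None:
    """Flag windows whose count profile departs from the cross-sample consensus.

    Requires at least 4 complete windows and 2 samples; otherwise the
    chromosome is skipped (returns None) with a logged warning.
    """
    n_samples = len(wm.samples)
    used = np.arange(wm.n_full if wm.partial_last else wm.n_windows)
    if used.size < 4 or n_samples < 2:
        logger.warning(
            "%s: skipped (%d complete windows, %d samples)",
            wm.chrom, used.size, n_samples)
        return None
    counts = wm.counts[used].astype(float)
    D = np.zeros((used.size, n_samples))
    total = counts.sum(axis=1)
    for j in range(n_samples):
        loo_mean = (total - counts[:, j]) / (n_samples - 1)
        D[:, j] = cooks_distances(counts[:, j], loo_mean)
    mean_d = D.mean(axis=0)
    thresholds = multiplier * mean_d
    flags = (D > thresholds[None, :]).any(axis=1)
    return OutlierResult(
        chrom=wm.chrom,
        window_size=wm.window_size,
        multiplier=multiplier,
        windows=used,
        samples=list(wm.samples),
        distances=D,
        mean_d=mean_d,
        thresholds=thresholds,
        flags=flags,
        max_d=D.max(axis=1),
    )


def outlier_genes(
    results: Mapping[str, OutlierResult | None],
    genes: GeneModelSet,
    ns_positions: Mapping[str, Mapping[str, np.ndarray]],
) -> pd.DataFrame:
    """Genes overlapping flagged windows that hold >= 1 nsSNV in any sample.

    ``ns_positions[sample][chrom]`` are 1-based positions of nonsynonymous
    SNVs carried by that sample.  Each gene is reported once, with the
    flagged windows it overlaps.
    """
    # genes harbouring at least one nsSNV anywhere
    genes_with_ns: set[str] = set()
    for per_chrom in ns_positions.values():
        for chrom, pos in per_chrom.items():
            for p in np.asarray(pos, dtype=np.int64):
                genes_with_ns |= genes.genes_overlapping(chrom, p - 1, p)

    hits: dict[str, list[tuple[str, int]]] = {}
    for chrom, res in results.items():
        if res is None:
            continue
        for k in res.flagged_windows():
            s0, e0 = int(k) * res.window_size, (int(k) + 1) * res.window_size
            for gid in genes.genes_overlapping(chrom, s0, e0):
                if gid in genes_with_ns:
                    hits.setdefault(gid, []).append((chrom, int(k)))
    rows = [
        {
            "gene_id": gid,
            "n_windows": len(ws),
            "windows": ";".join(f"{c}:{k}" for c, k in sorted(ws)),
        }
        for gid, ws in sorted(hits.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "n_windows", "windows"])
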