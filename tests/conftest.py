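"""Shared fixtures: handcrafted matrices, toy gene models, one demo simulation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from macdiv import GenotypeMatrix, demo_config, simulate


def make_matrix(samples, rows, reference_lengths=None):
    """Build a GenotypeMatrix from (chrom, pos, ref, alt, genotypes[, triallelic]) rows."""
    recs = {"chrom": [], "pos": [], "ref": [], "alt": [],
            "triallelic": [], "multiallelic": []}
    gts = []
    for row in rows:
        chrom, pos, ref, alt, genotypes = row[:5]
        tri = row[5] if len(row) > 5 else False
        recs["chrom"].append(chrom)
        recs["pos"].append(pos)
        recs["ref"].append(ref)
        recs["alt"].append(alt)
        recs["triallelic"].append(tri)
        recs["multiallelic"].append(False)
        gts.append(list(genotypes))
    sites = pd.DataFrame(recs)
    sites["pos"] = sites["pos"].astype(np.int64)
    g = (np.asarray(gts, dtype=np.int8) if gts
         else np.zeros((0, len(samples)), np.int8))
    return GenotypeMatrix(samples=list(samples), sites=sites, genotypes=g,
                          reference_lengths=dict(reference_lengths or {}))


@pytest.fixture(scope="session")
def demo_bundle():
    """One deterministic run of the eight-sample demo simulation."""
    return simulate(demo_config(seed=7))


@pytest.fixture(scope="session")
def demo_paths(demo_bundle, tmp_path_factory):
    """The demo bundle written to disk (FASTA/GFF3/VCFs/mask/truth)."""
    outdir = tmp_path_factory.mktemp("simdata")
    return demo_bundle.write(outdir)


TOY_GFF3 = """##gff-version 3
chr1\ttoy\tgene\t1001\t2200\t.\t+\t.\tID=G1
chr1\ttoy\tmRNA\t1001\t2200\t.\t+\t.\tID=T1;Parent=G1
chr1\ttoy\texon\t1001\t1400\t.\t+\t.\tID=T1.e1;Parent=T1
chr1\ttoy\texon\t1801\t2200\t.\t+\t.\tID=T1.e2;Parent=T1
chr1\ttoy\tCDS\t1101\t1400\t.\t+\t0\tID=T1.c1;Parent=T1
chr1\ttoy\tCDS\t1801\t2100\t.\t+\t0\tID=T1.c2;Parent=T1
chr1\ttoy\tgene\t5001\t6000\t.\t-\t.\tID=G2
chr1\ttoy\tmRNA\t5001\t6000\t.\t-\t.\tID=T2;Parent=G2
chr1\ttoy\texon\t5001\t6000\t.\t-\t.\tID=T2.e1;Parent=T2
chr1\ttoy\tCDS\t5101\t5700\t.\t-\t0\tID=T2.c1;Parent=T2
chr1\ttoy\tgene\t8001\t8500\t.\t+\t.\tID=G3
chr1\ttoy\tncRNA\t8001\t8500\t.\t+\t.\tID=T3;Parent=G3
chr1\ttoy\texon\t8001\t8500\t.\t+\t.\tID=T3.e1;Parent=T3
"""


@pytest.fixture(scope="session")
def toy_gff3(tmp_path_factory):
    p = tmp_path_factory.mktemp("gff") / "toy.gff3"
    p.write_text(TOY_GFF3)
    return p
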