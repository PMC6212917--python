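"""Site-filter battery: per-filter rules, ordering, and report accounting."""

from __future__ import annotations

import numpy as np
import pytest

from macdiv import (
    FilterConfig,
    HET,
    HOM_REF,
    IntervalSet,
    MISSING,
    ReferenceGenome,
    apply_filters,
    cpg_context,
)

from conftest import make_matrix


def flat_genome(length=10_000, base="A"):
    return ReferenceGenome.from_dict({"chr1": base * length})


class TestCpgContext:
    @pytest.mark.parametrize(
        "seq,pos,expected",
        [
            ("ACGT", 2, True),   # C followed by G
            ("ACGT", 3, True),   # G preceded by C
            ("ATAT", 1, False),
            ("ATAT", 2, False),
            ("CGTT", 1, True),   # chromosome start, C with next G
            ("TTGC", 3, False),  # G preceded by T
            ("AC", 2, False),    # C at chromosome end: no next base
        ],
    )
    def test_reference_context(self, seq, pos, expected):
        g = ReferenceGenome.from_dict({"chr1": seq})
        assert cpg_context(g, "chr1", pos) is expected


def test_missing_genotype_filter_counts():
    m = make_matrix(["A", "B"], [
        ("chr1", 100, "A", "G", [HET, MISSING]),
        ("chr1", 200, "C", "T", [HET, HOM_REF]),
    ])
    out, rep = apply_filters(m, flat_genome(), FilterConfig(proximity_bp=0, drop_cpg=False))
    assert out.n_sites == 1 and rep.removed == {"missing": 1}


def test_cpg_site_removed():
    g = ReferenceGenome.from_dict({"chr1": "AACGAA" + "A" * 100})
    m = make_matrix(["A"], [
        ("chr1", 3, "C", "T", [HET]),   # C of a CpG
        ("chr1", 50, "A", "G", [HET]),
    ])
    out, rep = apply_filters(m, g, FilterConfig(proximity_bp=0))
    assert rep.removed == {"cpg": 1}
    assert out.sites["pos"].tolist() == [50]


def test_proximity_pairs_removed_symmetrically():
    # derived by brute-force pairwise distance: 100-103 and 1000-1004 are
    # within 5 bp, so all four go; 200 and 5000 survive
    positions = [100, 103, 200, 1000, 1004, 5000]
    m = make_matrix(["A"], [("chr1", p, "A", "G", [HET]) for p in positions])
    out, rep = apply_filters(m, flat_genome(), FilterConfig(proximity_bp=5, drop_cpg=False))
    assert out.sites["pos"].tolist() == [200, 5000]
    assert rep.removed == {"proximity": 4}


def test_proximity_matches_brute_force_on_random_sites():
    rng = np.random.default_rng(11)
    for _ in range(20):
        positions = np.unique(rng.integers(1, 2000, size=60))
        m = make_matrix(["A"], [("chr1", int(p), "A", "G", [HET]) for p in positions])
        out, _ = apply_filters(m, flat_genome(3000),
                               FilterConfig(proximity_bp=7, drop_cpg=False))
        keep = [p for p in positions
                if all(q == p or abs(q - p) > 7 for q in positions)]
        assert out.sites["pos"].tolist() == keep


def test_mask_filter_uses_bed_coordinates():
    mask = IntervalSet.from_pairs([("chr1", 99, 100)])  # 0-based: only pos 100
    m = make_matrix(["A"], [
        ("chr1", 99, "A", "G", [HET]),
        ("chr1", 100, "A", "G", [HET]),
        ("chr1", 101, "A", "G", [HET]),
    ])
    out, rep = apply_filters(
        m, flat_genome(), FilterConfig(proximity_bp=0, drop_cpg=False, mask=mask))
    assert out.sites["pos"].tolist() == [99, 101]
    assert rep.removed == {"mask": 1}


def test_triallelic_flag_filter():
    m = make_matrix(["A"], [
        ("chr1", 100, "A", "G", [HET], True),
        ("chr1", 200, "C", "T", [HET]),
    ])
    out, rep = apply_filters(m, flat_genome(), FilterConfig(proximity_bp=0, drop_cpg=False))
    assert rep.removed == {"triallelic": 1} and out.n_sites == 1


def test_position_beyond_genome_end_rejected():
    m = make_matrix(["A"], [("chr1", 500, "A", "G", [HET])])
    with pytest.raises(ValueError, match="beyond"):
        apply_filters(m, flat_genome(100), FilterConfig())


def _random_matrix(rng, n=80):
    positions = np.sort(rng.choice(np.arange(1, 4000), size=n, replace=False))
    bases = np.array(list("ACGT"))
    rows = []
    for p in positions:
        ref, alt = rng.choice(bases, size=2, replace=False)
        gts = rng.choice([HOM_REF, HET, 2, MISSING], size=3, p=[0.3, 0.3, 0.3, 0.1])
        rows.append(("chr1", int(p), str(ref), str(alt), list(gts),
                     bool(rng.random() < 0.05)))
    return make_matrix(["A", "B", "C"], rows)


def random_genome(rng, length=5000):
    return ReferenceGenome.from_dict(
        {"chr1": "".join(rng.choice(list("ACGT"), size=length))})


def test_filters_idempotent_and_report_reconciles():
    rng = np.random.default_rng(5)
    cfg = FilterConfig(proximity_bp=5)
    for _ in range(10):
        m = _random_matrix(rng)
        g = random_genome(rng)
        once, rep = apply_filters(m, g, cfg)
        rep.check()
        assert rep.input_sites == rep.output_sites + sum(rep.removed.values())
        twice, rep2 = apply_filters(once, g, cfg)
        assert twice.n_sites == once.n_sites
        assert sum(rep2.removed.values()) == 0


def test_enabling_filters_only_shrinks_survivors():
    rng = np.random.default_rng(9)
    m = _random_matrix(rng)
    g = random_genome(rng)
    least = FilterConfig(drop_missing=True, drop_triallelic=False,
                         drop_cpg=False, proximity_bp=0)
    n_prev = apply_filters(m, g, least)[0].n_sites
    for cfg in (
        FilterConfig(drop_triallelic=True, drop_cpg=False, proximity_bp=0),
        FilterConfig(drop_triallelic=True, drop_cpg=True, proximity_bp=0),
        FilterConfig(drop_triallelic=True, drop_cpg=True, proximity_bp=5),
    ):
        n = apply_filters(m, g, cfg)[0].n_sites
        assert n <= n_prev
        n_prev = n
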