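"""Carrier-set logic: sharing counts, specific SNVs, within-species sharing."""

from __future__ import annotations

import numpy as np
import pytest

from macdiv import (
    HET,
    HOM_ALT,
    HOM_REF,
    merge_samples,
    sharing_counts,
    shared_within_species,
    specific_snvs,
)

from conftest import make_matrix


class TestSharingCounts:
    def test_exact_subset_counting(self):
        m = make_matrix(["A", "B", "C"], [
            ("chr1", 100, "A", "G", [HET, HOM_REF, HOM_REF]),
            ("chr1", 200, "C", "T", [HOM_ALT, HET, HOM_REF]),
            ("chr1", 300, "G", "A", [HET, HOM_ALT, HOM_REF]),
        ])
        table = sharing_counts(m)
        assert table == {frozenset({"A"}): 1, frozenset({"A", "B"}): 2}

    def test_all_carriers_single_entry(self):
        m = make_matrix(["A", "B"], [
            ("chr1", p, "A", "G", [HET, HOM_ALT]) for p in (10, 20, 30)
        ])
        assert sharing_counts(m) == {frozenset({"A", "B"}): 3}

    def test_counts_sum_to_matrix_size(self, demo_bundle):
        m = merge_samples(demo_bundle.per_sample,
                          roster=demo_bundle.config.samples)
        table = sharing_counts(m)
        assert sum(table.values()) == m.n_sites

    def test_subsets_match_branch_tallies_on_simulation(self, demo_bundle):
        """Infinite-sites clade mutations: every observed subset is a clade
        and its count equals the branch's mutation tally."""
        m = merge_samples(demo_bundle.per_sample,
                          roster=demo_bundle.config.samples)
        table = sharing_counts(m)
        truth = demo_bundle.truth
        ingroup = truth[truth["carriers"] != ""]
        expected = ingroup.groupby("carriers").size()
        assert len(table) == len(expected)
        for carriers, n in expected.items():
            assert table[frozenset(carriers.split(","))] == n


class TestSpecificSnvs:
    def test_single_sample_unit(self):
        m = make_matrix(["PM1", "X"], [
            ("chr1", 100, "A", "G", [HET, HOM_REF]),
            ("chr1", 200, "C", "T", [HET, HET]),
        ])
        idx = specific_snvs(m, ["PM1"])
        assert idx.tolist() == [0]

    def test_outgroup_carried_site_excluded(self):
        m = make_matrix(["SM1", "SM2", "X"], [
            ("chr1", 100, "A", "G", [HET, HOM_ALT, HOM_REF]),
            ("chr1", 200, "C", "T", [HOM_ALT, HET, HOM_REF]),
        ])
        idx = specific_snvs(m, ["SM1", "SM2"], outgroup_sites={("chr1", 100)})
        assert idx.tolist() == [1]

    def test_pair_unit_requires_both_and_only_both(self):
        m = make_matrix(["A", "B", "C"], [
            ("chr1", 100, "A", "G", [HET, HOM_REF, HOM_REF]),
            ("chr1", 200, "C", "T", [HET, HOM_ALT, HOM_REF]),
            ("chr1", 300, "G", "A", [HET, HOM_ALT, HET]),
        ])
        assert specific_snvs(m, ["A", "B"]).tolist() == [1]

    def test_unknown_unit_member_rejected(self):
        m = make_matrix(["A"], [("chr1", 100, "A", "G", [HET])])
        with pytest.raises(ValueError, match="not in roster"):
            specific_snvs(m, ["Z"])

    def test_outgroup_exclusion_only_shrinks(self, demo_bundle):
        m = merge_samples(demo_bundle.per_sample,
                          roster=demo_bundle.config.samples)
        base = set(specific_snvs(m, ["PM1"]).tolist())
        excl = set(specific_snvs(m, ["PM1"],
                                 outgroup_sites=demo_bundle.outgroup_sites).tolist())
        assert excl <= base

    def test_terminal_branch_concordance_on_simulation(self, demo_bundle):
        """Specific sets equal terminal-branch mutations minus outgroup-carried
        sites (zero under infinite sites; checked exactly with an injected
        outgroup-recurrent subset)."""
        m = merge_samples(demo_bundle.per_sample,
                          roster=demo_bundle.config.samples)
        truth = demo_bundle.truth
        keys = list(zip(m.sites["chrom"], m.sites["pos"].astype(int)))
        for sample in ("PM1", "TM1", "CR1"):
            term = truth[truth["carriers"] == sample]
            expect = set(zip(term["chrom"], term["pos"].astype(int)))
            idx = specific_snvs(m, [sample],
                                outgroup_sites=demo_bundle.outgroup_sites)
            assert {keys[i] for i in idx} == expect
            # inject outgroup recurrence: half the terminal sites become
            # outgroup-carried and must drop out, exactly
            recurrent = set(sorted(expect)[: len(expect) // 2])
            idx2 = specific_snvs(
                m, [sample],
                outgroup_sites=demo_bundle.outgroup_sites | recurrent)
            assert {keys[i] for i in idx2} == expect - recurrent


class TestSharedWithinSpecies:
    @pytest.mark.parametrize(
        "ga,gb,shared,merged",
        [
            (HET, HOM_ALT, True, HET),
            (HOM_REF, HOM_ALT, False, None),
            (HOM_ALT, HOM_ALT, True, HOM_ALT),
            (HET, HET, True, HET),
        ],
    )
    def test_genotype_merge_rules(self, ga, gb, shared, merged):
        m = make_matrix(["A", "B"], [("chr1", 100, "A", "G", [ga, gb])])
        out = shared_within_species(m, "A", "B")
        if shared:
            assert out.n_sites == 1 and out.genotypes[0, 0] == merged
        else:
            assert out.n_sites == 0

    def test_identical_samples_rejected(self):
        m = make_matrix(["A", "B"], [("chr1", 100, "A", "G", [HET, HET])])
        with pytest.raises(ValueError):
            shared_within_species(m, "A", "A")
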