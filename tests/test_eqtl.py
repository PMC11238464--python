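"""BH adjustment, interval merging, cis/trans classification, LD, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from egwas.eqtl import (
    CLASS_CIS,
    CLASS_TRANS_I,
    CLASS_TRANS_II,
    CLASS_UNKNOWN,
    EQTLRegion,
    bh_adjust,
    call_eqtl_regions,
    class_qvalue_anova,
    classify_eqtl,
    ld_within_region,
    merge_intervals,
    sample_regions_for_ld,
    top_snp,
)
from conftest import make_genotypes


def bh_stepup_oracle(p):
    """Brute-force BH: q_i = min over j with p_j >= p_i of m * p_j / rank_j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = np.inf
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, m * p[idx] / rank_from_top)
        q[idx] = min(running_min, 1.0)
    return q


def assoc_table(p_values, gene="g1", chrom=None, pos=None):
    m = len(p_values)
    return pd.DataFrame(
        {
            "gene_id": gene,
            "snp_id": [f"s{i}" for i in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "p_value": p_values,
        }
    )


class TestBH:
    def test_hand_worked_example(self):
        out = bh_adjust(assoc_table([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(out["q_value"], [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        out = bh_adjust(assoc_table([1.0, 1.0, 1.0]))
        np.testing.assert_array_equal(out["q_value"], 1.0)
        assert not out["significant"].any()

    def test_single_test_identity(self):
        out = bh_adjust(assoc_table([0.03]))
        assert out["q_value"].iloc[0] == pytest.approx(0.03)

    def test_na_p_values_excluded_from_ranking(self):
        out = bh_adjust(assoc_table([0.01, np.nan, 0.04]))
        assert np.isnan(out["q_value"].iloc[1])
        expected = bh_stepup_oracle(np.array([0.01, 0.04]))
        np.testing.assert_allclose(out["q_value"].iloc[[0, 2]], expected)
        assert not out["significant"].iloc[1]

    @given(
        st.lists(
            st.floats(min_value=1e-12, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=10,
        )
    )
    def test_matches_stepup_oracle_for_small_m(self, p):
        out = bh_adjust(assoc_table(p))
        np.testing.assert_allclose(
            out["q_value"].to_numpy(), bh_stepup_oracle(np.array(p)), rtol=1e-12
        )


def sig_table(positions, gene="g1", chrom="1", q=None):
    m = len(positions)
    return pd.DataFrame(
        {
            "gene_id": gene,
            "snp_id": [f"s{i}" for i in range(m)],
            "chrom": chrom,
            "pos": positions,
            "p_value": np.linspace(1e-8, 1e-6, m),
            "q_value": q if q is not None else np.linspace(1e-6, 1e-4, m),
        }
    )


class TestMergeIntervals:
    def test_hand_worked_gap_example(self):
        # gaps of ~4, 4, 16, 1, 1 Mb against the 10 Mb rule -> two regions
        pos = [1, 5_000_000, 9_000_000, 25_000_000, 26_000_000, 27_000_000]
        regions, discarded = merge_intervals(sig_table(pos))
        assert discarded == 0
        assert [(r.start_bp, r.end_bp, r.n_snps) for r in regions] == [
            (1, 9_000_000, 3),
            (25_000_000, 27_000_000, 3),
        ]

    def test_fewer_than_min_snps_discarded(self):
        regions, discarded = merge_intervals(sig_table([1, 2_000_000]))
        assert regions == [] and discarded == 2

    def test_gap_of_exactly_10mb_splits(self):
        pos = [1, 1000, 2000, 10_002_000, 10_003_000, 10_004_000]
        regions, _ = merge_intervals(sig_table(pos))
        assert len(regions) == 2  # gap 10_000_000 exactly: split

    def test_gap_just_under_10mb_merges(self):
        pos = [1, 1000, 2000, 10_001_999, 10_003_000, 10_004_000]
        regions, _ = merge_intervals(sig_table(pos))
        assert len(regions) == 1 and regions[0].n_snps == 6

    def test_partition_accounting(self):
        pos = [1, 1000, 2000, 50_000_000, 80_000_000, 80_001_000, 80_002_000, 80_003_000]
        regions, discarded = merge_intervals(sig_table(pos))
        assert sum(r.n_snps for r in regions) + discarded == len(pos)

    def test_input_order_invariance(self):
        pos = [1, 5_000_000, 9_000_000, 25_000_000, 26_000_000, 27_000_000]
        tab = sig_table(pos)
        shuffled = tab.sample(frac=1.0, random_state=3)
        a, _ = merge_intervals(tab)
        b, _ = merge_intervals(shuffled)
        assert [(r.start_bp, r.end_bp) for r in a] == [(r.start_bp, r.end_bp) for r in b]

    def test_idempotent_on_own_members(self):
        pos = [1, 5_000_000, 9_000_000, 25_000_000, 26_000_000, 27_000_000]
        regions, _ = merge_intervals(sig_table(pos))
        for r in regions:
            again, disc = merge_intervals(r.member_snps)
            assert disc == 0 and len(again) == 1
            assert (again[0].start_bp, again[0].end_bp) == (r.start_bp, r.end_bp)

    def test_multiple_genes_rejected(self):
        tab = pd.concat([sig_table([1, 2, 3]), sig_table([1, 2, 3], gene="g2")])
        with pytest.raises(ValueError):
            merge_intervals(tab)

    def test_chromosomes_never_merge(self):
        tab = pd.concat(
            [sig_table([1, 1000, 2000]), sig_table([1, 1000, 2000], chrom="2")]
        ).reset_index(drop=True)
        tab["snp_id"] = [f"s{i}" for i in range(len(tab))]
        regions, _ = merge_intervals(tab)
        assert len(regions) == 2
        assert {r.chrom for r in regions} == {"1", "2"}


def region_at(top_pos, chrom="1", gene="g1", n_snps=3, top_q=1e-4, top_p=1e-6):
    members = sig_table(
        [top_pos - 1000, top_pos, top_pos + 1000], gene=gene, chrom=chrom,
        q=[top_q * 10, top_q, top_q * 10],
    )
    return EQTLRegion(
        gene_id=gene, chrom=chrom, start_bp=top_pos - 1000, end_bp=top_pos + 1000,
        n_snps=n_snps, top_snp_id="s1", top_snp_pos=top_pos, top_p=top_p,
        top_q=top_q, member_snps=members,
    )


class TestClassify:
    def test_within_window_is_cis(self):
        r = region_at(1_500_000)
        assert classify_eqtl(r, ("1", 1_000_000)) == CLASS_CIS
        assert r.distance_bp == 500_000

    def test_exactly_1mb_is_cis_inclusive(self):
        r = region_at(2_000_000)
        assert classify_eqtl(r, ("1", 1_000_000)) == CLASS_CIS

    def test_beyond_window_same_chrom_is_trans_i(self):
        r = region_at(2_000_001)
        assert classify_eqtl(r, ("1", 1_000_000)) == CLASS_TRANS_I

    def test_other_chromosome_is_trans_ii(self):
        r = region_at(1_500_000, chrom="2")
        assert classify_eqtl(r, ("1", 1_500_000)) == CLASS_TRANS_II
        assert r.distance_bp is None

    def test_missing_tss_unclassified(self):
        r = region_at(1_500_000)
        assert classify_eqtl(r, None) == CLASS_UNKNOWN


class TestTopSnp:
    def test_argmin_q(self):
        tab = sig_table([10, 20, 30], q=[0.3, 0.01, 0.2])
        assert top_snp(tab)["snp_id"] == "s1"

    def test_tie_on_q_broken_by_p_then_position(self):
        tab = sig_table([10, 20, 30], q=[0.01, 0.01, 0.01])
        tab["p_value"] = [0.5, 0.001, 0.001]
        assert top_snp(tab)["pos"] == 20  # p tie between s1, s2 -> lower pos
        tab["p_value"] = [0.001, 0.001, 0.001]
        assert top_snp(tab)["pos"] == 10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            top_snp(sig_table([]))


class TestLD:
    def _geno_region(self, dosages):
        d = np.asarray(dosages, dtype=float)
        geno = make_genotypes(d)
        members = sig_table(list(geno.snp_map["pos"]))
        members["snp_id"] = list(geno.snp_map["snp_id"])
        region = EQTLRegion(
            gene_id="g1", chrom="1", start_bp=1, end_bp=10_000, n_snps=d.shape[1],
            top_snp_id="s0", top_snp_pos=1000, top_p=1e-8, top_q=1e-6,
            member_snps=members,
        )
        return region, geno

    def test_self_r2_is_one(self):
        region, geno = self._geno_region([[0, 0], [1, 1], [2, 2], [0, 0]])
        table, summary = ld_within_region(region, geno)
        assert table.iloc[0, 0] == pytest.approx(1.0)
        assert summary["max_r2"] == pytest.approx(1.0)

    def test_perfect_negative_correlation_squares_to_one(self):
        region, geno = self._geno_region([[0, 2], [1, 1], [2, 0], [0, 2]])
        table, _ = ld_within_region(region, geno)
        assert table.iloc[0, 1] == pytest.approx(1.0)

    def test_zero_variance_member_reported_na(self):
        region, geno = self._geno_region([[0, 1], [1, 1], [2, 1], [0, 1]])
        table, _ = ld_within_region(region, geno)
        assert np.isnan(table.iloc[0, 1])

    def test_independent_snps_have_small_mean_r2(self):
        rng = np.random.default_rng(8)
        n = 100
        d = rng.binomial(2, 0.4, (n, 20)).astype(float)
        region, geno = self._geno_region(d)
        table, _ = ld_within_region(region, geno)
        off = table.to_numpy()[np.triu_indices(20, k=1)]
        # null expectation of r^2 is about 1/(n-1)
        assert np.mean(off) < 5.0 / (n - 1)

    def test_region_sampler_is_seeded_and_without_replacement(self):
        regions = [region_at(1_000_000 * (i + 2), gene=f"g{i}") for i in range(10)]
        a = sample_regions_for_ld(regions, k=5, seed=1)
        b = sample_regions_for_ld(regions, k=5, seed=1)
        assert [r.gene_id for r in a] == [r.gene_id for r in b]
        assert len({r.gene_id for r in a}) == 5


class TestClassAnova:
    def _regions(self, qs_by_class):
        regions = []
        i = 0
        for cls, qs in qs_by_class.items():
            for q in qs:
                r = region_at(1_000_000 * (i + 2), gene=f"g{i}", top_q=q)
                r.eqtl_class = cls
                regions.append(r)
                i += 1
        return regions

    def test_identical_values_give_zero_f(self):
        res = class_qvalue_anova(
            self._regions({CLASS_CIS: [1e-4] * 3, CLASS_TRANS_I: [1e-4] * 3})
        )
        assert res["F"] == 0.0
        assert not res["lsd_pairs"]["significant"].any()

    def test_two_constant_groups_match_hand_decomposition(self):
        # within-group SS is zero, between-group SS positive: F is infinite
        res = class_qvalue_anova(
            self._regions({CLASS_CIS: [1e-8] * 3, CLASS_TRANS_I: [1e-2] * 3})
        )
        assert np.isinf(res["F"]) and res["p_value"] == 0.0
        assert res["lsd_pairs"]["significant"].all()

    def test_matches_hand_anova_formula(self):
        groups = {CLASS_CIS: [1e-8, 1e-7, 1e-6], CLASS_TRANS_I: [1e-3, 1e-2, 1e-1]}
        res = class_qvalue_anova(self._regions(groups))
        a = -np.log10(groups[CLASS_CIS])
        b = -np.log10(groups[CLASS_TRANS_I])
        grand = np.mean(np.concatenate([a, b]))
        ssb = 3 * (a.mean() - grand) ** 2 + 3 * (b.mean() - grand) ** 2
        ssw = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
        f_hand = (ssb / 1) / (ssw / 4)
        assert res["F"] == pytest.approx(f_hand, rel=1e-10)

    def test_cis_with_smaller_q_flagged_against_trans(self):
        rng = np.random.default_rng(9)
        res = class_qvalue_anova(
            self._regions(
                {
                    CLASS_CIS: list(10.0 ** rng.uniform(-12, -9, 8)),
                    CLASS_TRANS_I: list(10.0 ** rng.uniform(-4, -2, 8)),
                    CLASS_TRANS_II: list(10.0 ** rng.uniform(-4, -2, 8)),
                }
            )
        )
        pairs = res["lsd_pairs"]
        cis_rows = pairs[(pairs["class_a"] == CLASS_CIS) | (pairs["class_b"] == CLASS_CIS)]
        assert cis_rows["significant"].all()
        # direction: cis has larger -log10 q
        assert res["group_means"][CLASS_CIS] > res["group_means"][CLASS_TRANS_I]

    def test_small_class_excluded_with_warning(self):
        res = class_qvalue_anova(
            self._regions(
                {CLASS_CIS: [1e-6, 1e-5, 1e-4], CLASS_TRANS_I: [1e-3, 1e-2, 1e-2],
                 CLASS_TRANS_II: [1e-2]}
            )
        )
        assert res["excluded_classes"] == [CLASS_TRANS_II]

    def test_fewer_than_two_usable_classes_rejected(self):
        with pytest.raises(ValueError):
            class_qvalue_anova(self._regions({CLASS_CIS: [1e-6, 1e-5]}))


def test_call_eqtl_regions_accounting_partition():
    """Significant associations partition into merged + discarded."""
    rng = np.random.default_rng(10)
    rows = []
    for g in range(4):
        m = 40
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": f"g{g}",
                    "snp_id": [f"g{g}s{i}" for i in range(m)],
                    "chrom": rng.choice(["1", "2"], m),
                    "pos": rng.integers(1, 60_000_000, m),
                    "p_value": 10.0 ** rng.uniform(-9, 0, m),
                }
            )
        )
    assoc = bh_adjust(pd.concat(rows, ignore_index=True), alpha=0.4)
    annot = pd.DataFrame(
        {"chrom": ["1", "1", "2", "2"], "tss_pos": [5e6, 1e6, 2e6, 9e6]},
        index=[f"g{g}" for g in range(4)],
    )
    regions, acct = call_eqtl_regions(assoc, annot)
    assert acct["n_significant"] == acct["n_merged"] + acct["n_discarded"]
    assert acct["n_regions"] == len(regions)
    assert all(r.n_snps >= 3 for r in regions)
    # classification is exhaustive over annotated genes
    assert all(
        r.eqtl_class in {CLASS_CIS, CLASS_TRANS_I, CLASS_TRANS_II} for r in regions
    )
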