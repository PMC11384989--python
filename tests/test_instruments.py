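"""Instrument selection: p-value screen, LD clumping, strength filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medimr.errors import LdMatrixError
from medimr.instruments import (
    f_statistic,
    filter_weak,
    ld_clump,
    r2_from_maf,
    select_by_pvalue,
    select_instruments,
)
from medimr.synthetic import SimulationConfig, ld_matrix, simulate_mr_study

from conftest import identity_ld, make_study


class TestSelectByPvalue:
    def test_strictly_below_threshold_sorted(self):
        study = make_study(
            [
                {"snp_id": "rsA", "pval": 1e-6},
                {"snp_id": "rsB", "pval": 2e-5},
                {"snp_id": "rsC", "pval": 1e-8},
                {"snp_id": "rsD", "pval": 1e-5},  # exactly at threshold: excluded
            ]
        )
        assert select_by_pvalue(study, 1e-5) == ["rsC", "rsA"]

    def test_ties_broken_lexicographically(self):
        study = make_study(
            [{"snp_id": "rsB", "pval": 1e-7}, {"snp_id": "rsA", "pval": 1e-7}]
        )
        assert select_by_pvalue(study, 1e-5) == ["rsA", "rsB"]

    def test_threshold_domain(self):
        study = make_study([{"snp_id": "rs1"}])
        with pytest.raises(ValueError):
            select_by_pvalue(study, 0.0)

    def test_genomewide_threshold_selects_only_planted_instruments(self):
        """At 5e-8 with 50 strong planted instruments, no null SNP slips in."""
        hit_null = 0
        for seed in range(10):
            sim = simulate_mr_study(
                SimulationConfig(n_instruments=50, n_null_snps=500, n_exposure=200_000,
                                 gamma_sd=0.1, seed=seed)
            )
            hits = set(select_by_pvalue(sim.exposure, 5e-8))
            hit_null += bool(hits - set(sim.truth.instrument_ids))
        assert hit_null == 0  # expected false inclusions ~ 10*500*5e-8


class TestLdClump:
    def test_dominant_index_removes_correlated_neighbour(self):
        study = make_study(
            [
                {"snp_id": "rs1", "pos": 1000, "pval": 1e-8},
                {"snp_id": "rs2", "pos": 2000, "pval": 1e-6},
            ]
        )
        ld = identity_ld(["rs1", "rs2"])
        ld.loc["rs1", "rs2"] = ld.loc["rs2", "rs1"] = 0.9  # r^2 = 0.81
        assert ld_clump(["rs1", "rs2"], study, ld) == ["rs1"]

    def test_window_applies_within_chromosome_only(self):
        study = make_study(
            [
                {"snp_id": "rs1", "chrom": "1", "pos": 1000, "pval": 1e-8},
                {"snp_id": "rs2", "chrom": "2", "pos": 1000, "pval": 1e-6},
            ]
        )
        ld = identity_ld(["rs1", "rs2"])
        ld.loc["rs1", "rs2"] = ld.loc["rs2", "rs1"] = 0.9
        assert ld_clump(["rs1", "rs2"], study, ld) == ["rs1", "rs2"]

    def test_outside_window_retained(self):
        study = make_study(
            [
                {"snp_id": "rs1", "pos": 1, "pval": 1e-8},
                {"snp_id": "rs2", "pos": 1 + 10_000_001, "pval": 1e-6},
            ]
        )
        ld = identity_ld(["rs1", "rs2"])
        ld.loc["rs1", "rs2"] = ld.loc["rs2", "rs1"] = 0.9
        assert ld_clump(["rs1", "rs2"], study, ld) == ["rs1", "rs2"]

    def test_missing_from_ld_names_snp(self):
        study = make_study([{"snp_id": "rs1"}, {"snp_id": "rs2"}])
        with pytest.raises(LdMatrixError, match="rs2"):
            ld_clump(["rs1", "rs2"], study, identity_ld(["rs1"]))

    def test_blocks_reduce_to_min_pval_members_and_match_bruteforce(self):
        """30 candidates in 10 equicorrelated blocks: exactly the 10 block-best
        SNPs survive, matching an independent brute-force greedy oracle."""
        sim = simulate_mr_study(
            SimulationConfig(n_instruments=30, n_null_snps=0, n_exposure=200_000,
                             gamma_sd=0.1, ld_block_size=3, ld_r=0.9, seed=21)
        )
        study, ld = sim.exposure, ld_matrix(sim.truth)
        candidates = study.snp_ids
        kept = ld_clump(candidates, study, ld)

        # brute-force oracle over pairs, written independently of the package
        pval = dict(zip(study.df["snp_id"], study.df["pval"]))
        pos = dict(zip(study.df["snp_id"], study.df["pos"]))
        remaining = sorted(candidates, key=lambda s: (pval[s], s))
        expected = []
        while remaining:
            idx = remaining[0]
            expected.append(idx)
            remaining = [
                s
                for s in remaining[1:]
                if not (abs(pos[s] - pos[idx]) <= 1e7 and ld.loc[idx, s] ** 2 >= 0.001)
            ]
        assert kept == expected
        assert len(kept) == 10
        for block_start in range(0, 30, 3):
            block = candidates[block_start : block_start + 3]
            best = min(block, key=lambda s: (pval[s], s))
            assert best in kept

    def test_order_invariance(self):
        sim = simulate_mr_study(
            SimulationConfig(n_instruments=12, n_null_snps=0, ld_block_size=4, ld_r=0.8, seed=3)
        )
        study, ld = sim.exposure, ld_matrix(sim.truth)
        forward = ld_clump(study.snp_ids, study, ld)
        backward = ld_clump(list(reversed(study.snp_ids)), study, ld)
        assert forward == backward


class TestStrengthFormulas:
    def test_r2_hand_values(self):
        assert r2_from_maf(0.5, 1.0) == 0.5
        assert r2_from_maf(0.0, 3.0) == 0.0
        assert r2_from_maf(1.0, 3.0) == 0.0

    @given(st.floats(0.0, 1.0), st.floats(-2.0, 2.0))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_r2_maf_folding_symmetry(self, eaf, beta):
        # up to rounding in 1 - eaf, folding to the minor allele is symmetric
        assert r2_from_maf(eaf, beta) == pytest.approx(
            r2_from_maf(1.0 - eaf, beta), rel=1e-12, abs=1e-15
        )

    def test_f_hand_value(self):
        assert f_statistic(0.01, 1002) == pytest.approx(0.01 * 1000 / 0.99, rel=1e-12)
        assert f_statistic(0.0, 100) == 0.0

    def test_f_monotone_in_r2(self):
        for n in (10, 1000, 1_000_000):
            assert f_statistic(0.02, n) > f_statistic(0.01, n)

    def test_f_domain(self):
        with pytest.raises(ValueError):
            f_statistic(1.0, 100)
        with pytest.raises(ValueError):
            f_statistic(0.1, 2)


class TestFilterWeak:
    def snp_with_f(self, f, snp_id="rs1"):
        # eaf 0.5, beta 1 give r2 = 0.5 exactly, so F = (n-2) exactly
        return {"snp_id": snp_id, "eaf": 0.5, "beta": 1.0, "n": f + 2}

    def test_boundary_is_strict_less_than_ten(self):
        study = make_study(
            [self.snp_with_f(9.5, snp_id="rs_weak"), self.snp_with_f(10.0, snp_id="rs_ok")]
        )
        inst = filter_weak(["rs_weak", "rs_ok"], study)
        assert inst.snp_ids == ["rs_ok"]
        assert [(s, stage) for s, stage, _ in inst.exclusions] == [("rs_weak", "weak")]

    def test_monomorphic_snps_all_excluded_audit_complete(self):
        study = make_study([{"snp_id": f"rs{i}", "eaf": 0.0, "n": 1000} for i in range(3)])
        inst = filter_weak(study.snp_ids, study)
        assert inst.snp_ids == []
        assert len(inst.exclusions) == 3

    def test_missing_eaf_excluded_with_warning(self):
        study = make_study([{"snp_id": "rs1", "eaf": np.nan, "n": 1000}])
        with pytest.warns(UserWarning, match="rs1"):
            inst = filter_weak(["rs1"], study)
        assert inst.exclusions == [("rs1", "weak", "no_eaf")]

    def test_simulated_strong_instruments_none_excluded(self):
        sim = simulate_mr_study(
            SimulationConfig(n_instruments=30, n_null_snps=0, n_exposure=50_000,
                             gamma_sd=0.1, seed=8)
        )
        # beta >= 0.05 clears F = 10 at n = 50,000 for every eaf in [0.05, 0.95]
        strong = [
            s for s in sim.truth.instrument_ids
            if abs(sim.exposure.get(s).beta) >= 0.05
        ]
        inst = filter_weak(strong, sim.exposure)
        assert inst.snp_ids == strong


def test_pipeline_never_grows_and_audit_is_complete():
    sim = simulate_mr_study(SimulationConfig(n_instruments=40, n_null_snps=100, seed=17))
    study, ld = sim.exposure, ld_matrix(sim.truth)
    hits = select_by_pvalue(study, 1e-5)
    inst = select_instruments(study, ld)
    assert len(inst.snp_ids) <= len(hits) <= len(study)
    assert len(inst.snp_ids) + len(inst.exclusions) == len(study)
    assert set(inst.snp_ids) <= set(hits)
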