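"""The scan: MAF, per-SNP tau equivalence, MAF-matched ranks, calling, estimator API."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from geascan import (
    ConfigurationError,
    EnvAssociationScan,
    ScanConfig,
    SimConfig,
    ValidationError,
    call_significant,
    compute_maf,
    kendall_tau_b,
    maf_matched_rank,
    scan_snps,
    simulate_panel,
)
from geascan.scan import _maf_rank_core


class TestComputeMaf:
    def test_half_is_fixed_point(self):
        assert compute_maf([0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_folding(self):
        assert compute_maf([0.9, 0.8, 0.7]) == pytest.approx(0.2)

    def test_missing_ignored(self):
        assert compute_maf([0.2, np.nan, 0.4]) == pytest.approx(0.3)

    def test_all_missing_errors(self):
        with pytest.raises(ValidationError):
            compute_maf([np.nan, np.nan])

    def test_matches_independent_summation(self, rng):
        freqs = rng.random(52)
        total = 0.0
        for f in freqs:
            total += f
        mean = total / 52
        assert compute_maf(freqs) == pytest.approx(min(mean, 1 - mean), abs=1e-12)


class TestScanSnps:
    def test_elementwise_equivalence_with_single_snp_operation(self, small_sim):
        panel, fm, env, _ = small_sim
        results, _ = scan_snps(fm, env)
        sub = results.sample(n=50, random_state=0)
        for _, row in sub.iterrows():
            i = int(np.flatnonzero(fm.snp_ids == row["snp_id"])[0])
            tau, p = kendall_tau_b(fm.freqs[i], env.values)
            assert row["tau"] == pytest.approx(tau, abs=1e-12)
            assert row["p_value"] == pytest.approx(p, abs=1e-12)

    def test_monotone_snp_has_positive_tau_small_p(self, small_sim):
        panel, fm, env, _ = small_sim
        order = np.argsort(env.values)
        freqs = fm.freqs.copy()
        freqs[0, order] = np.linspace(0.05, 0.95, len(order))
        fm2 = type(fm)(fm.snp_meta, freqs, fm.populations)
        results, _ = scan_snps(fm2, env)
        row = results[results["snp_id"] == fm.snp_ids[0]].iloc[0]
        assert row["tau"] > 0.8
        assert row["p_value"] < 1e-8

    def test_constant_snp_goes_to_skip_report(self, small_sim):
        panel, fm, env, _ = small_sim
        freqs = fm.freqs.copy()
        freqs[3] = 0.25
        fm2 = type(fm)(fm.snp_meta, freqs, fm.populations)
        results, skipped = scan_snps(fm2, env)
        assert fm.snp_ids[3] not in set(results["snp_id"])
        rep = skipped[skipped["snp_id"] == fm.snp_ids[3]]
        assert rep["reason"].iloc[0] == "constant_frequency"

    def test_snp_with_few_populations_skipped(self, small_sim):
        panel, fm, env, _ = small_sim
        freqs = fm.freqs.copy()
        freqs[5, 9:] = np.nan  # 9 usable populations < 10
        fm2 = type(fm)(fm.snp_meta, freqs, fm.populations)
        _, skipped = scan_snps(fm2, env)
        assert (skipped["snp_id"] == fm.snp_ids[5]).any()

    def test_env_length_mismatch(self, small_sim):
        panel, fm, env, _ = small_sim
        from geascan import EnvVector

        with pytest.raises(ValidationError):
            scan_snps(fm, EnvVector(env.values[:-1], "short"))


class TestMafMatchedRank:
    def test_largest_abs_tau_in_identical_maf_pool_ranks_one(self):
        maf = np.full(101, 0.25)
        tau = np.linspace(-0.5, 0.5, 101)  # |tau| maximum is unique at the ends
        window_n, rank, widened = _maf_rank_core(maf, np.abs(tau), 0.01, 50)
        assert window_n.tolist() == [101] * 101
        # the two extremes tie on |tau| = 0.5; midrank gives (99 + 0.5)/100
        assert rank[0] == pytest.approx((99 + 0.5) / 100)

    def test_all_tied_taus_rank_half(self):
        maf = np.full(60, 0.3)
        tau = np.full(60, 0.2)
        _, rank, _ = _maf_rank_core(maf, np.abs(tau), 0.01, 50)
        assert np.allclose(rank, 0.5)

    def test_strict_maximum_ranks_one(self):
        maf = np.full(101, 0.25)
        tau = np.concatenate([np.linspace(0.0, 0.4, 100), [0.9]])
        _, rank, _ = _maf_rank_core(maf, np.abs(tau), 0.01, 50)
        assert rank[-1] == pytest.approx(1.0)

    def test_matches_brute_force_double_loop(self, rng):
        n = 400
        maf = rng.uniform(0.05, 0.5, n)
        tau = rng.normal(0, 0.2, n)
        w, min_w = 0.01, 30
        window_n, rank, widened = _maf_rank_core(maf, np.abs(tau), w, min_w)
        at = np.abs(tau)
        for i in range(0, n, 7):
            members = [j for j in range(n) if abs(maf[j] - maf[i]) <= w]
            if len(members) >= min_w:
                assert not widened[i]
                assert window_n[i] == len(members)
                less = sum(1 for j in members if at[j] < at[i])
                equal = sum(1 for j in members if at[j] == at[i]) - 1
                assert rank[i] == pytest.approx(
                    (less + 0.5 * equal) / (len(members) - 1), abs=1e-12
                )
            else:
                assert widened[i]
                assert window_n[i] >= min_w

    def test_too_few_snps_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            _maf_rank_core(np.array([0.1, 0.2]), np.array([0.1, 0.2]), 0.01, 50)


class TestCallSignificant:
    def _frame(self, p, rank):
        return pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(len(p))],
                "tau": 0.1,
                "p_value": p,
                "maf": 0.2,
                "n_used": 52,
                "window_n": 100,
                "rank": rank,
                "widened_window": False,
                "bonferroni_sig": False,
                "rank_sig": False,
                "final_sig": False,
            }
        )

    def test_both_criteria_required(self):
        df = self._frame([0.04, 1e-9], [0.995, 0.98])
        out = call_significant(df, ScanConfig(alpha=0.05), n_tests=1)
        assert out["final_sig"].tolist() == [True, False]
        assert out["bonferroni_sig"].tolist() == [True, True]
        assert out["rank_sig"].tolist() == [True, False]

    def test_bonferroni_denominator(self):
        df = self._frame([0.04 / 100, 0.06 / 100], [0.995, 0.995])
        out = call_significant(df, ScanConfig(alpha=0.05), n_tests=100)
        assert out["bonferroni_sig"].tolist() == [True, False]

    def test_unset_ranks_rejected(self):
        df = self._frame([0.01], [np.nan])
        with pytest.raises(ConfigurationError):
            call_significant(df, ScanConfig())


class TestScanInvariances:
    def test_coded_allele_flip_negates_tau_only(self, small_sim):
        panel, fm, env, _ = small_sim
        flipped = fm.freqs.copy()
        flipped[10] = 1 - flipped[10]
        fm2 = type(fm)(fm.snp_meta, flipped, fm.populations)
        cfg = ScanConfig(min_window=50)
        a = call_significant(maf_matched_rank(scan_snps(fm, env, cfg)[0], cfg), cfg)
        b = call_significant(maf_matched_rank(scan_snps(fm2, env, cfg)[0], cfg), cfg)
        ra = a[a["snp_id"] == fm.snp_ids[10]].iloc[0]
        rb = b[b["snp_id"] == fm.snp_ids[10]].iloc[0]
        assert rb["tau"] == pytest.approx(-ra["tau"], abs=1e-12)
        for col in ("p_value", "maf", "rank", "window_n", "final_sig"):
            assert rb[col] == pytest.approx(ra[col], abs=1e-12)

    def test_rank_invariant_under_monotone_env_transform(self, small_sim):
        panel, fm, env, _ = small_sim
        from geascan import EnvVector

        env2 = EnvVector(np.exp(env.values / 10.0), env.name)
        a = maf_matched_rank(scan_snps(fm, env)[0])
        b = maf_matched_rank(scan_snps(fm, env2)[0])
        assert np.allclose(a["rank"], b["rank"], atol=1e-12)
        assert np.allclose(a["tau"], b["tau"], atol=1e-12)


class TestEstimatorApi:
    def test_clone_and_params_roundtrip(self):
        est = EnvAssociationScan(alpha=0.01, min_window=20)
        est2 = clone(est)
        assert est2.get_params()["alpha"] == 0.01
        est2.set_params(rank_cutoff=0.95)
        assert est2.rank_cutoff == 0.95

    def test_fit_transform_selects_spiked_snps(self, spiked_sim):
        panel, fm, env, truth = spiked_sim
        est = EnvAssociationScan().fit(fm.freqs.T, env.values)
        kept = est.get_support(indices=True)
        ids = set(fm.snp_ids[kept])
        # most of what the scan keeps should be truly spiked
        assert len(ids) > 0
        assert len(ids & set(truth.selected_snp_ids)) / len(ids) > 0.5
        X2 = est.transform(fm.freqs.T)
        assert X2.shape == (fm.n_populations, len(kept))

    def test_dataframe_input_keeps_feature_names(self, small_sim):
        panel, fm, env, _ = small_sim
        X = pd.DataFrame(fm.freqs.T, columns=fm.snp_ids)
        est = EnvAssociationScan().fit(X, env.values)
        assert list(est.feature_names_in_) == list(fm.snp_ids)
        res = est.results()
        assert set(res["snp_id"]) <= set(fm.snp_ids)

    def test_constant_env_rejected(self, small_sim):
        panel, fm, env, _ = small_sim
        from geascan import ConstantInputError

        with pytest.raises(ConstantInputError):
            EnvAssociationScan().fit(fm.freqs.T, np.full(fm.n_populations, 3.0))


def test_neutral_panel_rank_gate_is_calibrated():
    """On a neutral panel the rank gate passes ~1% of SNPs by construction."""
    _, fm, env, _ = simulate_panel(SimConfig(n_snps=4000, seed=5))
    res = maf_matched_rank(scan_snps(fm, env)[0])
    frac = float((res["rank"] > 0.99).mean())
    se = np.sqrt(0.01 * 0.99 / len(res))
    assert abs(frac - 0.01) < 4 * se
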