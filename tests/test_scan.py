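import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import ols_loglik_lrt
from meqtlscan.exceptions import CollinearityError, DomainError
from meqtlscan.preprocess import beta_to_m, cell_surrogate
from meqtlscan.scan import (
    CisMeQTLScanner,
    encode_and_collapse,
    fit_association,
    pair_cis,
    run_scan,
    subgroup_concordance,
)


def _manifests():
    snps = pd.DataFrame({
        "snp_id": ["rs1", "rs2"],
        "chrom": ["chr1", "chr2"],
        "pos": [1_000_000, 5_000_000],
    })
    probes = pd.DataFrame({
        "probe_id": ["p_at_snp", "p_500k", "p_500k1", "p_otherchr", "p_near_rs2"],
        "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2"],
        "pos": [1_000_000, 1_500_000, 1_500_001, 1_000_000, 5_010_000],
    })
    return snps, probes


class TestPairCis:
    def test_window_boundary_inclusive(self):
        snps, probes = _manifests()
        pairs = pair_cis(snps, probes, window=500_000)
        got = set(map(tuple, pairs[["snp_id", "probe_id"]].to_numpy()))
        assert ("rs1", "p_500k") in got
        assert ("rs1", "p_500k1") not in got

    def test_zero_distance_included(self):
        snps, probes = _manifests()
        pairs = pair_cis(snps, probes)
        row = pairs[(pairs.snp_id == "rs1") & (pairs.probe_id == "p_at_snp")]
        assert len(row) == 1 and row["distance"].iloc[0] == 0

    def test_matches_brute_force_enumeration(self):
        snps, probes = _manifests()
        window = 500_000
        expected = {
            (s.snp_id, p.probe_id)
            for s in snps.itertuples()
            for p in probes.itertuples()
            if s.chrom == p.chrom and abs(s.pos - p.pos) <= window
        }
        pairs = pair_cis(snps, probes, window)
        assert set(map(tuple, pairs[["snp_id", "probe_id"]].to_numpy())) == expected
        assert pairs.attrs["per_snp_counts"] == {"rs1": 2, "rs2": 1}

    def test_missing_chromosome_rejected(self):
        snps, probes = _manifests()
        snps.loc[0, "chrom"] = np.nan
        with pytest.raises(DomainError, match="rs1"):
            pair_cis(snps, probes)


def _dosage(counts):
    return np.repeat([0.0, 1.0, 2.0], [counts.get(0, 0), counts.get(1, 0), counts.get(2, 0)])


class TestEncodeCollapse:
    def test_rare_risk_homozygotes_merged(self):
        enc = encode_and_collapse(_dosage({0: 200, 1: 120, 2: 9}))
        assert enc.collapsed and set(np.unique(enc.dosage)) == {0.0, 1.0}
        assert (enc.dosage == 1.0).sum() == 129

    def test_rare_nonrisk_homozygotes_merged_and_recoded(self):
        enc = encode_and_collapse(_dosage({0: 5, 1: 150, 2: 200}))
        assert enc.collapsed and set(np.unique(enc.dosage)) == {0.0, 1.0}
        assert (enc.dosage == 0.0).sum() == 155  # merged 0+1 class
        assert (enc.dosage == 1.0).sum() == 200  # risk homozygotes stay high

    def test_count_of_exactly_ten_is_kept(self):
        enc = encode_and_collapse(_dosage({0: 100, 1: 100, 2: 10}))
        assert not enc.collapsed
        assert set(np.unique(enc.dosage)) == {0.0, 1.0, 2.0}

    def test_missing_masked_and_monomorphic_untestable(self):
        enc = encode_and_collapse([1.0, np.nan, 1.0, 1.0, np.nan])
        assert enc.mask.sum() == 3 and enc.status == "untestable"

    def test_invalid_dosage_value_rejected(self):
        with pytest.raises(DomainError):
            encode_and_collapse([0.0, 3.0])


def _fit_inputs(n=200, seed=0, delta=0.5, noise=0.5):
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"s{i}" for i in range(n)])
    cov = pd.DataFrame({
        "sex": rng.binomial(1, 0.5, n),
        "age": rng.uniform(14, 34, n),
        "weight_category": rng.choice(3, n, p=[0.7, 0.2, 0.1]),
    }, index=idx)
    sur = pd.DataFrame(rng.normal(size=(n, 2)), index=idx, columns=["PC1", "PC2"])
    g = rng.binomial(2, 0.3, n).astype(float)
    y = (0.2 * cov["sex"] + 0.01 * cov["age"] + 0.1 * cov["weight_category"]
         + 0.3 * sur["PC1"] - 0.2 * sur["PC2"] + delta * g
         + rng.normal(0, noise, n))
    return pd.Series(y, index=idx), cov, sur, g


class TestFitAssociation:
    def test_pure_covariate_signal_gives_null(self):
        y, cov, sur, g = _fit_inputs(seed=1)
        y_exact = 1.0 + 0.5 * cov["sex"]  # exactly explained without genotype
        res = fit_association(y_exact, cov, sur, g)
        assert res.partial_r2 == 0.0 and res.p_value == 1.0

    def test_exact_genotype_signal_gives_partial_r2_one(self):
        y, cov, sur, g = _fit_inputs(seed=2)
        y_exact = pd.Series(2.0 + 1.5 * g, index=y.index)
        res = fit_association(y_exact, cov, sur, g)
        assert res.partial_r2 == pytest.approx(1.0)
        assert res.p_value < 1e-100

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_gaussian_likelihood_oracle_exactly(self, seed):
        y, cov, sur, g = _fit_inputs(seed=seed)
        res = fit_association(y, cov, sur, g)
        X_red = np.column_stack([np.ones(len(y)), cov, sur])
        X_full = np.column_stack([X_red, g])
        lrt, rss_red, rss_full = ols_loglik_lrt(X_full, X_red, y.to_numpy())
        assert res.lrt_stat == pytest.approx(lrt, rel=1e-9)
        assert res.p_value == pytest.approx(stats.chi2.sf(lrt, 1), rel=1e-9)
        assert res.partial_r2 == pytest.approx(1 - rss_full / rss_red, rel=1e-9)

    def test_agrees_with_partial_f_test_asymptotically(self):
        y, cov, sur, g = _fit_inputs(seed=3, n=200)
        res = fit_association(y, cov, sur, g)
        X_red = np.column_stack([np.ones(len(y)), cov, sur])
        X_full = np.column_stack([X_red, g])
        _, rss_red, rss_full = ols_loglik_lrt(X_full, X_red, y.to_numpy())
        df2 = len(y) - X_full.shape[1]
        f_stat = (rss_red - rss_full) / (rss_full / df2)
        p_f = stats.f.sf(f_stat, 1, df2)
        assert res.p_value == pytest.approx(p_f, rel=0.10)

    def test_partial_r2_invariant_to_covariate_rescaling(self):
        y, cov, sur, g = _fit_inputs(seed=4)
        res1 = fit_association(y, cov, sur, g)
        cov2 = cov.copy()
        cov2["age"] = cov2["age"] * 100 - 50
        sur2 = sur * 7.3
        res2 = fit_association(y, cov2, sur2, g)
        assert res2.partial_r2 == pytest.approx(res1.partial_r2, rel=1e-9)
        assert res2.p_value == pytest.approx(res1.p_value, rel=1e-9)

    def test_constant_dosage_untestable(self):
        y, cov, sur, _ = _fit_inputs(seed=5)
        res = fit_association(y, cov, sur, np.ones(len(y)))
        assert res.status == "untestable"

    def test_collinear_design_names_columns(self):
        y, cov, sur, g = _fit_inputs(seed=6)
        sur2 = sur.copy()
        sur2["PC2"] = sur2["PC1"]
        with pytest.raises(CollinearityError):
            fit_association(y, cov, sur2, g)


class TestScanner:
    def test_block_path_matches_per_pair_fit(self, small_dataset):
        cfg = small_dataset.config
        m = beta_to_m(small_dataset.beta)
        sur = cell_surrogate(m, cfg.reference_probe_ids)
        manifest = cfg.probe_manifest()
        manifest = manifest[~manifest["probe_id"].isin(cfg.reference_probe_ids)]
        sc = CisMeQTLScanner().fit(
            m, small_dataset.genotypes, covariates=small_dataset.covariates,
            surrogate=sur, snp_manifest=cfg.snp_manifest(), probe_manifest=manifest,
        )
        for _, row in sc.results_.iloc[:6].iterrows():
            res = fit_association(
                m[row["probe_id"]], small_dataset.covariates, sur,
                small_dataset.genotypes[row["snp_id"]],
                snp_id=row["snp_id"], probe_id=row["probe_id"],
            )
            assert row["coef"] == pytest.approx(res.coef_genotype, rel=1e-9)
            assert row["p"] == pytest.approx(res.p_value, rel=1e-9)
            assert row["coef_se"] == pytest.approx(res.coef_se, rel=1e-9)

    def test_planted_effects_recovered_and_significant(self, small_dataset):
        cfg = small_dataset.config
        m = beta_to_m(small_dataset.beta)
        sur = cell_surrogate(m, cfg.reference_probe_ids)
        manifest = cfg.probe_manifest()
        manifest = manifest[~manifest["probe_id"].isin(cfg.reference_probe_ids)]
        sc = CisMeQTLScanner().fit(
            m, small_dataset.genotypes, covariates=small_dataset.covariates,
            surrogate=sur, snp_manifest=cfg.snp_manifest(), probe_manifest=manifest,
        )
        sig = set(map(tuple, sc.significant_[["snp_id", "probe_id"]].to_numpy()))
        for (snp_id, probe_id), delta in small_dataset.truth.true_effects.items():
            assert (snp_id, probe_id) in sig
            coef = sc.results_.set_index(["snp_id", "probe_id"]).loc[
                (snp_id, probe_id), "coef"]
            assert np.sign(coef) == np.sign(delta)
            assert coef == pytest.approx(delta, abs=0.25)

    def test_single_pair_scan_q_equals_p(self):
        y, cov, sur, g = _fit_inputs(seed=7)
        m = pd.DataFrame({"cgX": y})
        geno = pd.DataFrame({"rsX": g}, index=y.index)
        pairs = pd.DataFrame({"snp_id": ["rsX"], "probe_id": ["cgX"], "distance": [10]})
        results, _ = run_scan(m, cov, sur, geno, pairs)
        assert results["q"].iloc[0] == pytest.approx(results["p"].iloc[0])

    def test_no_testable_pairs_rejected(self):
        y, cov, sur, _ = _fit_inputs(seed=8)
        m = pd.DataFrame({"cgX": y})
        geno = pd.DataFrame({"rsX": np.ones(len(y))}, index=y.index)
        pairs = pd.DataFrame({"snp_id": ["rsX"], "probe_id": ["cgX"], "distance": [10]})
        with pytest.raises(DomainError):
            run_scan(m, cov, sur, geno, pairs)


class TestSubgroupConcordance:
    @staticmethod
    def _results(coefs, ps):
        return pd.DataFrame({
            "snp_id": ["rs1"] * len(coefs),
            "probe_id": [f"cg{i}" for i in range(len(coefs))],
            "coef": coefs, "p": ps,
        })

    def test_identical_signs_full_agreement(self):
        a = self._results([0.5, -0.3, 0.8], [0.01, 0.2, 0.001])
        b = self._results([0.4, -0.1, 0.9], [0.04, 0.6, 0.003])
        pairs = [("rs1", f"cg{i}") for i in range(3)]
        out = subgroup_concordance(a, b, pairs)
        assert out["sign_agreement"] == 3
        assert out["n_raw_significant_a"] == 2 and out["n_raw_significant_b"] == 2

    def test_flipped_signs_zero_agreement(self):
        a = self._results([0.5, -0.3], [0.01, 0.01])
        b = self._results([-0.5, 0.3], [0.01, 0.01])
        out = subgroup_concordance(a, b, [("rs1", "cg0"), ("rs1", "cg1")])
        assert out["sign_agreement"] == 0

    def test_null_subgroups_agree_about_half_the_time(self):
        rng = np.random.default_rng(9)
        n = 2000
        a = self._results(rng.normal(size=n), rng.uniform(size=n))
        b = self._results(rng.normal(size=n), rng.uniform(size=n))
        pairs = [("rs1", f"cg{i}") for i in range(n)]
        frac = subgroup_concordance(a, b, pairs)["sign_agreement_fraction"]
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_missing_pairs_listed(self):
        a = self._results([0.5], [0.01])
        b = self._results([0.5], [0.01])
        with pytest.raises(DomainError, match="cg9"):
            subgroup_concordance(a, b, [("rs1", "cg9")])
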