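import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import netcgas as nc
from netcgas import (
    AssociationRecord,
    GenotypeMatrix,
    SNPRecord,
    TraitMatrix,
    TraitNetwork,
)
from netcgas.association import MEDIAN_CHI2_1DF, p_from_chi2


def _geno(g, snp_id="rs1", pos=1000, chrom="1"):
    g = np.asarray(g, dtype=float)
    snp = SNPRecord(snp_id, chrom, pos, "A", "G", eaf=float(g.mean() / 2))
    return GenotypeMatrix([f"s{i}" for i in range(g.size)], [snp], g[:, None])


def _tm(cols: dict):
    names = list(cols)
    X = np.column_stack([np.asarray(cols[c], dtype=float) for c in names])
    return TraitMatrix([f"s{i}" for i in range(X.shape[0])], names, X, state="adjusted_int")


def _exact_corr_trait(g, rho, rng):
    """Trait whose sample correlation with g is exactly rho (Gram-Schmidt)."""
    n = g.size
    gc = g - g.mean()
    u1 = gc / np.linalg.norm(gc)
    e = rng.standard_normal(n)
    e -= e.mean()
    e -= (e @ u1) * u1
    u2 = e / np.linalg.norm(e)
    return rho * u1 + math.sqrt(1 - rho**2) * u2


class TestUgasScan:
    def test_printed_formula_at_exact_correlation(self, rng):
        n = 100
        g = rng.binomial(2, 0.4, n).astype(float)
        y = _exact_corr_trait(g, 0.3, rng)
        [rec] = nc.ugas_scan(_tm({"y": y}), _geno(g))
        assert rec.chi2 == pytest.approx(100 * 0.09 / 0.91, rel=1e-9)
        assert rec.sigma2 == pytest.approx(0.91, rel=1e-9)
        assert rec.rho_yg == pytest.approx(0.3, abs=1e-12)

    def test_fads1_printed_row_consistency(self):
        # per-allele beta/se 0.61 (0.033) vs the GC-corrected p 2.12e-75:
        # the implied chi2 must sit within the reported lambda range 1.00-1.03
        chi2_wald = (0.61 / 0.033) ** 2
        chi2_from_p = float(nc.chi2_from_p(2.12e-75))
        assert chi2_from_p <= chi2_wald <= chi2_from_p * 1.03

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(99)
        n, n_snps = 1000, 1000
        G = rng.binomial(2, 0.3, size=(n, n_snps)).astype(float)
        y = rng.standard_normal(n)
        snps = [SNPRecord(f"rs{j}", "1", 1000 + j, "A", "G") for j in range(n_snps)]
        gm = GenotypeMatrix([f"s{i}" for i in range(n)], snps, G)
        recs = nc.ugas_scan(_tm({"y": y}), gm)
        pvals = np.array([r.p for r in recs])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_monomorphic_snp_skipped(self, rng):
        g = np.zeros(50)
        recs = nc.ugas_scan(_tm({"y": rng.standard_normal(50)}), _geno(g))
        assert recs == []

    def test_matches_statsmodels_coefficient(self, rng):
        import statsmodels.api as sm

        n = 300
        g = rng.binomial(2, 0.25, n).astype(float)
        y = 0.2 * g + rng.standard_normal(n)
        [rec] = nc.ugas_scan(_tm({"y": y}), _geno(g))
        ys = (y - y.mean()) / y.std(ddof=0)
        fit = sm.OLS(ys, sm.add_constant(g)).fit()
        assert rec.beta == pytest.approx(fit.params[1], rel=1e-10)


class TestCgasScan:
    def test_empty_covariate_set_falls_back_to_univariate(self, rng):
        n = 200
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.3 * g + rng.standard_normal(n)
        net = TraitNetwork(nodes=["y"])  # isolated node
        [u] = nc.ugas_scan(_tm({"y": y}), _geno(g))
        [c] = nc.cgas_scan(_tm({"y": y}), _geno(g), net)
        assert c.model == "cGAS" and c.n_cov == 0
        assert c.beta == pytest.approx(u.beta, abs=1e-12)
        assert c.se == pytest.approx(u.se, abs=1e-12)

    def test_mediation_direct_effect_recovered_as_zero(self):
        rng = np.random.default_rng(5)
        n = 5000
        g = rng.binomial(2, 0.3, n).astype(float)
        c = 0.4 * g + rng.standard_normal(n)
        y = 0.5 * c + rng.standard_normal(n)
        net = TraitNetwork(nodes=["y", "c"])
        net.add_edge("y", "c")
        recs = nc.cgas_scan(_tm({"y": y, "c": c}), _geno(g), net, trait_names=["y"])
        [rec] = recs
        assert abs(rec.beta) < 3 * rec.se

    def test_matches_normal_equations_oracle(self, small_dataset):
        gm, tm, net = small_dataset
        recs = nc.cgas_scan(tm, gm, net, trait_names=["y"])
        rec = next(r for r in recs if r.snp_id == "snp_causal")
        y = tm.column("y")
        ys = (y - y.mean()) / y.std(ddof=0)
        cols = [gm.dosages[:, 0]]
        for cn in rec.covariates:
            cv = tm.column(cn)
            cols.append((cv - cv.mean()) / cv.std(ddof=0))
        X = np.column_stack([np.ones(ys.size)] + cols)
        coefs = np.linalg.solve(X.T @ X, X.T @ ys)
        assert rec.beta == pytest.approx(coefs[1], abs=1e-10)
        np.testing.assert_allclose(rec.covariate_betas, coefs[2:], atol=1e-10)

    def test_collinear_covariates_dropped(self, rng):
        n = 200
        g = rng.binomial(2, 0.3, n).astype(float)
        c1 = rng.standard_normal(n)
        y = 0.4 * c1 + rng.standard_normal(n)
        net = TraitNetwork(nodes=["y", "c1", "c2"])
        net.add_edge("y", "c1")
        net.add_edge("y", "c2")
        tm = _tm({"y": y, "c1": c1, "c2": 2.0 * c1})  # c2 exactly collinear
        [rec] = nc.cgas_scan(tm, _geno(g), net, trait_names=["y"])
        assert len(rec.covariates) == 1
        assert rec.dropped_covariates == ("c2",)

    def test_nesting_sigma_c_not_larger(self, small_dataset):
        gm, tm, net = small_dataset
        u = {(r.snp_id, r.trait): r for r in nc.ugas_scan(tm, gm)}
        for c in nc.cgas_scan(tm, gm, net):
            assert c.sigma2 <= u[(c.snp_id, c.trait)].sigma2 + 1e-12


class TestSummaryLevel:
    def test_zero_z_gives_zero_correlation(self):
        assert nc.correlation_from_z(0.0, 0.1, 100) == 0.0

    @given(st.floats(-5, 5), st.floats(0.01, 1), st.integers(10, 10_000))
    def test_antisymmetry(self, beta, se, n):
        assert nc.correlation_from_z(-beta, se, n) == pytest.approx(
            -nc.correlation_from_z(beta, se, n), abs=1e-15
        )

    def test_recovers_sample_correlation_from_fit(self, rng):
        n = 250
        g = rng.binomial(2, 0.35, n).astype(float)
        y = 0.25 * g + rng.standard_normal(n)
        recs = nc.ugas_scan(_tm({"y": y}), _geno(g))
        table = nc.records_to_summary_stats(recs)
        row = table.row("rs1", "y")
        rho = nc.correlation_from_z(row["beta"], row["se"], int(row["n"]))
        assert rho == pytest.approx(np.corrcoef(y, g)[0, 1], abs=1e-10)

    def test_k0_reduces_to_univariate_statistic(self, rng):
        n = 400
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.2 * g + rng.standard_normal(n)
        tm = _tm({"y": y})
        [u] = nc.ugas_scan(tm, _geno(g))
        table = nc.records_to_summary_stats([u])
        R = nc.trait_correlations(tm.standardized())
        rec = nc.cgas_from_summary(table, R, "rs1", "y", [])
        assert rec.beta_std == pytest.approx(u.rho_yg, abs=1e-12)
        assert rec.chi2 == pytest.approx(n * u.rho_yg**2 / (1 - u.rho_yg**2), rel=1e-10)

    def test_k1_closed_form(self, small_dataset):
        gm, tm, _ = small_dataset
        u_recs = nc.ugas_scan(tm, gm, trait_names=["y", "c1"])
        table = nc.records_to_summary_stats(u_recs)
        R = nc.trait_correlations(tm)
        rec = nc.cgas_from_summary(table, R, "snp_causal", "y", ["c1"])
        rho_yg = rec.rho_yg
        rho_cg = rec.rho_gi[0]
        rho_yc = R.value("y", "c1")
        expected = (rho_yg - rho_yc * rho_cg) / (1 - rho_cg**2)
        assert rec.beta_std == pytest.approx(expected, rel=1e-10)

    def test_matches_individual_level_fit(self, small_dataset):
        gm, tm, net = small_dataset
        u_recs = nc.ugas_scan(tm, gm)
        table = nc.records_to_summary_stats(u_recs)
        R = nc.trait_correlations(tm)
        ind = next(r for r in nc.cgas_scan(tm, gm, net, trait_names=["y"])
                   if r.snp_id == "snp_causal")
        summ = nc.cgas_from_summary(table, R, "snp_causal", "y", list(ind.covariates))
        assert summ.beta_std == pytest.approx(ind.beta_std, rel=1e-8)
        assert summ.se_std == pytest.approx(ind.se_std, rel=1e-8)
        assert summ.chi2 == pytest.approx(ind.chi2, rel=1e-8)

    def test_incompatible_inputs_rejected(self, small_dataset):
        gm, tm, _ = small_dataset
        u_recs = nc.ugas_scan(tm, gm)
        frame = nc.records_to_summary_stats(u_recs).frame.copy()
        # force an impossible genotype-covariate correlation
        frame.loc[frame["trait_name"] == "c1", "se"] = 1e-6
        table = nc.SummaryStatsTable(frame)
        R = nc.trait_correlations(tm)
        with pytest.raises(ValueError, match="positive definite|residual variance"):
            nc.cgas_from_summary(table, R, "snp_causal", "y", ["c1", "c2"])


def _fake_record(snp_id, chi2, trait="y", model="uGAS", n=1000, pos=1000, chrom="1", p_gc=None):
    se = 0.01
    return AssociationRecord(
        snp_id=snp_id, trait=trait, model=model, n=n,
        beta=math.sqrt(chi2) * se, se=se, sigma2=0.5, chi2=chi2,
        p=float(p_from_chi2(chi2)), chr=chrom, pos=pos, p_gc=p_gc,
    )


class TestGenomicControl:
    def _records(self, chi2s):
        return [_fake_record(f"rs{i}", c) for i, c in enumerate(chi2s)]

    def test_lambda_one_leaves_p_untouched(self):
        recs = self._records([MEDIAN_CHI2_1DF / 2, MEDIAN_CHI2_1DF, MEDIAN_CHI2_1DF * 2])
        out, lambdas = nc.genomic_control(recs)
        assert lambdas[("y", "uGAS")] == pytest.approx(1.0)
        for before, after in zip(recs, out):
            assert after.p_gc == before.p

    def test_doubled_statistics_corrected_back(self):
        base = [MEDIAN_CHI2_1DF / 2, MEDIAN_CHI2_1DF, MEDIAN_CHI2_1DF * 2]
        out, lambdas = nc.genomic_control(self._records([2 * c for c in base]))
        assert lambdas[("y", "uGAS")] == pytest.approx(2.0)
        for rec, orig_chi2 in zip(out, base):
            assert rec.p_gc == pytest.approx(float(p_from_chi2(orig_chi2)), rel=1e-12)

    def test_deflated_scan_not_inflated(self):
        recs = self._records([0.9 * MEDIAN_CHI2_1DF / 2, 0.9 * MEDIAN_CHI2_1DF, 0.9 * MEDIAN_CHI2_1DF * 2])
        out, lambdas = nc.genomic_control(recs)
        assert lambdas[("y", "uGAS")] == pytest.approx(0.9)
        for before, after in zip(recs, out):
            assert after.p_gc == before.p

    def test_groups_are_per_trait_and_model(self):
        recs = [_fake_record("rs1", 1.0, trait="a"), _fake_record("rs1", 4.0, trait="b")]
        _, lambdas = nc.genomic_control(recs)
        assert set(lambdas) == {("a", "uGAS"), ("b", "uGAS")}


class TestDecomposition:
    def test_identity_on_simulated_records(self, small_dataset):
        gm, tm, net = small_dataset
        for c in nc.cgas_scan(tm, gm, net):
            d = nc.decompose_from_conditional(c)
            if d.degenerate:
                continue
            assert abs(d.noise + d.pleiotropic - d.total) <= 1e-9
            assert d.noise >= -1e-12

    def test_no_covariates_gives_zero_components(self, rng):
        n = 200
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.3 * g + rng.standard_normal(n)
        net = TraitNetwork(nodes=["y"])
        [c] = nc.cgas_scan(_tm({"y": y}), _geno(g), net)
        d = nc.decompose_from_conditional(c)
        assert d.noise == pytest.approx(0.0, abs=1e-12)
        assert d.pleiotropic == pytest.approx(0.0, abs=1e-12)

    def test_pure_noise_reduction_when_g_orthogonal_to_covariate(self, rng):
        n = 300
        g = rng.binomial(2, 0.3, n).astype(float)
        gc = g - g.mean()
        c = rng.standard_normal(n)
        c -= c.mean()
        c -= (c @ gc) / (gc @ gc) * gc  # exact sample orthogonality to g
        y = 0.6 * c + rng.standard_normal(n)
        net = TraitNetwork(nodes=["y", "c"])
        net.add_edge("y", "c")
        tm = _tm({"y": y, "c": c})
        [u] = nc.ugas_scan(tm, _geno(g), trait_names=["y"])
        [crec] = nc.cgas_scan(tm, _geno(g), net, trait_names=["y"])
        d = nc.decompose_from_conditional(crec)
        assert abs(d.pleiotropic) < 1e-9
        assert crec.chi2 >= u.chi2 - 1e-9

    def test_discordance_implies_conditional_gain(self, small_dataset):
        gm, tm, net = small_dataset
        for c in nc.cgas_scan(tm, gm, net):
            d = nc.decompose_from_conditional(c)
            if d.degenerate or not c.covariates:
                continue
            term = sum(b * r for b, r in zip(c.covariate_betas, c.rho_gi)) / c.rho_yg
            if term < 0:
                assert d.pleiotropic > 0
                assert d.total > 0  # T_c^2 > T_u^2 exactly

    def test_explicit_pair_interface(self, rng):
        n = 400
        g = rng.binomial(2, 0.3, n).astype(float)
        c = 0.3 * g + rng.standard_normal(n)
        y = 0.2 * g + 0.5 * c + rng.standard_normal(n)
        net = TraitNetwork(nodes=["y", "c"])
        net.add_edge("y", "c")
        tm = _tm({"y": y, "c": c})
        [u] = nc.ugas_scan(tm, _geno(g), trait_names=["y"])
        [crec] = nc.cgas_scan(tm, _geno(g), net, trait_names=["y"])
        d = nc.decompose_log_ratio(u, crec)
        assert d.total == pytest.approx(math.log10(crec.chi2 / u.chi2), abs=1e-12)
        assert d.rho_star == pytest.approx(tuple(r / crec.rho_yg for r in crec.rho_gi))


class TestThresholdAndLoci:
    def test_paper_scale_threshold(self):
        assert nc.significance_threshold(151) == pytest.approx(5e-8 / 151)
        assert nc.significance_threshold(151) == pytest.approx(3.31e-10, rel=1e-2)
        assert nc.significance_threshold(1) == 5e-8

    def test_threshold_monotone_decreasing(self):
        ts = [nc.significance_threshold(k) for k in (1, 2, 10, 151, 1000)]
        assert all(a > b for a, b in zip(ts, ts[1:]))

    def test_window_boundary(self):
        sig = 1e-12
        recs = [
            _fake_record("rs1", float(nc.chi2_from_p(sig)), pos=1_000_000),
            _fake_record("rs2", float(nc.chi2_from_p(sig)), pos=1_499_999),
        ]
        assert len(nc.define_loci(recs, 1e-10)) == 1
        recs[1] = _fake_record("rs2", float(nc.chi2_from_p(sig)), pos=1_500_000)
        assert len(nc.define_loci(recs, 1e-10)) == 2

    def test_different_chromosomes_split(self):
        sig = float(nc.chi2_from_p(1e-12))
        recs = [
            _fake_record("rs1", sig, pos=100, chrom="1"),
            _fake_record("rs2", sig, pos=100, chrom="2"),
        ]
        assert len(nc.define_loci(recs, 1e-10)) == 2

    def test_single_hit_is_its_own_best(self):
        rec = _fake_record("rs1", float(nc.chi2_from_p(1e-12)), pos=500)
        [locus] = nc.define_loci([rec], 1e-10)
        assert locus.best.snp_id == "rs1"
        assert (locus.start, locus.end) == (500, 500)

    def test_insignificant_hits_excluded(self):
        rec = _fake_record("rs1", 1.0, pos=500)
        assert nc.define_loci([rec], 1e-10) == []


def _exact_signed_rank_p(a, b):
    """Enumeration oracle for the paired two-sided Wilcoxon signed-rank test."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([False, True], repeat=len(d))]
    ws = np.array(ws)
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(p, 1.0)


class TestCompareScans:
    def _scan_pair(self, chi2s_a, chi2s_b):
        a = [_fake_record(f"rs{i}", c, pos=1 + i * 10**6, model="uGAS") for i, c in enumerate(chi2s_a)]
        b = [_fake_record(f"rs{i}", c, pos=1 + i * 10**6, model="cGAS") for i, c in enumerate(chi2s_b)]
        loci = nc.define_loci(a, threshold=1.0)  # every record significant at p<=1
        return a, b, loci

    def test_identical_scans(self):
        a, b, loci = self._scan_pair([50.0, 60.0, 70.0], [50.0, 60.0, 70.0])
        out = nc.compare_scans(a, b, loci)
        assert out["mean_ratio"] == pytest.approx(1.0)
        assert out["wilcoxon_p"] == 1.0

    def test_doubled_statistics(self):
        a, b, loci = self._scan_pair([50.0, 60.0, 70.0], [100.0, 120.0, 140.0])
        out = nc.compare_scans(a, b, loci)
        assert out["mean_ratio"] == pytest.approx(2.0)

    def test_wilcoxon_matches_enumeration_oracle(self, rng):
        chi2_a = rng.uniform(10, 100, 8)
        chi2_b = chi2_a * rng.uniform(0.5, 2.0, 8)
        a, b, loci = self._scan_pair(chi2_a, chi2_b)
        out = nc.compare_scans(a, b, loci)
        assert out["n_loci"] == 8
        assert out["wilcoxon_p"] == pytest.approx(
            _exact_signed_rank_p(chi2_a, chi2_b), rel=1e-9
        )

    def test_same_trait_keeps_lower_ugas_p(self):
        # two SNPs in one locus hitting the same trait: only the better
        # uGAS hit contributes
        a = [_fake_record("rs1", 50.0, pos=1000), _fake_record("rs2", 80.0, pos=2000)]
        b = [_fake_record("rs1", 500.0, pos=1000, model="cGAS"),
             _fake_record("rs2", 10.0, pos=2000, model="cGAS")]
        loci = nc.define_loci(a, threshold=1.0)
        out = nc.compare_scans(a, b, loci)
        assert out["n_loci"] == 1
        # rs2 has the lower uGAS p; its cGAS value (10) is the locus score
        assert out["per_locus"]["max_chi2_b"].iloc[0] == 10.0

    def test_empty_loci(self):
        out = nc.compare_scans([], [], [])
        assert out["n_loci"] == 0


class TestAssociationProfile:
    def test_profile_structure(self, small_dataset):
        gm, tm, net = small_dataset
        rec = next(r for r in nc.cgas_scan(tm, gm, net, trait_names=["y"])
                   if r.snp_id == "snp_causal")
        prof = nc.association_profile(tm, gm, "snp_causal", "y", list(rec.covariates))
        assert list(prof.index) == ["y", "snp_causal", *rec.covariates]
        np.testing.assert_allclose(np.diag(prof), 1.0, atol=1e-12)
        # upper-triangle correlation block is symmetric with the part of the
        # lower triangle not replaced by coefficients
        vals = prof.to_numpy()
        m = vals.shape[0]
        for i in range(1, m):
            for j in range(1, i):
                assert vals[i, j] == pytest.approx(vals[j, i], abs=1e-12)

    def test_first_column_holds_partial_coefficients(self, small_dataset):
        gm, tm, net = small_dataset
        rec = next(r for r in nc.cgas_scan(tm, gm, net, trait_names=["y"])
                   if r.snp_id == "snp_causal")
        prof = nc.association_profile(tm, gm, "snp_causal", "y", list(rec.covariates))
        assert prof.iloc[1, 0] == pytest.approx(rec.beta, abs=1e-12)
        np.testing.assert_allclose(prof.iloc[2:, 0], rec.covariate_betas, atol=1e-12)
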