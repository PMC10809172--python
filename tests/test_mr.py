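"""Two-sample MR: instrument selection, harmonization, Steiger filtering,
IVW/Egger/weighted-median estimation and the assumption checklist."""
import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from dietewas import mr


def make_instruments(rng, J=20, theta=0.2, n_exp=30_000, n_out=200_000,
                     pleiotropy_sd=0.0, intercept=0.0):
    """Harmonized instrument table generated under a known causal effect."""
    eaf = rng.uniform(0.1, 0.9, J)
    b_true = rng.uniform(0.05, 0.15, J) * rng.choice([-1.0, 1.0], J)
    se_exp = 1 / np.sqrt(2 * eaf * (1 - eaf) * n_exp)
    se_out = 1 / np.sqrt(2 * eaf * (1 - eaf) * n_out)
    b_exp = b_true + rng.standard_normal(J) * se_exp
    b_out = (theta * b_true + intercept * np.sign(b_true)
             + rng.standard_normal(J) * pleiotropy_sd
             + rng.standard_normal(J) * se_out)
    return pd.DataFrame({
        "snp": [f"rs{i}" for i in range(J)],
        "beta_exp": b_exp, "se_exp": se_exp,
        "beta_out": b_out, "se_out": se_out, "eaf": eaf,
        "palindromic": False, "F": (b_exp / se_exp) ** 2,
        "wald_ratio": b_out / b_exp,
    })


def _gwas_row(snp, ea, oa, eaf, beta, se=0.01, n=100_000):
    return {"snp": snp, "chr": 1, "pos": 1000, "effect_allele": ea,
            "other_allele": oa, "eaf": eaf, "beta": beta, "se": se,
            "p": 2 * stats.norm.sf(abs(beta / se)), "n": n}


class TestSelectInstruments:
    def _mqtl(self, ps):
        return pd.DataFrame([
            _gwas_row(f"rs{i}", "A", "G", 0.3, 0.1, se=0.01) | {"p": p}
            for i, p in enumerate(ps)])

    def test_high_ld_pair_keeps_smaller_p(self):
        mqtl = self._mqtl([1e-20, 1e-10])
        ld = pd.DataFrame([[1.0, 0.95], [0.95, 1.0]],
                          index=["rs0", "rs1"], columns=["rs0", "rs1"])
        kept = mr.select_instruments(mqtl, ld)
        assert list(kept["snp"]) == ["rs0"]

    def test_no_ld_all_pass(self):
        mqtl = self._mqtl([1e-20, 1e-10, 1e-12])
        ld = pd.DataFrame(np.eye(3), index=[f"rs{i}" for i in range(3)],
                          columns=[f"rs{i}" for i in range(3)])
        assert len(mr.select_instruments(mqtl, ld)) == 3

    def test_p_filter(self):
        mqtl = self._mqtl([1e-20, 1e-4])
        kept = mr.select_instruments(mqtl, None, p_max=1e-8)
        assert list(kept["snp"]) == ["rs0"]

    def test_greedy_equals_exhaustive_on_block_ld(self, rng):
        """Greedy best-p-first pruning reproduces the unique maximal set a
        brute-force search finds on block-structured LD."""
        J = 10
        ps = 10.0 ** -rng.uniform(9, 30, J)
        mqtl = self._mqtl(ps)
        r2 = np.eye(J)
        for a in range(0, J, 2):
            r2[a, a + 1] = r2[a + 1, a] = 0.9
        ld = pd.DataFrame(r2, index=mqtl["snp"], columns=mqtl["snp"])
        kept = set(mr.select_instruments(mqtl, ld)["snp"])
        # oracle: among all subsets with pairwise r2 < 0.8, the greedy-by-p
        # admissible one (take best p per block)
        want = set()
        for a in range(0, J, 2):
            pair = [a, a + 1]
            best = min(pair, key=lambda i: ps[i])
            want.add(f"rs{best}")
        assert kept == want
        for s1, s2 in itertools.combinations(kept, 2):
            assert ld.loc[s1, s2] < 0.8


class TestHarmonize:
    def _pair(self, out_ea, out_oa, out_beta=0.05, out_eaf=0.7, exp_ea="A",
              exp_oa="G", exp_eaf=0.3):
        exp = pd.DataFrame([_gwas_row("rs1", exp_ea, exp_oa, exp_eaf, 0.1)])
        out = pd.DataFrame([_gwas_row("rs1", out_ea, out_oa, out_eaf,
                                      out_beta)])
        return exp, out

    def test_swapped_alleles_flipped(self):
        exp, out = self._pair("G", "A")
        harm = mr.harmonize(exp, out)
        assert harm["beta_out"].iloc[0] == pytest.approx(-0.05)

    def test_incompatible_alleles_dropped(self):
        exp, out = self._pair("T", "C")
        assert mr.harmonize(exp, out).empty

    def test_palindromic_near_half_dropped(self):
        exp, out = self._pair("A", "T", exp_ea="A", exp_oa="T", exp_eaf=0.50)
        assert mr.harmonize(exp, out).empty

    def test_palindromic_skewed_kept(self):
        exp, out = self._pair("A", "T", exp_ea="A", exp_oa="T", exp_eaf=0.70)
        harm = mr.harmonize(exp, out)
        assert len(harm) == 1 and bool(harm["palindromic"].iloc[0])

    def test_allele_case_truth_table(self):
        """Enumerate aligned/swapped/incompatible cases on a mixed panel."""
        exp = pd.DataFrame([
            _gwas_row("rs1", "A", "G", 0.3, 0.10),
            _gwas_row("rs2", "C", "T", 0.4, -0.08),
            _gwas_row("rs3", "A", "C", 0.2, 0.12),
        ])
        out = pd.DataFrame([
            _gwas_row("rs1", "A", "G", 0.3, 0.05),    # aligned
            _gwas_row("rs2", "T", "C", 0.6, 0.02),    # swapped
            _gwas_row("rs3", "G", "T", 0.2, 0.01),    # incompatible
        ])
        harm = mr.harmonize(exp, out).set_index("snp")
        assert set(harm.index) == {"rs1", "rs2"}
        assert harm.loc["rs1", "beta_out"] == pytest.approx(0.05)
        assert harm.loc["rs2", "beta_out"] == pytest.approx(-0.02)
        assert harm.loc["rs1", "wald_ratio"] == pytest.approx(0.05 / 0.10)
        assert harm.loc["rs1", "F"] == pytest.approx((0.10 / 0.01) ** 2)

    def test_alignment_idempotent(self):
        exp = pd.DataFrame([
            _gwas_row("rs1", "A", "G", 0.3, 0.10),
            _gwas_row("rs2", "C", "T", 0.4, -0.08),
        ])
        out = pd.DataFrame([
            _gwas_row("rs1", "G", "A", 0.7, 0.05),
            _gwas_row("rs2", "C", "T", 0.4, 0.02),
        ])
        once = mr.align_outcome(exp, out)
        twice = mr.align_outcome(exp, once)
        pd.testing.assert_frame_equal(once.reset_index(drop=True),
                                      twice.reset_index(drop=True))

    def test_duplicate_snps_rejected(self):
        exp = pd.DataFrame([_gwas_row("rs1", "A", "G", 0.3, 0.1)] * 2)
        out = pd.DataFrame([_gwas_row("rs1", "A", "G", 0.3, 0.1)])
        with pytest.raises(ValueError, match="duplicate"):
            mr.harmonize(exp, out)


class TestSteiger:
    def _inst(self, z_exp, z_out):
        return pd.DataFrame({"snp": ["rs1"], "beta_exp": [z_exp * 0.01],
                             "se_exp": [0.01], "beta_out": [z_out * 0.01],
                             "se_out": [0.01], "eaf": [0.5],
                             "palindromic": [False]})

    def test_strong_exposure_kept(self):
        inst = self._inst(z_exp=12.0, z_out=1.0)
        assert len(mr.steiger_filter(inst, 30_000, 30_000)) == 1

    def test_equal_strength_tie_dropped(self):
        inst = self._inst(z_exp=5.0, z_out=5.0)
        assert mr.steiger_filter(inst, 30_000, 30_000).empty

    def test_reverse_causal_snp_removed(self):
        """A SNP acting on the outcome first (exposure effect flowing back
        through a weak reverse path) is removed in nearly every draw."""
        rng = np.random.default_rng(17)
        n_exp, n_out = 30_000, 200_000
        removed = 0
        for _ in range(200):
            se_e = 1 / np.sqrt(0.5 * n_exp)
            se_o = 1 / np.sqrt(0.5 * n_out)
            b_out_true = 0.1
            b_exp_true = 0.2 * b_out_true  # reverse path only
            inst = pd.DataFrame({
                "snp": ["rsX"],
                "beta_exp": [b_exp_true + rng.standard_normal() * se_e],
                "se_exp": [se_e],
                "beta_out": [b_out_true + rng.standard_normal() * se_o],
                "se_out": [se_o], "eaf": [0.5], "palindromic": [False]})
            removed += mr.steiger_filter(inst, n_exp, n_out).empty
        assert removed >= 190


class TestIvw:
    def test_constant_wald_ratio(self):
        inst = make_instruments(np.random.default_rng(0), J=5, theta=0.0,
                                n_out=10**9, n_exp=10**12)
        inst["beta_out"] = 0.25 * inst["beta_exp"]
        est = mr.ivw_mre(inst)
        assert est.beta == pytest.approx(0.25, abs=1e-10)

    def test_matches_weighted_regression_oracle(self, rng):
        inst = make_instruments(rng, J=7, pleiotropy_sd=0.05)
        est = mr.ivw_mre(inst)
        w = 1 / inst["se_out"] ** 2
        bx, by = inst["beta_exp"], inst["beta_out"]
        beta = np.sum(w * bx * by) / np.sum(w * bx ** 2)
        Q = np.sum(w * (by - beta * bx) ** 2)
        se = np.sqrt(1 / np.sum(w * bx ** 2)) * np.sqrt(max(1, Q / 6))
        assert est.beta == pytest.approx(beta, abs=1e-12)
        assert est.se == pytest.approx(se, abs=1e-12)

    def test_exposure_rescaling_invariance(self, rng):
        inst = make_instruments(rng)
        est = mr.ivw_mre(inst)
        scaled = inst.copy()
        scaled["beta_exp"] *= 4.0
        scaled["se_exp"] *= 4.0
        est2 = mr.ivw_mre(scaled)
        assert est2.beta == pytest.approx(est.beta / 4.0)
        assert est2.p == pytest.approx(est.p)

    def test_theta_recovered_within_two_se(self):
        inside = 0
        rng = np.random.default_rng(100)
        for _ in range(200):
            est = mr.ivw_mre(make_instruments(rng))
            inside += abs(est.beta - 0.2) <= 2 * est.se
        assert inside / 200 >= 0.93

    def test_type_i_error_under_null(self):
        rng = np.random.default_rng(200)
        rej = sum(mr.ivw_mre(make_instruments(rng, theta=0.0)).p < 0.05
                  for _ in range(500))
        assert 0.03 <= rej / 500 <= 0.07

    def test_too_few_instruments(self):
        inst = make_instruments(np.random.default_rng(0), J=5).iloc[:1]
        with pytest.raises(ValueError):
            mr.ivw_mre(inst)


class TestEgger:
    def test_proportional_data_zero_intercept(self, rng):
        inst = make_instruments(rng, J=10, n_out=10**9, n_exp=10**12)
        inst["beta_out"] = 0.3 * inst["beta_exp"]
        fit = mr.mr_egger(inst)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.slope == pytest.approx(0.3, abs=1e-10)
        assert fit.Q_rucker == pytest.approx(0.0, abs=1e-8)

    def test_matches_wls_oracle(self, rng):
        inst = make_instruments(rng, J=12, pleiotropy_sd=0.05)
        fit = mr.mr_egger(inst)
        flip = np.sign(inst["beta_exp"])
        bx = inst["beta_exp"] * flip
        by = inst["beta_out"] * flip
        w = 1 / inst["se_out"] ** 2
        wls = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
        assert fit.intercept == pytest.approx(wls.params.iloc[0], abs=1e-10)
        assert fit.slope == pytest.approx(wls.params.iloc[1], abs=1e-10)
        # with phi > 1 the dispersion-scaled SEs match the WLS ones
        if fit.Q_rucker / 10 > 1:
            assert fit.slope_se == pytest.approx(wls.bse.iloc[1], rel=1e-8)

    def test_detects_planted_directional_pleiotropy(self):
        rng = np.random.default_rng(300)
        power = sum(
            mr.mr_egger(make_instruments(rng, J=50, intercept=0.05)).intercept_p
            < 0.05 for _ in range(100))
        assert power / 100 >= 0.8
        # and the intercept estimate is near the planted 0.05
        rng = np.random.default_rng(300)
        ests = [mr.mr_egger(make_instruments(rng, J=50, intercept=0.05)).intercept
                for _ in range(50)]
        assert np.mean(ests) == pytest.approx(0.05, abs=0.01)


class TestWeightedMedian:
    def test_symmetric_ratios(self):
        inst = pd.DataFrame({
            "snp": ["a", "b", "c"], "beta_exp": [1.0, 1.0, 1.0],
            "se_exp": [0.01] * 3, "beta_out": [1.0, 2.0, 3.0],
            "se_out": [0.1] * 3, "eaf": [0.5] * 3, "palindromic": [False] * 3})
        est = mr.weighted_median(inst, n_boot=50, seed=1)
        assert est.beta == pytest.approx(2.0)

    def test_robust_to_single_outlier(self, rng):
        inst = make_instruments(rng, J=10, theta=0.2, n_out=10**7)
        inst.loc[0, "beta_out"] = 50.0 * inst.loc[0, "beta_exp"]
        est = mr.weighted_median(inst, n_boot=100, seed=2)
        assert abs(est.beta - 0.2) < 0.05

    def test_matches_cumulative_weight_oracle(self, rng):
        inst = make_instruments(rng, J=9)
        est = mr.weighted_median(inst, n_boot=10, seed=0)
        ratios = (inst["beta_out"] / inst["beta_exp"]).to_numpy()
        w = (inst["beta_exp"] ** 2 / inst["se_out"] ** 2).to_numpy()
        order = np.argsort(ratios)
        cum = (np.cumsum(w[order]) - 0.5 * w[order]) / w.sum()
        want = float(np.interp(0.5, cum, ratios[order]))
        assert est.beta == pytest.approx(want, abs=1e-12)

    def test_same_seed_same_se(self, rng):
        inst = make_instruments(rng)
        a = mr.weighted_median(inst, n_boot=200, seed=42)
        b = mr.weighted_median(inst, n_boot=200, seed=42)
        assert a.se == b.se


class TestCochranQAndChecks:
    def test_perfect_proportionality_q_zero(self, rng):
        inst = make_instruments(rng, J=8)
        inst["beta_out"] = 0.2 * inst["beta_exp"]
        Q, p = mr.cochran_q(inst, 0.2)
        assert Q == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_matches_formula_oracle(self, rng):
        inst = make_instruments(rng, J=8, pleiotropy_sd=0.03)
        est = mr.ivw_mre(inst)
        Q, p = mr.cochran_q(inst, est.beta)
        w = 1 / inst["se_out"] ** 2
        want = np.sum(w * (inst["beta_out"] - est.beta * inst["beta_exp"]) ** 2)
        assert Q == pytest.approx(want, abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(want, 7), abs=1e-12)

    def test_planted_heterogeneity_detected(self):
        rng = np.random.default_rng(400)
        power = 0
        for _ in range(100):
            inst = make_instruments(rng, J=20, pleiotropy_sd=0.02)
            est = mr.ivw_mre(inst)
            power += mr.cochran_q(inst, est.beta)[1] < 0.05
        assert power / 100 >= 0.8

    def test_strength_boundary_strict(self):
        ivw = mr.MREstimate(0.2, 0.05, 1e-4, 5)
        checks, valid = mr.assess_assumptions(ivw, None, None, 0.5, mean_F=10.0)
        assert checks["strength_ok"] is False
        assert checks["egger_intercept_ok"] is None
        assert not valid

    def test_clean_simulation_mostly_valid(self):
        """With precise instruments, all assumption checks pass in >= 90% of
        draws (noisy instruments legitimately trip the Q tests, since IVW
        weights ignore exposure-side noise)."""
        rng = np.random.default_rng(500)
        n_valid = 0
        for i in range(100):
            inst = make_instruments(rng, n_exp=300_000)
            est = mr.ivw_mre(inst)
            _, p_qc = mr.cochran_q(inst, est.beta)
            egger = mr.mr_egger(inst)
            wm = mr.weighted_median(inst, n_boot=100, seed=i)
            _, valid = mr.assess_assumptions(est, egger, wm, p_qc,
                                             float(inst["F"].mean()))
            n_valid += valid
        assert n_valid >= 90

    def test_pleiotropy_flags_invalid(self):
        rng = np.random.default_rng(600)
        flagged = 0
        for i in range(50):
            inst = make_instruments(rng, J=50, intercept=0.05)
            est = mr.ivw_mre(inst)
            _, p_qc = mr.cochran_q(inst, est.beta)
            egger = mr.mr_egger(inst)
            wm = mr.weighted_median(inst, n_boot=50, seed=i)
            checks, valid = mr.assess_assumptions(est, egger, wm, p_qc,
                                                  float(inst["F"].mean()))
            flagged += not checks["egger_intercept_ok"]
        assert flagged / 50 >= 0.8


class TestRunMr:
    def test_binary_outcome_reports_odds_ratio(self, rng):
        inst = make_instruments(rng)
        est = mr.ivw_mre(inst)
        res = mr.MRResult("cg1", "T2D", est.n_snps, est, None, None,
                          binary=True)
        orr, lo, hi = res.odds_ratio()
        assert orr == pytest.approx(np.exp(est.beta))
        assert lo < orr < hi
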