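"""Two-sample MR estimators against independently coded oracles, plus
their invariance and distributional properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hcymr.containers import HarmonizedInstrument, ValidationError
from hcymr.instruments import harmonize
from hcymr.onesample import wald_ratio
from hcymr.synthdata import simulate_summary_stats
from hcymr.twosample import (cochran_q, i2_gx, ivw, meta_fixed, mr_egger,
                             run_twosample, weighted_median)

from conftest import make_instruments


# ---------------------------------------------------------------------
# independent brute-force oracles (kept deliberately naive)
# ---------------------------------------------------------------------

def oracle_ivw(instr):
    """Weighted least squares of beta_y on beta_x through the origin."""
    w = np.array([1 / i.se_y ** 2 for i in instr])
    x = np.array([i.beta_x for i in instr])
    y = np.array([i.beta_y for i in instr])
    A = (np.sqrt(w) * x)[:, None]
    b = np.sqrt(w) * y
    slope = np.linalg.lstsq(A, b, rcond=None)[0][0]
    se = np.sqrt(1.0 / np.sum(w * x * x))
    return slope, se


def oracle_egger(instr):
    """Normal equations of the weighted regression with free intercept."""
    instr = [i if i.beta_x >= 0 else
             HarmonizedInstrument(i.snp_id, -i.beta_x, i.se_x,
                                  -i.beta_y, i.se_y)
             for i in instr]
    w = np.array([1 / i.se_y ** 2 for i in instr])
    x = np.array([i.beta_x for i in instr])
    y = np.array([i.beta_y for i in instr])
    sw = np.sqrt(w)
    A = np.column_stack([sw, sw * x])
    coef, *_ = np.linalg.lstsq(A, sw * y, rcond=None)
    resid = sw * y - A @ coef
    k = len(instr)
    phi = max(1.0, float(resid @ resid) / (k - 2))
    cov = np.linalg.inv(A.T @ A) * phi
    return coef[0], coef[1], np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1])


def oracle_weighted_median(instr):
    """CDF interpolation done with numpy.interp on midpoint weights."""
    r = np.array([i.beta_y / i.beta_x for i in instr])
    w = np.array([i.beta_x ** 2 / i.se_y ** 2 for i in instr])
    order = np.argsort(r)
    r, w = r[order], w[order] / w.sum()
    s = np.cumsum(w) - w / 2
    return float(np.interp(0.5, s, r))


def oracle_cochran_q(instr, theta):
    q = 0.0
    for i in instr:
        q += (i.beta_x ** 2 / i.se_y ** 2) * \
            (i.beta_y / i.beta_x - theta) ** 2
    return q


def oracle_i2_gx(instr):
    bx = np.abs(np.array([i.beta_x for i in instr]))
    sx = np.array([i.se_x for i in instr])
    w = 1 / sx ** 2
    mean = np.sum(w * bx) / np.sum(w)
    q = np.sum(((bx - mean) / sx) ** 2)
    return max(0.0, (q - (len(instr) - 1)) / q)


def oracle_meta(betas, ses):
    w = [1 / s ** 2 for s in ses]
    pooled = sum(wi * bi for wi, bi in zip(w, betas)) / sum(w)
    return pooled, sum(w) ** -0.5


# ---------------------------------------------------------------------


class TestMetaFixed:
    @staticmethod
    def _cohort(ids, betas, ses, ea="A", oa="G"):
        return pd.DataFrame({
            "snp_id": ids, "effect_allele": ea, "other_allele": oa,
            "beta": betas, "se": ses, "p": 0.5, "n": 4000,
            "trait": "outcome"})

    def test_identical_cohorts_closed_form(self):
        t = self._cohort(["a"], [0.1], [0.2])
        res = meta_fixed([t, t.copy()])
        assert res["beta"][0] == pytest.approx(0.1)
        assert res["se"][0] == pytest.approx(0.2 / np.sqrt(2))

    def test_symmetric_betas_pool_to_zero(self):
        res = meta_fixed([self._cohort(["a"], [0.1], [0.2]),
                          self._cohort(["a"], [-0.1], [0.2])])
        assert res["beta"][0] == pytest.approx(0.0, abs=1e-15)

    def test_swapped_alleles_flipped_before_pooling(self):
        res = meta_fixed([self._cohort(["a"], [0.1], [0.2]),
                          self._cohort(["a"], [-0.1], [0.2],
                                       ea="G", oa="A")])
        assert res["beta"][0] == pytest.approx(0.1)

    def test_irreconcilable_alleles_raise(self):
        with pytest.raises(ValidationError, match="mismatch"):
            meta_fixed([self._cohort(["a"], [0.1], [0.2]),
                        self._cohort(["a"], [0.1], [0.2], ea="A", oa="C")])

    def test_matches_bruteforce_weighted_mean(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            betas = rng.normal(0, 0.2, 3)
            ses = rng.uniform(0.05, 0.3, 3)
            tables = [self._cohort(["x"], [b], [s])
                      for b, s in zip(betas, ses)]
            res = meta_fixed(tables)
            eb, es = oracle_meta(betas, ses)
            assert res["beta"][0] == pytest.approx(eb, rel=1e-12)
            assert res["se"][0] == pytest.approx(es, rel=1e-12)


class TestIVW:
    def test_single_instrument_reduces_to_wald_ratio(self):
        i = HarmonizedInstrument("a", 0.04, 0.005, 0.03, 0.02)
        res = ivw([i])
        wr = wald_ratio(i.beta_x, 0.0, i.beta_y, i.se_y)
        assert res.estimate == pytest.approx(wr.estimate, rel=1e-12)
        assert res.se == pytest.approx(i.se_y / abs(i.beta_x), rel=1e-12)

    def test_equal_ratios_give_exact_theta_and_zero_q(self):
        instr = [HarmonizedInstrument(f"s{j}", bx, 0.01, 0.7 * bx, 0.02)
                 for j, bx in enumerate((0.1, 0.2, 0.3))]
        res = ivw(instr)
        assert res.estimate == pytest.approx(0.7, rel=1e-12)
        assert res.diagnostics["Q"] == pytest.approx(0.0, abs=1e-20)

    def test_matches_wls_through_origin_oracle(self):
        for seed in range(30):
            instr = make_instruments(k=5 + seed % 10, seed=seed)
            res = ivw(instr)
            slope, se = oracle_ivw(instr)
            assert res.estimate == pytest.approx(slope, rel=1e-10)
            assert res.se == pytest.approx(se, rel=1e-10)

    def test_random_effects_widens_se_under_heterogeneity(self):
        instr = make_instruments(k=10, seed=3, alpha_sd=0.1)
        fixed = ivw(instr, "fixed")
        rand = ivw(instr, "multiplicative_random")
        assert rand.se >= fixed.se
        assert rand.estimate == pytest.approx(fixed.estimate)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ivw([])


class TestWeightedMedian:
    def test_three_equal_weights_middle_ratio(self):
        instr = [HarmonizedInstrument(f"s{j}", 0.1, 0.01, r * 0.1, 0.02)
                 for j, r in enumerate((0.1, 0.7, 2.0))]
        res = weighted_median(instr, n_boot=50, seed=0)
        assert res.estimate == pytest.approx(0.7, rel=1e-12)

    def test_dominant_instrument_bounds(self):
        # one SNP with most of the weight: the interpolated estimate is
        # bracketed by its ratio and the adjacent ratio, converging to
        # the dominant ratio as its weight share grows
        def est(w_dom):
            se_dom = 0.1 / np.sqrt(w_dom)
            instr = [HarmonizedInstrument("dom", 0.1, 0.001, 0.05, se_dom),
                     HarmonizedInstrument("o1", 0.1, 0.001, 0.2, 0.1),
                     HarmonizedInstrument("o2", 0.1, 0.001, 0.3, 0.1)]
            return weighted_median(instr, n_boot=10, seed=1).estimate

        e = est(3.0)  # 60% of total weight
        assert 0.5 <= e <= 2.0 + 1e-9
        assert abs(est(50.0) - 0.5) < abs(e - 0.5)  # -> dominant ratio

    def test_matches_interp_oracle(self):
        for seed in range(30):
            instr = make_instruments(k=3 + seed % 12, seed=100 + seed)
            res = weighted_median(instr, n_boot=10, seed=seed)
            assert res.estimate == pytest.approx(
                oracle_weighted_median(instr), rel=1e-12)

    def test_estimate_within_ratio_range(self):
        for seed in range(20):
            instr = make_instruments(k=7, seed=200 + seed, alpha_sd=0.3)
            ratios = [i.beta_y / i.beta_x for i in instr]
            est = weighted_median(instr, n_boot=10, seed=seed).estimate
            assert min(ratios) - 1e-12 <= est <= max(ratios) + 1e-12

    def test_bootstrap_se_reproducible(self):
        instr = make_instruments(k=6, seed=9)
        a = weighted_median(instr, n_boot=200, seed=42)
        b = weighted_median(instr, n_boot=200, seed=42)
        assert a.se == b.se

    def test_k_below_three_rejected(self):
        with pytest.raises(ValidationError):
            weighted_median(make_instruments(k=2, seed=1))


class TestMREgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        instr = [HarmonizedInstrument(f"s{j}", b, 0.01, 0.05 + 0.7 * b, 0.02)
                 for j, b in enumerate(bx)]
        res = mr_egger(instr)
        assert res.estimate == pytest.approx(0.7, rel=1e-10)
        assert res.diagnostics["egger_intercept"] == pytest.approx(
            0.05, rel=1e-10)

    def test_matches_normal_equations_oracle(self):
        for seed in range(30):
            instr = make_instruments(k=4 + seed % 10, seed=300 + seed,
                                     alpha_sd=0.05)
            res = mr_egger(instr)
            b0, b1, se0, se1 = oracle_egger(instr)
            assert res.estimate == pytest.approx(b1, rel=1e-10)
            assert res.diagnostics["egger_intercept"] == pytest.approx(
                b0, rel=1e-10)
            assert res.se == pytest.approx(se1, rel=1e-10)
            assert res.diagnostics["intercept_se"] == pytest.approx(
                se0, rel=1e-10)

    def test_zero_intercept_constraint_equals_ivw(self):
        # refitting with the intercept forced to zero is exactly IVW
        instr = make_instruments(k=8, seed=7)
        slope, _ = oracle_ivw(instr)
        assert ivw(instr).estimate == pytest.approx(slope, rel=1e-12)

    def test_k_two_rejected(self):
        with pytest.raises(ValidationError):
            mr_egger(make_instruments(k=2, seed=2))


class TestCochranQ:
    def test_equal_ratios_zero(self):
        instr = [HarmonizedInstrument(f"s{j}", b, 0.01, 0.5 * b, 0.02)
                 for j, b in enumerate((0.1, 0.2, 0.3))]
        q, df, p = cochran_q(instr, 0.5)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert (df, p) == (2, 1.0)

    def test_matches_bruteforce_sum(self):
        for seed in range(30):
            instr = make_instruments(k=3 + seed % 8, seed=400 + seed,
                                     alpha_sd=0.1)
            theta = ivw(instr).estimate
            q, df, p = cochran_q(instr, theta)
            assert q == pytest.approx(oracle_cochran_q(instr, theta),
                                      rel=1e-12)
            assert p == pytest.approx(float(sps.chi2.sf(q, df)), rel=1e-12)

    def test_permutation_invariant(self):
        instr = make_instruments(k=9, seed=11, alpha_sd=0.1)
        theta = 0.6
        q1, *_ = cochran_q(instr, theta)
        q2, *_ = cochran_q(instr[::-1], theta)
        assert q1 == pytest.approx(q2, rel=1e-14)


class TestI2GX:
    def test_identical_betas_zero(self):
        instr = [HarmonizedInstrument(f"s{j}", 0.2, 0.01, 0.1, 0.05)
                 for j in range(5)]
        assert i2_gx(instr) == 0.0

    def test_precise_betas_approach_one(self):
        instr = [HarmonizedInstrument(f"s{j}", bx, 1e-8, 0.1, 0.05)
                 for j, bx in enumerate((0.1, 0.2, 0.3))]
        assert i2_gx(instr) > 0.999999

    def test_matches_bruteforce_formula(self):
        for seed in range(30):
            instr = make_instruments(k=3 + seed % 10, seed=500 + seed)
            assert i2_gx(instr) == pytest.approx(oracle_i2_gx(instr),
                                                 rel=1e-12)

    def test_in_unit_interval(self):
        for seed in range(20):
            v = i2_gx(make_instruments(k=6, seed=600 + seed))
            assert 0.0 <= v < 1.0


class TestAlleleRecodingInvariance:
    def test_all_estimators_invariant_to_joint_sign_flips(self):
        instr = make_instruments(k=9, seed=13, alpha_sd=0.05)
        rng = np.random.default_rng(13)
        flipped = [
            HarmonizedInstrument(i.snp_id, -i.beta_x, i.se_x, -i.beta_y,
                                 i.se_y) if rng.random() < 0.5 else i
            for i in instr]
        assert ivw(flipped).estimate == pytest.approx(
            ivw(instr).estimate, rel=1e-12)
        assert weighted_median(flipped, n_boot=10, seed=1).estimate == \
            pytest.approx(weighted_median(instr, n_boot=10, seed=1).estimate,
                          rel=1e-12)
        assert mr_egger(flipped).estimate == pytest.approx(
            mr_egger(instr).estimate, rel=1e-12)
        assert i2_gx(flipped) == pytest.approx(i2_gx(instr), rel=1e-12)

    def test_instrument_permutation_invariance(self):
        instr = make_instruments(k=8, seed=14, alpha_sd=0.05)
        perm = instr[::-1]
        assert ivw(perm).estimate == pytest.approx(ivw(instr).estimate,
                                                   rel=1e-13)
        assert mr_egger(perm).estimate == pytest.approx(
            mr_egger(instr).estimate, rel=1e-12)
        assert weighted_median(perm, n_boot=10, seed=2).estimate == \
            pytest.approx(weighted_median(instr, n_boot=10, seed=2).estimate,
                          rel=1e-13)


class TestNullCalibration:
    def test_ivw_z_standard_normal_under_null(self):
        # theta = 0, no pleiotropy: downstream IVW z-statistics are
        # standard normal (KS test over 500 replicates)
        zs = []
        freqs = np.linspace(0.25, 0.45, 8)
        betas = np.linspace(0.03, 0.06, 8)
        for r in range(500):
            exp, outs = simulate_summary_stats(
                freqs, betas, theta=0.0, n_exposure=20_000,
                n_outcome=(10_000,), seed=50_000 + r)
            instr, _ = harmonize(exp, outs[0])
            res = ivw(instr)
            zs.append(res.estimate / res.se)
        p = sps.kstest(zs, "norm").pvalue
        assert p > 0.01

    def test_egger_intercept_null_size(self):
        # balanced pleiotropy (zero intercept): rejection near 5%
        rej = 0
        reps = 400
        for r in range(reps):
            instr = make_instruments(k=15, seed=70_000 + r)
            rej += mr_egger(instr).diagnostics["intercept_p"] < 0.05
        assert 0.02 <= rej / reps <= 0.09


class TestRunTwosample:
    def test_report_structure_and_coverage(self):
        freqs = np.linspace(0.2, 0.5, 10)
        betas = np.linspace(0.03, 0.06, 10)
        exp, outs = simulate_summary_stats(
            freqs, betas, theta=0.7, n_exposure=50_000,
            n_outcome=(20_000, 20_000), seed=77)
        report = run_twosample(exp, outs, n_boot=100, seed=1)
        table = report["table"]
        assert list(table["method"]) == ["weighted_median", "ivw",
                                         "mr_egger"]
        assert np.isfinite(table[["beta", "se", "p"]].to_numpy()).all()
        d = report["diagnostics"]
        assert d["Q_df"] == 9
        assert 0 <= d["i2_gx"] < 1
        ivw_row = table[table["method"] == "ivw"].iloc[0]
        assert ivw_row["ci_low"] < 0.7 < ivw_row["ci_high"]

    def test_directional_pleiotropy_detected_at_k25(self):
        # theta = 0 with strong directional pleiotropy: IVW biased away
        # from zero, Egger intercept test powered
        freqs = np.linspace(0.2, 0.5, 25)
        betas = np.linspace(0.03, 0.06, 25)
        alpha = np.full(25, 0.15)
        biased, detected = [], 0
        reps = 60
        for r in range(reps):
            exp, outs = simulate_summary_stats(
                freqs, betas, theta=0.0, alpha_pleiotropy=alpha,
                n_exposure=50_000, n_outcome=(20_000,), seed=90_000 + r)
            instr, _ = harmonize(exp, outs[0])
            biased.append(ivw(instr).estimate)
            detected += mr_egger(instr).diagnostics["intercept_p"] < 0.05
        assert abs(np.mean(biased)) > 0.3
        assert detected / reps > 0.5

    def test_too_few_instruments_rejected(self):
        exp, outs = simulate_summary_stats([0.3, 0.4], [0.05, 0.04], 0.7,
                                           seed=5)
        with pytest.raises(ValidationError, match="instruments"):
            run_twosample(exp, outs)
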