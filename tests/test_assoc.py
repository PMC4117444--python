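"""Inverse-normal transform, regression models, screening, biomarker tests."""

import numpy as np
import pytest
from scipy import stats

import founderscan as fs
from founderscan.assoc import AssociationError, homozygote_fisher_test


def _toy_cohort(n=400, q=0.2, seed=0):
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, q, size=n).astype(np.int8)
    sex = rng.choice(["male", "female"], size=n)
    age = rng.uniform(25, 74, size=n)
    return dosage, sex, age, rng


class TestIntTransform:
    def test_standard_normal_contract(self):
        dosage, sex, age, rng = _toy_cohort(2000)
        y = 0.02 * age + rng.normal(size=2000)
        z = fs.int_transform(y, sex, age)
        for s in ("male", "female"):
            zi = z[sex == s]
            assert abs(zi.mean()) < 1e-6
            assert zi.std(ddof=0) == pytest.approx(1.0, rel=0.02)

    def test_blom_quantiles_three_values(self):
        """Three distinct residuals map to the Blom quantiles of
        (0.1923, 0.5, 0.8077) = (-0.8694, 0, 0.8694)."""
        y = [10.0, 20.0, 30.0] + list(np.linspace(0, 1, 12))
        sex = ["f"] * 3 + ["m"] * 12
        age = [50.0] * 15
        z = fs.int_transform(y, sex, age, min_stratum=3)
        assert np.allclose(np.sort(z[:3]), [-0.8694, 0.0, 0.8694], atol=1e-4)

    def test_monotone_invariance(self):
        """Any monotone transform of the trait leaves the z-scores unchanged
        when covariates are constant (ranks are all that matter)."""
        dosage, sex, age, rng = _toy_cohort(300, seed=2)
        y = rng.normal(size=300)
        const_age = np.full(300, 50.0)
        z1 = fs.int_transform(y, sex, const_age)
        z2 = fs.int_transform(np.exp(3 * y), sex, const_age)
        assert np.allclose(z1, z2, atol=1e-10)

    def test_rank_order_preserved(self):
        sex = np.array(["m"] * 40)
        age = np.full(40, 50.0)
        y = np.random.default_rng(3).normal(size=40)
        z = fs.int_transform(y, sex, age)
        assert np.array_equal(np.argsort(y), np.argsort(z))

    def test_constant_trait_rejected(self):
        with pytest.raises(AssociationError):
            fs.int_transform([1.0] * 20, ["m"] * 20, [50.0] * 20)

    def test_small_stratum_rejected(self):
        with pytest.raises(AssociationError):
            fs.int_transform([1.0, 2.0], ["m", "m"], [50.0, 50.0])


class TestLinear:
    def test_matches_closed_form_ols(self):
        """Six-sample fixture equals the hand OLS formulas."""
        d = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        y = np.array([0.1, -0.1, 0.5, 0.3, 1.1, 0.9])
        r = fs.linear_assoc(d, y)
        sxx = ((d - d.mean()) ** 2).sum()
        slope = ((d - d.mean()) * (y - y.mean())).sum() / sxx
        resid = y - (y.mean() + slope * (d - d.mean()))
        se = np.sqrt(resid @ resid / (len(d) - 2) / sxx)
        assert r.effect == pytest.approx(slope, rel=1e-10)
        assert r.se == pytest.approx(se, rel=1e-10)
        assert r.p == pytest.approx(2 * stats.t.sf(abs(slope / se), 4), rel=1e-10)

    def test_null_p_uniform_over_permutations(self):
        """Permuting dosages under the null gives uniform p (KS at alpha=0.01)."""
        dosage, sex, age, rng = _toy_cohort(50, seed=5)
        y = rng.normal(size=50)
        ps = []
        for _ in range(500):
            perm = rng.permutation(dosage)
            if np.ptp(perm) == 0:
                continue
            ps.append(fs.linear_assoc(perm, y).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_missing_dosages_dropped(self):
        d = np.array([0, 1, 2, -1, -1, 1, 0, 2], dtype=float)
        y = np.arange(8, dtype=float)
        r = fs.linear_assoc(d, y)
        assert r.n == 6

    def test_zero_variance_signalled(self):
        with pytest.raises(AssociationError):
            fs.linear_assoc([1, 1, 1, 1], [0.1, 0.2, 0.3, 0.4])


class TestLogistic:
    def test_null_log_or_near_zero(self):
        """Equal case fractions per genotype group give log-OR ~ 0."""
        d = np.repeat([0, 1, 2], 200)
        case = np.tile([0, 1], 300)
        r = fs.logistic_assoc(d, case)
        assert abs(r.effect) < 3 * r.se

    def test_matches_cross_product_ratio(self):
        """Without covariates, the allele-level 2x2 log cross-product ratio is
        recovered (dosage coding makes the logit linear in allele count)."""
        rng = np.random.default_rng(8)
        n = 4000
        d = rng.binomial(2, 0.3, size=n)
        logit = -1.0 + 0.5 * d
        case = rng.random(n) < 1 / (1 + np.exp(-logit))
        r = fs.logistic_assoc(d, case)
        assert r.effect == pytest.approx(0.5, abs=3 * r.se)

    def test_one_class_rejected(self):
        with pytest.raises(AssociationError):
            fs.logistic_assoc([0, 1, 2, 1], [1, 1, 1, 1])


class TestCox:
    def test_null_hr_ci_coverage(self):
        """Identical event processes across genotypes: 95% CI covers HR=1 in
        >=93% of 200 replicates."""
        covered = 0
        for k in range(200):
            rng = np.random.default_rng(k)
            d = rng.binomial(2, 0.3, size=150)
            t = rng.exponential(1.0, size=150)
            event = (t < 1.5).astype(int)
            t = np.minimum(t, 1.5)
            if np.ptp(d) == 0 or event.sum() == 0:
                continue
            r = fs.cox_assoc(d, event, t)
            covered += (r.effect - 1.96 * r.se) <= 0 <= (r.effect + 1.96 * r.se)
        assert covered / 200 >= 0.93

    def test_matches_brute_force_partial_likelihood(self):
        """Small uncensored two-group fixture equals direct maximization of
        the Breslow partial likelihood."""
        rng = np.random.default_rng(11)
        d = np.array([0] * 8 + [1] * 8, dtype=float)
        t = np.concatenate([rng.exponential(1.0, 8), rng.exponential(0.5, 8)])
        event = np.ones(16)

        def neg_breslow(beta):
            order = np.argsort(t)
            ts, ds = t[order], d[order]
            ll = 0.0
            for i in range(len(ts)):
                risk = ds[i:]  # everyone with time >= ts[i]
                ll += beta * ds[i] - np.log(np.exp(beta * risk).sum())
            return -ll

        from scipy.optimize import minimize_scalar

        opt = minimize_scalar(neg_breslow, bounds=(-4, 4), method="bounded")
        r = fs.cox_assoc(d, event, t, ties="breslow")
        assert r.effect == pytest.approx(opt.x, abs=1e-4)

    def test_agrees_with_lifelines_efron(self):
        """Independent fit through lifelines (Efron ties) agrees."""
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(13)
        n = 500
        d = rng.binomial(2, 0.25, size=n).astype(float)
        t = rng.exponential(np.exp(-0.4 * d))
        event = (t < 1.0).astype(int)
        t = np.minimum(t, 1.0)
        ours = fs.cox_assoc(d, event, t, ties="efron")
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": event, "d": d}), duration_col="t", event_col="e"
        )
        assert ours.effect == pytest.approx(float(cph.params_["d"]), rel=1e-4)
        assert ours.se == pytest.approx(float(cph.standard_errors_["d"]), rel=1e-3)

    def test_rare_event_matches_logistic(self):
        """With <=5% events, Cox log-HR and logistic log-OR agree within 10%."""
        rng = np.random.default_rng(17)
        n = 20_000
        d = rng.binomial(2, 0.2, size=n).astype(float)
        base = 0.03
        p_event = base * np.exp(0.5 * d)
        event = rng.random(n) < p_event
        t = np.where(event, rng.uniform(0, 10, n), 10.0)
        cox = fs.cox_assoc(d, event.astype(int), t)
        logit = fs.logistic_assoc(d, event.astype(int))
        assert cox.effect == pytest.approx(logit.effect, rel=0.10)

    def test_no_events_signalled(self):
        with pytest.raises(AssociationError):
            fs.cox_assoc([0, 1, 2], [0, 0, 0], [1.0, 2.0, 3.0])


class TestScreen:
    def test_chance_and_bonferroni_arithmetic(self):
        report = fs.screen_all([], n_variants=80, n_traits=60)
        assert report["expected_chance_hits"] == pytest.approx(0.96)
        assert round(report["expected_chance_hits"]) == 1
        assert report["bonferroni_threshold"] == pytest.approx(0.05 / 4800)
        assert float(f"{report['bonferroni_threshold']:.0e}") == pytest.approx(1e-5)

    def test_hits_listed_and_flagged(self):
        results = [
            fs.AssocResult("v1", "t1", 100, 0.5, 0.1, 1e-7, "linear"),
            fs.AssocResult("v2", "t1", 100, 0.1, 0.1, 0.3, "linear"),
            fs.AssocResult("v3", "t2", 100, 0.3, 0.1, 1e-4, "linear"),
        ]
        report = fs.screen_all(results, n_variants=80, n_traits=60)
        assert report["n_hits"] == 2
        assert [h["variant_id"] for h in report["hits"]] == ["v1", "v3"]
        assert report["hits"][0]["study_wide_significant"]
        assert not report["hits"][1]["study_wide_significant"]

    def test_null_scan_hit_count_poisson(self):
        """A global-null scan yields p<2e-4 hits within the central 99%
        Poisson(expected) interval."""
        rng = np.random.default_rng(23)
        n_tests = 4800
        # under the null each test's p is U(0,1): simulate the scan outcome
        hits = sum(
            fs.linear_assoc(rng.binomial(2, 0.3, 60), rng.normal(size=60)).p < 2e-4
            for _ in range(300)
        )
        lam = 300 * 2e-4
        assert hits <= stats.poisson.ppf(0.995, lam)


class TestBiomarkerDisease:
    def test_null_tails_complementary_and_centered(self):
        """Under the null the two one-sided p-values sum to 1 and are
        uniform, so their mean over replicates sits at 0.5."""
        rng = np.random.default_rng(29)
        his = []
        for _ in range(200):
            y = rng.normal(size=200)
            case = rng.random(200) < 0.3
            hi, lo = fs.biomarker_disease_test(y, case)
            assert hi + lo == pytest.approx(1.0, abs=1e-9)
            his.append(hi)
        assert np.mean(his) == pytest.approx(0.5, abs=3 * np.sqrt(1 / 12 / 200))

    def test_matches_hand_welch(self):
        a = np.array([1.2, 0.8, 1.5, 1.1, 0.9, 1.3])
        b = np.array([0.5, 0.7, 0.4, 0.6, 0.8])
        hi, lo = fs.biomarker_disease_test(np.concatenate([a, b]), [1] * 6 + [0] * 5)
        se = np.sqrt(a.var(ddof=1) / 6 + b.var(ddof=1) / 5)
        tstat = (a.mean() - b.mean()) / se
        df = (a.var(ddof=1) / 6 + b.var(ddof=1) / 5) ** 2 / (
            (a.var(ddof=1) / 6) ** 2 / 5 + (b.var(ddof=1) / 5) ** 2 / 4
        )
        assert hi == pytest.approx(stats.t.sf(tstat, df), rel=1e-8)
        assert lo == pytest.approx(stats.t.cdf(tstat, df), rel=1e-8)

    def test_direction_consistency(self):
        rng = np.random.default_rng(31)
        y = rng.normal(size=500)
        case = rng.random(500) < 0.4
        hi, lo = fs.biomarker_disease_test(y, case)
        diff = y[case].mean() - y[~case].mean()
        assert (hi < 0.5) == (diff > 0)


class TestHomozygoteFisher:
    def test_knockout_case_table(self):
        ko = np.array([2] * 10 + [0] * 90)
        case = np.array([1] * 8 + [0] * 2 + [1] * 20 + [0] * 70)
        p = homozygote_fisher_test(ko, case)
        assert p == pytest.approx(
            stats.fisher_exact([[8, 2], [20, 70]])[1], rel=1e-10
        )


class TestMediation:
    def test_mendelian_randomization_identity(self):
        """When the variant affects disease only through the biomarker, the
        genotype-disease Cox effect equals (genotype-biomarker effect in SD)
        x (biomarker-disease log-hazard per SD), within 3 SE."""
        cfg = fs.SimConfig(
            mode="deterministic",
            n_sites_per_class=1,
            sample_sizes={"founder": 12_000, "outbred": 1},
            class_specs=(fs.VariantClassSpec("lof", s=0.0, h=0.5, q0=0.1),),
            seed=37,
        )
        cohort = fs.simulate_cohorts(cfg)["founder"]
        spec = fs.EffectSpec(
            variant=cohort.variants["variant_id"][0], trait="biomarker", beta=-0.5, trait_loghr=0.4
        )
        ph = fs.simulate_phenotypes(cohort, [spec], seed=37)
        z = fs.int_transform(ph["biomarker"], ph["sex"], ph["age"])
        g_b = fs.linear_assoc(cohort.dosages[:, 0], z)
        g_d = fs.cox_assoc(cohort.dosages[:, 0], ph["event"], ph["time"])
        assert g_d.effect == pytest.approx(g_b.effect * spec.trait_loghr, abs=3 * g_d.se)
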