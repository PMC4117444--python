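"""Simulation module: trajectory recursions, genotype sampling, phenotypes, I/O."""

import numpy as np
import pytest

import founderscan as fs
from founderscan.simdata import ConfigurationError
from founderscan.vcfio import emit_cohort, read_cohort_vcf


def _det_config(spec, generations=100, n_sites=3):
    return fs.SimConfig(
        mode="deterministic",
        generations_post_bottleneck=generations,
        n_sites_per_class=n_sites,
        class_specs=(spec,),
        seed=0,
    )


class TestTrajectories:
    def test_recessive_lethal_matches_closed_form(self):
        """Deterministic q' = q/(1+q) has closed form q_t = q0/(1+t*q0)."""
        q0 = 0.01
        spec = fs.VariantClassSpec("recessive_lethal", s=1.0, h=0.0, q0=q0)
        tr = fs.simulate_trajectories(_det_config(spec, generations=100))
        for pop in ("founder", "outbred"):
            traj = tr[pop][0]
            t = np.arange(traj.freqs.shape[0])
            expected = fs.recessive_lethal_closed_form(q0, t)
            assert np.allclose(traj.freqs[:, 0], expected, atol=1e-12, rtol=0)
        assert tr["founder"][0].final[0] == pytest.approx(0.005, abs=1e-12)

    def test_recessive_lethal_closed_form_deep_time(self):
        """Recursion matches the closed form to 1e-12 out to 10,000 generations."""
        spec = fs.VariantClassSpec("recessive_lethal", s=1.0, h=0.0, q0=0.03)
        tr = fs.simulate_trajectories(_det_config(spec, generations=10_000, n_sites=1))
        t = np.arange(10_001)
        assert np.allclose(
            tr["outbred"][0].freqs[:, 0], fs.recessive_lethal_closed_form(0.03, t), atol=1e-12, rtol=0
        )

    @pytest.mark.parametrize("q0", [0.01, 0.02, 0.03, 0.04, 0.05])
    def test_lethal_persistence_window(self, q0):
        """Recessive lethals persist at 0.1-1% after 100 generations but not 1,000."""
        q100 = fs.recessive_lethal_closed_form(q0, 100)
        q1000 = fs.recessive_lethal_closed_form(q0, 1000)
        assert 0.001 <= q100 <= 0.01
        assert q1000 <= 0.001

    def test_neutral_deterministic_fixed_point(self):
        spec = fs.VariantClassSpec("synonymous", s=0.0, h=0.5, q0=0.37)
        tr = fs.simulate_trajectories(_det_config(spec))
        assert np.all(tr["outbred"][0].freqs == 0.37)

    def test_stochastic_neutral_drift_moments(self):
        """Neutral drift at constant N: mean stays q0, variance follows
        q0(1-q0)(1 - (1-1/2N)^t)."""
        N, t, q0, reps = 1000, 100, 0.1, 10_000
        cfg = fs.SimConfig(
            mode="stochastic",
            ancestral_size=N,
            bottleneck_size=N,
            present_size=N,
            generations_post_bottleneck=t,
            n_sites_per_class=reps,
            seed=1,
            class_specs=(fs.VariantClassSpec("synonymous", s=0.0, h=0.5, q0=q0),),
        )
        q = fs.simulate_trajectories(cfg)["outbred"][0].final
        var_expected = q0 * (1 - q0) * (1 - (1 - 1 / (2 * N)) ** t)
        assert q.mean() == pytest.approx(q0, abs=3 * np.sqrt(var_expected / reps))
        assert q.var() == pytest.approx(var_expected, rel=0.10)

    def test_frequencies_stay_in_unit_interval_and_absorb(self):
        cfg = fs.SimConfig(n_sites_per_class=500, seed=3)
        tr = fs.simulate_trajectories(cfg)
        for pop in tr:
            for traj in tr[pop]:
                assert np.all((traj.freqs >= 0) & (traj.freqs <= 1))
                # absorbing at 0: once lost, stays lost
                lost = traj.freqs[50] == 0
                assert np.all(traj.freqs[-1][lost] == 0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            fs.VariantClassSpec("recessive_lethal", s=0.5, h=0.0)
        with pytest.raises(ConfigurationError):
            fs.VariantClassSpec("synonymous", s=0.1, h=0.5)
        with pytest.raises(ConfigurationError):
            fs.VariantClassSpec("lof", s=np.nan, h=0.5)
        with pytest.raises(ConfigurationError):
            fs.SimConfig(substructure_F=1.5)
        with pytest.raises(ConfigurationError):
            fs.SimConfig(mode="magic")


class TestSampleGenotypes:
    def test_monomorphic_site_all_zero(self):
        assert not fs.sample_genotypes([0.0], 50, seed=1).any()

    def test_full_inbreeding_has_no_heterozygotes(self):
        dos = fs.sample_genotypes([0.5] * 20, 500, F=1.0, seed=2)
        assert not (dos == 1).any()

    def test_balding_nichols_heterozygosity(self):
        """Het fraction matches 2q(1-q)(1-F) within 3 binomial SE."""
        q, F, n = 0.2, 0.05, 10_000
        dos = fs.sample_genotypes([q], n, F=F, seed=3)
        p_het = 2 * q * (1 - q) * (1 - F)  # 0.304
        se = np.sqrt(p_het * (1 - p_het) / n)
        assert (dos == 1).mean() == pytest.approx(p_het, abs=3 * se)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            fs.sample_genotypes([0.5], 10, F=1.2)
        with pytest.raises(ConfigurationError):
            fs.sample_genotypes([1.5], 10)


class TestCohorts:
    def test_determinism_same_seed_identical(self, small_sim_config):
        a = fs.simulate_cohorts(small_sim_config)
        b = fs.simulate_cohorts(small_sim_config)
        assert np.array_equal(a["founder"].dosages, b["founder"].dosages)
        assert a["founder"].variants.equals(b["founder"].variants)

    def test_allele_counts_consistent_with_matrix(self, small_cohorts):
        c = small_cohorts["founder"]
        d = c.dosages
        manual = np.where(d == c.MISSING, 0, d).sum(axis=0)
        assert np.array_equal(c.allele_counts(), manual)

    def test_neutral_sfs_symmetric_without_bottleneck(self):
        """With identical demography the two populations' neutral spectra agree."""
        cfg = fs.SimConfig(
            ancestral_size=2000,
            bottleneck_size=2000,
            present_size=2000,
            n_sites_per_class=4000,
            sample_sizes={"founder": 500, "outbred": 500},
            seed=9,
            class_specs=(fs.VariantClassSpec("synonymous", s=0.0, h=0.5, q0=(1e-3, 0.05), q0_shape="log"),),
        )
        cohorts = fs.simulate_cohorts(cfg)
        seg = {p: int((c.allele_counts() > 0).sum()) for p, c in cohorts.items()}
        # binomial-scale agreement between segregating-site counts
        assert abs(seg["founder"] - seg["outbred"]) < 4 * np.sqrt(seg["founder"] + seg["outbred"])


class TestPhenotypes:
    def test_null_effects_ci_coverage(self):
        """With no genetic effect the OLS 95% CI covers 0 in >=93% of replicates."""
        cfg = fs.SimConfig(
            mode="deterministic",
            n_sites_per_class=1,
            sample_sizes={"founder": 200, "outbred": 1},
            class_specs=(fs.VariantClassSpec("lof", s=0.0, h=0.5, q0=0.2),),
            seed=0,
        )
        cohort = fs.simulate_cohorts(cfg)["founder"]
        covered = 0
        reps = 200
        for k in range(reps):
            ph = fs.simulate_phenotypes(cohort, [], seed=k)
            r = fs.linear_assoc(cohort.dosages[:, 0], ph["trait_null"])
            lo, hi = r.effect - 1.96 * r.se, r.effect + 1.96 * r.se
            covered += lo <= 0 <= hi
        assert covered / reps >= 0.93

    def test_effect_recovery_lpa_scale(self):
        """beta = -0.6 SD per allele at 7.5% frequency, n~8,900 is recovered."""
        cfg = fs.SimConfig(
            mode="deterministic",
            n_sites_per_class=1,
            sample_sizes={"founder": 8896, "outbred": 1},
            class_specs=(fs.VariantClassSpec("lof", s=0.0, h=0.5, q0=0.075),),
            seed=4,
        )
        cohort = fs.simulate_cohorts(cfg)["founder"]
        ph = fs.simulate_phenotypes(
            cohort, [fs.EffectSpec(variant=cohort.variants["variant_id"][0], trait="lpa", beta=-0.6)], seed=4
        )
        r = fs.linear_assoc(cohort.dosages[:, 0], ph["lpa"])
        assert r.effect == pytest.approx(-0.6, abs=3 * r.se)

    def test_unknown_variant_rejected(self, small_cohorts):
        with pytest.raises(ConfigurationError):
            fs.simulate_phenotypes(
                small_cohorts["founder"], [fs.EffectSpec(variant="nope", trait="t", beta=0.1)], seed=0
            )


class TestEmit:
    def test_vcf_round_trip_and_conservation(self, small_sim_config, tmp_path):
        cfg = small_sim_config.with_(missing_rate=0.03, seed=21)
        cohort = fs.simulate_cohorts(cfg)["founder"]
        fs.simulate_phenotypes(cohort, [], seed=1)
        paths = emit_cohort(cohort, tmp_path)
        back = read_cohort_vcf(paths["vcf"], "founder")
        assert np.array_equal(back.dosages, cohort.dosages)
        # per-site allele counts equal dosage column sums
        assert np.array_equal(back.allele_counts(), cohort.allele_counts())

    def test_vcf_info_frequency_recount(self, small_cohorts, tmp_path):
        """INFO AF equals count/(2 * called genotypes) recomputed from the matrix."""
        cohort = small_cohorts["founder"]
        paths = emit_cohort(cohort, tmp_path)
        back = read_cohort_vcf(paths["vcf"], "founder")
        rng = np.random.default_rng(0)
        cols = rng.choice(cohort.n_variants, size=100, replace=True)
        for j in cols:
            d = cohort.dosages[:, j]
            called = d != cohort.MISSING
            expect = d[called].sum() / (2 * called.sum()) if called.any() else 0.0
            assert back.variants["af_founder"].iloc[j] == pytest.approx(expect, abs=5e-7)
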