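import numpy as np
import pytest

from fdtica import (
    ARCHETYPES,
    GeneratorParams,
    archetype_template,
    generate_glaucoma_fields,
    generate_normal_fields,
    generate_study_cohort,
    layout_242,
    mean_deviation,
    sample_ica_mixture,
)
from conftest import make_ica_truth


class TestTemplates:
    @pytest.mark.parametrize("name", ARCHETYPES)
    def test_non_positive_with_some_loss(self, name):
        t = archetype_template(name)
        assert np.all(t <= 0) and np.any(t < 0)

    def test_superior_altitudinal_hits_superior_points_hardest(self):
        layout = layout_242()
        t = archetype_template("superior_altitudinal")
        assert t[layout.superior_mask].mean() < t[layout.inferior_mask].mean()

    def test_arrowhead_is_the_union_of_nasal_steps(self):
        layout = layout_242()
        arrow = archetype_template("arrowhead")
        assert np.all(arrow[layout.nasal_mask] == -1.0)
        assert np.all(arrow[~layout.nasal_mask] == -0.10)


class TestNormalGenerator:
    def test_noiseless_limit_equals_surface(self):
        p = GeneratorParams(subject_sd=1e-12, point_noise_sd=0.0, md_offset=0.0)
        c = generate_normal_fields(5, p, rng_seed=0)
        assert np.allclose(c.thresholds_matrix(), p.normal_mean_surface, atol=1e-9)

    def test_seeded_determinism(self):
        a = generate_normal_fields(20, rng_seed=9)
        b = generate_normal_fields(20, rng_seed=9)
        assert a.equals(b)

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            generate_normal_fields(0)

    def test_thresholds_non_negative(self):
        c = generate_glaucoma_fields(200, rng_seed=1)
        assert np.all(c.thresholds_matrix() >= 0)


class TestGlaucomaGenerator:
    def test_zero_severity_limit_matches_normal_model(self):
        p = GeneratorParams(abnormal_md_drop=1e-12)
        c = generate_glaucoma_fields(400, p, rng_seed=2)
        mds = [mean_deviation(r, p.normal_mean_surface) for r in c.records]
        # severity ~ 0 so MD should sit at the normal arm's -1 dB offset
        assert np.mean(mds) == pytest.approx(-1.0, abs=3 * np.std(mds) / 20)

    def test_superior_archetype_depresses_superior_points(self):
        p = GeneratorParams(archetype_weights={"superior_altitudinal": 1.0})
        c = generate_glaucoma_fields(300, p, rng_seed=3)
        layout = c.layout
        dev = c.thresholds_matrix() - p.normal_mean_surface
        assert dev[:, layout.superior_mask].mean() < dev[:, layout.inferior_mask].mean()

    def test_severity_monotonicity_on_support(self):
        """More severe defects never raise thresholds in the template region."""
        p = GeneratorParams()
        t = archetype_template("inferior_nasal")
        base = p.normal_mean_surface
        lo = np.clip(base + 2.0 * t, 0, None)
        hi = np.clip(base + 8.0 * t, 0, None)
        assert np.all(hi[t < 0] <= lo[t < 0])

    def test_ground_truth_recorded(self):
        c = generate_glaucoma_fields(10, rng_seed=4)
        assert all(r.archetype in ARCHETYPES and r.severity >= 0 for r in c.records)


class TestStudyCohort:
    def test_counts_and_shuffle(self):
        c = generate_study_cohort(30, 20, seed=5)
        labels = c.labels()
        assert len(c) == 50
        assert (labels == "normal").sum() == 30
        assert (labels == "abnormal").sum() == 20

    def test_all_abnormal_boundary(self):
        c = generate_study_cohort(0, 10, seed=6)
        assert len(c) == 10 and set(c.labels()) == {"abnormal"}

    def test_deterministic(self):
        assert generate_study_cohort(15, 15, seed=7).equals(
            generate_study_cohort(15, 15, seed=7))


class TestIcaMixtureSampler:
    def test_degenerate_limit_is_mean_plus_sources(self):
        rng = np.random.default_rng(0)
        truth = make_ica_truth(rng, K=1, D=4, L=2, noise_sd=0.0, mix_scale=1.0)
        truth.mixing = np.eye(4)[:, :2][None]  # identity embedding
        X, z, S = sample_ica_mixture(truth, 50, seed=1)
        assert np.allclose(X[:, :2], S, atol=1e-12)
        assert np.allclose(X[:, 2:], 0.0, atol=1e-12)

    def test_cluster_proportions_within_3se(self):
        rng = np.random.default_rng(1)
        truth = make_ica_truth(rng, K=2, D=6, L=2,
                               means=[[0] * 6, [10] * 6], weights=[0.7, 0.3])
        n = 10_000
        X, z, S = sample_ica_mixture(truth, n, seed=2)
        p_hat = (z == 0).mean()
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(p_hat - 0.7) <= 3 * se

    def test_single_cluster_covariance_moment_oracle(self):
        rng = np.random.default_rng(2)
        truth = make_ica_truth(rng, K=1, D=6, L=2, mix_scale=2.0, noise_sd=0.4)
        n = 40_000
        X, _, S = sample_ica_mixture(truth, n, seed=3)
        A = truth.mixing[0]
        w, mu, sd = truth.source_weights[0], truth.source_means[0], truth.source_sds[0]
        var_s = (w * (sd**2 + mu**2)).sum(axis=1) - ((w * mu).sum(axis=1)) ** 2
        expected = A @ np.diag(var_s) @ A.T + 0.4**2 * np.eye(6)
        emp = np.cov(X.T)
        assert np.max(np.abs(emp - expected)) < 0.15

    def test_rank_deficient_mixing_rejected(self):
        rng = np.random.default_rng(3)
        truth_kwargs = make_ica_truth(rng, K=1, D=4, L=2)
        bad = np.zeros((1, 4, 2))
        bad[0, :, 0] = 1.0
        bad[0, :, 1] = 1.0  # duplicate column
        from fdtica import GroundTruthICAMixture

        with pytest.raises(ValueError, match="rank"):
            GroundTruthICAMixture(
                weights=[1.0], means=np.zeros((1, 4)), mixing=bad,
                source_weights=truth_kwargs.source_weights,
                source_means=truth_kwargs.source_means,
                source_sds=truth_kwargs.source_sds,
                noise_sd=truth_kwargs.noise_sd)
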