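import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdtica import (
    VimConfig,
    axis_magnitudes,
    fit_vbica_mm,
    knee_point,
    orient_axes,
    prune_and_retrain,
    sample_ica_mixture,
)
from fdtica.axis_model import assign_to_nearest_axis
from conftest import amari_distance, make_ica_truth


def brute_force_knee(mags):
    """Independent oracle: exhaustive search of the discrete second difference."""
    best_pos, best_val = None, -np.inf
    for i in range(1, len(mags) - 1):
        d2 = mags[i - 1] - 2 * mags[i] + mags[i + 1]
        if d2 > best_val:
            best_pos, best_val = i, d2
    return best_pos


class TestKneePoint:
    @pytest.mark.parametrize("mags,expected", [
        ([10, 9, 1, 0.5, 0.2], 2),
        ([10, 8, 6, 5.5, 1, 0.4], 4),
        ([7.0], 1),
    ])
    def test_worked_examples(self, mags, expected):
        assert knee_point(mags) == expected

    def test_flat_curve_returns_full_length(self):
        assert knee_point([3.0, 3.0, 3.0, 3.0]) == 4

    def test_override_bypasses_detection(self):
        assert knee_point([10, 9, 1, 0.5], override=3) == 3
        with pytest.raises(ValueError):
            knee_point([10, 9, 1], override=5)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            knee_point([1.0, 5.0, 0.2])

    @given(st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=3,
                    max_size=20))
    @settings(max_examples=300, deadline=None)
    def test_agrees_with_exhaustive_second_difference(self, raw):
        mags = sorted(raw, reverse=True)
        if np.allclose(mags, mags[0]):
            return
        assert knee_point(mags) == brute_force_knee(mags)


@pytest.fixture(scope="module")
def overfitted_single_cluster():
    """True L=2 non-Gaussian sources fitted with L_max=10 (restart-selected)."""
    rng = np.random.default_rng(30)
    truth = make_ica_truth(rng, K=1, D=12, L=2, mix_scale=3.0, noise_sd=0.3)
    X, _, _ = sample_ica_mixture(truth, 1500, seed=31)
    best = max((fit_vbica_mm(X, VimConfig(K=1, L_max=10, m=3, n_iterations=250,
                                          seed=s)) for s in (0, 1, 2)),
               key=lambda f: f.final_elbo)
    return best, X, truth


class TestPruneAndRetrain:
    def test_ard_pruning_recovers_true_axis_count_and_mixing(
            self, overfitted_single_cluster):
        fit, X, truth = overfitted_single_cluster
        mags = np.sort(axis_magnitudes(fit.model, 0))[::-1]
        # suppressed axes carry <10% of the total magnitude
        assert mags[2:].sum() < 0.10 * mags.sum()
        keep = knee_point(mags)
        assert keep == 2
        pruned = prune_and_retrain(fit.model, [keep], X, n_iterations=60)
        assert pruned.axis_counts() == [2]
        assert amari_distance(pruned.clusters[0].mA, truth.mixing[0]) < 0.15

    def test_retraining_trace_is_monotone(self, overfitted_single_cluster):
        fit, X, _ = overfitted_single_cluster
        pruned = prune_and_retrain(fit.model, [2], X, n_iterations=40)
        t = np.asarray(pruned.elbo_trace)
        assert np.all(np.diff(t) >= -1e-6 * np.abs(t[:-1]) - 1e-9)

    def test_noop_pruning_keeps_training_monotone(self, overfitted_single_cluster):
        fit, X, _ = overfitted_single_cluster
        same = prune_and_retrain(fit.model, [fit.model.clusters[0].L], X,
                                 n_iterations=5)
        assert same.axis_counts() == [fit.model.clusters[0].L]
        assert same.elbo_trace[-1] >= fit.final_elbo - 1e-6 * abs(fit.final_elbo)

    def test_zero_retained_rejected(self, overfitted_single_cluster):
        fit, X, _ = overfitted_single_cluster
        with pytest.raises(ValueError):
            prune_and_retrain(fit.model, [0], X)


class TestOrientAxes:
    def test_orientation_follows_the_label_rule(self, small_pipeline, small_cohort):
        """+direction = greater abnormality: abnormal members project at least
        as high as normal members; clusters with one label class instead use
        the geometric rule (+direction lowers mean simulated sensitivity)."""
        res = small_pipeline
        labels = small_cohort.labels()
        assignments = res.model.hard_assignments()
        for axis in res.axes:
            members = np.flatnonzero(assignments == axis.cluster_index)
            mem_labels = labels[members]
            proj = (res.Z[members]
                    - res.model.clusters[axis.cluster_index].m_mu) @ axis.direction
            if (mem_labels == "normal").any() and (mem_labels == "abnormal").any():
                assert proj[mem_labels == "abnormal"].mean() >= \
                    proj[mem_labels == "normal"].mean()
            else:
                scale = np.asarray(res.model.standardization["scale"])[:52]
                assert (axis.direction[:52] * scale).mean() < 0

    def test_orientation_is_sign_idempotent(self, small_pipeline, small_cohort):
        """Re-orienting a sign-flipped model yields identical oriented axes."""
        import copy

        res = small_pipeline
        flipped = copy.deepcopy(res.model)
        for c in flipped.clusters:
            c.mA *= -1.0
        axes2 = orient_axes(flipped, res.normal_cluster_index, res.Z,
                            small_cohort.labels())
        for a, b in zip(res.axes, axes2):
            assert np.allclose(a.direction, b.direction, atol=1e-12)

    def test_projection_correlates_with_ground_truth_severity(self):
        """A pure glaucoma cluster (single archetype, modest noise): the
        dominant oriented axis must order fields by generating severity."""
        from scipy.stats import spearmanr

        from fdtica import (GeneratorParams, VimConfig, feature_matrix, fit_vbica_mm,
                            generate_glaucoma_fields, standardize)
        from fdtica.patterns import severity as severity_score

        params = GeneratorParams(archetype_weights={"superior_altitudinal": 1.0},
                                 subject_sd=1.0, point_noise_sd=1.0)
        cohort = generate_glaucoma_fields(300, params, rng_seed=77)
        X, _ = feature_matrix(cohort)
        Z, std = standardize(X)
        fit = fit_vbica_mm(Z, VimConfig(K=1, L_max=5, m=3, n_iterations=100, seed=4))
        fit.model.standardization = std
        axes = orient_axes(fit.model, 0, Z, cohort.labels())
        axis = max(axes, key=lambda a: a.magnitude)
        sev_true = [r.severity for r in cohort.records]
        sev_est = [severity_score(z, axis, fit.model) for z in Z]
        assert spearmanr(sev_true, sev_est).statistic > 0.8


class TestNearestAxis:
    def test_field_along_an_axis_is_assigned_to_it_scale_invariantly(
            self, small_pipeline):
        res = small_pipeline
        k = max(range(res.model.K),
                key=lambda kk: len([a for a in res.axes if a.cluster_index == kk]))
        axes_k = [a for a in res.axes if a.cluster_index == k]
        c = res.model.clusters[k]
        members, _ = assign_to_nearest_axis(res.model, res.Z, k, axes_k)
        probe_row = members[0]
        for target_pos, gain in ((len(axes_k) - 1, 2.0), (len(axes_k) - 1, 7.0),
                                 (0, 3.0)):
            Z2 = res.Z.copy()
            Z2[probe_row] = c.m_mu + gain * axes_k[target_pos].direction
            _, choice = assign_to_nearest_axis(res.model, Z2, k, axes_k)
            assert choice[list(members).index(probe_row)] == target_pos

    def test_members_split_by_generating_direction(self):
        rng = np.random.default_rng(33)
        truth = make_ica_truth(rng, K=1, D=10, L=2, mix_scale=4.0, noise_sd=0.15)
        X, _, S = sample_ica_mixture(truth, 800, seed=34)
        fit = fit_vbica_mm(X, VimConfig(K=1, L_max=6, m=3, n_iterations=200, seed=1))
        pruned = prune_and_retrain(fit.model, [2], X, n_iterations=50)
        members, choice = assign_to_nearest_axis(pruned, X, 0)
        # fields generated dominantly along one source should follow that axis
        dominant = np.argmax(np.abs(S) * np.linalg.norm(truth.mixing[0], axis=0),
                             axis=1)
        strong = np.abs(np.abs(S[:, 0]) - np.abs(S[:, 1])) > 1.0
        # map estimated axes to true sources by majority vote
        agree = np.mean(choice[strong] == dominant[strong])
        assert max(agree, 1 - agree) >= 0.95
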