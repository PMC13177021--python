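import dataclasses

import numpy as np
import pytest

from scwnet import (ClusterSpec, ComponentDescriptor, Frame, build_network,
                    calibrate_lambda, component_descriptors, curve_agreement,
                    distribution_error, frame_coordinate_vector,
                    generate_water_frame, planted_cluster_frame,
                    pooled_size_fractions, select_representative_component,
                    select_representative_frames)

from conftest import make_molecule


class TestDistributionError:
    def test_identical_distributions_give_zero(self):
        d = {1: 0.7, 2: 0.2, 3: 0.1}
        assert distribution_error(d, dict(d)) == (0.0, 0.0)

    def test_two_equal_deviations(self):
        mae, rmse = distribution_error({1: 0.5, 2: 0.5}, {1: 0.6, 2: 0.4})
        assert mae == pytest.approx(0.1)
        assert rmse == pytest.approx(0.1)

    def test_disjoint_supports_align_on_union(self):
        mae, rmse = distribution_error({1: 1.0}, {2: 1.0})
        assert mae == pytest.approx(1.0)
        assert rmse == pytest.approx(1.0)

    def test_symmetric(self):
        a, b = {1: 0.3, 3: 0.7}, {1: 0.6, 2: 0.4}
        assert distribution_error(a, b) == distribution_error(b, a)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            distribution_error({}, {1: 1.0})


class TestCurveAgreement:
    def test_identical_curves(self):
        y = np.sin(np.linspace(0, 3, 40))
        m = curve_agreement(y, y)
        assert (m.r_squared, m.rmse, m.mae) == (1.0, 0.0, 0.0)

    def test_constant_offset_closed_form(self):
        y = np.linspace(0.0, 1.0, 21)
        m = curve_agreement(y, y + 0.1)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        assert m.mae == pytest.approx(0.1)
        assert m.rmse == pytest.approx(0.1)
        assert m.r_squared == pytest.approx(1 - 0.01 * 21 / ss_tot)

    def test_mean_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = curve_agreement(y, np.full(4, y.mean()))
        assert m.r_squared == pytest.approx(0.0)

    def test_constant_observed_curve_rejected(self):
        with pytest.raises(ValueError):
            curve_agreement(np.ones(5), np.zeros(5))

    def test_resamples_on_mismatched_abscissas(self):
        x_obs = np.linspace(0, 1, 11)
        x_pred = np.linspace(0, 1, 101)
        y_obs = x_obs ** 2
        m = curve_agreement(y_obs, x_pred ** 2, x_observed=x_obs,
                            x_predicted=x_pred)
        assert m.rmse == pytest.approx(0.0, abs=1e-12)

    def test_rmse_at_least_mae(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(30)
        m = curve_agreement(y, y + rng.standard_normal(30))
        assert m.rmse >= m.mae >= 0.0


class TestCalibrateLambda:
    @pytest.mark.parametrize("lambda0", [0.3, 0.5, 0.655])
    def test_self_recovery_of_generating_lambda(self, params673, lambda0):
        frames = [generate_water_frame(250, box=2.3, T=650.0, seed=s,
                                       min_sep=0.24)
                  for s in (101, 102, 103, 104)]
        reference = pooled_size_fractions(
            frames, params673.with_lambda(lambda0))
        res = calibrate_lambda(frames, reference,
                               [0.2, 0.3, 0.4, 0.5, 0.6, 0.655, 0.8],
                               params673)
        assert res.lambda_star == lambda0
        assert res.mae_star == 0.0

    def test_single_point_grid(self, params673):
        f = generate_water_frame(60, box=1.8, T=650.0, seed=3)
        res = calibrate_lambda([f], {1: 1.0}, [0.655], params673)
        assert res.lambda_star == 0.655

    def test_edge_count_non_increasing_along_grid(self, params673):
        f = generate_water_frame(250, box=2.3, T=650.0, seed=77, min_sep=0.24)
        counts = [build_network(f, params673.with_lambda(lam)).n_edges
                  for lam in np.linspace(0.0, 1.0, 11)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_inputs_rejected(self, params673):
        with pytest.raises(ValueError):
            calibrate_lambda([], {1: 1.0}, [0.5], params673)
        f = generate_water_frame(10, box=1.6, T=650.0, seed=1)
        with pytest.raises(ValueError):
            calibrate_lambda([f], {1: 1.0}, [], params673)


def _perturbed(frame, rng, scale):
    mols = []
    for m in frame.molecules:
        delta = scale * rng.standard_normal(3)
        mols.append(dataclasses.replace(
            m, pos_Ha=m.pos_Ha + delta, pos_O=m.pos_O + delta,
            pos_M=m.pos_M + delta, pos_Hb=m.pos_Hb + delta))
    return Frame(box=frame.box, molecules=mols)


class TestSelectFrames:
    def test_flattened_layout_has_twelve_columns_per_molecule(self):
        f = generate_water_frame(17, box=2.0, T=650.0, seed=5)
        assert frame_coordinate_vector(f).shape == (12 * 17,)

    def test_identical_frames_select_first_indices(self):
        f = generate_water_frame(20, box=2.0, T=650.0, seed=9)
        assert select_representative_frames([f] * 6, n=3) == [0, 1, 2]

    def test_outlier_never_selected(self):
        rng = np.random.default_rng(55)
        base = generate_water_frame(30, box=2.0, T=650.0, seed=13)
        frames = [_perturbed(base, rng, 0.01) for _ in range(10)]
        outlier = _perturbed(base, rng, 1.5)
        frames.append(outlier)
        for n in (1, 3, 10):
            assert 10 not in select_representative_frames(frames, n=n)

    def test_brute_force_distance_ranking_agrees(self):
        # full-coordinate-space centred distances rank the same frames first
        rng = np.random.default_rng(56)
        base = generate_water_frame(25, box=2.0, T=650.0, seed=14)
        frames = [_perturbed(base, rng, 0.05) for _ in range(8)]
        x = np.stack([frame_coordinate_vector(f) for f in frames])
        dist_full = np.linalg.norm(x - x.mean(axis=0), axis=1)
        brute = int(np.argmin(dist_full))
        got = select_representative_frames(frames, n=1, variance=1.0)
        assert got == [brute]

    def test_requesting_all_frames_is_identity(self):
        rng = np.random.default_rng(57)
        base = generate_water_frame(10, box=2.0, T=650.0, seed=15)
        frames = [_perturbed(base, rng, 0.02) for _ in range(5)]
        assert sorted(select_representative_frames(frames, n=5)) == \
            [0, 1, 2, 3, 4]
        # n beyond the trajectory returns everything (with a warning)
        assert sorted(select_representative_frames(frames, n=9)) == \
            [0, 1, 2, 3, 4]

    def test_invariant_under_rigid_translation(self):
        rng = np.random.default_rng(58)
        base = generate_water_frame(15, box=2.0, T=650.0, seed=16)
        frames = [_perturbed(base, rng, 0.05) for _ in range(7)]
        shift = np.array([5.0, -3.0, 2.0])
        shifted = []
        for f in frames:
            mols = [dataclasses.replace(
                m, pos_Ha=m.pos_Ha + shift, pos_O=m.pos_O + shift,
                pos_M=m.pos_M + shift, pos_Hb=m.pos_Hb + shift)
                for m in f.molecules]
            shifted.append(Frame(box=f.box, molecules=mols))
        assert select_representative_frames(frames, n=3) == \
            select_representative_frames(shifted, n=3)


class TestComponentDescriptors:
    def test_dimer_single_edge_statistics(self, bound_dimer_frame, params673):
        net = build_network(bound_dimer_frame, params673)
        (d,) = component_descriptors(net, bound_dimer_frame)
        assert d.size == 2
        assert d.sum_edge_lengths == pytest.approx(0.28, abs=1e-9)
        assert d.std_edge_lengths == 0.0
        assert d.std_edge_energy == 0.0
        assert d.mean_edge_energy == pytest.approx(
            net.edges[0].V_coul + net.edges[0].V_LJ, rel=1e-12)

    def test_three_chain_two_point_statistics(self, params673):
        spec = ClusterSpec(counts={3: 1}, spacing=0.28)
        frame, _ = planted_cluster_frame(spec, T_cold=5.0, seed=2)
        net = build_network(frame, params673)
        (d,) = component_descriptors(net, frame)
        assert d.size == 3
        assert d.sum_edge_lengths == pytest.approx(0.56, abs=1e-6)
        assert d.std_edge_lengths == pytest.approx(0.0, abs=1e-6)

    def test_descriptor_count_matches_multimolecule_components(
            self, params673):
        spec = ClusterSpec(counts={1: 6, 2: 3, 4: 2}, spacing=0.28)
        frame, _ = planted_cluster_frame(spec, T_cold=5.0, seed=4)
        net = build_network(frame, params673)
        assert len(component_descriptors(net, frame)) == 5


class TestSelectComponent:
    def _desc(self, cid, vec):
        return ComponentDescriptor(component_id=cid, size=3,
                                   sum_edge_lengths=vec[0],
                                   std_edge_lengths=vec[1],
                                   mean_edge_energy=vec[2],
                                   std_edge_energy=vec[3])

    def test_single_candidate_selects_itself(self):
        d = self._desc(4, [0.5, 0.0, -20.0, 0.0])
        assert select_representative_component([d]) == 4

    def test_symmetric_pair_breaks_tie_to_lower_id(self):
        a = self._desc(2, [0.5, 0.01, -20.0, 1.0])
        b = self._desc(7, [0.7, 0.03, -24.0, 3.0])
        assert select_representative_component([a, b]) == 2

    def test_agrees_with_nearest_centroid_in_zscore_space(self):
        rng = np.random.default_rng(90)
        for _ in range(20):
            descs = [self._desc(k, rng.standard_normal(4))
                     for k in range(6)]
            x = np.stack([d.vector() for d in descs])
            z = (x - x.mean(0)) / x.std(0, ddof=0)
            brute = int(np.argmin(np.linalg.norm(z - z.mean(0), axis=1)))
            assert select_representative_component(descs) == brute

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            select_representative_component([])
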