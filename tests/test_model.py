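"""Two-segment recurrent model: targets, dynamics, gradients, optimization."""

import numpy as np
import pandas as pd
import pytest

from crawlnet import model as M
from crawlnet.errors import EmptyInputError, ValidationError
from crawlnet.model.network import WeightStructure
from crawlnet.model.training import PARAM_KEYS


def make_net(edges, records, cross):
    return M.build_two_segment(edges, records, cross)


@pytest.fixture(scope="module")
def toy_net(toy_connectome):
    c = toy_connectome
    return make_net(c["edges"], c["records"], c["cross_edges"])


@pytest.fixture(scope="module")
def full_net(connectome_default):
    c = connectome_default
    return make_net(c["edges"], c["records"], c["cross_edges"])


def coupling_free_net(n_pmn=3, n_mn=2):
    """A network with empty weight matrices for closed-form dynamics tests."""
    empty = lambda shape: WeightStructure(
        shape=shape,
        rows=np.array([], dtype=int),
        cols=np.array([], dtype=int),
        pidx=np.array([], dtype=int),
        sign=np.array([]),
        constrained=np.array([], dtype=bool),
        n_params=0,
    )
    return M.TwoSegmentNetwork(
        pmn_pairs=[f"p{i}" for i in range(n_pmn)],
        mn_pairs=[f"m{i}" for i in range(n_mn)],
        struct_p=empty((2 * n_pmn, 2 * n_pmn)),
        struct_m=empty((2 * n_mn, 2 * n_pmn)),
        wp0=np.array([]),
        wm0=np.array([]),
        cmug_fwd=np.zeros(2 * n_mn, dtype=int),
        cmug_bwd=np.zeros(2 * n_mn, dtype=int),
    )


class TestTargets:
    def test_group_window_arithmetic(self):
        trial = M.TrialSpec()
        # leading segment (A2 during forward) starts at 1 s
        for g, (on, off) in enumerate(
            [(1.0, 3.0), (1.25, 3.125), (1.5, 3.25), (1.75, 3.375)]
        ):
            got = trial.group_window(g, 4, segment=1, direction="forward")
            assert got == (pytest.approx(on), pytest.approx(off))
        # the trailing segment is delayed by the 1 s intersegmental lag
        assert trial.group_window(0, 4, 0, "forward") == (
            pytest.approx(2.0),
            pytest.approx(4.0),
        )
        # backward reverses which segment leads
        assert trial.group_window(0, 4, 0, "backward") == (
            pytest.approx(1.0),
            pytest.approx(3.0),
        )

    def test_pulse_zero_outside_window(self):
        t = np.linspace(0, 6, 121)
        pulse = M.rectified_cosine_pulse(t, 2.0, 4.0)
        assert (pulse[(t < 2.0) | (t > 4.0)] == 0).all()
        assert pulse[(t > 2.0) & (t < 4.0)].max() > 0.99

    def test_same_cmug_same_segment_identical_rows(self):
        cmug = np.array([0, 0, 1, 0, 0, 1])
        seg = np.array([0, 0, 0, 1, 1, 1])
        tgt = M.generate_targets(cmug, seg, "forward")
        np.testing.assert_array_equal(tgt.m_star[0], tgt.m_star[1])
        np.testing.assert_array_equal(tgt.m_star[3], tgt.m_star[4])
        assert not np.array_equal(tgt.m_star[0], tgt.m_star[3])

    def test_weights_favor_small_groups_and_sum_to_one(self):
        cmug = np.array([0, 0, 0, 1])
        seg = np.zeros(4, dtype=int)
        tgt = M.generate_targets(cmug, seg, "forward")
        assert tgt.weights.sum() == pytest.approx(1.0)
        assert tgt.weights[3] == pytest.approx(3 * tgt.weights[0])

    def test_overflowing_trial_rejected(self):
        trial = M.TrialSpec(first_group_duration_s=5.0)
        with pytest.raises(ValidationError):
            M.generate_targets(np.array([0]), np.array([0]), "forward", trial)


class TestCommandInput:
    def test_zero_outside_window_amplitude_inside(self):
        tgt = M.generate_targets(
            np.array([0, 1, 2, 3]), np.zeros(4, dtype=int), "forward"
        )
        amps = np.array([0.1, 0.2, 0.3])
        I = command = M.command_input(amps, tgt)
        t = tgt.trial.bin_centers
        on, off = tgt.command_window
        np.testing.assert_allclose(I[(t < on) | (t > off)], 0.0)
        inside = I[(t >= on) & (t <= off)]
        np.testing.assert_allclose(inside, np.tile(amps, (len(inside), 1)))

    def test_initial_amplitudes_in_paper_range(self, toy_net):
        params = toy_net.initial_parameters(np.random.default_rng(0))
        for amp in (params.i_fwd, params.i_bwd):
            assert ((amp >= 0.05) & (amp <= 0.15)).all()


class TestBuildTwoSegment:
    def test_toy_matrix_matches_hand_construction(self):
        """3 PMN pairs (exc/inh/unknown) onto 2 MN pairs, percent-of-input scale."""
        rows = []
        for name, klass, trans, muscles in [
            ("pe", "PMN", "excitatory", ""),
            ("pi", "PMN", "inhibitory", ""),
            ("pu", "PMN", "unknown", ""),
            ("ma", "MN", "excitatory", "2"),
            ("mb", "MN", "excitatory", "21"),
        ]:
            for side in ("L", "R"):
                rows.append(
                    {
                        "neuron_id": f"{name}_{side}",
                        "name": name,
                        "neuron_class": klass,
                        "segment": "A1",
                        "side": "left" if side == "L" else "right",
                        "transmitter": trans,
                        "homolog_id": f"{name}_{'R' if side == 'L' else 'L'}",
                        "muscle_targets": muscles,
                    }
                )
        records = pd.DataFrame(rows)
        edges = pd.DataFrame(
            [
                ("pe_L", "ma_L", 3), ("pe_R", "ma_R", 3),
                ("pi_L", "ma_L", 1), ("pi_R", "ma_R", 1),
                ("pu_L", "mb_L", 2), ("pu_R", "mb_R", 2),
                ("pe_L", "pi_L", 4), ("pe_R", "pi_R", 4),
                ("pe_L", "mb_L", 0), ("pe_R", "mb_R", 0),  # zero-count: no slot
            ],
            columns=["pre_id", "post_id", "synapse_count"],
        )
        net = make_net(edges, records, None)
        Jm = net.struct_m.matrix(net.wm0)
        Jp = net.struct_p.matrix(net.wp0)
        i_pe, i_pi, i_pu = (net.pmn_pairs.index(f"p{x}_L") for x in "eiu")
        i_ma, i_mb = (net.mn_pairs.index(f"m{x}_L") for x in "ab")
        # ma input: pe 6 of 8 (75%), pi 2 of 8 (25%); scale 0.005 per percent
        assert Jm[i_ma, i_pe] == pytest.approx(0.005 * 75.0)
        assert Jm[i_ma, i_pi] == pytest.approx(-0.005 * 25.0)
        # unknown transmitter: initialized inhibitory, unconstrained
        assert Jm[i_mb, i_pu] == pytest.approx(-0.005 * 100.0)
        assert not net.struct_m.constrained[
            net.struct_m.pidx[net.struct_m.rows == i_mb][0]
        ]
        # pi's only input is pe: 100%
        assert Jp[i_pi, i_pe] == pytest.approx(0.005 * 100.0)
        # zero-count edge contributes no parameter slot
        assert Jm[i_mb, i_pe] == 0.0

    def test_within_segment_blocks_identical(self, full_net):
        net = full_net
        nP, nM = net.n_pmn_per_seg, net.n_mn_per_seg
        Jp = net.struct_p.matrix(net.wp0)
        Jm = net.struct_m.matrix(net.wm0)
        np.testing.assert_array_equal(Jp[:nP, :nP], Jp[nP:, nP:])
        np.testing.assert_array_equal(Jm[:nM, :nP], Jm[nM:, nP:])

    def test_unknown_neuron_in_edges_rejected(self, toy_connectome):
        edges = toy_connectome["edges"].copy()
        edges.loc[0, "pre_id"] = "GHOST"
        with pytest.raises(ValidationError, match="GHOST"):
            make_net(edges, toy_connectome["records"], None)


class TestSimulate:
    def test_zero_coupling_relaxation_matches_closed_form(self):
        """u(t) = b (1 - e^(-t/tau)) under Euler integration, dt-refined."""
        net = coupling_free_net()
        params = net.initial_parameters(np.random.default_rng(0))
        params.bp[:] = 0.7
        params.bm[:] = 0.4
        params.taup[:] = 0.2
        params.taum[:] = 0.35
        errs = []
        for dt in (0.05, 0.01, 0.002):
            T = int(round(6.0 / dt))
            I = np.zeros((T, net.n_pmn))
            p, m, _, _ = M.simulate(params, net, I, np.zeros(net.n_pmn), dt=dt)
            for t_check in (0.5, 1.0, 3.0):
                k = int(round(t_check / dt))
                exact_p = 0.7 * (1 - np.exp(-k * dt / 0.2))
                exact_m = 0.4 * (1 - np.exp(-k * dt / 0.35))
                errs.append(abs(p[k, 0] - exact_p))
                errs.append(abs(m[k, 0] - exact_m))
        assert max(errs[-6:]) < 1e-3  # finest dt within tolerance
        assert max(errs[-6:]) <= max(errs[:6])  # refinement helps

    def test_tau_equal_dt_one_step_relaxation(self):
        net = coupling_free_net()
        params = net.initial_parameters(np.random.default_rng(0))
        params.taup[:] = 0.05
        params.bp[:] = 0.9
        I = np.zeros((10, net.n_pmn))
        _, _, u_p, _ = M.simulate(params, net, I, np.full(net.n_pmn, 0.3), dt=0.05)
        np.testing.assert_allclose(u_p[1], 0.9)  # jumps straight to the drive

    def test_nonpositive_drive_keeps_rates_zero(self):
        net = coupling_free_net()
        params = net.initial_parameters(np.random.default_rng(0))
        params.bp[:] = -0.2
        params.bm[:] = 0.0
        I = np.zeros((40, net.n_pmn))
        p, m, _, _ = M.simulate(params, net, I, np.full(net.n_pmn, -0.1))
        assert (p == 0).all() and (m == 0).all()

    def test_rates_nonnegative_everywhere(self, toy_net):
        params = toy_net.initial_parameters(np.random.default_rng(1))
        tgt = M.generate_targets(toy_net.cmug_fwd, toy_net.mn_segment_of, "forward")
        I = M.command_input(params.i_fwd, tgt)
        p, m, _, _ = M.simulate(params, toy_net, I, toy_net.initial_state(np.random.default_rng(2)))
        assert (p >= 0).all() and (m >= 0).all()


class TestSchedules:
    def test_lr_endpoints_and_midpoint(self):
        assert M.lr_schedule(0) == pytest.approx(1e-2)
        assert M.lr_schedule(1000) == pytest.approx(1e-3)
        assert M.lr_schedule(500) == pytest.approx(10 ** -2.5)

    def test_alpha_endpoints_and_midpoint(self):
        assert M.alpha_schedule(0) == 0.0
        assert M.alpha_schedule(1000) == pytest.approx(0.1)
        assert M.alpha_schedule(500) == pytest.approx(0.025)

    def test_out_of_range_epoch_rejected(self):
        with pytest.raises(ValidationError):
            M.lr_schedule(-1)
        with pytest.raises(ValidationError):
            M.alpha_schedule(1001)


class TestCost:
    def test_perfect_match_zero_target_cost(self, toy_net):
        params = toy_net.initial_parameters(np.random.default_rng(0))
        tgt = M.generate_targets(toy_net.cmug_fwd, toy_net.mn_segment_of, "forward")
        u0 = toy_net.initial_state(np.random.default_rng(3))
        I = M.command_input(params.i_fwd, tgt)
        _, m, _, _ = M.simulate(params, toy_net, I, u0)
        tgt.m_star = m.T.copy()  # target equals what the model produces
        costs, _ = M.trial_cost_and_grads(params, toy_net, tgt, u0, alpha=0.0)
        assert costs["c_targ"] == pytest.approx(0.0, abs=1e-20)

    def test_alpha_zero_disables_seg_term(self, toy_net):
        params = toy_net.initial_parameters(np.random.default_rng(0))
        tgt = M.generate_targets(toy_net.cmug_fwd, toy_net.mn_segment_of, "forward")
        u0 = toy_net.initial_state(np.random.default_rng(3))
        costs, _ = M.trial_cost_and_grads(params, toy_net, tgt, u0, alpha=0.0)
        assert costs["c_seg"] == 0.0


class TestGradients:
    def test_bptt_matches_central_differences(self, toy_net):
        """Analytic gradients vs finite differences, relative 1e-3."""
        rng = np.random.default_rng(0)
        params = toy_net.initial_parameters(rng)
        tgt = M.generate_targets(toy_net.cmug_fwd, toy_net.mn_segment_of, "forward")
        u0 = toy_net.initial_state(rng)
        alpha = 0.05
        costs, grads = M.trial_cost_and_grads(params, toy_net, tgt, u0, alpha)

        def total(p):
            c, _ = M.trial_cost_and_grads(
                p, toy_net, tgt, u0, alpha, with_grads=False
            )
            return c["c_targ"] + c["c_sel"] + c["c_seg"]

        checked = 0
        for key in PARAM_KEYS:
            if key == "i_bwd":
                continue  # unused in a forward trial
            arr = getattr(params, key)
            for i in rng.choice(arr.size, size=min(4, arr.size), replace=False):
                eps = 1e-6 * max(1.0, abs(arr.flat[i]))
                hi, lo = params.copy(), params.copy()
                getattr(hi, key).flat[i] += eps
                getattr(lo, key).flat[i] -= eps
                fd = (total(hi) - total(lo)) / (2 * eps)
                an = grads[key].flat[i]
                assert an == pytest.approx(fd, rel=1e-3, abs=1e-8), key
                checked += 1
        assert checked >= 30


class TestOptimize:
    def test_short_run_reduces_cost_and_keeps_constraints(self, toy_net):
        cfg = M.TrainingConfig(seed=5, epochs=80)
        res = M.optimize(toy_net, config=cfg, check_constraints_every=1)
        assert not res.diverged
        assert res.history["total"].iloc[-1] < res.history["total"].iloc[0]
        res.params.check(toy_net.struct_p, toy_net.struct_m)
        # sign-constrained magnitudes never crossed zero
        assert (res.params.wp[toy_net.struct_p.constrained] >= 0).all()
        assert (res.params.wm[toy_net.struct_m.constrained] >= 0).all()

    def test_weight_correlation_properties(self, toy_net):
        J0 = toy_net.struct_m.matrix(toy_net.wm0)
        assert M.weight_correlation(J0, J0) == pytest.approx(1.0)
        assert M.weight_correlation(2 * J0, J0) == pytest.approx(1.0)
        rng = np.random.default_rng(0)
        noisy = J0 * (1 + 0.1 * rng.normal(size=J0.shape))
        assert M.weight_correlation(noisy, J0) > 0.9
        with pytest.raises(ValidationError):
            M.weight_correlation(np.zeros((3, 3)), np.zeros((3, 3)))


class TestNormalizedTimeCourse:
    def test_target_onset_maps_near_zero(self):
        tgt = M.generate_targets(
            np.array([0, 1, 2, 3]), np.zeros(4, dtype=int), "forward"
        )
        m = tgt.m_star.T
        grid, curves = M.normalized_time_course(m, m)
        first = curves[:, 0]
        # the first CMUG rises right at normalized time 0
        # the summed-rate onset lies slightly after the first group's own
        # rise, so "near zero" allows a fraction of the segment duration
        rise = grid[np.nonzero(first > 0.05)[0][0]]
        assert abs(rise) < 0.2

    def test_time_shift_invariance(self):
        tgt = M.generate_targets(
            np.array([0, 1, 2, 3]), np.zeros(4, dtype=int), "forward"
        )
        m = tgt.m_star.T
        shifted = np.roll(m, 5, axis=0)
        g1, c1 = M.normalized_time_course(m, m)
        g2, c2 = M.normalized_time_course(shifted, shifted)
        np.testing.assert_allclose(c1, c2, atol=1e-9)

    def test_silent_mns_raise(self):
        with pytest.raises(EmptyInputError):
            M.normalized_time_course(np.zeros((10, 2)), np.zeros((10, 2)))


class TestEnsemble:
    def test_identical_seeds_identical_members(self, toy_net):
        cfg = M.TrainingConfig(epochs=30)
        summary = M.run_ensemble(toy_net, [7, 7], config=cfg)
        a, b = summary.results
        np.testing.assert_array_equal(a.params.wp, b.params.wp)
        np.testing.assert_array_equal(a.params.wm, b.params.wm)
        np.testing.assert_array_equal(a.params.i_fwd, b.params.i_fwd)

    def test_needs_two_seeds(self, toy_net):
        with pytest.raises(ValidationError):
            M.run_ensemble(toy_net, [1])
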