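import math

import numpy as np
import pytest
import scipy.integrate

from eisync import (
    Connectivity,
    NeuronParams,
    SimulationGrid,
    SpikeRecord,
    StimulusEnsemble,
    SynapseParams,
    build_connectivity,
    firing_rates,
    isolated_rate_closed_form,
    kernel_peak_time,
    simulate,
    simulate_isolated,
    spike_counts,
    synaptic_kernel,
)

E_PARAMS = NeuronParams(tau_m=50.0)
GRID = SimulationGrid(dt=0.05, duration=300.0)

EXC = SynapseParams(strength=0.002, tau_decay=6.0, tau_rise=0.1, e_rev=0.0, delay=0.2)
INH = SynapseParams(strength=7 / 600, tau_decay=6.0, tau_rise=0.1, e_rev=-85.0, delay=0.2)


def constant_ensemble(values, noise_sd=0.0, seed=0):
    return StimulusEnsemble(strengths=np.atleast_1d(values), noise_sd=noise_sd, seed=seed)


class TestConnectivity:
    def test_full_connectivity_has_all_weights_but_diagonal(self):
        conn = build_connectivity(5, 3, 1.0, 0.1, 0.2, 0.3, 0.4, seed=0)
        off_diag = ~np.eye(5, dtype=bool)
        assert np.all(conn.w_ee[off_diag] == 0.1)
        assert np.all(np.diagonal(conn.w_ee) == 0)
        assert np.all(conn.w_ei == 0.2)
        assert np.all(conn.w_ie == 0.3)
        assert np.all(np.diagonal(conn.w_ii) == 0)

    def test_zero_probability_gives_isolated_population(self):
        conn = build_connectivity(5, 3, 0.0, 0.1, 0.2, 0.3, 0.4, seed=0)
        assert conn.is_empty()

    def test_fill_fraction_matches_probability(self):
        fills = []
        for seed in range(20):
            conn = build_connectivity(450, 150, 0.7, 1, 1, 1, 1, seed=seed)
            total = sum(
                w.sum() for w in (conn.w_ee, conn.w_ei, conn.w_ie, conn.w_ii)
            )
            slots = 450 * 449 + 150 * 450 * 2 + 150 * 149  # off-diagonal only
            fills.append(total / slots)
        assert np.mean(fills) == pytest.approx(0.7, abs=0.01)

    def test_negative_strength_rejected(self):
        with pytest.raises(ValueError):
            build_connectivity(5, 3, 0.5, -0.1, 0.2, 0.3, 0.4, seed=0)

    def test_reproducible_by_seed(self):
        a = build_connectivity(20, 10, 0.5, 1, 1, 1, 1, seed=3)
        b = build_connectivity(20, 10, 0.5, 1, 1, 1, 1, seed=3)
        assert np.array_equal(a.w_ee, b.w_ee) and np.array_equal(a.w_ie, b.w_ie)

    def test_self_connections_rejected(self):
        w = np.full((3, 3), 0.1)
        with pytest.raises(ValueError):
            Connectivity(w_ee=w, w_ei=np.zeros((2, 3)), w_ie=np.zeros((3, 2)),
                         w_ii=np.zeros((2, 2)), connection_prob=1.0)


class TestSynapticKernel:
    def test_zero_before_and_at_delay(self):
        assert synaptic_kernel(0.0, EXC) == 0.0
        assert synaptic_kernel(0.19, EXC) == 0.0
        assert synaptic_kernel(EXC.delay, EXC) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_after_delay(self):
        t = np.linspace(0, 60, 2000)
        assert np.all(synaptic_kernel(t, EXC) >= 0)

    def test_unit_normalization(self):
        integral, _ = scipy.integrate.quad(
            lambda t: synaptic_kernel(t, EXC), 0.0, 400.0, limit=300
        )
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_peak_location_matches_closed_form(self):
        # d + tau_d*tau_r/(tau_d - tau_r) * ln(tau_d/tau_r) for (6, 0.1, 0.2)
        peak = kernel_peak_time(EXC)
        assert peak == pytest.approx(0.6164, abs=5e-4)
        t = np.arange(EXC.delay, 10.0, 1e-4)
        dense_argmax = t[np.argmax(synaptic_kernel(t, EXC))]
        assert peak == pytest.approx(dense_argmax, abs=2e-4)

    def test_equal_time_constants_rejected(self):
        with pytest.raises(ValueError):
            SynapseParams(strength=1.0, tau_decay=6.0, tau_rise=6.0, e_rev=0.0)


class TestClosedFormRate:
    @pytest.mark.parametrize(
        "c,expected",
        [(3.69, 25.612), (3.88, 27.603), (3.58, 24.452), (3.80, 26.766)],
    )
    def test_calibrated_rates(self, c, expected):
        assert isolated_rate_closed_form(c, E_PARAMS) == pytest.approx(expected, abs=1e-3)

    def test_subthreshold_drive_is_silent(self):
        assert isolated_rate_closed_form(1.9, E_PARAMS) == 0.0
        assert isolated_rate_closed_form(2.0, E_PARAMS) == 0.0

    def test_rheobase_limit_rate_vanishes(self):
        assert 0 < isolated_rate_closed_form(2.0 * 1.000001, E_PARAMS) < 2.0


class TestIsolatedSimulation:
    @pytest.mark.parametrize("c,count", [(4.26, 9), (3.53, 7)])
    def test_printed_strength_counts(self, c, count):
        rec = simulate_isolated(E_PARAMS, constant_ensemble(c), GRID)
        assert spike_counts(rec, 300.0).counts[0] == count

    def test_subthreshold_never_spikes(self):
        rec = simulate_isolated(E_PARAMS, constant_ensemble(1.99), GRID)
        assert rec.times.size == 0

    def test_counts_match_closed_form_oracle_within_one(self):
        rng = np.random.default_rng(0)
        cs = rng.uniform(2.5, 6.0, 100)
        rec = simulate_isolated(E_PARAMS, constant_ensemble(cs), GRID)
        counts = spike_counts(rec, 300.0).counts
        for c, k in zip(cs, counts):
            isi = 1000.0 / isolated_rate_closed_form(c, E_PARAMS)
            assert abs(k - math.floor(300.0 / isi)) <= 1

    def test_dt_refinement_changes_counts_by_at_most_one(self):
        cs = np.random.default_rng(7).uniform(2.5, 6.0, 30)
        ens = constant_ensemble(cs)
        c1 = spike_counts(
            simulate_isolated(E_PARAMS, ens, SimulationGrid(dt=0.05, duration=300.0)), 300.0
        ).counts
        c2 = spike_counts(
            simulate_isolated(E_PARAMS, ens, SimulationGrid(dt=0.025, duration=300.0)), 300.0
        ).counts
        assert np.abs(c1 - c2).max() <= 1


def tiny_net(n_e=3, n_i=2, duration=50.0, seed=2, record_state=True):
    conn = build_connectivity(n_e, n_i, 1.0, 0.05, 0.05, 0.1, 0.1, seed=seed)
    stim = constant_ensemble([4.5, 4.0, 3.8][:n_e], seed=1)
    bg = constant_ensemble([2.6, 2.5][:n_i], seed=2)
    grid = SimulationGrid(dt=0.05, duration=duration)
    return simulate(
        E_PARAMS, NeuronParams(tau_m=10.0), EXC, EXC, INH, INH,
        conn, stim, bg, grid, seed=0, record_state=record_state,
    ) + (conn, grid)


class TestSimulate:
    def test_subthreshold_fixed_point(self):
        # no synapses, no noise: v relaxes to V_L + R*c and never spikes
        n_e, n_i = 3, 1
        conn = build_connectivity(n_e, n_i, 0.0, 0, 0, 0, 0, seed=0)
        stim = constant_ensemble([1.0, 1.5, 1.9])
        bg = constant_ensemble([1.0])
        grid = SimulationGrid(dt=0.05, duration=500.0)
        rec, trace = simulate(
            E_PARAMS, NeuronParams(tau_m=10.0), EXC, EXC, INH, INH,
            conn, stim, bg, grid, seed=0, record_state=True,
        )
        assert rec.times.size == 0
        assert trace.v_e[-1] == pytest.approx(-65.0 + np.array([1.0, 1.5, 1.9]), abs=1e-3)

    def test_single_neuron_matches_isolated_path(self):
        conn = build_connectivity(1, 1, 0.0, 0, 0, 0, 0, seed=0)
        stim = constant_ensemble(4.26)
        bg = constant_ensemble(0.0)
        rec, _ = simulate(
            E_PARAMS, NeuronParams(tau_m=10.0), EXC, EXC, INH, INH,
            conn, stim, bg, GRID, seed=0,
        )
        rec_iso = simulate_isolated(E_PARAMS, stim, GRID)
        a, b = rec.spike_times(0), rec_iso.spike_times(0)
        # the two integrators may differ by one floating-point ulp in the
        # per-step update, which can shift a crossing by at most one step
        assert a.size == b.size
        assert np.abs(a - b).max() <= GRID.dt + 1e-12

    def test_filter_equals_explicit_double_sum(self):
        # the per-neuron filter pair must reproduce the per-synapse kernel sum
        (rec, trace, conn, grid) = tiny_net()
        assert rec.times.size > 0
        t = trace.time
        for weights, kernel, e_rev, ref_tr, v_tr, pre_offset, n_pre in (
            (conn.w_ee, EXC, EXC.e_rev, trace.i_ee, trace.v_e, 0, conn.n_e),
            (conn.w_ie, INH, INH.e_rev, trace.i_ie, trace.v_e, conn.n_e, conn.n_i),
            (conn.w_ei, EXC, EXC.e_rev, trace.i_ei, trace.v_i, 0, conn.n_e),
            (conn.w_ii, INH, INH.e_rev, trace.i_ii, trace.v_i, conn.n_e, conn.n_i),
        ):
            ref = np.zeros_like(ref_tr)
            for i in range(ref.shape[1]):
                g = np.zeros_like(t)
                for j in range(n_pre):
                    w = weights[i, j]
                    if w == 0:
                        continue
                    for tk in rec.spike_times(j + pre_offset):
                        g += w * synaptic_kernel(t - tk, kernel)
                ref[:, i] = g * (v_tr[:, i] - e_rev)
            scale = max(np.abs(ref_tr).max(), 1e-12)
            assert np.abs(ref - ref_tr).max() / scale < 1e-9

    def test_reset_discipline(self):
        (rec, trace, conn, grid) = tiny_net(duration=100.0)
        assert np.all(trace.v_e <= E_PARAMS.v_thresh + 1e-12)
        assert np.all(trace.v_i <= E_PARAMS.v_thresh + 1e-12)

    def test_spike_times_strictly_increasing_within_bounds(self):
        (rec, trace, conn, grid) = tiny_net(duration=200.0)
        for i in range(conn.n_e + conn.n_i):
            tt = rec.spike_times(i)
            assert np.all(np.diff(tt) > 0)
            assert tt.size == 0 or (tt[0] > 0 and tt[-1] <= 200.0)

    def test_mismatched_kernel_parameters_rejected(self):
        other = SynapseParams(strength=0.002, tau_decay=5.0, tau_rise=0.1, e_rev=0.0, delay=0.2)
        conn = build_connectivity(2, 1, 1.0, 0.1, 0.1, 0.1, 0.1, seed=0)
        with pytest.raises(ValueError):
            simulate(
                E_PARAMS, E_PARAMS, EXC, other, INH, INH, conn,
                constant_ensemble([4.0, 4.0]), constant_ensemble(2.4), GRID,
            )


class TestCountsAndRates:
    def test_empty_record_gives_zero_counts(self):
        rec = SpikeRecord(neuron_ids=[], times=[], n_e=5, n_i=2, duration=300.0)
        assert np.all(spike_counts(rec, 300.0).counts == 0)
        assert np.all(firing_rates(rec) == 0)

    def test_rate_unit_conversion(self):
        rec = SpikeRecord(
            neuron_ids=[0] * 9, times=np.linspace(30, 270, 9), n_e=1, n_i=0,
            duration=300.0,
        )
        assert firing_rates(rec)[0] == pytest.approx(30.0)

    def test_count_monotone_in_window(self):
        (rec, _, conn, _) = tiny_net(duration=200.0, record_state=False)
        c_short = spike_counts(rec, 100.0).counts
        c_long = spike_counts(rec, 200.0).counts
        assert np.all(c_short <= c_long)

    def test_window_beyond_duration_rejected(self):
        rec = SpikeRecord(neuron_ids=[], times=[], n_e=1, n_i=0, duration=300.0)
        with pytest.raises(ValueError):
            spike_counts(rec, 301.0)
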