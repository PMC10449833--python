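"""Tests for the network integrator, spike records, rates and PSTH."""

from dataclasses import replace

import numpy as np
import pytest

from epsvnet.drive import InputSpec
from epsvnet.engine import (
    SpikeRecord,
    TrialProtocol,
    population_rate,
    psth,
    run_trial,
    save_records_h5,
)
from epsvnet.model import (
    DEFAULT_NEURON_PARAMS,
    NeuronState,
    membrane_derivatives,
    spike_update,
)
from epsvnet.network import NetworkConfig, build_network


def _one_neuron_net(params):
    cfg = NetworkConfig(
        sizes={params.name: 1},
        neuron_params={params.name: params},
        conn_prob={},
        base_g={},
        excitatory=frozenset({params.name}),
    )
    return build_network(cfg, seed=0)


class TestTrialProtocol:
    def test_default_windows_partition_the_trial(self):
        p = TrialProtocol()
        assert (p.preparation, p.settle, p.measure) == (250.0, 250.0, 500.0)
        assert p.onset == 250.0
        assert p.measure_window == (500.0, 1000.0)

    def test_non_partitioning_windows_rejected(self):
        with pytest.raises(ValueError):
            TrialProtocol(total=1000.0, preparation=250.0, settle=100.0, measure=500.0)

    def test_baseline_protocol(self):
        p = TrialProtocol.baseline(measure=2000.0)
        assert p.total == 2250.0
        assert p.measure_window == (250.0, 2250.0)


class TestRunTrial:
    def test_silent_input_cold_start_gives_no_spikes(self, single_pop_net):
        rec = run_trial(
            single_pop_net,
            InputSpec(baseline={"PC": 0.0}),
            TrialProtocol(total=300.0, preparation=100.0, settle=100.0, measure=100.0),
            seed=1,
        )
        assert rec.n_spikes == 0

    def test_engine_matches_scalar_reference_implementation(self):
        """A single current-driven neuron integrated by the compiled
        engine reproduces, step for step, a pure-Python reference built
        from the scalar model operations."""
        params = replace(DEFAULT_NEURON_PARAMS["PC"], I_e=700.0, name="PC")
        net = _one_neuron_net(params)
        protocol = TrialProtocol(total=200.0, preparation=50.0, settle=50.0, measure=100.0)
        dt = 0.1
        rec = run_trial(
            net, InputSpec(baseline={"PC": 0.0}), protocol,
            seed=0, dt=dt, record_v_neuron=0,
        )
        trace = rec.meta["v_trace"]

        # reference: forward Euler on the scalar model, same conventions
        n_steps = int(round(protocol.total / dt))
        ref_steps = int(round(params.t_r / dt))
        state = NeuronState(V=params.E_L)
        ref_count = 0
        ref_trace = np.empty(n_steps)
        spikes = []
        for t in range(n_steps):
            if ref_count > 0:
                ref_count -= 1
                state.V = params.V_r
                state.w += dt * (
                    params.a * (params.V_r - params.E_L) - state.w
                ) / params.tau_w
            else:
                dv, dw = membrane_derivatives(state, params)
                v_new = state.V + dt * dv
                state.w += dt * dw
                if v_new >= params.V_ceiling:
                    state = spike_update(
                        NeuronState(V=params.V_ceiling, w=state.w),
                        params,
                        (t + 1) * dt,
                    )
                    spikes.append((t + 1) * dt)
                    ref_count = ref_steps
                else:
                    state.V = v_new
            ref_trace[t] = state.V

        assert rec.n_spikes == len(spikes)
        np.testing.assert_allclose(rec.times, spikes, atol=1e-9)
        np.testing.assert_allclose(trace, ref_trace, atol=1e-6)

    def test_identical_seeds_are_bitwise_reproducible(self, ei_net):
        protocol = TrialProtocol(total=400.0, preparation=100.0, settle=100.0, measure=200.0)
        a = run_trial(ei_net, InputSpec(), protocol, seed=99)
        b = run_trial(ei_net, InputSpec(), protocol, seed=99)
        assert np.array_equal(a.neuron_ids, b.neuron_ids)
        assert np.array_equal(a.times, b.times)
        c = run_trial(ei_net, InputSpec(), protocol, seed=100)
        assert not (
            c.n_spikes == a.n_spikes and np.array_equal(c.times, a.times)
        )

    def test_refractoriness_and_spike_time_invariants(self, ei_net):
        """Every neuron's inter-spike intervals respect t_r = 2 ms and all
        spike times lie inside the trial."""
        protocol = TrialProtocol(total=600.0, preparation=200.0, settle=100.0, measure=300.0)
        rec = run_trial(ei_net, InputSpec(), protocol, seed=17)
        assert rec.n_spikes > 0
        assert rec.times.min() >= 0 and rec.times.max() <= protocol.total
        for neuron in np.unique(rec.neuron_ids):
            isi = np.diff(rec.spike_times_of(neuron))
            assert np.all(isi >= 2.0 - 1e-9)

    def test_evoked_input_shifts_rate_at_onset(self, single_pop_net):
        protocol = TrialProtocol()
        rec = run_trial(
            single_pop_net, InputSpec(baseline={"PC": 16.0}), protocol,
            delta={"PC": 12.0}, seed=23,
        )
        pre = population_rate(rec, "PC", 50.0, 250.0)
        post = population_rate(rec, "PC", 500.0, 1000.0)
        assert post > pre + 5.0


class TestPopulationRate:
    def _record(self, ids, times, n=10, duration=1000.0):
        order = np.argsort(times)
        return SpikeRecord(
            neuron_ids=np.asarray(ids)[order],
            times=np.asarray(times, dtype=float)[order],
            pop_slices={"PC": slice(0, n)},
            n_neurons=n,
            duration=duration,
            dt=0.1,
        )

    def test_simple_arithmetic(self):
        rec = self._record(np.zeros(25, dtype=int), np.linspace(1, 999, 25))
        assert population_rate(rec, "PC", 0.0, 1000.0) == pytest.approx(2.5)

    def test_no_spikes_gives_zero(self):
        rec = self._record(np.array([], dtype=int), np.array([]))
        assert population_rate(rec, "PC", 0.0, 1000.0) == 0.0

    def test_invalid_window_rejected(self):
        rec = self._record(np.array([], dtype=int), np.array([]))
        with pytest.raises(ValueError):
            population_rate(rec, "PC", 500.0, 500.0)


class TestPsth:
    def _poisson_record(self, rate_hz, n=20, duration=2000.0, seed=0):
        rng = np.random.default_rng(seed)
        ids, times = [], []
        for i in range(n):
            k = rng.poisson(rate_hz * duration / 1000.0)
            ids.extend([i] * k)
            times.extend(rng.uniform(0, duration, size=k))
        order = np.argsort(times)
        return SpikeRecord(
            neuron_ids=np.asarray(ids, dtype=int)[order],
            times=np.asarray(times)[order],
            pop_slices={"PC": slice(0, n)},
            n_neurons=n,
            duration=duration,
            dt=0.1,
        )

    def test_spike_count_conservation(self):
        rec = self._poisson_record(5.0)
        edges, traces, avg = psth([rec], "PC", binsize=10.0)
        n = rec.pop_slices["PC"].stop
        total = traces[0].sum() * n * 10.0 / 1000.0
        assert total == pytest.approx(rec.n_spikes)

    def test_flat_trace_for_homogeneous_poisson_surrogate(self):
        """Average PSTH of stationary Poisson spiking has no structure:
        every bin within a 99.99% Poisson envelope of the flat rate."""
        recs = [self._poisson_record(5.0, seed=s) for s in range(30)]
        _, _, avg = psth(recs, "PC", binsize=50.0)
        # expected counts per bin over all trials/members
        n, binsize, trials = 20, 50.0, 30
        lam = 5.0 * n * trials * binsize / 1000.0
        from scipy import stats

        lo, hi = stats.poisson.interval(0.9999, lam)
        counts = avg * n * trials * binsize / 1000.0
        assert np.all((counts >= lo) & (counts <= hi))

    def test_binsize_must_be_multiple_of_dt(self):
        rec = self._poisson_record(5.0)
        with pytest.raises(ValueError):
            psth([rec], "PC", binsize=10.05)

    def test_records_must_share_geometry(self):
        a = self._poisson_record(5.0, duration=1000.0)
        b = self._poisson_record(5.0, duration=2000.0)
        with pytest.raises(ValueError):
            psth([a, b], "PC")


def test_spike_record_h5_roundtrip(tmp_path, single_pop_net):
    rec = run_trial(
        single_pop_net, InputSpec(baseline={"PC": 16.0}),
        TrialProtocol(total=300.0, preparation=100.0, settle=0.0, measure=200.0),
        seed=3,
    )
    path = tmp_path / "trials.h5"
    save_records_h5([rec], path)
    import h5py

    with h5py.File(path) as fh:
        assert fh.attrs["n_trials"] == 1
        assert fh["trial_0000/time_ms"].shape == rec.times.shape
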