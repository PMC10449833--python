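"""Time-stepped network simulation.

The integrator advances all neurons on a fixed 0.1 ms grid: synaptic
conductances decay exactly (closed-form exponential per step), V and w
advance by forward Euler, and spikes are delivered to their targets
after the uniform conduction delay (an exact multiple of the step).
External drive is realised per neuron as a single equivalent Poisson
process at ``n_sources`` times the population rate — statistically
identical to superposing that many independent homogeneous sources —
with arrivals generated from exponential inter-arrival times.

The hot loop is compiled with numba; a scalar reference implementation
of the same update rules lives in :mod:`epsvnet.model` and the test
suite checks the two against each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
from numba import njit

from .drive import InputSpec, evoked_rates
from .model import EXP_ARG_MAX, EXP_ARG_MIN, SPIKE_CEILING_FACTOR
from .network import Network

__all__ = [
    "TrialProtocol",
    "SpikeRecord",
    "run_trial",
    "population_rate",
    "psth",
    "SimulationError",
]

DT_DEFAULT = 0.1  # ms


class SimulationError(RuntimeError):
    """Divergence (non-finite state) or overflow during a trial."""


@dataclass(frozen=True)
class TrialProtocol:
    """Timing of one trial (all in ms).

    The default protocol is 1000 ms per trial: 250 ms preparation to
    reach the operating point, stimulus onset at 250 ms, 250 ms to
    settle into the evoked state, and the last 500 ms scored as the
    steady-state response.
    """

    total: float = 1000.0
    preparation: float = 250.0
    settle: float = 250.0
    measure: float = 500.0

    def __post_init__(self) -> None:
        if min(self.total, self.measure) <= 0 or min(self.preparation, self.settle) < 0:
            raise ValueError("window lengths must be positive (prep/settle >= 0)")
        if not math.isclose(
            self.preparation + self.settle + self.measure, self.total
        ):
            raise ValueError("windows must partition the trial")

    @property
    def onset(self) -> float:
        """Stimulus onset time (ms): end of the preparation window."""
        return self.preparation

    @property
    def measure_window(self) -> tuple[float, float]:
        return (self.total - self.measure, self.total)

    @classmethod
    def baseline(cls, measure: float = 2000.0, preparation: float = 250.0
                 ) -> "TrialProtocol":
        """Baseline-only protocol: discard the preparation, score the rest."""
        return cls(total=preparation + measure, preparation=preparation,
                   settle=0.0, measure=measure)


@dataclass
class SpikeRecord:
    """Spike times of all neurons for one trial.

    ``neuron_ids`` / ``times`` are parallel arrays sorted by time;
    times are in ms within ``[0, duration]``.
    """

    neuron_ids: np.ndarray
    times: np.ndarray
    pop_slices: dict[str, slice]
    n_neurons: int
    duration: float
    dt: float
    meta: dict = field(default_factory=dict)

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def spike_times_of(self, neuron: int) -> np.ndarray:
        return self.times[self.neuron_ids == neuron]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"neuron_id": self.neuron_ids, "time_ms": self.times})

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _kernel_arrays(net: Network) -> dict:
    """Per-neuron parameter vectors and outgoing CSR adjacency, cached."""
    if net._kernel_cache:
        return net._kernel_cache
    cfg = net.config
    n = net.n_neurons
    names = cfg.population_names

    def vec(get, dtype=np.float64):
        out = np.empty(n, dtype=dtype)
        for pop in names:
            out[net.pop_slices[pop]] = get(cfg.neuron_params[pop])
        return out

    arrs = {
        "C_m": vec(lambda p: p.C_m),
        "g_L": vec(lambda p: p.g_L),
        "E_L": vec(lambda p: p.E_L),
        "V_th": vec(lambda p: p.V_th),
        "V_r": vec(lambda p: p.V_r),
        "E_e": vec(lambda p: p.E_e),
        "E_i": vec(lambda p: p.E_i),
        "I_e": vec(lambda p: p.I_e),
        "Delta_T": vec(lambda p: p.Delta_T if p.has_exponential else 0.0),
        "has_exp": vec(lambda p: p.has_exponential, dtype=np.bool_),
        "a": vec(lambda p: p.a if p.has_adaptation else 0.0),
        "b": vec(lambda p: p.b if p.has_adaptation else 0.0),
        "tau_w": vec(lambda p: p.tau_w if p.has_adaptation else 1.0),
        "has_adapt": vec(lambda p: p.has_adaptation, dtype=np.bool_),
        "V_ceil": vec(
            lambda p: p.V_th + SPIKE_CEILING_FACTOR * p.Delta_T
            if p.has_exponential else p.V_th
        ),
        "tau_e": vec(lambda p: p.tau_e),
        "tau_i": vec(lambda p: p.tau_i),
        "t_r": vec(lambda p: p.t_r),
    }

    order = np.lexsort((net.target, net.source))
    src = net.source[order]
    arrs["adj_targets"] = net.target[order].astype(np.int64)
    arrs["adj_weights"] = net.conductance[order].astype(np.float64)
    arrs["adj_indptr"] = np.concatenate(
        ([0], np.cumsum(np.bincount(src, minlength=n)))
    ).astype(np.int64)
    arrs["is_exc"] = net.is_excitatory_neuron()
    net._kernel_cache.update(arrs)
    return net._kernel_cache


@njit(cache=True, fastmath={"contract", "reassoc", "arcp"})
def _simulate(
    n_steps, dt, n,
    C_m, g_L, E_L, V_th, V_r, E_e, E_i, I_e,
    Delta_T, has_exp, a, b, tau_w, has_adapt, V_ceil,
    dec_e, dec_i, ref_steps,
    indptr, adj_tgt, adj_w, is_exc,
    lam_base, lam_evoked, onset_step, w_ext,
    alpha_kernel, scale_e, scale_i,
    delay_steps, seed,
    rec_id, rec_t, max_spikes,
    v_neuron, v_trace,
):  # pragma: no cover - exercised via run_trial
    np.random.seed(seed)
    V = E_L.copy()
    w = np.zeros(n)
    g_e = np.zeros(n)
    g_i = np.zeros(n)
    # auxiliary kernel state: for the alpha kernel a spike adds
    # g_peak*e/tau to y and g(t) then rises as y0*t*exp(-t/tau)
    y_e = np.zeros(n)
    y_i = np.zeros(n)
    ref_count = np.zeros(n, dtype=np.int64)

    nslots = delay_steps + 1
    buf_e = np.zeros((nslots, n))
    buf_i = np.zeros((nslots, n))

    # next external arrival time per neuron (ms)
    next_arr = np.empty(n)
    for i in range(n):
        lam = lam_base[i]
        next_arr[i] = np.random.exponential() / lam if lam > 0 else np.inf

    spk_now = np.empty(n, dtype=np.int64)

    n_spk = 0
    for t in range(n_steps):
        tnow = t * dt
        if t == onset_step:
            # memoryless rescale of pending waiting times to the new rate
            for i in range(n):
                lo, ln = lam_base[i], lam_evoked[i]
                if ln == lo:
                    continue
                if ln <= 0.0:
                    next_arr[i] = np.inf
                elif lo <= 0.0 or next_arr[i] == np.inf:
                    next_arr[i] = tnow + np.random.exponential() / ln
                else:
                    next_arr[i] = tnow + (next_arr[i] - tnow) * lo / ln
        slot = t % nslots
        n_now = 0
        for i in range(n):
            lam = lam_base[i] if t < onset_step else lam_evoked[i]
            # conductance decay + delayed recurrent input + external input
            inc_e = buf_e[slot, i]
            inc_i = buf_i[slot, i]
            buf_e[slot, i] = 0.0
            buf_i[slot, i] = 0.0
            while next_arr[i] <= tnow:
                inc_e += w_ext
                next_arr[i] += np.random.exponential() / lam
            if alpha_kernel:
                ge = dec_e[i] * (g_e[i] + dt * y_e[i])
                gi = dec_i[i] * (g_i[i] + dt * y_i[i])
                y_e[i] = dec_e[i] * y_e[i] + inc_e * scale_e[i]
                y_i[i] = dec_i[i] * y_i[i] + inc_i * scale_i[i]
            else:
                ge = g_e[i] * dec_e[i] + inc_e
                gi = g_i[i] * dec_i[i] + inc_i
            g_e[i] = ge
            g_i[i] = gi

            if ref_count[i] > 0:
                # V clamped at reset; adaptation keeps evolving
                ref_count[i] -= 1
                V[i] = V_r[i]
                if has_adapt[i]:
                    w[i] += dt * (a[i] * (V_r[i] - E_L[i]) - w[i]) / tau_w[i]
                continue

            Vi = V[i]
            I = (
                -g_L[i] * (Vi - E_L[i])
                - ge * (Vi - E_e[i])
                - gi * (Vi - E_i[i])
                + I_e[i]
            )
            if has_exp[i]:
                arg = (Vi - V_th[i]) / Delta_T[i]
                if arg > EXP_ARG_MAX:
                    arg = EXP_ARG_MAX
                if arg >= EXP_ARG_MIN:
                    I += g_L[i] * Delta_T[i] * math.exp(arg)
            if has_adapt[i]:
                I -= w[i]
                w[i] += dt * (a[i] * (Vi - E_L[i]) - w[i]) / tau_w[i]
            Vn = Vi + dt * I / C_m[i]
            if not (Vn == Vn):  # NaN guard
                return -1
            if Vn >= V_ceil[i]:
                # spike: reset, adaptation jump, refractory window
                V[i] = V_r[i]
                if has_adapt[i]:
                    w[i] += b[i]
                ref_count[i] = ref_steps[i]
                if n_spk < max_spikes:
                    rec_id[n_spk] = i
                    rec_t[n_spk] = (t + 1) * dt
                n_spk += 1
                spk_now[n_now] = i
                n_now += 1
            else:
                V[i] = Vn
        # deliver this step's spikes into the slot that is read again
        # delay_steps + 1 steps from now (emission at the end of the
        # step, so arrival is exactly one conduction delay later)
        for s in range(n_now):
            i = spk_now[s]
            exc = is_exc[i]
            for k in range(indptr[i], indptr[i + 1]):
                if exc:
                    buf_e[slot, adj_tgt[k]] += adj_w[k]
                else:
                    buf_i[slot, adj_tgt[k]] += adj_w[k]
        if v_neuron >= 0:
            v_trace[t] = V[v_neuron]
    return n_spk


def run_trial(
    net: Network,
    spec: InputSpec,
    protocol: Optional[TrialProtocol] = None,
    delta: Sequence[float] | dict[str, float] | None = None,
    dt: float = DT_DEFAULT,
    seed: int = 0,
    record_v_neuron: Optional[int] = None,
) -> SpikeRecord:
    """Simulate one trial and return its spike record.

    The network runs from a cold start (V = E_L, w = 0, g = 0) under
    baseline drive; at stimulus onset the external rates switch to
    baseline + ``delta`` (state is carried across the switch).  The
    run is deterministic given ``seed``.
    """
    protocol = protocol or TrialProtocol()
    arrs = _kernel_arrays(net)
    n = net.n_neurons
    n_steps = int(round(protocol.total / dt))
    delay_steps = int(round(net.config.delay_ms / dt))
    if delay_steps < 1:
        raise ValueError("delay must be at least one time step")

    pop_label = net.population_of()
    names = net.config.population_names
    base = evoked_rates(spec, {p: 0.0 for p in spec.baseline})
    evoked = evoked_rates(spec, delta if delta is not None else {})
    base_by_pop = np.array([base[p] for p in names])
    evo_by_pop = np.array([evoked[p] for p in names])
    # equivalent single-process rate, events per ms
    lam_base = spec.n_sources * base_by_pop[pop_label] / 1000.0
    lam_evoked = spec.n_sources * evo_by_pop[pop_label] / 1000.0
    onset_step = int(round(protocol.onset / dt))

    max_spikes = int(n * protocol.total / 1000.0 * 400) + 1000
    rec_id = np.empty(max_spikes, dtype=np.int64)
    rec_t = np.empty(max_spikes, dtype=np.float64)

    v_neuron = -1 if record_v_neuron is None else int(record_v_neuron)
    v_trace = np.zeros(n_steps if v_neuron >= 0 else 1)

    n_spk = _simulate(
        n_steps, dt, n,
        arrs["C_m"], arrs["g_L"], arrs["E_L"], arrs["V_th"], arrs["V_r"],
        arrs["E_e"], arrs["E_i"], arrs["I_e"],
        arrs["Delta_T"], arrs["has_exp"], arrs["a"], arrs["b"],
        arrs["tau_w"], arrs["has_adapt"], arrs["V_ceil"],
        np.exp(-dt / arrs["tau_e"]), np.exp(-dt / arrs["tau_i"]),
        np.round(arrs["t_r"] / dt).astype(np.int64),
        arrs["adj_indptr"], arrs["adj_targets"], arrs["adj_weights"],
        arrs["is_exc"],
        lam_base, lam_evoked, onset_step, spec.weight_ns,
        net.config.synapse_kernel == "alpha",
        math.e / arrs["tau_e"], math.e / arrs["tau_i"],
        delay_steps, int(seed) % (2**32),
        rec_id, rec_t, max_spikes,
        v_neuron, v_trace,
    )
    if n_spk < 0:
        raise SimulationError("non-finite membrane potential during trial")
    if n_spk > max_spikes:
        raise SimulationError("spike buffer overflow (runaway activity)")

    rec = SpikeRecord(
        neuron_ids=rec_id[:n_spk].copy(),
        times=rec_t[:n_spk].copy(),
        pop_slices=dict(net.pop_slices),
        n_neurons=n,
        duration=protocol.total,
        dt=dt,
        meta={
            "seed": int(seed),
            "protocol": protocol,
            "delta": None if delta is None else np.asarray(delta, dtype=float)
            if not isinstance(delta, dict) else dict(delta),
        },
    )
    if v_neuron >= 0:
        rec.meta["v_trace"] = v_trace
    return rec


def population_rate(
    rec: SpikeRecord, population: str, t0: float, t1: float
) -> float:
    """Mean firing rate (Hz) of a population over ``[t0, t1)``.

    Total spike count of the population's members divided by member
    count and window length.
    """
    if not t0 < t1:
        raise ValueError("t0 must be smaller than t1")
    sl = rec.pop_slices[population]
    n_members = sl.stop - sl.start
    if n_members == 0:
        raise ValueError(f"population {population} is empty")
    in_pop = (rec.neuron_ids >= sl.start) & (rec.neuron_ids < sl.stop)
    in_win = (rec.times >= t0) & (rec.times < t1)
    count = int(np.count_nonzero(in_pop & in_win))
    return count / n_members / ((t1 - t0) / 1000.0)


def psth(
    records: Sequence[SpikeRecord],
    population: str,
    binsize: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Peristimulus time histogram over a set of trials.

    Returns ``(bin_edges, per_trial, average)`` where ``per_trial`` is
    an (n_trials, n_bins) array of rates (Hz) and ``average`` is the
    across-trial mean trace.  ``binsize`` must be a multiple of the
    integration step.
    """
    if not records:
        raise ValueError("no spike records given")
    dt = records[0].dt
    duration = records[0].duration
    for r in records:
        if r.dt != dt or r.duration != duration:
            raise ValueError("records must share duration and dt")
    ratio = binsize / dt
    if not math.isclose(ratio, round(ratio)):
        raise ValueError("binsize must be a multiple of dt")
    n_bins = int(round(duration / binsize))
    edges = np.arange(n_bins + 1) * binsize

    sl = records[0].pop_slices[population]
    n_members = sl.stop - sl.start
    traces = np.zeros((len(records), n_bins))
    for k, r in enumerate(records):
        mask = (r.neuron_ids >= sl.start) & (r.neuron_ids < sl.stop)
        counts, _ = np.histogram(r.times[mask], bins=edges)
        traces[k] = counts / n_members / (binsize / 1000.0)
    return edges, traces, traces.mean(axis=0)


def save_records_h5(records: Sequence[SpikeRecord], path) -> None:
    """Archive a multi-trial set of spike records to HDF5."""
    with h5py.File(path, "w") as fh:
        fh.attrs["n_trials"] = len(records)
        for k, r in enumerate(records):
            grp = fh.create_group(f"trial_{k:04d}")
            grp.create_dataset("neuron_id", data=r.neuron_ids)
            grp.create_dataset("time_ms", data=r.times)
            grp.attrs["duration"] = r.duration
            grp.attrs["dt"] = r.dt
            grp.attrs["n_neurons"] = r.n_neurons
            for pop, sl in r.pop_slices.items():
                grp.attrs[f"pop_{pop}"] = (sl.start, sl.stop)
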