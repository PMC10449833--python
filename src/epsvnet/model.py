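"""Single-neuron dynamics and synapse kernel.

Neurons are adaptive exponential integrate-and-fire (AdEx) point neurons
with conductance-based synapses.  Subthreshold dynamics:

    C_m dV/dt = -g_L (V - E_L) + g_L * Delta_T * exp((V - V_th)/Delta_T)
                - g_e(t) (V - E_e) - g_i(t) (V - E_i) - w + I_e
    tau_w dw/dt = a (V - E_L) - w

Two conductance kernels are supported, both with additive superposition
of presynaptic spikes:

* ``"alpha"`` (default): g(t) = g_peak * (t/tau) * exp(1 - t/tau), the
  alpha function with rise time tau and peak conductance g_peak at
  t = tau.  This is the kernel whose charge transfer reproduces the
  circuit's calibrated baseline firing rates (see docs/methods.md).
* ``"exp"``: g(t) = g_peak * exp(-t/tau) with an instantaneous
  (Heaviside) onset.

Populations without adaptation or slope-factor parameters (PV basket
cells here) reduce to plain leaky integrate-and-fire neurons with a
hard threshold.

The functions in this module are the scalar reference implementation;
the vectorised network integrator in :mod:`epsvnet.engine` is checked
against it in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "NeuronParams",
    "NeuronState",
    "DEFAULT_NEURON_PARAMS",
    "membrane_derivatives",
    "spike_update",
    "decay_conductance",
    "psp_peak",
    "conductance_cap",
    "params_to_yaml",
    "params_from_yaml",
]

#: number of slope factors above V_th at which a spike is detected for
#: neurons with an exponential term (the numerical surrogate for the
#: divergence of the AdEx upswing).
SPIKE_CEILING_FACTOR = 5.0

#: clip for the exponent of the AdEx spike-initiation term, to guard
#: against overflow when a large synaptic kick throws V past the ceiling
#: within a single step.
EXP_ARG_MAX = 16.0

#: below this exponent the spike-initiation term is dropped entirely;
#: at the cutoff it contributes < 0.3 pA (< 2e-3 mV/ms), far below the
#: integration error of the scheme.
EXP_ARG_MIN = -5.0


@dataclass(frozen=True)
class NeuronParams:
    """Per-population membrane, spike and synapse constants.

    Adaptation / exponential parameters (``a``, ``b``, ``Delta_T``,
    ``tau_w``) may be ``None``; they must then all be ``None`` and the
    neuron is integrated as a leaky integrate-and-fire unit.
    """

    name: str
    C_m: float  # pF
    E_L: float  # mV
    g_L: float  # nS
    V_th: float  # mV
    V_r: float  # mV
    tau_e: float  # ms
    tau_i: float  # ms
    Delta_T: Optional[float] = None  # mV
    a: Optional[float] = None  # nS
    b: Optional[float] = None  # pA
    tau_w: Optional[float] = None  # ms
    t_r: float = 2.0  # ms
    E_e: float = 0.0  # mV
    E_i: float = -85.0  # mV
    I_e: float = 0.0  # pA

    def __post_init__(self) -> None:
        if self.C_m <= 0:
            raise ValueError(f"{self.name}: C_m must be positive")
        if self.g_L <= 0:
            raise ValueError(f"{self.name}: g_L must be positive")
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError(f"{self.name}: synaptic time constants must be positive")
        if not self.V_r < self.V_th:
            raise ValueError(f"{self.name}: V_r must lie below V_th")
        adapt = (self.a, self.b, self.Delta_T, self.tau_w)
        if any(x is None for x in adapt) and not all(x is None for x in adapt):
            raise ValueError(
                f"{self.name}: a, b, Delta_T, tau_w must be all present or all absent"
            )
        if self.tau_w is not None and self.tau_w <= 0:
            raise ValueError(f"{self.name}: tau_w must be positive")

    @property
    def has_adaptation(self) -> bool:
        return self.a is not None

    @property
    def has_exponential(self) -> bool:
        return self.Delta_T is not None

    @property
    def V_ceiling(self) -> float:
        """Spike-detection potential (mV).

        ``V_th`` itself for hard-threshold neurons; a few slope factors
        above it when the exponential upswing makes the crossing of
        ``V_th`` alone ambiguous.
        """
        if self.Delta_T is None:
            return self.V_th
        return self.V_th + SPIKE_CEILING_FACTOR * self.Delta_T


@dataclass
class NeuronState:
    """Dynamic variables of a single neuron."""

    V: float  # mV
    w: float = 0.0  # pA
    g_e: float = 0.0  # nS
    g_i: float = 0.0  # nS
    refractory_until: float = -math.inf  # ms

    def __post_init__(self) -> None:
        if self.g_e < 0 or self.g_i < 0:
            raise ValueError("conductances must be non-negative")


# Membrane capacitance shared by all populations (pF).  The membrane
# time constant of pyramidal cells is then C_m / g_L ~ 9 ms; the value
# is fixed by calibrating the circuit's baseline firing rates against
# their in-vivo anchors (see docs/methods.md).
DEFAULT_C_M = 190.0

DEFAULT_NEURON_PARAMS: dict[str, NeuronParams] = {
    # excitatory pyramidal cells
    "PC": NeuronParams(
        name="PC", C_m=DEFAULT_C_M, E_L=-70.0, g_L=20.3, V_th=-41.5, V_r=-66.4,
        a=2.0, b=4.0, Delta_T=2.0, tau_w=120.0, tau_e=0.22, tau_i=5.0,
    ),
    # parvalbumin-expressing basket cells: adaptation disabled (a = b
    # = 0) but the spike-initiation slope factor kept at the common
    # 2 mV — the calibrated reading of the "no adaptation" entry
    "PV": NeuronParams(
        name="PV", C_m=DEFAULT_C_M, E_L=-70.0, g_L=77.1, V_th=-41.6, V_r=-67.4,
        a=0.0, b=0.0, Delta_T=2.0, tau_w=120.0, tau_e=0.2, tau_i=5.5,
    ),
    # somatostatin-expressing cells
    "SST": NeuronParams(
        name="SST", C_m=DEFAULT_C_M, E_L=-70.0, g_L=21.4, V_th=-41.8, V_r=-59.9,
        a=2.0, b=4.0, Delta_T=2.0, tau_w=120.0, tau_e=0.29, tau_i=9.1,
    ),
    # vasoactive-intestinal-polypeptide-expressing cells; note the
    # negative subthreshold adaptation
    "VIP": NeuronParams(
        name="VIP", C_m=DEFAULT_C_M, E_L=-70.0, g_L=26.6, V_th=-43.7, V_r=-65.7,
        a=-1.0, b=19.0, Delta_T=2.0, tau_w=120.0, tau_e=0.28, tau_i=12.2,
    ),
}


def membrane_derivatives(
    state: NeuronState, params: NeuronParams
) -> tuple[float, float]:
    """Right-hand side of the subthreshold dynamics.

    Returns ``(dV/dt, dw/dt)`` in (mV/ms, pA/ms).  The exponential
    spike-initiation term and the adaptation dynamics are omitted
    entirely for populations whose corresponding parameters are absent.
    """
    if not (
        math.isfinite(state.V)
        and math.isfinite(state.w)
        and math.isfinite(state.g_e)
        and math.isfinite(state.g_i)
    ):
        raise ValueError("non-finite neuron state")
    if state.V > params.V_ceiling:
        raise ValueError("membrane potential above the spike-detection ceiling")

    I = (
        -params.g_L * (state.V - params.E_L)
        - state.g_e * (state.V - params.E_e)
        - state.g_i * (state.V - params.E_i)
        + params.I_e
    )
    dw_dt = 0.0
    if params.has_exponential:
        arg = min((state.V - params.V_th) / params.Delta_T, EXP_ARG_MAX)
        if arg >= EXP_ARG_MIN:
            I += params.g_L * params.Delta_T * math.exp(arg)
    if params.has_adaptation:
        I -= state.w
        dw_dt = (params.a * (state.V - params.E_L) - state.w) / params.tau_w
    return I / params.C_m, dw_dt


def spike_update(state: NeuronState, params: NeuronParams, t: float) -> NeuronState:
    """Apply the reset rule after a spike detected at time ``t`` (ms).

    V is reset to ``V_r``, the adaptation current is incremented by
    ``b`` (by nothing when absent), and the neuron is made refractory
    for ``t_r`` ms with V clamped at ``V_r``.  Within an ongoing
    refractory window the call is a no-op (the detection is suppressed).
    """
    if t < state.refractory_until:
        return state
    b = params.b if params.has_adaptation else 0.0
    return replace(
        state,
        V=params.V_r,
        w=state.w + b,
        refractory_until=t + params.t_r,
    )


def decay_conductance(g: float, dt: float, tau: float) -> float:
    """Exponential decay of a synaptic conductance over ``dt`` ms.

    Incoming spikes add their peak conductance instantaneously
    (Heaviside onset) and superpose additively; the decay between
    events is exact: ``g * exp(-dt/tau)``.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if tau <= 0:
        raise ValueError("tau must be positive")
    return g * math.exp(-dt / tau)


def psp_peak(
    g_peak: float,
    tau_syn: float,
    E_rev: float,
    params: NeuronParams,
    V_hold: float = -55.0,
    dt: float = 0.005,
    kernel: str = "alpha",
) -> float:
    """Peak postsynaptic-potential deflection (mV) from ``V_hold``.

    Simulates the passive membrane (leak anchored at ``V_hold``, no
    adaptation or spike-initiation term) receiving a single spike of
    peak conductance ``g_peak`` through the chosen synapse kernel, and
    returns the signed extremum of ``V - V_hold``.  The sign follows
    the driving force ``E_rev - V_hold``.
    """
    if g_peak < 0:
        raise ValueError("g_peak must be non-negative")
    if g_peak == 0.0 or E_rev == V_hold:
        return 0.0
    peaks = _psp_peaks(
        np.asarray([g_peak], dtype=float), tau_syn, E_rev, params, V_hold,
        dt, kernel,
    )
    return float(peaks[0])


def _psp_peaks(
    g_peaks: np.ndarray,
    tau_syn: float,
    E_rev: float,
    params: NeuronParams,
    V_hold: float,
    dt: float = 0.005,
    kernel: str = "alpha",
) -> np.ndarray:
    """Vectorised PSP-peak computation for an array of conductances."""
    if kernel not in ("alpha", "exp"):
        raise ValueError("kernel must be 'alpha' or 'exp'")
    tau_m = params.C_m / params.g_L
    t_end = 12.0 * tau_syn + 5.0 * tau_m
    n_steps = int(math.ceil(t_end / dt))
    decay = math.exp(-dt / tau_syn)

    v = np.full(g_peaks.shape, V_hold, dtype=float)
    if kernel == "exp":
        g = g_peaks.astype(float).copy()
        y = np.zeros_like(g)
    else:
        # alpha kernel: g(t) = y0 * t * exp(-t/tau) with y0 = g_peak*e/tau
        g = np.zeros_like(g_peaks, dtype=float)
        y = g_peaks * math.e / tau_syn
    extremum = np.zeros_like(v)
    sign = 1.0 if E_rev > V_hold else -1.0
    for _ in range(n_steps):
        dv = (-params.g_L * (v - V_hold) - g * (v - E_rev)) / params.C_m
        v = v + dt * dv
        g = decay * (g + dt * y)  # exact for both kernels (y=0 for exp)
        y *= decay
        defl = sign * (v - V_hold)
        np.maximum(extremum, defl, out=extremum)
    return sign * extremum


def conductance_cap(
    cap_mv: float,
    tau_syn: float,
    E_rev: float,
    params: NeuronParams,
    V_hold: float = -55.0,
    kernel: str = "alpha",
) -> float:
    """Peak conductance (nS) whose PSP deflection equals ``cap_mv``.

    Inverts :func:`psp_peak` by bisection; used to clip sampled
    synaptic weights so that no EPSP (IPSP) exceeds its bound at the
    holding potential.
    """
    from scipy.optimize import brentq

    cap = abs(cap_mv)
    if cap == 0.0:
        return 0.0

    def f(g: float) -> float:
        return abs(psp_peak(g, tau_syn, E_rev, params, V_hold, kernel=kernel)) - cap

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e7:
            raise RuntimeError("could not bracket the conductance cap")
    return float(brentq(f, 0.0, hi, xtol=1e-6))


def params_to_yaml(params: dict[str, NeuronParams], path) -> None:
    """Serialize one parameter block per population to YAML."""
    blocks = {}
    for name, p in params.items():
        d = asdict(p)
        d.pop("name")
        blocks[name] = d
    with open(path, "w") as fh:
        yaml.safe_dump(blocks, fh, sort_keys=False)


def params_from_yaml(path) -> dict[str, NeuronParams]:
    """Load per-population parameter blocks written by :func:`params_to_yaml`."""
    with open(path) as fh:
        blocks = yaml.safe_load(fh)
    return {name: NeuronParams(name=name, **d) for name, d in blocks.items()}
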