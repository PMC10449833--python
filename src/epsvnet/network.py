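"""Construction of the recurrent microcircuit.

The default configuration is the EPSV circuit: 3600 excitatory
pyramidal cells (PC) plus three inhibitory interneuron populations —
480 PV, 360 SST and 360 VIP cells.  Any ordered pair of populations is
connected independently with a type-specific probability; synaptic
peak conductances are a type-specific base value scaled by log-normal
(mu=0, sigma=1) draws and clipped so that no single EPSP exceeds
+0.5 mV and no IPSP exceeds -2.0 mV at a -55 mV holding potential.
All synapses conduct with a 2 ms delay.  Autapses are never drawn.

Degenerate configurations — a single weakly coupled excitatory
population and a two-population E-I circuit — are built through the
same machinery and run through the same engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .model import DEFAULT_NEURON_PARAMS, NeuronParams, conductance_cap

__all__ = [
    "POPULATIONS",
    "CONNECTION_PROB",
    "BASE_CONDUCTANCE",
    "NetworkConfig",
    "Network",
    "draw_connections",
    "sample_weights",
    "build_network",
]

POPULATIONS = ("PC", "PV", "SST", "VIP")

# Connection probability, (source, target) -> p.  Pairs not listed do
# not connect.  The motif follows the canonical neocortical
# interneuron circuit: PC excites everyone, PV inhibits PC and itself,
# SST inhibits PC, PV and VIP (never itself), VIP inhibits SST almost
# exclusively — which is also the wiring whose baseline state
# calibrates to the in-vivo anchor rates.
CONNECTION_PROB: dict[tuple[str, str], float] = {
    ("PC", "PC"): 0.1, ("PC", "PV"): 0.45, ("PC", "SST"): 0.35,
    ("PC", "VIP"): 0.1,
    ("PV", "PC"): 0.6, ("PV", "PV"): 0.5,
    ("SST", "PC"): 0.55, ("SST", "PV"): 0.6, ("SST", "VIP"): 0.45,
    ("VIP", "SST"): 0.5,
}

# Base synaptic peak conductance (nS), (source, target) -> g.
BASE_CONDUCTANCE: dict[tuple[str, str], float] = {
    ("PC", "PC"): 0.20, ("PC", "PV"): 0.27, ("PC", "SST"): 0.21,
    ("PC", "VIP"): 0.78,
    ("PV", "PC"): 0.08, ("PV", "PV"): 0.46,
    ("SST", "PC"): 0.16, ("SST", "PV"): 0.45, ("SST", "VIP"): 0.07,
    ("VIP", "SST"): 0.07,
}


@dataclass
class NetworkConfig:
    """Sizes, connectivity matrices and weight rules of a circuit."""

    sizes: dict[str, int]
    neuron_params: dict[str, NeuronParams]
    conn_prob: dict[tuple[str, str], float]
    base_g: dict[tuple[str, str], float]
    excitatory: frozenset[str] = frozenset({"PC"})
    delay_ms: float = 2.0
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    epsp_cap_mv: float = 0.5
    ipsp_cap_mv: float = 2.0  # magnitude
    cap_hold_mv: float = -55.0
    #: conductance kernel: "alpha" (rise-time tau, calibrated default)
    #: or "exp" (instantaneous onset, exponential decay)
    synapse_kernel: str = "alpha"

    def __post_init__(self) -> None:
        if self.synapse_kernel not in ("alpha", "exp"):
            raise ValueError("synapse_kernel must be 'alpha' or 'exp'")
        if self.delay_ms <= 0:
            raise ValueError("delay must be positive")
        for pop, n in self.sizes.items():
            if n <= 0:
                raise ValueError(f"population {pop} must have positive size")
            if pop not in self.neuron_params:
                raise ValueError(f"population {pop} has no neuron parameters")
        for pair, p in self.conn_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"connection probability {pair} outside [0, 1]")
            if pair[0] not in self.sizes or pair[1] not in self.sizes:
                raise ValueError(f"connection pair {pair} names an unknown population")
            if p > 0 and self.base_g.get(pair) is None:
                raise ValueError(
                    f"pair {pair} has p={p} but no base conductance; "
                    "set base_g or zero the probability"
                )
        for pair, g in self.base_g.items():
            if g < 0:
                raise ValueError(f"base conductance {pair} must be non-negative")

    @property
    def population_names(self) -> tuple[str, ...]:
        return tuple(self.sizes)

    @classmethod
    def default(cls, **overrides) -> "NetworkConfig":
        """The full EPSV circuit (3600/480/360/360)."""
        kwargs = dict(
            sizes={"PC": 3600, "PV": 480, "SST": 360, "VIP": 360},
            neuron_params=dict(DEFAULT_NEURON_PARAMS),
            conn_prob=dict(CONNECTION_PROB),
            base_g=dict(BASE_CONDUCTANCE),
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def single_population(cls, n: int = 400, p: float = 0.1,
                          g: float = 0.1) -> "NetworkConfig":
        """One excitatory population with weak recurrent coupling."""
        return cls(
            sizes={"PC": n},
            neuron_params={"PC": DEFAULT_NEURON_PARAMS["PC"]},
            conn_prob={("PC", "PC"): p},
            base_g={("PC", "PC"): g},
        )

    @classmethod
    def excitatory_inhibitory(cls, n_exc: int = 400, n_inh: int = 100,
                              strong: bool = False) -> "NetworkConfig":
        """Two-population E-I circuit.

        ``strong`` switches between weak mutual coupling (the default,
        matching the weak-recurrency regime) and strong self-coupling.
        """
        if strong:
            prob = {("PC", "PC"): 0.2, ("PC", "PV"): 0.2,
                    ("PV", "PC"): 0.2, ("PV", "PV"): 0.5}
            cond = {("PC", "PC"): 0.3, ("PC", "PV"): 0.04,
                    ("PV", "PC"): 0.14, ("PV", "PV"): 0.46}
        else:
            prob = {("PC", "PC"): 0.1, ("PC", "PV"): 0.45,
                    ("PV", "PC"): 0.6, ("PV", "PV"): 0.5}
            cond = {("PC", "PC"): 0.20, ("PC", "PV"): 0.27,
                    ("PV", "PC"): 0.08, ("PV", "PV"): 0.46}
        return cls(
            sizes={"PC": n_exc, "PV": n_inh},
            neuron_params={"PC": DEFAULT_NEURON_PARAMS["PC"],
                           "PV": DEFAULT_NEURON_PARAMS["PV"]},
            conn_prob=prob,
            base_g=cond,
        )


@dataclass
class Network:
    """A realized circuit: populations plus an explicit edge list."""

    config: NetworkConfig
    pop_slices: dict[str, slice]
    source: np.ndarray  # global neuron index
    target: np.ndarray  # global neuron index
    conductance: np.ndarray  # nS
    seed: Optional[int] = None
    _kernel_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_neurons(self) -> int:
        return sum(self.config.sizes.values())

    @property
    def n_edges(self) -> int:
        return self.source.size

    def population_of(self) -> np.ndarray:
        """Integer population label per neuron, in config order."""
        lab = np.empty(self.n_neurons, dtype=np.int64)
        for k, pop in enumerate(self.config.population_names):
            lab[self.pop_slices[pop]] = k
        return lab

    def is_excitatory_neuron(self) -> np.ndarray:
        mask = np.zeros(self.n_neurons, dtype=bool)
        for pop in self.config.excitatory:
            if pop in self.pop_slices:
                mask[self.pop_slices[pop]] = True
        return mask

    def edges_between(self, src_pop: str, tgt_pop: str) -> np.ndarray:
        """Boolean mask over edges for one projection."""
        s, t = self.pop_slices[src_pop], self.pop_slices[tgt_pop]
        return (
            (self.source >= s.start) & (self.source < s.stop)
            & (self.target >= t.start) & (self.target < t.stop)
        )

    def to_dataframe(self) -> pd.DataFrame:
        exc = self.is_excitatory_neuron()
        sign = np.where(exc[self.source], "excitatory", "inhibitory")
        return pd.DataFrame(
            {
                "source_id": self.source,
                "target_id": self.target,
                "conductance_nS": self.conductance,
                "delay_ms": np.full(self.n_edges, self.config.delay_ms),
                "sign": sign,
            }
        )

    def save_edges_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def draw_connections(
    n_src: int,
    n_tgt: int,
    p: float,
    same_population: bool,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Independent Bernoulli(p) draw for every ordered (src, tgt) pair.

    Returns local index arrays.  Self-pairs are excluded when source
    and target are the same population (no autapses).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("connection probability must lie in [0, 1]")
    if p == 0.0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy()
    mask = rng.random((n_src, n_tgt)) < p
    if same_population:
        np.fill_diagonal(mask, False)
    src, tgt = np.nonzero(mask)
    return src.astype(np.int64), tgt.astype(np.int64)


def sample_weights(
    base_g: float,
    n_edges: int,
    rng: np.random.Generator,
    g_cap: float = np.inf,
    mu: float = 0.0,
    sigma: float = 1.0,
) -> np.ndarray:
    """Log-normal weight scaling with a hard conductance cap.

    Each weight is ``base_g`` times a LogNormal(mu, sigma) draw, then
    clipped at ``g_cap`` — the conductance whose PSP peak equals the
    EPSP/IPSP bound for the given target type (see
    :func:`epsvnet.model.conductance_cap`).
    """
    if base_g < 0:
        raise ValueError("base conductance must be non-negative")
    w = base_g * rng.lognormal(mean=mu, sigma=sigma, size=n_edges)
    return np.minimum(w, g_cap)


def _cap_table(config: NetworkConfig) -> dict[str, float]:
    """Conductance cap per (sign, target population), keyed 'e:POP'/'i:POP'."""
    caps: dict[str, float] = {}
    for pop in config.sizes:
        par = config.neuron_params[pop]
        caps[f"e:{pop}"] = conductance_cap(
            config.epsp_cap_mv, par.tau_e, par.E_e, par, config.cap_hold_mv,
            kernel=config.synapse_kernel,
        )
        caps[f"i:{pop}"] = conductance_cap(
            config.ipsp_cap_mv, par.tau_i, par.E_i, par, config.cap_hold_mv,
            kernel=config.synapse_kernel,
        )
    return caps


def build_network(config: NetworkConfig, seed: int) -> Network:
    """Realize a circuit from its configuration, deterministically.

    Connectivity and weight sampling use separate named RNG streams
    spawned from ``seed`` so either layer can be reproduced in
    isolation.
    """
    ss = np.random.SeedSequence(seed)
    conn_ss, weight_ss = ss.spawn(2)
    conn_rng = np.random.Generator(np.random.PCG64(conn_ss))
    weight_rng = np.random.Generator(np.random.PCG64(weight_ss))

    pop_slices: dict[str, slice] = {}
    offset = 0
    for pop, n in config.sizes.items():
        pop_slices[pop] = slice(offset, offset + n)
        offset += n

    caps = _cap_table(config)

    srcs, tgts, gs = [], [], []
    # iterate in a fixed order for determinism
    for src_pop in config.population_names:
        for tgt_pop in config.population_names:
            p = config.conn_prob.get((src_pop, tgt_pop), 0.0)
            if p == 0.0:
                continue
            s_local, t_local = draw_connections(
                config.sizes[src_pop],
                config.sizes[tgt_pop],
                p,
                same_population=(src_pop == tgt_pop),
                rng=conn_rng,
            )
            sign = "e" if src_pop in config.excitatory else "i"
            w = sample_weights(
                config.base_g[(src_pop, tgt_pop)],
                s_local.size,
                weight_rng,
                g_cap=caps[f"{sign}:{tgt_pop}"],
                mu=config.lognormal_mu,
                sigma=config.lognormal_sigma,
            )
            srcs.append(s_local + pop_slices[src_pop].start)
            tgts.append(t_local + pop_slices[tgt_pop].start)
            gs.append(w)

    if srcs:
        source = np.concatenate(srcs)
        target = np.concatenate(tgts)
        conductance = np.concatenate(gs)
    else:
        source = np.empty(0, dtype=np.int64)
        target = np.empty(0, dtype=np.int64)
        conductance = np.empty(0, dtype=float)

    return Network(
        config=config,
        pop_slices=pop_slices,
        source=source,
        target=target,
        conductance=conductance,
        seed=seed,
    )


def config_to_yaml(config: NetworkConfig, path) -> None:
    """Write sizes and the two connectivity matrices as YAML."""
    doc = {
        "sizes": dict(config.sizes),
        "conn_prob": {f"{s}->{t}": p for (s, t), p in config.conn_prob.items()},
        "base_g": {f"{s}->{t}": g for (s, t), g in config.base_g.items()},
        "excitatory": sorted(config.excitatory),
        "delay_ms": config.delay_ms,
        "lognormal_mu": config.lognormal_mu,
        "lognormal_sigma": config.lognormal_sigma,
        "epsp_cap_mv": config.epsp_cap_mv,
        "ipsp_cap_mv": config.ipsp_cap_mv,
        "cap_hold_mv": config.cap_hold_mv,
        "synapse_kernel": config.synapse_kernel,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path, neuron_params: Optional[dict[str, NeuronParams]] = None
                     ) -> NetworkConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)

    def unkey(d):
        out = {}
        for k, v in d.items():
            s, t = k.split("->")
            out[(s, t)] = v
        return out

    params = neuron_params or {
        p: DEFAULT_NEURON_PARAMS[p] for p in doc["sizes"]
    }
    return NetworkConfig(
        sizes=doc["sizes"],
        neuron_params=params,
        conn_prob=unkey(doc["conn_prob"]),
        base_g=unkey(doc["base_g"]),
        excitatory=frozenset(doc["excitatory"]),
        delay_ms=doc["delay_ms"],
        lognormal_mu=doc["lognormal_mu"],
        lognormal_sigma=doc["lognormal_sigma"],
        epsp_cap_mv=doc["epsp_cap_mv"],
        ipsp_cap_mv=doc["ipsp_cap_mv"],
        cap_hold_mv=doc["cap_hold_mv"],
        synapse_kernel=doc.get("synapse_kernel", "alpha"),
    )
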