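"""Propagation of trial-by-trial input statistics to output variability.

Two routes quantify how the across-trial distribution of input
modulations shapes the across-trial variance of the excitatory
population's steady-state rate:

* the fast route maps a sampled input point cloud through the
  trilinearly interpolated transfer-function;

* the reference route simulates the full spiking network for many
  trials, drawing one modulation vector per trial, and takes the
  sample covariance of the steady-state population rates.

Sweeps over input means, pairwise covariances and balance ratios
produce variability maps analogous to heat-map analyses; covariance
settings that are not positive semidefinite are masked, not evaluated.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .drive import (
    MODULATED,
    InputDistribution,
    InputSpec,
    build_covariance,
    covariance_from_balances,
    sample_cloud,
)
from .engine import TrialProtocol, population_rate, run_trial
from .network import Network
from .tf import TFGrid, interpolate_tf

__all__ = [
    "MappedCloud",
    "TrialCovariance",
    "VariabilityMap",
    "map_through_tf",
    "simulate_trial_covariance",
    "sweep_mean_variability",
    "sweep_factor_variability",
    "find_operating_regimes",
    "PV_DOMINATED_MEAN",
]

logger = logging.getLogger(__name__)

#: mean modulation of the default PV-dominated operating point: the
#: unmodulated baseline state of the circuit, which is PV-dominated.
PV_DOMINATED_MEAN = np.zeros(3)

#: abort threshold for the fraction of cloud points that fall outside
#: the transfer-function lattice (distribution too wide for the grid)
MAX_OUT_OF_HULL = 0.05


@dataclass
class MappedCloud:
    """Input cloud mapped through the transfer-function."""

    inputs: np.ndarray  # (n, 3) modulations after clipping
    outputs: np.ndarray  # (n, 3) rates of (PC, PV, SST)
    covariance: np.ndarray  # 3x3 across-trial output covariance
    n_clipped_rate: int
    n_clipped_hull: int

    @property
    def e_variance(self) -> float:
        """Across-trial variance of the excitatory output rate (Hz^2)."""
        return float(self.covariance[0, 0])

    @property
    def e_std(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))


@dataclass
class TrialCovariance:
    """Across-trial covariance of steady-state population rates.

    For the full circuit this is the 3x3 matrix over (E, P, S); for the
    two-population configuration it is 2x2 over (E, I).
    """

    matrix: np.ndarray
    n_trials: int
    populations: tuple[str, ...] = ("PC", "PV", "SST")

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.populations)
        if self.matrix.shape != (k, k):
            raise ValueError(f"covariance matrix must be {k}x{k}")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("covariance matrix must be symmetric")
        if np.any(np.diag(self.matrix) < 0):
            raise ValueError("variances must be non-negative")

    @property
    def e_variance(self) -> float:
        """The primary scalar: variance of the E population (Hz^2)."""
        return float(self.matrix[0, 0])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.populations, columns=self.populations
        )


@dataclass
class VariabilityMap:
    """E-population output variance over a sweep of input factors.

    ``mask`` is True where the cell was rejected (non-PSD covariance
    or unmappable cloud); masked cells carry NaN values.
    """

    axis_names: tuple[str, ...]
    axes: tuple[np.ndarray, ...]
    values: np.ndarray  # Hz^2
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != tuple(len(a) for a in self.axes):
            raise ValueError("values shape must match the sweep axes")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values")
        ok = self.values[~self.mask]
        if ok.size and np.nanmin(ok) < 0:
            raise ValueError("variance values must be non-negative")
        if np.all(self.mask):
            warnings.warn("variability map is fully masked")

    @property
    def std(self) -> np.ndarray:
        """Standard-deviation view of the map (Hz)."""
        return np.sqrt(self.values)

    def to_dataframe(self) -> pd.DataFrame:
        mesh = np.meshgrid(*self.axes, indexing="ij")
        cols = {name: m.ravel() for name, m in zip(self.axis_names, mesh)}
        cols["e_variance"] = self.values.ravel()
        cols["rejected"] = self.mask.ravel()
        return pd.DataFrame(cols)


def _clip_cloud(cloud: np.ndarray, spec: InputSpec, grid: TFGrid
                ) -> tuple[np.ndarray, int, int]:
    """Clip sampled modulations to realizable rates and the grid hull."""
    base = np.array([spec.baseline[p] for p in MODULATED])
    lo_rate = -base  # final rate must stay non-negative
    clipped = np.maximum(cloud, lo_rate)
    n_rate = int(np.count_nonzero(np.any(cloud < lo_rate, axis=1)))

    lo = np.array([ax[0] for ax in grid.axes])
    hi = np.array([ax[-1] for ax in grid.axes])
    out = np.any((clipped < lo) | (clipped > hi), axis=1)
    n_hull = int(np.count_nonzero(out))
    if n_hull > MAX_OUT_OF_HULL * len(cloud):
        raise ValueError(
            f"{n_hull}/{len(cloud)} cloud points outside the "
            "transfer-function lattice: distribution too wide for grid"
        )
    clipped = np.clip(clipped, lo, hi)
    if n_rate or n_hull:
        logger.info(
            "clipped %d points at the rate floor and %d at the grid hull",
            n_rate, n_hull,
        )
    return clipped, n_rate, n_hull


def map_through_tf(
    grid: TFGrid,
    dist: InputDistribution,
    n: int = 10000,
    seed: int = 0,
    spec: Optional[InputSpec] = None,
) -> MappedCloud:
    """Sample an input cloud and map it through the transfer-function.

    Draws ``n`` trial-wise modulation vectors, clips them to the
    realizable-rate floor and to the lattice hull (aborting when more
    than 5% fall outside the hull), interpolates the output rates of
    the modulated populations point by point, and returns the sample
    covariance of the outputs.
    """
    spec = spec or InputSpec()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    cloud = sample_cloud(dist, n, rng)
    cloud, n_rate, n_hull = _clip_cloud(cloud, spec, grid)
    outputs = interpolate_tf(grid, cloud, populations=MODULATED)
    finite = np.all(np.isfinite(outputs), axis=1)
    if np.count_nonzero(~finite) > MAX_OUT_OF_HULL * n:
        raise ValueError(
            "more than 5% of cloud points map onto invalid lattice nodes"
        )
    outputs = outputs[finite]
    cov = np.cov(outputs, rowvar=False) if len(outputs) > 1 else np.zeros((3, 3))
    return MappedCloud(
        inputs=cloud, outputs=outputs, covariance=np.atleast_2d(cov),
        n_clipped_rate=n_rate, n_clipped_hull=n_hull,
    )


def simulate_trial_covariance(
    net: Network,
    spec: InputSpec,
    dist: InputDistribution,
    n_trials: int = 100,
    protocol: Optional[TrialProtocol] = None,
    seed: int = 0,
    dt: float = 0.1,
    mean_offset: Optional[Sequence[float]] = None,
) -> TrialCovariance:
    """Across-trial output covariance from full network simulation.

    One modulation vector is drawn per trial from ``dist`` (clipped at
    the realizable-rate floor when a draw would push a final rate
    negative); every trial runs the full protocol with the stimulus
    switched on at onset, and the steady-state rates of (E, P, S) over
    the measurement window enter the sample covariance.
    ``mean_offset`` shifts the whole cloud (operating-point mean) on
    top of ``dist.mu``.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials for a covariance")
    protocol = protocol or TrialProtocol()
    ss = np.random.SeedSequence(seed)
    cloud_ss, trial_ss = ss.spawn(2)
    rng = np.random.Generator(np.random.PCG64(cloud_ss))
    cloud = sample_cloud(dist, n_trials, rng)
    if mean_offset is not None:
        cloud = cloud + np.asarray(mean_offset, dtype=float)

    base = np.array([spec.baseline[p] for p in MODULATED])
    floor_hits = np.any(cloud < -base, axis=1)
    if np.any(floor_hits):
        logger.info("clipping %d trials at the rate floor",
                    int(floor_hits.sum()))
        cloud = np.maximum(cloud, -base)

    pops = tuple(p for p in MODULATED if p in net.pop_slices)
    trial_seeds = trial_ss.generate_state(n_trials)
    t0, t1 = protocol.measure_window
    rates = np.empty((n_trials, len(pops)))
    for k in range(n_trials):
        rec = run_trial(
            net, spec, protocol, delta=cloud[k], dt=dt,
            seed=int(trial_seeds[k] % (2**31)),
        )
        for j, pop in enumerate(pops):
            rates[k, j] = population_rate(rec, pop, t0, t1)
    return TrialCovariance(
        matrix=np.cov(rates, rowvar=False), n_trials=n_trials, populations=pops
    )


def sweep_mean_variability(
    grid: TFGrid,
    mean_axes: Sequence[np.ndarray],
    sigma: Optional[np.ndarray] = None,
    n: int = 10000,
    seed: int = 0,
    spec: Optional[InputSpec] = None,
) -> VariabilityMap:
    """E-output variance as a function of the across-trial input means.

    ``mean_axes`` are three arrays of mean modulations (an axis may be
    a single value to fix that dimension).  The cloud shape defaults
    to the uncorrelated standard tri-variate normal (identity
    covariance).  Cells whose cloud cannot be mapped (out of hull)
    are masked.
    """
    sigma = np.eye(3) if sigma is None else np.asarray(sigma, dtype=float)
    axes = tuple(np.atleast_1d(np.asarray(a, dtype=float)) for a in mean_axes)
    shape = tuple(len(a) for a in axes)
    values = np.full(shape, np.nan)
    mask = np.ones(shape, dtype=bool)
    for idx in np.ndindex(shape):
        mu = np.array([axes[d][idx[d]] for d in range(3)])
        try:
            mapped = map_through_tf(
                grid, InputDistribution(mu=mu, sigma=sigma),
                n=n, seed=seed, spec=spec,
            )
        except ValueError:
            continue
        values[idx] = mapped.e_variance
        mask[idx] = False
    return VariabilityMap(
        axis_names=("mean_dλE", "mean_dλP", "mean_dλS"),
        axes=axes, values=values, mask=mask,
        meta={"sigma": sigma.tolist(), "n": n, "seed": seed},
    )


def sweep_factor_variability(
    grid: TFGrid,
    mu: Sequence[float],
    ep_axis: np.ndarray,
    es_axis: np.ndarray,
    factor: str = "covariance",
    variances: Sequence[float] = (1.8, 0.6, 0.6),
    ps_covariance: float = 0.0,
    total_variance: float = 3.0,
    cov_magnitude: float = 0.5,
    n: int = 10000,
    seed: int = 0,
    spec: Optional[InputSpec] = None,
) -> VariabilityMap:
    """E-output variance over a 2-D sweep of covariance or balance.

    With ``factor='covariance'`` the axes are the pairwise covariances
    sigma_EP and sigma_ES (Hz^2) at fixed variances (default
    diag(1.8, 0.6, 0.6)).  With ``factor='balance'`` the axes are the
    signed balance ratios sigma_E/P and sigma_E/S at fixed covariance
    magnitude and fixed total variance.  Cells whose covariance matrix
    is not positive semidefinite are masked (the white-cell
    convention), as are cells whose cloud leaves the lattice.
    """
    mu = np.asarray(mu, dtype=float)
    ep_axis = np.asarray(ep_axis, dtype=float)
    es_axis = np.asarray(es_axis, dtype=float)
    shape = (len(ep_axis), len(es_axis))
    values = np.full(shape, np.nan)
    mask = np.ones(shape, dtype=bool)

    for i, ep in enumerate(ep_axis):
        for j, es in enumerate(es_axis):
            if factor == "covariance":
                sigma = build_covariance(variances, (ep, es, ps_covariance))
            elif factor == "balance":
                sigma = covariance_from_balances(
                    total_variance, ep, es, cov_magnitude
                )
            else:
                raise ValueError("factor must be 'covariance' or 'balance'")
            if sigma is None:
                continue  # non-PSD: masked cell
            try:
                mapped = map_through_tf(
                    grid, InputDistribution(mu=mu, sigma=sigma),
                    n=n, seed=seed, spec=spec,
                )
            except ValueError:
                continue
            values[i, j] = mapped.e_variance
            mask[i, j] = False

    names = (
        ("σ_EP", "σ_ES") if factor == "covariance" else ("σ_E/P", "σ_E/S")
    )
    return VariabilityMap(
        axis_names=names, axes=(ep_axis, es_axis),
        values=values, mask=mask,
        meta={"mu": mu.tolist(), "factor": factor, "n": n, "seed": seed},
    )


def find_operating_regimes(
    grid: TFGrid, min_e_rate: float = 1.0, rate_match: float = 0.2
) -> dict[str, np.ndarray]:
    """Locate PV-dominated, SST-dominated and mixed operating points.

    Scans the lattice for mean-input nodes where the PV rate is high
    and SST low (PV-dominated), the reverse (SST-dominated), and both
    are intermediate (mixed), restricted to nodes whose E rate matches
    a common reference within ``rate_match`` (fractional).  Returns a
    mapping regime name -> mean modulation vector.
    """
    e = grid.rates[..., grid.pop_index("PC")]
    p = grid.rates[..., grid.pop_index("PV")]
    s = grid.rates[..., grid.pop_index("SST")]
    valid = np.isfinite(e) & np.isfinite(p) & np.isfinite(s) & (e >= min_e_rate)
    if not np.any(valid):
        raise ValueError("no valid lattice nodes above the minimum E rate")
    p_hat = p / max(p[valid].max(), 1e-12)
    s_hat = s / max(s[valid].max(), 1e-12)

    ref = np.median(e[valid])
    matched = valid & (np.abs(e - ref) <= rate_match * ref)
    if not np.any(matched):
        matched = valid

    def node_mu(idx_flat: int) -> np.ndarray:
        ie, ip, is_ = np.unravel_index(idx_flat, e.shape)
        return np.array(
            [grid.axis_e[ie], grid.axis_p[ip], grid.axis_s[is_]]
        )

    score_pv = np.where(matched, p_hat - s_hat, -np.inf)
    score_sst = np.where(matched, s_hat - p_hat, -np.inf)
    score_mix = np.where(matched, np.minimum(p_hat, s_hat), -np.inf)
    return {
        "pv_dominated": node_mu(int(np.argmax(score_pv))),
        "sst_dominated": node_mu(int(np.argmax(score_sst))),
        "mixed": node_mu(int(np.argmax(score_mix))),
    }


def save_manifest(
    path,
    dist: InputDistribution,
    protocol: TrialProtocol,
    seeds: dict[str, int],
    grid: Optional[TFGrid] = None,
) -> None:
    """JSON manifest recording the inputs behind a result."""
    doc = {
        "mu": dist.mu.tolist(),
        "sigma": dist.sigma.tolist(),
        "protocol": {
            "total": protocol.total,
            "preparation": protocol.preparation,
            "settle": protocol.settle,
            "measure": protocol.measure,
        },
        "seeds": {k: int(v) for k, v in seeds.items()},
    }
    if grid is not None:
        doc["grid_hash"] = hex(
            abs(hash(grid.rates[np.isfinite(grid.rates)].tobytes()))
        )
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
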