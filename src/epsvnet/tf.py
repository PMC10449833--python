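"""Multi-dimensional neuron transfer-function.

The transfer-function maps the stimulus-evoked modulation of the
external input rates to the three modulated populations,
(dL_E, dL_P, dL_S), to the steady-state output rates of all four
populations (VIP modulation is held at zero).  It is measured on a
3-D lattice of modulations by running the trial protocol at every
node, then interpolated trilinearly for dense queries; iso-firing-rate
surfaces are extracted from the interpolant by rejection sampling on a
refined lattice.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .drive import InputSpec, NegativeRateError, evoked_rates
from .engine import TrialProtocol, population_rate, run_trial
from .network import Network

__all__ = ["TFGrid", "sweep_tf", "interpolate_tf", "iso_rate_set", "OutOfHullError"]


class OutOfHullError(ValueError):
    """Query point outside the measured lattice; no extrapolation."""


@dataclass
class TFGrid:
    """Steady-state output rates on a lattice of input modulations.

    ``rates`` has shape ``(len(axis_e), len(axis_p), len(axis_s),
    n_pops)``; nodes whose final input rate would be negative are
    invalid and carried as NaN, never silently zeroed.
    """

    axis_e: np.ndarray  # Hz, strictly increasing
    axis_p: np.ndarray
    axis_s: np.ndarray
    rates: np.ndarray  # Hz
    populations: tuple[str, ...]
    meta: dict = field(default_factory=dict)
    _interp: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for ax in (self.axis_e, self.axis_p, self.axis_s):
            if np.any(np.diff(ax) <= 0):
                raise ValueError("axes must be strictly increasing")
        expected = (
            len(self.axis_e), len(self.axis_p), len(self.axis_s),
            len(self.populations),
        )
        if self.rates.shape != expected:
            raise ValueError(f"rates must have shape {expected}")
        valid = self.rates[np.isfinite(self.rates)]
        if valid.size and valid.min() < 0:
            raise ValueError("output rates must be non-negative")

    @property
    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.axis_e, self.axis_p, self.axis_s)

    def pop_index(self, population: str) -> int:
        return self.populations.index(population)

    def interpolator(self, population: str) -> RegularGridInterpolator:
        if population not in self._interp:
            self._interp[population] = RegularGridInterpolator(
                self.axes,
                self.rates[..., self.pop_index(population)],
                method="linear",
                bounds_error=True,
            )
        return self._interp[population]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format export: one row per node, one rate column per population."""
        e, p, s = np.meshgrid(self.axis_e, self.axis_p, self.axis_s, indexing="ij")
        cols = {"dλE": e.ravel(), "dλP": p.ravel(), "dλS": s.ravel()}
        for k, pop in enumerate(self.populations):
            cols[f"rate_{pop}"] = self.rates[..., k].ravel()
        return pd.DataFrame(cols)

    def save_h5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("axis_e", data=self.axis_e)
            fh.create_dataset("axis_p", data=self.axis_p)
            fh.create_dataset("axis_s", data=self.axis_s)
            fh.create_dataset("rates", data=self.rates)
            fh.attrs["populations"] = list(self.populations)
            for k, v in self.meta.items():
                if isinstance(v, (int, float, str)):
                    fh.attrs[k] = v

    @classmethod
    def load_h5(cls, path) -> "TFGrid":
        with h5py.File(path, "r") as fh:
            return cls(
                axis_e=fh["axis_e"][:],
                axis_p=fh["axis_p"][:],
                axis_s=fh["axis_s"][:],
                rates=fh["rates"][:],
                populations=tuple(fh.attrs["populations"]),
                meta={
                    k: fh.attrs[k] for k in fh.attrs if k != "populations"
                },
            )

    @classmethod
    def from_function(
        cls,
        axes: Sequence[np.ndarray],
        funcs: dict[str, callable],
    ) -> "TFGrid":
        """Analytic grid for testing and synthetic analyses.

        ``funcs`` maps population name -> f(dE, dP, dS) evaluated on
        the mesh.
        """
        ax = [np.asarray(a, dtype=float) for a in axes]
        e, p, s = np.meshgrid(*ax, indexing="ij")
        pops = tuple(funcs)
        rates = np.stack([np.asarray(funcs[k](e, p, s), dtype=float)
                          for k in pops], axis=-1)
        return cls(ax[0], ax[1], ax[2], rates, pops)


#: default lattice: 7 nodes per axis spanning +/- 8 Hz of modulation
DEFAULT_AXIS = np.linspace(-8.0, 8.0, 7)
#: coarser preset for quick runs
FAST_AXIS = np.linspace(-8.0, 8.0, 5)


def sweep_tf(
    net: Network,
    spec: InputSpec,
    axes: Optional[Sequence[np.ndarray]] = None,
    protocol: Optional[TrialProtocol] = None,
    repetitions: int = 3,
    seed: int = 0,
    dt: float = 0.1,
) -> TFGrid:
    """Measure the transfer-function on a lattice of input modulations.

    Each node runs the trial protocol ``repetitions`` times with
    independent seeds; node values are the average steady-state rate
    over the measurement window.  Nodes with negative final input
    rates are invalid (NaN).
    """
    if axes is None:
        axes = (DEFAULT_AXIS, DEFAULT_AXIS, DEFAULT_AXIS)
    axes = [np.asarray(a, dtype=float) for a in axes]
    protocol = protocol or TrialProtocol()
    pops = net.config.population_names
    shape = (len(axes[0]), len(axes[1]), len(axes[2]), len(pops))
    rates = np.full(shape, np.nan)

    ss = np.random.SeedSequence(seed)
    t0, t1 = protocol.measure_window
    for (ie, de), (ip, dp), (is_, ds) in itertools.product(
        enumerate(axes[0]), enumerate(axes[1]), enumerate(axes[2])
    ):
        delta = np.array([de, dp, ds])
        try:
            evoked_rates(spec, delta)
        except NegativeRateError:
            continue  # invalid node stays NaN
        node_rates = np.zeros(len(pops))
        child = ss.spawn(1)[0]
        trial_seeds = child.generate_state(repetitions)
        for r in range(repetitions):
            rec = run_trial(
                net, spec, protocol, delta=delta, dt=dt,
                seed=int(trial_seeds[r] % (2**31)),
            )
            for k, pop in enumerate(pops):
                node_rates[k] += population_rate(rec, pop, t0, t1)
        rates[ie, ip, is_] = node_rates / repetitions

    return TFGrid(
        axis_e=axes[0], axis_p=axes[1], axis_s=axes[2],
        rates=rates, populations=tuple(pops),
        meta={"repetitions": repetitions, "seed": seed, "dt": dt},
    )


def interpolate_tf(
    grid: TFGrid,
    query: Sequence[float] | np.ndarray,
    populations: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Trilinear interpolation of the measured transfer-function.

    ``query`` is a 3-vector or an (n, 3) array of (dL_E, dL_P, dL_S).
    Returns rates per requested population (default: all), shape
    ``(n_pops,)`` or ``(n, n_pops)``.  Queries outside the lattice
    hull raise :class:`OutOfHullError`; there is no extrapolation.
    """
    q = np.atleast_2d(np.asarray(query, dtype=float))
    if q.shape[1] != 3:
        raise ValueError("query must have 3 columns (dλE, dλP, dλS)")
    pops = tuple(populations) if populations is not None else grid.populations
    out = np.empty((q.shape[0], len(pops)))
    for k, pop in enumerate(pops):
        try:
            out[:, k] = grid.interpolator(pop)(q)
        except ValueError as err:
            raise OutOfHullError(str(err)) from err
    return out[0] if np.asarray(query).ndim == 1 else out


def iso_rate_set(
    grid: TFGrid,
    population: str,
    level: float,
    tol: float = 0.25,
    refine: int = 5,
    fixed_axis: Optional[int] = None,
    fixed_value: float = 0.0,
) -> np.ndarray:
    """Points of the input space on an iso-firing-rate surface.

    Densely samples a ``refine``-fold refinement of the lattice and
    keeps points whose interpolated rate of ``population`` lies within
    ``tol`` Hz of ``level``.  With ``fixed_axis`` (0, 1 or 2) the
    search is restricted to a 2-D slice, yielding iso-rate contours.
    Returns an (m, 3) array; empty (with a warning) when the level is
    outside the observed range.
    """
    vol = grid.rates[..., grid.pop_index(population)]
    finite = vol[np.isfinite(vol)]
    if finite.size == 0 or not (finite.min() <= level <= finite.max()):
        warnings.warn(
            f"iso level {level} Hz outside the observed range of {population}"
        )
        return np.empty((0, 3))

    dense_axes = []
    for i, ax in enumerate(grid.axes):
        if fixed_axis is not None and i == fixed_axis:
            dense_axes.append(np.asarray([fixed_value]))
        else:
            dense_axes.append(
                np.linspace(ax[0], ax[-1], refine * (len(ax) - 1) + 1)
            )
    e, p, s = np.meshgrid(*dense_axes, indexing="ij")
    pts = np.column_stack([e.ravel(), p.ravel(), s.ravel()])
    vals = grid.interpolator(population)(pts)
    keep = np.isfinite(vals) & (np.abs(vals - level) <= tol)
    return pts[keep]
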