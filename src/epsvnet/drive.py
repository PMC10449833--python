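"""Synthetic input generation.

Two layers of input statistics drive the circuit:

* within a trial, every neuron receives uncorrelated homogeneous
  Poisson spike trains from a fixed number of external sources through
  strong, brief excitatory synapses (baseline drive), optionally
  shifted by a stimulus-evoked rate modulation per population;

* across trials, the evoked modulation vector (dL_E, dL_P, dL_S) is a
  draw from a 3-D normal distribution with configurable mean and
  covariance.  The modulation to VIP cells is fixed at zero, which
  reduces the input space to three dimensions.

The across-trial covariance is factorised into variances (whose signed
ratios are the "trial-by-trial balance" of a pair) and pairwise
covariances, under an optional fixed-total-variance constraint.
Candidate matrices that are not positive semidefinite are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "InputSpec",
    "InputDistribution",
    "DEFAULT_BASELINE_RATES",
    "poisson_trains",
    "evoked_rates",
    "build_covariance",
    "covariance_from_balances",
    "is_positive_semidefinite",
    "sample_cloud",
    "NegativeRateError",
]

#: baseline external rates (Hz) per population, tuned so that the full
#: circuit fires at in-vivo-like spontaneous rates (~2.5 Hz for PC and
#: SST, ~14 Hz for PV and VIP).
DEFAULT_BASELINE_RATES = {"PC": 16.0, "PV": 90.0, "SST": 9.3, "VIP": 12.0}

#: relative tolerance on the most negative eigenvalue when testing
#: positive semidefiniteness (floating-point symmetry noise).
PSD_RTOL = 1e-10

# order of the modulated populations in mean vectors / covariance
# matrices (VIP is driven at baseline only)
MODULATED = ("PC", "PV", "SST")


class NegativeRateError(ValueError):
    """A final input rate (baseline + modulation) would be negative."""


@dataclass
class InputSpec:
    """External drive: baseline Poisson rates and synapse parameters."""

    baseline: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_RATES)
    )
    n_sources: int = 20
    weight_ns: float = 50.0

    def __post_init__(self) -> None:
        for pop, r in self.baseline.items():
            if r < 0:
                raise ValueError(f"baseline rate for {pop} must be non-negative")
        if self.n_sources <= 0:
            raise ValueError("n_sources must be positive")
        if self.weight_ns < 0:
            raise ValueError("external weight must be non-negative")


def poisson_trains(
    rate: float,
    n_sources: int,
    duration: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Independent homogeneous Poisson spike trains.

    Returns ``n_sources`` sorted spike-time arrays (ms) on
    ``[0, duration)``, each an independent process at ``rate`` Hz.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    trains = []
    lam = rate * duration / 1000.0
    for _ in range(n_sources):
        n = rng.poisson(lam)
        trains.append(np.sort(rng.uniform(0.0, duration, size=n)))
    return trains


def evoked_rates(
    spec: InputSpec, delta: Sequence[float] | dict[str, float]
) -> dict[str, float]:
    """Final per-population input rates, baseline plus modulation.

    ``delta`` is either a mapping or a 3-vector ordered (PC, PV, SST);
    the VIP modulation is forced to zero.  Raises
    :class:`NegativeRateError` if any final rate would be negative —
    modulations may be negative only as long as the final rate is not.
    """
    if isinstance(delta, dict):
        d = {pop: float(delta.get(pop, 0.0)) for pop in spec.baseline}
    else:
        vec = np.asarray(delta, dtype=float)
        if vec.shape != (len(MODULATED),):
            raise ValueError(f"delta must have shape ({len(MODULATED)},)")
        d = {pop: 0.0 for pop in spec.baseline}
        for pop, v in zip(MODULATED, vec):
            d[pop] = float(v)
    d["VIP"] = 0.0 if "VIP" in d else d.get("VIP", 0.0)

    rates = {}
    for pop, base in spec.baseline.items():
        r = base + d.get(pop, 0.0)
        if r < 0:
            raise NegativeRateError(
                f"final input rate for {pop} is {r:.3f} Hz (< 0)"
            )
        rates[pop] = r
    return rates


def is_positive_semidefinite(sigma: np.ndarray) -> bool:
    """PSD test with a small relative eigenvalue tolerance."""
    sigma = np.asarray(sigma, dtype=float)
    ev = np.linalg.eigvalsh(sigma)
    scale = max(ev.max(), 0.0)
    return bool(ev.min() >= -PSD_RTOL * max(scale, 1.0))


@dataclass
class InputDistribution:
    """Across-trial 3-D normal distribution of input modulations.

    ``mu`` and ``sigma`` are ordered (PC, PV, SST); entries of
    ``sigma`` are the across-trial variances (Hz^2, diagonal) and
    covariances (off-diagonal).
    """

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != (3,) or self.sigma.shape != (3, 3):
            raise ValueError("mu must be length 3 and sigma 3x3")
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("covariance matrix must be symmetric")
        if np.any(np.diag(self.sigma) < 0):
            raise ValueError("variances must be non-negative")
        if not is_positive_semidefinite(self.sigma):
            raise ValueError("covariance matrix is not positive semidefinite")

    def balance(self, x: str, y: str) -> float:
        """Signed variance ratio sigma_xx / sigma_yy of a pair.

        The sign is positive when the two inputs are correlated across
        trials and negative when anti-correlated (sign of the pair's
        covariance); a zero covariance leaves the ratio positive.
        """
        i, j = MODULATED.index(x), MODULATED.index(y)
        if self.sigma[j, j] == 0:
            raise ZeroDivisionError(f"variance of {y} is zero")
        ratio = self.sigma[i, i] / self.sigma[j, j]
        return -ratio if self.sigma[i, j] < 0 else ratio

    @property
    def balances(self) -> dict[str, float]:
        return {
            "E/P": self.balance("PC", "PV"),
            "E/S": self.balance("PC", "SST"),
            "P/S": self.balance("PV", "SST"),
        }

    @property
    def total_variance(self) -> float:
        return float(np.trace(self.sigma))

    def to_yaml(self, path) -> None:
        doc = {"mu": self.mu.tolist(), "sigma": self.sigma.tolist()}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "InputDistribution":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(mu=np.array(doc["mu"]), sigma=np.array(doc["sigma"]))


def build_covariance(
    variances: Sequence[float],
    covariances: Sequence[float] = (0.0, 0.0, 0.0),
) -> Optional[np.ndarray]:
    """Assemble a 3x3 across-trial covariance matrix, or reject it.

    ``variances`` = (sigma_EE, sigma_PP, sigma_SS) in Hz^2;
    ``covariances`` = (sigma_EP, sigma_ES, sigma_PS) in Hz^2, possibly
    negative (anti-correlated pairs).  Returns the symmetric matrix if
    it is positive semidefinite, ``None`` otherwise (the rejection
    marker rendered as masked cells in sweep maps).
    """
    v = np.asarray(variances, dtype=float)
    c = np.asarray(covariances, dtype=float)
    if v.shape != (3,) or c.shape != (3,):
        raise ValueError("expected 3 variances and 3 covariances")
    if np.any(v < 0):
        raise ValueError("variances must be non-negative")
    sigma = np.array(
        [
            [v[0], c[0], c[1]],
            [c[0], v[1], c[2]],
            [c[1], c[2], v[2]],
        ]
    )
    if not is_positive_semidefinite(sigma):
        return None
    return sigma


def covariance_from_balances(
    total_variance: float,
    balance_ep: float,
    balance_es: float,
    cov_magnitude: float | Sequence[float] = 0.5,
) -> Optional[np.ndarray]:
    """Covariance matrix from the balance factorisation.

    Splits a fixed total variance sigma_EE + sigma_PP + sigma_SS over
    the three populations according to the two signed balance ratios
    |sigma_E/P| = sigma_EE/sigma_PP and |sigma_E/S| = sigma_EE/sigma_SS
    (the P/S ratio is then implied).  Covariance magnitudes are fixed;
    their signs follow the balance signs, with the P-S sign given by
    the product of the other two.  Returns ``None`` when the assembled
    matrix is not positive semidefinite.
    """
    if total_variance <= 0:
        raise ValueError("total variance must be positive")
    if balance_ep == 0 or balance_es == 0:
        raise ValueError("balance ratios must be nonzero")
    r_ep, r_es = abs(balance_ep), abs(balance_es)
    v_e = total_variance / (1.0 + 1.0 / r_ep + 1.0 / r_es)
    v_p = v_e / r_ep
    v_s = v_e / r_es

    mags = np.broadcast_to(np.asarray(cov_magnitude, dtype=float), (3,))
    s_ep = np.sign(balance_ep)
    s_es = np.sign(balance_es)
    s_ps = s_ep * s_es
    cov = (s_ep * mags[0], s_es * mags[1], s_ps * mags[2])
    return build_covariance((v_e, v_p, v_s), cov)


def sample_cloud(
    dist: InputDistribution,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` trial-wise modulation vectors from the 3-D normal.

    Returns an (n, 3) array ordered (dL_E, dL_P, dL_S).  The default
    cloud size for transfer-function mapping is 10000 points; the
    simulated-trial protocol uses one draw per trial.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    return rng.multivariate_normal(dist.mu, dist.sigma, size=n, method="svd")


def cloud_to_csv(cloud: np.ndarray, path) -> None:
    df = pd.DataFrame(cloud, columns=["dλE", "dλP", "dλS"])
    df.insert(0, "trial", np.arange(len(df)))
    df.to_csv(path, index=False)
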