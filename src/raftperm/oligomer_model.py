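"""Oligomer-threshold model of membrane permeabilization.

Chain of three closures that turns non-cooperative monomer binding into a
cooperative killing curve:

1. Langmuir binding: bound density ``b(c) = S * c / (c + Kd)`` — a Hill curve
   with coefficient exactly 1, regardless of what happens downstream.
2. Mass-action oligomerization in the weak-association limit: the density of
   membrane m-mers is ``rho_m = k_olig * b**m``.
3. Per-cell kill threshold: a cell is permeabilized once ``rho_m`` exceeds its
   threshold ``theta``, log-normally distributed across the population with
   median ``theta_mean`` and log-scale spread ``theta_sigma``.  The kill
   fraction is then the closed form

       P(c) = Phi((ln rho_m(c) - ln theta_mean) / theta_sigma)

   degenerating to a sharp step at ``rho_m = theta_mean`` as
   ``theta_sigma -> 0``.

Because ``rho_m`` is a steep power of the occupancy, the killing curve is much
steeper than the binding curve: fitting it with a Hill equation yields an
apparent coefficient well above 1 even though each binding event is
independent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
from scipy import stats as _st

from raftperm import dose_response

__all__ = [
    "OligomerModelParams",
    "bound_density",
    "oligomer_density",
    "permeabilization_probability",
    "sample_kill_fraction",
    "apparent_hill_of_killing",
    "critical_site_density",
    "ic50_of_sites",
    "IC50Result",
    "calibrate_threshold",
    "demo_params",
]

BISECTION_RTOL = 1e-6


@dataclass(frozen=True)
class OligomerModelParams:
    """Parameters of the binding -> oligomerization -> threshold chain.

    Attributes
    ----------
    kd : uM
        Monomer binding dissociation constant.
    site_density : float
        Binding sites per cell membrane, arbitrary units.
    m : int
        Oligomer order (>= 1).
    k_olig : float
        Oligomerization constant scaling the m-mer density.
    theta_mean : float
        Median kill threshold, same units as the m-mer density.
    theta_sigma : float
        Log-scale spread of the per-cell threshold; 0 gives a sharp step.
    """

    kd: float
    site_density: float
    m: int
    k_olig: float
    theta_mean: float
    theta_sigma: float

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.site_density <= 0:
            raise ValueError("site_density must be positive")
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise ValueError("oligomer order m must be an integer >= 1")
        if self.k_olig <= 0:
            raise ValueError("k_olig must be positive")
        if self.theta_mean <= 0:
            raise ValueError("theta_mean must be positive")
        if self.theta_sigma < 0:
            raise ValueError("theta_sigma must be non-negative")


def bound_density(c, params: OligomerModelParams) -> np.ndarray:
    """Langmuir occupancy ``b = S c / (c + Kd)``; saturates at S."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    return params.site_density * c / (c + params.kd)


def oligomer_density(b, params: OligomerModelParams) -> np.ndarray:
    """Weak-association mass-action m-mer density ``rho_m = k_olig * b**m``."""
    b = np.asarray(b, dtype=float)
    return params.k_olig * b ** params.m


def permeabilization_probability(c, params: OligomerModelParams) -> np.ndarray:
    """Kill probability at free concentration(s) ``c``.

    Closed form of the log-normal threshold model; ``theta_sigma = 0`` gives
    a step (with P = 0.5 exactly at the median threshold), and ``rho_m = 0``
    is handled as the P = 0 limit.
    """
    rho = oligomer_density(bound_density(c, params), params)
    rho = np.atleast_1d(rho)
    p = np.zeros_like(rho)
    if params.theta_sigma == 0:
        p[rho > params.theta_mean] = 1.0
        p[rho == params.theta_mean] = 0.5
    else:
        pos = rho > 0
        z = (np.log(rho[pos]) - math.log(params.theta_mean)) / params.theta_sigma
        p[pos] = _st.norm.cdf(z)
    if np.isscalar(c) or np.ndim(c) == 0:
        return float(p[0])
    return p


def sample_kill_fraction(
    c, params: OligomerModelParams, n_cells: int, rng=None
) -> np.ndarray:
    """Monte-Carlo kill fraction from explicitly sampled per-cell thresholds.

    Independent oracle for :func:`permeabilization_probability`: draws
    ``n_cells`` log-normal thresholds and counts cells whose threshold is
    exceeded at each concentration.
    """
    rng = np.random.default_rng(rng)
    rho = np.atleast_1d(oligomer_density(bound_density(c, params), params))
    if params.theta_sigma == 0:
        thetas = np.full(n_cells, params.theta_mean)
    else:
        thetas = rng.lognormal(math.log(params.theta_mean),
                               params.theta_sigma, size=n_cells)
    frac = (rho[:, None] >= thetas[None, :]).mean(axis=1)
    if np.isscalar(c) or np.ndim(c) == 0:
        return float(frac[0])
    return frac


def apparent_hill_of_killing(params: OligomerModelParams, c_grid):
    """Hill coefficient obtained when the killing curve is naively Hill-fitted.

    Evaluates P(c) on the grid (which must span the transition from < 0.05 to
    > 0.95) and fits a Hill equation constrained to plateaus 0 and 1.
    """
    c_grid = np.asarray(c_grid, dtype=float)
    p = permeabilization_probability(c_grid, params)
    if p.min() > 0.05 or p.max() < 0.95:
        raise ValueError(
            "concentration grid does not span the killing transition "
            f"(P range [{p.min():.3f}, {p.max():.3f}])"
        )
    fit = dose_response.fit_hill(
        (c_grid, p), direction="increasing",
        constraints={"bottom": 0.0, "top": 1.0},
    )
    return fit


def critical_site_density(params: OligomerModelParams) -> float:
    """Site density below which the median threshold is unreachable.

    At full occupancy ``b = S``, so killing the median cell requires
    ``k_olig * S**m > theta_mean``, i.e. ``S > (theta_mean/k_olig)**(1/m)``.
    """
    return (params.theta_mean / params.k_olig) ** (1.0 / params.m)


@dataclass(frozen=True)
class IC50Result:
    ic50: float  # inf when no_kill
    no_kill: bool
    site_density: float


def ic50_of_sites(
    params: OligomerModelParams, site_density: float | None = None
) -> IC50Result:
    """Concentration at which P = 0.5, as a function of site density.

    Solved by bisection on log concentration to ``1e-6`` relative tolerance.
    If even saturating occupancy cannot reach the median threshold the result
    carries ``no_kill=True`` and an infinite IC50 — the model's picture of a
    resistant cell line.
    """
    if site_density is not None:
        if site_density <= 0:
            raise ValueError("site_density must be positive")
        params = replace(params, site_density=site_density)
    s = params.site_density
    if s <= critical_site_density(params):
        return IC50Result(ic50=math.inf, no_kill=True, site_density=s)

    def above(c):  # P(c) >= 0.5  <=>  rho_m(c) >= theta_mean
        rho = oligomer_density(bound_density(c, params), params)
        return rho >= params.theta_mean

    lo = params.kd * 1e-9
    hi = params.kd
    while not above(hi):
        hi *= 10.0
        if hi > params.kd * 1e15:  # unreachable: guarded by the check above
            return IC50Result(ic50=math.inf, no_kill=True, site_density=s)
    llo, lhi = math.log(lo), math.log(hi)
    while (lhi - llo) > math.log1p(BISECTION_RTOL):
        mid = 0.5 * (llo + lhi)
        if above(math.exp(mid)):
            lhi = mid
        else:
            llo = mid
    return IC50Result(ic50=math.exp(0.5 * (llo + lhi)), no_kill=False,
                      site_density=s)


def calibrate_threshold(
    kd: float,
    m: int,
    target_ic50: float,
    k_olig: float = 1.0,
    site_density: float = 1.0,
) -> float:
    """Median threshold placing the half-kill point at ``target_ic50``.

    Closed-form inversion: P = 0.5 at the concentration where the m-mer
    density equals the median threshold, so
    ``theta_mean = k_olig * b(target_ic50)**m``.
    """
    if target_ic50 <= 0:
        raise ValueError("target_ic50 must be positive")
    b = site_density * target_ic50 / (target_ic50 + kd)
    return k_olig * b ** m


def demo_params() -> OligomerModelParams:
    """Load the shipped demo regime (Kd 5.1 uM, IC50 calibrated to 10.2 uM,
    tetramer) used by the CLI examples and the acceptance checks."""
    cfg = json.loads(
        resources.files("raftperm.data").joinpath("demo_regime.json").read_text()
    )
    theta_mean = calibrate_threshold(
        kd=cfg["kd"], m=cfg["m"], target_ic50=cfg["target_ic50"],
        k_olig=cfg["k_olig"], site_density=cfg["site_density"],
    )
    return OligomerModelParams(
        kd=cfg["kd"], site_density=cfg["site_density"], m=cfg["m"],
        k_olig=cfg["k_olig"], theta_mean=theta_mean,
        theta_sigma=cfg["theta_sigma"],
    )
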