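"""Hill-equation fitting for viability, killing and binding curves.

The four-parameter Hill model

    R(c) = bottom + (top - bottom) * c^n / (c^n + ec50^n)

is fitted by least squares with the location parameters optimized on
logarithmic scales (log10 EC50, log n) and a multi-start over a log-spaced
EC50 grid to avoid local minima.  Decreasing curves (viability) use the
mirrored form ``R(c) = top - (top - bottom) * c^n / (c^n + ec50^n)``.
Responses are fitted in plain response space with equal weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "HillFit",
    "UnidentifiableFitError",
    "hill_curve",
    "fit_hill",
    "compare_binding_killing",
    "ic50_from_viability",
]

#: parameter bounds for the optimizer
N_BOUNDS = (0.1, 10.0)
EC50_SPAN = 100.0  # EC50 searched within [min(c)/EC50_SPAN, max(c)*EC50_SPAN]
N_STARTS = 5  # log-spaced EC50 multi-start grid


class UnidentifiableFitError(ValueError):
    """Raised when the data do not span the dose-response transition."""


@dataclass
class HillFit:
    """Result of a Hill-equation fit.

    ``ec50`` is reported as IC50 for inhibition/killing data and as Kd for
    binding data; the mathematics is identical.
    """

    ec50: float
    hill_n: float
    top: float
    bottom: float
    rss: float
    converged: bool
    direction: str = "increasing"
    stderr: dict = field(default_factory=dict)
    n_obs: int = 0

    def predict(self, c) -> np.ndarray:
        return hill_curve(c, self.ec50, self.hill_n, self.top, self.bottom,
                          direction=self.direction)


def hill_curve(c, ec50, hill_n, top=1.0, bottom=0.0, direction="increasing"):
    """Evaluate the Hill model at concentrations ``c``."""
    c = np.asarray(c, dtype=float)
    frac = c ** hill_n / (c ** hill_n + ec50 ** hill_n)
    if direction == "increasing":
        return bottom + (top - bottom) * frac
    if direction == "decreasing":
        return top - (top - bottom) * frac
    raise ValueError(f"unknown direction {direction!r}")


def _coerce_table(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        c = data["concentration"].to_numpy(dtype=float)
        r = data["response"].to_numpy(dtype=float)
    else:
        c, r = data
        c = np.asarray(c, dtype=float)
        r = np.asarray(r, dtype=float)
    if c.shape != r.shape:
        raise ValueError("concentration and response must have equal length")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if not np.all(np.isfinite(r)):
        raise ValueError("responses must be finite")
    return c, r


def fit_hill(
    data,
    direction: str = "increasing",
    constraints: dict | None = None,
) -> HillFit:
    """Least-squares Hill fit of a dose-response table.

    Parameters
    ----------
    data
        ``pandas.DataFrame`` with ``concentration`` and ``response`` columns
        (replicate rows allowed) or a ``(concentrations, responses)`` pair.
    direction
        ``"increasing"`` (binding, killing) or ``"decreasing"`` (viability).
    constraints
        Optional fixed parameters, e.g. ``{"bottom": 0.0, "top": 1.0}`` for
        fraction-type responses.

    Raises
    ------
    UnidentifiableFitError
        If all responses sit within 5% of a single plateau, so no
        concentration samples the transition and EC50 is unidentifiable.
    """
    constraints = dict(constraints or {})
    c, r = _coerce_table(data)
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct concentrations")

    spread = float(r.max() - r.min())
    scale = max(float(np.abs(r).max()), 1e-12)
    if spread <= 0.05 * scale:
        raise UnidentifiableFitError(
            "responses do not leave a single plateau; EC50 unidentifiable"
        )

    fixed_top = constraints.get("top")
    fixed_bottom = constraints.get("bottom")
    lo_c, hi_c = c.min() / EC50_SPAN, c.max() * EC50_SPAN

    def unpack(theta):
        ec50 = 10.0 ** theta[0]
        n = math.exp(theta[1])
        k = 2
        if fixed_top is None:
            top = theta[k]
            k += 1
        else:
            top = fixed_top
        bottom = fixed_bottom if fixed_bottom is not None else theta[k]
        return ec50, n, top, bottom

    def residuals(theta):
        ec50, n, top, bottom = unpack(theta)
        return hill_curve(c, ec50, n, top, bottom, direction) - r

    lo = [math.log10(lo_c), math.log(N_BOUNDS[0])]
    hi = [math.log10(hi_c), math.log(N_BOUNDS[1])]
    resp_lo = r.min() - 2.0 * max(spread, 1e-9)
    resp_hi = r.max() + 2.0 * max(spread, 1e-9)
    if fixed_top is None:
        lo.append(resp_lo)
        hi.append(resp_hi)
    if fixed_bottom is None:
        lo.append(resp_lo)
        hi.append(resp_hi)

    top0 = fixed_top if fixed_top is not None else float(r.max())
    bottom0 = fixed_bottom if fixed_bottom is not None else float(r.min())
    best = None
    for ec50_start in np.geomspace(c.min(), c.max(), N_STARTS):
        theta0 = [math.log10(ec50_start), 0.0]
        if fixed_top is None:
            theta0.append(top0)
        if fixed_bottom is None:
            theta0.append(bottom0)
        theta0 = np.clip(theta0, lo, hi)
        sol = least_squares(residuals, theta0, bounds=(lo, hi),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol

    ec50, n, top, bottom = unpack(best.x)
    rss = float(2.0 * best.cost)
    free_plateaus = [name for name, fixed in
                     (("top", fixed_top), ("bottom", fixed_bottom))
                     if fixed is None]
    stderr = _parameter_stderr(best, unpack, c.size, free_plateaus)
    if bottom > top:
        # keep the bottom <= top convention; flip labels for free-plateau fits
        top, bottom = bottom, top
    return HillFit(
        ec50=float(ec50), hill_n=float(n), top=float(top), bottom=float(bottom),
        rss=rss, converged=bool(best.success), direction=direction,
        stderr=stderr, n_obs=int(c.size),
    )


def _parameter_stderr(sol, unpack, n_obs, free_plateaus=()) -> dict:
    """Delta-method standard errors on the natural parameter scale."""
    dof = n_obs - sol.x.size
    if dof <= 0:
        return {}
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj) * (2.0 * sol.cost / dof)
    except np.linalg.LinAlgError:
        return {}
    sd_theta = np.sqrt(np.maximum(np.diag(cov), 0.0))
    ec50, n, *_ = unpack(sol.x)
    out = {
        "ec50": float(ec50 * math.log(10) * sd_theta[0]),
        "hill_n": float(n * sd_theta[1]),
    }
    for i, name in enumerate(free_plateaus):
        out[name] = float(sd_theta[i + 2])
    return out


def compare_binding_killing(binding: HillFit, killing: HillFit) -> dict:
    """Contrast a binding fit with a killing fit to expose cooperativity.

    Classification: ``hill_n <= 1.5`` non-cooperative, ``>= 2`` cooperative,
    in between intermediate.
    """
    if not (binding.converged and killing.converged):
        raise ValueError("both fits must have converged")

    def classify(n):
        if n <= 1.5:
            return "non-cooperative"
        if n >= 2.0:
            return "cooperative"
        return "intermediate"

    return {
        "ec50_ratio": killing.ec50 / binding.ec50,
        "hill_n_ratio": killing.hill_n / binding.hill_n,
        "binding_class": classify(binding.hill_n),
        "killing_class": classify(killing.hill_n),
        "binding_hill_n": binding.hill_n,
        "killing_hill_n": killing.hill_n,
    }


def ic50_from_viability(plate: pd.DataFrame) -> tuple[pd.DataFrame, HillFit]:
    """Dual-wavelength viability readout followed by a decreasing Hill fit.

    ``plate`` columns: ``concentration`` (ignored for controls), ``a_450``,
    ``a_620``, ``role`` (``"treated"`` or ``"control"``) and optionally
    ``replicate``.  Per-well signal is ``A450 - A620``; wells with
    non-positive signal are flagged and excluded.  Viability is each treated
    signal divided by the mean control signal.
    """
    required = {"concentration", "a_450", "a_620", "role"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    signal = plate["a_450"].to_numpy(float) - plate["a_620"].to_numpy(float)
    ok = signal > 0
    flagged = plate.loc[~ok]
    plate = plate.loc[ok].assign(signal=signal[ok])

    controls = plate[plate["role"] == "control"]
    if controls.empty:
        raise ValueError("no usable control wells")
    control_mean = float(controls["signal"].mean())
    if control_mean <= 0:
        raise ValueError("non-positive mean control signal")

    treated = plate[plate["role"] == "treated"].copy()
    treated["response"] = treated["signal"] / control_mean
    table = treated.rename(columns={"response": "response"})[
        [col for col in ("concentration", "response", "replicate")
         if col in treated.columns]
    ].reset_index(drop=True)
    table.attrs["excluded_wells"] = int(len(flagged))

    fit = fit_hill(table, direction="decreasing")
    return table, fit
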