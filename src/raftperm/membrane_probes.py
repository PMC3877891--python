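"""Membrane-probe polarization readouts.

Two cuvette-style steady-state quantities:

* l-format fluorescence anisotropy
  ``r = (I_vv - G * I_vh) / (I_vv + 2 * G * I_vh)``, where ``I_vv`` and
  ``I_vh`` are the vertically and horizontally polarized emission components
  under vertically polarized excitation and ``G`` corrects for the relative
  detection sensitivity of the two channels;
* generalized polarization of a solvatochromic probe
  ``GP = (I_blue - I_red) / (I_blue + I_red)`` from blue-edge and red-edge
  emission intensities.

The G-factor is an instrument measurement supplied by the caller; it is not
computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _st

__all__ = [
    "AnisotropyRecord",
    "LaurdanRecord",
    "anisotropy",
    "generalized_polarization",
    "compare_conditions",
]


@dataclass(frozen=True)
class AnisotropyRecord:
    """One anisotropy measurement: polarized components and G-factor."""

    i_vv: float
    i_vh: float
    g_factor: float = 1.0

    def __post_init__(self):
        if self.i_vv < 0 or self.i_vh < 0:
            raise ValueError("intensities must be non-negative")
        if self.g_factor <= 0:
            raise ValueError("g_factor must be positive")


@dataclass(frozen=True)
class LaurdanRecord:
    """One generalized-polarization measurement: blue and red-edge emission."""

    i_blue: float
    i_red: float

    def __post_init__(self):
        if self.i_blue < 0 or self.i_red < 0:
            raise ValueError("intensities must be non-negative")
        if self.i_blue + self.i_red <= 0:
            raise ValueError("total intensity must be positive")


def anisotropy(rec: AnisotropyRecord) -> float:
    """Steady-state anisotropy ``(I_vv - G I_vh) / (I_vv + 2 G I_vh)``.

    The value lies in ``(-0.5, 1]`` for physical inputs; it is invariant to
    joint scaling of the two intensity components.
    """
    denom = rec.i_vv + 2.0 * rec.g_factor * rec.i_vh
    if denom <= 0:
        raise ZeroDivisionError("total intensity I_vv + 2 G I_vh must be positive")
    return (rec.i_vv - rec.g_factor * rec.i_vh) / denom


def generalized_polarization(rec: LaurdanRecord) -> float:
    """Emission-ratio polarization ``(I_blue - I_red) / (I_blue + I_red)``.

    Bounded in ``[-1, 1]`` for non-negative intensities with a positive sum.
    """
    total = rec.i_blue + rec.i_red
    if total <= 0:
        raise ZeroDivisionError("total intensity must be positive")
    return (rec.i_blue - rec.i_red) / total


def _values(records: Iterable) -> np.ndarray:
    vals = []
    for rec in records:
        if isinstance(rec, AnisotropyRecord):
            vals.append(anisotropy(rec))
        elif isinstance(rec, LaurdanRecord):
            vals.append(generalized_polarization(rec))
        else:
            vals.append(float(rec))
    return np.asarray(vals, dtype=float)


def compare_conditions(
    records_by_condition: Mapping[str, Sequence],
) -> dict:
    """Summarize a probe readout per condition and compare pairs of conditions.

    Parameters
    ----------
    records_by_condition
        Mapping from condition label to a sequence of records
        (:class:`AnisotropyRecord`, :class:`LaurdanRecord` or plain floats,
        uniformly per condition).  Each condition needs at least 2 records.

    Returns
    -------
    dict
        ``{"summary": {cond: {"mean", "sem", "n"}}, "comparisons": [...]}``
        where each comparison holds the pair of labels, the difference of
        means and Welch-test statistics (delegated to scipy).
    """
    if len(records_by_condition) < 2:
        raise ValueError("need at least two conditions to compare")
    summary: dict[str, dict] = {}
    values: dict[str, np.ndarray] = {}
    for cond, recs in records_by_condition.items():
        v = _values(recs)
        if v.size < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 records")
        values[cond] = v
        summary[cond] = {
            "mean": float(v.mean()),
            "sem": float(v.std(ddof=1) / np.sqrt(v.size)),
            "n": int(v.size),
        }
    comparisons = []
    labels = list(values)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            diff = summary[b]["mean"] - summary[a]["mean"]
            if np.ptp(values[a]) == 0 and np.ptp(values[b]) == 0:
                # identical-constant conditions: difference is exact
                t, p = (0.0, 1.0) if diff == 0 else (np.inf, 0.0)
            else:
                t, p = _st.ttest_ind(values[b], values[a], equal_var=False)
            comparisons.append(
                {
                    "conditions": (a, b),
                    "difference": float(diff),
                    "t": float(t),
                    "p_value": float(p),
                }
            )
    return {"summary": summary, "comparisons": comparisons}
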