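"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator returns its artifact together with the ground truth used to
build it, so every downstream estimator can be tested without external data.
All generators take a ``seed`` and are bit-reproducible for a fixed seed.

The image-stack generator uses the fast-diffusion occupancy model: the
emitter occupancy of each pixel is redrawn independently every frame
(Poisson with the requested mean), and detected counts are Poisson given the
occupancy.  Under this model the apparent brightness has the closed form

    B = 1 + epsilon * (n * eps) / (n * eps + background)

(law of total variance), reducing to ``B = 1 + epsilon`` without background —
an analytic oracle for the N&B estimator.  Bleaching is a multiplicative
linear decay of expected counts across the stack; drift is an integer pixel
shift of the occupancy field per frame.  Both break the oracle and exist to
exercise the stack-QC rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from raftperm import oligomer_model, uptake_kinetics
from raftperm.dose_response import hill_curve
from raftperm.nb_brightness import ImageStack
from raftperm.uptake_kinetics import UptakeParams, UptakeTrace

__all__ = [
    "NBSimParams",
    "SpotSimParams",
    "gen_nb_stack",
    "gen_spot_image",
    "gen_cell_image",
    "gen_dose_response",
    "gen_uptake_trace",
    "gen_panel",
]


@dataclass(frozen=True)
class NBSimParams:
    """Configuration of the fluctuation-stack generator.

    ``mean_occupancy`` may be a scalar (spatially flat) or an (height, width)
    array; a structured map is required for drift to be observable.
    ``drift_px_per_frame`` is a ``(row, col)`` pair of pixels per frame.
    """

    mean_occupancy: float | np.ndarray = 2.0
    epsilon: float = 0.2
    background_rate: float = 0.0
    n_frames: int = 100
    height: int = 64
    width: int = 64
    bleach_fraction: float = 0.0
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)
    seed: int | None = None

    def __post_init__(self):
        if not isinstance(self.n_frames, (int, np.integer)):
            raise ValueError("n_frames must be an integer")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.height <= 0 or self.width <= 0:
            raise ValueError("zero-area image")
        if np.any(np.asarray(self.mean_occupancy) < 0):
            raise ValueError("mean_occupancy must be non-negative")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")
        if not 0 <= self.bleach_fraction < 1:
            raise ValueError("bleach_fraction must be in [0, 1)")


def gen_nb_stack(params: NBSimParams) -> tuple[ImageStack, dict]:
    """Simulate a photon-counting image stack with known brightness.

    Returns the stack and a ground-truth dict with the true molecular
    brightness ``epsilon``, the expected apparent brightness ``b`` (exact
    only without bleach/drift), and the per-frame cumulative drift shifts.
    """
    rng = np.random.default_rng(params.seed)
    occ_map = np.broadcast_to(
        np.asarray(params.mean_occupancy, dtype=float),
        (params.height, params.width),
    ).copy()

    frames = np.empty((params.n_frames, params.height, params.width), dtype=np.int64)
    shifts = np.zeros((params.n_frames, 2), dtype=int)
    denom = max(params.n_frames - 1, 1)
    for t in range(params.n_frames):
        dy = int(round(t * params.drift_px_per_frame[0]))
        dx = int(round(t * params.drift_px_per_frame[1]))
        shifts[t] = (dy, dx)
        field_t = np.roll(occ_map, (dy, dx), axis=(0, 1))
        occupancy = rng.poisson(field_t)
        scale = 1.0 - params.bleach_fraction * t / denom
        lam = scale * (occupancy * params.epsilon + params.background_rate)
        frames[t] = rng.poisson(lam)

    occ_mean = float(np.mean(occ_map))
    signal = occ_mean * params.epsilon
    total = signal + params.background_rate
    true_b = 1.0 + (params.epsilon * signal / total if total > 0 else 0.0)
    truth = {
        "epsilon": params.epsilon,
        "b": true_b,
        "mean_occupancy": occ_mean,
        "shifts": shifts,
        "seed": params.seed,
    }
    stack = ImageStack(
        frames=frames,
        metadata={"generator": "gen_nb_stack", "seed": params.seed},
    )
    return stack, truth


@dataclass(frozen=True)
class SpotSimParams:
    """Configuration of the punctate-spot image generator.

    ``min_separation`` defaults to ``4 * spot_sigma`` when left ``None``.
    Large blobs are smooth objects much wider than the spots, meant to be
    removed by a top-hat filter.
    """

    n_spots: int = 12
    spot_sigma: float = 1.5
    amplitude_range: tuple[float, float] = (60.0, 100.0)
    background: float = 10.0
    gradient_amplitude: float = 5.0
    n_large_blobs: int = 0
    blob_sigma: float = 15.0
    blob_amplitude: float = 80.0
    min_separation: float | None = None
    height: int = 128
    width: int = 128
    max_retries: int = 2000
    seed: int | None = None

    def __post_init__(self):
        if self.n_spots < 0 or self.n_large_blobs < 0:
            raise ValueError("object counts must be non-negative")
        if self.spot_sigma <= 0:
            raise ValueError("spot_sigma must be positive")

    @property
    def separation(self) -> float:
        return (self.min_separation if self.min_separation is not None
                else 4.0 * self.spot_sigma)


def _place_points(rng, n, shape, margin, min_sep, max_retries, existing=None):
    """Rejection-sample ``n`` points pairwise separated by ``min_sep``."""
    pts: list[np.ndarray] = list(existing or [])
    placed = []
    tries = 0
    while len(placed) < n:
        if tries >= max_retries:
            raise RuntimeError(
                f"could not place {n} points at separation {min_sep} "
                f"within {max_retries} retries"
            )
        tries += 1
        cand = np.array([
            rng.uniform(margin, shape[0] - margin),
            rng.uniform(margin, shape[1] - margin),
        ])
        if all(np.hypot(*(cand - p)) >= min_sep for p in pts):
            pts.append(cand)
            placed.append(cand)
    return np.array(placed).reshape(n, 2)


def gen_spot_image(params: SpotSimParams) -> tuple[np.ndarray, np.ndarray]:
    """Smooth background + Gaussian spots (+ optional large blobs).

    Returns ``(image, centers)`` where ``centers`` is the (n_spots, 2) array
    of true spot centers in ``(row, col)`` order; blob centers are not part
    of the ground truth since a spot counter must ignore them.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    margin = max(3.0 * params.spot_sigma, params.separation / 2.0)
    if params.n_spots > 0 and (h - 2 * margin <= 0 or w - 2 * margin <= 0):
        raise ValueError("spots do not fit inside the frame at this separation")

    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    image = params.background + params.gradient_amplitude * (
        rows / max(h - 1, 1) + cols / max(w - 1, 1)
    ) / 2.0

    centers = _place_points(rng, params.n_spots, (h, w), margin,
                            params.separation, params.max_retries)
    for (r, c) in centers:
        amp = rng.uniform(*params.amplitude_range)
        image += amp * np.exp(
            -((rows - r) ** 2 + (cols - c) ** 2) / (2.0 * params.spot_sigma ** 2)
        )

    if params.n_large_blobs > 0:
        # keep blob peaks a blob-width away from spots: a spot riding the
        # steepest part of a blob can merge with a neighbour in the maxima map
        blob_margin = min(2.0 * params.blob_sigma, min(h, w) / 2.0 - 1)
        blob_sep = params.separation + params.blob_sigma
        blobs = _place_points(
            rng, params.n_large_blobs, (h, w), blob_margin,
            blob_sep, params.max_retries, existing=list(centers),
        )
        for (r, c) in blobs:
            image += params.blob_amplitude * np.exp(
                -((rows - r) ** 2 + (cols - c) ** 2) / (2.0 * params.blob_sigma ** 2)
            )

    return image, centers


def gen_cell_image(
    shape: tuple[int, int] = (128, 128),
    rim_radius: float = 40.0,
    rim_width: float = 5.0,
    rim_intensity: float = 100.0,
    background: float = 20.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, list, dict]:
    """Ring-shaped membrane fluorescence on a diffuse background.

    Returns ``(image, rim_mask, seeds, info)``: the ground-truth rim pixel
    mask, one labeled seed point inside the ring and one outside (labels 1
    and 2), and an info dict flagging degenerate contrast when the rim is no
    brighter than the background.
    """
    if rim_width < 1:
        raise ValueError("rim_width must be at least 1 px")
    h, w = shape
    if rim_radius + rim_width / 2.0 >= min(h, w) / 2.0:
        raise ValueError("rim does not fit inside the frame")
    rng = np.random.default_rng(seed)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    dist = np.hypot(rows - cy, cols - cx)
    rim_mask = np.abs(dist - rim_radius) <= rim_width / 2.0
    image = np.full(shape, background, dtype=float)
    image[rim_mask] = rim_intensity
    if noise_sd > 0:
        image += rng.normal(0.0, noise_sd, size=shape)
    seeds = [(int(round(cy)), int(round(cx)), 1), (1, 1, 2)]
    info = {
        "degenerate_contrast": bool(rim_intensity <= background),
        "seed": seed,
    }
    return image, rim_mask, seeds, info


def gen_dose_response(
    model: str,
    model_params,
    concentrations,
    n_reps: int = 3,
    noise_sd: float = 0.0,
    seed: int | None = None,
    response_kind: str = "fraction",
) -> pd.DataFrame:
    """Dose-response table from a Hill or oligomer-threshold mean curve.

    ``model`` is ``"hill"`` (``model_params`` is a dict with ``ec50``,
    ``hill_n`` and optional ``top``, ``bottom``, ``direction``) or
    ``"oligomer"`` (``model_params`` is an
    :class:`~raftperm.oligomer_model.OligomerModelParams`).  Responses are
    the model mean plus Gaussian replicate noise, truncated to [0, 1] for
    fraction-type responses and to non-negative values otherwise.
    """
    c = np.asarray(concentrations, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if model == "hill":
        p = dict(model_params)
        mean = hill_curve(
            c, p["ec50"], p["hill_n"], p.get("top", 1.0), p.get("bottom", 0.0),
            direction=p.get("direction", "increasing"),
        )
    elif model == "oligomer":
        mean = np.atleast_1d(
            oligomer_model.permeabilization_probability(c, model_params)
        )
    else:
        raise ValueError(f"unknown model {model!r}")

    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        resp = mean + rng.normal(0.0, noise_sd, size=c.size)
        if response_kind == "fraction":
            resp = np.clip(resp, 0.0, 1.0)
        else:
            resp = np.clip(resp, 0.0, None)
        for ci, ri in zip(c, resp):
            rows.append({"concentration": ci, "response": ri, "replicate": rep})
    table = pd.DataFrame(rows)
    table.attrs["kind"] = response_kind
    table.attrs["seed"] = seed
    return table


def gen_uptake_trace(
    params: UptakeParams,
    t_grid,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> UptakeTrace:
    """Two-compartment uptake trace: closed-form solution plus noise."""
    trace = uptake_kinetics.solve_uptake(params, t_grid)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace.intensity = trace.intensity + rng.normal(
            0.0, noise_sd, size=trace.intensity.shape
        )
    trace.metadata["seed"] = seed
    return trace


def gen_panel(
    n_lines: int = 7,
    n_reps: int = 3,
    rho: float = -0.9,
    seed: int | None = None,
    condition: str = "normoxia",
    log_ic50_mean: float = math.log(10.0),
    log_ic50_sd: float = 0.6,
    marker_mean: float = 1000.0,
    marker_sd: float = 250.0,
    replicate_noise: float = 0.03,
) -> pd.DataFrame:
    """Cell-line panel with a target (log IC50, marker) correlation.

    Per-line ``(log IC50, marker level)`` pairs are drawn from a bivariate
    normal with correlation ``rho``; small multiplicative replicate noise is
    added on top.  Balanced: every line has exactly ``n_reps`` rows.
    """
    if n_lines < 3:
        raise ValueError("need at least 3 cell lines")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_lines,
                                method="cholesky")
    log_ic50 = log_ic50_mean + log_ic50_sd * z[:, 0]
    marker = np.clip(marker_mean + marker_sd * z[:, 1], 0.0, None)

    rows = []
    for i in range(n_lines):
        for rep in range(n_reps):
            noise = rng.normal(0.0, replicate_noise, size=2)
            rows.append({
                "cell_line": f"line_{i:02d}",
                "replicate": rep,
                "condition": condition,
                "ic50": float(np.exp(log_ic50[i] + noise[0])),
                "marker_level": float(max(marker[i] * (1.0 + noise[1]), 0.0)),
            })
    table = pd.DataFrame(rows)
    table.attrs["rho"] = rho
    table.attrs["seed"] = seed
    return table
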