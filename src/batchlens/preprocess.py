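"""Raw-intensity preprocessing: background correction, quantile
normalization, within-array MA-loess for two-color arrays, and channel
splitting.

The fixed order of operations is: background correction -> (MA-loess if
two-color) -> log2 -> quantile normalization across samples/channels.
Single-color data skip the loess step and are quantile-normalized only.

The two channels of a two-color array are correlated (shared spot
effects).  Rather than a generalized-least-squares consensus-correlation
fit, channel decoupling here is: loess within array, quantile across all
channels, and an optional array blocking covariate in downstream linear
models (channel provenance is recorded per column for that purpose).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .io_formats import ExpressionMatrix, FormatError

__all__ = [
    "TwoColorArray",
    "background_correct",
    "background_correct_array",
    "quantile_normalize",
    "ma_loess_normalize",
    "split_channels",
]


@dataclass
class TwoColorArray:
    """Linear-scale red/green signals (and backgrounds) of one array."""

    array_id: str
    probe_ids: list
    red_signal: np.ndarray
    green_signal: np.ndarray
    red_background: np.ndarray = None
    green_background: np.ndarray = None

    def __post_init__(self) -> None:
        self.probe_ids = list(map(str, self.probe_ids))
        n = len(self.probe_ids)
        for attr in ("red_signal", "green_signal", "red_background", "green_background"):
            v = getattr(self, attr)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            setattr(self, attr, v)
            if v.shape != (n,):
                raise FormatError(f"{attr} length {v.shape} does not match {n} probes")
            if attr.endswith("signal") and np.any(v < 0):
                raise ValueError(f"negative values in {attr}")


def background_correct(raw_signal, raw_background, method: str = "subtract-floor",
                       offset: float = 1.0) -> np.ndarray:
    """Background-correct linear intensities; output is strictly positive.

    ``subtract-floor``: ``max(signal - background, 0) + offset``.

    ``normexp-moment``: models the observed signal as true signal
    (exponential, mean alpha) plus additive background noise (normal,
    mean mu0, sd sigma) on top of the measured local background; the
    (alpha, mu0, sigma) parameters are estimated by matching the first
    three moments of ``signal - background``, and the corrected value is
    the posterior mean of the true signal, which is always positive.
    """
    s = np.asarray(raw_signal, dtype=float)
    b = np.asarray(raw_background, dtype=float)
    if s.shape != b.shape:
        raise ValueError("signal and background must have equal length")
    if np.any(s < 0) or np.any(b < 0):
        raise ValueError("negative raw intensities")
    x = s - b
    if method == "subtract-floor":
        if offset <= 0:
            raise ValueError("offset must be positive to keep log2 defined")
        return np.maximum(x, 0.0) + offset
    if method == "normexp-moment":
        alpha, mu0, sigma = _normexp_moments(x)
        return _normexp_posterior_mean(x, alpha, mu0, sigma)
    raise ValueError(f"unknown background method {method!r}")


def _normexp_moments(x: np.ndarray):
    """Moment estimates for the exponential-plus-normal convolution.

    mean = mu0 + alpha; var = sigma^2 + alpha^2; third central moment
    = 2 alpha^3 (the normal part is symmetric).
    """
    m1 = float(np.mean(x))
    m2 = float(np.var(x))
    m3 = float(np.mean((x - m1) ** 3))
    alpha = max((m3 / 2.0), 1e-12) ** (1.0 / 3.0)
    sigma2 = max(m2 - alpha**2, 1e-12)
    mu0 = m1 - alpha
    return alpha, mu0, np.sqrt(sigma2)


def _normexp_posterior_mean(x, alpha, mu0, sigma):
    # E[S | X=x] for S ~ Exp(alpha), noise ~ N(mu0, sigma^2), X = S + noise
    mu_sx = x - mu0 - sigma**2 / alpha
    log_ratio = stats.norm.logpdf(0.0, loc=mu_sx, scale=sigma) - stats.norm.logsf(0.0, loc=mu_sx, scale=sigma)
    out = mu_sx + sigma * np.exp(log_ratio)
    return np.maximum(out, 1e-12)


def background_correct_array(array: TwoColorArray, method: str = "subtract-floor",
                             offset: float = 1.0) -> TwoColorArray:
    if array.red_background is None or array.green_background is None:
        raise ValueError("array carries no background estimates")
    return TwoColorArray(
        array.array_id,
        array.probe_ids,
        background_correct(array.red_signal, array.red_background, method, offset),
        background_correct(array.green_signal, array.green_background, method, offset),
    )


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to the common distribution of row-wise means of
    the column order statistics.  Idempotent; conserves the grand mean."""
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    v = matrix.values
    if not np.all(np.isfinite(v)):
        raise ValueError("matrix contains missing or non-finite values")
    target = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    n = v.shape[0]
    for j in range(v.shape[1]):
        # average ranks so tied inputs receive a common output value
        ranks = stats.rankdata(v[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, np.arange(n), target)
    return ExpressionMatrix(matrix.probe_ids, matrix.sample_ids, out, matrix.species)


@dataclass
class MAResult:
    """Loess-normalized two-color array on the (M, A) scale."""

    array_id: str
    probe_ids: list
    M: np.ndarray          # normalized log2 ratio R/G
    A: np.ndarray          # average log2 intensity (unchanged)
    loess_fit: np.ndarray  # removed intensity-dependent dye bias

    @property
    def log_red(self) -> np.ndarray:
        return self.A + self.M / 2.0

    @property
    def log_green(self) -> np.ndarray:
        return self.A - self.M / 2.0


def ma_loess_normalize(array: TwoColorArray, span: float = 0.3,
                       iterations: int = 3) -> MAResult:
    """Remove the intensity-dependent dye bias of one two-color array.

    M = log2(R/G) is regressed on A = (log2 R + log2 G)/2 with robust
    locally-weighted regression; the fitted trend is subtracted from M.
    Signals must already be background-corrected (strictly positive).
    """
    r = np.asarray(array.red_signal, dtype=float)
    g = np.asarray(array.green_signal, dtype=float)
    if r.size < 50:
        raise ValueError("loess normalization needs at least 50 probes")
    if np.any(r <= 0) or np.any(g <= 0):
        raise ValueError("signals must be strictly positive (background-correct first)")
    logr, logg = np.log2(r), np.log2(g)
    m = logr - logg
    a = (logr + logg) / 2.0
    fitted = sm.nonparametric.lowess(
        m, a, frac=span, it=iterations, return_sorted=False,
    )
    return MAResult(array.array_id, array.probe_ids, m - fitted, a, fitted)


def split_channels(arrays, channel_samples, between_array_norm: bool = True,
                   span: float = 0.3, iterations: int = 3, species: str = ""):
    """Split loess-normalized two-color arrays into single-channel columns.

    ``channel_samples`` maps ``(array_id, dye)`` -- dye in {"red",
    "green"} -- to a sample id; every channel of every array must be
    assigned.  Returns the single-channel log2 :class:`ExpressionMatrix`
    (quantile-normalized across all channels when ``between_array_norm``)
    and a channel-provenance table (sample_id, array_id, dye) so
    downstream linear models can include an array blocking term.
    """
    columns, meta = [], []
    probe_ids = None
    for array in arrays:
        if isinstance(array, TwoColorArray):
            ma = ma_loess_normalize(array, span=span, iterations=iterations)
        else:
            ma = array  # already an MAResult
        if probe_ids is None:
            probe_ids = ma.probe_ids
        elif ma.probe_ids != probe_ids:
            raise FormatError(f"array {ma.array_id!r} has a different probe list")
        for dye, values in (("red", ma.log_red), ("green", ma.log_green)):
            key = (ma.array_id, dye)
            if key not in channel_samples:
                raise FormatError(f"missing dye assignment for array {ma.array_id!r} channel {dye!r}")
            meta.append({"sample_id": channel_samples[key], "array_id": ma.array_id, "dye": dye})
            columns.append(values)
    meta = pd.DataFrame(meta)
    matrix = ExpressionMatrix(probe_ids, list(meta["sample_id"]), np.column_stack(columns), species)
    if between_array_norm:
        matrix = quantile_normalize(matrix)
    return matrix, meta
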