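"""Temperature-resolved averaging and melting-temperature extraction.

A :class:`StabilityCurve` is the mean +/- SD of one observable at each
rung of a temperature ladder, computed over the final analysis window of
every replica. The unfolding temperature Tm is the ladder rung where the
first derivative of the (mildly smoothed) curve is most negative; curves
that fail a sigmoidality check fall back to the half-amplitude midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import ReplicaSeries


def make_ladder(t_min: float, t_max: float, n: int) -> np.ndarray:
    """Geometric (constant-ratio) temperature ladder with exact
    endpoints: T_i = t_min * r**i, r = (t_max/t_min)**(1/(n-1))."""
    if not t_min < t_max:
        raise ValueError("t_min must be below t_max")
    if n < 2:
        raise ValueError("a ladder needs at least 2 rungs")
    ratio = (t_max / t_min) ** (1.0 / (n - 1))
    ladder = t_min * ratio ** np.arange(n)
    ladder[-1] = t_max
    return ladder


@dataclass
class StabilityCurve:
    """Mean +/- SD of one observable along a temperature ladder."""

    ladder: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    observable: str
    units: str = ""
    window_fraction: float = 0.5

    def __post_init__(self):
        self.ladder = np.asarray(self.ladder, float)
        self.means = np.asarray(self.means, float)
        self.sds = np.asarray(self.sds, float)
        if not (len(self.ladder) == len(self.means) == len(self.sds)):
            raise ValueError("ladder/means/sds length mismatch")
        if np.any(np.diff(self.ladder) <= 0):
            raise ValueError("ladder must be strictly increasing")
        if np.any(self.sds < 0):
            raise ValueError("standard deviations must be non-negative")


def ensemble_averages(
    series: ReplicaSeries,
    observables: list[str],
    window_fraction: float = 0.5,
) -> dict[str, StabilityCurve]:
    """Mean +/- SD of each observable column over the final
    ``window_fraction`` of frames at every temperature."""
    win = series.window(window_fraction)
    curves = {}
    for obs in observables:
        if obs not in win.columns:
            raise KeyError(f"observable column not found: {obs!r}")
        g = win.groupby("temperature_K")[obs]
        if (g.size() < 2).any():
            raise ValueError("every temperature needs >= 2 frames in the window")
        means = g.mean().reindex(series.temperatures).to_numpy()
        sds = g.std(ddof=0).reindex(series.temperatures).to_numpy()
        curves[obs] = StabilityCurve(
            series.temperatures, means, sds, obs, window_fraction=window_fraction
        )
    return curves


def _smooth(y: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with truncated endpoints."""
    if width <= 1:
        return y.copy()
    half = width // 2
    out = np.empty_like(y)
    for i in range(len(y)):
        lo = max(0, i - half)
        hi = min(len(y), i + half + 1)
        out[i] = y[lo:hi].mean()
    return out


@dataclass
class TmResult:
    tm: float
    diagnostic: str  # "sigmoidal" | "non_sigmoidal"
    derivative: np.ndarray
    rung_index: int


def extract_tm(curve: StabilityCurve, smooth_window: int = 3) -> TmResult:
    """Unfolding temperature: the ladder rung where the first derivative
    of the smoothed means with respect to temperature is minimal.

    The diagnostic flags a curve as ``non_sigmoidal`` — signalling the
    midpoint fallback — when the steepest rung sits within 2 rungs of a
    ladder end, or when the total drop is smaller than 4x the median
    per-rung noise estimated from the SDs.
    """
    T = curve.ladder
    if len(T) < 5:
        raise ValueError("Tm extraction needs at least 5 ladder rungs")
    y = _smooth(curve.means, smooth_window)
    d = np.empty_like(y)
    d[1:-1] = (y[2:] - y[:-2]) / (T[2:] - T[:-2])
    d[0] = (y[1] - y[0]) / (T[1] - T[0])
    d[-1] = (y[-1] - y[-2]) / (T[-1] - T[-2])
    k = int(np.argmin(d))

    drop = float(np.max(curve.means) - np.min(curve.means))
    noise = float(np.median(curve.sds))
    near_edge = k <= 2 or k >= len(T) - 3
    weak = drop < 4.0 * noise
    diagnostic = "non_sigmoidal" if (near_edge or weak) else "sigmoidal"
    return TmResult(float(T[k]), diagnostic, d, k)


def extract_midpoint(curve: StabilityCurve) -> float:
    """Temperature where the mean first crosses (max+min)/2, by linear
    interpolation from the low-temperature side."""
    y = curve.means
    T = curve.ladder
    lo, hi = float(np.min(y)), float(np.max(y))
    if hi <= lo:
        raise ValueError("constant curve has no midpoint")
    mid = 0.5 * (lo + hi)
    for i in range(len(y) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - mid) == 0.0:
            return float(T[i])
        if (y0 - mid) * (y1 - mid) < 0:
            f = (mid - y0) / (y1 - y0)
            return float(T[i] + f * (T[i + 1] - T[i]))
    # curve starts past the midpoint or ends exactly on it
    if (y[-1] - mid) == 0.0:
        return float(T[-1])
    raise ValueError("curve never crosses its midpoint")
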