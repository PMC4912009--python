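"""Specific heat profiles, peak detection and critical temperatures.

By analogy with the physical quantity, the specific heat of a search at
temperature ``T`` is ``C = sigma^2 / T^2`` where ``sigma^2`` is the variance
of the cost (HI) samples collected at that temperature.  Peaks in ``C`` mark
phase transitions: temperature ranges where the distribution of states the
search visits reorganises, and below which the search becomes trapped in one
region of tree space.  Profiles show either one peak or two ("double
transitions", read as gross-then-fine resolution of tree structure); the
classifier therefore reports at most two peaks, keeping any further raw
local maxima for diagnostics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .annealing import RunTrace, TemperatureBlock

__all__ = [
    "HeatProfile",
    "PeakReport",
    "specific_heat",
    "profile",
    "detect_peaks",
    "critical_temperature",
    "plot_profile",
]


@dataclass
class HeatProfile:
    """Ordered (T, C) pairs, one per completed temperature block, T decreasing."""

    temperatures: np.ndarray
    c_values: np.ndarray
    run_id: str = ""

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.c_values = np.asarray(self.c_values, dtype=float)
        if self.temperatures.shape != self.c_values.shape:
            raise ValueError("temperature and C arrays differ in length")
        if (self.c_values < 0).any():
            raise ValueError("specific heat cannot be negative")

    def __len__(self) -> int:
        return len(self.temperatures)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"T": self.temperatures, "C": self.c_values})


@dataclass
class PeakReport:
    """Classified peaks ordered by descending magnitude.

    ``peaks`` holds the retained (T_c, C_max) pairs (at most two);
    ``raw_peaks`` lists every prominent local maximum for diagnostics.
    ``classification`` is ``single``, ``double`` or ``none``.
    """

    peaks: list[tuple[float, float]]
    n_peaks: int
    classification: str
    raw_peaks: list[tuple[float, float]] = field(default_factory=list)


def specific_heat(block: TemperatureBlock) -> float:
    """``C = var(HI samples, ddof=1) / T^2`` for one temperature block."""
    if block.T <= 0:
        raise ValueError("specific heat requires T > 0")
    if len(block.hi_samples) < 2:
        raise ValueError("need at least 2 cost samples to estimate a variance")
    s = np.asarray(block.hi_samples, dtype=float)
    if np.all(s == s[0]):
        return 0.0  # exact zero; np.var leaves ~1e-29 roundoff on constants
    return float(np.var(s, ddof=1)) / (block.T * block.T)


def profile(trace: RunTrace, run_id: str | None = None) -> HeatProfile:
    """One (T, C) point per completed block of a run, cooling order preserved."""
    blocks = [b for b in trace.blocks if len(b.hi_samples) >= 2]
    if len(blocks) < 3:
        raise ValueError("trace has fewer than 3 usable temperature blocks")
    return HeatProfile(
        temperatures=np.array([b.T for b in blocks]),
        c_values=np.array([specific_heat(b) for b in blocks]),
        run_id=run_id if run_id is not None else trace.alignment_id,
    )


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    kernel = np.ones(window)
    return np.convolve(y, kernel, mode="same") / np.convolve(np.ones_like(y), kernel, mode="same")


def detect_peaks(p: HeatProfile, smooth_window: int = 5,
                 prominence_frac: float = 0.25) -> PeakReport:
    """Locate and classify specific-heat maxima.

    The profile is moving-average smoothed, local maxima with prominence at
    least ``prominence_frac`` of the global smoothed maximum are retained, and
    the top two by magnitude are reported.  Two retained maxima separated by
    at least 3 smoothed points classify the profile as ``double``; otherwise
    ``single``.  A flat (or peakless) profile classifies as ``none``.
    """
    if len(p) < smooth_window:
        raise ValueError("profile shorter than the smoothing window")
    y = _smooth(p.c_values, smooth_window)
    ymax = float(y.max())
    if ymax <= 0 or np.allclose(y, y[0]):
        return PeakReport(peaks=[], n_peaks=0, classification="none")
    idx, props = find_peaks(y, prominence=prominence_frac * ymax)
    if len(idx) == 0:
        return PeakReport(peaks=[], n_peaks=0, classification="none")
    order = np.argsort(y[idx])[::-1]
    raw = [(float(p.temperatures[i]), float(y[i])) for i in idx[order]]
    top = idx[order][:2]
    if len(top) == 2 and abs(int(top[0]) - int(top[1])) >= 3:
        classification = "double"
        kept = [(float(p.temperatures[i]), float(y[i])) for i in top]
        n_peaks = 2
    else:
        classification = "single"
        kept = [(float(p.temperatures[top[0]]), float(y[top[0]]))]
        n_peaks = 1
    return PeakReport(peaks=kept, n_peaks=n_peaks, classification=classification,
                      raw_peaks=raw)


def critical_temperature(reports) -> float:
    """Mean over replicates of each replicate's largest-peak temperature."""
    tcs = [r.peaks[0][0] for r in reports if r.peaks]
    if not tcs:
        raise ValueError("no replicate produced a specific-heat peak")
    return float(np.mean(tcs))


def plot_profile(p: HeatProfile, path, report: PeakReport | None = None) -> None:
    """PNG of C vs T; the search progresses right to left as T decreases."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(p.temperatures, p.c_values, lw=1)
    if report is not None:
        for tc, cmax in report.peaks:
            ax.axvline(tc, color="crimson", ls="--", lw=0.8)
    ax.set_xlabel("temperature T")
    ax.set_ylabel("specific heat C")
    ax.set_title(p.run_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
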