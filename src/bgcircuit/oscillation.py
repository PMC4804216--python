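"""Spectral characterization of nucleus activity.

The circuit's selection dynamics live in two low-frequency bands: *slow*
oscillations (0.5-2 Hz), generated by the switching function of the
short indirect pathway, and *ultraslow* oscillations (0.017-0.5 Hz),
generated by the maintenance function of the direct pathway.  The unit
time constants impose a hard ~2 Hz ceiling on channel phase changes, so
no faster band is analysable by construction (beta-band phenomena are
out of reach of a rate model and deliberately out of scope).

Band powers are integrated Welch periodograms (Hann windows, segment
length half the analysis window, 50% overlap) of the mean-removed
transfer output ``y``; an alternative plain-periodogram estimator is
exposed for exact Parseval accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "SLOW_BAND",
    "ULTRASLOW_BAND",
    "DC_FLOOR_HZ",
    "band_power",
    "dominant_frequency",
    "summarize_trace",
    "SpectralSummary",
]

#: switching-related band, Hz
SLOW_BAND = (0.5, 2.0)
#: maintenance-related band, Hz (floor excludes DC / trends)
ULTRASLOW_BAND = (0.017, 0.5)
#: default DC-exclusion floor, Hz
DC_FLOOR_HZ = 0.017

#: alternative band edges quoted in the animal-electrophysiology literature
LITERATURE_SLOW_BAND = (0.3, 2.0)


def _psd(series: np.ndarray, fs: float, estimator: str, nperseg: int | None):
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 4:
        raise ValueError("series must be 1-d with length >= 4")
    x = series - series.mean()
    if estimator == "welch":
        nseg = nperseg if nperseg is not None else max(4, len(x) // 2)
        return signal.welch(x, fs=fs, window="hann", nperseg=min(nseg, len(x)),
                            noverlap=None, detrend="constant")
    if estimator == "periodogram":
        return signal.periodogram(x, fs=fs, window="boxcar", detrend="constant")
    raise ValueError(f"unknown estimator {estimator!r}")


def band_power(series, fs: float, band: tuple, estimator: str = "welch",
               nperseg: int | None = None) -> float:
    """Integrated power of the mean-removed series within ``[lo, hi)`` Hz.

    ``estimator='welch'`` (default) averages Hann-windowed segments of
    half the series length at 50% overlap; ``'periodogram'`` uses the
    plain periodogram, whose band powers over a full partition of the
    spectrum add up exactly to the series variance (Parseval).
    """
    lo, hi = band
    if not 0 <= lo < hi:
        raise ValueError(f"invalid band {band}")
    if lo > fs / 2:
        raise ValueError(f"band {band} lies above the Nyquist frequency {fs / 2}")
    f, p = _psd(series, fs, estimator, nperseg)
    m = (f >= lo) & (f < hi)
    if estimator == "periodogram":
        # sum of discrete spectral-line powers: exact Parseval partition
        return float(np.sum(p[m]) * (f[1] - f[0]))
    return float(np.trapezoid(p[m], f[m])) if m.sum() > 1 else float(np.sum(p[m]) * (f[1] - f[0]))


def dominant_frequency(series, fs: float, floor_hz: float = DC_FLOOR_HZ,
                       estimator: str = "periodogram") -> float:
    """Frequency of the periodogram peak above ``floor_hz``, Hz.

    ``floor_hz`` must be positive (it excludes the DC bin); the series
    must span at least one period of ``floor_hz``.
    """
    if not floor_hz > 0:
        raise ValueError("floor_hz must be > 0 (DC exclusion)")
    series = np.asarray(series, dtype=float)
    if len(series) < fs / floor_hz:
        raise ValueError(
            f"series shorter than one period of floor_hz={floor_hz} Hz")
    f, p = _psd(series, fs, estimator, None)
    m = f >= floor_hz
    if not m.any():
        raise ValueError("no frequency bins above floor_hz")
    return float(f[m][np.argmax(p[m])])


@dataclass
class SpectralSummary:
    """Per-(nucleus, channel) band powers and dominant frequencies."""

    table: pd.DataFrame  # nucleus, channel, dominant_hz, power_slow, power_ultraslow, ratio
    window: tuple

    def nucleus(self, name: str) -> pd.DataFrame:
        sub = self.table[self.table.nucleus == name]
        if sub.empty:
            raise KeyError(f"nucleus {name!r} not in summary")
        return sub

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def summarize_trace(trace, window: tuple | None = None, nuclei=None,
                    floor_hz: float = DC_FLOOR_HZ,
                    slow=SLOW_BAND, ultraslow=ULTRASLOW_BAND) -> SpectralSummary:
    """Band powers and dominant frequency of every unit over a window.

    ``window=(t0, t1)`` restricts the analysis (e.g. the 15-25 s epoch
    used for the oscillation case studies); default is the whole trace.
    The band ratio is ultraslow/slow power (NaN when the slow band is
    empty of power).
    """
    if window is not None:
        trace = trace.window(*window)
    else:
        window = (float(trace.t[0]), float(trace.t[-1]))
    fs = trace.fs
    rows = []
    for name in (nuclei if nuclei is not None else trace.slices):
        block = trace.nucleus(name)
        for ch in range(block.shape[1]):
            x = block[:, ch]
            ps = band_power(x, fs, slow)
            pu = band_power(x, fs, ultraslow)
            if x.std() == 0:
                dom = np.nan
            else:
                # a short window cannot resolve the nominal floor; raise it
                # to the window's own frequency resolution
                floor_eff = max(floor_hz, fs / len(x))
                dom = dominant_frequency(x, fs, floor_eff)
            rows.append({"nucleus": name, "channel": ch, "dominant_hz": dom,
                         "power_slow": ps, "power_ultraslow": pu,
                         "ratio_ultraslow_slow": pu / ps if ps > 0 else np.nan})
    return SpectralSummary(table=pd.DataFrame(rows), window=window)
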