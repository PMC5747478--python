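"""Dominant-frequency (DF) mapping and spatiotemporal DF statistics.

Per node, the DF of a 6-s membrane-potential window is the frequency of
maximal power of the mean-removed signal within an analysis band
(default 1-20 Hz, covering fibrillatory rates while excluding DC).  The
highest-k% DF area is the set of nodes with the top k% DF values; its
distribution over the ten atrial segments, tracked across analysis
windows, yields the spatial and temporal mean-variance statistics used
to quantify rotor stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tissue_solver import TissueDomain, VoltageMovie

__all__ = [
    "DFMap",
    "RegionalProportionTable",
    "compute_df_map",
    "highest_df_area",
    "regional_proportions",
    "spatial_mean_variance",
    "temporal_mean_variance",
]


@dataclass
class DFMap:
    """Per-node dominant frequency for one analysis window."""

    df_hz: np.ndarray          # nan where undefined
    peak_power: np.ndarray
    window_start_ms: float
    window_length_ms: float
    band_hz: tuple
    domain: TissueDomain | None = None

    @property
    def freq_resolution_hz(self) -> float:
        return 1000.0 / self.window_length_ms

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.df_hz)

    def to_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.df_hz, self.peak_power]),
                   header="DF_Hz peak_power", fmt="%.6g")


@dataclass
class RegionalProportionTable:
    """Highest-k% DF-area proportions: rows = 10 segments, cols = windows."""

    proportions: np.ndarray    # (n_regions, n_windows)
    k_percent: float
    window_labels: tuple = ()
    region_names: tuple = ()

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, float)
        if self.proportions.ndim != 2:
            raise ValueError("proportions must be 2-D (regions x windows)")

    def to_frame(self) -> pd.DataFrame:
        idx = self.region_names or [f"region_{i+1}" for i in range(self.proportions.shape[0])]
        cols = self.window_labels or [f"T{j+1}" for j in range(self.proportions.shape[1])]
        return pd.DataFrame(self.proportions, index=list(idx), columns=list(cols))


def compute_df_map(movie: VoltageMovie, window_start_ms: float | None = None,
                   window_length_ms: float = 6000.0,
                   band_hz: tuple = (1.0, 20.0),
                   taper: bool = False) -> DFMap:
    """Power-spectrum DF of every node over one window.

    The per-node signal is mean-removed (rectangular window by default;
    ``taper`` applies a Hann window) and Fourier transformed; DF is the
    frequency of maximal power inside ``band_hz``.  Nodes with no power
    in the band (e.g. quiescent tissue) get an undefined DF (nan).
    """
    if window_start_ms is None:
        window_start_ms = movie.t0_ms
    sub = movie.window(window_start_ms, window_length_ms)
    fs_hz = 1000.0 / movie.dt_ms
    if fs_hz < 2.0 * band_hz[1]:
        raise ValueError("sampling rate below twice the band upper edge")

    sig = sub.data.astype(np.float64)
    sig = sig - sig.mean(axis=1, keepdims=True)
    if taper:
        sig = sig * np.hanning(sig.shape[1])[None, :]
    spec = np.fft.rfft(sig, axis=1)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(sig.shape[1], d=movie.dt_ms / 1000.0)

    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not np.any(in_band):
        raise ValueError("analysis band contains no frequency bins")
    bidx = np.nonzero(in_band)[0]
    bpow = power[:, bidx]
    arg = np.argmax(bpow, axis=1)
    peak = bpow[np.arange(len(arg)), arg]
    df = freqs[bidx[arg]]
    # a flat signal has (numerically) zero power everywhere in the band
    total = bpow.sum(axis=1)
    undefined = peak <= 1e-9 * max(1.0, float(np.max(peak, initial=0.0)))
    undefined |= total <= 1e-12
    df = np.where(undefined, np.nan, df)
    peak = np.where(undefined, 0.0, peak)
    return DFMap(df_hz=df, peak_power=peak, window_start_ms=float(window_start_ms),
                 window_length_ms=float(window_length_ms), band_hz=tuple(band_hz),
                 domain=sub.domain or movie.domain)


def highest_df_area(dfmap: DFMap, k_percent: float) -> np.ndarray:
    """Indices of the ceil(k% x N) nodes with the largest DF.

    Ties are broken by peak spectral power, then by node index (lower
    index first), making the selection deterministic and nested across
    increasing k.  Raises if every node's DF is undefined.
    """
    if not 0.0 < k_percent < 100.0:
        raise ValueError("k must be in (0, 100)")
    df = dfmap.df_hz
    if not np.any(np.isfinite(df)):
        raise ValueError("all DFs undefined; no area can be selected")
    n = df.size
    count = int(np.ceil(k_percent / 100.0 * n))
    key_df = np.where(np.isfinite(df), df, -np.inf)
    order = np.lexsort((np.arange(n), -dfmap.peak_power, -key_df))
    return np.sort(order[:count])


def regional_proportions(node_set, domain_or_labels, n_regions: int | None = None) -> np.ndarray:
    """Fraction of the node set in each region (sums to 1)."""
    nodes = np.asarray(node_set, np.int64)
    if nodes.size == 0:
        raise ValueError("empty node set has no regional distribution")
    labels = (domain_or_labels.region_labels
              if isinstance(domain_or_labels, TissueDomain) else
              np.asarray(domain_or_labels))
    if n_regions is None:
        n_regions = int(labels.max())
    counts = np.bincount(labels[nodes], minlength=n_regions + 1)[1:n_regions + 1]
    return counts / counts.sum()


def _as_matrix(table) -> np.ndarray:
    mat = table.proportions if isinstance(table, RegionalProportionTable) else np.asarray(table, float)
    if np.any(~np.isfinite(mat)):
        raise ValueError("proportion table has missing entries")
    return mat


def spatial_mean_variance(table) -> float:
    """Mean over windows of the across-region sample variance (ddof=1)."""
    mat = _as_matrix(table)
    return float(np.mean(np.var(mat, axis=0, ddof=1)))


def temporal_mean_variance(table) -> float:
    """Mean over regions of the across-window sample variance (ddof=1)."""
    mat = _as_matrix(table)
    return float(np.mean(np.var(mat, axis=1, ddof=1)))
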