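"""Band-pass filtering, instantaneous phase, and phase-lag-index (PLI) FC.

The PLI between two signals is the absolute time-average of the sign of the
sine of their instantaneous phase difference:

    PLI_ij = | < sign( sin( phi_i(t) - phi_j(t) ) ) >_t |

It ranges from 0 (symmetric phase-difference distribution, e.g. identical or
zero-lag signals) to 1 (fully asymmetric: one signal consistently leads).
Being insensitive to zero-lag interactions makes it robust to field spread /
volume conduction in MEG. sign(0) contributes 0, so identical signals give
PLI = 0 exactly.

The analysis pipeline mirrors the MEG protocol: Butterworth band-pass into
the alpha range (8-12 Hz), instantaneous phase via the Hilbert transform,
PLI per epoch, and subject-level averaging over epochs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from scipy import signal as sps

from .errors import DegenerateSignalError, FormatError, ValidationError
from .model import TimeSeriesPanel

logger = logging.getLogger(__name__)

ALPHA_BAND = (8.0, 12.0)
BUTTER_ORDER = 4
EDGE_TRIM_S = 0.5  # trimmed from both ends before phase extraction


@dataclass(frozen=True)
class PhasePanel:
    """Instantaneous phases (radians, wrapped to (-pi, pi]), T x N."""

    phases: np.ndarray
    fs_hz: float
    labels: tuple[str, ...]
    band: tuple[float, float] | None = None

    def __post_init__(self):
        p = np.asarray(self.phases, dtype=float)
        if p.ndim != 2 or p.shape[1] != len(self.labels):
            raise ValidationError(f"phases must be T x {len(self.labels)}")
        if not np.all(np.isfinite(p)):
            raise ValidationError("non-finite phase values")
        if np.any(p > np.pi + 1e-9) or np.any(p < -np.pi - 1e-9):
            raise ValidationError("phases must be wrapped to (-pi, pi]")
        object.__setattr__(self, "phases", p)


@dataclass(frozen=True)
class PLIMatrix:
    """Symmetric N x N phase-lag-index matrix with zero diagonal.

    ``threshold_applied`` records proportional or median thresholding
    provenance as ``(kind, level)`` with kind in {"percentile", "median"}.
    """

    values: np.ndarray
    labels: tuple[str, ...]
    source: str = "simulated"  # "empirical" | "simulated"
    threshold_applied: tuple[str, float] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValidationError(f"PLI matrix must be {n}x{n}, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("non-finite PLI entries")
        if np.any(v < 0) or np.any(v > 1):
            raise ValidationError("PLI entries must lie in [0, 1]")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0):
            raise ValidationError("PLI matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("PLI diagonal must be zero")
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]


@dataclass(frozen=True)
class SpectralPeakTable:
    """Per-region spectral peak frequencies with acceptance flags.

    ``peak_hz`` is NaN where no peak was accepted. Accepted peaks are
    > 4 Hz by construction.
    """

    labels: tuple[str, ...]
    peak_hz: np.ndarray
    accepted: np.ndarray

    def __post_init__(self):
        pk = np.asarray(self.peak_hz, dtype=float)
        ac = np.asarray(self.accepted, dtype=bool)
        n = len(self.labels)
        if pk.shape != (n,) or ac.shape != (n,):
            raise ValidationError("peak table arrays must be length N")
        if np.any(pk[ac] <= 4.0):
            raise ValidationError("accepted peaks must exceed 4 Hz")
        object.__setattr__(self, "peak_hz", pk)
        object.__setattr__(self, "accepted", ac)


def bandpass(ts: TimeSeriesPanel, low_hz: float, high_hz: float) -> TimeSeriesPanel:
    """Zero-phase 4th-order Butterworth band-pass filter.

    Applied forward-backward (filtfilt) so relative phases between channels
    are not distorted by the filter's phase response.
    """
    nyq = ts.fs_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValidationError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyq} Hz"
        )
    sos = sps.butter(BUTTER_ORDER, [low_hz, high_hz], btype="bandpass",
                     fs=ts.fs_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, ts.values, axis=0)
    return TimeSeriesPanel(values=filtered, fs_hz=ts.fs_hz, labels=ts.labels)


def trim_edges(ts: TimeSeriesPanel, seconds: float = EDGE_TRIM_S) -> TimeSeriesPanel:
    """Drop ``seconds`` from both ends (filter / Hilbert edge artifacts)."""
    k = int(round(seconds * ts.fs_hz))
    if 2 * k >= ts.n_samples:
        raise ValidationError("trim would remove the entire signal")
    if k == 0:
        return ts
    return TimeSeriesPanel(values=ts.values[k:-k], fs_hz=ts.fs_hz, labels=ts.labels)


def instantaneous_phase(ts: TimeSeriesPanel) -> PhasePanel:
    """Per-channel analytic-signal phase via the Hilbert transform."""
    if ts.n_samples < 64:
        raise ValidationError("need at least 64 samples for phase extraction")
    if np.any(np.all(ts.values == 0.0, axis=0)):
        raise DegenerateSignalError("all-zero channel: phase undefined")
    analytic = sps.hilbert(ts.values, axis=0)
    phases = np.angle(analytic)
    return PhasePanel(phases=phases, fs_hz=ts.fs_hz, labels=ts.labels)


@njit(cache=True)
def _pli_core(phases):
    T, N = phases.shape
    pli = np.zeros((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            acc = 0.0
            for t in range(T):
                d = phases[t, i] - phases[t, j]
                # wrap into (-pi, pi]; sign(sin d) = sign of the wrapped d,
                # zero exactly at d in {0, pi} (mod 2 pi)
                while d > np.pi:
                    d -= 2 * np.pi
                while d <= -np.pi:
                    d += 2 * np.pi
                if d > 0.0 and d < np.pi:
                    acc += 1.0
                elif d < 0.0:
                    acc -= 1.0
            v = abs(acc) / T
            pli[i, j] = v
            pli[j, i] = v
    return pli


def phase_lag_index(phases: PhasePanel, source: str = "simulated") -> PLIMatrix:
    """PLI over all region pairs: |<sign(sin(phi_i - phi_j))>_t|."""
    if phases.phases.shape[0] < 2:
        raise ValidationError("need at least 2 time samples")
    values = _pli_core(np.ascontiguousarray(phases.phases))
    return PLIMatrix(values=values, labels=phases.labels, source=source)


def pli_from_timeseries(
    ts: TimeSeriesPanel,
    band: tuple[float, float] = ALPHA_BAND,
    edge_trim_s: float = EDGE_TRIM_S,
    source: str = "simulated",
) -> PLIMatrix:
    """Full pipeline: band-pass -> edge trim -> Hilbert phase -> PLI."""
    filtered = bandpass(ts, *band)
    trimmed = trim_edges(filtered, edge_trim_s)
    return phase_lag_index(instantaneous_phase(trimmed), source=source)


def epoch_average_pli(plis: list[PLIMatrix]) -> PLIMatrix:
    """Entrywise mean PLI over a subject's epochs (unthresholded inputs)."""
    if not plis:
        raise ValidationError("no PLI matrices to average")
    labels = plis[0].labels
    if any(p.labels != labels for p in plis):
        raise ValidationError("PLI matrices have mismatched region labels")
    if any(p.threshold_applied is not None for p in plis):
        raise ValidationError("cannot epoch-average thresholded PLI matrices")
    mean = np.mean([p.values for p in plis], axis=0)
    return PLIMatrix(values=mean, labels=labels, source=plis[0].source)


def _pair_order(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle pairs ordered by (magnitude, row, col) ascending."""
    rows, cols = np.triu_indices(values.shape[0], k=1)
    mags = np.abs(values[rows, cols])
    order = np.lexsort((cols, rows, mags))
    return rows[order], cols[order], mags[order]


def threshold_pli(pli: PLIMatrix, percent: float) -> PLIMatrix:
    """Zero the lowest ``percent``% of region pairs by magnitude.

    Exactly floor(P * percent / 100) of the P = N(N-1)/2 pairs are zeroed;
    ties are broken by a stable (magnitude, row, col) ordering so the count
    is deterministic.
    """
    if pli.threshold_applied is not None:
        raise ValidationError("PLI matrix is already thresholded")
    if not 0 <= percent < 100:
        raise ValidationError("threshold percent must be in [0, 100); 100 would "
                              "zero the whole matrix and break the fit objective")
    rows, cols, _ = _pair_order(pli.values)
    n_zero = int(np.floor(len(rows) * percent / 100.0))
    out = pli.values.copy()
    out[rows[:n_zero], cols[:n_zero]] = 0.0
    out[cols[:n_zero], rows[:n_zero]] = 0.0
    return replace(pli, values=out, threshold_applied=("percentile", float(percent)))


def median_threshold_pli(pli: PLIMatrix) -> PLIMatrix:
    """Zero all pairs strictly below the median off-diagonal PLI value."""
    if pli.threshold_applied is not None:
        raise ValidationError("PLI matrix is already thresholded")
    upper = pli.upper_triangle()
    med = float(np.median(upper))
    out = pli.values.copy()
    mask = out < med
    np.fill_diagonal(mask, False)
    out[mask] = 0.0
    return replace(pli, values=out, threshold_applied=("median", med))


def peak_frequency(
    ts: TimeSeriesPanel,
    min_hz: float = 4.0,
    background_band: tuple[float, float] = (4.0, 48.0),
    notch_hz: float = 1.0,
    rejection_ratio: float = 2.0,
) -> SpectralPeakTable:
    """Per-region spectral peak above ``min_hz`` with background rejection.

    Welch PSD (2 s Hann segments, 50% overlap, 0.5 Hz resolution at the
    default sampling rate); the candidate peak is the argmax over
    frequencies > min_hz and is accepted only if its density is at least
    ``rejection_ratio`` times the mean density of the background spectrum
    (``background_band`` excluding +-``notch_hz`` around the candidate).
    """
    if ts.duration_s < 2.0:
        raise ValidationError("peak estimation needs at least 2 s of signal")
    nperseg = min(int(round(2.0 * ts.fs_hz)), ts.n_samples)
    freqs, psd = sps.welch(ts.values, fs=ts.fs_hz, window="hann",
                           nperseg=nperseg, noverlap=nperseg // 2, axis=0)
    cand_mask = freqs > min_hz
    bg_mask = (freqs >= background_band[0]) & (freqs <= background_band[1])
    peaks = np.full(ts.n_channels, np.nan)
    accepted = np.zeros(ts.n_channels, dtype=bool)
    for ch in range(ts.n_channels):
        p = psd[:, ch]
        idx = np.flatnonzero(cand_mask)[np.argmax(p[cand_mask])]
        f_peak = freqs[idx]
        bg = bg_mask & (np.abs(freqs - f_peak) > notch_hz)
        if not np.any(bg):
            continue
        if p[idx] >= rejection_ratio * np.mean(p[bg]):
            peaks[ch] = f_peak
            accepted[ch] = True
    return SpectralPeakTable(labels=ts.labels, peak_hz=peaks, accepted=accepted)


def median_peak_frequencies(tables: list[SpectralPeakTable]) -> np.ndarray:
    """Per-region median peak frequency across subjects/epochs.

    Only accepted peaks enter the median. A region with no accepted peak in
    any table falls back to the global median across regions (logged); if no
    region has any accepted peak the data cannot parameterize the model.
    """
    if not tables:
        raise ValidationError("no peak tables given")
    labels = tables[0].labels
    if any(t.labels != labels for t in tables):
        raise ValidationError("peak tables have mismatched region labels")
    n = len(labels)
    medians = np.full(n, np.nan)
    for r in range(n):
        vals = [t.peak_hz[r] for t in tables if t.accepted[r]]
        if vals:
            medians[r] = np.median(vals)
    if np.all(np.isnan(medians)):
        raise DegenerateSignalError("no accepted spectral peak in any region")
    if np.any(np.isnan(medians)):
        fallback = float(np.nanmedian(medians))
        missing = [labels[i] for i in np.flatnonzero(np.isnan(medians))]
        logger.warning("regions %s have no accepted peak; using global median "
                       "%.3g Hz", missing, fallback)
        medians[np.isnan(medians)] = fallback
    return medians


# ---------------------------------------------------------------------------
# I/O

def write_pli(pli: PLIMatrix, path: str | Path) -> None:
    """Write a PLI matrix as labeled CSV plus a JSON provenance sidecar."""
    path = Path(path)
    pd.DataFrame(pli.values, columns=list(pli.labels)).to_csv(
        path, index=False, float_format="%.17g"
    )
    sidecar = {
        "source": pli.source,
        "threshold_applied": list(pli.threshold_applied) if pli.threshold_applied else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_pli(path: str | Path, labels: tuple[str, ...] | None = None) -> PLIMatrix:
    """Read a labeled-CSV PLI matrix (optionally checking label order)."""
    path = Path(path)
    from .connectome import _sniff_delimiter

    df = pd.read_csv(path, sep=_sniff_delimiter(path), float_precision="round_trip")
    file_labels = tuple(str(c) for c in df.columns)
    if labels is not None and file_labels != tuple(labels):
        raise FormatError(f"{path}: labels do not match the expected atlas order")
    values = df.to_numpy(dtype=float)
    source, threshold = "empirical", None
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        source = meta.get("source", source)
        if meta.get("threshold_applied"):
            kind, level = meta["threshold_applied"]
            threshold = (str(kind), float(level))
    return PLIMatrix(values=values, labels=file_labels, source=source,
                     threshold_applied=threshold)
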