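"""Segmentation and band-averaged imaginary coherency.

Recordings are cut into segments (2000 ms resting segments, or stimulus-
locked -500..1000 ms task epochs restricted to correct responses). Within
each segment, multitaper cross-spectra give the complex coherency

    C_xy(f) = S_xy(f) / sqrt(S_xx(f) S_yy(f)),

whose imaginary part is insensitive to zero-lag (volume-conducted)
coupling. Band values are the mean over in-band frequency bins of
|Im C_xy(f)|. The default estimator uses 3 discrete prolate spheroidal
(DPSS) tapers: a single-taper single-segment coherency is degenerate
(|C| = 1 at every bin), so at least a few tapers are required for the
per-segment estimates the thresholding step consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss

logger = logging.getLogger(__name__)

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "EEGEpochs",
    "CoherenceMatrix",
    "segment_resting",
    "segment_task",
    "coherency",
    "imaginary_coherency",
    "band_average",
    "band_coherence_per_segment",
    "pooled_band_coherency",
]


@dataclass(frozen=True)
class BandDefinition:
    """Frequency band; ``closed_high`` includes the upper edge.

    The shared 10 Hz edge between the alpha sub-bands is resolved
    half-open ([8, 10), [10, 13)) to avoid counting a bin twice.
    """

    name: str
    lo: float
    hi: float
    closed_high: bool = True

    def bins(self, freqs: np.ndarray) -> np.ndarray:
        if self.closed_high:
            return (freqs >= self.lo) & (freqs <= self.hi)
        return (freqs >= self.lo) & (freqs < self.hi)


DEFAULT_BANDS = (
    BandDefinition("theta", 4.0, 7.0, closed_high=True),
    BandDefinition("low_alpha", 8.0, 10.0, closed_high=False),
    BandDefinition("high_alpha", 10.0, 13.0, closed_high=False),
    BandDefinition("beta", 13.0, 30.0, closed_high=True),
)


@dataclass
class EEGEpochs:
    """Stack of equal-length segments: (n_segments, n_channels, n_times)."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    condition: str = ""
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3:
            raise ValueError("epochs data must be (segments, channels, times)")
        if not np.isfinite(d).all():
            raise ValueError("epochs contain non-finite samples")
        self.data = d

    @property
    def n_segments(self) -> int:
        return self.data.shape[0]


@dataclass
class CoherenceMatrix:
    """Band-averaged unsigned imaginary coherency for one segment."""

    values: np.ndarray
    band: BandDefinition | None = None
    segment_id: int | None = None
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("coherence matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("coherence matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("coherence matrix diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-9:
            raise ValueError("band |Im coherency| must lie in [0, 1]")
        self.values = v


def segment_resting(recording, segment_ms: float = 2000.0) -> EEGEpochs:
    """Cut a resting recording into consecutive non-overlapping segments.

    The trailing remainder shorter than one segment is dropped.
    """
    fs = recording.fs
    seg_len = int(round(segment_ms / 1000.0 * fs))
    samples = np.asarray(recording.samples)
    n_seg = samples.shape[1] // seg_len
    if n_seg == 0:
        raise ValueError(
            f"recording shorter ({samples.shape[1]} samples) than one "
            f"segment ({seg_len} samples)"
        )
    data = (
        samples[:, : n_seg * seg_len]
        .reshape(samples.shape[0], n_seg, seg_len)
        .transpose(1, 0, 2)
    )
    logger.info("resting segmentation: %d segments of %d samples", n_seg, seg_len)
    return EEGEpochs(
        data=data,
        fs=fs,
        channel_labels=list(recording.channel_labels),
        condition="rest",
        t0_ms=0.0,
    )


def segment_task(
    recording,
    trial_records: pd.DataFrame,
    labels: pd.DataFrame,
    tmin_ms: float = -500.0,
    tmax_ms: float = 1000.0,
    half_size_blocks: int = 10,
) -> dict[str, EEGEpochs]:
    """Stimulus-locked epochs per probability condition and task half.

    Stimulus events (codes starting with "S") are matched in order to
    ``trial_records`` rows. Epochs of -500..1000 ms around onsets of
    *correct* high-probability random and low-probability random trials
    are binned into blocks 1..half_size vs the rest. Epochs exceeding the
    recording bounds are skipped with a log entry; empty bins are reported
    (downstream analyses exclude such subjects).

    Returns a dict keyed ``high_h1, high_h2, low_h1, low_h2``.
    """
    fs = recording.fs
    stim_events = [(s, c) for s, c in recording.events if c.startswith("S")]
    if len(stim_events) != len(trial_records):
        raise ValueError(
            f"{len(stim_events)} stimulus events do not match "
            f"{len(trial_records)} trial records"
        )
    samples = np.asarray(recording.samples)
    lo = int(round(tmin_ms / 1000.0 * fs))
    hi = int(round(tmax_ms / 1000.0 * fs))
    bins: dict[str, list[np.ndarray]] = {
        "high_h1": [], "high_h2": [], "low_h1": [], "low_h2": []
    }
    n_skipped = 0
    records = trial_records.reset_index(drop=True)
    labs = labels.reset_index(drop=True)
    for (onset, _), (_, rec), (_, lab) in zip(
        stim_events, records.iterrows(), labs.iterrows()
    ):
        if rec["trial_class"] != "random" or not bool(rec["correct"]):
            continue
        if lab["probability"] not in ("high", "low"):
            continue
        start, stop = onset + lo, onset + hi
        if start < 0 or stop > samples.shape[1]:
            n_skipped += 1
            continue
        half = "h1" if rec["block"] <= half_size_blocks else "h2"
        bins[f"{lab['probability']}_{half}"].append(samples[:, start:stop])
    if n_skipped:
        logger.info("segment_task: skipped %d out-of-bounds epochs", n_skipped)
    out = {}
    for key, segs in bins.items():
        if not segs:
            logger.warning("segment_task: empty condition bin %s", key)
            continue
        out[key] = EEGEpochs(
            data=np.stack(segs),
            fs=fs,
            channel_labels=list(recording.channel_labels),
            condition=key,
            t0_ms=tmin_ms,
        )
    return out


def _taper_ffts(
    segment: np.ndarray, n_tapers: int, nw: float
) -> np.ndarray:
    """DPSS-tapered FFTs, shape (tapers, channels, freqs)."""
    n_t = segment.shape[-1]
    tapers = dpss(n_t, NW=nw, Kmax=n_tapers)
    return rfft(segment[None, :, :] * tapers[:, None, :], axis=-1)


def coherency(
    segment: np.ndarray,
    fs: float,
    n_tapers: int = 3,
    nw: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Complex coherency per frequency bin for one segment.

    Cross- and auto-spectra are averaged over the DPSS tapers within the
    single segment. Returns ``(freqs, C)`` with ``C`` of shape
    (n_freqs, n_channels, n_channels); ``|C| <= 1`` up to numerical
    tolerance. Zero-variance channels yield zero coherency with all
    partners (with a warning).
    """
    segment = np.asarray(segment, dtype=float)
    if not np.isfinite(segment).all():
        raise ValueError("segment contains non-finite samples")
    x = _taper_ffts(segment, n_tapers, nw)  # (k, ch, f)
    freqs = rfftfreq(segment.shape[-1], d=1.0 / fs)
    sxy = np.einsum("kif,kjf->fij", x, np.conj(x)) / n_tapers
    auto = np.einsum("fii->fi", sxy).real
    bad = auto.max(axis=0) <= 0
    if bad.any():
        warnings.warn(
            f"zero-variance channels {np.flatnonzero(bad).tolist()}: "
            "their coherency is set to 0",
            stacklevel=2,
        )
    denom = np.sqrt(auto[:, :, None] * auto[:, None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, sxy / np.where(denom > 0, denom, 1.0), 0.0)
    if bad.any():
        c[:, bad, :] = 0.0
        c[:, :, bad] = 0.0
    return freqs, c


def imaginary_coherency(
    segment: np.ndarray,
    fs: float,
    n_tapers: int = 3,
    nw: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin imaginary part of the coherency for one segment."""
    freqs, c = coherency(segment, fs, n_tapers=n_tapers, nw=nw)
    return freqs, c.imag


def band_average(
    freqs: np.ndarray,
    im_coherency: np.ndarray,
    band: BandDefinition,
    segment_id: int | None = None,
    node_labels: list[str] | None = None,
) -> CoherenceMatrix:
    """Mean over in-band bins of |Im C_xy(f)|, symmetric, zero diagonal."""
    mask = band.bins(np.asarray(freqs))
    if not mask.any():
        raise ValueError(
            f"band {band.name} contains no frequency bins at this resolution"
        )
    vals = np.abs(im_coherency[mask]).mean(axis=0)
    vals = 0.5 * (vals + vals.T)
    np.fill_diagonal(vals, 0.0)
    vals = np.clip(vals, 0.0, 1.0)
    return CoherenceMatrix(
        values=vals, band=band, segment_id=segment_id, node_labels=node_labels
    )


def band_coherence_per_segment(
    epochs: EEGEpochs,
    band: BandDefinition,
    n_tapers: int = 3,
    nw: float = 2.0,
) -> list[CoherenceMatrix]:
    """Per-segment band-averaged |Im coherency| matrices."""
    out = []
    for s in range(epochs.n_segments):
        freqs, im = imaginary_coherency(
            epochs.data[s], epochs.fs, n_tapers=n_tapers, nw=nw
        )
        out.append(
            band_average(
                freqs, im, band, segment_id=s, node_labels=epochs.channel_labels
            )
        )
    return out


def pooled_band_coherency(
    epochs: EEGEpochs,
    band: BandDefinition,
    n_tapers: int = 3,
    nw: float = 2.0,
) -> CoherenceMatrix:
    """Band |Im coherency| from cross-spectra pooled over segments.

    The cross- and auto-spectra are averaged over segments and tapers
    before normalization (the classic Welch-style coherence estimator);
    the result is the band mean of |Im C(f)| of the pooled coherency.
    Pooling suppresses the per-segment estimator noise and is the
    preferred estimator for planted-edge recovery, as opposed to the
    per-segment estimates that the percentile-thresholding pipeline
    requires.
    """
    n_t = epochs.data.shape[-1]
    freqs = rfftfreq(n_t, d=1.0 / epochs.fs)
    mask = band.bins(freqs)
    if not mask.any():
        raise ValueError(
            f"band {band.name} contains no frequency bins at this resolution"
        )
    sxy_sum = None
    for s in range(epochs.n_segments):
        x = _taper_ffts(epochs.data[s], n_tapers, nw)[:, :, mask]
        sxy = np.einsum("kif,kjf->fij", x, np.conj(x))
        sxy_sum = sxy if sxy_sum is None else sxy_sum + sxy
    auto = np.einsum("fii->fi", sxy_sum).real
    denom = np.sqrt(auto[:, :, None] * auto[:, None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, sxy_sum / np.where(denom > 0, denom, 1.0), 0.0)
    vals = np.abs(c.imag).mean(axis=0)
    vals = 0.5 * (vals + vals.T)
    np.fill_diagonal(vals, 0.0)
    vals = np.clip(vals, 0.0, 1.0)
    return CoherenceMatrix(values=vals, band=band, node_labels=epochs.channel_labels)
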