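"""Overall data quality (ODQ) scores for fMRI and EEG recordings.

Both metrics cut the recording into fixed-length segments, flag each segment
good or bad, and report ODQ = 100 x good / total.

fMRI: 20-TR segments; a segment is good iff (a) the region-median temporal
signal-to-noise ratio (segment mean / segment sd) exceeds a threshold
(default 50), (b) tSNR varies little across regions (coefficient of
variation below a ceiling), and (c) no sample deviates from the segment
median by more than ``spike_z`` robust standard deviations.

EEG: 1-second segments; a segment is good iff all four checks pass:
(1) no weak/constant channel (sd above a floor), (2) no amplitude-ratio
artifact (peak-to-peak over robust sd below a ceiling), (3) limited
high-frequency noise (power fraction above the cutoff frequency below a
limit), and (4) adequate inter-channel correlation (median absolute
correlation above a floor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hoi import RegionTimeSeries

__all__ = ["QualityReport", "fmri_odq", "eeg_odq"]

_MAD_TO_SD = 1.4826


@dataclass
class QualityReport:
    odq: float
    segments: pd.DataFrame
    segment_length: int
    thresholds: dict

    def __post_init__(self) -> None:
        if not 0.0 <= self.odq <= 100.0:
            raise ValueError("odq must lie in [0, 100]")


def _segment_views(values: np.ndarray, seg_len: int) -> np.ndarray:
    """(n_segments, n_channels, seg_len); trailing partial segment dropped."""
    n_ch, n_t = values.shape
    n_seg = n_t // seg_len
    if n_seg < 1:
        raise ValueError(f"recording shorter than one {seg_len}-sample segment")
    trimmed = values[:, : n_seg * seg_len]
    return trimmed.reshape(n_ch, n_seg, seg_len).transpose(1, 0, 2)


def fmri_odq(
    ts: RegionTimeSeries,
    tr: float | None = None,
    *,
    segment_trs: int = 20,
    tsnr_threshold: float = 50.0,
    cv_ceiling: float = 1.0,
    spike_z: float = 5.0,
) -> QualityReport:
    """Segment-wise tSNR quality score for an fMRI region x time matrix."""
    segs = _segment_views(ts.values, segment_trs)
    rows = []
    for k, seg in enumerate(segs):  # seg: (regions, seg_len)
        mean = seg.mean(axis=1)
        sd = seg.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tsnr = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.inf)
        tsnr_ok = bool(np.median(tsnr) > tsnr_threshold)

        finite = tsnr[np.isfinite(tsnr)]
        if finite.size == 0:
            cv = 0.0
        else:
            denom = abs(finite.mean())
            cv = float(finite.std() / denom) if denom > 0 else np.inf
        spatial_ok = bool(cv < cv_ceiling)

        med = np.median(seg, axis=1, keepdims=True)
        mad = np.median(np.abs(seg - med), axis=1, keepdims=True)
        robust_sd = _MAD_TO_SD * mad
        dev = np.abs(seg - med)
        spikes = np.where(
            robust_sd > 0, dev > spike_z * robust_sd, dev > 0
        )
        spike_ok = not bool(spikes.any())

        good = tsnr_ok and spatial_ok and spike_ok
        rows.append(
            {
                "segment": k,
                "tsnr_ok": tsnr_ok,
                "spatial_ok": spatial_ok,
                "spike_ok": spike_ok,
                "good": good,
                "median_tsnr": float(np.median(tsnr)),
            }
        )
    df = pd.DataFrame(rows)
    odq = 100.0 * df["good"].mean()
    return QualityReport(
        odq=float(odq),
        segments=df,
        segment_length=segment_trs,
        thresholds={
            "tsnr_threshold": tsnr_threshold,
            "cv_ceiling": cv_ceiling,
            "spike_z": spike_z,
        },
    )


def eeg_odq(
    ts: RegionTimeSeries,
    rate: float | None = None,
    *,
    sd_floor: float = 0.1,
    amp_ratio_ceiling: float = 12.0,
    hf_cutoff_hz: float = 40.0,
    hf_fraction_limit: float = 0.5,
    corr_floor: float = 0.1,
) -> QualityReport:
    """Four-check 1-second-segment quality score for an EEG channel x time matrix."""
    fs = rate if rate is not None else ts.sampling_rate
    if fs is None:
        raise ValueError("sampling rate required for EEG quality scoring")
    if fs <= 2.0 * hf_cutoff_hz:
        raise ValueError(
            f"sampling rate {fs} Hz cannot resolve content above {hf_cutoff_hz} Hz"
        )
    seg_len = int(round(fs))
    segs = _segment_views(ts.values, seg_len)
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / fs)
    hf_band = freqs > hf_cutoff_hz

    rows = []
    for k, seg in enumerate(segs):  # (channels, seg_len)
        sd = seg.std(axis=1, ddof=1)
        weak_ok = bool(np.all(sd >= sd_floor))

        med = np.median(seg, axis=1, keepdims=True)
        robust_sd = _MAD_TO_SD * np.median(np.abs(seg - med), axis=1)
        ptp = seg.max(axis=1) - seg.min(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(robust_sd > 0, ptp / np.where(robust_sd > 0, robust_sd, 1.0), np.inf)
        amp_ok = bool(np.all(ratio <= amp_ratio_ceiling))

        spec = np.abs(np.fft.rfft(seg - seg.mean(axis=1, keepdims=True), axis=1)) ** 2
        total = spec[:, 1:].sum(axis=1)  # exclude DC
        with np.errstate(invalid="ignore"):
            hf_frac = np.where(total > 0, spec[:, hf_band].sum(axis=1) / np.where(total > 0, total, 1.0), 0.0)
        hf_ok = bool(np.all(hf_frac <= hf_fraction_limit))

        if np.all(sd > 0) and seg.shape[0] >= 2:
            corr = np.corrcoef(seg)
            iu = np.triu_indices(seg.shape[0], k=1)
            corr_ok = bool(np.median(np.abs(corr[iu])) >= corr_floor)
        else:
            corr_ok = False

        good = weak_ok and amp_ok and hf_ok and corr_ok
        rows.append(
            {
                "segment": k,
                "weak_ok": weak_ok,
                "amp_ok": amp_ok,
                "hf_ok": hf_ok,
                "corr_ok": corr_ok,
                "good": good,
            }
        )
    df = pd.DataFrame(rows)
    odq = 100.0 * df["good"].mean()
    return QualityReport(
        odq=float(odq),
        segments=df,
        segment_length=seg_len,
        thresholds={
            "sd_floor": sd_floor,
            "amp_ratio_ceiling": amp_ratio_ceiling,
            "hf_cutoff_hz": hf_cutoff_hz,
            "hf_fraction_limit": hf_fraction_limit,
            "corr_floor": corr_floor,
        },
    )
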