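"""Global physiological noise removal and band-pass filtering.

Resting-state NIRS signals are dominated by systemic physiology (Mayer
waves, respiration, slow blood-pressure drifts) shared across the whole
probe array. Left in place, this global component inflates every pairwise
channel correlation. Removal is done in the wavelet domain: each channel is
decomposed with an undecimated (stationary) wavelet transform, and at every
scale the cross-channel mean coefficient series — the scale-wise estimate of
the global component — is regressed out of each channel's coefficients by
per-channel least squares before reconstruction. Operating scale-by-scale
lets channels carry different amounts of the global signal at different
frequencies.

The spontaneous-activity band (0.01-0.08 Hz) is then isolated with a
zero-phase two-pass Butterworth band-pass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy import signal as sps

from .errors import ConfigurationError, InputError
from .optics import HemoSeries


@dataclass
class DenoiseConfig:
    wavelet: str = "db4"
    level: int | None = None  # None: deepest scale covers >= 1/band_low seconds
    band: tuple[float, float] = (0.01, 0.08)
    filter_order: int = 3  # per pass; applied forward and backward
    remove_global: bool = True
    global_method: str = "mean"  # "mean" or "pca" (first principal component)

    def validate(self, sampling_rate: float) -> None:
        low, high = self.band
        nyq = sampling_rate / 2.0
        if not (0 < low < high):
            raise ConfigurationError(f"band must satisfy 0 < low < high, got {self.band}")
        if high >= nyq:
            raise ConfigurationError(
                f"band high cutoff {high} Hz >= Nyquist {nyq} Hz at fs={sampling_rate}"
            )
        if self.level is not None and self.level < 1:
            raise ConfigurationError("decomposition level must be >= 1")
        if self.filter_order < 1:
            raise ConfigurationError("filter_order must be >= 1")
        if self.global_method not in ("mean", "pca"):
            raise ConfigurationError(f"unknown global_method {self.global_method!r}")

    def resolved_level(self, sampling_rate: float) -> int:
        """Depth such that the coarsest detail band reaches below band low.

        Detail level j spans roughly fs/2^(j+1) .. fs/2^j Hz, so we need
        fs / 2^(level+1) <= band_low.
        """
        if self.level is not None:
            return self.level
        low = self.band[0]
        return max(1, int(np.ceil(np.log2(sampling_rate / low) - 1)))


def _global_estimate(coeff_matrix: np.ndarray, method: str) -> np.ndarray:
    """Cross-channel global component at one scale (coeff_matrix: channels x T)."""
    if method == "mean":
        return coeff_matrix.mean(axis=0)
    # first principal component, sign-aligned with the mean
    centered = coeff_matrix - coeff_matrix.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    g = vt[0]
    if np.dot(g, coeff_matrix.mean(axis=0)) < 0:
        g = -g
    return g


def _regress_out(rows: np.ndarray, g: np.ndarray) -> np.ndarray:
    gg = float(np.dot(g, g))
    if gg <= 0:
        return rows
    beta = rows @ g / gg
    return rows - np.outer(beta, g)


def remove_global_wavelet(series: HemoSeries, cfg: DenoiseConfig | None = None) -> HemoSeries:
    """Scale-wise regression of the cross-channel global component.

    After this operation, at every wavelet scale each channel's coefficient
    series has zero least-squares projection onto that scale's global
    estimate.
    """
    cfg = cfg or DenoiseConfig()
    series.validate()
    cfg.validate(series.sampling_rate)
    if series.n_channels < 2:
        raise InputError("global removal needs at least 2 channels")
    level = cfg.resolved_level(series.sampling_rate)
    block = 2 ** level
    T = series.n_samples
    pad_total = (-T) % block
    pad_left = pad_total // 2
    pad_right = pad_total - pad_left
    min_len = pywt.Wavelet(cfg.wavelet).dec_len
    if T + pad_total < max(block, min_len):
        raise InputError(f"series too short ({T} samples) for level-{level} decomposition")

    def process(data: np.ndarray) -> np.ndarray:
        padded = np.pad(data, ((0, 0), (pad_left, pad_right)), mode="reflect")
        # coeffs[s] is channels x T: approximation then details, coarse to fine
        coeffs = pywt.swt(padded, cfg.wavelet, level=level, trim_approx=True,
                          norm=True, axis=1)
        cleaned = []
        for mat in coeffs:
            g = _global_estimate(np.asarray(mat), cfg.global_method)
            cleaned.append(_regress_out(np.asarray(mat), g))
        out = pywt.iswt(cleaned, cfg.wavelet, norm=True)
        return out[:, pad_left : pad_left + T]

    return replace(series, hbo=process(series.hbo), hbr=process(series.hbr))


def _bandpass_sos(cfg: DenoiseConfig, sampling_rate: float):
    return sps.butter(
        cfg.filter_order, cfg.band, btype="bandpass", fs=sampling_rate, output="sos"
    )


def bandpass(series: HemoSeries, cfg: DenoiseConfig | None = None) -> HemoSeries:
    """Zero-phase band-pass to the spontaneous-activity band (default 0.01-0.08 Hz)."""
    cfg = cfg or DenoiseConfig()
    series.validate()
    cfg.validate(series.sampling_rate)
    sos = _bandpass_sos(cfg, series.sampling_rate)
    return replace(
        series,
        hbo=sps.sosfiltfilt(sos, series.hbo, axis=1),
        hbr=sps.sosfiltfilt(sos, series.hbr, axis=1),
    )


def bandpass_frequency_response(
    cfg: DenoiseConfig, sampling_rate: float, freqs: np.ndarray | None = None
):
    """Two-pass (zero-phase) magnitude response of the band-pass filter.

    Returns (freqs, magnitude); magnitude is |H(f)|^2 since the filter is
    applied forward and backward. Intended for QC export.
    """
    cfg.validate(sampling_rate)
    sos = _bandpass_sos(cfg, sampling_rate)
    if freqs is None:
        freqs = np.geomspace(1e-3, sampling_rate / 2 * 0.999, 512)
    w, h = sps.sosfreqz(sos, worN=freqs, fs=sampling_rate)
    return w, np.abs(h) ** 2
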