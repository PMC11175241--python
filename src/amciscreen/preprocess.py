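"""EEG preprocessing: per-channel zero-mean normalization and wavelet-
threshold artifact removal.

The artifact remover is a deliberately simple, tunable wavelet eliminator:
each channel is processed in sliding windows, decomposed with a db4 wavelet,
and detail coefficients whose magnitude exceeds a data-adaptive, β-scaled
threshold are zeroed before reconstruction ("elimination mode"). Thresholds
are estimated per channel and decomposition level from the coefficient
ensemble of the *whole* recording, so a rare large artifact cannot inflate
its own threshold, while clean bounded signals pass nearly unchanged.
Smaller β lowers every threshold and therefore removes more.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pywt

from .synthetic import EEGRecording


def zero_mean(recording: EEGRecording) -> EEGRecording:
    """Subtract each channel's mean (the per-electrode normalization step)."""
    if recording.signal.size == 0:
        raise ValueError("empty signal")
    sig = recording.signal - recording.signal.mean(axis=1, keepdims=True)
    return replace(recording, signal=sig)


def _window_starts(n: int, win: int, hop: int) -> np.ndarray:
    starts = np.arange(0, max(n - win, 0) + 1, hop)
    if starts.size == 0:
        starts = np.array([0])
    # cover the tail with one final (possibly overlapping) window
    if starts[-1] + win < n:
        starts = np.append(starts, n - win)
    return starts


def remove_artifacts(
    recording: EEGRecording,
    wavelet: str = "db4",
    beta: float = 0.1,
    mode: str = "elimination",
    window_sec: float = 1.0,
    overlap: float = 0.5,
    level: int = 5,
    quantile: float = 0.999,
    margin: float = 1.5,
) -> EEGRecording:
    """Remove large-amplitude transients by wavelet coefficient elimination.

    Per channel and decomposition level j, the threshold is
    ``θ_j = (β / 0.1) · margin · Q(|d_j|, quantile)`` over all windows'
    level-j detail coefficients; coefficients above θ_j are zeroed and the
    windows are recombined by Hann-weighted overlap-add. At the default
    β = 0.1 the thresholds sit above the coefficient range of clean bounded
    signals, so those pass nearly unchanged.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if mode != "elimination":
        raise ValueError(f"unsupported mode {mode!r}; only 'elimination' is implemented")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    try:
        wav = pywt.Wavelet(wavelet)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet {wavelet!r}") from exc

    n = recording.n_samples
    win = int(round(window_sec * recording.sampling_rate))
    win = min(win, n)
    if n < wav.dec_len:
        raise ValueError("signal shorter than the wavelet filter support")
    hop = max(1, int(round(win * (1 - overlap))))
    starts = _window_starts(n, win, hop)
    max_level = pywt.dwt_max_level(win, wav.dec_len)
    level = min(level, max_level) if max_level > 0 else 0

    taper = np.hanning(win) + 1e-12  # strictly positive so edge weights invert
    out = np.zeros_like(recording.signal)
    scale = beta / 0.1

    for c in range(recording.signal.shape[0]):
        x = recording.signal[c]
        coeff_sets = [pywt.wavedec(x[s:s + win], wav, level=level) for s in starts]
        # global per-band thresholds over the window ensemble
        thresholds = []
        for j in range(level + 1):  # approximation band + all detail bands
            pooled = np.abs(np.concatenate([cs[j] for cs in coeff_sets]))
            thresholds.append(scale * margin * np.quantile(pooled, quantile))
        acc = np.zeros(n)
        wsum = np.zeros(n)
        for s, cs in zip(starts, coeff_sets):
            cleaned = []
            for j in range(level + 1):
                d = cs[j].copy()
                d[np.abs(d) > thresholds[j]] = 0.0
                cleaned.append(d)
            rec = pywt.waverec(cleaned, wav)[:win]
            acc[s:s + win] += rec * taper
            wsum[s:s + win] += taper
        out[c] = acc / wsum
    return replace(recording, signal=out)
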