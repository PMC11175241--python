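"""Connectivity pathway of the SSVEP analysis.

For each (stimulation frequency f, band b) pair, phase coupling between
electrodes during the f-block is measured with the weighted phase lag index
(wPLI), a [0, 1] synchronization index that discounts zero-lag
(volume-conducted) coupling. Node-level integration is summarized by the
Onnela weighted clustering coefficient; lobe averages yield

* LCR(f, b) = LC_parietal / LC_occipital   (lobe connectivity ratio), and
* BCR(f, b1, b2) = LC_parietal(b1) / LC_parietal(b2), reported for the
  θ/β (TBR) and α/β (ABR) pairs.

:func:`extract_connectivity_features` emits the 24 LCR features
``<f>PS-POR-<band>`` (6 frequencies × 4 bands) and the 12 BCR features
``<f>PS-P-TBR`` / ``<f>PS-P-ABR``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .montage import (
    ALPHA,
    BANDS,
    BETA,
    Band,
    LobeSet,
    OCCIPITAL,
    PARIETAL,
    THETA,
    get_band,
)
from .synthetic import EEGRecording

#: weights below this are treated as absent when counting neighbors
DEGREE_EPS = 1e-12


@dataclass
class ConnectivityGraph:
    """Symmetric electrode × electrode wPLI weight matrix for one (f, band)."""

    weights: np.ndarray
    channel_labels: tuple[str, ...]
    f: float
    band: Band

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if w.shape[0] != len(self.channel_labels):
            raise ValueError("weights shape does not match channel labels")
        if not np.allclose(w, w.T, atol=1e-9):
            raise ValueError("weights must be symmetric")
        if np.any(np.abs(np.diag(w)) > 1e-12):
            raise ValueError("diagonal must be zero")
        if np.any(w < -1e-12) or np.any(w > 1 + 1e-9):
            raise ValueError("weights must lie in [0, 1]")
        self.weights = np.clip(w, 0.0, 1.0)

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ValueError(f"channel {label!r} not in graph") from None


def _wpli_spectrum(
    recording: EEGRecording,
    f: float,
    seg_sec: float = 1.0,
    overlap: float = 0.5,
    eps: float = 1e-15,
):
    """Per-frequency wPLI of the f-stimulation block.

    wPLI = |E[Im S_ij]| / E[|Im S_ij|] over Hann-tapered overlapping
    segments, where S_ij is the cross-spectrum X_i·conj(X_j). Returns
    ``(wpli, freqs)`` with ``wpli`` of shape (n_ch, n_ch, n_freqs);
    entries where the denominator vanishes (e.g. zero-lag coupling with no
    imaginary part) are 0. Segment sums are accumulated so memory stays
    O(n_ch² · n_freq) regardless of block length.
    """
    fs = recording.sampling_rate
    onset, offset = recording.schedule.block_for(f)
    sl = slice(int(round(onset * fs)), int(round(offset * fs)))
    block = recording.signal[:, sl]
    seg = int(round(seg_sec * fs))
    if block.shape[1] < seg:
        raise ValueError("stimulation block shorter than one analysis segment")
    hop = max(1, int(round(seg * (1 - overlap))))
    starts = np.arange(0, block.shape[1] - seg + 1, hop)
    taper = hann(seg)
    freqs = np.fft.rfftfreq(seg, d=1.0 / fs)
    n_ch = block.shape[0]
    num = np.zeros((n_ch, n_ch, len(freqs)))
    den = np.zeros_like(num)
    mag = np.zeros_like(num)
    for s in starts:
        spec = np.fft.rfft(block[:, s:s + seg] * taper, axis=-1)
        cross = spec[:, None] * np.conj(spec[None, :])
        num += cross.imag
        den += np.abs(cross.imag)
        mag += np.abs(cross)
    # an imaginary part that is pure float rounding of a real cross-spectrum
    # (zero-lag coupling) must not register as phase lag
    valid = den > np.maximum(eps, 1e-12 * mag)
    wpli = np.where(valid, np.abs(num) / np.maximum(den, eps), 0.0)
    return wpli, freqs


def wpli_graph(
    recording: EEGRecording,
    f: float,
    band: Band | str,
    seg_sec: float = 1.0,
    overlap: float = 0.5,
) -> ConnectivityGraph:
    """wPLI connectivity graph of the ``f``-stimulation block within ``band``.

    Cross-spectra are estimated over Hann-tapered segments (default 1 s,
    50% overlap), wPLI is computed per frequency bin and averaged over the
    bins inside the half-open band interval.
    """
    band = get_band(band)
    if band.high > recording.sampling_rate / 2.0:
        raise ValueError(f"band {band.name} exceeds Nyquist")
    wpli, freqs = _wpli_spectrum(recording, f, seg_sec, overlap)
    in_band = (freqs >= band.low) & (freqs < band.high)
    if not in_band.any():
        raise ValueError(f"no spectral bins inside band {band.name}")
    w = wpli[..., in_band].mean(axis=-1)
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0
    return ConnectivityGraph(w, recording.channel_labels, float(f), band)


def proportional_threshold(graph: ConnectivityGraph, keep: float) -> ConnectivityGraph:
    """Keep only the strongest ``keep`` fraction of off-diagonal weights.

    Optional sparsification giving the clustering coefficient a non-trivial
    notion of "neighboring electrodes"; wPLI graphs are otherwise complete.
    """
    if not 0 < keep <= 1:
        raise ValueError("keep must be in (0, 1]")
    w = graph.weights.copy()
    iu = np.triu_indices_from(w, k=1)
    vals = w[iu]
    k = max(1, int(round(keep * vals.size)))
    cutoff = np.sort(vals)[-k]
    w[w < cutoff] = 0.0
    np.fill_diagonal(w, 0.0)
    return ConnectivityGraph(w, graph.channel_labels, graph.f, graph.band)


def clustering_coefficient(
    graph: ConnectivityGraph,
    electrode: str,
    normalize: bool = False,
) -> float:
    """Onnela weighted clustering coefficient of one electrode.

    ``C(e) = Σ_{i≠j} (w_ei · w_ej · w_ij)^{1/3} / (deg(e)·(deg(e)−1))``
    over ordered neighbor pairs; ``deg(e)`` counts nonzero-weight neighbors.
    Defined as 0 when deg(e) < 2 (the no-triangle limit). With weights in
    [0, 1] the result lies in [0, 1]. ``normalize=True`` applies Onnela's
    scaling by the maximum weight first (off by default: wPLI is already
    bounded in [0, 1]).
    """
    w = graph.weights
    if w.shape[0] < 3:
        raise ValueError("clustering coefficient requires at least 3 nodes")
    if normalize and w.max() > 0:
        w = w / w.max()
    e = graph.channel_index(electrode)
    deg = int(np.count_nonzero(w[e] > DEGREE_EPS))
    if deg < 2:
        return 0.0
    cw = np.cbrt(w)
    v = cw[e]  # v[e] = 0, so i = e and j = e terms vanish
    total = float(v @ cw @ v)
    return total / (deg * (deg - 1))


def lobe_connectivity(graph: ConnectivityGraph, lobe: LobeSet, **kwargs) -> float:
    """LC: mean clustering coefficient over a lobe's electrodes."""
    return float(np.mean([clustering_coefficient(graph, e, **kwargs) for e in lobe]))


def lobe_connectivity_ratio(
    recording: EEGRecording,
    f: float,
    band: Band | str,
    **wpli_kwargs,
) -> float:
    """LCR(f, band) = LC_parietal / LC_occipital of the f-block wPLI graph."""
    graph = wpli_graph(recording, f, band, **wpli_kwargs)
    return lobe_connectivity_ratio_from_graph(graph)


def lobe_connectivity_ratio_from_graph(graph: ConnectivityGraph) -> float:
    num = lobe_connectivity(graph, PARIETAL)
    den = lobe_connectivity(graph, OCCIPITAL)
    if abs(den) < 1e-15:
        raise ZeroDivisionError("occipital lobe connectivity is zero; LCR undefined")
    return num / den


def band_connectivity_ratio(
    recording: EEGRecording,
    f: float,
    b1: Band | str,
    b2: Band | str = BETA,
    **wpli_kwargs,
) -> float:
    """BCR(f, b1, b2) = LC_parietal(b1) / LC_parietal(b2); b1 ∈ {θ, α}, b2 = β."""
    b1, b2 = get_band(b1), get_band(b2)
    if b1.name not in (THETA.name, ALPHA.name):
        raise ValueError("b1 must be the θ or α band")
    if b2.name != BETA.name:
        raise ValueError("b2 must be the β band")
    num = lobe_connectivity(wpli_graph(recording, f, b1, **wpli_kwargs), PARIETAL)
    den = lobe_connectivity(wpli_graph(recording, f, b2, **wpli_kwargs), PARIETAL)
    if abs(den) < 1e-15:
        raise ZeroDivisionError("parietal β connectivity is zero; BCR undefined")
    return num / den


def extract_connectivity_features(
    recording: EEGRecording,
    seg_sec: float = 1.0,
    overlap: float = 0.5,
) -> dict[str, float]:
    """All connectivity features of a recording.

    24 lobe connectivity ratios ``<f>PS-POR-<band>`` (6 frequencies × θαβγ)
    and 12 band connectivity ratios ``<f>PS-P-TBR`` / ``<f>PS-P-ABR``.
    Cross-spectra are computed once per stimulation block and reused across
    bands.
    """
    features: dict[str, float] = {}
    for f in recording.schedule.frequencies:
        wpli, freqs = _wpli_spectrum(recording, f, seg_sec, overlap)
        lc_parietal: dict[str, float] = {}
        for name, band in BANDS.items():
            in_band = (freqs >= band.low) & (freqs < band.high)
            w = wpli[..., in_band].mean(axis=-1)
            np.fill_diagonal(w, 0.0)
            graph = ConnectivityGraph((w + w.T) / 2.0, recording.channel_labels, float(f), band)
            features[f"{int(f)}PS-POR-{name}"] = lobe_connectivity_ratio_from_graph(graph)
            lc_parietal[name] = lobe_connectivity(graph, PARIETAL)
        beta_lc = lc_parietal[BETA.name]
        if abs(beta_lc) < 1e-15:
            raise ZeroDivisionError("parietal β connectivity is zero; BCR undefined")
        features[f"{int(f)}PS-P-TBR"] = lc_parietal[THETA.name] / beta_lc
        features[f"{int(f)}PS-P-ABR"] = lc_parietal[ALPHA.name] / beta_lc
    return features
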