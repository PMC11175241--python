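"""Harmonic power pathway of the SSVEP analysis.

Pipeline: a sliding-window multitaper time–frequency decomposition
(:func:`time_frequency`); the mean dB power of each harmonic ``f·n`` of a
stimulation frequency ``f`` over that frequency's block
(:func:`harmonic_power`); lobe averaging over the parietal and occipital
electrode sets (:func:`lobe_power`); and their ratio, the lobe power ratio
LPR = LP_parietal / LP_occipital on the dB scale
(:func:`lobe_power_ratio`). :func:`extract_power_features` names the
results ``<f>PS-POR-<n>H`` for every stimulation frequency and every
harmonic with ``f·n`` below 50 Hz.

Power calibration
-----------------
Window spectra are normalized so that a sinusoid of amplitude ``a`` whose
frequency lies on an analysis bin reads its mean-square power ``a²/2`` (µV²)
at that bin: with unit-energy tapers ``h_k``, the taper-averaged raw power
at the sinusoid bin is ``(a²/4)·C`` with ``C = mean_k |Σ_t h_k[t]|²``, so
dividing by ``C/2`` restores ``a²/2``. This makes downstream dB values — and
therefore dB *ratios* like the LPR — directly comparable with closed-form
sinusoid power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import dpss, hann

from .montage import LobeSet, OCCIPITAL, PARIETAL
from .synthetic import EEGRecording, StimulationSchedule

FREQ_MIN, FREQ_MAX = 1.0, 50.0  # analysis range, 1 Hz steps
DB_FLOOR = -120.0  # dB floor so zero power never yields -inf


@dataclass
class TimeFrequencyMap:
    """Channel × frequency × time power array (µV²) on a 1–50 Hz, 1 Hz grid."""

    power: np.ndarray
    frequencies: np.ndarray
    times: np.ndarray
    time_step: float
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        expected = np.arange(FREQ_MIN, FREQ_MAX + 1)
        if not np.array_equal(self.frequencies, expected):
            raise ValueError("frequency axis must be exactly 1..50 Hz in 1 Hz steps")

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ValueError(f"channel {label!r} not in map") from None

    def freq_index(self, freq: float) -> int:
        idx = int(round(freq - FREQ_MIN))
        if not 0 <= idx < len(self.frequencies) or abs(freq - self.frequencies[idx]) > 1e-9:
            raise ValueError(f"frequency {freq} Hz not on the 1..50 Hz grid")
        return idx


def _tapers(window_samples: int, taper: str, n_tapers: int, half_bandwidth_product: float):
    """Unit-energy analysis tapers and the sinusoid calibration constant C."""
    if taper == "dpss":
        h = dpss(window_samples, half_bandwidth_product, Kmax=n_tapers)
    elif taper == "hann":
        h = hann(window_samples)[np.newaxis, :]
    else:
        raise ValueError(f"unknown taper {taper!r}; use 'dpss' or 'hann'")
    h = h / np.sqrt(np.sum(h**2, axis=1, keepdims=True))
    c = float(np.mean(np.abs(h.sum(axis=1)) ** 2))
    return h, c


def time_frequency(
    recording: EEGRecording,
    window_sec: float = 0.5,
    step_sec: float = 0.1,
    taper: str = "dpss",
    n_tapers: int = 3,
    bandwidth_hz: float = 8.0,
) -> TimeFrequencyMap:
    """Sliding-window multitaper spectrogram over 1–50 Hz in 1 Hz steps.

    Defaults follow the analysis settings of the screening pipeline: 500 ms
    window, three DPSS tapers with 8 Hz (full-width) frequency smoothing. A
    single Hann taper is available via ``taper='hann'`` as the plain-FFT
    reading of the method. The FFT is zero-padded to the sampling rate so
    integer frequencies land exactly on bins.
    """
    fs = recording.sampling_rate
    win = int(round(window_sec * fs))
    hop = max(1, int(round(step_sec * fs)))
    n = recording.n_samples
    if n < win:
        raise ValueError("recording shorter than one analysis window")
    # half-bandwidth product NW = T * (bandwidth/2)
    nw = window_sec * bandwidth_hz / 2.0
    tapers, cal = _tapers(win, taper, n_tapers, nw)

    nfft = int(round(fs / 1.0))  # 1 Hz bin spacing
    if nfft < win:
        nfft = win
    freqs = np.arange(FREQ_MIN, FREQ_MAX + 1)
    bins = np.round(freqs * nfft / fs).astype(int)

    starts = np.arange(0, n - win + 1, hop)
    # (n_windows, win) view of every channel stacked: segment, taper, FFT
    idx = starts[:, None] + np.arange(win)[None, :]
    segs = recording.signal[:, idx]                       # (n_ch, n_win, win)
    tapered = segs[:, :, None, :] * tapers[None, None]    # (n_ch, n_win, K, win)
    spec = np.fft.rfft(tapered, n=nfft, axis=-1)[..., bins]
    power = (np.abs(spec) ** 2).mean(axis=2) * (2.0 / cal)  # (n_ch, n_win, n_freq)

    times = (starts + win / 2.0) / fs
    return TimeFrequencyMap(
        power=np.transpose(power, (0, 2, 1)),
        frequencies=freqs,
        times=times,
        time_step=hop / fs,
        channel_labels=recording.channel_labels,
    )


def to_db(power, floor_db: float = DB_FLOOR) -> np.ndarray:
    """10·log10(power) with a configurable floor replacing -inf."""
    floor_lin = 10.0 ** (floor_db / 10.0)
    return 10.0 * np.log10(np.maximum(np.asarray(power, dtype=float), floor_lin))


def harmonic_power(
    tf: TimeFrequencyMap,
    schedule: StimulationSchedule,
    electrode: str,
    f: float,
    n: int,
    edge_sec: float = 0.25,
    floor_db: float = DB_FLOOR,
) -> float:
    """Mean dB power of harmonic ``f·n`` over the ``f``-stimulation block.

    The first and last ``edge_sec`` of the block are excluded so half-window
    smearing from neighbouring rest periods does not dilute the estimate.
    """
    if f * n >= FREQ_MAX:
        raise ValueError(f"harmonic {f}·{n} = {f * n} Hz is outside the analysis range (< 50 Hz)")
    if n < 1:
        raise ValueError("harmonic number must be >= 1")
    onset, offset = schedule.block_for(f)  # raises if f not in schedule
    mask = (tf.times >= onset + edge_sec) & (tf.times <= offset - edge_sec)
    if not mask.any():
        raise ValueError("stimulation block shorter than the analysis window")
    p = tf.power[tf.channel_index(electrode), tf.freq_index(f * n), mask].mean()
    return float(to_db(p, floor_db))


@dataclass
class HarmonicPowerTable:
    """dB power per (electrode, stimulation frequency, harmonic)."""

    entries: dict[tuple[str, float, int], float]

    def __post_init__(self) -> None:
        for (e, f, n) in self.entries:
            if f * n >= FREQ_MAX:
                raise ValueError(f"entry ({e}, {f}, {n}) outside the harmonic domain f·n < 50")

    def __getitem__(self, key: tuple[str, float, int]) -> float:
        e, f, n = key
        try:
            return self.entries[(e, float(f), int(n))]
        except KeyError:
            raise KeyError(f"no harmonic power entry for electrode {e!r}, {f} Hz, n={n}") from None


def harmonics_for(f: float, fmax: float = FREQ_MAX) -> list[int]:
    """Valid harmonic numbers n ≥ 1 with f·n < fmax."""
    return list(range(1, int(np.ceil(fmax / f - 1e-9))))


def build_harmonic_power_table(
    tf: TimeFrequencyMap,
    schedule: StimulationSchedule,
    edge_sec: float = 0.25,
) -> HarmonicPowerTable:
    """Harmonic power for every electrode × schedule frequency × valid harmonic."""
    entries = {}
    for e in tf.channel_labels:
        for f in schedule.frequencies:
            for n in harmonics_for(f):
                entries[(e, float(f), n)] = harmonic_power(tf, schedule, e, f, n, edge_sec)
    return HarmonicPowerTable(entries)


def lobe_power(
    table: HarmonicPowerTable,
    lobe: LobeSet,
    f: float,
    n: int,
    average: str = "db",
) -> float:
    """Lobe power LP: mean of electrode harmonic powers over the lobe.

    Default averages the dB values directly (the dB conversion precedes
    channel averaging, which keeps lobe ratios near 0.7–1 meaningful);
    ``average='linear'`` averages linear power first and converts after.
    """
    values = np.array([table[(e, f, n)] for e in lobe])
    if average == "db":
        return float(values.mean())
    if average == "linear":
        return float(to_db(np.mean(10.0 ** (values / 10.0))))
    raise ValueError("average must be 'db' or 'linear'")


def lobe_power_ratio(
    table: HarmonicPowerTable,
    f: float,
    n: int,
    average: str = "db",
) -> float:
    """LPR = LP_parietal / LP_occipital on the dB scale (dorsal-stream response)."""
    num = lobe_power(table, PARIETAL, f, n, average)
    den = lobe_power(table, OCCIPITAL, f, n, average)
    if abs(den) < 1e-12:
        raise ZeroDivisionError("occipital lobe power is zero; LPR undefined")
    return num / den


def extract_power_features(
    recording: EEGRecording,
    taper: str = "dpss",
    edge_sec: float = 0.25,
    average: str = "db",
) -> dict[str, float]:
    """All lobe-power-ratio features ``<f>PS-POR-<n>H`` of a recording.

    Emits one feature per stimulation frequency and harmonic with f·n < 50
    (38 features for the full six-frequency schedule).
    """
    tf = time_frequency(recording, taper=taper)
    table = build_harmonic_power_table(tf, recording.schedule, edge_sec)
    features = {}
    for f in recording.schedule.frequencies:
        for n in harmonics_for(f):
            features[f"{int(f)}PS-POR-{n}H"] = lobe_power_ratio(table, f, n, average)
    return features
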