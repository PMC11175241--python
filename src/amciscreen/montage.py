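"""Electrode montage and frequency-band definitions shared across the pipeline.

The recording montage is the 19-channel international 10-20 layout used for
clinical EEG. Dorsal-stream features contrast two electrode lobes: the
occipital pair (primary visual cortex) and a six-electrode parietal set
(visuomotor integration). Connectivity features are computed within the four
classical EEG bands.
"""

from __future__ import annotations

from dataclasses import dataclass

#: 10-20 channel labels, in acquisition order.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4", "T3", "T4",
    "T5", "T6", "P3", "P4", "O1", "O2", "Fz", "Cz", "Pz",
)

#: Photic-stimulation frequencies of the screening paradigm (Hz).
STIM_FREQUENCIES: tuple[int, ...] = (3, 5, 10, 12, 15, 20)


@dataclass(frozen=True)
class LobeSet:
    """A named set of scalp electrodes treated as one lobe."""

    name: str
    electrodes: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = set(self.electrodes) - set(CHANNELS_1020)
        if unknown:
            raise ValueError(f"electrodes not in 10-20 montage: {sorted(unknown)}")

    def __iter__(self):
        return iter(self.electrodes)

    def __len__(self) -> int:
        return len(self.electrodes)


PARIETAL = LobeSet("parietal", ("P3", "P4", "C3", "C4", "Pz", "Cz"))
OCCIPITAL = LobeSet("occipital", ("O1", "O2"))

LOBES: dict[str, LobeSet] = {"parietal": PARIETAL, "occipital": OCCIPITAL}


@dataclass(frozen=True)
class Band:
    """Half-open EEG frequency band [low, high) in Hz.

    Half-open intervals make the band edges unambiguous: 8 Hz belongs to
    alpha only, 12 Hz to beta only.
    """

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("band requires low < high")

    def contains(self, freq: float) -> bool:
        return self.low <= freq < self.high

    def frequencies(self, step: float = 1.0):
        """Integer-step frequencies inside the band (used for bin averaging)."""
        import numpy as np

        return np.arange(self.low, self.high, step)


THETA = Band("θ", 4.0, 8.0)
ALPHA = Band("α", 8.0, 12.0)
BETA = Band("β", 12.0, 30.0)
GAMMA = Band("γ", 30.0, 50.0)

BANDS: dict[str, Band] = {"θ": THETA, "α": ALPHA, "β": BETA, "γ": GAMMA}
# ASCII aliases for keyboard-friendly lookup.
BAND_ALIASES: dict[str, Band] = {
    "theta": THETA, "alpha": ALPHA, "beta": BETA, "gamma": GAMMA, **BANDS,
}


def get_band(band: "Band | str") -> Band:
    """Resolve a band given either a :class:`Band` or a (Greek/ASCII) name."""
    if isinstance(band, Band):
        return band
    try:
        return BAND_ALIASES[band]
    except KeyError:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BAND_ALIASES)}") from None
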