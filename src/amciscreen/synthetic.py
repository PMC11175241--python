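"""Synthetic cohorts for the multimodal aMCI-screening pipeline.

The study data (clinical EEG under intermittent photic stimulation, plus
virtual-kiosk VR session logs) are private, so every downstream stage is
exercised on synthetic inputs generated here:

* :func:`make_ips_schedule` — the photic-stimulation paradigm: 10 s flash
  blocks at 3/5/10/12/15/20 Hz alternating with 10 s rest.
* :func:`simulate_eeg` — 19-channel 10-20 recordings containing steady-state
  visual evoked responses (sinusoids at each stimulation frequency and its
  harmonics, with separate occipital/parietal amplitudes) over pink + white
  background noise.
* :func:`simulate_vr_session` — timestamped gaze/hand/event logs of the
  six-step virtual-kiosk task, constructed so the behavioral feature
  extractor recovers requested target values.
* :func:`simulate_cohort` — subject × feature tables for both groups, with
  per-feature marginal families and a Gaussian copula imposing requested
  cross-modal correlations.

All generators are pure functions of their arguments including ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .montage import CHANNELS_1020, OCCIPITAL, PARIETAL, STIM_FREQUENCIES

DEFAULT_SAMPLING_RATE = 200.0  # Hz, clinical EEG system
KIOSK_STEPS = (1, 2, 3, 4, 5, 6)
#: Logging rate for synthetic VR streams (Hz). Generated features are
#: sums/ratios over the whole session and are insensitive to this rate.
DEFAULT_LOG_RATE = 50.0


# ---------------------------------------------------------------------------
# Stimulation schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulationSchedule:
    """Ordered photic-stimulation blocks with interleaved rest periods.

    ``blocks`` holds ``(frequency_hz, onset_s, offset_s)`` triples;
    ``rest_blocks`` holds ``(onset_s, offset_s)`` pairs.
    """

    blocks: tuple[tuple[float, float, float], ...]
    rest_blocks: tuple[tuple[float, float], ...]
    total_duration: float

    def __post_init__(self) -> None:
        prev_end = 0.0
        spans = sorted(
            [(on, off) for _, on, off in self.blocks] + list(self.rest_blocks)
        )
        for on, off in spans:
            if on < prev_end - 1e-9:
                raise ValueError("schedule blocks overlap")
            if off < on:
                raise ValueError("block offset precedes onset")
            prev_end = off
        covered = sum(off - on for _, on, off in self.blocks)
        covered += sum(off - on for on, off in self.rest_blocks)
        if not math.isclose(covered, self.total_duration, abs_tol=1e-6):
            raise ValueError("total_duration does not equal the sum of block durations")

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(f for f, _, _ in self.blocks)

    def block_for(self, frequency: float) -> tuple[float, float]:
        """Return ``(onset, offset)`` of the stimulation block at ``frequency``."""
        for f, on, off in self.blocks:
            if math.isclose(f, frequency):
                return on, off
        raise ValueError(f"no stimulation block at {frequency} Hz")


def make_ips_schedule(
    frequencies,
    stim_dur: float = 10.0,
    rest_dur: float = 10.0,
) -> StimulationSchedule:
    """Build an intermittent photic stimulation schedule.

    One stimulation block per frequency, in the given order, each followed by
    one rest block. The study paradigm ``([3, 5, 10, 12, 15, 20], 10, 10)``
    totals 120 s.
    """
    frequencies = list(frequencies)
    if not frequencies:
        raise ValueError("frequencies must be non-empty")
    if stim_dur < 0 or rest_dur < 0:
        raise ValueError("durations must be non-negative")
    blocks, rests = [], []
    t = 0.0
    for f in frequencies:
        blocks.append((float(f), t, t + stim_dur))
        t += stim_dur
        if rest_dur > 0:
            rests.append((t, t + rest_dur))
            t += rest_dur
    return StimulationSchedule(tuple(blocks), tuple(rests), t)


# ---------------------------------------------------------------------------
# EEG recording
# ---------------------------------------------------------------------------

@dataclass
class EEGRecording:
    """A channel × sample EEG signal (µV) with its stimulation schedule."""

    signal: np.ndarray
    channel_labels: tuple[str, ...]
    sampling_rate: float
    schedule: StimulationSchedule

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if set(self.channel_labels) != set(CHANNELS_1020):
            raise ValueError("channel_labels must be exactly the 19-channel 10-20 montage")
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channel_labels):
            raise ValueError("signal must be a (n_channels, n_samples) matrix")
        n_expected = int(round(self.schedule.total_duration * self.sampling_rate))
        if self.signal.shape[1] != n_expected:
            raise ValueError(
                f"sample count {self.signal.shape[1]} does not match schedule "
                f"duration ({n_expected} samples at {self.sampling_rate} Hz)"
            )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ValueError(f"channel {label!r} not in montage") from None

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class NoiseSpec:
    """Background EEG noise: pink (1/f) plus white Gaussian, in µV RMS.

    Defaults give a background of ~10 µV RMS, against which the default
    evoked amplitudes produce harmonic peaks clearly detectable in a 10 s
    block periodogram.
    """

    pink_sd: float = 10.0
    white_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.pink_sd < 0 or self.white_sd < 0:
            raise ValueError("noise SDs must be non-negative")


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0  # avoid division by zero at DC
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _expand_amplitude_targets(targets: dict) -> dict[str, dict[int, float]]:
    """Expand lobe names to channel labels in an amplitude mapping."""
    out: dict[str, dict[int, float]] = {}
    for target, harmonics in targets.items():
        if target == "occipital":
            chans = OCCIPITAL.electrodes
        elif target == "parietal":
            chans = PARIETAL.electrodes
        elif target in CHANNELS_1020:
            chans = (target,)
        else:
            raise ValueError(f"amplitude target {target!r} is neither a lobe nor a montage channel")
        for ch in chans:
            merged = out.setdefault(ch, {})
            for n, a in harmonics.items():
                merged[int(n)] = float(a)
    return out


def lobe_amplitudes(
    occipital: float,
    parietal: float,
    n_harmonics: int = 3,
    decay: float = 1.0,
) -> dict:
    """Convenience amplitude spec: first-harmonic lobe amplitudes with 1/n**decay rolloff."""
    return {
        "occipital": {n: occipital / n**decay for n in range(1, n_harmonics + 1)},
        "parietal": {n: parietal / n**decay for n in range(1, n_harmonics + 1)},
    }


def simulate_eeg(
    schedule: StimulationSchedule,
    amplitude_spec: dict,
    noise_spec: NoiseSpec | None = None,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    seed: int | None = 0,
) -> EEGRecording:
    """Simulate a 19-channel IPS recording with SSVEP responses.

    ``amplitude_spec`` maps stimulation frequency → {channel or lobe name →
    {harmonic n → amplitude µV}}. During each stimulation block the addressed
    channels carry sinusoids at ``f·n`` (random phase per channel/block) on
    top of background noise; rest blocks contain noise only.
    """
    if noise_spec is None:
        noise_spec = NoiseSpec(0.0, 0.0)
    nyquist = sampling_rate / 2.0
    n_samples = int(round(schedule.total_duration * sampling_rate))
    rng = np.random.default_rng(seed)
    signal = np.zeros((len(CHANNELS_1020), n_samples))
    t = np.arange(n_samples) / sampling_rate

    if noise_spec.pink_sd > 0 or noise_spec.white_sd > 0:
        for c in range(len(CHANNELS_1020)):
            if noise_spec.pink_sd > 0:
                signal[c] += noise_spec.pink_sd * _pink_noise(rng, n_samples)
            if noise_spec.white_sd > 0:
                signal[c] += noise_spec.white_sd * rng.standard_normal(n_samples)

    sched_freqs = set(schedule.frequencies)
    for f, targets in amplitude_spec.items():
        f = float(f)
        if f not in sched_freqs:
            raise ValueError(f"amplitude spec addresses {f} Hz, absent from schedule")
        per_channel = _expand_amplitude_targets(targets)
        onset, offset = schedule.block_for(f)
        sl = slice(int(round(onset * sampling_rate)), int(round(offset * sampling_rate)))
        for ch, harmonics in per_channel.items():
            idx = CHANNELS_1020.index(ch)
            for n, amp in harmonics.items():
                if f * n >= nyquist:
                    raise ValueError(f"harmonic {f}·{n} = {f * n} Hz is at/above Nyquist")
                phase = rng.uniform(0, 2 * np.pi)
                signal[idx, sl] += amp * np.sin(2 * np.pi * f * n * t[sl] + phase)

    return EEGRecording(signal, CHANNELS_1020, sampling_rate, schedule)


# ---------------------------------------------------------------------------
# Virtual-kiosk session logs
# ---------------------------------------------------------------------------

@dataclass
class VRSessionLog:
    """Raw streams of one virtual-kiosk session.

    ``gaze``: columns t, x, y, z, aoi (aoi ∈ {target, nontarget, none});
    ``hand``: columns t, x, y, z; ``events``: columns t, step, is_error,
    ending with the step-6 completion event.
    """

    gaze: pd.DataFrame
    hand: pd.DataFrame
    events: pd.DataFrame

    def __post_init__(self) -> None:
        for name, df in (("gaze", self.gaze), ("hand", self.hand), ("events", self.events)):
            if len(df) and not np.all(np.diff(df["t"].to_numpy()) > 0):
                raise ValueError(f"{name} timestamps must be strictly increasing")
        if len(self.events):
            steps = set(self.events["step"].astype(int))
            if not steps <= set(KIOSK_STEPS):
                raise ValueError("event step ids must be within the six kiosk steps")
            last = self.events.iloc[-1]
            if int(last["step"]) != 6 or bool(last["is_error"]):
                raise ValueError("session must end with the step-6 completion event")


@dataclass(frozen=True)
class SessionTargets:
    """Per-session behavioral targets the generated log should reproduce.

    ``hand_speed`` = hand_distance / time_to_completion is an identity of
    the extractor, so any two of {time, distance, speed} determine the
    third; supplying all three inconsistently is an error.
    """

    time_to_completion: float | None = None
    n_errors: int = 0
    scanpath_length: float = 25.0
    fixation_proportion: float = 55.0
    hand_distance: float | None = None
    hand_speed: float | None = None

    def resolve(self) -> tuple[float, float, float]:
        """Return consistent (time, hand_distance, hand_speed)."""
        t, d, v = self.time_to_completion, self.hand_distance, self.hand_speed
        given = sum(x is not None for x in (t, d, v))
        if given < 2 and t is None:
            raise ValueError("need time_to_completion, or hand_distance and hand_speed")
        if t is None:
            t = d / v
        elif d is None:
            d = (v if v is not None else 0.2) * t
        if v is None:
            v = d / t
        if t <= 0:
            raise ValueError("time_to_completion must be positive")
        if d < 0 or v < 0:
            raise ValueError("hand distance/speed must be non-negative")
        if abs(d - v * t) > 1e-6 * max(1.0, d):
            raise ValueError(
                f"infeasible targets: hand_distance {d} ≠ hand_speed·time {v * t:.6g}"
            )
        return float(t), float(d), float(v)


def _random_path(rng: np.random.Generator, n: int, total_length: float) -> np.ndarray:
    """3-D path of n points whose consecutive segment lengths sum to total_length."""
    if n < 2 or total_length <= 0:
        return np.zeros((max(n, 1), 3))
    steps = rng.standard_normal((n - 1, 3))
    norms = np.linalg.norm(steps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    steps = steps / norms * (total_length / (n - 1))
    return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])


def simulate_vr_session(
    targets: SessionTargets,
    seed: int | None = 0,
    log_rate: float = DEFAULT_LOG_RATE,
    menu_dwell_fraction: float = 0.85,
) -> VRSessionLog:
    """Generate a six-step kiosk session log matching the requested targets.

    Gaze and hand streams are random 3-D walks with the requested cumulative
    lengths; AOI labels are allocated so that the target/menu dwell ratio
    equals ``fixation_proportion``; error events are inserted at random
    interior times and the log closes with the step-6 completion event.
    """
    rng = np.random.default_rng(seed)
    total_t, hand_d, _ = targets.resolve()
    if not 0 <= targets.fixation_proportion <= 100:
        raise ValueError("fixation_proportion must be in [0, 100]")
    if targets.n_errors < 0:
        raise ValueError("n_errors must be non-negative")
    if targets.scanpath_length < 0:
        raise ValueError("scanpath_length must be non-negative")

    n = max(3, int(round(total_t * log_rate)) + 1)
    t = np.linspace(0.0, total_t, n)

    gaze_xyz = _random_path(rng, n, targets.scanpath_length)
    n_menu = int(round(menu_dwell_fraction * n))
    n_target = int(round(targets.fixation_proportion / 100.0 * n_menu))
    aoi = np.array(["none"] * n, dtype=object)
    menu_idx = rng.permutation(n)[:n_menu]
    aoi[menu_idx[:n_target]] = "target"
    aoi[menu_idx[n_target:]] = "nontarget"
    gaze = pd.DataFrame({"t": t, "x": gaze_xyz[:, 0], "y": gaze_xyz[:, 1],
                         "z": gaze_xyz[:, 2], "aoi": aoi})

    hand_xyz = _random_path(rng, n, hand_d)
    hand = pd.DataFrame({"t": t, "x": hand_xyz[:, 0], "y": hand_xyz[:, 1], "z": hand_xyz[:, 2]})

    # Step completions at equal spacing; error events at interior times.
    rows = []
    for k, step in enumerate(KIOSK_STEPS, start=1):
        rows.append((total_t * k / 6.0, step, False))
    if targets.n_errors:
        err_t = np.sort(rng.uniform(0.02 * total_t, 0.98 * total_t, targets.n_errors))
        for te in err_t:
            step = int(np.ceil(te / (total_t / 6.0)))
            rows.append((float(te), min(max(step, 1), 6), True))
    rows.sort(key=lambda r: r[0])
    # enforce strictly increasing timestamps after sorting
    ts = np.array([r[0] for r in rows])
    for i in range(1, len(ts)):
        if ts[i] <= ts[i - 1]:
            ts[i] = ts[i - 1] + 1e-6
    events = pd.DataFrame({"t": ts, "step": [r[1] for r in rows],
                           "is_error": [r[2] for r in rows]})
    # error times are capped below total_t, so the step-6 completion is last
    return VRSessionLog(gaze, hand, events)


# ---------------------------------------------------------------------------
# Cohort feature tables
# ---------------------------------------------------------------------------

GROUPS = ("HC", "aMCI")

#: Marginal families supported by the cohort sampler.
FAMILIES = ("gaussian", "lognormal", "truncnorm", "negbinom")


@dataclass(frozen=True)
class FeatureSpec:
    """One feature's marginal family and per-group location/scale.

    Families are moment-matched to (mean, sd): log-normal for strongly
    right-skewed magnitudes, negative binomial for overdispersed counts,
    zero-truncated Gaussian for roughly symmetric positive quantities.
    """

    name: str
    family: str
    mean: dict[str, float]
    sd: dict[str, float]
    lower: float = 0.0  # truncation bound for the truncnorm family

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        for g in GROUPS:
            if g not in self.mean or g not in self.sd:
                raise ValueError(f"feature {self.name}: missing parameters for group {g}")
            if self.sd[g] <= 0:
                raise ValueError(f"feature {self.name}: SD must be positive")

    def quantile(self, group: str, z: np.ndarray) -> np.ndarray:
        """Map standard-normal copula draws to the marginal for ``group``."""
        m, s = self.mean[group], self.sd[group]
        if self.family == "gaussian":
            return m + s * z
        if self.family == "lognormal":
            sigma2 = math.log(1.0 + (s / m) ** 2)
            mu = math.log(m) - sigma2 / 2.0
            return np.exp(mu + math.sqrt(sigma2) * z)
        if self.family == "truncnorm":
            a = (self.lower - m) / s
            return sps.truncnorm.ppf(sps.norm.cdf(z), a, np.inf, loc=m, scale=s)
        # negbinom: overdispersed count; Poisson fallback when var <= mean
        var = s * s
        u = sps.norm.cdf(z)
        if var <= m:
            return sps.poisson.ppf(u, m)
        r = m * m / (var - m)
        p = r / (r + m)
        return sps.nbinom.ppf(u, r, p)


@dataclass
class CohortSpec:
    """Specification of a two-group synthetic cohort.

    ``cross_modal_corr`` maps feature-name pairs to latent Gaussian-copula
    correlations (equal to the Pearson target for Gaussian marginals). The
    implied correlation matrix must complete to positive semi-definite.
    """

    n_per_group: int
    features: list[FeatureSpec]
    cross_modal_corr: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")
        for (a, b), rho in self.cross_modal_corr.items():
            if a not in names or b not in names:
                raise ValueError(f"correlation entry references unknown feature ({a}, {b})")
            if not -1.0 <= rho <= 1.0:
                raise ValueError("correlation entries must lie in [-1, 1]")

    def correlation_matrix(self) -> np.ndarray:
        names = [f.name for f in self.features]
        k = len(names)
        r = np.eye(k)
        for (a, b), rho in self.cross_modal_corr.items():
            i, j = names.index(a), names.index(b)
            r[i, j] = r[j, i] = rho
        return r


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a labeled subject × feature table from a cohort specification.

    Within each group, features are sampled through a Gaussian copula with
    the specified latent correlation matrix and mapped to their marginal
    families by inverse-CDF.
    """
    corr = spec.correlation_matrix()
    eigmin = np.linalg.eigvalsh(corr).min()
    if eigmin < -1e-10:
        raise ValueError(
            f"cross_modal_corr does not complete to a PSD matrix (min eigenvalue {eigmin:.3g})"
        )
    # symmetric square root tolerates the zero-eigenvalue boundary
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T

    rng = np.random.default_rng(spec.seed)
    frames = []
    sid = 0
    for group in GROUPS:
        z = rng.standard_normal((spec.n_per_group, len(spec.features))) @ root.T
        cols = {"subject_id": [f"S{sid + i:05d}" for i in range(spec.n_per_group)],
                "group": group}
        for j, fs in enumerate(spec.features):
            cols[fs.name] = fs.quantile(group, z[:, j])
        frames.append(pd.DataFrame(cols))
        sid += spec.n_per_group
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Study-calibrated cohort: the default conditions of the screening analysis
# ---------------------------------------------------------------------------

#: Printed group means/SDs of the six virtual-kiosk behavioral features.
BEHAVIORAL_CALIBRATION: dict[str, dict] = {
    "scanpath_length":      {"family": "lognormal", "HC": (30.59, 37.55), "aMCI": (52.60, 57.42)},
    "fixation_proportion":  {"family": "truncnorm", "HC": (56.31, 13.98), "aMCI": (45.76, 16.42)},
    "hand_distance":        {"family": "lognormal", "HC": (11.85, 6.78),  "aMCI": (15.95, 11.23)},
    "hand_speed":           {"family": "truncnorm", "HC": (0.23, 0.07),   "aMCI": (0.18, 0.06)},
    "time_to_completion":   {"family": "lognormal", "HC": (50.00, 54.94), "aMCI": (91.75, 84.38)},
    "n_errors":             {"family": "negbinom",  "HC": (1.75, 1.65),   "aMCI": (3.50, 2.90)},
}

#: Printed group means/SDs of the eight significant EEG-SSVEP features.
NEUROLOGICAL_CALIBRATION: dict[str, dict] = {
    "5PS-POR-2H":  {"family": "gaussian", "HC": (0.74, 0.08), "aMCI": (0.79, 0.05)},
    "12PS-POR-1H": {"family": "gaussian", "HC": (0.72, 0.06), "aMCI": (0.82, 0.09)},
    "15PS-POR-1H": {"family": "gaussian", "HC": (0.74, 0.07), "aMCI": (0.81, 0.07)},
    "3PS-POR-α":   {"family": "gaussian", "HC": (0.95, 0.05), "aMCI": (1.02, 0.05)},
    "5PS-POR-γ":   {"family": "gaussian", "HC": (0.99, 0.02), "aMCI": (1.01, 0.04)},
    "3PS-P-ABR":   {"family": "gaussian", "HC": (0.98, 0.08), "aMCI": (1.07, 0.14)},
    "10PS-P-ABR":  {"family": "gaussian", "HC": (1.04, 0.11), "aMCI": (1.13, 0.17)},
    "15PS-P-TBR":  {"family": "gaussian", "HC": (0.92, 0.11), "aMCI": (1.04, 0.11)},
}

#: Reported significant cross-modal Pearson correlations.
CROSS_MODAL_CORRELATIONS: dict[tuple[str, str], float] = {
    ("5PS-POR-2H", "time_to_completion"): 0.29,
    ("5PS-POR-2H", "n_errors"): 0.40,
    ("12PS-POR-1H", "fixation_proportion"): -0.35,
    ("12PS-POR-1H", "hand_speed"): -0.40,
    ("12PS-POR-1H", "time_to_completion"): 0.32,
    ("12PS-POR-1H", "n_errors"): 0.35,
}


def _specs_from_calibration(calib: dict[str, dict]) -> list[FeatureSpec]:
    specs = []
    for name, c in calib.items():
        specs.append(FeatureSpec(
            name=name, family=c["family"],
            mean={g: c[g][0] for g in GROUPS},
            sd={g: c[g][1] for g in GROUPS},
        ))
    return specs


def behavioral_feature_specs() -> list[FeatureSpec]:
    """The six kiosk features at their published group calibrations."""
    return _specs_from_calibration(BEHAVIORAL_CALIBRATION)


def neurological_feature_specs() -> list[FeatureSpec]:
    """The eight significant EEG-SSVEP features at their published calibrations."""
    return _specs_from_calibration(NEUROLOGICAL_CALIBRATION)


def study_cohort_spec(
    n_per_group: int = 24,
    seed: int | None = 0,
    with_correlations: bool = True,
) -> CohortSpec:
    """Cohort specification reproducing the study conditions: 24 + 24
    subjects, six behavioral + eight neurological features at their
    published group means/SDs, and the reported cross-modal correlations."""
    return CohortSpec(
        n_per_group=n_per_group,
        features=behavioral_feature_specs() + neurological_feature_specs(),
        cross_modal_corr=dict(CROSS_MODAL_CORRELATIONS) if with_correlations else {},
        seed=seed,
    )


def simulate_behavioral_sessions(
    group: str = "HC",
    n_sessions: int = 100,
    seed: int | None = 0,
    log_rate: float = DEFAULT_LOG_RATE,
):
    """Yield (targets, VRSessionLog) pairs drawn from a group's calibrated marginals.

    Per-session feature targets are sampled from the published marginal
    families; a raw session log is then constructed for each draw so the
    feature *extractor* — not the sampler — produces the cohort's values.
    Hand distance is derived as speed × time to keep each session internally
    consistent.
    """
    specs = {s.name: s for s in behavioral_feature_specs()}
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_sessions, len(specs)))
    draws = {name: spec.quantile(group, z[:, j])
             for j, (name, spec) in enumerate(specs.items())}
    session_seeds = rng.integers(2**31, size=n_sessions)
    for i in range(n_sessions):
        targets = SessionTargets(
            time_to_completion=max(float(draws["time_to_completion"][i]), 1.0),
            n_errors=int(draws["n_errors"][i]),
            scanpath_length=max(float(draws["scanpath_length"][i]), 0.0),
            fixation_proportion=min(max(float(draws["fixation_proportion"][i]), 0.0), 100.0),
            hand_speed=max(float(draws["hand_speed"][i]), 1e-3),
        )
        yield targets, simulate_vr_session(
            targets, seed=int(session_seeds[i]), log_rate=log_rate
        )
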