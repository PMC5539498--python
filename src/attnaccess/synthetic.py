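"""Synthetic cohort generator.

No public recordings exist for the protocol this package analyses, so a
generator produces streams with the statistical structure the analysis
assumes: five 14-trial sessions per subject, trials alternating between an
attention and a non-attention task half (30 s each at 1 Hz) with a
relaxation half in between, per-second attention following a clipped AR(1)
process whose latent mean switches from the previous attentional state to
the trial's class mean after an exponential latency, log-normal band
powers with class-dependent shifts, and Bernoulli contact losses.

Raw 512-sample epochs (clean / blink / EMG / motion) are generated
separately for the artifact-screening stage.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .artifacts import RawEpoch
from .core import (
    ATTENTION,
    NON_ATTENTION,
    REST,
    Session,
    Trial,
    default_band_names,
)

EPOCH_KINDS = ("clean", "blink", "emg", "motion")

#: Contact-loss value reported by the sensor when the signal is unusable.
POOR_SIGNAL_BAD = 200


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one synthetic subject.

    mu_att / mu_non
        Class means of the attention indicator (percent).  A "null"
        subject has ``mu_att == mu_non``.
    sigma_within
        Marginal per-second standard deviation of the attention process.
    ar_coeff
        Lag-1 autocorrelation of the AR(1) deviations, in [0, 1).
    tau_on / tau_off
        Mean exponential switching latency (s) after the onset of an
        attention / non-attention trial.
    band_shift
        Per-band additive shift of the log band power in attention trials
        relative to non-attention trials (None -> no class effect).
    artifact_rates
        Per-epoch probabilities of blink / EMG / motion contamination
        (used when raw epochs accompany the stream).
    poor_signal_rate
        Probability that a second is flagged as bad contact.
    """

    subject_id: str
    mu_att: float = 70.0
    mu_non: float = 30.0
    sigma_within: float = 12.0
    ar_coeff: float = 0.6
    tau_on: float = 2.5
    tau_off: float = 2.5
    band_shift: tuple[float, ...] | None = None
    artifact_rates: Mapping[str, float] = field(
        default_factory=lambda: {"blink": 0.05, "emg": 0.05, "motion": 0.02}
    )
    poor_signal_rate: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu_non <= self.mu_att <= 100.0):
            raise ValueError("require 0 <= mu_non <= mu_att <= 100")
        if self.sigma_within < 0:
            raise ValueError("sigma_within must be >= 0")
        if not (0.0 <= self.ar_coeff < 1.0):
            raise ValueError("ar_coeff must be in [0, 1)")
        if self.tau_on < 0 or self.tau_off < 0:
            raise ValueError("switching latencies must be >= 0")
        if not (0.0 <= self.poor_signal_rate <= 1.0):
            raise ValueError("poor_signal_rate must be a probability")
        for kind, p in self.artifact_rates.items():
            if kind not in EPOCH_KINDS[1:]:
                raise ValueError(f"unknown artifact kind {kind!r}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"artifact rate for {kind!r} not in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Protocol-level simulation settings (defaults match the study design)."""

    n_sessions: int = 5
    trials_per_session: int = 14
    trial_task_seconds: int = 30
    rest_seconds: int = 30
    sample_rate_raw: int = 512
    n_bands: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_sessions",
            "trials_per_session",
            "trial_task_seconds",
            "rest_seconds",
            "sample_rate_raw",
            "n_bands",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.trials_per_session % 2 != 0:
            raise ValueError("trials_per_session must be even (alternating trial types)")

    @property
    def band_names(self) -> tuple[str, ...]:
        return default_band_names(self.n_bands)


# Baseline log band power decreases with band index (1/f-like spectrum,
# sensor units are large unscaled integrals).
def _band_base_log(n_bands: int) -> np.ndarray:
    return np.log(60000.0) - 0.45 * np.arange(n_bands)


_BAND_LOG_SD = 0.35
_MEDITATION_MEAN = 50.0
_MEDITATION_SD = 15.0


def _ar1_block(
    rng: np.random.Generator,
    means: np.ndarray,
    sigma: float,
    ar: float,
    start_dev: float,
) -> tuple[np.ndarray, float]:
    """Clipped AR(1) around a time-varying mean; returns values and final dev."""
    n = means.shape[0]
    innov_sd = sigma * np.sqrt(1.0 - ar * ar)
    innov = rng.normal(0.0, 1.0, size=n) * innov_sd
    out = np.empty(n)
    dev = start_dev
    for t in range(n):
        dev = ar * dev + innov[t]
        out[t] = means[t] + dev
        clipped = min(max(out[t], 0.0), 100.0)
        # clip (not reflect); the clipped value is the carried state
        dev += clipped - out[t]
        out[t] = clipped
    return out, dev


def _half_block(
    rng: np.random.Generator,
    profile: SubjectProfile,
    config: SimConfig,
    *,
    subject_id: str,
    session_index: int,
    trial_index: int,
    trial_type: str,
    start_dev: float,
) -> tuple[Trial, float]:
    """Generate one 30 s half (task or rest) of the stream."""
    if trial_type == ATTENTION:
        n = config.trial_task_seconds
        mu_target, mu_prev, tau = profile.mu_att, profile.mu_non, profile.tau_on
        shifted = True
    elif trial_type == NON_ATTENTION:
        n = config.trial_task_seconds
        mu_target, mu_prev, tau = profile.mu_non, profile.mu_att, profile.tau_off
        shifted = False
    else:  # rest
        n = config.rest_seconds
        mu_target = mu_prev = 0.5 * (profile.mu_att + profile.mu_non)
        tau, shifted = 0.0, False

    latency = rng.exponential(tau) if tau > 0 else 0.0
    # sample t covers [t, t+1); the latent mean switches once the midpoint
    # t + 0.5 passes the latency, which keeps the recovered first-crossing
    # time ~ tau + 1 (near-unbiased discretization)
    midpoints = np.arange(n) + 0.5
    means = np.where(midpoints >= latency, mu_target, mu_prev)
    attention, dev = _ar1_block(
        rng, means, profile.sigma_within, profile.ar_coeff, start_dev
    )

    base = _band_base_log(config.n_bands)
    shift = np.zeros(config.n_bands)
    if shifted and profile.band_shift is not None:
        bs = np.asarray(profile.band_shift, dtype=float)
        if bs.shape[0] != config.n_bands:
            raise ValueError(
                f"band_shift length {bs.shape[0]} != n_bands {config.n_bands}"
            )
        shift = bs
    log_bands = rng.normal(
        base + shift, _BAND_LOG_SD, size=(n, config.n_bands)
    )
    bands = np.exp(log_bands)

    meditation = np.clip(
        rng.normal(_MEDITATION_MEAN, _MEDITATION_SD, size=n), 0.0, 100.0
    )
    poor = np.where(rng.random(n) < profile.poor_signal_rate, POOR_SIGNAL_BAD, 0)
    trial = Trial(
        subject_id=subject_id,
        session_index=session_index,
        trial_index=trial_index,
        trial_type=trial_type,
        attention=attention,
        meditation=meditation,
        bands=bands,
        poor_signal=poor,
        valid=poor == 0,
        band_names=config.band_names,
    )
    return trial, dev


def generate_session(
    profile: SubjectProfile,
    config: SimConfig,
    session_index: int,
    seed: int,
) -> Session:
    """Generate one session: alternating task halves with interleaved rests.

    Odd trials (1-based) are attention, even trials non-attention.  The
    output is a deterministic function of ``(profile, config,
    session_index, seed)``.
    """
    if not (1 <= session_index <= config.n_sessions):
        raise ValueError(
            f"session_index must be in [1, n_sessions={config.n_sessions}]"
        )
    rng = np.random.default_rng([int(seed), int(session_index)])
    trials: list[Trial] = []
    rests: list[Trial] = []
    dev = rng.normal(0.0, profile.sigma_within) if profile.sigma_within > 0 else 0.0
    for k in range(config.trials_per_session):
        trial_type = ATTENTION if k % 2 == 0 else NON_ATTENTION
        trial, dev = _half_block(
            rng,
            profile,
            config,
            subject_id=profile.subject_id,
            session_index=session_index,
            trial_index=k + 1,
            trial_type=trial_type,
            start_dev=dev,
        )
        trials.append(trial)
        rest, dev = _half_block(
            rng,
            profile,
            config,
            subject_id=profile.subject_id,
            session_index=session_index,
            trial_index=k + 1,
            trial_type=REST,
            start_dev=dev,
        )
        rests.append(rest)
    return Session(
        subject_id=profile.subject_id,
        session_index=session_index,
        trials=trials,
        rest=rests,
    )


def generate_cohort(
    profiles: Sequence[SubjectProfile], config: SimConfig
) -> dict[str, list[Session]]:
    """Full protocol for every profile, seeded from ``config.seed``.

    Per-subject seeds are derived deterministically from the config seed
    and the subject id, so the same config regenerates the same cohort.
    """
    if not profiles:
        raise ValueError("at least one profile is required")
    ids = [p.subject_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate subject_id in profiles: {ids}")
    cohort: dict[str, list[Session]] = {}
    for profile in profiles:
        subj_seed = subject_seed(config.seed, profile.subject_id)
        cohort[profile.subject_id] = [
            generate_session(profile, config, s, subj_seed)
            for s in range(1, config.n_sessions + 1)
        ]
    return cohort


def subject_seed(base_seed: int, subject_id: str) -> int:
    """Stable sub-seed (< 2**31) for one subject."""
    crc = zlib.crc32(subject_id.encode("utf-8"))
    return (int(base_seed) * 1_000_003 + crc) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Raw 512-sample epochs for the artifact screen
# ---------------------------------------------------------------------------

_CLEAN_SD = 30.0  # ADC counts; EEG-scale background
_ADC_MAX = 2047


def _clean_wave(rng: np.random.Generator, n: int, fs: int) -> np.ndarray:
    """Band-limited 1/f-like background noise (float, sd ~ _CLEAN_SD)."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    passband = (freqs >= 0.5) & (freqs <= 45.0)
    amp[passband] = 1.0 / np.sqrt(freqs[passband])
    shaped = np.fft.irfft(spec * amp, n)
    sd = shaped.std()
    if sd > 0:
        shaped *= _CLEAN_SD / sd
    return shaped


def generate_raw_epoch(
    kind: str,
    config: SimConfig,
    seed: int,
    amplitude_scale: float = 1.0,
    start_second: int = 0,
) -> RawEpoch:
    """One 512-sample integer epoch of the requested kind.

    ``clean`` is band-limited background noise; ``blink`` adds one large
    smooth biphasic deflection (raises the peak-to-peak range, leaves the
    high-frequency residual low); ``emg`` adds a broadband high-frequency
    burst (raises the residual energy); ``motion`` adds a large slow swing
    plus broadband noise (raises both).  The clean base is shared between
    kinds at the same seed, so artifact-vs-clean comparisons are paired.
    """
    if kind not in EPOCH_KINDS:
        raise ValueError(f"unknown epoch kind {kind!r}; expected one of {EPOCH_KINDS}")
    n = config.sample_rate_raw  # 1 s of raw signal
    fs = config.sample_rate_raw
    base_rng = np.random.default_rng([int(seed), 11])
    art_rng = np.random.default_rng([int(seed), 13])
    wave = _clean_wave(base_rng, n, fs)

    if kind == "blink":
        width = int(art_rng.uniform(0.3, 0.5) * fs)
        start = art_rng.integers(0, n - width + 1)
        amp = art_rng.uniform(350.0, 650.0)
        # one full sine period: up-then-down biphasic deflection at ~2-3 Hz
        wave[start : start + width] += amp * np.sin(
            2.0 * np.pi * np.arange(width) / width
        )
    elif kind == "emg":
        width = int(art_rng.uniform(0.15, 0.35) * fs)
        start = art_rng.integers(0, n - width + 1)
        burst = art_rng.normal(size=width)
        spec = np.fft.rfft(burst)
        freqs = np.fft.rfftfreq(width, d=1.0 / fs)
        spec[(freqs < 60.0) | (freqs > 220.0)] = 0.0
        burst = np.fft.irfft(spec, width)
        sd = burst.std()
        if sd > 0:
            burst *= 80.0 / sd
        taper = np.hanning(width)
        wave[start : start + width] += burst * taper
    elif kind == "motion":
        phase = art_rng.uniform(0.0, np.pi)
        amp = art_rng.uniform(600.0, 1000.0)
        wave += amp * np.sin(np.pi * np.arange(n) / n + phase)
        broadband = art_rng.normal(0.0, 90.0, size=n)
        wave += broadband

    wave *= amplitude_scale
    samples = np.clip(np.rint(wave), -_ADC_MAX - 1, _ADC_MAX).astype(int)
    return RawEpoch(samples=samples, start_second=start_second)


def generate_labeled_epochs(
    config: SimConfig,
    seed: int,
    n_per_kind: int,
    kinds: Sequence[str] = EPOCH_KINDS,
) -> list[tuple[RawEpoch, str]]:
    """A labelled epoch set (``n_per_kind`` of each kind) for calibration."""
    out = []
    for j, kind in enumerate(kinds):
        for i in range(n_per_kind):
            out.append(
                (generate_raw_epoch(kind, config, seed * 100_003 + j * 10_007 + i), kind)
            )
    return out


def session_epochs(
    profile: SubjectProfile,
    config: SimConfig,
    session: Session,
    seed: int,
) -> tuple[list[RawEpoch], list[str]]:
    """One raw epoch per task second of a session, with artifacts injected
    at the profile's per-epoch rates.  Returns the epochs (stream order)
    and their ground-truth kinds."""
    rng = np.random.default_rng([int(seed), 17, int(session.session_index)])
    kinds_order = ("blink", "emg", "motion")
    probs = np.array([profile.artifact_rates.get(k, 0.0) for k in kinds_order])
    epochs: list[RawEpoch] = []
    truth: list[str] = []
    second = 0
    for trial in session.trials:
        for _ in range(trial.n_seconds):
            u = rng.random()
            kind = "clean"
            acc = 0.0
            for k, p in zip(kinds_order, probs):
                acc += p
                if u < acc:
                    kind = k
                    break
            epoch_seed = int(rng.integers(0, 2**31 - 1))
            epochs.append(
                generate_raw_epoch(kind, config, epoch_seed, start_second=second)
            )
            truth.append(kind)
            second += 1
    return epochs, truth


# ---------------------------------------------------------------------------
# Demo profiles: a small cohort spanning the behaviours seen in practice
# ---------------------------------------------------------------------------

def demo_band_shift(n_bands: int = 8) -> tuple[float, ...]:
    """Class effect pattern typical of attentive states on a frontal lead:
    delta and theta power drop, beta rises (so theta/beta drops) and gamma
    rises during attention."""
    names = default_band_names(n_bands)
    shift = []
    for name in names:
        if "delta" in name:
            shift.append(-0.35)
        elif "theta" in name:
            shift.append(-0.30)
        elif "beta" in name:
            shift.append(+0.20)
        elif "gamma" in name:
            shift.append(+0.30)
        else:  # alpha: direction varies between people; leave neutral
            shift.append(0.0)
    return tuple(shift)


def demo_profiles(n_bands: int = 8) -> list[SubjectProfile]:
    """Three synthetic subjects: strong, moderate and weak control."""
    return [
        SubjectProfile(
            "S1",
            mu_att=78.0,
            mu_non=22.0,
            sigma_within=10.0,
            ar_coeff=0.55,
            tau_on=2.0,
            tau_off=1.8,
            band_shift=demo_band_shift(n_bands),
        ),
        SubjectProfile(
            "S2",
            mu_att=65.0,
            mu_non=35.0,
            sigma_within=14.0,
            ar_coeff=0.65,
            tau_on=3.0,
            tau_off=2.5,
            band_shift=demo_band_shift(n_bands),
        ),
        SubjectProfile(
            "S3",
            mu_att=57.0,
            mu_non=45.0,
            sigma_within=16.0,
            ar_coeff=0.7,
            tau_on=4.0,
            tau_off=3.5,
            band_shift=tuple(0.5 * s for s in demo_band_shift(n_bands)),
        ),
    ]
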