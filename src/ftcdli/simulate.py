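"""Synthetic fTCD recordings with known ground-truth lateralisation.

The generator reproduces the structure the pipeline is sensitive to: a
pulsatile bilateral blood-flow-velocity signal (fundamental plus two
harmonics at the heart rate), a smooth task-locked response bump shared
by both channels, a small left-excess component that produces a chosen
laterality index, white measurement noise, and optional spike/dropout
artifacts.  Trials follow the 38-s structure of the animation-
description task: 12 s silent watching, a 10-s description period, 16 s
rest; triggers mark each trial onset.

The left-excess amplitude is solved in closed form so that the expected
pipeline LI equals ``true_li`` exactly in the noise-free limit: with
bump shape ``b(t)`` (epoch mean ``b_bar``, 2-s window mean ``W``) and
bilateral response fraction ``R``, normalisation and baseline correction
give a corrected difference of ``100*alpha*b(t) / (M_L*M_R)`` where
``M_R = 1 + R*b_bar`` and ``M_L = M_R + alpha*b_bar``; setting the window
mean equal to ``true_li`` and solving for ``alpha`` yields
``alpha = L*c^2 / (100*W - L*c*b_bar)`` with ``c = M_R``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .preprocess import Recording
from .stats import GroupSummary

__all__ = [
    "SimParams",
    "CohortSpec",
    "TRIAL_LENGTH_S",
    "simulate_recording",
    "inject_artifacts",
    "simulate_cohort",
    "sample_group_values",
]

WATCH_S = 12.0
DESCRIBE_S = 10.0
REST_S = 16.0
TRIAL_LENGTH_S = WATCH_S + DESCRIBE_S + REST_S  # 38 s
RESPONSE_ONSET_S = 4.0      # start of the evoked-response support, = POI start
LEAD_IN_S = 14.0            # pre-task recording, covers the -12 s epoch edge
EPOCH = (-12.0, 26.0)
PULSE_HARMONICS = (1.0, 0.4, 0.15)  # relative amplitudes, systolic-like profile
DROPOUT_LEVEL = 0.3         # dropout runs forced to this fraction of channel mean
MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class SimParams:
    """Ground-truth parameters of one synthetic subject.

    ``true_li`` is the target pipeline LI in percentage points;
    ``bilateral_response_amplitude`` is the shared evoked response in % of
    baseline; ``noise_sd`` is white noise in % of baseline velocity;
    artifact rates are events per minute.
    """

    sampling_rate: float = 100.0
    n_trials: int = 20
    heart_rate: float = 90.0
    pulsatility_amplitude: float = 0.25
    baseline_velocity_left: float = 62.0
    baseline_velocity_right: float = 58.0
    bilateral_response_amplitude: float = 3.0
    true_li: float = 2.0
    trial_li_sd: float = 2.5
    response_peak_latency: float = 11.0
    response_width: float = 14.0
    noise_sd: float = 0.5
    spike_rate: float = 0.0
    spike_magnitude: float = 2.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not 1 <= self.n_trials <= 30:
            raise ValueError(f"n_trials must be in [1, 30], got {self.n_trials}")
        if not 40 <= self.heart_rate <= 200:
            raise ValueError(f"heart_rate must be in [40, 200], got {self.heart_rate}")
        if not 0 <= self.pulsatility_amplitude < 1:
            raise ValueError(
                f"pulsatility_amplitude must be in [0, 1), got "
                f"{self.pulsatility_amplitude}"
            )
        for name in ("baseline_velocity_left", "baseline_velocity_right"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.response_width <= 0:
            raise ValueError(f"response_width must be > 0, got {self.response_width}")
        lo = RESPONSE_ONSET_S
        hi = RESPONSE_ONSET_S + self.response_width
        if not lo < self.response_peak_latency < hi:
            raise ValueError(
                f"response_peak_latency must lie strictly inside "
                f"({lo}, {hi}) s, got {self.response_peak_latency}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.trial_li_sd < 0:
            raise ValueError(f"trial_li_sd must be >= 0, got {self.trial_li_sd}")
        for name in ("spike_rate", "dropout_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class CohortSpec:
    """A simulated group: per-subject true LIs drawn from Normal(li_mean, li_sd)."""

    n_subjects: int
    li_mean: float
    li_sd: float
    base_params: SimParams = field(default_factory=SimParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.li_sd < 0:
            raise ValueError(f"li_sd must be >= 0, got {self.li_sd}")


def _bump(t: np.ndarray, peak: float, width: float) -> np.ndarray:
    """Piecewise raised-cosine bump on [RESPONSE_ONSET_S, onset + width], peak 1."""
    lo = RESPONSE_ONSET_S
    hi = lo + width
    out = np.zeros_like(t)
    rise = (t >= lo) & (t <= peak)
    fall = (t > peak) & (t <= hi)
    out[rise] = 0.5 * (1.0 - np.cos(np.pi * (t[rise] - lo) / (peak - lo)))
    out[fall] = 0.5 * (1.0 + np.cos(np.pi * (t[fall] - peak) / (hi - peak)))
    return out


def _left_excess_amplitude(params: SimParams, target_li) -> np.ndarray:
    """Solve for the left-excess scale giving a noise-free pipeline LI = target.

    Vectorised over per-trial targets.
    """
    fs = params.sampling_rate
    n_pre = int(round(-EPOCH[0] * fs))
    n_total = int(round((EPOCH[1] - EPOCH[0]) * fs))
    rel = (np.arange(n_total) - n_pre) / fs
    b_ep = np.where(rel >= 0, _bump(rel, params.response_peak_latency,
                                    params.response_width), 0.0)
    b_bar = float(b_ep.mean())
    peak_idx = int(np.argmax(b_ep))
    tp = rel[peak_idx]
    win = (rel >= tp - 1.0) & (rel < tp + 1.0)
    w_mean = float(b_ep[win].mean())
    r_frac = params.bilateral_response_amplitude / 100.0
    c = 1.0 + r_frac * b_bar
    li = np.asarray(target_li, dtype=float)
    return li * c * c / (100.0 * w_mean - li * c * b_bar)


def simulate_recording(params: SimParams, subject_id: str = "sim") -> Recording:
    """Generate one synthetic recording of ``params.n_trials`` consecutive trials.

    Each channel is ``baseline x (1 + pulsatility) x (1 + response) + noise``;
    the response is a raised-cosine bump locked to trial onset, identical
    across channels except for the calibrated left-excess component.  The
    per-trial target LI is ``true_li`` plus Normal(0, trial_li_sd) jitter,
    emulating the trial-to-trial variability of lateralisation that real
    per-trial LIs show (within-subject SD of a few percentage points).
    Identical parameters (including seed) give bit-identical output.
    """
    fs = params.sampling_rate
    total_s = LEAD_IN_S + params.n_trials * TRIAL_LENGTH_S
    n = int(round(total_s * fs))
    time = np.arange(n) / fs
    triggers = LEAD_IN_S + TRIAL_LENGTH_S * np.arange(params.n_trials)

    tt = time - LEAD_IN_S
    phase = np.mod(tt, TRIAL_LENGTH_S)
    b = np.where(
        tt >= 0,
        _bump(phase, params.response_peak_latency, params.response_width),
        0.0,
    )
    r_frac = params.bilateral_response_amplitude / 100.0
    rng = np.random.default_rng(params.seed)
    trial_li = params.true_li + params.trial_li_sd * rng.standard_normal(
        params.n_trials
    )
    alpha_per_trial = _left_excess_amplitude(params, trial_li)
    # per-sample excess coefficient: trial k's alpha inside trial k, 0 before
    trial_index = np.clip(
        np.floor(tt / TRIAL_LENGTH_S).astype(int), 0, params.n_trials - 1
    )
    alpha = np.where(tt >= 0, alpha_per_trial[trial_index], 0.0)

    harmonics = np.asarray(PULSE_HARMONICS)
    f0 = params.heart_rate / 60.0
    pulse = np.zeros(n)
    for k, a in enumerate(harmonics, start=1):
        pulse += a * np.cos(2.0 * np.pi * k * f0 * time)
    pulse *= params.pulsatility_amplitude / harmonics.sum()

    bl, br = params.baseline_velocity_left, params.baseline_velocity_right
    noise_l = bl * (params.noise_sd / 100.0) * rng.standard_normal(n)
    noise_r = br * (params.noise_sd / 100.0) * rng.standard_normal(n)
    left = bl * (1.0 + pulse) * (1.0 + r_frac * b + alpha * b) + noise_l
    right = br * (1.0 + pulse) * (1.0 + r_frac * b) + noise_r
    return Recording(
        subject_id=subject_id,
        sampling_rate=fs,
        time=time,
        left=left,
        right=right,
        triggers=list(triggers),
    )


def _epoch_spans(recording: Recording) -> list:
    return [(trig + EPOCH[0], trig + EPOCH[1]) for trig in recording.triggers]


def inject_artifacts(
    recording: Recording, params: SimParams
) -> tuple[Recording, list]:
    """Add velocity spikes and dropout runs at Poisson-distributed times.

    Spikes set isolated samples to ``spike_magnitude x`` the channel mean;
    dropouts force runs (0.5-1.5 s) to 30% of the channel mean.  Returns
    the contaminated recording and the sorted list of trial indices whose
    epochs contain at least one artifact sample.
    """
    rng = np.random.default_rng([params.seed, 0xA27])
    left = recording.left.copy()
    right = recording.right.copy()
    n = len(left)
    fs = recording.sampling_rate
    minutes = recording.duration / 60.0
    means = (float(recording.left.mean()), float(recording.right.mean()))
    artifact_idx: list = []

    n_spikes = rng.poisson(params.spike_rate * minutes)
    for _ in range(n_spikes):
        i = int(rng.integers(0, n))
        ch = int(rng.integers(0, 2))
        (left if ch == 0 else right)[i] = params.spike_magnitude * means[ch]
        artifact_idx.append(i)

    n_drops = rng.poisson(params.dropout_rate * minutes)
    for _ in range(n_drops):
        start_t = float(rng.uniform(0.0, recording.duration))
        dur = float(rng.uniform(0.5, 1.5))
        i0 = int(round(start_t * fs))
        i1 = min(n, i0 + max(1, int(round(dur * fs))))
        ch = int(rng.integers(0, 2))
        (left if ch == 0 else right)[i0:i1] = DROPOUT_LEVEL * means[ch]
        artifact_idx.extend(range(i0, i1))

    contaminated = set()
    if artifact_idx:
        times = recording.time[np.asarray(sorted(set(artifact_idx)))]
        for k, (t0, t1) in enumerate(_epoch_spans(recording)):
            if np.any((times >= t0) & (times < t1)):
                contaminated.add(k)
    out = Recording(
        subject_id=recording.subject_id,
        sampling_rate=fs,
        time=recording.time,
        left=left,
        right=right,
        triggers=list(recording.triggers),
    )
    return out, sorted(contaminated)


def simulate_cohort(spec: CohortSpec) -> tuple[list, np.ndarray]:
    """Simulate a cohort; returns (recordings, ground-truth LI per subject).

    Per-subject true LIs are drawn from Normal(li_mean, li_sd) with the
    cohort seed; each subject then gets an independent child seed.
    Artifacts are injected when the base parameters request them.
    """
    rng = np.random.default_rng(spec.seed)
    truths = rng.normal(spec.li_mean, spec.li_sd, spec.n_subjects)
    child_seeds = rng.integers(0, MAX_SEED, spec.n_subjects)
    recordings = []
    for i in range(spec.n_subjects):
        p = replace(
            spec.base_params, true_li=float(truths[i]), seed=int(child_seeds[i])
        )
        rec = simulate_recording(p, subject_id=f"S{i:03d}")
        if p.spike_rate > 0 or p.dropout_rate > 0:
            rec, _ = inject_artifacts(rec, p)
        recordings.append(rec)
    return recordings, truths


def sample_group_values(summary: GroupSummary, seed: int = 0) -> np.ndarray:
    """Draw n values whose sample mean and SD match the summary exactly.

    Standard-normal draws are affinely rescaled, so summary-based and
    raw-data statistics can be cross-checked against one another.
    """
    if summary.n < 2:
        raise ValueError("sample_group_values requires n >= 2")
    rng = np.random.default_rng(seed)
    if summary.sd == 0:
        return np.full(summary.n, float(summary.mean))
    z = rng.standard_normal(summary.n)
    while np.std(z, ddof=1) == 0:  # vanishing probability, but keep it safe
        z = rng.standard_normal(summary.n)
    z = (z - z.mean()) / np.std(z, ddof=1)
    return summary.mean + summary.sd * z
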