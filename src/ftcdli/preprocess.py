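"""Preprocessing of raw two-channel CBFV recordings into analysable epochs.

The pipeline order is fixed: heart-cycle integration -> epoching ->
per-trial outlier screening on the velocity scale -> per-trial
normalisation to percent of epoch mean -> baseline correction of the
left-right difference wave.  Each trial of the task lasts 38 s (12 s
silent watching, 10 s description, 16 s rest); epochs are cut from -12 s
to +26 s around each trigger, the baseline window is [-10, -2) s before
onset, and all windows use the half-open convention [start, end) in
seconds with onset = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

logger = logging.getLogger("ftcdli.preprocess")

__all__ = [
    "Recording",
    "EpochSet",
    "PipelineConfig",
    "ProcessingError",
    "integrate_heart_cycles",
    "normalize_trial",
    "segment_and_baseline",
    "reject_outlier_trials",
    "channel_means",
]

REASON_FLOW = "flow-out-of-range"
REASON_BEHAVIORAL = "behavioral"
REASON_EDGE = "edge"


class ProcessingError(RuntimeError):
    """Raised when a signal-processing stage cannot proceed."""


@dataclass
class Recording:
    """A raw or heart-cycle-integrated two-channel CBFV recording.

    ``left`` and ``right`` are velocity traces (cm/s) on the uniform
    ``time`` grid (s); ``triggers`` are trial-onset times in seconds.
    """

    subject_id: str
    sampling_rate: float
    time: np.ndarray
    left: np.ndarray
    right: np.ndarray
    triggers: Sequence[float]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.triggers = list(float(t) for t in self.triggers)
        if not (len(self.time) == len(self.left) == len(self.right)):
            raise ValueError("time, left and right must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if len(self.time) >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not (np.all(np.isfinite(self.left)) and np.all(np.isfinite(self.right))):
            raise ValueError("velocities must be finite")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if len(self.time) else 0.0

    @property
    def n_trials(self) -> int:
        return len(self.triggers)


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis windows and thresholds, all times in seconds relative to onset."""

    epoch_window: tuple[float, float] = (-12.0, 26.0)
    baseline_window: tuple[float, float] = (-10.0, -2.0)
    poi: tuple[float, float] = (4.0, 18.0)
    li_window_width: float = 2.0
    rejection_band: float = 0.5
    min_accepted_trials: int = 9
    alpha: float = 0.05

    def __post_init__(self) -> None:
        e0, e1 = self.epoch_window
        for name, (w0, w1) in (
            ("baseline_window", self.baseline_window),
            ("poi", self.poi),
        ):
            if not (e0 <= w0 < w1 <= e1):
                raise ValueError(f"{name} must lie inside the epoch window")
        if self.li_window_width <= 0:
            raise ValueError("li_window_width must be > 0")
        if not 0 < self.rejection_band <= 1:
            raise ValueError("rejection_band must be in (0, 1]")
        if self.min_accepted_trials < 1:
            raise ValueError("min_accepted_trials must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class EpochSet:
    """Per-trial epochs of one subject, with accept/reject bookkeeping.

    ``raw_left``/``raw_right`` are velocity-scale epochs used by the ±50%
    screen; ``norm_left``/``norm_right`` are percent-of-epoch-mean signals
    (mean 100 by construction); ``diff`` is the baseline-corrected
    left-minus-right normalised difference.  Rows of rejected trials may
    be NaN (edge trials have no data).
    """

    subject_id: str
    rel_time: np.ndarray
    raw_left: np.ndarray      # (n_trials, n_samples)
    raw_right: np.ndarray
    norm_left: np.ndarray
    norm_right: np.ndarray
    diff: np.ndarray
    accepted: np.ndarray      # bool per trial
    reasons: list
    config: PipelineConfig = field(default_factory=PipelineConfig)

    @property
    def n_trials(self) -> int:
        return int(self.raw_left.shape[0])

    @property
    def n_accepted(self) -> int:
        return int(np.count_nonzero(self.accepted))

    def accepted_indices(self) -> np.ndarray:
        return np.flatnonzero(self.accepted)

    def subset(self, trial_indices: Sequence[int]) -> "EpochSet":
        """A new EpochSet containing only the given trials (order preserved)."""
        idx = np.asarray(trial_indices, dtype=int)
        return EpochSet(
            subject_id=self.subject_id,
            rel_time=self.rel_time,
            raw_left=self.raw_left[idx],
            raw_right=self.raw_right[idx],
            norm_left=self.norm_left[idx],
            norm_right=self.norm_right[idx],
            diff=self.diff[idx],
            accepted=self.accepted[idx].copy(),
            reasons=[self.reasons[i] for i in idx],
            config=self.config,
        )


def channel_means(recording: Recording) -> tuple[float, float]:
    """Whole-recording mean velocity of each channel."""
    return float(np.mean(recording.left)), float(np.mean(recording.right))


def integrate_heart_cycles(recording: Recording) -> Recording:
    """Remove cardiac pulsatility by averaging within each cardiac cycle.

    Systolic peaks are detected on the summed channels (more robust than
    either alone) with a minimum inter-beat interval of 0.3 s and a
    prominence threshold derived from the signal's amplitude range.  Each
    channel is replaced by its per-cycle mean assigned to the cycle
    midpoint and linearly interpolated back onto the original grid;
    length and triggers are unchanged.
    """
    fs = recording.sampling_rate
    if recording.duration < 2.0:
        raise ProcessingError("need at least 2 s of data for beat detection")
    if fs < 20:
        raise ProcessingError("sampling rate below 20 Hz cannot resolve heart beats")
    s = recording.left + recording.right
    spread = float(np.percentile(s, 95) - np.percentile(s, 5))
    if spread <= 0:
        raise ProcessingError(
            "no detectable cardiac cycles (flat signal); check the sampling "
            "rate and signal amplitude"
        )
    prominence = 0.25 * spread
    distance = max(1, int(round(0.3 * fs)))
    peaks, _ = find_peaks(s, distance=distance, prominence=prominence)
    if len(peaks) < 3:
        raise ProcessingError(
            "no detectable cardiac cycles; check the sampling rate and "
            "signal amplitude"
        )
    mids = 0.5 * (recording.time[peaks[:-1]] + recording.time[peaks[1:]])
    counts = np.diff(peaks)

    def _cycle_means(ch: np.ndarray) -> np.ndarray:
        sums = np.add.reduceat(ch, peaks[:-1])
        # reduceat's last segment runs to the end of the array; restrict to
        # full cycles (peak_j .. peak_{j+1}) only
        sums = sums.copy()
        sums[-1] = ch[peaks[-2]:peaks[-1]].sum()
        return sums / counts

    new_left = np.interp(recording.time, mids, _cycle_means(recording.left))
    new_right = np.interp(recording.time, mids, _cycle_means(recording.right))
    logger.info(
        "heart-cycle integration: subject=%s beats=%d mean_ibi=%.3fs",
        recording.subject_id, len(peaks), float(np.mean(np.diff(peaks))) / fs,
    )
    return replace(recording, left=new_left, right=new_right)


def normalize_trial(
    left_segment: np.ndarray, right_segment: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale each channel of one trial epoch to percent of its own mean.

    Raises ValueError when either channel's mean is non-positive (such
    trials are rejected upstream with reason ``flow-out-of-range``).
    """
    ml = float(np.mean(left_segment))
    mr = float(np.mean(right_segment))
    if ml <= 0 or mr <= 0:
        raise ValueError("channel mean must be positive to normalise a trial")
    return 100.0 * left_segment / ml, 100.0 * right_segment / mr


def segment_and_baseline(
    recording: Recording,
    config: Optional[PipelineConfig] = None,
    behavioral_rejects: Sequence[int] = (),
    raw_recording: Optional[Recording] = None,
) -> EpochSet:
    """Cut trigger-locked epochs, normalise, and baseline-correct the difference.

    ``recording`` should already be heart-cycle integrated.  If the
    original (pre-integration) recording is supplied via ``raw_recording``
    its samples populate the velocity-scale epochs used by the outlier
    screen, so that brief spikes are not diluted by cycle averaging.
    Trials in ``behavioral_rejects`` (0-based indices) are flagged with
    reason ``behavioral``; triggers too close to the recording edge are
    flagged ``edge``.
    """
    config = config or PipelineConfig()
    fs = recording.sampling_rate
    e0, e1 = config.epoch_window
    n_pre = int(round(-e0 * fs))
    n_total = int(round((e1 - e0) * fs))
    rel_time = (np.arange(n_total) - n_pre) / fs
    b0, b1 = config.baseline_window
    base_mask = (rel_time >= b0) & (rel_time < b1)

    raw_src = raw_recording if raw_recording is not None else recording
    if raw_src is not recording and len(raw_src.time) != len(recording.time):
        raise ValueError("raw_recording must share the integrated recording's grid")

    n_trials = recording.n_trials
    shape = (n_trials, n_total)
    raw_l = np.full(shape, np.nan)
    raw_r = np.full(shape, np.nan)
    norm_l = np.full(shape, np.nan)
    norm_r = np.full(shape, np.nan)
    diff = np.full(shape, np.nan)
    accepted = np.ones(n_trials, dtype=bool)
    reasons: list = [None] * n_trials
    behavioral = set(int(i) for i in behavioral_rejects)

    n_samples = len(recording.time)
    for k, trig in enumerate(recording.triggers):
        i_trig = int(round((trig - recording.time[0]) * fs))
        start = i_trig - n_pre
        end = start + n_total
        if start < 0 or end > n_samples:
            accepted[k] = False
            reasons[k] = REASON_EDGE
            continue
        seg_l = recording.left[start:end]
        seg_r = recording.right[start:end]
        raw_l[k] = raw_src.left[start:end]
        raw_r[k] = raw_src.right[start:end]
        try:
            nl, nr = normalize_trial(seg_l, seg_r)
        except ValueError:
            accepted[k] = False
            reasons[k] = REASON_FLOW
            continue
        norm_l[k] = nl
        norm_r[k] = nr
        d = nl - nr
        diff[k] = d - float(np.mean(d[base_mask]))
        if k in behavioral:
            accepted[k] = False
            reasons[k] = REASON_BEHAVIORAL

    epochs = EpochSet(
        subject_id=recording.subject_id,
        rel_time=rel_time,
        raw_left=raw_l,
        raw_right=raw_r,
        norm_left=norm_l,
        norm_right=norm_r,
        diff=diff,
        accepted=accepted,
        reasons=reasons,
        config=config,
    )
    for k in range(n_trials):
        if reasons[k] is not None:
            logger.info(
                "segment: subject=%s trial=%d rejected reason=%s",
                recording.subject_id, k, reasons[k],
            )
    return epochs


def reject_outlier_trials(
    epochs: EpochSet, recording_channel_means: tuple[float, float]
) -> EpochSet:
    """Flag trials whose velocity-scale samples leave the ±band around the mean.

    A trial is rejected (reason ``flow-out-of-range``) when any sample of
    either channel inside its epoch lies outside
    ``[1 - band, 1 + band] x`` that channel's whole-recording mean
    (computed after heart-cycle integration).  Already-rejected trials
    keep their original reason: rejection is monotone.
    """
    ml, mr = recording_channel_means
    band = epochs.config.rejection_band
    lo_l, hi_l = (1.0 - band) * ml, (1.0 + band) * ml
    lo_r, hi_r = (1.0 - band) * mr, (1.0 + band) * mr
    accepted = epochs.accepted.copy()
    reasons = list(epochs.reasons)
    for k in range(epochs.n_trials):
        if reasons[k] == REASON_EDGE:
            continue  # no data to screen
        out_l = np.any(epochs.raw_left[k] < lo_l) or np.any(epochs.raw_left[k] > hi_l)
        out_r = np.any(epochs.raw_right[k] < lo_r) or np.any(epochs.raw_right[k] > hi_r)
        if out_l or out_r:
            accepted[k] = False
            if reasons[k] is None:
                reasons[k] = REASON_FLOW
                logger.info(
                    "outlier screen: subject=%s trial=%d rejected (±%.0f%% band)",
                    epochs.subject_id, k, 100 * band,
                )
    return replace(epochs, accepted=accepted, reasons=reasons)
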