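import numpy as np
import pytest

from ftcdli.preprocess import EpochSet, PipelineConfig


@pytest.fixture
def config():
    return PipelineConfig()


def make_epochs(diff_waves, fs=10.0, subject_id="toy", config=None,
                baseline_correct=True):
    """Build an EpochSet directly from difference waves on a [-12, 26) grid.

    Channels are split symmetrically around 100 so that norm_left - norm_right
    equals the given wave; the difference is baseline-corrected over [-10, -2)
    the same way the pipeline does.
    """
    config = config or PipelineConfig()
    e0, e1 = config.epoch_window
    n = int(round((e1 - e0) * fs))
    rel_time = np.arange(n) / fs + e0
    waves = np.asarray(diff_waves, dtype=float)
    if waves.shape[1] != n:
        raise ValueError(f"waves must have {n} samples at fs={fs}")
    b0, b1 = config.baseline_window
    base = (rel_time >= b0) & (rel_time < b1)
    diff = waves.copy()
    if baseline_correct:
        diff = diff - diff[:, base].mean(axis=1, keepdims=True)
    norm_l = 100.0 + waves / 2.0
    norm_r = 100.0 - waves / 2.0
    raw_l = 60.0 * norm_l / 100.0
    raw_r = 60.0 * norm_r / 100.0
    n_trials = waves.shape[0]
    return EpochSet(
        subject_id=subject_id,
        rel_time=rel_time,
        raw_left=raw_l,
        raw_right=raw_r,
        norm_left=norm_l,
        norm_right=norm_r,
        diff=diff,
        accepted=np.ones(n_trials, dtype=bool),
        reasons=[None] * n_trials,
        config=config,
    )


def raised_cosine(rel_time, peak, half_width, amplitude=1.0):
    """A symmetric raised-cosine bump, zero outside [peak-hw, peak+hw]."""
    x = np.zeros_like(rel_time)
    mask = np.abs(rel_time - peak) <= half_width
    x[mask] = 0.5 * amplitude * (
        1.0 + np.cos(np.pi * (rel_time[mask] - peak) / half_width)
    )
    return x
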