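"""End-to-end subject and group analyses.

``run_subject`` composes the full chain — heart-cycle integration,
epoching with baseline correction, ±50% outlier screening, LI
computation and classification — on one recording.  ``run_group``
analyses two groups of recordings and produces the standard group
report: per-group LI summaries, category counts, split-half
reliability, between-group t-tests, a chi-square on categories, a
Fisher-z comparison of reliabilities, and optional equivalence/Bayes
analyses.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .equivalence import bayes_factor_directional, tost
from .io import read_recording
from .laterality import (
    SubjectResult,
    compute_li,
    group_mean_li,
    split_half_reliability,
)
from .preprocess import (
    EpochSet,
    PipelineConfig,
    Recording,
    channel_means,
    integrate_heart_cycles,
    reject_outlier_trials,
    segment_and_baseline,
)
from .stats import (
    GroupSummary,
    chi_square,
    fisher_z_compare,
    pooled_sd,
    summarize,
    two_sample_t_summary,
)

logger = logging.getLogger("ftcdli.pipeline")

__all__ = ["run_subject", "run_group", "config_hash"]


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def run_subject(
    recording: Recording | str | Path,
    config: Optional[PipelineConfig] = None,
    behavioral_rejects: Sequence[int] = (),
) -> tuple[SubjectResult, EpochSet]:
    """Run the complete single-subject pipeline; returns (result, epochs)."""
    if not isinstance(recording, Recording):
        recording = read_recording(recording)
    config = config or PipelineConfig()
    integrated = integrate_heart_cycles(recording)
    epochs = segment_and_baseline(
        integrated, config, behavioral_rejects, raw_recording=recording
    )
    epochs = reject_outlier_trials(epochs, channel_means(integrated))
    result = compute_li(epochs, config)
    logger.info(
        "subject=%s trials=%d accepted=%d li=%.3f latency=%.2fs category=%s "
        "excluded=%s",
        result.subject_id, result.n_trials_total, result.n_accepted,
        result.li, result.peak_latency, result.category, result.excluded,
    )
    return result, epochs


def _analyse_group(recordings: Sequence[Recording | str | Path],
                   config: PipelineConfig) -> dict:
    results, epoch_sets = [], []
    for rec in recordings:
        res, ep = run_subject(rec, config)
        results.append(res)
        epoch_sets.append(ep)
    kept = [r for r in results if not r.excluded]
    kept_eps = [e for r, e in zip(results, epoch_sets) if not r.excluded]
    if len(kept) < 3:
        raise ValueError("need at least 3 non-excluded subjects per group")
    summary = group_mean_li(results)
    reliability = split_half_reliability(kept_eps, config)
    for r, lo, le in zip(kept, reliability.li_odd, reliability.li_even):
        r.li_odd, r.li_even = float(lo), float(le)
    return {
        "results": results,
        "summary": summary,
        "reliability": reliability,
        "n_trials": summarize([r.n_accepted for r in kept]),
        "peak_latency": summarize([r.peak_latency for r in kept]),
    }


def _load_group(source) -> list:
    if isinstance(source, (str, Path)):
        paths = sorted(Path(source).glob("*.csv"))
        if not paths:
            raise ValueError(f"no recording files (*.csv) found in {source}")
        return list(paths)
    return list(source)


def run_group(
    group_a,
    group_b,
    config: Optional[PipelineConfig] = None,
    equivalence_bound: Optional[float] = None,
    bayes_prior_sd: Optional[float] = None,
) -> dict:
    """Compare two groups of recordings (directories, paths, or Recordings).

    The report difference orientation is group_a - group_b; for the TOST
    and Bayes options the caller should pass the group predicted to be
    *less* lateralised as ``group_a`` so that positive differences are in
    the predicted direction.
    """
    config = config or PipelineConfig()
    a = _analyse_group(_load_group(group_a), config)
    b = _analyse_group(_load_group(group_b), config)

    def group_block(g: dict) -> dict:
        s = g["summary"]
        return {
            "n": s.li.n,
            "li_mean": s.li.mean,
            "li_sd": s.li.sd,
            "n_trials_mean": g["n_trials"].mean,
            "n_trials_sd": g["n_trials"].sd,
            "peak_latency_mean": g["peak_latency"].mean,
            "peak_latency_sd": g["peak_latency"].sd,
            "category_counts": s.category_counts,
            "category_percent": s.category_percent,
            "n_excluded": s.n_excluded,
            "split_half_r": g["reliability"].r,
            "subjects": [r.to_dict() for r in g["results"]],
        }

    counts_a = a["summary"].category_counts
    counts_b = b["summary"].category_counts
    cats = [c for c in ("left", "right", "low")
            if counts_a[c] + counts_b[c] > 0]
    comparisons = {
        "li": two_sample_t_summary(a["summary"].li, b["summary"].li)._asdict(),
        "n_trials": two_sample_t_summary(a["n_trials"], b["n_trials"])._asdict(),
        "peak_latency": two_sample_t_summary(
            a["peak_latency"], b["peak_latency"]
        )._asdict(),
    }
    # the Fisher transform needs n > 3 per group and |r| < 1
    if (a["summary"].li.n > 3 and b["summary"].li.n > 3
            and abs(a["reliability"].r) < 1 and abs(b["reliability"].r) < 1):
        comparisons["reliability"] = fisher_z_compare(
            a["reliability"].r, a["summary"].li.n,
            b["reliability"].r, b["summary"].li.n,
        )._asdict()
    if len(cats) >= 2:
        comparisons["categories"] = chi_square(
            [[counts_a[c] for c in cats], [counts_b[c] for c in cats]]
        )._asdict()

    report = {
        "package_version": __version__,
        "config_hash": config_hash(config),
        "group_a": group_block(a),
        "group_b": group_block(b),
        "comparisons": comparisons,
    }
    if equivalence_bound is not None:
        eq = tost(a["summary"].li, b["summary"].li, equivalence_bound,
                  alpha=config.alpha)
        report["equivalence"] = asdict(eq)
    if bayes_prior_sd is not None:
        sa, sb = a["summary"].li, b["summary"].li
        diff = sa.mean - sb.mean
        se_diff = pooled_sd(sa, sb) * math.sqrt(1.0 / sa.n + 1.0 / sb.n)
        report["bayes"] = asdict(
            bayes_factor_directional(diff, se_diff, bayes_prior_sd)
        )
    return report
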