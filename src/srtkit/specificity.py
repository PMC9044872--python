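"""Shannon-entropy expression specificity scores and SRT classification.

For a transcript with per-type aggregated expression x_1..x_N, the expression
ratios are p_i = x_i / sum(x), and the specificity score is

    S = log2(N) - H(p),    H(p) = -sum_i p_i * log2(p_i)   (0*log2(0) := 0)

so S = 0 for perfectly uniform expression and S = log2(N) for expression
confined to a single type.  A transcript is called a *specific RNA
transcript* (SRT) in the type with the largest ratio when that ratio is more
than twice the second-largest ratio AND the score exceeds 1; both
inequalities are strict, and a tie for the largest ratio can never satisfy
the dominance condition.

Transcripts with zero total expression have undefined ratios; they are
reported with a NaN score and ``is_specific = False`` rather than dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix_io import TypeProfile

__all__ = [
    "FOLD_THRESHOLD",
    "SCORE_THRESHOLD",
    "SpecificityResult",
    "expression_ratios",
    "specificity_score",
    "classify_srt",
    "score_all",
    "results_to_frame",
]

#: Dominance threshold: the top ratio must exceed FOLD_THRESHOLD x the second.
FOLD_THRESHOLD = 2.0
#: Minimum specificity score for an SRT call.
SCORE_THRESHOLD = 1.0

_RATIO_SUM_TOL = 1e-8


@dataclass
class SpecificityResult:
    """Per-transcript specificity: score, ratio vector, top types and SRT call."""

    transcript_id: str
    score: float
    ratios: np.ndarray
    top_type: str | None
    top_ratio: float
    second_ratio: float
    is_specific: bool
    specific_type: str | None


def expression_ratios(profile: TypeProfile, transcript: str) -> np.ndarray:
    """Expression-ratio vector p_i = x_i / sum(x) for one transcript.

    Returns an all-NaN vector for transcripts with zero total expression
    (ratios undefined).  Raises ``KeyError`` for an unknown transcript id.
    """
    if transcript not in profile.x.index:
        raise KeyError(f"unknown transcript id: {transcript!r}")
    x = profile.x.loc[transcript].to_numpy(dtype=float)
    total = x.sum()
    if total == 0:
        return np.full(x.shape, np.nan)
    return x / total


def specificity_score(ratios: Sequence[float], n_types: int | None = None) -> float:
    """Specificity score log2(N) - Shannon entropy of a ratio vector.

    ``n_types`` defaults to ``len(ratios)``.  The result is clamped to
    [0, log2(N)] against floating-point underflow.  NaN propagates (undefined
    ratios give an undefined score).
    """
    p = np.asarray(ratios, dtype=float)
    if n_types is None:
        n_types = p.size
    if np.isnan(p).any():
        return float("nan")
    if abs(p.sum() - 1.0) > _RATIO_SUM_TOL:
        raise ValueError(f"ratio vector sums to {p.sum()!r}, not 1")
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    score = math.log2(n_types) - entropy
    return min(max(score, 0.0), math.log2(n_types))


def classify_srt(
    ratios: Sequence[float],
    score: float,
    type_labels: Sequence[str] | None = None,
    fold_threshold: float = FOLD_THRESHOLD,
    score_threshold: float = SCORE_THRESHOLD,
) -> tuple[bool, str | None]:
    """Apply the SRT rule: top ratio > fold_threshold x second ratio and score > score_threshold.

    Returns ``(is_specific, specific_type)``; ``specific_type`` is the label
    of the largest ratio when specific, else ``None``.  Ties for the largest
    ratio fail dominance and are never specific.
    """
    p = np.asarray(ratios, dtype=float)
    if np.isnan(p).any() or math.isnan(score):
        return False, None
    if p.size == 1:
        return False, None
    idx = np.argsort(-p, kind="stable")
    top, second = p[idx[0]], p[idx[1]]
    if top > fold_threshold * second and score > score_threshold:
        label = type_labels[idx[0]] if type_labels is not None else str(idx[0])
        return True, label
    return False, None


def score_all(
    profile: TypeProfile,
    fold_threshold: float = FOLD_THRESHOLD,
    score_threshold: float = SCORE_THRESHOLD,
) -> list[SpecificityResult]:
    """Score and classify every transcript of a profile (vectorised).

    Results are in profile row order; one score and N ratios per transcript.
    All-zero transcripts get NaN score and are non-specific.
    """
    x = profile.x.to_numpy(dtype=float)
    labels = profile.type_labels
    n = profile.n_types
    totals = x.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = x / totals[:, None]
    logp = np.zeros_like(ratios)
    pos = ratios > 0
    logp[pos] = np.log2(ratios[pos])
    entropy = -(ratios * logp).sum(axis=1)
    scores = np.clip(math.log2(n) - entropy, 0.0, math.log2(n))
    scores[totals == 0] = np.nan

    results: list[SpecificityResult] = []
    for i, tid in enumerate(profile.x.index):
        if totals[i] == 0:
            results.append(
                SpecificityResult(
                    transcript_id=str(tid),
                    score=float("nan"),
                    ratios=np.full(n, np.nan),
                    top_type=None,
                    top_ratio=float("nan"),
                    second_ratio=float("nan"),
                    is_specific=False,
                    specific_type=None,
                )
            )
            continue
        p = ratios[i]
        order = np.argsort(-p, kind="stable")
        top_i = int(order[0])
        top = float(p[top_i])
        second = float(p[order[1]]) if n > 1 else 0.0
        is_spec = n > 1 and top > fold_threshold * second and scores[i] > score_threshold
        results.append(
            SpecificityResult(
                transcript_id=str(tid),
                score=float(scores[i]),
                ratios=p,
                top_type=labels[top_i],
                top_ratio=top,
                second_ratio=second,
                is_specific=bool(is_spec),
                specific_type=labels[top_i] if is_spec else None,
            )
        )
    return results


def results_to_frame(
    results: Sequence[SpecificityResult],
    type_labels: Sequence[str] | None = None,
    include_ratios: bool = False,
) -> pd.DataFrame:
    """Tabulate results; optionally append one ratio column per type."""
    rows = {
        "transcript_id": [r.transcript_id for r in results],
        "score": [r.score for r in results],
        "top_type": [r.top_type if r.top_type is not None else "" for r in results],
        "top_ratio": [r.top_ratio for r in results],
        "second_ratio": [r.second_ratio for r in results],
        "is_specific": [r.is_specific for r in results],
        "specific_type": [r.specific_type if r.specific_type is not None else "" for r in results],
    }
    df = pd.DataFrame(rows)
    if include_ratios and type_labels is not None:
        for j, lab in enumerate(type_labels):
            df[f"ratio_{lab}"] = [float(r.ratios[j]) for r in results]
    return df
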