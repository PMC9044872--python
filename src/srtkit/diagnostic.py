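"""Diagnostic-candidate filtering and the composite specific diagnostic score.

Candidate diagnostic transcripts for a cancer type c are transcripts
expressed in its tumor samples but silent in the matched normal tissue.
Each candidate that is cancer-specific somewhere is then ranked by

    S_tc = b1 * log2(x_tc + 1) * s_tc * r_tc  +  b1 * b2 * s_tt

where x_tc is the mean tumor TPM in c, s_tc the cancer-context specificity
score, r_tc the fraction of c's tumor samples expressing the transcript, and
s_tt the tissue-context specificity score.  The weights encode the
cross-type logic:

* b1 = +1 when the transcript is cancer-specific in c itself, -1 when it is
  specific in a *different* cancer type (a cross-cancer confounder — the
  whole score flips negative);
* b2 = 1 when the transcript is tissue-specific in c's tissue of origin
  (a lineage marker: the tissue score is credited), 0 when it is specific in
  an unrelated tissue (the credit is withheld);
* a transcript that is not tissue-specific anywhere takes s_tt = 1 and
  b2 = 1, a fixed unit credit.

Larger S_tc means a more reliable single-analyte diagnostic marker for c.
Transcripts that are not cancer-specific in any type have no defined b1 and
are reported as unrankable rather than scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cross_specificity import OriginMap
from .matrix_io import ExpressionMatrix
from .specificity import SpecificityResult

__all__ = [
    "DiagnosticRecord",
    "UnrankableTranscript",
    "filter_tumor_only",
    "expression_frequency",
    "diagnostic_score",
    "rank_diagnostic",
    "score_candidates",
    "records_to_frame",
]


class UnrankableTranscript(ValueError):
    """Raised when b1 is undefined: the transcript is cancer-specific nowhere."""


@dataclass
class DiagnosticRecord:
    """One scored (transcript, cancer type) pair with all score components."""

    transcript_id: str
    cancer_type: str
    score: float
    mean_tumor_expr: float  # x_tc, TPM
    cancer_spec_score: float  # s_tc
    expr_frequency: float  # r_tc in [0, 1]
    tissue_spec_score: float  # s_tt
    beta1: int  # +1 | -1
    beta2: int  # 0 | 1
    comparator_all_tissues: bool = False  # matched normal absent; union comparator used

    def recompute(self) -> float:
        """Re-evaluate the score formula from the stored components."""
        return (
            self.beta1 * math.log2(self.mean_tumor_expr + 1.0)
            * self.cancer_spec_score * self.expr_frequency
            + self.beta1 * self.beta2 * self.tissue_spec_score
        )


def filter_tumor_only(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    origin_map: OriginMap,
    tpm_threshold: float = 0.1,
    normal_tolerance: float = 0.0,
) -> tuple[dict[str, set[str]], dict[str, bool]]:
    """Per cancer type, transcripts expressed in its tumors but silent in matched normals.

    A transcript is kept for cancer c when it exceeds *tpm_threshold* in at
    least one tumor sample of c and in at most a *normal_tolerance* fraction
    (default 0: none) of the matched normal tissue's samples.  Cancers with
    no matched normal tissue are compared against the union of all normal
    samples and flagged in the returned ``dict`` of flags.
    """
    if not 0.0 <= normal_tolerance <= 1.0:
        raise ValueError("normal_tolerance must be in [0, 1]")
    kept: dict[str, set[str]] = {}
    flagged: dict[str, bool] = {}
    normal_vals = normal.values
    for c in tumor.types():
        origin = origin_map.matched_tissue(c)  # raises on unknown cancer type
        tumor_cols = tumor.samples_of_type(c)
        expressed = (tumor.values[tumor_cols].to_numpy() > tpm_threshold).any(axis=1)
        if origin is not None:
            normal_cols = normal.samples_of_type(origin)
            flagged[c] = False
        else:
            normal_cols = list(normal.sample_ids)
            flagged[c] = True
        shared = tumor.transcript_ids.intersection(normal_vals.index)
        # transcripts absent from the normal matrix count as silent there
        frac_above = pd.Series(0.0, index=tumor.transcript_ids)
        if normal_cols and len(shared):
            above = (normal_vals.loc[shared, normal_cols].to_numpy() > tpm_threshold)
            frac_above.loc[shared] = above.mean(axis=1)
        silent = (frac_above <= normal_tolerance).to_numpy()
        kept[c] = set(tumor.transcript_ids[expressed & silent])
    return kept, flagged


def expression_frequency(
    m: ExpressionMatrix, cancer_type: str, tpm_threshold: float = 0.1
) -> pd.Series:
    """Per transcript, the fraction of *cancer_type* samples with TPM above threshold."""
    cols = m.samples_of_type(cancer_type)
    if not cols:
        raise ValueError(f"no samples of type {cancer_type!r}")
    above = m.values[cols].to_numpy() > tpm_threshold
    return pd.Series(above.mean(axis=1), index=m.transcript_ids, name="expr_frequency")


def diagnostic_score(
    transcript_id: str,
    cancer_type: str,
    mean_tumor_expr: float,
    cancer_spec_score: float,
    expr_frequency: float,
    tissue_spec_score: float | None,
    cancer_specific_in: str | None,
    tissue_specific_in: str | None,
    matched_tissue: str | None,
    comparator_all_tissues: bool = False,
) -> DiagnosticRecord:
    """Assemble the weights and evaluate the composite diagnostic score.

    ``cancer_specific_in`` / ``tissue_specific_in`` are the types where the
    transcript was called specific (``None`` = nowhere).  ``tissue_spec_score``
    may be ``None`` when the transcript is not tissue-specific; it is then
    replaced by the unit credit s_tt = 1.
    """
    if cancer_specific_in is None:
        raise UnrankableTranscript(
            f"{transcript_id!r} is not cancer-specific in any type; b1 undefined"
        )
    if not 0.0 <= expr_frequency <= 1.0:
        raise ValueError(f"expression frequency {expr_frequency!r} outside [0, 1]")
    beta1 = 1 if cancer_specific_in == cancer_type else -1
    if tissue_specific_in is None:
        beta2, s_tt = 1, 1.0
    elif matched_tissue is not None and tissue_specific_in == matched_tissue:
        beta2, s_tt = 1, float(tissue_spec_score)
    else:
        beta2, s_tt = 0, float(tissue_spec_score)
    rec = DiagnosticRecord(
        transcript_id=transcript_id,
        cancer_type=cancer_type,
        score=0.0,
        mean_tumor_expr=float(mean_tumor_expr),
        cancer_spec_score=float(cancer_spec_score),
        expr_frequency=float(expr_frequency),
        tissue_spec_score=s_tt,
        beta1=beta1,
        beta2=beta2,
        comparator_all_tissues=comparator_all_tissues,
    )
    rec.score = rec.recompute()
    return rec


def rank_diagnostic(
    records: Sequence[DiagnosticRecord],
    cancer_type: str,
    top_k: int | None = None,
) -> list[DiagnosticRecord]:
    """Records of one cancer type in descending-score order; ties by id ascending."""
    subset = [r for r in records if r.cancer_type == cancer_type]
    ordered = sorted(subset, key=lambda r: (-r.score, r.transcript_id))
    return ordered if top_k is None else ordered[:top_k]


def score_candidates(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    cancer_calls: Sequence[SpecificityResult],
    tissue_calls: Sequence[SpecificityResult],
    origin_map: OriginMap,
    cancer_type: str,
    tpm_threshold: float = 0.1,
    normal_tolerance: float = 0.0,
) -> tuple[list[DiagnosticRecord], list[str]]:
    """Full diagnostic workflow for one cancer type.

    Filters to tumor-only transcripts of *cancer_type*, joins the cancer- and
    tissue-context SRT calls, and scores every rankable candidate.  Returns
    ``(records, unrankable_ids)``; the latter are tumor-only transcripts that
    are cancer-specific nowhere (b1 undefined).
    """
    kept, flagged = filter_tumor_only(tumor, normal, origin_map, tpm_threshold, normal_tolerance)
    candidates = sorted(kept.get(cancer_type, set()))
    matched = origin_map.matched_tissue(cancer_type)
    cancer_by_id = {r.transcript_id: r for r in cancer_calls}
    tissue_by_id = {r.transcript_id: r for r in tissue_calls}
    freq = expression_frequency(tumor, cancer_type, tpm_threshold)
    tumor_cols = tumor.samples_of_type(cancer_type)
    mean_expr = tumor.values[tumor_cols].mean(axis=1)

    records: list[DiagnosticRecord] = []
    unrankable: list[str] = []
    for tid in candidates:
        call = cancer_by_id.get(tid)
        if call is None or call.specific_type is None:
            unrankable.append(tid)
            continue
        tcall = tissue_by_id.get(tid)
        tissue_specific_in = tcall.specific_type if tcall is not None else None
        s_tt = tcall.score if (tcall is not None and tcall.is_specific) else None
        records.append(
            diagnostic_score(
                transcript_id=tid,
                cancer_type=cancer_type,
                mean_tumor_expr=float(mean_expr[tid]),
                cancer_spec_score=float(call.score),
                expr_frequency=float(freq[tid]),
                tissue_spec_score=s_tt,
                cancer_specific_in=call.specific_type,
                tissue_specific_in=tissue_specific_in,
                matched_tissue=matched,
                comparator_all_tissues=flagged[cancer_type],
            )
        )
    return records, unrankable


def records_to_frame(records: Sequence[DiagnosticRecord]) -> pd.DataFrame:
    """Tabulate ranked records with a 1-based rank column."""
    df = pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "cancer_type": [r.cancer_type for r in records],
            "score": [r.score for r in records],
            "mean_tumor_expr": [r.mean_tumor_expr for r in records],
            "cancer_spec_score": [r.cancer_spec_score for r in records],
            "expr_frequency": [r.expr_frequency for r in records],
            "tissue_spec_score": [r.tissue_spec_score for r in records],
            "beta1": [r.beta1 for r in records],
            "beta2": [r.beta2 for r in records],
            "comparator_all_tissues": [r.comparator_all_tissues for r in records],
        }
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df
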