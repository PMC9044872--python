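"""Dual-specificity cross-tabulation: joining SRT calls across contexts.

Many tumor-specific transcripts are *also* specific in a normal tissue —
either the tumor's tissue of origin (e.g. a liver-cancer SRT that is
liver-specific) or an unrelated tissue, frequently testis.  This module joins
SRT call sets computed on different contexts (tumor vs. normal tissue, or
transcript- vs. gene-level) and tabulates:

* per tumor type, the three-way partition of its SRTs into
  matched-tissue-specific / other-tissue-specific / not-tissue-specific;
* the symmetric partition of tissue SRTs against tumor types;
* per tumor type, the fraction of its SRTs that are testis-specific;
* per type, the fraction of SRTs whose host gene is itself a specific gene.

A transcript absent from one context is treated as not-specific there, so
every SRT lands in exactly one category and totals are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .matrix_io import TypeProfile
from .specificity import SpecificityResult

__all__ = [
    "UNMATCHED",
    "OriginMap",
    "DualSpecificityTable",
    "dual_specificity",
    "testis_overlap",
    "srt_vs_srg",
    "aggregate_genes",
]

#: Sentinel in origin-map files for a cancer type with no matched normal tissue.
UNMATCHED = "."


@dataclass
class OriginMap:
    """Cancer-type → origin-tissue mapping; unmatched cancers map to ``None``."""

    mapping: dict[str, str | None]

    def matched_tissue(self, cancer_type: str) -> str | None:
        if cancer_type not in self.mapping:
            raise KeyError(f"cancer type missing from origin map: {cancer_type!r}")
        return self.mapping[cancer_type]

    def __contains__(self, cancer_type: str) -> bool:
        return cancer_type in self.mapping

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OriginMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df["cancer_type"].duplicated().any():
            dup = df.loc[df["cancer_type"].duplicated(), "cancer_type"].iloc[0]
            raise ValueError(f"cancer type appears twice in origin map: {dup!r}")
        return cls(
            {
                row.cancer_type: (None if row.origin_tissue == UNMATCHED else row.origin_tissue)
                for row in df.itertuples()
            }
        )

    @classmethod
    def default(cls) -> "OriginMap":
        """The shipped TCGA-cancer → GTEx-tissue mapping (anatomy-unambiguous pairs only)."""
        with resources.as_file(resources.files("srtkit.data") / "origin_map.tsv") as p:
            return cls.from_tsv(p)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "cancer_type": list(self.mapping),
                "origin_tissue": [v if v is not None else UNMATCHED for v in self.mapping.values()],
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class DualSpecificityTable:
    """Cross-tabulation of tumor SRTs vs tissue SRTs (both directions).

    ``tumor_table`` is indexed by tumor type with counts and fractions over
    the categories matched-tissue / other-tissue / not-tissue-specific;
    ``tissue_table`` is the symmetric table for tissue SRTs vs tumor types.
    """

    tumor_table: pd.DataFrame
    tissue_table: pd.DataFrame


def _specific_calls(calls: Sequence[SpecificityResult]) -> dict[str, str]:
    """transcript_id → specific_type for the SRTs among *calls*."""
    return {r.transcript_id: r.specific_type for r in calls if r.is_specific}


def dual_specificity(
    tumor_calls: Sequence[SpecificityResult],
    tissue_calls: Sequence[SpecificityResult],
    origin_map: OriginMap,
) -> DualSpecificityTable:
    """Partition each tumor type's SRTs by their tissue specificity (and vice versa).

    Every tumor SRT is placed in exactly one of three categories by comparing
    its tissue ``specific_type`` with the tumor's origin tissue: matched
    tissue, other tissue, or not tissue-specific.  The reverse table places
    each tissue SRT against tumor types whose origin is that tissue.
    """
    tumor_spec = _specific_calls(tumor_calls)
    tissue_spec = _specific_calls(tissue_calls)

    tumor_types = sorted(set(tumor_spec.values()))
    rows = []
    for c in tumor_types:
        origin = origin_map.matched_tissue(c)
        n_matched = n_other = n_none = 0
        for tid, ttype in tumor_spec.items():
            if ttype != c:
                continue
            in_tissue = tissue_spec.get(tid)
            if in_tissue is None:
                n_none += 1
            elif origin is not None and in_tissue == origin:
                n_matched += 1
            else:
                n_other += 1
        n = n_matched + n_other + n_none
        rows.append(
            {
                "tumor_type": c,
                "origin_tissue": origin if origin is not None else UNMATCHED,
                "n_srt": n,
                "n_matched_tissue": n_matched,
                "n_other_tissue": n_other,
                "n_not_tissue_specific": n_none,
                "frac_matched_tissue": n_matched / n if n else 0.0,
                "frac_other_tissue": n_other / n if n else 0.0,
                "frac_not_tissue_specific": n_none / n if n else 0.0,
            }
        )
    tumor_table = pd.DataFrame(rows).set_index("tumor_type") if rows else pd.DataFrame()

    # reverse direction: tissue SRTs vs tumor types originating from that tissue
    tissue_types = sorted(set(tissue_spec.values()))
    rows = []
    for u in tissue_types:
        matched_tumors = {c for c, t in origin_map.mapping.items() if t == u}
        n_matched = n_other = n_none = 0
        for tid, utype in tissue_spec.items():
            if utype != u:
                continue
            in_tumor = tumor_spec.get(tid)
            if in_tumor is None:
                n_none += 1
            elif in_tumor in matched_tumors:
                n_matched += 1
            else:
                n_other += 1
        n = n_matched + n_other + n_none
        rows.append(
            {
                "tissue_type": u,
                "n_srt": n,
                "n_matched_tumor": n_matched,
                "n_other_tumor": n_other,
                "n_not_cancer_specific": n_none,
                "frac_matched_tumor": n_matched / n if n else 0.0,
                "frac_other_tumor": n_other / n if n else 0.0,
                "frac_not_cancer_specific": n_none / n if n else 0.0,
            }
        )
    tissue_table = pd.DataFrame(rows).set_index("tissue_type") if rows else pd.DataFrame()
    return DualSpecificityTable(tumor_table=tumor_table, tissue_table=tissue_table)


def testis_overlap(
    tumor_calls: Sequence[SpecificityResult],
    tissue_calls: Sequence[SpecificityResult],
    testis_label: str = "testis",
) -> pd.Series:
    """Per tumor type, the fraction of its SRTs that are testis-specific.

    Raises ``ValueError`` if *testis_label* is not a known tissue type in the
    tissue call set.
    """
    tissue_labels = set()
    for r in tissue_calls:
        if r.ratios is not None and r.top_type is not None:
            tissue_labels.add(r.top_type)
        if r.specific_type is not None:
            tissue_labels.add(r.specific_type)
    if testis_label not in tissue_labels:
        raise ValueError(f"unknown testis label: {testis_label!r}")

    tumor_spec = _specific_calls(tumor_calls)
    tissue_spec = _specific_calls(tissue_calls)
    out = {}
    for c in sorted(set(tumor_spec.values())):
        ids = [tid for tid, t in tumor_spec.items() if t == c]
        n_testis = sum(1 for tid in ids if tissue_spec.get(tid) == testis_label)
        out[c] = n_testis / len(ids)
    return pd.Series(out, name="testis_overlap", dtype=float)


def aggregate_genes(profile: TypeProfile, tx2gene: Mapping[str, str]) -> TypeProfile:
    """Gene-level profile: per type, sum of member-transcript expression.

    TPM is additive over a gene's transcripts, so the gene profile is the
    exact column-wise sum of its members.  Raises ``KeyError`` for a
    transcript without a gene mapping.
    """
    missing = [t for t in profile.x.index if t not in tx2gene]
    if missing:
        raise KeyError(f"transcript with no gene mapping: {missing[0]!r}")
    members: dict[str, list[str]] = {}
    for t in profile.x.index:
        members.setdefault(tx2gene[t], []).append(t)
    # explicit summation in member (row) order keeps the sum bit-reproducible
    gx = pd.DataFrame(
        {g: profile.x.loc[ts].to_numpy().sum(axis=0) for g, ts in sorted(members.items())},
        index=profile.x.columns,
    ).T
    gx.columns = profile.x.columns
    return TypeProfile(gx, aggregation=profile.aggregation, context=profile.context)


def srt_vs_srg(
    transcript_calls: Sequence[SpecificityResult],
    gene_calls: Sequence[SpecificityResult],
    tx2gene: Mapping[str, str],
) -> pd.Series:
    """Per type, the fraction of SRTs whose host gene is specific in the same type.

    A gene is only counted as matching when it is specific in the *same*
    type as the transcript; isoform switching between types therefore counts
    as not-from-SRG, as does a gene whose summed expression is uniform.
    """
    gene_spec = _specific_calls(gene_calls)
    tx_spec = _specific_calls(transcript_calls)
    out: dict[str, float] = {}
    for c in sorted(set(tx_spec.values())):
        ids = [tid for tid, t in tx_spec.items() if t == c]
        n_from_srg = 0
        for tid in ids:
            if tid not in tx2gene:
                raise KeyError(f"transcript with no gene mapping: {tid!r}")
            if gene_spec.get(tx2gene[tid]) == c:
                n_from_srg += 1
        out[c] = n_from_srg / len(ids)
    return pd.Series(out, name="srt_from_srg_fraction", dtype=float)
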