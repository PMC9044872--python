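"""Reading, validation, filtering and aggregation of transcript expression matrices.

The central container is :class:`ExpressionMatrix`: a transcripts × samples
matrix of TPM values together with a per-sample type label (e.g. ``liver`` or
``LIHC``) and a context (``tumor``, ``tissue`` or ``cell_line``).  Per-type
aggregation produces a :class:`TypeProfile`, the transcripts × types matrix
that the specificity scoring consumes.

Matrices are exchanged as TSV (rows = transcripts, columns = samples, header
row of sample ids; gzip accepted) or MatrixMarket triplet files with sidecar
``<path>.rows`` / ``<path>.cols`` name files.  Sample metadata is a TSV with
columns ``sample_id``, ``type``, ``context``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONTEXTS",
    "ExpressionMatrix",
    "TypeProfile",
    "TranscriptAnnotation",
    "StructureSummary",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_metadata",
    "filter_expressed",
    "expressed_transcripts_by_type",
    "aggregate_by_type",
    "select_top_variable",
    "read_gtf_annotation",
    "summarize_transcript_structure",
    "EXON_COUNT_BINS",
]

CONTEXTS = ("tumor", "tissue", "cell_line")

#: Default pattern marking assembler-derived (novel) transcript ids.
DEFAULT_NOVEL_PATTERN = r"^(MSTRG|STRG)\."

#: Exon-count histogram bins: 1, 2-5, 6-10, 11-20, >20.
EXON_COUNT_BINS = ("1", "2-5", "6-10", "11-20", ">20")


class MatrixValidationError(ValueError):
    """A matrix or its metadata violates an invariant; message names the offender."""


@dataclass
class ExpressionMatrix:
    """Transcripts × samples TPM matrix with per-sample type and context labels.

    Parameters
    ----------
    values
        Non-negative finite TPM values; index = transcript ids, columns =
        sample ids, both unique.
    sample_type
        Maps each sample id to its tissue/cancer/cell-line type label.
    sample_context
        Maps each sample id to one of ``tumor``, ``tissue``, ``cell_line``.
    """

    values: pd.DataFrame
    sample_type: pd.Series
    sample_context: pd.Series

    def __post_init__(self) -> None:
        self.sample_type = pd.Series(self.sample_type)
        self.sample_context = pd.Series(self.sample_context)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise MatrixValidationError(f"duplicate transcript id: {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise MatrixValidationError(f"duplicate sample id: {dup!r}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise MatrixValidationError("expression values must be numeric")
        bad = ~np.isfinite(arr) | (arr < 0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise MatrixValidationError(
                f"invalid expression value {arr[i, j]!r} at "
                f"transcript {v.index[i]!r}, sample {v.columns[j]!r}"
            )
        for sample in v.columns:
            if sample not in self.sample_type.index or pd.isna(self.sample_type[sample]):
                raise MatrixValidationError(f"sample missing from metadata: {sample!r}")
            if sample not in self.sample_context.index:
                raise MatrixValidationError(f"sample missing context: {sample!r}")
            ctx = self.sample_context[sample]
            if ctx not in CONTEXTS:
                raise MatrixValidationError(
                    f"sample {sample!r} has context {ctx!r}; expected one of {CONTEXTS}"
                )

    # -- convenience --------------------------------------------------------
    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_of_type(self, type_label: str, context: str | None = None) -> list[str]:
        """Sample ids carrying *type_label* (optionally restricted to a context)."""
        out = []
        for s in self.sample_ids:
            if self.sample_type[s] != type_label:
                continue
            if context is not None and self.sample_context[s] != context:
                continue
            out.append(s)
        return out

    def subset_context(self, context: str) -> "ExpressionMatrix":
        """Restrict to samples of one context; raises on empty selection."""
        keep = [s for s in self.sample_ids if self.sample_context[s] == context]
        if not keep:
            raise ValueError(f"no samples with context {context!r}")
        return ExpressionMatrix(
            self.values[keep],
            self.sample_type.loc[keep],
            self.sample_context.loc[keep],
        )

    def types(self, context: str | None = None) -> list[str]:
        """Sorted type labels present (optionally within a context)."""
        labels = {
            self.sample_type[s]
            for s in self.sample_ids
            if context is None or self.sample_context[s] == context
        }
        return sorted(labels)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.sample_ids),
                "type": [self.sample_type[s] for s in self.sample_ids],
                "context": [self.sample_context[s] for s in self.sample_ids],
            }
        )


@dataclass
class TypeProfile:
    """Transcripts × types aggregated expression; the input to specificity scoring.

    ``x[t, i]`` is the aggregated (mean or median) TPM of transcript ``t``
    over the samples of type ``i``.  Columns are in deterministic
    lexicographic order.
    """

    x: pd.DataFrame
    aggregation: str = "mean"
    context: str | None = None

    def __post_init__(self) -> None:
        if self.aggregation not in ("mean", "median"):
            raise ValueError(f"aggregation must be mean or median, got {self.aggregation!r}")
        arr = self.x.to_numpy()
        if arr.size and ((arr < 0) | ~np.isfinite(arr)).any():
            raise MatrixValidationError("type profile contains negative or non-finite values")
        if self.x.columns.has_duplicates:
            raise MatrixValidationError("duplicate type labels in profile")

    @property
    def type_labels(self) -> list[str]:
        return list(self.x.columns)

    @property
    def n_types(self) -> int:
        return self.x.shape[1]


@dataclass
class TranscriptAnnotation:
    """Structural summary of one transcript from a GTF: exon count, spliced length, status."""

    transcript_id: str
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    exon_count: int
    length: int  # sum of exon lengths, bases
    status: str  # "annotated" | "novel"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"transcript {self.transcript_id!r}: start {self.start} > end {self.end}"
            )
        if self.exon_count < 1 or self.length < 1:
            raise ValueError(f"transcript {self.transcript_id!r}: empty exon structure")


@dataclass
class StructureSummary:
    """Aggregate structure statistics over a set of transcript annotations."""

    n_total: int
    n_annotated: int
    n_novel: int
    novel_fraction: float
    median_length: int
    exon_count_histogram: dict[str, int] = field(default_factory=dict)
    multi_exon_fraction: float = 0.0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata TSV with columns sample_id, type, context."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "type", "context"}
    missing = required - set(meta.columns)
    if missing:
        raise MatrixValidationError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise MatrixValidationError(f"duplicate sample id in metadata: {dup!r}")
    return meta


def _read_values(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    name = path.name
    if name.endswith(".mtx") or name.endswith(".mtx.gz"):
        from scipy.io import mmread

        raw = mmread(str(path))
        mat = np.asarray(raw.todense()) if hasattr(raw, "todense") else np.asarray(raw)
        rows = Path(str(path) + ".rows").read_text().split()
        cols = Path(str(path) + ".cols").read_text().split()
        return pd.DataFrame(mat, index=rows, columns=cols)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    # locate non-numeric cells explicitly so the error names the offender
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                t = df.index[bad][0]
                raise MatrixValidationError(
                    f"non-numeric value {df.loc[t, col]!r} at transcript {t!r}, sample {col!r}"
                )
            df[col] = coerced
    return df.astype(float)


def read_expression_matrix(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read a TPM matrix (TSV or MTX triplet) plus sample metadata and validate.

    Samples present in the matrix but absent from the metadata raise a
    :class:`MatrixValidationError` naming the sample.
    """
    values = _read_values(path)
    meta = read_sample_metadata(metadata_path)
    stype = meta.set_index("sample_id")["type"]
    sctx = meta.set_index("sample_id")["context"]
    return ExpressionMatrix(values, stype, sctx)


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    """Write matrix as TSV (and optionally its metadata TSV); round-trips bit-exactly."""
    # %.17g prints the shortest-but-sufficient digits for exact float64 round-trip
    m.values.to_csv(path, sep="\t", index_label="transcript_id", float_format="%.17g")
    if metadata_path is not None:
        m.metadata_frame().to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering / aggregation / selection
# ---------------------------------------------------------------------------

def expressed_transcripts_by_type(
    m: ExpressionMatrix, tpm_threshold: float = 0.1
) -> dict[str, list[str]]:
    """Per type, the transcripts with TPM strictly above *tpm_threshold* in ≥1 sample."""
    out: dict[str, list[str]] = {}
    for t in m.types():
        cols = m.samples_of_type(t)
        mask = (m.values[cols].to_numpy() > tpm_threshold).any(axis=1)
        out[t] = list(m.transcript_ids[mask])
    return out


def filter_expressed(
    m: ExpressionMatrix,
    tpm_threshold: float = 0.1,
    group_by_type: bool = True,
) -> ExpressionMatrix:
    """Keep transcripts expressed above the threshold in at least one sample.

    A transcript is expressed when its TPM is *strictly greater* than
    *tpm_threshold* (default 0.1) in at least one sample; with
    ``group_by_type`` this is evaluated per type and a transcript is retained
    for the whole matrix if it is expressed in at least one type.  Row order
    of survivors is preserved.
    """
    if tpm_threshold < 0:
        raise ValueError("tpm_threshold must be non-negative")
    if group_by_type:
        keep_ids: set[str] = set()
        for ids in expressed_transcripts_by_type(m, tpm_threshold).values():
            keep_ids.update(ids)
        mask = m.transcript_ids.isin(keep_ids)
    else:
        mask = (m.values.to_numpy() > tpm_threshold).any(axis=1)
    return ExpressionMatrix(m.values.loc[mask], m.sample_type, m.sample_context)


def aggregate_by_type(
    m: ExpressionMatrix,
    context: str | None = None,
    aggregation: str = "mean",
) -> TypeProfile:
    """Aggregate TPM over the samples of each type into a TypeProfile.

    Types are ordered lexicographically.  ``context`` restricts the samples
    (e.g. ``"tumor"``); an empty selection raises.
    """
    if aggregation not in ("mean", "median"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    sub = m if context is None else m.subset_context(context)
    types = sub.types()
    if not types:
        raise ValueError("no types to aggregate")
    cols = {}
    for t in types:
        block = sub.values[sub.samples_of_type(t)].to_numpy()
        cols[t] = block.mean(axis=1) if aggregation == "mean" else np.median(block, axis=1)
    x = pd.DataFrame(cols, index=sub.transcript_ids)
    return TypeProfile(x, aggregation=aggregation, context=context)


def select_top_variable(m: ExpressionMatrix, n: int = 2000) -> list[str]:
    """Top-*n* transcripts by variance of log2(TPM+1) across all samples.

    Ranked by descending variance; ties broken by transcript id ascending.
    """
    n_tx = m.values.shape[0]
    if n > n_tx:
        raise ValueError(f"n={n} exceeds transcript count {n_tx}")
    logv = np.log2(m.values.to_numpy() + 1.0)
    var = pd.Series(logv.var(axis=1), index=m.transcript_ids)
    order = var.sort_index().sort_values(ascending=False, kind="stable")
    return list(order.index[:n])


# ---------------------------------------------------------------------------
# GTF annotation
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\S+) "([^"]*)"')


def _parse_attrs(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf_annotation(
    path: str | Path, novel_pattern: str = DEFAULT_NOVEL_PATTERN
) -> list[TranscriptAnnotation]:
    """Parse a GTF into per-transcript structure records.

    Exon features are grouped by their ``transcript_id`` attribute;
    coordinates are 1-based inclusive per the GTF standard, so an exon of
    length L spans ``end - start + 1 = L`` bases.  A transcript whose id
    matches *novel_pattern* is flagged ``novel`` (default: assembler-style
    ``MSTRG.``/``STRG.`` prefixes), else ``annotated``.
    """
    novel_re = re.compile(novel_pattern)
    exons: dict[str, list[tuple[str, int, int, str, str]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"{path}:{lineno}: exon end {end_i} < start {start_i}")
            a = _parse_attrs(attrs)
            tid = a.get("transcript_id")
            if not tid:
                raise ValueError(f"{path}:{lineno}: exon with no parent transcript_id")
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
            exons[tid].append((chrom, start_i, end_i, strand, a.get("gene_id", "")))
    annots = []
    for tid in order:
        ex = exons[tid]
        length = sum(e - s + 1 for _, s, e, _, _ in ex)
        annots.append(
            TranscriptAnnotation(
                transcript_id=tid,
                gene_id=ex[0][4],
                chrom=ex[0][0],
                start=min(s for _, s, _, _, _ in ex),
                end=max(e for _, _, e, _, _ in ex),
                strand=ex[0][3],
                exon_count=len(ex),
                length=length,
                status="novel" if novel_re.search(tid) else "annotated",
            )
        )
    return annots


def _exon_bin(k: int) -> str:
    if k == 1:
        return "1"
    if k <= 5:
        return "2-5"
    if k <= 10:
        return "6-10"
    if k <= 20:
        return "11-20"
    return ">20"


def summarize_transcript_structure(
    annots: Sequence[TranscriptAnnotation],
) -> StructureSummary:
    """Counts, novel fraction, median length and exon-count histogram.

    The median of an even-sized length list is the lower of the two middle
    values, so it is always an observed transcript length.
    """
    if not annots:
        raise ValueError("empty annotation list")
    n_total = len(annots)
    n_novel = sum(1 for a in annots if a.status == "novel")
    lengths = sorted(a.length for a in annots)
    median_length = lengths[(n_total - 1) // 2]
    hist = {b: 0 for b in EXON_COUNT_BINS}
    for a in annots:
        hist[_exon_bin(a.exon_count)] += 1
    multi = sum(1 for a in annots if a.exon_count > 1)
    return StructureSummary(
        n_total=n_total,
        n_annotated=n_total - n_novel,
        n_novel=n_novel,
        novel_fraction=n_novel / n_total,
        median_length=median_length,
        exon_count_histogram=hist,
        multi_exon_fraction=multi / n_total,
    )
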