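"""Synthetic expression matrices with planted ground truth.

Real inputs for this kind of analysis are controlled-access RNA-seq cohorts;
everything here instead emulates the *statistical structure* the analysis
assumes, so each stage can be exercised end-to-end with no download:

* a transcripts × samples TPM matrix over N types containing housekeeping
  transcripts (uniform mean across types, the maximum-entropy null),
  single-type-specific transcripts (dominant type enriched ``fold_change``-x
  over a uniform floor), shared-subset transcripts (elevated in 2-3 types),
  and all-zero silent transcripts;
* multiplicative log-normal noise (``noise_sigma`` on the log2 scale) and
  optional Bernoulli dropout per sample;
* a paired tumor/normal cohort generator that plants diagnostic "ideal
  markers" (tumor-only, cancer-specific, with a chosen tissue fate) and
  cross-cancer confounders, for the dual-specificity and diagnostic
  workflows.

All randomness flows from a single ``numpy.random.default_rng(seed)``, so a
given seed and config reproduce the matrices bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cross_specificity import OriginMap
from .matrix_io import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "CohortConfig",
    "simulate_expression",
    "simulate_cohorts",
    "write_fixture_gtf",
    "load_config",
]


@dataclass
class SimulationConfig:
    """Knobs of the single-cohort generator.

    ``baseline_tpm`` is the housekeeping mean; specific transcripts draw
    ``baseline_tpm * fold_change`` in their dominant type and
    ``baseline_tpm / fold_change`` elsewhere.  ``noise_sigma`` is the SD of
    the multiplicative log-normal noise on the log2 scale.
    """

    n_types: int = 10
    samples_per_type: int | Sequence[int] = 20
    n_housekeeping: int = 200
    n_specific_per_type: int = 5
    n_shared: int = 30
    n_silent: int = 20
    baseline_tpm: float = 10.0
    fold_change: float = 8.0
    noise_sigma: float = 0.25
    dropout_prob: float = 0.0
    context: str = "tissue"
    type_prefix: str = "type"
    seed: int = 0

    def validate(self) -> None:
        if self.n_types < 2:
            raise ValueError("need at least 2 types")
        for name in ("n_housekeeping", "n_specific_per_type", "n_shared", "n_silent"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.baseline_tpm <= 0:
            raise ValueError("baseline_tpm must be positive")

    def samples_for(self, i: int) -> int:
        if isinstance(self.samples_per_type, (int, np.integer)):
            return int(self.samples_per_type)
        return int(self.samples_per_type[i])


def _apply_noise(
    means: np.ndarray, rng: np.random.Generator, sigma: float, dropout: float
) -> np.ndarray:
    vals = means * np.exp2(rng.normal(0.0, sigma, size=means.shape)) if sigma > 0 else means.copy()
    if dropout > 0:
        vals[rng.random(means.shape) < dropout] = 0.0
    return vals


def _assign_genes(transcript_ids: Sequence[str], rng: np.random.Generator) -> dict[str, str]:
    """Group transcripts into genes of 1-4 members, in randomised order."""
    order = list(transcript_ids)
    rng.shuffle(order)
    tx2gene: dict[str, str] = {}
    g = 0
    i = 0
    while i < len(order):
        size = int(rng.integers(1, 5))
        for tid in order[i : i + size]:
            tx2gene[tid] = f"G{g:05d}"
        g += 1
        i += size
    return tx2gene


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate one cohort and its planted truth table.

    Returns ``(matrix, truth)`` where ``truth`` has one row per transcript
    with columns ``transcript_id``, ``class`` (housekeeping | specific |
    shared | silent), ``specific_type`` (dominant type for specific
    transcripts, else empty), ``shared_types`` (comma-joined) and ``gene_id``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    types = [f"{config.type_prefix}{i + 1:02d}" for i in range(config.n_types)]
    b, f = config.baseline_tpm, config.fold_change

    tx_rows: list[tuple[str, str, str, str]] = []  # (class, specific_type, shared_types)
    mean_rows: list[np.ndarray] = []

    def add(cls: str, spec: str, shared: str, means: np.ndarray) -> None:
        tid = f"TX{len(tx_rows):05d}"
        tx_rows.append((tid, cls, spec, shared))
        mean_rows.append(means)

    for _ in range(config.n_housekeeping):
        add("housekeeping", "", "", np.full(config.n_types, b))
    for k, t in enumerate(types):
        for _ in range(config.n_specific_per_type):
            m = np.full(config.n_types, b / f)
            m[k] = b * f
            add("specific", t, "", m)
    for _ in range(config.n_shared):
        size = int(rng.integers(2, 4))
        subset = sorted(rng.choice(config.n_types, size=size, replace=False))
        m = np.full(config.n_types, b / f)
        m[subset] = b * f
        add("shared", "", ",".join(types[j] for j in subset), m)
    for _ in range(config.n_silent):
        add("silent", "", "", np.zeros(config.n_types))

    tids = [r[0] for r in tx_rows]
    mean_by_type = np.vstack(mean_rows) if mean_rows else np.zeros((0, config.n_types))

    cols: list[str] = []
    stypes: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    for i, t in enumerate(types):
        ns = config.samples_for(i)
        means = np.repeat(mean_by_type[:, i : i + 1], ns, axis=1)
        blocks.append(_apply_noise(means, rng, config.noise_sigma, config.dropout_prob))
        for j in range(ns):
            s = f"{t}_s{j + 1:03d}"
            cols.append(s)
            stypes[s] = t
    values = pd.DataFrame(np.hstack(blocks), index=tids, columns=cols)

    tx2gene = _assign_genes(tids, rng)
    truth = pd.DataFrame(
        {
            "transcript_id": tids,
            "class": [r[1] for r in tx_rows],
            "specific_type": [r[2] for r in tx_rows],
            "shared_types": [r[3] for r in tx_rows],
            "gene_id": [tx2gene[t] for t in tids],
        }
    )
    m = ExpressionMatrix(
        values,
        pd.Series(stypes),
        pd.Series({s: config.context for s in cols}),
    )
    return m, truth


@dataclass
class CohortConfig:
    """Knobs of the paired tumor/normal cohort generator.

    Cancer types ``C01..`` originate one-to-one from tissues ``T01..``; a
    ``testis`` tissue is always appended.  Each cancer gets
    ``n_markers_per_cancer`` tumor-only cancer-specific transcripts whose
    normal-tissue fate is drawn from the overlap fractions: tissue-specific
    in the matched tissue, in testis, in another tissue, or tissue-silent
    (the remainder).  Dual-specific markers are planted at ``low_tpm``
    (below the 0.1 TPM expressed threshold) so they stay tumor-only in the
    absolute sense while their tissue expression *ratios* remain sharply
    concentrated — specificity is scale-invariant.  Confounders are specific
    in the next cancer type but expressed in the target cancer too.
    """

    n_cancer_types: int = 5
    tumor_samples_per_type: int = 10
    normal_samples_per_type: int = 10
    n_markers_per_cancer: int = 20
    n_housekeeping: int = 100
    n_confounders_per_cancer: int = 0
    frac_matched: float = 0.3
    frac_testis: float = 0.15
    frac_other: float = 0.15
    baseline_tpm: float = 10.0
    fold_change: float = 8.0
    low_tpm: float = 0.04
    low_background: float = 0.0005
    noise_sigma: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_cancer_types < 2:
            raise ValueError("need at least 2 cancer types")
        for name in ("frac_matched", "frac_testis", "frac_other"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_matched + self.frac_testis + self.frac_other > 1.0 + 1e-12:
            raise ValueError("overlap fractions exceed 1")
        if self.fold_change < 1 or self.baseline_tpm <= 0:
            raise ValueError("fold_change must be >= 1 and baseline_tpm positive")
        if self.low_tpm <= 0 or self.low_tpm >= 0.1:
            raise ValueError("low_tpm must lie in (0, 0.1) to stay below the expressed threshold")


def simulate_cohorts(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, OriginMap]:
    """Generate paired tumor and normal cohorts sharing a transcript universe.

    Returns ``(tumor, normal, truth, origin_map)``.  ``truth`` has columns
    ``transcript_id``, ``role`` (housekeeping | marker | confounder),
    ``cancer_type`` (candidate list the transcript belongs to),
    ``specific_cancer`` (where it is planted cancer-specific),
    ``tissue_fate`` (matched | testis | other | silent | none) and
    ``tissue_type`` (the planted tissue), plus ``gene_id``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cancer_types
    cancers = [f"C{i + 1:02d}" for i in range(n)]
    tissues = [f"T{i + 1:02d}" for i in range(n)] + ["testis"]
    origin = OriginMap({c: tissues[i] for i, c in enumerate(cancers)})
    n_tissue = len(tissues)
    b, f = config.baseline_tpm, config.fold_change

    rows: list[dict[str, str]] = []
    tumor_means: list[np.ndarray] = []
    normal_means: list[np.ndarray] = []

    def add(role: str, cancer: str, spec_cancer: str, fate: str, tissue: str,
            tmean: np.ndarray, nmean: np.ndarray) -> None:
        rows.append(
            {
                "transcript_id": f"TX{len(rows):05d}",
                "role": role,
                "cancer_type": cancer,
                "specific_cancer": spec_cancer,
                "tissue_fate": fate,
                "tissue_type": tissue,
            }
        )
        tumor_means.append(tmean)
        normal_means.append(nmean)

    for _ in range(config.n_housekeeping):
        add("housekeeping", "", "", "none", "",
            np.full(n, b), np.full(n_tissue, b))

    nm = config.n_markers_per_cancer
    n_matched = int(round(config.frac_matched * nm))
    n_testis = int(round(config.frac_testis * nm))
    n_other = int(round(config.frac_other * nm))
    if n_matched + n_testis + n_other > nm:
        raise ValueError("rounded overlap counts exceed the marker count")
    fates = (["matched"] * n_matched + ["testis"] * n_testis
             + ["other"] * n_other + ["silent"] * (nm - n_matched - n_testis - n_other))

    for ci, c in enumerate(cancers):
        for fate in fates:
            tmean = np.zeros(n)
            tmean[ci] = b * f
            nmean = np.zeros(n_tissue)
            tissue = ""
            if fate == "matched":
                tissue = tissues[ci]
            elif fate == "testis":
                tissue = "testis"
            elif fate == "other":
                others = [t for j, t in enumerate(tissues) if j != ci and t != "testis"]
                tissue = str(rng.choice(others))
            if tissue:
                nmean[:] = config.low_background
                nmean[tissues.index(tissue)] = config.low_tpm
            add("marker", c, c, fate, tissue, tmean, nmean)
        for _ in range(config.n_confounders_per_cancer):
            other_ci = (ci + 1) % n
            tmean = np.zeros(n)
            tmean[other_ci] = b * f
            tmean[ci] = b
            add("confounder", c, cancers[other_ci], "silent", "",
                tmean, np.zeros(n_tissue))

    tids = [r["transcript_id"] for r in rows]
    tumor_mean_mat = np.vstack(tumor_means)
    normal_mean_mat = np.vstack(normal_means)

    def build(mean_mat: np.ndarray, labels: list[str], nsamp: int, context: str) -> ExpressionMatrix:
        cols, stypes, blocks = [], {}, []
        for i, t in enumerate(labels):
            means = np.repeat(mean_mat[:, i : i + 1], nsamp, axis=1)
            blocks.append(_apply_noise(means, rng, config.noise_sigma, 0.0))
            for j in range(nsamp):
                s = f"{t}_s{j + 1:03d}"
                cols.append(s)
                stypes[s] = t
        values = pd.DataFrame(np.hstack(blocks), index=tids, columns=cols)
        return ExpressionMatrix(
            values, pd.Series(stypes), pd.Series({s: context for s in cols})
        )

    tumor = build(tumor_mean_mat, cancers, config.tumor_samples_per_type, "tumor")
    normal = build(normal_mean_mat, tissues, config.normal_samples_per_type, "tissue")

    tx2gene = _assign_genes(tids, rng)
    truth = pd.DataFrame(rows)
    truth["gene_id"] = [tx2gene[t] for t in tids]
    return tumor, normal, truth, origin


def write_fixture_gtf(
    transcript_ids: Iterable[str] | pd.DataFrame,
    path: str | Path,
    seed: int = 0,
    max_exons: int = 25,
) -> dict[str, tuple[int, int]]:
    """Write a small valid GTF with random exon structures for the given transcripts.

    Accepts an iterable of transcript ids or a truth table with a
    ``transcript_id`` column.  Returns the generator's bookkeeping:
    ``{transcript_id: (exon_count, summed_exon_length)}``.
    """
    if isinstance(transcript_ids, pd.DataFrame):
        ids = list(transcript_ids["transcript_id"])
    else:
        ids = list(transcript_ids)
    rng = np.random.default_rng(seed)
    record: dict[str, tuple[int, int]] = {}
    with open(path, "w") as fh:
        pos = 1000
        for tid in ids:
            n_exons = int(rng.integers(1, max_exons + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            chrom = f"chr{int(rng.integers(1, 23))}"
            exons = []
            start = pos
            for _ in range(n_exons):
                length = int(rng.integers(50, 301))
                exons.append((pos, pos + length - 1))
                pos += length + int(rng.integers(50, 501))
            end = exons[-1][1]
            attrs = f'gene_id "{tid}_gene"; transcript_id "{tid}";'
            fh.write(
                f"{chrom}\tsrtkit_sim\ttranscript\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )
            for es, ee in exons:
                fh.write(f"{chrom}\tsrtkit_sim\texon\t{es}\t{ee}\t.\t{strand}\t.\t{attrs}\n")
            record[tid] = (n_exons, sum(e - s + 1 for s, e in exons))
            pos += 5000
    return record


_BOOL = {"true": True, "false": False, "yes": True, "no": False}


def load_config(path: str | Path, kind: str = "simulation") -> SimulationConfig | CohortConfig:
    """Load a flat ``key: value`` config file into a config dataclass.

    Unknown keys raise; values are coerced to the field's type.  ``kind`` is
    ``"simulation"`` or ``"cohort"``.
    """
    cls = SimulationConfig if kind == "simulation" else CohortConfig
    field_types = {f.name: f.type for f in fields(cls)}
    kwargs: dict[str, object] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key: value'")
        key, raw = (s.strip() for s in line.split(":", 1))
        if key not in field_types:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        if raw.lower() in _BOOL:
            kwargs[key] = _BOOL[raw.lower()]
        else:
            try:
                kwargs[key] = int(raw)
            except ValueError:
                try:
                    kwargs[key] = float(raw)
                except ValueError:
                    kwargs[key] = raw
    return cls(**kwargs)  # type: ignore[arg-type]
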