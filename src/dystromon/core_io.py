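"""Data model, file I/O, configuration and validation shared by all pipeline stages.

The universal pipeline input is a gene-by-sample integer count matrix
(:class:`CountMatrix`) plus a sample metadata table (a plain pandas DataFrame
with a documented set of columns, see :func:`validate_sample_table`).
All tabular I/O is tab-separated UTF-8 text.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("dystromon")

GENE_COLUMN = "gene_id"

#: Metadata columns understood by the pipeline stages.  Only ``sample_id`` is
#: mandatory; longitudinal stages additionally require ``subject_id``,
#: ``group`` and ``timepoint``.
SAMPLE_COLUMNS = ("sample_id", "subject_id", "group", "timepoint", "treatment", "age")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass(frozen=True)
class CountMatrix:
    """Integer gene x sample count matrix.

    Invariants (enforced at construction): counts is a non-negative integer
    matrix with one row per gene and one column per sample; gene and sample
    identifiers are unique; ``lib_sizes`` are exactly the column sums.
    """

    gene_ids: tuple
    sample_ids: tuple
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                bad = np.argwhere(counts != np.floor(counts))[0]
                raise ValidationError(
                    f"non-integer count for gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count for gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                seen, dups = set(), set()
                for i in ids:
                    if i in seen:
                        dups.add(i)
                    seen.add(i)
                raise ValidationError(f"duplicate {name} ids: {sorted(dups)}")
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def lib_sizes(self) -> np.ndarray:
        """Per-sample column sums of the raw counts."""
        return self.counts.sum(axis=0)

    @property
    def shape(self):
        return self.counts.shape

    def subset_genes(self, keep) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in keep], dtype=int)
        return CountMatrix(
            tuple(self.gene_ids[i] for i in idx), self.sample_ids, self.counts[idx]
        )

    def subset_samples(self, sample_ids) -> "CountMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return CountMatrix(self.gene_ids, tuple(sample_ids), self.counts[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.gene_ids), columns=list(self.sample_ids))


def read_counts(path, fmt: str = "tsv") -> CountMatrix:
    """Read a count matrix from a TSV file (first column ``gene_id``).

    Rejects malformed headers, duplicate identifiers and negative or
    non-integer entries (the offending gene and sample are named).
    """
    if fmt != "tsv":
        raise ValueError(f"unsupported format {fmt!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.columns[0] != GENE_COLUMN:
        raise ValidationError(
            f"{path}: first header field must be {GENE_COLUMN!r}, got {df.columns[0]!r}"
        )
    genes = tuple(df.iloc[:, 0])
    samples = tuple(df.columns[1:])
    body = df.iloc[:, 1:]
    try:
        values = body.astype(np.float64).to_numpy()
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric count entry ({exc})") from None
    cm = CountMatrix(genes, samples, values)  # integrality/negativity checked there
    logger.info("read_counts: %s -> %d genes x %d samples", path, *cm.shape)
    return cm


def write_counts(cm: CountMatrix, path) -> None:
    df = cm.to_frame()
    df.index.name = GENE_COLUMN
    df.to_csv(path, sep="\t")


def validate_sample_table(st: pd.DataFrame, longitudinal: bool = False) -> pd.DataFrame:
    """Validate a sample metadata table.

    ``sample_id`` values must be unique; in a longitudinal table the
    (subject_id, timepoint) pairs must also be unique.
    """
    if "sample_id" not in st.columns:
        raise ValidationError("sample table lacks a 'sample_id' column")
    if st["sample_id"].duplicated().any():
        dups = sorted(st.loc[st["sample_id"].duplicated(), "sample_id"])
        raise ValidationError(f"duplicate sample ids in metadata: {dups}")
    if longitudinal:
        for col in ("subject_id", "timepoint"):
            if col not in st.columns:
                raise ValidationError(f"longitudinal sample table lacks {col!r}")
        if st.duplicated(subset=["subject_id", "timepoint"]).any():
            raise ValidationError("duplicate (subject_id, timepoint) pairs")
    return st


def align_dataset(cm: CountMatrix, st: pd.DataFrame):
    """Join a count matrix with its metadata, ordered by the count matrix.

    Metadata rows without a matching sample are dropped with a warning;
    samples without metadata are an error (listing the missing ids).
    """
    validate_sample_table(st)
    have = set(st["sample_id"])
    missing = [s for s in cm.sample_ids if s not in have]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing}")
    extra = sorted(have - set(cm.sample_ids))
    if extra:
        logger.warning("align_dataset: dropping %d unmatched metadata rows: %s", len(extra), extra)
    st = st.set_index("sample_id").loc[list(cm.sample_ids)].reset_index()
    return cm, st


@dataclass
class AnalysisConfig:
    """Pipeline-wide settings; serializable to/from YAML round-trip identically."""

    min_cpm: float = 5.0
    min_frac: float = 0.10
    network_min_cpm: float = 10.0
    network_min_frac: float = 0.40
    tmm_trim_m: float = 0.30
    tmm_trim_a: float = 0.05
    voom_span: float = 0.5
    lmm_tol: float = 1e-8
    soft_powers: tuple = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)
    scale_free_r2: float = 0.8
    cut_height: float = 0.95
    min_module_size: int = 30
    merge_cutoff: float = 0.75
    fdr_level: float = 0.05
    display_threshold: float = 0.5
    edge_quantile: float = 0.05
    excluded_samples: tuple = ()
    seed: int = 13154

    def __post_init__(self):
        if not (0 < self.min_frac <= 1 and 0 < self.network_min_frac <= 1):
            raise ValidationError("sample fractions must lie in (0, 1]")
        if not (0 <= self.tmm_trim_m < 0.5 and 0 <= self.tmm_trim_a < 0.5):
            raise ValidationError("trim fractions must lie in [0, 0.5)")
        if not 0 < self.fdr_level < 1:
            raise ValidationError("fdr_level must lie in (0, 1)")
        if not 0 < self.cut_height <= 1:
            raise ValidationError("cut_height must lie in (0, 1]")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["soft_powers"] = list(self.soft_powers)
        d["excluded_samples"] = list(self.excluded_samples)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["soft_powers"] = tuple(d.get("soft_powers", cls.soft_powers))
        d["excluded_samples"] = tuple(d.get("excluded_samples", ()))
        return cls(**d)


def write_results(table: pd.DataFrame, path, sort_by=None) -> None:
    """Write a result table as TSV with floats at 6 significant digits.

    Row order is deterministic: by BH-adjusted p-value when present (ties broken
    lexicographically by gene id), otherwise the caller-specified ``sort_by``.
    """
    df = table.copy()
    keys = []
    if sort_by is not None:
        keys = list(sort_by)
    else:
        adj = [c for c in df.columns if c in ("adj_p", "fdr", "padj")]
        if adj:
            keys = [adj[0]]
        if GENE_COLUMN in df.columns:
            keys.append(GENE_COLUMN)
    if keys:
        df = df.sort_values(keys, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    logger.info("write_results: %s (%d rows)", path, len(df))


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
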