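"""Expression-matrix data model, TSV I/O, gene intersection and quantile normalization.

Matrices are genes x samples, tab-separated, first column gene identifiers,
header row sample identifiers.  Labels are a two-column TSV mapping sample id
to class name; class names are mapped onto the internal POSITIVE/NEGATIVE
labels (default: COPD -> POSITIVE, ILD -> NEGATIVE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

POSITIVE = "POSITIVE"
NEGATIVE = "NEGATIVE"

DEFAULT_LABEL_MAP = {"COPD": POSITIVE, "ILD": NEGATIVE}


def _find_duplicates(ids) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    return dups


@dataclass
class ExpressionMatrix:
    """Real-valued genes x samples matrix with optional binary class labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        dup_g = _find_duplicates(self.gene_ids)
        if dup_g:
            raise ValueError(f"duplicate gene identifiers: {dup_g}")
        dup_s = _find_duplicates(self.sample_ids)
        if dup_s:
            raise ValueError(f"duplicate sample identifiers: {dup_s}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if np.isnan(self.values).any():
            raise ValueError("values contain missing entries")
        if self.labels is not None:
            unknown = set(self.labels) - set(self.sample_ids)
            if unknown:
                raise ValueError(f"labels reference unknown samples: {sorted(unknown)}")
            missing = set(self.sample_ids) - set(self.labels)
            if missing:
                raise ValueError(f"samples without a label: {sorted(missing)}")
            bad = {v for v in self.labels.values() if v not in (POSITIVE, NEGATIVE)}
            if bad:
                raise ValueError(f"invalid label values: {sorted(bad)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def label_vector(self) -> np.ndarray:
        """Binary label vector aligned with sample_ids (1 = POSITIVE)."""
        if self.labels is None:
            raise ValueError("matrix has no labels")
        return np.array([1 if self.labels[s] == POSITIVE else 0 for s in self.sample_ids])

    def class_counts(self) -> tuple[int, int]:
        """(n_positive, n_negative)."""
        y = self.label_vector()
        return int(y.sum()), int(len(y) - y.sum())

    def gene_index(self, gene_ids) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([pos[g] for g in gene_ids], dtype=int)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = self.gene_index(gene_ids)
        return ExpressionMatrix(
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[idx, :].copy(),
            labels=dict(self.labels) if self.labels is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class DatasetPair:
    """Train/test matrices sharing the same genes in the same order."""

    train: ExpressionMatrix
    test: ExpressionMatrix

    def __post_init__(self) -> None:
        if self.train.gene_ids != self.test.gene_ids:
            raise ValueError("train and test gene_ids differ (run intersect_genes first)")
        overlap = set(self.train.sample_ids) & set(self.test.sample_ids)
        if overlap:
            raise ValueError(f"train and test share sample ids: {sorted(overlap)}")


def read_expression_matrix(
    path,
    label_path=None,
    label_map: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Load a genes x samples TSV; rows with any missing/non-numeric cell are dropped."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]  # pandas mangles duplicate columns, so check the raw header
    dup_s = _find_duplicates(sample_ids)
    if dup_s:
        raise ValueError(f"duplicate sample identifiers in {path}: {dup_s}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.columns = sample_ids
    gene_ids = [str(g) for g in df.index]
    dup_g = _find_duplicates(gene_ids)
    if dup_g:
        raise ValueError(f"duplicate gene identifiers in {path}: {dup_g}")

    num = df.apply(pd.to_numeric, errors="coerce")
    keep = ~num.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d gene rows with missing/non-numeric values", n_dropped)
    num = num.loc[keep]

    labels = None
    if label_path is not None:
        labels = read_labels(label_path, sample_ids, label_map=label_map)
    return ExpressionMatrix(
        gene_ids=[str(g) for g in num.index],
        sample_ids=sample_ids,
        values=num.to_numpy(dtype=float),
        labels=labels,
    )


def read_labels(path, sample_ids, label_map: dict[str, str] | None = None) -> dict[str, str]:
    """Read a two-column sample_id<TAB>label file and map class names to POSITIVE/NEGATIVE."""
    if label_map is None:
        label_map = DEFAULT_LABEL_MAP
    tab = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "label"], dtype=str)
    known = set(sample_ids)
    labels: dict[str, str] = {}
    for sid, lab in zip(tab["sample_id"], tab["label"]):
        if sid not in known:
            raise ValueError(f"label file references unknown sample: {sid}")
        if lab not in label_map:
            raise ValueError(f"unknown class name {lab!r}; expected one of {sorted(label_map)}")
        labels[str(sid)] = label_map[lab]
    return labels


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def write_labels(m: ExpressionMatrix, path, label_map: dict[str, str] | None = None) -> None:
    """Write labels back to class names (inverse of the load-time mapping)."""
    if m.labels is None:
        raise ValueError("matrix has no labels")
    if label_map is None:
        label_map = DEFAULT_LABEL_MAP
    inverse = {v: k for k, v in label_map.items()}
    with open(path, "w") as fh:
        for s in m.sample_ids:
            fh.write(f"{s}\t{inverse[m.labels[s]]}\n")


def intersect_genes(a: ExpressionMatrix, b: ExpressionMatrix) -> DatasetPair:
    """Restrict both matrices to their shared genes, lexicographically ordered."""
    common = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not common:
        raise ValueError("empty gene intersection between the two matrices")
    logger.info("gene intersection size: %d", len(common))
    return DatasetPair(train=a.subset_genes(common), test=b.subset_genes(common))


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to share the cross-sample mean empirical distribution.

    Each column's value at rank r is replaced by the mean over columns of the
    r-th order statistic; ties within a column receive the mean of the rank
    means they span.
    """
    v = m.values
    if v.shape[0] == 1 or v.shape[1] == 1:
        return ExpressionMatrix(m.gene_ids, m.sample_ids, v.copy(),
                                dict(m.labels) if m.labels is not None else None)
    rank_means = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v, dtype=float)
    for j in range(v.shape[1]):
        # fractional ranks (ties=average), 0-based
        r = rankdata(v[:, j], method="average") - 1.0
        lo = np.floor(r).astype(int)
        hi = np.ceil(r).astype(int)
        out[:, j] = 0.5 * (rank_means[lo] + rank_means[hi])
    return ExpressionMatrix(m.gene_ids, m.sample_ids, out,
                            dict(m.labels) if m.labels is not None else None)
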