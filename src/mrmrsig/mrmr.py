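"""Minimal-redundancy maximal-relevance (mRMR) gene ranking.

Expression values are discretized per gene into three states by z-score
thresholding, after which relevance and redundancy are measured with plug-in
mutual information.  Ranking is greedy forward selection under either the
difference (MID) or quotient (MIQ) objective:

    MID:  argmax_g  I(g, t) - mean_{s in selected} I(g, s)
    MIQ:  argmax_g  I(g, t) / mean_{s in selected} I(g, s)

Ties are broken toward the lexicographically earlier gene id, so the ranking
is independent of input row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel_io import ExpressionMatrix

MID = "MID"
MIQ = "MIQ"


@dataclass
class DiscretizedMatrix:
    """Three-state (-1/0/+1) version of an expression matrix."""

    gene_ids: list[str]
    sample_ids: list[str]
    states: np.ndarray
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("states shape does not match gene/sample ids")
        if not np.isin(self.states, (-1, 0, 1)).all():
            raise ValueError("states must be in {-1, 0, +1}")

    def label_vector(self) -> np.ndarray:
        from .datamodel_io import POSITIVE

        if self.labels is None:
            raise ValueError("matrix has no labels")
        return np.array([1 if self.labels[s] == POSITIVE else 0 for s in self.sample_ids])


@dataclass
class RankedGeneList:
    """mRMR ranking: ordered (gene_id, score) entries under a MID/MIQ criterion."""

    entries: list[tuple[str, float]]
    criterion: str = MID

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    def top(self, k: int) -> list[str]:
        return self.gene_ids[:k]

    def __len__(self) -> int:
        return len(self.entries)


def discretize(m: ExpressionMatrix, k_sd: float = 1.0) -> DiscretizedMatrix:
    """Per-gene z-score across samples, then threshold at +/- k_sd.

    Zero-variance genes map to all-zero states.
    """
    if m.n_samples < 2:
        raise ValueError("discretization requires at least 2 samples")
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    mu = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, keepdims=True)  # population SD (ddof=0)
    states = np.zeros(m.values.shape, dtype=np.int8)
    nz = (sd > 0).ravel()
    z = np.zeros_like(m.values)
    z[nz, :] = (m.values[nz, :] - mu[nz, :]) / sd[nz, :]
    states[z > k_sd] = 1
    states[z < -k_sd] = -1
    return DiscretizedMatrix(
        gene_ids=list(m.gene_ids),
        sample_ids=list(m.sample_ids),
        states=states,
        labels=dict(m.labels) if m.labels is not None else None,
    )


def mutual_information(x, y, base: float = 2.0) -> float:
    """Plug-in mutual information between two equal-length discrete vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("empty vectors")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.zeros((nx, ny))
    np.add.at(joint, (xi, yi), 1.0)
    return _mi_from_counts(joint, base)


def _mi_from_counts(joint: np.ndarray, base: float) -> float:
    n = joint.sum()
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log(pxy / (px * py))
    mi = float(np.nansum(terms)) / np.log(base)
    return max(mi, 0.0)


def entropy(x, base: float = 2.0) -> float:
    """Plug-in entropy of a discrete vector."""
    _, counts = np.unique(np.asarray(x), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum() / np.log(base))


def _mi_rows_vs_vector(states: np.ndarray, y: np.ndarray, n_y: int, base: float) -> np.ndarray:
    """MI of every row of a 3-state matrix against one discrete vector, vectorized."""
    s = states + 1  # {-1,0,1} -> {0,1,2}
    idx = s * n_y + y[np.newaxis, :]
    n_cells = 3 * n_y
    counts = np.empty((states.shape[0], n_cells))
    for c in range(n_cells):
        counts[:, c] = (idx == c).sum(axis=1)
    n = states.shape[1]
    pxy = counts / n
    px = pxy.reshape(-1, 3, n_y).sum(axis=2)  # (n_genes, 3)
    py = pxy.reshape(-1, 3, n_y).sum(axis=1)  # (n_genes, n_y)
    expected = (px[:, :, None] * py[:, None, :]).reshape(-1, n_cells)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log(pxy / expected)
    mi = np.nansum(terms, axis=1) / np.log(base)
    return np.maximum(mi, 0.0)


def mrmr_rank(
    d: DiscretizedMatrix,
    top_n: int = 500,
    criterion: str = MID,
    base: float = 2.0,
) -> RankedGeneList:
    """Greedy mRMR forward selection of ``top_n`` genes against the class label.

    Step 1 maximizes relevance I(g, t); each later step maximizes
    relevance - mean-redundancy (MID) or relevance / mean-redundancy (MIQ)
    over the not-yet-selected genes.
    """
    if criterion not in (MID, MIQ):
        raise ValueError(f"unknown criterion {criterion!r}; expected MID or MIQ")
    n_genes = len(d.gene_ids)
    if not 1 <= top_n <= n_genes:
        raise ValueError(f"top_n must be in [1, {n_genes}], got {top_n}")
    y = d.label_vector()

    # evaluate in lexicographic gene order so argmax's first-wins is the tie-break
    order = np.argsort(np.asarray(d.gene_ids, dtype=object))
    states = d.states[order, :]
    gene_ids = [d.gene_ids[i] for i in order]

    relevance = _mi_rows_vs_vector(states, y, 2, base)
    redundancy_sum = np.zeros(n_genes)
    remaining = np.ones(n_genes, dtype=bool)
    entries: list[tuple[str, float]] = []

    for step in range(top_n):
        if step == 0:
            objective = relevance.copy()
        else:
            mean_red = redundancy_sum / step
            if criterion == MID:
                objective = relevance - mean_red
            else:
                # zero mean-redundancy makes the quotient unbounded: such genes
                # win outright, falling back to the lexicographic tie-break
                with np.errstate(divide="ignore", invalid="ignore"):
                    objective = np.where(mean_red > 0, relevance / mean_red, np.inf)
        objective = np.where(remaining, objective, -np.inf)
        # ties (up to float noise in the MI sums) go to the lexicographically
        # earlier gene; rows are already in lexicographic order
        best = objective.max()
        tol = 1e-9 if np.isfinite(best) else 0.0
        pick = int(np.argmax(objective >= best - tol))
        score = float(objective[pick])
        if not np.isfinite(score):
            score = float(relevance[pick])
        entries.append((gene_ids[pick], score))
        remaining[pick] = False
        if step + 1 < top_n:
            picked_states = states[pick, :] + 1  # shift to {0,1,2}
            redundancy_sum += _mi_rows_vs_vector(states, picked_states, 3, base)
    return RankedGeneList(entries=entries, criterion=criterion)


def write_ranked(ranked: RankedGeneList, path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tgene_id\tscore\n")
        for i, (g, s) in enumerate(ranked.entries, start=1):
            fh.write(f"{i}\t{g}\t{s:.6g}\n")


def read_ranked(path) -> RankedGeneList:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return RankedGeneList(
        entries=[(str(g), float(s)) for g, s in zip(df["gene_id"], df["score"])]
    )
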