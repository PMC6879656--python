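"""Analysis artifacts: signature heatmap with hierarchical clustering and run report."""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from .datamodel_io import DatasetPair
from .ifs_classify import ConfusionMatrix, SignatureSelection, metrics

VALID_LINKAGE = ("average", "complete", "ward")
VALID_DISTANCE = ("euclidean", "correlation")


@dataclass
class ClusteringResult:
    sample_order: list[str]
    gene_order: list[str]
    linkage: str
    distance: str
    purity: float


def _leaf_order(Z) -> list[int]:
    return dendrogram(Z, no_plot=True)["leaves"]


def cluster_heatmap(
    pair: DatasetPair,
    genes,
    distance: str = "correlation",
    linkage: str = "average",
    image_path=None,
) -> ClusteringResult:
    """Cluster combined train+test samples on the signature genes.

    The combined matrix is per-gene z-scored for display only; purity is the
    best label agreement of a two-cluster cut of the sample dendrogram.
    """
    if distance not in VALID_DISTANCE:
        raise ValueError(f"distance must be one of {VALID_DISTANCE}")
    if linkage not in VALID_LINKAGE:
        raise ValueError(f"linkage must be one of {VALID_LINKAGE}")
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to cluster")
    tr = pair.train.subset_genes(genes)
    te = pair.test.subset_genes(genes)
    combined = np.hstack([tr.values, te.values])
    sample_ids = tr.sample_ids + te.sample_ids
    if combined.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    y = np.r_[tr.label_vector(), te.label_vector()]

    mu = combined.mean(axis=1, keepdims=True)
    sd = combined.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    display = (combined - mu) / sd

    if linkage == "ward":
        Zs = scipy_linkage(display.T, method="ward")
        Zg = scipy_linkage(display, method="ward")
    else:
        Zs = scipy_linkage(pdist(display.T, metric=distance), method=linkage)
        Zg = scipy_linkage(pdist(display, metric=distance), method=linkage)

    two_cut = fcluster(Zs, t=2, criterion="maxclust")
    in1 = two_cut == 1
    agree = max(
        int((y[in1] == 1).sum() + (y[~in1] == 0).sum()),
        int((y[in1] == 0).sum() + (y[~in1] == 1).sum()),
    )
    purity = agree / len(y)

    s_order = _leaf_order(Zs)
    g_order = _leaf_order(Zg)
    result = ClusteringResult(
        sample_order=[sample_ids[i] for i in s_order],
        gene_order=[genes[i] for i in g_order],
        linkage=linkage,
        distance=distance,
        purity=purity,
    )
    if image_path is not None:
        _draw_heatmap(display[np.ix_(g_order, s_order)], result, y[s_order], image_path)
    return result


def _draw_heatmap(display, result: ClusteringResult, labels01, image_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_lab, ax) = plt.subplots(
        2, 1, figsize=(10, 6), height_ratios=[1, 24], sharex=True
    )
    ax_lab.imshow(labels01[np.newaxis, :], aspect="auto", cmap="coolwarm", interpolation="nearest")
    ax_lab.set_yticks([])
    ax_lab.set_title("class (red = positive)")
    im = ax.imshow(display, aspect="auto", cmap="RdBu_r",
                   vmin=-3, vmax=3, interpolation="nearest")
    ax.set_xlabel("samples (clustered)")
    ax.set_ylabel("signature genes (clustered)")
    if len(result.gene_order) <= 60:
        ax.set_yticks(range(len(result.gene_order)))
        ax.set_yticklabels(result.gene_order, fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.6, label="per-gene z-score")
    fig.tight_layout()
    fig.savefig(image_path, dpi=120)
    plt.close(fig)


REPORT_STAGES = ("config", "n_common_genes", "selection", "train_cm", "test_cm", "clustering")


def build_report(
    config: dict,
    n_common_genes: int,
    selection: SignatureSelection,
    train_cm: ConfusionMatrix,
    test_cm: ConfusionMatrix,
    clustering: ClusteringResult,
) -> dict:
    """Assemble the machine-readable run report."""
    for name, value in zip(
        REPORT_STAGES, (config, n_common_genes, selection, train_cm, test_cm, clustering)
    ):
        if value is None:
            raise ValueError(f"missing stage output: {name}")
    train_m = metrics(train_cm).rounded()
    test_m = metrics(test_cm).rounded()
    priors = _class_priors(train_cm, test_cm)
    uninformative = clustering.purity < max(priors) + 0.05
    return {
        "config": config,
        "n_common_genes": n_common_genes,
        "chosen_k": selection.chosen_k,
        "argmax_k": selection.argmax_k,
        "floor_unmet": selection.floor_unmet,
        "train": {**train_cm.as_dict(),
                  "acc": train_m.acc, "sn": train_m.sn, "sp": train_m.sp},
        "test": {**test_cm.as_dict(),
                 "acc": test_m.acc, "sn": test_m.sn, "sp": test_m.sp},
        "clustering": {
            "distance": clustering.distance,
            "linkage": clustering.linkage,
            "purity": round(clustering.purity, 4),
            "uninformative_clustering": bool(uninformative),
        },
    }


def _class_priors(train_cm: ConfusionMatrix, test_cm: ConfusionMatrix) -> tuple[float, float]:
    pos = train_cm.tp + train_cm.fn + test_cm.tp + test_cm.fn
    neg = train_cm.fp + train_cm.tn + test_cm.fp + test_cm.tn
    total = pos + neg
    return pos / total, neg / total


def write_report(report: dict, json_path, text_path=None, timestamp: bool = True) -> None:
    """Write the JSON report plus an optional human-readable summary."""
    out = dict(report)
    if timestamp:
        out["generated_at"] = datetime.now(timezone.utc).isoformat()
    with open(json_path, "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(_summary_text(report))


def _summary_text(r: dict) -> str:
    lines = [
        "signature selection run summary",
        "===============================",
        f"common genes: {r['n_common_genes']}",
        f"chosen signature size k = {r['chosen_k']} (curve argmax k = {r['argmax_k']})",
        f"train LOOCV: acc={r['train']['acc']} sn={r['train']['sn']} sp={r['train']['sp']}",
        f"independent test: acc={r['test']['acc']} sn={r['test']['sn']} sp={r['test']['sp']}",
        f"clustering purity: {r['clustering']['purity']} "
        f"({r['clustering']['distance']}/{r['clustering']['linkage']})",
    ]
    if r["clustering"]["uninformative_clustering"]:
        lines.append("WARNING: uninformative clustering (purity near majority-class fraction)")
    if r.get("floor_unmet"):
        lines.append("WARNING: no curve point reached the accuracy floor; argmax k reported")
    return "\n".join(lines) + "\n"
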