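"""Result-analysis visualizations.

Eight plot kinds cover the standard views on a run: ROC and PR curves,
a radar map and a histogram of per-model metrics, a Pearson-correlation
heatmap of base-model score columns (complementarity), a score
distribution histogram, the contribution pie of the integrated ranker,
a similarity network above a score cutoff, and 3-D t-SNE scatter
projections of the input embeddings and of the per-pair score vectors.
Every figure also writes its underlying data table next to the image,
so any plotted number can be regenerated from the manifest alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .metrics import ScoredLabeledList, pr_curve_points, roc_curve_points
from .pipeline import ReportBundle

__all__ = ["PLOT_KINDS", "render_report"]

PLOT_KINDS = (
    "roc_curve",
    "pr_curve",
    "radar",
    "heatmap",
    "histogram",
    "pie",
    "network",
    "scatter3d",
)


def render_report(bundle: ReportBundle, kinds=PLOT_KINDS, score_cutoff: float | None = None) -> dict:
    """Render the requested plot kinds into the bundle's output directory.

    Returns {kind: [written file paths]}. Unknown kinds raise.
    """
    unknown = [k for k in kinds if k not in PLOT_KINDS]
    if unknown:
        raise ValueError(
            f"unknown plot kind(s) {unknown}; valid kinds: {', '.join(PLOT_KINDS)}"
        )
    out = Path(bundle.out_dir) / "plots"
    out.mkdir(parents=True, exist_ok=True)
    written: dict = {}
    for kind in kinds:
        written[kind] = globals()[f"_plot_{kind}"](bundle, out, score_cutoff)
    return written


def _test_labels(bundle: ReportBundle):
    _, ty, tg = bundle.dataset.pairs_in("test")
    return ty, tg


def _save(fig, path: Path) -> str:
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return str(path)


def _plot_roc_curve(bundle, out, _cutoff):
    ty, _ = _test_labels(bundle)
    fig, ax = plt.subplots(figsize=(5, 4))
    frames = []
    for name, (_, s) in bundle.test_scores.items():
        pts = roc_curve_points(ScoredLabeledList(np.asarray(s), ty))
        ax.plot(pts[:, 0], pts[:, 1], label=name)
        frames.append(pd.DataFrame({"model": name, "fpr": pts[:, 0], "tpr": pts[:, 1]}))
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7)
    table = out / "roc_curve.tsv"
    pd.concat(frames).to_csv(table, sep="\t", index=False)
    return [_save(fig, out / "roc_curve.png"), str(table)]


def _plot_pr_curve(bundle, out, _cutoff):
    ty, _ = _test_labels(bundle)
    fig, ax = plt.subplots(figsize=(5, 4))
    frames = []
    for name, (_, s) in bundle.test_scores.items():
        pts = pr_curve_points(ScoredLabeledList(np.asarray(s), ty))
        ax.plot(pts[:, 0], pts[:, 1], label=name)
        frames.append(
            pd.DataFrame({"model": name, "recall": pts[:, 0], "precision": pts[:, 1]})
        )
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.legend(fontsize=7)
    table = out / "pr_curve.tsv"
    pd.concat(frames).to_csv(table, sep="\t", index=False)
    return [_save(fig, out / "pr_curve.png"), str(table)]


def _plot_radar(bundle, out, _cutoff):
    table = bundle.metric_table.dropna(axis=1)
    metrics = list(table.columns)
    angles = np.linspace(0, 2 * np.pi, len(metrics), endpoint=False)
    fig, ax = plt.subplots(figsize=(5, 5), subplot_kw={"projection": "polar"})
    for model, row in table.iterrows():
        values = row.to_numpy()
        ax.plot(np.append(angles, angles[0]), np.append(values, values[0]), label=model)
    ax.set_xticks(angles)
    ax.set_xticklabels(metrics, fontsize=8)
    ax.legend(fontsize=7, loc="lower right", bbox_to_anchor=(1.2, 0))
    path = out / "radar.tsv"
    table.to_csv(path, sep="\t")
    return [_save(fig, out / "radar.png"), str(path)]


def _plot_histogram(bundle, out, _cutoff):
    """Per-model metric bars plus the score-distribution histogram."""
    table = bundle.metric_table.dropna(axis=1)
    fig, ax = plt.subplots(figsize=(6, 4))
    table.plot.bar(ax=ax)
    ax.set_ylabel("metric value")
    ax.legend(fontsize=7)
    path = out / "metric_histogram.tsv"
    table.to_csv(path, sep="\t")
    return [_save(fig, out / "metric_histogram.png"), str(path)] + _plot_score_histogram(
        bundle, out
    )


def _plot_heatmap(bundle, out, _cutoff):
    names = [n for n in bundle.test_scores if n != "integrated"]
    cols = np.column_stack([bundle.test_scores[n][1] for n in names])
    corr = np.corrcoef(cols, rowvar=False)
    corr = np.atleast_2d(corr)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(corr, vmin=-1, vmax=1, cmap="coolwarm")
    ax.set_xticks(range(len(names)), names, rotation=45, fontsize=8)
    ax.set_yticks(range(len(names)), names, fontsize=8)
    for i in range(len(names)):
        for j in range(len(names)):
            ax.text(j, i, f"{corr[i, j]:.2f}", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    path = out / "score_correlation.tsv"
    pd.DataFrame(corr, index=names, columns=names).to_csv(path, sep="\t")
    return [_save(fig, out / "score_correlation.png"), str(path)]


def _plot_pie(bundle, out, _cutoff):
    weights = bundle.weights
    fig, ax = plt.subplots(figsize=(4.5, 4))
    labels = list(weights)
    values = [weights[k] for k in labels]
    shown = [(l, v) for l, v in zip(labels, values)]
    ax.pie(
        [v for _, v in shown],
        labels=[l for l, _ in shown],
        autopct=lambda p: f"{p:.1f}%" if p > 1 else "",
        textprops={"fontsize": 8},
    )
    ax.set_title("contribution weights of integrated base models", fontsize=9)
    path = out / "contribution_pie.json"
    with path.open("w", encoding="utf-8") as fh:
        json.dump(weights, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return [_save(fig, out / "contribution_pie.png"), str(path)]


def _plot_score_histogram(bundle, out):
    fig, ax = plt.subplots(figsize=(5.5, 4))
    frames = []
    for name, (_, s) in bundle.test_scores.items():
        ax.hist(s, bins=25, histtype="step", label=name, density=True)
        frames.append(pd.DataFrame({"model": name, "score": np.asarray(s)}))
    ax.set_xlabel("similarity score")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    path = out / "score_distribution.tsv"
    pd.concat(frames).to_csv(path, sep="\t", index=False)
    return [_save(fig, out / "score_distribution.png"), str(path)]


def _plot_network(bundle, out, cutoff):
    pairs, scores = bundle.test_scores["integrated"]
    scores = np.asarray(scores)
    if cutoff is None:
        # default: the threshold that best separates test labels (F1 sweep)
        _, ty, _ = bundle.dataset.pairs_in("test")
        order = np.argsort(-scores, kind="stable")
        tp = np.cumsum(ty[order])
        k = np.arange(1, len(ty) + 1)
        f1 = 2 * tp / (k + ty.sum())
        cutoff = scores[order][max(int(np.argmax(f1)), 0)]
    G = nx.Graph()
    for (q, c), s in zip(pairs, scores):
        G.add_node(q)
        G.add_node(c)
        if s >= cutoff:
            G.add_edge(q, c, weight=float(s))
    fig, ax = plt.subplots(figsize=(6, 6))
    pos = nx.spring_layout(G, seed=bundle.config.seed)
    nx.draw_networkx(G, pos=pos, ax=ax, node_size=30, with_labels=False, width=0.5)
    ax.set_title(f"predicted similarity network (cutoff {cutoff:.3f})", fontsize=9)
    ax.axis("off")
    path = out / "network_edges.tsv"
    rows = [(u, v, d["weight"]) for u, v, d in G.edges(data=True)]
    pd.DataFrame(rows, columns=["query_id", "candidate_id", "score"]).to_csv(
        path, sep="\t", index=False
    )
    return [_save(fig, out / "network.png"), str(path)]


def _plot_scatter3d(bundle, out, _cutoff):
    from sklearn.manifold import TSNE

    written = []
    task = bundle.dataset.task
    # (a) input embeddings, colored by corpus side
    X_parts, side = [], []
    for label, corpus in (("a", task.corpus_a), ("b", task.corpus_b)):
        if corpus is None or (label == "b" and task.corpus_b is None):
            continue
        flat = corpus.values.reshape(len(corpus), -1)
        X_parts.append(flat)
        side.extend([label] * len(corpus))
    X = np.vstack(X_parts)
    # (b) per-pair base-score vectors, colored by relevance
    names = [n for n in bundle.test_scores if n != "integrated"]
    S = np.column_stack([bundle.test_scores[n][1] for n in names])
    _, ty, _ = bundle.dataset.pairs_in("test")
    for tag, data, color_labels in (
        ("embeddings", X, side),
        ("pair_scores", S, ["pos" if t else "neg" for t in ty]),
    ):
        perplexity = float(min(30, max(2, data.shape[0] // 4)))
        emb = TSNE(
            n_components=3,
            method="exact",
            random_state=bundle.config.seed,
            perplexity=perplexity,
            init="pca" if data.shape[1] >= 3 else "random",
        ).fit_transform(np.asarray(data, float))
        fig = plt.figure(figsize=(5, 4.5))
        ax = fig.add_subplot(projection="3d")
        for value in sorted(set(color_labels)):
            mask = np.asarray([c == value for c in color_labels])
            ax.scatter(emb[mask, 0], emb[mask, 1], emb[mask, 2], s=8, label=str(value))
        ax.legend(fontsize=7)
        ax.set_title(f"t-SNE of {tag} (perplexity {perplexity:g})", fontsize=9)
        table = out / f"tsne_{tag}.tsv"
        df = pd.DataFrame(emb, columns=["c1", "c2", "c3"])
        df["label"] = color_labels
        df.to_csv(table, sep="\t", index=False)
        bundle.manifest.setdefault("tsne", {})[tag] = {
            "perplexity": perplexity,
            "seed": bundle.config.seed,
        }
        written.extend([_save(fig, out / f"tsne_{tag}.png"), str(table)])
    return written
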