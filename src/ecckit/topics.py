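"""Latent-topic modeling of circle-read bin matrices.

Per-cell circle reads (those falling inside the cell's own CPRs) are counted
in fixed genomic bins (2 kb by default); the resulting cells x bins matrix
is decomposed with latent Dirichlet allocation (batch variational EM via
scikit-learn, symmetric priors alpha = 50/K and beta = 0.1, seeded). Model
selection over a topic-number grid uses the discrete second derivative of
the log-likelihood curve (elbow), with perplexity as tie-break. Topic
signature regions are the top-loading bins merged into intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import LatentDirichletAllocation

from .alignment_io import Alignment
from .cpr_detect import CPR
from .intervals import GenomicInterval, merge_intervals


@dataclass
class BinMatrix:
    """Cells x bins circle-read counts restricted to each cell's CPRs."""

    counts: pd.DataFrame              # raw integer counts
    normalized: pd.DataFrame          # per-cell total normalization
    bin_size: int
    bins: list[GenomicInterval]       # catalog, same order as columns
    excluded_cells: list[str] = field(default_factory=list)


def build_bin_matrix(
    cell_alignments: Mapping[str, Sequence[Alignment]],
    cprs_by_cell: Mapping[str, Sequence[CPR]],
    contig_lengths: Mapping[str, int],
    bin_size: int = 2000,
    excluded_contigs: Sequence[str] = ("chrM", "spike_circ", "spike_lin"),
) -> BinMatrix:
    """Count per-cell reads falling inside the cell's own CPRs into bins.

    Reads mapped outside the calling cell's CPRs are excluded, counts are
    normalized per cell total, and bins with no reads in any cell dropped.
    Cells with zero in-CPR reads are excluded (reported on the result).
    """
    contigs = [c for c in contig_lengths if c not in excluded_contigs]
    offsets: dict[str, int] = {}
    bins: list[GenomicInterval] = []
    for c in contigs:
        offsets[c] = len(bins)
        n = int(np.ceil(contig_lengths[c] / bin_size))
        bins.extend(
            GenomicInterval(c, i * bin_size, min((i + 1) * bin_size, contig_lengths[c]))
            for i in range(n)
        )

    cells = list(cell_alignments)
    counts = np.zeros((len(cells), len(bins)), dtype=np.int64)
    excluded_cells: list[str] = []
    for ci, cell in enumerate(cells):
        cprs = cprs_by_cell.get(cell, [])
        ivs_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c in cprs:
            iv = c.interval if isinstance(c, CPR) else c
            ivs_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        n_in = 0
        for a in cell_alignments[cell]:
            if not a.is_primary or a.is_duplicate or a.chrom not in offsets:
                continue
            mid = a.midpoint()
            inside = any(
                s <= mid < e for s, e in ivs_by_chrom.get(a.chrom, ())
            )
            if not inside:
                continue
            counts[ci, offsets[a.chrom] + mid // bin_size] += 1
            n_in += 1
        if n_in == 0:
            excluded_cells.append(cell)

    keep_cells = [i for i, cell in enumerate(cells) if cell not in excluded_cells]
    counts = counts[keep_cells]
    cells = [cells[i] for i in keep_cells]
    keep_bins = counts.sum(axis=0) > 0
    counts = counts[:, keep_bins]
    bins = [b for b, k in zip(bins, keep_bins) if k]

    names = [f"{b.chrom}:{b.start}-{b.end}" for b in bins]
    df = pd.DataFrame(counts, index=cells, columns=names)
    totals = df.sum(axis=1).replace(0, 1)
    return BinMatrix(
        counts=df,
        normalized=df.div(totals, axis=0),
        bin_size=bin_size,
        bins=bins,
        excluded_cells=excluded_cells,
    )


@dataclass
class TopicModel:
    """Fitted LDA decomposition of a cells x bins matrix."""

    n_topics: int
    cell_topic: pd.DataFrame   # rows sum to 1
    topic_bin: pd.DataFrame    # rows sum to 1
    log_likelihood: float
    perplexity: float
    loglik_trace: list[float] = field(default_factory=list)


def fit_lda(
    counts: pd.DataFrame | BinMatrix,
    n_topics: int,
    alpha: float | None = None,
    beta: float = 0.1,
    n_iter: int = 100,
    seed: int = 0,
) -> TopicModel:
    """Fit LDA with symmetric Dirichlet priors (alpha = 50/K unless given).

    Deterministic for a fixed seed (batch variational EM). Operates on raw
    counts; the per-cell normalization of a BinMatrix is for other analyses.
    """
    X = counts.counts if isinstance(counts, BinMatrix) else counts
    if X.empty:
        raise ValueError("empty matrix")
    if n_topics < 1 or n_topics > X.shape[1]:
        raise ValueError("n_topics must be in [1, n_bins]")
    # symmetric prior in the 50/K style, clamped to the [0, 1] range the
    # variational implementation accepts
    alpha = min(1.0, 50.0 / n_topics) if alpha is None else alpha
    lda = LatentDirichletAllocation(
        n_components=n_topics,
        doc_topic_prior=alpha,
        topic_word_prior=beta,
        learning_method="batch",
        max_iter=n_iter,
        random_state=seed,
        evaluate_every=-1,
    )
    theta = lda.fit_transform(X.to_numpy())
    theta = theta / theta.sum(axis=1, keepdims=True)
    phi = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    ll = float(lda.score(X.to_numpy()))
    return TopicModel(
        n_topics=n_topics,
        cell_topic=pd.DataFrame(
            theta, index=X.index, columns=[f"topic_{k + 1}" for k in range(n_topics)]
        ),
        topic_bin=pd.DataFrame(
            phi, index=[f"topic_{k + 1}" for k in range(n_topics)], columns=X.columns
        ),
        log_likelihood=ll,
        perplexity=float(lda.perplexity(X.to_numpy())),
        loglik_trace=[ll],
    )


def select_model(models: Sequence[TopicModel]) -> tuple[int, pd.DataFrame]:
    """Pick the topic number at the likelihood-curve elbow.

    Reports log-likelihood, its discrete second derivative and perplexity per
    grid point; the winner has the most negative curvature (sharpest drop in
    marginal gain), ties broken by lower perplexity. Needs >= 3 grid points.
    """
    if len(models) < 3:
        raise ValueError("need at least 3 grid points")
    models = sorted(models, key=lambda m: m.n_topics)
    ks = np.array([m.n_topics for m in models])
    ll = np.array([m.log_likelihood for m in models])
    px = np.array([m.perplexity for m in models])
    d2 = np.full(len(ks), np.nan)
    d2[1:-1] = ll[2:] - 2 * ll[1:-1] + ll[:-2]
    table = pd.DataFrame(
        {"n_topics": ks, "log_likelihood": ll, "second_derivative": d2, "perplexity": px}
    )
    interior = table.iloc[1:-1]
    best_curv = interior["second_derivative"].min()
    candidates = interior[np.isclose(interior["second_derivative"], best_curv)]
    best = candidates.sort_values("perplexity").iloc[0]
    return int(best["n_topics"]), table


def topic_regions(
    model: TopicModel,
    bins: Sequence[GenomicInterval],
    score_quantile: float = 0.99,
    merge_gap: int = 0,
) -> dict[str, list[GenomicInterval]]:
    """Per-topic signature regions: top-loading bins merged into intervals."""
    out: dict[str, list[GenomicInterval]] = {}
    for topic in model.topic_bin.index:
        scores = model.topic_bin.loc[topic].to_numpy()
        thr = np.quantile(scores, score_quantile)
        picked = [b for b, s in zip(bins, scores) if s >= thr]
        out[topic] = merge_intervals(picked, gap=merge_gap)
    return out


def match_signatures(
    regions: Sequence[GenomicInterval],
    annotations: Sequence[GenomicInterval],
    min_overlap: float = 0.4,
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """Pairs of (region, annotation) with reciprocal overlap >= min_overlap."""
    return [
        (r, a)
        for r in regions
        for a in annotations
        if r.reciprocal_overlap(a) >= min_overlap
    ]


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def differential_topics(
    cell_topic: pd.DataFrame,
    group_labels: Mapping[str, str] | pd.Series,
    fc_threshold: float = 2.0,
    padj_threshold: float = 0.5,
) -> pd.DataFrame:
    """Topics differing between two cell groups (rank-sum + BH).

    Fold change is the ratio of linear group means; selection requires both
    fold change > fc_threshold (either direction) and adjusted p < padj.
    """
    labels = pd.Series(group_labels)
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    ga = labels[labels == groups[0]].index
    gb = labels[labels == groups[1]].index
    if len(ga) < 3 or len(gb) < 3:
        raise ValueError("each group needs at least 3 cells")
    rows = []
    for topic in cell_topic.columns:
        a = cell_topic.loc[ga, topic].to_numpy()
        b = cell_topic.loc[gb, topic].to_numpy()
        mean_a, mean_b = a.mean(), b.mean()
        fc = mean_a / mean_b if mean_b > 0 else np.inf
        stat, p = stats.ranksums(a, b)
        rows.append(
            {"topic": topic, "mean_a": mean_a, "mean_b": mean_b, "fold_change": fc, "p_value": p}
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = benjamini_hochberg(table["p_value"])
    fc = table["fold_change"].to_numpy()
    effect = np.maximum(fc, np.divide(1.0, fc, out=np.full_like(fc, np.inf), where=fc > 0))
    table["selected"] = (effect > fc_threshold) & (table["p_adjusted"] < padj_threshold)
    return table


def dominant_topic_groups(model: TopicModel) -> pd.Series:
    """Cluster cells by their highest-weight topic."""
    return model.cell_topic.idxmax(axis=1)


def umap_embedding(model: TopicModel, seed: int = 0, **kwargs):
    """Optional seeded UMAP of the cell-topic matrix (needs umap-learn)."""
    import umap  # deferred: visualization-only extra

    reducer = umap.UMAP(random_state=seed, **kwargs)
    emb = reducer.fit_transform(model.cell_topic.to_numpy())
    return pd.DataFrame(emb, index=model.cell_topic.index, columns=["umap1", "umap2"])
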