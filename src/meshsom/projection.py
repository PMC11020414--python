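"""Projection of document sets onto a trained map, and the interpretive layer.

A document set (e.g. the Medline-indexed references of one textbook edition)
is projected by assigning each article its best matching unit; the resulting
grid positions are clustered with k-means, the cluster count is chosen by the
elbow of the within-cluster sum-of-squares curve, and each cluster is
characterized by its most frequent vocabulary terms and the member articles
that carry most of them.  95% bivariate-normal ellipses summarize cluster
footprints for cross-edition comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.cluster import KMeans

from .corpus import AnnotatedCorpus, Vocabulary
from .som import Codebook, find_bmus

logger = logging.getLogger(__name__)

__all__ = [
    "ProjectionResult",
    "WssCurve",
    "ClusterModel",
    "project",
    "kmeans_grid",
    "wss_curve",
    "elbow_select",
    "cluster_projection",
    "characterize_clusters",
    "normal_ellipse",
    "overlap_report",
    "export_projection_tsv",
    "export_density_tsv",
    "export_ellipses_tsv",
]


@dataclass(frozen=True)
class ProjectionResult:
    """Per-article BMU grid positions plus the per-node density grid."""

    article_ids: tuple[str, ...]
    rows: np.ndarray
    cols: np.ndarray
    bmu_indices: np.ndarray
    density: np.ndarray  # (R, C) integer counts
    source_label: str = ""

    @property
    def n(self) -> int:
        return len(self.article_ids)

    def points(self) -> np.ndarray:
        """(n, 2) float array of (row, col) positions, one per article."""
        return np.column_stack([self.rows, self.cols]).astype(np.float64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "article_id": self.article_ids,
                "row": self.rows,
                "col": self.cols,
                "bmu_index": self.bmu_indices,
            }
        )


@dataclass(frozen=True)
class WssCurve:
    """Within-cluster sum-of-squares for k = 1..K_max, plus the chosen elbow."""

    ks: tuple[int, ...]
    wss: tuple[float, ...]
    chosen_k: int


@dataclass(frozen=True)
class ClusterModel:
    """k-means result over grid positions, optionally enriched with
    cluster-defining terms, exemplar articles and normal ellipses."""

    k: int
    centers: np.ndarray
    labels: np.ndarray
    wss: float
    top_terms: tuple[tuple[tuple[str, int], ...], ...] = ()
    exemplars: tuple[tuple[tuple[str, int], ...], ...] = ()
    ellipses: tuple[tuple[np.ndarray, np.ndarray, float], ...] = field(
        default=(), repr=False
    )


# ---------------------------------------------------------------------------
# projection

def project(
    corpus_subset: AnnotatedCorpus,
    codebook: Codebook,
    source_label: str = "",
    check_digest: bool = True,
) -> ProjectionResult:
    """Map each article of the subset to the node best representing it."""
    if (
        check_digest
        and codebook.vocab_digest
        and corpus_subset.vocabulary.digest() != codebook.vocab_digest
    ):
        raise ValueError(
            "corpus is vectorized against a different vocabulary than the codebook"
        )
    row_sums = np.asarray(corpus_subset.matrix.sum(axis=1)).ravel()
    nonzero = row_sums > 0
    if not np.all(nonzero):
        rejected = [
            r.article_id for r, ok in zip(corpus_subset.records, nonzero) if not ok
        ]
        logger.warning("rejecting %d zero-annotation articles: %s",
                       len(rejected), rejected[:10])
        corpus_subset = corpus_subset.subset(np.flatnonzero(nonzero))
    b1, _, _, _ = find_bmus(corpus_subset.matrix, codebook)
    g = codebook.geometry
    rows, cols = np.divmod(b1, g.cols)
    density = np.zeros((g.rows, g.cols), dtype=np.int64)
    np.add.at(density, (rows, cols), 1)
    return ProjectionResult(
        article_ids=tuple(corpus_subset.article_ids),
        rows=rows,
        cols=cols,
        bmu_indices=b1,
        density=density,
        source_label=source_label,
    )


# ---------------------------------------------------------------------------
# k-means on grid positions

def kmeans_grid(
    points: np.ndarray,
    k: int,
    restarts: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd's k-means (k-means++ seeding, best of ``restarts``) on 2-D points.

    Points are raw (row, col) grid positions, duplicates retained — every
    article counts.  Deterministic given ``seed``.
    Returns (centers (k,2), labels (n,), wss).
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = np.unique(points, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds the number of distinct points ({n_distinct})"
        )
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        random_state=seed,
        algorithm="lloyd",
    ).fit(points)
    return km.cluster_centers_, km.labels_.astype(np.int64), float(km.inertia_)


def wss_curve(
    points: np.ndarray,
    k_max: int = 12,
    restarts: int = 10,
    seed: int = 0,
) -> WssCurve:
    """WSS for k = 1..k_max (capped at the number of distinct points)."""
    points = np.asarray(points, dtype=np.float64)
    n_distinct = np.unique(points, axis=0).shape[0]
    k_top = min(k_max, n_distinct)
    ks, wss = [], []
    for k in range(1, k_top + 1):
        _, _, w = kmeans_grid(points, k, restarts=restarts, seed=seed)
        ks.append(k)
        wss.append(w)
    curve = WssCurve(tuple(ks), tuple(wss), chosen_k=0)
    return replace(curve, chosen_k=elbow_select(curve))


def elbow_select(curve: WssCurve) -> int:
    """Elbow of the WSS curve: the k whose point is farthest (perpendicular)
    from the chord joining the first and last curve points; ties and
    degenerate (constant or straight-line) curves fall back to the smaller k.
    """
    ks = np.asarray(curve.ks, dtype=np.float64)
    wss = np.asarray(curve.wss, dtype=np.float64)
    if len(ks) < 3:
        warnings.warn("elbow selection needs >= 3 curve points; returning k=1")
        return 1
    p0 = np.array([ks[0], wss[0]])
    p1 = np.array([ks[-1], wss[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        warnings.warn("constant WSS curve: no elbow, returning k=1")
        return 1
    rel = np.column_stack([ks, wss]) - p0
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / norm
    best = float(dist.max())
    if best <= 1e-12:
        warnings.warn("straight-line WSS curve: no elbow, returning k=1")
        return 1
    return int(ks[int(np.argmax(dist))])


def cluster_projection(
    projection: ProjectionResult,
    k: int | None = None,
    k_max: int = 12,
    restarts: int = 10,
    seed: int = 0,
) -> tuple[ClusterModel, WssCurve]:
    """k-means over the projected article positions.

    With ``k=None`` the cluster count is elbow-selected from the WSS curve
    (scan capped at ``k_max``); a forced ``k`` reproduces a fixed layout.
    """
    pts = projection.points()
    curve = wss_curve(pts, k_max=k_max, restarts=restarts, seed=seed)
    k_use = curve.chosen_k if k is None else k
    centers, labels, wss = kmeans_grid(pts, k_use, restarts=restarts, seed=seed)
    return ClusterModel(k=k_use, centers=centers, labels=labels, wss=wss), curve


# ---------------------------------------------------------------------------
# cluster characterization

def characterize_clusters(
    model: ClusterModel,
    corpus_subset: AnnotatedCorpus,
    vocab: Vocabulary,
    top_n: int = 10,
    with_ellipses: bool = True,
    projection: ProjectionResult | None = None,
    level: float = 0.95,
) -> ClusterModel:
    """Enrich a cluster model with its defining terms and exemplar articles.

    Per cluster: the ``top_n`` most frequent terms among member articles
    (count ties broken alphabetically by term label), then each member scored
    by how many of those defining terms it carries, and the ``top_n``
    highest-scoring articles (score ties broken by input order).  Clusters
    smaller than ``top_n`` report all members, unpadded.
    """
    if len(model.labels) != corpus_subset.N:
        raise ValueError("labels and corpus subset are different lengths")
    top_terms: list[tuple[tuple[str, int], ...]] = []
    exemplars: list[tuple[tuple[str, int], ...]] = []
    ellipses: list[tuple[np.ndarray, np.ndarray, float]] = []
    for c in range(model.k):
        member_idx = np.flatnonzero(model.labels == c)
        counts = np.asarray(
            corpus_subset.matrix[member_idx].sum(axis=0)
        ).ravel().astype(int)
        order = sorted(
            np.flatnonzero(counts > 0),
            key=lambda j: (-counts[j], vocab.terms[j].label),
        )[:top_n]
        cluster_terms = tuple((vocab.terms[j].term_id, int(counts[j])) for j in order)
        top_terms.append(cluster_terms)
        top_cols = np.array([vocab.index_of[t] for t, _ in cluster_terms], dtype=int)
        if len(top_cols):
            scores = np.asarray(
                corpus_subset.matrix[member_idx][:, top_cols].sum(axis=1)
            ).ravel().astype(int)
        else:
            scores = np.zeros(len(member_idx), dtype=int)
        rank = sorted(range(len(member_idx)), key=lambda i: (-scores[i], i))[:top_n]
        exemplars.append(
            tuple(
                (corpus_subset.records[member_idx[i]].article_id, int(scores[i]))
                for i in rank
            )
        )
        if with_ellipses and projection is not None:
            pts = projection.points()[member_idx]
            try:
                ellipses.append(normal_ellipse(pts, level=level))
            except ValueError as exc:
                logger.warning("cluster %d: no ellipse (%s)", c, exc)
                ellipses.append(
                    (pts.mean(axis=0) if len(pts) else np.zeros(2),
                     np.full((2, 2), np.nan), float("nan"))
                )
    return replace(
        model,
        top_terms=tuple(top_terms),
        exemplars=tuple(exemplars),
        ellipses=tuple(ellipses),
    )


def normal_ellipse(
    points: np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray, float]:
    """Bivariate-normal confidence ellipse of a 2-D point cloud.

    Returns (mean, sample covariance, scale) where scale is the square root
    of the chi-square quantile at ``level`` with 2 degrees of freedom; the
    ellipse boundary is mean + scale * (eigen-structure of the covariance).
    At level 0.95 the squared scale is the familiar 5.99.
    """
    points = np.asarray(points, dtype=np.float64)
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 3:
        raise ValueError("need at least 3 two-dimensional points")
    mean = points.mean(axis=0)
    cov = np.cov(points, rowvar=False)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() <= 1e-12 * max(eigvals.max(), 1.0):
        raise ValueError("degenerate (collinear) point cloud: singular covariance")
    scale = float(np.sqrt(chi2.ppf(level, df=2)))
    return mean, cov, scale


# ---------------------------------------------------------------------------
# cross-edition overlap

def overlap_report(
    clusterings: dict[str, tuple[ProjectionResult, ClusterModel]],
) -> pd.DataFrame:
    """Pairwise cross-edition cluster comparison.

    For every ordered pair of editions, clusters are matched greedily by
    centroid distance (closest available pair first); each matched pair
    reports the centroid distance and the Jaccard overlap of occupied node
    sets.  Leftover clusters (unequal k) appear with ``matched=False``.
    """
    rows = []
    names = list(clusterings)
    for a in names:
        for b in names:
            proj_a, mod_a = clusterings[a]
            proj_b, mod_b = clusterings[b]
            pairs = _greedy_match(mod_a.centers, mod_b.centers)
            matched_a = {i for i, _ in pairs}
            matched_b = {j for _, j in pairs}
            for i, j in pairs:
                d = float(np.linalg.norm(mod_a.centers[i] - mod_b.centers[j]))
                nodes_a = _occupied_nodes(proj_a, mod_a, i)
                nodes_b = _occupied_nodes(proj_b, mod_b, j)
                union = nodes_a | nodes_b
                jac = len(nodes_a & nodes_b) / len(union) if union else 0.0
                rows.append(
                    dict(edition_a=a, edition_b=b, cluster_a=i, cluster_b=j,
                         centroid_distance=d, jaccard=jac, matched=True)
                )
            for i in range(mod_a.k):
                if i not in matched_a:
                    rows.append(
                        dict(edition_a=a, edition_b=b, cluster_a=i, cluster_b=-1,
                             centroid_distance=np.nan, jaccard=np.nan, matched=False)
                    )
            for j in range(mod_b.k):
                if j not in matched_b:
                    rows.append(
                        dict(edition_a=a, edition_b=b, cluster_a=-1, cluster_b=j,
                             centroid_distance=np.nan, jaccard=np.nan, matched=False)
                    )
    return pd.DataFrame(rows)


def _occupied_nodes(
    proj: ProjectionResult, model: ClusterModel, cluster: int
) -> set[int]:
    idx = np.flatnonzero(model.labels == cluster)
    return set(int(b) for b in proj.bmu_indices[idx])


def _greedy_match(
    centers_a: np.ndarray, centers_b: np.ndarray
) -> list[tuple[int, int]]:
    """Greedy bijective matching by ascending centroid distance."""
    ka, kb = len(centers_a), len(centers_b)
    dists = [
        (float(np.linalg.norm(centers_a[i] - centers_b[j])), i, j)
        for i in range(ka)
        for j in range(kb)
    ]
    dists.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in dists:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    return pairs


# ---------------------------------------------------------------------------
# tabular exports

def export_projection_tsv(
    projection: ProjectionResult, path: str | Path,
    model: ClusterModel | None = None,
) -> None:
    df = projection.to_frame()
    if model is not None:
        df["cluster"] = model.labels
    df.to_csv(path, sep="\t", index=False)


def export_density_tsv(projection: ProjectionResult, path: str | Path) -> None:
    pd.DataFrame(projection.density).to_csv(
        path, sep="\t", index=False, header=False
    )


def export_ellipses_tsv(model: ClusterModel, path: str | Path) -> None:
    rows = []
    for c, (mean, cov, scale) in enumerate(model.ellipses):
        rows.append(
            dict(cluster=c, mean_row=mean[0], mean_col=mean[1],
                 cov_rr=cov[0, 0], cov_rc=cov[0, 1], cov_cc=cov[1, 1],
                 scale=scale)
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
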