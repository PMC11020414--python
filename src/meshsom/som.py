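"""Batch self-organizing map over sparse binary corpora.

Kohonen's batch variant: in each epoch every article is assigned its best
matching unit (BMU) against the frozen pre-epoch codebook, neighborhood-
weighted numerators and denominators are accumulated, and all node weights
are replaced at epoch end.  Because inputs are binary, the per-node input
sums are exact integers in float64, which makes an epoch bitwise invariant
to article order.

The squared distance to a node is expanded as

    ||x - w_j||^2 = ||x||^2 + ||w_j||^2 - 2 x . w_j

so an article is only ever touched at its D_a nonzero columns; the full
N x D dense matrix is never formed.

Topographic error — the fraction of articles whose first and second BMUs
are not adjacent on the grid — is computed after every epoch and the
codebook with the lowest error is the one retained for analysis.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import h5py
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .corpus import AnnotatedCorpus, Vocabulary

logger = logging.getLogger(__name__)

__all__ = [
    "GridGeometry",
    "TrainingSchedule",
    "Codebook",
    "BmuPair",
    "init_codebook",
    "pca_plane_init",
    "find_bmu",
    "find_bmus",
    "batch_epoch",
    "topographic_error",
    "train",
    "classify_nodes",
    "save_codebook",
    "load_codebook",
    "export_weights_tsv",
]

_DEAD_NODE_EPS = 1e-12


@dataclass(frozen=True)
class GridGeometry:
    """Square-lattice map geometry; (row, col) 0-based, node index = row*cols + col."""

    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def M(self) -> int:
        return self.rows * self.cols

    def coords(self) -> np.ndarray:
        """(M, 2) array of (row, col) for each linear node index."""
        r, c = np.divmod(np.arange(self.M), self.cols)
        return np.column_stack([r, c]).astype(np.float64)

    def to_coord(self, index: int) -> tuple[int, int]:
        return divmod(int(index), self.cols)


@dataclass(frozen=True)
class TrainingSchedule:
    """Epoch count and shrinking neighborhood width sigma(e) = sigma0 / decay_base**e.

    Defaults are the full-scale map settings: 20 epochs, sigma0 = 175 (half a
    350-node grid side), decay base 1.7.  Epochs are 1-based in the formula, so
    the first epoch already trains below sigma0.
    """

    epochs: int = 20
    sigma0: float = 175.0
    decay_base: float = 1.7
    rng_seed: int = 0
    kernel: Literal["gaussian", "bubble"] = "gaussian"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if self.decay_base <= 1:
            raise ValueError("decay_base must be > 1")
        if self.kernel not in ("gaussian", "bubble"):
            raise ValueError(f"unknown kernel {self.kernel!r}")

    def sigma(self, epoch: int) -> float:
        """Neighborhood width at 1-based epoch ``epoch``; strictly decreasing."""
        if epoch < 1:
            raise ValueError("epoch is 1-based")
        return self.sigma0 / self.decay_base**epoch

    def unit_crossing_epoch(self) -> int:
        """First epoch at which sigma(e) falls below one grid unit."""
        e = 1
        while self.sigma(e) >= 1.0:
            e += 1
        return e


@dataclass(frozen=True)
class Codebook:
    """Node weight vectors plus geometry and training provenance."""

    geometry: GridGeometry
    W: np.ndarray = field(repr=False, compare=False)
    schedule: TrainingSchedule | None = None
    epoch_of_origin: int = 0
    te_history: tuple[float, ...] = ()
    vocab_digest: str = ""

    def __post_init__(self) -> None:
        if self.W.shape[0] != self.geometry.M:
            raise ValueError(
                f"W has {self.W.shape[0]} rows but grid has {self.geometry.M} nodes"
            )
        if not np.all(np.isfinite(self.W)):
            raise ValueError("codebook contains non-finite weights")

    @property
    def D(self) -> int:
        return self.W.shape[1]

    @property
    def M(self) -> int:
        return self.geometry.M


@dataclass(frozen=True)
class BmuPair:
    """Best and second-best matching units for one input vector."""

    first: int
    second: int
    first_dist2: float
    second_dist2: float


# ---------------------------------------------------------------------------
# initialization

def init_codebook(
    corpus: AnnotatedCorpus,
    geometry: GridGeometry,
    schedule: TrainingSchedule,
    jitter: float = 1e-3,
    method: Literal["sample", "pca", "pca_sample"] = "sample",
    blend: float = 0.7,
) -> Codebook:
    """Initial codebook.

    ``"sample"`` (default): each node is a uniformly sampled (seeded) article
    vector plus small jitter — binary data make uniform-random weights
    pathological BMU targets, so nodes start on actual articles.  Jitter
    breaks exact ties between nodes that sampled the same article.

    ``"pca"``: deterministic principal-plane init (:func:`pca_plane_init`).

    ``"pca_sample"``: convex blend ``blend * pca + (1 - blend) * sampled``;
    keeps the global ordering of the principal plane while dispersing node
    weights onto article-like vectors.  On small grids this combination
    resists the topological folds that pure article sampling produces.

    Weights are clipped to [0, 1] so the convex-hull invariant holds from the
    start.  Deterministic given ``schedule.rng_seed``.
    """
    if corpus.N == 0:
        raise ValueError("cannot initialize a codebook from an empty corpus")
    if geometry.M < 2:
        raise ValueError("grid must have at least 2 nodes")
    rng = np.random.default_rng(schedule.rng_seed)
    if method in ("sample", "pca_sample"):
        picks = rng.integers(0, corpus.N, size=geometry.M)
        W = np.asarray(corpus.matrix[picks].todense(), dtype=np.float64)
        if jitter:
            W += rng.uniform(0.0, jitter, size=W.shape)
        if method == "pca_sample":
            W = blend * pca_plane_init(corpus, geometry) + (1.0 - blend) * W
    elif method == "pca":
        W = pca_plane_init(corpus, geometry)
    else:
        raise ValueError(f"unknown init method {method!r}")
    np.clip(W, 0.0, 1.0, out=W)
    return Codebook(
        geometry=geometry,
        W=W,
        schedule=schedule,
        vocab_digest=corpus.vocabulary.digest(),
    )


def pca_plane_init(corpus: AnnotatedCorpus, geometry: GridGeometry) -> np.ndarray:
    """Linear (principal-plane) initialization: grid coordinates mapped onto
    the top two principal components of the corpus, spanning +-2 SD.

    This is the classical remedy for topological folding on small maps: the
    grid starts globally ordered, and batch epochs only refine locally.
    Deterministic (no RNG); the returned array may leave [0, 1] slightly and
    is clipped by callers that blend it with data vectors.
    """
    X = sp.csr_matrix(corpus.matrix, dtype=np.float64)
    mean = np.asarray(X.mean(axis=0)).ravel()
    n, D = X.shape
    k = min(2, min(n, D) - 1)
    if k < 2:
        raise ValueError("principal-plane init needs at least 3 articles and 3 terms")

    def mv(v):
        v = np.asarray(v).ravel()
        return X @ v - float(mean @ v) * np.ones(n)

    def rmv(v):
        v = np.asarray(v).ravel()
        return X.T @ v - mean * float(v.sum())

    op = spla.LinearOperator((n, D), matvec=mv, rmatvec=rmv)
    # fixed v0 makes ARPACK deterministic
    u, s, vt = spla.svds(op, k=2, v0=np.ones(min(n, D)) / np.sqrt(min(n, D)))
    order = np.argsort(s)[::-1]
    s, vt = s[order], vt[order]
    for i in range(2):  # fix eigenvector sign: largest-|.| component positive
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    coords = geometry.coords()
    for d in range(2):
        c = coords[:, d]
        span = c.max() - c.min()
        coords[:, d] = (c - c.mean()) / (span if span else 1.0)
    sd = s[:2] / np.sqrt(n)
    return mean[None, :] + (coords * (4.0 * sd)) @ vt[:2]


# ---------------------------------------------------------------------------
# BMU search

def _check_dim(D_x: int, codebook: Codebook) -> None:
    if D_x != codebook.D:
        raise ValueError(
            f"input dimension {D_x} != codebook dimension {codebook.D}"
        )


def find_bmus(
    X: sp.spmatrix, codebook: Codebook, chunk: int = 2048
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized first/second BMU search for every row of sparse ``X``.

    Returns (b1, b2, d1, d2) arrays.  Ties are broken toward the lowest
    linear node index (argmin's first-minimum rule).
    """
    X = sp.csr_matrix(X)
    _check_dim(X.shape[1], codebook)
    W = codebook.W
    wnorm = np.einsum("ij,ij->i", W, W)
    xnorm = np.asarray(X.multiply(X).sum(axis=1)).ravel()
    n = X.shape[0]
    b1 = np.empty(n, dtype=np.int64)
    b2 = np.empty(n, dtype=np.int64)
    d1 = np.empty(n, dtype=np.float64)
    d2 = np.empty(n, dtype=np.float64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        xw = np.asarray(X[start:stop] @ W.T)
        dist2 = wnorm[None, :] - 2.0 * xw + xnorm[start:stop, None]
        i1 = np.argmin(dist2, axis=1)
        rows = np.arange(stop - start)
        v1 = dist2[rows, i1]
        dist2[rows, i1] = np.inf
        i2 = np.argmin(dist2, axis=1)
        v2 = dist2[rows, i2]
        b1[start:stop] = i1
        b2[start:stop] = i2
        d1[start:stop] = np.maximum(v1, 0.0)
        d2[start:stop] = np.maximum(v2, 0.0)
    return b1, b2, d1, d2


def find_bmu(x, codebook: Codebook) -> BmuPair:
    """First and second BMU for a single vector (sparse row, dense 1-D, or set of columns)."""
    if sp.issparse(x):
        row = sp.csr_matrix(x)
    else:
        row = sp.csr_matrix(np.atleast_2d(np.asarray(x, dtype=np.float64)))
    b1, b2, d1, d2 = find_bmus(row, codebook)
    return BmuPair(int(b1[0]), int(b2[0]), float(d1[0]), float(d2[0]))


# ---------------------------------------------------------------------------
# batch epoch

def _grid_dist2(geometry: GridGeometry) -> np.ndarray:
    """(M, M) squared Euclidean distances between grid coordinates."""
    coords = geometry.coords()
    diff_r = coords[:, 0][:, None] - coords[:, 0][None, :]
    diff_c = coords[:, 1][:, None] - coords[:, 1][None, :]
    return diff_r**2 + diff_c**2


def _kernel_matrix(geometry: GridGeometry, sigma_e: float, kernel: str) -> np.ndarray:
    d2 = _grid_dist2(geometry)
    if kernel == "bubble":
        return (d2 <= sigma_e**2).astype(np.float64)
    return np.exp(-d2 / (2.0 * sigma_e**2))


def batch_epoch(
    codebook: Codebook, corpus: AnnotatedCorpus, sigma_e: float
) -> Codebook:
    """One batch update with the pre-epoch codebook answering all BMU queries.

    new w_j = sum_i h(b1(i), j) x_i / sum_i h(b1(i), j), with Gaussian (or
    bubble) neighborhood h on Euclidean grid distance.  Nodes whose kernel
    mass is below 1e-12 keep their previous weights (dead-node rule: no 0/0,
    no resampling).
    """
    if sigma_e <= 0:
        raise ValueError("sigma_e must be positive")
    _check_dim(corpus.matrix.shape[1], codebook)
    kernel = codebook.schedule.kernel if codebook.schedule else "gaussian"
    M = codebook.M
    b1, _, _, _ = find_bmus(corpus.matrix, codebook)
    # per-node article sums: exact integers in float64 for binary inputs,
    # hence order-invariant
    counts = np.bincount(b1, minlength=M).astype(np.float64)
    indicator = sp.csr_matrix(
        (np.ones(corpus.N), (b1, np.arange(corpus.N))), shape=(M, corpus.N)
    )
    T = np.asarray((indicator @ corpus.matrix).todense())  # (M, D) group sums
    H = _kernel_matrix(codebook.geometry, sigma_e, kernel)  # (M, M), symmetric
    S = H @ T
    Z = H @ counts
    W_new = codebook.W.copy()
    live = Z > _DEAD_NODE_EPS
    W_new[live] = S[live] / Z[live, None]
    if not np.all(np.isfinite(W_new)):
        raise FloatingPointError("batch epoch produced non-finite weights")
    return replace(codebook, W=W_new)


# ---------------------------------------------------------------------------
# topographic error

def topographic_error(
    codebook: Codebook,
    corpus: AnnotatedCorpus,
    adjacency: Literal["8", "4"] = "8",
) -> float:
    """Fraction of articles whose first and second BMUs are not grid-adjacent.

    Adjacency defaults to the 8-neighborhood (Chebyshev distance 1); the
    4-neighborhood (Manhattan distance 1) is available for comparison.
    """
    if corpus.N == 0:
        raise ValueError("topographic error undefined for an empty corpus")
    b1, b2, _, _ = find_bmus(corpus.matrix, codebook)
    r1, c1 = np.divmod(b1, codebook.geometry.cols)
    r2, c2 = np.divmod(b2, codebook.geometry.cols)
    dr = np.abs(r1 - r2)
    dc = np.abs(c1 - c2)
    if adjacency == "8":
        adjacent = np.maximum(dr, dc) == 1
    elif adjacency == "4":
        adjacent = (dr + dc) == 1
    else:
        raise ValueError(f"unknown adjacency {adjacency!r}")
    return float(np.mean(~adjacent))


# ---------------------------------------------------------------------------
# training loop

def train(
    corpus: AnnotatedCorpus,
    geometry: GridGeometry,
    schedule: TrainingSchedule,
    adjacency: Literal["8", "4"] = "8",
    init: Literal["sample", "pca", "pca_sample"] = "sample",
    restarts: int = 1,
) -> Codebook:
    """Run the batch-training schedule and keep the lowest-error codebook.

    Each restart trains for ``schedule.epochs`` epochs with
    sigma(e) = sigma0/decay^e, evaluating the topographic error after every
    epoch; the codebook with the minimum error over all restarts and epochs
    is returned (earliest restart, then earliest epoch, on ties), carrying
    the error history of its own restart.  Restart r derives its RNG seed as
    ``rng_seed + 100003 * r``, so a single run (restarts=1) is unchanged.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    best_W = None
    best_te = np.inf
    best_epoch = 0
    best_history: tuple[float, ...] = ()
    digest = corpus.vocabulary.digest()
    for r in range(restarts):
        sub = replace(schedule, rng_seed=schedule.rng_seed + 100003 * r)
        codebook = init_codebook(corpus, geometry, sub, method=init)
        history: list[float] = []
        improved = False
        for e in range(1, schedule.epochs + 1):
            t0 = time.perf_counter()
            sigma_e = schedule.sigma(e)
            codebook = batch_epoch(codebook, corpus, sigma_e)
            te = topographic_error(codebook, corpus, adjacency=adjacency)
            history.append(te)
            logger.info(
                "restart=%d epoch=%d sigma=%.4f topographic_error=%.4f wall=%.2fs",
                r, e, sigma_e, te, time.perf_counter() - t0,
            )
            if te < best_te:
                best_te = te
                best_W = codebook.W
                best_epoch = e
                improved = True
        if improved:
            best_history = tuple(history)
    return Codebook(
        geometry=geometry,
        W=best_W,
        schedule=schedule,
        epoch_of_origin=best_epoch,
        te_history=best_history,
        vocab_digest=digest,
    )


# ---------------------------------------------------------------------------
# node classification

def classify_nodes(codebook: Codebook, vocab: Vocabulary) -> np.ndarray:
    """Label each node domain-positive iff its mean weight over domain columns
    strictly exceeds its mean weight over non-domain columns.

    For the psychiatric-literature map this is the psychiatric / non-
    psychiatric split of nodes by which MeSH their weights prioritize.
    """
    mask = vocab.domain_mask
    if vocab.D != codebook.D:
        raise ValueError("vocabulary dimension does not match codebook")
    n_dom = int(mask.sum())
    if n_dom == 0:
        raise ValueError("no domain terms in vocabulary: classification undefined")
    if n_dom == vocab.D:
        raise ValueError("all terms are domain terms: classification undefined")
    dom_mean = codebook.W[:, mask].mean(axis=1)
    non_mean = codebook.W[:, ~mask].mean(axis=1)
    return dom_mean > non_mean


# ---------------------------------------------------------------------------
# persistence

def save_codebook(codebook: Codebook, path: str | Path) -> None:
    """Lossless HDF5 round-trip of weights (float64), geometry, schedule, history."""
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=codebook.W, dtype="float64")
        f.create_dataset("te_history", data=np.asarray(codebook.te_history))
        f.attrs["rows"] = codebook.geometry.rows
        f.attrs["cols"] = codebook.geometry.cols
        f.attrs["epoch_of_origin"] = codebook.epoch_of_origin
        f.attrs["vocab_digest"] = codebook.vocab_digest
        s = codebook.schedule
        if s is not None:
            f.attrs["epochs"] = s.epochs
            f.attrs["sigma0"] = s.sigma0
            f.attrs["decay_base"] = s.decay_base
            f.attrs["rng_seed"] = s.rng_seed
            f.attrs["kernel"] = s.kernel


def load_codebook(path: str | Path, vocab: Vocabulary | None = None) -> Codebook:
    """Load a codebook; warns if ``vocab`` is supplied and its digest differs."""
    try:
        with h5py.File(path, "r") as f:
            W = f["W"][...]
            te = tuple(float(t) for t in f["te_history"][...])
            geometry = GridGeometry(int(f.attrs["rows"]), int(f.attrs["cols"]))
            schedule = None
            if "epochs" in f.attrs:
                schedule = TrainingSchedule(
                    epochs=int(f.attrs["epochs"]),
                    sigma0=float(f.attrs["sigma0"]),
                    decay_base=float(f.attrs["decay_base"]),
                    rng_seed=int(f.attrs["rng_seed"]),
                    kernel=str(f.attrs["kernel"]),
                )
            digest = str(f.attrs.get("vocab_digest", ""))
            epoch = int(f.attrs.get("epoch_of_origin", 0))
    except OSError as exc:
        raise ValueError(f"{path}: not a readable codebook file ({exc})")
    if vocab is not None and digest and vocab.digest() != digest:
        logger.warning(
            "codebook %s was trained against a different vocabulary "
            "(digest mismatch)", path,
        )
    return Codebook(
        geometry=geometry,
        W=W,
        schedule=schedule,
        epoch_of_origin=epoch,
        te_history=te,
        vocab_digest=digest,
    )


def export_weights_tsv(codebook: Codebook, path: str | Path) -> None:
    """Write the M x D weight matrix as TSV (node, row, col, then weights)."""
    coords = codebook.geometry.coords().astype(int)
    with Path(path).open("w", encoding="utf-8") as fh:
        header = ["node", "row", "col"] + [f"w{j}" for j in range(codebook.D)]
        fh.write("\t".join(header) + "\n")
        for i in range(codebook.M):
            vals = "\t".join(repr(float(v)) for v in codebook.W[i])
            fh.write(f"{i}\t{coords[i, 0]}\t{coords[i, 1]}\t{vals}\n")
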