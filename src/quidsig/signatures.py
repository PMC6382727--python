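"""De-novo mutational-signature extraction and reference matching.

The extraction model is nonnegative matrix factorization (NMF) of the
samples x 96 context-count matrix ``M``: ``M.T ~ P @ E`` with ``P`` a
96 x K matrix of signature probability vectors (columns sum to 1) and ``E``
a K x samples matrix of nonnegative exposures.  ``P`` and ``E`` are found by
multiplicative updates minimising the Frobenius norm ``||M.T - P E||_F``,
best of several random restarts.

The number of operative processes K is selected by re-extracting signatures
on bootstrap-resampled catalogs (per-sample multinomial resampling, which
preserves each sample's mutation load), clustering the pooled signatures by
cosine distance, and scoring each K by signature stability (mean silhouette
width) together with the Frobenius reconstruction error.

Two scikit-learn style estimators expose this machinery:

* :class:`SignatureNMF` — a single factorization at fixed K;
* :class:`BootstrapSignatureExtractor` — consensus signatures over bootstrap
  replicates, with stability scores and NNLS-refit exposures.

Extracted signatures are matched to a reference panel (COSMIC-v2-style,
96 labelled rows x named columns) by cosine similarity and complete-linkage
hierarchical clustering on 1 - cosine distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.optimize import nnls
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.metrics import silhouette_samples
from sklearn.utils.validation import check_is_fitted

from quidsig.context import CONTEXT_CLASSES

_EPS = 1e-12


# ---------------------------------------------------------------------------
# low-level numerics


def _mu_nmf(
    V: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Multiplicative-update NMF of V (features x samples) at rank k.

    Returns (W, H, frobenius_error).  The update never increases the
    objective, so the returned error is <= the error at initialisation.
    """
    n, m = V.shape
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(0.5, 1.5, size=(n, k)) * scale
    H = rng.uniform(0.5, 1.5, size=(k, m)) * scale
    prev = np.inf
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        err = np.linalg.norm(V - W @ H)
        if prev - err < tol * max(prev, 1.0):
            prev = err
            break
        prev = err
    return W, H, float(np.linalg.norm(V - W @ H))


def _normalize_columns(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale W's columns to sum 1, moving the mass into H's rows."""
    col = W.sum(axis=0)
    col[col == 0] = 1.0
    return W / col, H * col[:, None]


def refit_exposures(X: np.ndarray | pd.DataFrame, signatures: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """Nonnegative least-squares exposures of each sample against fixed
    signatures.

    ``X`` is samples x 96 counts; ``signatures`` is 96 x K (columns are
    probability vectors).  Returns a samples x K DataFrame of exposures in
    mutation counts.
    """
    P = np.asarray(signatures, dtype=float)
    Xv = np.asarray(X, dtype=float)
    E = np.vstack([nnls(P, row)[0] for row in Xv])
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(Xv))
    cols = (
        signatures.columns
        if isinstance(signatures, pd.DataFrame)
        else [f"S{i+1}" for i in range(P.shape[1])]
    )
    return pd.DataFrame(E, index=index, columns=cols)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """a.b / (|a||b|); raises on a zero vector."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities between rows of A and rows of B."""
    An = A / np.linalg.norm(A, axis=1, keepdims=True)
    Bn = B / np.linalg.norm(B, axis=1, keepdims=True)
    return An @ Bn.T


def _pam(D: np.ndarray, k: int) -> np.ndarray:
    """Partitioning around medoids on a precomputed distance matrix.

    Deterministic greedy BUILD followed by SWAP to convergence; ties broken
    by lowest index.  Returns the array of medoid indices (sorted).
    """
    n = len(D)
    if k >= n:
        return np.arange(n)
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        cur = D[:, medoids].min(axis=1)
        gain = np.maximum(cur[None, :] - D, 0).sum(axis=1)
        gain[medoids] = -np.inf
        medoids.append(int(np.argmax(gain)))
    medoids = sorted(medoids)
    best_cost = D[:, medoids].min(axis=1).sum()
    improved = True
    while improved:
        improved = False
        for mi, m in enumerate(list(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = sorted(medoids[:mi] + [h] + medoids[mi + 1 :])
                cost = D[:, trial].min(axis=1).sum()
                if cost < best_cost - 1e-12:
                    medoids, best_cost, improved = trial, cost, True
                    break
            if improved:
                break
    return np.array(medoids)


def _cluster_signatures(pool: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Partition pooled bootstrap signatures (rows) into k clusters by
    cosine distance; returns (labels, medoid indices)."""
    D = 1.0 - _cosine_matrix(pool, pool)
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    medoids = _pam(D, k)
    labels = np.argmin(D[:, medoids], axis=1)
    return labels, medoids


# ---------------------------------------------------------------------------
# estimators


class SignatureNMF(BaseEstimator):
    """Single NMF factorization of a context matrix at fixed rank.

    Parameters
    ----------
    n_signatures : int
        Rank K of the factorization.
    n_restarts : int
        Random restarts; the solution with the lowest Frobenius error wins.
    max_iter, tol : int, float
        Multiplicative-update iteration cap and relative convergence
        tolerance on the objective.
    random_state : int or None
        Master seed; restart streams are derived from it, so fits are
        bitwise reproducible.

    Attributes
    ----------
    components_ : ndarray of shape (K, 96), rows sum to 1.
    signatures_ : DataFrame of shape (96, K) — the same signatures with
        context-class index (column-vector convention).
    exposures_ : DataFrame (samples, K), mutation-count scale.
    reconstruction_err_ : float, Frobenius norm of the residual.
    """

    def __init__(
        self,
        n_signatures: int = 3,
        n_restarts: int = 10,
        max_iter: int = 2000,
        tol: float = 1e-9,
        random_state: int | None = None,
    ):
        self.n_signatures = n_signatures
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = self._validate(X)
        V = np.asarray(X, dtype=float).T  # 96 x samples
        k = self.n_signatures
        if k < 1 or k > min(V.shape):
            raise ValueError(f"n_signatures={k} outside [1, {min(V.shape)}]")
        if not np.any(V > 0):
            raise ValueError("context matrix is all zero")
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_restarts)
        best = None
        for ss in seeds:
            W, H, err = _mu_nmf(V, k, np.random.default_rng(ss), self.max_iter, self.tol)
            if best is None or err < best[2]:
                best = (W, H, err)
        W, H, err = best
        W, H = _normalize_columns(W, H)
        order = np.argsort(-H.sum(axis=1))  # most active process first
        W, H = W[:, order], H[order]
        names = [f"S{i+1}" for i in range(k)]
        self.components_ = W.T
        self.signatures_ = pd.DataFrame(W, index=CONTEXT_CLASSES, columns=names)
        index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(V.shape[1])
        self.exposures_ = pd.DataFrame(H.T, index=index, columns=names)
        self.reconstruction_err_ = err
        return self

    def transform(self, X):
        check_is_fitted(self, "signatures_")
        X = self._validate(X)
        return refit_exposures(X, self.signatures_)

    def fit_transform(self, X, y=None):
        return self.fit(X).exposures_

    @staticmethod
    def _validate(X):
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(CONTEXT_CLASSES):
            raise ValueError("X must be samples x 96 context counts")
        if np.any(arr < 0) or np.any(~np.isfinite(arr)):
            raise ValueError("X must be finite and nonnegative")
        return X


class BootstrapSignatureExtractor(BaseEstimator):
    """Consensus signature extraction over bootstrap-resampled catalogs.

    Each bootstrap replicate multinomially resamples every sample's
    96-vector using its own total as the draw count, then factorizes it with
    :class:`SignatureNMF`.  The pooled signatures are partitioned into K
    clusters (PAM on cosine distance); consensus signatures are the
    renormalised cluster centroids, their stability the mean silhouette
    width of each cluster, and exposures are refit on the original matrix by
    nonnegative least squares.

    Attributes
    ----------
    signatures_ : DataFrame (96, K) consensus signatures, columns sum to 1.
    exposures_ : DataFrame (samples, K), NNLS refit counts.
    stability_ : ndarray (K,) per-cluster mean silhouette (cosine distance).
    stability_mean_ : float, mean over all pooled signatures.
    reconstruction_err_ : float, mean bootstrap Frobenius error.
    n_degenerate_resamples_ : int, all-zero resamples that were redrawn.
    """

    def __init__(
        self,
        n_signatures: int = 3,
        n_bootstrap: int = 50,
        n_restarts: int = 3,
        max_iter: int = 2000,
        tol: float = 1e-9,
        random_state: int | None = None,
    ):
        self.n_signatures = n_signatures
        self.n_bootstrap = n_bootstrap
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.n_bootstrap < 2:
            raise ValueError("n_bootstrap must be >= 2")
        SignatureNMF._validate(X)
        Xv = np.asarray(X, dtype=float)
        k = self.n_signatures
        root = np.random.SeedSequence(self.random_state)
        rng = np.random.default_rng(root.spawn(1)[0])
        fit_seeds = np.random.SeedSequence(root.entropy, spawn_key=(1,)).spawn(
            self.n_bootstrap
        )
        pool = []
        errs = []
        n_degenerate = 0
        for b in range(self.n_bootstrap):
            Xb = self._resample(Xv, rng)
            while not np.any(Xb > 0):
                n_degenerate += 1
                Xb = self._resample(Xv, rng)
            model = SignatureNMF(
                n_signatures=k,
                n_restarts=self.n_restarts,
                max_iter=self.max_iter,
                tol=self.tol,
                random_state=fit_seeds[b].generate_state(1)[0] % (2**31),
            ).fit(Xb)
            pool.append(model.signatures_.to_numpy().T)  # K x 96 rows
            errs.append(model.reconstruction_err_)
        pool = np.vstack(pool)
        labels, _ = _cluster_signatures(pool, k)
        centroids = np.vstack(
            [pool[labels == c].mean(axis=0) for c in range(k)]
        )
        centroids /= centroids.sum(axis=1, keepdims=True)
        if k > 1 and len(set(labels)) > 1:
            D = np.clip(1.0 - _cosine_matrix(pool, pool), 0.0, None)
            np.fill_diagonal(D, 0.0)
            sil = silhouette_samples(D, labels, metric="precomputed")
            self.stability_ = np.array(
                [sil[labels == c].mean() for c in range(k)]
            )
            self.stability_mean_ = float(sil.mean())
        else:
            # single cluster: score coherence as mean cosine to the centroid
            sims = _cosine_matrix(pool, centroids[:1]).ravel()
            self.stability_ = np.array([float(sims.mean())])
            self.stability_mean_ = float(sims.mean())
        order = np.argsort(-centroids.max(axis=1))  # stable, shape-based order
        centroids = centroids[order]
        self.stability_ = self.stability_[order]
        names = [f"S{i+1}" for i in range(k)]
        self.signatures_ = pd.DataFrame(
            centroids.T, index=CONTEXT_CLASSES, columns=names
        )
        self.exposures_ = refit_exposures(
            X if isinstance(X, pd.DataFrame) else Xv, self.signatures_
        )
        self.reconstruction_err_ = float(np.mean(errs))
        self.n_degenerate_resamples_ = n_degenerate
        return self

    def transform(self, X):
        check_is_fitted(self, "signatures_")
        return refit_exposures(X, self.signatures_)

    @staticmethod
    def _resample(Xv: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Per-sample multinomial resampling preserving each sample's load."""
        out = np.zeros_like(Xv)
        for i, row in enumerate(Xv):
            total = int(round(row.sum()))
            if total == 0:
                continue
            p = row / row.sum()
            out[i] = rng.multinomial(total, p)
        return out


# ---------------------------------------------------------------------------
# functional wrappers (library surface)


def nmf_decompose(
    M: pd.DataFrame,
    k: int,
    seed: int | None = None,
    n_restarts: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-9,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Factorize a samples x 96 matrix at rank ``k``.

    Returns (signatures 96 x K, exposures samples x K, frobenius_error).
    """
    model = SignatureNMF(
        n_signatures=k,
        n_restarts=n_restarts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(M)
    return model.signatures_, model.exposures_, model.reconstruction_err_


def extract_signatures(
    M: pd.DataFrame,
    k: int,
    n_bootstrap: int = 50,
    seed: int | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Bootstrap-consensus extraction at rank ``k``.

    Returns (consensus signatures 96 x K, NNLS exposures samples x K, a dict
    with stability and reconstruction-error summaries).
    """
    model = BootstrapSignatureExtractor(
        n_signatures=k, n_bootstrap=n_bootstrap, random_state=seed, **kwargs
    ).fit(M)
    profile = {
        "k": k,
        "stability": model.stability_mean_,
        "stability_per_signature": model.stability_,
        "reconstruction_error": model.reconstruction_err_,
        "n_degenerate_resamples": model.n_degenerate_resamples_,
    }
    return model.signatures_, model.exposures_, profile


def select_rank(
    M: pd.DataFrame,
    k_min: int = 1,
    k_max: int = 15,
    n_bootstrap: int = 20,
    seed: int | None = None,
    stability_threshold: float = 0.80,
    stability_drop: float = 0.10,
    **kwargs,
) -> tuple[pd.DataFrame, int]:
    """Stability / reconstruction-error profile over K = k_min..k_max.

    Ranks are scanned in ascending order and accepted while the mean
    signature stability stays at or above ``stability_threshold`` and does
    not fall by more than ``stability_drop`` relative to the previous rank;
    the chosen K is the last accepted rank before the first violation.  The
    full profile is always returned so the choice can be overridden
    manually.
    """
    k_max = min(k_max, min(np.asarray(M).shape) if min(np.asarray(M).shape) > 0 else k_max)
    seeds = np.random.SeedSequence(seed).spawn(k_max - k_min + 1)
    rows = []
    for i, k in enumerate(range(k_min, k_max + 1)):
        model = BootstrapSignatureExtractor(
            n_signatures=k,
            n_bootstrap=n_bootstrap,
            random_state=seeds[i].generate_state(1)[0] % (2**31),
            **kwargs,
        ).fit(M)
        rows.append(
            {
                "k": k,
                "stability": model.stability_mean_,
                "reconstruction_error": model.reconstruction_err_,
            }
        )
    profile = pd.DataFrame(rows).set_index("k")
    chosen = k_min
    prev = None
    for k in profile.index:
        s = profile.loc[k, "stability"]
        if s < stability_threshold or (prev is not None and s < prev - stability_drop):
            break
        chosen = k
        prev = s
    return profile, int(chosen)


# ---------------------------------------------------------------------------
# reference matching


def read_reference_panel(path) -> pd.DataFrame:
    """Read a tab-delimited reference panel: 96 labelled rows x named
    signature columns (COSMIC v2 layout).  Rows are reindexed to the fixed
    class order; columns are renormalised to sum 1."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CONTEXT_CLASSES) - set(df.index)
    if missing:
        raise ValueError(f"reference panel is missing classes: {sorted(missing)[:4]}...")
    df = df.loc[CONTEXT_CLASSES].astype(float)
    return df / df.sum(axis=0)


def match_to_reference(
    sigs: pd.DataFrame, ref: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Match extracted signatures to a reference panel by cosine similarity.

    Both arguments are 96 x K DataFrames indexed by the fixed context-class
    order (signatures as columns).  Returns:

    * the full query x reference cosine-similarity matrix;
    * a best-match table (argmax reference per query; ties broken by lowest
      reference column index, flagged in the ``tie`` column);
    * the complete-linkage tree (scipy linkage matrix) on 1 - cosine
      distance over the union of both signature sets, leaves ordered query
      columns first then reference columns.
    """
    if list(sigs.index) != CONTEXT_CLASSES or list(ref.index) != CONTEXT_CLASSES:
        raise ValueError("signature matrices must use the fixed 96-class order")
    Q = sigs.to_numpy(dtype=float).T
    R = ref.to_numpy(dtype=float).T
    sim = pd.DataFrame(_cosine_matrix(Q, R), index=sigs.columns, columns=ref.columns)
    best_idx = sim.to_numpy().argmax(axis=1)
    rows = []
    for qi, q in enumerate(sim.index):
        s = sim.iloc[qi]
        top = float(s.iloc[best_idx[qi]])
        ties = (s >= top - 1e-12).sum() > 1
        rows.append(
            {"query": q, "best_match": sim.columns[best_idx[qi]], "cosine": top, "tie": bool(ties)}
        )
    best = pd.DataFrame(rows).set_index("query")
    union = np.vstack([Q, R])
    D = np.clip(1.0 - _cosine_matrix(union, union), 0.0, None)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="complete")
    return sim, best, Z


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick string with branch
    lengths derived from merge heights."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height):
        length = max(parent_height - (0.0 if node.is_leaf() else node.dist), 0.0)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{max(parent_height - node.dist, 0.0):.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


# ---------------------------------------------------------------------------
# exposure statistics


def exposure_proportions(E: pd.DataFrame) -> pd.DataFrame:
    """Row-normalise an exposures table (samples x K) to per-sample
    signature proportions."""
    totals = E.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("sample with zero total exposure")
    return E.div(totals, axis=0)


def compare_exposure(
    cohorts: pd.DataFrame,
    proportions: pd.DataFrame,
    signature: str,
    group_a: str,
    group_b: str,
    welch: bool = False,
) -> dict:
    """Unpaired two-sided t-test on per-sample signature proportions
    between two cohorts.

    The classic pooled-variance test is the default; pass ``welch=True``
    for the unequal-variance variant.
    """
    labels = cohorts["cohort"]
    a = proportions.loc[labels[labels == group_a].index.intersection(proportions.index), signature]
    b = proportions.loc[labels[labels == group_b].index.intersection(proportions.index), signature]
    for name, vals in ((group_a, a), (group_b, b)):
        if len(vals) < 2:
            raise ValueError(f"cohort {name} has fewer than 2 samples")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "n_a": int(len(a)),
        "n_b": int(len(b)),
        "t": float(t),
        "p_value": float(p),
    }
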