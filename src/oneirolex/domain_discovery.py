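"""Discovery of lexical domains from a lemma embedding space.

Rather than extracting topics from documents directly, the lemma-level
semantic space is decomposed: the clipped cosine-similarity matrix between
all lemma embeddings is factorized with non-negative matrix factorization
(NNMF), the number of components is chosen by masked cross-validation
(randomly hiding 10% of cells and scoring the reconstruction on the hidden
cells), and each resulting component — a *lexical domain* — is summarized by
a domain embedding: the mean embedding of its 20 highest-loading lemmas.
Domains are finally grouped into macro-categories by classical MDS of the
domain-embedding similarity matrix followed by k-means with silhouette-based
model selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .corpus import EmbeddingTable, write_embeddings, read_embeddings

__all__ = [
    "SimilarityMatrix",
    "NnmfFit",
    "DomainModel",
    "build_similarity_matrix",
    "fit_nnmf",
    "cv_select_rank",
    "build_domain_embeddings",
    "classical_mds",
    "cluster_macro_categories",
]


@dataclass
class SimilarityMatrix:
    """Symmetric lemma x lemma matrix of cosine similarities clipped at 0."""

    lemmas: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (len(self.lemmas), len(self.lemmas)):
            raise ValueError("similarity matrix shape does not match lemma count")


@dataclass
class NnmfFit:
    K: int
    W: np.ndarray
    H: np.ndarray
    n_iter: int
    converged: bool
    objective: float
    rmse_curve: pd.DataFrame | None = None


@dataclass
class DomainModel:
    """NNMF-derived lexical domains with their embeddings and summaries."""

    embeddings: np.ndarray          # n_domains x d
    top_lemmas: list[list[str]]     # per-domain, ordered by H coefficient
    labels: list[str] | None = None  # optional free-text annotations
    macro_assignment: np.ndarray | None = None
    macro_k: int | None = None
    mds_coords: np.ndarray | None = None
    no_macro_structure: bool = False
    rmse_curve: pd.DataFrame | None = None
    selected_rank: int | None = None

    @property
    def n_domains(self) -> int:
        return self.embeddings.shape[0]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "top_lemmas": self.top_lemmas,
            "labels": self.labels,
            "macro_assignment": None if self.macro_assignment is None
            else [int(x) for x in self.macro_assignment],
            "macro_k": self.macro_k,
            "no_macro_structure": self.no_macro_structure,
            "selected_rank": self.selected_rank,
            "mds_coords": None if self.mds_coords is None
            else self.mds_coords.tolist(),
        }
        (directory / "domains.json").write_text(
            json.dumps(meta, ensure_ascii=False, indent=1), encoding="utf-8")
        names = [f"domain{k:02d}" for k in range(self.n_domains)]
        write_embeddings(EmbeddingTable(names, self.embeddings),
                         directory / "domain_embeddings.txt")
        if self.rmse_curve is not None:
            self.rmse_curve.to_csv(directory / "rmse_curve.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "DomainModel":
        directory = Path(directory)
        meta = json.loads((directory / "domains.json").read_text(encoding="utf-8"))
        emb = read_embeddings(directory / "domain_embeddings.txt")
        curve_path = directory / "rmse_curve.csv"
        return cls(
            embeddings=emb.vectors,
            top_lemmas=[list(t) for t in meta["top_lemmas"]],
            labels=meta.get("labels"),
            macro_assignment=None if meta["macro_assignment"] is None
            else np.asarray(meta["macro_assignment"], dtype=int),
            macro_k=meta.get("macro_k"),
            no_macro_structure=meta.get("no_macro_structure", False),
            selected_rank=meta.get("selected_rank"),
            mds_coords=None if meta.get("mds_coords") is None
            else np.asarray(meta["mds_coords"], dtype=float),
            rmse_curve=pd.read_csv(curve_path) if curve_path.exists() else None,
        )


# ---------------------------------------------------------------------------
# similarity matrix
# ---------------------------------------------------------------------------

def cosine_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Cosine similarity between every row of A and every row of B."""
    na = np.linalg.norm(A, axis=1, keepdims=True)
    nb = np.linalg.norm(B, axis=1, keepdims=True)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero-norm vector in cosine computation")
    return (A / na) @ (B / nb).T


def build_similarity_matrix(table: EmbeddingTable) -> SimilarityMatrix:
    """Pairwise cosine similarities with negative values clipped to zero.

    The diagonal is exactly 1 and the matrix exactly symmetric.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 lemmas")
    S = cosine_rows(table.vectors, table.vectors)
    np.clip(S, 0.0, None, out=S)
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(list(table.lemmas), S)


# ---------------------------------------------------------------------------
# NNMF with alternating least squares
# ---------------------------------------------------------------------------

def _nndsvd_ar(S: np.ndarray, K: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative double SVD initialization, zeros filled with small
    seeded random values (the 'ar' variant), so runs are deterministic
    under a seed but repetitions can differ."""
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    n = S.shape[0]
    W = np.zeros((n, K))
    H = np.zeros((K, n))
    W[:, 0] = np.sqrt(sv[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(sv[0]) * np.abs(Vt[0, :])
    for k in range(1, min(K, len(sv))):
        u, v = U[:, k], Vt[k, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        norm_p = np.linalg.norm(up) * np.linalg.norm(vp)
        norm_n = np.linalg.norm(un) * np.linalg.norm(vn)
        if norm_p >= norm_n:
            sigma = sv[k] * norm_p
            if norm_p > 0:
                W[:, k] = np.sqrt(sigma) * up / np.linalg.norm(up)
                H[k, :] = np.sqrt(sigma) * vp / np.linalg.norm(vp)
        else:
            sigma = sv[k] * norm_n
            W[:, k] = np.sqrt(sigma) * un / np.linalg.norm(un)
            H[k, :] = np.sqrt(sigma) * vn / np.linalg.norm(vn)
    mean = S.mean()
    for M in (W, H):
        zero = M <= 0
        M[zero] = rng.uniform(0, mean / 100.0, size=int(zero.sum()))
    return W, H


def fit_nnmf(
    S: SimilarityMatrix | np.ndarray,
    K: int,
    max_iter: int = 500,
    seed: int | None = 0,
    mask: np.ndarray | None = None,
    mask_mode: str = "missing",
    tol: float = 1e-6,
) -> NnmfFit:
    """Alternating-least-squares NNMF of a (similarity) matrix.

    Each sweep solves the unconstrained least-squares problem for one factor
    and projects negatives to zero.  When ``mask`` marks held-out cells they
    are treated as missing: under ``mask_mode='missing'`` they are imputed
    with the current reconstruction before every sweep (an EM scheme that
    minimizes the squared error over observed cells only); under
    ``mask_mode='zero'`` they are simply set to zero.
    """
    A = S.S if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    n = A.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"rank K={K} exceeds matrix size n={n}")
    if mask_mode not in ("missing", "zero"):
        raise ValueError("mask_mode must be 'missing' or 'zero'")
    rng = np.random.default_rng(seed)
    observed = None if mask is None else ~mask

    A_work = A.copy()
    if mask is not None:
        A_work[mask] = 0.0
    W, H = _nndsvd_ar(A_work, K, rng)

    eps = 1e-12
    prev_obj = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if mask is not None and mask_mode == "missing":
            recon = W @ H
            A_work = A.copy()
            A_work[mask] = recon[mask]
        # solve for W with H fixed, then project
        Wt, *_ = np.linalg.lstsq(H @ H.T + eps * np.eye(K), H @ A_work.T, rcond=None)
        W = np.maximum(Wt.T, 0.0)
        # solve for H with W fixed, then project
        H, *_ = np.linalg.lstsq(W.T @ W + eps * np.eye(K), W.T @ A_work, rcond=None)
        H = np.maximum(H, 0.0)
        resid = A_work - W @ H
        if observed is not None:
            obj = float(np.sum(resid[observed] ** 2))
        else:
            obj = float(np.sum(resid ** 2))
        if np.isfinite(prev_obj) and prev_obj - obj <= tol * max(prev_obj, 1e-30):
            converged = True
            break
        prev_obj = obj
    if not converged:
        warnings.warn(f"NNMF did not converge in {max_iter} iterations (K={K})",
                      RuntimeWarning)
    return NnmfFit(K=K, W=W, H=H, n_iter=n_iter, converged=converged, objective=obj)


def _draw_mask(n: int, mask_frac: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric boolean mask over off-diagonal cells: cells are sampled in
    the upper triangle and mirrored, keeping the matrix symmetric; the
    (identically 1) diagonal is never masked."""
    iu, ju = np.triu_indices(n, k=1)
    n_cells = len(iu)
    n_mask = max(1, int(round(mask_frac * n_cells)))
    idx = rng.choice(n_cells, size=n_mask, replace=False)
    mask = np.zeros((n, n), dtype=bool)
    mask[iu[idx], ju[idx]] = True
    mask |= mask.T
    return mask


def cv_select_rank(
    S: SimilarityMatrix | np.ndarray,
    ranks=range(1, 71),
    mask_frac: float = 0.10,
    reps: int = 50,
    seed: int = 0,
    max_iter: int = 500,
    selector: str = "mean",
) -> tuple[int, pd.DataFrame]:
    """Choose the NNMF rank by masked cross-validation.

    For each repetition, 10% of the similarity cells are hidden; every
    candidate rank is fitted on the masked matrix and scored by the RMSE
    between reconstruction and original on the hidden cells only (a paired
    design: all ranks see the same masks).  The selected rank minimizes the
    mean RMSE across repetitions (``selector='median'`` is also available).

    Returns ``(K*, rmse_curve)`` with the curve holding per-rank mean, sd and
    median of the held-out RMSE.
    """
    A = S.S if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    ranks = list(ranks)
    if not ranks:
        raise ValueError("empty rank grid")
    if not 0.0 < mask_frac < 1.0:
        raise ValueError("mask_frac must be in (0, 1)")
    if max(ranks) >= A.shape[0]:
        raise ValueError("largest candidate rank must be < matrix size")
    root = np.random.default_rng(seed)
    rep_seeds = root.integers(0, 2**31 - 1, size=reps)
    rmse = np.empty((len(ranks), reps))
    for r, rep_seed in enumerate(rep_seeds):
        rep_rng = np.random.default_rng(rep_seed)
        mask = _draw_mask(A.shape[0], mask_frac, rep_rng)
        for ki, K in enumerate(ranks):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = fit_nnmf(A, K, max_iter=max_iter, seed=int(rep_seed) + K,
                               mask=mask)
            recon = fit.W @ fit.H
            rmse[ki, r] = np.sqrt(np.mean((recon[mask] - A[mask]) ** 2))
    curve = pd.DataFrame({
        "rank": ranks,
        "mean_rmse": rmse.mean(axis=1),
        "sd_rmse": rmse.std(axis=1, ddof=1) if reps > 1 else np.nan,
        "median_rmse": np.median(rmse, axis=1),
    })
    key = "mean_rmse" if selector == "mean" else "median_rmse"
    k_star = int(curve.loc[curve[key].idxmin(), "rank"])
    return k_star, curve


# ---------------------------------------------------------------------------
# domain embeddings and macro-categories
# ---------------------------------------------------------------------------

def build_domain_embeddings(
    fit: NnmfFit,
    table: EmbeddingTable,
    top_n: int = 20,
) -> DomainModel:
    """Summarize each NNMF component by the mean embedding of its ``top_n``
    highest-H lemmas (ties at the boundary broken lexicographically).
    Components whose H row is entirely zero are dropped with a warning."""
    if fit.H.shape[1] != len(table):
        raise ValueError("NNMF fit and embedding table lemma counts differ")
    lemmas = np.asarray(table.lemmas)
    embeddings, tops = [], []
    for k in range(fit.K):
        h = fit.H[k]
        nz = np.flatnonzero(h > 0)
        if nz.size == 0:
            warnings.warn(f"domain {k} has an all-zero H row; dropped", RuntimeWarning)
            continue
        order = nz[np.lexsort((lemmas[nz], -h[nz]))]
        chosen = order[: min(top_n, len(order))]
        tops.append(lemmas[chosen].tolist())
        embeddings.append(table.vectors[chosen].mean(axis=0))
    if not embeddings:
        raise ValueError("no non-degenerate domains")
    return DomainModel(embeddings=np.vstack(embeddings), top_lemmas=tops)


def classical_mds(D: np.ndarray, n_dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling of a distance matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_dims]
    vals_t = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals_t)


def cluster_macro_categories(
    model: DomainModel,
    k_range=None,
    kmeans_reps: int = 1000,
    seed: int = 0,
    flat_silhouette: float = 0.05,
) -> DomainModel:
    """Group domains into macro-categories.

    Pipeline: cosine similarity between domain embeddings -> classical MDS to
    two dimensions -> k-means (``kmeans_reps`` restarts) for each candidate
    cluster count -> keep the count maximizing the mean silhouette.  If no
    candidate reaches ``flat_silhouette`` the result is flagged as having no
    macro structure (e.g. all domain embeddings nearly identical).

    Returns the model with ``macro_assignment``, ``macro_k`` and
    ``mds_coords`` filled in.
    """
    n = model.n_domains
    if n < 3:
        raise ValueError("need at least 3 domains for macro clustering")
    if k_range is None:
        k_range = range(2, min(10, n - 1) + 1)
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("no valid cluster counts in k_range")
    sim = cosine_rows(model.embeddings, model.embeddings)
    D = np.sqrt(np.clip(2.0 * (1.0 - sim), 0.0, None))
    # near-identical embeddings: clustering noise, not structure
    near_identical = bool(D.max() < 0.05)
    coords = classical_mds(D, 2)
    best = (-np.inf, None, None)
    for i, k in enumerate(k_range):
        km = KMeans(n_clusters=k, n_init=kmeans_reps, random_state=seed + i)
        lab = km.fit_predict(coords)
        if len(np.unique(lab)) < 2:
            continue
        sil = silhouette_score(coords, lab)
        if sil > best[0]:
            best = (sil, k, lab)
    sil, k, lab = best
    model.mds_coords = coords
    model.macro_k = k
    model.macro_assignment = lab
    model.no_macro_structure = bool(near_identical or sil < flat_silhouette)
    return model
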