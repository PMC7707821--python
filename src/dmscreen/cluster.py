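"""Unsupervised grouping of residues by their mutational response profiles.

Amino acids are collapsed into eight physicochemical classes; per residue
the mean activity of each class at each agonist condition forms one row of
the design matrix (log2, column-standardised, mean-imputed — a 412 x 32
matrix for the full receptor at four conditions). The matrix is embedded
with UMAP over a grid of (n_neighbors, n_components), each embedding is
density-clustered with HDBSCAN (minPts = 10), and a consensus over the runs
replaces manual cluster assignment: residues are grouped by how often they
co-cluster across embeddings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import HDBSCAN

logger = logging.getLogger(__name__)

#: the eight physicochemical amino-acid classes
AA_CLASSES: dict[str, str] = {
    "positive": "RHK",
    "negative": "DE",
    "aromatic": "FWY",
    "amide": "NQ",
    "nucleophilic": "CST",
    "hydrophobic": "ILVM",
    "small": "GA",
    "proline": "P",
}

N_NEIGHBORS_GRID: tuple[int, ...] = (4, 8, 16, 32)
N_COMPONENTS_GRID: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8, 9, 10)
MIN_DIST = 0.0
N_EPOCHS = 2000
MIN_PTS = 10
DISPLAY_SEED = 3308004
LOG2_FLOOR = 1e-3


def aa_class_of(aa: str) -> str | None:
    for name, members in AA_CLASSES.items():
        if aa in members:
            return name
    return None


def build_class_matrix(
    activity: pd.DataFrame,
    conditions: list[str] | None = None,
    epsilon: float = LOG2_FLOOR,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residue x (condition, class) design matrix.

    Per residue, condition and class: mean activity of the substitutions to
    that class, log2 (activities floored at ``epsilon``), then standardised
    per column over observed entries; missing entries are mean-imputed (0
    after standardisation). Returns (matrix, imputed_mask). Residues with no
    observed class at all are dropped with a warning.
    """
    mis = activity[activity["call_class"] == "missense"].dropna(subset=["position"]).copy()
    if conditions is None:
        conditions = sorted(mis["condition"].unique())
    mis = mis[mis["condition"].isin(conditions)]
    mis["aa_class"] = mis["mut_aa"].map(aa_class_of)
    mis["position"] = mis["position"].astype(int)

    mean_act = (mis.groupby(["position", "condition", "aa_class"])["activity"]
                .mean().unstack(["condition", "aa_class"]))
    cols = pd.MultiIndex.from_product([conditions, list(AA_CLASSES)],
                                      names=["condition", "aa_class"])
    mean_act = mean_act.reindex(columns=cols)

    empty = mean_act.isna().all(axis=1)
    if empty.any():
        logger.warning("dropping %d residues with no measured class", int(empty.sum()))
        mean_act = mean_act.loc[~empty]

    logged = np.log2(mean_act.clip(lower=epsilon))
    mu = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=0).replace(0.0, 1.0)
    z = (logged - mu) / sd
    mask = z.isna()
    z = z.fillna(0.0)  # mean imputation on the standardised scale
    return z, mask


@dataclass
class EmbeddingRun:
    """One UMAP embedding plus its HDBSCAN labels (-1 = noise)."""

    n_neighbors: int
    n_components: int
    min_dist: float
    n_epochs: int
    seed: int
    min_pts: int
    embedding: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)


def _umap_embed(X: np.ndarray, n_neighbors: int, n_components: int,
                min_dist: float, n_epochs: int, seed: int) -> np.ndarray:
    import umap  # deferred: numba compilation is slow at import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=n_neighbors, n_components=n_components,
            min_dist=min_dist, n_epochs=n_epochs, random_state=seed,
        )
        return reducer.fit_transform(X)


def hdbscan_labels(embedding: np.ndarray, min_pts: int = MIN_PTS) -> np.ndarray:
    """HDBSCAN with minPts semantics (min cluster size = core k = minPts)."""
    model = HDBSCAN(min_cluster_size=min_pts, min_samples=min_pts, copy=True)
    return model.fit_predict(embedding)


def sweep_embeddings(
    matrix: pd.DataFrame,
    n_neighbors_grid: tuple[int, ...] = N_NEIGHBORS_GRID,
    n_components_grid: tuple[int, ...] = N_COMPONENTS_GRID,
    min_dist: float = MIN_DIST,
    n_epochs: int = N_EPOCHS,
    min_pts: int = MIN_PTS,
    seed: int = 0,
) -> list[EmbeddingRun]:
    """UMAP x HDBSCAN over the hyperparameter grid (4 x 9 = 36 runs default).

    Each grid point gets a deterministic seed derived from ``seed``. Grid
    points with n_neighbors >= number of rows are skipped with a warning.
    """
    X = matrix.to_numpy(dtype=float)
    runs: list[EmbeddingRun] = []
    for i, n_nb in enumerate(n_neighbors_grid):
        for j, n_cp in enumerate(n_components_grid):
            if n_nb >= len(X):
                logger.warning("skipping n_neighbors=%d >= %d rows", n_nb, len(X))
                continue
            run_seed = int(np.random.SeedSequence([seed, i, j]).generate_state(1)[0] % 2**31)
            emb = _umap_embed(X, n_nb, n_cp, min_dist, n_epochs, run_seed)
            labels = hdbscan_labels(emb, min_pts)
            runs.append(EmbeddingRun(n_nb, n_cp, min_dist, n_epochs, run_seed,
                                     min_pts, emb, labels))
    return runs


def display_embedding(matrix: pd.DataFrame, seed: int = DISPLAY_SEED,
                      n_epochs: int = N_EPOCHS) -> pd.DataFrame:
    """Fixed 2D embedding for plotting (n_neighbors=4, min_dist=0)."""
    emb = _umap_embed(matrix.to_numpy(dtype=float), 4, 2, 0.0, n_epochs, seed)
    return pd.DataFrame(emb, index=matrix.index, columns=["umap1", "umap2"])


def coclustering_matrix(runs: list[EmbeddingRun]) -> np.ndarray:
    """Fraction of runs in which each residue pair shares a non-noise cluster."""
    n = len(runs[0].labels)
    C = np.zeros((n, n))
    for run in runs:
        lab = run.labels
        same = (lab[:, None] == lab[None, :]) & (lab[:, None] >= 0)
        C += same
    C /= len(runs)
    np.fill_diagonal(C, 1.0)
    return C


def consensus_clusters(
    runs: list[EmbeddingRun], k: int = 6
) -> tuple[np.ndarray, float, np.ndarray]:
    """Consensus residue clusters from co-clustering frequencies.

    Average-linkage hierarchical clustering on 1 - co-clustering frequency,
    cut to ``k`` clusters. Returns (labels 1..k, stability, C) where
    stability is the mean within-cluster co-clustering frequency.
    """
    C = coclustering_matrix(runs)
    if k == 1:
        return np.ones(len(C), dtype=int), 1.0, C
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")

    within = []
    for lab in np.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        if len(idx) < 2:
            within.append(1.0)
            continue
        sub = C[np.ix_(idx, idx)]
        within.append(float(sub[np.triu_indices(len(idx), 1)].mean()))
    return labels, float(np.mean(within)), C


def cluster_response_summary(
    labels: np.ndarray, matrix: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster mean response profile over (condition, class) columns."""
    df = matrix.copy()
    df["cluster"] = labels
    out = df.groupby("cluster").mean()
    empty = set(np.unique(labels)) - set(out.index)
    if empty:
        logger.warning("clusters with no members omitted: %s", sorted(empty))
    return out
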