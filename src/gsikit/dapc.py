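"""Discriminant analysis of principal components and K-means cluster discovery.

DAPC transforms mean-imputed, centered dosages with PCA and runs linear
discriminant analysis on the retained PC scores, maximizing among-group and
minimizing within-group variation without HWE or linkage assumptions.
Cluster discovery runs K-means on PC scores over a range of K and scores each
solution with BIC(K) = n·ln(W_K/n) + K·ln(n) (spherical Gaussian
approximation, W_K = total within-cluster sum of squares); the best K
minimizes BIC, smallest K on ties.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import train_test_split

from .containers import GenotypeMatrix


@dataclass
class DosageMatrix:
    """Numeric dosage matrix ready for multivariate analysis.

    Missing cells are imputed with the column mean of observed cells and the
    matrix is centered; the stored means allow exact round-trip of observed
    cells.  Scaling is off by default (dosage variance is bounded).
    """

    values: pd.DataFrame  # centered, imputed
    col_means: pd.Series
    col_scales: pd.Series
    individuals: list = field(default_factory=list)

    @property
    def markers(self) -> list:
        return list(self.values.columns)

    def array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def encode_genotypes(matrix: GenotypeMatrix, scale: bool = False) -> DosageMatrix:
    """Dosage 0/1/2 with mean imputation and centering.

    Markers with zero calls are dropped with a warning (their mean is
    undefined).
    """
    dos = matrix.dosage.copy()
    all_missing = dos.isna().all(axis=0)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} markers with zero calls: "
            f"{list(dos.columns[all_missing])[:5]}"
        )
        dos = dos.loc[:, ~all_missing]
    means = dos.mean(axis=0)
    filled = dos.fillna(means)
    scales = filled.std(axis=0, ddof=0).replace(0, 1.0) if scale else pd.Series(
        1.0, index=dos.columns
    )
    centered = (filled - means) / scales
    return DosageMatrix(centered, means, scales, list(matrix.individuals))


@dataclass
class DapcModel:
    """Fitted DAPC: PCA loadings + discriminant functions + posteriors."""

    n_pcs: int
    classes: list
    pca: PCA
    lda: LinearDiscriminantAnalysis
    coordinates: pd.DataFrame  # per-individual discriminant coordinates
    posteriors: pd.DataFrame  # per-individual class posterior probabilities
    disc_variance: np.ndarray  # proportion of discriminant variance per axis

    def transform(self, dosage: DosageMatrix) -> pd.DataFrame:
        scores = self.pca.transform(dosage.array())
        coords = self.lda.transform(scores)
        return pd.DataFrame(
            coords,
            index=dosage.individuals,
            columns=[f"LD{k + 1}" for k in range(coords.shape[1])],
        )

    def predict_proba(self, dosage: DosageMatrix) -> pd.DataFrame:
        scores = self.pca.transform(dosage.array())
        post = self.lda.predict_proba(scores)
        return pd.DataFrame(post, index=dosage.individuals, columns=self.lda.classes_)


def fit_dapc(dosage: DosageMatrix, labels, n_pcs: int) -> DapcModel:
    """PCA to ``n_pcs`` then LDA on the PC scores.

    Requires every class to have >= 2 members; the number of discriminant
    axes is min(n_pcs, n_classes - 1).
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    small = classes[counts < 2]
    if len(small):
        raise ValueError(f"classes with < 2 members: {list(small)}")
    x = dosage.array()
    rank = min(x.shape[0] - 1, x.shape[1])
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds rank {rank}")
    pca = PCA(n_components=n_pcs, svd_solver="full").fit(x)
    scores = pca.transform(x)
    lda = LinearDiscriminantAnalysis(solver="svd").fit(scores, y)
    coords = lda.transform(scores)
    post = lda.predict_proba(scores)
    ev = lda.explained_variance_ratio_
    return DapcModel(
        n_pcs=n_pcs,
        classes=list(classes),
        pca=pca,
        lda=lda,
        coordinates=pd.DataFrame(
            coords,
            index=dosage.individuals,
            columns=[f"LD{k + 1}" for k in range(coords.shape[1])],
        ),
        posteriors=pd.DataFrame(post, index=dosage.individuals, columns=lda.classes_),
        disc_variance=ev,
    )


def xval_dapc(
    dosage: DosageMatrix,
    labels,
    pc_grid,
    reps: int = 30,
    holdout_fraction: float = 0.1,
    seed: int = 0,
):
    """Cross-validated choice of the number of PCs.

    For each candidate PC count, repeated stratified holdout: fit DAPC on the
    training part, score assignment success on the holdout, and summarize as
    RMSE = sqrt(mean((1 - success)^2)) over repeats.  Returns
    ``(best n_pcs, DataFrame of RMSE per grid point)``; ties go to the
    smallest n_pcs.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if (counts * holdout_fraction < 1).any() and (counts < 2).any():
        raise ValueError("a class is too small to stratify")
    x_index = np.arange(len(y))
    pc_grid = sorted(int(p) for p in pc_grid)
    errors = {p: [] for p in pc_grid}
    rng = np.random.default_rng(seed)
    for rep in range(reps):
        tr, te = train_test_split(
            x_index,
            test_size=holdout_fraction,
            stratify=y,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        sub_train = DosageMatrix(
            dosage.values.iloc[tr],
            dosage.col_means,
            dosage.col_scales,
            [dosage.individuals[i] for i in tr],
        )
        sub_test = DosageMatrix(
            dosage.values.iloc[te],
            dosage.col_means,
            dosage.col_scales,
            [dosage.individuals[i] for i in te],
        )
        for p in pc_grid:
            model = fit_dapc(sub_train, y[tr], p)
            pred = model.predict_proba(sub_test).idxmax(axis=1).to_numpy()
            success = float((pred == y[te]).mean())
            errors[p].append(1.0 - success)
    rmse = pd.DataFrame(
        {
            "n_pcs": pc_grid,
            "rmse": [float(np.sqrt(np.mean(np.square(errors[p])))) for p in pc_grid],
        }
    )
    best = int(rmse.loc[rmse["rmse"].idxmin(), "n_pcs"])  # idxmin takes first = smallest
    return best, rmse


@dataclass
class ClusterSolution:
    """K-means solution over a K range with BIC model selection."""

    best_k: int
    assignments: pd.Series  # individual -> cluster id (1..K)
    bic: pd.Series  # K -> BIC value, full candidate range
    n_pcs: int


def find_clusters(
    dosage: DosageMatrix,
    k_range=range(1, 9),
    n_pcs: int | None = None,
    n_starts: int = 10,
    seed: int = 0,
) -> ClusterSolution:
    """K-means on PC scores with BIC over the candidate K range.

    BIC(K) = n·ln(W_K/n) + K·ln(n); best K minimizes BIC (smallest K wins
    ties).  K-means uses ``n_starts`` restarts of Lloyd iterations.
    """
    x = dosage.array()
    n = x.shape[0]
    k_range = sorted(int(k) for k in k_range)
    if min(k_range) < 1 or max(k_range) > n - 1:
        raise ValueError("k_range must lie within [1, n-1]")
    if n_pcs is None:
        n_pcs = min(n - 1, x.shape[1])
    pca = PCA(n_components=n_pcs, svd_solver="full").fit(x)
    scores = pca.transform(x)

    bic_vals = {}
    best_assign = {}
    for k in k_range:
        if k == 1:
            w = float(((scores - scores.mean(axis=0)) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(
                n_clusters=k,
                n_init=n_starts,
                algorithm="lloyd",
                tol=1e-8,
                max_iter=300,
                random_state=seed,
            ).fit(scores)
            w = float(km.inertia_)
            labels = km.labels_
        bic_vals[k] = n * np.log(w / n) + k * np.log(n)
        best_assign[k] = labels + 1  # clusters numbered 1..K
    bic = pd.Series(bic_vals).sort_index()
    best_k = int(bic.idxmin())  # idxmin returns the first (smallest K) on ties
    return ClusterSolution(
        best_k=best_k,
        assignments=pd.Series(best_assign[best_k], index=dosage.individuals, name="cluster"),
        bic=bic,
        n_pcs=n_pcs,
    )


def map_clusters_to_proxies(
    solution: ClusterSolution,
    known_labels: pd.Series,
    majority_threshold: float = 0.8,
):
    """Relabel clusters as population proxies from their known-label composition.

    Builds the two composition views (percentage of each population split by
    cluster, and percentage of each cluster split by population).  A cluster
    whose composition exceeds ``majority_threshold`` for one label becomes a
    proxy for that label (clusters sharing a majority label are merged); a
    cluster below threshold becomes an explicit mixed proxy named by its two
    most frequent labels ("A/B").

    Returns ``(proxy Series per individual, dict of the two composition
    DataFrames in percent)``.
    """
    clusters = solution.assignments
    labels = known_labels.loc[clusters.index]
    ct = pd.crosstab(labels, clusters)  # populations x clusters, counts
    pop_by_cluster = ct.div(ct.sum(axis=1), axis=0) * 100  # rows sum to 100
    cluster_by_pop = ct.div(ct.sum(axis=0), axis=1) * 100  # columns sum to 100

    proxy_of_cluster = {}
    for k in ct.columns:
        comp = cluster_by_pop[k].sort_values(ascending=False)
        if comp.iloc[0] / 100.0 > majority_threshold:
            proxy_of_cluster[k] = str(comp.index[0])
        else:
            top2 = sorted(comp.index[:2], key=lambda p: -comp[p])
            proxy_of_cluster[k] = f"{top2[0]}/{top2[1]}"
    proxies = clusters.map(proxy_of_cluster).rename("proxy")
    return proxies, {
        "populations_by_cluster": pop_by_cluster,
        "clusters_by_population": cluster_by_pop,
        "proxy_of_cluster": proxy_of_cluster,
    }
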