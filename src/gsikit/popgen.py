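"""Baseline population-genetic characterization.

Hardy-Weinberg exact tests (Levene conditional distribution), genotypic LD
G-tests with permutation nulls, multi-locus pairwise Weir-Cockerham (1984)
F_ST with permutation p-values and locus-bootstrap confidence intervals,
Holm (sequential Bonferroni) correction, and principal coordinate analysis
of the resulting distance matrix.

Missing genotypes are excluded pairwise per locus throughout; nothing is
imputed for these statistics.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import BaselineDataset


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _levene_log_pmf(n: int, n1: int, het_values: np.ndarray) -> np.ndarray:
    """Log P(#het = h | allele counts) under the Levene conditional distribution.

    n diploid individuals, n1 copies of allele 1 (so n2 = 2n - n1):
        P(h) = n! 2^h n1! n2! / ( n11! h! n22! (2n)! )
    with n11 = (n1-h)/2 homozygotes for allele 1 and n22 = (n2-h)/2.
    """
    n2 = 2 * n - n1
    h = het_values.astype(float)
    n11 = (n1 - h) / 2.0
    n22 = (n2 - h) / 2.0
    return (
        gammaln(n + 1)
        + h * np.log(2.0)
        + gammaln(n1 + 1)
        + gammaln(n2 + 1)
        - gammaln(n11 + 1)
        - gammaln(h + 1)
        - gammaln(n22 + 1)
        - gammaln(2 * n + 1)
    )


def _het_support(n1: int, n2: int) -> np.ndarray:
    """All possible heterozygote counts given allele counts (parity-matched)."""
    lo = n1 % 2
    hi = min(n1, n2)
    return np.arange(lo, hi + 1, 2)


def hwe_test(
    n_hom1: int,
    n_het: int,
    n_hom2: int,
    alternative: str = "two-sided",
    max_exact: int = 500,
    n_mc: int = 100_000,
    seed: int = 0,
):
    """Exact conditional HWE test on one biallelic locus.

    ``alternative``: "two-sided" (probability test: sum of all outcomes no
    more probable than the observed one), "deficit" (heterozygote deficiency:
    P(#het <= observed)), or "excess" (P(#het >= observed)).

    Exact enumeration of the Levene distribution for totals <= ``max_exact``;
    above that a seeded Monte Carlo version shuffles the 2n alleles into
    genotypes.  Monomorphic loci return p = 1 with ``monomorphic=True``.

    Returns ``(p_value, monomorphic_flag)``.
    """
    if min(n_hom1, n_het, n_hom2) < 0 or (n_hom1 + n_het + n_hom2) == 0:
        raise ValueError("genotype counts must be non-negative with positive total")
    if alternative not in {"two-sided", "deficit", "excess"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    n = n_hom1 + n_het + n_hom2
    n1 = 2 * n_hom1 + n_het
    n2 = 2 * n_hom2 + n_het
    if n1 == 0 or n2 == 0:
        return 1.0, True

    if n <= max_exact:
        support = _het_support(n1, n2)
        logp = _levene_log_pmf(n, n1, support)
        logp -= np.logaddexp.reduce(logp)  # normalize for numerical safety
        pmf = np.exp(logp)
        obs_idx = int(np.searchsorted(support, n_het))
        if alternative == "two-sided":
            p = float(pmf[pmf <= pmf[obs_idx] * (1 + 1e-12)].sum())
        elif alternative == "deficit":
            p = float(pmf[support <= n_het].sum())
        else:
            p = float(pmf[support >= n_het].sum())
        return min(p, 1.0), False

    # Monte Carlo: shuffle alleles into n diploid genotypes
    rng = np.random.default_rng(seed)
    alleles = np.concatenate([np.zeros(n1, dtype=np.int8), np.ones(n2, dtype=np.int8)])
    obs_logp = _levene_log_pmf(n, n1, np.array([n_het]))[0]
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(alleles)
        h = int((alleles[0::2] != alleles[1::2]).sum())
        if alternative == "two-sided":
            hits += _levene_log_pmf(n, n1, np.array([h]))[0] <= obs_logp + 1e-12
        elif alternative == "deficit":
            hits += h <= n_het
        else:
            hits += h >= n_het
    return (hits + 1) / (n_mc + 1), False


@dataclass
class LocusTestResult:
    """Per-locus HWE test bundle."""

    locus: str
    p_hwe: float
    p_deficit: float
    p_excess: float
    monomorphic: bool = False
    significant: bool | None = None  # set after multiple-test correction


def hwe_scan(baseline: BaselineDataset, alpha: float = 0.05) -> pd.DataFrame:
    """HWE, heterozygote-deficit and -excess tests per locus (pooled sample).

    Applies Holm correction to the two-sided p-values and flags survivors.
    """
    dos = baseline.genotypes.dosage
    rows = []
    for locus in dos.columns:
        col = dos[locus].dropna()
        n_hom1 = int((col == 2).sum())
        n_het = int((col == 1).sum())
        n_hom2 = int((col == 0).sum())
        if len(col) == 0:
            rows.append(LocusTestResult(locus, 1.0, 1.0, 1.0, True))
            continue
        p2, mono = hwe_test(n_hom1, n_het, n_hom2, "two-sided")
        pd_, _ = hwe_test(n_hom1, n_het, n_hom2, "deficit")
        pe, _ = hwe_test(n_hom1, n_het, n_hom2, "excess")
        rows.append(LocusTestResult(locus, p2, pd_, pe, mono))
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["significant"] = sequential_bonferroni(df["p_hwe"].to_numpy(), alpha)
    return df


# ---------------------------------------------------------------------------
# Linkage disequilibrium (genotypic G-test with permutation null)
# ---------------------------------------------------------------------------

def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood ratio statistic on a contingency table (0 cells ignored)."""
    total = table.sum()
    if total == 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    mask = table > 0
    return float(2.0 * (table[mask] * np.log(table[mask] / expected[mask])).sum())


def ld_test(
    geno_a,
    geno_b,
    n_permutations: int = 1000,
    seed: int = 0,
):
    """Genotypic LD test for one locus pair.

    Builds the genotype contingency table (up to 3x3) over individuals called
    at both loci and compares its G statistic against a null obtained by
    permuting one locus's genotypes across individuals.  Phase is unknown, so
    the test is genotypic, not haplotypic.

    Returns ``(p_value, monomorphic_flag)``; a locus monomorphic in the
    sample gives p = 1 with the flag set.
    """
    a = np.asarray(geno_a, dtype=float)
    b = np.asarray(geno_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok].astype(int), b[ok].astype(int)
    if len(a) < 2:
        raise ValueError("need >= 2 individuals called at both loci")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return 1.0, True

    def table_of(x, y):
        t = np.zeros((3, 3))
        np.add.at(t, (x, y), 1)
        return t

    g_obs = _g_statistic(table_of(a, b))
    rng = np.random.default_rng(seed)
    b_perm = b.copy()
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(b_perm)
        if _g_statistic(table_of(a, b_perm)) >= g_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1), False


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def wc_variance_components(dosages: list[np.ndarray]):
    """Per-locus Weir-Cockerham (1984) variance components for r groups.

    ``dosages`` is one array per group of allele-1 dosages (0/1/2 with NaN
    missing) shaped (individuals, loci).  Returns ``(a, b, c)`` arrays of
    per-locus components; loci where any group has < 2 called individuals
    come back as NaN in all three.
    """
    r = len(dosages)
    if r < 2:
        raise ValueError("need >= 2 groups")
    n_loci = dosages[0].shape[1]
    n_i = np.zeros((r, n_loci))
    p_i = np.zeros((r, n_loci))
    h_i = np.zeros((r, n_loci))
    for i, d in enumerate(dosages):
        called = ~np.isnan(d)
        n_i[i] = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_i[i] = np.nansum(d, axis=0) / (2 * n_i[i])
            h_i[i] = np.nansum(d == 1, axis=0) / n_i[i]

    bad = (n_i < 2).any(axis=0)
    n_bar = n_i.mean(axis=0)
    n_total = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (n_total - (n_i**2).sum(axis=0) / n_total) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / n_total
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / n_total

        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - ((r - 1) / r) * s2
            - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def multilocus_fst(dosages: list[np.ndarray]) -> float:
    """Multi-locus theta: ratio of summed components sum(a)/sum(a+b+c).

    Negative estimates are reported as computed (never truncated to zero).
    """
    a, b, c = wc_variance_components(dosages)
    ok = ~np.isnan(a)
    denom = (a + b + c)[ok].sum()
    if denom == 0:
        return np.nan
    return float(a[ok].sum() / denom)


@dataclass
class FstMatrix:
    """Pairwise multi-locus F_ST with permutation p-values and bootstrap CIs."""

    labels: list
    estimate: pd.DataFrame
    p_value: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    estimator: str = "Weir-Cockerham 1984, ratio-of-sums multilocus"

    def to_csv(self, prefix) -> None:
        self.estimate.to_csv(f"{prefix}_fst.csv")
        self.p_value.to_csv(f"{prefix}_pvalues.csv")
        self.ci_low.to_csv(f"{prefix}_ci_low.csv")
        self.ci_high.to_csv(f"{prefix}_ci_high.csv")


def pairwise_fst(
    baseline: BaselineDataset,
    grouping: str = "population",
    n_permutations: int = 10_000,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> FstMatrix:
    """All pairwise multi-locus F_ST between groups of the baseline.

    P-values permute individuals between the two groups of a pair (one-sided,
    large theta extreme); 95% CIs bootstrap loci with the ratio-of-sums
    recombination.  Loci unusable in a pair (any group < 2 called
    individuals) are dropped pairwise with a warning.
    """
    labels_series = baseline.metadata[grouping]
    groups = list(dict.fromkeys(labels_series))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    dos_all = baseline.genotypes.dosage.to_numpy(dtype=float)
    idx_of = {g: np.flatnonzero((labels_series == g).to_numpy()) for g in groups}
    for g, idx in idx_of.items():
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 individuals")

    k = len(groups)
    est = np.zeros((k, k))
    pval = np.zeros((k, k))
    lo = np.zeros((k, k))
    hi = np.zeros((k, k))
    rng = np.random.default_rng(seed)

    for i in range(k):
        for j in range(i + 1, k):
            d1 = dos_all[idx_of[groups[i]]]
            d2 = dos_all[idx_of[groups[j]]]
            a, b, c = wc_variance_components([d1, d2])
            usable = ~np.isnan(a)
            if not usable.all():
                warnings.warn(
                    f"pair ({groups[i]}, {groups[j]}): dropping "
                    f"{int((~usable).sum())} loci with insufficient calls"
                )
            a_u, abc_u = a[usable], (a + b + c)[usable]
            theta = a_u.sum() / abc_u.sum()
            est[i, j] = est[j, i] = theta

            # permutation p-value: shuffle individuals between the two groups
            pooled = np.vstack([d1, d2])
            n1 = d1.shape[0]
            hits = 0
            for _ in range(n_permutations):
                perm = rng.permutation(pooled.shape[0])
                t = multilocus_fst([pooled[perm[:n1]], pooled[perm[n1:]]])
                if t >= theta - 1e-12:
                    hits += 1
            pval[i, j] = pval[j, i] = (hits + 1) / (n_permutations + 1)

            # bootstrap over loci
            n_u = len(a_u)
            boots = np.empty(n_bootstrap)
            for t_ in range(n_bootstrap):
                pick = rng.integers(0, n_u, size=n_u)
                denom = abc_u[pick].sum()
                boots[t_] = a_u[pick].sum() / denom if denom != 0 else np.nan
            lo[i, j] = lo[j, i] = np.nanpercentile(boots, 2.5)
            hi[i, j] = hi[j, i] = np.nanpercentile(boots, 97.5)

    def df(x):
        return pd.DataFrame(x, index=groups, columns=groups)

    return FstMatrix(groups, df(est), df(pval), df(lo), df(hi))


def perlocus_fst(dosages: list[np.ndarray]) -> np.ndarray:
    """Per-locus theta a/(a+b+c); NaN where undefined."""
    a, b, c = wc_variance_components(dosages)
    with np.errstate(invalid="ignore", divide="ignore"):
        return a / (a + b + c)


# ---------------------------------------------------------------------------
# Multiple testing and ordination
# ---------------------------------------------------------------------------

def sequential_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down correction; returns a boolean significance flag array.

    Flags are monotone: if the i-th smallest p is significant, all smaller
    p-values are too.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] < alpha / (m - rank):
            flags[idx] = True
        else:
            break  # step-down stops at the first failure
    return flags


def pcoa(distances: pd.DataFrame):
    """Classical metric multidimensional scaling of a distance matrix.

    Double-centers the squared distances and eigendecomposes; axes are
    ordered by eigenvalue, axes with non-positive eigenvalues are dropped
    from the coordinates but all eigenvalues are reported.

    Returns ``(coordinates DataFrame, percent-variance Series, eigenvalues)``.
    """
    d = np.asarray(distances, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-12):
        raise ValueError("distance matrix must have zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > 1e-10
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    pos_sum = eigval[keep].sum()
    pct = 100.0 * eigval[keep] / pos_sum if pos_sum > 0 else eigval[keep] * 0
    labels = list(distances.index) if isinstance(distances, pd.DataFrame) else list(range(n))
    axes = [f"PCo{k + 1}" for k in range(int(keep.sum()))]
    return (
        pd.DataFrame(coords, index=labels, columns=axes),
        pd.Series(pct, index=axes, name="percent_variance"),
        eigval,
    )
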