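"""Diversity, ordination, permutation tests and compositional statistics.

Implements the 16S analysis layer: observed richness, Bray–Curtis
dissimilarity, principal coordinate analysis (PCoA), PERMANOVA with a
seeded permutation test, partial constrained analysis of principal
coordinates (CAP / db-RDA with a conditioned nuisance term), the ANCOM W
statistic for compositional differential abundance, and CLR–phenotype
Pearson correlation tables.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .preprocess import CountTable, bh_fdr

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "CapResult",
    "AncomResult",
    "observed_richness",
    "bray_curtis",
    "pcoa",
    "permanova",
    "cap_partial",
    "ancom_w",
    "clr_phenotype_correlations",
]


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with ids."""

    sample_ids: list
    data: np.ndarray

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        d = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (d < -1e-12).any():
            raise ValueError("negative distances")
        self.data = (d + d.T) / 2.0

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column ids differ")
        return cls(list(df.index), df.to_numpy())


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    seed: int | None


@dataclass
class CapResult:
    """Inertia decomposition of a partial db-RDA.

    Fractions are of the total inertia of the positive-eigenvalue PCoA
    embedding; ``constrained + conditioned + residual`` sums to 1.
    """

    term_variance: pd.Series        # fraction explained per constraint term
    term_p: pd.Series               # permutation p per term
    constrained: float
    conditioned: float
    residual: float
    n_permutations: int
    seed: int | None


@dataclass
class AncomResult:
    taxa_ids: list
    w: np.ndarray
    detected: np.ndarray
    threshold: float
    alpha: float
    pvalues: pd.DataFrame | None = field(default=None, repr=False)

    def detected_taxa(self) -> list:
        return [t for t, d in zip(self.taxa_ids, self.detected) if d]


def observed_richness(table: CountTable) -> pd.Series:
    """Number of taxa with count > 0 per sample."""
    return pd.Series((table.counts > 0).sum(axis=0), index=table.sample_ids,
                     name="observed_otus")


def bray_curtis(abundance, sample_ids=None) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between samples (rows).

    d_ij = 1 - 2 sum_k min(x_ik, x_jk) / (sum_k x_ik + sum_k x_jk);
    bounded in [0, 1] for non-negative data.  The triangle inequality is
    not guaranteed and not asserted.
    """
    if isinstance(abundance, pd.DataFrame):
        if sample_ids is None:
            sample_ids = list(abundance.index)
        abundance = abundance.to_numpy()
    X = np.asarray(abundance, dtype=float)
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    zero = X.sum(axis=1) == 0
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(X.shape[0])]
    if zero.any():
        bad = [s for s, z in zip(sample_ids, zero) if z]
        raise ValueError(f"all-zero sample(s): {bad}")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(sample_ids, d)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis (classical MDS).

    Eigendecomposition of the Gower-centered -0.5 D^2 matrix; coordinates
    are eigenvectors scaled by sqrt(eigenvalue) for positive eigenvalues.
    Negative eigenvalues (non-Euclidean distances) are reported, not
    corrected and not used for coordinates.
    """
    g = _gower_center(dist.data)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-10 * abs(evals[0]) if evals.size else 0.0)
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    axes = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    total_pos = evals[pos].sum()
    prop = evals[pos] / total_pos if total_pos > 0 else np.zeros(int(pos.sum()))
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dist.sample_ids, columns=axes),
        eigenvalues=evals[pos],
        proportion_explained=prop,
        negative_eigenvalues=evals[evals < -tol],
    )


def _permanova_f(d2: np.ndarray, groups: np.ndarray, uniq: np.ndarray):
    """Pseudo-F and R^2 from squared distances (Anderson's formulation)."""
    n = d2.shape[0]
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for g in uniq:
        idx = np.flatnonzero(groups == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ssa = sst - ssw
    a = uniq.size
    f = (ssa / (a - 1)) / (ssw / (n - a)) if ssw > 0 else math.inf
    r2 = ssa / sst if sst > 0 else 0.0
    return f, r2


def permanova(dist: DistanceMatrix, groups, n_permutations: int = 999,
              seed: int | None = 0, exhaustive: bool = False) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Whole-sample label permutations; p = (1 + #{F_perm >= F_obs}) /
    (1 + n_permutations).  With ``exhaustive=True`` all n! label
    permutations are enumerated (identity included) and p is the exact
    fraction with F >= F_obs — feasible only for small n.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    counts = [int((groups == g).sum()) for g in uniq]
    if min(counts) < 1:
        raise ValueError("empty group")
    d2 = dist.data ** 2
    f_obs, r2 = _permanova_f(d2, groups, uniq)

    if exhaustive:
        n = dist.n_samples
        fs = [
            _permanova_f(d2, groups[list(perm)], uniq)[0]
            for perm in itertools.permutations(range(n))
        ]
        ge = sum(1 for f in fs if f >= f_obs - 1e-12)
        return PermanovaResult(f_obs, r2, ge / len(fs), len(fs), None)

    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_permutations):
        f_p, _ = _permanova_f(d2, rng.permutation(groups), uniq)
        if f_p >= f_obs - 1e-12:
            ge += 1
    p = (1 + ge) / (1 + n_permutations)
    return PermanovaResult(f_obs, r2, p, n_permutations, seed)


def _design_columns(df: pd.DataFrame) -> tuple[np.ndarray, list[tuple[str, slice]]]:
    """Dummy-encode factors (first level reference); numeric columns pass
    through centered.  Returns the column matrix and per-term slices."""
    mats, terms, start = [], [], 0
    for col in df.columns:
        s = df[col]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object or s.dtype == bool:
            dummies = pd.get_dummies(s, drop_first=True).to_numpy(dtype=float)
        else:
            dummies = s.to_numpy(dtype=float)[:, None]
        dummies = dummies - dummies.mean(axis=0)
        mats.append(dummies)
        terms.append((col, slice(start, start + dummies.shape[1])))
        start += dummies.shape[1]
    if not mats:
        return np.empty((len(df), 0)), []
    return np.hstack(mats), terms


def _project(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Least-squares fitted values of y on columns of x (x may be rank 0)."""
    if x.shape[1] == 0:
        return np.zeros_like(y)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return x @ beta


def cap_partial(dist: DistanceMatrix, constraints: pd.DataFrame,
                condition: pd.DataFrame | None = None,
                n_permutations: int = 999, seed: int | None = 0,
                permute: str = "residuals") -> CapResult:
    """Partial constrained analysis of principal coordinates (db-RDA).

    The distance matrix is embedded via PCoA (positive axes).  Nuisance
    ``condition`` factors are regressed out first; residuals are then
    projected onto the (conditioned) constraint space.  Per-term variance
    fractions are sequential in column order; significance is assessed by
    Freedman–Lane permutation of the reduced-model residuals
    (``permute="labels"`` permutes raw embedded rows instead).
    """
    ord_res = pcoa(dist)
    y = ord_res.coordinates.to_numpy()
    y = y - y.mean(axis=0)
    total = float((y ** 2).sum())
    if total <= 0:
        raise ValueError("degenerate distance matrix: zero total inertia")

    constraints = constraints.loc[dist.sample_ids] if set(dist.sample_ids) <= set(
        constraints.index) else constraints.reset_index(drop=True)
    if condition is not None:
        condition = condition.loc[dist.sample_ids] if set(dist.sample_ids) <= set(
            condition.index) else condition.reset_index(drop=True)

    z, _ = _design_columns(condition) if condition is not None else (
        np.empty((len(y), 0)), [])
    x, terms = _design_columns(pd.DataFrame(constraints))
    n = y.shape[0]
    if n < x.shape[1] + z.shape[1] + 2:
        raise ValueError("too few samples for the requested design")

    y_fit_z = _project(y, z)
    y_res = y - y_fit_z
    conditioned = float((y_fit_z ** 2).sum())

    x_res = x - _project(x, z)
    rank = np.linalg.matrix_rank(x_res) if x_res.shape[1] else 0
    if x_res.shape[1] and rank < x_res.shape[1]:
        raise ValueError("constraint matrix is rank-deficient after conditioning")

    y_hat = _project(y_res, x_res)
    constrained = float((y_hat ** 2).sum())
    residual = float(((y_res - y_hat) ** 2).sum())

    # sequential per-term inertia in column order
    term_var, term_df = {}, {}
    prev = np.empty((n, 0))
    prev_fit_ss = 0.0
    for name, sl in terms:
        cur = np.hstack([prev, x_res[:, sl]])
        fit_ss = float((_project(y_res, cur) ** 2).sum())
        term_var[name] = (fit_ss - prev_fit_ss) / total
        term_df[name] = sl.stop - sl.start
        prev, prev_fit_ss = cur, fit_ss

    df_res = n - 1 - x_res.shape[1] - z.shape[1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    rng = np.random.default_rng(seed)
    term_ge = {name: 0 for name, _ in terms}
    obs_f = {
        name: (term_var[name] * total / term_df[name]) / (residual / df_res)
        for name, _ in terms
    }
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        y_p = y_res[perm] if permute == "residuals" else (y - y.mean(axis=0))[perm] - \
            _project((y - y.mean(axis=0))[perm], z)
        y_hat_p = _project(y_p, x_res)
        resid_p = float(((y_p - y_hat_p) ** 2).sum())
        prev_p, prev_ss = np.empty((n, 0)), 0.0
        for name, sl in terms:
            cur = np.hstack([prev_p, x_res[:, sl]])
            fit_ss = float((_project(y_p, cur) ** 2).sum())
            f_p = ((fit_ss - prev_ss) / term_df[name]) / (resid_p / df_res)
            if f_p >= obs_f[name] - 1e-12:
                term_ge[name] += 1
            prev_p, prev_ss = cur, fit_ss
    term_p = {
        name: (1 + term_ge[name]) / (1 + n_permutations) for name, _ in terms
    }
    return CapResult(
        term_variance=pd.Series(term_var, name="variance_fraction"),
        term_p=pd.Series(term_p, name="p_value"),
        constrained=constrained / total,
        conditioned=conditioned / total,
        residual=residual / total,
        n_permutations=n_permutations,
        seed=seed,
    )


def ancom_w(table: CountTable, groups, alpha: float = 0.05,
            pseudocount: float = 1.0, threshold_fraction: float = 0.7,
            keep_pvalues: bool = False) -> AncomResult:
    """Analysis of composition of microbiomes (ANCOM) W statistic.

    For each ordered taxon pair (i, j != i), test equality of location of
    log((x_i + pc)/(x_j + pc)) across groups — Wilcoxon rank-sum for two
    groups, Kruskal–Wallis otherwise.  Within each focal taxon i its m-1
    p-values are BH-adjusted at ``alpha``; W_i counts rejections.  A taxon
    is flagged when W_i >= threshold_fraction * (m - 1).
    """
    m = table.n_taxa
    if m < 3:
        raise ValueError("ANCOM requires at least 3 taxa")
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    logx = np.log(table.counts.astype(float) + pseudocount)  # taxa x samples
    masks = [groups == g for g in uniq]
    pmat = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            if j < i and not np.isnan(pmat[j, i]):
                pmat[i, j] = pmat[j, i]
                continue
            ratio = logx[i] - logx[j]
            grp_vals = [ratio[mk] for mk in masks]
            if np.ptp(ratio) == 0:
                pmat[i, j] = 1.0
                continue
            if uniq.size == 2:
                stat = stats.mannwhitneyu(grp_vals[0], grp_vals[1],
                                          alternative="two-sided")
            else:
                stat = stats.kruskal(*grp_vals)
            pmat[i, j] = stat.pvalue
    w = np.zeros(m, dtype=int)
    for i in range(m):
        pv = np.delete(pmat[i], i)
        q = bh_fdr(pv)
        w[i] = int((q < alpha).sum())
    detected = w >= threshold_fraction * (m - 1)
    pvals = None
    if keep_pvalues:
        pvals = pd.DataFrame(pmat, index=table.taxa_ids, columns=table.taxa_ids)
    return AncomResult(list(table.taxa_ids), w, detected,
                       float(threshold_fraction), float(alpha), pvals)


def clr_phenotype_correlations(clr_matrix, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations of CLR-transformed taxa with phenotypes.

    ``clr_matrix`` is taxa x samples (a NormalizedMatrix's values or a
    DataFrame); returns a tidy table of (taxon, phenotype, r, p, q) with
    BH-FDR across all pairs.
    """
    if hasattr(clr_matrix, "method"):  # NormalizedMatrix
        values = clr_matrix.values
    else:
        values = pd.DataFrame(clr_matrix)
    samples = list(values.columns)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    ph = phenotypes.loc[samples]
    rows = []
    for pheno in ph.columns:
        y = ph[pheno].to_numpy(dtype=float)
        if np.std(y) == 0:
            raise ValueError(f"zero-variance phenotype: {pheno!r}")
        for taxon in values.index:
            x = values.loc[taxon].to_numpy(dtype=float)
            if np.std(x) == 0:
                r, p = 0.0, 1.0
            else:
                r, p = stats.pearsonr(x, y)
            rows.append({"taxon": taxon, "phenotype": pheno, "r": r, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
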