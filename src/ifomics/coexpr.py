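"""Lean weighted co-expression network analysis.

Signed adjacency from Pearson correlation, soft-threshold selection by the
scale-free topology criterion, the topological overlap matrix (TOM),
module detection by average-linkage clustering with a static branch cut,
module eigengenes and kME, module–trait correlation, hub-gene selection
under conjunctive thresholds (kME > 0.8, |trait r| > 0.85, FDR-q < 0.01 by
default) and network-edge export (weight > 0.4 by default).

`CoexpressionNetwork` wraps the functional layer as a model object whose
``fit`` returns a `CoexpressionResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .preprocess import bh_fdr

__all__ = [
    "CoexpressionNetwork",
    "CoexpressionResults",
    "HubResult",
    "signed_adjacency",
    "pick_soft_threshold",
    "tom_similarity",
    "detect_modules",
    "module_eigengenes",
    "module_trait_correlation",
    "select_hub_genes",
    "export_network_edges",
]


def _corr_drop_constant(expr: pd.DataFrame):
    sd = expr.std(axis=0, ddof=1)
    zero = sd <= 0
    if zero.any():
        warnings.warn(
            f"dropping zero-variance gene(s): {list(expr.columns[zero])}")
        expr = expr.loc[:, ~zero]
    r = np.corrcoef(expr.to_numpy(), rowvar=False)
    return expr, np.atleast_2d(r)


def signed_adjacency(expr, beta: float = 6.0, signed: bool = True) -> pd.DataFrame:
    """Soft-thresholded adjacency a_ij = ((1 + r_ij)/2)^beta (signed network).

    ``signed=False`` gives the unsigned variant |r|^beta.  Zero-variance
    genes are dropped with a warning; the diagonal is 1.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    expr = pd.DataFrame(expr)
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    expr, r = _corr_drop_constant(expr)
    a = ((1.0 + r) / 2.0) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.columns, columns=expr.columns)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10):
    """R^2 (sign-adjusted) of log10 p(k) on log10 k over connectivity bins."""
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() > 0:
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return -np.sign(slope) * r ** 2, slope


def pick_soft_threshold(expr, powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14,
                                      16, 18, 20),
                        r2_target: float = 0.8, signed: bool = True,
                        n_bins: int = 10):
    """Choose the soft-threshold power by the scale-free topology criterion.

    For each candidate power the sign-adjusted R^2 of the log-log
    degree-distribution regression is computed; the smallest power reaching
    ``r2_target`` wins, else the argmax.  Returns (beta, fit table).
    """
    powers = list(powers)
    if not powers:
        raise ValueError("empty candidate power set")
    expr = pd.DataFrame(expr)
    if expr.shape[1] < 20:
        warnings.warn("fewer than 20 genes: scale-free fit is unreliable")
    rows = []
    for beta in powers:
        a = signed_adjacency(expr, beta=beta, signed=signed).to_numpy()
        k = a.sum(axis=0) - 1.0
        r2, slope = _scale_free_fit(k, n_bins=n_bins)
        rows.append({"power": beta, "sft_r2": r2, "slope": slope,
                     "mean_connectivity": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table[table["sft_r2"] >= r2_target]
    beta = float(ok["power"].iloc[0]) if len(ok) else float(
        table.loc[table["sft_r2"].idxmax(), "power"])
    return beta, table


def tom_similarity(adjacency) -> pd.DataFrame:
    """Topological overlap matrix.

    Omega_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_{u != i,j} a_iu a_uj and k_i the connectivity of node i;
    the diagonal is 1.  Values lie in [0, 1] for adjacencies in [0, 1].
    """
    df = pd.DataFrame(adjacency)
    a = df.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 1.0)
    a2 = a @ a
    # remove u == i and u == j terms from the path count
    l = a2 - 2.0 * a
    k = a.sum(axis=0) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = (l + a) / denom
    omega[~np.isfinite(omega)] = 0.0
    np.fill_diagonal(omega, 1.0)
    omega = np.clip((omega + omega.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(omega, index=df.index, columns=df.columns)


def detect_modules(tom, min_module_size: int = 30, cut_height: float = 0.25):
    """Average-linkage clustering of 1 - TOM with a static branch cut.

    Clusters smaller than ``min_module_size`` become label 0 (unassigned);
    surviving modules are renumbered 1..K by decreasing size.  Returns
    (labels Series, linkage matrix).
    """
    df = pd.DataFrame(tom)
    dissim = 1.0 - df.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = np.zeros(raw.size, dtype=int)
    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= min_module_size]
    kept.sort(key=lambda c: (-sizes[c], c))
    for new, old in enumerate(kept, start=1):
        labels[raw == old] = new
    if not kept:
        warnings.warn("no module reaches min_module_size; all genes unassigned")
    return pd.Series(labels, index=df.index, name="module"), z


def module_eigengenes(expr, labels):
    """Module eigengenes and kME.

    The eigengene of a module is the first principal component of its
    standardized expression (unit-norm over samples), sign-oriented so the
    mean gene–eigengene correlation is non-negative.  kME is the Pearson
    correlation of every gene with every module eigengene.
    Returns (eigengenes samples x modules, kME genes x modules).
    """
    expr = pd.DataFrame(expr)
    labels = pd.Series(labels).reindex(expr.columns)
    modules = sorted(int(m) for m in labels.unique() if m != 0)
    me = {}
    for m in modules:
        genes = labels.index[labels == m]
        if len(genes) < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        sub = expr[genes].to_numpy(dtype=float)
        sd = sub.std(axis=0, ddof=1)
        if (sd == 0).any():
            warnings.warn(f"module {m}: constant gene(s) excluded from eigengene")
            sub = sub[:, sd > 0]
            sd = sd[sd > 0]
        zs = (sub - sub.mean(axis=0)) / sd
        u, s, _ = np.linalg.svd(zs, full_matrices=False)
        ev = u[:, 0]
        mean_profile = zs.mean(axis=1)
        if mean_profile @ ev < 0:
            ev = -ev
        me[f"ME{m}"] = ev
    eigengenes = pd.DataFrame(me, index=expr.index)
    kme = pd.DataFrame(index=expr.columns, columns=eigengenes.columns,
                       dtype=float)
    for col in eigengenes.columns:
        v = eigengenes[col].to_numpy()
        for g in expr.columns:
            x = expr[g].to_numpy(dtype=float)
            kme.loc[g, col] = (
                0.0 if np.std(x) == 0 else float(stats.pearsonr(x, v)[0]))
    return eigengenes, kme


def module_trait_correlation(eigengenes, trait) -> pd.DataFrame:
    """Pearson r and two-sided t-based p per module eigengene vs a trait."""
    eigengenes = pd.DataFrame(eigengenes)
    y = np.asarray(trait, dtype=float)
    if np.std(y) == 0:
        raise ValueError("constant trait")
    rows = []
    for col in eigengenes.columns:
        r, p = stats.pearsonr(eigengenes[col].to_numpy(), y)
        rows.append({"module": col, "r": r, "p": p})
    return pd.DataFrame(rows).set_index("module")


@dataclass
class HubResult:
    """Hub genes and the per-gene statistics they were filtered from."""

    hub_genes: list
    table: pd.DataFrame   # per gene: module, kME, trait_r, trait_p, trait_q, is_hub
    kme_min: float
    trait_min: float
    fdr_max: float


def select_hub_genes(expr, labels, trait, kme=None, kme_min: float = 0.8,
                     trait_min: float = 0.85, fdr_max: float = 0.01) -> HubResult:
    """Conjunctive hub-gene filter.

    A gene is a hub iff (i) its correlation with its own module eigengene
    exceeds ``kme_min``, (ii) its |trait correlation| exceeds ``trait_min``,
    and (iii) the BH-FDR q of that trait correlation (across all assigned
    genes) is below ``fdr_max``.
    """
    expr = pd.DataFrame(expr)
    labels = pd.Series(labels).reindex(expr.columns)
    if kme is None:
        _, kme = module_eigengenes(expr, labels)
    y = np.asarray(trait, dtype=float)
    rows = []
    for g in expr.columns:
        m = int(labels[g])
        x = expr[g].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(x, y)
        own_kme = kme.loc[g, f"ME{m}"] if m != 0 and f"ME{m}" in kme.columns else np.nan
        rows.append({"gene": g, "module": m, "kME": own_kme,
                     "trait_r": r, "trait_p": p})
    table = pd.DataFrame(rows).set_index("gene")
    assigned = table["module"] != 0
    table["trait_q"] = np.nan
    if assigned.any():
        table.loc[assigned, "trait_q"] = bh_fdr(
            table.loc[assigned, "trait_p"].to_numpy())
    table["is_hub"] = (
        assigned
        & (table["kME"] > kme_min)
        & (table["trait_r"].abs() > trait_min)
        & (table["trait_q"] < fdr_max)
    )
    hubs = list(table.index[table["is_hub"]])
    return HubResult(hubs, table, kme_min, trait_min, fdr_max)


def export_network_edges(matrix, weight_min: float = 0.4) -> pd.DataFrame:
    """Undirected edge list (i < j) with weight strictly above ``weight_min``."""
    df = pd.DataFrame(matrix)
    a = df.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    ids = list(df.index)
    rows = []
    iu, ju = np.triu_indices(len(ids), 1)
    for i, j in zip(iu, ju):
        if a[i, j] > weight_min:
            rows.append({"gene_a": ids[i], "gene_b": ids[j],
                         "weight": a[i, j]})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])


# -------------------------------------------------------------- model shell

class CoexpressionNetwork:
    """Co-expression network model over a samples x genes expression matrix.

    ``beta="auto"`` selects the soft-threshold power by the scale-free
    criterion at fit time.
    """

    def __init__(self, expr, beta="auto", signed: bool = True):
        self.expr = pd.DataFrame(expr)
        self.beta = beta
        self.signed = signed

    def fit(self, cut_height: float = 0.25, min_module_size: int = 30,
            powers=None) -> "CoexpressionResults":
        if self.beta == "auto":
            kwargs = {} if powers is None else {"powers": powers}
            beta, sft = pick_soft_threshold(self.expr, signed=self.signed,
                                            **kwargs)
        else:
            beta, sft = float(self.beta), None
        adj = signed_adjacency(self.expr, beta=beta, signed=self.signed)
        tom = tom_similarity(adj)
        labels, link = detect_modules(tom, min_module_size=min_module_size,
                                      cut_height=cut_height)
        expr_used = self.expr[adj.columns]
        if (labels != 0).any():
            eigengenes, kme = module_eigengenes(expr_used, labels)
        else:
            eigengenes = pd.DataFrame(index=expr_used.index)
            kme = pd.DataFrame(index=expr_used.columns)
        return CoexpressionResults(
            model=self, beta=beta, sft_table=sft, adjacency=adj, tom=tom,
            labels=labels, linkage_matrix=link, eigengenes=eigengenes,
            kme=kme, cut_height=cut_height, min_module_size=min_module_size,
        )


@dataclass
class CoexpressionResults:
    model: CoexpressionNetwork
    beta: float
    sft_table: pd.DataFrame | None
    adjacency: pd.DataFrame = field(repr=False, default=None)
    tom: pd.DataFrame = field(repr=False, default=None)
    labels: pd.Series = None
    linkage_matrix: np.ndarray = field(repr=False, default=None)
    eigengenes: pd.DataFrame = None
    kme: pd.DataFrame = field(repr=False, default=None)
    cut_height: float = 0.25
    min_module_size: int = 30

    def module_trait_correlation(self, trait) -> pd.DataFrame:
        return module_trait_correlation(self.eigengenes, trait)

    def select_hub_genes(self, trait, **kw) -> HubResult:
        expr_used = self.model.expr[self.labels.index]
        return select_hub_genes(expr_used, self.labels, trait, kme=self.kme, **kw)

    def export_edges(self, weight_min: float = 0.4, use: str = "tom") -> pd.DataFrame:
        mat = self.tom if use == "tom" else self.adjacency
        return export_network_edges(mat, weight_min=weight_min)

    def summary(self) -> str:
        sizes = self.labels[self.labels != 0].value_counts().sort_index()
        lines = [
            "Co-expression network results",
            f"  genes:        {len(self.labels)}",
            f"  beta:         {self.beta}",
            f"  modules:      {len(sizes)}"
            f" (sizes {dict(sizes)})" if len(sizes) else "  modules:      0",
            f"  unassigned:   {int((self.labels == 0).sum())}",
        ]
        return "\n".join(lines)
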