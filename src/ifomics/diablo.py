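"""Multi-block sparse discriminant integration (DIABLO-style sGCCA).

Finds, per component, one latent variate per omics block such that the
design-weighted sum of covariances between block variates (and the
indicator-coded response) is maximal, with exactly ``keepX`` features
carrying nonzero weight in each block.  Sparsity is enforced by hard
cardinality (the keepX largest-|value| weight entries are retained each
update), which reproduces the keepX semantics of the reference method
exactly.  Fits are deterministic: initialization is each block's dominant
singular vector and no randomness enters the inner iterations.

`DIABLO` follows the statsmodels model/results pattern; the module-level
functions mirror it for pipeline use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .plsda import _indicator, _scale_train, _stratified_folds

__all__ = [
    "DIABLO",
    "DIABLOResults",
    "diablo_fit",
    "diablo_predict",
    "tune_keepx",
    "component_correlations",
    "circos_links",
    "cim_order",
    "full_design",
]


def full_design(block_names: Sequence[str], weight: float = 1.0) -> pd.DataFrame:
    """Full design matrix: every block pair connected at ``weight``."""
    k = len(block_names)
    d = np.full((k, k), float(weight))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=block_names, columns=block_names)


def _check_design(design: pd.DataFrame, names):
    d = design.loc[names, names].to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("design matrix must be symmetric")
    if (d < 0).any() or (d > 1).any():
        raise ValueError("design weights must lie in [0, 1]")
    if np.diag(d).any():
        raise ValueError("design diagonal must be zero")
    return d


def _hard_threshold(w: np.ndarray, keep: int) -> np.ndarray:
    """Zero all but the ``keep`` largest-|value| entries (ties: smaller
    index wins) and renormalize to unit norm."""
    if keep < w.size:
        order = np.lexsort((np.arange(w.size), -np.abs(w)))
        out = np.zeros_like(w)
        out[order[:keep]] = w[order[:keep]]
        w = out
    nrm = np.linalg.norm(w)
    return w / nrm if nrm > 0 else w


class DIABLO:
    """Multi-block sparse PLS discriminant model.

    Parameters
    ----------
    blocks : mapping of block name -> samples x features matrix
        Feature matrices on a common sample order (autoscaled internally).
    y : class labels.
    design : block x block DataFrame in [0, 1], zero diagonal; defaults to
        the full design (all off-diagonal weights 1).  The response block
        is implicitly connected to every X block with weight 1.
    """

    def __init__(self, blocks: Mapping[str, pd.DataFrame], y,
                 design: pd.DataFrame | None = None, scale: bool = True):
        if not blocks:
            raise ValueError("no blocks supplied")
        self.block_names = list(blocks)
        self.feature_ids = {}
        self.X = {}
        n_ref = None
        for name, mat in blocks.items():
            self.feature_ids[name] = (
                list(mat.columns) if isinstance(mat, pd.DataFrame)
                else [f"{name}_{i + 1}" for i in range(np.asarray(mat).shape[1])]
            )
            arr = np.asarray(mat, dtype=float)
            if arr.ndim != 2 or arr.shape[1] == 0:
                raise ValueError(f"block {name!r} is empty or not 2-D")
            if n_ref is None:
                n_ref = arr.shape[0]
            elif arr.shape[0] != n_ref:
                raise ValueError("blocks disagree on the number of samples")
            self.X[name] = arr
        self.y = np.asarray(y)
        if self.y.size != n_ref:
            raise ValueError("labels do not match the sample count")
        self.classes_ = np.unique(self.y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        self.design = (full_design(self.block_names) if design is None else design)
        self._design_arr = _check_design(self.design, self.block_names)
        self.scale = scale

    def fit(self, keepx: Mapping[str, int] | Sequence[int] | int | None = None,
            n_components: int = 1, tol: float = 1e-9,
            max_iter: int = 500) -> "DIABLOResults":
        names = self.block_names
        if keepx is None:
            keepx = {b: len(self.feature_ids[b]) for b in names}
        elif isinstance(keepx, int):
            keepx = {b: keepx for b in names}
        elif not isinstance(keepx, Mapping):
            keepx = dict(zip(names, keepx))
        for b in names:
            if not 1 <= keepx[b] <= len(self.feature_ids[b]):
                raise ValueError(f"keepX for block {b!r} out of range")

        n = self.y.size
        Xs, mus, sds = {}, {}, {}
        for b in names:
            if self.scale:
                Xs[b], mus[b], sds[b] = _scale_train(self.X[b])
            else:
                mus[b] = self.X[b].mean(axis=0)
                sds[b] = np.ones(self.X[b].shape[1])
                Xs[b] = self.X[b] - mus[b]
        Y = _indicator(self.y, self.classes_)
        ymean = Y.mean(axis=0)
        Y0 = Y - ymean
        C = self._design_arr

        weights = {b: np.zeros((self.X[b].shape[1], n_components)) for b in names}
        scores = {b: np.zeros((n, n_components)) for b in names}
        loadings = {b: np.zeros((self.X[b].shape[1], n_components)) for b in names}
        y_scores = np.zeros((n, n_components))
        objectives, iters, converged = [], [], []

        Xd = {b: Xs[b].copy() for b in names}
        for comp in range(n_components):
            w = {}
            t = {}
            for b in names:
                # dominant right singular vector, deterministic sign
                _, _, vt = np.linalg.svd(Xd[b], full_matrices=False)
                v = vt[0]
                k = int(np.argmax(np.abs(v)))
                w[b] = v if v[k] >= 0 else -v
                t[b] = Xd[b] @ w[b]
            wy = np.linalg.svd(Y0, full_matrices=False)[2][0]
            ty = Y0 @ wy

            obj_trace = []
            n_it = 0
            conv = False
            for n_it in range(1, max_iter + 1):
                delta = 0.0
                for i, b in enumerate(names):
                    target = sum(C[i, j] * t[nb] for j, nb in enumerate(names)
                                 if j != i)
                    target = target + ty  # response weight fixed at 1
                    wn = _hard_threshold(Xd[b].T @ target / n, keepx[b])
                    delta = max(delta, np.max(np.abs(wn - w[b])))
                    w[b] = wn
                    t[b] = Xd[b] @ wn
                wy_new = Y0.T @ sum(t[b] for b in names)
                nrm = np.linalg.norm(wy_new)
                if nrm > 0:
                    wy_new /= nrm
                delta = max(delta, np.max(np.abs(wy_new - wy)))
                wy = wy_new
                ty = Y0 @ wy
                obj = sum(
                    C[i, j] * (t[names[i]] @ t[names[j]]) / n
                    for i in range(len(names)) for j in range(i + 1, len(names))
                ) + sum((t[b] @ ty) / n for b in names)
                if obj_trace and obj < obj_trace[-1] - 1e-9 * max(1.0, abs(obj)):
                    raise AssertionError(
                        "sGCCA objective decreased between iterations"
                    )
                obj_trace.append(float(obj))
                if delta < tol:
                    conv = True
                    break
            if not conv:
                warnings.warn(
                    f"component {comp + 1}: not converged after {max_iter} "
                    f"iterations (last weight change {delta:.2e})"
                )
            # deterministic sign per component
            for b in names:
                k = int(np.argmax(np.abs(w[b])))
                if w[b][k] < 0:
                    w[b] = -w[b]
                    t[b] = -t[b]
                weights[b][:, comp] = w[b]
                scores[b][:, comp] = t[b]
                tt = t[b] @ t[b]
                p = Xd[b].T @ t[b] / tt if tt > 0 else np.zeros(Xd[b].shape[1])
                loadings[b][:, comp] = p
                Xd[b] = Xd[b] - np.outer(t[b], p)
            y_scores[:, comp] = ty
            objectives.append(obj_trace)
            iters.append(n_it)
            converged.append(conv)

        selected = {
            b: [self.feature_ids[b][i]
                for i in np.flatnonzero((weights[b] != 0).any(axis=1))]
            for b in names
        }
        # per-block regression of the response on that block's scores
        y_coefs = {}
        for b in names:
            T = scores[b]
            y_coefs[b], *_ = np.linalg.lstsq(T, Y0, rcond=None)
        return DIABLOResults(
            model=self, keepx=dict(keepx), n_components=n_components,
            weights=weights, scores=scores, loadings=loadings,
            y_scores=y_scores, y_coefs=y_coefs, x_mean=mus, x_std=sds,
            y_mean=ymean, x_scaled={b: Xs[b] for b in names},
            selected=selected, objective_traces=objectives,
            n_iterations=iters, converged=converged,
        )


@dataclass
class DIABLOResults:
    """Fitted multi-block sparse discriminant model."""

    model: DIABLO
    keepx: dict
    n_components: int
    weights: dict        # block -> features x A sparse unit-norm weights
    scores: dict         # block -> samples x A variates
    loadings: dict
    y_scores: np.ndarray
    y_coefs: dict        # block -> A x classes regression coefficients
    x_mean: dict
    x_std: dict
    y_mean: np.ndarray
    x_scaled: dict = field(repr=False, default=None)
    selected: dict = None
    objective_traces: list = field(repr=False, default=None)
    n_iterations: list = None
    converged: list = None

    @property
    def block_names(self):
        return self.model.block_names

    @property
    def classes_(self):
        return self.model.classes_

    # ---------------------------------------------------------- prediction
    def _block_scores(self, name: str, X_new: np.ndarray) -> np.ndarray:
        W, P = self.weights[name], self.loadings[name]
        R = W @ np.linalg.inv(P.T @ W)
        Xs = (np.asarray(X_new, dtype=float) - self.x_mean[name]) / self.x_std[name]
        return Xs @ R

    def predict(self, new_blocks: Mapping[str, np.ndarray]):
        """Majority vote across per-block predictions.

        Ties are broken by the average predicted indicator across blocks.
        Returns (assignments, per-block assignment DataFrame).
        """
        missing = [b for b in self.block_names if b not in new_blocks]
        if missing:
            raise ValueError(f"missing block(s): {missing}")
        yhats, votes = {}, {}
        for b in self.block_names:
            T = self._block_scores(b, new_blocks[b])
            yhats[b] = T @ self.y_coefs[b] + self.y_mean
            votes[b] = np.argmax(yhats[b], axis=1)
        vote_mat = np.stack([votes[b] for b in self.block_names], axis=1)
        n = vote_mat.shape[0]
        n_cls = self.classes_.size
        counts = np.stack([(vote_mat == c).sum(axis=1) for c in range(n_cls)], axis=1)
        avg_yhat = np.mean([yhats[b] for b in self.block_names], axis=0)
        winners = np.empty(n, dtype=np.int64)
        for i in range(n):
            top = counts[i].max()
            tied = np.flatnonzero(counts[i] == top)
            winners[i] = tied[0] if tied.size == 1 else tied[
                int(np.argmax(avg_yhat[i, tied]))]
        per_block = pd.DataFrame(
            {b: self.classes_[votes[b]] for b in self.block_names})
        return self.classes_[winners], per_block

    # ----------------------------------------------------------- summaries
    def component_correlations(self, component: int = 0) -> pd.DataFrame:
        """Pearson correlation between blocks' scores on one component."""
        names = self.block_names
        mat = np.column_stack([self.scores[b][:, component] for b in names])
        r = np.corrcoef(mat, rowvar=False)
        r = np.atleast_2d(r)
        np.fill_diagonal(r, 1.0)
        return pd.DataFrame(r, index=names, columns=names)

    def circos_links(self, r_threshold: float = 0.7) -> pd.DataFrame:
        """Cross-block Pearson correlations between selected features.

        Computed on the autoscaled training data; edges with
        |r| >= threshold are returned with their sign.
        """
        if not 0 < r_threshold <= 1:
            raise ValueError("r_threshold must be in (0, 1]")
        names = self.block_names
        cols, meta = [], []
        for b in names:
            ids = self.feature_index(b)
            for fid, col in zip(self.selected[b], ids):
                cols.append(self.x_scaled[b][:, col])
                meta.append((b, fid))
        rows = []
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if meta[i][0] == meta[j][0]:
                    continue  # no intra-block edges
                xi, xj = cols[i], cols[j]
                denom = np.linalg.norm(xi) * np.linalg.norm(xj)
                r = float(xi @ xj / denom) if denom > 0 else 0.0
                if abs(r) >= r_threshold:
                    rows.append({
                        "block_a": meta[i][0], "feature_a": meta[i][1],
                        "block_b": meta[j][0], "feature_b": meta[j][1],
                        "r": r, "sign": "positive" if r >= 0 else "negative",
                    })
        return pd.DataFrame(
            rows, columns=["block_a", "feature_a", "block_b", "feature_b",
                           "r", "sign"])

    def feature_index(self, name: str) -> list:
        lookup = {f: i for i, f in enumerate(self.model.feature_ids[name])}
        return [lookup[f] for f in self.selected[name]]

    def selected_matrix(self) -> pd.DataFrame:
        """Samples x selected-features matrix (autoscaled), all blocks."""
        pieces = []
        for b in self.block_names:
            idx = self.feature_index(b)
            pieces.append(pd.DataFrame(
                self.x_scaled[b][:, idx],
                columns=[f"{b}:{f}" for f in self.selected[b]]))
        return pd.concat(pieces, axis=1)

    def cim_order(self):
        """Clustered-image-map orderings (rows = samples, cols = features)."""
        return cim_order(self.selected_matrix())

    def summary(self) -> str:
        lines = [
            "DIABLO (multi-block sparse PLS-DA) results",
            f"  blocks:      {self.block_names}",
            f"  components:  {self.n_components}",
            f"  keepX:       {self.keepx}",
            f"  converged:   {self.converged} (iterations {self.n_iterations})",
        ]
        cc = self.component_correlations()
        for i, a in enumerate(self.block_names):
            for b in self.block_names[i + 1:]:
                lines.append(f"  corr(t_{a}, t_{b}) = {cc.loc[a, b]:.3f}")
        for b in self.block_names:
            lines.append(f"  selected[{b}]: {self.selected[b]}")
        return "\n".join(lines)


# ------------------------------------------------------------- module-level

def diablo_fit(blocks, labels, design=None, keepx=None,
               n_components: int = 1, **kw) -> DIABLOResults:
    return DIABLO(blocks, labels, design=design).fit(
        keepx=keepx, n_components=n_components, **kw)


def diablo_predict(result: DIABLOResults, new_blocks):
    return result.predict(new_blocks)


def component_correlations(result: DIABLOResults, component: int = 0) -> pd.DataFrame:
    return result.component_correlations(component)


def circos_links(result: DIABLOResults, r_threshold: float = 0.7) -> pd.DataFrame:
    return result.circos_links(r_threshold)


def tune_keepx(blocks, labels, design=None, grid=None, folds: int = 10,
               seed: int = 0, n_components: int = 1) -> dict:
    """Select keepX per block by cross-validated misclassification.

    Coordinate-wise search over blocks in input order: each block's grid is
    scanned with the other blocks held at their current value; ties take
    the smallest keepX.  Default tenfold CV.
    """
    names = list(blocks)
    if grid is None or (hasattr(grid, "__len__") and len(grid) == 0):
        raise ValueError("empty keepX grid")
    if not isinstance(grid, Mapping):
        grid = {b: list(grid) for b in names}
    for b in names:
        if len(grid[b]) == 0:
            raise ValueError(f"empty grid for block {b!r}")
    y = np.asarray(labels)
    classes, y_codes = np.unique(y, return_inverse=True)
    rng = np.random.default_rng(seed)
    fold_ids = _stratified_folds(y_codes, folds, rng)

    def cv_error(keepx: dict) -> float:
        errs = 0
        total = 0
        for k in range(folds):
            te = fold_ids == k
            tr = ~te
            if not te.any() or np.unique(y_codes[tr]).size < classes.size:
                continue
            tr_blocks = {b: np.asarray(blocks[b], dtype=float)[tr] for b in names}
            te_blocks = {b: np.asarray(blocks[b], dtype=float)[te] for b in names}
            res = DIABLO(tr_blocks, y[tr], design=design).fit(
                keepx=keepx, n_components=n_components)
            pred, _ = res.predict(te_blocks)
            errs += int((pred != y[te]).sum())
            total += int(te.sum())
        return errs / total if total else 1.0

    current = {b: int(grid[b][0]) for b in names}
    for b in names:
        best_err, best_k = None, current[b]
        for cand in sorted(set(int(g) for g in grid[b])):
            trial = dict(current)
            trial[b] = cand
            err = cv_error(trial)
            if best_err is None or err < best_err - 1e-12:
                best_err, best_k = err, cand
        current[b] = best_k
    return current


def cim_order(selected_matrix):
    """Hierarchical clustering orders for a clustered image map.

    Euclidean distance, complete linkage, on both rows (samples) and
    columns (features).  Leaf order is scipy's deterministic order; ties in
    merge distances resolve toward smaller indices via the stable distance
    computation.  Returns (row_order, col_order, row_linkage, col_linkage).
    """
    df = pd.DataFrame(selected_matrix)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    row_link = linkage(pdist(df.to_numpy(), metric="euclidean"),
                       method="complete")
    col_link = linkage(pdist(df.to_numpy().T, metric="euclidean"),
                       method="complete")
    row_order = [df.index[i] for i in leaves_list(row_link)]
    col_order = [df.columns[i] for i in leaves_list(col_link)]
    return row_order, col_order, row_link, col_link
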