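"""Normalization, transformation, filtering and scalar phenotype formulas.

Shared by every downstream stage: cumulative sum scaling (CSS) and
rarefaction for count tables, the centered log-ratio (CLR) transform for
compositional data, feature-wise autoscaling for continuous blocks, the
expression-level filter for FPKM matrices, Benjamini–Hochberg FDR control,
and the HOMA-IR / 2^-ddCT scalar formulas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountTable",
    "NormalizedMatrix",
    "css_normalize",
    "rarefy",
    "clr_transform",
    "autoscale",
    "filter_by_expression",
    "bh_fdr",
    "homa_ir",
    "ddct_ratio",
]


@dataclass
class CountTable:
    """Integer taxa-by-samples abundance table.

    The compositional object consumed by CSS normalization, rarefaction,
    the CLR transform and ANCOM.  ``counts[i, j]`` is the abundance of
    taxon ``taxa_ids[i]`` in sample ``sample_ids[j]``.
    """

    taxa_ids: list
    sample_ids: list
    counts: np.ndarray

    def __post_init__(self):
        self.taxa_ids = list(self.taxa_ids)
        self.sample_ids = list(self.sample_ids)
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D taxa x samples matrix")
        if counts.shape != (len(self.taxa_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxa_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.taxa_ids)) != len(self.taxa_ids):
            raise ValueError("duplicate taxa ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.counts = counts

    @property
    def library_size(self) -> np.ndarray:
        """Per-sample total counts (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def relative_abundance(self) -> np.ndarray:
        """Taxa x samples matrix of per-sample proportions (columns sum to 1)."""
        lib = self.library_size.astype(float)
        if (lib == 0).any():
            raise ValueError("sample(s) with zero library size")
        return self.counts / lib

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())


@dataclass
class NormalizedMatrix:
    """A transformed matrix together with the transform's provenance.

    ``values`` keeps the orientation of the input: taxa x samples for the
    count transforms (css, clr, relative), samples x features for
    ``autoscale``.  ``params`` records the knobs used; ``scaling_factors``
    carries the per-sample CSS scaling factor s_j, or the per-feature
    (mean, sd) pairs for autoscaling.
    """

    values: pd.DataFrame
    method: str
    params: dict = field(default_factory=dict)
    scaling_factors: pd.Series | pd.DataFrame | None = None

    def apply_to(self, new: pd.DataFrame) -> pd.DataFrame:
        """Apply stored autoscaling parameters to held-out samples."""
        if self.method != "autoscale":
            raise ValueError("apply_to is only defined for autoscaled matrices")
        mu = self.scaling_factors["mean"]
        sd = self.scaling_factors["sd"]
        cols = self.values.columns
        return (new[cols] - mu[cols]) / sd[cols]


def css_normalize(table: CountTable, quantile: float = 0.5,
                  scale: float = 1000.0) -> NormalizedMatrix:
    """Cumulative sum scaling.

    For each sample j, the scaling factor s_j is the sum of that sample's
    counts not exceeding the ``quantile`` of its positive counts; values are
    ``x_ij / s_j * scale``.  Robust to a handful of dominant taxa inflating
    the library size.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    if scale <= 0:
        raise ValueError("scale must be positive")
    lib = table.library_size
    if (lib <= 0).any():
        bad = [s for s, l in zip(table.sample_ids, lib) if l <= 0]
        raise ValueError(f"samples with zero library size: {bad}")
    counts = table.counts.astype(float)
    s = np.empty(table.n_samples)
    for j in range(table.n_samples):
        col = counts[:, j]
        positive = col[col > 0]
        q = np.quantile(positive, quantile)
        s[j] = col[col <= q].sum()
        if s[j] == 0:
            raise ValueError(
                f"CSS scaling factor is zero for sample {table.sample_ids[j]!r}"
            )
    values = counts / s * scale
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=table.taxa_ids, columns=table.sample_ids),
        method="css",
        params={"quantile": quantile, "scale": scale},
        scaling_factors=pd.Series(s, index=table.sample_ids, name="css_factor"),
    )


def rarefy(table: CountTable, depth: int, seed: int = 0) -> CountTable:
    """Subsample each sample without replacement to exactly ``depth`` counts.

    Samples whose library size is below ``depth`` are dropped with a warning
    (an all-dropped table is an error).  Sampling is multivariate
    hypergeometric, deterministic per seed.
    """
    depth = int(depth)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    lib = table.library_size
    keep = lib >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if not keep.any():
        raise ValueError(f"rarefaction depth {depth} exceeds every library size")
    if dropped:
        warnings.warn(
            f"rarefy: dropping {len(dropped)} sample(s) below depth {depth}: {dropped}"
        )
    out = np.zeros((table.n_taxa, int(keep.sum())), dtype=np.int64)
    kept_ids = []
    col = 0
    for j, k in enumerate(keep):
        if not k:
            continue
        if lib[j] == depth:
            out[:, col] = table.counts[:, j]
        else:
            out[:, col] = rng.multivariate_hypergeometric(table.counts[:, j], depth)
        kept_ids.append(table.sample_ids[j])
        col += 1
    return CountTable(table.taxa_ids, kept_ids, out)


def clr_transform(table: CountTable, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Centered log-ratio transform, per sample.

    y_i = log(x_i + pc) - mean_k log(x_k + pc).  Identical on counts and on
    relative abundances up to the pseudocount distortion, since the
    per-sample centering removes the library-size constant.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logged = np.log(table.counts + pseudocount)
    values = logged - logged.mean(axis=0, keepdims=True)
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=table.taxa_ids, columns=table.sample_ids),
        method="clr",
        params={"pseudocount": pseudocount},
    )


def autoscale(matrix, ddof: int = 1,
              on_zero_variance: str = "drop") -> NormalizedMatrix:
    """Feature-wise centering and unit-variance scaling (samples x features).

    The sd denominator uses ``ddof=1`` (sample standard deviation), so a
    three-sample column [1, 2, 3] maps to [-1, 0, 1].  Parameters are stored
    for application to held-out samples via :meth:`NormalizedMatrix.apply_to`.
    Zero-variance features are dropped with a warning by default
    (``on_zero_variance="error"`` raises instead).
    """
    df = pd.DataFrame(matrix)
    if df.shape[0] < 2:
        raise ValueError("autoscale requires at least 2 samples")
    mu = df.mean(axis=0)
    sd = df.std(axis=0, ddof=ddof)
    zero = sd <= 0
    if zero.any():
        bad = list(df.columns[zero])
        if on_zero_variance == "error":
            raise ValueError(f"zero-variance feature(s): {bad}")
        warnings.warn(f"autoscale: dropping zero-variance feature(s): {bad}")
        df = df.loc[:, ~zero]
        mu = mu[~zero]
        sd = sd[~zero]
    values = (df - mu) / sd
    return NormalizedMatrix(
        values=values,
        method="autoscale",
        params={"ddof": ddof},
        scaling_factors=pd.DataFrame({"mean": mu, "sd": sd}),
    )


def filter_by_expression(fpkm_matrix, threshold: float = 1.0,
                         min_samples: int = 10):
    """Keep features expressed above ``threshold`` (strictly) in at least
    ``min_samples`` samples.

    ``fpkm_matrix`` is features x samples (TSV dialect orientation).
    Returns (filtered DataFrame, kept feature ids).
    """
    df = pd.DataFrame(fpkm_matrix)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if min_samples > df.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    keep = (df > threshold).sum(axis=1) >= min_samples
    filtered = df.loc[keep]
    return filtered, list(filtered.index)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def homa_ir(fasting_insulin, fasting_glucose):
    """Homeostasis-model insulin-resistance index.

    (insulin [mU/L] x glucose [mg/dL] x 0.05551) / 22.5; the 0.05551 factor
    converts glucose from mg/dL to mmol/L.
    """
    ins = np.asarray(fasting_insulin, dtype=float)
    glu = np.asarray(fasting_glucose, dtype=float)
    if (ins < 0).any() or (glu < 0).any():
        raise ValueError("insulin and glucose must be non-negative")
    out = ins * glu * 0.05551 / 22.5
    return out.item() if out.ndim == 0 else out


def ddct_ratio(ct_target_treated, ct_ref_treated,
               ct_target_control, ct_ref_control):
    """Relative expression fold change by the 2^-ddCT method."""
    args = [np.asarray(a, dtype=float) for a in
            (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)]
    if any(not np.isfinite(a).all() for a in args):
        raise ValueError("CT values must be finite")
    ddct = (args[0] - args[1]) - (args[2] - args[3])
    out = 2.0 ** (-ddct)
    return out.item() if out.ndim == 0 else out
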