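"""Synthetic multi-omics study generator.

Emulates the statistical structure the analysis assumes: two treatment
groups of mice (control vs intermittent fasting), a shared latent factor
that induces cross-block correlation between a small gene signature, a
metabolite panel and a compositional microbial count table, a nuisance
timepoint covariate, and metabolic phenotypes (glucose, insulin,
bodyweight).  Every downstream stage is testable on this generator without
any external download.

The latent model: per sample i with group g(i),

    u_i = mu_{g(i)} + eps_i,            eps_i ~ N(0, 1)

continuous blocks are ``baseline + loading * u_i + N(0, noise_sd)`` on the
informative features (metabolites exponentiated to stay positive); taxon
log-abundances are ``baseline + gamma * u_i + noise`` pushed through a
softmax and drawn multinomially with log-normal library sizes, so counts
are compositional with realistic sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import CountTable

__all__ = [
    "SynthConfig",
    "MultiOmicsStudy",
    "generate_study",
    "generate_otu_counts",
    "generate_continuous_block",
]

GROUP_LABELS = ("control", "IF")


@dataclass
class SynthConfig:
    """Knobs of the generative model.

    Defaults mirror the study design the toolkit targets: groups of 10 and
    11 mice, a 36-gene hub signature with 10 informative genes, 26
    metabolites (23 plasma + 3 SCFA-like) with 10 informative, and 50 taxa
    of which 17 respond to treatment.  ``group_effect`` is the latent mean
    shift mu_1 - mu_0 in latent-SD units; the default 4.0 emulates the
    strongly separable treatment groups of the target study design (the
    Bayes accuracy of the latent classes is ~98%).  ``loading`` scales how
    strongly informative features follow the latent factor.
    """

    n_per_group: Sequence[int] = (10, 11)
    group_effect: float = 4.0
    n_genes: int = 36
    n_informative_genes: int = 10
    n_metabolites: int = 26
    n_informative_metabolites: int = 10
    n_taxa: int = 50
    n_informative_taxa: int = 17
    loading: float = 2.0
    noise_sd: float = 1.0
    library_size_mean: float = 35000.0
    library_size_sigma: float = 0.1
    time_levels: int = 2
    time_shift: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if len(self.n_per_group) != 2 or any(n < 1 for n in self.n_per_group):
            raise ValueError("n_per_group must be two positive counts")
        for name, n, k in [
            ("genes", self.n_genes, self.n_informative_genes),
            ("metabolites", self.n_metabolites, self.n_informative_metabolites),
            ("taxa", self.n_taxa, self.n_informative_taxa),
        ]:
            if n < 1:
                raise ValueError(f"n_{name} must be >= 1")
            if not 0 <= k <= n:
                raise ValueError(f"n_informative_{name} must be in [0, n_{name}]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.library_size_mean <= 0 or self.library_size_sigma < 0:
            raise ValueError("invalid library-size model")
        if self.time_levels < 1:
            raise ValueError("time_levels must be >= 1")


@dataclass
class MultiOmicsStudy:
    """Aligned sample set with three feature blocks, metadata and phenotypes.

    All blocks share identical sample ordering.  ``truth`` stores the
    planted informative-feature indices and latent factor values; it exists
    for recovery tests only and must never be read by analysis stages.
    """

    sample_ids: list
    metadata: pd.DataFrame            # group, genotype, timepoint
    gene_block: pd.DataFrame          # samples x genes (continuous)
    metabolite_block: pd.DataFrame    # samples x metabolites (positive)
    otu_block: CountTable             # taxa x samples (integer counts)
    phenotypes: pd.DataFrame          # glucose (mg/dL), insulin (mU/L), bodyweight (g)
    truth: dict = field(repr=False, default_factory=dict)

    def __post_init__(self):
        ids = list(self.sample_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        for name, idx in [
            ("metadata", list(self.metadata.index)),
            ("gene_block", list(self.gene_block.index)),
            ("metabolite_block", list(self.metabolite_block.index)),
            ("otu_block", self.otu_block.sample_ids),
            ("phenotypes", list(self.phenotypes.index)),
        ]:
            if idx != ids:
                raise ValueError(f"{name} sample ordering differs from sample_ids")

    @property
    def group(self) -> pd.Series:
        return self.metadata["group"]


def generate_continuous_block(latent, n_features, informative_idx, loading,
                              noise_sd, positive: bool = False, seed: int = 0,
                              baseline=None, feature_prefix: str = "f"):
    """Samples x features matrix driven by the latent factor.

    Informative columns are ``baseline + loading * u + N(0, noise_sd)``;
    the rest are baseline plus noise.  With ``positive=True`` the values are
    exponentiated (log-normal-like intensities).
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    u = np.asarray(latent, dtype=float)
    informative_idx = np.asarray(informative_idx, dtype=int)
    if informative_idx.size and (
        informative_idx.min() < 0 or informative_idx.max() >= n_features
    ):
        raise ValueError("informative_idx out of range")
    rng = np.random.default_rng(seed)
    if baseline is None:
        baseline = rng.normal(0.0, 1.0, size=n_features)
    baseline = np.asarray(baseline, dtype=float)
    loadings = np.zeros(n_features)
    loadings[informative_idx] = loading
    X = baseline + np.outer(u, loadings) + rng.normal(0.0, noise_sd, (u.size, n_features))
    if positive:
        X = np.exp(X)
    cols = [f"{feature_prefix}{i + 1}" for i in range(n_features)]
    return pd.DataFrame(X, columns=cols)


def generate_otu_counts(latent, baselines, loadings, library_size_mean=35000.0,
                        library_size_sigma=0.1, noise_sd=1.0, seed: int = 0,
                        taxa_ids=None, sample_ids=None,
                        extra_log_shift=None) -> CountTable:
    """Compositional counts from a logistic-normal / multinomial model.

    Per sample: log-abundances = baseline + gamma * u + N(0, noise_sd),
    softmaxed to a composition and drawn multinomially with a log-normal
    library size whose expectation is ``library_size_mean``.  Column sums
    equal the drawn library sizes.
    """
    u = np.asarray(latent, dtype=float)
    baselines = np.asarray(baselines, dtype=float)
    loadings = np.asarray(loadings, dtype=float)
    m = baselines.size
    if m < 2:
        raise ValueError("need at least 2 taxa")
    if not np.isfinite(baselines).all():
        raise ValueError("baselines must be finite")
    if loadings.shape != baselines.shape:
        raise ValueError("loadings must match baselines in length")
    rng = np.random.default_rng(seed)
    n = u.size
    log_abund = baselines + np.outer(u, loadings)
    if noise_sd > 0:
        log_abund = log_abund + rng.normal(0.0, noise_sd, (n, m))
    if extra_log_shift is not None:
        log_abund = log_abund + np.asarray(extra_log_shift, dtype=float)
    log_abund -= log_abund.max(axis=1, keepdims=True)
    comp = np.exp(log_abund)
    comp /= comp.sum(axis=1, keepdims=True)
    # log-normal with mean library_size_mean: mu = log(mean) - sigma^2/2
    mu = np.log(library_size_mean) - library_size_sigma ** 2 / 2.0
    libs = np.maximum(
        1, np.round(rng.lognormal(mu, library_size_sigma, n)).astype(np.int64)
    )
    counts = np.empty((m, n), dtype=np.int64)
    for j in range(n):
        counts[:, j] = rng.multinomial(libs[j], comp[j])
    if taxa_ids is None:
        taxa_ids = [f"otu{i + 1}" for i in range(m)]
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(n)]
    return CountTable(list(taxa_ids), list(sample_ids), counts)


def generate_study(config: SynthConfig | None = None, **overrides) -> MultiOmicsStudy:
    """Draw a full synthetic study from a :class:`SynthConfig`.

    Identical seeds give byte-identical studies.  Keyword overrides are a
    convenience for tests (``generate_study(seed=3, group_effect=0)``).
    """
    if config is None:
        config = SynthConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")

    n0, n1 = config.n_per_group
    n = n0 + n1
    ss = np.random.SeedSequence(config.seed)
    (s_latent, s_genes, s_mets, s_otus, s_pheno, s_time) = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(6)
    ]
    rng = np.random.default_rng(s_latent)

    group = np.array([GROUP_LABELS[0]] * n0 + [GROUP_LABELS[1]] * n1)
    mu = np.where(group == GROUP_LABELS[1], config.group_effect, 0.0)
    u = mu + rng.normal(0.0, 1.0, n)

    sample_ids = [f"m{i + 1:02d}" for i in range(n)]
    # timepoint alternates within each group: balanced, near-orthogonal to group
    timepoint = np.empty(n, dtype=int)
    timepoint[:n0] = np.arange(n0) % config.time_levels
    timepoint[n0:] = np.arange(n1) % config.time_levels

    t_rng = np.random.default_rng(s_time)
    t_ind = timepoint.astype(float) - timepoint.mean()

    def time_effect(n_features):
        # per-feature random directions scaled by time_shift
        coef = t_rng.normal(0.0, 1.0, n_features) * config.time_shift
        return np.outer(t_ind, coef), coef

    g_rng = np.random.default_rng(s_genes)
    gene_idx = np.arange(config.n_informative_genes)
    gene_baseline = g_rng.normal(5.0, 1.0, config.n_genes)
    genes = generate_continuous_block(
        u, config.n_genes, gene_idx, config.loading, config.noise_sd,
        positive=False, seed=s_genes + 1, baseline=gene_baseline,
        feature_prefix="gene",
    )
    gshift, gene_tcoef = time_effect(config.n_genes)
    genes = genes + gshift

    m_rng = np.random.default_rng(s_mets)
    met_idx = np.arange(config.n_informative_metabolites)
    met_baseline = m_rng.normal(0.0, 1.0, config.n_metabolites)
    mets = generate_continuous_block(
        u, config.n_metabolites, met_idx, config.loading, config.noise_sd,
        positive=False, seed=s_mets + 1, baseline=met_baseline,
        feature_prefix="met",
    )
    mshift, met_tcoef = time_effect(config.n_metabolites)
    mets = np.exp(mets + mshift)

    o_rng = np.random.default_rng(s_otus)
    taxa_baseline = o_rng.normal(0.0, 2.0, config.n_taxa)
    gamma = np.zeros(config.n_taxa)
    taxa_idx = np.arange(config.n_informative_taxa)
    # alternate enrichment/depletion so treatment reshapes, not just inflates
    gamma[taxa_idx] = config.loading * np.where(taxa_idx % 2 == 0, 1.0, -1.0)
    oshift, taxa_tcoef = time_effect(config.n_taxa)
    otus = generate_otu_counts(
        u, taxa_baseline, gamma,
        library_size_mean=config.library_size_mean,
        library_size_sigma=config.library_size_sigma,
        noise_sd=config.noise_sd, seed=s_otus + 1,
        sample_ids=sample_ids, extra_log_shift=oshift,
    )

    p_rng = np.random.default_rng(s_pheno)
    glucose = np.clip(420.0 - 40.0 * u + p_rng.normal(0, 20, n), 80.0, None)
    insulin = np.clip(10.0 - 1.5 * u + p_rng.normal(0, 1, n), 0.5, None)
    bodyweight = 48.0 - 2.0 * u + p_rng.normal(0, 1.5, n)
    phenotypes = pd.DataFrame(
        {"glucose": glucose, "insulin": insulin, "bodyweight": bodyweight},
        index=sample_ids,
    )

    metadata = pd.DataFrame(
        {
            "group": pd.Categorical(group, categories=list(GROUP_LABELS)),
            "genotype": pd.Categorical(["db/db"] * n),
            "timepoint": timepoint,
        },
        index=sample_ids,
    )
    genes.index = sample_ids
    mets = pd.DataFrame(np.asarray(mets), index=sample_ids,
                        columns=[f"met{i + 1}" for i in range(config.n_metabolites)])

    truth = {
        "latent": pd.Series(u, index=sample_ids),
        "informative_genes": list(genes.columns[gene_idx]),
        "informative_metabolites": list(mets.columns[met_idx]),
        "informative_taxa": [otus.taxa_ids[i] for i in taxa_idx],
        "gene_loading": config.loading,
        "taxa_loadings": gamma,
        "time_coefficients": {
            "genes": gene_tcoef, "metabolites": met_tcoef, "taxa": taxa_tcoef,
        },
        "config": config,
    }
    return MultiOmicsStudy(
        sample_ids=sample_ids,
        metadata=metadata,
        gene_block=genes,
        metabolite_block=mets,
        otu_block=otus,
        phenotypes=phenotypes,
        truth=truth,
    )
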