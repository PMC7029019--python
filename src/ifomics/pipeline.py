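"""End-to-end orchestration: simulate/load, preprocess, per-block rdCV with
a permutation gate, multi-block integration, microbiome statistics and
co-expression reports — reproducible under a single global seed, with a
run manifest (config snapshot, per-stage seeds, artifact checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coexpr import CoexpressionNetwork
from .diablo import DIABLO, full_design
from .io import read_matrix_tsv, read_metadata, write_matrix_tsv, write_metadata
from .microbiome import (ancom_w, bray_curtis, cap_partial,
                         clr_phenotype_correlations, observed_richness, pcoa,
                         permanova)
from .plsda import RdcvConfig, permutation_test, rdcv_run
from .preprocess import autoscale, clr_transform, css_normalize, rarefy
from .synth import SynthConfig, generate_study

logger = logging.getLogger("ifomics")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "write_report",
           "write_study"]


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults are desk-scale, not protocol-scale.

    The protocol-scale profile (rdcv_repetitions=200,
    n_permutations=1000, keepX=10, one component, tenfold tuning) is
    accepted and tagged in the manifest.
    """

    out_dir: str = "ifomics_run"
    synth: SynthConfig | None = None          # simulate when set
    gene_tsv: str | None = None               # else load from TSV
    metabolite_tsv: str | None = None
    otu_tsv: str | None = None
    metadata_tsv: str | None = None
    group_column: str = "group"
    time_column: str = "timepoint"
    rdcv: RdcvConfig = field(default_factory=lambda: RdcvConfig(repetitions=20))
    n_permutations: int = 50
    rarefaction_depth: int = 28257
    css_quantile: float = 0.5
    clr_pseudocount: float = 1.0
    keepx: int = 10
    n_components: int = 1
    tune_grid: list | None = None
    circos_threshold: float = 0.7
    ancom_alpha: float = 0.05
    permanova_permutations: int = 199
    coexpr_beta: float | str = 6.0
    coexpr_cut_height: float = 0.25
    coexpr_min_module_size: int = 5
    edge_weight_min: float = 0.4
    otu_integration: str = "clr"              # or "css"
    seed: int = 0


@dataclass
class RunManifest:
    config: dict
    version: str
    seeds: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    profile: str = "desk"

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "version": self.version,
                "profile": self.profile,
                "seeds": self.seeds,
                "stages": self.stages,
                "checksums": self.checksums,
                "warnings": self.warnings,
            },
            indent=2, default=str,
        )


def _stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: adding a stage never shifts the others."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_study(study, out_dir):
    """Write a study's blocks, metadata and truth in the TSV dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(study.gene_block.T, out / "gene_block.tsv")
    write_matrix_tsv(study.metabolite_block.T, out / "metabolite_block.tsv")
    write_matrix_tsv(study.otu_block.to_dataframe(), out / "otu_counts.tsv")
    meta = study.metadata.join(study.phenotypes)
    write_metadata(meta, out / "metadata.tsv")
    truth = {
        "informative_genes": study.truth["informative_genes"],
        "informative_metabolites": study.truth["informative_metabolites"],
        "informative_taxa": study.truth["informative_taxa"],
        "latent": study.truth["latent"].round(6).to_dict(),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return out


def _load_inputs(config: PipelineConfig):
    from .preprocess import CountTable

    if config.synth is not None:
        study = generate_study(replace(config.synth, seed=_stage_seed(
            config.seed, "synth")))
        meta = study.metadata.join(study.phenotypes)
        return (study.gene_block, study.metabolite_block, study.otu_block,
                meta)
    needed = [config.gene_tsv, config.metabolite_tsv, config.otu_tsv,
              config.metadata_tsv]
    if any(p is None for p in needed):
        raise ValueError("provide either a synth config or all four input TSVs")
    genes = read_matrix_tsv(config.gene_tsv).T        # samples x genes
    mets = read_matrix_tsv(config.metabolite_tsv).T
    otu_df = read_matrix_tsv(config.otu_tsv)
    otus = CountTable(list(otu_df.index), list(otu_df.columns),
                      otu_df.to_numpy())
    meta = read_metadata(config.metadata_tsv, block_samples=list(genes.index))
    return genes, mets, otus, meta


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis; returns the run manifest.

    Stage order mirrors the analysis design: per-block predictive
    validation (rdCV + permutation gate) precedes integration; the
    microbiome and co-expression suites report alongside.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(config)
    manifest = RunManifest(config=cfg_dict, version=__version__)
    protocol_scale = (config.rdcv.repetitions == 200
                   and config.n_permutations == 1000
                   and config.keepx == 10 and config.n_components == 1)
    manifest.profile = "protocol" if protocol_scale else "desk"

    def record(stage, seed=None, **info):
        entry = {"stage": stage, **info}
        if seed is not None:
            manifest.seeds[stage] = seed
        manifest.stages.append(entry)
        logger.info("stage=%s seed=%s %s", stage, seed, info)

    def emit(name: str, df: pd.DataFrame, index_label="id"):
        path = out / name
        write_matrix_tsv(df, path, index_label=index_label) if isinstance(
            df, pd.DataFrame) else path.write_text(df)
        manifest.checksums[name] = _checksum(path)

    t0 = time.time()
    stage = "load"
    try:
        genes, mets, otus, meta = _load_inputs(config)
        groups = meta[config.group_column].to_numpy()
        record(stage, seed=_stage_seed(config.seed, "synth"),
               n_samples=len(genes), n_genes=genes.shape[1],
               n_metabolites=mets.shape[1], n_taxa=otus.n_taxa)

        # ---------------------------------------------------- preprocessing
        stage = "preprocess"
        genes_scaled = autoscale(genes)
        mets_scaled = autoscale(np.log(mets) if (np.asarray(mets) > 0).all()
                                else mets)
        mets_scaled.values.index = mets.index
        css = css_normalize(otus, quantile=config.css_quantile)
        clr = clr_transform(otus, pseudocount=config.clr_pseudocount)
        emit("genes_scaled.tsv", genes_scaled.values.T)
        emit("metabolites_scaled.tsv", mets_scaled.values.T)
        emit("otu_css.tsv", css.values)
        emit("otu_clr.tsv", clr.values)
        (out / "normalization_params.json").write_text(json.dumps({
            "autoscale_ddof": genes_scaled.params["ddof"],
            "css": css.params, "clr": clr.params,
        }, indent=2))
        manifest.checksums["normalization_params.json"] = _checksum(
            out / "normalization_params.json")
        record(stage)

        otu_features = (clr if config.otu_integration == "clr" else css)
        otu_block = autoscale(otu_features.values.T).values

        blocks = {
            "genes": genes_scaled.values,
            "otus": otu_block,
            "metabolites": mets_scaled.values,
        }

        # --------------------------------------- per-block rdCV validation
        stage = "rdcv"
        seed = _stage_seed(config.seed, stage)
        rdcv_report = {}
        for name, block in blocks.items():
            cfg = replace(config.rdcv, seed=seed + len(name))
            res = rdcv_run(block, groups, cfg)
            perm = permutation_test(block, groups, cfg,
                                    n_permutations=config.n_permutations,
                                    seed=cfg.seed, observed=res)
            rdcv_report[name] = {
                "accuracy": res.accuracy,
                "misclassified": res.misclassified,
                "consensus_components": res.consensus_components,
                "permutation_p_empirical": perm.p_empirical,
                "permutation_p_parametric": perm.p_parametric,
            }
            emit(f"rdcv_probabilities_{name}.tsv", res.probabilities,
                 index_label="sample_id")
        (out / "rdcv_report.json").write_text(json.dumps(rdcv_report, indent=2))
        manifest.checksums["rdcv_report.json"] = _checksum(out / "rdcv_report.json")
        record(stage, seed=seed, **{k: v["accuracy"] for k, v in
                                    rdcv_report.items()})

        # ----------------------------------------------------- integration
        stage = "diablo"
        seed = _stage_seed(config.seed, stage)
        keepx = {b: min(config.keepx, blocks[b].shape[1]) for b in blocks}
        model = DIABLO(blocks, groups, design=full_design(list(blocks)))
        fit = model.fit(keepx=keepx, n_components=config.n_components)
        links = fit.circos_links(config.circos_threshold)
        row_order, col_order, _, _ = fit.cim_order()
        corr = fit.component_correlations()
        emit("diablo_component_correlations.tsv", corr, index_label="block")
        emit("diablo_links.tsv", links.set_index(
            links.index.rename("edge")) if len(links) else links,
            index_label="edge")
        (out / "diablo_selected.json").write_text(
            json.dumps(fit.selected, indent=2))
        (out / "cim_order.json").write_text(json.dumps(
            {"rows": [str(r) for r in row_order],
             "columns": [str(c) for c in col_order]}, indent=2))
        for f in ("diablo_selected.json", "cim_order.json"):
            manifest.checksums[f] = _checksum(out / f)
        record(stage, seed=seed, keepx=keepx,
               correlations={f"{a}|{b}": round(float(corr.loc[a, b]), 4)
                             for i, a in enumerate(corr.index)
                             for b in corr.index[i + 1:]})

        # ------------------------------------------------ microbiome suite
        stage = "microbiome"
        seed = _stage_seed(config.seed, stage)
        micro_report = {}
        try:
            rare = rarefy(otus, config.rarefaction_depth, seed=seed)
            rich = observed_richness(rare)
            micro_report["rarefaction_depth"] = config.rarefaction_depth
            micro_report["mean_observed_otus"] = float(rich.mean())
            emit("observed_richness.tsv", rich.to_frame(),
                 index_label="sample_id")
        except ValueError as exc:
            manifest.warnings.append(f"rarefaction skipped: {exc}")
        dist = bray_curtis(css.values.T)
        ordn = pcoa(dist)
        emit("pcoa_coordinates.tsv", ordn.coordinates, index_label="sample_id")
        perma = permanova(dist, groups,
                          n_permutations=config.permanova_permutations,
                          seed=seed)
        micro_report["permanova"] = {
            "pseudo_F": perma.pseudo_f, "R2": perma.r2, "p": perma.p_value}
        constraints = meta[[config.group_column]]
        condition = (meta[[config.time_column]].astype(float)
                     if config.time_column in meta else None)
        cap = cap_partial(dist, constraints, condition,
                          n_permutations=config.permanova_permutations,
                          seed=seed)
        micro_report["cap"] = {
            "term_variance": cap.term_variance.to_dict(),
            "term_p": cap.term_p.to_dict(),
            "conditioned": cap.conditioned,
        }
        ancom = ancom_w(otus, groups, alpha=config.ancom_alpha)
        micro_report["ancom_detected"] = ancom.detected_taxa()
        pheno_cols = [c for c in meta.columns if c in
                      ("glucose", "insulin", "bodyweight")]
        if pheno_cols:
            corr_table = clr_phenotype_correlations(clr, meta[pheno_cols])
            emit("clr_phenotype_correlations.tsv",
                 corr_table.set_index("taxon"), index_label="taxon")
        (out / "microbiome_report.json").write_text(
            json.dumps(micro_report, indent=2))
        manifest.checksums["microbiome_report.json"] = _checksum(
            out / "microbiome_report.json")
        record(stage, seed=seed, permanova_p=perma.p_value,
               ancom_detected=len(micro_report["ancom_detected"]))

        # ------------------------------------------------- coexpression
        stage = "coexpr"
        net = CoexpressionNetwork(genes, beta=config.coexpr_beta)
        cres = net.fit(cut_height=config.coexpr_cut_height,
                       min_module_size=config.coexpr_min_module_size)
        trait = (groups == np.unique(groups)[1]).astype(float)
        coexpr_report = {"beta": cres.beta,
                         "n_modules": int(cres.labels.max())}
        if cres.eigengenes.shape[1] > 0:
            mt = cres.module_trait_correlation(trait)
            hubs = cres.select_hub_genes(trait)
            coexpr_report["module_trait"] = mt.round(6).to_dict()
            coexpr_report["hub_genes"] = hubs.hub_genes
            emit("module_labels.tsv", cres.labels.to_frame(),
                 index_label="gene")
            emit("module_eigengenes.tsv", cres.eigengenes,
                 index_label="sample_id")
            emit("hub_statistics.tsv", hubs.table, index_label="gene")
        edges = cres.export_edges(config.edge_weight_min)
        emit("network_edges.tsv",
             edges.set_index(edges.index.rename("edge")) if len(edges)
             else edges, index_label="edge")
        (out / "coexpr_report.json").write_text(
            json.dumps(coexpr_report, indent=2))
        manifest.checksums["coexpr_report.json"] = _checksum(
            out / "coexpr_report.json")
        record(stage, n_modules=coexpr_report["n_modules"])

    except Exception as exc:
        manifest.warnings.append(f"aborted at stage {stage}: {exc}")
        (out / "manifest.json").write_text(manifest.to_json())
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    record("done", elapsed_s=round(time.time() - t0, 2))
    (out / "manifest.json").write_text(manifest.to_json())
    write_report(out)
    return manifest


def write_report(out_dir) -> str:
    """Render a human-readable Markdown summary from the run artifacts.

    Re-reads the emitted JSON artifacts so the report numbers are exactly
    the artifact values; regeneration is idempotent.
    """
    out = Path(out_dir)

    def load(name):
        p = out / name
        return json.loads(p.read_text()) if p.exists() else None

    rdcv = load("rdcv_report.json")
    micro = load("microbiome_report.json")
    coexpr = load("coexpr_report.json")
    selected = load("diablo_selected.json")
    lines = ["# ifomics run report", ""]
    if rdcv:
        lines.append("## Per-block rdCV-PLS-DA")
        for name, r in rdcv.items():
            lines.append(
                f"- **{name}**: accuracy {r['accuracy']:.3f}, "
                f"permutation p {r['permutation_p_empirical']:.4g}, "
                f"consensus components {r['consensus_components']}, "
                f"misclassified {r['misclassified'] or 'none'}")
    else:
        lines.append("## Per-block rdCV-PLS-DA\n_skipped_")
    lines.append("")
    if selected:
        lines.append("## DIABLO integration")
        for b, feats in selected.items():
            lines.append(f"- selected[{b}]: {', '.join(map(str, feats))}")
        links = out / "diablo_links.tsv"
        if links.exists():
            n_edges = max(0, sum(1 for _ in links.open()) - 1)
            lines.append(f"- cross-block links above threshold: {n_edges}")
    else:
        lines.append("## DIABLO integration\n_skipped_")
    lines.append("")
    if micro:
        lines.append("## Microbiome")
        if "permanova" in micro:
            pm = micro["permanova"]
            lines.append(
                f"- PERMANOVA: pseudo-F {pm['pseudo_F']:.3f}, "
                f"R² {pm['R2']:.3f}, p {pm['p']:.4g}")
        if "cap" in micro:
            for term, v in micro["cap"]["term_variance"].items():
                lines.append(
                    f"- CAP {term}: {100 * v:.1f}% of total variance "
                    f"(p {micro['cap']['term_p'][term]:.4g})")
        lines.append(f"- ANCOM detected: "
                     f"{', '.join(micro.get('ancom_detected', [])) or 'none'}")
    else:
        lines.append("## Microbiome\n_skipped_")
    lines.append("")
    if coexpr:
        lines.append("## Co-expression")
        lines.append(f"- modules: {coexpr['n_modules']} (beta {coexpr['beta']})")
        hubs = coexpr.get("hub_genes", [])
        lines.append(f"- hub genes: {', '.join(map(str, hubs)) or 'none'}")
    else:
        lines.append("## Co-expression\n_skipped_")
    text = "\n".join(lines) + "\n"
    (out / "report.md").write_text(text)
    return text
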