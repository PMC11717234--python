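"""Orchestration of the two study-shaped workflows over synthetic data.

``run_embryo_workflow`` mirrors the single-embryo blastocyst analysis:
simulate a cohort, QC-filter it, sex and genotype each embryo, run gene- and
repeat-level differential expression (the latter with the DNA-contamination
covariate), and finish with signed-rank GSEA and the developmental-delay
statistics. ``run_bulk_workflow`` mirrors the placenta-style bulk analysis:
sex-stratified differential expression plus marker-set enrichment.

Both emit flat, machine-readable reports (JSON + TSV) with every discarded
sample accounted for, and are byte-identical on rerun with the same config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, embryo_geno, enrichment, simdata, te_quant

__all__ = ["RunConfig", "run_embryo_workflow", "run_bulk_workflow", "WorkflowError"]


class WorkflowError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Thresholds and sizes of one pipeline run.

    Defaults mirror the study: genes called at padj < 0.05, repeats at
    padj < 0.1, embryos discarded below 1e6 reads, k = 6 unwanted-variation
    factors, tag-read genotyping cutoff 72.
    """

    workflow: str = "embryo"
    seed: int = 0
    outdir: str | None = None
    deg_alpha: float = 0.05
    te_alpha: float = 0.1
    depth_min: int = 1_000_000
    ruv_k: int = 6
    tag_cutoff: int = 72
    use_ruv: bool = False
    sex_threshold: float = 10.0
    n_embryos_per_group: int = 12
    n_genes: int = 400
    n_repeat_elements: int = 60
    te_depth_fragments: int = 6_000
    planted_family: str | None = None
    planted_family_fold: float = 1.0
    planted_gene_log2fc: dict[str, float] = field(default_factory=dict)
    dna_contamination_fraction: float = 0.05
    gsea_n_perm: int = 500

    def __post_init__(self):
        if self.workflow not in ("embryo", "bulk"):
            raise ValueError(f"unrecognized workflow {self.workflow}")
        for name in ("deg_alpha", "te_alpha", "depth_min", "ruv_k", "tag_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(str(path)) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _write_report(outdir: Path | None, report: dict, tables: dict[str, pd.DataFrame]) -> dict:
    payload = json.dumps(report, sort_keys=True, indent=1, default=str)
    report["report_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=1, default=str)
        )
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t")
    return report


def _embryo_sim_config(config: RunConfig) -> simdata.SimConfig:
    n = config.n_embryos_per_group
    allele_mix: dict[str, tuple[float, float, float]] = {}
    for i in range(2 * n):
        e = f"embryo{i + 1:03d}"
        # first half mutant (deletion allele), second half WT
        allele_mix[e] = (0.0, 0.0, 1.0) if i < n else (1.0, 0.0, 0.0)
    return simdata.SimConfig(
        seed=config.seed,
        n_repeat_elements=config.n_repeat_elements,
        n_genes=40,
        allele_mix=allele_mix,
        dna_contamination_fraction=config.dna_contamination_fraction,
        nb_dispersion=0.05,
        effect_log2fc=dict(config.planted_gene_log2fc),
        mean_depth_fragments=config.te_depth_fragments,
    )


def _te_stage(config: RunConfig, sim, annotation, genotypes: pd.Series):
    """Per-embryo repeat quantification: simulate fragments, filter, count,
    FPKM, DNA covariate, then repName-level DE with ~ dna_fpkm + genotype."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(77,)))
    repeats_df = annotation.repeats
    rep_names = sorted(repeats_df[~repeats_df.repClass.isin(te_quant.EXCLUDED_CLASSES)].repName.unique())
    name2fam = repeats_df.set_index("repName").repFamily.to_dict()
    name2cls = repeats_df.set_index("repName").repClass.to_dict()
    base = pd.Series(rng.uniform(0.5, 3.0, size=len(rep_names)), index=rep_names)
    base[[n for n in rep_names if name2cls[n] == "DNA"]] = 0.0  # silent in RNA

    elements = [
        te_quant.RepeatElement(r.chrom, int(r.start), int(r.end), r.strand, r.repName, r.repFamily, r.repClass)
        for r in repeats_df.itertuples(index=False)
    ]
    genes = annotation.genes
    disp = 0.05

    tables, discarded_fragments = [], {}
    for embryo in genotypes.index:
        fold = pd.Series(1.0, index=rep_names)
        if config.planted_family and genotypes[embryo] != "WT":
            members = [n for n in rep_names if name2fam.get(n) == config.planted_family]
            fold[members] = config.planted_family_fold
        noise = rng.gamma(1.0 / disp, disp, size=len(rep_names))
        rates = base * fold * noise
        frags_df, _ = simdata.simulate_fragments(sim, annotation, rates, sample=embryo)
        frags = [
            te_quant.AlignedFragment(r.read_id, r.chrom, (r.m1_start, r.m1_end), (r.m2_start, r.m2_end))
            for r in frags_df.itertuples(index=False)
        ]
        kept = te_quant.filter_repeat_fragments(frags, elements, genes)
        discarded_fragments[embryo] = len(frags) - len(kept)
        tables.append(
            te_quant.count_by_repname(kept, elements, input_read_count=2 * len(frags), sample=embryo)
        )
    table = te_quant.merge_count_tables(tables)
    fpkm = te_quant.fpkm_repname(table)
    dna, dna_flags = te_quant.dna_contamination_covariate(fpkm, table.name_to_class)

    meta = pd.DataFrame(
        {"genotype": genotypes, "dna_fpkm": dna.reindex(genotypes.index)}, index=genotypes.index
    )
    te_res = diffexpr.nb_wald_test(
        table.counts[genotypes.index], meta, condition="genotype", covariates=["dna_fpkm"]
    )
    te_res = diffexpr.independent_filtering(te_res, alpha=config.te_alpha)
    return table, fpkm, dna, dna_flags, te_res, discarded_fragments


def run_embryo_workflow(config: RunConfig) -> dict:
    """Single-embryo workflow over self-generated data; returns the report."""
    if config.workflow != "embryo":
        raise WorkflowError("validate", "config.workflow must be 'embryo'")
    sim = _embryo_sim_config(config)
    try:
        annotation = simdata.make_toy_annotation(sim)
        counts, locus_reads, truth = simdata.simulate_embryo_cohort(
            sim, annotation, n_genes=config.n_genes
        )
    except Exception as exc:
        raise WorkflowError("simulate", str(exc)) from exc

    # --- QC
    kept, discarded = embryo_geno.qc_filter_embryos(truth, depth_min=config.depth_min)
    kept_ids = list(kept.index)
    counts = counts[kept_ids]

    # --- normalization, sexing, genotyping
    sf = diffexpr.size_factors_median_ratios(counts)
    norm = diffexpr.normalized_counts(counts, sf)
    sex = embryo_geno.assign_sex(norm, ["Ddx3y", "Eif2s3y"], threshold=config.sex_threshold)
    templates = annotation.allele_templates()
    allele_calls = {
        e: embryo_geno.call_allele_at_locus(
            [r["sequence"] for r in locus_reads[e]], templates
        )
        for e in kept_ids
    }
    genotypes = pd.Series({e: allele_calls[e].call for e in kept_ids}, name="genotype")
    tag_geno = {
        e: embryo_geno.genotype_from_tag_counts(int(truth.loc[e, "tag_read_sum"]), config.tag_cutoff)
        for e in kept_ids
    }

    # --- gene-level DE: mutant vs WT
    contrast = genotypes[genotypes.isin(["WT", "deletion"])]
    if contrast.nunique() < 2 or (contrast.value_counts() < 2).any():
        raise WorkflowError("diffexpr", "need >= 2 embryos per genotype after QC")
    meta = pd.DataFrame({"genotype": contrast})
    covariates: list[str] = []
    if config.use_ruv:
        per_cond = [
            diffexpr.nb_wald_test(
                counts[contrast.index], meta, condition="genotype", size_factors=sf[contrast.index]
            )
        ]
        controls = diffexpr.select_control_genes(per_cond)
        ruv = diffexpr.ruv_factors(counts[contrast.index], controls, k=config.ruv_k)
        meta = meta.join(ruv.W)
        covariates = list(ruv.W.columns)
    gene_res = diffexpr.nb_wald_test(
        counts[contrast.index], meta, condition="genotype",
        covariates=covariates, size_factors=sf[contrast.index],
    )
    gene_res = diffexpr.independent_filtering(gene_res, alpha=config.deg_alpha)

    # --- TE stage
    try:
        te_table, fpkm, dna, dna_flags, te_res, disc_frag = _te_stage(
            config, sim, annotation, contrast
        )
    except Exception as exc:
        raise WorkflowError("te_quant", str(exc)) from exc

    # --- enrichment and delay statistics
    ranked = enrichment.rank_by_signed_significance(gene_res.dropna(subset=["padj"]))
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(88,)))
    up = ranked.index[: max(len(ranked) // 10, 5)]
    sets = [enrichment.GeneSet("top_decile_up", frozenset(up))]
    gsea_res = enrichment.gsea(
        ranked, sets, n_perm=config.gsea_n_perm, seed=config.seed, min_size=2, max_size=len(ranked)
    )

    # synthetic stage trajectory standing in for the public reference data
    stage = pd.DataFrame(
        rng.uniform(0, 100, size=(len(te_res), 3)),
        index=te_res.index, columns=["8cell", "E3.5_ICM", "E3.5_TE"],
    )
    e35 = enrichment.blastocyst_stage_value(stage)
    lfc_te = np.log2((stage["E3.5_TE"] + 1) / (stage["8cell"] + 1))
    lfc_icm = np.log2((stage["E3.5_ICM"] + 1) / (stage["8cell"] + 1))
    dev_lfc = enrichment.weighted_dev_log2fc(lfc_te, lfc_icm)
    mutant_lfc = te_res["log2FC"].dropna()
    sig_mask = te_res["padj"] < config.te_alpha
    delay = enrichment.delay_correlation(mutant_lfc, dev_lfc.loc[mutant_lfc.index], significant=sig_mask)

    n_deg = int((gene_res["padj"] < config.deg_alpha).sum())
    n_te = int((te_res["padj"] < config.te_alpha).sum())
    sig_names = sorted(te_res.index[te_res["padj"].fillna(1.0) < config.te_alpha])
    report = {
        "workflow": "embryo",
        "seed": config.seed,
        "n_embryos_simulated": int(len(truth)),
        "n_embryos_kept": int(len(kept_ids)),
        "discarded": {str(i): r for i, r in discarded["reasons"].items()},
        "sex_calls": sex.calls.to_dict(),
        "genotype_calls": genotypes.to_dict(),
        "tag_genotype_calls": tag_geno,
        "n_deg_genes": n_deg,
        "n_deg_repeats": n_te,
        "significant_repeats": sig_names,
        "dna_flagged_samples": sorted(dna_flags.index[dna_flags]),
        "discarded_fragments_per_embryo": disc_frag,
        "delay_correlation": delay,
        "gsea": gsea_res.reset_index().to_dict(orient="records"),
        "max_e35_value_mean": float(e35.mean()),
    }
    tables = {
        "gene_de": gene_res,
        "te_de": te_res,
        "fpkm_repname": fpkm.fpkm,
        "dna_covariate": dna.to_frame("dna_fpkm"),
    }
    return _write_report(Path(config.outdir) if config.outdir else None, report, tables)


def run_bulk_workflow(config: RunConfig, counts=None, meta=None) -> dict:
    """Bulk (placenta-style) workflow: sex-stratified DE + marker GSEA.

    With no inputs, a synthetic dataset with sex-linked dosage genes and a
    genotype effect is generated. ``meta`` must carry ``sex`` and
    ``genotype`` columns; validation failures abort before any computation.
    """
    if config.workflow != "bulk":
        raise WorkflowError("validate", "config.workflow must be 'bulk'")
    if counts is None:
        sim = simdata.SimConfig(
            seed=config.seed,
            n_samples_per_group=config.n_embryos_per_group,
            effect_log2fc=dict(config.planted_gene_log2fc),
            nb_dispersion=0.05,
        )
        n = 2 * config.n_embryos_per_group
        groups = [0] * (n // 2) + [1] * (n - n // 2)
        counts, meta_sim, truth = simdata.simulate_counts(
            sim, groups, feature_ids=[f"gene{i + 1:05d}" for i in range(config.n_genes)]
        )
        sexes = ["female" if i % 2 == 0 else "male" for i in range(n)]
        # planted X/Y dosage structure: chrY genes male-only, one X gene doubled in females
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(99,)))
        male = np.array([s == "male" for s in sexes])
        # small background in females mimics cross-mapping noise and keeps
        # the per-gene GLM away from the all-zero-group corner
        ydos = rng.poisson(60, size=(2, n)) * male + rng.poisson(1.0, size=(2, n))
        xdos = rng.poisson(np.where(male, 100, 200), size=(1, n))
        dosage = pd.DataFrame(
            np.vstack([ydos, xdos]), index=["Ddx3y", "Eif2s3y", "Xist_proxy"], columns=counts.columns
        )
        counts = pd.concat([dosage, counts])
        meta = pd.DataFrame(
            {"sex": sexes, "genotype": ["WT" if g == 0 else "mutant" for g in groups]},
            index=counts.columns,
        )
    for col in ("sex", "genotype"):
        if meta is None or col not in meta.columns:
            raise WorkflowError("validate", f"sample metadata missing required column '{col}'")

    results = {}
    for sex in sorted(meta["sex"].unique()):
        sub = meta.index[meta["sex"] == sex]
        sub_meta = meta.loc[sub]
        if sub_meta["genotype"].nunique() < 2 or (sub_meta.groupby("genotype").size() < 2).any():
            results[sex] = None
            continue
        res = diffexpr.nb_wald_test(counts[sub], sub_meta, condition="genotype")
        results[sex] = diffexpr.independent_filtering(res, alpha=config.deg_alpha)

    sex_res = diffexpr.nb_wald_test(counts, meta, condition="sex")
    sex_res = diffexpr.independent_filtering(sex_res, alpha=config.deg_alpha)

    ranked = enrichment.rank_by_signed_significance(sex_res.dropna(subset=["padj"]))
    marker = enrichment.GeneSet("sex_markers", frozenset(["Ddx3y", "Eif2s3y", "Xist_proxy"]))
    gsea_res = enrichment.gsea(
        ranked, [marker], n_perm=config.gsea_n_perm, seed=config.seed, min_size=2, max_size=len(ranked)
    )

    report = {
        "workflow": "bulk",
        "seed": config.seed,
        "n_samples": int(counts.shape[1]),
        "deg_counts_by_sex": {
            s: (int((r["padj"] < config.deg_alpha).sum()) if r is not None else None)
            for s, r in results.items()
        },
        "n_sex_deg": int((sex_res["padj"] < config.deg_alpha).sum()),
        "sex_deg": sorted(sex_res.index[sex_res["padj"].fillna(1.0) < config.deg_alpha]),
        "gsea": gsea_res.reset_index().to_dict(orient="records"),
    }
    tables = {"sex_de": sex_res}
    for s, r in results.items():
        if r is not None:
            tables[f"de_{s}"] = r
    return _write_report(Path(config.outdir) if config.outdir else None, report, tables)
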