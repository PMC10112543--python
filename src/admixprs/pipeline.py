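"""End-to-end orchestration: QC → structure → scoring → evaluation →
survival → focal haplotypes, with a reproducibility manifest.

Every stage is a pure function of (inputs, config, seed); outputs are
plain-text tables whose SHA-256 digests are recorded in the manifest,
so two runs with the same configuration produce identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry as anc
from . import haplotypes as hap
from . import relatedness as rel
from .config import PipelineConfig
from .evaluate import confusion_metrics, logistic_assoc, quintile_effects
from .io import (
    GenotypeSet,
    harmonize,
    read_cohort,
    read_summary_stats,
    read_vcf,
    remove_strand_ambiguous,
)
from .prs import PRSVector, clump, prune_and_threshold, score
from .simulate import SimConfig, simulate_cohort, simulate_focal_haplotypes, simulate_onset, write_bundle
from .survival import build_survival, cox_quintile, km_estimate

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def record_stage(self, name: str, status: str) -> None:
        self.stages.append({"name": name, "status": status})

    def record_output(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = digest

    def write(self, path: Path) -> None:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "stages": self.stages,
            "outputs": dict(sorted(self.outputs.items())),
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _table1_row(prs: PRSVector, cohort: pd.DataFrame, covariates: list[str], k: float) -> dict:
    assoc = logistic_assoc(prs, cohort, covariates, prevalence_k=k)
    lookup = pd.Series(prs.score, index=prs.sample_ids)
    sub = cohort[cohort["sample_id"].isin(lookup.index)]
    roc = confusion_metrics(lookup.loc[sub["sample_id"]].to_numpy(), sub["status"].to_numpy())
    return {
        "PVALUE": assoc.pvalue,
        "R2": assoc.liability_r2,
        "PSEUDO_R2": assoc.nagelkerke_r2,
        "AUC": roc.auc,
        "AUC_CI_LOW": roc.ci_low,
        "AUC_CI_HIGH": roc.ci_high,
        "ACC": roc.accuracy,
        "BAL_ACC": roc.balanced_accuracy,
        "SPEC": roc.specificity,
        "SENS": roc.sensitivity,
        "N": assoc.n,
        "N_VARIANTS": prs.n_variants,
    }


def run_all(
    pipe_cfg: PipelineConfig,
    out_dir: str | Path,
    sim_cfg: SimConfig | None = None,
    vcf_path: str | Path | None = None,
    sumstats_path: str | Path | None = None,
    cohort_path: str | Path | None = None,
    grid_search: bool = True,
    run_haplotypes: bool = True,
) -> RunManifest:
    """Execute the full analysis on a simulated or file-based bundle.

    With ``sim_cfg`` supplied the input bundle is generated (and written
    to disk); otherwise ``vcf_path``, ``sumstats_path`` and
    ``cohort_path`` name the inputs. Emits a Table-1-style evaluation
    report (ALL and unrelated-subset rows), per-sample scores, quintile
    odds ratios, survival tables, ancestry outputs and, when phased
    focal-window data are available, the haplotype analysis.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses.asdict(pipe_cfg), seed=pipe_cfg.seed if sim_cfg is None else sim_cfg.seed
    )

    # ---- inputs -----------------------------------------------------------
    if sim_cfg is not None:
        bundle = simulate_cohort(sim_cfg)
        paths = write_bundle(bundle, out / "inputs")
        for p in paths.values():
            manifest.record_output(p)
        genotypes, cohort, records = bundle.genotypes, bundle.cohort, bundle.sumstats
        truth = bundle.truth
        manifest.record_stage("simulate", "ok")
    else:
        if not (vcf_path and sumstats_path and cohort_path):
            raise ValueError("either sim_cfg or all three input paths are required")
        genotypes = read_vcf(vcf_path)
        records, _ = read_summary_stats(sumstats_path)
        cohort = read_cohort(cohort_path)
        truth = None
        manifest.record_stage("load", "ok")

    # ---- QC: MAF filter, kinship, unrelated subset ------------------------
    genotypes = rel.maf_filter(genotypes, pipe_cfg.maf_min)
    kin = rel.king_kinship(genotypes)
    kin.to_tsv(out / "kinship.tsv")
    manifest.record_output(out / "kinship.tsv")
    unrelated = rel.unrelated_subset(kin, pipe_cfg.kinship_max)
    manifest.record_stage("qc", "ok")

    # ---- ancestry structure -----------------------------------------------
    projection = anc.genotype_pca(genotypes, n_pcs=pipe_cfg.n_pcs)
    pcs = projection.to_frame()
    pcs.to_csv(out / "pcs.tsv", sep="\t", index=False, float_format="%.6g")
    manifest.record_output(out / "pcs.tsv")
    clusters = anc.pc_kmeans(projection, k=min(3, max(2, genotypes.n_samples)), seed=pipe_cfg.seed)
    pd.DataFrame({"sample_id": genotypes.sample_ids, "cluster": clusters}).to_csv(
        out / "clusters.tsv", sep="\t", index=False
    )
    manifest.record_output(out / "clusters.tsv")
    cohort = cohort.merge(pcs, on="sample_id", how="left")
    pc_cols = [f"PC{i+1}" for i in range(min(pipe_cfg.n_pcs, projection.coords.shape[1]))]
    covariates = ["sex", "site"] + pc_cols if "site" in cohort.columns else ["sex"] + pc_cols
    manifest.record_stage("ancestry", "ok")

    # ---- harmonize + score -------------------------------------------------
    records, _removed = remove_strand_ambiguous(records)
    stats = harmonize(records, genotypes)
    gw = stats.subset(stats.pvalue <= 5e-8)
    if len(gw) == 0:
        raise ValueError("no genome-wide-significant variants to score")
    clumped = clump(gw, genotypes, r2=pipe_cfg.clump_r2, window_kb=pipe_cfg.clump_window_kb)
    keep = set(clumped.index_variants)
    gw_index = gw.subset(np.array([v in keep for v in gw.variant_ids]))
    prs = score(genotypes, gw_index, standardize=True, p_threshold=5e-8)
    prs.to_frame().to_csv(out / "prs.tsv", sep="\t", index=False, float_format="%.6g")
    manifest.record_output(out / "prs.tsv")
    if grid_search:
        best_t, prs_full, fit_table = prune_and_threshold(
            stats, genotypes, cohort, pipe_cfg.threshold_grid, covariates,
            r2=pipe_cfg.clump_r2, window_kb=pipe_cfg.clump_window_kb,
        )
        fit_table.to_csv(out / "threshold_fits.tsv", sep="\t", index=False, float_format="%.6g")
        manifest.record_output(out / "threshold_fits.tsv")
    manifest.record_stage("score", "ok")

    # ---- evaluation (Table-1 style) ---------------------------------------
    rows = {"ALL": _table1_row(prs, cohort, covariates, pipe_cfg.prevalence_k)}
    unrel_cohort = cohort[cohort["sample_id"].isin(unrelated)]
    if len(unrel_cohort) < len(cohort):
        rows["UNREL_2ND_DEGREE"] = _table1_row(prs, unrel_cohort, covariates, pipe_cfg.prevalence_k)
    report = pd.DataFrame(rows).T.rename_axis("SUBSET").reset_index()
    report.to_csv(out / "evaluation.tsv", sep="\t", index=False, float_format="%.6g")
    manifest.record_output(out / "evaluation.tsv")
    quint = quintile_effects(prs, cohort, covariates)
    pd.DataFrame([dataclasses.asdict(qv) for qv in quint]).to_csv(
        out / "quintile_or.tsv", sep="\t", index=False, float_format="%.6g"
    )
    manifest.record_output(out / "quintile_or.tsv")
    manifest.record_stage("evaluate", "ok")

    # ---- survival ----------------------------------------------------------
    surv = build_survival(cohort, prs)
    km = km_estimate(surv)
    km.to_csv(out / "km_curves.tsv", sep="\t", index=False, float_format="%.6g")
    manifest.record_output(out / "km_curves.tsv")
    try:
        cox = cox_quintile(surv, covariates=["sex"] + pc_cols)
        pd.DataFrame([dataclasses.asdict(c) for c in cox]).to_csv(
            out / "cox_quintile.tsv", sep="\t", index=False, float_format="%.6g"
        )
        manifest.record_output(out / "cox_quintile.tsv")
        manifest.record_stage("survival", "ok")
    except ValueError as exc:
        logger.warning("Cox stage skipped: %s", exc)
        manifest.record_stage("survival", f"skipped: {exc}")

    # ---- focal haplotypes --------------------------------------------------
    if run_haplotypes and sim_cfg is not None:
        window, hap_cohort, hap_truth = simulate_focal_haplotypes(sim_cfg)
        blocks = hap.gabriel_blocks(window)
        pd.DataFrame(
            [
                {"chrom": b.chrom, "start": b.start, "end": b.end, "n_variants": b.n_variants}
                for b in blocks
            ]
        ).to_csv(out / "hap_blocks.tsv", sep="\t", index=False)
        manifest.record_output(out / "hap_blocks.tsv")
        table = hap.enumerate_haplotypes(window, hap_truth.focal_variant_id, pipe_cfg.hap_freq_min)
        focal_col = window.variant_index()[hap_truth.focal_variant_id]
        results = hap.screen_and_condition(
            table, window.dosage[:, focal_col], hap_cohort, covariates=["sex", "age", "site"]
        )
        pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
            out / "hap_assoc.tsv", sep="\t", index=False, float_format="%.6g"
        )
        manifest.record_output(out / "hap_assoc.tsv")
        g_haps = [h for h in table.haplotypes if h.focal_allele == "G"]
        if len(g_haps) >= 2:
            share = hap.haplotype_sharing(
                g_haps[0].alleles, g_haps[1].alleles, hap_truth.hap_ancestral
            )
            (out / "hap_sharing.txt").write_text(f"{share}\n")
            manifest.record_output(out / "hap_sharing.txt")
        if len(table.haplotypes) >= 2:
            net = hap.parsimony_network(table.haplotypes)
            net.edge_list().to_csv(out / "hap_network.tsv", sep="\t", index=False)
            manifest.record_output(out / "hap_network.tsv")
        manifest.record_stage("haplotypes", "ok")

    manifest.write(out / "manifest.json")
    return manifest
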