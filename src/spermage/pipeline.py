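"""End-to-end orchestration: simulate/load -> QC -> filter -> EWAS ->
clustering -> DMR -> annotation/enrichment -> outcomes -> mediation ->
subject clustering -> report."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from . import annotate as ann
from .core import MethylomeDataset, apply_probe_filters, imprinting_qc, read_exclusion_list
from .ewas import run_ewas
from .gee import run_dmr
from .mediation import run_mediation
from .outcomes import run_art_outcomes
from .regions import find_clusters, regions_to_bed
from .simulate import SimulationConfig, generate_annotations, simulate_cohort, write_cohort

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "cluster_subjects"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Either real-input paths or a simulation block must be present."""

    outdir: str = "spermage_out"
    seed: int = 0
    # real inputs
    manifest: str | None = None
    beta_matrix: str | None = None
    phenotypes: str | None = None
    tracks: dict[str, str] = field(default_factory=dict)  # name -> BED path
    tss: str | None = None
    exclusion_lists: dict[str, str] = field(default_factory=dict)
    maternal_loci: dict[str, list[str]] = field(default_factory=dict)
    paternal_loci: dict[str, list[str]] = field(default_factory=dict)
    # simulation block
    simulate: SimulationConfig | None = None
    # thresholds
    q_threshold: float = 0.05
    max_gap: int = 1000
    corr_threshold: float = 0.5
    corr_type: str = "spearman"
    linkage: str = "single"
    tss_window: int = 1500
    freq_threshold: float = 0.20
    bootstrap_B: int = 200
    n_subject_groups: int = 4
    run_mediation_stage: bool = True
    mediation_outcomes: tuple = ("fertilization", "live_birth")

    def __post_init__(self) -> None:
        real = self.manifest and self.beta_matrix and self.phenotypes
        if not real and self.simulate is None:
            raise ValueError("config needs real-input paths or a simulation block")
        if not 0 < self.q_threshold < 1 or not 0 < self.corr_threshold < 1:
            raise ValueError("thresholds out of range")
        if not 0 < self.freq_threshold <= 1:
            raise ValueError("freq_threshold out of range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw, simulate=None) if sim is None else cls(
            **raw, simulate=SimulationConfig(**{
                k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
                if isinstance(v, list) else v for k, v in sim.items()
            })
        )
        return cfg


@dataclass
class RunReport:
    counts: dict[str, int] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    files: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def cluster_subjects(sig_betas: np.ndarray, subject_ids, k: int = 4) -> pd.Series:
    """Agglomerative (Ward, Euclidean) clustering of subjects on the beta
    values of significant CpGs, tree cut at k groups."""
    if sig_betas.shape[0] < 2:
        raise ValueError("need >= 2 significant CpGs to cluster subjects")
    if len(subject_ids) < k:
        raise ValueError("fewer subjects than groups")
    Zl = linkage(sig_betas.T, method="ward", metric="euclidean")
    labels = fcluster(Zl, t=k, criterion="maxclust")
    return pd.Series(labels, index=list(subject_ids), name="group")


def _stage(report: RunReport, name: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s started", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            report.timings_s[name] = round(time.perf_counter() - self.t0, 3)
            if exc_type is not None:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, report.timings_s[name])

    return _T()


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(params={k: str(v) for k, v in dataclasses.asdict(cfg).items()},
                       seeds={"pipeline": cfg.seed})

    truth = None
    with _stage(report, "input"):
        if cfg.simulate is not None:
            sim = dataclasses.replace(cfg.simulate, seed=cfg.simulate.seed or cfg.seed)
            ds, couples, truth = simulate_cohort(sim)
            tracks, tss = generate_annotations(sim, ds, truth)
            from .outcomes import couples_to_frame

            pheno = couples_to_frame(couples)
            files = write_cohort(outdir / "inputs", ds, couples, truth, tracks, tss)
            report.files.update(files)
            report.seeds["simulation"] = sim.seed
        else:
            ds = MethylomeDataset.read(cfg.manifest, cfg.beta_matrix)
            from .outcomes import read_phenotypes

            pheno = read_phenotypes(cfg.phenotypes)
            tracks = [ann.AnnotationTrack.read_bed(n, p) for n, p in cfg.tracks.items()]
            tss = pd.read_csv(cfg.tss, sep="\t") if cfg.tss else None
        report.counts["input_probes"] = ds.n_probes
        report.counts["subjects"] = ds.n_subjects

    with _stage(report, "qc"):
        if cfg.simulate is not None:
            # demo loci from the cohort-mean extremes: exercises the QC path
            means = ds.beta.mean(axis=1)
            ids = ds.manifest.table["probe_id"]
            maternal = {"maternal_demo": ids[np.argsort(means)[:5]].tolist()}
            paternal = {"paternal_demo": ids[np.argsort(means)[-5:]].tolist()}
        else:
            maternal, paternal = cfg.maternal_loci, cfg.paternal_loci
        if maternal and paternal:
            qc = imprinting_qc(ds, maternal, paternal)
            qc.to_json(outdir / "qc_report.json")
            report.files["qc_report"] = str(outdir / "qc_report.json")
            report.counts["qc_failed_subjects"] = len(qc.failures)
            if qc.failures:
                report.warnings.append(f"imprinting QC flagged {len(qc.failures)} subjects")
        else:
            report.skipped.append("qc")

    with _stage(report, "filter"):
        if cfg.exclusion_lists:
            lists = {n: read_exclusion_list(p) for n, p in cfg.exclusion_lists.items()}
            ds = apply_probe_filters(ds, lists)
            report.counts["excluded_probes"] = report.counts["input_probes"] - ds.n_probes
        else:
            report.counts["excluded_probes"] = 0
        report.counts["filtered_probes"] = ds.n_probes

    with _stage(report, "ewas"):
        ewas = run_ewas(ds, pheno)
        ewas.write_csv(outdir / "ewas.csv")
        report.files["ewas"] = str(outdir / "ewas.csv")
        sig = ewas.significant(cfg.q_threshold)
        report.counts["ewas_tested"] = ewas.n_tested
        report.counts["ewas_q_significant"] = len(sig)
        report.counts["ewas_bonferroni"] = int(ewas.table["bonf_sig"].sum())

    with _stage(report, "regions"):
        regions = find_clusters(ds, cfg.max_gap, cfg.corr_threshold,
                                cfg.corr_type, cfg.linkage)
        regions_to_bed(regions, outdir / "regions.bed", outdir / "region_probes.tsv")
        report.files["regions"] = str(outdir / "regions.bed")
        report.counts["regions"] = len(regions)

    with _stage(report, "dmr"):
        dmr = run_dmr(regions, ds, pheno)
        dmr.write_csv(outdir / "dmr.csv")
        report.files["dmr"] = str(outdir / "dmr.csv")
        dmr_sig = dmr.significant(cfg.q_threshold)
        report.counts["dmr_q_significant"] = len(dmr_sig)
        report.counts["dmr_bonferroni"] = int(dmr.table["bonf_sig"].sum())
        hyper = (dmr_sig["direction"] == "hyper").mean() if len(dmr_sig) else np.nan
        report.counts["dmr_pct_hyper"] = round(100 * float(hyper), 1) if len(dmr_sig) else -1

    with _stage(report, "annotation"):
        gene_map = pd.DataFrame(columns=["gene_id", "distance", "ambiguous"])
        if tss is not None:
            gene_map = ann.assign_nearest_gene(regions, tss, cfg.tss_window)
            gene_map.to_csv(outdir / "gene_map.csv")
            report.files["gene_map"] = str(outdir / "gene_map.csv")
        if tracks:
            membership = ann.annotate_features(regions, tracks)
            dmr_flags = pd.Series(
                membership.index.isin(dmr_sig["region_id"]), index=membership.index
            )
            enr_rows = []
            if dmr_flags.any():
                for feature in membership.columns:
                    e = ann.fisher_enrichment(dmr_flags, membership, feature)
                    enr_rows.append({"feature": feature, **e.counts,
                                     "odds_ratio": e.odds_ratio, "p": e.p,
                                     "direction": e.direction})
            pd.DataFrame(enr_rows).to_csv(outdir / "enrichment.csv", index=False)
            report.files["enrichment"] = str(outdir / "enrichment.csv")
            dirs = ann.direction_summary(
                dmr_sig, membership.loc[membership.index.isin(dmr_sig["region_id"])]
            )
            dirs.to_csv(outdir / "direction_summary.csv")
            report.files["direction_summary"] = str(outdir / "direction_summary.csv")
        if tss is not None and len(dmr_sig):
            genes = ann.export_gene_list(gene_map, dmr_sig["region_id"],
                                         outdir / "dmr_genes.txt")
            report.files["dmr_genes"] = str(outdir / "dmr_genes.txt")
            report.counts["dmr_unique_genes"] = len(genes)

    with _stage(report, "outcomes"):
        outcome_tab = run_art_outcomes(pheno, stratify_infertility=True)
        outcome_tab.to_csv(outdir / "art_outcomes.csv", index=False)
        report.files["art_outcomes"] = str(outdir / "art_outcomes.csv")
        report.counts["outcome_models"] = len(outcome_tab)

    if cfg.run_mediation_stage and tss is not None:
        with _stage(report, "mediation"):
            region_probes = {r.region_id: list(r.probe_ids) for r in regions}
            for outcome in cfg.mediation_outcomes:
                res = run_mediation(
                    outcome, dmr.table, region_probes, ds, gene_map, pheno,
                    q_threshold=cfg.q_threshold, freq_threshold=cfg.freq_threshold,
                    bootstrap_B=cfg.bootstrap_B, seed=cfg.seed,
                )
                payload = dataclasses.asdict(res)
                path = outdir / f"mediation_{outcome}.json"
                path.write_text(json.dumps(payload, indent=2, default=float))
                report.files[f"mediation_{outcome}"] = str(path)
                report.counts[f"mediators_{outcome}"] = len(res.selected)
                if not res.empty:
                    res.edge_table().to_csv(outdir / f"paths_{outcome}.csv", index=False)
                    report.files[f"paths_{outcome}"] = str(outdir / f"paths_{outcome}.csv")
    else:
        report.skipped.append("mediation")

    with _stage(report, "subject_clustering"):
        sig = ewas.significant(cfg.q_threshold)
        if len(sig) >= 2:
            idx = ds.probe_index(sig["probe_id"])
            groups = cluster_subjects(ds.beta[idx], ds.subject_ids, cfg.n_subject_groups)
            summary = pheno.assign(group=groups).groupby("group").agg(
                n=("male_age", "size"), mean_age=("male_age", "mean"),
                live_birth_rate=("live_birth", "mean"),
            )
            summary.to_csv(outdir / "subject_groups.csv")
            report.files["subject_groups"] = str(outdir / "subject_groups.csv")
            report.counts["subject_groups"] = int(groups.nunique())
        else:
            report.skipped.append("subject_clustering")

    report.files["run_report"] = str(outdir / "run_report.json")
    report.to_json(outdir / "run_report.json")
    return report
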