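"""End-to-end pipeline: QC -> trajectory -> fertilization filter ->
re-trajectory -> differential expression -> decay -> sex analyses ->
marker scores, with every stage's table written to an output directory
and a manifest recording configuration and per-stage counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .cluster import kmedoids, select_k
from .decay import class_overlap, decay_de, maternal_set, quartile_decay
from .diffexp import compare_clusters
from .io import write_counts, write_table
from .markers import MarkerSet, local_trend, score_set
from .matrix import CountMatrix
from .qc import distance_matrix, filter_embryos, filter_genes, normalize
from .sexdiff import call_sex, dosage_report, spline_de
from .simulate import SimConfig, marker_gene_ids, simulate_cohort
from .trajectory import (
    call_fertilization,
    crosstab_order_vs_window,
    lineage_tree,
    pseudotime,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    """All pipeline parameters with their documented defaults."""

    # QC
    min_total: int = 250_000
    min_count: int = 3
    min_embryos: int = 5
    # clustering / trajectory
    k: int | None = None  # None -> silhouette selection over k_range
    k_min: int = 2
    k_max: int = 12
    # the fertilized-only re-analysis uses a finer clustering for
    # stage-resolved statistics (falls back to k-1 while the medoid MST
    # is not a simple path)
    k_refined: int = 9
    score_threshold: float = 1.0
    rank_cutoff: float = 0.25
    # differential expression
    padj: float = 0.01
    lfc: float = 1.0
    pseudocount: float = 0.1
    # maternal decay
    n_first: int = 10
    min_mean: float = 1.0
    decay_last_position: float = 0.6  # fraction along the path (major-wave onset)
    # sex analysis
    spline_df: int = 3
    smooth_window: int = 5
    smooth_order: int = 2
    # randomness
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _trajectory_stage(counts: CountMatrix, cfg: PipelineConfig, early_markers):
    nm = normalize(counts)
    d = distance_matrix(nm)
    if cfg.k is not None:
        k, scores = cfg.k, {}
    else:
        k_max = min(cfg.k_max, d.n_embryos - 1)
        k, scores = select_k(d, range(cfg.k_min, k_max + 1), seed=cfg.seed)
    clustering = kmedoids(d, k, seed=cfg.seed)
    tree = lineage_tree(nm, clustering)
    order = pseudotime(tree, nm, early_markers)
    return nm, d, clustering, tree, order, scores


def refined_trajectory(counts: CountMatrix, early_markers, k: int = 9, seed: int = 0):
    """Fine-grained trajectory for stage-resolved statistics.

    Clusters at ``k`` and reduces ``k`` stepwise while the medoid MST is
    not a simple path (small side groups can otherwise branch the tree).
    Returns (nm, clustering, tree, order, k_used).
    """
    nm = normalize(counts)
    d = distance_matrix(nm)
    k = min(k, d.n_embryos)
    last_error = None
    while k >= 2:
        clustering = kmedoids(d, k, seed=seed)
        tree = lineage_tree(nm, clustering)
        try:
            order = pseudotime(tree, nm, early_markers)
        except ValueError as exc:
            last_error = exc
            k -= 1
            continue
        return nm, clustering, tree, order, k
    raise ValueError(f"no path-shaped lineage tree found down to k=2: {last_error}")


def run_pipeline(
    counts: CountMatrix,
    metadata: pd.DataFrame,
    annotation: pd.DataFrame,
    outdir,
    cfg: PipelineConfig | None = None,
    early_markers=None,
    minor_set: MarkerSet | None = None,
    major_set: MarkerSet | None = None,
    female_marker: str | None = None,
    male_marker: str | None = None,
) -> dict:
    """Run the full analysis and write all tables under ``outdir``.

    ``annotation`` must map gene_id -> chromosome (and, for simulated
    cohorts, the generating program, from which default marker sets are
    derived when none are given).  Returns the manifest dictionary.
    """
    cfg = cfg or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": cfg.to_dict(), "stages": {}}
    stage = "setup"
    try:
        if early_markers is None or female_marker is None or male_marker is None:
            if "program" not in annotation.columns:
                raise ValueError(
                    "marker genes not given and annotation has no program column"
                )
            early_markers = early_markers or marker_gene_ids(annotation, "zygotic_minor")
            female = marker_gene_ids(annotation, "marker_female")
            male = marker_gene_ids(annotation, "marker_male")
            female_marker = female_marker or (female[0] if female else None)
            male_marker = male_marker or (male[0] if male else None)
        if minor_set is None and "program" in annotation.columns:
            minor_set = MarkerSet("minor", tuple(marker_gene_ids(annotation, "zygotic_minor")))
        if major_set is None and "program" in annotation.columns:
            major_set = MarkerSet("major", tuple(marker_gene_ids(annotation, "zygotic_major")))

        stage = "qc"
        counts, removed_embryos = filter_embryos(counts, cfg.min_total)
        counts, removed_genes = filter_genes(counts, cfg.min_count, cfg.min_embryos)
        manifest["stages"]["qc"] = {
            "embryos_removed": len(removed_embryos),
            "genes_removed": len(removed_genes),
            "embryos_kept": counts.n_embryos,
            "genes_kept": counts.n_genes,
        }
        qc_report = pd.DataFrame(
            {"embryo_id": counts.embryo_ids, "total": counts.totals().to_numpy(), "kept": True}
        )
        write_table(qc_report, outdir / "qc_report.tsv")

        stage = "trajectory"
        nm, d, clustering, tree, order, sil = _trajectory_stage(counts, cfg, early_markers)
        manifest["stages"]["trajectory"] = {
            "k": clustering.k,
            "silhouette": sil,
            "path": [int(c) for c in order.path],
        }

        stage = "fertilization"
        fertility = call_fertilization(
            nm, order, early_markers, cfg.score_threshold, cfg.rank_cutoff
        )
        write_table(fertility.reset_index(drop=True), outdir / "fertility.tsv")
        fertilized = list(fertility.index[fertility["status"] != "unfertilized"])
        manifest["stages"]["fertilization"] = {
            "unfertilized": int((fertility["status"] == "unfertilized").sum()),
            "indeterminate": int((fertility["status"] == "indeterminate").sum()),
        }

        stage = "re-trajectory"
        counts_f = CountMatrix(counts.values[fertilized])
        nm, clustering, tree, order, k_used = refined_trajectory(
            counts_f, early_markers, k=cfg.k_refined, seed=cfg.seed
        )
        order_table = order.order.copy()
        write_table(order_table.reset_index(drop=True), outdir / "order.tsv")
        manifest["stages"]["re_trajectory"] = {
            "embryos": counts_f.n_embryos,
            "k": k_used,
            "path": [int(c) for c in order.path],
        }

        stage = "crosstab"
        crosstab = crosstab_order_vs_window(order, metadata)
        write_table(crosstab.reset_index(), outdir / "crosstab.tsv")

        stage = "differential-expression"
        de_counts = {}
        for a, b in zip(order.path[:-1], order.path[1:]):
            de = compare_clusters(
                nm, clustering, a, b, cfg.padj, cfg.lfc, cfg.pseudocount
            )
            write_table(
                de.table.reset_index(drop=True), outdir / f"de_{a}_vs_{b}.tsv"
            )
            de_counts[f"{a}_vs_{b}"] = len(de.significant_genes)
        manifest["stages"]["differential_expression"] = de_counts

        stage = "decay"
        maternal = maternal_set(nm, order, cfg.n_first, cfg.min_mean)
        first_cluster = order.path[0]
        last_idx = max(1, int(round(cfg.decay_last_position * (len(order.path) - 1))))
        last_cluster = order.path[last_idx]
        degraded, decay_full = decay_de(
            nm, clustering, first_cluster, last_cluster, maternal, cfg.padj, -cfg.lfc
        )
        write_table(pd.DataFrame({"gene_id": maternal}), outdir / "maternal.tsv")
        write_table(degraded.reset_index(drop=True), outdir / "degraded.tsv")
        manifest["stages"]["decay"] = {
            "maternal": len(maternal),
            "degraded": len(degraded),
            "first_cluster": int(first_cluster),
            "last_cluster": int(last_cluster),
        }
        if len(degraded) >= 4:
            report = quartile_decay(
                nm, clustering, list(degraded.index), first_cluster, last_cluster, maternal
            )
            write_table(
                report.cluster_means.reset_index(), outdir / "quartiles.tsv"
            )
            write_table(
                report.ratios.rename_axis("quartile").reset_index(), outdir / "ratios.tsv"
            )
        if "program" in annotation.columns:
            overlap = class_overlap(
                list(degraded.index), annotation["program"]
            )
            write_table(overlap, outdir / "class_overlap.tsv")

        stage = "sex"
        if female_marker is None or male_marker is None:
            raise ValueError("female/male marker genes are required for sexing")
        sex_calls = call_sex(nm, female_marker, male_marker)
        write_table(sex_calls.table.reset_index(drop=True), outdir / "sexcalls.tsv")
        position = {cl: i for i, cl in enumerate(order.path)}
        time = clustering.labels.map(position)
        # the spline cannot carry more df than the sexed embryos span
        sexed = sex_calls.sexed_embryos()
        n_timepoints = time[time.index.isin(sexed)].nunique()
        df = min(cfg.spline_df, max(1, n_timepoints - 1))
        sde = spline_de(nm, time, sex_calls.calls, df, cfg.padj)
        write_table(sde.table.reset_index(drop=True), outdir / "spline_de.tsv")
        manifest["stages"]["sex"] = {
            "female": int((sex_calls.calls == "female").sum()),
            "male": int((sex_calls.calls == "male").sum()),
            "undetermined": int((sex_calls.calls == "undetermined").sum()),
            "spline_de_significant": len(sde.significant_genes),
        }

        stage = "dosage"
        if "chromosome" not in annotation.columns:
            raise ValueError("annotation lacks the chromosome column needed for dosage")
        dosage = dosage_report(
            nm,
            sex_calls,
            clustering,
            maternal,
            annotation["chromosome"],
            exclude=(female_marker, male_marker),
        )
        # order rows along the trajectory path
        dosage = dosage.loc[[c for c in order.path if c in dosage.index]]
        write_table(dosage.reset_index(drop=True), outdir / "dosage.tsv")

        stage = "marker-scores"
        for mset in (minor_set, major_set):
            if mset is None:
                continue
            scores = score_set(nm, order, mset)
            trended = local_trend(scores) if len(scores) >= 10 else scores
            write_table(trended.reset_index(drop=True), outdir / f"score_{mset.name}.tsv")

    except Exception as exc:  # noqa: BLE001 - stage attribution is the contract
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def simulate_inputs(sim_cfg: SimConfig, outdir=None):
    """Simulate a cohort and (optionally) write its three input files."""
    counts, annotation, truth = simulate_cohort(sim_cfg)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_counts(counts, outdir / "counts.mtx", fmt="mtx")
        write_table(
            annotation[["gene_id", "chromosome", "program"]], outdir / "annotation.tsv"
        )
        write_table(
            truth[
                [
                    "embryo_id",
                    "age_min",
                    "sex",
                    "fertilized",
                    "collection_window",
                    "withheld",
                    "depth",
                ]
            ],
            outdir / "truth.tsv",
        )
    return counts, annotation, truth
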