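"""End-to-end pipeline orchestration with a single config and provenance.

``run_pipeline`` executes the stages in dependency order — simulate,
footprint, deviation, eregulon, grn, overlap — writing deterministic
delimited outputs plus a provenance record (stage, parameters, seed, output
digests) so that two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .deviation import compute_deviation_zscores, rank_differential_motifs
from .eregulon import ERegulon, filter_eregulons, make_pseudobulks, \
    regulon_specificity_score, score_cells
from .footprints import (assign_nearest_gene, extract_profiles,
                         kmeans_cluster_profiles, scan_motif_instances,
                         score_differential_clusters)
from .formats import GenomicInterval, write_bed, write_bedgraph, write_fasta
from .grn import (PerturbationSpec, build_base_grn, fit_grn, log_normalize,
                  simulate_perturbation, transition_vectors)
from .overlap import (hypergeometric_overlap, map_orthologs,
                      monte_carlo_multiset_overlap, threshold_de, wilcoxon_de)
from .synthetic import SimulationConfig


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the analysis' standard settings."""

    seed: int = 0
    outdir: str = "regshift_run"
    stages: tuple[str, ...] = ("simulate", "footprint", "deviation",
                               "eregulon", "grn", "overlap")
    # simulate
    n_chrom: int = 2
    chrom_length: int = 50_000
    n_seqlets: int = 200
    differential_fraction: float = 0.25
    delta: float = 2.0
    noise_sd: float = 0.1
    n_cells_per_group: int = 100
    # footprint
    flank: int = 30
    k: int = 4
    n_perm: int = 999
    # deviation
    n_background: int = 50
    n_bins: int = 10
    n_decoy_motifs: int = 10
    # eregulon
    pseudobulk_size: int = 5
    pseudobulk_draws: int = 50
    correlation_cutoff: float = 0.5
    top_frac: float = 0.05
    # grn
    n_tfs: int = 10
    n_target_genes: int = 100
    p_cutoff: float = 0.001
    max_edges: int = 2000
    oe_factor: float = 1.5
    n_propagation: int = 3
    # overlap / DE
    p_adj_max: float = 0.05
    lfc_min: float = 0.25
    mc_iterations: int = 2000

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0 < self.top_frac <= 1:
            raise ValueError("top_frac must lie in (0, 1]")
        if self.pseudobulk_size < 1:
            raise ValueError("pseudobulk_size must be >= 1")
        if self.n_perm < 1 or self.mc_iterations < 1:
            raise ValueError("n_perm and mc_iterations must be >= 1")
        unknown = set(self.stages) - {"simulate", "footprint", "deviation",
                                      "eregulon", "grn", "overlap"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage sub-seed derived from the global seed."""
        return (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["stages"] = list(data["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.8g")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages; returns the run directory.

    Every output file receives one provenance entry; identical configs
    produce byte-identical outputs. A stage failure halts the run with the
    failing stage named; outputs of completed stages are retained.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance: list[dict] = []
    state: dict = {}

    def record(stage: str, params: dict, outputs: list[Path]) -> None:
        for path in outputs:
            provenance.append({
                "stage": stage, "seed": config.stage_seed(stage),
                "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in sorted(params.items())},
                "output": path.name, "sha256": _digest(path),
            })

    for stage in config.stages:
        try:
            outputs = _STAGES[stage](config, outdir, state)
        except Exception as exc:  # halt with the failing stage named
            raise PipelineError(stage, exc) from exc
        record(stage, {"seed": config.stage_seed(stage)}, outputs)

    with open(outdir / "provenance.json", "w") as fh:
        json.dump({"config": {**asdict(config), "stages": list(config.stages)},
                   "records": provenance}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


# ---------------------------------------------------------------------------
# Stage implementations

def _sim_config(config: PipelineConfig, stage: str) -> SimulationConfig:
    return SimulationConfig(
        seed=config.stage_seed(stage), n_chrom=config.n_chrom,
        chrom_length=config.chrom_length, noise_sd=config.noise_sd,
        n_cells_per_group=config.n_cells_per_group)


def _stage_simulate(config: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    sim = _sim_config(config, "simulate")
    motif = synthetic.ap1_motif()
    genome, truth = synthetic.generate_genome(sim, [motif], config.n_seqlets)
    tracks, peaks, truth = synthetic.generate_contribution_tracks(
        genome, truth, sim, differential_fraction=config.differential_fraction,
        delta=config.delta)
    motif_peaks = {p.name for p in peaks if p.name.startswith("peak_s")}
    adata = synthetic.generate_accessibility_matrix(
        peaks, motif_peaks, genome, sim, group_effect=1.5)
    grn_spec = synthetic.make_planted_grn(
        n_tfs=config.n_tfs, n_targets=config.n_target_genes,
        seed=config.stage_seed("simulate"))
    expr = synthetic.generate_expression_data(grn_spec, sim)
    state.update(genome=genome, truth=truth, tracks=tracks, peaks=peaks,
                 motif=motif, accessibility=adata, expression=expr)

    outputs = []
    write_fasta(genome, outdir / "genome.fa")
    outputs.append(outdir / "genome.fa")
    for cond, track in tracks.items():
        path = outdir / f"contribution_{cond}.bedGraph"
        write_bedgraph(track, path)
        outputs.append(path)
    write_bed(peaks, outdir / "peaks.bed")
    outputs.append(outdir / "peaks.bed")
    _write_tsv(truth.seqlets, outdir / "truth_seqlets.tsv", index=False)
    outputs.append(outdir / "truth_seqlets.tsv")
    _write_tsv(grn_spec, outdir / "truth_grn_edges.tsv", index=False)
    outputs.append(outdir / "truth_grn_edges.tsv")
    return outputs


def _stage_footprint(config: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    seed = config.stage_seed("footprint")
    seqlets = scan_motif_instances(state["genome"], state["motif"],
                                   mode="consensus_exact", within=state["peaks"])
    matrix = extract_profiles(state["tracks"], seqlets, flank=config.flank)
    result = kmeans_cluster_profiles(matrix, k=config.k, seed=seed)
    conds = matrix.conditions
    result = score_differential_clusters(result, matrix, (conds[-1], conds[0]),
                                         n_perm=config.n_perm, seed=seed)
    top = int(result.differential["delta"].idxmax())
    member = result.assignments == top
    regions = [GenomicInterval(r.chrom, r.start, r.end, r.strand)
               for r in matrix.seqlets.itertuples()]
    # simple synthetic gene annotation: one gene every 5 kb
    genes = []
    for chrom, seq in sorted(state["genome"].items()):
        for i, start in enumerate(range(1000, len(seq) - 1500, 5000)):
            genes.append(GenomicInterval(chrom, start, start + 500, "+",
                                         name=f"GENE_{chrom}_{i:03d}"))
    nearest = assign_nearest_gene([r for r, m in zip(regions, member) if m], genes)
    state.update(profiles=matrix, clusters=result, top_cluster=top)

    summary = result.differential.join(
        result.cluster_means.drop(columns="size"))
    _write_tsv(summary, outdir / "footprint_clusters.tsv")
    _write_tsv(nearest, outdir / "footprint_top_cluster_genes.tsv", index=False)
    assigned = matrix.seqlets.assign(cluster=result.assignments)
    _write_tsv(assigned, outdir / "footprint_seqlets.tsv", index=False)
    return [outdir / "footprint_clusters.tsv",
            outdir / "footprint_top_cluster_genes.tsv",
            outdir / "footprint_seqlets.tsv"]


def _stage_deviation(config: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    seed = config.stage_seed("deviation")
    adata = state["accessibility"]
    rng = np.random.default_rng(seed)
    bearing = adata.var["motif_bearing"].to_numpy()
    annotations = pd.DataFrame({"AP1": bearing.astype(int)}, index=adata.var_names)
    n_member = max(int(bearing.sum()), 1)
    for j in range(config.n_decoy_motifs):
        idx = rng.choice(adata.n_vars, size=n_member, replace=False)
        col = np.zeros(adata.n_vars, dtype=int)
        col[idx] = 1
        annotations[f"DECOY{j:02d}"] = col
    dev = compute_deviation_zscores(
        adata.X, annotations, gc=adata.var["gc"].to_numpy(),
        mean_accessibility=adata.var["mean_accessibility"].to_numpy(),
        n_background=config.n_background, n_bins=config.n_bins, seed=seed,
        cell_names=adata.obs_names)
    table = rank_differential_motifs(dev, adata.obs["group"])
    state["deviation_table"] = table
    _write_tsv(dev.z, outdir / "deviation_zscores.tsv")
    _write_tsv(table, outdir / "deviation_ranked_motifs.tsv", index=False)
    return [outdir / "deviation_zscores.tsv", outdir / "deviation_ranked_motifs.tsv"]


def _stage_eregulon(config: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    seed = config.stage_seed("eregulon")
    sim = _sim_config(config, "eregulon")
    data = synthetic.generate_regulon_dataset(sim)
    pbs, _ = make_pseudobulks(data.metadata, data.expression,
                              accessibility=data.accessibility,
                              size=config.pseudobulk_size,
                              n_draws=config.pseudobulk_draws, seed=seed)
    regs = [ERegulon(tf=tf, target_regions=regions)
            for tf, regions in sorted(data.regulons.items())]
    regs = filter_eregulons(regs, pbs, cutoff=config.correlation_cutoff,
                            top_frac=config.top_frac)
    enrich = score_cells(data.accessibility,
                         {er.tf: set(er.target_regions) for er in regs},
                         top_frac=config.top_frac)
    rss = regulon_specificity_score(enrich, data.metadata["condition"])
    table = pd.DataFrame(
        [{"tf": er.tf, "r": np.nan if er.r is None else er.r,
          "class": er.classification, "reason": er.drop_reason or ""}
         for er in regs])
    state["eregulons"] = regs
    _write_tsv(table, outdir / "eregulon_classification.tsv", index=False)
    _write_tsv(rss, outdir / "eregulon_rss.tsv", index=False)
    return [outdir / "eregulon_classification.tsv", outdir / "eregulon_rss.tsv"]


def _stage_grn(config: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    expr_sim = state["expression"]
    adata = expr_sim.human
    logx = pd.DataFrame(log_normalize(adata.X), index=adata.obs_names,
                        columns=adata.var_names)
    spec_edges = expr_sim.truth.grn_edges
    base = spec_edges.rename(columns={"target": "gene"})[["tf", "gene"]]
    outputs = []
    models = {}
    for cond in ["control", "disease"]:
        cells = adata.obs["condition"] == cond
        model = fit_grn(logx[cells.values], base, condition=cond,
                        p_cutoff=config.p_cutoff, max_edges=config.max_edges)
        models[cond] = model
        path = outdir / f"grn_edges_{cond}.tsv"
        _write_tsv(model.edges, path, index=False)
        outputs.append(path)
    labels = adata.obs["condition"].to_numpy()
    ko = simulate_perturbation(
        models["disease"], logx,
        PerturbationSpec(tf=expr_sim.driver, mode="KO",
                         n_propagation=config.n_propagation))
    ko = transition_vectors(ko, logx, labels, "control")
    oe = simulate_perturbation(
        models["control"], logx,
        PerturbationSpec(tf=expr_sim.driver, mode="OE",
                         oe_factor=config.oe_factor,
                         n_propagation=config.n_propagation))
    oe = transition_vectors(oe, logx, labels, "disease")
    scores = pd.DataFrame({
        "condition": labels,
        "ko_toward_control": ko.transition_scores,
        "oe_toward_disease": oe.transition_scores,
    })
    state.update(grn_models=models, ko=ko, oe=oe, grn_scores=scores)
    _write_tsv(scores, outdir / "perturbation_scores.tsv")
    outputs.append(outdir / "perturbation_scores.tsv")
    return outputs


def _stage_overlap(config: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    seed = config.stage_seed("overlap")
    expr_sim = state["expression"]
    results = {}
    for species, adata in [("human", expr_sim.human), ("mouse", expr_sim.mouse)]:
        logx = pd.DataFrame(log_normalize(adata.X), index=adata.obs_names,
                            columns=adata.var_names)
        labels = adata.obs["condition"].to_numpy()
        disease_label = "disease" if species == "human" else "TG"
        groups = np.where(labels == disease_label, "disease", "control")
        de = wilcoxon_de(logx, groups, group_order=["disease", "control"])
        results[species] = de
        _write_tsv(de, outdir / f"de_{species}.tsv")
    up_h = threshold_de(results["human"], config.p_adj_max, config.lfc_min, "up")
    up_m = threshold_de(results["mouse"], config.p_adj_max, config.lfc_min, "up")
    mapped_m, unmapped = map_orthologs(up_m, expr_sim.orthologs,
                                       fallback_case_rule=True)
    universe = set(results["human"].index) & {
        s.upper() for s in results["mouse"].index}
    hyper = hypergeometric_overlap(up_h & universe, mapped_m & universe, universe)
    mc = monte_carlo_multiset_overlap([up_h & universe, mapped_m & universe],
                                      universe, B=config.mc_iterations, seed=seed)
    report = {
        "up_human": len(up_h), "up_mouse": len(up_m), "unmapped": len(unmapped),
        "universe": hyper.universe_size, "overlap": hyper.observed_overlap,
        "hypergeometric_p": hyper.p, "monte_carlo_p": mc.p,
        "mc_iterations": mc.iterations,
    }
    state["overlap_report"] = report
    with open(outdir / "overlap_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return [outdir / "de_human.tsv", outdir / "de_mouse.tsv",
            outdir / "overlap_report.json"]


_STAGES = {
    "simulate": _stage_simulate,
    "footprint": _stage_footprint,
    "deviation": _stage_deviation,
    "eregulon": _stage_eregulon,
    "grn": _stage_grn,
    "overlap": _stage_overlap,
}
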