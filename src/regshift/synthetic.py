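"""Seeded synthetic data with planted ground truth.

Emulates the data structure of a lung single-cell multiome / bulk ATAC
study contrasting a disease condition with healthy controls:

* random genomes with planted AP-1 (TGAGTCA) motif instances,
* base-resolution contribution-score tracks in which a chosen subset of
  planted seqlets carries condition-specific elevated contribution,
* cell x peak accessibility counts with a group-specific effect on
  motif-bearing peaks,
* cell x gene expression counts for two conditions and two species-like
  symbol namespaces, driven by a planted TF -> target regulatory network
  with a designated disease-driver TF elevated in the disease group.

Every generator draws from a numpy Generator derived deterministically
from ``SimulationConfig.seed``, so a config fully determines all outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd

from .formats import ContributionTrack, GenomicInterval
from .motifs import IUPAC, BASE_INDEX, MotifModel, reverse_complement

AP1_CONSENSUS = "TGAGTCA"


def ap1_motif() -> MotifModel:
    """The AP-1 (FOS:JUN dimer) consensus element as a motif model."""
    return MotifModel.from_consensus("AP1", AP1_CONSENSUS)


@dataclass
class SimulationConfig:
    """Parameters shared by all synthetic generators; ``seed`` fixes everything."""

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 50_000
    gc_fraction: float = 0.41          # human-like background GC
    n_conditions: int = 2
    noise_sd: float = 0.1              # contribution-track noise scale
    seqlet_contribution: float = 1.0   # mean contribution at planted seqlets
    n_cells_per_group: int = 100
    mean_depth: float = 2_000.0        # mean ATAC counts per cell
    nb_dispersion: float = 0.1         # scRNA overdispersion (var = m + disp*m^2)
    expression_noise_sd: float = 0.3   # latent expression noise
    expression_scale: float = 10.0     # counts per unit latent expression
    tf_sd: float = 1.0                 # per-cell latent variability of root TFs
    driver_delta: float = 1.0          # latent elevation of the driver TF in disease

    def __post_init__(self) -> None:
        for name in ("n_chrom", "chrom_length", "n_conditions",
                     "n_cells_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic sub-generator for a named output stream."""
        import zlib
        sub = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence((self.seed, sub)))

    @property
    def condition_names(self) -> list[str]:
        if self.n_conditions == 1:
            return ["control"]
        if self.n_conditions == 2:
            return ["control", "disease"]
        return ["control"] + [f"disease{i}" for i in range(1, self.n_conditions)]


@dataclass
class PlantingTruth:
    """Ground-truth manifest for planted features, carried across stages."""

    seqlets: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "strand", "motif", "differential"]))
    de_genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene", "group", "latent_shift"]))
    grn_edges: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["tf", "target", "weight"]))


# ---------------------------------------------------------------------------
# Genome

def _sample_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)


def _realize_consensus(rng: np.random.Generator, motif: MotifModel) -> str:
    """A concrete sequence matching the consensus (ambiguity resolved by PFM weight)."""
    letters = []
    for j, c in enumerate(motif.consensus):
        allowed = IUPAC[c]
        weights = np.array([motif.pfm[BASE_INDEX[b], j] for b in allowed])
        if weights.sum() <= 0:
            weights = np.ones(len(allowed))
        letters.append(allowed[rng.choice(len(allowed), p=weights / weights.sum())])
    return "".join(letters)


def generate_genome(config: SimulationConfig, motifs: list[MotifModel],
                    n_plant_per_motif: int, margin: int = 100,
                    min_separation: int = 150):
    """Random genome with non-overlapping planted motif instances.

    Planted instances keep ``margin`` bases clear of chromosome ends and at
    least ``min_separation`` bases between instance starts, so downstream
    flank extraction never truncates and planted profile windows stay clean.

    Returns ``(genome, truth)`` where genome maps chromosome name to
    sequence and ``truth.seqlets`` records every planted instance.
    """
    max_len = max((m.length for m in motifs), default=10)
    if config.chrom_length <= 2 * (max_len + margin):
        raise ValueError("chromosome length too small for planting margins")
    rng = config.rng("genome")
    chroms = [f"chr{i + 1}" for i in range(config.n_chrom)]
    arrays = {c: _sample_background(rng, config.chrom_length, config.gc_fraction)
              for c in chroms}

    records = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    total = n_plant_per_motif * len(motifs)
    capacity = config.n_chrom * max(
        0, (config.chrom_length - 2 * margin) // max(min_separation, max_len))
    if total > capacity:
        raise ValueError(
            f"cannot place {total} instances: capacity ~{capacity} at "
            f"min_separation={min_separation}")
    for motif in motifs:
        placed = 0
        attempts = 0
        while placed < n_plant_per_motif:
            attempts += 1
            if attempts > 200 * max(n_plant_per_motif, 1):
                raise ValueError(
                    f"infeasible planting density for motif {motif.name}")
            chrom = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(margin, config.chrom_length - margin - motif.length))
            end = start + motif.length
            if any(start < e + min_separation and s - min_separation < end
                   for s, e in occupied[chrom]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            seq = _realize_consensus(rng, motif)
            genomic = seq if strand == "+" else reverse_complement(seq)
            arrays[chrom][start:end] = np.frombuffer(genomic.encode(), dtype="S1")
            occupied[chrom].append((start, end))
            records.append({"chrom": chrom, "start": start, "end": end,
                            "strand": strand, "motif": motif.name,
                            "differential": False})
            placed += 1

    genome = {c: arrays[c].tobytes().decode() for c in chroms}
    seqlets = pd.DataFrame(records, columns=["chrom", "start", "end", "strand",
                                             "motif", "differential"])
    seqlets = seqlets.sort_values(["chrom", "start"]).reset_index(drop=True)
    return genome, PlantingTruth(seqlets=seqlets)


# ---------------------------------------------------------------------------
# Contribution tracks

def generate_contribution_tracks(genome: dict[str, str], truth: PlantingTruth,
                                 config: SimulationConfig,
                                 differential_fraction: float = 0.25,
                                 delta: float = 2.0,
                                 peak_halfwidth: int = 100,
                                 n_decoy_peaks: int | None = None):
    """Per-condition contribution tracks with a planted differential seqlet subset.

    Background positions get independent Normal(0, noise_sd) noise per
    condition. Every planted seqlet receives positive contribution in all
    conditions; a random ``differential_fraction`` of seqlets is additionally
    multiplied by ``delta`` in the non-control ("disease") conditions.

    Returns ``(tracks, peaks, truth)``; tracks maps condition name to a
    :class:`ContributionTrack`, peaks are seqlet neighbourhoods plus decoys.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if not 0.0 <= differential_fraction <= 1.0:
        raise ValueError("differential_fraction must lie in [0, 1]")
    seqlets = truth.seqlets
    if len(seqlets) == 0 and differential_fraction > 0:
        raise ValueError("no planted seqlets to mark differential")
    rng = config.rng("contribution")
    chrom_lengths = {c: len(s) for c, s in genome.items()}

    n_diff = int(round(differential_fraction * len(seqlets)))
    diff_idx = rng.choice(len(seqlets), size=n_diff, replace=False) if n_diff else []
    differential = np.zeros(len(seqlets), dtype=bool)
    differential[list(diff_idx)] = True
    seqlets = seqlets.assign(differential=differential)

    tracks: dict[str, ContributionTrack] = {}
    for cond in config.condition_names:
        values = {c: rng.normal(0.0, config.noise_sd, size=n)
                  for c, n in chrom_lengths.items()}
        for row in seqlets.itertuples():
            amp = config.seqlet_contribution
            if cond != "control" and row.differential:
                amp *= delta
            values[row.chrom][row.start:row.end] += amp
        tracks[cond] = ContributionTrack(values)

    for cond in config.condition_names:
        col = f"delta_{cond}"
        seqlets[col] = np.where(
            differential & (cond != "control"), float(delta), 1.0)

    peaks: list[GenomicInterval] = []
    for i, row in enumerate(seqlets.itertuples()):
        start = max(0, row.start - peak_halfwidth)
        end = min(chrom_lengths[row.chrom], row.end + peak_halfwidth)
        peaks.append(GenomicInterval(row.chrom, start, end, name=f"peak_s{i:05d}"))
    n_decoys = len(seqlets) if n_decoy_peaks is None else n_decoy_peaks
    width = 2 * peak_halfwidth
    chroms = sorted(chrom_lengths)
    placed = 0
    attempts = 0
    while placed < n_decoys and attempts < 200 * max(n_decoys, 1):
        attempts += 1
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, chrom_lengths[chrom] - width))
        cand = GenomicInterval(chrom, start, start + width,
                               name=f"peak_d{placed:05d}")
        if any(cand.overlaps(p) for p in peaks):
            continue
        peaks.append(cand)
        placed += 1
    peaks.sort(key=lambda p: (p.chrom, p.start))

    new_truth = PlantingTruth(seqlets=seqlets.reset_index(drop=True),
                              de_genes=truth.de_genes, grn_edges=truth.grn_edges)
    return tracks, peaks, new_truth


# ---------------------------------------------------------------------------
# Accessibility counts

def gc_fraction_of(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def generate_accessibility_matrix(peaks: list[GenomicInterval],
                                  motif_bearing: set[str],
                                  genome: dict[str, str],
                                  config: SimulationConfig,
                                  group_effect: float = 1.5,
                                  groups: tuple[str, ...] = ("control", "disease")):
    """Cell x peak Poisson counts with a group effect on motif-bearing peaks.

    Per-peak weights are Gamma distributed; in the last (affected) group the
    weights of motif-bearing peaks are multiplied by ``group_effect``. Counts
    are Poisson(depth_cell * weight / group weight total), so a cell's total
    concentrates around its drawn depth. Peak GC content is computed from the
    genome and stored in ``var``.
    """
    if len(peaks) == 0:
        raise ValueError("zero peaks")
    if config.n_cells_per_group == 0:
        raise ValueError("zero cells")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if group_effect <= 0:
        raise ValueError("group_effect must be > 0")
    rng = config.rng("accessibility")
    n_peaks = len(peaks)
    base_weight = rng.gamma(shape=2.0, scale=0.5, size=n_peaks)
    bearing = np.array([p.name in motif_bearing for p in peaks])
    affected = groups[-1]

    obs_rows, counts = [], []
    depths_all = []
    for group in groups:
        w = base_weight.copy()
        if group == affected:
            w[bearing] *= group_effect
        probs = w / w.sum()
        depths = rng.lognormal(np.log(config.mean_depth), 0.3,
                               size=config.n_cells_per_group)
        lam = depths[:, None] * probs[None, :]
        counts.append(rng.poisson(lam))
        depths_all.append(depths)
        obs_rows += [{"group": group, "cell_type": "EC"}] * config.n_cells_per_group

    X = np.vstack(counts)
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"cell_{i:05d}" for i in range(len(obs))]
    obs["depth"] = np.concatenate(depths_all)
    var = pd.DataFrame({
        "chrom": [p.chrom for p in peaks],
        "start": [p.start for p in peaks],
        "end": [p.end for p in peaks],
        "gc": [gc_fraction_of(genome[p.chrom][p.start:p.end]) for p in peaks],
        "motif_bearing": bearing,
    }, index=[p.name for p in peaks])
    adata = ad.AnnData(X=X.astype(np.int64), obs=obs, var=var)
    adata.var["mean_accessibility"] = np.asarray(X.mean(axis=0)).ravel()
    return adata


# ---------------------------------------------------------------------------
# Planted GRN and expression counts

def make_planted_grn(n_tfs: int = 10, n_targets: int = 200,
                     driver: str = "FOSL2", seed: int = 0,
                     parents_per_target: tuple[int, int] = (1, 3),
                     weight_range: tuple[float, float] = (0.2, 1.0)) -> pd.DataFrame:
    """A random acyclic TF -> target edge list with signed weights.

    The first TF is the disease-driver symbol (default FOSL2); remaining TFs
    are named TFX2..TFXn and targets TGT0001.. so the Title-case/UPPER-case
    namespace rule maps them cleanly between species-like symbol sets.
    """
    rng = np.random.default_rng(seed)
    tfs = [driver] + [f"TFX{i}" for i in range(2, n_tfs + 1)]
    targets = [f"TGT{i:04d}" for i in range(1, n_targets + 1)]
    rows = []
    for t in targets:
        k = rng.integers(parents_per_target[0], parents_per_target[1] + 1)
        for tf in rng.choice(tfs, size=k, replace=False):
            w = rng.uniform(*weight_range) * (1 if rng.random() < 0.7 else -1)
            rows.append({"tf": tf, "target": t, "weight": float(w)})
    return pd.DataFrame(rows)


def generate_expression_data(grn_spec: pd.DataFrame, config: SimulationConfig,
                             driver: str | None = None,
                             n_background_genes: int = 50):
    """Expression counts for two conditions in two species-like namespaces.

    Latent expression follows a linear structural-equation model: root TFs
    vary around per-gene baselines, targets add the weighted deviations of
    their regulators plus Gaussian noise. The designated driver TF (first
    TF of the edge list if not given) is elevated by ``config.driver_delta`` in
    the disease group, so its targets shift by weight x delta. Counts are
    negative binomial around ``latent * expression_scale``.

    Returns an ``ExpressionSim`` with human-like (UPPER) and mouse-like
    (Title-case) AnnData objects, DE truth and an ortholog table.
    """
    g = nx.DiGraph()
    g.add_edges_from(zip(grn_spec["tf"], grn_spec["target"]))
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("planted GRN must be acyclic")
    tfs = sorted(set(grn_spec["tf"]))
    if driver is None:
        # FOSL2 when present (the planted disease driver), else first TF listed
        driver = "FOSL2" if "FOSL2" in tfs else grn_spec["tf"].iloc[0]
    if driver not in tfs:
        raise ValueError(f"driver TF {driver!r} absent from GRN spec")
    genes = sorted(set(grn_spec["tf"]) | set(grn_spec["target"]))
    genes += [f"BGD{i:04d}" for i in range(1, n_background_genes + 1)]
    order = [n for n in nx.topological_sort(g)]
    parents = {t: [] for t in genes}
    for row in grn_spec.itertuples():
        parents[row.target].append((row.tf, row.weight))

    rng = config.rng("expression")
    base = pd.Series(rng.uniform(1.0, 3.0, size=len(genes)), index=genes)
    tf_sd = config.tf_sd

    def _simulate(sub_rng: np.random.Generator, group: str, n_cells: int) -> np.ndarray:
        latent = np.zeros((n_cells, len(genes)))
        gi = {gname: j for j, gname in enumerate(genes)}
        for gname in genes:
            if gname not in order or g.in_degree(gname) == 0:
                mu = base[gname] + (config.driver_delta
                                    if gname == driver and group == "disease" else 0.0)
                latent[:, gi[gname]] = sub_rng.normal(mu, tf_sd, size=n_cells)
        for gname in order:
            if g.in_degree(gname) == 0:
                continue
            x = np.full(n_cells, base[gname])
            for p, w in parents[gname]:
                x = x + w * (latent[:, gi[p]] - base[p])
            latent[:, gi[gname]] = x + sub_rng.normal(
                0.0, config.expression_noise_sd, size=n_cells)
        mean = np.clip(latent, 0.05, None) * config.expression_scale
        depth_factor = sub_rng.lognormal(0.0, 0.2, size=n_cells)[:, None]
        mean = mean * depth_factor
        r = 1.0 / config.nb_dispersion
        return sub_rng.negative_binomial(r, r / (r + mean)).astype(np.int64)

    def _build(space_rng, group_names, namespace):
        blocks, obs_rows = [], []
        for group in group_names:
            label = "disease" if group in ("disease", "TG") else "control"
            blocks.append(_simulate(space_rng, label, config.n_cells_per_group))
            obs_rows += [{"condition": group, "cell_type": "EC"}] * config.n_cells_per_group
        X = np.vstack(blocks)
        names = genes if namespace == "human" else [s.title() for s in genes]
        obs = pd.DataFrame(obs_rows)
        obs.index = [f"{namespace}_cell_{i:05d}" for i in range(len(obs))]
        return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=names))

    adata_human = _build(config.rng("expression-human"), ["control", "disease"], "human")
    adata_mouse = _build(config.rng("expression-mouse"), ["WT", "TG"], "mouse")

    de_rows = [{"gene": driver, "group": "disease",
                "latent_shift": config.driver_delta}]
    for row in grn_spec[grn_spec["tf"] == driver].itertuples():
        de_rows.append({"gene": row.target, "group": "disease",
                        "latent_shift": row.weight * config.driver_delta})
    truth = PlantingTruth(
        de_genes=pd.DataFrame(de_rows),
        grn_edges=grn_spec.reset_index(drop=True))
    orthologs = pd.DataFrame({"mouse": [s.title() for s in genes], "human": genes})
    return ExpressionSim(adata_human, adata_mouse, truth, orthologs, driver)


@dataclass
class ExpressionSim:
    """Output bundle of :func:`generate_expression_data`."""

    human: ad.AnnData
    mouse: ad.AnnData
    truth: PlantingTruth
    orthologs: pd.DataFrame
    driver: str


def generate_de_counts(config: SimulationConfig, n_genes: int = 200,
                       n_de: int = 20, fold: float = 2.0,
                       base_mean: float = 10.0):
    """Two-group negative-binomial counts with a planted fold-change subset.

    The first ``n_de`` genes have their disease-group mean multiplied by
    ``fold``; the rest are null. Returns ``(counts, groups, de_genes)`` with
    counts as a cells x genes DataFrame.
    """
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    rng = config.rng("de-counts")
    genes = [f"DEG{i:04d}" for i in range(1, n_de + 1)] + \
            [f"NUL{i:04d}" for i in range(1, n_genes - n_de + 1)]
    gene_mean = rng.lognormal(np.log(base_mean), 0.4, size=n_genes)
    n = config.n_cells_per_group
    r = 1.0 / config.nb_dispersion
    blocks, labels = [], []
    for group in ("control", "disease"):
        mean = gene_mean.copy()
        if group == "disease":
            mean[:n_de] *= fold
        m = np.broadcast_to(mean, (n, n_genes))
        blocks.append(rng.negative_binomial(r, r / (r + m)).astype(np.int64))
        labels += [group] * n
    counts = pd.DataFrame(np.vstack(blocks), columns=genes,
                          index=[f"decell_{i:05d}" for i in range(2 * n)])
    return counts, np.array(labels), genes[:n_de]


# ---------------------------------------------------------------------------
# Multiome-like regulon dataset

@dataclass
class RegulonSim:
    """Paired per-cell TF expression and region accessibility with regulon truth."""

    expression: pd.DataFrame         # cells x genes (TFs)
    accessibility: pd.DataFrame      # cells x regions (continuous signal)
    metadata: pd.DataFrame           # cell_type, condition per cell
    regulons: dict[str, list[str]]   # TF -> target region names
    genuine_tfs: list[str]           # TFs whose regions track their expression


def generate_regulon_dataset(config: SimulationConfig, n_tfs: int = 11,
                             n_genuine: int = 1, regions_per_tf: int = 10,
                             n_background_regions: int = 40,
                             coupling: float = 1.5,
                             region_noise_sd: float = 0.5) -> RegulonSim:
    """Cells with TF expression and region signal for eRegulon filtering tests.

    The first ``n_genuine`` TFs are genuine regulators: the accessibility of
    their target regions is a linear function of the TF's per-cell
    expression (slope ``coupling``) plus noise. The remaining TFs are decoys
    whose assigned regions carry independent noise at the same scale, so
    their TF-to-region correlation is near zero. Cells split evenly into
    control/disease conditions within one cell type.
    """
    if n_genuine > n_tfs:
        raise ValueError("n_genuine cannot exceed n_tfs")
    rng = config.rng("regulon")
    tfs = ["FOSL2"] + [f"TFX{i}" for i in range(2, n_tfs + 1)]
    genuine = tfs[:n_genuine]
    n_cells = 2 * config.n_cells_per_group
    expr = pd.DataFrame(
        rng.normal(2.0, 1.0, size=(n_cells, n_tfs)),
        columns=tfs,
        index=[f"mcell_{i:05d}" for i in range(n_cells)])

    regulons: dict[str, list[str]] = {}
    acc_cols: dict[str, np.ndarray] = {}
    r = 0
    for tf in tfs:
        names = [f"region_{r + j:04d}" for j in range(regions_per_tf)]
        regulons[tf] = names
        for name in names:
            if tf in genuine:
                acc_cols[name] = (1.0 + coupling * expr[tf].to_numpy()
                                  + rng.normal(0, region_noise_sd, n_cells))
            else:
                acc_cols[name] = rng.normal(3.0, 1.0, n_cells)
        r += regions_per_tf
    for j in range(n_background_regions):
        acc_cols[f"region_bg{j:04d}"] = rng.normal(3.0, 1.0, n_cells)
    acc = pd.DataFrame(acc_cols, index=expr.index)
    metadata = pd.DataFrame({
        "cell_type": "EC",
        "condition": ["control"] * config.n_cells_per_group
                     + ["disease"] * config.n_cells_per_group,
    }, index=expr.index)
    return RegulonSim(expression=expr, accessibility=acc, metadata=metadata,
                      regulons=regulons, genuine_tfs=genuine)
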