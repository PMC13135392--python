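"""Motif footprinting on base-resolution contribution tracks.

The procedure: locate motif seqlets in the genome (within signal regions),
extract centered per-base contribution profiles across conditions, cluster
the profiles with k-means, and score each cluster for condition-differential
contribution over the motif span with a permutation test; differential
regions are then mapped to their nearest annotated gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .formats import ContributionTrack, GenomicInterval, merge_intervals
from .motifs import IUPAC, MotifModel, matches_consensus, reverse_complement


# ---------------------------------------------------------------------------
# Peak calling on contribution signal

def call_contribution_peaks(track: ContributionTrack, peaks,
                            min_abs_score: float | None = None,
                            min_run: int = 5, merge_gap: int = 10):
    """Threshold/run-length peak calling on a contribution track.

    The track is first restricted to ``peaks``. A called region is a maximal
    run of at least ``min_run`` consecutive bases with |score| >=
    ``min_abs_score``; qualifying runs separated by at most ``merge_gap``
    bases are merged. When ``min_abs_score`` is None it defaults to the 95th
    percentile of |score| within the peak regions.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    restricted = track.restrict(peaks)
    if min_abs_score is None:
        inside = np.concatenate([
            np.abs(track.slice(iv)) for iv in merge_intervals(peaks)
            if iv.chrom in track.values]) if peaks else np.array([0.0])
        min_abs_score = float(np.percentile(inside, 95)) if inside.size else 0.0
    out: list[GenomicInterval] = []
    for chrom in sorted(restricted.values):
        v = np.abs(restricted.values[chrom]) >= min_abs_score
        if not v.any():
            continue
        padded = np.concatenate(([False], v, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[0::2], edges[1::2]
        keep = (ends - starts) >= min_run
        starts, ends = starts[keep], ends[keep]
        if starts.size == 0:
            continue
        merged = [[int(starts[0]), int(ends[0])]]
        for s, e in zip(starts[1:], ends[1:]):
            if s - merged[-1][1] <= merge_gap:
                merged[-1][1] = int(e)
            else:
                merged.append([int(s), int(e)])
        out += [GenomicInterval(chrom, s, e) for s, e in merged]
    return out


# ---------------------------------------------------------------------------
# Motif scanning

def scan_motif_instances(genome: dict[str, str], motif: MotifModel,
                         mode: str = "consensus_exact",
                         within=None, max_mismatch: int = 1,
                         pwm_threshold: float | None = None,
                         background: np.ndarray | None = None):
    """Scan both strands for motif instances; each hit reported once with strand.

    Modes: ``consensus_exact`` (IUPAC match of the consensus),
    ``consensus_mismatch`` (up to ``max_mismatch`` errors), ``pwm``
    (log2-odds vs. background base frequencies >= ``pwm_threshold``, which
    defaults to ``motif.min_score``). A position matching on both strands is
    reported on '+'. ``within`` limits the scan to a set of intervals.
    """
    if mode not in {"consensus_exact", "consensus_mismatch", "pwm"}:
        raise ValueError(f"unknown scan mode {mode!r}")
    bad = set(motif.consensus) - set(IUPAC)
    if bad:
        raise ValueError(f"unknown IUPAC letters {sorted(bad)}")
    L = motif.length
    if within is not None:
        regions = [iv for iv in merge_intervals(within) if iv.chrom in genome]
    else:
        regions = [GenomicInterval(c, 0, len(s)) for c, s in sorted(genome.items())]

    if mode == "pwm":
        threshold = motif.min_score if pwm_threshold is None else pwm_threshold
        pwm = motif.pwm(background=background)
        lut = np.full(256, np.nan)
        for b, i in zip("ACGT", range(4)):
            lut[ord(b)] = i

    hits: list[GenomicInterval] = []
    rc = reverse_complement(motif.consensus)
    mm = 0 if mode == "consensus_exact" else max_mismatch
    for region in regions:
        seq = genome[region.chrom][region.start:region.end]
        if len(seq) < L:
            continue
        for off in range(len(seq) - L + 1):
            window = seq[off:off + L]
            start = region.start + off
            if mode == "pwm":
                idx = lut[np.frombuffer(window.encode(), dtype=np.uint8)]
                if np.isnan(idx).any():
                    continue
                idx = idx.astype(int)
                cols = np.arange(L)
                fwd = pwm[idx, cols].sum()
                rev = pwm[3 - idx[::-1], cols].sum()
                if fwd >= threshold and fwd >= rev:
                    hits.append(GenomicInterval(region.chrom, start, start + L, "+",
                                                motif.name, float(fwd)))
                elif rev >= threshold:
                    hits.append(GenomicInterval(region.chrom, start, start + L, "-",
                                                motif.name, float(rev)))
            else:
                if matches_consensus(window, motif.consensus, mm):
                    hits.append(GenomicInterval(region.chrom, start, start + L, "+",
                                                motif.name))
                elif matches_consensus(window, rc, mm):
                    hits.append(GenomicInterval(region.chrom, start, start + L, "-",
                                                motif.name))
    # collapse duplicate identical intervals (overlapping scan regions)
    seen, unique = set(), []
    for h in hits:
        key = (h.chrom, h.start, h.end, h.strand)
        if key not in seen:
            seen.add(key)
            unique.append(h)
    unique.sort(key=lambda h: (h.chrom, h.start))
    return unique


# ---------------------------------------------------------------------------
# Profile extraction

@dataclass
class SeqletProfileMatrix:
    """Per-base contribution profiles around seqlets, one block per condition."""

    data: np.ndarray                 # rows x (n_conditions * width)
    conditions: list[str]
    width: int                       # columns per condition block
    motif_length: int
    flank: int
    seqlets: pd.DataFrame            # row metadata: chrom,start,end,strand
    n_dropped: int = 0

    def block(self, condition: str) -> np.ndarray:
        i = self.conditions.index(condition)
        return self.data[:, i * self.width:(i + 1) * self.width]

    def motif_span_block(self, condition: str) -> np.ndarray:
        b = self.block(condition)
        return b[:, self.flank:self.flank + self.motif_length]

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]


def extract_profiles(tracks: dict[str, ContributionTrack], seqlets,
                     flank: int = 30, orient_by_strand: bool = True,
                     motif_length: int | None = None) -> SeqletProfileMatrix:
    """Centered multi-condition profile matrix for a list of seqlet intervals.

    Each row covers ``2*flank + motif_length`` bases per condition with the
    seqlet in the center. Seqlets whose window leaves any track are dropped
    and counted. Minus-strand seqlets are reversed when ``orient_by_strand``.
    """
    seqlets = list(seqlets)
    if motif_length is None:
        if not seqlets:
            raise ValueError("zero seqlets")
        motif_length = len(seqlets[0])
    width = 2 * flank + motif_length
    conditions = list(tracks)
    rows, meta, dropped = [], [], 0
    for s in seqlets:
        lo, hi = s.start - flank, s.end + flank
        ok = all(s.chrom in t.values and lo >= 0 and hi <= len(t.values[s.chrom])
                 for t in tracks.values())
        if not ok or len(s) != motif_length:
            dropped += 1
            continue
        blocks = []
        for cond in conditions:
            vals = tracks[cond].values[s.chrom][lo:hi]
            if orient_by_strand and s.strand == "-":
                vals = vals[::-1]
            blocks.append(vals)
        rows.append(np.concatenate(blocks))
        meta.append({"chrom": s.chrom, "start": s.start, "end": s.end,
                     "strand": s.strand})
    if not rows:
        raise ValueError("zero usable seqlets after edge filtering")
    return SeqletProfileMatrix(
        data=np.array(rows), conditions=conditions, width=width,
        motif_length=motif_length, flank=flank,
        seqlets=pd.DataFrame(meta), n_dropped=dropped)


# ---------------------------------------------------------------------------
# Clustering and differential scoring

@dataclass
class ClusterResult:
    k: int
    assignments: np.ndarray          # 1..k, clusters ordered by decreasing size
    centroids: np.ndarray
    cluster_means: pd.DataFrame      # per-cluster per-condition mean over motif span
    differential: pd.DataFrame | None = None  # per-cluster delta + permutation p


def kmeans_cluster_profiles(matrix: SeqletProfileMatrix, k: int = 4,
                            seed: int = 0, n_init: int = 10) -> ClusterResult:
    """Euclidean k-means on the concatenated condition blocks.

    k-means++ initialisation, best of ``n_init`` restarts by inertia,
    deterministic under ``seed``; clusters relabeled 1..k in decreasing
    size order (ties by original label).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > matrix.n_rows:
        raise ValueError(f"k={k} exceeds number of rows {matrix.n_rows}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    raw = km.fit_predict(matrix.data)
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    assignments = relabel[raw]
    centroids = km.cluster_centers_[order]
    rows = []
    for c in range(1, k + 1):
        member = assignments == c
        row = {"cluster": c, "size": int(member.sum())}
        for cond in matrix.conditions:
            row[f"mean_{cond}"] = float(matrix.motif_span_block(cond)[member].mean())
        rows.append(row)
    return ClusterResult(k=k, assignments=assignments, centroids=centroids,
                         cluster_means=pd.DataFrame(rows).set_index("cluster"))


def score_differential_clusters(result: ClusterResult,
                                matrix: SeqletProfileMatrix,
                                contrast: tuple[str, str],
                                n_perm: int = 999, seed: int = 0) -> ClusterResult:
    """Per-cluster condition contrast with a within-row label-permutation null.

    Delta = mean contribution over the motif span in condition A minus
    condition B across the cluster's rows. The null shuffles the two
    condition blocks within each row independently; p uses the add-one
    estimator, so p >= 1/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cond_a, cond_b = contrast
    for c in contrast:
        if c not in matrix.conditions:
            raise ValueError(f"condition {c!r} not in profile matrix")
    a = matrix.motif_span_block(cond_a).mean(axis=1)
    b = matrix.motif_span_block(cond_b).mean(axis=1)
    rng = np.random.default_rng(seed)
    flips = rng.random((n_perm, matrix.n_rows)) < 0.5
    diff = a - b                       # per-row contrast
    rows = []
    for c in range(1, result.k + 1):
        member = result.assignments == c
        obs = float(diff[member].mean())
        signs = np.where(flips[:, member], -1.0, 1.0)
        perm = (signs * diff[member]).mean(axis=1)
        p = (np.count_nonzero(np.abs(perm) >= abs(obs)) + 1) / (n_perm + 1)
        rows.append({"cluster": c, "delta": obs, "perm_p": p,
                     "size": int(member.sum())})
    result.differential = pd.DataFrame(rows).set_index("cluster")
    return result


# ---------------------------------------------------------------------------
# Nearest gene assignment

def assign_nearest_gene(regions, genes) -> pd.DataFrame:
    """Nearest gene by genomic distance for each region (0 when overlapping).

    Ties are broken toward the gene with the smaller start coordinate and
    flagged. Signed distance is positive when the region lies downstream
    (to the right) of the gene, negative when upstream. Regions on
    chromosomes absent from the annotation are reported with no gene.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene annotation")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for r in regions:
        candidates = by_chrom.get(r.chrom)
        if not candidates:
            rows.append({"chrom": r.chrom, "start": r.start, "end": r.end,
                         "gene": None, "distance": np.nan, "tie": False})
            continue
        best, best_dist, tie = None, None, False
        for g in sorted(candidates, key=lambda g: (g.start, g.end)):
            if r.start < g.end and g.start < r.end:
                dist = 0
            elif r.start >= g.end:
                dist = r.start - g.end + 1
            else:
                dist = -(g.start - r.end + 1)
            if best is None or abs(dist) < abs(best_dist):
                best, best_dist, tie = g, dist, False
            elif abs(dist) == abs(best_dist):
                tie = True  # earlier-start gene already kept (sorted order)
        rows.append({"chrom": r.chrom, "start": r.start, "end": r.end,
                     "gene": best.name, "distance": best_dist, "tie": tie})
    return pd.DataFrame(rows)
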