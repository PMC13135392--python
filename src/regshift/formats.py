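"""Genomic interval containers, bedGraph/FASTA/MTX readers and writers.

All coordinates are 0-based half-open (BED convention) everywhere inside the
package; conversion to other conventions happens only at format boundaries.
Writers emit deterministically ordered output so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional strand, name and score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


def sort_intervals(intervals) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(intervals) -> list[GenomicInterval]:
    """Union of intervals: overlapping or touching runs collapsed per chromosome."""
    merged: list[GenomicInterval] = []
    for iv in sort_intervals(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def intersect_intervals(a, b) -> list[GenomicInterval]:
    """Parts of intervals in ``a`` that overlap any interval of ``b``.

    Half-open semantics: touching intervals ([10,20) vs [20,30)) do not
    intersect. ``a`` fragments keep their strand/name; the score of the
    source interval is carried through.
    """
    b_merged = merge_intervals(b)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b_merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    starts = {c: np.array([iv.start for iv in ivs]) for c, ivs in by_chrom.items()}
    out: list[GenomicInterval] = []
    for iv in sort_intervals(a):
        ivs = by_chrom.get(iv.chrom)
        if not ivs:
            continue
        # first merged b interval that could overlap iv
        idx = int(np.searchsorted(starts[iv.chrom], iv.start, side="right")) - 1
        idx = max(idx, 0)
        for biv in ivs[idx:]:
            if biv.start >= iv.end:
                break
            lo, hi = max(iv.start, biv.start), min(iv.end, biv.end)
            if lo < hi:
                out.append(GenomicInterval(iv.chrom, lo, hi, iv.strand,
                                           iv.name, iv.score))
    return out


# ---------------------------------------------------------------------------
# BED

def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 and f[3] != "." else None
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, strand, name, score))
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in sort_intervals(intervals):
            score = "." if iv.score is None else format(iv.score, ".6g")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                     f"\t{score}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Contribution tracks and bedGraph

class ContributionTrack:
    """Dense per-base real-valued signal over a set of chromosomes."""

    def __init__(self, values: dict[str, np.ndarray]):
        self.values = {c: np.asarray(v, dtype=float) for c, v in values.items()}
        for chrom, v in self.values.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite contribution values on {chrom}")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.values.items()}

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.values[chrom]

    def slice(self, interval: GenomicInterval) -> np.ndarray:
        return self.values[interval.chrom][interval.start:interval.end]

    def restrict(self, intervals) -> "ContributionTrack":
        """Zero out the signal outside the union of ``intervals``."""
        masked = {c: np.zeros_like(v) for c, v in self.values.items()}
        for iv in merge_intervals(intervals):
            if iv.chrom in masked:
                end = min(iv.end, len(masked[iv.chrom]))
                masked[iv.chrom][iv.start:end] = self.values[iv.chrom][iv.start:end]
        return ContributionTrack(masked)


def read_bedgraph(path, chrom_sizes: dict[str, int] | None = None) -> ContributionTrack:
    """Read a 4-column bedGraph into a dense track (uncovered bases = 0).

    Overlapping records within a chromosome are an error; the track length
    per chromosome is ``chrom_sizes`` when given, else the maximum end seen.
    """
    records: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split()
            if len(f) != 4:
                raise ValueError(f"malformed bedGraph line: {line!r}")
            try:
                start, end, value = int(f[1]), int(f[2]), float(f[3])
            except ValueError:
                raise ValueError(f"non-numeric field in bedGraph line: {line!r}") from None
            records.setdefault(f[0], []).append((start, end, value))
    values: dict[str, np.ndarray] = {}
    for chrom, recs in records.items():
        recs.sort()
        prev_end = -1
        for start, end, _ in recs:
            if start < prev_end:
                raise ValueError(f"overlapping bedGraph records on {chrom} at {start}")
            prev_end = end
        length = (chrom_sizes or {}).get(chrom, recs[-1][1])
        arr = np.zeros(length)
        for start, end, value in recs:
            arr[start:end] = value
        values[chrom] = arr
    if chrom_sizes:
        for chrom, length in chrom_sizes.items():
            values.setdefault(chrom, np.zeros(length))
    return ContributionTrack(values)


def write_bedgraph(track: ContributionTrack, path) -> None:
    """Write a track as bedGraph, merging adjacent equal-valued runs; zero runs skipped."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            if len(v) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [len(v)]))
            for s, e in zip(starts, ends):
                val = v[s]
                if val != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{format(val, '.10g')}\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# MatrixMarket count matrices with delimited sidecars

def write_mtx(adata: ad.AnnData, outdir, prefix: str = "") -> None:
    """Write an AnnData as MTX + features/barcodes TSV sidecars (cells x features)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = scipy.sparse.csr_matrix(adata.X)
    scipy.io.mmwrite(str(outdir / f"{prefix}matrix.mtx"), X)
    adata.var.rename_axis("feature").reset_index().to_csv(
        outdir / f"{prefix}features.tsv", sep="\t", index=False)
    adata.obs.rename_axis("barcode").reset_index().to_csv(
        outdir / f"{prefix}barcodes.tsv", sep="\t", index=False)


def read_mtx(outdir, prefix: str = "") -> ad.AnnData:
    outdir = Path(outdir)
    X = scipy.io.mmread(str(outdir / f"{prefix}matrix.mtx")).tocsr()
    var = pd.read_csv(outdir / f"{prefix}features.tsv", sep="\t").set_index("feature")
    obs = pd.read_csv(outdir / f"{prefix}barcodes.tsv", sep="\t").set_index("barcode")
    var.index = var.index.astype(str)
    obs.index = obs.index.astype(str)
    return ad.AnnData(X=X, obs=obs, var=var)
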