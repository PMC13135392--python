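import numpy as np
import pandas as pd
import pytest

from regshift.footprints import (assign_nearest_gene, call_contribution_peaks,
                                 extract_profiles, kmeans_cluster_profiles,
                                 scan_motif_instances,
                                 score_differential_clusters)
from regshift.formats import ContributionTrack, GenomicInterval
from regshift.motifs import MotifModel
from regshift.synthetic import ap1_motif


def brute_force_runs(values, min_abs, min_run, merge_gap):
    """Oracle: per-base scan for qualifying runs, then gap merging."""
    flags = [abs(v) >= min_abs for v in values]
    runs, start = [], None
    for i, f in enumerate(flags + [False]):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if i - start >= min_run:
                runs.append([start, i])
            start = None
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [tuple(r) for r in merged]


class TestPeakCalling:
    def test_all_zero_track_yields_nothing(self):
        track = ContributionTrack({"chr1": np.zeros(100)})
        peaks = [GenomicInterval("chr1", 0, 100)]
        assert call_contribution_peaks(track, peaks, min_abs_score=0.5) == []

    def test_single_run_called_exactly(self):
        v = np.zeros(100)
        v[40:50] = 1.0
        track = ContributionTrack({"chr1": v})
        out = call_contribution_peaks(track, [GenomicInterval("chr1", 0, 100)],
                                      min_abs_score=0.5, min_run=5)
        assert [(iv.start, iv.end) for iv in out] == [(40, 50)]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            v = rng.normal(0, 1, size=300)
            track = ContributionTrack({"chr1": v})
            got = call_contribution_peaks(
                track, [GenomicInterval("chr1", 0, 300)],
                min_abs_score=1.2, min_run=3, merge_gap=4)
            assert [(iv.start, iv.end) for iv in got] == \
                brute_force_runs(v, 1.2, 3, 4)

    def test_min_run_validation(self):
        track = ContributionTrack({"chr1": np.zeros(10)})
        with pytest.raises(ValueError):
            call_contribution_peaks(track, [GenomicInterval("chr1", 0, 10)],
                                    min_abs_score=1, min_run=0)


class TestScan:
    def test_forward_hit_with_position_and_strand(self):
        hits = scan_motif_instances({"chr1": "ATGAGTCAT"}, ap1_motif())
        assert [(h.start, h.strand) for h in hits] == [(1, "+")]

    def test_reverse_complement_reported_on_minus(self):
        # TGACTCA is the reverse complement of TGAGTCA
        hits = scan_motif_instances({"chr1": "ATGACTCAT"}, ap1_motif())
        assert [(h.start, h.strand) for h in hits] == [(1, "-")]

    def test_recovers_all_planted_instances(self, planted_world):
        hits = scan_motif_instances(planted_world["genome"], ap1_motif())
        found = {(h.chrom, h.start, h.end) for h in hits}
        for row in planted_world["truth"].seqlets.itertuples():
            assert (row.chrom, row.start, row.end) in found

    def test_pwm_mode_scores_consensus_highest(self):
        motif = MotifModel.from_consensus("AP1", "TGAGTCA", count=1000.0)
        hits = scan_motif_instances({"c": "AATGAGTCATT"}, motif, mode="pwm",
                                    pwm_threshold=10.0)
        assert len(hits) == 1 and hits[0].score > 10

    def test_unknown_iupac_letter_rejected(self):
        bad = MotifModel.from_consensus("x", "TGAG")
        bad.consensus = "TGAZ"  # bypass constructor validation
        with pytest.raises(ValueError):
            scan_motif_instances({"c": "TTTT"}, bad)


class TestProfiles:
    def make_tracks(self, n=200, conds=("a", "b"), value=None, rng=None):
        out = {}
        for i, c in enumerate(conds):
            if value is not None:
                v = np.full(n, float(value))
            else:
                v = rng.normal(size=n)
            out[c] = ContributionTrack({"chr1": v})
        return out

    def test_width_is_two_flanks_plus_motif(self):
        tracks = self.make_tracks(value=0.0)
        seqlets = [GenomicInterval("chr1", 100, 107, "+")]
        m = extract_profiles(tracks, seqlets, flank=30)
        assert m.data.shape == (1, 2 * 67)
        assert m.width == 67

    def test_edge_seqlet_dropped_and_counted(self):
        tracks = self.make_tracks(value=0.0)
        seqlets = [GenomicInterval("chr1", 10, 17, "+"),
                   GenomicInterval("chr1", 100, 107, "+")]
        m = extract_profiles(tracks, seqlets, flank=30)
        assert m.n_rows == 1
        assert m.n_dropped == 1

    def test_constant_track_fills_block(self):
        tracks = {"a": ContributionTrack({"chr1": np.full(200, 2.5)}),
                  "b": ContributionTrack({"chr1": np.zeros(200)})}
        m = extract_profiles(tracks, [GenomicInterval("chr1", 90, 97, "+")],
                             flank=10)
        assert np.all(m.block("a") == 2.5)
        assert np.all(m.block("b") == 0.0)

    def test_minus_strand_rows_reversed(self, rng):
        tracks = self.make_tracks(rng=rng)
        fwd = extract_profiles(tracks,
                               [GenomicInterval("chr1", 90, 97, "+")], flank=5)
        rev = extract_profiles(tracks,
                               [GenomicInterval("chr1", 90, 97, "-")], flank=5)
        np.testing.assert_array_equal(rev.block("a"), fwd.block("a")[:, ::-1])

    def test_translation_equivariance(self, rng):
        v = rng.normal(size=300)
        shift = 50
        t1 = {"a": ContributionTrack({"chr1": v})}
        t2 = {"a": ContributionTrack({"chr1": np.concatenate([np.zeros(shift), v])})}
        s1 = [GenomicInterval("chr1", 100, 107, "+")]
        s2 = [GenomicInterval("chr1", 100 + shift, 107 + shift, "+")]
        m1 = extract_profiles(t1, s1, flank=20)
        m2 = extract_profiles(t2, s2, flank=20)
        np.testing.assert_array_equal(m1.data, m2.data)

    def test_zero_usable_seqlets_rejected(self):
        tracks = self.make_tracks(value=0.0)
        with pytest.raises(ValueError):
            extract_profiles(tracks, [GenomicInterval("chr1", 1, 8, "+")],
                             flank=30)


def planted_profile_matrix(n_flat=60, n_diff=30, noise=0.05, seed=0):
    """Two archetypes: flat-everywhere vs. elevated-only-in-condition-b."""
    rng = np.random.default_rng(seed)
    width = 27
    base = np.ones(width)
    rows, kinds = [], []
    for i in range(n_flat + n_diff):
        a = base + rng.normal(0, noise, width)
        b = base.copy()
        if i >= n_flat:
            b = b * 3
        b = b + rng.normal(0, noise, width)
        rows.append(np.concatenate([a, b]))
        kinds.append(i >= n_flat)
    from regshift.footprints import SeqletProfileMatrix
    return SeqletProfileMatrix(
        data=np.array(rows), conditions=["a", "b"], width=width,
        motif_length=7, flank=10,
        seqlets=pd.DataFrame({"chrom": "chr1",
                              "start": np.arange(len(rows)) * 100,
                              "end": np.arange(len(rows)) * 100 + 7,
                              "strand": "+"})), np.array(kinds)


class TestClustering:
    def test_planted_partition_recovered(self):
        matrix, kinds = planted_profile_matrix()
        result = kmeans_cluster_profiles(matrix, k=2, seed=0)
        # up to label swap, assignment equals the planted partition
        a = result.assignments == 1
        agreement = max((a == kinds).mean(), (a == ~kinds).mean())
        assert agreement == 1.0

    def test_k_equals_rows_gives_zero_inertia(self):
        matrix, _ = planted_profile_matrix(n_flat=4, n_diff=4, noise=0.2)
        result = kmeans_cluster_profiles(matrix, k=matrix.n_rows, seed=0)
        assert len(np.unique(result.assignments)) == matrix.n_rows

    def test_duplicating_rows_doubles_sizes(self):
        matrix, _ = planted_profile_matrix(n_flat=20, n_diff=20)
        r1 = kmeans_cluster_profiles(matrix, k=2, seed=0)
        matrix.data = np.vstack([matrix.data, matrix.data])
        matrix.seqlets = pd.concat([matrix.seqlets, matrix.seqlets],
                                   ignore_index=True)
        r2 = kmeans_cluster_profiles(matrix, k=2, seed=0)
        s1 = np.bincount(r1.assignments)[1:]
        s2 = np.bincount(r2.assignments)[1:]
        np.testing.assert_array_equal(np.sort(s2), np.sort(s1 * 2))

    def test_k_validation(self):
        matrix, _ = planted_profile_matrix(n_flat=5, n_diff=5)
        with pytest.raises(ValueError):
            kmeans_cluster_profiles(matrix, k=1)
        with pytest.raises(ValueError):
            kmeans_cluster_profiles(matrix, k=11)


class TestDifferentialScoring:
    def test_null_identical_blocks(self):
        matrix, _ = planted_profile_matrix(n_flat=40, n_diff=0, noise=0.05)
        matrix.data[:, matrix.width:] = matrix.data[:, :matrix.width]
        result = kmeans_cluster_profiles(matrix, k=2, seed=0)
        result = score_differential_clusters(result, matrix, ("b", "a"),
                                             n_perm=99, seed=0)
        assert np.allclose(result.differential["delta"], 0.0)
        assert (result.differential["perm_p"] > 0.5).all()

    def test_planted_cluster_maximally_significant(self):
        matrix, kinds = planted_profile_matrix(n_flat=60, n_diff=30,
                                               noise=0.1)
        result = kmeans_cluster_profiles(matrix, k=2, seed=0)
        result = score_differential_clusters(result, matrix, ("b", "a"),
                                             n_perm=999, seed=0)
        top = result.differential["delta"].idxmax()
        assert result.differential.loc[top, "perm_p"] == 1 / 1000
        member = result.assignments == top
        assert (member == kinds).all()

    def test_p_lower_bound(self):
        matrix, _ = planted_profile_matrix(n_flat=10, n_diff=10)
        result = kmeans_cluster_profiles(matrix, k=2, seed=0)
        result = score_differential_clusters(result, matrix, ("b", "a"),
                                             n_perm=19, seed=0)
        assert (result.differential["perm_p"] >= 1 / 20).all()
        with pytest.raises(ValueError):
            score_differential_clusters(result, matrix, ("b", "a"), n_perm=0)


class TestNearestGene:
    GENES = [GenomicInterval("chr1", 1000, 2000, "+", "G1"),
             GenomicInterval("chr1", 5000, 6000, "+", "G2"),
             GenomicInterval("chr2", 100, 200, "+", "G3")]

    def test_containment_gives_distance_zero(self):
        out = assign_nearest_gene([GenomicInterval("chr1", 1500, 1510)],
                                  self.GENES)
        assert out.loc[0, "gene"] == "G1"
        assert out.loc[0, "distance"] == 0

    def test_equidistant_tie_goes_to_smaller_start(self):
        # midpoint between G1 end (2000) and G2 start (5000)
        region = GenomicInterval("chr1", 3500 - 10, 3500 + 10)
        out = assign_nearest_gene([region], self.GENES)
        assert out.loc[0, "gene"] == "G1"
        assert bool(out.loc[0, "tie"])

    def test_missing_chromosome_reported_without_gene(self):
        out = assign_nearest_gene([GenomicInterval("chrX", 0, 10)], self.GENES)
        assert out.loc[0, "gene"] is None

    def test_matches_all_pairs_oracle(self, rng):
        genes = [GenomicInterval("c", int(s), int(s) + 100, "+", f"g{i}")
                 for i, s in enumerate(sorted(rng.integers(0, 10_000, 12)))]
        regions = [GenomicInterval("c", int(s), int(s) + 20)
                   for s in rng.integers(0, 10_000, 30)]
        out = assign_nearest_gene(regions, genes)
        for row, region in zip(out.itertuples(), regions):
            def dist(g):
                if region.start < g.end and g.start < region.end:
                    return 0
                if region.start >= g.end:
                    return region.start - g.end + 1
                return g.start - region.end + 1
            best = min(abs(dist(g)) for g in genes)
            assert abs(row.distance) == best
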