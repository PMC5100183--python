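"""Overlap alignment and similarity-graph clustering."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import oracles
from tedyn import synthetic_data as sd
from tedyn.read_clustering import (
    AnnotationLineage,
    CHLOROPLAST,
    Cluster,
    UNCLASSIFIED,
    annotate_from_truth,
    build_clusters,
    candidate_pairs,
    encode,
    filter_clusters,
    merge_by_annotation,
    pairwise_overlap,
    revcomp,
)

DNA = st.text(alphabet="ACGT", min_size=30, max_size=80)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestPairwiseOverlap:
    def test_identical_reads_full_identity(self, rng):
        seq = random_seq(rng, 125)
        hit = pairwise_overlap(seq, seq)
        assert hit.overlap_length == 125
        assert hit.identity == 1.0
        assert hit.orientation == "same"

    def test_reverse_complement_detected(self, rng):
        seq = random_seq(rng, 125)
        hit = pairwise_overlap(seq, revcomp(seq))
        assert hit.orientation == "reverse"
        assert hit.identity == 1.0

    def test_short_overlap_rejected(self, rng):
        # 60 of 125 bp shared: 0.48 < 0.55 minimum overlap fraction
        genome = random_seq(rng, 300)
        hit = pairwise_overlap(genome[:125], genome[65:190])
        assert hit is None

    def test_low_identity_rejected(self, rng):
        a = random_seq(rng, 125)
        b = oracles.revcomp(random_seq(rng, 125))
        assert pairwise_overlap(a, b) is None

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            pairwise_overlap("", "ACGT")

    def test_n_never_matches(self):
        a = "ACGTACGTAC" * 8
        b = a[:40] + "N" * 40
        hit_exact = pairwise_overlap(a, a)
        hit_n = pairwise_overlap(a, b)
        assert hit_exact.identity == 1.0
        # the N half contributes mismatch columns only
        assert hit_n is None or hit_n.identity < 1.0

    @given(DNA, DNA)
    def test_acceptance_symmetric(self, a, b):
        h1 = pairwise_overlap(a, b, min_overlap_frac=0.3, min_identity=0.5)
        h2 = pairwise_overlap(b, a, min_overlap_frac=0.3, min_identity=0.5)
        assert (h1 is None) == (h2 is None)
        if h1 is not None:
            assert h1.identity == h2.identity
            assert h1.overlap_length == h2.overlap_length
            assert h1.orientation == h2.orientation

    def test_matches_python_dp_oracle(self, rng):
        """Jitted DP agrees with an independent plain-Python transcription."""
        for trial in range(40):
            n = int(rng.integers(20, 70))
            genome = random_seq(rng, 160)
            start_a, start_b = rng.integers(0, 160 - n, size=2)
            a = genome[start_a : start_a + n]
            b = genome[start_b : start_b + n]
            if trial % 3 == 0:
                b = revcomp(b)
            got = pairwise_overlap(a, b, min_overlap_frac=0.3, min_identity=0.6)
            want = oracles.best_overlap(a, b, min_overlap_frac=0.3, min_identity=0.6)
            assert (got is None) == (want is None)
            if got is not None:
                assert got.identity == pytest.approx(want[0], abs=0)
                assert got.orientation == want[1]


class TestPrefilter:
    def test_lossless_on_family_reads(self, rng):
        """Clusters with and without the k-mer prefilter are identical."""
        reads = sd.simulate_cluster_reads(rng, [0.02] * 10, 60, 400, 125)
        reads += [(f"bg{i}", random_seq(rng, 125)) for i in range(20)]
        with_pf = build_clusters(reads, use_prefilter=True)
        without_pf = build_clusters(reads, use_prefilter=False)
        assert [c.read_ids for c in with_pf.clusters] == [
            c.read_ids for c in without_pf.clusters
        ]
        assert with_pf.unclustered == without_pf.unclustered

    def test_orientation_flags_cover_revcomp(self, rng):
        seq = random_seq(rng, 125)
        pairs = candidate_pairs([encode(seq), encode(revcomp(seq))])
        assert pairs[(0, 1)][1]  # reverse flag set


class TestBuildClusters:
    def test_zero_divergence_family_single_cluster(self, rng):
        """Reads tiling one exact consensus all land in one cluster."""
        consensus = random_seq(rng, 1000)
        reads = [(f"r{i:03d}", consensus[s : s + 125]) for i, s in
                 enumerate(range(0, 876, 25))]
        result = build_clusters(reads)
        assert len(result.clusters) == 1
        assert result.clusters[0].n_reads == len(reads)
        assert result.unclustered == ()

    def test_empty_input(self):
        result = build_clusters([])
        assert result.clusters == [] and result.total_reads == 0

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_clusters([("r", "ACGT" * 32), ("r", "ACGT" * 32)])

    def test_partition_property(self, demo_sim):
        sim, _, _ = demo_sim
        reads = sim.reads["11"]
        result = build_clusters(reads)
        clustered = [r for c in result.clusters for r in c.read_ids]
        assert len(clustered) == len(set(clustered))  # no read in two clusters
        assert len(clustered) + len(result.unclustered) == len(reads)
        for c in result.clusters:
            assert c.read_fraction == pytest.approx(c.n_reads / len(reads))
            assert c.total_read_bases == 125 * c.n_reads

    def test_matches_bruteforce_union_find_oracle(self, rng):
        """Production path (prefilter + graph lib) == all-pairs + union-find."""
        reads = sd.simulate_cluster_reads(rng, [0.01] * 8, 120, 600, 125)
        reads += sd.simulate_cluster_reads(rng, [0.04] * 8, 120, 600, 125)
        reads = [(f"r{i:03d}", seq) for i, (_, seq) in enumerate(reads)]
        reads += [(f"bg{i}", random_seq(rng, 125)) for i in range(60)]
        result = build_clusters(reads)
        edges = [
            (i, j)
            for i in range(len(reads))
            for j in range(i + 1, len(reads))
            if pairwise_overlap(reads[i], reads[j]) is not None
        ]
        expected = oracles.cluster_partition(edges, len(reads))
        got = {
            frozenset(i for i, (rid, _) in enumerate(reads) if rid in c.read_ids)
            for c in result.clusters
        }
        assert got == expected

    def test_ids_by_descending_size(self, rng):
        consensus_a = random_seq(rng, 400)
        consensus_b = random_seq(rng, 400)
        reads = [(f"a{i}", consensus_a[s : s + 125]) for i, s in enumerate(range(0, 226, 45))]
        reads += [(f"b{i}", consensus_b[s : s + 125]) for i, s in enumerate(range(0, 151, 50))]
        result = build_clusters(reads)
        sizes = [c.n_reads for c in result.clusters]
        assert sizes == sorted(sizes, reverse=True)
        assert result.clusters[0].cluster_id == "CL1"

    def test_truth_recovery_majority_family(self, demo_sim):
        """>= 95 % of clustered repeat reads land with their true family."""
        sim, _, _ = demo_sim
        truth = sim.truth_map()
        good = total = 0
        for acc in ("11", "12"):
            result = build_clusters(sim.reads[acc])
            for c in result.clusters:
                fams = [truth[r] for r in c.read_ids]
                majority = max(set(fams), key=fams.count)
                good += sum(1 for f in fams if f == majority)
                total += len(fams)
        assert total > 0
        assert good / total >= 0.95


class TestFilterClusters:
    @staticmethod
    def _cluster(n, total, annotation=UNCLASSIFIED, cid="CLx"):
        return Cluster(
            cluster_id=cid,
            read_ids=tuple(f"{cid}_{i}" for i in range(n)),
            total_read_bases=125 * n,
            read_fraction=n / total,
            annotation=annotation,
        )

    def test_boundary_inclusive(self):
        kept = filter_clusters([self._cluster(10, 5000)], total_reads=5000)
        assert len(kept) == 1  # exactly 0.2 % is kept
        dropped = filter_clusters([self._cluster(9, 5000)], total_reads=5000)
        assert dropped == []

    def test_chloroplast_excluded_even_if_abundant(self):
        chloro = self._cluster(250, 5000, CHLOROPLAST, "CLc")  # 5 %
        kept = filter_clusters([chloro, self._cluster(10, 5000)], total_reads=5000)
        assert all(c.annotation.te_class != "chloroplast" for c in kept)

    def test_threshold_against_nuclear_reads(self):
        # 9/5000 fails, but after removing 500 chloroplast reads 9/4500 = 0.2 %
        chloro = self._cluster(500, 5000, CHLOROPLAST, "CLc")
        kept = filter_clusters([chloro, self._cluster(9, 5000)], total_reads=5000)
        assert len(kept) == 1


class TestMergeByAnnotation:
    @staticmethod
    def _cluster(cid, n, lineage):
        return Cluster(
            cluster_id=cid,
            read_ids=tuple(f"{cid}_{i}" for i in range(n)),
            total_read_bases=125 * n,
            read_fraction=n / 1000,
            annotation=lineage,
            pair_identities=np.array([0.95] * n),
        )

    def test_same_lineage_merged_sums(self):
        chromo = AnnotationLineage("I", "LTR", "Gypsy", "Chromovirus")
        merged = merge_by_annotation(
            [self._cluster("CL1", 30, chromo), self._cluster("CL2", 10, chromo)]
        )
        assert len(merged) == 1
        assert merged[0].total_read_bases == 125 * 40
        assert merged[0].n_members == 2
        assert merged[0].read_fraction == pytest.approx(0.04)

    def test_different_families_not_merged(self):
        a = AnnotationLineage("I", "LTR", "Gypsy", "Chromovirus")
        b = AnnotationLineage("I", "LTR", "Gypsy", "Ogre-Tat")
        merged = merge_by_annotation([self._cluster("CL1", 5, a), self._cluster("CL2", 5, b)])
        assert len(merged) == 2

    def test_order_invariance(self):
        lineages = [
            AnnotationLineage("I", "LTR", "Copia", "AleII"),
            AnnotationLineage("I", "LTR", "Copia", "AleII"),
            AnnotationLineage("II", "TIR", "hAT", "hAT-1"),
        ]
        clusters = [self._cluster(f"CL{i}", 5 + i, lin) for i, lin in enumerate(lineages)]
        fwd = merge_by_annotation(clusters)
        rev = merge_by_annotation(clusters[::-1])
        assert [(c.read_ids, c.annotation) for c in fwd] == [
            (c.read_ids, c.annotation) for c in rev
        ]


class TestAnnotationLineage:
    def test_gap_in_lineage_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            AnnotationLineage("I", "", "Gypsy")

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            AnnotationLineage("III")

    def test_annotate_from_truth_majority(self):
        lineage = AnnotationLineage("I", "LTR", "Copia", "Maximus-SIRE")
        c = Cluster("CL1", ("r1", "r2", "r3"), 375, 0.3)
        out = annotate_from_truth(
            [c], {"r1": "fam", "r2": "fam", "r3": ""}, {"fam": lineage}
        )
        assert out[0].annotation == lineage
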