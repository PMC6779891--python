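import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qctcount.qct_core import (
    EMICluster,
    cluster_emis,
    cluster_partition,
    count_ge,
    decode_sample,
    partition_reads,
    subsample_and_recount,
    summarize_qct,
    threshold_clusters,
)
from qctcount.simdata import SimConfig, simulate_reaction


# ---------------------------------------------------------------------------
# partitioning

def test_pure_qct_input_all_classified_qct(assay, pools):
    emi = "ACGTACGTAC"
    reads = [pools[0].molecule_sequence(emi)] * 100
    part = partition_reads(reads, assay)
    assert part.qct_observations == [("QCT1", emi, 100)]
    assert part.goi_read_count == 0
    assert part.unmatched_count == 0


def test_simulated_mix_splits_exactly_at_zero_error(assay, pools):
    sim = SimConfig(
        n_qct_molecules_mean=50,
        n_goi_molecules=400,
        depth_per_molecule_mean=5,
        amplification_bias_sd=0.0,
        seq_error_rate=0.0,
    )
    reads, truth = simulate_reaction(pools, assay, sim, 7)
    part = partition_reads([r.sequence for r in reads], assay)
    assert part.qct_read_count == sum(d for _, _, d in truth.qct_molecules)
    assert part.goi_read_count == truth.n_goi_molecules * 5
    assert part.unmatched_count == 0
    assert part.goi_read_depth_by_allele == truth.goi_read_depth_by_allele


def test_single_mismatch_in_qct_id_is_not_qct(assay, pools):
    seq = pools[0].molecule_sequence("ACGTACGTAC")
    off = assay.qct_id_offset
    corrupted = seq[:off] + ("A" if seq[off] != "A" else "C") + seq[off + 1 :]
    part = partition_reads([corrupted], assay)
    # not a QCT read; the intact EMI bases leave it too far from the
    # reference to be a GOI read either
    assert part.qct_read_count == 0
    assert part.unmatched_count == 1


def test_goi_reads_tolerate_mismatch_budget_and_report_alleles(assay):
    ref = assay.reference_seq
    locus = assay.variant_loci[0]
    alt_read = ref[: locus.offset] + locus.alt_base + ref[locus.offset + 1 :]
    noisy = "T" + ref[1:] if ref[0] != "T" else "A" + ref[1:]
    part = partition_reads([ref, ref, alt_read, noisy], assay)
    assert part.goi_read_depth_by_allele == {locus.ref_base: 3, locus.alt_base: 1}


def test_short_reads_counted_unmatched(assay):
    part = partition_reads([assay.reference_seq[:20]], assay)
    assert part.unmatched_count == 1
    assert part.total_reads == 1


def test_empty_stream_gives_zero_partition(assay):
    part = partition_reads([], assay)
    assert part.total_reads == 0
    assert part.qct_observations == []


# ---------------------------------------------------------------------------
# clustering

def test_singleton_cluster():
    clusters = cluster_emis([("AAAAAAAAAA", 50)])
    assert len(clusters) == 1
    assert clusters[0].read_depth == 50
    assert clusters[0].consensus_emi == "AAAAAAAAAA"


def test_one_mismatch_merges_with_majority_consensus():
    clusters = cluster_emis([("AAAAAAAAAA", 50), ("AAAAAAAAAT", 2)])
    assert len(clusters) == 1
    assert clusters[0].read_depth == 52
    assert clusters[0].consensus_emi == "AAAAAAAAAA"


def test_three_mismatches_do_not_merge():
    clusters = cluster_emis([("AAAAAAAAAA", 10), ("AAAAAAATTT", 10)])
    assert len(clusters) == 2


def test_consensus_tie_breaks_lexicographically():
    clusters = cluster_emis([("AAAAAAAAAC", 5), ("AAAAAAAAAA", 5)])
    assert clusters[0].consensus_emi == "AAAAAAAAAA"


def test_mixed_emi_lengths_rejected():
    with pytest.raises(ValueError, match="lengths"):
        cluster_emis([("AAAA", 1), ("AAAAA", 1)])


def _brute_force_clusters(observations):
    """Independent oracle: all-pairs graph, networkx connected components."""
    graph = nx.Graph()
    counts = {}
    for emi, c in observations:
        counts[emi] = counts.get(emi, 0) + c
        graph.add_node(emi)
    emis = list(counts)
    for i, a in enumerate(emis):
        for b in emis[i + 1 :]:
            if sum(x != y for x, y in zip(a, b)) <= 2:
                graph.add_edge(a, b)
    result = set()
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        depth = sum(counts[m] for m in members)
        result.add((frozenset(members), depth))
    return result


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_clustering_matches_all_pairs_brute_force(seed):
    rng = np.random.default_rng(seed)
    base = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(12)]
    observations = []
    for emi in base:
        observations.append((emi, int(rng.integers(1, 60))))
        for _ in range(rng.integers(0, 3)):  # satellites within 1-2 mismatches
            err = list(emi)
            for pos in rng.choice(8, rng.integers(1, 3), replace=False):
                err[pos] = rng.choice(list("ACGT"))
            observations.append(("".join(err), int(rng.integers(1, 4))))
    ours = {
        (frozenset(m for m, _ in c.member_sequences), c.read_depth)
        for c in cluster_emis(observations)
    }
    assert ours == _brute_force_clusters(observations)


@given(st.permutations(list(range(6))))
def test_clustering_is_permutation_invariant(order):
    observations = [
        ("AAAAAAAAAA", 40),
        ("AAAAAAAAAT", 3),
        ("CCCCCCCCCC", 25),
        ("CCCCCCCCGG", 2),
        ("GGGGGGGGGG", 9),
        ("TTTTTTTTTT", 1),
    ]
    shuffled = [observations[i] for i in order]
    reference = cluster_emis(observations)
    assert cluster_emis(shuffled) == reference


# ---------------------------------------------------------------------------
# thresholding and summaries

def test_threshold_is_sqrt_of_mean_depth():
    clusters = [
        EMICluster("A" * 10, d, (("A" * 10, d),)) for d in (100, 100, 100, 1)
    ]
    t, classified = threshold_clusters(clusters)
    assert t == pytest.approx(math.sqrt(75.25))
    assert [c.depth_class for c in classified] == ["high", "high", "high", "low"]


def test_single_cluster_above_own_sqrt_is_high():
    t, classified = threshold_clusters([EMICluster("A" * 10, 9, (("A" * 10, 9),))])
    assert t == pytest.approx(3.0)
    assert classified[0].depth_class == "high"


def test_depth_exactly_at_threshold_is_low():
    # one cluster of depth 1: t = 1 and the strict comparison classes it low
    t, classified = threshold_clusters([EMICluster("A" * 10, 1, (("A" * 10, 1),))])
    assert t == pytest.approx(1.0)
    assert classified[0].depth_class == "low"


def test_empty_cluster_list_has_undefined_threshold():
    t, classified = threshold_clusters([])
    assert math.isnan(t)
    assert classified == []


def test_summary_counts_and_mean_depth():
    clusters = [
        EMICluster("A" * 10, 20, (("A" * 10, 20),), pool_id="QCT1"),
        EMICluster("C" * 10, 40, (("C" * 10, 40),), pool_id="QCT2"),
        EMICluster("G" * 10, 1, (("G" * 10, 1),), pool_id="QCT1"),
    ]
    _, classified = threshold_clusters(clusters)
    summary = summarize_qct(classified, sample_id="s1")
    assert summary.n_molecules == 2
    assert summary.mean_depth_per_molecule == pytest.approx(30.0)
    assert summary.per_pool_mean_depth == {"QCT1": 20.0, "QCT2": 40.0}
    assert summary.fingerprint == frozenset({"A" * 10, "C" * 10})
    assert summary.n_molecules == len(summary.fingerprint)
    assert summary.qc_pass


def test_zero_high_clusters_fails_qc():
    _, classified = threshold_clusters(
        [EMICluster("A" * 10, 1, (("A" * 10, 1),))]
    )
    summary = summarize_qct(classified)
    assert summary.n_molecules == 0
    assert not summary.qc_pass


def test_unthresholded_clusters_rejected():
    with pytest.raises(ValueError, match="threshold"):
        summarize_qct([EMICluster("A" * 10, 5, (("A" * 10, 5),))])


# ---------------------------------------------------------------------------
# genomic equivalents

def test_ge_formula():
    clusters = [EMICluster("A" * 10, 20, (("A" * 10, 20),))] * 5
    _, classified = threshold_clusters(clusters)
    summary = summarize_qct(classified)
    count = count_ge(40000, summary)
    assert count.genomic_equivalents == pytest.approx(2000.0)
    assert count_ge(0, summary).genomic_equivalents == 0.0


def test_ge_undefined_without_molecules():
    _, classified = threshold_clusters([EMICluster("A" * 10, 1, (("A" * 10, 1),))])
    summary = summarize_qct(classified)
    with pytest.raises(ValueError, match="GE undefined"):
        count_ge(100, summary)


def test_ge_recovers_spiked_molecule_count(assay, pools):
    """GE tracks the true number of amplifiable genomic molecules."""
    truth_n = 1850
    estimates = []
    for seed in range(6):
        sim = SimConfig(
            n_qct_molecules_mean=100,
            n_goi_molecules=truth_n,
            depth_per_molecule_mean=15,
            amplification_bias_sd=0.4,
            seq_error_rate=0.002,
        )
        reads, _ = simulate_reaction(pools, assay, sim, 100 + seed)
        dec = decode_sample([r.sequence for r in reads], assay)
        estimates.append(dec.count.genomic_equivalents)
    mean = float(np.mean(estimates))
    se = float(np.std(estimates, ddof=1) / math.sqrt(len(estimates)))
    assert abs(mean - truth_n) <= 3 * max(se, 1.0)


# ---------------------------------------------------------------------------
# subsampling robustness

def _reads_for_subsampling(assay, pools, depth, seed):
    sim = SimConfig(
        n_qct_molecules_mean=75,
        n_goi_molecules=0,
        depth_per_molecule_mean=depth,
        amplification_bias_sd=0.25,
        seq_error_rate=0.0,
    )
    reads, _ = simulate_reaction(pools, assay, sim, seed)
    return [r.sequence for r in reads]


def test_subsample_fraction_one_is_identity(assay, pools):
    reads = _reads_for_subsampling(assay, pools, depth=10, seed=3)
    n_full, n_sub = subsample_and_recount(reads, 1.0, 0, assay)
    assert n_full == n_sub


def test_counts_stable_at_half_depth_when_deep(assay, pools):
    reads = _reads_for_subsampling(assay, pools, depth=30, seed=4)
    n_full, n_sub = subsample_and_recount(reads, 0.5, 11, assay)
    assert n_full == n_sub


def test_shallow_library_subsampling_only_loses_molecules(assay, pools):
    reads = _reads_for_subsampling(assay, pools, depth=4, seed=5)
    n_full, n_sub = subsample_and_recount(reads, 0.5, 12, assay)
    assert n_full >= n_sub


def test_invalid_fraction_rejected(assay):
    with pytest.raises(ValueError):
        subsample_and_recount([], 0.0, 1, assay)


def test_cluster_partition_separates_pools(assay, pools):
    emi = "ACGTACGTAC"
    reads = [pools[0].molecule_sequence(emi)] * 30 + [
        pools[1].molecule_sequence(emi)
    ] * 10
    part = partition_reads(reads, assay)
    clusters = cluster_partition(part)
    assert {(c.pool_id, c.read_depth) for c in clusters} == {("QCT1", 30), ("QCT2", 10)}
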