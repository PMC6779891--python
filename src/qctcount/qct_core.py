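"""Decode QCT spike-in reads into molecule counts and genomic equivalents.

The decoding chain is: partition reads into QCT / gene-of-interest (GOI) /
unmatched; single-linkage cluster the EMI sequences of the QCT reads (Hamming
distance <= 2) so that PCR and sequencing errors collapse onto their parent
molecule; split clusters into high- and low-depth at sqrt(mean cluster depth);
count molecules as high-depth clusters; and convert GOI read depth into
genomic equivalents, GE = D_GOI / <D_QCT>, where <D_QCT> is the mean read
depth per counted QCT molecule.
"""

from __future__ import annotations

import gzip
import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .assay import AssayConfig

logger = logging.getLogger(__name__)

HIGH = "high"
LOW = "low"


# ---------------------------------------------------------------------------
# read input

def read_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (gzipped if suffixed .gz)."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fastq"):
            yield str(record.seq)


def _as_sequence(read) -> str:
    if isinstance(read, str):
        return read
    if isinstance(read, tuple):
        return read[1]
    seq = getattr(read, "sequence", None) or getattr(read, "seq", None)
    if seq is None:
        raise TypeError(f"cannot extract a sequence from {read!r}")
    return str(seq)


# ---------------------------------------------------------------------------
# partitioning

@dataclass
class ReadPartition:
    """Exhaustive classification of one sample's reads.

    ``qct_observations`` aggregates QCT reads as (pool_id, emi, count);
    ``goi_read_depth_by_allele`` keys are the concatenated bases observed at
    the assay's variant loci (empty string if the assay defines none).
    """

    qct_observations: list[tuple[str, str, int]] = field(default_factory=list)
    goi_read_depth_by_allele: dict[str, int] = field(default_factory=dict)
    unmatched_count: int = 0

    @property
    def qct_read_count(self) -> int:
        return sum(c for _, _, c in self.qct_observations)

    @property
    def goi_read_count(self) -> int:
        return sum(self.goi_read_depth_by_allele.values())

    @property
    def total_reads(self) -> int:
        return self.qct_read_count + self.goi_read_count + self.unmatched_count


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def partition_reads(
    reads: Iterable,
    config: AssayConfig,
    *,
    qct_mismatch_budget: int = 0,
    goi_mismatch_budget: int = 3,
) -> ReadPartition:
    """Split demultiplexed reads into QCT observations, GOI depth, unmatched.

    A read is a QCT observation iff it carries one of the configured pool IDs
    at the ID offset (within ``qct_mismatch_budget``, default exact); its EMI
    is the concatenation of the bases at the EMI offsets. Otherwise it is a
    GOI read if it matches the reference amplicon within
    ``goi_mismatch_budget`` mismatches, the variant loci not counting; any
    remaining read is unmatched. Reads too short for the features they need
    are unmatched (with a logged warning).
    """
    seqs = [_as_sequence(r) for r in reads]
    qct_counts: Counter[tuple[str, str]] = Counter()
    allele_counts: Counter[str] = Counter()
    unmatched = 0
    short_reads = 0

    pool_ids = sorted(config.qct_ids.items())  # deterministic pool priority
    id_off, id_len = config.qct_id_offset, config.qct_id_length
    exact_lookup = {seq: pool for pool, seq in pool_ids} if qct_mismatch_budget == 0 else None
    emi_offsets = list(config.emi_offsets)
    ref = config.reference_seq
    n_ref = len(ref)
    variant_offsets = [v.offset for v in config.variant_loci]
    min_goi_len = max(variant_offsets, default=-1) + 1

    # vectorized fast path for full-length reads (the common amplicon case)
    full_len = [s for s in seqs if len(s) == n_ref]
    other = [s for s in seqs if len(s) != n_ref]

    if full_len:
        arr = np.frombuffer("".join(full_len).encode("ascii"), dtype=np.uint8)
        arr = arr.reshape(len(full_len), n_ref)
        id_block = arr[:, id_off : id_off + id_len]
        pool_of = np.full(len(full_len), -1, dtype=np.int64)
        best = np.full(len(full_len), qct_mismatch_budget + 1, dtype=np.int64)
        for k, (pool, idseq) in enumerate(pool_ids):
            target = np.frombuffer(idseq.encode("ascii"), dtype=np.uint8)
            mm = (id_block != target).sum(axis=1)
            hit = mm < best
            pool_of[hit] = k
            best[hit] = mm[hit]
        is_qct = pool_of >= 0

        emi_block = arr[is_qct][:, emi_offsets]
        for row, k in zip(emi_block, pool_of[is_qct]):
            qct_counts[(pool_ids[k][0], row.tobytes().decode("ascii"))] += 1

        rest = arr[~is_qct]
        ref_arr = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
        cmp_cols = np.ones(n_ref, dtype=bool)
        cmp_cols[variant_offsets] = False
        mm = (rest[:, cmp_cols] != ref_arr[cmp_cols]).sum(axis=1)
        is_goi = mm <= goi_mismatch_budget
        if variant_offsets:
            labels = rest[is_goi][:, variant_offsets]
            for row in labels:
                allele_counts[row.tobytes().decode("ascii")] += 1
        else:
            allele_counts[""] += int(is_goi.sum())
        unmatched += int((~is_goi).sum())

    for seq in other:  # odd-length fallback, read by read
        pool_hit = None
        if len(seq) >= config.min_qct_read_length:
            window = seq[id_off : id_off + id_len]
            if exact_lookup is not None:
                pool_hit = exact_lookup.get(window)
            else:
                cands = [
                    (d, pool)
                    for pool, idseq in pool_ids
                    if (d := _hamming(window, idseq)) <= qct_mismatch_budget
                ]
                pool_hit = min(cands)[1] if cands else None
        elif len(seq) >= id_off + id_len:
            window = seq[id_off : id_off + id_len]
            matched = (
                window in exact_lookup
                if exact_lookup is not None
                else any(_hamming(window, s) <= qct_mismatch_budget for _, s in pool_ids)
            )
            if matched:
                short_reads += 1
                unmatched += 1
                continue
        if pool_hit is not None:
            emi = "".join(seq[o] for o in emi_offsets)
            qct_counts[(pool_hit, emi)] += 1
            continue
        if len(seq) < min_goi_len:
            short_reads += 1
            unmatched += 1
            continue
        span = min(len(seq), n_ref)
        mm = sum(
            seq[i] != ref[i] for i in range(span) if i not in variant_offsets
        )
        if mm <= goi_mismatch_budget:
            allele_counts["".join(seq[o] for o in variant_offsets)] += 1
        else:
            unmatched += 1

    if short_reads:
        logger.warning(
            "%d reads were too short to cover the configured offsets and were "
            "counted as unmatched",
            short_reads,
        )
    observations = sorted(
        ((pool, emi, count) for (pool, emi), count in qct_counts.items())
    )
    return ReadPartition(
        qct_observations=observations,
        goi_read_depth_by_allele=dict(sorted(allele_counts.items())),
        unmatched_count=unmatched,
    )


# ---------------------------------------------------------------------------
# EMI clustering

@dataclass
class EMICluster:
    """One putative QCT molecule: an EMI cluster with its read support."""

    consensus_emi: str
    read_depth: int
    member_sequences: tuple[tuple[str, int], ...]
    depth_class: str | None = None
    pool_id: str | None = None


def _pairwise_linked(arr: np.ndarray, max_mismatches: int) -> coo_matrix:
    """Sparse adjacency of rows within ``max_mismatches`` Hamming distance."""
    n, width = arr.shape
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    block = max(1, 4_000_000 // max(1, n * width))
    for start in range(0, n, block):
        chunk = arr[start : start + block]
        d = (chunk[:, None, :] != arr[None, :, :]).sum(axis=2)
        r, c = np.nonzero(d <= max_mismatches)
        rows.append(r + start)
        cols.append(c)
    data = np.ones(sum(len(r) for r in rows), dtype=np.int8)
    return coo_matrix(
        (data, (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )


def cluster_emis(
    observations: Iterable[tuple[str, int]],
    *,
    max_mismatches: int = 2,
) -> list[EMICluster]:
    """Single-linkage cluster EMI sequences under Hamming distance.

    Two EMIs belong to the same cluster whenever they are connected by a
    chain of pairs each within ``max_mismatches``. The consensus is the
    highest-count member (ties to the lexicographically smallest), and the
    result is deterministic regardless of input order.
    """
    counts: Counter[str] = Counter()
    for emi, count in observations:
        if count < 0:
            raise ValueError("observation counts must be non-negative")
        counts[emi] += count
    if not counts:
        return []
    lengths = {len(e) for e in counts}
    if len(lengths) != 1:
        raise ValueError(f"mixed EMI lengths in input: {sorted(lengths)}")

    emis = sorted(counts)
    arr = np.frombuffer("".join(emis).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(emis), lengths.pop())
    adjacency = _pairwise_linked(arr, max_mismatches)
    n_comp, labels = connected_components(adjacency, directed=False)

    clusters = []
    for comp in range(n_comp):
        members = [(emis[i], counts[emis[i]]) for i in np.nonzero(labels == comp)[0]]
        members.sort(key=lambda m: (-m[1], m[0]))
        clusters.append(
            EMICluster(
                consensus_emi=members[0][0],
                read_depth=sum(c for _, c in members),
                member_sequences=tuple(members),
            )
        )
    clusters.sort(key=lambda c: (-c.read_depth, c.consensus_emi))
    return clusters


def cluster_partition(
    partition: ReadPartition, *, max_mismatches: int = 2
) -> list[EMICluster]:
    """Cluster a partition's QCT observations separately within each pool."""
    by_pool: dict[str, list[tuple[str, int]]] = {}
    for pool, emi, count in partition.qct_observations:
        by_pool.setdefault(pool, []).append((emi, count))
    clusters: list[EMICluster] = []
    for pool in sorted(by_pool):
        for cl in cluster_emis(by_pool[pool], max_mismatches=max_mismatches):
            clusters.append(replace(cl, pool_id=pool))
    clusters.sort(key=lambda c: (-c.read_depth, c.consensus_emi))
    return clusters


# ---------------------------------------------------------------------------
# thresholding and summaries

def threshold_clusters(
    clusters: Sequence[EMICluster],
) -> tuple[float, list[EMICluster]]:
    """Classify clusters as high/low depth at sqrt(mean cluster depth).

    The mean is over all clusters and computed once; a cluster is high-depth
    iff its depth strictly exceeds the threshold (a depth exactly at the
    threshold is low). An empty input yields a NaN threshold.
    """
    if not clusters:
        return float("nan"), []
    t = math.sqrt(sum(c.read_depth for c in clusters) / len(clusters))
    out = [
        replace(c, depth_class=HIGH if c.read_depth > t else LOW) for c in clusters
    ]
    return t, out


@dataclass
class SampleQCTSummary:
    """Per-reaction decoded QCT counts, mean depth, and EMI fingerprint."""

    sample_id: str
    n_molecules: int
    mean_depth_per_molecule: float
    per_pool_mean_depth: dict[str, float]
    depth_threshold: float
    fingerprint: frozenset[str]
    qct_read_count: int = 0
    qc_pass: bool = True


def summarize_qct(
    clusters: Sequence[EMICluster],
    pool_assignment: Mapping[str, str] | None = None,
    *,
    sample_id: str = "sample",
) -> SampleQCTSummary:
    """Summarize thresholded clusters into molecule counts and <D_QCT>.

    ``pool_assignment`` (consensus EMI -> pool id) overrides any pool labels
    already on the clusters. A sample with zero high-depth clusters is marked
    as failing QC.
    """
    if any(c.depth_class is None for c in clusters):
        raise ValueError("clusters must be thresholded first (depth_class unset)")
    threshold = math.sqrt(sum(c.read_depth for c in clusters) / len(clusters)) if clusters else float("nan")
    high = [c for c in clusters if c.depth_class == HIGH]
    per_pool: dict[str, list[int]] = {}
    for c in high:
        pool = (
            pool_assignment.get(c.consensus_emi)
            if pool_assignment is not None
            else c.pool_id
        )
        per_pool.setdefault(pool if pool is not None else "pool", []).append(
            c.read_depth
        )
    n = len(high)
    mean_depth = sum(c.read_depth for c in high) / n if n else 0.0
    if n == 0:
        logger.warning("sample %s has no high-depth EMI clusters; QC fail", sample_id)
    return SampleQCTSummary(
        sample_id=sample_id,
        n_molecules=n,
        mean_depth_per_molecule=mean_depth,
        per_pool_mean_depth={
            pool: sum(d) / len(d) for pool, d in sorted(per_pool.items())
        },
        depth_threshold=threshold,
        fingerprint=frozenset(c.consensus_emi for c in high),
        qct_read_count=sum(c.read_depth for c in clusters),
        qc_pass=n > 0,
    )


@dataclass
class MolecularCount:
    """Genomic equivalents of the gene of interest: GE = D_GOI / <D_QCT>."""

    goi_depth: int
    genomic_equivalents: float
    n_qct: int


def count_ge(goi_depth: int, summary: SampleQCTSummary) -> MolecularCount:
    """Convert GOI read depth to genomic equivalents via <D_QCT>."""
    if summary.n_molecules == 0:
        raise ValueError(
            f"sample {summary.sample_id}: no QCT molecules counted; GE undefined"
        )
    if goi_depth < 0:
        raise ValueError("read depth must be non-negative")
    return MolecularCount(
        goi_depth=goi_depth,
        genomic_equivalents=goi_depth / summary.mean_depth_per_molecule,
        n_qct=summary.n_molecules,
    )


# ---------------------------------------------------------------------------
# whole-sample convenience

@dataclass
class SampleDecode:
    """All decode products for one sample."""

    sample_id: str
    partition: ReadPartition
    clusters: list[EMICluster]
    threshold: float
    summary: SampleQCTSummary
    count: MolecularCount | None


def decode_sample(
    reads: Iterable,
    config: AssayConfig,
    *,
    sample_id: str = "sample",
    qct_mismatch_budget: int = 0,
    goi_mismatch_budget: int = 3,
) -> SampleDecode:
    """Run partition -> cluster -> threshold -> summarize -> GE for one sample."""
    partition = partition_reads(
        reads,
        config,
        qct_mismatch_budget=qct_mismatch_budget,
        goi_mismatch_budget=goi_mismatch_budget,
    )
    clusters = cluster_partition(partition)
    threshold, clusters = threshold_clusters(clusters)
    summary = summarize_qct(clusters, sample_id=sample_id)
    count = (
        count_ge(partition.goi_read_count, summary) if summary.n_molecules else None
    )
    return SampleDecode(
        sample_id=sample_id,
        partition=partition,
        clusters=clusters,
        threshold=threshold,
        summary=summary,
        count=count,
    )


def subsample_and_recount(
    reads: Iterable,
    fraction: float,
    seed: int,
    config: AssayConfig,
) -> tuple[int, int]:
    """Molecule counts from the full read set and a random subsample.

    Each read is retained independently with probability ``fraction``; both
    read sets are decoded end to end. Used to check that molecule counts are
    robust to sequencing depth (they are once clusters retain >= ~10 reads).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    seqs = [_as_sequence(r) for r in reads]
    rng = np.random.default_rng(seed)
    keep = rng.random(len(seqs)) < fraction
    sub = [s for s, k in zip(seqs, keep) if k]
    n_full = decode_sample(seqs, config).summary.n_molecules
    n_sub = decode_sample(sub, config).summary.n_molecules
    return n_full, n_sub
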