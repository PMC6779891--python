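"""Sample-integrity analyses from QCT fingerprints.

A reaction's fingerprint — the set of its high-depth EMI consensus sequences —
is essentially unique (with ~100 molecules drawn from a pool of up to 4^10
sequences), so it identifies the physical PCR. Low-depth EMI clusters whose
consensus is another reaction's high-depth molecule expose cross-sample
contamination and index misassignment; whole fingerprints shared between two
reactions expose barcoding mixups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .qct_core import HIGH, LOW, EMICluster, SampleQCTSummary

logger = logging.getLogger(__name__)


@dataclass
class ContaminationReport:
    """Contamination of one reaction, as a fraction of its QCT reads."""

    sample_id: str
    contamination_fraction: float
    per_source: dict[str, float] = field(default_factory=dict)
    unattributed_low_depth_reads: int = 0
    total_qct_reads: int = 0

    @property
    def top_source(self) -> str | None:
        if not self.per_source:
            return None
        return max(sorted(self.per_source), key=lambda s: self.per_source[s])


def detect_contamination(
    clusters_by_sample: Mapping[str, Sequence[EMICluster]],
) -> list[ContaminationReport]:
    """Quantify contaminating QCT reads in every sample of a batch.

    An EMI cluster in sample A counts as a contaminant iff it is low-depth in
    A and its consensus EMI is in the high-depth fingerprint of at least one
    other sample; those samples share the attribution equally. The reported
    fraction is attributed contaminating reads over the sample's total QCT
    reads.
    """
    samples = list(clusters_by_sample)
    if len(samples) < 2:
        logger.warning("contamination detection needs >= 2 samples; empty report")
        return []
    for sid, clusters in clusters_by_sample.items():
        if any(c.depth_class not in (HIGH, LOW) for c in clusters):
            raise ValueError(f"sample {sid}: clusters must be thresholded first")

    fingerprints = {
        sid: {c.consensus_emi for c in clusters if c.depth_class == HIGH}
        for sid, clusters in clusters_by_sample.items()
    }
    reports = []
    for sid in samples:
        clusters = clusters_by_sample[sid]
        total = sum(c.read_depth for c in clusters)
        per_source: dict[str, float] = {}
        attributed = 0.0
        unattributed = 0
        for cluster in clusters:
            if cluster.depth_class != LOW:
                continue
            origins = [
                other
                for other in samples
                if other != sid and cluster.consensus_emi in fingerprints[other]
            ]
            if not origins:
                unattributed += cluster.read_depth
                continue
            attributed += cluster.read_depth
            share = cluster.read_depth / len(origins)
            for origin in origins:
                per_source[origin] = per_source.get(origin, 0.0) + share
        reports.append(
            ContaminationReport(
                sample_id=sid,
                contamination_fraction=attributed / total if total else 0.0,
                per_source=dict(sorted(per_source.items())),
                unattributed_low_depth_reads=unattributed,
                total_qct_reads=total,
            )
        )
    return reports


@dataclass
class CollisionMatrix:
    """Pairwise counts of shared high-depth EMI clusters."""

    samples: list[str]
    counts: np.ndarray

    def pair_count(self, a: str, b: str) -> int:
        return int(self.counts[self.samples.index(a), self.samples.index(b)])


def _fingerprints(
    summaries: Sequence[SampleQCTSummary] | Mapping[str, frozenset[str]],
) -> dict[str, frozenset[str]]:
    if isinstance(summaries, Mapping):
        return {sid: frozenset(fp) for sid, fp in summaries.items()}
    return {s.sample_id: frozenset(s.fingerprint) for s in summaries}


def collision_matrix(
    summaries: Sequence[SampleQCTSummary] | Mapping[str, frozenset[str]],
) -> CollisionMatrix:
    """Count exact fingerprint intersections for all sample pairs.

    The diagonal holds each sample's own fingerprint size.
    """
    fps = _fingerprints(summaries)
    samples = list(fps)
    n = len(samples)
    counts = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(samples):
        counts[i, i] = len(fps[a])
        for j in range(i + 1, n):
            shared = len(fps[a] & fps[samples[j]])
            counts[i, j] = counts[j, i] = shared
    return CollisionMatrix(samples=samples, counts=counts)


def flag_mixups(
    matrix: CollisionMatrix, min_collisions: int = 10
) -> list[tuple[str, str]]:
    """Sample pairs sharing at least ``min_collisions`` high-depth clusters.

    Independently fingerprinted reactions share ~0 clusters while a
    double-barcoded PCR shares its whole fingerprint, so any threshold in
    between separates them; 10 is the default.
    """
    if min_collisions < 1:
        raise ValueError("min_collisions must be >= 1")
    pairs = []
    n = len(matrix.samples)
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.counts[i, j] >= min_collisions:
                pairs.append((matrix.samples[i], matrix.samples[j]))
    return pairs
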