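"""Synthetic amplicon reads with QCT spike-ins and known ground truth.

The generator emulates the experimental regime the decoder is built for:
~100-1000 QCT molecules per reaction each carrying a distinct randomized EMI,
per-molecule PCR amplification bias (lognormal, spanning up to ~8-fold read
depth at the default spread), uniform per-base sequencing error, cross-sample
contamination at configurable read fractions, and index misassignment whose
impact depends on whether the plate uses dual-unique or combinatorial
(TruSeq-style) index pairs. cfDNA allele-count mixtures at a given fetal
fraction are generated directly as binomial molecule counts.

Every operation takes an explicit seed or ``numpy.random.Generator``;
identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .assay import AssayConfig, VariantLocus

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_QUALITY_CHAR = "?"  # constant Q30; qualities are not used by the decoder

#: Read-depth distribution of an injected contaminating EMI: P(depth 1),
#: P(depth 2). Carryover and index-hopped molecules are observed almost
#: exclusively at depth 1-2; the singleton share is calibrated so that a
#: reaction receiving only contamination detects >90% of it under the
#: sqrt-mean depth threshold (which can only ever flag the singletons there,
#: and additionally loses a few percent to chance EMI-cluster merges).
CONTAMINANT_DEPTH_PROBS: tuple[float, float] = (0.985, 0.015)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class FastqRead:
    name: str
    sequence: str
    quality: str | None = None

    def fastq_block(self) -> str:
        q = self.quality or DEFAULT_QUALITY_CHAR * len(self.sequence)
        return f"@{self.name}\n{self.sequence}\n+\n{q}\n"


def write_fastq(reads: Sequence[FastqRead], path: str | Path) -> None:
    """Write reads as plain (or gzipped, by .gz suffix) FASTQ."""
    import gzip

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for read in reads:
            fh.write(read.fastq_block())


# ---------------------------------------------------------------------------
# QCT pool templates

@dataclass(frozen=True)
class QCTPool:
    """A synthesized QCT pool: fixed pool ID, randomized EMI positions."""

    pool_id: str
    qct_id_seq: str
    config: AssayConfig

    def draw_emis(self, n: int, rng) -> list[str]:
        """Draw ``n`` molecules' EMIs, i.i.d. uniform bases per position."""
        k = self.config.emi_length
        rows = BASES[_rng(rng).integers(0, 4, size=(n, k))]
        return [row.tobytes().decode("ascii") for row in rows]

    def molecule_sequence(self, emi: str) -> str:
        cfg = self.config
        seq = list(cfg.reference_seq)
        seq[cfg.qct_id_offset : cfg.qct_id_offset + len(self.qct_id_seq)] = (
            self.qct_id_seq
        )
        for offset, base in zip(cfg.emi_offsets, emi):
            seq[offset] = base
        return "".join(seq)


def make_qct_pool(
    pool_id: str,
    qct_id_seq: str,
    config: AssayConfig,
    n_emi_bases: int | None = None,
) -> QCTPool:
    """Define a QCT pool template over the assay's amplicon geometry."""
    if n_emi_bases is not None and n_emi_bases != config.emi_length:
        raise ValueError(
            f"assay defines {config.emi_length} EMI bases, requested {n_emi_bases}"
        )
    if config.emi_length < 1:
        raise ValueError("at least one EMI base is required")
    id_span = set(
        range(config.qct_id_offset, config.qct_id_offset + len(qct_id_seq))
    )
    if id_span & set(config.emi_offsets):
        raise ValueError("QCT ID span overlaps the EMI positions")
    return QCTPool(pool_id=pool_id, qct_id_seq=qct_id_seq, config=config)


def demo_assay(alt_base: str = "T") -> AssayConfig:
    """A compact two-pool demonstration assay (80 bp amplicon).

    Mirrors the reference design: a 5-base pool ID (pools TCGCC and CTAGT,
    5 mismatches apart), 10 randomized EMI bases, and one interrogated
    variant locus.
    """
    ref = (
        "ACGTACGTACGTACGTACGTACGTACGTAC"  # 0-29: left arm / primer site
        "AAAAA"                            # 30-34: QCT ID slot
        "GGTCAGGTCA"                       # 35-44
        "TTTTTTTTTT"                       # 45-54: EMI slot (reference bases)
        "CCGGAACCGGTTAACCGGTTAACCG"        # 55-79: right arm
    )
    return AssayConfig(
        amplicon_name="demo_amplicon",
        reference_seq=ref,
        qct_id_offset=30,
        qct_ids={"QCT1": "TCGCC", "QCT2": "CTAGT"},
        emi_offsets=tuple(range(45, 55)),
        variant_loci=(VariantLocus(60, ref[60], alt_base, "rs_demo"),),
    )


def pools_from_config(config: AssayConfig) -> list[QCTPool]:
    return [
        make_qct_pool(pool, idseq, config)
        for pool, idseq in sorted(config.qct_ids.items())
    ]


# ---------------------------------------------------------------------------
# reaction simulation

@dataclass
class SimConfig:
    """Study conditions for one simulated PCR reaction.

    Defaults follow the reference regime: ~100 QCT molecules per pool per
    reaction, ~2000 amplifiable genomic molecules (the ~30 ng sheared-DNA
    scale), 30 reads per molecule, lognormal amplification bias wide enough
    to span ~8-fold molecule-to-molecule read depth, and no sequencing error
    unless requested.
    """

    n_qct_molecules_mean: float = 100.0
    n_goi_molecules: int = 2000
    depth_per_molecule_mean: float = 30.0
    amplification_bias_sd: float = 0.5
    seq_error_rate: float = 0.0
    goi_allele_fractions: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_qct_molecules_mean < 0:
            raise ValueError("Poisson mean must be >= 0")
        if not 0 <= self.seq_error_rate <= 1:
            raise ValueError("seq_error_rate must be in [0, 1]")
        if self.amplification_bias_sd < 0:
            raise ValueError("amplification_bias_sd must be >= 0")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the reads of one reaction."""

    sample_id: str
    qct_molecules: list[tuple[str, str, int]] = field(default_factory=list)
    n_goi_molecules: int = 0
    goi_allele_molecules: dict[str, int] = field(default_factory=dict)
    goi_read_depth_by_allele: dict[str, int] = field(default_factory=dict)
    contaminating_reads_received: dict[str, int] = field(default_factory=dict)

    @property
    def n_qct_molecules(self) -> int:
        return len(self.qct_molecules)

    @property
    def n_qct_molecules_observed(self) -> int:
        """Molecules that received at least one read."""
        return sum(1 for _, _, d in self.qct_molecules if d > 0)


def _molecule_depths(n: int, sim: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-molecule read depths: mean-preserving lognormal, rounded >= 0."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    sd = sim.amplification_bias_sd
    factors = np.exp(rng.normal(-sd * sd / 2.0, sd, size=n)) if sd > 0 else np.ones(n)
    return np.rint(sim.depth_per_molecule_mean * factors).astype(np.int64)


def _emit_reads(
    sequences: Sequence[str],
    depths: np.ndarray,
    error_rate: float,
    rng: np.random.Generator,
    name_prefix: str,
) -> list[FastqRead]:
    reads: list[FastqRead] = []
    counter = 0
    if not sequences:
        return reads
    length = len(sequences[0])
    for seq, depth in zip(sequences, depths):
        for _ in range(int(depth)):
            counter += 1
            reads.append(FastqRead(name=f"{name_prefix}:{counter}", sequence=seq))
    if error_rate > 0 and reads:
        n_err = rng.binomial(length, error_rate, size=len(reads))
        for i in np.nonzero(n_err)[0]:
            seq = bytearray(reads[i].sequence, "ascii")
            positions = rng.choice(length, size=n_err[i], replace=False)
            for pos in positions:
                shift = rng.integers(1, 4)
                current = np.searchsorted(BASES, seq[pos])
                seq[pos] = BASES[(current + shift) % 4]
            reads[i] = FastqRead(name=reads[i].name, sequence=seq.decode("ascii"))
    return reads


def _draw_goi_alleles(
    config: AssayConfig, sim: SimConfig, rng: np.random.Generator
) -> Counter[str]:
    fractions = sim.goi_allele_fractions
    if fractions is None:
        label = config.ref_allele_label()
        return Counter({label: sim.n_goi_molecules})
    labels = sorted(fractions)
    probs = np.array([fractions[l] for l in labels], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("allele fractions must sum to a positive value")
    probs = probs / probs.sum()
    counts = rng.multinomial(sim.n_goi_molecules, probs)
    return Counter({l: int(c) for l, c in zip(labels, counts) if c})


def _allele_sequence(config: AssayConfig, label: str) -> str:
    seq = list(config.reference_seq)
    for locus, base in zip(config.variant_loci, label):
        seq[locus.offset] = base
    return "".join(seq)


def simulate_reaction(
    pools: Sequence[QCTPool],
    config: AssayConfig,
    sim: SimConfig,
    seed_or_rng,
    *,
    sample_id: str = "sample",
) -> tuple[list[FastqRead], SimTruth]:
    """Simulate one PCR reaction: QCT + GOI molecules, bias, errors.

    The number of QCT molecules per pool is Poisson(``n_qct_molecules_mean``);
    every molecule's read depth is lognormal around ``depth_per_molecule_mean``
    and per-base substitution errors are applied i.i.d.
    """
    rng = _rng(seed_or_rng)
    truth = SimTruth(sample_id=sample_id)
    sequences: list[str] = []
    depths: list[int] = []

    for pool in pools:
        n = int(rng.poisson(sim.n_qct_molecules_mean))
        emis = pool.draw_emis(n, rng)
        mol_depths = _molecule_depths(n, sim, rng)
        for emi, depth in zip(emis, mol_depths):
            truth.qct_molecules.append((pool.pool_id, emi, int(depth)))
            sequences.append(pool.molecule_sequence(emi))
            depths.append(int(depth))

    allele_molecules = _draw_goi_alleles(config, sim, rng)
    truth.n_goi_molecules = sum(allele_molecules.values())
    truth.goi_allele_molecules = dict(sorted(allele_molecules.items()))
    for label in sorted(allele_molecules):
        n = allele_molecules[label]
        seq = _allele_sequence(config, label)
        mol_depths = _molecule_depths(n, sim, rng)
        truth.goi_read_depth_by_allele[label] = int(mol_depths.sum())
        sequences.extend([seq] * n)
        depths.extend(int(d) for d in mol_depths)

    reads = _emit_reads(
        sequences, np.asarray(depths), sim.seq_error_rate, rng, sample_id
    )
    return reads, truth


# ---------------------------------------------------------------------------
# plates: contamination and index misassignment

@dataclass
class PlateResult:
    reads_by_sample: dict[str, list[FastqRead]]
    truth_by_sample: dict[str, SimTruth]
    index_pairs: dict[str, tuple[str, str]]


def _index_pairs(sample_ids: Sequence[str], layout: str) -> dict[str, tuple[str, str]]:
    n = len(sample_ids)
    if layout == "dual_unique":
        return {s: (f"i5_{k:02d}", f"i7_{k:02d}") for k, s in enumerate(sample_ids)}
    if layout == "combinatorial":
        width = max(1, math.ceil(math.sqrt(n)))
        return {
            s: (f"i5_{k // width:02d}", f"i7_{k % width:02d}")
            for k, s in enumerate(sample_ids)
        }
    raise ValueError(f"unknown index layout {layout!r}")


def _contaminant_depth(rng: np.random.Generator) -> int:
    return 1 if rng.random() < CONTAMINANT_DEPTH_PROBS[0] else 2


def simulate_plate(
    sample_sims: Mapping[str, SimConfig],
    config: AssayConfig,
    seed: int,
    *,
    pools: Sequence[QCTPool] | None = None,
    contamination_matrix: np.ndarray | None = None,
    index_misassignment_rate: float = 0.0,
    index_layout: str = "dual_unique",
) -> PlateResult:
    """Simulate a multi-sample plate with cross-contamination and hopping.

    ``contamination_matrix[i, j]`` is the fraction of source sample i's QCT
    reads injected (as depth 1-2 copies of its molecules) into destination
    sample j; rows must sum to <= 1. Index misassignment swaps one index of
    a read at the given rate; for combinatorial layouts the swapped pair maps
    onto another sample on the plate, while for dual-unique layouts it forms
    an unused pair and the read is discarded during demultiplexing.
    """
    sample_ids = list(sample_sims)
    n = len(sample_ids)
    if contamination_matrix is not None:
        contamination_matrix = np.asarray(contamination_matrix, dtype=float)
        if contamination_matrix.shape != (n, n):
            raise ValueError("contamination matrix must be square over samples")
        if (contamination_matrix < 0).any():
            raise ValueError("contamination fractions must be >= 0")
        if (contamination_matrix.sum(axis=1) > 1 + 1e-12).any():
            raise ValueError("contamination matrix row sums exceed 1")
    if pools is None:
        pools = pools_from_config(config)

    seeds = np.random.SeedSequence(seed).spawn(n + 2)
    reads_by_sample: dict[str, list[FastqRead]] = {}
    truth_by_sample: dict[str, SimTruth] = {}
    for sid, child in zip(sample_ids, seeds):
        reads, truth = simulate_reaction(
            pools, config, sample_sims[sid], np.random.default_rng(child), sample_id=sid
        )
        reads_by_sample[sid] = reads
        truth_by_sample[sid] = truth

    pool_by_id = {p.pool_id: p for p in pools}

    if contamination_matrix is not None:
        rng = np.random.default_rng(seeds[n])
        qct_reads = {
            sid: sum(d for _, _, d in truth_by_sample[sid].qct_molecules)
            for sid in sample_ids
        }
        for i, src in enumerate(sample_ids):
            molecules = [m for m in truth_by_sample[src].qct_molecules if m[2] > 0]
            for j, dst in enumerate(sample_ids):
                frac = contamination_matrix[i, j]
                if i == j or frac == 0 or not molecules:
                    continue
                target = int(round(frac * qct_reads[src]))
                injected = 0
                k = 0
                # distinct source molecules leak, each at trace depth; only
                # once the source is exhausted do molecules repeat
                order: list[int] = []
                while injected < target:
                    if not order:
                        order = list(rng.permutation(len(molecules)))
                    pool_id, emi, _ = molecules[order.pop()]
                    depth = min(_contaminant_depth(rng), target - injected)
                    seq = pool_by_id[pool_id].molecule_sequence(emi)
                    for _ in range(depth):
                        k += 1
                        reads_by_sample[dst].append(
                            FastqRead(name=f"{dst}:contam:{k}", sequence=seq)
                        )
                    injected += depth
                truth_by_sample[dst].contaminating_reads_received[src] = (
                    truth_by_sample[dst].contaminating_reads_received.get(src, 0)
                    + injected
                )

    index_pairs = _index_pairs(sample_ids, index_layout)
    if index_misassignment_rate > 0:
        rng = np.random.default_rng(seeds[n + 1])
        pair_to_sample = {pair: sid for sid, pair in index_pairs.items()}
        i5_values = sorted({p[0] for p in index_pairs.values()})
        i7_values = sorted({p[1] for p in index_pairs.values()})
        moved: dict[str, list[FastqRead]] = {sid: [] for sid in sample_ids}
        for sid in sample_ids:
            kept: list[FastqRead] = []
            i5, i7 = index_pairs[sid]
            for read in reads_by_sample[sid]:
                if rng.random() >= index_misassignment_rate:
                    kept.append(read)
                    continue
                if rng.random() < 0.5:
                    new_pair = (i5_values[int(rng.integers(len(i5_values)))], i7)
                else:
                    new_pair = (i5, i7_values[int(rng.integers(len(i7_values)))])
                dest = pair_to_sample.get(new_pair)
                if dest is None or dest == sid:
                    continue  # unused pair: read lost in demultiplexing
                moved[dest].append(read)
                truth_by_sample[dest].contaminating_reads_received[sid] = (
                    truth_by_sample[dest].contaminating_reads_received.get(sid, 0) + 1
                )
            reads_by_sample[sid] = kept
        for sid in sample_ids:
            reads_by_sample[sid].extend(moved[sid])

    return PlateResult(
        reads_by_sample=reads_by_sample,
        truth_by_sample=truth_by_sample,
        index_pairs=index_pairs,
    )


# ---------------------------------------------------------------------------
# cfDNA allele mixtures and fragmentation

_GENOTYPE_DOSE = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2}


def genotype_dose(genotype: str) -> int:
    try:
        return _GENOTYPE_DOSE[genotype]
    except KeyError:
        raise ValueError(f"genotype must be 0/0, 0/1 or 1/1, got {genotype!r}")


@dataclass
class AlleleCounts:
    ref_molecules: int
    alt_molecules: int
    expected_fraction: float

    @property
    def n_molecules(self) -> int:
        return self.ref_molecules + self.alt_molecules

    @property
    def observed_fraction(self) -> float:
        return self.alt_molecules / self.n_molecules


def simulate_cfdna_counts(
    maternal_genotype: str,
    fetal_genotype: str,
    fetal_fraction: float,
    n_molecules: int,
    seed_or_rng,
) -> AlleleCounts:
    """Binomial molecule counts for a maternal/fetal cfDNA mixture.

    The variant-allele probability is
    p = (1 - ff) * dose_m / 2 + ff * dose_f / 2, and the variant molecule
    count is Binomial(n_molecules, p).
    """
    if not 0 <= fetal_fraction <= 1:
        raise ValueError("fetal fraction must be in [0, 1]")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    dose_m = genotype_dose(maternal_genotype)
    dose_f = genotype_dose(fetal_genotype)
    p = (1 - fetal_fraction) * dose_m / 2 + fetal_fraction * dose_f / 2
    alt = int(_rng(seed_or_rng).binomial(n_molecules, p))
    return AlleleCounts(
        ref_molecules=n_molecules - alt, alt_molecules=alt, expected_fraction=p
    )


def cfdna_allele_fractions(
    config: AssayConfig,
    maternal_genotype: str,
    fetal_genotype: str,
    fetal_fraction: float,
    *,
    locus: int = 0,
) -> dict[str, float]:
    """Per-allele molecule fractions for ``SimConfig.goi_allele_fractions``."""
    dose_m = genotype_dose(maternal_genotype)
    dose_f = genotype_dose(fetal_genotype)
    p = (1 - fetal_fraction) * dose_m / 2 + fetal_fraction * dose_f / 2
    return {
        config.ref_allele_label(): 1 - p,
        config.alt_allele_label(locus): p,
    }


def amplifiable_fraction(mean_fragment_len: float, span: int) -> float:
    """Probability a randomly sheared fragment spans the whole amplicon.

    Fragmentation is modeled as geometric with mean length L, so a molecule
    survives ``span`` consecutive positions unbroken with probability
    (1 - 1/L)^span.
    """
    if mean_fragment_len <= 1:
        raise ValueError("mean fragment length must exceed 1 bp")
    if span < 0:
        raise ValueError("span must be >= 0")
    return (1 - 1 / mean_fragment_len) ** span


def thin_amplifiable(
    n_molecules: int, mean_fragment_len: float, span: int, seed_or_rng
) -> int:
    """Number of sheared molecules that remain PCR-amplifiable."""
    p = amplifiable_fraction(mean_fragment_len, span)
    return int(_rng(seed_or_rng).binomial(n_molecules, p))


# ---------------------------------------------------------------------------
# fetal-fraction SNV panel

@dataclass
class PanelLocusTruth:
    locus: str
    maternal_genotype: str
    fetal_genotype: str
    informative: bool
    maf: float


def simulate_ff_panel(
    fetal_fraction: float,
    n_molecules_per_locus: int,
    seed_or_rng,
    *,
    n_snvs: int = 86,
    population_allele_freq: float = 0.3,
    seq_error_rate: float = 0.002,
) -> list[PanelLocusTruth]:
    """Simulate the multi-SNV fetal-fraction panel.

    Parental genotypes are drawn from Hardy-Weinberg at the given population
    frequency; the fetus receives one allele from each parent. Observed minor
    allele fractions are binomial over ``n_molecules_per_locus`` molecules
    with a symmetric per-molecule error floor. A locus is informative for
    fetal fraction when the mother is homozygous and the fetus carries the
    other allele (true MAF = ff/2).
    """
    rng = _rng(seed_or_rng)
    q = population_allele_freq
    out: list[PanelLocusTruth] = []
    for i in range(n_snvs):
        m_alleles = rng.random(2) < q
        p_alleles = rng.random(2) < q
        mat = int(m_alleles[0]) + int(m_alleles[1])
        m_transmit = m_alleles[int(rng.integers(2))]
        p_transmit = p_alleles[int(rng.integers(2))]
        fet = int(m_transmit) + int(p_transmit)
        gt = {0: "0/0", 1: "0/1", 2: "1/1"}
        p_alt = (1 - fetal_fraction) * mat / 2 + fetal_fraction * fet / 2
        p_obs = p_alt * (1 - seq_error_rate) + (1 - p_alt) * seq_error_rate
        x = rng.binomial(n_molecules_per_locus, p_obs) / n_molecules_per_locus
        maf = min(x, 1 - x)
        informative = mat in (0, 2) and fet == 1
        out.append(
            PanelLocusTruth(
                locus=f"snv{i:03d}",
                maternal_genotype=gt[mat],
                fetal_genotype=gt[fet],
                informative=informative,
                maf=float(maf),
            )
        )
    return out
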