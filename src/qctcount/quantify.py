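"""Allele-fraction and fetal-fraction quantification.

Covers the measurement layer between decoded read depths and the NIPT
caller: variant allele fractions with the fragmentation (shearing)
correction, Poisson counting noise, capture efficiency in genomic
equivalents per nanogram, classification of paternally inherited panel
SNVs, and the fetal-fraction estimate ff = 2 * median MAF of the chosen
paternally inherited loci.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .assay import AssayConfig
from .qct_core import ReadPartition

#: Theoretical haploid genome mass in picograms.
HAPLOID_GENOME_MASS_PG = 3.6

#: Paternal-inheritance classification band for panel SNV minor allele
#: fractions (inclusive bounds).
PATERNAL_MAF_BAND = (0.005, 0.20)


@dataclass
class AlleleMeasurement:
    """Variant allele fraction at one locus, optionally shear-corrected."""

    locus: str
    ref_depth: int
    alt_depth: int
    vaf: float
    shear_factor_applied: float = 1.0

    @property
    def total_depth(self) -> int:
        return self.ref_depth + self.alt_depth

    @property
    def maf(self) -> float:
        return min(self.vaf, 1 - self.vaf)


def allele_fraction(
    ref_depth: int,
    alt_depth: int,
    shear_factor: float = 1.0,
    *,
    locus: str = "",
) -> AlleleMeasurement:
    """VAF = shear_factor * alt / (ref + alt), clamped to [0, 1]."""
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("read depths must be non-negative")
    total = ref_depth + alt_depth
    if total == 0:
        raise ValueError("allele fraction undefined at zero total depth")
    vaf = min(1.0, max(0.0, shear_factor * alt_depth / total))
    return AlleleMeasurement(
        locus=locus,
        ref_depth=ref_depth,
        alt_depth=alt_depth,
        vaf=vaf,
        shear_factor_applied=shear_factor,
    )


def allele_depths(
    partition: ReadPartition, config: AssayConfig, locus: int = 0
) -> tuple[int, int]:
    """(ref, alt) read depths for one variant locus of a decoded partition."""
    variant = config.variant_loci[locus]
    ref = alt = 0
    for label, depth in partition.goi_read_depth_by_allele.items():
        base = label[locus]
        if base == variant.ref_base:
            ref += depth
        elif base == variant.alt_base:
            alt += depth
    return ref, alt


def shearing_correction(
    mean_fragment_len: float, span_long: int, span_short: int
) -> float:
    """Allele-fraction correction for a length-changing variant.

    Randomly sheared fragments with geometric length distribution of mean L
    span an amplicon of s consecutive bases with probability (1 - 1/L)^s, so
    the shorter allele of an indel is over-represented among amplifiable
    molecules by (1 - 1/L)^(span_long - span_short). Multiplying the raw
    fraction of the shorter allele by this factor (< 1) undoes the bias;
    only the span difference matters.
    """
    if mean_fragment_len <= 1:
        raise ValueError("mean fragment length must exceed 1 bp")
    if span_long < 1 or span_short < 1:
        raise ValueError("spans must be >= 1 bp")
    return (1 - 1 / mean_fragment_len) ** (span_long - span_short)


def poisson_cv(n_molecules: int) -> float:
    """Percent coefficient of variation from counting ``n`` molecules.

    Sampling N molecules is Poisson, so CV = 100/sqrt(N) percent, reported
    to one decimal.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    return round(100.0 / math.sqrt(n_molecules), 1)


def capture_efficiency(
    ge: float, mass_ng: float, haploid_mass_pg: float = HAPLOID_GENOME_MASS_PG
) -> tuple[float, float]:
    """(GE per ng, fraction of the theoretical maximum).

    The theoretical maximum is 1000/haploid_mass_pg GE/ng (~278 for a 3.6 pg
    haploid genome); fragmented DNA captures less because not every molecule
    spans both primer sites.
    """
    if mass_ng <= 0:
        raise ValueError("DNA mass must be positive")
    if ge < 0:
        raise ValueError("GE must be non-negative")
    ge_per_ng = ge / mass_ng
    theoretical_max = 1000.0 / haploid_mass_pg
    return ge_per_ng, ge_per_ng / theoretical_max


def theoretical_ge_per_ng(haploid_mass_pg: float = HAPLOID_GENOME_MASS_PG) -> float:
    return 1000.0 / haploid_mass_pg


def classify_paternal_snvs(
    per_snv_maf: Mapping[str, float],
    band: tuple[float, float] = PATERNAL_MAF_BAND,
) -> dict[str, float]:
    """Panel loci whose MAF falls in the paternally inherited band.

    A locus where the mother is homozygous but the fetus carries the other
    allele shows MAF ~ ff/2; MAFs below the band are error-level and MAFs
    above it maternal. Bounds are inclusive.
    """
    low, high = band
    for locus, maf in per_snv_maf.items():
        if not 0 <= maf <= 0.5:
            raise ValueError(f"MAF for {locus} outside [0, 0.5]: {maf}")
    return {
        locus: maf for locus, maf in per_snv_maf.items() if low <= maf <= high
    }


@dataclass
class FetalFractionEstimate:
    """Fetal fraction from the median MAF of paternally inherited loci."""

    per_snv_maf: dict[str, float]
    paternal_loci: list[str]
    epsilon_hat: float
    fetal_fraction: float
    adjustment_factor: float = 1.0
    reliable: bool = True

    @property
    def adjusted_fetal_fraction(self) -> float:
        return self.fetal_fraction * self.adjustment_factor


def fetal_fraction(
    classified: Mapping[str, float],
    n_loci: int = 9,
    adjustment: float = 1.0,
    loci: Sequence[str] | None = None,
) -> FetalFractionEstimate:
    """Estimate fetal fraction as 2 * median MAF over ``n_loci`` loci.

    By default the ``n_loci`` classified loci whose MAF is closest to the
    median of all classified MAFs are used (robust to stragglers at the band
    edges); pass ``loci`` to pin an explicit panel subset. With fewer than
    ``n_loci`` classified loci the estimate is computed from what is
    available but flagged unreliable.

    ``adjustment`` rescales the reported fetal fraction for assay-specific
    calibration (the HBB exon 1 assay uses 0.74); the unadjusted value is
    kept as ``fetal_fraction`` and the product exposed as
    ``adjusted_fetal_fraction``.
    """
    if not classified:
        raise ValueError("no classified paternally inherited loci")
    if loci is not None:
        missing = [l for l in loci if l not in classified]
        if missing:
            raise ValueError(f"requested loci not classified: {missing}")
        chosen = list(loci)
        reliable = len(chosen) >= n_loci
    else:
        center = statistics.median(classified.values())
        ranked = sorted(
            classified, key=lambda l: (abs(classified[l] - center), l)
        )
        chosen = sorted(ranked[:n_loci])
        reliable = len(classified) >= n_loci
    eps_hat = statistics.median(classified[l] for l in chosen)
    return FetalFractionEstimate(
        per_snv_maf=dict(classified),
        paternal_loci=chosen,
        epsilon_hat=eps_hat,
        fetal_fraction=2 * eps_hat,
        adjustment_factor=adjustment,
        reliable=reliable,
    )
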