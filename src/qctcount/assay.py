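"""Amplicon/QCT assay geometry.

An assay targets one amplicon. Synthetic Quantitative Counting Template (QCT)
molecules share the amplicon's primer-binding ends and length so they
co-amplify with the gene of interest; each spiked pool is distinguished by a
short fixed pool identifier (the QCT ID) at a known offset, and each molecule
within a pool by an Embedded Molecular Index (EMI) of randomized bases.

All coordinates are 0-based; spans are half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

DNA_BASES = frozenset("ACGT")


def _check_dna(seq: str, what: str) -> None:
    if not seq or set(seq) - DNA_BASES:
        raise ValueError(f"{what} must be a non-empty A/C/G/T string, got {seq!r}")


@dataclass(frozen=True)
class VariantLocus:
    """A biallelic variant position within the amplicon."""

    offset: int
    ref_base: str
    alt_base: str
    name: str = ""

    def __post_init__(self) -> None:
        _check_dna(self.ref_base, "ref_base")
        _check_dna(self.alt_base, "alt_base")
        if len(self.ref_base) != 1 or len(self.alt_base) != 1:
            raise ValueError("variant loci are single-base substitutions")
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt bases must differ")
        if self.offset < 0:
            raise ValueError("variant offset must be non-negative")


@dataclass(frozen=True)
class AssayConfig:
    """Geometry of one amplicon assay: reference, QCT pools, EMI, variants.

    Parameters
    ----------
    amplicon_name : str
        Label for the amplicon (e.g. the targeted exon).
    reference_seq : str
        Genomic reference sequence of the full amplicon.
    qct_id_offset : int
        0-based start of the QCT pool identifier within the amplicon.
    qct_ids : mapping of pool id -> identifier sequence
        Every spiked pool's fixed QCT ID. All IDs must share one length.
        Reads carrying one of these IDs at ``qct_id_offset`` are QCT reads.
    emi_offsets : sequence of int
        Positions of the randomized EMI bases (10 in the reference design).
    variant_loci : sequence of VariantLocus
        Positions interrogated for allele fractions; excluded from the
        mismatch count when matching gene-of-interest reads.
    """

    amplicon_name: str
    reference_seq: str
    qct_id_offset: int
    qct_ids: Mapping[str, str]
    emi_offsets: tuple[int, ...]
    variant_loci: tuple[VariantLocus, ...] = ()

    def __post_init__(self) -> None:
        _check_dna(self.reference_seq, "reference_seq")
        if not self.qct_ids:
            raise ValueError("at least one QCT pool identifier is required")
        lengths = {len(s) for s in self.qct_ids.values()}
        if len(lengths) != 1:
            raise ValueError("all QCT IDs must have the same length")
        for pool, seq in self.qct_ids.items():
            _check_dna(seq, f"QCT ID for pool {pool!r}")
        object.__setattr__(self, "qct_ids", dict(self.qct_ids))
        object.__setattr__(self, "emi_offsets", tuple(int(o) for o in self.emi_offsets))
        object.__setattr__(self, "variant_loci", tuple(self.variant_loci))
        n = self.amplicon_length
        id_span = set(range(self.qct_id_offset, self.qct_id_offset + self.qct_id_length))
        if self.qct_id_offset < 0 or max(id_span, default=0) >= n:
            raise ValueError("QCT ID span outside the amplicon")
        if len(set(self.emi_offsets)) != len(self.emi_offsets):
            raise ValueError("duplicate EMI offsets")
        if any(o < 0 or o >= n for o in self.emi_offsets):
            raise ValueError("EMI offsets outside the amplicon")
        if id_span & set(self.emi_offsets):
            raise ValueError("EMI offsets overlap the QCT ID span")
        for locus in self.variant_loci:
            if locus.offset >= n:
                raise ValueError(f"variant offset {locus.offset} outside the amplicon")
            if self.reference_seq[locus.offset] != locus.ref_base:
                raise ValueError(
                    f"reference base at offset {locus.offset} is "
                    f"{self.reference_seq[locus.offset]}, not {locus.ref_base}"
                )

    @property
    def amplicon_length(self) -> int:
        return len(self.reference_seq)

    @property
    def qct_id_length(self) -> int:
        return len(next(iter(self.qct_ids.values())))

    @property
    def emi_length(self) -> int:
        return len(self.emi_offsets)

    @property
    def min_qct_read_length(self) -> int:
        """Shortest read that can yield a pool ID and a complete EMI."""
        return max(self.qct_id_offset + self.qct_id_length, max(self.emi_offsets) + 1)

    def ref_allele_label(self) -> str:
        """Reference bases at the variant loci, concatenated in locus order."""
        return "".join(self.reference_seq[v.offset] for v in self.variant_loci)

    def alt_allele_label(self, locus: int = 0) -> str:
        """Allele label with the alt base substituted at one variant locus."""
        bases = [self.reference_seq[v.offset] for v in self.variant_loci]
        bases[locus] = self.variant_loci[locus].alt_base
        return "".join(bases)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "amplicon_name": self.amplicon_name,
            "reference_seq": self.reference_seq,
            "qct_id_offset": self.qct_id_offset,
            "qct_ids": dict(self.qct_ids),
            "emi_offsets": list(self.emi_offsets),
            "variant_loci": [
                {"offset": v.offset, "ref": v.ref_base, "alt": v.alt_base, "name": v.name}
                for v in self.variant_loci
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AssayConfig":
        loci = tuple(
            VariantLocus(int(v["offset"]), v["ref"], v["alt"], v.get("name", ""))
            for v in d.get("variant_loci", ())
        )
        return cls(
            amplicon_name=d["amplicon_name"],
            reference_seq=d["reference_seq"],
            qct_id_offset=int(d["qct_id_offset"]),
            qct_ids=dict(d["qct_ids"]),
            emi_offsets=tuple(int(o) for o in d["emi_offsets"]),
            variant_loci=loci,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "AssayConfig":
        """Load from YAML (or JSON, a YAML subset)."""
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
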