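"""End-to-end orchestration: decode -> integrity -> quantify -> call.

The pipeline is driven by a run manifest: an assay config plus a sample
sheet (TSV) with one row per sample. Required sample-sheet columns are
``sample_id`` and ``fastq``; optional ``maternal_gt`` and ``fetal_fraction``
columns enable NIPT calling on the decoded measurements. Outputs are
diff-able TSV/JSON files; re-running with identical inputs produces
byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assay import AssayConfig
from .integrity import collision_matrix, detect_contamination, flag_mixups
from .niptcall import call_table
from .qct_core import SampleDecode, decode_sample, read_fastq
from .quantify import allele_depths, allele_fraction

logger = logging.getLogger(__name__)


class ManifestError(ValueError):
    """Raised for malformed or inconsistent run manifests."""


@dataclass
class RunManifest:
    """Everything a pipeline run needs: assay, samples, global options."""

    assay: AssayConfig
    samples: pd.DataFrame
    qct_mismatch_budget: int = 0
    goi_mismatch_budget: int = 3
    shear_factor: float = 1.0
    adjustment: float = 0.74
    s_err: float = 0.005
    min_molecules: int = 200
    max_contamination: float = 0.05
    min_collisions: int = 10

    def __post_init__(self) -> None:
        required = {"sample_id", "fastq"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ManifestError(f"sample sheet missing columns: {sorted(missing)}")
        if self.samples.empty:
            raise ManifestError("sample sheet has no samples")
        ids = self.samples["sample_id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ManifestError(f"duplicate sample ids: {dupes}")

    @classmethod
    def from_files(
        cls, assay_path: str | Path, sample_sheet_path: str | Path, **options
    ) -> "RunManifest":
        assay = AssayConfig.from_file(assay_path)
        sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype={"sample_id": str})
        manifest = cls(assay=assay, samples=sheet, **options)
        base = Path(sample_sheet_path).parent
        for raw in sheet["fastq"]:
            path = Path(raw)
            if not path.is_absolute():
                path = base / path
            if not path.exists():
                raise ManifestError(f"FASTQ file not found: {path}")
        return manifest


@dataclass
class RunReport:
    """In-memory pipeline products, written out by :func:`write_report`."""

    qct_summary: pd.DataFrame
    fingerprints: dict[str, list[str]]
    contamination: pd.DataFrame
    collisions: pd.DataFrame
    mixup_pairs: list[tuple[str, str]]
    allele_fractions: pd.DataFrame
    nipt_calls: pd.DataFrame | None
    qc_failures: list[str]
    metadata: dict = field(default_factory=dict)


def _decode_all(manifest: RunManifest, base: Path | None) -> dict[str, SampleDecode]:
    decoded = {}
    for rec in manifest.samples.to_dict("records"):
        sid = str(rec["sample_id"])
        path = Path(rec["fastq"])
        if base is not None and not path.is_absolute():
            path = base / path
        reads = list(read_fastq(path))
        decoded[sid] = decode_sample(
            reads,
            manifest.assay,
            sample_id=sid,
            qct_mismatch_budget=manifest.qct_mismatch_budget,
            goi_mismatch_budget=manifest.goi_mismatch_budget,
        )
        logger.info(
            "decoded %s: %d molecules, %d GOI reads",
            sid,
            decoded[sid].summary.n_molecules,
            decoded[sid].partition.goi_read_count,
        )
    return decoded


def run_pipeline(
    manifest: RunManifest, *, fastq_base: str | Path | None = None
) -> RunReport:
    """Decode every sample, screen integrity, quantify, and (optionally) call."""
    base = Path(fastq_base) if fastq_base is not None else None
    decoded = _decode_all(manifest, base)

    summary_rows = []
    ge_by_sample: dict[str, float] = {}
    qc_failures: list[str] = []
    for sid, dec in decoded.items():
        ge = dec.count.genomic_equivalents if dec.count else float("nan")
        ge_by_sample[sid] = ge
        summary_rows.append(
            {
                "sample_id": sid,
                "n_qct": dec.summary.n_molecules,
                "mean_depth_per_molecule": dec.summary.mean_depth_per_molecule,
                "depth_threshold": dec.summary.depth_threshold,
                "goi_depth": dec.partition.goi_read_count,
                "genomic_equivalents": ge,
            }
        )
        if not dec.summary.qc_pass or (
            dec.count and ge < manifest.min_molecules
        ):
            qc_failures.append(sid)

    contamination_reports = detect_contamination(
        {sid: dec.clusters for sid, dec in decoded.items()}
    )
    contamination = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "contamination_fraction": r.contamination_fraction,
                "top_source": r.top_source or "",
                "top_source_reads": r.per_source.get(r.top_source, 0.0)
                if r.top_source
                else 0.0,
                "unattributed_low_depth_reads": r.unattributed_low_depth_reads,
            }
            for r in contamination_reports
        ]
    )
    for r in contamination_reports:
        if r.contamination_fraction > manifest.max_contamination:
            qc_failures.append(r.sample_id)

    matrix = collision_matrix(
        {sid: dec.summary.fingerprint for sid, dec in decoded.items()}
    )
    collisions = pd.DataFrame(
        matrix.counts, index=matrix.samples, columns=matrix.samples
    )
    mixups = flag_mixups(matrix, min_collisions=manifest.min_collisions)
    for a, b in mixups:
        qc_failures.extend([a, b])

    af_rows = []
    for sid, dec in decoded.items():
        for k, locus in enumerate(manifest.assay.variant_loci):
            ref, alt = allele_depths(dec.partition, manifest.assay, k)
            if ref + alt == 0:
                continue
            meas = allele_fraction(
                ref, alt, manifest.shear_factor, locus=locus.name or f"locus{k}"
            )
            af_rows.append(
                {
                    "sample_id": sid,
                    "locus": meas.locus,
                    "ref_depth": ref,
                    "alt_depth": alt,
                    "vaf": meas.vaf,
                }
            )
    allele_fractions = pd.DataFrame(af_rows)

    nipt_calls = None
    sheet = manifest.samples.assign(sample_id=manifest.samples["sample_id"].astype(str))
    if {"maternal_gt", "fetal_fraction"} <= set(sheet.columns) and af_rows:
        first_locus = allele_fractions.drop_duplicates("sample_id", keep="first")
        merged = sheet.merge(first_locus[["sample_id", "vaf"]], on="sample_id")
        merged["n_molecules"] = [
            int(round(ge_by_sample[sid])) for sid in merged["sample_id"]
        ]
        callable_rows = merged[merged["n_molecules"] >= 1]
        if not callable_rows.empty:
            nipt_calls = call_table(
                callable_rows,
                adjustment=manifest.adjustment,
                s_err=manifest.s_err,
                min_molecules=manifest.min_molecules,
            )

    qc_failures = sorted(set(qc_failures))
    metadata = {
        "tool_version": __version__,
        "assay_config_sha256": hashlib.sha256(
            json.dumps(manifest.assay.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "n_samples": len(decoded),
        "qc_failures": qc_failures,
    }
    return RunReport(
        qct_summary=pd.DataFrame(summary_rows),
        fingerprints={
            sid: sorted(dec.summary.fingerprint) for sid, dec in decoded.items()
        },
        contamination=contamination,
        collisions=collisions,
        mixup_pairs=mixups,
        allele_fractions=allele_fractions,
        nipt_calls=nipt_calls,
        qc_failures=qc_failures,
        metadata=metadata,
    )


def write_report(report: RunReport, out_dir: str | Path) -> None:
    """Write all pipeline products as TSV/JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.6g"
    report.qct_summary.to_csv(out / "qct_summary.tsv", sep="\t", index=False, float_format=fmt)
    report.contamination.to_csv(out / "contamination.tsv", sep="\t", index=False, float_format=fmt)
    report.collisions.to_csv(out / "collisions.tsv", sep="\t", float_format=fmt)
    report.allele_fractions.to_csv(out / "allele_fractions.tsv", sep="\t", index=False, float_format=fmt)
    if report.nipt_calls is not None:
        report.nipt_calls.to_csv(out / "nipt_calls.tsv", sep="\t", index=False, float_format=fmt)
    (out / "fingerprints.json").write_text(
        json.dumps(report.fingerprints, indent=2, sort_keys=True) + "\n"
    )
    (out / "run_metadata.json").write_text(
        json.dumps(report.metadata, indent=2, sort_keys=True) + "\n"
    )
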