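"""Binomial likelihood-ratio engine for single-gene NIPT.

Two inheritance tracks share one measurement tuple (allele fraction x,
molecule count N, fetal fraction ff):

* Paternal track (mother homozygous): is a low-level non-maternal allele a
  paternally inherited fetal allele or sequencing error? With
  epsilon = adjustment * ff / 2 the expected non-maternal fraction under
  paternal inheritance, and s_err the sequencing error rate,

      log LR = N x ln(epsilon / s_err) + N (1 - x) ln((1-epsilon)/(1-s_err))

  where x is the non-maternal allele fraction. The binomial coefficients of
  the two likelihoods cancel, so N x need not be an integer.

* Recessive track (mother heterozygous): is the fetus homozygous for the
  variant (expected VAF 1/2 + epsilon) or heterozygous (VAF 1/2)?

      log LR = N x ln(1 + 2 epsilon) + N (1 - x) ln(1 - 2 epsilon)

Calls require the LR to strictly exceed 8 (or fall below 1/8); the open
band in between is a no-call. All arithmetic is in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable

import numpy as np
import pandas as pd

from .simdata import genotype_dose

LN10 = math.log(10.0)

DEFAULT_S_ERR = 0.005
DEFAULT_ADJUSTMENT = 0.74
DEFAULT_LR_HI = 8.0
DEFAULT_LR_LO = 1.0 / 8.0
DEFAULT_MIN_MOLECULES = 200

CALL_HET = "het"
CALL_HOM_MATCHING = "hom-matching-mother"
CALL_AFFECTED = "affected"
CALL_NORMAL = "normal"
NO_CALL = "no-call"


def expected_vaf(
    fetal_fraction: float, maternal_genotype: str, fetal_genotype: str
) -> float:
    """Expected cfDNA variant allele fraction for a genotype pair.

    p = (1 - ff) * dose_m / 2 + ff * dose_f / 2; e.g. a heterozygous mother
    carrying a homozygous-variant fetus at 10% fetal fraction gives 0.55.
    """
    if not 0 <= fetal_fraction <= 1:
        raise ValueError("fetal fraction must be in [0, 1]")
    dose_m = genotype_dose(maternal_genotype)
    dose_f = genotype_dose(fetal_genotype)
    return (1 - fetal_fraction) * dose_m / 2 + fetal_fraction * dose_f / 2


@dataclass
class NIPTInput:
    """One sample's measurements entering the likelihood-ratio model."""

    maternal_genotype: str
    x: float
    n_molecules: int
    fetal_fraction: float
    sample_id: str = ""
    adjustment: float = DEFAULT_ADJUSTMENT
    s_err: float = DEFAULT_S_ERR

    def __post_init__(self) -> None:
        genotype_dose(self.maternal_genotype)
        if not 0 <= self.x <= 1:
            raise ValueError("allele fraction x must be in [0, 1]")
        if self.n_molecules < 1:
            raise ValueError("molecule count must be >= 1")
        if not 0 < self.fetal_fraction < 1:
            raise ValueError("fetal fraction must be in (0, 1)")
        if not 0 < self.s_err < 0.5:
            raise ValueError("s_err must be in (0, 0.5)")

    @property
    def epsilon(self) -> float:
        """Expected fetal minor-allele fraction, epsilon = adjustment*ff/2."""
        return self.adjustment * self.fetal_fraction / 2


def _finite_lr(log_lr: float) -> float:
    try:
        return math.exp(log_lr)
    except OverflowError:
        return math.inf


@dataclass
class LRPair:
    log_lr: float

    @property
    def log10_lr(self) -> float:
        return self.log_lr / LN10

    @property
    def lr(self) -> float:
        return _finite_lr(self.log_lr)

    @property
    def reciprocal_lr(self) -> float:
        return _finite_lr(-self.log_lr)


def lr_paternal(inp: NIPTInput) -> LRPair:
    """LR of paternal inheritance vs sequencing error (mother homozygous).

    ``LRPair.lr`` is P(paternal)/P(error); ``reciprocal_lr`` is the
    error-vs-paternal orientation some reports print.
    """
    dose = genotype_dose(inp.maternal_genotype)
    if dose == 1:
        raise ValueError("paternal track requires a homozygous mother")
    eps = inp.epsilon
    if not 0 < eps < 1:
        raise ValueError(f"epsilon out of range: {eps}")
    x_eff = inp.x if dose == 0 else 1 - inp.x
    n = inp.n_molecules
    log_lr = n * x_eff * math.log(eps / inp.s_err) + n * (1 - x_eff) * math.log(
        (1 - eps) / (1 - inp.s_err)
    )
    return LRPair(log_lr=log_lr)


def lr_recessive(inp: NIPTInput) -> LRPair:
    """LR of an affected (homozygous-variant) vs heterozygous fetus.

    Requires a heterozygous mother; equals p_aff/p_het for binomial
    likelihoods centered at 1/2 + epsilon and 1/2.
    """
    if genotype_dose(inp.maternal_genotype) != 1:
        raise ValueError("recessive track requires a heterozygous mother")
    eps = inp.epsilon
    if not 0 <= 2 * eps < 1:
        raise ValueError(f"2*epsilon must be < 1, got {2 * eps}")
    n = inp.n_molecules
    log_lr = n * inp.x * math.log1p(2 * eps) + n * (1 - inp.x) * math.log1p(-2 * eps)
    return LRPair(log_lr=log_lr)


@dataclass
class NIPTResult:
    """Likelihood ratios, categorical call and predicted fetal genotype."""

    input: NIPTInput
    track: str
    log10_lr: float
    call: str
    predicted_genotype: str | None
    lr_hi: float = DEFAULT_LR_HI
    lr_lo: float = DEFAULT_LR_LO
    qc_pass: bool = True

    @property
    def lr(self) -> float:
        return _finite_lr(self.log10_lr * LN10)

    @property
    def lr_reciprocal(self) -> float:
        return _finite_lr(-self.log10_lr * LN10)

    def concordant_with(self, neonate_genotype: str) -> bool:
        """Does the call agree with a confirmed neonate genotype?"""
        if self.call == NO_CALL:
            return False
        if self.track == "paternal":
            return self.predicted_genotype == neonate_genotype
        affected = genotype_dose(neonate_genotype) == 2
        return (self.call == CALL_AFFECTED) == affected


def call(
    inp: NIPTInput,
    *,
    lr_hi: float = DEFAULT_LR_HI,
    lr_lo: float = DEFAULT_LR_LO,
    min_molecules: int = DEFAULT_MIN_MOLECULES,
) -> NIPTResult:
    """Apply the LR decision rule with a no-call band and a QC gate.

    Heterozygous mother -> recessive track: affected if LR > lr_hi, normal
    if LR < lr_lo, otherwise no-call. Homozygous mother -> paternal track:
    fetus heterozygous if the paternal-vs-error LR > lr_hi, fetus matching
    the mother if it is < lr_lo, otherwise no-call. Boundary values are
    no-calls; samples under ``min_molecules`` genomic equivalents are
    no-calls on QC grounds.
    """
    if not lr_lo < 1 < lr_hi:
        raise ValueError("thresholds must satisfy lr_lo < 1 < lr_hi")
    dose = genotype_dose(inp.maternal_genotype)
    track = "recessive" if dose == 1 else "paternal"
    pair = lr_recessive(inp) if track == "recessive" else lr_paternal(inp)
    qc_pass = inp.n_molecules >= min_molecules

    verdict = NO_CALL
    predicted: str | None = None
    if qc_pass:
        if pair.log_lr > math.log(lr_hi):
            verdict = CALL_AFFECTED if track == "recessive" else CALL_HET
            predicted = "1/1" if track == "recessive" else "0/1"
        elif pair.log_lr < math.log(lr_lo):
            verdict = CALL_NORMAL if track == "recessive" else CALL_HOM_MATCHING
            predicted = None if track == "recessive" else inp.maternal_genotype
    return NIPTResult(
        input=inp,
        track=track,
        log10_lr=pair.log10_lr,
        call=verdict,
        predicted_genotype=predicted,
        lr_hi=lr_hi,
        lr_lo=lr_lo,
        qc_pass=qc_pass,
    )


# ---------------------------------------------------------------------------
# tabular interface

def load_validation_cohort() -> pd.DataFrame:
    """Published clinical validation measurements for HBB rs713040 NIPT.

    27 pregnancies with newborn genotype follow-up: per sample the measured
    fetal fraction, variant allele fraction, molecule count, the published
    likelihood ratio (error-vs-paternal orientation on the paternal track,
    affected-vs-het on the recessive track), the published call, and the
    confirmed neonate genotype.
    """
    path = resources.files("qctcount") / "data" / "rs713040_nipt_cohort.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype={"sample_id": str})


def call_table(
    table: pd.DataFrame,
    *,
    adjustment: float = DEFAULT_ADJUSTMENT,
    s_err: float = DEFAULT_S_ERR,
    lr_hi: float = DEFAULT_LR_HI,
    lr_lo: float = DEFAULT_LR_LO,
    min_molecules: int = DEFAULT_MIN_MOLECULES,
) -> pd.DataFrame:
    """Run the caller over a measurement table.

    Expects columns sample_id, maternal_gt, vaf, n_molecules, fetal_fraction;
    appends track, log10_lr, lr, call, predicted_genotype, qc_pass and, when
    a neonate_gt column is present, concordant.
    """
    required = {"sample_id", "maternal_gt", "vaf", "n_molecules", "fetal_fraction"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    rows = []
    for rec in table.to_dict("records"):
        inp = NIPTInput(
            sample_id=str(rec["sample_id"]),
            maternal_genotype=rec["maternal_gt"],
            x=float(rec["vaf"]),
            n_molecules=int(rec["n_molecules"]),
            fetal_fraction=float(rec["fetal_fraction"]),
            adjustment=adjustment,
            s_err=s_err,
        )
        res = call(inp, lr_hi=lr_hi, lr_lo=lr_lo, min_molecules=min_molecules)
        row = dict(rec)
        row.update(
            track=res.track,
            log10_lr=res.log10_lr,
            lr=res.lr,
            call=res.call,
            predicted_genotype=res.predicted_genotype,
            qc_pass=res.qc_pass,
        )
        if "neonate_gt" in rec and isinstance(rec["neonate_gt"], str):
            row["concordant"] = res.concordant_with(rec["neonate_gt"])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Monte-Carlo performance

@dataclass
class PerformanceSummary:
    sensitivity: float
    specificity: float
    no_call_rate: float
    n_sims: int
    n_affected: int
    n_called: int


def monte_carlo_performance(
    n_sims: int,
    seed: int,
    *,
    carrier_rate: float = 1 / 12,
    fetal_fraction: float | Callable[[np.random.Generator], float] = 0.10,
    n_molecules: int | Callable[[np.random.Generator], int] = 3500,
    adjustment: float = DEFAULT_ADJUSTMENT,
    s_err: float = DEFAULT_S_ERR,
    lr_hi: float = DEFAULT_LR_HI,
    lr_lo: float = DEFAULT_LR_LO,
    min_molecules: int = DEFAULT_MIN_MOLECULES,
) -> PerformanceSummary:
    """Sensitivity/specificity of the recessive track over simulated pregnancies.

    Each simulation draws a carrier (heterozygous) mother, a father who is a
    carrier with probability ``carrier_rate``, a Mendelian fetal genotype,
    and a binomial allele count at the fetus-implied expected VAF; the
    recessive caller is applied. Sensitivity and specificity are computed
    among called samples; the no-call rate is reported separately.
    ``fetal_fraction`` and ``n_molecules`` may be constants or samplers
    taking the generator.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)

    ff = (
        np.array([fetal_fraction(rng) for _ in range(n_sims)])
        if callable(fetal_fraction)
        else np.full(n_sims, float(fetal_fraction))
    )
    n_mol = (
        np.array([n_molecules(rng) for _ in range(n_sims)])
        if callable(n_molecules)
        else np.full(n_sims, int(n_molecules))
    ).astype(np.int64)

    father_carrier = rng.random(n_sims) < carrier_rate
    maternal_allele = rng.integers(0, 2, n_sims)  # mother het: 1 w.p. 1/2
    paternal_allele = np.where(
        father_carrier, rng.integers(0, 2, n_sims), 0
    )
    fetal_dose = maternal_allele + paternal_allele
    affected = fetal_dose == 2

    p = (1 - ff) * 0.5 + ff * fetal_dose / 2
    x = rng.binomial(n_mol, p) / n_mol

    eps = adjustment * ff / 2
    if np.any(2 * eps >= 1):
        raise ValueError("2*epsilon must stay below 1")
    log_lr = n_mol * x * np.log1p(2 * eps) + n_mol * (1 - x) * np.log1p(-2 * eps)

    qc = n_mol >= min_molecules
    called_affected = qc & (log_lr > math.log(lr_hi))
    called_normal = qc & (log_lr < math.log(lr_lo))
    called = called_affected | called_normal

    n_called = int(called.sum())
    pos = affected & called
    neg = ~affected & called
    sensitivity = (
        float(called_affected[pos].sum() / pos.sum()) if pos.any() else float("nan")
    )
    specificity = (
        float(called_normal[neg].sum() / neg.sum()) if neg.any() else float("nan")
    )
    return PerformanceSummary(
        sensitivity=sensitivity,
        specificity=specificity,
        no_call_rate=1 - n_called / n_sims,
        n_sims=n_sims,
        n_affected=int(affected.sum()),
        n_called=n_called,
    )
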