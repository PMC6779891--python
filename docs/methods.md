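# Methods

This note documents the models, defaults and numerical choices behind
`qctcount`, and what the synthetic-data tests do and do not demonstrate.

## Decoding model

**Read partition.** A read is a QCT observation iff it carries a configured
pool ID at the ID offset; the default mismatch budget is 0 (exact match),
which is safe because pool IDs are designed ≥ 5 mismatches apart and a
5-base window has little room for coincidence. Non-QCT reads are
gene-of-interest (GOI) reads if they match the amplicon reference within 3
mismatches, with the interrogated variant positions excluded from the
count; everything else (including reads too short to cover the configured
offsets) is unmatched. Direct reference comparison replaces genome
alignment: amplicon assays have a known reference, and per-read comparison
is exact and fast (the implementation vectorizes the common full-length
case with numpy).

**EMI clustering.** Clusters are the connected components of the graph
joining EMI pairs within Hamming distance 2 (single linkage), computed per
pool with `scipy.sparse.csgraph.connected_components` over a chunked
pairwise distance matrix. Consensus is the highest-count member, ties
broken lexicographically; output order is (depth descending, consensus),
so the result is independent of input order. Member-vs-member (rather than
consensus-vs-member) distance was chosen because it is order-free and has a
clean graph characterization; the unit tests pin it against an independent
all-pairs union-find oracle.

**Threshold.** `t = sqrt(mean cluster depth)`, mean over *all* clusters,
computed once without iteration; a cluster is a molecule iff its depth is
strictly greater than `t`. The depth distribution is strongly bimodal
(tens of reads for real molecules vs 1–2 for error/contaminant clusters),
so the boundary convention is immaterial in practice but fixed for
determinism.

**⟨D_QCT⟩ and GE.** ⟨D_QCT⟩ is the mean depth of the *high* clusters only
— low clusters are errors and contaminants, not molecules — while the
threshold mean uses all clusters. `GE = D_GOI / ⟨D_QCT⟩`. With zero high
clusters the sample fails QC and GE is undefined (raised as an error, never
reported as 0).

**Known bias: EMI collisions.** Two random 10-mers fall within Hamming 2
with probability ≈ 4.2e-4, so with `m` molecules per pool roughly
`m²/2 · 4.2e-4` cluster pairs merge (≈ 2 at m = 100, ≈ 8 at m = 200), and
error satellites can chain a few more. Molecule counts are therefore biased
low by ~2–6% in the 100–400 molecule regime; GE is much less affected
because the merged clusters' reads inflate ⟨D_QCT⟩ roughly in proportion.
Tolerances in the simulation tests account for this.

## Simulator

The generator emulates the study conditions end to end and is bit-for-bit
reproducible from (config, seed):

* **Molecule counts.** QCT molecules per pool ~ Poisson(mean), default mean
  100 (the "1x" spike level); GOI molecules fixed (default 2000, the ~30 ng
  sheared-DNA scale).
* **Amplification bias.** Per-molecule read depth is a mean-preserving
  lognormal around `depth_per_molecule_mean` (default 30 reads/molecule)
  with log-scale sd `amplification_bias_sd` (default 0.5, giving a
  molecule-to-molecule depth spread of order 8-fold); no published
  distributional form exists for this bias, so lognormal is an
  implementation choice surfaced in the config.
* **Errors.** i.i.d. per-base substitutions at `seq_error_rate`; FASTQ
  quality strings are constant Q30 and ignored by the decoder.
* **Contamination.** `matrix[src, dst]` is the fraction of the source's QCT
  reads injected into the destination as copies of *distinct* source
  molecules at trace depth (1 read with p = 0.985, else 2). The singleton
  share is calibrated so that a well receiving only contamination detects
  > 90% of it: under the sqrt-mean threshold such a well can only flag its
  singleton clusters, and a few percent of reads are additionally lost to
  chance EMI merges and to source-side merges that displace an EMI from its
  fingerprint.
* **Index misassignment.** Each read hops with the given rate by swapping
  one of its two indexes for another in use. On combinatorial (TruSeq-style)
  layouts the new pair usually belongs to another sample; on dual-unique
  layouts it is unused and the read is discarded at demultiplexing — which
  is exactly why dual-unique indexing suppresses measured contamination.
* **cfDNA mixtures.** Variant-allele probability
  `p = (1−ff)·dose_m/2 + ff·dose_f/2`; molecule counts are Binomial(N, p).
* **Fragmentation.** Amplifiable molecules survive a span of `s` bases with
  probability `(1 − 1/L)^s` (geometric fragment-length model, L = mean
  fragment length); the same model yields the shearing correction factor
  `(1 − 1/L)^(Δspan)` for length-changing variants, e.g. 0.980 for a 3 bp
  deletion at L = 150.
* **Fetal-fraction panel.** 86 SNVs at population frequency 0.3 under
  Hardy–Weinberg, Mendelian fetal genotypes, binomial MAFs over 2000
  molecules per locus with a 0.2% symmetric error floor — below the 0.5%
  classification band edge, as the band presumes.

**What the simulator does not model:** PCR chimeras and jackpot molecules
beyond the lognormal, instrument-specific error profiles or quality decay,
paired-end structure (the decoder consumes single sequences), primer
artifacts, and GC-dependent amplification. Passing tests therefore show the
*analysis* is correct and well-calibrated under the stated noise model, not
that real libraries meet that model.

## Integrity screens

A contaminant is a low-depth cluster whose consensus EMI is high-depth in
another reaction; attribution is split equally across tied sources (the
choice is arbitrary but rarely exercised: ~100 random 10-mers collide
between fingerprints with probability ~1e-2). Matching uses exact consensus
equality — fingerprints are post-clustering consensus strings, so a second
fuzzy match would double-count the error model. Mixup flagging uses a
default of 10 shared high-depth clusters, sitting in the wide gap between
the ~0 collisions of independent reactions and the ~150 of a re-indexed
library; it is configurable.

## Fetal fraction and calling

Panel SNVs with MAF in [0.5%, 20%] (inclusive; the interval's openness is
otherwise unspecified) are classified paternally inherited. The estimate is
`ff = 2 · median(MAF)` over 9 loci; when more than 9 classify, the 9 with
MAF closest to the median of all classified MAFs are used (robust to
band-edge stragglers), and an explicit locus list can be pinned instead.
With fewer than 9 the estimate is still computed but flagged unreliable.
The 0.74 assay adjustment is kept separate from the raw panel estimate:
both values are reported, and the caller applies `ε = 0.74 · ff / 2` on
both tracks — the convention that reproduces the published worked examples
(recessive rows to ≤ 0.3 log10, e.g. LR ≈ 1.8e14 at ff = 0.219, x = 0.603,
N = 1611).

All likelihood ratios are computed in log space (no overflow up to N = 1e7;
the validation cohort spans 1e-44 to 1e84 on the linear scale). Binomial
coefficients cancel in every ratio, so `N·x` need not be integral and no
rounding of successes occurs. Calls require strict threshold exceedance
(LR exactly 8 is a no-call), and samples under 200 GE are no-calls on QC
grounds regardless of their LR.

On the paternal track the published LRs of six cohort samples with VAF ≥
0.998 are not recomputable from their 3-decimal printed inputs: the
evidence term is proportional to `N·(1−VAF)` with `1−VAF ≈ 0.002`, so the
last printed digit of the VAF moves the log-LR by more than a full decade.
The tests assert numeric agreement on the 21 samples where the printed
precision permits it and call agreement on all 27 (the calls are orders of
magnitude away from the thresholds either way).

The Monte-Carlo performance simulator draws a carrier mother, a father who
carries with the configured rate (default 1/12), a Mendelian fetus, and a
binomial allele count; sensitivity and specificity are computed among
called samples with the no-call rate reported separately (the alternative
convention — counting no-calls as errors — is a one-line change at the
caller). Published sensitivity/specificity figures depend on cohort
parameters that are not available, so the simulator exposes them as
configuration rather than hard-coding a scenario.

## Problem sizes in the test suite

Simulation-backed tests run at reduced but regime-faithful sizes chosen as
a deliberate trade-off between statistical resolution and turnaround:
spike-in recovery uses 24 replicates per dilution at 12 reads/molecule;
pool-agreement uses 300 molecules/pool at 40 reads/molecule under
bias sd 0.75; plates use 4–12 samples; the Monte-Carlo regime check uses
10,000 simulations. Assertions use tolerances derived from the Poisson or
binomial noise of those sizes plus the merge bias above.
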