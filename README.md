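# qctcount

Absolute molecular counting for amplicon sequencing with Quantitative
Counting Templates (QCTs), and a likelihood-ratio caller for single-gene
noninvasive prenatal testing (NIPT).

## The problem

Amplicon NGS read depth is a poor proxy for the number of input DNA
molecules: PCR and library preparation introduce multi-fold biases, so
applications that need real molecule counts — fetal genotyping from cell-free
DNA (cfDNA), liquid biopsy, copy-number calls — cannot rely on depth alone.
QCTs solve this by spiking a known *kind* (not number) of synthetic molecule
into the reaction before amplification. Each QCT co-amplifies with the gene
of interest (GOI), carries a fixed 5-base pool identifier (QCT ID), and an
Embedded Molecular Index (EMI) of 10 randomized bases that uniquely labels
every spiked molecule and all of its PCR progeny. After sequencing:

1. reads carrying a QCT ID are grouped into EMI clusters (single-linkage,
   Hamming distance ≤ 2) so sequencing errors collapse onto their parent
   molecule;
2. clusters are split at a read-depth threshold `t = sqrt(mean cluster
   depth)`; the high-depth clusters are the spiked molecules, and their mean
   depth ⟨D_QCT⟩ is the reads-per-molecule exchange rate of this reaction;
3. the input molecule count of the gene is `GE = D_GOI / ⟨D_QCT⟩` (haploid
   genomic equivalents).

The same machinery yields two integrity screens: a reaction's *fingerprint*
(its set of high-depth EMIs) is essentially unique, so a low-depth cluster
matching another reaction's fingerprint is quantifiable cross-contamination
with a known source, and two reactions sharing many high-depth clusters
(*collisions*) expose a barcoding mixup.

For NIPT, the measured variant allele fraction `x`, molecule count `N` and
fetal fraction `ff` feed binomial likelihood ratios with
`ε = adjustment · ff / 2` (assay adjustment 0.74 for the HBB exon 1 assay)
and sequencing-error rate `s = 0.005`:

* paternal track (mother homozygous, `x` = non-maternal allele fraction):
  `log LR = N x ln(ε/s) + N(1−x) ln((1−ε)/(1−s))`
* recessive track (mother heterozygous):
  `log LR = N x ln(1+2ε) + N(1−x) ln(1−2ε)`

A fetal genotype is reported only when `LR > 8` or `LR < 1/8`; the open band
in between is a no-call, as is any sample under 200 GE.

A fully seeded simulator (`qctcount.simdata`) generates reads in the regime
the method targets — ~100–1000 QCT molecules per reaction, lognormal
amplification bias up to ~8-fold depth spread, per-base errors, plate-level
contamination and index misassignment, cfDNA allele mixtures — with ground
truth for every stage.

## Worked example

Simulate one reaction mimicking cfDNA from a heterozygous (0/1) mother
carrying a homozygous-variant (1/1) fetus at 12% fetal fraction, with ~200
QCT molecules (two pools) and 2000 genomic molecules, then decode and call:

```python
from qctcount import decode_sample
from qctcount.simdata import (SimConfig, demo_assay, pools_from_config,
                              simulate_reaction, cfdna_allele_fractions)
from qctcount.quantify import allele_depths, allele_fraction, poisson_cv
from qctcount.niptcall import NIPTInput, call

assay = demo_assay()
sim = SimConfig(n_qct_molecules_mean=100, n_goi_molecules=2000,
                depth_per_molecule_mean=30, amplification_bias_sd=0.5,
                seq_error_rate=0.002,
                goi_allele_fractions=cfdna_allele_fractions(assay, "0/1", "1/1", 0.12))
reads, truth = simulate_reaction(pools_from_config(assay), assay, sim, 7)
dec = decode_sample([r.sequence for r in reads], assay, sample_id="demo")
ref, alt = allele_depths(dec.partition, assay)
vaf = allele_fraction(ref, alt).vaf
res = call(NIPTInput(maternal_genotype="0/1", x=vaf,
                     n_molecules=round(dec.count.genomic_equivalents),
                     fetal_fraction=0.12, adjustment=1.0))
```

Output for this seed (65,690 reads; 190 QCT and 2000 genomic molecules were
truly present):

```
molecules=178  <D_QCT>=29.6  t=5.44   per-pool {QCT1: 27.8, QCT2: 31.8}
GE=2038  Poisson CV=2.2%
ref=26126  alt=34156  vaf=0.567
log10 LR=7.80  call=affected
```

Reading it: 178 of 190 spiked molecules are recovered (the shortfall is
chance EMI-cluster merges, see `docs/methods.md`), the two co-spiked pools
agree on reads-per-molecule, the 2038 GE estimate matches the 2000 input
molecules to within its own 2.2% counting noise, the VAF of 0.567 sits near
the 0.56 expected for an affected fetus at this fetal fraction, and the
recessive-track likelihood ratio (10^7.8 ≫ 8) calls the fetus affected.

The same flow is available from the shell: `qctcount simulate | run |
integrity | quantify | call | power` (see `qctcount --help`). The `call`
subcommand takes a TSV with columns `sample_id, maternal_gt, vaf,
n_molecules, fetal_fraction`.

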