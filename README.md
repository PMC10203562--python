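# displaycamp

Analysis toolkit for **mammalian-display antibody optimization campaigns**:
site-saturation library design statistics, FACS selection-round enrichment
analysis from paired-patch amplicon sequencing, biophysical assay scoring,
and descriptor-flag / rank-sum developability ranking — plus a synthetic
campaign generator with known ground truth for end-to-end validation.

It is written for antibody engineers running (or simulating) campaigns in
which a displayed IgG library — e.g. an NNK-randomized CDR patch library on
single-copy landing-pad CHO cells — is sorted by display level and antigen
binding, deep-sequenced per round, and triaged by developability assays.

## The quantities it computes

**Library design.** A degenerate codon such as NNK (N = A/C/G/T, K = G/T;
32 codons, all 20 amino acids, one stop) randomized at *n* positions gives
a DNA diversity of 32^n and a stop-free protein diversity of 20^n. For a
transfection of *C* cells at stable-integration efficiency *e*, the
oversampling fold over a diversity *D* is λ = C·e / D, and under a Poisson
model the expected covered fraction of the diversity is 1 − e^(−λ), with
probability (1 − e^(−λ))^D that no variant is missing. A codon-weighted
variant of the coverage model accounts for the unequal number of codons per
amino acid under the degenerate pattern.

**Enrichment.** Reads are keyed by the two mutagenized patches located
between fixed anchor sequences, clustered at 100% identity (DNA or
amino-acid level), and normalized per sample (reads of variant / total
reads). The enrichment factor of a variant in a sorted sample is

    EF(v) = normalized_count_sorted(v) / normalized_count_pre(v)

with per-position residue marginals, per-chain (VH/VL pair) marginals, and
per-round trajectories; a de-enrichment fold is 1/EF.

**Assay scores.** AC-SINS: plasmon wavelength (vertex of a local quadratic
fit to the nanoparticle absorbance maximum) of the sample minus a PBS
blank, in nm. Polyreactivity ELISA: mean blank-subtracted OD450 over six
antigens × four concentrations. nanoDSF Tm: temperature of the maximum
first derivative of the smoothed F350/F330 ratio curve.

**Developability triage.** A descriptor is flagged when its value strictly
exceeds mean + SD of a reference panel of approved antibodies; assay panels
are aggregated by direction-aware average ranks summed per variant (lower =
better), and associations are reported as tie-corrected Spearman
correlations.

## Worked example

```pycon
>>> from displaycamp import (DegenerateLibraryDesign, oversampling_fold,
...                          poisson_coverage, enrichment_factor)
>>> from displaycamp.library_design import report_fold
>>> design = DegenerateLibraryDesign.from_pattern("NNK", 4)
>>> design.dna_diversity, design.aa_diversity
(1048576, 160000)
>>> report_fold(oversampling_fold(2.4e8, 0.017, design.dna_diversity))
3.9
>>> report_fold(oversampling_fold(2.4e8, 0.017, design.aa_diversity))
26.0
>>> round(poisson_coverage(2.4e8*0.017, design.dna_diversity).expected_coverage, 2)
0.98
>>> rec = enrichment_factor(0.013, 0.0008)   # parental: 1.3% -> 0.08%
>>> round(rec.enrichment_factor, 4), round(rec.de_enrichment_fold)
(0.0615, 16)
```

A library of 1.05 × 10⁶ DNA variants transfected into 2.4 × 10⁸ cells at
1.7% integration efficiency is sampled 3.9-fold over its DNA diversity
(26-fold over the 160,000 protein variants), covering 98% of the DNA
diversity in expectation; a parental sequence falling from 1.3% to 0.08%
of reads has been depleted 16-fold (EF 0.06).

From the shell, the same report plus a full synthetic campaign:

```sh
displaycamp design --pattern NNK --positions 4 --cells 2.4e8 --efficiency 0.017
displaycamp run --config examples/campaign.yaml --outdir out/
```

The pipeline writes per-round FASTQ, ground-truth tables, variant/residue
enrichment tables, recomputed assay scores, descriptor flags, the overall
ranking and a reproducibility manifest.

## Layout

- `displaycamp.library_design` — degenerate-codon expansion, diversities, oversampling, Poisson coverage
- `displaycamp.amplicon` — amplicon template, patch coordinates, variant keys
- `displaycamp.enrichment` — read keying, clustering, normalized counts, enrichment factors
- `displaycamp.assays` — AC-SINS, polyreactivity ELISA, nanoDSF Tm scoring
- `displaycamp.ranking` — descriptor cutoffs/flags, rank sums, rank correlations
- `displaycamp.synthetic` — ground-truth campaign, read and assay-data simulators
- `displaycamp.pipeline` / `displaycamp.cli` — orchestration and the `displaycamp` command
- `docs/methods.md` — models, assumptions, parameter choices and limitations
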