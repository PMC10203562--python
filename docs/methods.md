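# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic campaign does and does not emulate,
and the numerical choices that matter for reproducing results.

## Library design statistics

A degenerate codon pattern is expanded against the standard genetic code;
an amino acid's *multiplicity* is its number of matching codons (NNK: Leu,
Arg, Ser = 3; Ala, Gly, Pro, Thr, Val = 2; the rest = 1; one stop, TAG).
DNA diversity is |codon set|^n over n randomized positions; protein
diversity is 20^n, excluding stop-containing combinations. Stops are
excluded from protein diversity but included in the expected per-position
amino-acid distribution, which describes the physical library before
selection.

Coverage uses the Poisson approximation: with N stable integrants over
diversity D, each variant is hit at rate λ = N/D, the expected covered
fraction is 1 − e^(−λ), and the probability of missing no variant is
(1 − e^(−λ))^D under the uniform model. The `codon_weighted` model rates
each protein variant at λ_dna × (product of its residues' codon
multiplicities); because single-codon amino acids (e.g. Trp, Met) are
sampled 3-fold less often than Leu/Arg/Ser, its full-coverage probability
is lower than the uniform model's at equal N. The uniform model is the
default: it is the convention under which the published campaign-scale
numbers (98% DNA coverage, >99.99% full protein coverage at λ = 25.5) are
reproduced, and the discrepancy is a documented bias of degenerate-codon
libraries, not of the calculator. The Poisson form (not exact multinomial
occupancy) is used throughout; the finite-D correction is O(λ²/2D) and
negligible at campaign scales.

Reported folds round to two significant figures below 10 and to the
nearest integer at or above 10, half away from zero (so 3.891 → 3.9 and
25.5 → 26). Enrichment factors display with two decimals below 1, two
significant figures otherwise, and to the nearest hundred above 1000;
display rounding is never used in computation.

## Amplicon keying and enrichment

A read is keyed by locating the fixed 17-nt anchor upstream of the VL
patch (exact string match first, then a Hamming scan within the mismatch
budget, then the reverse complement of the read), after which the other
three anchors and both 6-nt patches sit at template-determined offsets.
Default anchor tolerance is one mismatch per anchor; there is no
quality-score filtering. Rejections are categorized (anchor not found,
length mismatch, ambiguous base) and conserved: accepted + rejected =
input reads.

Clustering is exact identity at DNA (12 nt) or amino-acid (4 residue)
level; the amino-acid level aggregates synonymous DNA keys. Normalized
counts are per-sample fractions; EF is the ratio of normalized counts
versus pre-selection. A variant unseen in pre-selection has *undefined*
EF (status `undefined_pre_zero`) rather than a pseudocount — EFs against
an unobserved baseline are not meaningful at these depths; an optional
pseudocount exists for exploratory use only. Stop-containing variants
stay in frequency denominators (they are physically present before
selection) but are excluded from ranked reports by default. Ranked
reports sort by EF descending with ties broken by final-sample normalized
count, then key.

Marginal residue tables sum joint variant counts sharing a residue at one
of the four randomized positions (VL94, VL95, VH53, VH54 — position names
are labels in the antibody's own numbering, not recomputed). Chain-level
(VH-pair / VL-pair) enrichment marginalizes the paired key the same way.

## Assay scoring

**Plasmon wavelength.** Least-squares parabola over the points within
±10 nm of the raw absorbance argmax (21 points on the 1-nm grid); the
vertex abscissa is the plasmon wavelength. The window makes the fit local
enough for sharp nanoparticle peaks while keeping sub-nanometre vertex
precision; a raw argmax on the grid boundary is an error, and a fit that
opens upward falls back to the raw argmax. Replicates are fit first and
averaged second (robust to per-replicate baseline shifts). The AC-SINS
score is mean sample minus mean blank plasmon wavelength, in nm; negative
scores are allowed. The score is invariant to absorbance scaling/offset.

**Polyreactivity.** Mean of the 24 blank-subtracted OD450 wells (six
antigens × four concentrations), with per-antigen sub-scores. The blank
is a single PBS value per plate.

**Tm.** The F350/F330 ratio is smoothed by Savitzky–Golay local quadratic
regression over a 3 °C window; Tm is the temperature of the maximum first
derivative, refined by a parabola fitted to the derivative over the
smoothing window (more noise-tolerant than a 3-point refinement). A flat
curve, or near-equal derivative maxima separated by more than twice the
smoothing window, raises an ambiguous-transition error listing the
candidates; closer near-maxima are treated as one transition. The
estimate is invariant under affine transforms of the ratio.

## Flagging and ranking

Cutoffs are mean + SD per descriptor over the reference panel, with the
sample (n−1) SD — the 48 approved antibodies are a sample of the
therapeutic-antibody population. Flagging is strictly greater-than (a
value exactly at the cutoff is not flagged). Assay rank sums use average
ranks within each assay under declared better-directions (AC-SINS,
polyreactivity, PDI and HIC retention time: lower is better; Tm: higher);
KD is excluded from the default panel — affinity is a separate axis from
developability — but directions are configurable. Spearman correlations
are tie-corrected (Pearson on average ranks) with the large-sample t
approximation for p.

The flags-versus-ranking association reports Spearman rho as the primary
statistic and, as a secondary, a Wilcoxon–Mann–Whitney rank-sum test on
ranking scores split at the median flag count. Both are labelled in the
report; the secondary test holds its nominal type-I level under the null
(verified by simulation in the test suite).

## The synthetic campaign

The generator reproduces the statistical structure the analysis assumes,
with known ground truth:

- **Library.** Codons drawn i.i.d. per position from the degenerate set,
  with the parental codon's probability multiplied by a bias factor and
  renormalized — emulating the more efficient amplification of
  exact-match oligos in a degenerate pool. The bias is calibrated so the
  parental amino-acid variant's expected pre-selection frequency is 1.3%,
  the operating point of the campaign this package models.
- **Selection.** Each variant has additive per-residue contributions to
  latent log display and log binding signals; individual cells scatter
  log-normally (default SD 1.0 per channel, channels independent — no
  compensation/spillover). A gate is a lower bound on one or both
  channels, with the closed-form pass probability from the normal
  survival function. Default thresholds of +1 SD above the parental
  baseline give a parental double-gate pass rate of ≈2.5%, consistent
  with the campaign's collected-cell counts (10⁵–3×10⁶ of ~10⁸ stained).
  Sorting multiplies frequencies by pass probabilities and multinomially
  resamples to the collected cell count. MACS pre-enrichment is a
  permissive display-only gate (it selects antibody-expressing cells);
  stop-codon variants display nothing and never pass a gated channel.
  Growth between sorts is neutral; expansion-fitness differences are out
  of scope.
- **Reads.** Single merged amplicon reads (the patch-bearing context,
  with a synthetic inter-patch spacer standing in for the constant
  region), multinomial over the population, i.i.d. substitution errors
  (default 0.1%), constant Phred+33 qualities. No indels, chimeras or
  position-dependent error profiles.
- **Assay raw data.** Gaussian absorbance peaks on the 500–600 nm grid;
  ELISA ODs as blank + concentration-scaled signal (scale factors average
  1, so a flat signal s scores s) clipped at zero; two-state logistic
  melt curves on a 20–95 °C ramp; descriptor tables as per-descriptor
  normal reference values with variant values shifted by known SD
  multiples, making expected flag counts computable.

Everything is seeded and bit-reproducible. What passing tests show is
that the *analysis* recovers known truth under the assumed statistical
structure; they do not validate instrument realism (real Illumina error
profiles, spectral baselines, multi-domain unfolding) or biology (epistasis
between patches, expression silencing, copy-number effects), none of which
the generator models.

## Default problem sizes

The shipped pipeline defaults (2×10⁵ integrants, 2×10⁴ cells per sort,
5×10⁴ reads per sample) and the acceptance script's sizes (depth 10⁵
round trip, 200-seed assay recovery, 10³-replicate occupancy checks) are
chosen so a full run completes in a few minutes on one CPU while keeping
Monte-Carlo standard errors well below the tolerances being checked;
campaign-scale numbers (10⁶ diversity, 4×10⁶ integrants) appear only in
closed-form computations, which are size-independent.

## Known limitations

- EF estimates for variants with few pre-selection reads are noisy and
  undefined at zero; the package deliberately refuses to smooth them.
- Single-patch (half-keyed) reads are discarded; marginal tables are
  computed from fully keyed reads only. Real campaigns with separate
  VH/VL amplicons would need the alternative convention.
- The melt-curve model is single-transition; antibodies with resolved
  CH2/Fab transitions will trigger the ambiguity error rather than a
  (possibly wrong) automatic choice.
- Descriptor computation itself (aggregation scores, patch energies, pI)
  is proprietary-modeling territory and out of scope: descriptor tables
  are inputs.
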