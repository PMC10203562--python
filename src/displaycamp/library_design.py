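"""Degenerate-codon library mathematics.

Site-saturation mutagenesis randomizes chosen codons with a degenerate
(IUPAC) codon such as NNK.  This module computes the combinatorics of such
a library — the concrete codon set behind a pattern, per-amino-acid codon
multiplicities, theoretical DNA and protein diversities — and the sampling
statistics of transfecting the library into a limited number of cells:
oversampling fold and Poisson coverage (the expected fraction of the
diversity represented among N stable integrants, and the probability that
every variant is present at least once).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "DegenerateLibraryDesign",
    "TransfectionStats",
    "CoverageResult",
    "expand_degenerate_codon",
    "theoretical_diversity",
    "oversampling_fold",
    "report_fold",
    "poisson_coverage",
    "expected_aa_distribution",
]

STOP = "*"

#: amino acid (or '*') encoded by each concrete codon, standard genetic code
_CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
_CODON_TO_AA.update({c: STOP for c in standard_dna_table.stop_codons})


class InvalidPatternError(ValueError):
    """Raised for codon patterns that are not 3 IUPAC nucleotide symbols."""


def expand_degenerate_codon(pattern: str) -> tuple[tuple[str, ...], dict[str, int]]:
    """Expand an IUPAC degenerate codon into concrete codons and aa multiplicities.

    Parameters
    ----------
    pattern : str
        Exactly three IUPAC nucleotide symbols, e.g. ``"NNK"``.

    Returns
    -------
    codon_set : tuple of str
        Every concrete codon matching the pattern, lexicographic order.
    aa_multiplicity : dict
        Number of matching codons per encoded amino acid; stop codons are
        tallied under ``"*"``.  Amino acids with no matching codon are absent.
    """
    pattern = pattern.upper()
    if len(pattern) != 3:
        raise InvalidPatternError(f"codon pattern must have length 3, got {pattern!r}")
    iupac = set("ACGTRYSWKMBDHVN")  # Biopython's table also maps non-IUPAC 'X'
    if set(pattern) - iupac:
        raise InvalidPatternError(f"non-IUPAC symbol in pattern {pattern!r}")
    choices = [ambiguous_dna_values[sym] for sym in pattern]
    codons = tuple("".join(bases) for bases in itertools.product(*choices))
    multiplicity: dict[str, int] = {}
    for codon in codons:
        aa = _CODON_TO_AA[codon]
        multiplicity[aa] = multiplicity.get(aa, 0) + 1
    return codons, multiplicity


@dataclass(frozen=True)
class DegenerateLibraryDesign:
    """A library built from `n_positions` copies of one degenerate codon."""

    codon_pattern: str
    n_positions: int
    codon_set: tuple[str, ...] = field(repr=False)
    aa_multiplicity: Mapping[str, int] = field(repr=False)
    dna_diversity: int
    aa_diversity: int

    @classmethod
    def from_pattern(cls, pattern: str, n_positions: int) -> "DegenerateLibraryDesign":
        if n_positions < 1:
            raise ValueError(f"n_positions must be >= 1, got {n_positions}")
        codons, mult = expand_degenerate_codon(pattern)
        n_aa = sum(1 for aa in mult if aa != STOP)
        return cls(
            codon_pattern=pattern.upper(),
            n_positions=n_positions,
            codon_set=codons,
            aa_multiplicity=mult,
            dna_diversity=len(codons) ** n_positions,
            aa_diversity=n_aa ** n_positions,
        )


def theoretical_diversity(design: DegenerateLibraryDesign) -> tuple[int, int]:
    """(DNA diversity, stop-free amino-acid diversity) of the design."""
    return design.dna_diversity, design.aa_diversity


@dataclass(frozen=True)
class TransfectionStats:
    """Transfection scale of a library: cells, efficiency and oversampling."""

    cells_transfected: float
    integration_efficiency: float
    dna_diversity: int
    aa_diversity: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.integration_efficiency <= 1.0:
            raise ValueError(
                f"integration efficiency must lie in [0, 1], got "
                f"{self.integration_efficiency}"
            )

    @property
    def n_integrants(self) -> float:
        return self.cells_transfected * self.integration_efficiency

    @property
    def oversampling_dna(self) -> float:
        return oversampling_fold(
            self.cells_transfected, self.integration_efficiency, self.dna_diversity
        )

    @property
    def oversampling_aa(self) -> float:
        return oversampling_fold(
            self.cells_transfected, self.integration_efficiency, self.aa_diversity
        )


def oversampling_fold(
    cells_transfected: float, integration_efficiency: float, diversity: int
) -> float:
    """Stable integrants per library variant (N / D), unrounded."""
    if diversity < 1:
        raise ValueError(f"diversity must be >= 1, got {diversity}")
    if not 0.0 <= integration_efficiency <= 1.0:
        raise ValueError(
            f"integration efficiency must lie in [0, 1], got {integration_efficiency}"
        )
    return cells_transfected * integration_efficiency / diversity


def report_fold(fold: float) -> float:
    """Display rounding for oversampling folds.

    Two significant figures below 10, nearest integer at or above 10; ties
    round half away from zero (so 25.5 reports as 26).
    """
    if fold < 0:
        raise ValueError("fold must be non-negative")
    if fold == 0:
        return 0.0
    if fold >= 10:
        return float(math.floor(fold + 0.5))
    exponent = math.floor(math.log10(fold))
    scale = 10.0 ** (exponent - 1)
    return round(math.floor(fold / scale + 0.5) * scale, max(0, 1 - exponent))


@dataclass(frozen=True)
class CoverageResult:
    """Poisson coverage of a diversity D by N integrants."""

    lam: float
    expected_coverage: float
    full_coverage_probability: float


def _product_multiplicity_distribution(
    design: DegenerateLibraryDesign,
) -> dict[int, int]:
    """Distribution over amino-acid variants of the product of codon
    multiplicities of their residues (NNK bias: Leu has 3 codons, Trp 1...).

    Returns {product: number of stop-free aa variants with that product};
    counts sum to aa_diversity.
    """
    per_position: dict[int, int] = {}
    for aa, m in design.aa_multiplicity.items():
        if aa == STOP:
            continue
        per_position[m] = per_position.get(m, 0) + 1
    dist = {1: 1}
    for _ in range(design.n_positions):
        nxt: dict[int, int] = {}
        for prod, cnt in dist.items():
            for m, n_aa in per_position.items():
                nxt[prod * m] = nxt.get(prod * m, 0) + cnt * n_aa
        dist = nxt
    return dist


def poisson_coverage(
    n_integrants: float,
    diversity: int,
    model: Literal["uniform", "codon_weighted"] = "uniform",
    design: DegenerateLibraryDesign | None = None,
) -> CoverageResult:
    """Coverage of a library of `diversity` variants by `n_integrants` cells.

    Under the uniform model each variant is hit at Poisson rate
    lambda = N / D, so the expected represented fraction is 1 - exp(-lambda)
    and the probability that no variant is missed is (1 - exp(-lambda))**D.

    The codon_weighted model accounts for degenerate-codon bias at the
    protein level: an amino-acid variant whose residues are encoded by
    (m1, ..., mn) codons is hit at rate lambda_dna * m1*...*mn, where
    lambda_dna is the per-DNA-variant rate.  `design` is required and
    `diversity` must equal its aa_diversity.
    """
    if diversity < 1:
        raise ValueError(f"diversity must be >= 1, got {diversity}")
    if n_integrants < 0:
        raise ValueError(f"n_integrants must be >= 0, got {n_integrants}")
    lam = n_integrants / diversity

    if model == "uniform":
        cov = -math.expm1(-lam)
        if cov == 0.0:
            full = 0.0
        else:
            full = math.exp(diversity * math.log(cov))
        return CoverageResult(lam=lam, expected_coverage=cov, full_coverage_probability=full)

    if model == "codon_weighted":
        if design is None:
            raise ValueError("codon_weighted model requires the library design")
        if diversity != design.aa_diversity:
            raise ValueError(
                "codon_weighted coverage is defined over amino-acid diversity; "
                f"got diversity={diversity}, design.aa_diversity={design.aa_diversity}"
            )
        lam_dna = n_integrants / design.dna_diversity
        dist = _product_multiplicity_distribution(design)
        prods = np.array(sorted(dist), dtype=float)
        counts = np.array([dist[int(p)] for p in prods], dtype=float)
        cov_v = -np.expm1(-lam_dna * prods)
        expected = float(np.sum(counts * cov_v) / counts.sum())
        if np.any(cov_v <= 0.0):
            full = 0.0
        else:
            full = float(np.exp(np.sum(counts * np.log(cov_v))))
        return CoverageResult(
            lam=lam, expected_coverage=expected, full_coverage_probability=full
        )

    raise ValueError(f"unknown coverage model {model!r}")


def expected_aa_distribution(design: DegenerateLibraryDesign) -> dict[str, float]:
    """Per-position expected amino-acid frequencies, stop included.

    frequency(aa) = (codons encoding aa within the pattern) / |codon set|;
    the values sum to 1 at each randomized position.
    """
    total = len(design.codon_set)
    return {aa: m / total for aa, m in design.aa_multiplicity.items()}
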