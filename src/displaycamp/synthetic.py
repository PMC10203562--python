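"""Synthetic selection-campaign generator with known ground truth.

Emulates the statistical structure the analysis modules assume:

* an NNK-randomized four-position library with a parental-sequence bias
  (degenerate oligo pools amplify the exact-match parental oligo slightly
  more efficiently);
* multi-round gated FACS selection acting on latent per-variant display
  and antigen-binding phenotypes with log-normal per-cell scatter;
* multinomial amplicon read sampling with i.i.d. base errors;
* raw assay data (nanoparticle absorbance spectra, ELISA OD matrices,
  melt curves, descriptor tables) generated from known true scores.

Every simulator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .amplicon import (
    PARENTAL_DNA_KEY,
    PARENTAL_KEY,
    POSITIONS,
    AmpliconTemplate,
    VariantKey,
)
from .assays import (
    ELISA_ANTIGENS,
    ELISA_CONCENTRATIONS_NG_ML,
    ElisaPlate,
    MeltCurve,
    Spectrum,
)
from .library_design import _CODON_TO_AA, DegenerateLibraryDesign

__all__ = [
    "PhenotypeModel",
    "CellPopulation",
    "GateSpec",
    "FastqRecord",
    "EmptyGateError",
    "simulate_library",
    "calibrate_parental_bias",
    "simulate_round",
    "simulate_reads",
    "simulate_acsins_spectrum",
    "simulate_elisa_plate",
    "simulate_melt_curve",
    "simulate_descriptor_tables",
    "default_phenotype_model",
]


class EmptyGateError(ValueError):
    """The gate excludes every cell in the population."""


@dataclass(frozen=True)
class GateSpec:
    """A FACS gate: lower bounds on log display and/or log binding signal.

    The campaign's three gates: "best" bounds both channels, "affinity"
    only binding, "display" only display.
    """

    gate_name: str
    display_threshold: float | None = None
    binding_threshold: float | None = None


@dataclass
class PhenotypeModel:
    """Additive per-residue latent phenotypes on the log scale.

    A variant's mean log display (binding) signal is the baseline plus the
    sum of its residues' effects; the parental residues carry zero effect
    by construction, so the parental variant sits at the baselines.
    Individual cells scatter log-normally around the variant mean with
    `cell_noise_sd` per channel, channels independent.  Stop-containing
    variants display nothing (effectively -inf in both channels).
    """

    display_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    binding_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    baseline_display: float = 0.0
    baseline_binding: float = 0.0
    cell_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.cell_noise_sd < 0:
            raise ValueError("cell_noise_sd must be >= 0")

    def _mu(self, key: VariantKey, effects, baseline: float) -> float:
        if key.has_stop:
            return -math.inf
        residues = key.vl_pair + key.vh_pair
        pos_order = ("VL94", "VL95", "VH53", "VH54")
        return baseline + sum(
            effects.get((pos, aa), 0.0) for pos, aa in zip(pos_order, residues)
        )

    def display_mu(self, key: VariantKey) -> float:
        return self._mu(key, self.display_effects, self.baseline_display)

    def binding_mu(self, key: VariantKey) -> float:
        return self._mu(key, self.binding_effects, self.baseline_binding)

    def gate_pass_probability(self, key: VariantKey, gate: GateSpec) -> float:
        """Closed-form pass probability under the log-normal cell model."""
        p = 1.0
        for threshold, mu in (
            (gate.display_threshold, self.display_mu(key)),
            (gate.binding_threshold, self.binding_mu(key)),
        ):
            if threshold is None:
                continue
            if math.isinf(mu):
                return 0.0
            if self.cell_noise_sd == 0:
                p *= 1.0 if mu > threshold else 0.0
            else:
                p *= float(norm.sf((threshold - mu) / self.cell_noise_sd))
        return p


def default_phenotype_model(cell_noise_sd: float = 1.0) -> PhenotypeModel:
    """Phenotype landscape mirroring the campaign's qualitative findings.

    Negatively charged substitutions at the VH 53/54 patch raise the
    display level (hydrophobic-patch removal), VH54->E also helps antigen
    binding, and VL-patch substitutions act mostly on display.  Parental
    residues (VL L94/W95, VH P53/F54) have zero effect by construction.
    """
    display = {
        ("VH53", "A"): 0.8,
        ("VH53", "S"): 0.8,
        ("VH53", "E"): 0.7,
        ("VH53", "D"): 0.7,
        ("VH53", "R"): 0.5,
        ("VH54", "E"): 2.0,
        ("VH54", "D"): 1.8,
        ("VH54", "S"): 0.6,
        ("VH54", "Q"): 0.4,
        ("VL94", "G"): 0.5,
        ("VL94", "P"): 0.3,
        ("VL94", "C"): 0.3,
        ("VL95", "Q"): 0.6,
        ("VL95", "A"): 0.4,
        ("VL95", "G"): 0.3,
        ("VL95", "M"): 0.2,
        ("VL95", "S"): 0.2,
    }
    binding = {
        ("VH54", "E"): 1.0,
        ("VH53", "A"): 0.2,
        ("VH53", "S"): 0.2,
        ("VL95", "Q"): 0.3,
        ("VL94", "N"): 0.2,
        ("VL94", "R"): 0.2,
    }
    return PhenotypeModel(
        display_effects=display,
        binding_effects=binding,
        cell_noise_sd=cell_noise_sd,
    )


@dataclass
class CellPopulation:
    """Variant composition of one cell population (one round, one gate)."""

    frequencies: dict[VariantKey, float]
    round_label: str = "pre-selection"
    population_label: str = ""

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"frequencies must sum to 1, got {total}")
        if any(f < 0 for f in self.frequencies.values()):
            raise ValueError("frequencies must be non-negative")

    def variants(self) -> list[VariantKey]:
        return sorted(self.frequencies)


def _codon_probabilities(
    design: DegenerateLibraryDesign,
    parental_dna_key: str,
    parental_bias: float,
) -> np.ndarray:
    """(n_positions, n_codons) codon draw probabilities with parental bias."""
    codons = design.codon_set
    probs = np.ones((design.n_positions, len(codons)), dtype=float)
    for i in range(design.n_positions):
        parental_codon = parental_dna_key[3 * i : 3 * i + 3]
        if parental_codon not in codons:
            raise ValueError(
                f"parental codon {parental_codon!r} not in the {design.codon_pattern} set"
            )
        probs[i, codons.index(parental_codon)] = parental_bias
    return probs / probs.sum(axis=1, keepdims=True)


def simulate_library(
    design: DegenerateLibraryDesign,
    parental_dna_key: str = PARENTAL_DNA_KEY,
    parental_bias: float = 1.0,
    n_integrants: int = 1_000_000,
    seed: int = 0,
) -> CellPopulation:
    """Draw a transfected library: i.i.d. codons per position, the parental
    codon's probability multiplied by `parental_bias` then renormalized.

    Returns a DNA-level population (every key carries its 12-nt dna_key).
    """
    if parental_bias < 1:
        raise ValueError("parental_bias must be >= 1")
    if n_integrants <= 0:
        raise ValueError("n_integrants must be positive")
    if design.n_positions != 4:
        raise ValueError("campaign libraries randomize exactly 4 codons")
    rng = np.random.default_rng(seed)
    probs = _codon_probabilities(design, parental_dna_key, parental_bias)
    n_codons = len(design.codon_set)
    draws = np.empty((n_integrants, design.n_positions), dtype=np.int64)
    for i in range(design.n_positions):
        draws[:, i] = rng.choice(n_codons, size=n_integrants, p=probs[i])
    packed = np.zeros(n_integrants, dtype=np.int64)
    for i in range(design.n_positions):
        packed = packed * n_codons + draws[:, i]
    uniq, counts = np.unique(packed, return_counts=True)
    freqs: dict[VariantKey, float] = {}
    for code, count in zip(uniq.tolist(), counts.tolist()):
        idx = []
        for _ in range(design.n_positions):
            idx.append(code % n_codons)
            code //= n_codons
        dna = "".join(design.codon_set[j] for j in reversed(idx))
        freqs[VariantKey.from_dna(dna)] = count / n_integrants
    return CellPopulation(frequencies=freqs, round_label="pre-selection")


def calibrate_parental_bias(
    design: DegenerateLibraryDesign,
    target_parental_frequency: float,
    parental_dna_key: str = PARENTAL_DNA_KEY,
) -> float:
    """Bias making the parental amino-acid variant's expected pre-selection
    frequency equal `target_parental_frequency` (e.g. 0.013)."""
    if not 0 < target_parental_frequency < 1:
        raise ValueError("target frequency must lie in (0, 1)")
    n_codons = len(design.codon_set)

    def parental_freq(bias: float) -> float:
        total = 1.0
        for i in range(design.n_positions):
            codon = parental_dna_key[3 * i : 3 * i + 3]
            aa_mult = design.aa_multiplicity[_CODON_TO_AA[codon]]
            total *= (bias + aa_mult - 1) / (n_codons - 1 + bias)
        return total

    if parental_freq(1.0) >= target_parental_frequency:
        return 1.0
    return float(
        brentq(
            lambda b: parental_freq(b) - target_parental_frequency,
            1.0,
            1e9,
            xtol=1e-9,
            rtol=1e-12,
        )
    )


def simulate_round(
    pop: CellPopulation,
    model: PhenotypeModel,
    gate: GateSpec,
    n_cells_sorted: int,
    seed: int = 0,
) -> CellPopulation:
    """One gated sort: Bayes-update the composition by per-variant gate-pass
    probabilities, then multinomially resample to the collected cell count."""
    if n_cells_sorted < 1:
        raise ValueError("n_cells_sorted must be >= 1")
    rng = np.random.default_rng(seed)
    variants = pop.variants()
    freq = np.array([pop.frequencies[v] for v in variants])
    p_pass = np.ones(len(variants))
    for threshold, mu_fn in (
        (gate.display_threshold, model.display_mu),
        (gate.binding_threshold, model.binding_mu),
    ):
        if threshold is None:
            continue
        mu = np.array([mu_fn(v) for v in variants])
        if model.cell_noise_sd == 0:
            p_pass *= (mu > threshold).astype(float)
        else:
            p_pass *= norm.sf((threshold - mu) / model.cell_noise_sd)
    posterior = freq * p_pass
    total = posterior.sum()
    if total <= 0:
        raise EmptyGateError(f"gate {gate.gate_name!r} excludes every cell")
    counts = rng.multinomial(n_cells_sorted, posterior / total)
    keep = counts > 0
    freqs = {
        v: int(c) / n_cells_sorted
        for v, c in zip(variants, counts.tolist())
        if c > 0
    }
    del keep
    return CellPopulation(
        frequencies=freqs,
        round_label=f"{gate.gate_name}-sorted",
        population_label=gate.gate_name,
    )


class FastqRecord(NamedTuple):
    read_id: str
    sequence: str
    quality: str


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def simulate_reads(
    pop: CellPopulation,
    template: AmpliconTemplate,
    depth: int,
    per_base_error: float = 0.0,
    seed: int = 0,
    quality_char: str = "I",
) -> list[FastqRecord]:
    """Multinomial amplicon reads from a population, with i.i.d. base errors.

    Each read is the template with the drawn variant's 12 randomized
    nucleotides substituted in; errors replace a base with one of the
    other three uniformly; qualities are constant Phred+33.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= per_base_error < 0.25:
        raise ValueError("per_base_error must lie in [0, 0.25)")
    rng = np.random.default_rng(seed)
    variants = pop.variants()
    for v in variants:
        if v.dna_key is None:
            raise ValueError("read simulation requires DNA-level variant keys")
    freq = np.array([pop.frequencies[v] for v in variants])
    counts = rng.multinomial(depth, freq / freq.sum())
    length = template.length
    seqs = np.empty((len(variants), length), dtype=np.uint8)
    for i, v in enumerate(variants):
        seqs[i] = np.frombuffer(template.build(v.dna_key).encode(), dtype=np.uint8)
    reads = seqs[np.repeat(np.arange(len(variants)), counts)]
    reads = reads[rng.permutation(depth)]
    if per_base_error > 0:
        err = rng.random(reads.shape) < per_base_error
        if err.any():
            idx = _BASE_INDEX[reads[err]]
            shift = rng.integers(1, 4, size=idx.shape)
            reads[err] = _BASES[(idx + shift) % 4]
    quality = quality_char * length
    return [
        FastqRecord(f"read_{i}", bytes(row).decode(), quality)
        for i, row in enumerate(reads)
    ]


def simulate_acsins_spectrum(
    true_plasmon_nm: float,
    peak_width_nm: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 0.5,
    baseline: float = 0.05,
    wavelengths: Sequence[float] | None = None,
    sample_id: str = "",
    replicate_id: str = "",
) -> Spectrum:
    """Gaussian absorbance peak on the 500-600 nm grid plus i.i.d. noise."""
    if not 500.0 <= true_plasmon_nm <= 600.0:
        raise ValueError("true plasmon wavelength must lie in [500, 600] nm")
    wl = (
        np.arange(500.0, 601.0, 1.0)
        if wavelengths is None
        else np.asarray(wavelengths, dtype=float)
    )
    rng = np.random.default_rng(seed)
    ab = baseline + amplitude * np.exp(
        -0.5 * ((wl - true_plasmon_nm) / peak_width_nm) ** 2
    )
    if noise_sd > 0:
        ab = ab + rng.normal(0.0, noise_sd, size=wl.shape)
    return Spectrum(wl, ab, sample_id=sample_id, replicate_id=replicate_id)


#: concentration response factors (mean 1 so a flat true signal s scores s)
_ELISA_CONC_SCALE = (1.6, 1.2, 0.8, 0.4)


def simulate_elisa_plate(
    per_antigen_true_signal: Mapping[str, float],
    blank_od: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "",
) -> ElisaPlate:
    """6x4 OD matrix: blank + concentration-scaled true signal + noise, clipped
    at zero.  The concentration response factors average to 1, so the
    polyreactivity score of a noiseless plate equals the mean true signal."""
    missing = set(ELISA_ANTIGENS) - set(per_antigen_true_signal)
    if missing:
        raise ValueError(f"missing antigens: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    signal = np.array([per_antigen_true_signal[a] for a in ELISA_ANTIGENS])
    od = blank_od + np.outer(signal, _ELISA_CONC_SCALE)
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    od = np.clip(od, 0.0, None)
    return ElisaPlate(
        od450=od,
        blank_od450=blank_od,
        antigens=ELISA_ANTIGENS,
        concentrations_ng_ml=ELISA_CONCENTRATIONS_NG_ML,
        sample_id=sample_id,
    )


def simulate_melt_curve(
    tm_true: float,
    transition_width_c: float = 2.0,
    baselines: tuple[float, float] = (0.80, 1.00),
    noise_sd: float = 0.0,
    seed: int = 0,
    t_min: float = 20.0,
    t_max: float = 95.0,
    step_c: float = 0.25,
    sample_id: str = "",
) -> MeltCurve:
    """Two-state logistic F350/F330 ratio curve with midpoint `tm_true`."""
    if not t_min < tm_true < t_max:
        raise ValueError(f"tm_true must lie inside ({t_min}, {t_max})")
    rng = np.random.default_rng(seed)
    temp = np.arange(t_min, t_max + step_c / 2, step_c)
    low, high = baselines
    ratio = low + (high - low) / (1.0 + np.exp(-(temp - tm_true) / transition_width_c))
    if noise_sd > 0:
        ratio = ratio + rng.normal(0.0, noise_sd, size=temp.shape)
    return MeltCurve(temperature_c=temp, ratio=ratio, sample_id=sample_id)


def simulate_descriptor_tables(
    n_reference: int = 48,
    n_variants: int = 12,
    n_descriptors: int = 55,
    shift_per_variant: Sequence[float] | np.ndarray | None = None,
    seed: int = 0,
):
    """Reference and variant descriptor tables with known liability shifts.

    Reference values are i.i.d. normal per descriptor (descriptor-specific
    means, unit SD).  Variant d-values are normal around the descriptor
    mean plus `shift_per_variant` (in SD units; scalar per variant, or an
    (n_variants, n_descriptors) matrix), so expected flag counts are
    computable from the normal tail.

    Returns (reference, variants) as pandas DataFrames.
    """
    import pandas as pd

    if n_reference < 2:
        raise ValueError("need at least 2 reference antibodies")
    rng = np.random.default_rng(seed)
    names = [f"d{j:02d}" for j in range(n_descriptors)]
    mu = rng.normal(0.0, 3.0, size=n_descriptors)
    reference = pd.DataFrame(
        rng.normal(mu, 1.0, size=(n_reference, n_descriptors)),
        index=[f"ref_{i:03d}" for i in range(n_reference)],
        columns=names,
    )
    if shift_per_variant is None:
        shifts = np.zeros((n_variants, n_descriptors))
    else:
        shifts = np.asarray(shift_per_variant, dtype=float)
        if shifts.ndim == 1:
            if len(shifts) != n_variants:
                raise ValueError("one shift per variant required")
            shifts = np.repeat(shifts[:, None], n_descriptors, axis=1)
        elif shifts.shape != (n_variants, n_descriptors):
            raise ValueError(
                f"shift matrix must be ({n_variants}, {n_descriptors})"
            )
    variants = pd.DataFrame(
        rng.normal(mu + shifts, 1.0),
        index=[f"var_{i:03d}" for i in range(n_variants)],
        columns=names,
    )
    return reference, variants
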