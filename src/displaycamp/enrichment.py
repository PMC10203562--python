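"""Read-level variant extraction, clustering and enrichment factors.

Deep sequencing of each selection round yields reads covering both
mutagenized patches.  Each read is keyed by locating the fixed anchor
sequences flanking the patches, the keyed reads are clustered at 100%
identity (DNA or amino-acid level), and selection is quantified by the
enrichment factor

    EF(v) = normalized_count_sample(v) / normalized_count_pre(v),

where a normalized count is a variant's reads divided by the sample's
total reads.  A de-enrichment fold is the reciprocal of an EF below 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Mapping

import pandas as pd
from Bio.Seq import reverse_complement

from .amplicon import POSITIONS, AmpliconTemplate, VariantKey, translate_patch

__all__ = [
    "Rejection",
    "SampleCounts",
    "EnrichmentRecord",
    "ResidueTable",
    "extract_variant",
    "extract_all",
    "cluster_counts",
    "count_sample",
    "normalized_counts",
    "enrichment_factor",
    "residue_enrichment",
    "pair_enrichment",
    "round_trajectory",
    "format_ef",
]


class EmptySampleError(ValueError):
    """A sample with no accepted reads cannot be normalized."""


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class Rejection:
    """A read that could not be keyed, with the reason."""

    reason: Literal["anchor_not_found", "length_mismatch", "ambiguous_base"]


def _hamming_at(read: str, anchor: str, offset: int) -> int:
    return sum(a != b for a, b in zip(read[offset : offset + len(anchor)], anchor))


def _find_anchor(read: str, anchor: str, max_mismatches: int) -> int:
    """Leftmost offset of `anchor` in `read` within the mismatch budget, or -1."""
    pos = read.find(anchor)  # fast path: exact match
    if pos >= 0 or max_mismatches == 0:
        return pos
    limit = len(read) - len(anchor)
    for offset in range(limit + 1):
        if _hamming_at(read, anchor, offset) <= max_mismatches:
            return offset
    return -1


def _extract_oriented(
    read: str, template: AmpliconTemplate, max_anchor_mismatches: int
) -> VariantKey | Rejection:
    offset = _find_anchor(read, template.upstream_anchor_vl, max_anchor_mismatches)
    if offset < 0:
        return Rejection("anchor_not_found")
    (vl_s, vl_e), (vh_s, vh_e) = template.codon_offsets
    shift = offset - 0  # template coordinates start at the VL upstream anchor
    if len(read) < shift + vh_e + len(template.downstream_anchor_vh):
        return Rejection("length_mismatch")
    for anchor, start in (
        (template.downstream_anchor_vl, vl_e),
        (template.upstream_anchor_vh, vh_s - len(template.upstream_anchor_vh)),
        (template.downstream_anchor_vh, vh_e),
    ):
        if _hamming_at(read, anchor, shift + start) > max_anchor_mismatches:
            return Rejection("anchor_not_found")
    dna_key = read[shift + vl_s : shift + vl_e] + read[shift + vh_s : shift + vh_e]
    if set(dna_key) - set("ACGT"):
        return Rejection("ambiguous_base")
    return VariantKey.from_dna(dna_key)


def extract_variant(
    read: str, template: AmpliconTemplate, max_anchor_mismatches: int = 1
) -> VariantKey | Rejection:
    """Key a read by its two 6-nt patches, or reject it with a reason.

    The VL upstream anchor is located first (exact match, then a Hamming
    scan within the mismatch budget); the remaining three anchors must then
    match at the offsets the template dictates.  If the forward orientation
    fails on the first anchor, the reverse complement of the read is tried.
    """
    read = read.upper()
    if set(read) - set("ACGTN"):
        return Rejection("ambiguous_base")
    result = _extract_oriented(read, template, max_anchor_mismatches)
    if isinstance(result, Rejection) and result.reason == "anchor_not_found":
        rc = reverse_complement(read)
        rc_result = _extract_oriented(rc, template, max_anchor_mismatches)
        if not isinstance(rc_result, Rejection):
            return rc_result
    return result


def extract_all(
    reads: Iterable[str], template: AmpliconTemplate, max_anchor_mismatches: int = 1
) -> Iterator[VariantKey | Rejection]:
    for read in reads:
        yield extract_variant(read, template, max_anchor_mismatches)


@dataclass
class SampleCounts:
    """Per-variant read counts of one selection sample."""

    sample_id: str
    counts: dict[VariantKey, int] = field(default_factory=dict)
    rejected_reads: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected_reads.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": self.sample_id,
                "vh_pair": key.vh_pair,
                "vl_pair": key.vl_pair,
                "dna_key": key.dna_key or "",
                "reads": n,
            }
            for key, n in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["sample_id", "vh_pair", "vl_pair", "dna_key", "reads"]
        )


def cluster_counts(
    variants: Iterable[VariantKey],
    level: Literal["dna", "aa"] = "aa",
    sample_id: str = "",
) -> SampleCounts:
    """Group keyed reads by exact identity at the DNA or amino-acid level.

    The amino-acid level aggregates all synonymous DNA keys of a variant.
    """
    counts: dict[VariantKey, int] = {}
    empty = True
    for key in variants:
        empty = False
        if level == "aa":
            key = key.aa_key
        elif level != "dna":
            raise ConfigurationError(f"unknown clustering level {level!r}")
        counts[key] = counts.get(key, 0) + 1
    if empty:
        raise EmptySampleError("no variants to cluster")
    return SampleCounts(sample_id=sample_id, counts=counts)


def count_sample(
    reads: Iterable[str],
    template: AmpliconTemplate,
    sample_id: str = "",
    level: Literal["dna", "aa"] = "aa",
    max_anchor_mismatches: int = 1,
) -> SampleCounts:
    """Extract, filter and cluster raw reads into a SampleCounts."""
    sample = SampleCounts(sample_id=sample_id)
    for item in extract_all(reads, template, max_anchor_mismatches):
        if isinstance(item, Rejection):
            sample.rejected_reads[item.reason] = (
                sample.rejected_reads.get(item.reason, 0) + 1
            )
            continue
        key = item.aa_key if level == "aa" else item
        sample.counts[key] = sample.counts.get(key, 0) + 1
    return sample


def normalized_counts(sample: SampleCounts) -> dict[VariantKey, float]:
    """Each variant's reads divided by the sample total; sums to 1."""
    total = sample.total_reads
    if total < 1:
        raise EmptySampleError(f"sample {sample.sample_id!r} has no accepted reads")
    return {key: n / total for key, n in sample.counts.items()}


@dataclass(frozen=True)
class EnrichmentRecord:
    """Normalized counts of one variant (or residue, or chain pair) in the
    pre-selection and target samples, and their ratio."""

    variant: object
    nc_pre: float
    nc_sample: float
    enrichment_factor: float  # NaN when undefined
    status: Literal["defined", "undefined_pre_zero"] = "defined"

    @property
    def de_enrichment_fold(self) -> float:
        """Reciprocal EF: how many-fold the variant was depleted."""
        if self.status != "defined" or self.enrichment_factor == 0:
            return math.nan
        return 1.0 / self.enrichment_factor


def enrichment_factor(
    nc_pre: float, nc_sample: float, variant: object = None
) -> EnrichmentRecord:
    """EF = nc_sample / nc_pre; undefined (no pseudocount) when nc_pre = 0."""
    for value, name in ((nc_pre, "nc_pre"), (nc_sample, "nc_sample")):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be a fraction in [0, 1], got {value}")
    if nc_pre == 0.0:
        return EnrichmentRecord(variant, nc_pre, nc_sample, math.nan, "undefined_pre_zero")
    return EnrichmentRecord(variant, nc_pre, nc_sample, nc_sample / nc_pre, "defined")


def format_ef(ef: float) -> str:
    """Display rounding for EFs (display only, never used in computation):
    de-enrichment factors (< 1) print with two decimals, enrichment factors
    with two significant figures, and large EFs (>= 1000) to the nearest
    hundred."""
    if math.isnan(ef):
        return "NA"
    if ef == 0:
        return "0"
    if ef >= 1000:
        return f"{round(ef / 100) * 100:,d}"
    if ef >= 1:
        return f"{float(f'{ef:.2g}'):g}"
    return f"{ef:.2f}"


def _marginal_counts(
    sample: SampleCounts, keyfunc
) -> dict[object, int]:
    out: dict[object, int] = {}
    for key, n in sample.counts.items():
        k = keyfunc(key)
        out[k] = out.get(k, 0) + n
    return out


@dataclass
class ResidueTable:
    """Per-residue marginal frequencies and enrichment at one position."""

    position: str
    frequencies: dict[str, dict[str, float]]  # sample_id -> residue -> fraction
    enrichment: dict[str, EnrichmentRecord]  # residue -> record vs pre-selection


def residue_enrichment(
    pre: SampleCounts, final: SampleCounts, position: str
) -> ResidueTable:
    """Marginal residue frequencies at a randomized position and their EFs.

    Residue counts are sums of variant counts sharing the residue at the
    position; EF per residue as for variants (absent-from-final residues
    get EF 0, absent-from-pre residues are undefined).
    """
    if position not in POSITIONS:
        raise ConfigurationError(
            f"position must be one of {POSITIONS}, got {position!r}"
        )
    freqs: dict[str, dict[str, float]] = {}
    marginals = {}
    for sample in (pre, final):
        total = sample.total_reads
        if total < 1:
            raise EmptySampleError(f"sample {sample.sample_id!r} is empty")
        marg = _marginal_counts(sample, lambda k: k.residue(position))
        marginals[sample.sample_id] = marg
        freqs[sample.sample_id] = {res: n / total for res, n in marg.items()}
    pre_f = freqs[pre.sample_id]
    fin_f = freqs[final.sample_id]
    records = {}
    for res in sorted(set(pre_f) | set(fin_f)):
        records[res] = enrichment_factor(
            pre_f.get(res, 0.0), fin_f.get(res, 0.0), variant=res
        )
    return ResidueTable(position=position, frequencies=freqs, enrichment=records)


def _sort_records(records: list[EnrichmentRecord]) -> list[EnrichmentRecord]:
    # descending EF, undefined last; ties by nc_sample desc then key
    return sorted(
        records,
        key=lambda r: (
            r.status != "defined",
            -(r.enrichment_factor if r.status == "defined" else 0.0),
            -r.nc_sample,
            str(r.variant),
        ),
    )


def pair_enrichment(
    pre: SampleCounts,
    final: SampleCounts,
    chain: Literal["vh", "vl", "combined"] = "combined",
    top: int | None = None,
    include_stops: bool = False,
) -> list[EnrichmentRecord]:
    """Ranked EFs of VH pairs, VL pairs, or full paired variants.

    Chain marginals sum variant counts sharing the VH (or VL) pair;
    `combined` uses the joint amino-acid-level key.  Stop-containing
    variants stay in the frequency denominators but are dropped from the
    ranked report unless `include_stops`.
    """
    if chain == "vh":
        keyfunc = lambda k: k.vh_pair  # noqa: E731
    elif chain == "vl":
        keyfunc = lambda k: k.vl_pair  # noqa: E731
    elif chain == "combined":
        keyfunc = lambda k: k.aa_key  # noqa: E731
    else:
        raise ConfigurationError(f"unknown chain {chain!r}")
    pre_total, fin_total = pre.total_reads, final.total_reads
    if pre_total < 1 or fin_total < 1:
        raise EmptySampleError("both samples must be non-empty")
    pre_m = _marginal_counts(pre, keyfunc)
    fin_m = _marginal_counts(final, keyfunc)
    records = []
    for key in set(pre_m) | set(fin_m):
        if not include_stops and "*" in str(key):
            continue
        records.append(
            enrichment_factor(
                pre_m.get(key, 0) / pre_total,
                fin_m.get(key, 0) / fin_total,
                variant=key,
            )
        )
    ranked = _sort_records(records)
    return ranked[:top] if top is not None else ranked


def round_trajectory(
    samples: Mapping[str, SampleCounts], pre_id: str = "pre-selection"
) -> pd.DataFrame:
    """EF of every variant in every round, all versus pre-selection.

    Returns a variants x rounds frame (NaN where undefined); trajectories
    are not assumed monotone.
    """
    if pre_id not in samples:
        raise ConfigurationError(f"missing pre-selection sample {pre_id!r}")
    rounds = [sid for sid in samples if sid != pre_id]
    if not rounds:
        raise ConfigurationError("need at least one post-selection sample")
    nc_pre = normalized_counts(samples[pre_id])
    variants = sorted({k for s in samples.values() for k in s.counts})
    data = {}
    for sid in rounds:
        nc = normalized_counts(samples[sid])
        col = []
        for v in variants:
            rec = enrichment_factor(nc_pre.get(v, 0.0), nc.get(v, 0.0), variant=v)
            col.append(rec.enrichment_factor)
        data[sid] = col
    return pd.DataFrame(data, index=[str(v) for v in variants])
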