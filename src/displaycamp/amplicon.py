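"""Amplicon layout and variant keys for the two mutagenized patches.

The selection campaign randomizes two two-codon patches — positions 94/95
of the light-chain CDR-L3 and positions 53/54 of the heavy-chain CDR-H2 —
and sequences both patches on a single amplicon so that VL and VH variants
can be paired per read.  A variant is identified by the two amino-acid
pairs (and optionally the underlying 12 nucleotides for DNA-level
clustering).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

from .library_design import _CODON_TO_AA

__all__ = [
    "VariantKey",
    "AmpliconTemplate",
    "bococizumab_template",
    "PARENTAL_KEY",
    "PARENTAL_DNA_KEY",
    "POSITIONS",
    "translate_patch",
]

#: labels of the four randomized positions, amplicon order (VL before VH)
POSITIONS = ("VL94", "VL95", "VH53", "VH54")

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*")


def translate_patch(patch: str) -> str:
    """Translate a 3k-nucleotide patch with the standard code ('*' = stop)."""
    if len(patch) % 3:
        raise ValueError(f"patch length must be a multiple of 3, got {len(patch)}")
    return "".join(_CODON_TO_AA[patch[i : i + 3]] for i in range(0, len(patch), 3))


@dataclass(frozen=True, order=True)
class VariantKey:
    """Paired patch identity: VL 94/95 and VH 53/54 amino-acid pairs.

    `dna_key`, when present, is the concatenated 12 nucleotides of the four
    randomized codons (VL94, VL95, VH53, VH54 order) and must translate to
    the amino-acid pairs.
    """

    vl_pair: str
    vh_pair: str
    dna_key: str | None = None

    def __post_init__(self) -> None:
        for pair in (self.vl_pair, self.vh_pair):
            if len(pair) != 2 or any(sym not in _AA_ALPHABET for sym in pair):
                raise ValueError(f"invalid amino-acid pair {pair!r}")
        if self.dna_key is not None:
            if len(self.dna_key) != 12:
                raise ValueError(f"dna_key must have 12 nt, got {self.dna_key!r}")
            if translate_patch(self.dna_key) != self.vl_pair + self.vh_pair:
                raise ValueError(
                    f"dna_key {self.dna_key!r} does not translate to "
                    f"{self.vl_pair + self.vh_pair!r}"
                )

    @property
    def aa_key(self) -> "VariantKey":
        """The amino-acid-level key (dna_key dropped)."""
        if self.dna_key is None:
            return self
        return VariantKey(self.vl_pair, self.vh_pair)

    @property
    def has_stop(self) -> bool:
        return "*" in self.vl_pair or "*" in self.vh_pair

    def residue(self, position: str) -> str:
        """Residue at one of the four randomized positions (e.g. 'VH54')."""
        idx = POSITIONS.index(position)
        return (self.vl_pair + self.vh_pair)[idx]

    def __str__(self) -> str:  # 'PF/LW' style: VH then VL, the field's order
        return f"{self.vh_pair}/{self.vl_pair}"

    @classmethod
    def from_dna(cls, dna_key: str) -> "VariantKey":
        aa = translate_patch(dna_key)
        return cls(vl_pair=aa[:2], vh_pair=aa[2:], dna_key=dna_key)


@dataclass(frozen=True)
class AmpliconTemplate:
    """Fixed sequence context around the two randomized 6-nt patches.

    The amplicon reads, 5' to 3':
    ``upstream_anchor_vl | VL patch | downstream_anchor_vl |
    inter_patch_sequence | upstream_anchor_vh | VH patch |
    downstream_anchor_vh``.
    """

    upstream_anchor_vl: str
    downstream_anchor_vl: str
    upstream_anchor_vh: str
    downstream_anchor_vh: str
    inter_patch_sequence: str

    def __post_init__(self) -> None:
        for name in (
            "upstream_anchor_vl",
            "downstream_anchor_vl",
            "upstream_anchor_vh",
            "downstream_anchor_vh",
        ):
            anchor = getattr(self, name)
            if not anchor or set(anchor) - set("ACGT"):
                raise ValueError(f"{name} must be a non-empty ACGT string")

    @cached_property
    def codon_offsets(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """(start, end) spans of the VL and VH patches, 0-based half-open."""
        vl_start = len(self.upstream_anchor_vl)
        vh_start = (
            vl_start
            + 6
            + len(self.downstream_anchor_vl)
            + len(self.inter_patch_sequence)
            + len(self.upstream_anchor_vh)
        )
        return ((vl_start, vl_start + 6), (vh_start, vh_start + 6))

    @cached_property
    def length(self) -> int:
        return self.codon_offsets[1][1] + len(self.downstream_anchor_vh)

    def build(self, dna_key: str) -> str:
        """Amplicon sequence for a variant's 12 randomized nucleotides."""
        if len(dna_key) != 12:
            raise ValueError(f"dna_key must have 12 nt, got {dna_key!r}")
        return (
            self.upstream_anchor_vl
            + dna_key[:6]
            + self.downstream_anchor_vl
            + self.inter_patch_sequence
            + self.upstream_anchor_vh
            + dna_key[6:]
            + self.downstream_anchor_vh
        )


#: parental (bococizumab) patches: VL L94/W95, VH P53/F54
PARENTAL_KEY = VariantKey(vl_pair="LW", vh_pair="PF")
#: one NNK-compatible codon choice per parental residue (synthetic; the
#: codon-level parental sequence is a simulator convention)
PARENTAL_DNA_KEY = "CTGTGG" + "CCTTTT"

# Anchor sequences from the mutagenesis primer contexts: the VL patch sits
# between GCCAGCAAAGATATTCT and CGGACATTCGGGCAAGGA on the forward strand;
# the VH patch between GAGTGGATGGGCGAAATCTCC and GGCGGACGGACCAA (reverse
# primer context, reverse-complemented).
_VL_UP = "GCCAGCAAAGATATTCT"
_VL_DOWN = "CGGACATTCGGGCAAGGA"
_VH_UP = "GAGTGGATGGGCGAAATCTCC"
_VH_DOWN = "GGCGGACGGACCAA"

# Synthetic spacer standing in for the constant region between the patches
# (light-chain tail / T2A / heavy-chain lead); the real amplicon carries
# ~700 bp here, which is irrelevant to patch extraction.
_SPACER = "GGTACCGAGCTCGGATCCACTAGTCCAGTGTGGTGGAATTCTGCAGATATCCAGCACAGTGGCG"


def bococizumab_template(inter_patch_sequence: str = _SPACER) -> AmpliconTemplate:
    """Default amplicon template of the optimization campaign."""
    return AmpliconTemplate(
        upstream_anchor_vl=_VL_UP,
        downstream_anchor_vl=_VL_DOWN,
        upstream_anchor_vh=_VH_UP,
        downstream_anchor_vh=_VH_DOWN,
        inter_patch_sequence=inter_patch_sequence,
    )
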