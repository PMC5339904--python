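"""Focussed combinatorial TMD library: variants, pairs, hybrids.

The library template is a 19-residue poly-Leu helix with an invariant
GxxxG motif ("L19GG").  Each library member carries a single ionizable
residue (D, E, K or R) at one of eight randomized positions; together with
the unsubstituted backbone this gives 33 variants per plasmid side and
33 x 33 = 1089 ordered (N-side, C-side) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO

__all__ = [
    "BACKBONE_ID",
    "BACKBONE_SEQUENCE",
    "RANDOMIZED_POSITIONS",
    "IONIZABLE_RESIDUES",
    "NEGATIVE_RESIDUES",
    "POSITIVE_RESIDUES",
    "TMDVariant",
    "TMDPair",
    "HybridParts",
    "make_variant",
    "enumerate_library",
    "enumerate_pairs",
    "parse_variant",
    "shift_orientation",
    "assemble_hybrid",
    "write_fasta",
    "write_manifest",
]

BACKBONE_ID = "L19GG"
# Gly indices (14, 18) are a convention knob; all pattern statistics are
# independent of where the GxxxG sits, only the randomized set matters.
BACKBONE_SEQUENCE = "LLLLLLLLLLLLLGLLLGL"
RANDOMIZED_POSITIONS = (2, 3, 4, 6, 7, 9, 10, 11)
IONIZABLE_RESIDUES = ("D", "E", "K", "R")
NEGATIVE_RESIDUES = frozenset("DE")
POSITIVE_RESIDUES = frozenset("KR")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class TMDVariant:
    """A single library member: the backbone with at most one substitution.

    ``position`` is 1-based along the 19-mer, N to C.  The wild-type
    backbone has ``position is None`` and ``residue is None``.
    """

    sequence: str
    position: Optional[int] = None
    residue: Optional[str] = None
    backbone_id: str = BACKBONE_ID

    def __post_init__(self):
        if len(self.sequence) != 19:
            raise ValueError(f"TMD must be 19 residues, got {len(self.sequence)}")
        if (self.position is None) != (self.residue is None):
            raise ValueError("position and residue must be given together")
        if self.position is not None:
            if self.position not in RANDOMIZED_POSITIONS:
                raise ValueError(
                    f"position {self.position} not in randomized set "
                    f"{RANDOMIZED_POSITIONS}"
                )
            expected = (
                BACKBONE_SEQUENCE[: self.position - 1]
                + self.residue
                + BACKBONE_SEQUENCE[self.position :]
            )
            if self.sequence != expected:
                raise ValueError("sequence inconsistent with (position, residue)")

    @property
    def variant_id(self) -> str:
        if self.position is None:
            return self.backbone_id
        return f"{self.backbone_id}_{self.residue}{self.position}"

    @property
    def is_charged(self) -> bool:
        return self.residue is not None

    @property
    def charge_sign(self) -> int:
        """-1 / +1 for an ionizable substitution, 0 for the backbone."""
        if self.residue is None:
            return 0
        return -1 if self.residue in NEGATIVE_RESIDUES else 1


WILD_TYPE = TMDVariant(sequence=BACKBONE_SEQUENCE)


def make_variant(position: int, residue: str) -> TMDVariant:
    """Backbone with a single ionizable residue at one randomized position."""
    if position not in RANDOMIZED_POSITIONS:
        raise ValueError(
            f"position {position} is not randomized; allowed: "
            f"{RANDOMIZED_POSITIONS}"
        )
    if residue not in IONIZABLE_RESIDUES:
        raise ValueError(
            f"residue {residue!r} not ionizable; allowed: {IONIZABLE_RESIDUES}"
        )
    sequence = (
        BACKBONE_SEQUENCE[: position - 1] + residue + BACKBONE_SEQUENCE[position:]
    )
    return TMDVariant(sequence=sequence, position=position, residue=residue)


def enumerate_library(include_wild_type: bool = True) -> list[TMDVariant]:
    """All 32 single-charge variants (position-major, residue alphabetical)
    plus, by default, the unsubstituted backbone (33 total)."""
    variants = [
        make_variant(pos, res)
        for pos in RANDOMIZED_POSITIONS
        for res in sorted(IONIZABLE_RESIDUES)
    ]
    if include_wild_type:
        variants.append(WILD_TYPE)
    return variants


@dataclass(frozen=True)
class TMDPair:
    """Ordered combination of an N-side and a C-side library variant."""

    n_variant: TMDVariant
    c_variant: TMDVariant
    observed_count: int = 0
    percent_of_reference: Optional[float] = None
    affinity_class: Optional[str] = None

    def __post_init__(self):
        if self.observed_count < 0:
            raise ValueError("observed_count must be >= 0")

    @property
    def pair_id(self) -> str:
        return f"{self.n_variant.variant_id}/{self.c_variant.variant_id}"

    def swapped(self) -> "TMDPair":
        return TMDPair(
            n_variant=self.c_variant,
            c_variant=self.n_variant,
            observed_count=self.observed_count,
            percent_of_reference=self.percent_of_reference,
            affinity_class=self.affinity_class,
        )


def enumerate_pairs() -> list[TMDPair]:
    """Full ordered cross product of the per-plasmid library: 1089 pairs."""
    variants = enumerate_library()
    return [
        TMDPair(n_variant=n, c_variant=c) for n in variants for c in variants
    ]


def parse_variant(sequence: str) -> TMDVariant:
    """Recover (position, residue) from a library sequence (round-trip)."""
    if len(sequence) != 19:
        raise ValueError("library sequences are 19 residues")
    diffs = [
        i + 1
        for i, (a, b) in enumerate(zip(sequence, BACKBONE_SEQUENCE))
        if a != b
    ]
    if not diffs:
        return WILD_TYPE
    if len(diffs) > 1:
        raise ValueError(f"sequence differs from backbone at {diffs}")
    pos = diffs[0]
    return make_variant(pos, sequence[pos - 1])


def shift_orientation(
    parent_context: str, window_start: int, window_len: int, n: int
) -> str:
    """Slide a TMD window ``n`` residues toward the N-terminus of its
    natural flanking context, preserving the window length.

    This adds ``n`` residues at the TMD N-terminus and drops the same
    number at the C-terminus, rotating the helix face presented to the
    fused enzyme fragments.  ``window_start`` is a 0-based index into
    ``parent_context``.  ``n`` must be 0..3; n = 0 is the identity.
    """
    if not 0 <= n <= 3:
        raise ValueError("shift must be between 0 and 3 residues")
    if window_start < 0 or window_start + window_len > len(parent_context):
        raise ValueError("window outside parent context")
    new_start = window_start - n
    if new_start < 0:
        raise ValueError(
            f"insufficient N-terminal flanking context for shift {n}"
        )
    return parent_context[new_start : new_start + window_len]


# expanded defaults for the linkers connecting enzyme fragment, TMD and
# reporter: SGS(GGGS)2GS flexible, A(EAAAK)5A rigid helical
FLEXIBLE_LINKER = "SGS" + "GGGS" * 2 + "GS"
RIGID_LINKER = "A" + "EAAAK" * 5 + "A"


@dataclass(frozen=True)
class HybridParts:
    """Protein-level parts of one reporter hybrid, N to C terminus."""

    signal_peptide: str
    bla_fragment: str
    tmd: str
    reporter: str
    flexible_linker: str = FLEXIBLE_LINKER
    rigid_linker: str = RIGID_LINKER
    tag: str = "DYKDDDDK"  # FLAG epitope, appended C-terminally
    bla_fragment_id: str = "N-BLa"


def assemble_hybrid(parts: HybridParts) -> str:
    """Concatenate signal-BLa fragment-flexible linker-TMD-rigid
    linker-reporter-tag; the tag may be empty."""
    segments = [
        ("signal_peptide", parts.signal_peptide),
        ("bla_fragment", parts.bla_fragment),
        ("flexible_linker", parts.flexible_linker),
        ("tmd", parts.tmd),
        ("rigid_linker", parts.rigid_linker),
        ("reporter", parts.reporter),
        ("tag", parts.tag),
    ]
    for name, seq in segments:
        if name != "tag" and not seq:
            raise ValueError(f"hybrid part {name!r} must be non-empty")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"hybrid part {name!r} contains non-amino-acid letters {sorted(bad)}"
            )
    return "".join(seq for _, seq in segments)


def write_fasta(records: Iterable[tuple[str, str]], handle: TextIO) -> None:
    """Minimal FASTA writer for (id, sequence) records."""
    for name, seq in records:
        handle.write(f">{name}\n")
        for i in range(0, len(seq), 60):
            handle.write(seq[i : i + 60] + "\n")


def write_manifest(variants: Iterable[TMDVariant], handle: TextIO) -> None:
    """TSV library manifest: variant_id, position, residue, sequence."""
    handle.write("variant_id\tposition\tresidue\tsequence\n")
    for v in variants:
        pos = "" if v.position is None else str(v.position)
        res = "" if v.residue is None else v.residue
        handle.write(f"{v.variant_id}\t{pos}\t{res}\t{v.sequence}\n")
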