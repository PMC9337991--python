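"""Transcription-template constructs for single-round termination assays.

A construct is the RNA product of a double-stranded DNA template carrying a
constitutive promoter. Transcription is performed in two phases: an
*initiation* phase with a nucleotide mix lacking CTP, so that RNA polymerase
stalls at the first C residue of the template (the halt site), and an
*elongation* phase after the full nucleotide mix (plus heparin, to enforce a
single round) is added. The two phases use UTP pools with different
radiolabel fractions, so the number of U residues incorporated in each phase
determines the specific radioactivity of every possible transcript product.

Coordinates are 1-based and inclusive, matching nucleotide numbering on gel
annotations (e.g. "position A35"). The halt site belongs to the initiation
region: the initiation region is positions [1, halt_index] and the
elongation region of a product ending at position ``end`` is
(halt_index, end].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: Closed set of transcript-species labels: terminated at the single
#: terminator (T), at the first or second tandem terminator (T1, T2), or
#: read through to full length (FL).
SPECIES_LABELS = ("T", "T1", "T2", "FL")


@dataclass(frozen=True)
class TranscriptSpecies:
    """One possible transcription product of a construct.

    Parameters
    ----------
    label
        One of ``{"T", "T1", "T2", "FL"}``.
    end
        1-based inclusive 3' end position of the product on the construct.
    u_init
        Number of U residues in the initiation region (positions 1..halt).
    u_elong
        Number of U residues in the elongation region (halt..end].
    """

    label: str
    end: int
    u_init: int
    u_elong: int

    def __post_init__(self) -> None:
        if self.label not in SPECIES_LABELS:
            raise ValueError(
                f"species label {self.label!r} not in {SPECIES_LABELS}"
            )


@dataclass(frozen=True)
class AptamerConstruct:
    """An RNA transcription template with halt site and product ends.

    ``species_ends`` lists every possible product as ``(label, end)``,
    strictly increasing in ``end``; the last entry is always the full-length
    product ending at the final nucleotide.
    """

    name: str
    sequence: str
    halt_index: int
    species_ends: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        seq = self.sequence
        if not seq:
            raise ValueError("construct sequence is empty")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"construct {self.name!r}: illegal characters {sorted(bad)}; "
                "sequence must be over {A,C,G,U}"
            )
        if not 1 <= self.halt_index < len(seq):
            raise ValueError(
                f"halt_index {self.halt_index} must satisfy "
                f"1 <= halt < length ({len(seq)}); the halted polymerase must "
                "be able to elongate further"
            )
        ends = [e for _, e in self.species_ends]
        labels = [l for l, _ in self.species_ends]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate species labels: {labels}")
        if any(b <= a for a, b in zip(ends, ends[1:])):
            raise ValueError(f"species ends must be strictly increasing: {ends}")
        if not ends or ends[-1] != len(seq):
            raise ValueError("full-length species must end at the sequence end")
        if labels[-1] != "FL":
            raise ValueError("last species must be labelled FL")
        if any(e < self.halt_index for e in ends):
            raise ValueError("no species may end before the halt site")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def terminator_ends(self) -> tuple[tuple[str, int], ...]:
        """Species ends excluding the full-length product."""
        return self.species_ends[:-1]

    def species(self) -> list[TranscriptSpecies]:
        """All transcript species with populated U counts (see define_species)."""
        return define_species(self, self.terminator_ends)


def _to_rna(sequence: str, name: str) -> str:
    seq = sequence.upper().replace(" ", "")
    if "T" in seq:
        logger.info(
            "construct %s: DNA-alphabet input detected; transcribing T -> U",
            name,
        )
        seq = seq.replace("T", "U")
    return seq


def parse_construct(
    record,
    halt_rule: str = "first-C",
    halt_index: int | None = None,
    terminator_ends: Sequence[tuple[str, int]] | Sequence[int] = (),
) -> AptamerConstruct:
    """Build an :class:`AptamerConstruct` from a FASTA record or (name, seq).

    Parameters
    ----------
    record
        A Bio.SeqRecord, a ``(name, sequence)`` pair, or a bare sequence
        string. T characters (DNA alphabet) are transcribed to U.
    halt_rule
        ``"first-C"`` sets the halt site to the position of the first C
        residue (the initiation mix lacks CTP, so the polymerase stalls
        there); ``"explicit"`` takes ``halt_index`` as given.
    terminator_ends
        Ends of terminated products, either ``(label, end)`` pairs or bare
        end positions (auto-labelled ``T`` for a single terminator,
        ``T1``/``T2`` for a tandem pair). The full-length product is always
        registered at the sequence end.
    """
    if hasattr(record, "seq"):  # Bio.SeqRecord
        name, seq = record.id, str(record.seq)
    elif isinstance(record, tuple):
        name, seq = record
    else:
        name, seq = "construct", str(record)
    seq = _to_rna(seq, name)
    if not seq:
        raise ValueError("construct sequence is empty")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(
            f"construct {name!r}: illegal characters {sorted(bad)}"
        )

    if halt_rule == "first-C":
        pos = seq.find("C")
        if pos == -1:
            raise ValueError(
                f"construct {name!r}: halt rule 'first-C' requires a C "
                "residue, but the sequence contains none"
            )
        halt = pos + 1
    elif halt_rule == "explicit":
        if halt_index is None:
            raise ValueError("halt_rule 'explicit' requires halt_index")
        halt = halt_index
    else:
        raise ValueError(f"unknown halt rule {halt_rule!r}")

    ends = _label_terminators(terminator_ends)
    species_ends = tuple(ends) + (("FL", len(seq)),)
    return AptamerConstruct(
        name=name, sequence=seq, halt_index=halt, species_ends=species_ends
    )


def _label_terminators(
    terminator_ends: Sequence[tuple[str, int]] | Sequence[int],
) -> list[tuple[str, int]]:
    if not terminator_ends:
        return []
    first = terminator_ends[0]
    if isinstance(first, (tuple, list)):
        return [(str(l), int(e)) for l, e in terminator_ends]
    ends = [int(e) for e in terminator_ends]
    if len(ends) == 1:
        return [("T", ends[0])]
    if len(ends) == 2:
        return [("T1", ends[0]), ("T2", ends[1])]
    raise ValueError(
        "at most two internal terminators are supported (labels T1, T2)"
    )


def read_constructs_fasta(
    path,
    halt_rule: str = "first-C",
    halt_index: int | None = None,
    terminator_ends: Sequence = (),
) -> list[AptamerConstruct]:
    """Read one or more constructs from a FASTA file (RNA or DNA alphabet)."""
    from Bio import SeqIO

    return [
        parse_construct(rec, halt_rule, halt_index, terminator_ends)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def count_region_u(construct: AptamerConstruct, end: int) -> tuple[int, int]:
    """Count U residues in the initiation and elongation regions.

    Initiation region is positions ``[1, halt_index]`` (shared by every
    product of the construct); elongation region is ``(halt_index, end]``.
    These counts weight the two radiolabel fractions of the labelling scheme.
    """
    if end < construct.halt_index:
        raise ValueError(
            f"species end {end} precedes halt site {construct.halt_index}: "
            "a product cannot end before the halt site"
        )
    if end > construct.length:
        raise ValueError(f"end {end} beyond sequence length {construct.length}")
    seq = construct.sequence
    u_init = seq[: construct.halt_index].count("U")
    u_elong = seq[construct.halt_index : end].count("U")
    return u_init, u_elong


def define_species(
    construct: AptamerConstruct,
    terminator_ends: Sequence[tuple[str, int]] | Sequence[int],
) -> list[TranscriptSpecies]:
    """Define the transcript species of a construct with populated U counts.

    The full-length product is always included, ending at the last
    nucleotide; terminated products are supplied as ``(label, end)`` pairs
    (or bare positions, auto-labelled). Species are returned sorted by end.
    """
    ends = _label_terminators(terminator_ends) + [("FL", construct.length)]
    labels = [l for l, _ in ends]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate species labels: {labels}")
    ends.sort(key=lambda le: le[1])
    if ends[-1][0] != "FL":
        raise ValueError("a terminator end falls at or beyond the sequence end")
    out = []
    for label, end in ends:
        if not 1 <= end <= construct.length:
            raise ValueError(f"species {label}: end {end} out of range")
        u_init, u_elong = count_region_u(construct, end)
        out.append(TranscriptSpecies(label, end, u_init, u_elong))
    return out
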