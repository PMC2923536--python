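"""Enumeration of EMS-accessible changes in the standard genetic code.

EMS (ethyl methane sulfonate) alkylates guanine and induces, almost
exclusively, G:C -> A:T transitions.  On the sense strand every possible
EMS lesion is therefore either G->A or C->T, and the universe of coding
consequences can be enumerated exhaustively over the 64 codons: each G or
C occurrence in a codon is one mutable position, 96 in total.  This module
performs that census, classifies each change as silent / mis-sense /
nonsense, and profiles arbitrary coding sequences for their EMS effect
potential (e.g. to find the amplicon window richest in potential stop
codons before designing a TILLING screen).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator

from Bio.Data.CodonTable import standard_dna_table

STOP = "*"

#: codon -> amino acid (one-letter) or "*" for the three stop codons,
#: standard nuclear code (translation table 1).
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TABLE.update({c: STOP for c in standard_dna_table.stop_codons})

ALL_CODONS: tuple[str, ...] = tuple(sorted(CODON_TABLE))

#: EMS transition targets on the sense strand.
EMS_TRANSITIONS: dict[str, str] = {"G": "A", "C": "T"}

SILENT = "silent"
MISSENSE = "mis-sense"
NONSENSE = "nonsense"

#: Default chemical-similarity grouping used to flag "conservative"
#: mis-sense changes.  Any partition of the 20 amino acids may be passed
#: instead; this default groups aliphatic, aromatic, basic, acidic,
#: hydroxylic and amide side chains.
DEFAULT_SIMILARITY_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g) for g in ("ILVM", "FYW", "KRH", "DE", "ST", "NQ", "AG", "C", "P")
)


class SequenceError(ValueError):
    """Raised for sequences or codons outside the {A,C,G,T} alphabet."""


@dataclass(frozen=True)
class EMSChange:
    """A single G->A or C->T substitution at one codon position.

    ``position`` is 1-based within the codon.  ``change_class`` is
    ``silent`` when the encoded product is unchanged (stop -> stop counts
    as unchanged), ``nonsense`` when a sense codon gains a stop, and
    ``mis-sense`` otherwise.
    """

    codon: str
    position: int
    from_base: str
    to_base: str
    new_codon: str
    aa_from: str
    aa_to: str
    change_class: str


@dataclass(frozen=True)
class SpectrumSummary:
    """Exhaustive census of EMS-accessible changes over the 64 codons."""

    unaffected_codons: int
    mutable_positions: int
    silent: int
    mis_sense: int
    nonsense: int
    distinct_substitutions: int
    conservative_sites: int

    @property
    def class_counts(self) -> dict[str, int]:
        return {SILENT: self.silent, MISSENSE: self.mis_sense, NONSENSE: self.nonsense}


@dataclass
class CDSProfile:
    """Per-site EMS change classification along one coding sequence."""

    sequence_id: str
    length_bp: int
    mutable_sites: int
    per_site_changes: list[tuple[int, EMSChange]]
    class_counts: dict[str, int]
    window_nonsense_density: list[tuple[int, int, int]] = field(default_factory=list)


def _check_codon(codon: str) -> str:
    codon = codon.upper()
    if codon not in CODON_TABLE:
        raise SequenceError(f"not a valid DNA codon: {codon!r}")
    return codon


def translate_codon(codon: str) -> str:
    """Amino acid (one-letter) for ``codon``; ``*`` for a stop codon."""
    return CODON_TABLE[_check_codon(codon)]


def classify_change(from_codon: str, to_codon: str) -> str:
    """Classify a single EMS substitution between two codons.

    The codons must differ at exactly one position by G->A or C->T.
    Stop -> stop is silent (the product, chain termination, is unchanged).
    """
    from_codon = _check_codon(from_codon)
    to_codon = _check_codon(to_codon)
    diffs = [i for i in range(3) if from_codon[i] != to_codon[i]]
    if len(diffs) != 1 or EMS_TRANSITIONS.get(from_codon[diffs[0]]) != to_codon[diffs[0]]:
        raise SequenceError(
            f"{from_codon}->{to_codon} is not a single G->A or C->T substitution"
        )
    aa_from, aa_to = CODON_TABLE[from_codon], CODON_TABLE[to_codon]
    if aa_from == aa_to:
        return SILENT
    if aa_to == STOP:
        return NONSENSE
    return MISSENSE


def ems_changes_for_codon(codon: str) -> list[EMSChange]:
    """All EMS-accessible changes for one codon, in position order.

    Returns one :class:`EMSChange` per G or C in the codon; the empty list
    iff the codon contains neither (8 of the 64 codons).
    """
    codon = _check_codon(codon)
    changes = []
    for i, base in enumerate(codon):
        to = EMS_TRANSITIONS.get(base)
        if to is None:
            continue
        new_codon = codon[:i] + to + codon[i + 1 :]
        aa_from, aa_to = CODON_TABLE[codon], CODON_TABLE[new_codon]
        if aa_from == aa_to:
            cls = SILENT
        elif aa_to == STOP:
            cls = NONSENSE
        else:
            cls = MISSENSE
        changes.append(
            EMSChange(codon, i + 1, base, to, new_codon, aa_from, aa_to, cls)
        )
    return changes


def iter_all_changes() -> Iterator[EMSChange]:
    """Iterate the 96 EMS changes of the standard code, codon by codon."""
    for codon in ALL_CODONS:
        yield from ems_changes_for_codon(codon)


def _is_conservative(change: EMSChange, groups: tuple[frozenset[str], ...]) -> bool:
    if change.change_class != MISSENSE:
        return False
    return any(change.aa_from in g and change.aa_to in g for g in groups)


def code_spectrum(
    similarity_groups: tuple[frozenset[str], ...] = DEFAULT_SIMILARITY_GROUPS,
) -> SpectrumSummary:
    """Exhaustive EMS change census over the standard genetic code.

    The counts are fixed properties of the code: 8 codons carry no G/C and
    are untouchable by EMS; the remaining 56 codons expose 96 mutable
    positions, partitioned 33 silent / 58 mis-sense / 5 nonsense, with 26
    distinct amino-acid substitutions reachable.  ``conservative_sites``
    depends on the (pluggable) similarity grouping and is not a fixed
    property of the code.
    """
    changes = list(iter_all_changes())
    counts = Counter(c.change_class for c in changes)
    substitutions = {
        (c.aa_from, c.aa_to) for c in changes if c.change_class == MISSENSE
    }
    unaffected = sum(
        1 for codon in ALL_CODONS if not set(codon) & EMS_TRANSITIONS.keys()
    )
    return SpectrumSummary(
        unaffected_codons=unaffected,
        mutable_positions=len(changes),
        silent=counts[SILENT],
        mis_sense=counts[MISSENSE],
        nonsense=counts[NONSENSE],
        distinct_substitutions=len(substitutions),
        conservative_sites=sum(
            1 for c in changes if _is_conservative(c, similarity_groups)
        ),
    )


def expected_class_fractions() -> dict[str, float]:
    """Fractions of the 96 mutable positions in each change class.

    Under a uniform-codon-usage assumption these are the expected class
    fractions of EMS mutations falling in coding sequence (e.g. a 5/96
    chance that a coding hit creates a stop codon).
    """
    s = code_spectrum()
    return {
        SILENT: s.silent / s.mutable_positions,
        MISSENSE: s.mis_sense / s.mutable_positions,
        NONSENSE: s.nonsense / s.mutable_positions,
    }


def profile_cds(
    sequence: str,
    frame_offset: int = 0,
    window_bp: int = 100,
    sequence_id: str = "cds",
    skip_ambiguous: bool = False,
) -> CDSProfile:
    """Classify every possible EMS change along a coding sequence.

    Parameters
    ----------
    sequence
        Sense-strand DNA.  Codons are read from ``frame_offset`` onwards;
        a trailing partial codon is ignored.
    frame_offset
        0-based offset of the first codon (0, 1 or 2 typically).
    window_bp
        Width of the tiling windows used for the nonsense-site density
        track (the last window of the covered region may be shorter).
    skip_ambiguous
        If True, codons containing non-ACGT characters are skipped with a
        warning instead of raising :class:`SequenceError`.

    Antisense lesions are not double-counted: a C->T on the reported
    strand is the same lesion as G->A on the complement.
    """
    seq = sequence.upper()
    if frame_offset < 0 or frame_offset >= len(seq):
        raise SequenceError(
            f"frame_offset {frame_offset} outside sequence of length {len(seq)}"
        )
    if len(seq) - frame_offset < 3:
        raise SequenceError("fewer than one full codon after frame offset")

    per_site: list[tuple[int, EMSChange]] = []
    n_codons = (len(seq) - frame_offset) // 3
    for ci in range(n_codons):
        start = frame_offset + 3 * ci
        codon = seq[start : start + 3]
        if set(codon) - {"A", "C", "G", "T"}:
            if skip_ambiguous:
                warnings.warn(
                    f"{sequence_id}: skipping ambiguous codon {codon!r} "
                    f"at position {start + 1}",
                    stacklevel=2,
                )
                continue
            raise SequenceError(
                f"{sequence_id}: ambiguous codon {codon!r} at position {start + 1}"
            )
        for change in ems_changes_for_codon(codon):
            per_site.append((start + change.position, change))

    counts = Counter(c.change_class for _, c in per_site)
    class_counts = {
        SILENT: counts[SILENT],
        MISSENSE: counts[MISSENSE],
        NONSENSE: counts[NONSENSE],
    }

    covered_end = frame_offset + 3 * n_codons  # 1-based inclusive end of coverage
    windows: list[tuple[int, int, int]] = []
    w_start = frame_offset + 1
    while w_start <= covered_end:
        w_end = min(w_start + window_bp - 1, covered_end)
        n_non = sum(
            1
            for pos, c in per_site
            if w_start <= pos <= w_end and c.change_class == NONSENSE
        )
        windows.append((w_start, w_end, n_non))
        w_start = w_end + 1

    return CDSProfile(
        sequence_id=sequence_id,
        length_bp=len(seq),
        mutable_sites=len(per_site),
        per_site_changes=per_site,
        class_counts=class_counts,
        window_nonsense_density=windows,
    )
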