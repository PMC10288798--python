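"""Reference loci, guide placement, and indel coordinate canonicalization.

Conventions used throughout the package:

* Sequences are uppercase DNA over ``{A, C, G, T}``.
* All coordinates are 0-based; intervals are half-open ``[start, end)``.
* A Cas9 cut site is a *boundary* between two reference bases, stored as the
  integer index of the base to its right.  The blunt cut is placed 3 nt
  5' of the PAM (between protospacer positions 17 and 18), the standard
  SpCas9 geometry; the offset is configurable in :func:`locate_guide`.
* Guides found on the minus strand are stored with locus-forward
  coordinates, so everything downstream (deletion normalization,
  microhomology detection) operates on the forward reference only.

Deletions reported by upstream allele-decomposition tools are not guaranteed
to be left-aligned, and the same edited sequence can be produced by several
equal-length placements whenever the deletion boundaries share sequence (a
junction repeat).  :func:`normalize_deletion` maps any placement to the
left-most equivalent one and returns the size of the equivalence range — the
quantity later interpreted as junction microhomology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Union

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Locus",
    "ProgrammedEdit",
    "GuideRecord",
    "IndelDescriptor",
    "GuideNotFoundError",
    "AmbiguousGuidePlacementError",
    "reverse_complement",
    "locate_guide",
    "find_guide_sites",
    "normalize_deletion",
    "apply_indel",
    "apply_programmed_edit",
    "read_loci_fasta",
    "read_guide_table",
    "read_donor_table",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class GuideNotFoundError(ValueError):
    """The protospacer/PAM combination does not occur on either strand."""


class AmbiguousGuidePlacementError(ValueError):
    """The protospacer/PAM combination occurs at more than one site.

    Silent mis-anchoring would corrupt every downstream repair call, so an
    ambiguous placement is an error unless the caller disambiguates
    explicitly (``site_index`` or an explicit ``pam_start``).
    """


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _pam_matches(pattern: str, trinucleotide: str) -> bool:
    if len(pattern) != len(trinucleotide):
        return False
    return all(base in _IUPAC[p] for p, base in zip(pattern, trinucleotide))


@dataclass(frozen=True)
class ProgrammedEdit:
    """A donor-templated edit: substitution of ``[start, end)`` by
    ``replacement`` (insertion when the interval is empty)."""

    kind: Literal["substitution", "insertion"]
    start: int
    end: int
    replacement: str

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.start < 0 or self.end < self.start:
            raise ValueError("invalid edit interval")
        if not self.replacement:
            raise ValueError("replacement sequence must be non-empty")
        if self.kind == "insertion" and self.end != self.start:
            raise ValueError("insertion edits use an empty interval")
        if self.kind == "substitution" and self.end == self.start:
            raise ValueError("substitution edits need a non-empty interval")


@dataclass
class Locus:
    """A reference amplicon with an optional programmed donor edit."""

    name: str
    sequence: str
    donor_edit: Optional[ProgrammedEdit] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"locus {self.name!r}: empty sequence")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(
                f"locus {self.name!r}: non-ACGT characters {sorted(bad)}"
            )
        if self.donor_edit is not None and self.donor_edit.end > len(self.sequence):
            raise ValueError("programmed edit outside locus bounds")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GuideRecord:
    """A located sgRNA target site, in locus-forward coordinates.

    ``pam_start`` is the smallest forward coordinate of the PAM
    trinucleotide; ``cut_site`` the boundary index of the blunt cut.
    """

    locus_name: str
    protospacer: str
    strand: Literal["+", "-"]
    pam_start: int
    cut_site: int

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be 20 nt")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class IndelDescriptor:
    """One allele's edit relative to the reference.

    kind semantics:

    * ``deletion``   — ``[del_start, del_end)`` removed, ``ins_sequence`` empty.
    * ``insertion``  — zero-length interval marks the insertion point
      (``del_start == del_end``), ``ins_sequence`` inserted there.
    * ``delins``     — interval removed and ``ins_sequence`` put in its place.
    * ``substitution`` — like delins but length-preserving (the replacement
      has the same length as the interval); used for donor-programmed edits.
    * ``none``       — unedited allele; empty interval and sequence.
    """

    kind: Literal["deletion", "insertion", "delins", "substitution", "none"]
    del_start: int = 0
    del_end: int = 0
    ins_sequence: str = ""

    def __post_init__(self) -> None:
        kinds = ("deletion", "insertion", "delins", "substitution", "none")
        if self.kind not in kinds:
            raise ValueError(f"unknown indel kind {self.kind!r}")
        if self.del_end < self.del_start or self.del_start < 0:
            raise ValueError("invalid deletion interval")
        if self.kind in ("deletion", "delins", "substitution"):
            if self.del_end == self.del_start:
                raise ValueError(f"{self.kind} requires a non-empty interval")
        if self.kind in ("insertion", "delins", "substitution"):
            if not self.ins_sequence:
                raise ValueError(f"{self.kind} requires an inserted sequence")
        if self.kind == "substitution":
            if len(self.ins_sequence) != self.del_end - self.del_start:
                raise ValueError("substitution must be length-preserving")
        if self.kind == "deletion" and self.ins_sequence:
            raise ValueError("pure deletion carries no inserted sequence")
        if self.kind == "none" and (self.ins_sequence or self.del_end != self.del_start):
            raise ValueError("'none' descriptor must be empty")
        if self.kind == "insertion" and self.del_end != self.del_start:
            raise ValueError("insertion uses a zero-length interval")

    @property
    def del_length(self) -> int:
        return self.del_end - self.del_start


# ---------------------------------------------------------------------------
# guide placement
# ---------------------------------------------------------------------------

def find_guide_sites(
    locus: Locus,
    protospacer: str,
    pam_pattern: str = "NGG",
    cut_offset: int = 3,
) -> list[GuideRecord]:
    """Scan both strands for protospacer immediately 5' of a PAM match.

    Returns every site found, in forward-coordinate order (plus strand
    first).  ``cut_offset`` is the distance in nt from the PAM-proximal
    protospacer end to the blunt cut.
    """
    protospacer = protospacer.upper()
    if len(protospacer) != 20:
        raise ValueError("protospacer must be 20 nt")
    seq = locus.sequence
    plen = len(protospacer)
    pam_len = len(pam_pattern)
    sites: list[GuideRecord] = []
    # plus strand: [i, i+20) protospacer, PAM right of it
    for i in range(0, len(seq) - plen - pam_len + 1):
        if seq[i:i + plen] == protospacer and _pam_matches(
            pam_pattern, seq[i + plen:i + plen + pam_len]
        ):
            sites.append(
                GuideRecord(
                    locus_name=locus.name,
                    protospacer=protospacer,
                    strand="+",
                    pam_start=i + plen,
                    cut_site=i + plen - cut_offset,
                )
            )
    # minus strand: forward [j, j+20) holds revcomp(protospacer), PAM at
    # [j-pam_len, j) in forward coordinates (revcomp of the guide-strand PAM)
    rc = reverse_complement(protospacer)
    for j in range(pam_len, len(seq) - plen + 1):
        if seq[j:j + plen] == rc and _pam_matches(
            pam_pattern, reverse_complement(seq[j - pam_len:j])
        ):
            sites.append(
                GuideRecord(
                    locus_name=locus.name,
                    protospacer=protospacer,
                    strand="-",
                    pam_start=j - pam_len,
                    cut_site=j + cut_offset,
                )
            )
    return [s for s in sites if 0 < s.cut_site < len(seq)]


def locate_guide(
    locus: Locus,
    protospacer: str,
    pam_pattern: str = "NGG",
    cut_offset: int = 3,
    site_index: Optional[int] = None,
    pam_start: Optional[int] = None,
) -> GuideRecord:
    """Locate a guide uniquely on the locus, or fail loudly.

    When the protospacer/PAM combination occurs more than once, the caller
    must disambiguate with ``site_index`` (position in the site list) or an
    explicit ``pam_start``.
    """
    sites = find_guide_sites(locus, protospacer, pam_pattern, cut_offset)
    if not sites:
        raise GuideNotFoundError(
            f"guide not found: {protospacer} (PAM {pam_pattern}) on locus {locus.name!r}"
        )
    if pam_start is not None:
        matching = [s for s in sites if s.pam_start == pam_start]
        if not matching:
            raise GuideNotFoundError(
                f"no site with pam_start={pam_start} on locus {locus.name!r}"
            )
        return matching[0]
    if len(sites) > 1:
        if site_index is None:
            raise AmbiguousGuidePlacementError(
                f"ambiguous guide placement: {len(sites)} sites for {protospacer} "
                f"on locus {locus.name!r}; pass site_index or pam_start"
            )
        return sites[site_index]
    return sites[0]


# ---------------------------------------------------------------------------
# deletion canonicalization
# ---------------------------------------------------------------------------

def normalize_deletion(
    locus: Union[Locus, str], interval: tuple[int, int]
) -> tuple[tuple[int, int], int]:
    """Left-align a deletion and measure its placement ambiguity.

    Returns ``((start, end), ambiguity_span)`` where ``(start, end)`` is the
    left-most equal-length interval producing the identical edited sequence
    and ``ambiguity_span`` is the number of alternative placements minus one
    (equivalently, the length of the junction repeat shared by the two
    boundaries after left-alignment).
    """
    seq = locus.sequence if isinstance(locus, Locus) else locus
    start, end = interval
    if not (0 <= start < end <= len(seq)):
        raise ValueError(f"deletion interval [{start}, {end}) out of bounds")
    # shift left while the base entering on the right equals the one leaving
    while start > 0 and seq[start - 1] == seq[end - 1]:
        start -= 1
        end -= 1
    # count right-shifts available from the canonical placement
    span = 0
    while end + span < len(seq) and seq[end + span] == seq[start + span]:
        span += 1
    return (start, end), span


def apply_indel(sequence: str, indel: IndelDescriptor) -> str:
    """Apply an indel descriptor to a reference sequence."""
    if indel.kind == "none":
        return sequence
    if indel.del_end > len(sequence):
        raise ValueError("indel outside sequence bounds")
    return sequence[: indel.del_start] + indel.ins_sequence + sequence[indel.del_end:]


def apply_programmed_edit(sequence: str, edit: ProgrammedEdit) -> str:
    """Apply a donor-programmed edit to a reference sequence."""
    if edit.end > len(sequence):
        raise ValueError("programmed edit outside sequence bounds")
    return sequence[: edit.start] + edit.replacement + sequence[edit.end:]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_loci_fasta(path: Union[str, Path]) -> dict[str, Locus]:
    """Read reference loci from a (single- or multi-record) FASTA file.

    Record ids become locus names.
    """
    loci: dict[str, Locus] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        loci[record.id] = Locus(name=record.id, sequence=str(record.seq))
    if not loci:
        raise ValueError(f"no FASTA records in {path}")
    return loci


def read_guide_table(
    path: Union[str, Path],
    loci: dict[str, Locus],
    pam_pattern: str = "NGG",
    cut_offset: int = 3,
    one_based: bool = False,
) -> dict[str, GuideRecord]:
    """Read a tab-delimited guide table and locate each guide.

    Columns: ``guide_id``, ``locus``, ``protospacer``, and optionally
    ``pam_start`` (to disambiguate multi-site protospacers).  ``one_based``
    converts an explicit ``pam_start`` from 1-based input coordinates.
    """
    table = pd.read_csv(path, sep="\t", dtype={"guide_id": str, "locus": str})
    required = {"guide_id", "locus", "protospacer"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"guide table missing columns: {sorted(missing)}")
    guides: dict[str, GuideRecord] = {}
    for row in table.itertuples(index=False):
        locus = loci.get(row.locus)
        if locus is None:
            raise KeyError(f"guide {row.guide_id}: unknown locus {row.locus!r}")
        pam_start = None
        if "pam_start" in table.columns and pd.notna(getattr(row, "pam_start", None)):
            pam_start = int(row.pam_start) - (1 if one_based else 0)
        guides[str(row.guide_id)] = locate_guide(
            locus, row.protospacer, pam_pattern, cut_offset, pam_start=pam_start
        )
    return guides


def read_donor_table(
    path: Union[str, Path],
    loci: dict[str, Locus],
    one_based: bool = False,
) -> None:
    """Attach programmed donor edits to loci from a tab-delimited table.

    Columns: ``locus, kind, start, end, replacement`` (kind is
    ``substitution`` or ``insertion``).  Modifies the loci in place.
    """
    table = pd.read_csv(path, sep="\t", dtype={"locus": str, "kind": str})
    required = {"locus", "kind", "start", "end", "replacement"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"donor table missing columns: {sorted(missing)}")
    offset = 1 if one_based else 0
    for row in table.itertuples(index=False):
        locus = loci.get(row.locus)
        if locus is None:
            raise KeyError(f"donor edit references unknown locus {row.locus!r}")
        locus.donor_edit = ProgrammedEdit(
            kind=row.kind,
            start=int(row.start) - offset,
            end=int(row.end) - offset if row.kind == "substitution" else int(row.start) - offset,
            replacement=str(row.replacement),
        )
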