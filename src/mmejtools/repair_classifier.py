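"""Classify edited alleles into NHEJ / MMEJ / HDR / unedited categories.

The classification rule set, applied to each observed allele of an embryo:

1. An allele identical to the reference is **UNEDITED**.
2. An allele whose edited sequence equals the reference with the programmed
   donor edit applied exactly (reference flanks everywhere else) is **HDR**.
3. An indel that cannot be attributed to the cut — no boundary of the event
   within the repair window around the cut site — is **UNATTRIBUTABLE**:
   reported, excluded from category totals.  A substitution overlapping the
   programmed-edit interval but differing from it (imperfect HDR) is also
   unattributable rather than force-fitted into a category.
4. Any allele carrying inserted sequence (insertion or deletion+insertion),
   a single-base deletion, or a deletion without junction microhomology of
   at least ``mh_min`` nt is **NHEJ**.  Non-programmed substitutions are
   counted as NHEJ (mutagenic, templateless end joining).
5. A pure deletion of >= 2 nt whose junction microhomology lies in
   ``[mh_min, mh_max]`` is **MMEJ**.

Junction microhomology is operationalized as the placement ambiguity of the
deletion: the repeated sequence present at both deletion boundaries, i.e. the
number of alternative equal-length placements producing the same edited
sequence.  This makes classification invariant to how upstream tools chose to
place the deletion.  Repeats longer than ``mh_max`` are reported capped, with
an ``mh_capped`` flag (such events may be single-strand-annealing-like and
deserve inspection rather than a silent label).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import NamedTuple, Optional, Sequence, Union

import pandas as pd

from .cohort_stats import EmbryoProfile
from .sequence_core import (
    GuideRecord,
    IndelDescriptor,
    Locus,
    apply_indel,
    apply_programmed_edit,
    normalize_deletion,
)

__all__ = [
    "RepairCategory",
    "ClassifierParams",
    "AlleleObservation",
    "RepairCall",
    "MicrohomologyEvidence",
    "NonCanonicalIntervalError",
    "MalformedAlleleTableError",
    "detect_microhomology",
    "classify_repair",
    "classify_embryo",
    "classify_cohort",
    "read_allele_table",
    "calls_to_frame",
]


class RepairCategory(str, Enum):
    NHEJ = "NHEJ"
    MMEJ = "MMEJ"
    HDR = "HDR"
    UNEDITED = "UNEDITED"
    UNATTRIBUTABLE = "UNATTRIBUTABLE"


class NonCanonicalIntervalError(ValueError):
    """Microhomology detection requires a left-aligned deletion interval."""


class MalformedAlleleTableError(ValueError):
    """Per-embryo allele frequencies exceed 100% beyond tolerance."""


@dataclass(frozen=True)
class ClassifierParams:
    """Classification thresholds.

    mh_min/mh_max
        Junction-microhomology range (nt) counted as MMEJ evidence;
        deletions with shorter junctions are NHEJ, longer ones are capped
        and flagged.
    repair_window
        Distance (nt) from the cut site within which an indel must begin or
        end to be attributed to the cut.  The default of 50 nt suits
        amplicon-scale allele tables from trace decomposition.
    delins_is_nhej
        Whether deletion+insertion alleles follow the "insertion occurred"
        rule (NHEJ).  Configurable for sensitivity analyses.
    frequency_tolerance
        Slack (percentage points) allowed on per-embryo frequency sums.
    """

    mh_min: int = 2
    mh_max: int = 25
    repair_window: int = 50
    delins_is_nhej: bool = True
    frequency_tolerance: float = 0.5

    def __post_init__(self) -> None:
        if not 1 <= self.mh_min <= self.mh_max:
            raise ValueError("need 1 <= mh_min <= mh_max")
        if self.repair_window < 0:
            raise ValueError("repair_window must be nonnegative")


@dataclass(frozen=True)
class AlleleObservation:
    """One allele of one embryo, with its percent frequency."""

    embryo_id: str
    guide: GuideRecord
    indel: IndelDescriptor
    frequency: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.frequency <= 100 + 1e-9:
            raise ValueError(f"frequency {self.frequency} outside [0, 100]")


class MicrohomologyEvidence(NamedTuple):
    """Junction microhomology of a canonical deletion.

    ``length`` is the ambiguity span capped at ``mh_max``; ``sequence`` the
    repeated junction bases (reference bases at the left boundary);
    ``capped`` flags repeats longer than ``mh_max``.
    """

    length: int
    sequence: str
    capped: bool


@dataclass(frozen=True)
class RepairCall:
    """Classification of one allele with its microhomology evidence."""

    category: RepairCategory
    mh_length: int
    mh_sequence: str
    canonical_indel: IndelDescriptor
    mh_capped: bool = False
    note: str = ""


# ---------------------------------------------------------------------------
# microhomology detection
# ---------------------------------------------------------------------------

def detect_microhomology(
    locus: Locus,
    interval: tuple[int, int],
    params: ClassifierParams = ClassifierParams(),
) -> MicrohomologyEvidence:
    """Measure the junction microhomology of a *canonical* deletion.

    The junction microhomology equals the deletion's placement ambiguity;
    its sequence is read from the reference at the left boundary.  Lengths
    below ``mh_min`` are reported as-is — the caller applies the MMEJ
    threshold.  Lengths above ``mh_max`` are capped and flagged.
    """
    canonical, span = normalize_deletion(locus, interval)
    if canonical != tuple(interval):
        raise NonCanonicalIntervalError(
            f"interval {tuple(interval)} is not left-aligned "
            f"(canonical {canonical}); must normalize first"
        )
    length = min(span, params.mh_max)
    start = canonical[0]
    return MicrohomologyEvidence(
        length=length,
        sequence=locus.sequence[start:start + length],
        capped=span > params.mh_max,
    )


def _within_window(position: int, cut: int, window: int) -> bool:
    return cut - window <= position <= cut + window


def _deletion_attributable(
    canonical: tuple[int, int], span: int, cut: int, window: int
) -> bool:
    """Placement-invariant window test for deletions.

    The deletion's equivalent placements start anywhere in
    ``[start, start + span]``; the event is attributable when any placement
    begins or ends within the repair window.
    """
    start, end = canonical
    lo, hi = cut - window, cut + window
    starts_in = start <= hi and start + span >= lo
    ends_in = end <= hi and end + span >= lo
    return starts_in or ends_in


# ---------------------------------------------------------------------------
# per-allele classification
# ---------------------------------------------------------------------------

def classify_repair(
    obs: AlleleObservation,
    locus: Locus,
    params: ClassifierParams = ClassifierParams(),
) -> RepairCall:
    """Classify one observed allele; see module docstring for the rules."""
    indel = obs.indel
    cut = obs.guide.cut_site
    if not 0 < cut < len(locus):
        raise ValueError("observation references a guide outside the locus")
    no_evidence = dict(mh_length=0, mh_sequence="")

    if indel.kind == "none":
        return RepairCall(
            category=RepairCategory.UNEDITED, canonical_indel=indel, **no_evidence
        )

    # exact-match HDR: edited sequence reproduces the programmed edit with
    # reference flanks everywhere else
    if locus.donor_edit is not None:
        if apply_indel(locus.sequence, indel) == apply_programmed_edit(
            locus.sequence, locus.donor_edit
        ):
            return RepairCall(
                category=RepairCategory.HDR, canonical_indel=indel, **no_evidence
            )

    if indel.kind == "substitution":
        donor = locus.donor_edit
        if donor is not None and indel.del_start < donor.end and donor.start < indel.del_end:
            return RepairCall(
                category=RepairCategory.UNATTRIBUTABLE,
                canonical_indel=indel,
                note="imperfect HDR: substitution overlaps programmed edit",
                **no_evidence,
            )
        if not (
            _within_window(indel.del_start, cut, params.repair_window)
            or _within_window(indel.del_end, cut, params.repair_window)
        ):
            return RepairCall(
                category=RepairCategory.UNATTRIBUTABLE,
                canonical_indel=indel,
                note="substitution outside repair window",
                **no_evidence,
            )
        return RepairCall(
            category=RepairCategory.NHEJ,
            canonical_indel=indel,
            note="non-programmed substitution",
            **no_evidence,
        )

    if indel.kind == "insertion":
        if not _within_window(indel.del_start, cut, params.repair_window):
            return RepairCall(
                category=RepairCategory.UNATTRIBUTABLE,
                canonical_indel=indel,
                note="insertion outside repair window",
                **no_evidence,
            )
        return RepairCall(
            category=RepairCategory.NHEJ, canonical_indel=indel, **no_evidence
        )

    # deletion or delins: normalize the deleted interval first so the call is
    # invariant to the reported placement
    canonical, span = normalize_deletion(locus, (indel.del_start, indel.del_end))
    canonical_indel = IndelDescriptor(
        kind=indel.kind,
        del_start=canonical[0],
        del_end=canonical[1],
        ins_sequence=indel.ins_sequence,
    )
    if not _deletion_attributable(canonical, span, cut, params.repair_window):
        return RepairCall(
            category=RepairCategory.UNATTRIBUTABLE,
            canonical_indel=canonical_indel,
            note="deletion outside repair window",
            **no_evidence,
        )

    if indel.kind == "delins":
        category = RepairCategory.NHEJ if params.delins_is_nhej else RepairCategory.MMEJ
        return RepairCall(
            category=category,
            canonical_indel=canonical_indel,
            note="deletion with insertion",
            **no_evidence,
        )

    evidence = detect_microhomology(locus, canonical, params)
    if canonical_indel.del_length == 1:
        return RepairCall(
            category=RepairCategory.NHEJ,
            mh_length=evidence.length,
            mh_sequence=evidence.sequence,
            canonical_indel=canonical_indel,
            mh_capped=evidence.capped,
            note="single-base deletion",
        )
    if evidence.length >= params.mh_min:
        return RepairCall(
            category=RepairCategory.MMEJ,
            mh_length=evidence.length,
            mh_sequence=evidence.sequence,
            canonical_indel=canonical_indel,
            mh_capped=evidence.capped,
            note="junction repeat exceeds mh_max" if evidence.capped else "",
        )
    return RepairCall(
        category=RepairCategory.NHEJ,
        mh_length=evidence.length,
        mh_sequence=evidence.sequence,
        canonical_indel=canonical_indel,
    )


# ---------------------------------------------------------------------------
# per-embryo aggregation
# ---------------------------------------------------------------------------

def classify_embryo(
    observations: Sequence[AlleleObservation],
    locus: Locus,
    params: ClassifierParams = ClassifierParams(),
    guide_id: Optional[str] = None,
) -> EmbryoProfile:
    """Classify all alleles of one embryo and sum per-category frequencies.

    ``guide_id`` labels the resulting profile; it defaults to the guide's
    locus name (adequate when each locus carries one guide).
    """
    if not observations:
        raise ValueError("classify_embryo needs at least one allele observation")
    embryo_ids = {o.embryo_id for o in observations}
    guides = {o.guide for o in observations}
    if len(embryo_ids) != 1 or len(guides) != 1:
        raise ValueError("observations must share one embryo id and one guide")
    total = sum(o.frequency for o in observations)
    if total > 100 + params.frequency_tolerance:
        raise MalformedAlleleTableError(
            f"embryo {next(iter(embryo_ids))!r}: frequencies sum to {total:.2f} > 100"
        )
    sums = {c: 0.0 for c in RepairCategory}
    for obs in observations:
        call = classify_repair(obs, locus, params)
        sums[call.category] += obs.frequency
    return EmbryoProfile(
        embryo_id=embryo_ids.pop(),
        guide_id=guide_id if guide_id is not None else observations[0].guide.locus_name,
        f_nhej=sums[RepairCategory.NHEJ],
        f_mmej=sums[RepairCategory.MMEJ],
        f_hdr=sums[RepairCategory.HDR],
        f_unedited=sums[RepairCategory.UNEDITED],
        f_unattributable=sums[RepairCategory.UNATTRIBUTABLE],
    )


def classify_cohort(
    alleles: pd.DataFrame,
    loci: dict[str, Locus],
    guides: dict[str, GuideRecord],
    params: ClassifierParams = ClassifierParams(),
) -> tuple[pd.DataFrame, list[EmbryoProfile]]:
    """Classify an allele table and aggregate per-embryo profiles.

    ``alleles`` must have columns ``embryo_id, guide_id, kind, del_start,
    del_end, ins_seq, frequency_percent`` (the layout of
    :func:`read_allele_table` and of the synthetic cohort generator).
    Returns the per-allele call table and the per-embryo profiles.
    """
    call_rows = []
    profiles: list[EmbryoProfile] = []
    for (guide_id, embryo_id), group in alleles.groupby(
        ["guide_id", "embryo_id"], sort=True
    ):
        guide = guides[str(guide_id)]
        locus = loci[guide.locus_name]
        observations = [
            AlleleObservation(
                embryo_id=str(embryo_id),
                guide=guide,
                indel=_row_to_indel(row),
                frequency=float(row.frequency_percent),
            )
            for row in group.itertuples(index=False)
        ]
        for obs, row in zip(observations, group.itertuples(index=False)):
            call = classify_repair(obs, locus, params)
            call_rows.append(
                {
                    "embryo_id": obs.embryo_id,
                    "guide_id": str(guide_id),
                    "allele_id": getattr(row, "allele_id", ""),
                    "category": call.category.value,
                    "mh_length": call.mh_length,
                    "mh_sequence": call.mh_sequence,
                    "mh_capped": call.mh_capped,
                    "canonical_del_start": call.canonical_indel.del_start,
                    "canonical_del_end": call.canonical_indel.del_end,
                    "frequency_percent": obs.frequency,
                    "note": call.note,
                }
            )
        profiles.append(
            classify_embryo(observations, locus, params, guide_id=str(guide_id))
        )
    return pd.DataFrame(call_rows), profiles


def _row_to_indel(row) -> IndelDescriptor:
    kind = str(row.kind)
    ins = "" if pd.isna(row.ins_seq) else str(row.ins_seq)
    if kind == "none":
        return IndelDescriptor(kind="none")
    return IndelDescriptor(
        kind=kind,
        del_start=int(row.del_start),
        del_end=int(row.del_end),
        ins_sequence=ins,
    )


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

ALLELE_COLUMNS = [
    "embryo_id",
    "guide_id",
    "kind",
    "del_start",
    "del_end",
    "ins_seq",
    "frequency_percent",
]


def read_allele_table(
    path: Union[str, Path], one_based: bool = False
) -> pd.DataFrame:
    """Read a delimited per-allele table.

    Expected columns: ``embryo_id, guide_id, kind, del_start, del_end,
    ins_seq, frequency_percent``.  ``one_based=True`` converts inclusive
    1-based deletion coordinates to the package's 0-based half-open
    convention.  Reported placements are re-normalized downstream, so the
    table's deletion coordinates need not be left-aligned.
    """
    table = pd.read_csv(
        path, sep="\t", dtype={"embryo_id": str, "guide_id": str, "kind": str}
    )
    missing = set(ALLELE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"allele table missing columns: {sorted(missing)}")
    table = table.copy()
    table["del_start"] = table["del_start"].fillna(0).astype(int)
    table["del_end"] = table["del_end"].fillna(0).astype(int)
    if one_based:
        # inclusive 1-based [start, end] -> half-open 0-based [start-1, end)
        has_interval = table["kind"].isin(["deletion", "delins", "substitution"])
        table.loc[has_interval, "del_start"] -= 1
        insertion = table["kind"] == "insertion"
        # 1-based insertion point "after base i" -> boundary i
        table.loc[insertion, "del_end"] = table.loc[insertion, "del_start"]
    return table


def calls_to_frame(calls: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a per-allele call table as tab-delimited text."""
    calls.to_csv(path, sep="\t", index=False)
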