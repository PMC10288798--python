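"""Off-target bookkeeping rules as pure operations on record tables.

Three auxiliary procedures used around genome-wide off-target assessment of
embryo editing, kept deliberately free of any aligner or variant-caller
wrapping (those run upstream):

* **Caller consensus** — a variant is accepted only when all three variant
  callers report the same (chromosome, position, ref, alt) key.
* **Integration breakpoints** — genome-side positions of reference/donor
  chimeric reads are clustered within a window; a cluster is a true signal
  when its supporting read count reaches the threshold (both 10 and 20 are
  evaluated by default, inclusive).
* **Cut-site coverage loss** — the proportional depth drop of an inner
  window around the cut relative to the amplicon's outer flanks,
  ``max(0, 1 - inner_mean / flank_mean)``; invariant to uniform depth
  scaling.  This operationalizes "proportion of lost coverage"; read-level
  definitions on long-read data may differ.

Variant matching is exact-key: indel alleles are assumed left-normalized by
the upstream callers and are not re-normalized across callers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "VariantRecord",
    "Breakpoint",
    "DepthProfile",
    "ConsensusUndefinedError",
    "UncoveredAmpliconError",
    "consensus_variants",
    "call_integration_breakpoints",
    "coverage_loss",
    "read_caller_vcf",
    "read_chimeric_table",
    "read_depth_table",
]


class ConsensusUndefinedError(ValueError):
    """Consensus requires exactly three distinct callers."""


class UncoveredAmpliconError(ValueError):
    """Flank regions have zero depth; coverage loss is undefined."""


@dataclass(frozen=True)
class VariantRecord:
    """One called variant (1-based position, as in VCF)."""

    chromosome: str
    position: int
    ref: str
    alt: str
    caller: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref, self.alt)


@dataclass(frozen=True)
class Breakpoint:
    """A clustered candidate integration site with its read support."""

    chromosome: str
    position: int
    support: int
    passes: dict[int, bool]

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclass
class DepthProfile:
    """Per-position depth over one amplicon, with the cut position.

    ``depth[i]`` is the depth at 0-based amplicon position ``i``.
    """

    amplicon_id: str
    depth: np.ndarray
    cut_position: int

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1 or len(self.depth) == 0:
            raise ValueError("depth must be a non-empty 1-D array")
        if np.any(self.depth < 0):
            raise ValueError("depth values must be nonnegative")
        if not 0 <= self.cut_position < len(self.depth):
            raise ValueError("cut position outside the amplicon")


# ---------------------------------------------------------------------------
# caller consensus
# ---------------------------------------------------------------------------

def consensus_variants(
    records: Union[pd.DataFrame, Iterable[VariantRecord]],
) -> pd.DataFrame:
    """Variants reported identically by all three callers.

    Accepts a DataFrame with columns ``chromosome, position, ref, alt,
    caller`` or an iterable of :class:`VariantRecord`.  Order- and
    duplicate-invariant; returns the consensus keys sorted.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(
            [
                {
                    "chromosome": r.chromosome,
                    "position": r.position,
                    "ref": r.ref,
                    "alt": r.alt,
                    "caller": r.caller,
                }
                for r in records
            ],
            columns=["chromosome", "position", "ref", "alt", "caller"],
        )
    callers = sorted(records["caller"].unique()) if len(records) else []
    if len(callers) != 3:
        raise ConsensusUndefinedError(
            f"consensus undefined: need exactly 3 callers, got {len(callers)}"
        )
    key_cols = ["chromosome", "position", "ref", "alt"]
    key_sets = [
        set(map(tuple, records.loc[records["caller"] == c, key_cols].itertuples(index=False)))
        for c in callers
    ]
    consensus = key_sets[0] & key_sets[1] & key_sets[2]
    return (
        pd.DataFrame(sorted(consensus), columns=key_cols)
        if consensus
        else pd.DataFrame(columns=key_cols)
    )


# ---------------------------------------------------------------------------
# integration breakpoints
# ---------------------------------------------------------------------------

def call_integration_breakpoints(
    reads: pd.DataFrame,
    min_supports: Sequence[int] = (10, 20),
    window: int = 100,
) -> list[Breakpoint]:
    """Cluster chimeric-read genome positions into candidate breakpoints.

    ``reads`` needs columns ``chromosome`` and ``position`` (the
    genome-side coordinates of reference/donor chimeric reads).  Positions
    on one chromosome are clustered greedily: a read starts a new cluster
    when it lies more than ``window`` nt from the cluster's first position.
    Every read lands in exactly one cluster, so supports sum to the number
    of input reads.  ``passes[t]`` applies ``support >= t`` (inclusive).
    """
    if any(t < 1 for t in min_supports):
        raise ValueError("min_support thresholds must be >= 1")
    breakpoints: list[Breakpoint] = []
    if len(reads) == 0:
        return breakpoints
    for chromosome, group in reads.groupby("chromosome", sort=True):
        positions = np.sort(group["position"].to_numpy())
        anchor = positions[0]
        cluster: list[int] = []
        for pos in positions:
            if pos - anchor > window:
                breakpoints.append(_make_breakpoint(chromosome, cluster, min_supports))
                anchor = pos
                cluster = []
            cluster.append(int(pos))
        breakpoints.append(_make_breakpoint(chromosome, cluster, min_supports))
    return breakpoints


def _make_breakpoint(
    chromosome: str, cluster: list[int], min_supports: Sequence[int]
) -> Breakpoint:
    support = len(cluster)
    return Breakpoint(
        chromosome=str(chromosome),
        position=int(np.median(cluster)),
        support=support,
        passes={int(t): support >= t for t in min_supports},
    )


# ---------------------------------------------------------------------------
# coverage loss around the cut
# ---------------------------------------------------------------------------

def coverage_loss(
    profile: DepthProfile,
    inner_window: int = 50,
    flank_window: int | None = None,
) -> float:
    """Proportional depth drop around the cut site, in [0, 1].

    The inner window spans ``cut +/- inner_window``; the flanks are the
    outer ``flank_window`` positions at each end of the amplicon (default:
    a tenth of the amplicon per side, i.e. the outer 20% in total).  The
    windows must not overlap and the flanks must carry depth.
    """
    n = len(profile.depth)
    if flank_window is None:
        flank_window = max(1, n // 10)
    inner_lo = max(0, profile.cut_position - inner_window)
    inner_hi = min(n, profile.cut_position + inner_window + 1)
    if inner_lo < flank_window or inner_hi > n - flank_window:
        raise ValueError("flank windows overlap the inner window")
    flank = np.concatenate([profile.depth[:flank_window], profile.depth[n - flank_window:]])
    flank_mean = float(flank.mean())
    if flank_mean <= 0:
        raise UncoveredAmpliconError(
            f"amplicon {profile.amplicon_id!r}: zero flank depth"
        )
    inner_mean = float(profile.depth[inner_lo:inner_hi].mean())
    return float(min(1.0, max(0.0, 1.0 - inner_mean / flank_mean)))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_caller_vcf(path: Union[str, Path], caller: str) -> pd.DataFrame:
    """Read CHROM/POS/REF/ALT from one caller's VCF (multi-allelic expanded)."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for record in vcf:
            for alt in record.alts or ():
                rows.append(
                    {
                        "chromosome": record.chrom,
                        "position": record.pos,
                        "ref": record.ref,
                        "alt": alt,
                        "caller": caller,
                    }
                )
    return pd.DataFrame(rows, columns=["chromosome", "position", "ref", "alt", "caller"])


def read_chimeric_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a delimited chimeric-read table.

    Required columns: ``read_id, chromosome, position, orientation,
    donor_element, donor_position``; the donor element must be one of
    ``left_arm, right_arm, insert``.
    """
    table = pd.read_csv(path, sep="\t")
    required = {
        "read_id", "chromosome", "position", "orientation",
        "donor_element", "donor_position",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"chimeric-read table missing columns: {sorted(missing)}")
    bad = set(table["donor_element"].unique()) - {"left_arm", "right_arm", "insert"}
    if bad:
        raise ValueError(f"unknown donor elements: {sorted(bad)}")
    return table


def read_depth_table(path: Union[str, Path]) -> dict[str, DepthProfile]:
    """Read per-position depth in the three-column ``samtools depth`` layout.

    Columns (no header): reference id, 1-based position, depth.  The cut
    position is not part of the format; callers set it afterwards (it
    defaults to the amplicon midpoint).
    """
    table = pd.read_csv(
        path, sep="\t", header=None, names=["amplicon", "position", "depth"]
    )
    profiles: dict[str, DepthProfile] = {}
    for amplicon, group in table.groupby("amplicon", sort=True):
        group = group.sort_values("position")
        length = int(group["position"].max())
        depth = np.zeros(length, dtype=float)
        depth[group["position"].to_numpy() - 1] = group["depth"].to_numpy()
        profiles[str(amplicon)] = DepthProfile(
            amplicon_id=str(amplicon), depth=depth, cut_position=length // 2
        )
    return profiles
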