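"""Per-guide aggregation of embryo repair profiles and knock-in statistics.

An :class:`EmbryoProfile` carries the per-category percent frequencies of one
embryo's allele mixture.  Profiles for embryos edited with the same sgRNA are
averaged into a :class:`GuideSummary`; the per-guide repair-pathway balance is
the ratio

    R = mean f_NHEJ / mean f_MMEJ

computed on per-guide *mean* frequencies (not the mean of per-embryo ratios),
which keeps the statistic defined when individual embryos have f_MMEJ = 0 and
makes it invariant to proportional mosaicism.  Guides with R below the lower
bias threshold are called MMEJ-biased, above the upper threshold NHEJ-biased,
and balanced in between (boundaries inclusive in the balanced class).

Knock-in experiments are recorded as :class:`TrialRecord` replicates
(positives out of total, per locus and arm) and compared across arms by
per-locus baseline-mean normalized fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "EmbryoProfile",
    "GuideSummary",
    "StatsParams",
    "TrialRecord",
    "BiasCensus",
    "EfficiencyStrata",
    "FoldChangeResult",
    "summarize_guide",
    "bias_census",
    "stratify_by_efficiency",
    "positive_rate",
    "hdr_fold_change",
    "profiles_to_frame",
    "summaries_to_frame",
]

BIAS_CLASSES = ("MMEJ-biased", "balanced", "NHEJ-biased", "undefined")


@dataclass(frozen=True)
class EmbryoProfile:
    """Per-category percent frequencies for one embryo's allele mixture.

    ``efficiency`` is the edited fraction of the *attributable* allele mass:
    100 x (f_NHEJ + f_MMEJ + f_HDR) / (f_NHEJ + f_MMEJ + f_HDR + f_UNEDITED).
    """

    embryo_id: str
    guide_id: str
    f_nhej: float
    f_mmej: float
    f_hdr: float
    f_unedited: float
    f_unattributable: float = 0.0

    def __post_init__(self) -> None:
        for name in ("f_nhej", "f_mmej", "f_hdr", "f_unedited", "f_unattributable"):
            value = getattr(self, name)
            if not -1e-9 <= value <= 100 + 1e-9:
                raise ValueError(f"{name}={value} outside [0, 100]")

    @property
    def efficiency(self) -> float:
        attributable = self.f_nhej + self.f_mmej + self.f_hdr + self.f_unedited
        if attributable <= 0:
            return 0.0
        return 100.0 * (self.f_nhej + self.f_mmej + self.f_hdr) / attributable


@dataclass(frozen=True)
class GuideSummary:
    """Across-embryo means for one sgRNA plus the NHEJ/MMEJ balance call.

    ``ratio`` is ``None`` when both mean frequencies are zero (class
    ``undefined``) and ``math.inf`` when only f_MMEJ is zero.
    """

    guide_id: str
    n_embryos: int
    mean_f_nhej: float
    mean_f_mmej: float
    mean_f_hdr: float
    mean_efficiency: float
    ratio: Optional[float]
    bias_class: str

    def __post_init__(self) -> None:
        if self.bias_class not in BIAS_CLASSES:
            raise ValueError(f"unknown bias class {self.bias_class!r}")
        if self.ratio is not None and not self.ratio >= 0:
            raise ValueError("ratio must be nonnegative")


@dataclass(frozen=True)
class StatsParams:
    """Thresholds for bias classification and efficiency stratification.

    Defaults: guides with R < 0.5 are MMEJ-biased, R > 2 NHEJ-biased, and
    the efficiency strata split strictly below / at-or-above 66.7%.
    """

    bias_low: float = 0.5
    bias_high: float = 2.0
    efficiency_threshold: float = 66.7

    def __post_init__(self) -> None:
        if not 0 < self.bias_low < self.bias_high:
            raise ValueError("need 0 < bias_low < bias_high")

    def classify_ratio(self, ratio: Optional[float]) -> str:
        if ratio is None:
            return "undefined"
        if ratio < self.bias_low:
            return "MMEJ-biased"
        if ratio <= self.bias_high:
            return "balanced"
        return "NHEJ-biased"


@dataclass(frozen=True)
class TrialRecord:
    """One knock-in replicate: positive embryos/offspring out of total.

    ``arm`` is ``"baseline"`` (conventional donor co-injection) or
    ``"cati"`` (the MMEJ-suppression co-injection arm).
    """

    locus_id: str
    arm: str
    replicate_id: str
    positives: int
    total: int

    def __post_init__(self) -> None:
        if self.arm not in ("baseline", "cati"):
            raise ValueError("arm must be 'baseline' or 'cati'")
        if self.total <= 0:
            raise ValueError("total must be positive")
        if not 0 <= self.positives <= self.total:
            raise ValueError("positives must lie in [0, total]")

    @property
    def efficiency(self) -> float:
        return 100.0 * self.positives / self.total


# ---------------------------------------------------------------------------
# per-guide summaries
# ---------------------------------------------------------------------------

def summarize_guide(
    profiles: Sequence[EmbryoProfile], params: StatsParams = StatsParams()
) -> GuideSummary:
    """Average embryo profiles for one guide and classify its repair bias."""
    if not profiles:
        raise ValueError("summarize_guide needs at least one embryo profile")
    guide_ids = {p.guide_id for p in profiles}
    if len(guide_ids) != 1:
        raise ValueError(f"profiles span multiple guides: {sorted(guide_ids)}")
    n = len(profiles)
    mean_nhej = sum(p.f_nhej for p in profiles) / n
    mean_mmej = sum(p.f_mmej for p in profiles) / n
    mean_hdr = sum(p.f_hdr for p in profiles) / n
    mean_eff = sum(p.efficiency for p in profiles) / n
    if mean_mmej > 0:
        ratio: Optional[float] = mean_nhej / mean_mmej
    elif mean_nhej > 0:
        ratio = math.inf
    else:
        ratio = None
    return GuideSummary(
        guide_id=guide_ids.pop(),
        n_embryos=n,
        mean_f_nhej=mean_nhej,
        mean_f_mmej=mean_mmej,
        mean_f_hdr=mean_hdr,
        mean_efficiency=mean_eff,
        ratio=ratio,
        bias_class=params.classify_ratio(ratio),
    )


@dataclass(frozen=True)
class BiasCensus:
    """Counts of guides per bias class, with percentage helpers."""

    counts: dict[str, int]

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    def proportion(
        self, bias_class: str, of: Optional[Sequence[str]] = None
    ) -> float:
        """Percent of guides in ``bias_class``, 2-decimal rounded.

        ``of`` restricts the denominator to the listed classes (e.g. the
        balanced share among non-MMEJ-biased guides).
        """
        if of is None:
            denominator = self.n_total
        else:
            denominator = sum(self.counts.get(c, 0) for c in of)
        if denominator == 0:
            raise ValueError("empty denominator for bias proportion")
        return round(100.0 * self.counts.get(bias_class, 0) / denominator, 2)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "bias_class": c,
                "count": self.counts.get(c, 0),
                "percent_of_total": self.proportion(c),
            }
            for c in BIAS_CLASSES
        ]
        return pd.DataFrame(rows)


def bias_census(
    summaries: Sequence[GuideSummary], params: StatsParams = StatsParams()
) -> BiasCensus:
    """Count guides per bias class across the cohort."""
    if not summaries:
        raise ValueError("bias_census needs at least one guide summary")
    counts = {c: 0 for c in BIAS_CLASSES}
    for s in summaries:
        counts[s.bias_class] += 1
    return BiasCensus(counts=counts)


@dataclass(frozen=True)
class EfficiencyStrata:
    """MMEJ-biased share within low/high editing-efficiency strata."""

    threshold: float
    n_low: int
    n_high: int
    mmej_biased_low: int
    mmej_biased_high: int

    @property
    def pct_low(self) -> float:
        if self.n_low == 0:
            raise ValueError("empty low-efficiency stratum")
        return round(100.0 * self.mmej_biased_low / self.n_low, 2)

    @property
    def pct_high(self) -> float:
        if self.n_high == 0:
            raise ValueError("empty high-efficiency stratum")
        return round(100.0 * self.mmej_biased_high / self.n_high, 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stratum": f"E < {self.threshold}",
                    "n_guides": self.n_low,
                    "n_mmej_biased": self.mmej_biased_low,
                    "percent_mmej_biased": self.pct_low if self.n_low else float("nan"),
                },
                {
                    "stratum": f"E >= {self.threshold}",
                    "n_guides": self.n_high,
                    "n_mmej_biased": self.mmej_biased_high,
                    "percent_mmej_biased": self.pct_high if self.n_high else float("nan"),
                },
            ]
        )


def stratify_by_efficiency(
    summaries: Sequence[GuideSummary], params: StatsParams = StatsParams()
) -> EfficiencyStrata:
    """Split guides at the efficiency threshold (strictly below vs at-or-above)
    and report the MMEJ-biased share within each stratum."""
    if not summaries:
        raise ValueError("stratify_by_efficiency needs at least one summary")
    threshold = params.efficiency_threshold
    low = [s for s in summaries if s.mean_efficiency < threshold]
    high = [s for s in summaries if s.mean_efficiency >= threshold]
    return EfficiencyStrata(
        threshold=threshold,
        n_low=len(low),
        n_high=len(high),
        mmej_biased_low=sum(1 for s in low if s.bias_class == "MMEJ-biased"),
        mmej_biased_high=sum(1 for s in high if s.bias_class == "MMEJ-biased"),
    )


# ---------------------------------------------------------------------------
# knock-in statistics
# ---------------------------------------------------------------------------

def positive_rate(trial: TrialRecord) -> float:
    """Percent positive in one trial, 2-decimal rounded."""
    return round(trial.efficiency, 2)


@dataclass(frozen=True)
class FoldChangeResult:
    """Per-replicate fold changes and their unweighted mean."""

    per_replicate: pd.DataFrame  # locus_id, replicate_id, efficiency, baseline_mean, fold
    overall_fold: float
    excluded_loci: tuple[str, ...]

    @property
    def n_pairs(self) -> int:
        return len(self.per_replicate)


def hdr_fold_change(trials: Iterable[TrialRecord]) -> FoldChangeResult:
    """Fold improvement of the treated arm over the per-locus baseline mean.

    Each treated replicate is divided by the mean baseline efficiency at the
    same locus; the overall fold is the unweighted mean over replicate
    pairs.  Loci whose baseline mean is zero (or that lack one of the arms)
    cannot be normalized and are excluded and reported.
    """
    trials = list(trials)
    baseline: dict[str, list[float]] = {}
    treated: dict[str, list[TrialRecord]] = {}
    for t in trials:
        if t.arm == "baseline":
            baseline.setdefault(t.locus_id, []).append(t.efficiency)
        else:
            treated.setdefault(t.locus_id, []).append(t)
    rows = []
    excluded = []
    for locus_id in sorted(set(baseline) | set(treated)):
        base = baseline.get(locus_id)
        reps = treated.get(locus_id)
        if not base or not reps or sum(base) == 0:
            excluded.append(locus_id)
            continue
        base_mean = sum(base) / len(base)
        for t in sorted(reps, key=lambda t: t.replicate_id):
            rows.append(
                {
                    "locus_id": locus_id,
                    "replicate_id": t.replicate_id,
                    "efficiency": t.efficiency,
                    "baseline_mean": base_mean,
                    "fold": t.efficiency / base_mean,
                }
            )
    if not rows:
        raise ValueError("no valid baseline/treated pairs")
    frame = pd.DataFrame(rows)
    return FoldChangeResult(
        per_replicate=frame,
        overall_fold=float(frame["fold"].mean()),
        excluded_loci=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# table conversion
# ---------------------------------------------------------------------------

def profiles_to_frame(profiles: Iterable[EmbryoProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "embryo_id": p.embryo_id,
                "guide_id": p.guide_id,
                "f_nhej": p.f_nhej,
                "f_mmej": p.f_mmej,
                "f_hdr": p.f_hdr,
                "f_unedited": p.f_unedited,
                "f_unattributable": p.f_unattributable,
                "efficiency": p.efficiency,
            }
            for p in profiles
        ]
    )


def summaries_to_frame(summaries: Iterable[GuideSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "guide_id": s.guide_id,
                "n_embryos": s.n_embryos,
                "mean_f_nhej": s.mean_f_nhej,
                "mean_f_mmej": s.mean_f_mmej,
                "mean_f_hdr": s.mean_f_hdr,
                "mean_efficiency": s.mean_efficiency,
                # 3-decimal reporting convention for ratios
                "nhej_mmej_ratio": (
                    float("nan") if s.ratio is None else round(s.ratio, 3)
                ),
                "bias_class": s.bias_class,
            }
            for s in summaries
        ]
    )
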