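"""Seeded generator of embryo-editing cohorts with ground-truth repair labels.

The generator emulates the measurement layer that a Sanger-trace
decomposition tool produces: per embryo, a small mosaic mixture of alleles
(unedited / NHEJ insertion / NHEJ deletion / MMEJ deletion / HDR) with
percent frequencies summing to 100.  Each locus is built so that every
microhomology length the configuration can draw has a planted repeat pair
downstream of the cut site:

    ... protospacer PAM | sep R_m gap R_m | sep R_m' gap R_m' | ...

Deleting ``R_m + gap`` (one repeat copy plus the intervening bases) leaves a
junction whose microhomology is exactly ``m`` nt — verified at generation
time with the package's own normalization/ambiguity machinery and re-drawn
on accidental repeat extensions, so truth labels are guaranteed to agree
with the classifier's operational rules rather than assumed to.

NHEJ deletions are rejection-sampled around the cut until their junction
ambiguity falls below the MMEJ threshold (or they are single-base); NHEJ
insertions insert random sequence at the cut; HDR alleles apply the
programmed edit (an EcoRI-site substitution across the cut by default)
exactly.  Truth labels therefore partition cleanly, which is what makes
100% round-trip agreement a meaningful end-to-end check of the classifier
rather than a statistical accident.

What this simulator deliberately does **not** model: sequencing or trace
noise, chromatogram deconvolution error, PCR bias, large structural
variants, or any biophysical propensity model of repair-outcome spectra.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .cohort_stats import TrialRecord
from .repair_classifier import ClassifierParams
from .sequence_core import (
    GuideRecord,
    Locus,
    ProgrammedEdit,
    find_guide_sites,
    normalize_deletion,
)

__all__ = [
    "CATEGORIES",
    "SimulationConfig",
    "GeneratedLocus",
    "SimulatedCohort",
    "ConfigInfeasibleError",
    "generate_locus",
    "simulate_cohort",
    "simulate_knockin_trials",
    "config_for_ratio",
    "write_cohort",
]

CATEGORIES = (
    "unedited",
    "nhej_insertion",
    "nhej_deletion",
    "mmej_deletion",
    "hdr",
)

TRUE_CATEGORY = {
    "unedited": "UNEDITED",
    "nhej_insertion": "NHEJ",
    "nhej_deletion": "NHEJ",
    "mmej_deletion": "MMEJ",
    "hdr": "HDR",
}

_BASES = np.array(list("ACGT"))

_FLANK = 30          # random padding on each side of the engineered region
_SEPARATOR = 3       # random nt between planted repeat structures
_DONOR_SITE = "GAATTC"  # EcoRI recognition site used as the programmed edit


class ConfigInfeasibleError(ValueError):
    """The requested cohort cannot be realized (capacity or rejection cap)."""


def _default_mh_probs() -> dict[int, float]:
    # 90% of MMEJ mass on short junctions (2-8 nt), 10% tail out to 25 nt
    probs = {m: 0.9 / 7 for m in range(2, 9)}
    probs.update({m: 0.1 / 17 for m in range(9, 26)})
    return probs


def _default_weights() -> dict[str, float]:
    return {
        "unedited": 0.25,
        "nhej_insertion": 0.15,
        "nhej_deletion": 0.20,
        "mmej_deletion": 0.30,
        "hdr": 0.10,
    }


@dataclass
class SimulationConfig:
    """Generative model of an embryo-editing cohort.

    Parameters
    ----------
    seed
        Master seed; identical configs produce byte-identical tables.
    n_guides, n_embryos
        Cohort shape: guides (one locus each) x embryos per guide.
    alleles_per_embryo
        Inclusive range of mosaic allele counts per embryo.
    category_weights
        Simplex over allele categories (keys of :data:`CATEGORIES`).
    mh_length_probs
        Distribution of MMEJ junction lengths, support within [2, 25] nt.
    deletion_length_p / deletion_length_cap
        Geometric parameter (mean ``1/p``) and cap for deletion lengths.
    insertion_length_p / insertion_length_cap
        Same for NHEJ insertion lengths.
    locus_length
        Explicit locus length, or ``None`` to auto-size to the planted
        repeat structures.
    max_rejections
        Iteration cap for rejection sampling (locus structures and NHEJ
        deletions) before the config is declared infeasible.
    """

    seed: int
    n_guides: int = 88
    n_embryos: int = 10
    alleles_per_embryo: tuple[int, int] = (1, 4)
    category_weights: dict[str, float] = field(default_factory=_default_weights)
    mh_length_probs: dict[int, float] = field(default_factory=_default_mh_probs)
    deletion_length_p: float = 1 / 6
    deletion_length_cap: int = 30
    insertion_length_p: float = 0.5
    insertion_length_cap: int = 10
    locus_length: Optional[int] = None
    max_rejections: int = 200

    def __post_init__(self) -> None:
        if self.n_guides < 1 or self.n_embryos < 1:
            raise ValueError("n_guides and n_embryos must be positive")
        lo, hi = self.alleles_per_embryo
        if not 1 <= lo <= hi:
            raise ValueError("invalid alleles_per_embryo range")
        if set(self.category_weights) != set(CATEGORIES):
            raise ValueError(f"category_weights must have keys {CATEGORIES}")
        total = sum(self.category_weights.values())
        if abs(total - 1.0) > 1e-9 or min(self.category_weights.values()) < 0:
            raise ValueError("category weights must be a simplex summing to 1")
        if not self.mh_length_probs:
            raise ValueError("mh_length_probs must be non-empty")
        for m, p in self.mh_length_probs.items():
            if not (2 <= m <= 25) or p < 0:
                raise ValueError("mh lengths must lie in [2, 25] with p >= 0")
        if abs(sum(self.mh_length_probs.values()) - 1.0) > 1e-9:
            raise ValueError("mh_length_probs must sum to 1")
        if not 0 < self.deletion_length_p <= 1 or not 0 < self.insertion_length_p <= 1:
            raise ValueError("geometric parameters must lie in (0, 1]")

    @property
    def mh_support(self) -> list[int]:
        return sorted(m for m, p in self.mh_length_probs.items() if p > 0)

    def min_locus_length(self) -> int:
        """Smallest locus that fits all planted structures (gaps of 1 nt)."""
        planted = sum(_SEPARATOR + 2 * m + 1 for m in self.mh_support)
        return 2 * _FLANK + 20 + 3 + planted


@dataclass
class GeneratedLocus:
    """A simulated locus plus everything planted into it."""

    locus: Locus
    guide: GuideRecord
    mmej_deletions: dict[int, tuple[int, int]]  # mh length -> deletion interval
    repair_window: int


@dataclass
class SimulatedCohort:
    """Output of :func:`simulate_cohort`: tables plus the guaranteed params.

    ``classifier_params`` is the parameter set under which every truth label
    is guaranteed to match the classifier (notably a repair window wide
    enough to cover the planted-repeat region).
    """

    config: SimulationConfig
    loci: dict[str, Locus]
    guides: dict[str, GuideRecord]
    alleles: pd.DataFrame
    truth: pd.DataFrame
    classifier_params: ClassifierParams


def _random_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _geometric(rng: np.random.Generator, p: float, cap: int) -> int:
    return int(min(rng.geometric(p), cap))


# ---------------------------------------------------------------------------
# locus construction
# ---------------------------------------------------------------------------

def generate_locus(
    config: SimulationConfig,
    name: str = "locus000",
    rng: Optional[np.random.Generator] = None,
) -> GeneratedLocus:
    """Build a locus with a unique NGG guide site and planted repeat pairs.

    For every microhomology length ``m`` the config can draw, the locus
    contains a deletable block whose removal leaves a junction repeat of
    exactly ``m`` nt; each planted structure is verified against
    :func:`~mmejtools.sequence_core.normalize_deletion` and re-drawn when
    flanking sequence accidentally extends the repeat.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    support = config.mh_support
    min_length = config.min_locus_length()
    if config.locus_length is not None and config.locus_length < min_length:
        raise ConfigInfeasibleError(
            f"locus length {config.locus_length} cannot hold repeat pairs up to "
            f"{max(support)} nt (need >= {min_length})"
        )

    for _ in range(20):  # whole-locus attempts (guide-placement uniqueness)
        left = _random_seq(rng, _FLANK)
        protospacer = _random_seq(rng, 20)
        pam = _random_seq(rng, 1) + "GG"
        # one slot per supported mh length: separator + repeat + gap + repeat
        gaps: dict[int, int] = {}
        for m in support:
            drawn = _geometric(rng, config.deletion_length_p, config.deletion_length_cap)
            gaps[m] = max(1, drawn - m)  # MMEJ deletion length = m + gap
        if config.locus_length is not None:
            budget = (
                config.locus_length
                - 2 * _FLANK
                - 23
                - sum(_SEPARATOR + 2 * m for m in support)
            )
            while sum(gaps.values()) > budget:
                widest = max(gaps, key=lambda m: gaps[m])
                if gaps[widest] == 1:
                    break
                gaps[widest] -= 1
        slots = {
            m: {
                "sep": _random_seq(rng, _SEPARATOR),
                "repeat": _random_seq(rng, m),
                "gap": _random_seq(rng, gaps[m]),
            }
            for m in support
        }

        locus = None
        for _ in range(config.max_rejections):
            segments = [left, protospacer, pam]
            intervals: dict[int, tuple[int, int]] = {}
            pos = _FLANK + 23
            for m in support:
                slot = slots[m]
                pos += _SEPARATOR
                a = pos  # start of first repeat copy
                pos += m + len(slot["gap"])
                b = pos  # start of second copy == deletion right boundary
                pos += m
                intervals[m] = (a, b)
                segments.append(slot["sep"] + slot["repeat"] + slot["gap"] + slot["repeat"])
            right_pad = _FLANK
            if config.locus_length is not None:
                right_pad = config.locus_length - pos
            segments.append(_random_seq(rng, right_pad))
            sequence = "".join(segments)

            failed = []
            for m, (a, b) in intervals.items():
                # deleting [a, b) removes copy1 + gap; the junction repeat
                # must be exactly the planted m nt, no accidental extension
                _, span = normalize_deletion(sequence, (a, b))
                if span != m:
                    failed.append(m)
            if not failed:
                locus = sequence
                break
            for m in failed:  # redraw only the offending structures
                slots[m] = {
                    "sep": _random_seq(rng, _SEPARATOR),
                    "repeat": _random_seq(rng, m),
                    "gap": _random_seq(rng, gaps[m]),
                }
        if locus is None:
            raise ConfigInfeasibleError(
                "could not plant verified repeat structures within the rejection cap"
            )

        locus_obj = Locus(name=name, sequence=locus)
        sites = find_guide_sites(locus_obj, protospacer)
        if len(sites) != 1 or sites[0].strand != "+" or sites[0].cut_site != _FLANK + 17:
            continue  # accidental second site (or PAM elsewhere): rebuild
        cut = sites[0].cut_site
        locus_obj.donor_edit = ProgrammedEdit(
            kind="substitution",
            start=cut,
            end=cut + len(_DONOR_SITE),
            replacement=_DONOR_SITE,
        )
        deletions = dict(intervals)
        max_dist = max(
            max(abs(a - cut), abs(b - cut)) for a, b in deletions.values()
        )
        window = max(60, max_dist + 5)
        return GeneratedLocus(
            locus=locus_obj,
            guide=sites[0],
            mmej_deletions=deletions,
            repair_window=window,
        )
    raise ConfigInfeasibleError("could not place a unique guide site")


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _sample_nhej_deletion(
    rng: np.random.Generator,
    sequence: str,
    cut: int,
    config: SimulationConfig,
    mh_min: int,
) -> tuple[tuple[int, int], int]:
    """Rejection-sample a cut-spanning deletion with sub-threshold junction."""
    for _ in range(config.max_rejections):
        length = _geometric(rng, config.deletion_length_p, config.deletion_length_cap)
        offset = int(rng.integers(0, length + 1))
        start = cut - offset
        end = start + length
        if start < 1 or end > len(sequence) - 1:
            continue
        _, span = normalize_deletion(sequence, (start, end))
        if length == 1 or span < mh_min:
            return (start, end), span
    raise ConfigInfeasibleError(
        "config infeasible: could not sample a microhomology-free deletion"
    )


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate the full cohort: loci, guides, allele tables, truth labels."""
    rng = np.random.default_rng(config.seed)
    params = ClassifierParams()  # mh range fixed at the 2-25 nt convention
    loci: dict[str, Locus] = {}
    guides: dict[str, GuideRecord] = {}
    allele_rows: list[dict] = []
    truth_rows: list[dict] = []
    max_window = 60

    support = np.array(config.mh_support)
    mh_probs = np.array([config.mh_length_probs[m] for m in support])
    mh_probs = mh_probs / mh_probs.sum()
    weights = np.array([config.category_weights[c] for c in CATEGORIES])

    for gi in range(config.n_guides):
        guide_id = f"guide{gi:03d}"
        locus_name = f"locus{gi:03d}"
        generated = generate_locus(config, name=locus_name, rng=rng)
        loci[locus_name] = generated.locus
        guides[guide_id] = generated.guide
        max_window = max(max_window, generated.repair_window)
        cut = generated.guide.cut_site
        sequence = generated.locus.sequence
        donor = generated.locus.donor_edit

        lo, hi = config.alleles_per_embryo
        for ei in range(config.n_embryos):
            embryo_id = f"{guide_id}_embryo{ei:03d}"
            k = int(rng.integers(lo, hi + 1))
            frequencies = rng.dirichlet(np.ones(k)) * 100.0
            categories = rng.choice(len(CATEGORIES), size=k, p=weights)
            # distinct junction lengths within an embryo where possible, so
            # mosaic alleles are distinguishable rows
            n_mmej = int(np.sum(categories == CATEGORIES.index("mmej_deletion")))
            if 0 < n_mmej <= len(support):
                mh_draws = list(rng.choice(support, size=n_mmej, replace=False, p=mh_probs))
            else:
                mh_draws = list(rng.choice(support, size=max(n_mmej, 0), replace=True, p=mh_probs))
            for ai, (cat_idx, freq) in enumerate(zip(categories, frequencies)):
                category = CATEGORIES[cat_idx]
                allele_id = f"{embryo_id}_a{ai}"
                kind, ds, de, ins, true_mh = "none", 0, 0, "", 0
                if category == "nhej_insertion":
                    kind = "insertion"
                    ds = de = cut
                    ins = _random_seq(
                        rng,
                        _geometric(rng, config.insertion_length_p, config.insertion_length_cap),
                    )
                elif category == "nhej_deletion":
                    (ds, de), true_mh = _sample_nhej_deletion(
                        rng, sequence, cut, config, params.mh_min
                    )
                    kind = "deletion"
                elif category == "mmej_deletion":
                    m = int(mh_draws.pop())
                    ds, de = generated.mmej_deletions[m]
                    kind = "deletion"
                    true_mh = m
                elif category == "hdr":
                    kind = "substitution"
                    ds, de, ins = donor.start, donor.end, donor.replacement
                allele_rows.append(
                    {
                        "allele_id": allele_id,
                        "embryo_id": embryo_id,
                        "guide_id": guide_id,
                        "kind": kind,
                        "del_start": ds,
                        "del_end": de,
                        "ins_seq": ins,
                        "frequency_percent": float(freq),
                    }
                )
                truth_rows.append(
                    {
                        "allele_id": allele_id,
                        "embryo_id": embryo_id,
                        "guide_id": guide_id,
                        "true_category": TRUE_CATEGORY[category],
                        "true_mh_length": true_mh,
                    }
                )

    return SimulatedCohort(
        config=config,
        loci=loci,
        guides=guides,
        alleles=pd.DataFrame(allele_rows),
        truth=pd.DataFrame(truth_rows),
        classifier_params=ClassifierParams(repair_window=max_window),
    )


def config_for_ratio(
    ratio: float,
    seed: int,
    n_embryos: int = 50,
    n_guides: int = 1,
    edited_mass: float = 0.8,
    **overrides,
) -> SimulationConfig:
    """Config whose expected per-embryo NHEJ/MMEJ frequency ratio is ``ratio``.

    The non-unedited mass is split between NHEJ (insertions and deletions in
    equal parts) and MMEJ so that w_NHEJ / w_MMEJ = ratio; HDR is off.
    """
    if ratio < 0:
        raise ValueError("ratio must be nonnegative")
    w_nhej = edited_mass * ratio / (1.0 + ratio)
    w_mmej = edited_mass / (1.0 + ratio)
    weights = {
        "unedited": 1.0 - edited_mass,
        "nhej_insertion": w_nhej / 2,
        "nhej_deletion": w_nhej / 2,
        "mmej_deletion": w_mmej,
        "hdr": 0.0,
    }
    return SimulationConfig(
        seed=seed,
        n_guides=n_guides,
        n_embryos=n_embryos,
        category_weights=weights,
        **overrides,
    )


# ---------------------------------------------------------------------------
# knock-in trial simulation
# ---------------------------------------------------------------------------

def simulate_knockin_trials(
    seed: int,
    n_loci: int = 11,
    replicates_per_locus: int = 3,
    true_fold: float = 2.4,
    baseline_rate_range: tuple[float, float] = (0.05, 0.25),
    embryos_per_replicate: int = 40,
) -> list[TrialRecord]:
    """Simulate paired knock-in trials with a known treatment fold change.

    Each locus gets a latent baseline positive rate; treated replicates use
    ``true_fold`` times that rate (capped at 0.95).  Counts are binomial, so
    recovered folds scatter with the usual ratio-of-proportions noise.
    """
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    lo, hi = baseline_rate_range
    for li in range(n_loci):
        base_rate = float(rng.uniform(lo, hi))
        treated_rate = min(0.95, true_fold * base_rate)
        for ri in range(replicates_per_locus):
            for arm, rate in (("baseline", base_rate), ("cati", treated_rate)):
                positives = int(rng.binomial(embryos_per_replicate, rate))
                trials.append(
                    TrialRecord(
                        locus_id=f"locus{li:02d}",
                        arm=arm,
                        replicate_id=f"rep{ri}",
                        positives=positives,
                        total=embryos_per_replicate,
                    )
                )
    return trials


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, out_dir: Union[str, Path]) -> None:
    """Write a cohort as plain-text artifacts: FASTA loci, TSV tables, JSON config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "loci.fasta", "w") as handle:
        for name, locus in cohort.loci.items():
            handle.write(f">{name}\n{locus.sequence}\n")
    guides = pd.DataFrame(
        [
            {
                "guide_id": gid,
                "locus": g.locus_name,
                "protospacer": g.protospacer,
                "strand": g.strand,
                "pam_start": g.pam_start,
                "cut_site": g.cut_site,
            }
            for gid, g in cohort.guides.items()
        ]
    )
    guides.to_csv(out / "guides.tsv", sep="\t", index=False)
    donors = pd.DataFrame(
        [
            {
                "locus": name,
                "kind": locus.donor_edit.kind,
                "start": locus.donor_edit.start,
                "end": locus.donor_edit.end,
                "replacement": locus.donor_edit.replacement,
            }
            for name, locus in cohort.loci.items()
            if locus.donor_edit is not None
        ]
    )
    donors.to_csv(out / "donors.tsv", sep="\t", index=False)
    cohort.alleles.to_csv(out / "alleles.tsv", sep="\t", index=False)
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    config = asdict(cohort.config)
    config["mh_length_probs"] = {str(k): v for k, v in config["mh_length_probs"].items()}
    with open(out / "config.json", "w") as handle:
        json.dump(config, handle, indent=2)
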