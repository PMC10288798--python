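# Methods

## Scope and data model

The package consumes allele-level genotyping tables of CRISPR-edited
embryos — the output shape of Sanger-trace decomposition tools — together
with reference amplicon sequences and guide definitions. One
`AlleleObservation` is one allele of one embryo with a percent frequency;
mosaic embryos carry several alleles whose frequencies sum to 100%. The
package never re-estimates frequencies from reads or traces, and it does not
model trace-deconvolution error: an allele table is taken at face value.

Coordinates are 0-based half-open throughout; readers accept a `one_based`
flag for tables in 1-based inclusive convention. Guides found on the minus
strand are stored in locus-forward coordinates, so all junction arithmetic
operates on the forward reference.

## Cut-site geometry

The Cas9 blunt cut is placed 3 nt 5′ of the PAM, between protospacer
positions 17 and 18 — standard SpCas9 geometry. The offset is a parameter of
`locate_guide` for nucleases with different geometry. A protospacer/PAM
combination that matches more than one site is an error rather than a
"pick first": silent mis-anchoring would corrupt every downstream call, so
the caller must disambiguate via `site_index` or an explicit `pam_start`.

## Deletion canonicalization and junction microhomology

The same edited sequence can be produced by several equal-length deletion
placements whenever the two deletion boundaries share sequence. Upstream
tools are not guaranteed to left-align (we could find no statement either
way for trace-decomposition output), so every deletion is re-normalized: the
canonical interval is the left-most equivalent placement, and the
**ambiguity span** is the number of alternative placements minus one. The
junction microhomology of a deletion *is* this ambiguity: its sequence is
read from the reference at the left boundary. This junction-repeat reading —
rather than a distal homology search — matches how microhomology arms are
marked in allele-resolution editing figures and the convention of the
deletion-pattern literature.

Properties guaranteed (and property-tested against a brute-force
edited-string enumeration oracle): normalization is idempotent, preserves
the edited sequence, and the ambiguity equals the oracle's placement count
minus one.

## Classification rules

Per allele, in order:

1. **UNEDITED** — no edit.
2. **HDR** — the edited sequence equals the reference with the programmed
   donor edit applied exactly. Matching is whole-sequence string equality,
   so flanks must be reference; partial or imperfect donor integration
   (a substitution overlapping the donor interval but differing from it) is
   reported **unattributable** rather than force-fitted.
3. **Unattributable** — no boundary of the event lies within the repair
   window of the cut (default ±50 nt, amplicon scale; configurable). For
   deletions the window test is evaluated over the whole placement-
   equivalence range, which keeps the decision placement-invariant.
   Unattributable mass is reported and excluded from category totals.
4. **NHEJ** — any insertion occurred (pure insertion or deletion+insertion),
   the deletion is a single base (even inside a homopolymer), or the
   junction microhomology is shorter than `mh_min`. Non-programmed
   substitutions are also counted NHEJ (mutagenic, templateless end
   joining); the binary NHEJ/MMEJ split has no separate class for them.
5. **MMEJ** — a pure deletion ≥ 2 nt with junction microhomology in
   `[mh_min, mh_max]` = [2, 25] nt by default.

Junctions longer than `mh_max` are reported capped at 25 with an
`mh_capped` flag instead of being silently labelled or dropped — such
events may be single-strand-annealing-like and deserve inspection. The
`delins → NHEJ` rule ("insertion occurred" takes precedence) is
configurable (`delins_is_nhej`). With `mh_min = 2` the single-base rule and
the microhomology threshold never conflict; if `mh_min` is lowered to 1 the
single-base rule still wins, by design.

Per embryo, category frequencies are summed; editing efficiency is the
edited share of the *attributable* mass,
`100·(f_NHEJ+f_MMEJ+f_HDR)/(f_NHEJ+f_MMEJ+f_HDR+f_UNEDITED)`, which reduces
to `100 − f_UNEDITED` when everything is attributable. Frequency sums above
100 plus a 0.5-point tolerance are rejected as malformed.

## Cohort statistics

Per guide, category frequencies are averaged over embryos and the repair
balance is the ratio of *mean* frequencies, `R = mean f_NHEJ / mean f_MMEJ`
— not the mean of per-embryo ratios — which keeps R defined when single
embryos have zero MMEJ mass and makes it invariant under proportional
mosaicism. `R = +∞` (NHEJ-biased) when only the MMEJ mean is zero; the
class is `undefined` when both are zero. Bias boundaries: MMEJ-biased
R < 0.5, balanced 0.5 ≤ R ≤ 2 (boundaries inclusive in the balanced class),
NHEJ-biased R > 2; both thresholds configurable. Efficiency stratification
splits guides strictly below vs at-or-above the threshold (default 66.7%).
Reporting conventions: percentages at 2 decimals, ratios at 3.

Knock-in trials are counts (`positives`/`total`) per locus, arm and
replicate. Each treated replicate's efficiency is divided by the same
locus's baseline-mean efficiency; the overall fold is the unweighted mean
over replicate pairs. This per-locus baseline-mean normalization is one
defensible reading of a "standardization across loci" analysis — no formula
is standard — and loci with zero baseline mean are excluded and reported
rather than imputed.

## Synthetic cohorts

The generator emulates the targeted experimental design at the measurement
layer: a
cohort of 88 guides × 10 embryos by default, 1–4 mosaic alleles per embryo
(uniform), per-embryo frequencies drawn flat on the simplex (×100), and
allele categories drawn from a simplex of weights, default

| category | weight |
| --- | --- |
| unedited | 0.25 |
| NHEJ insertion | 0.15 |
| NHEJ deletion | 0.20 |
| MMEJ deletion | 0.30 |
| HDR | 0.10 |

chosen once as a realistic mid-efficiency editing mixture (deletions more
prevalent than insertions, substantial MMEJ, minority HDR). Outcome-length
defaults, likewise fixed once since no outcome-spectrum distributions are
published for this setting: deletion lengths geometric with mean 6 nt capped
at 30; insertion lengths geometric with mean 2 nt capped at 10; MMEJ
junction lengths with 90% of mass uniform on 2–8 nt and a 10% tail uniform
on 9–25 nt.

Each locus is constructed, not sampled blindly: downstream of a randomly
drawn protospacer+NGG site, one `repeat–gap–repeat` structure is planted per
junction length the configuration can draw. Deleting one repeat copy plus
the gap yields a junction of exactly that length; every planted structure is
verified with the package's own normalization machinery at generation time
and locally re-drawn when flanking sequence accidentally extends the repeat.
NHEJ deletions are rejection-sampled around the cut until their junction
ambiguity is below `mh_min` (or they are single-base); HDR alleles apply the
programmed edit (an EcoRI-site substitution across the cut, which also
destroys the PAM) exactly. Truth labels are therefore consistent with the
classifier's operational rules *by verified construction*, which is what
makes 100% round-trip agreement a meaningful end-to-end test of the
classification path rather than a statistical coincidence — and is also why
that agreement says nothing about trace-decomposition noise, imperfect HDR,
or complex alleles in real data, none of which the generator emits.

The planted region extends past a ±50 nt window for junction lengths near
25, so the simulator reports the `ClassifierParams` (with an auto-sized
repair window covering all planted structures) under which its guarantees
hold. Fixed seed implies byte-identical output; all randomness flows from
one `numpy` generator.

Simulated knock-in trials draw a latent baseline positive rate per locus
(uniform on 5–25%), apply a known treatment fold (capped at a 95% rate), and
emit binomial counts over 40 embryos per replicate — the scale at which a
33-pair cohort recovers the design fold within ratio-of-proportions noise.

## Off-target bookkeeping

Three rules on plain record tables, deliberately excluding the upstream
aligners and callers:

* **Consensus**: exact-key `(chromosome, position, ref, alt)` intersection
  across exactly three callers; order- and duplicate-invariant. Indel keys
  are assumed left-normalized upstream and are not re-normalized across
  callers (documented limitation).
* **Breakpoints**: genome-side chimeric-read positions clustered greedily
  per chromosome, new cluster when a read lies more than the window
  (default 100 nt, split-read scatter scale) past the cluster's first
  position; support = cluster size; thresholds (10 and 20 by default)
  applied inclusively. Every read lands in exactly one cluster, so support
  totals are conserved.
* **Coverage loss**: `max(0, 1 − inner_mean/flank_mean)` clipped to [0, 1],
  inner window ±50 nt of the cut, flanks the outer tenth of the amplicon at
  each end by default. This is an operationalization of "proportion of lost
  coverage" from per-position depth; published values computed from
  read-level long-read definitions are not comparable quantity-for-quantity
  and are not targeted. Zero flank depth is an error (uncovered amplicon);
  the statistic is invariant under uniform depth scaling.

## Numerical and degenerate-input choices

* Ratio sentinels: `+∞` (MMEJ mean zero, NHEJ positive), `None`/undefined
  (both zero). Empty profile lists, empty observation lists, fewer than
  three callers, zero-total trials and zero flank depth all raise.
* Rounding happens only at the reporting layer; internal arithmetic is full
  precision. A printed 3-decimal ratio can therefore differ in the last
  digit from a source that truncated instead of rounding.
* Rejection sampling is capped (`max_rejections`, default 200); exceeding
  the cap raises a config-infeasibility error instead of looping.
* Problem sizes used by the verification scripts — 10,000 oracle pairs at
  loci ≤ 200 nt, an 88 × 10 round-trip cohort, ratio-recovery cohorts of 50
  embryos, 33 simulated trial pairs — mirror the cohort scale the package
  targets while keeping every check cheap to re-run.

## Known limitations

* HDR calling is exact-match only; partial HDR, HDR with additional indels,
  and donor concatemers fall into the unattributable bucket.
* Substitution-only alleles cannot be assigned to NHEJ vs polymerase errors
  of the readout; they are counted NHEJ by convention.
* Single-strand annealing is never called as a category; very long junction
  repeats are merely flagged.
* The breakpoint clusterer is single-linkage-like by first-position anchor;
  pathological read scatter spanning several windows splits clusters at
  anchor boundaries.
* The synthetic generator's guarantees hold under the `ClassifierParams` it
  emits; classifying its output with a narrower repair window reclassifies
  distant planted MMEJ deletions as unattributable by design.
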