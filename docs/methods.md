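# Methods

## Data model

The unit of observation is a cell of the invariant *C. elegans* embryonic
lineage, identified in Sulston nomenclature: a founder prefix (P0–P4, AB,
EMS, MS, E, C, D, Z2, Z3) followed by a suffix over {a, p, l, r, d, v}, one
character per division. The early cleavages are hard-coded as the fixed
founder table P0→{AB, P1}, P1→{EMS, P2}, EMS→{MS, E}, P2→{C, P3},
P3→{D, P4}, P4→{Z2, Z3}; for suffixed names the parent is the name minus
its last character. Daughters are ordered anterior/left/dorsal first. The
EMS division carries no a/p character in the names, so for history labeling
E (the Wnt-signalled daughter) is treated as posterior-equivalent and MS as
anterior-equivalent; this mapping is a configuration of the founder table,
not an inference.

Each cell carries a single concentration statistic, the *blot*: mean
nuclear reporter intensity minus local non-nuclear background, averaged
over the cell's lifetime with equal weight per timepoint (the acquisition
interval is assumed constant; a time-weighted variant is available). Blot
values can be negative and are never clipped anywhere in the pipeline.
Per-cell tables use 1-based column indices (name in column 1, birth time in
column 3, blot in column 7 by default); every index is configurable because
the remaining columns of such deposits are typically undocumented, and the
reader tolerates extra columns and either line-ending convention.

## Sister asymmetry

Asymmetry of a division is the posterior daughter's blot minus the
anterior's (second-listed minus first-listed on l-r and d-v axes). It is an
absolute difference, not a ratio — the natural scale for
background-subtracted concentrations that can cross zero; a log-ratio
variant exists but is not the default. Each reporter family has a
configured expected sign (SYS-1/WRM-1 posterior-positive, POP-1
anterior-positive); the sign is never inferred from data.

Per-division significance is a two-sided one-sample *t*-test of the mean
asymmetry across replicate embryos (≥ 3 by default; Wilcoxon signed-rank
and exact sign-permutation alternatives are selectable), corrected across
divisions by Benjamini–Hochberg FDR. Testing per-division means across
embryos, rather than pooling cells, is the default because it respects the
replicate structure; a pooled mode exists. Polarity classes are assigned
against thresholds derived from an untreated wild-type reference group:
*none* within ± the largest |mean asymmetry| among a user-supplied list of
known-unpolarized divisions (the list is study design, not inferred);
*reversed* beyond that band opposite the expected sign; *low* in the
expected direction but at or below the bottom-5th-percentile cutoff of
wild-type asymmetries; *normal* otherwise. Boundaries are closed on the
"none" and "low" sides so classification is deterministic at thresholds.

Division-orientation deviation is the angle between a division's
daughter-to-daughter birth-position vector and the mean (direction-
normalised) wild-type vector for the same named division, flagged defective
beyond the wild-type 95th-percentile bound. Positions are never fabricated;
divisions without them are logged and skipped.

Stage stratification (e.g. before/after the 28-cell stage) uses the time at
which the embryo reaches a given live-cell count; boundary divisions fall
in the earlier stratum.

## History labels and cousin enrichment

A cell's history over its last *k* divisions is labeled High/Low per
division. By-name labeling uses the suffix characters (High iff the
character equals the reporter's High-polarity character); it applies only
to a-p divisions, and cells whose labeled divisions include a
reversed-polarity division (list supplied by the asymmetry stage) are
excluded from by-name labeling. By-measurement labeling calls a cell High
iff it had the greater blot of its sibling pair (ties break to Low, with a
warning); l-r and d-v divisions always use measurement since their names
carry no a/p polarity. The two modes agree on ≥ 99% of a-p divisions when
the planted boost is five noise SDs — verified as a test.

Cousin enrichment enumerates every grandparent quartet with a measurable
High-High cell (High daughter of a High parent) and its matched Low-High
cousin (grandparent + opposite character + High character); the pairing is
injective by construction. The headline statistic pools cells by class
across embryos: percent increase = (mean HH − mean LH)/mean LH × 100. A
mean of per-pair ratios is reported alongside but is deliberately not the
headline: with background-subtracted values the denominator can approach
zero, making per-pair ratios heavy-tailed and Jensen-biased upward, while
the group-mean version is stable (and exactly equal to the planted value in
the noise-free generator). The ratio is reported as not available when the
LH group mean is ≤ 0. Significance is a Wilcoxon signed-rank over matched
pairs (rank-sum alternative available); no cross-reporter "combined p" is
produced because there is no principled way to pick a combination rule for
two non-independent cell populations.

Triple-history contrasts compare group means of cells with 3-division
histories: HHH vs LHH isolates two-division memory; LHH vs HLH isolates
one-division memory at matched total numbers of High divisions.

The SYS-1-per-POP-1 ratio of a history class is estimated as the
ordinary-least-squares slope (with intercept; a through-origin variant
exists) of SYS-1 against POP-1 concentrations over the class's cells; the
fold between classes is the slope ratio. The slope is attenuated toward
zero when the predictor's within-class signal variance is small relative to
measurement noise — an errors-in-variables property of any slope-based
ratio estimate, stated here rather than corrected, since the published
quantity is defined as a best-fit slope.

## Stable lagged reporters

For POPTOP-family reporters (multimerised TCF sites driving a stable
histone fusion), transcription in one cell surfaces in its descendants
after a maturation delay. *Activity* of a cell is the unweighted mean blot
over the cell and all recorded descendants — the plainest reading of
"average expression of a cell and its descendants"; it satisfies
activity(c)·size(c) = blot(c) + Σ activity(d)·size(d) over daughters, which
the tests assert exactly. Activity sister asymmetry (posterior minus
anterior subtree) isolates single divisions; cohorts by parent birth stage
use 50/100/200-cell bins by default.

Expression-initiating cells are the operational replacement for manual
curation: maximal clades in which every recorded cell exceeds an onset
threshold, walked back along the unique ancestor path to the ancestor alive
at (clade-root birth − lag). The lag defaults to 30 minutes (mCherry-class
maturation) and is a parameter because maturation varies by fluorophore.
The per-gene High-High score is the fraction of a gene's initiating
lineages labeled SYS-1 HH (k = 2, by-name); regulation classes (activated /
repressed / dual / unregulated / indirect) are user-supplied annotations
from perturbation data, never inferred. Where a gene's lineages have mixed
histories, this operational lineage-counting rule is one consistent choice
among several the underlying definitions would admit.

## Motif scanning

TCF/HMG sites are found by IUPAC-consensus text search (default
`CTTTGWW`) and/or PWM scoring above a threshold, on both strands, with
coordinates 0-based half-open on the forward strand. Hits from different
definitions (or both strands of a palindrome) covering the same interval
are reported once. Helper sites (default consensus `GCCGCCR`) are flagged
within ±20 bp of each TCF site. The worm-specific HMG and Helper strings
used in any particular published count are not bundled — the defaults are
the canonical family consensi and are plain configuration, so published
per-gene site counts are reproducible only with the original motif strings
supplied. Enrichment is site density (sites per kb, since region lengths
differ) in targets over the mean density of permutation draws of
equal-count background sets, with a +1-corrected permutation p.

## Synthetic embryos

The generator emulates the statistical structure of lineage-traced reporter
data, not its biophysics. A skeleton expands from P0 in birth-time order
with cycle lengths jittered around 25 min (≈ the early-embryo cleavage
interval at 22.5 °C) until the target live-cell count; Z2/Z3 never divide;
~5% of later divisions sit on l-r/d-v axes by default, matching the small
minority of non-a-p divisions in the embryo.

Instant (concentration) reporters draw

    High daughter:  blot = μ + α·γ^m + ε
    Low daughter:   blot = μ − α/2 + ε

with m the number of consecutive reporter-High ancestors capped at the
memory depth (1 or 2), ε ~ N(0, σ²), and a per-embryo lognormal scale on
the means. With memory 1 and no noise the HH-over-LH percent increase is
exactly 100·α(γ−1)/(μ+α), which the tests assert; γ is therefore calibrated
from the enrichment each study condition states. Defaults are the
wild-type β-catenin condition: 350-cell stage, 8 embryos per group,
μ = 40 a.u., α = 60 a.u. = 3σ (σ = 20), 10% replicate scaling, and γ set so
the planted enrichment is 74%; WRM-1-like (24%), POP-1-like (52%,
anterior-High) and receptor-null (γ = 1 with α halved) conditions rescale
the same model. Reversed divisions swap the daughters' means; a
ligand-null-like option halves α before the 28-cell stage only. Optional
shared latents couple two reporters simulated over one skeleton: a
per-cell lognormal scale (detection/size variation, SD 0.3) that makes
class slopes estimate mean ratios, and a per-division boost effect
(SD 0.25) that plants cross-reporter asymmetry correlations. Negative
blots arise naturally at low μ and are not clipped.

Stable-lagged mode instead activates any cell whose consecutive-High depth
reaches the activation threshold (default 2, mimicking multi-TCF-site
enhancers) and gives the expression level only to cells born at least the
lag after their clade's activation; everything else is baseline noise.
Ground truth (per-cell High/Low, depth, activation and initiation flags,
true means) is stored beside every dataset; an activation is flagged
initiating only if some cell of its clade is born after the lag, i.e. only
if it is in principle visible.

What the generator does **not** emulate: spatial signaling (neighbor
positions play no role in High/Low assignment), cell-cycle-dependent
nuclear import, reporter bleaching or depth attenuation, segmentation and
tracking errors, and division-rate differences between lineages. Passing
recovery tests therefore demonstrates the statistics are implemented
correctly and calibrated, not that real embryos satisfy the model.

## Numerical choices and problem sizes

Degenerate inputs are handled deterministically: a zero-variance sample in
the one-sample *t* yields p = 1 (all-zero) or p = 0 (constant non-zero);
identical groups short-circuit to p = 1 in rank tests; measurement-label
ties go to Low with a warning; zero-variance predictors and zero-length
orientation vectors raise. Exact rank-sum null distributions are used
automatically for small tie-free samples. All simulation-backed tests run
the study condition at 8 embryos × 350 cells, with 20 seeds for parameter
recovery and 2000 divisions for null calibration; these sizes give the
recovery CIs a few percent half-width while keeping the full suite and the
acceptance script each under a minute of compute. All randomness flows
from explicit integer seeds, and regeneration with a fixed seed is
byte-identical.

## Known limitations

- By-name history labels presume the canonical polarity rule; in heavily
  perturbed genotypes with many reversed divisions, by-measurement mode is
  the safer default and the two modes will disagree.
- The slope-based ratio estimate is attenuated by measurement noise (see
  above) and is sensitive to the class composition of cells.
- Initiating-cell inference assumes expression, once started, persists in
  all descendants (true for stable histone fusions, not for destabilised
  reporters) and cannot see activations whose clades are entirely born
  within the lag window.
- The per-cell table reader trusts the declared column layout; it validates
  names, not the semantics of the remaining columns.
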