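# Methods

This note records the models implemented in `clonaldyn`, the parameter
conventions, and the design decisions taken where more than one
reasonable construction existed.

## The single-progenitor model with fate imbalance

Squamous epithelia such as mouse oesophagus are maintained by a single
population of equipotential basal progenitors. Each division produces
two progenitors (PP), one progenitor and one differentiating daughter
(PD), or two differentiating daughters (DD):

    P(PP) = r (1 + δ),   P(PD) = 1 − 2r,   P(DD) = r (1 − δ)

Progenitors divide at rate λ (divisions/week); differentiating basal
cells leave the basal layer (stratify) at rate Γ (/week). With δ = 0 the
symmetric outcomes balance and the tissue is homeostatic; labelled-clone
dynamics are then neutral drift (clone loss with compensating growth of
the survivors, constant labelled fraction). A heterozygous p53
gain-of-function mutation is modelled as a fate imbalance δ > 0 in the
mutant population only, with division and stratification rates unchanged
— mutant clones expand exponentially, with the mean number of basal
cells per induced clone growing asymptotically at rate 2rλδ per week.

Three published parameter combinations for mouse oesophagus are bundled
as `PUBLISHED_PARAMS` ((r, λ, Γ, δ) = (0.1, 1.9, 3.5, 0.29), (0.06, 2.9, 3.7,
0.32), (0.1, 2.9, 5.4, 0.19)). They were all fitted to the same clone
data and therefore encode essentially one growth rate, 2rλδ ≈
0.110–0.111 /week — the internal-consistency property the acceptance
script exercises.

## Non-spatial branching oracle (`branching`)

Each clone is an independent continuous-time branching process started
from one progenitor, simulated exactly (Gillespie). `simulate_clones`
vectorizes across clones: every iteration advances all still-active
clones by one event, recording the pre-event state at crossed record
times, so 10^5 clones over 24 weeks take seconds. The progenitor count
alone is an autonomous birth–death chain (up rate λr(1+δ)p, down rate
λr(1−δ)p); `progenitor_count_pmf` integrates its master equation on a
truncated state space and is used in tests as an independent oracle for
the samplers (total-variation agreement at 10^5 runs).

"Average clone size" needs care. The lineage-tracing observable is the
mean over *surviving* clones (`mean_surviving_size`, default
`survivors_only=True`). But the log-slope relation slope = 2rλδ holds
for the mean over **all induced clones** (total labelled basal cells per
induced clone). Conditioning on survival divides by the surviving
fraction S(t), adding −d ln S/dt to the log-slope; while clone loss is
ongoing this inflates the fitted slope by ~20% (e.g. 0.129 vs 0.110
/week over weeks 4–24 for the first parameter row) and hence δ̂. The
δ-estimation pipeline therefore regresses on the unconditional mean,
which is experimentally accessible as survivor mean × surviving
fraction; both factors are standard lineage-tracing readouts.

## Fate-imbalance estimation (`fate_regression`)

`FateImbalanceModel` is an ordinary least-squares fit of ln(mean clone
size) against time; `fit()` returns a results object with the slope, its
standard error, δ̂ = slope/(2rλ) with (r, λ) taken as known from prior
homeostatic measurements, and a `summary()`. The default window starts
at the first record time ≥ 4 weeks — past the induction transient,
when each clone's differentiating compartment has equilibrated so the
mean grows at its asymptotic rate — and runs to the last observation;
the window is a parameter.

## Spatial cellular automaton (`progenitor_ca`)

Basal cells live on a periodic hexagonal lattice (odd-r offset
coordinates, 6-neighbourhood), by default 100 × 100 = 10,000 sites,
about 1% of the basal area of an adult mouse oesophagus. A site holds
0, 1 or 2 cells. Events are sampled in exact continuous time: divisions
of singly resident progenitors at their genotype's λ, stratifications of
singly resident differentiating cells at their genotype's Γ.

* **Daughter placement.** Both daughters initially occupy the mother's
  site (occupancy 2), then the site resolves.
* **Resolution order.** Migration first: if any of the six neighbouring
  sites is empty, one resident (chosen uniformly) moves into one empty
  neighbour (chosen uniformly). With no space, a differentiating
  resident (chosen uniformly among them) is instantly extruded from the
  basal layer — crowding-driven delamination, counted as stratified.
  Two progenitors with no space remain paired. Resolution runs
  immediately after each division, and each stratification offers the
  freed site to one uniformly chosen doubly occupied neighbour, so
  extrusion and unblocking are event-driven.
* **Division blocking.** A progenitor sharing a site cannot divide until
  the pair resolves; allowing it would exceed two cells per site given
  the daughter-placement rule. This is the package's resolution of an
  otherwise inconsistent rule set, and it is also the mechanism through
  which crowding slows growth.
* **Crowding feedback.** A mutant progenitor with at least one doubly
  occupied neighbouring site has its imbalance multiplied by
  `crowding_multiplier` (default 0, full suppression); wild-type cells,
  whose δ is zero anyway, do not respond. The quantitative form of this
  feedback is not established; the multiplier is exposed in the config.
* **Initial condition.** Fully occupied, one cell per site, with
  progenitor fraction Γ/(λ+Γ) (the homeostatic balance Γ·D = λ·P). A
  fraction `induction_fraction` of basal cells — progenitors and
  differentiating cells alike — is labelled mutant, one clone id each.
* **Determinism.** The lattice initialization uses a `default_rng` from
  the config seed; the event loop runs in a numba kernel seeded from
  the same integer, with a fixed draw order (waiting time, channel,
  cell, outcome, resolution choices). Identical configs give
  bit-identical trajectories.

Relation to the branching oracle: at low induction density and early
times the lattice is fluid (the initial differentiating pool stratifies
with mean waiting time 1/Γ ≈ 2 days, so empty sites are plentiful and
pairs resolve promptly) and progenitor-founded mutant clones follow the
non-spatial process. The equivalence is tested on **progenitor counts**
over the first two weeks: extrusion shortens the basal residence of
differentiating cells relative to the non-spatial model, so total basal
counts are not comparable even at low density. Beyond ~2 weeks double
occupancy accumulates toward its quasi-steady level and the crowding
feedback plus division blocking slow mutant growth — the intended
density-dependent behaviour, and the reason the labelled fraction
saturates instead of growing exponentially forever.

## Clone genomics on gridded biopsies (`clone_genomics`)

Deep targeted sequencing of a contiguous grid of 2 mm² biopsies yields
per-sample mutation calls with variant allele frequencies (VAFs). Under
the diploid heterozygous assumption, 2×VAF approximates the fraction of
cells carrying the mutation, so a clone's areal extent in one sample is
bounded by VAF×area (every carrying cell mutant at one allele, possible
copy-number loss) and min(2·VAF, 1)×area.

* **Merging.** A clone larger than one sample appears as the same
  (chrom, pos, ref, alt) key in adjacent samples. Sample centres sit on
  a 2 mm grid; for each key, samples carrying it are joined by edges
  when their centre distance is strictly below 3 mm (edge neighbours at
  2 mm, diagonal at 2.83 mm; the shared-mutation decay curve plateaus
  beyond 3 mm), and each connected component becomes one clonal event.
  The event VAF is the area-weighted mean over member samples only;
  samples not carrying the key contribute nothing.
* **Tissue coverage per gene.** Per biopsy, VAFs (lower) or 2×VAFs
  (upper) of non-synonymous mutations in the gene are summed, capped at
  1.0; the tissue fraction is the mean over all biopsies including
  mutation-free ones.
* **Mutation burden.** Only synonymous SNVs are used (selected genes in
  a targeted panel would inflate a non-synonymous count):
  burden/Mb = Σ min(2·VAF, 1) / synonymous footprint × 10⁶ per sample,
  tissue burden = unweighted mean over samples. The ×2 cell-fraction
  factor assumes autosomal heterozygous diploid mutations; a VAF-only
  lower-bound variant is exposed (`double_vaf=False`). Indels take part
  in merging and coverage but never in burden.
* **Clone density** = merged events per mm² of sequenced epithelium
  (26 events over 80 mm² → 0.33 /mm², rounded to two decimals in
  summaries).
* **TP53 consequence ranking** for cohort summaries: dominant-negative
  (protein change on the literature list p.R175H, p.Y220C, p.M237L,
  p.R248Q, p.R248W, p.R273H, p.R282W, p.R249S) > nonsense > missense >
  other > none.
* **Coordinates.** Mutation positions are 1-based (VCF convention);
  genomic intervals (BED, bins, segments) are 0-based half-open.

## Copy-number calling from shallow coverage (`cna`)

Matched sample/control bin counts are combined into logR = log2 of the
count ratio divided by its mean over unmasked autosomal bins (sex
chromosomes are excluded from the normalization but included in
calling). Zero-count control bins are masked rather than pseudocounted.
The mean-ratio normalization makes the track invariant to the global
depth of either library; note it is computed over the whole genome, so
a planted event occupying a large share of a small test genome shifts
the baseline visibly — fixtures therefore keep events small relative to
the genome, as real CNAs are.

* **Off-target binning (targeted mode).** Reads are counted in 1 kb
  bins; every bin overlapping a bait interval by ≥ 1 bp is dropped; the
  survivors are summed into 1 Mb bins aligned to position 0, keeping the
  surviving width per output bin. Bins with under 50% of their span
  surviving are masked — too little off-target territory for a stable
  shallow ratio. Dividing sample by control bins built the same way
  normalizes out the variable effective widths. WGS mode skips bait
  filtering and typically uses 100 kb bins.
* **GC correction.** A lowess fit of logR against GC (default span 0.3)
  is subtracted, median preserved; a no-op with a warning when GC is
  absent or degenerate. In matched sample/control ratios only the
  *difference* in the libraries' GC response survives, which is exactly
  what the correction removes.
* **Segmentation.** Exact penalized least-squares change-point detection
  per chromosome by dynamic programming, followed by iterative boundary
  polishing (each interior boundary re-placed at the exact two-segment
  optimum over its flanking segments) and merging of neighbours whose
  separation does not pay for the penalty. The default penalty is
  4σ̂² ln n — twice the BIC rate, because the best split is a maximum
  over all positions and the plain BIC penalty demonstrably
  over-segments; σ̂ comes from the median absolute first difference.
  The penalty is a config knob and the `segment_logr` interface accepts
  any penalty, so CBS-like alternatives can be slotted in.
* **Cell fraction.** Single-copy-change model in a diploid background: a
  loss in a fraction f of cells gives expected ratio 1 − f/2, a gain
  1 + f/2, so f = 2(1 − 2^logR) for losses and f = 2(2^logR − 1) for
  gains, clipped to [0, 1]; a sign inconsistent with the direction gives
  f = 0.
* **Post-hoc filters.** A call is retained only if f ≥ 0.10 (at least
  10% of sequenced cells) and length ≥ 20 Mb; filtered segments are
  reported with their reason.

Recovery regime: with counting noise var = (1+φ)·μ per bin, the per-bin
logR noise is √(2(1+φ)/μ)/ln 2. Reliable ±1-bin breakpoint placement for
an f = 0.30 event (step 0.23 in log2) needs roughly μ ≳ 1500 reads per
bin; at μ = 100 the per-bin noise (~0.21) is comparable to the step and
only the segment-level call, not the exact boundary, is stable.

## Synthetic data (`synthetic`)

The generators are pure functions of (spec, seed) and come with truth
tables sufficient to score every estimator.

* **Biopsy grids.** Planted clones occupy stated fractions of stated
  samples; pre-noise VAF = fraction/2 (diploid heterozygous); read
  sampling is binomial at the stated depth, default 600× as typical of
  deep targeted sequencing of normal epithelium; `depth=None` gives
  noise-free VAFs for exactness tests. `burden_grid_spec` plants a
  uniform synonymous burden that the burden estimator inverts exactly in
  noise-free mode.
* **Genome read sets.** A scaled-down four-chromosome genome (420 Mb)
  keeps run times in seconds; chromosome sizes are configurable.
  Control counts are negative binomial with var = (1 + φ)·μ, φ = 0.1 by
  default — shallow-coverage bin counts are near-Poisson with a modest
  inflation from mappability and library effects. Sample means are
  scaled by 1 ± f/2 inside planted events. Default mean depth is 2000
  reads per 1 Mb bin, the off-target yield of a deep targeted capture
  (a few tenths of 1× coverage at 150 bp reads); WGS-like fixtures use
  1200 reads per 100 kb bin (1.8× coverage). The GC wave is applied with
  a per-library amplitude (default: sample only), because an identical
  multiplicative wave would cancel exactly in the ratio — it is the
  *differential* GC response that produces waves in real matched logR
  tracks.
* **What the fixtures do not emulate:** mappability holes, replication
  timing, wave structure beyond a smooth GC response, clustered
  mutations and shared artefact hotspots, non-integer local copy states,
  and read-level errors. Passing tests show the estimators invert the
  stated generative models at realistic depths, not that they are robust
  to every artefact of real libraries.

## Problem sizes

The test suite and the acceptance script size their simulations as
follows: fate-imbalance recoveries use 10^5 clones over 24 weeks (the
Monte-Carlo error on δ̂ is then ~4×10⁻⁴, an order of magnitude below the
two-decimal reporting resolution); lattice properties use 100 runs of
the default 100×100 lattice over 52 weeks; CNA recovery uses 20 seeded
replicates of the default genome plus 20 null replicates. The whole
suite runs in well under five minutes on one CPU.

## Known limitations

* The automaton has no suprabasal layer: "labelled area" is approximated
  by the labelled basal fraction.
* The crowding feedback form (full suppression on any doubly occupied
  neighbour) is a stand-in for an unpublished dose–response; the
  multiplier is exposed but the neighbourhood rule is fixed.
* Cell fractions assume a single-copy change on a diploid background;
  multi-copy amplifications will be reported as inflated fractions.
* The δ estimator takes (r, λ) as known; errors in those propagate
  linearly into δ̂.
* Clone merging treats any shared key within 3 mm as one clone; two
  independent clones sharing a hotspot mutation within that radius would
  be merged.
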