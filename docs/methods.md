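# Methods

This note documents the models implemented in `mbsv`, the defaults and
their rationale, what the synthetic-data generators do and do not emulate,
and the numerical choices a maintainer should know about.

## The variant model

The derived Mb allele is modelled as a *cassette insertion*: an ordered
list of duplicated source segments (1-based inclusive reference
intervals), concatenated in forward orientation and inserted immediately
after a reference position. Each cassette adjacency is either a
microhomology join of `k` bases (a block assignable to both flanks,
written once) or an untemplated insertion; the adjacency after the last
segment is reference-like because, in the Mb architecture, the cassette
closes back onto the position it was inserted at (the tandem
configuration). Derived length therefore equals
`ref + Σ segment − Σ homology + Σ insertion`; with the printed GGA27
breakpoints (CNV1 1,702,269–1,721,521; CNV2 3,578,409–3,592,890; CNV3
4,470,331–4,503,417) and the 2-nt homology / 2-nt + 8-nt insertions the
gain is 66,830 bp. Inversions are out of scope and rejected explicitly:
all three duplications are in forward orientation, and silently
mis-assembling an inverted segment would be worse than refusing.

`enforce_junction_homology(..., exact=True)` additionally mutates the
single reference base on each side of every junction so that no exact
match can extend past the specified breakpoint by chance. This makes the
spec the *canonical* maximal-overlap description of its own junctions —
without it, a random reference occasionally extends a homology block by
one base and the detector (correctly) reports `k+1`. The coordinates a
split-read caller can report for a homology junction are only defined up
to this convention.

## Cross simulation

Founders are treated as fully inbred and fixed for alternative alleles
(a `marker_informativeness` knob dilutes this); all F2 derive from one
F1 × F1 pair. Meiosis uses the Haldane map function with no crossover
interference: between adjacent positions `d` cM apart a gamete switches
parental strand with probability `r = (1 − e^{−2d/100})/2`, independently
per interval. The causal position is simulated as a latent locus on the
same lattice, so phenotype assignment never depends on a genotyped marker.
Penetrance defaults to 1.0 — the trait is described as fully penetrant
dominant, with "incomplete dominance" referring only to phenotype
strength — and a `birth_covariate_rate` (default 0.8) generates the
trait-at-birth record used as the models' covariate: high enough to be a
meaningful covariate, below 1 so the week-10 trait retains independent
information.

`n_background_chromosomes` adds unlinked chip markers (fully informative,
same meiosis model). These matter for one quantitative reason: the
genomic kinship `G = ZZ′/m` gives each independent marker direction an
eigenvalue of order `n/m`, so if the focal chromosome contributes a large
share of `m`, the polygenic BLUP absorbs the causal signal and deflates
the scan (we measured p collapsing from 1e-42 to 1e-3 with a 20-marker
kinship). At the chip scale used for headline runs (27 × 1600 ≈ 43k
markers) the absorption is negligible, as it is on a real 60k chip.

## Association scan

A two-stage GRAMMAR-type approximation replaces per-marker REML: (1) fit
`y = Xβ + g + e` with `g ~ N(0, σg²K)` by maximum likelihood on the
eigendecomposition of K (scalar profile optimisation over δ = σe²/σg²);
(2) score-test every marker against the environmental residuals
`ê = σe²V⁻¹(y − Xβ̂)` with a χ²₁ statistic. The binary trait is analysed
on the linear 0/1 scale. Both choices are standard for chip-era F2 scans
and are approximations, not exact mixed-model tests; null calibration is
verified by simulation (KS uniformity and tail rates at α = 0.05/0.01).
Missing genotypes are mean-imputed for kinship and excluded pairwise in
tests. QC follows the stated thresholds with strict inequalities
(individual call rate > 0.9, SNP call rate > 0.9, MAF ≥ 0.05, ≤ 5%
Mendelian inconsistency per entity with single offending calls blanked,
W-linked markers dropped, heterozygous Z calls in females blanked).

## Line origin, linkage and shared IBD

Line origin is a 3-state HMM over {HH, HL, LL} with stationary prior
(¼, ½, ¼), transitions from two independent Haldane meioses, and a
symmetric genotyping-error emission (default 0.001). The published
analysis used a different (unspecified) algorithm; this is a behavioural,
not bit-exact, reimplementation. Forward–backward is implemented directly
because the transition matrix changes per marker interval. Posteriors are
linearly interpolated to a 1-cM grid and renormalised.

The linkage scan regresses the phenotype on the per-position additive
(`P(HH) − P(LL)`) and dominance (`P(HL)`) expectations plus the covariate
and reports the 2-df F statistic, dropping to 1 df with a logged notice
when the design is rank-deficient (e.g. no LL class). The genome-wide
threshold is the 95th percentile of max-F over phenotype permutations
(default 1000; phenotype and covariate rows permuted together to preserve
their relation).

Shared-IBD intersection assumes a single fully dominant locus: a position
qualifies iff every affected bird carries ≥ 1 line-H allele and every
unaffected bird carries none. Hard calls require posterior > 0.99;
positions below that are "unknown" for that bird and cannot veto — the
conservative direction, since uncertain data then never shrinks the
interval. The interval is snapped outward to the flanking positions and
reported with the boundary-defining recombinants (the birds whose
incompatible state just outside the interval stops it from extending).
An empty intersection (phenocopy, reduced penetrance) is a valid, logged
result.

## CNV scan

"Sliding" windows are implemented as a non-overlapping tiling (the
per-window MQ rule is only well defined on a tiling). The MQ filter flags
windows strictly below `mean − 3·SD` of window MQ; with window MQ
distributed around mean 60, SD 10 this reproduces the familiar MQ < 30
cutoff as a special case of the rule. Each pool is normalised by its own
genome-wide median depth before the log2 ratio — the normalisation itself
was not published, and median-of-windows is robust to the CNVs being
scanned for. Windows with zero depth in either pool are excluded rather
than mapped to ±∞. Segmentation thresholds (|log2FC| ≥ 0.58 ≈ log2 1.5,
≥ 3 windows, ≤ 1 bridged window) are artifact defaults exposed in the
call signature. Call edges use hysteresis: after a run is seeded at the
main threshold, edges extend through adjacent same-sign windows above
half of it, so one noisy boundary window does not truncate a call.

## Split-read detection and assembly

Reads are matched by a k-mer seed (k = `min_anchor`, default 20) at each
end and extended maximally; a read votes for a junction when both anchors
map but are discordant. Overlap of the two matched read regions is
microhomology; a gap is an untemplated insertion. Votes cluster within
±2 bp; consensus is by majority with ties toward the smaller coordinate;
clusters need ≥ 2 supporting reads (the wet-lab validation this replaces
has no read-support analogue, so the default is minimal).

Assembly enumerates all permutations of the gained segments (one extra
copy per CNV gain call) against the junction set and requires the walk to
close back onto the backbone at the insertion site. Cassette *rotations*
are genuinely indistinguishable from short-read junctions plus copy
counts — the three rotations of the Mb cassette imply identical adjacency
sets — so without an `insertion_locus_hint` the assembler raises an
ambiguity error listing all candidates; the fine-mapped trait interval is
what pins the insertion site in practice, exactly as in the original
analysis. When the hint coincides with a gained interval's end, the
in-place copy of that interval leads the reported walk (the tandem
context), giving CNV1 – CNV3 – CNV2 – CNV1.

Original-vs-duplicate resolution enumerates (variant on proximal/distal
copy) × (crossover entering proximal/distal copy) and keeps hypotheses
whose implied recombinant haplotype matches the evidence bird's phenotype
(carries the complete cassette or not) and copy-specific genotype. A
unique surviving variant placement labels the copies; zero survivors is
an evidence contradiction; uninformative evidence (homozygous reference)
leaves the model unresolved rather than guessing.

## Dosage genotyping

A diagnostic site inside the tandem interval exists in `2 + k` copies for
a bird with `k` Mb alleles, giving T:C copy counts 2:0, 2:1, 2:2 — "T
only", "T twice C", "equal peaks". Peak heights are rescaled to 100
effective pseudo-counts and each genotype class is tested by χ² goodness
of fit; survivors at p > 0.05 must be unique, else the call is
"ambiguous" (never forced — the junction PCR is the backstop). Classes
expecting zero copies of an allele use a noise-floor proportion of 0.03:
the floor must stay below the χ² critical value in pseudo-counts (3.84),
or a cleanly absent allele — observed height exactly 0 — would reject the
true class, while smaller floors reject ordinary baseline noise. In-silico
PCR uses exact primer matching (no mismatch/3′-end model) on the plus
strand with a reverse-complement partner within `max_product`.

## Expression triage

ΔCt is the mean target Ct minus the sample's mean reference-gene
(`GAPDH`) Ct; ΔΔCt subtracts the calibrator group's mean ΔCt; fold change
is `2^−ΔΔCt`. Adding a constant to all Ct values (a plate shift) cancels
exactly. Group comparisons are Welch t-tests on replicate-level ΔCt (the
published analysis states only star thresholds, which are applied as
printed: *** < 0.001, ** < 0.01, * < 0.05); no multiple-testing
correction is applied across genes/stages, matching the per-panel stars.
A gene is Mb-consistent iff the carrier/wild-type difference in facial
skin is significant at every assayed embryonic stage *and* in the adult,
and wild-type facial expression is below 5% of the carrier level — the
operationalisation of "barely detectable"; the floor is configurable
because the source description is qualitative.

## Synthetic data: what it does and does not emulate

The generators reproduce the *design* of each experiment: founder-line
fixation and F2 structure; dosage-proportional pyrosequencing peaks with
Gaussian noise truncated at zero; sextuplicate Ct wells with
`Ct = base − log2(rel)` plus noise; pooled window depth as negative
binomial read counts (Poisson at zero overdispersion, default
overdispersion 0.01) with mean `depth · window/read_len · CN/2`, and MQ
depressed inside declared low-mappability regions. They do not emulate:
base-quality error profiles, paired-end inserts, GC bias, real LD
structure (all founders fully informative), genotyping platform artefacts,
or multi-family pedigrees. Passing tests therefore demonstrate that the
algorithms recover planted truth under the stated noise models, not that
they are robust to every artefact of real chicken data.

Problem sizes in tests and the acceptance run are scaled for a single
CPU: the toy chromosome is 50 kb with breakpoints at 1:100 (windows 25 bp
with pool depths scaled ×40 so each window keeps the ~630-read counting
statistics of 95× over 1 kb), the association run uses the full 564 birds
with ~43k markers, permutation thresholds use 400–1000 permutations, and
calibration loops use 150–200 replicates.

## Numerical choices

- Coordinates are 1-based inclusive everywhere except on-disk bedGraph
  (0-based half-open), converted only at that boundary.
- All generators draw from `numpy.random.default_rng(seed)`; outputs are
  bit-reproducible given the seed.
- Variance-component optimisation is bounded scalar search over
  `log δ ∈ [−10, 10]`; degenerate fits raise rather than returning junk.
- The linkage F statistic is computed from residual sums of squares of
  nested least-squares fits; with a perfectly separating locus RSS₁ → 0
  and F is numerically huge — reported as computed, not capped.
- Junction cluster ties break toward the smaller coordinate, making
  detection deterministic for fixed input order.
- LD r² uses pairwise-complete genotype correlation; monomorphic markers
  raise instead of returning NaN silently.

## Known limitations

- The mixed-model scan is an approximation (GRAMMAR deflation is real,
  if small at chip scale); an exact per-marker REML option was out of
  scope by design.
- The assembler enumerates permutations, fine for ≤ ~6 cassette segments;
  the Mb case has 3.
- `resolve_copy_order` models a single crossover in a carrier × wild-type
  gamete; double crossovers and gene conversion are not in the hypothesis
  space.
- The expression classifier requires complete facial-skin coverage for
  the assayed stages and errors out otherwise rather than imputing.

## Shape of the package

The artifact is a library plus narrative examples rather than a CLI tool:
every stage is a pure function over in-memory containers (numpy arrays,
pandas frames, small dataclasses), which is how it composes in tests and
scripts; `examples/` plays the role a `mbsv ...` command line otherwise
would, and `mbsv.io` covers the interchange formats (FASTA/FASTQ via
Biopython, CSV/TSV, bedGraph, BEDPE/VCF for junctions, JSON for allele
models).
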