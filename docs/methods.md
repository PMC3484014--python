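# Methods

## The locus and its coordinate frame

The model region is a 70,000-bp wild-type sequence with position 0 at the
*MLPH*-proximal end and coordinates increasing toward *LRRFIP1*; all
internal coordinates are 0-based half-open, with GFF3 conversion at the
I/O boundary. Four genes sit in chromosomal order: *MLPH* (10 exons, plus
strand; exons 1–9 proximal of BP1, exon 10 beyond it — BP1 falls in
intron 9), *PRLH* (3 exons, minus strand, wholly inside the later-deleted
content), *RAB17* (4 exons, minus strand; exon 1 just distal of BP2, exons
2–4 inside the deleted content), and *LRRFIP1* (plus strand; exon 1 inside
the first inversion, the rest of the gene beyond BP6). Six breakpoints
BP1 < … < BP6 are named by wild-type order; novel junctions in the derived
allele are named R1–R4 by derived-allele order.

Only the qualitative containment facts above are externally constrained;
absolute gene spacings inside the deleted content are free parameters of
the generator, chosen once to satisfy the containments with comfortable
margins.

## Breakpoint coordinates from printed distances

Five distances pin the geometry: the 246-bp BP5–BP6 fragment, the 2.2-kb
BP4–BP5 segment, and the three event lengths — 30.9 kb (inversion
BP3–BP6), 16.4 kb (inversion BP2–BP4) and 16 kb (deletion BP1–BP5). Each
event length is interpreted as measured in the allele state in which the
event occurs, because the narrative describes events sequentially on the
evolving allele; the solver also supports an all-wild-type-frame reading
and reports which interpretation satisfies the set. Under the sequential
reading the five hard constraints determine the gaps uniquely:

    BP2−BP1 = 13,800   BP3−BP2 = 13,954   BP4−BP3 = 28,454
    BP5−BP4 =  2,200   BP6−BP5 =    246

Values printed to 0.1-kb precision carry a ±50-bp tolerance; two-
significant-figure distances (the 60-kb span, the 27.6-kb walk-up
distance, the 30-kb walk-down distance) are soft constraints at ±10% and
only contribute reported residuals (−1,346, +154 and +654 bp
respectively). The solver measures each constrained distance by forward
simulation, probes its affine dependence on the six positions, and solves
the resulting linear program (scipy HiGHS) minimizing precision-weighted
absolute residuals — hard residuals weighted 10⁴× over soft ones so a
precisely printed length is never traded against a rounded one — with
ties broken toward the smallest BP6. The integer solution is verified by
re-simulating every constraint; an unsatisfiable set produces an
infeasibility report naming a minimal conflicting subset (deletion
filter), not an exception.

## Segment paintings and event application

A derived allele is an ordered list of (wt_start, wt_end, orientation)
segments; "−" means reverse complement of the wild-type plus strand.
Paintings are kept canonical: empty segments dropped and
wild-type-contiguous equal-orientation neighbours merged, so every
internal boundary of a canonical painting is a novel junction. Events are
specified in current-allele coordinates and applied sequentially
(inversion: reverse order and flip orientations within the interval,
splitting boundary segments; deletion: remove the interval). Helpers
anchor event endpoints on named wild-type breakpoints through their
current-state boundary images, which is how the fixture's three events
are expressed.

Fate tracking annotates every atomic wild-type segment (the partition
induced by all event-endpoint images) with per-event hit flags and a
final status. On the fixture this yields the two discussed segments
directly: the unique thrice-hit segment is BP4–BP5 (2,200 bp, ultimately
deleted — inverted once, restored, then removed), and the BP5–BP6
fragment (246 bp) survives both inversions and lands immediately distal
of the deletion scar.

## Walk reads and their interpretation

Walk reads are interpreted by greedy maximal exact matching from the 5′
end against the wild-type sequence (both strands), with a 20-bp minimum
anchor and a 5-bp merge tolerance for wild-type-contiguous same-strand
blocks. Exact matching is appropriate because the generator emulates
clean Sanger-derived junction sequence: reads are error-free and every
20-mer of the region is unique across both strands (rejection-sampled),
so matches are unambiguous and junction-spanning 20-mers cannot occur in
the wild type.

Read placement mirrors the walking chemistry. The walk-down read is the
reverse complement of a derived-allele window spanning both proximal
junctions from the distal side; it decomposes into three blocks with the
246-bp translocated fragment in the middle. The walk-up read runs
forward across the deletion scar, but its interpretable sequence begins
only 12 bp proximal of the scar — the nested primer's 3′ end sits nearly
on the junction, a deliberate modelling choice — so the proximal stub is
below the anchor length and the read reports exactly two locations, the
second on the opposite strand, reproducing how the walk-up product was
described. A longer proximal anchor makes the same read report all three
blocks; both regimes are exercised in tests.

Consecutive matched blocks become strand-aware adjacency observations
with ±5-bp breakend uncertainty; duplicates (including the same junction
read from the other side) collapse with support counts, contradictory
strand assignments raise a conflict error, and breakends falling inside
screening windows are flagged as corroborated.

## Screening model

An amplicon is called present on an allele iff its two primers map intact
(not split by a junction, not deleted) to opposite strands facing each
other within 5 kb — the same in-silico PCR used for assay prediction, so
screening and assays share one physical model. Each maximal run of
mutant-absent amplicons yields one missing block and two windows:
[end of last flanking present amplicon, end of first absent amplicon) on
the proximal side and symmetrically on the distal side. These windows
provably contain the true breakpoints (an intact flanking footprint
bounds the breakpoint on one side; the failing footprint bounds it on the
other); defining the window up to the *start* of the first absent
amplicon would lose containment whenever the breakpoint falls inside that
amplicon's footprint. The default 16-amplicon panel (A–P, 400-bp
products) is placed breakpoint-aware — flanking amplicons within 1 kb of
BP1/BP2 — reproducing the published 4-present / 8-absent / 4-present
pattern with two 800-bp windows; an evenly spaced jittered mode exists
for randomized tests.

## Scenario enumeration

`enumerate_scenarios` searches breadth-first over ordered event
sequences, deduplicating states by canonical painting and recording all
parents so that *all* minimal-length scenarios (as distinct painting
trajectories) are returned. Candidate event endpoints in each state are
the images of the wild-type cut coordinates bounding the target's
segments: any minimal scenario's cuts either surface as target junction
flanks or are consumed by a later deletion bounded by such flanks, so the
restriction preserves completeness at minimal depth while keeping the
branching factor small. No heuristic pruning is applied beyond two exact
ones (a deletion may not undershoot the target length; the last move must
reconcile the length). On the fixture the depth-2 search is exhaustive
and empty and the depth-3 search returns two trajectories, one of them
the simulated (published) scenario; the other is an equally parsimonious
alternative with a 28-kb second inversion — junction data alone cannot
distinguish them, which is precisely what the parsimony framing predicts.

## Assay prediction

All predictions are structural. A primer binds iff its wild-type
footprint lies unbroken inside one painting segment; products require
opposite-strand inward-facing images within 5 kb (default), with size
measured between outermost primer ends on the derived allele. The
genotyping fixture places Gen_F 223 bp proximal of BP1, Gen_wt_R inside
the deleted content (423-bp wild-type product) and Gen_lav_R inside the
inverted content so the 630-bp lavender product spans the deletion scar;
band patterns map to genotypes with a ±20-bp size tolerance. RT-PCR for
an exon pair amplifies iff both exons sit fully inside one common
segment — no splicing or expression-level model, so the prediction speaks
to transcript *structure* only. Gene consequences: deleted (no exon base
retained), truncated (some exons fully retained, others lost), rearranged
(all exons retained but the gene span plus a 200-bp promoter flank no
longer sits in one co-oriented run), else intact.

## Phenotype generator and statistics

The generator encodes the published cohort conditions: 59 lavender and 66
wild-type birds from 21 single-pair families (growth cohort), of which 51
and 41 from 18 families complete the 3-week feed trial; sexes alternate
within genotype. Per-bird growth parameters are drawn around the genotype
means (lavender A = 204.4 g, B = 221.4 g, k = 0.0405 d⁻¹; wild-type
215.9, 233.0, 0.0401) with the printed SDs, decomposed into a
once-per-family mean shift carrying 30% of each SD and an individual
residual carrying the rest, so marginal SDs match the printed ones.
Weekly weights (days 7–63) follow each bird's own curve with 3-g
measurement noise.

Feed intake is built from the printed sex-specific regressions
(females FI = 23.3 + 1.50·BWG + 6.56·MBW + 1.075·EM; males
FI = 255.2 + 3.35·BWG + 2.91·MBW) plus a genotype shift on the residual
(42 g between groups, centered to the published group means of roughly
+19 vs −23 g) and Gaussian noise calibrated so the regression R² matches
the printed 0.57/0.72 given the generated covariate spread. MBW is body
weight in grams to the 0.75 power (exponent configurable): in those units
the printed coefficients reproduce the observed feed-intake scale
(6.56 × 177^0.75 ≈ 315 g of a ~550-g 3-week intake), whereas kilogram
units would make the covariate numerically irrelevant and statistically
unidentifiable. Body temperature carries the −0.14 °C lavender shift
within the printed 0.28 °C SD and couples weakly (0.002 °C/g) to body
weight to exercise the ANCOVA path; 6-month body composition traits are
generated analogously from the printed means.

Growth curves are fitted by multi-start `scipy.optimize.least_squares`
(four starts spanning plausible asymptote/rate ranges, positive-parameter
bounds, relative tolerance 1e-8); degenerate inputs (flat weights, B at
the zero boundary) return an explicit failure report carrying the best
candidate rather than a silent estimate. RFI is the OLS residual of FI on
the sex-specific covariates (statsmodels), zero-mean and
covariate-orthogonal by construction. Full-vs-reduced comparisons fit
ordinary least squares with treatment-coded factors; because the
sums-of-squares convention is otherwise ambiguous in unbalanced designs,
the genotype test is always the nested-model F (full vs reduced), which
is invariant to that choice; significance codes are *, **, *** at
0.05/0.01/0.001 and NS otherwise.

## What the synthetic data do and do not show

The generator emulates the *structure* of the study — geometry, evidence
channels, assay designs, cohort layout and effect sizes — not its
biology. Sequence content is uniform random with unique 20-mers, so
matching is unambiguous by construction; real breakpoint neighbourhoods
carried no repeats either, but genomic sequence is not uniform. Reads are
error-free; there is no primer thermodynamics, no base-calling error, no
expression or splicing model, and family effects are simple Gaussian mean
shifts rather than pedigree genetics. Passing tests therefore demonstrate
that the inference machinery is correct on data satisfying its stated
assumptions — they do not re-derive the real birds' table values, the
prolactin assay results, or the 6/19/23 genotype counts of the
informative cross, which depend on the actual animals and are replaced
here by seeded parameter-recovery checks (cohort means within 2 SE;
regression coefficients within a Monte-Carlo-derived 3-SE joint band).

## Numerical choices and problem sizes

Defaults: min_anchor 20 bp, merge_tol 5 bp, max product 5 kb, size
tolerance 20 bp, ±50 bp on 0.1-kb-precision lengths, ±10% on
two-significant-figure lengths, BFS depth cap 5. The test suite runs the
full pipeline on the 70-kb fixture, 200 randomized
simulate-then-reconstruct trials on 3–8-kb regions, and the phenotype
cohort at the published n; the whole suite completes in well under a
minute on one CPU, and the acceptance script in a few seconds.

## Known limitations

Scenario enumeration targets the minimal-event regime (≤5 events) of a
single contiguous locus; it is not a general sorting-by-reversals engine
and does not weight scenarios probabilistically or adjudicate single-
meiosis versus sequential origin — the data cannot. The coordinate
solver linearizes around a feasible shape and iterates; wildly different
constraint geometries than the fixture's could require better
initialization. The walk-up two-location behaviour is a documented
consequence of read-endpoint placement, not an intrinsic property of the
allele; reads with longer proximal anchors correctly report three
locations.
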