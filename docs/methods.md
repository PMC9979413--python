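# Methods

This note documents the models, rules, numerical choices, and limitations of
`strainsift` in one place. The README gives the overview; this is the
reference for anyone auditing or extending the package.

## Input model

The pipeline consumes per-(sample, genome) **allele-count profiles**: for
every covered position of a dereplicated reference genome, the number of
reads supporting each of A, C, G, T. This is the information a
read-mapping-based strain profiler produces after alignment; read mapping,
assembly, binning and genome dereplication are upstream of this package and
out of scope. Positions are 0-based; plate rows/columns are 0-based integers
internally, with input label declarations (default rows A–H, columns 1–12)
mapping arbitrary row/column labelling schemes onto indices, since published
plate maps do not follow a single convention.

Samples carry subject and family identity (subjects in one family — twins,
mother–infant pairs — are biologically related and expected to share
strains), a role (biological, reagent-only negative control, mock-community
positive control), DNA yield in ng/µL as the biomass proxy (missing means
*unknown*, never zero, and excludes the sample from biomass tests), a
sequencing pool id, and zero or more wells. Zero wells (single-tube
extraction) excludes a sample from all plate-geometry analyses but not from
strain comparison. Multiple wells represent duplicate extractions merged into
one library; plate analyses use every contributing well and pair distances
take the minimum over well combinations, since transfer can act at any of
them.

## Detection and strain comparison

A genome is **present** in a sample when breadth ≥ 0.5 (inclusive): at least
half its positions carry ≥ 1 read. Comparisons are computed only for
unrelated pairs in which the genome is present in both samples.

At each position covered ≥ `min_cov` (default 5×) in both samples, an allele
is **detected** when its count ≥ 2 and its frequency ≥ 5 % (both
configurable); the consensus allele (highest count, ties broken by the fixed
order A<C<G<T) is always included. Upstream profilers do not expose a single
canonical allele-calling rule, so these two thresholds are documented package
choices: two supporting reads suppress single-read sequencing noise while a
true 20 % minor allele at 10× still has expected count 2.

- a **consensus substitution** is a position where consensus alleles differ;
- a **population substitution** is a position where the detected-allele sets
  are disjoint.

conANI and popANI are 1 minus the respective substitution count over
compared positions; population substitutions are a subset of consensus
substitutions, so popANI ≥ conANI always. `percent_genome_compared` divides
compared positions by the full genome length (not the covered union), which
keeps the ≥ 0.5 requirement interpretable as "half the genome was
comparable". With zero comparable positions both ANI values are null and the
pair is recorded as `insufficient_overlap` — low-overlap pairs are always
excluded from the network but never dropped from the comparison table, and
results within 0.005 % popANI or 0.2 % pgc of their cutoffs carry an
`edge_case` flag reproducing a manual-review band.

Two sharing thresholds are in common use — 99.999 % for deeply sequenced
gut communities, 99.995 % for noisier, lower-biomass data — and the
threshold is a per-run configuration value (default 0.99999).

**A caveat that shapes the classifier.** popANI is deliberately insensitive
to shared minor alleles, which makes strain *mixtures* promiscuous: a sample
carrying strains X+Y matches, at popANI = 1, any sample whose detected
alleles intersect at every position — including other two-strain mixtures
with no haplotype in common, because the reference allele is typically
detected in both. Contaminated samples are exactly such mixtures, so popANI
links between two contaminated samples on different plates are expected
artifacts, not shared strains. conANI breaks the symmetry: consensus-level
identity (conANI above the sharing threshold) demonstrates that the same
haplotype dominates both samples. The classifier uses this distinction
wherever transitivity matters (below).

## Sharing network and strain clusters

Samples are **unrelated** when they come from different families, or when
either is a negative control; positive-control pairs are related by default
(the mock community is not a subject) unless configured otherwise. Edges
connect unrelated pairs with ≥ 1 shared verdict. Because popANI sharing is
not transitive, "one strain across many samples" is modelled conservatively
as a connected component of the per-genome sharing graph; each component
becomes a `StrainScope` with carrier, subject, family, plate, pool, and
negative-control rollups. `subject_fraction` divides carriers' subjects by
the study's biological subjects; controls never enter the denominator.

## Plate proximity statistics

Per plate, the within-plate Euclidean distances (grid units) of unrelated
sharing pairs are compared against non-sharing pairs with a Wilcoxon
rank-sum test: midranks over the pooled distances,
z = (W − n₁(N+1)/2)/√(n₁n₂(N+1)/12) with no tie correction. The normal
approximation applies a 0.5 continuity correction to the p-value by default
(the reported statistic stays the uncorrected z): without it the gap to the
exact permutation p reaches 0.034 at group sizes of ten, with it ≤ 0.01.
`use_continuity=False` reproduces the uncorrected convention of the widely
used SciPy routine. A permutation mode recomputes p by exhaustive
enumeration when C(N, n₁) ≤ 10⁵ (forceable with `exact=True`) and by seeded
Monte-Carlo otherwise; with all values tied, z = 0 and two-sided p = 1 by
construction. Grid distances produce ties, but at plate scale the tie
correction would change the variance by < 0.1 %, and the permutation mode is
the reference whenever that matters.

The default alternative is two-sided; the directional hypothesis (sharing
pairs are *closer*) is available as `alternative="less"`. Plates with an
empty group are reported untestable with no p-value. Per-plate p-values are
reported raw; no multiplicity adjustment is applied by default.

## Classification rules

Precedence is total and deterministic: external > well_to_well >
cross_plate_leakage > residual_sharing. "Majority of subjects" is
operationalized as subject_fraction ≥ 0.5 and "adjacent" as Euclidean
distance ≤ 1.5 (the 8-neighbourhood); both configurable.

**external** (strain level): the cluster spans ≥ 2 plates and either covers
a majority of subjects or appears in negative controls of ≥ 2 plates.
Reagent or handler DNA enters wells independently of plate geometry, so
plate spread plus subject majority is its signature.

**well_to_well** (sample level): for each genome a sample shares, every
family with ≥ 2 carrier samples among its partners is a candidate source.
A candidate supports the flag when

- *exclusivity* — everyone sharing that genome with the candidate family,
  anywhere in the study, spans ≤ 1 other biological family besides the
  flagged sample ("otherwise unique to them"),
- *confinement* — the candidate's carriers and all their sharers sit on one
  plate,
- *direction* — no other sample of the flagged sample's family shares with
  the candidate (negative controls pass trivially). Transfer is directional:
  the source family carries its strain longitudinally, the recipient is its
  family's lone sharer. Without this gate every source sample would be
  flagged alongside its recipient.

One supporting strain suffices by default. Adjacency to a sharing partner
plus a significant plate proximity test can substitute for exclusivity;
adjacency plus confinement without either corroboration yields `ambiguous`.
The candidate-family formulation (rather than cluster membership) makes the
rule robust to the mixture-promiscuity artifact: spurious popANI links
attach to the contaminated mixtures, not to the source family, so the
source's spread stays clean.

**cross_plate_leakage** (strain level): the putative leaking library is the
family of the cluster's deepest carrier. Its direct partners split by
conANI: consensus-identical partners hold pure leaked material and must sit
at ≤ 20 % of the donor depth (`leakage_depth_ratio`) — one
consensus-identical partner at comparable depth is a genuine co-carrier and
vetoes the call — while popANI-only partners carry the leaked strain as a
minor component under their own strain, so their total depth is
uninformative. The donor family plus recipients must lie in one sequencing
pool, reach a plate the donors are not on, and show no spatial clustering.
A leak whose recipients all land on the donor's own plate is observationally
identical to well-to-well transfer and is flagged as such; only cross-plate
reach can separate the mechanisms.

**residual_sharing** (strain level): ≥ 2 plates, ≥ 2 subjects, below the
external fraction, no spatial clustering, and — decisively — at least one
*consensus-level* edge between carriers on different plates, so that chains
of contaminated mixtures cannot masquerade as a circulating strain. Such
clusters are reported as plausibly biological (e.g. hospital-acquired in
cohorts born at one hospital) rather than as contamination.

"Spatial clustering" for the strain-level rules uses the strain's own
carriers (more than half of its within-plate unrelated carrier pairs within
the adjacency radius) rather than the plate-level test, so one contaminated
plate does not veto calls for unrelated strains on the same plate.

Mock-community (Zymo) genomes are a declared genome subset; biological
samples detected with them are listed in a dedicated report section with a
note whether they also share the spiked samples' other organisms
(bulk transfer) or only the mock strains (aerosol / mis-pipetting).
Negative-control detections that share with no one (singleton NC organisms)
are reported uncategorized — the rules cannot resolve them and say so.

Each call carries named evidence items; the score is the fraction of
applicable evidence channels satisfied and orders the report — it is never
thresholded.

## Synthetic study generator

The generator emulates the study design the analysis assumes: by default 20
subjects (one twin family sharing its strain set), three longitudinal gut
samples each, two 8×12 plates loaded column-sequentially so one subject's
samples sit in consecutive wells, one reagent-only negative control per
plate placed after the biological samples, and two plates per sequencing
pool. Six species; each family carries a species with probability 0.7 and
receives a private strain (twins share); strains of one species differ at an
expected 0.5 % of positions (each strain mutates a random reference at
Binomial(L, divergence/2) private sites). Genomes default to 10 kb — three
orders below real bacterial genomes — because every decision operates on
fractions (breadth, pgc, popANI), so scale changes statistical resolution,
not logic; the popANI threshold at 10 kb tolerates zero disjoint positions,
which is the regime the sharing decision lives in anyway.

Biomass is lognormal per sample type (gut median 20 ng/µL, oral 5, skin 2;
σ = 0.6 on the log scale), and mean sequencing depth is 2.5× per ng/µL
(50× at 20 ng/µL). Rendering draws per-position depth Poisson per mixture
component and scatters a 0.1 % sequencing error uniformly over the other
three bases. A zero-biomass sample renders empty, mirroring re-extraction of
a contaminated low-biomass sample. Determinism: one seed; per-sample render
streams derive from CRC32 of the sample id, so adding a sample never
perturbs the others; placement and strain assignment are independent of the
event list, so events can be planned against the layout.

Planted events:

- **well_to_well(source, target, f)** adds the source's endogenous
  components to the target at fraction f of the source's depth. Chained
  transfer (contamination of a contaminant) is not modelled.
- **external_reagent(rate, depth)** creates a reagent genome and includes it
  in each sample with probability min(1, rate·h/b) — h the harmonic mean
  biomass, so the mean inclusion is ≈ rate and inclusion is ∝ 1/biomass —
  at a fixed depth (default 20×) independent of the recipient, which is the
  mechanism behind low-biomass enrichment of reagent contaminants.
- **index_switch(pool, rate, affected_fraction, donor)** leaks the pool's
  dominant library: each affected sample receives the donor genome at
  rate × (total donor depth). Detectable leakage at per-read rates requires
  a dominant library (at 0.5 % of a 2400× library, recipients get ~12×);
  ordinary-depth libraries leak below the detection floor and are not
  modelled. `affected_fraction` (default 0.1) models the per-library
  heterogeneity of misassignment; blanket leakage into every well would be
  observationally identical to external contamination under these rules.
  The donor family itself cannot observably receive its own strain.
- **zymo_spill(pc, target, fraction)** copies a positive control's mock
  genomes into a neighbouring well.

Truth labels record every event and its realized recipients.

For proximity-test calibration a dedicated null-plate generator places
samples at random wells and assigns sharing labels to a uniformly random
subset of pairs, independent of geometry. This isolates the test's
calibration from the rendering model and keeps a 1000-replicate null run
under seconds; the full generator is used wherever the planted mechanisms
matter.

## Problem sizes used in validation

The shipped validation (tests and `scripts/acceptance.py`) uses: 200
randomized profile pairs for oracle agreement; 40 draws at group sizes 10/10
for normal-vs-exact rank-sum accuracy; 1000 null plates for calibration;
20 studies (2 plates, 20 subjects × 3 samples, 4 planted transfers with
f ∈ [0.2, 0.4] between wells at ≥ 20× own coverage) for recovery and
false-flag rates; 20 three-plate studies with one event of each mechanism
for category discrimination; 5 regenerated studies for the re-extraction
analog; 50 studies for the biomass mechanism. These sizes were chosen to
keep the full validation in the minutes range on a single core while leaving
the binomial noise of each rate well inside its acceptance margin.

## Known limitations

- popANI mixture promiscuity (above) is handled by rule design, not removed;
  a dedicated mixture-deconvolution step is out of scope.
- A read-misassignment leak confined to the donor's plate is flagged as
  well-to-well: the mechanisms are observationally equivalent without
  cross-plate evidence, and the planted-event discrimination check budgets
  for such realizations.
- The generator does not simulate reads, assembly, taxonomic composition
  beyond a flat species pool, or realistic abundance distributions; passing
  tests demonstrate the *logic* of detection and classification under the
  stated statistical structure, not performance on any particular real
  dataset, where reference quality, mapping artifacts and uneven coverage
  add noise these simulations do not contain.
- Expert-judgment calls (e.g. attributing a non-adjacent sharer to a source
  family already implicated by adjacent wells) are not reproduced; such
  cases surface as `ambiguous` with their evidence attached.
- The pipeline flags and explains; it never corrects counts or removes
  reads.
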