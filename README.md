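# strainsift

Strain-resolved contamination detection for plate-extracted metagenomics
studies.

## The problem

DNA contamination corrupts microbiome studies in two distinct ways. External
contamination — reagent, kit, or handler DNA — has been widely studied and is
caught by negative controls. Contamination that originates *within* a study
is harder: DNA spilling between wells of a 96-well extraction plate, or reads
misassigned between pooled libraries at sequencing (index switching / sample
bleeding), introduces organisms that genuinely belong to the study, so no
"contaminant species" list can remove them. Left undetected, well-to-well
transfer inflates apparent strain sharing between unrelated subjects and can
fabricate biological conclusions.

Nearly identical strains essentially never occur in unrelated subjects by
chance, so *unexpected strain identity is the contamination signal*.
`strainsift` takes per-sample allele-count profiles over a dereplicated
reference genome set (the output of a strain profiler such as inStrain),
finds strains shared between unrelated samples, maps that sharing onto the
DNA extraction plates, and classifies each suspicious strain or sample by
mechanism. It is aimed at anyone running plate-extracted clinical or
environmental metagenomics who wants a contamination audit before analysis.

## Model and statistics

**Detection.** A genome is present in a sample when its *breadth* — the
fraction of positions covered by ≥ 1 read — is at least 0.5.

**Strain identity.** For samples *a*, *b* and genome *g*, over positions
covered ≥ 5× in both samples:

- conANI = 1 − (consensus substitutions) / (compared positions), counting a
  substitution wherever the majority alleles differ;
- popANI = 1 − (population substitutions) / (compared positions), counting a
  substitution only where the samples' detected-allele sets are *disjoint*,
  so shared minor alleles prevent a substitution.

Samples share a strain when popANI ≥ 0.99999 (configurable; 0.99995 for
noisier data) and ≥ 50 % of the genome was comparable
(`percent_genome_compared` ≥ 0.5). Results within 0.005 % popANI or 0.2 %
pgc of their cutoffs are decided by the rule but flagged for review.

**Sharing network.** Edges connect *unrelated* pairs — different families,
or any pair with a negative control — that share ≥ 1 strain. Per genome,
connected components define strain clusters with carrier/plate/pool rollups.

**Plate proximity.** Well-to-well transfer predominantly hits neighbouring
wells, so on a contaminated plate, sharing pairs sit closer than non-sharing
pairs. Per plate, within-plate Euclidean distances of sharing vs non-sharing
unrelated pairs are compared with a Wilcoxon rank-sum test
(z = (W − n₁(N+1)/2) / √(n₁n₂(N+1)/12), continuity-corrected normal p by
default, exact/Monte-Carlo permutation mode as reference).

**Classification**, with precedence external > well_to_well >
cross_plate_leakage > residual_sharing:

- *external*: one strain cluster on ≥ 2 plates covering a majority of
  subjects (or negative controls of ≥ 2 plates) — reagent/kit/handler DNA;
- *well_to_well*: a sample whose shared strains are otherwise unique to one
  other family, confined to a single plate, with the sample its family's
  sole carrier while the source family carries the strain in several
  samples; plate adjacency and a significant proximity test corroborate;
- *cross_plate_leakage*: a cluster spanning plates of one sequencing pool,
  dominated by a single family's deep library with every consensus-identical
  recipient at ≤ 20 % of its depth — index switching / sample bleeding;
- *residual_sharing*: cross-plate, multi-subject, consensus-level sharing
  without spatial structure — plausibly a circulating (e.g.
  hospital-acquired) strain, left for biological interpretation.

Low biomass (DNA yield as proxy) makes samples vulnerable; the report tests
flagged-vs-unflagged biomass with the same rank-sum machinery.

A fully seeded synthetic study generator (subject-specific strains,
column-sequential plate loading, biomass-dependent coverage, planted events
of each mechanism with truth labels) makes every stage testable without any
sequencing data.

## Worked example

Simulate a small two-plate study with one planted well-to-well transfer and
audit it:

```sh
cat > sim.yaml <<EOF
n_subjects: 8
samples_per_subject: 2
n_species: 4
genome_length: 4000
n_events: 1
EOF
strainsift simulate --seed 42 --out study --scenario well-to-well --sim-config sim.yaml
strainsift run --study study --out results
strainsift report --report-json results/report.json
```

prints

```
Contamination report
====================
samples: 18  genomes: 4  subjects: 8

Per-plate proximity tests (distance vs strain sharing):
  P1: z=-1.829 p=0.0744 (2 sharing vs 26 non-sharing pairs)
  P2: untestable

Negative controls:
  NC1: 0 genomes detected, 0 shared strain(s)
  NC2: 0 genomes detected, 0 shared strain(s)

Calls:
  [well_to_well] sample S03_T2 (score 0.75)
      - adjacency: shares strains with 1 unrelated sample(s) within 1.5 grid units
      - source_exclusivity: 2 shared strain(s) otherwise unique to source family/families F03
      - plate_confinement: supporting strains have no cross-plate carriers

Suggested exclusions: S03_T2
```

The generator's truth file (`study/truth.json`) confirms the planted event:
0.27 of sample S04_T1 (family F03) spilled into the adjacent well of S03_T2,
which is exactly the sample the pipeline flags — it shares two strains found
nowhere outside family F03, on one plate, next to the source. The proximity
test is underpowered on a plate this small (two sharing pairs), which is why
the evidence-based channels, not the plate-level p-value, carry the call.
`results/` also holds the machine-readable `report.json`, per-stage TSVs
(`detections.tsv`, `comparisons.tsv`, `edges.tsv`, `proximity.tsv`,
`calls.tsv`), a GraphML export of the sharing network, and `exclusions.txt`.

The same stages are available as a library (`strainsift.simulate_study`,
`strainsift.run_pipeline`, ...) and as individual subcommands
(`detect`, `compare`, `network`, `plate-test`, `classify`).

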