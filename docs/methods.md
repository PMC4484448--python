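# Methods

## The measurement model

Spectral counting treats the number of significant MS/MS spectra assigned
to a protein as a proxy for its abundance in the sample. For a two-sample
comparison the package uses the ratio of normalized spectral counts,

    RSc = (s_B + c)(T_A − s_A + c) / ((s_A + c)(T_B − s_B + c)),

with `s` the protein's significant-spectra count, `T` the total
significant spectra of the sample, and `c = 1.25` a pseudo-count
correction. The normalization by `T − s + c` makes the statistic a ratio
of within-sample odds rather than raw counts, so unequal sequencing depth
between the samples cancels to first order. When the raw ratio is below 1
the negative inverse is reported, giving a symmetric signed scale whose
magnitude is always ≥ 1 (+k and −k mean k-fold up and down in the test
sample). The pseudo-count keeps the statistic finite at `s = 0`, which is
what makes fold values quotable for proteins detected in only one
secretome; orientation is explicit (sample B is the test) because the
formula itself is direction-asymmetric.

No per-protein significance test is attached to RSc: with one run per
sample there is no replication to estimate within-condition variance, so
the analysis is cutoff-based, exactly as spectral-counting secretome
studies practice it.

## Identification rules

* A PSM is significant iff `score > identity_threshold`, strictly; each
  spectrum carries its own threshold.
* A protein is reported iff it has ≥ 2 distinct peptide sequences among
  its significant PSMs. Sequences are compared case-insensitively after
  stripping bracketed modification annotations (`M(Oxidation)…`,
  `M[+16]…`), so modified forms do not inflate the unique count. A peptide
  matching several accessions counts toward each; razor/parsimony
  assignment is deliberately out of scope.
* FDR is estimated at the protein level as decoys/targets over the
  accepted groups (`2D/(T+D)` available via `mode="combined"`). The
  decoy/target estimator is the simplest reading of a separate decoy
  search with per-hit decoy flags; whether the original criterion was
  computed at PSM or protein level is unknowable from the study text, so
  both the level (protein) and the estimator are explicit configuration.

## Partitioning and tiers

Proteins detected in exactly one sample are `unique_A`/`unique_B`; common
proteins are called higher/lower in B at an *inclusive* signed-RSc cutoff
(default 2, "at least two-fold") and unchanged otherwise; a strict
high tier (default > 15) marks extreme responders. The summary also
reports `unique_B + common_higher_B`, the "at least fold-cutoff increase
in the test secretome" set — the 228-analogue in the canonical 894-protein
catalogue arithmetic (179 unique + 49 common-higher). The sample totals
`T` are computed after the identification filters, over retained target
proteins only (configurable in principle; decoys never enter totals).

## Enrichment

Categories (GMT vocabularies) are intersected with the detected-protein
background before testing; the background is the union of proteins
detected in either sample, not a whole-proteome universe, and unannotated
proteins stay in `N` where they dilute `K/N`. Fold enrichment is
`(k/n)/(K/N)`. The tail is one-sided hypergeometric — `P[X ≥ k]` when the
query frequency is at or above the background frequency (enriched),
`P[X ≤ k]` otherwise (depleted), both including the observed point — with
Benjamini–Hochberg correction across the vocabulary. Choosing the
direction from the observed fold makes the per-category p-value adaptive;
the discreteness of the hypergeometric keeps the procedure conservative in
practice, which the null-calibration test measures directly (≈0.2% of
categories reach q < 0.05 under uniform null queries, against the 5%
bound). Ties in the output ordering break by descending fold, then
category name, so results are reproducible to the byte.

## Network modules

Interaction edges are undirected, deduplicated, self-loop-free, and
restricted to the detected background. Modules are connected components;
components above `split_threshold` (default 50) nodes are partitioned by
greedy modularity maximization, and each resulting community is peeled to
its 2-core. The peel exists because modularity communities in sparse
interaction graphs accrete tree-like satellites around a dense core:
iteratively removing degree-<2 nodes strips those satellites while leaving
any cyclic core (including triangles) intact, which is what raises planted
20-member-module recovery from Jaccard ≈ 0.6 to ≥ 0.83 across seeds.
Greedy modularity was chosen over Markov clustering for determinism and
availability; edges are re-inserted in sorted order so community detection
is stable under input reordering. Each module is then scored by the
enrichment machinery against the "abundant" set — by default the proteins
unique to, or ≥ 2-fold higher in, the test sample.

## The simulator

The generator emulates the study design the analysis assumes, not mass
spectra: per sample, a fixed budget of significant-quality spectra
(default 2000) is allocated multinomially over proteins with probability
proportional to abundance (log-normal, σ = 1) times the planted fold in
the up-regulated sample. Spectral detectability is abundance-only — no
peptide-length weighting — because the RSc statistic consumes raw
significant-spectra counts, not length-normalized indices. Defaults:
900 proteins (the scale of the two-cell-line catalogue), 30% differential
with folds uniform on [2, 30] and random sign, a 20-member module forced
up-in-B with folds on [8, 30] (the cathepsin-like co-regulated tier) and
one shared annotation category, plus a dense internal wiring of exactly
⌈0.6 · m(m−1)/2⌉ planted edges on an Erdős–Rényi background of mean
degree 2. Planting the module's internal edge count exactly (rather than
Bernoulli-per-pair) makes the fixture's edge-count guarantee
deterministic.

Contamination: 10% of proteins are flagged intracellular, annotated
"DNA binding"/"RNA binding", never differential, and receive spectra only
through a leakage channel sized per sample (defaults 8.5% and 7.8% of
depth, mirroring the slight differential cell death of the two cultures);
this reproduces the depletion of nucleic-acid-binding categories in the
test-sample-enriched sets. Decoy PSMs (5% of depth by default) are spread
uniformly over a decoy accession pool with scores `threshold + N(shift,
3²)`, `shift = −4` by default — mostly insignificant, a few surviving, so
the realized protein-level FDR is small but nonzero and tunable via the
shift. Eight percent of proteins carry exactly one peptide to exercise the
two-unique-peptide filter. Scores for targets are `threshold + N(8, 4²)`
(≈98% significant); thresholds jitter by N(0, 2²) around 40, Mascot-like.
All stages derive child RNG streams from the single config seed, so a
(config, seed) pair yields byte-identical fixture bundles.

What the simulator does **not** model: peptide physicochemistry (ionization
efficiency, missed cleavages, retention time), shared peptides between
target proteins, protein-length effects, inter-run variability/replicates,
and correlated annotation structure beyond the planted module. Passing
tests therefore demonstrate that the statistical machinery recovers planted
structure under the stated sampling model — not that the pipeline is robust
to every bias of real LC-MS/MS data.

## Calibration studies and problem sizes

* **FDR calibration** uses a larger bundle (2000 proteins, 40000
  spectra/sample, decoy fraction 0.1, decoy shift −6.4) chosen so decoy
  proteins surviving identification average ~0.5% of accepted proteins —
  half the 1% criterion. The size matters: the surviving-decoy count is
  approximately Poisson, so at ~900 accepted targets a true 0.5% rate
  leaves the sub-1% check a near coin flip per replicate, while at ~1700
  targets it concentrates (mean ≈ 9 against a threshold of ≈ 17). The
  observed pass rate is 100/100 replicates.
* **Recovery** is scored over planted |fold| ≥ 4 proteins that are
  *detected* (present in the identified union): proteins that fall below
  the detection/inference floor — including the planted single-peptide
  proteins, which the two-unique-peptide rule removes by design — receive
  no partition at all. Correctness means direction-consistent partition
  (`unique_B` or `common_higher_B` for up-in-B, mirrored for down).
  At the default depth ≈ 74% of such proteins are detected and ≈ 98% of
  those are direction-correct.
* **Module ranking** calls a replicate successful when the extracted module
  with the best Jaccard overlap to the planted membership is also the
  top-ranked module by enrichment p-value.

## Numerical choices and degenerate inputs

RSc is computed in floating point (the formula is a product of four small
terms; agreement with exact rational arithmetic is verified to 1e-9
relative over 10⁴ random tuples). `s > T`, zero sample totals, `c ≤ 0`,
empty queries, queries outside the background, infeasible hypergeometric
overlaps, zero target proteins for FDR, and `min_size < 2` for modules all
raise `ValueError` rather than returning sentinels. Empty PSM input yields
empty output at every stage that permits it. Output tables are written
with fixed formats (RSc 4 decimals, p/q scientific with 6 significant
digits) for diffability.

## Known limitations

Single-run-per-condition design (no variance model for RSc); no protein
grouping/parsimony; the enrichment engine is a generic
hypergeometric+BH replacement for tool-specific category databases, so
specific published fold values tied to proprietary annotation versions are
out of reach by construction; greedy-modularity-plus-2-core is one of many
defensible module definitions and is exposed as configuration rather than
claimed optimal.
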