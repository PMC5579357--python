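# Methods

This note documents the models and procedures implemented in `phyloprof`,
the parameters that matter, the numerical choices made where the design was
open, and what the synthetic-data generator does and does not emulate.

## Phylogenetic profiles

A profile is defined against an ordered catalog of 4-letter species codes
(first letter of the genus + first three of the species epithet); a sequence
id is that code plus six digits, and the code is the only join key between
sequences and species.  `copy_number[i]` counts a species' members of the
orthogroup; presence is its support, so the two vectors can never disagree.
Codes are matched case-sensitively (lowercasing could merge distinct
species), catalog construction rejects duplicate codes, and unknown codes in
an orthogroup are an error by default (a lenient mode skips them with a
logged warning, for exploratory use on messy data).  Profile matrices are
TSV (rows = proteins, columns = catalog codes, values = copy numbers) with
an optional companion 0/1 view; write→read is an exact round trip.

## Co-evolution scoring

Profile similarity is the Pearson correlation *r* of the 0/1 vectors, which
equals the phi coefficient of the 2×2 co-occurrence table.  *r* is undefined
for constant profiles (all-present or all-absent); these are assigned r = 0
and flagged, which keeps the correlation matrix complete for clustering
while excluding the uninformative rows from threshold calibration.

Threshold calibration sweeps the distinct observed *r* values in ascending
order; at candidate *t* the enrichment is the precision of the pair set
{r ≥ t} against a user-supplied reference of established interactors,
divided by the reference's base rate among all informative pairs.  The
returned threshold is the smallest candidate reaching the requested fold
(default 6×); if none does, a sentinel (−1) is returned together with the
full sweep for audit.  The sweep is inclusive (r ≥ t) and restricted to
observed values, so the threshold is always attained by at least one pair,
and raising the fold can only raise (or sentinel) the threshold.

Clustering is average linkage (scipy) on *d* = 1 − *r*.  Protein labels are
sorted lexicographically before linkage so tie-breaking is deterministic
across platforms.  Average linkage guarantees monotone merge heights.

Joint profiles (elementwise union, copy numbers summed) model
multifunctional proteins retained when *any* partner is present: if a
protein's profile equals the union of its partners', its correlation with
the joint profile is 1 and never below its correlation with either partner.

Family matching ranks a reference set of family profiles (e.g. built from
a PANTHER-style assignment table; presence = ≥ 1 assigned member in the
species, subfamily assignments propagated to the parent family upstream) by
descending *r* against a query, ties broken by family id; recurrent families
are those appearing in at least `min_count` of the per-query top-*k* lists
(default k = 30).

## Dollo parsimony

The single-gain model fully determines the maximum-parsimony history of a
profile on a rooted, topology-only tree: the origin is the MRCA of the
present leaves, and each maximal subtree below the origin containing no
present leaf is pruned as exactly one loss (per-branch counting — a
single-leaf loss counts the same as a clade loss, the standard Dollo
convention).  Replay (gain at origin, subtract loss clades) reproduces the
input profile bit for bit; this identity is asserted in tests.  Polytomies
are handled as-is: the MRCA walk and the maximal-absent-subtree recursion
never resolve multifurcations.  A profile is "ancestral" (LECA, for a
pan-eukaryotic panel) iff its origin is the provided root; root placement is
the caller's responsibility.  An exhaustive oracle
(`brute_force_min_losses`, trees ≤ 12 leaves) enumerates every gain node and
every loss subset by increasing size and confirms the greedy reconstruction
is minimal.

Transitions — the number of adjacent present/absent flips along the profile
— use the tree's left-to-right leaf order when one is supplied, so adjacency
reflects relatedness.  Mean loss counts over a protein subset are restricted
by default to ancestral (root-origin) proteins, the usual way post-ancestor
loss frequencies are summarized.

## Motif co-occurrence

Motif definitions use character classes, literal residues, `X` (any standard
residue, deliberately excluding the `*` truncation marker) and bounded
repeats: canonical MIM `[KR][ILV](2)X(3,7)P`, relaxed MIM
`[ILV](2)X(3,7)P` or `[RK][ILV](2)`.  The bounded spacer is matched lazily
(shortest per start position; the greediness is otherwise unconstrained by
the motif's biology), overlapping matches at different starts are all
reported, and every hit's substring re-matches the pattern in isolation.

`scan_alignment_window` scores motif presence at a conserved position: the
anchor sequence's motif is mapped from residue to alignment-column
coordinates, the column window is extended by `slack` columns (default 5 —
"similar position" needs a tolerance and ±5 columns is tight enough to
exclude spurious distal matches while absorbing small alignment wobble) and
each sequence is scanned after gap stripping.  Sequences whose motif lies
outside the window are scored absent and logged.  Species-level presence is
the OR over that species' sequences (profile semantics are species-level).

Co-occurrence with a partner protein is tested on the universe of species
carrying the motif's host protein (no ortholog, no motif — by construction
the motif profile is elementwise ≤ the host profile).  The test is the exact
one-sided (over-representation) upper hypergeometric tail
P(X ≥ k), computed by integer summation with `math.comb` — exact to the last
float digit, which the tests verify against full draw enumeration and
against scipy's survival function.  The phi correlation of motif and partner
on the same universe is reported alongside.

## Set statistics

Occurrence frequency is the presence mean; profile entropy is the binary
entropy of that fraction (maximal, 1 bit, at 50% occurrence — a measure of
presence/absence diversity, with 0·log 0 = 0).  Anchored completeness
restricts to species carrying all anchor proteins (proteins whose joint
presence indicates the species has the machine at all) and reports the mean
member fraction over those species; the unanchored panel-wide mean is
reported alongside because summaries are quoted both ways.  Loss-count
comparison between two sets uses the two-sided Mann–Whitney rank test with
the exact null distribution when both samples have n ≤ 25 (the asymptotic
tie-corrected approximation otherwise) and reports the sample means
alongside — a nonparametric choice consistent with using Spearman rank
correlation for loss-versus-rate association, which averages ranks over
ties and requires ≥ 3 shared proteins.

## The simulator

The generator produces exactly the structure the analysis assumes, with
ground truth attached:

- **Species tree** — random sequential leaf addition gives a rooted binary
  topology; leaf codes are collision-free random 4-letter strings.  Only
  topology is generated, matching the analysis' topology-only tree use;
  losses are therefore drawn per branch, not per unit branch length.
- **Gene history** — an origin (root by default; uniform over internal
  nodes, or a fixed clade, on request), then a preorder walk below it where
  each branch loses the gene with probability `loss_prob`; loss is inherited
  (no regain — Dollo's assumption).  Genes extinct in all leaves are
  resampled with an incremented sub-seed (observed orthogroups are
  conditioned on survival; a flag keeps extinct genes for error-path
  testing), with the resample count recorded and a hard error after 100
  consecutive extinctions.
- **Coupled pair** — both genes share the origin; losses are drawn for gene
  A at `loss_prob`, each copied to B with probability `coupling`, and B
  draws additional independent losses at `loss_prob · (1 − coupling)`.  The
  construction is exchangeable in distribution (equal marginal loss rates)
  though mechanically A-first.  Note the coupling acts per loss *event*: at
  coupling 0.95 a pair occasionally fails to copy one large-clade loss and
  its correlation collapses, so "coupled pairs rank above the calibrated
  threshold" is a strong-majority property (asserted in aggregate over
  replicate fixtures), not a per-fixture certainty.
- **Multifunctional triplet** — the enzyme's presence is the union of its
  two (coupled-pair) partners, flipped per species with probability
  `motif_noise`; at noise 0 its correlation with the joint partner profile
  is exactly 1.
- **Fixtures** — per-gene FASTA (ids follow the 4+6 convention; one
  sequence per copy), the newick tree, a truth TSV and a config echo,
  bit-reproducible given the seed.  Sequences are uniform random residues —
  no substitution model; they exist to exercise I/O and motif logic, and the
  background alphabet excludes proline so the only canonical MIM present is
  the planted one.  A motif-carrier gene's sequences carry a planted
  canonical MIM (`KILAAAAP` at a fixed offset, so alignment-free scanning
  suffices) iff the designated partner is present in that species, flipped
  at `motif_noise`.

Default conditions: 90 species, 70 genes, `loss_prob` 0.15, `coupling` 0.9,
`motif_noise` 0, sequence length 120.  Because the simulator is the test
substrate, passing tests demonstrate correctness of the inference machinery
under the single-gain/branch-loss model; they do not speak to the hard parts
of real data (homology detection failure, annotation errors, strain
collapse), which happen upstream of this package's inputs.

## Problem sizes and numerical notes

The test suite and the acceptance script use desk-scale problem sizes chosen
to exercise every code path with comfortable statistical margins: exhaustive
checks on 4-leaf trees (15 presence patterns) and all hypergeometric
parameters to N = 12; 200 random tree/profile instances against the
exhaustive Dollo oracle; 500 simulated genes for origin recovery; 200
replicate pairs at the full 90-species panel for coupling discrimination;
and a 26-gene end-to-end fixture.  Everything runs in seconds.

One measured property deserves note: with `loss_prob` 0.1 on a 10-species
tree, the simulated (root) origin is recovered for ~80% of genes.  The
remaining ~20% lose an entire root-side clade, after which every present
leaf lies inside one root child and no method can distinguish a root origin
from an origin at that child — the Dollo MRCA is the information-theoretic
optimum, and recovery approaches 100% only as the loss rate approaches 0
(measured ~95% at `loss_prob` 0.02).  The companion guarantee is exact,
however: inferred losses never exceed the simulated loss count (parsimony is
a lower bound), with zero violations across all runs.

Other conventions: Pearson values are clipped to [−1, 1] against floating
point drift; calibration candidates are observed r values only; cluster
labels are pre-sorted for deterministic ties; all simulation randomness uses
`numpy` Generators seeded with structured seed sequences
(config seed, object seed, attempt), so every output is a pure function of
(tree, config, seed) and resampling never perturbs sibling objects.

## Known limitations

- Orthogroups are consumed as given; no homology search, alignment building
  or gene-tree inference is performed, and "false absences" from homology
  detection failure propagate directly into loss counts.
- The species tree must be supplied (or simulated); LECA calls are only as
  good as the root placement.
- The exact-summation hypergeometric test is for species-scale universes
  (exact and fast to a few thousand); it is not meant for genome-scale
  contingency testing.
- The simulator's sequences carry no evolutionary signal; motif planting at
  a fixed offset means gapped-alignment window logic is exercised by
  dedicated alignment fixtures, not by the emitted FASTA.
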