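# Methods

## Model and procedure

The analysis treats experimentally validated phosphorylation as a directed
bipartite multigraph: kinases on one side, targets on the other, one edge per
validated kinase→substrate(-site) assertion.  Two target resolutions are
analyzed in parallel — *general* (target = substrate gene symbol) and
*site-specific* (target = `SUBSTRATE:SITE`) — and Ser/Thr and Tyr
phosphorylation events are analyzed separately throughout, assigned from the
leading letter of the site string (S/T vs Y; events on any other residue,
e.g. histidine, are dropped from both classes with a logged count).  A record
is a single assertion; a *convergent* relationship (cKSR) is a target with
in-degree K ≥ 2 after deduplication.

The procedure is: (1) parse the kinase–substrate table; (2) restrict to the
requested substrate organism (the kinase organism is retained as metadata
only — an upstream kinase of another species acting on a human substrate is
still evidence of convergence on that substrate); (3) normalize kinase
nomenclature against an alias map (idempotent; unmapped names pass through
with a warning); (4) deduplicate by string fingerprint `KINASE:SUBSTRATE` or
`KINASE:SUBSTRATE:SITE` (names uppercased; `:` reserved and rejected inside
names); (5) compile each unique target's active-kinase set; (6) tally K:1
topologies, kinase participation and degree distributions, family-subgroup
composition, reciprocal loops, and co-expression scores.

Autophosphorylation records (kinase = substrate) are genuine relationships
and are retained by default in substrate-centric counts; `--drop-self`
removes them.  Self-edges never count as reciprocal loops.

## Deduplication and filtering rules

- Duplicate fingerprints keep the **first occurrence** in input order; the
  kept record's report count is the **maximum** over its duplicates, so a
  well-replicated assertion is never demoted by a duplicate row.
- The multi-report subset (`min_reports ≥ 2`) requires report counts to be
  known (> 0) for every record; an unknown count is a hard error rather than
  a silent drop, because either silent choice would bias the subset.
- The report filter is monotone by construction: the `min_reports = m+1`
  output is a subset of the `min_reports = m` output at every stage.

## Topology and participation

K is tallied per topology bin from 1 to 50; targets with K > 50 accumulate in
an explicit overflow bin with a warning (none arise at realistic data sizes,
but silent truncation would corrupt the edge-count conservation invariant
`Σ_kinases degree = Σ_targets K`).  The convergent fraction is reported to
one decimal.  For the site-specific analysis both denominators are exposed:
per site (the map's targets) and per substrate carrying ≥ 1 convergent site,
since the two read differently and both are legitimate summaries.

A kinase *participates* in cKSRs when ≥ 1 of its targets is convergent — the
criterion is on the target, not on the kinase's own degree — which makes
site-level participation imply general-level participation (a shared site is
a fortiori a shared substrate).

## Family subgroups

Kinases map to the ten canonical kinome subgroups (AGC, CAMK, CK1, CMGC,
RGC, STE, TK, TKL, atypical, other) via a KinHub-dialect table; group labels
are case-folded onto the canonical set and an unrecognized label is a hard
error naming the row.  Kinases missing from the table are counted as
*unassigned*, not defaulted into OTHER (OTHER is reserved for the explicit
annotation); a convergent target left with < 2 assigned kinases is excluded
from the family tallies and reported in an exclusion count.  For fully
assigned targets the two predicates — multiple subgroups represented, and
≥ 2 kinases from one subgroup — cover every K ≥ 2 target by pigeonhole.

## Reciprocal loops

Loops are detected on the general-level, class-union dataset: mixed-class
loops (e.g. a Tyr kinase phosphorylated on serine) are real motifs, and a
class-restricted mode is available.  Each directed edge's residue class is
reported per loop; a direction supported by sites of several classes is
classed Ser/Thr if any S/T site supports it, else Tyr, else other — a fixed
priority so that the per-class edge counts always partition the
`2 × n_loops` directed edges.  The output table carries an empty
`annotation` column for manual literature curation.

## Co-expression scoring

Transcriptomes are stored as log₂(TPM+1); "expressed" means TPM ≥ threshold
(5, 10 or 20; 10 is the primary threshold, 5 and 20 are sensitivity
settings), evaluated in stored space as `value ≥ log₂(threshold+1)` — the
cutoff is inclusive.  MS proteomes are bridge-normalized relative values, so
only a relative cutoff is defensible: "expressed" means strictly above the
gene's across-cell-line median (per-gene by default; ties and missing values
are not expressed, and the choice is recorded in the binarization
provenance).  CCLE-style `"SYMBOL (ID)"` headers are cropped to the bare
symbol; duplicate symbols after cropping keep the column with the highest
mean.  A group's score is the percentage of cell lines expressing ≥ 2 of its
kinases; kinases absent from the matrix count as never expressed (the score
is a lower bound, and the per-group `n_in_matrix` reports coverage), and a
group with < 2 members present is flagged unscored rather than erroring.
Score distributions are summarized by median, mean, and the fraction of
groups co-expressed in < 2.5% of cell lines (the rarity cutoff).

Under independent Bernoulli(pᵢ) expression the expected score has the closed
form 100 × (1 − Π(1−pᵢ) − Σᵢ pᵢ Π_{j≠i}(1−pⱼ)); this is the calibration
oracle for the simulated matrices.

## Synthetic data

The generator *constructs* ground truth rather than estimating it.  A
general-level target of multiplicity K is a fresh substrate given K distinct
kinases on K distinct sites (each site then has exactly one kinase); a
site-level target is a fresh substrate with one site shared by K kinases (its
general-level K equals its site-level K).  The expected histogram at each
level is therefore an exact merge of the two planted distributions plus the
loop members (each loop kinase is also a 1-kinase target at both levels), and
recovery tests run at zero tolerance.  Loop pairs live in a kinase namespace
disjoint from the topology kinases so the expectations stay independent.
Duplicate rows (default 10% of records) and aliased kinase spellings
(default 10%, `NAME_RAW` → `NAME`) are injected to exercise deduplication and
nomenclature normalization without altering the ground truth.  Expression
matrices plant per-kinase Bernoulli calls: expressed entries are drawn
uniformly in TPM [threshold, 4×threshold], unexpressed in [0, 0.8×threshold],
stored as log₂(TPM+1), so thresholding at the planted TPM value recovers the
calls exactly while thresholds 5 and 20 still behave monotonically.

Default study conditions (chosen once as a desk-scale image of a curated
human phosphorylation network): 60 Ser/Thr and 25 Tyr kinases; general-level
topologies over 400 Ser/Thr and 160 Tyr substrates with ~48% and ~35%
convergent and a long-tailed K ∈ 1..10 dominated by K = 2–4; site-level
topologies with ~24% and ~23% convergent sites; 8 reciprocal loops; report
counts 1/2/3 with probabilities 0.5/0.3/0.2; expression probability 0.6 per
kinase over 500 cell lines.  Ser/Thr kinases cycle through the eight
non-tyrosine subgroups; Tyr kinases are all TK, mirroring the concentration
of tyrosine kinases in that group.  Note that the realized general-level
denominator is the union of general-planted substrates, site-planted
substrates and loop kinases, so the overall general-level convergent fraction
of a default run sits below the planted 48%/35% of the general component
alone.  The acceptance script's verification
stages use smaller problem sizes (random tables of 50–500 records;
10,000 cell lines for the co-expression calibration).

What the generator does **not** emulate: realistic kinome degree
distributions (kinases are sampled uniformly per target, where real networks
have heavy-tailed kinase degrees), literature ascertainment bias toward
well-studied kinases, correlated kinase expression (co-regulation makes real
co-expression scores higher than the independence closed form), shared sites
between planted targets, or sequence-level features.  Passing recovery tests
therefore demonstrates correctness of the counting machinery, not fidelity
of any biological summary statistic to real databases — on real exports the
numeric fractions are release-dependent.

## Numerical and degenerate-input choices

- Empty map → all-zero histogram, convergent fraction reported as 0 with an
  explicit `empty` flag (the fraction is undefined).
- Empty tables export as header-only TSVs; the JSON summary flags them.
- Targets and names are keyed uppercase to avoid symbol-case splits.
- All randomness flows from a single integer seed per generator call
  (table, expression matrix and alias injection use distinct derived
  streams); identical seeds yield byte-identical files, and the full
  pipeline is a pure function of (inputs, config).

## Known limitations

- Substrate identity is the short gene symbol, not an accession: isoforms
  collapse, and cross-species symbol collisions are possible if the species
  filter is disabled.
- Nomenclature repair is only as good as the supplied alias map; near-miss
  symbols are reported, never auto-merged.
- Loops of length > 2 and enrichment statistics are out of scope.
- Co-expression treats expression as binary and independent per cell line;
  it quantifies opportunity for convergence, not kinase activity.
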