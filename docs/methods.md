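# Methods

## The model

`gofp` predicts molecular function (GO:MF terms) and structural fold for
individual protein domains by searching a query sequence against a library
of position-specific scoring matrices, one per (fold, GO:MF term) pair.
The premise is that all domains carrying one molecular function within one
fold — across families and superfamilies — share sequence landmarks that
no single pairwise comparison can recover once the members have diverged
past the twilight zone, but that a profile over all of them can.

The pipeline has four stages, each an importable module:

1. **Chain-to-domain annotation transfer** (`gofp.annotation`).  Molecular
   functions are annotated per chain in source databases.  For each GO
   term we collect the fold composition of every annotated chain and find
   the minimum set of folds intersecting all of them (minimum hitting
   set); the term is assigned to the domains whose fold is in the cover.
   The optimisation is exact (subset enumeration in lexicographic order,
   giving a deterministic canonical optimum) up to a 20-fold universe and
   greedy largest-coverage-first beyond.  The procedure is a heuristic and
   inherits a known failure mode: isolated fragment chains annotated with
   the whole protein's function drag their fold into the cover.  The
   synthetic-world module can construct exactly this confound
   (`make_fragment_artifact`), and the test suite asserts that the
   spurious assignment *occurs* — the artifact documents the limitation
   rather than fixing it.

2. **Library construction** (`gofp.library`).  Eligible domains (not
   multidomain database entries, not from mutant or circular-permutation
   chains, terms at GO-depth ≥ 3) are grouped into (fold, term) cells;
   each cell is made non-redundant at < 40 % identity (greedy longest-
   first representative selection, identity = identical columns over
   non-gap columns of a global alignment); cells with < 3 survivors are
   dropped; the member with length closest to the cell mean becomes the
   master; every survivor is aligned to the master and the binary
   alignments are piled up into a master-framed pseudo-multiple alignment
   (columns = master residues; member residues in insertions relative to
   the master are discarded and counted); a PSSM is built and conserved
   columns flagged.

3. **Search** (`gofp.search`).  Local Smith–Waterman of the query against
   each entry's PSSM; hits below the E-value cutoff are returned sorted by
   E-value, ties by score, then (fold, term).  Each hit is a concomitant
   fold+function prediction for its query segment.  `predict_sites` maps
   the entry's conserved columns through the hit alignment onto query
   residues; conserved columns gapped in the query are reported separately
   as missing sites.  Conservation is expected at functional residues but
   also occurs for purely structural reasons; the code asserts only the
   mapping, not the biology.

4. **Benchmark** (`gofp.benchmark`).  Leave-similarity-cluster-out: for a
   test chain, all chains of its cluster are removed *before* any building
   happens, the library is re-derived, and a flat database holding exactly
   the profile member sequences (with their fold/GO labels) serves as the
   single-sequence comparator — same information, same sequences, the only
   difference being whether they are grouped into GO-informed profiles.
   Only the top hit per method is evaluated, with domain-region
   verification and exact-term semantics (below).  Pooled labelled top
   hits are swept into ROC curves at every distinct score; the sweep score
   is −log10(E), which is monotone in each method's ranking, so the AUC is
   invariant to the choice among monotone alternatives.

## Scoring and statistics

* **PSSM.**  Single-component background pseudocounts:
  `f(c,a) = (n(c,a) + β·p(a)) / (N(c) + β)`, `score = log2(f/p)` floored
  at −10 (so β = 0 stays finite); gaps contribute nothing to counts;
  all-gap columns score 0 with a warning.  β defaults to 5.  The library
  build renormalises observed counts to a fixed effective observation
  count (default 5) before pseudocounts.  Without this, an entry with more
  rows is systematically more generous to *any* same-fold query than an
  entry with fewer — and in the leave-cluster-out regime the correct entry
  is always the one that just lost the test cluster's members, so raw
  counts bias every comparison against the correct answer.  With the
  renormalisation, entry size affects only the variance of the frequency
  estimates, not the score scale.  Two alignments with identical column
  frequencies but different depths produce identical matrices (tested).
  Henikoff position-based sequence weighting is available
  (`sequence_weighting=True`) but off by default: the members entering a
  profile have already passed the 40 % redundancy filter, so
  over-representation is mild.

* **Conserved columns.**  A column is conserved when one residue accounts
  for ≥ 95 % of *all* rows; gaps count in the denominator (a gapped row is
  evidence against conservation) and the threshold is inclusive (19/20
  passes).

* **Backgrounds.**  Robinson–Robinson frequencies by default; uniform
  1/20 available for analytically tractable tests.

* **E-values.**  Gapped alignment statistics have no closed form, so each
  profile is calibrated empirically: optimal local scores of 500 random
  background sequences of length 200, Gumbel fit by the method of moments
  (λ = π/(σ√6), location absorbed into k = e^(λμ)/(m·n), μ = mean − γ/λ),
  deterministic given the seed.  Per-entry calibration seeds derive from a
  stable hash of the entry's membership, so a rebuild after removing
  unrelated domains reproduces untouched entries bit-for-bit — which also
  makes the per-test-chain rebuilds of the benchmark cheap to cache.  The
  flat comparator uses one Gumbel fit per benchmark (random query/target
  pairs at the database's typical sequence length), with E scaling
  linearly in the actual total database length; re-fitting after each
  exclusion (which removes ~2 % of the database) would change nothing
  but dominate runtime.

* **Gap penalties.**  Sequence-vs-sequence alignment uses BLOSUM62 with
  open −11 / extend −1 (a gap of length L costs open + L·extend).
  Sequence-vs-profile alignment uses −5.5 / −0.5: the PSSM is in bits
  (log2), i.e. half the numeric scale of BLOSUM62's half-bit units, so
  −11/−1 against a bit-scale matrix would double the effective gap
  stiffness and break profile alignments at indels.

* **Deterministic tie-breaks** everywhere: alignment DP prefers
  match/diagonal, then gap-in-first-sequence, then gap-in-second; optimal
  local cells keep the first in scan order; redundancy reduction sorts by
  (length desc, id asc); master selection breaks ties to the shorter
  domain then ascending id; hit ordering is (E, −score, fold, term).
  Coordinates are 0-based half-open internally, 1-based inclusive in
  reports.

## Evaluation semantics

A top hit is labelled via three gates:

1. **Domain verification.**  The hit's query segment is locally aligned
   against each of the chain's own domain sequences; the best domain wins
   only if it clears a random floor (mean + 3σ of the segment's score
   against 20 length-matched random sequences, seeded) and beats the
   runner-up by ≥ 2 score units (≈ 1 bit on BLOSUM62's half-bit scale).
   Ambiguity or insignificance → unverified, and nothing can be correct
   in an unverified domain.
2. **Fold**: the verified domain's fold must equal the hit's fold.
3. **Function**: the hit term must be *exactly* among the verified
   domain's terms.  No ontology credit in either direction — a prediction
   more specific than the annotation (a child term) counts as a failure,
   which is a property of the evaluation, not of the prediction.

Hits whose terms all sit above the depth filter (distance to the GO:MF
root < 2 or < 4) are excluded from the evaluation set entirely.  Depth is
the shortest is_a path to the root (longest-path available as a
sensitivity mode).  When a pooled label set contains a single class —
routine for fold labels, which are near-perfect — the benchmark reports a
degenerate curve (AUC 1 or 0, flagged) instead of failing; the `roc`
function itself refuses degenerate inputs.

## The synthetic world

The generator (`gofp.world`) emulates the data-generating process the
method assumes, with ground truth for every domain:

* **Folds**: independent random core sequences (length 120).  **Cell
  ancestors**: each (fold, function) cell derives from the fold core by
  substitutions at the *function-branch* divergence (default 0.05/site) —
  same-fold domains with different functions belong to long-diverged
  superfamilies, so cells of one fold must be farther apart than members
  within a cell — then the function's 8-residue motif is implanted at a
  fold-specific offset.  **Clusters**: 6 domains per cell in 5 clusters
  (sizes 2,1,1,1,1); a cluster founder diverges 0.55/site from the cell
  ancestor, members 0.05/site from their founder.  Substitutions are drawn
  from BLOSUM62-conditional target distributions so identity percentages
  and alignability behave like real homologs; indels are geometric (mean
  2), never inside motifs.  Motif columns substitute at 1/20 of the
  background rate — functional sites under strong purifying selection,
  consistent with the premise that they remain ~95 % conserved across
  entries whose members are mutually < 40 % identical.
* **Chains**: one chain per domain, except that ~20 % of clusters pair up
  (equal size, different folds) into two-domain chains; a paired cluster's
  chains all share one chain-level cluster id, so leave-cluster-out
  removes both domains of those chains together and no near-identical
  homolog of either domain leaks into the training side.
* **Ontology**: a layered is_a DAG, one leaf term per function at depth 4,
  sharing upper layers and with occasional double parents (a genuine DAG,
  not a tree).

With these defaults, cross-cluster members of one cell are ~25–30 %
identical (safely under the 40 % redundancy cutoff, as the real library's
members are), same-fold different-function domains ~20–25 %, and other
folds unrelated.  This is the regime the method was designed for: fold
recognition is easy for any method, function discrimination within a fold
is at the edge of what a single pairwise comparison can do, and the
profile's consensus over ~5 diverged members recovers the cell-level
signal that no individual sequence carries reliably.

**Structure-equivalent binary alignments.**  The pile-up consumes binary
master-vs-domain alignments through an interface.  The built-in producer
is sequence-based global alignment, but at 25–30 % identity it misaligns
enough columns to blur the profiles, whereas the real protocol's
structural superposition does not degrade with sequence divergence.  The
world therefore exposes `structural_aligner()` — residues align iff they
descend from the same ancestral core position, which is precisely what a
structural alignment of two same-fold domains recovers — and the
benchmark and acceptance runs inject it.  The redundancy filter always
uses sequence identity, mirroring a protocol whose identity filtering is
sequence-based even when its alignments are structural.

**What the generator does not emulate.**  Real fold cores vary in length
and secondary-structure constraints; real GO annotation is incomplete,
multi-label and uneven in depth (here every domain carries exactly one
leaf term, so the depth-2 and depth-4 evaluations coincide); real
conservation has rate variation beyond the binary motif/background split;
cluster sizes and cell occupancies are long-tailed, not uniform.  Passing
benchmarks on this world shows the machinery realises the method's
operating regime, not that the accuracy numbers transfer to any real
proteome.

## Problem sizes

The standard evaluation uses 4 folds × 4 functions × 6 domains per cell
(96 domains, ~87 chains), 40 test chains per world and three worlds, with
500 random sequences per E-value calibration; the hold-one-member-out
site evaluation queries every member of every entry (~80 queries).  These
sizes keep a full evaluation in the low tens of seconds on one CPU while
leaving every filter in the pipeline (redundancy, minimum members,
cluster exclusion) non-trivially exercised.

## Known limitations

* The cover-based annotation transfer is order-independent per term but
  shares the fragment-chain confound of its real-world counterpart (see
  above); it also over-annotates companion domains of multi-domain chains
  whose fold is in a term's cover for independent reasons.
* Method-of-moments Gumbel fits are adequate for ranking but not for
  absolute E-value accuracy in the extreme tail.
* The single-sequence comparator is an optimal local aligner with exact
  statistics — a strong baseline; iterated profile bootstrapping of the
  comparator is out of scope.
* With ~40 evaluated top hits per world and error counts in single
  digits, per-world AUC estimates carry substantial sampling noise; the
  profile-vs-single-sequence comparison is therefore asserted as a
  majority across three independent worlds, not per world.
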