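# gofp — concomitant fold and function prediction for protein domains

Most resources annotate molecular function at the level of whole protein
chains, yet the *domain* is the structural and functional unit: the two
domains of a kinase-phosphatase fusion do different chemistry, and a
whole-chain annotation cannot say which domain does what.  `gofp`
implements a profile-based predictor that works at the domain level.  From
a collection of domains annotated with Gene Ontology molecular-function
terms (GO:MF), it builds a library of position-specific scoring matrices
(PSSMs), one per **(structural fold, GO:MF term)** pair: every entry is a
master-framed alignment of all non-redundant domains known to carry that
function within that fold.  Searching a query sequence against the library
with profile Smith–Waterman yields hits that are *simultaneous* predictions
of fold and function for a segment of the query (i.e. a domain), and the
conserved columns of the matched profile, mapped through the alignment,
point at candidate functional residues.

## The method in brief

For a profile column *c* with residue counts *n(c,a)* the score of residue
*a* is the log-odds against the background *p(a)*,

    f(c,a) = (n(c,a) + β·p(a)) / (N(c) + β),   score(c,a) = log2 f(c,a)/p(a)

with a background pseudocount of total weight β (default 5) and an
optional fixed effective observation count that puts entries of different
sizes on one score scale.  Hit significance follows the Karlin–Altschul
form E = k·m·n·e^(−λS), with (λ, k) fitted per profile from the Gumbel
distribution of optimal local scores of random background sequences.

The library build per (fold, term) cell: exclude multidomain entries and
mutant / circular-permutation chains; drop terms at distance ≤ 2 from the
GO:MF root; reduce to <40 % mutual identity; discard cells with fewer than
3 survivors; pick the master (length closest to the cell mean); pile up
binary master-vs-domain alignments into a pseudo-multiple alignment
(insertions relative to the master are discarded); build the PSSM and flag
columns where one residue reaches 95 % of all rows.

Chain-level GO:MF annotations are transferred to domains by minimum set
cover: for each term, the smallest set of folds that intersects the fold
composition of every annotated chain receives the term.

The package also implements the full benchmarking protocol: for each test
chain, every training chain from the same sequence-similarity cluster is
removed, the library *and* a flat single-sequence database holding exactly
the same domain sequences are rebuilt, the chain is searched against both,
and only the top hit of each method is evaluated — correct only if its
term is *exactly* a term of the domain the hit's segment actually aligns
to (a more specific child term, or a correct term in the wrong domain,
counts as a failure).  Pooled top hits give ROC curves
(TPR = Tp/(Tp+Fn) vs FPR = Fp/(Fp+Tn)) per method and GO-depth filter.

Because no external structure/annotation database is bundled, a seeded
synthetic-world generator provides data with the statistical structure the
method assumes: fold core sequences, per-function conserved motifs,
cluster structure at controlled divergence tiers, multi-domain chains, and
a layered GO:MF DAG — plus ground truth for every domain.

## Worked example

```
$ gofp simulate --seed 1 --out world
wrote 96 domains / 87 chains to world
$ gofp build --world world --out library --seed 1
built 16 profile entries
$ gofp search --library library --query query.fasta \
      --obo world/ontology.obo --tsv hits.tsv
```

Here `query.fasta` holds one full-length two-domain chain from the world
(`d_0_0_0_0` fused to `d_2_1_0_0`, 242 residues).  The top of `hits.tsv`:

```
query_id                fold_id  go_id       go_depth  qstart  qend  score   evalue    n_sites
ch_d_0_0_0_0_d_2_1_0_0  f.1      GO:1000005  4         1       122   210.51  2.29e-58  8
ch_d_0_0_0_0_d_2_1_0_0  f.3      GO:1000008  4         125     242   185.24  6.18e-54  10
```

The two strongest hits segment the query correctly: residues 1–122 are
predicted to be a fold `f.1` domain with function `GO:1000005`, residues
125–242 a fold `f.3` domain with `GO:1000008` — which is exactly what the
generator implanted.  The companion `hits.sites.tsv` lists the conserved
profile columns mapped onto query residues (candidate functional sites),
e.g. query position 45 matching a 100 %-conserved alanine column of the
`f.1/GO:1000005` profile.

The benchmark subcommand runs the leave-cluster-out evaluation on a world
directory and writes labelled top hits, ROC points and an AUC summary:

```
$ gofp benchmark --world world --seed 1 --n-test 40 --out bench
```

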