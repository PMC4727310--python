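# Methods

## Model

A strand (a chromosome's sense or antisense sequence, or a reduced text) is
a string over a finite alphabet, analyzed in its own 1-based, inclusive
coordinate frame. The working hypothesis is positional: occurrences of a
non-functional symbol sequence are exchangeable across the strand, hence
uniform; a functional element clusters. A *word* is a symbol sequence that
is (i) repeated often enough to test, (ii) positionally non-uniform, and
(iii) a complete unit — its occurrences are not merely fragments of a
longer recognized word.

### Extraction

1. **Data initialization.** All symbol sequences repeated strictly more
   than `min_count` times are enumerated and grouped into length classes.
   Enumeration extends length-l survivors one symbol rightward (Apriori
   pruning); the result is exact. Out-of-alphabet symbols (`N` etc.) keep
   their coordinates — the full strand stays the reference frame — but no
   candidate may contain one.
2. **Per-class testing, longest class first.** With `n_class` candidates in
   a class, each is tested at `α = 1 − c^(1/n_class)` (family confidence
   `c = 0.95`), giving family-wise confidence `c` per class. A candidate is
   accepted iff (all strict) net count > `min_count`, KS distance
   `D_n > min_dn` (0.1) and `p < α`, where `p` is the asymptotic Kolmogorov
   tail probability at `λ = √n·D_n` (series truncated below 1e-10; no
   small-sample correction — samples always exceed 100, where the plain
   asymptotic law is slightly conservative).
3. **Integrity.** Before a candidate in a shorter class is tested, the
   union of positions occupied by every longer recognized word containing
   it as a contiguous substring is deleted. Deletion is occurrence-level by
   default: an occurrence survives only if its interval is wholly disjoint
   from that territory, so KS samples never contain fragments of
   partially-deleted occurrences. A literal position-set difference is
   available as `integrity="set-difference"`. Accepted words within one
   class never filter each other, making the result independent of
   within-class order (verified by a shuffle hook).

### Two calibration-critical choices

* **Occurrence counting is greedy non-overlapping** (Perl-global-match
  semantics), with overlapping window counting as an option. Overlapping
  counts give self-overlapping words (`TT`, `AA`) clumpy start processes —
  runs of one letter become bursts of adjacent starts — which the KS test
  reads as spurious clustering; short chance "words" then appear even on
  uniform random strands. Greedy counting is an anti-clustered renewal
  process, conservative for the test. The two coincide for all length-1
  words and for any word that cannot overlap itself.
* **The KS sample is the surviving occurrence start positions**
  (`ks_sample="starts"`), so the KS sample size equals the repetition count
  that the `> min_count` criterion is stated on. Testing all *occupied*
  positions instead (`ks_sample="occupied"`) hands the test k statistically
  dependent positions per occurrence of a length-k word, inflating the
  nominal sample size k-fold and destroying type-I calibration (a 100 kb
  uniform control then yields dozens of spurious words). Occupied-position
  sets remain the currency of the integrity subtraction, where they belong.

### What "zero false positives" does and does not mean

The per-class alpha controls family-wise error at 5% per length class — by
construction, not approximately. A negative-control run therefore has a
small but real chance (~5–10% at any scale, since the top length class
always sits at the repetition boundary) of emitting one genuine type-I
word: a chance cluster that actually satisfies every criterion. Across 25
desk-scale control runs we observe exactly two such words (e.g. a 5-mer
with net count 102, D_n 0.22, p just under its α of 1.3e-4), matching the
designed rate. Tests assert the calibrated property (at most a couple of
chance words over 20 seeds); a strict always-zero assertion is not
achievable by any faithful implementation.

## Association stage

Function terms form a DAG (child → parent edge list; one root per
category; an optional filter keeps a single category). A term's level is
its minimum child-chain distance from a root (min-depth under multiple
parents); descendants are transitively closed, and a gene annotated by a
descendant counts as annotated by the term. Per term, the annotated-gene
universe splits into **exclusive** (annotated by this term only, among
same-level terms), **share** (also by another same-level term) and
**control** (not by this term); terms qualify for modelling when exclusive
and control both exceed 150 genes. Annotation input is expected
pre-filtered (electronically-inferred IEA entries and identifier-conflict
genes removed).

Features are adjusted per-gene word frequencies: overlapping occurrence
counts, minus superword-count × (occurrences of the subword inside the
superword string) for every nested vocabulary pair, floored at zero;
multi-variant genes take the average over variants.

Word selection and fitting are staged exactly as: (1) keep words with
`fe > 0.6` and `fd = fe − fc > 0.1` (group means over exclusive and
control; on the interaction path the fd threshold rises in 0.01 steps
until fewer than 50 words remain); (2) fit maximum-likelihood logistic
regression, keep coefficients with `p < 0.2`, refit; (3, interaction path)
add all pairwise frequency products of the keepers, fit, keep `p < 0.2`,
refit. Newton fits fall back to BFGS under (quasi-)separation, flagged
non-converged; flagged models are excluded from reporting. Evaluation
bootstraps the exclusive∪control genes (100 replicates at original size),
refits the final terms, predicts on the full original data, and reports
median and MAD of sensitivity (exclusive, P > 0.5), specificity (control,
P < 0.5), agreement, and share-group accuracy (missing when the share
group is empty).

`fe`/`fc` are group means of per-gene adjusted counts (the reading that
makes `fe > 0.6` an expected-count threshold); the fraction-of-genes
alternative is a one-line change at the call site.

## Synthetic data

* `random_sequence`: i.i.d. equiprobable symbols — the negative control.
  Desk-scale lengths are 4,000 and 100,000 (the acceptance thresholds are
  absolute, so behavior at multi-Mb scale differs only in which length
  class sits at the repetition boundary).
* `plant_words`: overwrites non-overlapping copies of a word uniformly
  into a region (stars-and-bars placement), preserving length and
  coordinates; `exclusive=True` scrubs chance background occurrences so
  positional bounds (all occurrences below quantile q ⇒ `D_n ≥ 1 − q`)
  hold by construction.
* `toy_association_dataset`: per-gene signal-word copy numbers are Poisson
  with rate 0.4 in control and `0.4·e^effect` in exclusive genes, planted
  into 600 bp random gene sequences. Poisson class-conditionals make the
  true posterior log-odds exactly linear in the counts with slope `effect`
  per word — so `effect` is the generating logistic coefficient and
  recovery can be asserted against ground truth; `effect = 0` is an exact
  null with p-values asymptotically uniform (measured stage-2 survival at
  `p < 0.2`: 0.21 over 100 datasets).

What the generators do *not* emulate: real base composition, GC skew,
repeat families, codon structure, or annotation noise. Passing tests show
the machinery is calibrated and recovers planted structure under the
stated model; they say nothing about what fraction of words extracted from
a real genome are functional.

## Numerical and edge-case choices

* Positions are distinct integers by construction; ties are rejected, not
  silently tolerated. Input order never matters.
* The uniform reference always spans the full strand length, also for net
  positions after integrity subtraction (no support renormalization).
* The Kolmogorov series is truncated when a term falls below 1e-10 and the
  result clipped to [0, 1]; agreement with an independent backend is
  maintained to 1e-6.
* `n_class` (hence α) is fixed at data initialization, not recomputed
  after eliminations, so α cannot depend on processing order.
* Net count means surviving occurrences, keeping "repetitions > 100" one
  consistent criterion before and after filtering.
* Words are literal strings: a word and its reverse complement are
  distinct; each strand is analyzed in its own coordinates with its own
  vocabulary, and vocabularies are merged as string-set unions.
* Degenerate bootstrap resamples (one class absent) are redrawn with a
  retry cap; replicates whose refit fails outright are dropped.

## Problem sizes

The shipped tests and the acceptance script run entirely on generated
inputs: controls at 4–100 kb, planted constructions at 50–60 kb, 100
null datasets and 10 recovery datasets of 300–800 genes × ≤ 20 words, 100
bootstrap replicates. These sizes give stable statistics (Monte-Carlo error
well inside every asserted band) at interactive runtimes. Full-genome runs
(multi-Mb strands, real term hierarchies) use the same code paths via the
CLI; only input scale changes.

## Known limitations

* Unidirectional longest-first processing can amplify a wrong long
  acceptance into wrong short eliminations (no bidirectional search).
* No cross-strand or cross-chromosome integrity filtering.
* Wald p-values drive stage-2/3 screening; under near-separation they are
  conservative and may drop a perfectly predictive word (the fit is then
  flagged).
* The exact word inventory on real text/genomes is sensitive to edition
  and assembly versions; only construction-backed properties are asserted.
* Planted constructions create *junction words*: short sequences spanning
  the boundary between background and a planted copy cluster in the
  planted region and are correctly (from the test's point of view) flagged
  as non-uniform. Recovery tests therefore assert the presence of the
  planted word and the absence of its fragments, not an exact vocabulary.
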