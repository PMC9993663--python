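# Methods

## Genome models and read scoring

Each genome (all records of one FASTA file jointly — chromosome plus
plasmids are one model) is summarised by an order-k standard Markov model:
a transition table P(x | w) over all 4^k contexts w and an initial
distribution P(w) over k-mers. Every transition cell starts at a
pseudocount δ (default 1.0, Laplace) before counting, so all probabilities
are finite and a genome shorter than k+1 degenerates cleanly to the
uniform model. The initial distribution is the δ-smoothed, normalised
k-mer count vector. Counts never span a record boundary, and any window
containing a non-ACGT base is skipped both in counting and in scoring.

A read's raw score under a model is its total natural-log likelihood

    log P(w_1..k) + Σ_{i>k} log P(x_i | x_{i-k}..x_{i-1}),

evaluated on the forward and reverse-complement strand with the maximum
returned — shotgun reads have unknown strand. The score is kept *total*
(not per-base) because read length enters the calibration model as its own
feature. A read with no unambiguous (k+1)-mer is unscorable and is
reported unassigned at every rank.

Orders 10–12 are the validated operating range; 1–14 are accepted (with a
warning outside 10–12; 14 is a hard cap because the dense 4^(k+1) tables
grow fourfold per order). Contexts are 2-bit packed; tables are dense
NumPy arrays. The scoring driver indexes the reads once, then streams
genomes through a single count/probability buffer per worker that is reset
as each genome is modeled — memory is flat in the number of genomes and
there is no model database or serialization. Genomes are partitioned
across workers and results keyed by (read id, genome id), so the score
table is bit-identical for any worker count. Within a read, scores sort
descending with ties broken by ascending genome id.

## MJSD segmentation and clustering

The calibration pool must represent each genome's compositionally distinct
regions (vertically inherited backbone vs horizontally acquired islands),
so genomes are segmented by recursive binary splitting at the position of
maximal Markovian Jensen–Shannon divergence. With order-m context counts
(m = 2 by default; order-2 conditionals are the standard compromise
between resolution and count stability),

    H^m(p) = −Σ_w P(w) Σ_x P(x|w) log2 P(x|w)
    D(L, R) = H(L+R) − (n_L/n) H(L) − (n_R/n) H(R),

with maximum-likelihood probabilities from raw counts (no pseudocounts
here) and weights proportional to (m+1)-mer count totals. D ≥ 0 holds
exactly by concavity because the mixture profile is the literal sum of the
two count tables.

Every admissible split position is evaluated. Instead of recomputing
entropies afresh per position (quadratic in the interval), the split point
slides one nucleotide at a time and the entropy accumulators
S1 = Σ_w r_w log2 r_w and S2 = Σ_{w,x} c_wx log2 c_wx are adjusted for the
single context window that changes sides, making a full pass linear in the
interval length. Each (m+1)-mer window belongs to the side containing its
start position (the context may overhang the boundary, truncated only at
the sequence end). This convention makes the slider a one-window transfer
per step, keeps the mixture profile constant across split positions, and
makes segment profiles *exactly* additive: the integer sum of all segment
profiles equals the whole-genome profile. The tests assert incremental =
fresh recomputation to < 1e-9 at every split of random sequences; the
observed agreement is ~1e-13. The slider is compiled with numba; an
interpreted fallback with identical arithmetic is used if numba is absent.

A split is accepted when its p-value is below `alpha_segment` (default
0.05), then both halves are recursed. The statistic 2 n ln(2) D is
referred to a chi-square with 3·4^m degrees of freedom. The maximum over
candidate positions is corrected as p = 1 − F(x)^n_eff. Neighbouring
split statistics are almost perfectly correlated, so using the raw
candidate count would overcorrect by orders of magnitude; n_eff is instead
min(candidates, 1.5·(m+1)·log2 n), a rule calibrated once against the
Monte-Carlo permutation null (implemented as `split_significance_mc`, the
authoritative reference: shuffle the interval, recompute the max D, B
replicates). Under this rule the analytic test's measured type-I error at
α = 0.05 on homogeneous 10 kb sequences is 0.05–0.065 for m = 0–2.

`min_segment_len` defaults to 5,000 bp: order-2 profiles need on the order
of 10³ observations per context row to be stable. Tests use 100–500 bp on
toy sequences.

Segments are then merged agglomeratively: repeatedly merge the pair of
clusters with the *largest* divergence p-value (computed on summed
profiles, single-candidate correction) while that p-value exceeds
`p_cluster` (default 1e-5); ties break to the smallest member start
coordinates, so clustering is deterministic. Clusters strictly smaller
than `min_cluster_frac` (default 1e-5, i.e. 0.001%) of the genome are
discarded; a pluggable predicate hook can apply further screens (e.g. a
contaminant filter) and defaults to keeping everything.

## Calibration training sets

Fragments with lengths uniform on [30, 500] bp are sampled from the
retained clusters — cluster chosen proportional to its total length within
the genome, member segment proportional to its number of admissible start
positions, start uniform, never crossing a segment boundary (crossing
would blur the compositional label). Fragments containing ambiguous bases
are resampled with bounded retries. Each fragment is scored against the
whole genome panel; the top 50 hits per fragment are kept (with few
genomes, all of them), which balances correct against incorrect examples.
Each retained (fragment, genome) pair becomes one row (raw score, read
length, label), the label comparing the hit's and the source's taxon name
at the rank; pairs with an unknown (NA) name at the rank are excluded.
The production-scale configuration is 250,000 reads per dataset, 10
datasets; the tests and the acceptance run use thousands, which is
sufficient for the two-feature logistic fit.

## Calibration models

One logistic model per (rank, order) pair — 18 in full production, one or
two in tests — maps standardized (raw score, read length) to
P(assignment correct). Standardization (not part of the original recipe)
conditions the optimizer; the constants are stored with the model so a
persisted JSON model is self-contained, and prediction is a closed-form
sigmoid with no library dependency. Fitting uses penalized maximum
likelihood (liblinear, max_iter 15,000). Hyperparameters are searched
sequentially at random over the declared box — C log-uniform on
[1e-6, 1e5], tolerance log-uniform on [1e-7, 1e-2], L1/L2 penalty,
intercept on/off — scoring each candidate by threefold cross-validated
accuracy and refitting the winner on all data (default budget 60
candidates; any sequential search honoring the box, the 3-fold protocol
and the seed is conformant — a surrogate-guided optimizer is an
implementation detail, and plain accuracy is the objective). Models
round-trip through a versioned JSON schema; loading rejects missing fields
and unknown versions.

## Classification and hybrid merging

For each read, the single best-scoring genome fixes the candidate lineage
at all six ranks (phylum → species); ties go to the lexicographically
smaller genome id. Each rank is gated independently: assigned iff the
rank's calibrated probability clears the cutoff (default 0.25; 0 disables
gating) and the lineage is known at that rank. Lower-ranked hits never
supply higher-rank taxa — the simplest reading, recorded as an open
design point.

Hybrid mode parses a Kraken2-style per-read file (columns status, read id,
taxon, length; the k-mer LCA column is ignored), reclassifies only the
status-U reads, and merges: status-C reads keep their taxon verbatim with
no probability; a second-pass record for a status-C read is an error. The
merged table is rank-agnostic for first-pass reads (a first-pass line
carries a single taxon); a projection helper maps it to one rank for
evaluation.

## Metrics

Per rank: sensitivity = correct / all reads with known truth at the rank
(unclassified reads count against it); precision = correct / (correct +
incorrect) (unclassified excluded); F1 = harmonic mean. Reads whose truth
is unknown at the rank are excluded entirely. Empty denominators are
reported as undefined, never silently zero. Percentages print to two
decimals with round-half-even.

## Synthetic data

`synth` draws order-m (default 2, deliberately mismatched to the scoring
order so tests never see model-true data) Markov sources whose transition
rows mix a GC-biasable base distribution with flat-Dirichlet noise under a
divergence knob: knob 0 makes all sources identical, larger knobs increase
expected pairwise MJSD. Mosaic genomes concatenate blocks sampled from
given sources with a truth BED; shotgun reads have length-proportional
genome choice, uniform start and strand, and i.i.d. substitution errors to
a uniformly chosen different base (constant "I" qualities — the classifier
ignores them). It does **not** emulate indels, quality-correlated errors,
shared ancestry between taxa, or abundance skew — so passing tests
demonstrate the machinery's correctness and its behaviour on
well-separated communities, not performance on real metagenomes, where
taxa are phylogenetically correlated and databases incomplete.

Desk-scale study conditions used by the acceptance run: 4 single-source
100 kb genomes at knob 0.8, order 10, 5,000 calibration fragments, 2,000
error-free 100 nt reads; segmentation exactness on 50 random sequences of
1.2–5 kb at m = 0–2; calibration recovery at n = 20,000 and decile
calibration at n = 50,000.

## Known limitations

- The analytic split-significance null is an approximation; its effective
  candidate correction was calibrated on homogeneous sequences of 2–20 kb
  at m ≤ 2. Outside that regime, use the Monte-Carlo mode.
- Agglomerative clustering is O(S³) in the number of segments — fine for
  per-genome segment counts, not for pooling segments across thousands of
  genomes.
- No lowest-common-ancestor logic: ranks are gated independently from one
  genome's lineage, and first-pass taxa pass through verbatim with no
  taxonomy-tree reconciliation.
- Paired-end pairing, quality trimming, and any network retrieval of
  genomes are out of scope; genomes are always local FASTA paths.
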