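# smmtax

Alignment-free taxonomic classification of shotgun metagenomic reads with
fixed-order Markov models of genomes and calibrated assignment
probabilities.

Exact-k-mer classifiers (Kraken2 and kin) are fast and precise but leave a
large fraction of reads unclassified whenever the source organism — or any
close relative — is missing from their database. Markov-model scoring is
the classical alignment-free alternative: it always produces a best-matching
genome, but a raw log-likelihood says nothing about whether that match
should be *trusted*. `smmtax` addresses both problems for microbiome
researchers who need higher sensitivity at chosen confidence:

- **Genome models.** For each genome, an order-k standard Markov model
  (k = 10–12 validated) is built on the fly: an initial k-mer distribution
  P(w) and transitions P(x | w), both pseudocount-smoothed, in one reusable
  table that is reset per genome so memory stays flat in the database size.
- **Read scoring.** A read's raw score against a genome is its total
  log-likelihood, log P(w₁..k) + Σᵢ log P(xᵢ | xᵢ₋ₖ..xᵢ₋₁), maximised over
  strands.
- **Score calibration.** Per (taxonomic rank, model order), a logistic
  model maps (raw score, read length) to the probability that the implied
  taxon assignment is correct; an assignment is made only above a cutoff
  (default 0.25). Calibration data are labeled genome fragments sampled
  from compositionally homogeneous clusters found by recursive Markovian
  Jensen–Shannon divergence (MJSD) segmentation — so horizontally acquired
  islands and other atypical regions are represented, not averaged away.
- **Hybrid mode.** Run after a first-pass exact-k-mer classifier, scoring
  only the reads it left unclassified, and merge — first-pass calls are
  never altered.
- **Benchmarking.** Per-rank sensitivity A/B, precision X/(X+Z) and F1,
  with unclassified reads counting against sensitivity but not precision.

A synthetic-data module generates mosaic genomes from parameterized Markov
sources, toy taxonomies, and error-bearing shotgun reads with full truth
tables, so the whole pipeline runs and is tested without any download.

## Worked example

```python
import tempfile, pathlib
from smmtax import synth, seqio
from smmtax.estimators import MarkovTaxonomyClassifier
from smmtax.classify import assignments_for_rank
from smmtax.metrics import tally, compute_metrics

workdir = pathlib.Path(tempfile.mkdtemp())
genomes, lineages = synth.community(4, 100_000, divergence_knob=0.8, seed=0)
paths = []
for rec in genomes:
    path = workdir / f"{rec.id}.fasta"
    seqio.write_fasta(path, [rec])
    paths.append(str(path))

clf = MarkovTaxonomyClassifier(order=10, n_fragments=5000, seed=0)
clf.fit(paths, lineages)          # segment, cluster, sample, calibrate

reads, truth = synth.simulate_reads(
    genomes, synth.ReadSimSpec(n_reads=2000, length=100, error_rate=0.02, seed=1)
)
assignments = clf.predict_assignments(reads, cutoff=0.25)
truth_lineages = {rid: lineages[gid] for rid, gid, _, _ in truth}
for rank in ("phylum", "genus", "species"):
    cc = tally(assignments_for_rank(assignments, rank), truth_lineages, rank)
    m = compute_metrics(cc)
    print(f"{rank:8s} sensitivity={m.sensitivity:.4f} "
          f"precision={m.precision:.4f} f1={m.f1:.4f}")
```

prints

```
phylum   sensitivity=0.9925 precision=1.0000 f1=0.9962
genus    sensitivity=0.9925 precision=1.0000 f1=0.9962
species  sensitivity=0.9925 precision=1.0000 f1=0.9962
```

Four well-separated 100 kb genomes, 2,000 reads at 2% substitution error:
at the 0.25 cutoff a handful of reads fall below the calibrated
probability and stay unclassified (sensitivity 0.9925), while every made
assignment is correct (precision 1.0). The ranks agree because each toy
genome carries a distinct lineage at every rank.

The same pipeline is available from the shell:

```bash
smmtax simulate --n-genomes 4 --output sim
smmtax build-trainset --genomes-dir sim/genomes --lineage sim/lineage.tsv --output ts
smmtax train-models --trainset-dir ts --budget 0 --output models
smmtax classify --reads sim/reads.fastq --genomes-dir sim/genomes \
    --lineage sim/lineage.tsv --models-dir models --output out
smmtax evaluate --assignments out/assignments.tsv --truth sim/truth.tsv \
    --lineage sim/lineage.tsv --output eval
```

plus `segment` (MJSD segmentation/clustering to BED/TSV) and `hybrid`
(merge with a Kraken2-style per-read file).

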