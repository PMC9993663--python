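"""The end-to-end classifier as a scikit-learn-style estimator.

``MarkovTaxonomyClassifier.fit`` takes genome FASTA paths plus a lineage
map and builds the full calibration stack: MJSD segmentation and
clustering of each genome, fragment sampling from the retained
clusters, one scoring pass of the fragments against the genome panel,
and a per-rank logistic calibration fit. ``predict`` then classifies
reads, returning the per-rank assignments. Genome Markov models are
rebuilt on the fly at predict time (no model database).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .calibrate import HyperparameterSpace, ScoreModel, cv_search, fit_logistic
from .classify import Assignment, ClassifierConfig, classify_reads
from .mjsd import Cluster, MJSDSegmenter, Segment, count_contexts
from .seqio import RANKS, LineageMap, SequenceRecord, read_fasta
from .smm import score_reads_against_genomes
from .trainset import TrainingConfig, build_training_dataset, sample_fragments


class MarkovTaxonomyClassifier:
    """Alignment-free taxonomic read classifier with calibrated scores.

    Parameters
    ----------
    order : Markov model order k (validated range 10-12).
    delta : transition pseudocount.
    cutoff : assignment probability threshold, default 0.25.
    n_fragments : calibration fragments sampled across the panel.
    cv_budget : hyperparameter candidates per rank model; 0 fits a
        single default-parameter logistic instead of searching.
    min_segment_len, alpha_segment, p_cluster, min_cluster_frac, m :
        segmentation/clustering settings (see mjsd module).
    seed : master seed for fragment sampling and the CV search.
    workers : genome-parallel scoring workers.

    Fitted attributes: ``score_models_`` (rank -> ScoreModel),
    ``clusters_by_genome_``, ``genome_paths_``, ``lineage_map_``.
    """

    def __init__(
        self,
        order: int = 10,
        delta: float = 1.0,
        cutoff: float = 0.25,
        n_fragments: int = 5000,
        cv_budget: int = 0,
        top_n: int = 50,
        min_len: int = 30,
        max_len: int = 500,
        m: int = 2,
        alpha_segment: float = 0.05,
        p_cluster: float = 1e-5,
        min_segment_len: int = 5000,
        min_cluster_frac: float = 1e-5,
        seed: int = 0,
        workers: int = 1,
    ):
        self.order = order
        self.delta = delta
        self.cutoff = cutoff
        self.n_fragments = n_fragments
        self.cv_budget = cv_budget
        self.top_n = top_n
        self.min_len = min_len
        self.max_len = max_len
        self.m = m
        self.alpha_segment = alpha_segment
        self.p_cluster = p_cluster
        self.min_segment_len = min_segment_len
        self.min_cluster_frac = min_cluster_frac
        self.seed = seed
        self.workers = workers

    _param_names = (
        "order", "delta", "cutoff", "n_fragments", "cv_budget", "top_n",
        "min_len", "max_len", "m", "alpha_segment", "p_cluster",
        "min_segment_len", "min_cluster_frac", "seed", "workers",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params) -> "MarkovTaxonomyClassifier":
        for key, value in params.items():
            if key not in self._param_names:
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- fitting ----------------------------------------------------------

    def _segment_genome_file(self, path: str) -> tuple[str, str, list[Cluster]]:
        """Returns (genome_id, sequence, retained clusters).

        Multi-record files are joined with ambiguous spacers so no
        context window spans a record boundary; coordinates refer to
        the joined string.
        """
        records = read_fasta(path)
        if not records:
            raise ValueError(f"genome file {path} contains no sequences")
        spacer = "N" * (self.m + 1)
        seq = spacer.join(rec.residues for rec in records)
        from .smm import _genome_id_from_path

        genome_id = _genome_id_from_path(str(path), records)
        seg = MJSDSegmenter(
            m=self.m,
            alpha_segment=self.alpha_segment,
            p_cluster=self.p_cluster,
            min_segment_len=self.min_segment_len,
            min_cluster_frac=self.min_cluster_frac,
        ).fit(seq)
        clusters = seg.retained_clusters_
        if not clusters:  # size filter ate everything; fall back to one segment
            whole = Segment(0, len(seq), count_contexts(seq, self.m))
            clusters = [Cluster([whole], whole.profile)]
        return genome_id, seq, clusters

    def fit(self, genome_paths: Sequence[str], lineage_map: LineageMap) -> "MarkovTaxonomyClassifier":
        rng = np.random.default_rng(self.seed)
        clusters_by_genome: dict[str, list[Cluster]] = {}
        sequences: dict[str, str] = {}
        for path in genome_paths:
            gid, seq, clusters = self._segment_genome_file(str(path))
            clusters_by_genome[gid] = clusters
            sequences[gid] = seq
        config = TrainingConfig(
            min_len=self.min_len,
            max_len=self.max_len,
            reads_per_dataset=self.n_fragments,
            top_n=self.top_n,
            rng_seed=self.seed,
        )
        fragments = sample_fragments(
            clusters_by_genome, sequences, lineage_map, config, rng
        )
        frag_reads = [frag for frag, _ in fragments]
        score_table = score_reads_against_genomes(
            frag_reads, [str(p) for p in genome_paths], self.order,
            delta=self.delta, workers=self.workers,
        )
        self.score_models_: dict[str, ScoreModel] = {}
        for rank in RANKS:
            examples = build_training_dataset(
                fragments, [str(p) for p in genome_paths], lineage_map, rank,
                self.order, config, score_table=score_table,
            )
            if self.cv_budget > 0:
                model, _log = cv_search(
                    examples,
                    HyperparameterSpace(),
                    budget=self.cv_budget,
                    rng=np.random.default_rng(self.seed + 1),
                    rank=rank,
                    order=self.order,
                )
            else:
                model = fit_logistic(examples, rank=rank, order=self.order, seed=self.seed)
            self.score_models_[rank] = model
        self.clusters_by_genome_ = clusters_by_genome
        self.genome_paths_ = [str(p) for p in genome_paths]
        self.lineage_map_ = lineage_map
        return self

    # -- prediction -------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "score_models_"):
            raise RuntimeError("classifier is not fitted; call fit() first")

    def predict_assignments(
        self, reads: Sequence[SequenceRecord], cutoff: float | None = None
    ) -> list[Assignment]:
        self._check_fitted()
        config = ClassifierConfig(
            order=self.order,
            cutoff=self.cutoff if cutoff is None else cutoff,
            workers=self.workers,
        )
        return classify_reads(
            reads, self.genome_paths_, self.lineage_map_, self.score_models_, config
        )

    def predict(self, reads: Sequence[SequenceRecord], rank: str = "genus") -> np.ndarray:
        """Assigned taxon at ``rank`` per read ('NA' where unassigned)."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        assignments = self.predict_assignments(reads)
        return np.array(
            [a.taxa[rank] if a.assigned[rank] else "NA" for a in assignments]
        )
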