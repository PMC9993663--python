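import math
import warnings
from fractions import Fraction

import numpy as np
import pytest

from smmtax.seqio import SequenceRecord
from smmtax.smm import (
    ScoreTable,
    build_model,
    score_read,
    score_reads_against_genomes,
    top_n,
)
from smmtax.synth import ReadSimSpec, community, simulate_reads

from _oracles import brute_force_score as _oracle_score

pytestmark = pytest.mark.filterwarnings("ignore:order .* outside the validated range")


class TestBuildModel:
    def test_pseudocount_arithmetic_on_homopolymer(self):
        # 1000 A's at k=2: 998 observed AA->A transitions, delta=1 smoothing
        model = build_model([SequenceRecord("g", "A" * 1000)], k=2, delta=1.0)
        assert math.exp(model.transition_logprob[0, 0]) == pytest.approx(999 / 1002, abs=1e-12)

    def test_genome_shorter_than_k_gives_uniform_model(self):
        model = build_model([SequenceRecord("g", "A")], k=3)
        assert np.allclose(np.exp(model.transition_logprob), 0.25)
        assert np.allclose(np.exp(model.initial_logprob), 1 / 4**3)

    def test_no_context_spans_record_boundary(self):
        model = build_model([SequenceRecord("a", "AAA"), SequenceRecord("b", "CCC")], k=2)
        # context "AC" (code 1) was never observed: pure pseudocount row
        assert np.allclose(np.exp(model.transition_logprob[1]), 0.25)

    @pytest.mark.parametrize("k", [1, 2, 4, 6])
    def test_probability_conservation_per_context(self, rng, k):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        model = build_model([SequenceRecord("g", seq)], k=k)
        assert np.allclose(model.transition_prob_sums(), 1.0, atol=1e-9)
        assert model.initial_prob_sum() == pytest.approx(1.0, abs=1e-6)

    def test_order_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_model([SequenceRecord("g", "ACGT")], k=15)
        with pytest.raises(ValueError):
            build_model([SequenceRecord("g", "ACGT")], k=0)

    def test_nonvalidated_order_warns(self):
        with pytest.warns(UserWarning, match="validated"):
            warnings.simplefilter("always")
            build_model([SequenceRecord("g", "ACGTACGT")], k=2)


class TestScoreRead:
    def test_uniform_model_closed_form(self):
        model = build_model([SequenceRecord("g", "A")], k=2)
        read = SequenceRecord("r", "ACGTACGTACGTACG")
        assert score_read(model, read) == pytest.approx(-15 * math.log(4), abs=1e-9)

    @pytest.mark.parametrize("k", [2, 4, 6, 8])
    def test_matches_brute_force_oracle(self, rng, k):
        for _ in range(5):
            genome = "".join(rng.choice(list("ACGT"), size=int(rng.integers(500, 3000))))
            read = "".join(rng.choice(list("ACGT"), size=int(rng.integers(k + 2, 200))))
            model = build_model([SequenceRecord("g", genome)], k=k)
            expected = _oracle_score([SequenceRecord("g", genome)], k, 1.0, read)
            assert score_read(model, SequenceRecord("r", read)) == pytest.approx(expected, abs=1e-9)

    def test_reverse_complement_palindrome_scores_equal_per_strand(self, rng):
        genome = "".join(rng.choice(list("ACGT"), size=2000))
        model = build_model([SequenceRecord("g", genome)], k=3)
        read = "ACGCGT"  # its own reverse complement
        fwd_only = score_read(model, SequenceRecord("r", read), both_strands=False)
        both = score_read(model, SequenceRecord("r", read), both_strands=True)
        assert fwd_only == pytest.approx(both, abs=1e-12)

    def test_read_shorter_than_k_plus_1_unscorable(self):
        model = build_model([SequenceRecord("g", "ACGTACGT")], k=4)
        assert score_read(model, SequenceRecord("r", "ACG")) is None

    def test_ambiguous_windows_skipped(self):
        model = build_model([SequenceRecord("g", "A" * 100)], k=2)
        clean = score_read(model, SequenceRecord("r", "AAAA"), both_strands=False)
        # N kills every window covering it; only the leading AAAA block scores
        with_n = score_read(model, SequenceRecord("r", "AAAANAA"), both_strands=False)
        assert with_n == pytest.approx(clean, abs=1e-12)

    def test_score_additivity_with_shared_junction_context(self, rng):
        genome = "".join(rng.choice(list("ACGT"), size=2000))
        model = build_model([SequenceRecord("g", genome)], k=2)
        a = "ACGTAC"
        b = a[-2:] + "GGTT"  # b starts with a's last k bases
        concat = a + b[2:]
        sa = score_read(model, SequenceRecord("a", a), both_strands=False)
        sb = score_read(model, SequenceRecord("b", b), both_strands=False)
        s_concat = score_read(model, SequenceRecord("c", concat), both_strands=False)
        initial_b = model.initial_logprob[_code(b[:2])]
        assert s_concat == pytest.approx(sa + sb - initial_b, abs=1e-9)


def _code(kmer):
    value = 0
    for base in kmer:
        value = value * 4 + "ACGT".index(base)
    return value


class TestScoreTable:
    def test_equals_cross_product_of_score_read(self, tmp_path, rng):
        from smmtax.seqio import write_fasta

        genomes, paths = [], []
        for i in range(2):
            seq = "".join(rng.choice(list("ACGT"), size=1500))
            rec = SequenceRecord(f"G{i}", seq)
            genomes.append(rec)
            path = tmp_path / f"G{i}.fasta"
            write_fasta(path, [rec])
            paths.append(str(path))
        reads = [
            SequenceRecord(f"r{i}", "".join(rng.choice(list("ACGT"), size=80)))
            for i in range(3)
        ]
        table = score_reads_against_genomes(reads, paths, k=4)
        assert len(table) == 3
        for read in reads:
            scores = {rs.genome_id: rs.raw_score for rs in table[read.id]}
            assert len(scores) == 2
            for rec in genomes:
                model = build_model([rec], k=4)
                assert scores[rec.id] == pytest.approx(
                    score_read(model, read), abs=1e-9
                )
            values = [rs.raw_score for rs in table[read.id]]
            assert values == sorted(values, reverse=True)

    def test_worker_count_does_not_change_result(self, tmp_path, rng):
        from smmtax.seqio import write_fasta

        paths = []
        for i in range(5):
            rec = SequenceRecord(f"G{i}", "".join(rng.choice(list("ACGT"), size=1000)))
            path = tmp_path / f"G{i}.fasta"
            write_fasta(path, [rec])
            paths.append(str(path))
        reads = [
            SequenceRecord(f"r{i}", "".join(rng.choice(list("ACGT"), size=60)))
            for i in range(4)
        ]
        t1 = score_reads_against_genomes(reads, paths, k=3, workers=1)
        t4 = score_reads_against_genomes(reads, paths, k=3, workers=4)
        assert t1.scores == t4.scores

    def test_unscorable_reads_tracked_not_scored(self, tmp_path):
        from smmtax.seqio import write_fasta

        path = tmp_path / "g.fasta"
        write_fasta(path, [SequenceRecord("g", "ACGTACGTACGT" * 10)])
        reads = [SequenceRecord("ok", "ACGTACGT"), SequenceRecord("short", "AC")]
        table = score_reads_against_genomes(reads, [str(path)], k=4)
        assert table.unscorable == ["short"]
        assert set(table.scores) == {"ok"}

    def test_top_n_truncation(self):
        from smmtax.smm import ReadScore

        lst = [ReadScore("r", f"G{i}", -float(i), 50) for i in range(10)]
        table = ScoreTable(scores={"r": lst})
        assert len(top_n(table, 50)["r"]) == 10
        assert len(top_n(table, 3)["r"]) == 3
        assert top_n(table, 1)["r"][0].genome_id == "G0"
        with pytest.raises(ValueError):
            top_n(table, 0)


class TestRecognition:
    def test_self_recognition_on_separated_genomes(self, community_dir):
        """Error-free reads at k=10 should score their source genome highest."""
        genomes = community_dir["genomes"][:2]
        reads, truth = simulate_reads(
            genomes, ReadSimSpec(n_reads=200, length=100, error_rate=0.0, seed=5)
        )
        paths = community_dir["paths"][:2]
        table = score_reads_against_genomes(reads, paths, k=10)
        source = {rid: gid for rid, gid, _, _ in truth}
        hits = sum(table.best(r.id).genome_id == source[r.id] for r in reads)
        assert hits / len(reads) >= 0.95

    def test_score_margin_degrades_with_error_rate(self, community_dir):
        genomes = community_dir["genomes"][:2]
        paths = community_dir["paths"][:2]
        margins = []
        for eps in (0.0, 0.05, 0.10):
            reads, _ = simulate_reads(
                genomes, ReadSimSpec(n_reads=100, length=100, error_rate=eps, seed=6)
            )
            table = score_reads_against_genomes(reads, paths, k=10)
            margin = np.mean(
                [table[r.id][0].raw_score - table[r.id][1].raw_score for r in reads]
            )
            margins.append(margin)
        assert margins[0] > margins[1] > margins[2]
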