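import itertools

import numpy as np
import pytest

from beacongrn.data_io import GeneAnnotation
from beacongrn.motif import (
    PWM,
    LogOddsMatrix,
    classify_targets,
    extract_promoters,
    log_odds,
    read_meme_motifs,
    scan_promoters,
    scan_sequence,
    score_pvalue,
    secondary_cascade,
    write_meme_motifs,
)
from beacongrn.synthio import demo_pwm

MEME_TWO = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.3 C 0.2 G 0.2 T 0.3

MOTIF M1
letter-probability matrix: alength= 4 w= 3 nsites= 20 E= 0
0.8 0.1 0.05 0.05
0.25 0.25 0.25 0.25
0.1 0.1 0.1 0.7

MOTIF M2
letter-probability matrix: alength= 4 w= 2 nsites= 20 E= 0
0.25 0.25 0.25 0.25
0.25 0.25 0.25 0.25
"""


def brute_force_pvalues(mat: LogOddsMatrix):
    """Enumerate all 4^L windows with the integer score matrix (independent path)."""
    L = mat.length
    scores = []
    for word in itertools.product(range(4), repeat=L):
        scores.append(sum(int(mat.int_matrix[i, b]) for i, b in enumerate(word)))
    scores = np.array(scores)
    weights = []
    for word in itertools.product(range(4), repeat=L):
        w = 1.0
        for b in word:
            w *= mat.background[b]
        weights.append(w)
    return scores, np.array(weights)


class TestMemeFormat:
    def test_two_motifs_with_background(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(MEME_TWO)
        motifs = read_meme_motifs(path)
        assert [m.motif_id for m in motifs] == ["M1", "M2"]
        assert [m.length for m in motifs] == [3, 2]
        assert motifs[0].background == pytest.approx([0.3, 0.2, 0.2, 0.3])

    def test_uniform_pwm_accepted(self):
        PWM("u", np.full((4, 4), 0.25))

    def test_bad_column_sum_rejected(self, tmp_path):
        bad = MEME_TWO.replace("0.1 0.1 0.1 0.7", "0.1 0.1 0.1 0.5")
        path = tmp_path / "bad.meme"
        path.write_text(bad)
        with pytest.raises(ValueError, match="M1"):
            read_meme_motifs(path)

    def test_write_read_round_trip(self, tmp_path):
        pwm = demo_pwm(8, seed=3)
        write_meme_motifs([pwm], tmp_path / "w.meme")
        back = read_meme_motifs(tmp_path / "w.meme")[0]
        assert np.allclose(back.probs, pwm.probs, atol=1e-6)


class TestPromoters:
    GENOME = {"chr1": "ACGT" * 3000}

    def test_plus_strand_full_3000(self):
        anns = [GeneAnnotation("g", "chr1", "+", 5000, 5100)]
        proms, skipped = extract_promoters(self.GENOME, anns, ["g"])
        p = proms["g"]
        assert (p.start, p.end) == (2000, 4999)
        assert len(p.sequence) == 3000
        assert p.sequence == self.GENOME["chr1"][1999:4999]

    def test_plus_strand_truncated_by_neighbour(self):
        anns = [
            GeneAnnotation("up", "chr1", "+", 3000, 3500),
            GeneAnnotation("g", "chr1", "+", 5000, 5100),
        ]
        proms, _ = extract_promoters(self.GENOME, anns, ["g"])
        assert (proms["g"].start, proms["g"].end) == (3501, 4999)
        assert len(proms["g"].sequence) == 1499

    def test_minus_strand_reverse_complement(self):
        anns = [GeneAnnotation("g", "chr1", "-", 100, 200)]
        proms, _ = extract_promoters(self.GENOME, anns, ["g"])
        fwd = self.GENOME["chr1"][200:3200]
        rc = fwd.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert proms["g"].sequence == rc
        assert (proms["g"].start, proms["g"].end) == (201, 3200)

    def test_zero_length_region_skipped(self):
        anns = [GeneAnnotation("g", "chr1", "+", 1, 50)]
        proms, skipped = extract_promoters(self.GENOME, anns, ["g"])
        assert skipped == ["g"] and proms == {}

    def test_missing_gene_raises(self):
        with pytest.raises(KeyError, match="ghost"):
            extract_promoters(self.GENOME, [], ["ghost"])


class TestScoring:
    def test_uniform_pwm_scores_are_zero_without_pseudocount(self):
        mat = log_odds(PWM("u", np.full((3, 4), 0.25)), pseudocount=1e-12)
        assert np.allclose(mat.matrix, 0.0, atol=1e-9)

    def test_deterministic_column_log_odds(self):
        probs = np.zeros((1, 4))
        probs[0, 0] = 1.0
        mat = log_odds(PWM("d", probs), pseudocount=0.01)
        assert mat.matrix[0, 0] == pytest.approx(np.log2(1.0025 / (1.01 * 0.25)))
        assert mat.matrix[0, 1] == pytest.approx(np.log2(0.0025 / (1.01 * 0.25)))

    def test_sequence_score_is_sum_of_columns(self):
        pwm = demo_pwm(5, seed=9)
        mat = log_odds(pwm)
        seq = pwm.consensus
        hit = scan_sequence(seq, mat)[0]
        expected = sum(mat.int_matrix[i, "ACGT".index(b)] for i, b in enumerate(seq)) / 1000
        assert hit[2] == pytest.approx(expected)

    def test_consensus_scores_maximum_at_first_offset(self):
        pwm = demo_pwm(6, seed=2)
        mat = log_odds(pwm)
        hits = scan_sequence("TTTT" + pwm.consensus + "TTTT", mat)
        best = max(hits, key=lambda h: h[2])
        assert best[0] == 5
        assert best[2] == pytest.approx(mat.int_matrix.max(axis=1).sum() / 1000)

    def test_palindromic_motif_scores_equal_on_both_strands(self):
        # ACGT consensus is its own reverse complement
        probs = np.full((4, 4), 0.04)
        for i, b in enumerate("ACGT"):
            probs[i, "ACGT".index(b)] = 0.88
        mat = log_odds(PWM("pal", probs))
        fwd = mat.int_score("ACGT")
        rev = mat.int_score("ACGT"[::-1].translate(str.maketrans("ACGT", "TGCA")))
        assert fwd == rev

    def test_n_windows_skipped(self):
        mat = log_odds(demo_pwm(4, seed=1))
        assert scan_sequence("NNNNNNNN", mat) == []
        assert len(scan_sequence("ACGTNACGTACGT", mat)) < 13 - 4 + 1


class TestPValues:
    def test_sharp_trimer_consensus_pvalue(self):
        probs = np.full((3, 4), 0.01 / 3)
        probs[np.arange(3), [0, 1, 2]] = 0.99
        mat = log_odds(PWM("t", probs))
        assert score_pvalue(mat, mat.max_score()) == pytest.approx(1 / 64)

    def test_minimal_attainable_score_has_pvalue_one(self):
        mat = log_odds(demo_pwm(4, seed=4))
        min_attainable = mat.int_matrix.min(axis=1).sum() / 1000
        assert score_pvalue(mat, min_attainable) == pytest.approx(1.0)

    def test_monotone_nonincreasing_in_score(self):
        mat = log_odds(demo_pwm(5, seed=6))
        grid = np.linspace(mat.matrix.min(axis=1).sum(), mat.max_score(), 40)
        ps = [score_pvalue(mat, s) for s in grid]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_dp_matches_enumeration_random_pwms(self, rng):
        for L in (3, 4, 5, 6):
            probs = rng.dirichlet(np.ones(4) * 0.7, size=L)
            bg = rng.dirichlet(np.ones(4) * 5)
            mat = LogOddsMatrix(PWM("x", probs, bg))
            scores, weights = brute_force_pvalues(mat)
            for q in np.quantile(scores, [0.0, 0.3, 0.7, 1.0]):
                p_enum = weights[scores >= q].sum()
                assert mat.pvalue_int(int(np.ceil(q))) <= p_enum + 1e-6
                p_at = weights[scores >= int(np.floor(q))].sum()
                assert mat.pvalue_int(int(np.floor(q))) == pytest.approx(p_at, abs=1e-6)

    def test_reverse_complemented_promoter_mirrors_hits(self):
        pwm = demo_pwm(7, seed=8)
        mat = log_odds(pwm)
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=60)) + pwm.consensus + "ACGTACGT"
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        fwd_hits = {(h[0], h[2]) for h in scan_sequence(seq, mat)}
        rc_hits = {(len(seq) - (h[0] + mat.length - 1) + 1, h[2]) for h in scan_sequence(rc, mat)}
        assert fwd_hits == rc_hits


class TestClassification:
    def _promoters(self, genes):
        from beacongrn.motif import Promoter

        return {g: Promoter(g, "ACGT" * 25, "chr1", 1, 100, "+") for g in genes}

    def test_threshold_boundaries(self):
        from beacongrn.motif import MotifHit

        proms = self._promoters(["a", "b"])
        hits = [
            MotifHit("a", "M", 1, "+", 10.0, 5e-5),
            MotifHit("b", "M", 1, "+", 8.0, 1e-4),  # exactly alpha: not direct
        ]
        cl = classify_targets("R", {"a", "b", "c"}, hits, proms, alpha=1e-4)
        assert cl.direct == {"a"}
        assert cl.indirect == {"b"}
        assert cl.unscanned == {"c"}

    def test_partition_property(self, rng):
        genes = [f"g{i}" for i in range(12)]
        proms = self._promoters(genes[:9])
        from beacongrn.motif import MotifHit

        hits = [MotifHit(g, "M", 1, "+", 9.0, 1e-6) for g in genes[:4]]
        cl = classify_targets("R", set(genes), hits, proms)
        assert cl.direct | cl.indirect | cl.unscanned == set(genes)
        assert cl.direct & cl.indirect == set()
        assert cl.direct & cl.unscanned == set()

    def test_secondary_cascade_finds_planted_tf_targets(self):
        pwm_a = demo_pwm(8, seed=1)
        pwm_b = demo_pwm(8, seed=2)
        rng = np.random.default_rng(3)

        def prom(gene, planted=None):
            from beacongrn.motif import Promoter

            seq = list(rng.choice(list("ACGT"), size=200))
            if planted is not None:
                seq[50 : 50 + len(planted)] = list(planted)
            return Promoter(gene, "".join(seq), "chr1", 1, 200, "+")

        promoters = {
            "tfB": prom("tfB", pwm_a.consensus),   # direct target of A, itself a TF
            "x1": prom("x1", pwm_b.consensus),     # indirect for A, direct for B
            "x2": prom("x2"),                      # indirect for both
        }
        hits = scan_promoters(promoters, [pwm_a])
        primary = classify_targets("A", {"tfB", "x1", "x2"}, hits, promoters,
                                   motif_ids={pwm_a.motif_id})
        assert primary.direct == {"tfB"}
        result = secondary_cascade(
            primary, ["tfB", "other"], {"tfB": pwm_b}, promoters
        )
        assert "tfB" in result.secondary
        assert result.secondary["tfB"].direct == {"x1"}

    def test_secondary_tf_without_motif_flagged(self):
        from beacongrn.motif import TargetClassification

        primary = TargetClassification("A", {"tfB"}, {"x"}, set())
        result = secondary_cascade(primary, ["tfB"], {}, {})
        assert result.secondary == {}
        assert result.secondary_without_motif == {"tfB"}

    def test_no_tfs_among_direct_targets(self):
        from beacongrn.motif import TargetClassification

        primary = TargetClassification("A", {"g1"}, {"g2"}, set())
        result = secondary_cascade(primary, ["tfZ"], {}, {})
        assert result.secondary == {} and result.secondary_without_motif == set()
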