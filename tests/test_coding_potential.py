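"""Coding-potential scorers and the >=3-of-4 consensus vote."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cernapipe import seqmodels
from cernapipe.coding_potential import (
    consensus_classify,
    default_hexamer_models,
    fickett_score,
    fickett_value,
    hexamer_score,
    orf_score,
)
from cernapipe.synthetic_data import _sample_lncrna_sequence

SENSE = "GCT"  # alanine codon, not a stop


class TestOrfScore:
    def test_built_300nt_orf_votes_coding(self):
        seq = "ATG" + SENSE * 98 + "TAA"
        assert orf_score(seq) == (300, "coding")

    def test_no_start_codon_gives_zero(self):
        assert orf_score("CCCGGGCCC" * 10) == (0, "noncoding")

    def test_297nt_orf_is_below_threshold(self):
        seq = "ATG" + SENSE * 97 + "TAA"
        assert orf_score(seq) == (297, "noncoding")

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            orf_score("ATGXXX")


def _fickett_oracle(seq):
    """Independent table lookup (plain dict walk, no shared helpers)."""
    pos_prob = {"A": [0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36],
                "C": [0.29, 0.44, 0.55, 0.49, 0.52, 0.60, 0.60, 0.56, 0.51, 0.38],
                "G": [0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.66, 0.72, 0.83, 0.30],
                "T": [0.51, 0.60, 0.69, 0.64, 0.62, 0.67, 0.58, 0.48, 0.39, 0.24]}
    pos_w = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
    pos_para = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
    con_prob = {"A": [0.22, 0.20, 0.34, 0.45, 0.68, 0.58, 0.93, 0.84, 0.68, 0.94],
                "C": [0.23, 0.30, 0.33, 0.51, 0.48, 0.66, 0.81, 0.70, 0.70, 0.80],
                "G": [0.08, 0.08, 0.16, 0.27, 0.48, 0.53, 0.64, 0.74, 0.88, 0.90],
                "T": [0.09, 0.09, 0.20, 0.54, 0.44, 0.69, 0.68, 0.91, 0.97, 0.97]}
    con_w = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
    con_para = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.17, 0.0]
    total = 0.0
    for base in "ACGT":
        phases = [seq[i::3].count(base) for i in range(3)]
        position = max(phases) / (min(phases) + 1)
        content = seq.count(base) / len(seq)
        for para, prob in zip(pos_para, pos_prob[base]):
            if position >= para:
                total += prob * pos_w[base]
                break
        for para, prob in zip(con_para, con_prob[base]):
            if content >= para:
                total += prob * con_w[base]
                break
    return total


class TestFickett:
    def test_homopolymer_matches_table_oracle(self):
        seq = "A" * 600
        assert fickett_value(seq) == pytest.approx(_fickett_oracle(seq), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_sequences_match_table_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        assert fickett_value(seq) == pytest.approx(_fickett_oracle(seq), abs=1e-12)

    def test_reverse_complement_scored_independently(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        score_fwd, _ = fickett_score(seq)
        score_rc, _ = fickett_score(rc)
        assert isinstance(score_fwd, float) and isinstance(score_rc, float)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="200"):
            fickett_score("ACGT" * 10)


class TestHexamerScore:
    def test_identical_models_score_zero_noncoding(self):
        model = {h: 1.0 / 4096 for h in
                 ("".join(c) for c in itertools.product("ACGT", repeat=6))}
        score, vote = hexamer_score("ATGGCTGCTGCTTAA", model, model)
        assert score == 0.0 and vote == "noncoding"

    def test_coding_draws_score_positive(self):
        coding, noncoding = default_hexamer_models()
        rng = np.random.default_rng(11)
        positive = 0
        n = 1000
        for _ in range(n):
            seq = seqmodels.sample_coding_region(rng, 298)  # ~900 nt
            score, _ = hexamer_score(seq, coding, noncoding)
            positive += score > 0
        assert positive / n >= 0.99

    def test_sequence_shorter_than_hexamer_errors(self):
        coding, noncoding = default_hexamer_models()
        with pytest.raises(ValueError, match="hexamer"):
            hexamer_score("ACGTA", coding, noncoding)

    def test_empty_model_errors(self):
        with pytest.raises(ValueError, match="empty"):
            hexamer_score("ACGTAACGTA", {}, {"AAAAAA": 1.0})


def _external_table(ids, votes_by_id):
    rows = []
    for tid in ids:
        nc = votes_by_id[tid]  # tuple of 4 bools: True = noncoding vote
        rows.append({"transcript_id": tid,
                     "cpc": -1.0 if nc[0] else 1.0,
                     "cnci": -1.0 if nc[1] else 1.0,
                     "txcds": 100.0 if nc[2] else 700.0,
                     "pfam_hit": 0 if nc[3] else 1})
    return pd.DataFrame(rows).set_index("transcript_id")


class TestConsensus:
    @pytest.mark.parametrize("noncoding_votes,label", [
        ((True, True, True, False), "lncRNA"),   # 3 of 4 noncoding
        ((True, True, False, False), "mRNA"),    # only 2 noncoding
        ((True, True, True, True), "lncRNA"),
    ])
    def test_vote_rule(self, noncoding_votes, label):
        seqs = {"t1": "A" * 250}
        table = _external_table(["t1"], {"t1": noncoding_votes})
        (verdict,) = consensus_classify(seqs, external_scores=table)
        assert verdict.label == label
        assert verdict.n_noncoding_votes == sum(noncoding_votes)

    def test_short_transcript_is_too_short_regardless_of_votes(self):
        seqs = {"t1": "A" * 150}
        table = _external_table(["t1"], {"t1": (True, True, True, True)})
        (verdict,) = consensus_classify(seqs, external_scores=table)
        assert verdict.label == "too_short"

    def test_vote_counting_is_permutation_invariant(self):
        seqs = {"t1": "A" * 250}
        for combo in itertools.permutations([True, True, True, False]):
            table = _external_table(["t1"], {"t1": combo})
            (verdict,) = consensus_classify(seqs, external_scores=table)
            assert verdict.label == "lncRNA"

    def test_relaxing_min_votes_never_shrinks_lncrna_set(self):
        rng = np.random.default_rng(3)
        seqs = {}
        for i in range(30):
            if i % 2:
                seqs[f"t{i}"] = seqmodels.sample_mrna_sequence(rng, 150, 30, 60)[0]
            else:
                seqs[f"t{i}"] = seqmodels.sample_noncoding_sequence(rng, 500)
        strict = {v.transcript_id for v in consensus_classify(seqs, min_votes=3)
                  if v.label == "lncRNA"}
        relaxed = {v.transcript_id for v in consensus_classify(seqs, min_votes=2)
                   if v.label == "lncRNA"}
        assert strict <= relaxed

    def test_missing_sequences_error_lists_ids(self):
        with pytest.raises(ValueError, match="t_missing"):
            consensus_classify({"t1": "A" * 250}, required_ids=["t1", "t_missing"])

    def test_accuracy_on_generator_sequence_models(self):
        """>=95% consensus accuracy on 500 coding + 500 noncoding draws."""
        rng = np.random.default_rng(20)
        seqs, labels, hits = {}, {}, set()
        for i in range(500):
            tid = f"cod{i}"
            seqs[tid] = seqmodels.sample_mrna_sequence(
                rng, int(rng.integers(100, 401)), 50, 150)[0]
            labels[tid] = "mRNA"
            if rng.random() < 0.95:
                hits.add(tid)
        for i in range(500):
            tid = f"nc{i}"
            seqs[tid] = _sample_lncrna_sequence(rng, int(rng.integers(300, 2000)))
            labels[tid] = "lncRNA"
        verdicts = consensus_classify(seqs, domain_hits=hits)
        correct = sum(1 for v in verdicts if v.label == labels[v.transcript_id])
        assert correct / len(verdicts) >= 0.95
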