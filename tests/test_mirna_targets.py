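"""Penalty aligner, duplex energies, and the dual-criterion target scan."""

from functools import lru_cache

import numpy as np
import pytest

from cernapipe.mirna_targets import (
    duplex_energy,
    n_scan_windows,
    pair_kind,
    perfect_duplex_energy,
    position_weight,
    predict_mirna_targets,
    target_score,
)

_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def rc(rna: str) -> str:
    return "".join(_RC[b] for b in reversed(rna))


def alignment_oracle(mirna: str, window: str) -> float:
    """Exhaustive minimum over all gapped alignments (top-down recursion).

    Independent of the iterative DP: recurses over (miRNA consumed, window
    consumed) with the same cost model — substitution weights by miRNA
    position, deletion weighted at the deleted position, insertion weighted
    at the following miRNA position, window overhangs free at both ends.
    """
    wrev = window[::-1]
    m, n = len(mirna), len(wrev)

    def w(i):
        return 2.0 if 2 <= i <= 13 else 1.0

    def sub(i, j):
        kind = pair_kind(mirna[i - 1], wrev[j - 1])
        if kind in ("gc", "au"):
            return 0.0
        if kind == "gu":
            return 0.5 * w(i)
        return 1.0 * w(i)

    @lru_cache(maxsize=None)
    def best(i, j):
        if i == 0:
            return 0.0  # leading window overhang is free
        options = [best(i - 1, j) + 1.0 * w(i)]  # delete miRNA base i
        if j > 0:
            options.append(best(i - 1, j - 1) + sub(i, j))
            ins = 0.0 if i == m else 1.0 * w(min(i + 1, m))
            options.append(best(i, j - 1) + ins)
        return min(options)

    return min(best(m, j) for j in range(n + 1))


class TestTargetScore:
    def test_perfect_complement_scores_zero(self):
        mirna = "UGACCUAGGCAUUCAGGAACU"
        aln = target_score(mirna, rc(mirna))
        assert aln.penalty_score == 0.0
        assert aln.site_position == 0

    def test_single_wobble_in_seed_costs_one(self):
        mirna = "AAAACAAAAAAAAAAAAAAAA"  # C at position 5
        window = list(rc(mirna))
        # window base pairing miRNA position 5 sits at window index m-5
        window[len(mirna) - 5] = "U"  # C:G -> C:U? no -- make it G:U via miRNA G
        mirna = "AAAAGAAAAAAAAAAAAAAAA"
        window = list(rc(mirna))
        window[len(mirna) - 5] = "U"  # G pairs U as a wobble
        aln = target_score(mirna, "".join(window))
        assert aln.penalty_score == pytest.approx(1.0)  # 0.5 x seed weight 2

    def test_two_nonseed_mismatches_cost_two(self):
        mirna = "UGACCUAGGCAUUCAGGAACU"
        window = list(rc(mirna))
        for pos in (18, 20):  # miRNA positions outside 2..13
            idx = len(mirna) - pos
            base = mirna[pos - 1]
            window[idx] = next(b for b in "ACGU" if pair_kind(base, b) is None)
        aln = target_score(mirna, "".join(window))
        assert aln.penalty_score == pytest.approx(2.0)

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            target_score("ACGUX", "ACGU")

    @pytest.mark.parametrize("seed", range(10))
    def test_dp_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(6):
            m = int(rng.integers(4, 11))
            n = int(rng.integers(m, 14))
            mirna = "".join(rng.choice(list("ACGU"), size=m))
            window = "".join(rng.choice(list("ACGU"), size=n))
            aln = target_score(mirna, window)
            assert aln.penalty_score == pytest.approx(
                alignment_oracle(mirna, window), abs=1e-9)

    def test_flank_extension_never_hurts_and_keeps_perfect_sites(self):
        rng = np.random.default_rng(7)
        mirna = "".join(rng.choice(list("ACGU"), size=21))
        window = rc(mirna)
        extended = "CCCC" + window + "CCCC"
        assert target_score(mirna, extended).penalty_score <= \
            target_score(mirna, window).penalty_score
        assert target_score(mirna, extended).penalty_score == 0.0


class TestDuplexEnergy:
    def test_all_gc_perfect_duplex(self):
        mirna = "GCGCGCGCGC"
        energy, ratio = duplex_energy(mirna, rc(mirna))
        assert energy == pytest.approx(-30.0)
        assert ratio == pytest.approx(1.0)

    def test_unpairable_window_scores_zero(self):
        energy, ratio = duplex_energy("AAAAAAAAAA", "AAAAAAAAAA")  # A:A never pairs
        assert energy == 0.0 and ratio == 0.0

    def test_losing_one_au_pair_shifts_ratio_by_two_units(self):
        mirna = "UGACCUAGGCAUUCAGGAACA"  # position 21 is A (an A:U pair)
        perfect = perfect_duplex_energy(mirna)
        window = list(rc(mirna))
        window[0] = "C"  # breaks the pair at miRNA position 21 (A:C mismatch)
        energy, ratio = duplex_energy(mirna, "".join(window))
        assert ratio == pytest.approx((perfect + 2.0) / perfect)
        assert energy == pytest.approx(perfect + 2.0)


class TestPredictTargets:
    def test_planted_perfect_site_is_found(self):
        rng = np.random.default_rng(3)
        mirna = "".join(rng.choice(list("ACGU"), size=21))
        flanks = "".join(rng.choice(list("ACGU"), size=150))
        target = flanks[:80] + rc(mirna) + flanks[80:]
        edges = predict_mirna_targets({"miR1": mirna}, {"t1": target}, {"t1": "mRNA"})
        (edge,) = edges
        assert edge.penalty_score == 0.0
        assert edge.site_position == 80
        assert edge.edge_type == "mirna_mrna"

    def test_heavily_mismatched_site_is_rejected(self):
        mirna = "UGACCUAGGCAUUCAGGAACU"
        window = list(rc(mirna))
        for pos in (3, 5, 7, 9, 11):  # five seed mismatches: penalty 10
            idx = len(mirna) - pos
            window[idx] = next(b for b in "ACGU"
                               if pair_kind(mirna[pos - 1], b) is None)
        target = "A" * 50 + "".join(window) + "A" * 50
        edges = predict_mirna_targets({"miR1": mirna}, {"t1": target}, {"t1": "mRNA"})
        assert edges == []

    def test_dual_criterion_is_an_intersection(self):
        """Every emitted edge passes both cutoffs individually."""
        rng = np.random.default_rng(9)
        mirnas, targets, biotypes = {}, {}, {}
        for i in range(3):
            mi = "".join(rng.choice(list("ACGU"), size=21))
            mirnas[f"miR{i}"] = mi
            t = "".join(rng.choice(list("ACGU"), size=300))
            targets[f"t{i}"] = t[:100] + rc(mi) + t[100:]
            biotypes[f"t{i}"] = "lncRNA" if i % 2 else "mRNA"
        edges = predict_mirna_targets(mirnas, targets, biotypes,
                                      score_cutoff=4.0, ratio_cutoff=0.7)
        assert edges  # planted sites guarantee at least the diagonal pairs
        for e in edges:
            assert e.penalty_score <= 4.0
            assert e.energy_ratio >= 0.7

    def test_planted_recovery_and_false_positive_rate(self, default_bundle, recovery):
        """All planted sites recovered; spurious edges <= 5 per 1e6 windows."""
        _, bundle = default_bundle
        assert recovery["mirna_site_recall"] == 1.0
        planted = {(s["mirna"], s["target"])
                   for s in bundle.truth.planted_mirna_targets}
        biotypes = {m.transcript_id: ("lncRNA" if m.transcript_id.startswith("lncR")
                                      else "mRNA") for m in bundle.models}
        edges = predict_mirna_targets(bundle.mirna_seqs, bundle.transcript_seqs,
                                      biotypes)
        spurious = [e for e in edges if (e.regulator_id, e.target_id) not in planted]
        windows = n_scan_windows(bundle.mirna_seqs, bundle.transcript_seqs)
        assert len(spurious) / windows * 1e6 <= 5.0


def test_position_weight_convention():
    assert position_weight(1) == 1.0
    assert position_weight(2) == 2.0
    assert position_weight(13) == 2.0
    assert position_weight(14) == 1.0
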