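"""Correlation gate, 10-kb cis classification, and trans duplex energy."""

from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

from cernapipe.io_formats import ExpressionMatrix, TranscriptModel
from cernapipe.lncrna_targets import (
    classify_cis,
    correlation_gate,
    predict_lncrna_targets,
    trans_energy,
)
from cernapipe.synthetic_data import GeneratorConfig, generate_dataset, make_design, simulate_counts


class TestCorrelationGate:
    def test_linear_relation_passes(self):
        x = np.arange(6, dtype=float)
        res = correlation_gate(x, 2 * x + 1)
        assert res.pearson == pytest.approx(1.0)
        assert res.spearman == pytest.approx(1.0)
        assert res.passed

    def test_anticorrelation_fails_signed_threshold(self):
        x = np.arange(6, dtype=float)
        res = correlation_gate(x, -x)
        assert res.spearman == pytest.approx(-1.0)
        assert not res.passed

    def test_constant_vector_is_degenerate(self):
        res = correlation_gate([1.0] * 6, [1, 2, 3, 4, 5, 6])
        assert res.degenerate and not res.passed
        assert np.isnan(res.pearson)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            correlation_gate([1.0, 2.0], [1.0, 2.0])


def _model(tid, start, end, strand="+", chrom="chr1"):
    return TranscriptModel(tid, f"g_{tid}", chrom, strand, start, end,
                           exons=((start, end),))


def _cis_oracle(a_start, a_end, a_chrom, b_start, b_end, b_chrom, window=10_000):
    """Independent interval logic: order the spans, then measure the gap."""
    if a_chrom != b_chrom:
        return "trans_candidate"
    first, second = sorted([(a_start, a_end), (b_start, b_end)])
    if second[0] < first[1]:
        return "cis_overlap"
    return "cis_nonoverlap" if second[0] - first[1] <= window else "trans_candidate"


class TestClassifyCis:
    def test_antisense_overlap(self):
        mode, antisense = classify_cis(_model("l", 1000, 2000, "+"),
                                       _model("m", 1500, 3000, "-"))
        assert (mode, antisense) == ("cis_overlap", True)

    @pytest.mark.parametrize("gap,expected", [
        (9999, "cis_nonoverlap"), (10000, "cis_nonoverlap"), (10001, "trans_candidate"),
    ])
    def test_window_boundary_inclusive(self, gap, expected):
        mode, _ = classify_cis(_model("l", 1000, 2000), _model("m", 2000 + gap, 2000 + gap + 500))
        assert mode == expected

    def test_different_chromosome_is_trans(self):
        mode, _ = classify_cis(_model("l", 0, 100), _model("m", 0, 100, chrom="chr2"))
        assert mode == "trans_candidate"

    def test_matches_interval_oracle_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            a0 = int(rng.integers(0, 50_000)); a1 = a0 + int(rng.integers(1, 8000))
            b0 = int(rng.integers(0, 50_000)); b1 = b0 + int(rng.integers(1, 8000))
            chrom_b = "chr1" if rng.random() < 0.9 else "chr2"
            mode, _ = classify_cis(_model("l", a0, a1), _model("m", b0, b1, chrom=chrom_b))
            assert mode == _cis_oracle(a0, a1, "chr1", b0, b1, chrom_b)


def trans_oracle(a: str, b: str, loop: float = 8.0) -> float:
    """Exhaustive local-duplex minimum by top-down recursion (<= 30 nt)."""
    pairs = {("G", "C"): -3.0, ("C", "G"): -3.0, ("A", "U"): -2.0,
             ("U", "A"): -2.0, ("G", "U"): -1.0, ("U", "G"): -1.0}
    a = a.replace("T", "U")
    brev = b.replace("T", "U")[::-1]

    @lru_cache(maxsize=None)
    def h(i, j):
        if i == 0 or j == 0:
            return 0.0
        step = pairs.get((a[i - 1], brev[j - 1]), loop)
        return min(0.0, h(i - 1, j - 1) + step, h(i - 1, j) + loop, h(i, j - 1) + loop)

    return min(h(i, j) for i in range(len(a) + 1) for j in range(len(brev) + 1))


class TestTransEnergy:
    def test_ten_gc_pairs_hit_threshold_inclusively(self):
        lnc = "A" * 10 + "GCGCGCGCGC" + "A" * 10
        mrna = "A" * 10 + "GCGCGCGCGC" + "A" * 10  # reverse pairs the lnc run
        energy, passed = trans_energy(lnc, mrna)
        assert energy == pytest.approx(-30.0)
        assert passed

    def test_short_complementary_runs_fail(self):
        lnc = "ACA" * 10   # no complementary run beyond isolated pairs
        mrna = "CAC" * 10
        energy, passed = trans_energy(lnc, mrna)
        assert energy > -30.0 and not passed
        assert energy == pytest.approx(trans_oracle(lnc, mrna))

    def test_reverse_complement_of_self_passes(self):
        rng = np.random.default_rng(2)
        lnc = "".join(rng.choice(list("ACGU"), size=50, p=[0.2, 0.3, 0.3, 0.2]))
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        mrna = "".join(comp[b] for b in reversed(lnc))
        energy, passed = trans_energy(lnc, mrna)
        assert passed and energy <= -30.0

    @pytest.mark.parametrize("seed", range(8))
    def test_dp_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            a = "".join(rng.choice(list("ACGU"), size=int(rng.integers(20, 31))))
            b = "".join(rng.choice(list("ACGU"), size=int(rng.integers(20, 31))))
            energy, _ = trans_energy(a, b)
            assert energy == pytest.approx(trans_oracle(a, b), abs=1e-9)

    def test_sequences_below_20nt_rejected(self):
        with pytest.raises(ValueError, match="20"):
            trans_energy("ACGU" * 4, "ACGU" * 10)


def _expr(rows: dict[str, list[float]]) -> ExpressionMatrix:
    samples = [f"s{i}" for i in range(6)]
    return ExpressionMatrix(pd.DataFrame(rows, index=samples).T, unit="FPKM")


class TestPredictLncrnaTargets:
    def _setup(self, correlated: bool, lnc_start=1200, lnc_strand="-",
               lnc_seq=None, mrna_seq=None):
        lnc_seq = lnc_seq or "ACA" * 120
        mrna_seq = mrna_seq or "CAA" * 150
        models = [
            TranscriptModel("lnc1", "gl", "chr1", lnc_strand, lnc_start,
                            lnc_start + len(lnc_seq),
                            exons=((lnc_start, lnc_start + len(lnc_seq)),),
                            biotype="lncRNA"),
            TranscriptModel("m1", "gm", "chr1", "+", 1000, 1000 + len(mrna_seq),
                            exons=((1000, 1000 + len(mrna_seq)),), biotype="mRNA"),
        ]
        base = [10.0, 20.0, 35.0, 60.0, 90.0, 140.0]
        other = base if correlated else [90.0, 10.0, 140.0, 20.0, 60.0, 35.0]
        expr = _expr({"lnc1": base, "m1": other})
        return models, {"lnc1": lnc_seq, "m1": mrna_seq}, expr

    def test_correlated_antisense_pair_yields_cis_overlap_edge(self):
        models, seqs, expr = self._setup(correlated=True)
        (edge,) = predict_lncrna_targets(models, seqs, expr)
        assert edge.mode == "cis_overlap"
        assert edge.antisense is True

    def test_uncorrelated_pair_is_gated_out(self):
        models, seqs, expr = self._setup(correlated=False)
        assert predict_lncrna_targets(models, seqs, expr) == []

    def test_correlated_distal_pair_without_complementarity_fails_trans(self):
        models, seqs, expr = self._setup(correlated=True, lnc_start=500_000)
        assert predict_lncrna_targets(models, seqs, expr) == []

    def test_correlated_distal_pair_with_complement_is_trans(self):
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        mrna_seq = "CAA" * 150
        stretch = mrna_seq[100:130]
        insert = "".join(comp[b] for b in reversed(stretch))
        lnc_seq = "ACA" * 40 + insert + "ACA" * 40
        models, seqs, expr = self._setup(correlated=True, lnc_start=500_000,
                                         lnc_seq=lnc_seq, mrna_seq=mrna_seq)
        (edge,) = predict_lncrna_targets(models, seqs, expr)
        assert edge.mode == "trans"
        assert edge.energy <= -30.0

    def test_expression_feature_missing_from_models_errors(self):
        models, seqs, expr = self._setup(correlated=True)
        expr.data.loc["ghost"] = 1.0
        with pytest.raises(ValueError, match="ghost"):
            predict_lncrna_targets(models, seqs, expr)

    def test_edge_modes_partition_pairs(self, default_bundle, pipeline_runs):
        from cernapipe.io_formats import read_edges

        edges = read_edges(pipeline_runs[0]["dir"] / "edges_lncrna.tsv")
        pairs = [(e.regulator_id, e.target_id) for e in edges]
        assert len(pairs) == len(set(pairs))
        assert all(e.mode in ("cis_overlap", "cis_nonoverlap", "trans") for e in edges)


class TestPlantedPairRecovery:
    def test_recall_per_relation_over_twenty_seeds(self):
        """Gate + geometry + trans energy recover >=90% of planted pairs.

        Uses the same criteria the predictor applies, evaluated per planted
        pair across 20 generator seeds at default settings.
        """
        hits = {"antisense_overlap": 0, "neighbor_lt10kb": 0, "distal_correlated": 0}
        totals = dict.fromkeys(hits, 0)
        for seed in range(20):
            cfg = GeneratorConfig(seed=seed)
            bundle = generate_dataset(cfg)
            by_id = {m.transcript_id: m for m in bundle.models}
            counts = bundle.counts_rna.data
            for pair in bundle.truth.planted_lnc_pairs:
                lnc, mrna = pair["lncrna"], pair["mrna"]
                x = counts.loc[lnc].to_numpy()
                y = counts.loc[mrna].to_numpy()
                gate = correlation_gate(np.log2(x + 1), np.log2(y + 1))
                totals[pair["relation"]] += 1
                if not gate.passed:
                    continue
                mode, _ = classify_cis(by_id[lnc], by_id[mrna])
                if pair["relation"] == "distal_correlated":
                    ok = (mode == "trans_candidate"
                          and trans_energy(bundle.transcript_seqs[lnc],
                                           bundle.transcript_seqs[mrna])[1])
                elif pair["relation"] == "antisense_overlap":
                    ok = mode == "cis_overlap"
                else:
                    ok = mode == "cis_nonoverlap"
                hits[pair["relation"]] += ok
        for relation in hits:
            assert hits[relation] / totals[relation] >= 0.9, (relation, hits, totals)
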