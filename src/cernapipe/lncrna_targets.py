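"""lncRNA -> mRNA target assignment: correlation gate, cis window, trans duplex.

A candidate pair must first pass an expression-correlation gate (signed
Spearman AND Pearson >= 0.6 by default).  Pairs co-located within a 10-kb
genomic window are cis targets (``cis_overlap`` when the spans intersect,
with an antisense flag when strands differ; ``cis_nonoverlap`` otherwise);
all other pairs are trans candidates and are kept only when the best local
antiparallel duplex between the two sequences reaches -30 kcal/mol
(inclusive), the conventional hybridization cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import ExpressionMatrix, InteractionEdge, TranscriptModel

# Local-duplex parameters: per-pair energies (kcal/mol) plus a positive
# penalty per mismatched or looped-out position.  The penalty is
# deliberately large: with kilobase sequences a small penalty would let
# random pairing drift past any threshold (see docs/methods.md).
TRANS_PAIR_ENERGY = {"gc": -3.0, "au": -2.0, "gu": -1.0}
TRANS_LOOP_PENALTY = 8.0
DEFAULT_ENERGY_THRESHOLD = -30.0

_RNA = "ACGU"
_CODE = {b: i for i, b in enumerate(_RNA)}


@dataclass
class GateResult:
    pearson: float
    spearman: float
    passed: bool
    degenerate: bool = False  # zero-variance input; correlations undefined


def correlation_gate(
    expr_a: Sequence[float],
    expr_b: Sequence[float],
    spearman_min: float = 0.6,
    pearson_min: float = 0.6,
) -> GateResult:
    """Signed Pearson (on values) and Spearman (on average ranks) gate.

    Vectors must have equal length >= 3.  A zero-variance vector makes
    both coefficients undefined: the pair fails and is flagged.
    """
    x = np.asarray(expr_a, dtype=float)
    y = np.asarray(expr_b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expression vectors must be 1-D and equally long")
    if x.size < 3:
        raise ValueError("correlation gate requires >= 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return GateResult(float("nan"), float("nan"), passed=False, degenerate=True)
    pearson = float(stats.pearsonr(x, y)[0])
    spearman = float(stats.spearmanr(x, y)[0])
    return GateResult(pearson, spearman,
                      passed=(pearson >= pearson_min and spearman >= spearman_min))


def classify_cis(
    lnc: TranscriptModel, mrna: TranscriptModel, window: int = 10_000
) -> tuple[str, bool]:
    """(mode, antisense) for a lncRNA/mRNA pair by genomic position.

    Different chromosomes -> ``trans_candidate``.  Intersecting spans ->
    ``cis_overlap`` (antisense iff strands differ).  Otherwise the gap
    between nearest span edges decides: gap <= ``window`` (inclusive) ->
    ``cis_nonoverlap``, else ``trans_candidate``.
    """
    if lnc.chrom != mrna.chrom:
        return "trans_candidate", False
    if lnc.start < mrna.end and mrna.start < lnc.end:
        return "cis_overlap", lnc.strand != mrna.strand
    gap = max(lnc.start, mrna.start) - min(lnc.end, mrna.end)
    if gap <= window:
        return "cis_nonoverlap", False
    return "trans_candidate", False


def _encode_rna(seq: str) -> np.ndarray:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set(_RNA)
    if bad:
        raise ValueError(f"invalid RNA characters: {sorted(bad)}")
    return np.fromiter((_CODE[b] for b in s), dtype=np.int8, count=len(s))


def _pair_matrix(loop_penalty: float) -> np.ndarray:
    P = np.full((4, 4), loop_penalty)
    P[_CODE["G"], _CODE["C"]] = P[_CODE["C"], _CODE["G"]] = TRANS_PAIR_ENERGY["gc"]
    P[_CODE["A"], _CODE["U"]] = P[_CODE["U"], _CODE["A"]] = TRANS_PAIR_ENERGY["au"]
    P[_CODE["G"], _CODE["U"]] = P[_CODE["U"], _CODE["G"]] = TRANS_PAIR_ENERGY["gu"]
    return P


def trans_energy(
    lnc_seq: str,
    mrna_seq: str,
    energy_threshold: float = DEFAULT_ENERGY_THRESHOLD,
    loop_penalty: float = TRANS_LOOP_PENALTY,
) -> tuple[float, bool]:
    """Best local antiparallel duplex energy between two sequences.

    Smith-Waterman-style minimization with per-pair energies and a
    ``loop_penalty`` per mismatched or unpaired internal position; the
    empty duplex scores 0.  Pass iff energy <= ``energy_threshold``
    (inclusive).  Sequences must be >= 20 nt.
    """
    a = _encode_rna(lnc_seq)
    b = _encode_rna(mrna_seq)
    if len(a) < 20 or len(b) < 20:
        raise ValueError("trans_energy requires sequences of >= 20 nt")
    b = b[::-1]  # antiparallel orientation
    P = _pair_matrix(loop_penalty)

    n = len(b)
    prev = np.zeros(n + 1)
    row = np.empty(n + 1)
    steps = np.arange(n, dtype=float) * loop_penalty
    best = 0.0
    for i in range(len(a)):
        e = P[a[i], b]
        cand = np.minimum(np.minimum(prev[:-1] + e, prev[1:] + loop_penalty), 0.0)
        # fold in horizontal (gap-in-lncRNA) chains: running minimum of
        # cand[k] + (j-k)*loop_penalty over k <= j
        t = cand - steps
        np.minimum.accumulate(t, out=t)
        row[0] = 0.0
        np.minimum(cand, t + steps, out=row[1:])
        m = row.min()
        if m < best:
            best = m
        prev, row = row, prev
    return float(best), best <= energy_threshold


def predict_lncrna_targets(
    models: Sequence[TranscriptModel],
    seqs: Mapping[str, str],
    expr: ExpressionMatrix,
    spearman_min: float = 0.6,
    pearson_min: float = 0.6,
    cis_window: int = 10_000,
    energy_threshold: float = DEFAULT_ENERGY_THRESHOLD,
    loop_penalty: float = TRANS_LOOP_PENALTY,
    log_pearson: bool = True,
) -> list[InteractionEdge]:
    """Emit lncRNA->mRNA edges with mode cis_overlap/cis_nonoverlap/trans.

    Every (lncRNA, mRNA) pair present in ``expr`` is gated on expression
    correlation across all samples; passing pairs are classified by
    genomic position, and trans candidates are kept only when
    :func:`trans_energy` passes.  With ``log_pearson`` (default) the
    Pearson coefficient is computed on log2(x+1)-transformed expression —
    raw-scale Pearson over a handful of samples is dominated by single
    extreme values; Spearman is rank-based and unaffected.
    """
    by_id = {m.transcript_id: m for m in models}
    lnc_ids = sorted(t for t in expr.feature_ids if t in by_id and by_id[t].biotype == "lncRNA")
    mrna_ids = sorted(t for t in expr.feature_ids if t in by_id and by_id[t].biotype == "mRNA")
    missing = sorted(t for t in expr.feature_ids if t not in by_id)
    if missing:
        raise ValueError(f"expression features absent from transcript models: {missing}")
    if not lnc_ids or not mrna_ids:
        return []

    vals = expr.data
    lnc_raw = vals.loc[lnc_ids].to_numpy(dtype=float)
    mrna_raw = vals.loc[mrna_ids].to_numpy(dtype=float)

    def _corr_block(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        # rows of a vs rows of b; constant rows yield nan
        with np.errstate(invalid="ignore", divide="ignore"):
            az = (a - a.mean(axis=1, keepdims=True))
            bz = (b - b.mean(axis=1, keepdims=True))
            an = np.sqrt((az ** 2).sum(axis=1, keepdims=True))
            bn = np.sqrt((bz ** 2).sum(axis=1, keepdims=True))
            return (az @ bz.T) / (an * bn.T)

    pear_in_l = np.log2(lnc_raw + 1.0) if log_pearson else lnc_raw
    pear_in_m = np.log2(mrna_raw + 1.0) if log_pearson else mrna_raw
    pearson = _corr_block(pear_in_l, pear_in_m)
    ranks_l = np.apply_along_axis(stats.rankdata, 1, lnc_raw)
    ranks_m = np.apply_along_axis(stats.rankdata, 1, mrna_raw)
    spearman = _corr_block(ranks_l, ranks_m)

    with np.errstate(invalid="ignore"):
        passing = (pearson >= pearson_min) & (spearman >= spearman_min)

    edges: list[InteractionEdge] = []
    for li, mi in zip(*np.nonzero(passing)):
        lnc_id, mrna_id = lnc_ids[li], mrna_ids[mi]
        mode, antisense = classify_cis(by_id[lnc_id], by_id[mrna_id], window=cis_window)
        energy = None
        if mode == "trans_candidate":
            energy, ok = trans_energy(seqs[lnc_id], seqs[mrna_id],
                                      energy_threshold=energy_threshold,
                                      loop_penalty=loop_penalty)
            if not ok:
                continue
            mode = "trans"
        edges.append(InteractionEdge(
            regulator_id=lnc_id,
            target_id=mrna_id,
            edge_type="lncrna_mrna",
            mode=mode,
            energy=energy,
            spearman=float(spearman[li, mi]),
            pearson=float(pearson[li, mi]),
            antisense=antisense,
        ))
    edges.sort(key=lambda e: (e.regulator_id, e.target_id))
    return edges
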