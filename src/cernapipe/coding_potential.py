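"""Coding-potential scoring and consensus lncRNA/mRNA classification.

A transcript is confirmed as a lncRNA when it is at least ``min_lnc_length``
nucleotides long (default 200, the conventional long-ncRNA floor) and at
least ``min_votes`` of four independent scorers call it noncoding.  The four
built-in scorers fill the four vote slots of the standard multi-tool
protocol at desk scale:

1. longest-ORF length (coding if >= 300 nt),
2. Fickett TESTCODE statistic (coding if >= 0.74),
3. hexamer log-likelihood ratio, coding vs noncoding model (coding if > 0),
4. protein-domain hit (coding if the transcript has a supplied domain hit).

Scores from external tools (CPC, CNCI, txCdsPredict, PFAM) may be supplied
as a table instead, in which case the published thresholds apply (0 for
CPC/CNCI, 500 for txCdsPredict, any PFAM hit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import seqmodels

ORF_CODING_MIN_NT = 300
FICKETT_CODING_MIN = 0.74

_VALID = set("ACGTU")
_STOPS = frozenset(seqmodels.STOP_CODONS)


def _normalize(seq: str, allow_n: bool = False) -> str:
    s = seq.upper().replace("U", "T")
    allowed = _VALID | ({"N"} if allow_n else set())
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return s


def find_longest_orf(seq: str) -> tuple[int, int]:
    """Longest ATG->stop open reading frame over the three forward frames.

    Returns half-open (start, end); the stop codon is included.  An ORF
    running off the 3' end without a stop counts up to the last full codon.
    Returns (0, 0) when no ATG exists.
    """
    s = _normalize(seq, allow_n=True)
    best = (0, 0)
    n = len(s)
    for frame in range(3):
        i = frame
        while i + 3 <= n:
            if s[i:i + 3] == seqmodels.START_CODON:
                j = i + 3
                while j + 3 <= n and s[j:j + 3] not in _STOPS:
                    j += 3
                end = j + 3 if j + 3 <= n else j  # include stop when present
                if end - i > best[1] - best[0]:
                    best = (i, end)
                i = end if end > i else i + 3
            else:
                i += 3
    return best


def orf_score(seq: str, coding_min_nt: int = ORF_CODING_MIN_NT) -> tuple[int, str]:
    """Longest-ORF length (nt) and its coding/noncoding vote."""
    if not seq:
        raise ValueError("empty sequence")
    start, end = find_longest_orf(seq)
    longest = end - start
    return longest, ("coding" if longest >= coding_min_nt else "noncoding")


# Fickett (1982) TESTCODE lookup tables, as used by the classic
# implementations: positional asymmetry and base-content bins with
# per-base weights.
_POSITION_PROB = {
    "A": [0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36],
    "C": [0.29, 0.44, 0.55, 0.49, 0.52, 0.60, 0.60, 0.56, 0.51, 0.38],
    "G": [0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.66, 0.72, 0.83, 0.30],
    "T": [0.51, 0.60, 0.69, 0.64, 0.62, 0.67, 0.58, 0.48, 0.39, 0.24],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_CONTENT_PROB = {
    "A": [0.22, 0.20, 0.34, 0.45, 0.68, 0.58, 0.93, 0.84, 0.68, 0.94],
    "C": [0.23, 0.30, 0.33, 0.51, 0.48, 0.66, 0.81, 0.70, 0.70, 0.80],
    "G": [0.08, 0.08, 0.16, 0.27, 0.48, 0.53, 0.64, 0.74, 0.88, 0.90],
    "T": [0.09, 0.09, 0.20, 0.54, 0.44, 0.69, 0.68, 0.91, 0.97, 0.97],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.17, 0.0]


def _lookup(value: float, para: list[float], probs: list[float]) -> float:
    for idx, threshold in enumerate(para):
        if value >= threshold:
            return probs[idx]
    return probs[-1]


def fickett_value(seq: str) -> float:
    """Fickett TESTCODE statistic; ambiguous bases are skipped in counts."""
    s = _normalize(seq, allow_n=True)
    if len(s) < 2:
        return 0.0
    counts = {b: [0, 0, 0] for b in "ACGT"}
    total = {b: 0 for b in "ACGT"}
    for i, base in enumerate(s):
        if base == "N":
            continue
        counts[base][i % 3] += 1
        total[base] += 1
    n_counted = sum(total.values())
    score = 0.0
    for base in "ACGT":
        position = max(counts[base]) / (min(counts[base]) + 1)
        content = total[base] / n_counted if n_counted else 0.0
        score += _lookup(position, _POSITION_PARA, _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        score += _lookup(content, _CONTENT_PARA, _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


def fickett_score(seq: str, coding_min: float = FICKETT_CODING_MIN) -> tuple[float, str]:
    """TESTCODE statistic plus vote; requires length >= 200 nt."""
    if len(seq) < 200:
        raise ValueError(f"fickett_score requires length >= 200 (got {len(seq)})")
    value = fickett_value(seq)
    return value, ("coding" if value >= coding_min else "noncoding")


HexamerModel = Mapping[str, float]

_DEFAULT_MODELS: tuple[dict[str, float], dict[str, float]] | None = None


def default_hexamer_models() -> tuple[dict[str, float], dict[str, float]]:
    """(coding, noncoding) hexamer tables derived from the sequence models."""
    global _DEFAULT_MODELS
    if _DEFAULT_MODELS is None:
        _DEFAULT_MODELS = (seqmodels.coding_hexamer_table(), seqmodels.noncoding_hexamer_table())
    return _DEFAULT_MODELS


def hexamer_score(
    seq: str, coding_model: HexamerModel, noncoding_model: HexamerModel
) -> tuple[float, str]:
    """Mean log2 likelihood ratio over in-frame hexamers of the longest ORF.

    Falls back to frame 0 of the whole sequence when no ORF exists.
    Hexamers containing ambiguous bases are skipped.  Vote is coding iff
    the mean ratio is > 0.
    """
    if not coding_model or not noncoding_model:
        raise ValueError("empty hexamer model")
    s = _normalize(seq, allow_n=True)
    if len(s) < 6:
        raise ValueError(f"sequence shorter than one hexamer (length {len(s)})")
    start, end = find_longest_orf(s)
    region = s[start:end] if end - start >= 6 else s
    ratios = []
    for i in range(0, len(region) - 5, 3):
        hexamer = region[i:i + 6]
        if "N" in hexamer:
            continue
        pc = coding_model.get(hexamer)
        pn = noncoding_model.get(hexamer)
        if pc is None or pn is None or pc <= 0 or pn <= 0:
            continue
        ratios.append(math.log2(pc / pn))
    score = sum(ratios) / len(ratios) if ratios else 0.0
    return score, ("coding" if score > 0 else "noncoding")


@dataclass
class CodingVerdict:
    """Per-transcript scorer outputs, vote tally and the consensus label."""

    transcript_id: str
    scorer_scores: dict[str, float]
    scorer_votes: dict[str, str]
    n_noncoding_votes: int
    label: str  # lncRNA | mRNA | too_short


SCORER_NAMES = ("orf", "fickett", "hexamer", "domain")
EXTERNAL_SCORER_NAMES = ("cpc", "cnci", "txcds", "pfam_hit")


def _external_votes(row: pd.Series) -> dict[str, str]:
    return {
        "cpc": "coding" if row["cpc"] > 0 else "noncoding",
        "cnci": "coding" if row["cnci"] > 0 else "noncoding",
        "txcds": "coding" if row["txcds"] >= 500 else "noncoding",
        "pfam_hit": "coding" if row["pfam_hit"] > 0 else "noncoding",
    }


def consensus_classify(
    seqs: Mapping[str, str],
    domain_hits: Iterable[str] | None = None,
    external_scores: pd.DataFrame | None = None,
    min_votes: int = 3,
    min_lnc_length: int = 200,
    hexamer_models: tuple[HexamerModel, HexamerModel] | None = None,
    required_ids: Sequence[str] | None = None,
) -> list[CodingVerdict]:
    """Classify every transcript by the >=``min_votes``-of-4 noncoding rule.

    Transcripts shorter than ``min_lnc_length`` are labelled ``too_short``
    and short-circuit voting.  ``required_ids`` (e.g. the ids of a model
    set) must all have sequences; missing ones raise an error listing them.
    """
    if required_ids is not None:
        missing = sorted(set(required_ids) - set(seqs))
        if missing:
            raise ValueError(f"missing sequences for transcripts: {missing}")
    hits = set(domain_hits) if domain_hits is not None else set()
    if hexamer_models is None:
        hexamer_models = default_hexamer_models()
    coding_model, noncoding_model = hexamer_models

    verdicts = []
    for tid in seqs:
        seq = seqs[tid]
        if len(seq) < min_lnc_length:
            verdicts.append(CodingVerdict(tid, {}, {}, 0, "too_short"))
            continue
        if external_scores is not None:
            if tid not in external_scores.index:
                raise ValueError(f"external score table lacks transcript {tid!r}")
            row = external_scores.loc[tid]
            votes = _external_votes(row)
            scores = {name: float(row[name]) for name in EXTERNAL_SCORER_NAMES}
        else:
            orf_nt, orf_vote = orf_score(seq)
            fick = fickett_value(seq)
            fick_vote = "coding" if fick >= FICKETT_CODING_MIN else "noncoding"
            hexa, hexa_vote = hexamer_score(seq, coding_model, noncoding_model)
            domain_vote = "coding" if tid in hits else "noncoding"
            scores = {"orf": float(orf_nt), "fickett": fick, "hexamer": hexa,
                      "domain": 1.0 if tid in hits else 0.0}
            votes = {"orf": orf_vote, "fickett": fick_vote, "hexamer": hexa_vote,
                     "domain": domain_vote}
        n_noncoding = sum(1 for v in votes.values() if v == "noncoding")
        label = "lncRNA" if n_noncoding >= min_votes else "mRNA"
        verdicts.append(CodingVerdict(tid, scores, votes, n_noncoding, label))
    return verdicts


def verdicts_to_frame(verdicts: Sequence[CodingVerdict]) -> pd.DataFrame:
    """Tabular view of verdicts, sorted by transcript id."""
    rows = []
    for v in sorted(verdicts, key=lambda v: v.transcript_id):
        row: dict[str, object] = {"transcript_id": v.transcript_id, "label": v.label,
                                  "n_noncoding_votes": v.n_noncoding_votes}
        for name, score in v.scorer_scores.items():
            row[f"score_{name}"] = score
        for name, vote in v.scorer_votes.items():
            row[f"vote_{name}"] = vote
        rows.append(row)
    return pd.DataFrame(rows).set_index("transcript_id")


def read_domain_hits(path) -> set[str]:
    """Read a transcript_id<TAB>domain_id table into a hit set."""
    hits = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            hits.add(line.split("\t")[0])
    return hits
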