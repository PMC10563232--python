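"""Generative sequence models shared by the simulator and the classifiers.

Two classes of transcript sequence are modelled:

* coding: a position-within-codon base-composition model (GC3-rich, stop
  codons excluded), giving the 3-periodic compositional signal that
  coding-potential statistics key on;
* noncoding: a first-order AT-rich Markov chain with mild persistence.

The default hexamer log-likelihood tables used by
:func:`cernapipe.coding_potential.hexamer_score` are derived analytically
from these same parameters, so no training corpus is needed.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"

# P(base | codon position); order A, C, G, T.  Third position is GC-rich.
CODING_POSITION_PROBS = np.array([
    [0.27, 0.19, 0.33, 0.21],
    [0.31, 0.22, 0.17, 0.30],
    [0.18, 0.29, 0.30, 0.23],
])

# First-order chain for noncoding sequence: AT-rich stationary composition
# with a small same-base persistence term.
NONCODING_STATIONARY = np.array([0.33, 0.17, 0.17, 0.33])
_PERSISTENCE = 0.15
NONCODING_TRANSITION = (
    (1.0 - _PERSISTENCE) * np.tile(NONCODING_STATIONARY, (4, 1)) + _PERSISTENCE * np.eye(4)
)


def _codon_distribution() -> tuple[list[str], np.ndarray]:
    """Sense-codon distribution under the positional model (stops excluded)."""
    codons, probs = [], []
    for i, b1 in enumerate(BASES):
        for j, b2 in enumerate(BASES):
            for k, b3 in enumerate(BASES):
                codon = b1 + b2 + b3
                if codon in STOP_CODONS:
                    continue
                codons.append(codon)
                probs.append(
                    CODING_POSITION_PROBS[0, i]
                    * CODING_POSITION_PROBS[1, j]
                    * CODING_POSITION_PROBS[2, k]
                )
    p = np.asarray(probs)
    return codons, p / p.sum()


SENSE_CODONS, SENSE_CODON_PROBS = _codon_distribution()


_NONCODING_CUM = np.cumsum(NONCODING_TRANSITION, axis=1)
_STATIONARY_CUM = np.cumsum(NONCODING_STATIONARY)


def sample_noncoding_sequence(rng: np.random.Generator, length: int) -> str:
    """Draw a noncoding sequence from the first-order background chain."""
    if length < 1:
        raise ValueError("length must be >= 1")
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    state = int(np.searchsorted(_STATIONARY_CUM, u[0]))
    out[0] = state
    cum = _NONCODING_CUM
    for i in range(1, length):
        state = int(np.searchsorted(cum[state], u[i]))
        out[i] = state
    return "".join(BASES[i] for i in out)


def sample_coding_region(rng: np.random.Generator, n_codons: int) -> str:
    """Draw an ORF: ATG + ``n_codons`` sense codons + a stop codon."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    idx = rng.choice(len(SENSE_CODONS), size=n_codons, p=SENSE_CODON_PROBS)
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return START_CODON + "".join(SENSE_CODONS[i] for i in idx) + stop


def sample_mrna_sequence(
    rng: np.random.Generator, n_codons: int, utr5_len: int, utr3_len: int
) -> tuple[str, int, int]:
    """mRNA = 5'UTR (background chain) + ORF + 3'UTR (background chain).

    Returns (sequence, orf_start, orf_end) with half-open ORF coordinates.
    """
    utr5 = sample_noncoding_sequence(rng, utr5_len) if utr5_len else ""
    orf = sample_coding_region(rng, n_codons)
    utr3 = sample_noncoding_sequence(rng, utr3_len) if utr3_len else ""
    return utr5 + orf + utr3, len(utr5), len(utr5) + len(orf)


def coding_hexamer_table() -> dict[str, float]:
    """In-frame hexamer (codon-pair) probabilities under the coding model."""
    table: dict[str, float] = {}
    for c1, p1 in zip(SENSE_CODONS, SENSE_CODON_PROBS):
        for c2, p2 in zip(SENSE_CODONS, SENSE_CODON_PROBS):
            table[c1 + c2] = p1 * p2
    return _with_pseudocounts(table)


def noncoding_hexamer_table() -> dict[str, float]:
    """Hexamer probabilities under the first-order background chain."""
    table: dict[str, float] = {}
    for n in range(4096):
        idx = [(n >> (2 * (5 - k))) & 3 for k in range(6)]
        p = NONCODING_STATIONARY[idx[0]]
        for a, b in zip(idx[:-1], idx[1:]):
            p *= NONCODING_TRANSITION[a, b]
        table["".join(BASES[i] for i in idx)] = float(p)
    return _with_pseudocounts(table)


def _with_pseudocounts(table: dict[str, float], pseudo: float = 1e-9) -> dict[str, float]:
    total = sum(table.values()) + pseudo * 4096
    out = {}
    for n in range(4096):
        hexamer = "".join(BASES[(n >> (2 * (5 - k))) & 3] for k in range(6))
        out[hexamer] = (table.get(hexamer, 0.0) + pseudo) / total
    return out
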