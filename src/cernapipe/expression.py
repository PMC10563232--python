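"""Count normalization (FPKM/TPM) and descriptive lncRNA statistics.

FPKM = count / ((length/1e3) * (library_size/1e6)); effective length is the
sum of exon lengths (no fragment-length correction).  TPM divides each
count by its feature length, then rescales each sample so the column sums
to 1e6.  For miRNA tag counts the length is fixed at 1 (tag-count
normalization), making TPM a pure depth normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, TranscriptModel

logger = logging.getLogger(__name__)


def _lengths_vector(features: Sequence[str], lengths: Mapping[str, int]) -> np.ndarray:
    missing = [f for f in features if f not in lengths]
    if missing:
        raise ValueError(f"missing transcript lengths for: {missing}")
    vec = np.array([float(lengths[f]) for f in features])
    if (vec < 1).any():
        raise ValueError("all feature lengths must be >= 1")
    return vec


def to_fpkm(
    counts: ExpressionMatrix,
    lengths: Mapping[str, int],
    lib_sizes: Mapping[str, float] | None = None,
) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``lib_sizes`` defaults to the column sums of the count matrix.
    """
    if counts.unit != "count":
        raise ValueError(f"to_fpkm expects a count matrix, got unit {counts.unit!r}")
    lens = _lengths_vector(counts.feature_ids, lengths)
    if lib_sizes is None:
        libs = counts.data.sum(axis=0)
    else:
        libs = pd.Series({s: float(lib_sizes[s]) for s in counts.sample_ids})
    if (libs <= 0).any():
        raise ValueError("library sizes must be > 0")
    fpkm = counts.data.div(lens / 1e3, axis=0).div(libs / 1e6, axis=1)
    return ExpressionMatrix(fpkm, unit="FPKM")


def to_tpm(counts: ExpressionMatrix, lengths: Mapping[str, int] | None = None) -> ExpressionMatrix:
    """Transcripts per million; ``lengths=None`` uses length 1 everywhere.

    Column sums equal 1e6 whenever the column has any signal; an all-zero
    column stays all-zero (logged as a warning).
    """
    if counts.unit != "count":
        raise ValueError(f"to_tpm expects a count matrix, got unit {counts.unit!r}")
    if lengths is None:
        lens = np.ones(len(counts.feature_ids))
    else:
        lens = _lengths_vector(counts.feature_ids, lengths)
    rates = counts.data.div(lens, axis=0)
    totals = rates.sum(axis=0)
    zero_cols = totals[totals == 0].index.tolist()
    if zero_cols:
        logger.warning("all-zero TPM column(s): %s", zero_cols)
    totals = totals.replace(0, np.nan)
    tpm = (rates.div(totals, axis=1) * 1e6).fillna(0.0)
    return ExpressionMatrix(tpm, unit="TPM")


@dataclass
class LncRNASummary:
    """Descriptive statistics over a set of lncRNA transcript models."""

    n_transcripts: int
    n_genes: int
    length_min: int
    length_max: int
    length_mean: float
    exon_count_hist: dict[int, int]
    mean_exons: float
    share_le2_exons: float
    transcripts_per_gene_hist: dict[int, int]
    n_multi_transcript_genes: int

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["exon_count_hist"] = {str(k): v for k, v in sorted(self.exon_count_hist.items())}
        d["transcripts_per_gene_hist"] = {
            str(k): v for k, v in sorted(self.transcripts_per_gene_hist.items())
        }
        return d


def summarize_lncrna(models: Sequence[TranscriptModel]) -> LncRNASummary:
    """Length/exon/isoform summary of a non-empty lncRNA model list."""
    if not models:
        raise ValueError("summarize_lncrna requires a non-empty model list")
    lengths = [m.length for m in models]
    exon_counts = [m.n_exons for m in models]
    per_gene: dict[str, int] = {}
    for m in models:
        per_gene[m.gene_id] = per_gene.get(m.gene_id, 0) + 1
    exon_hist: dict[int, int] = {}
    for c in exon_counts:
        exon_hist[c] = exon_hist.get(c, 0) + 1
    tpg_hist: dict[int, int] = {}
    for c in per_gene.values():
        tpg_hist[c] = tpg_hist.get(c, 0) + 1
    return LncRNASummary(
        n_transcripts=len(models),
        n_genes=len(per_gene),
        length_min=min(lengths),
        length_max=max(lengths),
        length_mean=float(np.mean(lengths)),
        exon_count_hist=exon_hist,
        mean_exons=float(np.mean(exon_counts)),
        share_le2_exons=sum(1 for c in exon_counts if c <= 2) / len(exon_counts),
        transcripts_per_gene_hist=tpg_hist,
        n_multi_transcript_genes=sum(1 for c in per_gene.values() if c > 1),
    )
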