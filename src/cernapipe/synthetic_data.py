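"""Synthetic two-condition ncRNA study generator with recorded ground truth.

Emits a complete desk-scale input bundle — GTF + transcript/miRNA FASTA +
count matrices + sample design + GO and protein-domain tables — whose
statistical structure emulates a two-tissue (TPS vs MPS), three-replicate
plant RNA-seq design:

* mRNA loci carry a long planted ORF drawn from a biased codon model;
  lncRNA loci are drawn from an AT-rich background chain and are rejected
  until they contain no ORF >= 300 nt (lack of coding capacity is the
  defining property of the class);
* configured numbers of lncRNAs are planted as antisense-overlapping an
  mRNA, as <10-kb neighbors, or as distal-but-correlated partners (the
  distal ones carry a 30-nt complementary stretch so the trans duplex
  criterion can find them; "control" distal pairs are verified to carry
  no such complementarity);
* counts are negative-binomial (mean/dispersion parameterization) with
  planted MPS/TPS fold-changes, per-feature baseline variation, and
  correlated pairs coupled through a shared per-sample latent factor on
  the log2 scale;
* planted miRNA target sites are reverse-complement insertions with a
  controlled number of non-pairing substitutions;
* planted ceRNA triads wire one DE miRNA to one DE lncRNA and one DE mRNA
  through perfect target sites.

Everything planted is recorded in a :class:`SyntheticTruth` object
(serialized as ``truth.json``); identical config + seed give a
byte-identical bundle.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import seqmodels
from .coding_potential import (
    FICKETT_CODING_MIN,
    default_hexamer_models,
    fickett_value,
    find_longest_orf,
    hexamer_score,
)
from .io_formats import (
    ExpressionMatrix,
    GOAnnotationTable,
    TranscriptModel,
    write_design,
    write_expression_matrix,
    write_fasta,
    write_go_annotations,
    write_json,
    write_transcript_models,
)
from .lncrna_targets import trans_energy
from .mirna_targets import pair_kind

ORF_REJECT_NT = 300  # lncRNA sequences are resampled until no ORF reaches this


class ConfigurationError(ValueError):
    """Raised when generator parameters are inconsistent or infeasible."""


@dataclass
class GeneratorConfig:
    """All generator parameters, including the seed.

    Defaults describe the study conditions the generator emulates: two
    groups x 3 replicates, 8 disjoint planted ceRNA triads with 4-fold
    expression changes, baseline mean 500 counts, NB dispersion 0.05, and
    perfect (mismatch-free) planted miRNA sites.
    """

    seed: int = 0
    n_mrna: int = 80
    n_lncrna: int = 60
    n_mirna: int = 100
    n_triads: int = 8
    fold_change: float = 4.0
    baseline_mean: float = 500.0
    dispersion: float = 0.05
    baseline_log2_sd: float = 1.0
    depth_log2_sd: float = 0.1
    n_de_extra_mrna: int = 10
    n_de_extra_lncrna: int = 8
    n_de_extra_mirna: int = 16
    n_antisense: int = 6
    n_neighbor: int = 6
    n_distal: int = 6
    n_control_distal: int = 2
    latent_correlation: float = 0.95
    corr_log2_sd: float = 2.5
    latent_log2_bound: float = 3.0
    site_mismatches: int = 0
    chrom: str = "chr1"
    chrom_length: int = 2_000_000
    n_replicates: int = 3
    groups: tuple[str, str] = ("TPS", "MPS")
    lnc_multi_isoform_fraction: float = 0.15
    domain_hit_fraction: float = 0.95
    n_go_terms: int = 10
    mirna_length: int = 21

    def validate(self) -> None:
        if self.fold_change < 1:
            raise ConfigurationError("fold_change must be >= 1")
        if self.n_triads > min(self.n_mirna, self.n_lncrna, self.n_mrna):
            raise ConfigurationError("n_triads cannot exceed the smallest feature count")
        lnc_roles = (self.n_triads + self.n_de_extra_lncrna + self.n_antisense
                     + self.n_neighbor + self.n_distal + self.n_control_distal)
        if lnc_roles > self.n_lncrna:
            raise ConfigurationError(
                f"lncRNA roles ({lnc_roles}) exceed n_lncrna ({self.n_lncrna})")
        mrna_roles = (self.n_triads + self.n_de_extra_mrna + self.n_antisense
                      + self.n_neighbor + self.n_distal + self.n_control_distal)
        if mrna_roles > self.n_mrna:
            raise ConfigurationError(
                f"mRNA roles ({mrna_roles}) exceed n_mrna ({self.n_mrna})")
        if self.n_triads + self.n_de_extra_mirna > self.n_mirna:
            raise ConfigurationError("miRNA roles exceed n_mirna")
        if not 0 <= self.latent_correlation <= 1:
            raise ConfigurationError("latent_correlation must be in [0, 1]")
        if not 0 <= self.site_mismatches <= self.mirna_length:
            raise ConfigurationError("site_mismatches must be in [0, miRNA length]")


@dataclass
class SyntheticTruth:
    """Planted ground truth of one generated bundle."""

    de_mirnas: dict[str, float]  # id -> MPS/TPS fold factor
    de_lncrnas: dict[str, float]
    de_mrnas: dict[str, float]
    planted_mirna_targets: list[dict]
    planted_lnc_pairs: list[dict]
    control_lnc_pairs: list[dict]
    planted_triads: list[dict]
    mirna_ids: list[str] = field(default_factory=list)
    lncrna_ids: list[str] = field(default_factory=list)
    mrna_ids: list[str] = field(default_factory=list)
    correlated_pairs: list[dict] = field(default_factory=list)
    generator_config: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


@dataclass
class GeneratedBundle:
    """In-memory view of an emitted bundle."""

    models: list[TranscriptModel]
    transcript_seqs: dict[str, str]
    mirna_seqs: dict[str, str]
    counts_rna: ExpressionMatrix
    counts_mirna: ExpressionMatrix
    design: pd.DataFrame
    go_table: GOAnnotationTable
    domain_hits: set[str]
    truth: SyntheticTruth


def _nonpairing_base(mirna_base: str) -> str:
    """A target base that neither Watson-Crick- nor wobble-pairs the given base."""
    for candidate in "CAGU":
        if pair_kind(mirna_base, candidate) is None:
            return candidate
    raise AssertionError("unreachable")


def _revcomp_rna_to_dna(rna: str) -> str:
    comp = {"A": "T", "U": "A", "G": "C", "C": "G", "T": "A"}
    return "".join(comp[b] for b in reversed(rna.upper()))


def plant_mirna_site(
    target_seq: str,
    mirna_seq: str,
    n_mismatch: int,
    position: int,
    mismatch_positions: Sequence[int] | None = None,
) -> tuple[str, list[int]]:
    """Embed the reverse complement of a miRNA into a target sequence.

    Exactly ``n_mismatch`` site bases are substituted with non-pairing
    bases.  ``mismatch_positions`` are 1-based miRNA positions; when
    omitted they are taken outside the seed region (positions 14..m, then
    1) before falling back to seed positions.  Returns the modified
    sequence and the miRNA positions actually mutated.
    """
    m = len(mirna_seq)
    if not 0 <= position <= len(target_seq) - m:
        raise ValueError(f"site position {position} out of range for target of "
                         f"length {len(target_seq)} and miRNA of length {m}")
    if n_mismatch > m:
        raise ValueError("n_mismatch cannot exceed the miRNA length")
    mi = mirna_seq.upper().replace("T", "U")
    site = list(_revcomp_rna_to_dna(mi))
    if mismatch_positions is None:
        preference = list(range(14, m + 1)) + [1] + list(range(2, 14))
        mismatch_positions = preference[:n_mismatch]
    else:
        mismatch_positions = list(mismatch_positions)
        if len(mismatch_positions) != n_mismatch:
            raise ValueError("mismatch_positions length must equal n_mismatch")
    for pos in mismatch_positions:
        if not 1 <= pos <= m:
            raise ValueError(f"miRNA position {pos} out of range 1..{m}")
        offset = m - pos  # site index pairing miRNA position `pos`
        site[offset] = _nonpairing_base(mi[pos - 1]).replace("U", "T")
    new_seq = target_seq[:position] + "".join(site) + target_seq[position + m:]
    return new_seq, sorted(mismatch_positions)


def _looks_noncoding(seq: str) -> bool:
    """Operational lncRNA definition: the built-in consensus calls it noncoding.

    With no protein-domain hit, a sequence is consensus-noncoding unless
    it has an ORF >= 300 nt or both the Fickett and hexamer scorers vote
    coding.  Planted lncRNAs are sampled until they satisfy this — the
    class is *defined* by the consensus, exactly as a real lncRNA catalog
    is the output of the same vote.
    """
    s, e = find_longest_orf(seq)
    if e - s >= ORF_REJECT_NT:
        return False
    if fickett_value(seq) < FICKETT_CODING_MIN:
        return True
    _, vote = hexamer_score(seq, *default_hexamer_models())
    return vote == "noncoding"


def _sample_lncrna_sequence(rng: np.random.Generator, length: int, max_tries: int = 200) -> str:
    """Background-chain sequence passing the consensus-noncoding check."""
    for _ in range(max_tries):
        seq = seqmodels.sample_noncoding_sequence(rng, length)
        if _looks_noncoding(seq):
            return seq
    raise RuntimeError(f"could not sample a consensus-noncoding sequence of length {length}")


def _embed_site_orf_safe(
    rng: np.random.Generator, seq: str, mirna: str, n_mismatch: int, max_tries: int = 50
) -> tuple[str, int, list[int]]:
    """Plant a site at a random position without creating a long ORF."""
    m = len(mirna)
    for _ in range(max_tries):
        pos = int(rng.integers(10, len(seq) - m - 10))
        new_seq, offsets = plant_mirna_site(seq, mirna, n_mismatch, pos)
        if _looks_noncoding(new_seq):
            return new_seq, pos, offsets
    raise RuntimeError("could not embed miRNA site and stay consensus-noncoding")


_LNC_EXON_COUNTS = np.array([1, 2, 3, 4])
_LNC_EXON_PROBS = np.array([0.55, 0.32, 0.08, 0.05])

_GO_TERM_NAMES = [
    "secondary cell wall biogenesis",
    "cell wall organization or biogenesis",
    "cellulose synthase activity",
    "lignin biosynthetic process",
    "xylan biosynthetic process",
    "phenylpropanoid metabolic process",
    "transcription regulator activity",
    "response to auxin",
    "microtubule-based movement",
    "plasmodesma",
    "glucuronoxylan metabolic process",
    "laccase activity",
]

PLANTED_GO_TERM = "GO:0000001"  # assigned preferentially to DE mRNAs


def _make_exons(start: int, exonic_len: int, n_exons: int,
                rng: np.random.Generator) -> tuple[tuple[int, int], ...]:
    """Split an exonic length into exons separated by short introns."""
    n_exons = max(1, min(n_exons, exonic_len // 40))
    cuts = np.sort(rng.choice(np.arange(30, exonic_len - 30), size=n_exons - 1,
                              replace=False)) if n_exons > 1 else np.array([], dtype=int)
    sizes = np.diff(np.concatenate(([0], cuts, [exonic_len])))
    exons = []
    pos = start
    for idx, size in enumerate(sizes):
        exons.append((pos, pos + int(size)))
        pos += int(size)
        if idx < len(sizes) - 1:
            pos += int(rng.integers(80, 501))
    return tuple(exons)


def make_design(config: GeneratorConfig) -> pd.DataFrame:
    rows = [
        {"sample_id": f"{group}{rep}", "group": group, "replicate": rep}
        for group in config.groups
        for rep in range(1, config.n_replicates + 1)
    ]
    return pd.DataFrame(rows)


def simulate_counts(
    truth: SyntheticTruth,
    design: pd.DataFrame,
    rng: np.random.Generator,
    feature_ids: Sequence[str],
    which: str = "rna",
) -> ExpressionMatrix:
    """Draw a count matrix for ``feature_ids`` from the planted model.

    Per feature f and sample s the NB mean is
    ``baseline_f * fold_f(group(s)) * 2**latent_fs * depth_s`` where
    ``baseline_f`` is lognormal around ``baseline_mean``, ``fold_f``
    applies the planted MPS/TPS factor to MPS samples, ``latent_fs``
    couples correlated pairs through a shared per-sample factor, and
    ``depth_s`` is a per-library depth factor.  ``dispersion=0`` gives
    Poisson counts.
    """
    cfg = GeneratorConfig(**truth.generator_config)
    samples = design["sample_id"].tolist()
    is_mps = (design["group"] == cfg.groups[1]).to_numpy()
    n_s = len(samples)
    n_f = len(feature_ids)

    de_map = {"rna": {**truth.de_mrnas, **truth.de_lncrnas}, "mirna": truth.de_mirnas}[which]

    baselines = cfg.baseline_mean * 2.0 ** rng.normal(0.0, cfg.baseline_log2_sd, size=n_f)
    depth = 2.0 ** rng.normal(0.0, cfg.depth_log2_sd, size=n_s)

    latent = np.zeros((n_f, n_s))
    if which == "rna":
        index = {fid: i for i, fid in enumerate(feature_ids)}
        bound = cfg.latent_log2_bound
        for pair in truth.correlated_pairs:
            r = pair["latent_correlation"]
            shared = rng.normal(size=n_s)
            for member in (pair["lncrna"], pair["mrna"]):
                eps = rng.normal(size=n_s)
                if member not in index:  # subset simulation; stream unchanged
                    continue
                x = cfg.corr_log2_sd * (np.sqrt(r) * shared + np.sqrt(1.0 - r) * eps)
                # tanh squash: bounded spread, monotone (rank-preserving)
                latent[index[member]] = bound * np.tanh(x / bound)

    means = np.empty((n_f, n_s))
    for i, fid in enumerate(feature_ids):
        fold = de_map.get(fid, 1.0)
        group_factor = np.where(is_mps, fold, 1.0)
        means[i] = baselines[i] * group_factor * 2.0 ** latent[i] * depth

    if cfg.dispersion > 0:
        shape = 1.0 / cfg.dispersion
        lam = rng.gamma(shape, means / shape)
    else:
        lam = means
    counts = rng.poisson(lam)
    df = pd.DataFrame(counts, index=pd.Index(feature_ids, name="feature_id"),
                      columns=samples, dtype=float)
    return ExpressionMatrix(df, unit="count")


def generate_dataset(
    config: GeneratorConfig | None = None, out_dir: str | Path | None = None
) -> GeneratedBundle:
    """Generate the full bundle; optionally write it to ``out_dir``."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    seq_rng, layout_rng, counts_rna_rng, counts_mirna_rng, go_rng = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    mrna_ids = [f"Bnt{i + 1:05d}" for i in range(cfg.n_mrna)]
    lnc_ids = [f"lncR{i + 1:08d}" for i in range(cfg.n_lncrna)]
    mirna_ids = [f"miR{i + 1:04d}" for i in range(cfg.n_mirna)]

    # role slices; loci are exchangeable so index-based assignment is general
    t = cfg.n_triads
    lnc_roles = {
        "triad": lnc_ids[:t],
        "de_extra": lnc_ids[t:t + cfg.n_de_extra_lncrna],
    }
    cursor = t + cfg.n_de_extra_lncrna
    for name, count in (("antisense", cfg.n_antisense), ("neighbor", cfg.n_neighbor),
                        ("distal", cfg.n_distal), ("control", cfg.n_control_distal)):
        lnc_roles[name] = lnc_ids[cursor:cursor + count]
        cursor += count
    mrna_roles = {
        "triad": mrna_ids[:t],
        "de_extra": mrna_ids[t:t + cfg.n_de_extra_mrna],
    }
    cursor = t + cfg.n_de_extra_mrna
    for name, count in (("antisense", cfg.n_antisense), ("neighbor", cfg.n_neighbor),
                        ("distal", cfg.n_distal), ("control", cfg.n_control_distal)):
        mrna_roles[name] = mrna_ids[cursor:cursor + count]
        cursor += count
    mirna_roles = {
        "triad": mirna_ids[:t],
        "de_extra": mirna_ids[t:t + cfg.n_de_extra_mirna],
    }

    # ---- planted fold factors -------------------------------------------
    # directions alternate so planted DE splits evenly between up and down,
    # keeping TPM/FPKM totals (and hence observed folds) close to the
    # planted values under compositional normalization
    de_mirnas, de_lncrnas, de_mrnas = {}, {}, {}
    if cfg.fold_change > 1.0:
        for de_map, ids in ((de_mirnas, mirna_roles["triad"] + mirna_roles["de_extra"]),
                            (de_lncrnas, lnc_roles["triad"] + lnc_roles["de_extra"]),
                            (de_mrnas, mrna_roles["triad"] + mrna_roles["de_extra"])):
            for i, fid in enumerate(ids):
                de_map[fid] = cfg.fold_change if i % 2 == 0 else 1.0 / cfg.fold_change

    # ---- sequences ------------------------------------------------------
    mirna_seqs = {
        fid: "".join(seq_rng.choice(list("ACGU"), size=cfg.mirna_length))
        for fid in mirna_ids
    }

    transcript_seqs: dict[str, str] = {}
    orf_spans: dict[str, tuple[int, int]] = {}
    planted_sites: list[dict] = []

    triad_partner_mrna = dict(zip(mirna_roles["triad"], mrna_roles["triad"]))
    triad_partner_lnc = dict(zip(mirna_roles["triad"], lnc_roles["triad"]))

    for fid in mrna_ids:
        n_codons = int(seq_rng.integers(100, 401))
        utr5 = int(seq_rng.integers(20, 101))
        utr3 = int(seq_rng.integers(150, 301))
        seq, orf_start, orf_end = seqmodels.sample_mrna_sequence(seq_rng, n_codons, utr5, utr3)
        transcript_seqs[fid] = seq
        orf_spans[fid] = (orf_start, orf_end)

    for mirna_id, mrna_id in triad_partner_mrna.items():
        seq = transcript_seqs[mrna_id]
        orf_end = orf_spans[mrna_id][1]
        m = cfg.mirna_length
        pos = int(seq_rng.integers(orf_end + 5, len(seq) - m - 5))
        new_seq, offsets = plant_mirna_site(seq, mirna_seqs[mirna_id], cfg.site_mismatches, pos)
        transcript_seqs[mrna_id] = new_seq
        planted_sites.append({"mirna": mirna_id, "target": mrna_id,
                              "n_mismatch": cfg.site_mismatches, "site_position": pos,
                              "mismatch_positions": offsets})

    lnc_lengths = {
        fid: int(np.clip(seq_rng.lognormal(7.0, 0.55), 210, 8000)) for fid in lnc_ids
    }
    distal_partner = dict(zip(lnc_roles["distal"], mrna_roles["distal"]))
    control_partner = dict(zip(lnc_roles["control"], mrna_roles["control"]))

    for fid in lnc_ids:
        transcript_seqs[fid] = _sample_lncrna_sequence(seq_rng, lnc_lengths[fid])

    for mirna_id, lnc_id in triad_partner_lnc.items():
        new_seq, pos, offsets = _embed_site_orf_safe(
            seq_rng, transcript_seqs[lnc_id], mirna_seqs[mirna_id], cfg.site_mismatches)
        transcript_seqs[lnc_id] = new_seq
        planted_sites.append({"mirna": mirna_id, "target": lnc_id,
                              "n_mismatch": cfg.site_mismatches, "site_position": pos,
                              "mismatch_positions": offsets})

    # distal correlated pairs carry a 30-nt complementary stretch
    for lnc_id, mrna_id in distal_partner.items():
        partner = transcript_seqs[mrna_id]
        for _ in range(50):
            ws = int(seq_rng.integers(0, len(partner) - 30))
            stretch = partner[ws:ws + 30].replace("T", "U")
            insert = _revcomp_rna_to_dna(stretch)
            lseq = transcript_seqs[lnc_id]
            pos = int(seq_rng.integers(10, len(lseq) - 40))
            candidate = lseq[:pos] + insert + lseq[pos + 30:]
            if _looks_noncoding(candidate):
                transcript_seqs[lnc_id] = candidate
                break
        else:
            raise RuntimeError("could not embed complementary stretch and stay noncoding")

    # control pairs must NOT pass the trans-energy criterion
    for lnc_id, mrna_id in control_partner.items():
        for _ in range(100):
            energy, ok = trans_energy(transcript_seqs[lnc_id], transcript_seqs[mrna_id])
            if not ok:
                break
            transcript_seqs[lnc_id] = _sample_lncrna_sequence(seq_rng, lnc_lengths[lnc_id])
        else:
            raise RuntimeError("could not sample a complementarity-free control lncRNA")

    # ---- genome layout --------------------------------------------------
    paired_lnc: dict[str, tuple[str, str]] = {}
    for lnc_id, mrna_id in zip(lnc_roles["antisense"], mrna_roles["antisense"]):
        paired_lnc[mrna_id] = (lnc_id, "antisense")
    for lnc_id, mrna_id in zip(lnc_roles["neighbor"], mrna_roles["neighbor"]):
        paired_lnc[mrna_id] = (lnc_id, "neighbor")
    attached = {lnc for lnc, _ in paired_lnc.values()}

    models: list[TranscriptModel] = []
    isoform_seqs: dict[str, str] = {}
    clusters: list[tuple[str, str]] = [("mrna", fid) for fid in mrna_ids]
    clusters += [("lnc", fid) for fid in lnc_ids if fid not in attached]
    order = layout_rng.permutation(len(clusters))

    def _lnc_model(fid: str, start: int, strand: str) -> TranscriptModel:
        exonic = len(transcript_seqs[fid])
        n_ex = int(layout_rng.choice(_LNC_EXON_COUNTS, p=_LNC_EXON_PROBS))
        exons = _make_exons(start, exonic, n_ex, layout_rng)
        gene = fid.replace("lncR", "lncG")
        return TranscriptModel(fid, gene, cfg.chrom, strand, exons[0][0], exons[-1][1],
                               exons, biotype="unclassified")

    cursor = int(layout_rng.integers(1_000, 5_000))
    for idx in order:
        kind, fid = clusters[idx]
        if cursor >= cfg.chrom_length:
            raise ConfigurationError("chromosome too short for requested loci")
        if kind == "mrna":
            exonic = len(transcript_seqs[fid])
            n_ex = max(1, min(12, 1 + int(layout_rng.poisson(6.0))))
            strand = "+" if layout_rng.random() < 0.5 else "-"
            exons = _make_exons(cursor, exonic, n_ex, layout_rng)
            gene = fid.replace("Bnt", "BntG")
            model = TranscriptModel(fid, gene, cfg.chrom, strand, exons[0][0],
                                    exons[-1][1], exons, biotype="unclassified")
            models.append(model)
            cluster_end = model.end
            if fid in paired_lnc:
                lnc_id, relation = paired_lnc[fid]
                if relation == "antisense":
                    lnc_strand = "-" if strand == "+" else "+"
                    span = model.end - model.start
                    lstart = model.start + int(layout_rng.integers(0, max(1, span // 2)))
                    lnc_model = _lnc_model(lnc_id, lstart, lnc_strand)
                    if not (lnc_model.start < model.end and model.start < lnc_model.end):
                        # rare: long introns pushed the lncRNA past the mRNA end
                        lnc_model = _lnc_model(lnc_id, model.start + 10, lnc_strand)
                else:
                    gap = int(layout_rng.integers(500, 8_001))
                    lnc_strand = "+" if layout_rng.random() < 0.5 else "-"
                    lnc_model = _lnc_model(lnc_id, model.end + gap, lnc_strand)
                models.append(lnc_model)
                cluster_end = max(cluster_end, lnc_model.end)
        else:
            strand = "+" if layout_rng.random() < 0.5 else "-"
            model = _lnc_model(fid, cursor, strand)
            models.append(model)
            cluster_end = model.end
            has_role = any(fid in lnc_roles[r] for r in lnc_roles)
            if not has_role and layout_rng.random() < cfg.lnc_multi_isoform_fraction:
                iso_id = f"{fid}.2"
                if len(model.exons) > 1:
                    exons = model.exons[:-1]
                else:
                    a, b = model.exons[0]
                    exons = ((a, a + max(210, int((b - a) * 0.7))),)
                iso = TranscriptModel(iso_id, model.gene_id, cfg.chrom, strand,
                                      exons[0][0], exons[-1][1], exons,
                                      biotype="unclassified")
                iso_seq = transcript_seqs[fid][:iso.length]
                if iso.length >= 210 and _looks_noncoding(iso_seq):
                    models.append(iso)
                    isoform_seqs[iso_id] = iso_seq
                    cluster_end = max(cluster_end, iso.end)
        cursor = cluster_end + int(layout_rng.integers(10_300, 12_501))
    if cursor > cfg.chrom_length:
        raise ConfigurationError(
            f"chromosome too short: needed {cursor} bp, have {cfg.chrom_length}")
    transcript_seqs.update(isoform_seqs)

    # ---- truth assembly -------------------------------------------------
    planted_pairs = []
    for lnc_id, mrna_id in zip(lnc_roles["antisense"], mrna_roles["antisense"]):
        planted_pairs.append({"lncrna": lnc_id, "mrna": mrna_id,
                              "relation": "antisense_overlap",
                              "latent_correlation": cfg.latent_correlation})
    for lnc_id, mrna_id in zip(lnc_roles["neighbor"], mrna_roles["neighbor"]):
        planted_pairs.append({"lncrna": lnc_id, "mrna": mrna_id,
                              "relation": "neighbor_lt10kb",
                              "latent_correlation": cfg.latent_correlation})
    for lnc_id, mrna_id in distal_partner.items():
        planted_pairs.append({"lncrna": lnc_id, "mrna": mrna_id,
                              "relation": "distal_correlated",
                              "latent_correlation": cfg.latent_correlation})
    control_pairs = [
        {"lncrna": lnc_id, "mrna": mrna_id, "latent_correlation": cfg.latent_correlation}
        for lnc_id, mrna_id in control_partner.items()
    ]
    correlated = planted_pairs + [dict(p, relation="control_distal") for p in control_pairs]

    triads = []
    if cfg.fold_change > 1.0:
        for mirna_id in mirna_roles["triad"]:
            triads.append({"mirna": mirna_id,
                           "lncrna": triad_partner_lnc[mirna_id],
                           "mrna": triad_partner_mrna[mirna_id]})

    all_transcript_ids = [m.transcript_id for m in models]
    truth = SyntheticTruth(
        de_mirnas=de_mirnas,
        de_lncrnas=de_lncrnas,
        de_mrnas=de_mrnas,
        planted_mirna_targets=planted_sites,
        planted_lnc_pairs=planted_pairs,
        control_lnc_pairs=control_pairs,
        planted_triads=triads,
        mirna_ids=mirna_ids,
        lncrna_ids=[t for t in all_transcript_ids if t.startswith("lncR")],
        mrna_ids=[t for t in all_transcript_ids if t.startswith("Bnt")],
        correlated_pairs=correlated,
        generator_config=asdict(cfg),
    )

    # ---- counts ---------------------------------------------------------
    design = make_design(cfg)
    rna_feature_ids = sorted(all_transcript_ids)
    counts_rna = simulate_counts(truth, design, counts_rna_rng, rna_feature_ids, which="rna")
    counts_mirna = simulate_counts(truth, design, counts_mirna_rng, mirna_ids, which="mirna")

    # ---- GO annotations and domain hits ---------------------------------
    n_terms = max(1, cfg.n_go_terms)
    term_ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    term_names = {tid: _GO_TERM_NAMES[i % len(_GO_TERM_NAMES)] for i, tid in enumerate(term_ids)}
    de_mrna_set = set(de_mrnas)
    annotations: dict[str, frozenset[str]] = {}
    for fid in mrna_ids:
        terms = set()
        p_planted = 0.8 if fid in de_mrna_set else 0.05
        if go_rng.random() < p_planted:
            terms.add(PLANTED_GO_TERM)
        for tid in term_ids[1:]:
            if go_rng.random() < 0.15:
                terms.add(tid)
        if terms:
            annotations[fid] = frozenset(terms)
    go_table = GOAnnotationTable(annotations, term_names)

    domain_hits = {fid for fid in mrna_ids if go_rng.random() < cfg.domain_hit_fraction}

    bundle = GeneratedBundle(
        models=models,
        transcript_seqs=transcript_seqs,
        mirna_seqs=mirna_seqs,
        counts_rna=counts_rna,
        counts_mirna=counts_mirna,
        design=design,
        go_table=go_table,
        domain_hits=domain_hits,
        truth=truth,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


BUNDLE_FILES = {
    "gtf": "transcripts.gtf",
    "transcripts": "transcripts.fasta",
    "mirnas": "mirnas.fasta",
    "counts_rna": "counts_rna.tsv",
    "counts_mirna": "counts_mirna.tsv",
    "design": "design.tsv",
    "go": "go_annotations.tsv",
    "go_terms": "go_terms.tsv",
    "domains": "domain_hits.tsv",
    "truth": "truth.json",
}


def write_bundle(bundle: GeneratedBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_transcript_models(bundle.models, out / BUNDLE_FILES["gtf"])
    ordered_ids = sorted(bundle.transcript_seqs)
    write_fasta({t: bundle.transcript_seqs[t] for t in ordered_ids},
                out / BUNDLE_FILES["transcripts"])
    write_fasta(dict(sorted(bundle.mirna_seqs.items())), out / BUNDLE_FILES["mirnas"])
    write_expression_matrix(bundle.counts_rna, out / BUNDLE_FILES["counts_rna"])
    write_expression_matrix(bundle.counts_mirna, out / BUNDLE_FILES["counts_mirna"])
    write_design(bundle.design, out / BUNDLE_FILES["design"])
    write_go_annotations(bundle.go_table, out / BUNDLE_FILES["go"],
                         out / BUNDLE_FILES["go_terms"])
    lines = [f"{fid}\tPF{idx + 1:05d}" for idx, fid in enumerate(sorted(bundle.domain_hits))]
    (out / BUNDLE_FILES["domains"]).write_text("\n".join(lines) + "\n", encoding="utf-8")
    write_json(bundle.truth.as_dict(), out / BUNDLE_FILES["truth"])


def validate_truth(bundle: GeneratedBundle) -> None:
    """Truth-file closure: every referenced id exists exactly once."""
    truth = bundle.truth
    transcript_ids = {m.transcript_id for m in bundle.models}
    count_ids = set(bundle.counts_rna.feature_ids)
    fasta_ids = set(bundle.transcript_seqs)
    mirna_ids = set(bundle.mirna_seqs) & set(bundle.counts_mirna.feature_ids)
    if transcript_ids != count_ids or transcript_ids != fasta_ids:
        raise AssertionError("GTF, FASTA and count-matrix transcript ids disagree")
    for fid in list(truth.de_lncrnas) + list(truth.de_mrnas):
        if fid not in transcript_ids:
            raise AssertionError(f"truth references unknown transcript {fid!r}")
    for fid in truth.de_mirnas:
        if fid not in mirna_ids:
            raise AssertionError(f"truth references unknown miRNA {fid!r}")
    site_pairs = {(s["mirna"], s["target"]) for s in truth.planted_mirna_targets}
    for triad in truth.planted_triads:
        for key, de in (("mirna", truth.de_mirnas), ("lncrna", truth.de_lncrnas),
                        ("mrna", truth.de_mrnas)):
            if triad[key] not in de:
                raise AssertionError(f"triad member {triad[key]!r} is not in the DE truth set")
        if (triad["mirna"], triad["lncrna"]) not in site_pairs:
            raise AssertionError("triad lacks a planted miRNA->lncRNA site")
        if (triad["mirna"], triad["mrna"]) not in site_pairs:
            raise AssertionError("triad lacks a planted miRNA->mRNA site")
    for pair in truth.planted_lnc_pairs + truth.control_lnc_pairs:
        if pair["lncrna"] not in transcript_ids or pair["mrna"] not in transcript_ids:
            raise AssertionError("planted pair references unknown transcript")
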