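"""End-to-end orchestration: classify -> normalize -> de -> targets -> ceRNA.

``run_all`` executes the seven analysis stages on a bundle directory and
writes every intermediate table plus a run manifest.  Analysis stages are
seed-free and deterministic: rerunning on the same bundle produces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import pandas as pd

from . import cerna_enrich, coding_potential, diff_expr, expression, lncrna_targets, mirna_targets
from .io_formats import (
    read_design,
    read_expression_matrix,
    read_fasta,
    read_go_annotations,
    read_json,
    read_transcript_models,
    write_edges,
    write_json,
)
from .synthetic_data import BUNDLE_FILES, SyntheticTruth


@dataclass
class PipelineConfig:
    """Every analysis threshold, each defaulting to its conventional value."""

    q_threshold: float = 0.05
    fc_threshold: float = 2.0
    spearman_min: float = 0.6
    pearson_min: float = 0.6
    cis_window: int = 10_000
    energy_threshold: float = -30.0
    loop_penalty: float = lncrna_targets.TRANS_LOOP_PENALTY
    score_cutoff: float = 4.0
    ratio_cutoff: float = 0.7
    min_votes: int = 3
    min_lnc_length: int = 200
    go_alpha: float = 0.05
    log_pearson: bool = True
    seed: int = 0  # governs only the simulator; analysis is seed-free

    def validate(self) -> None:
        if not 0 < self.q_threshold <= 1 or not 0 < self.go_alpha <= 1:
            raise ValueError("q_threshold and go_alpha must be in (0, 1]")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not (-1 <= self.spearman_min <= 1 and -1 <= self.pearson_min <= 1):
            raise ValueError("correlation thresholds must be in [-1, 1]")
        if self.cis_window < 0 or self.min_lnc_length < 0:
            raise ValueError("window and length parameters must be non-negative")
        if not 1 <= self.min_votes <= 4:
            raise ValueError("min_votes must be between 1 and 4")

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        casts = {f.name: f.type for f in fields(cls)}
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path} line {lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in casts:
                raise ValueError(f"{path} line {lineno}: unknown config key {key!r}")
            kind = casts[key]
            if kind in ("bool", bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif kind in ("int", int):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def run_all(bundle_dir: str | Path, out_dir: str | Path,
            config: PipelineConfig | None = None) -> dict:
    """Run all seven stages on a bundle directory; returns the manifest."""
    cfg = config or PipelineConfig()
    cfg.validate()
    bundle = Path(bundle_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"config": asdict(cfg), "config_hash": _config_hash(cfg), "stages": []}

    def _stage(name: str):
        def wrap(fn):
            try:
                rows = fn()
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append({"name": name, "rows": int(rows)})
        return wrap

    models = read_transcript_models(bundle / BUNDLE_FILES["gtf"])
    transcript_seqs = read_fasta(bundle / BUNDLE_FILES["transcripts"])
    mirna_seqs = read_fasta(bundle / BUNDLE_FILES["mirnas"])
    counts_rna = read_expression_matrix(bundle / BUNDLE_FILES["counts_rna"], unit="count")
    counts_mirna = read_expression_matrix(bundle / BUNDLE_FILES["counts_mirna"], unit="count")
    design = read_design(bundle / BUNDLE_FILES["design"])
    go_table = read_go_annotations(bundle / BUNDLE_FILES["go"], bundle / BUNDLE_FILES["go_terms"])
    domain_hits = coding_potential.read_domain_hits(bundle / BUNDLE_FILES["domains"])

    state: dict = {}

    @_stage("classify")
    def _classify():
        verdicts = coding_potential.consensus_classify(
            transcript_seqs, domain_hits=domain_hits,
            min_votes=cfg.min_votes, min_lnc_length=cfg.min_lnc_length,
            required_ids=[m.transcript_id for m in models],
        )
        frame = coding_potential.verdicts_to_frame(verdicts)
        frame.to_csv(out / "verdicts.tsv", sep="\t")
        labels = {v.transcript_id: v.label for v in verdicts}
        biotype = {"lncRNA": "lncRNA", "mRNA": "mRNA", "too_short": "unclassified"}
        state["models"] = [m.with_biotype(biotype[labels[m.transcript_id]]) for m in models]
        state["labels"] = labels
        return len(verdicts)

    @_stage("normalize")
    def _normalize():
        lengths = {m.transcript_id: m.length for m in state["models"]}
        fpkm = expression.to_fpkm(counts_rna, lengths)
        tpm = expression.to_tpm(counts_mirna)  # tag counts: length 1
        fpkm.data.to_csv(out / "fpkm.tsv", sep="\t", index_label="feature_id")
        tpm.data.to_csv(out / "tpm_mirna.tsv", sep="\t", index_label="feature_id")
        state["fpkm"], state["tpm"] = fpkm, tpm
        return fpkm.shape[0] + tpm.shape[0]

    @_stage("de")
    def _de():
        from .io_formats import ExpressionMatrix

        labels = state["labels"]
        results = {}
        for cls_name, label in (("mrna", "mRNA"), ("lncrna", "lncRNA")):
            ids = [t for t in counts_rna.feature_ids if labels[t] == label]
            sub_counts = ExpressionMatrix(counts_rna.data.loc[ids], unit="count")
            sub_norm = ExpressionMatrix(state["fpkm"].data.loc[ids], unit="FPKM")
            res = diff_expr.call_differential(
                sub_counts, sub_norm, design,
                q_threshold=cfg.q_threshold, fc_threshold=cfg.fc_threshold)
            res.to_csv(out / f"de_{cls_name}.tsv", sep="\t")
            results[cls_name] = res
        res = diff_expr.call_differential(
            counts_mirna, state["tpm"], design,
            q_threshold=cfg.q_threshold, fc_threshold=cfg.fc_threshold)
        res.to_csv(out / "de_mirna.tsv", sep="\t")
        results["mirna"] = res
        state["de"] = results
        return sum(len(r) for r in results.values())

    @_stage("targets-mirna")
    def _targets_mirna():
        biotypes = {m.transcript_id: m.biotype for m in state["models"]}
        edges = mirna_targets.predict_mirna_targets(
            mirna_seqs, transcript_seqs, biotypes,
            score_cutoff=cfg.score_cutoff, ratio_cutoff=cfg.ratio_cutoff)
        write_edges(edges, out / "edges_mirna.tsv")
        state["edges_mirna"] = edges
        return len(edges)

    @_stage("targets-lncrna")
    def _targets_lncrna():
        edges = lncrna_targets.predict_lncrna_targets(
            state["models"], transcript_seqs, state["fpkm"],
            spearman_min=cfg.spearman_min, pearson_min=cfg.pearson_min,
            cis_window=cfg.cis_window, energy_threshold=cfg.energy_threshold,
            loop_penalty=cfg.loop_penalty, log_pearson=cfg.log_pearson)
        write_edges(edges, out / "edges_lncrna.tsv")
        state["edges_lncrna"] = edges
        return len(edges)

    @_stage("cerna")
    def _cerna():
        de = state["de"]
        de_sets = {
            cls_name: set(res.index[res["call"] != "ns"])
            for cls_name, res in de.items()
        }
        state["de_sets"] = de_sets
        triads = cerna_enrich.assemble_triads(
            de_sets["mirna"], de_sets["lncrna"], de_sets["mrna"], state["edges_mirna"])
        networks = cerna_enrich.build_networks(triads)
        state["triads"], state["networks"] = triads, networks
        lines = ["mirna\tlncrna\tmrna"]
        lines += [f"{t.mirna_id}\t{t.lncrna_id}\t{t.mrna_id}" for t in triads]
        (out / "triads.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
        node_lines = ["network_id\tnode_id\tnode_class"]
        edge_lines = ["network_id\tsource\ttarget"]
        for net in networks:
            for cls_name, nodes in (("miRNA", net.mirnas), ("lncRNA", net.lncrnas),
                                    ("mRNA", net.mrnas)):
                node_lines += [f"{net.network_id}\t{n}\t{cls_name}" for n in nodes]
            seen = set()
            for t in net.triads:
                for a, b in ((t.mirna_id, t.lncrna_id), (t.mirna_id, t.mrna_id)):
                    if (a, b) not in seen:
                        seen.add((a, b))
                        edge_lines.append(f"{net.network_id}\t{a}\t{b}")
        (out / "networks_nodes.tsv").write_text("\n".join(node_lines) + "\n", encoding="utf-8")
        (out / "networks_edges.tsv").write_text("\n".join(edge_lines) + "\n", encoding="utf-8")
        truth_path = bundle / BUNDLE_FILES["truth"]
        if truth_path.exists():
            report = recovery_report(
                SyntheticTruth.from_dict(read_json(truth_path)), state)
            write_json(report, out / "recovery_report.json")
        return len(triads)

    @_stage("enrich")
    def _enrich():
        labels = state["labels"]
        universe = [t for t in counts_rna.feature_ids if labels[t] == "mRNA"]
        de_lnc_targets = {
            e.target_id for e in state["edges_lncrna"]
            if e.regulator_id in state["de_sets"]["lncrna"]
        }
        de_set = sorted(de_lnc_targets & state["de_sets"]["mrna"])
        results = cerna_enrich.hypergeom_enrich(de_set, universe, go_table, alpha=cfg.go_alpha)
        rows = [{"term_id": r.term_id, "term_name": r.term_name, "k": r.k, "K": r.K,
                 "n": r.n, "N": r.N, "p": r.p, "enriched": r.enriched} for r in results]
        pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p",
                                    "enriched"]).to_csv(out / "enrichment.tsv", sep="\t",
                                                        index=False)
        return len(results)

    write_json(manifest, out / "manifest.json")
    return manifest


def recovery_report(truth: SyntheticTruth, state: dict) -> dict:
    """Compare pipeline output against the generator's planted truth."""
    de_sets = state["de_sets"]

    def _recall(planted: set[str], found: set[str]) -> float:
        return len(planted & found) / len(planted) if planted else 1.0

    found_triads = {(t.mirna_id, t.lncrna_id, t.mrna_id) for t in state["triads"]}
    planted_triads = {(t["mirna"], t["lncrna"], t["mrna"]) for t in truth.planted_triads}

    mirna_edge_pairs = {(e.regulator_id, e.target_id) for e in state["edges_mirna"]}
    planted_sites = {(s["mirna"], s["target"]) for s in truth.planted_mirna_targets}

    lnc_edges = {(e.regulator_id, e.target_id): e for e in state["edges_lncrna"]}
    expected_mode = {"antisense_overlap": "cis_overlap", "neighbor_lt10kb": "cis_nonoverlap",
                     "distal_correlated": "trans"}
    pair_recall = {}
    for relation, mode in expected_mode.items():
        pairs = [p for p in truth.planted_lnc_pairs if p["relation"] == relation]
        hit = sum(1 for p in pairs
                  if (p["lncrna"], p["mrna"]) in lnc_edges
                  and lnc_edges[(p["lncrna"], p["mrna"])].mode == mode)
        pair_recall[relation] = {"planted": len(pairs), "recovered": hit}
    control_with_edge = sum(
        1 for p in truth.control_lnc_pairs if (p["lncrna"], p["mrna"]) in lnc_edges)

    return {
        "triads_planted": len(planted_triads),
        "triads_recovered": len(planted_triads & found_triads),
        "triads_spurious": len(found_triads - planted_triads),
        "de_recall": {
            "mirna": _recall(set(truth.de_mirnas), de_sets["mirna"]),
            "lncrna": _recall(set(truth.de_lncrnas), de_sets["lncrna"]),
            "mrna": _recall(set(truth.de_mrnas), de_sets["mrna"]),
        },
        "mirna_site_recall": (
            len(planted_sites & mirna_edge_pairs) / len(planted_sites)
            if planted_sites else 1.0),
        "lnc_pair_recovery": pair_recall,
        "control_pairs_with_edges": control_with_edge,
        "n_networks": len(state["networks"]),
    }
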