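"""ceRNA triad/network assembly and hypergeometric GO enrichment.

A ceRNA triad is a differentially expressed miRNA that targets both a
differentially expressed lncRNA and a differentially expressed mRNA: the
lncRNA and the mRNA compete for the shared miRNA.  Networks are the
connected components of the union graph of all triad edges; a
lncRNA->mRNA edge, when present, is annotation rather than a membership
requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy import stats

from .io_formats import GOAnnotationTable, InteractionEdge


@dataclass(frozen=True)
class CeRNATriad:
    """A DE (miRNA, lncRNA, mRNA) triple supported by two miRNA edges."""

    mirna_id: str
    lncrna_id: str
    mrna_id: str


@dataclass
class CeRNANetwork:
    """One connected component of the triad union graph."""

    network_id: str
    triads: list[CeRNATriad]
    mirnas: list[str] = field(default_factory=list)
    lncrnas: list[str] = field(default_factory=list)
    mrnas: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.mirnas) + len(self.lncrnas) + len(self.mrnas)


def assemble_triads(
    de_mirnas: Iterable[str],
    de_lncrnas: Iterable[str],
    de_mrnas: Iterable[str],
    mirna_edges: Sequence[InteractionEdge],
) -> list[CeRNATriad]:
    """All (miRNA, lncRNA, mRNA) triples of DE features joined by edges.

    For every DE miRNA, every DE lncRNA it targets is combined with every
    DE mRNA it targets (cartesian product per miRNA).  Output order is
    deterministic (sorted ids).
    """
    de_mi, de_ln, de_mr = set(de_mirnas), set(de_lncrnas), set(de_mrnas)
    lnc_targets: dict[str, set[str]] = {}
    mrna_targets: dict[str, set[str]] = {}
    for e in mirna_edges:
        if e.edge_type == "mirna_lncrna":
            lnc_targets.setdefault(e.regulator_id, set()).add(e.target_id)
        elif e.edge_type == "mirna_mrna":
            mrna_targets.setdefault(e.regulator_id, set()).add(e.target_id)
    triads = []
    for m in sorted(de_mi):
        for l in sorted(lnc_targets.get(m, set()) & de_ln):
            for g in sorted(mrna_targets.get(m, set()) & de_mr):
                triads.append(CeRNATriad(m, l, g))
    return triads


def build_networks(triads: Sequence[CeRNATriad]) -> list[CeRNANetwork]:
    """Connected components of the triad edge union, largest first.

    Components are sorted by size (descending) then by lexicographically
    smallest node; node class lists are the union of member triads.
    """
    graph = nx.Graph()
    for t in triads:
        graph.add_edge(t.mirna_id, t.lncrna_id)
        graph.add_edge(t.mirna_id, t.mrna_id)
    components = sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    networks = []
    for idx, nodes in enumerate(components, start=1):
        member = [t for t in triads
                  if t.mirna_id in nodes or t.lncrna_id in nodes or t.mrna_id in nodes]
        networks.append(CeRNANetwork(
            network_id=f"ceRNA_net_{idx:03d}",
            triads=member,
            mirnas=sorted({t.mirna_id for t in member}),
            lncrnas=sorted({t.lncrna_id for t in member}),
            mrnas=sorted({t.mrna_id for t in member}),
        ))
    return networks


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # DE and annotated with the term
    K: int  # annotated with the term in the universe
    n: int  # DE set size
    N: int  # universe size
    p: float  # hypergeometric upper tail P(X >= k)
    enriched: bool


def hypergeom_enrich(
    de_set: Iterable[str],
    universe: Iterable[str],
    annotations: GOAnnotationTable | Mapping[str, frozenset[str]],
    alpha: float = 0.05,
    bh: bool = False,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric term enrichment of ``de_set`` in ``universe``.

    For each term with at least one annotated universe member,
    p = P(X >= k) with X ~ Hypergeometric(N, K, n).  By default no
    multiple-testing correction is applied (``enriched`` iff p < alpha);
    ``bh=True`` switches the enrichment call to BH-adjusted values.
    """
    if isinstance(annotations, GOAnnotationTable):
        ann = annotations.annotations
        names = annotations.term_names
    else:
        ann = dict(annotations)
        names = {}
    de = set(de_set)
    uni = set(universe)
    if not de <= uni:
        raise ValueError(f"DE set is not a subset of the universe: {sorted(de - uni)[:5]} ...")
    term_members: dict[str, set[str]] = {}
    for fid in uni:
        for term in ann.get(fid, ()):
            term_members.setdefault(term, set()).add(fid)
    N, n = len(uni), len(de)
    results = []
    for term in sorted(term_members):
        members = term_members[term]
        K = len(members)
        k = len(members & de)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        results.append(EnrichmentResult(term, names.get(term, ""), k, K, n, N, p, p < alpha))
    if bh:
        from .diff_expr import bh_adjust

        qs = bh_adjust([r.p for r in results]) if results else []
        for r, q in zip(results, qs):
            r.enriched = bool(q < alpha)
    results.sort(key=lambda r: (r.p, r.term_id))
    return results
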