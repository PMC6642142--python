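"""Bidirectional ceRNA (sponge) network construction.

A *sponge triad* is the directed hypothesis lncRNA -> miRNA -> mRNA in
which the lncRNA sequesters the miRNA and thereby de-represses the mRNA:
in the *forward* direction the lncRNA and mRNA are up-regulated and the
miRNA down-regulated; *reverse* is the mirror.  Highly expressed
lncRNAs sponge more effectively, so forward candidates additionally pass
a raw-intensity floor (default: strictly above 100 linear units) and an
annotation whitelist; by convention the reverse (down-regulated) leg is
gated by significance alone.

Triads from both directions assemble into a tripartite graph with typed
edges: lncRNA->miRNA edges weighted by binding-site count, miRNA->mRNA
target edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .diffexpr import DERecord
from .io_formats import InteractionTable

__all__ = [
    "SpongeTriad",
    "CeRNANetwork",
    "select_sponge_lncrnas",
    "build_sponge_triads",
    "assemble_network",
    "network_stats",
]


@dataclass(frozen=True)
class SpongeTriad:
    lnc_id: str
    mirna_id: str
    mrna_id: str
    direction: str  # forward | reverse
    binding_sites: int
    lnc_fc: float
    mirna_fc: float
    mrna_fc: float

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.binding_sites < 1:
            raise ValueError("binding_sites must be >= 1")
        sgn = 1 if self.direction == "forward" else -1
        if not (sgn * self.lnc_fc > 0 and sgn * self.mirna_fc < 0
                and sgn * self.mrna_fc > 0):
            raise ValueError(
                f"fold-change signs inconsistent with {self.direction} triad "
                f"({self.lnc_id}, {self.mirna_id}, {self.mrna_id})"
            )


@dataclass
class CeRNANetwork:
    """Tripartite graph over lncRNA / miRNA / mRNA nodes."""

    graph: nx.DiGraph

    def nodes_of_class(self, cls: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("cls") == cls
        )

    def validate(self) -> None:
        order = {"lncRNA": 0, "miRNA": 1, "mRNA": 2}
        for u, v in self.graph.edges():
            cu = self.graph.nodes[u]["cls"]
            cv = self.graph.nodes[v]["cls"]
            if order[cv] != order[cu] + 1:
                raise ValueError(f"non-tripartite edge {u} -> {v} ({cu}->{cv})")
        for n in self.graph.nodes():
            if self.graph.degree(n) == 0:
                raise ValueError(f"isolated node {n}")


def select_sponge_lncrnas(
    lnc_de: Sequence[DERecord],
    direction: str = "up",
    intensity_min: float | None = 100.0,
    whitelist: Iterable[str] | None = None,
) -> set[str]:
    """Significant-in-direction lncRNAs with raw intensity strictly above
    ``intensity_min`` (skip with None) and, if given, membership in the
    annotation ``whitelist``."""
    if direction not in ("up", "down"):
        raise ValueError(f"bad direction {direction!r}")
    wl = set(whitelist) if whitelist is not None else None
    out = set()
    for r in lnc_de:
        if r.direction != direction:
            continue
        if intensity_min is not None and not r.raw_intensity > intensity_min:
            continue
        if wl is not None and r.feature_id not in wl:
            continue
        out.add(r.feature_id)
    return out


def build_sponge_triads(
    lnc_set: Iterable[str],
    mirna_de: Sequence[DERecord],
    mrna_de: Sequence[DERecord],
    binding_table: InteractionTable,
    target_table: InteractionTable,
    direction: str = "forward",
    lnc_de: Sequence[DERecord] | None = None,
) -> list[SpongeTriad]:
    """Emit triad (L, M, G) iff L is a selected sponge lncRNA, M is
    significant in the opposite direction with a binding site on L, and
    G is significant in L's direction and a target of M.  Binding-site
    counts are carried from the binding table."""
    if direction not in ("forward", "reverse"):
        raise ValueError(f"bad direction {direction!r}")
    if binding_table.kind != "lnc_mirna_binding":
        raise ValueError(f"binding table has kind {binding_table.kind!r}")
    if target_table.kind != "mirna_mrna_target":
        raise ValueError(f"target table has kind {target_table.kind!r}")
    lnc_dir = "up" if direction == "forward" else "down"
    mir_dir = "down" if direction == "forward" else "up"
    lnc_set = set(lnc_set)
    lnc_fc = {r.feature_id: r.signed_fc for r in lnc_de or []}
    mir = {r.feature_id: r for r in mirna_de if r.direction == mir_dir}
    mr = {r.feature_id: r for r in mrna_de if r.direction == lnc_dir}
    targets_by_mir: dict[str, list[str]] = {}
    for m, g, _ev in target_table.records:
        targets_by_mir.setdefault(m, []).append(g)
    sgn = 1.0 if direction == "forward" else -1.0
    triads = []
    for lnc, mirna, sites in binding_table.records:
        if lnc not in lnc_set or mirna not in mir:
            continue
        for gene in targets_by_mir.get(mirna, ()):
            if gene not in mr:
                continue
            triads.append(
                SpongeTriad(
                    lnc_id=lnc, mirna_id=mirna, mrna_id=gene,
                    direction=direction, binding_sites=int(sites),
                    lnc_fc=lnc_fc.get(lnc, sgn * 1.5),
                    mirna_fc=mir[mirna].signed_fc,
                    mrna_fc=mr[gene].signed_fc,
                )
            )
    triads.sort(key=lambda t: (t.lnc_id, t.mirna_id, t.mrna_id))
    return triads


def assemble_network(
    triads_forward: Sequence[SpongeTriad] = (),
    triads_reverse: Sequence[SpongeTriad] = (),
) -> CeRNANetwork:
    """Union the two directed triad sets into one typed tripartite graph.
    Raises if a triad's declared direction disagrees with its fold-change
    signs (already enforced per-triad) or directions are mixed up."""
    for t in triads_forward:
        if t.direction != "forward":
            raise ValueError(f"triad {t.lnc_id} in forward set has {t.direction}")
    for t in triads_reverse:
        if t.direction != "reverse":
            raise ValueError(f"triad {t.lnc_id} in reverse set has {t.direction}")
    g = nx.DiGraph()
    for t in (*triads_forward, *triads_reverse):
        g.add_node(t.lnc_id, cls="lncRNA", signed_fc=t.lnc_fc, direction=t.direction)
        g.add_node(t.mirna_id, cls="miRNA", signed_fc=t.mirna_fc,
                   direction=t.direction)
        g.add_node(t.mrna_id, cls="mRNA", signed_fc=t.mrna_fc, direction=t.direction)
        g.add_edge(t.lnc_id, t.mirna_id, edge_type="lnc_mirna",
                   binding_sites=t.binding_sites)
        g.add_edge(t.mirna_id, t.mrna_id, edge_type="mirna_mrna")
    net = CeRNANetwork(g)
    if g.number_of_nodes():
        net.validate()
    return net


def network_stats(network: CeRNANetwork) -> pd.DataFrame:
    """Per-node table: class, degree, summed binding sites (lncRNA
    nodes) and distinct-target count (miRNA nodes)."""
    g = network.graph
    rows = []
    for n in sorted(g.nodes()):
        cls = g.nodes[n]["cls"]
        deg = g.degree(n)
        total_sites = 0
        n_targets = 0
        if cls == "lncRNA":
            total_sites = sum(
                d.get("binding_sites", 0) for _u, _v, d in g.out_edges(n, data=True)
            )
        elif cls == "miRNA":
            n_targets = sum(
                1 for _u, _v, d in g.out_edges(n, data=True)
                if d.get("edge_type") == "mirna_mrna"
            )
        rows.append((n, cls, deg, total_sites, n_targets))
    return pd.DataFrame(
        rows, columns=["id", "class", "degree", "total_binding_sites",
                       "distinct_targets"]
    )
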