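"""Weighted phonological network per AoA stage, plus node/network statistics.

Nodes are the word forms known at a stage (cumulative vocabulary); an edge
joins two forms at segment edit distance exactly 1 and carries the integer
phonetic-similarity weight.  Because the neighbor relation does not depend on
the stage, stage networks are nested: every stage-s edge is present at
stage s+1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import networkx as nx
import numpy as np

from . import phonetics
from .phonetics import FeatureTable
from .types import N_STAGES, StagedLexicon, Transcription, _check_stage

WeightFn = Callable[[Transcription, Transcription], int]


class AssortativityUndefined(ValueError):
    """Degree variance over edge endpoints is zero; the correlation is undefined."""


@dataclass
class PhonNetwork:
    """Stage network: an undirected weighted graph over word forms."""

    stage: int
    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, phon: Transcription) -> int:
        return self.graph.degree(tuple(phon))

    def weighted_degree(self, phon: Transcription) -> int:
        return int(self.graph.degree(tuple(phon), weight="similarity_int"))

    def neighbors(self, phon: Transcription) -> set[Transcription]:
        return set(self.graph.neighbors(tuple(phon)))


def build_stage_network(
    lexicon: StagedLexicon,
    stage: int,
    ft: FeatureTable | None = None,
    weight_fn: WeightFn | None = None,
) -> PhonNetwork:
    """Construct the weighted one-segment neighbor network at ``stage``.

    Edge weights come from the ALINE-style similarity under ``ft`` unless an
    explicit ``weight_fn`` overrides them (used e.g. by hand-built fixtures).
    """
    _check_stage(stage)
    g = nx.Graph(stage=stage)
    vocab = lexicon.stage_vocabulary(stage)
    for phon in vocab:
        e = lexicon.entry(phon)
        g.add_node(phon, aoa=e.aoa, freq_log=e.freq_log, length=e.length, l1_density=e.l1_density)
    for a, b in phonetics.find_neighbors(vocab):
        if weight_fn is not None:
            w = int(weight_fn(a, b))
        else:
            w = phonetics.similarity_int(a, b, ft)
        g.add_edge(a, b, similarity_int=w)
    return PhonNetwork(stage=stage, graph=g)


def build_all_networks(
    lexicon: StagedLexicon,
    ft: FeatureTable | None = None,
    weight_fn: WeightFn | None = None,
) -> dict[int, PhonNetwork]:
    """All six stage networks, via induced subgraphs of the final network.

    Edges are stage-independent, so each stage network is the subgraph of the
    stage-6 network induced by the stage vocabulary — output-equivalent to
    building each stage from scratch, but the phonetic weights are computed
    only once.
    """
    final = build_stage_network(lexicon, N_STAGES, ft, weight_fn)
    nets = {N_STAGES: final}
    for s in range(1, N_STAGES):
        sub = final.graph.subgraph(lexicon.stage_vocabulary(s)).copy()
        sub.graph["stage"] = s
        nets[s] = PhonNetwork(stage=s, graph=sub)
    return nets


def assortativity_degree(net: PhonNetwork) -> float:
    """Pearson correlation between the degrees of connected node pairs.

    Each undirected edge contributes both orientations, the standard degree-
    correlation convention.  Zero variance in endpoint degrees (e.g. a cycle)
    makes the correlation undefined and raises :class:`AssortativityUndefined`.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise AssortativityUndefined("network has no edges")
    deg = dict(g.degree())
    x, y = [], []
    for u, v in g.edges():
        x.extend((deg[u], deg[v]))
        y.extend((deg[v], deg[u]))
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if np.ptp(xa) == 0:
        raise AssortativityUndefined("all endpoint degrees are equal")
    return float(np.corrcoef(xa, ya)[0, 1])


def hermit_fraction(lexicon: StagedLexicon, stage: int, net: PhonNetwork) -> float:
    """Fraction of words uniquely acquired at ``stage`` that are isolated in ``net``.

    Passing the final-stage network gives the share of stage entrants that
    never experience growth (lexical hermits); passing the entry-stage network
    gives isolation at acquisition time.
    """
    new = lexicon.new_at_stage(stage)
    if not new:
        raise ValueError(f"no words uniquely acquired at stage {stage}")
    isolated = sum(1 for p in new if p not in net.graph or net.degree(p) == 0)
    return isolated / len(new)


def write_edge_list(net: PhonNetwork, path: str | Path) -> None:
    """Edge-list TSV: phon_a, phon_b, similarity_int (sorted, reproducible)."""
    rows = sorted(
        ("".join(min(u, v)), "".join(max(u, v)), d["similarity_int"])
        for u, v, d in net.graph.edges(data=True)
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("phon_a\tphon_b\tsimilarity_int\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w}\n")


def write_graphml(net: PhonNetwork, path: str | Path) -> None:
    """GraphML export with node attributes aoa/freq_log/length/l1_density."""
    g = nx.relabel_nodes(net.graph, {n: "".join(n) for n in net.graph.nodes}, copy=True)
    nx.write_graphml(g, path)
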