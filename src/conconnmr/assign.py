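"""Sequential-link assembly and Table-style scoring from anchor strips.

Each HNCO anchor defines a strip: a 2D (CO, N) cross-section whose picks are
sequential CON pairs.  The diagonal pick coincides with the anchor's own pair
(CO_{k-1}, N_k); the other picks are forward/backward cross-peaks whose pair
belongs to a neighbouring residue.  Linking matches every non-diagonal pick
against the diagonal pairs of the other anchors using a normalized Euclidean
distance; the closest in-tolerance anchor is accepted unless a second
candidate is nearly as close (distance ratio below the ambiguity ratio), in
which case the pick is rejected as ambiguous -- the remedy for real overlap is
the extra amide-proton dimension, not guessing.

Prolines carry no strip, so the pair (CO_{p-1}, N_p) matches no diagonal.  It
does, however, appear twice: as the forward pick of strip p-1 and the backward
pick of strip p+1.  Two unmatched picks from distinct strips that agree within
tolerance AND whose nitrogen lies in the proline 15N window create a virtual
pair node bridging the gap.  The nitrogen gate is what distinguishes a genuine
proline gap from a merely missing strip (an exchange-broadened amide, say),
whose flanking orphan picks carry an ordinary amide nitrogen; such gaps break
the chain instead of being bridged.

Direction (forward vs backward) of an accepted adjacency is not decidable
from shift content alone without residue typing, so chains are assembled
orientation-free; the scoring stage labels directions from ground-truth
provenance and reports the two Table-style rows "NN % (m/e)".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .peaks import ExperimentSpec, eligible_pairs
from .shiftgen import ShiftTable
from .smft import AnchorPeak

__all__ = ["Pick", "Strip", "Node", "Edge", "LinkGraph", "LinkStats",
           "build_links", "pair_complementary_picks", "assemble_chains",
           "score_links", "strips_from_peaklist", "PROLINE_N_WINDOW"]

#: Amide-nitrogen window (ppm) that identifies a bridged pair as a proline.
PROLINE_N_WINDOW = (128.0, 143.0)


@dataclass(frozen=True)
class Pick:
    """A 2D (CO, N) pick.

    ``parts`` identifies the underlying 1D picks when the 2D pick is a
    combination from the complementary 4Ds; combinations sharing a constituent
    with an already-accepted pick are excluded from proline bridging.
    """

    co_ppm: float
    n_ppm: float
    height: float
    parts: tuple = ()


@dataclass
class Strip:
    """One anchor with the cross-peaks picked from its 2D section."""

    anchor: AnchorPeak
    picks: list[Pick] = field(default_factory=list)

    @property
    def label(self) -> str:
        return self.anchor.label

    @property
    def own_pair(self) -> tuple[float, float]:
        return (self.anchor.co_ppm, self.anchor.n_ppm)


@dataclass(frozen=True)
class Node:
    """A CON pair node: an anchor's diagonal pair or a virtual bridged pair."""

    label: str
    co_ppm: float
    n_ppm: float
    kind: str                      # "anchor" | "virtual"
    truth_residue: int | None = None


@dataclass(frozen=True)
class Edge:
    """Evidence that ``source`` strip saw the pair of ``target`` as a cross-peak."""

    source: str                    # strip label
    target: str                    # node label
    distance: float                # normalized match distance (<= 1)
    pick: Pick


@dataclass
class LinkGraph:
    nodes: dict[str, Node]
    edges: list[Edge]
    ambiguities: list[tuple[str, Pick, list[str]]]
    unmatched: list[tuple[str, Pick]]
    flagged_strips: list[str]      # strips without an identifiable diagonal
    strips: dict[str, Strip]

    def edges_from(self, strip_label: str) -> list[Edge]:
        return [e for e in self.edges if e.source == strip_label]

    def edges_to(self, node_label: str) -> list[Edge]:
        return [e for e in self.edges if e.target == node_label]


@dataclass(frozen=True)
class LinkStats:
    """Forward/backward link completeness in the Table row format."""

    forward_matched: int
    forward_eligible: int
    backward_matched: int
    backward_eligible: int

    @staticmethod
    def _fmt(m: int, e: int) -> str:
        pct = round(100.0 * m / e) if e else 0
        return f"{pct} % ({m}/{e})"

    @property
    def forward_row(self) -> str:
        return self._fmt(self.forward_matched, self.forward_eligible)

    @property
    def backward_row(self) -> str:
        return self._fmt(self.backward_matched, self.backward_eligible)


def _distance(co_a: float, n_a: float, co_b: float, n_b: float,
              tol_co: float, tol_n: float) -> float:
    return math.hypot((co_a - co_b) / tol_co, (n_a - n_b) / tol_n)


def build_links(strips: list[Strip], tol_co: float = 0.05, tol_n: float = 0.2,
                ambiguity_ratio: float = 1.2,
                proline_n_window: tuple[float, float] = PROLINE_N_WINDOW) -> LinkGraph:
    """Match picks to anchor diagonals and bridge proline gaps.

    Steps: (1) each strip's diagonal is the nearest in-tolerance pick to its
    own (CO, N); a strip without one is flagged and excluded from the eligible
    set.  (2) Every other pick is matched against all other anchors' pairs;
    closest wins, near-ties (ratio < ``ambiguity_ratio``) are rejected and
    recorded.  (3) Unmatched picks from distinct strips that mutually agree
    and sit in the proline nitrogen window form virtual bridge nodes.
    """
    nodes: dict[str, Node] = {}
    for s in strips:
        if s.label in nodes:
            raise ValueError(f"duplicate strip label {s.label}")
        nodes[s.label] = Node(s.label, s.anchor.co_ppm, s.anchor.n_ppm, "anchor",
                              s.anchor.truth_residue)

    ambiguities: list[tuple[str, Pick, list[str]]] = []
    no_anchor: list[tuple[str, Pick]] = []
    flagged: list[str] = []
    used_parts: dict[str, set] = {s.label: set() for s in strips}
    diagonals: dict[str, Pick] = {}

    for s in strips:
        co0, n0 = s.own_pair
        diag, best = None, float("inf")
        for p in s.picks:
            d = _distance(p.co_ppm, p.n_ppm, co0, n0, tol_co, tol_n)
            if d <= 1.0 and d < best:
                diag, best = p, d
        if diag is None:
            flagged.append(s.label)
        else:
            diagonals[s.label] = diag
            used_parts[s.label].update(diag.parts)

    # Candidate edges (pick -> anchor) with ambiguity rejection.
    edge_cands: list[tuple[float, str, str, Pick]] = []
    for s in strips:
        diag = diagonals.get(s.label)
        for p in s.picks:
            if p is diag:
                continue
            cands = []
            for t in strips:
                if t is s:
                    continue
                d = _distance(p.co_ppm, p.n_ppm, t.anchor.co_ppm, t.anchor.n_ppm,
                              tol_co, tol_n)
                if d <= 1.0:
                    cands.append((d, t.label))
            cands.sort()
            if not cands:
                no_anchor.append((s.label, p))
            elif len(cands) >= 2 and cands[1][0] < ambiguity_ratio * max(cands[0][0], 0.5):
                # the floor of half the tolerance radius keeps a dead-on best
                # match from silently beating an equally plausible runner-up
                ambiguities.append((s.label, p, [c[1] for c in cands[:2]]))
            else:
                edge_cands.append((cands[0][0], s.label, cands[0][1], p))

    # Candidate proline bridges among picks that matched no anchor.  The
    # mutual comparison is pick against pick, so both carry position error and
    # the tolerance is widened by sqrt(2) relative to pick-vs-anchor matching.
    bridge_cands: list[tuple[float, int, int]] = []
    for a in range(len(no_anchor)):
        sa, pa = no_anchor[a]
        for b in range(a + 1, len(no_anchor)):
            sb, pb = no_anchor[b]
            if sb == sa:
                continue
            n_mean = 0.5 * (pa.n_ppm + pb.n_ppm)
            if not proline_n_window[0] <= n_mean <= proline_n_window[1]:
                continue
            d = _distance(pa.co_ppm, pa.n_ppm, pb.co_ppm, pb.n_ppm,
                          tol_co * math.sqrt(2), tol_n * math.sqrt(2))
            if d <= 1.0:
                bridge_cands.append((d, a, b))

    # Global greedy acceptance by ascending match distance: better evidence
    # consumes constituent picks first, which keeps accidental matches of the
    # redundant 4D combinations from starving genuine links and bridges.
    merged: list[tuple[float, int, str, tuple]] = []
    for d, src, tgt, p in edge_cands:
        merged.append((d, 0, src, (tgt, p)))
    for d, a, b in bridge_cands:
        merged.append((d / 2, 1, no_anchor[a][0], (a, b)))
    merged.sort(key=lambda item: (item[0], item[1], item[2]))

    edges: list[Edge] = []
    bridged = [False] * len(no_anchor)

    def consumed(strip_label: str, pick: Pick) -> bool:
        return any(part in used_parts[strip_label] for part in pick.parts)

    for d, kind, src, payload in merged:
        if kind == 0:
            tgt, p = payload
            if consumed(src, p):
                continue
            edges.append(Edge(src, tgt, d, p))
            used_parts[src].update(p.parts)
        else:
            a, b = payload
            sa, pa = no_anchor[a]
            sb, pb = no_anchor[b]
            if bridged[a] or bridged[b] or consumed(sa, pa) or consumed(sb, pb):
                continue
            label = f"virtual{sum(1 for x in nodes.values() if x.kind == 'virtual') + 1}"
            nodes[label] = Node(label, 0.5 * (pa.co_ppm + pb.co_ppm),
                                0.5 * (pa.n_ppm + pb.n_ppm), "virtual")
            edges.append(Edge(sa, label, d, pa))
            edges.append(Edge(sb, label, d, pb))
            bridged[a] = bridged[b] = True
            used_parts[sa].update(pa.parts)
            used_parts[sb].update(pb.parts)

    return LinkGraph(nodes=nodes, edges=edges, ambiguities=ambiguities,
                     unmatched=[u for u, f in zip(no_anchor, bridged) if not f],
                     flagged_strips=flagged, strips={s.label: s for s in strips})


def pair_complementary_picks(co_picks: list[tuple[float, float]],
                             n_picks: list[tuple[float, float]]) -> list[Pick]:
    """Combine CO-only and N-only picks of the complementary 4Ds into 2D picks.

    Each 4D contributes one coordinate; every (CO, N) combination is offered
    to the matcher with the weaker height.  Combinations that pair a forward
    CO with a backward N (or similar) correspond to no physical pair and are
    culled downstream because they match no anchor and fail the proline gate.
    """
    out = []
    for ic, (co, hc) in enumerate(co_picks):
        for jn, (n, hn) in enumerate(n_picks):
            out.append(Pick(co, n, min(hc, hn), parts=(("co", ic), ("n", jn))))
    return out


def _kept_adjacencies(graph: LinkGraph) -> list[tuple[str, str, float]]:
    """Undirected strip/node adjacencies after the mutual-consistency filter.

    An anchor-to-anchor edge k->m is kept if m also links back to k, or if m
    has spare capacity (fewer than two outgoing cross-edges), i.e. the reverse
    evidence is absent rather than contradictory.  Virtual nodes keep all
    their (already mutually supported) edges.
    """
    out_edges: dict[str, list[Edge]] = {}
    for e in graph.edges:
        out_edges.setdefault(e.source, []).append(e)

    kept = {}
    for e in graph.edges:
        tgt = graph.nodes[e.target]
        if tgt.kind == "anchor":
            back = [x for x in out_edges.get(e.target, []) if x.target == e.source]
            if not back and len(out_edges.get(e.target, [])) >= 2:
                continue  # target's both cross-peaks point elsewhere: contradiction
        key = tuple(sorted((e.source, e.target)))
        kept[key] = min(kept.get(key, float("inf")), e.distance)
    return [(a, b, d) for (a, b), d in kept.items()]


def assemble_chains(graph: LinkGraph) -> list[list[str]]:
    """Maximal consistent sequential chains, as ordered lists of node labels.

    Each chain is a simple path in the consistency-filtered adjacency graph;
    where branching or cycles survive (near-degenerate anchors), the worst
    (largest-distance) edges are removed first until only paths remain.
    Output is deterministic: chains sorted by length (descending) then first
    label; each chain oriented with its lexicographically smaller end first.
    """
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    for a, b, d in _kept_adjacencies(graph):
        g.add_edge(a, b, distance=d)

    # Prune to a path forest: drop worst edges at branch points, open cycles.
    changed = True
    while changed:
        changed = False
        for node in list(g.nodes):
            if g.degree(node) > 2:
                worst = max(g.edges(node, data=True), key=lambda e: e[2]["distance"])
                g.remove_edge(worst[0], worst[1])
                changed = True
    for cyc in list(nx.cycle_basis(g)):
        ring = list(zip(cyc, cyc[1:] + cyc[:1]))
        worst = max(ring, key=lambda ab: g.edges[ab]["distance"])
        g.remove_edge(*worst)

    chains = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        ends = [n for n in sub if sub.degree(n) <= 1]
        if not ends:  # isolated node handled by degree<=1; safety net
            ends = [min(comp)]
        start = min(ends)
        path = [start]
        prev = None
        while True:
            nxt = [n for n in sub.neighbors(path[-1]) if n != prev]
            if not nxt:
                break
            prev = path[-1]
            path.append(nxt[0])
        chains.append(path)
    chains.sort(key=lambda c: (-len(c), c[0]))
    return chains


def _structurally_absent(residue: int, sequence: str) -> bool:
    """True when no strip can exist at ``residue`` (out of range or proline)."""
    n = len(sequence)
    return residue < 2 or residue > n or sequence[residue - 1] == "P"


def score_links(graph: LinkGraph, truth: ShiftTable, experiment: ExperimentSpec | str,
                tol_co: float = 0.05, tol_n: float = 0.2) -> LinkStats:
    """Forward/backward link completeness against ground truth.

    For pair (j-1, j): the forward carrier is strip j-1 (its forward
    cross-peak shows the pair), the backward carrier is strip j+1.  A pair is
    matched in a direction when the carrier strip has an accepted edge to a
    node whose (CO, N) equals the pair's true shifts within tolerance.  When
    the carrier cannot exist (chain terminus or proline), the direction is
    credited iff the pair's own node was identified -- a perfect data set then
    scores e/e in both rows, as it should.
    """
    sequence = truth.sequence
    pairs = eligible_pairs(experiment, sequence)

    strip_by_residue = {}
    for s in graph.strips.values():
        if s.anchor.truth_residue is not None:
            strip_by_residue[s.anchor.truth_residue] = s.label

    def node_matches_pair(node: Node, j: int) -> bool:
        return _distance(node.co_ppm, node.n_ppm, truth.shift(j - 1, "CO"),
                         truth.shift(j, "N"), tol_co, tol_n) <= 1.0

    def pair_node_identified(j: int) -> bool:
        lab = strip_by_residue.get(j)
        if lab is not None and lab not in graph.flagged_strips:
            return True  # anchor j's diagonal pair was identified
        return any(n.kind == "virtual" and node_matches_pair(n, j)
                   for n in graph.nodes.values())

    def carried(carrier_res: int, j: int) -> bool:
        lab = strip_by_residue.get(carrier_res)
        if lab is None:
            return False
        return any(node_matches_pair(graph.nodes[e.target], j)
                   for e in graph.edges_from(lab))

    fwd = bwd = 0
    for (_, j) in pairs:
        if _structurally_absent(j - 1, sequence):
            fwd += pair_node_identified(j)
        else:
            fwd += carried(j - 1, j)
        if _structurally_absent(j + 1, sequence):
            bwd += pair_node_identified(j)
        else:
            bwd += carried(j + 1, j)
    e = len(pairs)
    return LinkStats(fwd, e, bwd, e)


def strips_from_peaklist(peaklist, shifts: ShiftTable) -> list[Strip]:
    """Noiseless strips directly from an enumerated 2D-resolved peak list.

    Bypasses synthesis/reconstruction: each anchor's peaks become exact picks.
    Used for fast linking studies and as the reference for the NUS pipeline.
    """
    if peaklist.experiment.resolved != ("COres", "Nres"):
        raise ValueError("need a peak list with CO and N resolved dimensions")
    by_anchor: dict[int, list] = {}
    for p in peaklist:
        by_anchor.setdefault(p.anchor_res, []).append(p)
    strips = []
    for k, plist in sorted(by_anchor.items()):
        anchor = AnchorPeak(label=shifts.label(k), hn_ppm=shifts.shift(k, "HN"),
                            n_ppm=shifts.shift(k, "N"), co_ppm=shifts.shift(k - 1, "CO"),
                            truth_residue=k)
        picks = [Pick(p.positions["COres"], p.positions["Nres"], p.amplitude)
                 for p in plist]
        strips.append(Strip(anchor=anchor, picks=picks))
    return strips
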