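"""Exclusive maximum-affinity pair extraction from a pen network.

Three algorithms, applied stepwise:

1. *greedy* — every cow is assigned its single top-scoring partner; the
   assignment need not be symmetric or exclusive.
2. *stable roommates* (Irving's algorithm) — an exclusive matching with no
   blocking pair: no two cows, not matched to each other, who each prefer
   the other over their current mate (or over being unmatched).
3. *maximum-weight matching* (blossom) — the fallback when no stable
   matching exists: an exclusive matching maximising total score.

Cows with only zero scores have no expressed preferences and are excluded
throughout; preference ties are broken by ascending cow id so every
algorithm is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .scoring import AffinityNetwork

__all__ = [
    "MatchedPair",
    "build_preferences",
    "greedy_pairs",
    "stable_roommates",
    "has_blocking_pair",
    "max_weight_pairs",
    "stepwise_match",
]


@dataclass(frozen=True)
class MatchedPair:
    """An affinity pair, with the algorithm that produced it."""

    pen_id: str
    cow_a: str
    cow_b: str
    score: float
    algorithm: str

    def __post_init__(self) -> None:
        if self.cow_a >= self.cow_b:
            raise ValueError("cow_a must sort before cow_b")
        if self.score <= 0:
            raise ValueError("zero-score pairs are excluded from matching")


def build_preferences(network: AffinityNetwork) -> dict[str, list[str]]:
    """Strict preference lists: partners by descending score, ties by id.

    Zero-score partners are omitted; cows with empty lists (no positive
    scores) are dropped from the table entirely.
    """
    prefs: dict[str, list[str]] = {}
    for i, cow in enumerate(network.cows):
        partners = [
            (float(s), p)
            for p, s in zip(network.cows, network.weights[i])
            if p != cow and s > 0
        ]
        partners.sort(key=lambda sp: (-sp[0], sp[1]))
        if partners:
            prefs[cow] = [p for _, p in partners]
    return prefs


def greedy_pairs(network: AffinityNetwork) -> list[dict]:
    """Top-partner assignment per cow (possibly asymmetric).

    Returns one record per cow with a positive score: its top partner, the
    score, and whether the choice is mutual (``symmetric=True`` when the
    partner's top choice is this cow).  Cows with only zero scores are
    unassigned and absent from the output.
    """
    prefs = build_preferences(network)
    tops = {cow: plist[0] for cow, plist in prefs.items()}
    out = []
    for cow in sorted(tops):
        partner = tops[cow]
        out.append(
            {
                "pen_id": network.pen_id,
                "cow": cow,
                "partner": partner,
                "score": network.score(cow, partner),
                "symmetric": tops.get(partner) == cow,
            }
        )
    return out


def _phase1(prefs: dict[str, list[str]], rank: dict[str, dict[str, int]], active: dict[str, dict[str, bool]]):
    """Proposal round of Irving's algorithm (semi-engagements)."""

    def first(p):
        for q in prefs[p]:
            if active[p][q]:
                return q
        return None

    holds: dict[str, str] = {}
    queue = sorted(prefs)
    while queue:
        x = queue.pop(0)
        while True:
            y = first(x)
            if y is None:
                break  # x exhausted its list; unmatched in any stable matching
            h = holds.get(y)
            if h is None:
                holds[y] = x
                break
            if rank[y][x] < rank[y][h]:
                holds[y] = x
                active[y][h] = active[h][y] = False
                x = h  # rejected holder proposes onward
                continue
            active[y][x] = active[x][y] = False
            # x keeps proposing down its list
    # each holder deletes everyone worse than the proposal it holds
    for y, x in holds.items():
        seen = False
        for z in prefs[y]:
            if not active[y][z]:
                continue
            if seen:
                active[y][z] = active[z][y] = False
            elif z == x:
                seen = True
            elif rank[y][z] > rank[y][x]:
                active[y][z] = active[z][y] = False
    return holds


def stable_roommates(prefs: dict[str, list[str]]) -> dict[str, str] | None:
    """Irving's stable-roommates algorithm over (possibly incomplete) lists.

    Returns a matching dict (both directions present) or ``None`` when no
    stable matching is found.  Stability is defined over the expressed
    preferences only: a blocking pair is two cows who each list the other
    and each prefer the other over their assigned mate (or are unmatched).
    Every candidate matching is verified against that definition before it
    is returned; any phase-2 list exhaustion is reported as "no stable
    matching" so the caller can fall back to maximum-weight matching.
    """
    # symmetrise: keep only mutually listed pairs (zero-score omissions)
    prefs = {p: [q for q in lst if p in prefs.get(q, [])] for p, lst in prefs.items()}
    prefs = {p: lst for p, lst in prefs.items() if lst}
    if not prefs:
        return {}
    rank = {p: {q: i for i, q in enumerate(lst)} for p, lst in prefs.items()}
    active = {p: {q: True for q in lst} for p, lst in prefs.items()}

    _phase1(prefs, rank, active)

    def current(p):
        return [q for q in prefs[p] if active[p][q]]

    # phase 2: eliminate rotations until all lists have <= 1 entry
    while True:
        long = [p for p in sorted(prefs) if len(current(p)) > 1]
        if not long:
            break
        # build the chain p_{i+1} = last(second(p_i))
        chain: list[str] = [long[0]]
        seen = {long[0]: 0}
        qs: list[str] = []
        while True:
            lst = current(chain[-1])
            if len(lst) < 2:
                return None  # chain fell off a shortened list: treat as unsolvable
            q = lst[1]
            qs.append(q)
            nxt = current(q)[-1]
            if nxt in seen:
                start = seen[nxt]
                cycle_p = chain[start:]
                cycle_q = qs[start:]
                break
            seen[nxt] = len(chain)
            chain.append(nxt)
        # eliminate the rotation: q_i rejects everyone it likes less than p_i
        for p, q in zip(cycle_p, cycle_q):
            for z in prefs[q]:
                if active[q][z] and rank[q][z] > rank[q][p]:
                    active[q][z] = active[z][q] = False
        for p in cycle_p:
            if len(current(p)) == 0:
                return None

    matching: dict[str, str] = {}
    for p in prefs:
        lst = current(p)
        if lst:
            matching[p] = lst[0]
    for p, q in list(matching.items()):
        if matching.get(q) != p:
            return None
    if has_blocking_pair(matching, prefs):
        return None
    return matching


def has_blocking_pair(matching: dict[str, str], prefs: dict[str, list[str]]) -> bool:
    """O(n^2) stability check over expressed preferences."""
    rank = {p: {q: i for i, q in enumerate(lst)} for p, lst in prefs.items()}

    def prefers(p, q):  # p prefers q over its current situation
        if q not in rank.get(p, {}):
            return False
        mate = matching.get(p)
        if mate is None:
            return True
        return rank[p][q] < rank[p].get(mate, math.inf)

    people = sorted(prefs)
    for i, p in enumerate(people):
        for q in people[i + 1 :]:
            if matching.get(p) == q:
                continue
            if prefers(p, q) and prefers(q, p):
                return True
    return False


def _nx_graph(network: AffinityNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(sorted(network.cows))
    edges = network.to_edge_frame().sort_values(["cow_a", "cow_b"])
    g.add_weighted_edges_from(edges[["cow_a", "cow_b", "score"]].itertuples(index=False, name=None))
    return g


def _matching_weight(g: nx.Graph, matching: set[tuple[str, str]]) -> float:
    return sum(g[a][b]["weight"] for a, b in matching)


def max_weight_pairs(network: AffinityNetwork, canonical: bool = True) -> list[tuple[str, str]]:
    """Maximum-weight (blossom) matching over the positive edges.

    With ``canonical=True`` ties between optimal matchings are broken toward
    the lexicographically smallest pair set: nodes are committed in
    ascending id order to their smallest-id partner that still permits an
    optimal completion.
    """
    g = _nx_graph(network)
    if g.number_of_edges() == 0:
        return []
    best = nx.max_weight_matching(g, maxcardinality=False)
    best_w = _matching_weight(g, best)
    if not canonical:
        return sorted(tuple(sorted(e)) for e in best)

    tol = 1e-9 * max(1.0, abs(best_w))
    forced: list[tuple[str, str]] = []
    h = g.copy()
    remaining = best_w
    for a in sorted(g.nodes):
        if not h.has_node(a):
            continue
        for b in sorted(h.neighbors(a)):
            w = h[a][b]["weight"]
            h2 = h.copy()
            h2.remove_node(a)
            h2.remove_node(b)
            rest = _matching_weight(h2, nx.max_weight_matching(h2, maxcardinality=False))
            if w + rest >= remaining - tol:
                forced.append((a, b))
                remaining -= w
                h = h2
                break
        else:
            if h.has_node(a):
                h.remove_node(a)  # a is unmatched in the canonical optimum
    return sorted(forced)


def stepwise_match(
    network: AffinityNetwork,
    mode: str = "exclusive",
    preferences: dict[str, list[str]] | None = None,
) -> list[MatchedPair]:
    """The stepwise pair-generation procedure.

    ``mode="non_exclusive"`` returns the greedy top-partner assignment
    (symmetric mutual choices only, tagged ``greedy``); ``mode="exclusive"``
    attempts a stable-roommates matching and falls back to maximum-weight
    blossom matching when none exists.  Zero-score pairs never appear; with
    an odd number of scorable cows one cow stays unmatched.

    ``preferences`` overrides the score-derived preference table for the
    stability step (symmetric score matrices essentially always admit a
    stable matching, so an explicitly cyclic table is the way to exercise
    the fallback).
    """
    if mode == "non_exclusive":
        pairs = []
        for rec in greedy_pairs(network):
            if rec["symmetric"] and rec["cow"] < rec["partner"]:
                pairs.append(
                    MatchedPair(network.pen_id, rec["cow"], rec["partner"], rec["score"], "greedy")
                )
        return pairs
    if mode != "exclusive":
        raise ValueError(f"unknown matching mode {mode!r}")

    prefs = build_preferences(network) if preferences is None else preferences
    matching = stable_roommates(prefs)
    if matching is not None:
        algorithm = "stable_roommates"
        edges = sorted({tuple(sorted((a, b))) for a, b in matching.items()})
    else:
        algorithm = "max_weight"
        edges = max_weight_pairs(network)
    return [
        MatchedPair(network.pen_id, a, b, network.score(a, b), algorithm)
        for a, b in edges
    ]


def pairs_frame(pairs: list[MatchedPair]):
    import pandas as pd

    return pd.DataFrame(
        [
            {"pen_id": p.pen_id, "cow_a": p.cow_a, "cow_b": p.cow_b, "score": p.score, "algorithm": p.algorithm}
            for p in pairs
        ],
        columns=["pen_id", "cow_a", "cow_b", "score", "algorithm"],
    )
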