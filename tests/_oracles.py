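"""Independent brute-force oracles used by unit and acceptance tests.

Deliberately naive (nested loops, exhaustive enumeration) and independent of
the package's vectorised implementations.
"""

from collections import defaultdict
from itertools import combinations


def oracle_lag(cow_seq, base=2.0, max_lag=4, event_weights=None):
    """Direct enumeration of the lag-sequence score for one pen."""
    scores = defaultdict(float)
    for i, c in enumerate(cow_seq):
        w_i = 1.0 if event_weights is None else event_weights[i]
        for k in range(1, max_lag + 1):
            j = i - k
            if j < 0:
                break
            c2 = cow_seq[j]
            if c2 != c:
                scores[frozenset((c, c2))] += base ** -(k - 1) * w_i
    return dict(scores)


def oracle_window(times_s, cow_seq, window_minutes=15.0, event_weights=None):
    """Presence-per-fixed-bin enumeration (bins aligned to the epoch/midnight)."""
    bin_s = window_minutes * 60.0
    bins = defaultdict(set)
    bin_w = {}
    for i, (t, c) in enumerate(zip(times_s, cow_seq)):
        b = int(t // bin_s)
        bins[b].add(c)
        if event_weights is not None:
            bin_w[b] = event_weights[i]
    scores = defaultdict(float)
    for b, present in bins.items():
        w = 1.0 if event_weights is None else bin_w[b]
        for a, c in combinations(sorted(present), 2):
            scores[frozenset((a, c))] += w
    return dict(scores)


def oracle_inverse(times_s, cow_seq, window_minutes=15.0, epsilon_seconds=1.0, event_weights=None):
    """O(n^2) pair enumeration of the inverse-interval score."""
    horizon = window_minutes * 60.0
    scores = defaultdict(float)
    n = len(times_s)
    for i in range(n):
        for j in range(i):
            dt = times_s[i] - times_s[j]
            if dt > horizon or cow_seq[i] == cow_seq[j]:
                continue
            w = 1.0 if event_weights is None else event_weights[i]
            scores[frozenset((cow_seq[i], cow_seq[j]))] += w / max(dt, epsilon_seconds)
    return dict(scores)


def network_to_pair_scores(net):
    """Nonzero upper-triangle scores of an AffinityNetwork as a dict."""
    out = {}
    for i, a in enumerate(net.cows):
        for j in range(i + 1, net.n_cows):
            if net.weights[i, j] != 0:
                out[frozenset((a, net.cows[j]))] = net.weights[i, j]
    return out


def all_matchings(nodes, edges):
    """Yield every matching (as a frozenset of sorted-tuple edges)."""
    nodes = sorted(nodes)
    edge_set = {tuple(sorted(e)) for e in edges}

    def rec(remaining, acc):
        yield frozenset(acc)
        for e in sorted(edge_set):
            if e[0] in remaining and e[1] in remaining and (not acc or e > max(acc)):
                yield from rec(remaining - set(e), acc | {e})

    yield from rec(set(nodes), frozenset())


def brute_max_weight(nodes, weighted_edges):
    """Exhaustive maximum-weight matching: (best_weight, best_matchings)."""
    w = {tuple(sorted(e)): s for e, s in weighted_edges.items()}
    best, arg = 0.0, [frozenset()]
    for m in set(all_matchings(nodes, w)):
        total = sum(w[e] for e in m)
        if total > best + 1e-12:
            best, arg = total, [m]
        elif abs(total - best) <= 1e-12:
            arg.append(m)
    return best, arg


def brute_stable_exists(prefs):
    """Exhaustively decide whether any matching has no blocking pair."""
    people = sorted(prefs)
    rank = {p: {q: i for i, q in enumerate(lst)} for p, lst in prefs.items()}
    edges = {
        tuple(sorted((p, q)))
        for p, lst in prefs.items()
        for q in lst
        if p in prefs.get(q, [])
    }

    def blocked(matching):
        mate = {}
        for a, b in matching:
            mate[a], mate[b] = b, a
        for p in people:
            for q in prefs[p]:
                if mate.get(p) == q or p not in prefs.get(q, []):
                    continue
                p_pref = mate.get(p) is None or rank[p][q] < rank[p][mate[p]]
                q_pref = mate.get(q) is None or rank[q][p] < rank[q][mate[q]]
                if p_pref and q_pref:
                    return True
        return False

    return any(not blocked(m) for m in set(all_matchings(people, edges)))
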