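"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (enumeration, O(n^3) DP, per-position
scans) and shares no code with the package internals it checks.
"""

from __future__ import annotations

from functools import lru_cache

CAN_PAIR = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def nussinov_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum number of nested canonical pairs (Nussinov DP)."""
    n = len(seq)

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        b = best(i, j - 1)
        for k in range(i, j - min_loop):
            if (seq[k], seq[j]) in CAN_PAIR:
                left = best(i, k - 1) if k > i else 0
                b = max(b, left + 1 + best(k + 1, j - 1))
        return b

    return best(0, n - 1)


def valid_nested_pairing(seq: str, table, min_loop: int = 3) -> bool:
    """Involution, canonical pairs, no pseudoknots, minimum loop size."""
    n = len(seq)
    open_stack = []
    for i, j in enumerate(table):
        if j is None:
            continue
        if table[j] != i or j == i:
            return False
        if (seq[i], seq[j]) not in CAN_PAIR:
            return False
        if j > i and j - i <= min_loop:
            return False
    # pseudoknot check by crossing-pair enumeration
    pairs = [(i, j) for i, j in enumerate(table) if j is not None and j > i]
    for a, (i, j) in enumerate(pairs):
        for k, l in pairs[a + 1 :]:
            if i < k < j < l:
                return False
    return True


def decompose_loops(table):
    """Brute-force loop decomposition of a pair table.

    Returns a list of (closing_pair_or_None, branches) where branches are the
    pairs directly inside that loop.  Hairpin loops have zero branches.
    """
    pairs = sorted((i, j) for i, j in enumerate(table) if j is not None and j > i)

    def directly_inside(outer):
        lo, hi = (-1, len(table)) if outer is None else outer
        inner = [p for p in pairs if lo < p[0] and p[1] < hi and p != outer]
        # keep only pairs not nested in another candidate
        return [p for p in inner if not any(q[0] < p[0] and p[1] < q[1] for q in inner)]

    loops = [(None, directly_inside(None))]
    for p in pairs:
        loops.append((p, directly_inside(p)))
    return loops


def brute_stem_chains(table):
    """Every maximal single stem-loop as a list of pairs outermost-first."""
    loops = dict((p, br) for p, br in decompose_loops(table))
    parent = {}
    for p, branches in loops.items():
        for b in branches:
            parent[b] = p
    chains = []
    for p, branches in loops.items():
        if p is None or branches:
            continue  # not a hairpin-closing pair
        chain = [p]
        par = parent.get(p)
        while par is not None and len(loops[par]) == 1:
            chain.append(par)
            par = parent.get(par)
        chains.append(list(reversed(chain)))
    return chains


# --- feature oracles -------------------------------------------------------

def count_base(seq: str, base: str) -> int:
    return sum(1 for c in seq if c == base)


def scan_unpaired(intervals, table) -> int:
    n = 0
    for lo, hi in intervals:
        for i in range(lo, hi):
            if table[i] is None:
                n += 1
    return n


def scan_runs(intervals, table):
    """(largest, count) of unpaired runs, run-length scan per interval."""
    largest = count = 0
    for lo, hi in intervals:
        runs = []
        cur = 0
        for i in range(lo, hi):
            if table[i] is None:
                cur += 1
            else:
                if cur:
                    runs.append(cur)
                cur = 0
        if cur:
            runs.append(cur)
        count += len(runs)
        if runs:
            largest = max(largest, max(runs))
    return largest, count


def scan_gu_pairs(intervals, table, seq) -> int:
    seen = set()
    n = 0
    for lo, hi in intervals:
        for i in range(lo, hi):
            j = table[i]
            if j is None:
                continue
            key = frozenset((i, j))
            if key in seen:
                continue
            seen.add(key)
            if {seq[i], seq[j]} == {"G", "U"}:
                n += 1
    return n


def linear_percentile(sorted_vals, q: float) -> float:
    """Closed-form linear-interpolation percentile on sorted data."""
    n = len(sorted_vals)
    pos = (n - 1) * q / 100.0
    lo = int(pos)
    frac = pos - lo
    if lo + 1 >= n:
        return float(sorted_vals[-1])
    return sorted_vals[lo] + frac * (sorted_vals[lo + 1] - sorted_vals[lo])
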