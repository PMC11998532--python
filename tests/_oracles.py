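"""Independent oracles used by the test suite.

These deliberately take different routes than the library code they check:
the hairpin-mining oracle works on an explicit nesting forest instead of the
library's outward scan, and the structure enumerator generates every
balanced dot-bracket string of a given length by recursion.
"""

from __future__ import annotations

from functools import lru_cache


@lru_cache(maxsize=None)
def enumerate_structures(n: int) -> tuple[str, ...]:
    """All balanced dot-bracket strings of length n (including empty loops)."""
    if n == 0:
        return ("",)
    out = []
    # first char '.' or start of a pair enclosing an inner structure
    for rest in enumerate_structures(n - 1):
        out.append("." + rest)
    for inner_len in range(0, n - 1):
        for inner in enumerate_structures(inner_len):
            for rest in enumerate_structures(n - 2 - inner_len):
                out.append("(" + inner + ")" + rest)
    return tuple(out)


def pair_forest(pair_table) -> tuple[dict, list]:
    """Nesting forest of pairs: children[(i,j)] = pairs directly inside.

    Returns (children, roots).  Built with an explicit stack, independent of
    the library's hairpin-loop scan.
    """
    n = len(pair_table) - 1
    children: dict = {}
    roots: list = []
    stack: list = []
    for i in range(1, n + 1):
        j = pair_table[i]
        if j > i:
            node = (i, j)
            children[node] = []
            if stack:
                children[stack[-1]].append(node)
            else:
                roots.append(node)
            stack.append(node)
        elif 0 < j < i:
            stack.pop()
    return children, roots


def mine_simple_hairpins_oracle(pair_table, min_stem_pairs: int = 3,
                                max_loop_size: int | None = None):
    """Brute-force loop-decomposition miner.

    For every hairpin loop (leaf of the nesting forest), climb toward the
    root while the parent has exactly one child (no multiloop) and, when a
    loop-size limit applies, the unpaired gaps stay within it.  Returns
    sorted (start, end, n_pairs, n_internal, n_bulges, apical_len) tuples.
    """
    children, roots = pair_forest(pair_table)
    parent = {}
    for node, kids in children.items():
        for k in kids:
            parent[k] = node
    results = []
    for leaf in [n for n, kids in children.items() if not kids]:
        chain = [leaf]
        node = leaf
        while node in parent and len(children[parent[node]]) == 1:
            p = parent[node]
            if max_loop_size is not None:
                left_gap = node[0] - p[0] - 1
                right_gap = p[1] - node[1] - 1
                if max(left_gap, right_gap) > max_loop_size:
                    break
            chain.append(p)
            node = p
        n_internal = n_bulges = 0
        for (i, j), (a, b) in zip(chain, chain[1:]):
            lg, rg = i - a - 1, b - j - 1
            if lg > 0 and rg > 0:
                n_internal += 1
            elif lg > 0 or rg > 0:
                n_bulges += 1
        top = chain[-1]
        if len(chain) >= min_stem_pairs:
            results.append(
                (top[0], top[1], len(chain), n_internal, n_bulges,
                 leaf[1] - leaf[0] - 1)
            )
    return sorted(results)
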