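"""Pedigree kinship and inbreeding coefficients.

Wright's inbreeding coefficient of an individual equals the kinship
(coancestry) coefficient of its parents; kinship is computed by the
standard recursive tabular rule. Pedigrees are mappings
``id -> (sire, dam)`` with ``None`` for founder parents.
"""

from __future__ import annotations

from functools import lru_cache

Pedigree = dict[object, tuple[object | None, object | None]]


def _check_acyclic(pedigree: Pedigree) -> None:
    state: dict[object, int] = {}

    def visit(node: object) -> None:
        if node is None or node not in pedigree:
            return
        mark = state.get(node, 0)
        if mark == 1:
            raise ValueError("pedigree contains a cycle")
        if mark == 2:
            return
        state[node] = 1
        for parent in pedigree[node]:
            visit(parent)
        state[node] = 2

    for node in pedigree:
        visit(node)


def kinship(pedigree: Pedigree, a: object, b: object) -> float:
    """Kinship (coancestry) coefficient between individuals a and b.

    f(x, x) = (1 + F_x) / 2; f(x, y) = (f(sire_x, y) + f(dam_x, y)) / 2
    with x the later-born of the pair (any topological order works for an
    acyclic pedigree). Founders are unrelated and non-inbred.
    """
    for ind in (a, b):
        if ind not in pedigree:
            raise KeyError(f"individual {ind!r} not in pedigree")
    _check_acyclic(pedigree)
    depth_memo: dict[object, int] = {}

    def depth(x: object) -> int:
        if x is None:
            return -1
        if x not in depth_memo:
            s, d = pedigree.get(x, (None, None))
            depth_memo[x] = 1 + max(depth(s), depth(d))
        return depth_memo[x]

    @lru_cache(maxsize=None)
    def f(x: object, y: object) -> float:
        if x is None or y is None:
            return 0.0
        if x == y:
            s, d = pedigree.get(x, (None, None))
            return 0.5 * (1.0 + f(s, d))
        # recurse on the individual further from the founders
        if depth(x) < depth(y):
            x, y = y, x
        s, d = pedigree.get(x, (None, None))
        return 0.5 * (f(s, y) + f(d, y))

    return f(a, b)


def inbreeding(pedigree: Pedigree, individual: object) -> float:
    """Wright's F: kinship of the individual's parents (0 for founders)."""
    if individual not in pedigree:
        raise KeyError(f"individual {individual!r} not in pedigree")
    sire, dam = pedigree[individual]
    if sire is None or dam is None:
        return 0.0
    return kinship(pedigree, sire, dam)
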