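"""Greedy decomposition of a base-pair set into pseudoknot-free layers.

Each layer is a maximum-cardinality subset of the remaining pairs that is
non-crossing and uses each sequence position at most once, found by a
Nussinov-style dynamic program (cubic time, quadratic space per pass).
Extracted layers are removed iteratively until no pairs remain.  The greedy
scheme does not guarantee the minimum possible number of layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .errors import ConsistencyError
from .pairio import BasePair, Residue

__all__ = [
    "IndexedPairSet",
    "LayerDecomposition",
    "crosses",
    "max_noncrossing_subset",
    "decompose",
    "pseudoknot_order",
    "MAX_LAYERS",
]

Pair = Tuple[int, int]

#: Safety cap on layer count; legitimate inputs never approach it.
MAX_LAYERS = 26


@dataclass
class IndexedPairSet:
    """Pairs mapped to 0-based sequential positions within one chain."""

    n: int
    pairs: Set[Pair]
    index_map: Dict[int, Residue] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pairs = {(int(i), int(j)) for (i, j) in self.pairs}
        for (i, j) in self.pairs:
            if not (0 <= i < j < self.n):
                raise ConsistencyError(
                    f"pair ({i}, {j}) out of range for n={self.n}")
        if self.index_map:
            missing = {k for p in self.pairs for k in p} - set(self.index_map)
            if missing:
                raise ConsistencyError(
                    f"index_map missing indices used by pairs: {sorted(missing)}")

    @classmethod
    def from_base_pairs(cls, pairs: Sequence[BasePair], n: int,
                        index_map: Optional[Dict[int, Residue]] = None,
                        ) -> "IndexedPairSet":
        """Build from BasePairs whose residues carry seq_index."""
        idx_pairs: Set[Pair] = set()
        imap: Dict[int, Residue] = dict(index_map or {})
        for p in pairs:
            i, j = p.res1.seq_index, p.res2.seq_index
            if i is None or j is None:
                raise ConsistencyError(
                    f"pair {p.res1.auth_token}-{p.res2.auth_token} lacks seq_index")
            if i > j:
                i, j = j, i
            idx_pairs.add((i, j))
            imap.setdefault(i, p.res1 if p.res1.seq_index == i else p.res2)
            imap.setdefault(j, p.res2 if p.res2.seq_index == j else p.res1)
        return cls(n=n, pairs=idx_pairs, index_map=imap)


@dataclass
class LayerDecomposition:
    """Ordered partition of a pair set into non-crossing layers.

    ``layers[0]`` is the core layer (the largest extracted subset); subsequent
    layers are the pseudoknot / non-nested layers in extraction order.
    """

    layers: List[FrozenSet[Pair]]
    n: int
    index_map: Dict[int, Residue] = field(default_factory=dict)
    residual: FrozenSet[Pair] = frozenset()
    mode: str = "canonical_only"

    @property
    def layer_sizes(self) -> List[int]:
        return [len(layer) for layer in self.layers]

    @property
    def all_pairs(self) -> Set[Pair]:
        out: Set[Pair] = set()
        for layer in self.layers:
            out |= layer
        return out

    def layer_of(self, pair: Pair) -> int:
        for k, layer in enumerate(self.layers):
            if pair in layer:
                return k
        raise KeyError(pair)


def crosses(p: Pair, q: Pair) -> bool:
    """True iff the pairs interleave (i<k<j<l or k<i<l<j).

    Sharing an endpoint is NOT crossing; endpoint conflicts are handled by the
    one-pair-per-index structure of the DP.
    """
    i, j = p
    k, l = q
    return (i < k < j < l) or (k < i < l < j)


def conflicts(p: Pair, q: Pair) -> bool:
    """True iff p and q cannot share a layer: they cross or share an index."""
    return crosses(p, q) or bool(set(p) & set(q))


def max_noncrossing_subset(ips: IndexedPairSet) -> Set[Pair]:
    """Maximum-cardinality non-crossing, one-pair-per-index subset of ips.pairs.

    Recurrence over intervals [i, j]::

        M[i][j] = max( M[i+1][j],
                       max over k with (i, k) in E, i < k <= j of
                           M[i+1][k-1] + M[k+1][j] + 1 )

    Traceback is deterministic: pairing position ``i`` is preferred over
    leaving it unpaired on score ties, and the smallest tied partner ``k``
    wins.
    """
    n = ips.n
    if not ips.pairs:
        return set()
    partners: Dict[int, List[int]] = {}
    for (i, j) in ips.pairs:
        partners.setdefault(i, []).append(j)
    for i in partners:
        partners[i].sort()

    # M[i][j] stored as list of rows; row i covers j in [i, n-1].
    M = [[0] * n for _ in range(n + 1)]

    def m(i: int, j: int) -> int:
        return M[i][j] if i <= j else 0

    for span in range(1, n):  # j - i
        for i in range(n - span - 1, -1, -1):
            j = i + span
            best = M[i + 1][j]
            for k in partners.get(i, ()):
                if k > j:
                    break
                cand = m(i + 1, k - 1) + m(k + 1, j) + 1
                if cand > best:
                    best = cand
            M[i][j] = best
    # ensure single-position rows exist (span 0 handled by init zeros)

    chosen: Set[Pair] = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or M[i][j] == 0:
            continue
        score = M[i][j]
        paired = False
        for k in partners.get(i, ()):
            if k > j:
                break
            if m(i + 1, k - 1) + m(k + 1, j) + 1 == score:
                chosen.add((i, k))
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return chosen


def decompose(ips: IndexedPairSet, mode: str = "canonical_only",
              max_layers: int = MAX_LAYERS) -> LayerDecomposition:
    """Iteratively extract maximum non-crossing subsets until no pairs remain.

    Raises :class:`ConsistencyError` if more than ``max_layers`` layers are
    produced (malformed-input guard; real chains stay far below the cap).
    """
    remaining = set(ips.pairs)
    layers: List[FrozenSet[Pair]] = []
    while remaining:
        if len(layers) >= max_layers:
            raise ConsistencyError(
                f"layer cap ({max_layers}) exceeded with {len(remaining)} pairs left; "
                "input is likely malformed")
        layer = max_noncrossing_subset(
            IndexedPairSet(n=ips.n, pairs=remaining, index_map=ips.index_map))
        if not layer:
            raise ConsistencyError("DP returned an empty layer on non-empty input")
        layers.append(frozenset(layer))
        remaining -= layer
    return LayerDecomposition(layers=layers, n=ips.n,
                              index_map=dict(ips.index_map), mode=mode)


def pseudoknot_order(d: LayerDecomposition) -> int:
    """Number of non-core layers; 0 means pseudoknot-free (or no pairs)."""
    return max(0, len(d.layers) - 1)
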