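"""Independent oracles and random-instance helpers for the test suite.

These deliberately avoid the package's DP code paths: the maximum
non-crossing subset is found by exhaustive subset enumeration, and layer
minimality by exhaustive bipartition search.
"""

from itertools import combinations

import numpy as np


def _crosses(p, q):
    i, j = p
    k, l = q
    return (i < k < j < l) or (k < i < l < j)


def _conflicts(p, q):
    return _crosses(p, q) or bool(set(p) & set(q))


def is_planar(pairs):
    """No crossing and no shared index within the set."""
    return all(not _conflicts(p, q) for p, q in combinations(sorted(pairs), 2))


def brute_force_max_noncrossing(pairs):
    """Largest non-crossing, one-pair-per-index subset by exhaustive search.

    Only feasible for <= ~14 pairs.
    """
    pairs = sorted(pairs)
    for size in range(len(pairs), 0, -1):
        for combo in combinations(pairs, size):
            if is_planar(combo):
                return set(combo)
    return set()


def two_layer_partition_exists(pairs):
    """True iff the pair set splits into two planar layers (exhaustive)."""
    pairs = sorted(pairs)
    m = len(pairs)
    for mask in range(2 ** m):
        a = [pairs[t] for t in range(m) if mask >> t & 1]
        b = [pairs[t] for t in range(m) if not mask >> t & 1]
        if is_planar(a) and is_planar(b):
            return True
    return False


def random_pair_set(rng, max_n=30, max_pairs=12):
    """A random partial matching: each index has at most one partner."""
    n = int(rng.integers(4, max_n + 1))
    n_pairs = int(rng.integers(0, min(max_pairs, n // 2) + 1))
    positions = rng.permutation(n)[: 2 * n_pairs]
    pairs = set()
    for t in range(n_pairs):
        i, j = sorted((int(positions[2 * t]), int(positions[2 * t + 1])))
        pairs.add((i, j))
    return n, pairs


def random_pair_set_multiplets(rng, max_n=30, max_pairs=12):
    """A random pair set where indices may have several partners."""
    n = int(rng.integers(4, max_n + 1))
    n_pairs = int(rng.integers(0, min(max_pairs, n * (n - 1) // 2) + 1))
    pairs = set()
    attempts = 0
    while len(pairs) < n_pairs and attempts < 200:
        i, j = sorted(rng.choice(n, size=2, replace=False).tolist())
        pairs.add((int(i), int(j)))
        attempts += 1
    return n, pairs


def decomposition_invariants_ok(d, input_pairs):
    """Check the full layer-decomposition contract; returns (ok, message)."""
    union = set()
    for layer in d.layers:
        if union & layer:
            return False, "layers are not disjoint"
        union |= layer
    if union != set(input_pairs):
        return False, "union of layers != input pairs"
    for k, layer in enumerate(d.layers):
        if not is_planar(layer):
            return False, f"layer {k} is not planar"
        if k + 1 < len(d.layers) and len(layer) < len(d.layers[k + 1]):
            return False, f"layer sizes increase at {k}"
    for k in range(1, len(d.layers)):
        for p in d.layers[k]:
            for earlier in d.layers[:k]:
                if not any(_conflicts(p, q) for q in earlier):
                    return False, (f"pair {p} in layer {k} does not conflict "
                                   f"with some earlier layer")
    return True, ""


def make_rng(seed):
    return np.random.default_rng(seed)
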