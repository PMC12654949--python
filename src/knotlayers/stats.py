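"""Corpus-level summaries: layer-count distribution and per-layer canonical
fraction."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .errors import ConsistencyError, InputError, ModeError
from .layering import LayerDecomposition
from .pairio import BasePair

__all__ = [
    "ChainRecord",
    "summarize_chain",
    "layer_histogram",
    "canonical_fraction_by_layer",
]


@dataclass
class ChainRecord:
    """Per-chain decomposition summary used by the corpus statistics."""

    chain_label: str
    mode: str
    layer_sizes: List[int] = field(default_factory=list)
    per_layer_canonical: List[Tuple[int, int]] = field(default_factory=list)
    excluded: bool = False  # chains with zero pairs are excluded from analysis

    @property
    def layer_count(self) -> int:
        return len(self.layer_sizes)


def summarize_chain(d: LayerDecomposition, pairs: Sequence[BasePair],
                    chain_label: str = "") -> ChainRecord:
    """Count canonical / non-canonical pairs per layer.

    ``pairs`` must be the decomposition's input (carrying canonical flags);
    a mismatch between the two raises :class:`ConsistencyError`.  A chain with
    zero pairs yields an empty record flagged ``excluded``.
    """
    if not pairs and not d.layers:
        return ChainRecord(chain_label=chain_label, mode=d.mode, excluded=True)

    canon: Dict[Tuple[int, int], bool] = {}
    for p in pairs:
        i, j = p.res1.seq_index, p.res2.seq_index
        if i is None or j is None:
            raise ConsistencyError("pair without seq_index in summarize_chain")
        if i > j:
            i, j = j, i
        canon[(i, j)] = canon.get((i, j), False) or p.canonical
    if set(canon) != d.all_pairs:
        raise ConsistencyError(
            "pair list does not match decomposition "
            f"({len(canon)} pairs vs {len(d.all_pairs)} decomposed)")

    per_layer = []
    for layer in d.layers:
        c = sum(1 for p in layer if canon[p])
        per_layer.append((c, len(layer) - c))
    return ChainRecord(chain_label=chain_label, mode=d.mode,
                       layer_sizes=d.layer_sizes,
                       per_layer_canonical=per_layer)


def layer_histogram(records: Sequence[ChainRecord]
                    ) -> Tuple[Dict[int, int], Dict[int, float]]:
    """Histogram of layer counts over included chains, plus the cumulative
    fraction of chains with at most k layers for k = 1..max."""
    included = [r for r in records if not r.excluded]
    if not included:
        raise InputError("no chains left after excluding zero-pair entries")
    hist = Counter(r.layer_count for r in included)
    total = len(included)
    cum: Dict[int, float] = {}
    running = 0
    for k in range(1, max(hist) + 1):
        running += hist.get(k, 0)
        cum[k] = running / total
    return dict(sorted(hist.items())), cum


def canonical_fraction_by_layer(records: Sequence[ChainRecord]) -> pd.DataFrame:
    """Per-layer non-canonical fraction over chains that have that layer.

    Requires records produced in ``include_all`` mode (canonical-only records
    have no non-canonical pairs by construction and would bias the table).
    Returns a DataFrame with both the mean of per-chain fractions (default
    aggregate) and the pooled-count fraction.
    """
    included = [r for r in records if not r.excluded]
    if not included:
        raise InputError("no chains left after excluding zero-pair entries")
    bad = [r for r in included if r.mode != "include_all"]
    if bad:
        raise ModeError(
            f"canonical_fraction_by_layer needs include_all records; got "
            f"{bad[0].mode!r} for chain {bad[0].chain_label!r}")

    max_layers = max(r.layer_count for r in included)
    rows = []
    for k in range(max_layers):
        fractions: List[float] = []
        pooled_c = pooled_nc = 0
        for r in included:
            if k >= r.layer_count:
                continue
            c, nc = r.per_layer_canonical[k]
            fractions.append(nc / (c + nc))
            pooled_c += c
            pooled_nc += nc
        rows.append({
            "layer": k,
            "mean_noncanonical_fraction": sum(fractions) / len(fractions),
            "pooled_noncanonical_fraction": pooled_nc / (pooled_c + pooled_nc),
            "chain_count": len(fractions),
        })
    return pd.DataFrame(rows)
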