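"""Ground-truthed synthetic fixtures.

Planted instances are built from mutually interleaved helical stems: all open
blocks precede all close blocks, and blocks appear in the same stem order on
both sides, so every pair of one stem crosses every pair of every other stem.
A maximum non-crossing subset is then exactly the largest stem, which makes
the greedy layering of a strictly-decreasing size profile provable by
construction (and checked against a brute-force oracle in the tests).

The module also writes schematic mmCIF/PDB coordinate files whose paired
residues satisfy the built-in detector's geometry envelope, plus RNAView-style
and DSSR-JSON-style annotation text for parser tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .errors import InputError
from .layering import IndexedPairSet, Pair
from .pairio import BasePair, Residue

__all__ = [
    "PlantedInstance",
    "gen_planted_pairs",
    "gen_helix_mmcif",
    "gen_helix_pdb",
    "gen_corpus",
    "gen_rnaview_text",
    "gen_dssr_json",
    "instance_pairs",
    "instance_to_ips",
    "instance_base_pairs",
]

# geometry constants used when writing coordinate fixtures (Å)
_NN_DIST = 2.9       # inside the detector's N···N <= 3.2 window
_C1_DIST = 10.4      # inside [9.8, 11.0]
_PAIR_SPACING = 30.0  # separation between placed pairs / unpaired residues

# identity given to pairs labelled non-canonical (A·G is never canonical)
_NONCANON_IDENTITY = ("A", "G")


@dataclass
class PlantedInstance:
    """A pair set with known ground-truth layering."""

    n: int
    planted_layers: List[Set[Pair]]
    pair_annotations: Dict[Pair, bool]  # pair -> canonical flag
    seed: int
    tie_broken: bool = False  # equal planted sizes: only size multiset is guaranteed

    @property
    def layer_sizes(self) -> List[int]:
        return [len(l) for l in self.planted_layers]


def gen_planted_pairs(layer_sizes: Sequence[int], seed: int = 0,
                      noncanonical_fraction: float = 0.0) -> PlantedInstance:
    """Construct mutually interleaved stems with the given sizes.

    ``layer_sizes`` must be non-increasing, each >= 1, at most 6 stems.  The
    seed controls gap widths between stem blocks and trailing padding.  With
    ``noncanonical_fraction`` > 0, that fraction of pairs is labelled
    non-canonical, drawn preferentially from the non-core stems.
    """
    sizes = list(layer_sizes)
    if not sizes or len(sizes) > 6:
        raise InputError("layer_sizes must contain 1..6 entries")
    if any(s < 1 for s in sizes):
        raise InputError("layer sizes must be >= 1")
    if any(sizes[k] < sizes[k + 1] for k in range(len(sizes) - 1)):
        raise InputError("layer_sizes must be non-increasing")

    rng = np.random.default_rng(seed)
    k = len(sizes)
    open_gaps = rng.integers(1, 3, size=k).tolist()
    close_gaps = rng.integers(1, 3, size=k).tolist()
    middle_gap = int(rng.integers(3, 6))  # >= 3 keeps a real hairpin loop
    trailing = int(rng.integers(4, 8))

    # open blocks in stem order, then close blocks in the same stem order:
    # every pair of stem m then crosses every pair of stem m' != m.
    pos = 0
    open_start: List[int] = []
    for m in range(k):
        open_start.append(pos)
        pos += sizes[m]
        if m < k - 1:
            pos += open_gaps[m]
    pos += middle_gap
    close_start: List[int] = []
    for m in range(k):
        close_start.append(pos)
        pos += sizes[m]
        if m < k - 1:
            pos += close_gaps[m]
    n = pos + trailing

    layers: List[Set[Pair]] = []
    for m in range(k):
        a = open_start[m]
        b_end = close_start[m] + sizes[m] - 1
        stem = {(a + t, b_end - t) for t in range(sizes[m])}
        layers.append(stem)

    all_pairs = sorted(p for stem in layers for p in stem)
    annotations = {p: True for p in all_pairs}
    n_noncanon = int(round(noncanonical_fraction * len(all_pairs)))
    if n_noncanon:
        # prefer non-core pairs when relabelling
        noncore = sorted(p for stem in layers[1:] for p in stem)
        core = sorted(layers[0])
        chosen_idx = rng.permutation(len(noncore)).tolist()
        picks = [noncore[i] for i in chosen_idx[:n_noncanon]]
        if len(picks) < n_noncanon:
            extra = rng.permutation(len(core)).tolist()
            picks += [core[i] for i in extra[: n_noncanon - len(picks)]]
        for p in picks:
            annotations[p] = False

    tie = any(sizes[i] == sizes[i + 1] for i in range(k - 1))
    return PlantedInstance(n=n, planted_layers=layers,
                           pair_annotations=annotations, seed=seed,
                           tie_broken=tie)


def instance_pairs(inst: PlantedInstance) -> Set[Pair]:
    return {p for stem in inst.planted_layers for p in stem}


def _instance_residues(inst: PlantedInstance) -> List[str]:
    """Residue identities: G-C for canonical pairs, A-G for non-canonical,
    U for unpaired positions."""
    names = ["U"] * inst.n
    for p in sorted(instance_pairs(inst)):
        i, j = p
        if inst.pair_annotations.get(p, True):
            names[i], names[j] = "G", "C"
        else:
            names[i], names[j] = _NONCANON_IDENTITY
    return names


def instance_to_ips(inst: PlantedInstance, chain_id: str = "A") -> IndexedPairSet:
    """IndexedPairSet over the instance with stub residues (author number =
    seq_index + 1)."""
    names = _instance_residues(inst)
    index_map = {
        i: Residue(chain_id=chain_id, seq_num=i + 1, res_name=names[i], seq_index=i)
        for i in range(inst.n)
    }
    return IndexedPairSet(n=inst.n, pairs=instance_pairs(inst), index_map=index_map)


def instance_base_pairs(inst: PlantedInstance, chain_id: str = "A",
                        source: str = "builtin") -> List[BasePair]:
    """The instance's pairs as BasePair objects carrying the planted canonical
    flags."""
    ips = instance_to_ips(inst, chain_id)
    out = []
    for (i, j) in sorted(ips.pairs):
        canonical = inst.pair_annotations.get((i, j), True)
        geometry = "builtin" if canonical else "Hoogsteen"
        out.append(BasePair.make(ips.index_map[i], ips.index_map[j],
                                 geometry, canonical, source))
    return out


# ---------------------------------------------------------------------------
# Coordinate fixtures
# ---------------------------------------------------------------------------

def _build_atom_array(inst: PlantedInstance, chain_id: str):
    import biotite.structure as struc

    names = _instance_residues(inst)
    partner: Dict[int, Tuple[int, int]] = {}
    for t, p in enumerate(sorted(instance_pairs(inst))):
        i, j = p
        partner[i] = (t, 0)
        partner[j] = (t, 1)

    wc_atom = {"A": "N1", "G": "N1", "C": "N3", "U": "N3"}
    coords: List[np.ndarray] = []
    atom_names: List[str] = []
    res_ids: List[int] = []
    res_names: List[str] = []
    n_unpaired_seen = 0
    for idx in range(inst.n):
        if idx in partner:
            t, side = partner[idx]
            x = t * _PAIR_SPACING
            sign = -1.0 if side == 0 else 1.0
            c1 = np.array([x, sign * _C1_DIST / 2.0, 0.0])
            nn = np.array([x, sign * _NN_DIST / 2.0, 0.0])
        else:
            x = n_unpaired_seen * _PAIR_SPACING
            n_unpaired_seen += 1
            c1 = np.array([x, 0.0, 1000.0])
            nn = np.array([x, 1.5, 1000.0])
        for name, xyz in (("C1'", c1), (wc_atom[names[idx]], nn)):
            coords.append(xyz)
            atom_names.append(name)
            res_ids.append(idx + 1)
            res_names.append(names[idx])

    arr = struc.AtomArray(len(coords))
    arr.coord = np.array(coords, dtype=float)
    arr.chain_id = np.full(len(coords), chain_id, dtype="U4")
    arr.res_id = np.array(res_ids)
    arr.res_name = np.array(res_names, dtype="U5")
    arr.atom_name = np.array(atom_names, dtype="U6")
    arr.ins_code = np.full(len(coords), "", dtype="U1")
    arr.hetero = np.zeros(len(coords), dtype=bool)
    arr.element = np.array(["C" if a == "C1'" else "N" for a in atom_names], dtype="U2")
    return arr


def gen_helix_mmcif(inst: PlantedInstance, path, chain_id: str = "A") -> Path:
    """Write the instance as a single-chain schematic mmCIF file.

    Paired residues are placed so the built-in detector accepts exactly the
    planted canonical pairs; unpaired residues sit far from everything else.
    """
    import biotite.structure.io.pdbx as pdbx

    path = Path(path)
    cif = pdbx.CIFFile()
    pdbx.set_structure(cif, _build_atom_array(inst, chain_id))
    cif.write(str(path))
    return path


def gen_helix_pdb(inst: PlantedInstance, path, chain_id: str = "A") -> Path:
    """Write the same schematic coordinates in PDB format."""
    import biotite.structure.io.pdb as pdbio

    path = Path(path)
    pdbf = pdbio.PDBFile()
    pdbio.set_structure(pdbf, _build_atom_array(inst, chain_id))
    pdbf.write(str(path))
    return path


# ---------------------------------------------------------------------------
# Annotation fixtures
# ---------------------------------------------------------------------------

def gen_rnaview_text(inst: PlantedInstance, chain_id: str = "A") -> str:
    """RNAView-style base-pair output for the instance (canonical pairs as
    ``+/+ cis`` / ``W/W cis``, non-canonical as ``H/W tran``)."""
    names = _instance_residues(inst)
    lines = ["BEGIN_base-pair"]
    for (i, j) in sorted(instance_pairs(inst)):
        canonical = inst.pair_annotations.get((i, j), True)
        b1, b2 = names[i], names[j]
        if canonical:
            ident = frozenset({b1, b2})
            annot = "W/W cis" if ident == frozenset({"G", "U"}) else "+/+ cis"
            saenger = "XXVIII" if ident == frozenset({"G", "U"}) else "XIX"
        else:
            annot, saenger = "H/W tran", "n/a"
        lines.append(
            f"{i + 1:6d}_{j + 1}, {chain_id}: {i + 1:5d} {b1}-{b2} "
            f"{j + 1:5d} {chain_id}: {annot}         {saenger}"
        )
    lines.append("END_base-pair")
    return "\n".join(lines) + "\n"


def gen_dssr_json(inst: PlantedInstance, chain_id: str = "A") -> str:
    """DSSR-JSON-style output for the instance."""
    names = _instance_residues(inst)
    entries = []
    for (i, j) in sorted(instance_pairs(inst)):
        canonical = inst.pair_annotations.get((i, j), True)
        b1, b2 = names[i], names[j]
        if canonical:
            name = "Wobble" if frozenset({b1, b2}) == frozenset({"G", "U"}) else "WC"
            lw = "cWW"
        else:
            name, lw = "Hoogsteen", "tHW"
        entries.append({
            "nt1": f"{chain_id}.{b1}{i + 1}",
            "nt2": f"{chain_id}.{b2}{j + 1}",
            "name": name,
            "LW": lw,
        })
    return json.dumps({"pairs": entries}, indent=1)


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

#: Layer-count sampling weights for the synthetic corpus: most chains have few
#: layers, echoing observed corpora.
_CORPUS_LAYER_WEIGHTS = {1: 0.50, 2: 0.30, 3: 0.15, 4: 0.05}

#: Probability that a non-core pair is labelled non-canonical, vs core.
_NONCANON_P_NONCORE = 0.55
_NONCANON_P_CORE = 0.08


def gen_corpus(num_chains: int, seed: int = 0) -> List[PlantedInstance]:
    """Generate ``num_chains`` planted instances with strictly decreasing
    layer sizes and non-canonical labels placed preferentially outside the
    core layer.  Deterministic per seed."""
    if num_chains < 1:
        raise InputError("num_chains must be >= 1")
    rng = np.random.default_rng(seed)
    counts = list(_CORPUS_LAYER_WEIGHTS)
    weights = np.array([_CORPUS_LAYER_WEIGHTS[c] for c in counts])
    weights = weights / weights.sum()
    instances: List[PlantedInstance] = []
    for c in range(num_chains):
        n_layers = int(rng.choice(counts, p=weights))
        # strictly decreasing sizes so the planted layering is the unique greedy one
        top = int(rng.integers(n_layers + 1, n_layers + 5))
        sizes = [top - m for m in range(n_layers)]
        inst_seed = int(rng.integers(0, 2**31 - 1))
        inst = gen_planted_pairs(sizes, seed=inst_seed)
        _relabel_noncanonical(inst, rng)
        instances.append(inst)
    return instances


def _relabel_noncanonical(inst: PlantedInstance, rng: np.random.Generator) -> None:
    for k, stem in enumerate(inst.planted_layers):
        p_nc = _NONCANON_P_CORE if k == 0 else _NONCANON_P_NONCORE
        for pair in sorted(stem):
            if rng.random() < p_nc:
                inst.pair_annotations[pair] = False
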