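"""Render layer decompositions as viewer coloring scripts and dot-bracket text.

PyMOL scripts use ``color <color>, <object> and chain <c> and resi <tokens>``
plus per-pseudoknot-layer ``select`` commands; Chimera scripts use the classic
Chimera 1.x atom-spec syntax ``color <color> #<model>:<tokens>.<chain>`` (no
selections).  Extended dot-bracket output assigns ``()``, ``[]``, ``{}``,
``<>`` to layers 0-3 and letter families ``Aa``, ``Bb``, ... beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

from .errors import ConsistencyError, InputError
from .layering import LayerDecomposition, Pair
from .pairio import Residue

__all__ = [
    "Palette",
    "ColorScript",
    "residues_by_layer",
    "emit_pymol",
    "emit_chimera",
    "to_dotbracket",
    "parse_dotbracket",
    "BRACKET_FAMILIES",
    "UNPAIRED",
]

#: Key used for residues participating in no pair.
UNPAIRED = "unpaired"

# layer0 -> "()", layer1 -> "[]", ... then Aa..Zz: 30 families total.
BRACKET_FAMILIES: List[Tuple[str, str]] = (
    [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]
    + [(chr(65 + i), chr(97 + i)) for i in range(26)]
)


@dataclass
class Palette:
    """Color assignment: unpaired, core layer, then one color per extra layer
    (cycled when exhausted)."""

    unpaired_color: str = "white"
    core_color: str = "gray"
    layer_colors: List[str] = field(
        default_factory=lambda: ["red", "blue", "green", "orange", "purple", "cyan"])

    def color_for_layer(self, k: int) -> str:
        if k == 0:
            return self.core_color
        return self.layer_colors[(k - 1) % len(self.layer_colors)]


@dataclass
class ColorScript:
    dialect: str
    lines: List[str]
    target_object: str
    chain_id: str

    @property
    def text(self) -> str:
        return "\n".join(self.lines) + "\n"


LayerKey = Union[int, str]


def residues_by_layer(d: LayerDecomposition,
                      index_map: Optional[Dict[int, Residue]] = None,
                      ) -> Dict[LayerKey, List[Residue]]:
    """Map each layer index to the sorted residues participating in its pairs.

    A residue appearing in several layers is assigned to its lowest-numbered
    layer.  Residues of the chain in no pair are listed under ``"unpaired"``.
    """
    imap = d.index_map if index_map is None else index_map
    assigned: Dict[int, int] = {}  # seq_index -> layer
    for k, layer in enumerate(d.layers):
        for (i, j) in layer:
            for idx in (i, j):
                if idx not in imap:
                    raise ConsistencyError(f"index {idx} missing from index map")
                assigned.setdefault(idx, k)
    out: Dict[LayerKey, List[Residue]] = {}
    for k in range(len(d.layers)):
        idxs = sorted(idx for idx, lk in assigned.items() if lk == k)
        out[k] = [imap[i] for i in idxs]
    out[UNPAIRED] = [imap[i] for i in sorted(set(imap) - set(assigned))]
    return out


def _nonempty_layers(by_layer: Dict[LayerKey, List[Residue]]) -> List[int]:
    return [k for k in sorted(k for k in by_layer if isinstance(k, int))
            if by_layer[k]]


def emit_pymol(d: LayerDecomposition, object_name: str, chain_id: str,
               palette: Optional[Palette] = None, precolor: bool = True,
               ) -> ColorScript:
    """Emit a PyMOL coloring script for one decomposed chain.

    Lines, in order: an optional whole-object precolor in the unpaired color;
    one ``color`` line per non-empty layer; one ``select`` line per non-empty
    pseudoknot layer named ``<object>_PK_layer<k>``.
    """
    palette = palette or Palette()
    if not d.index_map:
        raise InputError("cannot emit script for an empty chain")
    by_layer = residues_by_layer(d)
    lines: List[str] = []
    if precolor:
        lines.append(f"color {palette.unpaired_color}, {object_name}")
    sel = f"{object_name} and chain {chain_id}"
    for k in _nonempty_layers(by_layer):
        tokens = "+".join(r.auth_token for r in by_layer[k])
        lines.append(f"color {palette.color_for_layer(k)}, {sel} and resi {tokens}")
    for k in _nonempty_layers(by_layer):
        if k == 0:
            continue
        tokens = "+".join(r.auth_token for r in by_layer[k])
        lines.append(
            f"select {object_name}_PK_layer{k}, {sel} and resi {tokens}")
    return ColorScript("pymol", lines, object_name, chain_id)


def emit_chimera(d: LayerDecomposition, model_id: Union[int, str], chain_id: str,
                 palette: Optional[Palette] = None, precolor: bool = True,
                 ) -> ColorScript:
    """Emit a classic Chimera 1.x coloring script (no selection commands)."""
    palette = palette or Palette()
    if not d.index_map:
        raise InputError("cannot emit script for an empty chain")
    by_layer = residues_by_layer(d)
    lines: List[str] = []
    if precolor:
        lines.append(f"color {palette.unpaired_color} #{model_id}")
    for k in _nonempty_layers(by_layer):
        tokens = ",".join(r.auth_token for r in by_layer[k])
        lines.append(
            f"color {palette.color_for_layer(k)} #{model_id}:{tokens}.{chain_id}")
    return ColorScript("chimera", lines, str(model_id), chain_id)


def to_dotbracket(d: LayerDecomposition, n: Optional[int] = None) -> str:
    """Extended dot-bracket string of length ``n`` (default: the chain length)."""
    n = d.n if n is None else n
    if len(d.layers) > len(BRACKET_FAMILIES):
        raise InputError(
            f"{len(d.layers)} layers exceed the {len(BRACKET_FAMILIES)} "
            "supported bracket families")
    chars = ["."] * n
    for k, layer in enumerate(d.layers):
        op, cl = BRACKET_FAMILIES[k]
        for (i, j) in layer:
            if j >= n:
                raise InputError(f"pair index {j} out of range for n={n}")
            for idx, ch in ((i, op), (j, cl)):
                if chars[idx] != ".":
                    # a residue pairing in two layers (base multiplet) has no
                    # single-character encoding
                    raise InputError(
                        f"position {idx} participates in pairs of multiple "
                        "layers; dot-bracket cannot encode base multiplets")
                chars[idx] = ch
    return "".join(chars)


def parse_dotbracket(s: str) -> List[Set[Pair]]:
    """Recover the per-family pair sets from an extended dot-bracket string.

    Inverse of :func:`to_dotbracket` (test/round-trip utility).  Returns one
    pair set per bracket family actually used, in family order.
    """
    opens = {op: k for k, (op, _) in enumerate(BRACKET_FAMILIES)}
    closes = {cl: k for k, (_, cl) in enumerate(BRACKET_FAMILIES)}
    stacks: Dict[int, List[int]] = {}
    families: Dict[int, Set[Pair]] = {}
    for pos, ch in enumerate(s):
        if ch == ".":
            continue
        if ch in opens:
            stacks.setdefault(opens[ch], []).append(pos)
        elif ch in closes:
            k = closes[ch]
            if not stacks.get(k):
                raise ValueError(f"unbalanced {ch!r} at position {pos}")
            i = stacks[k].pop()
            families.setdefault(k, set()).add((i, pos))
        else:
            raise ValueError(f"unknown character {ch!r} at position {pos}")
    for k, st in stacks.items():
        if st:
            raise ValueError(f"unclosed bracket of family {k} at {st}")
    return [families[k] for k in sorted(families)]
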