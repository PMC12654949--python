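"""Structure reading, base-pair annotation parsing, and canonical classification.

Base pairs enter the pipeline from one of three sources:

* RNAView base-pair text output (``parse_rnaview``),
* DSSR JSON output (``parse_dssr``),
* a built-in geometric detector operating on coordinates (``detect_pairs_builtin``).

All three normalise their results into :class:`BasePair` lists; selection and
layer decomposition downstream are source-agnostic.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import EmptyResultError, FormatError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "Residue",
    "BasePair",
    "ChainStructure",
    "read_structure",
    "parse_rnaview",
    "parse_dssr",
    "detect_pairs_builtin",
    "classify_canonical",
    "select_pairs",
    "PARENT_MAP",
    "CANONICAL_IDENTITIES",
]

# Modified-nucleotide one-letter parent mapping.  Extensible by passing
# ``parent_map`` to classify_canonical; unknown residue names map to themselves.
PARENT_MAP: Dict[str, str] = {
    "A": "A", "ADE": "A", "DA": "A", "1MA": "A", "MA6": "A", "RIA": "A",
    "C": "C", "CYT": "C", "DC": "C", "5MC": "C", "OMC": "C", "4OC": "C",
    "G": "G", "GUA": "G", "DG": "G", "2MG": "G", "7MG": "G", "M2G": "G",
    "OMG": "G", "YG": "G", "1MG": "G",
    "U": "U", "URA": "U", "URI": "U", "DU": "U", "T": "U", "DT": "U",
    "PSU": "U", "5MU": "U", "4SU": "U", "H2U": "U", "OMU": "U", "UR3": "U",
}

#: Unordered residue-identity pairs allowed in a canonical base pair.
CANONICAL_IDENTITIES = {
    frozenset({"A", "U"}),
    frozenset({"G", "C"}),
    frozenset({"G", "U"}),
}

# WC-edge nitrogen per parent identity (purines: N1, pyrimidines: N3).
_WC_NITROGEN = {"A": "N1", "G": "N1", "C": "N3", "U": "N3"}

# Built-in detector geometry envelope (Å).
NN_DISTANCE_MAX = 3.2
C1_DISTANCE_MIN = 9.8
C1_DISTANCE_MAX = 11.0
MIN_SEQ_SEPARATION = 2  # require j > i + 2


@dataclass(frozen=True)
class Residue:
    """Author-numbered residue identity within a chain."""

    chain_id: str
    seq_num: int
    ins_code: str = ""
    res_name: str = ""
    seq_index: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.chain_id:
            raise ValueError("chain_id must be non-empty")

    @property
    def key(self) -> Tuple[str, int, str]:
        """Identity within one structure (seq_index and res_name excluded)."""
        return (self.chain_id, self.seq_num, self.ins_code)

    @property
    def auth_token(self) -> str:
        """Author number with insertion code appended, as used in viewer scripts."""
        return f"{self.seq_num}{self.ins_code}"


@dataclass(frozen=True)
class BasePair:
    """An annotated pairing between two residues.

    ``res1`` precedes ``res2`` in chain order (enforced at construction when
    both residues carry a ``seq_index`` on the same chain, otherwise by
    ``(chain_id, seq_num, ins_code)`` ordering).
    """

    res1: Residue
    res2: Residue
    geometry_class: str
    canonical: bool
    source: str

    def __post_init__(self) -> None:
        if self.res1.key == self.res2.key:
            raise ValueError(f"base pair with identical residues: {self.res1}")

    @staticmethod
    def make(res1: Residue, res2: Residue, geometry_class: str,
             canonical: bool, source: str) -> "BasePair":
        """Create a pair with residues normalised into chain order."""
        if _res_sort_key(res2) < _res_sort_key(res1):
            res1, res2 = res2, res1
        return BasePair(res1, res2, geometry_class, canonical, source)

    @property
    def key(self) -> Tuple[Tuple[str, int, str], Tuple[str, int, str]]:
        return (self.res1.key, self.res2.key)


def _res_sort_key(r: Residue):
    if r.seq_index is not None:
        return (r.chain_id, 0, r.seq_index, r.ins_code)
    return (r.chain_id, 1, r.seq_num, r.ins_code)


@dataclass
class ChainStructure:
    """One chain's nucleotide residues with the atom coordinates the built-in
    detector needs (C1' and the WC-edge nitrogen)."""

    chain_id: str
    residues: List[Residue] = field(default_factory=list)
    # aligned with residues: {atom_name: xyz} per residue
    atom_coords: List[Dict[str, np.ndarray]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def index_map(self) -> Dict[int, Residue]:
        return {r.seq_index: r for r in self.residues}


# ---------------------------------------------------------------------------
# Structure reading
# ---------------------------------------------------------------------------

def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    if suffix in {".pdb", ".ent"}:
        return "pdb"
    # content sniff: mmCIF files start with data_ blocks
    try:
        with open(path) as fh:
            for line in fh:
                s = line.strip()
                if not s:
                    continue
                return "mmcif" if s.startswith(("data_", "loop_", "#")) else "pdb"
    except OSError as exc:
        raise InputError(f"cannot read structure file: {path}") from exc
    raise FormatError(f"cannot detect format of empty file: {path}")


def read_structure(path, fmt: str = "auto") -> List[ChainStructure]:
    """Read a PDB or mmCIF file into per-chain nucleotide residue lists.

    Non-nucleotide chains are omitted; residue file order and author numbering
    are preserved; altloc duplicates collapse to the first-listed conformer.

    Raises
    ------
    InputError
        if the file does not exist or cannot be read.
    FormatError
        if the file cannot be parsed in the requested format.
    EmptyResultError
        if the file parses but contains no nucleotide chain.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio
    import biotite.structure.io.pdbx as pdbx

    path = Path(path)
    if not path.is_file():
        raise InputError(f"structure file not found: {path}")
    if fmt == "auto":
        fmt = _detect_format(path)
    if fmt not in {"pdb", "mmcif"}:
        raise InputError(f"unknown structure format {fmt!r} (use pdb/mmcif/auto)")

    try:
        if fmt == "mmcif":
            cif = pdbx.CIFFile.read(str(path))
            atoms = pdbx.get_structure(cif, model=1, altloc="first")
        else:
            pdbf = pdbio.PDBFile.read(str(path))
            atoms = pdbio.get_structure(pdbf, model=1, altloc="first")
    except InputError:
        raise
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"cannot parse {fmt} file {path}: {exc}") from exc

    if atoms.array_length() == 0:
        raise EmptyResultError(f"no atoms found in {path}")

    nuc_mask = struc.filter_nucleotides(atoms)

    chains: List[ChainStructure] = []
    for chain_id in _unique_in_order(atoms.chain_id):
        chain_atoms_idx = np.where(atoms.chain_id == chain_id)[0]
        chain = ChainStructure(chain_id=str(chain_id))
        seen: Dict[Tuple[int, str], int] = {}
        for ai in chain_atoms_idx:
            rkey = (int(atoms.res_id[ai]), str(atoms.ins_code[ai]))
            if rkey not in seen:
                # residue-level nucleotide test: recognised res_name or a ribose C1'
                res_idx_mask = (
                    (atoms.chain_id == chain_id)
                    & (atoms.res_id == atoms.res_id[ai])
                    & (atoms.ins_code == atoms.ins_code[ai])
                )
                res_atom_names = set(atoms.atom_name[res_idx_mask])
                is_nuc = bool(nuc_mask[res_idx_mask].any()) or "C1'" in res_atom_names
                if not is_nuc:
                    seen[rkey] = -1
                    continue
                seen[rkey] = len(chain.residues)
                chain.residues.append(
                    Residue(
                        chain_id=str(chain_id),
                        seq_num=rkey[0],
                        ins_code=rkey[1],
                        res_name=str(atoms.res_name[ai]),
                        seq_index=len(chain.residues),
                    )
                )
                chain.atom_coords.append({})
            ridx = seen[rkey]
            if ridx >= 0:
                name = str(atoms.atom_name[ai])
                chain.atom_coords[ridx].setdefault(name, np.asarray(atoms.coord[ai], dtype=float))
        if chain.residues:
            chains.append(chain)

    if not chains:
        raise EmptyResultError(f"no nucleotide chains in {path}")
    return chains


def _unique_in_order(values) -> List:
    seen = set()
    out = []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# Canonical classification
# ---------------------------------------------------------------------------

_warned_geometry_labels: set = set()

# RNAView labels whose edge notation denotes a cis Watson-Crick interaction.
_RNAVIEW_WC_PREFIXES = ("+/+", "-/-")


def classify_canonical(res_name1: str, res_name2: str, geometry_class: str,
                       source: str, *, require_geometry: bool = True,
                       parent_map: Optional[Dict[str, str]] = None) -> bool:
    """True iff the pair identity is A-U, G-C, or G-U (unordered, after mapping
    modified nucleotides to their parents) and the geometry label denotes a cis
    Watson-Crick-edge interaction in the source annotator's dialect.

    ``require_geometry=False`` classifies on identity alone.
    """
    mapping = PARENT_MAP if parent_map is None else {**PARENT_MAP, **parent_map}
    p1 = mapping.get(res_name1.upper(), res_name1.upper())
    p2 = mapping.get(res_name2.upper(), res_name2.upper())
    if frozenset({p1, p2}) not in CANONICAL_IDENTITIES:
        return False
    if not require_geometry:
        return True
    return _geometry_is_cis_wc(geometry_class, source)


def _geometry_is_cis_wc(geometry_class: str, source: str) -> bool:
    label = geometry_class.strip()
    src = source.lower()
    if src == "builtin":
        return True
    if src == "rnaview":
        if label.startswith(_RNAVIEW_WC_PREFIXES):
            return True
        if label.startswith("W/W") and "cis" in label.lower():
            return True
        _warn_label(label, source)
        return False
    if src == "dssr":
        if label.lower() in {"wc", "wobble"}:
            return True
        _warn_label(label, source)
        return False
    _warn_label(label, source)
    return False


def _warn_label(label: str, source: str) -> None:
    key = (source, label)
    if key not in _warned_geometry_labels:
        _warned_geometry_labels.add(key)
        logger.debug("geometry label %r from %s treated as non-cis-WC", label, source)


# ---------------------------------------------------------------------------
# RNAView output parsing
# ---------------------------------------------------------------------------

# e.g. "     1_20, A:     1 G-C    20 A: +/+ cis         XIX"
_RNAVIEW_LINE = re.compile(
    r"^\s*(\d+)_(\d+),\s*"
    r"(\S+):\s*(-?\d+)([A-Za-z]?)\s+"
    r"(\S+)-(\S+)\s+"
    r"(-?\d+)([A-Za-z]?)\s+(\S+):\s*"
    r"(.*)$"
)


def parse_rnaview(text: str) -> List[BasePair]:
    """Parse the base-pair section of RNAView text output.

    Lines RNAView marks as ``stacked`` (no pairing class) are skipped.  The
    geometry annotation (e.g. ``W/W cis``, ``+/+ cis``) is preserved verbatim
    in ``geometry_class``.

    Raises :class:`FormatError` when no base-pair line can be parsed, citing
    the first offending line.
    """
    pairs: List[BasePair] = []
    first_bad: Optional[str] = None
    for raw in text.splitlines():
        line = raw.rstrip()
        if not line.strip():
            continue
        stripped = line.strip()
        if stripped.startswith(("BEGIN_base-pair", "END_base-pair",
                                "BEGIN_multiplets", "END_multiplets",
                                "PDB", "uncommon", "#")):
            continue
        m = _RNAVIEW_LINE.match(line)
        if m is None:
            if first_bad is None and not stripped.startswith(("The ", "Time")):
                first_bad = stripped
            continue
        (_, _, ch1, num1, ins1, name1, name2, num2, ins2, ch2, annot) = m.groups()
        annot = annot.strip()
        # geometry annotation is the part before the trailing Saenger class
        # column, e.g. "+/+ cis         XIX" -> "+/+ cis"
        tokens = annot.split()
        if tokens and re.fullmatch(r"[IVXL]+(?:,[IVXL]+)*|n/a|!\S*|[0-9]+", tokens[-1]):
            geometry = " ".join(tokens[:-1])
        else:
            geometry = " ".join(tokens)
        if not geometry or "stack" in geometry.lower():
            continue
        r1 = Residue(chain_id=ch1, seq_num=int(num1), ins_code=ins1, res_name=name1)
        r2 = Residue(chain_id=ch2, seq_num=int(num2), ins_code=ins2, res_name=name2)
        canonical = classify_canonical(name1, name2, geometry, "RNAView")
        pairs.append(BasePair.make(r1, r2, geometry, canonical, "RNAView"))
    if not pairs:
        detail = f"; first offending line: {first_bad!r}" if first_bad else ""
        raise FormatError(f"no parseable RNAView base-pair lines{detail}")
    return pairs


# ---------------------------------------------------------------------------
# DSSR JSON parsing
# ---------------------------------------------------------------------------

# e.g. "A.G15", "B.2MG10", "A.G15^B", "0.U-1"
_DSSR_NT = re.compile(r"^(?:(?P<chain>[^.]+)\.)?(?P<name>.+?)(?P<num>-?\d+)(?:\^(?P<ins>\S+))?$")


def _parse_dssr_nt(ident: str) -> Residue:
    m = _DSSR_NT.match(ident.strip())
    if m is None:
        raise FormatError(f"cannot parse DSSR nucleotide identifier: {ident!r}")
    chain = m.group("chain") or "A"
    return Residue(
        chain_id=chain,
        seq_num=int(m.group("num")),
        ins_code=m.group("ins") or "",
        res_name=m.group("name"),
    )


def parse_dssr(text: str) -> List[BasePair]:
    """Parse DSSR JSON output (the ``pairs`` array with ``nt1``/``nt2``/``name``).

    Entries missing ``nt1`` or ``nt2`` are skipped with a warning; malformed
    JSON raises :class:`FormatError`.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed DSSR JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise FormatError("DSSR JSON root must be an object")
    entries = doc.get("pairs", [])
    pairs: List[BasePair] = []
    for entry in entries:
        nt1, nt2 = entry.get("nt1"), entry.get("nt2")
        if not nt1 or not nt2:
            logger.warning("DSSR pair entry missing nt1/nt2, skipped: %s", entry)
            continue
        try:
            r1 = _parse_dssr_nt(nt1)
            r2 = _parse_dssr_nt(nt2)
        except FormatError as exc:
            logger.warning("%s; entry skipped", exc)
            continue
        geometry = str(entry.get("name", ""))
        canonical = classify_canonical(r1.res_name, r2.res_name, geometry, "DSSR")
        pairs.append(BasePair.make(r1, r2, geometry, canonical, "DSSR"))
    return pairs


# ---------------------------------------------------------------------------
# Built-in geometric detector
# ---------------------------------------------------------------------------

def detect_pairs_builtin(chain: ChainStructure) -> List[BasePair]:
    """Detect canonical base pairs geometrically.

    A pair (i, j) with j > i + 2 is reported when the residue identities form
    a canonical combination and the WC-edge N···N distance is <= 3.2 Å with
    the C1'-C1' distance in [9.8, 11.0] Å.  Residues lacking the required
    atoms are skipped with a warning.  Only canonical pairs are found.
    """
    n = len(chain.residues)
    usable: List[Optional[Tuple[np.ndarray, np.ndarray, str]]] = []
    for res, coords in zip(chain.residues, chain.atom_coords):
        parent = PARENT_MAP.get(res.res_name.upper())
        wc_atom = _WC_NITROGEN.get(parent) if parent else None
        if wc_atom is None or "C1'" not in coords or wc_atom not in coords:
            if parent is not None:
                logger.warning(
                    "residue %s%s (%s) missing C1'/%s atoms; skipped by built-in detector",
                    res.seq_num, res.ins_code, res.res_name, wc_atom,
                )
            usable.append(None)
            continue
        usable.append((coords["C1'"], coords[wc_atom], parent))

    pairs: List[BasePair] = []
    for i in range(n):
        if usable[i] is None:
            continue
        c1_i, nn_i, p_i = usable[i]
        for j in range(i + MIN_SEQ_SEPARATION + 1, n):
            if usable[j] is None:
                continue
            c1_j, nn_j, p_j = usable[j]
            if frozenset({p_i, p_j}) not in CANONICAL_IDENTITIES:
                continue
            nn = float(np.linalg.norm(nn_i - nn_j))
            if nn > NN_DISTANCE_MAX:
                continue
            c1 = float(np.linalg.norm(c1_i - c1_j))
            if not (C1_DISTANCE_MIN <= c1 <= C1_DISTANCE_MAX):
                continue
            pairs.append(
                BasePair.make(chain.residues[i], chain.residues[j],
                              "builtin", True, "builtin")
            )
    return pairs


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_pairs(pairs: Sequence[BasePair], chain_id: str, mode: str) -> List[BasePair]:
    """Keep intra-chain pairs of ``chain_id``; ``canonical_only`` additionally
    drops non-canonical pairs.  Duplicates of the same residue pair collapse to
    one, preferring a canonical annotation."""
    if mode not in {"canonical_only", "include_all"}:
        raise ValueError(f"unknown selection mode {mode!r}")
    chains_present = {p.res1.chain_id for p in pairs} | {p.res2.chain_id for p in pairs}
    intra = [p for p in pairs
             if p.res1.chain_id == chain_id and p.res2.chain_id == chain_id]
    if not intra and chain_id not in chains_present:
        logger.warning("chain %r not present in pair list (chains seen: %s)",
                       chain_id, sorted(chains_present))
    deduped: Dict[tuple, BasePair] = {}
    for p in intra:
        prev = deduped.get(p.key)
        if prev is None or (p.canonical and not prev.canonical):
            deduped[p.key] = p
    out = list(deduped.values())
    if mode == "canonical_only":
        out = [p for p in out if p.canonical]
    return out


def assign_seq_indices(pairs: Sequence[BasePair], chain: ChainStructure) -> List[BasePair]:
    """Return pairs with residues replaced by the chain's indexed residues.

    Pairs whose residues are not found in the chain are dropped with a warning.
    """
    lookup = {r.key: r for r in chain.residues}
    out: List[BasePair] = []
    for p in pairs:
        r1 = lookup.get(p.res1.key)
        r2 = lookup.get(p.res2.key)
        if r1 is None or r2 is None:
            logger.warning("pair %s-%s references residues absent from chain %s; dropped",
                           p.res1.auth_token, p.res2.auth_token, chain.chain_id)
            continue
        out.append(BasePair.make(r1, r2, p.geometry_class, p.canonical, p.source))
    return out
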