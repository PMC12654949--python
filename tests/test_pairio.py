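from pathlib import Path

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from knotlayers.errors import EmptyResultError, FormatError, InputError
from knotlayers.pairio import (
    BasePair,
    Residue,
    classify_canonical,
    detect_pairs_builtin,
    parse_dssr,
    parse_rnaview,
    read_structure,
    select_pairs,
)
from knotlayers.synthdata import (
    gen_helix_mmcif,
    gen_helix_pdb,
    gen_planted_pairs,
    gen_rnaview_text,
    instance_pairs,
)

DATA = Path(__file__).parent / "data"


# ---------------------------------------------------------------------------
# Residue / BasePair types
# ---------------------------------------------------------------------------

def test_residue_requires_chain_id():
    with pytest.raises(ValueError):
        Residue(chain_id="", seq_num=1)


def test_basepair_rejects_self_pair():
    r = Residue(chain_id="A", seq_num=5, res_name="G")
    with pytest.raises(ValueError):
        BasePair(r, r, "WC", True, "DSSR")


def test_basepair_make_normalizes_order():
    r1 = Residue(chain_id="A", seq_num=20, res_name="C", seq_index=19)
    r2 = Residue(chain_id="A", seq_num=1, res_name="G", seq_index=0)
    p = BasePair.make(r1, r2, "WC", True, "DSSR")
    assert p.res1.seq_num == 1 and p.res2.seq_num == 20


# ---------------------------------------------------------------------------
# read_structure
# ---------------------------------------------------------------------------

def test_read_structure_roundtrip_mmcif(tmp_path):
    inst = gen_planted_pairs([3, 2], seed=0)
    path = gen_helix_mmcif(inst, tmp_path / "h.cif")
    chains = read_structure(path)
    assert len(chains) == 1
    chain = chains[0]
    assert len(chain) == inst.n
    assert [r.seq_index for r in chain.residues] == list(range(inst.n))
    assert [r.seq_num for r in chain.residues] == list(range(1, inst.n + 1))


def test_read_structure_pdb_matches_mmcif(tmp_path):
    inst = gen_planted_pairs([3, 2], seed=0)
    cif_chain = read_structure(gen_helix_mmcif(inst, tmp_path / "h.cif"))[0]
    pdb_chain = read_structure(gen_helix_pdb(inst, tmp_path / "h.pdb"))[0]
    assert [(r.chain_id, r.seq_num, r.ins_code, r.res_name) for r in cif_chain.residues] \
        == [(r.chain_id, r.seq_num, r.ins_code, r.res_name) for r in pdb_chain.residues]
    for ca, cb in zip(cif_chain.atom_coords, pdb_chain.atom_coords):
        assert set(ca) == set(cb)
        for name in ca:
            np.testing.assert_allclose(ca[name], cb[name], atol=1e-2)


PROTEIN_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.674   6.719  -4.163  1.00  0.00           C
ATOM      4  N   GLY A   2      10.102   5.902  -3.287  1.00  0.00           N
ATOM      5  CA  GLY A   2       9.145   6.366  -2.286  1.00  0.00           C
END
"""


def test_read_structure_protein_only_is_empty_result(tmp_path):
    path = tmp_path / "prot.pdb"
    path.write_text(PROTEIN_PDB)
    with pytest.raises(EmptyResultError):
        read_structure(path)


def test_read_structure_missing_file():
    with pytest.raises(InputError):
        read_structure("/nonexistent/file.cif")


# ---------------------------------------------------------------------------
# parse_rnaview
# ---------------------------------------------------------------------------

def test_parse_rnaview_fixture_counts():
    pairs = parse_rnaview((DATA / "rnaview_basic.txt").read_text())
    # 4 pair lines parse (the stacked line is skipped); 3 are canonical
    assert len(pairs) == 4
    assert sum(p.canonical for p in pairs) == 3
    geometries = {p.geometry_class for p in pairs}
    assert geometries == {"+/+ cis", "W/W cis", "H/W tran"}
    gu = [p for p in pairs if {p.res1.res_name, p.res2.res_name} == {"G", "U"}][0]
    assert gu.canonical


def test_parse_rnaview_empty_text_is_format_error():
    with pytest.raises(FormatError):
        parse_rnaview("")


def test_parse_rnaview_keeps_interchain_pairs():
    pairs = parse_rnaview((DATA / "rnaview_interchain.txt").read_text())
    assert len(pairs) == 2
    inter = [p for p in pairs if p.res1.chain_id != p.res2.chain_id]
    assert len(inter) == 1
    assert {inter[0].res1.chain_id, inter[0].res2.chain_id} == {"A", "B"}


def test_parse_rnaview_idempotent_on_generated_fixture():
    inst = gen_planted_pairs([4, 3, 2], seed=1, noncanonical_fraction=0.3)
    text = gen_rnaview_text(inst)
    pairs = parse_rnaview(text)
    got = {(p.res1.seq_num - 1, p.res2.seq_num - 1) for p in pairs}
    assert got == instance_pairs(inst)
    got_canon = {(p.res1.seq_num - 1, p.res2.seq_num - 1): p.canonical for p in pairs}
    assert got_canon == inst.pair_annotations


# ---------------------------------------------------------------------------
# parse_dssr
# ---------------------------------------------------------------------------

def test_parse_dssr_fixture_counts():
    pairs = parse_dssr((DATA / "dssr_basic.json").read_text())
    assert len(pairs) == 3
    assert sum(p.canonical for p in pairs) == 2


def test_parse_dssr_empty_pairs_array():
    assert parse_dssr('{"pairs": []}') == []


def test_parse_dssr_malformed_json():
    with pytest.raises(FormatError):
        parse_dssr("{not json")


def test_parse_dssr_skips_entry_missing_nt(caplog):
    text = '{"pairs": [{"nt2": "A.C5", "name": "WC"}, ' \
           '{"nt1": "A.G1", "nt2": "A.C9", "name": "WC"}]}'
    pairs = parse_dssr(text)
    assert len(pairs) == 1


def test_parse_dssr_insertion_code():
    pairs = parse_dssr('{"pairs": [{"nt1": "A.G15^B", "nt2": "A.C40", "name": "WC"}]}')
    (p,) = pairs
    assert p.res1.seq_num == 15 and p.res1.ins_code == "B"
    assert p.res1.res_name == "G"


def test_parse_dssr_modified_nucleotide_and_negative_number():
    pairs = parse_dssr(
        '{"pairs": [{"nt1": "B.2MG10", "nt2": "B.C-1", "name": "WC"}]}')
    (p,) = pairs
    names = {p.res1.res_name, p.res2.res_name}
    assert names == {"2MG", "C"}
    assert {p.res1.seq_num, p.res2.seq_num} == {10, -1}
    assert p.canonical  # 2MG maps to parent G


# ---------------------------------------------------------------------------
# classify_canonical
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "r1,r2,geom,source,expected",
    [
        ("G", "C", "WC", "DSSR", True),
        ("G", "U", "Wobble", "DSSR", True),
        ("A", "U", "WC", "DSSR", True),
        ("A", "G", "H/W tran", "RNAView", False),
        ("G", "C", "Hoogsteen", "DSSR", False),
        ("G", "C", "+/+ cis", "RNAView", True),
        ("A", "U", "-/- cis", "RNAView", True),
        ("G", "U", "W/W cis", "RNAView", True),
        ("G", "U", "W/W tran", "RNAView", False),
        ("A", "C", "WC", "DSSR", False),
        ("G", "C", "builtin", "builtin", True),
        ("PSU", "A", "WC", "DSSR", True),   # modified U parent
        ("2MG", "C", "WC", "DSSR", True),
        ("XYZ", "C", "WC", "DSSR", False),  # unknown modified name
    ],
)
def test_classify_canonical_truth_table(r1, r2, geom, source, expected):
    assert classify_canonical(r1, r2, geom, source) is expected


@given(
    r1=st.sampled_from(["A", "C", "G", "U", "PSU", "XYZ"]),
    r2=st.sampled_from(["A", "C", "G", "U", "2MG", "XYZ"]),
    geom=st.sampled_from(["WC", "Wobble", "Hoogsteen", "+/+ cis", "H/W tran"]),
    source=st.sampled_from(["DSSR", "RNAView", "builtin"]),
)
def test_classify_canonical_symmetric(r1, r2, geom, source):
    assert classify_canonical(r1, r2, geom, source) == \
        classify_canonical(r2, r1, geom, source)


def test_classify_canonical_identity_only_switch():
    assert not classify_canonical("G", "C", "Hoogsteen", "DSSR")
    assert classify_canonical("G", "C", "Hoogsteen", "DSSR", require_geometry=False)


# ---------------------------------------------------------------------------
# detect_pairs_builtin
# ---------------------------------------------------------------------------

def test_detect_duplex(tmp_path):
    inst = gen_planted_pairs([8], seed=3)
    chain = read_structure(gen_helix_mmcif(inst, tmp_path / "d.cif"))[0]
    pairs = detect_pairs_builtin(chain)
    got = {(p.res1.seq_index, p.res2.seq_index) for p in pairs}
    assert got == instance_pairs(inst)
    assert all(p.canonical and p.source == "builtin" for p in pairs)


def test_detect_translated_strand_finds_nothing(tmp_path):
    inst = gen_planted_pairs([8], seed=3)
    chain = read_structure(gen_helix_mmcif(inst, tmp_path / "d.cif"))[0]
    closing = {j for (_, j) in instance_pairs(inst)}
    for idx in closing:
        for name in chain.atom_coords[idx]:
            chain.atom_coords[idx][name] = chain.atom_coords[idx][name] + np.array([0.0, 5.0, 0.0])
    assert detect_pairs_builtin(chain) == []


def test_detect_htype_recovers_planted(tmp_path, htype_instance):
    chain = read_structure(gen_helix_mmcif(htype_instance, tmp_path / "h.cif"))[0]
    pairs = detect_pairs_builtin(chain)
    got = {(p.res1.seq_index, p.res2.seq_index) for p in pairs}
    assert got == instance_pairs(htype_instance)
    assert len(pairs) == 5


def test_detect_skips_residue_with_missing_atoms(tmp_path, caplog):
    inst = gen_planted_pairs([3], seed=0)
    chain = read_structure(gen_helix_mmcif(inst, tmp_path / "m.cif"))[0]
    (i0, j0) = sorted(instance_pairs(inst))[0]
    del chain.atom_coords[i0]["C1'"]
    pairs = detect_pairs_builtin(chain)
    got = {(p.res1.seq_index, p.res2.seq_index) for p in pairs}
    assert got == instance_pairs(inst) - {(i0, j0)}


# ---------------------------------------------------------------------------
# select_pairs
# ---------------------------------------------------------------------------

def _demo_pairs():
    def res(ch, num, name, idx=None):
        return Residue(chain_id=ch, seq_num=num, res_name=name, seq_index=idx)

    return [
        BasePair.make(res("A", 1, "G", 0), res("A", 20, "C", 19), "WC", True, "DSSR"),
        BasePair.make(res("A", 2, "A", 1), res("A", 19, "U", 18), "WC", True, "DSSR"),
        BasePair.make(res("A", 3, "G", 2), res("A", 18, "U", 17), "Wobble", True, "DSSR"),
        BasePair.make(res("A", 5, "A", 4), res("A", 15, "G", 14), "Hoogsteen", False, "DSSR"),
        BasePair.make(res("A", 4, "C", 3), res("B", 33, "G", None), "WC", True, "DSSR"),
    ]


def test_select_canonical_only():
    assert len(select_pairs(_demo_pairs(), "A", "canonical_only")) == 3


def test_select_include_all():
    assert len(select_pairs(_demo_pairs(), "A", "include_all")) == 4


def test_select_absent_chain_warns(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="knotlayers.pairio"):
        out = select_pairs(_demo_pairs()[:4], "Z", "include_all")
    assert out == []
    assert any("not present" in rec.message for rec in caplog.records)


def test_select_dedupes_preferring_canonical():
    pairs = _demo_pairs()[:1]
    dup = BasePair.make(pairs[0].res1, pairs[0].res2, "Hoogsteen", False, "DSSR")
    out = select_pairs([dup] + pairs, "A", "include_all")
    assert len(out) == 1 and out[0].canonical


def test_select_canonical_subset_of_include_all():
    pairs = _demo_pairs()
    canon = {p.key for p in select_pairs(pairs, "A", "canonical_only")}
    allp = {p.key for p in select_pairs(pairs, "A", "include_all")}
    assert canon <= allp


def test_select_unknown_mode():
    with pytest.raises(ValueError):
        select_pairs([], "A", "everything")
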