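"""Assembly-map conversion, scaffold reconstruction, edits and liftover."""

import hashlib

import numpy as np
import pytest

from notocraft.curation import (
    EditOperation,
    apply_edits,
    assembly_map_to_agp,
    build_fasta_from_agp,
    contig_to_object_map,
    liftover_features,
)
from notocraft.io_formats import (
    AssemblyMap,
    FeatureRecord,
    SeqRecord,
)


@pytest.fixture()
def two_contig_map():
    return AssemblyMap(entries=[("c1", 1, 1000), ("c2", 2, 500)],
                       scaffolds=[[1, -2]])


@pytest.fixture()
def two_contig_agp(two_contig_map):
    return assembly_map_to_agp(two_contig_map, gap_length=500)


CONTIGS = {
    "c1": SeqRecord(id="c1", sequence="A" * 1000),
    "c2": SeqRecord(id="c2", sequence="C" * 500),
}


# ---------------------------------------------------------------------------
# map -> AGP
# ---------------------------------------------------------------------------

def test_map_to_agp_coordinates(two_contig_agp):
    rows = two_contig_agp.rows
    assert len(rows) == 3
    w1, gap, w2 = rows
    # 1-based spans on disk would read: 1-1000 W c1 +, 1001-1500 N, 1501-2000 W c2 -
    assert (w1.object_beg, w1.object_end, w1.component_id, w1.orientation) == \
        (0, 1000, "c1", "+")
    assert (gap.object_beg, gap.object_end, gap.gap_length) == (1000, 1500, 500)
    assert gap.gap_type == "scaffold" and gap.linkage == "yes"
    assert gap.linkage_evidence == "proximity_ligation"
    assert (w2.object_beg, w2.object_end, w2.component_id, w2.orientation) == \
        (1500, 2000, "c2", "-")


def test_map_to_agp_singleton():
    amap = AssemblyMap(entries=[("c3", 1, 700)], scaffolds=[[1]])
    agp = assembly_map_to_agp(amap)
    assert len(agp.rows) == 1
    assert agp.rows[0].component_id == "c3"


def test_map_to_agp_zero_gap():
    amap = AssemblyMap(entries=[("c1", 1, 100), ("c2", 2, 50)], scaffolds=[[1, 2]])
    agp = assembly_map_to_agp(amap, gap_length=0)
    assert [r.component_type for r in agp.rows] == ["W", "W"]
    assert agp.object_length("scaffold_1") == 150


def test_map_to_agp_zero_length_entry_raises():
    amap = AssemblyMap(entries=[("c1", 1, 0)], scaffolds=[[1]])
    with pytest.raises(ValueError, match="zero-length"):
        assembly_map_to_agp(amap)


# ---------------------------------------------------------------------------
# AGP -> FASTA
# ---------------------------------------------------------------------------

def test_build_fasta_revcomp_and_gap(two_contig_agp):
    (scaffold,) = build_fasta_from_agp(two_contig_agp, CONTIGS)
    # revcomp of a C-run is a G-run
    assert scaffold.sequence == "A" * 1000 + "N" * 500 + "G" * 500


def test_build_fasta_identity_single_plus():
    amap = AssemblyMap(entries=[("c1", 1, 1000)], scaffolds=[[1]])
    agp = assembly_map_to_agp(amap)
    (scaffold,) = build_fasta_from_agp(agp, CONTIGS)
    assert scaffold.sequence == CONTIGS["c1"].sequence


def test_build_fasta_double_reorient_is_identity(two_contig_agp):
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=500))
    contigs = {"c1": CONTIGS["c1"], "c2": SeqRecord(id="c2", sequence=seq)}
    (before,) = build_fasta_from_agp(two_contig_agp, contigs)
    flip = [EditOperation("reorient", {"component": "c2"})]
    agp2, _ = apply_edits(two_contig_agp, flip)
    agp3, _ = apply_edits(agp2, flip)
    (after,) = build_fasta_from_agp(agp3, contigs)
    assert after.sequence == before.sequence


def test_build_fasta_missing_contig_raises(two_contig_agp):
    with pytest.raises(ValueError, match="missing contig c2"):
        build_fasta_from_agp(two_contig_agp, {"c1": CONTIGS["c1"]})


# ---------------------------------------------------------------------------
# edits
# ---------------------------------------------------------------------------

def test_empty_edit_list_is_identity(two_contig_agp, tmp_path):
    from notocraft.io_formats import write_agp

    agp2, lmap = apply_edits(two_contig_agp, [])
    p1, p2 = tmp_path / "a.agp", tmp_path / "b.agp"
    write_agp(two_contig_agp, p1)
    write_agp(agp2, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert all(not iv.flipped for iv in lmap.intervals)
    assert all(
        (iv.old_object, iv.old_start, iv.old_end)
        == (iv.new_object, iv.new_start, iv.new_end)
        for iv in lmap.intervals
    )


def test_reorient_flips_interval_only(two_contig_agp):
    agp2, lmap = apply_edits(
        two_contig_agp, [EditOperation("reorient", {"component": "c2"})]
    )
    w2 = [r for r in agp2.rows if r.component_id == "c2"][0]
    assert w2.orientation == "+"  # was '-'
    assert (w2.object_beg, w2.object_end) == (1500, 2000)  # spans unchanged
    (iv,) = [iv for iv in lmap.intervals if iv.old_start == 1500]
    assert iv.flipped


def test_move_retiles_both_objects():
    amap = AssemblyMap(
        entries=[("c1", 1, 1000), ("c2", 2, 500), ("c3", 3, 800)],
        scaffolds=[[1, 2], [3]],
    )
    agp = assembly_map_to_agp(amap, gap_length=500)
    agp2, lmap = apply_edits(
        agp,
        [EditOperation("move", {"component": "c2", "target": "scaffold_2",
                                "index": 0})],
    )
    # source re-tiled without c2, gap collapsed
    assert agp2.object_length("scaffold_1") == 1000
    # target re-tiled with c2 first: 500 + gap 500 + 800
    rows2 = agp2.object_rows("scaffold_2")
    assert [r.component_id for r in rows2 if not r.is_gap] == ["c2", "c3"]
    assert agp2.object_length("scaffold_2") == 1800
    # c3 shifted downstream by c2 span + gap
    iv3 = [iv for iv in lmap.intervals if iv.old_object == "scaffold_2"][0]
    assert (iv3.new_start, iv3.new_end) == (1000, 1800)


def test_edit_unknown_component_reports_index(two_contig_agp):
    with pytest.raises(ValueError, match="edit 0"):
        apply_edits(two_contig_agp, [EditOperation("reorient", {"component": "zz"})])


def test_join_keeps_lower_numbered_name():
    amap = AssemblyMap(
        entries=[("c1", 1, 100), ("c2", 2, 200)],
        scaffolds=[[1], [2]],
    )
    agp = assembly_map_to_agp(amap, naming=["chr11", "chr8"])
    agp2, _ = apply_edits(agp, [EditOperation("join", {"objects": ["chr11", "chr8"]})])
    assert agp2.objects == ["chr8"]
    assert agp2.object_length("chr8") == 100 + 500 + 200


def test_split_then_join_roundtrip(two_contig_agp):
    script = [
        EditOperation("split", {"object": "scaffold_1", "after_component": "c1",
                                "names": ["sA", "sB"]}),
        EditOperation("join", {"objects": ["sA", "sB"], "name": "scaffold_1"}),
    ]
    agp2, lmap = apply_edits(two_contig_agp, script)
    assert agp2.objects == ["scaffold_1"]
    assert agp2.object_length("scaffold_1") == 2000
    assert all(
        (iv.old_start, iv.old_end) == (iv.new_start, iv.new_end)
        for iv in lmap.intervals
    )


def _content_hash(agp, contigs):
    """Multiset of contig sequences up to reverse complement."""
    from Bio.Seq import Seq

    digests = []
    for row in agp.rows:
        if row.is_gap:
            continue
        seq = contigs[row.component_id].sequence[row.component_beg:row.component_end]
        canonical = min(seq, str(Seq(seq).reverse_complement()))
        digests.append(hashlib.sha256(canonical.encode()).hexdigest())
    return sorted(digests)


def test_sequence_conservation_under_edit_script():
    rng = np.random.default_rng(5)
    contigs = {
        f"c{i}": SeqRecord(id=f"c{i}", sequence="".join(rng.choice(list("ACGT"), size=400)))
        for i in range(1, 6)
    }
    amap = AssemblyMap(
        entries=[(f"c{i}", i, 400) for i in range(1, 6)],
        scaffolds=[[1, -2, 3], [4, 5]],
    )
    agp = assembly_map_to_agp(amap)
    script = [
        EditOperation("reorient", {"component": "c3"}),
        EditOperation("move", {"component": "c2", "target": "scaffold_2", "index": 1}),
        EditOperation("reorder", {"object": "scaffold_2",
                                  "order": ["c5", "c2", "c4"]}),
        EditOperation("rename", {"object": "scaffold_1", "name": "chr1"}),
    ]
    agp2, _ = apply_edits(agp, script)
    assert _content_hash(agp2, contigs) == _content_hash(agp, contigs)
    # both construction paths yield tiled, valid AGP and equal total W bases
    total = lambda a: sum(r.span for r in a.rows if not r.is_gap)  # noqa: E731
    assert total(agp2) == total(agp)


# ---------------------------------------------------------------------------
# liftover
# ---------------------------------------------------------------------------

def test_liftover_unedited_object_unchanged(two_contig_agp):
    _, lmap = apply_edits(two_contig_agp, [])
    feat = FeatureRecord("scaffold_1", "src", "gene", 100, 300, None, "+", ".",
                         {"ID": "g"})
    (lifted,) = liftover_features([feat], lmap)
    assert (lifted.seqid, lifted.start, lifted.end, lifted.strand) == \
        ("scaffold_1", 100, 300, "+")


def test_liftover_flip_formula(two_contig_agp):
    """A gene at 1-based 1501-1600 (+) inside the 1501-2000 interval of a
    flipped contig lands at 401-500 on the minus strand."""
    agp2, lmap = apply_edits(
        two_contig_agp, [EditOperation("reorient", {"component": "c2"})]
    )
    feat = FeatureRecord("scaffold_1", "src", "gene", 1500, 1600, None, "+", ".",
                         {"ID": "g"})
    (lifted,) = liftover_features([feat], lmap)
    # interval old [1500,2000) maps to new [1500,2000) flipped
    assert (lifted.start + 1, lifted.end) == (1901, 2000)
    assert lifted.strand == "-"


def test_liftover_flip_formula_worked_example():
    """Flipped interval moved to the start of its object: old 1501-2000
    -> new 1-500; a gene at old 1501-1600 maps to 401-500, strand '-'."""
    from notocraft.curation import LiftoverMap, MappedInterval

    lmap = LiftoverMap([
        MappedInterval("X", 1500, 2000, "Y", 0, 500, flipped=True),
    ])
    feat = FeatureRecord("X", "src", "gene", 1500, 1600, None, "+", ".", {})
    (lifted,) = liftover_features([feat], lmap)
    assert (lifted.start + 1, lifted.end) == (401, 500)
    assert lifted.strand == "-"


def test_liftover_boundary_spanning_feature_errors(two_contig_agp):
    _, lmap = apply_edits(two_contig_agp, [])
    feat = FeatureRecord("scaffold_1", "src", "gene", 900, 1600, None, "+", ".", {})
    with pytest.raises(ValueError, match="spans|unmapped"):
        liftover_features([feat], lmap)


def test_liftover_gap_feature_errors(two_contig_agp):
    _, lmap = apply_edits(two_contig_agp, [])
    feat = FeatureRecord("scaffold_1", "src", "gene", 1100, 1200, None, "+", ".", {})
    with pytest.raises(ValueError, match="unmapped"):
        liftover_features([feat], lmap)


def test_liftover_split_policy_shares_id():
    from notocraft.curation import LiftoverMap, MappedInterval

    lmap = LiftoverMap([
        MappedInterval("X", 0, 500, "Y", 0, 500),
        MappedInterval("X", 500, 1000, "Z", 0, 500),
    ])
    feat = FeatureRecord("X", "src", "gene", 400, 600, None, "+", ".", {"ID": "g1"})
    parts = liftover_features([feat], lmap, boundary="split")
    assert [(p.seqid, p.start, p.end) for p in parts] == [("Y", 400, 500), ("Z", 0, 100)]
    assert all(p.attributes["ID"] == "g1" for p in parts)


def test_liftover_roundtrip_identity_on_random_features():
    """liftover through a map then its inverse is the identity (1,000
    random features over a multi-edit script)."""
    rng = np.random.default_rng(17)
    amap = AssemblyMap(
        entries=[(f"c{i}", i, 10_000) for i in range(1, 7)],
        scaffolds=[[1, -2, 3], [4, 5, -6]],
    )
    agp = assembly_map_to_agp(amap)
    script = [
        EditOperation("reorient", {"component": "c2"}),
        EditOperation("move", {"component": "c5", "target": "scaffold_1",
                               "index": 0}),
        EditOperation("reorder", {"object": "scaffold_1",
                                  "order": ["c3", "c5", "c1", "c2"]}),
    ]
    _, lmap = apply_edits(agp, script)
    inverse = lmap.inverse()
    # features confined to W intervals of the old assembly
    w_ivs = [(iv.old_object, iv.old_start, iv.old_end) for iv in lmap.intervals]
    feats = []
    for _ in range(1_000):
        obj, lo, hi = w_ivs[int(rng.integers(0, len(w_ivs)))]
        start = int(rng.integers(lo, hi - 1))
        end = int(rng.integers(start + 1, hi + 1))
        feats.append(FeatureRecord(obj, "s", "gene", start, end, None,
                                   "+" if rng.integers(0, 2) else "-", ".", {}))
    back = liftover_features(liftover_features(feats, lmap), inverse)
    assert [(f.seqid, f.start, f.end, f.strand) for f in back] == \
        [(f.seqid, f.start, f.end, f.strand) for f in feats]


def test_contig_to_object_map_covers_w_bases(two_contig_agp):
    lmap = contig_to_object_map(two_contig_agp)
    assert sorted((iv.old_object, iv.old_start, iv.old_end) for iv in lmap.intervals) \
        == [("c1", 0, 1000), ("c2", 0, 500)]
    c2 = [iv for iv in lmap.intervals if iv.old_object == "c2"][0]
    assert c2.flipped and (c2.new_start, c2.new_end) == (1500, 2000)
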