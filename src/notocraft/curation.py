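"""Assembly curation: 3d-DNA map -> AGP conversion, scaffold FASTA
reconstruction, structural edits, and annotation coordinate liftover.

A scaffolded assembly is represented by an AGP file: each object
(scaffold/chromosome) is a tiling of oriented contig spans (W rows) and
gap runs (N rows).  Curation edits — reorder, reorient, move, split,
join, rename — operate on that representation; contigs are atomic under
every edit, so the old->new coordinate map used to lift annotations is
derived directly from each contig's placement before and after the edit
script.

All coordinates here are 0-based half-open (I/O conversion happens in
:mod:`notocraft.io_formats`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .io_formats import AgpFile, AgpRow, AssemblyMap, FeatureRecord, SeqRecord

__all__ = [
    "EditOperation",
    "MappedInterval",
    "LiftoverMap",
    "assembly_map_to_agp",
    "build_fasta_from_agp",
    "apply_edits",
    "liftover_features",
    "contig_to_object_map",
]

DEFAULT_GAP_LENGTH = 500


@dataclass
class EditOperation:
    """One curation action.

    kinds and arguments:
      - ``reorient``: component
      - ``reorder``: object, order (list of component ids)
      - ``move``: component, target (object), index (component rank in target)
      - ``split``: object, after_component, names (2 new object names)
      - ``join``: objects (list of 2), name (optional; defaults to the
        lower-numbered of the two, mirroring the convention of keeping
        the smaller chromosome label for a fusion)
      - ``rename``: object, name
    """

    kind: str
    args: dict = field(default_factory=dict)

    KINDS = ("reorient", "reorder", "move", "split", "join", "rename")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown edit kind {self.kind!r}")


@dataclass
class MappedInterval:
    old_object: str
    old_start: int
    old_end: int
    new_object: str
    new_start: int
    new_end: int
    flipped: bool = False

    def __post_init__(self) -> None:
        if self.old_end - self.old_start != self.new_end - self.new_start:
            raise ValueError("liftover interval is not length-preserving")


@dataclass
class LiftoverMap:
    """Ordered, non-overlapping old->new interval map (contig-granular)."""

    intervals: list[MappedInterval]

    def inverse(self) -> "LiftoverMap":
        return LiftoverMap(
            [
                MappedInterval(
                    iv.new_object, iv.new_start, iv.new_end,
                    iv.old_object, iv.old_start, iv.old_end, iv.flipped,
                )
                for iv in self.intervals
            ]
        )

    def by_old_object(self) -> dict[str, list[MappedInterval]]:
        idx: dict[str, list[MappedInterval]] = {}
        for iv in self.intervals:
            idx.setdefault(iv.old_object, []).append(iv)
        for ivs in idx.values():
            ivs.sort(key=lambda iv: iv.old_start)
        return idx


# ---------------------------------------------------------------------------
# internal object model: object -> ordered parts
# ---------------------------------------------------------------------------

@dataclass
class _Comp:
    cid: str
    cbeg: int
    cend: int
    orientation: str

    @property
    def span(self) -> int:
        return self.cend - self.cbeg


@dataclass
class _Gap:
    length: int
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "proximity_ligation"


def _parts_from_agp(agp: AgpFile) -> dict[str, list]:
    objects: dict[str, list] = {}
    for row in agp.rows:
        parts = objects.setdefault(row.object, [])
        if row.is_gap:
            parts.append(_Gap(row.gap_length, row.gap_type, row.linkage,
                              row.linkage_evidence))
        else:
            parts.append(_Comp(row.component_id, row.component_beg,
                               row.component_end, row.orientation))
    return objects


def _agp_from_parts(objects: dict[str, list]) -> AgpFile:
    rows: list[AgpRow] = []
    for obj, parts in objects.items():
        pos = 0
        part_number = 0
        for part in parts:
            part_number += 1
            if isinstance(part, _Gap):
                rows.append(
                    AgpRow(
                        object=obj, object_beg=pos, object_end=pos + part.length,
                        part_number=part_number, component_type="N",
                        gap_length=part.length, gap_type=part.gap_type,
                        linkage=part.linkage, linkage_evidence=part.evidence,
                    )
                )
                pos += part.length
            else:
                rows.append(
                    AgpRow(
                        object=obj, object_beg=pos, object_end=pos + part.span,
                        part_number=part_number, component_type="W",
                        component_id=part.cid, component_beg=part.cbeg,
                        component_end=part.cend, orientation=part.orientation,
                    )
                )
                pos += part.span
    agp = AgpFile(rows=rows)
    agp.validate()
    return agp


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", name)]


# ---------------------------------------------------------------------------
# 3d-DNA map -> AGP
# ---------------------------------------------------------------------------

def assembly_map_to_agp(amap: AssemblyMap, gap_length: int = DEFAULT_GAP_LENGTH,
                        naming=None) -> AgpFile:
    """Convert a 3d-DNA assembly map into an AGP file.

    Each scaffold becomes one object: W rows in map order (orientation
    from the id sign) alternating with N gap rows of ``gap_length``
    (gap_type "scaffold", linkage "yes", evidence "proximity_ligation").
    With ``gap_length`` 0 the W rows abut directly.  ``naming`` may be a
    list of object names or a callable of the scaffold index; the
    default is ``scaffold_1`` ...
    """
    amap.validate()
    names = amap.id_to_name()
    lengths = amap.id_to_length()
    for name, eid, length in amap.entries:
        if length <= 0:
            raise ValueError(f"zero-length entry {name}")
    objects: dict[str, list] = {}
    for i, scaffold in enumerate(amap.scaffolds):
        if callable(naming):
            obj = naming(i)
        elif naming is not None:
            obj = naming[i]
        else:
            obj = f"scaffold_{i + 1}"
        parts: list = []
        for sid in scaffold:
            if parts and gap_length > 0:
                parts.append(_Gap(gap_length))
            cid = names[abs(sid)]
            parts.append(_Comp(cid, 0, lengths[abs(sid)], "+" if sid > 0 else "-"))
        objects[obj] = parts
    return _agp_from_parts(objects)


# ---------------------------------------------------------------------------
# AGP -> FASTA
# ---------------------------------------------------------------------------

def build_fasta_from_agp(agp: AgpFile, contigs) -> list[SeqRecord]:
    """Reconstruct scaffold sequences from an AGP file plus contigs.

    '-' orientation inserts the reverse complement of the component
    slice; N/U gap rows insert runs of N.
    """
    if not isinstance(contigs, dict):
        contigs = {rec.id: rec for rec in contigs}
    agp.validate()
    out: list[SeqRecord] = []
    for obj in agp.objects:
        chunks: list[str] = []
        for row in agp.object_rows(obj):
            if row.is_gap:
                chunks.append("N" * row.gap_length)
                continue
            if row.component_id not in contigs:
                raise ValueError(f"missing contig {row.component_id}")
            seq = contigs[row.component_id].sequence
            if row.component_end > len(seq):
                raise ValueError(
                    f"component_end {row.component_end} beyond contig "
                    f"{row.component_id} length {len(seq)}"
                )
            piece = seq[row.component_beg:row.component_end]
            if row.orientation == "-":
                piece = str(Seq(piece).reverse_complement())
            chunks.append(piece)
        out.append(SeqRecord(id=obj, sequence="".join(chunks)))
    return out


# ---------------------------------------------------------------------------
# edits
# ---------------------------------------------------------------------------

def _find_component(objects: dict[str, list], cid: str):
    for obj, parts in objects.items():
        for i, part in enumerate(parts):
            if isinstance(part, _Comp) and part.cid == cid:
                return obj, i
    raise KeyError(cid)


def _remove_component(parts: list, i: int) -> list:
    """Remove the component at index i, collapsing the adjacent gap."""
    del parts[i]
    if i < len(parts) and isinstance(parts[i], _Gap):
        del parts[i]
    elif i > 0 and isinstance(parts[i - 1], _Gap):
        del parts[i - 1]
    return parts


def _component_indices(parts: list) -> list[int]:
    return [i for i, p in enumerate(parts) if isinstance(p, _Comp)]


def _apply_one(objects: dict[str, list], edit: EditOperation,
               gap_length: int) -> None:
    a = edit.args
    if edit.kind == "reorient":
        obj, i = _find_component(objects, a["component"])
        comp = objects[obj][i]
        comp.orientation = "-" if comp.orientation == "+" else "+"

    elif edit.kind == "reorder":
        parts = objects[a["object"]]
        comps = {p.cid: p for p in parts if isinstance(p, _Comp)}
        if set(a["order"]) != set(comps):
            raise ValueError(
                f"reorder of {a['object']} must list exactly its components"
            )
        gaps = [p for p in parts if isinstance(p, _Gap)]
        new_parts: list = []
        for j, cid in enumerate(a["order"]):
            if j:
                new_parts.append(gaps[j - 1] if j - 1 < len(gaps) else _Gap(gap_length))
            new_parts.append(comps[cid])
        objects[a["object"]] = new_parts

    elif edit.kind == "move":
        obj, i = _find_component(objects, a["component"])
        comp = objects[obj][i]
        _remove_component(objects[obj], i)
        if not objects[obj]:
            del objects[obj]
        target = a["target"]
        if target not in objects:
            objects[target] = []
        parts = objects[target]
        cidx = _component_indices(parts)
        rank = a.get("index", len(cidx))
        if rank < 0 or rank > len(cidx):
            raise ValueError(f"move index {rank} out of range for {target}")
        at = cidx[rank] if rank < len(cidx) else len(parts)
        insert: list = [comp]
        if rank < len(cidx):  # a component follows: gap after
            if gap_length > 0:
                insert = [comp, _Gap(gap_length)]
        elif cidx:  # appending after existing components: gap before
            if gap_length > 0:
                insert = [_Gap(gap_length), comp]
        parts[at:at] = insert

    elif edit.kind == "split":
        obj = a["object"]
        parts = objects[obj]
        obj_pos = list(objects).index(obj)
        cut = None
        for i, part in enumerate(parts):
            if isinstance(part, _Comp) and part.cid == a["after_component"]:
                cut = i + 1
                break
        if cut is None:
            raise KeyError(a["after_component"])
        left, right = parts[:cut], parts[cut:]
        if right and isinstance(right[0], _Gap):
            right = right[1:]  # the gap at the split boundary is dropped
        if not right:
            raise ValueError("split after the last component is a no-op")
        n1, n2 = a["names"]
        rebuilt = list(objects.items())
        del objects[obj]
        objects.clear()
        for name, p in rebuilt:
            if name == obj:
                objects[n1] = left
                objects[n2] = right
            else:
                objects[name] = p

    elif edit.kind == "join":
        o1, o2 = a["objects"]
        name = a.get("name") or min(o1, o2, key=_natural_key)
        joined = list(objects[o1])
        if gap_length > 0 and joined and objects[o2]:
            joined.append(_Gap(gap_length))
        joined.extend(objects[o2])
        rebuilt = list(objects.items())
        objects.clear()
        placed = False
        for oname, p in rebuilt:
            if oname in (o1, o2):
                if not placed:
                    objects[name] = joined
                    placed = True
            else:
                objects[oname] = p

    elif edit.kind == "rename":
        obj, new = a["object"], a["name"]
        if new in objects and new != obj:
            raise ValueError(f"rename target {new} already exists")
        rebuilt = list(objects.items())
        objects.clear()
        for oname, p in rebuilt:
            objects[new if oname == obj else oname] = p


def _component_placements(agp: AgpFile) -> dict[str, tuple[str, int, int, str]]:
    placements = {}
    for row in agp.rows:
        if not row.is_gap:
            placements[row.component_id] = (
                row.object, row.object_beg, row.object_end, row.orientation
            )
    return placements


def apply_edits(agp: AgpFile, edits, gap_length: int = DEFAULT_GAP_LENGTH
                ) -> tuple[AgpFile, LiftoverMap]:
    """Apply an ordered edit script; return the new AGP and a liftover map.

    Each edit applies to the result of the previous one.  Contigs are
    never split, so the returned :class:`LiftoverMap` has one interval
    per W row, mapping its old placement to its new one (``flipped``
    when the orientation changed).  The contig content multiset is
    unchanged by construction.
    """
    agp.validate()
    objects = _parts_from_agp(agp)
    for idx, edit in enumerate(edits):
        try:
            _apply_one(objects, edit, gap_length)
        except KeyError as exc:
            raise ValueError(f"edit {idx} ({edit.kind}): unknown id {exc}") from exc
        except ValueError as exc:
            raise ValueError(f"edit {idx} ({edit.kind}): {exc}") from exc
    new_agp = _agp_from_parts(objects)

    old_place = _component_placements(agp)
    new_place = _component_placements(new_agp)
    if set(old_place) != set(new_place):
        raise AssertionError("edit script changed the contig content multiset")
    intervals = [
        MappedInterval(
            *old_place[cid][:3],
            *new_place[cid][:3],
            flipped=old_place[cid][3] != new_place[cid][3],
        )
        for cid in old_place
    ]
    intervals.sort(key=lambda iv: (iv.old_object, iv.old_start))
    return new_agp, LiftoverMap(intervals)


def contig_to_object_map(agp: AgpFile) -> LiftoverMap:
    """Map contig-local coordinates to object coordinates for an AGP.

    Useful for lifting per-contig annotation onto the scaffolds the AGP
    describes.  The map is flipped for '-' oriented placements.
    """
    intervals = [
        MappedInterval(
            row.component_id, row.component_beg, row.component_end,
            row.object, row.object_beg, row.object_end,
            flipped=row.orientation == "-",
        )
        for row in agp.rows if not row.is_gap
    ]
    return LiftoverMap(intervals)


# ---------------------------------------------------------------------------
# liftover
# ---------------------------------------------------------------------------

def _lift_one(feat: FeatureRecord, iv: MappedInterval) -> FeatureRecord:
    if not iv.flipped:
        new_start = iv.new_start + (feat.start - iv.old_start)
        new_end = iv.new_start + (feat.end - iv.old_start)
        strand = feat.strand
    else:
        new_start = iv.new_start + (iv.old_end - feat.end)
        new_end = iv.new_start + (iv.old_end - feat.start)
        strand = {"+": "-", "-": "+"}.get(feat.strand, feat.strand)
    return FeatureRecord(
        seqid=iv.new_object, source=feat.source, ftype=feat.ftype,
        start=new_start, end=new_end, score=feat.score, strand=strand,
        phase=feat.phase, attributes=dict(feat.attributes),
    )


def liftover_features(features, lmap: LiftoverMap,
                      boundary: str = "error") -> list[FeatureRecord]:
    """Translate features through a liftover map.

    Features fully inside one mapped interval are translated (with
    strand flip on flipped intervals); lengths are preserved exactly.
    A feature spanning a mapped-interval boundary raises by default;
    with ``boundary="split"`` it is cut into per-interval parts that
    share the original ID attribute.  Features on unmapped (gap) bases
    raise.
    """
    if boundary not in ("error", "split"):
        raise ValueError("boundary must be 'error' or 'split'")
    index = lmap.by_old_object()
    out: list[FeatureRecord] = []
    for feat in features:
        ivs = index.get(feat.seqid, [])
        containing = [
            iv for iv in ivs
            if iv.old_start <= feat.start and feat.end <= iv.old_end
        ]
        if containing:
            out.append(_lift_one(feat, containing[0]))
            continue
        touching = [
            iv for iv in ivs
            if iv.old_start < feat.end and feat.start < iv.old_end
        ]
        if not touching:
            raise ValueError(
                f"feature [{feat.start}, {feat.end}) on {feat.seqid} "
                "lies on unmapped bases"
            )
        if boundary == "error":
            raise ValueError(
                f"feature [{feat.start}, {feat.end}) on {feat.seqid} "
                "spans a mapped-interval boundary"
            )
        covered = sum(
            min(feat.end, iv.old_end) - max(feat.start, iv.old_start)
            for iv in touching
        )
        if covered < feat.end - feat.start:
            raise ValueError(
                f"feature [{feat.start}, {feat.end}) on {feat.seqid} "
                "partially lies on unmapped bases"
            )
        for iv in touching:
            piece = FeatureRecord(
                seqid=feat.seqid, source=feat.source, ftype=feat.ftype,
                start=max(feat.start, iv.old_start),
                end=min(feat.end, iv.old_end),
                score=feat.score, strand=feat.strand, phase=feat.phase,
                attributes=dict(feat.attributes),
            )
            out.append(_lift_one(piece, iv))
    return out
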