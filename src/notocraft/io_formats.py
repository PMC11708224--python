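"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open.  GFF3 and AGP are 1-based
inclusive on disk; the conversion happens here, at the I/O boundary, and
nowhere else.  Every reader/writer pair is idempotent after one
normalization pass (``read(write(read(p))) == read(p)``).

Formats covered: FASTA (sequences and MSAs), GFF3 (GTF read-only),
AGP v2.1, the 3d-DNA ``.assembly`` dialect, BLAST-tab-like ortholog hit
tables and PAF-like overlap tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "FeatureRecord",
    "AgpRow",
    "AgpFile",
    "AssemblyMap",
    "OrthologHit",
    "Msa",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_gtf",
    "read_agp",
    "write_agp",
    "read_assembly_map",
    "write_assembly_map",
    "read_hits_table",
    "write_hits_table",
    "read_overlaps_table",
    "write_overlaps_table",
    "read_msa",
    "write_msa",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SeqRecord:
    """A named DNA sequence (contig, scaffold, chromosome or read)."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FeatureRecord:
    """One annotation feature (gene/mRNA/exon/CDS/repeat).

    ``start``/``end`` are 0-based half-open; GFF3 serialization converts
    back to 1-based inclusive.  ``attributes`` preserves key order.
    """

    seqid: str
    source: str
    ftype: str
    start: int
    end: int
    score: float | None = None
    strand: str = "."
    phase: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(
                f"invalid feature span [{self.start}, {self.end}) on {self.seqid}"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    @property
    def feature_id(self) -> str | None:
        return self.attributes.get("ID")


@dataclass
class AgpRow:
    """One AGP v2.1 row; component (W) or gap (N/U).

    ``object_beg``/``object_end`` and ``component_beg``/``component_end``
    are 0-based half-open internally.
    """

    object: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str  # W, N or U
    # W fields
    component_id: str | None = None
    component_beg: int | None = None
    component_end: int | None = None
    orientation: str | None = None
    # N/U fields
    gap_length: int | None = None
    gap_type: str | None = None
    linkage: str | None = None
    linkage_evidence: str | None = None

    KNOWN_GAP_TYPES = frozenset(
        {"scaffold", "contig", "centromere", "short_arm", "heterochromatin",
         "telomere", "repeat", "contamination"}
    )

    @property
    def is_gap(self) -> bool:
        return self.component_type in ("N", "U")

    @property
    def span(self) -> int:
        return self.object_end - self.object_beg

    def validate(self) -> None:
        if self.span <= 0:
            raise ValueError(f"empty AGP row span on {self.object} part {self.part_number}")
        if self.is_gap:
            if self.span != self.gap_length:
                raise ValueError(
                    f"gap row span {self.span} != gap_length {self.gap_length} "
                    f"({self.object} part {self.part_number})"
                )
        else:
            comp_span = self.component_end - self.component_beg
            if self.span != comp_span:
                raise ValueError(
                    f"object span {self.span} != component span {comp_span} "
                    f"({self.object} part {self.part_number}, {self.component_id})"
                )
            if self.orientation not in ("+", "-"):
                raise ValueError(
                    f"bad orientation {self.orientation!r} "
                    f"({self.object} part {self.part_number})"
                )


@dataclass
class AgpFile:
    """An ordered set of AGP rows grouped by object.

    Invariants (checked by :meth:`validate`): per-object rows tile the
    object contiguously from 0 with consecutive part numbers, and no W
    component id is used twice anywhere in the file.
    """

    rows: list[AgpRow]

    @property
    def objects(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.object, None)
        return list(seen)

    def object_rows(self, name: str) -> list[AgpRow]:
        return [r for r in self.rows if r.object == name]

    def object_length(self, name: str) -> int:
        rows = self.object_rows(name)
        if not rows:
            raise KeyError(name)
        return max(r.object_end for r in rows)

    def validate(self) -> None:
        used_components: set[str] = set()
        by_object: dict[str, list[AgpRow]] = {}
        for r in self.rows:
            r.validate()
            by_object.setdefault(r.object, []).append(r)
            if not r.is_gap:
                if r.component_id in used_components:
                    raise ValueError(f"component {r.component_id} used more than once")
                used_components.add(r.component_id)
        for obj, rows in by_object.items():
            pos = 0
            for i, r in enumerate(rows, start=1):
                if r.part_number != i:
                    raise ValueError(
                        f"object {obj}: part_number {r.part_number} at rank {i} "
                        "(parts must be consecutive from 1)"
                    )
                if r.object_beg != pos:
                    kind = "hole" if r.object_beg > pos else "overlap"
                    raise ValueError(
                        f"object {obj}: {kind} in tiling at part {r.part_number}"
                    )
                pos = r.object_end


@dataclass
class AssemblyMap:
    """A 3d-DNA ``.assembly`` map: declared contigs plus signed order.

    ``entries`` holds (name, internal id, length); ``scaffolds`` is a list
    of signed-id lists where a negative id means reverse orientation.
    """

    entries: list[tuple[str, int, int]]
    scaffolds: list[list[int]]

    def id_to_name(self) -> dict[int, str]:
        return {eid: name for name, eid, _ in self.entries}

    def id_to_length(self) -> dict[int, int]:
        return {eid: length for _, eid, length in self.entries}

    def validate(self) -> None:
        declared = {eid for _, eid, _ in self.entries}
        if len(declared) != len(self.entries):
            raise ValueError("duplicate internal id in .assembly header")
        seen: set[int] = set()
        for scaffold in self.scaffolds:
            for sid in scaffold:
                if abs(sid) not in declared:
                    raise ValueError(f"scaffold references undeclared id {abs(sid)}")
                if abs(sid) in seen:
                    raise ValueError(f"id {abs(sid)} used more than once")
                seen.add(abs(sid))


@dataclass
class OrthologHit:
    """One directed cross-genome similarity hit between two genes."""

    query_gene: str
    subject_gene: str
    bitscore: float
    identity_pct: float

    def __post_init__(self) -> None:
        if not self.query_gene or not self.subject_gene:
            raise ValueError("empty gene id in ortholog hit")


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length rows over DNA + '-'."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate taxon name in MSA")
        if self.rows and len({len(r) for r in self.rows}) > 1:
            raise ValueError("unequal row lengths in MSA")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects (uppercased).

    Raises ``ValueError`` on a duplicate id; warns on (and keeps) empty
    sequences.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        seq = str(rec.seq).upper()
        if not seq:
            warnings.warn(f"empty sequence for id {rec.id}", stacklevel=2)
        records.append(SeqRecord(id=rec.id, sequence=seq, description=desc))
    return records


def write_fasta(records, path, line_width: int = 60) -> None:
    """Write records with fixed-width sequence lines (byte-stable)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i:i + line_width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 / GTF
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"malformed GFF3 attribute {part!r}")
        key, value = part.split("=", 1)
        attrs[key] = value
    return attrs


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            raise ValueError(f"malformed GTF attribute {part!r}")
        key, value = part.split(" ", 1)
        attrs[key] = value.strip().strip('"')
    return attrs


def _read_feature_table(path, attr_parser) -> list[FeatureRecord]:
    features: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"line {lineno}: expected 9 columns, got {len(cols)}")
            seqid, source, ftype, start_s, end_s, score_s, strand, phase, attr_s = cols
            try:
                start = int(start_s)
                end = int(end_s)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinates") from exc
            if start > end:
                raise ValueError(f"line {lineno}: start {start} > end {end}")
            if start < 1:
                raise ValueError(f"line {lineno}: start {start} < 1")
            score = None if score_s == "." else float(score_s)
            features.append(
                FeatureRecord(
                    seqid=seqid,
                    source=source,
                    ftype=ftype,
                    start=start - 1,  # to 0-based half-open
                    end=end,
                    score=score,
                    strand=strand,
                    phase=phase,
                    attributes=attr_parser(attr_s),
                )
            )
    return features


def read_gff3(path) -> list[FeatureRecord]:
    """Read a 9-column GFF3 file; attribute order is preserved."""
    return _read_feature_table(path, _parse_gff3_attributes)


def read_gtf(path) -> list[FeatureRecord]:
    """Read a GTF file into the GFF3 feature model (read-only).

    GTF ``gene_id``/``transcript_id`` attributes are re-keyed so that each
    feature carries a GFF3-style ``ID`` (the transcript id when present,
    else the gene id) and, for transcript-level features, a ``Parent``.
    """
    features = _read_feature_table(path, _parse_gtf_attributes)
    for feat in features:
        attrs = feat.attributes
        gene_id = attrs.get("gene_id")
        tx_id = attrs.get("transcript_id")
        rekeyed: dict[str, str] = {}
        if tx_id and feat.ftype != "gene":
            rekeyed["ID"] = tx_id
            if gene_id:
                rekeyed["Parent"] = gene_id
        elif gene_id:
            rekeyed["ID"] = gene_id
        for k, v in attrs.items():
            if k not in ("gene_id", "transcript_id"):
                rekeyed[k] = v
        feat.attributes = rekeyed
    return features


def write_gff3(features, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            score = "." if feat.score is None else f"{feat.score:g}"
            attrs = ";".join(f"{k}={v}" for k, v in feat.attributes.items())
            fh.write(
                "\t".join(
                    (
                        feat.seqid,
                        feat.source,
                        feat.ftype,
                        str(feat.start + 1),  # back to 1-based inclusive
                        str(feat.end),
                        score,
                        feat.strand,
                        feat.phase,
                        attrs or ".",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# AGP v2.1
# ---------------------------------------------------------------------------

def read_agp(path) -> AgpFile:
    """Read an AGP v2.1 file; the tiling invariant is validated."""
    rows: list[AgpRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"line {lineno}: expected 9 AGP columns, got {len(cols)}")
            obj, beg_s, end_s, part_s, ctype = cols[:5]
            try:
                beg, end, part = int(beg_s), int(end_s), int(part_s)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer field") from exc
            if ctype in ("N", "U"):
                gap_type = cols[6]
                if gap_type not in AgpRow.KNOWN_GAP_TYPES:
                    warnings.warn(
                        f"line {lineno}: unknown gap_type {gap_type!r}", stacklevel=2
                    )
                row = AgpRow(
                    object=obj,
                    object_beg=beg - 1,
                    object_end=end,
                    part_number=part,
                    component_type=ctype,
                    gap_length=int(cols[5]),
                    gap_type=gap_type,
                    linkage=cols[7],
                    linkage_evidence=cols[8],
                )
            else:
                row = AgpRow(
                    object=obj,
                    object_beg=beg - 1,
                    object_end=end,
                    part_number=part,
                    component_type=ctype,
                    component_id=cols[5],
                    component_beg=int(cols[6]) - 1,
                    component_end=int(cols[7]),
                    orientation=cols[8],
                )
            rows.append(row)
    agp = AgpFile(rows=rows)
    agp.validate()
    return agp


def write_agp(agp: AgpFile, path) -> None:
    agp.validate()
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for r in agp.rows:
            if r.is_gap:
                tail = (str(r.gap_length), r.gap_type, r.linkage, r.linkage_evidence)
            else:
                tail = (
                    r.component_id,
                    str(r.component_beg + 1),
                    str(r.component_end),
                    r.orientation,
                )
            fh.write(
                "\t".join(
                    (
                        r.object,
                        str(r.object_beg + 1),
                        str(r.object_end),
                        str(r.part_number),
                        r.component_type,
                        *tail,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# 3d-DNA ".assembly"
# ---------------------------------------------------------------------------

def read_assembly_map(path) -> AssemblyMap:
    """Parse the 3d-DNA ``.assembly`` dialect.

    Header lines are ``>name id length``; the remaining lines are
    whitespace-separated signed ids, one scaffold per line.  Both pre- and
    post-review name forms are accepted (names are free strings).
    """
    entries: list[tuple[str, int, int]] = []
    scaffolds: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                parts = line[1:].split()
                if len(parts) != 3:
                    raise ValueError(f"line {lineno}: malformed .assembly header")
                name, eid_s, length_s = parts
                entries.append((name, int(eid_s), int(length_s)))
            else:
                try:
                    ids = [int(tok) for tok in line.split()]
                except ValueError as exc:
                    raise ValueError(f"line {lineno}: non-integer id") from exc
                scaffolds.append(ids)
    amap = AssemblyMap(entries=entries, scaffolds=scaffolds)
    amap.validate()
    return amap


def write_assembly_map(amap: AssemblyMap, path) -> None:
    amap.validate()
    with open(path, "w") as fh:
        for name, eid, length in amap.entries:
            fh.write(f">{name} {eid} {length}\n")
        for scaffold in amap.scaffolds:
            fh.write(" ".join(str(sid) for sid in scaffold) + "\n")


# ---------------------------------------------------------------------------
# tabular records
# ---------------------------------------------------------------------------

def read_hits_table(path) -> list[OrthologHit]:
    """Read a BLAST-tab-like TSV: query, subject, bitscore, identity_pct."""
    hits: list[OrthologHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ValueError(f"line {lineno}: expected 4 columns, got {len(cols)}")
            try:
                hits.append(
                    OrthologHit(cols[0], cols[1], float(cols[2]), float(cols[3]))
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    return hits


def write_hits_table(hits, path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.query_gene}\t{h.subject_gene}\t{h.bitscore:g}\t{h.identity_pct:g}\n")


def read_overlaps_table(path):
    """Read a PAF-like 12-column TSV into :class:`notocraft.read_qc.Overlap`.

    PAF spans are already 0-based half-open, matching the internal
    convention, so coordinates pass through unchanged.
    """
    from .read_qc import Overlap

    overlaps = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"line {lineno}: expected 12 columns, got {len(cols)}")
            try:
                overlaps.append(
                    Overlap(
                        qname=cols[0],
                        qlen=int(cols[1]),
                        qstart=int(cols[2]),
                        qend=int(cols[3]),
                        strand=cols[4],
                        tname=cols[5],
                        tlen=int(cols[6]),
                        tstart=int(cols[7]),
                        tend=int(cols[8]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    return overlaps


def write_overlaps_table(overlaps, path) -> None:
    """Write overlaps as 12-column PAF-like TSV (idealized: matches = span)."""
    with open(path, "w") as fh:
        for ov in overlaps:
            span = ov.qend - ov.qstart
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        ov.qname, ov.qlen, ov.qstart, ov.qend, ov.strand,
                        ov.tname, ov.tlen, ov.tstart, ov.tend,
                        span, span, 255,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# MSA FASTA
# ---------------------------------------------------------------------------

def read_msa(path) -> Msa:
    """Read an aligned FASTA file (rows may contain '-' gaps)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    names = [r.id for r in records]
    rows = [str(r.seq).upper() for r in records]
    return Msa(names=names, rows=rows)


def write_msa(msa: Msa, path, line_width: int = 60) -> None:
    write_fasta(
        [SeqRecord(id=n, sequence=r) for n, r in zip(msa.names, msa.rows)],
        path,
        line_width=line_width,
    )
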