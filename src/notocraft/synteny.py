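"""Conserved-synteny engine plus supermatrix/MSA utilities.

The engine follows the classic two-genome recipe: reciprocal best hits
(RBH) define putative orthologs; a sliding window over each A-genome
chromosome grows clusters of consecutive orthologs whose partners share
one B-genome chromosome; cluster geometry then defines chromosome
orthology and exposes rearrangements —

* **fusion**: one A chromosome whose clustered genes split between two
  B chromosomes occupying disjoint A intervals;
* **inversion**: an interior run of ortholog pairs whose B positions
  step in the direction opposite to both flanking runs;
* **translocation**: a cluster touching a chromosome end whose B
  partner is not that chromosome's assigned ortholog; reciprocal
  terminal translocations pair into one end-swap call.

The MSA helpers (gap-column filtering, concatenation + partitioning,
ortholog-id remapping) prepare supermatrix input for phylogenomic
inference; the inference itself is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import Msa, OrthologHit

__all__ = [
    "OrthologPair",
    "SyntenyCluster",
    "RearrangementCall",
    "ClusterParams",
    "reciprocal_best_hits",
    "locate_pairs",
    "build_synteny_clusters",
    "assign_chromosome_orthology",
    "detect_rearrangements",
    "filter_gappy_columns",
    "concat_and_partition",
    "remap_gene_ids",
]


@dataclass
class OrthologPair:
    """One RBH ortholog pair, optionally located on both genomes."""

    gene_a: str
    gene_b: str
    bitscore: float = 0.0
    chrom_a: str | None = None
    pos_a: float | None = None
    chrom_b: str | None = None
    pos_b: float | None = None


@dataclass
class SyntenyCluster:
    """A run of positionally coherent ortholog pairs anchoring two
    chromosomes.  ``orientation_sign`` is +1/-1 by the sign of the
    Spearman rank correlation of member positions, or "mixed" when
    |rho| < 0.5."""

    id: int
    chrom_a: str
    chrom_b: str
    members: list[OrthologPair]
    span_a: tuple[float, float]
    span_b: tuple[float, float]
    orientation_sign: object  # +1 | -1 | "mixed"


@dataclass
class RearrangementCall:
    kind: str  # fusion | inversion | translocation
    chroms: tuple
    intervals: list
    support: int
    note: str = ""


@dataclass
class ClusterParams:
    window_size: int = 5
    max_gap: int = 3
    min_cluster_size: int = 5
    fusion_min_fraction: float = 0.2
    terminal_fraction: float = 0.2
    mixed_rho: float = 0.5

    def __post_init__(self) -> None:
        if min(self.window_size, self.max_gap, self.min_cluster_size) < 0 or \
                self.window_size < 1 or self.min_cluster_size < 1:
            raise ValueError("window/cluster params must be positive")
        if not (0 < self.fusion_min_fraction <= 0.5):
            raise ValueError("fusion_min_fraction must be in (0, 0.5]")


# ---------------------------------------------------------------------------
# RBH
# ---------------------------------------------------------------------------

def _best_hits(hits) -> dict[str, OrthologHit]:
    """Deterministic best hit per query: bitscore, then identity, then
    lexicographically smaller subject id."""
    best: dict[str, OrthologHit] = {}
    for h in hits:
        cur = best.get(h.query_gene)
        if cur is None:
            best[h.query_gene] = h
            continue
        key = (h.bitscore, h.identity_pct)
        cur_key = (cur.bitscore, cur.identity_pct)
        if key > cur_key or (key == cur_key and h.subject_gene < cur.subject_gene):
            best[h.query_gene] = h
    return best


def reciprocal_best_hits(hits_ab, hits_ba) -> list[OrthologPair]:
    """Ortholog pairs (a, b) where each is the other's best hit.

    The output is a bijection on its support: one pair per gene_a and
    per gene_b.
    """
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = []
    for a in sorted(best_ab):
        hit = best_ab[a]
        b = hit.subject_gene
        back = best_ba.get(b)
        if back is not None and back.subject_gene == a:
            pairs.append(OrthologPair(gene_a=a, gene_b=b, bitscore=hit.bitscore))
    assert len({p.gene_b for p in pairs}) == len(pairs), "RBH not bijective"
    return pairs


def locate_pairs(pairs, annotation_a, annotation_b) -> list[OrthologPair]:
    """Fill chromosome/midpoint positions from two gene annotations."""
    def gene_index(annotation):
        idx = {}
        for f in annotation:
            if f.ftype == "gene" and f.feature_id:
                idx[f.feature_id] = (f.seqid, f.midpoint)
        return idx

    idx_a, idx_b = gene_index(annotation_a), gene_index(annotation_b)
    located = []
    for p in pairs:
        if p.gene_a not in idx_a:
            raise ValueError(f"unknown gene id {p.gene_a} in genome A annotation")
        if p.gene_b not in idx_b:
            raise ValueError(f"unknown gene id {p.gene_b} in genome B annotation")
        (ca, pa), (cb, pb) = idx_a[p.gene_a], idx_b[p.gene_b]
        located.append(
            OrthologPair(p.gene_a, p.gene_b, p.bitscore, ca, pa, cb, pb)
        )
    return located


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

def _orientation_sign(members, mixed_rho: float):
    if len(members) < 2:
        return "mixed"
    pa = [m.pos_a for m in members]
    pb = [m.pos_b for m in members]
    if len(set(pb)) < 2 or len(set(pa)) < 2:
        return "mixed"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(pa, pb).statistic
    if not np.isfinite(rho) or abs(rho) < mixed_rho:
        return "mixed"
    return 1 if rho > 0 else -1


def build_synteny_clusters(pairs, annotation_a=None, annotation_b=None,
                           params: ClusterParams | None = None) -> list[SyntenyCluster]:
    """Grow synteny clusters along each A chromosome.

    Pairs may arrive pre-located; otherwise both annotations must be
    given.  Along each A chromosome (paired genes in positional order),
    pairs hitting one B chromosome chain together while at most
    ``max_gap`` consecutive interloper pairs (partners elsewhere)
    intervene; a chain is a cluster when it contains a seed run of
    ``window_size`` consecutive paired genes on that B chromosome and
    has at least ``min_cluster_size`` members.
    """
    if params is None:
        params = ClusterParams()
    if annotation_a is not None:
        pairs = locate_pairs(pairs, annotation_a, annotation_b)
    pairs = [p for p in pairs if p.chrom_a is not None]

    by_chrom_a: dict[str, list[OrthologPair]] = {}
    for p in pairs:
        by_chrom_a.setdefault(p.chrom_a, []).append(p)

    clusters: list[SyntenyCluster] = []
    next_id = 1
    for chrom_a in sorted(by_chrom_a):
        ordered = sorted(by_chrom_a[chrom_a], key=lambda p: (p.pos_a, p.gene_a))
        targets = sorted({p.chrom_b for p in ordered})
        for chrom_b in targets:
            idxs = [i for i, p in enumerate(ordered) if p.chrom_b == chrom_b]
            # chain indices allowing <= max_gap interlopers
            chains: list[list[int]] = []
            current = [idxs[0]]
            for i in idxs[1:]:
                if i - current[-1] - 1 <= params.max_gap:
                    current.append(i)
                else:
                    chains.append(current)
                    current = [i]
            chains.append(current)
            for chain in chains:
                if len(chain) < params.min_cluster_size:
                    continue
                # seed run: window_size strictly consecutive paired genes
                run = best_run = 1
                for a, b in zip(chain, chain[1:]):
                    run = run + 1 if b == a + 1 else 1
                    best_run = max(best_run, run)
                if best_run < params.window_size:
                    continue
                members = [ordered[i] for i in chain]
                clusters.append(
                    SyntenyCluster(
                        id=next_id,
                        chrom_a=chrom_a,
                        chrom_b=chrom_b,
                        members=members,
                        span_a=(min(m.pos_a for m in members),
                                max(m.pos_a for m in members)),
                        span_b=(min(m.pos_b for m in members),
                                max(m.pos_b for m in members)),
                        orientation_sign=_orientation_sign(members, params.mixed_rho),
                    )
                )
                next_id += 1
    return clusters


# ---------------------------------------------------------------------------
# chromosome orthology + rearrangements
# ---------------------------------------------------------------------------

def assign_chromosome_orthology(clusters, chromosomes_a=None,
                                params: ClusterParams | None = None
                                ) -> dict[str, list[str]]:
    """Name each A chromosome by its plurality B partner.

    Returns ``chrom_a -> [primary]`` normally, ``[primary, secondary]``
    when a second B chromosome holds >= ``fusion_min_fraction`` of the
    clustered genes over an A interval disjoint from the primary's (a
    fusion candidate), and ``[]`` for chromosomes without clustered
    genes.
    """
    if params is None:
        params = ClusterParams()
    by_a: dict[str, list[SyntenyCluster]] = {}
    for c in clusters:
        by_a.setdefault(c.chrom_a, []).append(c)
    chroms = sorted(set(by_a) | set(chromosomes_a or []))
    naming: dict[str, list[str]] = {}
    for chrom_a in chroms:
        cl = by_a.get(chrom_a, [])
        if not cl:
            naming[chrom_a] = []
            continue
        counts: dict[str, int] = {}
        spans: dict[str, tuple[float, float]] = {}
        for c in cl:
            counts[c.chrom_b] = counts.get(c.chrom_b, 0) + len(c.members)
            lo, hi = spans.get(c.chrom_b, (c.span_a[0], c.span_a[1]))
            spans[c.chrom_b] = (min(lo, c.span_a[0]), max(hi, c.span_a[1]))
        total = sum(counts.values())
        primary = max(sorted(counts), key=lambda b: counts[b])
        assigned = [primary]
        for b in sorted(counts):
            if b == primary or counts[b] < params.fusion_min_fraction * total:
                continue
            lo1, hi1 = spans[primary]
            lo2, hi2 = spans[b]
            if hi2 < lo1 or hi1 < lo2:  # disjoint A intervals
                assigned.append(b)
                break
        naming[chrom_a] = assigned
    return naming


def _inversion_calls(chrom_a, chrom_b, members, params) -> list[RearrangementCall]:
    """Interior opposite-direction runs within one chromosome-pair chain."""
    ordered = sorted(members, key=lambda m: (m.pos_a, m.gene_a))
    signs = []
    for m1, m2 in zip(ordered, ordered[1:]):
        d = m2.pos_b - m1.pos_b
        signs.append(0 if d == 0 else (1 if d > 0 else -1))
    # maximal constant-sign runs over the steps (zero steps extend the run)
    runs: list[tuple[int, int, int]] = []  # (sign, first_step, last_step)
    for i, s in enumerate(signs):
        if runs and (s == runs[-1][0] or s == 0):
            runs[-1] = (runs[-1][0], runs[-1][1], i)
        elif runs and runs[-1][0] == 0:
            runs[-1] = (s, runs[-1][1], i)
        else:
            runs.append((s, i, i))
    calls = []
    for r in range(1, len(runs) - 1):
        sign, first, last = runs[r]
        n_pairs = last - first + 2
        if sign == 0 or n_pairs < params.min_cluster_size:
            continue
        prev_sign, next_sign = runs[r - 1][0], runs[r + 1][0]
        if prev_sign == next_sign and prev_sign == -sign:
            block = ordered[first:last + 2]
            calls.append(
                RearrangementCall(
                    kind="inversion",
                    chroms=(chrom_a, chrom_b),
                    intervals=[(chrom_a, block[0].pos_a, block[-1].pos_a)],
                    support=n_pairs,
                    note=f"genes {block[0].gene_a}..{block[-1].gene_a}",
                )
            )
    return calls


def detect_rearrangements(clusters, naming, params: ClusterParams | None = None,
                          chrom_lengths_a: dict[str, int] | None = None
                          ) -> list[RearrangementCall]:
    """Fusion, inversion and translocation calls from cluster geometry.

    ``chrom_lengths_a`` sharpens the terminal-region test; without it
    the farthest clustered position on each A chromosome stands in for
    its length.  Deterministic for fixed inputs.
    """
    if params is None:
        params = ClusterParams()
    calls: list[RearrangementCall] = []

    by_a: dict[str, list[SyntenyCluster]] = {}
    for c in clusters:
        by_a.setdefault(c.chrom_a, []).append(c)

    # fusions
    for chrom_a in sorted(naming):
        assigned = naming[chrom_a]
        if len(assigned) >= 2:
            support = sum(len(c.members) for c in by_a.get(chrom_a, [])
                          if c.chrom_b in assigned)
            intervals = [
                (chrom_a, min(c.span_a[0] for c in by_a[chrom_a] if c.chrom_b == b),
                 max(c.span_a[1] for c in by_a[chrom_a] if c.chrom_b == b))
                for b in assigned
            ]
            calls.append(
                RearrangementCall(
                    kind="fusion",
                    chroms=(chrom_a, *assigned),
                    intervals=intervals,
                    support=support,
                    note=f"{chrom_a} spans orthologs of {' and '.join(assigned)}",
                )
            )

    # inversions: per chromosome pair participating in the naming
    for chrom_a in sorted(by_a):
        assigned = set(naming.get(chrom_a, []))
        for chrom_b in sorted({c.chrom_b for c in by_a[chrom_a]}):
            if chrom_b not in assigned:
                continue
            members = [m for c in by_a[chrom_a] if c.chrom_b == chrom_b
                       for m in c.members]
            calls.extend(_inversion_calls(chrom_a, chrom_b, members, params))

    # translocations
    terminal: list[tuple[str, str, SyntenyCluster]] = []
    for chrom_a in sorted(by_a):
        assigned = set(naming.get(chrom_a, []))
        if not assigned:
            continue
        if chrom_lengths_a and chrom_a in chrom_lengths_a:
            length = chrom_lengths_a[chrom_a]
        else:
            length = max(c.span_a[1] for c in by_a[chrom_a])
        for c in by_a[chrom_a]:
            if c.chrom_b in assigned:
                continue
            t = params.terminal_fraction * length
            if c.span_a[0] < t or c.span_a[1] > length - t:
                terminal.append((chrom_a, c.chrom_b, c))

    primary = {a: (bs[0] if bs else None) for a, bs in naming.items()}
    used: set[int] = set()
    for i, (ax, bx, cx) in enumerate(terminal):
        if cx.id in used:
            continue
        partner = None
        for ay, by, cy in terminal[i + 1:]:
            if cy.id in used:
                continue
            # X's stray cluster maps to Y's ortholog and vice versa
            if primary.get(ay) == bx and primary.get(ax) == by:
                partner = (ay, by, cy)
                break
        if partner:
            ay, by, cy = partner
            used.update((cx.id, cy.id))
            calls.append(
                RearrangementCall(
                    kind="translocation",
                    chroms=(ax, ay),
                    intervals=[(ax, *cx.span_a), (ay, *cy.span_a)],
                    support=len(cx.members) + len(cy.members),
                    note=f"end swap between {ax} and {ay}",
                )
            )
        else:
            used.add(cx.id)
            calls.append(
                RearrangementCall(
                    kind="translocation",
                    chroms=(ax, bx),
                    intervals=[(ax, *cx.span_a)],
                    support=len(cx.members),
                    note=f"terminal cluster of {ax} maps to {bx}",
                )
            )
    return calls


# ---------------------------------------------------------------------------
# MSA utilities
# ---------------------------------------------------------------------------

def filter_gappy_columns(msa: Msa, max_gap_rate: float = 0.2) -> Msa:
    """Remove columns whose gap fraction exceeds ``max_gap_rate``."""
    if not msa.rows:
        return Msa(names=list(msa.names), rows=list(msa.rows))
    n = len(msa.rows)
    keep = [
        j for j in range(msa.n_columns)
        if sum(1 for row in msa.rows if row[j] == "-") / n <= max_gap_rate
    ]
    if not keep:
        warnings.warn("all columns filtered out", stacklevel=2)
    rows = ["".join(row[j] for j in keep) for row in msa.rows]
    return Msa(names=list(msa.names), rows=rows)


def concat_and_partition(msas) -> tuple[Msa, list[tuple[str, int, int]]]:
    """Concatenate named MSAs into a supermatrix plus a partition table.

    ``msas`` is an ordered (name, Msa) sequence (or dict).  Taxa are the
    union over all alignments in first-appearance order; a taxon missing
    from an alignment is padded with all-gap rows.  The partition table
    lists 1-based inclusive column ranges per source alignment.
    """
    items = list(msas.items()) if isinstance(msas, dict) else list(msas)
    taxa: list[str] = []
    for _, msa in items:
        for name in msa.names:
            if name not in taxa:
                taxa.append(name)
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: list[tuple[str, int, int]] = []
    col = 0
    for label, msa in items:
        width = msa.n_columns
        rows = dict(zip(msa.names, msa.rows))
        for t in taxa:
            chunks[t].append(rows.get(t, "-" * width))
        partitions.append((label, col + 1, col + width))
        col += width
    supermatrix = Msa(names=taxa, rows=["".join(chunks[t]) for t in taxa])
    return supermatrix, partitions


def remap_gene_ids(ids, mapping) -> tuple[list[str], list[str]]:
    """Replace ids through a two-column map; report unmapped ids.

    ``mapping`` is a dict or (old, new) row list.  Conflicting duplicate
    rows (one-to-many for some id) raise, naming the id.  Unmapped ids
    are kept in place and listed in the second return value.
    """
    if not isinstance(mapping, dict):
        table: dict[str, str] = {}
        for old, new in mapping:
            if old in table and table[old] != new:
                raise ValueError(f"one-to-many mapping for id {old}")
            table[old] = new
        mapping = table
    remapped: list[str] = []
    unmapped: list[str] = []
    for gid in ids:
        if gid in mapping:
            remapped.append(mapping[gid])
        else:
            remapped.append(gid)
            unmapped.append(gid)
    return remapped, unmapped
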