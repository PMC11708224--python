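"""Seeded generators for genomes, annotations, repeat families,
rearranged ortholog genomes, and long-read sets with planted chimeras.

These emulate the statistical structure the downstream stages assume in
a chromosome-scale fish genome project, scaled to desk size:

* genomes whose protein-coding genes concentrate in chromosome centers
  and whose interspersed repeats concentrate at the terminal ends
  (Beta-shaped placement laws);
* repeat families with a recent-expansion divergence profile, emitted as
  copy-vs-consensus alignments mutated at a 2:1 transition:transversion
  ratio so that Kimura landscapes can be recovered;
* orthologous genome pairs with planted fusions, inversions and
  terminal-end swaps, plus a truth log for parameter-recovery tests;
* long-read sets with log-normal lengths and planted chimeric reads
  (two fragments from loci >= 100 kb apart), together with idealized
  all-vs-all overlaps in which chimeric junctions receive no spanning
  overlaps.

Every generator is a pure function of its seed: identical inputs yield
identical bytes.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .io_formats import AssemblyMap, FeatureRecord, SeqRecord
from .read_qc import Overlap

__all__ = [
    "GenomeSpec",
    "RepeatAgeProfile",
    "RepeatCopyAlignment",
    "RearrangementPlan",
    "ReadSimSpec",
    "default_age_profile",
    "generate_genome",
    "generate_repeat_copies",
    "write_repeat_copies",
    "read_repeat_copies",
    "apply_rearrangement_plan",
    "random_rearrangement_plan",
    "simulate_long_reads",
    "make_overlaps",
    "export_assembly_map",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    """Parameters of one synthetic genome.

    The defaults emulate a 23-chromosome notothenioid-like karyotype at
    roughly 1:40 scale: ~1 Mbp chromosomes carrying ~100 genes each,
    with center-biased genes and terminal-biased repeats.  A bias of 0
    means uniform placement; gene placement uses Beta(1+b, 1+b) and
    repeat placement a symmetric mixture of Beta(1, 1+b)/Beta(1+b, 1).
    """

    n_chromosomes: int = 23
    chrom_length_range: tuple[int, int] = (900_000, 1_600_000)
    gene_count_per_chrom: int = 100
    gene_center_bias: float = 2.0
    repeat_terminal_bias: float = 3.0
    repeat_count_per_chrom: int = 150
    gene_length: int = 2_000
    repeat_length: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.chrom_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid chrom_length_range")
        if not (math.isfinite(self.gene_center_bias)
                and math.isfinite(self.repeat_terminal_bias)):
            raise ValueError("biases must be finite")
        if self.gene_center_bias < 0 or self.repeat_terminal_bias < 0:
            raise ValueError("biases must be >= 0")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _ALPHABET[rng.integers(0, 4, size=length)].tobytes().decode()


def _place_features(rng, length, count, feat_len, draw_midpoint, label) -> list[tuple[int, int]]:
    """Draw non-overlapping (start, end) intervals via rejection sampling."""
    if count * feat_len > 0.6 * length:
        raise ValueError(
            f"infeasible packing: {count} x {feat_len} bp {label}s "
            f"on a {length} bp chromosome"
        )
    placed: list[tuple[int, int]] = []
    starts: list[int] = []
    tries = 0
    limit = 200 * count + 1000
    while len(placed) < count:
        tries += 1
        if tries > limit:
            raise ValueError(f"infeasible packing of {label}s after {limit} draws")
        mid = draw_midpoint()
        start = int(round(mid - feat_len / 2))
        start = max(0, min(start, length - feat_len))
        end = start + feat_len
        i = bisect.bisect_left(starts, start)
        if i > 0 and placed[i - 1][1] > start:
            continue
        if i < len(placed) and placed[i][0] < end:
            continue
        starts.insert(i, start)
        placed.insert(i, (start, end))
    return placed


_REPEAT_CLASSES = ("DNA", "LINE", "SINE", "LTR", "Unclassified")


def generate_genome(spec: GenomeSpec) -> tuple[list[SeqRecord], list[FeatureRecord]]:
    """Generate a genome plus its gene/repeat annotation.

    Gene midpoints are drawn from Beta(1+b, 1+b) scaled to the
    chromosome (center bias); repeat midpoints from an equal mixture of
    Beta(1, 1+b) and Beta(1+b, 1) (symmetric terminal bias).  Features
    are non-overlapping within type.  Gene ids (``chrN_gXXXX``) are
    stable identifiers reused by :func:`apply_rearrangement_plan` so
    that genome pairs share an orthology.
    """
    rng = np.random.default_rng(spec.seed)
    ag = 1 + spec.gene_center_bias
    br = 1 + spec.repeat_terminal_bias
    genome: list[SeqRecord] = []
    features: list[FeatureRecord] = []
    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        length = int(rng.integers(spec.chrom_length_range[0],
                                  spec.chrom_length_range[1] + 1))
        genome.append(SeqRecord(id=chrom, sequence=_random_sequence(rng, length)))

        gene_spans = _place_features(
            rng, length, spec.gene_count_per_chrom, spec.gene_length,
            lambda: rng.beta(ag, ag) * length, "gene",
        )
        for gi, (start, end) in enumerate(gene_spans):
            features.append(
                FeatureRecord(
                    seqid=chrom, source="notocraft_sim", ftype="gene",
                    start=start, end=end,
                    strand="+" if rng.integers(0, 2) else "-",
                    attributes={"ID": f"{chrom}_g{gi + 1:04d}"},
                )
            )

        def repeat_mid():
            if rng.integers(0, 2):
                return rng.beta(1, br) * length
            return rng.beta(br, 1) * length

        repeat_spans = _place_features(
            rng, length, spec.repeat_count_per_chrom, spec.repeat_length,
            repeat_mid, "repeat",
        )
        for ri, (start, end) in enumerate(repeat_spans):
            features.append(
                FeatureRecord(
                    seqid=chrom, source="notocraft_sim", ftype="repeat",
                    start=start, end=end, strand=".",
                    attributes={
                        "ID": f"{chrom}_r{ri + 1:04d}",
                        "class": _REPEAT_CLASSES[int(rng.integers(0, len(_REPEAT_CLASSES)))],
                    },
                )
            )
    features.sort(key=lambda f: (f.seqid, f.start, f.ftype))
    return genome, features


# ---------------------------------------------------------------------------
# repeat family copies
# ---------------------------------------------------------------------------

@dataclass
class RepeatAgeProfile:
    """Mixture weights over 1%-wide Kimura-divergence bins per copy.

    The default profile is recent-expansion-shaped: an exponential decay
    over bins 0..29% so most copies sit at low divergence.
    """

    family_classes: tuple[str, ...] = _REPEAT_CLASSES
    copies_per_family: int = 200
    divergence_weights: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if self.divergence_weights is None:
            self.divergence_weights = default_age_profile()
        total = sum(self.divergence_weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            self.divergence_weights = {
                b: w / total for b, w in self.divergence_weights.items()
            }


def default_age_profile(n_bins: int = 30, scale: float = 6.0) -> dict[int, float]:
    weights = {b: math.exp(-b / scale) for b in range(n_bins)}
    total = sum(weights.values())
    return {b: w / total for b, w in weights.items()}


@dataclass
class RepeatCopyAlignment:
    class_label: str
    copy_id: str
    aligned_copy: str
    aligned_consensus: str


def _solve_q_for_k(k_target: float) -> float:
    """Q such that K2P(P=2Q, Q) == k_target (2:1 ts:tv ratio)."""
    if k_target <= 0:
        return 0.0

    def f(q):
        return -0.5 * math.log((1 - 5 * q) * math.sqrt(1 - 2 * q)) - k_target

    return brentq(f, 0.0, 0.2 - 1e-9)


def generate_repeat_copies(consensus_length: int, profile: RepeatAgeProfile,
                           seed: int = 0) -> list[RepeatCopyAlignment]:
    """Mutate per-class consensus sequences into aligned copies.

    Each copy draws a divergence bin from the profile, targets a Kimura
    distance uniform within the interior of that bin, and is mutated at
    distinct sites with transitions and transversions in a 2:1 ratio so
    the realized (P, Q, K) lands in the drawn bin.  No indels; the
    alignment is the (copy, consensus) string pair itself.
    """
    if consensus_length < 50:
        raise ValueError("consensus_length must be >= 50")
    rng = np.random.default_rng(seed)
    bins = sorted(profile.divergence_weights)
    weights = np.array([profile.divergence_weights[b] for b in bins])
    out: list[RepeatCopyAlignment] = []
    for label in profile.family_classes:
        consensus = _random_sequence(rng, consensus_length)
        for i in range(profile.copies_per_family):
            b = bins[int(rng.choice(len(bins), p=weights))]
            # bin 0 stands for "no divergence yet": the copy is an exact
            # duplicate of the consensus.  Other bins aim at the bin
            # interior so site-count rounding rarely crosses a bin edge.
            k_target = 0.0 if b == 0 else (b + rng.uniform(0.2, 0.8)) / 100
            q = _solve_q_for_k(k_target)
            p = 2 * q
            n_tv = int(round(q * consensus_length))
            n_ts = int(round(p * consensus_length))
            sites = rng.choice(consensus_length, size=n_ts + n_tv, replace=False)
            copy = list(consensus)
            for site in sites[:n_ts]:
                copy[site] = _TRANSITION[copy[site]]
            for site in sites[n_ts:]:
                choices = _TRANSVERSIONS[copy[site]]
                copy[site] = choices[int(rng.integers(0, 2))]
            out.append(
                RepeatCopyAlignment(
                    class_label=label,
                    copy_id=f"{label}_c{i + 1:05d}",
                    aligned_copy="".join(copy),
                    aligned_consensus=consensus,
                )
            )
    return out


def write_repeat_copies(copies, path) -> None:
    """TSV: class, copy_id, aligned_copy, aligned_consensus."""
    with open(path, "w") as fh:
        for c in copies:
            fh.write(f"{c.class_label}\t{c.copy_id}\t{c.aligned_copy}\t{c.aligned_consensus}\n")


def read_repeat_copies(path) -> list[RepeatCopyAlignment]:
    copies = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ValueError(f"line {lineno}: expected 4 columns")
            copies.append(RepeatCopyAlignment(*cols))
    return copies


# ---------------------------------------------------------------------------
# rearrangement plans
# ---------------------------------------------------------------------------

@dataclass
class RearrangementPlan:
    """Planted structural edits: fusions, inversions, terminal swaps.

    ``fusions``: (chromA, chromB, fused_name); ``inversions``:
    (chrom, start, end) 0-based half-open; ``terminal_translocations``:
    ((chromX, endX), (chromY, endY), swap_length) with end flags
    "left"/"right".
    """

    fusions: list[tuple[str, str, str]] = field(default_factory=list)
    inversions: list[tuple[str, int, int]] = field(default_factory=list)
    terminal_translocations: list[tuple[tuple[str, str], tuple[str, str], int]] = \
        field(default_factory=list)

    def touched_chromosomes(self) -> list[str]:
        chroms = [c for a, b, _ in self.fusions for c in (a, b)]
        chroms += [c for c, _, _ in self.inversions]
        chroms += [c for (x, _), (y, _), _ in self.terminal_translocations
                   for c in (x, y)]
        return chroms


def _features_crossing(features, chrom, pos) -> list[FeatureRecord]:
    return [f for f in features
            if f.seqid == chrom and f.start < pos < f.end]


def apply_rearrangement_plan(genome, annotation, plan: RearrangementPlan,
                             gap_length: int = 500):
    """Apply planted rearrangements; return (genome2, annotation2, truth_log).

    Gene ids are preserved, total non-gap sequence length and gene count
    are conserved, and every planted event is recorded in the truth log
    with coordinates and the ids of the genes it moved.  Breakpoints
    falling inside a feature, or overlapping edits on one chromosome,
    raise.
    """
    seqs = {rec.id: rec.sequence for rec in genome}
    feats = [FeatureRecord(f.seqid, f.source, f.ftype, f.start, f.end,
                           f.score, f.strand, f.phase, dict(f.attributes))
             for f in annotation]
    truth_log: list[dict] = []

    # validate edit disjointness per chromosome
    edit_spans: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in plan.inversions:
        if chrom not in seqs:
            raise ValueError(f"unknown chromosome {chrom}")
        if not (0 <= start < end <= len(seqs[chrom])):
            raise ValueError(f"inversion [{start}, {end}) outside {chrom}")
        edit_spans.setdefault(chrom, []).append((start, end))
    for (cx, ex), (cy, ey), swap in plan.terminal_translocations:
        for chrom, flag in ((cx, ex), (cy, ey)):
            if chrom not in seqs:
                raise ValueError(f"unknown chromosome {chrom}")
            if flag not in ("left", "right"):
                raise ValueError(f"bad end flag {flag!r}")
            if swap <= 0 or swap >= len(seqs[chrom]):
                raise ValueError(f"swap length {swap} invalid for {chrom}")
            span = (0, swap) if flag == "left" else (len(seqs[chrom]) - swap,
                                                     len(seqs[chrom]))
            edit_spans.setdefault(chrom, []).append(span)
    for chrom, spans in edit_spans.items():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping edits on {chrom}")

    # breakpoints must fall between features
    for chrom, spans in edit_spans.items():
        for start, end in spans:
            for pos in (start, end):
                if pos in (0, len(seqs[chrom])):
                    continue
                crossing = _features_crossing(feats, chrom, pos)
                if crossing:
                    raise ValueError(
                        f"breakpoint {pos} on {chrom} falls inside feature "
                        f"{crossing[0].feature_id}"
                    )

    def genes_in(chrom, start, end):
        return [f.feature_id for f in feats
                if f.seqid == chrom and f.ftype == "gene"
                and start <= f.start and f.end <= end]

    # --- inversions ---
    for chrom, start, end in plan.inversions:
        truth_log.append({
            "kind": "inversion", "chrom": chrom, "start": start, "end": end,
            "genes": genes_in(chrom, start, end),
        })
        seq = seqs[chrom]
        seqs[chrom] = seq[:start] + _revcomp(seq[start:end]) + seq[end:]
        for f in feats:
            if f.seqid == chrom and start <= f.start and f.end <= end:
                f.start, f.end = start + (end - f.end), start + (end - f.start)
                if f.strand in "+-":
                    f.strand = "-" if f.strand == "+" else "+"

    # --- terminal translocations (end swaps) ---
    for (cx, ex), (cy, ey), swap in plan.terminal_translocations:
        lx, ly = len(seqs[cx]), len(seqs[cy])
        span_x = (0, swap) if ex == "left" else (lx - swap, lx)
        span_y = (0, swap) if ey == "left" else (ly - swap, ly)
        truth_log.append({
            "kind": "terminal_translocation",
            "chrom_x": cx, "end_x": ex, "chrom_y": cy, "end_y": ey,
            "swap_length": swap,
            "genes_x": genes_in(cx, *span_x), "genes_y": genes_in(cy, *span_y),
        })
        seg_x = seqs[cx][span_x[0]:span_x[1]]
        seg_y = seqs[cy][span_y[0]:span_y[1]]
        flip = ex != ey  # preserve telomeric polarity on mixed-end swaps
        in_x = _revcomp(seg_y) if flip else seg_y
        in_y = _revcomp(seg_x) if flip else seg_x
        if ex == "left":
            seqs[cx] = in_x + seqs[cx][swap:]
        else:
            seqs[cx] = seqs[cx][:lx - swap] + in_x
        if ey == "left":
            seqs[cy] = in_y + seqs[cy][swap:]
        else:
            seqs[cy] = seqs[cy][:ly - swap] + in_y

        moved_x = [f for f in feats if f.seqid == cx
                   and span_x[0] <= f.start and f.end <= span_x[1]]
        moved_y = [f for f in feats if f.seqid == cy
                   and span_y[0] <= f.start and f.end <= span_y[1]]

        def relocate(fs, src_span, dst_chrom, dst_span, flipped):
            s0, _ = src_span
            d0, d1 = dst_span
            for f in fs:
                off_start, off_end = f.start - s0, f.end - s0
                f.seqid = dst_chrom
                if flipped:
                    f.start = d0 + (swap - off_end)
                    f.end = d0 + (swap - off_start)
                    if f.strand in "+-":
                        f.strand = "-" if f.strand == "+" else "+"
                else:
                    f.start, f.end = d0 + off_start, d0 + off_end

        # destination spans are same-size terminal windows on the other chrom
        dst_x = (0, swap) if ex == "left" else (lx - swap, lx)
        dst_y = (0, swap) if ey == "left" else (ly - swap, ly)
        relocate(moved_x, span_x, cy, dst_y, flip)
        relocate(moved_y, span_y, cx, dst_x, flip)

    # --- fusions ---
    for chrom_a, chrom_b, fused_name in plan.fusions:
        if chrom_a not in seqs or chrom_b not in seqs:
            raise ValueError(f"unknown chromosome in fusion {chrom_a}+{chrom_b}")
        la = len(seqs[chrom_a])
        truth_log.append({
            "kind": "fusion", "chrom_a": chrom_a, "chrom_b": chrom_b,
            "fused_name": fused_name, "junction": la, "gap_length": gap_length,
            "genes_a": genes_in(chrom_a, 0, la),
            "genes_b": genes_in(chrom_b, 0, len(seqs[chrom_b])),
        })
        fused = seqs[chrom_a] + "N" * gap_length + seqs[chrom_b]
        shift = la + gap_length
        for f in feats:
            if f.seqid == chrom_b:
                f.seqid = fused_name
                f.start += shift
                f.end += shift
            elif f.seqid == chrom_a:
                f.seqid = fused_name
        del seqs[chrom_a], seqs[chrom_b]
        seqs[fused_name] = fused

    genome2 = [SeqRecord(id=c, sequence=s) for c, s in seqs.items()]
    feats.sort(key=lambda f: (f.seqid, f.start, f.ftype))
    return genome2, feats, truth_log


def _free_position(features, chrom, lo, hi) -> int | None:
    """A position in (lo, hi) not inside any feature on chrom, or None."""
    if hi <= lo:
        return None
    covering = sorted(
        (f.start, f.end) for f in features
        if f.seqid == chrom and f.start < hi and f.end > lo
    )
    pos = lo
    for s, e in covering:
        if pos < s:
            return pos
        pos = max(pos, e)
    return pos if pos < hi else None


def random_rearrangement_plan(annotation, chrom_lengths: dict[str, int],
                              n_fusions: int = 0, n_inversions: int = 0,
                              genes_per_inversion: int = 15,
                              n_end_swaps: int = 0, genes_per_end: int = 12,
                              seed: int = 0) -> RearrangementPlan:
    """Draw a valid plan whose breakpoints fall between features.

    Each chromosome is used by at most one event.  Inversions cover
    ``genes_per_inversion`` consecutive genes away from the terminal 20%
    of the chromosome; end swaps exchange right-end windows covering
    about ``genes_per_end`` genes on each side.
    """
    rng = np.random.default_rng(seed)
    genes_by_chrom: dict[str, list[FeatureRecord]] = {}
    for f in annotation:
        if f.ftype == "gene":
            genes_by_chrom.setdefault(f.seqid, []).append(f)
    for fs in genes_by_chrom.values():
        fs.sort(key=lambda f: f.start)
    chroms = [c for c in chrom_lengths if len(genes_by_chrom.get(c, [])) > 0]
    order = [chroms[i] for i in rng.permutation(len(chroms))]
    needed = 2 * n_fusions + n_inversions + 2 * n_end_swaps
    if needed > len(order):
        raise ValueError("not enough chromosomes for the requested plan")

    plan = RearrangementPlan()
    pool = iter(order)

    for _ in range(n_fusions):
        a, b = next(pool), next(pool)
        plan.fusions.append((a, b, a))  # fused element keeps the first name

    for _ in range(n_inversions):
        chrom = next(pool)
        genes = genes_by_chrom[chrom]
        length = chrom_lengths[chrom]
        interior = [i for i, g in enumerate(genes)
                    if g.start > 0.2 * length and g.end < 0.8 * length]
        k = genes_per_inversion
        candidates = [i for i in interior if i + k - 1 < len(genes)
                      and genes[i + k - 1].end < 0.8 * length]
        if not candidates:
            raise ValueError(f"no room for a {k}-gene inversion on {chrom}")
        order_c = [candidates[t] for t in rng.permutation(len(candidates))]
        for i in order_c:
            lo = genes[i - 1].end if i > 0 else 0
            start = _free_position(annotation, chrom, lo, genes[i].start)
            j = i + k - 1
            hi = genes[j + 1].start if j + 1 < len(genes) else length
            end = _free_position(annotation, chrom, genes[j].end, hi)
            if start is not None and end is not None:
                plan.inversions.append((chrom, start, end))
                break
        else:
            raise ValueError(f"no feature-free breakpoint on {chrom}")

    for _ in range(n_end_swaps):
        x, y = next(pool), next(pool)
        # smallest swap that covers genes_per_end genes on each side
        swap0 = 0
        for chrom in (x, y):
            genes = genes_by_chrom[chrom]
            j = max(0, len(genes) - genes_per_end)
            swap0 = max(swap0, chrom_lengths[chrom] - genes[j].start + 1)
        # scan for a shared swap length whose cut is feature-free on both
        swap = None
        for cand in range(swap0, swap0 + 100_000, 47):
            ok = True
            for chrom in (x, y):
                cut = chrom_lengths[chrom] - cand
                if cut <= 0 or _features_crossing(annotation, chrom, cut):
                    ok = False
                    break
            if ok:
                swap = cand
                break
        if swap is None:
            raise ValueError(f"no feature-free shared swap length for {x}/{y}")
        plan.terminal_translocations.append(((x, "right"), (y, "right"), swap))

    return plan


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------

@dataclass
class ReadSimSpec:
    """Log-normal read lengths with an optional planted chimera rate.

    Defaults follow a CLR-like length law (median ~20 kb); tests scale
    the median down with the genome.
    """

    n_reads: int = 2_000
    median_len: int = 20_000
    sigma: float = 0.55
    chimera_rate: float = 0.0
    min_len: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.chimera_rate <= 1):
            raise ValueError("chimera_rate must be in [0, 1]")


MIN_CHIMERA_SEPARATION = 100_000


def simulate_long_reads(genome, spec: ReadSimSpec):
    """Sample reads from the genome; return (reads, truth).

    ``truth`` maps read id -> {"chimeric": bool, "fragments":
    [(chrom, start, end), ...]} with read-order fragments.  A chimeric
    read concatenates two fragments drawn from loci at least 100 kb
    apart (possibly on different chromosomes).  Reads are emitted on the
    forward strand.
    """
    if not genome:
        raise ValueError("empty genome")
    rng = np.random.default_rng(spec.seed)
    chroms = [rec.id for rec in genome]
    seqs = {rec.id: rec.sequence for rec in genome}
    lengths = np.array([len(seqs[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()

    def draw_fragment(frag_len):
        ci = int(rng.choice(len(chroms), p=weights))
        chrom = chroms[ci]
        lmax = len(seqs[chrom])
        frag_len = min(frag_len, lmax)
        start = int(rng.integers(0, lmax - frag_len + 1))
        return chrom, start, start + frag_len

    reads: list[SeqRecord] = []
    truth: dict[str, dict] = {}
    mu = math.log(spec.median_len)
    for i in range(spec.n_reads):
        rid = f"read_{i + 1:06d}"
        total = max(spec.min_len, int(rng.lognormal(mu, spec.sigma)))
        chimeric = bool(rng.random() < spec.chimera_rate)
        if chimeric:
            l1 = total // 2
            l2 = total - l1
            c1, s1, e1 = draw_fragment(l1)
            for _ in range(1000):
                c2, s2, e2 = draw_fragment(l2)
                if c2 != c1 or abs(s2 - s1) >= MIN_CHIMERA_SEPARATION:
                    break
            else:
                raise RuntimeError("could not separate chimera fragments")
            seq = seqs[c1][s1:e1] + seqs[c2][s2:e2]
            fragments = [(c1, s1, e1), (c2, s2, e2)]
        else:
            chrom, start, end = draw_fragment(total)
            seq = seqs[chrom][start:end]
            fragments = [(chrom, start, end)]
        reads.append(SeqRecord(id=rid, sequence=seq))
        truth[rid] = {"chimeric": chimeric, "fragments": fragments}
    return reads, truth


def make_overlaps(reads, truth, min_overlap: int = 2_000,
                  junction_margin: int = 150) -> list[Overlap]:
    """Idealized all-vs-all overlaps from the reads' true coordinates.

    Two reads overlap where their genomic fragments intersect by at
    least ``min_overlap`` bp.  On a chimeric read, overlaps are trimmed
    to stay ``junction_margin`` bp clear of the junction, so no overlap
    spans it and coverage dips to zero there — the signature the
    scrubber detects.
    """
    read_len = {r.id: len(r.sequence) for r in reads}
    # usable genomic windows per fragment, after junction trimming
    frags: dict[str, list[tuple[int, int, str, int]]] = {}
    for rid, info in truth.items():
        offset = 0
        n_frag = len(info["fragments"])
        for k, (chrom, gstart, gend) in enumerate(info["fragments"]):
            flen = gend - gstart
            lead = junction_margin if k > 0 else 0
            tail = junction_margin if k < n_frag - 1 else 0
            if flen > lead + tail:
                frags.setdefault(chrom, []).append(
                    (gstart + lead, gend - tail, rid, offset - gstart)
                )
            offset += flen
    overlaps: list[Overlap] = []
    for chrom, entries in frags.items():
        entries.sort()
        for i, (s1, e1, rid1, off1) in enumerate(entries):
            for s2, e2, rid2, off2 in entries[i + 1:]:
                if s2 >= e1:
                    break
                if rid1 == rid2:
                    continue
                s, e = max(s1, s2), min(e1, e2)
                if e - s < min_overlap:
                    continue
                overlaps.append(
                    Overlap(
                        qname=rid1, qlen=read_len[rid1],
                        qstart=off1 + s, qend=off1 + e,
                        tname=rid2, tlen=read_len[rid2],
                        tstart=off2 + s, tend=off2 + e,
                        strand="+",
                    )
                )
    return overlaps


# ---------------------------------------------------------------------------
# assembly-map export
# ---------------------------------------------------------------------------

def export_assembly_map(contigs, scaffold_order, path) -> AssemblyMap:
    """Write a 3d-DNA-style ``.assembly`` file for the given scaffolding.

    ``scaffold_order`` is a list of scaffolds, each a list of
    (contig_name, orientation) with orientation '+'/'-'.  Returns the
    written map (which :func:`notocraft.io_formats.read_assembly_map`
    round-trips).
    """
    from .io_formats import write_assembly_map

    if not isinstance(contigs, dict):
        contigs = {rec.id: rec for rec in contigs}
    entries = [(name, i + 1, len(rec.sequence))
               for i, (name, rec) in enumerate(contigs.items())]
    ids = {name: i + 1 for i, name in enumerate(contigs)}
    scaffolds: list[list[int]] = []
    for scaffold in scaffold_order:
        row: list[int] = []
        for name, orient in scaffold:
            if name not in ids:
                raise ValueError(f"unknown contig {name}")
            row.append(ids[name] if orient == "+" else -ids[name])
        scaffolds.append(row)
    amap = AssemblyMap(entries=entries, scaffolds=scaffolds)
    write_assembly_map(amap, path)
    return amap
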