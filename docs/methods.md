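# Methods notes

This note records the models, conventions and numerical choices behind
notocraft, what the synthetic-data generators do and do not emulate, and
the design decisions taken where the problem was genuinely open.

## Coordinate conventions

All internal coordinates are 0-based half-open. GFF3 and AGP are 1-based
inclusive on disk; the conversion happens only in `io_formats`, so any
off-by-one bug has a single home. FASTA is written at fixed 60-character
lines with uppercase normalization on read, which makes
read∘write∘read byte-stable. GTF is accepted read-only and converted to
the GFF3 attribute model (`transcript_id`/`gene_id` re-keyed to
`ID`/`Parent`).

## Read scrubbing

The scrubber classifies reads from a per-base coverage profile built
from all-vs-all overlaps, counting both the query and target roles of a
read (all-vs-all is symmetric). Before profiling, overlaps are filtered:
aligned query span < 2,000 bp, or an *internal match* — one read's full
length contained in the other's aligned span while neither alignment
boundary on the container comes within 50 bp of the container's ends.
The 50 bp end tolerance is a free parameter; the containment concept
needs some end-distance cutoff and 50 bp is small against typical
long-read alignment noise.

Classification: a read is **chimeric** when some maximal run of
positions with coverage ≤ 3 is strictly interior (flanked on both sides
by above-threshold runs) — the junction of two unrelated fragments
receives no spanning overlaps, so coverage collapses there but recovers
on both sides. A read is **low-coverage** when such positions make up
≥ 40% of its length. Chimeric takes precedence in reporting. A
low-coverage run touching a read end is deliberately *not* chimeric:
terminal coverage loss is the ordinary signature of sparse sampling, not
of a junction. Chimeric reads are removed, not split; splitting would be
a natural extension but changes the read-set bookkeeping downstream.

The subsampler takes reads in input order (deterministic; an optional
shuffle seed randomizes first), keeps those inside the length window,
and stops at the first read whose inclusion reaches the basepair budget,
including it.

## Assembly statistics

N*x*/L*x* follow the standard definition: sort descending, walk the
cumulative sum, report the first length at which it reaches *x*% of the
total and its 1-based rank; ties resolve naturally in the sorted order.
Gap (N) bases count toward scaffold length. "Chromosome-level scaffold"
is an explicit id list, never a length threshold. Percentages round
half-up at the printed precision (2 decimals for assembly percentages,
1 for BUSCO classes) — the convention that reproduces published summary
tables exactly when recomputed from their own counts.

## Curation and liftover

A 3d-DNA `.assembly` map converts to AGP with one object per scaffold:
W rows in map order (sign → orientation) alternating with N gap rows,
`gap_type=scaffold`, `linkage=yes`, `evidence=proximity_ligation`. The
default gap of 500 bp is a common scaffolding convention and is
surfaced as a flag; `gap_length=0` produces gapless joins.

Edits never split a contig (splits are only allowed at component
boundaries), so contigs are atomic and the liftover map can be derived
directly by comparing each contig's placement in the original versus
the final AGP — one length-preserving interval per contig, flagged
`flipped` when the orientation changed. This is equivalent to composing
per-edit maps but simpler and exactly invertible, which the round-trip
tests exploit. Features fully inside one interval translate by offset;
on flipped intervals `new_start = interval_new_start + (interval_old_end
− feature_end)` and strand toggles. A feature spanning an interval
boundary is an error by default (silent truncation hides corruption);
an opt-in `split` policy cuts it into parts sharing the original ID.

Joined objects take the lower-numbered name by natural sort, mirroring
the convention of keeping the smaller chromosome label when two
chromosomes fuse.

## Conserved synteny

Ortholog pairs are reciprocal best hits by bitscore with deterministic
tie-breaking (higher identity, then lexicographically smaller subject).
Gene position is the midpoint of the annotated span — stable under
strand and minor boundary edits.

The published description of the clustering algorithm is qualitative,
so its parameters are package parameters with defaults: seed window 5
consecutive orthologs on one partner chromosome, ≤ 3 intervening
interloper orthologs tolerated during extension, minimum cluster size 5,
fusion secondary fraction 0.2. Cluster orientation is the sign of the
Spearman rank correlation between member positions (|ρ| < 0.5 →
"mixed"); rank correlation is robust to singleton misplacements where
strict adjacency signs are not.

Chromosome orthology is the plurality partner of the clustered genes; a
second partner holding ≥ 20% of them over an A-interval disjoint from
the first's yields dual orthology, i.e. a fusion candidate. Inversions
are interior maximal runs (≥ 5 pairs) of opposite step direction within
a chromosome-pair chain, flanked on both sides by runs of the opposing
sign. Translocation candidates are clusters touching the outer 20% of a
chromosome whose partner is not the assigned ortholog; two candidates
that point at each other's orthologs merge into one end-swap call. The
20% terminal fraction reflects that such swaps are telomeric; it is a
flag.

## Repeat landscape

Kimura 2-parameter distance over ungapped, unambiguous columns:
P = transitions/n, Q = transversions/n,
K = −½ ln[(1 − 2P − Q)·√(1 − 2Q)]. Distances are undefined (saturation)
when either log argument is non-positive; such pairs are skipped and
counted. Ambiguity codes are excluded from the denominators. No
CpG-adjusted variant is implemented — plain K2P only. Each copy
contributes its ungapped aligned bp to bin ⌊100·K⌋ of its class;
fractions are bp over genome size.

Klump detection uses exact canonical (strand-collapsed) k-mers, so the
output is invariant under reverse-complementing the reference. Matches
within `range` bp start-to-start group into one klump; the span runs
from the first match start to the last match start plus k. Defaults
k = 17, ≥ 20 matches, range 1,000 bp.

CDS integrity: frameshift when length mod 3 ≠ 0; else premature stop
when a stop codon precedes the final codon; else intact when the final
codon is a stop and incomplete otherwise (a CDS that simply runs off the
end of its model is not intact). A missing ATG start is reported in the
details without changing the status.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the pipeline
assumes, at roughly 1:40 scale so the whole suite runs in seconds:

* **Genomes** — default 23 chromosomes of 0.9–1.6 Mbp, ~100 genes and
  ~150 repeats each; gene midpoints Beta(1+b, 1+b) (center bias b = 2),
  repeat midpoints an equal mixture of Beta(1, 1+b)/Beta(1+b, 1)
  (terminal bias b = 3, symmetric). Bias 0 degenerates to uniform.
  Features are placed without overlap within type by rejection sampling,
  which at the default densities (~20% occupancy) perturbs the placement
  law negligibly. No quantitative terminal-enrichment factor is
  established for real repeat distributions, so the bias parameters are
  free and only the qualitative shape is asserted.
* **Repeat families** — per-class consensus sequences mutated into
  copies whose target Kimura distance is drawn from a mixture over
  1%-wide bins (default: exponential decay over 0–29%, a
  recent-expansion profile). Substitutions are planted at a 2:1
  transition:transversion ratio, which exercises both the P and Q
  channels of the distance. Bin 0 stands for "no divergence yet" and
  yields exact duplicates; other bins aim at the bin interior
  (K ∈ [b+0.2, b+0.8]%) so site-count rounding rarely crosses a bin
  edge. No indels, no CpG structure, no subfamily nesting.
* **Rearrangements** — plans of fusions (500 bp N junction), inversions
  and terminal end swaps, with breakpoints that must fall between
  features and at most one event per chromosome; a truth log records
  every event with coordinates and moved gene ids. Gene ids persist
  across the edit, giving a perfect orthology for recovery tests.
* **Long reads** — log-normal lengths, forward strand, sampled
  error-free from the genome; a chimeric read concatenates two fragments
  from loci ≥ 100 kb apart. Idealized all-vs-all overlaps come from the
  true coordinates; overlaps onto a chimeric read are trimmed to stay
  150 bp clear of the junction, realizing the guarantee that no overlap
  spans it and coverage dips to zero there. Real base errors, quality
  scores, strand mixture and repeat-induced spurious overlaps are *not*
  modeled — so a passing scrub test shows the classification rules are
  implemented correctly under the stated coverage model, not that the
  scrubber is robust to alignment noise.

The recovery scenarios are fixed study conditions, not tuning knobs:
rearrangement recovery uses 8-chromosome genomes (~80 genes each) with
one fusion and two 12-gene inversions per seed; the false-call check
compares 20 genomes against renamed, uniformly rescaled copies of
themselves (cluster membership is scale-invariant); scrubbing uses 2,000
reads at ~25× depth (median 12 kb, σ = 0.25, 5% chimeras) — depth
matters because the containment-dropping overlap filter thins coverage
on short reads; landscape recovery uses 10,000 copies of 400 bp across
the 5 default classes.

## Known limitations

* The synteny engine handles two genomes at a time; multi-genome synteny
  graphs are out of scope.
* Rearrangement calls are gene-order based; breakpoints are reported at
  gene-midpoint resolution, not base resolution.
* The edit-script vocabulary is general rather than a replay of any
  particular curation session; gap lengths inserted by edits are a
  single configurable default, not re-estimated.
* `.assembly` parsing accepts both pre- and post-review name forms but
  does not model Juicebox fragment splitting annotations.
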