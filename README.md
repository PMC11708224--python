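# notocraft

Toolkit for the bespoke computational stages of a chromosome-scale fish
genome project: long-read QC and subsampling, assembly statistics, Hi-C
assembly-map → AGP conversion, synteny-guided assembly curation with
annotation liftover, conserved-synteny rearrangement detection, windowed
gene/repeat density tracks, Kimura repeat landscapes, k-mer "klump"
locus validation, and supermatrix preparation for phylogenomics.

It is aimed at genome-assembly practitioners — the people who sit between
an automated scaffolder's output and a finished, named chromosome set —
and at anyone who wants these curation steps reproducible and testable.
A seeded synthetic-data module generates genomes with center-biased
genes, terminal-biased repeats, planted chromosomal rearrangements, and
long-read sets with planted chimeras, so the entire pipeline can be
exercised end to end without any sequencing data.

## What it computes

**Read scrubbing.** From idealized or real all-vs-all overlaps (PAF-like),
overlaps shorter than 2 kb and internal matches are dropped; a read is then
removed when coverage ≤ 3× over ≥ 40% of its length (low coverage) or when
a low-coverage run is strictly interior (the chimeric-junction signature).
A complementary subsampler selects reads in a 10–40 kb window up to a
total-basepair budget.

**Assembly statistics.** N*x*/L*x* by the standard descending cumulative
walk; percentage of assembly in chromosomes; BUSCO class percentages from
the 6 counts (with the identities `complete = single + duplicated` and
`complete + fragmented + missing = total` enforced); read-set summaries.
Percentages are rounded half-up at the printed precision.

**Curation.** A 3d-DNA `.assembly` map becomes an AGP v2.1 file (oriented
W rows alternating with 500 bp scaffold gaps); scaffold FASTA is rebuilt
from AGP + contigs; ordered edit scripts (reorder / reorient / move /
split / join / rename) re-tile the AGP and produce an exact, invertible
liftover map that translates annotation coordinates, flipping strand on
reoriented contigs.

**Conserved synteny.** Reciprocal best hits define orthologs; a sliding
window grows clusters of consecutive orthologs sharing one partner
chromosome; cluster geometry then yields chromosome orthology naming and
calls of fusions (one chromosome spanning two partners in disjoint
intervals), inversions (interior runs of opposite orientation), and
terminal translocations (paired into end-swap calls when reciprocal).

**Landscapes.** Feature density in 250 kb windows every 100 kb; Kimura
2-parameter divergence *K* = −½ ln[(1 − 2P − Q)·√(1 − 2Q)] per repeat
copy vs consensus, binned at 1% into a per-class repeat landscape; exact
canonical k-mer klump detection (k = 17, ≥ 20 k-mers within 1 kb); CDS
integrity checks for pseudogene screening (frameshift, premature stop,
missing terminal stop).

## Worked example

Simulate a toy genome, convert a scaffolding map to AGP, and summarize
BUSCO counts:

```
$ notocraft simulate --seed 7 --chromosomes 2 --genes-per-chrom 40 -o toy
wrote genome with 2 chromosomes

$ printf '>c1 1 1000\n>c2 2 500\n1 -2\n' > toy.assembly
$ notocraft curate to-agp toy.assembly -o toy.agp
wrote 1 objects
$ cat toy.agp
##agp-version	2.1
scaffold_1	1	1000	1	W	c1	1	1000	+
scaffold_1	1001	1500	2	N	500	scaffold	yes	proximity_ligation
scaffold_1	1501	2000	3	W	c2	1	500	-
```

The two contigs become one 2,000 bp object: contig c1 forward at 1–1000,
a 500 bp proximity-ligation gap, and contig c2 reverse-complemented at
1501–2000.

```
$ notocraft stats busco 3520 3475 45 31 89 3640
{
  "complete": 96.7,
  "single": 95.5,
  "duplicated": 1.2,
  "fragmented": 0.9,
  "missing": 2.4
}
```

Those are the completeness percentages for an assembly with 3,520 of
3,640 conserved orthologs complete, 3,475 of them single-copy.

Other entry points: `notocraft reads sample|scrub`, `notocraft curate
apply` (edit scripts with liftover), `notocraft synteny`, `notocraft
density`, `notocraft landscape`, `notocraft klumps` — see `--help` on
each.

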