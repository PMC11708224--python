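"""Generator determinism, placement laws, planted-truth bookkeeping."""

import numpy as np
import pytest
from scipy import stats

from notocraft import io_formats as io
from notocraft import synthetic_data as sd


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def test_same_seed_identical_bytes(tmp_path):
    spec = sd.GenomeSpec(n_chromosomes=2, chrom_length_range=(100_000, 150_000),
                         gene_count_per_chrom=20, repeat_count_per_chrom=20,
                         seed=7)
    for run in (1, 2):
        genome, ann = sd.generate_genome(spec)
        io.write_fasta(genome, tmp_path / f"g{run}.fa")
        io.write_gff3(ann, tmp_path / f"a{run}.gff3")
    assert (tmp_path / "g1.fa").read_bytes() == (tmp_path / "g2.fa").read_bytes()
    assert (tmp_path / "a1.gff3").read_bytes() == (tmp_path / "a2.gff3").read_bytes()


def test_zero_center_bias_gives_uniform_midpoints():
    """With gene_center_bias=0 the midpoint law is uniform (KS at n=2,000)."""
    spec = sd.GenomeSpec(n_chromosomes=1, chrom_length_range=(2_000_000, 2_000_000),
                         gene_count_per_chrom=2_000, gene_center_bias=0.0,
                         gene_length=100, repeat_count_per_chrom=0, seed=13)
    genome, ann = sd.generate_genome(spec)
    length = len(genome[0].sequence)
    mids = [f.midpoint / length for f in ann if f.ftype == "gene"]
    assert stats.kstest(mids, "uniform").pvalue > 0.01


def test_center_bias_concentrates_genes_in_middle_third():
    spec = sd.GenomeSpec(n_chromosomes=3, chrom_length_range=(500_000, 600_000),
                         gene_count_per_chrom=90, gene_center_bias=4.0, seed=14)
    genome, ann = sd.generate_genome(spec)
    for chrom in genome:
        mids = [f.midpoint / len(chrom.sequence) for f in ann
                if f.ftype == "gene" and f.seqid == chrom.id]
        thirds = np.histogram(mids, bins=[0, 1 / 3, 2 / 3, 1])[0]
        assert thirds[1] > thirds[0]
        assert thirds[1] > thirds[2]


def test_terminal_bias_concentrates_repeats_at_ends():
    spec = sd.GenomeSpec(n_chromosomes=3, chrom_length_range=(500_000, 600_000),
                         gene_count_per_chrom=10, repeat_terminal_bias=5.0,
                         repeat_count_per_chrom=120, seed=15)
    genome, ann = sd.generate_genome(spec)
    for chrom in genome:
        mids = [f.midpoint / len(chrom.sequence) for f in ann
                if f.ftype == "repeat" and f.seqid == chrom.id]
        thirds = np.histogram(mids, bins=[0, 1 / 3, 2 / 3, 1])[0]
        assert thirds[0] > thirds[1]
        assert thirds[2] > thirds[1]


def test_features_non_overlapping_within_type(small_genome):
    _, ann = small_genome
    for ftype in ("gene", "repeat"):
        by_chrom = {}
        for f in ann:
            if f.ftype == ftype:
                by_chrom.setdefault(f.seqid, []).append((f.start, f.end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(e1 <= s2 for (_, e1), (s2, _) in zip(spans, spans[1:]))


def test_infeasible_packing_raises():
    spec = sd.GenomeSpec(n_chromosomes=1, chrom_length_range=(10_000, 10_000),
                         gene_count_per_chrom=100, gene_length=2_000, seed=1)
    with pytest.raises(ValueError, match="infeasible"):
        sd.generate_genome(spec)


# ---------------------------------------------------------------------------
# repeat copies
# ---------------------------------------------------------------------------

def test_zero_divergence_profile_gives_identical_copies():
    profile = sd.RepeatAgeProfile(family_classes=("DNA",), copies_per_family=20,
                                  divergence_weights={0: 1.0})
    copies = sd.generate_repeat_copies(200, profile, seed=3)
    assert all(c.aligned_copy == c.aligned_consensus for c in copies)


def test_repeat_copies_deterministic():
    profile = sd.RepeatAgeProfile(copies_per_family=10)
    c1 = sd.generate_repeat_copies(200, profile, seed=4)
    c2 = sd.generate_repeat_copies(200, profile, seed=4)
    assert c1 == c2


def test_repeat_copies_tsv_roundtrip(tmp_path):
    profile = sd.RepeatAgeProfile(copies_per_family=5)
    copies = sd.generate_repeat_copies(100, profile, seed=5)
    p = tmp_path / "copies.tsv"
    sd.write_repeat_copies(copies, p)
    assert sd.read_repeat_copies(p) == copies


def test_landscape_recovers_generating_weights():
    """Per-bin coverage fractions from the landscape module match the
    generating mixture weights (small-n version of the recovery check)."""
    from notocraft.landscape import repeat_landscape

    weights = {0: 0.4, 3: 0.3, 8: 0.2, 15: 0.1}
    profile = sd.RepeatAgeProfile(family_classes=("DNA", "LINE"),
                                  copies_per_family=1_000,
                                  divergence_weights=weights)
    copies = sd.generate_repeat_copies(400, profile, seed=6)
    total_bp = sum(len(c.aligned_consensus) for c in copies)
    result = repeat_landscape(
        [(c.class_label, c.aligned_copy, c.aligned_consensus) for c in copies],
        genome_size=total_bp,
    )
    by_bin = {}
    for b in result.bins:
        by_bin[b.bin_lower_pct] = by_bin.get(b.bin_lower_pct, 0) + b.genome_fraction
    for bin_pct, w in weights.items():
        assert by_bin.get(bin_pct, 0) == pytest.approx(w, abs=0.03)


# ---------------------------------------------------------------------------
# rearrangement plans
# ---------------------------------------------------------------------------

def test_empty_plan_is_identity(small_genome):
    genome, ann = small_genome
    g2, a2, log = sd.apply_rearrangement_plan(genome, ann, sd.RearrangementPlan())
    assert [(g.id, g.sequence) for g in g2] == [(g.id, g.sequence) for g in genome]
    assert [(f.seqid, f.start, f.end) for f in a2] == \
        [(f.seqid, f.start, f.end) for f in ann]
    assert log == []


def test_fusion_conserves_length_and_genes(small_genome):
    genome, ann = small_genome
    plan = sd.RearrangementPlan(fusions=[("chr1", "chr2", "chr1")])
    g2, a2, log = sd.apply_rearrangement_plan(genome, ann, plan, gap_length=500)
    lengths = {g.id: len(g.sequence) for g in genome}
    fused = [g for g in g2 if g.id == "chr1"][0]
    assert len(fused.sequence) == lengths["chr1"] + 500 + lengths["chr2"]
    assert sum(1 for f in a2 if f.ftype == "gene") == \
        sum(1 for f in ann if f.ftype == "gene")
    assert log[0]["kind"] == "fusion" and log[0]["junction"] == lengths["chr1"]


def test_inversion_reverses_gene_order_and_sequence(small_genome):
    genome, ann = small_genome
    lengths = {g.id: len(g.sequence) for g in genome}
    plan = sd.random_rearrangement_plan(ann, lengths, n_inversions=1,
                                        genes_per_inversion=30, seed=8)
    (chrom, start, end) = plan.inversions[0]
    g2, a2, log = sd.apply_rearrangement_plan(genome, ann, plan)
    planted = log[0]["genes"]
    assert len(planted) == 30
    # relative order of the inverted genes is reversed in the new annotation
    order2 = [f.feature_id for f in a2
              if f.ftype == "gene" and f.feature_id in set(planted)]
    assert order2 == planted[::-1]
    # sequence inside the window is the reverse complement
    old = [g for g in genome if g.id == chrom][0].sequence
    new = [g for g in g2 if g.id == chrom][0].sequence
    assert new[start:end] == sd._revcomp(old[start:end])
    assert new[:start] == old[:start] and new[end:] == old[end:]


def test_overlapping_edits_rejected(small_genome):
    genome, ann = small_genome
    plan = sd.RearrangementPlan(inversions=[("chr1", 100_000, 200_000),
                                            ("chr1", 150_000, 250_000)])
    with pytest.raises(ValueError, match="overlapping"):
        sd.apply_rearrangement_plan(genome, ann, plan)


def test_breakpoint_inside_feature_rejected(small_genome):
    genome, ann = small_genome
    gene = next(f for f in ann if f.ftype == "gene" and f.seqid == "chr1")
    mid = (gene.start + gene.end) // 2
    plan = sd.RearrangementPlan(inversions=[("chr1", mid, mid + 50_000)])
    with pytest.raises(ValueError, match="inside feature"):
        sd.apply_rearrangement_plan(genome, ann, plan)


def test_end_swap_conserves_totals(small_genome):
    genome, ann = small_genome
    lengths = {g.id: len(g.sequence) for g in genome}
    plan = sd.random_rearrangement_plan(ann, lengths, n_end_swaps=1,
                                        genes_per_end=8, seed=9)
    g2, a2, log = sd.apply_rearrangement_plan(genome, ann, plan)
    assert sum(len(g.sequence) for g in g2) == sum(lengths.values())
    assert sum(1 for f in a2 if f.ftype == "gene") == \
        sum(1 for f in ann if f.ftype == "gene")
    ev = log[0]
    assert ev["kind"] == "terminal_translocation"
    moved = set(ev["genes_x"])
    assert moved and all(
        f.seqid == ev["chrom_y"] for f in a2 if f.feature_id in moved
    )


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------

def test_zero_chimera_rate_all_clean(scrub_scenario):
    genome = [io.SeqRecord(id="c", sequence="ACGT" * 100_000)]
    spec = sd.ReadSimSpec(n_reads=50, median_len=5_000, chimera_rate=0.0, seed=2)
    _, truth = sd.simulate_long_reads(genome, spec)
    assert not any(v["chimeric"] for v in truth.values())


def test_chimera_rate_within_binomial_ci(scrub_scenario):
    reads, truth, _ = scrub_scenario
    n = len(reads)
    frac = sum(1 for v in truth.values() if v["chimeric"]) / n
    # 99% binomial CI around 0.05 at n = 2,000
    half = 2.576 * (0.05 * 0.95 / n) ** 0.5
    assert abs(frac - 0.05) <= half


def test_reads_reproducible_for_fixed_seed():
    genome = [io.SeqRecord(id="c", sequence="ACGT" * 50_000)]
    spec = sd.ReadSimSpec(n_reads=30, median_len=4_000, chimera_rate=0.1, seed=5)
    r1, t1 = sd.simulate_long_reads(genome, spec)
    r2, t2 = sd.simulate_long_reads(genome, spec)
    assert r1 == r2 and t1 == t2


def test_chimera_fragments_far_apart(scrub_scenario):
    reads, truth, _ = scrub_scenario
    for info in truth.values():
        if info["chimeric"]:
            (c1, s1, _), (c2, s2, _) = info["fragments"]
            assert c1 != c2 or abs(s2 - s1) >= sd.MIN_CHIMERA_SEPARATION


def test_chimeric_junction_has_no_spanning_overlap(scrub_scenario):
    reads, truth, overlaps = scrub_scenario
    junctions = {}
    for rid, info in truth.items():
        if info["chimeric"]:
            c, s, e = info["fragments"][0]
            junctions[rid] = e - s
    for ov in overlaps:
        for name, lo, hi in ((ov.qname, ov.qstart, ov.qend),
                             (ov.tname, ov.tstart, ov.tend)):
            if name in junctions:
                j = junctions[name]
                assert not (lo < j < hi)


# ---------------------------------------------------------------------------
# assembly-map export
# ---------------------------------------------------------------------------

def test_export_assembly_map_roundtrip(tmp_path):
    contigs = [io.SeqRecord(id="c1", sequence="A" * 100),
               io.SeqRecord(id="c2", sequence="C" * 50)]
    p = tmp_path / "m.assembly"
    sd.export_assembly_map(contigs, [[("c1", "+"), ("c2", "-")]], p)
    amap = io.read_assembly_map(p)
    names = amap.id_to_name()
    assert [(names[abs(s)], "+" if s > 0 else "-") for s in amap.scaffolds[0]] \
        == [("c1", "+"), ("c2", "-")]


def test_export_assembly_map_empty_scaffolds_header_only(tmp_path):
    contigs = [io.SeqRecord(id="c1", sequence="A" * 100)]
    p = tmp_path / "m.assembly"
    sd.export_assembly_map(contigs, [], p)
    amap = io.read_assembly_map(p)
    assert amap.scaffolds == [] and len(amap.entries) == 1


def test_export_assembly_map_unknown_contig_raises(tmp_path):
    contigs = [io.SeqRecord(id="c1", sequence="A" * 100)]
    with pytest.raises(ValueError, match="unknown contig"):
        sd.export_assembly_map(contigs, [[("zz", "+")]], tmp_path / "m.assembly")
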