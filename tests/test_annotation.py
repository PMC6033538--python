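"""Gene-model partitioning, region assignment, and 3'-end distances."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clipshift.annotation import (
    GeneModel,
    GenomicInterval,
    assign_region,
    distance_to_transcript_end,
    load_gene_models,
)
from clipshift.simulate import SimulationConfig, simulate_dataset


def test_interval_validation():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 10, "+")  # zero length
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 20, 10, "+")
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 0, 5, "*")
    assert GenomicInterval("chr1", 0, 5, "+").length == 5


class TestPartition:
    def test_two_exon_partition(self, toy_gene):
        """UTR5/CDS/UTR3 lengths tile the exonic span; one intron."""
        gm = toy_gene
        assert len(gm.introns) == 1
        assert (gm.introns[0].start, gm.introns[0].end) == (150, 240)
        utr5 = sum(i.length for i in gm.utr5)
        cds = sum(i.length for i in gm.cds)
        utr3 = sum(i.length for i in gm.utr3)
        assert (utr5, cds, utr3) == (20, 30, 60)
        assert utr5 + cds + utr3 == gm.exonic_length

    def test_single_exon_fully_coding(self):
        gm = GeneModel.from_exons("g", "chr1", "+", [(100, 400)],
                                  cds_span=(100, 400))
        assert gm.utr5 == [] and gm.utr3 == []
        assert [(c.start, c.end) for c in gm.cds] == [(100, 400)]

    def test_minus_strand_utr3_at_lower_coords(self, toy_gene_minus):
        gm = toy_gene_minus
        assert all(u.end <= 220 for u in gm.utr3)
        assert all(u.start >= 280 for u in gm.utr5)

    def test_strand_flip_oracle(self, toy_gene):
        """Mirroring all coordinates and flipping strand preserves the
        region-length partition."""
        M = 10_000
        mirrored_exons = sorted((M - e.end, M - e.start) for e in toy_gene.exons)
        cs, ce = toy_gene.cds[0].start, toy_gene.cds[-1].end
        gm = GeneModel.from_exons("flip", "chr1", "-", mirrored_exons,
                                  cds_span=(M - ce, M - cs), downstream=0)
        for attr in ("utr5", "cds", "utr3", "introns"):
            assert sum(i.length for i in getattr(gm, attr)) == sum(
                i.length for i in getattr(toy_gene, attr)
            )

    def test_noncoding_gene(self):
        gm = GeneModel.from_exons("nc", "chr1", "+", [(0, 100)], cds_span=None)
        assert not gm.is_coding
        assert "noncoding" in gm.region_intervals()

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            GeneModel.from_exons("bad", "chr1", "+", [(0, 50), (40, 80)])

    def test_partition_property_on_simulated_genes(self):
        bundle = simulate_dataset(SimulationConfig(seed=3, n_genes=40,
                                                   n_utr3_targets=5,
                                                   n_cds_targets=5,
                                                   n_intron_targets=5))
        for gm in bundle.gene_models.values():
            total = sum(
                i.length for part in (gm.utr5, gm.cds, gm.utr3) for i in part
            )
            assert total == gm.exonic_length
            # introns exactly tile inter-exon gaps
            gaps = sum(
                b.start - a.end for a, b in zip(gm.exons, gm.exons[1:])
            )
            assert sum(i.length for i in gm.introns) == gaps


@settings(max_examples=60, derandomize=True)
@given(
    strand=st.sampled_from("+-"),
    utr_a=st.integers(1, 400),
    cds_len=st.integers(1, 2000),
    utr_b=st.integers(1, 400),
    gap=st.integers(0, 1500),
    break_off=st.integers(1, 200),
)
def test_partition_property_random_genes(strand, utr_a, cds_len, utr_b, gap,
                                         break_off):
    """For any coding gene the UTR5/CDS/UTR3 lengths tile the exonic span,
    and introns tile exactly the inter-exon gaps."""
    exonic = utr_a + cds_len + utr_b
    break_at = min(break_off, exonic - 1)
    if gap > 0:
        exons = [(1000, 1000 + break_at),
                 (1000 + break_at + gap, 1000 + exonic + gap)]
    else:
        exons = [(1000, 1000 + exonic)]
    cs = 1000 + utr_a + (gap if utr_a >= break_at and gap > 0 else 0)
    gm = GeneModel.from_exons("g", "chr1", strand, exons,
                              (cs, cs + cds_len), downstream=5000)
    in_cds = sum(i.length for i in gm.cds)
    total = sum(i.length for part in (gm.utr5, gm.cds, gm.utr3) for i in part)
    assert total == gm.exonic_length
    assert in_cds <= cds_len
    assert sum(i.length for i in gm.introns) == (gap if gap > 0 else 0)


class TestAssignRegion:
    def test_containment(self, toy_gene):
        iv = GenomicInterval("chr1", 250, 260, "+")
        assert assign_region(iv, toy_gene) == {"UTR3"}

    def test_boundary_spanning_modes(self, toy_gene):
        iv = GenomicInterval("chr1", 140, 160, "+")  # CDS into intron
        assert assign_region(iv, toy_gene, "non_exclusive") == {"CDS", "intron"}
        assert assign_region(iv, toy_gene, "exclusive") == {"CDS"}

    def test_downstream_extension(self, toy_gene):
        iv = GenomicInterval("chr1", 5300, 5320, "+")  # 5 kb past 3' end
        assert assign_region(iv, toy_gene) == {"downstream"}

    def test_outside_everything(self, toy_gene):
        iv = GenomicInterval("chr1", 50_000, 50_010, "+")
        assert assign_region(iv, toy_gene) == {"none"}

    def test_exclusive_subset_of_non_exclusive(self, toy_gene, rng):
        for _ in range(50):
            s = int(rng.integers(90, 11_000))
            iv = GenomicInterval("chr1", s, s + int(rng.integers(1, 200)), "+")
            ne = assign_region(iv, toy_gene, "non_exclusive")
            ex = assign_region(iv, toy_gene, "exclusive")
            assert ex <= ne or ex == {"none"}

    def test_wrong_strand_rejected(self, toy_gene):
        with pytest.raises(ValueError):
            assign_region(GenomicInterval("chr1", 250, 260, "-"), toy_gene)


class TestDistanceToEnd:
    def test_upstream_midpoint(self, toy_gene):
        # tx_end=300 (3' base 299); interval [285,295) midpoint 289 -> -10
        iv = GenomicInterval("chr1", 285, 295, "+")
        assert distance_to_transcript_end(iv, toy_gene) == -10

    def test_midpoint_at_end_is_zero(self, toy_gene):
        iv = GenomicInterval("chr1", 299, 300, "+")
        assert distance_to_transcript_end(iv, toy_gene) == 0

    def test_minus_strand_downstream_is_positive(self, toy_gene_minus):
        # 3' end of a minus-strand gene = tx_start = 100
        iv = GenomicInterval("chr1", 80, 90, "-")
        assert distance_to_transcript_end(iv, toy_gene_minus) > 0

    def test_even_length_rounds_toward_5prime(self):
        plus = GeneModel.from_exons("p", "chr1", "+", [(0, 100)], (0, 100))
        minus = GeneModel.from_exons("m", "chr1", "-", [(0, 100)], (0, 100))
        iv_p = GenomicInterval("chr1", 10, 14, "+")  # positions 10..13
        iv_m = GenomicInterval("chr1", 10, 14, "-")
        # + strand 5' side is the left: midpoint 11; - strand: midpoint 12
        assert distance_to_transcript_end(iv_p, plus) == 11 - 99
        assert distance_to_transcript_end(iv_m, minus) == 0 - 12


class TestLoaders:
    BED12 = (
        "chr1\t100\t300\ttoy\t0\t+\t120\t180\t0\t2\t50,60,\t0,140,\n"
        "chr2\t0\t500\tnc\t0\t-\t0\t0\t0\t1\t500,\t0,\n"
    )

    def test_bed12_round_partition(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text(self.BED12)
        models = load_gene_models(p, "BED12")
        gm = models["toy"]
        assert sum(i.length for i in gm.cds) == 30
        assert sum(i.length for i in gm.utr3) == 60
        assert not models["nc"].is_coding

    def test_gtf_matches_bed12(self, tmp_path):
        gtf = (
            'chr1\tx\texon\t101\t150\t.\t+\t.\tgene_id "toy"; transcript_id "t1";\n'
            'chr1\tx\texon\t241\t300\t.\t+\t.\tgene_id "toy"; transcript_id "t1";\n'
            'chr1\tx\tCDS\t121\t150\t.\t+\t.\tgene_id "toy"; transcript_id "t1";\n'
        )
        p = tmp_path / "genes.gtf"
        p.write_text(gtf)
        models = load_gene_models(p, "GTF")
        gm = models["toy"]
        assert (gm.tx_start, gm.tx_end) == (100, 300)
        assert sum(i.length for i in gm.utr5) == 20
        # CDS span extends to the thick end seen in CDS features only
        assert gm.cds[0].start == 120

    def test_malformed_bed12_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t300\ttoy\t0\t+\t120\n")
        with pytest.raises(ValueError, match="line 1"):
            load_gene_models(p, "BED12")

    def test_region_track_writer(self, toy_gene, tmp_path):
        from clipshift.annotation import write_regions_bed

        p = tmp_path / "regions.bed"
        write_regions_bed([toy_gene], p)
        lines = [ln.split("\t") for ln in p.read_text().splitlines()]
        assert all(len(f) == 6 and int(f[1]) < int(f[2]) for f in lines)
        labels = {f[3].split(":")[1] for f in lines}
        assert {"UTR3", "CDS", "UTR5", "intron", "downstream"} <= labels

    def test_isoform_union_collapse(self, tmp_path):
        two_tx = (
            'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "a";\n'
            'chr1\tx\tCDS\t121\t200\t.\t+\t.\tgene_id "g"; transcript_id "a";\n'
            'chr1\tx\texon\t151\t260\t.\t+\t.\tgene_id "g"; transcript_id "b";\n'
            'chr1\tx\tCDS\t151\t240\t.\t+\t.\tgene_id "g"; transcript_id "b";\n'
        )
        p = tmp_path / "iso.gtf"
        p.write_text(two_tx)
        gm = load_gene_models(p, "GTF")["g"]
        assert (gm.tx_start, gm.tx_end) == (100, 260)  # union of exons
        # CDS from the longest coding transcript (b: 90 nt > a: 79 nt)
        assert gm.cds[0].start == 150
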