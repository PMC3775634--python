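"""Pileup tallies, site/background fractions and the Yates chi-square
site-vs-background test."""

import numpy as np
import pytest
from scipy import stats

from edscan.genemodel import COMPLEMENT, GeneModel
from edscan.pileup import (
    BaseCallTally,
    CATEGORIES,
    ReadFilterConfig,
    UndefinedStatisticError,
    background_fraction,
    call_editing_site,
    read_snp_positions,
    read_tally_tsv,
    site_fraction,
    tally_from_alignments,
    write_tally_tsv,
    yates_chi_square,
)
from edscan.simulate import PileupSimConfig, simulate_alignments, simulate_tally

from conftest import random_locus, revcomp


def recount_sam(sam_path, model):
    """Independent brute-force recount oracle: parse the SAM text
    directly (simulated reads are fully matched, quality 'I')."""
    counts = np.zeros((model.cds_length, 5), dtype=np.int64)
    cat = {c: i for i, c in enumerate(CATEGORIES)}
    minus = model.strand == "-"
    for line in open(sam_path):
        if line.startswith("@"):
            continue
        f = line.rstrip("\n").split("\t")
        chrom, pos, cigar, seq = f[2], int(f[3]) - 1, f[5], f[9]
        assert chrom == model.chrom and cigar == f"{len(seq)}M"
        for i, base in enumerate(seq):
            cds = model.map_genome_to_cds(pos + i)
            if cds is None:
                continue
            b = COMPLEMENT[base] if minus else base
            counts[cds - 1, cat[b if b in "ACGT" else "ambiguous"]] += 1
    return counts


def tally_with(counts_by_pos, length):
    t = BaseCallTally.zeros(length)
    for pos, d in counts_by_pos.items():
        for base, n in d.items():
            t.add(pos, base, n)
    return t


class TestTallyFromAlignments:
    def test_error_free_reads_match_reference(self, tmp_path):
        rng = np.random.default_rng(0)
        model, genome = random_locus(rng, n_exons=2, strand="+")
        cfg = PileupSimConfig(
            model=model, reference=genome, seed=1, depth=10, error_rate=0.0, read_length=20
        )
        sam = tmp_path / "r.sam"
        simulate_alignments(cfg, sam)
        t = tally_from_alignments(sam, model)
        for pos in range(1, model.cds_length + 1):
            ref = model.cds_sequence[pos - 1]
            assert t.count(pos, ref) == t.depth(pos)  # only reference calls

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_brute_force_recount(self, tmp_path, strand):
        rng = np.random.default_rng(3)
        model, genome = random_locus(rng, n_exons=3, strand=strand)
        edit_pos = next(
            p for p in range(1, model.cds_length + 1) if model.transcript_base(p) == "C"
        )
        cfg = PileupSimConfig(
            model=model,
            reference=genome,
            seed=9,
            depth=200,
            error_rate=0.01,
            edits={edit_pos: 0.2},
            read_length=25,
        )
        sam = tmp_path / "r.sam"
        simulate_alignments(cfg, sam)
        t = tally_from_alignments(sam, model)
        np.testing.assert_array_equal(t.counts, recount_sam(sam, model))

    def test_minus_strand_complementation(self, tmp_path):
        """A plus-strand read carrying A at the genomic spot of a CDS C
        site on a minus-strand gene is tallied as T."""
        cds = "ATGCCCGGGTAA"
        exons = ((100, 112),)
        model = GeneModel("g", "chrT", "-", exons, exons, cds)
        gpos, pbase, tbase = model.map_cds_to_genome(4)  # a C site
        assert tbase == "C" and pbase == "G"
        plus_seq = revcomp(cds)
        read = plus_seq[: gpos - 100] + "A" + plus_seq[gpos - 100 + 1 :]
        sam = tmp_path / "hand.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chrT\tLN:300\n"
            f"r1\t0\tchrT\t101\t60\t12M\t*\t0\t0\t{read}\t{'I' * 12}\n"
        )
        t = tally_from_alignments(sam, model)
        assert t.count(4, "T") == 1
        assert t.count(4, "C") == 0

    def test_filters_and_ambiguity(self, tmp_path):
        cds = "ATGAAACCCTGA"
        exons = ((10, 22),)
        model = GeneModel("g", "chrT", "+", exons, exons, cds)
        # read1 clean; read2 duplicate; read3 secondary; read4 low mapq;
        # read5 has an N (ambiguous) and a low-quality base (dropped)
        quals = "I" * 12
        low_first = "#" + "I" * 11  # Phred 2 at first base
        lines = [
            "@HD\tVN:1.6",
            "@SQ\tSN:chrT\tLN:100",
            f"r1\t0\tchrT\t11\t60\t12M\t*\t0\t0\t{cds}\t{quals}",
            f"r2\t1024\tchrT\t11\t60\t12M\t*\t0\t0\t{cds}\t{quals}",
            f"r3\t256\tchrT\t11\t60\t12M\t*\t0\t0\t{cds}\t{quals}",
            f"r4\t0\tchrT\t11\t5\t12M\t*\t0\t0\t{cds}\t{quals}",
            f"r5\t0\tchrT\t11\t60\t12M\t*\t0\t0\tN{cds[1:]}\t{low_first}",
        ]
        sam = tmp_path / "f.sam"
        sam.write_text("\n".join(lines) + "\n")
        t = tally_from_alignments(
            sam, model, ReadFilterConfig(min_base_quality=13, min_mapping_quality=10)
        )
        # position 1: r1 counts A; r5's N is below the quality floor -> dropped
        assert t.depth(1) == 1 and t.count(1, "A") == 1
        # other positions: r1 + r5 pass
        assert t.depth(2) == 2
        # ambiguous category: N at high quality
        sam2 = tmp_path / "n.sam"
        sam2.write_text(
            "\n".join(lines[:2] + [f"r6\t0\tchrT\t11\t60\t12M\t*\t0\t0\tN{cds[1:]}\t{quals}"])
            + "\n"
        )
        t2 = tally_from_alignments(sam2, model)
        assert t2.count(1, "ambiguous") == 1

    def test_deletion_counts_ambiguous(self, tmp_path):
        cds = "ATGAAACCCTGA"
        exons = ((10, 22),)
        model = GeneModel("g", "chrT", "+", exons, exons, cds)
        sam = tmp_path / "d.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chrT\tLN:100\n"
            f"r1\t0\tchrT\t11\t60\t3M1D8M\t*\t0\t0\t{cds[:3] + cds[4:]}\t{'I' * 11}\n"
        )
        t = tally_from_alignments(sam, model)
        assert t.count(4, "ambiguous") == 1

    def test_missing_chromosome_errors(self, tmp_path):
        cds = "ATGAAACCCTGA"
        model = GeneModel("g", "chrZ", "+", ((10, 22),), ((10, 22),), cds)
        sam = tmp_path / "e.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:chrT\tLN:100\n")
        with pytest.raises(ValueError, match="chrZ"):
            tally_from_alignments(sam, model)

    def test_category_conservation(self, tmp_path, sdhb_locus):
        model, genome = sdhb_locus
        cfg = PileupSimConfig(
            model=model, reference=genome, seed=4, depth=30, error_rate=0.01, edits={136: 0.3}
        )
        sam = tmp_path / "c.sam"
        simulate_alignments(cfg, sam)
        t = tally_from_alignments(sam, model)
        assert (t.counts.sum(axis=1) == t.filtered_depth).all()
        assert t.filtered_depth.min() > 0

    def test_tsv_round_trip(self, tmp_path, sdhb_model):
        t, _ = simulate_tally(
            PileupSimConfig(model=sdhb_model, reference="", seed=5, depth=50, error_rate=0.01)
        )
        p = tmp_path / "t.tsv"
        write_tally_tsv(t, p, sdhb_model)
        t2 = read_tally_tsv(p)
        np.testing.assert_array_equal(t.counts, t2.counts)


class TestFractions:
    def test_site_fraction_arithmetic(self):
        t = tally_with({10: {"C": 983, "T": 17}}, 20)
        frac, edited, depth = site_fraction(t, 10, "T")
        assert (frac, edited, depth) == (17 / 1000, 17, 1000)

    def test_site_fraction_extremes(self):
        t = tally_with({1: {"C": 100}, 2: {"T": 100}}, 3)
        assert site_fraction(t, 1, "T")[0] == 0.0
        assert site_fraction(t, 2, "T")[0] == 1.0
        with pytest.raises(UndefinedStatisticError):
            site_fraction(t, 3, "T")

    def test_ambiguous_in_denominator_toggle(self):
        t = tally_with({1: {"C": 90, "T": 5, "ambiguous": 5}}, 1)
        assert site_fraction(t, 1, "T")[0] == pytest.approx(0.05)
        assert site_fraction(t, 1, "T", include_ambiguous_in_depth=False)[0] == pytest.approx(
            5 / 95
        )

    def test_background_pooled_arithmetic(self):
        m = GeneModel("g", "c", "+", ((0, 6),), ((0, 6),), "CCAGTT")  # C at c.1 and c.2
        t = tally_with({1: {"C": 990, "T": 10}, 2: {"C": 1000}}, 6)
        frac, edited, depth = background_fraction(t, m, "C", "T")
        assert (edited, depth) == (10, 2000)
        assert frac == pytest.approx(0.005)

    def test_background_error_free_is_zero(self, sdhb_model):
        t, _ = simulate_tally(
            PileupSimConfig(model=sdhb_model, reference="", seed=6, depth=100, error_rate=0.0)
        )
        assert background_fraction(t, sdhb_model)[0] == 0.0

    def test_background_matches_error_spectrum(self, sdhb_model):
        """Uniform error spectrum eps gives a pooled T-at-C fraction of
        eps/3 within 3 binomial SD."""
        eps = 0.0012
        t, _ = simulate_tally(
            PileupSimConfig(model=sdhb_model, reference="", seed=7, depth=2000, error_rate=eps)
        )
        frac, edited, depth = background_fraction(t, sdhb_model)
        expect = eps / 3
        sd = np.sqrt(expect * (1 - expect) / depth)
        assert abs(frac - expect) <= 3 * sd

    def test_exclude_query_site(self, sdhb_model):
        t, _ = simulate_tally(
            PileupSimConfig(
                model=sdhb_model, reference="", seed=8, depth=500, error_rate=0.0, edits={136: 0.5}
            )
        )
        incl = background_fraction(t, sdhb_model, include_query_site=True)
        excl = background_fraction(t, sdhb_model, include_query_site=False, query_site=136)
        assert incl[2] - excl[2] == t.depth(136)
        assert excl[0] == 0.0 and incl[0] > 0

    def test_background_undefined_without_depth(self, sdhb_model):
        t = BaseCallTally.zeros(sdhb_model.cds_length)
        with pytest.raises(UndefinedStatisticError):
            background_fraction(t, sdhb_model)


class TestYatesChiSquare:
    def test_identical_rows(self):
        chi2, p = yates_chi_square(5, 95, 5, 95)
        assert chi2 == 0.0 and p == 1.0

    def test_site_vs_background_example(self):
        chi2, p = yates_chi_square(5, 95, 10, 9990)
        assert chi2 == pytest.approx(129.0, abs=0.5)
        assert p < 1e-20

    def test_correction_saturates(self):
        # |ad - bc| <= N/2 -> statistic clipped to zero
        chi2, p = yates_chi_square(1, 10, 1, 11)
        assert chi2 == 0.0 and p == 1.0

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            a, b, c, d = rng.integers(1, 400, size=4)
            chi2, p = yates_chi_square(a, b, c, d)
            s_chi2, s_p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=True)
            assert chi2 == pytest.approx(s_chi2, abs=1e-9)
            assert p == pytest.approx(s_p, abs=1e-9)

    def test_zero_marginal_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            yates_chi_square(0, 0, 5, 5)


class TestCallEditingSite:
    def test_detects_low_fraction_editing_at_depth(self, sdhb_model):
        """f = 0.017 at depth 5000 over a 0.1% error background is
        called with P < 0.001."""
        t, _ = simulate_tally(
            PileupSimConfig(
                model=sdhb_model,
                reference="",
                seed=13,
                depth=5000,
                error_rate=0.001,
                edits={136: 0.017},
            )
        )
        call = call_editing_site(t, sdhb_model, 136)
        assert call.p_value < 0.001
        assert call.site_fraction > call.background_fraction
        assert not call.snp_overlap

    def test_snp_overlap_flag(self, sdhb_model):
        t, _ = simulate_tally(
            PileupSimConfig(model=sdhb_model, reference="", seed=14, depth=100, error_rate=0.001)
        )
        gpos = sdhb_model.map_cds_to_genome(136)[0]
        call = call_editing_site(
            t, sdhb_model, 136, snp_positions=[(sdhb_model.chrom, gpos)]
        )
        assert call.snp_overlap
        call2 = call_editing_site(
            t, sdhb_model, 136, snp_positions=[(sdhb_model.chrom, gpos + 1), ("chrX", gpos)]
        )
        assert not call2.snp_overlap

    def test_strand_invariance_of_simulated_tally(self, sdhb_model):
        """The same molecule population on the minus-strand model and on
        a plus-strand mirror yields the identical transcript-orientation
        tally under the same seed."""
        mirror = GeneModel(
            "mir", "chrM1", "+", sdhb_model.exons, sdhb_model.exons, sdhb_model.cds_sequence
        )
        cfg = dict(reference="", seed=15, depth=300, error_rate=0.002, edits={136: 0.1})
        t_minus, _ = simulate_tally(PileupSimConfig(model=sdhb_model, **cfg))
        t_plus, _ = simulate_tally(PileupSimConfig(model=mirror, **cfg))
        np.testing.assert_array_equal(t_minus.counts, t_plus.counts)


class TestSnpInput:
    def test_tsv_and_vcf(self, tmp_path):
        tsv = tmp_path / "snps.tsv"
        tsv.write_text("chr1\t101\nchr2\t5\n")
        assert read_snp_positions(tsv) == [("chr1", 100), ("chr2", 4)]
        vcf = tmp_path / "snps.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t101\t.\tC\tT\t.\t.\t.\n"
        )
        assert read_snp_positions(vcf) == [("chr1", 100)]
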