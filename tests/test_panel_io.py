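"""Panel containers, haps/VCF round trips, allele alignment, and filters."""

import numpy as np
import pandas as pd
import pytest

from kirimp.panel_io import (
    MISSING,
    AlignmentAction,
    HaplotypePanel,
    KirTypeTable,
    PanelFormatError,
    PanelValidationError,
    SnpDefinition,
    align_alleles,
    drop_monomorphic,
    filter_by_region,
    read_haps,
    read_kir_types,
    read_vcf_phased,
    write_haps,
    write_vcf_phased,
)


def make_panel(matrix, positions=None, alleles=None, ids=None):
    matrix = np.asarray(matrix, dtype=np.int8)
    n, p = matrix.shape
    positions = positions or [1000 * (j + 1) for j in range(p)]
    alleles = alleles or [("A", "G")] * p
    snps = [
        SnpDefinition(snp_id=f"snp{j}", position=positions[j],
                      allele1=alleles[j][0], allele2=alleles[j][1])
        for j in range(p)
    ]
    ids = ids or [f"h{i}" for i in range(n)]
    return HaplotypePanel(snps=snps, haplotype_ids=ids, alleles=matrix)


class TestHapsFormat:
    def test_well_formed_file_parses(self, tmp_path):
        haps = tmp_path / "t.haps"
        sample = tmp_path / "t.sample"
        haps.write_text(
            "19 rs1 100 A G 0 1 0 1\n"
            "19 rs2 200 C T 1 1 0 0\n"
        )
        sample.write_text("ID_1 ID_2 missing\n0 0 0\ns1 s1 0\ns2 s2 0\n")
        panel = read_haps(haps, sample)
        assert panel.n_haplotypes == 4
        assert panel.n_snps == 2
        assert panel.haplotype_ids == ["s1_1", "s1_2", "s2_1", "s2_2"]
        assert panel.alleles[:, 0].tolist() == [0, 1, 0, 1]

    def test_ragged_row_names_line_number(self, tmp_path):
        haps = tmp_path / "t.haps"
        sample = tmp_path / "t.sample"
        haps.write_text("19 rs1 100 A G 0 1 0 1\n19 rs2 200 C T 1 1\n")
        sample.write_text("ID_1 ID_2 missing\n0 0 0\ns1 s1 0\ns2 s2 0\n")
        with pytest.raises(PanelFormatError, match="line 2"):
            read_haps(haps, sample)

    def test_bad_allele_token_rejected(self, tmp_path):
        haps = tmp_path / "t.haps"
        sample = tmp_path / "t.sample"
        haps.write_text("19 rs1 100 A G 0 2\n")
        sample.write_text("ID_1 ID_2 missing\n0 0 0\ns1 s1 0\n")
        with pytest.raises(PanelFormatError, match="'2'"):
            read_haps(haps, sample)

    def test_duplicate_snp_id_named(self, tmp_path):
        haps = tmp_path / "t.haps"
        sample = tmp_path / "t.sample"
        haps.write_text("19 rs1 100 A G 0 1\n19 rs1 200 C T 1 0\n")
        sample.write_text("ID_1 ID_2 missing\n0 0 0\ns1 s1 0\n")
        with pytest.raises(PanelFormatError, match="rs1"):
            read_haps(haps, sample)

    @pytest.mark.parametrize("seed", range(8))
    def test_round_trip_is_identity(self, seed, tmp_path):
        rnd = np.random.default_rng(seed)
        n_samples = int(rnd.integers(1, 6))
        n_snps = int(rnd.integers(1, 7))
        matrix = rnd.choice([0, 1, MISSING], size=(2 * n_samples, n_snps),
                            p=[0.45, 0.45, 0.1]).astype(np.int8)
        panel = make_panel(matrix, ids=[f"s{i//2}_{i%2+1}" for i in range(2 * n_samples)])
        write_haps(panel, tmp_path / "x.haps", tmp_path / "x.sample")
        back = read_haps(tmp_path / "x.haps", tmp_path / "x.sample")
        assert np.array_equal(back.alleles, panel.alleles)
        assert back.snp_ids == panel.snp_ids
        assert back.haplotype_ids == panel.haplotype_ids


class TestVcf:
    def test_phased_records_parse(self, tmp_path):
        matrix = np.array([[0, 1, 1], [1, 0, 1], [0, 0, 0], [1, 1, 0]], dtype=np.int8)
        panel = make_panel(matrix, ids=["s1_1", "s1_2", "s2_1", "s2_2"])
        path = tmp_path / "x.vcf"
        write_vcf_phased(panel, path)
        back = read_vcf_phased(path)
        assert back.n_haplotypes == 4
        assert back.n_snps == 3
        assert np.array_equal(back.alleles, panel.alleles)

    def test_unphased_record_skipped(self, tmp_path):
        path = tmp_path / "u.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=19>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "19\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\n"
            "19\t200\trs2\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
        )
        panel = read_vcf_phased(path)
        assert panel.n_snps == 1
        assert panel.skipped_records == 1

    def test_no_usable_records_errors(self, tmp_path):
        path = tmp_path / "e.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=19>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "19\t200\trs2\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(PanelFormatError):
            read_vcf_phased(path)

    def test_cross_format_agreement(self, tmp_path):
        rnd = np.random.default_rng(4)
        matrix = rnd.integers(0, 2, size=(6, 5)).astype(np.int8)
        panel = make_panel(matrix, ids=[f"s{i//2}_{i%2+1}" for i in range(6)])
        write_haps(panel, tmp_path / "x.haps", tmp_path / "x.sample")
        write_vcf_phased(panel, tmp_path / "x.vcf")
        from_haps = read_haps(tmp_path / "x.haps", tmp_path / "x.sample")
        from_vcf = read_vcf_phased(tmp_path / "x.vcf")
        assert np.array_equal(from_haps.alleles, from_vcf.alleles)
        assert [s.position for s in from_haps.snps] == [s.position for s in from_vcf.snps]


class TestKirTypeTable:
    def test_copy_number_table_valid(self, tmp_path):
        path = tmp_path / "k.tsv"
        path.write_text("id\tKIR2DS2\tKIR2DL2\nh1\t0\t1\nh2\t2\t1\n")
        table = read_kir_types(path, unit="haplotype")
        assert table.loci == ["KIR2DS2", "KIR2DL2"]
        assert table.values.loc["h2", "KIR2DS2"] == 2

    def test_individual_table_rejects_haplotype_loci(self, tmp_path):
        path = tmp_path / "k.tsv"
        path.write_text("id\tKIR2DS2\tKIRhaplotype\ni1\t1\tcA01-tA01\n")
        with pytest.raises(PanelValidationError, match="per haplotype"):
            read_kir_types(path, unit="individual")

    def test_empty_cell_is_missing(self, tmp_path):
        path = tmp_path / "k.tsv"
        path.write_text("id\tKIR2DS2\nh1\t1\nh2\t\n")
        table = read_kir_types(path, unit="haplotype")
        assert pd.isna(table.values.loc["h2", "KIR2DS2"])

    def test_negative_copy_number_rejected(self):
        with pytest.raises(PanelValidationError, match="negative"):
            KirTypeTable(unit="haplotype",
                         values=pd.DataFrame({"KIR2DS2": [-1]}, index=["h1"]))

    def test_avsb_outside_ab_rejected(self):
        with pytest.raises(PanelValidationError, match="AvsB"):
            KirTypeTable(unit="haplotype",
                         values=pd.DataFrame({"AvsB": ["C"]}, index=["h1"]))

    def test_unknown_locus_needs_allow_extra(self, tmp_path):
        path = tmp_path / "k.tsv"
        path.write_text("id\tNOTALOCUS\nh1\t1\n")
        with pytest.raises(PanelValidationError, match="NOTALOCUS"):
            read_kir_types(path, unit="haplotype")
        table = read_kir_types(path, unit="haplotype", allow_extra=True)
        assert "NOTALOCUS" in table.loci


class TestAlignAlleles:
    def test_swapped_coding_inverts_bits(self):
        ref = make_panel([[0], [0], [1], [1]], alleles=[("A", "G")])
        qry = make_panel([[0], [1], [1], [1]], alleles=[("G", "A")])
        aligned, report = align_alleles(ref, qry)
        assert report.records.action.tolist() == [AlignmentAction.SWAPPED_CODING.value]
        assert aligned.alleles[:, 0].tolist() == [1, 0, 0, 0]
        assert (aligned.snps[0].allele1, aligned.snps[0].allele2) == ("A", "G")

    def test_strand_flip_matches_complement(self):
        ref = make_panel([[0], [1], [0], [1]], alleles=[("A", "G")])
        qry = make_panel([[0], [1], [0], [0]], alleles=[("T", "C")])
        aligned, report = align_alleles(ref, qry)
        assert report.records.action.tolist() == [AlignmentAction.STRAND_FLIPPED.value]
        # complement of T/C is A/G in the same order: bits unchanged
        assert aligned.alleles[:, 0].tolist() == [0, 1, 0, 0]

    def test_ambiguous_pair_resolved_by_frequency(self):
        # reference allele-1 frequency 0.30; query freq(A)=0.69 so the
        # inverted coding matches within tolerance 0.1
        ref = make_panel([[0]] * 3 + [[1]] * 7, alleles=[("A", "T")])
        qry = make_panel([[0]] * 9 + [[1]] * 4, alleles=[("A", "T")])
        aligned, report = align_alleles(ref, qry, freq_tol=0.1)
        assert report.records.action.tolist() == [AlignmentAction.SWAPPED_CODING.value]
        assert aligned.alleles[:5, 0].tolist() == [1, 1, 1, 1, 1]

    def test_ambiguous_pair_unresolvable_dropped(self):
        ref = make_panel([[0], [1], [0], [1]], alleles=[("C", "G")])  # freq 0.5
        qry = make_panel([[0], [1], [0], [0]], alleles=[("C", "G")])  # freq 0.75
        aligned, report = align_alleles(ref, qry, freq_tol=0.1)
        assert report.records.action.tolist() == [AlignmentAction.DROPPED_AMBIGUOUS.value]
        assert aligned.n_snps == 0

    def test_absent_position_dropped(self):
        ref = make_panel([[0], [1]], positions=[1000])
        qry = make_panel([[0, 1], [1, 0]], positions=[1000, 2000])
        aligned, report = align_alleles(ref, qry)
        assert report.action_counts()[AlignmentAction.DROPPED_ABSENT.value] == 1
        assert aligned.n_snps == 1

    def test_no_shared_positions_errors(self):
        ref = make_panel([[0], [1]], positions=[1000])
        qry = make_panel([[0], [1]], positions=[2000])
        with pytest.raises(PanelValidationError, match="shared"):
            align_alleles(ref, qry)

    def test_idempotent_on_aligned_panel(self):
        rnd = np.random.default_rng(9)
        matrix = rnd.integers(0, 2, size=(20, 6)).astype(np.int8)
        ref = make_panel(matrix, alleles=[("A", "G"), ("C", "T"), ("A", "C"),
                                          ("G", "T"), ("A", "G"), ("C", "T")])
        qry = make_panel(rnd.integers(0, 2, size=(20, 6)).astype(np.int8),
                         alleles=[("G", "A"), ("C", "T"), ("A", "C"),
                                  ("T", "G"), ("A", "G"), ("T", "C")])
        aligned, _ = align_alleles(ref, qry)
        again, report = align_alleles(ref, aligned)
        actions = set(report.records.action)
        assert actions == {AlignmentAction.KEPT_AS_IS.value}
        assert np.array_equal(again.alleles, aligned.alleles)


class TestFilters:
    def test_region_filter_closed_interval(self):
        panel = make_panel(np.zeros((2, 3), dtype=np.int8) + [[0], [1]],
                           positions=[55_245_738, 53_000_000 + 1, 56_000_000])
        kept = filter_by_region(panel, 55.1e6, 55.5e6)
        assert [s.position for s in kept.snps] == [55_245_738]

    def test_extended_region_excludes_below_cutoff(self):
        panel = make_panel([[0, 0], [1, 1]], positions=[53_000_000, 55_300_000])
        kept = filter_by_region(panel, 53.6e6, 60e6)
        assert kept.n_snps == 1 and kept.snps[0].position == 55_300_000

    def test_full_window_is_identity_and_idempotent(self):
        rnd = np.random.default_rng(2)
        panel = make_panel(rnd.integers(0, 2, (4, 5)).astype(np.int8))
        once = filter_by_region(panel, 0, 1e9)
        twice = filter_by_region(once, 0, 1e9)
        assert np.array_equal(once.alleles, panel.alleles)
        assert np.array_equal(twice.alleles, once.alleles)

    def test_drop_monomorphic_counts(self):
        # 1,118 SNPs of which exactly 40 constant leaves 1,078
        rnd = np.random.default_rng(7)
        matrix = rnd.integers(0, 2, size=(8, 1118)).astype(np.int8)
        matrix[0, :] = 0
        matrix[1, :] = 1  # guarantee polymorphism everywhere...
        mono = rnd.choice(1118, size=40, replace=False)
        matrix[:, mono] = 0  # ...then force 40 monomorphic columns
        panel = make_panel(matrix)
        kept = drop_monomorphic(panel)
        assert kept.n_snps == 1078

    def test_all_monomorphic_errors(self):
        panel = make_panel(np.zeros((3, 2), dtype=np.int8))
        with pytest.raises(PanelValidationError):
            drop_monomorphic(panel)


class TestInvariants:
    def test_snps_sorted_and_duplicates_rejected(self):
        snps = [
            SnpDefinition("b", 200, "A", "G"),
            SnpDefinition("a", 100, "C", "T"),
        ]
        panel = HaplotypePanel(snps=snps, haplotype_ids=["h1"],
                               alleles=np.array([[1, 0]], dtype=np.int8))
        assert panel.positions.tolist() == [100, 200]
        assert panel.alleles[0].tolist() == [0, 1]
        with pytest.raises(PanelValidationError, match="duplicate"):
            HaplotypePanel(
                snps=[SnpDefinition("a", 100, "A", "G"), SnpDefinition("b", 100, "C", "T")],
                haplotype_ids=["h1"], alleles=np.array([[0, 1]], dtype=np.int8),
            )

    def test_snp_definition_validation(self):
        with pytest.raises(PanelValidationError):
            SnpDefinition("x", 0, "A", "G")
        with pytest.raises(PanelValidationError):
            SnpDefinition("x", 10, "A", "A")
        with pytest.raises(PanelValidationError):
            SnpDefinition("x", 10, "A", "N")

    def test_ambiguous_frequency_bound_holds_after_alignment(self):
        rnd = np.random.default_rng(33)
        ref = make_panel(rnd.integers(0, 2, (40, 4)).astype(np.int8),
                         alleles=[("A", "T"), ("C", "G"), ("A", "T"), ("C", "G")])
        qry = make_panel(rnd.integers(0, 2, (40, 4)).astype(np.int8),
                         alleles=[("A", "T"), ("C", "G"), ("T", "A"), ("G", "C")])
        aligned, report = align_alleles(ref, qry, freq_tol=0.15)
        kept = report.records[report.records.action != AlignmentAction.DROPPED_AMBIGUOUS.value]
        assert (kept.freq_diff <= 0.15 + 1e-12).all()
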