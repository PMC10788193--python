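"""Allele counting from SAM records and the eSNP filter cascade."""

import numpy as np
import pandas as pd
import pytest

from ednapop import (
    AlleleCountMatrix,
    LakeScenario,
    SnpPanel,
    count_alleles,
    filter_esnps,
    locate_snps,
    simulate_scenario,
    synthetic_panel,
    variable_snps,
    write_sam_reads,
)


def make_panel(pos=111, ref="A", alt="G"):
    """One-SNP panel on chrTest: amplicon [100, 200), SNP 1-based pos."""
    return SnpPanel(pd.DataFrame([dict(
        snp_id="s1", chrom="chrTest", pos=pos, ref_allele=ref, alt_allele=alt,
        locus_id="L1", amp_start=100, amp_end=200,
    )]))


HEADER = "@HD\tVN:1.6\n@SQ\tSN:chrTest\tLN:1000\n"


def sam_line(pos1, cigar, seq, qname="r1", flag=0, mapq=60, qual=None):
    qual = qual or "I" * len(seq)
    return f"{qname}\t{flag}\tchrTest\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}\n"


def count_from_text(text, panel, **kw):
    import tempfile, os

    with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as fh:
        fh.write(text)
        path = fh.name
    try:
        return count_alleles(path, panel, **kw)
    finally:
        os.unlink(path)


def brute_force_read_index(pos1, cigar, target_pos1):
    """Independent CIGAR walk: reconstruct (read_index, ref_pos) pairs
    base by base and return the read index aligned to target_pos1."""
    import re

    qpos, rpos = 0, pos1
    for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        n = int(n)
        if op in "M=X":
            for _ in range(n):
                if rpos == target_pos1:
                    return qpos
                qpos += 1
                rpos += 1
        elif op in "IS":
            qpos += n
        elif op in "DN":
            rpos += n
    return None


class TestCigarWalk:
    def test_all_match_ref_base(self):
        panel = make_panel(pos=111)  # offset 10 into a read at pos 101
        text = HEADER + sam_line(101, "50M", "C" * 10 + "A" + "C" * 39)
        counts = count_from_text(text, panel)
        assert counts.ref[0, 0] == 1 and counts.alt[0, 0] == 0

    def test_insertion_shifts_read_index(self):
        # CIGAR 10M2I40M from pos p: reference offset 15 -> read index 17
        p = 101
        panel = make_panel(pos=p + 15)
        seq = list("C" * 52)
        idx = brute_force_read_index(p, "10M2I40M", p + 15)
        assert idx == 17
        seq[idx] = "A"
        counts = count_from_text(HEADER + sam_line(p, "10M2I40M", "".join(seq)), panel)
        assert counts.ref[0, 0] == 1

    @pytest.mark.parametrize("cigar,read_len", [
        ("50M", 50), ("5S45M", 50), ("20M3D30M", 50), ("10M2I38M", 50),
        ("3S10M1I10M2D26M", 50),
    ])
    def test_matches_brute_force_walker(self, cigar, read_len):
        p = 120
        panel = make_panel(pos=p + 22)
        idx = brute_force_read_index(p, cigar, p + 22)
        seq = ["C"] * read_len
        if idx is not None:
            seq[idx] = "G"  # alt allele
        counts = count_from_text(HEADER + sam_line(p, cigar, "".join(seq)), panel)
        expected_alt = 1 if idx is not None else 0
        assert counts.alt.sum() == expected_alt
        assert counts.ref.sum() == 0

    def test_deletion_spanning_snp_ignored(self):
        panel = make_panel(pos=111)
        text = HEADER + sam_line(101, "5M20D25M", "C" * 30)
        counts = count_from_text(text, panel)
        assert counts.total().sum() == 0

    def test_third_allele_ignored(self):
        panel = make_panel(pos=111, ref="A", alt="G")
        text = HEADER + sam_line(101, "50M", "C" * 10 + "T" + "C" * 39)
        counts = count_from_text(text, panel)
        assert counts.total().sum() == 0


class TestRecordFilters:
    def test_flagged_records_skipped(self):
        panel = make_panel(pos=111)
        seq = "C" * 10 + "A" + "C" * 39
        text = HEADER
        for flag in (4, 256, 1024, 2048):  # unmapped/secondary/dup/supplementary
            text += sam_line(101, "50M", seq, qname=f"r{flag}", flag=flag)
        counts = count_from_text(text, panel)
        assert counts.total().sum() == 0

    def test_quality_thresholds(self):
        panel = make_panel(pos=111)
        seq = "C" * 10 + "A" + "C" * 39
        low_mq = sam_line(101, "50M", seq, qname="lowmq", mapq=5)
        low_bq = sam_line(101, "50M", seq, qname="lowbq",
                          qual="I" * 10 + "#" + "I" * 39)
        good = sam_line(101, "50M", seq, qname="good")
        counts = count_from_text(HEADER + low_mq + low_bq + good, panel)
        assert counts.ref[0, 0] == 1

    def test_mate_overlap_counted_once(self):
        panel = make_panel(pos=111)
        seq = "C" * 10 + "A" + "C" * 39
        pair = sam_line(101, "50M", seq, qname="frag") + sam_line(101, "50M", seq, qname="frag")
        counts = count_from_text(HEADER + pair, panel)
        assert counts.ref[0, 0] == 1

    def test_off_panel_chromosome_ignored(self):
        panel = make_panel(pos=111)
        text = ("@HD\tVN:1.6\n@SQ\tSN:chrTest\tLN:1000\n@SQ\tSN:chrOther\tLN:1000\n"
                "r1\t0\tchrOther\t101\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t" + "I" * 50 + "\n")
        counts = count_from_text(text, panel)
        assert counts.total().sum() == 0

    def test_record_order_invariance(self, small_panel, tmp_path):
        sc = LakeScenario(n_snps=12, n_loci=10, mean_depth_per_snp=4, seed=3)
        _, counts, _ = simulate_scenario(sc)
        sam = tmp_path / "r.sam"
        write_sam_reads(counts, small_panel, sam, seed=1)
        lines = sam.read_text().splitlines(keepends=True)
        header = [l for l in lines if l.startswith("@")]
        body = [l for l in lines if not l.startswith("@")]
        rng = np.random.default_rng(0)
        shuffled = tmp_path / "shuf.sam"
        shuffled.write_text("".join(header + [body[i] for i in rng.permutation(len(body))]))
        a = count_alleles(sam, small_panel, 0, 0)
        b = count_alleles(shuffled, small_panel, 0, 0)
        np.testing.assert_array_equal(a.ref, b.ref)
        np.testing.assert_array_equal(a.alt, b.alt)


class TestFilterCascade:
    def make_counts(self, ref, alt, depths=None):
        ref = np.asarray(ref)
        n_s, n_v = ref.shape
        return AlleleCountMatrix(
            ref, np.asarray(alt),
            [f"s{i}" for i in range(n_s)], [f"v{j}" for j in range(n_v)],
            depths if depths is not None else np.full(n_s, 3.0),
        )

    def test_locate_empty(self):
        c = self.make_counts(np.zeros((2, 3), int), np.zeros((2, 3), int))
        assert locate_snps(c) == []

    def test_locate_all_without_dropout(self):
        sc = LakeScenario(dropout_rate=0.0, seed=2)
        _, counts, _ = simulate_scenario(sc)
        assert len(locate_snps(counts)) == counts.n_snps

    def test_variable_excludes_monomorphic(self):
        c = self.make_counts([[5, 1], [3, 0]], [[0, 1], [0, 0]])
        assert variable_snps(c) == ["v1"]

    def test_presence_threshold_12_of_16(self):
        ref = np.zeros((16, 2), int)
        ref[:12, 0] = 1   # present in exactly 12 -> kept
        ref[:11, 1] = 1   # present in 11 -> dropped
        c = self.make_counts(ref, np.zeros_like(ref))
        kept = filter_esnps(c, 0.75)
        assert kept.snp_ids == ["v0"]

    def test_zero_fraction_is_identity(self, simulated):
        _, counts, _ = simulated
        assert filter_esnps(counts, 0.0).snp_ids == counts.snp_ids

    def test_threshold_sweep_monotone_and_matches_tally(self, simulated):
        _, counts, _ = simulated
        present = counts.present(1).sum(axis=0)
        prev = counts.n_snps + 1
        for frac in np.linspace(0, 1, 11):
            kept = filter_esnps(counts, frac)
            expected = int((present >= np.ceil(frac * counts.n_samples)).sum())
            assert kept.n_snps == expected
            assert kept.n_snps <= prev
            prev = kept.n_snps

    def test_filter_idempotent(self, simulated):
        _, counts, _ = simulated
        once = filter_esnps(counts, 0.75)
        twice = filter_esnps(once, 0.75)
        assert twice.snp_ids == once.snp_ids

    def test_empty_sample_set_rejected(self):
        c = AlleleCountMatrix(
            np.zeros((0, 3), int), np.zeros((0, 3), int), [], ["a", "b", "c"], []
        )
        with pytest.raises(ValueError):
            filter_esnps(c)

    def test_total_dropout_fixture_locates_114_of_120(self):
        """Injecting complete dropout at 6 SNPs leaves 114 of 120 located."""
        sc = LakeScenario(dropout_rate=0.0, seed=13)
        _, counts, _ = simulate_scenario(sc)
        dead = np.random.default_rng(0).choice(120, size=6, replace=False)
        counts.ref[:, dead] = 0
        counts.alt[:, dead] = 0
        assert len(locate_snps(counts)) == 114

    def test_tsv_round_trip(self, tmp_path, simulated):
        _, counts, _ = simulated
        path = tmp_path / "counts.tsv"
        counts.to_tsv(path)
        back = AlleleCountMatrix.from_tsv(path)
        np.testing.assert_array_equal(back.ref, counts.ref)
        np.testing.assert_array_equal(back.alt, counts.alt)
        assert back.sample_ids == counts.sample_ids
        np.testing.assert_allclose(back.depths_m, counts.depths_m)


def test_panel_validation():
    with pytest.raises(ValueError):
        SnpPanel(pd.DataFrame([dict(
            snp_id="x", chrom="c", pos=50, ref_allele="A", alt_allele="A",
            locus_id="L", amp_start=40, amp_end=60,
        )]))
    with pytest.raises(ValueError):
        SnpPanel(pd.DataFrame([dict(
            snp_id="x", chrom="c", pos=500, ref_allele="A", alt_allele="G",
            locus_id="L", amp_start=40, amp_end=60,
        )]))


def test_panel_bed_round_trip(tmp_path):
    panel = synthetic_panel(20, 15, seed=4)
    panel.to_bed(tmp_path / "p.bed")
    panel.to_allele_tsv(tmp_path / "p.tsv")
    back = SnpPanel.from_bed_and_alleles(tmp_path / "p.bed", tmp_path / "p.tsv")
    pd.testing.assert_frame_equal(
        back.table[panel.table.columns], panel.table, check_dtype=False
    )
    assert back.n_loci == 15
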