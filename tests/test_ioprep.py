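"""Read preparation: primer matching/orientation, quality and length filters."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanotu.ioprep import (AmpliconConfig, AttritionLog, PreparedRead, RawRead,
                           filter_reads, match_and_trim_primers, median_quality,
                           prepare_reads, read_fastq, read_sample_sheet, revcomp)

F = "AGRGTTYGATYMTGGCTCAG"   # 16S V1-V9 forward (degenerate)
R = "CGGYTACCTTGTTACGACTT"   # 16S V1-V9 reverse
F_CONCRETE = "AGAGTTTGATCATGGCTCAG"  # one IUPAC resolution of F


def _cfg(**kw):
    defaults = dict(primer_f=F, primer_r=R, min_len=5, max_len=2000)
    defaults.update(kw)
    return AmpliconConfig(**defaults)


def _read(seq, qual=30, rid="r1"):
    q = np.full(len(seq), qual) if np.isscalar(qual) else np.asarray(qual)
    return RawRead(id=rid, seq=seq, qual=q, sample_id="s")


INSERT = "ACGTACGTCCGGTTAAGGCCTTAACCGGATCG"


class TestPrimerMatching:
    def test_plus_strand_read_is_trimmed_not_flipped(self):
        read = _read(F_CONCRETE + INSERT + revcomp(R))
        prep = match_and_trim_primers(read, _cfg())
        assert prep.seq == INSERT
        assert not prep.flipped
        assert len(prep.qual) == len(INSERT)

    def test_reverse_strand_read_is_flipped_to_plus(self):
        read = _read(revcomp(F_CONCRETE + INSERT + revcomp(R)))
        prep = match_and_trim_primers(read, _cfg())
        assert prep.seq == INSERT
        assert prep.flipped

    def test_missing_reverse_primer_rejects(self):
        read = _read(F_CONCRETE + INSERT)
        assert match_and_trim_primers(read, _cfg()) is None

    def test_missing_forward_primer_rejects(self):
        read = _read(INSERT + revcomp(R))
        assert match_and_trim_primers(read, _cfg()) is None

    def test_iupac_degeneracy_matches_any_resolution(self):
        # F contains R,Y,M codes; both purine choices at the R position match
        alt = "AGGGTTCGATCATGGCTCAG"
        read = _read(alt + INSERT + revcomp(R))
        prep = match_and_trim_primers(read, _cfg())
        assert prep is not None and prep.seq == INSERT

    def test_primer_match_tolerates_errors_within_budget(self):
        mutated = F_CONCRETE[:5] + "T" + F_CONCRETE[6:]  # 1 mismatch, budget 2
        read = _read(mutated + INSERT + revcomp(R))
        prep = match_and_trim_primers(read, _cfg())
        assert prep is not None and prep.seq == INSERT

    def test_revcomp_symmetry_yields_identical_insert(self):
        plus = _read(F_CONCRETE + INSERT + revcomp(R), rid="p")
        minus = _read(revcomp(plus.seq), rid="m")
        p1 = match_and_trim_primers(plus, _cfg())
        p2 = match_and_trim_primers(minus, _cfg())
        assert p1.seq == p2.seq
        np.testing.assert_array_equal(p1.qual, p2.qual[::1])

    def test_orientation_idempotence(self):
        prep = match_and_trim_primers(_read(F_CONCRETE + INSERT + revcomp(R)), _cfg())
        redecorated = _read(F_CONCRETE + prep.seq + revcomp(R))
        again = match_and_trim_primers(redecorated, _cfg())
        assert again.seq == prep.seq

    def test_flipped_read_quality_follows_bases(self):
        qual = np.arange(len(F_CONCRETE + INSERT + revcomp(R))) % 40 + 1
        plus = _read(F_CONCRETE + INSERT + revcomp(R), qual=qual)
        minus = _read(revcomp(plus.seq), qual=qual[::-1])
        p1 = match_and_trim_primers(plus, _cfg())
        p2 = match_and_trim_primers(minus, _cfg())
        np.testing.assert_array_equal(p1.qual, p2.qual)


class TestMedianQuality:
    def test_constant_vector(self):
        assert median_quality([20, 20, 20]) == 20.0

    def test_capped_positions_excluded(self):
        assert median_quality([10, 20, 30, 90, 90], 90) == 20.0

    def test_all_capped_falls_back_to_full_vector(self):
        assert median_quality([90, 90], 90) == 90.0

    def test_empty_vector_raises(self):
        with pytest.raises(ValueError):
            median_quality([])


class TestFilters:
    def _prep(self, length, q=30):
        return PreparedRead(id="r", seq="A" * length, qual=np.full(length, q))

    def test_long_amplicon_bounds_reject_short_read(self):
        cfg = _cfg(min_len=900, max_len=1600)  # 16S V1-V9 window
        kept, log = filter_reads([self._prep(800)], cfg)
        assert not kept and log.too_short == 1

    def test_short_amplicon_bounds_keep_read(self):
        cfg = _cfg(min_len=100, max_len=500)  # ITS1 window
        kept, log = filter_reads([self._prep(300, q=25)], cfg)
        assert len(kept) == 1 and log.kept == 1

    def test_low_median_quality_rejected(self):
        cfg = _cfg(min_len=1, max_len=100)
        kept, log = filter_reads([self._prep(50, q=15)], cfg)
        assert not kept and log.bad_quality == 1

    def test_q20_is_inclusive(self):
        cfg = _cfg(min_len=1, max_len=100)
        kept, _ = filter_reads([self._prep(50, q=20)], cfg)
        assert len(kept) == 1

    def test_too_long_rejected(self):
        cfg = _cfg(min_len=1, max_len=40)
        kept, log = filter_reads([self._prep(50)], cfg)
        assert not kept and log.too_long == 1

    def test_empty_input_gives_zeroed_log(self):
        kept, log = filter_reads([], _cfg())
        assert kept == [] and log.total == 0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 60), st.integers(1, 80)), max_size=30))
    def test_attrition_conserves_every_read(self, specs):
        reads = [PreparedRead(id=str(i), seq="C" * n, qual=np.full(n, q))
                 for i, (q, n) in enumerate(specs)]
        cfg = _cfg(min_len=10, max_len=50)
        kept, log = filter_reads(reads, cfg)
        assert log.total == len(reads)
        assert log.kept == len(kept)

    def test_prepare_reads_conservation(self):
        cfg = _cfg(min_len=10, max_len=100)
        reads = [
            _read(F_CONCRETE + INSERT + revcomp(R), rid="ok"),
            _read(INSERT, rid="noprimer"),
            _read(F_CONCRETE + INSERT + revcomp(R), qual=5, rid="lowq"),
        ]
        kept, log = prepare_reads(reads, cfg)
        assert log.total == 3
        assert log.no_primer == 1 and log.bad_quality == 1 and log.kept == 1
        assert [r.id for r in kept] == ["ok"]


class TestFastqIO:
    def test_roundtrip_plain_and_gzip(self, tmp_path):
        records = [("r1", "ACGTN", [2, 40, 90, 0, 17]), ("r2", "TTGG", [20, 21, 22, 23])]
        text = "".join(f"@{rid}\n{seq}\n+\n{''.join(chr(q + 33) for q in qual)}\n"
                       for rid, seq, qual in records)
        plain = tmp_path / "a.fastq"
        plain.write_text(text)
        gz = tmp_path / "a.fastq.gz"
        with gzip.open(gz, "wt") as fh:
            fh.write(text)
        for path in (plain, gz):
            reads = list(read_fastq(path, sample_id="sx"))
            assert [(r.id, r.seq, list(r.qual)) for r in reads] == \
                [(rid, seq, qual) for rid, seq, qual in records]
            assert all(r.sample_id == "sx" for r in reads)

    def test_sample_sheet_resolves_relative_paths(self, tmp_path):
        (tmp_path / "x.fastq").write_text("")
        sheet = tmp_path / "samples.tsv"
        sheet.write_text("# comment\nsampleA\tx.fastq\n")
        samples = read_sample_sheet(sheet)
        assert samples == {"sampleA": tmp_path / "x.fastq"}


def test_raw_read_length_mismatch_rejected():
    with pytest.raises(ValueError):
        RawRead(id="r", seq="ACGT", qual=np.array([1, 2, 3]))


def test_amplicon_config_validation():
    with pytest.raises(ValueError):
        AmpliconConfig(primer_f="", primer_r=R, min_len=1, max_len=2)
    with pytest.raises(ValueError):
        AmpliconConfig(primer_f=F, primer_r=R, min_len=10, max_len=5)
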