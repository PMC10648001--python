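"""Record assembly, serialization round-trips, validation, SPLASH."""

import hashlib

import numpy as np
import pytest

from mixlib import annotate, records, splash
from mixlib.fixtures import default_settings
from mixlib.isobars import Assignment
from mixlib.msio import CompoundEntry


def reference_splash(mz, intensity):
    """Independently coded spectral-hash oracle (same published block
    layout, implemented without the package's helper functions)."""
    pairs = [(m, i) for m, i in zip(mz, intensity) if i > 0]
    base = max(i for _, i in pairs)
    rel = [(m, i / base * 999.0) for m, i in pairs]
    # block 2: top-ten hash
    by_int = sorted(rel, key=lambda p: (-p[1], p[0]))[:10]
    top_mz = sorted(int(round(m * 1e6)) for m, _ in by_int)
    digest = hashlib.sha256(
        " ".join(str(v) for v in top_mz).encode()).hexdigest()
    value = int(digest[:10], 16) % 36**4
    digits = "0123456789abcdefghijklmnopqrstuvwxyz"
    block2 = ""
    v = value
    for _ in range(4):
        block2 = digits[v % 36] + block2
        v //= 36
    # block 3: wrapped histogram
    bins = [0.0] * 10
    for m, r in rel:
        bins[int(m // 100) % 10] += r
    top = max(bins)
    block3 = "".join(str(int(b * 9.0 / top + 1e-9)) for b in bins)
    # block 4: full spectrum hash
    ordered = sorted(rel, key=lambda p: (p[0], p[1]))
    text = " ".join(f"{int(round(m * 1e6))}:{int(round(r))}"
                    for m, r in ordered)
    block4 = hashlib.sha256(text.encode()).hexdigest()[:20]
    return f"splash10-{block2}-{block3}-{block4}"


class TestRelativeIntensities:
    def test_single_peak_is_999(self):
        assert records.relative_intensities([123.0]) == [999]

    def test_stated_rounding(self):
        assert records.relative_intensities([1e6, 5e5]) == [999, 500]

    def test_floor_at_one(self):
        assert records.relative_intensities([1e6, 1.0]) == [999, 1]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            records.relative_intensities([])


class TestSplash:
    def random_spectrum(self, rng):
        n = int(rng.integers(3, 60))
        mz = np.sort(rng.uniform(50, 900, n))
        intensity = rng.uniform(1, 1e6, n)
        return mz, intensity

    def test_matches_independent_implementation(self):
        """Oracle agreement on 25 random spectra."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            mz, intensity = self.random_spectrum(rng)
            assert splash.splash_ms(mz, intensity) == \
                reference_splash(mz, intensity)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        mz, intensity = self.random_spectrum(rng)
        assert splash.splash_ms(mz, intensity) == \
            splash.splash_ms(mz, intensity * 1234.5)

    def test_different_spectra_differ(self):
        a = splash.splash_ms([100.0, 200.0], [1.0, 2.0])
        b = splash.splash_ms([100.0, 201.0], [1.0, 2.0])
        assert a != b
        assert a.startswith("splash10-") and b.startswith("splash10-")

    def test_format_shape(self):
        value = splash.splash_ms([100.0], [1.0])
        blocks = value.split("-")
        assert len(blocks) == 4
        assert blocks[0] == "splash10"
        assert len(blocks[1]) == 4
        assert len(blocks[2]) == 10 and blocks[2].isdigit()
        assert len(blocks[3]) == 20

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            splash.splash_ms([], [])


def make_spectrum(base=1.2e6, n_extra=2):
    mz = [91.0542, 120.0808, 164.1070][: n_extra + 1]
    intensity = [base * f for f in (0.2, 0.6, 1.0)][: n_extra + 1]
    return annotate.CleanSpectrum(
        compound_id="A1", mix="503", polarity="+", collision_energy=30.0,
        precursor_mz=164.1070, retention_time=12.3,
        mz=np.array(mz), intensity=np.array(intensity),
        formulas=["C7H7", "C8H10N", "C10H14NO"][: n_extra + 1])


ENTRY = CompoundEntry.from_smiles(
    "A1", "2,2-dimethyl-2,3-dihydro-1-benzofuran-7-amine",
    "CC1(C)Cc2cccc(N)c2O1")
LEVEL1 = Assignment("A1", "503", "1", "alone_in_mix", rt=12.3)


class TestBuildRecord:
    def test_minimal_record_fields(self):
        record = records.build_record(ENTRY, make_spectrum(),
                                      LEVEL1, default_settings(), "LU109201")
        assert record.accession == "MSBNK-LCSB-LU109201"
        assert record.num_peak == 3
        assert record.get("CH$FORMULA") == "C10H13NO"
        assert record.get("MS$FOCUSED_ION: PRECURSOR_TYPE") == "[M+H]+"
        assert records.validate_record(record).ok

    def test_base_peak_gate(self):
        with pytest.raises(records.RecordRejected, match="base peak"):
            records.build_record(ENTRY, make_spectrum(base=9e4),
                                 LEVEL1, default_settings(), "LU000001")

    def test_tentative_assignment_rejected(self):
        level3 = Assignment("A1", "503", "3", "ambiguous")
        with pytest.raises(records.RecordRejected, match="level"):
            records.build_record(ENTRY, make_spectrum(), level3,
                                 default_settings(), "LU000001")


class TestRoundTrip:
    @pytest.mark.parametrize("n_extra", [0, 1, 2])
    def test_parse_write_identity(self, n_extra):
        record = records.build_record(
            ENTRY, make_spectrum(n_extra=n_extra), LEVEL1,
            default_settings(), "LU109201")
        text = records.write_record(record)
        back = records.parse_record(text)
        assert back == record
        assert records.write_record(back) == text

    def test_unknown_fields_preserved(self):
        record = records.build_record(ENTRY, make_spectrum(), LEVEL1,
                                      default_settings(), "LU109201")
        text = records.write_record(record)
        text = text.replace("PK$SPLASH:",
                            "XX$CUSTOM: something kept\nPK$SPLASH:")
        back = records.parse_record(text)
        assert back.get("XX$CUSTOM") == "something kept"
        assert records.write_record(back) == text

    def test_truncated_file_errors(self):
        record = records.build_record(ENTRY, make_spectrum(), LEVEL1,
                                      default_settings(), "LU109201")
        text = records.write_record(record)
        with pytest.raises(ValueError, match="terminator"):
            records.parse_record(text.replace("//", ""))


class TestValidateRecord:
    def valid(self):
        return records.build_record(ENTRY, make_spectrum(), LEVEL1,
                                    default_settings(), "LU109201")

    def test_valid_record_empty_report(self):
        assert records.validate_record(self.valid()).violations == []

    def test_num_peak_off_by_one(self):
        record = self.valid()
        record.set("PK$NUM_PEAK", "4")
        report = records.validate_record(record)
        assert any("PK$NUM_PEAK" in v for v in report.violations)

    def test_formula_mass_mismatch(self):
        record = self.valid()
        record.set("CH$EXACT_MASS", "163.2000")  # > 5 ppm off C10H13NO
        report = records.validate_record(record)
        assert any("inconsistent" in v for v in report.violations)

    def test_malformed_accession(self):
        record = self.valid()
        record.set("ACCESSION", "LU109201")
        report = records.validate_record(record)
        assert any("accession" in v for v in report.violations)

    def test_unsorted_peaks(self):
        record = self.valid()
        record.peaks = list(reversed(record.peaks))
        record.set("PK$SPLASH", records.compute_splash(
            [(p[0], p[1]) for p in record.peaks]))
        report = records.validate_record(record)
        assert any("sorted" in v for v in report.violations)

    def test_splash_mismatch_detected(self):
        record = self.valid()
        record.set("PK$SPLASH", "splash10-0000-0000000000-" + "0" * 20)
        report = records.validate_record(record)
        assert any("SPLASH" in v for v in report.violations)


class TestSummarize:
    def test_rows_and_fields(self, tmp_path):
        settings = default_settings()
        for i in range(3):
            record = records.build_record(ENTRY, make_spectrum(), LEVEL1,
                                          settings, f"LU10000{i}")
            records.write_record(record,
                                 tmp_path / f"{record.accession}.txt")
        table = records.summarize_records(
            tmp_path, ["ACCESSION", "CH$FORMULA"])
        assert len(table) == 3
        assert set(table["CH$FORMULA"]) == {"C10H13NO"}

    def test_empty_directory(self, tmp_path):
        table = records.summarize_records(tmp_path, ["ACCESSION"])
        assert len(table) == 0
        assert list(table.columns) == ["file", "ACCESSION"]
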