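"""mzML round-trips, compound list / setID / settings readers."""

import textwrap

import numpy as np
import pytest

from mixlib import msio
from mixlib.msio import CompoundEntry, Run, Scan


def small_run():
    scans = [
        Scan(1, 0.10, [100.0, 200.0, 300.5], [1e5, 2e5, 3e5]),
        Scan(2, 0.12, [91.0542, 164.1070], [5e4, 2e5],
             precursor_mz=164.1070, isolation_window_width=1.0,
             collision_energy=30.0),
        Scan(1, 0.15, [100.0], [1.5e5]),
    ]
    return Run(scans, mix="m1", mode="+", collision_energy=30.0)


class TestScanRun:
    def test_peaks_sorted_on_construction(self):
        scan = Scan(1, 1.0, [200.0, 100.0], [2.0, 1.0])
        assert list(scan.mz) == [100.0, 200.0]
        assert list(scan.intensity) == [1.0, 2.0]

    def test_ms2_requires_precursor(self):
        with pytest.raises(msio.MsDataError):
            Scan(2, 1.0, [100.0], [1.0])

    def test_negative_intensity_rejected(self):
        with pytest.raises(msio.MsDataError):
            Scan(1, 1.0, [100.0], [-1.0])

    def test_run_orders_scans_and_checks_polarity(self):
        run = Run([Scan(1, 2.0, [], []), Scan(1, 1.0, [], [])])
        assert [s.retention_time for s in run.scans] == [1.0, 2.0]
        with pytest.raises(msio.MsDataError):
            Run([Scan(1, 1.0, [], [], polarity="+"),
                 Scan(1, 2.0, [], [], polarity="-")])


class TestMzml:
    def test_round_trip_field_for_field(self, tmp_path):
        run = small_run()
        path = tmp_path / "run.mzML"
        msio.write_run(run, path)
        back = msio.read_run(path, mix="m1", collision_energy=30.0)
        assert len(back) == len(run)
        for a, b in zip(run.scans, back.scans):
            assert a.ms_level == b.ms_level
            assert a.retention_time == pytest.approx(b.retention_time,
                                                     abs=1e-12)
            assert np.array_equal(a.mz, b.mz)
            assert np.array_equal(a.intensity, b.intensity)
            assert a.precursor_mz == b.precursor_mz
            assert a.isolation_window_width == b.isolation_window_width
            assert a.collision_energy == b.collision_energy
            assert a.polarity == b.polarity

    def test_double_round_trip_is_stable(self, tmp_path):
        run = small_run()
        p1, p2 = tmp_path / "a.mzML", tmp_path / "b.mzML"
        msio.write_run(run, p1)
        msio.write_run(msio.read_run(p1, mix="m1"), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            msio.read_run("/nonexistent/run.mzML")

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.mzML"
        path.write_text(
            '<?xml version="1.0" encoding="utf-8"?>\n'
            '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
            '<run id="r"><spectrumList count="0" /></run></mzML>')
        with pytest.raises(msio.MsDataError):
            msio.read_run(path)

    def test_profile_mode_rejected(self, tmp_path):
        # hand-written literal, independent of the writer
        text = textwrap.dedent("""\
            <?xml version="1.0" encoding="utf-8"?>
            <mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
             <run id="r"><spectrumList count="1">
              <spectrum index="0" id="scan=1" defaultArrayLength="0">
               <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
               <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
               <scanList count="1"><scan>
                <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="1.0" unitName="minute"/>
               </scan></scanList>
              </spectrum>
             </spectrumList></run></mzML>
            """)
        path = tmp_path / "profile.mzML"
        path.write_text(text)
        with pytest.raises(msio.MsDataError, match="centroid"):
            msio.read_run(path)

    def test_seconds_unit_normalized_to_minutes(self, tmp_path):
        text = textwrap.dedent("""\
            <?xml version="1.0" encoding="utf-8"?>
            <mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
             <run id="r"><spectrumList count="1">
              <spectrum index="0" id="scan=1" defaultArrayLength="0">
               <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
               <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
               <scanList count="1"><scan>
                <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="90.0" unitName="second"/>
               </scan></scanList>
              </spectrum>
             </spectrumList></run></mzML>
            """)
        path = tmp_path / "seconds.mzML"
        path.write_text(text)
        run = msio.read_run(path)
        assert run.scans[0].retention_time == pytest.approx(1.5)


class TestCompoundList:
    def test_two_rows(self, tmp_path):
        path = tmp_path / "compounds.csv"
        path.write_text("Identifier,Name,SMILES\n"
                        "A1,ethanol,CCO\n"
                        "A2,benzene,c1ccccc1\n")
        entries, problems = msio.read_compound_list(path)
        assert [e.identifier for e in entries] == ["A1", "A2"]
        assert not problems
        assert entries[0].formula == {"C": 2, "H": 6, "O": 1}
        assert entries[0].monoisotopic_mass == pytest.approx(46.0419, abs=1e-3)

    def test_bad_smiles_skipped_with_log(self, tmp_path):
        path = tmp_path / "compounds.csv"
        path.write_text("Identifier,Name,SMILES\n"
                        "A1,ok,CCO\n"
                        "A2,bad,C10H13NO-compound\n")
        entries, problems = msio.read_compound_list(path)
        assert [e.identifier for e in entries] == ["A1"]
        assert len(problems) == 1 and "A2" in problems[0]

    def test_duplicate_identifiers_error(self, tmp_path):
        path = tmp_path / "compounds.csv"
        path.write_text("Identifier,Name,SMILES\nA1,x,CCO\nA1,y,CCN\n")
        with pytest.raises(msio.MsDataError, match="A1"):
            msio.read_compound_list(path)

    def test_header_aliases(self, tmp_path):
        path = tmp_path / "compounds.csv"
        path.write_text("ID,Compound,ms_ready_SMILES\nA1,ethanol,CCO\n")
        entries, _ = msio.read_compound_list(path)
        assert entries[0].name == "ethanol"


class TestSetId:
    def test_one_mix_of_two(self, tmp_path):
        path = tmp_path / "setid.csv"
        path.write_text("Identifier,Mix\nid1,mix499\nid2,mix499\n")
        design = msio.read_setid(path)
        assert design.compounds_in("mix499") == {"id1", "id2"}

    def test_dangling_identifier_error(self, tmp_path):
        path = tmp_path / "setid.csv"
        path.write_text("Identifier,Mix\nid1,mix499\nghost,mix499\n")
        compounds = [CompoundEntry.from_smiles("id1", "ethanol", "CCO")]
        with pytest.raises(msio.MsDataError, match="ghost"):
            msio.read_setid(path, compounds=compounds)

    def test_empty_file_empty_design(self, tmp_path):
        path = tmp_path / "setid.csv"
        path.write_text("Identifier,Mix\n")
        design = msio.read_setid(path)
        assert design.mixes == {}


class TestSettings:
    def write(self, tmp_path, **overrides):
        from mixlib.fixtures import default_settings
        settings = default_settings()
        for key, value in overrides.items():
            setattr(settings, key, value)
        return msio.write_settings(settings, tmp_path / "settings.ini")

    def test_round_trip(self, tmp_path):
        path = self.write(tmp_path)
        settings = msio.read_settings(path)
        assert settings.contributor == "LCSB"
        assert settings.license == "CC BY"
        assert settings.base_peak_min == 1e5

    def test_missing_mandatory_key(self, tmp_path):
        path = tmp_path / "settings.ini"
        path.write_text("[record]\nauthors = A\n")
        with pytest.raises(msio.MsDataError, match="missing"):
            msio.read_settings(path)

    def test_bad_license_rejected(self, tmp_path):
        path = self.write(tmp_path, license="All rights reserved")
        with pytest.raises(msio.MsDataError, match="license"):
            msio.read_settings(path)
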