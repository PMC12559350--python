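"""mzML round-trip, feature building/linking, peak utilities."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seldecode.spectra import (
    Ms1Feature,
    Ms1Spectrum,
    Ms2Scan,
    ProfileModeError,
    Run,
    extract_ion_chromatogram,
    find_features,
    link_ms2_to_features,
    read_feature_table,
    read_mzml,
    top_n_peaks,
    write_feature_table,
    write_mzml,
)


def _scan(scan_id, pre, rt, peaks):
    mz = np.array([p[0] for p in peaks], dtype=float)
    inten = np.array([p[1] for p in peaks], dtype=float)
    return Ms2Scan(scan_id, pre, rt, mz, inten)


def _simple_run(n_scans=5):
    rng = np.random.default_rng(0)
    ms1 = [
        Ms1Spectrum(f"ms1={i}", rt=2.0 * i,
                    mz=np.sort(rng.uniform(100, 900, 8)),
                    intensity=rng.uniform(1e3, 1e6, 8))
        for i in range(4)
    ]
    scans = [
        _scan(f"scan={i}", 400.0 + i, 1.0 + i,
              [(100 + 10 * j, 1000.0 * (j + 1)) for j in range(6)])
        for i in range(n_scans)
    ]
    return Run("r", ms1_spectra=ms1, scans=scans)


class TestMzmlRoundTrip:
    def test_write_read_identity(self, tmp_path):
        run = _simple_run()
        path = tmp_path / "run.mzML"
        write_mzml(run, path)
        back = read_mzml(path, build_features=False)
        assert back.n_scans == run.n_scans
        assert len(back.ms1_spectra) == len(run.ms1_spectra)
        for orig, rt in zip(run.scans, back.scans):
            assert rt.scan_id == orig.scan_id
            assert rt.precursor_mz == pytest.approx(orig.precursor_mz, abs=1e-9)
            assert rt.rt == pytest.approx(orig.rt, abs=1e-9)
            np.testing.assert_allclose(rt.mz, orig.mz, atol=1e-9)
            np.testing.assert_allclose(rt.intensity, orig.intensity, rtol=1e-9)

    def test_zero_peak_scan_preserved(self, tmp_path):
        run = Run("z", scans=[Ms2Scan("scan=0", 500.0, 10.0,
                                      np.array([]), np.array([]))])
        path = tmp_path / "z.mzML"
        write_mzml(run, path)
        back = read_mzml(path, build_features=False)
        assert back.n_scans == 1 and back.scans[0].n_peaks == 0

    def test_empty_run(self, tmp_path):
        path = tmp_path / "empty.mzML"
        write_mzml(Run("empty"), path)
        back = read_mzml(path)
        assert back.n_scans == 0 and not back.ms1_spectra

    def test_deterministic_bytes(self, tmp_path):
        run = _simple_run()
        write_mzml(run, tmp_path / "a.mzML")
        write_mzml(run, tmp_path / "b.mzML")
        assert (tmp_path / "a.mzML").read_bytes() == (tmp_path / "b.mzML").read_bytes()

    @settings(deadline=None, max_examples=15)
    @given(st.integers(0, 2**31 - 1))
    def test_randomized_round_trip(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        scans = []
        for i in range(rng.integers(1, 6)):
            k = int(rng.integers(0, 20))
            scans.append(Ms2Scan(
                f"scan={i}", float(rng.uniform(100, 2000)),
                float(rng.uniform(0, 3600)),
                np.sort(rng.uniform(50, 2000, k)),
                rng.uniform(0, 1e7, k),
            ))
        run = Run("p", scans=scans)
        path = tmp_path_factory.mktemp("rt") / "p.mzML"
        write_mzml(run, path)
        back = read_mzml(path, build_features=False)
        assert back.n_scans == len(scans)
        by_id = {s.scan_id: s for s in back.scans}
        for s in scans:
            b = by_id[s.scan_id]
            np.testing.assert_allclose(b.mz, s.mz, atol=1e-6)
            np.testing.assert_allclose(b.intensity, s.intensity, rtol=1e-3)
            assert b.rt == pytest.approx(s.rt, abs=1e-3)

    def test_minute_rt_converted(self, tmp_path):
        path = tmp_path / "min.mzML"
        write_mzml(_simple_run(1), path)
        text = path.read_text()
        # rewrite the RT unit to minutes, value to 1/60th
        import re
        def to_minutes(m):
            return (m.group(0)
                    .replace(m.group(1), repr(float(m.group(1)) / 60.0))
                    .replace("UO:0000010", "UO:0000031")
                    .replace("second", "minute"))
        text = re.sub(
            r'accession="MS:1000016" name="scan start time" value="([^"]+)"'
            r'[^/]*unitAccession="UO:0000010" unitName="second"',
            to_minutes, text)
        path.write_text(text)
        back = read_mzml(path, build_features=False)
        assert back.scans[0].rt == pytest.approx(1.0, abs=1e-6)

    def test_profile_mode_rejected(self, tmp_path):
        path = tmp_path / "prof.mzML"
        write_mzml(_simple_run(1), path)
        text = path.read_text().replace(
            'accession="MS:1000127" name="centroid spectrum"',
            'accession="MS:1000128" name="profile spectrum"',
        )
        path.write_text(text)
        with pytest.raises(ProfileModeError, match="centroid"):
            read_mzml(path)

    def test_ms2_without_precursor_skipped(self, tmp_path):
        path = tmp_path / "nopre.mzML"
        write_mzml(_simple_run(2), path)
        text = path.read_text()
        # mangle the first selected-ion m/z cvParam so it is unrecognisable
        text = text.replace(
            'accession="MS:1000744" name="selected ion m/z"',
            'accession="MS:1000999" name="not a precursor"', 1,
        )
        path.write_text(text)
        with pytest.warns(UserWarning, match="lacks a precursor"):
            back = read_mzml(path, build_features=False)
        assert back.n_scans == 1

    def test_writer_readable_by_bioconductor_mzr(self, tmp_path):
        """Independent oracle: R/mzR parses our mzML and sees the same peaks."""
        run = _simple_run(2)
        path = tmp_path / "oracle.mzML"
        write_mzml(run, path)
        script = tmp_path / "check.R"
        script.write_text(
            f"""
            suppressMessages(library(mzR))
            h <- openMSfile("{path}")
            hd <- header(h)
            cat(nrow(hd), sum(hd$msLevel == 2), "\n")
            p <- peaks(h, 1)
            cat(nrow(p), sprintf("%.6f", p[1, 1]), "\n")
            """
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        if proc.returncode != 0:
            pytest.skip(f"mzR unavailable: {proc.stderr[-200:]}")
        lines = proc.stdout.strip().splitlines()
        n_spectra, n_ms2 = map(int, lines[0].split())
        assert n_spectra == len(run.ms1_spectra) + run.n_scans
        assert n_ms2 == run.n_scans
        n_peaks, first_mz = lines[1].split()
        first = sorted(
            list(run.ms1_spectra) + list(run.scans), key=lambda s: s.rt
        )[0]
        assert int(n_peaks) == first.mz.size
        assert float(first_mz) == pytest.approx(first.mz[0], abs=1e-5)


class TestTopNPeaks:
    def test_fewer_peaks_than_n(self):
        s = _scan("s", 500.0, 1.0, [(100, 10), (200, 20), (300, 30)])
        mz, inten = top_n_peaks(s, 5)
        assert mz.size == 3

    def test_ties_keep_lowest_mz(self):
        s = _scan("s", 500.0, 1.0, [(100, 50), (200, 50), (300, 50), (400, 99)])
        mz, _ = top_n_peaks(s, 2)
        assert mz.tolist() == [100.0, 400.0]

    def test_output_in_mz_order_and_subset(self, rng):
        for _ in range(20):
            k = int(rng.integers(1, 50))
            s = Ms2Scan("s", 900.0, 0.0,
                        np.sort(rng.uniform(50, 899, k)),
                        rng.integers(1, 1000, k).astype(float))
            n = int(rng.integers(1, 10))
            mz, inten = top_n_peaks(s, n)
            assert np.all(np.diff(mz) > 0) if mz.size > 1 else True
            # subset of scan peaks
            assert set(mz.tolist()) <= set(s.mz.tolist())
            # oracle: sort by (-intensity, mz)
            order = sorted(range(k), key=lambda i: (-s.intensity[i], s.mz[i]))
            expected = sorted(s.mz[order[:n]].tolist())
            assert mz.tolist() == expected
            # excluded max <= included min
            if k > n:
                assert s.intensity[order[n:]].max() <= inten.min()


class TestXic:
    def test_no_matching_peaks_all_zero(self):
        run = _simple_run()
        rt, inten = extract_ion_chromatogram(run, 5000.0, ppm=5)
        assert inten.sum() == 0.0 and rt.size == len(run.ms1_spectra)

    def test_single_spike_apex(self):
        ms1 = [
            Ms1Spectrum(f"m{i}", rt=10.0 * i, mz=np.array([500.0]),
                        intensity=np.array([100.0 if i == 2 else 0.0]))
            for i in range(5)
        ]
        run = Run("x", ms1_spectra=ms1)
        rt, inten = extract_ion_chromatogram(run, 500.0, ppm=5)
        assert rt[np.argmax(inten)] == 20.0

    def test_matches_linear_scan_oracle(self, rng):
        ms1 = [
            Ms1Spectrum(f"m{i}", rt=float(i),
                        mz=np.sort(rng.uniform(100, 1000, 30)),
                        intensity=rng.uniform(0, 1e5, 30))
            for i in range(10)
        ]
        run = Run("x", ms1_spectra=ms1)
        for mz in rng.uniform(100, 1000, 10):
            _, inten = extract_ion_chromatogram(run, float(mz), ppm=200)
            tol = mz * 200e-6
            expected = [
                s.intensity[np.abs(s.mz - mz) <= tol].sum() for s in ms1
            ]
            np.testing.assert_allclose(inten, expected)


class TestFeatures:
    def test_hand_built_linking(self):
        """3 MS1 traces + 2 MS2 scans link exactly as constructed."""
        mzs = [400.0, 500.0, 600.0]
        ms1 = [
            Ms1Spectrum(f"m{i}", rt=2.0 * i, mz=np.array(mzs),
                        intensity=np.array([10.0, 20.0 * (i + 1), 30.0]))
            for i in range(3)
        ]
        scans = [
            Ms2Scan("scan=a", 500.00001, 2.5, np.array([100.0]), np.array([1.0])),
            Ms2Scan("scan=b", 600.0, 3.9, np.array([100.0]), np.array([1.0])),
        ]
        run = Run("f", ms1_spectra=ms1, scans=scans)
        run.features = find_features(ms1, ppm=5, rt_gap_s=6)
        link_ms2_to_features(run, ppm=5, rt_pad_s=6)
        assert len(run.features) == 3
        by_mz = {round(f.mz): f for f in run.features}
        assert by_mz[500].ms2_scan_ids == ["scan=a"]
        assert by_mz[600].ms2_scan_ids == ["scan=b"]
        assert by_mz[400].ms2_scan_ids == []
        # apex of the 500 trace is the last (most intense) point
        assert by_mz[500].intensity == 60.0 and by_mz[500].rt_apex == 4.0

    def test_rt_gap_splits_features(self):
        ms1 = [
            Ms1Spectrum(f"m{i}", rt=rt, mz=np.array([500.0]),
                        intensity=np.array([10.0]))
            for i, rt in enumerate([0.0, 2.0, 100.0, 102.0])
        ]
        feats = find_features(ms1, ppm=5, rt_gap_s=6)
        assert len(feats) == 2

    def test_feature_table_round_trip(self, tmp_path):
        feats = [
            Ms1Feature("F0", 500.0, 10.0, 1e5, 8.0, 12.0, ["scan=1", "scan=2"]),
            Ms1Feature("F1", 600.0, 20.0, 2e5),
        ]
        path = tmp_path / "features.tsv"
        write_feature_table(feats, path)
        back = read_feature_table(path)
        assert [f.feature_id for f in back] == ["F0", "F1"]
        assert back[0].ms2_scan_ids == ["scan=1", "scan=2"]
        assert back[1].ms2_scan_ids == []
        assert back[0].mz == pytest.approx(500.0)
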