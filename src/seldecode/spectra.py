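"""Centroided LC-MS/MS runs: mzML I/O, features, peak utilities.

A :class:`Run` holds the MS1 spectra, the MS2 scans (with precursor m/z and
retention time) and the MS1 *features* — persistent m/z traces across
adjacent MS1 spectra — that background subtraction and replicate comparison
operate on.  mzML 1.1.0 is read and written with a compact lxml-based
parser/serialiser (the reader understands 32/64-bit float arrays with or
without zlib compression; the writer emits uncompressed 64-bit floats), so
simulated runs round-trip through the same standard format real data
arrives in.

Feature finding is deliberately simple and transparent: MS1 peaks are
clustered by m/z (ppm gap) and then split on retention-time gaps; the apex
is the most intense peak.  Vendor-grade feature detection is out of scope —
an external feature table can be supplied instead via
:func:`read_feature_table`.

Retention times are seconds everywhere; mzML minutes are converted on read.
"""

from __future__ import annotations

import base64
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "Ms1Spectrum",
    "Ms2Scan",
    "Ms1Feature",
    "Run",
    "ProfileModeError",
    "read_mzml",
    "write_mzml",
    "find_features",
    "link_ms2_to_features",
    "top_n_peaks",
    "extract_ion_chromatogram",
    "read_feature_table",
    "write_feature_table",
]


class ProfileModeError(ValueError):
    """Raised when an mzML file contains profile-mode spectra."""


def _as_peak_arrays(
    mz: Sequence[float], intensity: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.shape != intensity.shape:
        raise ValueError("mz and intensity must have equal length")
    if mz.size and (np.any(mz <= 0) or np.any(intensity < 0)):
        raise ValueError("require mz > 0 and intensity >= 0")
    order = np.argsort(mz, kind="stable")
    return mz[order], intensity[order]


@dataclass
class Ms1Spectrum:
    """One survey (MS1) spectrum: centroided peaks at one retention time."""

    scan_id: str
    rt: float  # seconds
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz, self.intensity = _as_peak_arrays(self.mz, self.intensity)


@dataclass
class Ms2Scan:
    """One fragmentation (MS2) scan with its selected precursor."""

    scan_id: str
    precursor_mz: float
    rt: float  # seconds
    mz: np.ndarray
    intensity: np.ndarray
    precursor_charge: int = 1

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be > 0")
        self.mz, self.intensity = _as_peak_arrays(self.mz, self.intensity)

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class Ms1Feature:
    """A persistent MS1 m/z trace; the unit of background subtraction."""

    feature_id: str
    mz: float
    rt_apex: float
    intensity: float  # apex intensity (configurable to area upstream)
    rt_lo: float = 0.0
    rt_hi: float = 0.0
    ms2_scan_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("feature intensity must be >= 0")
        if self.rt_hi == 0.0 and self.rt_lo == 0.0:
            self.rt_lo = self.rt_hi = self.rt_apex


@dataclass
class Run:
    """A full LC-MS/MS run: MS1 spectra, MS2 scans and MS1 features."""

    run_id: str
    ms1_spectra: list[Ms1Spectrum] = field(default_factory=list)
    scans: list[Ms2Scan] = field(default_factory=list)
    features: list[Ms1Feature] = field(default_factory=list)
    polarity: str = "positive"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        scan_ids = {s.scan_id for s in self.scans}
        for f in self.features:
            missing = [sid for sid in f.ms2_scan_ids if sid not in scan_ids]
            if missing:
                raise ValueError(
                    f"feature {f.feature_id} links unknown MS2 scans {missing}"
                )

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    def scan_by_id(self, scan_id: str) -> Ms2Scan:
        for s in self.scans:
            if s.scan_id == scan_id:
                return s
        raise KeyError(scan_id)


# ---------------------------------------------------------------------------
# mzML reading (lxml)
# ---------------------------------------------------------------------------

_MZML_NS_READ = "{http://psi.hupo.org/ms/mzml}"

# cvParam accessions the reader interprets
_ACC_MS_LEVEL = "MS:1000511"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_CHARGE = "MS:1000041"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_FLOAT64 = "MS:1000523"
_ACC_FLOAT32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _cv_params(elem) -> dict[str, str]:
    """accession -> value for cvParams that are direct children of ``elem``."""
    return {
        cv.get("accession"): cv.get("value", "")
        for cv in elem.findall(f"{_MZML_NS_READ}cvParam")
    }


def _decode_binary_array(array_elem) -> tuple[str | None, np.ndarray]:
    accs = _cv_params(array_elem)
    kind = (
        "mz" if _ACC_MZ_ARRAY in accs
        else "intensity" if _ACC_INTENSITY_ARRAY in accs
        else None
    )
    binary = array_elem.find(f"{_MZML_NS_READ}binary")
    payload = base64.b64decode(binary.text or "") if binary is not None else b""
    if _ACC_ZLIB in accs:
        payload = zlib.decompress(payload)
    dtype = "<f4" if _ACC_FLOAT32 in accs else "<f8"
    return kind, np.frombuffer(payload, dtype=dtype).astype(float)


def _scan_rt_seconds(spectrum_elem) -> float:
    for scan in spectrum_elem.iter(f"{_MZML_NS_READ}scan"):
        for cv in scan.findall(f"{_MZML_NS_READ}cvParam"):
            if cv.get("accession") == _ACC_SCAN_START:
                rt = float(cv.get("value", "0"))
                unit = (cv.get("unitName") or "").lower()
                if "minute" in unit or cv.get("unitAccession") == "UO:0000031":
                    rt *= 60.0
                return rt
    return 0.0


def read_mzml(
    path: str | Path,
    build_features: bool = True,
    feature_ppm: float = 5.0,
    feature_rt_gap_s: float = 6.0,
) -> Run:
    """Read a centroided mzML file into a :class:`Run`.

    MS2 scans without a precursor are skipped with a warning; profile-mode
    spectra raise :class:`ProfileModeError` advising centroiding.  Unless
    ``build_features=False``, MS1 features are built with
    :func:`find_features` and MS2 scans are linked to them.  Retention
    times in minutes are converted to seconds.
    """
    ms1: list[Ms1Spectrum] = []
    ms2: list[Ms2Scan] = []
    for _, spec in etree.iterparse(
        str(path), events=("end",), tag=f"{_MZML_NS_READ}spectrum"
    ):
        accs = _cv_params(spec)
        sid = str(spec.get("id", spec.get("index", "")))
        if _ACC_PROFILE in accs:
            raise ProfileModeError(
                f"{path}: profile-mode spectrum {sid!r}; "
                "centroid the data before decoding"
            )
        level = int(accs.get(_ACC_MS_LEVEL, "1") or 1)
        rt = _scan_rt_seconds(spec)
        mz = np.array([], dtype=float)
        inten = np.array([], dtype=float)
        for arr in spec.iter(f"{_MZML_NS_READ}binaryDataArray"):
            kind, values = _decode_binary_array(arr)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                inten = values
        if mz.size != inten.size:  # tolerate missing intensity array
            inten = np.ones_like(mz)
        if level == 1:
            ms1.append(Ms1Spectrum(sid, rt, mz, inten))
        else:
            pre_mz = None
            charge = 1
            for ion in spec.iter(f"{_MZML_NS_READ}selectedIon"):
                ion_accs = _cv_params(ion)
                if _ACC_SELECTED_MZ in ion_accs:
                    pre_mz = float(ion_accs[_ACC_SELECTED_MZ])
                    charge = int(ion_accs.get(_ACC_CHARGE, "1") or 1)
                break
            if pre_mz is None:
                warnings.warn(
                    f"MS2 scan {sid!r} lacks a precursor; skipped",
                    stacklevel=2,
                )
            else:
                ms2.append(Ms2Scan(sid, pre_mz, rt, mz, inten, charge))
        spec.clear(keep_tail=True)

    run = Run(run_id=Path(path).stem, ms1_spectra=ms1, scans=ms2)
    if build_features:
        run.features = find_features(ms1, ppm=feature_ppm, rt_gap_s=feature_rt_gap_s)
        link_ms2_to_features(run, ppm=feature_ppm, rt_pad_s=feature_rt_gap_s)
    return run


# ---------------------------------------------------------------------------
# mzML writing (minimal serialiser)
# ---------------------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _b64(values: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack(f"<{values.size}d", *map(float, values))
    ).decode("ascii")


def _cv(parent, accession: str, name: str, value: str = "", **unit) -> None:
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    attrs.update(unit)
    etree.SubElement(parent, f"{{{_MZML_NS}}}cvParam", attrs)


def _binary_array(parent, values: np.ndarray, accession: str, name: str) -> None:
    payload = _b64(values)
    arr = etree.SubElement(
        parent,
        f"{{{_MZML_NS}}}binaryDataArray",
        {"encodedLength": str(len(payload))},
    )
    _cv(arr, "MS:1000523", "64-bit float")
    _cv(arr, "MS:1000576", "no compression")
    _cv(arr, accession, name)
    etree.SubElement(arr, f"{{{_MZML_NS}}}binary").text = payload


def write_mzml(run: Run, path: str | Path) -> None:
    """Write a :class:`Run` as centroided mzML 1.1.0.

    Spectra (MS1 and MS2 together) are ordered by retention time; peak
    arrays are uncompressed little-endian 64-bit floats, so
    ``read_mzml(write_mzml(run))`` reproduces m/z, intensity and RT to
    floating-point precision.  Deterministic byte-for-byte for equal runs.
    """
    E = lambda parent, tag, **attrs: etree.SubElement(  # noqa: E731
        parent, f"{{{_MZML_NS}}}{tag}", {k: str(v) for k, v in attrs.items()}
    )
    root = etree.Element(
        f"{{{_MZML_NS}}}mzML", {"version": "1.1.0"}, nsmap={None: _MZML_NS}
    )
    cvs = E(root, "cvList", count=2)
    E(
        cvs, "cv", id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    E(cvs, "cv", id="UO", fullName="Unit Ontology",
      URI="http://ontologies.berkeleybop.org/uo.obo")
    fdesc = E(root, "fileDescription")
    fcontent = E(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    _cv(fcontent, "MS:1000580", "MSn spectrum")
    sw = E(root, "softwareList", count=1)
    E(sw, "software", id="seldecode", version="0.1.0")
    icl = E(root, "instrumentConfigurationList", count=1)
    E(icl, "instrumentConfiguration", id="IC1")
    dpl = E(root, "dataProcessingList", count=1)
    dp = E(dpl, "dataProcessing", id="DP1")
    pm = E(dp, "processingMethod", order=1, softwareRef="seldecode")
    _cv(pm, "MS:1000544", "Conversion to mzML")

    runel = E(root, "run", id=run.run_id, defaultInstrumentConfigurationRef="IC1")
    entries: list[tuple[float, int, object]] = []
    for i, s in enumerate(run.ms1_spectra):
        entries.append((s.rt, i, s))
    for i, s in enumerate(run.scans):
        entries.append((s.rt, len(run.ms1_spectra) + i, s))
    entries.sort(key=lambda t: (t[0], t[1]))

    slist = E(runel, "spectrumList", count=len(entries),
              defaultDataProcessingRef="DP1")
    polarity_cv = ("MS:1000130", "positive scan") if run.polarity == "positive" \
        else ("MS:1000129", "negative scan")
    for index, (_, _, s) in enumerate(entries):
        is_ms2 = isinstance(s, Ms2Scan)
        spec = E(slist, "spectrum", index=index, id=s.scan_id,
                 defaultArrayLength=int(s.mz.size))
        _cv(spec, "MS:1000511", "ms level", "2" if is_ms2 else "1")
        _cv(spec, *( ("MS:1000580", "MSn spectrum") if is_ms2
                     else ("MS:1000579", "MS1 spectrum") ))
        _cv(spec, "MS:1000127", "centroid spectrum")
        _cv(spec, *polarity_cv)
        sl = E(spec, "scanList", count=1)
        _cv(sl, "MS:1000795", "no combination")
        scan = E(sl, "scan")
        _cv(scan, "MS:1000016", "scan start time", repr(float(s.rt)),
            unitCvRef="UO", unitAccession="UO:0000010", unitName="second")
        if is_ms2:
            plist = E(spec, "precursorList", count=1)
            prec = E(plist, "precursor")
            sil = E(prec, "selectedIonList", count=1)
            ion = E(sil, "selectedIon")
            _cv(ion, "MS:1000744", "selected ion m/z",
                repr(float(s.precursor_mz)),
                unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
            _cv(ion, "MS:1000041", "charge state", str(s.precursor_charge))
        bdal = E(spec, "binaryDataArrayList", count=2)
        _binary_array(bdal, s.mz, "MS:1000514", "m/z array")
        _binary_array(bdal, s.intensity, "MS:1000515", "intensity array")

    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )


# ---------------------------------------------------------------------------
# Feature finding and MS2 linking
# ---------------------------------------------------------------------------


def find_features(
    ms1_spectra: Sequence[Ms1Spectrum],
    ppm: float = 5.0,
    rt_gap_s: float = 6.0,
    min_points: int = 1,
) -> list[Ms1Feature]:
    """Group MS1 peaks across spectra into features.

    Peaks are sorted by m/z and clustered wherever the relative gap between
    neighbours stays within ``ppm``; each m/z cluster is then split at
    retention-time gaps larger than ``rt_gap_s``.  The feature m/z is the
    intensity-weighted mean, the apex is the most intense point.
    """
    rows = [
        (mz, spec.rt, inten)
        for spec in ms1_spectra
        for mz, inten in zip(spec.mz, spec.intensity)
    ]
    if not rows:
        return []
    arr = np.array(rows, dtype=float)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]  # by mz, then rt
    mz, rt, inten = arr[:, 0], arr[:, 1], arr[:, 2]

    features: list[Ms1Feature] = []
    gaps = np.diff(mz) / mz[:-1] > ppm * 1e-6
    cluster_bounds = np.concatenate(
        ([0], np.flatnonzero(gaps) + 1, [mz.size])
    )
    fid = 0
    for a, b in zip(cluster_bounds[:-1], cluster_bounds[1:]):
        order = np.argsort(rt[a:b], kind="stable") + a
        sub_rt = rt[order]
        splits = np.concatenate(
            ([0], np.flatnonzero(np.diff(sub_rt) > rt_gap_s) + 1, [order.size])
        )
        for u, v in zip(splits[:-1], splits[1:]):
            sel = order[u:v]
            if sel.size < min_points:
                continue
            w = inten[sel]
            apex = sel[int(np.argmax(w))]
            features.append(
                Ms1Feature(
                    feature_id=f"F{fid:05d}",
                    mz=float(np.average(mz[sel], weights=np.maximum(w, 1e-12))),
                    rt_apex=float(rt[apex]),
                    intensity=float(inten[apex]),
                    rt_lo=float(sub_rt[u]),
                    rt_hi=float(sub_rt[v - 1]),
                )
            )
            fid += 1
    features.sort(key=lambda f: f.mz)
    return features


def link_ms2_to_features(
    run: Run, ppm: float = 5.0, rt_pad_s: float = 6.0
) -> None:
    """Attach each MS2 scan to the feature containing its precursor.

    A scan links to the feature whose m/z is nearest among those within
    ``ppm`` (relative to the feature m/z) whose padded RT span covers the
    scan.  Scans with no such feature stay unlinked.
    """
    for f in run.features:
        f.ms2_scan_ids.clear()
    if not run.features:
        return
    fmz = np.array([f.mz for f in run.features])
    for scan in run.scans:
        rel = np.abs(fmz - scan.precursor_mz) / fmz
        ok = [
            i
            for i in np.flatnonzero(rel <= ppm * 1e-6)
            if run.features[i].rt_lo - rt_pad_s
            <= scan.rt
            <= run.features[i].rt_hi + rt_pad_s
        ]
        if ok:
            best = min(ok, key=lambda i: rel[i])
            run.features[best].ms2_scan_ids.append(scan.scan_id)


# ---------------------------------------------------------------------------
# Peak utilities
# ---------------------------------------------------------------------------


def top_n_peaks(scan: Ms2Scan, n: int) -> tuple[np.ndarray, np.ndarray]:
    """The ``n`` most intense peaks, ties to lower m/z, in m/z order.

    Mirrors the decoder's "number of considered peaks" setting: only these
    peaks participate in fragment matching.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if scan.n_peaks <= n:
        return scan.mz.copy(), scan.intensity.copy()
    order = np.lexsort((scan.mz, -scan.intensity))[:n]
    order.sort()  # restore m/z order (peaks are mz-sorted already)
    return scan.mz[order], scan.intensity[order]


def extract_ion_chromatogram(
    run: Run, mz: float, ppm: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """XIC: per MS1 spectrum, summed intensity of peaks within +-ppm of mz.

    The ppm window is referenced to the queried (theoretical) m/z.
    """
    if ppm <= 0:
        raise ValueError("ppm must be > 0")
    tol = mz * ppm * 1e-6
    rts = np.array([s.rt for s in run.ms1_spectra])
    intensities = np.array(
        [
            float(s.intensity[(s.mz >= mz - tol) & (s.mz <= mz + tol)].sum())
            for s in run.ms1_spectra
        ]
    )
    return rts, intensities


# ---------------------------------------------------------------------------
# Sidecar feature tables
# ---------------------------------------------------------------------------


def write_feature_table(features: Iterable[Ms1Feature], path: str | Path) -> None:
    rows = [
        {
            "feature_id": f.feature_id,
            "mz": f.mz,
            "rt_s": f.rt_apex,
            "intensity": f.intensity,
            "rt_lo": f.rt_lo,
            "rt_hi": f.rt_hi,
            "ms2_scan_ids": ";".join(f.ms2_scan_ids),
        }
        for f in features
    ]
    pd.DataFrame(
        rows,
        columns=[
            "feature_id", "mz", "rt_s", "intensity", "rt_lo", "rt_hi",
            "ms2_scan_ids",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> list[Ms1Feature]:
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    out = []
    for row in df.itertuples(index=False):
        ids = getattr(row, "ms2_scan_ids", "")
        ids = [] if pd.isna(ids) or ids == "" else str(ids).split(";")
        out.append(
            Ms1Feature(
                feature_id=str(row.feature_id),
                mz=float(row.mz),
                rt_apex=float(row.rt_s),
                intensity=float(row.intensity),
                rt_lo=float(getattr(row, "rt_lo", row.rt_s)),
                rt_hi=float(getattr(row, "rt_hi", row.rt_s)),
                ms2_scan_ids=ids,
            )
        )
    return out
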