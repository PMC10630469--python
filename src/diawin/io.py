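"""mzML and tabular I/O plus the in-memory run model.

The run model is deliberately small: centroided spectra only, retention
times in minutes throughout the API, and (for DIA) the isolation-window
scheme reconstructed from the precursor-window metadata on the MS2 scans.
mzML support is self-contained on the standard library: the reader
handles plain and indexed mzML with 32/64-bit float arrays, optional
zlib compression and second- or minute-valued scan times; the writer
emits plain mzML with uncompressed 64-bit arrays so simulated runs
survive a write/read round trip losslessly.
"""

from __future__ import annotations

import base64
import zlib
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class MzmlError(ValueError):
    """Raised for malformed or unsupported mzML content."""


@dataclass
class Spectrum:
    """One centroided scan.

    ``mz`` / ``intensity`` are parallel arrays sorted by ascending m/z.
    ``precursor_window`` is the quadrupole isolation interval (low, high)
    in Th and is required for MS2 scans.
    """

    index: int
    ms_level: int
    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "positive"
    precursor_window: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise MzmlError("mz and intensity arrays differ in length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            if np.any(np.diff(self.mz) == 0):
                raise MzmlError(f"duplicate m/z within spectrum {self.index}")
        if self.rt < 0:
            raise MzmlError(f"negative retention time on spectrum {self.index}")
        if self.ms_level == 2 and self.precursor_window is None:
            raise MzmlError(f"MS2 spectrum {self.index} lacks a precursor isolation window")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class Run:
    """An acquisition: ordered spectra plus mode and (DIA) window scheme.

    ``windows`` holds the *extended* isolation bounds as read from the MS2
    scans, sorted by low bound; for simulated runs these equal the scheme
    handed to the simulator bit for bit.
    """

    spectra: list[Spectrum]
    mode: str = "DDA"  # {"DDA", "DIA"}
    windows: list[tuple[float, float]] = field(default_factory=list)
    sample_id: str = ""
    polarity: str = "positive"

    def ms1_spectra(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2_spectra(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]


@dataclass
class SampleManifest:
    sample_id: str
    path: str
    group: str
    injection_volume_uL: Optional[float] = None
    replicate: Optional[int] = None


MANIFEST_COLUMNS = ["sample_id", "path", "group", "injection_volume_uL", "replicate"]


def infer_mode(spectra: Sequence[Spectrum]) -> str:
    """A run is DIA iff at least two MS2 scans share identical precursor
    bounds spanning more than 2 Th; otherwise DDA."""
    seen: dict[tuple[float, float], int] = {}
    for s in spectra:
        if s.ms_level != 2 or s.precursor_window is None:
            continue
        lo, hi = s.precursor_window
        if hi - lo <= 2.0:
            continue
        seen[(lo, hi)] = seen.get((lo, hi), 0) + 1
        if seen[(lo, hi)] >= 2:
            return "DIA"
    return "DDA"


def collect_windows(spectra: Sequence[Spectrum]) -> list[tuple[float, float]]:
    wins = {s.precursor_window for s in spectra if s.ms_level == 2 and s.precursor_window}
    return sorted(wins)


def make_run(spectra: list[Spectrum], sample_id: str = "", polarity: str = "positive") -> Run:
    mode = infer_mode(spectra)
    windows = collect_windows(spectra) if mode == "DIA" else []
    return Run(spectra=spectra, mode=mode, windows=windows, sample_id=sample_id, polarity=polarity)


# ---------------------------------------------------------------------------
# mzML reading
# ---------------------------------------------------------------------------

def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda: ET.Element) -> np.ndarray:
    dtype = "<f8"
    compressed = False
    payload = ""
    for child in bda.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":
                dtype = "<f4"
            elif acc == "MS:1000523":
                dtype = "<f8"
            elif acc == "MS:1000574":
                compressed = True
        elif name == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(elem: ET.Element, index: int, path_name: str) -> Spectrum:
    level = 1
    rt = 0.0
    rt_seconds = False
    polarity = "positive"
    window = None
    has_window_meta = False
    mz = np.array([])
    inten = np.array([])
    for child in elem.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000511":
                level = int(child.get("value", "1"))
            elif acc == "MS:1000128":
                raise MzmlError(
                    f"{path_name}: spectrum {index} is profile mode; centroid the data first"
                )
            elif acc == "MS:1000129":
                polarity = "negative"
            elif acc == "MS:1000016":
                rt = float(child.get("value", "0"))
                unit = (child.get("unitName") or "").lower()
                rt_seconds = unit.startswith("second") or child.get("unitAccession") == "UO:0000010"
    if rt_seconds:
        rt /= 60.0
    for iso in elem.iter():
        if _local(iso.tag) != "isolationWindow":
            continue
        target = lower = upper = None
        for cv in iso:
            acc = cv.get("accession", "")
            if acc == "MS:1000827":
                target = float(cv.get("value"))
            elif acc == "MS:1000828":
                lower = float(cv.get("value"))
            elif acc == "MS:1000829":
                upper = float(cv.get("value"))
        if target is not None and lower is not None and upper is not None:
            window = (target - lower, target + upper)
            has_window_meta = True
    arrays = []
    for bda in elem.iter():
        if _local(bda.tag) == "binaryDataArray":
            kinds = {cv.get("accession") for cv in bda.iter() if _local(cv.tag) == "cvParam"}
            arrays.append(("mz" if "MS:1000514" in kinds else
                           "intensity" if "MS:1000515" in kinds else "other",
                           _decode_binary_array(bda)))
    for kind, arr in arrays:
        if kind == "mz":
            mz = arr
        elif kind == "intensity":
            inten = arr
    if level >= 2 and not has_window_meta:
        raise MzmlError(f"{path_name}: MS2 spectrum {index} has no isolation window metadata")
    return Spectrum(index=index, ms_level=level, rt=rt, mz=mz, intensity=inten,
                    polarity=polarity, precursor_window=window)


def read_mzml(path: str | Path) -> Run:
    """Read a centroided mzML file into a :class:`Run`.

    MS2 scans must carry isolation-window metadata; profile-mode spectra
    are rejected (centroid upstream, e.g. during vendor conversion).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    polarity = "positive"
    i = 0
    for _, elem in ET.iterparse(str(path), events=("end",)):
        if _local(elem.tag) != "spectrum":
            continue
        spec = _parse_spectrum(elem, i, path.name)
        if spec.polarity == "negative":
            polarity = "negative"
        spectra.append(spec)
        i += 1
        elem.clear()
    return make_run(spectra, sample_id=path.stem, polarity=polarity)


# ---------------------------------------------------------------------------
# mzML writing
# ---------------------------------------------------------------------------

_CV = "MS"


def _cv(parent: ET.Element, accession: str, name: str, value: str = "", **unit) -> None:
    attrs = {"cvRef": _CV, "accession": accession, "name": name, "value": value}
    attrs.update(unit)
    ET.SubElement(parent, "cvParam", attrs)


def _encode(array: np.ndarray) -> str:
    data = np.asarray(array, dtype="<f8").tobytes()
    return base64.b64encode(data).decode("ascii")


def _binary_array(parent: ET.Element, array: np.ndarray, kind: str) -> None:
    payload = _encode(array)
    bda = ET.SubElement(parent, "binaryDataArray", {"encodedLength": str(len(payload))})
    _cv(bda, "MS:1000523", "64-bit float")
    _cv(bda, "MS:1000576", "no compression")
    if kind == "mz":
        _cv(bda, "MS:1000514", "m/z array", unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
    else:
        _cv(bda, "MS:1000515", "intensity array", unitCvRef="MS",
            unitAccession="MS:1000131", unitName="number of detector counts")
    ET.SubElement(bda, "binary").text = payload


def write_mzml(run: Run, path: str | Path) -> Path:
    """Serialize a run as plain (non-indexed) mzML readable by pyteomics."""
    path = Path(path)
    root = ET.Element(
        "mzML",
        {
            "xmlns": "http://psi.hupo.org/ms/mzml",
            "version": "1.1.0",
            "id": run.sample_id or path.stem,
        },
    )
    cvlist = ET.SubElement(root, "cvList", {"count": "2"})
    ET.SubElement(cvlist, "cv", {"id": "MS", "fullName": "PSI-MS", "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"})
    ET.SubElement(cvlist, "cv", {"id": "UO", "fullName": "UNIT-ONTOLOGY", "URI": "https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"})
    fdl = ET.SubElement(root, "fileDescription")
    fc = ET.SubElement(fdl, "fileContent")
    _cv(fc, "MS:1000580", "MSn spectrum")
    slist = ET.SubElement(root, "softwareList", {"count": "1"})
    ET.SubElement(slist, "software", {"id": "diawin", "version": "0.1.0"})
    icl = ET.SubElement(root, "instrumentConfigurationList", {"count": "1"})
    ET.SubElement(icl, "instrumentConfiguration", {"id": "IC1"})
    dpl = ET.SubElement(root, "dataProcessingList", {"count": "1"})
    dp = ET.SubElement(dpl, "dataProcessing", {"id": "DP1"})
    pm = ET.SubElement(dp, "processingMethod", {"order": "1", "softwareRef": "diawin"})
    _cv(pm, "MS:1000544", "Conversion to mzML")

    runel = ET.SubElement(
        root, "run", {"id": run.sample_id or "run", "defaultInstrumentConfigurationRef": "IC1"}
    )
    speclist = ET.SubElement(
        runel, "spectrumList", {"count": str(len(run.spectra)), "defaultDataProcessingRef": "DP1"}
    )
    for i, s in enumerate(run.spectra):
        spec = ET.SubElement(
            speclist,
            "spectrum",
            {"index": str(i), "id": f"scan={i}", "defaultArrayLength": str(s.n_peaks)},
        )
        if s.ms_level == 1:
            _cv(spec, "MS:1000579", "MS1 spectrum")
        else:
            _cv(spec, "MS:1000580", "MSn spectrum")
        _cv(spec, "MS:1000511", "ms level", str(s.ms_level))
        _cv(spec, "MS:1000127", "centroid spectrum")
        if s.polarity == "negative":
            _cv(spec, "MS:1000129", "negative scan")
        else:
            _cv(spec, "MS:1000130", "positive scan")
        scanlist = ET.SubElement(spec, "scanList", {"count": "1"})
        _cv(scanlist, "MS:1000795", "no combination")
        scan = ET.SubElement(scanlist, "scan")
        _cv(scan, "MS:1000016", "scan start time", repr(float(s.rt)),
            unitCvRef="UO", unitAccession="UO:0000031", unitName="minute")
        if s.ms_level == 2:
            lo, hi = s.precursor_window
            target = 0.5 * (lo + hi)
            plist = ET.SubElement(spec, "precursorList", {"count": "1"})
            prec = ET.SubElement(plist, "precursor")
            iso = ET.SubElement(prec, "isolationWindow")
            _cv(iso, "MS:1000827", "isolation window target m/z", repr(float(target)),
                unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
            _cv(iso, "MS:1000828", "isolation window lower offset", repr(float(target - lo)),
                unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
            _cv(iso, "MS:1000829", "isolation window upper offset", repr(float(hi - target)),
                unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
            act = ET.SubElement(prec, "activation")
            _cv(act, "MS:1000422", "beam-type collision-induced dissociation")
        arrays = ET.SubElement(spec, "binaryDataArrayList", {"count": "2"})
        _binary_array(arrays, s.mz, "mz")
        _binary_array(arrays, s.intensity, "intensity")

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Sample manifests
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> list[SampleManifest]:
    """Read a tab-delimited sample manifest.

    Required columns: sample_id, path, group; optional:
    injection_volume_uL, replicate. Duplicate sample ids and non-positive
    or non-numeric volumes are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"manifest {path} has no data rows")
    for col in ("sample_id", "path", "group"):
        if col not in df.columns:
            raise ValueError(f"manifest {path} lacks required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in manifest")
    records = []
    for _, row in df.iterrows():
        vol = None
        raw = row.get("injection_volume_uL")
        if raw is not None and not pd.isna(raw) and str(raw) != "":
            try:
                vol = float(raw)
            except ValueError:
                raise ValueError(
                    f"non-numeric injection volume {raw!r} for sample {row['sample_id']}"
                ) from None
            if vol <= 0:
                raise ValueError(f"injection volume must be > 0 (sample {row['sample_id']})")
        rep = row.get("replicate")
        rep = int(rep) if rep is not None and not pd.isna(rep) and str(rep) != "" else None
        records.append(
            SampleManifest(
                sample_id=str(row["sample_id"]),
                path=str(row["path"]),
                group=str(row["group"]),
                injection_volume_uL=vol,
                replicate=rep,
            )
        )
    return records


def write_manifest(records: Sequence[SampleManifest], path: str | Path) -> Path:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "path": r.path,
                "group": r.group,
                "injection_volume_uL": r.injection_volume_uL,
                "replicate": r.replicate,
            }
            for r in records
        ],
        columns=MANIFEST_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)
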