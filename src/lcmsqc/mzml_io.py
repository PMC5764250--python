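"""mzML and qcML I/O, plus the file-naming convention that routes runs.

The mzML reader is a streaming lxml parser covering the metadata this
package needs (MS level, retention time, ion injection time, per-scan TIC,
precursor m/z, peak arrays, SRM chromatograms); indexed and non-indexed
documents are accepted, binary arrays may be 32/64-bit and zlib-compressed,
and profile spectra are centroided by local-maximum picking with
intensity-weighted m/z. Writing (needed so synthetic runs can be
round-tripped through the open standard) emits a minimal, deterministic
mzML 1.1 document with 64-bit uncompressed binary arrays.

Metric sets are exported in a small, self-consistent qcML-style dialect:
one ``runQuality`` block per run, one ``qualityParameter`` per metric,
carrying the HUPO-PSI CV accession where the metric has one and a local
``LCMSQC:`` accession otherwise.

File-naming convention (the routing contract for ingestion):
``<YYYYMMDDThhmmss>_<instrument>_<QC1|QC2>_<freetext>.mzML``,
underscore-delimited; the QC token is case-insensitive.
"""

from __future__ import annotations

import base64
import re
import zlib
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Optional
from xml.sax.saxutils import quoteattr

import numpy as np
from lxml import etree

__all__ = [
    "SpectrumMeta",
    "Chromatogram",
    "RunData",
    "read_run",
    "write_mzml",
    "parse_run_name",
    "RunNameError",
    "write_qcml",
    "read_qcml",
    "QCML_NAMESPACE",
    "LOCAL_CV_PREFIX",
]

QCML_NAMESPACE = "urn:lcmsqc:qcml-lite:0.1"
LOCAL_CV_PREFIX = "LCMSQC"


class MzmlFormatError(ValueError):
    """Raised when an mzML file lacks required per-spectrum metadata."""


class RunNameError(ValueError):
    """Raised when a file name does not match the routing convention."""


@dataclass
class SpectrumMeta:
    """One spectrum: scan metadata plus centroided peak arrays."""

    index: int
    ms_level: int
    rt: float  # seconds
    tic: float
    injection_time: Optional[float] = None  # milliseconds
    precursor_mz: Optional[float] = None  # MS2 only
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class Chromatogram:
    """An SRM-style chromatogram: id plus time/intensity arrays."""

    id: str
    rt: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None


@dataclass
class RunData:
    """One parsed QC acquisition."""

    spectra: list[SpectrumMeta]
    chromatograms: list[Chromatogram] = field(default_factory=list)
    instrument: Optional[str] = None
    qc_type: Optional[str] = None
    acquired_at: Optional[datetime] = None
    source_name: Optional[str] = None

    @property
    def ms1_count(self) -> int:
        return sum(1 for s in self.spectra if s.ms_level == 1)

    @property
    def ms2_count(self) -> int:
        return sum(1 for s in self.spectra if s.ms_level == 2)

    @property
    def chromatogram_count(self) -> int:
        return len(self.chromatograms)

    def ms1_spectra(self) -> list[SpectrumMeta]:
        return [s for s in self.spectra if s.ms_level == 1]


# --- file-naming convention -------------------------------------------------

_NAME_RE = re.compile(
    r"^(?P<ts>\d{8}T\d{6})_(?P<instrument>[^_]+)_(?P<qc>[Qq][Cc][12])_(?P<rest>.+)\.mzml$",
    re.IGNORECASE,
)

_NAME_PATTERN = "<YYYYMMDDThhmmss>_<instrument>_<QC1|QC2>_<freetext>.mzML"


def parse_run_name(name: str) -> tuple[str, str, datetime]:
    """Extract (instrument, qc_type, timestamp) from a run file name."""
    m = _NAME_RE.match(Path(name).name)
    if m is None:
        raise RunNameError(
            f"file name {Path(name).name!r} does not match the naming "
            f"convention {_NAME_PATTERN}"
        )
    ts = datetime.strptime(m.group("ts"), "%Y%m%dT%H%M%S")
    return m.group("instrument"), m.group("qc").upper(), ts


# --- mzML reading -----------------------------------------------------------

def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> dict[str, dict]:
    """All cvParam descendants of ``elem``, keyed by name."""
    return {
        cv.get("name"): {
            "value": cv.get("value"),
            "unit": cv.get("unitName"),
            "accession": cv.get("accession"),
        }
        for cv in elem.iter()
        if _local(cv.tag) == "cvParam"
    }


def _to_seconds(value: float, unit: Optional[str]) -> float:
    if unit and unit.startswith("minute"):
        return value * 60.0
    if unit and unit.startswith("hour"):
        return value * 3600.0
    return value


def _decode_arrays(elem) -> dict[str, tuple[np.ndarray, Optional[str]]]:
    """Decode the binaryDataArrayList of a spectrum/chromatogram element.

    Returns {array kind: (values, unit)} for the m/z, intensity and time
    arrays; 32/64-bit floats and zlib compression are handled.
    """
    out: dict[str, tuple[np.ndarray, Optional[str]]] = {}
    for bda in elem.iter():
        if _local(bda.tag) != "binaryDataArray":
            continue
        params = _cv_params(bda)
        binary = next(
            (c for c in bda if _local(c.tag) == "binary"), None
        )
        raw = base64.b64decode(binary.text or "") if binary is not None else b""
        if "zlib compression" in params:
            raw = zlib.decompress(raw)
        dtype = "<f4" if "32-bit float" in params else "<f8"
        values = np.frombuffer(raw, dtype=dtype).astype(float)
        for kind in ("m/z array", "intensity array", "time array"):
            if kind in params:
                out[kind] = (values, params[kind]["unit"])
                break
    return out


def _centroid_profile(mz: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid a profile spectrum by local-maximum picking.

    Each local maximum becomes one centroid at the intensity-weighted m/z
    of the maximum and its immediate neighbours, with the summed intensity
    of that 3-point window.
    """
    n = len(intensity)
    if n < 3:
        return mz, intensity
    is_max = np.zeros(n, dtype=bool)
    is_max[1:-1] = (
        (intensity[1:-1] >= intensity[:-2])
        & (intensity[1:-1] > intensity[2:])
        & (intensity[1:-1] > 0)
    )
    cmz, cint = [], []
    for i in np.flatnonzero(is_max):
        w = intensity[i - 1 : i + 2]
        total = float(w.sum())
        cmz.append(float((mz[i - 1 : i + 2] * w).sum()) / total)
        cint.append(total)
    return np.asarray(cmz), np.asarray(cint)


def _parse_spectrum(elem, ordinal: int) -> SpectrumMeta:
    params = _cv_params(elem)
    level = int(params["ms level"]["value"]) if "ms level" in params else 1
    index = int(elem.get("index", ordinal))
    if "scan start time" not in params:
        raise MzmlFormatError(f"spectrum index {index} has no retention time")
    rt = _to_seconds(
        float(params["scan start time"]["value"]), params["scan start time"]["unit"]
    )
    it = params.get("ion injection time")
    arrays = _decode_arrays(elem)
    mz_arr = arrays.get("m/z array", (np.empty(0), None))[0]
    int_arr = arrays.get("intensity array", (np.empty(0), None))[0]
    if "profile spectrum" in params and "centroid spectrum" not in params:
        mz_arr, int_arr = _centroid_profile(mz_arr, int_arr)
    prec = None
    if level >= 2:
        if "selected ion m/z" in params:
            prec = float(params["selected ion m/z"]["value"])
        elif "isolation window target m/z" in params:
            prec = float(params["isolation window target m/z"]["value"])
        if prec is None:
            raise MzmlFormatError(f"MS2 spectrum index {index} has no precursor m/z")
    tic = params.get("total ion current")
    return SpectrumMeta(
        index=index,
        ms_level=level,
        rt=rt,
        tic=float(tic["value"]) if tic and tic["value"] else float(int_arr.sum()),
        injection_time=float(it["value"]) if it and it["value"] else None,
        precursor_mz=prec,
        mz=mz_arr,
        intensity=int_arr,
    )


def _parse_chromatogram(elem) -> Chromatogram:
    params = _cv_params(elem)
    arrays = _decode_arrays(elem)
    t, t_unit = arrays.get("time array", (np.empty(0), None))
    inten = arrays.get("intensity array", (np.empty(0), None))[0]
    prec = None
    if "isolation window target m/z" in params:
        prec = float(params["isolation window target m/z"]["value"])
    return Chromatogram(
        id=str(elem.get("id")),
        rt=np.asarray([_to_seconds(v, t_unit) for v in t]),
        intensity=inten,
        precursor_mz=prec,
    )


def read_run(path: str | Path) -> RunData:
    """Read an mzML file into :class:`RunData`.

    Retention times are normalized to seconds; per-scan TIC is recomputed
    from the peak list when the file does not record it; injection time is
    kept in milliseconds and left absent when not recorded (e.g. SRM data).
    Routing fields are populated from the file name when it matches the
    naming convention.
    """
    path = Path(path)
    spectra: list[SpectrumMeta] = []
    chroms: list[Chromatogram] = []
    try:
        ordinal = 0
        for _event, elem in etree.iterparse(str(path), events=("end",)):
            tag = _local(elem.tag)
            if tag == "spectrum":
                spectra.append(_parse_spectrum(elem, ordinal))
                ordinal += 1
                elem.clear()
            elif tag == "chromatogram":
                chroms.append(_parse_chromatogram(elem))
                elem.clear()
    except etree.XMLSyntaxError as exc:
        raise IOError(f"unreadable mzML file {path}: {exc}") from exc

    run = RunData(spectra=spectra, chromatograms=chroms, source_name=path.name)
    try:
        run.instrument, run.qc_type, run.acquired_at = parse_run_name(path.name)
    except RunNameError:
        pass
    return run


# --- mzML writing -----------------------------------------------------------

def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


def _cv(acc: str, name: str, value: str = "", unit: tuple[str, str, str] | None = None) -> str:
    s = f'<cvParam cvRef="MS" accession="{acc}" name={quoteattr(name)} value={quoteattr(value)}'
    if unit is not None:
        ref, uacc, uname = unit
        s += f' unitCvRef="{ref}" unitAccession="{uacc}" unitName="{uname}"'
    return s + "/>"


_UNIT_S = ("UO", "UO:0000010", "second")
_UNIT_MS = ("UO", "UO:0000028", "millisecond")
_UNIT_MZ = ("MS", "MS:1000040", "m/z")


def _binary_array(arr: np.ndarray, kind: str, out: list[str]) -> None:
    enc = _b64(arr)
    out.append(f'<binaryDataArray encodedLength="{len(enc)}">')
    out.append(_cv("MS:1000523", "64-bit float"))
    out.append(_cv("MS:1000576", "no compression"))
    if kind == "mz":
        out.append(_cv("MS:1000514", "m/z array", unit=_UNIT_MZ))
    elif kind == "time":
        out.append(_cv("MS:1000595", "time array", unit=_UNIT_S))
    else:
        out.append(_cv("MS:1000515", "intensity array"))
    out.append(f"<binary>{enc}</binary>")
    out.append("</binaryDataArray>")


def write_mzml(run: RunData, path: str | Path) -> None:
    """Write :class:`RunData` as a minimal mzML 1.1 document.

    Output is deterministic (no wall-clock timestamps): identical RunData
    produces byte-identical files.
    """
    out: list[str] = []
    out.append('<?xml version="1.0" encoding="utf-8"?>')
    out.append(
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" '
        f'id={quoteattr(run.source_name or "run")}>'
    )
    out.append('<cvList count="2">')
    out.append(
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" '
        'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
    )
    out.append(
        '<cv id="UO" fullName="Unit Ontology" '
        'URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
    )
    out.append("</cvList>")
    out.append("<fileDescription><fileContent>")
    out.append(_cv("MS:1000579", "MS1 spectrum"))
    out.append("</fileContent></fileDescription>")
    out.append('<softwareList count="1"><software id="lcmsqc" version="0.1.0"/></softwareList>')
    out.append(
        '<instrumentConfigurationList count="1">'
        '<instrumentConfiguration id="IC1"/></instrumentConfigurationList>'
    )
    out.append(
        '<dataProcessingList count="1"><dataProcessing id="dp">'
        '<processingMethod order="1" softwareRef="lcmsqc">'
        + _cv("MS:1000544", "Conversion to mzML")
        + "</processingMethod></dataProcessing></dataProcessingList>"
    )
    attrs = f"id={quoteattr(run.source_name or 'run')} defaultInstrumentConfigurationRef=\"IC1\""
    if run.acquired_at is not None:
        attrs += f' startTimeStamp="{run.acquired_at.isoformat()}"'
    out.append(f"<run {attrs}>")

    out.append(f'<spectrumList count="{len(run.spectra)}" defaultDataProcessingRef="dp">')
    for s in run.spectra:
        out.append(
            f'<spectrum index="{s.index}" id="scan={s.index + 1}" '
            f'defaultArrayLength="{len(s.mz)}">'
        )
        if s.ms_level == 1:
            out.append(_cv("MS:1000579", "MS1 spectrum"))
        else:
            out.append(_cv("MS:1000580", "MSn spectrum"))
        out.append(_cv("MS:1000511", "ms level", str(s.ms_level)))
        out.append(_cv("MS:1000127", "centroid spectrum"))
        out.append(_cv("MS:1000285", "total ion current", repr(float(s.tic))))
        out.append('<scanList count="1">')
        out.append(_cv("MS:1000795", "no combination"))
        out.append("<scan>")
        out.append(_cv("MS:1000016", "scan start time", repr(float(s.rt)), unit=_UNIT_S))
        if s.injection_time is not None:
            out.append(
                _cv("MS:1000927", "ion injection time", repr(float(s.injection_time)), unit=_UNIT_MS)
            )
        out.append("</scan></scanList>")
        if s.ms_level >= 2 and s.precursor_mz is not None:
            out.append('<precursorList count="1"><precursor>')
            out.append('<selectedIonList count="1"><selectedIon>')
            out.append(
                _cv("MS:1000744", "selected ion m/z", repr(float(s.precursor_mz)), unit=_UNIT_MZ)
            )
            out.append("</selectedIon></selectedIonList>")
            out.append("<activation>" + _cv("MS:1000133", "collision-induced dissociation") + "</activation>")
            out.append("</precursor></precursorList>")
        out.append('<binaryDataArrayList count="2">')
        _binary_array(s.mz, "mz", out)
        _binary_array(s.intensity, "intensity", out)
        out.append("</binaryDataArrayList>")
        out.append("</spectrum>")
    out.append("</spectrumList>")

    if run.chromatograms:
        out.append(
            f'<chromatogramList count="{len(run.chromatograms)}" defaultDataProcessingRef="dp">'
        )
        for i, c in enumerate(run.chromatograms):
            out.append(
                f'<chromatogram index="{i}" id={quoteattr(c.id)} '
                f'defaultArrayLength="{len(c.rt)}">'
            )
            out.append(_cv("MS:1000627", "selected ion current chromatogram"))
            if c.precursor_mz is not None:
                out.append("<precursor><isolationWindow>")
                out.append(
                    _cv(
                        "MS:1000827",
                        "isolation window target m/z",
                        repr(float(c.precursor_mz)),
                        unit=_UNIT_MZ,
                    )
                )
                out.append("</isolationWindow></precursor>")
            out.append('<binaryDataArrayList count="2">')
            _binary_array(c.rt, "time", out)
            _binary_array(c.intensity, "intensity", out)
            out.append("</binaryDataArrayList>")
            out.append("</chromatogram>")
        out.append("</chromatogramList>")

    out.append("</run></mzML>")
    Path(path).write_bytes("\n".join(out).encode("utf-8"))


# --- qcML-style metric export ------------------------------------------------

def write_qcml(metric_set, path: str | Path) -> None:
    """Write a MetricSet as a qcML-style XML document.

    Each metric is emitted as a ``qualityParameter`` with its controlled-
    vocabulary accession where one exists and a local ``LCMSQC:`` accession
    otherwise. Values are serialized with full precision so a read-back
    round-trips exactly.
    """
    root = etree.Element("{%s}qcML" % QCML_NAMESPACE, nsmap={None: QCML_NAMESPACE})
    root.set("version", "0.1")
    rq = etree.SubElement(root, "{%s}runQuality" % QCML_NAMESPACE)
    rq.set("ID", metric_set.run_id or "run")
    for attr in ("instrument", "qc_type"):
        value = getattr(metric_set, attr, None)
        if value:
            rq.set(attr, value)
    if getattr(metric_set, "acquired_at", None):
        rq.set("acquiredAt", metric_set.acquired_at.isoformat())
    for rec in metric_set.records:
        qp = etree.SubElement(rq, "{%s}qualityParameter" % QCML_NAMESPACE)
        acc = rec.cv_accession or f"{LOCAL_CV_PREFIX}:{rec.metric_id}"
        qp.set("accession", acc)
        qp.set("name", rec.metric_id)
        qp.set("value", repr(rec.value))
        if rec.units:
            qp.set("unit", rec.units)
        if rec.target is not None:
            qp.set("target", rec.target)
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )


def read_qcml(path: str | Path):
    """Read back a qcML-style document written by :func:`write_qcml`."""
    from .qc_metrics import MetricRecord, MetricSet  # deferred: avoids cycle

    tree = etree.parse(str(path))
    ns = {"q": QCML_NAMESPACE}
    sets = []
    for rq in tree.getroot().findall("q:runQuality", ns):
        records = []
        for qp in rq.findall("q:qualityParameter", ns):
            acc = qp.get("accession")
            if acc is not None and acc.startswith(LOCAL_CV_PREFIX + ":"):
                acc = None
            records.append(
                MetricRecord(
                    metric_id=qp.get("name"),
                    value=float(qp.get("value")),
                    units=qp.get("unit") or "",
                    cv_accession=acc,
                    target=qp.get("target"),
                    run_id=rq.get("ID"),
                )
            )
        acquired = rq.get("acquiredAt")
        sets.append(
            MetricSet(
                run_id=rq.get("ID"),
                instrument=rq.get("instrument"),
                qc_type=rq.get("qc_type"),
                acquired_at=datetime.fromisoformat(acquired) if acquired else None,
                records=records,
            )
        )
    return sets[0] if len(sets) == 1 else sets
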