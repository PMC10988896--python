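"""Minimal centroided mzML export of a simulated run.

Writes a self-contained mzML 1.1 document (64-bit, zlib-free, base64-encoded
binary arrays) that standard readers such as pyteomics.mzml parse back into
the same m/z and intensity arrays. Scan start times are recorded in minutes,
injection times in milliseconds, and MS2-type scans carry their isolation
window targets.
"""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET

import numpy as np

from .engine import RunResult
from .instrument import ScanRecord, ScanType

__all__ = ["write_mzml"]

_CV = "MS"


def _cv(parent, accession, name, value="", unit=None):
    attrs = {"cvRef": _CV, "accession": accession, "name": name, "value": str(value)}
    if unit is not None:
        attrs.update(
            {"unitCvRef": "UO", "unitAccession": unit[0], "unitName": unit[1]}
        )
    ET.SubElement(parent, "cvParam", attrs)


def _binary(parent, data: np.ndarray, accession: str, name: str, unit=None) -> None:
    raw = struct.pack(f"<{len(data)}d", *np.asarray(data, dtype=float))
    b64 = base64.b64encode(raw).decode()
    bda = ET.SubElement(parent, "binaryDataArray", {"encodedLength": str(len(b64))})
    _cv(bda, "MS:1000523", "64-bit float")
    _cv(bda, "MS:1000576", "no compression")
    _cv(bda, accession, name, unit=unit)
    ET.SubElement(bda, "binary").text = b64


def _spectrum_element(parent, index: int, scan: ScanRecord) -> None:
    n = len(scan.spectrum.mz)
    spec = ET.SubElement(
        parent,
        "spectrum",
        {"index": str(index), "id": f"scan={index + 1}", "defaultArrayLength": str(n)},
    )
    ms_level = 1 if scan.request.scan_type is ScanType.MS1 else 2
    _cv(spec, "MS:1000511", "ms level", ms_level)
    _cv(spec, "MS:1000127", "centroid spectrum")
    if ms_level == 1:
        _cv(spec, "MS:1000579", "MS1 spectrum")
    else:
        _cv(spec, "MS:1000580", "MSn spectrum")
    scan_list = ET.SubElement(spec, "scanList", {"count": "1"})
    _cv(scan_list, "MS:1000795", "no combination")
    sc = ET.SubElement(scan_list, "scan")
    _cv(sc, "MS:1000016", "scan start time", scan.start_s / 60.0,
        unit=("UO:0000031", "minute"))
    _cv(sc, "MS:1000927", "ion injection time", scan.injection_ms,
        unit=("UO:0000028", "millisecond"))
    if scan.request.isolation_windows:
        precursors = ET.SubElement(
            spec, "precursorList", {"count": str(len(scan.request.isolation_windows))}
        )
        for center, width in scan.request.isolation_windows:
            prec = ET.SubElement(precursors, "precursor")
            iso = ET.SubElement(prec, "isolationWindow")
            _cv(iso, "MS:1000827", "isolation window target m/z", center,
                unit=("MS:1000040", "m/z"))
            _cv(iso, "MS:1000828", "isolation window lower offset", width / 2,
                unit=("MS:1000040", "m/z"))
            _cv(iso, "MS:1000829", "isolation window upper offset", width / 2,
                unit=("MS:1000040", "m/z"))
            act = ET.SubElement(prec, "activation")
            _cv(act, "MS:1000422", "beam-type collision-induced dissociation")
    arrays = ET.SubElement(spec, "binaryDataArrayList", {"count": "2"})
    _binary(arrays, scan.spectrum.mz, "MS:1000514", "m/z array",
            unit=("MS:1000040", "m/z"))
    _binary(arrays, scan.spectrum.intensity, "MS:1000515", "intensity array",
            unit=("MS:1000131", "number of detector counts"))


def write_mzml(run: RunResult, path) -> None:
    """Write every scan of the run as a centroided mzML spectrum."""
    root = ET.Element(
        "mzML",
        {
            "xmlns": "http://psi.hupo.org/ms/mzml",
            "version": "1.1.0",
            "id": run.sample_name,
        },
    )
    cv_list = ET.SubElement(root, "cvList", {"count": "2"})
    ET.SubElement(cv_list, "cv", {
        "id": "MS", "fullName": "Proteomics Standards Initiative Mass Spectrometry Ontology",
        "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    })
    ET.SubElement(cv_list, "cv", {
        "id": "UO", "fullName": "Unit Ontology",
        "URI": "https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo",
    })
    fdl = ET.SubElement(root, "fileDescription")
    fc = ET.SubElement(fdl, "fileContent")
    _cv(fc, "MS:1000579", "MS1 spectrum")
    _cv(fc, "MS:1000580", "MSn spectrum")
    softwares = ET.SubElement(root, "softwareList", {"count": "1"})
    ET.SubElement(softwares, "software", {"id": "hybridia", "version": "0.1.0"})
    icl = ET.SubElement(root, "instrumentConfigurationList", {"count": "1"})
    ET.SubElement(icl, "instrumentConfiguration", {"id": "IC1"})
    dpl = ET.SubElement(root, "dataProcessingList", {"count": "1"})
    dp = ET.SubElement(dpl, "dataProcessing", {"id": "DP1"})
    pm = ET.SubElement(dp, "processingMethod", {"order": "1", "softwareRef": "hybridia"})
    _cv(pm, "MS:1000544", "Conversion to mzML")
    mzml_run = ET.SubElement(
        root, "run", {"id": run.sample_name, "defaultInstrumentConfigurationRef": "IC1"}
    )
    spectra = ET.SubElement(
        mzml_run, "spectrumList",
        {"count": str(len(run.scans)), "defaultDataProcessingRef": "DP1"},
    )
    for i, scan in enumerate(run.scans):
        _spectrum_element(spectra, i, scan)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="utf-8")
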