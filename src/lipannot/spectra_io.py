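"""Reading and writing mass-spectral runs and annotation tables.

mzML is the canonical interchange format.  Both directions use a compact
lxml-based codec keyed on the standard PSI-MS controlled-vocabulary
accessions: the reader handles 32/64-bit float binary arrays, zlib or no
compression, and second- or minute-unit retention times; the writer emits
centroided 64-bit uncompressed spectra that round-trip exactly.  MGF (via
pyteomics) covers MS2-only workflows.  Retention times are minutes
internally; m/z in Da.
"""

from __future__ import annotations

import base64
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree
from pyteomics import mgf as _mgf


class SpectraIOError(ValueError):
    pass


@dataclass
class Scan:
    scan_id: str
    ms_level: int
    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "positive"
    precursor_mz: float | None = None
    isolation_width: float | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        order = np.argsort(self.mz, kind="stable")
        if not np.all(order == np.arange(len(order))):
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise SpectraIOError(f"negative intensity in scan {self.scan_id}")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise SpectraIOError(f"MS2 scan {self.scan_id} lacks precursor m/z")

    @property
    def n_peaks(self) -> int:
        return len(self.mz)


@dataclass
class Run:
    scans: list[Scan] = field(default_factory=list)
    polarity: str = "positive"
    source_path: str = ""

    def __post_init__(self):
        rts = [s.rt for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            self.scans = sorted(self.scans, key=lambda s: s.rt)

    def ms1_scans(self) -> list[Scan]:
        return [s for s in self.scans if s.ms_level == 1]

    def ms2_scans(self) -> list[Scan]:
        return [s for s in self.scans if s.ms_level == 2]


# ---------------------------------------------------------------------------
# mzML reading

_NS = "http://psi.hupo.org/ms/mzml"


def _accessions(element) -> dict[str, str]:
    """accession -> value for all cvParams directly under ``element``."""
    return {
        cv.get("accession"): cv.get("value", "")
        for cv in element.findall(f"{{{_NS}}}cvParam") + element.findall("cvParam")
    }


def _find(element, tag: str):
    hit = element.find(f"{{{_NS}}}{tag}")
    return hit if hit is not None else element.find(tag)


def _findall(element, tag: str):
    return element.findall(f"{{{_NS}}}{tag}") or element.findall(tag)


def _decode_binary_arrays(spectrum) -> dict[str, np.ndarray]:
    """Decode m/z and intensity arrays from a <spectrum> element."""
    out: dict[str, np.ndarray] = {}
    bal = _find(spectrum, "binaryDataArrayList")
    if bal is None:
        return out
    for bda in _findall(bal, "binaryDataArray"):
        acc = _accessions(bda)
        raw = _find(bda, "binary")
        data = base64.b64decode((raw.text or "").strip()) if raw is not None else b""
        if "MS:1000574" in acc:  # zlib compression
            data = zlib.decompress(data)
        dtype = "<f4" if "MS:1000521" in acc else "<f8"  # 32- vs 64-bit float
        values = np.frombuffer(data, dtype=dtype).astype(float)
        if "MS:1000514" in acc:
            out["mz"] = values
        elif "MS:1000515" in acc:
            out["intensity"] = values
    return out


def read_mzml(path: str | Path) -> Run:
    """Load a centroided mzML file into a :class:`Run`.

    Profile-mode spectra raise an error instructing centroiding; MS2 scans
    without a recorded precursor are skipped (a warning reports the count).
    Retention times are converted to minutes whatever the source unit.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    # tolerate the indexedmzML wrapper
    if etree.QName(root).localname == "indexedmzML":
        root = _find(root, "mzML")
    scans: list[Scan] = []
    polarity = "positive"
    skipped = 0
    for spectrum in root.iter(f"{{{_NS}}}spectrum"):
        acc = _accessions(spectrum)
        if "MS:1000128" in acc:
            raise SpectraIOError(
                f"{path}: profile-mode spectrum {spectrum.get('id')}; "
                "centroid the data before annotation"
            )
        ms_level = int(acc.get("MS:1000511", 1))
        if "MS:1000129" in acc:
            polarity = "negative"
        elif "MS:1000130" in acc:
            polarity = "positive"
        rt = 0.0
        scan_list = _find(spectrum, "scanList")
        if scan_list is not None:
            scan_el = _find(scan_list, "scan")
            if scan_el is not None:
                sacc_el = [
                    cv
                    for cv in scan_el.findall(f"{{{_NS}}}cvParam")
                    if cv.get("accession") == "MS:1000016"
                ]
                if sacc_el:
                    cv = sacc_el[0]
                    rt = float(cv.get("value"))
                    if cv.get("unitName", "minute").startswith("second"):
                        rt /= 60.0
        prec_mz = None
        iso_width = None
        if ms_level >= 2:
            plist = _find(spectrum, "precursorList")
            prec_el = _find(plist, "precursor") if plist is not None else None
            if prec_el is not None:
                iso_el = _find(prec_el, "isolationWindow")
                if iso_el is not None:
                    iacc = _accessions(iso_el)
                    lo = iacc.get("MS:1000828")
                    hi = iacc.get("MS:1000829")
                    if lo is not None and hi is not None:
                        iso_width = float(lo) + float(hi)
                silist = _find(prec_el, "selectedIonList")
                sion = _find(silist, "selectedIon") if silist is not None else None
                if sion is not None:
                    prec_mz = float(_accessions(sion).get("MS:1000744", "nan"))
            if prec_mz is None or prec_mz != prec_mz:
                skipped += 1
                continue
        arrays = _decode_binary_arrays(spectrum)
        scans.append(
            Scan(
                scan_id=str(spectrum.get("id", len(scans))),
                ms_level=ms_level,
                rt=rt,
                mz=arrays.get("mz", np.array([])),
                intensity=arrays.get("intensity", np.array([])),
                polarity=polarity,
                precursor_mz=prec_mz,
                isolation_width=iso_width,
            )
        )
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} MS2 scan(s) without precursor")
    return Run(scans=scans, polarity=polarity, source_path=str(path))


# ---------------------------------------------------------------------------
# mzML writing (minimal centroided subset)


def _cv(parent, accession: str, name: str, value: str = "", **unit) -> None:
    attrib = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    attrib.update(unit)
    etree.SubElement(parent, "cvParam", attrib)


def _binary_array(parent, values: np.ndarray, kind: str) -> None:
    data = base64.b64encode(
        struct.pack(f"<{len(values)}d", *map(float, values))
    ).decode()
    bda = etree.SubElement(parent, "binaryDataArray", encodedLength=str(len(data)))
    _cv(bda, "MS:1000523", "64-bit float")
    _cv(bda, "MS:1000576", "no compression")
    if kind == "mz":
        _cv(bda, "MS:1000514", "m/z array", unitCvRef="MS",
            unitAccession="MS:1000040", unitName="m/z")
    else:
        _cv(bda, "MS:1000515", "intensity array", unitCvRef="MS",
            unitAccession="MS:1000131", unitName="number of detector counts")
    etree.SubElement(bda, "binary").text = data


def write_mzml(run: Run, path: str | Path) -> None:
    """Serialize a :class:`Run` as centroided mzML readable by pyteomics."""
    root = etree.Element("mzML", xmlns=_NS, version="1.1.0")
    cv_list = etree.SubElement(root, "cvList", count="1")
    etree.SubElement(
        cv_list, "cv", id="MS", fullName="PSI-MS",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000127", "centroid spectrum")
    run_el = etree.SubElement(root, "run", id="run1")
    sl = etree.SubElement(run_el, "spectrumList", count=str(len(run.scans)))
    for i, scan in enumerate(run.scans):
        sp = etree.SubElement(
            sl, "spectrum", index=str(i),
            id=f"scan={scan.scan_id}", defaultArrayLength=str(scan.n_peaks),
        )
        _cv(sp, "MS:1000511", "ms level", str(scan.ms_level))
        _cv(sp, "MS:1000127", "centroid spectrum")
        if scan.polarity == "negative":
            _cv(sp, "MS:1000129", "negative scan")
        else:
            _cv(sp, "MS:1000130", "positive scan")
        scan_list = etree.SubElement(sp, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan_el = etree.SubElement(scan_list, "scan")
        _cv(scan_el, "MS:1000016", "scan start time", f"{scan.rt:.8f}",
            unitCvRef="UO", unitAccession="UO:0000031", unitName="minute")
        if scan.ms_level == 2 and scan.precursor_mz is not None:
            plist = etree.SubElement(sp, "precursorList", count="1")
            prec = etree.SubElement(plist, "precursor")
            if scan.isolation_width:
                iso = etree.SubElement(prec, "isolationWindow")
                _cv(iso, "MS:1000827", "isolation window target m/z",
                    f"{scan.precursor_mz:.6f}")
                half = scan.isolation_width / 2.0
                _cv(iso, "MS:1000828", "isolation window lower offset", f"{half:.4f}")
                _cv(iso, "MS:1000829", "isolation window upper offset", f"{half:.4f}")
            silist = etree.SubElement(prec, "selectedIonList", count="1")
            sion = etree.SubElement(silist, "selectedIon")
            _cv(sion, "MS:1000744", "selected ion m/z", f"{scan.precursor_mz:.6f}",
                unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
        bal = etree.SubElement(sp, "binaryDataArrayList", count="2")
        _binary_array(bal, scan.mz, "mz")
        _binary_array(bal, scan.intensity, "intensity")
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


# ---------------------------------------------------------------------------
# MGF (MS2-only workflows)


def read_mgf(path: str | Path) -> Run:
    scans = []
    with _mgf.MGF(str(path)) as reader:
        for i, spec in enumerate(reader):
            params = spec["params"]
            rt = params.get("rtinseconds")
            rt_min = float(rt) / 60.0 if rt is not None else 0.0
            pepmass = params.get("pepmass", (None,))
            charge = params.get("charge")
            polarity = "negative" if charge and int(charge[0]) < 0 else "positive"
            scans.append(
                Scan(
                    scan_id=str(params.get("title", i)),
                    ms_level=2,
                    rt=rt_min,
                    mz=spec["m/z array"],
                    intensity=spec["intensity array"],
                    polarity=polarity,
                    precursor_mz=float(pepmass[0]) if pepmass[0] else None,
                )
            )
    run = Run(scans=scans, source_path=str(path))
    if scans:
        run.polarity = scans[0].polarity
    return run


def write_mgf(run: Run, path: str | Path) -> None:
    entries = []
    for scan in run.ms2_scans():
        entries.append(
            {
                "m/z array": scan.mz,
                "intensity array": scan.intensity,
                "params": {
                    "title": scan.scan_id,
                    "pepmass": scan.precursor_mz,
                    "rtinseconds": scan.rt * 60.0,
                    "charge": "1-" if scan.polarity == "negative" else "1+",
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# annotation tables


def write_annotations(results, path: str | Path) -> None:
    """Full annotation table (CSV), one row per annotated feature."""
    import pandas as pd

    rows = []
    for r in results:
        constituents = ""
        if r.mixture is not None:
            constituents = ";".join(
                f"{sp.name_constituent}={pct:.1f}"
                for sp, pct in zip(r.mixture.candidates, r.mixture.percent_abundances)
            )
        rows.append(
            {
                "name": r.name,
                "structure_level": r.structure_level,
                "class": r.species_or_sum.class_abbrev,
                "adduct": r.adduct,
                "mz": r.feature.mz,
                "rt": r.feature.rt_apex,
                "abundance": r.feature.area,
                "p_mass": r.scores.p_mass,
                "p_isotope": r.scores.p_isotope,
                "p_msms": r.scores.p_msms,
                "combined_score": r.scores.combined,
                "constituents": constituents,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "name", "structure_level", "class", "adduct", "mz", "rt",
            "abundance", "p_mass", "p_isotope", "p_msms", "combined_score",
            "constituents",
        ],
    ).to_csv(path, index=False)


def write_target_list(results, path: str | Path) -> None:
    """Targeted peak list: name, m/z, rt (minutes), one row per annotation.

    Duplicated names at different retention times are kept — chromatographically
    resolved isomers that MS/MS cannot distinguish are distinct targets.
    """
    with open(path, "w") as fh:
        fh.write("name\tmz\trt\n")
        for r in results:
            fh.write(f"{r.name}\t{r.feature.mz:.5f}\t{r.feature.rt_apex:.3f}\n")
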