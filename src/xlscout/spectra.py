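"""Fragment-spectrum I/O, MS2 charge deconvolution and light/heavy
precursor pairing.

mzML and MGF are read through :mod:`pyteomics`.  A minimal mzML writer
(uncompressed base64 float64 arrays) is provided so simulated data can be
round-tripped through the standard format without binary fixtures.
"""

from __future__ import annotations

import base64
import logging
import struct
import xml.sax.saxutils
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyteomics import mgf as _mgf

from .proteome import PROTON

__all__ = [
    "Ms2Spectrum",
    "NeutralPeakList",
    "read_spectra",
    "write_mgf",
    "write_mzml",
    "neutral_mass",
    "mass_to_mz",
    "deconvolute",
    "pair_precursors",
]

logger = logging.getLogger(__name__)


@dataclass
class Ms2Spectrum:
    """A centroided MS2 scan with precursor information."""

    scan_id: str
    precursor_mz: float
    precursor_charge: int
    peaks: list  # (mz, intensity), sorted by mz
    retention_time: float | None = None  # seconds

    def __post_init__(self) -> None:
        self.peaks = sorted((float(m), float(i)) for m, i in self.peaks)
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")

    @property
    def precursor_neutral_mass(self) -> float:
        return neutral_mass(self.precursor_mz, self.precursor_charge)


@dataclass
class NeutralPeakList:
    """Deconvoluted fragment masses (neutral, Da) for one scan."""

    scan_id: str
    precursor_neutral_mass: float
    peaks: list = field(default_factory=list)  # (neutral_mass, intensity)

    def __post_init__(self) -> None:
        self.peaks = sorted((float(m), float(i)) for m, i in self.peaks)

    @property
    def masses(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])


def neutral_mass(mz: float, z: int) -> float:
    """Neutral mass from m/z at charge z: M = z*mz - z*m_proton."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return z * mz - z * PROTON

def mass_to_mz(mass: float, z: int) -> float:
    """Inverse of :func:`neutral_mass`."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (mass + z * PROTON) / z


def read_spectra(path, fmt: str | None = None) -> list[Ms2Spectrum]:
    """Read MS2 spectra from an mzML or MGF file.

    Scans without an assigned precursor charge are dropped (the count is
    logged), matching acquisition practice where unassigned charge states
    are excluded from fragmentation.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mgf" if path.suffix.lower() == ".mgf" else "mzml"
    if path.stat().st_size == 0:
        return []
    spectra: list[Ms2Spectrum] = []
    dropped = 0
    if fmt == "mgf":
        with _mgf.MGF(str(path)) as reader:
            for entry in reader:
                params = entry["params"]
                charge = params.get("charge")
                if not charge:
                    dropped += 1
                    continue
                rt = params.get("rtinseconds")
                spectra.append(Ms2Spectrum(
                    scan_id=str(params.get("title", f"scan={len(spectra)}")),
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=int(charge[0]),
                    peaks=list(zip(entry["m/z array"], entry["intensity array"])),
                    retention_time=float(rt) if rt is not None else None,
                ))
    elif fmt == "mzml":
        for entry in _iter_mzml(path):
            if entry["ms_level"] != 2:
                continue
            if entry["precursor_mz"] is None or entry["charge"] is None:
                dropped += 1
                continue
            spectra.append(Ms2Spectrum(
                scan_id=entry["id"],
                precursor_mz=entry["precursor_mz"],
                precursor_charge=entry["charge"],
                peaks=list(zip(entry["mz"], entry["intensity"])),
                retention_time=entry["rt"],
            ))
    else:
        raise ValueError(f"unknown spectrum format {fmt!r}")
    if dropped:
        logger.info("dropped %d scans without assigned precursor charge", dropped)
    return spectra


def write_mgf(spectra, path) -> None:
    entries = []
    for sp in spectra:
        params = {
            "title": sp.scan_id,
            "pepmass": sp.precursor_mz,
            "charge": f"{sp.precursor_charge}+",
        }
        if sp.retention_time is not None:
            params["rtinseconds"] = sp.retention_time
        entries.append({
            "params": params,
            "m/z array": np.array([m for m, _ in sp.peaks]),
            "intensity array": np.array([i for _, i in sp.peaks]),
        })
    _mgf.write(entries, str(path), file_mode="w")


def _decode_binary(b64_text: str, precision: int, compressed: bool) -> np.ndarray:
    raw = base64.b64decode(b64_text)
    if compressed:
        import zlib

        raw = zlib.decompress(raw)
    dtype = np.float64 if precision == 64 else np.float32
    return np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<"))


def _iter_mzml(path):
    """Stream spectra from an mzML file (stdlib XML, base64 arrays).

    Supports 32/64-bit float arrays, uncompressed or zlib-compressed.
    """
    import xml.etree.ElementTree as ET

    def local(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    stack: list[str] = []
    current = None
    array_meta = None
    for event, elem in ET.iterparse(str(path), events=("start", "end")):
        tag = local(elem.tag)
        if event == "start":
            stack.append(tag)
            if tag == "spectrum":
                current = {"id": elem.get("id", ""), "ms_level": 0,
                           "precursor_mz": None, "charge": None, "rt": None,
                           "mz": np.empty(0), "intensity": np.empty(0)}
            elif tag == "binaryDataArray":
                array_meta = {"precision": 64, "compressed": False,
                              "kind": None}
            continue
        stack.pop()
        if current is None:
            elem.clear()
            continue
        if tag == "cvParam":
            acc = elem.get("accession", "")
            value = elem.get("value", "")
            in_ion = "selectedIon" in stack
            if acc == "MS:1000511":
                current["ms_level"] = int(value)
            elif acc == "MS:1000744" and in_ion:
                current["precursor_mz"] = float(value)
            elif acc == "MS:1000041" and in_ion:
                current["charge"] = int(value)
            elif acc == "MS:1000016":
                unit = elem.get("unitName", "minute")
                current["rt"] = float(value) * (60.0 if unit == "minute" else 1.0)
            elif array_meta is not None:
                if acc == "MS:1000523":
                    array_meta["precision"] = 64
                elif acc == "MS:1000521":
                    array_meta["precision"] = 32
                elif acc == "MS:1000574":
                    array_meta["compressed"] = True
                elif acc == "MS:1000514":
                    array_meta["kind"] = "mz"
                elif acc == "MS:1000515":
                    array_meta["kind"] = "intensity"
        elif tag == "binary" and array_meta is not None:
            array_meta["data"] = _decode_binary(
                elem.text or "", array_meta["precision"],
                array_meta["compressed"])
        elif tag == "binaryDataArray":
            if array_meta.get("kind") and "data" in array_meta:
                current[array_meta["kind"]] = array_meta["data"]
            array_meta = None
        elif tag == "spectrum":
            yield current
            current = None
            elem.clear()


def _b64(values) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode("ascii")


def write_mzml(spectra, path) -> None:
    """Write MS2 spectra as minimal indexed-free mzML (64-bit, uncompressed)."""
    esc = xml.sax.saxutils.escape
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0" encoding="utf-8"?>\n')
        fh.write('<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n')
        fh.write('<cvList count="1"><cv id="MS" fullName="PSI-MS" '
                 'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/></cvList>\n')
        fh.write('<run id="run1">\n')
        fh.write(f'<spectrumList count="{len(spectra)}">\n')
        for idx, sp in enumerate(spectra):
            mzs = [m for m, _ in sp.peaks]
            ints = [i for _, i in sp.peaks]
            fh.write(f'<spectrum index="{idx}" id="{esc(sp.scan_id)}" '
                     f'defaultArrayLength="{len(mzs)}">\n')
            fh.write('<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>\n')
            fh.write('<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>\n')
            if sp.retention_time is not None:
                fh.write('<scanList count="1"><cvParam cvRef="MS" accession="MS:1000795" '
                         'name="no combination" value=""/><scan>'
                         f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
                         f'value="{sp.retention_time / 60.0:.8f}" unitCvRef="UO" '
                         'unitAccession="UO:0000031" unitName="minute"/></scan></scanList>\n')
            fh.write('<precursorList count="1"><precursor>'
                     '<selectedIonList count="1"><selectedIon>\n')
            fh.write(f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" '
                     f'value="{sp.precursor_mz:.8f}" unitCvRef="MS" unitAccession="MS:1000040" '
                     'unitName="m/z"/>\n')
            fh.write(f'<cvParam cvRef="MS" accession="MS:1000041" name="charge state" '
                     f'value="{sp.precursor_charge}"/>\n')
            fh.write('</selectedIon></selectedIonList></precursor></precursorList>\n')
            fh.write('<binaryDataArrayList count="2">\n')
            for accession, name, unit, values in (
                ("MS:1000514", "m/z array",
                 ' unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"', mzs),
                ("MS:1000515", "intensity array", "", ints),
            ):
                b64 = _b64(values)
                fh.write(f'<binaryDataArray encodedLength="{len(b64)}">\n')
                fh.write('<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n')
                fh.write('<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n')
                fh.write(f'<cvParam cvRef="MS" accession="{accession}" name="{name}" value=""{unit}/>\n')
                fh.write(f'<binary>{b64}</binary>\n</binaryDataArray>\n')
            fh.write('</binaryDataArrayList>\n</spectrum>\n')
        fh.write('</spectrumList>\n</run>\n</mzML>\n')


def deconvolute(
    spectrum: Ms2Spectrum,
    max_fragment_charge: int | None = None,
    merge_tol_da: float = 0.01,
) -> NeutralPeakList:
    """Convert fragment m/z values to neutral masses.

    Each peak is interpreted at every plausible charge 1..max (default:
    precursor charge minus one, at least 1).  Hypotheses above the
    precursor neutral mass (plus a small tolerance) are discarded;
    hypotheses agreeing within ``merge_tol_da`` are merged keeping the
    most intense representative.
    """
    if max_fragment_charge is None:
        max_fragment_charge = max(1, spectrum.precursor_charge - 1)
    cap = spectrum.precursor_neutral_mass + 1.0
    hypotheses = []
    for mz, intensity in spectrum.peaks:
        for z in range(1, max_fragment_charge + 1):
            m = neutral_mass(mz, z)
            if 0.0 <= m <= cap:
                hypotheses.append((m, intensity))
    hypotheses.sort()
    merged: list[list[float]] = []
    for m, inten in hypotheses:
        if merged and m - merged[-1][0] <= merge_tol_da:
            if inten > merged[-1][1]:
                merged[-1] = [m, inten]
        else:
            merged.append([m, inten])
    return NeutralPeakList(
        scan_id=spectrum.scan_id,
        precursor_neutral_mass=spectrum.precursor_neutral_mass,
        peaks=[(m, i) for m, i in merged],
    )


def pair_precursors(
    spectra,
    delta: float = 12.07532,
    tol_ppm: float = 10.0,
    rt_window: float | None = 120.0,
) -> list[tuple]:
    """Detect light/heavy precursor pairs differing by ``delta`` daltons.

    Returns (light, heavy) spectrum pairs whose precursor neutral masses
    differ by ``delta`` within ``tol_ppm`` (relative to the heavy mass) and,
    when both scans carry a retention time, elute within ``rt_window``
    seconds of each other.
    """
    by_mass = sorted(spectra, key=lambda s: (s.precursor_neutral_mass, s.scan_id))
    masses = [s.precursor_neutral_mass for s in by_mass]
    import bisect

    pairs = []
    for light in by_mass:
        target = light.precursor_neutral_mass + delta
        tol = target * tol_ppm * 1e-6
        i = bisect.bisect_left(masses, target - tol)
        j = bisect.bisect_right(masses, target + tol)
        for heavy in by_mass[i:j]:
            if heavy is light:
                continue
            if (rt_window is not None
                    and light.retention_time is not None
                    and heavy.retention_time is not None
                    and abs(light.retention_time - heavy.retention_time) > rt_window):
                continue
            pairs.append((light, heavy))
    return pairs
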