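"""Spectrum containers and readers/writers for standard MS formats.

Supported inputs: centroided mzML, centroided mzXML, and a two-column
whitespace-separated ``mz intensity`` peak-list dialect ('#' starts a
comment) used as the fixture format.  Output: an msalign-style block text
format for deconvoluted monoisotopic mass lists, plus the peak-list dialect.
"""

from __future__ import annotations

import base64
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple
from xml.etree import ElementTree

import numpy as np

__all__ = [
    "Peak",
    "Spectrum",
    "read_spectra",
    "read_peaklist",
    "write_peaklist",
    "read_mzml",
    "read_mzxml",
    "write_masslist",
    "read_masslist",
]


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """A centroided spectrum: parallel mz/intensity arrays sorted by m/z.

    Duplicate m/z values are merged on construction (intensities summed).
    """

    mz: np.ndarray
    intensity: np.ndarray
    identifier: str = ""
    ms_level: int = 2
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    precursor_mass: float | None = None
    activation: str | None = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if mz.shape != intensity.shape:
            raise ValueError("mz and intensity must have the same length")
        if np.any(intensity < 0):
            raise ValueError("negative intensity")
        if len(mz) and np.any(mz <= 0):
            raise ValueError("non-positive m/z")
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        if len(mz) > 1:
            uniq, inverse = np.unique(mz, return_inverse=True)
            if len(uniq) < len(mz):
                intensity = np.bincount(inverse, weights=intensity)
                mz = uniq
        self.mz = mz
        self.intensity = intensity

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(float(m), float(i)) for m, i in zip(self.mz, self.intensity)]


# ---------------------------------------------------------------------------
# peak-list dialect

def read_peaklist(path: str | Path, identifier: str | None = None) -> Spectrum:
    path = Path(path)
    mz, intensity = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'mz intensity', got {raw!r}")
        try:
            mz.append(float(fields[0]))
            intensity.append(float(fields[1]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric peak line {raw!r}") from exc
    name = identifier if identifier is not None else path.stem
    return Spectrum(np.array(mz), np.array(intensity), identifier=name)


def write_peaklist(spectrum: Spectrum, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# spectrum {spectrum.identifier}"]
    lines += [f"{m:.6f} {i:.6f}" for m, i in zip(spectrum.mz, spectrum.intensity)]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# mzML / mzXML
#
# Minimal stdlib readers for centroided spectra: no indexed access, no
# vendor extensions.  Binary arrays are base64-encoded little-endian floats
# (mzML) or network-order floats (mzXML), optionally zlib-compressed.

_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_mzml_array(element) -> np.ndarray:
    dtype, compressed = None, False
    for cv in element.iter(f"{_MZML_NS}cvParam"):
        acc = cv.get("accession")
        if acc == "MS:1000523":
            dtype = "<f8"
        elif acc == "MS:1000521":
            dtype = "<f4"
        elif acc == "MS:1000574":
            compressed = True
    binary = element.find(f"{_MZML_NS}binary")
    raw = base64.b64decode(binary.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    if dtype is None:
        dtype = "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> Iterator[Spectrum]:
    """Iterate over centroided spectra in an mzML file.

    Profile-mode spectra (cvParam MS:1000128) are skipped with a warning.
    """
    path = Path(path)
    for _, elem in ElementTree.iterparse(str(path)):
        if elem.tag != f"{_MZML_NS}spectrum":
            continue
        ident = elem.get("id", "")
        ms_level, profile = 1, False
        for cv in elem.findall(f"{_MZML_NS}cvParam"):
            acc = cv.get("accession")
            if acc == "MS:1000511":
                ms_level = int(cv.get("value", "1"))
            elif acc == "MS:1000128":
                profile = True
        if profile:
            warnings.warn(f"skipping profile-mode spectrum {ident!r} in {path}")
            elem.clear()
            continue
        arrays: dict[str, np.ndarray] = {}
        for bda in elem.iter(f"{_MZML_NS}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.iter(f"{_MZML_NS}cvParam")}
            if "MS:1000514" in accs:
                arrays["mz"] = _decode_mzml_array(bda)
            elif "MS:1000515" in accs:
                arrays["intensity"] = _decode_mzml_array(bda)
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(f"spectrum {ident!r} in {path}: missing m/z or intensity array")
        prec_mz = prec_z = None
        activation = None
        for ion in elem.iter(f"{_MZML_NS}selectedIon"):
            for cv in ion.findall(f"{_MZML_NS}cvParam"):
                if cv.get("accession") == "MS:1000744":
                    prec_mz = float(cv.get("value"))
                elif cv.get("accession") == "MS:1000041":
                    prec_z = int(cv.get("value"))
        yield Spectrum(
            arrays["mz"],
            arrays["intensity"],
            identifier=ident,
            ms_level=ms_level,
            precursor_mz=prec_mz,
            precursor_charge=prec_z,
            activation=activation,
        )
        elem.clear()


def read_mzxml(path: str | Path) -> Iterator[Spectrum]:
    """Iterate over centroided spectra in an mzXML file."""
    path = Path(path)
    ns = None
    for _, elem in ElementTree.iterparse(str(path)):
        tag = elem.tag
        if ns is None and "}" in tag:
            ns = tag.split("}", 1)[0] + "}"
        if not tag.endswith("scan"):
            continue
        ident = elem.get("num", "")
        if elem.get("centroided") == "0":
            warnings.warn(f"skipping profile-mode scan {ident!r} in {path}")
            elem.clear()
            continue
        peaks_el = elem.find(f"{ns or ''}peaks")
        if peaks_el is None:
            raise ValueError(f"scan {ident!r} in {path}: no peaks element")
        raw = base64.b64decode(peaks_el.text or "")
        if peaks_el.get("compressionType") == "zlib":
            raw = zlib.decompress(raw)
        precision = int(peaks_el.get("precision", "32"))
        dtype = ">f8" if precision == 64 else ">f4"
        data = np.frombuffer(raw, dtype=dtype).astype(float)
        pairs = data.reshape(-1, 2)
        prec_mz = prec_z = None
        prec_el = elem.find(f"{ns or ''}precursorMz")
        if prec_el is not None and prec_el.text:
            prec_mz = float(prec_el.text)
            if prec_el.get("precursorCharge"):
                prec_z = int(prec_el.get("precursorCharge"))
        yield Spectrum(
            pairs[:, 0],
            pairs[:, 1],
            identifier=ident,
            ms_level=int(elem.get("msLevel", "1")),
            precursor_mz=prec_mz,
            precursor_charge=prec_z,
            activation=elem.get("activationMethod"),
        )
        elem.clear()


def read_spectra(path: str | Path, format: str | None = None) -> list[Spectrum]:
    """Read spectra from mzML, mzXML or the peak-list dialect.

    ``format`` overrides extension-based detection; one of
    ``{"mzML", "mzXML", "peaklist"}`` (case-insensitive).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".mzml": "mzml", ".mzxml": "mzxml"}.get(suffix, "peaklist")
    fmt = format.lower()
    if fmt == "mzml":
        return list(read_mzml(path))
    if fmt == "mzxml":
        return list(read_mzxml(path))
    if fmt == "peaklist":
        return [read_peaklist(path)]
    raise ValueError(f"unknown spectrum format {format!r}")


# ---------------------------------------------------------------------------
# msalign-style deconvolution output


def write_masslist(result, path: str | Path) -> None:
    """Write a deconvolution result as an msalign-style BEGIN/END block.

    One row per reported envelope: monoisotopic mass (5 decimals), summed
    intensity, charge, raw score, local FDR — tab-separated.
    """
    path = Path(path)
    lines = ["BEGIN IONS", f"ID={result.identifier}"]
    if result.precursor_mz is not None:
        lines.append(f"PRECURSOR_MZ={result.precursor_mz:.5f}")
    if result.precursor_charge is not None:
        lines.append(f"PRECURSOR_CHARGE={result.precursor_charge}")
    if result.precursor_mass is not None:
        lines.append(f"PRECURSOR_MASS={result.precursor_mass:.5f}")
    for e in result.entries:
        fdr = "" if e.fdr is None else f"{e.fdr:.6f}"
        lines.append(f"{e.mass:.5f}\t{e.intensity:.2f}\t{e.charge}\t{e.score:.4f}\t{fdr}")
    lines.append("END IONS")
    path.write_text("\n".join(lines) + "\n")


def read_masslist(path: str | Path):
    """Parse a mass-list block written by :func:`write_masslist`."""
    from .deconv import DeconvResult, MassEntry

    header: dict[str, str] = {}
    entries: list[MassEntry] = []
    in_block = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line == "BEGIN IONS":
            in_block = True
            continue
        if line == "END IONS":
            break
        if not in_block:
            continue
        if "=" in line and "\t" not in line:
            key, value = line.split("=", 1)
            header[key] = value
            continue
        fields = line.split("\t")
        entries.append(
            MassEntry(
                mass=float(fields[0]),
                intensity=float(fields[1]),
                charge=int(fields[2]),
                score=float(fields[3]),
                fdr=float(fields[4]) if len(fields) > 4 and fields[4] else None,
            )
        )
    return DeconvResult(
        identifier=header.get("ID", ""),
        entries=entries,
        precursor_mz=float(header["PRECURSOR_MZ"]) if "PRECURSOR_MZ" in header else None,
        precursor_charge=int(header["PRECURSOR_CHARGE"]) if "PRECURSOR_CHARGE" in header else None,
        precursor_mass=float(header["PRECURSOR_MASS"]) if "PRECURSOR_MASS" in header else None,
    )
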