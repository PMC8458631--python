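"""Reading and writing spectra and annotation tables.

Centroided MS1 spectra come in as mzML (parsed with pyteomics) or as
plain two-column peak lists.  Results go out as a profiling table (CSV,
one row per matched isotope cluster and component) and a JSON report.

Both directions of mzML handling are implemented here directly against
the PSI-MS schema: the reader walks ``<spectrum>`` elements with
ElementTree (namespace-agnostic), decoding 32-/64-bit float binary
arrays with optional zlib compression; the writer emits 64-bit float
uncompressed arrays with standard controlled-vocabulary accessions.
"""

from __future__ import annotations

import base64
import csv
import json
import struct
import zlib
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence
from xml.sax.saxutils import escape

import numpy as np

__all__ = [
    "Peak",
    "Spectrum",
    "read_mzml",
    "read_peaklist",
    "write_mzml",
    "write_profile_table",
    "write_report_json",
    "format_mz",
]


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """A centroided spectrum: parallel m/z and intensity arrays.

    Peaks are kept strictly sorted ascending by m/z; exact duplicate m/z
    values are merged by summing intensity on construction.
    """

    mz: np.ndarray
    intensity: np.ndarray
    scan_id: str = "scan=1"
    ms_level: int = 1
    polarity: str = "negative"

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("mz and intensity must have the same length")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        if mz.size and np.any(mz <= 0):
            raise ValueError("m/z values must be positive")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if mz.size:
            uniq, inverse = np.unique(mz, return_inverse=True)
            if uniq.size != mz.size:
                summed = np.zeros(uniq.size)
                np.add.at(summed, inverse, inten)
                mz, inten = uniq, summed
        self.mz = mz
        self.intensity = inten

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(float(m), float(i)) for m, i in zip(self.mz, self.intensity)]

    @property
    def base_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0

    def mz_range(self) -> tuple[float, float]:
        if not len(self):
            raise ValueError("empty spectrum has no m/z range")
        return float(self.mz[0]), float(self.mz[-1])

    def replace_peaks(self, mz: np.ndarray, intensity: np.ndarray) -> "Spectrum":
        return Spectrum(
            mz=mz,
            intensity=intensity,
            scan_id=self.scan_id,
            ms_level=self.ms_level,
            polarity=self.polarity,
        )


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda: ET.Element) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind, values)."""
    kind = None
    dtype = "<d"
    compressed = False
    text = ""
    for child in bda.iter():
        name = _localname(child.tag)
        if name == "cvParam":
            accession = child.get("accession", "")
            if accession == "MS:1000514":
                kind = "mz"
            elif accession == "MS:1000515":
                kind = "intensity"
            elif accession == "MS:1000521":
                dtype = "<f"
            elif accession == "MS:1000523":
                dtype = "<d"
            elif accession == "MS:1000574":
                compressed = True
        elif name == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> list[Spectrum]:
    """Read all scans of an mzML file, one Spectrum per scan.

    Peaks are sorted ascending by m/z regardless of on-disk order;
    polarity is taken from scan metadata when present (default negative).
    Handles 32-/64-bit float arrays with or without zlib compression.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    try:
        tree = ET.parse(path)
        for elem in tree.getroot().iter():
            if _localname(elem.tag) != "spectrum":
                continue
            polarity = "negative"
            ms_level = 1
            mz = np.empty(0)
            intensity = np.empty(0)
            for child in elem.iter():
                name = _localname(child.tag)
                if name == "cvParam":
                    accession = child.get("accession", "")
                    if accession == "MS:1000511":
                        ms_level = int(child.get("value", "1"))
                    elif accession == "MS:1000130":
                        polarity = "positive"
                    elif accession == "MS:1000129":
                        polarity = "negative"
                elif name == "binaryDataArray":
                    kind, values = _decode_binary_array(child)
                    if kind == "mz":
                        mz = values
                    elif kind == "intensity":
                        intensity = values
            n = int(elem.get("defaultArrayLength", len(mz)))
            if len(mz) != len(intensity) or (n and len(mz) not in (0, n)):
                raise ValueError(
                    f"array length mismatch in scan {elem.get('id')!r}"
                )
            spectra.append(
                Spectrum(
                    mz=mz,
                    intensity=intensity,
                    scan_id=str(elem.get("id", f"scan={len(spectra) + 1}")),
                    ms_level=ms_level,
                    polarity=polarity,
                )
            )
    except ValueError:
        raise
    except Exception as exc:  # malformed XML, bad base64, truncated file ...
        raise ValueError(f"could not parse mzML file {path}: {exc}") from exc
    return spectra


def read_peaklist(path: str | Path) -> Spectrum:
    """Read a two-column (m/z, intensity) text/CSV peak list.

    Rows may be comma-, tab- or whitespace-separated; duplicate m/z rows
    are merged by intensity sum; a header row is tolerated.
    """
    path = Path(path)
    mzs: list[float] = []
    intens: list[float] = []
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").replace("\t", " ").split() if p]
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                mzs.append(float(parts[0]))
                intens.append(float(parts[1]))
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}") from None
    return Spectrum(mz=np.array(mzs), intensity=np.array(intens), scan_id=path.stem)


# ---------------------------------------------------------------------------
# mzML writing (minimal, uncompressed 64-bit floats)

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="run1">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _encode_array(values: np.ndarray) -> str:
    data = struct.pack(f"<{len(values)}d", *map(float, values))
    return base64.b64encode(data).decode("ascii")


def _binary_array_xml(values: np.ndarray, kind_accession: str, kind_name: str) -> str:
    encoded = _encode_array(values)
    return f"""          <binaryDataArray encodedLength="{len(encoded)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
            <cvParam cvRef="MS" accession="{kind_accession}" name="{kind_name}"/>
            <binary>{encoded}</binary>
          </binaryDataArray>
"""


def write_mzml(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra to a minimal centroided mzML file."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_MZML_HEADER.format(count=len(spectra)))
        for index, spec in enumerate(spectra):
            polarity_acc, polarity_name = (
                ("MS:1000129", "negative scan")
                if spec.polarity == "negative"
                else ("MS:1000130", "positive scan")
            )
            fh.write(
                f'      <spectrum index="{index}" id="{escape(spec.scan_id, {chr(34): "&quot;"})}" '
                f'defaultArrayLength="{len(spec)}">\n'
            )
            fh.write(
                f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{spec.ms_level}"/>\n'
                '        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum"/>\n'
                f'        <cvParam cvRef="MS" accession="{polarity_acc}" name="{polarity_name}"/>\n'
                '        <binaryDataArrayList count="2">\n'
            )
            fh.write(_binary_array_xml(spec.mz, "MS:1000514", "m/z array"))
            fh.write(_binary_array_xml(spec.intensity, "MS:1000515", "intensity array"))
            fh.write("        </binaryDataArrayList>\n      </spectrum>\n")
        fh.write(_MZML_FOOTER)


# ---------------------------------------------------------------------------
# result export

PROFILE_COLUMNS = ["m/z", "Charge", "Isotopic peak", "Components", "Loss"]


def format_mz(mz: float) -> str:
    """m/z printed to 4 decimals below 1000 and 3 decimals at/above 1000."""
    return f"{mz:.4f}" if mz < 1000 else f"{mz:.3f}"


def write_profile_table(rows: Iterable, path: str | Path) -> None:
    """Write the profiling table: one CSV row per matched cluster/component.

    Each row object needs attributes ``mz``, ``charge``, ``isotope_order``,
    ``composition`` and ``loss`` (or may be a 5-tuple in that order).
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(PROFILE_COLUMNS)
        for row in rows:
            if hasattr(row, "mz"):
                mz, charge, order, comp, loss = (
                    row.mz,
                    row.charge,
                    row.isotope_order,
                    row.composition,
                    row.loss,
                )
            else:
                mz, charge, order, comp, loss = row
            writer.writerow(
                [
                    format_mz(float(mz)),
                    int(charge),
                    int(order),
                    "[" + ", ".join(str(int(c)) for c in comp) + "]",
                    "[" + ", ".join(str(int(c)) for c in loss) + "]",
                ]
            )


def write_report_json(report: dict, path: str | Path) -> None:
    """Write the full-result JSON report (scores, p-values, assignments)."""

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=_default)
        fh.write("\n")
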