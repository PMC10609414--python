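"""Tandem-mass-spectrum containers and I/O (MGF, mzML).

Spectra are centroided peak lists with a precursor m/z, as produced by
data-dependent acquisition on a QTOF instrument. The acquisition-window
filter mirrors typical DDA trigger settings: precursors inside an m/z
window and fragment peaks above a detector-count threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import base64
import struct
import zlib

from lxml import etree
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

NEGATIVE = "negative"
POSITIVE = "positive"


class SpectrumParseError(ValueError):
    """Raised for malformed spectrum files (block index included in message)."""


@dataclass(frozen=True, slots=True)
class Peak:
    """One centroided fragment peak: m/z (Th) and intensity (counts, >= 0)."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(slots=True)
class Spectrum:
    """One MS/MS scan.

    Peaks are stored sorted strictly ascending by m/z; duplicate m/z values
    are merged by summing intensity (see :meth:`make`). ``retention_time``
    is minutes and is carried as metadata only.
    """

    spectrum_id: str
    precursor_mz: float
    peaks: list[Peak]
    retention_time: float | None = None
    polarity: str = NEGATIVE
    metadata: dict = field(default_factory=dict)

    @classmethod
    def make(
        cls,
        spectrum_id: str,
        precursor_mz: float,
        peaks: Iterable[tuple[float, float]] | Iterable[Peak],
        retention_time: float | None = None,
        polarity: str = NEGATIVE,
        metadata: dict | None = None,
    ) -> "Spectrum":
        """Build a spectrum, normalizing the peak list.

        Peaks are sorted ascending by m/z and exact duplicate m/z values are
        merged by summing their intensities, so the stored list is strictly
        increasing.
        """
        raw: list[Peak] = [p if isinstance(p, Peak) else Peak(*p) for p in peaks]
        merged: dict[float, float] = {}
        for p in raw:
            merged[p.mz] = merged.get(p.mz, 0.0) + p.intensity
        norm = [Peak(mz, inten) for mz, inten in sorted(merged.items())]
        return cls(
            spectrum_id=spectrum_id,
            precursor_mz=precursor_mz,
            peaks=norm,
            retention_time=retention_time,
            polarity=polarity,
            metadata=metadata or {},
        )

    @property
    def mzs(self) -> list[float]:
        return [p.mz for p in self.peaks]

    @property
    def intensities(self) -> list[float]:
        return [p.intensity for p in self.peaks]

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(slots=True)
class SpectrumCollection:
    """A list of spectra with unique ids, plus the source they came from."""

    spectra: list[Spectrum]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        ids = [s.spectrum_id for s in self.spectra]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate spectrum ids in collection: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]

    def get(self, spectrum_id: str) -> Spectrum:
        for s in self.spectra:
            if s.spectrum_id == spectrum_id:
                return s
        raise KeyError(spectrum_id)


def _polarity_from_charge(charge) -> str | None:
    try:
        # pyteomics parses CHARGE into a ChargeList of signed ints
        values = list(charge)
    except TypeError:
        values = [charge]
    for v in values:
        if int(v) < 0:
            return NEGATIVE
        if int(v) > 0:
            return POSITIVE
    return None


def read_mgf(path: str | Path, default_polarity: str = NEGATIVE) -> SpectrumCollection:
    """Read an MGF file into a :class:`SpectrumCollection`.

    One spectrum per BEGIN IONS/END IONS block. PEPMASS is required; a block
    without it raises :class:`SpectrumParseError` naming the block index.
    Polarity is taken from the sign of CHARGE when present, else
    ``default_polarity``. RTINSECONDS, when present, is converted to minutes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise SpectrumParseError(f"MGF block {i} in {path.name}: missing PEPMASS")
            precursor = float(pepmass[0])
            polarity = default_polarity
            if "charge" in params:
                polarity = _polarity_from_charge(params["charge"]) or default_polarity
            rt = None
            if "rtinseconds" in params:
                rt = float(params["rtinseconds"]) / 60.0
            sid = str(params.get("title", f"scan_{i}"))
            peaks = list(zip(entry["m/z array"], entry["intensity array"]))
            spectra.append(
                Spectrum.make(sid, precursor, peaks, retention_time=rt, polarity=polarity)
            )
    return SpectrumCollection(spectra, source=str(path))


def write_mgf(coll: SpectrumCollection, path: str | Path) -> Path:
    """Write a collection as MGF with 6-decimal m/z and intensity.

    The fixed number format makes the output byte-reproducible and supports
    the 1e-6 round-trip guarantee of :func:`read_mgf`.
    """
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for s in coll:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            if s.retention_time is not None:
                fh.write(f"RTINSECONDS={s.retention_time * 60.0:.6f}\n")
            fh.write("CHARGE=1-\n" if s.polarity == NEGATIVE else "CHARGE=1+\n")
            for p in s.peaks:
                fh.write(f"{p.mz:.6f} {p.intensity:.6f}\n")
            fh.write("END IONS\n")
    return path


# PSI-MS controlled-vocabulary accessions used by the mzML reader
_CV_MS_LEVEL = "MS:1000511"
_CV_SELECTED_ION_MZ = "MS:1000744"
_CV_NEGATIVE_SCAN = "MS:1000129"
_CV_POSITIVE_SCAN = "MS:1000130"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"
_CV_FLOAT64 = "MS:1000523"
_CV_FLOAT32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_SCAN_START_TIME = "MS:1000016"


def _localname(element) -> str:
    return etree.QName(element).localname


def _cv_accessions(element) -> dict[str, str]:
    """accession -> value for all cvParam children (any depth below element)."""
    return {
        cv.get("accession"): cv.get("value", "")
        for cv in element.iter()
        if _localname(cv) == "cvParam"
    }


def _decode_binary_array(array_element) -> list[float]:
    params = _cv_accessions(array_element)
    binary = array_element.findtext("{*}binary") or ""
    raw = base64.b64decode(binary)
    if _CV_ZLIB in params:
        raw = zlib.decompress(raw)
    fmt = "f" if _CV_FLOAT32 in params else "d"
    width = 4 if fmt == "f" else 8
    return list(struct.unpack(f"<{len(raw) // width}{fmt}", raw))


def read_mzml(path: str | Path, default_polarity: str = NEGATIVE) -> SpectrumCollection:
    """Read MS2 scans from an mzML file.

    The reader walks ``<spectrum>`` elements directly (streaming, via lxml)
    and understands the standard controlled-vocabulary terms for MS level,
    selected-ion m/z, scan polarity, scan start time, and 32/64-bit
    (optionally zlib-compressed) peak arrays. MS1 scans are skipped; a file
    without any MS2 scan yields an empty collection and a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    for _, element in etree.iterparse(str(path), tag="{*}spectrum"):
        params = _cv_accessions(element)
        if params.get(_CV_MS_LEVEL) != "2":
            element.clear()
            continue
        scan_id = element.get("id", f"scan_{len(spectra)}")
        precursor_text = None
        for ion in element.iter("{*}selectedIon"):
            precursor_text = _cv_accessions(ion).get(_CV_SELECTED_ION_MZ)
            break
        if precursor_text is None:
            raise SpectrumParseError(f"MS2 scan {scan_id} in {path.name}: no selected ion")
        polarity = default_polarity
        if _CV_NEGATIVE_SCAN in params:
            polarity = NEGATIVE
        elif _CV_POSITIVE_SCAN in params:
            polarity = POSITIVE
        rt = None
        for scan in element.iter("{*}scan"):
            for cv in scan.iter("{*}cvParam"):
                if cv.get("accession") == _CV_SCAN_START_TIME:
                    value = float(cv.get("value"))
                    rt = value / 60.0 if cv.get("unitName") == "second" else value
            break
        mz_values: list[float] | None = None
        intensity_values: list[float] | None = None
        for array in element.iter("{*}binaryDataArray"):
            array_params = _cv_accessions(array)
            if _CV_MZ_ARRAY in array_params:
                mz_values = _decode_binary_array(array)
            elif _CV_INTENSITY_ARRAY in array_params:
                intensity_values = _decode_binary_array(array)
        if mz_values is None or intensity_values is None:
            raise SpectrumParseError(f"MS2 scan {scan_id} in {path.name}: missing peak arrays")
        spectra.append(
            Spectrum.make(
                str(scan_id),
                float(precursor_text),
                list(zip(mz_values, intensity_values)),
                retention_time=rt,
                polarity=polarity,
            )
        )
        element.clear()
    if not spectra:
        logger.warning("%s contains no MS2 scans; returning empty collection", path)
    return SpectrumCollection(spectra, source=str(path))


def filter_acquisition(
    coll: SpectrumCollection,
    mz_min: float = 100.0,
    mz_max: float = 1000.0,
    min_intensity: float = 5000.0,
    inclusive: bool = True,
) -> SpectrumCollection:
    """Apply the acquisition-window filter.

    Removes spectra whose precursor lies outside ``[mz_min, mz_max]`` (both
    ends inclusive), drops fragment peaks below ``min_intensity`` (">="
    retained by default; set ``inclusive=False`` for a strict ">"), and then
    drops spectra left with fewer than two peaks -- a one-peak spectrum can
    never satisfy a matched-peak threshold downstream.

    Idempotent: applying the same filter twice equals applying it once.
    """
    if not mz_min < mz_max:
        raise ValueError("mz_min must be < mz_max")
    if min_intensity < 0:
        raise ValueError("min_intensity must be >= 0")
    keep = (lambda x: x >= min_intensity) if inclusive else (lambda x: x > min_intensity)
    out: list[Spectrum] = []
    for s in coll:
        if not (mz_min <= s.precursor_mz <= mz_max):
            continue
        peaks = [p for p in s.peaks if keep(p.intensity)]
        if len(peaks) < 2:
            continue
        out.append(replace(s, peaks=peaks))
    return SpectrumCollection(out, source=coll.source)
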