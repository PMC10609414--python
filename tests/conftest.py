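"""Shared fixtures: tiny spectra builders and a minimal mzML writer."""

from __future__ import annotations

import base64
import struct
from pathlib import Path

import numpy as np
import pytest

from metanet.spectra import Spectrum, SpectrumCollection


def make_spectrum(
    spectrum_id: str,
    precursor_mz: float,
    peaks: list[tuple[float, float]],
    **kwargs,
) -> Spectrum:
    return Spectrum.make(spectrum_id, precursor_mz, peaks, **kwargs)


@pytest.fixture
def five_peak_spectrum() -> Spectrum:
    return make_spectrum(
        "s1", 300.0, [(100.0, 10.0), (120.0, 40.0), (150.0, 90.0), (200.0, 160.0), (250.0, 250.0)]
    )


def random_spectrum(
    rng: np.random.Generator,
    spectrum_id: str,
    n_peaks: int,
    precursor_range: tuple[float, float] = (200.0, 800.0),
) -> Spectrum:
    """A random small spectrum for oracle-equivalence and property tests."""
    precursor = float(rng.uniform(*precursor_range))
    mz = np.sort(rng.uniform(100.0, precursor, n_peaks))
    intensities = rng.uniform(1.0, 1000.0, n_peaks)
    return Spectrum.make(spectrum_id, precursor, list(zip(mz.tolist(), intensities.tolist())))


def _b64_floats(values) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode()


def write_minimal_mzml(path: Path, scans: list[dict]) -> Path:
    """Write a minimal-but-valid mzML document.

    Each scan dict: ``ms_level`` (1 or 2), ``mz`` list, ``intensity`` list,
    and for MS2 a ``precursor_mz``. Arrays are 64-bit floats, uncompressed.
    """
    spectra_xml = []
    for i, scan in enumerate(scans):
        mz_b64 = _b64_floats(scan["mz"])
        int_b64 = _b64_floats(scan["intensity"])
        precursor_block = ""
        if scan["ms_level"] == 2:
            precursor_block = f"""
        <precursorList count="1">
          <precursor>
            <selectedIonList count="1">
              <selectedIon>
                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{scan['precursor_mz']}"/>
              </selectedIon>
            </selectedIonList>
          </precursor>
        </precursorList>"""
        spectra_xml.append(f"""
      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(scan['mz'])}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{scan['ms_level']}"/>
        <cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>{precursor_block}
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(int_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>""")
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="run1">
    <spectrumList count="{len(scans)}" defaultDataProcessingRef="dp1">{''.join(spectra_xml)}
    </spectrumList>
  </run>
</mzML>
"""
    path.write_text(doc)
    return path


def collection(*spectra: Spectrum) -> SpectrumCollection:
    return SpectrumCollection(list(spectra), source="synthetic")
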