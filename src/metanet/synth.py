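"""Synthetic inputs with planted structure for every pipeline stage.

Each generator is a pure function of its spec (including the seed):
identical inputs produce identical outputs, down to the byte when written
to disk.

* :func:`make_spectral_families` plants families of MS/MS spectra sharing
  fragment peaks -- half at fixed m/z (matched directly), half riding the
  member's precursor offset (matched via the precursor shift) -- plus
  uniform noise peaks kept away from planted peaks, so noise cannot
  silently create matches.
* :func:`make_spectral_library` copies selected spectra as library entries,
  which must match back at score 1.0.
* :func:`make_reference_table` writes a ligand--target TSV in the BindingDB
  dialect whose "SMILES" column carries hex-encoded fingerprints, with
  planted near-duplicates of the query metabolites carrying known target
  sets, decoy organisms, and one over-long line to exercise the dialect
  filters.
* :func:`make_disease_list` unions planted targets with decoy identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from metanet.ctnet import DiseaseGeneSet
from metanet.spectra import Spectrum, SpectrumCollection
from metanet.targets import (
    BINDINGDB_ORGANISM_COL,
    BINDINGDB_SMILES_COL,
    BINDINGDB_UNIPROT_COL,
    DEFAULT_N_BITS,
    DEFAULT_RADIUS,
    FingerprintBitSet,
)


@dataclass
class SpectralFamilySpec:
    """Parameters of the planted spectral-family generator.

    Defaults emulate a negative-mode DDA run on a plant extract: precursors
    inside the 100--1000 Th acquisition window, eight shared fragments per
    family (comfortably above library matching's six-peak floor), homologue
    members separated by a methylene-like 14 Da precursor step, a handful
    of noise peaks per spectrum just above the 5000-count trigger, and a
    0.01 Da m/z jitter well inside the 0.05 Da fragment tolerance.
    """

    n_families: int = 5
    members_per_family: int = 10
    shared_peaks: int = 8
    precursor_base: float = 300.0
    precursor_shift_step: float = 14.0
    noise_peaks: int = 5
    noise_intensity_range: tuple[float, float] = (5000.0, 30000.0)
    mz_jitter_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shared_peaks < 6:
            raise ValueError("shared_peaks must be >= 6 to support library matching")
        if self.n_families < 1 or self.members_per_family < 1:
            raise ValueError("need at least one family with one member")
        if self.mz_jitter_sd < 0 or self.noise_peaks < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class ReferencePlantSpec:
    """Parameters of the planted ligand--target reference generator."""

    n_background: int = 50
    planted: list[tuple[str, float, frozenset[str]]] = field(default_factory=list)
    n_bits: int = DEFAULT_N_BITS
    radius: int = DEFAULT_RADIUS
    n_decoy_organism_rows: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for mid, fidelity, _ in self.planted:
            if not 0.0 < fidelity <= 1.0:
                raise ValueError(f"copy_fidelity for {mid!r} must be in (0, 1]")


def _family_peak_templates(
    rng: np.random.Generator, spec: SpectralFamilySpec, family_precursor: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Template m/z, intensities, and shift mask for one family.

    Template m/z are drawn with >= 1 Th spacing below the family precursor;
    intensities are shared by all members so in-family cosine is high. Even
    template indices stay fixed across members (direct matches); odd indices
    ride the member's precursor offset (shifted matches).
    """
    max_offset = spec.precursor_shift_step * (spec.members_per_family - 1)
    lo, hi = 105.0, min(family_precursor - 10.0, 1000.0 - max_offset - 5.0)
    while True:
        mz = np.sort(rng.uniform(lo, hi, spec.shared_peaks))
        if np.all(np.diff(mz) >= 1.0):
            break
    intensities = rng.uniform(5e4, 5e5, spec.shared_peaks)
    shifted = np.arange(spec.shared_peaks) % 2 == 1
    return mz, intensities, shifted


def make_spectral_families(
    spec: SpectralFamilySpec,
) -> tuple[SpectrumCollection, dict[str, str]]:
    """Generate planted spectral families; returns (collection, truth labels).

    Within a family every member pair shares all ``shared_peaks`` fragments
    -- directly for the fixed half, at the precursor-mass difference for
    the shifted half -- so at zero jitter the modified cosine between
    members exceeds 0.6 by construction. Across families, templates are
    independent and noise peaks avoid +-0.2 Th around any planted peak, so
    expected cross-family matches are ~0.
    """
    rng = np.random.default_rng(spec.seed)
    spectra: list[Spectrum] = []
    truth: dict[str, str] = {}
    planted_mz: list[float] = []
    family_templates = []
    for f in range(spec.n_families):
        fam_precursor = spec.precursor_base + 120.0 * f
        mz, inten, shifted = _family_peak_templates(rng, spec, fam_precursor)
        family_templates.append((fam_precursor, mz, inten, shifted))
        for m in mz:
            for i in range(spec.members_per_family):
                planted_mz.append(m + spec.precursor_shift_step * i)
    planted_arr = np.array(planted_mz)
    for f, (fam_precursor, mz, inten, shifted) in enumerate(family_templates):
        family_label = f"fam{f:02d}"
        for i in range(spec.members_per_family):
            offset = spec.precursor_shift_step * i
            precursor = fam_precursor + offset
            peak_mz = np.where(shifted, mz + offset, mz)
            if spec.mz_jitter_sd > 0:
                peak_mz = peak_mz + rng.normal(0.0, spec.mz_jitter_sd, len(peak_mz))
            peaks = list(zip(peak_mz.tolist(), inten.tolist()))
            for _ in range(spec.noise_peaks):
                while True:
                    nmz = float(rng.uniform(100.0, 1000.0))
                    if np.min(np.abs(planted_arr - nmz)) > 0.2:
                        break
                nint = float(rng.uniform(*spec.noise_intensity_range))
                peaks.append((nmz, nint))
            sid = f"F{f:02d}_M{i:02d}"
            spectra.append(Spectrum.make(sid, precursor, peaks))
            truth[sid] = family_label
    return SpectrumCollection(spectra, source="synthetic"), truth


def make_spectral_library(
    coll: SpectrumCollection, n_entries: int, name_prefix: str = "LIB"
) -> SpectrumCollection:
    """Copy selected spectra as library entries (exact precursors, >= 6 peaks).

    Matching the library back against its source collection must yield
    score-1.0 hits. Source spectra with fewer than 6 peaks are skipped.
    """
    if len(coll) == 0:
        raise ValueError("cannot build a library from an empty collection")
    eligible = [s for s in coll if len(s) >= 6]
    if n_entries > len(eligible):
        raise ValueError(f"requested {n_entries} entries but only {len(eligible)} eligible spectra")
    entries: list[Spectrum] = []
    for i, src in enumerate(eligible[:n_entries]):
        lib_id = f"{name_prefix}_{i:03d}"
        entries.append(
            Spectrum.make(
                lib_id,
                src.precursor_mz,
                list(zip(src.mzs, src.intensities)),
                polarity=src.polarity,
                metadata={"compound_name": f"{name_prefix} compound {i}", "source_id": src.spectrum_id},
            )
        )
    return SpectrumCollection(entries, source="synthetic")


def _random_bitset(rng: np.random.Generator, n_bits: int, popcount: int, radius: int) -> FingerprintBitSet:
    on = rng.choice(n_bits, size=popcount, replace=False)
    return FingerprintBitSet(frozenset(int(b) for b in on), n_bits=n_bits, radius=radius)


def _degrade_bitset(
    rng: np.random.Generator, fp: FingerprintBitSet, fidelity: float
) -> FingerprintBitSet:
    """Keep a ``fidelity`` fraction of on-bits, replacing the rest randomly."""
    if fidelity >= 1.0:
        return fp
    bits = sorted(fp.bits)
    n_keep = int(round(fidelity * len(bits)))
    kept = set(rng.choice(bits, size=n_keep, replace=False).tolist()) if n_keep else set()
    n_new = len(bits) - n_keep
    free = sorted(set(range(fp.n_bits)) - set(bits))
    new = set(rng.choice(free, size=n_new, replace=False).tolist()) if n_new else set()
    return FingerprintBitSet(frozenset(int(b) for b in kept | new), n_bits=fp.n_bits, radius=fp.radius)


@dataclass
class ReferenceTableResult:
    """Output of :func:`make_reference_table`."""

    path: Path
    truth: dict[str, frozenset[str]]
    query_fingerprints: dict[str, FingerprintBitSet]
    n_overlong_lines: int
    n_decoy_organism_rows: int


def make_reference_table(
    spec: ReferencePlantSpec,
    path: str | Path,
    max_tabs: int = 283,
    popcount: int = 48,
) -> ReferenceTableResult:
    """Write a planted BindingDB-dialect reference TSV.

    The SMILES column carries hex-encoded bit vectors (read back with the
    ``hex`` fingerprint backend). Background compounds get random bit sets
    -- expected Tanimoto to any query is far below 0.6 -- and random
    single-target annotations. Each planted entry copies its query's bit
    set at the stated fidelity and carries the stated target set. Decoy
    rows with a non-human organism and one line with more than ``max_tabs``
    tabs are appended to exercise the dialect filters.
    """
    path = Path(path)
    rng = np.random.default_rng(spec.seed)
    query_fps: dict[str, FingerprintBitSet] = {}
    truth: dict[str, frozenset[str]] = {}
    rows: list[tuple[str, str, str]] = []
    for mid, fidelity, targets in spec.planted:
        qfp = _random_bitset(rng, spec.n_bits, popcount, spec.radius)
        query_fps[mid] = qfp
        truth[mid] = frozenset(targets)
        planted_fp = _degrade_bitset(rng, qfp, fidelity)
        rows.append((planted_fp.to_hex(), "Homo sapiens", ",".join(sorted(targets))))
    for i in range(spec.n_background):
        fp = _random_bitset(rng, spec.n_bits, popcount, spec.radius)
        target = f"Q{int(rng.integers(10000, 99999)):05d}"
        rows.append((fp.to_hex(), "Homo sapiens", target))
    for i in range(spec.n_decoy_organism_rows):
        fp = _random_bitset(rng, spec.n_bits, popcount, spec.radius)
        rows.append((fp.to_hex(), "Mus musculus", f"D{i:05d}"))
    with open(path, "w") as fh:
        fh.write(
            "\t".join([BINDINGDB_SMILES_COL, BINDINGDB_ORGANISM_COL, BINDINGDB_UNIPROT_COL])
            + "\n"
        )
        for smiles, organism, targets in rows:
            fh.write(f"{smiles}\t{organism}\t{targets}\n")
        # one malformed over-wide line (> max_tabs tab characters)
        fh.write("\t".join(["junk"] * (max_tabs + 2)) + "\n")
    return ReferenceTableResult(
        path=path,
        truth=truth,
        query_fingerprints=query_fps,
        n_overlong_lines=1,
        n_decoy_organism_rows=spec.n_decoy_organism_rows,
    )


def make_disease_list(
    targets: set[str] | frozenset[str], n_decoys: int, seed: int = 0, name: str = "synthetic-disease"
) -> DiseaseGeneSet:
    """Union planted targets with deterministic random decoy identifiers."""
    rng = np.random.default_rng(seed)
    decoys = {f"X{int(rng.integers(10000, 99999)):05d}" for _ in range(n_decoys)}
    return DiseaseGeneSet(name=name, ids=set(targets) | decoys, source="synthetic")
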