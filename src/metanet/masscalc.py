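"""Molecular formulas, monoisotopic masses, adduct m/z, and annotation QC.

In negative-mode electrospray the dominant species is the deprotonated
molecular ion [M-H]-, whose m/z is the neutral monoisotopic mass minus the
proton mass. Recomputing that value from the annotated molecular formula
and comparing it against the library m/z is a cheap arithmetic check on
every row of an annotation table: rows where the printed mass difference
cannot be reproduced are flagged for manual review rather than corrected.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from metanet.networking import LibraryHit

logger = logging.getLogger(__name__)

#: Monoisotopic masses (Da) of the most abundant isotope (IUPAC/CODATA).
MONOISOTOPIC: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "S": 31.97207100,
    "P": 30.97376163,
    "F": 18.99840322,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "I": 126.904473,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Mg": 23.9850417,
    "Ca": 39.96259098,
    "Fe": 55.9349375,
    "Zn": 63.9291422,
    "Se": 73.9224764,
    "Si": 27.9769265325,
    "B": 11.0093054,
}

#: Mass of a proton (Da); the [M-H]- convention subsumes the electron mass.
PROTON_MASS = 1.007276466

_SUBSCRIPT_TRANS = str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789")
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparseable formulas or unknown element symbols."""


@dataclass(frozen=True)
class MolecularFormula:
    """Element symbol -> count mapping for a neutral molecule."""

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        counts = dict(self.element_counts)
        unknown = sorted(set(counts) - set(MONOISOTOPIC))
        if unknown:
            raise FormulaError(f"unknown element symbol(s): {unknown}")
        if any(c < 0 for c in counts.values()):
            raise FormulaError("negative element count")
        if not any(c > 0 for c in counts.values()):
            raise FormulaError("empty formula")
        object.__setattr__(self, "element_counts", counts)

    def __getitem__(self, element: str) -> int:
        return self.element_counts.get(element, 0)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical
        items = dict(self.element_counts)
        parts = []
        for el in ["C", "H"] + sorted(k for k in items if k not in ("C", "H")):
            n = items.get(el, 0)
            if n > 0:
                parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string such as ``C7H12O6``.

    Underscore-delimited subscripts (``C_7_H_12_O_6_``) and Unicode
    subscript digits are tolerated. Unknown element symbols raise
    :class:`FormulaError`.
    """
    cleaned = text.strip().replace("_", "").translate(_SUBSCRIPT_TRANS)
    if not cleaned:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(cleaned):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {text!r} at {cleaned[pos:]!r}")
        if not m.group(0):
            break
        el = m.group(1)
        if el not in MONOISOTOPIC:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
        pos = m.end()
    if pos != len(cleaned):
        raise FormulaError(f"cannot parse formula {text!r} at {cleaned[pos:]!r}")
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Neutral monoisotopic mass in Da: sum of count x most-abundant-isotope mass."""
    return sum(MONOISOTOPIC[el] * n for el, n in f.element_counts.items())


_ADDUCTS = {
    "[M-H]-": -PROTON_MASS,
    "[M+H]+": +PROTON_MASS,
}


def _normalize_adduct(adduct: str) -> str:
    # tolerate unicode minus signs and superscript charge markup
    return (
        adduct.replace("−", "-")
        .replace("‒", "-")
        .replace("–", "-")
        .replace("^", "")
        .strip()
    )


def adduct_mz(f: MolecularFormula, adduct: str = "[M-H]-") -> float:
    """Theoretical m/z of the given singly charged adduct of formula ``f``.

    Supported adducts: ``[M-H]-`` (deprotonation) and ``[M+H]+``
    (protonation). The proton-mass convention subsumes the electron mass.
    """
    key = _normalize_adduct(adduct)
    if key not in _ADDUCTS:
        raise ValueError(f"unsupported adduct {adduct!r}; supported: {sorted(_ADDUCTS)}")
    return monoisotopic_mass(f) + _ADDUCTS[key]


def mass_diff(observed: float, reference: float) -> float:
    """Absolute mass difference in Da between two m/z values."""
    if observed <= 0 or reference <= 0:
        raise ValueError("m/z values must be positive")
    return abs(observed - reference)


@dataclass
class AnnotationRecord:
    """One row of an annotation table: a named library match with mass QC."""

    compound_name: str
    adduct: str
    precursor_mz: float
    library_mz: float
    mass_diff: float
    formula: MolecularFormula | None
    retention_time: float | None = None
    fragment_ions: list[float] = field(default_factory=list)
    needs_review: bool = False


ANNOTATION_COLUMNS = [
    "Compound Name",
    "Adduct",
    "Precursor m/z",
    "Library m/z",
    "Mass Diff (Da)",
    "Chemical Formula",
    "RT (min)",
    "Fragment Ions",
]


def build_annotation_table(
    hits: Sequence[LibraryHit],
    formulas: Mapping[str, MolecularFormula | str],
    library_mz: Mapping[str, float] | None = None,
    retention_times: Mapping[str, float] | None = None,
    adduct: str = "[M-H]-",
    review_threshold: float = 0.01,
) -> list[AnnotationRecord]:
    """Assemble annotation records from library hits.

    ``formulas`` maps compound name to a formula (object or string);
    ``library_mz`` maps library id to the reference precursor m/z (when
    absent it is recovered from the hit's precursor delta); and
    ``retention_times`` maps query id to RT in minutes. Records are sorted
    by retention time ascending (records without RT sort last). A record
    whose measured-vs-library difference exceeds ``review_threshold`` Da is
    flagged ``needs_review``; nothing is ever "corrected".
    """
    records: list[AnnotationRecord] = []
    for h in hits:
        raw = formulas.get(h.compound_name)
        formula: MolecularFormula | None
        if raw is None:
            logger.warning("no formula for %r; emitting record without one", h.compound_name)
            formula = None
        else:
            formula = raw if isinstance(raw, MolecularFormula) else parse_formula(raw)
        rt = (retention_times or {}).get(h.query_id)
        # reconstruct the measured precursor from the library value and delta
        if library_mz and h.library_id in library_mz:
            lib = library_mz[h.library_id]
        else:
            lib = None
        if lib is None and formula is not None:
            lib = adduct_mz(formula, adduct)
        if lib is None:
            lib = 0.0
        observed = lib + h.precursor_delta
        diff = mass_diff(observed, lib) if lib > 0 else abs(h.precursor_delta)
        records.append(
            AnnotationRecord(
                compound_name=h.compound_name,
                adduct=adduct,
                precursor_mz=observed,
                library_mz=lib,
                mass_diff=diff,
                formula=formula,
                retention_time=rt,
                needs_review=diff > review_threshold,
            )
        )
    records.sort(key=lambda r: (r.retention_time is None, r.retention_time or 0.0))
    return records


def check_annotation_consistency(
    records: Sequence[AnnotationRecord], tolerance: float = 0.005
) -> dict[str, bool]:
    """QC: does the formula's theoretical adduct m/z agree with the library m/z?

    Returns compound name -> bool; ``False`` marks internally inconsistent
    rows (|theoretical - library| > ``tolerance`` Da) which should be
    reviewed, not asserted, downstream.
    """
    out: dict[str, bool] = {}
    for r in records:
        if r.formula is None or r.library_mz <= 0:
            out[r.compound_name] = False
            continue
        theo = adduct_mz(r.formula, r.adduct)
        out[r.compound_name] = abs(theo - r.library_mz) <= tolerance
    return out


def write_annotation_table(records: Sequence[AnnotationRecord], path: str | Path) -> Path:
    """Write records as TSV with the standard annotation column set."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ANNOTATION_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.compound_name,
                    r.adduct,
                    f"{r.precursor_mz:.4f}",
                    f"{r.library_mz:.4f}",
                    f"{r.mass_diff:.6g}",
                    str(r.formula) if r.formula else "",
                    f"{r.retention_time:.2f}" if r.retention_time is not None else "",
                    ", ".join(f"{x:g}" for x in r.fragment_ions),
                ]
            )
    return path


def read_annotation_table(path: str | Path) -> list[AnnotationRecord]:
    """Read a TSV annotation table written by :func:`write_annotation_table`.

    Also accepts hand-curated tables using the same column names; empty
    formula cells yield ``formula=None``.
    """
    path = Path(path)
    records: list[AnnotationRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            formula_text = (row.get("Chemical Formula") or "").strip()
            frag_text = (row.get("Fragment Ions") or "").strip()
            rt_text = (row.get("RT (min)") or "").strip()
            records.append(
                AnnotationRecord(
                    compound_name=row["Compound Name"],
                    adduct=row.get("Adduct", "[M-H]-"),
                    precursor_mz=float(row["Precursor m/z"]),
                    library_mz=float(row["Library m/z"]),
                    mass_diff=float(row["Mass Diff (Da)"]),
                    formula=parse_formula(formula_text) if formula_text else None,
                    retention_time=float(rt_text) if rt_text else None,
                    fragment_ions=[float(x) for x in frag_text.split(",") if x.strip()],
                )
            )
    return records
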