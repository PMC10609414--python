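"""Ligand-based target prediction from fingerprint similarity.

The idea: a metabolite probably binds the targets of reference ligands that
are chemically very similar to it. Reference compounds come from a
ligand--target table in the BindingDB TSV dialect (one row per
ligand/target measurement, organism and UniProt columns), similarity is
computed on hashed circular (Morgan/ECFP-style) fingerprints with the Dice
and Tanimoto coefficients, and references at or above a similarity cutoff
contribute their UniProt target sets. Per metabolite the module reports,
independently for the Dice and Tanimoto channels: the retained matches,
mean similarity, the union of target sets, a frequency-normalized target
ranking, and the overlap between the two channels.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 2048
DEFAULT_CUTOFF = 0.6  # inclusive: similarity >= cutoff is retained
DEFAULT_MAX_TABS = 283

#: Default column names of the BindingDB all-data TSV.
BINDINGDB_SMILES_COL = "Ligand SMILES"
BINDINGDB_ORGANISM_COL = "Target Source Organism According to Curator or DataSource"
BINDINGDB_UNIPROT_COL = "UniProt (SwissProt) Primary ID of Target Chain"


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be converted to a molecule."""


@dataclass(frozen=True)
class FingerprintBitSet:
    """Fixed-length molecular fingerprint stored as the set of on-bit indices."""

    bits: frozenset[int]
    n_bits: int = DEFAULT_N_BITS
    radius: int = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.n_bits):
            raise ValueError("bit index out of range")

    @property
    def popcount(self) -> int:
        return len(self.bits)

    def to_hex(self) -> str:
        """Hex encoding of the bit vector (bit i = byte i//8, LSB first)."""
        buf = bytearray(self.n_bits // 8)
        for b in self.bits:
            buf[b // 8] |= 1 << (b % 8)
        return buf.hex()

    @classmethod
    def from_hex(cls, text: str, radius: int = DEFAULT_RADIUS) -> "FingerprintBitSet":
        buf = bytes.fromhex(text.strip())
        bits = frozenset(
            i * 8 + j for i, byte in enumerate(buf) for j in range(8) if byte >> j & 1
        )
        return cls(bits=bits, n_bits=len(buf) * 8, radius=radius)


def fingerprint(
    smiles: str, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS
) -> FingerprintBitSet:
    """Morgan (circular, ECFP-style) hashed fingerprint of a SMILES string.

    Deterministic for identical input and parameters. Raises
    :class:`InvalidSmilesError` for strings that do not parse; callers
    exclude such compounds rather than abort.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"cannot parse SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return FingerprintBitSet(frozenset(fp.GetOnBits()), n_bits=n_bits, radius=radius)


def dice(a: FingerprintBitSet, b: FingerprintBitSet) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|); 0 when both sets are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprints have different lengths")
    denom = a.popcount + b.popcount
    if denom == 0:
        return 0.0
    return 2.0 * len(a.bits & b.bits) / denom


def tanimoto(a: FingerprintBitSet, b: FingerprintBitSet) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B|; 0 when both sets are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprints have different lengths")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


@dataclass(frozen=True)
class ReferenceRecord:
    """One unique reference ligand with its consolidated UniProt target set."""

    smiles: str
    organism: str
    uniprot_ids: frozenset[str]


@dataclass
class ReferenceParseStats:
    """Row accounting from :func:`parse_reference_table`."""

    total_lines: int = 0
    overlong_dropped: int = 0
    organism_dropped: int = 0
    empty_smiles_dropped: int = 0
    rows_kept: int = 0
    unique_smiles: int = 0


def parse_reference_table(
    path: str | Path,
    organism_filter: str = "Homo sapiens",
    max_tabs: int = DEFAULT_MAX_TABS,
    smiles_col: str = BINDINGDB_SMILES_COL,
    organism_col: str = BINDINGDB_ORGANISM_COL,
    uniprot_col: str = BINDINGDB_UNIPROT_COL,
) -> tuple[list[ReferenceRecord], ReferenceParseStats]:
    """Parse a BindingDB-dialect ligand--target TSV.

    The file is read line by line so that malformed over-wide lines (more
    than ``max_tabs`` tab characters, a known quirk of the BindingDB dump)
    can be dropped and counted before field parsing. Rows whose organism
    does not match ``organism_filter`` are dropped. Surviving rows are
    grouped by unique SMILES with UniProt target sets unioned; a UniProt
    cell may hold several comma-separated accessions.
    """
    path = Path(path)
    stats = ReferenceParseStats()
    kept_lines: list[str] = []
    with open(path, newline="") as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty file")
        header = header_line.rstrip("\n").split("\t")
        for col in (smiles_col, organism_col, uniprot_col):
            if col not in header:
                raise ValueError(f"{path}: missing required column {col!r}")
        for line in fh:
            stats.total_lines += 1
            if line.count("\t") > max_tabs:
                stats.overlong_dropped += 1
                continue
            kept_lines.append(line.rstrip("\n"))
    idx_smiles = header.index(smiles_col)
    idx_org = header.index(organism_col)
    idx_uni = header.index(uniprot_col)
    grouped: dict[str, set[str]] = {}
    for line in kept_lines:
        fields = line.split("\t")
        if max(idx_smiles, idx_org, idx_uni) >= len(fields):
            fields = fields + [""] * (max(idx_smiles, idx_org, idx_uni) + 1 - len(fields))
        organism = fields[idx_org].strip()
        if organism != organism_filter:
            stats.organism_dropped += 1
            continue
        smiles = fields[idx_smiles].strip()
        if not smiles:
            stats.empty_smiles_dropped += 1
            continue
        targets = {t.strip() for t in fields[idx_uni].split(",") if t.strip()}
        grouped.setdefault(smiles, set()).update(targets)
        stats.rows_kept += 1
    stats.unique_smiles = len(grouped)
    records = [
        ReferenceRecord(smiles=s, organism=organism_filter, uniprot_ids=frozenset(t))
        for s, t in sorted(grouped.items())
    ]
    return records, stats


def fingerprint_references(
    records: Iterable[ReferenceRecord],
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    backend: str = "rdkit",
) -> tuple[list[tuple[ReferenceRecord, FingerprintBitSet]], int]:
    """Fingerprint reference records; unconvertible compounds are excluded.

    ``backend="rdkit"`` treats the SMILES field as a SMILES string;
    ``backend="hex"`` treats it as a hex-encoded pre-computed bit vector
    (used for synthetic references that bypass chemistry entirely). Returns
    the fingerprinted list and the count of excluded records.
    """
    if backend not in ("rdkit", "hex"):
        raise ValueError(f"unknown fingerprint backend {backend!r}")
    out: list[tuple[ReferenceRecord, FingerprintBitSet]] = []
    excluded = 0
    for rec in records:
        try:
            if backend == "hex":
                fp = FingerprintBitSet.from_hex(rec.smiles, radius=radius)
            else:
                fp = fingerprint(rec.smiles, radius=radius, n_bits=n_bits)
        except (InvalidSmilesError, ValueError):
            # only conversion failures are skipped; they are counted
            excluded += 1
            continue
        out.append((rec, fp))
    if excluded:
        logger.info("excluded %d reference compounds that could not be converted", excluded)
    return out, excluded


def _channel(
    sims: Sequence[tuple[ReferenceRecord, float]], cutoff: float
) -> tuple[list[tuple[ReferenceRecord, float]], float, frozenset[str], list[tuple[str, float]]]:
    """Apply the cutoff to one similarity channel and rank targets by frequency."""
    retained = [(rec, s) for rec, s in sims if s >= cutoff]
    mean = sum(s for _, s in retained) / len(retained) if retained else 0.0
    targets = frozenset().union(*(rec.uniprot_ids for rec, _ in retained)) if retained else frozenset()
    freq: dict[str, int] = {}
    for rec, _ in retained:
        for t in rec.uniprot_ids:
            freq[t] = freq.get(t, 0) + 1
    total = sum(freq.values())
    ranked = sorted(
        ((t, f / total) for t, f in freq.items()),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return retained, mean, targets, ranked


@dataclass
class SimilarityMatch:
    """Similarity of one metabolite/reference pair on both metrics."""

    metabolite_id: str
    reference_smiles: str
    dice: float
    tanimoto: float


@dataclass
class TargetPredictionResult:
    """Per-metabolite prediction: retained matches, channel means, targets, ranking.

    The Dice and Tanimoto channels are filtered independently at the same
    cutoff; ``overlap_count`` reports the size of the intersection of the
    two channel target sets. ``ranked_targets`` (per channel) carries
    within-metabolite frequency scores normalized to sum to 1; an optional
    promiscuity-corrected variant (each frequency divided by the target's
    global frequency in the whole reference table) is stored alongside when
    global frequencies are supplied.
    """

    metabolite_id: str
    matches: list[SimilarityMatch]
    mean_dice: float
    mean_tanimoto: float
    mean_dice_all: float
    mean_tanimoto_all: float
    targets_dice: frozenset[str]
    targets_tanimoto: frozenset[str]
    overlap_count: int
    ranked_targets_dice: list[tuple[str, float]]
    ranked_targets_tanimoto: list[tuple[str, float]]
    promiscuity_corrected_dice: list[tuple[str, float]] = field(default_factory=list)
    promiscuity_corrected_tanimoto: list[tuple[str, float]] = field(default_factory=list)

    @property
    def ranked_targets(self) -> list[tuple[str, float]]:
        """Primary ranking (Dice channel)."""
        return self.ranked_targets_dice

    @property
    def all_targets(self) -> frozenset[str]:
        """Union of the two channels' predicted target sets."""
        return self.targets_dice | self.targets_tanimoto


def predict_targets(
    metabolite_id: str,
    query_fp: FingerprintBitSet,
    reference: Sequence[tuple[ReferenceRecord, FingerprintBitSet]],
    cutoff: float = DEFAULT_CUTOFF,
    global_target_freq: Mapping[str, int] | None = None,
) -> TargetPredictionResult:
    """Predict protein targets of one metabolite from reference similarity.

    For each reference compound both Dice and Tanimoto similarities to the
    query fingerprint are computed. Each channel independently retains
    references with similarity >= ``cutoff`` and unions their UniProt sets;
    per-channel target frequencies (number of retained references annotated
    to the target) are normalized to sum to 1 and ranked descending with
    ties broken by accession. An empty result (no reference passes the
    cutoff) is valid.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0,1]")
    if not reference:
        raise ValueError("reference set is empty")
    dice_sims: list[tuple[ReferenceRecord, float]] = []
    tani_sims: list[tuple[ReferenceRecord, float]] = []
    matches_all: list[tuple[ReferenceRecord, float, float]] = []
    for rec, fp in reference:
        d = dice(query_fp, fp)
        t = tanimoto(query_fp, fp)
        dice_sims.append((rec, d))
        tani_sims.append((rec, t))
        matches_all.append((rec, d, t))
    d_ret, d_mean, d_targets, d_ranked = _channel(dice_sims, cutoff)
    t_ret, t_mean, t_targets, t_ranked = _channel(tani_sims, cutoff)
    retained_smiles = {rec.smiles for rec, _ in d_ret} | {rec.smiles for rec, _ in t_ret}
    matches = [
        SimilarityMatch(metabolite_id, rec.smiles, d, t)
        for rec, d, t in matches_all
        if rec.smiles in retained_smiles
    ]
    n = len(matches_all)
    result = TargetPredictionResult(
        metabolite_id=metabolite_id,
        matches=matches,
        mean_dice=d_mean,
        mean_tanimoto=t_mean,
        mean_dice_all=sum(d for _, d, _ in matches_all) / n,
        mean_tanimoto_all=sum(t for _, _, t in matches_all) / n,
        targets_dice=d_targets,
        targets_tanimoto=t_targets,
        overlap_count=len(d_targets & t_targets),
        ranked_targets_dice=d_ranked,
        ranked_targets_tanimoto=t_ranked,
    )
    if global_target_freq:
        for attr, ranked in (
            ("promiscuity_corrected_dice", d_ranked),
            ("promiscuity_corrected_tanimoto", t_ranked),
        ):
            corrected = sorted(
                ((t, s / max(global_target_freq.get(t, 1), 1)) for t, s in ranked),
                key=lambda kv: (-kv[1], kv[0]),
            )
            setattr(result, attr, corrected)
    return result


def global_target_frequencies(records: Iterable[ReferenceRecord]) -> dict[str, int]:
    """Number of reference compounds annotated to each target, table-wide."""
    freq: dict[str, int] = {}
    for rec in records:
        for t in rec.uniprot_ids:
            freq[t] = freq.get(t, 0) + 1
    return freq


PREDICTION_COLUMNS = [
    "metabolite_id",
    "mean_dice",
    "mean_tanimoto",
    "targets_dice",
    "targets_tanimoto",
    "overlap_count",
    "top_targets_dice",
    "top_targets_tanimoto",
]


def prediction_table(results: Sequence[TargetPredictionResult], top_n: int = 10) -> pd.DataFrame:
    """Tabulate predictions, one row per metabolite, input order preserved."""
    rows = []
    for r in results:
        rows.append(
            {
                "metabolite_id": r.metabolite_id,
                "mean_dice": round(r.mean_dice, 6),
                "mean_tanimoto": round(r.mean_tanimoto, 6),
                "targets_dice": ";".join(sorted(r.targets_dice)),
                "targets_tanimoto": ";".join(sorted(r.targets_tanimoto)),
                "overlap_count": r.overlap_count,
                "top_targets_dice": ";".join(
                    f"{t}:{s:.4f}" for t, s in r.ranked_targets_dice[:top_n]
                ),
                "top_targets_tanimoto": ";".join(
                    f"{t}:{s:.4f}" for t, s in r.ranked_targets_tanimoto[:top_n]
                ),
            }
        )
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


def write_prediction_table(
    results: Sequence[TargetPredictionResult], path: str | Path, top_n: int = 10
) -> Path:
    path = Path(path)
    prediction_table(results, top_n).to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path
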