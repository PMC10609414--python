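# Methods

This note documents the models and procedures implemented in `metanet`,
their assumptions, the parameters that matter, and the design choices
made where the design was genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Spectra and the acquisition filter

A spectrum is a centroided peak list (m/z, intensity) with a precursor
m/z, optional retention time (minutes, metadata only — no alignment is
performed), and polarity (default negative, matching negative-mode ESI
acquisitions of plant phenolics). On construction, peaks are sorted
ascending and exact duplicate m/z values are merged by summing
intensity, so peak lists are strictly increasing.

The acquisition filter emulates DDA trigger settings: precursors outside
[`mz_min`, `mz_max`] (default 100–1000 Th, both ends inclusive) are
removed, fragment peaks below `min_intensity` (default 5000 counts) are
dropped, and spectra left with fewer than two peaks are discarded — a
one-peak spectrum can never satisfy a matched-peak threshold downstream.
Whether a 5000-count threshold is meant strictly or inclusively is
ambiguous in common usage; the inclusive reading (≥) is the default with
a flag for strict (>). The filter applies both at the precursor-trigger
level and per peak; the two uses share one threshold but the function is
reusable with either. The filter is idempotent.

mzML reading is implemented in-package on lxml: a streaming walk over
`<spectrum>` elements using the PSI-MS controlled-vocabulary accessions
for MS level, selected-ion m/z, polarity, scan start time, and 32/64-bit
(optionally zlib-compressed) peak arrays. MGF reading goes through
pyteomics; the MGF writer formats m/z and intensity at fixed 6 decimals
so that outputs are byte-reproducible and round-trip to 1e-6.

## Modified cosine and network topology

Peak vectors are square-root intensities scaled to unit Euclidean norm;
square-root weighting damps the dominance of base peaks. Candidate peak
pairs (i, j) are those with |mzₐᵢ − mz_bⱼ| ≤ `fragment_tol` (direct) or
|mzₐᵢ − mz_bⱼ − Δ| ≤ `fragment_tol`, Δ the precursor difference
(shifted) — the "modified" part that lets structural analogues match. A
peak can serve in at most one pair, and a pair eligible both directly
and shifted is counted once.

The score is the maximum-weight one-to-one assignment of candidate
pairs (weights = products of normalized magnitudes), solved exactly with
the Hungarian algorithm (`scipy.optimize.linear_sum_assignment`) rather
than the greedy best-first heuristic common in networking servers. The
exact solution makes small-instance brute-force equivalence an exact
test (the suite checks 200+ random pairs against exhaustive enumeration
over all one-to-one pairings); the greedy variant remains available via
`method="greedy"` and can only ever score lower. By Cauchy–Schwarz on
unit-norm vectors the score lies in [0, 1]; symmetry holds because the
candidate criterion is invariant under swapping the spectra (Δ changes
sign with the order of subtraction).

Network construction applies, in order:

1. **Thresholds** — keep edges with score strictly > `score_min` (0.6)
   and matched peaks ≥ `min_matched` (4). Strict vs inclusive mirrors
   the conventional phrasing of the two rules ("higher than" vs
   "minimum of").
2. **Mutual top-k** (k = 10) — an edge survives only if each endpoint
   ranks the other among its k highest-scoring neighbours; rank lists
   order by score descending, ties by partner id ascending, so the
   filter is deterministic. Filters run in this order (thresholds first,
   rank filter on survivors); the reverse order is a plausible variant
   but is not implemented as a switch because the survivors-first
   reading is the natural composition of the two rules.
3. **Family cap** (100) — while any connected component ("molecular
   family") exceeds the cap, the lowest-scoring edge inside an oversized
   component is removed (ties lexicographic by edge endpoints) and
   components are recomputed after every single removal — the
   conservative reading of iterative pruning. Components within the cap
   are never touched; the comparison is "size ≤ cap retained".

Library matching restricts candidates to library spectra within
`precursor_tol` (0.05 Da) of the query precursor, scores with the same
modified cosine, and keeps hits with score > 0.7 and ≥ 6 matched peaks,
reporting all retained hits per query with the best flagged.

Defaults: `fragment_tol` 0.05 Da, `precursor_tol` 0.05 Da, `score_min`
0.6, `min_matched` 4, `top_k` 10, `family_max` 100, library thresholds
0.7 / 6 — the standard feature-based molecular networking settings for
QTOF data; all configurable.

## Mass annotation

Monoisotopic masses use the most abundant isotope per element
(C 12 exactly, H 1.00782503207, O 15.99491461956, N 14.0030740048,
S 31.97207100, …); the proton mass is 1.007276466 Da and the [M−H]⁻ /
[M+H]⁺ conventions subsume the electron mass in the proton term. These
constants reproduce curated annotation-table values to 3 decimals on
self-consistent rows (verified by `scripts/acceptance.py` and the test
suite). Rounding at a row's printed precision uses round-half-even.

The annotation QC recomputes the theoretical adduct m/z from each row's
formula and compares to the library m/z with a 5 mDa consistency band.
Some curated rows are internally inconsistent (formula vs m/z off by
> 1 Da — transcription artifacts) and some look truncated rather than
rounded at the printed precision; the builder computes and flags, never
corrects, and rows whose measured-vs-library difference exceeds a
configurable 0.01 Da are marked `needs_review`.

## Target prediction

Reference ligand–target data follow the BindingDB all-data TSV dialect.
The file is read line by line so that malformed over-wide lines (more
than 283 tab characters — a known quirk of that dump, kept as a
configurable dialect rule) can be dropped and counted before field
parsing; rows are then filtered to one organism (default Homo sapiens)
and grouped by unique SMILES with UniProt sets unioned. A "counts"
column, where present, is parsed but unused.

Fingerprints are Morgan circular fingerprints, radius 2, 2048 bits (the
community-standard ECFP4-equivalent), via RDKit. A second backend
accepts hex-encoded bit vectors directly, so the scoring logic is
testable with synthetic fingerprints that bypass chemistry entirely.
Unparseable SMILES raise a typed error; batch helpers exclude and count
them.

Dice and Tanimoto are computed on the bit sets; both are 0 for two
empty sets by convention. Dice ≥ Tanimoto always (algebraic identity,
property-tested). The similarity cutoff (default 0.6) is applied
inclusively (≥) and independently per metric; each channel's predicted
targets are the union of retained references' UniProt sets, channel
means are over retained pairs (over-all-pairs means are also emitted),
and the overlap count captures the joint view. Per-channel target
frequencies (number of retained references annotated to the target) are
normalized to sum to 1 and ranked descending, ties by accession. An
optional promiscuity correction divides each score by the target's
global frequency across the whole reference table, down-weighting
targets that are annotated to everything; both rankings are emitted,
labelled. The module is fully deterministic.

## Compound–target network

Each metabolite's predicted targets (union of channels) are intersected
with a disease gene list (plain text, one identifier per line, `#`
comments; identifiers are taken as-is with no namespace mapping — an
optional user-supplied mapping table can be applied upstream).
Metabolites with nonempty overlap become compound nodes, each overlapped
identifier a target node, with one edge per (compound, target). Compound
degree — distinct disease targets reached — is the ranking statistic;
ties break lexicographically. An external PPI table (3 columns: protein
A, protein B, combined score) can be imported with a strict > 0.7 score
threshold, used only as a GraphML overlay between target nodes already
in the network; no PPI retrieval, clustering or enrichment is computed
here. The pipeline run log reports both the union and the intersection
of predicted target sets across metabolites.

## Synthetic data

All generators are pure functions of (spec, seed): one
`numpy.random.default_rng(seed)` per call, no global state; identical
inputs give byte-identical output files.

**Spectral families.** Each family has `shared_peaks` (default 8)
template fragments with ≥ 1 Th spacing and member-invariant intensities
drawn from 5×10⁴–5×10⁵; members are a homologue series with precursors
at `precursor_base + 120·family + 14·member` (a methylene-like step;
families offset by 120 Th so series never collide). Even-indexed
template peaks stay at fixed m/z across members (matched directly);
odd-indexed peaks ride the member's precursor offset (matched via the
precursor shift) — so every in-family pair shares all template peaks
under the modified cosine. Noise peaks (default 5/spectrum) are uniform
over 100–1000 Th excluding ±0.2 Th around every planted peak position
(including all shifted positions), with intensities 5000–30000 counts
just above the trigger threshold; m/z jitter is N(0, 0.01 Da), well
inside the 0.05 Da tolerance. Worst-case in-family score with these
defaults stays above 0.7 (template weight ≥ 8·5×10⁴ against noise
weight ≤ 5·3×10⁴), hence the planted families sit safely above the 0.6
edge threshold; cross-family matches require ≥ 4 coincidental sub-0.05
Da alignments and are vanishingly rare. What this generator does *not*
emulate: realistic fragmentation chemistry, isotope envelopes,
chromatographic co-elution, or intensity correlation structure — so
passing recovery tests demonstrates the topology chain's correctness,
not annotation accuracy on real extracts.

**Spectral library.** Verbatim copies of eligible (≥ 6 peak) spectra
renamed as library entries; matching them back must give score-1.0 hits,
and a +0.2 Da precursor shift must break matching at the 0.05 Da
tolerance.

**Reference table.** Background compounds get random 48-bit-popcount
bit sets of 2048 bits — expected Tanimoto to an independent query ≈
48/(2·2048) ≪ 0.6 — with random single-target annotations. Planted
entries copy a query's bit set at the stated fidelity (fraction of
on-bits preserved, the rest rehashed to free positions; fidelity 1.0 is
an identical copy) and carry known target sets. Decoy rows with a
non-human organism and one over-long line exercise the dialect filters;
their counts are part of the generator's contract.

**Disease list.** Planted targets unioned with random decoy accessions.

## Pipeline

Stages run in order spectra → network → library → annotation →
prediction → compound–target network; a stage whose inputs are absent
is skipped and logged. Outputs are written atomically (temp file +
rename). The JSON manifest echoes the effective config and per-stage
counts, which must be internally monotone (edges after the rank filter ≤
edges after thresholds ≤ all pairs). All stages are deterministic, so a
rerun with identical config and inputs reproduces every stage output
bitwise; the manifest itself carries wall-clock timestamps and is the
one file excluded from that guarantee. Config is YAML (nested sections
flattened); every CLI flag overrides its config key. Exit codes: 0 ok,
1 user error, 2 internal.

## Numerical choices and scales

- Assignment scores are clipped to [0, 1] against float round-off; test
  comparisons of exact-vs-brute-force scores use 1e-10 absolute
  tolerance; rank-score sums are checked to 1e-12.
- Deterministic tie-breaks throughout: neighbour ranks by (score desc,
  id asc), edge pruning by (score, source, target), compound ranking by
  (degree desc, id asc), target ranking by (score desc, accession asc).
- Test problem sizes — 50-spectrum family recovery, 200 brute-force
  oracle pairs capped at 6 peaks (exhaustive enumeration is factorial),
  100 random capping graphs, 1000 bit-set pairs — are chosen so each
  property gets dense coverage while the whole suite stays in tens of
  seconds.

## Known limitations

- Only [M−H]⁻ and [M+H]⁺ adducts; no isotope-pattern scoring, formula
  inference from mass, or identification-confidence levels (manual
  judgements by design).
- No peak picking, feature detection, or chromatographic alignment —
  inputs are assumed centroided and deconvoluted upstream.
- Library search scores every candidate pair without indexing; fine at
  desk scale (10³–10⁴ spectra), not engineered for repository scale.
- PPI analysis, GO/pathway enrichment, and docking are out of scope:
  their file formats are imported/exported, their computations never
  performed.
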