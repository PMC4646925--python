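# Methods

## Problem and model

A compound record couples one structure (an MDL MOL block) with free-text
identifiers. The pipeline treats structure identity as equality of a
single canonical string — the Standard InChI of the molecule after FICTS
standardization — and defines ambiguity on top of that key:

- an identifier is ambiguous *within* a database iff its set of distinct
  structure keys has size ≥ 2. Two records with byte-identical keys that
  share a name are one compound, not an ambiguity; this is deliberate,
  since under a record-count definition standardization could never reduce
  ambiguity.
- an identifier shared by two databases is ambiguous *across* them iff it
  is ambiguous within either one, or both sides are singletons with
  different keys. The within-attributable share isolates the first case.
- "structures per ambiguous identifier" averages distinct keys (not
  records), consistent with the key-based definition.

Records whose standardization or InChI generation fails are excluded from
every comparison and denominators; the per-index `excluded_records` count
keeps the loss visible. Percentages are stored at full precision and
rendered to one decimal in the CSV reports.

## FICTS standardization

A code such as `uICTS` is parsed positionally: each position holds its
canonical letter of `FICTS` (rule off) or `u` (rule applied). The enabled
rules run in the fixed order F → I → C → T → S:

| rule | operation | implementation |
|------|-----------|----------------|
| F | keep one connected component | most heavy atoms; ties broken by lexicographically smallest canonical SMILES |
| I | clear all isotope labels | set every atom's isotope to unspecified |
| C | neutralize protonation charges | RDKit `Uncharger`; quaternary and other non-neutralizable centers stay |
| T | canonical tautomer | RDKit `TautomerEnumerator.Canonicalize` |
| S | erase stereochemistry | remove tetrahedral and double-bond descriptors from the graph |

The order is a design choice (no canonical order exists for the
convention): the kept fragment must be selected before its properties are
edited, and erasing stereo last cannot influence earlier rules. "Small
fragments" is read as keep-largest-component, the standard salt/solvate
stripping interpretation. Stereo removal edits the molecular graph rather
than truncating InChI layers, so there is exactly one key-generation path.
The tautomer canonicalizer is RDKit's and is not byte-compatible with
other toolkits'; everything that depends on tautomer merging is therefore
verified against this canonicalizer at data-generation time rather than
assumed.

## Systematic-name filtering

Identifier fields mix non-systematic names with SMILES/InChI strings and
IUPAC nomenclature. Classification consults an ordered, pluggable
detector list exhaustively (no short-circuit, so per-detector counts are
reproducible) and labels a name systematic as soon as any detector
recognizes it. Built-in detectors:

1. **linear_notation** — parse as InChI (by prefix) or as SMILES with the
   structure toolkit. Raw SMILES parsing would accept short all-letter
   strings ("CNS", "SCN") that are really abbreviations, so the SMILES
   branch requires length ≥ 3, no spaces, and at least one non-alphabetic
   SMILES-syntax character. Research codes like "AMP" and "AP" are never
   flagged; the corollary is that an all-letter SMILES such as "CCO" is
   also retained — the cost of not destroying legitimate codes.
2. **iupac_heuristic** — a lexical screen for nomenclature morphology:
   stereo-descriptor locant groups `(2S,5R,6R)`, von Baeyer descriptors
   `azabicyclo[3.2.0]`, locant+multiplier+substituent patterns
   `3,3-dimethyl`/`7-oxo`, indicated hydrogen `2H-`. It is not a grammar
   and makes no parse; it exists because full nomenclature parsers are
   external tools. None of its patterns fire on ordinary brand names or
   research codes (including hyphen-digit codes like "ay-6108").
3. **opsin** — an adapter to the OPSIN name-to-structure parser that
   registers itself only when `py2opsin` (and a Java runtime) is present.

Filtering runs before any ambiguity computation and is idempotent; adding
a detector can only move names from non-systematic to systematic.

## Synthetic study conditions

The generator emulates the statistical structure of public registries
without reproducing any real content:

- **records**: `n_compounds` per database (default 400), structures drawn
  from an enumerable family of small acyclic scaffolds chosen to be inert
  under every FICTS rule (no fragments, isotopes, charges, stereocenters
  or tautomerizable motifs), so plain records never interact with
  standardization.
- **identifiers per compound**: mean 3.6 (a typical large-registry value;
  observed registry means span roughly 1.3–35) with a gamma-Poisson
  dispersion of 0.3 for a skewed synonym count. Dispersion 0 gives a
  deterministic allocation whose total is exact — used whenever a test
  needs an exact unique-identifier denominator. Identifier tokens are
  research-code-like (`QZ-00137`) and built from letters that cannot begin
  a SMILES atom symbol, so they are unparsable by construction.
- **collisions**: the within-database plan (default 36 across the six
  classes, ≈ 2.3 % ambiguity — registries typically sit near 2.5 %) is
  applied to each database; the cross-database plan (default 38, stereo
  dominant) attaches one fresh identifier to an A-record and a B-record
  whose structures differ only in the class feature. A fifth of plain
  identifiers are shared with identical structures, and a few
  within-database collision identifiers are copied to the partner
  (`shared_within_ambiguous`), which produces the within-attributable
  component (default cross ambiguity ≈ 45 % of ~100 shared identifiers,
  with stereo removal recovering ≈ 15 percentage points — the magnitudes
  public registries exhibit).
- **contamination**: `contamination_rate` of identifier instances are
  valid SMILES/InChI strings, all recognizable by the baseline detector,
  so filter recovery is exact.
- **heavy tail** (off by default): identifiers attached to 101 distinct
  structures, to exercise the over-100-structures statistic.

Every collision pair must pass `verify_resolvable`: keys differ at
baseline, merge under exactly the class's own single-u code (and under
`uuuuu` unless true-structural), and stay distinct under every other
single-u code. Pairs failing any leg are regenerated. Consequently
pipeline recovery of the manifest is exact — not statistical — and the
per-rule confusion matrix is diagonal by construction. Tautomer pairs are
keto/enol motifs: the textbook mobile-H pairs (2-pyridone/2-hydroxypyridine,
amide/imidic acid) already share one Standard InChI at baseline because
InChI normalizes mobile hydrogens itself, so they cannot act as
baseline-distinguishable collisions under an InChI key; the verification
step enforces this, and a test pins it down.

What passing on synthetic data does *not* show: the scaffolds are tiny
and acyclic, identifier strings are clean ASCII tokens, every collision is
resolvable by exactly one rule, and structure multiplicity is 2 by
default. Real databases have messier names (case and whitespace variants,
Unicode), collisions that mix classes, and tautomer conventions that
differ between toolkits; results on real data are therefore
implementation-faithful but not guaranteed exact.

## Numerical and interface choices

- Identifier matching is exact-string after NFC normalization, whitespace
  strip and internal-run collapse; case folding is opt-in (`case_fold`),
  since folding would merge legitimately distinct research codes.
- Per-record duplicate identifiers collapse; cross-record duplicates are
  the signal and are kept.
- Records without a parsable, non-empty structure are dropped at ingest
  and counted (`dropped_count`); retained + dropped always equals entries
  read.
- Multi-line SDF field values split into one identifier per line (the
  dominant synonym-field convention); tabular identifier cells split on
  `|`.
- `between_ambiguity` refuses indices built under different codes, warns
  when both indices carry the same database name, and reports undefined
  percentages (`None`) for an empty shared set rather than inventing 0.
- Randomness is a single `numpy` generator seeded from `SyntheticSpec.seed`;
  the same spec yields byte-identical snapshots and manifest.

## Problem sizes

The test suite and the acceptance script run the generator at 950- and
450-record databases for the exact-recovery conditions (2000 and 1200
unique identifiers), 400 records for the default study conditions, 20-
record snapshots for the brute-force oracle comparison (20 seeds), and
14-record snapshots for the 100-spec monotonicity/decomposition sweep.
These sizes make every property exact while keeping a full run in the
low minutes on one CPU; the statistics themselves are linear in records ×
codes, so the same code paths scale to registry-sized inputs.

## Known limitations

- The linear-notation guard intentionally retains all-letter SMILES; a
  database whose synonym fields contain bare unbranched SMILES will keep
  them as (likely ambiguous) identifiers.
- The IUPAC heuristic under-reaches compared to a real nomenclature
  parser; installing `py2opsin` tightens the filter without code changes.
- Charge neutralization cannot touch permanently charged centers, and
  tautomer canonicalization follows RDKit; both are documented
  substitutes for the (unspecified) configurations of commercial
  standardizers.
- Cross-database comparison assumes both databases were keyed by this
  package; keys imported from other InChI producers may differ in corner
  cases (aromatic perception, tautomer-sensitive InChI options).
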