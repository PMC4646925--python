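# chemambig

Audit the ambiguity of **non-systematic chemical identifiers** — brand
names, generic names, research codes, registry numbers — within and
between small-molecule databases.

Compound databases attach many free-text identifiers to each structure.
Whether an identifier is *correct* can only be judged manually, but whether
it is *ambiguous* — attached to more than one distinct structure — can be
checked automatically, and ambiguous identifiers are a direct hazard for
text mining, database integration and curation. `chemambig` is a pipeline
for exactly that check, aimed at curators and cheminformaticians who need
to quantify and localize identifier collisions in their collections.

## The statistics

Structures are compared by a single key: the **Standard InChI**
(`InChI=1S/...`) of the molecule after a configurable **FICTS**
standardization. FICTS names five rules — remove small **F**ragments,
disregard **I**sotopes, disregard **C**harges, generate canonical
**T**automers, ignore **S**tereochemistry. A five-letter code selects any
combination by replacing a letter with `u` ("un-sensitive"): `FICTS`
applies nothing, `uICTS` strips salt/solvate fragments, `FICTu` erases
stereochemistry, `uuuuu` applies all five.

With `U` the set of unique non-systematic identifiers of a database and
`K(i)` the set of distinct structure keys attached to identifier `i`:

- **within-database ambiguity** = `100 × |{i ∈ U : |K(i)| ≥ 2}| / |U|`
- **between-database ambiguity** (for the shared set `S = U_A ∩ U_B`): an
  `i ∈ S` is ambiguous across if it is ambiguous within either database,
  *or* if its single structure on each side differs
  (`K_A(i) ≠ K_B(i)`). The **within-attributable** share counts only the
  first case; the remainder is cross-only ambiguity.

Before any statistic is computed, systematic identifiers (SMILES, InChI,
IUPAC-style nomenclature) are filtered out by a pluggable set of
name-to-structure detectors: a name is removed as soon as *any* detector
recognizes it. Records whose InChI cannot be generated are excluded from
all comparisons and reported.

Because real registry dumps are huge and non-redistributable, the package
ships a first-class synthetic generator: paired databases with
research-code-like identifiers, a controllable shared fraction, injected
systematic-name contaminants, and identifier collisions of six classes
(true structural, fragment/salt, isotope, charge, tautomer, stereo). Every
injected pair is verified at generation time to be resolved by *exactly*
its own FICTS rule, so the manifest is an exact oracle for every statistic
the pipeline reports.

## Worked example

```sh
chemambig simulate --seed 11 --out sim/          # synthetic pair + manifest
chemambig ingest sim/synthA.sdf sim/synthB.sdf \
    --config fieldmap.yaml --out snaps/          # SDF -> snapshots
chemambig filter --snapshots snaps/ --out filtered/
chemambig audit --snapshots filtered/ --ficts uICTS --ficts FICTu \
    --between --out reports/
```

with `fieldmap.yaml` naming the SDF fields that hold identifiers:

```yaml
identifier_fields: [SYNONYMS]
id_field: auto
```

The same audit through the Python API, on a small simulated pair:

```python
>>> from chemambig import *
>>> spec = SyntheticSpec(seed=3)                # default study conditions
>>> raw_a, raw_b, truth = generate_pair(spec)
>>> snap_a, rep = filter_snapshot(raw_a)
>>> rep.removed_systematic                      # injected SMILES/InChI contaminants
15
>>> idx = build_index(snap_a, parse_ficts("FICTS"))
>>> w = within_ambiguity(idx)
>>> round(w.ambiguity_pct, 2), w.unique_identifiers
(2.31, 1557)
```

2.31 % of the 1557 unique identifiers in the simulated database point at
more than one structure — exactly the 36 collisions the manifest injected
(`truth.expected_within_pct("synthA", "FICTS")` gives the same number).
Re-indexing under `FICTu` drops the 10 stereo collisions, and `uuuuu`
leaves only the 10 true-structural ones.

`audit` writes `within_ambiguity.csv` (unique/ambiguous counts, per-code
percentages, structures per ambiguous identifier), `between_ambiguity.csv`
(shared counts, ambiguity and its within-attributable decomposition per
pair), `standardization_effect.csv` (per-code deltas against the `FICTS`
baseline) and an `audit.json` bundle recording codes, versions and
excluded-record accounting.

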