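# uvvisdb

Tools for building and validating a comparative database of UV/vis
absorption attributes: experimentally reported absorption maxima (λmax) and
molar extinction coefficients (ε), paired with computed first-excitation
wavelengths and oscillator strengths.

The package covers:

- **`uvvisdb.records`** — the PRISTINE/FILTERED compound-record document
  tree: JSON and flat-CSV (de)serialization, MongoDB-compatible documents,
  InChIKey generation, deduplication and invariant validation. Missing
  values and explicit `"NULL"` strings both map to one null marker.
- **`uvvisdb.tableparse`** — parsing of multi-valued λmax/ε table cells
  (plain, `×10ⁿ` standard-form and `log` unit forms) and index pairing of
  wavelength and intensity lists into peak objects.
- **`uvvisdb.chemfilter`** — the five-rule opto-electronic filter:
  SMILES sanitization/canonicalization, metal/charge rejection,
  π-conjugation detection, alkyl-chain trimming to methyl, and
  electron-count (NEL) banding (small 50–140, medium 141–220, large
  221–300, extra-large 301–370; outside → rejected).
- **`uvvisdb.valstats`** — validation statistics: fixed-width histograms
  and their intersection similarity, subsample stability, ε range/percentile
  flagging, the empirical conversion ε = f·2.699×10⁴/b, MAE, OLS regression
  with a 98% mean-response confidence band, Tukey quartile summaries,
  Spearman rank correlation, and solvent normalization/tallying ordered by
  dielectric constant.
- **`uvvisdb.fixtures`** — seeded synthetic generators: record databases
  with skewed wavelength laws and corrupted-exponent ε sub-populations, a
  curated molecule suite with expected filter fates (including all NEL band
  boundaries), and blue-shifted computed overlays.
- **`uvvisdb.accession`** — deterministic queries over a loaded database
  (filtered counts, strong first excitations, wavelength windows, the
  dual-method comparison subset).

## CLI

```sh
uvvisdb fixtures --n 1000 --seed 42 --out fixtures.json
uvvisdb load --in fixtures.json --format json --out validated.json
uvvisdb export --in validated.json --format csv --out flat.csv
uvvisdb pair-tables --lambda-col lam.txt --eps-col eps.txt --eps-header "ε ×10⁴" --out pairs.json
uvvisdb filter --smiles molecules.smi --report filter.json
uvvisdb stats --in validated.json --report stats.json --bin-width 12
```

Exit status is 0 on success and 2 on schema/validation errors.

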