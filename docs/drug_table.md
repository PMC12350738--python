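# The packaged drug table: column dictionary and provenance

`src/mpolykit/data/drug_table.csv` — 45 rows, one per polycyclic drug.
Transcribed from a published table set in which rows were typeset as
concatenated digit runs; the parse was validated cell-by-cell (see
"Transcription provenance" below). Values are carried exactly as printed;
no unit conversions are applied.

## Identifier columns

| column | meaning |
|---|---|
| `name` | drug name as printed (brand or generic, verbatim) |
| `pubchem_cid` | PubChem compound identifier |
| `chemspider_id` | ChemSpider identifier |

## Index columns (computed on the hydrogen-suppressed graph)

| column | definition |
|---|---|
| `AZI` | augmented Zagreb, Σ (i·j/(i+j−2))³ |
| `M1` | first Zagreb, Σ (i+j) |
| `M2` | second Zagreb, Σ i·j |
| `mM2` | modified second Zagreb, Σ 1/(i·j) |
| `H` | harmonic, Σ 2/(i+j) |
| `ReZG3` | redefined third Zagreb, Σ i·j·(i+j) |
| `Sch` | **opaque** — no published definition; numerically equals 2·M2 in every row |
| `Gut` | **opaque** — no published definition; numerically equals 2·ReZG3 in every row |
| `SDD` | symmetric division (printed as "SDI"), Σ (i²+j²)/(i·j) |
| `I` | inverse sum indeg, Σ i·j/(i+j) |
| `F` | forgotten, Σ (i²+j²) |

Sums run over edges with endpoint degrees (i, j). `Sch` and `Gut` are
never used as defaults anywhere in the package and are excluded from
recomputation checks.

## Property columns (database-reported, as printed)

| column | meaning | unit as printed |
|---|---|---|
| `MW` | molecular weight | g/mol |
| `EM` | exact (monoisotopic) mass | Da |
| `PSA` | polar surface area | Å² |
| `C` | structural complexity score | unitless |
| `BP` | boiling point | °C/K not stated consistently; verbatim |
| `EoV` | enthalpy of vaporization | kJ/mol |
| `FP` | flash point | verbatim |
| `IoR` | index of refraction | unitless |
| `MR` | molar refractivity | cm³/mol |
| `P` | polarizability | 10⁻²⁴ cm³ |
| `ST` | surface tension | dyne/cm |
| `MV` | molar volume | cm³ |

## Transcription provenance

The source rows were concatenated digit strings without delimiters. The
parse used here was validated three independent ways:

1. **Recomputation.** For acetaminophen, metformin, ibuprofen, gabapentin
   and cephalexin the hydrogen-suppressed graphs were hand-encoded and all
   nine computable index cells recomputed; every cell matches the parsed
   value exactly (to the printed 4 decimals).
2. **Structural identities.** `Sch` = 2·`M2` and `Gut` = 2·`ReZG3` hold in
   all 45 parsed rows; these identities were used to fix token boundaries
   in otherwise ambiguous runs.
3. **External magnitudes.** Exact masses match the molecular formulas
   (e.g. cephalexin C₁₆H₁₇N₃O₄S → 347.0941) and PSA values match known
   compound records (e.g. metformin 91.5, apremilast 127), pinning the
   property-column boundaries.

Cells that required a judgment call (the parse below is the only split
consistent with 12 property columns and plausible magnitudes):

* **Benzonatate** `...12156564995.7...`: parsed PSA = 121, C = 565,
  BP = 649. The alternative split PSA = 12 / C = 1565 was rejected
  (complexity 1565 is far outside this molecule's range).
* **Ativan** `1.6948132.156211`: parsed IoR = 1.694, MR = 81, P = 32.1,
  ST = 56, MV = 211.
* **Meloxicam** `1.728634.185.3217.7`: parsed IoR = 1.72, MR = 86,
  P = 34.1, ST = 85.3, MV = 217.7.
* **Probuphine / Buprenorphine** share identical index columns and all
  property columns except BP, EoV and FP — carried as printed.

The loader checks a SHA-256 checksum of the file so silent corruption is
impossible.
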