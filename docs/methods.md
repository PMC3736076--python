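# Methods

## Scope and data model

`admetprof` profiles a compound library against the standard
early-DMPK heuristics. The unit of work is a `DescriptorVector` of ~25
named pharmacokinetic descriptors; every field is optional and carries a
provenance marker (`tag` — parsed from an SD annotation, `computed` —
derived from a structure or a formula, `surrogate` — from an estimator
shipped here). Missingness is first-class: a missing descriptor is never
coerced to zero, never counts as a rule violation, and every percentage
is reported with the denominator it was computed over.

Descriptors produced by proprietary QSAR predictors (log S_wat,
log K_HSA, log B/B, Caco-2, MDCK, log HERG, %HOA, CNS, #metab,
polarizability) are consumed from SD tags or generated synthetically;
the package deliberately does not re-derive those regressions. The SD-tag
alias table ships with the common QikProp-style export names
("QPlogPo/w", "#metab", "accptHB", ...) plus generic fallbacks and is
fully user-overridable, since export tag names vary between predictor
versions. hba/hbd are declared `real` in the schema because some
predictors export fractional hydrogen-bond counts; when tags supply
them they are used as-is for compliance scoring.

## Rules

* **Ro5 violations** (0–4): failures of MW < 500, log P < 5, HBD ≤ 5,
  HBA ≤ 10. Inequalities are honored exactly as conventionally typeset:
  MW and log P bounds are strict (a compound at exactly MW = 500
  violates), HBD/HBA bounds are non-strict.
* **Ro3**: log S_wat > −5.7, Caco-2 > 22 nm/s, #metab < 7, all strict.
  The default pass requires all three; a lenient ≥2-of-3 reading
  (`ro3_lenient_pass`) is provided because "compliance to the rule of
  three" is sometimes reported under that interpretation, and the two can
  differ by tens of percentage points on the same library.
* **Subsets**: drug-like = the Ro5 window; lead-like
  150 ≤ MW ≤ 350, log P ≤ 4, HBD ≤ 3, HBA ≤ 6; fragment-like
  MW ≤ 250, −2 ≤ log P ≤ 3, HBD < 3, HBA < 6, NRB < 3. Lead-like ⊆
  drug-like is provable from the bounds and is property-tested.
* **#stars**: the count of descriptors strictly outside their
  compliance interval. Interval membership is closed
  (`lower ≤ x ≤ upper`); one-sided entries check a single bound
  (log HERG is compliant at or above −5). The scorer also returns how
  many descriptors it actually checked (`stars_evaluated`), which is the
  denominator for compliance percentages.

### The default range table

The packaged default (`data/ranges_default.yaml`) carries the
95%-of-known-drugs intervals: S_mol 300–1000 Å², S_mol,hfob 0–750 Å²,
V_mol 500–2000 Å³, log S_wat −6.0–0.5, log K_HSA −1.5–1.2, log B/B
−3.0–1.0, Ind_coh 0.00–0.05, Glob 0.75–0.95, QP_polrz 13.0–70.0,
log HERG ≥ −5, log Kp −8.0 to −1.0, #metab 1–8, MDCK 25–500 nm/s.
Two published values conflict between sources — log K_HSA upper (1.2 vs
1.5) and log B/B upper (1.0 vs 1.2); the tighter pair is the default and
the wider pair ships as `ranges_alternate.yaml`. Caco-2 has only
qualitative published cutpoints (< 5 low, > 100 high), so its two-sided
entry (25–500 nm/s) is adopted by analogy with MDCK and is documented as
such in the config. The table is ~14 entries, fewer than the ~24 a full
commercial #stars uses; it is explicitly configurable and every report
logs the ranges in use, so absolute #stars values from this package are
comparable across its own runs but not to scores computed against a
different table.

## Formula-level descriptors

* **Globularity** `Glob = 4πr²/S_mol`, r the radius of the sphere with
  the molecular volume. Equals 1 for a sphere, ~0.806 for a cube
  (closed forms used as test oracles); bounded by 1 for convex bodies
  (isoperimetric inequality, property-tested on prolate spheroids via
  their exact surface/volume formulas).
* **Cohesion index** `Ind_coh = HBA·√HBD / SASA`. The index is defined
  as a function of exactly those three quantities with a drug range of
  0.00–0.05; this functional form was adopted because it reproduces the
  expected magnitude (at reference library means HBA = 11.69,
  HBD = 3.47, SASA = 748 Å² it gives 0.029 against a reported mean of
  0.028) and respects the range. It is a package design choice, kept
  behind its own function so an alternative form can be swapped in.
* **Transdermal flux** `Jm = 10^logKp · 10^logS · MW · 1000` in
  µg cm⁻² h⁻¹: permeability Kp in cm/h times the saturated aqueous
  concentration in µg/cm³. With typical inputs this yields the expected
  0 to ~10⁵ span.
* **Similarity blend**: below similarity 0.9 the model prediction passes
  through unchanged; from 0.9 to 1 the prediction is pulled linearly to
  the experimental value of the nearest training analogue. The linear
  form is the unique interpolation satisfying the two anchor conditions
  (s < 0.9 → model value; s = 1 → experimental value) while remaining
  continuous.
* **Potts–Guy log Kp surrogate**: `0.71·logP − 0.0061·MW − 6.3` (cm/s),
  shifted by log10(3600) to cm/h. Clearly labelled `surrogate` in
  provenance and never overwrites a tag-derived value.

Structural descriptors use RDKit: exact formula weight, Lipinski N+O /
NH+OH counts, strict rotatable bonds (excludes amide C–N and terminal
bonds), Crippen atom-additive log P (flagged surrogate-quality: additive
schemes trained on synthetic drugs can misestimate natural-product
functional-group combinations by several log units), and FreeSASA
surface/volume at 1.4 Å probe when 3D coordinates are present. The
hydrophobic surface is the per-atom SASA summed over carbons, halogens
and their attached hydrogens. Salts are reduced to the largest fragment
with a diagnostic.

## I/O

SDF records are split on `$$$$` and the connection table handed to
RDKit; tag extraction is done by the package so that a record whose
connection table fails to parse is *retained* (structure missing,
flagged) with its tags intact — descriptor tags are often usable even
when the structure block is not, and library sizes must not silently
shrink. Input text is UTF-8 with Latin-1 fallback; tag values are
trimmed of surrounding whitespace only. Duplicate or missing titles get
deterministic unique ids. MOL2 files are split on `@<TRIPOS>MOLECULE`;
SMILES files are one molecule per line with an optional id.

## Synthetic library generator

The generator emulates the marginal descriptor distributions of a
natural-product screening library of ~2,400 microbial secondary
metabolites, which is the regime the pipeline is designed for:

| channel | family | rationale |
|---|---|---|
| MW | lognormal(µ=6.1127, σ=0.5048) | 100-Da histogram mode in 301–400 Da and P(MW > 500) = 0.42, solved exactly from those two constraints |
| log P | 0.98·N(2.5, 1.8) + 0.02·(5 + Exp(4)) | Gaussian peak at 2.5 with rare extreme outliers (> 19 possible) |
| HBA, HBD | shifted negative binomials, modes strictly 5 and 2 | count peaks at 5 acceptors / 2 donors |
| NRB | geometric(p=0.25) capped at 72 | mode 1–2, long flexibility tail |
| S_mol | 120 + 1.25·MW + N(0, 60) | surface tracks size; library means ~(485 Da, 748 Å²) |
| V_mol | 1.9·S_mol + N(0, 80); Glob from the exact formula, capped at the sphere bound | surface/volume/globularity mutually consistent |
| Ind_coh | computed as HBA·√HBD/S_mol | consistent with the adopted formula |
| Jm | computed from log Kp, log S_wat, MW | consistent with the flux formula |
| others | normal (log-normal for permeabilities) around typical library means | only marginals are being emulated |

Couplings are minimal — a Gaussian-copula rank correlation (ρ = 0.5) of
HBA and NRB with MW — because only marginal shapes are specified.
Everything is a pure function of (spec, seed): same inputs, byte-identical
SDF. `plant_fraction` displaces an exact count `round(f·n)` of records
strictly outside a descriptor's range (everything else strictly inside),
so downstream percentage assertions are sharp, not statistical. The
generated tags omit #stars — it is a derived score, always recomputed by
the rule layer.

What the generator does **not** emulate: real covariance structure
between predicted descriptors, predictor error modes, structures
consistent with the tags, or natural-product scaffolds (the toy
structure generator assembles alkyl/phenyl/amide/carboxyl fragments for
I/O and structural-descriptor tests only). Tests passing on synthetic
libraries therefore validate the bookkeeping, rule logic and
aggregation exactly, but say nothing about the accuracy of any upstream
descriptor predictor on real compounds.

## Aggregation and reporting

Histograms use half-open equal-width bins labelled by lower limit (the
"0" bin is [0, 1)), with values beyond a truncation cap pooled into the
top bin (MW capped at 1000 Da, log P at 10, HBA/NRB at 40, HBD at 10 by
default). Summary rows report arithmetic means of present values for 19
descriptors, for the total library and each standard subset over its
members only. Percentages print to one decimal, half-up. Default
denominator policies: Ro5/Ro3 percentages over all records, #stars
percentages over descriptor-evaluable records; both the count and the
denominator are always shown, and the policy is switchable per report.

## Numerical and edge-case choices

* Empty library on read → explicit error; empty profile → explicit
  marker, never a row of zeros. Zero denominators → `undefined`, never
  0%.
* Range-table validation rejects inverted bounds and unknown descriptor
  names by name.
* Tag parsing is total: a garbled value is a recorded per-field
  diagnostic plus a missing field, never an exception or a zero.
* Planted values keep a ≥5%-of-span margin from interval edges, so
  6-decimal tag formatting cannot flip inside/outside.
* Problem sizes in the test suite and acceptance script (10,000 vectors
  for oracle equivalence, 2,000 for planting, 100,000 for the subset
  implication, 2,444 for end-to-end profiles, 20,000–50,000 for
  generator marginals) were chosen as the smallest sizes at which the
  checks are sharp; all complete in seconds.

## Known limitations

* #stars absolute values depend on the configured range table (see
  above); only ~14 ranges ship by default.
* The Crippen log P and Potts–Guy log Kp surrogates are order-of-
  magnitude tools, flagged as such in provenance.
* Ro5/subset rules require their descriptors; compounds missing MW,
  log P, HBA or HBD are excluded from those denominators rather than
  imputed.
* No inter-library statistical testing is provided; the output is
  descriptive.
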