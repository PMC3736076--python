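# admetprof

Drug-likeness and ADMET-compliance profiling of compound libraries.

`admetprof` is for medicinal and natural-product chemists who want to
triage a screening library — typically a few thousand structures exported
as SDF with predicted pharmacokinetic descriptors in the SD tags — before
committing to virtual screening or hit-to-lead work. It answers the
standard early-DMPK questions: how many compounds obey Lipinski's Rule of
Five, how many are orally available by Jorgensen's Rule of Three, how
many fall entirely inside the descriptor ranges spanned by 95% of known
drugs, and how the library's property distributions compare with
drug-like, lead-like and fragment-like reference windows.

## The model

Per compound, from a descriptor vector (MW, log *P*, HBA, HBD, NRB,
SASA-based surfaces and volume, predicted solubility/permeability/
binding/toxicity descriptors):

* **Ro5 violations** — number of failures among MW < 500 Da,
  log *P* < 5, HBD ≤ 5, HBA ≤ 10.
* **Ro3 flags** — log *S*<sub>wat</sub> > −5.7, Caco-2 > 22 nm s⁻¹,
  \#metab < 7 (all three required to pass by default).
* **Subsets** — drug-like (the Ro5 window), lead-like
  (150 ≤ MW ≤ 350, log *P* ≤ 4, HBD ≤ 3, HBA ≤ 6), fragment-like
  (MW ≤ 250, −2 ≤ log *P* ≤ 3, HBD < 3, HBA < 6, NRB < 3). Lead-like is
  provably nested in drug-like.
* **\#stars** — the count of descriptors strictly outside their
  95%-of-known-drugs interval (e.g. *S*<sub>mol</sub> 300–1000 Å²,
  log B/B −3.0 to 1.0, log HERG > −5); 0 stars = fully compliant. Missing
  descriptors are skipped and the number actually checked is reported —
  they never count as violations.

Formula-level descriptors are computed directly: globularity
Glob = 4π*r*²/*S*<sub>mol</sub> with *r* the volume-equivalent sphere
radius; cohesion index Ind<sub>coh</sub> = HBA·√HBD/SASA; maximum
transdermal flux *J*<sub>m</sub> = *K*<sub>p</sub> · *C*<sub>sat</sub>
in µg cm⁻² h⁻¹; a Potts–Guy surrogate for log *K*<sub>p</sub>; and the
similarity-adjusted prediction
*P*<sub>pred</sub> = *P*<sub>QP</sub> + ((*S* − 0.9)/0.1)(*P*<sub>exp</sub> − *P*<sub>QP</sub>)
for *S* ≥ 0.9. Open structural descriptors (MW, Lipinski HBA/HBD, strict
rotatable bonds, Crippen log *P*, SASA/volume at 1.4 Å probe) are
computed with RDKit when 3D structures are supplied.

A seeded synthetic-library generator emulates the property marginals of
a natural-product library (MW lognormal peaking in 301–400 Da with ~42%
above 500 Da; log *P* centred at 2.5 with rare extreme outliers; HBA/HBD
peaking at 5 and 2; NRB peaking at 1–2 with a tail to 72), so the whole
pipeline is testable without downloads, and can plant exact out-of-range
fractions for sharp percentage tests.

## Worked example

```sh
admetprof synth --n 2444 --seed 1 --out demo
admetprof profile demo/library.sdf --out demo_report
```

prints

```
admetprof 0.1.0 — library profile
input: demo/library.sdf (sdf), 2444 records, 0 structure-parse failures (kept)
descriptor-evaluable: 2444/2444

ro5_zero: 34.5% (843/2444, all)
ro5_le2: 86.4% (2112/2444, all)
ro3_pass: 51.8% (1267/2444, all)
stars0: 7.4% (180/2444, evaluable)
stars_le2: 54.1% (1322/2444, evaluable)
cns_active: 2.2% (53/2444, evaluable)

drug-like: 843 compounds
lead-like: 281 compounds
fragment-like: 66 compounds
```

Reading: 34.5% of the 2,444 synthetic compounds have zero Lipinski
violations and 86.4% have at most two; 7.4% are fully \#stars-compliant
(every checked descriptor inside its 95%-of-drugs range). Every
percentage is printed with its numerator and denominator, and the
denominator policy (`all` records vs records `evaluable` for that rule)
is explicit, because the two policies give different headline numbers
whenever some compounds lack descriptors. The report directory also
contains per-compound outcomes (`outcomes.csv`), the library/subset
summary table (`profile.csv`, `profile.json`), binned distributions
(`distributions.csv`) and the resolved run configuration.

The same operations are available as a library:

```python
from admetprof import (GeneratorSpec, generate_tagged_library,
                       profile_library, fraction_satisfying)
records = generate_tagged_library(GeneratorSpec(n=2444, seed=1))
dvs, outcomes, profile = profile_library(records)
print(fraction_satisfying(dvs, outcomes, "stars0", "evaluable"))
# stars0: 7.4% (180/2444, evaluable)
```

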