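"""Per-compound classification rules.

Implements the drug-likeness and ADMET-compliance layer:

* Lipinski Rule-of-Five violation counting (MW < 500, log P < 5,
  HBD <= 5, HBA <= 10);
* Jorgensen Rule-of-Three oral-availability flags (log S_wat > -5.7,
  Caco-2 > 22 nm/s, fewer than 7 primary metabolic reactions);
* drug-like / lead-like / fragment-like subset membership;
* the #stars compliance score — the number of descriptors falling
  outside the ranges spanned by 95% of known drugs;
* qualitative Caco-2 / MDCK permeability bands.

Missing descriptors never count as violations: each rule reports
not-evaluable (``None``) instead, and #stars tracks how many descriptors
it actually checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Optional

import yaml

from .descriptors import DESCRIPTOR_FIELDS, DescriptorVector

__all__ = [
    "RangeEntry",
    "RangeTable",
    "RangeTableError",
    "RuleOutcome",
    "default_range_table",
    "alternate_range_table",
    "load_range_table",
    "ro5_violations",
    "ro3_check",
    "classify_subsets",
    "count_stars",
    "qualitative_bands",
    "evaluate",
]


class RangeTableError(ValueError):
    """A range-table configuration failed validation."""


@dataclass(frozen=True)
class RangeEntry:
    """One compliance interval: ``[lower, upper]`` with either bound
    optional (one-sided ranges check a single bound)."""

    descriptor: str
    lower: Optional[float]
    upper: Optional[float]

    @property
    def sidedness(self) -> str:
        if self.lower is not None and self.upper is not None:
            return "two-sided"
        return "one-sided-above" if self.lower is not None else "one-sided-below"

    def contains(self, value: float) -> bool:
        """Closed-interval membership; out-of-range is strict."""
        if self.lower is not None and value < self.lower:
            return False
        if self.upper is not None and value > self.upper:
            return False
        return True


@dataclass
class RangeTable:
    """Per-descriptor compliance intervals ("range for 95% of drugs")."""

    entries: dict = field(default_factory=dict)  # descriptor -> RangeEntry

    def __post_init__(self):
        for name, entry in self.entries.items():
            _validate_entry(name, entry)

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self):
        return len(self.entries)

    def __contains__(self, descriptor: str) -> bool:
        return descriptor in self.entries

    def __getitem__(self, descriptor: str) -> RangeEntry:
        return self.entries[descriptor]

    def as_dict(self) -> dict:
        return {
            e.descriptor: {"lower": e.lower, "upper": e.upper, "sidedness": e.sidedness}
            for e in self
        }


def _validate_entry(name: str, entry: RangeEntry) -> None:
    if name != entry.descriptor:
        raise RangeTableError(f"entry key {name!r} does not match descriptor {entry.descriptor!r}")
    if name not in DESCRIPTOR_FIELDS:
        raise RangeTableError(f"unknown descriptor name {name!r}")
    if entry.lower is None and entry.upper is None:
        raise RangeTableError(f"{name}: at least one bound is required")
    if entry.lower is not None and entry.upper is not None and entry.lower >= entry.upper:
        raise RangeTableError(
            f"{name}: lower bound {entry.lower} must be below upper bound {entry.upper}")


def _table_from_mapping(mapping: dict) -> RangeTable:
    entries = {}
    for name, bounds in mapping.items():
        if not isinstance(bounds, dict):
            raise RangeTableError(f"{name}: bounds must be a mapping with lower/upper")
        unknown = set(bounds) - {"lower", "upper"}
        if unknown:
            raise RangeTableError(f"{name}: unknown keys {sorted(unknown)}")
        lower = bounds.get("lower")
        upper = bounds.get("upper")
        entries[name] = RangeEntry(
            name,
            None if lower is None else float(lower),
            None if upper is None else float(upper),
        )
    return RangeTable(entries)


def load_range_table(path) -> RangeTable:
    """Load and validate a range table from a YAML/JSON key-value file.

    Expected layout::

        ranges:
          s_mol: {lower: 300, upper: 1000}
          log_herg: {lower: -5}        # one-sided

    Raises :class:`RangeTableError` on inverted bounds or unknown
    descriptor names.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "ranges" not in doc:
        raise RangeTableError("range config must contain a top-level 'ranges' mapping")
    return _table_from_mapping(doc["ranges"])


@lru_cache(maxsize=4)
def _packaged_mapping(name: str):
    text = resources.files("admetprof.data").joinpath(name).read_text(encoding="utf-8")
    return yaml.safe_load(text)["ranges"]


def _packaged_table(name: str) -> RangeTable:
    return _table_from_mapping(_packaged_mapping(name))


def default_range_table() -> RangeTable:
    """The packaged default compliance ranges (95%-of-known-drugs)."""
    return _packaged_table("ranges_default.yaml")


def alternate_range_table() -> RangeTable:
    """Alternate ranges using the wider log K_HSA (to 1.5) and
    log B/B (to 1.2) bounds quoted in per-property discussions."""
    return _packaged_table("ranges_alternate.yaml")


@dataclass
class RuleOutcome:
    """All rule results for one compound.

    ``None`` anywhere means the rule was not evaluable because a required
    descriptor was missing; such compounds are excluded from the
    denominators of the corresponding library statistics.
    """

    ro5_violations: Optional[int] = None
    ro5_pass: Optional[bool] = None
    ro3_flags: tuple = (None, None, None)  # (solubility, caco2, metabolites)
    ro3_pass: Optional[bool] = None
    is_drug_like: Optional[bool] = None
    is_lead_like: Optional[bool] = None
    is_fragment_like: Optional[bool] = None
    stars: int = 0
    stars_evaluated: int = 0
    caco2_band: Optional[str] = None
    mdck_band: Optional[str] = None

    def as_dict(self) -> dict:
        d = {
            "ro5_violations": self.ro5_violations,
            "ro5_pass": self.ro5_pass,
            "ro3_solubility": self.ro3_flags[0],
            "ro3_caco2": self.ro3_flags[1],
            "ro3_metabolites": self.ro3_flags[2],
            "ro3_pass": self.ro3_pass,
            "is_drug_like": self.is_drug_like,
            "is_lead_like": self.is_lead_like,
            "is_fragment_like": self.is_fragment_like,
            "stars": self.stars,
            "stars_evaluated": self.stars_evaluated,
            "caco2_band": self.caco2_band,
            "mdck_band": self.mdck_band,
        }
        return d


def ro5_violations(dv: DescriptorVector) -> Optional[int]:
    """Count Lipinski Rule-of-Five violations (0–4).

    The four conditions are MW < 500, log P < 5, HBD <= 5, HBA <= 10,
    with the inequalities exactly as conventionally stated (a compound at
    MW = 500 violates the MW condition).  Returns ``None`` if any of the
    four descriptors is missing.
    """
    if not dv.present("mw", "log_p", "hba", "hbd"):
        return None
    return sum([
        not (dv.mw < 500.0),
        not (dv.log_p < 5.0),
        not (dv.hbd <= 5.0),
        not (dv.hba <= 10.0),
    ])


def ro3_check(dv: DescriptorVector):
    """Jorgensen Rule-of-Three flags and overall pass.

    Returns ``(flags, ro3_pass)`` where ``flags`` is the triple of strict
    comparisons (log S_wat > -5.7, Caco-2 > 22 nm/s, #metab < 7); a flag
    is ``None`` when its descriptor is missing, and ``ro3_pass`` requires
    all three to be evaluable and true.
    """
    sol = None if dv.log_s_wat is None else dv.log_s_wat > -5.7
    caco = None if dv.bip_caco2 is None else dv.bip_caco2 > 22.0
    metab = None if dv.n_metab is None else dv.n_metab < 7
    flags = (sol, caco, metab)
    ro3_pass = None if any(f is None for f in flags) else all(flags)
    return flags, ro3_pass


def ro3_lenient_pass(dv: DescriptorVector) -> Optional[bool]:
    """Lenient Rule-of-Three reading: at least two of the three flags.

    Reported alongside the strict all-three default in verbose output, to
    make the sensitivity of the compliance percentage to the reading
    visible.
    """
    flags, _ = ro3_check(dv)
    if any(f is None for f in flags):
        return None
    return sum(flags) >= 2


def classify_subsets(dv: DescriptorVector):
    """Standard drug-like / lead-like / fragment-like membership.

    * drug-like:     MW < 500, log P < 5, HBD <= 5, HBA <= 10
    * lead-like:     150 <= MW <= 350, log P <= 4, HBD <= 3, HBA <= 6
    * fragment-like: MW <= 250, -2 <= log P <= 3, HBD < 3, HBA < 6, NRB < 3

    Lead-like implies drug-like (each lead-like bound is at least as
    strict).  A flag is ``None`` when a descriptor it needs is missing
    (NRB only matters for the fragment rule).
    """
    if not dv.present("mw", "log_p", "hba", "hbd"):
        return None, None, None
    drug = dv.mw < 500.0 and dv.log_p < 5.0 and dv.hbd <= 5.0 and dv.hba <= 10.0
    lead = (150.0 <= dv.mw <= 350.0 and dv.log_p <= 4.0
            and dv.hbd <= 3.0 and dv.hba <= 6.0)
    if dv.nrb is None:
        frag = None
    else:
        frag = (dv.mw <= 250.0 and -2.0 <= dv.log_p <= 3.0
                and dv.hbd < 3.0 and dv.hba < 6.0 and dv.nrb < 3)
    return drug, lead, frag


def count_stars(dv: DescriptorVector, ranges: RangeTable):
    """#stars compliance score.

    Returns ``(stars, stars_evaluated)``: the number of descriptors in
    the range table whose value falls strictly outside its compliance
    interval, and the number of non-missing descriptors that were
    actually checked.  Missing descriptors are skipped, never counted as
    violations.
    """
    stars = 0
    evaluated = 0
    for entry in ranges:
        value = dv.get(entry.descriptor)
        if value is None:
            continue
        evaluated += 1
        if not entry.contains(value):
            stars += 1
    return stars, evaluated


def qualitative_bands(dv: DescriptorVector):
    """Three-way permeability bands.

    Caco-2: < 5 nm/s low, > 100 high, otherwise intermediate.
    MDCK:  < 25 nm/s poor, > 500 great, otherwise intermediate.
    """
    if dv.bip_caco2 is None:
        caco = None
    elif dv.bip_caco2 < 5.0:
        caco = "low"
    elif dv.bip_caco2 > 100.0:
        caco = "high"
    else:
        caco = "intermediate"
    if dv.mdck is None:
        mdck = None
    elif dv.mdck < 25.0:
        mdck = "poor"
    elif dv.mdck > 500.0:
        mdck = "great"
    else:
        mdck = "intermediate"
    return caco, mdck


def evaluate(dv: DescriptorVector, ranges: Optional[RangeTable] = None) -> RuleOutcome:
    """Run every rule on one descriptor vector and collect the outcome."""
    if ranges is None:
        ranges = default_range_table()
    out = RuleOutcome()
    out.ro5_violations = ro5_violations(dv)
    out.ro5_pass = None if out.ro5_violations is None else out.ro5_violations == 0
    out.ro3_flags, out.ro3_pass = ro3_check(dv)
    out.is_drug_like, out.is_lead_like, out.is_fragment_like = classify_subsets(dv)
    out.stars, out.stars_evaluated = count_stars(dv, ranges)
    out.caco2_band, out.mdck_band = qualitative_bands(dv)
    return out
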