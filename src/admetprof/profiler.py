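"""Library-level aggregation: summary tables, binned distributions and
compliance percentages.

Percentages are always carried with their numerator and denominator,
because the choice of denominator (all records vs. records evaluable for
the rule in question) changes headline numbers materially — e.g. a
#stars compliance fraction over descriptor-evaluable compounds differs
from the same count over the full library whenever some structures could
not be processed by the descriptor predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Optional, Sequence

import pandas as pd

from .descriptors import DescriptorVector, derive_formula_descriptors
from .io import MoleculeRecord, TagSchema, parse_descriptor_tags
from .rules import RangeTable, RuleOutcome, default_range_table, evaluate

__all__ = [
    "TABLE_DESCRIPTORS",
    "BinSpec",
    "BinnedDistribution",
    "LibraryProfile",
    "FractionResult",
    "DEFAULT_BIN_SPECS",
    "PREDICATES",
    "round_half_up",
    "summarize",
    "bin_distribution",
    "fraction_satisfying",
    "pairwise_export",
    "profile_library",
    "descriptor_in_range",
    "threshold_above",
    "threshold_at_least",
    "band_membership",
]

#: The 19 descriptors reported in library summary tables.
TABLE_DESCRIPTORS = (
    "mw", "log_p", "hba", "hbd", "nrb",
    "log_bb", "bip_caco2", "s_mol", "s_mol_hfob", "v_mol",
    "log_s_wat", "log_k_hsa", "mdck", "ind_coh", "glob",
    "qp_polrz", "log_herg", "log_kp", "n_metab",
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BinSpec:
    """Half-open equal-width bins ``[origin + k*w, origin + (k+1)*w)``,
    labelled by their lower limit; values at or above ``truncation_max``
    are pooled into the top bin."""

    width: float
    origin: float = 0.0
    truncation_max: Optional[float] = None

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("bin width must be positive")


@dataclass
class BinnedDistribution:
    labels: list
    counts: list
    n_missing: int = 0

    def items(self):
        return list(zip(self.labels, self.counts))

    @property
    def n_binned(self) -> int:
        return sum(self.counts)


def _fmt_label(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


def bin_distribution(values: Sequence, spec: BinSpec) -> BinnedDistribution:
    """Bin values into lower-limit-labelled equal-width bins.

    ``None`` entries are excluded and counted in ``n_missing``.  With a
    ``truncation_max`` the bin axis always spans ``[origin,
    truncation_max)`` (so an empty input yields all-zero bins) and larger
    values are pooled into the top bin.
    """
    present = [v for v in values if v is not None]
    n_missing = len(values) - len(present)
    w, o, t = spec.width, spec.origin, spec.truncation_max

    if t is not None:
        n_bins = max(1, math.ceil((t - o) / w - 1e-12))
    elif present:
        n_bins = None  # determined from the data below
    else:
        return BinnedDistribution([], [], n_missing)

    ks = []
    for v in present:
        k = math.floor((v - o) / w)
        ks.append(k)
    if t is not None:
        k_lo = min([0] + ks) if ks else 0
        k_hi = n_bins - 1
        ks = [min(k, k_hi) for k in ks]
    else:
        k_lo = min([0] + ks)
        k_hi = max(ks)
    counts = {k: 0 for k in range(k_lo, k_hi + 1)}
    for k in ks:
        counts[k] += 1
    labels = [_fmt_label(o + k * w) for k in sorted(counts)]
    return BinnedDistribution(labels, [counts[k] for k in sorted(counts)], n_missing)


#: Default bin widths (width, origin, truncation), following the usual
#: presentation of compound-library property histograms.
DEFAULT_BIN_SPECS = {
    "mw": BinSpec(100.0, 0.0, 1000.0),
    "log_p": BinSpec(1.0, 0.0, 10.0),
    "hba": BinSpec(1.0, 0.0, 40.0),
    "hbd": BinSpec(1.0, 0.0, 10.0),
    "nrb": BinSpec(1.0, 0.0, 40.0),
    "stars": BinSpec(1.0, 0.0, None),
    "log_bb": BinSpec(1.0, 0.0, None),
    "log_kp": BinSpec(1.0, 0.0, None),
    "log_herg": BinSpec(1.0, 0.0, None),
    "log_s_wat": BinSpec(1.0, 0.0, None),
    "n_metab": BinSpec(1.0, 0.0, None),
}


@dataclass
class LibraryProfile:
    """Aggregated library statistics: per-library sizes, #stars
    compliance counts and descriptor means, plus subset membership."""

    n_total: int = 0
    n_descriptor_evaluable: int = 0
    n_stars0: int = 0
    rows: Optional[pd.DataFrame] = None  # index: library name
    subset_members: dict = field(default_factory=dict)
    is_empty: bool = False


_SUBSETS = (
    ("drug-like", "is_drug_like"),
    ("lead-like", "is_lead_like"),
    ("fragment-like", "is_fragment_like"),
)


def _row_stats(dvs, outcomes):
    n = len(dvs)
    evaluable = [o for o in outcomes if o.stars_evaluated > 0]
    n_compl = sum(1 for o in evaluable if o.stars == 0)
    stats = {"lib_size": n, "n_compl": n_compl, "n_evaluable": len(evaluable)}
    for name in TABLE_DESCRIPTORS:
        vals = [dv.get(name) for dv in dvs if dv.get(name) is not None]
        stats[name] = (sum(vals) / len(vals)) if vals else None
    return stats


def summarize(records: Sequence[MoleculeRecord],
              outcomes: Sequence[RuleOutcome]) -> LibraryProfile:
    """Build the library summary: one row for the total library and one
    per standard subset (drug-, lead-, fragment-like), each with size,
    number of fully compliant compounds (#stars = 0) and arithmetic means
    of present descriptor values over that row's members only."""
    if len(records) != len(outcomes):
        raise ValueError("records and outcomes must align 1:1")
    profile = LibraryProfile()
    if not records:
        profile.is_empty = True
        return profile
    dvs = [r.descriptors if r.descriptors is not None else DescriptorVector()
           for r in records]

    rows = {"total": _row_stats(dvs, outcomes)}
    members = {}
    for label, attr in _SUBSETS:
        idx = [i for i, o in enumerate(outcomes) if getattr(o, attr)]
        members[label] = [records[i].id for i in idx]
        rows[label] = _row_stats([dvs[i] for i in idx], [outcomes[i] for i in idx])

    profile.rows = pd.DataFrame.from_dict(rows, orient="index")
    profile.subset_members = members
    profile.n_total = len(records)
    profile.n_descriptor_evaluable = rows["total"]["n_evaluable"]
    profile.n_stars0 = rows["total"]["n_compl"]
    return profile


@dataclass
class FractionResult:
    """A compliance percentage carried with its counts."""

    name: str
    count: int
    denominator: int
    denominator_policy: str

    @property
    def percent(self) -> Optional[float]:
        if self.denominator == 0:
            return None  # undefined, never reported as 0%
        return 100.0 * self.count / self.denominator

    @property
    def percent_rounded(self) -> Optional[float]:
        p = self.percent
        return None if p is None else round_half_up(p, 1)

    def __str__(self):
        if self.percent is None:
            return f"{self.name}: undefined (0 denominator)"
        return (f"{self.name}: {self.percent_rounded}% "
                f"({self.count}/{self.denominator}, {self.denominator_policy})")


def _stars_eval(o: RuleOutcome) -> Optional[bool]:
    return None if o.stars_evaluated == 0 else o.stars == 0


#: Registered named rule conditions: (dv, outcome) -> True/False/None.
PREDICATES: dict = {
    "ro5_zero": lambda dv, o: None if o.ro5_violations is None else o.ro5_violations == 0,
    "ro5_le2": lambda dv, o: None if o.ro5_violations is None else o.ro5_violations <= 2,
    "ro3_pass": lambda dv, o: o.ro3_pass,
    "stars0": lambda dv, o: _stars_eval(o),
    "stars_le2": lambda dv, o: None if o.stars_evaluated == 0 else o.stars <= 2,
    "cns_active": lambda dv, o: None if dv.cns is None else dv.cns > 1,
    "drug_like": lambda dv, o: o.is_drug_like,
    "lead_like": lambda dv, o: o.is_lead_like,
    "fragment_like": lambda dv, o: o.is_fragment_like,
}


def descriptor_in_range(name: str, ranges: Optional[RangeTable] = None) -> Callable:
    """Predicate factory: descriptor value inside its compliance range."""
    table = ranges if ranges is not None else default_range_table()
    entry = table[name]

    def pred(dv, o):
        v = dv.get(name)
        return None if v is None else entry.contains(v)

    pred.__name__ = f"{name}_in_range"
    return pred


def threshold_above(name: str, threshold: float) -> Callable:
    """Predicate factory: descriptor strictly above a threshold
    (e.g. transdermal flux Jm > 100 ug/cm^2/h)."""
    def pred(dv, o):
        v = dv.get(name)
        return None if v is None else v > threshold
    pred.__name__ = f"{name}_gt_{threshold:g}"
    return pred


def threshold_at_least(name: str, threshold: float) -> Callable:
    """Predicate factory: descriptor at or above a threshold
    (e.g. percent human oral absorption >= 90)."""
    def pred(dv, o):
        v = dv.get(name)
        return None if v is None else v >= threshold
    pred.__name__ = f"{name}_ge_{threshold:g}"
    return pred


def band_membership(which: str, band: str) -> Callable:
    """Predicate factory: qualitative Caco-2/MDCK band membership."""
    attr = {"caco2": "caco2_band", "mdck": "mdck_band"}[which]

    def pred(dv, o):
        b = getattr(o, attr)
        return None if b is None else b == band
    pred.__name__ = f"{which}_band_{band}"
    return pred


def fraction_satisfying(dvs: Sequence[DescriptorVector],
                        outcomes: Sequence[RuleOutcome],
                        predicate,
                        denominator: str = "all") -> FractionResult:
    """Percentage of compounds satisfying a named or callable rule
    condition, under an explicit denominator policy.

    ``denominator="all"`` divides by every record; ``"evaluable"``
    divides only by records for which the predicate could be evaluated.
    The count and denominator are always reported next to the percentage.
    """
    if isinstance(predicate, str):
        try:
            fn = PREDICATES[predicate]
            name = predicate
        except KeyError:
            raise KeyError(f"unknown predicate {predicate!r}; "
                           f"registered: {sorted(PREDICATES)}") from None
    else:
        fn = predicate
        name = getattr(predicate, "__name__", "predicate")
    if denominator not in ("all", "evaluable"):
        raise ValueError("denominator policy must be 'all' or 'evaluable'")

    results = [fn(dv, o) for dv, o in zip(dvs, outcomes)]
    count = sum(1 for r in results if r is True)
    den = len(results) if denominator == "all" else sum(1 for r in results if r is not None)
    return FractionResult(name, count, den, denominator)


def pairwise_export(records: Sequence[MoleculeRecord], x: str, y: str):
    """Rows of (id, x, y) for compounds where both descriptors are
    present, with a Lipinski region-of-interest flag (MW < 500,
    -2 < log P < 5, HBA < 10, HBD < 5) when those four descriptors are
    available.  Returns ``(DataFrame, n_excluded)``."""
    rows = []
    n_excluded = 0
    for rec in records:
        dv = rec.descriptors
        if dv is None or dv.get(x) is None or dv.get(y) is None:
            n_excluded += 1
            continue
        if dv.present("mw", "log_p", "hba", "hbd"):
            region = (dv.mw < 500.0 and -2.0 < dv.log_p < 5.0
                      and dv.hba < 10.0 and dv.hbd < 5.0)
        else:
            region = None
        rows.append({"id": rec.id, x: dv.get(x), y: dv.get(y),
                     "in_lipinski_region": region})
    return pd.DataFrame(rows, columns=["id", x, y, "in_lipinski_region"]), n_excluded


def profile_library(records: Sequence[MoleculeRecord],
                    schema: Optional[TagSchema] = None,
                    ranges: Optional[RangeTable] = None,
                    compute_structural: bool = False,
                    derive_formulas: bool = True):
    """End-to-end pipeline on a list of records.

    Parses descriptor tags (records without a parsed vector), optionally
    computes structural descriptors from 3D structures for fields the
    tags did not supply, derives the formula-level descriptors
    (globularity, cohesion index, transdermal flux, surrogate log Kp),
    evaluates every rule, and aggregates.  Returns ``(dvs, outcomes,
    profile)``; each record's ``descriptors`` field is filled in place.
    """
    if ranges is None:
        ranges = default_range_table()
    from .descriptors import compute_structural_descriptors  # local: optional heavy path

    dvs = []
    for rec in records:
        dv = rec.descriptors if rec.descriptors is not None else \
            parse_descriptor_tags(rec, schema)
        if compute_structural and rec.structure is not None:
            computed = compute_structural_descriptors(rec.structure)
            for name, value in computed.as_dict().items():
                if value is not None and dv.get(name) is None:
                    dv.set(name, value, provenance=computed.provenance.get(name, "computed"))
            dv.diagnostics.extend(computed.diagnostics)
        if derive_formulas:
            derive_formula_descriptors(dv)
        rec.descriptors = dv
        dvs.append(dv)
    outcomes = [evaluate(dv, ranges) for dv in dvs]
    for dv, o in zip(dvs, outcomes):
        if o.stars_evaluated > 0 and dv.stars is None:
            dv.set("stars", o.stars, provenance="computed")
    profile = summarize(records, outcomes)
    return dvs, outcomes, profile
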