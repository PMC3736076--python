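"""Synthetic descriptor-annotated libraries and toy structures.

The default generator emulates the marginal property distributions of a
natural-product screening library of ~2,400 *Streptomyces* metabolites:
molecular weight lognormal with its 100-Da histogram mode in 301–400 Da
and ~42% of compounds above 500 Da; log P centred at 2.5 with rare
extreme outliers (atom-additive log P estimates can exceed 19 for
unusual natural-product scaffolds); H-bond acceptor/donor counts peaked
at 5 and 2; rotatable bonds peaked at 1–2 with a tail reaching 72; and
the remaining predicted pharmacokinetic descriptors normal (or
log-normal for permeabilities) around typical library means.  Couplings
between descriptors are minimal — a mild positive rank correlation of
size-related counts with MW via a Gaussian copula — since only marginals
are being emulated.

Everything is a pure function of (spec, seed): fixed inputs give
byte-identical output, so fixtures never need to be stored.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.stats import geom, nbinom, norm

from .descriptors import INTEGER_FIELDS
from .io import MoleculeRecord, default_tag_schema, write_library
from .rules import RangeTable

__all__ = [
    "GeneratorSpec",
    "StructureGrammar",
    "generate_tagged_library",
    "plant_fraction",
    "generate_structures",
    "write_fixture_sdf",
]

# Lognormal MW parameters solving: histogram mode (100 Da bins) at
# ~350 Da and P(MW > 500) = 0.42.
_MW_MU = 6.1127
_MW_SIGMA = 0.5048


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic library generator.

    ``normal_overrides`` replaces the (mean, sd) of any of the
    normally-distributed descriptor channels; ``couple_counts`` switches
    the mild MW→HBA/NRB rank correlation on or off.
    """

    n: int = 2444
    seed: int = 0
    normal_overrides: dict = field(default_factory=dict)
    couple_counts: bool = True
    outlier_fraction: float = 0.02  # heavy-tail admixture for log P

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if not (0.0 <= self.outlier_fraction <= 1.0):
            raise ValueError("outlier_fraction must lie in [0, 1]")
        for name, (mu, sd) in self.normal_overrides.items():
            if sd <= 0:
                raise ValueError(f"{name}: scale must be positive (got {sd})")


#: Default (mean, sd) of the plain-normal descriptor channels.
_NORMAL_DEFAULTS = {
    "log_p": (2.5, 1.8),
    "log_s_wat": (-3.2, 1.8),
    "log_k_hsa": (-0.48, 0.7),
    "log_bb": (-1.8, 1.2),
    "qp_polrz": (44.5, 15.0),
    "log_herg": (-4.8, 1.3),
    "log_kp": (-4.5, 1.6),
    "percent_hoa": (60.0, 25.0),
    "ln_caco2": (5.0, 1.4),   # log-normal channel, exp() applied
    "ln_mdck": (4.7, 1.5),
}

_INT_FMT = {"nrb", "n_metab", "qual_hoa", "cns", "hba", "hbd"}


def _draw(spec: GeneratorSpec, rng: np.random.Generator) -> dict:
    n = spec.n
    params = dict(_NORMAL_DEFAULTS)
    params.update(spec.normal_overrides)

    z_mw = rng.standard_normal(n)
    mw = np.exp(_MW_MU + _MW_SIGMA * z_mw)

    rho = 0.5 if spec.couple_counts else 0.0
    z_hba = rho * z_mw + math.sqrt(1 - rho * rho) * rng.standard_normal(n)
    hba = nbinom.ppf(norm.cdf(z_hba), 3, 1 / 3.75)         # mode strictly 5
    z_hbd = 0.6 * z_hba + 0.8 * rng.standard_normal(n)
    hbd = nbinom.ppf(norm.cdf(z_hbd), 2, 1 / 3.5)          # mode strictly 2
    z_nrb = rho * z_mw + math.sqrt(1 - rho * rho) * rng.standard_normal(n)
    nrb = np.clip(geom.ppf(norm.cdf(z_nrb), 0.25), 1, 72)  # mode 1-2, tail to 72

    mu, sd = params["log_p"]
    log_p = rng.normal(mu, sd, n)
    outliers = rng.random(n) < spec.outlier_fraction
    log_p = np.where(outliers, 5.0 + rng.exponential(4.0, n), log_p)

    s_mol = np.clip(120.0 + 1.25 * mw + rng.normal(0.0, 60.0, n), 150.0, None)
    s_mol_hfob = s_mol * rng.beta(5.0, 4.0, n)
    v_mol = np.clip(1.9 * s_mol + rng.normal(0.0, 80.0, n), 200.0, None)
    # surface/volume-consistent globularity, capped at the sphere bound
    r = (3.0 * v_mol / (4.0 * math.pi)) ** (1.0 / 3.0)
    glob = np.minimum(4.0 * math.pi * r * r / s_mol, 1.0)
    ind_coh = hba * np.sqrt(hbd) / s_mol

    log_s_wat = rng.normal(*params["log_s_wat"], n)
    ci_log_s_wat = log_s_wat + rng.normal(0.0, 0.4, n)
    log_k_hsa = rng.normal(*params["log_k_hsa"], n)
    log_bb = rng.normal(*params["log_bb"], n)
    bip_caco2 = np.clip(np.exp(rng.normal(*params["ln_caco2"], n)), 0.1, 1e4)
    mdck = np.clip(np.exp(rng.normal(*params["ln_mdck"], n)), 0.1, 1e4)
    qp_polrz = np.clip(rng.normal(*params["qp_polrz"], n), 1.0, None)
    log_herg = rng.normal(*params["log_herg"], n)
    log_kp = rng.normal(*params["log_kp"], n)
    n_metab = 1 + rng.poisson(5.0, n)
    jm = 1000.0 * (10.0 ** log_kp) * (10.0 ** log_s_wat) * mw
    percent_hoa = np.clip(rng.normal(*params["percent_hoa"], n), 0.0, 100.0)
    qual_hoa = np.where(percent_hoa < 30.0, 1, np.where(percent_hoa > 80.0, 3, 2))
    cns = rng.choice(np.array([-2, -1, 0, 1, 2]), size=n,
                     p=[0.38, 0.32, 0.20, 0.075, 0.025])

    return {
        "mw": mw, "log_p": log_p, "hba": hba, "hbd": hbd, "nrb": nrb,
        "s_mol": s_mol, "s_mol_hfob": s_mol_hfob, "v_mol": v_mol,
        "log_s_wat": log_s_wat, "ci_log_s_wat": ci_log_s_wat,
        "log_k_hsa": log_k_hsa, "log_bb": log_bb,
        "bip_caco2": bip_caco2, "mdck": mdck,
        "ind_coh": ind_coh, "glob": glob, "qp_polrz": qp_polrz,
        "log_herg": log_herg, "log_kp": log_kp, "n_metab": n_metab,
        "jm": jm, "percent_hoa": percent_hoa, "qual_hoa": qual_hoa, "cns": cns,
    }


def _primary_alias(name: str) -> str:
    return default_tag_schema().entries[name]["aliases"][0]


def _format_value(name: str, value) -> str:
    if name in _INT_FMT:
        return str(int(round(float(value))))
    return f"{float(value):.6g}"


def generate_tagged_library(spec: GeneratorSpec) -> list:
    """Generate ``spec.n`` tag-only records with a full set of descriptor
    SD tags (QikProp-style names).  #stars is deliberately absent: it is
    a derived compliance score, computed by the rule layer."""
    rng = np.random.default_rng(spec.seed)
    columns = _draw(spec, rng)
    alias = {name: _primary_alias(name) for name in columns}
    records = []
    for i in range(spec.n):
        tags = {alias[name]: _format_value(name, col[i]) for name, col in columns.items()}
        records.append(MoleculeRecord(id=f"SYNTH-{i + 1:05d}", tags=tags))
    return records


def _inside_value(entry, rng: np.random.Generator, integer: bool):
    lo, hi = entry.lower, entry.upper
    if lo is not None and hi is not None:
        if integer:
            return int(rng.integers(math.ceil(lo), math.floor(hi) + 1))
        return lo + (0.05 + 0.9 * rng.random()) * (hi - lo)
    anchor = lo if lo is not None else hi
    offset = 0.5 + 2.0 * rng.random()
    value = anchor + offset if lo is not None else anchor - offset
    return int(round(value)) if integer else value


def _outside_value(entry, rng: np.random.Generator, integer: bool):
    lo, hi = entry.lower, entry.upper
    if hi is not None:
        if integer:
            return int(math.floor(hi)) + 1 + int(rng.integers(0, 5))
        span = (hi - lo) if lo is not None else max(abs(hi), 1.0)
        return hi + (0.1 + rng.random()) * max(0.1 * span, 0.5)
    # one-sided-above: violation is below the lower bound
    if integer:
        return int(math.ceil(lo)) - 1 - int(rng.integers(0, 5))
    return lo - (0.1 + 2.0 * rng.random())


def plant_fraction(records: Sequence[MoleculeRecord], descriptor: str,
                   fraction: float, ranges: RangeTable, seed: int) -> list:
    """Return copies of ``records`` in which exactly
    ``round(fraction * n)`` randomly chosen compounds have ``descriptor``
    strictly outside its compliance interval and every other compound has
    it strictly inside.

    Planting is exact-count, not Bernoulli, so downstream compliance
    percentages are sharp test oracles.  Deterministic under ``seed``.
    """
    n = len(records)
    if n == 0:
        raise ValueError("cannot plant a fraction into an empty record list")
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    if descriptor not in ranges:
        raise KeyError(f"descriptor {descriptor!r} not in the range table")
    entry = ranges[descriptor]
    integer = descriptor in INTEGER_FIELDS
    alias = _primary_alias(descriptor)

    rng = np.random.default_rng(seed)
    k = int(round(fraction * n))
    outside_idx = set(rng.choice(n, size=k, replace=False).tolist()) if k else set()

    planted = []
    for i, rec in enumerate(records):
        value = (_outside_value(entry, rng, integer) if i in outside_idx
                 else _inside_value(entry, rng, integer))
        tags = dict(rec.tags)
        tags[alias] = _format_value(descriptor, value) if descriptor in _INT_FMT \
            else (str(int(value)) if integer else f"{float(value):.6f}")
        new = replace(rec, tags=tags)
        if rec.descriptors is not None:
            new.descriptors = copy.deepcopy(rec.descriptors)
            new.descriptors.set(descriptor, float(value) if not integer else int(value),
                                provenance="tag")
        planted.append(new)
    return planted


@dataclass(frozen=True)
class StructureGrammar:
    """Fragment grammar for toy molecules: a scaffold, an alkyl chain and
    a terminal functional group, concatenated as SMILES."""

    scaffolds: tuple = ("", "c1ccccc1", "C1CCCCC1")
    chain_lengths: tuple = (1, 2, 3, 4, 5)
    terminals: tuple = ("", "O", "N", "C(=O)O", "C(=O)N", "C(=O)NC")


def generate_structures(n: int, seed: int,
                        grammar: Optional[StructureGrammar] = None) -> list:
    """Generate ``n`` small valid molecules with deterministic 3D
    coordinates (distance-geometry embedding with a seeded RNG).

    These are toys for I/O and structural-descriptor testing — no attempt
    is made at realistic natural-product scaffolds.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if grammar is None:
        grammar = StructureGrammar()
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        scaffold = grammar.scaffolds[rng.integers(len(grammar.scaffolds))]
        chain = "C" * int(grammar.chain_lengths[rng.integers(len(grammar.chain_lengths))])
        terminal = grammar.terminals[rng.integers(len(grammar.terminals))]
        smiles = scaffold + chain + terminal
        if not smiles:
            smiles = "C"
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # pragma: no cover - grammar only emits valid SMILES
            raise ValueError(f"grammar produced invalid SMILES {smiles!r}")
        mol = Chem.AddHs(mol)
        AllChem.EmbedMolecule(mol, randomSeed=int(rng.integers(1, 2 ** 30)))
        records.append(MoleculeRecord(id=f"STR-{i + 1:04d}", structure=mol))
    return records


def write_fixture_sdf(records: Sequence[MoleculeRecord], path) -> None:
    """Write a descriptor-tagged fixture SDF readable by the library
    reader with zero tag loss.  An empty record list is an error — an
    empty fixture file is never useful and usually indicates a bug."""
    if not records:
        raise ValueError("refusing to write an empty fixture SDF")
    write_library(records, path, format="sdf")
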