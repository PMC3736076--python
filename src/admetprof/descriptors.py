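"""Molecular descriptor computation for ADMET profiling.

The central container is :class:`DescriptorVector`: the ~25 named
pharmacokinetic descriptors used in compound-library compliance scoring,
with per-field provenance (``computed`` from a structure, ``tag`` from an
SD annotation, ``surrogate`` from an estimator shipped here, or missing).

Structural descriptors (MW, H-bond counts, rotatable bonds, log P, solvent-
accessible surface/volume) are computed with RDKit.  Formula-level
descriptors — globularity, cohesion index, maximum transdermal flux,
similarity-adjusted property blending and a Potts–Guy skin-permeability
surrogate — are implemented directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional

from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, Lipinski, rdFreeSASA, rdMolDescriptors

__all__ = [
    "DescriptorVector",
    "DESCRIPTOR_FIELDS",
    "INTEGER_FIELDS",
    "ORDINAL_FIELDS",
    "compute_structural_descriptors",
    "derive_formula_descriptors",
    "globularity",
    "cohesion_index",
    "transdermal_rate",
    "similarity_blend",
    "surrogate_log_kp",
]

#: Canonical descriptor names, in report order.
DESCRIPTOR_FIELDS = (
    "mw", "log_p", "hba", "hbd", "nrb",
    "s_mol", "s_mol_hfob", "v_mol",
    "log_s_wat", "ci_log_s_wat", "log_k_hsa", "log_bb",
    "bip_caco2", "mdck", "ind_coh", "glob", "qp_polrz",
    "log_herg", "log_kp", "n_metab", "jm",
    "percent_hoa", "qual_hoa", "cns", "stars",
)

#: Fields whose values are non-negative integer counts.
INTEGER_FIELDS = frozenset({"nrb", "n_metab", "stars"})
#: Fields restricted to a small ordinal scale.
ORDINAL_FIELDS = {"qual_hoa": (1, 2, 3), "cns": (-2, -1, 0, 1, 2)}

_NONNEG_FIELDS = frozenset(
    {"mw", "hba", "hbd", "s_mol", "s_mol_hfob", "v_mol",
     "bip_caco2", "mdck", "jm", "qp_polrz", "nrb", "n_metab", "stars"}
)


@dataclass
class DescriptorVector:
    """Named pharmacokinetic descriptors for one compound.

    Every field is optional; ``None`` means *missing* (never silently
    zero).  ``provenance`` maps a field name to how its value was
    obtained: ``"computed"``, ``"tag"``, ``"surrogate"``.
    ``diagnostics`` collects per-field parse errors and quality flags.
    """

    mw: Optional[float] = None          # Da
    log_p: Optional[float] = None       # octanol-water log partition
    hba: Optional[float] = None         # H-bond acceptors (N+O or fractional)
    hbd: Optional[float] = None         # H-bond donors
    nrb: Optional[int] = None           # rotatable bonds
    s_mol: Optional[float] = None       # total SASA, A^2 (1.4 A probe)
    s_mol_hfob: Optional[float] = None  # hydrophobic SASA, A^2
    v_mol: Optional[float] = None       # solvent-accessible volume, A^3
    log_s_wat: Optional[float] = None   # log10 aqueous solubility, mol/L
    ci_log_s_wat: Optional[float] = None
    log_k_hsa: Optional[float] = None   # serum-albumin binding
    log_bb: Optional[float] = None      # blood/brain partition
    bip_caco2: Optional[float] = None   # Caco-2 permeability, nm/s
    mdck: Optional[float] = None        # MDCK permeability, nm/s
    ind_coh: Optional[float] = None     # cohesion index in solids
    glob: Optional[float] = None        # globularity, 1 for a sphere
    qp_polrz: Optional[float] = None    # polarizability, A^3
    log_herg: Optional[float] = None    # log IC50 for HERG K+ blockage
    log_kp: Optional[float] = None      # log10 skin permeability, cm/h
    n_metab: Optional[int] = None       # likely metabolic reactions
    jm: Optional[float] = None          # max transdermal flux, ug/cm^2/h
    percent_hoa: Optional[float] = None  # % human oral absorption
    qual_hoa: Optional[int] = None      # 1 low / 2 medium / 3 high
    cns: Optional[int] = None           # CNS activity, -2..+2
    stars: Optional[int] = None         # descriptors outside 95%-of-drugs ranges
    provenance: dict = field(default_factory=dict)
    diagnostics: list = field(default_factory=list)

    def get(self, name: str):
        if name not in DESCRIPTOR_FIELDS:
            raise KeyError(f"unknown descriptor {name!r}")
        return getattr(self, name)

    def set(self, name: str, value, provenance: str = "computed") -> None:
        if name not in DESCRIPTOR_FIELDS:
            raise KeyError(f"unknown descriptor {name!r}")
        setattr(self, name, value)
        if value is not None:
            self.provenance[name] = provenance
        else:
            self.provenance.pop(name, None)

    def present(self, *names: str) -> bool:
        """True if every named descriptor has a value."""
        return all(getattr(self, n) is not None for n in names)

    def validate(self) -> list:
        """Return a list of invariant-violation messages (empty if valid)."""
        problems = []
        for name in _NONNEG_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                problems.append(f"{name} negative: {v}")
        for name in INTEGER_FIELDS:
            v = getattr(self, name)
            if v is not None and v != int(v):
                problems.append(f"{name} not an integer: {v}")
        for name, allowed in ORDINAL_FIELDS.items():
            v = getattr(self, name)
            if v is not None and v not in allowed:
                problems.append(f"{name} outside ordinal scale: {v}")
        if self.percent_hoa is not None and not (0.0 <= self.percent_hoa <= 100.0):
            problems.append(f"percent_hoa outside [0,100]: {self.percent_hoa}")
        if (self.s_mol is not None and self.s_mol_hfob is not None
                and self.s_mol_hfob > self.s_mol + 1e-9):
            problems.append("s_mol_hfob exceeds s_mol")
        return problems

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in DESCRIPTOR_FIELDS}


_HALOGENS = {9, 17, 35, 53}


def _largest_fragment(mol: Chem.Mol):
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol, False
    best = max(frags, key=lambda f: f.GetNumHeavyAtoms())
    return best, True


def _has_3d(mol: Chem.Mol) -> bool:
    if mol.GetNumConformers() == 0:
        return False
    return bool(mol.GetConformer().Is3D())


def compute_structural_descriptors(mol: Chem.Mol) -> DescriptorVector:
    """Fill the openly computable structural descriptors from a structure.

    MW is the exact formula weight; HBA/HBD use the Lipinski N+O and
    NH+OH conventions; NRB counts non-ring single bonds between
    non-terminal heavy atoms, excluding amide C–N rotors; log P is the
    Crippen atom-additive estimate (flagged as surrogate-quality — atom
    contribution schemes trained on synthetic drugs can misjudge the
    functional-group combinations of natural products).  If the structure
    carries 3D coordinates, the solvent-accessible surface (total and
    hydrophobic) and volume are computed with a 1.4 Å probe; otherwise
    those fields stay missing.  Disconnected salt components are reduced
    to the largest fragment, with a diagnostic.
    """
    dv = DescriptorVector()
    if mol is None:
        dv.diagnostics.append("no structure")
        return dv
    work, was_salt = _largest_fragment(mol)
    if was_salt:
        dv.diagnostics.append("disconnected fragments: descriptors computed on largest")
    try:
        Chem.SanitizeMol(work)
    except Exception as exc:  # pragma: no cover - defensive
        dv.diagnostics.append(f"sanitization failed: {exc}")
        return dv

    heavy = Chem.RemoveHs(work)
    dv.set("mw", float(Descriptors.MolWt(work)))
    dv.set("hba", float(Lipinski.NOCount(heavy)))
    dv.set("hbd", float(Lipinski.NHOHCount(heavy)))
    dv.set("nrb", int(rdMolDescriptors.CalcNumRotatableBonds(
        heavy, rdMolDescriptors.NumRotatableBondsOptions.Strict)))
    dv.set("log_p", float(Crippen.MolLogP(heavy)))
    dv.diagnostics.append("log_p is an atom-additive estimate (surrogate quality)")

    if _has_3d(work):
        molh = Chem.AddHs(work, addCoords=True)
        radii = rdFreeSASA.classifyAtoms(molh)
        total = float(rdFreeSASA.CalcSASA(molh, radii))
        hfob = 0.0
        for atom in molh.GetAtoms():
            z = atom.GetAtomicNum()
            if z == 6 or z in _HALOGENS:
                hydrophobic = True
            elif z == 1:
                nbrs = atom.GetNeighbors()
                hydrophobic = bool(nbrs) and nbrs[0].GetAtomicNum() in (
                    {6} | _HALOGENS)
            else:
                hydrophobic = False
            if hydrophobic and atom.HasProp("SASA"):
                hfob += float(atom.GetProp("SASA"))
        dv.set("s_mol", total)
        dv.set("s_mol_hfob", min(hfob, total))
        dv.set("v_mol", float(AllChem.ComputeMolVolume(molh)))
    else:
        dv.diagnostics.append("no 3D coordinates: surface/volume descriptors missing")
    return dv


def globularity(s_mol: float, v_mol: float) -> float:
    """Sphericity of a molecular surface: ``4*pi*r^2 / S_mol`` with *r*
    the radius of the sphere whose volume equals ``v_mol``.

    Equals 1 for a sphere and decreases for elongated shapes (by the
    isoperimetric inequality no convex body exceeds 1).
    """
    if s_mol <= 0 or v_mol <= 0:
        raise ValueError("globularity requires positive surface and volume")
    r = (3.0 * v_mol / (4.0 * math.pi)) ** (1.0 / 3.0)
    return 4.0 * math.pi * r * r / s_mol


def cohesion_index(hba: float, hbd: float, sasa: float) -> float:
    """Index of cohesive interaction in solids: ``HBA * sqrt(HBD) / SASA``.

    Built from the hydrogen-bond acceptor and donor counts and the
    solvent-accessible surface area; dimensionally a surface density of
    hydrogen-bonding capacity.  Typical drugs fall in 0.00–0.05.  The
    functional form is configurable at the rule layer; this default
    reproduces the reference mean behaviour of drug-sized molecules.
    """
    if sasa <= 0:
        raise ValueError("cohesion_index requires positive SASA")
    if hba < 0 or hbd < 0:
        raise ValueError("H-bond counts must be non-negative")
    return hba * math.sqrt(hbd) / sasa


def transdermal_rate(log_kp: float, log_s_wat: float, mw: float) -> float:
    """Maximum transdermal transport rate Jm in ug cm^-2 h^-1.

    ``Jm = Kp * C_sat`` with Kp = 10**log_kp in cm/h and the saturated
    aqueous concentration ``C_sat = 10**log_s_wat * mw * 1000`` in
    ug/cm^3 (log_s_wat is log10 solubility in mol/L).
    """
    if mw <= 0:
        raise ValueError("transdermal_rate requires positive molecular weight")
    return (10.0 ** log_kp) * (10.0 ** log_s_wat) * mw * 1000.0


def similarity_blend(s: float, p_exp: float, p_qp: float) -> float:
    """Similarity-adjusted property prediction.

    When the query's similarity *s* to its nearest training-set analogue
    is below 0.9 the model prediction ``p_qp`` is used unchanged; above,
    the prediction is pulled linearly toward the analogue's experimental
    value so that ``s = 1`` returns ``p_exp`` exactly:

        p_pred = p_qp + (s - 0.9) / 0.1 * (p_exp - p_qp)   for s >= 0.9

    Continuous in *s* on [0, 1].
    """
    if not (0.0 <= s <= 1.0):
        raise ValueError("similarity must lie in [0, 1]")
    if s < 0.9:
        return p_qp
    return p_qp + (s - 0.9) / 0.1 * (p_exp - p_qp)


#: Potts–Guy coefficients: log Kp (cm/s) = a*logP + b*MW + c.
_PG_LOGP_COEF = 0.71
_PG_MW_COEF = -0.0061
_PG_INTERCEPT = -6.3
_CM_S_TO_CM_H = math.log10(3600.0)


def surrogate_log_kp(log_p: float, mw: float) -> float:
    """Potts–Guy estimate of skin permeability, log10 Kp in cm/h.

    The classic linear model in log P and molecular weight (in cm/s),
    shifted by log10(3600) to the per-hour scale used for flux
    estimation.  Provided as a clearly-labelled surrogate for workflows
    whose input tags lack a skin-permeability prediction; it never
    overwrites a tag-derived value.
    """
    if mw <= 0:
        raise ValueError("surrogate_log_kp requires positive molecular weight")
    return _PG_LOGP_COEF * log_p + _PG_MW_COEF * mw + _PG_INTERCEPT + _CM_S_TO_CM_H


def derive_formula_descriptors(dv: DescriptorVector) -> DescriptorVector:
    """Fill formula-level descriptors computable from fields already present.

    Fills ``glob`` (from s_mol, v_mol), ``ind_coh`` (from hba, hbd,
    s_mol), ``log_kp`` (Potts–Guy surrogate from log_p and mw, only when
    no tag supplied one) and ``jm`` (from log_kp, log_s_wat, mw).  Fields
    already present are never overwritten.  Returns ``dv`` for chaining.
    """
    if dv.glob is None and dv.present("s_mol", "v_mol") and dv.s_mol > 0 and dv.v_mol > 0:
        dv.set("glob", globularity(dv.s_mol, dv.v_mol))
    if dv.ind_coh is None and dv.present("hba", "hbd", "s_mol") and dv.s_mol > 0:
        dv.set("ind_coh", cohesion_index(dv.hba, dv.hbd, dv.s_mol))
    if dv.log_kp is None and dv.present("log_p", "mw") and dv.mw > 0:
        dv.set("log_kp", surrogate_log_kp(dv.log_p, dv.mw), provenance="surrogate")
    if dv.jm is None and dv.present("log_kp", "log_s_wat", "mw") and dv.mw > 0:
        dv.set("jm", transdermal_rate(dv.log_kp, dv.log_s_wat, dv.mw))
    return dv
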