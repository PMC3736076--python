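"""Reading and writing compound libraries with descriptor annotations.

Supports SDF (V2000 connection table + SD tags), multi-molecule MOL2 and
SMILES files (one molecule per line, optional identifier after
whitespace).  SD tags are captured verbatim; a record whose connection
table fails to parse is *kept* with ``structure=None`` and flagged,
because its tags may still carry usable descriptor values — library
sizes are never silently reduced by parse failures.

RDKit parses the individual connection tables; block splitting and SD-tag
extraction are done here so that malformed records can be retained
instead of dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Optional

import yaml
from rdkit import Chem, RDLogger

from .descriptors import DESCRIPTOR_FIELDS, ORDINAL_FIELDS, DescriptorVector
from .rules import RangeTable, RangeTableError, load_range_table  # noqa: F401  (re-export)

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeRecord",
    "TagSchema",
    "TagSchemaError",
    "EmptyLibraryError",
    "read_library",
    "write_library",
    "parse_descriptor_tags",
    "load_tag_schema",
    "default_tag_schema",
    "load_range_table",
]


class EmptyLibraryError(ValueError):
    """A library file yielded zero molecule records."""


class TagSchemaError(ValueError):
    """A tag-schema configuration failed validation."""


@dataclass
class MoleculeRecord:
    """One compound: identifier, optional structure, raw SD tags and
    (once parsed or computed) a descriptor vector."""

    id: str
    structure: Optional[Chem.Mol] = None
    tags: dict = field(default_factory=dict)
    descriptors: Optional[DescriptorVector] = None
    parse_failed: bool = False
    diagnostics: list = field(default_factory=list)


@dataclass
class TagSchema:
    """Mapping of canonical descriptor name -> accepted SD-tag aliases
    plus the declared value kind (real | integer | ordinal)."""

    entries: dict  # name -> {"aliases": [...], "kind": str}

    def __post_init__(self):
        for name, spec in self.entries.items():
            if name not in DESCRIPTOR_FIELDS:
                raise TagSchemaError(f"unknown descriptor name {name!r}")
            aliases = spec.get("aliases")
            if not aliases:
                raise TagSchemaError(f"{name}: alias list must be non-empty")
            kind = spec.get("kind")
            if kind not in ("real", "integer", "ordinal"):
                raise TagSchemaError(f"{name}: kind must be real|integer|ordinal, got {kind!r}")

    def items(self):
        return self.entries.items()


def load_tag_schema(path) -> TagSchema:
    """Load a tag schema from a YAML/JSON config with a top-level
    ``descriptors`` mapping."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "descriptors" not in doc:
        raise TagSchemaError("tag schema must contain a top-level 'descriptors' mapping")
    return TagSchema(doc["descriptors"])


@lru_cache(maxsize=1)
def _default_schema_doc() -> str:
    return resources.files("admetprof.data").joinpath(
        "tag_schema_default.yaml").read_text(encoding="utf-8")


@lru_cache(maxsize=1)
def default_tag_schema() -> TagSchema:
    """The packaged default schema (QikProp-style tag names plus generic
    fallbacks).  Cached; treat the returned schema as read-only."""
    return TagSchema(yaml.safe_load(_default_schema_doc())["descriptors"])


def _read_text(path) -> str:
    with open(path, "rb") as fh:
        raw = fh.read()
    try:
        return raw.decode("utf-8")
    except UnicodeDecodeError:
        return raw.decode("latin-1")


_TAG_HEADER = re.compile(r"^>\s*<([^>]+)>")


def _parse_sd_tags(lines) -> dict:
    tags = {}
    i = 0
    while i < len(lines):
        m = _TAG_HEADER.match(lines[i])
        if m:
            name = m.group(1)
            value_lines = []
            i += 1
            while i < len(lines) and lines[i].strip() != "":
                value_lines.append(lines[i])
                i += 1
            tags[name] = "\n".join(value_lines).strip()
        else:
            i += 1
    return tags


def _unique_id(candidate: str, seen: set) -> str:
    uid = candidate
    n = 2
    while uid in seen:
        uid = f"{candidate}_{n}"
        n += 1
    seen.add(uid)
    return uid


def _read_sdf(text: str):
    records = []
    seen = set()
    block_lines: list = []
    blocks = []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            blocks.append(block_lines)
            block_lines = []
        else:
            block_lines.append(line)
    if any(l.strip() for l in block_lines):
        blocks.append(block_lines)

    for i, lines in enumerate(blocks):
        end_idx = None
        for j, line in enumerate(lines):
            if line.rstrip() == "M  END":
                end_idx = j
                break
        structure = None
        failed = False
        diagnostics = []
        if end_idx is not None:
            molblock = "\n".join(lines[: end_idx + 1]) + "\n"
            structure = Chem.MolFromMolBlock(molblock, removeHs=False)
            if structure is None:
                failed = True
                diagnostics.append("connection table failed to parse")
            elif structure.GetNumAtoms() == 0:
                structure = None  # tags-only record, not a failure
            tag_lines = lines[end_idx + 1:]
        else:
            failed = True
            diagnostics.append("no 'M  END' terminator: connection table unreadable")
            tag_lines = lines
        tags = _parse_sd_tags(tag_lines)
        title = lines[0].strip() if lines else ""
        rid = _unique_id(title or f"MOL{i + 1:05d}", seen)
        records.append(MoleculeRecord(rid, structure, tags,
                                      parse_failed=failed, diagnostics=diagnostics))
    return records


def _read_mol2(text: str):
    records = []
    seen = set()
    chunks = re.split(r"(?m)^(?=@<TRIPOS>MOLECULE)", text)
    idx = 0
    for chunk in chunks:
        if not chunk.strip().startswith("@<TRIPOS>MOLECULE"):
            continue
        idx += 1
        mol = Chem.MolFromMol2Block(chunk, removeHs=False)
        failed = mol is None
        lines = chunk.splitlines()
        name = lines[1].strip() if len(lines) > 1 else ""
        rid = _unique_id(name or f"MOL{idx:05d}", seen)
        diagnostics = ["MOL2 block failed to parse"] if failed else []
        records.append(MoleculeRecord(rid, mol, {}, parse_failed=failed,
                                      diagnostics=diagnostics))
    return records


def _read_smiles(text: str):
    records = []
    seen = set()
    idx = 0
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        idx += 1
        parts = line.split(None, 1)
        smi = parts[0]
        name = parts[1].strip() if len(parts) > 1 else ""
        mol = Chem.MolFromSmiles(smi)
        failed = mol is None
        rid = _unique_id(name or f"MOL{idx:05d}", seen)
        diagnostics = [f"SMILES failed to parse: {smi!r}"] if failed else []
        records.append(MoleculeRecord(rid, mol, {}, parse_failed=failed,
                                      diagnostics=diagnostics))
    return records


def read_library(path, format: str = "sdf"):
    """Read a compound library, preserving order and SD tags.

    Returns an ordered list of :class:`MoleculeRecord`, one per molecule
    block (SDF/MOL2) or non-empty line (SMILES).  Records whose structure
    fails to parse are retained with ``parse_failed=True`` so that
    tag-borne descriptors survive.  Raises ``OSError`` for unreadable
    files and :class:`EmptyLibraryError` when nothing was parsed.
    """
    text = _read_text(path)
    if format == "sdf":
        records = _read_sdf(text)
    elif format == "mol2":
        records = _read_mol2(text)
    elif format == "smiles":
        records = _read_smiles(text)
    else:
        raise ValueError(f"unsupported format {format!r} (expected sdf, mol2 or smiles)")
    if not records:
        raise EmptyLibraryError(f"no molecules parsed from {path}")
    return records


_EMPTY_CTAB = "  0  0  0  0  0  0  0  0  0  0999 V2000\nM  END\n"


def _record_sdf_block(rec: MoleculeRecord) -> str:
    if rec.structure is not None and rec.structure.GetNumAtoms() > 0:
        mol = Chem.Mol(rec.structure)
        mol.SetProp("_Name", rec.id)
        block = Chem.MolToMolBlock(mol, kekulize=True)
    else:
        block = f"{rec.id}\n     admetprof\n\n{_EMPTY_CTAB}"
    parts = [block.rstrip("\n")]
    for name, value in rec.tags.items():
        parts.append(f">  <{name}>\n{value}\n")
    return "\n".join(parts) + "\n$$$$\n"


def write_library(records, path, format: str = "sdf") -> None:
    """Write records to SDF (tags preserved verbatim) or SMILES."""
    if format == "sdf":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(_record_sdf_block(rec))
    elif format == "smiles":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in records:
                if rec.structure is None:
                    continue
                fh.write(f"{Chem.MolToSmiles(rec.structure)} {rec.id}\n")
    else:
        raise ValueError(f"unsupported output format {format!r}")


def _parse_value(raw: str, kind: str, name: str):
    if kind == "real":
        return float(raw)
    value = float(raw)
    if value != int(value):
        raise ValueError(f"{raw!r} is not an integer")
    value = int(value)
    if kind == "ordinal":
        allowed = ORDINAL_FIELDS.get(name)
        if allowed is not None and value not in allowed:
            raise ValueError(f"{value} outside ordinal scale {allowed}")
    return value


def parse_descriptor_tags(record: MoleculeRecord,
                          schema: Optional[TagSchema] = None) -> DescriptorVector:
    """Resolve a record's raw SD tags into a :class:`DescriptorVector`.

    For each canonical descriptor, the first matching alias wins; values
    are parsed per the declared kind.  Total over arbitrary tag maps: a
    present-but-garbled value yields a recorded parse error and a missing
    field, never a silent zero and never an exception.
    """
    if schema is None:
        schema = default_tag_schema()
    dv = DescriptorVector()
    for name, spec in schema.items():
        raw = None
        for alias in spec["aliases"]:
            if alias in record.tags:
                raw = record.tags[alias]
                break
        if raw is None:
            continue
        try:
            dv.set(name, _parse_value(raw.strip(), spec["kind"], name), provenance="tag")
        except (ValueError, TypeError) as exc:
            dv.diagnostics.append(f"{name}: unparseable tag value ({exc})")
    return dv
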