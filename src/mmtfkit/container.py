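"""Top-level document: field schema, MessagePack serialization, versioning.

A document is a map of named fields.  Columnar fields hold packed encoded
records (see :mod:`mmtfkit.codec_registry`); everything else is stored
with native MessagePack types.  Files may be transparently gzip-wrapped.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Optional

import msgpack

from . import codec_registry as reg
from .codec_core import CodecError

__all__ = [
    "FORMAT_VERSION",
    "PRODUCER",
    "GroupType",
    "MmtfDocument",
    "SchemaError",
    "VersionError",
    "Verdict",
    "serialize",
    "deserialize",
    "validate",
    "check_version",
    "read_file",
    "write_file",
]

FORMAT_VERSION = "1.0.0"
PRODUCER = "mmtfkit 0.1.0"

GZIP_MAGIC = b"\x1f\x8b"


class SchemaError(Exception):
    """Document violates the field schema; carries the violation list."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class VersionError(Exception):
    """Major format version of the file is not supported."""


class Verdict(Enum):
    COMPATIBLE = "compatible"
    COMPATIBLE_WITH_WARNING = "compatible-with-warning"
    INCOMPATIBLE = "incompatible"


_SEMVER_RE = re.compile(r"^(\d+)\.(\d+)(?:\.(\d+))?")


def check_version(found: str, supported: str = FORMAT_VERSION) -> Verdict:
    """Compare two semantic versions; only major mismatches are fatal."""
    parsed = []
    for v in (found, supported):
        m = _SEMVER_RE.match(str(v).strip())
        if not m:
            raise ValueError(f"unparseable version string: {v!r}")
        parsed.append(tuple(int(x or 0) for x in m.groups()))
    if parsed[0][0] != parsed[1][0]:
        return Verdict.INCOMPATIBLE
    if parsed[0][1:] != parsed[1][1:]:
        return Verdict.COMPATIBLE_WITH_WARNING
    return Verdict.COMPATIBLE


@dataclass
class GroupType:
    """Dictionary entry describing one unique residue type."""

    group_name: str
    atom_names: list[str]
    elements: list[str]
    formal_charges: list[int]
    intra_bond_atoms: list[int] = field(default_factory=list)  # flat pairs
    intra_bond_orders: list[int] = field(default_factory=list)
    single_letter_code: str = "?"
    chem_comp_type: str = "NON-POLYMER"

    @property
    def atom_count(self) -> int:
        return len(self.atom_names)

    @property
    def bond_count(self) -> int:
        return len(self.intra_bond_orders)

    def to_map(self) -> dict:
        return {
            "groupName": self.group_name,
            "atomNameList": list(self.atom_names),
            "elementList": list(self.elements),
            "formalChargeList": list(self.formal_charges),
            "bondAtomList": list(self.intra_bond_atoms),
            "bondOrderList": list(self.intra_bond_orders),
            "singleLetterCode": self.single_letter_code,
            "chemCompType": self.chem_comp_type,
        }

    @classmethod
    def from_map(cls, m: dict) -> "GroupType":
        return cls(
            group_name=m.get("groupName", ""),
            atom_names=list(m.get("atomNameList", [])),
            elements=list(m.get("elementList", [])),
            formal_charges=list(m.get("formalChargeList", [])),
            intra_bond_atoms=list(m.get("bondAtomList", [])),
            intra_bond_orders=list(m.get("bondOrderList", [])),
            single_letter_code=m.get("singleLetterCode", "?"),
            chem_comp_type=m.get("chemCompType", "NON-POLYMER"),
        )

    def validate(self, prefix: str) -> list[str]:
        out = []
        n = len(self.atom_names)
        if not (len(self.elements) == len(self.formal_charges) == n):
            out.append(f"{prefix}: atom_names/elements/formal_charges lengths differ")
        if len(self.intra_bond_atoms) != 2 * len(self.intra_bond_orders):
            out.append(f"{prefix}: bond atom list is not twice the bond order list")
        if any(i < 0 or i >= n for i in self.intra_bond_atoms):
            out.append(f"{prefix}: bond index out of range")
        if any(o not in (1, 2, 3, 4) for o in self.intra_bond_orders):
            out.append(f"{prefix}: bond order outside 1..4")
        return out


# (attribute, wire key, required, columnar, expected-length key or None)
# expected-length: "atom" | "group" | "chain" | "bondpair" | "bond"
_FIELDS = [
    ("format_version", "mmtfVersion", True, False, None),
    ("producer", "mmtfProducer", True, False, None),
    ("structure_id", "structureId", False, False, None),
    ("title", "title", False, False, None),
    ("deposition_date", "depositionDate", False, False, None),
    ("release_date", "releaseDate", False, False, None),
    ("experimental_methods", "experimentalMethods", False, False, None),
    ("space_group", "spaceGroup", False, False, None),
    ("unit_cell", "unitCell", False, False, None),
    ("ncs_operators", "ncsOperatorList", False, False, None),
    ("resolution", "resolution", False, False, None),
    ("r_free", "rFree", False, False, None),
    ("r_work", "rWork", False, False, None),
    ("entities", "entityList", False, False, None),
    ("bio_assemblies", "bioAssemblyList", False, False, None),
    ("num_models", "numModels", True, False, None),
    ("num_chains", "numChains", True, False, None),
    ("num_groups", "numGroups", True, False, None),
    ("num_atoms", "numAtoms", True, False, None),
    ("num_bonds", "numBonds", True, False, None),
    ("chains_per_model", "chainsPerModel", True, False, None),
    ("groups_per_chain", "groupsPerChain", True, False, None),
    ("group_dictionary", "groupList", True, False, None),
    ("chain_ids", "chainIdList", True, True, "chain"),
    ("chain_names", "chainNameList", False, True, "chain"),
    ("group_types", "groupTypeList", True, True, "group"),
    ("group_ids", "groupIdList", True, True, "group"),
    ("ins_codes", "insCodeList", False, True, "group"),
    ("sequence_indices", "sequenceIndexList", False, True, "group"),
    ("sec_struct", "secStructList", False, True, "group"),
    ("x", "xCoordList", True, True, "atom"),
    ("y", "yCoordList", True, True, "atom"),
    ("z", "zCoordList", True, True, "atom"),
    ("b_factors", "bFactorList", False, True, "atom"),
    ("occupancies", "occupancyList", False, True, "atom"),
    ("alt_locs", "altLocList", False, True, "atom"),
    ("atom_ids", "atomIdList", False, True, "atom"),
    ("inter_group_bond_atoms", "bondAtomList", False, True, "bondpair"),
    ("inter_group_bond_orders", "bondOrderList", False, True, "bond"),
]

_KEY_TO_ATTR = {key: attr for attr, key, *_ in _FIELDS}
_REQUIRED = [(attr, key) for attr, key, req, *_ in _FIELDS if req]


@dataclass
class MmtfDocument:
    """Top-level map of named fields; columnar fields hold packed records."""

    format_version: str = FORMAT_VERSION
    producer: str = PRODUCER
    structure_id: Optional[str] = None
    title: Optional[str] = None
    deposition_date: Optional[str] = None
    release_date: Optional[str] = None
    experimental_methods: Optional[list[str]] = None
    space_group: Optional[str] = None
    unit_cell: Optional[list[float]] = None
    ncs_operators: Optional[list[list[float]]] = None
    resolution: Optional[float] = None
    r_free: Optional[float] = None
    r_work: Optional[float] = None
    entities: Optional[list[dict]] = None
    bio_assemblies: Optional[list[dict]] = None
    num_models: int = 0
    num_chains: int = 0
    num_groups: int = 0
    num_atoms: int = 0
    num_bonds: int = 0
    chains_per_model: list[int] = field(default_factory=list)
    groups_per_chain: list[int] = field(default_factory=list)
    group_dictionary: list[GroupType] = field(default_factory=list)
    chain_ids: Optional[bytes] = None
    chain_names: Optional[bytes] = None
    group_types: Optional[bytes] = None
    group_ids: Optional[bytes] = None
    ins_codes: Optional[bytes] = None
    sequence_indices: Optional[bytes] = None
    sec_struct: Optional[bytes] = None
    x: Optional[bytes] = None
    y: Optional[bytes] = None
    z: Optional[bytes] = None
    b_factors: Optional[bytes] = None
    occupancies: Optional[bytes] = None
    alt_locs: Optional[bytes] = None
    atom_ids: Optional[bytes] = None
    inter_group_bond_atoms: Optional[bytes] = None
    inter_group_bond_orders: Optional[bytes] = None
    #: unknown top-level keys, preserved round-trip
    extras: dict[str, Any] = field(default_factory=dict)


def validate(doc: MmtfDocument) -> list[str]:
    """Check every schema invariant; returns violations, never raises."""
    out: list[str] = []
    if sum(doc.chains_per_model) != doc.num_chains:
        out.append(
            f"chainsPerModel: sum {sum(doc.chains_per_model)} != numChains {doc.num_chains}"
        )
    if len(doc.chains_per_model) != doc.num_models:
        out.append(
            f"chainsPerModel: {len(doc.chains_per_model)} entries for numModels {doc.num_models}"
        )
    if sum(doc.groups_per_chain) != doc.num_groups:
        out.append(
            f"groupsPerChain: sum {sum(doc.groups_per_chain)} != numGroups {doc.num_groups}"
        )
    if len(doc.groups_per_chain) != doc.num_chains:
        out.append(
            f"groupsPerChain: {len(doc.groups_per_chain)} entries for numChains {doc.num_chains}"
        )
    for i, gt in enumerate(doc.group_dictionary):
        out.extend(gt.validate(f"groupList[{i}]"))

    decoded: dict[str, Any] = {}
    for attr, key, required, columnar, _ in _FIELDS:
        if not columnar:
            continue
        record = getattr(doc, attr)
        if record is None:
            continue
        try:
            decoded[attr] = reg.decode_column(record)
        except CodecError as exc:
            out.append(f"{key}: decode failed ({exc})")

    group_types = decoded.get("group_types")
    n_dict = len(doc.group_dictionary)
    atoms_from_dict = None
    intra_bonds = None
    if group_types is not None:
        bad = [int(t) for t in group_types if t < 0 or t >= n_dict]
        if bad:
            out.append(f"groupTypeList: index {bad[0]} outside dictionary of size {n_dict}")
        else:
            atoms_from_dict = sum(doc.group_dictionary[t].atom_count for t in group_types)
            intra_bonds = sum(doc.group_dictionary[t].bond_count for t in group_types)
            if atoms_from_dict != doc.num_atoms:
                out.append(
                    f"groupTypeList: dictionary atom counts sum to {atoms_from_dict}, "
                    f"numAtoms is {doc.num_atoms}"
                )

    expected = {
        "atom": doc.num_atoms,
        "group": doc.num_groups,
        "chain": doc.num_chains,
    }
    for attr, key, required, columnar, length_kind in _FIELDS:
        if not columnar or attr not in decoded or length_kind not in expected:
            continue
        got = len(decoded[attr])
        if got != expected[length_kind]:
            out.append(f"{key}: decodes to {got} values, expected {expected[length_kind]}")

    bond_pairs = decoded.get("inter_group_bond_atoms")
    bond_orders = decoded.get("inter_group_bond_orders")
    n_inter = None
    if bond_pairs is not None:
        if len(bond_pairs) % 2:
            out.append("bondAtomList: odd number of atom indices")
        else:
            n_inter = len(bond_pairs) // 2
            bad = [int(i) for i in bond_pairs if i < 0 or i >= doc.num_atoms]
            if bad:
                out.append(f"bondAtomList: atom index {bad[0]} out of range")
        if bond_orders is not None and len(bond_orders) * 2 != len(bond_pairs):
            out.append("bondOrderList: length does not match bondAtomList pairs")
    elif bond_orders is not None and len(bond_orders):
        out.append("bondOrderList present without bondAtomList")
    if n_inter is None:
        n_inter = 0
    if intra_bonds is not None and doc.num_bonds != intra_bonds + n_inter:
        out.append(
            f"numBonds: {doc.num_bonds} != {intra_bonds} intra + {n_inter} inter bonds"
        )
    return out


def serialize(doc: MmtfDocument) -> bytes:
    """Serialize a validated document to MessagePack bytes."""
    violations = validate(doc)
    if violations:
        raise SchemaError(violations)
    out: dict[str, Any] = {}
    for attr, key, required, columnar, _ in _FIELDS:
        value = getattr(doc, attr)
        if value is None:
            if required:
                raise SchemaError([f"{key}: required field is missing"])
            continue
        if attr == "group_dictionary":
            value = [gt.to_map() for gt in value]
        out[key] = value
    for key, value in doc.extras.items():
        out.setdefault(key, value)
    return msgpack.packb(out, use_bin_type=True)


def deserialize(data: bytes) -> MmtfDocument:
    """Parse MessagePack bytes (gzip-wrapped or not) into a document.

    Unknown keys are preserved in ``extras``; missing optional fields stay
    ``None``; a missing required field raises :class:`SchemaError`.
    """
    if data[:2] == GZIP_MAGIC:
        data = gzip.decompress(data)
    try:
        raw = msgpack.unpackb(data, raw=False, strict_map_key=False)
    except Exception as exc:
        raise ValueError(f"not a MessagePack document: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError("top level is not a MessagePack map")

    missing = [key for attr, key in _REQUIRED if key not in raw]
    if missing:
        raise SchemaError([f"{key}: required field is missing" for key in missing])

    version = raw.get("mmtfVersion", FORMAT_VERSION)
    if check_version(version, FORMAT_VERSION) is Verdict.INCOMPATIBLE:
        raise VersionError(
            f"file format version {version} is incompatible with supported {FORMAT_VERSION}"
        )

    doc = MmtfDocument()
    for key, value in raw.items():
        attr = _KEY_TO_ATTR.get(key)
        if attr is None:
            doc.extras[key] = value
            continue
        if attr == "group_dictionary":
            value = [GroupType.from_map(m) for m in value]
        setattr(doc, attr, value)
    return doc


def write_file(doc: MmtfDocument, path, gzipped: bool = False) -> None:
    data = serialize(doc)
    if gzipped:
        data = gzip.compress(data, mtime=0)
    with open(path, "wb") as fh:
        fh.write(data)


def read_file(path) -> MmtfDocument:
    with open(path, "rb") as fh:
        return deserialize(fh.read())
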