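"""End-to-end encoding: parsed structure -> document.

Builds the group dictionary, attaches bonds, applies the per-field codec
choices and emits a validated document under the full (lossless) or
reduced (lossy, backbone-trace) profile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from . import codec_registry as reg
from . import container
from .container import GroupType, MmtfDocument
from .structure_model import IntegrityError, StructureData

__all__ = [
    "Atom",
    "Group",
    "Chain",
    "Model",
    "Entity",
    "RawStructure",
    "EncodingProfile",
    "FULL",
    "REDUCED",
    "PROFILES",
    "classify_group",
    "build_group_dictionary",
    "attach_inter_group_bonds",
    "reduce_structure",
    "encode_structure",
    "to_raw_structure",
]

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# distance caps for inferred backbone links; avoids bonding across breaks
PEPTIDE_BOND_MAX = 2.0  # C-N, angstrom
PHOSPHODIESTER_BOND_MAX = 2.2  # O3'-P, angstrom


@dataclass
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    b_factor: float = 0.0
    alt_loc: str = ""
    serial: Optional[int] = None
    formal_charge: int = 0


@dataclass
class Group:
    name: str
    group_id: int
    atoms: list[Atom] = field(default_factory=list)
    ins_code: str = ""
    sequence_index: int = -1


@dataclass
class Chain:
    chain_id: str
    chain_name: str = ""
    groups: list[Group] = field(default_factory=list)

    def __post_init__(self):
        if not self.chain_name:
            self.chain_name = self.chain_id


@dataclass
class Model:
    chains: list[Chain] = field(default_factory=list)


@dataclass
class Entity:
    type: str  # "polymer" | "non-polymer" | "water"
    description: str = ""
    sequence: str = ""
    chain_indices: list[int] = field(default_factory=list)


@dataclass
class RawStructure:
    """Parser-produced intermediate consumed by the encoder."""

    models: list[Model] = field(default_factory=list)
    entities: list[Entity] = field(default_factory=list)
    #: explicit inter-group covalent links: (global atom a, global atom b, order)
    inter_bonds: list[tuple[int, int, int]] = field(default_factory=list)
    sec_struct: Optional[list[int]] = None  # per group, 8-state codes, -1 undefined
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
    bio_assemblies: Optional[list[dict]] = None

    def iter_chains(self) -> Iterable[tuple[int, Chain]]:
        for mi, model in enumerate(self.models):
            for chain in model.chains:
                yield mi, chain

    def iter_groups(self) -> Iterable[Group]:
        for _, chain in self.iter_chains():
            yield from chain.groups

    def iter_atoms(self) -> Iterable[Atom]:
        for group in self.iter_groups():
            yield from group.atoms

    @property
    def num_models(self) -> int:
        return len(self.models)

    @property
    def num_chains(self) -> int:
        return sum(len(m.chains) for m in self.models)

    @property
    def num_groups(self) -> int:
        return sum(1 for _ in self.iter_groups())

    @property
    def num_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())


@dataclass(frozen=True)
class EncodingProfile:
    """Divisors and atom-subset rule of one output flavour."""

    name: str
    coord_divisor: int
    b_factor_divisor: int
    occupancy_divisor: int
    reduce_atoms: bool


FULL = EncodingProfile("full", 1000, 100, 100, reduce_atoms=False)
REDUCED = EncodingProfile("reduced", 10, 10, 10, reduce_atoms=True)
PROFILES = {"full": FULL, "reduced": REDUCED}


def classify_group(group: Group) -> str:
    """'peptide' | 'nucleotide' | 'water' | 'other' from name and atoms."""
    if group.name in WATER_NAMES:
        return "water"
    names = {a.name for a in group.atoms}
    if {"N", "CA", "C"} <= names:
        return "peptide"
    if "C1'" in names and ({"O3'", "O4'", "C4'"} & names):
        return "nucleotide"
    if "P" in names and ({"O3'", "O5'"} & names):
        return "nucleotide"
    return "other"


def build_group_dictionary(raw: RawStructure, templates=None):
    """Collapse group instances into unique dictionary entries.

    The identity of an entry is the group name together with the ordered
    atom name/element/charge lists, so a residue observed with a
    different atom order gets its own entry.  Intra-residue bonds and
    orders are filled from the component template when one is available;
    otherwise the bond list is empty and a warning is logged once.

    Returns
    -------
    (list of GroupType, list of per-group dictionary indices)
    """
    templates = templates or {}
    entries: list[GroupType] = []
    index_of: dict[tuple, int] = {}
    type_indices: list[int] = []
    warned: set[str] = set()
    for group in raw.iter_groups():
        names = tuple(a.name for a in group.atoms)
        elements = tuple(a.element for a in group.atoms)
        charges = tuple(a.formal_charge for a in group.atoms)
        signature = (group.name, names, elements, charges)
        idx = index_of.get(signature)
        if idx is None:
            tmpl = templates.get(group.name)
            bond_atoms: list[int] = []
            bond_orders: list[int] = []
            single_letter = "?"
            comp_type = "NON-POLYMER"
            if tmpl is not None:
                pos = {n: i for i, n in enumerate(names)}
                for (a, b), order in zip(tmpl.bond_pairs, tmpl.bond_orders):
                    if a in pos and b in pos:
                        bond_atoms.extend((pos[a], pos[b]))
                        bond_orders.append(order)
                single_letter = tmpl.one_letter_code or "?"
                comp_type = tmpl.comp_type or "NON-POLYMER"
            elif group.name not in warned:
                warned.add(group.name)
                warnings.warn(
                    f"no component template for {group.name!r}; "
                    "intra-residue bonds left empty",
                    stacklevel=2,
                )
            idx = len(entries)
            entries.append(
                GroupType(
                    group_name=group.name,
                    atom_names=list(names),
                    elements=list(elements),
                    formal_charges=list(charges),
                    intra_bond_atoms=bond_atoms,
                    intra_bond_orders=bond_orders,
                    single_letter_code=single_letter,
                    chem_comp_type=comp_type,
                )
            )
            index_of[signature] = idx
        type_indices.append(idx)
    return entries, type_indices


def _distance(a: Atom, b: Atom) -> float:
    return math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))


def attach_inter_group_bonds(
    raw: RawStructure, infer_backbone: bool = True
) -> list[tuple[int, int, int]]:
    """Explicit covalent links plus inferred backbone links, deduplicated.

    Backbone peptide (C-N) and phosphodiester (O3'-P) bonds between
    consecutive polymer groups of a chain are added when missing,
    subject to a distance sanity cap.
    """
    n_atoms = raw.num_atoms
    seen: set[frozenset] = set()
    bonds: list[tuple[int, int, int]] = []

    def add(a: int, b: int, order: int) -> None:
        key = frozenset((a, b))
        if a == b or key in seen:
            return
        seen.add(key)
        bonds.append((a, b, order))

    for a, b, order in raw.inter_bonds:
        if not (0 <= a < n_atoms) or not (0 <= b < n_atoms):
            raise IntegrityError(f"inter-group bond ({a}, {b}) references a missing atom")
        add(a, b, order)

    if infer_backbone:
        base = 0
        for _, chain in raw.iter_chains():
            offsets = []
            for group in chain.groups:
                offsets.append(base)
                base += len(group.atoms)
            for i in range(len(chain.groups) - 1):
                g1, g2 = chain.groups[i], chain.groups[i + 1]
                k1, k2 = classify_group(g1), classify_group(g2)
                if k1 == k2 == "peptide":
                    pair, cap = ("C", "N"), PEPTIDE_BOND_MAX
                elif k1 == k2 == "nucleotide":
                    pair, cap = ("O3'", "P"), PHOSPHODIESTER_BOND_MAX
                else:
                    continue
                a1 = next((a for a in g1.atoms if a.name == pair[0]), None)
                a2 = next((a for a in g2.atoms if a.name == pair[1]), None)
                if a1 is None or a2 is None or _distance(a1, a2) > cap:
                    continue
                add(
                    offsets[i] + g1.atoms.index(a1),
                    offsets[i + 1] + g2.atoms.index(a2),
                    1,
                )
    return bonds


def reduce_structure(raw: RawStructure) -> RawStructure:
    """Backbone-trace subset: CA of peptides, P of nucleotides, all
    atoms of other non-water groups; waters dropped.

    A polymer group lacking its trace atom is dropped with a warning.
    Explicit inter-group bonds that reference removed atoms are dropped;
    atom indices are remapped.  Idempotent.
    """
    new = RawStructure(
        entities=[
            Entity(e.type, e.description, e.sequence, list(e.chain_indices))
            for e in raw.entities
        ],
        structure_id=raw.structure_id,
        title=raw.title,
        deposition_date=raw.deposition_date,
        release_date=raw.release_date,
        experimental_methods=(
            list(raw.experimental_methods) if raw.experimental_methods else None
        ),
        space_group=raw.space_group,
        unit_cell=list(raw.unit_cell) if raw.unit_cell else None,
        ncs_operators=raw.ncs_operators,
        resolution=raw.resolution,
        r_free=raw.r_free,
        r_work=raw.r_work,
        bio_assemblies=raw.bio_assemblies,
    )
    index_map: dict[int, int] = {}
    old_index = 0
    new_index = 0
    kept_sec: list[int] = []
    group_cursor = 0
    chain_kept: list[bool] = []
    for mi, model in enumerate(raw.models):
        new_model = Model()
        for chain in model.chains:
            new_chain = Chain(chain.chain_id, chain.chain_name)
            for group in chain.groups:
                kind = classify_group(group)
                keep: Optional[list[Atom]]
                if kind == "water":
                    keep = None
                elif kind == "peptide":
                    trace = [a for a in group.atoms if a.name == "CA" and a.element == "C"]
                    if not trace:
                        warnings.warn(
                            f"polypeptide group {group.name} {group.group_id} has no "
                            "CA atom; dropped from reduced representation",
                            stacklevel=2,
                        )
                        keep = None
                    else:
                        keep = trace
                elif kind == "nucleotide":
                    trace = [a for a in group.atoms if a.name == "P"]
                    if not trace:
                        warnings.warn(
                            f"polynucleotide group {group.name} {group.group_id} has "
                            "no P atom; dropped from reduced representation",
                            stacklevel=2,
                        )
                        keep = None
                    else:
                        keep = trace
                else:
                    keep = list(group.atoms)
                if keep is not None:
                    kept_set = {id(a) for a in keep}
                    for a in group.atoms:
                        if id(a) in kept_set:
                            index_map[old_index] = new_index
                            new_index += 1
                        old_index += 1
                    new_chain.groups.append(
                        Group(
                            name=group.name,
                            group_id=group.group_id,
                            atoms=keep,
                            ins_code=group.ins_code,
                            sequence_index=group.sequence_index,
                        )
                    )
                    if raw.sec_struct is not None:
                        kept_sec.append(raw.sec_struct[group_cursor])
                else:
                    old_index += len(group.atoms)
                group_cursor += 1
            if new_chain.groups:
                new_model.chains.append(new_chain)
                chain_kept.append(True)
            else:
                chain_kept.append(False)
        new.models.append(new_model)

    # remap entity chain indices over surviving chains
    survivor_index = np.cumsum(chain_kept) - 1
    for entity in new.entities:
        entity.chain_indices = [
            int(survivor_index[ci]) for ci in entity.chain_indices if chain_kept[ci]
        ]
    new.entities = [e for e in new.entities if e.chain_indices or e.type != "water"]
    new.entities = [e for e in new.entities if e.chain_indices]

    new.inter_bonds = [
        (index_map[a], index_map[b], order)
        for a, b, order in raw.inter_bonds
        if a in index_map and b in index_map
    ]
    if raw.sec_struct is not None:
        new.sec_struct = kept_sec
    return new


def encode_structure(
    raw: RawStructure,
    profile: EncodingProfile = FULL,
    templates=None,
    producer: str = container.PRODUCER,
) -> MmtfDocument:
    """Encode a parsed structure into a validated document."""
    if profile.reduce_atoms:
        raw = reduce_structure(raw)

    inter = attach_inter_group_bonds(raw)
    dictionary, type_indices = build_group_dictionary(raw, templates)

    chain_ids: list[str] = []
    chain_names: list[str] = []
    chains_per_model: list[int] = []
    groups_per_chain: list[int] = []
    group_ids: list[int] = []
    ins_codes: list[str] = []
    seq_indices: list[int] = []
    xs: list[float] = []
    ys: list[float] = []
    zs: list[float] = []
    bfs: list[float] = []
    occs: list[float] = []
    alts: list[str] = []
    serials: list[int] = []
    auto_serial = 0
    for model in raw.models:
        chains_per_model.append(len(model.chains))
        for chain in model.chains:
            chain_ids.append(chain.chain_id)
            chain_names.append(chain.chain_name)
            groups_per_chain.append(len(chain.groups))
            for group in chain.groups:
                group_ids.append(group.group_id)
                ins_codes.append(group.ins_code)
                seq_indices.append(group.sequence_index)
                for atom in group.atoms:
                    auto_serial += 1
                    xs.append(atom.x)
                    ys.append(atom.y)
                    zs.append(atom.z)
                    bfs.append(atom.b_factor)
                    occs.append(atom.occupancy)
                    alts.append(atom.alt_loc)
                    serials.append(atom.serial if atom.serial is not None else auto_serial)

    n_atoms = len(xs)
    n_groups = len(group_ids)
    n_intra = sum(dictionary[t].bond_count for t in type_indices)

    bond_pairs: list[int] = []
    bond_orders: list[int] = []
    for a, b, order in inter:
        bond_pairs.extend((a, b))
        bond_orders.append(order)

    doc = MmtfDocument(
        producer=producer,
        structure_id=raw.structure_id,
        title=raw.title,
        deposition_date=raw.deposition_date,
        release_date=raw.release_date,
        experimental_methods=raw.experimental_methods,
        space_group=raw.space_group,
        unit_cell=raw.unit_cell,
        ncs_operators=raw.ncs_operators,
        resolution=raw.resolution,
        r_free=raw.r_free,
        r_work=raw.r_work,
        bio_assemblies=raw.bio_assemblies,
        entities=[
            {
                "description": e.description,
                "type": e.type,
                "sequence": e.sequence,
                "chainIndexList": list(e.chain_indices),
            }
            for e in raw.entities
        ]
        or None,
        num_models=len(raw.models),
        num_chains=len(chain_ids),
        num_groups=n_groups,
        num_atoms=n_atoms,
        num_bonds=n_intra + len(bond_orders),
        chains_per_model=chains_per_model,
        groups_per_chain=groups_per_chain,
        group_dictionary=dictionary,
        chain_ids=reg.encode_column(chain_ids, 5, 4),
        chain_names=reg.encode_column(chain_names, 5, 4),
        group_types=reg.encode_column(type_indices, 4),
        group_ids=reg.encode_column(group_ids, 8),
        ins_codes=reg.encode_column(ins_codes, 6),
        sequence_indices=reg.encode_column(seq_indices, 8),
        sec_struct=(
            reg.encode_column(raw.sec_struct, 2) if raw.sec_struct is not None else None
        ),
        x=reg.encode_column(xs, 10, profile.coord_divisor),
        y=reg.encode_column(ys, 10, profile.coord_divisor),
        z=reg.encode_column(zs, 10, profile.coord_divisor),
        b_factors=reg.encode_column(bfs, 10, profile.b_factor_divisor),
        occupancies=reg.encode_column(occs, 9, profile.occupancy_divisor),
        alt_locs=reg.encode_column(alts, 6),
        atom_ids=reg.encode_column(serials, 8),
        inter_group_bond_atoms=reg.encode_column(bond_pairs, 4),
        inter_group_bond_orders=reg.encode_column(bond_orders, 2),
    )
    violations = container.validate(doc)
    if violations:  # encoder bug if ever reached
        raise container.SchemaError(violations)
    return doc


def to_raw_structure(structure: StructureData) -> RawStructure:
    """Rebuild an editable RawStructure from decoded flat columns."""
    raw = RawStructure(
        inter_bonds=[
            (
                int(structure.inter_bond_pairs[2 * i]),
                int(structure.inter_bond_pairs[2 * i + 1]),
                int(structure.inter_bond_orders[i]),
            )
            for i in range(len(structure.inter_bond_orders))
        ],
        entities=[
            Entity(
                type=e.get("type", ""),
                description=e.get("description", ""),
                sequence=e.get("sequence", ""),
                chain_indices=list(e.get("chainIndexList", [])),
            )
            for e in structure.entities
        ],
        sec_struct=(
            [int(v) for v in structure.sec_struct]
            if np.any(np.asarray(structure.sec_struct) != -1)
            else None
        ),
        bio_assemblies=structure.bio_assemblies or None,
        **{
            k: structure.metadata.get(k)
            for k in (
                "structure_id",
                "title",
                "deposition_date",
                "release_date",
                "experimental_methods",
                "space_group",
                "unit_cell",
                "ncs_operators",
                "resolution",
                "r_free",
                "r_work",
            )
        },
    )
    s = structure
    for m in range(s.num_models):
        model = Model()
        for c in range(int(s.model_chain_offsets[m]), int(s.model_chain_offsets[m + 1])):
            chain = Chain(s.chain_ids[c], s.chain_names[c])
            for g in range(int(s.chain_group_offsets[c]), int(s.chain_group_offsets[c + 1])):
                gt = s.group_dictionary[int(s.group_types[g])]
                a_lo = int(s.group_atom_offsets[g])
                group = Group(
                    name=gt.group_name,
                    group_id=int(s.group_ids[g]),
                    ins_code=s.ins_codes[g],
                    sequence_index=int(s.sequence_indices[g]),
                )
                for k in range(gt.atom_count):
                    a = a_lo + k
                    group.atoms.append(
                        Atom(
                            name=gt.atom_names[k],
                            element=gt.elements[k],
                            x=float(s.x[a]),
                            y=float(s.y[a]),
                            z=float(s.z[a]),
                            occupancy=float(s.occupancies[a]),
                            b_factor=float(s.b_factors[a]),
                            alt_loc=s.alt_locs[a],
                            serial=int(s.atom_ids[a]) or None,
                            formal_charge=int(gt.formal_charges[k]),
                        )
                    )
                chain.groups.append(group)
            model.chains.append(chain)
        raw.models.append(model)
    return raw
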