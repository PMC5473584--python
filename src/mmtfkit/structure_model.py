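"""Decoded flat structure data with hierarchical traversal.

The consumer-facing view: every column of the document decoded into flat
arrays, plus offset tables that make model -> chain -> group -> atom
traversal cheap without materializing nested objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np

from . import codec_registry as reg
from .codec_core import CodecError
from .container import GroupType, MmtfDocument

__all__ = [
    "StructureData",
    "BondList",
    "AtomContext",
    "Visitor",
    "DecodeError",
    "IntegrityError",
    "decode_structure",
    "traverse",
    "reconstruct_bonds",
    "select_atoms",
]


class DecodeError(Exception):
    """A column failed to decode; message names the field."""


class IntegrityError(Exception):
    """Decoded data is internally inconsistent (e.g. bond index range)."""


class BondList(NamedTuple):
    """Undirected bonds: flat (2*n,) atom-index pairs plus n orders."""

    atom_pairs: np.ndarray
    orders: np.ndarray

    def __len__(self) -> int:
        return len(self.orders)


@dataclass
class StructureData:
    """All decoded columns plus derived offset tables."""

    num_models: int
    num_chains: int
    num_groups: int
    num_atoms: int
    num_bonds: int
    chains_per_model: list[int]
    groups_per_chain: list[int]
    group_dictionary: list[GroupType]
    chain_ids: list[str]
    chain_names: list[str]
    group_types: np.ndarray
    group_ids: np.ndarray
    ins_codes: list[str]
    sequence_indices: np.ndarray
    sec_struct: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    b_factors: np.ndarray
    occupancies: np.ndarray
    alt_locs: list[str]
    atom_ids: np.ndarray
    inter_bond_pairs: np.ndarray
    inter_bond_orders: np.ndarray
    entities: list[dict] = field(default_factory=list)
    bio_assemblies: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    # offset tables: first atom of each group, first group of each chain,
    # first chain of each model; each carries a trailing sentinel total.
    group_atom_offsets: np.ndarray = field(default_factory=lambda: np.zeros(1, dtype=np.int64))
    chain_group_offsets: np.ndarray = field(default_factory=lambda: np.zeros(1, dtype=np.int64))
    model_chain_offsets: np.ndarray = field(default_factory=lambda: np.zeros(1, dtype=np.int64))

    def group_of_atom(self, atom_index: int) -> int:
        return int(np.searchsorted(self.group_atom_offsets, atom_index, side="right") - 1)

    def chain_of_group(self, group_index: int) -> int:
        return int(np.searchsorted(self.chain_group_offsets, group_index, side="right") - 1)

    def model_of_chain(self, chain_index: int) -> int:
        return int(np.searchsorted(self.model_chain_offsets, chain_index, side="right") - 1)


def _decode(doc: MmtfDocument, attr: str, key: str):
    record = getattr(doc, attr)
    if record is None:
        return None
    try:
        return reg.decode_column(record)
    except CodecError as exc:
        raise DecodeError(f"field {key} failed to decode: {exc}") from exc


def decode_structure(doc: MmtfDocument) -> StructureData:
    """Decode every column of a validated document into a StructureData."""
    n_atoms, n_groups, n_chains = doc.num_atoms, doc.num_groups, doc.num_chains

    def col(attr, key, default_value, length, dtype=None):
        decoded = _decode(doc, attr, key)
        if decoded is None:
            if isinstance(default_value, str):
                return [default_value] * length
            return np.full(length, default_value, dtype=dtype)
        if dtype is not None:
            return np.asarray(decoded, dtype=dtype)
        return decoded

    group_types = np.asarray(_decode(doc, "group_types", "groupTypeList"), dtype=np.int64)
    atom_counts = np.array(
        [doc.group_dictionary[t].atom_count for t in group_types], dtype=np.int64
    )

    pairs = _decode(doc, "inter_group_bond_atoms", "bondAtomList")
    orders = _decode(doc, "inter_group_bond_orders", "bondOrderList")
    pairs = np.asarray(pairs if pairs is not None else [], dtype=np.int64)
    if orders is None:
        orders = np.ones(len(pairs) // 2, dtype=np.int64)
    else:
        orders = np.asarray(orders, dtype=np.int64)

    metadata = {
        name: getattr(doc, name)
        for name in (
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
            "format_version",
            "producer",
        )
        if getattr(doc, name) is not None
    }

    data = StructureData(
        num_models=doc.num_models,
        num_chains=n_chains,
        num_groups=n_groups,
        num_atoms=n_atoms,
        num_bonds=doc.num_bonds,
        chains_per_model=list(doc.chains_per_model),
        groups_per_chain=list(doc.groups_per_chain),
        group_dictionary=list(doc.group_dictionary),
        chain_ids=_decode(doc, "chain_ids", "chainIdList"),
        chain_names=(
            _decode(doc, "chain_names", "chainNameList") or [""] * n_chains
        ),
        group_types=group_types,
        group_ids=np.asarray(_decode(doc, "group_ids", "groupIdList"), dtype=np.int64),
        ins_codes=col("ins_codes", "insCodeList", "", n_groups),
        sequence_indices=col(
            "sequence_indices", "sequenceIndexList", -1, n_groups, np.int64
        ),
        sec_struct=col("sec_struct", "secStructList", -1, n_groups, np.int64),
        x=np.asarray(_decode(doc, "x", "xCoordList"), dtype=np.float64),
        y=np.asarray(_decode(doc, "y", "yCoordList"), dtype=np.float64),
        z=np.asarray(_decode(doc, "z", "zCoordList"), dtype=np.float64),
        b_factors=col("b_factors", "bFactorList", 0.0, n_atoms, np.float64),
        occupancies=col("occupancies", "occupancyList", 1.0, n_atoms, np.float64),
        alt_locs=col("alt_locs", "altLocList", "", n_atoms),
        atom_ids=col("atom_ids", "atomIdList", 0, n_atoms, np.int64),
        inter_bond_pairs=pairs,
        inter_bond_orders=orders,
        entities=list(doc.entities or []),
        bio_assemblies=list(doc.bio_assemblies or []),
        metadata=metadata,
    )
    data.group_atom_offsets = np.concatenate(([0], np.cumsum(atom_counts)))
    data.chain_group_offsets = np.concatenate(
        ([0], np.cumsum(np.asarray(doc.groups_per_chain, dtype=np.int64)))
    )
    data.model_chain_offsets = np.concatenate(
        ([0], np.cumsum(np.asarray(doc.chains_per_model, dtype=np.int64)))
    )
    return data


class Visitor:
    """No-op callbacks; subclass and override what you need."""

    def enter_model(self, model_index: int) -> None: ...

    def leave_model(self, model_index: int) -> None: ...

    def enter_chain(
        self, chain_index: int, chain_id: str, chain_name: str, group_count: int
    ) -> None: ...

    def leave_chain(self, chain_index: int) -> None: ...

    def enter_group(
        self, group_index: int, group_id: int, group_name: str, group_type: int
    ) -> None: ...

    def leave_group(self, group_index: int) -> None: ...

    def enter_atom(
        self,
        atom_index: int,
        name: str,
        element: str,
        x: float,
        y: float,
        z: float,
        serial: int,
    ) -> None: ...


def traverse(structure: StructureData, visitor: Visitor) -> list[tuple]:
    """Depth-first model -> chain -> group -> atom walk in file order.

    Returns the visit trace as ``(kind, index)`` tuples; the visitor
    callbacks receive the identifying fields of each level.
    """
    trace: list[tuple] = []
    s = structure
    for m in range(s.num_models):
        trace.append(("model", m))
        visitor.enter_model(m)
        for c in range(int(s.model_chain_offsets[m]), int(s.model_chain_offsets[m + 1])):
            g_lo, g_hi = int(s.chain_group_offsets[c]), int(s.chain_group_offsets[c + 1])
            trace.append(("chain", c))
            visitor.enter_chain(c, s.chain_ids[c], s.chain_names[c], g_hi - g_lo)
            for g in range(g_lo, g_hi):
                gt = s.group_dictionary[int(s.group_types[g])]
                trace.append(("group", g))
                visitor.enter_group(g, int(s.group_ids[g]), gt.group_name, int(s.group_types[g]))
                a_lo, a_hi = int(s.group_atom_offsets[g]), int(s.group_atom_offsets[g + 1])
                for a in range(a_lo, a_hi):
                    trace.append(("atom", a))
                    visitor.enter_atom(
                        a,
                        gt.atom_names[a - a_lo],
                        gt.elements[a - a_lo],
                        float(s.x[a]),
                        float(s.y[a]),
                        float(s.z[a]),
                        int(s.atom_ids[a]),
                    )
                visitor.leave_group(g)
            visitor.leave_chain(c)
        visitor.leave_model(m)
    return trace


def reconstruct_bonds(structure: StructureData) -> BondList:
    """Union of per-group-instance intra bonds and the inter-group column.

    Intra bonds come from the dictionary entry of each group instance,
    offset by the instance's first atom index.
    """
    s = structure
    pairs: list[int] = []
    orders: list[int] = []
    for g in range(s.num_groups):
        gt = s.group_dictionary[int(s.group_types[g])]
        base = int(s.group_atom_offsets[g])
        for k in range(gt.bond_count):
            pairs.append(base + gt.intra_bond_atoms[2 * k])
            pairs.append(base + gt.intra_bond_atoms[2 * k + 1])
            orders.append(gt.intra_bond_orders[k])
    pairs.extend(int(i) for i in s.inter_bond_pairs)
    orders.extend(int(o) for o in s.inter_bond_orders)
    pair_arr = np.asarray(pairs, dtype=np.int64)
    if pair_arr.size and (pair_arr.min() < 0 or pair_arr.max() >= s.num_atoms):
        raise IntegrityError("bond atom index out of range")
    half = pair_arr.reshape(-1, 2)
    if np.any(half[:, 0] == half[:, 1]):
        raise IntegrityError("self-bond in reconstructed bond list")
    bonds = BondList(pair_arr, np.asarray(orders, dtype=np.int64))
    if len(bonds) != s.num_bonds:
        raise IntegrityError(
            f"reconstructed {len(bonds)} bonds but numBonds is {s.num_bonds}"
        )
    return bonds


class AtomContext(NamedTuple):
    atom_index: int
    name: str
    element: str
    group_index: int
    group_name: str
    group_id: int
    chain_index: int
    chain_id: str
    chain_name: str
    model_index: int


def select_atoms(
    structure: StructureData, predicate: Callable[[AtomContext], bool]
) -> list[int]:
    """Ascending global indices of atoms whose context satisfies the predicate."""
    out: list[int] = []
    s = structure
    for m in range(s.num_models):
        for c in range(int(s.model_chain_offsets[m]), int(s.model_chain_offsets[m + 1])):
            for g in range(int(s.chain_group_offsets[c]), int(s.chain_group_offsets[c + 1])):
                gt = s.group_dictionary[int(s.group_types[g])]
                a_lo = int(s.group_atom_offsets[g])
                for k in range(gt.atom_count):
                    ctx = AtomContext(
                        atom_index=a_lo + k,
                        name=gt.atom_names[k],
                        element=gt.elements[k],
                        group_index=g,
                        group_name=gt.group_name,
                        group_id=int(s.group_ids[g]),
                        chain_index=c,
                        chain_id=s.chain_ids[c],
                        chain_name=s.chain_names[c],
                        model_index=m,
                    )
                    if predicate(ctx):
                        out.append(a_lo + k)
    return out
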