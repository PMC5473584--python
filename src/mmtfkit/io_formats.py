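"""Readers for the encoder's inputs: PDB, PDBx/mmCIF and component
dictionaries; plus a plain-text summary writer.

The PDB reader is a strict fixed-column parser for the
ATOM/HETATM/MODEL/ENDMDL/TER/SSBOND/CONECT subset.  The mmCIF reader
covers atom_site, struct_conn, cell, symmetry, entity and refine — the
categories the encoder consumes — and ignores everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from Bio.PDB.MMCIF2Dict import MMCIF2Dict

from ._ccd_data import BUILTIN_CCD_CIF
from .encoder_pipeline import (
    Atom,
    Chain,
    Entity,
    Group,
    Model,
    RawStructure,
    classify_group,
)
from .structure_model import StructureData

__all__ = [
    "ComponentTemplate",
    "ParseError",
    "read_pdb",
    "read_mmcif",
    "read_component_dictionary",
    "builtin_templates",
    "templates_from_dictionary",
    "write_summary",
]

_BOND_ORDER_WORDS = {"SING": 1, "DOUB": 2, "TRIP": 3, "QUAD": 4}


class ParseError(Exception):
    """Input text violates the expected format; names the line when known."""


@dataclass
class ComponentTemplate:
    """One chemical component: canonical atoms and intra-residue bonds."""

    component_id: str
    atom_names: list[str] = field(default_factory=list)
    elements: list[str] = field(default_factory=list)
    formal_charges: list[int] = field(default_factory=list)
    bond_pairs: list[tuple[str, str]] = field(default_factory=list)
    bond_orders: list[int] = field(default_factory=list)
    one_letter_code: str = "?"
    comp_type: str = "NON-POLYMER"


# ---------------------------------------------------------------------------
# shared post-parse normalization


def _assign_sequence_indices(models: list[Model]) -> None:
    """Number polymer groups 0.. within each chain; others stay -1."""
    for model in models:
        for chain in model.chains:
            counter = 0
            for group in chain.groups:
                if classify_group(group) in ("peptide", "nucleotide"):
                    group.sequence_index = counter
                    counter += 1


def _one_letter(name: str, templates) -> str:
    tmpl = templates.get(name) if templates else None
    code = tmpl.one_letter_code if tmpl else "?"
    return code if code not in ("?", "") else "X"


def _infer_entities(models: list[Model], templates=None) -> list[Entity]:
    """Heuristic entity records when the source file declares none.

    Chains with identical polymer sequences share an entity; each unique
    non-polymer group name becomes an entity; waters share one entity.
    """
    entities: list[Entity] = []
    key_to_entity: dict[tuple, int] = {}
    chain_index = 0
    for model in models:
        for chain in model.chains:
            kinds = {classify_group(g) for g in chain.groups}
            if kinds & {"peptide", "nucleotide"}:
                seq = "".join(
                    _one_letter(g.name, templates)
                    for g in chain.groups
                    if classify_group(g) in ("peptide", "nucleotide")
                )
                key = ("polymer", seq)
                etype, desc = "polymer", "polymer"
            elif kinds == {"water"}:
                key = ("water",)
                etype, desc, seq = "water", "water", ""
            else:
                name = chain.groups[0].name if chain.groups else ""
                key = ("non-polymer", name)
                etype, desc, seq = "non-polymer", name, ""
            idx = key_to_entity.get(key)
            if idx is None:
                idx = len(entities)
                entities.append(Entity(type=etype, description=desc, sequence=seq))
                key_to_entity[key] = idx
            entities[idx].chain_indices.append(chain_index)
            chain_index += 1
    return entities


def _finalize(raw: RawStructure, templates=None) -> RawStructure:
    _assign_sequence_indices(raw.models)
    if not raw.entities:
        raw.entities = _infer_entities(raw.models, templates)
    return raw


# ---------------------------------------------------------------------------
# PDB reader


_GROUP_CATEGORY = {"water": "water", "peptide": "polymer", "nucleotide": "polymer"}


def _float_field(line: str, lo: int, hi: int, lineno: int, what: str) -> float:
    text = line[lo:hi].strip()
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"line {lineno}: malformed {what} field {text!r}") from None


def _int_field(line: str, lo: int, hi: int, lineno: int, what: str) -> int:
    text = line[lo:hi].strip()
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"line {lineno}: malformed {what} field {text!r}") from None


def _element_from_name(name: str) -> str:
    stripped = name.strip("0123456789'\"")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "MN"):
        return stripped[:2].capitalize()
    return stripped[:1].upper()


def read_pdb(text: str, templates=None) -> RawStructure:
    """Parse fixed-column PDB content into a RawStructure.

    Chains split on chain-identifier changes and on category changes
    (polymer / non-polymer / water runs become separate chains).  SSBOND
    records and inter-group CONECT records become explicit bonds.
    Serials above 99999 are a parse error: the dialect is strict
    fixed-column with no hybrid extension.
    """
    models: list[Model] = []
    current = Model()
    explicit_models = False
    ssbonds: list[tuple] = []
    conects: list[tuple[int, list[int], int]] = []
    atom_records = 0

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if current.chains:
                models.append(current)
            current = Model()
            explicit_models = True
        elif rec == "ENDMDL":
            models.append(current)
            current = Model()
        elif rec in ("ATOM", "HETATM"):
            atom_records += 1
            serial_text = line[6:11].strip()
            if not serial_text.isdigit() and not (
                serial_text.startswith("-") and serial_text[1:].isdigit()
            ):
                raise ParseError(
                    f"line {lineno}: unsupported atom serial {serial_text!r} "
                    "(hybrid serials beyond 99999 are not supported)"
                )
            serial = int(serial_text)
            name = line[12:16].strip()
            alt_loc = line[16:17].strip()
            res_name = line[17:20].strip()
            chain_id = line[21:22].strip() or "A"
            res_seq = _int_field(line, 22, 26, lineno, "residue number")
            ins_code = line[26:27].strip()
            x = _float_field(line, 30, 38, lineno, "x coordinate")
            y = _float_field(line, 38, 46, lineno, "y coordinate")
            z = _float_field(line, 46, 54, lineno, "z coordinate")
            occ_text = line[54:60].strip()
            occupancy = float(occ_text) if occ_text else 1.0
            b_text = line[60:66].strip()
            b_factor = float(b_text) if b_text else 0.0
            element = line[76:78].strip() or _element_from_name(name)
            element = element.capitalize()
            atom = Atom(name, element, x, y, z, occupancy, b_factor, alt_loc, serial)
            _pdb_place_atom(current, chain_id, res_name, res_seq, ins_code, atom)
        elif rec == "SSBOND":
            ssbonds.append(
                (
                    line[15:16].strip(),
                    _int_field(line, 17, 21, lineno, "SSBOND residue number"),
                    line[21:22].strip(),
                    line[29:30].strip(),
                    _int_field(line, 31, 35, lineno, "SSBOND residue number"),
                    line[35:36].strip(),
                )
            )
        elif rec == "CONECT":
            base = _int_field(line, 6, 11, lineno, "CONECT serial")
            partners = []
            for lo in (11, 16, 21, 26):
                chunk = line[lo : lo + 5].strip()
                if chunk:
                    partners.append(int(chunk))
            conects.append((base, partners, lineno))
    if current.chains:
        models.append(current)
    if not models and not explicit_models:
        models = [Model()]

    raw = RawStructure(models=models)
    parsed_atoms = raw.num_atoms
    if parsed_atoms != atom_records:
        raise ParseError(
            f"parsed {parsed_atoms} atoms from {atom_records} atom records"
        )
    _resolve_pdb_bonds(raw, ssbonds, conects)
    return _finalize(raw, templates)


def _pdb_place_atom(model, chain_id, res_name, res_seq, ins_code, atom) -> None:
    group_key = (res_name, res_seq, ins_code)
    probe = Group(res_name, res_seq, [atom], ins_code)
    category = _GROUP_CATEGORY.get(classify_group_by_name(res_name), "non-polymer")
    chain = model.chains[-1] if model.chains else None
    if (
        chain is None
        or chain.chain_name != chain_id
        or getattr(chain, "_category", None) != category
    ):
        last = chain.groups[-1] if chain is not None and chain.groups else None
        if (
            chain is not None
            and chain.chain_name == chain_id
            and last is not None
            and (last.name, last.group_id, last.ins_code) == group_key
        ):
            # same residue continuing; never split mid-group
            last.atoms.append(atom)
            return
        chain = Chain(chain_id, chain_id)
        chain._category = category  # transient parser bookkeeping
        model.chains.append(chain)
    last = chain.groups[-1] if chain.groups else None
    if last is not None and (last.name, last.group_id, last.ins_code) == group_key:
        last.atoms.append(atom)
    else:
        chain.groups.append(Group(res_name, res_seq, [atom], ins_code))


_WATER = {"HOH", "WAT", "DOD", "H2O"}
_AMINO = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
_NUCLEIC = {"A", "C", "G", "U", "DA", "DC", "DG", "DT", "DU", "I", "DI"}


def classify_group_by_name(name: str) -> str:
    if name in _WATER:
        return "water"
    if name in _AMINO:
        return "peptide"
    if name in _NUCLEIC:
        return "nucleotide"
    return "other"


def _global_atom_tables(raw: RawStructure):
    """Per-model serial->global-index map plus residue lookup tables."""
    serial_maps: list[dict[int, int]] = []
    residue_maps: list[dict[tuple, Group]] = []
    group_base: list[dict[int, int]] = []
    index = 0
    for model in raw.models:
        serials: dict[int, int] = {}
        residues: dict[tuple, Group] = {}
        bases: dict[int, int] = {}
        for chain in model.chains:
            for group in chain.groups:
                residues[(chain.chain_name, group.group_id, group.ins_code)] = group
                bases[id(group)] = index
                for atom in group.atoms:
                    if atom.serial is not None:
                        serials[atom.serial] = index
                    index += 1
        serial_maps.append(serials)
        residue_maps.append(residues)
        group_base.append(bases)
    return serial_maps, residue_maps, group_base


def _resolve_pdb_bonds(raw, ssbonds, conects) -> None:
    serial_maps, residue_maps, group_bases = _global_atom_tables(raw)
    for model_i in range(len(raw.models)):
        residues = residue_maps[model_i]
        bases = group_bases[model_i]
        for ch1, seq1, ic1, ch2, seq2, ic2 in ssbonds:
            g1 = residues.get((ch1, seq1, ic1))
            g2 = residues.get((ch2, seq2, ic2))
            if g1 is None or g2 is None:
                continue
            try:
                i1 = next(i for i, a in enumerate(g1.atoms) if a.name == "SG")
                i2 = next(i for i, a in enumerate(g2.atoms) if a.name == "SG")
            except StopIteration:
                continue
            raw.inter_bonds.append((bases[id(g1)] + i1, bases[id(g2)] + i2, 1))
        serials = serial_maps[model_i]
        group_of_atom = {}
        for group in residues.values():
            base = bases[id(group)]
            for k in range(len(group.atoms)):
                group_of_atom[base + k] = id(group)
        for base_serial, partners, lineno in conects:
            a = serials.get(base_serial)
            if a is None:
                continue
            for p in partners:
                b = serials.get(p)
                if b is None:
                    continue
                if group_of_atom.get(a) != group_of_atom.get(b):
                    raw.inter_bonds.append((a, b, 1))


# ---------------------------------------------------------------------------
# mmCIF reader


def _cif_value(v) -> str:
    return "" if v in (".", "?", None) else str(v)


def read_mmcif(text: str, templates=None) -> RawStructure:
    """Parse PDBx/mmCIF content into a RawStructure.

    ``label_asym_id`` becomes the chain id, ``auth_asym_id`` the chain
    name; models split on ``pdbx_PDB_model_num``.  struct_conn covale
    and disulf rows become explicit inter-group bonds.
    """
    cif = MMCIF2Dict(StringIO(text))
    if "_atom_site.id" not in cif and "_atom_site.Cartn_x" not in cif:
        raise ParseError("no atom_site category in mmCIF input")

    def column(item, n, default=None):
        values = cif.get(f"_atom_site.{item}")
        if values is None:
            return [default] * n
        return values

    xs = cif["_atom_site.Cartn_x"]
    n = len(xs)
    ys = column("Cartn_y", n)
    zs = column("Cartn_z", n)
    group_pdb = column("group_PDB", n, "ATOM")
    serials = column("id", n)
    names = column("label_atom_id", n)
    alt = column("label_alt_id", n, ".")
    comp = column("label_comp_id", n)
    label_asym = column("label_asym_id", n, "A")
    auth_asym = column("auth_asym_id", n, None)
    auth_seq = column("auth_seq_id", n)
    label_seq = column("label_seq_id", n)
    ins = column("pdbx_PDB_ins_code", n, ".")
    occ = column("occupancy", n, "1.0")
    bf = column("B_iso_or_equiv", n, "0.0")
    elem = column("type_symbol", n)
    charge = column("pdbx_formal_charge", n, "?")
    model_num = column("pdbx_PDB_model_num", n, "1")

    models: list[Model] = []
    model_ids: list[str] = []
    chain = None
    group = None
    last_model = last_chain = last_group = object()
    for i in range(n):
        if model_num[i] != last_model:
            models.append(Model())
            model_ids.append(model_num[i])
            last_model = model_num[i]
            last_chain = last_group = object()
        if label_asym[i] != last_chain:
            name = _cif_value(auth_asym[i]) or _cif_value(label_asym[i])
            chain = Chain(_cif_value(label_asym[i]), name)
            models[-1].chains.append(chain)
            last_chain = label_asym[i]
            last_group = object()
        seq_text = _cif_value(auth_seq[i]) or _cif_value(label_seq[i]) or "0"
        group_key = (comp[i], seq_text, _cif_value(ins[i]))
        if group_key != last_group:
            try:
                group_id = int(seq_text)
            except ValueError:
                raise ParseError(f"atom_site row {i + 1}: bad auth_seq_id {seq_text!r}") from None
            group = Group(_cif_value(comp[i]), group_id, ins_code=_cif_value(ins[i]))
            chain.groups.append(group)
            last_group = group_key
        charge_text = _cif_value(charge[i])
        try:
            group.atoms.append(
                Atom(
                    name=_cif_value(names[i]),
                    element=_cif_value(elem[i]).capitalize()
                    or _element_from_name(_cif_value(names[i])),
                    x=float(xs[i]),
                    y=float(ys[i]),
                    z=float(zs[i]),
                    occupancy=float(_cif_value(occ[i]) or 1.0),
                    b_factor=float(_cif_value(bf[i]) or 0.0),
                    alt_loc=_cif_value(alt[i]),
                    serial=int(serials[i]) if _cif_value(serials[i]) else None,
                    formal_charge=int(charge_text) if charge_text else 0,
                )
            )
        except ValueError as exc:
            raise ParseError(f"atom_site row {i + 1}: {exc}") from None

    raw = RawStructure(models=models)
    _read_struct_conn(cif, raw)
    _read_cif_metadata(cif, raw)
    _read_cif_entities(cif, raw)
    return _finalize(raw, templates)


def _read_struct_conn(cif, raw: RawStructure) -> None:
    types = cif.get("_struct_conn.conn_type_id")
    if not types:
        return
    n = len(types)

    def col(item):
        return cif.get(f"_struct_conn.{item}", [""] * n)

    a_asym, a_seq, a_atom = col("ptnr1_label_asym_id"), col("ptnr1_auth_seq_id"), col("ptnr1_label_atom_id")
    b_asym, b_seq, b_atom = col("ptnr2_label_asym_id"), col("ptnr2_auth_seq_id"), col("ptnr2_label_atom_id")
    a_ins, b_ins = col("pdbx_ptnr1_PDB_ins_code"), col("pdbx_ptnr2_PDB_ins_code")
    orders = col("pdbx_value_order")

    # per-model lookup by (chain_id, group_id, ins_code)
    index = 0
    for model in raw.models:
        lookup: dict[tuple, tuple[Group, int]] = {}
        for chain in model.chains:
            for group in chain.groups:
                lookup[(chain.chain_id, group.group_id, group.ins_code)] = (group, index)
                index += len(group.atoms)
        for i in range(n):
            if types[i] not in ("disulf", "covale"):
                continue
            try:
                key1 = (_cif_value(a_asym[i]), int(a_seq[i]), _cif_value(a_ins[i]))
                key2 = (_cif_value(b_asym[i]), int(b_seq[i]), _cif_value(b_ins[i]))
            except (ValueError, TypeError):
                continue
            hit1, hit2 = lookup.get(key1), lookup.get(key2)
            if hit1 is None or hit2 is None:
                continue
            g1, base1 = hit1
            g2, base2 = hit2
            try:
                i1 = next(k for k, a in enumerate(g1.atoms) if a.name == _cif_value(a_atom[i]))
                i2 = next(k for k, a in enumerate(g2.atoms) if a.name == _cif_value(b_atom[i]))
            except StopIteration:
                continue
            order = _BOND_ORDER_WORDS.get(_cif_value(orders[i]).upper(), 1)
            raw.inter_bonds.append((base1 + i1, base2 + i2, order))


def _read_cif_metadata(cif, raw: RawStructure) -> None:
    def scalar(key):
        v = cif.get(key)
        if isinstance(v, list):
            v = v[0] if v else None
        v = _cif_value(v)
        return v or None

    raw.title = scalar("_struct.title")
    raw.structure_id = scalar("_entry.id")
    methods = cif.get("_exptl.method")
    if methods:
        raw.experimental_methods = [str(m) for m in methods]
    raw.space_group = scalar("_symmetry.space_group_name_H-M")
    cell = []
    for item in ("length_a", "length_b", "length_c", "angle_alpha", "angle_beta", "angle_gamma"):
        v = scalar(f"_cell.{item}")
        if v is None:
            cell = []
            break
        cell.append(float(v))
    if cell:
        raw.unit_cell = cell
    for attr, key in (
        ("resolution", "_refine.ls_d_res_high"),
        ("r_free", "_refine.ls_R_factor_R_free"),
        ("r_work", "_refine.ls_R_factor_R_work"),
    ):
        v = scalar(key)
        if v is not None:
            try:
                setattr(raw, attr, float(v))
            except ValueError:
                pass
    raw.deposition_date = scalar("_pdbx_database_status.recvd_initial_deposition_date")


def _read_cif_entities(cif, raw: RawStructure) -> None:
    asym_ids = cif.get("_struct_asym.id")
    entity_of_asym = {}
    if asym_ids:
        for asym, ent in zip(asym_ids, cif.get("_struct_asym.entity_id", [])):
            entity_of_asym[asym] = ent
    entity_ids = cif.get("_entity.id")
    if not entity_ids or not entity_of_asym:
        return
    types = cif.get("_entity.type", ["polymer"] * len(entity_ids))
    descriptions = cif.get("_entity.pdbx_description", [""] * len(entity_ids))
    sequences = {}
    for eid, seq in zip(
        cif.get("_entity_poly.entity_id", []),
        cif.get("_entity_poly.pdbx_seq_one_letter_code", []),
    ):
        sequences[eid] = "".join(str(seq).split())
    entities: dict[str, Entity] = {}
    order: list[str] = []
    chain_index = 0
    for model in raw.models:
        for chain in model.chains:
            eid = entity_of_asym.get(chain.chain_id)
            if eid is None:
                chain_index += 1
                continue
            if eid not in entities:
                k = entity_ids.index(eid)
                entities[eid] = Entity(
                    type=_cif_value(types[k]) or "polymer",
                    description=_cif_value(descriptions[k]),
                    sequence=sequences.get(eid, ""),
                )
                order.append(eid)
            entities[eid].chain_indices.append(chain_index)
            chain_index += 1
    raw.entities = [entities[eid] for eid in order]


# ---------------------------------------------------------------------------
# component dictionary


def read_component_dictionary(text: str) -> dict[str, ComponentTemplate]:
    """Parse CCD-style CIF content into templates, one per component id."""
    templates: dict[str, ComponentTemplate] = {}
    # split multi-block files; MMCIF2Dict keeps only one block's keys
    blocks = []
    current: list[str] = []
    for line in text.splitlines():
        if line.startswith("data_") and current:
            blocks.append("\n".join(current))
            current = []
        current.append(line)
    if current:
        blocks.append("\n".join(current))

    for block in blocks:
        cif = MMCIF2Dict(StringIO(block))
        comp_ids = cif.get("_chem_comp_atom.comp_id")
        if not comp_ids:
            continue
        cid = comp_ids[0]
        tmpl = ComponentTemplate(component_id=cid)
        one = cif.get("_chem_comp.one_letter_code")
        if one:
            tmpl.one_letter_code = _cif_value(one[0] if isinstance(one, list) else one) or "?"
        ctype = cif.get("_chem_comp.type")
        if ctype:
            tmpl.comp_type = _cif_value(ctype[0] if isinstance(ctype, list) else ctype) or "NON-POLYMER"
        charges = cif.get("_chem_comp_atom.charge", ["0"] * len(comp_ids))
        for name, element, q in zip(
            cif["_chem_comp_atom.atom_id"], cif["_chem_comp_atom.type_symbol"], charges
        ):
            tmpl.atom_names.append(str(name))
            tmpl.elements.append(str(element).capitalize())
            q = _cif_value(q)
            tmpl.formal_charges.append(int(q) if q else 0)
        atom_set = set(tmpl.atom_names)
        bond_a = cif.get("_chem_comp_bond.atom_id_1", [])
        bond_b = cif.get("_chem_comp_bond.atom_id_2", [])
        bond_o = cif.get("_chem_comp_bond.value_order", ["SING"] * len(bond_a))
        for a, b, order in zip(bond_a, bond_b, bond_o):
            if a not in atom_set or b not in atom_set:
                raise ParseError(
                    f"component {cid}: bond references unknown atom {a!r}/{b!r}"
                )
            tmpl.bond_pairs.append((str(a), str(b)))
            tmpl.bond_orders.append(_BOND_ORDER_WORDS.get(str(order).upper(), 1))
        templates[cid] = tmpl
    return templates


def builtin_templates() -> dict[str, ComponentTemplate]:
    """The bundled component vocabulary (amino acids, water, U, LIG)."""
    return read_component_dictionary(BUILTIN_CCD_CIF)


def templates_from_dictionary(group_dictionary) -> dict[str, ComponentTemplate]:
    """Derive templates from an existing group dictionary, so a decoded
    structure can be re-encoded without losing its intra-residue bonds."""
    out: dict[str, ComponentTemplate] = {}
    for gt in group_dictionary:
        if gt.group_name in out:
            continue
        tmpl = ComponentTemplate(
            component_id=gt.group_name,
            atom_names=list(gt.atom_names),
            elements=list(gt.elements),
            formal_charges=list(gt.formal_charges),
            one_letter_code=gt.single_letter_code,
            comp_type=gt.chem_comp_type,
        )
        for k in range(gt.bond_count):
            tmpl.bond_pairs.append(
                (
                    gt.atom_names[gt.intra_bond_atoms[2 * k]],
                    gt.atom_names[gt.intra_bond_atoms[2 * k + 1]],
                )
            )
            tmpl.bond_orders.append(gt.intra_bond_orders[k])
        out[gt.group_name] = tmpl
    return out


# ---------------------------------------------------------------------------
# summary writer


def write_summary(structure: StructureData) -> str:
    """Human-readable report of counts, metadata and per-chain layout."""
    s = structure
    lines = []
    sid = s.metadata.get("structure_id")
    if sid:
        lines.append(f"structure: {sid}")
    title = s.metadata.get("title")
    if title:
        lines.append(f"title: {title}")
    for key in ("resolution", "space_group", "r_free", "r_work"):
        if key in s.metadata:
            lines.append(f"{key.replace('_', ' ')}: {s.metadata[key]}")
    lines.append(f"models: {s.num_models}")
    lines.append(f"chains: {s.num_chains}")
    lines.append(f"groups: {s.num_groups}")
    lines.append(f"atoms: {s.num_atoms}")
    lines.append(f"bonds: {s.num_bonds}")
    for m in range(s.num_models):
        lines.append(f"model {m}:")
        for c in range(int(s.model_chain_offsets[m]), int(s.model_chain_offsets[m + 1])):
            n_groups = int(s.chain_group_offsets[c + 1] - s.chain_group_offsets[c])
            lines.append(
                f"  chain {s.chain_ids[c]} ({s.chain_names[c]}): {n_groups} groups"
            )
    return "\n".join(lines) + "\n"
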