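"""Deterministic synthetic structures for exercising every code path.

Structures have no physical realism beyond the statistical shape that
matters for the codecs: successive-atom coordinate steps near bond scale
(so delta + recursive indexing stays one element per value) with an
optional heavy tail that forces multi-element continuation groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder_pipeline import Atom, Chain, Group, Model, RawStructure
from .io_formats import builtin_templates

__all__ = [
    "FixtureSpec",
    "make_structure",
    "make_worked_example_columns",
    "write_pdb",
    "write_mmcif",
]

#: residue vocabulary available to the generator; resolved against the
#: bundled component dictionary.
DEFAULT_RESIDUES = ("GLY", "ALA", "SER")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_models: int = 1
    chains_per_model: int = 1
    residues_per_chain: int = 5
    residue_names: tuple[str, ...] = DEFAULT_RESIDUES
    n_ligands: int = 0
    n_waters: int = 0
    step_scale: float = 1.5
    heavy_tail: bool = False
    occupancy_pattern: str = "constant"  # "constant" | "mixed"
    b_factor_scale: float = 0.5


_CHAIN_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


class _Walk:
    """Coordinate random walk on the 0.001 A grid."""

    def __init__(self, rng: np.random.Generator, step: float, heavy_tail: bool):
        self.rng = rng
        self.step = step
        self.heavy_tail = heavy_tail
        self.pos = np.zeros(3)

    def jump(self, scale: float) -> tuple[float, float, float]:
        direction = self.rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        self.pos = self.pos + direction * scale
        snapped = np.round(self.pos, 3)
        return tuple(float(v) for v in snapped)

    def next_atom(self) -> tuple[float, float, float]:
        return self.jump(self.step * float(self.rng.uniform(0.8, 1.2)))

    def break_chain(self) -> None:
        # separate unrelated molecules; occasionally far enough to need
        # multi-element recursive-index groups
        scale = 40.0 if self.heavy_tail else 5.0
        self.jump(scale)


def make_structure(spec: FixtureSpec) -> RawStructure:
    """Build a reproducible RawStructure from a fixture spec."""
    rng = np.random.default_rng(spec.seed)
    templates = builtin_templates()
    walk = _Walk(rng, spec.step_scale, spec.heavy_tail)
    raw = RawStructure()
    serial = 0
    group_counter = 0

    def b_factor() -> float:
        return round(float(abs(rng.normal(10.0, spec.b_factor_scale * 10))) % 99.0, 2)

    def occupancy(i: int) -> float:
        if spec.occupancy_pattern == "constant":
            return 1.0
        return 1.0 if i % 3 else 0.5

    for _ in range(spec.n_models):
        model = Model()
        chain_cursor = 0
        serial = 0
        for _ in range(spec.chains_per_model):
            chain = Chain(_CHAIN_LETTERS[chain_cursor % len(_CHAIN_LETTERS)])
            chain_cursor += 1
            walk.break_chain()
            for r in range(spec.residues_per_chain):
                name = spec.residue_names[int(rng.integers(len(spec.residue_names)))]
                tmpl = templates[name]
                if spec.heavy_tail and r and rng.uniform() < 0.2:
                    walk.break_chain()
                group = Group(name, r + 1)
                for atom_i, (aname, elem) in enumerate(
                    zip(tmpl.atom_names, tmpl.elements)
                ):
                    serial += 1
                    x, y, z = walk.next_atom()
                    group.atoms.append(
                        Atom(
                            aname,
                            elem,
                            x,
                            y,
                            z,
                            occupancy=occupancy(group_counter * 16 + atom_i),
                            b_factor=b_factor(),
                            serial=serial,
                            formal_charge=tmpl.formal_charges[atom_i],
                        )
                    )
                chain.groups.append(group)
                group_counter += 1
            model.chains.append(chain)
        for _ in range(spec.n_ligands):
            chain = Chain(_CHAIN_LETTERS[chain_cursor % len(_CHAIN_LETTERS)])
            chain_cursor += 1
            walk.break_chain()
            tmpl = templates["LIG"]
            group = Group("LIG", 1)
            for atom_i, (aname, elem) in enumerate(zip(tmpl.atom_names, tmpl.elements)):
                serial += 1
                x, y, z = walk.next_atom()
                group.atoms.append(
                    Atom(aname, elem, x, y, z, b_factor=b_factor(), serial=serial)
                )
            chain.groups.append(group)
            group_counter += 1
            model.chains.append(chain)
        if spec.n_waters:
            chain = Chain(_CHAIN_LETTERS[chain_cursor % len(_CHAIN_LETTERS)])
            chain_cursor += 1
            for w in range(spec.n_waters):
                walk.break_chain()
                serial += 1
                x, y, z = walk.next_atom()
                chain.groups.append(
                    Group("HOH", w + 1, [Atom("O", "O", x, y, z, b_factor=b_factor(), serial=serial)])
                )
                group_counter += 1
            model.chains.append(chain)
        raw.models.append(model)
    # sequence indices and entities are assigned the same way the file
    # readers do, so generator output and parsed fixtures are comparable
    from .io_formats import _assign_sequence_indices, _infer_entities

    _assign_sequence_indices(raw.models)
    raw.entities = _infer_entities(raw.models, templates)
    return raw


def make_worked_example_columns() -> dict[str, np.ndarray]:
    """The three canonical worked example columns.

    - ``occupancy``: 2,000 values of 1.0
    - ``serial``: 1 .. 2000
    - ``coordinate``: a stream whose x1000 integer deltas begin
      32,867, 2,001, 1,053 (the first delta is the first value)
    """
    deltas = np.array([32867, 2001, 1053], dtype=np.int64)
    return {
        "occupancy": np.ones(2000, dtype=np.float64),
        "serial": np.arange(1, 2001, dtype=np.int64),
        "coordinate": np.cumsum(deltas) / 1000.0,
    }


# ---------------------------------------------------------------------------
# plain-text emitters used to exercise the file readers


def _pdb_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3}"
    return f"{name:<4}"


def write_pdb(raw: RawStructure) -> str:
    """Emit fixed-column PDB text for a synthetic structure."""
    from .io_formats import classify_group_by_name

    lines: list[str] = []
    multi = len(raw.models) > 1
    for mi, model in enumerate(raw.models):
        if multi:
            lines.append(f"MODEL     {mi + 1:>4}")
        for chain in model.chains:
            polymer = any(
                classify_group_by_name(g.name) in ("peptide", "nucleotide")
                for g in chain.groups
            )
            for group in chain.groups:
                record = "ATOM  " if classify_group_by_name(group.name) in ("peptide", "nucleotide") else "HETATM"
                for atom in group.atoms:
                    lines.append(
                        f"{record}{atom.serial:>5} {_pdb_atom_name(atom.name, atom.element)}"
                        f"{atom.alt_loc or ' '}{group.name:>3} {chain.chain_name[:1]}"
                        f"{group.group_id:>4}{group.ins_code or ' '}   "
                        f"{atom.x:>8.3f}{atom.y:>8.3f}{atom.z:>8.3f}"
                        f"{atom.occupancy:>6.2f}{atom.b_factor:>6.2f}"
                        f"          {atom.element.upper():>2}"
                    )
            if polymer:
                lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_mmcif(raw: RawStructure) -> str:
    """Emit minimal mmCIF text (atom_site only) for a synthetic structure."""
    from .io_formats import classify_group_by_name

    lines = [
        "data_synthetic",
        "loop_",
        "_atom_site.group_PDB",
        "_atom_site.id",
        "_atom_site.label_atom_id",
        "_atom_site.label_alt_id",
        "_atom_site.label_comp_id",
        "_atom_site.label_asym_id",
        "_atom_site.auth_asym_id",
        "_atom_site.auth_seq_id",
        "_atom_site.pdbx_PDB_ins_code",
        "_atom_site.Cartn_x",
        "_atom_site.Cartn_y",
        "_atom_site.Cartn_z",
        "_atom_site.occupancy",
        "_atom_site.B_iso_or_equiv",
        "_atom_site.type_symbol",
        "_atom_site.pdbx_formal_charge",
        "_atom_site.pdbx_PDB_model_num",
    ]
    for mi, model in enumerate(raw.models):
        for chain in model.chains:
            for group in chain.groups:
                record = (
                    "ATOM"
                    if classify_group_by_name(group.name) in ("peptide", "nucleotide")
                    else "HETATM"
                )
                for atom in group.atoms:
                    name = f'"{atom.name}"' if "'" in atom.name else atom.name
                    lines.append(
                        " ".join(
                            [
                                record,
                                str(atom.serial),
                                name,
                                atom.alt_loc or ".",
                                group.name,
                                chain.chain_id,
                                chain.chain_name,
                                str(group.group_id),
                                group.ins_code or ".",
                                f"{atom.x:.3f}",
                                f"{atom.y:.3f}",
                                f"{atom.z:.3f}",
                                f"{atom.occupancy:.2f}",
                                f"{atom.b_factor:.2f}",
                                atom.element.upper(),
                                str(atom.formal_charge),
                                str(mi + 1),
                            ]
                        )
                    )
    return "\n".join(lines) + "\n"
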