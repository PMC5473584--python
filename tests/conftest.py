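import pytest

from mmtfkit.encoder_pipeline import Atom, Chain, Group, Model, RawStructure
from mmtfkit.io_formats import builtin_templates
from mmtfkit.synthetic import FixtureSpec, make_structure


@pytest.fixture(scope="session")
def templates():
    return builtin_templates()


def make_peptide(residues=("GLY", "ALA", "SER"), chain_id="A", templates=None):
    """Hand-built peptide with backbone geometry: consecutive C-N ~1.33 A."""
    templates = templates or builtin_templates()
    chain = Chain(chain_id)
    x = 0.0
    serial = 0
    for i, name in enumerate(residues):
        tmpl = templates[name]
        group = Group(name, i + 1, sequence_index=i)
        for k, (aname, elem) in enumerate(zip(tmpl.atom_names, tmpl.elements)):
            serial += 1
            # N, CA, C spaced ~1.4 A along x; sidechain atoms offset in y
            if aname in ("N", "CA", "C"):
                pos = (x + 1.4 * ("N", "CA", "C").index(aname), 0.0, 0.0)
            else:
                pos = (x + 1.0 + 0.5 * k, 1.5, 0.0)
            group.atoms.append(Atom(aname, elem, *pos, serial=serial))
        chain.groups.append(group)
        x += 4.1  # next N at C + 1.3 A
    return RawStructure(models=[Model(chains=[chain])])


@pytest.fixture
def peptide3(templates):
    return make_peptide(("GLY", "ALA", "SER"), templates=templates)


@pytest.fixture
def small_fixture():
    return make_structure(
        FixtureSpec(
            seed=11,
            n_models=2,
            chains_per_model=2,
            residues_per_chain=4,
            n_ligands=1,
            n_waters=3,
        )
    )


@pytest.fixture
def minimal_fixture():
    return make_structure(
        FixtureSpec(seed=5, n_models=1, chains_per_model=1, residues_per_chain=1)
    )
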