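"""Built-in chemical component templates (CIF text).

A small vocabulary sufficient for the synthetic structures used in tests
and for converting simple peptide/nucleotide/ligand files without an
external dictionary: three amino acids, water, one nucleotide and a
12-atom organic ligand.  Heavy atoms only.
"""

BUILTIN_CCD_CIF = """\
data_GLY
_chem_comp.id GLY
_chem_comp.type "PEPTIDE LINKING"
_chem_comp.one_letter_code G
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
_chem_comp_atom.charge
GLY N  N 0
GLY CA C 0
GLY C  C 0
GLY O  O 0
loop_
_chem_comp_bond.comp_id
_chem_comp_bond.atom_id_1
_chem_comp_bond.atom_id_2
_chem_comp_bond.value_order
GLY N  CA SING
GLY CA C  SING
GLY C  O  DOUB
data_ALA
_chem_comp.id ALA
_chem_comp.type "L-PEPTIDE LINKING"
_chem_comp.one_letter_code A
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
_chem_comp_atom.charge
ALA N  N 0
ALA CA C 0
ALA C  C 0
ALA O  O 0
ALA CB C 0
loop_
_chem_comp_bond.comp_id
_chem_comp_bond.atom_id_1
_chem_comp_bond.atom_id_2
_chem_comp_bond.value_order
ALA N  CA SING
ALA CA C  SING
ALA C  O  DOUB
ALA CA CB SING
data_SER
_chem_comp.id SER
_chem_comp.type "L-PEPTIDE LINKING"
_chem_comp.one_letter_code S
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
_chem_comp_atom.charge
SER N  N 0
SER CA C 0
SER C  C 0
SER O  O 0
SER CB C 0
SER OG O 0
loop_
_chem_comp_bond.comp_id
_chem_comp_bond.atom_id_1
_chem_comp_bond.atom_id_2
_chem_comp_bond.value_order
SER N  CA SING
SER CA C  SING
SER C  O  DOUB
SER CA CB SING
SER CB OG SING
data_CYS
_chem_comp.id CYS
_chem_comp.type "L-PEPTIDE LINKING"
_chem_comp.one_letter_code C
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
_chem_comp_atom.charge
CYS N  N 0
CYS CA C 0
CYS C  C 0
CYS O  O 0
CYS CB C 0
CYS SG S 0
loop_
_chem_comp_bond.comp_id
_chem_comp_bond.atom_id_1
_chem_comp_bond.atom_id_2
_chem_comp_bond.value_order
CYS N  CA SING
CYS CA C  SING
CYS C  O  DOUB
CYS CA CB SING
CYS CB SG SING
data_HOH
_chem_comp.id HOH
_chem_comp.type NON-POLYMER
_chem_comp.one_letter_code ?
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
_chem_comp_atom.charge
HOH O O 0
data_U
_chem_comp.id U
_chem_comp.type "RNA LINKING"
_chem_comp.one_letter_code U
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
_chem_comp_atom.charge
U P     P 0
U OP1   O 0
U OP2   O 0
U "O5'" O 0
U "C5'" C 0
U "C4'" C 0
U "O4'" O 0
U "C3'" C 0
U "O3'" O 0
U "C2'" C 0
U "O2'" O 0
U "C1'" C 0
U N1    N 0
U C2    C 0
U O2    O 0
U N3    N 0
U C4    C 0
U O4    O 0
U C5    C 0
U C6    C 0
loop_
_chem_comp_bond.comp_id
_chem_comp_bond.atom_id_1
_chem_comp_bond.atom_id_2
_chem_comp_bond.value_order
U P     OP1   DOUB
U P     OP2   SING
U P     "O5'" SING
U "O5'" "C5'" SING
U "C5'" "C4'" SING
U "C4'" "O4'" SING
U "C4'" "C3'" SING
U "C3'" "O3'" SING
U "C3'" "C2'" SING
U "C2'" "O2'" SING
U "C2'" "C1'" SING
U "C1'" "O4'" SING
U "C1'" N1    SING
U N1    C2    SING
U C2    O2    DOUB
U C2    N3    SING
U N3    C4    SING
U C4    O4    DOUB
U C4    C5    SING
U C5    C6    DOUB
U C6    N1    SING
data_LIG
_chem_comp.id LIG
_chem_comp.type NON-POLYMER
_chem_comp.one_letter_code ?
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
_chem_comp_atom.charge
LIG C1  C 0
LIG C2  C 0
LIG C3  C 0
LIG C4  C 0
LIG C5  C 0
LIG C6  C 0
LIG C7  C 0
LIG O1  O 0
LIG N1  N 0
LIG C8  C 0
LIG C9  C 0
LIG C10 C 0
loop_
_chem_comp_bond.comp_id
_chem_comp_bond.atom_id_1
_chem_comp_bond.atom_id_2
_chem_comp_bond.value_order
LIG C1 C2  DOUB
LIG C2 C3  SING
LIG C3 C4  DOUB
LIG C4 C5  SING
LIG C5 C6  DOUB
LIG C6 C1  SING
LIG C1 C7  SING
LIG C7 O1  DOUB
LIG C7 N1  SING
LIG N1 C8  SING
LIG C8 C9  SING
LIG C9 C10 SING
"""
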