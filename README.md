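# mmtfkit

Encoder/decoder library and command-line tool for the MacroMolecular
Transmission Format (MMTF): a compressed, binary, columnar representation
of macromolecular structures stored in a MessagePack container, with a
lossless **full** profile (all atoms, 0.001 Å coordinate / 0.01 B-factor
precision) and a lossy **reduced** profile (C-alpha / P backbone trace plus
non-polymer atoms, 0.1 precision).

## What's inside

| module | purpose |
| --- | --- |
| `mmtfkit.codec_core` | primitive transforms: fixed-point integer encoding, delta, run-length, recursive indexing (16- and 8-bit), and exact inverses |
| `mmtfkit.codec_registry` | the 15-strategy codec table, 12-byte big-endian record headers, byte-exact pack/unpack |
| `mmtfkit.container` | document schema, MessagePack (de)serialization, gzip wrapping, validation, semantic-version checks |
| `mmtfkit.structure_model` | decoded flat columns + offset tables, Models→Chains→Groups→Atoms traversal, bond reconstruction, atom selection |
| `mmtfkit.encoder_pipeline` | group-dictionary building, bond attachment (explicit + inferred backbone), reduced-profile subsetting, end-to-end encoding |
| `mmtfkit.io_formats` | fixed-column PDB reader, PDBx/mmCIF reader, chemical-component dictionary reader, text summary writer |
| `mmtfkit.synthetic` | deterministic synthetic-structure generator and PDB/mmCIF text emitters used by the test suite |
| `mmtfkit.cli` | `mmtfkit` command: convert / validate / traverse / fetch |

## CLI

```sh
# PDB or mmCIF (or MMTF) in, MMTF out; profile full|reduced
mmtfkit convert input.cif -o out.mmtf --profile full --gzip

# schema validation + full decode
mmtfkit validate out.mmtf

# print the model/chain hierarchy, or a full count report
mmtfkit traverse out.mmtf
mmtfkit traverse --summary out.mmtf

# download one entry (network required; never used by the test suite)
mmtfkit fetch 4CUP --base-url https://mmtf.rcsb.org/v1.0/full
```

`convert` is deterministic: the same input and profile produce
byte-identical output (fixed producer string, no timestamps).  Errors are
written to stderr with the greppable prefix `mmtfkit-error:` and a
non-zero exit status.

## Library example

```python
from mmtfkit import read_file, decode_structure, traverse, Visitor

structure = decode_structure(read_file("out.mmtf"))

class Printer(Visitor):
    def enter_chain(self, index, chain_id, chain_name, group_count):
        print(chain_id, chain_name, group_count)

traverse(structure, Printer())
```

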