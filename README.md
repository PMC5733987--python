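# protchar

In-silico characterization of proteins: composition-based physicochemistry,
sliding-window sequence profiles, motif scanning, antigenicity, and
structure-based analyses (lysine glycation geometry, simplified
secondary-structure assignment, interface contacts, pose hydrogen bonds) —
with a deterministic synthetic-fixture generator so the whole pipeline is
testable offline.

## Modules

| module | what it does |
|---|---|
| `protchar.core_seq` | validated one-letter sequences, composition tables, FASTA I/O |
| `protchar.param_tables` | checksummed store of every vendored constant (masses, Bjellqvist pKa, Kyte–Doolittle, Guruprasad DIWV, Kolaskar–Tongaonkar, N-end rule) |
| `protchar.physchem` | MW, pI (bisection of the Henderson–Hasselbalch net charge), charge tallies, GRAVY, aliphatic index, instability index, half-life lookup |
| `protchar.profiles` | sliding-window profiles (no edge padding) and ranked extrema |
| `protchar.motifs` | N-glycosylation sequon (N-X-S/T, X≠P) and RHGXRXP…HD catalytic-motif scanners |
| `protchar.antigenicity` | window-7 antigenic propensity, protein mean, determinant extraction |
| `protchar.structure_io` | minimal strict-column PDB reader/writer, PDBQT read-only, atom selection |
| `protchar.glycation` | per-lysine NZ→acid/base minimum distances, <10 Å classification, cross-method agreement |
| `protchar.secondary_structure` | Kabsch–Sander H-bond energies, 3-state H/E/C assignment |
| `protchar.interactions` | inter-chain interface residues, receptor–ligand hydrogen-bond enumeration |
| `protchar.synthetic_data` | seeded sequences with exact composition, ideal-geometry toy structures, bundled printed-table fixtures |
| `protchar.cli` | the `characterize` command chaining all stages |

## CLI

```sh
characterize --fasta protein.fasta --out reports/
characterize --composition comp.tsv --nterm A --out reports/
characterize --fasta protein.fasta --pdb model.pdb --chain A \
             --ligand pose.pdbqt --out reports/
```

Reports are written as TSV (rounded to printed precision) with JSON twins
(full precision), plus a `run_log.json` recording all parameters. Cutoffs,
window sizes and the profile scale are flags or a `key=value` config file;
defaults: window 9, glycation 10 Å, contacts 4.0 Å, H-bonds 3.5 Å / 120°.

## Data files

`src/protchar/data/params/` holds the vendored constant tables and
`src/protchar/data/fixtures/` the transcribed printed tables, each with a
`MANIFEST.sha256` verified at load time. Fixture transcriptions keep the
printed values verbatim; the one arithmetic-forced correction (a molecular
weight typo) is kept as a separate overlay column.
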