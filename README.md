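# glycotopo

Tools for mapping O- and N-glycosylation sites onto membrane-protein topology
and re-validating the calls against 3D structures.

The pipeline has five stages:

1. **Tabular I/O** (`glycotopo.io_annotations`) — glycosylation-site tables
   (GlyGen-export shape), topology-segment tables (UniProt transmembrane
   annotation shape), per-residue predictor profiles, and classification
   outputs. All coordinates are 1-based with inclusive range ends.
2. **Topology mapping** (`glycotopo.topology_mapping`) — classify each site as
   `in_tm` (inside a TM helix/strand, inclusive boundaries), `interface`
   (within a window *w* of a TM segment, default 3), `extramembrane`, or
   `annotation_mismatch` (the site's own listed domain does not contain it).
3. **Structural validation** (`glycotopo.structure_validation`) — PDB/mmCIF
   parsing (via biotite), membrane-slab residue location (OPM/PDBTM-style
   plane sidecars), signal-peptide numbering remaps, covalent-glycan detection
   (anomeric C1 within 2.0 Å of Asn ND2 / Ser OG / Thr OG1), side-chain
   orientation relative to a TM bundle, pLDDT-style confidence filtering
   (strictly > 70 over a region), and combined per-site verdicts.
4. **Consensus** (`glycotopo.consensus_topology`) — per-residue membrane votes
   across predictor profiles, with optional reference vote and strand-blind
   predictor handling.
5. **Reporting** (`glycotopo.report`) — headline counts (sites, proteins,
   multiplicity histogram, structure triage, interface strata) and
   deterministic TSV/JSON reports.

`glycotopo.synthetic_data` generates seeded fixtures with planted ground
truth for every stage: annotation sets with known labels, and ideal-helix TM
bundles (1.5 Å rise, 100°/residue, 2.3 Å CA radius) with planted glycans,
side-chain orientations, and numbering offsets.

The package ships transcriptions of the source study's site tables under
`src/glycotopo/fixtures/` (`table1_sites.tsv`, `table2_interface_O.tsv`,
`table3_interface_N.tsv`, and a derived `topology.tsv`); use
`glycotopo.fixture_path(name)` or `glycotopo fixtures` to locate them.

## CLI

```sh
# classify sites against topology annotations
glycotopo map --sites src/glycotopo/fixtures/table1_sites.tsv \
              --topology src/glycotopo/fixtures/topology.tsv \
              --window 3 --out classified.tsv

# generate synthetic fixtures with ground truth
glycotopo simulate --preset bundle --seed 1 --out-dir fixtures/

# re-validate classified sites against a structure + membrane planes
glycotopo validate --structure fixtures/bundle.pdb --slab fixtures/slab.yaml \
                   --sites classified.tsv --signal-peptide 1:18 --out verdicts.tsv

# aggregate into summary reports
glycotopo report --classified classified.tsv --out report/
```

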