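# pilusmech

Analysis toolkit for type IVa pilus filaments: helical filament construction
and descriptors, subunit-interface buried-area and salt-bridge analysis,
worm-like-chain persistence-length estimation from 2D filament traces, AFM
force–distance nanospring/plateau analysis, and a large-scale major-pilin
sequence survey. Every analysis stage is paired with a deterministic,
seeded synthetic-data generator so the whole pipeline is testable offline.

## Modules

| Module | What it does |
| --- | --- |
| `pilusmech.structure_core` | PDB/mmCIF reading, PDB writing, van der Waals radius assignment, rigid transforms |
| `pilusmech.helix_builder` | (twist, rise) → descriptors (subunits/turn, pitch, subunits/µm); filament construction from one asymmetric unit; radial profiles |
| `pilusmech.interface_analysis` | Shrake–Rupley SASA (deterministic Fibonacci point set), buried interface area per neighbor offset N:N-k (halved PISA-style convention plus the unhalved difference), salt bridges, φ/ψ helix segmentation |
| `pilusmech.filament_mechanics` | 2D worm-like-chain persistence length by tangent-correlation and mean-squared end-to-end estimators, with bootstrap CIs |
| `pilusmech.afm_fd` | Baseline correction and classification of retraction force–distance curves (nanospring / plateau / both / none); spring constant, rupture and plateau forces |
| `pilusmech.pilin_survey` | Class III signal-peptide (G\|F-x-x-x-E) detection and cleavage, mature-length size classes (≥166 aa = large), >90%-identity redundancy filtering, per-taxon statistics, N-terminal consensus |
| `pilusmech.synthetic_data` | Seeded generators: toy helical subunit, 2D-equilibrium WLC traces, labeled force–distance curves, prepilin FASTA sets with planted motifs and taxonomy |
| `pilusmech.cli` | `pilusmech` command-line interface |

## CLI

```bash
# helical descriptors + n-subunit filament from a single subunit (axis on z)
pilusmech build-filament --in subunit.pdb --twist 100.7 --rise 10.0 \
    --range -9:9 --out filament.pdb

# buried interface areas per neighbor offset, salt bridges, totals
pilusmech interfaces --in subunit.pdb --twist 100.7 --rise 10.0 \
    --max-offset 9 --points 960 --out interfaces.json

# persistence length from 2D traces (TSV blocks: "# id", x_nm <tab> y_nm)
pilusmech persistence --traces traces.tsv --ds 10 --mode 2d --out pl.json

# AFM force-distance signatures (directory of 2-column TSVs)
pilusmech afm --curves curves/ --speed 1.0 --out signatures.tsv

# sequence survey (FASTA + taxonomy sidecar, or a combined XLSX/TSV table)
pilusmech survey --fasta prepilins.faa --tax tax.tsv --large 166 \
    --identity 0.90 --out survey/

# synthetic inputs with ground-truth sidecars
pilusmech simulate --kind wlc_traces --seed 1 --param lp_um=21 --out traces.tsv

# all-synthetic end-to-end smoke run
pilusmech demo --seed 0 --out demo_report.json
```

## Conventions

- Filament axis is z; right-handed helices advance +z with positive
  rotation. Author residue numbering is authoritative throughout.
- Buried interface area is the halved difference
  (SASA(A)+SASA(B)−SASA(AB))/2; the unhalved value is reported alongside.
- 2D-equilibrated traces decay as ⟨cos θ(s)⟩ = exp(−s/2Lp); a `3d` mode
  (decay exp(−s/Lp)) exists for projected data.
- Forces are tension-positive pN; distances nm; persistence lengths µm;
  areas Å².
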