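# triadscan

Analysis pipeline for **self-assembled catalytic peptides**: short peptides
with protease/esterase-like activity gain catalytic power when fused to an
amyloidogenic fragment and assembled into β-sheet fibrils.  The package
covers the three computational legs of that story:

1. **Idealized structure building** — all-atom models of peptide chains from
   backbone internal coordinates (NeRF), stacked into three-strand
   antiparallel amyloid β-sheets ((φ, ψ) = (−135°, 135°), 5 Å inter-strand
   spacing along X, alternate strands rotated 180° about X) with a catalytic
   peptide fused onto each N-terminus.  The model system is the fusion
   CP4–Aβ = `SMESLSKTHHYR` + `FFKLVFF`, plus its alanine mutants and the
   amidated-C-terminus variant (a 12-entry activity panel).
2. **Catalytic triad occupancy** — a conformation is *hydrolysis-competent*
   when a hydroxyl oxygen (Ser OG / Thr OG1), a histidine imidazole nitrogen
   (ND1/NE2) and a carboxylate oxygen (Glu/Asp side chain or the free
   C-terminus) lie mutually within a 5 Å cutoff.  Over a conformational
   ensemble (multi-model PDB, 20 ps frame spacing) the package reports
   per-identity occupancy fractions, the any-triad series, and the
   most-frequent triad.
3. **Esterase kinetics** — *p*-nitrophenyl acetate hydrolysis followed by
   absorbance at 400 nm: reference (turbidity) subtraction, Beer–Lambert
   conversion with ε(*p*-NP) = 15600 M⁻¹cm⁻¹, initial-rate (OLS over the
   first 120 s) or 1200 s-endpoint activity, normalization by the no-peptide
   control, and the normalized-fold panel table.

Because neither the original MD trajectories nor the raw absorbance curves
are distributable, a first-class synthetic-data module generates both inputs
with known ground truth (planted triads at controlled occupancy; calibrated
burst-phase absorbance traces), making every stage testable offline.  See
`docs/methods.md` for the models, parameters and their limits.

## Worked example

```bash
triadscan run --out out/ --seed 2
```

builds the CP4–Aβ sheet, generates a 400-frame jittered ensemble with the
dominant cross-chain triad planted at 60 % occupancy, analyzes the second
half of the trajectory, and reduces the kinetics panel.  It prints:

```
top triad: A/S1-A/H10-B/F19ct (occupancy 0.570)
panel folds: assembled 7.76, monomer 1.89
reports written to out/
```

Reading: the most frequent competent triad joins Ser1 and His10 of one chain
with the C-terminal carboxylate of Phe19 on the *adjacent* chain — the
intermolecular active site the sheet geometry creates — with an occupancy of
0.570 over the production window (the planted 0.6 minus Bernoulli sampling
noise).  The assembled construct hydrolyzes the ester 7.76-fold faster than
background (noisy realization of the designed 7.7), the non-assembled
monomer 1.89-fold, i.e. assembly buys a ~4-fold enhancement.  `out/`
contains `occupancy.csv`, `any_triad.csv`, `panel.csv` and
`provenance.json`; re-running with the same seed reproduces them
byte-for-byte.

The same stages are available as a library
(`build_construct_model`, `plant_triad`, `occupancy`, `rank_triads`,
`analyze_trace`, `panel_report`, …) and as the subcommands
`triadscan build | synth | detect | kinetics | run`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the noiseless calibrated fixture panel, pushes every trace
through the full kinetics analysis, and reports the recovered headline
quantities (fold activity of the assembled and monomeric constructs, and the
leupeptin-inhibited assembly as a percentage of the uninhibited one) as
JSON.
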