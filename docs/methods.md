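# Methods

## 1. Idealized structure construction

Chains are built from internal coordinates with the natural extension
reference frame (NeRF): each atom is placed from the previous three by a
bond length, bond angle and torsion.  Backbone geometry uses standard
literature values (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å,
C–OXT 1.249 Å; τ(N–Cα–C) = 111.0°, Cα–C–N = 116.2°, C–N–Cα = 121.7°;
ω = 180° unless overridden).  Any self-consistent standard set would do —
all downstream checks measure angles and offsets, not absolute coordinates —
so these values are fixed once and audited by the bond-table test
(every placed bond within 0.01 Å).

Side chains are reduced to the atoms the triad detector needs: CB on all
non-Gly residues (improper torsion C–N–Cα–CB = −120°, the L-configuration,
validated against chemical-component-dictionary templates), hydroxyl oxygens
of Ser/Thr, the full imidazole ring of His, and the carboxylates of Glu/Asp,
with bond lengths/angles taken from CCD averages and one idealized rotamer
per residue type.  No rotamer sampling, no energetics: torsional relaxation
is deliberately out of scope, and the geometric criterion below is the only
consumer of these atoms.

**Sheet assembly.**  The amyloid core strand (`FFKLVFF`) is built at
(φ, ψ) = (−135°, 135°), aligned with its Cα principal axis on +Z, and
stacked along X at 5 Å spacing.  Flipped strands are rotated 180° about the
X-axis ((x, y, z) → (x, −y, −z)), reversing the N→C direction.  The default
flip pattern alternates (strand 2 of 3 flipped) so *every* adjacent pair is
antiparallel; the literal "two of three flipped" variant
(`SheetSpec.literal_two_of_three()`) is available but leaves one parallel
pair, which is why alternation is the default.  "Rotated along the X-axis"
is read as rotation *about* X; with strands on Z and stacking on X this is
the only reading that produces an antiparallel sheet.

**N-terminal fusion.**  The catalytic dodecamer (`SMESLSKTHHYR`) is grown
N-terminally onto each assembled strand by reverse NeRF, continuing the
extended (−135°, 135°) conformation through the fusion segment and the
junction φ (both overridable).  Residues are renumbered 1–19 from the fused
N-terminus.  Free C-termini carry OXT; amidation removes it (and with it the
C-terminal acid function).

## 2. Triad criterion and occupancy

Candidate atoms: hydroxyl O = Ser OG, Thr OG1; imidazole N = His ND1, NE2;
acid O = Glu OE1/OE2, Asp OD1/OD2, plus O and OXT of the last residue of
chains with a free C-terminus.  A triad *identity* is a residue-level triple
(hydroxyl residue, His residue, acid residue-or-C-terminus); it is competent
in a frame when **any** atom-level combination satisfies the distance
criterion — this prevents double-counting chemically equivalent oxygens or
the two ring nitrogens.

The criterion applies the 5 Å cutoff to **all three** pairwise distances by
default (`pair_mode="all"`, the strictest reading of "within a cutoff of
each other"); `pair_mode="bridge"` relaxes the hydroxyl–acid pair, keeping
the His-mediated pairs only, since the source geometry definition does not
state which pairs were measured.  Intra-chain and cross-chain triads are
both allowed (`chain_mode` restricts either way).

Detection uses a k-d tree over the candidate atoms per frame; a pure-Python
O(n³) triple loop serves as the test oracle, never the implementation.
Occupancy is the fraction of analysis-window frames in which an identity is
competent; the window is a half-open time interval, defaulting to the second
half of the trajectory (mirroring an equilibration/production split).
Ranking sorts by occupancy, ties broken lexicographically by identity label
for determinism.  An ensemble with no competent triads yields an explicit
empty ranking, not an error.

## 3. Synthetic ensembles

Real MD is replaced by Gaussian positional jitter: σ = 0.3 Å per coordinate
(a modest thermal wiggle, small enough not to flip contacts at bond scale),
20 ps frame spacing, seeded `numpy` Generator.  The planted-triad generator
makes one chosen identity competent in a Bernoulli(p) subset of frames by
placing its three designated atoms on an equilateral triangle of side
0.8 × cutoff (competent) or a collinear arrangement at 1.4 × cutoff spacing
(incompetent), on a staging site offset beyond the model bounding box.
Designated atoms are placed exactly (not jittered), so with the 0.2/0.4
guard bands the frame labels are provably noise-proof and the analyzer must
recover the realized Bernoulli fraction *exactly* — parameter-recovery
tolerances then reduce to binomial sampling error only.

What this emulates: controlled occupancy statistics over a fixed topology.
What it does not: correlated motions, realistic side-chain dynamics, solvent,
or any physically meaningful triad geometry beyond the distance criterion.
A green recovery test establishes that the detector and occupancy
bookkeeping are correct, not that the real ensemble would show any
particular occupancy.

## 4. Kinetics model and fixture calibration

Synthetic traces follow a burst-plus-linear product model
P(t) = A₀(1 − e^(−k_b t)) + (v_ss + v_bg)·t — the burst shape of
acyl-intermediate hydrolases — observed as
A(t) = ε·l·P(t) + ramp·t + noise, with an independently-noised reference
channel carrying the same turbidity ramp (physically separate cuvettes).
This functional form is the package's synthetic stand-in, not a mechanistic
claim.  Defaults (duration 1800 s, Δt 5 s, background 2×10⁻⁸ M/s, noise
5×10⁻⁴ AU per channel) are chosen to resemble a bench-top UV/Vis esterase
assay; with these values the initial-rate standard error is ≈1–3 % of the
control rate, which is why noisy fold recovery is tested at a 10 % band.

Analysis defaults: the initial rate is the OLS slope of concentration over
the **first 120 s** (falling back to the first 10 points if under-sampled);
the exact window is not dictated by the source, so it is fixed here and the
fixtures are calibrated against the same window.  Negative corrected
absorbances are clipped to zero for concentration reporting but retained for
slope fitting (Beer–Lambert domain vs unbiased estimation).  One construct
(the collagen-mimetic fusion, panel 4) is scored by the product
concentration at 1200 s instead; its control is the same no-peptide trace
reduced by the same endpoint rule.

**Calibration.**  Each fixture stores a designed fold; the generator solves
for the steady rate v_ss such that the documented analysis recovers that
fold exactly on a noiseless trace (subtracting the closed-form OLS slope of
the burst term over the sampled window, or its endpoint contribution).  The
assembled constructs' designed folds encode the measured panel: 7.7
(assembly), 1.9 (monomer), 0.24 × 7.7 (leupeptin-inhibited).  Mutant folds
(panel 5–11) are qualitative placeholders chosen only to preserve the
ordering "S1, S6, H10 and the C-terminus are essential; S4, H9, E3 are not",
and are excluded from numeric acceptance.  The panel table reports each fold
and its percentage of the reference construct (panel 2), under which the
inhibited entry reads as 24 %; the alternative reading (percent of the
no-peptide standard) is available by changing `reference_panel_id`.

## 5. Numerical notes and limitations

* Torsions use the IUPAC sign convention, reported in (−180°, 180°]; the
  NeRF placement and the torsion measurement are mutually consistent to
  <10⁻¹³ degrees, so round-trip tolerances (10⁻³°) are dominated by nothing.
* Sheet assembly is rigid-motion only; intra-strand geometry is preserved to
  float64 rounding (<10⁻⁹ Å over tens of Å).
* PDB I/O goes through biotite with a pre-scan enforcing the supported
  dialect: congruent MODEL atom counts (the error names the offending
  MODEL), no altlocs, no insertion codes.  Coordinates survive a round trip
  to the format's 10⁻³ Å precision.
* The His ring is traced by sequential placement with ring-internal angles;
  its closure bond is emergent (≈0.01 Å residual) and intentionally not part
  of the audited bond table.
* Degenerate inputs are rejected loudly: empty windows, n_strands < 1,
  no-op mutations, zero control rates, traces not spanning the endpoint.
* Everything is seeded; pipelines re-run byte-identically from
  (config, seed).  Derived sub-seeds stay below 2³¹.
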