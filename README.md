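# porescribe

Quantitative characterisation of large oligomeric membrane pores formed by
pore-forming antimicrobial peptides, built around the TMcin bacteriocin of
*Staphylococcus aureus* as the reference system.

Pore-forming peptides are usually studied through a chain of small,
scattered computations: peptide mass from an ESI charge-state ladder,
hydrophobicity and transmembrane-helix calls from the sequence, stepwise
single-pore conductances from voltage-clamped planar-bilayer recordings,
ion selectivity from reversal potentials under a salt gradient, pore size
from conductance, barrel geometry from oligomer stoichiometry, and
stoichiometry itself from structure-predictor confidence scans.
`porescribe` packages that whole chain as tested, seedable library code
with a thin CLI, plus synthetic generators that emulate each raw input so
every stage can be exercised without instrument data.

## The quantitative core

* **Charge-state deconvolution.** For each ESI peak with charge *i*,
  *M*<sub>*i*</sub> = (*m/z*<sub>*i*</sub> − 1.007)·*i*; the reported mass
  is the arithmetic mean across charge states with the sample
  (*n*−1) standard deviation. Peptide masses are monoisotopic residue sums
  plus one water, minus 2 H per disulfide bond.
* **Step detection.** Insertion events are persistent upward current jumps.
  A two-window moving-mean difference statistic flags candidates above a
  threshold (default 6× the robust, MAD-based noise SD), merges candidates
  within a dead time, and measures each amplitude from the flanking plateau
  means; conductance is *G* = Δ*I*/*V* (pA/mV = nS).
* **Selectivity.** Per-level ordinary-least-squares I/V fits give the slope
  conductance and the reversal potential Ψ_rev (the voltage-axis intercept).
  The single-salt Goldman–Hodgkin–Katz equation
  Ψ_rev = (RT/F)·ln[(P_K[K]ₜ + P_Cl[Cl]꜀)/(P_K[K]꜀ + P_Cl[Cl]ₜ)]
  is inverted exactly for P_K/P_Cl; |Ψ_rev| ≤ 2 mV is called non-selective.
* **Pore geometry.** The access-resistance-corrected cylinder (Hille) model
  *G* = σ·[*l*/(π*r*²) + 1/(2*r*)]⁻¹ links conductance to radius, with a
  closed-form quadratic inverse. β-barrel backbone radius follows the
  polygon chord relation *R* = *d*/(2 sin(π/*n*ₛ))/cos α for *n*ₛ strands.
  Permeant sizes use Stokes–Einstein radii *r* = k_BT/(6πη*D*).
* **Model ranking.** Multimer stoichiometries are ranked by the standard
  predictor confidence score 0.8·ipTM + 0.2·pTM (ties to the lower *n*),
  with a two-round scan report (broad scan, template-seeded rescan,
  improvement flag).

## Worked example

```python
import porescribe as ps

rec = ps.PeptideRecord.tmcin_g1905()        # mature 52-mer, Cys25-Cys50
mass = ps.monoisotopic_mass(rec)
frac = ps.hydrophobic_fraction(rec)
prof = ps.hydropathy_profile(rec, window=19)

cfg = ps.TraceSimConfig(seed=3)             # synthetic bilayer recording
raw, truth = ps.simulate_trace(cfg)
events = ps.detect_steps(ps.bessel_lowpass(raw))
stats = ps.event_statistics(events, bin_width_nS=2.0)

r = ps.radius_from_conductance(10.8, length_nm=5.0, conductivity_S_per_m=1.66)
```

prints, with the values above:

```text
monoisotopic mass: 5839.08 Da  (5.8 kDa)
hydrophobic residues: 34/52 = 65.4% (~65%)
TMH span (window 19, threshold 1.6): (1, 29)
simulated insertions: 12, detected: 12, median step conductance: 10.2 nS
pore radius for a 10.8 nS step: 5.23 nm
21-mer beta-barrel backbone radius: 3.21 nm
```

The 5.8 kDa mass and 65% hydrophobicity identify the mature peptide; the
detector recovers every simulated insertion and the ~10 nS step scale maps,
through the cylinder model, to a pore radius of ~5 nm — large enough to
pass dextran-scale polymers (Stokes–Einstein radii ≈ 4–5 nm), consistent
with a wide β-barrel whose 21-protomer backbone ring is ~3.2 nm in radius
before side chains and strand tilt.

The same operations are available from the shell, e.g.

```sh
porescribe peptide-mass --sequence AWFVV... --disulfide 25:50
porescribe simulate-trace --seed 3 --out trace.csv
porescribe detect-steps --trace trace.csv
porescribe analyze-iv --iv iv.csv --salt 150:730
porescribe pore-size --g 10.8 --length 5 --sigma 1.66
```

Every CLI run emits a JSON provenance block (version, config, seed, input
hashes).

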