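# Methods

This note records the models behind `porescribe`, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions the implementation commits to.

## Peptide mass and deconvolution

Monoisotopic peptide mass is the sum of standard residue monoisotopic
masses plus one water (18.010565 Da), minus two hydrogen atoms
(2 × 1.0078250 Da) per disulfide bond. Residue masses come from the
pyteomics table. The reference peptide is the mature 52-residue TMcin-G1905
sequence with a single Cys25–Cys50 disulfide; its mass evaluates to
5839.08 Da (5.8 kDa at one-decimal rounding, half-up).

ESI deconvolution follows the quadrupole protocol exactly:
M_i = (m/z_i − m_p)·i per peak, arithmetic mean across peaks, and the
sample standard deviation with divisor n−1 (the protocol divides by 3 for
four charge states; we generalise to n−1 for arbitrary peak sets). The
proton mass defaults to the protocol's printed constant 1.007 Da ("paper
mode") so worked examples reproduce digit-for-digit; a "physical mode"
value of 1.00728 Da is available. A single peak has no defined sample SD
and is reported as such rather than zero.

## Hydrophobicity and the transmembrane helix

No universal definition of "hydrophobic residue" exists. The default set
{A, F, G, I, L, M, V, W} is a documented choice: on the mature sequence it
counts 34/52 = 65.4%, the conventional two-thirds figure for this peptide
family; the set is a parameter everywhere, never a silent constant (the
alternative {A, C, F, I, L, M, V, W}, swapping G for C, gives 61.5%).

Hydropathy profiles use the Kyte–Doolittle scale with a sliding-window
mean. Window 19 and threshold 1.6 are the classical single-TMH screening
convention; both are exposed. The TMH call takes the longest run of window
centers at or above threshold, expanded to full window extent, with ties
broken toward the N-terminus. On the reference sequence the maximal window
centers on residue 12, inside the Trp2/Trp24 flank of the predicted helix.
The Eisenberg hydrophobic moment |Σ h_k·e^{ikδ}|/N (δ = 100° helix, 180°
strand) quantifies amphipathicity of the C-terminal hairpin.

## Trace model and step detection

The synthetic recording model: pore insertions arrive as a homogeneous
Poisson process (default 1/3 events/s over 60 s, ≈20 events per record);
each insertion adds a persistent conductance drawn i.i.d. from a lognormal
with median 10.8 nS (the observed median step size in 150 mM KCl) and shape
σ = 0.35, giving the broad right-tailed amplitude histogram such recordings
show; current is V·ΣG_k plus white Gaussian noise (default 10 pA SD at
5 kHz sampling, 50 mV holding). With these defaults the smallest plausible
step (~5 nS → 250 pA) has SNR ≥ 5, the regime for which the detector's
acceptance properties are stated. Pores never close by default — total
conductance increases monotonically, matching the persistent-pore
phenotype; a flicker option exists for robustness exercises only and is off
in all acceptance runs.

What the generator does **not** emulate: 1/f and capacitance noise of the
recording chain, baseline drift, concentration-dependent insertion
kinetics, sub-conductance states, and gating. Passing tests therefore
demonstrate correctness of the analysis chain under the stated statistical
model, not robustness to every artefact of real recordings.

Filtering applies a digital 8-pole Bessel low-pass at 1 kHz
(magnitude-normalised: −3 dB at the cutoff), forward-only with the DC
group delay compensated by an integer sample shift, so step edges stay at
their true times without the squared response a forward–backward pass
would give. The 15 kHz hardware anti-alias filter of a typical rig is
treated as already applied upstream.

Step detection uses a two-window moving-mean difference: d[k] =
mean(x[k..k+w)) − mean(x[k−w..k)). Contiguous regions with |d| ≥ min_step
yield one candidate each (the |d| peak); candidates within the dead time
(default 20 ms) merge keeping the largest. Amplitudes are differences of
flanking plateau means excluding a guard of w/4 samples around the edge so
the filter-smeared transition does not bias them; when two insertions merge
the measured amplitude spans both, which preserves total-conductance
conservation. Only upward steps count by default (insertions; the pores are
persistent). min_step defaults to 6× the robust noise SD (1.4826 × MAD of
first differences / √2), floored at 10⁻⁶ pA so noiseless traces remain
analysable. This detector was chosen over an interactive or
changepoint-penalty approach for transparency and testability; a penalised
changepoint variant could sit behind the same contract.

Event statistics use half-open lower-inclusive bins [k·w, (k+1)·w) and the
lower-interpolation median (the lower of the two middle order statistics
for even n). The seal check regresses segment-mean current on the test
voltages of an equal-duration step protocol; the default pass threshold of
10⁻⁵ nS (0.01 pS) mirrors the conventional printed figure but is
physically surprising for a bilayer seal (0.01 nS would be typical), so it
is a configuration value, not a constant the analysis relies on.

## Selectivity

I/V fits are ordinary least squares of current on voltage per conductance
level; Ψ_rev is the voltage-axis intercept −b/G, undefined (and flagged)
at zero slope. The GHK voltage equation for a single 1:1 salt uses nominal
concentrations (no activity coefficients — the bath compositions are
reported as molarities; an activity option would change |Ψ| by ~1 mV at
these strengths and is out of scope), temperature 298.15 K by default, and
CODATA R and F. The default gradient is 150 mM cis / 730 mM trans KCl.
The inversion P_K/P_Cl = (e·[trans] − [cis])/([trans] − e·[cis]), with
e = exp(Ψ F/RT), is exact and rejects reversals at or beyond the Nernst
limits (±40.66 mV for this gradient at 298.15 K). "Non-selective" is
operationalised as |Ψ_rev| ≤ 2 mV, roughly the resolution of bilayer
reversal measurements.

## Pore geometry

The access-resistance-corrected cylinder is the canonical minimal model for
a wide, short pore: R_total = l/(σπr²) + 1/(2σr), the second term being the
two-sided hemispherical access resistance. Defaults: pore length 5 nm (a
typical bilayer span) and σ = 1.66 S/m for 150 mM KCl at 25 °C; both are
parameters, since neither is measured by the recordings themselves. At
r = 5 nm, l ∈ [4, 6] nm and σ ∈ [1.5, 1.8] S/m the model predicts
G ∈ [8.5, 12] nS, bracketing the observed 10.8 nS median; the closed-form
inverse maps 10.8 nS to r = 5.23 nm. These are mutual consistency checks —
conductance-derived and structure-derived pore sizes are independent
routes — not equalities.

Barrel geometry places the n_s = n_protomers × strands_per_protomer strands
at the vertices of a regular polygon of side d (default 4.8 Å, the
β-sheet interstrand spacing), so the backbone circumradius is
d/(2 sin(π/n_s)), widened by 1/cos α for strand tilt α (default 0°, since
the hairpins of this family run nearly parallel to the pore axis). The
lumen diameter subtracts a configurable 0.25 nm side-chain wall allowance.
A 21-protomer, 42-strand barrel gives a 3.21 nm backbone radius. This
idealised formula complements, rather than reproduces, neural-network
structure models. Permeation is a hard size-exclusion predicate on
Stokes–Einstein radii (r = k_BT/6πηD, water viscosity 8.9×10⁻⁴ Pa·s at
298.15 K); partitioning and hindered-diffusion corrections are out of
scope.

## Model ranking

Stoichiometry scans are ranked by 0.8·ipTM + 0.2·pTM, the standard overall
confidence for multimer predictions; the predictor itself is never run —
only its metric tables are consumed. Ties break toward the lower
stoichiometry (parsimony; a tie carries no evidence for the larger
assembly). pLDDT bands use the community cutpoints low ≤ 50 <
moderate ≤ 70 < confident < 90 ≤ very-high; the "confident" band is the
open interval (70, 90), matching the strict inequalities in which that
range is conventionally quoted. The two-round report records the round-1
winner, whether round 2 revisits it, the final winner by round-2 scores and
whether the best score improved; stoichiometries outside a declared
round-2 range raise warnings, not errors, since published range statements
are sometimes internally inconsistent.

The synthetic metrics generator produces a single Gaussian bump in ipTM
(pTM riding 0.05 above it) centred on a chosen peak stoichiometry. Note
that recovery of the peak under score noise improves as the bump gets
*narrower* — a sharp peak separates neighbouring scores beyond the noise —
so the noisy-recovery test uses width 2 (recovering the peak in ≥ 90% of
seeds at noise SD 0.02), while the noiseless recovery sweep holds for any
width.

## Assays

Liposome-leakage fluorescence is normalised on the two-point scale
100·(F_sample − F_buffer)/(F_Triton − F_buffer): detergent lysis defines
100%, buffer 0%. Values outside [0, 100] (quenching, scatter) are returned
unclipped with a flag so artefacts stay visible. The normalisation is
invariant under any common gain/offset.

## Problem sizes

The default test and acceptance workloads are sized for a laptop-class
single core: 20 synthetic recordings of 60 s at 5 kHz for detector
characterisation, 100 seeds for reversal-potential recovery, 1000 masses
for deconvolution round trips, 1000 seeds for the Poisson event-count
check. All generators are pure functions of (config, seed).

## Known limitations

- The step detector assumes persistent, well-separated steps; bursts
  closer than the dead time merge (amplitude is conserved, counts are not).
- Real event-calling in interactive electrophysiology software involves
  operator judgment; counts and medians from real recordings are
  consistency references for this pipeline, not exact targets.
- The GHK treatment is restricted to one 1:1 salt (K⁺/Cl⁻); multi-ion
  mixtures, surface potentials and voltage-dependent permeabilities are
  out of scope.
- The cylinder and polygon-barrel models ignore lumen profile,
  electrostatics and side-chain packing; they bracket scales, they do not
  replace structure-based pore profiling.
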