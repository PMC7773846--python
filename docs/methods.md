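# Methods

## The model

`metadhs` studies ligand unbinding from a coarse-grained model of one
DHS binding site. The site is a cylindrical tunnel of 25 residue
clusters (axis = z, length 14 Å, lining-cluster ring radius 4.0 Å) built
in two variants that share every conserved position bead-for-bead and
differ only at the 10 substituted positions. Each residue is a cluster
of heavy beads (counts equal to amino-acid heavy-atom numbers, mean ≈ 8
beads/residue) jittered deterministically about the cluster centre; a
radial clearance rule keeps the lining out of the cavity. The ligand is
a 9-bead chain (guanidinium bead +1 e at the −z end, amine bead +1 e at
the +z end, bond length 1.3 Å, 1–2 bonds of 800 kJ/mol/Å² plus 1–3
pseudo-bonds that keep it semi-rigid). A restrained neutral 6-bead
cluster next to the guanidino end stands in for the NAD cofactor.

Variant differences, all at named positions:

* human-like: anchors D243 (amine end), D316 and E323 (guanidino end)
  carry −1 e with radial reaches 3.85/4.4/5.0 Å; gate A at the +z mouth
  holds E136 (−1 e, reach 4.0 Å) and E137 (−1 e, second shell, 9.0 Å);
  gate B at the −z mouth holds E180 (−1 e, reach 3.0 Å); N292 has an
  h-bond-like LJ well (ε = 1.0 kJ/mol).
* archaeal-like: T200, L272 and H96 are uncharged; D95 keeps −1 e but
  sits 1.5 Å further out (shorter sidechain reach); W248 has its LJ
  radius inflated ×1.5 (steric bulk) and no h-bond well; E141 and the
  E323 analog (E279) are conserved. Production temperature is 348 K
  versus 300 K for the human-like variant.

Eight invented basic lining positions (+1 e each, reach 5.5 Å, placed
z-symmetrically) keep the pocket near electroneutral (net +2 e
human-like, +5 e archaeal-like once three acidic positions are lost).
Without them the −6 e pocket exerts a screened Coulomb tail that makes
the 11 Å exit uphill by tens of kJ/mol everywhere along the path, which
no 0.2 kJ/mol hill schedule can fill at desk scale; with them the exit
landscape is a localised bound well plus two gated mouths. This is the
single most important design choice in the package.

## Force field and dynamics

Terms: harmonic bonds; Lennard-Jones 12-6 with Lorentz–Berthelot
combination (base well depth ε = 0.05 kJ/mol, σ = 3.2 Å); Debye-screened
Coulomb with relative dielectric 20 and screening length 8 Å (implicit
solvent); harmonic positional restraints tethering pocket beads
(20 kJ/mol/Å²) and the scaffold (50 kJ/mol/Å²) to the native geometry;
two repulsive Gaussian ridges on the ligand COM z (heights 6.0 and
8.1 kJ/mol at z = ±5.5 Å, width 1.5 Å) defining exit channels A and B;
and confinement — a stiff harmonic wall at a 30 Å sphere plus a soft
cylindrical wall (radius 4 Å, 10 kJ/mol/Å², smoothly switched off past
the mouths) that keeps exits axial rather than letting the ligand slip
between lining clusters. Nonbonded interactions couple the ligand to
everything else; the restrained lining beads are mutually
non-interacting, so their fluctuations are exactly the analytic
tethered-bead values (RMSF = √(3k_BT/k)) and the model stays cheap.

Dynamics is BAOAB-splitting Langevin, dt = 10 fs, friction 0.25 ps⁻¹,
integrated in numba kernels seeded per replica (numpy SeedSequence →
one integer stream each; identical seeds give bit-identical
trajectories). Friction 0.25 ps⁻¹ rather than a solvent-like 1 ps⁻¹ is
deliberate: at 1 ps⁻¹ the ligand's diffusion constant makes the ~11 Å
exit diffusion-limited (~4 ns) and the variant contrast is hidden behind
that common floor; at 0.25 ps⁻¹ unbinding is barrier-limited, which is
the regime the comparison is about. Equilibration mirrors a multistage
protocol: 2,000 steps of steepest descent, then five 20-ps Langevin
stages with extra ligand restraints of 20, 5, 2, 1 and 0.5 kJ/mol/Å²
(the classic 2000→500→200→100→50 kJ/mol/nm² ladder, unit-converted).
Unbiased production defaults to 2,000 ps.

## Collective variable and metadynamics

The contacts CV sums the rational switching function
s(r) = (1−(r/r0)⁶)/(1−(r/r0)¹²) over all ligand-bead × site-bead pairs
(9 × ~200 pairs; bead-level granularity is what reaches the ~650
native-contact scale). `calibrate_switching` bisects r0 in [3, 7] Å
until the native pose scores 650 ± 50 contacts; with the default
geometry it converges near r0 = 5.5 Å and the CV first drops below 200
contacts when the ligand is rigidly displaced ≈12 Å along the exit axis
(`validate_geometry` asserts d* ∈ [9, 13] Å and names the axial-spread
parameter to adjust otherwise).

Metadynamics is standard (not well-tempered): Gaussian hills of height
0.2 kJ/mol and width 2.0 contacts deposited every 2 ps at 300 K for both
variants, summed exactly (no grid). A replica stops once the CV falls
below an analysis floor of 150 contacts (or at max_time = 2,000 ps,
entering the statistics censored); its residence time is the first
crossing below 200 contacts, so the stored traces support re-evaluating
residence at thresholds {150, 200, 250} without re-simulation. The
Tiwary-style acceleration factor is computed from the accumulated bias
and logged per replica for information only — residence times are
reported in biased simulation time. max_time is a fixed default rather
than an adaptive pilot multiple so campaigns are single-pass and
deterministic.

## Path classification

Within the exit window (last frame with CV ≥ 0.9 × native down to the
first frame below 200), a replica is path A when its cumulative contact
time (< 4.5 Å) with the gate-A beads exceeds that with the gate-B beads
by ≥ 2×, path B for the converse, undetermined otherwise; an
intermediate state is flagged when the amine/gate-A-anion distance stays
below 4.0 Å for ≥ 5 consecutive ps. The dwell-ratio constants are
configuration keys. With the ridge heights 6.0/8.1 kJ/mol and
near-symmetric channel electrostatics, the Boltzmann two-channel
prediction 1/(1+e^(−ΔΔG/k_BT)) ≈ 0.70 matches the human-like campaign's
channel-A fraction. Gate-residue and anchor placement (E137 in a distant second shell, E180
reach 3.0 Å, guanidino anchors at 4.4/5.0 Å) was chosen so the two
channels' barrier tops differ mainly by the ridges; this geometric
design calibration was iterated against pilot campaigns and then frozen.

## Statistics

Residence campaigns are compared with a two-sided Mann–Whitney U test —
exact enumeration when both samples have ≤ 12 uncensored values and no
ties, otherwise the normal approximation with continuity and tie
correction — with Welch's t reported alongside for transparency.
Censored replicas are excluded from the rank test but reported.
Confidence intervals on campaign means are BCa bootstrap (B = 10,000);
the plain percentile interval was measured at 92.3% coverage on
exponential samples of size 30 and replaced, BCa measures ≈ 94%.

## What the toy does and does not show

The generator emulates the *comparative* structure of the real problem:
the contact-count scale (~650 native, < 200 unbound, ~11 Å COM drift at
release), the anchor chemistry that differentiates the variants, the
two gated exit channels, the 30-replica campaign design and the two
production temperatures. Passing tests therefore demonstrate that the
pipeline — CV calibration, biased dynamics, residence statistics, path
classification — behaves correctly and that the encoded pocket
differences are sufficient to reproduce the directional claims
(human-like residence ≫ archaeal-like, ~70% channel-A exits, threshold
insensitivity). They do not validate all-atom energetics: absolute
residence times are in toy picoseconds, solvent and protein flexibility
are reduced to implicit screening and harmonic tethers, and free
energies are not transferable to the real enzymes.

Known limitations:

* The archaeal-like variant exits predominantly through channel B in
  this model, whereas the original comparison reports ~70% path A for
  both enzymes. Removing the gate-A charges (D95 displaced, H96
  neutral) while keeping the conserved E141 at gate B tips the archaeal
  channel preference toward the preformed tunnel; capturing the
  loop-opening mechanics behind the archaeal path-A exits would need
  flexible gates, which the restrained scaffold does not model. Only
  the human-like split is a quantitative target.
* One binding site is modelled; the dimer's second site is represented
  by running the same site with different seeds (the sites are
  symmetric).
* The reported p-values concern toy campaigns; they inherit the toy's
  idealisations (independent replicas, shared equilibrated start with
  independent thermal noise).

## Problem sizes and determinism

Default campaign sizes: 30 metadynamics replicas per variant
(~5–8 minutes total on one CPU), 5 × 2,000 ps unbiased productions per
variant for the stability/RMSF analyses, and a 0.1 Å-resolution rigid
scan for geometry validation. Every stochastic stage takes an explicit
seed; campaign replica seeds derive from a master seed via numpy
SeedSequence, so results are reproducible and independent of execution
order.
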