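# metadhs

Coarse-grained metadynamics analysis of inhibitor unbinding from the
deoxyhypusine synthase (DHS) binding pocket, comparing a **human-like**
and an **archaeal-like** (thermophile) variant of the site.

## The scientific problem

DHS catalyses the first step of hypusination, the post-translational
modification that activates translation factor 5A. Its strongest
inhibitor, GC7 (N1-guanyl-1,7-diaminoheptane), is a doubly charged
linear spermidine analog that binds in a narrow tunnel at a dimer
interface, pinned by acidic anchor residues at both termini (Asp243 at
the amine end; Asp316 and Glu323 at the guanidino end in the human
enzyme). In the thermophilic archaeal enzyme 10 of the 25 binding-site
positions differ (60% site identity); critically, Asp243→Thr200 and
Asp316→Leu272 remove two anchoring salt bridges, Glu136/Glu137→Asp95/His96
weaken one channel mouth, and Asn292→Trp248 trades an h-bond network for
steric bulk. The package quantifies how these substitutions change the
inhibitor's residence time and its unbinding routes.

Because the original comparison rests on hundreds of nanoseconds of
all-atom simulation, `metadhs` re-creates the *statistical and energetic
structure* of the problem at desk scale: a bead model of one binding
tunnel (228 beads: 25 residue clusters, a 9-bead +2e ligand, a
restrained NAD-like scaffold), an implicit-solvent force field
(Lennard-Jones + Debye-screened Coulomb), BAOAB Langevin dynamics, and a
from-scratch metadynamics engine. Everything is deterministic per seed.

## The method

The collective variable is a smooth contact count over all ligand-bead ×
site-bead pairs,

    CV = Σ_pairs s(r),   s(r) = (1 − (r/r0)^6) / (1 − (r/r0)^12),

with `r0` calibrated by bisection so the native pose scores ≈650
contacts. Metadynamics deposits Gaussian hills on this CV (height
0.2 kJ/mol, width 2.0 contacts, every 2 ps, at 300 K for both variants);
a replica's **residence time** is the biased simulation time until the
CV first drops below 200 contacts, at which point the ligand COM has
moved ≈11 Å from the native pose. Campaigns of 30 independently seeded
replicas per variant are compared with a two-sided Mann–Whitney U test
(BCa bootstrap CIs on the means). Exits are classified **path A**
(through the gate formed by the E136/E137 analogs, via a transient
amine salt-bridge intermediate) or **path B** (the preformed tunnel past
the E180 analog) from gate-contact dwell times; the two channels carry
repulsive Gaussian ridges of 6.0 and 8.1 kJ/mol, which at 300 K sets an
A:B preference of ≈70:30.

## Worked example

```bash
python examples/03_metad_campaign.py
```

prints (6 replicas per variant; a few minutes on one CPU):

```
human-like: residence times (ps) = [1666, 810, 1152, 1588, 1708, 1242]
archaeal-like: residence times (ps) = [512, 130, 162, 188, 284, 330]

Mann-Whitney U = 36, two-sided p = 0.0022, longer residence: human-like
human-like exit paths: {'A': 50.0, 'B': 50.0, 'undetermined': 0.0}
mean COM displacement at unbinding: 11.2 Å
```

The inhibitor resides significantly longer in the human-like pocket and
unbinding is complete once the centre of mass has drifted ≈11 Å. At
this demonstration size the path split is coarse (3 A / 3 B); the full
30-replica campaign recovers the ≈70:30 channel preference. The other
examples build and calibrate the complexes (`01`), contrast unbiased
bound-state stability at 300 K vs 348 K (`02`: the human-like ligand
keeps 98% of frames within 3 Å of the native pose and 90% of its native
contacts, the archaeal-like one drifts early and ends with none),
classify exit paths and check threshold insensitivity (`04`), and
validate the bias machinery on an analytic 1D double well (`05`: 5-seed
mean ΔF estimate 2.086 kJ/mol vs the exact 2.000).

A thin CLI wraps the same library:

```bash
metadhs build --variant human-like --out out/
metadhs metad --variant human-like --replicas 30 --seed 1 --out out/
metadhs report --out out/
```

Outputs use open formats: PDB/XYZ structures, PLUMED-style HILLS/COLVAR
tables, CSV summaries and JSON manifests with per-replica seeds.

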