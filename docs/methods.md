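# Methods

This note documents the models, conventions and numerical choices behind
`thiohelix`, in the spirit of a package's methods appendix: enough detail
to reproduce or audit any quantity the code computes.

## Reference frames and step parameters

Each base receives a right-handed orthonormal frame by Kabsch
superposition of an idealized planar ring template (6 atoms for
pyrimidines, 9 for purines) onto the observed ring atoms. The templates
are built at import time from regular fused-ring geometry (hexagon bond
1.39 Å, fused pentagon sharing the C4–C5 edge, glycosidic bond 1.47 Å,
C1′–C1′ separation 10.7 Å, glycosidic angle λ = 54.5°). Only
self-consistency matters: the same templates drive both duplex
construction and frame assignment, so a built structure re-analyzes to its
construction parameters to numerical precision (~1e−9).

The strand-reversal convention flips a partner frame's x and z axes
(rotation by 180° about y); a Watson–Crick pair frame is the half-rotation
average of the two base frames with the midpoint origin. Pair detection
gates candidates on sequence complementarity, C1′–C1′ distance ≤ 12 Å,
anti-aligned z axes (dot ≤ −0.5 before the flip) and, for same-strand
(hairpin) candidates, a sequence separation of at least 4 residues; the
greedy matching then ranks candidates by base-frame origin distance, which
is near zero for true partners and about one helical rise for
register-shifted contacts that pass the distance gate.

Step parameters use a mid-frame rotation-vector decomposition: for pair
frames (R₁,o₁) and (R₂,o₂), the rotation vector of R₁ᵀR₂ *is*
(tilt, roll, twist) and the origin displacement expressed in the half-way
frame is (shift, slide, rise). This scheme is exactly invertible
(`rebuild_from_steps` is the literal inverse, round-trip tested at 1e−8
over 1000 random draws), symmetric, and satisfies the classical reversal
property (reversing the reading direction negates shift and tilt and
preserves the other four). It differs from the curvilinear-axis convention
of Curves+ by small systematic offsets (order 1–2°/0.2 Å on strongly bent
steps); exact equivalence with that program is not claimed.

Helical-axis parameters come from the screw decomposition of the same
step transform: h-twist is the rotation angle about the screw axis, h-rise
the translation along it, x-displacement the offset of the mid base-pair
origin from the axis measured along the (axis-perpendicular projection of
the) mid-frame x axis, and inclination the angle by which the mid-frame y
axis climbs out of the plane normal to the axis. For a coaxial step the
two parameter sets coincide exactly; the tested B-form mirror property
(|h-rise − rise| < 0.2 Å, |h-twist − twist| < 1°) and the A-form
diagnostics follow.

## Fiber forms and the duplex builder

Two idealized forms are built in:

* **B form** — straight helix, twist 36.0°, rise 3.38 Å, all other step
  parameters zero; sugar target C2′-endo (P = 155°, νmax = 38°); classical
  fiber backbone torsion targets (α −41°, β 136°, γ 36°, δ 139°, ε −133°,
  ζ −157°, χ −102°).
* **A form** — generated helically: base pairs inclined 19.1° and displaced
  −4.17 Å from a common axis, h-twist 32.7°, h-rise 2.81 Å (classical
  fiber-model values). The equivalent uniform step parameters are derived
  at import and drive the same rebuild machinery. Interior-step analysis
  of the built 10-bp hybrid gives mean x-displacement −4.00 Å, inclination
  19.1°, h-rise 2.81 Å and rise 3.42 Å — inside the A-form diagnostic
  region (xdisp < −3 Å, incl > 10°, h-rise < 3 Å) with the step-frame rise
  above 3 Å, the signature separating the two descriptions.

Nucleotides are instantiated from per-form internal-coordinate templates.
The sugar ring is closed numerically: five ring atoms are solved by
weighted least squares against hard bond-length targets and the five
Altona–Sundaralingam torsions of the form's pseudorotation state (measured
phase within 0.01° of target). The ring attaches through the glycosidic
bond at the form's χ; the C1′ epimer branch is fixed to the configuration
validated by backbone chain closure. Because every base places its
glycosidic nitrogen and C1′ at identical base-frame coordinates, one
sugar/backbone unit per form serves all bases.

A rigid-residue fiber cannot simultaneously satisfy arbitrary torsion
targets and backbone connectivity, so the three torsions that move the
phosphate relative to the helix (χ, γ, β) are refined per form until the
O3′(i)–P(i+1) linkage closes at 1.607 Å with a sensible C3′-O3′-P angle
and ε/ζ near target. For the B form the refined backbone stays canonical
(BI with ε, ζ both negative; α/γ in the canonical g−/g+ state; χ ≈ −97°).
For the strongly displaced A form the closure solution departs further
from single-crystal backbone values (ε/ζ near 0°); the helical and pucker
observables, which the A-form analyses rely on, are unaffected.

Phosphorothioate sites are represented by renaming one non-bridging
phosphate oxygen (OP1) to the sulfur record `SP1` at a stretched 1.99 Å
bond and setting the residue's linkage annotation to `PS`; Rp/Sp chirality
is metadata only, since the same force-field parameters serve both
isomers. The sulfur substitutes an atom that appears in no torsion
quadruple, so backbone analysis of PS residues is unchanged by
construction.

## Synthetic ensembles

The generator perturbs per-step parameters with independent Gaussian noise
(user-set SDs, default 0) and rebuilds frames; every residue moves rigidly
with its pair frame, so re-analysis returns exactly the perturbed
parameters. Selected steps can follow a symmetric two-state Markov process
on the twist mean (defaults in the examples: 30.5°/36.5°, switch
probability 0.05 per frame), emulating the high/low twist-state switching
reported for CpG steps in phosphorothioated B-DNA. Randomness uses
counter-based Philox streams keyed on (seed, frame) so any frame is
reproducible independently; the Markov state sequence has a dedicated
stream.

What the generator does **not** emulate: sequence-dependent stiffness,
intra-pair degrees of freedom (propeller, buckle, opening), backbone
substate dynamics decoupled from the helical frame, solvent and ion
effects, and any actual PS-specific physics — PS sites alter topology and
annotation, not the fluctuation model, unless the user assigns them a
two-state process. Passing ensemble tests therefore validates the analysis
machinery and the statistical detectors, not force-field realism.

## Ensemble statistics

RMSD/RMSF are unweighted over the named selection ("P", "heavy", "all");
RMSF superposes frames to the time-average in two passes before measuring
fluctuations. Clustering is the greedy neighbour-count algorithm on the
pairwise superposed-RMSD matrix with a 0.2 nm default cutoff (nm at the
interface, Å internally), ties broken by lowest frame index, clusters
re-ranked by non-increasing size. The bimodality detector fits 1- and
2-component Gaussian mixtures at a fixed internal seed and requires
ΔBIC > 10 *and* component-mean separation above one pooled SD; series
shorter than 50 samples are never called bimodal. The detector is
deliberately conservative so that a bimodal call is reproducible and hard
to obtain by chance.

## Parameter derivation

* **RESP**: minimizes the squared potential misfit on the grid plus the
  hyperbolic restraint a·Σ(√(q²+b²)−b) under an exact net-charge
  constraint, by iteratively re-linearized KKT solves (tolerance 1e−12,
  limit 200 iterations). Defaults a = 0.0005, b = 0.1 (the conventional
  single-stage values; the tooling behind the published charges does not
  print its weights). Grid potentials are in e/Å units so the model
  potential is Σqᵢ/rᵢ with no prefactor.
* **Bond/angle constants**: default route projects the pseudo-inverse
  Hessian onto the internal coordinate's Wilson B-row, k = 1/(2 gᵀH⁺g)
  (pinv rcond 1e−8 to drop rigid-body modes). This is exact for decoupled
  harmonic force fields at the minimum: on a finite-difference Hessian of
  a harmonic triatomic it recovers the generating constants to <0.1%,
  whereas the classical Seminario sub-block construction (kept as
  `method="seminario"`) is exact only at 90° angles and deviates by tens
  of percent at tetrahedral geometry — the reason it is the cross-check
  rather than the default. Equilibria are always read from the supplied
  geometry.
* **Dihedral fit**: residual PES fitted to ΣKₙ(1+cos(nφ−δₙ)) with phases
  restricted to {0°, 180°}, which keeps the problem linear (signed cosine
  coefficients; sign absorbed into the phase). The reference grid is the
  15° pace used for the S–P–O–C scan (24 points); the fit requires more
  grid points than 2×(max multiplicity). RMSE is the least-squares
  residual RMS.
* **MM evaluator**: harmonic bonds/angles E = k(Δ)², cosine dihedrals,
  Coulomb 332.0636·qq/r, 12-6 LJ with Lorentz–Berthelot-style combination
  (ε geometric, Rmin additive) on pairs separated by ≥3 bonds, unscaled.
  Analytic forces agree with central finite differences to <1e−6
  kcal·mol⁻¹·Å⁻¹ on the DMPT fragment.

### Packaged parameter fixtures

The published values carried at full precision are: P partial charge
+0.9300 e (this work) vs +0.6258 e (comparison set); S-centred equilibrium
angles 121.171°/110.965° vs 108.230°/108.230°; natural phosphate angles
119.9°/108.230°; and the 0.018 Å P–S equilibrium-length difference between
the two PS sets. Everything else in the fixtures — non-phosphorus charges,
force constants, Lennard-Jones constants (assigned by analogy, never
derived) and the absolute P–S lengths — is synthetic placeholder data
constructed to be internally consistent: both charge sets sum exactly to
the −1 net charge, and every non-P charge difference between the two PS
sets lies inside the reported 0.0627–0.1309 e band. The fixture docstrings
and `notes` fields flag which is which.

## Problem sizes and tolerances

Tests and the acceptance script run at desk scale by design: duplexes of
4–10 bp, ensembles of 40–5000 frames, 24-point torsion scans, 40-frame
clustering problems. Monte-Carlo checks use 3000–5000 frames with 5%
relative tolerances (the SD of an SD estimate at n = 3000 is ~1.3%);
deterministic geometric identities are asserted at 1e−6 to 1e−9. Pucker
sector boundaries are half-open ([k·36°, (k+1)·36°)); torsions live in
(−180°, 180°] with −180° mapped to +180°.

## Known limitations

* Frame and step conventions are mid-frame/standard-template based, not
  Curves+; distributions from that program may be offset slightly.
* The A-form fiber backbone prioritizes chain closure over classical
  torsion values (see above).
* The builder produces heavy atoms only — no hydrogens, solvent, ions or
  energetics — and makes no attempt to mimic experimentally prepared
  coordinates.
* Groove geometry, intra-pair parameters, PCA/time-correlation analyses
  and Lennard-Jones derivation are out of scope; LJ values are packaged
  constants.
* The two-state twist process is symmetric; asymmetric occupancies would
  need a two-probability chain.
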