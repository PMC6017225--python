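# Methods

This note documents the models and estimators implemented in
`dendrisome`, the parameter choices that matter, what the synthetic
structures do and do not emulate, and the numerical conventions.

## Molecule grammar

A dendron is a rooted tree of repeat units. A generation-`g` dendron
(`g ≥ 1`) carries `2^g − 1` bis-MPA (2,2-bis(hydroxymethyl)propionic
acid) units in `g` branching layers; the deepest layer bears `2^g`
terminal positions, occupied by hydroxyl markers, myristoyl (C14 acyl)
tails, or acetonide caps (one cap protects the two hydroxyls of one
unit, so a protected dendron has `2^(g−1)` cap leaves). `g = 0` with an
acid focal point denotes the bare monomer. The Janus dendrimer joins a
hydroxyl-terminated and an acyl-terminated dendron through an ethylene
glycol diester; the default is G2/G2 with C13 alkyl tails — four
hydroxyls, four myristoyls.

Formulas are computed by summing the free-molecule formula of every unit
and subtracting one H₂O per condensation (ester or acetal) bond. The
bookkeeping is done per bond at assembly time, so any subtree is itself
a valid molecule. Adducts (e.g. `+2 Na`, `−H`) are formula deltas, never
tree nodes. Average masses use the IUPAC 2005-era standard atomic
weights (C 12.0107, H 1.00794, O 15.9994, Na 22.98977); with these the
sodiated-adduct masses of the default dendrimer and its precursor
dendrons reproduce the calculated MALDI-TOF values to ±0.02 Da
(1646.16 Da for C₈₈H₁₅₈Na₂O₂₄, 1342.88 Da for C₇₈H₁₃₅Na₂O₁₄). Only
average masses are computed — no isotope patterns.

## MARTINI mapping

Each myristoyl tail maps to one Na bead (ester carbonyl) plus three C1
beads (~4 heavy atoms per bead; for other tail lengths the C1 count is
`round(n_alkyl/4)`, minimum 1). Each bis-MPA unit maps to one Na bead;
its methyl substituent is not mapped. Each terminal hydroxymethyl maps
to one small polar SP2 bead. The ethylene glycol linker is absorbed into
the two focal branch beads, which are bonded directly. Bead connectivity
mirrors the chemical tree: the default JD has 26 beads and 25 bonds.

Block classes for the analyses: SP2 → `polar_head`; branch Na →
`hydrophilic`; tail Na and C1 → `hydrophobic`, with the distal C1 of
each chain labelled `tail_end`. Composite selections `hydrophilic_total`
(= heads + branch Na) and `hydrophobic_total` (= tails incl. ester Na)
are what density profiles report.

Bonded parameters default to MARTINI v2.0 standards: bonds 0.47 nm with
K_b = 1250 kJ mol⁻¹ nm⁻²; angles 180°/25 kJ mol⁻¹ along chains and
120°/45 kJ mol⁻¹ where the apex bead branches (degree > 2). Overrides —
typically from Boltzmann inversion — are keyed by bead-index pairs and
must reference existing bonds. Boltzmann inversion is harmonic:
`r₀ = ⟨r⟩`, `K = k_B T / Var` (variance in nm² for bonds, rad² for
angles; k_B = 0.0083144621 kJ mol⁻¹ K⁻¹), requires ≥ 100 samples, and
rejects (numerically) zero-variance input. Nonbonded parameters are not
derived — bead types carry the standard MARTINI interactions.

For SASA, beads use half the LJ diameter as radius: 0.235 nm for
regular beads, 0.215 nm for S-type (SP2).

## System builder

The starting state is `n` randomly rotated (uniform quaternion) and
translated copies of a canonical single-molecule conformation, accepted
only when every bead keeps at least `min_separation` (default 0.5 nm,
about one bead diameter) from all previously placed molecules under the
minimum-image convention; a periodic cell grid makes this O(N). The
reference composition is 1700 molecules in 37.6 × 37.4 × 37 nm; packing
it takes a few seconds. Water beads are not placed — no analysis here
needs solvent, and the emitted GRO can be solvated externally.

The geometric concentration of the reference system is
1700/(N_A · 52 026 nm³) ≈ 54.3 mM. The nominal figure quoted for this
composition elsewhere is 76 mM, which is inconsistent with the stated
box volume; the package always reports the computed value.

The MDP writer emits the reference run settings — 310 K
(velocity-rescale), 1 bar (Parrinello–Rahman), 30 fs time step, LJ and
Coulomb shifted from 0.9/0.0 nm to the 1.2 nm cutoff, PME — with a fixed
key order so output is byte-stable. Running GROMACS is out of scope.

## Synthetic structures

The multi-microsecond self-assembly trajectory that produced the
reference geometry is not desk-reproducible, so the analyzers are
validated on constructed assemblies whose ground truth is known exactly
and returned in `BeadFrame.ground_truth`.

**Bilayer patch.** Two apposed leaflets on a hexagonal lattice (square
optional) at `area_per_molecule` spacing (default 1.1 nm² — a plausible
value for a four-tailed amphiphile; nothing measured depends on it).
Within a molecule, beads sit on a straight axis normal to the leaflet
with ≤ 0.06 nm lateral offsets: heads exactly at ±D_hh/2, the distal
tail bead at D_hh/2 − L (per-tail stagger ±0.03 nm, zero-mean, so the
*mean* head→tail-end distance is exactly L), the first tail C1 exactly
l_t above its distal bead, ester Na beads just inside the core boundary
d_core/2, and mid-chain C1 beads crowded toward the distal end so the
hydrophobic density peaks at the bilayer center where the two leaflets'
tails meet. Gaussian noise σ (default 0.05 nm, small enough to keep
0.1 nm-binned peaks resolvable) is applied to all coordinates, seeded.
The registered `reference_patch` uses D_hh = 4.1, d_core = 1.8, L = 2.0,
l_t = 0.7 nm on a 6.5 × 5.4 nm patch (63 molecules), seed 42.
Consistency is enforced: non-interdigitated patches require
D_hh ≥ 2L and D_hh ≥ 2 l_t, and d_core ≥ 2(D_hh/2 − L + l_t) so the
tails fit inside the core; `interdigitated=True` lifts the overlap
restriction.

**Vesicle** — two concentric leaflet shells sharing the midsurface
radius R − D_hh/2, heads at R and R − D_hh, molecules split between
leaflets in proportion to shell area on Fibonacci spirals; rejects
< 0.4 nm² per head. **Micelle** — one shell, tails inward, all radial
coordinates proportional to R. **Aggregate box** — compact clusters
built as confined random walks with 0.35 nm steps (guaranteeing
single-linkage connectivity at any larger cutoff), placed with a
guaranteed minimum-image gap; explicit centers allow boundary-straddling
clusters. Cluster labels are ground truth.

These fixtures certify estimator correctness, not physics: conformations
are schematic (some bonded bead distances are unphysically short),
thermal disorder is isotropic Gaussian noise, and there is no curvature-
dependent packing, undulation spectrum or compositional disorder. A
passing recovery test therefore shows the estimator measures what it
claims on ideal geometry — not that real simulation output would be this
clean.

## Analyzers

**Clustering.** Two molecules link when any pair of selected beads
(default `hydrophobic_total` — aggregates cohere through hydrophobic
contact) is within the cutoff under minimum image; aggregates are the
connected components (single linkage) via a periodic k-d tree. The
default cutoff 0.6 nm is the MARTINI LJ σ plus a contact margin.
Cutoffs ≥ half the smallest box length are rejected as ambiguous. An
O(N²) brute-force oracle is tested equivalent on 100 random ≤ 280-bead
systems. Cluster metrics (R_g, sphere-equivalent diameter 2 R_g √(5/3),
convex-hull volume) unwrap each molecule to the minimum image of the
cluster's first molecule — valid while a cluster spans less than half
the box. Singletons are flagged degenerate (R_g = 0, no hull).

**Density profiles.** Per-group bead counts in uniform bins along a box
axis, divided by bin volume (cross-section from the other two box
lengths). Conservation is exact by construction: Σ density · bin volume
equals the selected bead count. Bilayer thickness = distance between the
two dominant `polar_head` maxima after merging maxima closer than three
bins and refining each peak with a parabola through its three bins
(clamped to ±half a bin); fewer than two maxima raises a
not-a-bilayer error. Core thickness = FWHM of `hydrophobic_total`,
measured between the *outermost* half-maximum crossings with linear
interpolation, so an interior dip between non-touching leaflets does not
narrow the estimate. On the reference fixture at 0.1 nm bins these
recover 4.10 and ~1.78 nm; across a sweep D_hh ∈ {3.0, 4.1, 5.0} nm and
σ ∈ {0, 0.05, 0.1} nm all estimators stay within one bin of ground
truth.

**Lengths.** Monomer length L is the distance from a molecule's
polar-head centroid to each distal tail bead, averaged; tail length l_t
pairs each `tail_end` bead with its first chain bead through the
`T<t>A..C` naming convention. Interdigitation ratio = D/(2L);
> 1 → non-interdigitated, = 1 flagged boundary, < 1 → interdigitated.
The reference values give 4.1/(2 · 2.0) = 1.025.

**SASA.** Shrake–Rupley with a deterministic golden-angle (Fibonacci)
point set, default 960 points, probe 0.264 nm (on the order of half a
MARTINI water bead). A point on the expanded sphere r_i + probe is
accessible when outside every neighbouring expanded sphere; exactly
coincident equal beads are counted once. Non-periodic (frames are
compact assemblies). Accuracy: exact for isolated spheres, within 2% of
the two-sphere closed form at 960 points. Plateau detection fits a line
in a sliding window (default 10% of the series) and reports the earliest
time from which every later window's |slope| stays within the tolerance
(default: 1% of the series mean shed per window span); a constant series
plateaus at t = 0, a drifting one returns "not converged". The fitted
slope reflects the window midpoint, so detection on an exponential
relaxation lands a few time constants in.

**Packing parameter.** p = v/(a₀ l_c), with Tanford's chain volume
v = (0.0274 + 0.0269 n_C) nm³ per chain available as a helper. Classes:
p < 1/3 spherical micelles, 1/3–1/2 cylindrical, 1/2–1
bilayers/vesicles, ≥ 1 planar or inverted; exact boundary values are
flagged. For four C13 tails at l_c = 0.7 nm, p stays well above 1/3 for
any plausible head area — consistent with this JD's refusal to form
micelles.

## I/O and pipeline

GRO records are written/parsed at the fixed-column layout (3-decimal nm,
numbering modulo 100000); multi-frame concatenated files are the
trajectory path (binary XTC/TRR is out of scope). GRO cannot carry block
labels, so readers reconstruct group classes from bead names (for tails
longer than three C1 beads this convention misclassifies the
intermediate letters — a known limitation; pass an explicit
`name_to_group` for nonstandard topologies). The writer is cross-checked
against an independent reader (MDAnalysis) in the test suite. The
pipeline runs build → map → (pack | fixture) → analyses from one JSON
config with explicit seeds and writes a manifest of SHA-256 checksums;
identical configs yield identical checksums.

## Problem sizes

Defaults were chosen so the whole suite runs in well under a minute of
CPU: the reference patch holds 63 molecules (1638 beads), the clustering
oracle runs 100 systems of ≤ 70 molecules, Boltzmann-inversion recovery
uses 10⁵ samples, SASA checks use ≤ 2 beads at 960 points, and the full
1700-molecule reference pack (44 200 beads) is built once.
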