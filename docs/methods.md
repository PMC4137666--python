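# Methods

This note records the models, numerical choices and known limitations
of the package, in the order the pipeline runs them.

## Ideal coiled-coil construction

A straight ideal alpha helix is first built from internal coordinates
(N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å; angles
C–N–CA 121.7°, N–CA–C 111.2°, CA–C–N 116.2°; φ = −57.8°, ψ = −47.0°,
ω = 180°) by natural-extension (NeRF) chain growth. Its exact screw
parameters (per-residue twist, rise, per-atom cylindrical offsets) are
measured from the rotation relating consecutive residues, rescaled to
the requested minor-helix parameters (defaults R1 = 2.26 Å,
w1 = 102.857°/residue — the 7/2 heptad repeat — rise 1.51 Å/residue),
and the straight helix is then bent onto the supercoil path of radius
R0 and frequency w0 using the path's parallel frame, with arc length
along the path equal to the straight-helix axial coordinate. w0
defaults to the left-handed value implied by R0 and a 140 Å pitch
(≈ −3.7°/residue at R0 = 6.1 Å); w0 = 0 produces straight parallel
helices. Bundle chains are exact rotated copies, so cyclic symmetry is
exact to floating-point precision.

The register is phased so that the side chains of heptad positions a
and d straddle the inward (core) direction, ±(360/14)° either side of
it — the knobs-into-holes arrangement; `registry_offset` rotates which
sequence index sits at position a.

Side chains are single pseudo-atoms placed along the idealized
beta-carbon direction at a per-residue calibrated distance equal to
the side-chain center-of-mass distance from CA; charged residues
(K, R, H, D, E) carry one further pseudo-atom 2.5 Å out for the
charged group. Amide hydrogens sit 1.00 Å from N in the
C(i−1)–N–CA plane opposite the angle bisector; prolines and
chain-initial residues have none.

**Verified consequences** (pinned in the tests): built backbones fall
inside the helix dihedral window; each L-residue chain forms exactly
L−4 backbone i→i−4 hydrogen bonds (N···O 2.85–2.95 Å, deviation from
linearity 19–23°); the supercoil radius estimator recovers R0 within
0.04 Å across R0 ∈ [4, 8] Å.

## Synthetic replica ensembles

The generator emulates the outcome of temperature-replica sampling
with a two-state model per degree of freedom, not molecular dynamics:

* each residue is independently helical with probability
  1/(1+exp((T−tm_helix)/width_helix));
* each frame is associated (chains at folded positions) or
  dissociated (each chain displaced 25 Å radially) by a Bernoulli draw
  of the association order parameter
  1/(1+exp((T−tm_association)/width_association));
* the per-frame pseudo-energy is −e_helix·(#helical residues) −
  e_contact·(#intermonomer hydrophobic contacts) + Gaussian noise.

Sampling association as a two-state draw (rather than displacing
chains by a deterministic, temperature-dependent distance) makes the
mean radial separation follow one minus the order parameter while
placing the midpoint of the mean contact curve exactly at
tm_association, so melting-curve extraction can be validated as a
parameter-recovery problem.

Frames are rebuilt by batched NeRF from the folded structure's own
internal coordinates; helical residues keep their folded dihedrals
(hence folded coordinates, exactly), coil residues draw
φ ~ U[−180°, −30°], ψ ~ U[60°, 180°]. Two deliberate refinements keep
the realized secondary structure identical to the sampled state: the
chain-terminal residue, judged by its single defined dihedral, draws
its coil φ from [−180°, −100°] (outside the helix window), and the
0.5 Å coil coordinate jitter is applied only to atoms that define no
backbone dihedral (O, H, side-chain pseudo-atoms). Frames are i.i.d.
per temperature — there is no autocorrelation, so windowed averages
are simply sub-sample means.

Defaults (tm_association 454.52 K, tm_helix 556.59 K, widths 20/15 K,
200 frames/rung, e_helix 2, e_contact 4, noise 5 kJ/mol; k_B =
0.0083144621 kJ/mol/K) are artifact choices placing both midpoints on
ladder rungs and ordering the transitions as observed for this protein
family: association is lost before secondary structure. They are not
measurements.

**What passing tests do and do not show.** The generator realizes
logistic order parameters, exact Boltzmann toys, and geometrically
consistent frames; recovery of its midpoints shows the analysis stack
is correct, not that any real protein melts at these temperatures.
Real trajectories additionally have autocorrelation, partial unfolding
intermediates, and side-chain rotamer flexibility that the single
pseudo-atom representation cannot express.

## Interaction census

All cutoffs are inclusive (≤): hydrogen bonds at 3.5 Å donor–acceptor
distance and 30° deviation of the donor-H-acceptor angle from
linearity (i.e. the angle at H ≥ 150°); salt bridges at 4.0 Å between
the closest basic-group/acidic-group atoms, geometry-free, counted
once per residue pair and for intermonomer pairs only; hydrophobic
contacts at 7.0 Å between side-chain centers of mass of apolar
residues (A, V, L, I, M, F, W — Gly, Pro and Tyr excluded) on
different chains. H-bonds are counted per (donor-H, acceptor) pair;
donors without an attached hydrogen (within 1.25 Å) are skipped with a
warning. Helix content replaces a secondary-structure program with a
documented dihedral window (φ ∈ [−100°, −30°], ψ ∈ [−67°, −7°];
terminal residues judged by their single defined dihedral), averaged
over the chains of the bundle. Every detector is checked for exact
count agreement against an independent all-pairs double loop on random
200–500-atom frames.

Protonation follows a threshold model: protonated iff pH < pKa
strictly (Asp 3.65, Glu 4.25, His 6.0, Lys 10.4, Arg 12.0, C-term 3.6,
N-term 8.0), which is deterministic and monotone in pH. Protonated
carboxylates are removed from the acceptor and salt-bridge catalogs;
histidine joins the salt-bridge donor catalog only while protonated.

**Limitation.** With rigid, radially placed single-pseudo-atom side
chains, the closest cross-chain K···E charged-group distance at
classic g–e′ pairings is ≈ 4.4 Å, just outside the 4.0 Å criterion, so
ideal-geometry frames report no salt bridges and no intermonomer
side-chain hydrogen bonds (pseudo side chains also carry no donor
hydrogens). The pH comparison (acidic ≤ neutral on identical frames)
still holds, and the detectors are validated on constructed
coordinates where those interactions do occur. Real side chains flex
to close that gap; emulating rotamers is out of scope.

## Superposition descriptors and clustering

Superposition is the closed-form least-squares rigid transform (SVD
with a determinant guard; checked against a random-restart quaternion
search). RMSD series use frame 1 as the reference; RMSF superposes the
whole assembly onto an iterated mean (two passes), then averages
equivalent residues over the monomers. The supercoil radius is the
mean distance of window-5 CA centroids (which cancel the minor-helix
oscillation to ~0.04 Å) from the principal axis of all CA atoms.

Decoy clustering selects the `top_n` = 400 lowest-energy models and
repeatedly promotes the unassigned model with the most unassigned
neighbors (pairwise superposed CA RMSD ≤ 3.0 Å, neighbor count
excluding self, cluster including self) to cluster center; ties break
toward lower energy, making the procedure deterministic. The final
model is the center of the most populated cluster.

## Melting curves

Observables are averaged (mean ± SD) over the final half
(`window_fraction` 0.5) of the frames at each rung. Tm is the rung
minimizing the central-difference derivative of the means after a
width-3 centered moving average (endpoints truncated); reporting
on-grid keeps every Tm at an actual ladder rung, the convention for
replica-ladder melting analyses. A curve is flagged non-sigmoidal — signalling the
half-amplitude midpoint fallback — when the steepest rung lies within
2 rungs of a ladder end (a strictly linear curve lands there) or the
total drop is below 4× the median per-rung SD. Both the smoothing
width and the flag thresholds are configuration, since the fallback
criterion is a judgment call; the diagnostic only approximates the
per-observable choice a human analyst would make.

## WHAM

The Ferrenberg–Swendsen equations are iterated in log space on
per-energy-bin counts (200 energy bins spanning the observed range by
default): f_k ← −logsumexp over occupied energy bins of the
counts-over-denominator term, to a max|Δf| tolerance of 1e−7 within
10000 iterations (non-convergence is reported and the partial result
flagged). Because every bin of one energy slice shares its reweighting
denominator, the coordinate grid (default 50×50 over percentage axes)
only enters the final projection P(x, y; T0) ∝ Σ_E M(E, x, y)
e^{−β0 E}/D(E). Empty bins carry probability 0 and masked (NaN) free
energy; the free-energy minimum is shifted to 0. With a single replica
the estimate reduces algebraically to the empirical histogram, which
the tests pin to 1e−10. Validation against closed forms: two-state
occupancy to 2 %, harmonic variance k_B T0/k to 5 %.

Basins are strict 3×3 local maxima of P (a flat surface has none),
merged below a `min_separation` of 3 bins, ranked by the probability
mass of their steepest-ascent watershed catchments. On generator data
the dominant basin sits at high helix/high contacts when reweighting
to the lowest rung and at low/low far above the helix midpoint,
reproducing the two-basin landscape with no stable intermediate.

## Scales used in the shipped checks

The acceptance script and heavy tests use a 35-residue trimer on the
full 64-rung ladder with 200 frames/rung for Tm recovery (contact and
helix transitions well separated at these sizes) and 40 frames/rung
for the landscape; toys use 50 000 samples per temperature. These
sizes give sampling errors comfortably inside the asserted tolerances
while keeping a full run under a minute.

## Known limitations

* Pseudo-atom side chains: no rotamers, no salt bridges in ideal
  geometry (above), hydrophobic COM distances approximate.
* The generator's independence assumptions (per-residue helicity,
  i.i.d. frames) make melting curves cleaner than real data.
* Pseudo-energies are bookkeeping quantities, not force-field
  energies; WHAM on generator data demonstrates the estimator, not
  thermodynamics of a real system.
* `LIC80_SYNTHETIC` is a constructed benchmark sequence carrying the
  documented feature positions of the mature lipoprotein chain; it is
  not the real sequence, which is why sequence-level outputs (register
  score, hydropathy profile) are structural sanity checks rather than
  biological claims.
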