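# coilstab

Stability analysis of trimeric coiled-coil lipoproteins: heptad and
lipobox sequence analysis, pH-dependent protonation, a geometric
interaction census (hydrogen bonds, salt bridges, hydrophobic
contacts), superposition descriptors and decoy clustering,
melting-temperature extraction over a replica temperature ladder, and
2-D free-energy landscape reconstruction by the weighted histogram
analysis method (WHAM).

## The problem

Acid-stable secreted lipoproteins such as the bioleaching-associated
Licanantase family fold as parallel trimeric coiled coils with an
alanine-rich hydrophobic core (an "alanine zipper"). Their thermal and
pH stability is studied by simulating the trimer over a ladder of
temperatures and following, rung by rung, the loss of intermonomer
hydrogen bonds and salt bridges, then hydrophobic contacts, then
main-chain hydrogen bonds and helix content. This package implements
that analysis pipeline as a tested, reusable library and CLI. Because
raw folding-engine decoys and MD trajectories for such systems are not
generally available, the package includes a first-class synthetic
stage: an ideal Crick-parameterized coiled-coil builder and a two-state
replica-ensemble generator with Boltzmann-like per-frame
pseudo-energies, so every downstream stage is exercised end to end.

## The model in brief

* **Geometry.** A chain is an ideal alpha helix (minor helix radius
  R1 = 2.26 Å, frequency w1 = 102.857°/residue, rise 1.51 Å/residue)
  bent onto a left-handed supercoil of radius R0 (default 6.1 Å);
  chains of the C_n bundle are exact rotated copies. Side chains are
  single pseudo-atoms at the side-chain center of mass, plus a
  charged-group pseudo-atom for K/R/H/D/E.
* **Census.** H-bond: donor–acceptor ≤ 3.5 Å and donor-H-acceptor
  deviation from linearity ≤ 30°; salt bridge: closest charged-group
  atom pair ≤ 4.0 Å, intermonomer only; hydrophobic contact: side-chain
  centers of mass of two apolar residues on different chains ≤ 7.0 Å.
  A residue is helical iff φ ∈ [−100°, −30°] and ψ ∈ [−67°, −7°].
* **Protonation.** Threshold pKa model: a titratable group is
  protonated iff pH < pKa (Asp 3.65, Glu 4.25, His 6.0, C-term 3.6, …);
  protonated carboxylates stop accepting H-bonds and salt bridges.
* **Melting.** Observable means ± SD over the last half of each
  replica; Tm is the ladder rung minimizing the first derivative
  d⟨O⟩/dT of the (lightly smoothed) curve, with a half-amplitude
  midpoint fallback for non-sigmoidal curves. The 64-rung geometric
  ladder T_i = 303.15 · r^i (r fixed by T_max = 809.57 K) reproduces
  the reference REMD ladder within 0.3 K.
* **WHAM.** Ferrenberg–Swendsen multiple-histogram reweighting of
  (energy, helix %, contact %) histograms to a target temperature T0,
  giving P(helix, contacts; T0) and F = −k_B T0 ln P; basins are local
  maxima ranked by steepest-ascent watershed mass.

## Worked example

```python
from coilstab import (CrickParameters, MeltingModel, build_ideal_coiled_coil,
                      generate_replica_ensembles, assign_heptad_register,
                      assign_protonation, detect_hbonds, detect_hydrophobic_contacts,
                      classify_and_count, estimate_supercoil_radius,
                      measure_observables, ensemble_averages, extract_tm, make_ladder)
from coilstab.sequences import LIC80_SYNTHETIC  # synthetic 80-residue mature chain

reg = assign_heptad_register(LIC80_SYNTHETIC)
print(f"register offset {reg.offset}, {reg.n_complete_heptads} heptads, "
      f"a/d hydrophobic occupancy {reg.score:.2f}")

trimer = build_ideal_coiled_coil(LIC80_SYNTHETIC, CrickParameters(supercoil_radius_r0=6.1))
print(f"supercoil radius estimate: {estimate_supercoil_radius(trimer):.2f} A")
print(f"main-chain H-bonds: {classify_and_count(detect_hbonds(trimer))[('hbond', 'mainchain')]}")
print(f"intermonomer hydrophobic contacts: {len(detect_hydrophobic_contacts(trimer))}")
print(f"protonated carboxyls at pH 1.6: "
      f"{len(assign_protonation(LIC80_SYNTHETIC, ph=1.6).protonated_carboxyls)} side chains")

ladder = make_ladder(303.15, 809.57, 64)
model = MeltingModel(tm_association=454.52, tm_helix=556.59,
                     frames_per_temperature=50, seed=1)
series = generate_replica_ensembles(trimer, ladder, model)
meas = measure_observables(series, None, ("helix_content_pct", "hydrophobic_contacts"))
for name, curve in ensemble_averages(meas, ["helix_content_pct", "hydrophobic_contacts"]).items():
    tm = extract_tm(curve)
    print(f"Tm({name}) = {tm.tm:.2f} K ({tm.diagnostic})")
```

prints

```
register offset 0, 11 heptads, a/d hydrophobic occupancy 0.78
supercoil radius estimate: 6.09 A
main-chain H-bonds: 228
intermonomer hydrophobic contacts: 96
protonated carboxyls at pH 1.6: 9 side chains
Tm(helix_content_pct) = 556.85 K (sigmoidal)
Tm(hydrophobic_contacts) = 440.73 K (sigmoidal)
```

The 80-residue chain partitions into 11 heptads with its alanine core
at positions a/d; the built trimer round-trips its supercoil radius,
carries exactly 3·(80−4) = 228 main-chain i→i−4 hydrogen bonds, and at
pH 1.6 exactly the nine Asp/Glu side chains (plus the C-terminus) are
protonated. On the synthetic melting ensembles the extracted contact
Tm lies below the helix-content Tm — tertiary structure is lost before
secondary structure — and each recovers its generator midpoint to
within about one ladder rung.

The same stages are available from the shell:

```bash
coilstab build --seq seq.fasta --r0 6.1 --out trimer.pdb
coilstab simulate --pdb trimer.pdb --frames 200 --seed 1 --out-dir sim/
coilstab analyze --pdb ensemble.pdb --ph 1.6 --out obs.tsv
coilstab tm --tables sim/ --observable helix_content_pct
coilstab wham --tables sim/ --t0 303.15 --out surface.tsv
coilstab report --config config.yaml --out-dir report/
```

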