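# xbond

Halogen-bond analysis of protein–ligand structures and MD trajectory
snapshots, built for active-site studies of halogenated substrates — the
kind of question where moving a chlorine from the meta to the ortho position
of a substrate rewires its non-covalent anchoring and flips an enzyme's
substrate selectivity.

A carbon-bound halogen carries a **σ-hole** — positive electrostatic
potential on the extension of the C–X axis — which binds electron-rich
acceptors. `xbond` detects both flavors of the resulting halogen bond with
strict geometric criteria:

* **C–X···Y** (Y = O, N, S): d(X···Y) < r(X) + r(Y) (Bondi vdW sum, e.g.
  Cl···O < 3.27 Å, Cl···N < 3.30 Å, Cl···S < 3.55 Å) and β = ∠(C,X,Y) > 140°;
* **C–X···π** (Phe/Tyr/His/Trp rings): d(X···centroid) < 4.2 Å, α < 60°
  (angle to the ring normal), θ = ∠(C,X,centroid) > 146°.

On top of the detector sit: per-residue **occupancy** profiles over
trajectories (fraction of frames with ≥ 1 X-bond to each residue), labeled
**key-distance** time series with mean ± SD summaries (e.g. D_C8-SG, the
nitrile-carbon-to-catalytic-cysteine distance that gates nucleophilic
attack), a **wild-type-referenced screen** (a candidate passes iff both key
distances are strictly shorter, on mean, than the WT reference), σ-hole
**extra-point placement** (a positive pseudo-atom 1.90 Å beyond the halogen
on the C–X axis, with conserved total charge), and a **synthetic complex
generator** that plants halogen-bond geometries at exact occupancies so the
whole pipeline is testable without running MD.

See `docs/methods.md` for the geometric definitions, statistical choices
and the limits of what the synthetic data demonstrates.

## Worked example

```python
from xbond import (
    DistanceSpec, PlantedContact, SyntheticSpec, make_toy_complex,
    find_donor_pairs, select_atoms, analysis_report,
)

# a 100-frame toy complex: a chlorinated ligand with an X-bond to a backbone
# oxygen planted in 80% of frames and to an aromatic ring in 25%
spec = SyntheticSpec(
    n_frames=100,
    seed=42,
    contacts=(
        PlantedContact("point", 3.0, (165.0,), 0.80, acceptor_element="O"),
        PlantedContact("pi", 3.5, (20.0, 170.0), 0.25),
    ),
)
traj = make_toy_complex(spec)
donors = find_donor_pairs(traj.frame(0), select_atoms(traj, "resname LIG").indices)
report = analysis_report(
    traj,
    [
        DistanceSpec("D_C8-SG", "resid 1 and name C8", "resid 169 and name SG"),
        DistanceSpec("D_N1-HZ", "resid 1 and name N1", "resid 135 and name HZ"),
    ],
    donors,
)
for d in report["distances"]:
    print(f'{d["label"]}: {d["mean"]:.2f} +/- {d["sd"]:.2f} A over {d["n_frames"]} frames')
for residue, frac in report["occupancy"].items():
    print(f"X-bond occupancy {residue}: {frac:.0%}")
print("dominant acceptor:", report["dominant_acceptor"])
```

prints

```
D_C8-SG: 3.76 +/- 0.22 A over 100 frames
D_N1-HZ: 2.78 +/- 0.51 A over 100 frames
X-bond occupancy GLY195:A: 80%
X-bond occupancy PHE202:A: 25%
dominant acceptor: GLY195:A
```

The key distances recover the generator's defaults (3.76 ± 0.21 Å and
2.83 ± 0.56 Å — the reference values of a productive wild-type complex)
within sampling error at 100 frames, and both planted occupancies come back
exactly: the dominant halogen-bond partner is the backbone oxygen of
residue Gly195, bonded in 80 % of frames.

The same pipeline is available from the shell:

```bash
xbond simulate --spec spec.yaml --out wt/          # synthetic trajectory
xbond detect wt/trajectory.pdb --ligand "resname LIG" -o bonds.csv
xbond report wt/trajectory.pdb --ligand "resname LIG" \
    --distance D_C8-SG "resid 1 and name C8" "resid 169 and name SG" \
    --distance D_N1-HZ "resid 1 and name N1" "resid 135 and name HZ" \
    -o wt.json
xbond screen wt.json mutant.json -o verdict.json   # WT-referenced screen
xbond placeep complex.pdb --ligand "resname LIG" --ep-charge 0.05 -o pep.pdb
```

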