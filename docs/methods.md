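# Methods

## The halogen bond and why an enzyme cares

A carbon-bound halogen (C–X, X = F, Cl, Br, I) carries a **σ-hole**: a cap of
positive electrostatic potential on the extension of the C–X axis, opposite
the covalent bond. Electron-rich partners — carbonyl oxygens, amide
nitrogens, thioether sulfurs, or the π face of an aromatic ring — can bind
into this cap, forming a **halogen bond (X-bond)**: a short, highly
directional non-covalent contact, geometrically analogous to a hydrogen
bond. In an enzyme active site, an X-bond between a chlorinated substrate
and a pocket residue acts as an anchor that orients the substrate; moving
the chlorine around a phenyl ring (ortho/meta/para) redistributes the
X-bonds and can flip which isomer the enzyme turns over. The package
quantifies exactly that: where X-bonds form, how often, and how they
correlate with the catalytic approach distances.

## Geometric models

Two acceptor classes are treated, each with strict (`<` / `>`) criteria;
geometries exactly at a threshold are never counted as bonds.

**Point acceptor, C–X···Y** (Y ∈ {O, N, S} by default):

* d(X···Y) < r_vdW(X) + r_vdW(Y) — the vdW-sum cutoff. With the default
  Bondi radii this gives Cl···O < 3.27 Å, Cl···N < 3.30 Å, Cl···S < 3.55 Å.
  The Bondi set is the default precisely because its pairwise sums reproduce
  these standard chlorine cutoffs; the table is user-overridable, and
  per-pair cutoffs can be pinned explicitly.
* β = ∠(C, X, Y) > 140° — the acceptor must sit in the σ-hole, i.e. near
  the C–X axis extension.

**π acceptor, C–X···π** (rings of Phe, Tyr, His, Trp):

* d(X···centroid) < 4.2 Å,
* α < 60°, where α is the acute angle between the centroid→X vector and the
  ring normal (acute: the normal's sign is arbitrary, so min(α, 180°−α) is
  used),
* θ = ∠(C, X, centroid) > 146°.

α and θ follow the convention of Zhu and co-workers' halogen-bond surveys;
since conventions differ in the literature, every observation records its
full measured geometry (d, β or α/θ, and additionally the distance to the
nearest ring atom) so users can re-filter under any alternative definition
without re-running detection.

Ring planes are fitted by total least squares: the normal is the singular
vector of the centered ring coordinates with the smallest singular value.
Rings are enumerated from residue-name templates (Phe/Tyr: CG–CZ six-ring;
His: five-ring; Trp: pyrrole and benzene rings tested independently, since
the two π faces are distinct acceptors). A residue missing template atoms in
a frame is skipped with a warning rather than failing the frame.

Donor (C, X) pairs are auto-discovered inside the ligand selection: any
halogen whose nearest carbon lies within 2.1 Å. The ligand's own O/N/S
atoms are never counted as acceptors, and water is excluded by default
(`include_water=True` restores it): occupancy statistics are about
protein–ligand anchoring, and transient water contacts would dilute the
per-residue percentages; the flag exists because the choice is a convention,
not a law.

## Trajectory statistics

Trajectories are ordered PDB MODEL blocks over a fixed topology; frames are
weighted equally. Two aggregate quantities are computed:

* **Key distances.** A labeled single-atom-pair distance per frame, e.g.
  D_C8-SG (substrate nitrile carbon → catalytic Cys SG, the gatekeeper of
  nucleophilic attack) and D_N1-HZ (nitrile nitrogen → catalytic Lys HZ,
  proxy for intermediate stabilization). Summaries report the arithmetic
  mean and the *sample* SD (n−1 denominator; at the usual 1000-frame scale
  the n vs n−1 distinction is ~0.05 %, and `ddof` is configurable). A
  single-frame series reports SD = 0 with a warning.
* **Occupancy.** Per acceptor residue, the fraction of frames with ≥ 1
  X-bond to that residue; several simultaneous bonds to one residue in one
  frame count once, matching the residue-level way such percentages are
  quoted. Point and π bonds are pooled in the headline figure and broken
  out per type in the CSV/JSON outputs.

## Mutant screening rule

A candidate complex passes iff **both** key-distance means are strictly
shorter than the wild-type reference means. The rule operates on means only
— the spreads are reported but never enter the verdict; this mirrors how
such screens are actually phrased, and is a documented limitation (a
candidate with a short mean but huge variance still passes). For
conservative use, `margin_k` requires mean + k·SD < reference mean.
Ranking places passes first, ordered by the ascending sum of the two means,
ties broken by label. The screen accepts single-snapshot summaries
(n_frames = 1), so it can be used both for quick first-pass filtering and
for MD-averaged confirmation.

## σ-hole extra point (PEP)

Isotropic atomic point charges cannot represent the σ-hole, so fixed-charge
force fields underestimate X-bonds. The positive-extra-point correction adds
a massless pseudo-atom on the C–X axis, beyond the halogen, at a fixed
offset — **1.90 Å** by default. Placement is purely geometric:
ep = x + offset·(x−c)/|x−c|. The EP charge magnitude is a parameterization
result (typically a RESP fit) and is deliberately a **required user input**
with no default: shipping invented electrostatics would be worse than
shipping none. Charge bookkeeping subtracts the EP charge from its parent
halogen, so the molecular total is conserved to 1e-10. Output is PDB plus a
sidecar CSV charge table (PDB has no charge column with usable precision).

## Synthetic data: what it emulates and what it does not

MD trajectories of a solvated enzyme are neither cheap nor redistributable,
so the generator builds a toy active site with *known* ground truth:

* a chlorobenzyl-cyanide-like pseudo-ligand (ring C1–C6, Cl, C7, C8, N1), so
  realistic selections (`name C8`, `element Cl`) work;
* pseudo residues supplying each acceptor class (Gly195 backbone O, Gln205
  side-chain N, Met180 S, Phe202 and Tyr173 rings) and the catalytic atoms
  Cys169 SG / Lys135 HZ;
* planted contacts: exactly ⌈fraction·n_frames⌉ frames are constructed
  inside all criteria at the requested distance/angles (measured after
  jitter, because the planted atom is positioned relative to the jittered
  C–Cl axis), and every other frame violates the distance criterion by a
  0.5 Å margin. The ≥ 0.3 Å / 10° margin rule exists so floating-point
  noise can never flip a frame's classification — occupancy recovery is
  exact by construction, which is what makes it a usable oracle;
* key distances drawn per frame from a Gaussian truncated at 0.5 Å; the
  defaults (D_C8-SG 3.76 ± 0.21 Å, D_N1-HZ 2.83 ± 0.56 Å, 1000 frames)
  mirror a productive wild-type complex and serve as the reference
  conditions for the statistical tests;
* WT/mutant scenario pairs whose planted mean separations (≥ 0.5 Å at
  per-frame SD 0.2 over 200 frames, i.e. ≥ 15 standard errors) guarantee
  the screening verdict, giving end-to-end ground truth.

What the generator does **not** emulate: physical dynamics (no correlation
between frames, no solvent, no forces), realistic protein packing (acceptor
atoms float freely), or competition between acceptors. Passing tests
therefore demonstrate that the *measurement machinery* is correct — not
that any particular enzyme behaves any particular way. Real headline
numbers (per-residue occupancies, MD-averaged key distances of specific
complexes) require the original crystal structure, ligand parameterization
and nanosecond MD, which are out of scope here; printed values from such
studies are used only as screening-rule inputs and as format precedents.

## Numerical choices

* Units are fixed package-wide: Å and degrees.
* All criteria comparisons strict; angle cosines clipped to [−1, 1] before
  `arccos`.
* Collinearity in the plane fit is detected via the second singular value
  (≤ 1e-8 relative) → degenerate-ring error; < 3 points likewise.
* PDB coordinates round-trip at the format's 3-decimal precision; tests use
  5.1e-4 Å tolerance accordingly.
* Altloc policy: keep blank or "A", drop the rest (deterministic
  single-conformer analysis).
* One integer seed drives every random draw in the generator
  (`numpy.random.default_rng`); identical seeds give byte-identical PDB
  output.
* Problem sizes in the test and acceptance runs — 10-frame occupancy
  fixtures, 1000-frame statistics, 20 screening scenarios of 200 frames,
  25 random frames of ~50 atoms for detector/oracle equivalence — were
  chosen so every statistical assertion sits at ≥ 3 standard errors while
  the whole suite stays interactive.

## Known limitations

* Bond perception is distance-only (2.1 Å C–X rule); no formal topology.
* The detector tests every (donor, acceptor) pair exhaustively per frame —
  O(donors × acceptors); fine for active-site analyses, not tuned for
  whole-proteome scans (no spatial indexing).
* mmCIF and binary trajectory formats are not supported; PDB (or a
  directory of PDB files) is the carrier.
* The screening verdict ignores distance variance unless `margin_k` is set.
* Charge handling is bookkeeping only; no electrostatics are computed.
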