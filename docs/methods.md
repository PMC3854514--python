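# Methods

## Scope and model

`tmexpo` treats an α-helical membrane protein as a set of annotated
transmembrane (TM) segments on one or more chains.  Two quantities are
central:

* **rASA** — a residue's accessible surface area in a lipid-mimicking
  probe environment divided by its reference area in an extended Gly-X-Gly
  tripeptide.  Residues with rASA < 5 % are *buried* (label B), otherwise
  *exposed* (label E); the 5 % rule is strict (`rasa == 0.05` is exposed).
* **Rotational angle** — viewing a helix down its own principal axis from
  the N-terminal side, the angle from the first TM residue's Cα vector to
  the lipid-facing direction (molecule center → helix center, in-plane),
  measured in the sense that appears clockwise from the N-terminal side,
  in [0°, 360°).

The exposure moment connects them: scores placed at helical-wheel
positions θᵢ = (i−1)·100° are summed as vectors; the resultant's direction
is the predicted rotational angle, its length the exposure anisotropy.

## Angular conventions (one sign rule everywhere)

All angle-valued code uses a top-view frame (u, v, axis) with
u × v = axis (axis oriented N→C).  Increasing `atan2(v, u)` is then
exactly "clockwise as seen from the N-terminal side", and an ideal
right-handed α-helix advances +100° per residue in this sense.  The same
+100° spacing defines the moment's wheel positions, so observed and
moment-predicted angles are directly comparable.  A cross-module test pins
this: a helix built so that residue *i* faces the lipid has observed angle
(i−1)·100° mod 360, identical to the moment direction of a delta exposure
profile at residue *i*.

## Surface area

Dot-sphere (Shrake–Rupley-style) sampling: each atom's sphere of radius
(vdW + probe) carries a deterministic Fibonacci-spiral point set; points
inside any neighbour's expanded sphere are inaccessible.  Defaults:

* `probe_radius = 2.0 Å` — mimics the -CH₂ group of lipid hydrocarbon
  chains (the appropriate probe for the bilayer environment; water's
  1.4 Å probe would overstate crevice accessibility).
* `n_points = 960` — per-residue areas change by < 2 % on fixtures when
  doubled; the isolated-atom analytic value 4π(r+probe)² is reproduced
  within 1 % (exactly, in practice, by symmetry of the spiral set).
* vdW radii: NACCESS/Chothia-convention element table
  (`data/vdw_radii.json`, editable; C 1.87, N 1.65, O 1.40, S 1.85 Å).
  Hydrogens are ignored; HETATM records are excluded by default.

Because the point set is shared and deterministic, adding atoms can only
remove accessible points: subunit-derived rASA ≥ complex-derived rASA holds
*exactly*, residue by residue, not just statistically.

The algorithm is implemented here rather than delegated because the exact
occlusion semantics (probe radius, radii table, determinism, HETATM
handling) are load-bearing for the tests; it is verified by analytic and
invariance properties rather than bit-comparison against any particular
external program (NACCESS-style slicing differs in the third digit).

### Gly-X-Gly reference areas

The bundled reference table (`data/gxg_reference_probe2.0.tsv`) is computed
by this package itself: extended (φ=ψ≈180°) Gly-X-Gly tripeptides are
assembled from ideal residue geometries (chemical component dictionary via
biotite), hydrogens stripped, and the central residue's ASA evaluated at
the default 2.0 Å probe and 960 points.  Literature reference tables are
computed at the 1.4 Å water probe and would mis-normalize areas measured
with the lipid probe; computing the references under identical conventions
makes rASA a true fraction of maximum exposure (the self-consistency test
recomputes the table and checks ratios ≈ 1 within 5 %).  Any code path
accepts an alternative table as a parameter.

## Observed-angle geometry

* **Principal axis**: the Cα trace is smoothed with a 4-residue window
  [1, a, a, 1], a = cos 30°/cos 50°, which annihilates the
  100°-per-residue harmonic — for an ideal helix the smoothed points fall
  exactly on the axis, so the subsequent line fit (dominant singular
  vector) is unbiased even when the helix ends mid-turn.  Sign: from the
  N-half centroid toward the C-half centroid.
* **Molecule center**: the Cα of all *annotated TM residues* of the chain
  unit (atoms outside the membrane segments are removed first).  A
  multi-chain complex can be analyzed by passing the combined TM Cα set.
* **Per-helix frames**: each helix's angle is computed in its own frame;
  in-plane basis choice cancels because only angle differences are used.
* **First residue**: the first annotated TM residue possessing a Cα; a
  fallback to a later residue is recorded in the output flags.
* **Kinked helices**: no kink splitting — a single global axis is fit.
  Accuracy degrades gracefully for kinked or highly irregular helices;
  this is a known limitation, not special-cased.

Degenerate inputs raise typed errors: < 3 Cα, coincident points, helix
center equal to molecule center, first Cα projecting onto the axis.

## Moment

Equations are applied exactly as stated above; degrees throughout.  A
moment shorter than 1e-9 has no defined direction and raises an error
carrying |M| (the arccos form divides by |M|); the CLI reports such
helices as `undefined` with exit code 0.  An optional post-processing hook
on the score profile (identity by default) is exposed for outlier/ramp
smoothing schemes; the default pipeline applies none.

## Feature encoding

Window length 17 (8 on each side), 28 features per position, 476 per
vector, fixed layout versioned as `tmexpo-features-1`; models refuse
vectors from another schema version.  Encodings:

* PSSM (PSI-BLAST ASCII layout, reader included): `1 − 1/(1+e^(−v))`
  per entry (20 per position).
* Conservation: Jensen–Shannon divergence (λ = 0.5, base-2 logs, bounded
  by 1) between the alignment column distribution and BLOSUM62-style
  background frequencies, scaled by the column's non-gap fraction; raw
  scores, no windowing or Z-transform.  When no alignment is available the
  slot is filled with the neutral 0.5.
* Volume, contact propensity, turn propensity: divided by their table
  maxima — 237.2 (Tyr), 1.43 (Cys) and 2.7 (Pro) respectively; these three
  anchors are asserted at table load.
* Polarity and insertion energy: `1 − 1/(1+e^(−v))`; amphiphilicity uses
  the opposite printed sign, `1 − 1/(1+e^(+v))`.
* Charge: +1 positive (K, R), 0.5 neutral (His included), 0 negative
  (D, E).
* Padding for off-chain window positions: 0 for charge, contact and
  volume; 0.5 for everything else.

The numeric property tables are bundled as editable, versioned data files
(`data/property_tables.json`).  The volume, polarity, contact,
amphiphilicity and turn values are representative defaults in the style of
the standard literature scales (the insertion-energy and hydrophobicity
scales are the well-known published values); the three anchors above are
exact.  Swapping in other tables only requires the anchors to hold.

## Models

scikit-learn's libsvm wrappers, RBF kernel:

* burial classifier (C-SVC): C = 2¹, γ = 2⁻⁴;
* rASA regressor (ε-SVR): C = 2⁻¹, γ = 2⁻⁵, ε = 10⁻³, termination
  tolerance 10⁻².

These defaults are the chain-wise LOOCV optima of the original development
study; a powers-of-two grid search is available but never invoked
implicitly.  Regression outputs are clamped to [0, 1].  No class
weighting; decision values only.  Model bundles persist as tar archives
with JSON metadata (schema version, hyperparameters) and refuse
cross-schema loads.

Training/evaluation residues whose rASA differs between the single-subunit
and complete-complex calculations by more than 10⁻³ (interface residues),
or which have missing atoms, are excluded: their true exposure is
ambiguous from a single-chain sequence.  The 10⁻³ tolerance operationalizes
"identical" for floating-point areas while catching any real contact.

## Synthetic fixtures

* Ideal helix: rise 1.5 Å, twist 100°, Cα radius 2.3 Å (canonical α-helix);
  backbone N, C, O, CB placed at fixed local-frame offsets — adequate for
  parsing, SASA and geometry fixtures, not stereochemically exact.
* Bundles: parallel helices at distinct in-plane positions; ground-truth
  angles follow from construction arithmetic alone (no fitting).
* Profiles: baseline + amplitude·cos((i−1)·100° − φ), optional clamped
  Gaussian noise (a fixture convenience, not a claim about real rASA noise).
* Training sets: 5 chains × 36 residues by default; targets follow a
  planted wheel (baseline 0.4, amplitude 0.4, so both burial classes
  occur), features carry the signal through a synthetic PSSM and the real
  encoder.  All generators are deterministic under a fixed seed.

What passing these tests shows: the machinery (geometry, moment, encoding,
training, cross-validation plumbing) is correct and internally consistent.
What it does not show: predictive accuracy on real membrane proteins —
fixtures have no side-chain packing, no kinks, no real evolutionary
profiles.  The bundled 73-helix benchmark supplies the real-data anchor for
the metrics layer (its angle pairs are inputs; every error, per-chain MAAE,
the 41.04° global MAAE and the distribution counts are recomputed).

## Numerical choices

* Angles canonicalized to [0, 360); the float edge `x % 360 == 360.0` maps
  to 0.
* Printed benchmark values carry two decimals, so recomputed per-helix
  errors are compared within 0.01°, and threshold counts use a 1e-9
  absolute slack (one benchmark error sits exactly at the 100.29°
  boundary).
* MCC with a zero denominator factor is reported as 0 (common convention);
  other undefined ratios are reported as unavailable, never silently 0.
* Alternate locations: highest occupancy wins, ties to file order.
* Residue completeness: a residue is incomplete if any heavy atom of its
  ideal chemical-component composition (terminal OXT excluded) is absent.

## Problem sizes

Default test and reproduction runs use small fixtures — bundles of 2–5
helices of 14–36 residues, 960-point spheres, 180-residue training sets,
1,000 random moment profiles — chosen so the full suite completes in well
under a minute while still exercising every code path at meaningful
precision.

## Known limitations

* Observed angles for severely kinked or broken helices use a single
  global axis and can be off by tens of degrees.
* The bundled property tables are editable defaults; results on real
  sequences depend on the table provenance.
* PSSM/MSA generation (PSI-BLAST, MAFFT) is out of scope; the package
  consumes their standard file formats.
* No mmCIF input, no biological-assembly reconstruction, no membrane-normal
  or tilt estimation.
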