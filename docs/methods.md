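# Methods

## Model

A molecule with A atoms is represented as an A × N *hypershape* matrix:
three Cartesian coordinate columns (Å) followed by F feature columns,
N = 3 + F. Features are arbitrary per-atom real numbers produced by a
named scheme; the same scheme must be applied to every molecule being
compared (enforced by a metadata check at scoring time, which refuses to
score fingerprints that differ in length, scheme, method, or chirality
flag).

The fingerprint is computed in five stages:

1. **Center.** Subtract the column means (the N-dimensional centroid).
2. **Eigendecompose.** Diagonalize the population covariance matrix
   (divisor A, not A−1; eigenvectors are unaffected, eigenvalues are A/(A−1)
   smaller than the sample convention). PCs are ordered by descending
   |eigenvalue|.
3. **Orient.** Eigenvectors are sign-ambiguous, so each PC is oriented by
   a cascade over its projection scores sorted by descending magnitude:
   symmetric ± pairs are skipped, and the first unpaired projection fixes
   the sign (flip if it is negative). If every projection pairs off, the
   cloud has a mirror plane orthogonal to that PC — a linear symmetric
   molecule like acetylene is the canonical case — and the axis is marked
   *undetermined* and left alone; its sign provably does not affect the
   fingerprint, which the test suite asserts to 1e-10.
4. **Reference points.** One point at the center, one per PC at the
   largest positive projection on that PC (times an optional scale
   factor, default 1.0). A zero-variance PC contributes a point at the
   center, duplicating the center distribution, so the fingerprint keeps
   its fixed length 3(N+1) across a comparison set.
5. **Moments.** For each of the N+1 reference points, the Euclidean
   distances in N-space to all atoms form a distribution whose mean,
   population standard deviation, and skewness are recorded — center
   triplet first, then per PC in significance order.

Similarity of two fingerprints is S = 1/(1 + d_M/K) with d_M the
Manhattan distance and K the fingerprint length. Scores of different
dimensionality are never comparable (K differs) and raise an error; for
cross-dimensionality studies the raw Manhattan distances should be used,
and the library exposes them everywhere it exposes scores.

## Chirality

The oriented PC basis has determinant det_f = det_i · (−1)^{n_c}, where
det_i is the determinant of the raw eigenvector matrix and n_c the number
of cascade flips; this identity is asserted on every frame construction.
Mirror-image molecules receive mirror-image frames (identical
fingerprints). With chirality enforcement on, any frame with det_f = −1
gets one extra flip on the PC whose projection scores have the largest
absolute skewness (standardized, population; ties broken by lowest axis
index), making all determinants +1 and the frames of enantiomers no
longer mirror images. Chirality is off by default and is *refused* (with
a warning, frame returned unchanged) whenever any axis is undetermined or
has zero variance: such hypershapes — planar, isotopically uniform along
a feature dimension, or mirror-symmetric — do not have enough significant
PCs for a determinant-based orientation to mean anything. The method
signals *that* two enantiomers differ, not which kind of chirality they
exhibit.

## Parameters

| parameter | default | meaning |
|---|---|---|
| scheme | `default6d` | hypershape columns; also `3d`, `4d`, `5d_isotope`, `5d_charge`, `electroshape4d`, or custom YAML |
| chirality | off | enforce det = +1 frames |
| symmetry_tolerance | 1e-4 | relative tolerance |a+b| ≤ tol·max(1,|a|) for symmetric projection pairs; crystal-structure coordinates carry ~1e-3–1e-4 relative noise, so a tighter default would misclassify real symmetric pairs as asymmetric |
| skewness_convention | standardized | m₃/m₂^1.5 with sign; `cbrt` (cube root of the third central moment) is available for strict emulation of the older USR literature |
| reference_scale | 1.0 | multiplier on reference-point distances from the center |

Feature values are used raw by default — the unit is absorbed by an
implicit 1/unit conversion constant — because no principled universal
scaling exists. Autoscaling (mean-center, unit variance per dimension) is
offered only as an explicit utility over a *pooled* molecule set:
autoscaling each molecule independently destroys absolute information
(e.g. the proton-count distinction between PH₃ and NH₃). Zero-variance
dimensions are centered but not scaled.

## Numerical choices

- Eigenvalue ties (within 1e-9 relative) are ordered by the larger
  maximum |projection|, then original column order, so symmetric
  molecules get deterministic frames.
- A single atom or an all-identical cloud yields an identity basis, zero
  eigenvalues, and a degenerate-frame flag rather than an error; every
  moment triplet is then (0, 0, 0).
- Skewness is defined as 0 whenever the variance is 0 (relative floor
  1e-24 on m₂) to avoid 0/0 amplification on numerically constant
  distributions.
- All heuristic atom selections in the USR-family baselines break ties by
  lowest atom index and record that a tie occurred, since tie-dependent
  reference points are a documented source of input-order-dependent
  scores; the CSR cross product falls back to the USR ctc point (with a
  warning) when ctd/ftc/ftf are collinear.
- The subset (USRCAT-style) fingerprint gives an empty atom-type subset a
  block of 12 zeros, keeping fingerprint length fixed across a set. The
  bundled predicates are deliberately simple element-based rules
  (hydrophobic = C + halogens, donor = N/O, acceptor = N/O/F, aromatic =
  passthrough of a user-supplied flag), *not* the Credo SMARTS types:
  connectivity-derived typing is exactly what breaks for molecules
  outside standard valence rules, and the predicate interface is
  pluggable for users who need a specific typing.

## Synthetic fixtures: what they show and what they do not

All tests run on programmatically generated molecules (pure functions of
a seed), written to real SDF/XYZ files so the I/O path is always
exercised. The fixtures emulate the *geometric and feature structure* of
the relevant phenomena, not chemical realism:

- The **torsion sweep** is a point-cloud mechanism study: a rotor atom
  sweeps a narrow dihedral window (±0.10 rad, 21 steps) centered — by
  bisection, per seed — on the exact angle where it overtakes a rival
  atom as USR's farthest-from-ftc reference. Dedicated anisotropy anchor
  atoms keep the PC frame stable across the window. This isolates the
  discontinuity mechanism (reference-atom switching) cleanly; real
  conformer ensembles mix it with frame rearrangements and larger
  geometry changes.
- The **isotopologue/protonation series** use idealized zigzag
  heavy-atom amine chains (1.5 Å bonds, 111° angles, no explicit
  hydrogens except the added proton). They demonstrate the dimensionality
  logic — a ¹³C label invisible in 3D/4D, visible in 5D with an effect
  that shrinks as the chain grows; Manhattan distances ordered
  3D < 4D < 5D for protonation while scores need not be, because K
  changes with N — but the magnitudes are fixture-specific.
- The **chiral tetrahedron** is the minimal chiral cloud; enantiomer
  discrimination on it is tested with the pure-3D scheme, since a 4-atom
  cloud has rank ≤ 3 and any higher-dimensional scheme necessarily leaves
  zero-variance axes, for which chirality is (by design) refused.

Passing these tests therefore establishes the method's invariances
(rigid motion, atom permutation, reflection handling), its continuity
advantage over atom-anchored references, and its feature-dimensionality
semantics. It does not establish screening performance on real compound
libraries, which depends on conformer quality and feature choices outside
the scope of the fixtures.

## Problem sizes

The test suite uses clouds of 4–12 atoms, 1,000 random clouds for the
determinant-identity sweep, 100 rigid motions per invariance fixture, and
20 seeds × 21 conformers for the continuity contrast; the whole suite
runs in a few seconds. The acceptance script fingerprints a 12-atom cloud.

## Known limitations

- No conformer generation, bond perception, sanitization, or charge
  computation: the point cloud is taken exactly as supplied (including
  hydrogens), and partial charges for the ElectroShape-style scheme must
  be provided by the user.
- SDF support is V2000 only; V3000 files are rejected explicitly.
- Near-degenerate eigenvalues make the PC ordering itself unstable under
  small perturbations; the tie-breaks make the output deterministic for a
  given input but cannot make the frame continuous *across* an eigenvalue
  crossing. This is inherent to any PCA-based frame.
- The most-common-isotope table comes from RDKit's periodic table; for
  elements with near-equal isotope abundances the choice is RDKit's, not
  a claim of this package.
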