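# Methods

## Descriptor definition

The R-GETAWAY autocorrelation is computed exactly as

R_k(w) = Σ_{i<j} [ √(h_ii h_jj) / r_ij ] · w_i w_j · δ(k; d_ij)

with every atom — hydrogens included — participating. The pieces:

- **Leverages.** Coordinates are centered on the unweighted geometric mean
  (geometric, not mass-weighted, centering: the influence matrix is defined
  on the centered molecular matrix and nothing in the descriptor's
  definition weights the centroid). H = M(MᵀM)⁻Mᵀ uses the Moore–Penrose
  pseudo-inverse so planar and collinear geometries — where MᵀM is rank
  deficient — are handled without special-casing; trace(H) then equals the
  coordinate rank (3 generic, 2 planar, 1 collinear). No truncation is
  applied to small leverages. `influence_matrix` rejects non-centered input
  (column mean above 1e−6 of the coordinate scale) rather than silently
  re-centering, so the contract is visible at the call site.
- **Topological distances.** Exact integer bond-count distances by
  breadth-first search from every atom (scipy.sparse.csgraph). Disconnected
  fragments get infinite distances, which never satisfy δ; no tolerance is
  applied to δ.
- **Weights.** `mass` uses IUPAC conventional standard atomic weights
  divided by carbon's (H → 0.0839, S → 2.669); `unit` uses 1. Isotopes are
  not supported. (rdkit's GETAWAY, used as a cross-check in the tests,
  carries Dragon's 3-decimal rounded mass ratios, which shifts R3m by
  ~1e−3 on typical molecules; this package keeps full precision.)
- **Degenerate geometry.** Two coincident atoms on a pair that would
  contribute (r_ij = 0) raise an error rather than being skipped: silent
  skipping would mask corrupt coordinates.
- **Per-atom decomposition.** Each pair term is split half-and-half between
  its two atoms. The split is a convention — any convex split conserves the
  total — and the symmetric one is the only choice that respects atom
  exchange within a pair. Contributions therefore sum to the descriptor
  value to 1e−10, and element-class percentages (e.g. the N/O/S share) are
  sums of these halves.

Useful exact properties, all enforced by tests: rigid motions leave R_k
unchanged; relabeling atoms leaves it unchanged; uniform scaling of the
coordinates by s scales it by exactly 1/s (leverages are scale-invariant,
r_ij is not).

## Structure handling

SDF/MOL (V2000, explicit bond block), XYZ and PDB are parsed directly; the
parsers are deliberately small, report the offending line number on
malformed input, and never attempt valence or aromaticity perception.
Multi-record SDF and multi-MODEL PDB become conformer ensembles and must
share one topology. XYZ carries no connectivity, so bonds are perceived by
the covalent-radius rule r_ij < 1.2 × (rcov_i + rcov_j) with Cordero
single-bond radii; the 1.2 factor is configurable and any chemically
sensible rule serves, since descriptor lags are short and tree-like
perception errors would surface immediately in the distance matrix.
Molecules are assumed whole (no periodic-boundary unwrapping). Atom indices
are 0-based internally; file formats keep their native 1-based indices at
the boundary.

## Conformer distributions

Frame selection mirrors equilibrated-trajectory sampling: `count` equally
spaced times inclusive of both window endpoints (7 frames across a 300 ps
window → 50 ps spacing); a single frame returns the window end. Distribution
summaries use type-7 (linear interpolation) quartiles and MATLAB-style
1.5 × IQR whiskers — whiskers reach the most extreme sample points inside
the fences, everything beyond is an outlier. Threshold exceedance uses
strict ">". Value-set comparisons report mean |Δ|, the fraction within a
configurable |Δ| threshold (default 0.05), and the OLS slope and R² of one
set on the other.

## The dispersibility model

`predict_probability` evaluates P = expit(β₀ + β₁·x) with the numerically
stable scipy expit; `r3m_at_probability` inverts it exactly. The published
coefficients (−46.79, 74.01) are printed, rounded values: the implied
probability bands are <1% below 0.570 and >99% above 0.694. The upper cut
is sometimes quoted as 0.693, which only follows from unrounded
coefficients; this package recomputes both cuts from whatever coefficients
the model object carries, so the band logic is always self-consistent, and
the CLI notes the 0.693 convention in a report footnote.

Refitting uses iteratively reweighted least squares on the Bernoulli
log-likelihood: convergence when the log-likelihood changes by less than
1e−10, hard stop (an error, never partial results) at 100 iterations.
Working weights are floored at 1e−12 for stability. Complete separation is
detected two ways — perfect in-sample classification by a threshold, or the
coefficient norm passing 1e3 during the iterations — and yields a flagged
model (coefficients from the last stable iteration) plus a warning steering
the caller to the midpoint rule, which is the correct estimator for
separated data: boundary = (max failing value + min dispersing value)/2.
Diagnostics are the log-likelihood, the intercept-only null log-likelihood,
McFadden's pseudo-R² = 1 − LL/LL₀ (the definition is a documented choice;
other pseudo-R² variants are out of scope), the likelihood-ratio
χ² = 2(LL − LL₀) on 1 df, and Wald standard errors from the inverse Fisher
information. Classification uses strict ">" at the boundary, so a value
exactly on the boundary is conservatively labeled as failing.

When conformer distributions are fitted, every conformer of a compound
carries that compound's single experimental 0/1 label, unweighted — 15
compounds × 840 conformations = 12,600 observations.

## Synthetic data

The generators replace two inputs that cannot be recomputed here: the
molecular-dynamics conformer ensembles (the MD engine and force field are
commercial) and the labeled descriptor dataset behind the fitted model.

- **Chains and rings** have closed-form answers: a collinear chain's
  leverages reduce to x_i²/Σx², giving exact R_k values (C4 chain → 0.15,
  C5 chain → 2/15) computed independently of the production path; a planar
  regular n-ring has uniform leverages 2/n.
- **Torsion ensembles** twist each rotatable (bridge, non-terminal) bond by
  an independent uniform angle within ±max_twist per conformer, rigidly
  rotating one side so bond lengths are preserved exactly. The default
  layout is 3 cells × 7 frames × 40 molecules = 840 conformations per
  compound, matching the study bookkeeping. Uniform (not Boltzmann) torsion
  sampling is intentional: these fixtures exercise descriptor plumbing and
  distribution statistics, not thermodynamics, so passing tests demonstrate
  correctness of the computation, not realism of amorphous-state
  conformational populations. Features of real MD they do not emulate:
  correlated torsions, excluded volume, intermolecular packing, bond-angle
  relaxation.
- **Labeled datasets** draw x ~ Uniform(0.55, 0.72) — the descriptor range
  where the logistic curve actually moves — and labels ~
  Bernoulli(expit(β₀ + β₁x)). With n = 5000 the refit recovers both
  published coefficients within 3 standard errors and the 0.632 boundary to
  ±0.01; that checks the estimator, not the original data.

All generators take a single integer seed and hold no global state; the
same (parameters, seed) pair is reproducible bit-for-bit.

## Problem sizes and numerical choices

Everything here is desk scale: molecules of tens of atoms, ensembles of
hundreds of frames, fits of a few thousand points — chosen because every
quantity being checked (closed-form descriptor values, invariances,
estimator recovery) is already fully determined at that size. Double
precision throughout; the leverage matrix is explicitly symmetrized after
the pseudo-inverse product to remove rounding asymmetry; dihedral angles
use the atan2 construction on the (−180, 180] branch and refuse collinear
triples.

## Known limitations

- The descriptor family implemented is the R autocorrelation over k and
  {mass, unit} weights only — not the full GETAWAY battery (H/HATS indices,
  ITH, ISH).
- The model is univariate and PVPVA-specific; other polymers, drug
  loadings, or ternary formulations are out of scope.
- Single-conformation crystal-structure anchors (e.g. polymorph pairs from
  the CCDC) require structures that cannot be redistributed here; the
  descriptor conventions they would pin down (notably hydrogen inclusion)
  are instead fixed by definition and cross-checked against an independent
  GETAWAY implementation.
- Bond perception is purely geometric; unusual coordination or very
  distorted geometries can mis-perceive, which shifts topological distances
  and hence the descriptor.
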