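# Methods

This note documents the models, numerical choices and limitations behind
`fatiguenet`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Network construction

For one effort intensity, the analysis slice holds one row per participant
and one column per variable (9 per-test variables plus 4 subject-level
ones; subject-level variables differ across participants, so they
correlate legitimately within an intensity slice). Every unordered pair is
assigned a Pearson coefficient; a constant column makes the coefficient
undefined and the variable is kept as an isolated node with a warning
rather than dropped, so the node set is stable across intensities.

Classification uses magnitude thresholds 0.3 (weak/moderate) and 0.7
(moderate/high). The defining inequalities are strict on both sides, which
leaves the boundary magnitudes unassigned; we assign boundaries to the
stronger class (closed lower bounds). This is deterministic, documented,
and of measure zero for continuous data. Thresholds are configurable,
which also enables the monotonicity property test (raising the link
threshold can only remove links).

Link weights are correlation magnitudes: negative correlations link by
|r| (the sign is preserved in the emitted correlation records for
reporting, but a strong negative correlation is as much of a connection as
a strong positive one). Two weight modes exist because two conventions are
in circulation: `raw` (weight = |r|, so r = 0.75 is a 75%-influence link)
and `max_normalized` (weight = |r| / max |r| over links, so the strongest
link has weight 1). `raw` is the default; the report records the mode.
With n = 9 participants, |r| ≥ 0.3 occurs easily by chance (the two-sided
p-value of r = 0.3 at n = 9 is ≈ 0.43), so small-cohort networks carry
many spurious links; the pipeline logs a warning whenever n ≤ 12. No
multiple-testing correction is applied — thresholding, not inference, is
the construction rule.

## Influence metrics

*Degree* counts strictly positive off-diagonal entries of the node's row.

*Eigen-influence.* Attributing one eigenvalue to each node is not
mathematically meaningful (eigenvalues belong to the matrix), so node-level
influence is operationalised as eigenvector centrality: the magnitude of
the node's component in the eigenvector of the algebraically largest
eigenvalue, rescaled to a maximum of 1. For a nonnegative symmetric C the
largest eigenvalue equals the spectral radius and the eigenvector can be
taken nonnegative (Perron–Frobenius); we fix the sign so the
largest-magnitude component is nonnegative. The empty graph has no
meaningful direction and gets all-zero scores. The full spectrum and the
spectral radius are reported at network level. This operationalisation is
the one consistent with the state dynamics below, whose asymptotic
direction is exactly that eigenvector.

*State dynamics.* S(t) = C^t S(0), computed by iterated multiplication.
The statement "each node's state evolves as its eigenvalue to the power t"
holds only along eigendirections, not componentwise; what is true in
general is that ‖S(t+1)‖/‖S(t)‖ → ρ(C) for generic starts (on non-bipartite
link topologies) and that ρ > 1 / ρ < 1 separates unbounded growth from
decay. `stability_class` encodes that trichotomy with tolerance 1e-9
around ρ = 1.

*Betweenness* is computed on the binarised (unweighted) graph: the weights
are influence strengths, not distances, and no distance transform is
specified by the construction, so weighted-geodesic betweenness is
deliberately not offered. Default counting is fractional (Brandes-style:
each source–target pair distributes one unit over its geodesics),
endpoints excluded, unordered pairs; an `integer` mode counts raw numbers
of geodesics through the node instead. Disconnected pairs contribute
nothing. Both modes are verified against independent implementations
(networkx; exhaustive path enumeration) on random graphs.

*Ranking* reports the complete argmax set per metric (ties sorted by node
name, relative tolerance 1e-9) — never a silent first-wins.

## Critical-power model

t_lim = AWC / (P − CP), P > CP. AWC is held in joules internally;
kilojoule output is an explicit conversion. Two estimators:

- `fit_linearized`: OLS of P on 1/t (slope AWC, intercept CP). Exact on
  noiseless data, and the default initialiser for the nonlinear fit.
- `fit_hyperbolic` (default in the pipeline): nonlinear least squares on
  t-residuals with CP bounded below the minimum observed power (the model
  is undefined otherwise); an infeasible initial CP is projected into the
  feasible region with a warning.

The two agree to ≤ 1e-6 relative on noiseless data (tested). Because the
estimators are nonlinear in the data, parameters fitted to group-mean
(P, t) pairs do not equal the mean of per-participant parameters; no such
equality is asserted anywhere. Trial durations outside the 2–10 min window
conventionally recommended for the two-parameter model trigger a warning,
not an error, since realistic high-intensity trials sit near the lower
edge. Cohorts simulated without physics consistency have no hyperbolic
structure across a participant's four tests, so pipeline CP fits on such
data are exercises of the machinery, not recoverable parameters; recovery
is demonstrated on physics-consistent and forward-simulated data.

## Group statistics

One-way ANOVA is computed from explicit between/within sums of squares
(the defining identity) with p from the F(k−1, N−k) distribution. The
same nine subjects are tested at every intensity, but the comparison is
deliberately plain one-way (not repeated-measures), matching the
table-footnote convention of the study design emulated here.

SNK: group means are ordered; a span of p means is tested with the
studentized-range critical value q(α, p, N−k) (scipy's
`studentized_range`, accurate to well below 1e-6 at these levels); a
significant span declares its extreme pair different and opens its two
(p−1)-spans; a non-significant span seals all pairs inside it. Unbalanced
groups use the harmonic mean n (the design here is balanced; this is a
robustness extra). Letters follow the table convention: group i is
annotated with the letter of every group it differs from ("a" = group 1,
"b" = group 2, …). The pairwise difference set is symmetric by
construction; the displayed letters are its per-group projection. With
zero within-group variance the q statistic is undefined; any mean
difference is then declared a difference.

## Synthetic cohorts

The generator emulates the study design the analysis assumes: n
participants (default 9) × four intensities, per-intensity means/SDs
defaulting to the group statistics of a tethered-running cohort (mean
power rising 248→512 W, time to exhaustion falling 626→174 s across
intensities; subject-level CP 139.26 W, AWC 47.14 kJ, lean mass 91.49%,
IPAQ 2106.66).

*Distributional family.* The raw measurements' family is unknown; a
multivariate-normal backbone is the simplest family matching the
mean/SD/correlation structure the analysis consumes. Variables are ordered
subject-block-first and drawn via the Cholesky factor of the target
correlation matrix: subject latents are drawn once per participant, so the
subject block of the factor (which only touches them) makes those
variables exactly constant across a participant's rows while preserving
their correlations with the per-test variables at each intensity. This
requires the subject×subject block of the target to be identical across
intensities (validated).

*Correlation targets.* No inter-variable correlation matrices are
published for this kind of dataset, so targets are user configuration. The
default is an explicitly synthetic, plausible structure (mechanical
variables at 0.6, endurance-related pairs 0.45–0.55, physiological pairs
0.3–0.4, background 0.15) — adequate for exercising the pipeline, not an
estimate of anything. Hand-built targets (including the default and all
planted-hub targets) are validated for symmetry, unit diagonal and
eigenvalues ≥ −1e-10; failing matrices are either rejected (user targets,
with the offending eigenvalue in the message) or repaired by clipping
eigenvalues at 1e-8, reconstructing and renormalising the diagonal
(constructed targets, with the repair recorded in the config). Note that
an "arrow" matrix with one hub row at 0.8 and background 0.1 over 13
variables is *not* PSD — the repair is the normal path for planted-hub
targets and shrinks the effective hub correlation to ≈ 0.46 against a
≈ 0.14 background, still cleanly separated by the 0.3 link threshold.

*Positivity.* All quantities are physical and must be positive; rows with
any non-positive draw are redrawn (subject rows against the subject block,
per-test rows against the per-test block, conditional on the participant's
subject latents), with a bounded retry count. For variables whose
configured mean sits within ~3 SDs of zero (anaerobic capacity and IPAQ
at ≈ 1.8 SD, lactate time at higher intensities) this truncation shifts
the realised mean a few percent above the configured value; the
calibration tests compare such variables against a brute-force
rejection-sampling reference rather than pretending the constraint is
free.

*Physics consistency* (off by default) overwrites mean power with
force × velocity, time limit with AWC/(P − CP) from the participant's own
capacities, and work with P × t/1000, each optionally perturbed by
relative Gaussian noise; rows whose power does not exceed the
participant's CP are redrawn, and persistent failure names the
participant. With zero noise the identities hold to machine precision
(tested). The default is off because the identities distort the marginal
means/SDs away from the calibration targets; it exists for recovery
studies of the CP fitters and for generating mechanically coherent data.

*Determinism.* One `numpy` Generator seeded from the config drives every
draw, including resampling loops, so a fixed config is byte-identical
across runs (tested at CSV level and at full-report level).

## What the generator does and does not emulate

It reproduces the study-design shape (complete participant × intensity
grid, constant subject-level variables), the published group means/SDs,
any specified correlation structure, and optional mechanical identities.
It does not emulate: non-Gaussian marginals (lactate and IPAQ
distributions are typically right-skewed beyond what truncation induces),
within-test time-series structure (signals are summarised per test),
participant-level random effects beyond the subject-block correlations,
or any dependence between intensities other than through subject-level
variables. Passing tests therefore show the pipeline is correct and
recovers planted structure under the stated statistical conditions — not
that real tethered-running data satisfy those conditions.

## Problem sizes and numerical choices

Recovery and calibration studies use: n = 500–40,000 participants for
generator moment/correlation checks; 100 seeds × n = 200 for hub
recovery; 1000 replicates for CP noise recovery; 10⁴ replicates for the
ANOVA type-I calibration; 200 random graphs of ≤ 8 nodes for metric/oracle
equivalence. Tie detection uses relative tolerance 1e-9; stability uses
1e-9 around ρ = 1; eigen residuals are held to 1e-10·‖C‖. Report JSON
rounds to 6 significant digits with a full-precision sidecar
(`report.full.json`) for byte-exact comparisons.

## Known limitations

- Exact reproduction of any specific published network (link counts, hub
  identities per intensity) is impossible without the underlying raw
  measurements, which are not deposited; the pipeline's claims are
  property-based (oracle equivalence, planted-structure recovery,
  calibration) plus the exact weighting-rule example.
- Betweenness ignores link weights (see above).
- The SNK procedure controls error rates stepwise, not family-wise in the
  strong sense; that is inherent to the method, not to this
  implementation.
- GraphML export is not provided; the link-list CSV and labelled matrix
  CSV are the interchange formats.
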