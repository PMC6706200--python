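# Methods

This note records what the package computes, the modelling assumptions, the
defaults and why they were chosen, and what the synthetic-data tests do and
do not establish.

## From detections to movements

A detection is one time-stamped record of a transmitter at a receiver.
Receiver clocks are assumed exact at deployment and off by a measured
offset at retrieval; the correction removes a linearly accruing error
(positive offset = clock ran fast, so timestamps shift back by
`offset × elapsed/deployment`). False-detection screening uses the
conservative short-interval rule for coded transmitters: a detection is
rejected when no other detection of the same transmitter occurs at the same
receiver within ±1 h (both the window and the neighbour count are
configurable). The literature this rule descends from does not fix
parameters; ours are explicit configuration, and the flag is idempotent by
construction (neighbour counting always uses all records, and the flag only
ANDs onto the existing one).

The first 24 h of each fish's record after release are discarded (handling
stress). Runs of consecutive detections at one receiver are collapsed to
residence events; a movement is the transition between two successive
residence events at different receivers, with departure the last detection
at the origin and arrival the first at the destination. Transits under
4 min are removed as detection-range overlap artefacts, and removal does
**not** chain the neighbouring events into a longer movement — a filter
that merged endpoints would fabricate paths that were never observed.

"Day" always means a local calendar date (default `Europe/Stockholm`;
timestamps are stored UTC). Days monitored is the difference between the
study-end date and the release date — the convention that reproduces the
published days-at-liberty arithmetic for this design (15 Aug 2015 →
18 Jan 2016 = 156). Whether the 24-h window should also be subtracted is
not decidable from the published table; it is not subtracted here.
Residency index RI = days detected / days monitored ∈ [0, 1]; movement
index MI = movements / days detected, computed after the transit filter.

Exclusions mirror the study: fish with no detections left after the 24-h
window ("left the array"), then fish with detections but no movements.

## Networks and weekly metrics

Movement networks keep all receivers as nodes (isolated ones included) so
the node count — and hence the triad-census denominator — is constant.
Directed networks weight each ordered receiver pair by its movement count;
undirected networks pool both directions. Node strength is the sum of
incident edge weights, degree the number of distinct neighbours; both are
computed on undirected weekly (7 × 24 h) networks per fish, starting from
25 Aug 2015 by default, and summed across receivers. Summing "across all
receivers" counts every edge twice (once per endpoint); the doubling
convention is fixed so model coefficients are comparable run to run. A
trailing partial week is dropped by default. Weeks without movements yield
0/0 rows and are kept — they carry the zeros the zero-inflated degree
model is for.

## Triad census

Every unordered receiver triple induces a 3-node sub-digraph classified
into the 16 Davis–Leinhardt classes (003, 012, 102, 021D, 021U, 021C,
111D, 111U, 030T, 030C, 201, 120D, 120U, 120C, 210, 300), numbered 1–16 in
that standard census order, so class 1 = 003 is the "no movement" triad.
Edges are binarised (≥1 movement) before classification. The fast census
classifies each triple through a 64-entry lookup over the six possible
ordered edges; the table is built at import time by brute-force
isomorphism against canonical exemplars, so the fast path cannot drift
from the definitions. The test suite keeps an independent triple-by-triple
brute-force enumerator and cross-checks a reference graph-library census.
Monthly per-fish censuses (movement month = local departure date) join the
month's mean SST; "relative abundance" is modelled as raw counts (the /165
normalisation is a constant and would only shift the intercept).

## Count mixed models

Weekly node strength is modelled as NB2 (Var = μ + μ²/θ) with log link,
fixed environmental effects and a per-fish Normal random intercept; weekly
degree uses the zero-inflated variant with an intercept-only structural-zero
logit (no ZI covariates are identified by the design) and the random
intercept in the count part. The marginal likelihood integrates the random
effect per subject by adaptive Gauss–Hermite quadrature: the conditional
mode is found by a damped Newton iteration (finite-difference derivatives,
warm-started between evaluations), nodes are recentred and rescaled by the
mode curvature, and 15 nodes are used by default — estimates move by less
than 1e-3 between 15 and 25 nodes on the reference fixtures. The NB log-pmf
is written in `log1p` form so the Poisson limit (θ → ∞, available via
`fixed_theta`) stays numerically stable. Optimisation is L-BFGS-B over
(β, log θ [, logit π], log σ_b); standard errors are Wald, from the
numerical Hessian at the optimum; p-values are two-sided. No
multiple-testing correction is applied across the 16 motif models. On a
frozen fixture the fitter agrees with an independent TMB-based mixed-model
implementation to ~3 decimals in estimates and standard errors; fits that
do not converge are flagged, never silently returned.

Environmental covariates enter as weekly means; wind speed is
log-transformed and PAR square-root transformed, wind direction is kept as
a linear covariate in degrees (a sin/cos circular encoding is available but
off by default, to keep the per-degree coefficient of the reference model
shape). Collinearity is screened by iterated VIF (drop the worst predictor
above 3, recompute); the reference model formulas themselves are fixed
configuration (strength ~ SST + log wind speed + wind direction; degree ~
SST + wind direction), with the VIF table emitted as a diagnostic.

Seasonal contrasts in relative daily movements (movements per day / fish
detected per day; days with no fish detected are missing, not zero) use
Welch's heteroscedastic F and Games–Howell post hocs via the studentized
range distribution. Note that the "Welch reduces to classical F" identity
under equal variances and sizes holds only asymptotically — the Welch
denominator is 1 + O(1/n) — so the equivalence test uses n = 200 per group.
Spearman correlations use tie-corrected ranks with seeded-permutation
p-values (exhaustive enumeration for n ≤ 8).

## Synthetic generator

Fish occupy discrete receiver *zones*; the analysis only observes
receiver-level presence, so continuous-space simulation would add cost
without testable structure. Defaults encode the study conditions: 48 fish
(lengths truncated-Normal 29.8 ± 5.2 cm on [16, 47], cubic length–weight
with lognormal scatter), staggered mid-August releases at two sites, 11
receivers (ranges 216 m unvegetated / 94–114 m seagrass), study period
15 Aug 2015 – 18 Jan 2016, ping intervals U(30, 90) s, detection
probability 0.6 per ping (the convention by which the printed ranges were
defined). Daily SST follows a logistic decline calibrated so the three
season windows average 16.3 / 9.4 / 3.7 °C, plus N(0, 0.8²) daily noise.
Movement is a continuous-time jump process with per-fish departure rate
`exp(β₀ + b_i + β_SST·SST(t))` per day, β₀ = −4.8, β_SST = 0.25,
σ_b = 0.6 — the temperature effect matches the scale of published weekly
connectivity models, and β₀ puts the realised movement total (~1200 from
48 fish) at the order observed in the field (838 from 39). Destinations
are uniform over graph neighbours: within-site cliques plus exactly two
between-site corridor pairs, which is what keeps higher-order motifs rare.
Inter-zone travel is an undetectable dead-time U(5, 30) min — receivers
are hundreds of metres apart and juvenile cod cruise at tens of cm/s, and
the dead-time also ensures genuine transits are not destroyed by the 4-min
overlap filter. Permanent departure (emigration and mortality are not
distinguishable in this design and are not distinguished here) has hazard
0.01/day. PAR tracks SST tightly and sea level is a season + wind
composite, giving the collinearity screen realistic structure.

What the generator does *not* emulate: detection-probability decay with
range and weather, tag collisions and code false-positives (the QC screen
is exercised by construction, not by realistic noise), tidal/diel
behaviour, depth use, and movement during the undetectable transit. Passing
tests therefore show the pipeline computes its quantities correctly and
recovers known generative parameters — not that the biological conclusions
transfer to any particular field dataset.

## Problem sizes and numerical choices

Test fixtures scale the cohort (not the study conditions) — e.g. 8 fish
over the full period (~0.8 M detections) for pipeline tests; parameter
recovery uses the reference design of 40 subjects × 21 weeks over 50
replicates. Degenerate inputs are explicit: all-zero responses and
zero-free responses for the ZINB are reported non-estimable; constant
motif classes are reported, not fitted; zero-variance groups are rejected
by the comparison tests; empty networks yield zero metrics and an all-null
census. Ties in ranks use average ranks. The optimizer's objective trace
is recorded on every fit and asserted monotone in tests.

## Known limitations

- The random-intercept integral is one-dimensional by design; crossed or
  nested random effects are out of scope.
- Wald inference can be optimistic for variance parameters near zero; only
  fixed-effect inference is exposed prominently.
- The movement index counts post-filter movements; if a published table
  counted pre-filter movements the MI (not RI) could differ slightly.
- Weekly environmental joins align by week start date; sub-weekly
  misalignment between metric weeks and environmental weeks is not modelled.
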