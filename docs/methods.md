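# Methods

This note documents the models, numerical choices and open design
decisions behind `gagprofiler`, and what the synthetic-data tests do and
do not demonstrate about real spectra.

## Composition model

A component is a residue-count tuple
`[ΔHexA, HexA, GlcN, Ac, SO3, Levoglucosan, Anhydromannitol]` under the
residues-plus-one-water mass convention (neutral monoisotopic mass =
Σ residue masses + H₂O). Residue formulas: ΔHexA C₆H₆O₅ (158.02152 Da),
HexA C₆H₈O₆ (176.03209), GlcN C₆H₁₁NO₄ (161.06881), acetyl +C₂H₂O
(42.01057), sulfate +SO₃ (79.95682), levoglucosan C₆H₈O₄ (144.04226),
anhydromannitol C₆H₁₀O₄ (146.05791). Element masses are IUPAC
monoisotopic values; the proton mass 1.00727646 Da is used for
`[M − zH]z⁻` arithmetic and 1.0033548 Da for isotope-ladder spacing.

The enumeration rules encode standard heparin chain chemistry: an
alternating chain implies |uronic − hexosamine-type| ≤ 1 (anhydromannitol
counts as a hexosamine-type reducing end); at most one ΔHexA
(lyase-generated unsaturated end); levoglucosan and anhydromannitol are
mutually exclusive reducing-end artifacts; Ac ≤ GlcN; and sulfation is
capped at 3 sites per GlcN (N/3-O/6-O), 1 per uronic acid (2-O) and 2
per anhydromannitol. There is no standard, published rule set for
this enumeration; ours is documented, configurable
(`CompositionRules`) and produces 15,355 compositions in 200–4,000 Da,
so fit statistics that depend on the universe (below) are treated as
approximate.

Neutral losses SO₃, NH, NHSO₃ and COO (taken as CO₂ — it reproduces the
worked-example rows within tolerance, CHO₂ does not) are expanded up to
2 groups per ion, bounded by availability: SO₃-containing losses by the
sulfate count, NH-containing losses by free (non-acetylated) amines,
CO₂ by uronic-acid count.

## Isotope engine

Aggregated isotopologue abundances are the coefficients of
Π_e Q_e(x)^{n_e}, where Q_e is element e's isotope-abundance polynomial
indexed by nominal mass shift (S-36 enters at shift +4). Coefficients
are computed by the BRAIN-style Newton–Girard recursion over power sums
of the inverse roots of the elemental polynomials: c₀ = Π a_{e,0}^{n_e},
c_j = −(1/j) Σ_{l≤j} ψ_l c_{j−l} with ψ_l = Σ_e n_e Σ_roots r^{−l}.
Cost is O(k²) in the number of requested peaks and independent of
molecule size; the per-element power sums are precomputed once, so the
recursion vectorizes across hundreds of thousands of formulas. Tests
pin the engine against a direct polynomial-convolution oracle at 1e-9.

The **intensity model** used for cluster screening fits one degree-4
polynomial per isotopic-peak index (1st–5th) against neutral mass over
200–4,000 Da: compositions are enumerated, 70 are sampled evenly by
mass (stratified over 70 equal-width bins, one uniform draw per
occupied bin), each sample's first five abundances are renormalized to
sum 1, and ordinary least squares is run on mass/1000 for conditioning.
Mean R² across the five curves is ≈0.84–0.87 depending on the sampling
seed; the scatter is real (sulfur content varies at fixed mass), which
is why the second-peak curve fits worst. Predictions are clipped to
[0, 1]; outside the fitted range the filter falls back to an exact
distribution for a GAG-averaged CHNOS composition of that mass.

**Similarity** is 1 − JS(p, q) with the base-2 Jensen–Shannon
divergence (bounded in [0, 1]); distributions are renormalized before
comparison, and truncation to a cluster's member count happens before
renormalization.

## Detection, matching, selection

Cluster extraction grows runs rightward from each seed peak at spacing
1.0033548/z within 20 ppm (nearest peak per step, ≤5 members, ≥3 to
emit); a seed with a matching peak one spacing to its left is skipped,
so the monoisotopic peak is the leftmost member. Two non-obvious
choices:

- **Nested-ladder suppression.** The alternating peaks of every z=2
  envelope are spaced exactly 1.0033548 and form a legitimate z=1
  candidate whose truncated distribution also passes the 0.9 similarity
  screen. Candidates whose members are a subset of a higher-charge
  candidate's members are therefore dropped at extraction. Genuine
  co-eluting envelopes of distinct species overlap only partially and
  are unaffected.
- **Peak-level explanation.** During greedy selection the explained set
  is tracked as member *peaks*; a cluster counts as explained once all
  its peaks are. For disjoint clusters this is identical to tracking
  clusters, but it prevents any surviving shared-peak ladder from
  rewarding a spurious component after the true component has claimed
  the peaks.

Matching pairs a cluster with every equal-charge theoretical ion whose
k-th isotopic peak (k ≥ 0, smallest k wins) lies within 20 ppm of the
cluster's monoisotopic m/z; the ion's distribution is aligned at offset
k before computing JS. The theoretical ion space is held in a
per-charge sorted index, so matching is a few binary searches per
cluster (≈400k ions are routine).

Greedy selection maximizes marginal gain, breaking ties toward the
lexicographically smaller composition, stops at zero gain, and returns
the prefix with maximal Sg = αⁿ·Σ gains (α read as a power — with
α = 0.99 < 1 this penalizes selection size, which matches its stated
role; a multiplicative α·n would reward size). The greedy prefix is a
heuristic, not a global optimizer: when one candidate has the largest
single gain but its coverage is contained in the union of two others,
an exhaustive search over subsets can beat it (a 3-candidate,
5-cluster instance suffices). Tests therefore assert equality with an
exhaustive oracle on the toy worked instance and on disjoint-coverage
instances (where equality is a theorem), and the bound
`greedy ≤ optimum` in general.

## Calibration

The shift model is a constant additive m/z offset (not ppm-linear),
estimated from the five most intense peaks pre-matched against the
monoisotopic m/z of intact (loss-free) candidate ions. Every index
value within 0.05 Th of an anchor yields a candidate signed difference;
the difference supported by the most anchors (each contributing its
closest difference within a 0.002 Th consensus window) wins, and the
applied shift is the median of that consensus set — the minimizer of
the summed absolute differences. Two details matter in practice: the
loss-expanded index is ~6× denser than the intact-only index and makes
nearest-neighbour differences meaningless (~500 ions/Th in a dp4
window), and a plain nearest-match median under-corrects for the same
reason. With consensus + intact-only anchors a ±0.005 Th synthetic
shift is recovered to ≲1e-9 on clean fixtures and exactly (to the
anchor scatter) on noisy ones.

## Significance

For each scored candidate, n is the number of its theoretical isotope
peaks (all charges, all losses, 5 per ion) inside the experimental m/z
span, k the number of distinct theoretical peaks matched, and
p_m = Σ 2·ppm·10⁻⁶·mzᵢ / span the per-peak random-match probability
(windows summed, not union-merged — for very dense ladders this
overestimates p_m, i.e. is conservative). The p-value is the binomial
survival function P(X ≥ k); Benjamini–Hochberg adjustment (statsmodels)
runs over all scored candidates of the spectrum, and
−log₁₀(p_adj) > 3 flags reliability. On 100 pure-noise spectra the
false-flag rate is ≤10⁻³ (test `TestNullCalibration`).

## Synthetic data

`simulate.FixtureSpec` generates what the pipeline must survive:
BRAIN-exact isotope envelopes per component/charge/loss (loss
satellites at 0.3× by default), uniform-m/z noise peaks with
log-uniform intensities, instrumental noise as one exact intensity
value repeated many times, a constant m/z shift, and optional
over-segmentation of every peak into 2–4 sub-peaks (Dirichlet-split
intensities arranged unimodally within ±0.003 Th, conserving both total
intensity and centroid). The standard stress condition in the tests is
200 noise peaks at ≤5% of the base intensity, 1,000 repeated-intensity
peaks, a +0.005 Th shift, and over-segmentation.

What this does not emulate: chromatographic elution and scan summing,
detector saturation, ppm-proportional (rather than constant) mass
error, adducted species, and co-eluting envelopes that share peaks
between different species. Recovery results on fixtures are therefore
evidence of algorithmic correctness, not of performance on arbitrary
real data.

**Identifiability.** Some mixtures are inherently ambiguous under the
loss model: GlcN + SO₃ − NHSO₃ is atom-identical to anhydromannitol, so
a composition X and its NH-loss isobar X−NH cannot be distinguished
when both are present — a single enumerated composition then explains
both via different losses and is preferred by parsimony. The recovery
fixtures use a component pool whose pairwise mass differences are not
differences of two ≤2-group loss sums, which is the precondition for
recovery to be well-posed at all.

## Problem sizes and determinism

Default test problem sizes: dp2–dp6 components, 2–5 per spectrum,
charges spanning 1–5, composition spaces of ~5–15k candidates
(~300–600k theoretical ions). Every stochastic step (fixture
generation, model sampling) is driven by an explicit seed; rerunning
the pipeline on the same input writes byte-identical outputs. The
intensity model can be fitted once and passed to `run_pipeline` to
amortize the ~2 s fit across many spectra.
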