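# Methods

## Network construction

Per subject, the N×T regional time-series matrix is reduced to pairwise
Pearson correlations, clipped to ±(1 − 10⁻⁷) and Fisher z-transformed
(atanh), diagonal zeroed. Binarization keeps a fixed fraction *d* of the
N(N−1)/2 possible edges (default d = 0.04, i.e. 1205 edges for N = 246;
rounding is half-away-from-zero). To guarantee a single connected component
the **maximum-weight spanning tree** of the signed z matrix is retained
first and the remaining budget is filled with the strongest non-tree edges
in descending signed-z order. "Maximum" rather than literal minimum: the
backbone must preserve connectivity through the *strongest* correlations,
which is the standard reading of spanning-tree thresholding in connectomics
(a minimum tree would keep the weakest edges and defeat the purpose). Edge
ranking uses signed z by default — negative correlations (which global
signal regression induces) are retained in the matrix but lose the ranking;
an absolute-value ranking and an absolute z-cutoff mode are available as
config switches for sensitivity analyses. Ties between equal-weight edges
break lexicographically on (min id, max id), so output is deterministic.
Because non-tree edges are taken as a prefix of one fixed ordering, edge
sets nest monotonically across densities (tree edges aside).

## DomiRank

DomiRank scores node dominance as the fixed point of
Γ̇ = αA(θ1 − Γ) − βΓ, computed exactly by solving
(σA + I)Γ = σθA1 with σ = α/β and θ = 1 (pure scale). The solver verifies
the residual ∞-norm is below 10⁻⁸. Dominated nodes can legitimately score
negative. σ must lie in (0, −1/λ_N), λ_N being the most negative adjacency
eigenvalue (dense `eigvalsh`; networks here are ≤ a few hundred nodes). The
scan uses 100 candidates at fractions j/101 of the upper bound — evenly
spaced, endpoints excluded, since σ → 0 degenerates to degree and σ at the
bound makes (σA + I) singular. Each candidate is scored by the area under
the LCC curve of a **non-adaptive** attack ranked by its own Γ; the argmin
(first on ties) is selected. An independent forward-Euler integrator of the
dynamics is shipped for cross-checking the closed form on small graphs
(agreement within 10⁻⁶ is asserted in the tests).

σ is selected per subject by default; a shared template-network option
exists because the original description leaves the granularity open.

Classical centralities use networkx with standard conventions: unweighted
shortest paths for betweenness/closeness/harmonic (normalized; harmonic
divided by N−1), nonnegative unit-norm principal eigenvector, PageRank
damping 0.85, binary degree, and strength as the sum of retained Fisher-z
weights (the only weights the pipeline preserves).

## Targeted attack and robustness

Nodes are removed one at a time in descending centrality order (ties:
ascending node id), the ranking fixed on the intact network (non-adaptive;
an adaptive variant exists behind a flag). The LCC is normalized by the
original N, so curves start at 1 for connected inputs and end at 0. Curves
are computed in O(N + E) by reverse percolation (union-find while adding
nodes back); the test suite validates this against brute-force component
recomputation. Areas are trapezoidal integrals over fraction-removed in
[0, 1]; group-level curves are pointwise means of subject curves.

## Mega-analysis

Each site is tested separately: per region, an ordinary least-squares model
`value ~ group + age + sex` (single model with a group indicator —
equivalent to residualizing when slopes are shared), with the t and
two-sided p of the group coefficient. The covariate list is extensible.
Site evidence is combined with the Liptak–Stouffer formula
z = Σwᵢzᵢ/√(Σwᵢ²), wᵢ = √nᵢ. The transform zᵢ = Φ⁻¹(1 − pᵢ/2) is
magnitude-only, so the sign of the site t is attached before weighting —
increases and decreases combine directionally instead of cancelling into
magnitudes. p = 0 is clipped to the smallest positive float with a warning.
Multiplicity over regions uses the standard Benjamini–Hochberg step-up
(via statsmodels), which the tests verify against an exhaustive
threshold-maximization oracle for m ≤ 12.

## Demographic statistics

Sex-by-group tables use Pearson's χ² without continuity correction; this
choice reproduces the published seven-site MCADI sex p-values exactly
(0.747, 0.129, 0.286, 0.508 for the sites checked). Age/MMSE comparisons
use one-way ANOVA reconstructed from per-group (n, mean, sd) summaries
(SSB from means, SSW from (n−1)·sd²), which equals classical ANOVA on raw
data collapsed to summaries. Published summaries are rounded to one
decimal, so reproduced p-values carry ~±0.01 slack. The printed per-site N
totals of the source table disagree slightly with its own sex counts; the
preset follows the sex counts (total 793 subjects).

## Synthetic cohort generator

The generator emulates a seven-site, three-group (HC/MCI/AD) resting-state
cohort with per-site group sizes 41/34/44, 21/23/24, 24/33/37, 42/16/66,
64/93/39, 21/18/33, 42/37/41 (preset `mcadi_like`), 246 regions and T = 170
frames by default (T is configurable; series length is otherwise
unreported per site).

Time series are multivariate normal: a block ("community") base correlation
matrix (default 6 blocks, within r = 0.3, between r = 0.05) is perturbed in
Fisher-z space by (i) group effects — per-edge Δz shifts and/or attenuation
of all edges incident to designated hub regions, (ii) a per-site scalar
offset (SD 0.05) on all edges, and (iii) small per-subject covariate
effects (0.01 z per SD of age, 0.02 z per sex unit) — then mapped back via
tanh and factorized by Cholesky. Planting in z space keeps effects in the
units the pipeline measures, so recovered group differences are directly
comparable to the configured truth. If a perturbed matrix leaves the
positive-definite cone it is repaired by flooring eigenvalues at 10⁻⁶ and
renormalizing the diagonal; a non-PD *base* matrix is a configuration error
reported with the first violated leading minor. Age is N(68, 7²) per site,
sex Bernoulli(0.5). MMSE group means/SDs are 28.5/25/16 and 2/3/6 (MoCA
26/22/13 analogous), magnitudes consistent with published dementia cohorts;
each subject's planted deltas are scaled by a N(1, 0.2) severity multiplier
whose excess feeds back into cognition (loading 2), so cognition co-varies
with realized effect size as in real patients. One global seed expands into
per-subject substreams keyed by subject index, so adding subjects never
changes earlier subjects' draws.

The generator does **not** model hemodynamics, autocorrelated BOLD noise,
motion artefacts, scanner-specific spectral signatures or non-Gaussian
tails; passing tests demonstrate correctness of the analysis machinery
under the stated population model, not robustness to those realities.

Gene expression matrices are regions × genes with a designated block of
signal genes following `weight · standardize(map) + noise` and the rest
unit-variance noise; signal-gene identities are returned for truth
checking.

## Prediction

Leave-one-site-out: each site is held out once; features are z-scored with
training-fold statistics only. Classification uses a linear SVM (C = 1)
with Platt-calibrated pseudoprobabilities (seeded internal CV, so reports
are deterministic given the seed); the defaults are deliberately plain
since only "SVM" is specified upstream, and hyperparameters are exposed.
Cognition prediction uses linear support-vector regression for symmetry.
The reported correlation between predicted and actual scores averages
per-site correlations by default (pooled correlation is also returned).
Region-wise cognition association fits
`centrality ~ score + age + sex + site` (site as indicator columns) per
region with BH-FDR over regions.

## PLS transcriptomics

Gene columns are z-scored and the response standardized; components come
from NIPALS PLS regression (scikit-learn). Per component the explained
share of the gene-block variance is ‖t‖²‖p‖²/‖X‖²_F and of the response
(tᵀy)²/(‖t‖²‖y‖²); both are reported because "variance explained" is
ambiguous between the two blocks. Components are oriented so PLS1 scores
correlate nonnegatively with the response. Note that per-component
explained response variance is *not* monotone non-increasing for PLS (only
the cumulative share is monotone); the tests assert the valid invariant.

The permutation test permutes region labels of the response
(p = (1 + #{stat ≥ observed})/(B + 1), default B = 5000; an exact
enumeration mode covers n ≤ 8 regions). The statistic is PLS1's explained
gene-block share, computed by a closed form valid for univariate responses
(w ∝ Xᵀy), vectorized across permutations; its equivalence with the full
NIPALS fit is asserted in the tests. The null is a naive label permutation
— it does not preserve spatial autocorrelation of brain maps, which is a
known limitation of this class of test. Bootstrap stability resamples
regions with replacement, re-standardizes within the resample, sign-aligns
each resample's weight vector to the full model, and reports
Z = weight/SE; degenerate resamples are redrawn and counted. Gene ranking
always uses the full-model component-1 weight vector (|weight| descending,
ties by gene name). Enrichment is an upper-tail hypergeometric test per
gene set (equivalent to one-sided Fisher exact), BH-corrected across sets;
missing regions in the expression matrix are handled by aligning the
response to the supplied region subset.

## Problem sizes and numerical choices

Analyses run comfortably at the full design size (793 subjects × 246
regions). Repeated-replicate studies (null calibration, permutation
uniformity) use reduced sizes — 40 regions, T = 80, 20 subjects per group
per site, 100–200 replicates — chosen so Monte-Carlo error, not runtime,
dominates the comparison; planted-effect recovery uses the full preset
over several seeds. Correlations are clipped at ±(1 − 10⁻⁷) before atanh;
linear solves assert residuals < 10⁻⁸; the Fisher-z estimator's O(1/T)
bias is documented and kept below Monte-Carlo error in recovery checks by
using longer series there. Region indices are 0-based internally and
1-based in all user-facing tables.
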