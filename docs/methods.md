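# Methods

## Feature space

Each gene is reduced to two numbers computed from its per-condition mean
log₂ expressions X̄ᴬ and X̄ᴮ: the average expression level
AG = (X̄ᴬ + X̄ᴮ)/2 and the average difference AD = |X̄ᴬ − X̄ᴮ|. On log-scale
data AD is exactly the absolute log fold change. AG deliberately averages
the two condition means rather than all P samples, so an unbalanced design
(P₁ ≠ P₂) does not tilt AG toward the larger group. Both quantities are
invariant to swapping the condition labels.

Per-condition unbiased variances (ddof = 1) ride along for the t
statistic; a condition with a single replicate stores NaN — an explicit
"undefined" marker — and the t statistic refuses such designs rather than
guessing.

## Pruning rule

Two genes are neighbors when their Euclidean distance in (AG, AD) is
*strictly* smaller than R₀; a gene with nᵢ ≥ N₀ neighbors is pruned. Strictness
makes R₀ = 0 a guaranteed no-op and fixes the tie behavior at exactly R₀
(not a neighbor). Coincident genes are mutual neighbors for any R₀ > 0;
duplicate probe identifiers are kept as independent rows throughout.

Distances are compared as d² < R₀², with a single shared pairwise-d²
routine, so every code path — direct counting, the radius search, repeated
calls at the same radius — produces identical floating-point decisions.
Counting is exact O(N²), chunked to ~32 MB of scratch; at N ≈ 2·10⁴ a full
pass takes a few seconds on one core. No approximate spatial index is used:
the pruning rule *is* the brute-force definition, and the test suite holds
the implementation to it bit-for-bit.

Distances are taken in raw log units by default. The radius search range
"0 to max AD" is only meaningful on that scale. A min–max rescaling of both
axes to [0, 1] is available behind a flag (`GeneFeatures.rescaled()`,
`--rescale`) for users who want a radius whose meaning is dataset-independent;
it is off by default and no default radius is claimed to transfer between
scalings.

## Radius search

Users usually know how many candidates they can afford (K), not R₀. Since
the survivor count is a non-increasing step function of R₀, a bisection
over [0, max AD] homes in on K: at most 64 iterations, stopping early on an
exact hit; among all visited radii (endpoints included) the survivor count
closest to K wins, ties broken toward *more* survivors — the conservative
side, which retains more candidate DEGs. An exact K may be unattainable
(the count jumps where R₀ crosses a pairwise distance); the tests verify
the search lands within the best achievable gap found by exhaustively
scanning all distance midpoints.

Internally each bisection step is O(log N): a gene survives at radius r iff
its N₀-th smallest neighbor distance² ≥ r², so one O(N²) pass computing
those N₀-th distances (exact `np.partition`, same d² arithmetic) yields the
survivor count at any radius by binary search in a sorted array. The
returned `PruningResult` is recomputed by the direct counting rule at the
chosen radius and asserted to agree.

## Ranking statistics

All scorers return "higher = more DEG-like" in input row order; ranking is
a stable descending sort (ties broken by row order, for determinism).

* **Fold change** — AD itself. A score of 1.0 is the conventional "2-fold"
  significance cutoff on log₂ data.
* **t statistic** — pooled-variance Student's |t|:
  |X̄ᴬ − X̄ᴮ| / √(s²ₚ(1/P₁ + 1/P₂) + ε), with ε = 1e-8 a variance floor that
  turns zero-variance genes into finite, very large scores (they rank first
  rather than crashing — the classic small-variance pathology is preserved,
  visible, and exactly what pruning mitigates). Pooled rather than Welch by
  default, matching long-standing small-sample microarray practice; Welch
  is behind `welch=True`. Requires ≥ 2 replicates per condition.
* **Rank product** — for each of the P₁ × P₂ ordered sample pairs, genes
  are ranked by the pairwise difference B − A, descending (rank 1 = most
  up-regulated) and ascending (rank 1 = most down-regulated), average ranks
  on ties; RP_up/RP_down are geometric means of those ranks across pairs,
  and the score is −log(min(RP_up, RP_down)) so DEGs of either direction
  rank high. All P₁ × P₂ pairings are used (the published default for
  unpaired designs). The permutation-based significance estimate of the
  original method is out of scope: only the ranking is needed here. Note
  the two-sided min-combination is *not* order-identical to fold change
  even for a single sample pair: the least-changed gene is simultaneously
  the best "down" candidate.
* **WAD** — AD × w, with w the min–max-normalized AG (w = 1 everywhere when
  AG is constant). Uses the same high-expression prior as the pruning
  itself, which is why pruning helps it least.

With a pruning result attached, mode `append` (default) places score-sorted
survivors before score-sorted pruned genes. Every kept gene's rank is then
≤ its unpruned rank (pruned genes can only vacate positions above it), and
N is unchanged, so ROC axes stay comparable between the with/without lists
for any K — even a K exceeding the survivor count. Mode `exclude` restricts
the ranking to survivors.

## Evaluation

Prefix ROC: for k = 0..K_max, TPR(k) = TP(k)/|truth| and
FPR(k) = FP(k)/(N − |truth|), where the top-k prefix of the ranking is the
prediction set — K is a prediction budget, not a score threshold. The
partial AUC is the raw trapezoidal area of that curve, left unnormalized;
over 2·10⁴ genes with K_max = 1000 the FPR range is ≈ 0.045, so realistic
values are a few hundredths. Top-K true-positive counts default to the grid
K ∈ {150, 250, 350, 450, 550}. Enrichment is the fraction of true DEGs in
a list; the fold enrichment is its after/before-pruning ratio. Confusion
labeling at a cutoff k assigns TP/FP/FN/TN per gene (truth ids absent from
the matrix are an error, never silently dropped). When several datasets
are benchmarked, top-K counts are summed across datasets at each K.

## Synthetic generator

Log₂-scale Gaussian model: non-DEG gene i draws a baseline
μᵢ ~ N(baseline_mean, baseline_sd²) and every sample adds N(0, noise_sd²)
replicate noise. A DEG additionally (i) shifts its baseline up by
`deg_level_shift` — except a `hard_deg_fraction` of "hard" DEGs left at
core expression level, emulating the minority of true DEGs buried in the
dense region — and (ii) shifts condition B by δᵢ = sᵢ·U(effect_min,
effect_max), sign sᵢ uniform on {−1, +1}, since real truth sets contain
both directions.

Defaults: 10000 genes, 100 DEGs, 10 samples per condition, baseline
7 ± 1.5, noise 0.3, level shift 1.5, effect 1–3 log₂ units, hard fraction
0.1, chosen as a typical disease-vs-normal microarray scale: a baseline
spread of ~1.5 log₂ units across genes, replicate noise well below the
smallest effect (an AD of ≥ 1 ≈ two-fold change is the conventional
threshold of interest), and 1% true DEGs. Under these settings the non-DEG
AD distribution is folded-normal with scale noise_sd·√(1/n_A + 1/n_B) ≈
0.13, forming the dense core, while DEG ADs land near |δ| ≥ 1 — the
structural premise of the method, stated by construction.

What the generator does *not* model: probe-level effects, array batch
effects, intensity-dependent (heteroscedastic) noise, correlated gene
modules, or any normalization artifacts. Passing tests therefore
demonstrate the pipeline's correctness and the geometric mechanism of
pruning, not performance on any particular real platform; on real data the
core is wider and survival of true DEGs below 100% is expected.

## Problem sizes and numerical choices

The heavy tests and the acceptance script run the generator defaults
(N = 10⁴, seeds 1..10), where one radius search costs a few seconds; exact
oracle comparisons run at N ≤ 1000 where the independent O(N²) reference is
instant. JSON reports round floats to 6 significant digits and sort keys,
making repeated runs byte-identical; matrices are written with 6
significant digits, so a write/read round trip preserves values to ~1e-5
relative. Degenerate inputs are pinned by tests: R₀ = 0 prunes nothing,
coincident points count each other, zero-variance genes get finite t
scores, constant-AG inputs give WAD weight 1, and a constant matrix ties
every rank-product score at −log((N+1)/2).

## Limitations

* Two conditions only; no multi-group extension.
* Requires pre-normalized input; only a log transform is offered, because
  normalization choices are upstream of this method's scope.
* R₀ and N₀ remain user-set (or K-targeted); no parameter-free variant.
* No statistical significance for the rankings (no RP permutation
  p-values, no FDR control) — the output is an ordering plus evaluation
  metrics against a supplied truth set.
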