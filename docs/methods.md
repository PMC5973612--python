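# Methods

## Model and procedure

A food web is a directed graph: `S` trophic species, `L` feeding links
running resource → consumer. All structural testing is done on the
**undirected simple projection**: self-loops (cannibalism) are removed and
reciprocal pairs `a→b, b→a` are merged into one edge, giving `E ≤ L` edges.
Connectance `C = L/S²` alone is computed on the directed web, since it
measures realized feeding links out of the `S²` possible ones. The reason
for projecting is structural: the clustering denominator `Kᵢ(Kᵢ−1)` and the
pair normalization `S(S−1)/2` are undirected quantities, and loops would
make the former undefined.

**Characteristic path length.** Shortest-path lengths are counted in
*edges* (a pair of adjacent nodes is at distance 1) and averaged over the
unordered pairs that are mutually reachable. Dense webs have CPL between 1
and 2 under this convention; counting nodes-on-the-path instead would put
the floor at 2 and is inconsistent with observed values for highly connected
webs. Unreachable pairs are excluded from the average (not assigned a
penalty distance) and returned as a separate count, so CPL stays finite for
fragmented webs; an entirely disconnected graph raises an error rather than
returning a number.

**Clustering.** `CCᵢ = 2Eᵢ/(Kᵢ(Kᵢ−1))` for nodes of degree ≥ 2; nodes of
degree 0 or 1 contribute `CCᵢ = 0` and are *included* in the network mean
(the common zero convention). The inclusion matters: large sparse webs have
many low-degree species, which is how network-level CC values of order
10⁻³ arise.

**Null ensemble.** `G(n, M)` Erdős–Rényi graphs — uniform over all simple
undirected graphs with exactly `S` nodes and a fixed edge count — matched to
the empirical web. `G(n, M)` rather than `G(n, p)` because the comparison
matches the link count exactly, not in expectation. Edges are sampled as a
uniform draw of `M` distinct pair-indices from the `S(S−1)/2` possible pairs,
so each replicate is exact and cheap. Connectivity is *not* enforced;
replicate CPLs handle unreachable pairs exactly as the empirical metric
does, and a replicate with no connected pair at all (possible only at
extremely low density) is skipped, with a hard error if more than 1% of
replicates are lost.

The matched edge count defaults to the projection's `E`; a configuration
switch (`null_edge_convention="raw_links"`) instead uses the directed `L` as
an undirected edge count. The published random-CC values for marine webs are
consistent with the raw-`L` convention (their random CC equals
`L/(S(S−1)/2)`), which is why the switch exists; for self-generated data the
projection convention is the defensible default.

**Confidence intervals.** Percentile intervals: the 0.5% and 99.5% empirical
quantiles of the replicate distribution, with linear interpolation between
order statistics (numpy's default quantile definition). The coverage level
(default 99%) and replicate count (default 1000) are configurable; below 100
replicates the tail quantiles are poorly determined and a warning is logged.

**Classification.** Two criteria, reported side by side:

* CI rule: small-world iff `CPL_emp ≤ ci_high(CPL_rand)` (non-strict:
  "within or below the interval") and `CC_emp > ci_high(CC_rand)` (strict:
  "above the interval").
* Small-world-ness: `S^ws = γ/λ` with `γ = CC_emp/⟨CC_rand⟩`,
  `λ = CPL_emp/⟨CPL_rand⟩`; small-world iff `S^ws > 1` and `S^ws` exceeds
  the 99.5% quantile of the null `S^ws` distribution. The null distribution
  is built by scoring each replicate graph against the ensemble means
  (replicate r gives `(CC_r/⟨CC⟩)/(CPL_r/⟨CPL⟩)`). This construction is a
  declared design choice — leave-one-out or re-simulated nulls would also be
  defensible; at 1000 replicates the difference is negligible.

The CI rule is far stricter than `S^ws`. Its CPL condition demands paths *no
longer than random* — the random-CPL interval is extremely narrow (width of
order 10⁻² at `S` a few hundred), so any graph whose paths are even a few
percent longer than random fails. Watts–Strogatz graphs at rewiring
`p = 0.05` (n=200, k=10) have CPL ≈ 3.7 against a random mean ≈ 2.55 and are
therefore essentially never called small-world by the CI rule, while `S^ws`
flags them with near-certain power (S^ws ≈ 8). This asymmetry is the
method's point, not a defect: applied to a battery of webs the CI rule
always calls a subset of what `S^ws` calls.

## Degree-distribution fitting

Maximum likelihood on the raw degree sequence of the projection (total
degree), never least squares on the cumulative curve — the survival form
`P(k)` is presentation only. `kmin` is the minimum observed degree; no
tail-threshold (xmin) optimization is attempted, which is a documented
limitation: exponents are interpretable as whole-distribution fits, not
tail fits.

| model | pmf on support | parameters (K) | estimation |
|---|---|---|---|
| poisson | `e^{−λ}λ^k/k!`, k ≥ 0 | λ (1) | closed form (mean) |
| exponential | `(1−q)q^{k−kmin}`, `q = e^{−1/κ}` | κ (1) | closed form |
| power_law | `k^{−α}/ζ(α, kmin)` | α (1) | bounded 1-D ML |
| truncated_power_law | `∝ k^{−α}e^{−k/κ}` | α, κ (2) | Nelder–Mead, numeric normalization |
| lognormal | `∝ exp(−(ln k−μ)²/2σ²)/k` | μ, σ (2) | Nelder–Mead, numeric normalization |
| uniform | `1/(kmax−kmin+1)` | kmin, kmax (2) | bounds from data |

Numerical choices: the truncated power law is normalized by direct summation
to `kmin + max(1000, 20·kmax, 30·κ)` (capped at 2·10⁵), making the truncation
error below 10⁻¹³ of the mass inside the feasible box `α ∈ [0, 25]`,
`κ ∈ [10⁻³, 10⁴]`; the lognormal normalization uses log-sum-exp with
`σ ≤ 5`. Every fit records its achieved total pmf mass (partial sum plus
analytic tail where one exists) and agrees with 1 to 10⁻⁸. The uniform
model's bounds count as K = 2 estimated parameters because they are
data-determined. `n` in AICc is the node count. Selection takes the minimal
AICc among converged fits; exact ties break toward fewer parameters, then a
fixed model order. Degenerate sequences (a single distinct degree) only
attempt uniform and poisson; sequences containing isolated nodes (degree 0)
exclude the three models needing `k ≥ 1`.

On preferential-attachment test graphs (n=500, m=3) the selected model is
always heavy-tailed, splitting roughly 2:1 between the power-law family and
lognormal — discrete lognormals genuinely rival power laws at this sample
size, a well-known ambiguity that AICc at n=500 cannot always resolve.

## Synthetic data

The generators provide controls with known topology class, not imitations
of real food webs: Watts–Strogatz (positive control for `S^ws`; the CI rule
is expected to reject it, see above), ring lattices (clustered but
long-pathed negative control), preferential attachment (heavy-tailed
degrees), and configuration-model graphs with uniform degrees (the
stub-matching draw is simplified and then repaired by re-linking deficient
non-adjacent node pairs, with a retry cap; for `d_max ≪ n` the repaired
sequence is almost always exact). Directed fixtures orient each edge
uniformly at random, which reproduces the directed/undirected bookkeeping
of real webs but none of their trophic ordering — passing tests demonstrate
correctness of the statistical machinery, not realism of niche structure.
Real webs also exhibit near-reciprocal links, cannibalism and aggregated
basal nodes; only the first two are exercised, via dedicated I/O tests.

Reproducibility: every stochastic component takes an integer seed;
ensembles derive one substream per replicate from `(seed, replicate_index)`,
so results are independent of parallelization and extending an ensemble
preserves its prefix. Re-running the CLI with the same configuration and
seed is bit-identical.

## Problem sizes

Default analyses use 1000 replicates. The test suite exercises the
published-web ensemble sizes (S up to 442) at 300 replicates and the
error-rate simulations (200 type-I trials, 100 power trials) at 200
replicates per trial; these sizes give Monte-Carlo standard errors an order
of magnitude below the tolerances being checked. The acceptance script uses
the full 1000 replicates.

## Known limitations

- No degree-preserving (configuration-model) null: the comparison is to
  Erdős–Rényi graphs by design, so "higher clustering than random" partly
  reflects degree heterogeneity.
- No xmin optimization or bootstrap goodness-of-fit for degree models;
  AICc ranks the six candidates but does not certify absolute fit.
- CPL on fragmented webs conditions on reachability; two webs with equal
  CPL can differ greatly in their unreachable-pair counts (reported, but
  not folded into the statistic).
- No weighted, directed-path, or modularity metrics.
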