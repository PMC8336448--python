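# Methods

## Pipeline overview

`ms2path` plans targeted MS2 acquisition from a preliminary MS1-only run in
four stages:

1. **Background filtering.** Apex features also present in the blank/control
   sample are discarded: a feature survives iff `intensity_blank == 0` or
   `intensity_sample / intensity_blank ≥ min_ratio` (default 3). Filtering
   happens before clustering, so discarded features contribute no clusters.
2. **Apex-centered clustering.** Each raw MS1 scan point is assigned to the
   nearest surviving apex under the tolerance-scaled Chebyshev distance
   `d = max(|Δmz|/mz_tol, |Δrt|/rt_tol)`, with a hard cutoff at `d = 1`.
   Points farther than the tolerance from every apex stay unassigned and are
   only counted (reported in the run manifest). Ties are broken by smaller
   `|Δmz|`, then lexicographically smaller feature id, so assignment is
   deterministic. Chebyshev (rather than Euclidean) distance makes the
   tolerance box explicit and keeps "out of tolerance" well defined.
3. **Feature-DAG construction.** Per cluster, member signals are binned into
   half-open RT intervals `[t0 + k·w, t0 + (k+1)·w)` anchored at the
   cluster's first scan point; non-empty bins become nodes (rt = bin
   midpoint, intensity = summed member intensity), each split into an
   in-node and an out-node. For every ordered bin pair `(a, b)` with
   `min_duration ≤ rt_b − rt_a ≤ max_duration` whose padded-window integral
   predicts TIC at or above the threshold, a weight-1 edge `in(a) → out(b)`
   is added carrying the window and its integral. Weight-0 transition edges
   run from out-nodes to in-nodes of *different* clusters at
   `rt_in ≥ rt_out + transition_gap`, plus a virtual source into every
   in-node and a virtual sink out of every out-node. Retention times are
   nondecreasing along every edge, so the graph is acyclic by construction.
   Transition edges are implied by the time rule rather than stored — their
   number grows quadratically while the path search only ever needs the best
   finished out-node of a different cluster — and are materialized on demand
   for inspection of small graphs.
4. **Path search and iteration.** The maximum-weight source-to-sink path is
   computed by dynamic programming over the topological order (see below).
   Features acquired by the resulting path are excluded and planning repeats
   on the remainder, up to `num_paths` runs, stopping early when a path
   scores 0 (all further paths would be empty too, by monotonicity).

## TIC prediction and window integration

The spectrum-quality gate needs the MS2 TIC a window would yield. TIC is
modeled as a linear function of the integrated MS1 intensity in the window:
`predicted_tic = max(0, slope·integral + intercept)`, fitted by ordinary
least squares on `(integral, observed TIC)` pairs from a platform
calibration run (`fit_tic_model`; R² is reported as a diagnostic). The
integral is the trapezoid over member scan points with
`rt ∈ [t_s − Δ, t_e + Δ]`; the padding Δ (default 0.2 s) absorbs small RT
shifts between the preliminary and the planned run. Points outside the
padded window are excluded entirely — no partial-interval extrapolation —
and windows holding fewer than two scan points integrate to 0. When no
trained model is supplied the identity model (slope 1, intercept 0) is used,
which turns the TIC threshold into a threshold on the integrated MS1 signal
itself; this is equivalent in effect and needs no platform-specific training
data. The model deliberately includes an intercept (a regression through the
origin is a special case the fit can discover on its own), and predictions
are floored at zero because a negative TIC is physically meaningless.

Inside the DAG builder all window integrals of a cluster are computed at
once from a cumulative-trapezoid table over the member scan points
(`enumerate_windows`); this is algebraically identical to the scalar
trapezoid and a test pins the two routes together at 1e-9 relative.

## Exactness of the path search

A source-to-sink path alternates acquisition (weight-1) and transition
(weight-0) edges, so it is exactly a time-ordered chain of acquisition
windows, and its weight is the number of windows. The node splitting forbids
consuming two windows of a cluster back-to-back, but it does **not** forbid
leaving a long-eluting cluster and legally re-entering it later through a
nested cluster: if cluster A has feasible windows both entirely before and
entirely after a full window of cluster B, the path A → B → A is
structurally valid yet acquires A twice, inflating the edge count above the
number of distinct features. A plain longest path is therefore an upper
bound, not always a feasible schedule.

`longest_path` resolves this exactly on the instance sizes that matter:

* The DP sweeps nodes in topological order `(rt, out-before-in)`, keeping
  per in-node the best finished out-candidate from a different cluster
  (a running best-two over distinct clusters — equivalent to materializing
  every transition edge). Ties are broken by larger summed window intensity,
  then by lexicographically earliest window-start sequence, making the
  result deterministic and total.
* If the extracted max-weight path repeats some cluster (windows w1 then
  w2), the search branches on confining that cluster's single window to
  *start before* or *end after* the midpoint between `w1.rt_end` and
  `w2.rt_start`. Every repeat-free path survives in at least one branch,
  each branch eliminates one of the offending windows, and the DP value of a
  branch bounds all its feasible paths, so branches that cannot beat the
  incumbent are pruned. The first-occurrence-only "repair" of every DP path
  provides a feasible incumbent immediately.
* The branch budget adapts to instance size (hundreds of DP passes for
  small instances, a handful for instances with hundreds of clusters). The
  search is provably optimal whenever it converges within budget — which
  covers the exhaustively verified regime — and otherwise returns the best
  feasible schedule found, which is always constraint-valid. Selecting at
  most one interval per feature from overlapping interval families is a
  combinatorial problem with no known polynomial exact algorithm, so a
  budgeted search is the principled trade at scale.

An exhaustive oracle (`brute_force_optimum`) enumerates all cluster subsets
and visiting orders, realizing each order greedily by earliest window end
(optimal within a fixed order by the standard exchange argument). On 200
random instances with ≤ 6 clusters and ≤ 8 bins each, the DP search matches
it exactly.

## Schedule-matrix validation

`to_schedule_matrix` discretizes planned windows onto a time grid and
re-checks the scheduling constraints independently of the planner: one
contiguous run of bins per feature, at most one feature per bin, binary
assignments. Iterated paths are separate instrument runs whose RT ranges
legitimately overlap, so the matrix concatenates runs along the time axis
(run *k* occupies its own block of bins); constraints are thereby enforced
per run while the objective counts distinct features over the whole plan. A
bin belongs to a window when its center lies in `[rt_start, rt_end)`; the
default bin width is half the shortest window, which guarantees every window
covers at least one bin and that touching (non-overlapping) windows never
collide.

## Synthetic data

`generate_run` emulates the preliminary MS1 experiment: each feature is a
Gaussian elution profile `I(t) = h·exp(−(t−rt0)²/2σ²)` sampled on a regular
scan grid, truncated at 3σ, with multiplicative log-normal noise
(`exp(σ_noise·z)`, median-unbiased, keeping intensities positive — additive
Gaussian noise would produce negative ion counts). Feature m/z values are
drawn without replacement from a 0.05 Th grid so that co-eluting features
remain m/z-resolvable, as distinct metabolites are on a high-resolution
instrument. Background contaminants are emitted with
`intensity_blank == intensity_sample`. Default conditions describe an
ordinary short metabolomics gradient: 10 min run scanned at 2 Hz, σ = 4 s,
apex heights log-uniform over 10⁴–10⁷ counts, 10% intensity noise.

The top-N DDA simulator fragments, at each MS1 scan, the `top_n` most
intense non-excluded features (default top-5 with 10 s dynamic exclusion,
five replicate runs) and is deliberately minimal: no injection-time
modeling, no charge-state rejection, no stochastic selection. It exists to
compare *relative* acquisition redundancy against planned paths on identical
ground truth, not to emulate a specific instrument.

What the synthetic benchmarks do **not** show: real chromatography has
tailing/fronting, isotope envelopes, adducts, RT drift between runs and
m/z-dependent resolution, none of which are modeled; apexes here are exact
ground truth rather than feature-finder output; and the TIC gate in the
default identity mode is a proxy, not a measured instrument response.
Passing tests therefore demonstrate the correctness of the planning
machinery under the stated model, not end-to-end performance on instrument
data.

## Parameter defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| `tic_threshold` | 10³ | TIC counts | usable-spectrum floor on a q-Orbitrap-class instrument; equivalently an integral threshold in identity mode |
| `delta` (Δ) | 0.2 | s | RT-fluctuation padding of the window integral |
| `num_paths` | 5 | – | matches a typical iterative-experiment series |
| `bin_width` | median inter-scan interval | s | one node per scan; finer would create empty bins |
| `min_duration` | one scan interval | s | a window must span at least two scan points to integrate |
| `max_duration` | ∞ | s | unbounded by default; bound it to model injection-time limits |
| `transition_gap` | 0 | s | bare RT ordering between features; raise for instrument switching overhead |
| `mz_tol` / `rt_tol` | 0.01 Th / 5 s | – | clustering tolerance box around an apex, ~high-resolution mass accuracy and a fraction of a peak width |
| `min_ratio` | 3 | – | conventional sample/blank intensity ratio for background removal |

All are exposed through `PlannerConfig`, the CLI and the TOML config file
(flag > file > default).

## Problem sizes used in verification

The acceptance script and test suite use: 200 random instances of ≤ 6
clusters / ≤ 8 bins for oracle equivalence; 100 instances for constraint and
iteration properties; 50 for threshold monotonicity; 200 noisy pairs for TIC
recovery; 20 disjoint features for the full-coverage construction; 50
co-elution-heavy runs (30 features in 150 s) for the redundancy contrast;
and one 1000-feature, 1-hour-gradient run for the large-instance runtime.
These sizes keep every check exhaustive or well-replicated while the whole
verification remains a desk-scale computation.

## Known limitations

* Whole-feature exclusion between iterations: a feature acquired in run *k*
  is never rescheduled, even if only part of its elution was used.
* No isolation-window overlap checks between co-eluting clusters; chimeric
  risk is reduced only by apex-centered clustering.
* No online replanning, multi-sample joint planning, or instrument control;
  the output is an inclusion-list table.
* Vendor inclusion-list dialects are not emitted directly; the path table is
  a stable TSV from which vendor formats are a thin mapping.
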