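# ms2path

Iterative optimized MS2 acquisition planning for untargeted LC-MS
metabolomics.

## The problem

In untargeted metabolomics, fragmentation spectra (MS2) are the fingerprints
used to identify metabolites. Standard data-dependent acquisition (DDA)
selects the top-*N* most intense precursor ions at every survey scan, which
is greedy: the most abundant ions are fragmented again and again — often at
sub-optimal points of their elution — while low-abundance features never get
a spectrum. Repeating DDA on the same sample mostly re-collects the same
ions.

`ms2path` takes the opposite, plan-ahead approach. From a preliminary run
acquired in MS1-only full-scan mode (raw *m/z* / RT / intensity triplets
plus the feature apexes detected by an upstream OpenMS-style feature
finder), it schedules one or more *targeted* MS2 acquisition paths that
maximize the number of **distinct** features fragmented with adequate
spectrum quality. The emitted path tables are inclusion lists for
consecutive instrument runs.

## The model

With *N* detected features and *T* scan times, let `X[t,i] ∈ {0,1}` indicate
that feature *i* is being fragmented at time *t*, and `Int[t,i]` its MS1
intensity. The planner solves

```
maximize   Σᵢ 1( Σₜ X[t,i] > 0 )                  (number of distinct features)
subject to f( Σₜ Int[t,i]·X[t,i] ) ≥ TIC_min      (spectrum-quality gate)
           Σₜ |X[t+1,i] − X[t,i]| ≤ 2             (one contiguous window per feature)
           Σᵢ X[t,i] ≤ 1                          (one precursor at a time)
```

where `f` is a linear map from integrated MS1 intensity to expected MS2
total ion current (TIC), calibrated per platform from DDA training pairs, or
the identity by default (thresholding the integral directly). The search
works on a **feature DAG**: raw signals are clustered around apexes, each
cluster's signals are binned by RT, bins are split into in/out nodes,
weight-1 edges represent above-threshold acquisition windows and weight-0
edges represent transitions to later features. The maximum-weight
source-to-sink path — found by dynamic programming over the topological
order, with an exact repair step for the rare case where the raw path would
revisit a long-eluting feature — is the optimal schedule. Scheduled features
are then excluded and planning repeats for the next run.

## Worked example

`python examples/01_plan_from_synthetic_run.py` generates a 20-feature
synthetic run with 4 background contaminants and plans up to three runs:

```
synthetic run: 1152 MS1 scan points, 24 detected apexes
background features discarded: 4
signals outside clustering tolerance: 192

run 0: 20 feature(s)
  F03  m/z  784.600  RT    16.8-   40.2 s  predicted TIC     102846
  F12  m/z  180.200  RT    49.2-   63.8 s  predicted TIC    7245112
  ...
20/20 sample features scheduled across 1 run(s); every feature at most once.
```

Each row is one acquisition window: the isolation m/z, the RT interval in
which to fragment that precursor, and the predicted MS2 TIC (≥ the 10³
default threshold). Here all 20 sample features fit in a single run because
their elution windows can be sequenced without conflict; the 4 background
features were removed before planning ever saw them.

`examples/03_planner_vs_dda_redundancy.py` contrasts planned acquisition
with five replicates of simulated top-5 DDA on a co-elution-heavy run:

```
planned (5 runs)   30/30 features acquired,  30 MS2 spectra, 100.0% collected 1-2 times
top-5 DDA (5 runs) 30/30 features acquired, 600 MS2 spectra,   0.0% collected 1-2 times
```

## Command line

```
ms2path simulate --spec run.toml --out-dir sim/          # synthetic MS1 run
ms2path fit-tic  --pairs pairs.tsv --out model.txt       # calibrate TIC model
ms2path plan     --raw sim/raw.tsv --apex sim/apex.tsv \
                 --out paths.tsv --num-paths 5 --tic-threshold 1e3
ms2path validate --paths paths.tsv                       # constraint check
```

`plan` exits 0 with at least one path, 3 when nothing is feasible above the
threshold, 2 on input errors; every path table gets a JSON manifest with the
effective configuration, input digests and per-iteration scores.

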