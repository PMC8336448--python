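"""Plan MS2 acquisition paths for a small synthetic MS1 run.

Generates a 20-feature run (plus 4 background contaminants), runs the full
pipeline — background filtering, apex-centered clustering, iterative path
planning — and prints the schedule. Each printed window is one precursor the
instrument would fragment in that run: isolation m/z, the RT interval, and
the predicted MS2 total ion current (here equal to the integrated MS1
signal, since no trained TIC model is supplied).
"""

from ms2path import PlannerConfig, SyntheticRunSpec, generate_run, plan_run

spec = SyntheticRunSpec(n_features=20, rt_range=400.0, n_background=4, seed=42)
signals, apexes = generate_run(spec)
print(f"synthetic run: {len(signals)} MS1 scan points, {len(apexes)} detected apexes")

config = PlannerConfig(tic_threshold=1e3, num_paths=3, rt_tol=15.0)
result = plan_run(signals, apexes, config=config)

print(f"background features discarded: {result.n_background_discarded}")
print(f"signals outside clustering tolerance: {result.n_unassigned_signals}")
for path in result.paths:
    print(f"\nrun {path.index}: {path.score} feature(s)")
    for w in path.windows:
        print(
            f"  {w.feature_id}  m/z {w.iso_mz:8.3f}  "
            f"RT {w.rt_start:7.1f}-{w.rt_end:7.1f} s  "
            f"predicted TIC {w.predicted_tic:10.0f}"
        )
covered = sum(p.score for p in result.paths)
print(f"\n{covered}/{spec.n_features} sample features scheduled across "
      f"{len(result.paths)} run(s); every feature at most once.")
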