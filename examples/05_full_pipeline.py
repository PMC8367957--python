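"""One-call pipeline: synthetic CVs -> MSM -> PCCA+ -> TPT -> report.

Runs every stage with a small problem size and prints the headline report
entries.  Artifacts (CV table, model container, JSON report, resolved
config) are cached under out_dir; a second run with the same configuration
resumes from the cache.
"""

import json
import tempfile

from nucleakin import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as out:
    cfg = PipelineConfig(seed=1, out_dir=out, n_traj=4, n_steps=20_000,
                         n_states=60, msm_lag=1, its_lags=[1, 2, 5],
                         ts_window=[0.35, 0.65])
    report = run_pipeline(cfg)
    print("macro-state populations:",
          {k: round(v, 3) for k, v in report["macro_populations"].items()})
    print("total reactive flux:", f"{report['total_flux']:.3e}")
    print("top pathways (macro labels ordered by mean nucleus size):")
    for p in report["pathways"][:3]:
        print("  ", "->".join(p["states"]),
              f"({p['micro_path_len']} microstates, {100 * p['fraction']:.1f}%)")
    print("transition-state microstates:",
          len(report["transition_state_microstates"]))
    print("nucleation rate (report units):",
          f"{report['nucleation_rate_per_s_m3']:.2e} s^-1 m^-3")
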