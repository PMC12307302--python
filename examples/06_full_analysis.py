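"""Run the whole chain and render the report.

Equivalent to `hippoatrophy analyze --seed 7 --out report/` from a shell.
"""

from hippoatrophy import AnalysisConfig, SimulationParams, render_markdown, run_full_analysis

cfg = AnalysisConfig(sim_params=SimulationParams(seed=7))
report = run_full_analysis(cfg)

for hemi, r in report.correlations.items():
    print(f"{hemi}: r = {r.r:.3f}, one-tailed p = {r.p_one_tailed:.4f}")
print(f"retained n = {report.demographics['n']}, amyloid subset n = "
      f"{report.regressions[('left', 'with_amyloid')].n}")
print("\n--- markdown report (first 25 lines) ---")
print("\n".join(render_markdown(report).splitlines()[:25]))
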