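"""End-to-end pipeline on a simulated cohort.

Simulates a 187-patient two-arm cohort in which higher baseline GI favors
remission on rituximab and lower GI favors remission on cyclophosphamide,
then runs gate -> query -> GI -> Youden band cutoffs -> stratification ->
projection, writing all intermediates under ./pipeline_out.
"""

from cytogi import CohortConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    outdir="pipeline_out",
    simulate=CohortConfig(
        n_patients=187,
        n_events=2000,
        gi_effect_rtx=30.0,
        gi_effect_cyc=-30.0,
        seed=1,
    ),
)
bundle = run_pipeline(config)

print(open("pipeline_out/report.txt").read())
print(
    "The low band should favor CYC and the high band RTX; with only "
    f"{len(bundle.patients)} patients the per-band Fisher tests are "
    "underpowered in some runs, mirroring a real trial-sized cohort."
)
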