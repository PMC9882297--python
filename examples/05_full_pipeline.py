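"""Run the full pipeline on the anomalous surrogate and print the report.

simulate -> infer states -> kinetics -> dynamics -> report, from one
config.  Equivalent shell command:

    locusdyn all --config config.yaml --outdir run/
"""

import yaml

from locusdyn import PipelineConfig, SurrogateConfig, run_pipeline

config = PipelineConfig(
    outdir="scratch/demo_run",
    seed=2024,
    surrogate=SurrogateConfig(n_trajectories=100),
    hmm_restarts=2,
    n_bootstrap=150,
)
outdir = run_pipeline(config)

summary = yaml.safe_load((outdir / "report.yaml").read_text())
print("\nreport summary:")
for key, value in summary.items():
    print(f"  {key}: {value}")
print("\ngamma ~ 0.67 is the anomalous relaxation-time scaling implied by the")
print("generator exponents (1/d=0.31, alpha=0.27, beta=0.52); the full table")
print(f"set is in {outdir}/")
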