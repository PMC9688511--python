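"""Run the complete pipeline on the bundled two-group baseline config.

generate -> segment -> fit -> stats: phantom scenes for two culture
conditions (free-NAD(P)H fraction 77% vs 83%), classical segmentation,
per-cell biexponential fits, and the trim/normality/Welch comparison.
Artifacts (TIFF scenes, masks, per-cell CSV, summary report, log) land in
./pipeline_demo.
"""

from pathlib import Path

from flimcell.pipeline import PipelineConfig, run_pipeline

config_path = Path(__file__).parent / "configs" / "baseline_two_group.yaml"
config = PipelineConfig.from_file(config_path).model_copy(
    update={"output_dir": "pipeline_demo"}
)
out = run_pipeline(config)

print((out / "report.md").read_text())
print(f"per-cell table: {out / 'percell.csv'}")
print(f"summary table : {out / 'summary.csv'}")
# The report flags the a1 difference between the groups as SIGNIFICANT and
# shows tau_m moving opposite to a1, the expected free/bound trade-off.
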