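"""Shared configuration for the numbered analysis scripts.

One cohort at the study's sample size (84 healthy, 52 MCI), default
acquisition/timing/noise, fixed seed.  Raw and intermediate per-subject
files go under scratch/ (large, regenerable); every table a reader would
look at goes under results/.
"""

from pathlib import Path

from nirsmci.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]
WORK_DIR = ROOT / "scratch" / "pipeline"
RESULTS_DIR = ROOT / "results"
SEED = 11


def pipeline_config() -> PipelineConfig:
    return PipelineConfig(seed=SEED)
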