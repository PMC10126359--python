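"""Extract per-subject regional mHbO features.

Epochs each cleaned HbO series around the 15 encoding onsets (baseline
-2..0 s), averages trials, takes the 3-12 s window mean per channel, and
averages within hemispheres.  Writes the per-subject feature table to
results/features.tsv and group-level moments to results/feature_moments.tsv.
"""

import importlib
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
cfg_mod = importlib.import_module("00_config")

from nirsmci.dataio import write_feature_table  # noqa: E402
from nirsmci.pipeline import stage_extract  # noqa: E402


def main() -> None:
    config = cfg_mod.pipeline_config()
    features = stage_extract(config, cfg_mod.WORK_DIR)
    write_feature_table(features, cfg_mod.RESULTS_DIR / "features.tsv")

    moments = (
        features.groupby("group")[["mhbo_left", "mhbo_right", "mhbo_total",
                                   "moca_k", "vdst_score"]]
        .agg(["mean", "std"])
        .round(3)
    )
    moments.columns = ["_".join(c) for c in moments.columns]
    out = cfg_mod.RESULTS_DIR / "feature_moments.tsv"
    moments.to_csv(out, sep="\t")
    print(f"features -> {cfg_mod.RESULTS_DIR / 'features.tsv'} ({len(features)} subjects)")
    print(moments.to_string())


if __name__ == "__main__":
    main()
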