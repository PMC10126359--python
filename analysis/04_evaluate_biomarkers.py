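"""Diagnostic comparison of the four candidate MCI screeners.

For mHbO left/right/total PFC and the MoCA-K score: group t tests,
empirical ROC with AUC, Youden-optimal cutoff with sensitivity and
specificity, confusion matrix, and predictive values under both
positive-class conventions; plus Pearson correlations of MoCA-K with each
regional mHbO.  Writes report.json and the four rendered tables under
results/.
"""

import importlib
import shutil
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
cfg_mod = importlib.import_module("00_config")

from nirsmci.dataio import read_feature_table  # noqa: E402
from nirsmci.diagstats import evaluate_biomarkers  # noqa: E402
from nirsmci.pipeline import report_render  # noqa: E402


def main() -> None:
    features = read_feature_table(cfg_mod.RESULTS_DIR / "features.tsv")
    report = evaluate_biomarkers(features)
    report.save(cfg_mod.RESULTS_DIR / "report.json")
    paths = report_render(report, cfg_mod.RESULTS_DIR)

    print(f"evaluated {report.n_healthy} healthy vs {report.n_mci} MCI subjects")
    print("ranking by Youden J:", " > ".join(report.ranking))
    for name in report.ranking:
        c = report.candidates[name]
        m = c["metrics"]
        print(
            f"  {name:11s} AUC={c['roc'].auc:.3f} J={m.youden_j:.3f} "
            f"sens={m.sensitivity:.3f} spec={m.specificity:.3f} cutoff={m.cutoff:.3f}"
        )
    print("MoCA-K correlations:",
          {k: round(v["r"], 3) for k, v in report.correlations.items()})
    for key, path in paths.items():
        print(f"  {key} -> {path}")


if __name__ == "__main__":
    main()
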