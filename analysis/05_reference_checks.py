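"""Recompute the published tables' worked examples and expectations.

Exact statistics from printed inputs (sex-ratio chi-square, education
pooled t, Youden indices, predictive values from the confusion matrices)
and the two stochastic expectations under the calibrated generator (the
left-PFC group t and the MoCA-K/left-PFC correlation).  Results go to
results/reference_checks.tsv.
"""

import importlib
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
cfg_mod = importlib.import_module("00_config")

from nirsmci.diagstats import (  # noqa: E402
    ConfusionMatrix,
    chi_square_2x2,
    pooled_t_test,
    pooled_t_test_from_data,
    predictive_values,
)
from nirsmci.synth import CohortSpec, draw_latent_features  # noqa: E402

N_REPLICATES = 500


def main() -> None:
    rows = []

    chi2 = chi_square_2x2([[37, 47], [21, 31]])
    rows.append(("sex ratio chi-square", f"{chi2.statistic:.3f}", "0.176"))

    t_edu = pooled_t_test(6.88, 4.23, 84, 6.00, 4.32, 52)
    rows.append(("education pooled t", f"{abs(t_edu.statistic):.3f}", "1.170"))

    for label, (sens, spec) in [("MoCA-K", (0.762, 0.885)), ("total PFC", (0.762, 0.923))]:
        rows.append((f"Youden J ({label})", f"{sens + spec - 1:.3f}", ""))

    confusions = {
        "MoCA-K": (64, 5, 20, 47),
        "left PFC": (70, 3, 14, 49),
        "right PFC": (60, 5, 24, 47),
        "total PFC": (65, 4, 19, 48),
    }
    for label, counts in confusions.items():
        ppv, npv = predictive_values(ConfusionMatrix(*counts), "healthy_positive")
        rows.append((f"PPV ({label})", f"{100 * ppv:.2f}%", ""))
        rows.append((f"NPV ({label})", f"{100 * npv:.2f}%", ""))

    rng = np.random.default_rng(cfg_mod.SEED)
    ts, rs = [], []
    for _ in range(N_REPLICATES):
        t = draw_latent_features(CohortSpec(), rng=rng)
        ts.append(
            pooled_t_test_from_data(
                t.loc[t.group == "healthy", "mhbo_left"],
                t.loc[t.group == "mci", "mhbo_left"],
            ).statistic
        )
        rs.append(np.corrcoef(t.moca_k, t.mhbo_left)[0, 1])
    rows.append((f"E[t] left PFC ({N_REPLICATES} replicate cohorts)",
                 f"{np.mean(ts):.3f}", "10.100"))
    rows.append((f"E[r] MoCA-K vs left PFC ({N_REPLICATES} replicate cohorts)",
                 f"{np.mean(rs):.3f}", "0.500"))

    df = pd.DataFrame(rows, columns=["quantity", "recomputed", "published"])
    out = cfg_mod.RESULTS_DIR / "reference_checks.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"-> {out}")


if __name__ == "__main__":
    main()
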