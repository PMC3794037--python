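"""Survey one landscape at a coarse and a fine grain and compare protocols.

Runs the field protocol (all roads, certain detection to 0.3 km) and the
imagery protocol (covered roads only, 0.1 km with a 0.05 km clear band)
on the same seed-1 landscape, at 16 km and 2 km grains, then prints the
confusion matrix and agreement statistics per grain.

Writes per-cell status tables and a metrics table to results/.
"""

from pathlib import Path

import pandas as pd

from streetsurvey import ScenarioConfig, round_report, run_scenario

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    results = run_scenario(
        ScenarioConfig(), grains=[16.0, 2.0], n_replicates=1, seed=0, replicate_seeds=[SEED]
    )
    rows = []
    for r in results:
        r.table.to_csv(OUT / f"cells_grain{r.grain:g}km.csv", index=False)
        rows.append(
            {
                "grain_km": r.grain,
                "analyzed_cells": r.cm.total,
                "no_data_cells": int((r.table.imagery_status == "NO_DATA").sum()),
                "TP": r.cm.tp,
                "FP": r.cm.fp,
                "FN": r.cm.fn,
                "TN": r.cm.tn,
                "sensitivity": round_report(r.metrics.sensitivity),
                "specificity": round_report(r.metrics.specificity),
                "accuracy": round_report(r.metrics.accuracy),
                "mcc": round_report(r.metrics.mcc),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "survey_metrics.csv", index=False)
    print(table.to_string(index=False))
    print(
        "\nThe imagery survey never produces a false positive (it can only "
        "detect real nests), and the fine grain loses sensitivity: many 2 km "
        "cells hold nests far from any imagery-covered road."
    )


if __name__ == "__main__":
    main()
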