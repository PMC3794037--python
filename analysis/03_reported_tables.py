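"""Agreement statistics of the published campaign confusion matrices.

The two printed matrices — large grid (16 km grain, 183 cells) TP=165,
FP=0, FN=13, TN=5 and small grid (2 km grain, 115 analyzed of 121
cells) TP=3, FP=0, FN=63, TN=49 — are fed to the metrics operation.

Writes results/reported_metrics.csv.
"""

from pathlib import Path

import pandas as pd

from streetsurvey import ConfusionMatrix, metrics, round_report

OUT = Path(__file__).resolve().parent.parent / "results"

MATRICES = {
    "large_grid_16km": ConfusionMatrix(165, 0, 13, 5),
    "small_grid_2km": ConfusionMatrix(3, 0, 63, 49),
}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for name, cm in MATRICES.items():
        m = metrics(cm)
        rows.append(
            {
                "grid": name,
                "TP": cm.tp,
                "FP": cm.fp,
                "FN": cm.fn,
                "TN": cm.tn,
                "analyzed": cm.total,
                "sensitivity": round_report(m.sensitivity),
                "specificity": round_report(m.specificity),
                "accuracy": round_report(m.accuracy),
                "mcc": round_report(m.mcc),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "reported_metrics.csv", index=False)
    print(table.to_string(index=False))
    print(
        "\nCoarse grain: near-perfect agreement (accuracy 0.929, MCC 0.507). "
        "Fine grain: the imagery survey misses 63 of 66 occupied cells "
        "(sensitivity 0.045) although it never raises a false presence."
    )


if __name__ == "__main__":
    main()
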