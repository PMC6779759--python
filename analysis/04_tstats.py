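"""Extract the T-statistic tables from the pipeline report.

Writes results/tstats_records.csv (per-assemblage T_IP/IC and T_IC/IR) and
results/tstats_trends.csv (each ratio regressed on elevation, temperature
and precipitation).
"""

import json
from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    report = json.loads((RESULTS / "pipeline_report.json").read_text())

    records = pd.DataFrame(report["tstats"]["records"])
    records.to_csv(RESULTS / "tstats_records.csv", index=False)

    rows = []
    for name, fit in report["tstats"]["trends"].items():
        rows.append(
            {
                "trend": name,
                "slope": fit["slope"],
                "slope_lower": fit["slope_ci"][0],
                "slope_upper": fit["slope_ci"][1],
                "r2": fit["r2"],
                "p_value": fit["p_value"],
            }
        )
    pd.DataFrame(rows).to_csv(RESULTS / "tstats_trends.csv", index=False)
    print(f"{len(records)} assemblages, {len(rows)} trends -> tstats_*.csv")


if __name__ == "__main__":
    main()
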