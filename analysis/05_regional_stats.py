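"""Compare the spatial distributions of the three lesion classes.

Runs the Friedman two-way ANOVA by ranks over the regional PD table
(regions as blocks, lesion classes as treatments, left/right averaged):
acute infarcts vs covert WMH, and acute infarcts vs lacunes.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import MAPS_DIR, STATS_DIR

from svdmap.stats import compare_lesion_distributions


def main() -> None:
    STATS_DIR.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(MAPS_DIR / "region_table.csv").fillna({"laterality": ""})
    reports = {}
    for treatments in (["infarct", "wmh"], ["infarct", "lacune"]):
        name = "_vs_".join(treatments)
        report = compare_lesion_distributions(table, treatments)
        reports[name] = report
        print(
            f"{name}: chi2({report['df']}) = {report['statistic']:.3f}, "
            f"p = {report['pvalue']:.4f} ({report['method']}, "
            f"{report['n_blocks']} region blocks)"
        )
    (STATS_DIR / "comparisons.json").write_text(json.dumps(reports, indent=2))
    print(f"\nwrote {STATS_DIR / 'comparisons.json'}")


if __name__ == "__main__":
    main()
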