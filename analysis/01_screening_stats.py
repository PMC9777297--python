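"""Screening-phase descriptives: alexithymia category percentages.

Writes results/screening_percentages.csv and prints the headline rates.
"""

from pathlib import Path

import pandas as pd

from emodecode import DEFAULT_SCREENING, affected_rate, category_percentages

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = DEFAULT_SCREENING
    pct = category_percentages(table)
    rows = [{"label": k, "count": table.category_counts.get(
                 k, table.sex_counts.get(k.removeprefix("sex_"), 0)),
             "percent": v} for k, v in pct.items()]
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "screening_percentages.csv", index=False)
    print(df.to_string(index=False))
    print(f"\naffected rate (truncated to 2 decimals): "
          f"{affected_rate(table):.2f}% of {table.total} screened")


if __name__ == "__main__":
    main()
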