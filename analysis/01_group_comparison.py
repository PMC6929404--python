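#!/usr/bin/env python
"""Compare MAF and reported-OR distributions between East Asian and
Caucasian rs744373 studies (Welch t-test, studies as units)."""

from pathlib import Path

import pandas as pd

from bin1meta import compare_groups, load_bundled_roster, write_results_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    roster = load_bundled_roster()
    comps = compare_groups(roster)  # East Asian minus Caucasian
    rows = []
    for name, res in comps.items():
        rows.append({
            "variable": name, "mean_east_asian": res.mean_a, "mean_caucasian": res.mean_b,
            "t": res.t, "df": res.df, "p": res.p,
        })
        verdict = "differs" if res.p < 0.05 else "does not differ"
        print(f"{name.upper()}: East Asian mean {res.mean_a:.3f} vs Caucasian {res.mean_b:.3f} "
              f"-> t = {res.t:.3f} (df {res.df:.1f}), p = {res.p:.3g}; {verdict} between ancestries")
    OUT.mkdir(exist_ok=True)
    write_results_table(pd.DataFrame(rows), OUT / "group_comparison.csv")
    print(f"wrote {OUT / 'group_comparison.csv'}")


if __name__ == "__main__":
    main()
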