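#!/usr/bin/env python
"""Entropy weights per year and subsystem for the synthetic panel.

Reads results/synthetic/panel.csv (run 02_simulate_panel.py first), writes
the weight table, and prints the top-weighted indicator per subsystem in the
first and last year — dispersion across regions, not magnitude, is what
earns an indicator weight.
"""

from pathlib import Path

from eldercare_coupling import DEFAULT_INDICATORS, read_panel, weight_table, write_results

BASE = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main():
    panel = read_panel(BASE / "panel.csv", DEFAULT_INDICATORS)
    wt = weight_table(panel)
    write_results(wt, BASE / "weights.csv")
    for year in (panel.years[0], panel.years[-1]):
        for sub in ("supply", "demand"):
            sl = wt[(wt["year"] == year) & (wt["subsystem"] == sub)]
            top = sl.loc[sl["weight"].idxmax()]
            print(f"{year} {sub:7s}: top weight {top['indicator']} = {top['weight']:.4f}")
    print(f"wrote {BASE / 'weights.csv'}")


if __name__ == "__main__":
    main()
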