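#!/usr/bin/env python
"""Plot clone/repeat location histograms from a run-all report directory.

Optional figure helper (requires matplotlib); the analysis itself never
depends on plotting.

Usage: python scripts/plot_locations.py <reports_dir> <out.png>
"""

import sys
from pathlib import Path

import pandas as pd


def main() -> None:
    if len(sys.argv) != 3:
        sys.exit(__doc__)
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    reports = Path(sys.argv[1])
    df = pd.read_csv(reports / "location_histograms.tsv", sep="\t")
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for lib, sub in df.groupby("library"):
        ax1.plot(sub["percent_bin"], sub["fraction"], label=lib, lw=1)
        ax2.plot(sub["percent_bin"], sub["cumulative_at_or_after"], label=lib, lw=1)
    ax1.set_xlabel("percent of chromosome")
    ax1.set_ylabel("fraction starting in bin")
    ax2.set_xlabel("percent of chromosome")
    ax2.set_ylabel("fraction starting at or after")
    ax1.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(sys.argv[2], dpi=150)
    print(f"wrote {sys.argv[2]}")


if __name__ == "__main__":
    main()
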