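#!/usr/bin/env python
"""Plot among- vs within-population slopes against the line of unity.

Species on the unity line respond identically to temperature over space
and time (pure plasticity); species below it (shallower spatial slope,
with both slopes negative) are consistent with countergradient local
adaptation.

Writes results/space_time.png.
"""

from pathlib import Path

import pandas as pd

from phenodecomp.pipeline import plot_space_time

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    summary = pd.read_csv(ROOT / "species_summary.csv")
    path = plot_space_time(summary, ROOT / "space_time.png")
    below = (summary["b_time_mode"] < summary["b_space_mode"]).sum()
    print(f"wrote {path}; {below}/{len(summary)} species below the unity line "
          "(temporal response steeper than spatial)")


if __name__ == "__main__":
    main()
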