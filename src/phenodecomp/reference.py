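"""Published modal slope estimates for 31 UK butterfly species.

Bundled reference values from a long-term UK monitoring analysis of
flight-date/temperature slopes (posterior modes with 95% intervals for the
within-population slope, among-population slope, and their difference).
Used for convention checks — the delta_b sign convention and the HPD
decision rule — not as inputs to any fit.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_published_slopes() -> pd.DataFrame:
    """Load the bundled species slope-estimate table.

    Columns include ``b_time_mode/lo/hi``, ``b_space_mode/lo/hi`` and
    ``delta_b_mode/lo/hi`` (days per degC), the selected window centre
    month, and sample sizes.
    """
    with resources.files("phenodecomp.data").joinpath("species_slope_estimates.csv").open() as fh:
        return pd.read_csv(fh)
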