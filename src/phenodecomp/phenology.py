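"""Flight-period phenology measures from transect counts.

The timing of a flight period at one site in one year is measured as the
count-weighted mean day of the adult counts, an estimate of the date of mean
abundance.  Days are indexed from the start of the recording season
(day 1 = 1 April); the standard season spans 26 weekly visits, days 1-182.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default full-season day range (1 April .. late September)
SEASON_WINDOW: tuple[int, int] = (1, 182)


def weighted_mean_flight_date(days, counts, window: tuple[int, int] | None = None) -> float:
    """Count-weighted mean day for one site-year-species series.

    ``sum(count_d * d) / sum(count_d)`` over visits inside ``window``.
    Zero-count visits carry zero weight.  Returns NaN (the "no flight
    record" sentinel) when no positive count falls inside the window, so
    batch processing can continue.
    """
    d = np.asarray(days, dtype=float)
    c = np.asarray(counts, dtype=float)
    if d.shape != c.shape:
        raise ValueError("days and counts must have equal length")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    if window is not None:
        lo, hi = window
        keep = (d >= lo) & (d <= hi)
        d, c = d[keep], c[keep]
    total = c.sum()
    if total <= 0:
        return float("nan")
    return float((c * d).sum() / total)


def generation_window(config, species_id: str) -> tuple[int, int]:
    """Day range restricting phenology to a single generation.

    ``config`` maps species id to an inclusive ``(first_day, last_day)``
    pair, e.g. restricting a bivoltine species to its spring brood or an
    adult-overwintering species to the prehibernation period.  Species
    absent from the config get the full season.
    """
    window = None
    if config:
        window = config.get(species_id)
    if window is None:
        return SEASON_WINDOW
    lo, hi = int(window[0]), int(window[1])
    if lo > hi:
        raise ValueError(f"inverted generation window for {species_id}: ({lo}, {hi})")
    return (lo, hi)


def flight_records(counts: pd.DataFrame,
                   generation_windows=None) -> pd.DataFrame:
    """Per site x year x species flight records from a transect count table.

    Parameters
    ----------
    counts
        Table with columns ``site_id, species_id, year, day, count``.
    generation_windows
        Optional mapping species_id -> (first_day, last_day); counts outside
        a species' window are ignored (see :func:`generation_window`).

    Returns
    -------
    One row per site-year-species with at least one positive in-window count:
    ``site_id, species_id, year, mean_flight_date, total_count,
    n_positive_visits, n_visits, first_positive_day, last_positive_day``.
    Combinations with no positive count yield no record.
    """
    required = {"site_id", "species_id", "year", "day", "count"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if (counts["count"] < 0).any():
        raise ValueError("counts must be non-negative")

    frames = []
    for sp, g in counts.groupby("species_id", sort=True):
        lo, hi = generation_window(generation_windows, sp)
        g = g[(g["day"] >= lo) & (g["day"] <= hi)]
        if g.empty:
            continue
        grp = g.groupby(["site_id", "year"], sort=True)
        agg = grp.agg(n_visits=("day", "size"), total_count=("count", "sum"))
        wsum = grp.apply(lambda x: float((x["count"] * x["day"]).sum()), include_groups=False)
        pos = g[g["count"] > 0].groupby(["site_id", "year"], sort=True)
        pagg = pos.agg(n_positive_visits=("day", "size"),
                       first_positive_day=("day", "min"),
                       last_positive_day=("day", "max"))
        rec = agg.join(pagg, how="inner")  # drops site-years with no positive count
        rec["mean_flight_date"] = wsum.loc[rec.index] / rec["total_count"]
        rec = rec.reset_index()
        rec["species_id"] = sp
        frames.append(rec)

    cols = ["site_id", "species_id", "year", "mean_flight_date", "total_count",
            "n_positive_visits", "n_visits", "first_positive_day", "last_positive_day"]
    if not frames:
        return pd.DataFrame(columns=cols)
    out = pd.concat(frames, ignore_index=True)
    return out[cols]


def sufficiency_filter(records: pd.DataFrame,
                       min_positive_visits: int = 3,
                       min_span_days: int = 7) -> pd.DataFrame:
    """Drop records too sparse to characterise a flight period.

    Keeps records with ``n_positive_visits >= min_positive_visits`` and a
    span of at least ``min_span_days`` between first and last positive day.
    A simple, explicit filter standing in for scheme-specific annual-index
    sufficiency rules; thresholds are knobs, logged on every call.
    """
    if min_positive_visits < 0 or min_span_days < 0:
        raise ValueError("thresholds must be non-negative")
    span = records["last_positive_day"] - records["first_positive_day"]
    keep = (records["n_positive_visits"] >= min_positive_visits) & (span >= min_span_days)
    out = records[keep].reset_index(drop=True)
    logger.info("sufficiency_filter(min_positive_visits=%d, min_span_days=%d): "
                "kept %d / %d records", min_positive_visits, min_span_days,
                len(out), len(records))
    return out
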