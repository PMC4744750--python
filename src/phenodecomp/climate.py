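"""Three-monthly running-mean temperatures and predictive-window selection.

A species' flight date is driven by temperature over some seasonal window.
Rather than assuming which developmental period matters, twelve candidate
three-month windows (labelled by their centre month) are regressed against
the national annual mean flight date and the window with the strongest
relationship is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: grid-cell edge used for linking sites to the temperature grid (m)
DEFAULT_CELL_SIZE_M = 5000.0


def assign_site_to_cell(sites: pd.DataFrame, cell_size_m: float = DEFAULT_CELL_SIZE_M) -> pd.DataFrame:
    """Attach grid-cell indices to a site table.

    Cells are half-open squares on the projected grid: a site at coordinate
    ``x`` falls in cell ``floor(x / cell_size_m)``, so a point exactly on a
    boundary belongs to the higher-indexed cell.

    Parameters
    ----------
    sites
        Table with columns ``site_id, easting_m, northing_m``.
    cell_size_m
        Cell edge length in metres.

    Returns
    -------
    Copy of ``sites`` with integer columns ``cell_e`` and ``cell_n``.
    """
    if cell_size_m <= 0:
        raise ValueError("cell_size_m must be positive")
    east = sites["easting_m"].to_numpy(dtype=float)
    north = sites["northing_m"].to_numpy(dtype=float)
    if (east < 0).any() or (north < 0).any():
        raise ValueError("site coordinates must be non-negative on the projected grid")
    out = sites.copy()
    out["cell_e"] = np.floor(east / cell_size_m).astype(int)
    out["cell_n"] = np.floor(north / cell_size_m).astype(int)
    return out


def three_month_running_mean(temps: pd.DataFrame) -> pd.DataFrame:
    """Three-month running means of monthly temperatures, per grid cell.

    The window centred on month ``m`` of year ``y`` averages months
    ``m-1, m, m+1``; January borrows December of ``y-1`` and December borrows
    January of ``y+1``.  Windows whose neighbours are missing are absent from
    the output rather than zero-filled.

    Parameters
    ----------
    temps
        Table with columns ``cell_e, cell_n, year, month, mean_temp_c``.

    Returns
    -------
    Table with columns ``cell_e, cell_n, year, center_month, mean_temp``.
    """
    required = {"cell_e", "cell_n", "year", "month", "mean_temp_c"}
    missing = required - set(temps.columns)
    if missing:
        raise ValueError(f"temperature table missing columns: {sorted(missing)}")
    frames = []
    for (ce, cn), g in temps.groupby(["cell_e", "cell_n"], sort=True):
        t = g["year"].to_numpy(dtype=int) * 12 + (g["month"].to_numpy(dtype=int) - 1)
        s = pd.Series(g["mean_temp_c"].to_numpy(dtype=float), index=t)
        if s.index.has_duplicates:
            raise ValueError(f"duplicate (year, month) rows for cell ({ce}, {cn})")
        s = s.sort_index()
        full = s.reindex(range(s.index.min(), s.index.max() + 1))
        win = (full.shift(1) + full + full.shift(-1)) / 3.0
        win = win.dropna()
        if win.empty:
            continue
        idx = win.index.to_numpy()
        frames.append(pd.DataFrame({
            "cell_e": ce, "cell_n": cn,
            "year": idx // 12, "center_month": idx % 12 + 1,
            "mean_temp": win.to_numpy(),
        }))
    if not frames:
        return pd.DataFrame(columns=["cell_e", "cell_n", "year", "center_month", "mean_temp"])
    return pd.concat(frames, ignore_index=True)


@dataclass
class WindowSelection:
    """Per-window regression diagnostics and the selected centre month."""

    species_id: str
    selected_center_month: int
    criterion: str
    table: pd.DataFrame = field(repr=False)  # center_month, coefficient, se, t_value, n_years
    national: pd.DataFrame = field(repr=False)  # year, flight_date, temp per window


def select_window(records: pd.DataFrame,
                  window_temps: pd.DataFrame,
                  sites: pd.DataFrame,
                  cell_size_m: float = DEFAULT_CELL_SIZE_M,
                  criterion: str = "t_value",
                  min_years: int = 3,
                  species_id: str | None = None) -> WindowSelection:
    """Select the three-month window most predictive of national flight date.

    For each of the twelve candidate windows an ordinary least-squares
    regression of national annual mean flight date on national annual mean
    window temperature is fitted; the window maximizing ``|t|`` (or the
    absolute coefficient, under ``criterion="coefficient"``) is selected.
    National means are unweighted: the flight date averages over all sites
    with a record in that year, and the temperature averages over those
    sites' grid cells.

    Ties are broken toward the earlier centre month.  Windows with fewer than
    ``min_years`` usable years or zero temperature variance are excluded
    (reported with NaN diagnostics).
    """
    if criterion not in ("t_value", "coefficient"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if records.empty:
        raise ValueError("no flight records supplied")
    if species_id is None:
        ids = records["species_id"].unique() if "species_id" in records.columns else ["?"]
        if len(ids) != 1:
            raise ValueError("records contain multiple species; pass one species at a time")
        species_id = str(ids[0])

    national_phen = records.groupby("year")["mean_flight_date"].mean()

    cells = assign_site_to_cell(sites, cell_size_m)[["site_id", "cell_e", "cell_n"]]
    contrib = records[["site_id", "year"]].drop_duplicates().merge(cells, on="site_id", how="left")
    if contrib[["cell_e", "cell_n"]].isna().any().any():
        bad = contrib.loc[contrib["cell_e"].isna(), "site_id"].unique()
        raise ValueError(f"sites missing from site table: {list(bad)[:5]}")
    site_temp = contrib.merge(window_temps, on=["cell_e", "cell_n", "year"], how="inner")
    national_temp = (site_temp.groupby(["center_month", "year"])["mean_temp"].mean()
                     .rename("temp").reset_index())

    rows = []
    nat_frames = []
    for m in range(1, 13):
        sub = national_temp[national_temp["center_month"] == m]
        merged = pd.DataFrame({"year": national_phen.index, "flight_date": national_phen.to_numpy()})
        merged = merged.merge(sub[["year", "temp"]], on="year", how="inner")
        nat = merged.assign(center_month=m)
        nat_frames.append(nat)
        if len(merged) < min_years:
            rows.append((m, np.nan, np.nan, np.nan, len(merged)))
            continue
        x = merged["temp"].to_numpy()
        y = merged["flight_date"].to_numpy()
        if np.ptp(x) == 0:
            warnings.warn(f"window {m}: zero temperature variance, excluded")
            rows.append((m, np.nan, np.nan, np.nan, len(merged)))
            continue
        res = stats.linregress(x, y)
        slope, se = res.slope, res.stderr
        if se == 0:
            t = np.inf * np.sign(slope) if slope != 0 else 0.0
        else:
            t = slope / se
        rows.append((m, slope, se, t, len(merged)))

    table = pd.DataFrame(rows, columns=["center_month", "coefficient", "se", "t_value", "n_years"])
    crit_col = "t_value" if criterion == "t_value" else "coefficient"
    crit = table[crit_col].abs()
    if crit.isna().all():
        raise ValueError("no window has enough usable years (need >= "
                         f"{min_years} years with both responses)")
    # deterministic tie-break toward the earlier centre month
    best_m, best_val = None, -np.inf
    for _, row in table.sort_values("center_month").iterrows():
        v = abs(row[crit_col])
        if np.isfinite(v) or v == np.inf:
            if v > best_val:
                best_val, best_m = v, int(row["center_month"])
    return WindowSelection(species_id=species_id, selected_center_month=best_m,
                           criterion=criterion, table=table,
                           national=pd.concat(nat_frames, ignore_index=True))
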