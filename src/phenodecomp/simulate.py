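"""Synthetic monitoring-scheme data with known ground truth.

Everything downstream of this module (phenology measures, window selection,
slope decomposition, meta-analysis) is validated against data generated here
with known parameters: a landscape of transect sites on a projected grid, a
gridded monthly temperature field with a south-north gradient and shared
interannual anomalies, seasonal flight curves whose latent mean date responds
to a three-month temperature cue with separate within-population (plastic)
and among-population (plastic + locally adapted) slopes, and species-level
estimates evolved on a phylogeny.

All generators are pure functions of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .climate import assign_site_to_cell, three_month_running_mean
from .decompose import aggregate_populations

DEFAULT_CELL_SIZE_M = 5000.0

#: 26 weekly visit days starting 1 April (day 1)
WEEKLY_SCHEDULE = np.arange(1, 183, 7)


@dataclass(frozen=True)
class LandscapeSpec:
    """Landscape and temperature-field parameters.

    The temperature for grid cell c in (year, month) is

        base + seasonal(month) + gradient * northing_c / 1e6
             + anomaly(year) + noise(year, month)

    with both stochastic terms shared across all cells: the year anomaly is
    a common interannual shift and the month noise an independent
    spatially-coherent fluctuation per (year, month).  Weather anomalies at
    this landscape scale are strongly spatially correlated, so the spatial
    dimension of the field is the static latitudinal gradient while the
    temporal dimension mixes year- and month-level variation — which is what
    lets the window-selection stage discriminate candidate windows.  The
    generated table covers (first_year - 1) .. (last_year + 1) so windows
    centred on January and December of the analysis years are computable.
    """

    n_sites: int = 60
    extent_m: float = 1_000_000.0
    temp_south_north_gradient: float = -6.0   # degC per 1000 km of northing
    annual_anomaly_sd: float = 0.7            # degC, per year, shared across cells
    month_noise_sd: float = 1.2               # degC, per (year, month), shared across cells
    seasonal_amplitude: float = 6.0           # degC, half peak-to-trough
    base_temp_c: float = 9.0
    year_range: tuple[int, int] = (1976, 2005)

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.extent_m <= 0:
            raise ValueError("extent_m must be positive")
        for name in ("annual_anomaly_sd", "month_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        y0, y1 = self.year_range
        if y1 - y0 + 1 < 2:
            raise ValueError("year_range must span at least 2 years")


def _seasonal_cycle(month: np.ndarray, amplitude: float) -> np.ndarray:
    # warmest around June/July, coldest around December/January
    return amplitude * -np.cos(2 * np.pi * month / 12.0)


def make_landscape(spec: LandscapeSpec, seed: int,
                   cell_size_m: float = DEFAULT_CELL_SIZE_M) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate site coordinates and the monthly temperature table.

    Sites are uniform over the square ``[0, extent_m]^2``; each occupied grid
    cell gets a monthly mean temperature series (cell centroids carry the
    latitudinal gradient, so sites sharing a cell share temperatures).

    Returns
    -------
    sites : DataFrame ``site_id, easting_m, northing_m``
    temps : DataFrame ``cell_e, cell_n, year, month, mean_temp_c``
    """
    rng = np.random.default_rng(seed)
    n = spec.n_sites
    coords = rng.uniform(0.0, spec.extent_m, size=(n, 2))
    sites = pd.DataFrame({
        "site_id": [f"S{i:04d}" for i in range(n)],
        "easting_m": coords[:, 0],
        "northing_m": coords[:, 1],
    })
    cells = (assign_site_to_cell(sites, cell_size_m)[["cell_e", "cell_n"]]
             .drop_duplicates().sort_values(["cell_e", "cell_n"]).reset_index(drop=True))

    y0, y1 = spec.year_range
    years = np.arange(y0 - 1, y1 + 2)
    months = np.arange(1, 13)
    anomaly = rng.normal(0.0, spec.annual_anomaly_sd, size=years.size)
    month_noise = rng.normal(0.0, spec.month_noise_sd, size=(years.size, 12))
    ym = pd.DataFrame({"year": np.repeat(years, 12), "month": np.tile(months, years.size)})
    ym["anom"] = (np.repeat(anomaly, 12) + month_noise.reshape(-1)
                  + _seasonal_cycle(ym["month"].to_numpy(), spec.seasonal_amplitude))

    grid = cells.merge(ym, how="cross")
    north_center = (grid["cell_n"].to_numpy() + 0.5) * cell_size_m
    temp = (spec.base_temp_c + grid["anom"].to_numpy()
            + spec.temp_south_north_gradient * north_center / 1e6)
    temps = grid.drop(columns="anom").assign(mean_temp_c=temp)
    return sites, temps


@dataclass(frozen=True)
class SpeciesSim:
    """Ground-truth phenological parameters for one simulated species.

    The latent mean flight date of site s in year y is

        mu_sy = mu0 + b_time * (T_sy - Tbar_s)
                    + (b_time + delta_b) * (Tbar_s - Tbar)
                    + u_pop + v_year + e_sy

    where T_sy is the site's cue-window temperature, Tbar_s its across-year
    mean and Tbar the grand mean; so b_time is the within-population
    (plastic) slope and b_space = b_time + delta_b the among-population
    slope.  Counts on each visit follow the seasonal flight curve (Gaussian
    with SD flight_sd around mu_sy) scaled to the expected seasonal total.
    """

    species_id: str = "sp1"
    mu0: float = 60.0                # baseline mean flight date, day 1 = 1 April
    b_time: float = -6.4             # days per degC, within population
    delta_b: float = 2.4             # days per degC, local-adaptation difference
    cue_window: int = 4              # centre month of the driving 3-month window
    flight_sd: float = 10.0          # days
    site_abundance_mean: float = 200.0
    pop_date_sd: float = 3.0
    year_date_sd: float = 2.0
    resid_date_sd: float = 5.0

    def __post_init__(self):
        if self.flight_sd <= 0:
            raise ValueError("flight_sd must be positive")
        if self.site_abundance_mean < 0:
            raise ValueError("site_abundance_mean must be >= 0")
        if not 1 <= self.cue_window <= 12:
            raise ValueError("cue_window must be a month in 1..12")
        for name in ("pop_date_sd", "year_date_sd", "resid_date_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def b_space(self) -> float:
        return self.b_time + self.delta_b


@dataclass
class SimTruth:
    """Ground truth recorded at generation time for downstream validation."""

    sim: SpeciesSim
    site_to_population: pd.Series          # site_id -> population label
    site_mean_temp: pd.Series              # Tbar_s
    pop_mean_temp: pd.Series               # mean of Tbar_s over member sites
    grand_mean_temp: float
    latent: pd.DataFrame = field(repr=False)  # site_id, population_id, year, window_temp, mu_latent

    def __post_init__(self):
        if self.site_to_population.index.has_duplicates:
            raise ValueError("a site appears more than once in the population map")


def simulate_counts(sites: pd.DataFrame,
                    temps: pd.DataFrame,
                    sim: SpeciesSim,
                    visit_schedule: np.ndarray | None = None,
                    seed: int = 0,
                    years=None,
                    pop_grid_m: float = 50_000.0,
                    cell_size_m: float = DEFAULT_CELL_SIZE_M,
                    nb_dispersion: float | None = None) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate transect counts for one species over a landscape.

    Parameters
    ----------
    sites, temps
        Output of :func:`make_landscape` (or equivalent tables).
    sim
        Ground-truth species parameters.
    visit_schedule
        Visit days within the season; defaults to the 26 weekly visits
        (days 1, 8, ..., 176).  Pass ``np.arange(1, 183)`` for daily visits.
    years
        Years to simulate; defaults to the interior years of the temperature
        table (first and last serve only as window guards).
    pop_grid_m
        Grid used to assign the *true* population labels recorded in the
        returned :class:`SimTruth`.
    nb_dispersion
        If given, counts are negative-binomial with this shape parameter
        (variance ``m + m^2/k``) instead of Poisson.

    Returns
    -------
    counts : DataFrame ``site_id, species_id, year, day, count``
    truth : SimTruth
    """
    rng = np.random.default_rng(seed)
    schedule = WEEKLY_SCHEDULE if visit_schedule is None else np.asarray(visit_schedule, dtype=int)
    if schedule.size == 0:
        raise ValueError("visit schedule is empty")

    windows = three_month_running_mean(temps)
    cue = windows[windows["center_month"] == sim.cue_window]
    sites_c = assign_site_to_cell(sites, cell_size_m)
    site_win = sites_c.merge(cue[["cell_e", "cell_n", "year", "mean_temp"]],
                             on=["cell_e", "cell_n"], how="left")

    if years is None:
        all_years = np.sort(temps["year"].unique())
        if all_years.size < 3:
            raise ValueError("temperature table must cover at least 3 years")
        years = all_years[1:-1]
    years = np.asarray(sorted(years), dtype=int)

    T = (site_win[site_win["year"].isin(years)]
         .pivot_table(index="site_id", columns="year", values="mean_temp"))
    T = T.reindex(index=sites["site_id"], columns=years)
    if T.isna().any().any():
        bad = np.argwhere(T.isna().to_numpy())[0]
        raise ValueError("no cue-window temperature for site "
                         f"{T.index[bad[0]]!r} in year {T.columns[bad[1]]}")

    Tmat = T.to_numpy()                       # (n_sites, n_years)
    Tbar_s = Tmat.mean(axis=1)
    Tbar = float(Tbar_s.mean())

    pops = aggregate_populations(sites, pop_grid_m)
    pop_of_site = pops.loc[T.index].to_numpy()
    pop_labels, pop_codes = np.unique(pop_of_site, return_inverse=True)

    u = rng.normal(0.0, sim.pop_date_sd, size=pop_labels.size)
    v = rng.normal(0.0, sim.year_date_sd, size=years.size)
    e = rng.normal(0.0, sim.resid_date_sd, size=Tmat.shape)

    mu = (sim.mu0
          + sim.b_time * (Tmat - Tbar_s[:, None])
          + (sim.b_time + sim.delta_b) * (Tbar_s[:, None] - Tbar)
          + u[pop_codes][:, None] + v[None, :] + e)

    # flight curve: Gaussian density over the visit days, normalised so the
    # expected seasonal total over the schedule equals site_abundance_mean
    dens = stats.norm.pdf(schedule[None, None, :], loc=mu[..., None], scale=sim.flight_sd)
    tot = dens.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(tot > 0, dens / tot, 0.0)
    lam = sim.site_abundance_mean * probs
    if nb_dispersion is None:
        counts = rng.poisson(lam)
    else:
        k = float(nb_dispersion)
        if k <= 0:
            raise ValueError("nb_dispersion must be positive")
        p = k / (k + lam)
        counts = rng.negative_binomial(k, p)

    n_s, n_y, n_d = counts.shape
    out = pd.DataFrame({
        "site_id": np.repeat(T.index.to_numpy(), n_y * n_d),
        "species_id": sim.species_id,
        "year": np.tile(np.repeat(years, n_d), n_s),
        "day": np.tile(schedule, n_s * n_y),
        "count": counts.reshape(-1),
    })

    latent = pd.DataFrame({
        "site_id": np.repeat(T.index.to_numpy(), n_y),
        "population_id": np.repeat(pop_of_site, n_y),
        "year": np.tile(years, n_s),
        "window_temp": Tmat.reshape(-1),
        "mu_latent": mu.reshape(-1),
    })
    truth = SimTruth(
        sim=sim,
        site_to_population=pd.Series(pop_of_site, index=T.index, name="population_id"),
        site_mean_temp=pd.Series(Tbar_s, index=T.index, name="mean_window_temp"),
        pop_mean_temp=pd.Series(Tbar_s, index=pop_of_site).groupby(level=0).mean(),
        grand_mean_temp=Tbar,
        latent=latent,
    )
    return out, truth


# ---------------------------------------------------------------------------
# phylogenetic simulation

def random_ultrametric_tree(n_tips: int, seed: int = 0, birth_rate: float = 1.0):
    """Pure-birth ultrametric tree with tips labelled ``sp01..spNN``."""
    import random as _random

    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(birth_rate=birth_rate, death_rate=0.0,
                                    num_extant_tips=n_tips, rng=_random.Random(seed))
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)):
        leaf.taxon.label = f"sp{i + 1:02d}"
    return tree


def simulate_phylo_estimates(tree,
                             mu: float = 0.0,
                             beta: float = 0.0,
                             trait_sd: float = 1.0,
                             sigma_a2: float = 1.0,
                             sigma_e2: float = 1.0,
                             m_variances=0.0,
                             seed: int = 0,
                             n_species: int | None = None) -> tuple[pd.DataFrame, float]:
    """Species-level estimates generated under the phylogenetic meta-model.

    ``y_i = mu + beta * x_i + a_i + e_i + m_i`` with the phylogenetic effect
    ``a ~ N(0, sigma_a2 * A(tree))``, trait ``x`` evolved by Brownian motion
    on the same tree (``x ~ N(0, trait_sd^2 * A)``), independent residuals
    ``e ~ N(0, sigma_e2)`` and measurement error ``m_i ~ N(0, m_var_i)``.

    Returns the estimate table (``species, trait, y, m_var``) and the true
    phylogenetic heritability ``H2 = sigma_a2 / (sigma_a2 + sigma_e2)``.
    """
    from .phylometa import phylo_correlation_matrix

    if sigma_a2 < 0 or sigma_e2 < 0:
        raise ValueError("variances must be >= 0")
    corr = phylo_correlation_matrix(tree)
    labels = list(corr.labels)
    if n_species is not None:
        if n_species > len(labels):
            raise ValueError(f"tree has {len(labels)} tips, {n_species} species requested")
        labels = labels[:n_species]
    idx = [corr.labels.index(l) for l in labels]
    A = corr.matrix[np.ix_(idx, idx)]
    n = len(labels)

    m_var = np.broadcast_to(np.asarray(m_variances, dtype=float), (n,)).copy()
    if (m_var < 0).any():
        raise ValueError("measurement-error variances must be >= 0")

    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
    x = trait_sd * (L @ rng.standard_normal(n))
    a = np.sqrt(sigma_a2) * (L @ rng.standard_normal(n))
    e = rng.normal(0.0, np.sqrt(sigma_e2), size=n)
    m = rng.normal(0.0, np.sqrt(m_var))
    y = mu + beta * x + a + e + m

    df = pd.DataFrame({"species": labels, "trait": x, "y": y, "m_var": m_var})
    denom = sigma_a2 + sigma_e2
    true_h2 = float("nan") if denom == 0 else sigma_a2 / denom
    return df, true_h2
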