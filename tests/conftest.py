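import numpy as np
import pytest

from phenodecomp.phylometa import phylo_correlation_matrix
from phenodecomp.simulate import (LandscapeSpec, SpeciesSim, make_landscape,
                                  simulate_counts)
from phenodecomp.studies import standard_tree


@pytest.fixture(scope="session")
def tree31():
    return standard_tree()


@pytest.fixture(scope="session")
def corr31(tree31):
    return phylo_correlation_matrix(tree31)


@pytest.fixture(scope="session")
def small_world():
    """25-site landscape over 30 years plus one low-noise species driven by
    the March-centred window; used by the climate and phenology tests."""
    spec = LandscapeSpec(n_sites=25, year_range=(1976, 2005))
    sites, temps = make_landscape(spec, seed=11)
    sim = SpeciesSim(species_id="spA", cue_window=3, b_time=-6.0, delta_b=0.0,
                     pop_date_sd=0.5, year_date_sd=0.3, resid_date_sd=1.0)
    counts, truth = simulate_counts(sites, temps, sim, seed=12)
    return {"sites": sites, "temps": temps, "sim": sim, "counts": counts, "truth": truth}
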