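import numpy as np
import pandas as pd
import pytest

from sbamix import CovariateSet, PlotTable


@pytest.fixture()
def three_plot_frame() -> pd.DataFrame:
    """A minimal valid wide-layout table with exact additivity."""
    rows = []
    for i, (sba_p, sba_b) in enumerate([(12.0, 6.0), (15.5, 4.5), (9.25, 7.75)]):
        rows.append(
            {
                "plot_id": f"p{i+1}",
                "si_p": 14.0 + i, "adbh_p": 25.0 + i, "sdi_p": 450.0 + 10 * i,
                "si_b": 15.0 + i, "adbh_b": 28.0 + i, "sdi_b": 240.0 + 10 * i,
                "si_t": 16.0 + i, "adbh_t": 27.0 + i, "sdi_t": 690.0 + 10 * i,
                "sba_p": sba_p, "sba_b": sba_b, "sba_t": sba_p + sba_b,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture()
def three_plot_table(three_plot_frame) -> PlotTable:
    return PlotTable(three_plot_frame)


@pytest.fixture()
def mean_covariates() -> dict[str, CovariateSet]:
    """Published mean covariates per stratum."""
    return {
        "P": CovariateSet(si=14.7, adbh=26.0, sdi=469.2),
        "B": CovariateSet(si=14.8, adbh=29.0, sdi=242.7),
        "total": CovariateSet(si=15.8, adbh=28.0, sdi=698.3),
    }


def random_covariates(rng: np.random.Generator, n: int) -> CovariateSet:
    """Covariates spanning realistic stand conditions."""
    return CovariateSet(
        si=rng.uniform(8.0, 24.0, n),
        adbh=rng.uniform(13.0, 45.0, n),
        sdi=rng.uniform(50.0, 1000.0, n),
    )
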