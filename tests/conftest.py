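"""Shared fixtures: reference records, sites, and analytic climatologies."""

import numpy as np
import pandas as pd
import pytest

import fluxfoot as ff
from fluxfoot.climatology import ACFC
from fluxfoot.micromet import HalfHourRecord, SiteMeta


@pytest.fixture
def ref_site() -> SiteMeta:
    """Forest-height tower with explicit roughness (zm above displacement)."""
    return SiteMeta(site_id="REF", igbp_code=10, lat=50.0, lon=0.0,
                    zm=20.0, hc=1.0, z0=0.1, d=0.0)


@pytest.fixture
def ref_record() -> HalfHourRecord:
    """Moderately convective reference interval."""
    return HalfHourRecord(
        timestamp=pd.Timestamp("2015-06-01 12:00"),
        ws=3.0, wd=270.0, ustar=0.3, sigma_v=0.4, L=-100.0, pblh=1500.0,
        sw_in=600.0, pa=101.0, ta=20.0, h=100.0,
    )


def make_record(**overrides) -> HalfHourRecord:
    base = dict(
        timestamp=pd.Timestamp("2015-06-01 12:00"),
        ws=3.0, wd=270.0, ustar=0.3, sigma_v=0.4, L=-100.0, pblh=1500.0,
        sw_in=600.0, pa=101.0, ta=20.0, h=100.0,
    )
    base.update(overrides)
    return HalfHourRecord(**base)


def gaussian_acfc(sigma: float = 300.0, cell: float = 20.0,
                  half_width: float = 1500.0) -> ACFC:
    """Isotropic Gaussian climatology (analytic percentile areas known)."""
    grid = ff.GridSpec(cell_size=cell, half_width=half_width)
    X, Y = grid.meshgrid()
    w = np.exp(-(X**2 + Y**2) / (2.0 * sigma**2))
    return ACFC(grid=grid, weights=w / w.sum(), n_contributing=1)


@pytest.fixture(scope="session")
def sigma_v_noisy_fit():
    """Shared noisy σ_v training fit (expensive): (model, attainable R²)."""
    cfg = ff.SceneConfig(seed=5)
    training, attainable = ff.gen_sigma_v_training(cfg, n=12000, target_r2=0.78)
    model = ff.fit_sigma_v(training, folds=5, seed=1)
    return model, attainable
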