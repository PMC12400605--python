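"""Environmental characterization of growing regions and PCA scan covariates.

Per-region environmental variables are derived from monthly climate
summaries over the region's growing windows (vegetative and reproductive),
then summarized by a standardized PCA whose first two axes serve as the
population covariates of the genome scan.  A built-in table ships the
published environmental characterization of the six Chinese soybean growing
regions (latitude plus five variables per phase, V = 11).

Conventions pinned down by the published scores: columns are standardized
with the population standard deviation (divisor R), eigenvectors have unit
norm, so eigenvalues sum to V and region scores satisfy (1/R) sum score^2 =
eigenvalue per axis.  PCA sign is arbitrary; orientation is fixed by named
loadings (vegetative-phase mean temperature positive on PC1, reproductive
accumulated temperature negative on PC2 by default).
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

#: Reference (non-leap) year used to resolve calendar windows.
_YEAR = 2001

ENV_COLUMNS = [
    "lat",
    "tavg_veg", "tacc15_veg", "dtr_veg", "prec_veg", "srad_veg",
    "tavg_rep", "tacc15_rep", "dtr_rep", "prec_rep", "srad_rep",
]


def load_builtin_env_table() -> pd.DataFrame:
    """The shipped region x variable table for the six growing regions."""
    with resources.files("adaptscape.data").joinpath("table2_env.csv").open() as fh:
        return pd.read_csv(fh, index_col="region")


@dataclass
class RegionDefinition:
    """A growing region: latitude and the two phenological windows."""

    region_id: int
    latitude: float
    vegetative_window: tuple[dt.date, dt.date]
    reproductive_window: tuple[dt.date, dt.date]

    def __post_init__(self) -> None:
        for w in (self.vegetative_window, self.reproductive_window):
            if w[1] < w[0]:
                raise ValueError(f"region {self.region_id}: empty window {w}")
        if self.reproductive_window[0] <= self.vegetative_window[0]:
            raise ValueError(
                f"region {self.region_id}: reproductive window must start "
                "after the vegetative window"
            )


def _days_in_window(month: int, window: tuple[dt.date, dt.date]) -> int:
    start, end = window
    m_start = dt.date(_YEAR, month, 1)
    m_end = dt.date(_YEAR, month, calendar.monthrange(_YEAR, month)[1])
    lo, hi = max(start, m_start), min(end, m_end)
    return max(0, (hi - lo).days + 1)


def _window_stats(monthly: pd.DataFrame, window: tuple[dt.date, dt.date]) -> dict:
    """Day-weighted window summaries from 12 monthly rows.

    ``monthly`` is indexed by month 1..12 with columns tavg, dtr, prec, srad.
    Accumulated temperature counts only months whose mean is >= 15 C,
    prorated by the days of the month inside the window; precipitation is
    prorated by the fraction of the month inside the window.
    """
    days = np.array([_days_in_window(m, window) for m in range(1, 13)])
    if days.sum() == 0:
        raise ValueError(f"window {window} covers no days")
    m = monthly.reindex(range(1, 13))
    if m[["tavg", "dtr", "prec", "srad"]].to_numpy()[days > 0].size and np.isnan(
        m.loc[days > 0, ["tavg", "dtr", "prec", "srad"]].to_numpy()
    ).any():
        raise ValueError(f"monthly climate missing for months inside {window}")
    w = days / days.sum()
    tavg = float(np.nansum(w * m["tavg"]))
    warm = m["tavg"] >= 15.0
    tacc15 = float(np.nansum(np.where(warm, days * m["tavg"], 0.0)))
    dtr = float(np.nansum(w * m["dtr"]))
    month_len = np.array([calendar.monthrange(_YEAR, mm)[1] for mm in range(1, 13)])
    prec = float(np.nansum(m["prec"] * days / month_len))
    srad = float(np.nansum(w * m["srad"]))
    return {"tavg": tavg, "tacc15": tacc15, "dtr": dtr, "prec": prec, "srad": srad}


def derive_region_variables(
    monthly_climate: dict[int, pd.DataFrame], regions: list[RegionDefinition]
) -> pd.DataFrame:
    """Build the region x variable table from per-region monthly climate.

    ``monthly_climate`` maps region_id to a DataFrame indexed by month
    (1..12) with columns ``tavg`` (degC), ``dtr`` (degC), ``prec`` (mm/month)
    and ``srad`` (kJ m-2 day-1); cell-set aggregation over a cultivation
    mask happens upstream of this table.
    """
    rows = {}
    for reg in regions:
        if reg.region_id not in monthly_climate:
            raise ValueError(f"no monthly climate for region {reg.region_id}")
        monthly = monthly_climate[reg.region_id]
        row = {"lat": reg.latitude}
        for suffix, window in (
            ("veg", reg.vegetative_window),
            ("rep", reg.reproductive_window),
        ):
            stats = _window_stats(monthly, window)
            row.update({f"{k}_{suffix}": v for k, v in stats.items()})
        rows[reg.region_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index")[ENV_COLUMNS]
    table.index.name = "region"
    return table


@dataclass
class EnvPCAResult:
    eigenvalues: np.ndarray  # length V, sums to V
    variance_fraction: np.ndarray  # eigenvalue / V
    loadings: pd.DataFrame  # V x K unit-norm eigenvectors
    scores: pd.DataFrame  # R x K region scores
    columns: list[str]

    @property
    def cumulative_fraction(self) -> np.ndarray:
        return np.cumsum(self.variance_fraction)


def env_pca(
    table: pd.DataFrame,
    orientation: dict[int, tuple[str, float]] | None = None,
) -> EnvPCAResult:
    """Standardized PCA of the region x environmental-variable table.

    Columns are centred and scaled by the population sd (divisor R); the
    correlation matrix is eigendecomposed; scores are the standardized
    matrix times the unit eigenvectors.  ``orientation`` maps axis index to
    ``(column, required_sign)`` of a loading used to fix the arbitrary sign.
    """
    if len(table) < 3:
        raise ValueError("PCA needs at least 3 regions")
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0)
    constant = np.isclose(sd, 0.0)
    if constant.any():
        names = list(table.columns[constant])
        raise ValueError(f"constant column(s): {names}")
    Z = (X - X.mean(axis=0)) / sd
    R, V = Z.shape
    corr = Z.T @ Z / R
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scores = Z @ eigvec

    if orientation is None:
        orientation = {0: ("tavg_veg", +1.0), 1: ("tacc15_rep", -1.0)}
    cols = list(table.columns)
    for axis, (col, sign) in orientation.items():
        if axis >= V or col not in cols:
            continue
        if np.sign(eigvec[cols.index(col), axis]) != np.sign(sign):
            eigvec[:, axis] *= -1.0
            scores[:, axis] *= -1.0

    pc_names = [f"PC{k + 1}" for k in range(V)]
    return EnvPCAResult(
        eigenvalues=eigval,
        variance_fraction=eigval / V,
        loadings=pd.DataFrame(eigvec, index=cols, columns=pc_names),
        scores=pd.DataFrame(scores, index=table.index, columns=pc_names),
        columns=cols,
    )


def scan_covariates(
    pca: EnvPCAResult,
    group_to_region: dict[str, int],
    k: int = 2,
) -> pd.DataFrame:
    """Per-population covariate vectors from region PC scores.

    Populations sharing a region share scores; each covariate is then
    standardized to zero mean / unit variance over the P populations
    (divisor P).  Raises if a population maps to an unknown region or if a
    covariate is constant over the populations.
    """
    missing = [g for g, r in group_to_region.items() if r not in pca.scores.index]
    if missing:
        raise ValueError(f"populations mapped to unknown regions: {missing}")
    rows = {g: pca.scores.loc[r].iloc[:k] for g, r in group_to_region.items()}
    cov = pd.DataFrame.from_dict(rows, orient="index")
    cov.index.name = "population"
    for col in cov.columns:
        sd = cov[col].std(ddof=0)
        if np.isclose(sd, 0.0):
            raise ValueError(f"constant covariate {col} over the scan populations")
        cov[col] = (cov[col] - cov[col].mean()) / sd
    return cov
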