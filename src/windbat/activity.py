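"""Monthly activity aggregation and the group x month binomial GLMM.

Feeding and social activity are analysed as the proportion of a turbine
year's monthly bat recordings that contain feeding buzzes (or social
vocalizations), compared between the Nyctaloid and Pipistrelloid species
groups.  Month enters as an ordered factor with orthogonal polynomial
contrasts (degree 5 over the April-October window), and the binomial
logit model carries random intercepts for site and for each observation
(the latter absorbing overdispersion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import GlmmResult, fit_binomial_glmm

__all__ = [
    "MONTH_LEVELS",
    "GROUPS",
    "ActivityCells",
    "aggregate_activity",
    "orthogonal_month_contrasts",
    "build_design",
    "fit_activity_glmm",
    "marginal_means_and_contrasts",
    "activity_correlation",
]

#: study sampling window (ordered factor levels)
MONTH_LEVELS: tuple[int, ...] = (4, 5, 6, 7, 8, 9, 10)
GROUPS: tuple[str, str] = ("Nyctaloid", "Pipistrelloid")
_REFERENCE_GROUP = GROUPS[0]

CELL_COLUMNS = [
    "site_id",
    "turbine_year_id",
    "month",
    "group",
    "n_recordings",
    "n_feeding",
    "n_social",
]


@dataclass
class ActivityCells:
    """Aggregated cells plus the zero-recording cells that were excluded."""

    cells: pd.DataFrame
    excluded: pd.DataFrame


def aggregate_activity(
    recordings: pd.DataFrame,
    buzzes: pd.DataFrame | None = None,
    social: pd.DataFrame | None = None,
    months: tuple[int, ...] = MONTH_LEVELS,
) -> ActivityCells:
    """Count recordings / feeding recordings / social recordings per
    (site, turbine-year, month, group) using only valid recordings.

    ``recordings`` needs columns recording_id, site_id, turbine_year_id,
    month, group and (optionally) valid; ``buzzes`` and ``social`` need a
    recording_id column referring to it.  Cells with zero recordings are
    dropped from the model table and returned separately.
    """
    req = {"recording_id", "site_id", "turbine_year_id", "month", "group"}
    missing = req - set(recordings.columns)
    if missing:
        raise ValueError(f"recordings table missing columns: {sorted(missing)}")
    rec = recordings.copy()
    if "valid" in rec.columns:
        rec = rec[rec["valid"].astype(bool)]
    rec = rec[rec["month"].isin(months)]

    for name, table in (("buzzes", buzzes), ("social", social)):
        if table is not None and len(table):
            stray = set(table["recording_id"]) - set(recordings["recording_id"])
            if stray:
                raise ValueError(
                    f"{name} table references unknown recordings: {sorted(stray)[:5]}"
                )

    feeding_ids = set(buzzes["recording_id"]) if buzzes is not None and len(buzzes) else set()
    social_ids = set(social["recording_id"]) if social is not None and len(social) else set()
    rec = rec.assign(
        has_feeding=rec["recording_id"].isin(feeding_ids),
        has_social=rec["recording_id"].isin(social_ids),
    )
    grouped = (
        rec.groupby(["site_id", "turbine_year_id", "month", "group"], sort=True)
        .agg(
            n_recordings=("recording_id", "count"),
            n_feeding=("has_feeding", "sum"),
            n_social=("has_social", "sum"),
        )
        .reset_index()
    )

    # full turbine-year x month x group grid, to report empty cells
    ty = rec[["site_id", "turbine_year_id"]].drop_duplicates()
    grid = (
        ty.merge(pd.DataFrame({"month": list(months)}), how="cross")
        .merge(pd.DataFrame({"group": list(GROUPS)}), how="cross")
    )
    full = grid.merge(
        grouped, on=["site_id", "turbine_year_id", "month", "group"], how="left"
    )
    excluded = full[full["n_recordings"].isna()][
        ["site_id", "turbine_year_id", "month", "group"]
    ].reset_index(drop=True)
    cells = grouped.astype(
        {"n_recordings": int, "n_feeding": int, "n_social": int}
    )
    return ActivityCells(cells=cells, excluded=excluded)


def orthogonal_month_contrasts(levels, degree: int | None = None) -> np.ndarray:
    """Orthonormal polynomial contrast matrix for ordered levels.

    Column k is a degree-k polynomial in the level index, orthogonal to
    all lower-degree columns (the ordered-factor coding of standard
    statistical software).  The degree is truncated to n_levels - 1.
    """
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two ordered levels")
    if degree is None:
        degree = k - 1
    if degree > k - 1:
        degree = k - 1
    x = np.arange(1, k + 1, dtype=float)
    V = np.vander(x, degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    Q = Q * np.sign(np.diag(R))  # fix signs so leading coefficients are positive
    return Q[:, 1:]


def build_design(
    cells: pd.DataFrame,
    degree: int = 5,
    months: tuple[int, ...] = MONTH_LEVELS,
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design: intercept + group + month polynomials + interaction.

    With the 7-month window and degree 5 this yields the 12-column design
    (1 + 1 + 5 + 5) of the group x month activity model.
    """
    month_list = list(months)
    if not set(cells["month"]).issubset(month_list):
        raise ValueError("cells contain months outside the configured window")
    C = orthogonal_month_contrasts(month_list, degree)
    degree = C.shape[1]
    m_idx = cells["month"].map({m: i for i, m in enumerate(month_list)}).to_numpy()
    g = (cells["group"] != _REFERENCE_GROUP).to_numpy(dtype=float)
    n = len(cells)
    X = np.empty((n, 2 + 2 * degree))
    X[:, 0] = 1.0
    X[:, 1] = g
    X[:, 2 : 2 + degree] = C[m_idx]
    X[:, 2 + degree :] = C[m_idx] * g[:, None]
    poly = ["Linear", "Quadratic", "Cubic", "Quartic", "Quintic"] + [
        f"^{d}" for d in range(6, degree + 1)
    ]
    names = (
        ["(Intercept)", "Species Group (Pip)"]
        + [f"Month ({poly[d]})" for d in range(degree)]
        + [f"Species Group (Pip) x Month ({poly[d]})" for d in range(degree)]
    )
    return X, names


def fit_activity_glmm(
    cells: pd.DataFrame,
    response: str = "feeding",
    degree: int = 5,
    months: tuple[int, ...] = MONTH_LEVELS,
    olre: bool = True,
    include_year: bool = False,
    **glmm_kwargs,
) -> GlmmResult:
    """Fit the binomial GLMM for feeding or social activity.

    Random intercepts: site and observation level.  A year effect is
    omitted by default (it explained no variability in the study design
    this mirrors); pass ``include_year=True`` to add year codes as an
    extra grouping level via pooled site-year codes.
    """
    col = {"feeding": "n_feeding", "social": "n_social"}.get(response)
    if col is None:
        raise ValueError("response must be 'feeding' or 'social'")
    cells = cells[cells["n_recordings"] > 0].reset_index(drop=True)
    sites = sorted(cells["site_id"].unique())
    if len(sites) < 2:
        raise ValueError("need >= 2 sites for the site random intercept")
    X, names = build_design(cells, degree=degree, months=months)
    if include_year and "year" in cells.columns:
        key = cells["site_id"].astype(str) + ":" + cells["year"].astype(str)
        codes = pd.Categorical(key).codes
    else:
        codes = pd.Categorical(cells["site_id"], categories=sites).codes
    return fit_binomial_glmm(
        y=cells[col].to_numpy(),
        n=cells["n_recordings"].to_numpy(),
        X=X,
        group_idx=codes,
        term_names=names,
        olre=olre,
        **glmm_kwargs,
    )


def _emm_grid(degree: int, months) -> tuple[np.ndarray, list[tuple[str, int]]]:
    month_list = list(months)
    C = orthogonal_month_contrasts(month_list, degree)
    rows, labels = [], []
    for gi, group in enumerate(GROUPS):
        for mi, month in enumerate(month_list):
            row = np.concatenate(([1.0, float(gi)], C[mi], float(gi) * C[mi]))
            rows.append(row)
            labels.append((group, month))
    return np.vstack(rows), labels


def marginal_means_and_contrasts(
    fit: GlmmResult,
    degree: int = 5,
    months: tuple[int, ...] = MONTH_LEVELS,
    conf_level: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimated marginal means for group x month (log-odds scale) and
    Tukey-adjusted pairwise contrasts across the full cell family.

    Means use delta-method standard errors from the fixed-effect
    covariance; the family-wise adjustment uses the studentized range
    distribution with the asymptotic (large) degrees of freedom.
    """
    L, labels = _emm_grid(degree, months)
    est = L @ fit.beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", L, fit.vcov, L))
    zc = stats.norm.ppf(0.5 + conf_level / 2.0)
    emm = pd.DataFrame(
        {
            "group": [g for g, _ in labels],
            "month": [m for _, m in labels],
            "emmean": est,
            "se": se,
            "lower": est - zc * se,
            "upper": est + zc * se,
        }
    )
    k = len(labels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = L[i] - L[j]
            d = float(diff @ fit.beta)
            sd = float(np.sqrt(diff @ fit.vcov @ diff))
            z = d / sd if sd > 0 else np.nan
            p_raw = 2.0 * stats.norm.sf(abs(z))
            p_tukey = float(
                stats.studentized_range.sf(abs(z) * np.sqrt(2.0), k, 1e6)
            )
            rows.append(
                {
                    "contrast": f"{labels[i][0]} {labels[i][1]} - {labels[j][0]} {labels[j][1]}",
                    "estimate": d,
                    "se": sd,
                    "z": z,
                    "p_unadjusted": p_raw,
                    "p_tukey": min(max(p_tukey, p_raw), 1.0),
                }
            )
    return emm, pd.DataFrame(rows)


def activity_correlation(per_turbine_year: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation of feeding / social file counts with
    overall bat-recording counts across turbine years."""
    req = {"n_bat_files", "n_feeding_files", "n_social_files"}
    if not req.issubset(per_turbine_year.columns):
        raise ValueError(f"need columns {sorted(req)}")
    if len(per_turbine_year) < 4:
        raise ValueError("need at least 4 turbine years")
    x = per_turbine_year["n_bat_files"].to_numpy(dtype=float)
    rows = []
    for response in ("n_feeding_files", "n_social_files"):
        yv = per_turbine_year[response].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(yv == yv[0]):
            raise ValueError(f"constant vector: correlation undefined for {response}")
        rho, p = stats.spearmanr(x, yv)
        rows.append({"response": response, "rho": float(rho), "p": float(p),
                     "n": len(per_turbine_year)})
    return pd.DataFrame(rows)
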