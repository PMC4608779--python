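"""Cross-species comparison of standardized expression profiles.

Orthologous profiles measured on different day grids are compared by
linear interpolation onto a common equidistant grid, Pearson correlation,
and a t-based significance assessment:

    t = PCC * sqrt((NP - 2) / (1 - PCC^2)),   df = NP - 2,

where NP is the number of *measured* time points (interpolation adds no
information, so the degrees of freedom are taken from the smaller of the
two original grids inside the compared interval, not from the common
grid).  With NP = 9 the two-tailed p < 0.05 boundary sits at PCC 0.67 and
with NP = 8 at 0.71.

The module also provides the Fisher-z test for a difference between two
correlations, a scan over candidate human interval lengths to estimate the
human/mouse developmental time dilation, and the PCA eigenvector-half
comparison of concatenated human+mouse profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def interpolate_profile(
    days: np.ndarray,
    values: np.ndarray,
    start_day: float,
    end_day: float,
    n_points: int = 11,
) -> np.ndarray:
    """Linearly interpolate a profile onto ``n_points`` equidistant days.

    Measured days that coincide with grid points are reproduced exactly;
    extrapolation beyond the measured range is refused.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if n_points < 2:
        raise ValueError("need at least 2 grid points")
    if start_day < days[0] or end_day > days[-1]:
        raise ValueError(
            f"interval [{start_day}, {end_day}] outside measured range "
            f"[{days[0]}, {days[-1]}] (no extrapolation)"
        )
    if end_day <= start_day:
        raise ValueError("end_day must exceed start_day")
    grid = np.linspace(start_day, end_day, n_points)
    return np.interp(grid, days, values)


def interpolate_profiles(
    profiles: pd.DataFrame,
    start_day: float,
    end_day: float,
    n_points: int = 11,
) -> pd.DataFrame:
    """Vectorized :func:`interpolate_profile` over a genes x days frame."""
    days = np.asarray(profiles.columns, dtype=float)
    grid = np.linspace(start_day, end_day, n_points)
    if start_day < days[0] or end_day > days[-1]:
        raise ValueError("interval outside measured day range")
    out = np.empty((len(profiles), n_points))
    vals = profiles.to_numpy()
    for i in range(len(profiles)):
        out[i] = np.interp(grid, days, vals[i])
    return pd.DataFrame(out, index=profiles.index, columns=grid)


# ---------------------------------------------------------------------------
# correlation significance
# ---------------------------------------------------------------------------

def pcc_significance(pcc: float, n_points: int) -> tuple[float, float]:
    """Two-tailed significance of a Pearson correlation.

    Returns ``(t_stat, p_value)`` with ``df = n_points - 2``.  For
    |pcc| = 1 the statistic is infinite and p = 0 is returned (logged).
    """
    if n_points < 3:
        raise ValueError("need at least 3 points")
    if abs(pcc) > 1:
        raise ValueError("correlation outside [-1, 1]")
    df = n_points - 2
    if abs(pcc) == 1.0:
        log.debug("degenerate |PCC| = 1; returning p = 0")
        return float(np.copysign(np.inf, pcc)), 0.0
    t = pcc * np.sqrt(df / (1.0 - pcc * pcc))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def significance_threshold(n_points: int, alpha: float = 0.05) -> float:
    """Smallest two-decimal PCC significant at ``alpha`` (two-tailed)."""
    for r in np.round(np.arange(0.01, 1.0, 0.01), 2):
        if pcc_significance(float(r), n_points)[1] < alpha:
            return float(r)
    return 1.0


def fisher_difference(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-tailed p-value for a difference between two correlations.

    Uses the Fisher variance-stabilizing transform z = atanh(r);
    Z = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3)) is compared to a standard
    normal.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("Fisher comparison needs n > 3 in both samples")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# pairwise correlations
# ---------------------------------------------------------------------------

def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise PCC between two equally shaped matrices.

    Rows with zero variance (a profile constant inside the compared
    window) are assigned correlation 0 -- no shape information.
    """
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ac, axis=1)
    nb = np.linalg.norm(bc, axis=1)
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac * bc).sum(axis=1) / denom
    r[denom == 0.0] = 0.0
    return np.clip(r, -1.0, 1.0)


def _n_measured(profiles: pd.DataFrame, start: float, end: float) -> int:
    days = np.asarray(profiles.columns, dtype=float)
    return int(((days >= start - 1e-9) & (days <= end + 1e-9)).sum())


def pair_correlations(
    human_profiles: pd.DataFrame,
    mouse_profiles: pd.DataFrame,
    pairs: pd.DataFrame,
    human_interval: tuple[float, float] = (0.0, 21.0),
    mouse_interval: tuple[float, float] = (0.0, 10.0),
    n_grid: int = 11,
) -> pd.DataFrame:
    """Per-ortholog-pair Pearson correlation with significance.

    Both profiles are interpolated to ``n_grid`` equidistant points over
    the species-specific intervals.  Degrees of freedom come from the
    smaller count of measured days inside the intervals.  Pairs whose gene
    was excluded during standardization are skipped (logged).
    """
    keep = pairs["human_gene"].isin(human_profiles.index) & pairs[
        "mouse_gene"
    ].isin(mouse_profiles.index)
    if (~keep).any():
        log.info("skipping %d pairs with excluded genes", int((~keep).sum()))
    pairs = pairs.loc[keep]

    h = interpolate_profiles(
        human_profiles.loc[pairs["human_gene"]], *human_interval, n_grid
    ).to_numpy()
    m = interpolate_profiles(
        mouse_profiles.loc[pairs["mouse_gene"]], *mouse_interval, n_grid
    ).to_numpy()
    r = _pearson_rows(h, m)

    np_eff = min(
        _n_measured(human_profiles, *human_interval),
        _n_measured(mouse_profiles, *mouse_interval),
    )
    out = pairs.reset_index(drop=True).copy()
    out["pcc"] = r
    ts, ps = zip(*(pcc_significance(x, np_eff) for x in r))
    out["n_points"] = np_eff
    out["t_stat"] = ts
    out["p_value"] = ps
    return out


# ---------------------------------------------------------------------------
# time-scale scan
# ---------------------------------------------------------------------------

@dataclass
class TimeScaleScanResult:
    candidate_end_day: float
    frac_positive: float
    frac_significant: float


def time_scale_scan(
    human_profiles: pd.DataFrame,
    mouse_profiles: pd.DataFrame,
    pairs: pd.DataFrame,
    mouse_end: float = 10.0,
    candidate_human_ends: tuple[float, ...] = (12.0, 15.0, 18.0, 21.0),
    n_grid: int = 11,
    alpha: float = 0.05,
):
    """Scan candidate human interval lengths against the mouse interval.

    For each candidate end day E the human [0, E] profiles are correlated
    with the mouse [0, mouse_end] profiles; the candidate maximizing the
    fraction of positively correlated pairs wins (ties broken by the
    fraction significant at ``alpha``, then by the larger end day).

    To keep candidates comparable, significance inside the scan uses one
    fixed correlation threshold for every candidate, derived from the full
    measured grids (shorter candidate windows contain fewer measured human
    days, and letting the threshold float with the window would bias the
    tie-break toward long windows).  Returns ``(table, best_end_day)``.
    """
    if pairs.empty:
        raise ValueError("empty ortholog pair set")
    np_ref = min(
        _n_measured(human_profiles, 0.0, max(candidate_human_ends)),
        _n_measured(mouse_profiles, 0.0, mouse_end),
    )
    rows = []
    for end in candidate_human_ends:
        cor = pair_correlations(
            human_profiles, mouse_profiles, pairs,
            human_interval=(0.0, end), mouse_interval=(0.0, mouse_end),
            n_grid=n_grid,
        )
        p_ref = np.array(
            [pcc_significance(r, np_ref)[1] for r in cor["pcc"]]
        )
        rows.append(
            TimeScaleScanResult(
                candidate_end_day=float(end),
                frac_positive=float((cor["pcc"] > 0).mean()),
                frac_significant=float(
                    ((p_ref < alpha) & (cor["pcc"] > 0)).mean()
                ),
            )
        )
    table = pd.DataFrame([r.__dict__ for r in rows])
    best = table.sort_values(
        ["frac_positive", "frac_significant", "candidate_end_day"],
        ascending=False, kind="mergesort",
    ).iloc[0]
    return table, float(best["candidate_end_day"])


# ---------------------------------------------------------------------------
# PCA eigenvector comparison
# ---------------------------------------------------------------------------

def pca_eigenvector_match(
    human_profiles: pd.DataFrame,
    mouse_profiles: pd.DataFrame,
    pairs: pd.DataFrame,
    human_interval: tuple[float, float] = (0.0, 21.0),
    mouse_interval: tuple[float, float] = (0.0, 10.0),
    n_grid: int = 11,
    n_components: int = 7,
) -> pd.DataFrame:
    """Compare species halves of PCA eigenvectors of concatenated profiles.

    Each ortholog pair contributes a row of 2 * n_grid values (human
    profile interpolated to ``n_grid`` points, then the mouse profile).
    PCA is run on the concatenated matrix and every eigenvector is split
    into its human and mouse halves, which are then correlated.  Reported
    matches are the diagonal pairs (1,1) .. (n_components, n_components)
    plus the off-diagonal (1,2).  Because an eigenvector's sign is
    arbitrary, |PCC| is reported; the raw signed value is kept in a
    separate column.
    """
    keep = pairs["human_gene"].isin(human_profiles.index) & pairs[
        "mouse_gene"
    ].isin(mouse_profiles.index)
    pairs = pairs.loc[keep]
    if len(pairs) < n_components:
        raise ValueError("need at least n_components ortholog pairs")

    h = interpolate_profiles(
        human_profiles.loc[pairs["human_gene"]], *human_interval, n_grid
    ).to_numpy()
    m = interpolate_profiles(
        mouse_profiles.loc[pairs["mouse_gene"]], *mouse_interval, n_grid
    ).to_numpy()
    x = np.hstack([h, m])
    if np.allclose(x.var(axis=0), 0.0):
        raise ValueError("degenerate covariance: all profiles identical")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(x)
    comps = pca.components_  # (n_components, 2 * n_grid)

    def half_pcc(i: int, j: int) -> float:
        a = comps[i - 1, :n_grid]
        b = comps[j - 1, n_grid:]
        return float(np.corrcoef(a, b)[0, 1])

    rows = []
    for i in range(1, n_components + 1):
        r = half_pcc(i, i)
        rows.append((i, i, abs(r), r))
    if n_components >= 2:
        r = half_pcc(1, 2)
        rows.append((1, 2, abs(r), r))
    return pd.DataFrame(
        rows, columns=["component_human", "component_mouse", "abs_pcc", "raw_pcc"]
    )
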