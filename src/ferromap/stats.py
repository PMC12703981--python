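"""Parcel-wise statistics: covariate-adjusted OLS, FDR, effect sizes, power,
method agreement and inter-rater reliability.

For each parcel, susceptibility is the dependent variable in an ordinary
least-squares model with age, sex and either the group indicator
(patients vs controls) or a standardized test score as predictors.  P-values
are corrected with the Benjamini-Hochberg step-up procedure; group effect
sizes are Glass' delta (difference of means over the control SD); post-hoc
power comes from the noncentral-F distribution with ncp = n R^2 / (1 - R^2).
Inter-rater reliability over multi-label hemisphere-by-lobe ratings uses a
lenient pairwise partial-overlap agreement and Krippendorff's alpha with a
set distance (0 if two label sets intersect, else 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .phantom import RaterTable

__all__ = [
    "fit_parcel_regression",
    "bh_fdr",
    "glass_delta",
    "posthoc_power",
    "bland_altman",
    "pairwise_agreement",
    "krippendorff_alpha",
    "InterRaterResult",
    "group_analysis",
]


def fit_parcel_regression(
    values: pd.DataFrame,
    covariates: pd.DataFrame,
    predictor: str = "group",
) -> pd.DataFrame:
    """Per-parcel OLS of susceptibility on age, sex and ``predictor``.

    ``values`` is wide (subjects x parcels); ``covariates`` must contain
    ``age``, ``sex`` and the predictor column ("group" is recoded 1 for
    group "a" / patients, 0 for "b" / controls).  Missing scores are handled
    per parcel by complete-case analysis.  Returns one row per parcel with
    beta/SE/t/p for the predictor, plus R^2 and n.
    """
    cov = covariates.loc[values.index].copy()
    if predictor == "group":
        pred = (cov["group"].astype(str) == "a").astype(float)
    else:
        pred = pd.to_numeric(cov[predictor], errors="coerce")
    X = pd.DataFrame({"age": cov["age"].astype(float), "sex": cov["sex"].astype(float), predictor: pred})

    rows = []
    for parcel in values.columns:
        y = values[parcel]
        ok = y.notna() & X.notna().all(axis=1)
        yy, xx = y[ok].to_numpy(float), X[ok]
        design = sm.add_constant(xx.to_numpy(float), has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            bad = [c for c in xx.columns if xx[c].nunique() <= 1]
            raise ValueError(f"rank-deficient design for parcel {parcel!r}; constant columns: {bad}")
        fit = sm.OLS(yy, design).fit()
        j = 1 + list(xx.columns).index(predictor)
        rows.append(
            {
                "parcel": parcel,
                "beta": fit.params[j],
                "se": fit.bse[j],
                "t": fit.tvalues[j],
                "p": fit.pvalues[j],
                "r2": fit.rsquared,
                "n": int(ok.sum()),
                "k": design.shape[1] - 1,
            }
        )
    return pd.DataFrame(rows).set_index("parcel")


def bh_fdr(pvals, q: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (adjusted p-values, reject flags); rejection uses a strict
    ``adjusted p < q`` so the reported flag always satisfies the invariant
    reject => adjusted p < q.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj < q


def glass_delta(values_a, values_b) -> float:
    """Glass' delta: (mean_a - mean_b) / sample SD of the control group b."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if b.size < 2:
        raise ValueError("control group must have >= 2 observations")
    sd = b.std(ddof=1)
    if sd == 0:
        raise ValueError("control group SD is zero")
    return float((a.mean() - b.mean()) / sd)


def posthoc_power(r2: float, n: int, k: int, alpha: float = 0.01) -> float:
    """Post-hoc power of the overall regression F-test from R^2.

    ncp = n * R^2 / (1 - R^2); power = P(F'(k, n-k-1, ncp) > F_crit(alpha)).
    """
    if not 0 <= r2 < 1:
        raise ValueError("R^2 must be in [0, 1)")
    df1, df2 = k, n - k - 1
    if df2 <= 0:
        raise ValueError("n must exceed k + 1")
    fcrit = sps.f.isf(alpha, df1, df2)
    ncp = n * r2 / (1.0 - r2)
    if ncp == 0:
        return float(alpha)
    return float(sps.ncf.sf(fcrit, df1, df2, ncp))


def bland_altman(a, b) -> tuple[float, tuple[float, float]]:
    """Bias and 95% limits of agreement of paired measurements:
    bias = mean(a - b), LoA = bias +/- 1.96 SD(a - b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    half = 1.96 * float(d.std(ddof=1))
    return bias, (bias - half, bias + half)


@dataclass(frozen=True)
class InterRaterResult:
    pairwise_agreement: float
    krippendorff_alpha: float
    n_raters: int
    n_units: int


def _cells(table: RaterTable) -> dict[str, list[frozenset]]:
    units: dict[str, list[frozenset]] = {}
    for _, row in table.data.iterrows():
        lab = row["labels"]
        if lab is None or (isinstance(lab, float) and np.isnan(lab)) or len(lab) == 0:
            continue
        units.setdefault(row["participant"], []).append(frozenset(lab))
    return units


def pairwise_agreement(table: RaterTable) -> float:
    """Lenient partial-overlap agreement: over all units and rater pairs,
    the fraction of pairs sharing at least one hemisphere-lobe label."""
    units = _cells(table)
    hits = total = 0
    for cells in units.values():
        for s1, s2 in combinations(cells, 2):
            total += 1
            hits += bool(s1 & s2)
    if total == 0:
        raise ValueError("no scorable rater pairs")
    return hits / total


def _set_distance(s1: frozenset, s2: frozenset) -> float:
    # nominal distance generalized to label sets: agreement iff they overlap
    return 0.0 if s1 & s2 else 1.0


def krippendorff_alpha(table: RaterTable) -> float:
    """Krippendorff's alpha with the nominal/set distance.

    alpha = 1 - D_o / D_e where D_o is the within-unit mean pairwise
    disagreement (each unit weighted by m_u / (m_u - 1) ratings in the usual
    coincidence accounting) and D_e the disagreement expected if all ratings
    were exchanged at random across units.
    """
    units = {u: c for u, c in _cells(table).items() if len(c) >= 2}
    if not units:
        raise ValueError("all units are single-rated")
    n_pairable = sum(len(c) for c in units.values())
    d_o = 0.0
    for cells in units.values():
        m = len(cells)
        s = sum(_set_distance(a, b) for a, b in combinations(cells, 2))
        d_o += 2.0 * s / (m - 1)
    d_o /= n_pairable

    all_cells = [c for cells in units.values() for c in cells]
    s = sum(_set_distance(a, b) for a, b in combinations(all_cells, 2))
    d_e = 2.0 * s / (n_pairable * (n_pairable - 1))
    if d_e == 0:
        return 1.0
    return 1.0 - d_o / d_e


def group_analysis(
    values: pd.DataFrame,
    covariates: pd.DataFrame,
    predictor: str = "group",
    q: float = 0.01,
) -> pd.DataFrame:
    """Full parcel-wise analysis: OLS fit, BH-FDR, Glass' delta (for the
    group contrast) and post-hoc power per parcel."""
    res = fit_parcel_regression(values, covariates, predictor=predictor)
    res["p_fdr"], res["reject"] = bh_fdr(res["p"].to_numpy(), q=q)
    res["power"] = [posthoc_power(r.r2, int(r.n), int(r.k), alpha=q) for r in res.itertuples()]
    if predictor == "group":
        grp = covariates.loc[values.index, "group"].astype(str)
        deltas = []
        for parcel in res.index:
            a = values.loc[grp == "a", parcel].dropna()
            b = values.loc[grp == "b", parcel].dropna()
            deltas.append(glass_delta(a, b))
        res["glass_delta"] = deltas
    return res
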