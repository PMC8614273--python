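"""Spatial structure of sand darkness and its link to nesting activity.

Three analyses around the darkness index:

* a Mantel permutation test of the correlation between the matrix of
  geographic distances among beaches and the matrix of pairwise
  darkness differences (is sand colour spatially organised?);
* an AIC comparison of ``darkness ~ distance to nearest Holocene
  volcano`` against an intercept-only model (is dark sand volcanic?);
* ordinary least squares of the log10 nesting share per beach on
  darkness, optionally per km of beach or with length as a covariate
  (do darker beaches host fewer nests?).

Distance matrices are built from beach midpoints with the haversine
formula; the Mantel null is generated by simultaneously permuting the
rows and columns of one matrix, with the correlation taken over the
strictly-lower triangle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .beach_color import BeachRecord, VolcanoRecord, beach_midpoint, haversine_km, nearest_volcano_km
from .nesting import NestingIndex, akaike_weights

__all__ = [
    "MantelResult",
    "LinearFitResult",
    "pairwise_geo",
    "pairwise_absdiff",
    "mantel",
    "mantel_exact",
    "fit_log10_activity",
    "darkness_vs_volcano",
]


def _beach_list(beaches) -> list[BeachRecord]:
    if isinstance(beaches, pd.DataFrame):
        out = []
        for _, row in beaches.iterrows():
            out.append(
                BeachRecord(
                    id=str(row["id"]),
                    lat1=float(row["lat1"]),
                    lon1=float(row["lon1"]),
                    lat2=float(row["lat2"]),
                    lon2=float(row["lon2"]),
                    darkness=float(row["darkness"]),
                    length_km=float(row["length_km"])
                    if "length_km" in row and not pd.isna(row["length_km"])
                    else None,
                )
            )
        return out
    return list(beaches)


def pairwise_geo(beaches) -> pd.DataFrame:
    """Haversine distance matrix (km) between beach midpoints."""
    beaches = _beach_list(beaches)
    if len(beaches) < 2:
        raise ValueError("need at least two beaches")
    mids = [beach_midpoint(b) for b in beaches]
    ids = [b.id for b in beaches]
    n = len(mids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(*mids[i], *mids[j])
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=ids, columns=ids)


def pairwise_absdiff(values: Sequence[float], labels: Sequence[str] | None = None) -> pd.DataFrame:
    """|v_i - v_j| dissimilarity matrix for a scalar beach attribute."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    D = np.abs(v[:, None] - v[None, :])
    if labels is None:
        labels = [str(i) for i in range(v.size)]
    return pd.DataFrame(D, index=list(labels), columns=list(labels))


@dataclass(frozen=True)
class MantelResult:
    r_obs: float
    p_value: float
    n_perm: int
    tail: str
    seed: int | None = None


def _check_square(A: np.ndarray, name: str) -> None:
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(A, A.T, atol=1e-9):
        raise ValueError(f"{name} must be symmetric")


def _tri_corr(a_tri: np.ndarray, b_tri: np.ndarray) -> float:
    a = a_tri - a_tri.mean()
    b = b_tri - b_tri.mean()
    denom = math.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("undefined correlation: a distance matrix is constant")
    return float((a @ b) / denom)


def mantel(
    A,
    B,
    n_perm: int = 9999,
    tail: str = "greater",
    seed: int | None = None,
) -> MantelResult:
    """Mantel permutation test of matrix correlation.

    r_obs is the Pearson correlation of the strictly-lower-triangle
    entries.  The null distribution permutes the row/column order of B
    simultaneously; the p-value uses the add-one estimator
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm) for ``tail='greater'``
    (mirrored for 'less', on |r| for 'two-sided'), which is never zero.
    """
    if isinstance(A, pd.DataFrame) and isinstance(B, pd.DataFrame):
        if list(A.index) != list(B.index):
            raise ValueError("matrices must share the same labels in the same order")
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    _check_square(A, "A")
    _check_square(B, "B")
    if A.shape != B.shape:
        raise ValueError("matrices must have the same shape")
    if A.shape[0] < 3:
        raise ValueError("need at least three items")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = A.shape[0]
    il = np.tril_indices(n, k=-1)
    a_tri = A[il]
    r_obs = _tri_corr(a_tri, B[il])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = _tri_corr(a_tri, B[np.ix_(perm, perm)][il])
        if tail == "greater":
            hits += r >= r_obs
        elif tail == "less":
            hits += r <= r_obs
        elif tail == "two-sided":
            hits += abs(r) >= abs(r_obs)
        else:
            raise ValueError("tail must be greater, less or two-sided")
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(r_obs=r_obs, p_value=float(p), n_perm=n_perm, tail=tail, seed=seed)


def mantel_exact(A, B, tail: str = "greater") -> tuple[float, float]:
    """Exact Mantel p by full enumeration of all n! permutations.

    Tractable only for tiny matrices (n <= 8); serves as the oracle for
    the sampled-permutation test.  The identity permutation is part of
    the null set, so p is the exact proportion of permutations at least
    as extreme as the observed ordering.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    n = A.shape[0]
    if n > 8:
        raise ValueError("exact enumeration limited to n <= 8")
    il = np.tril_indices(n, k=-1)
    a_tri = A[il]
    r_obs = _tri_corr(a_tri, B[il])
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        idx = np.array(perm)
        r = _tri_corr(a_tri, B[np.ix_(idx, idx)][il])
        if tail == "greater":
            hits += r >= r_obs
        elif tail == "less":
            hits += r <= r_obs
        else:
            hits += abs(r) >= abs(r_obs)
        total += 1
    return r_obs, hits / total


@dataclass
class LinearFitResult:
    """OLS fit summary for the darkness regressions."""

    params: pd.Series
    bse: pd.Series
    resid_sd: float
    llf: float
    aic: float
    n: int
    excluded: list[str] = field(default_factory=list)
    sm_results: object = field(default=None, repr=False)

    def summary(self) -> str:
        return str(self.sm_results.summary()) if self.sm_results is not None else repr(self)


def _ols(y: np.ndarray, X: pd.DataFrame) -> sm.regression.linear_model.RegressionResultsWrapper:
    return sm.OLS(y, sm.add_constant(X)).fit()


def fit_log10_activity(
    index: NestingIndex,
    beaches,
    per_km: bool = False,
    include_length: bool = False,
) -> LinearFitResult:
    """OLS of log10 nesting share on sand darkness.

    ``per_km`` regresses log10(p_j / length_km) instead (nest density);
    ``include_length`` adds beach length as a covariate.  Beaches whose
    share is numerically zero are excluded and reported.
    """
    beaches = _beach_list(beaches)
    by_id = {b.id: b for b in beaches}
    rows = []
    excluded = list(index.excluded)
    for beach_id, lp in index.log10_p.items():
        if beach_id not in by_id:
            continue
        if np.isnan(lp):
            if beach_id not in excluded:
                excluded.append(beach_id)
            continue
        b = by_id[beach_id]
        y = lp - np.log10(b.length_km) if per_km else lp
        rows.append({"id": beach_id, "y": y, "darkness": b.darkness, "length_km": b.length_km})
    df = pd.DataFrame(rows)
    if len(df) < 3:
        raise ValueError("need at least three beaches with a positive nesting share")
    if df.darkness.nunique() == 1:
        raise ValueError("degenerate design: darkness is constant")
    cols = ["darkness", "length_km"] if include_length else ["darkness"]
    res = _ols(df.y.to_numpy(), df[cols])
    return LinearFitResult(
        params=res.params,
        bse=res.bse,
        resid_sd=float(np.sqrt(res.scale)),
        llf=float(res.llf),
        aic=float(res.aic),
        n=int(res.nobs),
        excluded=excluded,
        sm_results=res,
    )


def darkness_vs_volcano(beaches, volcanos: Sequence[VolcanoRecord]) -> pd.DataFrame:
    """AIC comparison of darkness ~ nearest-volcano distance vs intercept only.

    Returns one row per model with AIC, delta-AIC and Akaike weight; the
    slope row carries the fitted distance coefficient.
    """
    beaches = _beach_list(beaches)
    if len(beaches) < 3:
        raise ValueError("need at least three beaches")
    if len(volcanos) == 0:
        raise ValueError("need at least one volcano")
    darkness = np.array([b.darkness for b in beaches])
    dist = np.array([nearest_volcano_km(b, volcanos) for b in beaches])
    full = _ols(darkness, pd.DataFrame({"distance_km": dist}))
    null = sm.OLS(darkness, np.ones_like(darkness)).fit()
    aics = np.array([full.aic, null.aic])
    delta, w = akaike_weights(aics)
    return pd.DataFrame(
        {
            "model": ["darkness ~ distance", "intercept only"],
            "aic": aics,
            "delta_aic": delta,
            "akaike_weight": w,
            "slope": [float(full.params["distance_km"]), np.nan],
        }
    )
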