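"""Spatio-temporal nesting-activity model.

Nest counts from a regional monitoring database form a sparse beach x
year table: most beach-year combinations were never surveyed.  To rank
beaches by nesting activity despite that sparseness, the expected count
for year i on beach j is modelled as

    E_ij = T_i * p_j

where T_i is the regional total for year i and p_j is the
time-constant share of beach j (sum_j p_j = 1, so K beaches contribute
K - 1 free parameters).  Three families describe the totals:

* ``constant``       T_i = T                      (1 parameter)
* ``exponential``    T_i = T0 * exp(r * i)        (2 parameters)
* ``year_specific``  free T_1 .. T_Y              (Y parameters)

Observed counts N_ij enter a Gaussian likelihood with a count-dependent
standard deviation S_ij = a * N_ij + b (a, b > 0); unobserved cells
contribute nothing.  Model families are compared by AIC and Akaike
weights, and the fitted model imputes E_ij only where no observation
exists - observed counts are always preferred.

The likelihood is maximised over an unconstrained parameterisation:
shares through the additive-logistic (multinomial-logit) transform,
positive quantities (T, T0, a, b) through logs.  The three families are
nested (constant = exponential at r = 0; any exponential is a
year-specific configuration), and the fitting ladder seeds each family
with the optimum of the simpler one, so minimised -lnL never increases
along the ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_softmax, softmax
from scipy.stats import norm

TemporalKind = Literal["constant", "exponential", "year_specific"]
_KINDS: tuple[TemporalKind, ...] = ("constant", "exponential", "year_specific")

__all__ = [
    "NestCountTable",
    "NestingActivityModel",
    "NestingActivityResults",
    "NestingIndex",
    "temporal_totals",
    "expected_nests",
    "akaike_weights",
    "select_models",
]

# proportions below this are treated as numerically zero on the log10 scale
P_FLOOR = 1e-12


class NestCountTable:
    """Sparse beach x year matrix of observed nest counts.

    ``N`` is a (Y, K) float array with NaN marking unsurveyed cells.
    """

    def __init__(self, beaches: Sequence[str], years: Sequence[int], N) -> None:
        self.beaches = [str(b) for b in beaches]
        self.years = [int(y) for y in years]
        N = np.asarray(N, dtype=float)
        if N.shape != (len(self.years), len(self.beaches)):
            raise ValueError(
                f"N has shape {N.shape}, expected "
                f"({len(self.years)}, {len(self.beaches)})"
            )
        if len(self.beaches) < 1 or len(self.years) < 1:
            raise ValueError("need at least one beach and one year")
        obs = ~np.isnan(N)
        if not obs.any():
            raise ValueError("table contains no observations")
        if np.nanmin(N) < 0:
            raise ValueError("nest counts must be non-negative")
        self.N = N

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "NestCountTable":
        """Build from long-format rows (beach_id, year, nests)."""
        required = {"beach_id", "year", "nests"}
        if not required.issubset(df.columns):
            raise ValueError(f"missing columns: {sorted(required - set(df.columns))}")
        wide = df.pivot_table(
            index="year", columns="beach_id", values="nests", aggfunc="sum"
        )
        wide = wide.sort_index()
        return cls(list(wide.columns), list(wide.index), wide.to_numpy(dtype=float))

    @property
    def n_beaches(self) -> int:
        return len(self.beaches)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def mask(self) -> np.ndarray:
        """Boolean (Y, K) array, True where a count was observed."""
        return ~np.isnan(self.N)

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, year in enumerate(self.years):
            for j, beach in enumerate(self.beaches):
                if not np.isnan(self.N[i, j]):
                    rows.append({"beach_id": beach, "year": year, "nests": self.N[i, j]})
        return pd.DataFrame(rows, columns=["beach_id", "year", "nests"])


def temporal_totals(kind: TemporalKind, params: Sequence[float], n_years: int) -> np.ndarray:
    """Yearly totals T_i for a temporal family.

    ``params`` is (T,) for constant, (T0, r) for exponential with the
    year index i starting at 0 for the first year, or the Y free totals
    for year_specific.  All totals must be strictly positive.
    """
    params = np.asarray(params, dtype=float)
    if kind == "constant":
        if params.shape != (1,):
            raise ValueError("constant model takes one parameter T")
        T = np.full(n_years, params[0])
    elif kind == "exponential":
        if params.shape != (2,):
            raise ValueError("exponential model takes parameters (T0, r)")
        T0, r = params
        T = T0 * np.exp(r * np.arange(n_years))
    elif kind == "year_specific":
        if params.shape != (n_years,):
            raise ValueError(f"year_specific model takes {n_years} totals")
        T = params.copy()
    else:
        raise ValueError(f"unknown temporal model kind: {kind!r}")
    if not np.all(T > 0):
        raise ValueError("all yearly totals must be positive")
    return T


def expected_nests(T: Sequence[float], p: Sequence[float]) -> np.ndarray:
    """Expected counts E_ij = T_i * p_j; rows sum to T_i."""
    T = np.asarray(T, dtype=float)
    p = np.asarray(p, dtype=float)
    if T.ndim != 1 or p.ndim != 1:
        raise ValueError("T and p must be vectors")
    if np.any(T <= 0):
        raise ValueError("totals must be positive")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("p must lie on the simplex")
    return np.outer(T, p)


def akaike_weights(aics: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Delta-AIC and Akaike weights for a compared model set.

    delta_m = AIC_m - min AIC;  w_m = exp(-delta_m/2) / sum exp(-delta/2).
    The weights are the relative probabilities that each model is the
    best of those compared.
    """
    aics = np.asarray(aics, dtype=float)
    if aics.size == 0 or not np.all(np.isfinite(aics)):
        raise ValueError("AIC values must be finite and non-empty")
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return delta, w / w.sum()


# ---------------------------------------------------------------------------
# parameter packing: theta = [temporal block | z (K-1 logits) | log a | log b]


def _n_temporal(kind: TemporalKind, n_years: int) -> int:
    return {"constant": 1, "exponential": 2, "year_specific": n_years}[kind]


def _unpack(theta: np.ndarray, kind: TemporalKind, n_years: int, n_beaches: int):
    nt = _n_temporal(kind, n_years)
    t_block = theta[:nt]
    z = theta[nt : nt + n_beaches - 1]
    log_a, log_b = theta[nt + n_beaches - 1 :]
    if kind == "constant":
        tpar = np.array([np.exp(t_block[0])])
    elif kind == "exponential":
        tpar = np.array([np.exp(t_block[0]), t_block[1]])
    else:
        tpar = np.exp(t_block)
    p = softmax(np.concatenate([z, [0.0]]))
    return tpar, p, np.exp(log_a), np.exp(log_b)


def _negloglik_theta(
    theta: np.ndarray,
    table: NestCountTable,
    kind: TemporalKind,
) -> float:
    try:
        with np.errstate(over="ignore"):
            tpar, p, a, b = _unpack(theta, kind, table.n_years, table.n_beaches)
        if not (np.all(np.isfinite(tpar)) and np.isfinite(a) and np.isfinite(b)):
            return np.inf
        T = temporal_totals(kind, tpar, table.n_years)
    except (ValueError, OverflowError, FloatingPointError):
        return np.inf
    mask = table.mask
    N = table.N[mask]
    E = np.outer(T, p)[mask]
    S = a * N + b
    with np.errstate(over="ignore", invalid="ignore"):
        ll = norm.logpdf(N, loc=E, scale=S)
    total = -float(np.sum(ll))
    return total if np.isfinite(total) else np.inf


def gaussian_negloglik(
    table: NestCountTable,
    kind: TemporalKind,
    temporal_params: Sequence[float],
    p: Sequence[float],
    a: float,
    b: float,
) -> float:
    """-ln likelihood of the observed counts under the model.

    Sum over observed cells of -ln phi(N_ij; E_ij, S_ij) with
    S_ij = a*N_ij + b; missing cells contribute nothing.
    """
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be > 0")
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("p must lie on the simplex")
    T = temporal_totals(kind, temporal_params, table.n_years)
    mask = table.mask
    N = table.N[mask]
    E = np.outer(T, p)[mask]
    S = a * N + b
    out = -float(np.sum(norm.logpdf(N, loc=E, scale=S)))
    if not np.isfinite(out):
        raise ValueError("likelihood is not finite at the given parameters")
    return out


def _moment_init(table: NestCountTable, kind: TemporalKind) -> np.ndarray:
    """Method-of-moments starting point in the unconstrained space."""
    N, mask = table.N, table.mask
    col_mean = np.array(
        [np.nanmean(N[:, j]) if mask[:, j].any() else np.nan for j in range(table.n_beaches)]
    )
    overall = np.nanmean(N)
    col_mean = np.where(np.isnan(col_mean), overall, col_mean)
    col_mean = np.maximum(col_mean, 1e-3)
    p0 = col_mean / col_mean.sum()
    # per-year total implied by observed shares
    T0 = np.empty(table.n_years)
    for i in range(table.n_years):
        obs = mask[i]
        T0[i] = N[i, obs].sum() / max(p0[obs].sum(), 1e-6) if obs.any() else np.nan
    T0 = np.where(np.isnan(T0) | (T0 <= 0), max(np.nanmean(T0), 1.0), T0)
    if kind == "constant":
        t_block = [np.log(T0.mean())]
    elif kind == "exponential":
        t_block = [np.log(T0.mean()), 0.0]
    else:
        t_block = list(np.log(T0))
    z = np.log(p0[:-1]) - np.log(p0[-1])
    resid_sd = max(float(np.nanstd(N)), 1.0)
    return np.concatenate([t_block, z, [np.log(0.2), np.log(resid_sd)]])


@dataclass
class NestingIndex:
    """Final per-beach activity index from a fitted model.

    ``filled`` holds the observed count where one exists and the model
    expectation E_ij elsewhere.  ``log10_p`` is NaN for beaches whose
    share is numerically zero (below 1e-12); those ids are listed in
    ``excluded`` so downstream regressions can report them.
    """

    filled: pd.DataFrame
    p: pd.Series
    log10_p: pd.Series
    excluded: list[str] = field(default_factory=list)


class NestingActivityResults:
    """Fitted nesting-activity model: estimates, fit quality, imputation."""

    def __init__(
        self,
        model: "NestingActivityModel",
        temporal_params: np.ndarray,
        p: np.ndarray,
        a: float,
        b: float,
        negloglik: float,
        converged: bool,
        n_restarts: int,
        message: str = "",
    ) -> None:
        self.model = model
        self.kind: TemporalKind = model.temporal
        self.temporal_params = temporal_params
        self.p = p
        self.a = a
        self.b = b
        self.negloglik = negloglik
        self.converged = converged
        self.n_restarts = n_restarts
        self.message = message
        table = model.table
        self.n_params = _n_temporal(self.kind, table.n_years) + (table.n_beaches - 1) + 2
        self.aic = 2.0 * self.n_params + 2.0 * negloglik
        self.n_obs = table.n_obs
        self.identifiability_warning = self.n_obs < self.n_params

    @property
    def T(self) -> np.ndarray:
        """Fitted yearly totals."""
        return temporal_totals(self.kind, self.temporal_params, self.model.table.n_years)

    def predict(self) -> np.ndarray:
        """Expected counts E_ij = T_i * p_j for every beach-year cell."""
        return expected_nests(self.T, self.p)

    def index(self) -> NestingIndex:
        """Observed-where-available activity index and log10 shares."""
        table = self.model.table
        E = self.predict()
        filled = np.where(table.mask, table.N, E)
        p = pd.Series(self.p, index=table.beaches, name="p")
        with np.errstate(divide="ignore"):
            log10_p = pd.Series(
                np.where(self.p < P_FLOOR, np.nan, np.log10(np.maximum(self.p, P_FLOOR))),
                index=table.beaches,
                name="log10_p",
            )
        excluded = [b for b, val in zip(table.beaches, self.p) if val < P_FLOOR]
        return NestingIndex(
            filled=pd.DataFrame(filled, index=table.years, columns=table.beaches),
            p=p,
            log10_p=log10_p,
            excluded=excluded,
        )

    def to_dict(self) -> dict:
        return {
            "temporal_model": self.kind,
            "temporal_params": [float(v) for v in self.temporal_params],
            "p": {b: float(v) for b, v in zip(self.model.table.beaches, self.p)},
            "a": float(self.a),
            "b": float(self.b),
            "negloglik": float(self.negloglik),
            "n_params": int(self.n_params),
            "aic": float(self.aic),
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "identifiability_warning": bool(self.identifiability_warning),
        }

    def summary(self) -> str:
        lines = [
            "Nesting activity model",
            "=" * 46,
            f"temporal family : {self.kind}",
            f"beaches (K)     : {self.model.table.n_beaches}",
            f"years (Y)       : {self.model.table.n_years}",
            f"observations    : {self.n_obs}",
            f"parameters      : {self.n_params}",
            f"-ln L           : {self.negloglik:.3f}",
            f"AIC             : {self.aic:.3f}",
            f"error SD        : S = {self.a:.4f} * N + {self.b:.4f}",
            f"converged       : {self.converged}",
        ]
        if self.identifiability_warning:
            lines.append(
                "warning         : fewer observations than parameters; "
                "estimates may be weakly identified"
            )
        lines.append("-" * 46)
        T = self.T
        for year, t in zip(self.model.table.years, T):
            lines.append(f"  T[{year}] = {t:12.2f}")
        lines.append("-" * 46)
        for beach, share in zip(self.model.table.beaches, self.p):
            lines.append(f"  p[{beach}] = {share:.6f}")
        return "\n".join(lines)


class NestingActivityModel:
    """Likelihood model for sparse beach x year nest counts.

    Parameters
    ----------
    table:
        Observed counts with missing cells allowed.
    temporal:
        Family for the yearly totals: "constant", "exponential" or
        "year_specific".
    """

    def __init__(self, table: NestCountTable, temporal: TemporalKind = "year_specific") -> None:
        if temporal not in _KINDS:
            raise ValueError(f"temporal must be one of {_KINDS}")
        self.table = table
        self.temporal = temporal

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, temporal: TemporalKind = "year_specific"
    ) -> "NestingActivityModel":
        return cls(NestCountTable.from_dataframe(df), temporal)

    def negloglik(self, temporal_params, p, a, b) -> float:
        return gaussian_negloglik(self.table, self.temporal, temporal_params, p, a, b)

    def _fit_from(self, theta0: np.ndarray) -> optimize.OptimizeResult:
        res = optimize.minimize(
            _negloglik_theta,
            theta0,
            args=(self.table, self.temporal),
            method="L-BFGS-B",
            options={"maxiter": 2000, "maxfun": 20000},
        )
        # keep whichever of init/optimum is better; L-BFGS-B line search is
        # monotone but a failed first step can return the init unchanged
        f0 = _negloglik_theta(theta0, self.table, self.temporal)
        if f0 < res.fun:
            res.x, res.fun = theta0, f0
        return res

    def fit(
        self,
        seed: int | None = 0,
        restarts: int = 5,
        init: np.ndarray | None = None,
        extra_inits: Sequence[np.ndarray] = (),
    ) -> NestingActivityResults:
        """Maximise the likelihood from several starting points.

        The method-of-moments start is always used; ``restarts`` seeded
        perturbations of it guard against local optima in the share
        parameters for sparse tables.  ``extra_inits`` lets callers seed
        the fit with the optimum of a nested (simpler) family.
        """
        rng = np.random.default_rng(seed)
        inits = [init if init is not None else _moment_init(self.table, self.temporal)]
        inits.extend(np.asarray(e, dtype=float) for e in extra_inits)
        base = inits[0]
        for _ in range(restarts):
            inits.append(base + rng.normal(0.0, 0.5, size=base.shape))
        best = None
        for theta0 in inits:
            res = self._fit_from(theta0)
            if best is None or res.fun < best.fun:
                best = res
        tpar, p, a, b = _unpack(best.x, self.temporal, self.table.n_years, self.table.n_beaches)
        return NestingActivityResults(
            model=self,
            temporal_params=tpar,
            p=p,
            a=a,
            b=b,
            negloglik=float(best.fun),
            converged=bool(best.success and np.isfinite(best.fun)),
            n_restarts=len(inits) - 1,
            message=str(best.message),
        )


def _promote_theta(
    res: NestingActivityResults, target: TemporalKind, table: NestCountTable
) -> np.ndarray:
    """Re-express a fitted simpler model in a richer family's space."""
    T = res.T
    if target == "exponential":
        t_block = [np.log(T.mean()), 0.0] if res.kind == "constant" else None
        if t_block is None:
            raise ValueError("can only promote constant to exponential")
    elif target == "year_specific":
        t_block = list(np.log(T))
    else:
        raise ValueError("promotion target must be a richer family")
    z = np.log(np.maximum(res.p[:-1], P_FLOOR)) - np.log(max(res.p[-1], P_FLOOR))
    return np.concatenate([t_block, z, [np.log(res.a), np.log(res.b)]])


def select_models(
    table: NestCountTable,
    kinds: Sequence[TemporalKind] = _KINDS,
    seed: int | None = 0,
    restarts: int = 5,
) -> tuple[pd.DataFrame, NestingActivityResults]:
    """Fit each temporal family and compare them by AIC.

    Families are fitted from simplest to richest, each seeded with the
    reparameterised optimum of the previous one, which enforces the
    nesting inequality -lnL(year_specific) <= -lnL(exponential) <=
    -lnL(constant) numerically.  Returns the selection table (AIC,
    delta-AIC, Akaike weight, sorted as given) and the minimum-AIC fit.
    """
    if len(kinds) < 2:
        raise ValueError("need at least two model families to compare")
    order = [k for k in _KINDS if k in kinds]
    fits: dict[TemporalKind, NestingActivityResults] = {}
    prev: NestingActivityResults | None = None
    errors: dict[TemporalKind, str] = {}
    for kind in order:
        extra = []
        if prev is not None:
            try:
                extra.append(_promote_theta(prev, kind, table))
            except ValueError:
                pass
        try:
            fits[kind] = NestingActivityModel(table, kind).fit(
                seed=seed, restarts=restarts, extra_inits=extra
            )
            prev = fits[kind]
        except Exception as exc:  # propagate only if every family fails
            errors[kind] = str(exc)
    if not fits:
        raise RuntimeError(f"all model fits failed: {errors}")
    aics = np.array([fits[k].aic for k in order if k in fits])
    delta, w = akaike_weights(aics)
    rows = pd.DataFrame(
        {
            "model": [k for k in order if k in fits],
            "aic": aics,
            "delta_aic": delta,
            "akaike_weight": w,
        }
    )
    best = min(fits.values(), key=lambda r: r.aic)
    return rows, best


def select_model(*args, **kwargs):
    """Alias for :func:`select_models`."""
    return select_models(*args, **kwargs)
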