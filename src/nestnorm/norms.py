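"""Thermal reaction norms for sex ratio and hatching success.

Sea-turtle embryos have temperature-dependent sex determination: at
constant incubation temperature t the expected female proportion
follows a logistic curve

    sr(t) = 1 / (1 + exp((P - t) / S))

where P is the pivotal temperature (sr(P) = 0.5 exactly) and S sets the
steepness; with S > 0 warmer incubation gives more females.  The
transitional range of temperatures TRT(l) is the interval producing
between l and 1-l females; under the symmetric logistic it has the
closed form width 2|S| ln((1-l)/l) centred on P.

Hatching success is null at both thermal extremes and is modelled as a
scaled product of a rising and a falling logistic,

    HS(t) = MaxHS / (1 + e^{4(P_low - t)/S_low})
                  / (1 + e^{4(P_low + dP - t)/S_high})

with S_low > 0 (rising limb), S_high < 0 (falling limb), dP > 0 the
separation of the two midpoints, and the factor 4 making each S the
slope of its limb at the midpoint.

Both norms are fitted to constant-temperature incubation outcomes by
binomial maximum likelihood (females out of sexed hatchlings; hatched
out of incubated eggs), and credible intervals come from
Metropolis-Hastings sampling under box-uniform priors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import binom

from .mcmc import MCMCConfig, PosteriorChain, credible_interval, mh_sample

__all__ = [
    "IncubationDataset",
    "SexRatioNorm",
    "HatchSuccessNorm",
    "TRTResult",
    "sex_ratio",
    "hatching_success",
    "trt",
    "trt_credible",
    "SexRatioModel",
    "HatchingSuccessModel",
    "SEX_RATIO_PRIORS",
    "HATCH_PRIORS",
]

_PROB_FLOOR = 1e-12

# box-uniform prior supports; the hatching priors are the published ones,
# the sex-ratio priors span all reported turtle pivotal temperatures
SEX_RATIO_PRIORS: dict[str, tuple[float, float]] = {"P": (25.0, 35.0), "S": (0.01, 5.0)}
HATCH_PRIORS: dict[str, tuple[float, float]] = {
    "MaxHS": (0.0, 1.0),
    "P_low": (20.0, 40.0),
    "S_low": (0.0, 5.0),
    "dP": (0.0, 10.0),
    "S_high": (-5.0, 0.0),
}


@dataclass(frozen=True)
class SexRatioNorm:
    P: float  # pivotal temperature, degC
    S: float  # transition scale, degC

    def __post_init__(self) -> None:
        if self.S == 0:
            raise ValueError("S must be nonzero")


@dataclass(frozen=True)
class HatchSuccessNorm:
    MaxHS: float  # asymptotic hatching success in (0, 1]
    P_low: float  # rising-limb midpoint, degC
    S_low: float  # rising-limb slope scale, degC (> 0)
    dP: float  # midpoint separation, degC (> 0)
    S_high: float  # falling-limb slope scale, degC (< 0)

    def __post_init__(self) -> None:
        if not (0.0 < self.MaxHS <= 1.0):
            raise ValueError("MaxHS must be in (0, 1]")
        if self.S_low <= 0:
            raise ValueError("S_low must be > 0")
        if self.S_high >= 0:
            raise ValueError("S_high must be < 0")
        if self.dP <= 0:
            raise ValueError("dP must be > 0")


@dataclass(frozen=True)
class TRTResult:
    """Transitional range of temperatures at level l."""

    level: float
    lower: float
    upper: float

    @property
    def width(self) -> float:
        return self.upper - self.lower


def sex_ratio(t, norm: SexRatioNorm | None = None, *, P: float | None = None, S: float | None = None):
    """Female proportion at constant temperature t under the logistic norm."""
    if norm is not None:
        P, S = norm.P, norm.S
    if S == 0 or S is None:
        raise ValueError("S must be nonzero")
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp((P - t) / S))
    return float(out) if out.ndim == 0 else out


def hatching_success(t, norm: HatchSuccessNorm):
    """Hatching success at constant temperature t (double logistic)."""
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        rising = 1.0 / (1.0 + np.exp(4.0 * (norm.P_low - t) / norm.S_low))
        falling = 1.0 / (1.0 + np.exp(4.0 * (norm.P_low + norm.dP - t) / norm.S_high))
        out = norm.MaxHS * rising * falling
    return float(out) if out.ndim == 0 else out


def trt(norm: SexRatioNorm, l: float = 0.05) -> TRTResult:
    """Closed-form transitional range of temperatures.

    Inverting the logistic at l and 1-l gives limits symmetric about P:
    P -/+ |S| ln((1-l)/l), hence width 2|S| ln((1-l)/l).
    """
    if not (0.0 < l < 0.5):
        raise ValueError("l must be in (0, 0.5)")
    half = abs(norm.S) * np.log((1.0 - l) / l)
    return TRTResult(level=l, lower=norm.P - half, upper=norm.P + half)


def trt_credible(
    chain: PosteriorChain, l: float = 0.05, level: float = 0.95
) -> dict[str, tuple[float, float]]:
    """Credible intervals for TRT width and limits from a (P, S) chain."""
    iP = chain.param_names.index("P")
    iS = chain.param_names.index("S")
    res = chain.map_derived(
        lambda row: (lambda r: (r.width, r.lower, r.upper))(trt(SexRatioNorm(row[iP], row[iS]), l))
    )
    return {
        "width": credible_interval(res[:, 0], level=level),
        "lower": credible_interval(res[:, 1], level=level),
        "upper": credible_interval(res[:, 2], level=level),
    }


class IncubationDataset:
    """Constant-temperature incubation outcomes.

    Each record: temperature (degC), eggs incubated, eggs hatched,
    hatchlings sexed, and the female/male split of the sexed ones.
    """

    COLUMNS = ["temperature_C", "n_eggs", "n_hatched", "n_sexed", "n_female", "n_male"]

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df.reset_index(drop=True)
        bad: list[str] = []
        for i, row in df.iterrows():
            if row.n_hatched > row.n_eggs:
                bad.append(f"row {i}: n_hatched > n_eggs")
            if row.n_sexed > row.n_hatched:
                bad.append(f"row {i}: n_sexed > n_hatched")
            if row.n_female + row.n_male != row.n_sexed:
                bad.append(f"row {i}: n_female + n_male != n_sexed")
            if not (15.0 <= row.temperature_C <= 45.0):
                bad.append(f"row {i}: temperature {row.temperature_C} outside 15-45 degC")
        if bad:
            raise ValueError("invalid incubation records:\n  " + "\n  ".join(bad))
        self.df = df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "IncubationDataset":
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def temperatures(self) -> np.ndarray:
        return self.df["temperature_C"].to_numpy(dtype=float)


def _binom_nll(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    return -float(np.sum(binom.logpmf(k, n, p)))


def sex_ratio_negloglik(data: IncubationDataset, norm: SexRatioNorm) -> float:
    """Binomial -lnL of female counts out of sexed hatchlings."""
    df = data.df[data.df.n_sexed > 0]
    if len(df) == 0:
        raise ValueError("no records with sexed hatchlings")
    p = sex_ratio(df.temperature_C.to_numpy(float), norm)
    return _binom_nll(df.n_female.to_numpy(int), df.n_sexed.to_numpy(int), p)


def hatching_negloglik(data: IncubationDataset, norm: HatchSuccessNorm) -> float:
    """Binomial -lnL of hatched counts out of incubated eggs."""
    df = data.df[data.df.n_eggs > 0]
    if len(df) == 0:
        raise ValueError("no records with incubated eggs")
    p = hatching_success(df.temperature_C.to_numpy(float), norm)
    return _binom_nll(df.n_hatched.to_numpy(int), df.n_eggs.to_numpy(int), p)


class _NormResultsBase:
    """Shared reporting/posterior surface for fitted reaction norms."""

    param_names: list[str]

    def __init__(self, model, params: np.ndarray, negloglik: float, converged: bool, message: str):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.negloglik = float(negloglik)
        self.converged = converged
        self.message = message
        self.aic = 2.0 * len(self.params) + 2.0 * self.negloglik

    def to_dict(self) -> dict:
        d = {name: float(v) for name, v in zip(self.param_names, self.params)}
        d.update(
            negloglik=self.negloglik, aic=self.aic, converged=bool(self.converged)
        )
        return d

    def sample_posterior(self, config: MCMCConfig | None = None) -> PosteriorChain:
        """Metropolis-Hastings chain started at the ML estimate."""
        bounds = [self.model.priors[name] for name in self.param_names]
        init = np.clip(
            self.params,
            [lo + 1e-9 * (hi - lo) for lo, hi in bounds],
            [hi - 1e-9 * (hi - lo) for lo, hi in bounds],
        )
        return mh_sample(
            self.model._nll_vec, bounds, init, config=config, param_names=self.param_names
        )

    def summary(self) -> str:
        lines = [
            f"{type(self).__name__}",
            "=" * 40,
            f"records      : {len(self.model.data)}",
            f"-ln L        : {self.negloglik:.4f}",
            f"AIC          : {self.aic:.4f}",
            f"converged    : {self.converged}",
            "-" * 40,
        ]
        for name, v in zip(self.param_names, self.params):
            lines.append(f"  {name:8s} = {v:10.4f}")
        return "\n".join(lines)


class SexRatioResults(_NormResultsBase):
    param_names = ["P", "S"]

    @property
    def norm(self) -> SexRatioNorm:
        return SexRatioNorm(P=self.params[0], S=self.params[1])

    def predict(self, t):
        return sex_ratio(t, self.norm)

    def trt(self, l: float = 0.05) -> TRTResult:
        return trt(self.norm, l)


class HatchingSuccessResults(_NormResultsBase):
    param_names = ["MaxHS", "P_low", "S_low", "dP", "S_high"]

    @property
    def norm(self) -> HatchSuccessNorm:
        return HatchSuccessNorm(*self.params)

    def predict(self, t):
        return hatching_success(t, self.norm)

    @property
    def midpoints(self) -> tuple[float, float]:
        """Rising and falling limb midpoint temperatures (degC)."""
        return float(self.params[1]), float(self.params[1] + self.params[3])


class _NormModelBase:
    """Binomial ML fit of a reaction norm within box prior supports."""

    priors: dict[str, tuple[float, float]]
    results_cls: type
    param_names: list[str]

    def __init__(self, data: IncubationDataset) -> None:
        if isinstance(data, pd.DataFrame):
            data = IncubationDataset(data)
        usable = self._usable_temperatures(data)
        if len(np.unique(usable)) < 3:
            raise ValueError("need counts at >= 3 distinct temperatures")
        self.data = data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame):
        return cls(IncubationDataset(df))

    def _nll_vec(self, theta: np.ndarray) -> float:
        raise NotImplementedError

    def _init(self) -> np.ndarray:
        raise NotImplementedError

    def _usable_temperatures(self, data: IncubationDataset) -> np.ndarray:
        raise NotImplementedError

    def fit(self, seed: int | None = 0, restarts: int = 5, init=None):
        rng = np.random.default_rng(seed)
        bounds = [self.priors[n] for n in self.param_names]
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        margin = 1e-6 * (hi - lo)
        x0 = np.asarray(init, dtype=float) if init is not None else self._init()
        starts = [x0]
        for _ in range(restarts):
            starts.append(lo + (hi - lo) * rng.uniform(0.05, 0.95, size=lo.size))
        best = None
        for s in starts:
            s = np.clip(s, lo + margin, hi - margin)
            res = optimize.minimize(
                self._nll_vec,
                s,
                method="Nelder-Mead",
                options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-10},
            )
            # polish within the prior box
            res2 = optimize.minimize(
                self._nll_vec,
                np.clip(res.x, lo + margin, hi - margin),
                method="L-BFGS-B",
                bounds=list(zip(lo + margin, hi - margin)),
            )
            cand = res2 if res2.fun <= res.fun else res
            if best is None or cand.fun < best.fun:
                best = cand
        return self.results_cls(
            self, best.x, best.fun, bool(best.success and np.isfinite(best.fun)), str(best.message)
        )


class SexRatioModel(_NormModelBase):
    """Logistic sex-ratio norm fitted to sexed-hatchling counts."""

    priors = SEX_RATIO_PRIORS
    param_names = ["P", "S"]

    @property
    def results_cls(self):
        return SexRatioResults

    def _usable_temperatures(self, data: IncubationDataset) -> np.ndarray:
        df = data.df
        return df.loc[df.n_sexed > 0, "temperature_C"].to_numpy(float)

    def _nll_vec(self, theta: np.ndarray) -> float:
        P, S = theta
        if S == 0:
            return np.inf
        df = self.data.df[self.data.df.n_sexed > 0]
        p = sex_ratio(df.temperature_C.to_numpy(float), P=P, S=S)
        return _binom_nll(df.n_female.to_numpy(int), df.n_sexed.to_numpy(int), p)

    def _init(self) -> np.ndarray:
        df = self.data.df[self.data.df.n_sexed > 0].sort_values("temperature_C")
        frac = df.n_female / df.n_sexed
        # first temperature where the female fraction crosses one half
        above = df.temperature_C[frac >= 0.5]
        P0 = float(above.iloc[0]) if len(above) else float(df.temperature_C.iloc[-1])
        return np.array([P0, 0.5])


class HatchingSuccessModel(_NormModelBase):
    """Double-logistic hatching-success norm fitted to egg outcomes."""

    priors = HATCH_PRIORS
    param_names = ["MaxHS", "P_low", "S_low", "dP", "S_high"]

    @property
    def results_cls(self):
        return HatchingSuccessResults

    def _usable_temperatures(self, data: IncubationDataset) -> np.ndarray:
        df = data.df
        return df.loc[df.n_eggs > 0, "temperature_C"].to_numpy(float)

    def _nll_vec(self, theta: np.ndarray) -> float:
        max_hs, p_low, s_low, dp, s_high = theta
        if not (0.0 < max_hs <= 1.0) or s_low <= 0 or s_high >= 0 or dp <= 0:
            return np.inf
        df = self.data.df[self.data.df.n_eggs > 0]
        t = df.temperature_C.to_numpy(float)
        with np.errstate(over="ignore"):
            p = (
                max_hs
                / (1.0 + np.exp(4.0 * (p_low - t) / s_low))
                / (1.0 + np.exp(4.0 * (p_low + dp - t) / s_high))
            )
        return _binom_nll(df.n_hatched.to_numpy(int), df.n_eggs.to_numpy(int), p)

    def _init(self) -> np.ndarray:
        df = self.data.df[self.data.df.n_eggs > 0].sort_values("temperature_C")
        frac = (df.n_hatched / df.n_eggs).to_numpy(float)
        t = df.temperature_C.to_numpy(float)
        max_hs0 = float(np.clip(frac.max(), 0.05, 0.999))
        half = max_hs0 / 2.0
        above = frac >= half
        p_low0 = float(t[above][0]) if above.any() else float(t[0])
        p_high0 = float(t[above][-1]) if above.any() else float(t[-1])
        dp0 = float(np.clip(p_high0 - p_low0, 0.5, 9.5))
        return np.array([max_hs0, p_low0, 1.0, dp0, -1.0])
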