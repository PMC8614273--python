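"""Synthetic data with the statistical structure the analyses assume.

The real inputs of this kind of study - a regional nesting-count
database, constant-temperature incubation experiments, and sand colour
scored from satellite images - are emulated here so every stage of the
pipeline can be exercised and validated end to end:

* beaches on a 1-D coastline with spatially autocorrelated darkness
  (a squashed Gaussian random field), optionally darkened near
  volcanos;
* sparse beach x year nest counts drawn from E_ij = T_i * p_j with
  Gaussian noise of SD a*E_ij + b, truncated at zero, rounded, and
  thinned to the configured observation probability (the fit uses the
  observed-count SD a*N_ij + b; the deliberate mean/observation
  mismatch in the noise scale probes the estimator's robustness);
* binomial incubation outcomes drawn from the logistic sex-ratio and
  double-logistic hatching-success norms at a grid of constant
  temperatures.

Every generator is a pure function of (config, seed): per-stage random
streams are spawned from the scenario seed, so re-running a scenario
reproduces its tables exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .beach_color import haversine_km
from .nesting import temporal_totals
from .norms import HatchSuccessNorm, SexRatioNorm, hatching_success, sex_ratio

__all__ = ["ScenarioConfig", "gen_beaches", "gen_nest_counts", "gen_incubation", "gen_pixel_block"]

_STAGE = {"beaches": 1, "nests": 2, "incubation": 3, "pixels": 4}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE[stage]]))


@dataclass
class ScenarioConfig:
    """One reproducible study scenario.

    Defaults emulate the scale of the motivating survey: 291 beaches
    along ~3000 km of Pacific Central American coastline, nest counts
    for 1997-2014 with roughly one beach-year cell in ten observed, and
    reaction norms at published point estimates for East Pacific olive
    ridleys (pivotal 30.24 degC, TRT5% 3.84 degC, rising hatching limb
    at 24.83 degC, falling limb at 33.57 degC).
    """

    seed: int
    # coastline & beaches
    n_beaches: int = 291
    coast_start: tuple[float, float] = (21.5, -105.5)  # lat, lon
    coast_end: tuple[float, float] = (7.5, -80.0)
    darkness_corr_km: float = 100.0
    volcano_positions: Sequence[float] | None = None  # fractions along the coast
    volcano_effect: float = 1.0  # latent darkness boost at a volcano
    volcano_scale_km: float = 50.0
    beach_length_km: tuple[float, float] = (0.5, 10.0)
    # nesting
    years: Sequence[int] = tuple(range(1997, 2015))
    temporal_kind: str = "year_specific"
    temporal_params: Sequence[float] | None = None
    mean_total: float = 10_000.0
    total_log_sd: float = 0.5  # spread of year-specific totals
    p_darkness_slope: float = -2.0  # log10 p_j ~ slope * darkness
    a: float = 0.1
    b: float = 2.0
    obs_prob: float = 169.0 / 1620.0
    # incubation
    sex_ratio_truth: SexRatioNorm = field(default_factory=lambda: SexRatioNorm(P=30.24, S=0.6521))
    hatch_truth: HatchSuccessNorm = field(
        default_factory=lambda: HatchSuccessNorm(MaxHS=0.8, P_low=24.83, S_low=1.0, dP=8.74, S_high=-1.0)
    )
    temperature_grid: Sequence[float] = tuple(np.round(np.linspace(22.0, 36.0, 20), 2))
    eggs_per_temperature: int = 50
    sexed_fraction: float = 1.0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sex_ratio_truth"] = {"P": self.sex_ratio_truth.P, "S": self.sex_ratio_truth.S}
        d["hatch_truth"] = {
            "MaxHS": self.hatch_truth.MaxHS,
            "P_low": self.hatch_truth.P_low,
            "S_low": self.hatch_truth.S_low,
            "dP": self.hatch_truth.dP,
            "S_high": self.hatch_truth.S_high,
        }
        for k in ("coast_start", "coast_end", "beach_length_km", "years", "temperature_grid"):
            d[k] = [float(v) for v in d[k]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "sex_ratio_truth" in d and isinstance(d["sex_ratio_truth"], dict):
            d["sex_ratio_truth"] = SexRatioNorm(**d["sex_ratio_truth"])
        if "hatch_truth" in d and isinstance(d["hatch_truth"], dict):
            d["hatch_truth"] = HatchSuccessNorm(**d["hatch_truth"])
        for k in ("coast_start", "coast_end", "beach_length_km"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _coast_length_km(cfg: ScenarioConfig) -> float:
    return haversine_km(*cfg.coast_start, *cfg.coast_end)


def _positions_to_latlon(cfg: ScenarioConfig, fractions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lat0, lon0 = cfg.coast_start
    lat1, lon1 = cfg.coast_end
    return lat0 + fractions * (lat1 - lat0), lon0 + fractions * (lon1 - lon0)


def gen_beaches(cfg: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Beach and volcano tables for one scenario.

    Beaches sit at sorted uniform positions along the coastline.  Their
    darkness is a squared-exponential Gaussian random field in coastal
    distance (correlation length ``darkness_corr_km``), plus an
    exponentially decaying boost near each volcano, squashed through
    the normal CDF into [0, 1].
    """
    rng = _stage_rng(cfg.seed, "beaches")
    L = _coast_length_km(cfg)
    frac = np.sort(rng.uniform(0.0, 1.0, cfg.n_beaches))
    s = frac * L  # coastal position, km
    # GRF with squared-exponential covariance in coastal distance
    if cfg.darkness_corr_km > 0:
        cov = np.exp(-0.5 * ((s[:, None] - s[None, :]) / cfg.darkness_corr_km) ** 2)
        cov += 1e-8 * np.eye(cfg.n_beaches)
        latent = np.linalg.cholesky(cov) @ rng.standard_normal(cfg.n_beaches)
    else:
        latent = rng.standard_normal(cfg.n_beaches)

    if cfg.volcano_positions is None:
        volcano_frac = np.array([0.15, 0.35, 0.55, 0.75, 0.9])
    else:
        volcano_frac = np.asarray(cfg.volcano_positions, dtype=float)
    v_s = volcano_frac * L
    if v_s.size and cfg.volcano_effect != 0.0:
        d_volc = np.min(np.abs(s[:, None] - v_s[None, :]), axis=1)
        latent = latent + cfg.volcano_effect * np.exp(-d_volc / cfg.volcano_scale_km)

    from scipy.stats import norm as _norm

    darkness = _norm.cdf((latent - latent.mean()) / max(latent.std(), 1e-12))

    lat_mid, lon_mid = _positions_to_latlon(cfg, frac)
    lengths = rng.uniform(*cfg.beach_length_km, size=cfg.n_beaches)
    half_frac = (lengths / 2.0) / L
    lat1, lon1 = _positions_to_latlon(cfg, np.clip(frac - half_frac, 0, 1))
    lat2, lon2 = _positions_to_latlon(cfg, np.clip(frac + half_frac, 0, 1))
    beaches = pd.DataFrame(
        {
            "id": [f"B{k:03d}" for k in range(cfg.n_beaches)],
            "lat1": lat1,
            "lon1": lon1,
            "lat2": lat2,
            "lon2": lon2,
            "darkness": darkness,
            "length_km": np.array(
                [haversine_km(a, b, c, d) for a, b, c, d in zip(lat1, lon1, lat2, lon2)]
            ),
        }
    )
    v_lat, v_lon = _positions_to_latlon(cfg, volcano_frac)
    volcanos = pd.DataFrame(
        {"name": [f"V{k}" for k in range(v_s.size)], "lat": v_lat, "lon": v_lon}
    )
    return beaches, volcanos


def true_shares(cfg: ScenarioConfig, beaches: pd.DataFrame) -> np.ndarray:
    """Beach nesting shares p_j, log-linear in darkness."""
    logp = cfg.p_darkness_slope * beaches["darkness"].to_numpy(float)
    p = 10.0 ** logp
    return p / p.sum()


def true_totals(cfg: ScenarioConfig) -> np.ndarray:
    """Yearly totals T_i implied by the configured temporal family."""
    n_years = len(cfg.years)
    if cfg.temporal_params is not None:
        return temporal_totals(cfg.temporal_kind, cfg.temporal_params, n_years)
    if cfg.temporal_kind == "constant":
        return np.full(n_years, cfg.mean_total)
    if cfg.temporal_kind == "exponential":
        return temporal_totals("exponential", [cfg.mean_total, 0.05], n_years)
    rng = _stage_rng(cfg.seed, "nests")  # totals share the nests stream head
    return cfg.mean_total * np.exp(rng.normal(0.0, cfg.total_log_sd, n_years))


def gen_nest_counts(cfg: ScenarioConfig, beaches: pd.DataFrame) -> pd.DataFrame:
    """Sparse long-format nest counts (beach_id, year, nests).

    Latent E_ij = T_i * p_j gets Gaussian noise of SD a*E_ij + b, is
    truncated at zero and rounded (counts are non-negative integers),
    then each cell is observed with probability ``obs_prob``.
    """
    rng = _stage_rng(cfg.seed, "nests")
    n_years = len(cfg.years)
    if cfg.temporal_params is not None:
        T = temporal_totals(cfg.temporal_kind, cfg.temporal_params, n_years)
    elif cfg.temporal_kind == "constant":
        T = np.full(n_years, cfg.mean_total)
    elif cfg.temporal_kind == "exponential":
        T = temporal_totals("exponential", [cfg.mean_total, 0.05], n_years)
    else:
        T = cfg.mean_total * np.exp(rng.normal(0.0, cfg.total_log_sd, n_years))
    p = true_shares(cfg, beaches)
    E = np.outer(T, p)
    noise_sd = cfg.a * E + cfg.b
    N = np.round(np.maximum(E + rng.normal(0.0, 1.0, E.shape) * noise_sd, 0.0))
    observed = rng.uniform(size=E.shape) < cfg.obs_prob
    # guarantee a fittable table: at least one cell per year and per beach
    for i in range(n_years):
        if not observed[i].any():
            observed[i, rng.integers(len(p))] = True
    for j in range(len(p)):
        if not observed[:, j].any():
            observed[rng.integers(n_years), j] = True
    rows = []
    ids = beaches["id"].tolist()
    for i, year in enumerate(cfg.years):
        for j, beach_id in enumerate(ids):
            if observed[i, j]:
                rows.append({"beach_id": beach_id, "year": int(year), "nests": float(N[i, j])})
    return pd.DataFrame(rows, columns=["beach_id", "year", "nests"])


def gen_incubation(cfg: ScenarioConfig) -> pd.DataFrame:
    """Binomial incubation outcomes at the configured temperature grid."""
    rng = _stage_rng(cfg.seed, "incubation")
    rows = []
    for t in cfg.temperature_grid:
        n_eggs = int(cfg.eggs_per_temperature)
        hs = hatching_success(t, cfg.hatch_truth)
        n_hatched = int(rng.binomial(n_eggs, hs))
        n_sexed = int(np.floor(cfg.sexed_fraction * n_hatched))
        sr = sex_ratio(t, cfg.sex_ratio_truth)
        n_female = int(rng.binomial(n_sexed, sr)) if n_sexed > 0 else 0
        rows.append(
            {
                "temperature_C": float(t),
                "n_eggs": n_eggs,
                "n_hatched": n_hatched,
                "n_sexed": n_sexed,
                "n_female": n_female,
                "n_male": n_sexed - n_female,
                "source": "synthetic",
            }
        )
    return pd.DataFrame(rows)


def gen_pixel_block(
    mean_rgb: Sequence[float], sd: float, size: int = 85, seed: int = 0
) -> np.ndarray:
    """Square RGB pixel block with Gaussian channel noise around a mean.

    ``sd = 0`` gives a constant block; values are clipped to [0, 255]
    and returned as uint8, shape (size, size, 3).
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = _stage_rng(seed, "pixels")
    mean = np.asarray(mean_rgb, dtype=float)
    if mean.shape != (3,):
        raise ValueError("mean_rgb must be an RGB triple")
    block = mean[None, None, :] + sd * rng.standard_normal((size, size, 3))
    return np.clip(np.round(block), 0, 255).astype(np.uint8)
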