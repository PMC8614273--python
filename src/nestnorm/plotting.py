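"""Diagnostic figures for fitted thermal reaction norms."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_norm_fit(results, which: str, path) -> None:
    """Observed proportions and the fitted curve over temperature."""
    df = results.model.data.df
    fig, ax = plt.subplots(figsize=(6, 4))
    t_grid = np.linspace(df.temperature_C.min() - 1, df.temperature_C.max() + 1, 300)
    ax.plot(t_grid, results.predict(t_grid), "k-", lw=1.5, label="fitted norm")
    if which == "sex_ratio":
        obs = df[df.n_sexed > 0]
        ax.scatter(obs.temperature_C, obs.n_female / obs.n_sexed, s=20, label="observed")
        ax.set_ylabel("female proportion")
    else:
        obs = df[df.n_eggs > 0]
        ax.scatter(obs.temperature_C, obs.n_hatched / obs.n_eggs, s=20, label="observed")
        ax.set_ylabel("hatching success")
    ax.set_xlabel("constant incubation temperature (°C)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
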