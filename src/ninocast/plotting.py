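"""Optional diagnostic plots (requires matplotlib, extra ``plots``)."""

from __future__ import annotations

import numpy as np


def _plt():
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (install extra 'plots')") from exc
    return plt


def plot_increment_history(rows, model, forecast=None, path=None):
    """Observed vs reconstructed annual increments, optionally with a forecast.

    ``rows`` are calibration :class:`~ninocast.DesignRow` tuples; the
    reconstruction is the model's fitted increment for each row.
    """
    from .regression import reconstruct_history

    plt = _plt()
    years = [r.year for r in rows]
    obs = [r.delta_co2 for r in rows]
    fitted = reconstruct_history(model, rows)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(years, obs, "k-", lw=1, label="observed increment")
    ax.plot(fitted.index, fitted.to_numpy(), "b-", lw=1.5, label="reconstructed")
    if forecast is not None:
        fy, fc, f2sd = forecast
        ax.errorbar([fy], [fc], yerr=[f2sd], fmt="o", color="tab:orange", label="forecast")
    ax.set_xlabel("year")
    ax.set_ylabel("annual CO2 increment (ppm)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_monthly_forecast(result, observed_months=None, path=None):
    """Forecast monthly concentrations with the 2 s.d. band, vs observations."""
    plt = _plt()
    months = np.arange(1, 13)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(months, result.monthly_means, "g-o", ms=3, label="forecast")
    ax.fill_between(
        months,
        result.monthly_means - result.increment_two_sd,
        result.monthly_means + result.increment_two_sd,
        color="g",
        alpha=0.2,
        label="+/- 2 s.d.",
    )
    if observed_months is not None:
        ax.plot(months, observed_months, "k-s", ms=3, label="observed")
    ax.set_xlabel("month")
    ax.set_ylabel("CO2 (ppm)")
    ax.set_title(f"monthly means, {result.target_year}")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
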