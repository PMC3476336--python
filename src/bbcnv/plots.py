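"""Diagnostic figures: the confidence-band plot and the power curve."""

from __future__ import annotations

import numpy as np

from .model import RobustFit, confidence_band

__all__ = ["plot_confidence_bands", "plot_power_curve"]


def plot_confidence_bands(fit: RobustFit, x, level: float = 0.99, path=None, ax=None):
    """Observed test proportion vs total depth with the 99% binomial and
    beta-binomial bands overlaid (the over-dispersion diagnostic)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    idx = fit.fitted_on
    n = fit.depths[idx]
    ok = n > 0
    n = n[ok]
    mu = fit.mu[idx][ok]
    obs = x[idx][ok] / n

    order = np.argsort(n)
    n_line = n[order].astype(np.int64)
    mu_line = mu[order]
    phi_line = np.asarray(fit.phi_profile.phi_at(n_line), dtype=float)
    lo_b, hi_b = confidence_band(n_line, mu_line, 0.0, level)
    lo_bb, hi_bb = confidence_band(n_line, mu_line, phi_line, level)

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(obs, n, ".", ms=2, color="0.4", alpha=0.5, label="exons")
    ax.plot(lo_b / n_line, n_line, "-", color="red", lw=1, label=f"binomial {level:.0%}")
    ax.plot(hi_b / n_line, n_line, "-", color="red", lw=1)
    ax.plot(lo_bb / n_line, n_line, "-", color="blue", lw=1,
            label=f"beta-binomial {level:.0%}")
    ax.plot(hi_bb / n_line, n_line, "-", color="blue", lw=1)
    ax.set_xlabel("proportion of reads in test sample")
    ax.set_ylabel("total read depth (test + reference)")
    ax.legend(loc="best", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_power_curve(curve, sweep: str = "test_reads", path=None, ax=None):
    """Expected posterior along a depth or reference-size sweep."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve[sweep], curve["expected_posterior"], "-o", ms=3)
    ax.set_xlabel(sweep.replace("_", " "))
    ax.set_ylabel("expected posterior")
    ax.set_ylim(0, 1.02)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
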