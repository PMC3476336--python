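"""Robust beta-binomial model for the test-vs-reference read-count split.

Given per-exon counts X (test sample) and Y (aggregate reference), the
total N = X + Y is treated as fixed and X | N is modelled.  Under pure
sampling variability X | N ~ Binomial(N, p) with

    logit(p_i) = beta0 + beta_gc * GC_i        (GC optional)

fitted by binomial logistic regression assuming diploid copy number
everywhere.  Technical variability between samples over-disperses the
split, so the working model is the beta-binomial with intraclass
correlation phi:

    X | N ~ BetaBinomial(N, a, b),  a = p(1-phi)/phi,  b = (1-p)(1-phi)/phi

which keeps the mean at N*p and inflates the variance to
N*p*(1-p)*(1 + (N-1)*phi).  phi is estimated by maximum likelihood within
depth strata (two by default) and combined by linear interpolation
between the strata's median depths, because the observed over-dispersion
typically varies with total depth.

The fitted model is summarised by the Rs statistic: the mean over exons
of sqrt(1 + (N_i - 1) * phi(N_i)), i.e. the ratio of beta-binomial to
binomial standard errors.  Rs = 1 means no technical over-dispersion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import betaln, expit, gammaln
from scipy.stats import betabinom as _sp_betabinom, binom as _sp_binom

__all__ = [
    "betabinom_logpmf",
    "betabinom_loglik",
    "PhiProfile",
    "GlmFit",
    "RobustFit",
    "fit_null_glm",
    "fit_phi_stratified",
    "fit_robust_model",
    "rs_statistic",
    "confidence_band",
    "band_outlier_fraction",
    "exclude_common_cnv",
]

_PHI_BINOMIAL = 1e-10  # below this the binomial limit is used
_PHI_MAX = 0.99


def betabinom_logpmf(x, n, p, phi):
    """Log-pmf of the beta-binomial with mean ``n*p`` and variance
    ``n*p*(1-p)*(1 + (n-1)*phi)``.

    Shape parameters are ``a = p*(1-phi)/phi`` and ``b = (1-p)*(1-phi)/phi``
    so that ``phi`` is the intraclass correlation.  As ``phi -> 0`` the
    density converges to the binomial pmf, which is substituted directly
    for ``phi < 1e-10`` for numerical stability.  Fully vectorised.
    """
    x = np.asarray(x, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    if np.any(phi < 0) or np.any(phi >= 1):
        raise ValueError("phi must lie in [0, 1)")
    if np.any((x < 0) | (x > n)):
        raise ValueError("require 0 <= x <= n")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie in (0, 1)")

    x, n, p, phi = np.broadcast_arrays(x, n, p, phi)
    out = np.empty(x.shape, dtype=np.float64)
    bb = phi >= _PHI_BINOMIAL

    choose = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    if np.any(bb):
        ph = phi[bb]
        a = p[bb] * (1.0 - ph) / ph
        b = (1.0 - p[bb]) * (1.0 - ph) / ph
        out[bb] = (
            choose[bb]
            + betaln(x[bb] + a, n[bb] - x[bb] + b)
            - betaln(a, b)
        )
    if np.any(~bb):
        m = ~bb
        out[m] = (
            choose[m]
            + x[m] * np.log(p[m])
            + (n[m] - x[m]) * np.log1p(-p[m])
        )
    return out if out.ndim else float(out)


def betabinom_loglik(x, n, p, phi) -> float:
    """Summed beta-binomial log-likelihood over exons."""
    return float(np.sum(betabinom_logpmf(x, n, p, phi)))


@dataclass(frozen=True)
class PhiProfile:
    """Depth-dependent over-dispersion: linear interpolation between
    per-stratum maximum-likelihood estimates anchored at stratum median
    depths, clamped to the boundary anchors outside their range."""

    anchor_depths: tuple[float, ...]
    anchor_phis: tuple[float, ...]

    def __post_init__(self):
        if len(self.anchor_depths) != len(self.anchor_phis) or not self.anchor_depths:
            raise ValueError("need matching, non-empty anchor arrays")
        if any(ph < 0 or ph >= 1 for ph in self.anchor_phis):
            raise ValueError("phi anchors must lie in [0, 1)")

    @classmethod
    def constant(cls, phi: float) -> "PhiProfile":
        return cls((1.0,), (float(phi),))

    def phi_at(self, n):
        """Interpolated phi for total depth(s) ``n``; floored at 0."""
        vals = np.interp(np.asarray(n, dtype=float), self.anchor_depths, self.anchor_phis)
        vals = np.maximum(vals, 0.0)
        return float(vals) if vals.ndim == 0 else vals

    def is_zero(self) -> bool:
        return all(ph < _PHI_BINOMIAL for ph in self.anchor_phis)


@dataclass
class GlmFit:
    """Binomial logistic null fit (diploid everywhere)."""

    beta0: float
    beta_gc: float
    beta0_se: float
    beta_gc_se: float
    converged: bool

    def predict_mu(self, gc=None, n_exons: int | None = None) -> np.ndarray:
        if gc is None:
            if n_exons is None:
                raise ValueError("need gc or n_exons")
            eta = np.full(n_exons, self.beta0)
        else:
            eta = self.beta0 + self.beta_gc * np.asarray(gc, dtype=float)
        return expit(eta)


def fit_null_glm(x, y, gc=None) -> GlmFit:
    """Fit logit(p_i) = beta0 (+ beta_gc * GC_i) by binomial ML.

    ``x`` are test counts, ``y`` aggregate-reference counts; exons with
    ``x + y == 0`` must already be removed.  Copy number is assumed
    diploid at every exon for this null fit.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x + y
    if np.any(n <= 0):
        raise ValueError("exons with zero total depth must be excluded before fitting")
    if x.sum() == 0:
        raise ValueError("test sample has no fragments on fitted exons")
    if y.sum() == 0:
        raise ValueError("reference has no fragments on fitted exons")

    if gc is None:
        exog = np.ones((x.size, 1))
    else:
        gc = np.asarray(gc, dtype=np.float64)
        if gc.shape != x.shape:
            raise ValueError("gc must match x in length")
        exog = np.column_stack([np.ones(x.size), gc])

    model = sm.GLM(np.column_stack([x, y]), exog, family=sm.families.Binomial())
    res = model.fit()
    if not res.converged:
        raise RuntimeError(
            f"binomial GLM did not converge (deviance {res.deviance:.3g})"
        )
    beta = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if gc is None:
        return GlmFit(beta[0], 0.0, bse[0], 0.0, True)
    return GlmFit(beta[0], beta[1], bse[0], bse[1], True)


def _phi_mle(x, n, mu, lo: float = 0.0, hi: float = _PHI_MAX):
    """Bounded 1-D ML estimate of phi with mu fixed; returns (phi, se)."""

    def nll(ph):
        return -betabinom_loglik(x, n, mu, ph)

    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    phi = float(res.x)
    if nll(0.0) <= res.fun:  # boundary check: binomial at least as likely
        phi = 0.0
    # curvature-based standard error (observed information)
    h = max(1e-7, phi * 1e-3)
    if phi - h < 0:
        se = np.nan
    else:
        d2 = (nll(phi + h) - 2 * nll(phi) + nll(phi - h)) / h**2
        se = 1.0 / np.sqrt(d2) if d2 > 0 else np.nan
    return phi, se


def fit_phi_stratified(
    x, y, mu, n_bins: int = 2, min_exons_per_bin: int = 50
) -> tuple[PhiProfile, list[dict]]:
    """Maximum-likelihood phi per depth stratum, with mu held fixed.

    Exons are split into ``n_bins`` quantile strata of total depth
    N = x + y.  Strata with fewer than ``min_exons_per_bin`` exons are
    merged into their neighbour (with a warning).  Returns the
    interpolating :class:`PhiProfile` and per-stratum diagnostics.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    n = x + y
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")

    order = np.argsort(n, kind="stable")
    edges = [order.size * k // n_bins for k in range(n_bins + 1)]
    groups = [order[edges[k] : edges[k + 1]] for k in range(n_bins)]
    groups = [g for g in groups if g.size]

    merged = []
    for g in groups:
        if merged and (g.size < min_exons_per_bin or merged[-1].size < min_exons_per_bin):
            if g.size < min_exons_per_bin:
                warnings.warn(
                    f"depth stratum with {g.size} exons merged into neighbour",
                    stacklevel=2,
                )
            merged[-1] = np.concatenate([merged[-1], g])
        else:
            merged.append(g)
    groups = merged

    depths, phis, info = [], [], []
    for g in groups:
        ph, se = _phi_mle(x[g], n[g], mu[g])
        med = float(np.median(n[g]))
        depths.append(med)
        phis.append(ph)
        info.append(
            {"n_exons": int(g.size), "median_depth": med, "phi": ph, "phi_se": se}
        )
    order2 = np.argsort(depths)
    profile = PhiProfile(
        tuple(np.asarray(depths)[order2]), tuple(np.asarray(phis)[order2])
    )
    return profile, info


@dataclass
class RobustFit:
    """Fitted null model for one test-vs-reference pair."""

    glm: GlmFit
    phi_profile: PhiProfile
    mu: np.ndarray            # fitted null proportion for every exon
    depths: np.ndarray        # total depth N_i for every exon
    fitted_on: np.ndarray     # indices of exons used in estimation
    gc_used: bool
    phi_info: list[dict] = field(default_factory=list)

    @property
    def beta0(self) -> float:
        return self.glm.beta0

    @property
    def beta_gc(self) -> float:
        return self.glm.beta_gc

    def phi_at(self, n):
        return self.phi_profile.phi_at(n)

    @property
    def rs(self) -> float:
        return rs_statistic(self.phi_profile, self.depths[self.fitted_on])

    def to_json(self, path=None) -> str:
        payload = {
            "beta0": self.glm.beta0,
            "beta_gc": self.glm.beta_gc,
            "gc_used": self.gc_used,
            "phi_anchors": {
                "depth": list(self.phi_profile.anchor_depths),
                "phi": list(self.phi_profile.anchor_phis),
            },
            "phi_strata": self.phi_info,
            "rs": self.rs,
            "n_exons_total": int(self.mu.size),
            "n_exons_fitted": int(self.fitted_on.size),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit_robust_model(
    x,
    y,
    gc=None,
    n_bins: int = 2,
    fit_mask=None,
) -> RobustFit:
    """Two-stage fit: binomial GLM for mu, then stratified phi by ML.

    ``fit_mask`` marks exons eligible for parameter estimation (e.g. with
    common-CNV regions removed); exons with zero total depth are always
    excluded from estimation.  Fitted proportions ``mu`` are produced for
    *all* exons so that calling can use every exon.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    n = x + y
    mask = np.ones(x.size, dtype=bool) if fit_mask is None else np.asarray(fit_mask, bool).copy()
    mask &= n > 0

    if not mask.any():
        raise ValueError("no exons left to fit after exclusions")

    gc_arr = None if gc is None else np.asarray(gc, dtype=float)
    glm = fit_null_glm(
        x[mask], y[mask], None if gc_arr is None else gc_arr[mask]
    )
    mu = glm.predict_mu(gc=gc_arr, n_exons=x.size)
    profile, info = fit_phi_stratified(x[mask], y[mask], mu[mask], n_bins=n_bins)
    return RobustFit(
        glm=glm,
        phi_profile=profile,
        mu=mu,
        depths=n.astype(np.float64),
        fitted_on=np.flatnonzero(mask),
        gc_used=gc is not None,
        phi_info=info,
    )


def rs_statistic(phi_profile: PhiProfile, depths) -> float:
    """Mean over exons of sqrt(1 + (N_i - 1) * phi(N_i)).

    The per-exon ratio of beta-binomial to binomial standard errors,
    averaged arithmetically; 1 exactly when phi is identically zero.
    """
    n = np.asarray(depths, dtype=np.float64)
    phi = phi_profile.phi_at(n)
    return float(np.mean(np.sqrt(1.0 + (n - 1.0) * phi)))


def confidence_band(n, p, phi, level: float = 0.99):
    """Central interval [x_lo, x_hi] of the (beta-)binomial pmf with
    coverage >= ``level`` by equal-tail trimming.  Vectorised over ``n``
    (and ``p``/``phi`` if arrays)."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    n = np.asarray(n)
    p = np.asarray(p, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi >= 1):
        raise ValueError("phi must lie in [0, 1)")
    alpha = 1.0 - level
    n_b, p_b, phi_b = np.broadcast_arrays(n, p, phi)
    lo = np.empty(n_b.shape, dtype=np.int64)
    hi = np.empty(n_b.shape, dtype=np.int64)
    bb = phi_b >= _PHI_BINOMIAL
    if np.any(bb):
        ph = phi_b[bb]
        a = p_b[bb] * (1 - ph) / ph
        b = (1 - p_b[bb]) * (1 - ph) / ph
        lo[bb] = _sp_betabinom.ppf(alpha / 2, n_b[bb], a, b).astype(np.int64)
        hi[bb] = _sp_betabinom.ppf(1 - alpha / 2, n_b[bb], a, b).astype(np.int64)
    if np.any(~bb):
        m = ~bb
        lo[m] = _sp_binom.ppf(alpha / 2, n_b[m], p_b[m]).astype(np.int64)
        hi[m] = _sp_binom.ppf(1 - alpha / 2, n_b[m], p_b[m]).astype(np.int64)
    if lo.ndim == 0:
        return int(lo), int(hi)
    return lo, hi


def band_outlier_fraction(x, n, p, phi, level: float = 0.99) -> float:
    """Fraction of observed exon counts outside their confidence band."""
    x = np.asarray(x)
    lo, hi = confidence_band(n, p, phi, level)
    return float(np.mean((x < lo) | (x > hi)))


def exclude_common_cnv(regions, exclusion_regions) -> np.ndarray:
    """Boolean keep-mask: False for exons overlapping any exclusion
    interval by >= 1 bp.

    Used to remove common-CNV regions from *parameter estimation* only;
    calling always runs on the full exon set.
    """
    keep = np.ones(len(regions), dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for ex in exclusion_regions:
        by_chrom.setdefault(ex.chrom, []).append((ex.start, ex.end))
    arrs = {
        c: (np.array([s for s, _ in v]), np.array([e for _, e in v]))
        for c, v in by_chrom.items()
    }
    for i, r in enumerate(regions):
        if r.chrom not in arrs:
            continue
        starts, ends = arrs[r.chrom]
        if np.any((starts < r.end) & (ends > r.start)):
            keep[i] = False
    return keep
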