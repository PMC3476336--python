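"""Expected posterior probability of a CNV call under the fitted model.

For an exon with total depth N and null proportion mu, the read count
under a CNV of copy ratio r follows the beta-binomial at the shifted
proportion p' = r*mu / (r*mu + 1 - mu).  For each possible outcome x the
Bayes factor BF(x) is the CNV-vs-diploid likelihood ratio, and the
single-exon posterior is prior*BF / (prior*BF + 1 - prior).  The
*expected* posterior is the mean of this posterior over the outcome
distribution under the CNV hypothesis — the quantity that measures how
much confidence the data could provide if the CNV were real.

Outcomes are enumerated exactly for N <= 5000; deeper exons use a
window of +/- 8 standard deviations around the CNV-hypothesis mean
(renormalised), which loses < 1e-10 of the probability mass.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit

from .hmm import shift_proportion
from .model import betabinom_logpmf

__all__ = [
    "GENOME_WIDE_EXONS",
    "DEFAULT_CNV_PRIOR",
    "expected_posterior",
    "outcome_logbf_distribution",
    "multi_exon_expected_posterior",
]

# Autosomal exome size after merging close targets; sets the default
# per-exon CNV prior of expected_cnvs / (2 * n_exons).
GENOME_WIDE_EXONS = 229_056
DEFAULT_CNV_PRIOR = 20.0 / (2.0 * GENOME_WIDE_EXONS)

_MAX_ENUM = 5000
_WINDOW_SD = 8.0


def _windows(n, p_alt, phi, max_enum=_MAX_ENUM):
    """Per-exon outcome windows [lo, hi] inclusive."""
    n = np.asarray(n, dtype=np.int64)
    mean = n * p_alt
    sd = np.sqrt(np.maximum(n * p_alt * (1 - p_alt) * (1 + (n - 1) * phi), 1e-12))
    lo = np.where(n <= max_enum, 0, np.maximum(0, np.floor(mean - _WINDOW_SD * sd)))
    hi = np.where(n <= max_enum, n, np.minimum(n, np.ceil(mean + _WINDOW_SD * sd)))
    return lo.astype(np.int64), hi.astype(np.int64)


def expected_posterior(
    n,
    mu,
    phi,
    prior: float,
    cnv_ratio: float = 0.5,
    max_enum: int = _MAX_ENUM,
):
    """Per-exon expected posterior of a copy-ratio-``cnv_ratio`` CNV.

    Vectorised over exons; ``n``, ``mu`` and ``phi`` broadcast.  Exons
    with zero depth return the prior exactly (no information).
    """
    if not (0.0 < prior < 1.0):
        raise ValueError("prior must be in (0, 1)")
    n = np.atleast_1d(np.asarray(n, dtype=np.int64))
    mu = np.broadcast_to(np.asarray(mu, dtype=float), n.shape).copy()
    phi = np.broadcast_to(np.asarray(phi, dtype=float), n.shape).copy()
    out = np.full(n.shape, prior, dtype=float)
    ok = n > 0
    if not ok.any():
        return out if out.size > 1 else float(out[0])

    p_null = mu[ok]
    p_alt = shift_proportion(p_null, cnv_ratio)
    nn = n[ok]
    ph = phi[ok]
    lo, hi = _windows(nn, p_alt, ph, max_enum)
    lens = hi - lo + 1
    seg = np.repeat(np.arange(nn.size), lens)
    offsets = np.concatenate([[0], np.cumsum(lens)[:-1]])
    xs = np.arange(lens.sum()) - np.repeat(offsets, lens) + np.repeat(lo, lens)

    lp_alt = betabinom_logpmf(xs, nn[seg], p_alt[seg], ph[seg])
    lp_null = betabinom_logpmf(xs, nn[seg], p_null[seg], ph[seg])
    w = np.exp(lp_alt)
    post = expit(logit(prior) + (lp_alt - lp_null))

    starts = offsets
    w_sum = np.add.reduceat(w, starts)
    ep = np.add.reduceat(w * post, starts) / w_sum
    out[ok] = ep
    return out if out.size > 1 else float(out[0])


def outcome_logbf_distribution(
    n: int, mu: float, phi: float, cnv_ratio: float, max_enum: int = _MAX_ENUM
):
    """Distribution of the log Bayes factor for one exon under the CNV
    hypothesis: returns (logbf values, probabilities)."""
    p_alt = shift_proportion(mu, cnv_ratio)
    lo, hi = _windows(np.array([n]), np.array([p_alt]), np.array([phi]), max_enum)
    xs = np.arange(lo[0], hi[0] + 1)
    lp_alt = betabinom_logpmf(xs, n, p_alt, phi)
    lp_null = betabinom_logpmf(xs, n, mu, phi)
    w = np.exp(lp_alt)
    w /= w.sum()
    return lp_alt - lp_null, w


def multi_exon_expected_posterior(
    n: int,
    mu: float,
    phi: float,
    prior: float,
    cnv_ratio: float,
    n_cnv_exons: int,
    grid_step: float = 0.02,
) -> float:
    """Expected posterior for a CNV spanning several exons of equal depth.

    Exon outcomes are independent given the model, so the total log
    Bayes factor is a sum; its distribution is obtained by discretising
    the single-exon log-BF distribution on a uniform grid and convolving
    it ``n_cnv_exons`` times.
    """
    if n_cnv_exons < 1:
        raise ValueError("n_cnv_exons must be >= 1")
    if n <= 0:
        return prior
    logbf, w = outcome_logbf_distribution(n, mu, phi, cnv_ratio)
    if n_cnv_exons == 1:
        return float(np.sum(w * expit(logit(prior) + logbf)))

    g0 = logbf.min()
    idx = np.round((logbf - g0) / grid_step).astype(np.int64)
    base = np.zeros(idx.max() + 1)
    np.add.at(base, idx, w)
    total = base
    for _ in range(n_cnv_exons - 1):
        total = np.convolve(total, base)
    grid = g0 * n_cnv_exons + grid_step * np.arange(total.size)
    return float(np.sum(total * expit(logit(prior) + grid)))
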