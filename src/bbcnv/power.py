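"""Detection power as expected posterior probability of a CNV call.

A power scenario is summarised by: the dispersion regime (the target
value of the Rs standard-error-ratio statistic, with named presets 1.0,
1.6 and 2.5 for no technical noise, a well-matched batch and a poorly
matched batch), the reference:test depth ratio R, the expected number of
test reads at normal copy, the CNV type and the per-CNV prior.  The
over-dispersion phi is calibrated so that sqrt(1 + (N-1)*phi) equals
the Rs target at the scenario's calibration depth N = test_reads*(1+R),
and is then held constant along depth sweeps: sweeping depth at fixed
phi is what shows that extra depth cannot compensate for cross-sample
technical noise, because the proportion's standard deviation floors at
sqrt(p*(1-p)*phi).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .posterior import (
    DEFAULT_CNV_PRIOR,
    expected_posterior,
    multi_exon_expected_posterior,
)

__all__ = [
    "RS_PRESETS",
    "PowerScenario",
    "calibrate_phi",
    "power_curve",
    "hom_del_threshold",
]

RS_PRESETS = {"ideal": 1.0, "well_matched": 1.6, "poorly_matched": 2.5}

_CNV_RATIOS = {"het-del": 0.5, "het-dup": 1.5}


def calibrate_phi(rs_target: float, total_depth: float) -> float:
    """phi such that sqrt(1 + (N-1)*phi) = rs_target at depth N."""
    if rs_target < 1.0:
        raise ValueError("rs_target must be >= 1")
    if total_depth <= 1:
        raise ValueError("total_depth must exceed 1")
    return (rs_target**2 - 1.0) / (total_depth - 1.0)


@dataclass(frozen=True)
class PowerScenario:
    """Parameters of one power computation."""

    rs_target: float = 1.6
    ref_test_ratio: float = 10.0
    test_reads: float = 100.0       # expected reads at normal copy (calibration point)
    cnv_type: str = "het-del"       # het-del | het-dup | hom-del
    n_cnv_exons: int = 1
    prior: float = DEFAULT_CNV_PRIOR
    background_rate: float = 0.01   # residual mapping rate under cn = 0

    def __post_init__(self):
        if self.cnv_type not in ("het-del", "het-dup", "hom-del"):
            raise ValueError(f"unknown cnv_type {self.cnv_type!r}")
        if self.ref_test_ratio <= 0:
            raise ValueError("ref_test_ratio must be positive")
        if not (0.0 < self.prior < 1.0):
            raise ValueError("prior must be in (0, 1)")

    @property
    def cnv_ratio(self) -> float:
        if self.cnv_type == "hom-del":
            return self.background_rate
        return _CNV_RATIOS[self.cnv_type]

    @property
    def calibration_depth(self) -> float:
        return self.test_reads * (1.0 + self.ref_test_ratio)

    @property
    def phi(self) -> float:
        """Dispersion calibrated to the Rs target at the calibration depth."""
        return calibrate_phi(self.rs_target, self.calibration_depth)


def _expected_posterior_single(
    test_reads: float, ref_test_ratio: float, phi: float,
    prior: float, cnv_ratio: float, n_cnv_exons: int = 1,
) -> float:
    n = int(round(test_reads * (1.0 + ref_test_ratio)))
    if n <= 0:
        return prior
    mu = 1.0 / (1.0 + ref_test_ratio)
    if n_cnv_exons == 1:
        return float(expected_posterior(n, mu, phi, prior, cnv_ratio))
    return multi_exon_expected_posterior(n, mu, phi, prior, cnv_ratio, n_cnv_exons)


def power_curve(
    scenario: PowerScenario,
    sweep: str = "test_reads",
    values=None,
    recalibrate_phi: bool = False,
) -> pd.DataFrame:
    """Expected posterior along a sweep of depth or reference size.

    ``sweep`` is ``"test_reads"`` or ``"ref_test_ratio"``.  phi stays at
    the scenario's calibrated value unless ``recalibrate_phi`` is set, in
    which case it is re-derived at each swept total depth (keeping the
    Rs target, rather than the noise floor, constant).
    """
    if sweep not in ("test_reads", "ref_test_ratio"):
        raise ValueError("sweep must be 'test_reads' or 'ref_test_ratio'")
    if values is None:
        values = (
            np.arange(10, 501, 10)
            if sweep == "test_reads"
            else np.arange(1, 21, dtype=float)
        )
    base_phi = scenario.phi
    rows = []
    for v in np.asarray(values, dtype=float):
        sc = replace(scenario, **{sweep: float(v)})
        phi = sc.phi if recalibrate_phi else base_phi
        ep = _expected_posterior_single(
            sc.test_reads, sc.ref_test_ratio, phi,
            sc.prior, sc.cnv_ratio, sc.n_cnv_exons,
        )
        rows.append({sweep: v, "phi": phi, "expected_posterior": ep})
    return pd.DataFrame(rows)


def hom_del_threshold(
    scenario: PowerScenario,
    epsilon: float | None = None,
    target_posterior: float = 0.99,
    max_reads: int = 500,
) -> int | None:
    """Smallest expected test read count identifying a homozygous deletion.

    Under cn = 0 the test exon retains only a background fraction
    ``epsilon`` of its expected reads; the threshold is the least
    ``test_reads`` whose expected posterior exceeds ``target_posterior``
    (None if not reached within ``max_reads``).  phi is recalibrated at
    each depth so the Rs regime stays fixed while depth varies.
    """
    eps = scenario.background_rate if epsilon is None else epsilon
    if not (0.0 < eps <= 0.5):
        raise ValueError("epsilon must be in (0, 0.5]")
    for reads in range(1, max_reads + 1):
        sc = replace(scenario, test_reads=float(reads))
        ep = _expected_posterior_single(
            reads, sc.ref_test_ratio, sc.phi, sc.prior, eps, sc.n_cnv_exons
        )
        if ep > target_posterior:
            return reads
    return None
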