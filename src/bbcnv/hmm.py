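"""Three-state hidden Markov CNV caller.

Per-exon beta-binomial log-likelihoods are computed under copy numbers
1 (heterozygous deletion, read ratio 0.5), 2 (diploid) and 3
(duplication, ratio 1.5).  A hidden Markov chain over exon order — one
step per exon, restarted at each chromosome — encodes the prior: the
probability of entering a CNV state from the diploid state is

    q = expected_cnvs / (2 * n_exons)

per CNV type, so that about ``expected_cnvs`` state entries are expected
a priori; a CNV state reverts to diploid with probability 0.5 and
persists with probability 0.5.  The most probable path is obtained by
Viterbi decoding, maximal non-diploid runs become calls, and each call
is scored by the odds of the decoded path against the same path with the
call's exons reset to diploid (transition terms included).  Relative
copy number is estimated afterwards from the observed/expected read
ratio; it is relative to the reference, not absolute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import RobustFit, betabinom_logpmf, fit_robust_model

__all__ = [
    "DEL", "DIP", "DUP", "STATE_NAMES",
    "HmmParams",
    "CnvCall",
    "shift_proportion",
    "exon_likelihoods",
    "make_transition_matrix",
    "viterbi_decode",
    "assemble_calls",
    "estimate_copies",
    "call_span_bp",
    "call_cnvs",
    "calls_to_dataframe",
    "calls_to_tsv",
    "calls_to_vcf",
]

DEL, DIP, DUP = 0, 1, 2
STATE_NAMES = {DEL: "deletion", DIP: "diploid", DUP: "duplication"}
# deterministic tie-break preference when Viterbi scores are equal
_TIE_ORDER = (DIP, DEL, DUP)


def shift_proportion(mu, ratio):
    """Null proportion shifted by a copy ratio on the odds scale.

    p' = ratio*mu / (ratio*mu + 1 - mu); ratio 1 is the identity,
    0.5 models a heterozygous deletion, 1.5 a duplication.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(ratio < 0):
        raise ValueError("ratio must be >= 0")
    out = ratio * mu / (ratio * mu + 1.0 - mu)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class HmmParams:
    """Transition-prior parameters of the copy-number chain."""

    n_exons: int
    expected_cnvs: float = 20.0
    p_stay: float = 0.5

    def __post_init__(self):
        if self.n_exons <= 0:
            raise ValueError("n_exons must be positive")
        if self.expected_cnvs < 0:
            raise ValueError("expected_cnvs must be >= 0")
        if self.expected_cnvs >= self.n_exons:
            raise ValueError("expected_cnvs must be < n_exons")
        if not (0.0 < self.p_stay < 1.0):
            raise ValueError("p_stay must be in (0, 1)")

    @property
    def q(self) -> float:
        """Per-exon entry probability into each CNV state."""
        return self.expected_cnvs / (2.0 * self.n_exons)


def make_transition_matrix(params: HmmParams) -> tuple[np.ndarray, np.ndarray]:
    """Transition matrix (rows: DEL, DIP, DUP) and initial distribution."""
    q = params.q
    stay = params.p_stay
    trans = np.array(
        [
            [stay, 1.0 - stay, 0.0],
            [q, 1.0 - 2.0 * q, q],
            [0.0, 1.0 - stay, stay],
        ]
    )
    init = np.array([q, 1.0 - 2.0 * q, q])
    return trans, init


def exon_likelihoods(x, n, mu, phi_profile) -> tuple[np.ndarray, np.ndarray]:
    """Per-exon log-likelihood triplets (DEL, DIP, DUP).

    Exons with zero total depth emit a neutral (all-zero) triplet and are
    flagged uncallable so that single dropout exons do not break calls.
    """
    x = np.asarray(x, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    loglik = np.zeros((x.size, 3))
    flagged = n == 0
    ok = ~flagged
    if ok.any():
        phi = np.asarray(phi_profile.phi_at(n[ok]), dtype=float)
        for state, ratio in ((DEL, 0.5), (DIP, 1.0), (DUP, 1.5)):
            p = shift_proportion(mu[ok], ratio)
            loglik[ok, state] = betabinom_logpmf(x[ok], n[ok], p, phi)
    return loglik, flagged


def viterbi_decode(
    loglik: np.ndarray,
    trans: np.ndarray,
    init: np.ndarray,
    chroms: Sequence[str] | None = None,
) -> np.ndarray:
    """Most probable state path, decoded independently per chromosome.

    Exact dynamic program in log space; ties are broken deterministically
    in favour of the diploid state.
    """
    loglik = np.asarray(loglik, dtype=np.float64)
    n_exons = loglik.shape[0]
    if chroms is None:
        chroms = ["chr"] * n_exons
    path = np.empty(n_exons, dtype=np.int64)
    start = 0
    for stop in _chrom_blocks(chroms):
        path[start:stop] = _viterbi_block(loglik[start:stop], trans, init)
        start = stop
    return path


def _chrom_blocks(chroms: Sequence[str]):
    blocks = []
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[i - 1]:
            blocks.append(i)
    return blocks


def _log(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(p)


def _tie_argmax(scores: np.ndarray) -> int:
    best = scores.max()
    for s in _TIE_ORDER:
        if scores[s] == best:
            return s
    raise AssertionError("unreachable")


def _viterbi_block(loglik: np.ndarray, trans: np.ndarray, init: np.ndarray) -> np.ndarray:
    T = loglik.shape[0]
    log_trans = _log(trans)
    delta = _log(init) + loglik[0]
    back = np.empty((T, 3), dtype=np.int64)
    for t in range(1, T):
        for j in range(3):
            cand = delta + log_trans[:, j]
            back[t, j] = _tie_argmax(cand)
        delta = np.array([delta[back[t, j]] + log_trans[back[t, j], j] for j in range(3)]) + loglik[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = _tie_argmax(delta)
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


@dataclass
class CnvCall:
    """A maximal run of non-diploid exons."""

    chrom: str
    start_exon: int           # global exon index, inclusive
    end_exon: int             # global exon index, inclusive
    start: int                # genomic, 0-based half-open
    end: int
    state: str                # "deletion" | "duplication"
    n_exons: int
    log10_bayes_factor: float
    posterior: float
    read_ratio: float
    estimated_copies: int     # relative to the reference, not absolute
    has_flagged_exons: bool = False


def _path_logscore(path, loglik, log_trans, log_init) -> float:
    score = log_init[path[0]] + loglik[0, path[0]]
    for t in range(1, path.size):
        score += log_trans[path[t - 1], path[t]] + loglik[t, path[t]]
    return float(score)


def assemble_calls(
    path: np.ndarray,
    loglik: np.ndarray,
    trans: np.ndarray,
    init: np.ndarray,
    regions,
    x,
    expected,
    chroms: Sequence[str] | None = None,
    flagged=None,
) -> list[CnvCall]:
    """Turn a decoded path into scored CNV calls.

    The call posterior is the probability of the decoded path against
    the identical path with the call's exons reset to diploid, so
    evidence accumulates across the exons of a call: a multi-exon call
    can be far more confident than any of its exons alone.
    """
    path = np.asarray(path)
    x = np.asarray(x, dtype=np.float64)
    expected = np.asarray(expected, dtype=np.float64)
    if chroms is None:
        chroms = [r.chrom for r in regions]
    if flagged is None:
        flagged = np.zeros(path.size, dtype=bool)
    log_trans = _log(trans)
    log_init = _log(init)

    calls: list[CnvCall] = []
    start_block = 0
    for stop in _chrom_blocks(chroms):
        block = slice(start_block, stop)
        bpath = path[block]
        bll = loglik[block]
        i = 0
        while i < bpath.size:
            if bpath[i] == DIP:
                i += 1
                continue
            j = i
            while j + 1 < bpath.size and bpath[j + 1] == bpath[i]:
                j += 1
            lo, hi = start_block + i, start_block + j  # global, inclusive
            state = int(bpath[i])
            log10_bf = float(
                (bll[i : j + 1, state] - bll[i : j + 1, DIP]).sum() / np.log(10)
            )
            reset = bpath.copy()
            reset[i : j + 1] = DIP
            s_called = _path_logscore(bpath, bll, log_trans, log_init)
            s_reset = _path_logscore(reset, bll, log_trans, log_init)
            posterior = float(1.0 / (1.0 + np.exp(s_reset - s_called)))
            ratio, copies = estimate_copies(x[lo : hi + 1], expected[lo : hi + 1])
            calls.append(
                CnvCall(
                    chrom=chroms[lo],
                    start_exon=lo,
                    end_exon=hi,
                    start=regions[lo].start,
                    end=regions[hi].end,
                    state=STATE_NAMES[state],
                    n_exons=hi - lo + 1,
                    log10_bayes_factor=log10_bf,
                    posterior=posterior,
                    read_ratio=ratio,
                    estimated_copies=copies,
                    has_flagged_exons=bool(np.any(flagged[lo : hi + 1])),
                )
            )
            i = j + 1
        start_block = stop
    return calls


def estimate_copies(x_call, expected_call) -> tuple[float, int]:
    """Observed/expected read ratio over a call and the implied relative
    copy number round(2 * ratio), floored at 0."""
    tot_exp = float(np.sum(expected_call))
    if tot_exp <= 0:
        return 0.0, 0
    ratio = float(np.sum(x_call)) / tot_exp
    copies = max(0, int(np.floor(2.0 * ratio + 0.5)))
    return ratio, copies


def call_span_bp(start: int, end: int, convention: str = "one_based_inclusive") -> int:
    """Length in bp of a printed or internal interval.

    ``one_based_inclusive`` (chrN:a-b notation): end - start + 1;
    ``half_open`` (BED): end - start.
    """
    if end < start:
        raise ValueError(f"end {end} < start {start}")
    if convention == "one_based_inclusive":
        return end - start + 1
    if convention == "half_open":
        if end == start:
            raise ValueError("empty half-open interval")
        return end - start
    raise ValueError(f"unknown convention {convention!r}")


# --------------------------------------------------------------- pipeline
def call_cnvs(
    counts,
    test_sample: str,
    reference_samples: Sequence[str],
    expected_cnvs: float = 20.0,
    n_bins: int = 2,
    use_gc: bool = False,
    fit_mask=None,
    prior_n_exons: int | None = None,
) -> tuple[list[CnvCall], RobustFit]:
    """Fit the robust model and call CNVs for one test sample.

    ``prior_n_exons`` overrides the exon count in the transition prior
    (e.g. the genome-wide total when calling on a subset); by default the
    number of exons in the matrix is used.
    """
    x = counts.column(test_sample)
    y = counts.aggregate(reference_samples)
    gc = None
    if use_gc:
        gc = np.array([r.gc for r in counts.regions], dtype=float)
        if np.any(np.isnan(gc)):
            raise ValueError("use_gc requested but some regions lack GC content")
    fit = fit_robust_model(x, y, gc=gc, n_bins=n_bins, fit_mask=fit_mask)
    n = x + y
    loglik, flagged = exon_likelihoods(x, n, fit.mu, fit.phi_profile)
    params = HmmParams(
        n_exons=prior_n_exons or counts.n_regions, expected_cnvs=expected_cnvs
    )
    trans, init = make_transition_matrix(params)
    chroms = [r.chrom for r in counts.regions]
    path = viterbi_decode(loglik, trans, init, chroms)
    expected = n * fit.mu
    calls = assemble_calls(
        path, loglik, trans, init, counts.regions, x, expected, chroms, flagged
    )
    return calls, fit


def calls_to_dataframe(calls: list[CnvCall]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "state": c.state,
                "n_exons": c.n_exons,
                "log10_bf": c.log10_bayes_factor,
                "posterior": c.posterior,
                "read_ratio": c.read_ratio,
                "copies": c.estimated_copies,
            }
            for c in calls
        ],
        columns=[
            "chrom", "start", "end", "state", "n_exons",
            "log10_bf", "posterior", "read_ratio", "copies",
        ],
    )


def calls_to_tsv(calls: list[CnvCall], path) -> None:
    calls_to_dataframe(calls).to_csv(path, sep="\t", index=False)


def calls_to_vcf(calls: list[CnvCall], path, sample: str = "SAMPLE") -> None:
    """Minimal symbolic-allele VCF (<DEL>/<DUP>) for the calls."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion relative to reference set">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication relative to reference set">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=EXONS,Number=1,Type=Integer,Description="Exons in call">\n')
        fh.write('##INFO=<ID=BF,Number=1,Type=Float,Description="log10 Bayes factor">\n')
        fh.write('##INFO=<ID=POSTERIOR,Number=1,Type=Float,Description="Call posterior">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            svtype = "DEL" if c.state == "deletion" else "DUP"
            info = (
                f"END={c.end};SVTYPE={svtype};EXONS={c.n_exons};"
                f"BF={c.log10_bayes_factor:.3f};POSTERIOR={c.posterior:.6f}"
            )
            fh.write(
                f"{c.chrom}\t{c.start + 1}\t.\tN\t<{svtype}>\t.\tPASS\t{info}\n"
            )
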