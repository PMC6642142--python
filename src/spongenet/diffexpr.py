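"""Normalization and differential-expression statistics.

The microarray leg uses quantile normalization followed by an
equal-variance two-sample t-test on log2(intensity + 1); the small-RNA
leg uses an exact conditional negative-binomial test on per-group count
sums with a single moment-estimated common dispersion (variance
mu + phi*mu^2).  Both legs report a *signed fold change* on the linear
scale — the treated/control mean ratio when >= 1, minus its reciprocal
otherwise, so |FC| >= 1 always — a raw p, and a Benjamini-Hochberg q.
The conventional significance gate is |FC| >= 1.5 and raw p <= 0.05.

The common-dispersion exact test is a deliberate simplification of
edgeR-style NB-GLM fitting with empirical-Bayes tagwise dispersions; it
is calibrated (type-I error at nominal alpha) rather than output-matched,
and reduces to the two-sided binomial exact test in the Poisson limit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix, ExpressionMatrix

__all__ = [
    "DERecord",
    "DEFilter",
    "quantile_normalize",
    "ttest_de",
    "nb_exact_de",
    "apply_de_filter",
    "hierarchical_cluster",
]

_TINY = 1e-12


@dataclass(frozen=True)
class DERecord:
    """Per-feature differential-expression summary.

    ``signed_fc`` is the linear-scale treated/control ratio if >= 1,
    else the negated control/treated ratio (so its magnitude is always
    >= 1 and its sign tracks the direction of change).  ``raw_intensity``
    is the larger of the two linear group means, used downstream as the
    expression floor for sponge candidacy.
    """

    feature_id: str
    mean_ctrl: float
    mean_trt: float
    signed_fc: float
    p: float
    q: float
    raw_intensity: float
    direction: str  # up | down | flat


@dataclass(frozen=True)
class DEFilter:
    """Significance gate: |signed FC| >= fc_min and p <= p_max
    (q <= p_max instead when ``use_adjusted``)."""

    fc_min: float = 1.5
    p_max: float = 0.05
    use_adjusted: bool = False

    def __post_init__(self) -> None:
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must be in (0, 1]")

    def passes(self, signed_fc: float, p: float, q: float) -> bool:
        pv = q if self.use_adjusted else p
        return abs(signed_fc) >= self.fc_min and pv <= self.p_max


def _signed_fc(mean_ctrl: float, mean_trt: float) -> float:
    a = max(mean_ctrl, _TINY)
    b = max(mean_trt, _TINY)
    return b / a if b >= a else -a / b


def _direction(signed_fc: float, p: float, q: float, filt: DEFilter) -> str:
    if filt.passes(signed_fc, p, q):
        return "up" if signed_fc > 0 else "down"
    return "flat"


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common distribution of cross-sample
    sorted-row means; ties within a column receive the mean of the tied
    reference quantiles.  Row and column order are preserved."""
    x = matrix.values
    if x.size == 0:
        raise ValueError("empty matrix")
    n = x.shape[0]
    ref = np.sort(x, axis=0).mean(axis=1)  # reference distribution
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = st.rankdata(x[:, j], method="average")  # 1..n, may be half-int
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (ref[lo] + ref[np.minimum(hi, n - 1)])
    return ExpressionMatrix(
        list(matrix.feature_ids), list(matrix.sample_ids), out,
        dict(matrix.sample_groups),
    )


def _two_group_columns(
    matrix: ExpressionMatrix, control: str
) -> tuple[np.ndarray, np.ndarray, str]:
    groups = matrix.groups()
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {sorted(groups)}")
    if control not in groups:
        raise ValueError(f"control group {control!r} not present")
    treated = next(g for g in groups if g != control)
    idx = {s: i for i, s in enumerate(matrix.sample_ids)}
    ci = np.array([idx[s] for s in groups[control]])
    ti = np.array([idx[s] for s in groups[treated]])
    return ci, ti, treated


def ttest_de(
    matrix: ExpressionMatrix,
    filter: DEFilter = DEFilter(),
    control: str = "control",
    pseudocount: float = 1.0,
) -> list[DERecord]:
    """Equal-variance two-sample t-test per feature on
    log2(intensity + pseudocount); fold changes from linear group means;
    BH adjustment across all tested features."""
    ci, ti, _ = _two_group_columns(matrix, control)
    if len(ci) < 2 or len(ti) < 2:
        raise ValueError("each group needs >= 2 samples")
    lx = np.log2(matrix.values + pseudocount)
    with warnings.catch_warnings():
        # near-constant null features trigger scipy's precision-loss
        # note; they are handled explicitly below (NaN -> p = 1)
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = st.ttest_ind(lx[:, ti], lx[:, ci], axis=1, equal_var=True)
    p = np.where(np.isnan(p), 1.0, p)  # zero variance, equal means
    q = multipletests(p, method="fdr_bh")[1]
    mc = matrix.values[:, ci].mean(axis=1)
    mt = matrix.values[:, ti].mean(axis=1)
    records = []
    for i, fid in enumerate(matrix.feature_ids):
        fc = _signed_fc(mc[i], mt[i])
        records.append(
            DERecord(
                feature_id=fid, mean_ctrl=float(mc[i]), mean_trt=float(mt[i]),
                signed_fc=float(fc), p=float(p[i]), q=float(q[i]),
                raw_intensity=float(max(mc[i], mt[i])),
                direction=_direction(fc, p[i], q[i], filter),
            )
        )
    return records


# --------------------------------------------------------------------------
# NB exact test


def _estimate_common_dispersion(
    norm: np.ndarray, ci: np.ndarray, ti: np.ndarray
) -> float:
    """Method-of-moments common dispersion across features using pooled
    within-group means/variances: phi = (var - mu) / mu^2, averaged over
    informative features, floored at 1e-8."""
    phis = []
    for idx in (ci, ti):
        if len(idx) < 2:
            continue
        mu = norm[:, idx].mean(axis=1)
        var = norm[:, idx].var(axis=1, ddof=1)
        ok = mu > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (var[ok] - mu[ok]) / mu[ok] ** 2
        phis.append(phi)
    if not phis:
        return 1e-8
    allphi = np.concatenate(phis)
    if allphi.size == 0:
        return 1e-8
    return float(max(np.mean(allphi), 1e-8))


def _nb_logpmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    if phi < 1e-10:
        return st.poisson.logpmf(k, mean)
    r = 1.0 / phi
    return st.nbinom.logpmf(k, r, r / (r + mean))


def _exact_nb_p(s1: int, s2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact conditional p for group sums (s1, s2) under a
    common-mean NB model: sum over partitions of the total whose
    probability does not exceed the observed partition's (minimum-
    likelihood rule).  Group sums of n iid NB(mu, phi) are NB(n*mu, phi/n)."""
    total = s1 + s2
    if total == 0:
        return 1.0
    lam = total / (n1 + n2)
    k = np.arange(total + 1)
    logw = _nb_logpmf(k, n1 * lam, phi / n1) + _nb_logpmf(
        total - k, n2 * lam, phi / n2
    )
    logw -= logw.max()
    w = np.exp(logw)
    obs = w[s1]
    p = w[w <= obs * (1 + 1e-10)].sum() / w.sum()
    return float(min(p, 1.0))


def nb_exact_de(
    counts: CountMatrix,
    filter: DEFilter = DEFilter(),
    control: str = "control",
) -> list[DERecord]:
    """Exact conditional NB test per miRNA on library-size-normalized
    group sums with a common moment-estimated dispersion; BH q across
    features.  All-zero features get p = 1, direction flat."""
    ci, ti, _ = _two_group_columns(counts, control)
    lib = counts.values.sum(axis=0)
    common = lib.mean()
    norm = counts.values * (common / lib)[None, :]
    phi = _estimate_common_dispersion(norm, ci, ti)
    n1, n2 = len(ci), len(ti)
    # test on rounded normalized sums (integer support for the exact test)
    s_ctrl = np.rint(norm[:, ci].sum(axis=1)).astype(int)
    s_trt = np.rint(norm[:, ti].sum(axis=1)).astype(int)
    p = np.ones(len(counts.feature_ids))
    for i in range(len(p)):
        if s_ctrl[i] + s_trt[i] > 0:
            p[i] = _exact_nb_p(int(s_trt[i]), int(s_ctrl[i]), n2, n1, phi)
    q = multipletests(p, method="fdr_bh")[1]
    mc = norm[:, ci].mean(axis=1)
    mt = norm[:, ti].mean(axis=1)
    records = []
    for i, fid in enumerate(counts.feature_ids):
        if s_ctrl[i] + s_trt[i] == 0:
            records.append(
                DERecord(fid, 0.0, 0.0, 1.0, 1.0, float(q[i]), 0.0, "flat")
            )
            continue
        fc = _signed_fc(mc[i], mt[i])
        records.append(
            DERecord(
                feature_id=fid, mean_ctrl=float(mc[i]), mean_trt=float(mt[i]),
                signed_fc=float(fc), p=float(p[i]), q=float(q[i]),
                raw_intensity=float(max(mc[i], mt[i])),
                direction=_direction(fc, p[i], q[i], filter),
            )
        )
    return records


def apply_de_filter(
    records: Iterable[DERecord], filter: DEFilter = DEFilter()
) -> tuple[set[str], set[str]]:
    """Split records into significant (up_ids, down_ids) under the gate;
    the two sets are disjoint by construction."""
    up, down = set(), set()
    for r in records:
        if filter.passes(r.signed_fc, r.p, r.q):
            (up if r.signed_fc > 0 else down).add(r.feature_id)
    return up, down


def hierarchical_cluster(
    matrix: np.ndarray | ExpressionMatrix,
    distance: str = "euclidean",
    linkage: str = "ward",
) -> tuple[list[int], np.ndarray]:
    """Agglomerative clustering of rows; returns (leaf order, scipy
    linkage matrix).  Duplicate rows merge first at height 0; scipy's
    deterministic smallest-index tie-breaking applies."""
    x = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in clustering input")
    z = sch.linkage(x, method=linkage, metric=distance)
    order = sch.leaves_list(z).tolist()
    return order, z
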