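"""Group-comparison statistics for targeted (qRT-PCR-style) validation.

Measurements arrive already normalized relative to an untreated control.
The omnibus test across treatment groups is Kruskal-Wallis on midranks
with tie correction; pairwise follow-up uses Dunn's test (rank-mean z
with tie-corrected pooled variance, two-sided normal p) with
Benjamini-Hochberg adjustment over the requested comparisons.  Fold
presentation divides each group mean by the reference mean, pinning the
reference at exactly 1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .enrichment import bh_adjust

__all__ = ["GroupedMeasurements", "kruskal_wallis", "dunn_posthoc",
           "relative_fold"]


@dataclass
class GroupedMeasurements:
    """Label -> measurements, plus the reference (control) label."""

    groups: dict[str, list[float]]
    reference_label: str = "control"

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        for label, vals in self.groups.items():
            if len(vals) == 0:
                raise ValueError(f"group {label!r} is empty")
        if self.reference_label not in self.groups:
            raise ValueError(f"reference {self.reference_label!r} missing")


def _check_groups(groups: Mapping[str, Sequence[float]]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for label, vals in groups.items():
        if len(vals) == 0:
            raise ValueError(f"group {label!r} is empty")


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p with g-1 df.
    All-identical data degenerates to H = 0, p = 1."""
    _check_groups(groups)
    samples = [np.asarray(v, dtype=float) for v in groups.values()]
    if sum(len(s) for s in samples) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = st.kruskal(*samples)
    return float(h), float(p)


def _tie_term(pooled: np.ndarray) -> float:
    """Sum (t^3 - t) over tied groups."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]],
    comparisons: Sequence[tuple[str, str]] | None = None,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Dunn's pairwise rank test after a Kruskal-Wallis omnibus.

    z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)),
    with T the tie term; two-sided normal p; BH q across the requested
    comparisons only (default: all unordered pairs in label order).
    """
    _check_groups(groups)
    labels = list(groups)
    if comparisons is None:
        comparisons = list(itertools.combinations(labels, 2))
    for a, b in comparisons:
        for lab in (a, b):
            if lab not in groups:
                raise ValueError(f"unknown group label {lab!r}")
    samples = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    pooled = np.concatenate([samples[k] for k in labels])
    n_total = len(pooled)
    ranks = st.rankdata(pooled)
    rank_mean: dict[str, float] = {}
    pos = 0
    for k in labels:
        n_k = len(samples[k])
        rank_mean[k] = float(ranks[pos:pos + n_k].mean())
        pos += n_k
    tie = _tie_term(pooled)
    var_base = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_base -= tie / (12.0 * (n_total - 1))
    rows = []
    for a, b in comparisons:
        se = math.sqrt(var_base * (1.0 / len(samples[a]) + 1.0 / len(samples[b])))
        z = 0.0 if se == 0 else (rank_mean[a] - rank_mean[b]) / se
        p = min(1.0, 2.0 * st.norm.sf(abs(z)))
        rows.append((a, b, z, p))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    if adjust == "bh":
        df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    elif adjust == "none":
        df["q"] = df["p"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df


def relative_fold(
    groups: Mapping[str, Sequence[float]],
    reference: str = "control",
) -> pd.DataFrame:
    """Per-group mean fold versus the reference group; the reference row
    is exactly 1 (the convention for control-normalized bar plots).
    A reference-only input is allowed and yields the single fold-1 row."""
    for label, vals in groups.items():
        if len(vals) == 0:
            raise ValueError(f"group {label!r} is empty")
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} missing")
    ref_mean = float(np.mean(groups[reference]))
    if ref_mean == 0:
        raise ValueError("reference group mean is zero")
    rows = []
    for label, vals in groups.items():
        m = float(np.mean(vals))
        fold = 1.0 if label == reference else m / ref_mean
        rows.append((label, m, fold))
    return pd.DataFrame(rows, columns=["group", "mean", "fold_vs_reference"])
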