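"""Co-expression concordance filtering and disease annotation of
lncRNA-mRNA candidate pairs.

Reference co-expression correlations (lnCaNet-style tables) are external
inputs, not recomputed from the study's own samples.  A candidate pair
survives the concordance filter when both members are significantly
differentially expressed, the reference |r| lies in a configurable band
(default 0.6-0.8 inclusive), and — in ``sign_concordant`` mode — the
sign of r matches the sign of the product of the two fold changes
(positive co-expression implies the pair moves together).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .diffexpr import DERecord
from .io_formats import InteractionTable

__all__ = ["ConcordancePair", "concordance_filter", "disease_join"]

MODES = ("sign_concordant", "any")


@dataclass(frozen=True)
class ConcordancePair:
    lnc_id: str
    mrna_id: str
    r: float
    lnc_fc: float
    mrna_fc: float
    concordant: bool


def _significant(records: Iterable[DERecord]) -> dict[str, DERecord]:
    return {r.feature_id: r for r in records if r.direction != "flat"}


def concordance_filter(
    lnc_de: Sequence[DERecord],
    mrna_de: Sequence[DERecord],
    coexpr_table: InteractionTable,
    r_min: float = 0.6,
    r_max: float = 0.8,
    mode: str = "sign_concordant",
) -> list[ConcordancePair]:
    """Keep reference co-expression pairs whose members are both
    significant, with r_min <= |r| <= r_max, and (unless mode="any")
    sign(r) agreeing with sign(lnc_fc * mrna_fc)."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if coexpr_table.kind != "lnc_mrna_coexpression":
        raise ValueError(f"wrong table kind {coexpr_table.kind!r}")
    lnc = _significant(lnc_de)
    mrna = _significant(mrna_de)
    out: list[ConcordancePair] = []
    for lnc_id, mrna_id, r in coexpr_table.records:
        if lnc_id not in lnc or mrna_id not in mrna:
            continue
        r = float(r)
        if not r_min <= abs(r) <= r_max:
            continue
        lf, mf = lnc[lnc_id].signed_fc, mrna[mrna_id].signed_fc
        concordant = (r > 0) == (lf * mf > 0)
        if mode == "sign_concordant" and not concordant:
            continue
        out.append(ConcordancePair(lnc_id, mrna_id, r, lf, mf, concordant))
    out.sort(key=lambda p: (p.lnc_id, p.mrna_id))
    return out


def disease_join(
    lnc_de: Sequence[DERecord],
    disease_table: InteractionTable,
    disease_filter: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Inner-join significant lncRNAs to their disease labels, optionally
    restricted to a label set (case-insensitive substring match, so
    'cardiovascular' matches 'cardiovascular disease').  Empty joins are
    allowed and return an empty frame."""
    if disease_table.kind != "lnc_disease":
        raise ValueError(f"wrong table kind {disease_table.kind!r}")
    sig = _significant(lnc_de)
    wanted = None
    if disease_filter is not None:
        wanted = [w.lower() for w in disease_filter]
    rows = []
    for lnc_id, disease, source in disease_table.records:
        if lnc_id not in sig:
            continue
        if wanted is not None and not any(w in disease.lower() for w in wanted):
            continue
        rec = sig[lnc_id]
        rows.append((lnc_id, rec.signed_fc, rec.p, disease, source))
    df = pd.DataFrame(
        rows, columns=["lnc_id", "signed_fc", "p", "disease", "source"]
    )
    return df.sort_values(["lnc_id", "disease"], ignore_index=True)
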