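"""Dosage / compensation categories from paired differential runs.

Two analyses of the same peaks are combined: the *total* run (no CN
normalization — total signal from all copies) and the *per-copy* run (CN
normalized — average signal per chromosome copy).  For trisomy 21 the
per-copy run is simply the total signal divided by CNR = 3/2.  The five
categories:

====  ==============  ================  ==========================================
cat   total status    per-copy status   interpretation
====  ==============  ================  ==========================================
I     nd              nd                no change
II    down            down              over-compensation, CN-independent decrease
III   nd              down              compensation: total constant, per-copy down
IV    up              nd                pure dosage effect
V     up              up                dosage effect plus CN-independent increase
====  ==============  ================  ==========================================

The remaining four status combinations are biologically unanticipated and
mapped to ``other`` rather than coerced into a named category.
"""
from __future__ import annotations

import logging
from enum import Enum
from typing import Callable, Dict, Optional, Sequence, Tuple, Union

import pandas as pd

from .core import Peak, ValidationError
from .diff import STATUS_DOWN, STATUS_ND, STATUS_UP

logger = logging.getLogger(__name__)


class DosageCategory(str, Enum):
    I_NO_CHANGE = "I"
    II_OVERCOMPENSATORY = "II"
    III_COMPENSATORY = "III"
    IV_DOSAGE_ONLY = "IV"
    V_DOSAGE_PLUS_INCREASE = "V"
    OTHER = "other"


CATEGORY_TABLE: Dict[Tuple[str, str], DosageCategory] = {
    (STATUS_ND, STATUS_ND): DosageCategory.I_NO_CHANGE,
    (STATUS_DOWN, STATUS_DOWN): DosageCategory.II_OVERCOMPENSATORY,
    (STATUS_ND, STATUS_DOWN): DosageCategory.III_COMPENSATORY,
    (STATUS_UP, STATUS_ND): DosageCategory.IV_DOSAGE_ONLY,
    (STATUS_UP, STATUS_UP): DosageCategory.V_DOSAGE_PLUS_INCREASE,
}

_VALID = {STATUS_UP, STATUS_DOWN, STATUS_ND}


def classify_region(total_status: str, percopy_status: str) -> DosageCategory:
    """Map a (total, per-copy) status pair to its dosage category."""
    for s in (total_status, percopy_status):
        if s not in _VALID:
            raise ValidationError(f"unknown status token {s!r}")
    return CATEGORY_TABLE.get((total_status, percopy_status), DosageCategory.OTHER)


RegionFilter = Union[None, str, Callable[[Peak], bool]]


def classify_all(
    results_total: pd.DataFrame,
    results_percopy: pd.DataFrame,
    peaks: Optional[Sequence[Peak]] = None,
    region: RegionFilter = None,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Classify every peak; returns (per-peak table, category counts).

    The two result tables must cover identical peak sets.  ``region``
    restricts the output: a chromosome name, or a predicate on
    :class:`Peak` (both require ``peaks``).
    """
    set_t = set(results_total["peak"])
    set_p = set(results_percopy["peak"])
    if set_t != set_p:
        diff = sorted(set_t.symmetric_difference(set_p))
        raise ValidationError(f"peak sets differ between runs: {diff[:10]}")

    merged = results_total[["peak", "status"]].merge(
        results_percopy[["peak", "status"]], on="peak", suffixes=("_total", "_percopy")
    )
    if region is not None:
        if peaks is None:
            raise ValidationError("region filtering requires the peak list")
        by_name = {p.name: p for p in peaks}
        if callable(region):
            keep = {n for n, p in by_name.items() if region(p)}
        else:
            keep = {n for n, p in by_name.items() if p.chrom == region}
        merged = merged[merged["peak"].isin(keep)].reset_index(drop=True)

    merged["category"] = [
        classify_region(t, p).value
        for t, p in zip(merged["status_total"], merged["status_percopy"])
    ]
    counts = (
        merged["category"]
        .value_counts()
        .reindex([c.value for c in DosageCategory], fill_value=0)
    )
    counts.name = "n"
    n_other = int(counts[DosageCategory.OTHER.value])
    if n_other:
        logger.warning("%d peak(s) with unanticipated status combinations -> 'other'", n_other)
    return merged, counts
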