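"""Composite readiness and process-quality metrics from binary indicators.

Readiness is the proportion of required items (equipment, amenities,
medicines, diagnostics, staff training) available at a facility on the day of
assessment; process quality is the proportion of clinical diagnostic
protocols adhered to in a sick-child consultation or vignette.  Both weight
every item equally.  Item masks support cross-survey harmonisation (e.g.
dropping staff-training items not collected by every instrument).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ItemDefinition",
    "FacilityMetrics",
    "ConsultationScore",
    "compute_readiness",
    "compute_process_quality",
    "facility_process_score",
    "score_facility_table",
    "score_consultation_table",
    "aggregate_consultations",
]


@dataclass(frozen=True)
class ItemDefinition:
    """Ordered item list with an active mask and optional domain labels."""

    item_ids: tuple
    mask: frozenset = None  # type: ignore[assignment]
    domains: dict = field(default_factory=dict)

    def __post_init__(self):
        mask = self.mask
        if mask is None:
            mask = frozenset(self.item_ids)
        else:
            mask = frozenset(mask)
        if not mask:
            raise ValueError("item mask is empty")
        if not mask <= set(self.item_ids):
            raise ValueError(f"mask contains unknown items: {mask - set(self.item_ids)}")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))

    @property
    def active_items(self) -> list:
        return [i for i in self.item_ids if i in self.mask]


@dataclass(frozen=True)
class FacilityMetrics:
    facility_id: object
    readiness: float
    n_items_assessed: int


@dataclass(frozen=True)
class ConsultationScore:
    consultation_id: object
    facility_id: object
    process_quality: float
    n_protocols_assessed: int


def _masked_proportion(values: np.ndarray, missing_as_absent: bool):
    values = np.asarray(values, dtype=float)
    if missing_as_absent:
        values = np.nan_to_num(values, nan=0.0)
    present = ~np.isnan(values)
    n = int(present.sum())
    if n == 0:
        return None, 0
    bad = values[present][~np.isin(values[present], (0.0, 1.0))]
    if bad.size:
        raise ValueError(f"indicators must be binary, got {bad[:5]}")
    return float(values[present].sum() / n), n


def compute_readiness(
    item_indicators,
    definition: ItemDefinition,
    facility_id=None,
    missing_as_absent: bool = False,
) -> FacilityMetrics | None:
    """Proportion of masked, non-missing items available at one facility.

    ``item_indicators`` is a mapping/Series keyed by item id, with NaN for
    missing.  Missing items are excluded from numerator and denominator
    (set ``missing_as_absent`` to count them as unavailable instead).
    Returns None when every masked item is missing; such facilities are
    flagged and excluded downstream.
    """
    s = pd.Series(item_indicators)
    vals = s.reindex(definition.active_items).to_numpy(dtype=float)
    p, n = _masked_proportion(vals, missing_as_absent)
    if p is None:
        logger.warning("facility %r: all masked items missing", facility_id)
        return None
    return FacilityMetrics(facility_id=facility_id, readiness=p, n_items_assessed=n)


def compute_process_quality(
    protocol_indicators, consultation_id=None, facility_id=None,
    missing_as_absent: bool = False,
) -> ConsultationScore | None:
    """Proportion of non-missing protocols adhered to in one consultation."""
    vals = pd.Series(protocol_indicators).to_numpy(dtype=float)
    p, n = _masked_proportion(vals, missing_as_absent)
    if p is None:
        logger.warning("consultation %r: all protocols missing", consultation_id)
        return None
    return ConsultationScore(
        consultation_id=consultation_id,
        facility_id=facility_id,
        process_quality=p,
        n_protocols_assessed=n,
    )


def facility_process_score(scores) -> float:
    """Unweighted mean of one facility's consultation scores.

    Consultations aggregate to a facility mean before design weighting, so a
    facility with many observed consultations is not overweighted beyond its
    survey weight.
    """
    vals = [s.process_quality if isinstance(s, ConsultationScore) else float(s) for s in scores]
    if not vals:
        raise ValueError("no consultation scores for facility")
    return float(np.mean(vals))


def score_facility_table(
    facilities: pd.DataFrame,
    definition: ItemDefinition,
    item_prefix: str = "item_",
    missing_as_absent: bool = False,
) -> pd.DataFrame:
    """Vectorised readiness over a facility table.

    Item columns are ``<item_prefix><item_id>``.  Facilities with no
    assessable masked item are dropped with a logged count.
    """
    cols = [f"{item_prefix}{i}" for i in definition.active_items]
    missing_cols = [c for c in cols if c not in facilities.columns]
    if missing_cols:
        raise ValueError(f"facility table lacks item columns: {missing_cols}")
    vals = facilities[cols].to_numpy(dtype=float)
    if missing_as_absent:
        vals = np.nan_to_num(vals, nan=0.0)
    present = ~np.isnan(vals)
    n = present.sum(axis=1)
    ok = n > 0
    if (~ok).any():
        logger.warning(
            "excluding %d facilities with all masked items missing", int((~ok).sum())
        )
    out = facilities.loc[ok, [c for c in facilities.columns if not c.startswith(item_prefix)]].copy()
    out["readiness"] = np.nansum(vals[ok], axis=1) / n[ok]
    out["n_items_assessed"] = n[ok].astype(int)
    return out


def score_consultation_table(
    consultations: pd.DataFrame,
    protocol_prefix: str = "protocol_",
    missing_as_absent: bool = False,
) -> pd.DataFrame:
    """Per-consultation process-quality scores from a consultation table."""
    cols = [c for c in consultations.columns if c.startswith(protocol_prefix)]
    if not cols:
        raise ValueError(f"no columns with prefix {protocol_prefix!r}")
    vals = consultations[cols].to_numpy(dtype=float)
    if missing_as_absent:
        vals = np.nan_to_num(vals, nan=0.0)
    present = ~np.isnan(vals)
    n = present.sum(axis=1)
    ok = n > 0
    if (~ok).any():
        logger.warning(
            "excluding %d consultations with all protocols missing", int((~ok).sum())
        )
    out = consultations.loc[ok, [c for c in consultations.columns if c not in cols]].copy()
    out["process_quality"] = np.nansum(vals[ok], axis=1) / n[ok]
    out["n_protocols_assessed"] = n[ok].astype(int)
    return out


def aggregate_consultations(consultation_scores: pd.DataFrame) -> pd.DataFrame:
    """Facility-level mean process quality (one row per facility)."""
    grp = consultation_scores.groupby("facility_id", sort=True)
    out = grp["process_quality"].mean().rename("process_quality").reset_index()
    out["n_consultations"] = grp.size().to_numpy()
    return out
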