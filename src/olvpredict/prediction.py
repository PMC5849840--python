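"""Scenario assignment and the parotid-sparing decision rule, with calibration.

The deliverable rule: for a parotid that overlaps the high-dose PTV plus a
5 mm expansion (scenario A), a fractional overlap OLV_HD05 greater than
0.083 predicts a mean parotid dose above the 26 Gy sparing tolerance.  A
parotid that overlaps only the intermediate-dose PTV (scenario B) is
predicted to exceed tolerance iff that overlap is at least 0.25; overlap
with the low-dose PTV only (scenario C), or no PTV overlap at all, predicts
sparing.

Scenario stratification supports two grouping modes: ``"expansion"`` gates
scenario A on the 5 mm-expanded high-dose PTV (the decision rule's form) and
``"ptv"`` on the raw high-dose PTV (the descriptive stratification by dose
level).  Dose levels rank *within* a plan: the highest prescription is
"high", the lowest "low", anything between "intermediate" — relative
ranking, because published Gy bands for the level groups overlap at 60 Gy
and per-plan rank resolves every prescription scheme unambiguously.

``calibrate_rule`` re-derives the scenario-A threshold from a cohort via the
ROC sweep and Youden-optimal operating point, and reports the side-by-side
AUC comparison of the five overlap predictors.  The shipped default
threshold (0.083) is never silently overwritten: calibration returns a new
config object for the caller to adopt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from .cohort_stats import (
    OperatingPoint,
    ParotidRecord,
    RocCurve,
    optimal_operating_point,
    roc_curve,
)
from .dosimetry import mean_dose
from .geometry import (
    distance_map_mm,
    fractional_overlap,
    union_masks,
    volume_cc,
)
from .grid_io import DoseGrid, StructureMask

__all__ = [
    "PredictionRuleConfig",
    "PredictionResult",
    "CalibrationReport",
    "rank_dose_levels",
    "compute_record",
    "assign_scenario",
    "predict_exceeds",
    "calibrate_rule",
]

RULE_VERSION = "olv-threshold-rule/1"


@dataclass(frozen=True)
class PredictionRuleConfig:
    """Tunable constants of the decision rule.

    tolerance_gy      sparing tolerance on parotid D_mean (Gy)
    hd_margin_mm      expansion of the high-dose PTV used by scenario A
    threshold_hd05    scenario-A cut on OLV_HD05 (positive iff strictly above)
    threshold_im      scenario-B cut on OLV_IM (positive iff at or above)
    grouping          "expansion" (rule form) or "ptv" (raw stratification)
    """

    tolerance_gy: float = 26.0
    hd_margin_mm: float = 5.0
    threshold_hd05: float = 0.083
    threshold_im: float = 0.25
    grouping: str = "expansion"

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_hd05 < 1.0):
            raise ValueError(f"threshold_hd05 must lie in (0, 1), got {self.threshold_hd05}")
        if not (0.0 < self.threshold_im < 1.0):
            raise ValueError(f"threshold_im must lie in (0, 1), got {self.threshold_im}")
        if self.hd_margin_mm < 0:
            raise ValueError("hd_margin_mm must be >= 0")
        if self.grouping not in ("expansion", "ptv"):
            raise ValueError(f"grouping must be 'expansion' or 'ptv', got {self.grouping!r}")

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps({
            "tolerance_gy": self.tolerance_gy,
            "hd_margin_mm": self.hd_margin_mm,
            "threshold_hd05": self.threshold_hd05,
            "threshold_im": self.threshold_im,
            "grouping": self.grouping,
            "rule_version": RULE_VERSION,
        }, indent=2)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, source: str | Path) -> "PredictionRuleConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        doc.pop("rule_version", None)
        return cls(**doc)


@dataclass
class PredictionResult:
    scenario: str  # "A", "B", "C", or "none"
    exceeds: bool
    driving_statistic: str | None
    driving_value: float | None
    rule_version: str = RULE_VERSION
    note: str = ""

    def __post_init__(self) -> None:
        if self.scenario == "none" and self.exceeds:
            raise ValueError("a parotid with no PTV overlap cannot be predicted positive")


def rank_dose_levels(prescriptions: Sequence[float]) -> list[str]:
    """Rank a plan's descending prescriptions as high/intermediate/low.

    The highest level is "high", the lowest "low", and middle level(s)
    "intermediate"; a 2-level plan has no intermediate.
    """
    rx = [float(p) for p in prescriptions]
    if sorted(rx, reverse=True) != rx or len(set(rx)) != len(rx):
        raise ValueError(f"prescriptions must be strictly descending, got {rx}")
    if len(rx) < 2:
        raise ValueError("a plan needs at least 2 dose levels")
    return ["high"] + ["intermediate"] * (len(rx) - 2) + ["low"]


def compute_record(
    parotid: StructureMask,
    ptvs: Sequence[tuple[float, StructureMask]],
    dose: DoseGrid | None = None,
    plan_id: str = "",
    side: str = "",
    config: PredictionRuleConfig | None = None,
) -> ParotidRecord:
    """Fill every OLV field (and D_mean, when dose is given) for one parotid.

    ``ptvs`` are (prescription Gy, mask) pairs in strictly descending dose
    order.  OLV_CT/CT05/CT10 are taken against the union of all PTVs and its
    5/10 mm expansions; OLV_HD/HD05 against the high-dose PTV and its
    expansion (margin from ``config``); OLV_IM/LD against the union of
    intermediate levels and the low level.
    """
    cfg = config or PredictionRuleConfig()
    if parotid.is_empty():
        raise ValueError(f"parotid '{parotid.name}' is empty")
    ranks = rank_dose_levels([rx for rx, _ in ptvs])
    masks = [m for _, m in ptvs]

    combined = union_masks(masks, name="PTV_combined")
    d_combined = distance_map_mm(combined)
    d_high = distance_map_mm(masks[0])
    grid = parotid.grid

    def _olv(occ) -> float:
        return fractional_overlap(parotid, StructureMask(grid, occ, "target"))

    intermediates = [m for m, r in zip(masks, ranks) if r == "intermediate"]

    olv_ct = _olv(combined.occupancy)
    olv_ct05 = _olv(d_combined <= 5.0)
    olv_ct10 = _olv(d_combined <= 10.0)
    olv_hd = _olv(masks[0].occupancy)
    olv_hd05 = _olv(d_high <= cfg.hd_margin_mm) if cfg.hd_margin_mm > 0 else olv_hd
    olv_im = _olv(union_masks(intermediates).occupancy) if intermediates else 0.0
    olv_ld = _olv(masks[-1].occupancy)

    d_mean = mean_dose(dose, parotid) if dose is not None else None
    return ParotidRecord(
        plan_id=plan_id, side=side, volume_cc=volume_cc(parotid),
        olv_ct=olv_ct, olv_ct05=olv_ct05, olv_ct10=olv_ct10,
        olv_hd=olv_hd, olv_hd05=olv_hd05, olv_im=olv_im, olv_ld=olv_ld,
        d_mean=d_mean,
    )


def assign_scenario(record: ParotidRecord, mode: str = "expansion") -> str:
    """Stratify a parotid by which dose level it overlaps.

    ``"ptv"`` mode: A iff it overlaps the raw high-dose PTV; else B iff it
    overlaps an intermediate-dose PTV; else C iff it overlaps the low-dose
    PTV; else "none".  ``"expansion"`` mode gates scenario A on the 5 mm
    expanded high-dose PTV instead (the decision rule's grouping).
    """
    if mode not in ("expansion", "ptv"):
        raise ValueError(f"mode must be 'expansion' or 'ptv', got {mode!r}")
    gate = record.olv_hd05 if mode == "expansion" else record.olv_hd
    if gate > 0:
        return "A"
    if record.olv_im > 0:
        return "B"
    if record.olv_ld > 0:
        return "C"
    return "none"


def predict_exceeds(
    record: ParotidRecord, cfg: PredictionRuleConfig | None = None
) -> PredictionResult:
    """Apply the threshold rule: does this parotid's D_mean exceed tolerance?

    Scenario A: positive iff OLV_HD05 > threshold (strict).  Scenario B:
    positive iff OLV_IM >= threshold_im; an overlap exactly at the boundary
    is flagged indeterminate in the note while the boolean stays positive
    (conservative).  Scenarios C and "none" predict sparing.
    """
    cfg = cfg or PredictionRuleConfig()
    scenario = assign_scenario(record, cfg.grouping)
    note = ""
    if scenario == "A":
        value = record.olv_hd05
        exceeds = value > cfg.threshold_hd05
        driving = "olv_hd05"
    elif scenario == "B":
        value = record.olv_im
        exceeds = value >= cfg.threshold_im
        driving = "olv_im"
        if value == cfg.threshold_im:
            note = ("OLV_IM sits exactly at the scenario-B boundary; "
                    "treated as positive but clinically indeterminate")
    elif scenario == "C":
        value = record.olv_ld
        exceeds = False
        driving = "olv_ld"
    else:
        value = None
        exceeds = False
        driving = None
    return PredictionResult(scenario, exceeds, driving, value, note=note)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationReport:
    n_records: int
    n_scenario_a: int
    n_positive_a: int
    n_negative_a: int
    roc_hd05: RocCurve
    operating_point: OperatingPoint
    sensitivity: float
    specificity: float
    auc: dict = field(default_factory=dict)
    threshold_im_candidate: float | None = None
    notes: list[str] = field(default_factory=list)


def _labels(records: Sequence[ParotidRecord], tolerance: float) -> list[bool]:
    out = []
    for r in records:
        if r.d_mean is None:
            raise ValueError(f"record {r.plan_id}/{r.side} has no D_mean; "
                             "calibration needs outcomes")
        out.append(r.d_mean > tolerance)
    return out


def calibrate_rule(
    cohort: Sequence[ParotidRecord],
    base_config: PredictionRuleConfig | None = None,
) -> tuple[PredictionRuleConfig, CalibrationReport]:
    """Re-derive the scenario-A OLV_HD05 threshold from a cohort.

    Restricts to scenario-A records (per the config's grouping mode), sweeps
    the ROC of OLV_HD05 against the D_mean > tolerance outcome, and places
    the threshold at the Youden-optimal operating point.  The report carries
    the AUC of all five overlap predictors — the combined-target family on
    the full cohort and the high-dose family on the scenario-A subset, which
    is the subset each was designed to discriminate.  ``threshold_im`` stays
    at its default; if positive scenario-B records exist, the midpoint
    between the largest negative and smallest positive OLV_IM is reported as
    a candidate only.
    """
    cfg = base_config or PredictionRuleConfig()
    records = list(cohort)
    if not records:
        raise ValueError("empty cohort")

    scen = [assign_scenario(r, cfg.grouping) for r in records]
    sub_a = [r for r, s in zip(records, scen) if s == "A"]
    lab_a = _labels(sub_a, cfg.tolerance_gy)
    n_pos = sum(lab_a)
    n_neg = len(lab_a) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"scenario-A subset is single-class ({n_pos} positive, {n_neg} "
            f"negative of {len(sub_a)} records); cannot calibrate a threshold"
        )

    rc = roc_curve([r.olv_hd05 for r in sub_a], lab_a)
    op = optimal_operating_point(rc)

    # direct confusion-matrix recount at the chosen threshold
    pred = [r.olv_hd05 > op.threshold for r in sub_a]
    tp = sum(p and l for p, l in zip(pred, lab_a))
    tn = sum((not p) and (not l) for p, l in zip(pred, lab_a))
    sens = tp / n_pos
    spec = tn / n_neg

    auc: dict[str, float | None] = {}
    lab_full = _labels(records, cfg.tolerance_gy)
    for name in ("olv_ct", "olv_ct05", "olv_ct10"):
        if 0 < sum(lab_full) < len(lab_full):
            auc[name] = roc_curve([getattr(r, name) for r in records], lab_full).auc
        else:
            auc[name] = None
    for name in ("olv_hd", "olv_hd05"):
        auc[name] = roc_curve([getattr(r, name) for r in sub_a], lab_a).auc

    notes: list[str] = []
    im_candidate = None
    sub_b = [r for r, s in zip(records, scen) if s == "B"]
    if sub_b:
        lab_b = _labels(sub_b, cfg.tolerance_gy)
        pos_im = [r.olv_im for r, l in zip(sub_b, lab_b) if l]
        neg_im = [r.olv_im for r, l in zip(sub_b, lab_b) if not l]
        if pos_im and neg_im:
            im_candidate = (max(neg_im) + min(pos_im)) / 2.0
            notes.append(
                f"scenario-B candidate threshold {im_candidate:.4f} "
                "(midpoint of largest negative and smallest positive OLV_IM); "
                "threshold_im left at default"
            )
        elif pos_im:
            notes.append("all scenario-B records positive; threshold_im left at default")

    new_cfg = replace(cfg, threshold_hd05=float(op.threshold))
    report = CalibrationReport(
        n_records=len(records), n_scenario_a=len(sub_a),
        n_positive_a=n_pos, n_negative_a=n_neg,
        roc_hd05=rc, operating_point=op,
        sensitivity=sens, specificity=spec,
        auc=auc, threshold_im_candidate=im_candidate, notes=notes,
    )
    return new_cfg, report
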