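"""Closed-form assay conversions.

Insulin unit conversion (ng/ml -> uIU/mL, factor 26), the HOMA insulin
resistance index (insulin * glucose / 405), and fatty-acid-oxidation
activity from a background-subtracted OD(492) reading (factor 12.96 IU/l
per OD unit).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

INSULIN_NG_TO_UIU = 26.0
HOMA_IR_DENOMINATOR = 405.0
FAO_IU_PER_OD = 12.96

NEGATIVE_NET_OD = "NEGATIVE_NET_OD"


def insulin_ng_to_uIU(x: float) -> float:
    """Convert fasting insulin from ng/ml to uIU/mL (x 26)."""
    if x < 0:
        raise ValueError("insulin concentration must be >= 0")
    return INSULIN_NG_TO_UIU * x


def homa_ir(glucose_mg_dl: float, insulin_uIU_ml: float) -> float:
    """HOMA-IR = insulin (uIU/mL) * glucose (mg/dL) / 405."""
    if glucose_mg_dl < 0 or insulin_uIU_ml < 0:
        raise ValueError("glucose and insulin must be >= 0")
    return insulin_uIU_ml * glucose_mg_dl / HOMA_IR_DENOMINATOR


@dataclass(frozen=True)
class FaoResult:
    activity_iu_l: float
    flags: frozenset[str] = frozenset()


def fao_activity(od_reaction: float, od_control: float) -> FaoResult:
    """FAO activity (IU/l) = 12.96 * (OD reaction - OD control).

    A negative net OD (control above reaction) is non-physical and is
    clamped to 0 with a QC flag.
    """
    if od_reaction < 0 or od_control < 0:
        raise ValueError("optical densities must be >= 0")
    net = od_reaction - od_control
    if net < 0:
        return FaoResult(0.0, frozenset({NEGATIVE_NET_OD}))
    return FaoResult(FAO_IU_PER_OD * net)


def annotate_batch(samples: pd.DataFrame) -> pd.DataFrame:
    """Append computed columns to a batch table.

    Recognized inputs (all optional, per column): ``insulin_ng_ml``,
    ``glucose_mg_dl``, ``od_reaction``, ``od_control``.
    """
    out = samples.copy()
    if "insulin_ng_ml" in out:
        out["insulin_uIU_ml"] = out["insulin_ng_ml"].map(insulin_ng_to_uIU)
    if "glucose_mg_dl" in out and "insulin_uIU_ml" in out:
        out["homa_ir"] = [
            homa_ir(g, i) for g, i in zip(out["glucose_mg_dl"], out["insulin_uIU_ml"])
        ]
    if "od_reaction" in out and "od_control" in out:
        results = [
            fao_activity(r, c) for r, c in zip(out["od_reaction"], out["od_control"])
        ]
        out["fao_iu_l"] = [r.activity_iu_l for r in results]
        out["fao_flags"] = [";".join(sorted(r.flags)) for r in results]
    return out
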