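"""Screen statistics: DMSO conversion, robust Z, toxicity gate, hit calling.

The per-well raw lipophagy score is converted against a vehicle-only (DMSO)
plate at the same well position to remove positional artifacts, then
standardized over the pooled compound wells as

    Z_i = (x_i - median(x)) / (1.4826 * MAD(x))

where MAD is the median absolute deviation from the median. Hits are
strictly Z > 3 among non-toxic wells; toxic wells are those with cell
count strictly below 80% of the DMSO-well median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

UNDEFINED_FOLD = "UNDEFINED_FOLD"


class DegenerateScaleError(ValueError):
    """All values identical: robust scale is zero, Z undefined."""


@dataclass
class ScreenConfig:
    """Thresholds and modes for the screen statistics stage."""

    hit_z_threshold: float = 3.0
    toxicity_fraction: float = 0.80
    dmso_correction_mode: str = "subtract"
    robust_scale_constant: float = 1.4826
    pool_per_plate: bool = False

    def __post_init__(self) -> None:
        if self.hit_z_threshold <= 0 or self.toxicity_fraction <= 0:
            raise ValueError("thresholds must be positive")
        if self.dmso_correction_mode not in ("subtract", "divide"):
            raise ValueError("dmso_correction_mode must be 'subtract' or 'divide'")
        if self.robust_scale_constant <= 0:
            raise ValueError("robust_scale_constant must be positive")


def dmso_convert(
    quant: pd.DataFrame,
    dmso_plate: pd.DataFrame,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Convert raw scores against the DMSO plate, position by position.

    ``subtract`` (default): converted = raw - dmso at the same (row, col).
    ``divide``: converted = raw / dmso, requiring dmso well values away
    from zero.

    Returns a copy of ``quant`` with a ``score_converted`` column.
    """
    config = config or ScreenConfig()
    dmso_map = {
        (int(r), int(c)): s
        for r, c, s in zip(dmso_plate["row"], dmso_plate["col"], dmso_plate["score_raw"])
    }
    missing = [
        (int(r), int(c))
        for r, c in zip(quant["row"], quant["col"])
        if (int(r), int(c)) not in dmso_map
    ]
    if missing:
        raise KeyError(f"DMSO plate missing well positions: {sorted(set(missing))}")
    ref = np.array(
        [dmso_map[(int(r), int(c))] for r, c in zip(quant["row"], quant["col"])],
        dtype=float,
    )
    raw = quant["score_raw"].to_numpy(dtype=float)
    out = quant.copy()
    if config.dmso_correction_mode == "subtract":
        out["score_converted"] = raw - ref
    else:
        near_zero = np.abs(ref) < 1e-9
        if near_zero.any():
            bad = [
                (int(r), int(c))
                for (r, c), z in zip(zip(quant["row"], quant["col"]), near_zero)
                if z
            ]
            raise ZeroDivisionError(
                f"divide mode with zero/near-zero DMSO values at wells {bad}"
            )
        out["score_converted"] = raw / ref
    return out


def robust_z(
    converted: Sequence[float] | np.ndarray,
    config: ScreenConfig | None = None,
) -> np.ndarray:
    """Robust Z over the pooled sample: (x - median) / (c * MAD)."""
    config = config or ScreenConfig()
    x = np.asarray(converted, dtype=float)
    if x.size < 3:
        raise ValueError(f"robust Z needs >= 3 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("robust Z input contains non-finite values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise DegenerateScaleError("all converted scores equal: MAD is zero")
    return (x - med) / (config.robust_scale_constant * mad)


def toxicity_filter(
    quant: pd.DataFrame,
    dmso_reference_counts: Sequence[float],
    config: ScreenConfig | None = None,
) -> pd.Series:
    """Flag wells whose cell count is strictly below 80% of the DMSO median.

    Returns a boolean Series aligned with ``quant`` plus attrs carrying the
    reference count.
    """
    config = config or ScreenConfig()
    ref_counts = np.asarray(list(dmso_reference_counts), dtype=float)
    if ref_counts.size == 0:
        raise ValueError("DMSO reference cell counts are empty")
    reference = float(np.median(ref_counts))
    toxic = quant["cell_count"].to_numpy(dtype=float) < config.toxicity_fraction * reference
    out = pd.Series(toxic, index=quant.index, name="toxic")
    out.attrs["reference_count"] = reference
    return out


def build_screen_table(
    quant: pd.DataFrame,
    dmso_plate: pd.DataFrame,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Compound-well screen table: converted score, robust Z, toxic, hit.

    ``quant`` holds the compound-plate quantification (compound and on-plate
    DMSO wells); ``dmso_plate`` is the vehicle-only plate used for the
    positional conversion. Toxicity is referenced to the median cell count
    of DMSO wells (on-plate DMSO wells if present, else the DMSO plate).
    Robust Z pools all compound wells unless ``config.pool_per_plate``.
    """
    config = config or ScreenConfig()
    converted = dmso_convert(quant, dmso_plate, config)
    comp = converted[converted["role"] == "compound"].copy()
    if comp.empty:
        raise ValueError("no compound wells to score")

    dmso_counts = converted.loc[converted["role"] == "dmso", "cell_count"]
    if dmso_counts.empty:
        dmso_counts = dmso_plate["cell_count"]
    toxic = toxicity_filter(comp, dmso_counts.tolist(), config)
    comp["cell_fraction_of_reference"] = comp["cell_count"] / toxic.attrs["reference_count"]
    comp["toxic"] = toxic

    if config.pool_per_plate and "plate" in comp.columns:
        z = np.empty(len(comp))
        for _, idx in comp.groupby("plate").indices.items():
            z[idx] = robust_z(comp["score_converted"].to_numpy()[idx], config)
        comp["robust_z"] = z
    else:
        comp["robust_z"] = robust_z(comp["score_converted"].to_numpy(), config)
    comp["hit"] = (comp["robust_z"] > config.hit_z_threshold) & ~comp["toxic"]
    return comp.reset_index(drop=True)


def call_hits(
    screen: pd.DataFrame,
    config: ScreenConfig | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Strict-threshold hit calling on a screen table.

    hit <=> robust_z > threshold (strict) and not toxic. Returns the
    boolean flags plus the hit list sorted by descending Z, ties broken by
    (row, col).
    """
    config = config or ScreenConfig()
    if "robust_z" not in screen or "toxic" not in screen:
        raise KeyError("screen table needs robust_z and toxic columns")
    flags = (screen["robust_z"] > config.hit_z_threshold) & ~screen["toxic"]
    flags.name = "hit"
    hits = screen[flags].copy()
    hits = hits.sort_values(
        ["robust_z", "row", "col"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return flags, hits


def fold_change(
    treated_scores: Sequence[float], control_scores: Sequence[float]
) -> float | str:
    """median(treated) / median(control); UNDEFINED_FOLD if control <= 0."""
    treated = np.asarray(list(treated_scores), dtype=float)
    control = np.asarray(list(control_scores), dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValueError("fold_change needs non-empty score lists")
    ctrl_med = float(np.median(control))
    if ctrl_med <= 0:
        return UNDEFINED_FOLD
    return float(np.median(treated)) / ctrl_med


def screen_summary(screen: pd.DataFrame, config: ScreenConfig) -> dict:
    """JSON-ready run summary."""
    return {
        "n_wells": int(len(screen)),
        "n_toxic": int(screen["toxic"].sum()),
        "n_hits": int(screen["hit"].sum()),
        "config": {
            "hit_z_threshold": config.hit_z_threshold,
            "toxicity_fraction": config.toxicity_fraction,
            "dmso_correction_mode": config.dmso_correction_mode,
            "robust_scale_constant": config.robust_scale_constant,
            "pool_per_plate": config.pool_per_plate,
        },
    }


def write_screen_tsv(screen: pd.DataFrame, path) -> None:
    cols = [
        "plate", "row", "col", "compound_id", "score_raw", "score_converted",
        "robust_z", "cell_count", "cell_fraction_of_reference", "toxic", "hit",
    ]
    screen[[c for c in cols if c in screen.columns]].to_csv(path, sep="\t", index=False)
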