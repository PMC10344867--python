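"""Ground-truth generators for every downstream stage.

Everything here is synthetic with known truth: 384-well plate layouts,
per-well cell populations rendered as three-channel images (nuclear BFP,
droplet GFP/mCherry where droplet GFP is attenuated by the quench
fraction), flow-cytometry-like event tables, and patient registries with a
controlled exposure-outcome odds ratio.

All randomness flows from explicit integer seeds; no global RNG state is
touched. Identical seeds and parameters give identical outputs.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .image_quant import WellImage

ROW_LETTERS = string.ascii_uppercase


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> 'A1'-style address."""
    return f"{ROW_LETTERS[row]}{col + 1}"


def parse_well_name(name: str) -> tuple[int, int]:
    return ROW_LETTERS.index(name[0]), int(name[1:]) - 1


# ---------------------------------------------------------------------------
# plate layout


@dataclass
class PlateLayout:
    """Well-role and compound assignment map for one plate.

    ``wells`` has one row per well with columns ``row, col, role,
    compound_id`` (0-based indices; role in {compound, dmso, empty};
    compound_id non-null iff role == compound).
    """

    plate_id: str
    n_rows: int = 16
    n_cols: int = 24
    wells: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.wells) != self.n_rows * self.n_cols:
            raise ValueError("layout must assign a role to every well")
        roles = set(self.wells["role"])
        if not roles <= {"compound", "dmso", "empty"}:
            raise ValueError(f"unknown roles: {roles - {'compound', 'dmso', 'empty'}}")
        comp = self.wells["role"] == "compound"
        if comp.any() and not (self.wells["role"] == "dmso").any():
            raise ValueError("a plate with compound wells needs at least one dmso well")
        if self.wells.loc[comp, "compound_id"].isna().any():
            raise ValueError("compound wells must carry a compound_id")
        if self.wells.loc[~comp, "compound_id"].notna().any():
            raise ValueError("non-compound wells must not carry a compound_id")

    @property
    def n_compound(self) -> int:
        return int((self.wells["role"] == "compound").sum())

    @property
    def n_dmso(self) -> int:
        return int((self.wells["role"] == "dmso").sum())


def make_plate_layout(
    n_compounds: int,
    n_dmso: int,
    seed: int,
    *,
    plate_id: str = "plate01",
    n_rows: int = 16,
    n_cols: int = 24,
    compound_prefix: str = "CPD",
) -> PlateLayout:
    """Randomly scatter compound and DMSO wells across the plate.

    DMSO wells are spread over the whole plate (uniform random positions,
    not a contiguous block), so a positional artifact is sampled everywhere.
    """
    capacity = n_rows * n_cols
    if n_compounds < 0 or n_dmso < 0:
        raise ValueError("well counts must be non-negative")
    if n_compounds + n_dmso > capacity:
        raise ValueError(
            f"{n_compounds} compound + {n_dmso} dmso wells exceed plate "
            f"capacity {capacity} ({n_rows}x{n_cols})"
        )
    if n_compounds > 0 and n_dmso == 0:
        raise ValueError("a plate with compound wells needs at least one dmso well")
    rng = np.random.default_rng(seed)
    order = rng.permutation(capacity)
    roles = np.array(["empty"] * capacity, dtype=object)
    roles[order[:n_compounds]] = "compound"
    roles[order[n_compounds : n_compounds + n_dmso]] = "dmso"
    rows, cols = np.divmod(np.arange(capacity), n_cols)
    compound_ids = np.array([None] * capacity, dtype=object)
    counter = 1
    for idx in range(capacity):
        if roles[idx] == "compound":
            compound_ids[idx] = f"{compound_prefix}{counter:05d}"
            counter += 1
    wells = pd.DataFrame(
        {"row": rows, "col": cols, "role": roles, "compound_id": compound_ids}
    )
    return PlateLayout(plate_id=plate_id, n_rows=n_rows, n_cols=n_cols, wells=wells)


def write_plate_map(layout: PlateLayout, path) -> None:
    """Plate map CSV: plate_id,row,col,role,compound_id with A1-style wells."""
    df = layout.wells.copy()
    out = pd.DataFrame(
        {
            "plate_id": layout.plate_id,
            "row": [ROW_LETTERS[r] for r in df["row"]],
            "col": df["col"] + 1,
            "role": df["role"],
            "compound_id": df["compound_id"],
        }
    )
    out.to_csv(path, index=False)


def read_plate_map(path) -> PlateLayout:
    df = pd.read_csv(path)
    rows = df["row"].map(ROW_LETTERS.index)
    wells = pd.DataFrame(
        {
            "row": rows.astype(int),
            "col": df["col"].astype(int) - 1,
            "role": df["role"],
            "compound_id": df["compound_id"].where(df["compound_id"].notna(), None),
        }
    )
    n_rows = int(wells["row"].max()) + 1
    n_cols = int(wells["col"].max()) + 1
    return PlateLayout(
        plate_id=str(df["plate_id"].iloc[0]),
        n_rows=max(n_rows, 16),
        n_cols=max(n_cols, 24),
        wells=wells.sort_values(["row", "col"]).reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# screen ground truth


def simulate_screen_truth(
    layout: PlateLayout,
    n_actives: int,
    active_quench: float,
    n_toxic: int,
    seed: int,
    *,
    mean_cell_count: int = 60,
    cell_count_cv: float = 0.06,
    droplet_density: float = 4.0,
    toxic_factor_range: tuple[float, float] = (0.3, 0.6),
) -> pd.DataFrame:
    """Assign quench/toxicity truth to a layout's non-empty wells.

    Exactly ``n_actives`` compound wells get ``quench_fraction ==
    active_quench``; exactly ``n_toxic`` distinct compound wells get a
    ``toxicity_factor`` drawn from ``toxic_factor_range``. All other wells
    (including DMSO) have quench 0 and toxicity factor 1.
    """
    if not (0 < active_quench <= 1) and n_actives > 0:
        raise ValueError("active_quench must be in (0, 1]")
    wells = layout.wells
    comp_idx = wells.index[wells["role"] == "compound"].to_numpy()
    if n_actives + n_toxic > len(comp_idx):
        raise ValueError(
            f"{n_actives} actives + {n_toxic} toxic exceed "
            f"{len(comp_idx)} compound wells"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(comp_idx, size=n_actives + n_toxic, replace=False)
    active_set = set(picked[:n_actives].tolist())
    toxic_set = set(picked[n_actives:].tolist())

    nonempty = wells[wells["role"] != "empty"]
    lo, hi = toxic_factor_range
    records = []
    for idx, rec in zip(nonempty.index, nonempty.itertuples(index=False)):
        # dispensed cell numbers are tightly controlled; narrow spread keeps
        # the <80% toxicity gate specific for genuinely toxic wells
        count = max(0, int(round(mean_cell_count * (1 + cell_count_cv * rng.normal()))))
        records.append(
            {
                "row": int(rec.row),
                "col": int(rec.col),
                "role": rec.role,
                "compound_id": rec.compound_id,
                "true_cell_count": count,
                "quench_fraction": active_quench if idx in active_set else 0.0,
                "toxicity_factor": float(rng.uniform(lo, hi)) if idx in toxic_set else 1.0,
                "droplet_density": droplet_density,
            }
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# image rendering


@dataclass
class ImagingParams:
    """Renderer configuration.

    Blobs are isotropic Gaussians with sigma = radius / 2, truncated to a
    circle of radius ``1.9 * radius`` so that blobs spaced >= 4 * radius
    apart have disjoint supports (noiseless counts are then exact).
    The position artifact is an additive per-well offset on the mCherry
    channel: ``row_amp * row/(n_rows-1) + col_amp * col/(n_cols-1)``.
    """

    image_size: tuple[int, int] = (256, 256)
    bit_depth: int = 16
    background_level: float = 100.0
    noise_sd: float = 30.0
    poisson_noise: bool = False
    nucleus_radius_px: float = 3.0
    droplet_radius_px: float = 2.5
    nucleus_amplitude: float = 3000.0
    droplet_gfp_amplitude: float = 2500.0
    droplet_mcherry_amplitude: float = 2500.0
    nucleus_min_sep_factor: float = 4.0
    artifact_row_amp: float = 0.0
    artifact_col_amp: float = 0.0
    plate_shape: tuple[int, int] = (16, 24)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if min(self.image_size) < 1:
            raise ValueError("image_size must be positive")
        if self.artifact_row_amp < 0 or self.artifact_col_amp < 0:
            raise ValueError("artifact amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def artifact_offset(self, row: int, col: int) -> float:
        nr, nc = self.plate_shape
        r = row / (nr - 1) if nr > 1 else 0.0
        c = col / (nc - 1) if nc > 1 else 0.0
        return self.artifact_row_amp * r + self.artifact_col_amp * c


def _gaussian_stamp(radius: float) -> np.ndarray:
    """Unit-amplitude Gaussian blob, circularly truncated at 1.9 * radius."""
    sigma = radius / 2.0
    half = int(np.ceil(1.9 * radius))
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    r2 = x * x + y * y
    stamp = np.exp(-r2 / (2.0 * sigma * sigma))
    stamp[r2 > (1.9 * radius) ** 2] = 0.0
    return stamp


def _add_stamp(field: np.ndarray, stamp: np.ndarray, cy: int, cx: int, amp: float) -> None:
    h, w = field.shape
    half = stamp.shape[0] // 2
    y0, y1 = cy - half, cy + half + 1
    x0, x1 = cx - half, cx + half + 1
    sy0, sx0 = max(0, -y0), max(0, -x0)
    sy1 = stamp.shape[0] - max(0, y1 - h)
    sx1 = stamp.shape[1] - max(0, x1 - w)
    field[max(0, y0) : min(h, y1), max(0, x0) : min(w, x1)] += (
        amp * stamp[sy0:sy1, sx0:sx1]
    )


def _dart_throw(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_sep: float,
    max_tries: int = 200,
) -> np.ndarray:
    """Sample n points with pairwise separation >= min_sep (best effort)."""
    h, w = shape
    pts: list[tuple[float, float]] = []
    for _ in range(n):
        best = None
        best_d = -1.0
        for _ in range(max_tries):
            cand = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            if pts:
                arr = np.asarray(pts)
                d = float(np.min(np.hypot(arr[:, 0] - cand[0], arr[:, 1] - cand[1])))
            else:
                d = np.inf
            if d >= min_sep:
                best = cand
                break
            if d > best_d:
                best_d, best = d, cand
        pts.append(best)
    return np.asarray(pts).reshape(n, 2)


def render_well_image(
    truth,
    params: ImagingParams,
    *,
    return_truth: bool = False,
):
    """Render one well's three channels from its ground truth.

    ``truth`` is a row of the table from :func:`simulate_screen_truth`
    (attribute access: row, col, true_cell_count, quench_fraction,
    toxicity_factor, droplet_density).

    The BFP channel carries one nucleus blob per surviving cell
    (``round(true_cell_count * toxicity_factor)``); GFP and mCherry carry
    co-localized droplet blobs with the GFP amplitude scaled by
    ``1 - quench_fraction``. A per-well additive positional offset is
    applied to the mCherry channel, then Gaussian read noise (optional
    Poisson shot noise), clipping to the bit-depth range.

    With ``return_truth=True`` also returns a dict with nucleus centers,
    droplet centers, and the boolean droplet support mask.
    """
    if min(params.image_size) < 1:
        raise ValueError("zero-size image")
    row, col = int(truth.row), int(truth.col)
    rng = np.random.default_rng([params.rng_seed, row, col])
    h, w = params.image_size
    n_cells = int(round(float(truth.true_cell_count) * float(truth.toxicity_factor)))

    bfp = np.zeros((h, w), dtype=float)
    gfp = np.zeros((h, w), dtype=float)
    mch = np.zeros((h, w), dtype=float)

    nuc_stamp = _gaussian_stamp(params.nucleus_radius_px)
    drop_stamp = _gaussian_stamp(params.droplet_radius_px)
    margin = 2.0 * params.nucleus_radius_px + 1
    min_sep = params.nucleus_min_sep_factor * params.nucleus_radius_px
    centers = _dart_throw(rng, n_cells, (h, w), margin, min_sep)

    gfp_amp = params.droplet_gfp_amplitude * (1.0 - float(truth.quench_fraction))
    mch_amp = params.droplet_mcherry_amplitude
    for cy, cx in centers:
        _add_stamp(bfp, nuc_stamp, int(round(cy)), int(round(cx)), params.nucleus_amplitude)

    # droplets sit in an annulus around their nucleus (vectorized draws)
    n_drop_per_cell = rng.poisson(float(truth.droplet_density), size=n_cells)
    n_drop = int(n_drop_per_cell.sum())
    if n_drop > 0 and n_cells > 0:
        owner = np.repeat(np.arange(n_cells), n_drop_per_cell)
        ang = rng.uniform(0, 2 * np.pi, size=n_drop)
        rad = rng.uniform(2.0, 4.0, size=n_drop) * params.nucleus_radius_px
        dy = np.round(centers[owner, 0] + rad * np.sin(ang)).astype(int)
        dx = np.round(centers[owner, 1] + rad * np.cos(ang)).astype(int)
        inside = (dy >= 0) & (dy < h) & (dx >= 0) & (dx < w)
        dy, dx = dy[inside], dx[inside]
        for y, x in zip(dy.tolist(), dx.tolist()):
            _add_stamp(gfp, drop_stamp, y, x, gfp_amp)
            _add_stamp(mch, drop_stamp, y, x, mch_amp)
        droplet_centers = list(zip(dy.tolist(), dx.tolist()))
    else:
        droplet_centers = []

    mch += params.artifact_offset(row, col)

    channels = {}
    max_val = float(2**params.bit_depth - 1)
    if params.noise_sd > 0:
        noise = rng.normal(0.0, params.noise_sd, size=(3, h, w))
    else:
        noise = np.zeros((3, h, w))
    for i, (name, base) in enumerate((("BFP", bfp), ("GFP", gfp), ("mCherry", mch))):
        img = base + params.background_level
        if params.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        img = img + noise[i]
        np.round(img, out=img)
        np.clip(img, 0, max_val, out=img)
        # detector counts fit comfortably in float32; halves plate memory
        channels[name] = img.astype(np.float32)

    image = WellImage(channels=channels, row=row, col=col)
    if not return_truth:
        return image

    drop_mask = np.zeros((h, w), dtype=bool)
    half = drop_stamp.shape[0] // 2
    support = drop_stamp > 0
    for dy, dx in droplet_centers:
        y0, y1 = dy - half, dy + half + 1
        x0, x1 = dx - half, dx + half + 1
        sy0, sx0 = max(0, -y0), max(0, -x0)
        sy1 = support.shape[0] - max(0, y1 - h)
        sx1 = support.shape[1] - max(0, x1 - w)
        drop_mask[max(0, y0) : min(h, y1), max(0, x0) : min(w, x1)] |= support[
            sy0:sy1, sx0:sx1
        ]
    return image, {
        "n_cells": n_cells,
        "nucleus_centers": centers,
        "droplet_centers": droplet_centers,
        "droplet_mask": drop_mask,
    }


def render_plate(truth: pd.DataFrame, params: ImagingParams) -> dict[tuple[int, int], WellImage]:
    """Render every well in a truth table; keys are 0-based (row, col)."""
    return {
        (int(t.row), int(t.col)): render_well_image(t, params)
        for t in truth.itertuples(index=False)
    }


def write_well_tiff(image: WellImage, directory, plate_id: str | None = None) -> str:
    """Write one 3-channel 16-bit TIFF named {plate}_{row}{col}.tif."""
    import os

    import tifffile

    from .image_quant import CHANNEL_ORDER

    plate = plate_id or image.plate_id or "plate"
    stack = np.stack(
        [image.channels[c].astype(np.uint16) for c in CHANNEL_ORDER], axis=0
    )
    path = os.path.join(directory, f"{plate}_{well_name(image.row, image.col)}.tif")
    tifffile.imwrite(path, stack, photometric="minisblack")
    return path


def read_well_tiff(path) -> WellImage:
    import os
    import re

    import tifffile

    from .image_quant import CHANNEL_ORDER

    stack = tifffile.imread(path)
    name = os.path.splitext(os.path.basename(path))[0]
    m = re.match(r"(.+)_([A-P])(\d+)$", name)
    plate, row, col = (m.group(1), ROW_LETTERS.index(m.group(2)), int(m.group(3)) - 1) if m else ("", 0, 0)
    return WellImage(
        channels={c: stack[i].astype(float) for i, c in enumerate(CHANNEL_ORDER)},
        row=row,
        col=col,
        plate_id=plate,
    )


# ---------------------------------------------------------------------------
# flow events


@dataclass
class FlowEvents:
    """Event-by-channel intensity table with a component label column."""

    data: pd.DataFrame
    sample: str = "sample"
    seed: int = 0

    LABEL = "component"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FlowEvents needs at least one channel")
        vals = self.data[self.channels].to_numpy()
        if np.any(vals < 0):
            raise ValueError("event intensities must be non-negative")

    @property
    def channels(self) -> list[str]:
        return [c for c in self.data.columns if c != self.LABEL]

    def __len__(self) -> int:
        return len(self.data)


def simulate_flow_events(
    mixture: Sequence[tuple[float, dict[str, tuple[float, float]]]],
    n_events: int,
    seed: int,
    *,
    sample: str = "sample",
) -> FlowEvents:
    """Sample a log-normal mixture of event populations.

    ``mixture`` is a list of ``(weight, {channel: (log_mean, log_sd)})``;
    weights must be non-negative and sum to 1. Component counts are
    multinomial. The output table carries a ``component`` integer column
    recording the generating component of each event (ground truth for
    gating oracles; not a fluorescence channel).
    """
    if len(mixture) == 0:
        raise ValueError("mixture must have at least one component")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    weights = np.array([w for w, _ in mixture], dtype=float)
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be >= 0 and sum to 1")
    channel_sets = [tuple(sorted(spec)) for _, spec in mixture]
    if len(set(channel_sets)) != 1:
        raise ValueError("all components must define the same channels")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_events, weights)
    frames = []
    for comp, (n_comp, (_, spec)) in enumerate(zip(counts, mixture)):
        cols = {
            ch: rng.lognormal(mu, sd, size=n_comp) for ch, (mu, sd) in sorted(spec.items())
        }
        frame = pd.DataFrame(cols)
        frame[FlowEvents.LABEL] = comp
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)
    data = data.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    return FlowEvents(data=data, sample=sample, seed=seed)


# ---------------------------------------------------------------------------
# patient registry


REGISTRY_COLUMNS = [
    "subject_id", "age", "sex", "bmi", "af", "hf_nyha", "digoxin", "fatty_liver",
]


def simulate_registry(
    n: int,
    digoxin_rate: float,
    fl_rate_unexposed: float,
    fl_odds_ratio_digoxin: float,
    missing_rate: float,
    hf_rate: float,
    seed: int,
    *,
    af_rate: float = 0.10,
    clamp_age: bool = False,
    confounding_strength: float = 0.0,
) -> pd.DataFrame:
    """Sample a registry with a controlled digoxin/fatty-liver odds ratio.

    Fatty liver follows a logistic model: centred age, sex, BMI and AF
    covariate terms plus ``log(fl_odds_ratio_digoxin)`` for exposed
    subjects, with intercept ``logit(fl_rate_unexposed)``. With the default
    ``confounding_strength = 0`` digoxin is independent of the covariates,
    so the crude 2x2 odds ratio converges to the requested value (up to
    mild non-collapsibility attenuation, well within Monte-Carlo error at
    the tested scales).

    ``missing_rate`` blanks age or BMI per subject; ``hf_rate`` assigns
    NYHA class 2-4. Ages are drawn N(62, 13) and include values outside
    20-80 unless ``clamp_age``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for name, rate in (
        ("digoxin_rate", digoxin_rate),
        ("fl_rate_unexposed", fl_rate_unexposed),
        ("missing_rate", missing_rate),
        ("hf_rate", hf_rate),
        ("af_rate", af_rate),
    ):
        if not (0 <= rate <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    if fl_odds_ratio_digoxin <= 0:
        raise ValueError("fl_odds_ratio_digoxin must be > 0")

    rng = np.random.default_rng(seed)
    age = rng.normal(62.0, 13.0, size=n)
    if clamp_age:
        age = np.clip(age, 20.0, 80.0)
    sex = np.where(rng.random(n) < 0.55, "M", "F")
    bmi = np.clip(rng.normal(22.5, 3.2, size=n), 12.0, None)
    af = rng.random(n) < af_rate

    # modest covariate effects: enough signal for matching to act on, small
    # enough that crude/marginal and conditional odds ratios agree within
    # the Monte-Carlo tolerances used downstream (non-collapsibility of the
    # logistic OR attenuates the crude estimate as these grow)
    lin_conf = (
        0.008 * (age - 62.0)
        + 0.05 * (sex == "M")
        + 0.04 * (bmi - 22.5)
        + 0.10 * af
    )
    dig_logit = _logit(digoxin_rate) + confounding_strength * (lin_conf - lin_conf.mean())
    digoxin = rng.random(n) < _expit(dig_logit)

    logit_fl = (
        _logit(fl_rate_unexposed)
        + (lin_conf - lin_conf.mean())
        + np.log(fl_odds_ratio_digoxin) * digoxin
    )
    fatty_liver = rng.random(n) < _expit(logit_fl)

    hf_nyha = np.full(n, np.nan)
    has_hf = rng.random(n) < hf_rate
    hf_nyha[has_hf] = rng.integers(2, 5, size=int(has_hf.sum()))
    mild = (~has_hf) & (rng.random(n) < 0.02)
    hf_nyha[mild] = 1.0

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "af": af,
            "hf_nyha": hf_nyha,
            "digoxin": digoxin,
            "fatty_liver": fatty_liver,
        }
    )
    miss = rng.random(n) < missing_rate
    which = rng.random(n) < 0.5
    df.loc[miss & which, "bmi"] = np.nan
    df.loc[miss & ~which, "age"] = np.nan
    return df


def make_cohort_flow_registry(
    n_total: int,
    n_violating: int,
    seed: int,
) -> pd.DataFrame:
    """Registry where exactly ``n_violating`` subjects fail a cohort filter.

    Starts from a clean registry (no missing data, no NYHA >= 2, ages
    clamped to 20-80) and corrupts exactly ``n_violating`` distinct
    subjects, split roughly evenly between missing BMI, NYHA class 2-4,
    and out-of-range age.
    """
    if n_violating > n_total:
        raise ValueError("cannot violate more subjects than exist")
    df = simulate_registry(
        n_total,
        digoxin_rate=0.02,
        fl_rate_unexposed=0.2,
        fl_odds_ratio_digoxin=0.58,
        missing_rate=0.0,
        hf_rate=0.0,
        seed=seed,
        clamp_age=True,
    )
    df["hf_nyha"] = np.nan  # drop even NYHA-1 records so the base is fully clean
    rng = np.random.default_rng([seed, 1])
    victims = rng.choice(n_total, size=n_violating, replace=False)
    n_miss = n_violating // 3
    n_hf = n_violating // 3
    for i in victims[:n_miss]:
        df.iat[i, df.columns.get_loc("bmi")] = np.nan
    for i in victims[n_miss : n_miss + n_hf]:
        df.iat[i, df.columns.get_loc("hf_nyha")] = float(rng.integers(2, 5))
    for i in victims[n_miss + n_hf :]:
        df.iat[i, df.columns.get_loc("age")] = float(
            rng.choice([15.0, 85.0, 90.0, 18.0])
        )
    return df


def write_registry_csv(registry: pd.DataFrame, path) -> None:
    registry.to_csv(path, index=False)


def read_registry_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("af", "digoxin", "fatty_liver"):
        if df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False}).astype(bool)
    return df


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))
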