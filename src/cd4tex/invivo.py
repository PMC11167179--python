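"""Statistics layer for the mouse checkpoint-blockade experiment.

Caliper measurements become tumor volumes via the ellipsoid approximation
V = (pi/6) * L * W^2 (a ``literal`` mode computing (pi/6) * L * W is also
provided); endpoint volumes are compared across treatment arms with Tukey's
HSD; and the ratio of Module1-Tex to Module2-Tex frequency is correlated
with endpoint volume under the conjunction rule p < 0.05 AND R^2 > 0.25.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .stats import CorrelationResult, pearson_corr, tukey_hsd, welch_t

VOLUME_MODES = ("width_squared", "literal")


def tumor_volume(length: float, width: float, mode: str = "width_squared") -> float:
    """Caliper tumor volume in mm^3.

    ``width_squared`` (default) uses the standard ellipsoid approximation
    (pi/6) * L * W^2; ``literal`` computes (pi/6) * L * W.
    """
    length = float(length)
    width = float(width)
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be positive")
    if mode == "width_squared":
        return math.pi / 6.0 * length * width**2
    if mode == "literal":
        return math.pi / 6.0 * length * width
    raise ValueError(f"unknown volume mode {mode!r}")


def volumes_from_measurements(measurements: pd.DataFrame, mode: str = "width_squared") -> pd.DataFrame:
    """Add a ``volume_mm3`` column; swaps length/width (with a warning) for
    rows violating length >= width."""
    df = measurements.copy()
    bad = df["length_mm"] < df["width_mm"]
    if bad.any():
        warnings.warn(f"{int(bad.sum())} measurements have width > length; axes swapped")
        l, w = df.loc[bad, "width_mm"].copy(), df.loc[bad, "length_mm"].copy()
        df.loc[bad, "length_mm"], df.loc[bad, "width_mm"] = l, w
    df["volume_mm3"] = [
        tumor_volume(l, w, mode=mode) for l, w in zip(df["length_mm"], df["width_mm"])
    ]
    return df


def endpoint_volumes(measurements: pd.DataFrame, mode: str = "width_squared",
                     day: int | None = None) -> pd.DataFrame:
    """Per-mouse volume at ``day`` (default: the last day measured for every
    mouse)."""
    df = volumes_from_measurements(measurements, mode=mode)
    if day is None:
        day = int(df.groupby("mouse_id")["day"].max().min())
    at = df[df["day"] == day]
    if at.empty:
        raise ValueError(f"no measurements at day {day}")
    return at[["mouse_id", "arm", "day", "volume_mm3"]].reset_index(drop=True)


def tukey_compare(volumes: pd.DataFrame, value_col: str = "volume_mm3",
                  group_col: str = "arm") -> pd.DataFrame:
    """Tukey HSD across arms on per-mouse endpoint values."""
    return tukey_hsd(volumes[value_col].to_numpy(), volumes[group_col].to_numpy())


def ratio_volume_correlation(
    tex_ratios: pd.DataFrame,
    volumes: pd.DataFrame,
    alpha: float = 0.05,
    r2_threshold: float = 0.25,
) -> CorrelationResult:
    """Pearson correlation between the Module1-Tex/Module2-Tex ratio and
    endpoint tumor volume, paired on mouse_id; significant iff p < alpha AND
    R^2 > r2_threshold."""
    merged = tex_ratios.merge(volumes[["mouse_id", "volume_mm3"]], on="mouse_id", how="inner")
    if (merged["module2_tex_freq"] <= 0).any():
        raise ValueError("module2_tex_freq must be positive to form the ratio")
    return pearson_corr(merged["ratio"], merged["volume_mm3"],
                        alpha=alpha, r2_threshold=r2_threshold)


def mfi_compare(mfi: pd.DataFrame, value_col: str = "mfi", group_col: str = "group"):
    """Compare per-mouse marker intensities: Welch's t for two groups, Tukey
    HSD for more."""
    labels = sorted(pd.unique(mfi[group_col]).tolist())
    if len(labels) == 2:
        a = mfi.loc[mfi[group_col] == labels[0], value_col].to_numpy()
        b = mfi.loc[mfi[group_col] == labels[1], value_col].to_numpy()
        t, df, p = welch_t(a, b)
        return pd.DataFrame([{"group_a": labels[0], "group_b": labels[1],
                              "t": t, "df": df, "p": p}])
    return tukey_hsd(mfi[value_col].to_numpy(), mfi[group_col].to_numpy())
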