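"""Electron-microscopy and in-situ morphometry: g-ratio, myelination, mitochondria.

Areas are measured in μm² on transverse profiles; diameters are derived
assuming circular cross-sections, so g = d(axon) / d(axon + myelin) =
sqrt(axon_area / outer_area).  Axons with diameter < 0.4 μm are excluded as
unmyelinated small-calibre fibres (the boundary 0.4 μm itself is kept).
Group comparisons use the animal as the unit of inference: a
Lilliefors-corrected Kolmogorov-Smirnov normality check decides between a
two-sided unpaired t-test and a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclass
class MorphometryConfig:
    min_axon_diameter: float = 0.4  # μm
    normality_alpha: float = 0.05
    lilliefors_sims: int = 1000
    lilliefors_seed: int = 0


def diameter_from_area(area) -> np.ndarray | float:
    """Equivalent circular diameter d = 2 sqrt(area / π) in μm."""
    arr = np.asarray(area, dtype=float)
    if np.any(arr <= 0):
        raise ValidationError("area must be positive")
    d = 2.0 * np.sqrt(arr / np.pi)
    return float(d) if np.isscalar(area) or arr.ndim == 0 else d


def g_ratio(axon_area, outer_area) -> np.ndarray | float:
    """g = d(axon) / d(axon + myelin) = sqrt(axon_area / outer_area), in (0, 1]."""
    a = np.asarray(axon_area, dtype=float)
    o = np.asarray(outer_area, dtype=float)
    if np.any(a <= 0):
        raise ValidationError("axon area must be positive")
    if np.any(o < a):
        raise ValidationError("outer (axon + myelin) area smaller than axon area")
    g = np.sqrt(a / o)
    return float(g) if np.isscalar(axon_area) or a.ndim == 0 else g


def exclude_small_axons(
    profiles: pd.DataFrame, cfg: MorphometryConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split profiles into (kept, excluded) by the small-calibre diameter rule.

    Kept iff diameter >= min_axon_diameter (exclusion is strict '<')."""
    cfg = cfg or MorphometryConfig()
    if len(profiles) == 0:
        return profiles.copy(), profiles.copy()
    d = diameter_from_area(profiles["axon_area"].to_numpy())
    keep = d >= cfg.min_axon_diameter
    return profiles[keep].reset_index(drop=True), profiles[~keep].reset_index(drop=True)


def myelinated_fraction(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentage of myelinated axons per animal, with condition mean ± SEM.

    Axons flagged with uncompacted membranes count as unmyelinated; the SEM
    is computed over animals, not axons.
    """
    myel = profiles["myelinated"].astype(bool)
    if "uncompacted" in profiles.columns:
        myel = myel & ~profiles["uncompacted"].astype(bool)
    df = profiles.assign(_myel=myel)
    rows = []
    for (animal, condition), grp in df.groupby(["animal_id", "condition"], sort=True):
        if len(grp) == 0:
            warnings.warn(f"animal {animal} has no scored axons; skipped")
            continue
        rows.append(
            {
                "animal_id": animal,
                "condition": condition,
                "n_scored": len(grp),
                "pct_myelinated": 100.0 * grp["_myel"].mean(),
            }
        )
    per_animal = pd.DataFrame(rows)
    summaries = []
    for condition, grp in per_animal.groupby("condition", sort=True):
        vals = grp["pct_myelinated"].to_numpy()
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
        summaries.append(
            {
                "condition": condition,
                "n_animals": len(vals),
                "mean_pct": vals.mean(),
                "sem_pct": sem,
            }
        )
    return per_animal, pd.DataFrame(summaries)


def mito_area_fraction(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mitochondrial area normalised to the compartment area.

    Returns per-object values and per-animal means (the animal is the unit
    of inference; per-object values indicate the spread).  Count, total area
    and fraction are reported separately.
    """
    rows = []
    for _, rec in profiles.iterrows():
        mitos = rec["mito_areas"]
        if isinstance(mitos, str):
            mitos = [float(x) for x in mitos.split(";") if x != ""]
        mitos = list(mitos) if mitos is not None else []
        area = float(rec["axon_area"])
        if area <= 0:
            raise ValidationError("compartment area must be positive")
        total = float(np.sum(mitos)) if mitos else 0.0
        if total >= area:
            raise ValidationError(
                f"mitochondrial area {total} exceeds compartment area {area}"
            )
        rows.append(
            {
                "axon_id": rec.get("axon_id"),
                "animal_id": rec.get("animal_id"),
                "condition": rec.get("condition"),
                "mito_count": len(mitos),
                "mito_total_area": total,
                "mito_fraction": total / area,
            }
        )
    per_object = pd.DataFrame(rows)
    per_animal = (
        per_object.groupby(["animal_id", "condition"], sort=True)[
            ["mito_count", "mito_total_area", "mito_fraction"]
        ]
        .mean()
        .reset_index()
    )
    return per_object, per_animal


def composite_score(rois: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RNAscope composite score per ROI: (fraction OLIG2⁺ cells) × (mean puncta).

    Summarised per animal, then per condition (mean ± SEM over animals).
    """
    rows = []
    for (roi, animal, condition, probe), grp in rois.groupby(
        ["roi_id", "animal_id", "condition", "probe"], sort=True
    ):
        if len(grp) == 0:
            raise ValidationError(f"ROI {roi} has no cells")
        frac = grp["olig2_positive"].astype(bool).mean()
        mean_puncta = grp["puncta"].mean()
        rows.append(
            {
                "roi_id": roi,
                "animal_id": animal,
                "condition": condition,
                "probe": probe,
                "n_cells": len(grp),
                "fraction_olig2": frac,
                "mean_puncta": mean_puncta,
                "composite_score": frac * mean_puncta,
            }
        )
    per_roi = pd.DataFrame(rows)
    per_animal = (
        per_roi.groupby(["animal_id", "condition", "probe"], sort=True)["composite_score"]
        .mean()
        .reset_index()
    )
    summaries = []
    for (condition, probe), grp in per_animal.groupby(["condition", "probe"], sort=True):
        vals = grp["composite_score"].to_numpy()
        summaries.append(
            {
                "condition": condition,
                "probe": probe,
                "n_animals": len(vals),
                "mean_score": vals.mean(),
                "sem_score": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan,
            }
        )
    return per_roi, pd.DataFrame(summaries)


def lilliefors_ks(x: np.ndarray, n_sims: int = 1000, seed: int = 0) -> tuple[float, float]:
    """KS normality statistic with parameters estimated from the data.

    The p-value comes from a seeded Monte-Carlo null of the same statistic
    on standard-normal samples of equal size (the Lilliefors correction for
    estimated mean and variance).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        # too few observations to assess normality; treat as normal
        return 0.0, 1.0
    stat = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).statistic
    rng = np.random.default_rng(seed)
    null = np.empty(n_sims)
    for i in range(n_sims):
        s = rng.standard_normal(n)
        null[i] = stats.kstest(s, "norm", args=(s.mean(), s.std(ddof=1))).statistic
    p = (1 + np.sum(null >= stat)) / (1 + n_sims)
    return float(stat), float(p)


def group_compare(
    values: pd.DataFrame,
    value_col: str,
    condition_col: str = "condition",
    cfg: MorphometryConfig | None = None,
) -> dict:
    """Two-group comparison on per-animal values.

    Both groups normal by the Lilliefors-corrected KS check → two-sided
    unpaired t-test; otherwise two-sided Mann-Whitney U.  The chosen test is
    recorded in the result.
    """
    cfg = cfg or MorphometryConfig()
    conditions = sorted(values[condition_col].unique(), key=str)
    if len(conditions) != 2:
        raise ValidationError("group comparison requires exactly two conditions")
    a = values.loc[values[condition_col] == conditions[0], value_col].to_numpy(dtype=float)
    b = values.loc[values[condition_col] == conditions[1], value_col].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each condition needs at least two animals")
    _, p_a = lilliefors_ks(a, cfg.lilliefors_sims, cfg.lilliefors_seed)
    _, p_b = lilliefors_ks(b, cfg.lilliefors_sims, cfg.lilliefors_seed + 1)
    normal = p_a > cfg.normality_alpha and p_b > cfg.normality_alpha
    if normal:
        res = stats.ttest_ind(a, b)
        test = "t-test"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann-whitney"
    return {
        "test": test,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "normality_p": (float(p_a), float(p_b)),
        "conditions": conditions,
        "means": (float(a.mean()), float(b.mean())),
    }
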