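"""Histology-derived scalar metrics.

Hemispheric lateralization ratios from nuclei-count tables (c-Fos as an
activity proxy, DAPI as a density control) and fluorescence-based
expression-localization indices.  Counts are inputs; nuclei segmentation is
out of scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = {"region", "region_class", "hemisphere", "count", "stain"}
REGION_CLASSES = {"expressing", "non-expressing"}
HEMISPHERES = {"ipsi", "contra"}


def validate_region_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a region-count table (region, region_class, hemisphere,
    count, stain); returns the table unchanged."""
    missing = REQUIRED_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (table["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    if not set(table["hemisphere"]).issubset(HEMISPHERES):
        raise ValueError(f"hemisphere must be one of {sorted(HEMISPHERES)}")
    if not set(table["region_class"]).issubset(REGION_CLASSES):
        raise ValueError(f"region_class must be one of {sorted(REGION_CLASSES)}")
    return table


def lateralization_ratio(table: pd.DataFrame, region_class: str,
                         stain: str = "cfos",
                         per_region_mean: bool = False) -> float:
    """Ipsilateral fraction of nuclei for a region class.

    ratio = sum(ipsi counts) / (sum(ipsi) + sum(contra)) over all regions of
    ``region_class`` for the given stain.  0.5 means hemispheric symmetry, 0
    means all nuclei contralateral, 1 all ipsilateral.

    ``per_region_mean=True`` averages per-region ratios instead of pooling
    counts (regions with a zero denominator are dropped).
    """
    validate_region_counts(table)
    sub = table[(table["region_class"] == region_class)
                & (table["stain"] == stain)]
    if sub.empty:
        raise ValueError(f"no rows for class {region_class!r}, stain {stain!r}")
    if per_region_mean:
        ratios = []
        for _, grp in sub.groupby("region"):
            ipsi = grp.loc[grp["hemisphere"] == "ipsi", "count"].sum()
            contra = grp.loc[grp["hemisphere"] == "contra", "count"].sum()
            if ipsi + contra > 0:
                ratios.append(ipsi / (ipsi + contra))
        if not ratios:
            return float("nan")
        return float(np.mean(ratios))
    ipsi = sub.loc[sub["hemisphere"] == "ipsi", "count"].sum()
    contra = sub.loc[sub["hemisphere"] == "contra", "count"].sum()
    if ipsi + contra == 0:
        return float("nan")
    return float(ipsi / (ipsi + contra))


def dapi_cr_er_ratio(table: pd.DataFrame) -> dict:
    """Lateralization ratios of DAPI nuclei for control (non-expressing)
    vs expressing ipsilateral regions.

    Applies the same ipsi/(ipsi+contra) normalization to DAPI counts per
    region class; equal nuclear density across hemispheres gives ~0.5 for
    both classes.  Returns {'CR': ratio_non_expressing, 'ER': ratio_expressing}.
    """
    return {
        "CR": lateralization_ratio(table, "non-expressing", stain="dapi"),
        "ER": lateralization_ratio(table, "expressing", stain="dapi"),
    }


def layer1_restriction_index(layer1_values, center_values) -> float:
    """Soma-restriction index: mean layer-1 fluorescence normalized by the
    mean fluorescence at the injection center.  Lower values indicate
    stronger restriction of expression to somata (less neuropil signal in
    layer 1)."""
    l1 = np.asarray(layer1_values, dtype=float)
    ctr = np.asarray(center_values, dtype=float)
    if l1.size == 0 or ctr.size == 0:
        raise ValueError("empty input")
    center_mean = ctr.mean()
    if center_mean <= 0:
        return float("nan")
    return float(l1.mean() / center_mean)


def normalize_to_reference(values, reference_mean: float) -> np.ndarray:
    """Express values as fold change over a reference group mean."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return np.asarray(values, dtype=float) / reference_mean
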