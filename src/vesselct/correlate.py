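"""Volume normalization and the HU–collagen Pearson correlation.

Across samples, stain uptake varies with tissue volume (a fixed stain bath is
diluted over more tissue), which masks the HU–collagen association.  The
study's correction divides each sample's tissue volume by the cohort's
smallest tissue volume to obtain a normalizing ratio (>= 1, exactly 1 for the
smallest sample) and multiplies the mean HU by that ratio.  Pearson's r
between (normalized) HU and the histological collagen content is then the
headline statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DataError,
    DegenerateDataError,
    PairingError,
    SampleSizeError,
)

__all__ = [
    "SampleRecord",
    "CorrelationResult",
    "CohortAnalysis",
    "volume_normalize",
    "pearson",
    "run_cohort_analysis",
]


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample (or per sample-region) derived quantities.

    ``normalizing_ratio`` and ``normalized_hu`` are filled in by
    :func:`volume_normalize`; ``region_tag`` distinguishes internal/external
    media observations when pooling at region level.
    """

    sample_id: str
    tissue_volume_mm3: float
    mean_hu: float
    collagen_content: float
    region_tag: str | None = None
    normalizing_ratio: float | None = None
    normalized_hu: float | None = None


def volume_normalize(records: Sequence[SampleRecord]) -> list[SampleRecord]:
    """Fill in each record's normalizing ratio and volume-normalized HU.

    ``ratio_i = volume_i / min_j volume_j`` and
    ``normalized_hu_i = mean_hu_i * ratio_i``; the smallest-volume record's
    HU is left exactly unchanged.  Input order is preserved.
    """
    if not records:
        raise DataError("no records to normalize")
    for rec in records:
        if not rec.tissue_volume_mm3 > 0:
            raise DataError(
                f"sample {rec.sample_id!r} has non-positive tissue volume "
                f"{rec.tissue_volume_mm3}"
            )
    min_vol = min(rec.tissue_volume_mm3 for rec in records)
    out = []
    for rec in records:
        ratio = rec.tissue_volume_mm3 / min_vol
        out.append(replace(rec, normalizing_ratio=ratio, normalized_hu=rec.mean_hu * ratio))
    return out


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its two-sided p-value (t-transform, n-2 df)."""

    r: float
    n: int
    p_value: float
    variant: str = "raw_hu"


def pearson(x: Sequence[float], y: Sequence[float], variant: str = "raw_hu") -> CorrelationResult:
    """Pearson correlation between two equal-length samples (n >= 3).

    r = sample covariance / (sd_x * sd_y); the two-sided p-value comes from
    the t-transform with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1D sequences of equal length")
    n = x.size
    if n < 3:
        raise SampleSizeError(f"Pearson correlation needs n >= 3, got n = {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in x or y; correlation undefined")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=n, p_value=float(res.pvalue), variant=variant)


@dataclass
class CohortAnalysis:
    """Cohort-level outputs: raw and normalized correlations plus audit tables."""

    raw: CorrelationResult
    normalized: CorrelationResult
    records: pd.DataFrame
    region_contrast: pd.DataFrame

    @property
    def summary(self) -> dict:
        return {
            "r_raw": self.raw.r,
            "p_raw": self.raw.p_value,
            "r_normalized": self.normalized.r,
            "p_normalized": self.normalized.p_value,
            "n": self.raw.n,
        }


def run_cohort_analysis(
    ct_records: pd.DataFrame,
    histo_records: pd.DataFrame,
    level: str = "region",
) -> CohortAnalysis:
    """Pair CT and histology records and compute raw and volume-normalized
    HU–collagen Pearson correlations.

    ``ct_records`` needs columns ``sample_id, region_tag, mean_hu,
    tissue_volume_mm3``; ``histo_records`` needs ``sample_id, region_tag,
    collagen_content``.  ``level="region"`` (default) pools internal/external
    observations per sample; ``level="sample"`` averages regions first.
    Also returns the per-sample internal-vs-external mean-HU contrast table.
    """
    required_ct = {"sample_id", "region_tag", "mean_hu", "tissue_volume_mm3"}
    required_h = {"sample_id", "region_tag", "collagen_content"}
    if not required_ct <= set(ct_records.columns):
        raise DataError(f"ct_records missing columns {required_ct - set(ct_records.columns)}")
    if not required_h <= set(histo_records.columns):
        raise DataError(f"histo_records missing columns {required_h - set(histo_records.columns)}")
    if level not in ("region", "sample"):
        raise DataError(f"level must be 'region' or 'sample', got {level!r}")

    keys = ["sample_id", "region_tag"]
    merged = ct_records.merge(
        histo_records[["sample_id", "region_tag", "collagen_content"]],
        on=keys, how="outer", indicator=True,
    )
    orphans = merged[merged["_merge"] != "both"]
    if len(orphans):
        missing = [
            f"{row['sample_id']}/{row['region_tag']} "
            f"({'no histology' if row['_merge'] == 'left_only' else 'no CT'})"
            for _, row in orphans.iterrows()
        ]
        raise PairingError("unpaired observations: " + ", ".join(missing))
    merged = merged.drop(columns="_merge")

    if level == "sample":
        merged = (
            merged.groupby("sample_id", as_index=False)
            .agg(
                mean_hu=("mean_hu", "mean"),
                tissue_volume_mm3=("tissue_volume_mm3", "first"),
                collagen_content=("collagen_content", "mean"),
            )
            .assign(region_tag=None)
        )

    records = [
        SampleRecord(
            sample_id=row.sample_id,
            tissue_volume_mm3=float(row.tissue_volume_mm3),
            mean_hu=float(row.mean_hu),
            collagen_content=float(row.collagen_content),
            region_tag=getattr(row, "region_tag", None),
        )
        for row in merged.itertuples()
    ]
    records = volume_normalize(records)
    table = pd.DataFrame([r.__dict__ for r in records])

    raw = pearson(table["mean_hu"], table["collagen_content"], variant="raw_hu")
    normalized = pearson(
        table["normalized_hu"], table["collagen_content"], variant="volume_normalized"
    )

    contrast = (
        ct_records.pivot_table(index="sample_id", columns="region_tag", values="mean_hu")
        if ct_records["region_tag"].notna().any()
        else pd.DataFrame()
    )
    if {"internal_media", "external_media"} <= set(contrast.columns):
        contrast = contrast.assign(
            external_minus_internal=contrast["external_media"] - contrast["internal_media"]
        )
    return CohortAnalysis(raw=raw, normalized=normalized, records=table, region_contrast=contrast)
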