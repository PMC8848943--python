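"""MS1 feature quality-control filters.

Three filters trim an aligned feature table before precursor selection:

1. retention-time range trimming (drop void volume and column wash),
2. blank fold-change filtering (study mean must exceed ``fold`` times the
   matrix-blank mean; background/contaminant removal),
3. relative-standard-deviation filtering across study replicates
   (irreproducible features are poor MS/MS targets).

Boundary semantics follow strict-violator removal: a feature at exactly
the fold-change or RSD threshold is retained. RSD uses the sample (n-1)
standard deviation. Fold change compares pooled arithmetic means; a
feature absent from all blanks (blank mean 0) is always retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import FeatureTable


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the three QC filters.

    rt_min/rt_max : seconds, inclusive retention-time window (default 30-930).
    fold : minimum study/blank mean intensity ratio (default 3).
    rsd_max : maximum relative standard deviation over study samples,
        as a fraction (default 0.30).
    """

    rt_min: float = 30.0
    rt_max: float = 930.0
    fold: float = 3.0
    rsd_max: float = 0.30

    def __post_init__(self) -> None:
        if not self.rt_min < self.rt_max:
            raise ValueError("rt_min must be < rt_max")
        if self.fold <= 0:
            raise ValueError("fold must be positive")
        if not 0 < self.rsd_max < 1:
            raise ValueError("rsd_max must lie in (0, 1)")


def trim_rt_range(table: FeatureTable, cfg: FilterConfig = FilterConfig()) -> FeatureTable:
    """Keep features with rt_min <= RT <= rt_max (boundaries inclusive)."""
    mask = (table.rt >= cfg.rt_min) & (table.rt <= cfg.rt_max)
    return table.subset(mask)


def blank_fold_change_filter(
    table: FeatureTable, cfg: FilterConfig = FilterConfig()
) -> FeatureTable:
    """Keep features whose study mean is >= fold x pooled blank mean.

    Features with zero blank mean are retained without forming a ratio.
    """
    if table.blank_indices.size == 0:
        raise ValueError(
            "table has no blank samples; skip the fold-change filter explicitly "
            "instead of calling it"
        )
    if table.study_indices.size == 0:
        raise ValueError("table has no study samples")
    study_mean = table.mean_study_intensity()
    blank_mean = table.blank_intensities().mean(axis=1)
    threshold = cfg.fold * blank_mean
    # boundary (ratio exactly `fold`) is retained; guard float round-off
    mask = (blank_mean == 0) | (study_mean >= threshold) | np.isclose(study_mean, threshold, rtol=1e-9)
    return table.subset(mask)


def rsd_filter(table: FeatureTable, cfg: FilterConfig = FilterConfig()) -> FeatureTable:
    """Keep features with study-sample RSD (sd/mean, ddof=1) <= rsd_max.

    Features with zero study mean are removed (RSD undefined, and a feature
    absent from every study sample is not a usable precursor).
    """
    if table.study_indices.size < 2:
        raise ValueError("RSD filter needs at least 2 study samples")
    study = table.study_intensities()
    mean = study.mean(axis=1)
    sd = study.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(mean > 0, sd / mean, np.inf)
    # boundary (RSD exactly rsd_max) is retained; guard float round-off
    keep = (rsd <= cfg.rsd_max) | np.isclose(rsd, cfg.rsd_max, rtol=1e-9)
    return table.subset(keep)


def apply_qc_filters(
    table: FeatureTable,
    cfg: FilterConfig = FilterConfig(),
    use_blank_filter: bool | None = None,
) -> FeatureTable:
    """Run RT trim, blank fold-change filter and RSD filter in sequence.

    ``use_blank_filter=None`` applies the fold-change filter only when the
    table actually has blank samples; ``True`` requires them.
    """
    out = trim_rt_range(table, cfg)
    has_blanks = out.blank_indices.size > 0
    if use_blank_filter is None:
        use_blank_filter = has_blanks
    if use_blank_filter:
        out = blank_fold_change_filter(out, cfg)
    out = rsd_filter(out, cfg)
    return out
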