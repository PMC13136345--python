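"""Regional and extreme climate-response statistics.

Covers the reporting layer of the analysis chain: the TXx extreme index
(annual maximum of daily maximum 2 m temperature), paired scenario-vs-
reference significance by the two-sided Wilcoxon signed-rank test over years
(pairing removes year-to-year variability shared through common boundary
conditions), unpaired future-vs-recent comparison by the two-sided
Mann–Whitney U test, Benjamini–Hochberg false-discovery-rate control across
cells, top-1% focus masks and PFT-perturbation bins, and significant-area
shares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MaskSet",
    "txx",
    "paired_scenario_test",
    "unpaired_change_test",
    "adjust_fdr",
    "masks_and_bins",
    "significant_area_share",
    "regional_summary",
]

#: PFT-perturbation bin edges (fraction of cell area changed); right-open
#: except the last bin, which includes 1.
BIN_EDGES = (0.0, 0.1, 0.3, 0.5, 1.0)
BIN_LABELS = ("0-10%", "10-30%", "30-50%", "50-100%")


def txx(daily_tmax: np.ndarray) -> np.ndarray:
    """Annual maximum of daily maximum temperature per cell and year.

    ``daily_tmax`` has shape (year, day, ...); missing days may be NaN and
    are skipped (the maximum is over available days).
    """
    arr = np.asarray(daily_tmax, dtype=float)
    if arr.ndim < 2 or arr.shape[1] < 1:
        raise ValueError("need a (year, day, ...) array with >= 1 day")
    if np.isnan(arr).all(axis=1).any():
        raise ValueError("a year with no available days has no annual maximum")
    return np.nanmax(arr, axis=1)


def paired_scenario_test(
    field_scen: np.ndarray, field_ref: np.ndarray
) -> np.ndarray:
    """Two-sided Wilcoxon signed-rank p-value per cell over paired years.

    Both fields are (year, ...) on the same years. Cells whose paired
    differences are all exactly tied (zero) have no defined p-value and are
    returned as NaN (treated as not significant downstream).
    """
    scen = np.asarray(field_scen, dtype=float)
    ref = np.asarray(field_ref, dtype=float)
    if scen.shape != ref.shape:
        raise ValueError("scenario and reference must share shape (year, ...)")
    diff = (scen - ref).reshape(scen.shape[0], -1)
    all_tied = (diff == 0).all(axis=0)
    p = np.full(diff.shape[1], np.nan)
    active = ~all_tied
    if active.any():
        # exact null distribution for the short yearly samples typical here
        # (handles tied magnitudes); fall back to the approximation beyond
        method = "exact" if diff.shape[0] <= 25 else "auto"
        res = sps.wilcoxon(
            diff[:, active], axis=0, alternative="two-sided", method=method
        )
        p[active] = res.pvalue
    return p.reshape(scen.shape[1:])


def unpaired_change_test(
    field_future: np.ndarray, field_recent: np.ndarray
) -> np.ndarray:
    """Two-sided Mann–Whitney U p-value per cell between two year samples."""
    fut = np.asarray(field_future, dtype=float)
    rec = np.asarray(field_recent, dtype=float)
    if fut.shape[0] < 2 or rec.shape[0] < 2:
        raise ValueError("need >= 2 years per sample")
    res = sps.mannwhitneyu(fut, rec, axis=0, alternative="two-sided")
    return np.asarray(res.pvalue, dtype=float)


def adjust_fdr(p_grid: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment over one family of tests.

    The family is all finite p-values in the grid (one call per
    variable × season × scenario). NaN entries stay NaN.
    """
    p = np.asarray(p_grid, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    if finite.any():
        out[finite] = multipletests(p[finite].ravel(), method="fdr_bh")[1]
    return out


@dataclass
class MaskSet:
    """Focus masks and perturbation bins derived from PFT change."""

    most_affected: np.ndarray  # top 1% by PFT change fraction
    most_extreme_reference: np.ndarray  # top 1% of a reference variable
    most_changing: np.ndarray  # top 1% of reference-minus-recent change
    bins: np.ndarray  # int grid, index into BIN_LABELS

    def bin_mask(self, label: str) -> np.ndarray:
        return self.bins == BIN_LABELS.index(label)


def top_percent_mask(field: np.ndarray, percent: float = 1.0) -> np.ndarray:
    """Boolean mask of the ⌈percent%⌉ largest cells; ties break by cell index."""
    flat = np.asarray(field, dtype=float).ravel()
    k = int(np.ceil(percent / 100.0 * flat.size))
    order = np.argsort(-flat, kind="stable")  # stable: ties in index order
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(np.asarray(field).shape)


def pft_change_fraction(pft_ref: np.ndarray, pft_scen: np.ndarray) -> np.ndarray:
    """Per-cell fraction of area with changed PFT cover, Σ|ΔPFT|/2."""
    return np.abs(np.asarray(pft_scen) - np.asarray(pft_ref)).sum(axis=0) / 2.0


def masks_and_bins(
    change_fraction: np.ndarray,
    reference_extreme: np.ndarray,
    reference_minus_recent: np.ndarray,
) -> MaskSet:
    """Build the three top-1% focus masks and the perturbation bins.

    Bins follow {0–10, 10–30, 30–50, 50–100}% of cell area changed,
    right-open except the last.
    """
    cf = np.asarray(change_fraction, dtype=float)
    if np.any(cf < 0) or np.any(cf > 1):
        raise ValueError("change fraction must lie in [0, 1]")
    bins = np.digitize(cf, BIN_EDGES[1:-1], right=False)  # 0..3
    return MaskSet(
        most_affected=top_percent_mask(cf),
        most_extreme_reference=top_percent_mask(reference_extreme),
        most_changing=top_percent_mask(np.asarray(reference_minus_recent)),
        bins=bins,
    )


def significant_area_share(
    adjusted_p: np.ndarray,
    alpha: float = 0.05,
    region_mask: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """Area-weighted percentage of the region with adjusted p < alpha.

    NaN p-values (undefined tests) count as not significant.
    """
    p = np.asarray(adjusted_p, dtype=float)
    mask = np.ones(p.shape, dtype=bool) if region_mask is None else np.asarray(region_mask, dtype=bool)
    w = np.ones(p.shape) if weights is None else np.asarray(weights, dtype=float)
    w = np.where(mask, w, 0.0)
    sig = np.where(np.isfinite(p), p < alpha, False)
    return float(100.0 * (w * sig).sum() / w.sum())


def regional_summary(
    diff_by_year: dict[str, np.ndarray],
    region_masks: dict[str, np.ndarray],
    adjusted_p: dict[str, np.ndarray] | None = None,
    alpha: float = 0.05,
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tabulate regional mean responses ± interannual standard deviation.

    ``diff_by_year`` maps variable name → (year, ny, nx) response field;
    ``adjusted_p`` optionally maps variable name → adjusted p grid, from
    which the regional significant-area share is reported.
    """
    rows = []
    for region, mask in region_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"empty region {region!r}")
        w = np.ones(mask.shape) if weights is None else np.asarray(weights, dtype=float)
        w = np.where(mask, w, 0.0)
        w = w / w.sum()
        for var, field in diff_by_year.items():
            field = np.asarray(field, dtype=float)
            yearly = np.tensordot(field, w, axes=((1, 2), (0, 1)))
            row = {
                "region": region,
                "variable": var,
                "mean": float(yearly.mean()),
                "interannual_sd": float(yearly.std(ddof=1)),
            }
            if adjusted_p is not None and var in adjusted_p:
                row["significant_area_pct"] = significant_area_share(
                    adjusted_p[var], alpha=alpha, region_mask=mask, weights=weights
                )
            rows.append(row)
    return pd.DataFrame(rows)
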