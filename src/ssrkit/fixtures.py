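"""Bundled reference marker panel and its summary statistics.

Two small TSV fixtures ship with the package: the 34-marker panel
(primer sequences, motifs, observed size ranges, annealing
temperatures) and the per-marker diversity table (allele counts, Ho,
gene diversity, PIC) estimated on the original 70-accession panel.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd
from scipy import stats

__all__ = [
    "load_marker_panel",
    "load_marker_diversity",
    "round_half_up",
    "marker_table_summaries",
    "REFERENCE_SUMMARIES",
]

EXPECTED_ROWS = 34

#: Published reference values for the bundled diversity table.
REFERENCE_SUMMARIES = {
    "total_alleles": 202,
    "mean_na": 5.94,
    "mean_ho": 0.55,
    "mean_gd": 0.59,
    "mean_pic": 0.54,
    "n_pic_gt_0.5": 26,
    "min_na": 2,
    "max_na": 12,
    "r_na_gd": 0.55,
    "r_na_pic": 0.64,
}


def _load(name: str) -> pd.DataFrame:
    with resources.files("ssrkit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_marker_panel() -> pd.DataFrame:
    """34-row marker panel: marker, forward, reverse, motif, repeats,
    size_range, ta."""
    df = _load("marker_panel.tsv")
    if len(df) != EXPECTED_ROWS:
        raise ValueError(f"marker panel must have {EXPECTED_ROWS} rows")
    return df


def load_marker_diversity() -> pd.DataFrame:
    """34-row diversity table: marker, n_alleles, ho, gd, pic."""
    df = _load("marker_diversity.tsv")
    if len(df) != EXPECTED_ROWS:
        raise ValueError(f"diversity table must have {EXPECTED_ROWS} rows")
    return df


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (matches how printed tables round)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def marker_table_summaries(df: pd.DataFrame | None = None) -> dict:
    """Column summaries of the diversity table.

    Totals and means of the allele-count / Ho / GD / PIC columns, the
    count of markers with PIC > 0.5, the Na range, and Pearson
    correlations of Na with GD and PIC.
    """
    if df is None:
        df = load_marker_diversity()
    if len(df) != EXPECTED_ROWS:
        raise ValueError(f"expected {EXPECTED_ROWS} rows, got {len(df)}")
    na = df["n_alleles"].to_numpy(dtype=float)
    r_gd, p_gd = stats.pearsonr(na, df["gd"])
    r_pic, p_pic = stats.pearsonr(na, df["pic"])
    return {
        "total_alleles": int(df["n_alleles"].sum()),
        "mean_na": round_half_up(float(df["n_alleles"].mean())),
        "mean_ho": round_half_up(float(df["ho"].mean())),
        "mean_gd": round_half_up(float(df["gd"].mean())),
        "mean_pic": round_half_up(float(df["pic"].mean())),
        "n_pic_gt_0.5": int((df["pic"] > 0.5).sum()),
        "min_na": int(df["n_alleles"].min()),
        "max_na": int(df["n_alleles"].max()),
        "r_na_gd": round_half_up(float(r_gd)),
        "r_na_pic": round_half_up(float(r_pic)),
        "p_na_gd": float(p_gd),
        "p_na_pic": float(p_pic),
    }
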