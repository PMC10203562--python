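"""Developability flagging and rank-sum aggregation.

In-silico protein descriptors of candidate antibodies are compared
against a reference panel of approved therapeutic antibodies: a
descriptor is *flagged* when the candidate's value strictly exceeds the
panel mean plus one standard deviation (high values are liabilities by
default).  Measured assay panels are aggregated by direction-aware
ranking: each assay ranks the variants (rank 1 = best, average ranks on
ties) and the per-variant rank sum orders the candidates overall, lower
being better.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CutoffSet",
    "DEFAULT_ASSAY_DIRECTIONS",
    "compute_cutoffs",
    "count_flags",
    "overall_ranking",
    "spearman_correlation",
    "flags_vs_ranking",
]

logger = logging.getLogger(__name__)

#: better-direction per assay: "lower" = smaller value is better
DEFAULT_ASSAY_DIRECTIONS: dict[str, str] = {
    "acsins_nm": "lower",
    "polyreactivity": "lower",
    "pdi": "lower",
    "hic_rt_min": "lower",
    "tm_c": "higher",
}


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class CutoffSet:
    """Per-descriptor liability cutoffs c_d = mu_d + sigma_d of a reference panel."""

    table: pd.DataFrame  # index: descriptor; columns: mean, sd, cutoff
    sd_mode: Literal["sample", "population"] = "sample"

    @property
    def descriptors(self) -> list[str]:
        return list(self.table.index)


def compute_cutoffs(
    reference: pd.DataFrame, sd_mode: Literal["sample", "population"] = "sample"
) -> CutoffSet:
    """Cutoffs (mean + SD per descriptor) from a reference antibody panel.

    Sample (n-1) standard deviation by default.  A constant descriptor
    yields sigma = 0 and cutoff = mean, with a warning.
    """
    if len(reference) < 2:
        raise ValueError("need at least 2 reference antibodies")
    if reference.isna().any().any():
        raise ValueError("reference panel must have no missing values")
    ddof = 1 if sd_mode == "sample" else 0
    if sd_mode not in ("sample", "population"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    mean = reference.mean(axis=0)
    sd = reference.std(axis=0, ddof=ddof)
    constant = sd.index[sd == 0.0]
    if len(constant):
        logger.warning(
            "constant reference descriptors (cutoff = mean): %s", list(constant)
        )
    table = pd.DataFrame({"mean": mean, "sd": sd, "cutoff": mean + sd})
    table.index.name = "descriptor"
    return CutoffSet(table=table, sd_mode=sd_mode)


def count_flags(variants: pd.DataFrame, cutoffs: CutoffSet) -> pd.Series:
    """Flags per variant: descriptors whose value strictly exceeds the cutoff.

    Equality with the cutoff is not flagged.  Every variant column must
    have a cutoff.
    """
    unknown = set(variants.columns) - set(cutoffs.descriptors)
    if unknown:
        raise SchemaError(f"descriptors without cutoffs: {sorted(unknown)}")
    cut = cutoffs.table["cutoff"].reindex(variants.columns)
    flags = variants.gt(cut, axis=1)
    return flags.sum(axis=1).rename("n_flags")


def flagged_descriptors(variants: pd.DataFrame, cutoffs: CutoffSet) -> pd.Series:
    """Comma-joined names of the flagged descriptors per variant."""
    unknown = set(variants.columns) - set(cutoffs.descriptors)
    if unknown:
        raise SchemaError(f"descriptors without cutoffs: {sorted(unknown)}")
    cut = cutoffs.table["cutoff"].reindex(variants.columns)
    flags = variants.gt(cut, axis=1)
    return flags.apply(
        lambda row: ",".join(variants.columns[row.to_numpy()]), axis=1
    ).rename("flagged")


def overall_ranking(
    panel: pd.DataFrame, directions: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Direction-aware per-assay ranks and their sum, sorted best first.

    Rank 1 is the best value of an assay according to its declared
    direction ("lower" or "higher" is better); ties receive average ranks.
    Variants with any missing assay value are excluded with a warning.
    Returns per-assay rank columns plus `rank_sum`, ascending (lower =
    better overall).
    """
    if directions is None:
        directions = DEFAULT_ASSAY_DIRECTIONS
    if len(panel) < 2:
        raise ValueError("need at least 2 variants to rank")
    missing_dir = set(panel.columns) - set(directions)
    if missing_dir:
        raise SchemaError(f"assays without a declared direction: {sorted(missing_dir)}")
    incomplete = panel.index[panel.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"variants excluded for missing assay values: {list(incomplete)}",
            stacklevel=2,
        )
        panel = panel.drop(index=incomplete)
    ranks = pd.DataFrame(index=panel.index)
    for assay in panel.columns:
        ascending = directions[assay] == "lower"
        ranks[f"rank_{assay}"] = panel[assay].rank(
            ascending=ascending, method="average"
        )
    ranks["rank_sum"] = ranks.sum(axis=1)
    return ranks.sort_values("rank_sum")


def spearman_correlation(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rho and two-sided p (t approximation).

    rho is the Pearson correlation of average ranks; a constant input
    yields (nan, nan) — correlation undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs differ in length")
    if len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return (float("nan"), float("nan"))
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def flags_vs_ranking(
    flags: Mapping[str, float] | pd.Series, rank_sums: Mapping[str, float] | pd.Series
) -> dict:
    """Association between descriptor flag counts and assay rank sums.

    Primary statistic: tie-corrected Spearman correlation over the common
    variants.  Secondary: a Wilcoxon-Mann-Whitney rank-sum test comparing
    the ranking scores of variants above vs at-or-below the median flag
    count.  Both are labelled in the returned report.
    """
    flags = pd.Series(flags, dtype=float)
    rank_sums = pd.Series(rank_sums, dtype=float)
    common = flags.index.intersection(rank_sums.index)
    if len(common) < 4:
        raise ValueError("need at least 4 variants in common")
    f = flags.loc[common]
    r = rank_sums.loc[common]
    rho, p = spearman_correlation(f.to_numpy(), r.to_numpy())
    report = {
        "n": int(len(common)),
        "primary": {"statistic": "spearman_rho", "rho": rho, "p": p},
    }
    median = float(f.median())
    hi = r[f > median]
    lo = r[f <= median]
    if len(hi) and len(lo):
        mw = stats.mannwhitneyu(hi, lo, alternative="two-sided")
        report["secondary"] = {
            "statistic": "median_split_rank_sum_test",
            "median_flag_count": median,
            "n_high": int(len(hi)),
            "n_low": int(len(lo)),
            "U": float(mw.statistic),
            "p": float(mw.pvalue),
        }
    else:
        report["secondary"] = {
            "statistic": "median_split_rank_sum_test",
            "median_flag_count": median,
            "error": "median split produced an empty group",
        }
    return report
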