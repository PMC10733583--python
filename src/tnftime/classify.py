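"""Rule-based classification of genes as TNF-regulated.

A gene counts as TNF-upregulated when (1) its control expression is stable
over time (CV of per-time-point mean TPM < 0.3), (2) its treated
expression varies over time (CV > 0.3), (3) the maximal log2 fold change
of the treated profile against the treated initial time point exceeds 0.7,
and it is differentially expressed at two or more sequential time points
with a consistent direction. Downregulation mirrors this, except that the
peak-fold-change criterion is |log2 FC| > 0.7 against the time-matched
control (the asymmetry between the two peak criteria is deliberate and
kept). Genes failing a criterion receive a specific exclusion label so
that every analyzed gene carries exactly one label with full per-criterion
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import TREATED
from .preprocess import per_time_means

LABELS = (
    "upregulated",
    "downregulated",
    "excluded_control_variable",
    "excluded_low_peak_fc",
    "excluded_inconsistent_direction",
    "excluded_not_sequential",
    "excluded_low_expression",
    "not_regulated",
)


@dataclass
class ClassifyThresholds:
    """Classification thresholds (strict inequalities at the boundary)."""

    cv_stable: float = 0.3  # control CV must be < this
    cv_variable: float = 0.3  # treated CV must be > this
    peak_lfc: float = 0.7  # peak log2 FC must exceed this
    min_run: int = 2  # DEG at >= this many sequential time points


def check_sequential(deg_flags: Sequence[str], min_run: int = 2) -> tuple[bool, int]:
    """Whether any ``min_run`` consecutive grid positions share a DEG sign.

    Returns (passes, longest same-sign consecutive run).
    """
    longest = 0
    run = 0
    prev = "none"
    for flag in deg_flags:
        if flag != "none" and flag == prev:
            run += 1
        elif flag != "none":
            run = 1
        else:
            run = 0
        prev = flag
        longest = max(longest, run)
    return longest >= min_run, longest


def check_direction_consistency(deg_flags: Sequence[str]) -> bool:
    """False iff both up and down flags occur across the time course."""
    present = set(deg_flags) - {"none"}
    return not ({"up", "down"} <= present)


def _classify_one(
    cv_control: float,
    cv_treated: float,
    peak_up: float,
    peak_abs_vs_control: float,
    deg_flags: Sequence[str],
    expressed: bool,
    thresholds: ClassifyThresholds,
) -> tuple[str, bool, int, str]:
    """Label one gene; returns (label, direction_consistent, run, direction)."""
    present = set(deg_flags) - {"none"}
    consistent = check_direction_consistency(deg_flags)
    sequential, longest = check_sequential(deg_flags, thresholds.min_run)
    direction = "".join(sorted(present)) if present else ""
    if not expressed:
        return "excluded_low_expression", consistent, longest, direction
    if not present:
        return "not_regulated", consistent, longest, direction
    if not consistent:
        return "excluded_inconsistent_direction", consistent, longest, direction
    if not sequential:
        return "excluded_not_sequential", consistent, longest, direction
    # CV pattern: stable control, variable treated. NaN CV (mean <= 0)
    # fails the stability criterion.
    cv_ok = (
        np.isfinite(cv_control)
        and cv_control < thresholds.cv_stable
        and np.isfinite(cv_treated)
        and cv_treated > thresholds.cv_variable
    )
    if not cv_ok:
        return "excluded_control_variable", consistent, longest, direction
    if direction == "up":
        if peak_up > thresholds.peak_lfc:
            return "upregulated", consistent, longest, direction
        return "excluded_low_peak_fc", consistent, longest, direction
    if peak_abs_vs_control > thresholds.peak_lfc:
        return "downregulated", consistent, longest, direction
    return "excluded_low_peak_fc", consistent, longest, direction


def peak_log2fc_vs_t0(
    tpm_values: pd.DataFrame,
    samples: pd.DataFrame,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Max over time of log2(treated mean at t / treated mean at t0).

    The treated profile's own first time point is the baseline; per-time
    means are over pools.
    """
    treated = per_time_means(tpm_values, samples, TREATED)
    t0 = treated.columns[0]
    ratio = np.log2(
        (treated + pseudocount).div(treated[t0] + pseudocount, axis=0)
    )
    return ratio.max(axis=1).rename("peak_log2fc_vs_t0")


def classify_regulation(
    cv: pd.DataFrame,
    deg: pd.DataFrame,
    log2fc: pd.DataFrame,
    peak_vs_t0: pd.Series,
    expressed: pd.Series,
    thresholds: ClassifyThresholds | None = None,
) -> pd.DataFrame:
    """Classify every gene; returns labels plus per-criterion evidence.

    Parameters are per-sex-group inputs: ``cv`` (cv_control / cv_treated),
    the DE stage's per-time DEG flags and log2 fold changes, the peak
    treated-vs-t0 fold change, and the expression-filter mask. Genes absent
    from the DE tables (e.g. removed by the total-count filter) are treated
    as having no DEG evidence.
    """
    thresholds = thresholds or ClassifyThresholds()
    genes = cv.index
    deg = deg.reindex(genes).fillna("none")
    log2fc = log2fc.reindex(genes)
    peak_abs = log2fc.abs().max(axis=1).fillna(0.0)
    peak_vs_t0 = peak_vs_t0.reindex(genes)
    expressed = expressed.reindex(genes).fillna(False)

    rows = []
    deg_arr = deg.to_numpy()
    for i, g in enumerate(genes):
        label, consistent, longest, direction = _classify_one(
            cv["cv_control"].iloc[i],
            cv["cv_treated"].iloc[i],
            peak_vs_t0.iloc[i],
            peak_abs.iloc[i],
            deg_arr[i],
            bool(expressed.iloc[i]),
            thresholds,
        )
        rows.append((label, consistent, longest, direction))
    out = pd.DataFrame(
        rows,
        index=genes,
        columns=["label", "direction_consistent", "longest_deg_run", "direction_set"],
    )
    out["cv_control"] = cv["cv_control"]
    out["cv_treated"] = cv["cv_treated"]
    out["peak_log2fc_vs_t0"] = peak_vs_t0
    out["peak_abs_log2fc_vs_control"] = peak_abs
    return out


def merge_sex_calls(calls_by_group: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Combine per-sex-group regulation calls into both/one-sex/neither.

    Expects exactly the groups "F" and "M" with identical gene universes.
    ``merged_class`` is one of both / female_only / male_only / neither for
    membership in the regulated classes; ``conflict`` marks genes called
    up in one sex and down in the other.
    """
    if set(calls_by_group) != {"F", "M"}:
        raise ValueError(f"expected groups F and M, got {sorted(calls_by_group)}")
    f, m = calls_by_group["F"], calls_by_group["M"]
    if not f.index.equals(m.index):
        raise ValueError("gene universes differ between sex groups")
    regulated = {"upregulated", "downregulated"}
    f_reg = f["label"].isin(regulated)
    m_reg = m["label"].isin(regulated)
    merged = np.select(
        [f_reg & m_reg, f_reg & ~m_reg, ~f_reg & m_reg],
        ["both", "female_only", "male_only"],
        default="neither",
    )
    conflict = (
        f_reg
        & m_reg
        & (f["label"] != m["label"])
    )
    direction = np.select(
        [
            f_reg & (f["label"] == "upregulated"),
            f_reg & (f["label"] == "downregulated"),
            m_reg & (m["label"] == "upregulated"),
            m_reg & (m["label"] == "downregulated"),
        ],
        ["up", "down", "up", "down"],
        default="",
    )
    return pd.DataFrame(
        {
            "label_F": f["label"],
            "label_M": m["label"],
            "merged_class": merged,
            "direction": direction,
            "conflict": conflict,
        },
        index=f.index,
    )
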