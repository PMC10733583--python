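"""Between-sex comparisons: baseline differential expression and the
sex-specific-regulation concordance check.

Baseline sex DE fits, per time point, an NB GLM of the control
(unstimulated) samples on a sex factor and LRT-tests it against the
intercept-only model; a gene is flagged as baseline sex-DE when it passes
|log2FC| > 1 and adjusted p < 0.05 at every time point of the grid.

The concordance check asks whether any gene is regulated by treatment in
one sex only: a pool-level treated/control log2 ratio must exceed 1 in
magnitude for at least one sample of one sex while staying below 0.1375
(fold change 1.1) in magnitude for every sample of the other sex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .datasets import CONTROL, TREATED, CountDataset
from .diffexpr import _fit_llf, bh_adjust, estimate_dispersion
from .preprocess import estimate_size_factors, normalize_counts

logger = logging.getLogger(__name__)


@dataclass
class SexBaselineResult:
    """Per-time-point female-vs-male fold changes and adjusted p-values.

    ``log2fc`` and ``padj`` are genes x time; ``de_all_timepoints`` is True
    only for genes passing both thresholds at every time point.
    """

    log2fc: pd.DataFrame
    padj: pd.DataFrame
    de_all_timepoints: pd.Series


def baseline_sex_de(
    dataset: CountDataset,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    pseudocount: float = 0.5,
    min_total_counts: int = 10,
) -> SexBaselineResult:
    """Sex-factor NB GLM on control samples, per time point."""
    controls = dataset.subset_samples(
        (dataset.samples["condition"] == CONTROL).to_numpy()
    )
    samples = controls.samples
    times = np.sort(samples["time_h"].unique())
    for t in times:
        present = set(samples.loc[samples["time_h"] == t, "sex"])
        if present != {"F", "M"}:
            raise ValueError(f"both sexes required at every time point; {t} h has {sorted(present)}")
    counts = controls.counts
    counts = counts[counts.sum(axis=1) >= min_total_counts]
    size_factors = estimate_size_factors(counts)
    # dispersion cells = sex x time on controls
    disp_samples = samples.copy()
    disp_samples["condition"] = disp_samples["sex"].map({"F": CONTROL, "M": TREATED})
    dispersions = estimate_dispersion(counts, size_factors, disp_samples)
    denom_df = dispersions.attrs.get("resid_df", 0) + dispersions.attrs.get(
        "prior_df", 0
    )
    norm = normalize_counts(counts, size_factors)

    lfc = {}
    padj = {}
    arr = counts.to_numpy()
    alphas = dispersions.to_numpy()
    for t in times:
        mask = (samples["time_h"] == t).to_numpy()
        sub_ids = samples.index[mask]
        is_f = (samples.loc[sub_ids, "sex"] == "F").astype(float).to_numpy()
        x_full = np.column_stack([np.ones(len(sub_ids)), is_f])
        x_red = np.ones((len(sub_ids), 1))
        offset = np.log(size_factors.loc[sub_ids].to_numpy(dtype=float))
        sub_norm = norm[sub_ids]
        f_mean = sub_norm.loc[:, is_f == 1].mean(axis=1)
        m_mean = sub_norm.loc[:, is_f == 0].mean(axis=1)
        lfc[t] = np.log2((f_mean + pseudocount) / (m_mean + pseudocount))
        sub_counts = counts[sub_ids].to_numpy()
        pvals = np.full(len(counts), np.nan)
        for i in range(len(counts)):
            llf_full, conv_f = _fit_llf(sub_counts[i], x_full, offset, alphas[i])
            llf_red, conv_r = _fit_llf(sub_counts[i], x_red, offset, alphas[i])
            if not (conv_f and conv_r):
                continue
            stat = max(2.0 * (llf_full - llf_red), 0.0)
            if denom_df > 0:
                pvals[i] = scipy.stats.f.sf(stat, 1, denom_df)
            else:
                pvals[i] = scipy.stats.chi2.sf(stat, 1)
        padj[t] = bh_adjust(pvals)
    lfc_df = pd.DataFrame(lfc, index=counts.index)
    padj_df = pd.DataFrame(padj, index=counts.index)
    flag = ((lfc_df.abs() > lfc_threshold) & (padj_df < alpha)).all(axis=1)
    return SexBaselineResult(
        log2fc=lfc_df, padj=padj_df, de_all_timepoints=flag.rename("de_all_timepoints")
    )


def pool_level_log2fc(
    dataset: CountDataset, pseudocount: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool-matched treated/control log2 ratios per (pool, time) sample pair.

    Returns (log2fc genes x pairs, pair annotation with pool/time_h/sex).
    """
    sf = estimate_size_factors(dataset.counts)
    norm = normalize_counts(dataset.counts, sf)
    samples = dataset.samples
    pairs = []
    cols = {}
    for (pool, t), grp in samples.groupby(["pool", "time_h"], sort=True):
        trt = grp.index[grp["condition"] == TREATED]
        ctl = grp.index[grp["condition"] == CONTROL]
        if len(trt) != 1 or len(ctl) != 1:
            raise ValueError(
                f"pool {pool} at {t} h lacks a matched control/treated pair"
            )
        name = f"{pool}_{t:g}h"
        cols[name] = np.log2(
            (norm[trt[0]] + pseudocount) / (norm[ctl[0]] + pseudocount)
        )
        pairs.append((name, pool, t, grp["sex"].iloc[0]))
    lfc = pd.DataFrame(cols)
    meta = pd.DataFrame(
        pairs, columns=["pair", "pool", "time_h", "sex"]
    ).set_index("pair")
    return lfc, meta


def sex_specific_regulation_check(
    dataset: CountDataset,
    lfc_threshold: float = 1.0,
    null_lfc: float = 0.1375,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Flag genes regulated in one sex with no regulation in the other.

    A gene is flagged ``female_only`` when some female pool-level |log2FC|
    exceeds ``lfc_threshold`` while every male pool-level |log2FC| stays
    strictly below ``null_lfc`` (fold change 1.1); ``male_only`` mirrors
    this. Swapping the sex labels swaps the two flags exactly.
    """
    lfc, meta = pool_level_log2fc(dataset, pseudocount=pseudocount)
    flags = {}
    for sex_a, sex_b, name in (("F", "M", "female_only"), ("M", "F", "male_only")):
        a_cols = meta.index[meta["sex"] == sex_a]
        b_cols = meta.index[meta["sex"] == sex_b]
        if len(a_cols) == 0 or len(b_cols) == 0:
            raise ValueError("both sexes required for the concordance check")
        regulated_a = (lfc[a_cols].abs() > lfc_threshold).any(axis=1)
        quiet_b = (lfc[b_cols].abs() < null_lfc).all(axis=1)
        flags[name] = regulated_a & quiet_b
    out = pd.DataFrame(flags)
    out["sex_specific"] = out["female_only"] | out["male_only"]
    return out
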