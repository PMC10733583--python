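"""Normalization, filtering and QC: size factors, TPM, CV, classical MDS.

Size factors use the median-of-ratios estimator: a reference set of genes
with no zero count, per-gene geometric means across samples, and the
per-sample median of count/geomean ratios. TPM divides counts by gene
length in kb and rescales each sample to one million. The coefficient of
variation (sd/mean, sample sd) is computed over per-time-point mean
expression and measures temporal stability.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datasets import CONTROL, TREATED


def estimate_size_factors(
    counts: pd.DataFrame, pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    Reference genes are rows with strictly positive counts in every sample.
    If no such row exists an error is raised unless ``pseudo_reference=True``,
    in which case geometric means are taken over the positive entries only
    (zeros ignored), as a fallback for sparse matrices.
    """
    arr = counts.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if all_pos.any() and not pseudo_reference:
        ref = arr[all_pos]
        log_ref = np.log(ref)
        log_geo = log_ref.mean(axis=1)
        log_ratios = log_ref - log_geo[:, None]
    else:
        if not all_pos.any() and not pseudo_reference:
            raise ValueError(
                "no gene has positive counts in all samples; rerun with "
                "pseudo_reference=True to use a zero-ignoring pseudo-reference"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            log_arr = np.log(arr)
        log_arr[~np.isfinite(log_arr)] = np.nan  # zero counts drop out
        log_geo = np.nanmean(log_arr, axis=1)
        usable = np.isfinite(log_geo)
        if not usable.any():
            raise ValueError("count matrix is all zero; size factors undefined")
        log_ratios = log_arr[usable] - log_geo[usable, None]
    factors = np.exp(np.nanmedian(log_ratios, axis=0))
    if not np.all(np.isfinite(factors)) or (factors <= 0).any():
        raise ValueError("size factor estimation produced non-positive factors")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Counts divided by per-sample size factors."""
    return counts / size_factors.loc[counts.columns]


def tpm(counts: pd.DataFrame, lengths_bp: pd.Series) -> pd.DataFrame:
    """Transcripts per kilobase per million mapped reads.

    Columns sum to 1e6 over the genes present in ``counts``; if genes were
    filtered beforehand, TPM is renormalized over the retained set. An
    all-zero sample yields NaN for that column with a warning.
    """
    lengths = lengths_bp.reindex(counts.index)
    missing = lengths.index[lengths.isna() | (lengths <= 0)]
    if len(missing):
        raise ValueError(
            f"missing or non-positive gene lengths for: {list(missing[:10])}"
        )
    rate = counts.div(lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    zero_cols = totals[totals == 0].index
    if len(zero_cols):
        warnings.warn(
            f"all-zero sample column(s), TPM undefined: {list(zero_cols)}",
            RuntimeWarning,
            stacklevel=2,
        )
        totals = totals.replace(0, np.nan)
    return rate.div(totals, axis=1) * 1e6


def coefficient_of_variation(values, ddof: int = 1) -> float:
    """sd / mean over an ordered series of per-time-point means.

    Returns NaN (flagged undefined) when the mean is non-positive; callers
    treat NaN as failing any stability criterion.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV requires at least two time points")
    m = x.mean()
    if not np.isfinite(m) or m <= 0:
        return float("nan")
    return float(x.std(ddof=ddof) / m)


def per_time_means(
    values: pd.DataFrame, samples: pd.DataFrame, condition: str
) -> pd.DataFrame:
    """Per-time-point mean expression over pools for one condition.

    Returns genes x time (columns = sorted unique hours).
    """
    mask = samples["condition"] == condition
    sub = values.loc[:, samples.index[mask]]
    times = samples.loc[mask, "time_h"]
    grouped = sub.T.groupby(times.to_numpy()).mean().T
    return grouped[sorted(grouped.columns)]


def cv_profile(values: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-gene CV of per-time-point mean expression, by condition.

    Expression is averaged over pools at each time point first (mean-then-CV);
    result has columns ``cv_control`` and ``cv_treated``.
    """
    out = {}
    for cond, col in ((CONTROL, "cv_control"), (TREATED, "cv_treated")):
        means = per_time_means(values, samples, cond)
        arr = means.to_numpy()
        m = arr.mean(axis=1)
        sd = arr.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.where(m > 0, sd / m, np.nan)
        out[col] = pd.Series(cv, index=values.index)
    return pd.DataFrame(out)


def filter_low_expression(
    tpm_values: pd.DataFrame,
    samples: pd.DataFrame,
    min_tpm: float = 1.0,
    group_cols: Sequence[str] = ("condition", "time_h"),
) -> pd.Series:
    """Mask of genes whose maximum group-mean TPM reaches ``min_tpm``.

    Group means are taken over pools within each ``group_cols`` cell
    (default condition x time). Genes strictly below the threshold at every
    cell are excluded; a maximum exactly at the threshold is retained.
    """
    keys = [samples[c].to_numpy() for c in group_cols]
    means = tpm_values.T.groupby(keys).mean().T
    max_mean = means.max(axis=1)
    return (max_mean >= min_tpm).rename("expressed")


def classical_mds(
    data: pd.DataFrame | np.ndarray,
    dims: int = 2,
    *,
    is_distance: bool = False,
    neg_eig_tol: float = 1e-8,
) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples.

    ``data`` is either a samples x features matrix (pairwise Euclidean
    distances are computed) or a precomputed square distance matrix
    (``is_distance=True``). Squared distances are double-centered and
    eigendecomposed; coordinates are the top-``dims`` eigenvectors scaled by
    the square roots of their eigenvalues. Distances are reproduced exactly
    when the points embed in ``dims`` Euclidean dimensions. Substantially
    negative eigenvalues trigger a non-Euclidean-input warning.
    """
    if isinstance(data, pd.DataFrame):
        index = data.index
        arr = data.to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
        index = pd.RangeIndex(arr.shape[0])
    if is_distance:
        d = arr
        if d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
    else:
        d = squareform(pdist(arr, metric="euclidean"))
    m = d.shape[0]
    if m < dims + 1:
        raise ValueError(f"classical MDS with dims={dims} needs at least {dims + 1} samples")
    j = np.eye(m) - np.ones((m, m)) / m
    b = -0.5 * j @ (d**2) @ j
    b = 0.5 * (b + b.T)
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = max(abs(eigval[0]), 1.0)
    if eigval[-1] < -neg_eig_tol * scale:
        warnings.warn(
            "distance matrix is not Euclidean (negative eigenvalues); "
            "coordinates are an approximation",
            RuntimeWarning,
            stacklevel=2,
        )
    top = np.clip(eigval[:dims], 0.0, None)
    coords = eigvec[:, :dims] * np.sqrt(top)[None, :]
    return pd.DataFrame(
        coords, index=index, columns=[f"MDS{i + 1}" for i in range(dims)]
    )
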