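"""Benchmark evaluations of the pipeline on synthetic data with known truth.

These routines regenerate data under the study's design (2 conditions x 11
time points x 3 pools per sex), run the relevant stages, and score them
against the planted ground truth: classifier recovery, likelihood-ratio
test calibration, coexpression-module recovery and the between-sex
concordance property.
"""

from __future__ import annotations

import math
import numpy as np
import pandas as pd
import scipy.stats

from .classify import classify_regulation, merge_sex_calls, peak_log2fc_vs_t0
from .diffexpr import de_analysis
from .network import detect_modules
from .preprocess import (
    cv_profile,
    estimate_size_factors,
    filter_low_expression,
    normalize_counts,
    tpm,
)
from .sexdiff import sex_specific_regulation_check
from .simulate import SyntheticConfig, generate_dataset

#: archetype mix of the recovery benchmark: 200 early-induced, 200 delayed,
#: 100 sustained-down, 100 resolving-down, 200 drift confounders, 1200 null
RECOVERY_MIX = {
    "early_transient": 0.05,
    "early_sustained": 0.05,
    "delayed": 0.10,
    "down_sustained": 0.05,
    "down_resolving": 0.05,
    "tnf_delayed_drift": 0.10,
    "null": 0.60,
}

UP_ARCHETYPES = ("early_transient", "early_sustained", "delayed")
DOWN_ARCHETYPES = ("down_sustained", "down_resolving")


def classifier_recovery(seed: int, n_genes: int = 2000) -> dict:
    """Sensitivity/specificity of the regulation classifier vs planted truth.

    Runs the full per-sex pipeline (normalization, DE, classification) and
    merges the two sexes; a gene counts as recovered when it is called in
    the true direction in at least one sex.
    """
    cfg = SyntheticConfig(n_genes=n_genes, seed=seed, archetype_mix=RECOVERY_MIX)
    res = generate_dataset(cfg)
    calls = {}
    for sex in ("F", "M"):
        ds = res.dataset.sex_subset(sex)
        de = de_analysis(ds.counts, ds.samples)
        tpm_vals = tpm(ds.counts, ds.genes["length_bp"])
        calls[sex] = classify_regulation(
            cv_profile(tpm_vals, ds.samples),
            de.deg,
            de.log2fc,
            peak_log2fc_vs_t0(tpm_vals, ds.samples),
            filter_low_expression(tpm_vals, ds.samples),
        )
    merged = merge_sex_calls(calls)
    truth = res.truth["archetype"]

    up_true = truth.isin(UP_ARCHETYPES)
    down_true = truth.isin(DOWN_ARCHETYPES)
    called = merged["merged_class"] != "neither"
    up_called = called & (merged["direction"] == "up")
    down_called = called & (merged["direction"] == "down")
    null_mask = truth == "null"
    drift = truth == "tnf_delayed_drift"
    drift_excluded = (
        (calls["F"]["label"] == "excluded_control_variable")
        | (calls["M"]["label"] == "excluded_control_variable")
    )
    return {
        "n_genes": n_genes,
        "up_sensitivity": float(up_called[up_true].mean()),
        "down_sensitivity": float(down_called[down_true].mean()),
        "null_specificity": float((~called[null_mask]).mean()),
        "drift_exclusion_rate": float(drift_excluded[drift].mean()),
        "n_up_true": int(up_true.sum()),
        "n_down_true": int(down_true.sum()),
        "n_null": int(null_mask.sum()),
        "n_drift": int(drift.sum()),
    }


def lrt_null_calibration(seed: int, n_genes: int = 1000) -> dict:
    """Type-I error and p-value uniformity of the LRT on all-null data."""
    cfg = SyntheticConfig(n_genes=n_genes, seed=seed, archetype_mix={"null": 1.0})
    res = generate_dataset(cfg)
    ds = res.dataset.sex_subset("F")
    de = de_analysis(ds.counts, ds.samples)
    p = de.table["p"].dropna()
    ks = scipy.stats.kstest(p.to_numpy(), "uniform")
    return {
        "n_genes": int(len(p)),
        "rejection_rate_05": float((p < 0.05).mean()),
        "ks_uniformity_pvalue": float(ks.pvalue),
    }


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two label vectors."""
    a = pd.Categorical(labels_a).codes
    b = pd.Categorical(labels_b).codes
    table = pd.crosstab(a, b).to_numpy()
    comb = np.vectorize(lambda x: math.comb(int(x), 2))
    sum_cells = comb(table).sum()
    sum_rows = comb(table.sum(axis=1)).sum()
    sum_cols = comb(table.sum(axis=0)).sum()
    total = math.comb(int(table.sum()), 2)
    expected = sum_rows * sum_cols / total
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def module_recovery(seed: int, beta: float = 6.0) -> dict:
    """Recovery of planted coexpression blocks (150/120/80 + a 10-block).

    Scores the number of modules, the adjusted Rand index restricted to
    genes of the three large blocks, the worst eigengene-to-latent-factor
    correlation, and whether the sub-minimum block stayed unassigned.
    """
    cfg = SyntheticConfig(
        n_genes=600,
        seed=seed,
        archetype_mix={"null": 1.0},
        coexpression_blocks=(150, 120, 80, 10),
    )
    res = generate_dataset(cfg)
    sf = estimate_size_factors(res.dataset.counts)
    log_norm = np.log2(normalize_counts(res.dataset.counts, sf) + 1.0)
    mods = detect_modules(log_norm, beta=beta)
    truth_block = res.truth["block"]
    big = truth_block.isin([0, 1, 2])
    ari = adjusted_rand_index(truth_block[big], mods.labels[big])
    eig_cors = []
    for b in (0, 1, 2):
        members = truth_block.index[truth_block == b]
        mod = mods.labels[members].mode()[0]
        if mod == 0:
            eig_cors.append(0.0)
            continue
        z = res.block_factors.loc[f"block{b}"]
        eig_cors.append(abs(float(np.corrcoef(mods.eigengenes.loc[mod], z)[0, 1])))
    small_unassigned = bool((mods.labels[truth_block == 3] == 0).all())
    return {
        "n_genes": 600,
        "n_modules": int(len(mods.eigengenes)),
        "ari_planted_blocks": float(ari),
        "min_eigengene_latent_cor": float(min(eig_cors)),
        "small_block_unassigned": small_unassigned,
    }


def sex_concordance(seed: int, n_runs: int = 20, n_genes: int = 300) -> dict:
    """Sex-specific-regulation flags on sex-identical data over many seeds."""
    zero_runs = 0
    total_flags = 0
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    for s in sub_seeds:
        res = generate_dataset(SyntheticConfig(n_genes=n_genes, seed=int(s)))
        flags = sex_specific_regulation_check(res.dataset)
        n = int(flags["sex_specific"].sum())
        total_flags += n
        zero_runs += n == 0
    return {
        "n_runs": n_runs,
        "n_genes": n_genes,
        "runs_with_zero_flags": int(zero_runs),
        "total_flags": int(total_flags),
    }
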