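"""Synthetic negative-binomial time-course generator with planted truth.

Emulates the statistical structure of a pooled bulk RNA-seq cytokine
time course: two conditions (control / TNF-treated), an 11-point grid from
0.5 h to 72 h, a few replicate pools per sex, NB-distributed counts, and a
set of temporal response archetypes:

``early_transient``
    induction starting ~1 h, peaking 4-8 h, resolving toward baseline.
``early_sustained``
    early induction that stays elevated through 72 h.
``delayed``
    induction rising between 12 and 24 h and held high to 72 h.
``down_sustained`` / ``down_resolving``
    suppression that is maintained, or that trends back to baseline.
``control_drift``
    both conditions drift identically over the course (no true treatment
    effect; a confounder for variance-based screens).
``tnf_delayed_drift``
    the control drifts and treatment delays the same drift: differential
    expression exists but is driven by the control's temporal change -- the
    confounder class a regulation classifier must exclude.
``null``
    flat in both conditions.

Mean curves are piecewise-logistic (an onset sigmoid times an optional
resolution sigmoid), normalized so the treated-minus-control difference at
``peak_h`` equals ``peak_log2fc`` exactly. Optional coexpression blocks add
a shared per-sample latent factor on the log2 scale so that downstream
module detection has planted ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .datasets import CONTROL, TREATED, CountDataset

ARCHETYPES = (
    "early_transient",
    "early_sustained",
    "delayed",
    "down_sustained",
    "down_resolving",
    "control_drift",
    "tnf_delayed_drift",
    "null",
)

#: default 11-point comparison grid in hours
DEFAULT_TIME_GRID = (0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0, 72.0)


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parameters of one temporal response archetype.

    ``resolve_h`` is the time by which a transient response has returned
    toward baseline (None = sustained). For ``tnf_delayed_drift`` it instead
    holds the treatment-induced lag of the control drift, in hours.
    """

    name: str
    baseline_log2_tpm: float
    peak_log2fc: float
    onset_h: float
    peak_h: float
    resolve_h: float | None = None
    dispersion: float = 0.05

    def __post_init__(self) -> None:
        if self.name not in ARCHETYPES:
            raise ValueError(f"unknown archetype name: {self.name!r}")
        if self.peak_h < self.onset_h:
            raise ValueError("peak_h must be >= onset_h")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.name == "null" and self.peak_log2fc != 0:
            raise ValueError("null archetype must have peak_log2fc = 0")


# onset/peak/resolve defaults per archetype (hours); peak_log2fc sign fixed
_ARCHETYPE_SHAPES: dict[str, dict] = {
    "early_transient": dict(onset_h=1.0, peak_h=6.0, resolve_h=48.0, sign=+1),
    "early_sustained": dict(onset_h=1.0, peak_h=8.0, resolve_h=None, sign=+1),
    "delayed": dict(onset_h=12.0, peak_h=24.0, resolve_h=None, sign=+1),
    "down_sustained": dict(onset_h=2.0, peak_h=12.0, resolve_h=None, sign=-1),
    "down_resolving": dict(onset_h=2.0, peak_h=8.0, resolve_h=48.0, sign=-1),
    "control_drift": dict(onset_h=8.0, peak_h=36.0, resolve_h=None, sign=+1),
    "tnf_delayed_drift": dict(onset_h=8.0, peak_h=36.0, resolve_h=24.0, sign=+1),
    "null": dict(onset_h=0.5, peak_h=0.5, resolve_h=None, sign=0),
}


def default_archetype(
    name: str,
    baseline_log2_tpm: float,
    peak_log2fc_magnitude: float = 2.0,
    dispersion: float = 0.05,
) -> ArchetypeSpec:
    """Build the archetype with its default temporal shape parameters."""
    if name not in _ARCHETYPE_SHAPES:
        raise ValueError(f"unknown archetype name: {name!r}")
    shape = _ARCHETYPE_SHAPES[name]
    return ArchetypeSpec(
        name=name,
        baseline_log2_tpm=baseline_log2_tpm,
        peak_log2fc=shape["sign"] * abs(peak_log2fc_magnitude),
        onset_h=shape["onset_h"],
        peak_h=shape["peak_h"],
        resolve_h=shape["resolve_h"],
        dispersion=dispersion,
    )


def _shape(t: np.ndarray, onset: float, peak: float, resolve: float | None) -> np.ndarray:
    """Onset sigmoid times optional resolution sigmoid, un-normalized."""
    mid = 0.5 * (onset + peak)
    width = max((peak - onset) / 8.0, 1e-3)
    g = expit((t - mid) / width)
    if resolve is not None:
        rmid = 0.5 * (peak + resolve)
        rwidth = max((resolve - peak) / 8.0, 1e-3)
        g = g * expit(-(t - rmid) / rwidth)
    return g


def _delta(spec: ArchetypeSpec, t: np.ndarray) -> np.ndarray:
    """Treated-minus-control log2 difference; exactly peak_log2fc at peak_h."""
    raw = _shape(t, spec.onset_h, spec.peak_h, spec.resolve_h)
    at_peak = _shape(np.asarray([spec.peak_h]), spec.onset_h, spec.peak_h, spec.resolve_h)[0]
    return spec.peak_log2fc * raw / at_peak


def _drift(spec: ArchetypeSpec, t: np.ndarray) -> np.ndarray:
    """Shared control-side drift curve (log2 units above baseline)."""
    raw = _shape(t, spec.onset_h, spec.peak_h, None)
    at_peak = _shape(np.asarray([spec.peak_h]), spec.onset_h, spec.peak_h, None)[0]
    return spec.peak_log2fc * raw / at_peak


def archetype_mean(spec: ArchetypeSpec, t, condition: str) -> np.ndarray | float:
    """Expected log2 expression of an archetype at time(s) ``t``.

    Deterministic and smooth in t. Control and treated curves are identical
    for ``null`` and ``control_drift``; for ``tnf_delayed_drift`` the treated
    curve is the control curve shifted later in time by ``resolve_h`` hours.
    """
    if condition not in (CONTROL, TREATED):
        raise ValueError(f"condition must be control/treated, got {condition!r}")
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if spec.name == "null":
        out = np.full_like(t_arr, spec.baseline_log2_tpm)
    elif spec.name == "control_drift":
        out = spec.baseline_log2_tpm + _drift(spec, t_arr)
    elif spec.name == "tnf_delayed_drift":
        lag = spec.resolve_h if spec.resolve_h is not None else 24.0
        shift = t_arr - lag if condition == TREATED else t_arr
        out = spec.baseline_log2_tpm + _drift(spec, shift)
    else:
        out = np.full_like(t_arr, spec.baseline_log2_tpm, dtype=float)
        if condition == TREATED:
            out = out + _delta(spec, t_arr)
    return float(out[0]) if scalar else out


def nb_sample(mean, dispersion, rng: np.random.Generator):
    """Draw NB counts with Var = mean + dispersion * mean^2.

    ``dispersion`` (alpha) may be a scalar or broadcastable array; alpha = 0
    degrades to Poisson. Negative means raise.
    """
    mean = np.asarray(mean, dtype=float)
    alpha = np.asarray(dispersion, dtype=float)
    if (mean < 0).any():
        raise ValueError("negative mean passed to nb_sample")
    if (alpha < 0).any():
        raise ValueError("dispersion must be >= 0")
    mean_b, alpha_b = np.broadcast_arrays(mean, alpha)
    out = np.zeros(mean_b.shape, dtype=np.int64)
    pois = alpha_b < 1e-12
    if pois.any():
        out[pois] = rng.poisson(mean_b[pois])
    nb = ~pois
    if nb.any():
        size = 1.0 / alpha_b[nb]
        p = size / (size + mean_b[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


@dataclass
class SyntheticConfig:
    """Study-design configuration for the generator.

    Defaults mirror the emulated study design: 2 conditions x 11 time
    points x 3 pooled replicates per sex, peak effect |log2FC| = 2, NB
    dispersion 0.05 with log-normal gene-level jitter, and an archetype mix
    dominated by unregulated genes with a control-drift confounder class.
    """

    n_genes: int = 2000
    archetype_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "early_transient": 0.05,
            "early_sustained": 0.05,
            "delayed": 0.10,
            "down_sustained": 0.05,
            "down_resolving": 0.05,
            "tnf_delayed_drift": 0.10,
            "null": 0.60,
        }
    )
    time_grid: Sequence[float] = DEFAULT_TIME_GRID
    n_pools_per_sex: Mapping[str, int] = field(
        default_factory=lambda: {"F": 3, "M": 3}
    )
    peak_log2fc: float = 2.0
    baseline_log2_tpm_range: tuple[float, float] = (3.0, 7.0)
    library_size_range: tuple[float, float] = (3e5, 1e6)
    gene_length_range: tuple[float, float] = (500.0, 5000.0)
    dispersion: float = 0.05
    dispersion_jitter_sd: float = 0.3
    #: sizes of planted coexpression blocks (carved out of null genes)
    coexpression_blocks: Sequence[int] = ()
    #: target within-block correlation of log2 expression
    block_cor: float = 0.7
    #: number of genes given a constant between-sex baseline shift
    n_sex_genes: int = 0
    sex_baseline_log2fc: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype mix proportions must sum to 1, got {total}")
        unknown = set(self.archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes in mix: {sorted(unknown)}")
        grid = np.asarray(self.time_grid, dtype=float)
        if len(grid) == 0 or (np.diff(grid) <= 0).any():
            raise ValueError("time_grid must be non-empty and strictly increasing")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "seed" not in raw:
            raise ValueError("synthetic config requires an explicit seed")
        for key in ("time_grid", "coexpression_blocks"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("baseline_log2_tpm_range", "library_size_range", "gene_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticDataset:
    """Generator output: counts plus per-gene ground truth.

    ``truth`` has one row per gene (archetype, curve parameters, dispersion,
    block id or -1, planted sex shift). ``block_factors`` holds the latent
    per-sample factor of each coexpression block (blocks x samples).
    """

    dataset: CountDataset
    truth: pd.DataFrame
    block_factors: pd.DataFrame

    def write(self, outdir: str | Path, matrix_market: bool = False) -> None:
        outdir = Path(outdir)
        self.dataset.write(outdir, matrix_market=matrix_market)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index_label="gene_id")
        if len(self.block_factors):
            self.block_factors.to_csv(
                outdir / "block_factors.tsv", sep="\t", index_label="block"
            )


def _archetype_counts(mix: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n genes over the mix."""
    names = sorted(mix)
    exact = {k: mix[k] * n for k in names}
    base = {k: int(math.floor(v)) for k, v in exact.items()}
    short = n - sum(base.values())
    by_rem = sorted(names, key=lambda k: (-(exact[k] - base[k]), k))
    for k in by_rem[:short]:
        base[k] += 1
    return {k: v for k, v in base.items() if v > 0}


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate counts, metadata and truth for the configured study design."""
    rng = np.random.default_rng(config.seed)
    grid = np.asarray(config.time_grid, dtype=float)
    n = config.n_genes

    # --- gene-level truth -------------------------------------------------
    alloc = _archetype_counts(config.archetype_mix, n)
    arch_names = np.concatenate(
        [np.full(c, name) for name, c in sorted(alloc.items())]
    )
    rng.shuffle(arch_names)
    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    baselines = rng.uniform(*config.baseline_log2_tpm_range, size=n)
    log_alpha_jitter = rng.normal(0.0, config.dispersion_jitter_sd, size=n)
    dispersions = config.dispersion * np.exp(log_alpha_jitter)
    lengths = np.exp(rng.uniform(*np.log(config.gene_length_range), size=n))

    specs = [
        default_archetype(
            arch_names[i], baselines[i], config.peak_log2fc, dispersions[i]
        )
        for i in range(n)
    ]

    # coexpression blocks are carved out of null genes so that the block
    # signal, not a treatment response, drives their correlation
    block_of = np.full(n, -1, dtype=int)
    if config.coexpression_blocks:
        null_idx = np.flatnonzero(arch_names == "null")
        need = sum(config.coexpression_blocks)
        if need > len(null_idx):
            raise ValueError(
                f"coexpression blocks need {need} null genes, only {len(null_idx)} available"
            )
        cursor = 0
        for b, size in enumerate(config.coexpression_blocks):
            block_of[null_idx[cursor : cursor + size]] = b
            cursor += size

    sex_shift = np.zeros(n)
    if config.n_sex_genes > 0:
        chosen = rng.choice(n, size=config.n_sex_genes, replace=False)
        sex_shift[chosen] = config.sex_baseline_log2fc

    # --- sample sheet -----------------------------------------------------
    rows = []
    for sex in sorted(config.n_pools_per_sex):
        for p in range(1, config.n_pools_per_sex[sex] + 1):
            pool = f"{sex}{p}"
            for cond in (CONTROL, TREATED):
                for t in grid:
                    sid = f"{pool}_{cond}_{t:g}h"
                    rows.append((sid, cond, t, pool, sex))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "condition", "time_h", "pool", "sex"]
    ).set_index("sample_id")
    n_samples = len(samples)

    # --- expected log2 expression per gene x sample -----------------------
    log2_mu = np.empty((n, n_samples))
    cond_arr = samples["condition"].to_numpy()
    t_arr = samples["time_h"].to_numpy()
    sex_arr = samples["sex"].to_numpy()
    for cond in (CONTROL, TREATED):
        cmask = cond_arr == cond
        t_sub = t_arr[cmask]
        # group genes by identical (archetype, curve params) for speed
        for i, spec in enumerate(specs):
            log2_mu[i, cmask] = archetype_mean(spec, t_sub, cond)
    log2_mu += np.where(sex_arr == "F", 1.0, 0.0)[None, :] * sex_shift[:, None]

    # latent block factors: one draw per (block, sample), loading chosen so
    # that the within-block log2 correlation approximates block_cor given
    # the NB noise floor sqrt(alpha)/ln 2
    block_ids = sorted(set(block_of[block_of >= 0]))
    if block_ids:
        z = rng.normal(size=(len(block_ids), n_samples))
        noise_sd = math.sqrt(config.dispersion) / math.log(2.0)
        sigma = noise_sd * math.sqrt(config.block_cor / (1.0 - config.block_cor))
        for b in block_ids:
            members = np.flatnonzero(block_of == b)
            log2_mu[members, :] += sigma * z[b][None, :]
        block_factors = pd.DataFrame(
            z, index=[f"block{b}" for b in block_ids], columns=samples.index
        )
    else:
        block_factors = pd.DataFrame(columns=samples.index)

    # --- counts -----------------------------------------------------------
    lib_sizes = np.exp(rng.uniform(*np.log(config.library_size_range), size=n_samples))
    rel = np.exp2(log2_mu) * (lengths / 1000.0)[:, None]  # counts ~ TPM * length
    frac = rel / rel.sum(axis=0, keepdims=True)
    mu_counts = frac * lib_sizes[None, :]
    counts = nb_sample(mu_counts, dispersions[:, None], rng)

    genes = pd.DataFrame(
        {
            "symbol": [f"SYN{i:05d}" for i in range(n)],
            "biotype": np.where(
                rng.uniform(size=n) < 0.9, "protein_coding", "lncRNA"
            ),
            "length_bp": np.round(lengths).astype(int),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    counts_df = pd.DataFrame(counts, index=genes.index, columns=samples.index)
    dataset = CountDataset(counts=counts_df, samples=samples, genes=genes)

    truth = pd.DataFrame(
        {
            "archetype": arch_names,
            "baseline_log2_tpm": baselines,
            "peak_log2fc": [s.peak_log2fc for s in specs],
            "onset_h": [s.onset_h for s in specs],
            "peak_h": [s.peak_h for s in specs],
            "resolve_h": [
                np.nan if s.resolve_h is None else s.resolve_h for s in specs
            ],
            "dispersion": dispersions,
            "block": block_of,
            "sex_baseline_log2fc": sex_shift,
        },
        index=genes.index,
    )
    return SyntheticDataset(dataset=dataset, truth=truth, block_factors=block_factors)
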