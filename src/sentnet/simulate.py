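"""Synthetic cohort generator with full ground truth.

Emulates the statistical structure the analysis chain assumes: a set of
homotopic region pairs in which a planted subset is jointly activated
and leftward asymmetric in all three tasks; resting-state series whose
correlation structure contains planted modules (with designated hub
regions) and planted inter-module correlations; and a subject-level
coupling between resting connectivity strength and task activation.

Design of the coupling mechanism
--------------------------------
Each subject s carries a latent connectivity factor
``w_s = clip(Normal(1, sigma_w), 0.2, 1.0)``.  The subject's true
correlation matrix is the convex blend ``C_s = I + w_s (C - I)`` of the
population target C toward the identity (the upper clip keeps C_s
positive semi-definite, since the repaired C sits on the PSD boundary),
and the same factor shifts the planted left-hemisphere activation of
selected regions additively by ``c (w_s - E[w])``.  ``sigma_w`` is
calibrated by bisection against a closed-form predictor of the pooled
degree-centrality/activation correlation so that the measured pooled
coupling lands on ``coupling_rho``; the predictor uses the asymptotic
sampling covariance of Pearson correlations with an effective sample
size computed from the bandpass/AR(1) spectrum.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .config import derive_seed
from .data import (
    ContrastPanel,
    DataError,
    RegionTable,
    TASKS,
    TimeSeriesPanel,
    write_contrast_panel,
    write_region_table,
    write_timeseries,
)
from .preprocess import NuisanceSet, design_bandpass, effective_sample_size


@dataclass
class NuisanceParams:
    """Amplitudes of the simulated nuisance components (signal-SD units)."""

    trend_sd: float = 0.15
    n_regressors: int = 2
    loading_sd: float = 0.2


@dataclass
class GeneratorParams:
    """Study conditions of the emulated cohort.

    Defaults reproduce the reference cohort: 185 homotopic pairs, 144
    subjects with three task contrasts, 138 of them with an 8-minute
    resting run (240 samples at TR = 2 s), a planted 32-region selected
    set organised in three connectivity modules of sizes 18/8/6, and
    network-level inter-module resting correlations of -0.27, +0.06 and
    -0.04.  Activation and asymmetry means per task follow the published
    volume-weighted profile of the core network.
    """

    n_pairs: int = 185
    n_contrast_subjects: int = 144
    n_rest_subjects: int = 138
    T: int = 240
    sampling_interval: float = 2.0
    selected_sizes: tuple = (18, 8, 6)
    within_r: tuple = (0.35, 0.25, 0.25)
    # network-level (mean-series) correlation targets per module pair
    between_r: tuple = ((0, 1, -0.27), (1, 2, 0.06), (0, 2, -0.04))
    background_r_sd: float = 0.05
    n_hub_regions: int = 3
    hub_boost: float = 0.15
    task_means: tuple = (0.73, 0.43, 0.55)  # PROD, LISN, READ
    task_asym: tuple = (0.41, 0.25, 0.28)
    task_sd: float = 0.3
    coupling_rho: float = 0.25
    coupling_amplitude: float = 1.0
    ar1_phi: float = 0.3
    nuisance: NuisanceParams = field(default_factory=NuisanceParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.selected_sizes) > self.n_pairs:
            raise DataError("selected module sizes exceed n_pairs")
        for r in list(self.within_r) + [t[2] for t in self.between_r]:
            if not -1 < r < 1:
                raise DataError(f"target correlation {r} outside (-1, 1)")
        if not -1 < self.coupling_rho < 1:
            raise DataError("coupling_rho must lie in (-1, 1)")
        if self.T <= 2 * len(self.selected_sizes):
            raise DataError("T must exceed twice the number of modules")
        if self.n_rest_subjects > self.n_contrast_subjects:
            raise DataError("rest subjects must be a subset of contrast subjects")

    @classmethod
    def profile(cls, name: str, seed: int = 0) -> "GeneratorParams":
        """'full' = reference-cohort sizes; 'reduced' = fast test profile."""
        if name == "full":
            return cls(seed=seed)
        if name == "reduced":
            return cls(
                n_pairs=40,
                n_contrast_subjects=40,
                n_rest_subjects=40,
                seed=seed,
            )
        raise ValueError(f"unknown profile {name!r}")


MODULE_LABELS = ("M1", "M2", "M3", "M4", "M5")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort."""

    selected_set: list
    partition: dict  # pair_id -> module label
    hub_set: list
    coupling_rho: float
    params: GeneratorParams
    seed: int
    subject_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        first = MODULE_LABELS[0]
        if any(self.partition.get(h) != first for h in self.hub_set):
            raise DataError("hub_set must lie inside the first module")
        if set(self.partition) != set(self.selected_set):
            raise DataError("partition must cover exactly the selected set")

    def module_members(self, label: str) -> list:
        return [p for p in self.selected_set if self.partition[p] == label]

    def to_json(self) -> dict:
        return {
            "selected_set": list(self.selected_set),
            "partition": dict(self.partition),
            "hub_set": list(self.hub_set),
            "coupling_rho": self.coupling_rho,
            "seed": self.seed,
            "subject_weights": (
                None
                if self.subject_weights is None
                else np.asarray(self.subject_weights).tolist()
            ),
        }


def region_names(params: GeneratorParams) -> list[str]:
    return [f"r{i + 1:03d}" for i in range(params.n_pairs)]


def pair_ids(params: GeneratorParams) -> list[str]:
    return [f"p{i + 1:03d}" for i in range(params.n_pairs)]


def planted_structure(params: GeneratorParams):
    """Deterministic (from params.seed) module/hub placement.

    Returns (module_index_lists, hub_indices): positions within the
    region ordering for each planted module, and the hub regions (a
    subset of the first module).
    """
    rng = np.random.default_rng(derive_seed(params.seed, "structure"))
    total = sum(params.selected_sizes)
    chosen = rng.choice(params.n_pairs, size=total, replace=False)
    modules, start = [], 0
    for size in params.selected_sizes:
        modules.append(np.sort(chosen[start : start + size]))
        start += size
    n_hubs = min(params.n_hub_regions, len(modules[0]))
    hubs = np.sort(rng.choice(modules[0], size=n_hubs, replace=False))
    return modules, hubs


def _block_variance_of_mean(block: np.ndarray) -> float:
    """Variance of the mean of n unit-variance signals with corr block."""
    n = block.shape[0]
    off = block.sum() - np.trace(block)
    return (n + off) / n**2


def block_mean(C: np.ndarray, idx_a, idx_b) -> float:
    """Mean off-diagonal entry of the (idx_a, idx_b) block."""
    sub = C[np.ix_(idx_a, idx_b)]
    if list(idx_a) == list(idx_b):
        n = len(idx_a)
        return float((sub.sum() - np.trace(sub)) / (n * (n - 1)))
    return float(sub.mean())


def build_target_correlation(params: GeneratorParams) -> np.ndarray:
    """Population correlation matrix with planted modules and hubs.

    Within-module entries equal ``within_r`` (hub rows boosted by
    ``hub_boost``); between-module entries are derived from the
    network-level targets via r_pair = R * sqrt(vbar_a * vbar_b), where
    vbar is the variance of the module-mean series, so that the
    correlation between module-mean time series matches ``between_r``.
    Background entries are Normal(0, background_r_sd).  The matrix is
    repaired to PSD by eigenvalue clipping at 1e-6 and diagonal
    renormalization; an error is raised if the repair drifts any planted
    block mean by more than 0.05.
    """
    N = params.n_pairs
    modules, hubs = planted_structure(params)
    rng = np.random.default_rng(derive_seed(params.seed, "background"))

    C = np.zeros((N, N))
    if params.background_r_sd > 0:
        noise = rng.normal(0.0, params.background_r_sd, size=(N, N))
        C = (noise + noise.T) / np.sqrt(2.0)
    for m, idx in enumerate(modules):
        C[np.ix_(idx, idx)] = params.within_r[m]
        if m == 0 and params.hub_boost:
            boosted = params.within_r[0] + params.hub_boost
            for h in hubs:
                C[h, idx] = boosted
                C[idx, h] = boosted
    np.fill_diagonal(C, 1.0)
    # derive pairwise between-module values from network-level targets
    vbar = [
        _block_variance_of_mean(C[np.ix_(idx, idx)]) for idx in modules
    ]
    targets = {}
    for a, b, r_net in params.between_r:
        if max(a, b) >= len(modules):
            continue
        r_pair = r_net * np.sqrt(vbar[a] * vbar[b])
        C[np.ix_(modules[a], modules[b])] = r_pair
        C[np.ix_(modules[b], modules[a])] = r_pair
        targets[(a, b)] = r_pair
    np.fill_diagonal(C, 1.0)

    planted = {(m, m): block_mean(C, idx, idx) for m, idx in enumerate(modules)}
    planted.update(targets)

    # PSD repair: clip eigenvalues, renormalize the diagonal to 1
    vals, vecs = np.linalg.eigh((C + C.T) / 2)
    if vals[0] < 1e-6:
        vals = np.clip(vals, 1e-6, None)
        C = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    C = (C + C.T) / 2

    for (a, b), target in planted.items():
        got = block_mean(C, modules[a], modules[b] if b != a else modules[a])
        drift = abs(got - target)
        if drift > 0.05:
            raise DataError(
                f"PSD repair drifted block ({a},{b}) mean by {drift:.3f} "
                f"(target {target:.3f}, got {got:.3f})"
            )
    return C


# ---------------------------------------------------------------------------
# Subject-factor calibration
# ---------------------------------------------------------------------------

_W_LO, _W_HI = 0.2, 1.0


def _censored_moments(sigma: float, lo: float = _W_LO, hi: float = _W_HI):
    """Mean and variance of clip(Normal(1, sigma), lo, hi)."""
    if sigma <= 0:
        return 1.0 if lo <= 1.0 <= hi else np.clip(1.0, lo, hi), 0.0
    z = np.linspace(-8.0, 8.0, 8001)
    w = np.clip(1.0 + sigma * z, lo, hi)
    pdf = stats.norm.pdf(z)
    mean = np.trapezoid(w * pdf, z)
    second = np.trapezoid(w**2 * pdf, z)
    return float(mean), float(second - mean**2)


def _pearson_cov_matrix(rho: np.ndarray, core: np.ndarray, t_eff: float):
    """Asymptotic variance of each core region's degree centrality.

    Sums Var(r_ij) and Cov(r_ij, r_ik) over the region's within-module
    edges, using the classical large-sample moments of sample Pearson
    correlations of a multivariate normal.
    """
    k = len(core)
    sub = rho[np.ix_(core, core)]
    out = np.zeros(k)
    for i in range(k):
        others = [j for j in range(k) if j != i]
        total = 0.0
        for a_pos, j in enumerate(others):
            rij = sub[i, j]
            total += (1 - rij**2) ** 2
            for l in others[a_pos + 1 :]:
                ril = sub[i, l]
                rjl = sub[j, l]
                cov = rjl * (1 - rij**2 - ril**2) - 0.5 * rij * ril * (
                    1 - rij**2 - ril**2 - rjl**2
                )
                total += 2 * cov
        out[i] = total / t_eff
    return out


def calibrate_subject_sd(params: GeneratorParams, C: np.ndarray) -> float:
    """Bisection for sigma_w hitting the pooled coupling target."""
    if params.coupling_rho == 0:
        return 0.0
    modules, _ = planted_structure(params)
    core = modules[0]
    taps = design_bandpass(params.sampling_interval)
    t_eff = effective_sample_size(
        params.T, params.sampling_interval, taps=taps, ar_phi=params.ar1_phi
    )
    sub = C[np.ix_(core, core)].copy()
    np.fill_diagonal(sub, 0.0)
    d = np.where(sub > 0, sub, 0.0).sum(axis=1)
    m_d, m_d2 = d.mean(), (d**2).mean()
    v_d = d.var()
    c_amp = abs(params.coupling_amplitude)
    rho_target = abs(params.coupling_rho)

    def predicted(sigma: float) -> float:
        w_bar, var_w = _censored_moments(sigma)
        v_e = _pearson_cov_matrix(w_bar * C, core, t_eff).mean()
        cov = c_amp * var_w * m_d
        var_dc = var_w * m_d2 + w_bar**2 * v_d + v_e
        var_a = c_amp**2 * var_w + params.task_sd**2
        return cov / np.sqrt(var_dc * var_a)

    lo, hi = 1e-4, 0.8
    if predicted(hi) < rho_target:
        raise DataError(
            f"coupling_rho={params.coupling_rho} unreachable with "
            f"coupling_amplitude={params.coupling_amplitude}"
        )
    return float(optimize.brentq(lambda s: predicted(s) - rho_target, lo, hi))


def sample_subject_weights(
    params: GeneratorParams, sigma_w: float, seed: int
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    raw = rng.normal(1.0, sigma_w, size=params.n_contrast_subjects)
    return np.clip(raw, _W_LO, _W_HI)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def sample_timeseries(
    cov: np.ndarray,
    params: GeneratorParams,
    seed: int | None,
    weights: np.ndarray | None = None,
    subjects: list | None = None,
) -> TimeSeriesPanel:
    """Draw per-subject T x N series with the planted correlation blend.

    With ``weights`` w_s, subject s's series have true correlation
    I + w_s (cov - I); temporal structure is AR(1) with coefficient
    ``ar1_phi`` and unit marginal variance, so sample correlations
    converge to the planted values as T grows.
    """
    if seed is None:
        raise DataError("sample_timeseries requires an explicit seed")
    cov = np.asarray(cov, float)
    N = cov.shape[0]
    if subjects is None:
        subjects = [f"sub{i + 1:03d}" for i in range(params.n_rest_subjects)]
    if weights is None:
        weights = np.ones(len(subjects))
    if params.T < N:
        warnings.warn(
            f"T={params.T} < N={N}: subject correlation matrices will be "
            "rank-deficient",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    phi = params.ar1_phi
    burn = 50 if phi else 0
    names = region_names(params) if N == params.n_pairs else [
        f"r{i + 1:03d}" for i in range(N)
    ]
    series = []
    eye = np.eye(N)
    for w in weights[: len(subjects)]:
        C_s = eye + w * (cov - eye)
        # PSD by construction for w in [0, 1]; guard tiny negatives
        L = np.linalg.cholesky(C_s + 1e-10 * eye)
        innov = rng.standard_normal((params.T + burn, N)) @ L.T
        if phi:
            x = signal.lfilter([np.sqrt(1 - phi**2)], [1.0, -phi], innov, axis=0)
            x = x[burn:]
        else:
            x = innov
        series.append(x)
    return TimeSeriesPanel(subjects, series, names, params.sampling_interval)


def sample_nuisance(
    params: GeneratorParams, panel: TimeSeriesPanel, seed: int
) -> tuple[TimeSeriesPanel, dict]:
    """Add trend + shared nuisance signals; return (raw panel, NuisanceSets)."""
    rng = np.random.default_rng(seed)
    nui = params.nuisance
    out_series, nuisets = [], {}
    for subj, mat in zip(panel.subjects, panel.series):
        T, N = mat.shape
        trend = np.linspace(-1.0, 1.0, T)
        slopes = rng.normal(0.0, nui.trend_sd, size=N)
        regs = []
        contrib = np.outer(trend, slopes)
        for _ in range(nui.n_regressors):
            raw = signal.lfilter([1.0], [1.0, -0.9], rng.standard_normal(T))
            raw = (raw - raw.mean()) / max(raw.std(), 1e-12)
            loadings = rng.normal(0.0, nui.loading_sd, size=N)
            contrib += np.outer(raw, loadings)
            regs.append(raw)
        out_series.append(mat + contrib)
        nuisets[subj] = NuisanceSet(np.column_stack(regs)) if regs else None
    raw_panel = TimeSeriesPanel(
        list(panel.subjects), out_series, list(panel.region_names),
        panel.sampling_interval,
    )
    return raw_panel, nuisets


def sample_contrasts(
    truth: SyntheticTruth, params: GeneratorParams, seed: int
) -> ContrastPanel:
    """Draw the subject x pair x task x hemisphere contrast panel.

    Selected regions: left mean = task mean (+ the subject coupling
    shift), right mean = task mean - task asymmetry.  Non-selected
    regions have zero means in both hemispheres.  All cells get iid
    Normal(0, task_sd) noise.
    """
    rng = np.random.default_rng(seed)
    pids = pair_ids(params)
    n_s, n_p = params.n_contrast_subjects, params.n_pairs
    subjects = [f"sub{i + 1:03d}" for i in range(n_s)]
    sel_idx = np.array(
        [pids.index(p) for p in truth.selected_set], dtype=int
    )
    means = np.zeros((n_p, len(TASKS), 2))
    for t in range(len(TASKS)):
        means[sel_idx, t, 0] = params.task_means[t]
        means[sel_idx, t, 1] = params.task_means[t] - params.task_asym[t]
    values = means[None] + rng.normal(0.0, params.task_sd, (n_s, n_p, 3, 2))
    if truth.subject_weights is not None and params.coupling_amplitude:
        w = np.asarray(truth.subject_weights)[:n_s]
        # centre on the cohort mean so non-coupled analyses stay unbiased
        shift = params.coupling_amplitude * (w - w.mean())
        # advanced indexing moves the selected-pair axis to the front
        values[:, sel_idx, :, 0] += shift[None, :, None]
    return ContrastPanel(subjects, pids, values)


@dataclass
class SyntheticCohort:
    regions: RegionTable
    contrasts: ContrastPanel
    rest_raw: TimeSeriesPanel
    nuisance: dict
    truth: SyntheticTruth
    target_matrix: np.ndarray


def _make_region_table(params: GeneratorParams) -> RegionTable:
    rng = np.random.default_rng(derive_seed(params.seed, "regions"))
    pids = pair_ids(params)
    names = region_names(params)
    volumes = np.exp(rng.normal(np.log(4000.0), 0.4, size=params.n_pairs))
    x = -rng.uniform(4.0, 60.0, size=params.n_pairs)
    y = rng.uniform(-75.0, 50.0, size=params.n_pairs)
    z = rng.uniform(-25.0, 75.0, size=params.n_pairs)
    rows = []
    for i, (pid, name) in enumerate(zip(pids, names)):
        for hemi, sign in (("L", 1.0), ("R", -1.0)):
            rows.append(
                (
                    f"{name}{hemi}",
                    f"{name}{hemi}",
                    pid,
                    hemi,
                    round(float(volumes[i]), 1),
                    round(float(sign * x[i]), 1),
                    round(float(y[i]), 1),
                    round(float(z[i]), 1),
                    "",
                )
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "region_id",
            "abbreviation",
            "pair_id",
            "hemisphere",
            "volume_mm3",
            "mni_x",
            "mni_y",
            "mni_z",
            "network_label",
        ],
    )
    return RegionTable(frame)


def generate_cohort(params: GeneratorParams) -> SyntheticCohort:
    """Generate a full cohort (regions, contrasts, raw rest series, truth)."""
    regions = _make_region_table(params)
    pids = pair_ids(params)
    modules, hubs = planted_structure(params)
    C = build_target_correlation(params)
    sigma_w = (
        calibrate_subject_sd(params, C) if params.coupling_rho != 0 else 0.0
    )
    weights = sample_subject_weights(
        params, sigma_w, derive_seed(params.seed, "weights")
    )
    partition = {}
    for m, idx in enumerate(modules):
        for i in idx:
            partition[pids[i]] = MODULE_LABELS[m]
    truth = SyntheticTruth(
        selected_set=[pids[i] for i in np.sort(np.concatenate(modules))],
        partition=partition,
        hub_set=[pids[i] for i in hubs],
        coupling_rho=params.coupling_rho,
        params=params,
        seed=params.seed,
        subject_weights=weights,
    )
    rest_subjects = [
        f"sub{i + 1:03d}" for i in range(params.n_rest_subjects)
    ]
    clean = sample_timeseries(
        C,
        params,
        derive_seed(params.seed, "timeseries"),
        weights=weights[: params.n_rest_subjects],
        subjects=rest_subjects,
    )
    clean = TimeSeriesPanel(
        clean.subjects, clean.series, regions.abbreviations("L"),
        clean.sampling_interval,
    )
    raw, nuisets = sample_nuisance(
        params, clean, derive_seed(params.seed, "nuisance")
    )
    contrasts = sample_contrasts(
        truth, params, derive_seed(params.seed, "contrasts")
    )
    return SyntheticCohort(regions, contrasts, raw, nuisets, truth, C)


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write regions.csv, contrasts.csv, timeseries/, nuisance/, truth.json."""
    os.makedirs(out_dir, exist_ok=True)
    write_region_table(cohort.regions, os.path.join(out_dir, "regions.csv"))
    write_contrast_panel(
        cohort.contrasts, os.path.join(out_dir, "contrasts.csv")
    )
    write_timeseries(cohort.rest_raw, os.path.join(out_dir, "timeseries"))
    nui_dir = os.path.join(out_dir, "nuisance")
    os.makedirs(nui_dir, exist_ok=True)
    for subj, nui in cohort.nuisance.items():
        if nui is None:
            continue
        pd.DataFrame(
            nui.regressors,
            columns=[f"nuis{i + 1}" for i in range(nui.regressors.shape[1])],
        ).to_csv(
            os.path.join(nui_dir, f"{subj}.tsv"),
            sep="\t",
            index=False,
            float_format="%.17g",
        )
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(cohort.truth.to_json(), fh, indent=1, sort_keys=True)
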