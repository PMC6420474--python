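"""Coupling between resting degree centrality and task activation.

Per region: Pearson correlations across subjects between resting DC and
left-hemisphere activation in each task, plus a repeated-measures linear
model giving a DC main effect (between subjects) and a DC x task
interaction (within subjects).  Pooled: the correlation over all
subject x region points per task, with a Steiger-type z test for
comparing two such correlations that share the DC variable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .data import ContrastPanel, DataError, TASKS


def _dc_frame(dc: pd.DataFrame, contrasts: ContrastPanel, regions: list[str]):
    missing = [r for r in regions if r not in dc.columns]
    if missing:
        raise DataError(f"DC missing for region(s) {missing[:5]}")
    if len(dc) > len(contrasts.subjects):
        raise DataError("more DC rows than contrast subjects")
    return dc[regions]


def region_coupling(
    dc: pd.DataFrame,
    contrasts: ContrastPanel,
    network_regions: list[str],
) -> pd.DataFrame:
    """Per-region DC-activation coupling table.

    ``dc`` rows are the resting-state subjects (aligned with the first
    rows of the contrast panel by subject id where available).  Columns:
    per-task Pearson r and p, the DC main-effect p (regression of the
    subject's task-mean activation on DC) and the DC x task interaction
    p (equality of task-specific slopes after within-subject centering).
    """
    dcf = _dc_frame(dc, contrasts, network_regions)
    subjects = contrasts.subjects[: len(dcf)]
    panel = contrasts.subset_subjects(subjects)
    rows = []
    n = len(subjects)
    if n <= 3:
        raise DataError("need more than 3 subjects")
    for region in network_regions:
        x = dcf[region].to_numpy(float)
        if np.allclose(x.std(), 0):
            raise DataError(f"constant DC across subjects for {region}")
        pi = panel.pair_ids.index(region) if region in panel.pair_ids else None
        acts = {}
        per_task = {}
        for task in TASKS:
            y = panel.left_values(task)[:, pi]
            acts[task] = y
            r, p = stats.pearsonr(x, y)
            per_task[task] = (float(r), float(p))
        # DC main effect: task-mean activation regressed on DC
        ymean = np.mean([acts[t] for t in TASKS], axis=0)
        main = sm.OLS(ymean, sm.add_constant(x)).fit()
        p_main = float(main.pvalues[1])
        # interaction: task-specific slopes after within-subject centering
        yc = np.concatenate([acts[t] - ymean for t in TASKS])
        task_idx = np.repeat(np.arange(3), n)
        X = np.zeros((3 * n, 6))
        for t in range(3):
            rows_t = task_idx == t
            X[rows_t, t] = 1.0
            X[rows_t, 3 + t] = np.tile(x, 3)[rows_t]
        fit = sm.OLS(yc, X).fit()
        slopes = fit.params[3:6]
        if float(np.var(fit.resid)) < 1e-18:
            # saturated fit: the interaction is exactly its point estimate
            p_inter = 1.0 if float(np.ptp(slopes)) < 1e-10 else 0.0
        else:
            # F test: the three task-specific slopes are equal
            contrast = np.zeros((2, 6))
            contrast[0, 3], contrast[0, 4] = 1.0, -1.0
            contrast[1, 4], contrast[1, 5] = 1.0, -1.0
            p_inter = float(fit.f_test(contrast).pvalue)
        rows.append(
            {
                "region": region,
                "p_dc_main": p_main,
                "p_dc_task_interaction": p_inter,
                **{
                    f"r_{t}": per_task[t][0] for t in TASKS
                },
                **{
                    f"p_{t}": per_task[t][1] for t in TASKS
                },
            }
        )
    return pd.DataFrame(rows)


def hemisphere_dc_control(
    matrices,
    all_regions: list[str],
    network_regions: list[str],
    contrasts: ContrastPanel,
    alpha: float = 1.0,
) -> pd.DataFrame:
    """Specificity control: same coupling table with hemisphere-wide DC.

    DC of each network region is recomputed as its summed positive
    correlation with *every* region of the hemisphere (``all_regions``),
    not only its own network, and the per-region coupling analysis is
    rerun; fewer significant regions than with the network DC indicates
    that the coupling is specific to within-network connectivity.
    """
    from .graph import subject_centralities

    dc, _ = subject_centralities(
        matrices, network_regions, alpha=alpha, dc_over=all_regions
    )
    return region_coupling(dc, contrasts, network_regions)


def pooled_coupling(
    dc: pd.DataFrame,
    contrasts: ContrastPanel,
    network_regions: list[str],
) -> pd.DataFrame:
    """Per-task Pearson r over all subject x region points.

    Every (subject, region) pair contributes one point; n is reported
    alongside each correlation.
    """
    dcf = _dc_frame(dc, contrasts, network_regions)
    subjects = contrasts.subjects[: len(dcf)]
    panel = contrasts.subset_subjects(subjects)
    idx = [panel.pair_ids.index(r) for r in network_regions]
    x = dcf.to_numpy(float).ravel()
    if not np.isfinite(x).all():
        raise DataError("missing DC values in pooled analysis")
    rows = []
    for task in TASKS:
        y = panel.left_values(task)[:, idx].ravel()
        r, p = stats.pearsonr(x, y)
        rows.append(
            {"task": task, "r": float(r), "p": float(p), "n": len(x)}
        )
    return pd.DataFrame(rows)


def compare_dependent_correlations(
    r1: float, r2: float, n: int, r12: float
) -> tuple[float, float]:
    """Steiger z for two overlapping dependent correlations.

    ``r1`` and ``r2`` share one variable (here DC); ``r12`` is the
    correlation between the two non-shared variables.  Returns (z, two-
    sided p).
    """
    if n <= 3:
        raise DataError("need n > 3")
    for r in (r1, r2, r12):
        if not -1 < r < 1:
            raise DataError("correlations must lie strictly in (-1, 1)")
    if r1 == r2:
        return 0.0, 1.0
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rm2 = (r1**2 + r2**2) / 2.0
    f = min((1.0 - r12) / (2.0 * (1.0 - rm2)), 1.0)
    h = (1.0 - f * rm2) / (1.0 - rm2)
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - r12) * h))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def compare_task_couplings(
    dc: pd.DataFrame,
    contrasts: ContrastPanel,
    network_regions: list[str],
) -> pd.DataFrame:
    """Pairwise Steiger comparisons of the pooled per-task correlations."""
    pooled = pooled_coupling(dc, contrasts, network_regions).set_index("task")
    dcf = _dc_frame(dc, contrasts, network_regions)
    subjects = contrasts.subjects[: len(dcf)]
    panel = contrasts.subset_subjects(subjects)
    idx = [panel.pair_ids.index(r) for r in network_regions]
    ys = {t: panel.left_values(t)[:, idx].ravel() for t in TASKS}
    n = len(dcf.to_numpy().ravel())
    rows = []
    for t1, t2 in itertools.combinations(TASKS, 2):
        r12 = float(np.corrcoef(ys[t1], ys[t2])[0, 1])
        z, p = compare_dependent_correlations(
            pooled.loc[t1, "r"], pooled.loc[t2, "r"], n, r12
        )
        rows.append(
            {
                "task_a": t1,
                "task_b": t2,
                "r_a": pooled.loc[t1, "r"],
                "r_b": pooled.loc[t2, "r"],
                "r_ab": r12,
                "z": z,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
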