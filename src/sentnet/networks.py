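"""Network profiles, profile comparisons and inter-network correlations.

A network's activation (or asymmetry) for one subject and task is the
volume-weighted mean of its member regions' values.  Profiles are
compared with a two-factor repeated-measures ANOVA (network x task) plus
Holm-corrected paired task contrasts within each network.  Inter-network
resting correlations are computed per subject from network-mean time
series, Fisher-z averaged across subjects, and tested against zero with
a one-sided exact binomial sign test in the direction of the observed
majority, Bonferroni-corrected over the number of network pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from .cluster import Partition
from .data import ContrastPanel, DataError, RegionTable, TASKS, TimeSeriesPanel

_R_CAP = 1.0 - 1e-12


@dataclass
class NetworkProfile:
    """Per-subject and cohort-level volume-weighted network profiles."""

    per_subject: pd.DataFrame  # subject, network, task, activation, asymmetry
    summary: pd.DataFrame  # network x task means +/- SD
    volumes: dict  # network -> total volume mm^3


def network_profiles(
    partition: Partition | dict,
    contrasts: ContrastPanel,
    regions: RegionTable,
) -> NetworkProfile:
    """Volume-weighted mean activation and asymmetry per network.

    For every subject, network and task:
    sum(value_i * vol_i) / sum(vol_i) over member regions, separately
    for left-hemisphere values and for left-minus-right asymmetries.
    """
    mapping = (
        partition.as_dict() if isinstance(partition, Partition) else dict(partition)
    )
    unknown = set(mapping) - set(contrasts.pair_ids)
    if unknown:
        raise DataError(f"partition regions missing from panel: {sorted(unknown)[:5]}")
    networks = sorted(set(mapping.values()))
    rows = []
    vols_by_net = {}
    for net in networks:
        members = [p for p in contrasts.pair_ids if mapping.get(p) == net]
        vols = regions.volumes(members)
        if not np.all(np.isfinite(vols)) or np.any(vols <= 0):
            raise DataError(f"network {net}: member without a valid volume")
        weights = vols / vols.sum()
        vols_by_net[net] = float(vols.sum())
        idx = [contrasts.pair_ids.index(p) for p in members]
        for task in TASKS:
            act = contrasts.left_values(task)[:, idx] @ weights
            asym = contrasts.asymmetry(task)[:, idx] @ weights
            for subj, a, s in zip(contrasts.subjects, act, asym):
                rows.append((subj, net, task, a, s))
    per_subject = pd.DataFrame(
        rows, columns=["subject", "network", "task", "activation", "asymmetry"]
    )
    summary = (
        per_subject.groupby(["network", "task"])[["activation", "asymmetry"]]
        .agg(["mean", "std"])
    )
    return NetworkProfile(per_subject, summary, vols_by_net)


def profile_comparisons(profile: NetworkProfile, measure: str = "activation"):
    """Repeated-measures ANOVA (network x task) + Holm paired contrasts.

    Returns (anova table, pairwise table).  With a single network, a
    task-only ANOVA is run instead (with a warning column in the table).
    """
    if measure not in ("activation", "asymmetry"):
        raise DataError("measure must be 'activation' or 'asymmetry'")
    df = profile.per_subject
    networks = sorted(df["network"].unique())
    if np.allclose(df[measure].std(ddof=0), 0.0):
        # no variance anywhere: every effect is null by construction
        effects = (
            ["network", "task", "network:task"] if len(networks) >= 2 else ["task"]
        )
        anova = pd.DataFrame(
            {"F Value": 0.0, "Pr > F": 1.0}, index=effects
        )
        pairwise = pd.DataFrame(
            [
                (net, t1, t2, 0.0, 0.0, 1.0)
                for net in networks
                for t1, t2 in itertools.combinations(TASKS, 2)
            ],
            columns=["network", "task_a", "task_b", "mean_diff", "t", "p"],
        )
        pairwise["p_holm"] = 1.0
        pairwise["significant_holm05"] = False
        return anova, pairwise
    if len(networks) >= 2:
        aov = AnovaRM(
            df, depvar=measure, subject="subject", within=["network", "task"]
        ).fit()
        anova = aov.anova_table
    else:
        aov = AnovaRM(
            df, depvar=measure, subject="subject", within=["task"]
        ).fit()
        anova = aov.anova_table
        anova["note"] = "single network: task-only ANOVA"
    rows = []
    for net in networks:
        sub = df[df["network"] == net].pivot(
            index="subject", columns="task", values=measure
        )
        for t1, t2 in itertools.combinations(TASKS, 2):
            diff = sub[t1] - sub[t2]
            if np.allclose(diff.std(ddof=1), 0) and np.allclose(diff.mean(), 0):
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_rel(sub[t1], sub[t2])
            rows.append((net, t1, t2, float(diff.mean()), float(t_stat), float(p)))
    pairwise = pd.DataFrame(
        rows, columns=["network", "task_a", "task_b", "mean_diff", "t", "p"]
    )
    pairwise["p_holm"] = multipletests(pairwise["p"], method="holm")[1]
    pairwise["significant_holm05"] = pairwise["p_holm"] < 0.05
    return anova, pairwise


def sign_test(n_majority: int, n: int) -> float:
    """One-sided exact binomial p for the observed majority sign.

    P(X >= n_majority) under Binomial(n, 1/2) — the probability of a
    majority at least as large as observed if signs were coin flips.
    """
    if not 0 <= n_majority <= n:
        raise DataError("majority count outside [0, n]")
    return float(
        stats.binomtest(n_majority, n, p=0.5, alternative="greater").pvalue
    )


def internetwork_correlations(
    ts: TimeSeriesPanel,
    partition: Partition | dict,
    regions: RegionTable | None = None,
    volume_weighted: bool = False,
) -> pd.DataFrame:
    """Cohort-mean correlation and sign test for every network pair.

    Per subject: network time series = mean over member regions' series
    (volume-weighted when requested); Pearson r per network pair; Fisher
    z averaged over subjects, back-transformed.  The sign test is the
    one-sided exact binomial on the majority-sign count, and the
    Bonferroni flag multiplies by the number of network pairs.
    """
    mapping = (
        partition.as_dict() if isinstance(partition, Partition) else dict(partition)
    )
    networks = sorted(set(mapping.values()))
    name_to_col = {n: i for i, n in enumerate(ts.region_names)}
    member_cols = {}
    weights = {}
    for net in networks:
        members = [r for r in mapping if mapping[r] == net]
        cols = [name_to_col[m] for m in members if m in name_to_col]
        if not cols:
            raise DataError(f"network {net} has no members in the time series")
        member_cols[net] = cols
        if volume_weighted:
            if regions is None:
                raise DataError("volume weighting requires a region table")
            abbrevs = regions.abbreviations("L")
            vol_all = regions.volumes()
            v = np.array(
                [vol_all[abbrevs.index(ts.region_names[c])] for c in cols]
            )
            weights[net] = v / v.sum()
        else:
            weights[net] = np.full(len(cols), 1.0 / len(cols))
    pairs = list(itertools.combinations(networks, 2))
    z_per_subject = {pair: [] for pair in pairs}
    for mat in ts.series:
        net_series = {
            net: mat[:, member_cols[net]] @ weights[net] for net in networks
        }
        for a, b in pairs:
            r = np.corrcoef(net_series[a], net_series[b])[0, 1]
            z_per_subject[(a, b)].append(
                np.arctanh(np.clip(r, -_R_CAP, _R_CAP))
            )
    rows = []
    n_pairs = len(pairs)
    for (a, b), zs in z_per_subject.items():
        zs = np.asarray(zs)
        n = len(zs)
        mean_r = float(np.tanh(zs.mean()))
        n_pos = int((zs > 0).sum())
        majority = max(n_pos, n - n_pos)
        majority_sign = "positive" if n_pos >= n - n_pos else "negative"
        p = sign_test(majority, n)
        rows.append(
            {
                "network_a": a,
                "network_b": b,
                "mean_r": mean_r,
                "n_subjects": n,
                "majority_sign": majority_sign,
                "majority_fraction": majority / n,
                "sign_test_p": p,
                "significant_bonferroni05": p * n_pairs < 0.05,
            }
        )
    return pd.DataFrame(rows)
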