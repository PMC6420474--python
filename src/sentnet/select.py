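"""Selection of jointly activated, jointly leftward-asymmetric regions.

A region pair is selected when, in each of the three task contrasts, its
left-hemisphere value is significantly positive AND its left-minus-right
asymmetry is significantly positive.  Per-task tests are two-sided
one-sample (activation) or paired (asymmetry) t tests with an explicit
positivity guard on the mean; the conjunction across the three tasks has
joint level alpha^3 under the conjunction null, and the conjunction of
the two conjunctions has level (alpha^3)^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .data import ContrastPanel, DataError, TASKS


@dataclass
class SelectionResult:
    per_task_stats: pd.DataFrame  # pair x task rows with both test families
    activated_set: list
    asymmetric_set: list
    selected_set: list
    alpha_per_task: float

    @property
    def conjunction_alpha(self) -> float:
        return self.alpha_per_task**3

    @property
    def overall_alpha(self) -> float:
        return self.conjunction_alpha**2

    def summary(self) -> dict:
        return {
            "alpha_per_task": self.alpha_per_task,
            "conjunction_alpha": self.conjunction_alpha,
            "overall_alpha": self.overall_alpha,
            "n_activated": len(self.activated_set),
            "n_asymmetric": len(self.asymmetric_set),
            "n_selected": len(self.selected_set),
            "activated_set": list(self.activated_set),
            "asymmetric_set": list(self.asymmetric_set),
            "selected_set": list(self.selected_set),
        }


def _per_pair_ttest(values: np.ndarray, pair_ids, alpha: float) -> pd.DataFrame:
    """Vectorised one-sample t of per-pair columns against zero.

    A pair passes iff two-sided p < alpha and its mean is positive.
    Zero-variance pairs are reported as failures with NaN statistics (and
    a warning); the run aborts only if more than 1% of pairs are
    degenerate.
    """
    n = values.shape[0]
    if n < 3:
        raise DataError("need at least 3 subjects for the per-pair t tests")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        frac = zero_var.mean()
        bad = [p for p, z in zip(pair_ids, zero_var) if z]
        if frac > 0.01:
            raise DataError(
                f"zero variance across subjects for {len(bad)} pair(s), "
                f"e.g. {bad[:5]}"
            )
        warnings.warn(
            f"zero-variance pair(s) reported as failures: {bad}",
            stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, np.nan, mean / (sd / np.sqrt(n)))
    p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    passes = (~zero_var) & (p < alpha) & (mean > 0)
    return pd.DataFrame(
        {
            "pair_id": list(pair_ids),
            "mean": mean,
            "t": t,
            "p": p,
            "passes": passes,
        }
    )


def task_activation_test(
    panel: ContrastPanel, task: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-pair t test of left-hemisphere values against zero."""
    return _per_pair_ttest(panel.left_values(task), panel.pair_ids, alpha)


def task_asymmetry_test(
    panel: ContrastPanel, task: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-pair paired t test of left - right values against zero."""
    return _per_pair_ttest(panel.asymmetry(task), panel.pair_ids, alpha)


def conjunction_select(
    panel: ContrastPanel, config: AnalysisConfig | None = None
) -> SelectionResult:
    """Intersect per-task activation and asymmetry significance.

    activated_set: pairs passing the activation test in all three tasks;
    asymmetric_set: likewise for asymmetry; selected_set: intersection,
    in the panel's canonical pair order.
    """
    config = config or AnalysisConfig()
    alpha = config.alpha_per_task
    frames = []
    act_pass = {}
    asym_pass = {}
    for task in TASKS:
        act = task_activation_test(panel, task, alpha)
        asym = task_asymmetry_test(panel, task, alpha)
        merged = act.merge(
            asym, on="pair_id", suffixes=("_activation", "_asymmetry")
        )
        merged.insert(1, "task", task)
        frames.append(merged)
        act_pass[task] = set(act.loc[act["passes"], "pair_id"])
        asym_pass[task] = set(asym.loc[asym["passes"], "pair_id"])
    activated = set.intersection(*act_pass.values())
    asymmetric = set.intersection(*asym_pass.values())
    selected = activated & asymmetric
    order = {p: i for i, p in enumerate(panel.pair_ids)}
    return SelectionResult(
        per_task_stats=pd.concat(frames, ignore_index=True),
        activated_set=sorted(activated, key=order.get),
        asymmetric_set=sorted(asymmetric, key=order.get),
        selected_set=sorted(selected, key=order.get),
        alpha_per_task=alpha,
    )
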