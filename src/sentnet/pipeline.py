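"""End-to-end pipeline: select -> cluster -> characterize -> graph -> couple.

One :class:`AnalysisConfig` and one seed reproduce the whole run; the
report is a plain nested dictionary serialisable to JSON whose bytes are
identical across reruns with the same inputs and seed (wall-clock
information goes to the log stream, never into the report).
"""

from __future__ import annotations

import json
import logging
import os
import time

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (
    adjusted_rand,
    alternative_partitions,
    bootstrap_support,
    choose_k,
    connectivity_panel,
    correlation_to_distance,
    cut_tree,
    mean_connectivity,
    ward_cluster,
)
from .config import AnalysisConfig, derive_seed
from .coupling import (
    compare_task_couplings,
    hemisphere_dc_control,
    pooled_coupling,
    region_coupling,
)
from .data import (
    DataError,
    TimeSeriesPanel,
    export_dendrogram_newick,
    load_contrast_panel,
    load_region_table,
    load_timeseries,
)
from .graph import participation_index, positive_graph, subject_centralities, summarize_and_classify
from .networks import internetwork_correlations, network_profiles, profile_comparisons
from .preprocess import NuisanceSet, bandpass_fir, clean_timeseries
from .select import conjunction_select

logger = logging.getLogger("sentnet")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - report the stage
                raise StageError(name, exc) from exc
            logger.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def _load_nuisance(input_dir, subjects):
    nui_dir = os.path.join(input_dir, "nuisance")
    if not os.path.isdir(nui_dir):
        return None
    out = {}
    for subj in subjects:
        path = os.path.join(nui_dir, f"{subj}.tsv")
        if os.path.exists(path):
            out[subj] = NuisanceSet(
                pd.read_csv(path, sep="\t").to_numpy(float)
            )
    return out or None


def run_pipeline(
    config: AnalysisConfig, input_dir, out_dir=None
) -> dict:
    """Run the full analysis chain on a cohort directory.

    Expects regions.csv, contrasts.csv and timeseries/ under
    ``input_dir`` (nuisance/ optional).  Returns the report dictionary;
    when ``out_dir`` is given, writes report.json plus the intermediate
    artifacts (selection stats, partition, support, dendrogram, metrics,
    coupling tables).
    """
    @_stage("load")
    def load():
        regions = load_region_table(os.path.join(input_dir, "regions.csv"))
        contrasts = load_contrast_panel(
            os.path.join(input_dir, "contrasts.csv"), regions
        )
        return regions, contrasts

    regions, contrasts = load()

    @_stage("select")
    def select():
        return conjunction_select(contrasts, config)

    selection = select()
    if len(selection.selected_set) < 3:
        raise StageError(
            "select",
            DataError(
                f"only {len(selection.selected_set)} regions selected; "
                "cannot cluster"
            ),
        )

    @_stage("cluster")
    def cluster():
        ts_dir = os.path.join(input_dir, "timeseries")
        if not os.path.isdir(ts_dir):
            raise DataError(f"missing time-series directory {ts_dir}")
        ts = load_timeseries(ts_dir, regions)
        # relabel columns with pair ids so every stage shares identifiers
        ts = TimeSeriesPanel(
            ts.subjects, ts.series, list(regions.pair_ids), ts.sampling_interval
        )
        nuisance = _load_nuisance(input_dir, ts.subjects)
        clean = clean_timeseries(ts, nuisance)
        filtered = bandpass_fir(
            clean,
            low=config.bandpass_low_hz,
            high=config.bandpass_high_hz,
            order=config.filter_order,
        )
        sel = filtered.subset_regions(selection.selected_set)
        mats = connectivity_panel(sel)
        mean_mat = mean_connectivity(mats)
        dist = correlation_to_distance(mean_mat)
        tree = ward_cluster(dist, mean_mat.region_names)
        k, votes = choose_k(dist, tree, config.k_range)
        partition = cut_tree(tree, k)
        subject_z = np.stack(
            [np.arctanh(m.values) for m in mats]
        )
        support = bootstrap_support(
            subject_z,
            partition,
            config,
            seed=derive_seed(config.seed, "bootstrap"),
        )
        alts = alternative_partitions(
            dist, mean_mat, k, seed=derive_seed(config.seed, "alternatives")
        )
        aris = {
            name: adjusted_rand(partition, alt) for name, alt in alts.items()
        }
        return filtered, mats, mean_mat, tree, k, votes, partition, support, aris

    (filtered, mats, mean_mat, tree, k, votes, partition, support,
     aris) = cluster()

    @_stage("characterize")
    def characterize():
        profile = network_profiles(partition, contrasts, regions)
        anova_act, pairwise_act = profile_comparisons(profile, "activation")
        anova_asym, pairwise_asym = profile_comparisons(profile, "asymmetry")
        inter = internetwork_correlations(
            filtered.subset_regions(selection.selected_set), partition
        )
        return profile, anova_act, pairwise_act, anova_asym, pairwise_asym, inter

    (profile, anova_act, pairwise_act, anova_asym, pairwise_asym,
     inter) = characterize()

    @_stage("graph")
    def graph_stage():
        core = partition.members(1)  # largest network
        dc, bc = subject_centralities(mats, core, alpha=config.opsahl_alpha)
        g_mean = positive_graph(mean_mat)
        pindex = participation_index(g_mean, partition)
        metrics = summarize_and_classify(
            dc, bc, pindex, config, n_total_regions=len(partition.region_names)
        )
        return core, dc, bc, metrics

    core, dc, bc, metrics = graph_stage()

    @_stage("couple")
    def couple():
        table = region_coupling(dc, contrasts, core)
        pooled = pooled_coupling(dc, contrasts, core)
        comparisons = compare_task_couplings(dc, contrasts, core)
        control = hemisphere_dc_control(
            mats, list(mean_mat.region_names), core, contrasts,
            alpha=config.opsahl_alpha,
        )
        return table, pooled, comparisons, control

    coupling_table, pooled, comparisons, control = couple()

    report = {
        "software_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "selection": selection.summary(),
        "clustering": {
            "k": k,
            "votes": {str(kk): int(v) for kk, v in votes["vote"].items()},
            "partition": partition.as_dict(),
            "cluster_sizes": [
                len(partition.members(lab)) for lab in range(1, k + 1)
            ],
            "support": support.table.drop(columns=["members"]).assign(
                members=[";".join(m) for m in support.table["members"]]
            ).to_dict(orient="records"),
            "method_aris": aris,
        },
        "profiles": {
            "volumes_mm3": profile.volumes,
            "summary": {
                f"{net}|{task}": {
                    "activation_mean": float(
                        profile.summary.loc[(net, task), ("activation", "mean")]
                    ),
                    "activation_sd": float(
                        profile.summary.loc[(net, task), ("activation", "std")]
                    ),
                    "asymmetry_mean": float(
                        profile.summary.loc[(net, task), ("asymmetry", "mean")]
                    ),
                    "asymmetry_sd": float(
                        profile.summary.loc[(net, task), ("asymmetry", "std")]
                    ),
                }
                for net, task in profile.summary.index
            },
            "anova_activation": anova_act.to_dict(),
            "anova_asymmetry": anova_asym.to_dict(),
        },
        "internetwork": inter.to_dict(orient="records"),
        "graph": {
            "core_regions": core,
            "dc_threshold": metrics.dc_threshold,
            "bc_threshold": metrics.bc_threshold,
            "centrality_hubs": metrics.centrality_hubs,
            "connector_hubs": metrics.connector_hubs,
            "provincial_hubs": metrics.provincial_hubs,
        },
        "coupling": {
            "per_region": coupling_table.to_dict(orient="records"),
            "pooled": pooled.to_dict(orient="records"),
            "task_comparisons": comparisons.to_dict(orient="records"),
            "hemisphere_control": control.to_dict(orient="records"),
        },
    }

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        selection.per_task_stats.to_csv(
            os.path.join(out_dir, "selection_stats.csv"), index=False
        )
        pd.Series(partition.as_dict()).rename("network").to_csv(
            os.path.join(out_dir, "partition.csv"), index_label="pair_id"
        )
        votes.to_csv(os.path.join(out_dir, "votes.csv"), index_label="k")
        with open(os.path.join(out_dir, "dendrogram.nwk"), "w") as fh:
            fh.write(export_dendrogram_newick(tree) + "\n")
        metrics.per_region.to_csv(
            os.path.join(out_dir, "graph_metrics.csv"), index=False
        )
        coupling_table.to_csv(
            os.path.join(out_dir, "coupling.csv"), index=False
        )
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
            fh.write("\n")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
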