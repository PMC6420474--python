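"""Shared data containers and tabular I/O.

All stages of the pipeline exchange four containers: a region metadata
table (homotopic left/right pairs with volumes and MNI coordinates), a
task-contrast panel (subject x pair x task x hemisphere BOLD contrast
values), a resting-state time-series panel (one T x N matrix per
subject), and a binary merge tree produced by the clustering stage.

File formats are deliberately plain: comma-separated metadata and
contrasts, tab-separated time series (one file per subject), Newick for
dendrograms.  Missing cells are errors, never imputed — the analyses
operate on complete cases only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

TASKS = ("PROD", "LISN", "READ")
HEMISPHERES = ("L", "R")

REGION_COLUMNS = [
    "region_id",
    "abbreviation",
    "pair_id",
    "hemisphere",
    "volume_mm3",
    "mni_x",
    "mni_y",
    "mni_z",
    "network_label",
]


class DataError(ValueError):
    """Raised when an input file or container violates its invariants."""


@dataclass
class RegionTable:
    """Atlas metadata: homotopic region pairs with volumes and coordinates.

    Each homotopic pair id maps to exactly one left (L) and one right (R)
    region.  Volumes are strictly positive (mm^3).  Abbreviations are
    unique within a hemisphere.  Row order is canonical: every loader
    reorders data to this order.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REGION_COLUMNS if c not in self.frame.columns]
        if missing:
            raise DataError(f"region table missing column(s): {missing}")
        df = self.frame
        bad_hemi = df[~df["hemisphere"].isin(HEMISPHERES)]
        if len(bad_hemi):
            raise DataError(
                f"invalid hemisphere value(s) in rows {list(bad_hemi.index)}"
            )
        nonpos = df[df["volume_mm3"] <= 0]
        if len(nonpos):
            raise DataError(
                "non-positive volume for region(s) "
                f"{nonpos['region_id'].tolist()}"
            )
        dup = df.duplicated(subset=["pair_id", "hemisphere"])
        if dup.any():
            rows = df[dup]
            raise DataError(
                "duplicate (pair_id, hemisphere) for rows "
                f"{rows[['pair_id', 'hemisphere']].values.tolist()}"
            )
        counts = df.groupby("pair_id")["hemisphere"].nunique()
        incomplete = counts[counts != 2]
        if len(incomplete):
            raise DataError(
                f"pair(s) without both hemispheres: {incomplete.index.tolist()}"
            )
        for hemi in HEMISPHERES:
            sub = df[df["hemisphere"] == hemi]
            if sub["abbreviation"].duplicated().any():
                dups = sub[sub["abbreviation"].duplicated()]["abbreviation"]
                raise DataError(
                    f"duplicate abbreviation(s) within hemisphere {hemi}: "
                    f"{sorted(set(dups))}"
                )

    @property
    def pair_ids(self) -> list:
        """Pair ids in first-appearance (canonical) order."""
        seen: dict = {}
        for pid in self.frame["pair_id"]:
            seen.setdefault(pid, None)
        return list(seen)

    def hemisphere_frame(self, hemisphere: str) -> pd.DataFrame:
        """Rows of one hemisphere indexed by pair_id, canonical pair order."""
        sub = self.frame[self.frame["hemisphere"] == hemisphere]
        sub = sub.set_index("pair_id").loc[self.pair_ids]
        return sub

    def abbreviations(self, hemisphere: str = "L") -> list[str]:
        return self.hemisphere_frame(hemisphere)["abbreviation"].tolist()

    def volumes(self, pair_ids: Sequence | None = None) -> np.ndarray:
        """Left-region volumes (mm^3) for the given pairs (all by default)."""
        left = self.hemisphere_frame("L")
        if pair_ids is None:
            pair_ids = self.pair_ids
        return left.loc[list(pair_ids), "volume_mm3"].to_numpy(float)

    def subset(self, pair_ids: Sequence) -> "RegionTable":
        wanted = set(pair_ids)
        return RegionTable(
            self.frame[self.frame["pair_id"].isin(wanted)].reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.pair_ids)


@dataclass
class ContrastPanel:
    """Dense subject x pair x task x hemisphere BOLD contrast values.

    ``values`` has shape (n_subjects, n_pairs, 3, 2); task axis follows
    :data:`TASKS`, hemisphere axis is (L, R).  Asymmetry is always
    left minus right (leftward positive).
    """

    subjects: list
    pair_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.subjects), len(self.pair_ids), len(TASKS), 2)
        if self.values.shape != expected:
            raise DataError(
                f"contrast panel shape {self.values.shape} != {expected}"
            )
        if not np.isfinite(self.values).all():
            raise DataError("contrast panel contains non-finite values")

    def task_index(self, task: str) -> int:
        if task not in TASKS:
            raise DataError(f"unknown task {task!r}; expected one of {TASKS}")
        return TASKS.index(task)

    def left_values(self, task: str) -> np.ndarray:
        """(n_subjects, n_pairs) left-hemisphere values for one task."""
        return self.values[:, :, self.task_index(task), 0]

    def asymmetry(self, task: str) -> np.ndarray:
        """(n_subjects, n_pairs) left - right values for one task."""
        t = self.task_index(task)
        return self.values[:, :, t, 0] - self.values[:, :, t, 1]

    def subset_pairs(self, pair_ids: Sequence) -> "ContrastPanel":
        idx = [self.pair_ids.index(p) for p in pair_ids]
        return ContrastPanel(
            list(self.subjects), list(pair_ids), self.values[:, idx]
        )

    def subset_subjects(self, subjects: Sequence) -> "ContrastPanel":
        idx = [self.subjects.index(s) for s in subjects]
        return ContrastPanel(
            list(subjects), list(self.pair_ids), self.values[idx]
        )

    def to_long(self) -> pd.DataFrame:
        rows = []
        for si, s in enumerate(self.subjects):
            for pi, p in enumerate(self.pair_ids):
                for ti, t in enumerate(TASKS):
                    for hi, h in enumerate(HEMISPHERES):
                        rows.append((s, p, t, h, self.values[si, pi, ti, hi]))
        return pd.DataFrame(
            rows, columns=["subject", "pair_id", "task", "hemisphere", "value"]
        )


@dataclass
class TimeSeriesPanel:
    """Per-subject region-level resting signal: T x N matrices.

    All subjects share the same region set and ordering (``region_names``,
    canonical RegionTable order).  ``sampling_interval`` is the repetition
    time in seconds.
    """

    subjects: list
    series: list  # list of (T_s, N) float arrays
    region_names: list[str]
    sampling_interval: float

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise DataError("sampling_interval must be > 0 seconds")
        cleaned = []
        n = len(self.region_names)
        for s, mat in zip(self.subjects, self.series):
            arr = np.asarray(mat, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != n:
                raise DataError(
                    f"subject {s}: series shape {arr.shape} incompatible "
                    f"with {n} regions"
                )
            if arr.shape[0] < 3:
                raise DataError(f"subject {s}: fewer than 3 time points")
            if not np.isfinite(arr).all():
                raise DataError(f"subject {s}: non-finite values in series")
            cleaned.append(arr)
        self.series = cleaned

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def subset_regions(self, names: Sequence[str]) -> "TimeSeriesPanel":
        idx = [self.region_names.index(nm) for nm in names]
        return TimeSeriesPanel(
            list(self.subjects),
            [mat[:, idx] for mat in self.series],
            list(names),
            self.sampling_interval,
        )

    def map(self, fn) -> "TimeSeriesPanel":
        """Apply ``fn`` (array -> array of same width) to every subject."""
        return TimeSeriesPanel(
            list(self.subjects),
            [fn(mat) for mat in self.series],
            list(self.region_names),
            self.sampling_interval,
        )


@dataclass
class MergeTree:
    """Binary agglomeration tree: (a, b, height) merges plus leaf names.

    ``linkage`` is a scipy-style (N-1) x 4 matrix; heights must be
    non-decreasing.
    """

    linkage: np.ndarray
    leaf_names: list[str]

    def __post_init__(self) -> None:
        self.linkage = np.asarray(self.linkage, dtype=float)
        n = len(self.leaf_names)
        if n == 0:
            raise DataError("merge tree has no leaves")
        if self.linkage.shape != (n - 1, 4):
            raise DataError(
                f"linkage shape {self.linkage.shape} != {(n - 1, 4)}"
            )
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise DataError("merge heights are not non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def clades(self) -> list[frozenset]:
        """Leaf-name set of every internal node, in merge order."""
        n = self.n_leaves
        sets: dict[int, frozenset] = {
            i: frozenset([self.leaf_names[i]]) for i in range(n)
        }
        out = []
        for k, (a, b, _h, _c) in enumerate(self.linkage):
            merged = sets[int(a)] | sets[int(b)]
            sets[n + k] = merged
            out.append(merged)
        return out


# ---------------------------------------------------------------------------
# Loaders / writers
# ---------------------------------------------------------------------------


def load_region_table(path) -> RegionTable:
    """Load regions.csv (see REGION_COLUMNS); row order is preserved."""
    df = pd.read_csv(path, dtype={"pair_id": str, "region_id": str})
    if "network_label" not in df.columns:
        df["network_label"] = ""
    df["network_label"] = df["network_label"].fillna("")
    try:
        return RegionTable(df)
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from exc


def write_region_table(regions: RegionTable, path) -> None:
    regions.frame.to_csv(path, index=False)


def load_contrast_panel(path, regions: RegionTable) -> ContrastPanel:
    """Load long-format contrasts.csv into a dense panel.

    Every (subject, pair, task, hemisphere) cell must be present exactly
    once; pairs are ordered canonically by ``regions``.
    """
    df = pd.read_csv(
        path, dtype={"pair_id": str}, float_precision="round_trip"
    )
    needed = {"subject", "pair_id", "task", "hemisphere", "value"}
    if not needed.issubset(df.columns):
        raise DataError(f"{path}: missing column(s) {needed - set(df.columns)}")
    known = set(regions.pair_ids)
    unknown = set(df["pair_id"]) - known
    if unknown:
        raise DataError(f"{path}: unknown pair id(s) {sorted(unknown)[:5]}")
    bad_tasks = set(df["task"]) - set(TASKS)
    if bad_tasks:
        raise DataError(f"{path}: unknown task(s) {sorted(bad_tasks)}")
    subjects = list(dict.fromkeys(df["subject"]))
    pair_ids = [p for p in regions.pair_ids if p in set(df["pair_id"])]
    cube = df.set_index(["subject", "pair_id", "task", "hemisphere"])["value"]
    if cube.index.duplicated().any():
        dup = cube.index[cube.index.duplicated()][0]
        raise DataError(f"{path}: duplicate cell {dup}")
    full = pd.MultiIndex.from_product(
        [subjects, pair_ids, list(TASKS), list(HEMISPHERES)],
        names=["subject", "pair_id", "task", "hemisphere"],
    )
    cube = cube.reindex(full)
    if cube.isna().any():
        missing = cube[cube.isna()].index[0]
        raise DataError(
            f"{path}: missing cell (subject={missing[0]}, pair={missing[1]}, "
            f"task={missing[2]}, hemisphere={missing[3]})"
        )
    values = cube.to_numpy().reshape(len(subjects), len(pair_ids), 3, 2)
    return ContrastPanel(subjects, pair_ids, values)


def write_contrast_panel(panel: ContrastPanel, path) -> None:
    panel.to_long().to_csv(path, index=False, float_format="%.17g")


def load_timeseries(directory, regions: RegionTable) -> TimeSeriesPanel:
    """Load one TSV per subject; columns reordered to RegionTable order.

    Headers must hold exactly the left-hemisphere abbreviations of
    ``regions`` (any column order).  ``sampling_interval`` is read from a
    ``sampling_interval.txt`` sidecar if present, else defaults to 2 s.
    """
    expected = regions.abbreviations("L")
    files = sorted(
        f for f in os.listdir(directory) if f.endswith(".tsv")
    )
    if not files:
        raise DataError(f"{directory}: no .tsv time-series files")
    subjects, series = [], []
    for fname in files:
        fpath = os.path.join(directory, fname)
        df = pd.read_csv(fpath, sep="\t", float_precision="round_trip")
        if set(df.columns) != set(expected):
            raise DataError(
                f"{fpath}: header does not match the region table "
                f"(missing {sorted(set(expected) - set(df.columns))[:5]}, "
                f"extra {sorted(set(df.columns) - set(expected))[:5]})"
            )
        arr = df[expected].to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = df[expected].map(
                lambda v: not isinstance(v, (int, float, np.number))
            )
            row = int(np.argwhere(bad.to_numpy())[0][0])
            raise DataError(f"{fpath}: non-numeric cell at data row {row}")
        subjects.append(fname[: -len(".tsv")])
        series.append(arr.astype(float))
    tr_path = os.path.join(directory, "sampling_interval.txt")
    tr = 2.0
    if os.path.exists(tr_path):
        with open(tr_path) as fh:
            tr = float(fh.read().strip())
    return TimeSeriesPanel(subjects, series, expected, tr)


def write_timeseries(panel: TimeSeriesPanel, directory) -> None:
    os.makedirs(directory, exist_ok=True)
    for subj, mat in zip(panel.subjects, panel.series):
        df = pd.DataFrame(mat, columns=panel.region_names)
        df.to_csv(
            os.path.join(directory, f"{subj}.tsv"),
            sep="\t",
            index=False,
            float_format="%.17g",
        )
    with open(os.path.join(directory, "sampling_interval.txt"), "w") as fh:
        fh.write(f"{panel.sampling_interval:.17g}\n")


def export_dendrogram_newick(tree: MergeTree) -> str:
    """Render a merge tree as a Newick string with branch lengths.

    Branch length of a node is its parent's merge height minus its own
    (leaves sit at height zero), so leaf-to-root path length equals the
    root merge height.
    """
    n = tree.n_leaves
    link = tree.linkage
    heights = {i: 0.0 for i in range(n)}
    for k in range(n - 1):
        heights[n + k] = float(link[k, 2])

    def render(node: int, parent_height: float) -> str:
        length = parent_height - heights[node]
        if node < n:
            name = tree.leaf_names[node]
            return f"{name}:{length:.10g}"
        a, b = int(link[node - n, 0]), int(link[node - n, 1])
        inner = f"({render(a, heights[node])},{render(b, heights[node])})"
        return f"{inner}:{length:.10g}" if node != 2 * n - 2 else inner

    if n == 1:
        return f"{tree.leaf_names[0]}:0;"
    root = 2 * n - 2
    return render(root, heights[root]) + ";"
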