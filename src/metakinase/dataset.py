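"""Labelled interaction tables, long-tail splits and support/query episodes.

The partially observed compound x kinase activity matrix is stored sparsely
as labelled (compound_id, kinase_id, label) pairs: label 1 for active
(pKi/pKd/pIC50 >= 6, i.e. <= 1 uM), 0 for inactive, absent pairs unknown.
Kinases lacking either class are dropped at build time, mirroring standard
curation of mixed-source bioactivity panels.

The long-tail protocol splits kinases into data-rich "head" tasks (500
active + 500 inactive training pairs each) and data-poor "tail" tasks
(5 + 5 support pairs; every remaining labelled pair of a tail kinase is
test).  Meta-training consumes episodes: per-kinase support/query sets
drawn without replacement and mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .seeding import substream

ACTIVITY_THRESHOLD = 6.0  # -log10 molar; >= 6 (<= 1 uM) is active
MEASURES = ("pKi", "pKd", "pIC50")

PAIR_COLUMNS = ["compound_id", "kinase_id", "label"]


def binarize_activity(value: float) -> int:
    """1 iff the -log10 molar activity is >= 6 (boundary inclusive)."""
    v = float(value)
    if not np.isfinite(v):
        raise ValueError(f"activity value must be finite, got {value!r}")
    return int(v >= ACTIVITY_THRESHOLD)


@dataclass
class InteractionTable:
    """Sparse labelled pairs of the partially observed interaction matrix."""

    pairs: pd.DataFrame  # columns compound_id, kinase_id, label

    def __post_init__(self):
        df = self.pairs
        missing = set(PAIR_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"pairs missing column(s) {sorted(missing)}")
        df = df[PAIR_COLUMNS].copy()
        df["compound_id"] = df["compound_id"].astype(str)
        df["kinase_id"] = df["kinase_id"].astype(str)
        df["label"] = df["label"].astype(int)
        if not df["label"].isin((0, 1)).all():
            raise ValueError("labels must be 0/1")
        if df.duplicated(["compound_id", "kinase_id"]).any():
            raise ValueError("duplicate (compound, kinase) pair in table")
        self.pairs = df.reset_index(drop=True)

    @property
    def n(self) -> int:
        """Distinct compound count."""
        return self.pairs["compound_id"].nunique()

    @property
    def m(self) -> int:
        """Distinct kinase count."""
        return self.pairs["kinase_id"].nunique()

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def kinases(self) -> list[str]:
        return sorted(self.pairs["kinase_id"].unique())

    @property
    def compounds(self) -> list[str]:
        return sorted(self.pairs["compound_id"].unique())

    def pairs_for(self, kinase_id: str) -> pd.DataFrame:
        return self.pairs[self.pairs["kinase_id"] == str(kinase_id)]

    def class_counts(self) -> pd.DataFrame:
        """Per-kinase (n_active, n_inactive, total) counts."""
        g = self.pairs.groupby("kinase_id")["label"]
        out = pd.DataFrame(
            {"n_active": g.sum(), "n_inactive": g.count() - g.sum(), "total": g.count()}
        )
        return out.astype(int)

    def to_tsv(self, path: str) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "InteractionTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"compound_id": str, "kinase_id": str}))


def read_activity_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"compound_id", "kinase_id", "measure", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"activity CSV missing column(s) {sorted(missing)}")
    return df


def build_table(
    records: pd.DataFrame,
    conflict_policy: str = "mean",
    exclude_kinases: Iterable[str] = (),
) -> tuple[InteractionTable, dict]:
    """Binarize activity records into an InteractionTable.

    Replicate (compound, kinase) records — including across pKi/pKd/pIC50 —
    are resolved by averaging their values before thresholding (the only
    supported ``conflict_policy``).  Kinases on ``exclude_kinases`` (e.g. a
    mutant-kinase id list) are dropped up front, and any kinase left without
    both an active and an inactive pair is removed.  Returns the table and a
    filtering report with kept/dropped counts.
    """
    if conflict_policy != "mean":
        raise ValueError(f"unsupported conflict_policy {conflict_policy!r}")
    report: dict = {
        "n_records": int(len(records)),
        "n_excluded_kinase_records": 0,
        "n_merged_duplicates": 0,
        "kinases_dropped_single_class": [],
    }
    if records.empty:
        empty = pd.DataFrame(columns=PAIR_COLUMNS)
        return InteractionTable(empty), report

    df = records.copy()
    df["compound_id"] = df["compound_id"].astype(str)
    df["kinase_id"] = df["kinase_id"].astype(str)
    if "measure" in df.columns:
        bad = set(df["measure"].unique()) - set(MEASURES)
        if bad:
            raise ValueError(f"unknown measure(s) {sorted(bad)}; expected {MEASURES}")
    if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
        raise ValueError("activity values must be finite")

    excl = {str(k) for k in exclude_kinases}
    if excl:
        mask = df["kinase_id"].isin(excl)
        report["n_excluded_kinase_records"] = int(mask.sum())
        df = df[~mask]

    merged = (
        df.groupby(["compound_id", "kinase_id"], as_index=False)["value"].mean()
    )
    report["n_merged_duplicates"] = int(len(df) - len(merged))
    merged["label"] = (merged["value"] >= ACTIVITY_THRESHOLD).astype(int)

    per_kinase = merged.groupby("kinase_id")["label"].agg(["min", "max"])
    single_class = per_kinase[per_kinase["min"] == per_kinase["max"]].index
    report["kinases_dropped_single_class"] = sorted(single_class)
    merged = merged[~merged["kinase_id"].isin(single_class)]

    table = InteractionTable(merged[PAIR_COLUMNS].reset_index(drop=True))
    report["n_pairs"] = len(table)
    report["n_kinases"] = table.m
    report["n_compounds"] = table.n
    return table, report


@dataclass
class Episode:
    """One kinase's support and query sets (mutually exclusive pairs)."""

    kinase_id: str
    support: pd.DataFrame  # columns compound_id, label
    query: pd.DataFrame

    def __post_init__(self):
        s = set(self.support["compound_id"])
        q = set(self.query["compound_id"])
        if s & q:
            raise ValueError(f"support/query overlap for {self.kinase_id}: {sorted(s & q)}")


@dataclass
class LongTailSplit:
    """Head training pools, tail supports and tail test sets, by kinase."""

    head_support: dict[str, pd.DataFrame]
    tail_support: dict[str, pd.DataFrame]
    tail_test: dict[str, pd.DataFrame]
    head_per_class: int
    tail_per_class: int
    seed: int

    @property
    def head_kinases(self) -> list[str]:
        return sorted(self.head_support)

    @property
    def tail_kinases(self) -> list[str]:
        return sorted(self.tail_support)

    def to_manifest(self) -> dict:
        def pairs(df: pd.DataFrame) -> list[list]:
            return df[["compound_id", "label"]].to_numpy().tolist()

        return {
            "head_per_class": self.head_per_class,
            "tail_per_class": self.tail_per_class,
            "seed": self.seed,
            "head": {k: pairs(v) for k, v in self.head_support.items()},
            "tail_support": {k: pairs(v) for k, v in self.tail_support.items()},
            "tail_test": {k: pairs(v) for k, v in self.tail_test.items()},
        }

    @classmethod
    def from_manifest(cls, manifest: Mapping) -> "LongTailSplit":
        def df(rows, kid):
            out = pd.DataFrame(rows, columns=["compound_id", "label"])
            out["kinase_id"] = kid
            out["label"] = out["label"].astype(int)
            return out[PAIR_COLUMNS]

        return cls(
            head_support={k: df(v, k) for k, v in manifest["head"].items()},
            tail_support={k: df(v, k) for k, v in manifest["tail_support"].items()},
            tail_test={k: df(v, k) for k, v in manifest["tail_test"].items()},
            head_per_class=int(manifest["head_per_class"]),
            tail_per_class=int(manifest["tail_per_class"]),
            seed=int(manifest["seed"]),
        )


def _sample_per_class(
    pool: pd.DataFrame, n_per_class: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw n_per_class pairs of each label without replacement, sorted pool order."""
    parts = []
    for label in (1, 0):
        cls = pool[pool["label"] == label].sort_values("compound_id")
        if len(cls) < n_per_class:
            raise ValueError(
                f"kinase {pool['kinase_id'].iat[0]!r}: need {n_per_class} pairs of "
                f"class {label}, have {len(cls)}"
            )
        idx = rng.choice(len(cls), size=n_per_class, replace=False)
        parts.append(cls.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)


def long_tail_split(
    table: InteractionTable,
    head_count: int,
    head_per_class: int = 500,
    tail_per_class: int = 5,
    seed: int = 0,
) -> LongTailSplit:
    """Split kinases into head and tail tasks and sample their training pairs.

    Head eligibility requires >= head_per_class pairs of each class; the
    ``head_count`` most populous eligible kinases (descending total pairs,
    lexicographic id tie-break) become head tasks and contribute exactly
    head_per_class + head_per_class seeded training pairs each.  Every other
    kinase with >= tail_per_class of each class and at least one further
    labelled pair becomes a tail task: 5+5-style support, all remaining
    pairs test.  Deterministic for a given seed; per-kinase draws use
    independent substreams so they do not depend on kinase order.
    """
    counts = table.class_counts()
    eligible = counts[
        (counts["n_active"] >= head_per_class) & (counts["n_inactive"] >= head_per_class)
    ]
    if len(eligible) < head_count:
        raise ValueError(
            f"requested {head_count} head kinases but only {len(eligible)} are "
            f"eligible (need >= {head_per_class} pairs of each class); "
            f"per-kinase counts:\n{counts.to_string()}"
        )
    order = eligible.reset_index().sort_values(
        ["total", "kinase_id"], ascending=[False, True]
    )
    head_ids = list(order["kinase_id"].iloc[:head_count])

    head_support: dict[str, pd.DataFrame] = {}
    for kid in head_ids:
        rng = substream(seed, "split", "head", kid)
        head_support[kid] = _sample_per_class(table.pairs_for(kid), head_per_class, rng)

    tail_support: dict[str, pd.DataFrame] = {}
    tail_test: dict[str, pd.DataFrame] = {}
    for kid in table.kinases:
        if kid in head_support:
            continue
        row = counts.loc[kid]
        if (
            row["n_active"] < tail_per_class
            or row["n_inactive"] < tail_per_class
            or row["total"] < 2 * tail_per_class + 1
        ):
            continue
        rng = substream(seed, "split", "tail", kid)
        pool = table.pairs_for(kid)
        support = _sample_per_class(pool, tail_per_class, rng)
        chosen = set(support["compound_id"])
        tail_support[kid] = support
        tail_test[kid] = pool[~pool["compound_id"].isin(chosen)].reset_index(drop=True)

    return LongTailSplit(
        head_support=head_support,
        tail_support=tail_support,
        tail_test=tail_test,
        head_per_class=head_per_class,
        tail_per_class=tail_per_class,
        seed=seed,
    )


def sample_episode(
    pool: pd.DataFrame | InteractionTable,
    kinase_id: str,
    n_support_per_class: int = 5,
    n_query_per_class: int = 10,
    rng: np.random.Generator | None = None,
) -> Episode:
    """Draw a support/query episode for one kinase without replacement.

    ``pool`` is either a full InteractionTable or a per-kinase pair frame
    (e.g. a head task's training pairs).  Support and query are mutually
    exclusive and hit their per-class counts exactly.
    """
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(pool, InteractionTable):
        pool = pool.pairs_for(kinase_id)
    else:
        pool = pool[pool["kinase_id"] == str(kinase_id)]
    need = n_support_per_class + n_query_per_class
    for label in (1, 0):
        have = int((pool["label"] == label).sum())
        if have < need:
            raise ValueError(
                f"kinase {kinase_id!r}: need {need} pairs of class {label} "
                f"for a {n_support_per_class}+{n_query_per_class} episode, have {have}"
            )
    drawn = _sample_per_class(pool, need, rng)
    support_parts, query_parts = [], []
    for label in (1, 0):
        cls = drawn[drawn["label"] == label].reset_index(drop=True)
        perm = rng.permutation(len(cls))
        support_parts.append(cls.iloc[perm[:n_support_per_class]])
        query_parts.append(cls.iloc[perm[n_support_per_class:]])
    return Episode(
        kinase_id=str(kinase_id),
        support=pd.concat(support_parts, ignore_index=True),
        query=pd.concat(query_parts, ignore_index=True),
    )


SIZE_BINS = ((1, 99), (100, 499), (500, 999), (1000, None))


def summarize_table(table: InteractionTable) -> dict:
    """Per-kinase sample-count histogram over the long-tail size bins."""
    totals = (
        table.class_counts()["total"] if len(table) else pd.Series(dtype=int)
    )
    bins = {}
    for lo, hi in SIZE_BINS:
        name = f"{lo}-{hi}" if hi is not None else f">={lo}"
        mask = totals >= lo
        if hi is not None:
            mask &= totals <= hi
        bins[name] = int(mask.sum())
    return {"bins": bins, "per_kinase": {k: int(v) for k, v in totals.items()}}
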