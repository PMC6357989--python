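"""Classification-tree pooling of survey rows and response assignment.

A small needs-assessment survey cannot be matched one-to-one to a
country-scale synthetic population.  Instead, a single multi-target
classification tree partitions the survey rows on the three predictors
every synthetic household also carries — ethnicity, household size, and
household age structure — using the mean Gini impurity reduction across
seven binary need indicators as the split criterion.  Sparse leaves are
merged into a fixed number of pools (five by default), and every
synthetic household is routed down the tree to its pool and assigned a
survey row drawn uniformly (with replacement) from that pool.  The
household then inherits the row's full response vector, from which the
seven binary need flags are derived.

The tree is fully deterministic: greedy best split, ties broken by
predictor order (ethnicity < household_size < age_structure) and then
by the lowest threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .survey import AGE_STRUCTURES, SurveyRecord, age_structure, compute_scores
from .synthpop import SyntheticHousehold

PREDICTORS = ("ethnicity", "household_size", "age_structure")

#: the seven binary need indicators carried through to the maps
NEED_FLAGS = (
    "no_electricity",
    "severe_poverty",
    "insecure_housing",
    "no_improved_water",
    "diarrhea",
    "low_education",
    "rural",
)

LOW_EDUCATION_GRADE = 8  # adverse: not educated beyond 8th grade


def row_need_flags(record: SurveyRecord) -> dict[str, int]:
    """The seven binary need flags of one survey row (1 = adverse).

    ``rural`` is geographic rather than need-based but is carried as a
    layer alongside the others.
    """
    scores = compute_scores(record)
    return {
        "no_electricity": int(not record.electricity),
        "severe_poverty": int(not record.spends_over_2usd),
        "insecure_housing": int(scores.insecure_housing_flag),
        "no_improved_water": int(not record.piped_tap),
        "diarrhea": int(record.diarrhea_mod_severe),
        "low_education": int(record.education_grade <= LOW_EDUCATION_GRADE),
        "rural": int(record.geography_class == "rural"),
    }


def indicator_matrix(records: Sequence[SurveyRecord]) -> np.ndarray:
    """(n, 7) matrix of the need flags for every survey row."""
    return np.array(
        [[row_need_flags(r)[f] for f in NEED_FLAGS] for r in records], dtype=float
    )


def _predictor_vector(ethnicity: str, household_size: int, age_struct: str) -> np.ndarray:
    return np.array(
        [
            1.0 if ethnicity == "roma" else 0.0,
            float(household_size),
            float(AGE_STRUCTURES.index(age_struct)),
        ]
    )


def predictor_matrix(records: Sequence[SurveyRecord]) -> np.ndarray:
    """(n, 3) numeric predictor matrix: roma flag, size, age-structure level."""
    return np.array(
        [
            _predictor_vector(r.ethnicity, r.household_size, age_structure(r))
            for r in records
        ]
    )


@dataclass
class TreeNode:
    """Binary tree node; leaves carry the member survey row indices."""

    depth: int
    rows: np.ndarray
    split_var: int | None = None  # index into PREDICTORS; None for a leaf
    threshold: float | None = None  # left child: x[split_var] <= threshold
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    node_id: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()  # type: ignore[union-attr]

    def route(self, x: np.ndarray) -> "TreeNode":
        node = self
        while not node.is_leaf:
            if x[node.split_var] <= node.threshold:  # type: ignore[index]
                node = node.left  # type: ignore[assignment]
            else:
                node = node.right  # type: ignore[assignment]
        return node

    def render(self, names: Sequence[str] = PREDICTORS, indent: str = "") -> str:
        if self.is_leaf:
            return f"{indent}leaf[{self.node_id}] n={len(self.rows)}\n"
        head = (
            f"{indent}{names[self.split_var]} <= {self.threshold:g} "
            f"(node {self.node_id})\n"
        )
        return (
            head
            + self.left.render(names, indent + "  ")  # type: ignore[union-attr]
            + self.right.render(names, indent + "  ")  # type: ignore[union-attr]
        )


def mean_gini(Y: np.ndarray) -> float:
    """Mean binary Gini impurity across indicator columns."""
    if Y.shape[0] == 0:
        return 0.0
    p = Y.mean(axis=0)
    return float(np.mean(2.0 * p * (1.0 - p)))


def best_split(
    X: np.ndarray, Y: np.ndarray, rows: np.ndarray, min_leaf: int
) -> tuple[int, float, float] | None:
    """Best (predictor, threshold, gain) for one node; None if no gain.

    Evaluates every midpoint between consecutive distinct predictor
    values, in predictor order then ascending threshold, keeping the
    first split attaining the maximal impurity reduction.
    """
    parent = mean_gini(Y[rows])
    n = len(rows)
    best: tuple[int, float, float] | None = None
    for j in range(X.shape[1]):
        vals = np.unique(X[rows, j])
        if vals.size < 2:
            continue
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2.0
            mask = X[rows, j] <= thr
            nl = int(mask.sum())
            if nl < min_leaf or n - nl < min_leaf:
                continue
            child = (
                nl * mean_gini(Y[rows[mask]]) + (n - nl) * mean_gini(Y[rows[~mask]])
            ) / n
            gain = parent - child
            if gain > 1e-12 and (best is None or gain > best[2] + 1e-12):
                best = (j, thr, gain)
    return best


def fit_tree(
    records: Sequence[SurveyRecord] | None = None,
    indicators: np.ndarray | None = None,
    max_depth: int = 4,
    min_leaf: int = 1,
    X: np.ndarray | None = None,
) -> TreeNode:
    """Fit the multi-target classification tree on the survey.

    Parameters
    ----------
    records
        Survey rows; predictor and indicator matrices are derived from
        them unless ``X``/``indicators`` are given explicitly.
    max_depth, min_leaf
        Stopping rules; growth also stops on zero impurity gain.
    """
    if X is None:
        if records is None:
            raise ValueError("provide records or X")
        X = predictor_matrix(records)
    if indicators is None:
        if records is None:
            raise ValueError("provide records or indicators")
        indicators = indicator_matrix(records)
    Y = np.asarray(indicators, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("predictor/indicator row mismatch")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 survey rows")

    counter = [0]

    def grow(rows: np.ndarray, depth: int) -> TreeNode:
        node = TreeNode(depth=depth, rows=rows, node_id=counter[0])
        counter[0] += 1
        if depth >= max_depth:
            return node
        found = best_split(X, Y, rows, min_leaf)
        if found is None:
            return node
        j, thr, _ = found
        node.split_var = j
        node.threshold = thr
        mask = X[rows, j] <= thr
        node.left = grow(rows[mask], depth + 1)
        node.right = grow(rows[~mask], depth + 1)
        return node

    return grow(np.arange(X.shape[0]), 0)


@dataclass
class Pool:
    pool_id: int
    leaf_ids: list[int]
    rows: np.ndarray


@dataclass
class PoolSet:
    """Merged leaf pools; routing goes leaf -> pool."""

    pools: list[Pool]
    leaf_to_pool: dict[int, int]
    tree: TreeNode
    under_target: bool = False  # fewer pools than requested

    def route(self, ethnicity: str, household_size: int, age_struct: str) -> Pool:
        leaf = self.tree.route(_predictor_vector(ethnicity, household_size, age_struct))
        return self.pools[self.leaf_to_pool[leaf.node_id]]


def _leaf_paths(tree: TreeNode) -> dict[int, tuple[int, ...]]:
    """node_id -> path of ancestor node ids from the root, per leaf."""
    paths: dict[int, tuple[int, ...]] = {}

    def walk(node: TreeNode, path: tuple[int, ...]) -> None:
        if node.is_leaf:
            paths[node.node_id] = path + (node.node_id,)
            return
        walk(node.left, path + (node.node_id,))  # type: ignore[arg-type]
        walk(node.right, path + (node.node_id,))  # type: ignore[arg-type]

    walk(tree, ())
    return paths


def _lca_depth(p1: tuple[int, ...], p2: tuple[int, ...]) -> int:
    d = 0
    for a, b in zip(p1, p2):
        if a != b:
            break
        d += 1
    return d


def merge_to_pools(tree: TreeNode, target: int = 5, min_rows: int = 2) -> PoolSet:
    """Merge tree leaves into ``target`` pools of at least ``min_rows`` rows.

    Sparse leaves are absorbed by the pool sharing the deepest common
    ancestor (the tree's own notion of predicate similarity); then the
    smallest pools are pairwise merged, again preferring the deepest
    common ancestor, until the target count is reached.
    """
    paths = _leaf_paths(tree)
    # working pools: list of [leaf_ids, row arrays]
    pools: list[Pool] = [
        Pool(pool_id=i, leaf_ids=[leaf.node_id], rows=leaf.rows)
        for i, leaf in enumerate(tree.leaves())
    ]

    def pool_path_depth(p: Pool, q: Pool) -> int:
        return max(
            _lca_depth(paths[a], paths[b]) for a in p.leaf_ids for b in q.leaf_ids
        )

    def merge(i: int, j: int) -> None:
        keep, gone = pools[i], pools[j]
        keep.leaf_ids = keep.leaf_ids + gone.leaf_ids
        keep.rows = np.concatenate([keep.rows, gone.rows])
        del pools[j]

    def partner_for(i: int) -> int:
        cands = [j for j in range(len(pools)) if j != i]
        return max(
            cands,
            key=lambda j: (
                pool_path_depth(pools[i], pools[j]),
                -len(pools[j].rows),
                -j,
            ),
        )

    # 1) absorb sparse pools
    while len(pools) > 1:
        sparse = [i for i in range(len(pools)) if len(pools[i].rows) < min_rows]
        if not sparse:
            break
        i = min(sparse, key=lambda k: (len(pools[k].rows), k))
        j = partner_for(i)
        merge(min(i, j), max(i, j))
    # 2) reduce to the target count
    while len(pools) > target:
        i = min(range(len(pools)), key=lambda k: (len(pools[k].rows), k))
        j = partner_for(i)
        merge(min(i, j), max(i, j))

    under = len(pools) < target
    for k, p in enumerate(pools):
        p.pool_id = k
        p.rows = np.sort(p.rows)
    leaf_to_pool = {lid: p.pool_id for p in pools for lid in p.leaf_ids}
    return PoolSet(pools=pools, leaf_to_pool=leaf_to_pool, tree=tree, under_target=under)


def assign_responses(
    households: Sequence[SyntheticHousehold],
    pools: PoolSet,
    records: Sequence[SurveyRecord],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Assign each synthetic household a survey row from its pool.

    Returns a DataFrame with ``household_id``, ``pool_id``,
    ``survey_row`` (index into ``records``) and the seven binarized
    need flags inherited from the assigned row.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    flag_matrix = indicator_matrix(records).astype(int)
    out = {
        "household_id": [],
        "commune_id": [],
        "county_id": [],
        "pool_id": [],
        "survey_row": [],
    }
    for h in households:
        pool = pools.route(h.ethnicity, h.size, h.age_structure)
        row = int(pool.rows[rng.integers(len(pool.rows))])
        out["household_id"].append(h.household_id)
        out["commune_id"].append(h.commune_id)
        out["county_id"].append(h.county_id)
        out["pool_id"].append(pool.pool_id)
        out["survey_row"].append(row)
    df = pd.DataFrame(out)
    flags = pd.DataFrame(
        flag_matrix[df["survey_row"].to_numpy()], columns=list(NEED_FLAGS)
    )
    return pd.concat([df, flags], axis=1)


def binarize_indicators(assignment: pd.DataFrame) -> pd.DataFrame:
    """The per-household need-flag columns of an assignment table."""
    return assignment[list(NEED_FLAGS)].copy()
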