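"""Cross-validation split constructors.

Four strategies, each producing a :class:`SplitPlan` partition of complex
ids into k folds (default k=5):

- random: uniform shuffle, fold sizes differing by at most one;
- ligand scaffold: k-means clustering of ligand fingerprints, cluster =
  fold, so chemically similar ligands share a fold;
- protein classes: whole protein families packed greedily (largest first)
  into folds, so no family ever spans two folds;
- protein classes balanced: stratified dealing, every fold receiving
  ≈ 1/k of each family.

All four are also usable as scikit-learn cross-validators via ``split()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans
from sklearn.model_selection import BaseCrossValidator

__all__ = [
    "SplitPlan",
    "RandomSplit",
    "ScaffoldSplit",
    "ProteinClassSplit",
    "BalancedProteinClassSplit",
]


@dataclass
class SplitPlan:
    """A reproducible k-fold assignment of complex ids."""

    strategy: str
    k: int
    seed: int | None
    assignment: dict  # complex_id -> fold index in [0, k)

    def __post_init__(self):
        folds = set(self.assignment.values())
        if folds and not folds <= set(range(self.k)):
            raise ValueError("fold indices must lie in [0, k)")

    def fold_of(self, ids) -> np.ndarray:
        return np.array([self.assignment[i] for i in ids], dtype=int)

    def fold_members(self, fold: int) -> list:
        return [i for i, f in self.assignment.items() if f == fold]

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"strategy": self.strategy, "k": self.k, "seed": self.seed,
             "assignment": self.assignment},
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "SplitPlan":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        return cls(strategy=data["strategy"], k=data["k"], seed=data["seed"],
                   assignment=data["assignment"])


class _PlanSplitter(BaseCrossValidator):
    """Shared scikit-learn cross-validator plumbing."""

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return self.k

    def _iter_test_masks(self, X=None, y=None, groups=None):
        plan = self._plan_for(X, groups)
        folds = plan.fold_of(self._ids_for(X))
        for f in range(self.k):
            yield folds == f

    @staticmethod
    def _ids_for(X):
        n = len(X)
        return [str(i) for i in range(n)]

    def split(self, X, y=None, groups=None):
        indices = np.arange(len(X))
        for test_mask in self._iter_test_masks(X, y, groups):
            yield indices[~test_mask], indices[test_mask]


class RandomSplit(_PlanSplitter):
    """Completely random split; fold sizes differ by at most one."""

    def __init__(self, k: int = 5, seed: int | None = None):
        self.k = k
        self.seed = seed

    def plan(self, ids) -> SplitPlan:
        ids = list(ids)
        if self.k > len(ids):
            raise ValueError(f"k={self.k} exceeds the number of complexes ({len(ids)})")
        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(len(ids))
        assignment = {}
        for fold, chunk in enumerate(np.array_split(perm, self.k)):
            for i in chunk:
                assignment[ids[i]] = fold
        return SplitPlan("random", self.k, self.seed, assignment)

    def _plan_for(self, X, groups):
        return self.plan(self._ids_for(X))


class ScaffoldSplit(_PlanSplitter):
    """Ligand-scaffold split: k-means clusters of fingerprint bit vectors
    (euclidean metric, seeded initialization) become the folds.

    Cluster sizes are inherently unequal — that is the point of a scaffold
    split, not a defect.
    """

    def __init__(self, k: int = 5, seed: int | None = None):
        self.k = k
        self.seed = seed

    def plan(self, ids, fingerprints) -> SplitPlan:
        ids = list(ids)
        fps = np.asarray(fingerprints, dtype=float)
        if fps.shape[0] != len(ids):
            raise ValueError("one fingerprint row per complex required")
        n_distinct = len(np.unique(fps, axis=0))
        if n_distinct < self.k:
            raise ValueError(
                f"only {n_distinct} distinct fingerprints for k={self.k} clusters"
            )
        km = KMeans(n_clusters=self.k, random_state=self.seed, n_init=10)
        labels = km.fit_predict(fps)
        return SplitPlan("ligand_scaffold", self.k, self.seed,
                         dict(zip(ids, (int(l) for l in labels))))

    def _plan_for(self, X, groups):
        return self.plan(self._ids_for(X), X)


class ProteinClassSplit(_PlanSplitter):
    """Protein-family split: whole families are packed into folds by
    greedy largest-first bin packing on complex counts; no family spans
    two folds."""

    def __init__(self, k: int = 5):
        self.k = k
        self.seed = None

    def plan(self, ids, families) -> SplitPlan:
        ids = list(ids)
        fam = self._family_list(ids, families)
        groups: dict[str, list] = {}
        for cid, f in zip(ids, fam):
            groups.setdefault(f, []).append(cid)
        if len(groups) < self.k:
            raise ValueError(f"need at least k={self.k} families, got {len(groups)}")
        loads = np.zeros(self.k, dtype=int)
        assignment = {}
        for f in sorted(groups, key=lambda f: (-len(groups[f]), f)):
            fold = int(np.argmin(loads))  # ties -> lowest fold index
            loads[fold] += len(groups[f])
            for cid in groups[f]:
                assignment[cid] = fold
        return SplitPlan("protein_classes", self.k, None, assignment)

    @staticmethod
    def _family_list(ids, families):
        if isinstance(families, dict):
            return [families[i] for i in ids]
        families = list(families)
        if len(families) != len(ids):
            raise ValueError("families must map every complex id")
        return families

    def _plan_for(self, X, groups):
        return self.plan(self._ids_for(X), list(groups))


class BalancedProteinClassSplit(_PlanSplitter):
    """Stratified family split: within each family, members are shuffled
    and dealt round-robin (seeded starting fold), so each fold's
    validation set holds ≈ 1/k of every family — exactly 1/k when the
    family size is divisible by k."""

    def __init__(self, k: int = 5, seed: int | None = None, val_fraction: float | None = None):
        if val_fraction is not None and abs(val_fraction - 1.0 / k) > 1e-9:
            raise ValueError("val_fraction must equal 1/k for a k-fold scheme")
        self.k = k
        self.seed = seed

    def plan(self, ids, families) -> SplitPlan:
        ids = list(ids)
        fam = ProteinClassSplit._family_list(ids, families)
        groups: dict[str, list] = {}
        for cid, f in zip(ids, fam):
            groups.setdefault(f, []).append(cid)
        rng = np.random.default_rng(self.seed)
        assignment = {}
        for f in sorted(groups):
            members = groups[f]
            order = rng.permutation(len(members))
            offset = int(rng.integers(self.k))
            for j, m in enumerate(order):
                assignment[members[m]] = (offset + j) % self.k
        return SplitPlan("protein_classes_balanced", self.k, self.seed, assignment)

    def _plan_for(self, X, groups):
        return self.plan(self._ids_for(X), list(groups))
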