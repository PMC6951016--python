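"""Dataset splitting and per-task target normalization.

Splits follow the MoleculeNet-style protocol: train/valid/test in fixed
ratios (80/10/10 by default), either uniformly at random under a fixed seed
or by Bemis-Murcko scaffold so that no scaffold class spans two sets.
Regression targets are standardized per task on training-set statistics and
predictions are mapped back to original units before scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem_graph import SmilesParseError

__all__ = ["SplitSpec", "NormalizationStats", "random_split",
           "murcko_scaffold", "scaffold_split", "fit_normalization",
           "save_split", "load_split"]


@dataclass
class SplitSpec:
    """Materialized train/valid/test membership."""

    method: str                       # "random" | "scaffold"
    ratios: tuple[float, float, float]
    seed: int | None
    train: np.ndarray
    valid: np.ndarray
    test: np.ndarray

    def __post_init__(self):
        self.train = np.asarray(self.train, dtype=np.intp)
        self.valid = np.asarray(self.valid, dtype=np.intp)
        self.test = np.asarray(self.test, dtype=np.intp)
        sets = [set(self.train), set(self.valid), set(self.test)]
        if (sets[0] & sets[1]) or (sets[0] & sets[2]) or (sets[1] & sets[2]):
            raise ValueError("split index lists must be disjoint")

    @property
    def n(self) -> int:
        return len(self.train) + len(self.valid) + len(self.test)


def _check_ratios(ratios) -> tuple[float, float, float]:
    r = tuple(float(x) for x in ratios)
    if len(r) != 3 or abs(sum(r) - 1.0) > 1e-8:
        raise ValueError(f"ratios must be 3 fractions summing to 1, got {ratios}")
    return r


def random_split(n: int, ratios=(0.8, 0.1, 0.1), seed: int = 0) -> SplitSpec:
    """Uniform random split, deterministic for fixed (n, ratios, seed)."""
    ratios = _check_ratios(ratios)
    if n < 3:
        raise ValueError("need at least 3 rows to form three sets")
    perm = np.random.default_rng(seed).permutation(n)
    # round to ratios but keep all three sets non-empty
    n_train = max(1, min(int(round(ratios[0] * n)), n - 2))
    n_valid = max(1, min(int(round(ratios[1] * n)), n - n_train - 1))
    return SplitSpec("random", ratios, seed, perm[:n_train],
                     perm[n_train:n_train + n_valid], perm[n_train + n_valid:])


def murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis-Murcko scaffold: ring systems plus linkers.

    Acyclic molecules map to the empty string (one shared scaffold class).
    """
    try:
        return MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles)
    except Exception as exc:  # RDKit raises bare ValueError on parse failure
        raise SmilesParseError(f"cannot derive scaffold for {smiles!r}") from exc


def scaffold_split(smiles_list: list[str],
                   ratios=(0.8, 0.1, 0.1)) -> SplitSpec:
    """Greedy scaffold-grouped split with zero scaffold leakage.

    Scaffold groups, largest first (ties by scaffold string), fill train
    until its target size, then valid, then test. A group larger than the
    whole train allocation is still placed in train.
    """
    import warnings

    ratios = _check_ratios(ratios)
    n = len(smiles_list)
    groups: dict[str, list[int]] = {}
    for i, smi in enumerate(smiles_list):
        groups.setdefault(murcko_scaffold(smi), []).append(i)

    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    if len(ordered) == 1:
        warnings.warn("all molecules share one scaffold; everything assigned "
                      "to the training set")
    n_train, n_valid = round(ratios[0] * n), round(ratios[1] * n)
    train, valid, test = [], [], []
    for scaffold, members in ordered:
        if len(train) + len(members) <= n_train or not train:
            train.extend(members)
        elif len(valid) + len(members) <= n_valid or not valid:
            valid.extend(members)
        else:
            test.extend(members)
    if not test:
        warnings.warn("scaffold split produced an empty test set")
    return SplitSpec("scaffold", ratios, None, train, valid, test)


@dataclass
class NormalizationStats:
    """Per-task mean/std fitted on observed training cells only."""

    mean: np.ndarray
    std: np.ndarray
    task_names: list[str]

    def transform(self, labels: np.ndarray) -> np.ndarray:
        return (labels - self.mean) / self.std

    def inverse(self, labels: np.ndarray) -> np.ndarray:
        return labels * self.std + self.mean


def fit_normalization(train_labels: np.ndarray, mask: np.ndarray,
                      task_names: list[str] | None = None) -> NormalizationStats:
    """Fit per-task standardization over observed training cells.

    Sample standard deviation (ddof=1); a constant task is an error because
    its normalized values would be undefined.
    """
    train_labels = np.asarray(train_labels, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    n_tasks = train_labels.shape[1]
    task_names = task_names or [f"task_{j}" for j in range(n_tasks)]
    mean = np.empty(n_tasks)
    std = np.empty(n_tasks)
    for j in range(n_tasks):
        vals = train_labels[mask[:, j], j]
        if len(vals) < 2:
            raise ValueError(f"task {task_names[j]!r} has <2 observed "
                             "training values; cannot normalize")
        mean[j] = vals.mean()
        std[j] = vals.std(ddof=1)
        if std[j] <= 0:
            raise ValueError(f"task {task_names[j]!r} is constant on the "
                             "training set; cannot normalize")
    return NormalizationStats(mean, std, task_names)


def save_split(split: SplitSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump({"method": split.method, "ratios": list(split.ratios),
                   "seed": split.seed,
                   "train": split.train.tolist(),
                   "valid": split.valid.tolist(),
                   "test": split.test.tolist()}, fh)


def load_split(path) -> SplitSpec:
    with open(path) as fh:
        d = json.load(fh)
    return SplitSpec(d["method"], tuple(d["ratios"]), d["seed"],
                     d["train"], d["valid"], d["test"])
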