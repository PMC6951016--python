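"""SMD (Standardised Missing Data) preprocessing.

Sparse multitask bioactivity tables usually arrive with unlabelled cells
imputed as inactive, which injects a large artificial class imbalance. SMD
preprocessing (a) replaces every structure by its charge parent — the
uncharged form of the largest organic covalent unit of a salt or complex —
and (b) turns empty cells back into explicit missing-value masks so they can
be excluded from losses and metrics downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .chem_graph import SmilesParseError

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = ["TaskTable", "LabelCensus", "charge_parent", "apply_smd",
           "census", "read_task_table", "write_task_table"]

MISSING_MARKERS = ("", "NA")


@dataclass
class TaskTable:
    """Aligned SMILES, per-task labels, and an observed-cell mask."""

    smiles: list[str]
    labels: np.ndarray                 # [n_molecules, n_tasks]
    mask: np.ndarray                   # [n_molecules, n_tasks] bool, True = observed
    task_names: list[str]
    task_kind: str = "classification"  # "classification" | "regression"

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.labels.shape != self.mask.shape:
            raise ValueError("labels and mask must have identical shape")
        if self.labels.shape[0] != len(self.smiles):
            raise ValueError("row count mismatch between smiles and labels")

    @property
    def n_molecules(self) -> int:
        return len(self.smiles)

    @property
    def n_tasks(self) -> int:
        return self.labels.shape[1]

    def subset(self, indices) -> "TaskTable":
        idx = np.asarray(indices, dtype=np.intp)
        return TaskTable([self.smiles[i] for i in idx], self.labels[idx],
                         self.mask[idx], list(self.task_names), self.task_kind)


@dataclass
class LabelCensus:
    """Per-task and total label accounting for a classification table.

    Two active-fraction conventions are reported: over all cells with missing
    imputed as inactive (the "original dataset" convention), and over
    observed cells only (the SMD convention). Both are None when undefined.
    """

    actives: np.ndarray
    inactives: np.ndarray
    missing: np.ndarray
    task_names: list[str] = field(default_factory=list)

    @property
    def total_actives(self) -> int:
        return int(self.actives.sum())

    @property
    def total_inactives(self) -> int:
        return int(self.inactives.sum())

    @property
    def total_missing(self) -> int:
        return int(self.missing.sum())

    @property
    def n_cells(self) -> int:
        return self.total_actives + self.total_inactives + self.total_missing

    @property
    def missing_ratio(self) -> float:
        return self.total_missing / self.n_cells

    @property
    def active_fraction_imputed(self) -> float | None:
        """Actives over all cells, missing counted as inactive."""
        return self.total_actives / self.n_cells if self.n_cells else None

    @property
    def active_fraction_observed(self) -> float | None:
        """Actives over observed cells only."""
        obs = self.total_actives + self.total_inactives
        return self.total_actives / obs if obs else None

    def to_dict(self) -> dict:
        return {
            "per_task": {name: {"actives": int(a), "inactives": int(i),
                                "missing": int(m)}
                         for name, a, i, m in zip(self.task_names, self.actives,
                                                  self.inactives, self.missing)},
            "total": {"actives": self.total_actives,
                      "inactives": self.total_inactives,
                      "missing": self.total_missing},
            "missing_ratio": self.missing_ratio,
            "active_fraction_imputed": self.active_fraction_imputed,
            "active_fraction_observed": self.active_fraction_observed,
        }


def charge_parent(smiles: str) -> str:
    """Uncharged canonical form of the largest organic covalent unit.

    Neutralization that is chemically impossible (e.g. quaternary nitrogen)
    keeps the charge on the retained fragment and is logged. Idempotent on
    its own output.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    parent = rdMolStandardize.ChargeParent(mol)
    out = Chem.MolToSmiles(parent)
    if Chem.GetFormalCharge(parent) != 0:
        logger.info("charge retained after standardization: %s -> %s",
                    smiles, out)
    return out


def read_task_table(path, smiles_col: str = "smiles",
                    task_kind: str = "classification",
                    missing_markers=MISSING_MARKERS) -> TaskTable:
    """Read a delimited table (MoleculeNet CSV dialect) into a TaskTable.

    Empty cells (and any string in ``missing_markers``) mark missing labels.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return task_table_from_frame(df, smiles_col, task_kind, missing_markers)


def task_table_from_frame(df: pd.DataFrame, smiles_col: str = "smiles",
                          task_kind: str = "classification",
                          missing_markers=MISSING_MARKERS) -> TaskTable:
    if smiles_col not in df.columns:
        raise KeyError(f"no SMILES column {smiles_col!r} in table "
                       f"(columns: {list(df.columns)})")
    task_names = [c for c in df.columns if c != smiles_col]
    raw = df[task_names].astype(str).map(str.strip)
    mask = ~raw.isin(missing_markers).to_numpy()
    labels = np.zeros(mask.shape)
    vals = raw.to_numpy()
    labels[mask] = np.array([float(v) for v in vals[mask]])
    return TaskTable(df[smiles_col].tolist(), labels, mask, task_names, task_kind)


def write_task_table(table: TaskTable, path, smiles_col: str = "smiles") -> None:
    """Write back in the same dialect; masked cells become empty."""
    cols = {smiles_col: table.smiles}
    for j, name in enumerate(table.task_names):
        col = []
        for i in range(table.n_molecules):
            if table.mask[i, j]:
                v = table.labels[i, j]
                col.append(str(int(v)) if table.task_kind == "classification"
                           and float(v).is_integer() else repr(float(v)))
            else:
                col.append("")
        cols[name] = col
    pd.DataFrame(cols).to_csv(path, index=False)


def apply_smd(table: TaskTable) -> TaskTable:
    """Charge-parent standardize the SMILES column of a table.

    Missing-label masks are already explicit on a TaskTable (empty source
    cells were masked at read time); this step standardizes structures and
    drops — with a logged count — the rows whose standardization fails.
    """
    keep, std_smiles = [], []
    n_failed = 0
    for i, smi in enumerate(table.smiles):
        try:
            std_smiles.append(charge_parent(smi))
            keep.append(i)
        except SmilesParseError:
            n_failed += 1
    if n_failed:
        logger.warning("dropped %d molecules that failed standardization",
                       n_failed)
    idx = np.asarray(keep, dtype=np.intp)
    return TaskTable(std_smiles, table.labels[idx], table.mask[idx],
                     list(table.task_names), table.task_kind)


def census(table: TaskTable) -> LabelCensus:
    """Count actives / inactives / missing per task and overall."""
    if table.task_kind != "classification":
        raise ValueError("census is defined for classification tables only")
    obs = table.mask
    actives = ((table.labels == 1.0) & obs).sum(axis=0)
    inactives = ((table.labels == 0.0) & obs).sum(axis=0)
    missing = (~obs).sum(axis=0)
    return LabelCensus(actives.astype(int), inactives.astype(int),
                       missing.astype(int), list(table.task_names))


def impute_missing_as_inactive(table: TaskTable) -> TaskTable:
    """The "original dataset" convention: unlabelled cells become inactive."""
    labels = table.labels.copy()
    labels[~table.mask] = 0.0
    return TaskTable(list(table.smiles), labels,
                     np.ones_like(table.mask, dtype=bool),
                     list(table.task_names), table.task_kind)
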