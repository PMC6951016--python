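"""Synthetic molecule sets and label tables with known generative rules.

Every label rule is a deterministic function of the molecular graph, so a
model that learns a fixture task can be checked against the generative
formula (the recovery oracle). Molecules are assembled from a small fragment
grammar — rings, chains, heteroatoms, optionally charged salt pairs — and
capped at 12 heavy atoms so exhaustive brute-force oracles stay fast.

The generated tables use the same delimited-text dialect as real benchmark
CSVs (one SMILES column, one column per task, empty cell = missing label),
so fixtures flow through preprocessing, splitting and training unchanged.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .preprocess import TaskTable

__all__ = ["TaskSpec", "FixtureSpec", "gen_molecules", "gen_labels",
           "make_fixture_table", "LABEL_RULES"]

MAX_HEAVY_ATOMS = 12

_SCAFFOLDS = ("c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cnccn1",
              "C1CCCCC1", "C1CCNCC1", "C1CCOC1", "C1CCCC1", "C1CCNC1")
_CHAINS = ("C", "CC", "CCC", "CCO", "CCN", "CO", "CN", "CS", "CCl", "CBr",
           "C(F)(F)F", "C(=O)C", "C(=O)O", "C(C)C", "CC#N", "C=C")
_SALTS = ("{core}C(=O)[O-].[Na+]", "{core}C(=O)[O-].[K+]",
          "{core}[NH3+].[Cl-]", "{core}S(=O)(=O)[O-].[Na+]")


# ---- label rules (each: canonical deterministic function of the graph) ----

def _mol(smiles: str) -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise ValueError(f"fixture rule got unparseable SMILES {smiles!r}")
    return m


def _n_aromatic_atoms(s):  # regression
    return float(sum(a.GetIsAromatic() for a in _mol(s).GetAtoms()))


def _n_heavy_atoms(s):  # regression
    return float(_mol(s).GetNumAtoms())


_ADDITIVE_WEIGHTS = {"C": 0.5, "N": 1.2, "O": -0.7, "S": 0.8}


def _additive_atom_property(s):
    """Graph-additive regression target: sum of per-element contributions
    plus a bonus per aromatic atom. Exactly representable by a summed
    readout, hence the parameter-recovery task."""
    m = _mol(s)
    total = 0.0
    for a in m.GetAtoms():
        total += _ADDITIVE_WEIGHTS.get(a.GetSymbol(), 0.3)
        if a.GetIsAromatic():
            total += 0.3
    return total


def _aromatic_ring_present(s):  # classification
    return 1.0 if any(a.GetIsAromatic() for a in _mol(s).GetAtoms()) else 0.0


def _ring_present(s):
    return 1.0 if _mol(s).GetRingInfo().NumRings() > 0 else 0.0


def _contains_nitrogen(s):
    return 1.0 if any(a.GetSymbol() == "N" for a in _mol(s).GetAtoms()) else 0.0


def _contains_oxygen(s):
    return 1.0 if any(a.GetSymbol() == "O" for a in _mol(s).GetAtoms()) else 0.0


def _hash_bernoulli(s, rate=0.5):
    """Deterministic pseudo-label: active iff a hash of the canonical SMILES
    falls below `rate`. Matches a requested active rate in expectation while
    remaining a pure function of the molecule (used for census-style
    fixtures, not for learnability tests)."""
    canon = Chem.MolToSmiles(_mol(s))
    h = int(hashlib.sha256(canon.encode()).hexdigest()[:12], 16)
    return 1.0 if (h / 16 ** 12) < rate else 0.0


LABEL_RULES = {
    "n_aromatic_atoms": _n_aromatic_atoms,
    "n_heavy_atoms": _n_heavy_atoms,
    "additive_atom_property": _additive_atom_property,
    "aromatic_ring_present": _aromatic_ring_present,
    "ring_present": _ring_present,
    "contains_nitrogen": _contains_nitrogen,
    "contains_oxygen": _contains_oxygen,
}


_CLASSIFICATION_RULES = frozenset({"aromatic_ring_present", "ring_present",
                                   "contains_nitrogen", "contains_oxygen"})


@dataclass(frozen=True)
class TaskSpec:
    """One synthetic task: a named rule plus sparsity / rate knobs."""

    name: str
    rule: str
    missing_rate: float = 0.0
    active_rate: float | None = None   # hash_bernoulli tasks only
    noise_sd: float = 0.0              # regression label noise


@dataclass
class FixtureSpec:
    n_molecules: int = 100
    scaffold_diversity: int = 10       # how many ring scaffolds to draw from
    salt_fraction: float = 0.0         # fraction built as charged salt pairs
    tasks: list[TaskSpec] = field(default_factory=lambda: [
        TaskSpec("aromatic", "aromatic_ring_present")])
    seed: int = 0


def gen_molecules(spec: FixtureSpec) -> list[str]:
    """Deterministic, deduplicated canonical SMILES from the fragment grammar."""
    if spec.n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(spec.seed)
    scaffolds = _SCAFFOLDS[:max(1, min(spec.scaffold_diversity,
                                       len(_SCAFFOLDS)))]
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < spec.n_molecules:
        attempts += 1
        if attempts > 200 * spec.n_molecules:
            raise RuntimeError(
                "fragment grammar exhausted before reaching "
                f"{spec.n_molecules} unique molecules (got {len(out)})")
        if rng.random() < spec.salt_fraction:
            core = str(rng.choice(_CHAINS + scaffolds))
            smi = str(rng.choice(_SALTS)).format(core=core)
        else:
            mode = rng.random()
            if mode < 0.25:  # acyclic chain only
                smi = str(rng.choice(_CHAINS)) + str(rng.choice(_CHAINS))
            elif mode < 0.65:  # one substituent on a scaffold
                smi = str(rng.choice(_CHAINS)) + str(rng.choice(scaffolds))
            else:  # substituents on both ends of a scaffold
                smi = (str(rng.choice(_CHAINS)) + str(rng.choice(scaffolds))
                       + str(rng.choice(_CHAINS)))
        mol = Chem.MolFromSmiles(smi)
        if mol is None or mol.GetNumAtoms() > MAX_HEAVY_ATOMS:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        out.append(canon)
    return out


def gen_labels(molecules: list[str], spec: FixtureSpec) -> TaskTable:
    """Label a molecule list under the FixtureSpec's task rules and rates."""
    rng = np.random.default_rng(spec.seed + 1)
    n, t = len(molecules), len(spec.tasks)
    labels = np.zeros((n, t))
    mask = np.ones((n, t), dtype=bool)
    kinds = set()
    for j, task in enumerate(spec.tasks):
        if task.active_rate is not None:
            values = np.array([_hash_bernoulli(s, task.active_rate)
                               for s in molecules])
            kinds.add("classification")
        else:
            if task.rule not in LABEL_RULES:
                raise ValueError(f"unknown label rule {task.rule!r}")
            fn = LABEL_RULES[task.rule]
            values = np.array([fn(s) for s in molecules])
            kinds.add("classification" if task.rule in _CLASSIFICATION_RULES
                      else "regression")
        if task.noise_sd > 0:
            values = values + rng.normal(0.0, task.noise_sd, size=n)
        labels[:, j] = values
        if task.missing_rate > 0:
            mask[:, j] = rng.random(n) >= task.missing_rate
    kind = "classification" if kinds == {"classification"} else "regression"
    return TaskTable(list(molecules), labels, mask,
                     [task.name for task in spec.tasks], kind)


def make_fixture_table(spec: FixtureSpec) -> TaskTable:
    """Generate molecules and labels in one call."""
    return gen_labels(gen_molecules(spec), spec)
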