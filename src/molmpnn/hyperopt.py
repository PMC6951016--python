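"""Bayesian hyperparameter optimization over the per-architecture domains.

A Gaussian-process surrogate (Matern kernel) is fit to the evaluated
(configuration, score) history; Expected Improvement proposes the next
configuration, and Local Penalisation discounts the acquisition near points
already chosen within a batch so that batch suggestions spread out.
Continuous dimensions are scaled to [0, 1] (the learning rate on a log
scale); discrete dimensions are one-hot encoded as categoricals.

The search domains (per architecture):

========================  ==================  ==================  ==================
hyperparameter            selu-mpnn           ampnn               emnn
========================  ==================  ==================  ==================
learn_rate                1e-6 .. 1e-4 (log)  same                same
message_size              {10,16,25,40}       same                n/a
message_passes            1 .. 10             1 .. 10             1 .. 8
msg_hidden_dim            {50,85,150}         same                same
gather_width              {30,45,70,100}      same                same
gather_emb_hidden_dim     {15,26,45,80}       same                {15,26,45}
gather_att_hidden_dim     {15,26,45,80}       same                {15,26,45}
out_hidden_dim            {360,450,560}       same                same
out_dropout_p             0.0 .. 0.1          same                same
out_layer_shrinkage       0.2 .. 0.6          same                same
att_hidden_dim            n/a                 {50,85,150}         {50,85,150}
edge_emb_hidden_dim       n/a                 n/a                 {60,105,180}
edge_embedding_size       n/a                 n/a                 {30,50,80}
========================  ==================  ==================  ==================
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm as _norm
from scipy.stats import qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .models import ARCHITECTURES, ModelConfig

__all__ = ["Dimension", "SearchDomain", "build_domain", "suggest_batch",
           "optimize", "OptimizationRecord"]

N_INITIAL_DESIGN = 5


@dataclass(frozen=True)
class Dimension:
    """One hyperparameter: continuous (lo, hi[, log]) or a discrete choice list."""

    name: str
    kind: str                          # "continuous" | "discrete"
    low: float = 0.0
    high: float = 1.0
    log: bool = False
    choices: tuple = ()

    def sample(self, rng: np.random.Generator):
        if self.kind == "discrete":
            return self.choices[rng.integers(len(self.choices))]
        u = rng.random()
        return self._from_unit(u)

    def _from_unit(self, u: float):
        if self.log:
            return math.exp(math.log(self.low)
                            + u * (math.log(self.high) - math.log(self.low)))
        return self.low + u * (self.high - self.low)

    def to_unit(self, value) -> float:
        if self.log:
            return ((math.log(value) - math.log(self.low))
                    / (math.log(self.high) - math.log(self.low)))
        return (value - self.low) / (self.high - self.low)

    def contains(self, value) -> bool:
        if self.kind == "discrete":
            return value in self.choices
        return self.low - 1e-12 <= value <= self.high + 1e-12

    @property
    def encoded_width(self) -> int:
        return len(self.choices) if self.kind == "discrete" else 1

    def encode(self, value) -> np.ndarray:
        if self.kind == "discrete":
            v = np.zeros(len(self.choices))
            v[self.choices.index(value)] = 1.0
            return v
        return np.array([self.to_unit(value)])


@dataclass
class SearchDomain:
    """Ordered set of dimensions defining the hyperparameter space."""

    architecture: str
    dimensions: list[Dimension] = field(default_factory=list)

    def sample(self, rng: np.random.Generator) -> dict:
        return {d.name: d.sample(rng) for d in self.dimensions}

    def sample_unit(self, unit_row: np.ndarray) -> dict:
        """Map a point of the unit hypercube to a configuration."""
        out = {}
        for d, u in zip(self.dimensions, unit_row):
            if d.kind == "discrete":
                out[d.name] = d.choices[min(int(u * len(d.choices)),
                                            len(d.choices) - 1)]
            else:
                out[d.name] = d._from_unit(float(u))
        return out

    def contains(self, params: dict) -> bool:
        return all(d.contains(params[d.name]) for d in self.dimensions)

    def encode(self, params: dict) -> np.ndarray:
        return np.concatenate([d.encode(params[d.name])
                               for d in self.dimensions])

    def to_config(self, params: dict) -> ModelConfig:
        cfg = ModelConfig(architecture=self.architecture, att_hidden_dim=None,
                          message_size=None, edge_emb_hidden_dim=None,
                          edge_embedding_size=None)
        for k, v in params.items():
            setattr(cfg, k, v)
        cfg.validate()
        return cfg


def build_domain(architecture: str) -> SearchDomain:
    """The per-architecture search domain (see module docstring)."""
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    emnn = architecture == "emnn"
    dims = [Dimension("learn_rate", "continuous", 1e-6, 1e-4, log=True)]
    if not emnn:
        dims.append(Dimension("message_size", "discrete",
                              choices=(10, 16, 25, 40)))
    dims += [
        Dimension("message_passes", "discrete",
                  choices=tuple(range(1, 9 if emnn else 11))),
        Dimension("msg_hidden_dim", "discrete", choices=(50, 85, 150)),
        Dimension("gather_width", "discrete", choices=(30, 45, 70, 100)),
        Dimension("gather_emb_hidden_dim", "discrete",
                  choices=(15, 26, 45) if emnn else (15, 26, 45, 80)),
        Dimension("gather_att_hidden_dim", "discrete",
                  choices=(15, 26, 45) if emnn else (15, 26, 45, 80)),
        Dimension("out_hidden_dim", "discrete", choices=(360, 450, 560)),
        Dimension("out_dropout_p", "continuous", 0.0, 0.1),
        Dimension("out_layer_shrinkage", "continuous", 0.2, 0.6),
    ]
    if architecture in ("ampnn", "emnn"):
        dims.append(Dimension("att_hidden_dim", "discrete",
                              choices=(50, 85, 150)))
    if emnn:
        dims += [Dimension("edge_emb_hidden_dim", "discrete",
                           choices=(60, 105, 180)),
                 Dimension("edge_embedding_size", "discrete",
                           choices=(30, 50, 80))]
    return SearchDomain(architecture, dims)


# ---------------------------------------------------------------------------

def _expected_improvement(mu: np.ndarray, sigma: np.ndarray,
                          best: float) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return (mu - best) * _norm.cdf(z) + sigma * _norm.pdf(z)


def _local_penalty(X: np.ndarray, chosen: np.ndarray, mu_chosen: np.ndarray,
                   sigma_chosen: np.ndarray, lipschitz: float,
                   best: float) -> np.ndarray:
    """Gonzalez-style soft penalizer around already-selected batch points."""
    pen = np.ones(len(X))
    for xj, mj, sj in zip(chosen, mu_chosen, sigma_chosen):
        d = np.linalg.norm(X - xj, axis=1)
        z = (lipschitz * d - (best - mj)) / (math.sqrt(2.0) * max(sj, 1e-9))
        pen *= np.clip(_norm.cdf(z), 1e-12, 1.0)
    return pen


def _initial_design(domain: SearchDomain, n: int,
                    rng: np.random.Generator) -> list[dict]:
    """Quasi-random (Sobol) space-filling points before the GP takes over."""
    sob = qmc.Sobol(d=len(domain.dimensions),
                    seed=int(rng.integers(2 ** 31)))
    n_pow2 = 1 << (n - 1).bit_length()
    rows = sob.random(n_pow2)[:n]
    return [domain.sample_unit(r) for r in rows]


def suggest_batch(history: list[tuple[dict, float]], domain: SearchDomain,
                  batch_size: int = 1, rng: np.random.Generator | None = None,
                  n_candidates: int = 512) -> list[dict]:
    """Propose ``batch_size`` distinct in-domain configurations (maximization).

    With fewer evaluations than the initial design size, quasi-random
    space-filling points are returned; afterwards a GP surrogate with EI and
    local penalization selects from a random candidate pool.
    """
    rng = rng or np.random.default_rng(0)
    if len(history) < N_INITIAL_DESIGN:
        pts, seen = [], {tuple(domain.encode(p).round(12)) for p, _ in history}
        for p in _initial_design(domain, N_INITIAL_DESIGN + batch_size, rng):
            key = tuple(domain.encode(p).round(12))
            if key not in seen:
                pts.append(p)
                seen.add(key)
            if len(pts) == batch_size:
                break
        while len(pts) < batch_size:
            pts.append(domain.sample(rng))
        return pts

    X = np.array([domain.encode(p) for p, _ in history])
    y = np.array([s for _, s in history], dtype=np.float64)
    y_mean, y_std = y.mean(), max(y.std(), 1e-12)
    yn = (y - y_mean) / y_std
    kernel = ConstantKernel(1.0) * Matern(length_scale=1.0, nu=2.5) \
        + WhiteKernel(noise_level=1e-6, noise_level_bounds=(1e-10, 1e-1))
    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=False,
                                  random_state=int(rng.integers(2 ** 31)))
    with warnings.catch_warnings():
        # kernel hyperparameter bounds routinely pinch on tiny histories
        warnings.simplefilter("ignore")
        gp.fit(X, yn)

    cand_params = [domain.sample(rng) for _ in range(n_candidates)]
    Xc = np.array([domain.encode(p) for p in cand_params])
    mu, sigma = gp.predict(Xc, return_std=True)
    best = yn.max()
    # crude Lipschitz estimate from the history
    lip = 0.0
    for i in range(len(X)):
        for j in range(i + 1, len(X)):
            d = np.linalg.norm(X[i] - X[j])
            if d > 1e-12:
                lip = max(lip, abs(yn[i] - yn[j]) / d)
    lip = max(lip, 1e-6)

    chosen, chosen_enc, chosen_mu, chosen_sigma = [], [], [], []
    used = set()
    ei = _expected_improvement(mu, sigma, best)
    for _ in range(batch_size):
        score = ei * (_local_penalty(Xc, np.array(chosen_enc), chosen_mu,
                                     chosen_sigma, lip, best)
                      if chosen_enc else 1.0)
        order = np.argsort(-score)
        pick = next((k for k in order
                     if tuple(Xc[k].round(12)) not in used), None)
        if pick is None:
            cand = domain.sample(rng)
            chosen.append(cand)
            chosen_enc.append(domain.encode(cand))
            chosen_mu.append(0.0)
            chosen_sigma.append(1.0)
            continue
        used.add(tuple(Xc[pick].round(12)))
        chosen.append(cand_params[pick])
        chosen_enc.append(Xc[pick])
        chosen_mu.append(mu[pick])
        chosen_sigma.append(sigma[pick])
    return chosen


@dataclass
class OptimizationRecord:
    """Audit trail of one optimization run."""

    architecture: str
    maximize: bool
    evaluations: list[dict] = field(default_factory=list)  # params, score, ok
    best_params: dict | None = None
    best_score: float = -np.inf

    def to_dict(self) -> dict:
        return {"architecture": self.architecture, "maximize": self.maximize,
                "evaluations": self.evaluations,
                "best_params": self.best_params,
                "best_score": self.best_score}


def optimize(objective, domain: SearchDomain, budget: int,
             maximize: bool = True, batch_size: int = 1,
             seed: int = 0) -> OptimizationRecord:
    """Run Bayesian optimization of ``objective(params) -> float``.

    AUC-style metrics are maximized; error metrics should be passed with
    ``maximize=False`` (they are negated internally). An objective that
    raises is recorded as a failure at the worst observed score and the
    search continues.
    """
    rng = np.random.default_rng(seed)
    record = OptimizationRecord(domain.architecture, maximize)
    history: list[tuple[dict, float]] = []
    sign = 1.0 if maximize else -1.0
    while len(record.evaluations) < budget:
        k = min(batch_size, budget - len(record.evaluations))
        batch = suggest_batch(history, domain, batch_size=k, rng=rng)
        for params in batch:
            try:
                raw = float(objective(params))
                ok = True
            except Exception as exc:  # noqa: BLE001 - failures scored worst-case
                raw, ok = np.nan, False
            internal = sign * raw if ok and np.isfinite(raw) else None
            if internal is None:
                floor = min((s for _, s in history), default=0.0)
                internal = floor - 1.0
            history.append((params, internal))
            record.evaluations.append(
                {"params": params, "score": None if not ok else raw, "ok": ok})
            if internal > record.best_score:
                record.best_score = internal
                record.best_params = params
    return record
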