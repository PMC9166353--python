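"""Generators with known ground truth: Yule trees, model-driven traits,
phylogenetically correlated regression data, pairwise dN/dS tables and
codon-alignment pairs. Every generator is a pure function of its arguments
including the mandatory seed."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .tree_core import (
    Node,
    Tree,
    eb_covariance,
    ou_covariance,
    transform_lambda,
    trend_covariance,
    vcv,
)
from .dnds_pipeline import _CODE, _NUCS, _STOPS, _aa

__all__ = [
    "SimSpec",
    "simulate_yule",
    "simulate_trait",
    "simulate_regression",
    "simulate_pairwise_dnds",
    "make_codon_pair",
]


@dataclass
class SimSpec:
    """Declarative description of one synthetic dataset."""

    n_tips: int
    seed: int
    birth_rate: float = 1.0
    model: str = "bm"
    params: dict[str, float] = field(default_factory=dict)
    beta: tuple[float, ...] = ()
    resid_lambda: float = 1.0
    resid_sigma2: float = 1.0


def simulate_yule(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0, jitter: float = 0.0
) -> Tree:
    """Pure-birth tree with exponential waiting times and exactly ``n_tips``
    tips. ``jitter`` > 0 multiplies each branch by an independent lognormal
    factor (sigma = jitter) to emulate a non-ultrametric substitution tree."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    root = Node()
    # active lineages carry the time at which their branch started
    active: list[tuple[Node, float]] = []
    for _ in range(2):
        child = Node()
        root.add_child(child)
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = rng.integers(len(active))
        node, t0 = active.pop(i)
        node.length = t - t0
        for _ in range(2):
            child = Node()
            node.add_child(child)
            active.append((child, t))
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for node, t0 in active:
        node.length = t - t0
    tree = Tree(root, validate=False)
    for i, tip in enumerate(tree.tips):
        tip.label = f"t{i + 1}"
    if jitter > 0:
        for node in tree.iter_nodes():
            if node.parent is not None:
                node.length *= float(rng.lognormal(0.0, jitter))
    return Tree(tree.root)


def _model_mean_cov(
    tree: Tree, model: str, params: dict[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Mean vector and full covariance (sigma2 folded in) for a named model."""
    p = dict(params)
    sigma2 = p.get("sigma2", 1.0)
    z0 = p.get("z0", 0.0)
    C = vcv(tree)
    n = C.n
    mean = np.full(n, z0)
    if model == "bm":
        V = sigma2 * C.values
    elif model == "white":
        V = sigma2 * np.eye(n)
    elif model == "lambda":
        V = sigma2 * transform_lambda(C, p["lambda"]).values
    elif model == "ou":
        V = ou_covariance(tree, p["alpha"], sigma2).values
    elif model == "eb":
        V = eb_covariance(tree, p["a"], sigma2).values
    elif model == "trend":
        V = trend_covariance(tree, sigma2, p["slope"]).values
    elif model == "drift":
        V = sigma2 * C.values
        mean = z0 + p["drift"] * C.values.diagonal()
    else:
        raise ValueError(f"unknown model {model!r}")
    return mean, V


def simulate_trait(
    tree: Tree, model: str = "bm", params: dict[str, float] | None = None, seed: int = 0
) -> np.ndarray:
    """Draw one tip-trait vector from MVN(m(theta), V(theta)) via a
    symmetric (Cholesky) factor of V. sigma2 = 0 returns a constant z0."""
    params = params or {}
    mean, V = _model_mean_cov(tree, model, params)
    if params.get("sigma2", 1.0) == 0.0:
        return mean.copy()
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(mean)))
    return mean + L @ rng.standard_normal(len(mean))


def simulate_regression(
    tree: Tree,
    beta: tuple[float, ...] | np.ndarray,
    resid_lambda: float = 1.0,
    resid_sigma2: float = 1.0,
    x_mode: str = "iid",
    intercept: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Regression data with phylogenetically correlated residuals of known
    lambda: y = intercept + X beta + eps, eps ~ MVN(0, sigma2 * C_lambda).

    Predictor columns are iid standard normal (``x_mode='iid'``) or BM
    traits on the same tree (``x_mode='bm'``).
    """
    beta = np.asarray(beta, dtype=float)
    rng = np.random.default_rng(seed)
    n = tree.n_tips
    C = vcv(tree)
    cols = {}
    for j in range(beta.shape[0]):
        if x_mode == "iid":
            cols[f"x{j + 1}"] = rng.standard_normal(n)
        elif x_mode == "bm":
            L = np.linalg.cholesky(C.values + 1e-12 * np.eye(n))
            cols[f"x{j + 1}"] = L @ rng.standard_normal(n)
        else:
            raise ValueError(f"unknown x_mode {x_mode!r}")
    X = pd.DataFrame(cols, index=tree.tip_labels)
    Vr = resid_sigma2 * transform_lambda(C, resid_lambda).values
    if resid_sigma2 == 0.0:
        eps = np.zeros(n)
    else:
        L = np.linalg.cholesky(Vr + 1e-12 * np.eye(n))
        eps = L @ rng.standard_normal(n)
    y = intercept + X.to_numpy() @ beta + eps
    return y, X


def simulate_pairwise_dnds(
    n_genera: int,
    genomes_per_genus: int,
    seed: int = 0,
    ds_low: float = 0.0,
    ds_high: float = 2.0,
    omega_mu: float = np.log(0.1),
    omega_sigma: float = 0.5,
) -> pd.DataFrame:
    """All-vs-all pairwise dN/dS rows per genus with dS uniform on
    (ds_low, ds_high] and omega lognormal — known survival fractions under
    the divergence filters."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_genera):
        genus = f"g{g + 1:03d}"
        genomes = [f"{genus}_acc{i + 1:02d}" for i in range(genomes_per_genus)]
        for a, b in combinations(genomes, 2):
            ds = float(rng.uniform(ds_low, ds_high))
            omega = float(rng.lognormal(omega_mu, omega_sigma))
            rows.append(
                {
                    "genus": genus,
                    "genome_a": a,
                    "genome_b": b,
                    "dN": omega * ds,
                    "dS": ds,
                    "omega": omega,
                }
            )
    return pd.DataFrame(rows)


# single-nucleotide codon changes classified once at import
_SYN_CHANGES: list[tuple[str, int, str]] = []
_NONSYN_CHANGES: list[tuple[str, int, str]] = []
for _codon in sorted(_CODE.forward_table):
    for _pos in range(3):
        for _nt in _NUCS:
            if _nt == _codon[_pos]:
                continue
            _alt = _codon[:_pos] + _nt + _codon[_pos + 1 :]
            if _alt in _STOPS:
                continue
            if _aa(_alt) == _aa(_codon):
                _SYN_CHANGES.append((_codon, _pos, _nt))
            else:
                _NONSYN_CHANGES.append((_codon, _pos, _nt))


def make_codon_pair(
    n_codons: int, n_syn_changes: int, n_nonsyn_changes: int, seed: int = 0
) -> tuple[str, str]:
    """A gap-free codon-alignment pair differing by exactly the requested
    numbers of single-nucleotide synonymous and nonsynonymous substitutions,
    each at a distinct codon."""
    if n_syn_changes + n_nonsyn_changes > n_codons:
        raise ValueError("more requested changes than codons")
    rng = np.random.default_rng(seed)
    sense = sorted(_CODE.forward_table)
    codons1: list[str] = []
    codons2: list[str] = []
    slots = list(rng.permutation(n_codons))
    syn_slots = set(slots[:n_syn_changes])
    nonsyn_slots = set(slots[n_syn_changes : n_syn_changes + n_nonsyn_changes])
    for i in range(n_codons):
        if i in syn_slots:
            codon, pos, nt = _SYN_CHANGES[rng.integers(len(_SYN_CHANGES))]
            codons1.append(codon)
            codons2.append(codon[:pos] + nt + codon[pos + 1 :])
        elif i in nonsyn_slots:
            codon, pos, nt = _NONSYN_CHANGES[rng.integers(len(_NONSYN_CHANGES))]
            codons1.append(codon)
            codons2.append(codon[:pos] + nt + codon[pos + 1 :])
        else:
            codon = sense[rng.integers(len(sense))]
            codons1.append(codon)
            codons2.append(codon)
    return "".join(codons1), "".join(codons2)
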