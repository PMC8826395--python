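"""Calibrated strict-clock root-age estimation by penalized least squares.

Given a rooted tree whose branch lengths are in expected substitutions per
site, and one or more fossil calibrations expressed as normal node-age priors
(mean, sigma in Ma), the fitter asks: if every lineage evolved at one shared
rate, how old must the root be for the branch lengths and the calibrations to
agree?  It minimizes

    sum_branches (b_i - r * tau_i)^2 / max(b_i, eps)
        + sum_calibrations ((t_c - mu_c) / sigma_c)^2

over the rate ``r > 0`` and internal-node ages ``t`` subject to parent >=
child ordering with tips fixed at age 0.  The per-branch weight treats the
branch-length variance as proportional to the branch length (Poisson-like),
floored at ``eps`` so zero-length branches stay finite.  The rate enters the
objective quadratically and is profiled out in closed form; node ages are
then optimized under the linear ordering constraints.

This is a fast, deterministic point estimator in the spirit of least-squares
dating; it is not a posterior.  Uncertainty comes from a nonparametric
residual bootstrap over branch lengths (``root_age_interval``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path


import dendropy
import numpy as np
from scipy.optimize import minimize

__all__ = [
    "Calibration",
    "CalibratedTree",
    "ClockFit",
    "fit_strict_clock",
    "default_calibrations",
    "read_calibrations_tsv",
    "root_age_interval",
    "load_tree",
]

EPS = 1e-6


@dataclass(frozen=True)
class Calibration:
    """Normal age prior on the MRCA of a taxon set."""

    taxa: frozenset[str]
    mean: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("calibration sigma must be positive")
        if len(self.taxa) < 2:
            raise ValueError("a calibration needs at least two taxa")


@dataclass
class CalibratedTree:
    tree: dendropy.Tree
    calibrations: list[Calibration]

    def __post_init__(self) -> None:
        if not self.calibrations:
            raise ValueError("at least one calibration is required")
        self.tree.is_rooted = True


@dataclass
class ClockFit:
    rate: float                          # substitutions/site/My
    node_ages: dict[frozenset[str], float]   # clade leaf set -> age (Ma)
    root_age: float
    objective: float
    n_branches: int
    ci95_root: tuple[float, float] | None = None

    def to_json(self) -> str:
        return json.dumps({
            "rate_subs_per_site_per_My": self.rate,
            "root_age_Ma": self.root_age,
            "objective": self.objective,
            "n_branches": self.n_branches,
            "ci95_root_Ma": self.ci95_root,
            "node_ages_Ma": {
                "|".join(sorted(k)): v for k, v in self.node_ages.items()
            },
        }, indent=2)


def load_tree(source: str | Path, from_path: bool = True) -> dendropy.Tree:
    kwargs = {"path": str(source)} if from_path else {"data": str(source)}
    tree = dendropy.Tree.get(schema="newick", **kwargs)
    tree.is_rooted = True
    return tree


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _structure(ct: CalibratedTree):
    """Index internal nodes, branches and calibration targets."""
    tree = ct.tree
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    index = {id(n): i for i, n in enumerate(internal)}
    leafsets = {id(n): _leafset(n) for n in internal}

    branches = []   # (parent_idx, child_idx or None for leaf, length)
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            if child.edge.length is None:
                raise ValueError("every branch needs a length")
            cidx = index[id(child)] if not child.is_leaf() else None
            branches.append((index[id(node)], cidx, float(child.edge.length)))

    cal_idx = []
    for cal in ct.calibrations:
        mrca = tree.mrca(taxon_labels=sorted(cal.taxa))
        if mrca is None or mrca.is_leaf():
            raise ValueError(f"no internal MRCA for calibration {sorted(cal.taxa)}")
        if leafsets[id(mrca)] != cal.taxa:
            raise ValueError(
                f"calibration clade {sorted(cal.taxa)} is not monophyletic "
                f"(MRCA spans {sorted(leafsets[id(mrca)])})"
            )
        cal_idx.append((index[id(mrca)], cal.mean, cal.sigma))
    return internal, leafsets, branches, cal_idx


def _branch_arrays(branches, n: int):
    """Parent index, child index (-1 for leaves), lengths and weights."""
    P = np.array([p for p, _, _ in branches], dtype=int)
    C = np.array([-1 if c is None else c for _, c, _ in branches], dtype=int)
    b = np.array([x[2] for x in branches])
    w = np.maximum(b, EPS)
    return P, C, b, w


def _tau(x: np.ndarray, P: np.ndarray, C: np.ndarray) -> np.ndarray:
    child_age = np.where(C >= 0, x[np.clip(C, 0, None)], 0.0)
    return x[P] - child_age


def _profiled_rate_arr(tau: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    denom = float((tau * tau / w).sum())
    if denom <= 0:
        return 0.0
    return max(float((b * tau / w).sum() / denom), 0.0)


def _solve(P, C, b, cal_i, cal_mu, cal_s, x0):
    """Minimize the penalized-WLS objective over internal-node ages.

    Returns (ages, rate, objective).  The rate is profiled out in closed
    form; the envelope theorem makes the analytic gradient exact at the
    profiled rate.  Raises ArithmeticError on non-convergence.
    """
    n = x0.size
    w = np.maximum(b, EPS)

    def objective(x: np.ndarray) -> float:
        tau = _tau(x, P, C)
        r = _profiled_rate_arr(tau, b, w)
        fit = float((((b - r * tau) ** 2) / w).sum())
        pen = float((((x[cal_i] - cal_mu) / cal_s) ** 2).sum()) if cal_i.size else 0.0
        return fit + pen

    def gradient(x: np.ndarray) -> np.ndarray:
        tau = _tau(x, P, C)
        r = _profiled_rate_arr(tau, b, w)
        g_edge = -2.0 * r * (b - r * tau) / w
        grad = np.zeros_like(x)
        np.add.at(grad, P, g_edge)
        internal_child = C >= 0
        np.add.at(grad, C[internal_child], -g_edge[internal_child])
        if cal_i.size:
            np.add.at(grad, cal_i, 2.0 * (x[cal_i] - cal_mu) / cal_s ** 2)
        return grad

    # ordering constraints parent - child >= 0 for internal children
    rows = np.nonzero(C >= 0)[0]
    A = np.zeros((rows.size, n))
    A[np.arange(rows.size), P[rows]] = 1.0
    A[np.arange(rows.size), C[rows]] = -1.0
    cons = ([{"type": "ineq", "fun": lambda x: A @ x, "jac": lambda x: A}]
            if rows.size else [])
    bounds = [(0.0, None)] * n

    res = minimize(objective, x0, jac=gradient, method="SLSQP", bounds=bounds,
                   constraints=cons, options={"maxiter": 2000, "ftol": 1e-14})
    if not res.success:
        res = minimize(objective, res.x, jac=gradient, method="SLSQP",
                       bounds=bounds, constraints=cons,
                       options={"maxiter": 20000, "ftol": 1e-14})
    if not res.success:
        raise ArithmeticError(f"clock fit did not converge: {res.message} "
                              f"(objective {res.fun:.4g})")

    ages = np.maximum(res.x, 0.0)
    # repair within-tolerance ordering violations exactly (children before
    # parents: branch list is in preorder, so walk it backwards)
    for k in range(len(P) - 1, -1, -1):
        if C[k] >= 0:
            ages[P[k]] = max(ages[P[k]], ages[C[k]])
    rate = _profiled_rate_arr(_tau(ages, P, C), b, w)
    return ages, rate, float(objective(ages))


def _init_ages(ct: CalibratedTree, internal, cal_idx) -> np.ndarray:
    """Deterministic init: substitution depths scaled through calibrations."""
    idx = {id(nd): i for i, nd in enumerate(internal)}
    depth = np.zeros(len(internal))
    for node in ct.tree.postorder_node_iter():
        if node.is_leaf():
            continue
        depth[idx[id(node)]] = max(
            (0.0 if ch.is_leaf() else depth[idx[id(ch)]]) + ch.edge.length
            for ch in node.child_nodes()
        )
    scales = [depth[i] / mu for i, mu, _ in cal_idx if depth[i] > 0 and mu > 0]
    r0 = float(np.median(scales)) if scales else (depth.max() or 1.0) / 1000.0
    if r0 <= 0:
        r0 = 1e-3
    return depth / r0


def fit_strict_clock(ct: CalibratedTree) -> ClockFit:
    """Fit the shared rate and node ages; see the module docstring.

    Deterministic: fixed initialization and a deterministic constrained
    quadratic solver.
    """
    internal, leafsets, branches, cal_idx = _structure(ct)
    P, C, b, w = _branch_arrays(branches, len(internal))
    cal_i = np.array([i for i, _, _ in cal_idx], dtype=int)
    cal_mu = np.array([mu for _, mu, _ in cal_idx])
    cal_s = np.array([s for _, _, s in cal_idx])

    x0 = _init_ages(ct, internal, cal_idx)
    ages, rate, obj = _solve(P, C, b, cal_i, cal_mu, cal_s, x0)

    idx = {id(nd): i for i, nd in enumerate(internal)}
    root_idx = idx[id(ct.tree.seed_node)]
    node_ages = {leafsets[id(nd)]: float(ages[idx[id(nd)]]) for nd in internal}
    return ClockFit(rate=rate, node_ages=node_ages,
                    root_age=float(ages[root_idx]),
                    objective=obj, n_branches=len(branches))


def read_calibrations_tsv(source: str) -> list[Calibration]:
    """TSV columns: taxon_set (pipe-separated), mean_Ma, sigma_Ma."""
    cals = []
    for line in source.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("taxon_set\t"):
            continue
        taxa, mean, sigma = line.split("\t")[:3]
        cals.append(Calibration(frozenset(taxa.split("|")),
                                float(mean), float(sigma)))
    if not cals:
        raise ValueError("no calibrations parsed")
    return cals


def default_calibrations() -> list[Calibration]:
    """The six shipped fossil-record normal node-age priors (deepest first)."""
    text = resources.files("hgtscan.data").joinpath("calibrations.tsv").read_text()
    return read_calibrations_tsv(text)


def root_age_interval(
    fit: ClockFit,
    ct: CalibratedTree,
    reps: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Nonparametric residual-bootstrap 95% interval for the root age.

    Branch residuals about the fitted clock are resampled with replacement,
    added back onto the fitted branch lengths (truncated at zero), and the
    clock refitted; the 2.5 and 97.5 percentiles of the refitted root ages
    form the interval.  Deterministic given the seed.
    """
    if reps < 40:
        raise ValueError("need at least 40 bootstrap replicates")
    internal, leafsets, branches, cal_idx = _structure(ct)
    P, C, b, _ = _branch_arrays(branches, len(internal))
    cal_i = np.array([i for i, _, _ in cal_idx], dtype=int)
    cal_mu = np.array([mu for _, mu, _ in cal_idx])
    cal_s = np.array([s for _, _, s in cal_idx])

    idx = {id(nd): i for i, nd in enumerate(internal)}
    ages_hat = np.array([fit.node_ages[leafsets[id(nd)]] for nd in internal])
    root_idx = idx[id(ct.tree.seed_node)]

    fitted = fit.rate * _tau(ages_hat, P, C)
    resid = b - fitted
    rng = np.random.default_rng(seed)
    roots = []
    for _ in range(reps):
        e_star = rng.choice(resid, size=resid.size, replace=True)
        b_star = np.maximum(fitted + e_star, 0.0)
        try:
            ages, _, _ = _solve(P, C, b_star, cal_i, cal_mu, cal_s, ages_hat)
        except ArithmeticError:
            continue
        if np.isfinite(ages[root_idx]):
            roots.append(float(ages[root_idx]))
    if len(roots) < reps * 0.8:
        raise ArithmeticError("too many bootstrap refits failed to converge")
    lo, hi = np.percentile(roots, [2.5, 97.5])
    fit.ci95_root = (float(lo), float(hi))
    return fit.ci95_root
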