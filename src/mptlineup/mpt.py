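"""Generic multinomial processing tree (MPT) machinery.

An MPT model assigns to each response category of each tree a probability
that is a sum of branch probabilities, where every branch probability is a
product of free parameters theta, complements (1 - theta), and constants.
This module provides the model containers, the multinomial likelihood, and
maximum-likelihood fitting under equality/fixed-value restrictions via an
EM algorithm (latent branch-completion counts) followed by bounded
quasi-Newton refinement on the logit scale.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

FREE = "free"
CONSTANT = "constant"

__all__ = [
    "Parameter",
    "Factor",
    "Branch",
    "Tree",
    "MptModel",
    "FrequencyTable",
    "RestrictionSet",
    "FitOptions",
    "FitResult",
    "IdentifiabilityReport",
    "MptError",
    "MissingAssignmentError",
    "DomainError",
    "category_probabilities",
    "g_squared",
    "log_likelihood",
    "fit",
    "standard_errors",
    "check_identifiability",
]


class MptError(Exception):
    """Base class for model specification and evaluation errors."""


class MissingAssignmentError(MptError):
    """A free parameter was left unassigned when evaluating the model."""


class DomainError(MptError):
    """A probability value fell outside the closed unit interval."""


@dataclass(frozen=True)
class Parameter:
    """A named model quantity: a free probability in [0, 1] or a constant.

    Constants carry their value (e.g. the suspect-sampling probability
    1/n stored as a fixed decimal); free parameters are estimated.
    """

    name: str
    role: str = FREE
    value: float | None = None

    def __post_init__(self) -> None:
        if self.role not in (FREE, CONSTANT):
            raise MptError(f"unknown parameter role {self.role!r}")
        if self.role == CONSTANT:
            if self.value is None:
                raise MptError(f"constant {self.name!r} needs a value")
            if not 0.0 <= self.value <= 1.0:
                raise DomainError(
                    f"constant {self.name!r} = {self.value} outside [0, 1]"
                )
        elif self.value is not None:
            raise MptError(f"free parameter {self.name!r} must not carry a value")


@dataclass(frozen=True)
class Factor:
    """One multiplicative term of a branch.

    ``ref`` is either the name of a registered parameter/constant or a
    numeric literal in [0, 1]; ``complement`` multiplies by 1 - value.
    """

    ref: str | float
    complement: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.ref, (int, float)) and not isinstance(self.ref, bool):
            if not 0.0 <= float(self.ref) <= 1.0:
                raise DomainError(f"literal factor {self.ref} outside [0, 1]")


@dataclass(frozen=True)
class Branch:
    """A root-to-leaf path: an ordered product of factors ending in a category."""

    factors: tuple[Factor, ...]
    category: str


@dataclass(frozen=True)
class Tree:
    """One processing tree with an ordered category list and its branches."""

    name: str
    categories: tuple[str, ...]
    branches: tuple[Branch, ...]

    def __post_init__(self) -> None:
        if len(set(self.categories)) != len(self.categories):
            raise MptError(f"tree {self.name!r} has duplicate categories")
        for br in self.branches:
            if br.category not in self.categories:
                raise MptError(
                    f"tree {self.name!r}: branch targets unknown category "
                    f"{br.category!r}"
                )


class MptModel:
    """A collection of trees sharing one parameter/constant registry."""

    def __init__(self, trees: Sequence[Tree], parameters: Iterable[Parameter]):
        self.trees = list(trees)
        self.parameters: dict[str, Parameter] = {}
        for p in parameters:
            if p.name in self.parameters:
                raise MptError(f"duplicate parameter name {p.name!r}")
            self.parameters[p.name] = p
        names = [t.name for t in self.trees]
        if len(set(names)) != len(names):
            raise MptError("duplicate tree names")
        for tree in self.trees:
            for br in tree.branches:
                for f in br.factors:
                    if isinstance(f.ref, str) and f.ref not in self.parameters:
                        raise MptError(
                            f"tree {tree.name!r}: factor references "
                            f"unregistered name {f.ref!r}"
                        )

    @property
    def free_parameters(self) -> list[str]:
        return [n for n, p in self.parameters.items() if p.role == FREE]

    @property
    def constants(self) -> dict[str, float]:
        return {
            n: p.value for n, p in self.parameters.items() if p.role == CONSTANT
        }

    def tree(self, name: str) -> Tree:
        for t in self.trees:
            if t.name == name:
                return t
        raise KeyError(name)


class FrequencyTable:
    """Observed response counts per tree and category.

    Counts are nonnegative integers; per-tree totals are the sums of the
    category counts.
    """

    def __init__(self, counts: Mapping[str, Mapping[str, int]]):
        self.counts: dict[str, dict[str, int]] = {}
        for tree, cats in counts.items():
            row: dict[str, int] = {}
            for cat, n in cats.items():
                n = int(n)
                if n < 0:
                    raise ValueError(
                        f"negative count {n} for {tree!r}/{cat!r}"
                    )
                row[cat] = n
            self.counts[tree] = row

    def total(self, tree: str) -> int:
        return sum(self.counts[tree].values())

    @property
    def totals(self) -> dict[str, int]:
        return {t: self.total(t) for t in self.counts}

    @property
    def grand_total(self) -> int:
        return sum(self.totals.values())

    def get(self, tree: str, category: str) -> int:
        row = self.counts.get(tree, {})
        if category in row:
            return row[category]
        # EQN models qualify categories with the tree name; CSV tables
        # store them unqualified
        prefix = tree + "."
        if category.startswith(prefix) and category[len(prefix):] in row:
            return row[category[len(prefix):]]
        return 0

    def __eq__(self, other) -> bool:
        return isinstance(other, FrequencyTable) and self.counts == other.counts


@dataclass
class RestrictionSet:
    """Equality classes and fixed values over free parameters.

    A parameter may appear in at most one equality class; fixing any member
    of a class fixes the whole class.
    """

    equalities: list[frozenset[str]] = field(default_factory=list)
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.equalities = [frozenset(c) for c in self.equalities if len(c) > 1]
        seen: set[str] = set()
        for cls in self.equalities:
            if cls & seen:
                raise MptError(
                    f"parameter(s) {sorted(cls & seen)} in more than one "
                    "equality class"
                )
            seen |= cls
        for name, v in self.fixed.items():
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"fixed value {name}={v} outside [0, 1]")

    def with_equality(self, names: Iterable[str]) -> "RestrictionSet":
        """Return a new set with one more equality constraint, merging any
        classes the named parameters already belong to."""
        names = set(names)
        merged = set(names)
        keep = []
        for cls in self.equalities:
            if cls & names:
                merged |= cls
            else:
                keep.append(cls)
        keep.append(frozenset(merged))
        return RestrictionSet(equalities=keep, fixed=dict(self.fixed))

    def resolve(self, model: MptModel) -> tuple[dict[str, str], dict[str, float]]:
        """Map every free model parameter to its representative name, and
        return the fixed-value map expanded over equality classes."""
        free = set(model.free_parameters)
        for cls in self.equalities:
            unknown = cls - free
            if unknown:
                raise MptError(f"equality over non-free parameters {sorted(unknown)}")
        for name in self.fixed:
            if name not in free:
                raise MptError(f"fixed value for non-free parameter {name!r}")
        rep_of: dict[str, str] = {}
        for cls in self.equalities:
            rep = min(cls)
            for n in cls:
                rep_of[n] = rep
        for n in free:
            rep_of.setdefault(n, n)
        fixed: dict[str, float] = {}
        for name, v in self.fixed.items():
            rep = rep_of[name]
            if rep in fixed and fixed[rep] != v:
                raise MptError(f"conflicting fixed values within class of {rep!r}")
            fixed[rep] = v
        return rep_of, fixed


# ---------------------------------------------------------------------------
# Compilation: flatten the model into arrays for fast likelihood evaluation.
# ---------------------------------------------------------------------------


class _Compiled:
    """Array form of (model, restrictions, frequency table).

    Branch b has probability  const[b] * prod_k theta_k^D[b,k] (1-theta_k)^C[b,k]
    over the K free representative parameters.
    """

    def __init__(
        self,
        model: MptModel,
        restrictions: RestrictionSet | None,
        freqs: FrequencyTable | None,
    ):
        restrictions = restrictions or RestrictionSet()
        self.model = model
        self.rep_of, self.fixed = restrictions.resolve(model)
        reps = sorted({r for r in self.rep_of.values() if r not in self.fixed})
        self.free_names = reps
        idx = {r: k for k, r in enumerate(reps)}
        K = len(reps)

        consts: list[float] = []
        bcat: list[int] = []
        D_rows: list[np.ndarray] = []
        C_rows: list[np.ndarray] = []
        cat_tree: list[int] = []
        self.cat_labels: list[tuple[str, str]] = []
        cat_index: dict[tuple[str, str], int] = {}
        for ti, tree in enumerate(model.trees):
            for cat in tree.categories:
                cat_index[(tree.name, cat)] = len(self.cat_labels)
                self.cat_labels.append((tree.name, cat))
                cat_tree.append(ti)
        for tree in model.trees:
            for br in tree.branches:
                const = 1.0
                d = np.zeros(K)
                c = np.zeros(K)
                for f in br.factors:
                    if isinstance(f.ref, str):
                        p = model.parameters[f.ref]
                        if p.role == CONSTANT:
                            v = p.value
                        else:
                            rep = self.rep_of[f.ref]
                            if rep in self.fixed:
                                v = self.fixed[rep]
                            else:
                                if f.complement:
                                    c[idx[rep]] += 1
                                else:
                                    d[idx[rep]] += 1
                                continue
                        const *= (1.0 - v) if f.complement else v
                    else:
                        v = float(f.ref)
                        const *= (1.0 - v) if f.complement else v
                consts.append(const)
                bcat.append(cat_index[(tree.name, br.category)])
                D_rows.append(d)
                C_rows.append(c)

        self.K = K
        self.const = np.asarray(consts)
        self.bcat = np.asarray(bcat, dtype=int)
        self.D = np.vstack(D_rows) if D_rows else np.zeros((0, K))
        self.C = np.vstack(C_rows) if C_rows else np.zeros((0, K))
        self.ncat = len(self.cat_labels)
        self.cat_tree = np.asarray(cat_tree, dtype=int)
        self.ntrees = len(model.trees)

        if freqs is not None:
            obs = np.zeros(self.ncat)
            for j, (tname, cat) in enumerate(self.cat_labels):
                obs[j] = freqs.get(tname, cat)
            self.obs = obs
            self.tree_totals = np.zeros(self.ntrees)
            np.add.at(self.tree_totals, self.cat_tree, obs)
        else:
            self.obs = None
            self.tree_totals = None

    # -- probabilities -----------------------------------------------------

    def branch_probs(self, theta: np.ndarray) -> np.ndarray:
        th = np.clip(theta, 0.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = self.const * np.prod(
                np.power(th, self.D) * np.power(1.0 - th, self.C), axis=1
            )
        return p

    def category_probs(self, theta: np.ndarray) -> np.ndarray:
        p = np.zeros(self.ncat)
        np.add.at(p, self.bcat, self.branch_probs(theta))
        return p

    def per_tree_probs(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        p = self.category_probs(theta)
        out: dict[str, np.ndarray] = {}
        for ti, tree in enumerate(self.model.trees):
            out[tree.name] = p[self.cat_tree == ti]
        return out

    # -- likelihood --------------------------------------------------------

    def loglik(self, theta: np.ndarray) -> float:
        p = self.category_probs(theta)
        mask = self.obs > 0
        if np.any(p[mask] <= 0):
            return -np.inf
        return float(np.sum(self.obs[mask] * np.log(p[mask])))

    def saturated_loglik(self) -> float:
        mask = self.obs > 0
        n = self.obs[mask]
        N = self.tree_totals[self.cat_tree[mask]]
        return float(np.sum(n * np.log(n / N)))

    def grad_loglik(self, theta: np.ndarray) -> np.ndarray:
        """Analytic gradient; valid for theta strictly inside (0, 1)."""
        th = np.clip(theta, 1e-12, 1.0 - 1e-12)
        pb = self.branch_probs(th)
        pc = np.zeros(self.ncat)
        np.add.at(pc, self.bcat, pb)
        mask = self.obs > 0
        w = np.zeros(self.ncat)
        w[mask] = self.obs[mask] / np.clip(pc[mask], 1e-300, None)
        wb = w[self.bcat] * pb  # (B,)
        # d pb / d theta_k = pb * (D/theta - C/(1-theta))
        return (wb[:, None] * (self.D / th - self.C / (1.0 - th))).sum(axis=0)

    def em_step(self, theta: np.ndarray) -> np.ndarray:
        """One EM update: allocate observed counts to branches (E), then set
        each parameter to expected successes / expected trials (M)."""
        th = np.clip(theta, 1e-12, 1.0 - 1e-12)
        pb = self.branch_probs(th)
        pc = np.zeros(self.ncat)
        np.add.at(pc, self.bcat, pb)
        ratio = np.zeros(self.ncat)
        mask = pc > 0
        ratio[mask] = self.obs[mask] / pc[mask]
        w = ratio[self.bcat] * pb  # expected branch counts
        S = w @ self.D
        F = w @ self.C
        new = theta.copy()
        tot = S + F
        upd = tot > 0
        new[upd] = S[upd] / tot[upd]
        return new


def _point_vector(comp: _Compiled, point: Mapping[str, float]) -> np.ndarray:
    theta = np.empty(comp.K)
    for k, name in enumerate(comp.free_names):
        if name not in point:
            raise MissingAssignmentError(f"no value assigned to parameter {name!r}")
        v = float(point[name])
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"{name} = {v} outside [0, 1]")
        theta[k] = v
    return theta


def _expand_point(
    comp: _Compiled, point: Mapping[str, float]
) -> Mapping[str, float]:
    """Accept values keyed by any class member and relay them to reps."""
    out = dict(point)
    for member, rep in comp.rep_of.items():
        if rep not in out and member in out:
            out[rep] = out[member]
    return out


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def category_probabilities(
    model: MptModel,
    point: Mapping[str, float],
    restrictions: RestrictionSet | None = None,
) -> dict[str, np.ndarray]:
    """Category probability vector of every tree at a parameter point.

    Each vector follows the tree's category order and sums to 1.
    """
    comp = _Compiled(model, restrictions, None)
    theta = _point_vector(comp, _expand_point(comp, point))
    return comp.per_tree_probs(theta)


def log_likelihood(
    model: MptModel,
    point: Mapping[str, float],
    freqs: FrequencyTable,
    restrictions: RestrictionSet | None = None,
) -> float:
    comp = _Compiled(model, restrictions, freqs)
    return comp.loglik(_point_vector(comp, _expand_point(comp, point)))


def g_squared(
    model: MptModel,
    point: Mapping[str, float],
    freqs: FrequencyTable,
    restrictions: RestrictionSet | None = None,
) -> float:
    """Likelihood-ratio statistic 2*sum obs*ln(obs/expected) against the
    saturated model; categories with zero observed count contribute 0.

    Returns +inf when a category with positive observed count has expected
    probability 0 (structural lack of fit).
    """
    comp = _Compiled(model, restrictions, freqs)
    theta = _point_vector(comp, _expand_point(comp, point))
    ll = comp.loglik(theta)
    if not np.isfinite(ll):
        return math.inf
    return max(2.0 * (comp.saturated_loglik() - ll), 0.0)


@dataclass
class FitOptions:
    n_starts: int = 10
    seed: int = 1
    em_max_iter: int = 10000
    em_tol: float = 1e-10
    bound_eps: float = 1e-8
    multistart_tol: float = 1e-6


@dataclass
class FitResult:
    """Maximum-likelihood fit of an MPT model to a frequency table."""

    estimates: dict[str, float]
    standard_errors: dict[str, float | None]
    log_likelihood: float
    g2: float
    df: int
    p: float
    converged: bool
    n_free_parameters: int
    free_names: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    n_em_iterations: int = 0
    multistart_spread: float = 0.0


def _fit_single_start(comp: _Compiled, theta0: np.ndarray, opts: FitOptions):
    theta = theta0.copy()
    ll = comp.loglik(theta)
    n_iter = 0
    converged = False
    for n_iter in range(1, opts.em_max_iter + 1):
        theta = np.clip(comp.em_step(theta), opts.bound_eps, 1.0 - opts.bound_eps)
        new_ll = comp.loglik(theta)
        if abs(new_ll - ll) <= opts.em_tol * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    # quasi-Newton polish on the logit scale (unconstrained)
    if comp.K > 0:
        x0 = np.log(theta / (1.0 - theta))

        def negll(x):
            th = 1.0 / (1.0 + np.exp(-x))
            return -comp.loglik(th)

        def grad(x):
            th = 1.0 / (1.0 + np.exp(-x))
            return -comp.grad_loglik(th) * th * (1.0 - th)

        res = minimize(
            negll, x0, jac=grad, method="L-BFGS-B",
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 2000},
        )
        th = 1.0 / (1.0 + np.exp(-res.x))
        if comp.loglik(th) > ll:
            theta, ll = th, comp.loglik(th)
        # final bounded polish on the natural scale: boundary optima land
        # exactly on the clamp, making boundary detection exact
        res2 = minimize(
            lambda t: -comp.loglik(t),
            theta,
            jac=lambda t: -comp.grad_loglik(t),
            method="L-BFGS-B",
            bounds=[(opts.bound_eps, 1.0 - opts.bound_eps)] * comp.K,
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 2000},
        )
        if -res2.fun >= ll:
            theta, ll = np.clip(res2.x, opts.bound_eps, 1 - opts.bound_eps), -res2.fun
    return theta, ll, n_iter, converged


def fit(
    model: MptModel,
    freqs: FrequencyTable,
    restrictions: RestrictionSet | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Maximum-likelihood fit under restrictions.

    EM iterations (expected branch counts in the E-step; each free parameter
    updated as expected successes over expected trials) are followed by
    L-BFGS refinement on the logit scale. The default 10 seeded random
    starts must agree in log-likelihood within ``multistart_tol`` or a
    warning is attached to the result.
    """
    opts = options or FitOptions()
    comp = _Compiled(model, restrictions, freqs)
    for ti, tree in enumerate(model.trees):
        if comp.tree_totals[ti] == 0:
            raise MptError(f"tree {tree.name!r} has no observations")

    rng = np.random.default_rng(opts.seed)
    results = []
    for s in range(max(opts.n_starts, 1)):
        theta0 = (
            np.full(comp.K, 0.5)
            if s == 0
            else rng.uniform(0.05, 0.95, size=comp.K)
        )
        results.append(_fit_single_start(comp, theta0, opts))
    lls = np.array([r[1] for r in results])
    best = int(np.argmax(lls))  # ties break to the lowest start index
    theta, ll, n_iter, converged = results[best]
    spread = float(lls.max() - lls.min()) if len(lls) > 1 else 0.0

    warnings: list[str] = []
    if spread > opts.multistart_tol:
        warnings.append(
            f"multistart log-likelihoods disagree by {spread:.3g} "
            f"(> {opts.multistart_tol:g}); possible local maxima"
        )
    if not converged:
        warnings.append(
            f"EM did not converge within {opts.em_max_iter} iterations"
        )

    g2 = max(2.0 * (comp.saturated_loglik() - ll), 0.0)
    df = int(comp.ncat - comp.ntrees - comp.K)
    p = float(chi2.sf(g2, df)) if df > 0 else float("nan")

    ses, se_warn = _standard_errors_compiled(comp, theta, opts.bound_eps)
    warnings += se_warn

    estimates: dict[str, float] = {}
    se_map: dict[str, float | None] = {}
    rep_value = dict(zip(comp.free_names, theta))
    for member, rep in comp.rep_of.items():
        if rep in comp.fixed:
            estimates[member] = comp.fixed[rep]
            se_map[member] = None
        else:
            estimates[member] = float(rep_value[rep])
            se_map[member] = ses.get(rep)

    return FitResult(
        estimates=estimates,
        standard_errors=se_map,
        log_likelihood=float(ll),
        g2=float(g2),
        df=df,
        p=p,
        converged=converged,
        n_free_parameters=comp.K,
        free_names=list(comp.free_names),
        warnings=warnings,
        n_em_iterations=n_iter,
        multistart_spread=spread,
    )


def _hessian(fun, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central finite-difference Hessian."""
    k = len(x)
    H = np.zeros((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += h; xpp[j] += h
            xpm = x.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (
                4 * h * h
            )
    del f0
    return H


def _standard_errors_compiled(
    comp: _Compiled, theta: np.ndarray, bound_eps: float
) -> tuple[dict[str, float | None], list[str]]:
    ses: dict[str, float | None] = {}
    warnings: list[str] = []
    if comp.K == 0:
        return ses, warnings
    boundary = (theta <= 10 * bound_eps) | (theta >= 1.0 - 10 * bound_eps)
    interior = ~boundary
    for k, name in enumerate(comp.free_names):
        if boundary[k]:
            ses[name] = None
            warnings.append(
                f"estimate of {name!r} is on the [0, 1] boundary; SE suppressed"
            )
    idx = np.where(interior)[0]
    if len(idx) == 0:
        return ses, warnings

    def negll_sub(sub: np.ndarray) -> float:
        th = theta.copy()
        th[idx] = sub
        return -comp.loglik(np.clip(th, 1e-12, 1 - 1e-12))

    info = _hessian(negll_sub, theta[idx])  # observed information
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        if np.any(diag < 0):
            raise np.linalg.LinAlgError("negative variance")
        for pos, k in enumerate(idx):
            ses[comp.free_names[k]] = float(np.sqrt(diag[pos]))
    except np.linalg.LinAlgError:
        bad = [comp.free_names[k] for k in idx]
        warnings.append(
            "observed information matrix singular or indefinite for "
            f"parameters {bad}; SEs unavailable"
        )
        for k in idx:
            ses[comp.free_names[k]] = None
    return ses, warnings


def standard_errors(
    model: MptModel,
    point: Mapping[str, float],
    freqs: FrequencyTable,
    restrictions: RestrictionSet | None = None,
) -> dict[str, float | None]:
    """SEs from the inverse observed information at the supplied MLE,
    computed on the natural probability scale; boundary estimates get None.
    """
    comp = _Compiled(model, restrictions, freqs)
    theta = _point_vector(comp, _expand_point(comp, point))
    ses, _ = _standard_errors_compiled(comp, theta, 1e-8)
    out: dict[str, float | None] = {}
    for member, rep in comp.rep_of.items():
        out[member] = None if rep in comp.fixed else ses.get(rep)
    return out


@dataclass
class IdentifiabilityReport:
    n_free_parameters: int
    n_independent_categories: int
    rank: int
    identifiable: bool
    free_names: list[str]


def check_identifiability(
    model: MptModel,
    restrictions: RestrictionSet | None = None,
    n_points: int = 5,
    seed: int = 0,
) -> IdentifiabilityReport:
    """Numerical local identifiability check.

    Computes the Jacobian of all category probabilities with respect to the
    free parameters at several random interior points and reports the
    maximal numerical rank; full column rank means locally identifiable.
    """
    comp = _Compiled(model, restrictions, None)
    rng = np.random.default_rng(seed)
    n_indep = comp.ncat - comp.ntrees
    best_rank = 0
    h = 1e-6
    for _ in range(n_points):
        theta = rng.uniform(0.2, 0.8, size=comp.K)
        J = np.zeros((comp.ncat, comp.K))
        for k in range(comp.K):
            tp = theta.copy(); tp[k] += h
            tm = theta.copy(); tm[k] -= h
            J[:, k] = (comp.category_probs(tp) - comp.category_probs(tm)) / (2 * h)
        best_rank = max(best_rank, int(np.linalg.matrix_rank(J, tol=1e-8)))
    return IdentifiabilityReport(
        n_free_parameters=comp.K,
        n_independent_categories=n_indep,
        rank=best_rank,
        identifiable=(best_rank == comp.K) and (comp.K <= n_indep),
        free_names=list(comp.free_names),
    )
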