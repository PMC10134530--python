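"""Maximum-likelihood estimation of the loss model, branch lengths and the
tracking switch rate, plus the likelihood-ratio test for biased fractionation.

The total HMM log-likelihood of the pillar set is maximized over all branch
lengths (including the stem), the retention rate phi, the loss bias epsilon
and the switch probability s, by bounded quasi-Newton optimization.  Branch
lengths and phi are optimized on a log scale; epsilon and s on their natural
bounded scales.  The biased-fractionation test compares the free fit to a fit
constrained to epsilon = 1 (no bias); 2*delta-lnL is referred to chi-square
with one degree of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .datamodel import PillarSet, SpeciesTree
from .errors import FitError, ValidationError
from .hmm import HMMSpec, forward_backward
from .loss_model import LossModel, pattern_log_likelihoods

BRANCH_BOUNDS = (1e-6, 20.0)
PHI_BOUNDS = (1e-6, 50.0)
EPSILON_BOUNDS = (1e-4, 1.0)
S_BOUNDS = (0.0, 0.4999)

_DEFAULT_INIT = {"branch_length": 0.2, "phi": 0.5, "epsilon": 0.8, "s": 0.01}


@dataclass
class FitResult:
    """Fitted parameters and diagnostics."""

    tree: SpeciesTree  # topology of the input with fitted branch lengths
    phi: float
    epsilon: float
    s: float
    log_likelihood: float
    n_evaluations: int
    n_restarts: int
    converged: bool
    constrained: Optional["FitResult"] = None
    lrt_statistic: Optional[float] = None
    lrt_p_value: Optional[float] = None

    @property
    def model(self) -> LossModel:
        return LossModel(phi=self.phi, epsilon=self.epsilon)

    def report(self) -> Dict[str, object]:
        out: Dict[str, object] = {
            "log_likelihood": f"{self.log_likelihood:.6f}",
            "phi": f"{self.phi:.6g}",
            "epsilon": f"{self.epsilon:.6g}",
            "s": f"{self.s:.6g}",
            "n_evaluations": self.n_evaluations,
            "n_restarts": self.n_restarts,
            "converged": self.converged,
            "tree": self.tree.newick(),
        }
        if self.lrt_statistic is not None:
            out["lrt_statistic"] = f"{self.lrt_statistic:.6f}"
            out["lrt_p_value"] = f"{self.lrt_p_value:.6g}"
        return out


class _Objective:
    """Negative HMM log-likelihood over transformed parameters.

    Pillars are collapsed to unique presence patterns for the pruning step;
    the chain itself still runs over every pillar.
    """

    def __init__(
        self,
        pillars: PillarSet,
        tree: SpeciesTree,
        fix_epsilon: Optional[float],
        fix_s: Optional[float],
    ) -> None:
        self.tree = tree
        self.fix_epsilon = fix_epsilon
        self.fix_s = fix_s
        self.block_bounds = pillars.block_bounds()
        self.genomes = pillars.genomes

        order = [pillars.genomes.index(g) for g in tree.tip_names]
        patterns = pillars.presence_matrix()[:, order]
        self.uniq, self.inverse = np.unique(patterns, axis=0, return_inverse=True)
        n = tree.n_tips
        bits = np.arange(1 << n)
        tip_bits = np.zeros_like(bits)
        for tip_i, gen_i in enumerate(order):
            tip_bits |= ((bits >> gen_i) & 1) << tip_i
        self.tip_bits = tip_bits
        self.n_branches = tree.n_nodes
        self.n_calls = 0

    # parameter vector: [log branch lengths..., log phi, (epsilon), (s)]
    def pack(self, lengths, phi, epsilon, s) -> np.ndarray:
        x = list(np.log(lengths)) + [np.log(phi)]
        if self.fix_epsilon is None:
            x.append(epsilon)
        if self.fix_s is None:
            x.append(s)
        return np.array(x)

    def unpack(self, x: np.ndarray):
        nb = self.n_branches
        lengths = np.exp(x[:nb])
        phi = float(np.exp(x[nb]))
        pos = nb + 1
        if self.fix_epsilon is None:
            epsilon = float(x[pos])
            pos += 1
        else:
            epsilon = self.fix_epsilon
        s = float(x[pos]) if self.fix_s is None else self.fix_s
        return lengths, phi, epsilon, s

    def bounds(self) -> List[Tuple[float, float]]:
        lo, hi = np.log(BRANCH_BOUNDS[0]), np.log(BRANCH_BOUNDS[1])
        b = [(lo, hi)] * self.n_branches
        b.append((np.log(PHI_BOUNDS[0]), np.log(PHI_BOUNDS[1])))
        if self.fix_epsilon is None:
            b.append(EPSILON_BOUNDS)
        if self.fix_s is None:
            b.append(S_BOUNDS)
        return b

    def log_likelihood(self, x: np.ndarray) -> float:
        self.n_calls += 1
        lengths, phi, epsilon, s = self.unpack(x)
        model = LossModel(phi=phi, epsilon=epsilon)
        tree = self.tree.with_lengths(lengths)
        log_e = pattern_log_likelihoods(self.uniq, tree, model, self.tip_bits)[
            self.inverse
        ]
        hmm = HMMSpec(
            genomes=self.genomes, switch_prob=s, block_bounds=self.block_bounds
        )
        _, total = forward_backward(log_e, hmm)
        return total

    def __call__(self, x: np.ndarray) -> float:
        ll = self.log_likelihood(x)
        if not np.isfinite(ll):
            return 1e12
        return -ll


def fit_model(
    pillars: PillarSet,
    tree: SpeciesTree,
    fix_epsilon: Optional[float] = None,
    fix_s: Optional[float] = None,
    restarts: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    with_lrt: bool = False,
) -> FitResult:
    """Fit branch lengths, phi, epsilon and s by maximum likelihood.

    The topology is fixed.  ``restarts`` jittered starting points are tried
    (deterministic given ``seed``) and the best optimum kept.  With
    ``with_lrt`` a second, epsilon=1-constrained fit is run and the
    likelihood-ratio statistic attached.
    """
    if len(pillars) < 20:
        warnings.warn(
            f"only {len(pillars)} pillars; estimates may be unstable", stacklevel=2
        )
    result = _fit_once(pillars, tree, fix_epsilon, fix_s, restarts, seed, tol)
    if with_lrt:
        if fix_epsilon is not None:
            raise ValidationError("cannot run the bias LRT with epsilon fixed")
        constrained = _fit_once(pillars, tree, 1.0, fix_s, restarts, seed, tol)
        if result.log_likelihood < constrained.log_likelihood:
            # the free model nests the constrained one; restart the free fit
            # from the constrained optimum to escape the poorer local optimum
            retry = _fit_once(
                pillars, tree, fix_epsilon, fix_s, 1, seed, tol,
                start=(constrained.tree.lengths, constrained.phi, 1.0,
                       constrained.s),
            )
            if retry.log_likelihood > result.log_likelihood:
                result = retry
        stat = 2.0 * (result.log_likelihood - constrained.log_likelihood)
        if stat < -1e-4:
            raise FitError(
                f"constrained fit beat the free fit (2dlnL = {stat:.4g}); "
                "optimizer failure",
                best=result,
            )
        stat = max(stat, 0.0)
        result.constrained = constrained
        result.lrt_statistic = stat
        result.lrt_p_value = float(chi2.sf(stat, df=1))
    return result


def _fit_once(
    pillars: PillarSet,
    tree: SpeciesTree,
    fix_epsilon: Optional[float],
    fix_s: Optional[float],
    restarts: int,
    seed: int,
    tol: float,
    start: Optional[tuple] = None,
) -> FitResult:
    obj = _Objective(pillars, tree, fix_epsilon, fix_s)
    rng = np.random.default_rng(seed)
    init = _DEFAULT_INIT
    if start is not None:
        lengths0, phi0, eps0, s0 = start
        x0 = obj.pack(np.asarray(lengths0), phi0, eps0, s0)
    else:
        x0 = obj.pack(
            np.full(obj.n_branches, init["branch_length"]),
            init["phi"],
            init["epsilon"],
            init["s"],
        )
    bounds = obj.bounds()
    best = None
    n_done = 0
    for r in range(max(restarts, 1)):
        x_start = x0.copy()
        if r > 0:  # jitter within bounds
            jit = rng.normal(0.0, 0.3, size=x_start.shape)
            x_start = np.clip(
                x_start + jit,
                [b[0] for b in bounds],
                [b[1] for b in bounds],
            )
        res = minimize(
            obj,
            x_start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "maxiter": 500},
        )
        n_done += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("optimization did not produce a finite likelihood")
    lengths, phi, epsilon, s = obj.unpack(best.x)
    return FitResult(
        tree=tree.with_lengths(lengths),
        phi=phi,
        epsilon=epsilon,
        s=s,
        log_likelihood=-float(best.fun),
        n_evaluations=obj.n_calls,
        n_restarts=n_done,
        converged=bool(best.success),
    )


def lrt_biased_fractionation(
    pillars: PillarSet,
    tree: SpeciesTree,
    restarts: int = 3,
    seed: int = 0,
    **kwargs,
) -> Tuple[float, float]:
    """Test epsilon = 1 (no biased fractionation) against the free model.

    Returns (2*delta-lnL, p-value) with the statistic referred to chi-square,
    1 df.
    """
    result = fit_model(
        pillars, tree, restarts=restarts, seed=seed, with_lrt=True, **kwargs
    )
    return result.lrt_statistic, result.lrt_p_value


def profile_epsilon(
    pillars: PillarSet,
    tree: SpeciesTree,
    fit: FitResult,
    grid: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Log-likelihood slice in epsilon through the fitted optimum.

    Other parameters are held at their MLEs; by definition of the joint MLE
    no grid point can exceed the fitted log-likelihood.
    """
    if grid is None:
        grid = np.linspace(EPSILON_BOUNDS[0], 1.0, 21)
    obj = _Objective(pillars, tree, fix_epsilon=None, fix_s=None)
    lengths = fit.tree.lengths
    values = np.array(
        [
            obj.log_likelihood(obj.pack(lengths, fit.phi, e, fit.s))
            for e in grid
        ]
    )
    return np.asarray(grid), values
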