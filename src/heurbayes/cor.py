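"""Covariance Orthogonalizing Regularization (COR).

COR multiplexes the outcome of a binary-comparison regression once per cue,
giving a multivariate problem whose weights form an m x m matrix W: the
diagonal ("direct weights") connects each cue to its own copy of the
outcome, the off-diagonal ("cross-weights") carries all sensitivity to
cue-cue covariance.  A zero-mean Gaussian prior with precision lambda =
1/eta^2 is placed on the cross-weights only (flat prior on the direct
weights, error SD sigma = 1), so the mean posterior for column j solves

    min_w ||y - Xw||^2 + lambda * sum_{k != j} w_k^2
    =>  w^(j) = (X'X + lambda M_j)^-1 X'y,

with M_j the identity whose (j,j) entry is zeroed.

* lambda = 0: no penalty; every column is the OLS solution, and either
  decision rule returns the sign of the OLS prediction.
* lambda -> infinity: cross-weights vanish and each diagonal entry tends to
  the simple-regression slope sum_i x_ij y_i / sum_i x_ij^2 = 2 v_j - 1, a
  linear transform of the cue validity; the TTB decision rule then
  reproduces take-the-best and the tallying rule reproduces undirected
  tallying.

Decision rules map the output vector yhat = x W to a choice in {-1,0,+1}:
the TTB rule takes the sign of the maximum-absolute output, the tallying
rule the sign of the sum of output signs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .comparisons import InputError, PairedComparisons

__all__ = [
    "CORConfig",
    "CORWeights",
    "cor_outputs",
    "cor_predict",
    "cor_weights",
    "tally_rule",
    "ttb_rule",
]

#: Output components (and argmax ties) within this relative tolerance of the
#: largest |yhat_j| are treated as zero (resp. tied).  At large lambda the
#: residual cross-weights contribute O(1/lambda) leakage to outputs that are
#: exactly zero in the limit; the band absorbs it while staying far below
#: any genuine validity signal (|2v - 1| >= 1/n on discriminating cues).
RULE_REL_TOL = 1e-4

#: Outputs below this absolute magnitude are treated as exactly zero.  It
#: sits between the worst-case cross-weight leakage at the numerical
#: stand-in for lambda = infinity (order n*m/lambda ~ 1e-5 at lambda=1e8)
#: and the smallest nonzero validity signal |2v - 1| >= 1/n, so a test item
#: that discriminates only on uninformative cues yields a guess, exactly as
#: the heuristics do.
RULE_ABS_TOL = 1e-5

RULES = ("ttb_rule", "tally_rule")


@dataclass
class CORConfig:
    """Cross-weight prior precision and the decision rule to apply."""

    lmbda: float
    decision_rule: str = "ttb_rule"

    def __post_init__(self) -> None:
        if self.lmbda < 0:
            raise InputError("lambda must be nonnegative")
        if self.decision_rule not in RULES:
            raise InputError(f"decision_rule must be one of {RULES}")


@dataclass
class CORWeights:
    """Mean posterior weight matrix W (columns indexed by outcome copy)."""

    W: np.ndarray
    lmbda: float

    @property
    def direct(self) -> np.ndarray:
        return np.diag(self.W)

    @property
    def cross(self) -> np.ndarray:
        return self.W - np.diag(np.diag(self.W))


def cor_weights(pc: PairedComparisons, lmbda: float) -> CORWeights:
    """Mean posterior weight matrix at cross-weight precision lambda."""
    if lmbda < 0:
        raise InputError("lambda must be nonnegative")
    X = pc.X.astype(float)
    G = X.T @ X
    b = X.T @ pc.y
    m = pc.m
    if lmbda == 0:
        if m > pc.n or np.linalg.cond(G) > 1e12:
            raise np.linalg.LinAlgError(
                "X'X is singular at lambda=0; use lambda > 0"
            )
        w_ols = np.linalg.solve(G, b)
        return CORWeights(W=np.tile(w_ols[:, None], (1, m)), lmbda=0.0)
    W = np.empty((m, m))
    for j in range(m):
        A = G + lmbda * np.eye(m)
        A[j, j] -= lmbda            # flat prior on the direct weight
        # lstsq keeps never-discriminating cues (zero column => singular
        # system) well-defined with w^(j) = 0 in the dead coordinates.
        W[:, j] = np.linalg.lstsq(A, b, rcond=None)[0]
    return CORWeights(W=W, lmbda=float(lmbda))


def cor_outputs(x, w: CORWeights) -> np.ndarray:
    """Multiplexed outputs yhat = x W, one per outcome copy."""
    x = np.asarray(x, dtype=float)
    if x.shape != (w.W.shape[0],):
        raise InputError(f"x has shape {x.shape}, expected ({w.W.shape[0]},)")
    return x @ w.W


def ttb_rule(yhat, rel_tol: float = RULE_REL_TOL, abs_tol: float = RULE_ABS_TOL) -> int:
    """Sign of the maximum-absolute output; ties go to the lowest index."""
    yhat = np.asarray(yhat, dtype=float)
    if yhat.size == 0:
        raise InputError("empty output vector")
    scale = np.max(np.abs(yhat))
    if scale <= abs_tol:
        return 0
    j_star = int(np.flatnonzero(np.abs(yhat) >= (1 - rel_tol) * scale)[0])
    return int(np.sign(yhat[j_star]))


def tally_rule(yhat, rel_tol: float = RULE_REL_TOL, abs_tol: float = RULE_ABS_TOL) -> int:
    """Sign of the sum of output signs (majority of outcome copies)."""
    yhat = np.asarray(yhat, dtype=float)
    if yhat.size == 0:
        raise InputError("empty output vector")
    scale = np.max(np.abs(yhat))
    if scale <= abs_tol:
        return 0
    signs = np.where(np.abs(yhat) > max(rel_tol * scale, abs_tol), np.sign(yhat), 0.0)
    return int(np.sign(signs.sum()))


def cor_predict(x, w: CORWeights, rule: str = "ttb_rule") -> int:
    """Choice for comparison x: outputs through the chosen decision rule."""
    if rule not in RULES:
        raise InputError(f"rule must be one of {RULES}")
    yhat = cor_outputs(x, w)
    return ttb_rule(yhat) if rule == "ttb_rule" else tally_rule(yhat)
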