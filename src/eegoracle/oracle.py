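"""Oracle recombination: box-constrained least squares against the clean target.

Given components C (K x T) of a noisy epoch and the clean reference X, the
oracle chooses weights

    min_w || X - C^T w ||_2^2   s.t.  0 <= w_k <= 1,

a convex problem solved with bounded-variable least squares.  The box keeps
the oracle a soft component-selection/attenuation mechanism — no sign flips,
no large cancellations — so its RRMSE is a best-case bound on what any
selector over the same components could achieve.  All-ones weights are
always feasible, hence for additively exact families the oracle can never be
worse than the unprocessed observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear

from .decomp import ComponentSet, MethodConfig
from .mixture import Epoch

__all__ = ["OracleResult", "oracle_weights", "reconstruct", "rrmse", "pcc", "evaluate_epoch"]

_OPT_TOL = 1e-6


@dataclass
class OracleResult:
    w: np.ndarray
    X_hat: np.ndarray
    rrmse: float
    pcc: float  # NaN flags an undefined correlation (zero-variance input)
    epoch_id: str = ""
    config: MethodConfig | None = None


def oracle_weights(C: np.ndarray, X: np.ndarray, tol: float = _OPT_TOL) -> np.ndarray:
    """Solve the box-constrained least-squares recombination.

    Degenerate all-zero component rows are excluded from the solve and get
    weight 0.  Optimality is verified through the projected-gradient
    condition at the returned point.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    X = np.asarray(X, dtype=float)
    if not (np.all(np.isfinite(C)) and np.all(np.isfinite(X))):
        raise ValueError("oracle_weights: non-finite inputs")
    if np.linalg.norm(X) == 0:
        raise ValueError("oracle_weights: zero-norm clean reference")
    if C.shape[1] != X.size:
        raise ValueError(f"component length {C.shape[1]} != target length {X.size}")

    nonzero = np.linalg.norm(C, axis=1) > 0
    w = np.zeros(C.shape[0])
    if not np.any(nonzero):
        return w
    A = C[nonzero].T  # T x K_active
    res = lsq_linear(A, X, bounds=(0.0, 1.0), method="bvls")
    if not res.success:
        res = lsq_linear(A, X, bounds=(0.0, 1.0), method="trf")
        if not res.success:
            raise RuntimeError(f"box-constrained solver failed: {res.message}")
    w_active = np.clip(res.x, 0.0, 1.0)

    # projected-gradient optimality check, scaled by the Gram matrix norm
    grad = A.T @ (A @ w_active - X)
    scale = max(np.linalg.norm(A.T @ A, ord=2), 1.0)
    gtol = tol * scale
    at_lo, at_hi = w_active <= 1e-12, w_active >= 1 - 1e-12
    interior = ~(at_lo | at_hi)
    ok = (
        np.all(grad[at_lo] >= -gtol)
        and np.all(grad[at_hi] <= gtol)
        and np.all(np.abs(grad[interior]) <= gtol)
    )
    if not ok:
        raise RuntimeError("solver returned a point violating projected-gradient optimality")
    w[nonzero] = w_active
    return w


def reconstruct(C: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Linear recombination ``X_hat = C^T w`` (no clipping)."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    w = np.asarray(w, dtype=float)
    if w.size != C.shape[0]:
        raise ValueError(f"weight length {w.size} != component count {C.shape[0]}")
    return C.T @ w


def rrmse(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Relative root-mean-square error ||X - X_hat|| / ||X||."""
    X = np.asarray(X, dtype=float)
    nx = np.linalg.norm(X)
    if nx == 0:
        raise ValueError("rrmse: zero-norm reference")
    return float(np.linalg.norm(X - np.asarray(X_hat, dtype=float)) / nx)


def pcc(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Pearson correlation over samples; NaN when either vector is constant."""
    X = np.asarray(X, dtype=float)
    X_hat = np.asarray(X_hat, dtype=float)
    if X.size < 2 or X_hat.size != X.size:
        raise ValueError("pcc requires two equal-length vectors of length >= 2")
    if np.std(X) == 0 or np.std(X_hat) == 0:
        return float("nan")
    return float(np.corrcoef(X, X_hat)[0, 1])


def evaluate_epoch(epoch: Epoch, component_set: ComponentSet) -> OracleResult:
    """oracle_weights -> reconstruct -> metrics for one (epoch, config)."""
    w = oracle_weights(component_set.C, epoch.X)
    X_hat = reconstruct(component_set.C, w)
    return OracleResult(
        w=w,
        X_hat=X_hat,
        rrmse=rrmse(epoch.X, X_hat),
        pcc=pcc(epoch.X, X_hat),
        epoch_id=epoch.epoch_id,
        config=component_set.config,
    )
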