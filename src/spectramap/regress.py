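"""Per-channel response scoring by regression against the design matrix.

With unit-norm, mutually orthogonal design columns the least-squares
coefficients reduce to ``beta = G.T @ dff``.  Each coefficient is converted
to a T-score ``T_i = beta_i / sqrt(rss / (n - 3))`` with ``n`` the number of
time samples (418 on the canonical timeline), and the spectrally agnostic
responsiveness statistic is the Euclidean norm ``T4D = ||T||``.

Note the ``n - 3`` degrees of freedom with four regressors and no
intercept is the convention this statistic was defined with; it is kept
literally (it only rescales all T-scores by a common constant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import CHANNELS, DesignMatrix

__all__ = ["RegressionTable", "fit", "t_scores", "t4d", "regress_all", "T_CAP"]

#: Finite stand-in for an infinite T-score (rss == 0); above any threshold.
T_CAP = 1e6


@dataclass
class RegressionTable:
    """Per-ROI regression coefficients, T-scores and residuals."""

    beta: np.ndarray  # (n_rois, 4)
    T: np.ndarray  # (n_rois, 4)
    T4D: np.ndarray  # (n_rois,)
    rss: np.ndarray  # (n_rois,)
    n: int

    def to_frame(self, roi_ids: np.ndarray | None = None) -> pd.DataFrame:
        ids = np.arange(len(self.rss)) if roi_ids is None else roi_ids
        data = {"roi_id": ids}
        for j, ch in enumerate(CHANNELS):
            data[f"beta_{ch}"] = self.beta[:, j]
        for j, ch in enumerate(CHANNELS):
            data[f"T_{ch}"] = self.T[:, j]
        data["T4D"] = self.T4D
        data["rss"] = self.rss
        return pd.DataFrame(data)


def fit(dFF: np.ndarray, design: DesignMatrix | np.ndarray):
    """Project traces on the design columns.

    Returns ``(beta, fitted, rss)``.  ``dFF`` may be one trace
    ``(n_frames,)`` or a matrix ``(n_rois, n_frames)``.
    """
    G = design.G if isinstance(design, DesignMatrix) else np.asarray(design)
    X = np.atleast_2d(np.asarray(dFF, dtype=float))
    if X.shape[1] != G.shape[0]:
        raise ValueError(
            f"trace length {X.shape[1]} does not match design rows {G.shape[0]}"
        )
    beta = X @ G  # (n_rois, 4)
    fitted = beta @ G.T
    rss = np.sum((X - fitted) ** 2, axis=1)
    if np.asarray(dFF).ndim == 1:
        return beta[0], fitted[0], float(rss[0])
    return beta, fitted, rss


def t_scores(beta: np.ndarray, rss: np.ndarray | float, n: int) -> np.ndarray:
    """T_i = beta_i / sqrt(rss / (n - 3)); a zero-residual fit maps to ±T_CAP."""
    if n <= 3:
        raise ValueError("need more than 3 time samples")
    beta = np.asarray(beta, dtype=float)
    rss_arr = np.atleast_1d(np.asarray(rss, dtype=float))
    if np.any(rss_arr < 0):
        raise ValueError("rss must be nonnegative")
    scale = np.sqrt(rss_arr / (n - 3))
    b2 = np.atleast_2d(beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = b2 / scale[:, None]
    T = np.where(np.isfinite(T), T, np.sign(b2) * T_CAP)
    T = np.clip(T, -T_CAP, T_CAP)
    return T[0] if beta.ndim == 1 else T


def t4d(T: np.ndarray) -> np.ndarray:
    """Euclidean norm of the four per-channel T-scores."""
    T = np.asarray(T, dtype=float)
    return np.linalg.norm(T, axis=-1)


def regress_all(
    dFF: np.ndarray, design: DesignMatrix, center: bool = True
) -> RegressionTable:
    """Fit every ROI and assemble the regression table.

    With ``center=True`` the constant component is projected out of both
    the traces and the design columns before the fit (the columns are
    demeaned and renormalized to unit norm) — the orthogonal-projection
    form of an intercept.  Two effects make this necessary: the
    low-quantile running baseline leaves a positive DC offset in null
    dF/F0 that the nonnegative design columns would otherwise convert
    into a uniform upward T bias, and broadband responders carry a DC
    term of their own signal that would otherwise inflate the residual
    and crush their T-scores.  The stored design is untouched.
    """
    X = np.atleast_2d(np.asarray(dFF, dtype=float))
    G = design.G
    if center:
        X = X - X.mean(axis=1, keepdims=True)
        G = G - G.mean(axis=0, keepdims=True)
        norms = np.linalg.norm(G, axis=0)
        G = np.divide(G, norms, out=np.zeros_like(G), where=norms > 0)
    beta, _, rss = fit(X, G)
    n = design.G.shape[0]
    T = t_scores(beta, rss, n)
    return RegressionTable(beta=beta, T=T, T4D=t4d(T), rss=rss, n=n)
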