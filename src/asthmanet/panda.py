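"""Message-passing regulatory network inference (PANDA).

Integrates three z-score-normalized inputs — a TF x gene motif prior
W0, a symmetric TF-TF interaction prior P0, and a symmetric gene-gene
co-expression matrix C0 — by iterating a continuous Tanimoto similarity:

    R = T(P, W)          (responsibility: TF neighborhoods agree on targets)
    A = T(W, C)          (availability: targets agree on co-expression)
    W <- (1 - alpha) W + alpha (R + A) / 2

after which P is updated toward T(W, W^T) and C toward T(W^T, W), each
with the same step alpha and a refreshed diagonal (row-standard-
deviation scaled by matrix size and exp(2 * alpha * step)) so self-
similarity does not dominate the messages. Iteration stops when the
mean absolute change of W drops below ``tol``. Edge weights stay on a
z-score-like scale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def zscore_network(m: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Standardize every entry by the matrix's overall mean and SD."""
    values = m.to_numpy(dtype=float) if isinstance(m, pd.DataFrame) else np.asarray(m, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("matrix contains non-finite entries")
    sd = values.std()
    if sd == 0:
        raise ValueError("constant matrix cannot be z-score normalized")
    z = (values - values.mean()) / sd
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(z, index=m.index, columns=m.columns)
    return z


def tanimoto(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Continuous Tanimoto similarity of rows of ``x`` against columns of ``y``.

    S_ij = <x_i, y_j> / sqrt(|x_i|^2 + |y_j|^2 - |<x_i, y_j>|); pairs of
    zero vectors yield 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s = x @ y
    xn = (x ** 2).sum(axis=1)[:, None]
    yn = (y ** 2).sum(axis=0)[None, :]
    denom = np.sqrt(np.maximum(xn + yn - np.abs(s), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = s / denom
    return np.where(denom > 0, out, 0.0)


def _refresh_diagonal(m: np.ndarray, size: int, alpha: float, step: int) -> np.ndarray:
    np.fill_diagonal(m, np.nan)
    row_sd = np.nanstd(m, axis=1, ddof=1)
    np.fill_diagonal(m, row_sd * size * np.exp(2.0 * alpha * step))
    return m


@dataclass
class PandaNetwork:
    """Fitted TF x gene edge-weight network on the z-score scale."""

    weights: pd.DataFrame
    n_iter: int
    converged: bool
    final_delta: float
    delta_history: list[float] = field(default_factory=list)


def panda_fit(w0: pd.DataFrame, p0: pd.DataFrame, c0: pd.DataFrame,
              alpha: float = 0.1, tol: float = 1e-3,
              max_iter: int = 200) -> PandaNetwork:
    """Run the message-passing iteration to (near) convergence.

    Inputs must already be z-score normalized; ``p0`` and ``c0`` must be
    symmetric. Non-convergence at ``max_iter`` is reported on the result
    rather than raised.
    """
    if list(w0.index) != list(p0.index) or list(p0.index) != list(p0.columns):
        raise ValueError("P0 must be TF x TF on the same TF ordering as W0")
    if list(w0.columns) != list(c0.index) or list(c0.index) != list(c0.columns):
        raise ValueError("C0 must be gene x gene on the same gene ordering as W0")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    p = p0.to_numpy(dtype=float).copy()
    c = c0.to_numpy(dtype=float).copy()
    w = w0.to_numpy(dtype=float).copy()
    if not np.allclose(p, p.T, atol=1e-8):
        raise ValueError("P0 must be symmetric")
    if not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("C0 must be symmetric")
    n_tf, n_gene = w.shape

    history: list[float] = []
    converged = False
    step = 0
    for step in range(max_iter):
        responsibility = tanimoto(p, w)
        availability = tanimoto(w, c.T)
        w_new = (1.0 - alpha) * w + alpha * 0.5 * (responsibility + availability)
        delta = float(np.abs(w_new - w).mean())
        history.append(delta)
        w = w_new
        if delta < tol:
            converged = True
            break
        p_msg = _refresh_diagonal(tanimoto(w, w.T), n_tf, alpha, step)
        p = (1.0 - alpha) * p + alpha * 0.5 * (p_msg + p_msg.T)
        c_msg = _refresh_diagonal(tanimoto(w.T, w), n_gene, alpha, step)
        c = (1.0 - alpha) * c + alpha * 0.5 * (c_msg + c_msg.T)
    return PandaNetwork(
        weights=pd.DataFrame(w, index=w0.index, columns=w0.columns),
        n_iter=step + 1, converged=converged,
        final_delta=history[-1] if history else 0.0,
        delta_history=history)


def coexpression(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene-gene Pearson correlation; zero-variance rows get 0 off-diagonal."""
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.corrcoef(x)
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 1.0)
    if (sd == 0).any():
        np.fill_diagonal(c, 1.0)
    return pd.DataFrame(c, index=expr.index, columns=expr.index)


def prepare_inputs(prior: pd.DataFrame, ppi: pd.DataFrame,
                   expr: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Align and z-score-normalize (W0, P0, C0) for one network fit.

    ``expr`` rows must cover the prior's gene universe and the TFs whose
    expression is available; the co-expression matrix is computed over
    the prior's gene columns only.
    """
    tfs = list(prior.index)
    genes = list(prior.columns)
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValueError(f"expression lacks prior genes: {missing[:5]}")
    ppi = ppi.loc[tfs, tfs]
    c0 = coexpression(expr.loc[genes])
    return (zscore_network(prior.astype(float)),
            zscore_network(ppi),
            zscore_network(c0))
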