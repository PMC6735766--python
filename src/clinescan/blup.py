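"""Clone-level BLUPs from replicated randomized-block common-garden data.

Model per trait and garden:

    y_ijk = mu + b_i + c_j + e_ijk,
    b_i ~ N(0, s2_block),  c_j ~ N(0, s2_clone),  e_ijk ~ N(0, s2_e),

with blocks and clones crossed.  Variance components are estimated by REML,
profiling the residual variance and optimizing the two variance ratios
(s2_block/s2_e, s2_clone/s2_e) with a bounded quasi-Newton search; the
likelihood is evaluated in the random-effect dimension via the Woodbury
identity, so fits scale with (#blocks + #clones), not with observations.
The empirical BLUPs of the clone effects are the GWAS phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = ["BlupTable", "fit_blups"]


@dataclass
class BlupTable:
    trait: str
    garden: str
    blups: pd.Series  # clone id -> BLUP of the clone effect
    sigma2_block: float
    sigma2_clone: float
    sigma2_resid: float
    grand_mean: float
    loglik: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clone": self.blups.index,
                "garden": self.garden,
                "trait": self.trait,
                "blup": self.blups.values,
            }
        )


def _reml_neg_loglik(log_ratios, y, zb, zc, xtx_solve):
    """-2 * restricted log-likelihood (up to a constant), profiled over the
    residual variance, at block/clone variance ratios exp(log_ratios)."""
    gb, gc = np.exp(log_ratios)
    n = y.shape[0]
    z = np.hstack([np.sqrt(gb) * zb, np.sqrt(gc) * zc])
    q = z.shape[1]
    m = np.eye(q) + z.T @ z  # I_q + Z'Z  (V* = I + ZZ')
    cho = np.linalg.cholesky(m)
    logdet_v = 2.0 * np.log(np.diag(cho)).sum()

    def vinv(a):
        # V*^{-1} a = a - Z M^{-1} Z' a
        w = np.linalg.solve(cho, z.T @ a)
        return a - z @ np.linalg.solve(cho.T, w)

    one = np.ones((n, 1))
    vi_y = vinv(y[:, None])
    vi_1 = vinv(one)
    xvx = (one.T @ vi_1).item()
    beta = (one.T @ vi_y).item() / xvx
    r = y[:, None] - one * beta
    ypy = (r.T @ vinv(r)).item()
    ypy = max(ypy, 1e-300)
    return logdet_v + np.log(xvx) + (n - 1) * np.log(ypy)


def fit_blups(
    obs: pd.DataFrame,
    trait: str,
    garden: str,
    tol: float = 1e-10,
) -> BlupTable:
    """REML fit of the block+clone random-effects model for one trait/garden.

    ``obs`` is the long phenotype table (columns: clone, garden, block, ramet,
    trait, value).  Clones with no finite observation for the trait are
    excluded.  Returns clone-effect BLUPs centred (by construction) near zero.
    """
    sub = obs[(obs["trait"] == trait) & (obs["garden"] == garden)].copy()
    sub = sub[np.isfinite(sub["value"].to_numpy(dtype=float))]
    if sub.empty:
        raise ValueError(f"no observations for trait={trait!r} garden={garden!r}")
    y = sub["value"].to_numpy(dtype=float)
    blocks = pd.Categorical(sub["block"])
    clones = pd.Categorical(sub["clone"])
    nb, nc = len(blocks.categories), len(clones.categories)
    if nb < 2 or nc < 2:
        raise ValueError("degenerate design: need >=2 blocks and >=2 clones")

    n = len(y)
    zb = np.zeros((n, nb))
    zb[np.arange(n), blocks.codes] = 1.0
    zc = np.zeros((n, nc))
    zc[np.arange(n), clones.codes] = 1.0

    res = minimize(
        _reml_neg_loglik,
        x0=np.zeros(2),  # ratios start at 1
        args=(y, zb, zc, None),
        method="L-BFGS-B",
        bounds=[(-12.0, 12.0)] * 2,
        options={"ftol": tol, "gtol": 1e-10},
    )
    gb, gc = np.exp(res.x)

    # final pass: variance components, fixed effect and BLUPs at the optimum
    z = np.hstack([np.sqrt(gb) * zb, np.sqrt(gc) * zc])
    m = np.eye(z.shape[1]) + z.T @ z
    cho = np.linalg.cholesky(m)

    def vinv(a):
        w = np.linalg.solve(cho, z.T @ a)
        return a - z @ np.linalg.solve(cho.T, w)

    one = np.ones((n, 1))
    vi_1 = vinv(one)
    mu = (one.T @ vinv(y[:, None])).item() / (one.T @ vi_1).item()
    r = y - mu
    vi_r = vinv(r[:, None])[:, 0]
    sigma2_e = float(r @ vi_r) / (n - 1)
    # u_hat = G Z' V^{-1} r with G = gamma * sigma2_e * I in original scale
    u_clone = gc * (zc.T @ vi_r)
    blups = pd.Series(u_clone, index=list(clones.categories), name="blup")

    return BlupTable(
        trait=trait,
        garden=garden,
        blups=blups,
        sigma2_block=gb * sigma2_e,
        sigma2_clone=gc * sigma2_e,
        sigma2_resid=sigma2_e,
        grand_mean=mu,
        loglik=-0.5 * res.fun,
    )
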