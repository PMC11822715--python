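"""Shared goodness-of-fit bookkeeping for the model-fitting stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GoodnessOfFit:
    """Summary of a least-squares fit.

    reduced_chi2 is the residual sum of squares over (n - n_params)
    degrees of freedom (unit data weights unless the fit weighted its
    residuals); r2 is the coefficient of determination on the quantity
    actually fitted.
    """

    reduced_chi2: float
    r2: float
    adj_r2: float
    n_points: int
    n_params: int

    def as_dict(self) -> dict:
        return {
            "reduced_chi2": self.reduced_chi2,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "n_points": self.n_points,
            "n_params": self.n_params,
        }


def goodness_of_fit(y: np.ndarray, y_model: np.ndarray, n_params: int) -> GoodnessOfFit:
    """Compute reduced chi-square, R^2 and adjusted R^2 from residuals."""
    y = np.asarray(y, dtype=float)
    resid = y - np.asarray(y_model, dtype=float)
    n = y.size
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    dof = max(n - n_params, 1)
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -np.inf)
    if n - n_params - 1 > 0 and tss > 0:
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)
    else:
        adj = r2
    return GoodnessOfFit(rss / dof, r2, adj, n, n_params)
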