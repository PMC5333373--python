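"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity through a different route than the
package (explicit normal equations, exact rational enumeration, literal
step-up loops) so agreement is evidence, not tautology.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats


def ols_oracle(y: np.ndarray, g: np.ndarray, cov: np.ndarray | None = None):
    """OLS beta/se/t/p for PSI ~ 1 + dosage + covariates via explicit
    matrix inversion of the normal equations."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    n = len(y)
    cols = [np.ones(n), g]
    if cov is not None and np.size(cov):
        cov = np.asarray(cov, dtype=float)
        cols.extend(cov[:, j] for j in range(cov.shape[1]))
    X = np.column_stack(cols)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta_hat = xtx_inv @ X.T @ y
    resid = y - X @ beta_hat
    k = X.shape[1] - 2  # covariate columns
    df = n - k - 2
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    t = float(beta_hat[1]) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(beta_hat[1]), se, t, p


def bh_oracle(p_values) -> np.ndarray:
    """Literal step-up definition: adj_i = min over ranks k >= rank(i) of
    p_(k) * m / k, capped at 1, written with plain loops."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = min(1.0, running_min)
    return np.array(adjusted)


def fisher_oracle(a: int, b: int, c: int, d: int, sidedness: str = "two-tailed") -> float:
    """Fisher p by exhaustive enumeration of all tables with the observed
    margins, in exact rational arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(r1 + r2, c1)
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    pmf = {k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom) for k in range(kmin, kmax + 1)}
    obs = pmf[a]
    if sidedness == "one-tailed":
        total = sum(p for k, p in pmf.items() if k >= a)
    else:
        total = sum(p for p in pmf.values() if p <= obs)
    return float(total)


def cis_pairs_oracle(snp_meta, event_meta, window_bp=100_000):
    """All (snp_id, event_id) pairs with gap distance < window_bp, by
    exhaustive double loop over data-frame rows."""
    pairs = set()
    for snp_id, snp in snp_meta.iterrows():
        for event_id, ev in event_meta.iterrows():
            if snp["chrom"] != ev["chrom"]:
                continue
            if snp["pos"] < ev["span_start"]:
                gap = ev["span_start"] - snp["pos"]
            elif snp["pos"] > ev["span_end"]:
                gap = snp["pos"] - ev["span_end"]
            else:
                gap = 0
            if gap < window_bp:
                pairs.add((snp_id, event_id))
    return pairs


def r2_oracle(x, y) -> float:
    """Squared Pearson correlation via the textbook sum formulas."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x * x).sum() - sx * sx) * np.sqrt(n * (y * y).sum() - sy * sy)
    return float((num / den) ** 2)
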