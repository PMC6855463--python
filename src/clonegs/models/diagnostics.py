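"""MCMC run-length diagnostic of Raftery and Lewis.

The chain is dichotomised at its q-quantile; the indicator sequence is
thinned until a first-order Markov chain is preferred (BIC) over a
second-order one, and the transition probabilities of the accepted
two-state chain give the required burn-in M, the required run length N,
the minimum i.i.d. length Nmin and the dependence factor (M+N)/Nmin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["RafteryLewisResult", "raftery_lewis"]


@dataclass
class RafteryLewisResult:
    burn_in: int  # M
    required_n: int  # N
    nmin: int
    dependence_factor: float
    thin: int
    degenerate: bool = False


def _nmin(q: float, r: float, s: float) -> int:
    phi = norm.ppf((s + 1.0) / 2.0)
    return int(np.ceil((phi / r) ** 2 * q * (1.0 - q)))


def _second_order_bic(z: np.ndarray) -> float:
    """BIC contrasting second- vs first-order Markov dependence of a
    binary sequence (positive favours the second-order model)."""
    n = len(z) - 2
    counts = np.zeros((2, 2, 2))
    for a, b, c in zip(z[:-2], z[1:-1], z[2:]):
        counts[a, b, c] += 1
    g2 = 0.0
    for b in (0, 1):
        nb = counts[:, b, :]
        tot = nb.sum()
        if tot == 0:
            continue
        rows = nb.sum(axis=1)
        cols = nb.sum(axis=0)
        for a in (0, 1):
            for c in (0, 1):
                if nb[a, c] > 0:
                    fitted = rows[a] * cols[c] / tot
                    g2 += 2.0 * nb[a, c] * np.log(nb[a, c] / fitted)
    return g2 - 2.0 * np.log(n)


def raftery_lewis(
    chain, q: float = 0.025, r: float = 0.005, s: float = 0.95, eps: float = 1e-3
) -> RafteryLewisResult:
    """Run-length diagnosis for estimating the q-quantile to within +/- r
    with probability s.

    Raises ``ValueError`` when the chain is shorter than Nmin (the error
    message carries Nmin); a constant chain returns a result flagged
    ``degenerate``.
    """
    x = np.asarray(chain, dtype=float).ravel()
    nmin = _nmin(q, r, s)
    if len(x) < nmin:
        raise ValueError(
            f"chain of length {len(x)} is shorter than Nmin={nmin} required "
            f"for q={q}, r={r}, s={s}"
        )
    if np.ptp(x) == 0:
        return RafteryLewisResult(0, nmin, nmin, np.nan, 1, degenerate=True)

    cutoff = np.quantile(x, q)
    dichot = (x <= cutoff).astype(np.int64)

    kthin = 1
    while True:
        z = dichot[::kthin]
        if len(z) < 3 or _second_order_bic(z) < 0:
            break
        kthin += 1
    z = dichot[::kthin]

    # two-state transition probabilities
    from_counts = np.zeros(2)
    trans = np.zeros((2, 2))
    for a, b in zip(z[:-1], z[1:]):
        trans[a, b] += 1
        from_counts[a] += 1
    if from_counts.min() == 0:
        return RafteryLewisResult(0, nmin, nmin, np.nan, kthin, degenerate=True)
    alpha = trans[0, 1] / from_counts[0]  # P(0 -> 1)
    beta = trans[1, 0] / from_counts[1]  # P(1 -> 0)
    ab = alpha + beta
    if alpha <= 0 or beta <= 0:
        return RafteryLewisResult(0, nmin, nmin, np.nan, kthin, degenerate=True)

    lam = abs(1.0 - ab)
    if lam <= 0:
        m_star = 0.0
    else:
        m_star = np.log(eps * ab / max(alpha, beta)) / np.log(lam)
        m_star = max(m_star, 0.0)
    M = int(np.ceil(m_star)) * kthin

    phi = norm.ppf((s + 1.0) / 2.0)
    n_star = (alpha * beta * (2.0 - ab)) / (ab**3) * (phi / r) ** 2
    N = int(np.ceil(n_star)) * kthin

    return RafteryLewisResult(
        burn_in=M,
        required_n=N,
        nmin=nmin,
        dependence_factor=(M + N) / nmin,
        thin=kthin,
    )
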