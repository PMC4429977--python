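"""Equilibrium model quantities and the log-log tail-fit estimator.

A system of M proteins, the i-th of length t_i built from a_i distinct
symbols, conserves the total token count T = sum t_i and the total
Hartley-Shannon information I = sum t_i ln a_i.  The most likely partition
of T over components under those constraints is the power law

    t_i / T = a_i^(-beta) / Q(beta),      Q(beta) = sum_a a^(-beta),

with the dual form a_i / A = t_i^(-1/beta) / sum_j t_j^(-1/beta),
A = sum a_i, implying a power law in lengths as well.  Empirically the tail
exponent is read off a log-log complementary cumulative plot by ordinary
least squares; the fitted cumulative slope is reported as-is and never
algebraically conflated with the pmf exponent beta.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class EquilibriumModel:
    """Fitted/constructed equilibrium state: exponent, normalization, totals."""

    beta: float
    Q: float
    T: float
    I: float
    A: float
    M: int


@dataclass(frozen=True)
class TailFit:
    """OLS summary in the layout linear-model software prints.

    ``slope``/``stderr`` are the slope estimate and its standard error,
    ``adj_r2`` the adjusted R^2, ``F`` the slope F statistic (= t^2),
    ``df`` the residual degrees of freedom (n - 2) and ``p`` the two-sided
    p-value.  ``window`` records the inclusive fit range on the x variable.
    """

    slope: float
    stderr: float
    adj_r2: float
    F: float
    df: int
    p: float
    intercept: float = 0.0
    window: tuple[float, float] | None = None
    n_points: int = 0

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "stderr": self.stderr,
            "adj_r2": self.adj_r2,
            "F": self.F,
            "df": self.df,
            "p": self.p,
            "intercept": self.intercept,
            "window": list(self.window) if self.window else None,
            "n_points": self.n_points,
        }


def conserved_totals(
    pairs: Iterable[tuple[int, int]]
) -> tuple[float, float, float, int]:
    """The conserved totals (T, I, A, M) of a list of (t, a) duals.

    T = sum t_i, I = sum t_i ln a_i (natural log), A = sum a_i, M = count.
    """
    T = 0.0
    I = 0.0
    A = 0.0
    M = 0
    for t, a in pairs:
        if a < 1:
            raise ValueError(f"unique count must be >= 1, got {a}")
        T += t
        I += t * math.log(a)
        A += a
        M += 1
    return T, I, A, M


def equilibrium_pmf(beta: float, support: Sequence[int]) -> np.ndarray:
    """p(a) = a^(-beta) / Q(beta) over an integer support, summing to 1."""
    support = np.asarray(list(support), dtype=float)
    if support.size == 0:
        raise ValueError("empty support")
    if np.any(support < 1):
        raise ValueError("support values must be >= 1")
    # work in log space: steep exponents underflow a^(-beta) directly
    logw = -beta * np.log(support)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def dual_pmf(beta: float, lengths: Sequence[int]) -> np.ndarray:
    """q(t) = t^(-1/beta) / sum_j t_j^(-1/beta); the dual power law in length."""
    if beta == 0:
        raise ValueError("dual form undefined at beta = 0")
    lengths = np.asarray(list(lengths), dtype=float)
    if lengths.size == 0:
        raise ValueError("empty length list")
    if np.any(lengths < 1):
        raise ValueError("lengths must be >= 1")
    logw = (-1.0 / beta) * np.log(lengths)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def partition_function(beta: float, support: Sequence[int]) -> float:
    """Q(beta) = sum over the support of a^(-beta)."""
    support = np.asarray(list(support), dtype=float)
    return float(np.sum(support ** (-beta)))


def model_from_pairs(
    pairs: Iterable[tuple[int, int]], beta: float, support: Sequence[int]
) -> EquilibriumModel:
    """Bundle conserved totals with an exponent and its normalization."""
    T, I, A, M = conserved_totals(pairs)
    return EquilibriumModel(
        beta=beta, Q=partition_function(beta, support), T=T, I=I, A=A, M=M
    )


def verify_duality(beta: float, support: Sequence[int]) -> float:
    """Max discrepancy between the equilibrium solution and its dual form.

    Construct lengths proportional to p(a) = a^(-beta)/Q over the support;
    the dual form then asserts a/A = t^(-1/beta)/sum t^(-1/beta).  Returns
    the max absolute difference between the two normalized vectors — zero
    (to rounding) for every beta > 0 by substitution.
    """
    if beta <= 0:
        raise ValueError("duality check requires beta > 0")
    support_arr = np.asarray(list(support), dtype=float)
    p = equilibrium_pmf(beta, support)
    # lengths proportional to p; rescale so the smallest is 1 (scale cancels
    # in the dual normalization)
    through_dual = dual_pmf(beta, p / p.min())
    direct = support_arr / support_arr.sum()
    return float(np.max(np.abs(through_dual - direct)))


def linear_fit(
    x: Sequence[float],
    y: Sequence[float],
    window: tuple[float, float] | None = None,
) -> TailFit:
    """Unweighted OLS of y on x with intercept, summarized as a TailFit."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 points for a fit, got {n}")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    if res.stderr > 0:
        F = (res.slope / res.stderr) ** 2
    else:
        F = math.inf
    return TailFit(
        slope=float(res.slope),
        stderr=float(res.stderr),
        adj_r2=float(adj_r2),
        F=float(F),
        df=n - 2,
        p=float(res.pvalue),
        intercept=float(res.intercept),
        window=window,
        n_points=n,
    )


def fit_loglog_tail(
    points: Iterable[tuple[float, float]],
    window: tuple[float, float],
) -> TailFit:
    """OLS of log10(count) on log10(x) over an inclusive x window.

    Points with non-positive counts inside the window are dropped with a
    warning (they carry no log); fewer than 3 usable points is an error.
    """
    lo, hi = window
    xs: list[float] = []
    ys: list[float] = []
    for x, count in points:
        if not (lo <= x <= hi):
            continue
        if count <= 0:
            warnings.warn(
                f"dropping zero/negative count at x={x} inside fit window",
                stacklevel=2,
            )
            continue
        xs.append(math.log10(x))
        ys.append(math.log10(count))
    if len(xs) < 3:
        raise ValueError(
            f"need >= 3 positive-count points in window [{lo}, {hi}], got {len(xs)}"
        )
    return linear_fit(xs, ys, window=(lo, hi))
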