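"""Statistical validation of the rigidity metrics.

Two questions are addressed.  First, do the wildtype-vs-experimental
and wildtype-vs-computational RDSM scores agree (Spearman correlation
across proteins), and is the mutant-vs-mutant score W typically smaller
than both — quantified as P(W < min(X, Y)) = P(D < 0) with
D = W − min(X, Y), estimated both from a normal approximation of D and
as the raw empirical fraction.  Second, do the rigidity metrics track
experimentally measured mutant fitness (Pearson correlation per metric
column of a fitness table).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoreTriple:
    """Per-protein RDSM triple.

    X: wildtype vs experimental (PDB) mutant; Y: wildtype vs
    computational mutant; W: experimental vs computational mutant.
    """

    label: str
    x: float
    y: float
    w: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.w)):
            raise ValueError(f"non-finite score in triple {self.label!r}")

    @property
    def d(self) -> float:
        return self.w - min(self.x, self.y)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation {self.r} outside [-1, 1]")


def _check_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(xv) < 3:
        raise ValueError("need at least 3 observations")
    return xv, yv


def pearson_r(x, y) -> CorrelationResult:
    """Sample Pearson r with a two-sided t-test p-value (n−2 df)."""
    xv, yv = _check_xy(x, y)
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("undefined correlation: zero variance")
    res = sps.pearsonr(xv, yv)
    return CorrelationResult(r=float(res.statistic), n=len(xv), p=float(res.pvalue))


def spearman_rho(x, y) -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    xv, yv = _check_xy(x, y)
    rx, ry = sps.rankdata(xv), sps.rankdata(yv)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("undefined correlation: zero rank variance")
    res = sps.spearmanr(xv, yv)
    return CorrelationResult(r=float(res.statistic), n=len(xv), p=float(res.pvalue))


def prob_w_below_min(
    triples: list[ScoreTriple], method: str = "normal"
) -> float:
    """Estimate P(W < min(X, Y)) from per-protein score triples.

    ``normal``: fit a Gaussian to D = W − min(X, Y) and return
    Φ(−mean/sd) (sample sd); ``empirical``: fraction of D < 0.
    """
    if method not in ("normal", "empirical"):
        raise ValueError(f"unknown method {method!r}")
    if not triples:
        raise ValueError("no triples")
    d = np.array([t.d for t in triples], dtype=float)
    if method == "empirical":
        return float(np.mean(d < 0))
    if len(d) < 2:
        raise ValueError("normal method needs at least 2 triples")
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0:
        logger.warning("zero spread in D; returning degenerate probability")
        return 1.0 if mean < 0 else (0.0 if mean > 0 else 0.5)
    return float(sps.norm.cdf(-mean / sd))


def metric_fitness_correlations(
    table: pd.DataFrame, fitness_column: str = "fitness"
) -> dict[str, CorrelationResult]:
    """Pearson r of fitness against every metric column of a table.

    Rows with missing values are dropped (logged); every non-fitness
    numeric column is treated as a metric.
    """
    if fitness_column not in table.columns:
        raise ValueError(f"no {fitness_column!r} column")
    metrics = [c for c in table.columns
               if c != fitness_column and pd.api.types.is_numeric_dtype(table[c])]
    if not metrics:
        raise ValueError("no metric columns")
    out: dict[str, CorrelationResult] = {}
    for col in metrics:
        sub = table[[fitness_column, col]].dropna()
        dropped = len(table) - len(sub)
        if dropped:
            logger.info("%s: dropped %d rows with missing values", col, dropped)
        out[col] = pearson_r(sub[fitness_column].to_numpy(), sub[col].to_numpy())
    return out
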