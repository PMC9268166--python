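"""Sum of ranking differences (SRD) with CRRN validation.

SRD compares columns (here: lipophilicity measures) against a consensus
reference ranking built from row averages.  For each measure the objects
(compounds) are ranked, and SRD is the city-block distance between that
ranking and the reference ranking — a measure with SRD 0 ranks the
compounds exactly as the consensus does.

Validation is twofold:

* CRRN ("comparison of ranks by random numbers"): the null distribution
  of SRD for a random permutation against the reference, obtained by
  exact enumeration (small n) or Monte Carlo sampling.  A measure whose
  SRD falls below the null's 5th percentile ranks significantly better
  than chance.
* k-fold cross-validation: roughly 1/k of the compounds are left out at
  a time and the SRD% values recomputed, giving a spread per measure;
  measures are then grouped by pairwise Wilcoxon matched-pair tests on
  those cross-validated values.

Normalization: SRD% = 100 * SRD / SRDmax(n), where SRDmax is n^2/2 for
even n and (n^2 - 1)/2 for odd n (the value attained by the reversed
ranking).

Columns are scaled before the row-average reference is built (the raw
row mean would be dominated by whichever measure spans the widest
scale).  The default is interval (min-max) scaling onto [0, 1], the
customary preprocessing for consensus-reference SRD; autoscaling
(``scaling="standardize"``) and no scaling are also available.  The
per-column rankings themselves are scale-invariant — only the reference
depends on this choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .transforms import range_scale_columns, standardize_columns

__all__ = [
    "rank_with_ties",
    "reference_ranking",
    "srd_value",
    "srd_max",
    "srd_normalize",
    "CRRNDistribution",
    "crrn",
    "wilcoxon_matched_pairs",
    "WilcoxonResult",
    "SRDAnalysis",
    "SRDResults",
    "srd_analysis",
    "srd_crossvalidate",
]

EXACT_LIMIT = 10
_QUANTILE_LEVELS = (5, 25, 50, 75, 95)


def rank_with_ties(values) -> np.ndarray:
    """Ascending ranks; tied values share the mean of their positions."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need a 1-d vector of length >= 2")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    return stats.rankdata(arr, method="average")


def reference_ranking(table: pd.DataFrame) -> np.ndarray:
    """Rank the compounds by their row-average value (the consensus)."""
    if table.size == 0:
        raise ValueError("empty table")
    return rank_with_ties(table.to_numpy(dtype=float).mean(axis=1))


def srd_value(column_ranks, reference_ranks) -> float:
    """Sum over objects of |column rank - reference rank|."""
    a = np.asarray(column_ranks, dtype=float)
    b = np.asarray(reference_ranks, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rank vectors differ in length")
    return float(np.abs(a - b).sum())


def srd_max(n_objects: int) -> int:
    """Maximum attainable SRD: reversal of n ranks."""
    n = int(n_objects)
    if n < 2:
        raise ValueError("need at least 2 objects")
    return n * n // 2 if n % 2 == 0 else (n * n - 1) // 2


def srd_normalize(srd_raw: float, n_objects: int) -> float:
    """Normalize a raw SRD onto the 0-100 scale (SRD%)."""
    m = srd_max(n_objects)
    if not 0 <= srd_raw <= m:
        raise ValueError(f"SRD {srd_raw} outside [0, {m}] for n={n_objects}")
    return 100.0 * srd_raw / m


@dataclass
class CRRNDistribution:
    """Null distribution of SRD for random rankings of ``n_objects``.

    ``support``/``probabilities`` hold the exact distribution when
    ``method == "exact"``; ``draws`` holds Monte-Carlo samples otherwise.
    """

    n_objects: int
    method: str
    support: np.ndarray | None = None
    probabilities: np.ndarray | None = None
    draws: np.ndarray | None = field(default=None, repr=False)

    @property
    def mean(self) -> float:
        if self.method == "exact":
            return float(np.dot(self.support, self.probabilities))
        return float(self.draws.mean())

    def quantile(self, q: float) -> float:
        if self.method == "exact":
            cdf = np.cumsum(self.probabilities)
            return float(self.support[np.searchsorted(cdf, q)])
        return float(np.quantile(self.draws, q))

    @property
    def quantiles(self) -> dict[int, float]:
        """The 5/25/50/75/95 percent points of the null."""
        return {lv: self.quantile(lv / 100.0) for lv in _QUANTILE_LEVELS}

    def sf(self, srd: float) -> float:
        """P(SRD_null <= srd): how deep into the null an observed SRD sits."""
        if self.method == "exact":
            return float(self.probabilities[self.support <= srd].sum())
        return float(np.mean(self.draws <= srd))


def _crrn_exact(n: int) -> tuple[np.ndarray, np.ndarray]:
    # Distribution of sum_i |pi(i) - i| over all permutations, by a
    # bitmask dynamic program: dp[mask] counts assignments of the value
    # set `mask` to the first popcount(mask) positions, binned by the
    # partial SRD.  O(2^n * n * SRDmax) — fine up to n = 10.
    size = srd_max(n) + 1
    dp = np.zeros((1 << n, size))
    dp[0, 0] = 1.0
    for mask in range(1 << n):
        row = dp[mask]
        if not row.any():
            continue
        pos = bin(mask).count("1")
        for v in range(n):
            bit = 1 << v
            if mask & bit:
                continue
            d = abs(v - pos)
            dp[mask | bit, d:] += row[: size - d]
    counts = dp[-1]
    support = np.flatnonzero(counts)
    return support.astype(int), counts[support] / math.factorial(n)


def _crrn_monte_carlo(n: int, n_draws: int, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    ident = np.arange(1, n + 1)
    out = np.empty(n_draws, dtype=np.int32)
    pos = 0
    chunk = 200_000
    while pos < n_draws:
        m = min(chunk, n_draws - pos)
        perms = rng.permuted(np.tile(ident, (m, 1)), axis=1)
        out[pos : pos + m] = np.abs(perms - ident).sum(axis=1)
        pos += m
    return out


def crrn(n_objects: int, method: str = "auto", n_draws: int = 1_000_000,
         seed=None) -> CRRNDistribution:
    """Null SRD distribution for rankings of ``n_objects`` items.

    ``method`` is "exact" (full enumeration, n <= 10), "monte_carlo", or
    "auto" (exact when feasible).
    """
    n = int(n_objects)
    if n < 2:
        raise ValueError("n_objects must be >= 2")
    if method == "auto":
        method = "exact" if n <= EXACT_LIMIT else "monte_carlo"
    if method == "exact":
        if n > EXACT_LIMIT:
            raise ValueError(
                f"exact enumeration limited to n <= {EXACT_LIMIT}; "
                "use method='monte_carlo'"
            )
        support, probs = _crrn_exact(n)
        return CRRNDistribution(n, "exact", support=support, probabilities=probs)
    if method == "monte_carlo":
        if n_draws < 1:
            raise ValueError("n_draws must be positive")
        draws = _crrn_monte_carlo(n, n_draws, seed)
        return CRRNDistribution(n, "monte_carlo", draws=draws)
    raise ValueError(f"unknown CRRN method: {method!r}")


@dataclass
class WilcoxonResult:
    statistic: float
    pvalue: float
    all_zero: bool = False


def wilcoxon_matched_pairs(x, y) -> WilcoxonResult:
    """Two-sided Wilcoxon matched-pair signed-rank test.

    Zero differences are dropped (Wilcoxon's convention).  The p-value
    is exact (enumeration over sign assignments) for up to 25 nonzero
    tie-free differences and uses the normal approximation otherwise.
    All-zero differences return p = 1 with the ``all_zero`` flag set.
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples differ in length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return WilcoxonResult(0.0, 1.0, all_zero=True)
    if d.size < 3:
        raise ValueError("need at least 3 nonzero differences")
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if d.size <= 25 and not ties else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         correction=False, method=method)
    return WilcoxonResult(float(res.statistic), float(res.pvalue))


_SCALERS = {
    "range": range_scale_columns,
    "standardize": standardize_columns,
    "none": lambda t: t,
}


def _srd_table(table: pd.DataFrame,
               scaling: str = "range") -> tuple[pd.Series, pd.Series, np.ndarray]:
    """Scale columns, build the row-average reference, score every column."""
    try:
        scaled = _SCALERS[scaling](table)
    except KeyError:
        raise ValueError(f"unknown scaling: {scaling!r}") from None
    ref = reference_ranking(scaled)
    n = len(scaled)
    raw = {}
    for name in scaled.columns:
        raw[name] = srd_value(rank_with_ties(scaled[name].to_numpy()), ref)
    raw = pd.Series(raw, name="srd")
    pct = raw.map(lambda v: srd_normalize(v, n)).rename("srd_pct")
    return raw, pct, ref


class SRDAnalysis:
    """Sum-of-ranking-differences model for a compound-by-measure table.

    Parameters
    ----------
    table:
        Numeric DataFrame, compounds in rows, measures in columns.
        Columns are scaled internally (see module docstring) before the
        row-average reference is built.
    scaling:
        "range" (default), "standardize", or "none".
    crrn_method, n_draws, seed:
        Passed to :func:`crrn` for the null distribution over
        ``len(table)`` objects.  ``crrn_method=None`` skips the null.
    """

    def __init__(self, table: pd.DataFrame, crrn_method: str | None = "auto",
                 n_draws: int = 1_000_000, seed=None, scaling: str = "range"):
        if table.shape[0] < 2 or table.shape[1] < 2:
            raise ValueError("need at least 2 compounds and 2 measures")
        if scaling not in _SCALERS:
            raise ValueError(f"unknown scaling: {scaling!r}")
        self.table = table.astype(float)
        self.crrn_method = crrn_method
        self.n_draws = n_draws
        self.seed = seed
        self.scaling = scaling

    def fit(self) -> "SRDResults":
        raw, pct, ref = _srd_table(self.table, self.scaling)
        null = None
        if self.crrn_method is not None:
            null = crrn(len(self.table), method=self.crrn_method,
                        n_draws=self.n_draws, seed=self.seed)
        order = raw.sort_values(kind="stable").index.tolist()
        return SRDResults(self, raw, pct, ref, null, order)


@dataclass
class SRDResults:
    """Fitted SRD ranking with its CRRN null and CV utilities."""

    model: SRDAnalysis
    srd_raw: pd.Series
    srd_pct: pd.Series
    reference_ranks: np.ndarray
    crrn: CRRNDistribution | None
    ordering: list[str]

    def crossvalidate(self, k: int = 7, seed=None) -> pd.DataFrame:
        """k-fold SRD% values (rows = folds, columns = measures)."""
        return srd_crossvalidate(self.model.table, k=k, seed=seed,
                                 scaling=self.model.scaling)

    def wilcoxon_matrix(self, cv_pct: pd.DataFrame) -> pd.DataFrame:
        """Pairwise Wilcoxon p-values between measures' CV SRD% vectors."""
        cols = list(cv_pct.columns)
        p = pd.DataFrame(np.ones((len(cols), len(cols))), index=cols, columns=cols)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                res = wilcoxon_matched_pairs(cv_pct[a].to_numpy(),
                                             cv_pct[b].to_numpy())
                p.loc[a, b] = p.loc[b, a] = res.pvalue
        return p

    def summary(self) -> str:
        lines = [
            "Sum of ranking differences (row-average reference)",
            f"  objects: {len(self.model.table)}   measures: {self.srd_raw.size}",
            "",
            f"  {'measure':<18}{'SRD':>8}{'SRD%':>9}",
        ]
        for name in self.ordering:
            lines.append(
                f"  {name:<18}{self.srd_raw[name]:>8.1f}{self.srd_pct[name]:>9.2f}"
            )
        if self.crrn is not None:
            q = self.crrn.quantiles
            lines += [
                "",
                "  CRRN null (random rankings): "
                + ", ".join(f"{lv}%={q[lv]:.0f}" for lv in _QUANTILE_LEVELS)
                + f", mean={self.crrn.mean:.1f}",
            ]
        return "\n".join(lines)


def srd_analysis(table: pd.DataFrame, crrn_method: str | None = "auto",
                 n_draws: int = 1_000_000, seed=None,
                 scaling: str = "range") -> SRDResults:
    """Convenience wrapper: ``SRDAnalysis(table, ...).fit()``."""
    return SRDAnalysis(table, crrn_method=crrn_method, n_draws=n_draws,
                       seed=seed, scaling=scaling).fit()


def srd_crossvalidate(table: pd.DataFrame, k: int = 7, seed=None,
                      scaling: str = "range") -> pd.DataFrame:
    """Leave-one-fold-out SRD%: omit ~1/k of compounds, rescore the rest.

    Folds are a seeded random partition into k nearly equal groups
    (27 compounds, k=7 gives sizes 4,4,4,4,4,4,3).  Each left-out fold
    yields one SRD% value per measure, computed on the retained
    compounds after rescaling and rebuilding the reference.
    """
    n = len(table)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), k)
    rows = []
    for fold in folds:
        keep = np.setdiff1d(np.arange(n), fold)
        _, pct, _ = _srd_table(table.iloc[keep], scaling)
        rows.append(pct)
    out = pd.DataFrame(rows, index=pd.RangeIndex(k, name="fold"))
    out.columns.name = table.columns.name
    return out
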