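"""Investigative analyses: exact vs asymptotic Wilcoxon, confounding tests,
relative expression and ESS-stratified calibration summaries."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ScreenDataset
from .nb_glm import fit_null_glm

__all__ = [
    "WilcoxonComparison",
    "EssBins",
    "DEFAULT_ESS_BINS",
    "relative_expression",
    "wilcoxon_exact_vs_asymptotic",
    "confounding_grna_test",
    "confounding_gene_test",
    "stratified_calibration",
]

# effective-sample-size strata used for calibration summaries
DEFAULT_ESS_BINS = [(7, 10), (11, 16), (17, 27), (28, 46), (47, 121)]


@dataclass
class WilcoxonComparison:
    p_asymptotic: float
    p_exact: float
    ks_gof: float
    ess: int
    degenerate: bool = False

    @property
    def p_ratio(self) -> float:
        return self.p_exact / self.p_asymptotic


@dataclass
class EssBins:
    edges: list[tuple[int, int]] = field(default_factory=lambda: list(DEFAULT_ESS_BINS))

    def __post_init__(self) -> None:
        for (lo, hi), (lo2, _) in zip(self.edges, self.edges[1:]):
            if hi >= lo2 or lo > hi:
                raise ValueError("bins must be ascending, disjoint intervals")

    def assign(self, ess: int) -> int | None:
        for k, (lo, hi) in enumerate(self.edges):
            if lo <= ess <= hi:
                return k
        return None

    @classmethod
    def equal_frequency(cls, ess_values: np.ndarray, n_bins: int = 5) -> "EssBins":
        """Bins holding approximately equal numbers of pairs."""
        ess = np.sort(np.asarray(ess_values))
        qs = np.quantile(ess, np.linspace(0, 1, n_bins + 1), method="inverted_cdf")
        edges = []
        lo = int(qs[0])
        for k in range(1, n_bins + 1):
            hi = int(qs[k]) if k == n_bins else int(qs[k]) - 1
            if hi >= lo:
                edges.append((lo, hi))
                lo = hi + 1
        return cls(edges=edges)


def relative_expression(u: float, l: float) -> float:
    """1000 * ln(u / l + 1) for a UMI count u and library size l > 0."""
    if l <= 0:
        raise ValueError("library size must be positive")
    if u < 0:
        raise ValueError("UMI count must be nonnegative")
    return 1000.0 * math.log(u / l + 1.0)


def _rank_sum_stats(y: np.ndarray, n1: int) -> tuple[np.ndarray, float, float]:
    """Mid-ranks plus null mean/SD of the group-1 rank sum (tie-corrected)."""
    n = len(y)
    ranks = stats.rankdata(y)
    mean = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(y, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * (n - n1) / 12.0 * ((n + 1) - tie_term)
    return ranks, mean, math.sqrt(max(var, 0.0))


def wilcoxon_exact_vs_asymptotic(
    y_norm: np.ndarray,
    treatment_idx: np.ndarray,
    B: int = 200_000,
    seed: int = 0,
) -> WilcoxonComparison:
    """Two-sample Wilcoxon p-value: Gaussian reference vs B-permutation null.

    The statistic is the treatment rank sum standardized with the
    tie-corrected null moments; the exact p uses the add-one convention and
    the permutation distribution of the same standardized statistic, whose
    KS distance to N(0,1) is also reported.
    """
    y = np.asarray(y_norm, dtype=float)
    treatment_idx = np.asarray(treatment_idx)
    n = len(y)
    n1 = len(treatment_idx)
    if n1 == 0 or n1 >= n:
        raise ValueError("both groups must be nonempty")
    ess = int(np.count_nonzero(y[treatment_idx]))
    if np.ptp(y) == 0:
        return WilcoxonComparison(1.0, 1.0, np.nan, ess, degenerate=True)

    ranks, mean, sd = _rank_sum_stats(y, n1)
    z_obs = (float(ranks[treatment_idx].sum()) - mean) / sd
    p_asym = float(2 * stats.norm.sf(abs(z_obs)))

    rng = np.random.default_rng(seed)
    # permuting labels = drawing n1-subsets of the fixed rank vector
    z_null = np.empty(B)
    chunk = max(1, min(B, 10_000_000 // max(n, 1)))
    pos = 0
    while pos < B:
        m = min(chunk, B - pos)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
        z_null[pos : pos + m] = (ranks[idx].sum(axis=1) - mean) / sd
        pos += m
    more_extreme = np.sum(np.abs(z_null) >= abs(z_obs) - 1e-12)
    p_exact = (1 + int(more_extreme)) / (B + 1)
    ks = float(stats.ks_1samp(z_null, stats.norm.cdf).statistic)
    return WilcoxonComparison(p_asym, p_exact, ks, ess)


# ---------------------------------------------------------------------------
# Confounding tests
# ---------------------------------------------------------------------------

def _log_table_prob(row1: np.ndarray, col_tot: np.ndarray, n1: int, n: int) -> float:
    """Log probability of a 2xk table under fixed margins (multivariate
    hypergeometric)."""
    from scipy.special import gammaln

    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return float(np.sum(logc(col_tot, row1)) - logc(n, n1))


def _fisher_exact_2xk(table: np.ndarray, rng=None, n_sim: int = 100_000) -> float:
    """Fisher exact p for a 2xk table: probability-ordering criterion.

    Small tables are enumerated exhaustively; large ones use a seeded
    multivariate-hypergeometric Monte Carlo with the add-one convention.
    """
    row1 = table[0]
    col_tot = table.sum(axis=0)
    n1 = int(row1.sum())
    n = int(table.sum())
    k = table.shape[1]
    lp_obs = _log_table_prob(row1, col_tot, n1, n)

    # exhaustive when the composition space is small
    ranges = [range(0, min(int(c), n1) + 1) for c in col_tot[:-1]]
    space = np.prod([len(r) for r in ranges]) if k > 1 else 1
    if space <= 200_000:
        total = 0.0
        hit = 0.0
        for combo in itertools.product(*ranges):
            last = n1 - sum(combo)
            if last < 0 or last > col_tot[-1]:
                continue
            r1 = np.array(list(combo) + [last])
            lp = _log_table_prob(r1, col_tot, n1, n)
            p = math.exp(lp)
            total += p
            if lp <= lp_obs + 1e-12:
                hit += p
        return min(1.0, hit / total)

    rng = rng or np.random.default_rng(0)
    draws = rng.multivariate_hypergeometric(col_tot.astype(int), n1, size=n_sim)
    lps = np.array([_log_table_prob(d, col_tot, n1, n) for d in draws])
    return (1 + int(np.sum(lps <= lp_obs + 1e-12))) / (n_sim + 1)


def confounding_grna_test(
    ds: ScreenDataset, grna_id: str, factor: str, seed: int = 0
) -> float:
    """Fisher exact test of gRNA presence/absence against a categorical factor."""
    fac = ds.covariates[factor].astype(str)
    levels = sorted(fac.unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    vec = ds.assignment_vector()
    present = vec == grna_id
    table = np.array(
        [
            [int(np.sum(present & (fac.to_numpy() == lev))) for lev in levels],
            [int(np.sum(~present & (fac.to_numpy() == lev))) for lev in levels],
        ]
    )
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        return 1.0
    if table.shape[1] == 2:
        return float(stats.fisher_exact(table)[1])
    return _fisher_exact_2xk(table, rng=np.random.default_rng(seed))


def confounding_gene_test(ds: ScreenDataset, response_id: str, factor: str) -> float:
    """Likelihood-ratio test of a categorical factor's effect on expression.

    Compares NB fits with covariates {library size} vs {library size, factor};
    the size parameter is re-estimated in each model.
    """
    from .data_model import build_covariate_matrix

    y = ds.response_row(response_id)
    Z0 = build_covariate_matrix(ds, ["library_size"]).to_numpy()
    Z1 = build_covariate_matrix(ds, ["library_size", factor]).to_numpy()
    fit0 = fit_null_glm(y, Z0, family="nb")
    fit1 = fit_null_glm(y, Z1, family="nb")
    if not (fit0.converged and fit1.converged):
        return float("nan")
    lr = 2.0 * (fit1.loglik - fit0.loglik)
    df = Z1.shape[1] - Z0.shape[1]
    return float(stats.chi2.sf(max(lr, 0.0), df))


# ---------------------------------------------------------------------------
# Stratified calibration
# ---------------------------------------------------------------------------

def stratified_calibration(results, bins: EssBins | None = None) -> pd.DataFrame:
    """Per-ESS-bin QQ summaries of a batch of pair results.

    For each bin: sorted p-values, uniform expected quantiles k/(m+1), a
    pointwise 95% band from the Beta(k, m+1-k) order-statistic distribution,
    and the KS statistic against Uniform(0, 1).
    """
    bins = bins or EssBins()
    rows = []
    for k, (lo, hi) in enumerate(bins.edges):
        ps = np.sort(
            [r.p_two for r in results if r.qc_pass and lo <= r.ess <= hi]
        )
        m = len(ps)
        if m == 0:
            continue
        ks_idx = np.arange(1, m + 1)
        expected = ks_idx / (m + 1.0)
        lower = stats.beta.ppf(0.025, ks_idx, m + 1 - ks_idx)
        upper = stats.beta.ppf(0.975, ks_idx, m + 1 - ks_idx)
        ks_stat = float(stats.ks_1samp(ps, stats.uniform.cdf).statistic)
        for i in range(m):
            rows.append(
                {
                    "bin": k,
                    "ess_lo": lo,
                    "ess_hi": hi,
                    "rank": int(ks_idx[i]),
                    "p": float(ps[i]),
                    "expected": float(expected[i]),
                    "band_lo": float(lower[i]),
                    "band_hi": float(upper[i]),
                    "n_pairs": m,
                    "ks_stat": ks_stat,
                }
            )
    return pd.DataFrame(rows)
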