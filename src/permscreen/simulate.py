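"""Synthetic screen generators and the confounding simulation study.

Three generators:

* :func:`simulate_null_screen` — a signal-free screen: gene-wise NB means
  drawn from Gamma(shape=0.5, rate=2), sizes from Unif(1, 25), one
  non-targeting gRNA per cell assigned uniformly at random, no confounding.
  Paper-scale default: 5000 genes, 25 gRNAs, 10,000 cells.
* :func:`simulate_positive_control_screen` — adds positive-control gRNAs,
  each linked to one gene whose mean in that gRNA's cells is an independent
  Gamma draw.  Paper-scale default: 125 genes, 25 PC gRNAs, 100 NT gRNAs,
  15,000 cells.
* :func:`simulate_confounding_study` — the confounding-by-batch study: a single
  response model NB(exp(beta' Z), theta_star) with the treatment indicator
  either tilted by batch (confounded) or i.i.d. Bernoulli (unconfounded),
  evaluated with the size parameter set to theta_star or 5*theta_star.

All generators are pure functions of their config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .data_model import ScreenDataset
from .nb_glm import fit_null_glm
from .resampling import ResampleBank, empirical_p, universe_key
from .score import precompute, score_stat, score_stat_many

__all__ = [
    "SyntheticConfig",
    "ConfoundingStudyConfig",
    "ConfoundingStudyBundle",
    "simulate_null_screen",
    "simulate_positive_control_screen",
    "simulate_confounding_study",
    "run_confounding_evaluation",
]


@dataclass
class SyntheticConfig:
    """Parameters of the null / positive-control screen generators."""

    n_genes: int = 5000
    n_nt_grnas: int = 25
    n_pc_grnas: int = 0
    n_cells: int = 10_000
    gene_mean_shape: float = 0.5
    gene_mean_rate: float = 2.0
    size_low: float = 1.0
    size_high: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_nt_grnas, self.n_cells) <= 0:
            raise ValueError("counts must be positive")
        if self.gene_mean_shape <= 0 or self.gene_mean_rate <= 0:
            raise ValueError("gamma parameters must be positive")
        if not self.size_low < self.size_high:
            raise ValueError("size_law requires low < high")


def _nb_draws(rng, mean: float | np.ndarray, size_param: float, n: int) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def _assemble(cfg: SyntheticConfig, rng, grna_ids, targeting, targets, counts) -> ScreenDataset:
    n = cfg.n_cells
    cell_ids = [f"cell_{i}" for i in range(n)]
    response_ids = [f"gene_{g}" for g in range(cfg.n_genes)]
    assignment_idx = rng.integers(0, len(grna_ids), size=n)
    assignment = pd.DataFrame(
        {"cell_id": cell_ids, "grna_id": [grna_ids[j] for j in assignment_idx]}
    )
    grna_table = pd.DataFrame(
        {
            "grna_id": grna_ids,
            "target": targets,
            "targeting": targeting,
            "grna_group": grna_ids,
        }
    ).set_index("grna_id")
    covariates = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    ds = ScreenDataset(
        counts=counts,
        response_ids=response_ids,
        cell_ids=cell_ids,
        grna_assignment=assignment,
        grna_table=grna_table,
        covariates=covariates,
    )
    ds.validate()
    return ds, assignment_idx


def simulate_null_screen(cfg: SyntheticConfig | None = None) -> ScreenDataset:
    """Signal-free screen: NB counts per gene, one NT gRNA per cell."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    means = rng.gamma(cfg.gene_mean_shape, 1.0 / cfg.gene_mean_rate, size=cfg.n_genes)
    sizes = rng.uniform(cfg.size_low, cfg.size_high, size=cfg.n_genes)

    rows = []
    for g in range(cfg.n_genes):
        y = _nb_draws(rng, means[g], sizes[g], cfg.n_cells)
        rows.append(sp.csr_matrix(y[None, :]))
    counts = sp.vstack(rows, format="csr")

    grna_ids = [f"nt_{i}" for i in range(cfg.n_nt_grnas)]
    ds, _ = _assemble(
        cfg, rng, grna_ids, [False] * cfg.n_nt_grnas, ["non-targeting"] * cfg.n_nt_grnas, counts
    )
    return ds


def simulate_positive_control_screen(
    cfg: SyntheticConfig | None = None,
) -> tuple[ScreenDataset, pd.DataFrame]:
    """Screen with known signal: each PC gRNA shifts one linked gene's mean.

    Returns the dataset and a truth table (grna_id, response_id, control and
    treatment means).  Linkage is bijective over the first ``n_pc_grnas``
    genes.
    """
    cfg = cfg or SyntheticConfig(
        n_genes=125, n_nt_grnas=100, n_pc_grnas=25, n_cells=15_000
    )
    if cfg.n_pc_grnas > cfg.n_genes:
        raise ValueError("need at least one gene per PC gRNA")
    rng = np.random.default_rng(cfg.seed)
    means = rng.gamma(cfg.gene_mean_shape, 1.0 / cfg.gene_mean_rate, size=cfg.n_genes)
    sizes = rng.uniform(cfg.size_low, cfg.size_high, size=cfg.n_genes)

    grna_ids = [f"pc_{i}" for i in range(cfg.n_pc_grnas)] + [
        f"nt_{i}" for i in range(cfg.n_nt_grnas)
    ]
    targeting = [True] * cfg.n_pc_grnas + [False] * cfg.n_nt_grnas
    targets = [f"gene_{i}" for i in range(cfg.n_pc_grnas)] + [
        "non-targeting"
    ] * cfg.n_nt_grnas

    n = cfg.n_cells
    assignment_idx = rng.integers(0, len(grna_ids), size=n)

    truth_rows = []
    rows = []
    for g in range(cfg.n_genes):
        y = _nb_draws(rng, means[g], sizes[g], n)
        if g < cfg.n_pc_grnas:  # gene g is linked to PC gRNA g
            cells = np.flatnonzero(assignment_idx == g)
            mean_t = rng.gamma(cfg.gene_mean_shape, 1.0 / cfg.gene_mean_rate)
            y[cells] = _nb_draws(rng, mean_t, sizes[g], len(cells))
            truth_rows.append(
                {
                    "grna_id": f"pc_{g}",
                    "grna_group": f"pc_{g}",
                    "response_id": f"gene_{g}",
                    "mean_control": means[g],
                    "mean_treatment": mean_t,
                }
            )
        rows.append(sp.csr_matrix(y[None, :]))
    counts = sp.vstack(rows, format="csr")

    cell_ids = [f"cell_{i}" for i in range(n)]
    assignment = pd.DataFrame(
        {"cell_id": cell_ids, "grna_id": [grna_ids[j] for j in assignment_idx]}
    )
    grna_table = pd.DataFrame(
        {"grna_id": grna_ids, "target": targets, "targeting": targeting, "grna_group": grna_ids}
    ).set_index("grna_id")
    ds = ScreenDataset(
        counts=counts,
        response_ids=[f"gene_{g}" for g in range(cfg.n_genes)],
        cell_ids=cell_ids,
        grna_assignment=assignment,
        grna_table=grna_table,
        covariates=pd.DataFrame(index=pd.Index(cell_ids, name="cell_id")),
    )
    ds.validate()
    return ds, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Confounding simulation study
# ---------------------------------------------------------------------------

@dataclass
class ConfoundingStudyConfig:
    """Generative and evaluation parameters of the confounding study.

    The response model is NB(exp(beta' Z), theta_star) where Z holds an
    intercept, batch indicators and one standard-normal continuous factor.
    The confounded treatment indicator is Bernoulli with a batch-dependent
    logit tilt; the unconfounded indicator is i.i.d. Bernoulli(pi_hat).  Both
    indicator vectors are drawn once and shared across replicate datasets.
    Methods are handed theta_star or 5*theta_star.
    """

    n_cells: int = 2000
    n_batches: int = 3
    batch_effects: tuple[float, ...] = (0.0, 0.75, -0.75)
    cont_effect: float = 0.2
    intercept: float = float(np.log(5.0))
    theta_star: float = 2.0
    misspec_factor: float = 5.0
    pi_hat: float = 0.05
    grna_tilt: float = 1.0
    B_datasets: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.batch_effects) != self.n_batches:
            raise ValueError("need one batch effect per batch")
        if not 0 < self.pi_hat < 1:
            raise ValueError("pi_hat must be in (0, 1)")


@dataclass
class ConfoundingStudyBundle:
    """Replicate responses plus the two treatment pairings."""

    cfg: ConfoundingStudyConfig
    Z: np.ndarray  # design including intercept, batch dummies, continuous
    batch: np.ndarray
    mu: np.ndarray
    X_confounded: np.ndarray
    X_unconfounded: np.ndarray
    Y: np.ndarray = field(repr=False)  # (B_datasets, n_cells)


def simulate_confounding_study(cfg: ConfoundingStudyConfig | None = None) -> ConfoundingStudyBundle:
    cfg = cfg or ConfoundingStudyConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    batch = rng.integers(0, cfg.n_batches, size=n)
    cont = rng.standard_normal(n)
    Z = np.column_stack(
        [np.ones(n)]
        + [(batch == b).astype(float) for b in range(1, cfg.n_batches)]
        + [cont]
    )
    beta = np.array(
        [cfg.intercept]
        + [cfg.batch_effects[b] - cfg.batch_effects[0] for b in range(1, cfg.n_batches)]
        + [cfg.cont_effect]
    )
    mu = np.exp(Z @ beta)

    # batch-tilted treatment probabilities, centered so the marginal ~ pi_hat
    base_logit = np.log(cfg.pi_hat / (1 - cfg.pi_hat))
    tilts = np.linspace(-cfg.grna_tilt, cfg.grna_tilt, cfg.n_batches)
    logits = base_logit + tilts[batch]
    p_conf = 1 / (1 + np.exp(-logits))
    p_conf *= cfg.pi_hat / p_conf.mean()
    X_conf = (rng.random(n) < p_conf).astype(int)
    X_unconf = (rng.random(n) < cfg.pi_hat).astype(int)
    # degenerate draws would make a pair untestable; regenerate is overkill at
    # these sizes (probability ~ (1-pi)^n)
    for X in (X_conf, X_unconf):
        if X.sum() in (0, n):
            raise RuntimeError("degenerate treatment draw; change seed")

    p_nb = cfg.theta_star / (cfg.theta_star + mu)
    Y = rng.negative_binomial(cfg.theta_star, p_nb, size=(cfg.B_datasets, n))
    return ConfoundingStudyBundle(
        cfg=cfg, Z=Z, batch=batch, mu=mu,
        X_confounded=X_conf, X_unconfounded=X_unconf, Y=Y,
    )


def run_confounding_evaluation(
    bundle: ConfoundingStudyBundle,
    alphas: tuple[float, ...] = (0.01, 0.05, 0.1),
    B_perm: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Rejection rates of the three methods in the four study arms.

    Methods: the permuted score statistic with empirical p (``permuted_score``), the
    same score statistic against the N(0,1) reference (``nb_regression``),
    and the plain permutation test with the treatment-cell expression sum as
    statistic (``perm_sum``).  The size parameter is fixed at the arm's
    theta (never estimated).  Two-sided p-values throughout.
    """
    cfg = bundle.cfg
    n = cfg.n_cells
    arms = {
        ("confounded", "theta_star"): (bundle.X_confounded, cfg.theta_star),
        ("confounded", "theta_misspec"): (bundle.X_confounded, cfg.theta_star * cfg.misspec_factor),
        ("unconfounded", "theta_star"): (bundle.X_unconfounded, cfg.theta_star),
        ("unconfounded", "theta_misspec"): (bundle.X_unconfounded, cfg.theta_star * cfg.misspec_factor),
    }
    universe = np.arange(n)
    bank = ResampleBank(n, seed, universe_key(universe))
    perm_block = bank.orderings_block(0, B_perm)

    pvals: dict[tuple[str, str, str], list[float]] = {}
    fits_cache: dict[tuple[int, float], tuple] = {}
    for j in range(cfg.B_datasets):
        y = bundle.Y[j].astype(float)
        for (conf_label, theta_label), (X, theta_used) in arms.items():
            key = (j, theta_used)
            if key not in fits_cache:
                fit = fit_null_glm(y, bundle.Z, family="nb", theta=theta_used)
                fits_cache[key] = (fit, precompute(fit, bundle.Z))
                if len(fits_cache) > 2:  # keep only this replicate's two fits
                    fits_cache = {k: v for k, v in fits_cache.items() if k[0] == j}
            fit, pc = fits_cache[key]
            t_idx = np.flatnonzero(X)
            t = len(t_idx)
            z_obs = score_stat(t_idx, pc)
            z_null = score_stat_many(perm_block[:, :t], pc)
            z_null = z_null[np.isfinite(z_null)]
            pvals.setdefault(("permuted_score", conf_label, theta_label), []).append(
                empirical_p(z_obs, z_null, "two")
            )
            pvals.setdefault(("nb_regression", conf_label, theta_label), []).append(
                float(2 * stats.norm.sf(abs(z_obs)))
            )
            s_obs = float(y[t_idx].sum())
            s_null = y[perm_block[:, :t]].sum(axis=1)
            pvals.setdefault(("perm_sum", conf_label, theta_label), []).append(
                empirical_p(s_obs, s_null, "two")
            )

    rows = []
    for (method, conf_label, theta_label), ps in sorted(pvals.items()):
        ps_arr = np.asarray(ps)
        row = {
            "method": method,
            "confounding": conf_label,
            "theta": theta_label,
            "n_datasets": len(ps_arr),
        }
        for a in alphas:
            row[f"reject_at_{a}"] = float(np.mean(ps_arr <= a))
        rows.append(row)
    return pd.DataFrame(rows)
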