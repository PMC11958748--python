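"""Permutation-based empirical t-testing of normalized expression matrices.

The statistic is the pooled-variance two-sample Student t per gene (Welch
available as a switch). Because a 3 vs 3 design admits only C(6,3) = 20
distinct label assignments, per-gene permutation nulls are far too discrete
to reach small p-values; the null is therefore *pooled*: |t| values from
label permutations are aggregated across all genes and permutations into
one global empirical distribution, and each gene's two-sided p-value is its
add-one-smoothed exceedance fraction in that pool. Random permutations
sample label assignments uniformly with replacement (the identity is not
excluded); an exhaustive mode enumerating all distinct assignments serves
as the exactness oracle.

Multiple testing is corrected with Benjamini-Hochberg by default; a plugin
permutation-FDR (mean null exceedances over observed exceedances) is
available behind a config switch for sensitivity analysis. A gene is called
differentially expressed when its adjusted p-value is below ``alpha``
(strict) and its |log2 fold change| exceeds the cutoff (strict), where the
cutoff is either the 95th percentile of |log2FC| over all expressed genes
(percentile mode) or a fixed value such as 0.336 (~1.26-fold).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError

__all__ = [
    "DeConfig",
    "NullDistribution",
    "t_statistic",
    "build_null",
    "empirical_pvalue",
    "adjust_pvalues",
    "fc_cutoff",
    "call_degs",
    "PermutationTTest",
]


@dataclass(frozen=True)
class DeConfig:
    """Configuration of the empirical t-test stage.

    ``fc_cutoff_mode`` selects how the fold-change threshold is derived:
    ``"percentile"`` takes the ``fc_percentile`` quantile of |log2FC| over
    all expressed genes (default 0.95, i.e. the top 5%), ``"fixed"`` uses
    ``fc_fixed`` verbatim (0.336 reproduces the published cutoff).
    """

    n_permutations: int = 1000
    alpha_adj: float = 0.05
    fc_cutoff_mode: str = "percentile"
    fc_percentile: float = 0.95
    fc_fixed: float = 0.336
    variance_floor: float = 1e-8
    permutation_scheme: str = "sampled"
    adjust_method: str = "bh"
    statistic: str = "pooled"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if not 0.0 < self.alpha_adj < 1.0:
            raise ConfigurationError("alpha_adj must lie in (0, 1)")
        if self.fc_cutoff_mode not in ("percentile", "fixed"):
            raise ConfigurationError("fc_cutoff_mode must be 'percentile' or 'fixed'")
        if not 0.0 < self.fc_percentile < 1.0:
            raise ConfigurationError("fc_percentile must lie in (0, 1)")
        if self.fc_fixed < 0:
            raise ConfigurationError("fc_fixed must be nonnegative")
        if self.variance_floor <= 0:
            raise ConfigurationError("variance_floor must be strictly positive")
        if self.permutation_scheme not in ("sampled", "exhaustive"):
            raise ConfigurationError("permutation_scheme must be 'sampled' or 'exhaustive'")
        if self.adjust_method not in ("bh", "perm-fdr"):
            raise ConfigurationError("adjust_method must be 'bh' or 'perm-fdr'")
        if self.statistic not in ("pooled", "welch"):
            raise ConfigurationError("statistic must be 'pooled' or 'welch'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class NullDistribution:
    """Pooled empirical null of |t| across genes and permutations."""

    pooled_abs_t: np.ndarray  # sorted ascending, nonnegative
    n_permutations: int
    permutation_scheme: str
    seed: int

    @property
    def size(self) -> int:
        return int(self.pooled_abs_t.size)


# ---------------------------------------------------------------------------
# primitives

def t_statistic(x_control, x_treated, variance_floor: float = 1e-8) -> float:
    """Pooled-variance two-sample Student t of treated minus control.

    ``(mean_treated - mean_control) / sqrt(s2p * (1/n1 + 1/n2))`` with the
    pooled sample variance ``s2p`` floored at ``variance_floor`` so that
    exactly tied rows (common after quantile normalization) stay finite.
    """
    x = np.asarray(x_control, dtype=float)
    y = np.asarray(x_treated, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    n1, n2 = x.size, y.size
    s2p = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    s2p = max(s2p, variance_floor)
    return float((y.mean() - x.mean()) / np.sqrt(s2p * (1.0 / n1 + 1.0 / n2)))


def _t_matrix(values: np.ndarray, treated_masks: np.ndarray,
              variance_floor: float, statistic: str = "pooled") -> np.ndarray:
    """t-statistics for every gene (rows of ``values``) under each mask.

    ``values`` is genes x samples; ``treated_masks`` is B x samples boolean.
    Vectorized with matrix products so a 5,000-gene, 1,000-permutation null
    costs a few matrix multiplies.
    """
    masks = np.atleast_2d(treated_masks)
    n1 = masks.sum(axis=1).astype(float)
    n0 = masks.shape[1] - n1
    if (n1 < 2).any() or (n0 < 2).any():
        raise ValueError("each group needs at least 2 samples under every assignment")
    A = masks.T.astype(float)
    Ac = 1.0 - A
    sq = values ** 2
    s1t, s1c = values @ A, values @ Ac
    s2t, s2c = sq @ A, sq @ Ac
    mt, mc = s1t / n1, s1c / n0
    vt = (s2t - n1 * mt ** 2) / (n1 - 1)
    vc = (s2c - n0 * mc ** 2) / (n0 - 1)
    # guard tiny negatives from cancellation
    vt = np.clip(vt, 0.0, None)
    vc = np.clip(vc, 0.0, None)
    if statistic == "welch":
        denom = np.sqrt(np.maximum(vt, variance_floor) / n1
                        + np.maximum(vc, variance_floor) / n0)
    else:
        s2p = ((n1 - 1) * vt + (n0 - 1) * vc) / (n1 + n0 - 2)
        denom = np.sqrt(np.maximum(s2p, variance_floor) * (1.0 / n1 + 1.0 / n0))
    return (mt - mc) / denom


def _sampled_masks(base_mask: np.ndarray, n_permutations: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Uniform-with-replacement label reassignments, group sizes preserved."""
    tiled = np.tile(base_mask, (n_permutations, 1))
    return rng.permuted(tiled, axis=1)


def _exhaustive_masks(n_samples: int, n_treated: int) -> np.ndarray:
    combos = list(itertools.combinations(range(n_samples), n_treated))
    masks = np.zeros((len(combos), n_samples), dtype=bool)
    for i, combo in enumerate(combos):
        masks[i, list(combo)] = True
    return masks


def build_null(values, treated_mask, config: DeConfig) -> NullDistribution:
    """Estimate the pooled empirical null of |t| by label permutation.

    ``values`` is the normalized genes x samples matrix (array or DataFrame)
    and ``treated_mask`` the boolean treated indicator over samples. In
    sampled mode, ``n_permutations`` reassignments are drawn uniformly with
    replacement from all label assignments (the identity included); in
    exhaustive mode all distinct assignments are enumerated (C(6,3) = 20 for
    a 3 vs 3 design). |t| values are pooled over genes and assignments into
    one sorted distribution.
    """
    arr = np.asarray(values, dtype=float)
    mask = np.asarray(treated_mask, dtype=bool)
    if config.permutation_scheme == "exhaustive":
        masks = _exhaustive_masks(mask.size, int(mask.sum()))
        n_perm = masks.shape[0]
    else:
        rng = np.random.default_rng(config.seed)
        masks = _sampled_masks(mask, config.n_permutations, rng)
        n_perm = config.n_permutations
    pooled = np.abs(_t_matrix(arr, masks, config.variance_floor, config.statistic))
    pooled = np.sort(pooled.ravel())
    return NullDistribution(
        pooled_abs_t=pooled,
        n_permutations=n_perm,
        permutation_scheme=config.permutation_scheme,
        seed=config.seed,
    )


def empirical_pvalue(t_obs, null: NullDistribution):
    """Two-sided empirical p with add-one smoothing.

    ``p = (1 + #{|t*| >= |t_obs|}) / (1 + N)`` over the pooled null, hence
    always in (0, 1], monotone non-increasing in |t_obs|, and valid
    (super-uniform) under the null. Accepts scalars or arrays.
    """
    if null.size == 0:
        raise ValueError("empty null distribution")
    abs_t = np.abs(np.asarray(t_obs, dtype=float))
    count_ge = null.size - np.searchsorted(null.pooled_abs_t, abs_t, side="left")
    p = (1.0 + count_ge) / (1.0 + null.size)
    if np.isscalar(t_obs):
        return float(p)
    return p


def adjust_pvalues(p_emp) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, monotone and capped at 1."""
    p = np.asarray(p_emp, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def permutation_fdr(abs_t_obs: np.ndarray, null: NullDistribution) -> np.ndarray:
    """Plugin permutation-FDR q-values (mean null exceedances / observed).

    For each gene's |t| threshold, the estimated FDR is the expected number
    of pooled-null exceedances per permutation divided by the observed
    exceedance count; monotone in |t| by cumulative minimum, clipped to
    (0, 1].
    """
    abs_t = np.abs(np.asarray(abs_t_obs, dtype=float))
    n_perm = null.size / abs_t.size if abs_t.size else 1
    null_ge = null.size - np.searchsorted(null.pooled_abs_t, abs_t, side="left")
    order = np.argsort(-abs_t, kind="mergesort")
    obs_sorted = np.sort(abs_t)
    obs_ge = abs_t.size - np.searchsorted(obs_sorted, abs_t, side="left")
    q = (null_ge / n_perm) / np.maximum(obs_ge, 1)
    # enforce monotone non-increasing q in |t|
    q_sorted = np.minimum.accumulate(q[order])
    out = np.empty_like(q)
    out[order] = q_sorted
    return np.clip(out, 1.0 / (1.0 + null.size), 1.0)


def fc_cutoff(log2fc, config: DeConfig) -> float:
    """Absolute log2 fold-change threshold for the DEG call.

    Percentile mode returns the ``fc_percentile`` quantile (linear
    interpolation) of |log2FC| over all expressed genes; fixed mode returns
    ``fc_fixed`` (0.336 reproduces the published cutoff verbatim).
    """
    fc = np.asarray(log2fc, dtype=float)
    if fc.size == 0:
        raise ValueError("empty fold-change vector")
    if config.fc_cutoff_mode == "fixed":
        return float(config.fc_fixed)
    return float(np.quantile(np.abs(fc), config.fc_percentile))


# ---------------------------------------------------------------------------
# estimator

class PermutationTTest(BaseEstimator):
    """Two-group differential expression by pooled-permutation empirical t-test.

    scikit-learn-style estimator: ``fit(X, y)`` takes ``X`` of shape
    ``(n_samples, n_genes)`` (array or DataFrame; DataFrame columns become
    gene identifiers) and two-group labels ``y``. The alphabetically first
    label is treated as the reference ("control") group; log2 fold changes
    are treated minus control on the log2(FPKM+1) scale.

    Samples are reordered internally to a canonical (group, sample id)
    order before any random draw, so fitted results do not depend on the
    order in which samples are supplied.

    Parameters mirror :class:`DeConfig`; ``random_state`` seeds the single
    permutation stream.

    Attributes
    ----------
    results_ : DataFrame
        Per-gene table (mean_control, mean_treated, log2fc, t_stat, p_emp,
        p_adj, is_deg, direction) sorted by p_adj, then |log2fc| descending,
        ties broken by gene id.
    null_distribution_ : NullDistribution
    fc_cutoff_ : float
        Realized fold-change threshold.
    classes_ : ndarray of the two group labels (reference first).
    """

    def __init__(self, n_permutations: int = 1000, alpha: float = 0.05,
                 fc_cutoff_mode: str = "percentile", fc_percentile: float = 0.95,
                 fc_fixed: float = 0.336, variance_floor: float = 1e-8,
                 permutation_scheme: str = "sampled", adjust_method: str = "bh",
                 statistic: str = "pooled", random_state: int = 0):
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.fc_cutoff_mode = fc_cutoff_mode
        self.fc_percentile = fc_percentile
        self.fc_fixed = fc_fixed
        self.variance_floor = variance_floor
        self.permutation_scheme = permutation_scheme
        self.adjust_method = adjust_method
        self.statistic = statistic
        self.random_state = random_state

    def _config(self) -> DeConfig:
        return DeConfig(
            n_permutations=self.n_permutations, alpha_adj=self.alpha,
            fc_cutoff_mode=self.fc_cutoff_mode, fc_percentile=self.fc_percentile,
            fc_fixed=self.fc_fixed, variance_floor=self.variance_floor,
            permutation_scheme=self.permutation_scheme,
            adjust_method=self.adjust_method, statistic=self.statistic,
            seed=self.random_state,
        )

    def fit(self, X, y):
        config = self._config()
        if hasattr(X, "iloc"):
            gene_ids = np.asarray(X.columns, dtype=object)
            sample_ids = np.asarray(X.index, dtype=object)
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            gene_ids = np.asarray([f"g{i}" for i in range(arr.shape[1])], dtype=object)
            sample_ids = np.asarray([f"s{i}" for i in range(arr.shape[0])], dtype=object)
        y = np.asarray(y)
        if arr.ndim != 2 or y.shape[0] != arr.shape[0]:
            raise ValueError("X must be (n_samples, n_genes) with one label per sample")
        if np.isnan(arr).any():
            raise ValueError("missing values are not supported")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"exactly two groups required, got {classes.tolist()}")
        # canonical sample order: by (group, sample id)
        group_idx = (y == classes[1]).astype(int)
        order = np.lexsort((sample_ids.astype(str), group_idx))
        arr = arr[order]
        treated = group_idx[order].astype(bool)
        if treated.sum() < 2 or (~treated).sum() < 2:
            raise ValueError("each group needs at least 2 samples")

        values = arr.T  # genes x samples
        t_obs = _t_matrix(values, treated[None, :], config.variance_floor,
                          config.statistic)[:, 0]
        mean_control = values[:, ~treated].mean(axis=1)
        mean_treated = values[:, treated].mean(axis=1)
        log2fc = mean_treated - mean_control

        null = build_null(values, treated, config)
        p_emp = empirical_pvalue(t_obs, null)
        if config.adjust_method == "perm-fdr":
            p_adj = permutation_fdr(t_obs, null)
        else:
            p_adj = adjust_pvalues(p_emp)
        cutoff = fc_cutoff(log2fc, config)
        is_deg = (p_adj < config.alpha_adj) & (np.abs(log2fc) > cutoff)
        direction = np.where(~is_deg, "none", np.where(log2fc > 0, "up", "down"))

        table = pd.DataFrame(
            {
                "mean_control": mean_control,
                "mean_treated": mean_treated,
                "log2fc": log2fc,
                "t_stat": t_obs,
                "p_emp": p_emp,
                "p_adj": p_adj,
                "is_deg": is_deg,
                "direction": direction,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
        sort_order = np.lexsort((gene_ids.astype(str), -np.abs(log2fc), p_adj))
        self.results_ = table.iloc[sort_order]
        self.null_distribution_ = null
        self.fc_cutoff_ = float(cutoff)
        self.classes_ = classes
        self.t_stat_ = t_obs
        self.log2fc_ = log2fc
        self.p_emp_ = p_emp
        self.p_adj_ = p_adj
        self.is_deg_ = is_deg
        self.n_features_in_ = values.shape[0]
        self.feature_names_in_ = gene_ids
        return self

    @property
    def deg_counts_(self) -> dict:
        res = self.results_
        up = int((res["direction"] == "up").sum())
        down = int((res["direction"] == "down").sum())
        return {"up": up, "down": down, "total": up + down}


def call_degs(normalized: pd.DataFrame, groups: pd.Series, config: DeConfig | None = None
              ) -> pd.DataFrame:
    """Run the full DEG call on a normalized genes x samples DataFrame.

    Thin wrapper over :class:`PermutationTTest`; ``groups`` maps sample id to
    one of two labels. Returns the sorted per-gene DeTable.
    """
    config = config or DeConfig()
    y = groups.loc[normalized.columns].to_numpy()
    est = PermutationTTest(
        n_permutations=config.n_permutations, alpha=config.alpha_adj,
        fc_cutoff_mode=config.fc_cutoff_mode, fc_percentile=config.fc_percentile,
        fc_fixed=config.fc_fixed, variance_floor=config.variance_floor,
        permutation_scheme=config.permutation_scheme,
        adjust_method=config.adjust_method, statistic=config.statistic,
        random_state=config.seed,
    )
    est.fit(normalized.T, y)
    return est.results_
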