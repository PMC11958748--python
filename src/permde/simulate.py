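"""Synthetic bulk RNA-seq FPKM data with planted group effects.

The generator emulates a small two-condition transcriptome experiment: two
groups of ``n_per_group`` biological replicates (default 3 vs 3), several
thousand genes with lognormal-like expression, a minority of genes carrying
an additive group shift on the log2(FPKM+1) scale, and a fraction of genes
forced below the downstream expression filter. Because the simulation is
parameterized directly on the log2(FPKM+1) scale, the preprocessing
transform exactly inverts the generator and planted effect sizes are
directly comparable to log2 fold-change cutoffs.

A single integer seed drives one ``numpy.random.Generator`` stream; draws
are consumed in a fixed, documented order (gene roles, effect signs,
baselines, noise matrix, silent-gene values), so all outputs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["SimConfig", "simulate_fpkm", "simulate_gene_sets"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic FPKM generator.

    Parameters
    ----------
    n_genes : int
        Number of genes in the matrix.
    n_per_group : int
        Biological replicates per condition (the motivating design is 3 vs 3).
    frac_de : float
        Fraction of genes carrying a planted group effect, in [0, 1).
    effect_size_log2 : float
        Magnitude of the planted shift on the log2(FPKM+1) scale; the sign is
        drawn per gene (Rademacher), so both up- and downregulation occur.
    baseline_mean_log2, baseline_sd_log2 : float
        Mean and spread of per-gene baseline expression on the log2 scale;
        baselines are truncated (clipped) at 0.
    noise_sd_log2 : float
        Per-sample replicate noise s.d. on the log2 scale.
    frac_silent : float
        Fraction of genes forced below the FPKM > 1 expression filter, in [0, 1).
    seed : int
        Seed of the single generator stream.
    """

    n_genes: int = 5000
    n_per_group: int = 3
    frac_de: float = 0.1
    effect_size_log2: float = 2.0
    baseline_mean_log2: float = 4.0
    baseline_sd_log2: float = 2.0
    noise_sd_log2: float = 0.5
    frac_silent: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be a positive count")
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be a positive count")
        if not 0.0 <= self.frac_de < 1.0:
            raise ConfigurationError("frac_de must lie in [0, 1)")
        if not 0.0 <= self.frac_silent < 1.0:
            raise ConfigurationError("frac_silent must lie in [0, 1)")
        if self.frac_de + self.frac_silent >= 1.0:
            raise ConfigurationError("frac_de + frac_silent must be < 1")
        if self.effect_size_log2 < 0:
            raise ConfigurationError("effect_size_log2 must be nonnegative")
        if self.baseline_sd_log2 <= 0:
            raise ConfigurationError("baseline_sd_log2 must be strictly positive")
        if self.noise_sd_log2 <= 0:
            raise ConfigurationError("noise_sd_log2 must be strictly positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _sample_ids(n_per_group: int) -> tuple[list[str], pd.Series]:
    samples = [f"control_{i + 1}" for i in range(n_per_group)]
    samples += [f"treated_{i + 1}" for i in range(n_per_group)]
    groups = pd.Series(
        ["control"] * n_per_group + ["treated"] * n_per_group,
        index=samples, name="group",
    )
    return samples, groups


def simulate_fpkm(config: SimConfig) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate an FPKM matrix with planted differential expression.

    For each non-silent gene a baseline ``b ~ Normal(mean, sd)`` clipped at 0
    is drawn; each sample value on the log2(FPKM+1) scale is
    ``b + group_shift + Normal(0, noise_sd)`` where the shift of
    ``+/- effect_size_log2`` applies to the treated group of planted genes
    only. FPKM is recovered as ``2**x - 1`` clipped below at 0. Genes
    designated silent have every FPKM drawn uniformly in [0, 0.5], so they
    fail the FPKM > 1 filter with certainty of design.

    Returns
    -------
    fpkm : DataFrame, genes x samples
    groups : Series mapping sample_id -> {"control", "treated"}
    truth : DataFrame indexed by gene_id with columns ``is_de`` (bool),
        ``planted_effect_log2`` (signed, 0 iff not DE) and ``is_silent``.
        ``is_silent`` records the *realized* below-filter status: the
        designated silent genes plus any gene whose sampled values all fall
        at or below FPKM = 1, so it flags exactly the genes the expression
        filter removes downstream.
    """
    rng = np.random.default_rng(config.seed)
    n, s = config.n_genes, 2 * config.n_per_group
    n_silent = round(config.frac_silent * n)
    n_de = round(config.frac_de * n)

    # draw 1: gene roles -- silent first, then DE among the remainder
    roles = rng.permutation(n)
    silent_idx = roles[:n_silent]
    de_idx = roles[n_silent:n_silent + n_de]
    # draw 2: effect signs (Rademacher)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    # draw 3: baselines, truncated at 0
    baseline = np.clip(
        rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, size=n), 0.0, None
    )
    # draw 4: replicate noise
    log2_vals = baseline[:, None] + rng.normal(0.0, config.noise_sd_log2, size=(n, s))
    shift = np.zeros(n)
    shift[de_idx] = signs * config.effect_size_log2
    log2_vals[:, config.n_per_group:] += shift[:, None]
    fpkm = np.clip(np.exp2(log2_vals) - 1.0, 0.0, None)
    # draw 5: silent genes, uniform below the filter
    fpkm[silent_idx] = rng.uniform(0.0, 0.5, size=(n_silent, s))

    width = len(str(n))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, n + 1)]
    samples, groups = _sample_ids(config.n_per_group)
    fpkm_df = pd.DataFrame(fpkm, index=pd.Index(gene_ids, name="gene_id"), columns=samples)

    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True
    planted = np.zeros(n)
    planted[de_idx] = signs * config.effect_size_log2
    is_silent = fpkm.max(axis=1) <= 1.0
    is_silent[silent_idx] = True
    truth = pd.DataFrame(
        {"is_de": is_de, "planted_effect_log2": planted, "is_silent": is_silent},
        index=fpkm_df.index,
    )
    return fpkm_df, groups, truth


def simulate_gene_sets(
    truth: pd.DataFrame,
    n_sets: int = 20,
    set_size: int = 50,
    enriched_frac: float = 0.8,
    seed: int = 0,
    n_enriched: int | None = None,
):
    """Generate gene-set collections that preferentially overlap planted DE genes.

    A designated subset of ``n_enriched`` sets (default: a quarter of
    ``n_sets``, at least one) draws ``enriched_frac`` of its members from the
    planted DE genes and the remainder uniformly from non-DE genes; the other
    sets draw uniformly from all genes. All draws are without replacement.

    Returns
    -------
    collection : GeneSetCollection
    set_truth : DataFrame with columns ``set_name`` and ``is_enriched``.
    """
    from .enrichment import GeneSet, GeneSetCollection

    genes = np.asarray(truth.index, dtype=object)
    if set_size > genes.size:
        raise ConfigurationError("set_size exceeds the gene universe")
    if not 0.0 <= enriched_frac <= 1.0:
        raise ConfigurationError("enriched_frac must lie in [0, 1]")
    if n_enriched is None:
        n_enriched = max(1, n_sets // 4)
    if n_enriched > n_sets:
        raise ConfigurationError("n_enriched cannot exceed n_sets")

    de_genes = genes[truth["is_de"].to_numpy()]
    other_genes = genes[~truth["is_de"].to_numpy()]
    n_from_de = round(enriched_frac * set_size)
    if n_enriched > 0 and (n_from_de > de_genes.size
                           or set_size - n_from_de > other_genes.size):
        raise ConfigurationError(
            "not enough DE (or non-DE) genes to fill enriched sets at this size"
        )

    rng = np.random.default_rng(seed)
    sets: dict[str, GeneSet] = {}
    enriched_flags = []
    for i in range(n_sets):
        enriched = i < n_enriched
        if enriched:
            members = np.concatenate([
                rng.choice(de_genes, size=n_from_de, replace=False),
                rng.choice(other_genes, size=set_size - n_from_de, replace=False),
            ])
            name, desc = f"ENRICHED_{i + 1:03d}", "planted DE-enriched set"
        else:
            members = rng.choice(genes, size=set_size, replace=False)
            name, desc = f"RANDOM_{i + 1:03d}", "uniform background set"
        sets[name] = GeneSet(name=name, description=desc, members=tuple(members))
        enriched_flags.append(enriched)
    set_truth = pd.DataFrame({"set_name": list(sets), "is_enriched": enriched_flags})
    return GeneSetCollection(sets=sets), set_truth
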