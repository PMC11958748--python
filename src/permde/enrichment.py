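"""EASE-score gene-set enrichment against GMT collections.

The statistic is the one-sided Fisher exact (hypergeometric upper-tail)
enrichment p of the overlap between the differentially expressed genes and
each gene set, together with its conservative jackknifed variant -- the
EASE score -- in which one gene is removed from the overlap before the tail
is evaluated. Tails are computed by explicit summation of the
hypergeometric mass in log space for numerical safety at large universes.

The background universe is the set of expressed (filtered) genes scored by
the differential-expression stage, and set membership is always intersected
with that universe before testing. Significance defaults to raw EASE
p < 0.05 with no correction across sets; Benjamini-Hochberg across sets is
available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import GmtParseError

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeom_upper_tail",
    "upper_tail_grid",
    "ease_test",
    "enrich",
]

logger = logging.getLogger(__name__)


class GeneSet(NamedTuple):
    name: str
    description: str
    members: tuple


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with unique names and deduplicated member lists."""

    sets: dict

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> tuple:
        return self.sets[name].members


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (per line: name, description, member ids, tab-separated).

    Duplicate member ids within a line are deduplicated preserving order;
    duplicate set names raise; a line with fewer than three fields raises a
    parse error naming the line. An empty file yields an empty collection.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise GmtParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = tuple(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = GeneSet(name=name, description=description, members=members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *map(str, gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# hypergeometric tails

def _log_hypergeom_pmf(k, n_universe, n_set, n_deg):
    """log P(X = k) for X ~ Hypergeom(n_universe, n_set, n_deg), vectorized."""
    k = np.asarray(k, dtype=float)
    M, n, N = float(n_universe), np.asarray(n_set, float), np.asarray(n_deg, float)

    def lbinom(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return lbinom(n, k) + lbinom(M - n, N - k) - lbinom(M, N)


def hypergeom_upper_tail(k: int, n_universe: int, n_set: int, n_deg: int) -> float:
    """P(X >= k) by log-space summation of the hypergeometric mass.

    Exact 1.0 below the support; 0.0 above it. Valid for any universe size
    (the summation is performed entirely in log space).
    """
    kmax = min(n_set, n_deg)
    kmin = max(0, n_set + n_deg - n_universe)
    if k <= kmin:
        return 1.0
    if k > kmax:
        return 0.0
    ks = np.arange(k, kmax + 1)
    return float(min(1.0, np.exp(logsumexp(_log_hypergeom_pmf(ks, n_universe, n_set, n_deg)))))


def upper_tail_grid(n_universe: int, n_set: int):
    """Upper tails for every valid (n_deg, k) at a fixed universe and set size.

    Vectorized scan utility: evaluates the log-space hypergeometric mass on
    a padded (n_deg, k) rectangle and accumulates each row from the top of
    its support, so even far-tail values keep full relative precision.
    Intended for exhaustive validation sweeps; the double-precision mass
    underflows for universes beyond ~1000, for which the scalar
    :func:`hypergeom_upper_tail` remains valid.

    Returns
    -------
    n_deg, k, tail : flat ndarrays over all valid tuples, ordered by
        (n_deg ascending, k ascending).
    """
    M, n = int(n_universe), int(n_set)
    if not 0 <= n <= M:
        raise ValueError("need 0 <= n_set <= n_universe")
    N = np.arange(M + 1)[:, None]
    j = np.arange(n + 1)[None, :]
    kmin = np.maximum(0, n + N - M)
    kmax = np.minimum(n, N)
    valid = (j >= kmin) & (j <= kmax)
    lp = _log_hypergeom_pmf(np.broadcast_to(j, valid.shape)[valid],
                            M, n, np.broadcast_to(N, valid.shape)[valid])
    pmf = np.zeros(valid.shape)
    pmf[valid] = np.exp(lp)
    tail = np.cumsum(pmf[:, ::-1], axis=1)[:, ::-1]
    rows, cols = np.nonzero(valid)
    return rows, cols, np.minimum(tail[valid], 1.0)


def ease_test(n_universe: int, n_deg: int, n_set: int, n_overlap: int
              ) -> tuple[float, float]:
    """One-sided Fisher enrichment p and its jackknifed EASE variant.

    ``fisher_p`` is the hypergeometric upper tail P(X >= n_overlap) for
    X ~ Hypergeom(n_universe, n_set, n_deg); ``ease_p`` is the same tail at
    ``max(n_overlap - 1, 0)``, i.e. with one overlapping gene removed, which
    penalizes sets supported by very few genes. ``ease_p >= fisher_p``
    always, with equality only when the jackknife changes nothing (e.g. an
    empty overlap).
    """
    counts = (n_universe, n_deg, n_set, n_overlap)
    if any(int(c) != c or c < 0 for c in counts):
        raise ValueError(f"counts must be nonnegative integers, got {counts}")
    if n_deg > n_universe or n_set > n_universe:
        raise ValueError("n_deg and n_set cannot exceed n_universe")
    if n_overlap > min(n_deg, n_set):
        raise ValueError("n_overlap cannot exceed min(n_deg, n_set)")
    if n_overlap < max(0, n_deg + n_set - n_universe):
        raise ValueError("n_overlap below the hypergeometric support")
    fisher_p = hypergeom_upper_tail(n_overlap, n_universe, n_set, n_deg)
    ease_p = hypergeom_upper_tail(max(n_overlap - 1, 0), n_universe, n_set, n_deg)
    return fisher_p, ease_p


# ---------------------------------------------------------------------------
# enrichment over a DE table

def enrich(de_table: pd.DataFrame, gene_sets: GeneSetCollection,
           alpha: float = 0.05, degs: Iterable | None = None,
           adjust: bool = False) -> pd.DataFrame:
    """EASE enrichment of every gene set in the DEG list of a DeTable.

    The universe is all expressed genes in ``de_table`` (its index); the
    query is its ``is_deg`` genes unless an explicit ``degs`` iterable is
    given, in which case query genes absent from the universe are dropped
    with a logged warning. One row per set, sorted by ease_p then set name;
    ``significant`` is raw ease_p < alpha (uncorrected). With
    ``adjust=True`` a Benjamini-Hochberg column across sets is added
    (significance still refers to the raw EASE p).

    An empty DEG list is valid: every overlap is 0 and every tail is 1.
    """
    universe = set(map(str, de_table.index))
    if degs is None:
        deg_set = set(map(str, de_table.index[de_table["is_deg"].astype(bool)]))
    else:
        requested = set(map(str, degs))
        deg_set = requested & universe
        dropped = requested - universe
        if dropped:
            logger.warning(
                "%d DEG identifiers absent from the expressed-gene universe were dropped",
                len(dropped),
            )
    n_universe, n_deg = len(universe), len(deg_set)

    rows = []
    for gs in gene_sets:
        members = set(map(str, gs.members)) & universe
        n_overlap = len(members & deg_set)
        fisher_p, ease_p = ease_test(n_universe, n_deg, len(members), n_overlap)
        rows.append((gs.name, n_universe, n_deg, len(members), n_overlap,
                     fisher_p, ease_p, ease_p < alpha))
    table = pd.DataFrame(
        rows,
        columns=["set_name", "n_universe", "n_deg", "n_set", "n_overlap",
                 "fisher_p", "ease_p", "significant"],
    )
    table = table.sort_values(["ease_p", "set_name"], kind="mergesort").reset_index(drop=True)
    if adjust and len(table):
        from statsmodels.stats.multitest import multipletests

        table["ease_p_adj"] = multipletests(table["ease_p"].to_numpy(), method="fdr_bh")[1]
    return table
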