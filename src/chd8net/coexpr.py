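"""Seed-anchored co-expression networks and seed-permutation enrichment.

A network is built by attaching to each seed gene the k background genes
best correlated with it (by absolute Pearson r, signed edges retained)
subject to a minimum correlation. Enrichment of a query set among non-seed
members is assessed against null networks grown from random seed sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import PermutationResult

logger = logging.getLogger(__name__)

DEFAULT_K = 20
DEFAULT_R_MIN = 0.7


@dataclass
class SeedNetwork:
    seeds: list[str]
    members: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(s, g, r) for s, nbrs in self.members.items() for g, r in nbrs]

    @property
    def member_genes(self) -> set[str]:
        """All genes in the network: seeds plus their neighbours."""
        out = set(self.seeds)
        for nbrs in self.members.values():
            out.update(g for g, _ in nbrs)
        return out

    @property
    def nonseed_members(self) -> set[str]:
        return self.member_genes - set(self.seeds)


def _standardize(mat: np.ndarray) -> np.ndarray:
    centered = mat - mat.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, keepdims=True)
    sd[sd == 0] = np.nan  # constant genes correlate with nothing
    return centered / sd


def build_network(
    expr: pd.DataFrame,
    seeds: Sequence[str],
    k: int = DEFAULT_K,
    r_min: float = DEFAULT_R_MIN,
    background: Sequence[str] | None = None,
    signed: bool = False,
) -> SeedNetwork:
    """Attach to each seed its top-k correlated background genes.

    ``expr`` is genes x samples. Ranking is by |Pearson r| (or signed r when
    ``signed``), requiring |r| >= r_min (r >= r_min when signed); ties at the
    rank-k cutoff are broken by gene identifier order. Edges keep the signed
    correlation. Seeds missing from the matrix are skipped with a warning.
    """
    if expr.shape[1] < 3:
        raise ValueError(f"need >= 3 samples to correlate, got {expr.shape[1]}")
    if background is None:
        background = list(expr.index)
    bg = [g for g in background if g in expr.index]
    present_seeds = [s for s in seeds if s in expr.index]
    for s in set(seeds) - set(present_seeds):
        logger.warning("seed %s absent from expression matrix; skipped", s)

    bg_std = _standardize(expr.loc[bg].to_numpy(dtype=float))
    n_samples = expr.shape[1]
    bg_index = {g: i for i, g in enumerate(bg)}

    net = SeedNetwork(seeds=list(present_seeds))
    for seed in present_seeds:
        seed_vec = _standardize(expr.loc[[seed]].to_numpy(dtype=float))[0]
        with np.errstate(invalid="ignore"):
            r = bg_std @ seed_vec / n_samples
        candidates = []
        for g in bg:
            if g == seed:
                continue
            rv = r[bg_index[g]]
            if np.isnan(rv):
                continue
            score = rv if signed else abs(rv)
            if score >= r_min:
                candidates.append((-score, g, float(rv)))
        candidates.sort()  # descending score, then gene id
        net.members[seed] = [(g, rv) for _, g, rv in candidates[:k]]
    return net


def seed_permutation_enrichment(
    expr: pd.DataFrame,
    observed_seeds: Sequence[str],
    query_set: set[str],
    k: int = DEFAULT_K,
    r_min: float = DEFAULT_R_MIN,
    background: Sequence[str] | None = None,
    n_iter: int = 10_000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    signed: bool = False,
) -> PermutationResult:
    """Seed-label permutation test for query-set enrichment in the network.

    The statistic counts non-seed network members in the query set; seed
    genes (observed or permuted) never count as hits. Null networks are grown
    from uniform random seed sets of the same size drawn from the background.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if len(observed_seeds) < 1:
        raise ValueError("need at least one observed seed")
    if background is None:
        background = list(expr.index)
    background = [g for g in background if g in expr.index]
    if len(background) < len(observed_seeds):
        raise ValueError("background smaller than the seed count")

    def statistic(seed_list: Sequence[str]) -> int:
        net = build_network(expr, seed_list, k=k, r_min=r_min,
                            background=background, signed=signed)
        return len(net.nonseed_members & query_set)

    observed = statistic(observed_seeds)
    bg_arr = np.array(background, dtype=object)
    null_counts = np.empty(n_iter, dtype=int)
    for it in range(n_iter):
        perm = rng.choice(bg_arr, size=len(observed_seeds), replace=False)
        null_counts[it] = statistic(list(perm))
    return PermutationResult(observed=observed, null_counts=null_counts,
                             n_iter=n_iter, seed=seed)
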