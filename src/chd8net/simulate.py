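"""Synthetic-data generators with planted ground truth for every stage.

Each generator is a pure function of (config, seed): a fresh RNG seeded from
the config reproduces identical output. The emitted structures exercise the
whole pipeline — replicate peak sets with planted shared promoter binding,
covariate-carrying gene models, risk lists enriched among bound genes,
count matrices with batch effects and knockdown-induced downregulation,
block-correlated expression around seed genes, and Z-scores drawn from an
Ising-structured hidden risk state with a binding effect d.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dawn import IsingParams, SparseNetwork, simulate_ising
from .genes import ExonLocus, GeneModel
from .intervals import GenomicInterval
from .knockdown import SampleInfo

GENE_SPACING = 50_000  # nt between gene starts on the toy chromosomes
GENES_PER_CHROM = 50


@dataclass
class SimulationConfig:
    seed: int
    n_genes: int = 200
    # peak structure
    contexts: tuple[str, ...] = ("hNSC", "brain")
    binding_rate: float = 0.3
    sharing_rate: float = 0.7
    active_rate: float = 0.9
    peak_jitter: int = 60
    noise_peaks_per_replicate: int = 30
    # risk list
    risk_size: int = 30
    risk_odds: float = 4.0
    risk_mutability_weighted: bool = False
    # knockdown counts
    count_mean: float = 100.0
    dispersion: float = 0.05  # NB alpha; 0 gives Poisson
    batch_sd: float = 0.2
    libsize_sd: float = 0.15
    kd_lfc: float = 0.6
    kd_down_fraction: float = 0.8
    kd_bound_fraction: float = 0.5
    n_replicates: int = 4
    n_batches: int = 2
    # co-expression
    coexpr_block_size: int = 25
    coexpr_rho: float = 0.9
    coexpr_samples: int = 40
    coexpr_background: int = 100
    # hidden risk field
    ising: IsingParams = field(default_factory=lambda: IsingParams(
        b=-2.0, eta=0.5, d=1.5, mu=2.0, sigma=1.0))
    graph_model: str = "chain"  # chain | scale_free | erdos_renyi
    graph_p: float = 0.02

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("binding_rate", "sharing_rate", "active_rate",
                     "kd_down_fraction", "kd_bound_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not -1.0 < self.coexpr_rho < 1.0:
            raise ValueError(f"coexpr_rho={self.coexpr_rho} outside (-1, 1)")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


@dataclass
class GroundTruth:
    bound_sets: dict[str, set[str]] = field(default_factory=dict)
    risk_set: set[str] = field(default_factory=set)
    de_effects: dict[str, float] = field(default_factory=dict)  # gene -> log2FC
    graph_edges: list[tuple[int, int]] = field(default_factory=list)
    hidden_states: np.ndarray | None = None


# ---------------------------------------------------------------------------


def gen_genome(config: SimulationConfig, rng: np.random.Generator | None = None) -> list[GeneModel]:
    """Toy gene models with exon covariates g ~ Beta(5,5), lognormal sizes
    and coverage ~ Beta(20,2); 1-3 isoform TSSs within 500 nt."""
    if config.n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    rng = rng or config.rng(salt=1)
    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        chrom = f"chrS{i // GENES_PER_CHROM + 1}"
        base = 10_000 + (i % GENES_PER_CHROM) * GENE_SPACING
        strand = "+" if rng.random() < 0.5 else "-"
        n_iso = int(rng.integers(1, 4))
        tss0 = base + 2_000
        tss_list = sorted({tss0 + int(rng.integers(0, 501)) for _ in range(n_iso)})
        n_exons = int(rng.integers(1, 11))
        exons = []
        cursor = tss0 + 1_500
        for _ in range(n_exons):
            size = max(1, int(rng.lognormal(np.log(200.0), 0.8)))
            gc = float(rng.beta(5, 5))
            cov = float(rng.beta(20, 2))
            exons.append(ExonLocus(gc=gc, size=size, coverage=cov,
                                   interval=GenomicInterval(chrom, cursor, cursor + size)))
            cursor += size + int(rng.integers(200, 1_000))
        genes.append(GeneModel(
            gene_id=f"G{i:05d}", chrom=chrom, strand=strand,
            tss_list=tss_list, exons=exons,
            active=bool(rng.random() < config.active_rate),
        ))
    return genes


def gen_peaks(
    config: SimulationConfig,
    genome: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, dict[str, list[GenomicInterval]]], GroundTruth]:
    """Replicate peak sets per context with planted shared promoter binding.

    Bound genes receive a promoter-overlapping peak in both replicates
    (coordinates jittered so reproducibility filtering is exercised); each
    replicate additionally carries unreproducible noise peaks.
    """
    rng = rng or config.rng(salt=2)
    ids = [g.gene_id for g in genome]
    n_bound = int(round(config.binding_rate * len(ids)))
    n_shared = int(round(config.sharing_rate * n_bound))
    shared = set(rng.choice(ids, size=n_shared, replace=False))
    truth = GroundTruth()
    by_id = {g.gene_id: g for g in genome}
    replicates: dict[str, dict[str, list[GenomicInterval]]] = {}
    span_max = 10_000 + GENES_PER_CHROM * GENE_SPACING
    n_chroms = (len(ids) - 1) // GENES_PER_CHROM + 1

    for ctx in config.contexts:
        pool = [g for g in ids if g not in shared]
        extra = rng.choice(pool, size=max(0, n_bound - n_shared), replace=False)
        bound = shared | set(extra)
        truth.bound_sets[ctx] = bound
        reps: dict[str, list[GenomicInterval]] = {"rep1": [], "rep2": []}
        for gid in sorted(bound):
            g = by_id[gid]
            prom = g.promoter_union[0]
            center = (prom.start + prom.end) // 2
            for rep in ("rep1", "rep2"):
                j1 = int(rng.integers(-config.peak_jitter, config.peak_jitter + 1))
                j2 = int(rng.integers(-config.peak_jitter, config.peak_jitter + 1))
                start = max(0, center - 250 + j1)
                end = center + 250 + j2
                reps[rep].append(GenomicInterval(g.chrom, start, max(end, start + 50)))
        for rep in ("rep1", "rep2"):
            for _ in range(config.noise_peaks_per_replicate):
                chrom = f"chrS{int(rng.integers(1, n_chroms + 1))}"
                pos = int(rng.integers(0, span_max))
                reps[rep].append(GenomicInterval(chrom, pos, pos + 200))
        replicates[ctx] = reps
    return replicates, truth


def gen_risk_list(
    config: SimulationConfig,
    bound_sets: Mapping[str, set[str]],
    genome: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
    mutabilities: Mapping[str, float] | None = None,
) -> list[str]:
    """Risk genes sampled with an odds multiplier for bound genes.

    With ``risk_mutability_weighted`` the base weight is the gene mutability
    (to exercise confounder control); otherwise base weights are uniform.
    """
    if config.risk_odds < 1.0:
        raise ValueError("risk enrichment odds must be >= 1")
    rng = rng or config.rng(salt=3)
    ids = [g.gene_id for g in genome]
    bound_union: set[str] = set()
    for s in bound_sets.values():
        bound_union |= s
    base = np.ones(len(ids))
    if config.risk_mutability_weighted:
        from .enrichment import mutability

        mut = mutabilities or {g.gene_id: mutability(g.exon_loci) for g in genome}
        base = np.array([max(mut[g], 1e-9) for g in ids])
    weights = base * np.where([g in bound_union for g in ids], config.risk_odds, 1.0)
    from .enrichment import weighted_sample_without_replacement

    idx = weighted_sample_without_replacement(weights, config.risk_size, rng)
    return sorted(ids[i] for i in idx)


def gen_counts(
    config: SimulationConfig,
    genome: Sequence[GeneModel],
    bound_sets: Mapping[str, set[str]],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[SampleInfo], GroundTruth]:
    """Knockdown count matrix: 3 arms x n_replicates units, >= 2 batches.

    Negative-binomial counts with lognormal baselines, multiplicative batch
    effects, library-size variation and knockdown effects (predominantly
    downregulation) on a configured fraction of bound genes. Genes violating
    each QC filter (low total, single-unit, extreme VMR) are planted with
    QC_* identifiers.
    """
    rng = rng or config.rng(salt=4)
    ids = [g.gene_id for g in genome]
    arms = ["control", "kdC", "kdG"]
    units, infos = [], []
    for arm in arms:
        for r in range(config.n_replicates):
            unit = f"{arm}_{r + 1}"
            units.append(unit)
            infos.append(SampleInfo(unit=unit, treatment=arm,
                                    batch=f"b{r % config.n_batches + 1}"))

    bound_union: set[str] = set()
    for s in bound_sets.values():
        bound_union |= s
    bound_sorted = sorted(bound_union & set(ids))
    n_affected = int(round(config.kd_bound_fraction * len(bound_sorted)))
    affected = list(rng.choice(bound_sorted, size=n_affected, replace=False)) if n_affected else []
    signs = np.where(rng.random(len(affected)) < config.kd_down_fraction, -1.0, 1.0)
    effects = {g: float(s * config.kd_lfc) for g, s in zip(affected, signs)}

    baseline = rng.lognormal(np.log(config.count_mean), 1.0, size=len(ids))
    batch_eff = rng.normal(0.0, config.batch_sd, size=(len(ids), config.n_batches))
    lib = rng.lognormal(0.0, config.libsize_sd, size=len(units))

    mu = np.empty((len(ids), len(units)))
    for ui, info in enumerate(infos):
        b_idx = int(info.batch[1:]) - 1
        m = baseline * np.exp(batch_eff[:, b_idx]) * lib[ui]
        if info.treatment != "control":
            lfc = np.array([effects.get(g, 0.0) for g in ids])
            m = m * 2.0**lfc
        mu[:, ui] = m
    if config.dispersion > 0:
        r_nb = 1.0 / config.dispersion
        counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
    else:
        counts = rng.poisson(mu)
    df = pd.DataFrame(counts, index=ids, columns=units)

    # planted QC violators
    low = np.zeros(len(units), dtype=int)
    low[: min(5, len(units))] = 1  # grand total 5 <= 20
    single = np.zeros(len(units), dtype=int)
    single[0] = 30
    vmr_row = np.full(len(units), 3, dtype=int)
    vmr_row[0] = 4040  # one huge control outlier -> within-group VMR >> 100
    qc = pd.DataFrame(
        [low, single, vmr_row],
        index=["QC_LOWTOTAL", "QC_SINGLEUNIT", "QC_HIGHVMR"],
        columns=units,
    )
    df = pd.concat([df, qc])

    truth = GroundTruth(bound_sets=dict(bound_sets), de_effects=effects)
    return df, infos, truth


def gen_coexpression(
    config: SimulationConfig,
    seeds: Sequence[str],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Block-correlated expression: each seed anchors one latent-factor block.

    Within-block correlation is ``coexpr_rho`` (shared factor construction),
    between-block approximately zero; independent background genes pad the
    matrix.
    """
    rho = config.coexpr_rho
    rng = rng or config.rng(salt=5)
    m = config.coexpr_samples
    rows, names = [], []
    a, b = np.sqrt(abs(rho)), np.sqrt(1.0 - abs(rho))
    for bi, seed_gene in enumerate(seeds):
        f = rng.standard_normal(m)
        for gi in range(config.coexpr_block_size):
            x = a * f + b * rng.standard_normal(m)
            names.append(seed_gene if gi == 0 else f"BLK{bi}_{gi:03d}")
            rows.append(x)
    for gi in range(config.coexpr_background):
        names.append(f"BG_{gi:04d}")
        rows.append(rng.standard_normal(m))
    return pd.DataFrame(np.array(rows), index=names,
                        columns=[f"s{j:02d}" for j in range(m)])


# ---------------------------------------------------------------------------
# Hidden risk field


def gen_graph(
    config: SimulationConfig,
    n: int,
    rng: np.random.Generator | None = None,
    gene_ids: Sequence[str] | None = None,
) -> SparseNetwork:
    """Chain, scale-free or Erdos-Renyi graph as a SparseNetwork."""
    import networkx as nx
    import scipy.sparse as sp

    rng = rng or config.rng(salt=6)
    if config.graph_model == "chain":
        g = nx.path_graph(n)
    elif config.graph_model == "scale_free":
        g = nx.barabasi_albert_graph(n, 2, seed=int(rng.integers(2**31)))
    elif config.graph_model == "erdos_renyi":
        g = nx.erdos_renyi_graph(n, config.graph_p, seed=int(rng.integers(2**31)))
    else:
        raise ValueError(f"unknown graph model {config.graph_model!r}")
    adj = nx.to_scipy_sparse_array(g, format="csr", dtype=np.int8)
    ids = list(gene_ids) if gene_ids is not None else [f"G{i:05d}" for i in range(n)]
    return SparseNetwork(genes=ids, adjacency=sp.csr_matrix(adj), lam=np.nan)


def gen_graph_expression(
    config: SimulationConfig,
    graph: SparseNetwork,
    rng: np.random.Generator | None = None,
    n_samples: int = 120,
    coupling: float = 0.4,
) -> pd.DataFrame:
    """Gaussian expression whose partial-correlation graph matches ``graph``.

    The precision matrix is I - c*A with c scaled by the maximum degree to
    keep it diagonally dominant (hence positive definite), so network
    estimation by neighbourhood regression can recover the edges.
    """
    rng = rng or config.rng(salt=8)
    A = graph.adjacency.toarray().astype(float)
    n = A.shape[0]
    max_deg = max(A.sum(axis=1).max(), 1.0)
    P = np.eye(n) - (coupling / max_deg) * A
    L = np.linalg.cholesky(np.linalg.inv(P))
    X = L @ rng.standard_normal((n, n_samples))
    return pd.DataFrame(X, index=graph.genes,
                        columns=[f"s{j:03d}" for j in range(n_samples)])


def gen_zscores(
    config: SimulationConfig,
    graph: SparseNetwork,
    H: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate hidden states from the Ising prior, then z and one-sided p.

    Returns (p_values, z_scores, hidden_states).
    """
    from scipy import stats

    rng = rng or config.rng(salt=7)
    I = simulate_ising(config.ising, graph, H, rng)
    n = len(I)
    z = rng.standard_normal(n)
    z[I == 1] = config.ising.mu + config.ising.sigma * z[I == 1]
    p = stats.norm.sf(z)
    return p, z, I


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["ising"] = vars(config.ising).copy()
    return d
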