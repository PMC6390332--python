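"""Synthetic pathway collections, expression data, and evaluation protocols.

The generator emulates the structure of a target-pathway benchmark: a
collection of random signaling pathways with KEGG-like gene overlap, an
expression matrix whose case samples carry a mean shift on a fraction of
one designated target pathway's genes, and desk-scale versions of the
standard validation protocols — false-positive rate under permuted labels,
decoy-pathway discrimination (AUC), target-pathway rank summaries, and
robustness to edge removal/rewiring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .graph import (
    Edge,
    InteractionKind,
    PathwayCollection,
    PathwayGraph,
    perturb_graph,
)
from .scoring import AnalysisConfig, analyze_all, permutation_pvalue
from .stats import CASE, CONTROL, ExpressionDataset

__all__ = [
    "SimulationSpec",
    "random_pathway",
    "simulate_collection",
    "simulate_expression",
    "fp_rate_protocol",
    "decoy_auc",
    "target_metrics",
    "robustness_curve",
]


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic benchmark dataset.

    ``effect_size`` is the case-group mean shift in units of the noise
    standard deviation; ``de_fraction`` is the fraction of the target
    pathway's genes that receive it.  ``gene_pool_size`` controls pathway
    overlap (pathway genes are drawn from a shared pool; default 5x
    ``genes_per_pathway``, giving a KEGG-like mean gene frequency of a few
    pathways); ``n_filler_genes`` adds off-pathway measured genes.
    """

    n_pathways: int = 20
    genes_per_pathway: int = 12
    n_edges: int = 15
    inhibition_fraction: float = 0.2
    target_pathway_id: str = "P01"
    de_fraction: float = 0.3
    effect_size: float = 1.5
    n_control: int = 10
    n_case: int = 10
    noise_sd: float = 1.0
    n_filler_genes: int = 500
    gene_pool_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pathways, self.genes_per_pathway, self.n_control, self.n_case) < 1:
            raise ValueError("counts must be positive")
        for frac in (self.inhibition_fraction, self.de_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0,1]")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")

    @property
    def pool_size(self) -> int:
        return self.gene_pool_size or 5 * self.genes_per_pathway


def random_pathway(
    n_genes: int,
    n_edges: int,
    inhibition_fraction: float,
    seed: int,
    genes: list[str] | None = None,
    pathway_id: str = "P",
) -> PathwayGraph:
    """Random simple directed pathway with a guaranteed final effector.

    One node is designated terminal before edges are sampled; no edge
    leaves it, so the pathway always has at least one out-degree-0 gene.
    ``floor(inhibition_fraction * n_edges)`` edges are inhibiting.
    """
    if genes is None:
        genes = [f"{pathway_id}_g{i:03d}" for i in range(n_genes)]
    if len(genes) != n_genes:
        raise ValueError("genes list must have length n_genes")
    genes = sorted(genes)
    rng = np.random.default_rng(seed)
    terminal = genes[int(rng.integers(n_genes))]
    pairs = [
        (a, b)
        for a in genes
        for b in genes
        if a != b and a != terminal
    ]
    if n_edges > len(pairs):
        raise ValueError(
            f"cannot place {n_edges} edges on {n_genes} genes with a terminal node"
        )
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    n_inhib = int(math.floor(inhibition_fraction * n_edges))
    edges = []
    for j, ci in enumerate(chosen):
        a, b = pairs[int(ci)]
        kind = InteractionKind.INHIBITION if j < n_inhib else InteractionKind.ACTIVATION
        edges.append(Edge(a, b, kind))
    return PathwayGraph(
        id=pathway_id,
        nodes=set(genes),
        edges=edges,
        provenance=f"random_pathway(seed={seed})",
    )


def simulate_collection(spec: SimulationSpec) -> PathwayCollection:
    """Random collection with overlapping gene membership across pathways."""
    rng = np.random.default_rng(spec.seed)
    pool = [f"gene{i:04d}" for i in range(spec.pool_size)]
    pathways = []
    for k in range(spec.n_pathways):
        pid = f"P{k + 1:02d}"
        members = [
            pool[i]
            for i in rng.choice(len(pool), size=spec.genes_per_pathway, replace=False)
        ]
        pathways.append(
            random_pathway(
                spec.genes_per_pathway,
                spec.n_edges,
                spec.inhibition_fraction,
                seed=int(rng.integers(2**31)),
                genes=members,
                pathway_id=pid,
            )
        )
    return PathwayCollection(pathways)


def simulate_expression(
    spec: SimulationSpec, collection: PathwayCollection
) -> ExpressionDataset:
    """Two-class expression matrix with a perturbed target pathway.

    Baseline expression is iid Normal(0, sd^2); a ``de_fraction`` of the
    target pathway's genes get a +effect_size*sd mean shift in the case
    samples.  Measured genes are the collection's gene universe plus
    ``n_filler_genes`` unaffiliated filler genes.
    """
    target = collection[spec.target_pathway_id]
    rng = np.random.default_rng(spec.seed + 1)
    genes = sorted(collection.gene_universe) + [
        f"filler{i:04d}" for i in range(spec.n_filler_genes)
    ]
    n = spec.n_control + spec.n_case
    values = rng.normal(0.0, spec.noise_sd, size=(len(genes), n))
    tgenes = sorted(target.gene_nodes())
    n_shift = int(round(spec.de_fraction * len(tgenes)))
    shifted = [tgenes[i] for i in rng.choice(len(tgenes), size=n_shift, replace=False)]
    gidx = {g: i for i, g in enumerate(genes)}
    for g in shifted:
        values[gidx[g], spec.n_control :] += spec.effect_size * spec.noise_sd
    samples = [f"C{i + 1:02d}" for i in range(spec.n_control)] + [
        f"D{i + 1:02d}" for i in range(spec.n_case)
    ]
    labels = [CONTROL] * spec.n_control + [CASE] * spec.n_case
    return ExpressionDataset(
        pd.DataFrame(values, index=genes, columns=samples),
        pd.Series(labels, index=samples),
    )


# ---------------------------------------------------------------------------
# Evaluation protocols
# ---------------------------------------------------------------------------


def fp_rate_protocol(
    data: ExpressionDataset,
    collection: PathwayCollection,
    n_trials: int,
    threshold: float,
    seed: int,
    config: AnalysisConfig | None = None,
) -> float:
    """False-positive rate under random relabeling of the samples.

    Each trial permutes the class labels, runs the whole-collection
    analysis, and records the fraction of pathways with P_F below the
    threshold; the mean fraction over trials is returned.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    config = config or AnalysisConfig()
    rng = np.random.default_rng(seed)
    fracs = []
    for trial in range(n_trials):
        labels = data.labels.to_numpy().copy()
        labels = labels[rng.permutation(len(labels))]
        shuffled = data.with_labels(labels)
        cfg = replace(config, seed=int(rng.integers(2**31)))
        table = analyze_all(shuffled, collection, cfg)
        fracs.append(float((table["p_value"] < threshold).mean()))
    return float(np.mean(fracs))


def decoy_auc(
    real_results: pd.DataFrame, decoy_results: pd.DataFrame
) -> float:
    """Real-vs-decoy discrimination AUC from result tables.

    Both tables need ``p_value`` (and optionally ``score``) columns.  All
    entries are ranked jointly by p_value ascending then score descending;
    the AUC is the probability that a random real pathway outranks a random
    decoy, ties counting 1/2.
    """
    if len(real_results) == 0 or len(decoy_results) == 0:
        raise ValueError("both result lists must be non-empty")

    def key(df: pd.DataFrame) -> np.ndarray:
        p = df["p_value"].to_numpy(float)
        s = df["score"].to_numpy(float) if "score" in df else np.zeros(len(df))
        return p, -s

    pr, sr = key(real_results)
    pd_, sd_ = key(decoy_results)
    p_all = np.concatenate([pr, pd_])
    s_all = np.concatenate([sr, sd_])
    order_key = np.lexsort((s_all, p_all))
    # average ranks over exact (p, score) ties
    ranks = np.empty(len(p_all))
    ranks[order_key] = np.arange(1, len(p_all) + 1, dtype=float)
    combo = np.stack([p_all, s_all], axis=1)
    uniq, inv = np.unique(combo, axis=0, return_inverse=True)
    for u in range(len(uniq)):
        mask = inv == u
        ranks[mask] = ranks[mask].mean()
    n_r, n_d = len(pr), len(pd_)
    rank_decoy = ranks[n_r:]
    # count of (real, decoy) pairs where the real pathway ranks better
    auc = (rank_decoy.sum() - n_d * (n_d + 1) / 2.0) / (n_r * n_d)
    return float(auc)


def target_metrics(results: list[tuple[str, float, float, int]]) -> dict[str, float]:
    """Summaries over benchmark datasets: each entry is
    (dataset id, target rank, target p-value, number of pathways).

    Returns median target p (sensitivity), median and mean rank percentage
    (prioritization), and the mean reciprocal rank.
    """
    if not results:
        raise ValueError("no results")
    ranks = np.array([r[1] for r in results], dtype=float)
    pvals = np.array([r[2] for r in results], dtype=float)
    npath = np.array([r[3] for r in results], dtype=float)
    rank_pct = 100.0 * ranks / npath
    return {
        "median_p": float(np.median(pvals)),
        "median_rank_percentage": float(np.median(rank_pct)),
        "mean_rank_percentage": float(np.mean(rank_pct)),
        "mean_reciprocal_rank": float(np.mean(1.0 / ranks)),
    }


def robustness_curve(
    g: PathwayGraph,
    data: ExpressionDataset,
    collection: PathwayCollection,
    fractions: list[float],
    modes: list[str],
    n_reps: int,
    seed: int,
    config: AnalysisConfig | None = None,
    call_threshold: float = 0.05,
) -> pd.DataFrame:
    """Stability of a pathway's significance call under topology noise.

    For each (fraction, mode) the pathway is perturbed ``n_reps`` times;
    similarity is the fraction of perturbed versions whose call
    (P_F < threshold) matches the unperturbed pathway's call.  Each
    perturbed pathway replaces the original inside the collection so the
    interaction-frequency counts see the perturbed topology.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(seed)
    # one analysis seed for the base and all perturbed runs, so that only the
    # topology perturbation (not permutation/simulation noise) moves the call
    analysis_seed = int(rng.integers(2**31))
    base_pf = permutation_pvalue(data, g, collection, seed=analysis_seed, config=config)
    base_call = base_pf < call_threshold
    rows = []
    for mode in modes:
        for frac in fractions:
            matches = 0
            for _ in range(n_reps):
                pg = perturb_graph(g, frac, mode, seed=int(rng.integers(2**31)))
                coll = collection.replace_pathway(pg)
                pf = permutation_pvalue(data, pg, coll, seed=analysis_seed, config=config)
                matches += int((pf < call_threshold) == base_call)
            rows.append(
                {
                    "mode": mode,
                    "fraction": frac,
                    "similarity": matches / n_reps,
                    "base_p_value": base_pf,
                    "n_reps": n_reps,
                }
            )
    return pd.DataFrame(rows)
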