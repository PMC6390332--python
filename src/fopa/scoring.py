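"""Pathway scores and permutation significance.

A pathway's score is the sum, over its final-effector genes, of the
probability that the effector eventually becomes differentially activated
(state 4) in the guarded-command model:

    score(path) = sum_g P[F (g = 4)]

Significance is assessed against the label-permutation null: sample class
labels are shuffled (class sizes preserved), the full pipeline (moderated
t -> DE calls -> P(A) -> parameters -> model -> score) is recomputed for
each permutation, and

    P_F = #{permutations with score_perm >= score_real} / N_perm

with no pseudocount.  ``analyze_all`` shares one set of permutations across
all pathways of a collection, which is statistically equivalent per pathway
and saves one moderated-t pass per pathway x permutation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine as eng
from .engine import EngineConfig, reachability, reachability_batch_mc
from .graph import PathwayCollection, PathwayGraph, final_effectors
from .model import Command, CommandKind, GuardedModel, build_model, command_structure
from .params import (
    DEFAULT_ALPHA_ERROR,
    DEFAULT_ALPHA_WEIGHT,
    ModelParameters,
    interaction_probability,
)
from .stats import (
    CASE,
    ExpressionDataset,
    adjust_fdr,
    frequency_weight,
    gene_frequencies,
    moderated_t_arrays,
)

__all__ = [
    "AnalysisConfig",
    "ScoreResult",
    "pathway_score",
    "permutation_pvalue",
    "analyze_all",
    "CollectionAnalyzer",
]


@dataclass
class AnalysisConfig:
    """Tunables of a whole-collection analysis.

    alpha_weight: the DE-pair ladder unit (diff term), default 1/6.
    fdr_cutoff: DE call threshold v; also the initialisation error alpha.
    n_perm: label permutations for P_F (exhaustive enumeration is used
        automatically when the number of distinct labelings is smaller).
    plus_one_smoothing: optional (1 + k)/(1 + N) estimator; off by default
        to stay literal to the score-comparison definition of P_F.
    """

    alpha_weight: float = DEFAULT_ALPHA_WEIGHT
    fdr_cutoff: float = DEFAULT_ALPHA_ERROR
    n_perm: int = 200
    seed: int = 0
    freq_mode: str = "literal"
    prob_scaling: str = "max_normalize"
    plus_one_smoothing: bool = False
    engine: EngineConfig = field(default_factory=EngineConfig)


@dataclass
class ScoreResult:
    pathway_id: str
    effector_probs: dict[str, float]
    score: float
    p_value: float | None = None
    n_perm: int | None = None
    rank: float | None = None
    rank_percentage: float | None = None
    engine: str = ""
    n_states_or_traj: int | None = None


def pathway_score(
    g: PathwayGraph,
    params: ModelParameters,
    de: set[str] | frozenset[str],
    config: EngineConfig | None = None,
) -> ScoreResult:
    """Score one pathway from precomputed parameters (p_value left unset)."""
    config = config or EngineConfig()
    effectors = final_effectors(g)
    if not effectors:
        warnings.warn(f"pathway {g.id} has no final effector; score is 0")
        return ScoreResult(g.id, {}, 0.0, engine=config.engine)
    m = build_model(g, params, de)
    if config.engine == "monte_carlo":
        res = reachability_batch_mc(
            m, effectors, n_traj=config.n_traj, step_cap=config.step_cap, seed=config.seed
        )
        probs = {e: res[e].probability for e in effectors}
        n_info = config.n_traj
        method = "monte_carlo"
    else:
        probs = {}
        n_info = 0
        method = "exact"
        for e in effectors:
            r = reachability(m, e, config)
            probs[e] = r.probability
            if r.method == "monte_carlo":
                method = "monte_carlo"
            n_info = max(n_info, r.n_states or r.n_trajectories or 0)
    return ScoreResult(
        g.id,
        probs,
        float(sum(probs.values())),
        engine=method,
        n_states_or_traj=n_info,
    )


# ---------------------------------------------------------------------------
# Fast whole-collection analyzer
# ---------------------------------------------------------------------------


@dataclass
class _CompiledPathway:
    pathway_id: str
    genes: list[str]
    kind: np.ndarray  # int8 per command
    src: np.ndarray  # local gene index
    tgt: np.ndarray
    pe: np.ndarray  # interaction probability per command (0 for init/source)
    g2u: np.ndarray  # local gene index -> index in the collection gene list
    effector_idx: np.ndarray
    effectors: list[str]
    step_cap: int


class CollectionAnalyzer:
    """Precompiled pipeline for repeated (permutation) scoring.

    Everything independent of the sample labels — pathway command
    structures, interaction probabilities, frequency weights, expression
    matrices — is computed once; each labeling then costs one moderated-t
    pass plus one simulation (or exact solve) per pathway.  Scores agree
    exactly with the object-level path
    (``build_gene_stats`` -> ``compute_parameters`` -> ``build_model`` ->
    engine) given the same engine settings and seed.
    """

    def __init__(
        self,
        data: ExpressionDataset,
        collection: PathwayCollection,
        config: AnalysisConfig | None = None,
    ):
        self.config = config or AnalysisConfig()
        self.collection = collection
        self.data = data

        self.values = data.values.to_numpy(float)
        self.case_mask = (data.labels == CASE).to_numpy()

        # collection-wide gene list and label-independent weights
        self.univ = sorted(collection.gene_universe)
        u_index = {g: i for i, g in enumerate(self.univ)}
        f = gene_frequencies(collection)
        Fn = frequency_weight(f, mode=self.config.freq_mode)
        self.Fn = Fn.reindex(self.univ).fillna(0.0).to_numpy(float)
        measured = {g: i for i, g in enumerate(data.values.index)}
        self.u2m = np.array([measured.get(g, -1) for g in self.univ], dtype=np.int64)

        pe_cache: dict[tuple[str, str, int], float] = {}

        def p_edge(a: str, b: str, pol: int) -> float:
            key = (a, b, pol)
            if key not in pe_cache:
                pe_cache[key] = interaction_probability(
                    collection, a, b, "activating" if pol > 0 else "inhibiting"
                )
            return pe_cache[key]

        self.compiled: dict[str, _CompiledPathway] = {}
        for p in collection:
            genes = p.sorted_genes()
            gi = {g: i for i, g in enumerate(genes)}
            struct = command_structure(p)
            kind = np.array([int(k) for k, _, _ in struct], dtype=np.int8)
            src = np.array([gi[s] for _, s, _ in struct], dtype=np.int64)
            tgt = np.array([gi[t] for _, _, t in struct], dtype=np.int64)
            pe = np.zeros(len(struct))
            for i, (k, s, t) in enumerate(struct):
                if k == CommandKind.ACTIVATE:
                    pe[i] = p_edge(s, t, 1)
                elif k in (CommandKind.INHIBIT1, CommandKind.INHIBIT2):
                    pe[i] = p_edge(s, t, -1)
            effectors = final_effectors(p)
            self.compiled[p.id] = _CompiledPathway(
                pathway_id=p.id,
                genes=genes,
                kind=kind,
                src=src,
                tgt=tgt,
                pe=pe,
                g2u=np.array([u_index[g] for g in genes], dtype=np.int64),
                effector_idx=np.array([gi[e] for e in effectors], dtype=np.int64),
                effectors=effectors,
                step_cap=max(1, 10 * len(struct) * len(genes)),
            )

    # -- per-labeling statistics ------------------------------------------
    def gene_evidence(self, case_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(P, is_de) over the collection gene list for one labeling."""
        case = self.values[:, case_mask]
        ctrl = self.values[:, ~case_mask]
        T, p = moderated_t_arrays(case, ctrl)
        q = adjust_fdr(p)
        de_measured = q < self.config.fdr_cutoff
        absT = np.abs(T)
        meas = self.u2m >= 0
        T_u = np.zeros(len(self.univ))
        T_u[meas] = absT[self.u2m[meas]]
        de_u = np.zeros(len(self.univ), dtype=bool)
        de_u[meas] = de_measured[self.u2m[meas]]
        if self.config.prob_scaling == "max_normalize":
            tmax = absT.max() if absT.size else 0.0
            P_u = (T_u / tmax) * self.Fn if tmax > 0 else np.zeros(len(self.univ))
        else:  # clip
            P_u = np.minimum(1.0, T_u * self.Fn)
        return P_u, de_u

    def command_probs(
        self, cp: _CompiledPathway, P_u: np.ndarray, de_u: np.ndarray
    ) -> np.ndarray:
        """Per-command branch-1 probabilities for one labeling."""
        a_w = self.config.alpha_weight
        a_e = self.config.fdr_cutoff
        P = P_u[cp.g2u]
        de = de_u[cp.g2u]
        p = np.empty(len(cp.kind))
        k = cp.kind
        de_src = de[cp.src]
        de_tgt = de[cp.tgt]
        diff = a_w * (1 + de_src.astype(int) + de_tgt.astype(int))
        p[k == 0] = np.where(de_tgt[k == 0], a_e, 1.0 - a_e)
        p[k == 1] = P[cp.tgt[k == 1]]
        edge = k >= 2
        # same association order as edge_parameters: diff * P(A) * p_edge
        p[edge] = diff[edge] * P[cp.src[edge]] * cp.pe[edge]
        p[k == 3] = cp.pe[k == 3]
        return p

    def _score_compiled(
        self, cp: _CompiledPathway, p: np.ndarray, seed: int
    ) -> tuple[float, dict[str, float]]:
        cfg = self.config.engine
        if cp.effector_idx.size == 0:
            return 0.0, {}
        if cfg.engine == "monte_carlo":
            counts, _ = eng._simulate_kernel(
                cp.kind,
                cp.src,
                cp.tgt,
                p,
                len(cp.genes),
                cfg.n_traj,
                cfg.step_cap or cp.step_cap,
                seed % (2**31),
                -1,
            )
            probs = {
                e: counts[i] / cfg.n_traj
                for e, i in zip(cp.effectors, cp.effector_idx)
            }
            return float(sum(probs.values())), probs
        # exact / auto: materialize the model and use the dispatcher
        m = GuardedModel(
            pathway_id=cp.pathway_id,
            genes=cp.genes,
            commands=[
                Command(CommandKind(int(k)), cp.genes[s], cp.genes[t], float(pi))
                for k, s, t, pi in zip(cp.kind, cp.src, cp.tgt, p)
            ],
            effectors=cp.effectors,
        )
        cfg_local = EngineConfig(
            engine=cfg.engine,
            state_cap=cfg.state_cap,
            n_traj=cfg.n_traj,
            step_cap=cfg.step_cap,
            seed=seed,
        )
        probs = {e: reachability(m, e, cfg_local).probability for e in cp.effectors}
        return float(sum(probs.values())), probs

    def score_pathway(
        self, pathway_id: str, case_mask: np.ndarray, seed: int
    ) -> tuple[float, dict[str, float]]:
        P_u, de_u = self.gene_evidence(case_mask)
        cp = self.compiled[pathway_id]
        return self._score_compiled(cp, self.command_probs(cp, P_u, de_u), seed)

    def score_all(
        self, case_mask: np.ndarray, seeds: dict[str, int]
    ) -> dict[str, tuple[float, dict[str, float]]]:
        P_u, de_u = self.gene_evidence(case_mask)
        out = {}
        for pid, cp in self.compiled.items():
            out[pid] = self._score_compiled(
                cp, self.command_probs(cp, P_u, de_u), seeds[pid]
            )
        return out


# ---------------------------------------------------------------------------
# Permutations
# ---------------------------------------------------------------------------


def _label_permutations(
    samples: list[str],
    n_case: int,
    n_perm: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Class-size-preserving relabelings as case masks over ``samples``.

    Case sets are drawn over the *sorted* sample names, so the permutation
    stream is invariant to the column order of the input matrix (permuting
    columns together with their labels changes nothing downstream).
    Exhaustive enumeration replaces sampling when few enough labelings exist.
    """
    n = len(samples)
    canon = sorted(samples)
    pos = {s: i for i, s in enumerate(samples)}
    n_distinct = math.comb(n, n_case)

    def mask_from(names) -> np.ndarray:
        m = np.zeros(n, dtype=bool)
        for s in names:
            m[pos[s]] = True
        return m

    if n_distinct <= n_perm:
        return [mask_from(c) for c in itertools.combinations(canon, n_case)]
    out = []
    for _ in range(n_perm):
        idx = rng.permutation(n)[:n_case]
        out.append(mask_from(canon[i] for i in idx))
    return out


def _pf(perm_scores: np.ndarray, real: float, smoothing: bool) -> float:
    k = int(np.sum(perm_scores >= real))
    n = len(perm_scores)
    return (1 + k) / (1 + n) if smoothing else k / n


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


def permutation_pvalue(
    data: ExpressionDataset,
    g: PathwayGraph,
    collection: PathwayCollection,
    n_perm: int | None = None,
    seed: int | None = None,
    config: AnalysisConfig | None = None,
) -> float:
    """Label-permutation p-value P_F for one pathway (deterministic given seed)."""
    config = config or AnalysisConfig()
    n_perm = config.n_perm if n_perm is None else n_perm
    seed = config.seed if seed is None else seed
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    analyzer = CollectionAnalyzer(data, collection, config)
    case_mask = analyzer.case_mask
    rng = np.random.default_rng(seed)
    perms = _label_permutations(
        list(data.values.columns), int(case_mask.sum()), n_perm, rng
    )
    # common random numbers: the real and every permuted score share one
    # simulation seed, so Monte-Carlo noise largely cancels in the
    # score-vs-score comparison (and cancels exactly for the exact engine)
    crn_seed = int(_spawn_seeds(seed, 1)[0])
    real, _ = analyzer.score_pathway(g.id, case_mask, crn_seed)
    perm_scores = np.array(
        [analyzer.score_pathway(g.id, pm, crn_seed)[0] for pm in perms]
    )
    return float(_pf(perm_scores, real, config.plus_one_smoothing))


def analyze_all(
    data: ExpressionDataset,
    collection: PathwayCollection,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Score and rank every pathway of a collection.

    Returns a table sorted by p_value ascending (ties: score descending,
    then pathway id), with 1-based ranks; entries tied on (p_value, score)
    receive the mean of their positions.
    """
    config = config or AnalysisConfig()
    if len(collection) == 0:
        raise ValueError("collection is empty")
    analyzer = CollectionAnalyzer(data, collection, config)
    case_mask = analyzer.case_mask
    rng = np.random.default_rng(config.seed)
    perms = _label_permutations(
        list(data.values.columns), int(case_mask.sum()), config.n_perm, rng
    )
    pids = [p.id for p in collection]
    # one simulation seed per pathway, shared by the real scoring and every
    # permutation (common random numbers; see permutation_pvalue)
    crn = _spawn_seeds(config.seed, len(pids))
    seeds = {pid: int(crn[j]) for j, pid in enumerate(pids)}

    real = analyzer.score_all(case_mask, seeds)
    perm_scores = {pid: np.empty(len(perms)) for pid in pids}
    for i, pm in enumerate(perms):
        res = analyzer.score_all(pm, seeds)
        for pid in pids:
            perm_scores[pid][i] = res[pid][0]

    rows = []
    for pid in pids:
        score, probs = real[pid]
        pf = _pf(perm_scores[pid], score, config.plus_one_smoothing)
        rows.append(
            {
                "pathway_id": pid,
                "score": score,
                "p_value": pf,
                "n_effectors": len(probs),
                "engine": config.engine.engine,
                "n_states_or_traj": config.engine.n_traj
                if config.engine.engine == "monte_carlo"
                else None,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["p_value", "score", "pathway_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    pos = np.arange(1, len(table) + 1, dtype=float)
    # average positions within groups tied on (p_value, score)
    table["rank"] = (
        pd.Series(pos)
        .groupby([table["p_value"], -table["score"]], sort=False)
        .transform("mean")
        .to_numpy()
    )
    table["rank_percentage"] = 100.0 * table["rank"] / len(table)
    return table
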