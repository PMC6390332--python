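"""Reachability probabilities P[F (g = 4)] for guarded-command models.

Two engines:

* ``exact`` — breadth-first enumeration of the reachable state space from
  the all-(-1) state into an explicit discrete-time Markov chain, then the
  standard linear reachability solve.  Local nondeterminism (several
  commands enabled in one state) is resolved by the uniform scheduler: the
  successor distribution is the uniform mixture over enabled commands of
  their branch distributions.  Deadlock states self-loop.
* ``monte_carlo`` — seeded trajectory simulation under the same scheduler
  (numba-compiled), estimating the reachability probability as a success
  fraction.

Before an exact query the model is restricted to the ancestors of the
target gene: commands targeting other genes can never influence the target,
and under the uniform scheduler the jump chain of the retained commands is
exactly the sub-model's chain, so the reachability probability is
unchanged.  The Monte-Carlo engine always simulates the full model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from numba import njit

from .model import CommandKind, GuardedModel

__all__ = [
    "EngineConfig",
    "ExplicitChain",
    "ReachabilityResult",
    "StateCapExceeded",
    "build_chain",
    "reachability_exact",
    "reachability_mc",
    "reachability_batch_mc",
    "reachability",
    "restrict_to_target",
]

DEFAULT_STATE_CAP = 500_000
DEFAULT_N_TRAJ = 20_000


@dataclass
class EngineConfig:
    """How reachability queries are answered.

    engine: 'exact' | 'monte_carlo' | 'auto' (exact first, MC fallback when
    the reachable space exceeds ``state_cap``).  ``step_cap=None`` defaults
    to 10 * |commands| * |genes| per trajectory.
    """

    engine: str = "auto"
    state_cap: int = DEFAULT_STATE_CAP
    n_traj: int = DEFAULT_N_TRAJ
    step_cap: int | None = None
    seed: int = 0
    notes: list[str] = field(default_factory=list)


@dataclass
class ReachabilityResult:
    target_gene: str
    probability: float
    method: str  # 'exact' | 'monte_carlo'
    std_error: float = 0.0
    n_states: int | None = None
    n_trajectories: int | None = None
    censored_fraction: float | None = None


class StateCapExceeded(RuntimeError):
    def __init__(self, cap: int):
        super().__init__(
            f"reachable state space exceeds the cap of {cap} states; "
            "use the Monte-Carlo engine"
        )
        self.cap = cap


# ---------------------------------------------------------------------------
# Exact engine
# ---------------------------------------------------------------------------


@dataclass
class ExplicitChain:
    """Enumerated reachable states + sparse transition matrix.

    ``states[i]`` is the tuple of variable values in the order of
    ``model.genes``; state 0 is the initial all-(-1) state.
    """

    model: GuardedModel
    states: list[tuple[int, ...]]
    transitions: sp.csr_matrix

    @property
    def n_states(self) -> int:
        return len(self.states)


def build_chain(m: GuardedModel, state_cap: int = DEFAULT_STATE_CAP) -> ExplicitChain:
    """Breadth-first exploration from the all-(-1) state."""
    genes = m.genes
    idx_of_gene = m.gene_index()
    cmds = m.commands
    init = tuple([-1] * len(genes))
    index: dict[tuple[int, ...], int] = {init: 0}
    order: list[tuple[int, ...]] = [init]
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    head = 0
    while head < len(order):
        s = order[head]
        si = head
        head += 1
        state = dict(zip(genes, s))
        enabled = [c for c in cmds if c.guard(state)]
        if not enabled:
            rows.append(si)
            cols.append(si)
            vals.append(1.0)
            continue
        w = 1.0 / len(enabled)
        acc: dict[tuple[int, ...], float] = {}
        for c in enabled:
            ti = idx_of_gene[c.tgt]
            for prob, val in c.branches(state):
                if prob == 0.0:
                    continue
                ns = s[:ti] + (val,) + s[ti + 1 :]
                acc[ns] = acc.get(ns, 0.0) + w * prob
        for ns, prob in acc.items():
            if ns not in index:
                if len(order) >= state_cap:
                    raise StateCapExceeded(state_cap)
                index[ns] = len(order)
                order.append(ns)
            rows.append(si)
            cols.append(index[ns])
            vals.append(prob)
    n = len(order)
    mat = sp.csr_matrix(
        (np.array(vals), (np.array(rows), np.array(cols))), shape=(n, n)
    )
    return ExplicitChain(model=m, states=order, transitions=mat)


def reachability_exact(chain: ExplicitChain, target_gene: str) -> ReachabilityResult:
    """Probability of eventually reaching a state with target variable = 4.

    States that cannot reach the target set get probability 0 (backward
    graph analysis); the rest solve x = P x with boundary conditions via a
    sparse direct solve, with value iteration as fallback.
    """
    if target_gene not in chain.model.genes:
        raise ValueError(f"unknown gene {target_gene!r}")
    gi = chain.model.genes.index(target_gene)
    n = chain.n_states
    target = np.array([s[gi] == 4 for s in chain.states], dtype=bool)
    if not target.any():
        return ReachabilityResult(target_gene, 0.0, "exact", n_states=n)

    P = chain.transitions
    # backward reachability: states with a path into the target set
    can_reach = _backward_reachable(P, target)
    x = np.zeros(n)
    x[target] = 1.0
    maybe = can_reach & ~target
    if maybe.any():
        mi = np.flatnonzero(maybe)
        Q = P[mi][:, mi]
        b = np.asarray(P[mi][:, target].sum(axis=1)).ravel()
        A = sp.identity(len(mi), format="csc") - Q.tocsc()
        try:
            sol = spla.spsolve(A, b)
            if not np.all(np.isfinite(sol)):
                raise RuntimeError("non-finite solution")
        except Exception:
            sol = _value_iteration(Q.tocsr(), b)
        x[mi] = np.clip(sol, 0.0, 1.0)
    return ReachabilityResult(
        target_gene, float(x[0]), "exact", std_error=0.0, n_states=n
    )


def _backward_reachable(P: sp.csr_matrix, target: np.ndarray) -> np.ndarray:
    Pt = P.T.tocsr()
    seen = target.copy()
    frontier = np.flatnonzero(target)
    while frontier.size:
        nxt: list[int] = []
        for j in frontier:
            for i in Pt.indices[Pt.indptr[j] : Pt.indptr[j + 1]]:
                if not seen[i]:
                    seen[i] = True
                    nxt.append(i)
        frontier = np.array(nxt, dtype=int)
    return seen


def _value_iteration(
    Q: sp.csr_matrix, b: np.ndarray, tol: float = 1e-10, max_iter: int = 10**6
) -> np.ndarray:
    x = np.zeros(len(b))
    for _ in range(max_iter):
        x_new = Q @ x + b
        if np.max(np.abs(x_new - x)) < tol:
            return x_new
        x = x_new
    return x


def restrict_to_target(m: GuardedModel, target_gene: str) -> GuardedModel:
    """Sub-model over the ancestors of the target gene (reachability-preserving)."""
    if target_gene not in m.genes:
        raise ValueError(f"unknown gene {target_gene!r}")
    parents: dict[str, set[str]] = {g: set() for g in m.genes}
    for c in m.commands:
        if c.kind in (CommandKind.ACTIVATE, CommandKind.INHIBIT1, CommandKind.INHIBIT2):
            parents[c.tgt].add(c.src)
    keep = {target_gene}
    frontier = [target_gene]
    while frontier:
        g = frontier.pop()
        for p in parents[g]:
            if p not in keep:
                keep.add(p)
                frontier.append(p)
    genes = [g for g in m.genes if g in keep]
    commands = [c for c in m.commands if c.tgt in keep]
    return GuardedModel(
        pathway_id=m.pathway_id,
        genes=genes,
        commands=commands,
        effectors=[g for g in m.effectors if g in keep],
        de_genes=frozenset(g for g in m.de_genes if g in keep),
    )


# ---------------------------------------------------------------------------
# Monte-Carlo engine
# ---------------------------------------------------------------------------


@njit(cache=True)
def _simulate_kernel(kind, src, tgt, p, n_genes, n_traj, step_cap, seed, target):
    """Trajectory simulation under the uniform scheduler.

    Returns (per-gene count of trajectories in which the gene ever reached
    state 4, number of censored trajectories).  ``target >= 0`` stops each
    trajectory as soon as that gene hits 4 (single-query mode); ``-1`` runs
    every trajectory to absorption and records all genes (batch mode).
    """
    np.random.seed(seed)
    n_cmds = kind.shape[0]
    counts = np.zeros(n_genes, dtype=np.int64)
    censored = 0
    state = np.empty(n_genes, dtype=np.int8)
    ever4 = np.zeros(n_genes, dtype=np.bool_)
    enabled = np.empty(n_cmds, dtype=np.int64)
    for _ in range(n_traj):
        for i in range(n_genes):
            state[i] = -1
            ever4[i] = False
        stopped = False  # absorbed, or target hit in single-query mode
        for _step in range(step_cap):
            ne = 0
            for c in range(n_cmds):
                a = state[src[c]]
                b = state[tgt[c]]
                k = kind[c]
                ok = False
                if k == 0:  # init
                    ok = b == -1
                elif k == 1:  # source
                    ok = b == 1 or b == 2
                elif k == 2:  # activate
                    ok = a > 2 and (b == 1 or b == 2)
                elif k == 3:  # inhibit1
                    ok = a < 3 and (b == 1 or b == 2)
                else:  # inhibit2
                    ok = a > 2 and b > 2
                if ok:
                    enabled[ne] = c
                    ne += 1
            if ne == 0:
                stopped = True
                break
            c = enabled[np.random.randint(ne)]
            a = state[src[c]]
            b = state[tgt[c]]
            k = kind[c]
            u = np.random.random()
            if k == 0:
                val = 1 if u < p[c] else 2
            elif k == 1:
                val = b + 2 if u < p[c] else 0
            elif k == 2:
                if u < p[c]:
                    val = 3 if (a == 3 and b == 1) else 4
                else:
                    val = 0
            elif k == 3:
                val = b + 2 if u < p[c] else 0
            else:
                val = b - 2 if u < p[c] else 0
            state[tgt[c]] = val
            if val == 4:
                ever4[tgt[c]] = True
                if target >= 0 and tgt[c] == target:
                    stopped = True
                    break
        if not stopped:
            censored += 1
        for i in range(n_genes):
            if ever4[i]:
                counts[i] += 1
    return counts, censored


def _default_step_cap(m: GuardedModel) -> int:
    return max(1, 10 * len(m.commands) * len(m.genes))


def reachability_mc(
    m: GuardedModel,
    target_gene: str,
    n_traj: int = DEFAULT_N_TRAJ,
    step_cap: int | None = None,
    seed: int = 0,
) -> ReachabilityResult:
    """Monte-Carlo estimate of P[F (target = 4)] (deterministic given seed)."""
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    if target_gene not in m.genes:
        raise ValueError(f"unknown gene {target_gene!r}")
    cap = _default_step_cap(m) if step_cap is None else step_cap
    kind, src, tgt, p = m.to_arrays()
    ti = m.genes.index(target_gene)
    counts, censored = _simulate_kernel(
        kind, src, tgt, p, len(m.genes), n_traj, cap, seed % (2**31), ti
    )
    phat = counts[ti] / n_traj
    return ReachabilityResult(
        target_gene,
        float(phat),
        "monte_carlo",
        std_error=float(np.sqrt(phat * (1.0 - phat) / n_traj)),
        n_trajectories=n_traj,
        censored_fraction=censored / n_traj,
    )


def reachability_batch_mc(
    m: GuardedModel,
    target_genes: list[str],
    n_traj: int = DEFAULT_N_TRAJ,
    step_cap: int | None = None,
    seed: int = 0,
) -> dict[str, ReachabilityResult]:
    """One trajectory batch, reachability estimates for several genes at once.

    All estimates share the same trajectories (run to absorption), so the sum
    over targets estimates the expected number of targets ever reaching 4.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    cap = _default_step_cap(m) if step_cap is None else step_cap
    kind, src, tgt, p = m.to_arrays()
    counts, censored = _simulate_kernel(
        kind, src, tgt, p, len(m.genes), n_traj, cap, seed % (2**31), -1
    )
    out: dict[str, ReachabilityResult] = {}
    for g in target_genes:
        ti = m.genes.index(g)
        phat = counts[ti] / n_traj
        out[g] = ReachabilityResult(
            g,
            float(phat),
            "monte_carlo",
            std_error=float(np.sqrt(phat * (1.0 - phat) / n_traj)),
            n_trajectories=n_traj,
            censored_fraction=censored / n_traj,
        )
    return out


def reachability(
    m: GuardedModel, target_gene: str, config: EngineConfig | None = None
) -> ReachabilityResult:
    """Dispatcher: 'exact', 'monte_carlo', or 'auto' (exact with MC fallback)."""
    config = config or EngineConfig()
    if config.engine not in ("exact", "monte_carlo", "auto"):
        raise ValueError(f"unknown engine {config.engine!r}")
    if config.engine in ("exact", "auto"):
        try:
            sub = restrict_to_target(m, target_gene)
            chain = build_chain(sub, state_cap=config.state_cap)
            return reachability_exact(chain, target_gene)
        except StateCapExceeded:
            if config.engine == "exact":
                raise
            config.notes.append(
                f"{m.pathway_id}/{target_gene}: state cap exceeded, "
                "falling back to Monte Carlo"
            )
    return reachability_mc(
        m, target_gene, n_traj=config.n_traj, step_cap=config.step_cap, seed=config.seed
    )
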