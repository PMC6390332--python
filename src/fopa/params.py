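"""Probability parameters of the guarded-command pathway model.

Each activation-family edge A -> B carries

    prob_active   = diff(A,B) * P(A) * P(A->B)

and each inhibition-family edge A -| B carries

    prob_inhibit1 = P(A-|B)
    prob_inhibit2 = diff(A,B) * P(A) * P(A-|B)

where diff(A,B) in {alpha, 2*alpha, 3*alpha} weights the DE status of the
endpoint pair, P(A) is the gene probability from the moderated-t evidence,
and P(A->B) / P(A-|B) are empirical interaction frequencies counted over the
pathway collection.  Note the deliberate asymmetry: prob_inhibit1 is the raw
interaction frequency alone.  Gene initialisation uses (prob1, prob2) =
(1-alpha_e, alpha_e) for non-DE genes and (alpha_e, 1-alpha_e) for DE genes,
with alpha_e the DE-call error taken equal to the FDR cutoff v, and
prob_init = P(A) for genes with no incoming interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import Edge, PathwayCollection, PathwayGraph
from .stats import GeneStatTable

__all__ = [
    "ModelParameters",
    "diff_term",
    "interaction_probability",
    "edge_parameters",
    "init_parameters",
    "compute_parameters",
]

DEFAULT_ALPHA_WEIGHT = 1.0 / 6.0
DEFAULT_ALPHA_ERROR = 0.05


def diff_term(de_A: bool, de_B: bool, alpha_weight: float = DEFAULT_ALPHA_WEIGHT) -> float:
    """DE-pair weight: alpha, 2*alpha or 3*alpha for 0, 1 or 2 DE endpoints.

    DEG-DEG interactions carry the most evidence that the pathway is tied to
    the condition, hence the 1:2:3 ladder.  alpha <= 1/3 keeps the term <= 1.
    """
    if not 0.0 < alpha_weight <= 1.0 / 3.0:
        raise ValueError(f"alpha_weight must lie in (0, 1/3], got {alpha_weight}")
    return alpha_weight * (1 + int(de_A) + int(de_B))


def interaction_probability(
    collection: PathwayCollection, A: str, B: str, polarity: str
) -> float:
    """Empirical frequency of the directed interaction across the collection.

    Numerator: pathways containing an A-to-B edge of the requested polarity
    family; denominator: pathways containing both A and B as nodes.
    """
    if polarity not in ("activating", "inhibiting"):
        raise ValueError(f"polarity must be 'activating' or 'inhibiting', got {polarity!r}")
    want = 1 if polarity == "activating" else -1
    both = 0
    linked = 0
    for p in collection:
        genes = p.gene_nodes()
        if A in genes and B in genes:
            both += 1
            if (A, B, want) in p.edge_set():
                linked += 1
    if both == 0:
        raise ValueError(
            f"genes {A!r} and {B!r} co-occur in no pathway; include the scored "
            "pathway itself in the collection"
        )
    return linked / both


def edge_parameters(
    edge: Edge,
    stats: GeneStatTable,
    collection: PathwayCollection,
    alpha_weight: float = DEFAULT_ALPHA_WEIGHT,
) -> dict[str, float]:
    """Per-edge command probabilities (see module docstring)."""
    A, B = edge.source, edge.target
    d = diff_term(stats.is_de(A), stats.is_de(B), alpha_weight)
    if edge.polarity > 0:
        p_edge = interaction_probability(collection, A, B, "activating")
        return {"diff": d, "p_edge": p_edge, "prob_active": d * stats.P(A) * p_edge}
    p_edge = interaction_probability(collection, A, B, "inhibiting")
    return {
        "diff": d,
        "p_edge": p_edge,
        "prob_inhibit1": p_edge,
        "prob_inhibit2": d * stats.P(A) * p_edge,
    }


def init_parameters(
    gene: str,
    is_de: bool,
    alpha_error: float,
    stats: GeneStatTable,
) -> tuple[float, float, float]:
    """(prob1, prob2, prob_init) for one gene's initialisation commands."""
    if not 0.0 <= alpha_error < 0.5:
        raise ValueError(f"alpha_error must lie in [0, 0.5), got {alpha_error}")
    if is_de:
        prob1, prob2 = alpha_error, 1.0 - alpha_error
    else:
        prob1, prob2 = 1.0 - alpha_error, alpha_error
    return prob1, prob2, stats.P(gene)


@dataclass
class ModelParameters:
    """Every probability parameter of one pathway's guarded-command model."""

    alpha_weight: float = DEFAULT_ALPHA_WEIGHT
    alpha_error: float = DEFAULT_ALPHA_ERROR
    # keyed by (source, target, polarity)
    edge_params: dict[tuple[str, str, int], dict[str, float]] = field(default_factory=dict)
    # keyed by gene: (prob1, prob2, prob_init)
    gene_params: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for key, p in self.edge_params.items():
            for name, val in p.items():
                if name in ("prob_active", "prob_inhibit1", "prob_inhibit2", "p_edge", "diff"):
                    if not 0.0 <= val <= 1.0:
                        raise ValueError(f"{name}={val} out of [0,1] for edge {key}")
        for gene, (p1, p2, pi) in self.gene_params.items():
            if abs(p1 + p2 - 1.0) > 1e-12:
                raise ValueError(f"prob1+prob2 != 1 for gene {gene}")
            if not 0.0 <= pi <= 1.0:
                raise ValueError(f"prob_init={pi} out of [0,1] for gene {gene}")

    def to_tsv(self) -> str:
        lines = ["record\tkey\tvalues"]
        for gene in sorted(self.gene_params):
            p1, p2, pi = self.gene_params[gene]
            lines.append(f"gene\t{gene}\tprob1={p1:.10g};prob2={p2:.10g};prob_init={pi:.10g}")
        for key in sorted(self.edge_params):
            vals = ";".join(
                f"{k}={v:.10g}" for k, v in sorted(self.edge_params[key].items())
            )
            lines.append(f"edge\t{key[0]}->{key[1]}({'+' if key[2] > 0 else '-'})\t{vals}")
        return "\n".join(lines) + "\n"


def compute_parameters(
    g: PathwayGraph,
    stats: GeneStatTable,
    collection: PathwayCollection,
    alpha_weight: float = DEFAULT_ALPHA_WEIGHT,
    alpha_error: float = DEFAULT_ALPHA_ERROR,
) -> ModelParameters:
    """All edge and gene parameters for pathway ``g``.

    ``g`` must be a member of ``collection`` (the interaction-frequency
    denominators count co-occurrence over the collection including ``g``).
    """
    if not any(p.id == g.id for p in collection):
        raise ValueError(
            f"pathway {g.id!r} is not in the collection; interaction "
            "probabilities would be undefined"
        )
    out = ModelParameters(alpha_weight=alpha_weight, alpha_error=alpha_error)
    for e in g.sorted_edges():
        out.edge_params[(e.source, e.target, e.polarity)] = edge_parameters(
            e, stats, collection, alpha_weight
        )
    for gene in g.sorted_genes():
        out.gene_params[gene] = init_parameters(
            gene, stats.is_de(gene), alpha_error, stats
        )
    out.validate()
    return out
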