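"""Compile a parameterized pathway into a probabilistic guarded-command model.

One variable per gene over the domain {-1, 0, 1, 2, 3, 4}:

    -1 uninitialized, 0 not expressed, 1 expressed, 2 differentially
    expressed, 3 activated, 4 differentially activated.

Five command shapes cover the whole model:

    init      [] A=-1                 -> prob1:(A'=1) + prob2:(A'=2)
    source    [] A=1|A=2              -> prob_init:(A'=A+2) + (1-prob_init):(A'=0)
    activate  [] A>2 & (B=1|B=2)      -> p:(B'=(A=3&B=1)?3:4) + (1-p):(B'=0)
    inhibit1  [] A<3 & (B=1|B=2)      -> p:(B'=B+2) + (1-p):(B'=0)
    inhibit2  [] A>2 & B>2            -> p:(B'=B-2) + (1-p):(B'=0)

Every gene gets an init command; genes with no incoming interaction get a
source command; every activation-family edge contributes one activate
command; every inhibition-family edge contributes the inhibit1/inhibit2
pair.  A gene moves to 4 (differentially activated) exactly when it is
activated while differentially expressed, or activated by a differentially
activated source.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field

import numpy as np

from .graph import PathwayGraph, final_effectors
from .params import ModelParameters

__all__ = [
    "CommandKind",
    "Command",
    "GuardedModel",
    "command_structure",
    "build_model",
    "export_model_text",
    "parse_model_text",
]

DOMAIN = (-1, 0, 1, 2, 3, 4)


class CommandKind(enum.IntEnum):
    INIT = 0
    SOURCE = 1
    ACTIVATE = 2
    INHIBIT1 = 3
    INHIBIT2 = 4


@dataclass(frozen=True)
class Command:
    """One guarded command; ``p`` is the probability of the first branch.

    ``src`` equals ``tgt`` for init/source commands.  Only ``tgt`` is ever
    assigned.
    """

    kind: CommandKind
    src: str
    tgt: str
    p: float

    def guard(self, state: dict[str, int]) -> bool:
        a, b = state[self.src], state[self.tgt]
        if self.kind == CommandKind.INIT:
            return b == -1
        if self.kind == CommandKind.SOURCE:
            return b in (1, 2)
        if self.kind == CommandKind.ACTIVATE:
            return a > 2 and b in (1, 2)
        if self.kind == CommandKind.INHIBIT1:
            return a < 3 and b in (1, 2)
        return a > 2 and b > 2  # INHIBIT2

    def branches(self, state: dict[str, int]) -> list[tuple[float, int]]:
        """(probability, new value of tgt) pairs; probabilities sum to 1."""
        a, b = state[self.src], state[self.tgt]
        if self.kind == CommandKind.INIT:
            return [(self.p, 1), (1.0 - self.p, 2)]
        if self.kind == CommandKind.SOURCE:
            return [(self.p, b + 2), (1.0 - self.p, 0)]
        if self.kind == CommandKind.ACTIVATE:
            val = 3 if (a == 3 and b == 1) else 4
            return [(self.p, val), (1.0 - self.p, 0)]
        if self.kind == CommandKind.INHIBIT1:
            return [(self.p, b + 2), (1.0 - self.p, 0)]
        return [(self.p, b - 2), (1.0 - self.p, 0)]  # INHIBIT2


@dataclass
class GuardedModel:
    """Variables (one per gene, initial value -1) plus guarded commands."""

    pathway_id: str
    genes: list[str]  # sorted; defines variable order
    commands: list[Command]
    effectors: list[str] = field(default_factory=list)
    de_genes: frozenset[str] = frozenset()

    def validate(self) -> None:
        gene_set = set(self.genes)
        inits = [c.tgt for c in self.commands if c.kind == CommandKind.INIT]
        if sorted(inits) != sorted(gene_set):
            raise ValueError("every variable needs exactly one init command")
        for c in self.commands:
            if c.src not in gene_set or c.tgt not in gene_set:
                raise ValueError(f"command references unknown gene {c.src}/{c.tgt}")
            if not 0.0 <= c.p <= 1.0:
                raise ValueError(f"command probability {c.p} out of [0,1]")

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(kind, src_idx, tgt_idx, p) arrays for the simulation kernel."""
        idx = self.gene_index()
        kind = np.array([int(c.kind) for c in self.commands], dtype=np.int8)
        src = np.array([idx[c.src] for c in self.commands], dtype=np.int64)
        tgt = np.array([idx[c.tgt] for c in self.commands], dtype=np.int64)
        p = np.array([c.p for c in self.commands], dtype=np.float64)
        return kind, src, tgt, p

    def structurally_equal(self, other: "GuardedModel") -> bool:
        return (
            self.pathway_id == other.pathway_id
            and self.genes == other.genes
            and len(self.commands) == len(other.commands)
            and all(
                a.kind == b.kind
                and a.src == b.src
                and a.tgt == b.tgt
                and math.isclose(a.p, b.p, rel_tol=0, abs_tol=1e-15)
                for a, b in zip(self.commands, other.commands)
            )
            and self.effectors == other.effectors
        )


def command_structure(g: PathwayGraph) -> list[tuple[CommandKind, str, str]]:
    """Deterministic command skeleton of a pathway (no probabilities).

    Order: init per gene (sorted), source per in-degree-0 gene (sorted),
    then per sorted edge the activate command or the inhibit1/inhibit2 pair.
    Shared by :func:`build_model` and the fast scoring path so both compile
    identical models.
    """
    genes = g.sorted_genes()
    targets = {e.target for e in g.edges}
    out: list[tuple[CommandKind, str, str]] = []
    for gene in genes:
        out.append((CommandKind.INIT, gene, gene))
    for gene in genes:
        if gene not in targets:
            out.append((CommandKind.SOURCE, gene, gene))
    for e in g.sorted_edges():
        if e.polarity > 0:
            out.append((CommandKind.ACTIVATE, e.source, e.target))
        else:
            out.append((CommandKind.INHIBIT1, e.source, e.target))
            out.append((CommandKind.INHIBIT2, e.source, e.target))
    return out


def build_model(
    g: PathwayGraph, params: ModelParameters, de: set[str] | frozenset[str] = frozenset()
) -> GuardedModel:
    """Instantiate the guarded-command model of pathway ``g``.

    ``params`` must cover every gene and edge of ``g``; the DE set is kept
    as metadata (the probabilities already encode it).
    """
    commands: list[Command] = []
    for kind, src, tgt in command_structure(g):
        if kind in (CommandKind.INIT, CommandKind.SOURCE):
            if tgt not in params.gene_params:
                raise ValueError(f"missing gene parameters for {tgt!r}")
            prob1, prob2, prob_init = params.gene_params[tgt]
            p = prob1 if kind == CommandKind.INIT else prob_init
        else:
            pol = 1 if kind == CommandKind.ACTIVATE else -1
            key = (src, tgt, pol)
            if key not in params.edge_params:
                raise ValueError(f"missing edge parameters for {key}")
            ep = params.edge_params[key]
            if kind == CommandKind.ACTIVATE:
                p = ep["prob_active"]
            elif kind == CommandKind.INHIBIT1:
                p = ep["prob_inhibit1"]
            else:
                p = ep["prob_inhibit2"]
        commands.append(Command(kind, src, tgt, p))
    m = GuardedModel(
        pathway_id=g.id,
        genes=g.sorted_genes(),
        commands=commands,
        effectors=final_effectors(g),
        de_genes=frozenset(de),
    )
    m.validate()
    return m


# ---------------------------------------------------------------------------
# Textual dialect (PRISM guarded-command language, dtmc)
# ---------------------------------------------------------------------------


def _var_names(genes: list[str]) -> dict[str, str]:
    names: dict[str, str] = {}
    used: set[str] = set()
    for g in genes:
        base = "g_" + re.sub(r"\W", "_", g)
        name = base
        k = 1
        while name in used:
            k += 1
            name = f"{base}_{k}"
        used.add(name)
        names[g] = name
    return names


def _fmt(p: float) -> str:
    return repr(float(p))


def export_model_text(m: GuardedModel) -> str:
    """Deterministic PRISM-dialect rendering of the model.

    Includes the gene <-> variable mapping and one reachability property
    ``P=? [ F (g=4) ]`` per effector, so the file can optionally be fed to
    an external probabilistic model checker.
    """
    names = _var_names(m.genes)
    lines = ["dtmc", f"// pathway: {m.pathway_id}"]
    for g in m.genes:
        lines.append(f"// gene {names[g]} = {g}")
    module_name = re.sub(r"\W", "_", m.pathway_id) or "pathway"
    lines.append(f"module {module_name}")
    for g in m.genes:
        lines.append(f"  {names[g]} : [-1..4] init -1;")
    for c in m.commands:
        a, b = names[c.src], names[c.tgt]
        p1, p2 = _fmt(c.p), _fmt(1.0 - c.p)
        if c.kind == CommandKind.INIT:
            body = f"[] ({b}=-1) -> {p1}:({b}'=1) + {p2}:({b}'=2);"
        elif c.kind == CommandKind.SOURCE:
            body = f"[] ({b}=1)|({b}=2) -> {p1}:({b}'={b}+2) + {p2}:({b}'=0);"
        elif c.kind == CommandKind.ACTIVATE:
            body = (
                f"[] ({a}>2)&(({b}=1)|({b}=2)) -> "
                f"{p1}:({b}'=({a}=3&{b}=1)?3:4) + {p2}:({b}'=0);"
            )
        elif c.kind == CommandKind.INHIBIT1:
            body = (
                f"[] ({a}<3)&(({b}=1)|({b}=2)) -> "
                f"{p1}:({b}'={b}+2) + {p2}:({b}'=0);"
            )
        else:
            body = f"[] ({a}>2)&({b}>2) -> {p1}:({b}'={b}-2) + {p2}:({b}'=0);"
        lines.append("  " + body)
    lines.append("endmodule")
    for g in m.effectors:
        lines.append(f"// effector: {names[g]}")
        lines.append(f'// property: P=? [ F ({names[g]}=4) ]')
    return "\n".join(lines) + "\n"


class ModelTextError(ValueError):
    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


_RE_DECL = re.compile(r"^(\w+) : \[-1\.\.4\] init -1;$")
_RE_GENE = re.compile(r"^// gene (\w+) = (.+)$")
_RE_EFF = re.compile(r"^// effector: (\w+)$")
_FLOAT = r"[0-9.eE+-]+"
_RE_INIT = re.compile(
    rf"^\[\] \((\w+)=-1\) -> ({_FLOAT}):\(\1'=1\) \+ ({_FLOAT}):\(\1'=2\);$"
)
_RE_SOURCE = re.compile(
    rf"^\[\] \((\w+)=1\)\|\(\1=2\) -> ({_FLOAT}):\(\1'=\1\+2\) \+ ({_FLOAT}):\(\1'=0\);$"
)
_RE_ACT = re.compile(
    rf"^\[\] \((\w+)>2\)&\(\((\w+)=1\)\|\(\2=2\)\) -> "
    rf"({_FLOAT}):\(\2'=\(\1=3&\2=1\)\?3:4\) \+ ({_FLOAT}):\(\2'=0\);$"
)
_RE_INH1 = re.compile(
    rf"^\[\] \((\w+)<3\)&\(\((\w+)=1\)\|\(\2=2\)\) -> "
    rf"({_FLOAT}):\(\2'=\2\+2\) \+ ({_FLOAT}):\(\2'=0\);$"
)
_RE_INH2 = re.compile(
    rf"^\[\] \((\w+)>2\)&\((\w+)>2\) -> ({_FLOAT}):\(\2'=\2-2\) \+ ({_FLOAT}):\(\2'=0\);$"
)


def parse_model_text(text: str) -> GuardedModel:
    """Parse the dialect written by :func:`export_model_text`.

    Validates branch-probability sums; grammar violations raise
    :class:`ModelTextError` with the offending line number.
    """
    lines = text.splitlines()
    if not lines or lines[0].strip() != "dtmc":
        raise ModelTextError(1, "expected 'dtmc' header")
    pathway_id = ""
    var_to_gene: dict[str, str] = {}
    variables: list[str] = []
    commands: list[tuple[CommandKind, str, str, float, float]] = []
    effector_vars: list[str] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line or line in ("endmodule",) or line.startswith("module "):
            continue
        if line.startswith("// pathway: "):
            pathway_id = line[len("// pathway: ") :]
            continue
        m = _RE_GENE.match(line)
        if m:
            var_to_gene[m.group(1)] = m.group(2)
            continue
        m = _RE_EFF.match(line)
        if m:
            effector_vars.append(m.group(1))
            continue
        if line.startswith("// "):
            continue
        m = _RE_DECL.match(line)
        if m:
            variables.append(m.group(1))
            continue
        for kind, regex, has_src in (
            (CommandKind.ACTIVATE, _RE_ACT, True),
            (CommandKind.INHIBIT1, _RE_INH1, True),
            (CommandKind.INHIBIT2, _RE_INH2, True),
            (CommandKind.INIT, _RE_INIT, False),
            (CommandKind.SOURCE, _RE_SOURCE, False),
        ):
            m = regex.match(line)
            if m:
                if has_src:
                    src, tgt, p1, p2 = m.groups()
                else:
                    tgt, p1, p2 = m.groups()
                    src = tgt
                try:
                    f1, f2 = float(p1), float(p2)
                except ValueError:
                    raise ModelTextError(lineno, f"bad probability in {line!r}") from None
                commands.append((kind, src, tgt, f1, f2))
                break
        else:
            raise ModelTextError(lineno, f"unrecognized statement {line!r}")

    if not variables:
        raise ModelTextError(len(lines), "no variable declarations found")
    gene_of = {v: var_to_gene.get(v, v) for v in variables}
    for lineno_chk, (kind, src, tgt, f1, f2) in enumerate(commands):
        if abs(f1 + f2 - 1.0) > 1e-9:
            raise ModelTextError(0, f"branch probabilities sum to {f1 + f2!r}, not 1")
        if src not in gene_of or tgt not in gene_of:
            raise ModelTextError(0, f"command references undeclared variable")
    model = GuardedModel(
        pathway_id=pathway_id or "pathway",
        genes=sorted(gene_of[v] for v in variables),
        commands=[
            Command(kind, gene_of[src], gene_of[tgt], f1)
            for kind, src, tgt, f1, _ in commands
        ],
        effectors=[gene_of[v] for v in effector_vars],
    )
    model.validate()
    return model
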