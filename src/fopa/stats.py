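"""Per-gene differential-expression evidence feeding the pathway model.

Pipeline: empirical-Bayes moderated two-sample t -> Benjamini-Hochberg FDR ->
DE calls at cutoff v -> pathway-frequency weight Fn(A) -> gene probability
P(A) = |T(A) * Fn(A)| rescaled into [0,1].

The moderated t follows Smyth's hierarchical model: per-gene pooled sample
variances s_g^2 with d_g degrees of freedom are shrunk toward a common prior
value s0^2 with prior degrees of freedom d0, both estimated by method of
moments on log s_g^2.  This stabilises variance estimates in the
small-sample designs typical of expression studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .graph import PathwayCollection

__all__ = [
    "ExpressionDataset",
    "GeneStatTable",
    "moderated_t",
    "moderated_t_arrays",
    "fit_variance_prior",
    "adjust_fdr",
    "flag_de",
    "gene_frequencies",
    "frequency_weight",
    "gene_probability",
    "build_gene_stats",
]

CONTROL = "control"
CASE = "case"


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix (log scale) with two-class labels."""

    values: pd.DataFrame  # rows = genes, columns = samples
    labels: pd.Series  # per sample: 'control' | 'case'

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            raise ValueError("every sample column needs a class label")
        bad = set(self.labels.unique()) - {CONTROL, CASE}
        if bad:
            raise ValueError(f"labels must be 'control'/'case', got {sorted(bad)}")
        counts = self.labels.value_counts()
        if counts.get(CONTROL, 0) < 2 or counts.get(CASE, 0) < 2:
            raise ValueError("need at least 2 samples per class")
        if self.values.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        if self.values.isna().any().any():
            raise ValueError("missing expression values are not supported")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def with_labels(self, labels: np.ndarray | pd.Series) -> "ExpressionDataset":
        return ExpressionDataset(
            self.values, pd.Series(np.asarray(labels), index=self.values.columns)
        )

    @classmethod
    def from_text(cls, matrix_text: str, labels_text: str, sep: str = "\t"):
        """Load from delimited text: matrix with sample-id header, and a
        two-column ``sample<TAB>class`` label file."""
        import io

        values = pd.read_csv(io.StringIO(matrix_text), sep=sep, index_col=0)
        labels = pd.read_csv(
            io.StringIO(labels_text), sep=sep, index_col=0, header=None
        ).iloc[:, 0]
        # a header line ("sample  class") is tolerated
        if labels.index[0] == "sample":
            labels = labels.iloc[1:]
        labels.index = labels.index.astype(str)
        values.columns = values.columns.astype(str)
        return cls(values, labels.reindex(values.columns))


# ---------------------------------------------------------------------------
# Moderated t
# ---------------------------------------------------------------------------

_DF_CAP = 1e6  # stands in for d0 = infinity in the t reference distribution


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-12 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment estimates of (d0, s0^2) from pooled variances s2 with df d_g.

    Works on e_g = log(s_g^2) adjusted by the digamma/log terms of the
    scaled-F sampling model; the excess spread of e_g over its sampling
    component identifies the prior degrees of freedom d0.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all genes have zero variance; prior is undefined")
    z = np.log(np.where(ok, s2, np.nan))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = np.nanmean(e)
    n = int(ok.sum())
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = np.nansum((e - emean) ** 2) / (n - 1)
    excess = evar - special.polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    else:
        half_d0 = _trigamma_inverse(float(excess))
        d0 = 2.0 * half_d0
        s0_2 = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_2


def moderated_t_arrays(
    case: np.ndarray, ctrl: np.ndarray, d0_override: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Array-level moderated t: genes x case / genes x control matrices in,
    (T, two-sided p) out.  Shared by :func:`moderated_t` and the fast
    permutation-scoring path so both compute identical statistics."""
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per class")
    df_g = n1 + n2 - 2
    mean_diff = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_g

    if d0_override is not None:
        d0 = float(d0_override)
        s0_2 = 0.0 if d0 == 0 else fit_variance_prior(s2, df_g)[1]
    else:
        d0, s0_2 = fit_variance_prior(s2, df_g)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = _DF_CAP
    else:
        s2_post = (d0 * s0_2 + df_g * s2) / (d0 + df_g)
        df_total = min(d0 + df_g, _DF_CAP)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean_diff / np.where(se > 0, se, 1.0), 0.0)
    t = np.where((se == 0) & (mean_diff == 0), 0.0, t)
    if np.any((se == 0) & (mean_diff != 0)):
        t = np.where((se == 0) & (mean_diff != 0), np.sign(mean_diff) * 1e9, t)
    p = 2.0 * sps.t.sf(np.abs(t), df_total)
    return t, np.clip(p, 0.0, 1.0)


def moderated_t(
    data: ExpressionDataset, d0_override: float | None = None
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t per gene.

    Returns a DataFrame with columns ``T`` and ``p`` (two-sided), indexed by
    gene.  ``d0_override`` forces the prior degrees of freedom (0 recovers
    the ordinary pooled-variance t; mainly for validation).
    """
    case = data.values.loc[:, (data.labels == CASE).values].to_numpy(float)
    ctrl = data.values.loc[:, (data.labels == CONTROL).values].to_numpy(float)
    t, p = moderated_t_arrays(case, ctrl, d0_override=d0_override)
    return pd.DataFrame({"T": t, "p": p}, index=data.values.index)


# ---------------------------------------------------------------------------
# FDR, DE calls, weights, P(A)
# ---------------------------------------------------------------------------


def adjust_fdr(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    arr = np.asarray(p, dtype=float)
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        raise ValueError("p-values must lie in [0,1]")
    if arr.size == 0:
        return arr
    return np.clip(sps.false_discovery_control(arr, method="bh"), 0.0, 1.0)


def flag_de(q: np.ndarray | pd.Series, v: float = 0.05) -> np.ndarray:
    """DE calls: genes with FDR-adjusted p strictly below the cutoff v."""
    if not 0.0 < v < 1.0:
        raise ValueError("cutoff v must be in (0,1)")
    return np.asarray(q) < v


def gene_frequencies(collection: PathwayCollection) -> pd.Series:
    """f(A): number of member pathways whose node set contains gene A."""
    if len(collection) == 0:
        raise ValueError("collection is empty")
    counts: dict[str, int] = {}
    for p in collection:
        for gene in p.gene_nodes():
            counts[gene] = counts.get(gene, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def frequency_weight(f: pd.Series, mode: str = "literal") -> pd.Series:
    """Frequency weight Fn(A) = sqrt((f - min f)/(max f - min f)).

    ``literal`` follows the printed min-max form (weight grows with
    frequency); ``inverted`` flips it so that pathway-specific genes get
    weight near 1 and ubiquitous genes near 0, matching the down-weighting
    rationale.  Both are exposed because the two readings disagree; see
    docs/methods.md.  Degenerate case max f = min f gives Fn = 1.
    """
    if len(f) == 0:
        raise ValueError("empty frequency table")
    fmin, fmax = float(f.min()), float(f.max())
    if fmax == fmin:
        return pd.Series(1.0, index=f.index)
    frac = (f.astype(float) - fmin) / (fmax - fmin)
    if mode == "inverted":
        frac = 1.0 - frac
    elif mode != "literal":
        raise ValueError(f"mode must be 'literal' or 'inverted', got {mode!r}")
    return np.sqrt(frac)


def gene_probability(
    T: pd.Series, Fn: pd.Series, scaling: str = "max_normalize"
) -> pd.Series:
    """P(A) = |T(A) * Fn(A)| rescaled into [0,1].

    ``max_normalize`` divides |T| by the largest |T| over measured genes;
    ``clip`` truncates |T*Fn| at 1.  The raw product is unbounded, so one of
    the two rescalings is always applied.
    """
    T, Fn = T.align(Fn, join="left")
    Fn = Fn.fillna(0.0)
    absT = T.abs()
    if scaling == "max_normalize":
        tmax = float(absT.max()) if len(absT) else 0.0
        if tmax == 0:
            return pd.Series(0.0, index=T.index)
        out = (absT / tmax) * Fn
    elif scaling == "clip":
        out = np.minimum(1.0, absT * Fn)
    else:
        raise ValueError(f"scaling must be 'max_normalize' or 'clip', got {scaling!r}")
    return out.clip(0.0, 1.0)


# ---------------------------------------------------------------------------
# Assembled per-gene table
# ---------------------------------------------------------------------------


@dataclass
class GeneStatTable:
    """Per-gene T, p, q, DE flag, frequency f, weight Fn, probability P.

    Genes present in pathways but absent from the expression matrix get
    T = 0 and are treated as expressed non-DE (platform coverage should not
    switch a pathway off); their Fn still comes from the frequency count.
    """

    table: pd.DataFrame  # columns: T, p, q, is_de, f, Fn, P
    v: float

    def __post_init__(self) -> None:
        t = self.table
        for col in ("q", "Fn", "P"):
            vals = t[col].to_numpy(float)
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError(f"column {col} must lie in [0,1]")
        if not (t["is_de"] == (t["q"] < self.v)).all():
            raise ValueError("is_de flag inconsistent with q < v")

    def de_genes(self) -> set[str]:
        return set(self.table.index[self.table["is_de"]])

    def P(self, gene: str) -> float:
        return float(self.table.at[gene, "P"]) if gene in self.table.index else 0.0

    def is_de(self, gene: str) -> bool:
        return bool(self.table.at[gene, "is_de"]) if gene in self.table.index else False

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index_label="gene")


def build_gene_stats(
    data: ExpressionDataset | None,
    collection: PathwayCollection,
    v: float = 0.05,
    freq_mode: str = "literal",
    prob_scaling: str = "max_normalize",
    precomputed: pd.DataFrame | None = None,
) -> GeneStatTable:
    """Full per-gene table over the union of measured and pathway genes.

    ``precomputed`` may supply a ``gene -> (T, q)`` table in place of raw
    expression data (bypassing the moderated t).
    """
    if precomputed is not None:
        tp = pd.DataFrame(
            {"T": precomputed["T"].astype(float), "p": np.nan}, index=precomputed.index
        )
        q = precomputed["q"].astype(float).to_numpy()
    elif data is not None:
        tp = moderated_t(data)
        q = adjust_fdr(tp["p"].to_numpy())
    else:
        raise ValueError("either expression data or a precomputed table is required")

    genes = tp.index.union(pd.Index(sorted(collection.gene_universe)))
    table = pd.DataFrame(index=genes)
    table["T"] = tp["T"].reindex(genes).fillna(0.0)
    table["p"] = tp["p"].reindex(genes)
    table["q"] = pd.Series(q, index=tp.index).reindex(genes).fillna(1.0)
    table["is_de"] = flag_de(table["q"].to_numpy(), v)

    f = gene_frequencies(collection)
    table["f"] = f.reindex(genes).fillna(0).astype(int)
    # Fn spread is defined by genes that actually occur in pathways
    Fn = frequency_weight(f, mode=freq_mode)
    table["Fn"] = Fn.reindex(genes).fillna(0.0)
    table["P"] = gene_probability(table["T"], table["Fn"], scaling=prob_scaling)
    return GeneStatTable(table=table, v=v)
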