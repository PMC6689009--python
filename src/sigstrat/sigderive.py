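"""Functionally tuned gene-signature derivation.

The signature is built in two halves and intersected: (1) a co-expression
module around an anchor gene — every feature's Spearman rank correlation with
the anchor in a clinical cohort, thresholded at |rho| > tau; (2) a knockdown
differential table — per-feature linear models contrasting knockdown against
control profiles with Benjamini-Hochberg adjustment and a log2-fold-change
floor.  Genes positively co-expressed with the anchor that go DOWN upon its
knockdown form the high-activation template; negatively co-expressed genes
that go UP form the low-activation template.  This inverse-expression
intersection keeps only genes functionally downstream of the anchor pathway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptySignatureError, FitError, ValidationError
from .synthio import KDExperiment

DEFAULT_TAU = 0.3  # |Spearman rho| threshold for co-expression membership
DEFAULT_LFC = 2.0  # log2 fold-change floor for signature-grade KD response
DEFAULT_ALPHA = 0.05  # BH-adjusted significance level


# ---------------------------------------------------------------------------
# co-expression module
# ---------------------------------------------------------------------------


@dataclass
class CoexprModule:
    """Anchor-centred co-expression module.

    ``rho`` holds the Spearman correlation of every usable feature against
    the anchor; ``pos_set`` / ``neg_set`` are the features with rho > tau and
    rho < -tau respectively (the anchor itself is excluded).
    """

    anchor: str
    rho: pd.Series
    tau: float
    pos_set: list[str]
    neg_set: list[str]
    excluded: list[str] = field(default_factory=list)


def coexpr_module(
    expr: pd.DataFrame, anchor: str, tau: float = DEFAULT_TAU
) -> CoexprModule:
    """Rank-correlate every feature against the anchor and threshold.

    Parameters
    ----------
    expr : DataFrame, features x samples (log2 scale; only ranks are used).
    anchor : feature id to correlate against; must be present.
    tau : membership threshold on |rho|.

    Constant features have undefined rank correlation and are excluded with
    a warning.  Ties are handled by average ranks.
    """
    if anchor not in expr.index:
        raise KeyError(f"anchor feature {anchor!r} not in expression matrix")
    if expr.shape[1] < 3:
        raise ValidationError("need at least 3 samples for rank correlation")

    values = expr.to_numpy(dtype=float)
    ranks = stats.rankdata(values, axis=1)
    sd = ranks.std(axis=1)
    constant = sd == 0
    excluded = list(expr.index[constant])
    if excluded:
        warnings.warn(
            f"{len(excluded)} constant feature(s) excluded from co-expression "
            f"module (undefined correlation)",
            stacklevel=2,
        )

    a = ranks[expr.index.get_loc(anchor)]
    if a.std() == 0:
        raise ValidationError(f"anchor {anchor!r} is constant; correlation undefined")
    a_c = a - a.mean()
    r_c = ranks - ranks.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (r_c @ a_c) / (np.sqrt((r_c**2).sum(axis=1)) * np.sqrt((a_c**2).sum()))
    rho = pd.Series(rho, index=expr.index, name="rho")
    rho = rho[~constant].drop(index=anchor)

    pos = rho[rho > tau].sort_values(ascending=False)
    neg = rho[rho < -tau].sort_values()
    return CoexprModule(
        anchor=anchor,
        rho=rho,
        tau=tau,
        pos_set=list(pos.index),
        neg_set=list(neg.index),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# row-wise OLS shared by the two differential operations
# ---------------------------------------------------------------------------


def _rowwise_ols(
    y: np.ndarray, x: np.ndarray, coef: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of every row of ``y`` on design ``x``.

    Returns (beta[coef], t, p two-sided) per row.  One shared normal-equation
    solve covers all rows, so this scales to tens of thousands of features.
    """
    n, p = x.shape
    df = n - p
    if df <= 0:
        raise FitError(f"zero residual degrees of freedom (n={n}, p={p})")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ x @ xtx_inv.T  # features x p
    resid = y - beta @ x.T
    sigma2 = (resid**2).sum(axis=1) / df
    se = np.sqrt(sigma2 * xtx_inv[coef, coef])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[:, coef] / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals = np.where(np.isnan(t), 1.0, pvals)
    return beta[:, coef], t, pvals


# ---------------------------------------------------------------------------
# knockdown differential table
# ---------------------------------------------------------------------------


@dataclass
class DiffTable:
    """Per-feature knockdown differential statistics.

    ``table`` columns: log2FC (knockdown minus control), p, adj_p (BH).
    Thresholds: ``alpha`` on adjusted p (significance), ``lfc`` on |log2FC|
    (signature grade).
    """

    table: pd.DataFrame
    alpha: float
    lfc: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["adj_p"] < self.alpha]

    @property
    def down_genes(self) -> list[str]:
        """Signature-grade genes suppressed by knockdown."""
        t = self.significant
        return list(t.index[t["log2FC"] <= -self.lfc])

    @property
    def up_genes(self) -> list[str]:
        """Signature-grade genes induced by knockdown."""
        t = self.significant
        return list(t.index[t["log2FC"] >= self.lfc])


def kd_differential(
    kd: KDExperiment, alpha: float = DEFAULT_ALPHA, lfc: float = DEFAULT_LFC
) -> DiffTable:
    """Per-feature linear model of expression on condition, lines as blocks.

    Fits ``expression ~ condition (+ line)`` by ordinary least squares for
    every feature, with the cell line entering as a fixed blocking factor
    whenever more than one line is present.  Two-sided p-values on the
    knockdown coefficient are BH-adjusted across features.
    """
    design = kd.design.loc[kd.expr.columns]
    cond = (design["condition"] == "kd").to_numpy(dtype=float)
    if len(np.unique(cond)) < 2:
        raise ValidationError("need both control and knockdown conditions")
    cols = [np.ones_like(cond), cond]
    lines = pd.unique(design["line"])
    if len(lines) > 1:
        for ln in lines[1:]:
            cols.append((design["line"] == ln).to_numpy(dtype=float))
    x = np.column_stack(cols)

    logfc, _, pvals = _rowwise_ols(kd.expr.to_numpy(dtype=float), x, coef=1)
    adj = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"log2FC": logfc, "p": pvals, "adj_p": adj}, index=kd.expr.index
    )
    return DiffTable(table=table, alpha=alpha, lfc=lfc)


# ---------------------------------------------------------------------------
# signature assembly
# ---------------------------------------------------------------------------


@dataclass
class GeneSignature:
    """Two directed templates plus per-gene annotations.

    ``high_template``: genes positively co-expressed with the anchor and
    suppressed by its knockdown (markers of pathway-high samples).
    ``low_template``: negatively co-expressed genes induced by knockdown.
    Both are ordered by |rho| descending; ``annotations`` carries rho,
    log2FC and adjusted p per member.
    """

    high_template: list[str]
    low_template: list[str]
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        overlap = set(self.high_template) & set(self.low_template)
        if overlap:
            raise ValidationError(f"templates overlap: {sorted(overlap)[:5]}")

    def __len__(self) -> int:
        return len(self.high_template) + len(self.low_template)

    def to_gmt_sets(self, name: str = "SIG") -> dict[str, list[str]]:
        return {f"{name}_HIGH": self.high_template, f"{name}_LOW": self.low_template}

    @classmethod
    def from_gmt_sets(cls, sets: dict[str, list[str]]) -> "GeneSignature":
        high = next((v for k, v in sets.items() if k.upper().endswith("_HIGH")), None)
        low = next((v for k, v in sets.items() if k.upper().endswith("_LOW")), None)
        if high is None or low is None:
            raise ValidationError("GMT must contain one *_HIGH and one *_LOW set")
        ann = pd.DataFrame(index=pd.Index(high + low, name="gene"))
        return cls(high_template=high, low_template=low, annotations=ann)


def build_signature(module: CoexprModule, diff: DiffTable) -> GeneSignature:
    """Intersect the co-expression module with the inverse knockdown response.

    high = pos_set ∩ {signature-grade down upon knockdown};
    low = neg_set ∩ {signature-grade up upon knockdown}.  Raises
    ``EmptySignatureError`` when both intersections are empty.
    """
    down = set(diff.down_genes)
    up = set(diff.up_genes)
    abs_rho = module.rho.abs()

    def ordered(genes: set[str]) -> list[str]:
        return sorted(genes, key=lambda g: (-abs_rho[g], g))

    high = ordered(set(module.pos_set) & down)
    low = ordered(set(module.neg_set) & up)
    if not high and not low:
        raise EmptySignatureError(
            "no genes survive the co-expression x inverse-knockdown intersection"
        )
    members = high + low
    ann = pd.DataFrame(
        {
            "rho": module.rho.reindex(members),
            "log2FC": diff.table["log2FC"].reindex(members),
            "adj_p": diff.table["adj_p"].reindex(members),
            "template": ["high"] * len(high) + ["low"] * len(low),
        },
        index=pd.Index(members, name="gene"),
    )
    return GeneSignature(high_template=high, low_template=low, annotations=ann)


# ---------------------------------------------------------------------------
# class-vs-class disease signature
# ---------------------------------------------------------------------------


@dataclass
class DiseaseSignature:
    """Differential genes between two sample classes, ranked by |t|.

    ``table`` columns: t, log2FC (positive class minus other), p, adj_p,
    direction (+1 up in the positive class).  Exposes ``genes`` and
    ``directions`` so it plugs directly into signature-concordance scoring.
    """

    table: pd.DataFrame
    positive_class: str
    fdr_max: float

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def directions(self) -> np.ndarray:
        return self.table["direction"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.table)


def class_differential(
    expr: pd.DataFrame,
    classes: pd.Series,
    positive: str | None = None,
    fdr_max: float = 1e-4,
) -> DiseaseSignature:
    """Two-class per-gene linear model with BH FDR control.

    ``classes`` assigns each sample (column of ``expr``) to one of exactly
    two labels; ``positive`` names the class whose overexpression counts as
    direction +1 (default: lexicographically first label).  Genes with
    adjusted p below ``fdr_max`` are retained, ranked by |t| descending.
    """
    classes = classes.reindex(expr.columns)
    levels = sorted(classes.dropna().unique())
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 classes, got {levels}")
    positive = positive or levels[0]
    if positive not in levels:
        raise ValidationError(f"positive class {positive!r} not among {levels}")
    counts = classes.value_counts()
    if (counts < 2).any():
        raise ValidationError("each class needs at least 2 samples")

    indicator = (classes == positive).to_numpy(dtype=float)
    x = np.column_stack([np.ones_like(indicator), indicator])
    logfc, t, pvals = _rowwise_ols(expr.to_numpy(dtype=float), x, coef=1)
    adj = multipletests(pvals, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "t": t,
            "log2FC": logfc,
            "p": pvals,
            "adj_p": adj,
            "direction": np.where(logfc >= 0, 1, -1),
        },
        index=expr.index,
    )
    table = table[table["adj_p"] < fdr_max]
    table = table.reindex(
        table["t"].abs().sort_values(ascending=False, kind="stable").index
    )
    return DiseaseSignature(table=table, positive_class=positive, fdr_max=fdr_max)
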