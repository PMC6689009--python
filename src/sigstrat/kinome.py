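"""Kinome peptide-array analytics.

Peptide phosphorylation readouts are mapped to kinases through a many-to-many
peptide-kinase table, correlated peptides are clustered within each kinase,
activity is summarized per kinase and condition from array-wide ranks (so
activities are comparable between kinases and invariant to monotone intensity
transforms), and differential regulation across drug doses is tested by
per-kinase linear regression.  The ranked output is annotated against the
transcriptomic signature to surface candidate resistance kinases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ValidationError
from .sigderive import GeneSignature

log = logging.getLogger(__name__)

DEFAULT_R_MIN = 0.6  # Pearson threshold linking peptides into a cluster
DEFAULT_ALPHA = 0.1  # per-kinase significance level on the dose slope


@dataclass
class KinasePeptideView:
    """Per-kinase view of the peptide intensity matrix."""

    readouts: pd.DataFrame  # peptides x conditions
    kinase_peptides: dict[str, list[str]]
    orphans: list[str]  # measured peptides with no kinase mapping


def build_matrix(readouts: pd.DataFrame, kmap: pd.DataFrame) -> KinasePeptideView:
    """Organise measured peptides under their mapped kinases.

    ``kmap`` has columns ``peptide`` and ``kinase`` and may map one peptide
    to several kinases.  Mapped-but-unmeasured peptides are ignored;
    measured-but-unmapped peptides are retained in the orphan bucket and
    logged.
    """
    if kmap.empty:
        raise ValidationError("empty peptide-kinase mapping")
    if (readouts.to_numpy() < 0).any():
        raise ValidationError("negative phospho intensities")
    measured = set(readouts.index)
    kmap = kmap[kmap["peptide"].isin(measured)]
    if kmap.empty:
        raise ValidationError("no mapped peptide is present in the readout matrix")
    view: dict[str, list[str]] = {}
    for kin, sub in kmap.groupby("kinase", sort=True):
        view[kin] = sorted(set(sub["peptide"]))
    mapped = set(kmap["peptide"])
    orphans = sorted(measured - mapped)
    if orphans:
        log.info("%d orphan peptide(s) without kinase mapping", len(orphans))
    return KinasePeptideView(readouts=readouts, kinase_peptides=view, orphans=orphans)


@dataclass
class PeptideClusters:
    """Connected components of the peptide correlation graph, per kinase."""

    clusters: dict[str, list[list[str]]]
    r_min: float


def cluster_peptides(view: KinasePeptideView, r_min: float = DEFAULT_R_MIN) -> PeptideClusters:
    """Cluster each kinase's peptides by Pearson correlation across conditions.

    Two peptides join the same cluster when they are connected through edges
    with r ≥ r_min.  Constant peptides have undefined correlation and become
    singletons with a warning.  Singletons are allowed.
    """
    if view.readouts.shape[1] < 2:
        raise ValidationError("need at least 2 conditions to correlate peptides")
    out: dict[str, list[list[str]]] = {}
    warned_constant = False
    for kin, peps in view.kinase_peptides.items():
        sub = view.readouts.loc[peps].to_numpy(dtype=float)
        if len(peps) == 1:
            out[kin] = [[peps[0]]]
            continue
        sd = sub.std(axis=1)
        if (sd == 0).any() and not warned_constant:
            warnings.warn(
                "constant peptide(s) encountered; treated as singleton clusters",
                stacklevel=2,
            )
            warned_constant = True
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(sub)
        corr = np.nan_to_num(corr, nan=-np.inf)
        adj = csr_matrix((corr >= r_min).astype(int))
        n_comp, labels = connected_components(adj, directed=False)
        comps: list[list[str]] = [[] for _ in range(n_comp)]
        for pep, lab in zip(peps, labels):
            comps[lab].append(pep)
        out[kin] = [sorted(c) for c in comps]
    return PeptideClusters(clusters=out, r_min=r_min)


def kinase_activity(clusters: PeptideClusters, readouts: pd.DataFrame) -> pd.DataFrame:
    """Scaled-rank activity per kinase and condition, in (0, 1].

    Within each condition all measured peptides are ranked across the whole
    array (average ranks for ties) and scaled by the peptide count, so the
    top peptide scores 1.  A cluster scores the mean scaled rank of its
    members; the kinase activity is the cluster-size-weighted mean over its
    clusters.  Kinases with no measured peptide are absent (logged upstream).
    The cluster membership trace is attached as ``result.attrs['clusters']``.
    """
    n = readouts.shape[0]
    ranks = pd.DataFrame(
        stats.rankdata(readouts.to_numpy(dtype=float), axis=0) / n,
        index=readouts.index,
        columns=readouts.columns,
    )
    rows = {}
    for kin, comps in clusters.clusters.items():
        sizes = np.array([len(c) for c in comps], dtype=float)
        cluster_means = np.vstack([ranks.loc[c].mean(axis=0).to_numpy() for c in comps])
        rows[kin] = (sizes[:, None] * cluster_means).sum(axis=0) / sizes.sum()
    activity = pd.DataFrame.from_dict(rows, orient="index", columns=readouts.columns)
    activity.index.name = "kinase"
    activity.attrs["clusters"] = clusters.clusters
    return activity


def differential_kinase(
    activity: pd.DataFrame, doses: pd.Series, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Per-kinase linear regression of activity on dose.

    ``doses`` gives the drug dose in uM for every condition column (DMSO
    control = 0).  Two-sided p on the slope; significant iff p < alpha
    (default 0.1, unadjusted); direction is the slope sign.
    """
    doses = doses.reindex(activity.columns)
    if doses.isna().any():
        raise ValidationError("dose missing for some condition(s)")
    d = doses.to_numpy(dtype=float)
    if len(np.unique(d)) < 2:
        raise ValidationError("need at least 2 distinct doses")
    if len(d) < 3:
        raise ValidationError("need at least 3 conditions (doses or replicates)")
    rows = []
    for kin, y in activity.iterrows():
        res = stats.linregress(d, y.to_numpy(dtype=float))
        rows.append(
            {
                "kinase": kin,
                "slope": res.slope,
                "p": res.pvalue if not np.isnan(res.pvalue) else 1.0,
                "significant": bool(res.pvalue < alpha) if not np.isnan(res.pvalue) else False,
                "direction": "up" if res.slope > 0 else "down",
            }
        )
    out = pd.DataFrame(rows).set_index("kinase")
    out.attrs["alpha"] = alpha
    return out


def prioritize(
    diff: pd.DataFrame,
    sig: GeneSignature | None = None,
    gene_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Rank kinases: significant ones first, then by |slope| descending.

    Each kinase is annotated with whether its gene (via ``gene_map``, default
    the kinase id itself) belongs to the signature, and whether the direction
    is concordant with the resistance reading — a kinase rising where the
    low-activation template genes are up, or falling where the high-activation
    template genes sit.  Unannotated kinases are ranked but flagged.
    """
    if diff.empty:
        out = diff.copy()
        out["rank"] = pd.Series(dtype=int)
        return out
    gene_map = gene_map or {}
    high = set(sig.high_template) if sig is not None else set()
    low = set(sig.low_template) if sig is not None else set()

    ann = diff.copy()
    genes = [gene_map.get(k, k) for k in ann.index]
    ann["gene"] = genes
    ann["in_signature"] = [g in high or g in low for g in genes]
    ann["concordant"] = [
        (d == "up" and g in low) or (d == "down" and g in high)
        for g, d in zip(genes, ann["direction"])
    ]
    ann["annotated"] = sig is not None
    ann = ann.sort_values(
        by=["significant", "slope", "gene"],
        key=lambda s: s.abs() if s.name == "slope" else s,
        ascending=[False, False, True],
        kind="stable",
    )
    ann["rank"] = np.arange(1, len(ann) + 1)
    return ann
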