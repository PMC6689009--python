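"""Drug-interaction analytics.

Median-effect (Chou-Talalay) fits of monotherapy titrations, IC50, the
combination index with Fa-CI curves, and concordance/discordance ranking of
drug signatures against a reference compound and a disease signature: a
combination is a promising reverser when its transcriptomic signature is
highly discordant with the disease signature while sharing little with the
reference compound already in use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, ValidationError
from .synthio import DrugSignature, DrugSignatureLibrary

FA_CLIP = (0.005, 0.995)  # logit-stabilising bounds on fraction affected
ADDITIVE_BAND = (0.9, 1.1)  # CI band called 'additive'
DEFAULT_TOP_K = 250


# ---------------------------------------------------------------------------
# median-effect fits
# ---------------------------------------------------------------------------


@dataclass
class MedianEffectFit:
    """Median-effect parameters: fa/fu = (D/Dm)^m, so IC50 = Dm."""

    m: float  # Hill-type slope, unitless
    dm: float  # median-effect dose, uM
    r: float  # correlation of the log-linear fit
    n_points: int


def _median_effect_fa(dose: np.ndarray, m: float, dm: float) -> np.ndarray:
    return 1.0 / (1.0 + (dm / dose) ** m)


def median_effect_fit(
    doses: Sequence[float],
    fa: Sequence[float],
    clip: tuple[float, float] = FA_CLIP,
    refine: bool = True,
) -> MedianEffectFit:
    """Fit of the log-linearised median-effect equation.

    log10(fa/(1−fa)) = m·log10(D) − m·log10(Dm).  Points whose fraction
    affected falls outside ``clip`` carry no stable logit information (near
    total kill or no effect) and are excluded from the log-linear stage; at
    least 3 usable dose points must remain and doses must be positive.
    The log-linear least squares uses delta-method weights
    (fa·(1−fa))² — the inverse variance of the logit under additive fa
    noise — and, with ``refine`` (default), the parameters are polished by
    nonlinear least squares on the fa scale over all points, which is exact
    on noiseless data and robust when low-dose points are noise-dominated.
    """
    d = np.asarray(doses, dtype=float)
    f = np.asarray(fa, dtype=float)
    if (d <= 0).any():
        raise ValidationError("doses must be positive")
    usable = ~np.isnan(f) & (f >= clip[0]) & (f <= clip[1])
    du, fu = d[usable], f[usable]
    if len(du) < 3:
        raise FitError(f"median-effect fit needs >= 3 usable points, got {len(du)}")
    x = np.log10(du)
    y = np.log10(fu / (1.0 - fu))
    w = (fu * (1.0 - fu)) ** 2
    w = w / w.sum()
    xm, ym = (w * x).sum(), (w * y).sum()
    sxx = (w * (x - xm) ** 2).sum()
    if sxx == 0:
        raise FitError("all usable doses identical; slope undefined")
    m = float((w * (x - xm) * (y - ym)).sum() / sxx)
    if m <= 0:
        raise FitError(f"non-positive median-effect slope (m={m:.3g})")
    dm = float(10.0 ** (-(ym - m * xm) / m))
    r = float(stats.pearsonr(x, y)[0]) if len(du) > 2 else 1.0

    if refine:
        from scipy.optimize import curve_fit

        keep = ~np.isnan(f)
        try:
            (m, dm), _ = curve_fit(
                _median_effect_fa,
                d[keep],
                f[keep],
                p0=[m, dm],
                bounds=([1e-6, 1e-12], [50.0, 1e12]),
            )
            m, dm = float(m), float(dm)
        except RuntimeError:  # keep the log-linear estimate
            pass
    return MedianEffectFit(m=m, dm=dm, r=r, n_points=len(du))


def ic50(fit: MedianEffectFit) -> float:
    """Half-maximal inhibitory dose: the dose with fa = 0.5, i.e. Dm."""
    return fit.dm


# ---------------------------------------------------------------------------
# combination index
# ---------------------------------------------------------------------------


@dataclass
class CIResult:
    """Chou-Talalay combination index at one combination point."""

    d1: float
    d2: float
    fa: float
    dx1: float
    dx2: float
    ci: float
    verdict: str  # synergistic / additive / antagonistic
    reliable: bool  # False when fa sat at a clipping boundary


def _dx(fit: MedianEffectFit, fa: float) -> float:
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def combination_index(
    d1: float,
    d2: float,
    fa_combo: float,
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    band: tuple[float, float] = ADDITIVE_BAND,
    clip: tuple[float, float] = FA_CLIP,
) -> CIResult:
    """Mutually exclusive (Loewe-form) combination index.

    Dx_i = Dm_i·[fa/(1−fa)]^(1/m_i) is the monotherapy dose of drug i that
    alone produces the combination's fraction affected; CI = d1/Dx1 + d2/Dx2.
    CI < 1 synergy, CI = 1 additivity, CI > 1 antagonism; the verdict uses
    the configured additive band.  A combination whose fa sits at a clipping
    boundary is flagged unreliable.
    """
    if d1 < 0 or d2 < 0 or d1 + d2 == 0:
        raise ValidationError("combination doses must be >= 0 with a positive sum")
    fa = float(np.clip(fa_combo, clip[0], clip[1]))
    reliable = clip[0] < fa_combo < clip[1]
    dx1 = _dx(fit1, fa)
    dx2 = _dx(fit2, fa)
    ci = d1 / dx1 + d2 / dx2
    if ci < band[0]:
        verdict = "synergistic"
    elif ci > band[1]:
        verdict = "antagonistic"
    else:
        verdict = "additive"
    return CIResult(
        d1=d1, d2=d2, fa=fa, dx1=dx1, dx2=dx2, ci=float(ci),
        verdict=verdict, reliable=reliable,
    )


def fa_ci_curve(combos: Iterable[CIResult]) -> pd.DataFrame:
    """(Fa, CI) points sorted by Fa, ready for plotting against the CI = 1 line."""
    rows = [
        {"fa": c.fa, "ci": c.ci, "d1": c.d1, "d2": c.d2, "verdict": c.verdict}
        for c in combos
    ]
    if not rows:
        raise ValidationError("need at least one combination point")
    return pd.DataFrame(rows).sort_values("fa", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# signature concordance / discordance ranking
# ---------------------------------------------------------------------------


def _top_k(sig, k: int) -> tuple[list[str], dict[str, int]]:
    genes = list(sig.genes)[:k]
    dirs = {g: int(d) for g, d in zip(genes, np.asarray(sig.directions)[:k])}
    return genes, dirs


def _check_k(k: int, *sigs) -> None:
    for s in sigs:
        n = len(s.genes) if hasattr(s, "genes") else len(s)
        if n == 0:
            raise ValidationError("empty signature")
        if k > n:
            raise ValidationError(f"k={k} exceeds signature length {n}")


def concordance_score(drug, reference, k: int = DEFAULT_TOP_K) -> float:
    """Fraction of the drug's top-k genes matching the reference's top-k in direction."""
    _check_k(k, drug, reference)
    genes, dirs = _top_k(drug, k)
    _, ref_dirs = _top_k(reference, k)
    hits = sum(1 for g in genes if g in ref_dirs and ref_dirs[g] == dirs[g])
    return hits / k


def discordance_score(drug, disease, k: int = DEFAULT_TOP_K) -> float:
    """Fraction of the disease's top-k genes reversed in the drug's top-k.

    A gene counts when it appears in the drug's top-k with the opposite
    direction — the signature-reversal reading of therapeutic benefit.
    """
    _check_k(k, drug, disease)
    dis_genes, dis_dirs = _top_k(disease, k)
    _, drug_dirs = _top_k(drug, k)
    hits = sum(
        1 for g in dis_genes if g in drug_dirs and drug_dirs[g] == -dis_dirs[g]
    )
    return hits / k


def synergy_rank(
    library: DrugSignatureLibrary,
    reference: DrugSignature | None = None,
    disease=None,
    k: int = DEFAULT_TOP_K,
) -> pd.DataFrame:
    """Rank library drugs by (discordance desc, concordance asc, drug id).

    High discordance with the disease signature and low concordance with the
    reference compound mark candidates likely to reverse the disease state
    while adding a mechanism orthogonal to the reference.  ``k`` is clamped
    to the shortest signature in play.
    """
    if not library.drugs:
        raise ValidationError("empty drug library")
    reference = reference or library.reference
    disease = disease if disease is not None else library.disease
    lengths = [len(s.genes) for s in library.drugs.values()]
    lengths += [len(reference.genes), len(list(disease.genes))]
    k_eff = min(k, min(lengths))
    rows = []
    for drug_id, sig in library.drugs.items():
        rows.append(
            {
                "drug": drug_id,
                "concordance": concordance_score(sig, reference, k_eff),
                "discordance": discordance_score(sig, disease, k_eff),
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        by=["discordance", "concordance", "drug"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["k"] = k_eff
    return out
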