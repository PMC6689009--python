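"""Synthetic data generators with planted ground truth.

Every input the pipeline consumes can be simulated here: a two-class patient
cohort whose signature-gene expression is driven by a latent pathway-activation
level, paired control/knockdown expression profiles with planted
inverse-direction responders, kinome peptide-array readouts with planted
dose-responsive kinases, dose-response viability data generated from known
median-effect parameters under Loewe additivity (or planted synergy), and a
ranked drug-signature library with a planted disease-reversing compound.

All randomness flows from a single integer seed through named substreams
(`numpy.random.SeedSequence` spawn keys), so adding a generator never perturbs
the draws of another and identical configurations are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

# fixed substream ids; append only, never renumber
_STREAMS = {
    "cohort_class": 0,
    "cohort_expr": 1,
    "cohort_surv": 2,
    "cohort_covar": 3,
    "kd": 4,
    "kinome": 5,
    "dose": 6,
    "library": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


def _feature_ids(n: int) -> list[str]:
    return [f"F{i:05d}" for i in range(n)]


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Two-class cohort whose signature genes track a latent activation level.

    Expression is on the log2 scale throughout.  ``effect_size`` is the log2
    separation coefficient applied to the latent activation ``a_s`` for every
    planted signature gene; ``median_survival_high``/``low`` are the true
    exponential survival medians (months) of the two classes, defaulting to
    the 8.04 / 57.48 month split observed between pathway-high and -low
    glioma patients.
    """

    n_samples: int = 300
    n_features: int = 5000
    n_signature_genes: int = 100  # per direction
    # explicit planted sets (e.g. to simulate an independent validation cohort
    # sharing the discovery cohort's signature biology); drawn at random if None
    high_genes: tuple[str, ...] | None = None
    low_genes: tuple[str, ...] | None = None
    effect_size: float = 2.0
    activation_sd: float = 1.0
    noise_sd: float = 1.0
    median_survival_high: float = 8.04
    median_survival_low: float = 57.48
    censor_rate: float = 0.2
    anchor: str = "ANCHOR"
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    anchor_noise_sd: float = 0.1
    p_idh_wt_high: float = 0.9
    p_idh_wt_low: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signature_genes * 2 > self.n_features - 1:
            raise ConfigError(
                "2 * n_signature_genes must fit among the non-anchor features"
            )
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.median_survival_high <= 0 or self.median_survival_low <= 0:
            raise ConfigError("survival medians must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise ConfigError("censor_rate must lie in [0, 1)")
        if self.n_samples < 2:
            raise ConfigError("need at least 2 samples")
        if (self.high_genes is None) != (self.low_genes is None):
            raise ConfigError("high_genes and low_genes must be given together")
        if self.high_genes is not None:
            if set(self.high_genes) & set(self.low_genes):
                raise ConfigError("explicit planted sets must be disjoint")
            space = set(_feature_ids(self.n_features - 1))
            unknown = (set(self.high_genes) | set(self.low_genes)) - space
            if unknown:
                raise ConfigError(
                    f"explicit planted genes outside feature space: {sorted(unknown)[:5]}"
                )


@dataclass
class CohortTruth:
    """Planted ground truth for a simulated cohort."""

    class_label: pd.Series  # 'high' / 'low' per sample
    latent_activation: pd.Series
    high_genes: list[str]
    low_genes: list[str]
    anchor: str


def gen_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Simulate a cohort: expression matrix, survival table, planted truth.

    Returns
    -------
    expr : DataFrame, features x samples, log2 scale
    surv : DataFrame indexed by sample with columns time_months, event,
        who_grade, idh, karnofsky, age, group
    truth : CohortTruth
    """
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    rng = _rng(config.seed, "cohort_class")
    n_high = n // 2
    labels = np.array(["high"] * n_high + ["low"] * (n - n_high))
    rng.shuffle(labels)
    sign = np.where(labels == "high", 1.0, -1.0)
    # mirrored Gaussians, magnitude |N(1, sd)| so the sign encodes the class
    activation = sign * np.abs(rng.normal(1.0, config.activation_sd, size=n))

    rng = _rng(config.seed, "cohort_expr")
    regular = _feature_ids(config.n_features - 1)
    features = regular + [config.anchor]
    if config.high_genes is not None:
        high_genes = list(config.high_genes)
        low_genes = list(config.low_genes)
    else:
        k = config.n_signature_genes
        planted = rng.choice(len(regular), size=2 * k, replace=False)
        high_genes = [regular[i] for i in planted[:k]]
        low_genes = [regular[i] for i in planted[k:]]

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=len(features))
    expr = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(len(features), n))
    expr = pd.DataFrame(expr, index=features, columns=samples)
    expr.loc[high_genes] += config.effect_size * activation
    expr.loc[low_genes] -= config.effect_size * activation
    expr.loc[config.anchor] = (
        baseline[-1] + activation + rng.normal(0.0, config.anchor_noise_sd, size=n)
    )
    expr.index.name = "feature"

    rng = _rng(config.seed, "cohort_surv")
    median = np.where(
        labels == "high", config.median_survival_high, config.median_survival_low
    )
    t_event = rng.exponential(median / np.log(2.0), size=n)
    # censoring independent of class: a censor_rate subset gets a uniform
    # censoring time on (0, 3 x larger median]
    censored = rng.random(n) < config.censor_rate
    horizon = 3.0 * max(config.median_survival_high, config.median_survival_low)
    c_time = rng.uniform(0.0, horizon, size=n)
    c_time = np.maximum(c_time, 1e-6)
    time = np.where(censored & (c_time < t_event), c_time, t_event)
    event = (~(censored & (c_time < t_event))).astype(int)

    rng = _rng(config.seed, "cohort_covar")
    is_high = labels == "high"
    grade = np.where(
        is_high,
        rng.choice([3, 4], size=n, p=[0.2, 0.8]),
        rng.choice([2, 3], size=n, p=[0.6, 0.4]),
    )
    idh_p = np.where(is_high, config.p_idh_wt_high, config.p_idh_wt_low)
    idh = np.where(rng.random(n) < idh_p, "WT", "Mut")
    karnofsky = rng.choice([60, 70, 80, 90, 100], size=n)
    age = np.clip(rng.normal(55.0, 12.0, size=n), 18.0, 90.0)

    surv = pd.DataFrame(
        {
            "time_months": time,
            "event": event,
            "who_grade": grade,
            "idh": idh,
            "karnofsky": karnofsky,
            "age": age,
            "group": labels,
        },
        index=pd.Index(samples, name="sample"),
    )
    truth = CohortTruth(
        class_label=pd.Series(labels, index=samples, name="class"),
        latent_activation=pd.Series(activation, index=samples, name="activation"),
        high_genes=high_genes,
        low_genes=low_genes,
        anchor=config.anchor,
    )
    return expr, surv, truth


# ---------------------------------------------------------------------------
# knockdown generator
# ---------------------------------------------------------------------------


@dataclass
class KDConfig:
    """Paired control/knockdown profiles across patient-derived lines.

    ``responders_down`` are genes planted to drop by ``kd_logfc`` upon
    knockdown (the positively co-expressed module in the paired cohort);
    ``responders_up`` rise by the same amount (the negatively co-expressed
    module).  Three lines, each with a non-targeting control and three
    knockdown clones, mirror the triplicate patient-derived culture design
    with its triplet of short-hairpin clones.
    """

    n_lines: int = 3
    n_clones: int = 3  # knockdown clones per line
    n_controls: int = 1  # non-targeting control arrays per line
    n_features: int = 5000
    responders_down: tuple[str, ...] = ()
    responders_up: tuple[str, ...] = ()
    kd_logfc: float = 3.0
    noise_sd: float = 0.2
    anchor: str = "ANCHOR"
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    line_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kd_logfc < 0:
            raise ConfigError("kd_logfc must be >= 0")
        if self.n_lines < 1 or self.n_clones < 1 or self.n_controls < 1:
            raise ConfigError("need at least one line, clone and control")
        features = set(_feature_ids(self.n_features - 1)) | {self.anchor}
        unknown = (set(self.responders_down) | set(self.responders_up)) - features
        if unknown:
            raise ConfigError(f"planted responders outside feature space: {sorted(unknown)[:5]}")
        if set(self.responders_down) & set(self.responders_up):
            raise ConfigError("responder sets must be disjoint")


@dataclass
class KDExperiment:
    """Expression for paired control/knockdown samples plus the design table."""

    expr: pd.DataFrame  # features x samples
    design: pd.DataFrame  # sample, line, condition ('control'/'kd')


def gen_kd(config: KDConfig) -> KDExperiment:
    """Simulate paired control vs knockdown arrays.

    The anchor gene itself is shifted down by ``kd_logfc`` (it is the
    knocked-down transcript); planted responders shift in their configured
    directions; all other genes have zero true shift.
    """
    rng = _rng(config.seed, "kd")
    features = _feature_ids(config.n_features - 1) + [config.anchor]
    idx = pd.Index(features, name="feature")

    delta = pd.Series(0.0, index=idx)
    delta.loc[list(config.responders_down)] = -config.kd_logfc
    delta.loc[list(config.responders_up)] = config.kd_logfc
    delta.loc[config.anchor] = -config.kd_logfc

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=len(features))
    cols, mats, design_rows = [], [], []
    for line in range(1, config.n_lines + 1):
        line_shift = rng.normal(0.0, config.line_sd, size=len(features))
        base_line = baseline + line_shift
        profiles = [
            (
                "control" if config.n_controls == 1 else f"control{c}",
                base_line + rng.normal(0.0, config.noise_sd, size=len(features)),
            )
            for c in range(1, config.n_controls + 1)
        ]
        for clone in range(1, config.n_clones + 1):
            kd = base_line + delta.to_numpy() + rng.normal(
                0.0, config.noise_sd, size=len(features)
            )
            profiles.append((f"kd{clone}", kd))
        for label, vec in profiles:
            name = f"L{line}_{label}"
            cols.append(name)
            mats.append(vec)
            design_rows.append(
                {
                    "sample": name,
                    "line": f"L{line}",
                    "condition": "control" if label.startswith("control") else "kd",
                }
            )

    expr = pd.DataFrame(np.column_stack(mats), index=idx, columns=cols)
    design = pd.DataFrame(design_rows).set_index("sample")
    return KDExperiment(expr=expr, design=design)


# ---------------------------------------------------------------------------
# kinome generator
# ---------------------------------------------------------------------------


@dataclass
class KinomeConfig:
    """Peptide phosphorylation array with planted dose-responsive kinases.

    144 kinases mirror the chip-wide kinome panel.  Peptides of the same
    kinase share a per-condition latent wiggle (``shared_sd``) on top of
    peptide-level noise, making them mutually correlated — the default
    shared/noise variance ratio plants a within-kinase peptide correlation
    of about 0.9; planted kinases gain a linear intensity trend of
    ``effect_slope`` per uM of drug dose.
    """

    n_kinases: int = 144
    peptides_per_kinase: int = 4
    doses: tuple[float, ...] = (0.0, 0.1, 0.5, 1.0, 2.0)  # uM; 0 = DMSO control
    n_reps: int = 2
    planted_up: tuple[str, ...] = ("K001",)
    planted_down: tuple[str, ...] = ("K002",)
    effect_slope: float = 1.5  # intensity units per uM; >> condition noise
    shared_sd: float = 0.3
    noise_sd: float = 0.1  # shared_sd/3 -> within-kinase correlation ~0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.doses) != sorted(set(self.doses)):
            raise ConfigError("doses must be strictly increasing")
        if set(self.planted_up) & set(self.planted_down):
            raise ConfigError("planted kinase sets must be disjoint")
        kin = set(self.kinase_ids())
        unknown = (set(self.planted_up) | set(self.planted_down)) - kin
        if unknown:
            raise ConfigError(f"planted kinases outside panel: {sorted(unknown)}")

    def kinase_ids(self) -> list[str]:
        return [f"K{i + 1:03d}" for i in range(self.n_kinases)]


@dataclass
class KinomeTruth:
    planted_up: tuple[str, ...]
    planted_down: tuple[str, ...]


def gen_kinome(config: KinomeConfig) -> tuple[pd.DataFrame, pd.DataFrame, KinomeTruth]:
    """Simulate a peptide array.

    Returns the peptide x condition intensity matrix, the peptide-to-kinase
    map (two columns, many-to-many capable), and the planted truth.  Condition
    columns are named ``d<dose>_r<rep>`` and the dose is recoverable from the
    returned matrix's column metadata (``matrix.attrs['dose_uM']``).
    """
    rng = _rng(config.seed, "kinome")
    kinases = config.kinase_ids()
    doses = np.repeat(config.doses, config.n_reps)
    cond = [
        f"d{d:g}_r{r + 1}"
        for d in config.doses
        for r in range(config.n_reps)
    ]

    rows, pep_ids, map_rows = [], [], []
    for kin in kinases:
        slope = 0.0
        if kin in config.planted_up:
            slope = config.effect_slope
        elif kin in config.planted_down:
            slope = -config.effect_slope
        shared = rng.normal(0.0, config.shared_sd, size=len(cond))
        # planted kinases start from the array's mid intensity so their dose
        # trend is observable in rank space (not censored at the array's
        # ceiling or floor); null kinases span the full baseline range
        base_kin = 7.0 if slope != 0.0 or kin in config.planted_up + config.planted_down else rng.uniform(4.0, 10.0)
        for p in range(config.peptides_per_kinase):
            pid = f"{kin}_p{p + 1}"
            pep_ids.append(pid)
            map_rows.append({"peptide": pid, "kinase": kin})
            level = (
                base_kin
                + slope * doses
                + shared
                + rng.normal(0.0, config.noise_sd, size=len(cond))
            )
            rows.append(np.maximum(level, 0.0))

    matrix = pd.DataFrame(rows, index=pd.Index(pep_ids, name="peptide"), columns=cond)
    matrix.attrs["dose_uM"] = pd.Series(doses, index=cond, name="dose_uM")
    kmap = pd.DataFrame(map_rows)
    return matrix, kmap, KinomeTruth(config.planted_up, config.planted_down)


# ---------------------------------------------------------------------------
# dose-response generator
# ---------------------------------------------------------------------------


def _default_doses() -> tuple[float, ...]:
    # 10-point titration spanning 1e-4 .. 1e2 uM
    return tuple(np.logspace(-4, 2, 10))


@dataclass
class DoseConfig:
    """Median-effect monotherapy curves plus Loewe combination points.

    Each drug is parameterised by its Hill-type slope ``m`` and median-effect
    dose ``Dm`` (uM).  Combination points are constructed so that the Loewe
    interaction sum equals ``synergy_factor`` (psi): psi = 1 plants exact
    additivity, psi < 1 plants synergy.
    """

    drugs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"drugA": (2.0, 1.0), "drugB": (1.5, 0.5)}
    )
    doses: tuple[float, ...] = field(default_factory=_default_doses)
    # constant-ratio combination design sampling the mid-fa region where the
    # combination index is well conditioned
    combo_fractions: tuple[float, ...] = (
        0.30, 0.35, 0.40, 0.45, 0.50, 0.55, 0.60, 0.65, 0.70,
    )
    synergy_factor: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (m, dm) in self.drugs.items():
            if m <= 0 or dm <= 0:
                raise ConfigError(f"drug {name}: m and Dm must be > 0")
        if self.synergy_factor <= 0:
            raise ConfigError("synergy_factor must be > 0")
        if any(d <= 0 for d in self.doses):
            raise ConfigError("doses must be positive")


@dataclass
class DoseResponseSet:
    """Monotherapy curves and combination points with generation truth."""

    mono: pd.DataFrame  # drug, dose_uM, fa
    combos: pd.DataFrame  # d1_uM, d2_uM, fa
    params: dict[str, tuple[float, float]]  # drug -> (m, Dm)
    synergy_factor: float


def _median_effect_fa(dose: np.ndarray, m: float, dm: float) -> np.ndarray:
    return 1.0 / (1.0 + (dm / dose) ** m)


def _loewe_fa(d1: float, d2: float, p1, p2, psi: float) -> float:
    """Fraction affected at which d1/Dx1 + d2/Dx2 equals psi."""
    from scipy.optimize import brentq

    m1, dm1 = p1
    m2, dm2 = p2

    def loewe_sum(fa: float) -> float:
        ratio = fa / (1.0 - fa)
        return d1 / (dm1 * ratio ** (1.0 / m1)) + d2 / (dm2 * ratio ** (1.0 / m2)) - psi

    return brentq(loewe_sum, 1e-12, 1.0 - 1e-12)


def gen_dose_response(config: DoseConfig) -> DoseResponseSet:
    """Simulate monotherapy titrations and Loewe-constructed combinations.

    Combination doses pair ``f * Dm`` of the first two configured drugs for
    each fraction ``f``; the combination fa is the root of the Loewe sum at
    the configured synergy factor, so a noiseless run has a known true
    combination index equal to ``synergy_factor`` at every point.
    """
    rng = _rng(config.seed, "dose")
    doses = np.asarray(config.doses, dtype=float)

    mono_rows = []
    for name, (m, dm) in config.drugs.items():
        fa = _median_effect_fa(doses, m, dm)
        fa = fa + rng.normal(0.0, config.noise_sd, size=fa.shape)
        fa = np.clip(fa, 1e-6, 1.0 - 1e-6)
        for d, f in zip(doses, fa):
            mono_rows.append({"drug": name, "dose_uM": d, "fa": f})
    mono = pd.DataFrame(mono_rows)

    names = list(config.drugs)
    combo_rows = []
    if len(names) >= 2:
        (m1, dm1), (m2, dm2) = config.drugs[names[0]], config.drugs[names[1]]
        for f in config.combo_fractions:
            d1, d2 = f * dm1, f * dm2
            fa = _loewe_fa(d1, d2, (m1, dm1), (m2, dm2), config.synergy_factor)
            fa = float(np.clip(fa + rng.normal(0.0, config.noise_sd), 1e-6, 1 - 1e-6))
            combo_rows.append({"d1_uM": d1, "d2_uM": d2, "fa": fa})
    combos = pd.DataFrame(combo_rows, columns=["d1_uM", "d2_uM", "fa"])

    return DoseResponseSet(
        mono=mono,
        combos=combos,
        params=dict(config.drugs),
        synergy_factor=config.synergy_factor,
    )


# ---------------------------------------------------------------------------
# drug-signature library generator
# ---------------------------------------------------------------------------


@dataclass
class DrugSignature:
    """A drug's transcriptomic signature: ranked genes with ±1 directions."""

    drug_id: str
    genes: list[str]  # ranked, most-perturbed first
    directions: np.ndarray  # +1 up, -1 down

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ConfigError(f"{self.drug_id}: duplicate genes in signature")
        self.directions = np.asarray(self.directions, dtype=int)
        if len(self.directions) != len(self.genes):
            raise ConfigError(f"{self.drug_id}: genes/directions length mismatch")
        if not np.isin(self.directions, (-1, 1)).all():
            raise ConfigError(f"{self.drug_id}: directions must be ±1")


@dataclass
class DrugSignatureLibrary:
    """A library of ranked drug signatures plus the reference and disease context.

    Contains two constructed entries: ``planted_reversal`` (the disease
    signature with every direction flipped — a perfect reverser) and
    ``planted_refcopy`` (identical to the reference compound).
    """

    drugs: dict[str, DrugSignature]
    reference: DrugSignature
    disease: DrugSignature


def gen_signature_library(
    n_drugs: int,
    n_genes: int,
    seed: int = 0,
    sig_len: int | None = None,
    disease: DrugSignature | None = None,
    reference: DrugSignature | None = None,
) -> DrugSignatureLibrary:
    """Generate ranked signed drug signatures over a shared gene universe."""
    if n_drugs <= 0 or n_genes <= 0:
        raise ConfigError("n_drugs and n_genes must be > 0")
    rng = _rng(seed, "library")
    universe = [f"G{i:05d}" for i in range(n_genes)]
    sig_len = sig_len or max(1, min(250, n_genes // 2))

    def random_sig(name: str) -> DrugSignature:
        genes = list(rng.choice(universe, size=sig_len, replace=False))
        dirs = rng.choice([-1, 1], size=sig_len)
        return DrugSignature(name, genes, dirs)

    if disease is None:
        disease = random_sig("disease")
    if reference is None:
        reference = random_sig("reference")

    drugs = {f"drug{i:04d}": random_sig(f"drug{i:04d}") for i in range(n_drugs)}
    drugs["planted_reversal"] = DrugSignature(
        "planted_reversal", list(disease.genes), -np.asarray(disease.directions)
    )
    drugs["planted_refcopy"] = DrugSignature(
        "planted_refcopy", list(reference.genes), np.asarray(reference.directions)
    )
    return DrugSignatureLibrary(drugs=drugs, reference=reference, disease=disease)
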