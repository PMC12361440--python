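"""Synthetic multiomics study generator with planted, recoverable structure.

Every downstream stage of the pipeline is exercised against cohorts produced
here, so the generator plants four kinds of ground truth:

* gestational-age (GA) regulation: selected analytes receive a linear GA term
  on their layer's link scale (identity for abundance layers, log for counts
  layers), restricted to one fetal sex or shared by both;
* cross-layer correlation communities: a per-sample latent factor is added to
  the member analytes of a community, only for samples of the community's
  condition; the designated hub carries the largest loading, which makes it
  the most central node of the recovered subnetwork;
* a differential-abundance signature: a fixed log2 fold-change added (on the
  log scale) to a small analyte set in one condition, nested inside a planted
  community;
* a compositional shift: one cell type's centered log-ratio mean moved by a
  planted amount in one condition.

Counts layers are rounded exponentiated Gaussians: Spearman statistics are
rank-based, so the marginal family is immaterial and the log-normal form keeps
the latent-factor correlation structure intact through the exponential.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    CONDITIONS,
    DEFAULT_GROUP_SIZES,
    SEXES,
    OmicsLayer,
    qualify,
    validate_cohort,
)

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# ground-truth specification
# ---------------------------------------------------------------------------

@dataclass
class GaEffect:
    """A planted linear GA effect on one analyte's link scale."""

    layer: str
    analyte: str
    sex: str  # "female", "male" or "both"
    slope: float

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male", "both"):
            raise ValueError(f"GA effect sex must be female/male/both, got {self.sex!r}")


@dataclass
class CommunitySpec:
    """A planted cross-layer correlation community.

    ``members`` are (layer, analyte) pairs; the ``hub`` must be a member and
    receives ``hub_loading`` (> ``loading``) on the shared latent factor.
    """

    condition: str
    members: list[tuple[str, str]]
    hub: tuple[str, str]
    loading: float
    hub_loading: float | None = None
    #: alternate the sign of member loadings (hub stays positive), producing
    #: both positively and negatively correlated member pairs as in real
    #: correlation networks; |rho| and edge recovery are unaffected
    mixed_signs: bool = False

    def __post_init__(self) -> None:
        self.members = [tuple(m) for m in self.members]
        self.hub = tuple(self.hub)
        if self.hub not in self.members:
            raise ValueError("community hub must be one of its members")
        if self.hub_loading is None:
            self.hub_loading = self.loading

    @property
    def member_nodes(self) -> list[str]:
        return [qualify(layer, analyte) for layer, analyte in self.members]

    @property
    def hub_node(self) -> str:
        return qualify(*self.hub)


@dataclass
class SignatureSpec:
    """A planted fold-change signature in one condition (log2 scale)."""

    condition: str
    members: list[tuple[str, str]]
    log2fc: float

    def __post_init__(self) -> None:
        self.members = [tuple(m) for m in self.members]

    @property
    def member_nodes(self) -> list[str]:
        return [qualify(layer, analyte) for layer, analyte in self.members]


@dataclass
class CompositionShift:
    """A planted clr-scale mean shift for one cell type in one condition."""

    condition: str
    cell_type: str
    shift: float


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream recovery checks."""

    ga_effects: list[GaEffect] = field(default_factory=list)
    communities: list[CommunitySpec] = field(default_factory=list)
    signature: SignatureSpec | None = None
    composition_shift: CompositionShift | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LayerSpec:
    """Shape and marginal parameters of one generated layer."""

    name: str
    kind: str
    n_analytes: int
    baseline_mean: float
    baseline_sd: float = 1.0
    missing_rate: float = 0.0
    high_missing_frac: float = 0.0  # fraction of analytes with ~35% missingness


def default_layer_specs(scale: float = 1.0) -> list[LayerSpec]:
    """Layer sizes matching the study's post-filter feature counts.

    ``scale`` < 1 shrinks every layer proportionally (minimum 5 analytes) for
    quicker runs; the histopathology layer keeps its 13 features.
    """

    def n(count: int) -> int:
        return max(5, int(round(count * scale)))

    return [
        LayerSpec("metabolites", "abundance", n(865), baseline_mean=10.0,
                  missing_rate=0.03, high_missing_frac=0.02),
        LayerSpec("proteins", "abundance", n(343), baseline_mean=5.0,
                  missing_rate=0.02, high_missing_frac=0.02),
        LayerSpec("mirna", "counts", n(448), baseline_mean=6.0),
        LayerSpec("mrna", "counts", n(9582), baseline_mean=7.5),
        LayerSpec("histopath", "abundance", 13, baseline_mean=1.0),
    ]


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

# Per-condition covariate laws. GA at delivery is pushed preterm for PTD and
# FGR+HDP; spontaneous-labor rates reflect that PTD is spontaneous by
# definition while PE / FGR+HDP pregnancies are mostly induced or unlabored.
_GA_PARAMS = {  # (mean, sd, low, high) in weeks
    "Control": (39.3, 1.1, 37.0, 42.0),
    "FGR": (36.5, 2.6, 26.0, 41.9),
    "FGR+HDP": (33.0, 3.0, 24.0, 39.0),
    "PE": (35.5, 2.8, 24.0, 41.9),
    "PTD": (33.5, 2.5, 23.0, 36.9),
}

_SPONTANEOUS_LABOR = {
    "Control": 0.80,
    "FGR": 0.45,
    "FGR+HDP": 0.25,
    "PE": 0.25,
    "PTD": 1.00,
}

_SMOKING_RATE = 0.14
_DRUG_RATE = 0.14
_BMI_LOG_MEAN = math.log(26.0)
_BMI_LOG_SD = 0.22


def generate_cohort(
    group_sizes: dict[str, int] | None = None,
    sex_balance: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a cohort table with per-condition covariate distributions.

    Parameters
    ----------
    group_sizes
        Mapping condition -> number of samples; defaults to the study's
        113/36/30/71/71 split.
    sex_balance
        Probability that a fetus is female.
    seed
        Seed for the generator; identical seeds give identical tables.
    """
    if group_sizes is None:
        group_sizes = dict(DEFAULT_GROUP_SIZES)
    unknown = set(group_sizes) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown condition name(s) {sorted(unknown)}; expected {CONDITIONS}")
    if any(n <= 0 for n in group_sizes.values()):
        raise ValueError("all group sizes must be positive")
    if not 0.0 < sex_balance < 1.0:
        raise ValueError("sex_balance must lie strictly between 0 and 1")

    rng = np.random.default_rng(seed)
    rows = []
    # iterate in canonical condition order for determinism
    for condition in CONDITIONS:
        if condition not in group_sizes:
            continue
        n = int(group_sizes[condition])
        mean, sd, low, high = _GA_PARAMS[condition]
        ga = np.clip(rng.normal(mean, sd, size=n), low, high)
        bmi = np.clip(np.exp(rng.normal(_BMI_LOG_MEAN, _BMI_LOG_SD, size=n)), 15.0, 60.0)
        sex = np.where(rng.random(n) < sex_balance, "female", "male")
        labor = (rng.random(n) < _SPONTANEOUS_LABOR[condition]).astype(int)
        smoking = (rng.random(n) < _SMOKING_RATE).astype(int)
        drug = (rng.random(n) < _DRUG_RATE).astype(int)
        for i in range(n):
            rows.append(
                dict(
                    condition=condition,
                    fetal_sex=sex[i],
                    ga_weeks=float(ga[i]),
                    bmi=float(bmi[i]),
                    labor_init=int(labor[i]),
                    smoking=int(smoking[i]),
                    drug_use=int(drug[i]),
                )
            )
    cohort = pd.DataFrame(rows)
    cohort.index = pd.Index([f"S{i:04d}" for i in range(1, len(cohort) + 1)], name="sample_id")
    validate_cohort(cohort)
    return cohort


# ---------------------------------------------------------------------------
# omics layers
# ---------------------------------------------------------------------------

def loading_for_correlation(target_rho: float, noise_sd: float) -> float:
    """Latent-factor loading giving pairwise member correlation ``target_rho``.

    Under the single-factor model value = loading * f + noise the correlation
    between two members with equal loading l is l^2 / (l^2 + sd^2); inverting
    gives l = sd * sqrt(rho / (1 - rho)).
    """
    if not 0.0 < target_rho < 1.0:
        raise ValueError("target_rho must lie strictly between 0 and 1")
    return noise_sd * math.sqrt(target_rho / (1.0 - target_rho))


def _validate_truth(truth: GroundTruth, specs: dict[str, LayerSpec]) -> None:
    def check_member(layer: str, analyte: str, what: str) -> None:
        if layer not in specs:
            raise ValueError(f"{what} references unknown layer {layer!r}")
        idx = int(analyte.split("_")[-1]) if analyte.split("_")[-1].isdigit() else None
        # analyte ids are generated as <layer>_<k>; anything else must be checked later
        if idx is not None and not 0 <= idx < specs[layer].n_analytes:
            raise ValueError(f"{what} references analyte {analyte!r} outside layer {layer!r}")

    for eff in truth.ga_effects:
        check_member(eff.layer, eff.analyte, "GA effect")
    for comm in truth.communities:
        if comm.condition not in CONDITIONS:
            raise ValueError(f"community condition {comm.condition!r} unknown")
        for layer, analyte in comm.members:
            check_member(layer, analyte, f"community ({comm.condition})")
    if truth.signature is not None:
        sig = truth.signature
        if sig.condition not in CONDITIONS:
            raise ValueError(f"signature condition {sig.condition!r} unknown")
        sig_set = set(sig.members)
        if not any(sig_set <= set(c.members) for c in truth.communities):
            raise ValueError("signature analytes must be a subset of one planted community")
        for layer, _ in sig.members:
            if specs[layer].kind != "counts":
                raise ValueError(
                    "signature analytes must live in a counts layer, where the "
                    "planted log2 fold-change is exact on the ratio of means"
                )


def analyte_id(layer: str, k: int) -> str:
    return f"{layer}_{k:05d}"


def generate_layers(
    cohort: pd.DataFrame,
    truth: GroundTruth | None = None,
    layer_specs: list[LayerSpec] | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
    ga_center: float = 37.0,
) -> tuple[list[OmicsLayer], GroundTruth]:
    """Generate all omics layers with the planted structure of ``truth``.

    Each analyte's signal on its link scale is::

        s = baseline + slope * (GA - ga_center) * [planted, matching sex]
            + signed_loading * factor * [community member, matching condition]
            + log2fc * ln(2) * [signature member, matching condition]
            + Normal(0, noise_sd)

    Abundance layers report ``s`` directly (Olink/Metabolon-style normalized
    values, which may be negative); counts layers report ``round(exp(s))``.
    Centering GA at ``ga_center`` (term weeks) makes ``baseline`` the level
    at a typical term delivery, so a sex-specific GA slope does not also
    plant a sex main effect at the cohort's usual gestational age; the
    regression slope of a planted analyte on GA is still exactly ``slope``.
    """
    validate_cohort(cohort)
    if layer_specs is None:
        layer_specs = default_layer_specs()
    if truth is None:
        truth = GroundTruth()
    specs = {s.name: s for s in layer_specs}
    _validate_truth(truth, specs)

    rng = np.random.default_rng(seed)
    n = len(cohort)
    ga = cohort["ga_weeks"].to_numpy(dtype=float)
    sex = cohort["fetal_sex"].to_numpy()
    condition = cohort["condition"].to_numpy()

    # one latent factor per planted community, shared by all its members
    factors = [rng.standard_normal(n) for _ in truth.communities]

    layers: list[OmicsLayer] = []
    for spec in layer_specs:
        m = spec.n_analytes
        cols = [analyte_id(spec.name, k) for k in range(m)]
        baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=m)
        col_index_pre = {c: j for j, c in enumerate(cols)}
        if spec.kind == "counts":
            # planted analytes must survive the uniqueness filter: low-count
            # analytes round to few distinct values, so keep planted baselines
            # at or above the layer's typical expression
            planted_here = {a for e in truth.ga_effects if e.layer == spec.name for a in [e.analyte]}
            for comm in truth.communities:
                planted_here.update(a for l, a in comm.members if l == spec.name)
            if truth.signature is not None:
                planted_here.update(a for l, a in truth.signature.members if l == spec.name)
            for a in planted_here:
                j = col_index_pre[a]
                baseline[j] = max(baseline[j], spec.baseline_mean)
        signal = np.broadcast_to(baseline, (n, m)).copy()
        if noise_sd > 0:
            signal += rng.normal(0.0, noise_sd, size=(n, m))
        col_index = {c: j for j, c in enumerate(cols)}

        for eff in truth.ga_effects:
            if eff.layer != spec.name:
                continue
            j = col_index[eff.analyte]
            mask = np.ones(n, bool) if eff.sex == "both" else (sex == eff.sex)
            signal[mask, j] += eff.slope * (ga[mask] - ga_center)

        for comm, factor in zip(truth.communities, factors):
            in_cond = condition == comm.condition
            for k, (layer_name, analyte) in enumerate(comm.members):
                if layer_name != spec.name:
                    continue
                j = col_index[analyte]
                if (layer_name, analyte) == comm.hub:
                    loading = comm.hub_loading
                else:
                    loading = comm.loading
                    if comm.mixed_signs and k % 2 == 1:
                        loading = -loading
                signal[in_cond, j] += loading * factor[in_cond]

        if truth.signature is not None:
            in_cond = condition == truth.signature.condition
            for layer_name, analyte in truth.signature.members:
                if layer_name != spec.name:
                    continue
                signal[in_cond, col_index[analyte]] += truth.signature.log2fc * LN2

        if spec.kind == "counts":
            values = np.round(np.exp(signal))
        else:
            values = signal
        df = pd.DataFrame(values, index=cohort.index, columns=cols)

        if spec.missing_rate > 0 or spec.high_missing_frac > 0:
            miss = rng.random((n, m)) < spec.missing_rate
            if spec.high_missing_frac > 0:
                n_high = int(round(spec.high_missing_frac * m))
                high_cols = rng.choice(m, size=n_high, replace=False)
                miss[:, high_cols] |= rng.random((n, n_high)) < 0.35
            # never knock out planted analytes: ground truth must survive filtering
            planted = {a for e in truth.ga_effects if e.layer == spec.name for a in [e.analyte]}
            for comm in truth.communities:
                planted.update(a for l, a in comm.members if l == spec.name)
            if truth.signature is not None:
                planted.update(a for l, a in truth.signature.members if l == spec.name)
            for a in planted:
                miss[:, col_index[a]] = False
            df = df.mask(pd.DataFrame(miss, index=df.index, columns=df.columns))

        layers.append(OmicsLayer(spec.name, df, spec.kind))

    return layers, truth


# ---------------------------------------------------------------------------
# cell-type fractions
# ---------------------------------------------------------------------------

DEFAULT_CELL_ALPHA = {
    "syncytiotrophoblast": 10.0,
    "cytotrophoblast": 6.0,
    "extravillous_trophoblast": 2.0,
    "hofbauer": 3.0,
    "endothelial": 3.0,
    "stromal": 4.0,
    "monocyte": 1.5,
    "t_cell": 1.0,
    "b_cell": 0.5,
    "nk_cell": 0.8,
}


def generate_fractions(
    cohort: pd.DataFrame,
    base_alpha: dict[str, float] | None = None,
    shift: CompositionShift | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Dirichlet cell-type fractions with an optional planted clr shift.

    The shift is planted exactly on the clr scale: sampled rows of the target
    condition are clr-transformed, moved along the zero-sum direction
    ``delta * K/(K-1) * (e_t - 1/K)`` (so the target coordinate moves by
    exactly ``delta``), and mapped back to the simplex via softmax.
    """
    validate_cohort(cohort)
    if base_alpha is None:
        base_alpha = dict(DEFAULT_CELL_ALPHA)
    if any(a <= 0 for a in base_alpha.values()):
        raise ValueError("base_alpha concentrations must all be positive")
    cell_types = list(base_alpha)
    if shift is not None and shift.cell_type not in base_alpha:
        raise ValueError(
            f"composition shift names unknown cell type {shift.cell_type!r}"
        )

    rng = np.random.default_rng(seed)
    alpha = np.array([base_alpha[c] for c in cell_types], dtype=float)
    n, k = len(cohort), len(cell_types)
    gammas = rng.gamma(shape=np.broadcast_to(alpha, (n, k)))
    fractions = gammas / gammas.sum(axis=1, keepdims=True)

    if shift is not None and shift.shift != 0.0:
        in_cond = (cohort["condition"] == shift.condition).to_numpy()
        t = cell_types.index(shift.cell_type)
        x = fractions[in_cond]
        logx = np.log(x)
        clr = logx - logx.mean(axis=1, keepdims=True)
        direction = np.full(k, -shift.shift / (k - 1))
        direction[t] = shift.shift
        shifted = clr + direction
        expv = np.exp(shifted)
        fractions[in_cond] = expv / expv.sum(axis=1, keepdims=True)

    return pd.DataFrame(fractions, index=cohort.index, columns=cell_types)


# ---------------------------------------------------------------------------
# cohort balance table
# ---------------------------------------------------------------------------

_CONTINUOUS_VARS = ("ga_weeks", "bmi")
_BINARY_VARS = ("labor_init", "smoking", "drug_use")
_CATEGORICAL_VARS = ("condition",)


def describe_cohort(cohort: pd.DataFrame, group_var: str = "fetal_sex") -> pd.DataFrame:
    """Covariate balance between the two levels of ``group_var``.

    Continuous variables get a two-tailed Student t-test, binary variables a
    Fisher exact test, categorical variables a chi-square test. Categorical
    levels with a zero count in either group are dropped before testing; when
    fewer than two levels survive, the test is reported degenerate (p = NaN).
    """
    levels = sorted(cohort[group_var].unique())
    if len(levels) != 2:
        raise ValueError(f"group_var {group_var!r} must have exactly 2 levels, found {levels}")
    a = cohort[cohort[group_var] == levels[0]]
    b = cohort[cohort[group_var] == levels[1]]

    rows = []

    def add(variable, test, statistic, p, note=""):
        rows.append(dict(variable=variable, test=test, statistic=statistic, p_value=p, note=note))

    for var in _CONTINUOUS_VARS:
        if var == group_var:
            continue
        stat, p = stats.ttest_ind(a[var], b[var])
        add(var, "t-test", float(stat), float(p))

    for var in _BINARY_VARS:
        if var == group_var:
            continue
        table, dropped = _zero_drop_table(a[var], b[var])
        if table.shape[0] < 2:
            add(var, "fisher", np.nan, np.nan, "degenerate after zero-category drop")
            continue
        odds, p = stats.fisher_exact(table)
        note = f"dropped levels: {dropped}" if dropped else ""
        add(var, "fisher", float(odds), float(p), note)

    for var in _CATEGORICAL_VARS:
        if var == group_var:
            continue
        table, dropped = _zero_drop_table(a[var], b[var])
        if table.shape[0] < 2:
            add(var, "chi-square", np.nan, np.nan, "degenerate after zero-category drop")
            continue
        chi2, p, _, _ = stats.chi2_contingency(table)
        note = f"dropped levels: {dropped}" if dropped else ""
        add(var, "chi-square", float(chi2), float(p), note)

    return pd.DataFrame(rows)


def _zero_drop_table(a: pd.Series, b: pd.Series) -> tuple[np.ndarray, list]:
    """Levels-by-group count table with zero-count levels removed."""
    levels = sorted(set(a.unique()) | set(b.unique()))
    counts = np.array(
        [[(a == lev).sum(), (b == lev).sum()] for lev in levels], dtype=int
    )
    keep = (counts > 0).all(axis=1)
    dropped = [lev for lev, k in zip(levels, keep) if not k]
    return counts[keep], dropped


# ---------------------------------------------------------------------------
# default planted study
# ---------------------------------------------------------------------------

def default_ground_truth(
    layer_specs: list[LayerSpec],
    n_community: int = 100,
    n_signature: int = 12,
    ga_slope: float = 0.05,
    n_ga_per_group: int = 20,
    loading: float = 1.2,
    hub_loading: float = 2.5,
    signature_log2fc: float = 1.5,
    disease_condition: str = "FGR+HDP",
    composition_shift: float = 1.0,
    shifted_cell_type: str = "extravillous_trophoblast",
) -> GroundTruth:
    """Ground truth mirroring the study design at any layer scale.

    Plants one 100-analyte control community (hub in the miRNA layer), a
    disrupted disease community sharing a subset of those analytes but with a
    different miRNA hub, a 12-mRNA fold-change signature nested in the control
    community, sex-specific and shared GA-regulated analytes in the abundance
    layers, and an extravillous-trophoblast clr shift in the disease condition.
    """
    specs = {s.name: s for s in layer_specs}
    for needed in ("metabolites", "proteins", "mirna", "mrna"):
        if needed not in specs:
            raise ValueError(f"default ground truth requires a {needed!r} layer")

    # control community membership spread across the molecular layers; the
    # hub is the sole miRNA member, so it alone correlates with every other
    # member cross-layer and is strictly the most central node once the
    # community is recovered
    quota = {"metabolites": 0.25, "proteins": 0.20}
    # the disease hub (second miRNA) is an ordinary member of the control
    # community — its rise to hub in the disease condition is the planted
    # rewiring the tracking stage must detect
    members: list[tuple[str, str]] = [
        ("mirna", analyte_id("mirna", 0)),
        ("mirna", analyte_id("mirna", 1)),
    ]
    counts = {l: max(2, int(round(q * n_community))) for l, q in quota.items()}
    counts["mrna"] = max(n_signature + 2, n_community - 2 - sum(counts.values()))
    for layer_name, c in counts.items():
        if c > specs[layer_name].n_analytes:
            raise ValueError(f"layer {layer_name!r} too small for the default community")
        members.extend((layer_name, analyte_id(layer_name, k)) for k in range(c))
    control_hub = ("mirna", analyte_id("mirna", 0))

    # disease community: a disrupted remnant of the control community — a new
    # sole-miRNA hub plus abundance-layer members shared with the control
    # community. Members are drawn from the abundance layers only: a latent
    # factor on a counts layer's log scale would inflate that analyte's mean
    # multiplicatively and confound the planted fold-change signature.
    sig_members = [("mrna", analyte_id("mrna", k)) for k in range(n_signature)]
    disease_members = [("mirna", analyte_id("mirna", 1))] + [
        ("metabolites", analyte_id("metabolites", k)) for k in range(3)
    ] + [("proteins", analyte_id("proteins", k)) for k in range(3)]
    disease_hub = ("mirna", analyte_id("mirna", 1))

    # GA-regulated analytes in the abundance layers, avoiding community members
    member_set = set(members)
    ga_effects: list[GaEffect] = []
    pool = [
        ("metabolites", analyte_id("metabolites", k))
        for k in range(specs["metabolites"].n_analytes)
        if ("metabolites", analyte_id("metabolites", k)) not in member_set
    ] + [
        ("proteins", analyte_id("proteins", k))
        for k in range(specs["proteins"].n_analytes)
        if ("proteins", analyte_id("proteins", k)) not in member_set
    ]
    need = 3 * n_ga_per_group
    if len(pool) < need:
        raise ValueError("abundance layers too small for the requested GA-regulated sets")
    for i, sex in enumerate(["female", "male", "both"]):
        for layer_name, analyte in pool[i * n_ga_per_group:(i + 1) * n_ga_per_group]:
            ga_effects.append(GaEffect(layer_name, analyte, sex, ga_slope))

    return GroundTruth(
        ga_effects=ga_effects,
        communities=[
            CommunitySpec("Control", members, control_hub, loading, hub_loading,
                          mixed_signs=True),
            CommunitySpec(disease_condition, disease_members, disease_hub, loading,
                          hub_loading, mixed_signs=True),
        ],
        signature=SignatureSpec(disease_condition, sig_members, signature_log2fc),
        composition_shift=CompositionShift(disease_condition, shifted_cell_type, composition_shift),
    )
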