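"""Synthetic datasets with known ground truth for the four study designs.

Counts are negative-binomial (Var = mu + phi mu^2) with gene-wise dispersions
drawn from a log-normal, log-normal library sizes, and a log2-scale linear
mean structure: a baseline log2-cpm per gene, planted disease log2
fold-changes (per-timepoint profiles in the longitudinal design), planted
co-expression modules driven by latent per-sample factors (shared across two
tissues with attenuation rho per module), per-subject random intercepts, and
treatment / cohort effects.  Every generator is a pure function of
(design, seed) and records its ground truth before noise is added, so each
downstream stage has a parameter-recovery test surface.

Scenario factories (:func:`momus_design` etc.) encode the default study
conditions: four mouse groups with week-30 muscle biopsies, five blood
timepoints for 5+5+5+5 mice, a three-arm antisense treatment experiment, and
a human cohort of 18 healthy controls and 39 patients (32 on corticosteroids)
with 24 body measurements and 12 physical tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import CountMatrix


class DesignError(ValueError):
    """Raised when a simulation design violates its invariants."""


@dataclass(frozen=True)
class ModuleSpec:
    sizes: tuple = (60, 60, 60, 60, 60)
    loading: float = 0.8               # log2-scale factor loading per member gene
    cross_rho: tuple = (0.8, 0.8, 0.6, 0.0, -0.6)  # blood-muscle factor coupling

    def __post_init__(self):
        if len(self.cross_rho) != len(self.sizes):
            raise DesignError("cross_rho must have one entry per module")
        if any(abs(r) > 1 for r in self.cross_rho):
            raise DesignError("cross-tissue rho must lie in [-1, 1]")


@dataclass(frozen=True)
class TreatmentSpec:
    arms: tuple = (("saline", 4), ("PMO", 5), ("PS49", 5))
    kappa: dict = field(default_factory=lambda: {"PMO": 0.3, "PS49": 0.05})
    side_effect_arm: str = "PS49"
    n_side_effect: int = 30
    side_effect_logfc: float = 2.0

    def __post_init__(self):
        if any(not 0 <= k <= 1 for k in self.kappa.values()):
            raise DesignError("restoration fraction kappa must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    n_healthy: int = 18
    n_case: int = 39
    n_steroid: int = 32
    age_range: tuple = (4.0, 18.0)
    healthy_age_range: tuple = (5.0, 13.0)
    age_group_slope: float = -0.1      # log2FC per year, applied toward baseline
    n_steroid_genes: int = 40
    steroid_logfc: float = -0.75       # opposite in sign to the group effect
    body_block_size: int = 24
    body_pc1_target: float = 0.70
    physical_block_size: int = 12
    physical_pc1_target: float = 0.78
    anchor_gene_slope: float = 0.3     # log2 units per sd of the physical factor

    def __post_init__(self):
        for frac in (self.body_pc1_target, self.physical_pc1_target):
            if not 0 < frac < 1:
                raise DesignError("target PC variance fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SimDesign:
    n_genes: int = 2000
    group_sizes: tuple = (("WT", 8), ("mdx", 8))
    timepoints: tuple = (6, 12, 18, 24, 30)
    baseline_mean: float = 5.0         # log2-cpm
    baseline_sd: float = 1.5
    phi_meanlog: float = np.log(0.1)   # gene-wise NB dispersion ~ log-normal
    phi_sdlog: float = 0.5
    lib_meanlog: float = np.log(2e6)
    lib_sdlog: float = 0.3
    n_de: int = 150
    de_logfc: float = 2.0              # cross-sectional effect size
    de_profile: tuple = (2.0, 1.0, 1.0, 0.3, 0.2)   # longitudinal per-week logFC
    sigma_b: float = 0.5               # subject random-intercept sd (log2)
    modules: ModuleSpec | None = field(default_factory=ModuleSpec)
    treatment: TreatmentSpec = field(default_factory=TreatmentSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    seed: int = 13154

    def __post_init__(self):
        if self.sigma_b < 0:
            raise DesignError("sigma_b must be non-negative")
        msize = sum(self.modules.sizes) if self.modules else 0
        extra_side = max(0, self.treatment.n_side_effect - self.n_de)
        if self.n_de + extra_side + msize > self.n_genes:
            raise DesignError("gene sets exceed the number of genes (overlap)")

    # deterministic gene-index layout: the side-effect set overlaps the head
    # of the disease set (drug side effects hit disease-dysregulated genes,
    # e.g. the interferon response), module sets are disjoint from both
    @property
    def de_idx(self):
        return np.arange(self.n_de)

    @property
    def side_effect_idx(self):
        n_side = self.treatment.n_side_effect
        if n_side <= self.n_de:
            return np.arange(n_side)
        return np.concatenate([np.arange(self.n_de),
                               np.arange(self.n_de, n_side)])

    @property
    def module_idx(self):
        if not self.modules:
            return []
        start = self.n_de + max(0, self.treatment.n_side_effect - self.n_de)
        out = []
        for size in self.modules.sizes:
            out.append(np.arange(start, start + size))
            start += size
        return out

    @property
    def gene_ids(self):
        return tuple(f"g{i:04d}" for i in range(self.n_genes))


@dataclass
class SimTruth:
    """Ground truth recorded before noise: everything a recovery test needs."""

    logfc: pd.DataFrame | None = None          # gene x contrast (or per-week)
    module_assignment: dict = field(default_factory=dict)  # gene -> module index
    factors: pd.DataFrame | None = None        # latent module factors per sample
    de_genes: list = field(default_factory=list)
    side_effect_genes: list = field(default_factory=list)
    concordant_genes: list = field(default_factory=list)
    steroid_genes: list = field(default_factory=list)
    anchor_gene: str | None = None
    sigma_b: float = 0.0
    baseline: np.ndarray | None = None
    dispersion: np.ndarray | None = None
    block_factors: pd.DataFrame | None = None
    de_sign: np.ndarray | None = None


def _nb_counts(rng, log2cpm, libs, phi):
    mu = libs[None, :] * (2.0 ** log2cpm) * 1e-6
    phi_col = phi[:, None]
    lam = np.where(phi_col < 1e-8, mu,
                   rng.gamma(np.broadcast_to(1.0 / np.maximum(phi_col, 1e-8), mu.shape),
                             np.maximum(phi_col, 1e-8) * mu))
    return rng.poisson(lam).astype(np.int64)


def _gene_params(rng, design: SimDesign):
    mu = rng.normal(design.baseline_mean, design.baseline_sd, design.n_genes)
    phi = rng.lognormal(design.phi_meanlog, design.phi_sdlog, design.n_genes)
    return mu, phi


def _module_loadings(design: SimDesign):
    """Gene x module loading matrix (log2 scale)."""
    L = np.zeros((design.n_genes, len(design.modules.sizes) if design.modules else 0))
    for m, idx in enumerate(design.module_idx):
        L[idx, m] = design.modules.loading
    return L


def simulate_cross_sectional(design: SimDesign, tissue: str = "muscle",
                             factors: np.ndarray | None = None, rng=None):
    """One cross-sectional tissue dataset (the week-30 muscle design).

    ``factors`` optionally supplies latent module factors for matched samples
    (used by :func:`simulate_paired_tissues` to couple tissues with the
    per-module attenuation rho); otherwise fresh standard-normal factors are
    drawn per sample.
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    mu, phi = _gene_params(rng, design)
    groups = [g for g, n in design.group_sizes for _ in range(n)]
    n = len(groups)
    libs = rng.lognormal(design.lib_meanlog, design.lib_sdlog, n)
    L = _module_loadings(design)
    n_mod = L.shape[1]
    if factors is None:
        f = rng.standard_normal((n_mod, n))
    else:
        f = np.asarray(factors, float)
        if f.shape != (n_mod, n):
            raise DesignError(f"factors shape {f.shape} != ({n_mod}, {n})")
    affected = np.array([g != design.group_sizes[0][0] for g in groups], float)
    de_sign = np.where(np.arange(design.n_de) % 2 == 0, 1.0, -1.0)
    delta = np.zeros(design.n_genes)
    delta[design.de_idx] = design.de_logfc * de_sign
    log2cpm = mu[:, None] + L @ f + delta[:, None] * affected[None, :]
    counts = _nb_counts(rng, log2cpm, libs, phi)
    ref = design.group_sizes[0][0]
    sample_ids = tuple(f"{tissue[:2]}_s{i:03d}" for i in range(n))
    cm = CountMatrix(design.gene_ids, sample_ids, counts)
    st = pd.DataFrame({
        "sample_id": sample_ids,
        "subject_id": [f"subj{i:03d}" for i in range(n)],
        "group": groups,
        "timepoint": design.timepoints[-1],
        "tissue": tissue,
    })
    gid = np.array(design.gene_ids)
    contrasts = {f"{g}_vs_{ref}": delta for g, _ in design.group_sizes[1:]}
    truth = SimTruth(
        logfc=pd.DataFrame(contrasts, index=gid),
        module_assignment={gid[i]: m for m, idx in enumerate(design.module_idx) for i in idx},
        factors=pd.DataFrame(f.T, index=list(sample_ids),
                             columns=[f"module{m}" for m in range(n_mod)]),
        de_genes=list(gid[design.de_idx]),
        baseline=mu, dispersion=phi, de_sign=de_sign,
    )
    return cm, st, truth


def simulate_paired_tissues(design: SimDesign, rng=None):
    """Matched muscle and blood datasets for the same subjects.

    The same latent module factors drive both tissues, attenuated per module
    by rho: f_blood = rho * f_muscle + sqrt(1 - rho^2) * noise, which couples
    module eigengenes across tissues without forcing identical membership.
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    n = sum(s for _, s in design.group_sizes)
    n_mod = len(design.modules.sizes) if design.modules else 0
    f_muscle = rng.standard_normal((n_mod, n))
    rho = np.asarray(design.modules.cross_rho, float)[:, None]
    f_blood = rho * f_muscle + np.sqrt(1.0 - rho ** 2) * rng.standard_normal((n_mod, n))
    muscle = simulate_cross_sectional(design, "muscle", factors=f_muscle, rng=rng)
    blood = simulate_cross_sectional(design, "blood", factors=f_blood, rng=rng)
    # align subject ids: same subjects, two tissues
    blood[1]["subject_id"] = muscle[1]["subject_id"].to_numpy()
    return muscle, blood


def simulate_longitudinal(design: SimDesign, rng=None):
    """Longitudinal blood dataset: repeated samples per subject with a
    subject random intercept and a per-week planted disease logFC profile."""
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    if len(design.timepoints) < 2:
        raise DesignError("longitudinal design needs at least 2 timepoints")
    for g, s in design.group_sizes:
        if s < 2:
            raise DesignError(f"group {g!r} has a single subject; "
                              "random intercept unidentifiable")
    mu, phi = _gene_params(rng, design)
    profile = np.asarray(design.de_profile, float)
    if profile.size != len(design.timepoints):
        raise DesignError("de_profile must have one logFC per timepoint")
    subjects, groups = [], []
    for g, s in design.group_sizes:
        for i in range(s):
            subjects.append(f"{g}_m{i:02d}")
            groups.append(g)
    n_subj = len(subjects)
    T = len(design.timepoints)
    # gene-specific subject intercepts, constant across a subject's timepoints
    # (a gene-shared intercept would be a library-size effect and vanish in TMM)
    b = rng.normal(0.0, design.sigma_b, (design.n_genes, n_subj))
    rows = []
    for i, (subj, g) in enumerate(zip(subjects, groups)):
        for t, week in enumerate(design.timepoints):
            rows.append((f"{subj}_w{week}", subj, g, week, i, t))
    st = pd.DataFrame(rows, columns=["sample_id", "subject_id", "group",
                                     "timepoint", "_si", "_ti"])
    n = len(st)
    libs = rng.lognormal(design.lib_meanlog, design.lib_sdlog, n)
    L = _module_loadings(design)
    n_mod = L.shape[1]
    f = rng.standard_normal((n_mod, n))
    ref = design.group_sizes[0][0]
    affected = (st["group"] != ref).to_numpy(float)
    de_sign = np.where(np.arange(design.n_de) % 2 == 0, 1.0, -1.0)
    delta_tw = np.zeros((design.n_genes, T))
    delta_tw[design.de_idx] = de_sign[:, None] * profile[None, :]
    per_sample_delta = delta_tw[:, st["_ti"].to_numpy()] * affected[None, :]
    log2cpm = (mu[:, None] + b[:, st["_si"].to_numpy()]
               + L @ f + per_sample_delta)
    counts = _nb_counts(rng, log2cpm, libs, phi)
    cm = CountMatrix(design.gene_ids, tuple(st["sample_id"]), counts)
    st = st.drop(columns=["_si", "_ti"])
    gid = np.array(design.gene_ids)
    truth = SimTruth(
        logfc=pd.DataFrame(delta_tw, index=gid,
                           columns=[f"week{w}" for w in design.timepoints]),
        module_assignment={gid[i]: m for m, idx in enumerate(design.module_idx) for i in idx},
        factors=pd.DataFrame(f.T, index=list(cm.sample_ids),
                             columns=[f"module{m}" for m in range(n_mod)]),
        de_genes=list(gid[design.de_idx]),
        sigma_b=design.sigma_b, baseline=mu, dispersion=phi, de_sign=de_sign,
    )
    return cm, st, truth


def simulate_treatment(design: SimDesign, reference_truth: SimTruth,
                       week: int = 12, rng=None):
    """Three-arm treatment dataset on a dystrophic background.

    All mice carry the disease logFC of the reference longitudinal truth at
    ``week``; each treated arm is shifted by -kappa_arm * (disease logFC)
    (restoration) and the side-effect gene set gets an extra logFC in the
    side-effect arm only.  The truly concordant set (both arms moving against
    the disease signature) is recorded.
    """
    if reference_truth is None or reference_truth.logfc is None:
        raise DesignError("treatment simulation needs a reference longitudinal truth")
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    spec = design.treatment
    if len(spec.arms) != 3:
        raise DesignError("treatment design needs exactly three arms")
    col = f"week{week}"
    if col not in reference_truth.logfc.columns:
        raise DesignError(f"reference truth lacks disease logFC at week {week}")
    disease = reference_truth.logfc[col].reindex(list(design.gene_ids)).fillna(0.0).to_numpy()
    mu, phi = _gene_params(rng, design)
    arms = [a for a, n in spec.arms for _ in range(n)]
    n = len(arms)
    libs = rng.lognormal(design.lib_meanlog, design.lib_sdlog, n)
    kappa = np.array([spec.kappa.get(a, 0.0) for a in arms])
    side = np.zeros(design.n_genes)
    side[design.side_effect_idx] = spec.side_effect_logfc
    is_side_arm = np.array([a == spec.side_effect_arm for a in arms], float)
    log2cpm = (mu[:, None] + disease[:, None] * (1.0 - kappa[None, :])
               + side[:, None] * is_side_arm[None, :])
    counts = _nb_counts(rng, log2cpm, libs, phi)
    sample_ids = tuple(f"tr_s{i:03d}" for i in range(n))
    cm = CountMatrix(design.gene_ids, sample_ids, counts)
    st = pd.DataFrame({
        "sample_id": sample_ids,
        "subject_id": [f"trsubj{i:03d}" for i in range(n)],
        "group": "mdx",
        "timepoint": week,
        "treatment": arms,
    })
    gid = np.array(design.gene_ids)
    treated = [a for a, _ in spec.arms[1:]]
    arm_truth = {}
    for a in treated:
        shift = -spec.kappa.get(a, 0.0) * disease
        if a == spec.side_effect_arm:
            shift = shift + side
        arm_truth[a] = shift
    concordant = []
    for i, g in enumerate(gid):
        d = -disease[i]
        if d == 0:
            continue
        if all(np.sign(arm_truth[a][i]) == np.sign(d) for a in treated):
            concordant.append(g)
    truth = SimTruth(
        logfc=pd.DataFrame(arm_truth, index=gid).assign(disease=disease),
        de_genes=list(gid[np.nonzero(disease)[0]]),
        side_effect_genes=list(gid[design.side_effect_idx]),
        concordant_genes=concordant,
        baseline=mu, dispersion=phi,
    )
    return cm, st, truth


def _block_loading(p: int, target: float) -> float:
    """Equal loading a with first-PC variance share target on p standardized
    variables: share = (1 + (p-1) a^2) / p."""
    a2 = (p * target - 1.0) / (p - 1.0)
    if not 0 < a2 < 1:
        raise DesignError(f"PC1 target {target} infeasible for {p} variables")
    return float(np.sqrt(a2))


def simulate_cohort(design: SimDesign, rng=None):
    """Human-cohort dataset: group, age x group and steroid effects on
    expression, plus correlated body-measurement and physical-test blocks
    generated from single latent factors with loadings set for a target
    first-PC variance share; one designated gene tracks the physical factor."""
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    spec = design.cohort
    mu, phi = _gene_params(rng, design)
    n = spec.n_healthy + spec.n_case
    group = np.array(["healthy"] * spec.n_healthy + ["DMD"] * spec.n_case)
    age = np.concatenate([
        rng.uniform(*spec.healthy_age_range, spec.n_healthy),
        rng.uniform(*spec.age_range, spec.n_case),
    ])
    steroid = np.zeros(n)
    treated_idx = spec.n_healthy + rng.choice(spec.n_case, spec.n_steroid, replace=False)
    steroid[treated_idx] = 1.0
    libs = rng.lognormal(design.lib_meanlog, design.lib_sdlog, n)
    is_case = (group == "DMD").astype(float)
    age_c = age - age.mean()

    de_sign = np.where(np.arange(design.n_de) % 2 == 0, 1.0, -1.0)
    delta = np.zeros(design.n_genes)
    delta[design.de_idx] = design.de_logfc * de_sign
    slope = np.zeros(design.n_genes)
    # planted decay toward baseline with age: interaction opposite to the effect
    slope[design.de_idx] = spec.age_group_slope * de_sign
    ster_effect = np.zeros(design.n_genes)
    n_sg = min(spec.n_steroid_genes, design.n_de)
    ster_idx = design.de_idx[:n_sg]
    ster_effect[ster_idx] = spec.steroid_logfc * de_sign[:n_sg]

    f_body = rng.standard_normal(spec.n_case)
    f_phys = rng.standard_normal(spec.n_case)
    anchor_gene = design.gene_ids[design.n_genes - 1]
    anchor_track = np.zeros(n)
    anchor_track[spec.n_healthy:] = spec.anchor_gene_slope * f_phys

    log2cpm = (mu[:, None]
               + delta[:, None] * is_case[None, :]
               + slope[:, None] * (age_c * is_case)[None, :]
               + ster_effect[:, None] * steroid[None, :])
    log2cpm[-1] += anchor_track
    counts = _nb_counts(rng, log2cpm, libs, phi)
    sample_ids = tuple(f"pt_s{i:03d}" for i in range(n))
    cm = CountMatrix(design.gene_ids, sample_ids, counts)
    st = pd.DataFrame({
        "sample_id": sample_ids,
        "subject_id": [f"pt{i:03d}" for i in range(n)],
        "group": group,
        "timepoint": None,
        "treatment": steroid,
        "age": age,
    })

    def _block(f, p, target, prefix):
        a = _block_loading(p, target)
        noise = rng.standard_normal((spec.n_case, p))
        vals = a * f[:, None] + np.sqrt(1.0 - a * a) * noise
        return pd.DataFrame(vals, index=list(sample_ids[spec.n_healthy:]),
                            columns=[f"{prefix}{j + 1}" for j in range(p)])

    body = _block(f_body, spec.body_block_size, spec.body_pc1_target, "body")
    phys = _block(f_phys, spec.physical_block_size, spec.physical_pc1_target, "test")
    gid = np.array(design.gene_ids)
    truth = SimTruth(
        logfc=pd.DataFrame({"DMD_vs_healthy": delta, "age_x_group": slope,
                            "steroid": ster_effect}, index=gid),
        de_genes=list(gid[design.de_idx]),
        steroid_genes=list(gid[ster_idx]),
        anchor_gene=anchor_gene,
        baseline=mu, dispersion=phi, de_sign=de_sign,
        block_factors=pd.DataFrame({"body": f_body, "physical": f_phys},
                                   index=list(sample_ids[spec.n_healthy:])),
    )
    return cm, st, {"body": body, "physical": phys}, truth


# ---------------------------------------------------------------------------
# scenario factories: the default study conditions

def momus_design(seed: int = 13154, **kw) -> SimDesign:
    """Cross-sectional muscle: 31 week-30 biopsies (7 WT + 8/8/8 dystrophic)."""
    base = SimDesign(group_sizes=(("WT", 7), ("mdx", 8), ("mdx++", 8), ("mdx+-", 8)),
                     seed=seed)
    return replace(base, **kw) if kw else base


def molong_design(seed: int = 13154, **kw) -> SimDesign:
    """Longitudinal blood: 5 subjects per group, weeks 6-30 (90 samples)."""
    base = SimDesign(group_sizes=(("WT", 5), ("mdx", 5), ("mdx++", 5), ("mdx+-", 5)),
                     seed=seed)
    return replace(base, **kw) if kw else base


def motreat_design(seed: int = 13154, **kw) -> SimDesign:
    """Three-arm antisense treatment experiment on dystrophic blood."""
    base = SimDesign(group_sizes=(("mdx", 14),), seed=seed)
    return replace(base, **kw) if kw else base


def dmdmex_design(seed: int = 13154, **kw) -> SimDesign:
    """Human cohort: 18 healthy + 39 patients, 32 on corticosteroids."""
    base = SimDesign(group_sizes=(("healthy", 18), ("DMD", 39)),
                     n_de=300, de_logfc=1.5, seed=seed)
    return replace(base, **kw) if kw else base
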