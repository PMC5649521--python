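"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generative model:

* gene-wise residual variances follow the scaled inverse-chi-square
  prior sigma_g^2 ~ d0 * s0^2 / chi^2_{d0} (so the moderated-t
  machinery's assumptions hold exactly);
* expression (log2 scale) = per-gene baseline + subgroup effect +
  Normal(0, sigma_g^2), with controls carrying zero effects;
* disease samples fall into K latent severity subgroups; planted gene
  modules (a core block perturbed in every subgroup, severity-patterned
  co-expression blocks, subgroup-unique blocks including an "advanced"
  block in the most severe subgroup, and a weakly-informative secreted
  biomarker block) define the per-subgroup effects;
* clinical lung-function measures are drawn per subgroup with means
  descending with severity, so clinical separation peaks at the true K.

Everything is returned with full ground truth (labels, effect matrix,
truth gene sets, planted annotations) for recovery tests.  A companion
generator emits a synthetic annotation database whose planted
disease terms are enriched in the known-gene training set and annotate
the planted candidate genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from fibrostrat.io_formats import ClinicalTable, ExpressionMatrix, GeneSetCollection
from fibrostrat.prioritization import DEFAULT_CATEGORIES, AnnotationDB

#: lung-function generation: (control mean, control SD,
#: (mildest, most severe) disease subgroup mean range, subgroup SD)
DEFAULT_CLINICAL = {
    "fev1_pct": (94.33, 9.86, (90.0, 55.0), 3.0),
    "fvc_pct": (91.75, 7.44, (85.0, 48.0), 3.0),
    "dlco_pct": (97.00, 21.30, (75.0, 35.0), 3.0),
}


@dataclass(frozen=True)
class ModuleSpec:
    """A planted gene block: per-subgroup log2 effects and the fraction
    of member genes whose pattern is sign-flipped (down-regulated).

    With ``scale_by_sigma`` the pattern is a standardized effect
    (signal-to-noise units): each member gene's log2 shift is the
    pattern value times that gene's own residual SD, so every member is
    equally informative regardless of its noise level."""

    name: str
    n_genes: int
    pattern: tuple[float, ...]
    down_fraction: float = 0.0
    scale_by_sigma: bool = False


def default_modules(
    k: int, effect: float = 1.5, moderate: float = 0.75, candidate_effect: float = 2.2
) -> list[ModuleSpec]:
    """Default planted structure for K subgroups.

    For K = 6 the co-expression blocks mirror the reported Gm1-3
    severity patterns; otherwise a binary-code pattern keeps every
    subgroup distinguishable.  Always includes: a core block (all
    subgroups), an advanced block (most severe only), a unique block
    per remaining subgroup (so every pair of subgroups differs on a
    few hundred genes and is recoverable by expression clustering),
    high-effect planted prioritization candidates inside the core and
    advanced blocks, and the secreted biomarker block (11 weakly
    informative + 49 null genes).
    """
    if k < 2:
        raise ValueError("need at least two subgroups")
    zeros = [0.0] * k
    if k == 6:
        gm = [
            ("gm1", (effect, 0, effect, effect, moderate, effect)),
            ("gm2", (effect, 0, effect, 0, effect, effect)),
            ("gm3", (-moderate, 0, -effect, -moderate, -effect, -effect)),
        ]
    else:
        gm = []
        for j in range(3):
            pat = [effect if (i >> j) & 1 else 0.0 for i in range(k)]
            gm.append((f"gm{j + 1}", tuple(-p for p in pat) if j == 2 else tuple(pat)))
    unique_last = zeros.copy()
    unique_last[k - 1] = effect
    uniques = []
    for i in range(k - 1):
        pat = zeros.copy()
        pat[i] = effect
        n = 100 if i == k - 2 else 80  # the second-most-severe block is largest
        name = "preterminal_unique" if i == k - 2 else f"unique_s{i + 1}"
        uniques.append(ModuleSpec(name, n, tuple(pat)))
    modules = [
        ModuleSpec("core", 144, tuple([effect] * k), down_fraction=1 / 3),
        ModuleSpec("core_candidate", 6, tuple([candidate_effect] * k)),
        *[ModuleSpec(name, 150, pat) for name, pat in gm],
        *uniques,
        ModuleSpec("advanced", 94, tuple(unique_last), down_fraction=0.3),
        ModuleSpec("advanced_candidate", 6, tuple([candidate_effect if i == k - 1 else 0.0 for i in range(k)])),
    ]
    return modules


@dataclass
class SyntheticConfig:
    """Generator parameters; the defaults are the study-like conditions
    every recovery test runs under (see docs/methods.md)."""

    n_genes: int = 2000
    n_controls: int = 12
    n_disease: int = 96
    k_subgroups: int = 6
    modules: list[ModuleSpec] | None = None  # None -> default_modules(k)
    effect: float = 1.5
    moderate_effect: float = 0.75
    candidate_effect: float = 2.2
    # variance prior (scaled inverse-chi-square)
    d0: float = 4.0
    s0_sq: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    clinical: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL))
    dlco_missing_rate: float = 0.05
    # secreted biomarker block: every secreted gene carries a fixed
    # standardized effect (log2 shift = snr * sigma_g); the informative
    # genes are clearly useful individually only in aggregate (~10
    # needed), the remaining fillers are marginal
    n_informative_biomarkers: int = 11
    n_secreted: int = 60
    biomarker_snr: float = 0.82
    biomarker_filler_snr: float = 0.30
    # known-disease training genes for prioritization
    n_known_core: int = 12
    n_known_advanced: int = 8
    n_known_external: int = 10

    def resolved_modules(self) -> list[ModuleSpec]:
        mods = (
            list(self.modules)
            if self.modules is not None
            else default_modules(
                self.k_subgroups, self.effect, self.moderate_effect, self.candidate_effect
            )
        )
        n_null_secreted = self.n_secreted - self.n_informative_biomarkers
        if n_null_secreted < 0:
            raise ValueError("n_secreted must be >= n_informative_biomarkers")
        mods.append(
            ModuleSpec(
                "biomarker_informative",
                self.n_informative_biomarkers,
                tuple([self.biomarker_snr] * self.k_subgroups),
                scale_by_sigma=True,
            )
        )
        mods.append(
            ModuleSpec(
                "biomarker_filler",
                n_null_secreted,
                tuple([self.biomarker_filler_snr] * self.k_subgroups),
                scale_by_sigma=True,
            )
        )
        return mods

    def validate(self) -> None:
        if min(self.n_genes, self.n_controls, self.n_disease, self.k_subgroups) < 1:
            raise ValueError("counts must be positive")
        if self.n_disease < self.k_subgroups:
            raise ValueError("need at least one disease sample per subgroup")
        if not (self.d0 > 0 and self.s0_sq > 0):
            raise ValueError("variance prior parameters must be positive")
        mods = self.resolved_modules()
        total = sum(m.n_genes for m in mods)
        if total > self.n_genes:
            raise ValueError(f"modules need {total} genes but n_genes = {self.n_genes}")
        for m in mods:
            if len(m.pattern) != self.k_subgroups:
                raise ValueError(f"module {m.name}: pattern length != K")
            if not all(np.isfinite(m.pattern)):
                raise ValueError(f"module {m.name}: non-finite effect")

    @classmethod
    def null(cls, **kwargs) -> "SyntheticConfig":
        """Zero-effect configuration (for type-I-error calibration)."""
        cfg = cls(**kwargs)
        silent = [
            replace(m, pattern=tuple([0.0] * cfg.k_subgroups))
            for m in cfg.resolved_modules()
            if m.name not in ("biomarker_informative", "biomarker_filler")
        ]
        cfg.modules = silent
        cfg.biomarker_snr = 0.0
        cfg.biomarker_filler_snr = 0.0
        return cfg

    @classmethod
    def paper_scale(cls, **kwargs) -> "SyntheticConfig":
        """Full study-sized preset: 14,110 genes x (12 + 131) samples."""
        kwargs.setdefault("n_genes", 14110)
        kwargs.setdefault("n_controls", 12)
        kwargs.setdefault("n_disease", 131)
        return cls(**kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated cohort."""

    subgroups: pd.Series  # disease sample -> 1..K
    effects: pd.DataFrame  # genes x subgroups ("S1".."SK"), log2 units
    module_of: pd.Series  # gene -> module name ("" = unperturbed background)
    core_genes: list[str]
    advanced_genes: list[str]
    unique_sets: dict[int, list[str]]  # subgroup index -> unique genes
    secreted_genes: list[str]
    informative_biomarkers: list[str]
    known_genes: list[str]
    candidate_genes: list[str]
    variances: pd.Series  # gene -> sigma_g^2
    baselines: pd.Series  # gene -> baseline log2 intensity
    config: SyntheticConfig

    def to_report(self) -> dict:
        return {
            "k_subgroups": int(self.subgroups.max()),
            "n_core": len(self.core_genes),
            "n_advanced": len(self.advanced_genes),
            "n_secreted": len(self.secreted_genes),
            "n_known": len(self.known_genes),
            "n_candidates": len(self.candidate_genes),
        }


def _subgroup_sizes(n_disease: int, k: int) -> list[int]:
    base, extra = divmod(n_disease, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def generate_cohort(
    cfg: SyntheticConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    template: "SyntheticTruth | None" = None,
) -> tuple[ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Draw one cohort (expression, clinical, truth); deterministic for
    a given seed.

    Pass the ``template`` truth of a previously generated cohort to
    reuse its gene-wise variances and baselines, as when simulating a
    validation cohort measured on the same platform: residual variance
    is a property of the gene, not of the cohort.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    k = cfg.k_subgroups
    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    controls = [f"CTRL{i + 1:03d}" for i in range(cfg.n_controls)]
    disease = [f"IPF{i + 1:03d}" for i in range(cfg.n_disease)]

    # --- planted effects -------------------------------------------------
    modules = cfg.resolved_modules()
    effects = np.zeros((cfg.n_genes, k))
    module_of = np.array([""] * cfg.n_genes, dtype=object)
    cursor = 0
    module_genes: dict[str, list[str]] = {}
    sigma_scaled_idx: list[np.ndarray] = []
    for mod in modules:
        idx = np.arange(cursor, cursor + mod.n_genes)
        cursor += mod.n_genes
        n_down = int(round(mod.n_genes * mod.down_fraction))
        signs = np.ones(mod.n_genes)
        signs[mod.n_genes - n_down :] = -1.0
        effects[idx] = signs[:, None] * np.asarray(mod.pattern)[None, :]
        if mod.scale_by_sigma:
            sigma_scaled_idx.append(idx)
        module_of[idx] = mod.name
        module_genes[mod.name] = [genes[i] for i in idx]

    # --- expression -------------------------------------------------------
    if template is not None:
        if len(template.variances) != cfg.n_genes:
            raise ValueError("template truth has a different gene count")
        sigma2 = template.variances.to_numpy()
        baseline = template.baselines.to_numpy()
    else:
        sigma2 = cfg.d0 * cfg.s0_sq / rng.chisquare(cfg.d0, size=cfg.n_genes)
        baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    for idx in sigma_scaled_idx:
        effects[idx] *= np.sqrt(sigma2[idx])[:, None]
    sizes = _subgroup_sizes(cfg.n_disease, k)
    subgroup_of = np.repeat(np.arange(1, k + 1), sizes)
    n_samples = cfg.n_controls + cfg.n_disease
    noise = rng.normal(0.0, 1.0, size=(cfg.n_genes, n_samples)) * np.sqrt(sigma2)[:, None]
    X = baseline[:, None] + noise
    X[:, cfg.n_controls :] += effects[:, subgroup_of - 1]
    matrix = ExpressionMatrix.from_arrays(genes, controls + disease, X)

    # --- clinical ---------------------------------------------------------
    rows = []
    for i, sample in enumerate(controls):
        row = {"sample_id": sample, "group": "control"}
        for measure, (c_mean, c_sd, _, _) in cfg.clinical.items():
            row[measure] = float(np.clip(rng.normal(c_mean, c_sd), 0.0, 200.0))
        row["age"] = float(rng.normal(64.1, 8.2))
        row["sex"] = "male" if rng.random() < 0.5 else "female"
        row["smoking"] = str(rng.choice(["never", "former", "current"], p=[0.3, 0.6, 0.1]))
        rows.append(row)
    subgroup_means = {
        measure: np.linspace(rng_pair[0], rng_pair[1], k)
        for measure, (_, _, rng_pair, _) in cfg.clinical.items()
    }
    for i, sample in enumerate(disease):
        g = subgroup_of[i]
        row = {"sample_id": sample, "group": "disease"}
        for measure, (_, _, _, sd) in cfg.clinical.items():
            row[measure] = float(np.clip(rng.normal(subgroup_means[measure][g - 1], sd), 0.0, 200.0))
        if cfg.dlco_missing_rate and rng.random() < cfg.dlco_missing_rate:
            row["dlco_pct"] = np.nan
        row["age"] = float(rng.normal(62.6, 12.2))
        row["sex"] = "male" if rng.random() < 0.672 else "female"
        row["smoking"] = str(rng.choice(["never", "former", "current"], p=[0.3, 0.6, 0.1]))
        rows.append(row)
    clinical = ClinicalTable(pd.DataFrame(rows))

    # --- truth ------------------------------------------------------------
    core = module_genes.get("core", []) + module_genes.get("core_candidate", [])
    advanced = module_genes.get("advanced", []) + module_genes.get("advanced_candidate", [])
    unique_sets = {k: list(advanced)}
    if "preterminal_unique" in module_genes:
        unique_sets[k - 1] = module_genes["preterminal_unique"]
    for i in range(1, k - 1):
        name = f"unique_s{i}"
        if name in module_genes:
            unique_sets[i] = module_genes[name]
    secreted = module_genes.get("biomarker_informative", []) + module_genes.get(
        "biomarker_filler", []
    )
    known = (
        module_genes.get("core", [])[: cfg.n_known_core]
        + module_genes.get("advanced", [])[: cfg.n_known_advanced]
        + [g for g, m in zip(genes, module_of) if m == ""][: cfg.n_known_external]
    )
    truth = SyntheticTruth(
        subgroups=pd.Series(subgroup_of, index=pd.Index(disease, name="sample_id")),
        effects=pd.DataFrame(effects, index=genes, columns=[f"S{i + 1}" for i in range(k)]),
        module_of=pd.Series(module_of, index=genes, name="module"),
        core_genes=core,
        advanced_genes=advanced,
        unique_sets=unique_sets,
        secreted_genes=secreted,
        informative_biomarkers=module_genes.get("biomarker_informative", []),
        known_genes=known,
        candidate_genes=module_genes.get("core_candidate", [])
        + module_genes.get("advanced_candidate", []),
        variances=pd.Series(sigma2, index=genes, name="sigma2"),
        baselines=pd.Series(baseline, index=genes, name="baseline"),
        config=cfg,
    )
    return matrix, clinical, truth


def generate_annotation_db(
    cfg: SyntheticConfig,
    truth: SyntheticTruth,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_background_terms: int = 20,
) -> tuple[AnnotationDB, set[str], set[str]]:
    """Synthetic annotation database plus training and secreted sets.

    Each category carries two planted "disease" terms built from most
    of the known training genes plus the planted candidate genes (so
    those terms come out enriched in the training set and annotate the
    candidates), and random background terms.  Deterministic for a
    given seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    all_genes = np.array(truth.effects.index)
    known = list(truth.known_genes)
    candidates = list(truth.candidate_genes)
    db = AnnotationDB()
    for cat in DEFAULT_CATEGORIES:
        coll = GeneSetCollection()
        for j in range(2):
            n_known_in = max(1, int(round(0.8 * len(known))))
            members = list(rng.choice(known, size=n_known_in, replace=False))
            members += candidates
            members += list(rng.choice(all_genes, size=8, replace=False))
            coll.add(f"{cat}_disease_term_{j + 1}", "planted disease term", dict.fromkeys(members))
        for j in range(n_background_terms):
            size = int(rng.integers(10, 51))
            members = rng.choice(all_genes, size=size, replace=False)
            coll.add(f"{cat}_background_{j + 1}", "background term", members.tolist())
        db.categories[cat] = coll
    return db, set(known), set(truth.secreted_genes)
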