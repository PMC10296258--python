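"""Simulation configuration for the synthetic head-and-neck cancer cohort.

The defaults encode the study conditions the pipeline is designed for: a
209-patient cohort measured on 186 level-1-identified plasma metabolites in
two chromatography modes, a latent 41%/59% two-subtype structure whose
effect sizes are concentrated on a handful of metabolic pathways, triplicate
injections with batch structure and intensity-dependent missingness, and
survival in which the high-risk subtype carries a ~3-fold hazard among
ever-smokers but no excess hazard among never-smokers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class PathwaySpec:
    """A synthetic pathway: ``size`` members of which ``n_shifted`` carry a
    per-metabolite subtype mean-shift of ``shift`` latent SD units, with
    exchangeable within-pathway noise correlation ``correlation`` (None
    falls back to the config-wide ``block_correlation``)."""

    name: str
    size: int
    shift: float = 0.0
    n_shifted: int | None = None  # None -> all members shifted
    correlation: float | None = None

    def resolved_n_shifted(self) -> int:
        return self.size if self.n_shifted is None else self.n_shifted


def default_pathway_spec() -> list[PathwaySpec]:
    # Four signal pathways mirroring the enriched-pathway pattern the
    # pipeline should recover (strongly co-regulated, rho 0.5 — the fatty
    # acid pattern), plus mildly co-regulated null pathways, so the
    # metabolite-wide pairwise correlation stays near zero.
    return [
        PathwaySpec("Fatty acid biosynthesis", 6, 1.00, 4, 0.5),
        PathwaySpec("Transfer of acetyl groups into mitochondria",
                    5, 0.75, 3, 0.5),
        PathwaySpec("Arginine and proline metabolism", 12, 0.90, 5, 0.5),
        PathwaySpec("Galactose metabolism", 6, 1.15, 3, 0.5),
        PathwaySpec("Glycine and serine metabolism", 14, 0.0, None, 0.1),
        PathwaySpec("Tryptophan metabolism", 12, 0.0, None, 0.1),
        PathwaySpec("Bile acid biosynthesis", 10, 0.0, None, 0.1),
        PathwaySpec("Purine metabolism", 11, 0.0, None, 0.1),
        PathwaySpec("Phospholipid biosynthesis", 9, 0.0, None, 0.1),
        PathwaySpec("Carnitine synthesis", 8, 0.0, None, 0.1),
        PathwaySpec("Urea cycle", 7, 0.0, None, 0.1),
        PathwaySpec("Pyruvate metabolism", 6, 0.0, None, 0.1),
    ]


def default_covariate_probs() -> dict:
    """Marginal frequencies of the categorical clinical covariates."""
    return {
        "sex": {"Male": 0.75, "Female": 0.25},
        "race": {"White": 0.81, "Black": 0.19},
        "hpv_status": {"Related": 0.48, "Unrelated": 0.52},
        "smoking": {"Never": 0.39, "Former": 0.33, "Current": 0.28},
        "alcohol": {"<1 drink/week": 0.55, "1+ drink/week": 0.45},
        "marital": {"Married or partnered": 0.71, "Single": 0.29},
        "tumor_site": {
            "Oropharynx": 0.51, "Oral cavity": 0.15, "Larynx": 0.17, "Other": 0.17,
        },
        "stage": {"I": 0.05, "II": 0.08, "III": 0.40, "IV": 0.47},
        "treatment": {
            "Radiotherapy": 0.22,
            "Chemoradiotherapy with Cisplatin": 0.56,
            "Chemoradiotherapy with Carboplatin and Paclitaxel": 0.22,
        },
        "feeding_tube": {"No": 0.40, "Yes": 0.60},
        "ecog": {"Active": 0.50, "Restricted": 0.37, "Non-working": 0.13},
        "comorbidity": {"Yes": 0.75, "No": 0.25},
    }


def default_lab_params() -> dict:
    """Mean/SD of the continuous lab covariates (truncated at a floor)."""
    return {
        "bmi": (27.5, 5.2, 12.0),
        "albumin": (3.95, 0.42, 1.0),
        "hemoglobin": (13.18, 1.80, 5.0),
        "nlr": (3.18, 2.07, 0.2),
        "plr": (170.3, 98.9, 20.0),  # platelet-to-lymphocyte ratio / 1000
    }


@dataclass
class SimulationConfig:
    n_patients: int = 209
    n_metabolites: int = 186
    hilic_fraction: float = 125 / 186  # share of metabolites on HILIC+
    subtype_prevalence: float = 0.41  # P(latent subtype A)

    pathway_spec: Sequence[PathwaySpec] = field(default_factory=default_pathway_spec)
    n_diffuse_shifted: int = 24  # differential metabolites outside named pathways
    diffuse_shift_range: tuple = (0.75, 1.2)
    n_weak_shifted: int = 40  # tail of mildly differential metabolites
    weak_shift_range: tuple = (0.3, 0.7)
    background_shift_sd: float = 0.05  # small heterogeneous null shifts
    block_correlation: float = 0.30  # exchangeable within-pathway correlation

    n_batches: int = 4
    batch_shift_sd: float = 0.40  # additive per-(batch, feature) log2 shift SD
    batch_scale_sd: float = 0.10  # log-SD of multiplicative batch scale effects
    replicate_cv: float = 0.10  # median technical replicate CV
    replicate_cv_spread: float = 0.35  # log-SD of per-feature CV heterogeneity
    high_cv_rate: float = 0.03  # fraction of irreproducible features (CV ~ 0.9)
    n_unidentified: int = 20  # features with no library identity
    missing_rate: float = 0.015
    mnar_strength: float = 6.0  # logistic slope of missingness in log-intensity

    smoking_probs: tuple = (0.39, 0.33, 0.28)  # never / former / current
    hpv_positive_prob: float = 0.48
    age_mean_by_subtype: tuple = (61.7, 57.6)  # years, subtype (A, B)
    age_sd: float = 10.0
    covariate_probs: dict = field(default_factory=default_covariate_probs)
    lab_params: dict = field(default_factory=default_lab_params)
    covariate_missing_rate: float = 0.05  # per-lab-covariate MCAR missingness

    hr_subtypeA_smoker: float = 3.0
    hr_subtypeA_never: float = 1.0
    hr_never_smoker: float = 0.60  # baseline hazard multiplier for never-smokers
    baseline_3yr_survival: float = 0.863  # subtype-B ever-smoker S(3)
    pfs_rate_multiplier: float = 0.5  # progression hazard / mortality hazard
    censor_window: tuple = (2.5, 8.0)  # years of administrative censoring
    loss_to_followup: float = 20 / 209

    seed: int = 0

    def validate(self) -> None:
        err = ConfigurationError
        if self.n_patients < 0 or self.n_metabolites <= 0:
            raise err("n_patients must be >= 0 and n_metabolites > 0")
        if not 0 < self.subtype_prevalence < 1:
            raise err("subtype_prevalence must lie in (0, 1)")
        if not 0 <= self.block_correlation < 1:
            raise err("block_correlation must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise err("missing_rate must lie in [0, 1)")
        for name in ("background_shift_sd", "batch_shift_sd", "replicate_cv",
                     "mnar_strength", "age_sd"):
            if getattr(self, name) < 0:
                raise err(f"{name} must be nonnegative")
        if abs(sum(self.smoking_probs) - 1) > 1e-9 or min(self.smoking_probs) < 0:
            raise err("smoking_probs must be a nonnegative 3-vector summing to 1")
        if not 0 <= self.hpv_positive_prob <= 1:
            raise err("hpv_positive_prob must lie in [0, 1]")
        if not 0 < self.baseline_3yr_survival < 1:
            raise err("baseline_3yr_survival must lie in (0, 1)")
        for name in ("hr_subtypeA_smoker", "hr_subtypeA_never", "hr_never_smoker"):
            if getattr(self, name) <= 0:
                raise err(f"{name} must be positive")
        if not 0 <= self.loss_to_followup < 1:
            raise err("loss_to_followup must lie in [0, 1)")
        if self.censor_window is not None:
            lo, hi = self.censor_window
            if lo <= 0 or hi < lo:
                raise err("censor_window must satisfy 0 < min <= max")
        for probs in self.covariate_probs.values():
            vals = list(probs.values())
            if min(vals) < 0 or abs(sum(vals) - 1) > 1e-9:
                raise err("covariate probabilities must be nonnegative and sum to 1")
        total = sum(p.size for p in self.pathway_spec)
        if total + self.n_diffuse_shifted + self.n_weak_shifted \
                > self.n_metabolites:
            raise err("pathway sizes plus shifted sets exceed n_metabolites")
        for p in self.pathway_spec:
            if p.size <= 0 or p.resolved_n_shifted() > p.size:
                raise err(f"pathway {p.name!r}: invalid size / n_shifted")

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["pathway_spec"] = [asdict(p) for p in self.pathway_spec]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "pathway_spec" in d:
            d["pathway_spec"] = [
                p if isinstance(p, PathwaySpec) else PathwaySpec(**p)
                for p in d["pathway_spec"]
            ]
        for key in ("smoking_probs", "age_mean_by_subtype", "censor_window",
                    "diffuse_shift_range", "weak_shift_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
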