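"""Synthetic cohort generator.

Emulates a prospective head-and-neck cancer metabolomics study: a clinical
table with the usual demographic / tumor / lab covariates, a latent
two-subtype structure over patients, replicate-level LC-MS feature tables in
two chromatography modes with batch effects and intensity-dependent
missingness, a pathway membership map over synthetic HMDB-style accessions,
and survival outcomes in which the high-risk subtype carries excess hazard
only among ever-smokers.

Every function is deterministic given the configuration seed; independent
numbered streams are used per stage so that, e.g., regenerating survival
does not perturb the metabolome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig, ConfigurationError
from .containers import (
    HILIC_POS, C18_NEG, MetaboliteLibrary, RawFeatureTable, PathwayMap,
)

CLINICAL_COLUMNS = [
    "id", "age", "sex", "race", "bmi", "hpv_status", "smoking", "alcohol",
    "marital", "tumor_site", "stage", "treatment", "feeding_tube", "ecog",
    "comorbidity", "albumin", "hemoglobin", "nlr", "plr", "true_subtype",
]

_STREAM = {"clinical": 1, "library": 2, "pathways": 3, "metabolome": 4,
           "survival": 5}


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAM[stage]])


# ----------------------------------------------------------------- clinical

def generate_clinical(config: SimulationConfig) -> pd.DataFrame:
    """Draw the baseline clinical table with a latent subtype per patient.

    The latent subtype is independent of every covariate except age (drawn
    from a per-subtype normal), matching a cohort in which the metabolic
    subtypes are balanced on smoking, HPV and tumor factors.
    """
    config.validate()
    n = config.n_patients
    if n == 0:
        return pd.DataFrame(columns=CLINICAL_COLUMNS)
    rng = _rng(config, "clinical")

    subtype = np.where(rng.random(n) < config.subtype_prevalence, "A", "B")
    mean_a, mean_b = config.age_mean_by_subtype
    age = rng.normal(np.where(subtype == "A", mean_a, mean_b), config.age_sd)
    age = np.maximum(age, 21.0)

    out = {"id": [f"P{i + 1:04d}" for i in range(n)], "age": age}
    for col, probs in config.covariate_probs.items():
        levels = list(probs)
        out[col] = rng.choice(levels, size=n, p=[probs[k] for k in levels])
    # smoking / HPV come from their dedicated config knobs
    out["smoking"] = rng.choice(
        ["Never", "Former", "Current"], size=n, p=list(config.smoking_probs))
    out["hpv_status"] = np.where(
        rng.random(n) < config.hpv_positive_prob, "Related", "Unrelated")
    for col, (mu, sd, floor) in config.lab_params.items():
        vals = np.maximum(rng.normal(mu, sd, size=n), floor)
        if config.covariate_missing_rate > 0:
            vals = np.where(rng.random(n) < config.covariate_missing_rate,
                            np.nan, vals)
        out[col] = vals
    out["true_subtype"] = subtype
    return pd.DataFrame(out)[CLINICAL_COLUMNS]


# ------------------------------------------------------- library & pathways

def generate_library(config: SimulationConfig) -> MetaboliteLibrary:
    """Synthetic level-1 identification library over both modes."""
    config.validate()
    rng = _rng(config, "library")
    m = config.n_metabolites
    n_hilic = int(round(m * config.hilic_fraction))
    modes = np.array([HILIC_POS] * n_hilic + [C18_NEG] * (m - n_hilic))
    mz = rng.uniform(85.0, 1275.0, size=m)
    rt = np.where(modes == HILIC_POS,
                  rng.uniform(60.0, 300.0, size=m),
                  rng.uniform(10.0, 260.0, size=m))
    adduct = np.where(modes == HILIC_POS, "(M+H)", "(M-H)")
    entries = pd.DataFrame({
        "name": [f"Metabolite_{j + 1:03d}" for j in range(m)],
        "mz": np.round(mz, 4),
        "rt": np.round(rt, 1),
        "mode": modes,
        "adduct": adduct,
        "hmdb_id": [f"HMDB9{j:06d}" for j in range(m)],
    })
    return MetaboliteLibrary(entries)


def generate_pathway_map(config: SimulationConfig,
                         library: MetaboliteLibrary | None = None) -> PathwayMap:
    """Assign disjoint accession sets of the configured sizes to pathways."""
    config.validate()
    if not config.pathway_spec:
        return {}
    if library is None:
        library = generate_library(config)
    rng = _rng(config, "pathways")
    accessions = list(library.entries["hmdb_id"])
    order = rng.permutation(len(accessions))
    pmap: PathwayMap = {}
    cursor = 0
    for spec in config.pathway_spec:
        members = {accessions[i] for i in order[cursor:cursor + spec.size]}
        pmap[spec.name] = members
        cursor += spec.size
    return pmap


def _shift_vector(config: SimulationConfig, library: MetaboliteLibrary,
                  pathways: PathwayMap,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-metabolite subtype mean-shift in latent SD units (A minus B)."""
    acc_index = {a: j for j, a in enumerate(library.entries["hmdb_id"])}
    m = len(library)
    shift = rng.normal(0.0, config.background_shift_sd, size=m) \
        if config.background_shift_sd > 0 else np.zeros(m)
    in_pathway = np.zeros(m, dtype=bool)
    for spec in config.pathway_spec:
        if spec.name not in pathways:
            continue
        members = sorted(pathways[spec.name])
        for acc in members:
            if acc not in acc_index:
                raise ConfigurationError(
                    f"pathway {spec.name!r} references accession {acc} "
                    "absent from the library")
        idx = [acc_index[a] for a in members]
        in_pathway[idx] = True
        for j in idx[: spec.resolved_n_shifted()]:
            shift[j] = spec.shift
    free = np.flatnonzero(~in_pathway)
    n_diffuse = min(config.n_diffuse_shifted, free.size)
    chosen = np.array([], dtype=int)
    if n_diffuse > 0:
        chosen = rng.choice(free, size=n_diffuse, replace=False)
        shift[chosen] = rng.uniform(*config.diffuse_shift_range,
                                    size=n_diffuse)
    # a tail of mildly differential metabolites: real differential
    # expression does not stop abruptly at the selection threshold
    free = np.setdiff1d(free, chosen)
    n_weak = min(config.n_weak_shifted, free.size)
    if n_weak > 0:
        weak = rng.choice(free, size=n_weak, replace=False)
        shift[weak] = rng.uniform(*config.weak_shift_range, size=n_weak)
    return shift


# ---------------------------------------------------------------- metabolome

def generate_metabolome(clinical: pd.DataFrame, pathways: PathwayMap,
                        config: SimulationConfig,
                        library: MetaboliteLibrary | None = None,
                        ) -> RawFeatureTable:
    """Replicate-level feature intensities consistent with ``library``.

    Generative model, per metabolite j and patient i on the log2 scale:

        L_ij = mu_j + shift_j * 1{subtype_i = A} + z_ij
        z_ij = sqrt(rho) * g_{i,pathway(j)} + sqrt(1 - rho) * e_ij

    with unit-variance noise, exchangeable within-pathway correlation rho,
    per-(batch, feature) additive location and multiplicative scale effects,
    per-feature replicate CV heterogeneity, and logistic-in-log-intensity
    (missing-not-at-random) detection.
    """
    config.validate()
    if "true_subtype" not in clinical.columns:
        raise ValueError("clinical table lacks latent subtypes")
    if library is None:
        library = generate_library(config)
    rng = _rng(config, "metabolome")
    n = len(clinical)
    m = len(library)
    shift = _shift_vector(config, library, pathways, rng)
    is_a = (clinical["true_subtype"] == "A").to_numpy()

    # latent standardized values with within-pathway exchangeable correlation
    rho_by_name = {p.name: p.correlation for p in config.pathway_spec}
    z = rng.standard_normal((n, m))
    acc_index = {a: j for j, a in enumerate(library.entries["hmdb_id"])}
    for name, members in pathways.items():
        rho = rho_by_name.get(name)
        if rho is None:
            rho = config.block_correlation
        idx = [acc_index[a] for a in sorted(members) if a in acc_index]
        if rho <= 0 or len(idx) < 2:
            continue
        g = rng.standard_normal(n)
        z[:, idx] = np.sqrt(rho) * g[:, None] + np.sqrt(1 - rho) * z[:, idx]

    mu = rng.uniform(14.0, 24.0, size=m)
    latent = mu[None, :] + np.outer(is_a.astype(float), shift) + z  # log2

    # unidentified junk features (no subtype signal, no library identity)
    n_junk = config.n_unidentified
    if n_junk:
        junk_mu = rng.uniform(14.0, 24.0, size=n_junk)
        junk = junk_mu[None, :] + rng.standard_normal((n, n_junk))
        latent = np.concatenate([latent, junk], axis=1)
    m_tot = latent.shape[1]

    # batch structure
    samples = clinical["id"].to_numpy()
    batch_of = rng.integers(0, config.n_batches, size=n)
    gamma = rng.normal(0.0, config.batch_shift_sd, (config.n_batches, m_tot)) \
        if config.batch_shift_sd > 0 else np.zeros((config.n_batches, m_tot))
    delta = np.exp(rng.normal(0.0, config.batch_scale_sd,
                              (config.n_batches, m_tot))) \
        if config.batch_scale_sd > 0 else np.ones((config.n_batches, m_tot))
    centered = latent - latent.mean(axis=0, keepdims=True)
    batched = (latent.mean(axis=0, keepdims=True) + gamma[batch_of]
               + delta[batch_of] * centered)

    # replicate technical noise: per-feature CV, a small irreproducible tail
    if config.replicate_cv > 0:
        cv = config.replicate_cv * np.exp(
            rng.normal(0.0, config.replicate_cv_spread, size=m_tot))
        if config.high_cv_rate > 0 and n_junk:
            # irreproducible features live among the unidentified signals;
            # level-1 library metabolites are analytically well-behaved
            bad = np.flatnonzero(rng.random(n_junk) < 10 * config.high_cv_rate)
            cv[m + bad] = 1.8 * np.exp(rng.normal(0.0, 0.2, size=bad.size))
        sigma_log2 = np.sqrt(np.log1p(cv ** 2)) / np.log(2.0)
    else:
        sigma_log2 = np.zeros(m_tot)
    reps = batched[:, :, None] + sigma_log2[None, :, None] * \
        rng.standard_normal((n, m_tot, 3))

    # MNAR detection: missingness is logistic in the sample-level log2
    # value about a per-feature detection threshold (each compound sits at
    # its own point of the instrument's dynamic range)
    if config.missing_rate > 0:
        thresh = np.quantile(batched, config.missing_rate, axis=0,
                             keepdims=True)
        p_sample = 1.0 / (1.0 + np.exp(config.mnar_strength * (batched - thresh)))
        drop_sample = rng.random((n, m_tot)) < p_sample
        drop_rep = rng.random((n, m_tot, 3)) < (p_sample[:, :, None] / 2.0)
        reps[drop_sample, :] = np.nan
        reps[drop_rep] = np.nan
    intens = np.power(2.0, reps)

    # feature metadata: library m/z and rt plus small measurement error
    lib = library.entries
    feat_mz = np.concatenate([
        lib["mz"].to_numpy() * (1 + rng.normal(0.0, 2.0, size=m) * 1e-6),
        rng.uniform(85.0, 1275.0, size=n_junk),
    ])
    feat_rt = np.concatenate([
        np.maximum(lib["rt"].to_numpy() + rng.normal(0.0, 5.0, size=m), 1.0),
        rng.uniform(10.0, 300.0, size=n_junk),
    ])
    feat_mode = np.concatenate([
        lib["mode"].to_numpy(),
        rng.choice([HILIC_POS, C18_NEG], size=n_junk),
    ])
    feature_ids = [f"F{j + 1:05d}" for j in range(m_tot)]
    features = pd.DataFrame(
        {"mz": feat_mz, "rt": feat_rt, "mode": feat_mode}, index=feature_ids)
    features.index.name = "feature_id"

    cols = pd.MultiIndex.from_product([list(samples), [1, 2, 3]],
                                      names=["sample", "replicate"])
    flat = intens.transpose(1, 0, 2).reshape(m_tot, n * 3)
    intensities = pd.DataFrame(flat, index=features.index, columns=cols)
    batches = pd.Series([f"B{b + 1}" for b in batch_of], index=samples,
                        name="batch")
    table = RawFeatureTable(features, intensities, batches)
    table.validate()
    return table


# ------------------------------------------------------------------ survival

def group_hazard(config: SimulationConfig, subtype: str, smoking: str) -> float:
    """Mortality hazard for a (subtype, smoking) group under the config."""
    lam = -np.log(config.baseline_3yr_survival) / 3.0
    if smoking == "Never":
        hr = config.hr_never_smoker * (
            config.hr_subtypeA_never if subtype == "A" else 1.0)
    else:
        hr = config.hr_subtypeA_smoker if subtype == "A" else 1.0
    return lam * hr


def generate_survival(clinical: pd.DataFrame,
                      config: SimulationConfig) -> pd.DataFrame:
    """Append overall- and progression-free-survival outcomes.

    Death times are exponential with a (subtype x smoking)-specific hazard;
    progression is an independent exponential at ``pfs_rate_multiplier``
    times the group mortality hazard, so PFS = min(progression, death).
    Administrative censoring is uniform over ``censor_window`` (None
    disables it) and a ``loss_to_followup`` fraction is flagged unfollowed.
    """
    config.validate()
    for col in ("true_subtype", "smoking"):
        if col not in clinical.columns:
            raise ValueError(f"clinical table lacks {col!r}")
    rng = _rng(config, "survival")
    n = len(clinical)
    lam = np.array([
        group_hazard(config, s, smk)
        for s, smk in zip(clinical["true_subtype"], clinical["smoking"])
    ])
    death = rng.exponential(1.0, size=n) / lam
    prog_lam = np.maximum(config.pfs_rate_multiplier * lam, 1e-12)
    progression = rng.exponential(1.0, size=n) / prog_lam
    if config.censor_window is not None:
        lo, hi = config.censor_window
        censor = rng.uniform(lo, hi, size=n)
    else:
        censor = np.full(n, np.inf)

    out = clinical.copy()
    out["os_time"] = np.minimum(death, censor)
    out["os_event"] = (death <= censor).astype(int)
    pfs_raw = np.minimum(progression, death)
    out["pfs_time"] = np.minimum(pfs_raw, censor)
    out["pfs_event"] = (pfs_raw <= censor).astype(int)
    out["followed"] = rng.random(n) >= config.loss_to_followup
    return out


# ------------------------------------------------------------------- cohort

@dataclass
class SimulatedCohort:
    clinical: pd.DataFrame
    raw: RawFeatureTable
    library: MetaboliteLibrary
    pathway_map: PathwayMap
    config: SimulationConfig


def generate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Full synthetic study: clinical + survival, metabolome, library, map."""
    clinical = generate_clinical(config)
    library = generate_library(config)
    pathway_map = generate_pathway_map(config, library)
    raw = generate_metabolome(clinical, pathway_map, config, library)
    clinical = generate_survival(clinical, config)
    return SimulatedCohort(clinical, raw, library, pathway_map, config)


def write_cohort(cohort: SimulatedCohort, outdir) -> dict:
    """Write the four study input files plus the resolved config."""
    from pathlib import Path
    from .enrichment import write_gmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "clinical": outdir / "clinical.csv",
        "features": outdir / "features.tsv",
        "library": outdir / "library.tsv",
        "pathways": outdir / "pathways.gmt",
        "config": outdir / "config.yaml",
    }
    cohort.clinical.to_csv(paths["clinical"], index=False)
    cohort.raw.to_tsv(paths["features"])
    cohort.library.to_tsv(paths["library"])
    write_gmt(cohort.pathway_map, paths["pathways"])
    cohort.config.to_yaml(paths["config"])
    return {k: str(v) for k, v in paths.items()}
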