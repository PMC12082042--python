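"""Seeded synthetic cohort and repertoire generator.

The study data (blood IGH BCR-seq in a COPD-enriched smoking/vaping
cohort) are controlled-access, so this module generates cohorts with the
same statistical structure the analysis assumes: per-participant
repertoires of unique IGH clones with isotype subclass labels, V-allele
assignments, junction sequences, per-sequence germline-mismatch counts,
and heavy-tailed clone read abundances, alongside a participant metadata
table whose covariate distributions approximate the published cohort
(group sizes 44 former / 41 never / 41 vaping / 51 cigarette / 57
dual-use; group-specific age, sex, race, pack-years, and GOLD spirometry
mixes).

Group effects are expressed per exposure group: an isotype mixture (the
default direction is dual > cigarette ~ vaping > former for IgA usage and
class switching, IgM reversed), mutation rates by switched status, a
clone-size skew parameter (larger -> heavier Zipf tail -> more clonal
expansion -> lower Hill diversity), and V-allele weights (the dual group
upweights IGHV5-51*01, IGHV1-18*01 and IGHV3-7*01). Magnitudes are
plausible defaults, not fits to the published effect sizes.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .io import (
    CLASS_SWITCHED,
    EXPOSURE_LEVELS,
    GOLD_LEVELS,
    ISOTYPE_TO_C_CALL,
    ISOTYPES,
    REARRANGEMENT_FIELDS,
)

log = logging.getLogger("ighrep")

GROUP_ORDER = ("former", "never", "vaping", "cigarette", "dual")

J_GENES = ("IGHJ1", "IGHJ2", "IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6")
J_WEIGHTS = (0.02, 0.03, 0.10, 0.35, 0.10, 0.40)

#: Default V-allele panel and baseline weights (must include the three
#: alleles the dual-use group perturbs).
DEFAULT_V_WEIGHTS = {
    "IGHV1-18*01": 0.07,
    "IGHV1-2*02": 0.15,
    "IGHV1-69*01": 0.08,
    "IGHV2-5*01": 0.05,
    "IGHV3-23*01": 0.12,
    "IGHV3-30*01": 0.09,
    "IGHV3-48*01": 0.06,
    "IGHV3-7*01": 0.07,
    "IGHV4-34*01": 0.10,
    "IGHV4-59*01": 0.08,
    "IGHV5-51*01": 0.09,
    "IGHV6-1*01": 0.04,
}

_DUAL_ENRICHED = ("IGHV5-51*01", "IGHV1-18*01", "IGHV3-7*01")

_CDR3_MEAN = {"IgM": 51, "IgD": 51, "IgA1": 48, "IgA2": 48,
              "IgG1": 48, "IgG2": 48, "IgG3": 51, "IgE": 54}
_CDR3_SD = {iso: 9.0 for iso in ISOTYPES}

_BASES_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


def _check_probs(name: str, probs: dict, tol: float = 1e-8) -> None:
    vals = np.array(list(probs.values()), dtype=float)
    if (vals < 0).any():
        raise ConfigError(f"{name}: negative probability")
    if abs(vals.sum() - 1.0) > tol:
        raise ConfigError(f"{name}: probabilities sum to {vals.sum():.6f}, not 1")


@dataclass(frozen=True)
class GroupEffectConfig:
    """Repertoire-generating parameters for one exposure group."""

    isotype_mixture: dict[str, float]
    switch_mutation_rate: float
    baseline_mutation_rate: float
    clone_size_shape: float
    v_allele_weights: dict[str, float]
    n_clones_mean: float
    cdr3_length_mean: dict[str, float] = field(default_factory=lambda: dict(_CDR3_MEAN))
    cdr3_length_sd: dict[str, float] = field(default_factory=lambda: dict(_CDR3_SD))

    def validate(self) -> None:
        _check_probs("isotype_mixture", self.isotype_mixture)
        if set(self.isotype_mixture) != set(ISOTYPES):
            raise ConfigError("isotype_mixture must cover the 8 subclasses")
        _check_probs("v_allele_weights", self.v_allele_weights)
        for rate in (self.switch_mutation_rate, self.baseline_mutation_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"mutation rate {rate} not in [0, 1]")
        if self.clone_size_shape <= 0:
            raise ConfigError("clone_size_shape must be > 0")
        if self.n_clones_mean <= 0:
            raise ConfigError("n_clones_mean must be > 0")


@dataclass(frozen=True)
class CovariateConfig:
    """Metadata-generating parameters for one exposure group."""

    age_mean: float
    age_sd: float
    male_frac: float
    nhw_frac: float
    pack_years_mean: float
    pack_years_sd: float
    gold_probs: dict[str, float]
    ics_prob: float

    def validate(self) -> None:
        _check_probs("gold_probs", self.gold_probs)
        if set(self.gold_probs) != set(GOLD_LEVELS):
            raise ConfigError("gold_probs must cover the 4 GOLD levels")
        for frac in (self.male_frac, self.nhw_frac, self.ics_prob):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"fraction {frac} not in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Full cohort specification: sizes, covariates, group effects, seed."""

    n_per_group: dict[str, int]
    seed: int
    group_effects: dict[str, GroupEffectConfig]
    covariates: dict[str, CovariateConfig]
    #: tilt of IgA mass (taken from IgM) per 25 pack-years above 40;
    #: 0 disables any covariate-driven repertoire effect.
    pack_years_iga_slope: float = 0.0

    def validate(self) -> None:
        for group, n in self.n_per_group.items():
            if group not in EXPOSURE_LEVELS:
                raise ConfigError(f"unknown exposure group {group!r}")
            if n < 1:
                raise ConfigError(f"group size for {group} must be >= 1")
        for group in self.n_per_group:
            if group not in self.group_effects:
                raise ConfigError(f"no group_effects for {group!r}")
            if group not in self.covariates:
                raise ConfigError(f"no covariates for {group!r}")
            self.group_effects[group].validate()
            self.covariates[group].validate()


# --- defaults (cohort-anchored covariates, direction-anchored effects) --

_BASE_MIX = {
    "former":    {"IgM": 0.42, "IgD": 0.070, "IgA1": 0.160, "IgA2": 0.065,
                  "IgG1": 0.140, "IgG2": 0.090, "IgG3": 0.045, "IgE": 0.010},
    "never":     {"IgM": 0.43, "IgD": 0.070, "IgA1": 0.155, "IgA2": 0.065,
                  "IgG1": 0.140, "IgG2": 0.085, "IgG3": 0.045, "IgE": 0.010},
    "vaping":    {"IgM": 0.38, "IgD": 0.060, "IgA1": 0.185, "IgA2": 0.080,
                  "IgG1": 0.150, "IgG2": 0.090, "IgG3": 0.045, "IgE": 0.010},
    "cigarette": {"IgM": 0.37, "IgD": 0.055, "IgA1": 0.190, "IgA2": 0.085,
                  "IgG1": 0.150, "IgG2": 0.095, "IgG3": 0.045, "IgE": 0.010},
    "dual":      {"IgM": 0.30, "IgD": 0.050, "IgA1": 0.225, "IgA2": 0.105,
                  "IgG1": 0.160, "IgG2": 0.100, "IgG3": 0.050, "IgE": 0.010},
}

_SWITCH_MUT = {"former": 0.75, "never": 0.72, "vaping": 0.78,
               "cigarette": 0.78, "dual": 0.85}
_BASE_MUT = {"former": 0.25, "never": 0.25, "vaping": 0.26,
             "cigarette": 0.26, "dual": 0.30}
_CLONE_SHAPE = {"former": 0.60, "never": 0.55, "vaping": 0.70,
                "cigarette": 0.70, "dual": 1.00}
_V_ENRICH = {"former": 1.0, "never": 1.0, "vaping": 1.2, "cigarette": 1.2,
             "dual": 1.5}

_COVARIATES = {
    #          age (mean, sd)  male  nhw   pack-years     gold probs (norm, g1, g2_4, prism)  ics
    "former":    (69.6, 7.42, 0.477, 0.864, 43.0, 23.3, (0.341, 0.136, 0.477, 0.046), 0.35),
    "never":     (65.3, 9.96, 0.293, 0.951, 0.0, 0.0, (0.952, 0.000, 0.024, 0.024), 0.05),
    "vaping":    (64.4, 6.56, 0.366, 0.902, 52.2, 24.6, (0.463, 0.122, 0.317, 0.098), 0.25),
    "cigarette": (62.0, 7.21, 0.392, 0.451, 48.5, 27.8, (0.431, 0.059, 0.392, 0.118), 0.30),
    "dual":      (61.3, 6.47, 0.491, 0.737, 52.9, 25.3, (0.333, 0.105, 0.509, 0.053), 0.40),
}

DEFAULT_N_PER_GROUP = {"former": 44, "never": 41, "vaping": 41,
                       "cigarette": 51, "dual": 57}

DEFAULT_N_CLONES_MEAN = 300.0


def _scaled_v_weights(factor: float) -> dict[str, float]:
    w = dict(DEFAULT_V_WEIGHTS)
    for allele in _DUAL_ENRICHED:
        w[allele] *= factor
    total = sum(w.values())
    return {a: v / total for a, v in w.items()}


def default_group_effects(
    n_clones_mean: float = DEFAULT_N_CLONES_MEAN, null: bool = False
) -> dict[str, GroupEffectConfig]:
    """Per-group effect configs; ``null=True`` gives every group the
    former-smoker parameters (no group differences)."""
    out = {}
    for group in GROUP_ORDER:
        src = "former" if null else group
        out[group] = GroupEffectConfig(
            isotype_mixture=dict(_BASE_MIX[src]),
            switch_mutation_rate=_SWITCH_MUT[src],
            baseline_mutation_rate=_BASE_MUT[src],
            clone_size_shape=_CLONE_SHAPE[src],
            v_allele_weights=_scaled_v_weights(_V_ENRICH[src]),
            n_clones_mean=n_clones_mean,
        )
    return out


def default_covariates() -> dict[str, CovariateConfig]:
    out = {}
    for group, (am, asd, male, nhw, pym, pysd, gold, ics) in _COVARIATES.items():
        out[group] = CovariateConfig(
            age_mean=am, age_sd=asd, male_frac=male, nhw_frac=nhw,
            pack_years_mean=pym, pack_years_sd=pysd,
            gold_probs=dict(zip(GOLD_LEVELS, gold)), ics_prob=ics,
        )
    return out


def default_cohort_config(
    seed: int = 0,
    n_per_group: dict[str, int] | None = None,
    n_clones_mean: float = DEFAULT_N_CLONES_MEAN,
    null_effects: bool = False,
    pack_years_iga_slope: float = 0.0,
) -> CohortConfig:
    """The default study-like cohort configuration."""
    return CohortConfig(
        n_per_group=dict(n_per_group or DEFAULT_N_PER_GROUP),
        seed=seed,
        group_effects=default_group_effects(n_clones_mean, null=null_effects),
        covariates=default_covariates(),
        pack_years_iga_slope=pack_years_iga_slope,
    )


# --- config (de)serialization -------------------------------------------


def cohort_config_to_dict(config: CohortConfig) -> dict:
    return dataclasses.asdict(config)


def cohort_config_from_dict(d: dict) -> CohortConfig:
    try:
        cfg = CohortConfig(
            n_per_group={k: int(v) for k, v in d["n_per_group"].items()},
            seed=int(d["seed"]),
            group_effects={
                g: GroupEffectConfig(**e) for g, e in d["group_effects"].items()
            },
            covariates={
                g: CovariateConfig(**c) for g, c in d["covariates"].items()
            },
            pack_years_iga_slope=float(d.get("pack_years_iga_slope", 0.0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed cohort config: {exc}") from exc
    cfg.validate()
    return cfg


def load_cohort_config(path) -> CohortConfig:
    """Load a cohort config from a YAML file."""
    with open(path) as fh:
        try:
            d = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config file: {exc}") from exc
    if not isinstance(d, dict):
        raise ConfigError("config file is not a mapping")
    return cohort_config_from_dict(d)


def save_cohort_config(config: CohortConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cohort_config_to_dict(config), fh, sort_keys=True)


# --- repertoire simulation ----------------------------------------------


def _tilted_mixture(mix: np.ndarray, iga_shift: float) -> np.ndarray:
    """Move ``iga_shift`` probability mass from IgM into IgA1/IgA2."""
    if iga_shift == 0.0:
        return mix
    out = mix.copy()
    i_m = ISOTYPES.index("IgM")
    i_a1, i_a2 = ISOTYPES.index("IgA1"), ISOTYPES.index("IgA2")
    iga = out[i_a1] + out[i_a2]
    shift = np.clip(iga_shift, -0.9 * iga, 0.9 * out[i_m])
    out[i_a1] += shift * out[i_a1] / iga
    out[i_a2] += shift * out[i_a2] / iga
    out[i_m] -= shift
    return out / out.sum()


def simulate_repertoire(
    participant_id: str,
    effects: GroupEffectConfig,
    rng: np.random.Generator,
    iga_shift: float = 0.0,
) -> pd.DataFrame:
    """Rearrangement rows for one participant.

    Clone count ~ Poisson(n_clones_mean); per clone one isotype, one V
    allele, one J gene, a random junction whose length is a multiple of 3
    ~ Normal(per-subclass mean, sd) truncated at 9 nt, a mutated flag ~
    Bernoulli(rate by switched status) realized as mutation_count ~
    1 + Poisson(2), and a read abundance ~ Zipf(1 + 1/clone_size_shape).
    Mutated multi-read clones may be emitted as several rows carrying
    slightly diverged junction variants whose duplicate_counts sum to the
    clone abundance — this is what clonal grouping later undoes.
    """
    effects.validate()
    n = max(1, int(rng.poisson(effects.n_clones_mean)))
    mix = np.array([effects.isotype_mixture[i] for i in ISOTYPES])
    mix = _tilted_mixture(mix / mix.sum(), iga_shift)
    iso_idx = rng.choice(len(ISOTYPES), size=n, p=mix)

    alleles = sorted(effects.v_allele_weights)
    w = np.array([effects.v_allele_weights[a] for a in alleles])
    v_idx = rng.choice(len(alleles), size=n, p=w / w.sum())
    j_idx = rng.choice(len(J_GENES), size=n, p=np.array(J_WEIGHTS))

    mu = np.array([effects.cdr3_length_mean[i] for i in ISOTYPES])[iso_idx]
    sd = np.array([effects.cdr3_length_sd[i] for i in ISOTYPES])[iso_idx]
    lengths = np.clip(np.rint(rng.normal(mu, sd) / 3.0).astype(int) * 3, 9, 99)

    iso_arr = np.array(ISOTYPES, dtype=object)[iso_idx]
    switched = np.isin(iso_arr.astype(str), sorted(CLASS_SWITCHED))
    p_mut = np.where(switched, effects.switch_mutation_rate,
                     effects.baseline_mutation_rate)
    mutated = rng.random(n) < p_mut
    mut_counts = np.where(mutated, 1 + rng.poisson(2.0, size=n), 0)

    a_exp = 1.0 + 1.0 / effects.clone_size_shape
    abundance = np.minimum(rng.zipf(a_exp, size=n), 10_000)

    n_extra = np.where(mutated, rng.poisson(0.35, size=n), 0)
    n_extra = np.minimum(n_extra, abundance - 1)

    offsets = np.concatenate([[0], np.cumsum(lengths)])
    codes = rng.integers(0, 4, size=int(offsets[-1]), dtype=np.uint8)
    buf = _BASES_ASCII[codes].tobytes()

    seq_ids, pids, v_calls, j_calls, c_calls = [], [], [], [], []
    junctions, jlens, mcounts, dups = [], [], [], []
    for i in range(n):
        junction = buf[offsets[i]:offsets[i + 1]].decode("ascii")
        base_id = f"{participant_id}.{i:05d}"
        extras = int(n_extra[i])
        seq_ids.append(base_id)
        junctions.append(junction)
        mcounts.append(int(mut_counts[i]))
        dups.append(int(abundance[i]) - extras)
        for r in range(extras):
            jarr = np.frombuffer(junction.encode("ascii"), dtype=np.uint8).copy()
            max_sub = max(1, int(0.06 * len(jarr)))
            k_sub = min(1 + int(rng.poisson(0.4)), max_sub)
            pos = rng.choice(len(jarr), size=k_sub, replace=False)
            jarr[pos] = _BASES_ASCII[
                (np.searchsorted(_BASES_ASCII, jarr[pos]) + rng.integers(1, 4, k_sub)) % 4
            ]
            seq_ids.append(f"{base_id}.{r + 1}")
            junctions.append(jarr.tobytes().decode("ascii"))
            mcounts.append(1 + int(rng.poisson(2.0)))
            dups.append(1)
        reps = 1 + extras
        pids.extend([participant_id] * reps)
        v_calls.extend([alleles[v_idx[i]]] * reps)
        j_calls.extend([J_GENES[j_idx[i]]] * reps)
        c_calls.extend([ISOTYPE_TO_C_CALL[iso_arr[i]]] * reps)
        jlens.extend([int(lengths[i])] * reps)

    return pd.DataFrame(
        {
            "sequence_id": seq_ids,
            "participant_id": pids,
            "v_call": v_calls,
            "j_call": j_calls,
            "c_call": c_calls,
            "junction": junctions,
            "junction_length": jlens,
            "mutation_count": mcounts,
            "duplicate_count": dups,
        },
        columns=list(REARRANGEMENT_FIELDS),
    )


# --- cohort simulation --------------------------------------------------


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (metadata, rearrangements) for a whole cohort.

    Deterministic given the config (which includes the seed): the same
    config always yields byte-identical tables.
    """
    config.validate()
    groups = [g for g in GROUP_ORDER if g in config.n_per_group]
    n_total = sum(config.n_per_group[g] for g in groups)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(n_total + 1)
    rng_meta = np.random.default_rng(children[0])

    meta_rows = []
    repertoires = []
    serial = 0
    for group in groups:
        cov = config.covariates[group]
        eff = config.group_effects[group]
        for _ in range(config.n_per_group[group]):
            pid = f"P{serial:04d}"
            age = float(np.clip(rng_meta.normal(cov.age_mean, cov.age_sd), 45, 90))
            sex = int(rng_meta.random() < cov.male_frac)
            race = int(rng_meta.random() < cov.nhw_frac)
            if group == "never":
                pack_years = 0.0
            else:
                pack_years = float(
                    np.clip(rng_meta.normal(cov.pack_years_mean, cov.pack_years_sd),
                            10.0, 150.0)
                )
            gold = rng_meta.choice(
                GOLD_LEVELS, p=[cov.gold_probs[g] for g in GOLD_LEVELS]
            )
            ics = bool(rng_meta.random() < cov.ics_prob)
            income = int(rng_meta.integers(1, 7))
            deprivation = float(np.clip(rng_meta.normal(50, 20), 1, 100))
            ct_emph = float(abs(rng_meta.normal(3.5, 4.0)))
            ct_wall = float(rng_meta.normal(50.0, 8.0))
            scanner = str(rng_meta.choice(("modelA", "modelB")))
            pc1 = float((race - 0.5) * 2 + rng_meta.normal(0, 0.5))
            pc2 = float(rng_meta.normal(0, 1))
            pc3 = float(rng_meta.normal(0, 1))
            meta_rows.append(
                dict(
                    participant_id=pid, exposure_group=group,
                    age=round(age, 1), sex=sex, race=race,
                    pack_years=round(pack_years, 1), gold_group=gold,
                    ics_use=ics, income_level=income,
                    deprivation_index=round(deprivation, 1),
                    ct_emphysema_pct=round(ct_emph, 2),
                    ct_wall_area_pct=round(ct_wall, 2), ct_scanner=scanner,
                    oral_steroids=False,
                    pc1=round(pc1, 4), pc2=round(pc2, 4), pc3=round(pc3, 4),
                )
            )
            iga_shift = config.pack_years_iga_slope * (pack_years - 40.0) / 25.0
            rng_rep = np.random.default_rng(children[serial + 1])
            repertoires.append(
                simulate_repertoire(pid, eff, rng_rep, iga_shift=iga_shift)
            )
            serial += 1

    metadata = pd.DataFrame(meta_rows)
    rearrangements = pd.concat(repertoires, ignore_index=True)
    log.info(
        "simulated cohort: %d participants, %d rearrangement rows",
        len(metadata), len(rearrangements),
    )
    return metadata, rearrangements
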