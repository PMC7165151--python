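"""Synthetic expression / clinical / mutation cohorts with known ground truth.

The generator emulates the statistical structure the signature analysis
assumes: three latent expression groups — normal-like (N), intestinal-like
(INT) and core diffuse-type (COD) — with group-specific gene modules (a
proliferation-like module up in INT, an EMT-like module up in COD),
subtype-dependent proportional-hazards survival with independent
right-censoring, a chemotherapy benefit concentrated in the COD subtype,
and overdispersed mutation counts that are higher in INT, with designated
marker loci (a MUC16-like gene enriched in COD, PIK3CA/ARID1A-like genes
enriched in INT).

All randomness flows through one ``numpy`` Generator seeded from the config,
drawn in a fixed documented order, so identical configs give bit-identical
cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import ConfigError, ValidationError
from .io import CohortAnnotation, ExpressionMatrix, MutationTable
import pandas as pd

__all__ = ["SimulationConfig", "GroundTruth", "simulate_cohort", "simulate_survival"]

_VARIANT_CLASSES = ("missense", "nonsense", "frameshift", "splice_site")
_VARIANT_PROBS = (0.75, 0.10, 0.10, 0.05)

# molecular-subtype mixtures per latent group (shaped after the TCGA
# composition the signature contrasts: MSI/EBV concentrate in INT, GS in COD)
_MOL_PROBS = {
    "INT": (("MSI", 0.25), ("EBV", 0.15), ("CIN", 0.50), ("GS", 0.10)),
    "COD": (("MSI", 0.03), ("EBV", 0.07), ("CIN", 0.50), ("GS", 0.40)),
    "N": (("MSI", 0.05), ("EBV", 0.10), ("CIN", 0.55), ("GS", 0.30)),
}


def _default_markers() -> dict[str, tuple[float, float]]:
    # gene -> (freq in INT-like, freq in COD-like) diffuse tumors
    return {
        "MUC16": (0.15, 0.40),
        "PIK3CA": (0.30, 0.05),
        "ARID1A": (0.25, 0.04),
    }


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator; defaults mirror the derivation study.

    Sample counts default to the original-cohort composition (20 normal, 23
    intestinal-type, 107 diffuse-type tumors); module sizes default to the 252
    INT-associated and 397 COD-associated genes of the discovery heatmap;
    per-subtype chemotherapy hazard ratios default to 0.333 (COD) and 0.576
    (INT).  Hazards are per month.
    """

    n_normal: int = 20
    n_intestinal: int = 23
    n_diffuse: int = 107
    n_genes: int = 2000
    n_int_module: int = 252
    n_cod_module: int = 397
    effect_size: float = 1.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    diffuse_subtype_props: tuple[float, float, float] = (0.2, 0.3, 0.5)
    normal_contamination: float = 0.9
    baseline_hazard: float = 0.02
    true_hr_cod: float = 2.0
    age_hr: float = 1.02
    stage_hr: float = 2.5
    weibull_shape: float = 1.0
    censor_rate: float = 0.01
    followup_horizon: float = math.inf
    chemo_assign_prob: float = 0.5
    chemo_hr_cod: float = 0.333
    chemo_hr_int: float = 0.576
    tmb_mean_int: float = 8.0
    tmb_mean_cod: float = 2.0
    tmb_dispersion: float = 2.0
    marker_gene_freqs: dict[str, tuple[float, float]] = field(
        default_factory=_default_markers
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_normal", "n_intestinal", "n_diffuse", "n_genes",
                     "n_int_module", "n_cod_module"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_int_module + self.n_cod_module > self.n_genes:
            raise ConfigError(
                f"module sizes {self.n_int_module}+{self.n_cod_module} exceed "
                f"n_genes={self.n_genes}"
            )
        props = tuple(float(p) for p in self.diffuse_subtype_props)
        if len(props) != 3 or any(p < 0 for p in props) or \
                not math.isclose(sum(props), 1.0, abs_tol=1e-9):
            raise ConfigError(
                f"diffuse_subtype_props must be 3 nonnegative values summing to 1, "
                f"got {props}"
            )
        self.diffuse_subtype_props = props
        if not 0.0 <= self.normal_contamination <= 1.0:
            raise ConfigError("normal_contamination must be in [0, 1]")
        for name in ("baseline_hazard", "true_hr_cod", "chemo_hr_cod",
                     "chemo_hr_int", "weibull_shape", "age_hr", "stage_hr"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("noise_sd", "censor_rate", "tmb_mean_int", "tmb_mean_cod",
                     "tmb_dispersion"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if not 0.0 <= self.chemo_assign_prob <= 1.0:
            raise ConfigError("chemo_assign_prob must be in [0, 1]")
        for g, (fi, fc) in self.marker_gene_freqs.items():
            if not (0.0 <= fi <= 1.0 and 0.0 <= fc <= 1.0):
                raise ConfigError(f"marker frequencies for {g!r} must be in [0, 1]")

    def to_dict(self) -> dict:
        out = asdict(self)
        out["diffuse_subtype_props"] = list(self.diffuse_subtype_props)
        out["marker_gene_freqs"] = {
            g: list(v) for g, v in self.marker_gene_freqs.items()
        }
        if math.isinf(self.followup_horizon):
            out["followup_horizon"] = None
        return out


@dataclass
class GroundTruth:
    """Oracle for recovery tests: latent labels and planted module genes."""

    latent_subtype: dict[str, str]
    int_module_genes: list[str]
    cod_module_genes: list[str]
    marker_genes: list[str]

    def __post_init__(self) -> None:
        if set(self.int_module_genes) & set(self.cod_module_genes):
            raise ValidationError("module gene lists must be disjoint")

    def labels_for(self, sample_ids: Sequence[str]) -> list[str]:
        return [self.latent_subtype[s] for s in sample_ids]


def _event_times(rng: np.random.Generator, hazards: np.ndarray,
                 shape: float) -> np.ndarray:
    """Proportional-hazards event times: H(t) = h * t^shape."""
    e = rng.exponential(1.0, size=hazards.size)
    return (e / hazards) ** (1.0 / shape)


def simulate_survival(labels: Sequence[str], config: SimulationConfig,
                      rng: np.random.Generator | None = None,
                      chemo: Sequence[bool] | None = None,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Survival block alone: (times, events, chemo flags) for INT/COD labels.

    The hazard for sample i is ``baseline_hazard * true_hr_cod^[COD_i] *
    chemo_hr_subtype^[treated_i]``; event times follow a Weibull with the
    configured shape (exponential at shape 1), censoring is an independent
    exponential clipped at the administrative follow-up horizon.

    Draw order: chemo flags (unless supplied), event times, censoring times.
    """
    labels = list(labels)
    if not labels:
        raise ValidationError("empty label vector")
    bad = sorted(set(labels) - {"INT", "COD"})
    if bad:
        raise ValidationError(f"labels must be INT or COD; got {bad}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = len(labels)
    is_cod = np.array([lab == "COD" for lab in labels])
    if chemo is None:
        chemo_arr = rng.random(n) < config.chemo_assign_prob
    else:
        chemo_arr = np.asarray(chemo, dtype=bool)
        if chemo_arr.size != n:
            raise ValidationError("chemo flags must match the label vector")
    chemo_hr = np.where(is_cod, config.chemo_hr_cod, config.chemo_hr_int)
    hazards = config.baseline_hazard * np.where(is_cod, config.true_hr_cod, 1.0)
    hazards = hazards * np.where(chemo_arr, chemo_hr, 1.0)
    t_event = _event_times(rng, hazards, config.weibull_shape)
    if config.censor_rate > 0:
        t_censor = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        t_censor = np.full(n, np.inf)
    t_censor = np.minimum(t_censor, config.followup_horizon)
    times = np.minimum(t_event, t_censor)
    events = t_event <= t_censor
    if not np.all(np.isfinite(times)):
        raise ValidationError(
            "non-finite follow-up time; set censor_rate > 0 or a finite "
            "followup_horizon when the event hazard can vanish"
        )
    return times, events, chemo_arr


def simulate_cohort(config: SimulationConfig) -> tuple[
        ExpressionMatrix, list[CohortAnnotation], MutationTable, GroundTruth]:
    """Generate one full cohort (expression, clinical, mutations, truth).

    Draw order from the single seeded stream: (1) per-gene baseline means,
    (2) latent diffuse subtypes, (3) expression noise, (4) demographics /
    stage / site / PCC, (5) chemotherapy flags, (6) survival event times,
    (7) censoring, (8) molecular subtypes, (9) mutation counts, (10) mutated
    gene draws and variant classes.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    int_module = gene_ids[: config.n_int_module]
    cod_module = gene_ids[config.n_int_module:
                          config.n_int_module + config.n_cod_module]

    sample_ids = (
        [f"N{i + 1:03d}" for i in range(config.n_normal)]
        + [f"I{i + 1:03d}" for i in range(config.n_intestinal)]
        + [f"D{i + 1:03d}" for i in range(config.n_diffuse)]
    )
    histology = (["normal"] * config.n_normal
                 + ["intestinal"] * config.n_intestinal
                 + ["diffuse"] * config.n_diffuse)

    # (1) gene baselines
    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          size=config.n_genes)

    # (2) latent subtype per sample; diffuse tumors split into the three
    # latent groups by the configured proportions
    latent = ["N"] * config.n_normal + ["INT"] * config.n_intestinal
    latent += list(rng.choice(["N", "INT", "COD"], size=config.n_diffuse,
                              p=config.diffuse_subtype_props))
    latent_arr = np.array(latent)

    # module mean shifts per sample; normal-like diffuse tumors are a
    # contamination mixture of normal and COD profiles
    n_samples = len(sample_ids)
    shifts = np.zeros((config.n_genes, n_samples))
    is_int = latent_arr == "INT"
    is_cod = latent_arr == "COD"
    is_nlike_diffuse = (latent_arr == "N") & (np.array(histology) == "diffuse")
    int_idx = slice(0, config.n_int_module)
    cod_idx = slice(config.n_int_module, config.n_int_module + config.n_cod_module)
    shifts[int_idx, :] += config.effect_size * is_int
    shifts[cod_idx, :] += config.effect_size * is_cod
    shifts[cod_idx, :] += (config.effect_size
                           * (1.0 - config.normal_contamination)
                           * is_nlike_diffuse)

    # (3) expression noise
    values = baseline[:, None] + shifts
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    expr = ExpressionMatrix(gene_ids, sample_ids, values)

    # (4) demographics and pathology (independent of survival except via the
    # configured age/stage hazard effects below)
    age = np.clip(rng.normal(60.0, 10.0, size=n_samples), 30.0, 90.0).round(1)
    sex = np.where(rng.random(n_samples) < 0.6, "male", "female")
    stage = rng.choice([1, 2, 3, 4], size=n_samples, p=[0.15, 0.30, 0.35, 0.20])
    site = rng.choice(["cardia", "body", "antrum", "whole"], size=n_samples)
    pcc_prob = np.where(is_cod, 0.5, 0.15)
    pcc = rng.random(n_samples) < pcc_prob

    # (5)-(7) treatment and survival for tumor samples (diffuse + intestinal);
    # normal tissues carry no survival.  Normal-like diffuse tumors take the
    # INT (baseline) hazard.
    is_tumor = np.array(histology) != "normal"
    surv_labels = np.where(is_cod, "COD", "INT")
    chemo = rng.random(n_samples) < config.chemo_assign_prob
    chemo &= is_tumor
    chemo_hr = np.where(is_cod, config.chemo_hr_cod, config.chemo_hr_int)
    hazards = config.baseline_hazard * np.where(is_cod, config.true_hr_cod, 1.0)
    hazards = hazards * np.where(chemo, chemo_hr, 1.0)
    hazards = hazards * config.age_hr ** (age - 60.0)
    hazards = hazards * config.stage_hr ** (stage - 2.0)
    t_event = _event_times(rng, hazards, config.weibull_shape)
    if config.censor_rate > 0:
        t_censor = rng.exponential(1.0 / config.censor_rate, size=n_samples)
    else:
        t_censor = np.full(n_samples, np.inf)
    t_censor = np.minimum(t_censor, config.followup_horizon)
    os_time = np.minimum(t_event, t_censor)
    os_event = t_event <= t_censor
    if is_tumor.any() and not np.all(np.isfinite(os_time[is_tumor])):
        raise ValidationError(
            "non-finite follow-up time; set censor_rate > 0 or a finite "
            "followup_horizon"
        )

    # (8) molecular subtypes for diffuse tumors
    mol: list[str | None] = [None] * n_samples
    for i in range(n_samples):
        if histology[i] == "diffuse":
            names, probs = zip(*_MOL_PROBS[latent[i]])
            mol[i] = str(rng.choice(names, p=probs))

    # (9)-(10) mutations for diffuse tumors: a negative-binomial background
    # count over non-marker genes plus per-subtype Bernoulli marker loci
    marker_genes = list(config.marker_gene_freqs)
    background_genes = np.array([g for g in gene_ids if g not in marker_genes])
    records: list[dict[str, str]] = []
    theta = config.tmb_dispersion
    for i in range(n_samples):
        if histology[i] != "diffuse":
            continue
        sid = sample_ids[i]
        mean = config.tmb_mean_cod if latent[i] == "COD" else config.tmb_mean_int
        if mean > 0:
            if theta > 0:
                count = int(rng.negative_binomial(theta, theta / (theta + mean)))
            else:
                count = int(rng.poisson(mean))
        else:
            count = 0
        count = min(count, background_genes.size)
        hit = rng.choice(background_genes, size=count, replace=False)
        classes = rng.choice(_VARIANT_CLASSES, size=count, p=_VARIANT_PROBS)
        records.extend(
            {"sample_id": sid, "gene_id": str(g), "variant_class": str(vc)}
            for g, vc in zip(hit, classes)
        )
        for g in marker_genes:
            fi, fc = config.marker_gene_freqs[g]
            freq = fc if latent[i] == "COD" else fi
            if rng.random() < freq:
                vc = str(rng.choice(_VARIANT_CLASSES, p=_VARIANT_PROBS))
                records.append({"sample_id": sid, "gene_id": g,
                                "variant_class": vc})
    mut = MutationTable(pd.DataFrame(
        records, columns=["sample_id", "gene_id", "variant_class"]))

    annotations = []
    for i, sid in enumerate(sample_ids):
        tumor = bool(is_tumor[i])
        annotations.append(CohortAnnotation(
            sample_id=sid,
            histology=histology[i],
            pcc=bool(pcc[i]) if tumor else None,
            age=float(age[i]),
            sex=str(sex[i]),
            ajcc_stage=int(stage[i]) if tumor else None,
            tumor_site=str(site[i]) if tumor else None,
            chemo=bool(chemo[i]) if tumor else None,
            os_time=float(os_time[i]) if tumor else None,
            os_event=bool(os_event[i]) if tumor else None,
            dfs_time=float(os_time[i]) if tumor else None,
            dfs_event=bool(os_event[i]) if tumor else None,
            molecular_subtype=mol[i],
            extras={"latent_subtype": latent[i],
                    "survival_label": str(surv_labels[i]) if tumor else None},
        ))
    truth = GroundTruth(
        latent_subtype=dict(zip(sample_ids, latent)),
        int_module_genes=int_module,
        cod_module_genes=cod_module,
        marker_genes=marker_genes,
    )
    return expr, annotations, mut, truth


def simulate_mutation_counts(rng: np.random.Generator, n_int: int, n_cod: int,
                             config: SimulationConfig
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Raw mutation-burden draws per arm (INT, COD) — the TMB block alone."""
    theta = config.tmb_dispersion

    def draw(mean: float, n: int) -> np.ndarray:
        if mean == 0:
            return np.zeros(n, dtype=int)
        if theta > 0:
            return rng.negative_binomial(theta, theta / (theta + mean), size=n)
        return rng.poisson(mean, size=n)

    return draw(config.tmb_mean_int, n_int), draw(config.tmb_mean_cod, n_cod)
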