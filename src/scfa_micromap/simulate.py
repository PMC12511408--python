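"""Synthetic IBS cohort generator with known microbe-SCFA ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, with every causal ingredient planted explicitly so recovery can
be scored:

* three clinical groups (HV, IBS-C, IBS-D) with realistic sizes;
* colonic transit time, log-normal per group, acting as a confounder: it
  shifts both taxon log-abundances (sparse slopes ``delta``) and SCFA
  concentrations (slopes ``gamma``);
* a logistic-normal species composition: latent log-abundance =
  base skeleton + delta * transit + Gaussian noise, row-softmaxed onto the
  simplex (heavy right-skew comes from the log-normal skeleton);
* "driver" taxa with signed loadings ``beta`` onto individual SCFAs,
  acting through the taxon's ALR value net of transit, so that the
  microbe-SCFA coupling survives conditioning on transit;
* Gaussian measurement noise on SCFA, truncated at zero by resampling.

Trait scales target the magnitudes seen in adult IBS cohorts (total stool
SCFA median ~10 ug/mg, transit ~1 day, stool bile acids in the hundreds of
umol/48h); these are plausible defaults, not assertions about any dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .tables import AbundanceTable, CohortMetadata, GMMDefinition

SCFA_NAMES = ("acetate", "butyrate", "propionate")

# Group-level trait anchors (medians of log-normal distributions).
_TRANSIT_MEDIAN = {"HV": 1.4, "IBS-C": 1.5, "IBS-D": 0.9}  # days
_BILE_TOTAL_MEDIAN = {"HV": 342.0, "IBS-C": 190.0, "IBS-D": 607.0}  # umol/48h
_SCFA_INTERCEPT = {"acetate": 9.5, "butyrate": 2.4, "propionate": 2.7}  # ug/mg


@dataclass(frozen=True)
class Driver:
    """A planted taxon -> SCFA effect: ``beta`` on the ALR scale."""

    taxon_index: int
    scfa: str
    beta: float

    def __post_init__(self) -> None:
        if self.scfa not in SCFA_NAMES:
            raise ConfigError(f"driver target {self.scfa!r} is not an SCFA")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    Defaults encode the study conditions the pipeline targets: HV/IBS-C/
    IBS-D groups of 17/15/26, 120 species, six planted drivers (one
    positive and one negative per SCFA, |beta| = 2 on the ALR scale),
    transit slopes gamma (SCFA per day) and delta (log-abundance per day)
    that make transit a genuine confounder, and unit-scale noise.
    """

    n_per_group: tuple[tuple[str, int], ...] = (("HV", 17), ("IBS-C", 15), ("IBS-D", 26))
    p_taxa: int = 120
    drivers: tuple[Driver, ...] = (
        Driver(0, "acetate", 0.5),
        Driver(1, "acetate", -0.5),
        Driver(2, "butyrate", 0.3),
        Driver(3, "butyrate", -0.3),
        Driver(4, "propionate", 0.3),
        Driver(5, "propionate", -0.3),
    )
    gamma: tuple[tuple[str, float], ...] = (
        ("acetate", -1.5),
        ("butyrate", -0.3),
        ("propionate", -0.3),
    )
    n_delta_taxa: int = 12
    delta_scale: float = 0.8
    base_logmean_sd: float = 1.0
    dispersion: float = 0.35
    driver_dispersion: float = 2.4
    driver_base_logmean: float | None = -1.2
    scfa_noise: float = 0.25
    transit_log_sd: float = 0.45
    count_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_taxa < 10:
            raise ConfigError("p_taxa must be >= 10")
        if self.dispersion <= 0 or self.scfa_noise <= 0:
            raise ConfigError("noise scales must be > 0")
        if not self.n_per_group or any(n < 1 for _, n in self.n_per_group):
            raise ConfigError("every included group needs >= 1 sample")
        for d in self.drivers:
            if not 0 <= d.taxon_index < self.p_taxa - 1:
                raise ConfigError(
                    f"driver index {d.taxon_index} out of range "
                    f"(taxon {self.p_taxa - 1} is the internal ALR reference)"
                )
        if self.n_delta_taxa > self.p_taxa - 1 - len(self.drivers):
            raise ConfigError("too many transit-affected taxa for p_taxa")

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery scoring."""

    drivers: list[Driver]
    gamma: dict[str, float]
    delta: np.ndarray  # per-taxon transit slope on the latent log scale
    latent_logs: pd.DataFrame  # per-sample latent log-abundances
    reference_index: int  # internal ALR reference taxon
    taxon_ids: list[str]

    def driver_ids(self, scfa: str | None = None) -> list[str]:
        return [
            self.taxon_ids[d.taxon_index]
            for d in self.drivers
            if scfa is None or d.scfa == scfa
        ]

    def driver_sign(self, taxon_id: str, scfa: str) -> int:
        for d in self.drivers:
            if self.taxon_ids[d.taxon_index] == taxon_id and d.scfa == scfa:
                return int(np.sign(d.beta))
        raise KeyError(f"{taxon_id!r} is not a driver of {scfa!r}")


def _truncated_normal(rng: np.random.Generator, mean: np.ndarray, sd: float) -> np.ndarray:
    """Normal(mean, sd) truncated at 0 by resampling (no point mass at 0)."""
    out = rng.normal(mean, sd)
    for _ in range(1000):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean[bad], sd)
    # Pathological mean far below zero: fall back to folding.
    return np.abs(out)


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[AbundanceTable, CohortMetadata, GroundTruth]:
    """Draw one cohort; deterministic given ``config`` (including its seed)."""
    rng = np.random.default_rng(config.seed)
    groups = [g for g, n in config.n_per_group for _ in range(n)]
    n = len(groups)
    p = config.p_taxa
    taxon_ids = [f"taxon_{j:04d}" for j in range(p)]
    sample_ids = []
    counts: dict[str, int] = {}
    for g in groups:
        counts[g] = counts.get(g, 0) + 1
        sample_ids.append(f"{g}_{counts[g]:03d}")

    # Log-abundance skeleton: heavy right-skew on the relative scale.
    base = rng.normal(0.0, config.base_logmean_sd, size=p)
    if config.driver_base_logmean is not None and config.drivers:
        # Pin drivers to a common skeleton level: comparable, moderately
        # abundant fermenters rather than a lottery over the skew.
        base[sorted({d.taxon_index for d in config.drivers})] = config.driver_base_logmean

    # Transit-affected taxa: disjoint from drivers and from the internal
    # ALR reference (the last taxon), so driver couplings stay net of transit.
    driver_idx = sorted({d.taxon_index for d in config.drivers})
    free = [j for j in range(p - 1) if j not in driver_idx]
    delta = np.zeros(p)
    delta_idx = free[: config.n_delta_taxa]
    signs = np.where(np.arange(config.n_delta_taxa) % 2 == 0, 1.0, -1.0)
    delta[delta_idx] = signs * config.delta_scale

    transit = np.empty(n)
    for g in set(groups):
        mask = np.array([gi == g for gi in groups])
        transit[mask] = np.exp(
            rng.normal(np.log(_TRANSIT_MEDIAN[g]), config.transit_log_sd, mask.sum())
        )

    eps = rng.normal(0.0, config.dispersion, size=(n, p))
    # Driver taxa fluctuate more (strain-bloom variability of SCFA
    # producers), which also gives them the chi-square inertia a real
    # fermenter signal carries in the ordination.
    if driver_idx and config.driver_dispersion != config.dispersion:
        eps[:, driver_idx] *= config.driver_dispersion / config.dispersion
    latent = base[None, :] + np.outer(transit, delta) + eps
    # Composition: row softmax of the latent logs.
    shifted = latent - latent.max(axis=1, keepdims=True)
    comp = np.exp(shifted)
    comp /= comp.sum(axis=1, keepdims=True)
    if config.count_depth is not None:
        raw = np.vstack(
            [rng.multinomial(config.count_depth, comp[i]) for i in range(n)]
        ).astype(float)
        table = AbundanceTable(
            pd.DataFrame(raw, index=sample_ids, columns=taxon_ids), kind="counts"
        )
    else:
        table = AbundanceTable(
            pd.DataFrame(comp, index=sample_ids, columns=taxon_ids), kind="relative"
        )

    # SCFA: intercept + sum_drivers beta * (ALR net of its expectation)
    # + gamma * transit + truncated Gaussian noise.  The ALR of taxon j
    # w.r.t. the internal reference (last taxon) is latent_j - latent_ref,
    # whose centered part is eps_j - eps_ref for delta-free taxa.
    ref = p - 1
    gamma = dict(config.gamma)
    scfa = {}
    for s in SCFA_NAMES:
        mean = np.full(n, _SCFA_INTERCEPT[s]) + gamma.get(s, 0.0) * transit
        for d in config.drivers:
            if d.scfa == s:
                mean = mean + d.beta * (eps[:, d.taxon_index] - eps[:, ref])
        scfa[s] = _truncated_normal(rng, mean, config.scfa_noise)

    bile_total = np.empty(n)
    for g in set(groups):
        mask = np.array([gi == g for gi in groups])
        bile_total[mask] = np.exp(
            rng.normal(np.log(_BILE_TOTAL_MEDIAN[g]), 0.7, mask.sum())
        )
    bile_primary_pct = np.clip(np.exp(rng.normal(np.log(2.5), 1.0, n)), 0.0, 100.0)

    age = np.clip(rng.normal(34.0, 13.0, n), 18.0, 80.0)
    sex = (rng.random(n) < 0.73).astype(float)  # 1 = female
    bmi = np.clip(rng.normal(26.0, 6.0, n), 16.0, 55.0)
    starch = np.exp(rng.normal(np.log(100.0), 0.5, n))
    energy = np.exp(rng.normal(np.log(1800.0), 0.4, n))
    protein = np.exp(rng.normal(np.log(90.0), 0.4, n))

    meta = CohortMetadata(
        pd.DataFrame(
            {
                "group": groups,
                "age": age,
                "sex": sex,
                "bmi": bmi,
                "starch": starch,
                "energy": energy,
                "protein": protein,
                "transit": transit,
                "acetate": scfa["acetate"],
                "butyrate": scfa["butyrate"],
                "propionate": scfa["propionate"],
                "total_scfa": scfa["acetate"] + scfa["butyrate"] + scfa["propionate"],
                "bile_acids_total": bile_total,
                "bile_acids_primary_pct": bile_primary_pct,
                "bam_flag": bile_total > 1000.0,
            },
            index=sample_ids,
        )
    )
    truth = GroundTruth(
        drivers=list(config.drivers),
        gamma=gamma,
        delta=delta,
        latent_logs=pd.DataFrame(latent, index=sample_ids, columns=taxon_ids),
        reference_index=ref,
        taxon_ids=taxon_ids,
    )
    return table, meta, truth


def generate_ko_table(
    config: GeneratorConfig,
    gmm: list[GMMDefinition],
    *,
    table: AbundanceTable | None = None,
    truth: GroundTruth | None = None,
    ko_noise: float = 0.1,
    slope: float = 1.0,
) -> AbundanceTable:
    """KO functional abundances as noisy linear readouts of taxa.

    Each KO from the supplied gut-metabolic modules is tied round-robin to
    one taxon (driver taxa first, so module signal tracks planted signal):
    ko = slope * relative_abundance(taxon) + Normal(0, ko_noise * sd).
    When ``table`` is omitted the cohort is regenerated from ``config``.
    """
    if not gmm:
        raise ConfigError("at least one gut-metabolic module is required")
    if table is None or truth is None:
        table, _, truth = generate_cohort(config)
    rel = table.to_relative().values
    rng = np.random.default_rng(config.seed + 104729)
    ko_ids = sorted({ko for m in gmm for ko in m.ko_ids})
    driver_idx = [d.taxon_index for d in truth.drivers]
    order = driver_idx + [j for j in range(rel.shape[1]) if j not in driver_idx]
    cols = {}
    for k, ko in enumerate(ko_ids):
        j = order[k % len(order)]
        base = slope * rel[:, j]
        noise_sd = ko_noise * max(base.std(), 1e-6)
        cols[ko] = np.clip(base + rng.normal(0.0, noise_sd, rel.shape[0]), 0.0, None)
    return AbundanceTable(
        pd.DataFrame(cols, index=table.data.index), kind="counts"
    )
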