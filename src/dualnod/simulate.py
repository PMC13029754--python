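"""Synthetic dual-transcriptome experiment with ground truth.

The generator emulates the statistical structure of a two-strain nodule
comparison: 2 treatments (WE2, WWL2) x 3 biological replicates; a
host-dominated mixed library in which the symbiont accounts for only a few
percent of the clean reads (per-sample rhizobial mapped rate drawn in the
1.64-5.04% band); negative-binomial counts

    y_gj ~ NB(mean mu_gj, variance mu_gj + phi_g * mu_gj^2),
    mu_gj proportional to  L_j * q_g * 2^(beta_g * x_j + rho * gamma_g * u_j),

where x_j indicates the WWL2 treatment, beta_g is the planted log2 fold
change (so beta < 0 means higher in WE2, matching the global log2(WWL2/WE2)
orientation), u_j is a per-sample latent factor shared by the two coupled
modules (host substrate-supply/microaerobic vs symbiont N-fixation/
respiration, membership gamma_g in {0,1}), and rho is the coupling strength.
Planted effects are concentrated in predefined functional modules, with the
host-supply and symbiont-fixation modules higher in WE2 and the symbiont
nodulation/chemotaxis/transport modules higher in WWL2 — the directional
structure a strong-fixer vs environment-sensing strain contrast produces.

Phenotypes are drawn per treatment from normal distributions calibrated so
the WE2 group reproduces the reference magnitudes (shoot fresh weight
0.243 g, ARA 23.4 per g nodule per h; printed SEMs converted to SDs via
SD = SEM * sqrt(3) for n = 3). qPCR Ct values derive from normalized
expression of assayed marker genes with a constant-expression reference gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .io import (
    HOST,
    SYMBIONT,
    CountMatrix,
    GeneAnnotation,
    ModuleDefinition,
    TREATMENT_A,
    TREATMENT_B,
    validate_samples,
)

logger = logging.getLogger("dualnod")

LABEL_UP_A = f"up_in_{TREATMENT_A}"
LABEL_UP_B = f"up_in_{TREATMENT_B}"
LABEL_NULL = "null"

QPCR_CT_OFFSET = 34.0  # Ct of a transcript at ~1 CPM
QPCR_CT_NOISE_SD = 0.15
MIN_EFFECT_LOG2 = 0.25


class ConfigError(ValueError):
    """A simulation configuration is internally infeasible."""


@dataclass(frozen=True)
class SimModuleSpec:
    """A planted module: gene block, effect direction, latent-coupling flag.

    ``direction`` is the sign of the planted log2(WWL2/WE2) effect: -1 means
    the module is higher in WE2 nodules.
    """

    module_id: str
    partner: str
    direction: int
    coupled: bool = False
    size: int = 30


@dataclass(frozen=True)
class PhenotypeParams:
    """Per-treatment phenotype means and SDs (SD = printed SEM * sqrt(3))."""

    shoot_fw_mean_A: float = 0.243
    shoot_fw_sd_A: float = 0.015 * np.sqrt(3.0)
    shoot_fw_mean_B: float = 0.180
    shoot_fw_sd_B: float = 0.012 * np.sqrt(3.0)
    ara_mean_A: float = 23.4
    ara_sd_A: float = 1.0 * np.sqrt(3.0)
    ara_mean_B: float = 15.6
    ara_sd_B: float = 1.2 * np.sqrt(3.0)


def default_modules(module_size: int = 30) -> list[SimModuleSpec]:
    return [
        SimModuleSpec("host_supply_microaerobic", HOST, -1, coupled=True, size=module_size),
        SimModuleSpec("sym_nfix_respiration", SYMBIONT, -1, coupled=True, size=module_size),
        SimModuleSpec("sym_nodulation_surface", SYMBIONT, +1, size=module_size),
        SimModuleSpec("sym_chemotaxis_motility", SYMBIONT, +1, size=module_size),
        SimModuleSpec("sym_transport_nutrient", SYMBIONT, +1, size=module_size),
    ]


@dataclass
class SimConfig:
    seed: int
    n_rep_per_group: int = 3
    n_host_genes: int = 5000
    n_symbiont_genes: int = 1500
    host_lib_size_mean: float = 2.0e6
    symbiont_lib_size_mean: float = 3.0e5
    lib_size_cv: float = 0.05
    symbiont_rate_band: tuple[float, float] = (1.64, 5.04)
    baseline_mean_log_range: tuple[float, float] = (0.0, 9.0)  # log2 rel. abundance
    dispersion_median: float = 0.1
    dispersion_log_sigma: float = 0.5
    de_fraction_host: float = 0.10
    de_fraction_symbiont: float = 0.15
    effect_size_log2_mean: float = 2.0
    effect_size_log2_sd: float = 0.5
    coupling_strength: float = 0.9
    module_size: int = 30
    modules: list[SimModuleSpec] | None = None
    phenotype_params: PhenotypeParams = field(default_factory=PhenotypeParams)

    def __post_init__(self) -> None:
        lo, hi = self.symbiont_rate_band
        if not 0 < lo <= hi:
            raise ConfigError("rate band must satisfy 0 < lower <= upper")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ConfigError("coupling strength must lie in [0, 1]")
        for frac in (self.de_fraction_host, self.de_fraction_symbiont):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("DE fractions must lie in [0, 1]")
        if self.modules is None:
            self.modules = default_modules(self.module_size)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ConfigError("simulation config must set a seed")
        for key in ("symbiont_rate_band", "baseline_mean_log_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "phenotype_params" in raw:
            raw["phenotype_params"] = PhenotypeParams(**raw["phenotype_params"])
        if "modules" in raw and raw["modules"] is not None:
            raw["modules"] = [SimModuleSpec(**m) for m in raw["modules"]]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["symbiont_rate_band"] = list(self.symbiont_rate_band)
        d["baseline_mean_log_range"] = list(self.baseline_mean_log_range)
        return d


@dataclass
class SimTruth:
    de_labels: pd.Series  # gene -> up_in_WE2 | up_in_WWL2 | null
    true_log2fc: pd.Series  # planted beta_g (log2 WWL2/WE2)
    latent_factor: pd.Series  # sample -> u_j
    module_effect_direction: dict[str, int]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.de_labels, "true_log2fc": self.true_log2fc}
        ).rename_axis("gene_id")


@dataclass
class SimulatedExperiment:
    host: CountMatrix
    symbiont: CountMatrix
    samples: pd.DataFrame
    truth: SimTruth
    phenotypes: pd.DataFrame
    qpcr: pd.DataFrame
    modules: list[ModuleDefinition]
    annotation: GeneAnnotation
    config: SimConfig


def sample_nb(rng: np.random.Generator, mean, dispersion, size=None) -> np.ndarray:
    """Draw NB(mean mu, variance mu + phi*mu^2) via the gamma-Poisson mixture.

    ``mean`` and ``dispersion`` broadcast; dispersion 0 falls back to Poisson.
    """
    if size is not None:
        mean = np.broadcast_to(np.asarray(mean, dtype=float), size).copy()
        dispersion = np.broadcast_to(np.asarray(dispersion, dtype=float), size)
    else:
        mean, dispersion = np.broadcast_arrays(
            np.asarray(mean, dtype=float), np.asarray(dispersion, dtype=float)
        )
    out = np.empty(mean.shape, dtype=np.int64)
    pois = np.asarray(dispersion) <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        phi = np.asarray(dispersion)[~pois]
        lam = rng.gamma(shape=1.0 / phi, scale=mean[~pois] * phi)
        out[~pois] = rng.poisson(lam)
    return out


def _plant_effects(
    rng: np.random.Generator,
    gene_ids: list[str],
    module_specs: list[SimModuleSpec],
    de_fraction: float,
    effect_mean: float,
    effect_sd: float,
) -> tuple[np.ndarray, np.ndarray, list[ModuleDefinition], dict[str, int]]:
    """Assign planted log2 effects (beta) and coupled-module membership (gamma).

    Module genes occupy leading blocks of the gene list and receive their
    module's effect direction first; remaining DE slots (up to
    round(de_fraction * n)) go to randomly chosen background genes with random
    signs. With de_fraction = 0 nothing is planted at all.
    """
    n = len(gene_ids)
    beta = np.zeros(n)
    gamma = np.zeros(n, dtype=bool)
    modules: list[ModuleDefinition] = []
    directions: dict[str, int] = {}
    n_de = int(round(de_fraction * n))

    cursor = 0
    module_slots: list[tuple[int, int]] = []  # (gene index, direction)
    for spec in module_specs:
        if cursor + spec.size > n:
            raise ConfigError(
                f"not enough genes for module {spec.module_id!r} ({n} available)"
            )
        block = list(range(cursor, cursor + spec.size))
        modules.append(
            ModuleDefinition(
                spec.module_id,
                spec.partner,
                frozenset(gene_ids[i] for i in block),
                description=f"synthetic module partner={spec.partner}",
            )
        )
        directions[spec.module_id] = spec.direction
        for i in block:
            module_slots.append((i, spec.direction))
            if spec.coupled:
                gamma[i] = True
        cursor += spec.size

    planted = module_slots[:n_de]
    remaining = n_de - len(planted)
    if remaining > 0:
        background = np.arange(cursor, n)
        chosen = rng.choice(background, size=min(remaining, len(background)), replace=False)
        signs = rng.choice([-1, 1], size=len(chosen))
        planted += list(zip(chosen.tolist(), signs.tolist()))
    for idx, direction in planted:
        magnitude = max(MIN_EFFECT_LOG2, rng.normal(effect_mean, effect_sd)) \
            if effect_sd > 0 else effect_mean
        beta[idx] = direction * magnitude
    return beta, gamma, modules, directions


def _simulate_partner(
    rng: np.random.Generator,
    config: SimConfig,
    partner: str,
    treatments: np.ndarray,
    latent: np.ndarray,
) -> tuple[pd.DataFrame, np.ndarray, list[ModuleDefinition], dict[str, int], np.ndarray]:
    if partner == HOST:
        n_genes = config.n_host_genes
        lib_mean = config.host_lib_size_mean
        frac = config.de_fraction_host
        prefix = "hg"
    else:
        n_genes = config.n_symbiont_genes
        lib_mean = config.symbiont_lib_size_mean
        frac = config.de_fraction_symbiont
        prefix = "sg"
    gene_ids = [f"{prefix}{i:05d}" for i in range(n_genes)]
    specs = [m for m in config.modules if m.partner == partner]
    beta, gamma, modules, directions = _plant_effects(
        rng, gene_ids, specs, frac, config.effect_size_log2_mean, config.effect_size_log2_sd
    )

    lo, hi = config.baseline_mean_log_range
    q = 2.0 ** rng.uniform(lo, hi, size=n_genes)
    q /= q.sum()
    phi = config.dispersion_median * np.exp(
        rng.normal(0.0, config.dispersion_log_sigma, size=n_genes)
    )
    n_samples = len(treatments)
    lib = np.maximum(
        1000, np.rint(rng.normal(lib_mean, config.lib_size_cv * lib_mean, size=n_samples))
    )

    x = (treatments == TREATMENT_B).astype(float)  # WWL2 indicator
    log2_mod = np.outer(beta, x) + config.coupling_strength * np.outer(
        gamma.astype(float), latent
    )
    concentration = 1e6 * q[:, None] * 2.0**log2_mod  # per unit organism RNA
    mu = concentration / concentration.sum(axis=0, keepdims=True) * lib[None, :]
    counts = sample_nb(rng, mu, phi[:, None])

    frame = pd.DataFrame(counts, index=gene_ids)
    conc_frame = pd.DataFrame(concentration, index=gene_ids)
    return frame, beta, modules, directions, conc_frame


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Generate a complete synthetic experiment with ground truth.

    Identical configs (including the seed) give bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    n_rep = config.n_rep_per_group
    if n_rep < 2:
        raise ConfigError("need >= 2 replicates per treatment")
    sample_ids = [f"{t}_{r}" for t in (TREATMENT_A, TREATMENT_B) for r in range(1, n_rep + 1)]
    treatments = np.array([s.split("_")[0] for s in sample_ids])
    replicates = [int(s.split("_")[1]) for s in sample_ids]
    latent = rng.normal(0.0, 1.0, size=len(sample_ids))

    host_frame, host_beta, host_modules, host_dirs, host_conc = _simulate_partner(
        rng, config, HOST, treatments, latent
    )
    sym_frame, sym_beta, sym_modules, sym_dirs, sym_conc = _simulate_partner(
        rng, config, SYMBIONT, treatments, latent
    )
    host_frame.columns = sample_ids
    sym_frame.columns = sample_ids
    host_conc.columns = sample_ids
    sym_conc.columns = sample_ids
    host = CountMatrix(host_frame, HOST)
    symbiont = CountMatrix(sym_frame, SYMBIONT)

    # Read accounting: the symbiont's realized column sum is a draw from the
    # mapped-rate band of the whole library, which fixes total clean reads.
    lo, hi = config.symbiont_rate_band
    rates = rng.uniform(lo, hi, size=len(sample_ids))
    sym_mapped = symbiont.library_sizes.to_numpy()
    host_mapped = host.library_sizes.to_numpy()
    total_clean = np.rint(100.0 * sym_mapped / rates).astype(np.int64)
    if (host_mapped + sym_mapped > total_clean).any():
        raise ConfigError(
            "rate band infeasible: host + symbiont mapped reads exceed the total "
            "clean reads implied by the symbiont mapped-rate band"
        )
    samples = validate_samples(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "treatment": treatments,
                "replicate": replicates,
                "total_clean_reads": total_clean,
                "host_mapped": host_mapped,
                "symbiont_mapped": sym_mapped,
            }
        )
    )

    labels = np.concatenate([host_beta, sym_beta])
    gene_index = pd.Index(list(host_frame.index) + list(sym_frame.index), name="gene_id")
    de_labels = pd.Series(
        np.where(labels < 0, LABEL_UP_A, np.where(labels > 0, LABEL_UP_B, LABEL_NULL)),
        index=gene_index,
    )
    truth = SimTruth(
        de_labels=de_labels,
        true_log2fc=pd.Series(labels, index=gene_index),
        latent_factor=pd.Series(latent, index=sample_ids),
        module_effect_direction={**host_dirs, **sym_dirs},
    )

    annotation = GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": gene_index,
                "length_bp": np.concatenate(
                    [
                        rng.integers(500, 4000, size=config.n_host_genes),
                        rng.integers(300, 2500, size=config.n_symbiont_genes),
                    ]
                ),
                "partner": [HOST] * config.n_host_genes + [SYMBIONT] * config.n_symbiont_genes,
            }
        )
    )

    phenotypes = _simulate_phenotypes(rng, config, sample_ids, treatments)
    qpcr = _simulate_qpcr(
        rng, truth, host_modules + sym_modules,
        {HOST: host_conc, SYMBIONT: sym_conc},
    )

    return SimulatedExperiment(
        host=host,
        symbiont=symbiont,
        samples=samples,
        truth=truth,
        phenotypes=phenotypes,
        qpcr=qpcr,
        modules=host_modules + sym_modules,
        annotation=annotation,
        config=config,
    )


def _simulate_phenotypes(rng, config, sample_ids, treatments) -> pd.DataFrame:
    p = config.phenotype_params
    fw, ara = [], []
    for t in treatments:
        if t == TREATMENT_A:
            fw.append(rng.normal(p.shoot_fw_mean_A, p.shoot_fw_sd_A))
            ara.append(rng.normal(p.ara_mean_A, p.ara_sd_A))
        else:
            fw.append(rng.normal(p.shoot_fw_mean_B, p.shoot_fw_sd_B))
            ara.append(rng.normal(p.ara_mean_B, p.ara_sd_B))
    return pd.DataFrame(
        {
            "replicate_id": sample_ids,
            "treatment": treatments,
            "shoot_fw": np.maximum(0.0, fw),
            "ethylene_rate": np.maximum(0.0, ara),
        }
    )


def _qpcr_targets(truth: SimTruth, modules: list[ModuleDefinition], partner: str,
                  concentration: pd.DataFrame, n_targets: int = 3) -> tuple[list[str], str]:
    """Marker genes of the partner's coupled module plus a stable reference.

    The reference is the highest-expressed unplanted (null) gene, mimicking a
    housekeeping gene chosen for stability; by construction its transcript
    concentration is identical in every sample.
    """
    coupled = [m for m in modules if m.partner == partner][0]
    targets = sorted(coupled.gene_ids)[:n_targets]
    null_genes = truth.de_labels[
        (truth.de_labels == LABEL_NULL)
        & truth.de_labels.index.isin(concentration.index)
    ].index
    reference = concentration.loc[null_genes].mean(axis=1).idxmax()
    return targets, reference


def _simulate_qpcr(rng, truth, modules, concentrations: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Ct values from model transcript concentrations.

    qPCR quantifies the concentration of a transcript in the RNA aliquot, so
    Ct derives from the model concentration (not from realized read shares,
    which carry library-composition effects a reference-gene normalization is
    meant to escape): Ct = c0 - log2(concentration) + technical noise.
    """
    rows = []
    for partner, conc in concentrations.items():
        targets, reference = _qpcr_targets(truth, modules, partner, conc)
        for gene in targets + [reference]:
            for sample in conc.columns:
                treatment, replicate = sample.split("_")
                base_ct = QPCR_CT_OFFSET - np.log2(conc.loc[gene, sample] + 0.5)
                cts = base_ct + rng.normal(0.0, QPCR_CT_NOISE_SD, size=3)
                rows.append(
                    {
                        "target_gene": gene,
                        "reference_gene": reference,
                        "treatment": treatment,
                        "replicate": int(replicate),
                        "ct1": cts[0],
                        "ct2": cts[1],
                        "ct3": cts[2],
                        "partner": partner,
                    }
                )
    return pd.DataFrame.from_records(rows)
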