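"""Forward simulator for a synthetic twin methylation cohort.

Generates beta-scale methylation matrices, probe manifests and sample
sheets with the statistical structure the downstream analysis assumes:
irregular clustered CpG positions (islands on a sparse background),
bimodal per-CpG population means, per-individual residual tracks drawn
from an exponential-covariance Gaussian field plus white noise,
individual-specific (log tau, log kappa) that are consistent across
chromosomes within an individual, MZ > DZ co-twin similarity,
plate/BeadChip batch shifts (including one outlier plate), a sex effect
and an age-group shift in log tau.  Every parameter actually used is
recorded in a ground-truth table for recovery tests.

All effect sizes are synthetic (chosen for detectability at the default
cohort size, not measured from any real cohort); the cohort layout
(twin-pair fractions, plate sizes, two age groups) mirrors a typical
twin-register 450k study at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .matern_field import MaternSpec
from .methylation_io import (
    MethylationMatrix,
    ProbeManifest,
    SampleSheet,
    m_to_beta,
)

__all__ = ["CohortSimConfig", "SimulatedCohort", "simulate_positions",
           "simulate_track", "simulate_cohort"]


@dataclass(frozen=True)
class CohortSimConfig:
    """Simulation settings; defaults define the package's study conditions.

    Positions are base pairs.  Individuals are parameterized by the field
    variance and the decay rate: ``logkappa_mean`` defaults to log(2/3000)
    (range 3000 bp) and ``logsigma2_mean`` to log(0.75) so that field plus
    noise (sigma0 = 0.5) has unit total variance, matching
    population-normalized residuals; log tau is derived from the two.
    """

    n_families: int = 200
    mz_fraction: float = 336.0 / 604.0
    n_chromosomes: int = 5
    sites_per_chromosome: int = 400

    # island geometry (dense CpG spacing inside islands is what makes the
    # noise nugget identifiable against the field's short-range roughness)
    island_count: int = 14
    island_width_bp: int = 300
    island_spacing_bp: int = 30
    background_spacing_bp: int = 1500

    # population means on the beta scale (bimodal mixture of Betas)
    pop_mean_low: tuple = (2.0, 8.0)
    pop_mean_high: tuple = (8.0, 2.0)
    pop_mean_high_weight: float = 0.5

    # individual-level dependency parameters: individuals are drawn in
    # (log sigma^2, log kappa) space — log tau is derived — so the
    # field-to-noise variance ratio stays in the identifiable regime
    logsigma2_mean: float = float(np.log(0.75))
    logsigma2_sd: float = 0.25
    logkappa_mean: float = float(np.log(2.0 / 3000.0))
    logkappa_sd: float = 0.3
    cross_chromosome_sd: float = 0.12
    twin_corr_mz: float = 0.85
    twin_corr_dz: float = 0.45

    # batch structure
    pairs_per_plate: int = 26
    samples_per_chip: int = 12
    same_chip_prob: float = 0.8
    plate_sd: float = 0.15
    chip_sd: float = 0.08
    plate_intercept_sd: float = 0.05
    outlier_plate_logtau_shift: float = -0.4
    outlier_plate_logkappa_shift: float = 0.25
    outlier_plate_intercept_shift: float = 0.2

    # biology
    old_fraction: float = 425.0 / 1611.0
    age_young_loc: float = 23.0
    age_young_scale: float = 3.0
    age_old_loc: float = 62.0
    age_old_scale: float = 7.0
    age_logtau_shift: float = -0.25
    dz_same_sex_fraction: float = 175.0 / 268.0
    sex_effect: float = 0.3

    noise_sd: float = 0.5
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("logsigma2_sd", "logkappa_sd", "cross_chromosome_sd",
                     "plate_sd", "chip_sd", "plate_intercept_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("mz_fraction", "old_fraction", "same_chip_prob",
                     "dz_same_sex_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("twin_corr_mz", "twin_corr_dz"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [-1, 1], got {v}")
        if self.n_chromosomes < 1 or self.n_chromosomes > 22:
            raise ValueError("n_chromosomes must be in 1..22")


@dataclass
class SimulatedCohort:
    matrix: MethylationMatrix
    manifest: ProbeManifest
    sheet: SampleSheet
    truth: pd.DataFrame
    config: CohortSimConfig = field(repr=False, default=None)


def _islands_for_chromosome(config: CohortSimConfig, chrom_index: int) -> int:
    # deterministic per-chromosome variation so island proportions differ
    if config.island_count <= 0:
        return 0
    return max(1, config.island_count + (chrom_index % 5) - 2)


def simulate_positions(config: CohortSimConfig, chrom_index: int, seed: int):
    """Sorted clustered positions and island flags for one chromosome.

    Island sites sit on a regular fine grid (``island_spacing_bp``) inside
    islands of ``island_width_bp``; background sites have jittered gaps
    around ``background_spacing_bp``.  Same seed, same positions.
    """
    rng = np.random.default_rng([int(seed), int(chrom_index), 11])
    n = config.sites_per_chromosome
    sites_per_island = config.island_width_bp // config.island_spacing_bp + 1
    n_islands = _islands_for_chromosome(config, chrom_index)
    n_island_sites = min(n_islands * sites_per_island, n)
    n_bg = n - n_island_sites
    if config.island_spacing_bp < 1 or config.background_spacing_bp < 2:
        raise ValueError("spacing geometry would create duplicate positions")
    # background run lengths between islands (n_islands + 1 runs)
    runs = np.full(n_islands + 1, n_bg // (n_islands + 1))
    runs[: n_bg % (n_islands + 1)] += 1
    positions = []
    flags = []
    pos = 1.0
    for isl in range(n_islands + 1):
        for _ in range(int(runs[isl])):
            pos += rng.uniform(0.5, 1.5) * config.background_spacing_bp
            positions.append(pos)
            flags.append(False)
        if isl < n_islands and n_island_sites > 0:
            take = min(sites_per_island, n_island_sites - isl * sites_per_island)
            for _ in range(max(take, 0)):
                pos += config.island_spacing_bp
                positions.append(pos)
                flags.append(True)
    positions = np.round(np.asarray(positions[:n]))
    flags = np.asarray(flags[:n], dtype=bool)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("position geometry produced duplicates")
    return positions, flags


def simulate_track(
    positions,
    spec: MaternSpec,
    sigma0: float,
    seed_or_rng,
    return_field: bool = False,
):
    """Exact draw of the exponential field plus white noise at the given
    positions.

    The Markov property gives sequential conditional draws:
    ``xi_1 ~ N(0, sigma^2)``, ``xi_{i+1} | xi_i ~ N(rho_i xi_i,
    sigma^2 (1 - rho_i^2))`` with ``rho_i = exp(-kappa * gap_i)``.
    """
    if spec.lambda_smoothness != 0.5:
        raise ValueError("track simulation requires the Markov case lambda = 0.5")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    pos = np.asarray(positions, dtype=float)
    n = pos.size
    z = rng.standard_normal(n)
    noise = rng.standard_normal(n) * sigma0
    sigma = spec.sigma
    xi = np.empty(n)
    xi[0] = sigma * z[0]
    if n > 1:
        rho = np.exp(-spec.kappa * np.diff(pos))
        scale = sigma * np.sqrt(-np.expm1(-2.0 * spec.kappa * np.diff(pos)))
        for i in range(1, n):
            xi[i] = rho[i - 1] * xi[i - 1] + scale[i - 1] * z[i]
    y = xi + noise
    if return_field:
        return y, xi
    return y


def _assign_sexes(rng, zygosity: np.ndarray, config: CohortSimConfig):
    sexes_a, sexes_b = [], []
    for z in zygosity:
        s1 = "M" if rng.random() < 0.5 else "F"
        if z == "MZ" or rng.random() < config.dz_same_sex_fraction:
            s2 = s1
        else:
            s2 = "F" if s1 == "M" else "M"
        sexes_a.append(s1)
        sexes_b.append(s2)
    return sexes_a, sexes_b


def simulate_cohort(config: CohortSimConfig | None = None) -> SimulatedCohort:
    """Full forward simulation of a twin cohort (see module docstring)."""
    config = config if config is not None else CohortSimConfig()
    rng = np.random.default_rng([config.seed, 2024])
    nf = config.n_families
    n_mz = int(round(config.mz_fraction * nf))

    zygosity = np.array(["MZ"] * n_mz + ["DZ"] * (nf - n_mz))
    rng.shuffle(zygosity)
    is_old = rng.random(nf) < config.old_fraction
    ages = np.where(
        is_old,
        rng.normal(config.age_old_loc, config.age_old_scale, nf),
        rng.normal(config.age_young_loc, config.age_young_scale, nf),
    )
    ages = np.clip(np.round(ages, 1), 18.0, 95.0)
    # keep the groups cleanly separated at the thresholds the analysis uses
    ages = np.where(is_old, np.maximum(ages, 51.0), np.minimum(ages, 39.0))
    sex_a, sex_b = _assign_sexes(rng, zygosity, config)

    # batches: pairs fill plates sequentially; chips fill within plates
    n_plates = int(np.ceil(nf / config.pairs_per_plate))
    plate_of_pair = np.repeat(np.arange(n_plates), config.pairs_per_plate)[:nf]
    # batch shifts move along the constant-sigma^2 ridge (delta logkappa =
    # -2 delta logtau): plates shift both dependency parameters jointly,
    # which is also what keeps the field-to-noise ratio identifiable
    plate_shift_lt = rng.normal(0.0, config.plate_sd, n_plates)
    plate_shift_lk = -2.0 * plate_shift_lt
    plate_shift_b = rng.normal(0.0, config.plate_intercept_sd, n_plates)
    plate_shift_lt[0] += config.outlier_plate_logtau_shift
    plate_shift_lk[0] += config.outlier_plate_logkappa_shift
    plate_shift_b[0] += config.outlier_plate_intercept_shift

    chip_of_sample: list[int] = []
    chip_counter = -1
    chip_fill = config.samples_per_chip
    prev_plate = -1
    for f in range(nf):
        if plate_of_pair[f] != prev_plate:
            chip_counter += 1
            chip_fill = 0
            prev_plate = plate_of_pair[f]
        same = rng.random() < config.same_chip_prob
        if chip_fill + 2 > config.samples_per_chip:
            chip_counter += 1
            chip_fill = 0
        if same:
            chip_of_sample.extend([chip_counter, chip_counter])
            chip_fill += 2
        else:
            chip_of_sample.append(chip_counter)
            chip_counter += 1
            chip_of_sample.append(chip_counter)
            chip_fill = 1
    n_chips = max(chip_of_sample) + 1
    chip_shift_lt = rng.normal(0.0, config.chip_sd, n_chips)
    chip_shift_lk = -2.0 * chip_shift_lt

    # individual-level dependency parameters with co-twin correlation
    def pair_draws(sd: float) -> np.ndarray:
        out = np.empty(2 * nf)
        for f in range(nf):
            c = config.twin_corr_mz if zygosity[f] == "MZ" else config.twin_corr_dz
            c = min(max(c, 0.0), 1.0)
            shared = rng.normal(0.0, sd * np.sqrt(c))
            out[2 * f] = shared + rng.normal(0.0, sd * np.sqrt(1.0 - c))
            out[2 * f + 1] = shared + rng.normal(0.0, sd * np.sqrt(1.0 - c))
        return out

    ind_ls2 = config.logsigma2_mean + pair_draws(config.logsigma2_sd)
    ind_lk = config.logkappa_mean + pair_draws(config.logkappa_sd)
    # tau follows from the field variance: sigma^2 = 1/(2 kappa tau^2)
    ind_lt = -0.5 * (np.log(2.0) + ind_lk + ind_ls2)
    sexes = np.array([s for f in range(nf) for s in (sex_a[f], sex_b[f])])
    sex_term = np.where(sexes == "M", 0.5, -0.5) * config.sex_effect
    sex_term_lk = -2.0 * sex_term
    plate_of_sample = np.repeat(plate_of_pair, 2)
    age_of_sample = np.repeat(ages, 2)
    old_of_sample = np.repeat(is_old, 2)
    chips = np.asarray(chip_of_sample)
    ind_lt = (
        ind_lt
        + plate_shift_lt[plate_of_sample]
        + chip_shift_lt[chips]
        + sex_term
        + np.where(old_of_sample, config.age_logtau_shift, 0.0)
    )
    ind_lk = (
        ind_lk
        + plate_shift_lk[plate_of_sample]
        + chip_shift_lk[chips]
        + sex_term_lk
    )

    sample_ids = [f"S{f:04d}_{t}" for f in range(nf) for t in (1, 2)]
    n_samples = 2 * nf

    # positions and manifest
    pos_by_chrom, flag_by_chrom = {}, {}
    manifest_rows = []
    probe_counter = 0
    for c in range(config.n_chromosomes):
        pos, flags = simulate_positions(config, c, config.seed)
        pos_by_chrom[c] = pos
        flag_by_chrom[c] = flags
        for p, fl in zip(pos, flags):
            manifest_rows.append(
                {
                    "probe_id": f"cg{probe_counter:07d}",
                    "chrom": c + 1,
                    "pos": int(p),
                    "island": bool(fl),
                }
            )
            probe_counter += 1
    manifest = ProbeManifest(pd.DataFrame(manifest_rows))
    n_probes = probe_counter

    # population means on the M scale
    is_high = rng.random(n_probes) < config.pop_mean_high_weight
    a_lo, b_lo = config.pop_mean_low
    a_hi, b_hi = config.pop_mean_high
    pop_beta = np.where(
        is_high, rng.beta(a_hi, b_hi, n_probes), rng.beta(a_lo, b_lo, n_probes)
    )
    pop_beta = np.clip(pop_beta, 1e-4, 1.0 - 1e-4)
    pop_m = np.log2(pop_beta / (1.0 - pop_beta))

    # residual tracks
    m_values = np.empty((n_probes, n_samples))
    truth_rows = []
    row0 = {c: sum(len(pos_by_chrom[cc]) for cc in range(c)) for c in
            range(config.n_chromosomes)}
    for s in range(n_samples):
        for c in range(config.n_chromosomes):
            lt = ind_lt[s] + rng.normal(0.0, config.cross_chromosome_sd)
            lk = ind_lk[s] + rng.normal(0.0, config.cross_chromosome_sd)
            spec = MaternSpec(kappa=float(np.exp(lk)), tau=float(np.exp(lt)))
            y = simulate_track(pos_by_chrom[c], spec, config.noise_sd, rng)
            r0 = row0[c]
            m_values[r0 : r0 + y.size, s] = y + plate_shift_b[plate_of_sample[s]]
            truth_rows.append(
                {
                    "sample_id": sample_ids[s],
                    "chrom": c + 1,
                    "true_logtau": lt,
                    "true_logkappa": lk,
                    "ind_logtau": ind_lt[s],
                    "ind_logkappa": ind_lk[s],
                }
            )
    m_values += pop_m[:, None]

    if config.missing_rate > 0:
        mask = rng.random(m_values.shape) < config.missing_rate
        m_values[mask] = np.nan

    beta_values = m_to_beta(m_values)

    matrix = MethylationMatrix(
        probe_ids=pd.Index([f"cg{i:07d}" for i in range(n_probes)]),
        sample_ids=pd.Index(sample_ids),
        values=beta_values,
        value_scale="beta",
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "family_id": [f"F{f:04d}" for f in range(nf) for _ in range(2)],
                "pair_id": [f"P{f:04d}" for f in range(nf) for _ in range(2)],
                "zygosity": np.repeat(zygosity, 2),
                "sex": sexes,
                "age": age_of_sample,
                "plate": [f"plate{p:02d}" for p in plate_of_sample],
                "beadchip": [f"chip{c:04d}" for c in chips],
            }
        )
    )
    truth = pd.DataFrame(truth_rows)
    truth["seed"] = config.seed
    return SimulatedCohort(
        matrix=matrix, manifest=manifest, sheet=sheet, truth=truth, config=config
    )


def config_from_dict(d: dict) -> CohortSimConfig:
    """Build a config from a (YAML-loaded) dict, validating field names."""
    valid = set(CohortSimConfig.__dataclass_fields__)
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown simulation config fields: {sorted(unknown)}")
    d = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
    return CohortSimConfig(**d)


def config_to_dict(config: CohortSimConfig) -> dict:
    return {k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()}
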