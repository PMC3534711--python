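"""Seeded generators for every input class, with recorded ground truth.

Each generator returns both the observable data object and a ``*Truth``
sidecar holding the designed quantities (gradients, fluxes, uptake rate,
fragment membership, shared-core fraction), so downstream recovery tests
never peek at the generator internals.

Noise models are deliberately minimal: i.i.d. Gaussian noise for sensor
readings and fragment size calling, multinomial sampling for sequence
counts, Bernoulli dropout for PCR replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from woodfall.arisa import PeakProfile
from woodfall.chamber_tou import ChamberTimeSeries
from woodfall.community_stats import TagTable
from woodfall.profiles_flux import FLUX_TO_MMOL_M2_D, ConcentrationProfile
from woodfall.tracer_rates import TracerIncubation

# ---------------------------------------------------------------------------
# Microsensor profiles


@dataclass
class ProfileSpec:
    """Piecewise-linear profile description.

    ``breakpoints`` are (depth_mm, value) nodes; the interface node
    (0, interface_value) is prepended automatically when absent.  Depths
    must be strictly increasing.
    """

    analyte: str
    interface_value: float
    breakpoints: list[tuple[float, float]]
    porosity: float = 1.0
    noise_sd: float = 0.0
    points_per_mm: float = 1.0
    d_sed_m2_s: float | None = None

    def nodes(self) -> tuple[np.ndarray, np.ndarray]:
        pts = list(self.breakpoints)
        if not pts or pts[0][0] > 0.0:
            pts = [(0.0, self.interface_value)] + pts
        depths = np.array([p[0] for p in pts], dtype=float)
        values = np.array([p[1] for p in pts], dtype=float)
        if np.any(np.diff(depths) <= 0):
            raise ValueError("breakpoint depths must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        return depths, values


@dataclass
class ProfileTruth:
    """Designed gradients (µM mm⁻¹) and fluxes (mmol m⁻² d⁻¹)."""

    gradient: float  # steepest by |slope|, sign preserved
    gradient_up: float | None  # steepest negative (towards interface)
    gradient_down: float | None  # steepest positive (away from interface)
    flux: float | None = None
    flux_total: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def gen_profile(
    spec: ProfileSpec, seed: int | None = None
) -> tuple[ConcentrationProfile, ProfileTruth]:
    """Sample a piecewise-linear profile plus Gaussian noise.

    Ground truth records the steepest segment slopes and — when the spec
    carries a diffusion coefficient — the corresponding Fick fluxes.
    """
    depths, values = spec.nodes()
    rng = np.random.default_rng(seed)
    n = int(round((depths[-1] - depths[0]) * spec.points_per_mm)) + 1
    grid = np.linspace(depths[0], depths[-1], n)
    clean = np.interp(grid, depths, values)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd else clean
    profile = ConcentrationProfile(spec.analyte, grid, noisy, spec.porosity)

    slopes = np.diff(values) / np.diff(depths)
    steepest = float(slopes[np.argmax(np.abs(slopes))])
    neg = slopes[slopes < 0]
    pos = slopes[slopes > 0]
    grad_up = float(neg[np.argmax(np.abs(neg))]) if len(neg) else None
    grad_down = float(pos[np.argmax(pos)]) if len(pos) else None
    flux = flux_total = None
    if spec.d_sed_m2_s is not None:
        factor = spec.porosity * spec.d_sed_m2_s * FLUX_TO_MMOL_M2_D
        flux = factor * steepest
        flux_total = factor * (
            (abs(grad_up) if grad_up is not None else 0.0)
            + (grad_down if grad_down is not None else 0.0)
        )
    truth = ProfileTruth(steepest, grad_up, grad_down, flux, flux_total)
    return profile, truth


# ---------------------------------------------------------------------------
# Benthic chamber


@dataclass
class ChamberTruth:
    tou_mmol_m2_d: float
    slope_uM_per_h: float
    plateau_after_h: float | None = None


def gen_chamber(
    tou_true: float,
    water_height_m: float = 0.12,
    duration_h: float = 12.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    n_points: int = 61,
    o2_start_uM: float = 250.0,
    plateau_after_h: float | None = None,
    chamber_area_cm2: float = 284.0,
) -> tuple[ChamberTimeSeries, ChamberTruth]:
    """Linear O₂ drawdown in an enclosed chamber, plus noise.

    slope = −TOU / (24 · height) µM h⁻¹ (µM ≡ mmol m⁻³).  An optional
    plateau after ``plateau_after_h`` freezes the concentration, to
    exercise initial-window selection; concentrations never go below 0.
    """
    rng = np.random.default_rng(seed)
    slope = -tou_true / (24.0 * water_height_m)
    t = np.linspace(0.0, duration_h, n_points)
    o2 = o2_start_uM + slope * t
    if plateau_after_h is not None:
        o2 = np.where(
            t <= plateau_after_h, o2, o2_start_uM + slope * plateau_after_h
        )
    o2 = np.maximum(o2, 0.0)
    if noise_sd:
        o2 = o2 + rng.normal(0.0, noise_sd, size=len(t))
    series = ChamberTimeSeries(t, o2, water_height_m, chamber_area_cm2)
    return series, ChamberTruth(tou_true, slope, plateau_after_h)


# ---------------------------------------------------------------------------
# Fingerprint peak tables


@dataclass
class ArisaSpec:
    """Designed fragment community for one sample's PCR replicates."""

    fragment_lengths_bp: list[float]
    relative_intensities: list[float]
    n_replicates: int = 3
    size_call_sd_bp: float = 0.4
    replicate_dropout_prob: float = 0.0
    total_area: float = 10_000.0

    def __post_init__(self) -> None:
        lengths = np.asarray(self.fragment_lengths_bp, dtype=float)
        intens = np.asarray(self.relative_intensities, dtype=float)
        if lengths.shape != intens.shape:
            raise ValueError("lengths and intensities must have equal length")
        if np.any((lengths < 100.0) | (lengths > 1000.0)):
            raise ValueError("fragment lengths must lie in [100, 1000] bp")
        if not np.isclose(intens.sum(), 1.0):
            raise ValueError("relative intensities must sum to 1")
        if self.size_call_sd_bp < 0:
            raise ValueError("size_call_sd must be non-negative")
        if not 0.0 <= self.replicate_dropout_prob < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")


@dataclass
class ArisaTruth:
    fragment_lengths_bp: np.ndarray
    relative_intensities: np.ndarray
    #: observed[replicate][fragment index] → called size or nan if dropped
    called_sizes: np.ndarray


def gen_arisa(
    spec: ArisaSpec, sample_id: str = "s1", seed: int | None = None
) -> tuple[list[PeakProfile], ArisaTruth]:
    """Per-replicate peak tables with size-calling jitter and dropout."""
    rng = np.random.default_rng(seed)
    lengths = np.asarray(spec.fragment_lengths_bp, dtype=float)
    intens = np.asarray(spec.relative_intensities, dtype=float)
    n_frag = len(lengths)
    called = np.full((spec.n_replicates, n_frag), np.nan)
    profiles = []
    for r in range(spec.n_replicates):
        keep = rng.random(n_frag) >= spec.replicate_dropout_prob
        jitter = rng.normal(0.0, spec.size_call_sd_bp, size=n_frag)
        sizes = lengths + jitter
        called[r, keep] = sizes[keep]
        areas = intens * spec.total_area
        profiles.append(
            PeakProfile(sample_id, f"rep{r + 1}", sizes[keep], areas[keep])
        )
    return profiles, ArisaTruth(lengths, intens, called)


# ---------------------------------------------------------------------------
# Tag-sequence tables


@dataclass
class CommunitySpec:
    """Multi-sample OTU community with a designed shared core.

    Core OTUs appear in every sample; each sample additionally carries its
    own private OTUs.  Within each group, relative abundances decay
    geometrically with rank (``abundance_decay``); the core receives
    ``core_weight`` of each sample's sequencing effort.  Singleton OTUs
    (one read in the whole dataset) are appended at ``singleton_rate`` of
    the final OTU total.
    """

    n_samples: int = 3
    n_core_otus: int = 18
    n_unique_otus_per_sample: int = 27
    reads_per_sample: int = 5000
    core_weight: float = 0.8
    abundance_decay: float = 0.9
    singleton_rate: float = 0.0
    taxonomy_pool: tuple[str, ...] = (
        "Bacteria;Proteobacteria;Gammaproteobacteria;Alteromonadales;Alteromonadaceae;Teredinibacter",
        "Bacteria;Proteobacteria;Alphaproteobacteria;Rhodobacterales;Rhodobacteraceae;Thalassobacter",
        "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfobacterales;Desulfobulbaceae;Desulforhopalus",
        "Bacteria;Actinobacteria;Actinobacteria;Micrococcales;Demequinaceae;Demequina",
        "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;unassigned",
        "Bacteria;Bacteroidetes;Flavobacteria;Flavobacteriales;Flavobacteriaceae;Cellulophaga",
        "Bacteria;Verrucomicrobia;Verrucomicrobiae;Verrucomicrobiales;Verrucomicrobiaceae;unassigned",
        "Bacteria;Planctomycetes;Planctomycetacia;Planctomycetales;Planctomycetaceae;Blastopirellula",
    )

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.reads_per_sample < 1:
            raise ValueError("need at least one sample and one read per sample")
        if min(self.n_core_otus, self.n_unique_otus_per_sample) < 0:
            raise ValueError("OTU counts must be non-negative")
        if not 0.0 <= self.singleton_rate < 1.0:
            raise ValueError("singleton_rate must be in [0, 1)")

    @property
    def designed_shared_fraction(self) -> float:
        """Core OTUs over the pooled designed (non-singleton) OTU list."""
        pooled = self.n_core_otus + self.n_samples * self.n_unique_otus_per_sample
        return self.n_core_otus / pooled if pooled else 0.0


@dataclass
class CommunityTruth:
    designed_shared_fraction: float
    otu_roles: pd.Series  # otu id → "core" | "unique:<sample>" | "singleton"
    designed_abundances: pd.DataFrame  # samples × OTUs, expected proportions


def _geometric_weights(n: int, decay: float) -> np.ndarray:
    w = decay ** np.arange(n)
    return w / w.sum()


def gen_tag_table(
    spec: CommunitySpec, seed: int | None = None
) -> tuple[TagTable, CommunityTruth]:
    """Multinomial sample × OTU count table with a designed shared core."""
    rng = np.random.default_rng(seed)
    samples = [f"s{i + 1}" for i in range(spec.n_samples)]
    core_ids = [f"core_{i:04d}" for i in range(spec.n_core_otus)]
    unique_ids = {
        s: [f"uniq_{s}_{i:04d}" for i in range(spec.n_unique_otus_per_sample)]
        for s in samples
    }
    all_ids = core_ids + [o for s in samples for o in unique_ids[s]]
    roles = {o: "core" for o in core_ids}
    for s in samples:
        for o in unique_ids[s]:
            roles[o] = f"unique:{s}"

    core_w = _geometric_weights(spec.n_core_otus, spec.abundance_decay) if core_ids else np.array([])
    design = pd.DataFrame(0.0, index=samples, columns=all_ids)
    for s in samples:
        if len(core_ids):
            design.loc[s, core_ids] = spec.core_weight * core_w
        if unique_ids[s]:
            uw = _geometric_weights(len(unique_ids[s]), spec.abundance_decay)
            design.loc[s, unique_ids[s]] = (1.0 - spec.core_weight) * uw
        design.loc[s] /= design.loc[s].sum()

    counts = pd.DataFrame(0, index=samples, columns=all_ids, dtype=np.int64)
    for s in samples:
        counts.loc[s] = rng.multinomial(spec.reads_per_sample, design.loc[s].values)

    # append designed singletons: one read each, placed in a random sample
    if spec.singleton_rate > 0:
        n_design = len(all_ids)
        n_single = int(round(spec.singleton_rate / (1 - spec.singleton_rate) * n_design))
        single_ids = [f"single_{i:04d}" for i in range(n_single)]
        placement = rng.integers(0, spec.n_samples, size=n_single)
        single_block = pd.DataFrame(0, index=samples, columns=single_ids, dtype=np.int64)
        for o, si in zip(single_ids, placement):
            single_block.loc[samples[si], o] = 1
        counts = pd.concat([counts, single_block], axis=1)
        for o in single_ids:
            roles[o] = "singleton"

    taxonomy = pd.Series(
        {
            o: spec.taxonomy_pool[i % len(spec.taxonomy_pool)]
            for i, o in enumerate(counts.columns)
        }
    )
    truth = CommunityTruth(
        spec.designed_shared_fraction, pd.Series(roles), design
    )
    return TagTable(counts, taxonomy), truth


# ---------------------------------------------------------------------------
# Radiotracer incubations


def gen_tracer_layers(
    true_rates_nmol_cm3_d: list[float],
    pool_mM: float = 30.0,
    porosity: float = 0.8,
    incubation_time_h: float = 12.0,
    fractionation_factor: float = 1.06,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[list[TracerIncubation], list[float]]:
    """Invert designed layer rates into tracer-fraction incubation rows."""
    rng = np.random.default_rng(seed)
    pool_nmol_cm3 = pool_mM * 1_000.0
    time_d = incubation_time_h / 24.0
    layers = []
    for i, rate in enumerate(true_rates_nmol_cm3_d):
        fraction = rate * time_d / (pool_nmol_cm3 * porosity * fractionation_factor)
        if noise_sd:
            fraction = max(0.0, fraction + rng.normal(0.0, noise_sd))
        layers.append(
            TracerIncubation(
                depth_cm=float(i),
                tracer_product_fraction=float(fraction),
                pool_concentration_mM=pool_mM,
                porosity=porosity,
                incubation_time_h=incubation_time_h,
                fractionation_factor=fractionation_factor,
            )
        )
    return layers, list(true_rates_nmol_cm3_d)
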