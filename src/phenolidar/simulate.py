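"""Synthetic field trials with known ground truth.

The generator emulates the data a ground-based LiDAR phenotyping campaign
produces, with every source of variation controlled and recoverable:

* genotype effects on maximum height, canopy density (peak green-area
  index), developmental rate and phenology (GS31/GS65 dates);
* smooth second-order spatial trend over the field plus independent row and
  column effects — deliberately *not* identical to the row/column model the
  statistics module fits, so the analysis is stressed under mild model
  misspecification;
* LiDAR scans: a regular grid of nadir beams per plot; each beam traverses
  the canopy top-down through thin layers and is intercepted in a layer
  with probability 1 − exp(−k·d·Δz) (Beer–Lambert, with d the green-area
  density), else returns from the soil. Exactly one return per beam; z
  noise is truncated at ±3 sd so returns never fall below terrain − 3 sd;
* destructive AGB sampling with noise sd scaling as 1/sqrt(quadrat area) —
  small quadrats are noisier, which is what drives the repeatability gap
  between destructive AGB and the LiDAR indices;
* an NDVI surrogate: a saturating function of green-area index with
  additive noise (no radiometric model).

Canopy height and green area follow logistic trajectories between sowing
and anthesis — the simplest monotone saturating growth law. All randomness
flows through explicit seeds; the same seed gives bit-identical output.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import TrialDesign
from .errors import ValidationError
from .pointcloud import PointCloud

__all__ = [
    "ScanConfig",
    "TruthSpec",
    "SimTruth",
    "simulate_truth",
    "simulate_scan",
    "simulate_agb",
    "simulate_ndvi",
    "simulate_trait",
    "interception_probability",
    "AGB_REFERENCE_AREA",
]

#: Reference quadrat area (m²) at which the configured AGB noise sd applies.
AGB_REFERENCE_AREA = 1.0


@dataclass(frozen=True)
class ScanConfig:
    """Scanner geometry and interception-model settings.

    ``extinction`` is the dimensionless canopy light-extinction coefficient
    k (≈0.4–0.7 for wheat); interception per layer of thickness Δz at
    green-area density d (m²/m³) is 1 − exp(−k·d·Δz). ``gap_fraction`` is
    the fraction of beams falling in permanent inter-row gaps that reach
    the soil regardless of canopy state.
    """

    beam_spacing_along: float = 0.03
    beam_spacing_across: float = 0.03
    layer_thickness: float = 0.01
    extinction: float = 0.5
    gap_fraction: float = 0.05
    noise_sd: float = 0.005

    def __post_init__(self):
        if min(self.beam_spacing_along, self.beam_spacing_across, self.layer_thickness) <= 0:
            raise ValidationError("beam spacings and layer thickness must be > 0")
        if self.extinction < 0 or not (0.0 <= self.gap_fraction < 1.0):
            raise ValidationError("extinction must be >= 0 and gap_fraction in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class TruthSpec:
    """Variance settings of the generator.

    Latent genotype-parameter spreads (height, canopy density, rate,
    phenology) shape what the scanner sees; ``agb_sigma2_g`` and
    ``agb_sigma2_e`` are the genotypic and residual variances of the
    observed destructive-AGB trait (t/ha)², the residual applying at the
    1 m² reference quadrat. Spatial settings are multiplicative anomalies.
    """

    height_base: float = 0.85  # m, mean maximum height
    height_sd: float = 0.08
    gai_base: float = 5.0  # peak green-area index
    gai_log_sd: float = 0.15
    growth_sd: float = 0.06  # sd of the developmental-rate multiplier
    phenology_sd_days: float = 3.0
    gs31_offset_days: int = 80  # days after sowing (population mean)
    gs65_offset_days: int = 125
    agb_base: float = 12.0  # t/ha at anthesis for an average genotype
    agb_sigma2_g: float = 1.44
    agb_sigma2_e: float = 2.4  # at the 1 m² reference quadrat
    ndvi_sigma2_e: float = 4e-4
    row_sd: float = 0.03
    col_sd: float = 0.03
    trend_scale: float = 0.04
    terrain_slope: float = 0.01  # m per plot column (gentle cross-field slope)

    def __post_init__(self):
        for name in ("height_sd", "gai_log_sd", "growth_sd", "phenology_sd_days",
                     "agb_sigma2_g", "row_sd", "col_sd", "trend_scale"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.agb_sigma2_e <= 0 or self.ndvi_sigma2_e <= 0:
            raise ValidationError("residual variances must be > 0")


# documented scenario constants: the water-limited environment grows slower
# and measures noisier
WATER_LIMITED_GROWTH_FACTOR = 0.6
WATER_LIMITED_NOISE_FACTOR = 2.0


@dataclass
class SimTruth:
    """Ground truth of one simulated trial (see :func:`simulate_truth`)."""

    genotypes: tuple[str, ...]
    height_max: np.ndarray
    gai_max: np.ndarray
    rate_mult: np.ndarray
    gs31: np.ndarray  # datetime.date per genotype
    gs65: np.ndarray
    sowing: dt.date
    spec: TruthSpec
    scenario: str
    trend_coef: np.ndarray
    row_effects: np.ndarray
    col_effects: np.ndarray
    rng_seed: int
    _agb_ceiling: np.ndarray | None = field(default=None, repr=False)
    _agb_density_effect: np.ndarray | None = field(default=None, repr=False)
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {g: i for i, g in enumerate(self.genotypes)}
        for g31, g65 in zip(self.gs31, self.gs65):
            if g31 >= g65:
                raise ValidationError("GS31 must precede GS65 for every genotype")

    # -- developmental trajectories -------------------------------------
    def _logistic(self, gi: int, date) -> float:
        t = (pd.Timestamp(date).date() - self.sowing).days
        t31 = (self.gs31[gi] - self.sowing).days
        t65 = (self.gs65[gi] - self.sowing).days
        # base rate puts the curve at 25% of its ceiling at GS31 and 75% at
        # GS65 (a first-node wheat canopy is roughly a quarter of final
        # height); rate modifiers pivot the curve around GS31, so slower
        # growth lowers everything after stem elongation
        r = 2.0 * np.log(3.0) / max(t65 - t31, 1)
        r *= self.rate_mult[gi]
        if self.scenario == "water_limited":
            r *= WATER_LIMITED_GROWTH_FACTOR
        t_mid = t31 + np.log(3.0) / r
        return float(1.0 / (1.0 + np.exp(-r * (t - t_mid))))

    def index(self, genotype: str) -> int:
        return self._index[genotype]

    def height_at(self, genotype: str, date) -> float:
        gi = self.index(genotype)
        return float(self.height_max[gi] * self._logistic(gi, date))

    def gai_at(self, genotype: str, date) -> float:
        gi = self.index(genotype)
        return float(self.gai_max[gi] * self._logistic(gi, date))

    def agb_expected(self, genotype: str, date) -> float:
        gi = self.index(genotype)
        return float(self._agb_ceiling[gi] * self._logistic(gi, date))

    def spatial_mult(self, row: int, col: int) -> float:
        """Multiplicative canopy/AGB anomaly at a field position."""
        nr, nc = len(self.row_effects), len(self.col_effects)
        r = (row - (nr + 1) / 2.0) / max(nr, 1)
        c = (col - (nc + 1) / 2.0) / max(nc, 1)
        a = self.trend_coef
        trend = a[0] * r + a[1] * c + a[2] * r * r + a[3] * c * c + a[4] * r * c
        return float(
            1.0 + trend + self.row_effects[row - 1] + self.col_effects[col - 1]
        )

    @property
    def agb_genotype_effects(self) -> np.ndarray:
        """Additive genotype effects on biomass density (t/ha).

        The canopy-size contribution (height × green area) is excluded;
        this is the independent tissue-density component with the
        configured genotypic variance.
        """
        return self._agb_density_effect

    def terrain_z(self, row: int, col: int) -> float:
        # constant along a column of plots: the ground model pools soil
        # returns per column, as the scanner traverses column-wise
        return float(self.spec.terrain_slope * (col - 1))

    def noise_factor(self) -> float:
        return WATER_LIMITED_NOISE_FACTOR if self.scenario == "water_limited" else 1.0

    # -- recovery hooks --------------------------------------------------
    def phenology_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"genotype": self.genotypes, "gs31": self.gs31, "gs65": self.gs65}
        )

    def true_repeatability(
        self, trait: str, nrep: float, quadrat_area: float | None = None
    ) -> float:
        """Implied ρ = σ²g/(σ²g + σ²ε/nrep) of a directly simulated trait.

        For AGB the residual variance is rescaled to the given quadrat
        area; values refer to the anthesis scale at which the configured
        genotypic variance applies.
        """
        if trait != "agb":
            raise ValidationError(f"no configured variances for trait {trait!r}")
        s2g = self.spec.agb_sigma2_g
        s2e = self.spec.agb_sigma2_e * self.noise_factor() ** 2
        if quadrat_area is not None:
            if quadrat_area <= 0:
                raise ValidationError("quadrat_area must be > 0")
            s2e *= AGB_REFERENCE_AREA / quadrat_area
        if s2g == 0.0:
            return 0.0
        return s2g / (s2g + s2e / nrep)


def simulate_truth(
    design: TrialDesign,
    variance_spec: TruthSpec | None = None,
    scenario: str = "well_watered",
    rng_seed: int = 0,
    *,
    sowing: dt.date = dt.date(2016, 5, 23),
) -> SimTruth:
    """Draw genotype effects, phenology and spatial fields for a trial."""
    if scenario not in ("well_watered", "water_limited"):
        raise ValidationError(f"unknown scenario {scenario!r}")
    spec = variance_spec or TruthSpec()
    rng = np.random.default_rng(rng_seed)
    genotypes = design.genotypes
    ng = len(genotypes)

    height = np.clip(spec.height_base + spec.height_sd * rng.standard_normal(ng), 0.3, None)
    gai = spec.gai_base * np.exp(spec.gai_log_sd * rng.standard_normal(ng))
    rate = np.clip(1.0 + spec.growth_sd * rng.standard_normal(ng), 0.5, None)

    g31_jit = np.rint(spec.phenology_sd_days * rng.standard_normal(ng)).astype(int)
    span_jit = np.rint(spec.phenology_sd_days * rng.standard_normal(ng)).astype(int)
    gs31 = np.array(
        [sowing + dt.timedelta(days=int(spec.gs31_offset_days + j)) for j in g31_jit]
    )
    span = spec.gs65_offset_days - spec.gs31_offset_days
    gs65 = np.array(
        [
            d + dt.timedelta(days=int(max(span + j, 7)))
            for d, j in zip(gs31, span_jit)
        ]
    )

    nr = max(p.row for p in design.plots)
    nc = max(p.col for p in design.plots)
    trend = spec.trend_scale * rng.standard_normal(5)
    row_eff = spec.row_sd * rng.standard_normal(nr)
    col_eff = spec.col_sd * rng.standard_normal(nc)

    truth = SimTruth(
        genotypes=genotypes,
        height_max=height,
        gai_max=gai,
        rate_mult=rate,
        gs31=gs31,
        gs65=gs65,
        sowing=sowing,
        spec=spec,
        scenario=scenario,
        trend_coef=trend,
        row_effects=row_eff,
        col_effects=col_eff,
        rng_seed=rng_seed,
    )
    # AGB ceiling per genotype: biomass tracks canopy volume × density.
    # The canopy-size factor couples AGB to what the scanner sees (height ×
    # green area); the additive effect on top is independent
    # tissue-density variation with the configured genotypic variance.
    volume_factor = (height * gai) / (spec.height_base * spec.gai_base)
    g_agb = np.sqrt(spec.agb_sigma2_g) * rng.standard_normal(ng)
    truth._agb_density_effect = g_agb
    truth._agb_ceiling = np.clip((spec.agb_base + g_agb) * volume_factor, 0.1, None)
    return truth


def interception_probability(extinction: float, density: float, dz: float) -> float:
    """Beer–Lambert interception of one layer: 1 − exp(−k·d·Δz)."""
    if extinction < 0 or density < 0 or dz <= 0:
        raise ValidationError("extinction/density must be >= 0 and dz > 0")
    return float(1.0 - np.exp(-extinction * density * dz))


def _scan_one_plot(rect, h, gai, terrain, config: ScanConfig, rng) -> PointCloud:
    sx, sy = config.beam_spacing_across, config.beam_spacing_along
    xs = np.arange(rect.x_min + sx / 2.0, rect.x_max, sx)
    ys = np.arange(rect.y_min + sy / 2.0, rect.y_max, sy)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    x = gx.ravel() + rng.uniform(-0.2 * sx, 0.2 * sx, gx.size)
    y = gy.ravel() + rng.uniform(-0.2 * sy, 0.2 * sy, gy.size)
    nb = x.size

    dz = config.layer_thickness
    n_layers = int(np.ceil(h / dz)) if h > 0 else 0
    z = np.full(nb, terrain)
    if n_layers > 0 and gai > 0:
        d = gai / h  # uniform vertical green-area density, m²/m³
        p = interception_probability(config.extinction, d, dz)
        canopy = rng.uniform(size=nb) >= config.gap_fraction
        if p >= 1.0:
            layer = np.zeros(nb, dtype=np.int64)
        else:
            u = rng.uniform(size=nb)
            with np.errstate(divide="ignore"):
                layer = np.floor(np.log(u) / np.log1p(-p)).astype(np.int64)
        hit = canopy & (layer < n_layers)
        # layer midpoints, clamped so a partial bottom layer cannot place a
        # return below the soil surface
        z[hit] = np.maximum(terrain + h - (layer[hit] + 0.5) * dz, terrain)
    if config.noise_sd > 0:
        noise = np.clip(
            rng.standard_normal(nb) * config.noise_sd,
            -3.0 * config.noise_sd,
            3.0 * config.noise_sd,
        )
        z = z + noise
    return PointCloud(x, y, z)


def simulate_scan(
    design: TrialDesign,
    truth: SimTruth,
    date,
    config: ScanConfig = ScanConfig(),
    rng_seed: int = 0,
) -> dict[str, PointCloud]:
    """Simulate one scanning event; returns one cloud per plot_id.

    Every beam yields exactly one return: either a canopy interception
    (first layer, top-down, whose Beer–Lambert draw succeeds) or a soil
    return at the plot's terrain elevation. Canopy state follows each
    genotype's logistic growth at ``date`` times the plot's spatial
    anomaly.
    """
    if design.n_plots == 0:
        raise ValidationError("design has no plots")
    rng = np.random.default_rng(rng_seed)
    clouds: dict[str, PointCloud] = {}
    for p in design.plots:
        s = truth.spatial_mult(p.row, p.col)
        h = truth.height_at(p.genotype, date) * max(s, 0.0)
        gai = truth.gai_at(p.genotype, date) * max(s, 0.0)
        clouds[p.plot_id] = _scan_one_plot(
            p.rect, h, gai, truth.terrain_z(p.row, p.col), config, rng
        )
    return clouds


def simulate_agb(
    design: TrialDesign,
    truth: SimTruth,
    date,
    quadrat_area: float,
    rng_seed: int = 0,
    *,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Destructive AGB sampling (t/ha) of every plot on one date.

    The plot expectation is the genotype's logistic AGB trajectory times
    its spatial anomaly; sampling noise has sd
    ``sd_ref × sqrt(reference_area / quadrat_area)`` so smaller quadrats
    are noisier. ``noise_sd`` overrides the configured reference sd
    (0 gives the deterministic expectation).
    """
    if quadrat_area <= 0:
        raise ValidationError("quadrat_area must be > 0")
    rng = np.random.default_rng(rng_seed)
    sd_ref = (
        np.sqrt(truth.spec.agb_sigma2_e) * truth.noise_factor()
        if noise_sd is None
        else float(noise_sd)
    )
    sd = sd_ref * np.sqrt(AGB_REFERENCE_AREA / quadrat_area)
    rows = []
    date_ts = pd.Timestamp(date).date()
    for p in design.plots:
        mean = truth.agb_expected(p.genotype, date_ts) * truth.spatial_mult(p.row, p.col)
        value = mean + sd * rng.standard_normal() if sd > 0 else mean
        rows.append(
            {
                "plot_id": p.plot_id,
                "genotype": p.genotype,
                "date": date_ts,
                "trait": "agb",
                "value": max(value, 0.0) if sd > 0 else value,
            }
        )
    return pd.DataFrame(rows)


def simulate_ndvi(
    design: TrialDesign,
    truth: SimTruth,
    date,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """NDVI surrogate: saturating in green-area index, additive noise."""
    rng = np.random.default_rng(rng_seed)
    sd = np.sqrt(truth.spec.ndvi_sigma2_e) * truth.noise_factor()
    rows = []
    date_ts = pd.Timestamp(date).date()
    for p in design.plots:
        gai = truth.gai_at(p.genotype, date_ts) * max(truth.spatial_mult(p.row, p.col), 0.0)
        mean = 0.15 + 0.75 * (1.0 - np.exp(-0.5 * gai))
        value = np.clip(mean + sd * rng.standard_normal(), 0.0, 1.0)
        rows.append(
            {
                "plot_id": p.plot_id,
                "genotype": p.genotype,
                "date": date_ts,
                "trait": "ndvi",
                "value": float(value),
            }
        )
    return pd.DataFrame(rows)


def simulate_trait(
    design: TrialDesign,
    sigma2_g: float,
    sigma2_e: float,
    rng_seed: int = 0,
    *,
    mean: float = 0.0,
) -> pd.DataFrame:
    """Directly simulate a generic plot trait: y = μ + g(genotype) + ε.

    The exact variance-component sampler used by parameter-recovery tests;
    its implied repeatability is σ²g/(σ²g + σ²ε/nrep).
    """
    if sigma2_g < 0 or sigma2_e < 0:
        raise ValidationError("variances must be >= 0")
    rng = np.random.default_rng(rng_seed)
    genotypes = design.genotypes
    g = np.sqrt(sigma2_g) * rng.standard_normal(len(genotypes))
    lookup = dict(zip(genotypes, g))
    rows = []
    for p in design.plots:
        rows.append(
            {
                "plot_id": p.plot_id,
                "genotype": p.genotype,
                "row": p.row,
                "col": p.col,
                "value": mean + lookup[p.genotype] + np.sqrt(sigma2_e) * rng.standard_normal(),
            }
        )
    return pd.DataFrame(rows)
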