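"""Synthetic mpMRI + expression study generator with known ground truth.

Emulates the study design the pipeline targets: a prostate gland partitioned
into peripheral zone (PZ), transition zone (TZ) and urethra, with
normal-appearing-tissue (NAT) reference regions and tumor-suspicious biopsy
ROIs.  Geometry is built from nested ellipsoids and a cylindrical urethra on
an anisotropic voxel grid.

Signal model
------------
* T2w and ADC are region-mean Gaussian fields (per-region mean/sd).
* DCE voxel curves are forward extended-Tofts curves driven by the Parker
  population AIF, with region-specific (Ktrans, kep, vp) plus additive
  Gaussian noise; 13 frames (1 pre-contrast + 12 post-contrast) at 30 s
  spacing by default.
* The expression matrix is SCAN-normalized-like (values around [0, 1]):
  planted genes are linear-plus-noise transforms of named radiomic features
  achieving a target correlation, a configurable fraction of genes is
  low-expression (median < 0.25 and IQR < 0.5, removable by the filter), and
  the rest is independent noise.

Everything is deterministic for a fixed ``rng_seed``: each substream derives
its own generator from the master seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError
from .pharmacokinetics import PKParameters, parker_aif, tofts_forward
from .study import MpMRIStudy

__all__ = [
    "RegionParams",
    "SyntheticConfig",
    "GroundTruth",
    "generate_study",
    "generate_cohort",
    "generate_expression",
]


@dataclass(frozen=True)
class RegionParams:
    """Tissue parameters for one region class.

    T2w is in arbitrary signal units; ADC in um^2/s; Ktrans and kep in
    min^-1; vp a plasma volume fraction.  The sd fields are voxelwise
    biological heterogeneity, not scanner noise.
    """

    t2w_mean: float
    t2w_sd: float
    adc_mean: float
    adc_sd: float
    ktrans: float
    kep: float
    vp: float

    def pk(self) -> PKParameters:
        return PKParameters.from_rates(self.ktrans, self.kep, self.vp)


def _default_region_params() -> dict[str, RegionParams]:
    return {
        # Healthy PZ: high ADC, slow contrast uptake.
        "pz": RegionParams(180.0, 20.0, 1500.0, 140.0, 0.05, 0.40, 0.010),
        # TZ: intermediate ADC, moderately vascular stroma.
        "tz": RegionParams(120.0, 15.0, 1150.0, 120.0, 0.12, 0.60, 0.015),
        # Urethra: fluid-bright, very high ADC, weak enhancement.
        "urethra": RegionParams(210.0, 20.0, 2200.0, 150.0, 0.03, 0.35, 0.010),
        # Tumor: restricted diffusion, rapid wash-in and washout.
        "tumor": RegionParams(90.0, 12.0, 700.0, 50.0, 0.45, 1.60, 0.020),
    }


_DEFAULT_PLANTED = (
    ("ROI_ADC_Mean", "KLK3", -0.9),
    ("ROI_Ktrans", "TRPM8", 0.9),
    ("ProbMap.High_Volume", "MKI67", 0.9),
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults describe the emulated acquisition: 13 DCE frames (one
    pre-contrast plus twelve post-contrast) at 30 s spacing on a 64^3 grid of
    1 x 1 x 1.5 mm voxels, a 17-biopsy cohort from 6 patients, and a
    200-gene expression matrix with three planted feature-gene links and 15%
    filter-removable low-expression genes.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.5)
    n_timepoints: int = 13
    dt_s: float = 30.0
    region_params: dict[str, RegionParams] = field(default_factory=_default_region_params)
    n_genes: int = 200
    n_samples: int = 17
    n_patients: int = 6
    planted_links: Sequence[tuple[str, str, float]] = _DEFAULT_PLANTED
    low_expression_fraction: float = 0.15
    dce_noise_sd: float = 0.02
    expression_scale: float = 0.12
    expression_center: float = 0.55
    param_jitter: float = 0.10
    hct: float = 0.42
    rng_seed: int = 0

    def __post_init__(self):
        if any(int(n) <= 0 for n in self.grid_shape) or len(self.grid_shape) != 3:
            raise ConfigurationError("grid_shape must be three positive ints")
        if self.dt_s <= 0:
            raise ConfigurationError("dt_s must be > 0")
        if self.n_timepoints < 4:
            raise ConfigurationError("need at least 4 DCE frames")
        for name, rp in self.region_params.items():
            if not (0 <= rp.vp < 1):
                raise ConfigurationError(f"region '{name}': vp must be in [0, 1)")
            if rp.ktrans > 0 and rp.kep <= 0:
                raise ConfigurationError(f"region '{name}': kep must be > 0 when ktrans > 0")
        for feat, gene, r in self.planted_links:
            if not (-1.0 <= r <= 1.0):
                raise ConfigurationError(
                    f"planted link {feat}~{gene}: target correlation {r} outside [-1, 1]")
        if not (0 <= self.low_expression_fraction < 1):
            raise ConfigurationError("low_expression_fraction must be in [0, 1)")

    @classmethod
    def zero_noise(cls, **overrides) -> "SyntheticConfig":
        """A noise-free variant: voxel fields equal region means, DCE curves
        equal the forward model exactly, and no per-patient parameter jitter."""
        params = {
            name: RegionParams(rp.t2w_mean, 0.0, rp.adc_mean, 0.0,
                               rp.ktrans, rp.kep, rp.vp)
            for name, rp in _default_region_params().items()
        }
        kw = dict(region_params=params, dce_noise_sd=0.0, param_jitter=0.0)
        kw.update(overrides)
        return cls(**kw)

    @property
    def t_min(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.dt_s / 60.0


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream verification."""

    region_labels: np.ndarray          # per-voxel region name index
    label_names: tuple[str, ...]       # index -> region name
    tumor_mask: np.ndarray             # union of biopsy ROIs (true habitat)
    region_pk: dict[str, PKParameters]  # realized PK parameters per region
    region_curves: dict[str, np.ndarray]  # noiseless tissue curve per region
    region_params: dict[str, RegionParams]
    seed: int


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    q = sum(((idx[i] - center[i]) / semiaxes[i]) ** 2 for i in range(3))
    return q <= 1.0


def _ball(r: int) -> np.ndarray:
    z = np.indices((2 * r + 1,) * 3) - r
    return (z ** 2).sum(axis=0) <= r ** 2


def _place_sphere(zone: np.ndarray, radius: int, rng: np.random.Generator,
                  forbidden: np.ndarray | None = None) -> np.ndarray:
    """Pick a sphere of ``radius`` fully inside ``zone`` (minus ``forbidden``),
    deterministically under ``rng``.  Raises if no center fits."""
    allowed_zone = zone & ~forbidden if forbidden is not None else zone
    allowed = ndimage.binary_erosion(allowed_zone, structure=_ball(radius))
    centers = np.argwhere(allowed)
    if len(centers) == 0:
        raise ConfigurationError(
            f"no room for a radius-{radius} region inside the requested zone")
    c = centers[rng.integers(len(centers))]
    out = np.zeros(zone.shape, dtype=bool)
    sl = tuple(slice(max(0, ci - radius), ci + radius + 1) for ci in c)
    sub = _ball(radius)
    out[sl] = sub[tuple(slice(0, s.stop - s.start) for s in sl)]
    return out & zone


def _jitter(rp: RegionParams, frac: float, rng: np.random.Generator) -> RegionParams:
    if frac <= 0:
        return rp
    f = lambda v: float(v * (1.0 + frac * rng.uniform(-1, 1)))
    return RegionParams(f(rp.t2w_mean), rp.t2w_sd, f(rp.adc_mean), rp.adc_sd,
                        f(rp.ktrans), f(rp.kep), min(f(rp.vp), 0.5))


def generate_study(config: SyntheticConfig, patient_index: int = 0,
                   n_biopsies: int = 3) -> tuple[MpMRIStudy, GroundTruth]:
    """Generate one patient's synthetic mpMRI study plus its ground truth.

    ``patient_index`` selects an independent random substream and (when
    ``param_jitter`` > 0) a patient-specific perturbation of region
    parameters and gland size, so cohorts show between-patient variation.
    """
    ss = np.random.SeedSequence([int(config.rng_seed), 101, int(patient_index)])
    rng_geom, rng_tissue, rng_noise, rng_sem = (
        np.random.default_rng(s) for s in ss.spawn(4))

    shape = tuple(int(n) for n in config.grid_shape)
    nx, ny, nz = shape
    cx, cy, cz = nx / 2.0, ny / 2.0, nz / 2.0

    size_jit = 1.0 + config.param_jitter * rng_geom.uniform(-1, 1)
    semi = (0.34 * nx * size_jit, 0.30 * ny * size_jit, 0.28 * nz * size_jit)
    prostate = _ellipsoid(shape, (cx, cy, cz), semi)
    if not prostate.any():
        raise ConfigurationError("grid too small: empty prostate mask")

    # Urethra: central cylinder along z, clipped to the gland.
    r_u = max(1, round(0.030 * nx))
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cyl = ((xs - cx) ** 2 + (ys - cy) ** 2 <= r_u ** 2)[..., None] & np.ones((1, 1, nz), bool)
    urethra = cyl & prostate

    # PZ: the posterior portion of the gland; TZ is the remainder.
    pz = prostate & (np.arange(ny)[None, :, None] >= cy + 0.06 * ny) & ~urethra
    tz = prostate & ~pz & ~urethra
    if not pz.any() or not tz.any():
        raise ConfigurationError("degenerate zonal anatomy on this grid")

    # Biopsy ROIs: tumor-signal spheres of varying size, alternating PZ / TZ
    # placement.
    occupied = np.zeros(shape, dtype=bool)
    rois: dict[str, np.ndarray] = {}
    roi_zones: dict[str, str] = {}
    for b in range(int(n_biopsies)):
        zone_name = "pz" if b % 2 == 0 else "tz"
        zone = pz if zone_name == "pz" else tz
        r_roi = max(2, round(0.065 * nx * (1.0 + 0.3 * rng_geom.uniform(-1, 1))))
        m = _place_sphere(zone, r_roi, rng_geom,
                          forbidden=ndimage.binary_dilation(occupied, _ball(2)))
        name = f"roi_{b + 1:02d}"
        rois[name] = m
        roi_zones[name] = zone_name
        occupied |= m

    # NAT reference regions avoid every ROI.
    r_nat = max(2, round(0.055 * nx))
    forbidden = ndimage.binary_dilation(occupied, _ball(2))
    nat_pz = _place_sphere(pz, r_nat, rng_geom, forbidden=forbidden)
    nat_tz = _place_sphere(tz, r_nat, rng_geom, forbidden=forbidden)

    # Per-voxel region class: zone background, urethra, then tumor overrides.
    label_names = ("background", "pz", "tz", "urethra", "tumor")
    labels = np.zeros(shape, dtype=np.uint8)
    labels[pz] = 1
    labels[tz] = 2
    labels[urethra] = 3
    tumor_mask = np.zeros(shape, dtype=bool)
    for m in rois.values():
        tumor_mask |= m
    labels[tumor_mask] = 4

    params = {name: _jitter(rp, config.param_jitter, rng_tissue)
              for name, rp in config.region_params.items()}

    t2w = np.zeros(shape)
    adc = np.zeros(shape)
    for li, region in ((1, "pz"), (2, "tz"), (3, "urethra"), (4, "tumor")):
        m = labels == li
        rp = params[region]
        t2w[m] = rp.t2w_mean + rp.t2w_sd * rng_noise.standard_normal(int(m.sum()))
        adc[m] = rp.adc_mean + rp.adc_sd * rng_noise.standard_normal(int(m.sum()))
    # Background outside the gland: dim T2w, mid ADC, for visual realism only.
    bg = labels == 0
    t2w[bg] = 40.0 + 8.0 * rng_noise.standard_normal(int(bg.sum()))
    adc[bg] = np.maximum(
        900.0 + 150.0 * rng_noise.standard_normal(int(bg.sum())), 1.0)

    # DCE: one noiseless forward-Tofts curve per region class, broadcast to
    # its voxels, plus iid Gaussian noise.
    t_min = config.t_min
    aif = parker_aif(np.linspace(0, float(t_min.max()), max(2, int(t_min.max() * 60) + 1)),
                     hct=config.hct)
    region_pk = {name: rp.pk() for name, rp in params.items()}
    region_curves = {name: tofts_forward(pk, aif, t_min).C
                     for name, pk in region_pk.items()}
    dce = np.zeros(shape + (config.n_timepoints,))
    for li, region in ((1, "pz"), (2, "tz"), (3, "urethra"), (4, "tumor")):
        dce[labels == li] = region_curves[region]
    if config.dce_noise_sd > 0:
        dce += config.dce_noise_sd * rng_noise.standard_normal(dce.shape)

    study = MpMRIStudy(
        t2w=t2w, adc=adc, dce=dce, t_min=t_min,
        voxel_size_mm=tuple(config.voxel_size_mm),
        masks={"prostate": prostate, "pz": pz, "tz": tz, "urethra": urethra,
               "nat_pz": nat_pz, "nat_tz": nat_tz},
        rois=rois, roi_zones=roi_zones,
        ece=int(rng_sem.random() < 0.4),
        patient_id=f"P{patient_index + 1:03d}",
        metadata={"rng_seed": int(config.rng_seed),
                  "patient_index": int(patient_index)},
    )
    study.validate_partition()
    for name, m in rois.items():
        if (m & ~prostate).any():
            raise ConfigurationError(f"ROI {name} extends outside the prostate")
    gt = GroundTruth(region_labels=labels, label_names=label_names,
                     tumor_mask=tumor_mask, region_pk=region_pk,
                     region_curves=region_curves, region_params=params,
                     seed=int(config.rng_seed))
    return study, gt


def biopsy_allocation(config: SyntheticConfig) -> list[int]:
    """Distribute ``n_samples`` biopsies over ``n_patients`` as evenly as
    possible (earlier patients take the remainder)."""
    if config.n_patients <= 0 or config.n_samples < config.n_patients:
        raise ConfigurationError("need n_samples >= n_patients >= 1")
    base, rem = divmod(config.n_samples, config.n_patients)
    return [base + (1 if i < rem else 0) for i in range(config.n_patients)]


def generate_cohort(config: SyntheticConfig) -> list[tuple[MpMRIStudy, GroundTruth]]:
    """Generate the full synthetic cohort (one study per patient)."""
    return [generate_study(config, patient_index=i, n_biopsies=nb)
            for i, nb in enumerate(biopsy_allocation(config))]


@dataclass
class ExpressionGroundTruth:
    planted: list[tuple[str, str, float, float]]  # feature, gene, target r, realized r
    low_expression_genes: list[str]


def generate_expression(config: SyntheticConfig, feature_table: pd.DataFrame,
                        ) -> tuple[pd.DataFrame, ExpressionGroundTruth]:
    """Generate a genes x samples expression matrix tied to a feature table.

    Planted genes are built as ``rho * z(feature) + sqrt(1 - rho^2) * eps``
    rescaled to the SCAN-like range, so their population correlation with the
    named feature equals the target (exact when ``|rho| = 1``).  A
    ``low_expression_fraction`` of genes is drawn uniform on [0.02, 0.2]
    (median < 0.25, IQR < 0.5: removable by the expression filter); remaining
    genes are independent Gaussian noise.
    """
    n = len(feature_table)
    if n != config.n_samples:
        raise ConfigurationError(
            f"feature table has {n} samples but config.n_samples = {config.n_samples}")
    for feat, gene, r in config.planted_links:
        if feat not in feature_table.columns:
            raise ConfigurationError(f"planted link names unknown feature '{feat}'")
        if not (-1.0 <= r <= 1.0):
            raise ConfigurationError(f"target correlation {r} outside [-1, 1]")
    n_planted = len(config.planted_links)
    if config.n_genes < n_planted + 1:
        raise ConfigurationError("n_genes too small for the planted links")

    rng = np.random.default_rng(np.random.SeedSequence([int(config.rng_seed), 7919]))
    samples = list(feature_table.index)

    rows: list[np.ndarray] = []
    ids: list[str] = []
    planted_out: list[tuple[str, str, float, float]] = []
    for feat, gene, rho in config.planted_links:
        x = feature_table[feat].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ConfigurationError(f"planted feature '{feat}' is constant in this cohort")
        z = (x - x.mean()) / x.std()
        y = rho * z + np.sqrt(max(0.0, 1.0 - rho ** 2)) * rng.standard_normal(n)
        g = config.expression_center + config.expression_scale * y
        realized = float(np.corrcoef(x, g)[0, 1])
        rows.append(g)
        ids.append(gene)
        planted_out.append((feat, gene, float(rho), realized))

    n_low = int(round(config.low_expression_fraction * config.n_genes))
    n_low = min(n_low, config.n_genes - n_planted)
    low_ids = []
    for i in range(n_low):
        gid = f"LOWG{i + 1:04d}"
        rows.append(rng.uniform(0.02, 0.20, size=n))
        ids.append(gid)
        low_ids.append(gid)

    for i in range(config.n_genes - n_planted - n_low):
        rows.append(config.expression_center + 0.15 * rng.standard_normal(n))
        ids.append(f"G{i + 1:05d}")

    order = rng.permutation(len(ids))
    expr = pd.DataFrame(np.vstack(rows)[order],
                        index=[ids[i] for i in order], columns=samples)
    expr.index.name = "gene"
    return expr, ExpressionGroundTruth(planted=planted_out, low_expression_genes=low_ids)
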