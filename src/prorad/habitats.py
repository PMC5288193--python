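"""Tumor-habitat delineation from perfusion and diffusion maps.

The DCE series inside the prostate is decomposed into a small number of
nonnegative temporal patterns; the amplitude A of the tumor-like pattern
(rapid wash-in, gradual washout) is thresholded at mean(A) + k * stdev(A)
for k = 2, 1.5 and 1 into high / mid / low perfusion-risk bands.  The ADC
map is binned at 800, 1000 and 1200 um^2/s into high / mid / low
diffusion-risk bands (lower ADC = higher risk).  A voxel's combined habitat
probability is the intersection of the two: ``none`` unless both parents
assign a band, otherwise the lower-risk (more conservative) of the two
labels, so a combined ``high`` requires high perfusion AND restricted
diffusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import NMF

from .errors import ConfigurationError, DegenerateInputError, FactorizationError
from .study import MpMRIStudy

__all__ = [
    "LABELS",
    "AmplitudeMap",
    "HabitatMaps",
    "decompose_dce",
    "perfusion_bands",
    "diffusion_bands",
    "intersect_habitats",
]

#: Band label encoding used in every labelled volume (uint8).
LABELS = {"none": 0, "low": 1, "mid": 2, "high": 3}

#: Amplitude threshold multipliers: high, mid, low risk cutoffs at
#: mean(A) + k * stdev(A).
DEFAULT_K = (2.0, 1.5, 1.0)

#: ADC cutoffs in um^2/s: high <= 800 < mid <= 1000 < low <= 1200 < none.
DEFAULT_ADC_CUTOFFS = (800.0, 1000.0, 1200.0)


@dataclass
class AmplitudeMap:
    """Per-voxel amplitude of the tumor-like temporal pattern.

    A is zero outside the prostate mask and nonnegative inside;
    ``pattern_curves`` holds all fitted temporal patterns (pattern x time)
    and ``pattern_index_tumor`` marks the one identified as tumor-like.
    """

    A: np.ndarray
    mask: np.ndarray
    pattern_curves: np.ndarray
    pattern_index_tumor: int
    reconstruction_err: float = float("nan")
    n_iter: int = 0


@dataclass
class HabitatMaps:
    """Disjoint perfusion/diffusion bands and their intersection."""

    perfusion_band: np.ndarray
    diffusion_band: np.ndarray
    probability_map: np.ndarray
    thresholds_used: dict = field(default_factory=dict)
    band_volumes_cc: dict = field(default_factory=dict)


def _washout_score(curve: np.ndarray, n_pre: int = 1) -> tuple[bool, float, int]:
    """(is tumor-like, washout depth, time-to-peak) for one temporal pattern.

    Tumor-like = peak within the first half of the post-contrast frames AND a
    non-increasing trend over the last third of the series AND a substantial
    drop from peak to the final frame.  A fully washed-out curve has a flat
    zero tail, so the tail-slope test is <= 0 rather than strictly negative.
    """
    c = np.asarray(curve, dtype=float)
    T = len(c)
    peak = int(np.argmax(c))
    post_mid = n_pre + (T - n_pre) // 2
    tail = c[-max(2, T // 3):]
    slope = float(np.polyfit(np.arange(len(tail)), tail, 1)[0])
    scale = float(c.max())
    depth = (c[peak] - c[-1]) / scale if scale > 0 else 0.0
    washing_out = slope <= 1e-9 * max(scale, 1.0) and depth >= 0.1
    return (peak <= post_mid and washing_out), float(depth), peak


def identify_tumor_pattern(patterns: np.ndarray, n_pre: int = 1) -> int:
    """Pick the tumor-like pattern: among candidates with an early peak and a
    falling tail, the one with the deepest washout; ties broken by earliest
    time-to-peak.  Falls back to deepest washout overall if no candidate."""
    scored = [_washout_score(p, n_pre) for p in patterns]
    candidates = [i for i, (ok, _, _) in enumerate(scored) if ok]
    pool = candidates if candidates else list(range(len(patterns)))
    return min(pool, key=lambda i: (-scored[i][1], scored[i][2]))


def decompose_dce(study: MpMRIStudy, n_patterns: int = 3,
                  tol: float = 1e-4, max_iter: int = 2000) -> AmplitudeMap:
    """Factorize prostate DCE curves into nonnegative temporal patterns and
    return the amplitude of the tumor-like one.

    The (voxels x time) enhancement matrix D is factorized as D ~ W @ H with
    W, H >= 0 by NMF (coordinate descent, deterministic NNDSVDa
    initialization, no random restarts).  On noisy data the residual floor is
    the noise itself, so ``tol`` is on the solver's relative progress, not on
    the fit.  Patterns are normalized to unit maximum so amplitudes carry the
    scale.
    """
    if study.dce.shape[-1] < 4:
        raise ConfigurationError("DCE series must have at least 4 frames")
    mask = study.masks["prostate"]
    if not mask.any():
        raise ConfigurationError("prostate mask is empty")
    if n_patterns < 1:
        raise ConfigurationError("n_patterns must be >= 1")

    D = np.clip(np.asarray(study.dce[mask], dtype=float), 0.0, None)
    if D.max() == 0:
        raise DegenerateInputError("all-zero enhancement inside the prostate")

    # Coordinate descent from a deterministic NNDSVDa start (the zero-free
    # variant): no random restarts, and it reaches the tolerance reliably
    # where multiplicative updates stall short of it.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns at max_iter; handled below
        model = NMF(n_components=n_patterns, init="nndsvda", solver="cd",
                    tol=tol, max_iter=max_iter)
        W = model.fit_transform(D)
    H = model.components_
    # The solver's own stopping rule can fail to fire on exactly factorizable
    # data even at machine-precision fits, and on noisy data the residual
    # cannot drop below the noise floor; only a max-iter exit that also left
    # most of the signal unexplained counts as non-convergence.
    rel_err = model.reconstruction_err_ / max(np.linalg.norm(D), 1e-300)
    if model.n_iter_ >= max_iter and rel_err > 0.5:
        raise FactorizationError(
            f"NMF did not converge in {max_iter} iterations "
            f"(relative reconstruction error {rel_err:.3g})",
            n_iter=model.n_iter_, reconstruction_err=model.reconstruction_err_)

    # Move each pattern's scale into its amplitude column.
    scale = H.max(axis=1)
    keep = scale > 0
    H[keep] = H[keep] / scale[keep, None]
    W[:, keep] = W[:, keep] * scale[keep]

    idx = identify_tumor_pattern(H)
    A = np.zeros(study.shape)
    A[mask] = W[:, idx]
    return AmplitudeMap(A=A, mask=mask, pattern_curves=H, pattern_index_tumor=idx,
                        reconstruction_err=float(model.reconstruction_err_),
                        n_iter=int(model.n_iter_))


def perfusion_bands(amap: AmplitudeMap, k: tuple[float, float, float] = DEFAULT_K,
                    ) -> np.ndarray:
    """Label prostate voxels by amplitude band.

    With m = mean(A) and s = stdev(A) over prostate voxels (population
    denominator): high iff A >= m + k_high * s, mid iff the next threshold is
    reached but not high, low likewise; none below m + k_low * s.  A constant
    amplitude map (s = 0) labels every voxel none, with a warning.
    """
    k_high, k_mid, k_low = k
    if not (k_high > k_mid > k_low):
        raise ConfigurationError("k multipliers must be strictly decreasing")
    mask = amap.mask
    if not mask.any():
        raise ConfigurationError("empty mask in perfusion_bands")
    a = amap.A[mask]
    m, s = float(a.mean()), float(a.std())
    out = np.zeros(amap.A.shape, dtype=np.uint8)
    if s == 0:
        warnings.warn("constant amplitude map: no perfusion bands assigned")
        return out
    vals = np.zeros(a.shape, dtype=np.uint8)
    vals[a >= m + k_low * s] = LABELS["low"]
    vals[a >= m + k_mid * s] = LABELS["mid"]
    vals[a >= m + k_high * s] = LABELS["high"]
    out[mask] = vals
    return out


def diffusion_bands(adc: np.ndarray, prostate_mask: np.ndarray,
                    cutoffs: tuple[float, float, float] = DEFAULT_ADC_CUTOFFS,
                    ) -> np.ndarray:
    """Label prostate voxels by ADC band (um^2/s), half-open bins:
    high iff ADC <= c1; mid iff c1 < ADC <= c2; low iff c2 < ADC <= c3;
    none above c3."""
    c1, c2, c3 = cutoffs
    if not (c1 < c2 < c3):
        raise ConfigurationError("ADC cutoffs must be strictly increasing")
    if not prostate_mask.any():
        raise ConfigurationError("empty mask in diffusion_bands")
    vals = np.asarray(adc[prostate_mask], dtype=float)
    neg = vals < 0
    if neg.any():
        locs = np.argwhere(prostate_mask)[neg]
        raise ConfigurationError(
            f"{int(neg.sum())} negative ADC voxel(s) inside the prostate, "
            f"first at {tuple(locs[0])}")
    lab = np.zeros(vals.shape, dtype=np.uint8)
    lab[vals <= c3] = LABELS["low"]
    lab[vals <= c2] = LABELS["mid"]
    lab[vals <= c1] = LABELS["high"]
    out = np.zeros(adc.shape, dtype=np.uint8)
    out[prostate_mask] = lab
    return out


def intersect_habitats(perfusion: np.ndarray, diffusion: np.ndarray,
                       voxel_size_mm: tuple[float, float, float],
                       thresholds: dict | None = None) -> HabitatMaps:
    """Combine perfusion and diffusion bands into the habitat probability map.

    A voxel is ``none`` if either parent is ``none``; otherwise it takes the
    lower-risk of the two labels (min over the none < low < mid < high
    encoding), so combined ``high`` requires both parents high.
    """
    if perfusion.shape != diffusion.shape:
        raise ConfigurationError("perfusion and diffusion grids differ")
    combined = np.minimum(perfusion, diffusion).astype(np.uint8)
    voxel_cc = float(np.prod(voxel_size_mm)) / 1000.0
    volumes = {name: float((combined == lab).sum() * voxel_cc)
               for name, lab in LABELS.items() if name != "none"}
    return HabitatMaps(perfusion_band=perfusion, diffusion_band=diffusion,
                       probability_map=combined,
                       thresholds_used=dict(thresholds or {}),
                       band_volumes_cc=volumes)


def compute_habitats(study: MpMRIStudy, n_patterns: int = 3,
                     k: tuple[float, float, float] = DEFAULT_K,
                     adc_cutoffs: tuple[float, float, float] = DEFAULT_ADC_CUTOFFS,
                     ) -> HabitatMaps:
    """End-to-end habitat delineation for one study."""
    amap = decompose_dce(study, n_patterns=n_patterns)
    perf = perfusion_bands(amap, k=k)
    diff = diffusion_bands(study.adc, study.masks["prostate"], cutoffs=adc_cutoffs)
    a = amap.A[amap.mask]
    m, s = float(a.mean()), float(a.std())
    thresholds = {
        "amplitude": [m + ki * s for ki in k],
        "amplitude_mean": m, "amplitude_std": s, "k": list(k),
        "adc": list(adc_cutoffs),
    }
    return intersect_habitats(perf, diff, study.voxel_size_mm, thresholds)
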