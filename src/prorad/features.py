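"""The 49-feature radiomic vector and the feature redundancy analysis.

Per biopsy sample the vector has a 25-entry patient-level block (gland/zone
volumes, NAT first-order statistics, NAT pharmacokinetics, habitat
probability-map volumes, extracapsular extension) and a 24-entry ROI block
(ROI volume, first-order T2w/ADC statistics with tail percentiles and
moments, ROI pharmacokinetics, ROI intersections with the probability maps,
and ROI zonal location).  Names are canonical and version-stable, e.g.
``NAT.PZ_ADC_Mean`` is the mean ADC inside the PZ normal-appearing-tissue
contour.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, MaskError, RegionStatsError
from .habitats import LABELS, HabitatMaps
from .pharmacokinetics import PKParameters
from .study import MpMRIStudy

__all__ = [
    "PATIENT_FEATURES",
    "ROI_FEATURES",
    "ALL_FEATURES",
    "FEATURE_GROUPS",
    "derive_tz_mask",
    "region_volume",
    "intensity_stats",
    "extract_all",
    "redundancy_analysis",
]

_ZONES = ("PZ", "TZ")
_MODS = ("T2w", "ADC")
_BASIC = ("Mean", "StDev", "Median")
_EXTENDED = ("Mean", "Median", "StDev", "Q5", "Q95", "Integral", "Skewness", "Kurtosis")
_PK = ("Ktrans", "kep", "ve")
_LEVELS = ("Low", "Mid", "High")

PATIENT_FEATURES: tuple[str, ...] = (
    "Prostate_Volume", "PZ_Volume", "TZ_Volume",
    *[f"NAT.{z}_{m}_{s}" for z in _ZONES for m in _MODS for s in _BASIC],
    *[f"NAT.{z}_{p}" for z in _ZONES for p in _PK],
    *[f"ProbMap.{lv}_Volume" for lv in _LEVELS],
    "ECE",
)

ROI_FEATURES: tuple[str, ...] = (
    "ROI_Volume",
    *[f"ROI_{m}_{s}" for m in _MODS for s in _EXTENDED],
    *[f"ROI_{p}" for p in _PK],
    *[f"ROI.ProbMap.{lv}_Volume" for lv in _LEVELS],
    "ROI_Location",
)

ALL_FEATURES: tuple[str, ...] = PATIENT_FEATURES + ROI_FEATURES

#: Provenance groups of the 49 features (sizes 4 / 18 / 10 / 9 / 6 / 2):
#: region volumes; basic first-order statistics; extended ROI statistics;
#: pharmacokinetic parameters; probability-map volumes; semantic features.
FEATURE_GROUPS: Mapping[str, tuple[str, ...]] = {
    "volumes": ("Prostate_Volume", "PZ_Volume", "TZ_Volume", "ROI_Volume"),
    "intensity_basic": tuple(
        [f"NAT.{z}_{m}_{s}" for z in _ZONES for m in _MODS for s in _BASIC]
        + [f"ROI_{m}_{s}" for m in _MODS for s in _BASIC]),
    "intensity_extended": tuple(
        f"ROI_{m}_{s}" for m in _MODS
        for s in ("Q5", "Q95", "Integral", "Skewness", "Kurtosis")),
    "pharmacokinetic": tuple(
        [f"NAT.{z}_{p}" for z in _ZONES for p in _PK] + [f"ROI_{p}" for p in _PK]),
    "probability_volumes": tuple(
        [f"ProbMap.{lv}_Volume" for lv in _LEVELS]
        + [f"ROI.ProbMap.{lv}_Volume" for lv in _LEVELS]),
    "semantic": ("ECE", "ROI_Location"),
}

assert len(PATIENT_FEATURES) == 25 and len(ROI_FEATURES) == 24
assert sum(len(v) for v in FEATURE_GROUPS.values()) == 49


def derive_tz_mask(prostate: np.ndarray, pz: np.ndarray,
                   urethra: np.ndarray) -> np.ndarray:
    """TZ = prostate minus PZ minus urethra (set difference on voxels)."""
    for name, m in (("PZ", pz), ("urethra", urethra)):
        n_out = int((m & ~prostate).sum())
        if n_out:
            raise MaskError(f"{name} mask has {n_out} voxel(s) outside the prostate")
    tz = prostate & ~pz & ~urethra
    if not tz.any():
        warnings.warn("derived TZ mask is empty")
    return tz


def region_volume(mask: np.ndarray, voxel_size_mm: Sequence[float]) -> float:
    """Volume of a boolean mask in cc (voxel count x voxel volume / 1000)."""
    return float(mask.sum()) * float(np.prod(voxel_size_mm)) / 1000.0


def intensity_stats(volume: np.ndarray, mask: np.ndarray,
                    stat_set: Sequence[str] = _EXTENDED,
                    voxel_size_mm: Sequence[float] = (1.0, 1.0, 1.0),
                    ddof: int = 1) -> dict[str, float]:
    """First-order statistics of masked voxel intensities.

    Q5/Q95 are the 5th/95th percentiles (linear interpolation between order
    statistics); Integral is the intensity sum times the voxel volume in cc;
    Skewness is Fisher g1 and Kurtosis excess kurtosis, both with population
    (biased) moments, and both 0 for a constant region.  StDev uses the n-1
    denominator by default (configurable through ``ddof``).
    """
    vals = np.asarray(volume[mask], dtype=float)
    if vals.size == 0:
        raise RegionStatsError("empty mask in intensity_stats")
    if not np.all(np.isfinite(vals)):
        raise RegionStatsError("non-finite intensities inside the mask")
    needs_spread = {"StDev", "Skewness", "Kurtosis"} & set(stat_set)
    if vals.size < 2 and needs_spread:
        raise RegionStatsError(
            f"mask has {vals.size} voxel(s): {sorted(needs_spread)} undefined")
    voxel_cc = float(np.prod(voxel_size_mm)) / 1000.0
    table = {
        "Mean": lambda v: float(v.mean()),
        "Median": lambda v: float(np.median(v)),
        "StDev": lambda v: float(v.std(ddof=ddof)),
        "Q5": lambda v: float(np.percentile(v, 5)),
        "Q95": lambda v: float(np.percentile(v, 95)),
        "Integral": lambda v: float(v.sum() * voxel_cc),
        # constant regions (zero variance) take the symmetric/neutral value 0
        "Skewness": lambda v: float(stats.skew(v, bias=True)) if v.std() > 0 else 0.0,
        "Kurtosis": (lambda v: float(stats.kurtosis(v, fisher=True, bias=True))
                     if v.std() > 0 else 0.0),
    }
    unknown = set(stat_set) - set(table)
    if unknown:
        raise ConfigurationError(f"unknown statistic(s): {sorted(unknown)}")
    return {s: table[s](vals) for s in stat_set}


def _pk_entries(prefix: str, pk: PKParameters) -> dict[str, float]:
    return {f"{prefix}_Ktrans": pk.Ktrans, f"{prefix}_kep": pk.kep,
            f"{prefix}_ve": pk.ve}


def extract_all(study: MpMRIStudy, habitats: HabitatMaps,
                pk_by_region: Mapping[str, PKParameters],
                ece: int | None = None) -> pd.DataFrame:
    """Compute the full 49-feature vector for every biopsy ROI of a study.

    ``pk_by_region`` must hold fits keyed ``"nat_pz"``, ``"nat_tz"`` and one
    per ROI name.  Returns a DataFrame indexed ``patientID_roiID`` with the
    49 canonical columns; the 25 patient-level columns are identical across
    the study's biopsies by construction.
    """
    vs = study.voxel_size_mm
    masks = study.masks
    for region in ("nat_pz", "nat_tz"):
        if region not in pk_by_region:
            raise ConfigurationError(f"missing pharmacokinetic fit for '{region}'")
        if not masks[region].any():
            raise MaskError(f"mask '{region}' is empty")
    if not study.rois:
        raise ConfigurationError("study has no biopsy ROIs")

    patient: dict[str, float] = {
        "Prostate_Volume": region_volume(masks["prostate"], vs),
        "PZ_Volume": region_volume(masks["pz"], vs),
        "TZ_Volume": region_volume(masks["tz"], vs),
    }
    for zone, key in (("PZ", "nat_pz"), ("TZ", "nat_tz")):
        for mod, vol in (("T2w", study.t2w), ("ADC", study.adc)):
            st = intensity_stats(vol, masks[key], _BASIC, vs)
            patient.update({f"NAT.{zone}_{mod}_{s}": v for s, v in st.items()})
        patient.update(_pk_entries(f"NAT.{zone}", pk_by_region[key]))
    prob = habitats.probability_map
    for lv in _LEVELS:
        patient[f"ProbMap.{lv}_Volume"] = region_volume(prob == LABELS[lv.lower()], vs)
    patient["ECE"] = float(study.ece if ece is None else ece)

    rows = {}
    for roi_name, roi in study.rois.items():
        if roi_name not in pk_by_region:
            raise ConfigurationError(f"missing pharmacokinetic fit for ROI '{roi_name}'")
        row = dict(patient)
        row["ROI_Volume"] = region_volume(roi, vs)
        for mod, vol in (("T2w", study.t2w), ("ADC", study.adc)):
            st = intensity_stats(vol, roi, _EXTENDED, vs)
            row.update({f"ROI_{mod}_{s}": v for s, v in st.items()})
        row.update(_pk_entries("ROI", pk_by_region[roi_name]))
        for lv in _LEVELS:
            row[f"ROI.ProbMap.{lv}_Volume"] = region_volume(
                roi & (prob == LABELS[lv.lower()]), vs)
        zone = study.roi_zones.get(roi_name, "pz")
        row["ROI_Location"] = 1.0 if zone.lower() == "pz" else 0.0
        rows[f"{study.patient_id}_{roi_name}"] = row

    df = pd.DataFrame.from_dict(rows, orient="index")[list(ALL_FEATURES)]
    bad = df.columns[df.isna().any()]
    if len(bad):
        raise RegionStatsError(f"NaN feature value(s): {list(bad)}")
    df.index.name = "sample"
    return df


def redundancy_analysis(feature_table: pd.DataFrame, alpha: float = 0.05,
                        ) -> pd.DataFrame:
    """Pairwise Pearson correlation of all feature columns with Holm-adjusted
    p-values.

    Every unordered pair is listed (C(49, 2) = 1176 for the full vector).
    Constant columns are flagged and their pairs marked non-evaluable (NaN r,
    excluded from the Holm family), as are pairs with fewer than 3 complete
    observations.  ``significant`` is Holm-adjusted p < ``alpha``.
    """
    if len(feature_table) < 4:
        raise ConfigurationError("need at least 4 samples for redundancy analysis")
    cols = list(feature_table.columns)
    const = [c for c in cols if feature_table[c].nunique(dropna=True) <= 1]
    if const:
        warnings.warn(f"constant feature column(s) excluded: {const}")

    records = []
    for a, b in combinations(cols, 2):
        pair = feature_table[[a, b]].dropna()
        if a in const or b in const or len(pair) < 3:
            records.append((a, b, np.nan, np.nan, False))
            continue
        r, p = stats.pearsonr(pair[a], pair[b])
        records.append((a, b, float(r), float(p), True))
    df = pd.DataFrame(records, columns=["feature_a", "feature_b", "r", "p", "evaluable"])

    df["p_holm"] = np.nan
    ev = df["evaluable"].to_numpy()
    if ev.any():
        _, p_adj, _, _ = multipletests(df.loc[ev, "p"], method="holm")
        df.loc[ev, "p_holm"] = p_adj
    df["significant"] = df["p_holm"] < alpha
    return df
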