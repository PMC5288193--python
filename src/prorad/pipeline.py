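"""End-to-end pipeline driver: simulate (or load) -> habitats -> PK fits ->
features -> expression filter -> correlation -> reports.

Every run writes a manifest listing each output file with a SHA-256 content
hash, the configuration echo and the master seed, so that a rerun with the
same configuration and seed is byte-identical on the tabular outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ProradError
from .features import extract_all, redundancy_analysis
from .habitats import DEFAULT_ADC_CUTOFFS, DEFAULT_K, compute_habitats
from .pharmacokinetics import ConcentrationCurve, fit_tofts, parker_aif
from .radiogenomics import (correlate, cluster_heatmap, export_enrichment_inputs,
                            filter_expression, sample_clustering)
from .study import MpMRIStudy
from .synthetic import (GroundTruth, RegionParams, SyntheticConfig,
                        generate_cohort, generate_expression)

__all__ = ["PipelineConfig", "run_pipeline", "fit_study_pk"]

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Complete configuration of one pipeline run (JSON round-trippable)."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    n_patterns: int = 3
    k: tuple[float, float, float] = DEFAULT_K
    adc_cutoffs: tuple[float, float, float] = DEFAULT_ADC_CUTOFFS
    alpha: float = 0.05
    filter_mode: str = "and"
    linkage: str = "average"
    signatures_path: str | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ProradError("alpha must be in (0, 1)")
        if tuple(sorted(self.adc_cutoffs)) != tuple(self.adc_cutoffs):
            raise ProradError("ADC cutoffs must be increasing")
        # The master seed drives the synthetic substreams.
        object.__setattr__(self.synthetic, "rng_seed", int(self.seed))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["region_params"] = {
            k: dataclasses.asdict(v) for k, v in self.synthetic.region_params.items()}
        # normalize containers to their JSON form so round-trips compare equal
        return json.loads(json.dumps(d))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = dict(d.pop("synthetic", {}))
        if "region_params" in syn:
            syn["region_params"] = {k: RegionParams(**v)
                                    for k, v in syn["region_params"].items()}
        for key in ("grid_shape", "voxel_size_mm"):
            if key in syn:
                syn[key] = tuple(syn[key])
        if "planted_links" in syn:
            syn["planted_links"] = [tuple(x) for x in syn["planted_links"]]
        for key in ("k", "adc_cutoffs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(synthetic=SyntheticConfig(**syn), **d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_study_pk(study: MpMRIStudy, hct: float = 0.42) -> dict:
    """Fit the extended Tofts model to the region-averaged DCE curves of the
    NAT regions and every biopsy ROI of one study."""
    t = study.t_min
    aif = parker_aif(np.linspace(0, float(t.max()), max(2, int(t.max() * 60) + 1)),
                     hct=hct)
    fits = {}
    for name in ("nat_pz", "nat_tz", *study.rois):
        mask = study.rois[name] if name in study.rois else study.masks[name]
        curve = ConcentrationCurve(t=t, C=study.dce[mask].mean(axis=0))
        fits[name] = fit_tofts(curve, aif)
    return fits


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig, out_dir,
                 cohort: list[tuple[MpMRIStudy, GroundTruth]] | None = None,
                 ) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    If ``cohort`` is None the synthetic generator provides the study cohort
    (the ``--simulate`` path); otherwise pre-loaded studies are analyzed.
    Returns a manifest dict (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    stage = "setup"
    try:
        stage = "simulate"
        if cohort is None:
            cohort = generate_cohort(config.synthetic)

        stage = "habitats+features"
        tables = []
        habitat_summaries = {}
        for study, _gt in cohort:
            hab = compute_habitats(study, n_patterns=config.n_patterns,
                                   k=config.k, adc_cutoffs=config.adc_cutoffs)
            pk = fit_study_pk(study, hct=config.synthetic.hct)
            tables.append(extract_all(study, hab, pk))
            habitat_summaries[study.patient_id] = {
                "thresholds": hab.thresholds_used,
                "band_volumes_cc": hab.band_volumes_cc,
            }
        feature_table = pd.concat(tables)
        fpath = out / "features.tsv"
        _write_tsv(feature_table, fpath)
        outputs["features"] = str(fpath)
        hpath = out / "habitats.json"
        hpath.write_text(json.dumps(habitat_summaries, indent=2, sort_keys=True))
        outputs["habitats"] = str(hpath)

        stage = "redundancy"
        red = redundancy_analysis(feature_table, alpha=config.alpha)
        rpath = out / "redundancy.tsv"
        red.to_csv(rpath, sep="\t", index=False, float_format=_FLOAT_FMT)
        outputs["redundancy"] = str(rpath)

        stage = "expression"
        expr, _egt = generate_expression(config.synthetic, feature_table)
        _write_tsv(expr, out / "expression.tsv")
        outputs["expression"] = str(out / "expression.tsv")
        expr_f, filter_log = filter_expression(expr, mode=config.filter_mode)
        _write_tsv(expr_f, out / "expression_filtered.tsv")
        _write_tsv(filter_log, out / "expression_filter_log.tsv")
        outputs["expression_filtered"] = str(out / "expression_filtered.tsv")
        outputs["expression_filter_log"] = str(out / "expression_filter_log.tsv")

        stage = "correlate"
        result = correlate(feature_table, expr_f, alpha=config.alpha)
        for name, mat in (("correlation_r", result.r), ("correlation_p", result.p),
                          ("correlation_fdr", result.p_fdr)):
            _write_tsv(mat, out / f"{name}.tsv")
            outputs[name] = str(out / f"{name}.tsv")
        sig = result.significant_fdr
        long = (result.r.stack()[sig.stack()]
                .rename("r").reset_index())
        long.columns = ["feature", "gene", "r"]
        long["p"] = [result.p.at[f, g] for f, g in zip(long.feature, long.gene)]
        long["p_fdr"] = [result.p_fdr.at[f, g] for f, g in zip(long.feature, long.gene)]
        _write_tsv(long.set_index("feature"), out / "significant_pairs.tsv")
        outputs["significant_pairs"] = str(out / "significant_pairs.tsv")

        stage = "clustering"
        signatures = None
        if config.signatures_path:
            signatures = json.loads(Path(config.signatures_path).read_text())
            signatures.pop("_comment", None)
        heat = cluster_heatmap(result.r, out_path=out / "heatmap.png",
                               signatures=signatures, method=config.linkage)
        outputs["heatmap"] = heat.get("figure_path", "")
        tree = sample_clustering(expr_f, method=config.linkage)
        (out / "samples.nwk").write_text(tree["newick"] + "\n")
        outputs["sample_tree"] = str(out / "samples.nwk")

        stage = "enrichment"
        export_enrichment_inputs(result, out / "enrichment")
        outputs["enrichment_dir"] = str(out / "enrichment")

        stage = "manifest"
        cfg_path = out / "config.json"
        config.to_json(cfg_path)
        outputs["config"] = str(cfg_path)
        manifest = {
            "prorad_version": __version__,
            "seed": int(config.seed),
            "n_samples": int(len(feature_table)),
            "n_genes_in": int(expr.shape[0]),
            "n_genes_filtered": int(expr_f.shape[0]),
            "n_significant_raw": result.n_significant_raw,
            "n_significant_fdr": result.n_significant_fdr,
            "config_sha256": _sha256(cfg_path),
            "files": {k: {"path": v, "sha256": _sha256(Path(v))}
                      for k, v in outputs.items()
                      if v and Path(v).is_file()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except ProradError:
        raise
    except Exception as e:  # annotate unexpected failures with the stage
        partial = {"failed_stage": stage, "outputs_so_far": outputs}
        (out / "manifest.partial.json").write_text(json.dumps(partial, indent=2))
        raise ProradError(f"pipeline failed in stage '{stage}': {e}") from e
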