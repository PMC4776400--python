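"""Configuration-driven orchestration of the full analysis.

Stage order: simulate -> rois -> meg -> bold -> cbf -> correlate.  Every
stage writes TSV/NIfTI outputs under the run directory and registers them
in a JSON manifest with a content hash; deterministic stages reproduce
their hashes on rerun with the same configuration.  A disabled stage is
skipped and downstream stages read its cached files from the run
directory instead.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .asl import cbf_map
from .bold import preprocess_bold, variability_maps
from .entropy import EntropyParams
from .geometry import BinaryMask, VolumeGeometry
from .io import save_cohort, save_volume
from .meg import MEGMeasureParams, roi_measures
from .stats import curve_table, pearson_roi, sign_test, two_sample_t_map
from .synthetic import CohortSpec, SubjectRecord, synth_cohort
from .volume_ops import RimParams, mirror, perilesional_rim

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger("restdyn")

ALL_STAGES = ("simulate", "rois", "meg", "bold", "cbf", "correlate")

MEG_MEASURES = ("delta", "theta", "alpha", "beta", "mse_short", "mse_long")
BOLD_MEASURES = ("sd", "mssd", "sampen")


@dataclass
class PipelineConfig:
    """Everything a run needs; serializes to/from YAML.

    ``cohort_overrides`` passes arbitrary :class:`CohortSpec` fields
    (effect sizes, noise levels) by name; the explicit fields below cover
    the knobs every run touches.
    """

    out_dir: str = "results/run"
    seed: int = 0
    n_per_group: int = 19
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)
    meg_epochs: int = 24
    bold_volumes: int = 180
    cohort_overrides: dict = field(default_factory=dict)
    stages: tuple[str, ...] = ALL_STAGES
    rim_radius_mm: float = 10.0
    bold_fwhm_mm: float = 8.0
    asl_fwhm_mm: float = 6.0
    p_threshold: float = 0.01
    min_cluster_voxels: int = 20
    mse_scales: int = 20
    write_volumes: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        fields = {f.name for f in dataclasses.fields(CohortSpec)}
        bad = set(self.cohort_overrides) - fields
        if bad:
            raise ValueError(f"unknown cohort overrides {sorted(bad)}")

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_stroke=self.n_per_group,
            n_old=self.n_per_group,
            n_young=self.n_per_group,
            geometry=VolumeGeometry(
                tuple(self.grid_shape), tuple(self.voxel_size_mm)
            ),
            seed=self.seed,
            meg_n_epochs=self.meg_epochs,
            bold_n_volumes=self.bold_volumes,
            **self.cohort_overrides,
        )

    def meg_params(self) -> MEGMeasureParams:
        return MEGMeasureParams(
            entropy=EntropyParams(scales=tuple(range(1, self.mse_scales + 1)))
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["voxel_size_mm"] = list(self.voxel_size_mm)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("grid_shape", "voxel_size_mm", "stages"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def _rim_and_mirror(
    subject: SubjectRecord, radius_mm: float
) -> tuple[BinaryMask, BinaryMask]:
    rim = perilesional_rim(
        subject.lesion_mask,
        RimParams(dilation_radius_mm=radius_mm, gm_mask=subject.gm_mask),
    )
    return rim, mirror(rim)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the run
    manifest (also written to ``<out_dir>/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"config": config.to_dict(), "outputs": []}

    def register(stage: str, path: Path, **extra) -> None:
        manifest["outputs"].append(
            {"stage": stage, "path": str(path.relative_to(out)),
             "sha256": _sha256(path), **extra}
        )

    spec = config.cohort_spec()
    cohort = synth_cohort(spec)
    stroke = [s for s in cohort if s.group == "stroke"]
    old = [s for s in cohort if s.group == "old"]
    young = [s for s in cohort if s.group == "young"]

    # ---------------------------------------------------------------- simulate
    if "simulate" in config.stages:
        logger.info("simulate: %d subjects on %s grid", len(cohort), spec.geometry.shape)
        if config.write_volumes:
            save_cohort(cohort, out / "cohort")
            register("simulate", out / "cohort" / "manifest.tsv")
        else:
            rows = [
                {"subject_id": s.subject_id, "group": s.group,
                 "planted_slowing": s.planted["slowing"]}
                for s in cohort
            ]
            _write_tsv(pd.DataFrame(rows), out / "cohort_manifest.tsv")
            register("simulate", out / "cohort_manifest.tsv")

    # ---------------------------------------------------------------- rois
    rois: dict[str, tuple[BinaryMask, BinaryMask]] = {}
    if {"rois", "meg", "cbf"} & set(config.stages):
        for subj in stroke:
            rois[subj.subject_id] = _rim_and_mirror(subj, config.rim_radius_mm)
    if "rois" in config.stages:
        rows = [
            {"subject_id": sid, "rim_voxels": rim.count,
             "mirror_voxels": mir.count}
            for sid, (rim, mir) in rois.items()
        ]
        _write_tsv(pd.DataFrame(rows), out / "rim_counts.tsv")
        register("rois", out / "rim_counts.tsv")

    # ---------------------------------------------------------------- meg
    if "meg" in config.stages:
        params = config.meg_params()
        rows, spectra, curves = [], {"rim": [], "mirror": []}, {"rim": [], "mirror": []}
        freqs = scales = None
        for subj in stroke:
            rim, mir = rois[subj.subject_id]
            if rim.count == 0:
                logger.warning("%s: empty rim, excluded from MEG ROI stats",
                               subj.subject_id)
                continue
            for name, roi in (("rim", rim), ("mirror", mir)):
                m = roi_measures(subj, roi, params)
                rows.append(
                    {"subject_id": subj.subject_id, "roi": name,
                     **{k: m[k] for k in MEG_MEASURES},
                     "n_voxels": m["n_voxels"]}
                )
                spectra[name].append(m["spectrum"])
                curves[name].append(m["mse_curve"])
                freqs, scales = m["freqs"], m["scales"]
        _write_tsv(pd.DataFrame(rows), out / "meg_roi_measures.tsv")
        register("meg", out / "meg_roi_measures.tsv")
        if spectra["rim"]:
            _write_tsv(
                curve_table(freqs, np.array(spectra["rim"]),
                            np.array(spectra["mirror"]), "frequency_hz"),
                out / "meg_roi_spectra.tsv",
            )
            _write_tsv(
                curve_table(scales, np.array(curves["rim"]),
                            np.array(curves["mirror"]), "scale"),
                out / "meg_roi_mse.tsv",
            )
            register("meg", out / "meg_roi_spectra.tsv")
            register("meg", out / "meg_roi_mse.tsv")
            # paired rim-vs-mirror direction summary (sign tests)
            df = pd.DataFrame(rows)
            summary = []
            for meas in MEG_MEASURES:
                wide = df.pivot(index="subject_id", columns="roi", values=meas)
                diff = wide["rim"] - wide["mirror"]
                n_pos, n, p = sign_test(diff.to_numpy())
                summary.append(
                    {"measure": meas, "mean_rim_minus_mirror": float(diff.mean()),
                     "n_positive": n_pos, "n": n, "sign_test_p": p}
                )
            _write_tsv(pd.DataFrame(summary), out / "meg_rim_vs_mirror.tsv")
            register("meg", out / "meg_rim_vs_mirror.tsv")

    # ---------------------------------------------------------------- bold
    if "bold" in config.stages:
        maps: dict[str, dict[str, list]] = {m: {} for m in BOLD_MEASURES}
        roi_rows = []
        for subj in cohort:
            pre = preprocess_bold(subj.bold, fwhm_mm=config.bold_fwhm_mm)
            vm = variability_maps(pre)
            for meas in BOLD_MEASURES:
                maps[meas].setdefault(subj.group, []).append(vm[meas])
            row = {"subject_id": subj.subject_id, "group": subj.group}
            aging = BinaryMask(spec.aging_mask.data, spec.geometry)
            for meas in BOLD_MEASURES:
                row[f"{meas}_aging_mask"] = vm[meas].mean_in(aging)
            if subj.group == "stroke" and subj.subject_id in rois:
                rim, mir = rois[subj.subject_id]
                for meas in BOLD_MEASURES:
                    row[f"{meas}_rim"] = vm[meas].mean_in(rim) if rim.count else np.nan
                    row[f"{meas}_mirror"] = vm[meas].mean_in(mir) if mir.count else np.nan
            roi_rows.append(row)
        _write_tsv(pd.DataFrame(roi_rows), out / "bold_roi_measures.tsv")
        register("bold", out / "bold_roi_measures.tsv")
        gm = BinaryMask(spec.gm_mask.data, spec.geometry)
        stat_rows = []
        for meas in BOLD_MEASURES:
            for name, (ga, gb) in {
                "old_vs_young": (maps[meas].get("old", []), maps[meas].get("young", [])),
                "stroke_vs_young": (maps[meas].get("stroke", []), maps[meas].get("young", [])),
                "stroke_vs_old": (maps[meas].get("stroke", []), maps[meas].get("old", [])),
            }.items():
                if len(ga) < 2 or len(gb) < 2:
                    continue
                sm = two_sample_t_map(ga, gb, mask=gm)
                supra = (sm.p < config.p_threshold) & sm.mask
                stat_rows.append(
                    {"measure": meas, "comparison": name,
                     "frac_supra": float(supra.sum() / sm.mask.sum()),
                     "mean_t_aging_mask": float(np.mean(sm.t[spec.aging_mask.data])),
                     "df": sm.df}
                )
                if config.write_volumes:
                    from .geometry import VolumeMap as _VM
                    save_volume(_VM(sm.t, spec.geometry),
                                out / f"bold_{meas}_{name}_t.nii")
                    register("bold", out / f"bold_{meas}_{name}_t.nii")
        _write_tsv(pd.DataFrame(stat_rows), out / "bold_group_stats.tsv")
        register("bold", out / "bold_group_stats.tsv")

    # ---------------------------------------------------------------- cbf
    if "cbf" in config.stages:
        rows = []
        gm = BinaryMask(spec.gm_mask.data, spec.geometry)
        for subj in cohort:
            cmap = cbf_map(subj.asl, spec.asl_params, fwhm_mm=config.asl_fwhm_mm)
            row = {"subject_id": subj.subject_id, "group": subj.group,
                   "gm_mean": cmap.mean_in(gm)}
            if subj.group == "stroke" and subj.subject_id in rois:
                rim, mir = rois[subj.subject_id]
                row["rim_mean"] = cmap.mean_in(rim) if rim.count else np.nan
                row["mirror_mean"] = cmap.mean_in(mir) if mir.count else np.nan
            rows.append(row)
            if config.write_volumes:
                save_volume(cmap, out / f"cbf_{subj.subject_id}.nii")
                register("cbf", out / f"cbf_{subj.subject_id}.nii")
        _write_tsv(pd.DataFrame(rows), out / "cbf_roi.tsv")
        register("cbf", out / "cbf_roi.tsv")

    # ---------------------------------------------------------------- correlate
    if "correlate" in config.stages:
        meg_df = pd.read_csv(out / "meg_roi_measures.tsv", sep="\t")
        cbf_df = pd.read_csv(out / "cbf_roi.tsv", sep="\t")
        bold_df_path = out / "bold_roi_measures.tsv"
        bold_df = (
            pd.read_csv(bold_df_path, sep="\t") if bold_df_path.exists() else None
        )
        rows = []
        for roi_name, cbf_col in (("rim", "rim_mean"), ("mirror", "mirror_mean")):
            cbf_sub = cbf_df.dropna(subset=[cbf_col]).set_index("subject_id")[cbf_col]
            sel = meg_df[meg_df["roi"] == roi_name].set_index("subject_id")
            common = cbf_sub.index.intersection(sel.index)
            if len(common) < 3:
                logger.warning("fewer than 3 subjects with %s data; "
                               "correlations undefined", roi_name)
                continue
            for meas in MEG_MEASURES:
                res = pearson_roi(sel.loc[common, meas], cbf_sub.loc[common])
                rows.append({"x": meas, "roi": roi_name, "r": res.r,
                             "p": res.p, "n": res.n})
            if bold_df is not None:
                bsel = bold_df.set_index("subject_id")
                for meas in BOLD_MEASURES:
                    col = f"{meas}_{roi_name}"
                    if col not in bsel.columns:
                        continue
                    bcommon = cbf_sub.index.intersection(
                        bsel[col].dropna().index
                    )
                    if len(bcommon) < 3:
                        continue
                    res = pearson_roi(bsel.loc[bcommon, col], cbf_sub.loc[bcommon])
                    rows.append({"x": f"bold_{meas}", "roi": roi_name,
                                 "r": res.r, "p": res.p, "n": res.n})
        _write_tsv(pd.DataFrame(rows), out / "cbf_correlations.tsv")
        register("correlate", out / "cbf_correlations.tsv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
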