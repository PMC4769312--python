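"""End-to-end workflow orchestration.

Reproduces the full analysis chain: summed-PET → structural rigid
co-registration (mutual information), structural → template symmetric
diffeomorphic normalization (with constrained cost-function masking when a
lesion mask is supplied), concatenation of the transforms, atlas label
propagation into PET space, cerebellar-gray reference TAC extraction,
parametric mapping (CBF and nCBF from dynamic water; R_I and R_P from
dynamic FDDNP), regional statistics and agreement reports.  Driven by a
YAML config; deterministic — no stage uses randomness — and every
parameter that was applied is written to a machine-readable log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import agreement_stats, atlas_roi, core_io, registration, srtm_kinetics, water_kinetics
from .atlas_roi import LabelVolume, RegionSet
from .core_io import VolumeGeometry
from .registration import TransformChain

__all__ = ["WorkflowConfig", "run_workflow", "write_phantom_bundle"]


@dataclass
class WorkflowConfig:
    """Paths and parameters of one workflow run (see the bundled YAML)."""

    paths: dict
    output_dir: Path
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    REQUIRED = (
        "template", "template_labels", "label_table", "region_set", "subject_mr",
        "water_image", "water_timing", "fddnp_image", "fddnp_timing", "blood",
    )

    @classmethod
    def from_yaml(cls, path) -> "WorkflowConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        paths = {k: (base / v if not Path(v).is_absolute() else Path(v))
                 for k, v in raw["paths"].items()}
        out = Path(raw["output_dir"])
        if not out.is_absolute():
            out = base / out
        return cls(paths=paths, output_dir=out,
                   parameters=raw.get("parameters", {}), seed=int(raw.get("seed", 0)))

    def validate(self):
        for key in self.REQUIRED:
            if key not in self.paths:
                raise ValueError(f"config missing path {key!r}")
            if not Path(self.paths[key]).exists():
                raise FileNotFoundError(f"{key}: {self.paths[key]}")
        if "lesion_mask" in self.paths and not Path(self.paths["lesion_mask"]).exists():
            raise FileNotFoundError(f"lesion_mask: {self.paths['lesion_mask']}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _defaults(params: dict) -> dict:
    out = {
        "extraction_fraction": 0.85,
        "water_window_min": [0.0, 10.0],
        "fddnp_window_min": [0.0, 6.0],
        "theta_n": 100,
        "theta_lo": 0.00636,
        "theta_hi": 1.0,
        "syn_levels": [8, 4, 2, 1],
        "syn_max_iter": 250,
        "cc_radius": 4,
        "rigid_levels": [4, 2, 1],
        "mi_bins": 32,
        "ridge": True,
    }
    out.update(params or {})
    return out


def run_workflow(config: WorkflowConfig) -> dict:
    """Execute the full workflow; returns a results dict and writes artifacts.

    Any stage failure raises :class:`StageError` naming the stage; artifacts
    produced before the failure remain on disk.
    """
    config.validate()
    p = _defaults(config.parameters)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = {"parameters": p, "seed": config.seed, "stages": []}

    def stage(name):
        log["stages"].append(name)
        return name

    try:
        stage("load_inputs")
        template, tgeom = core_io.load_volume(config.paths["template"])
        atlas_data, ageom = core_io.load_volume(config.paths["template_labels"])
        table = atlas_roi.load_label_table(config.paths["label_table"])
        atlas = LabelVolume(np.asarray(atlas_data).astype(np.int32), ageom, table)
        regions = atlas_roi.load_region_set(config.paths["region_set"])
        regions.validate_against(atlas)
        subject, sgeom = core_io.load_volume(config.paths["subject_mr"])
        water = core_io.load_dynamic_image(config.paths["water_image"],
                                           config.paths["water_timing"])
        fddnp = core_io.load_dynamic_image(config.paths["fddnp_image"],
                                           config.paths["fddnp_timing"])
        blood = core_io.load_blood_curve(config.paths["blood"])
        lesion = None
        if "lesion_mask" in config.paths:
            lesion_data, _ = core_io.load_volume(config.paths["lesion_mask"])
            lesion = np.asarray(lesion_data) > 0
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError("load_inputs", e) from e

    try:
        stage("integrate_frames")
        w0, w1 = p["water_window_min"]
        f0, f1 = p["fddnp_window_min"]
        summed_water = core_io.integrate_frames(water, w0, w1)
        summed_fddnp = core_io.integrate_frames(fddnp, f0, f1)
        core_io.save_volume(summed_water, water.geometry, out / "summed_water.nii.gz")
        core_io.save_volume(summed_fddnp, fddnp.geometry, out / "summed_fddnp.nii.gz")
    except Exception as e:
        raise StageError("integrate_frames", e) from e

    try:
        stage("rigid_coregistration")
        rigid_water = registration.rigid_register(summed_water, subject,
                                                  levels=p["rigid_levels"], bins=p["mi_bins"],
                                                  fixed_mask=lesion)
        rigid_fddnp = registration.rigid_register(summed_fddnp, subject,
                                                  levels=p["rigid_levels"], bins=p["mi_bins"],
                                                  fixed_mask=lesion)
        for name, tr in (("rigid_water", rigid_water), ("rigid_fddnp", rigid_fddnp)):
            np.savetxt(out / f"{name}.tsv",
                       np.atleast_2d(list(tr.angles_deg) + list(tr.translation)),
                       delimiter="\t", header="angles_deg... translation_vox...")
        log["rigid_water"] = {"angles_deg": list(rigid_water.angles_deg),
                              "translation_vox": list(rigid_water.translation)}
        log["rigid_fddnp"] = {"angles_deg": list(rigid_fddnp.angles_deg),
                              "translation_vox": list(rigid_fddnp.translation)}
    except Exception as e:
        raise StageError("rigid_coregistration", e) from e

    try:
        stage("diffeomorphic_normalization")
        syn = registration.syn_register(
            subject, template, levels=p["syn_levels"], max_iter=p["syn_max_iter"],
            radius=p["cc_radius"], mask=lesion,
        )
        core_io.save_volume(np.moveaxis(syn.forward.disp, 0, -1), sgeom,
                            out / "syn_forward.nii.gz")
        core_io.save_volume(np.moveaxis(syn.inverse.disp, 0, -1), sgeom,
                            out / "syn_inverse.nii.gz")
        log["syn_final_metric"] = syn.metric_trace[-1] if syn.metric_trace else None
        log["ccfm"] = lesion is not None
    except Exception as e:
        raise StageError("diffeomorphic_normalization", e) from e

    try:
        stage("label_propagation")
        # point path: PET grid --rigid⁻¹--> structural grid --syn.inverse--> template grid
        # (the rigid result maps structural coords to PET coords, so it enters inverted)
        chain_water = TransformChain().add(rigid_water, inverted=True).add(syn.inverse)
        chain_fddnp = TransformChain().add(rigid_fddnp, inverted=True).add(syn.inverse)
        labels_water = atlas_roi.propagate_labels(atlas, chain_water, water.geometry)
        labels_fddnp = atlas_roi.propagate_labels(atlas, chain_fddnp, fddnp.geometry)
        core_io.save_volume(labels_water.labels, water.geometry, out / "labels_water.nii.gz")
        core_io.save_volume(labels_fddnp.labels, fddnp.geometry, out / "labels_fddnp.nii.gz")
    except Exception as e:
        raise StageError("label_propagation", e) from e

    cgm_ids = regions.groups["CGM"]

    try:
        stage("water_kinetics")
        brain_mask = labels_water.labels > 0
        present = [int(i) for i in np.unique(labels_water.labels) if i != 0]
        wb_tac = atlas_roi.region_tac(water, labels_water, present)
        corrected, dd, wb_params = water_kinetics.correct_delay_dispersion(blood, wb_tac)
        log["delay_s"] = dd.delta_t_s
        log["dispersion_tau_s"] = dd.tau_s
        log["whole_brain_fit"] = {"K1": wb_params.K1, "k2": wb_params.k2, "Vb": wb_params.Vb}
        maps = water_kinetics.ridge_parametric_fit(water, corrected, brain_mask,
                                                   ridge=bool(p["ridge"]))
        cbf = water_kinetics.flow_map(maps["K1"], p["extraction_fraction"])
        cgm_mask_w = labels_water.mask_for(cgm_ids)
        cgm_cbf = float(np.nanmean(cbf.data[cgm_mask_w]))
        ncbf = water_kinetics.normalize_map(cbf, cgm_cbf)
        ncbf.name = "nCBF"
        for m in (maps["K1"], maps["k2"], maps["Vb"], cbf, ncbf):
            core_io.save_volume(np.nan_to_num(m.data), m.geometry, out / f"{m.name}.nii.gz")
        wrss_vals = maps["wrss"].data[np.isfinite(maps["wrss"].data)]
        pd.DataFrame([{"n_voxels": int(wrss_vals.size),
                       "median_wrss": float(np.median(wrss_vals))}]).to_csv(
            out / "fit_summary_water.tsv", sep="\t", index=False)
        log["cgm_cbf"] = cgm_cbf
    except Exception as e:
        raise StageError("water_kinetics", e) from e

    try:
        stage("fddnp_kinetics")
        ref_tac = atlas_roi.region_tac(fddnp, labels_fddnp, cgm_ids)
        fmask = labels_fddnp.labels > 0
        thetas = srtm_kinetics.theta_grid(p["theta_n"], p["theta_lo"], p["theta_hi"])
        srtm_maps = srtm_kinetics.srtm_parametric_map(fddnp, ref_tac, fmask, thetas)
        cgm_mask_f = labels_fddnp.mask_for(cgm_ids)
        rp = srtm_kinetics.early_sum_ratio(fddnp, cgm_mask_f, tuple(p["fddnp_window_min"]))
        for m in (srtm_maps["R_I"], srtm_maps["BP"], srtm_maps["k2"], rp):
            core_io.save_volume(np.nan_to_num(m.data), m.geometry, out / f"{m.name}.nii.gz")
    except Exception as e:
        raise StageError("fddnp_kinetics", e) from e

    try:
        stage("region_statistics")
        stats = {}
        for name, pmap, labs in (
            ("CBF", cbf, labels_water),
            ("nCBF", ncbf, labels_water),
            ("R_I", srtm_maps["R_I"], labels_fddnp),
            ("R_P", rp, labels_fddnp),
        ):
            st = atlas_roi.region_statistics(pmap, labs, regions)
            st.table.to_csv(out / f"region_stats_{name}.tsv", sep="\t", index=False)
            stats[name] = st
        gw = agreement_stats.gray_white_ratio(stats["CBF"].mean_of("WBGM"),
                                              stats["CBF"].mean_of("SWM"))
        log["gray_white_ratio"] = gw
    except Exception as e:
        raise StageError("region_statistics", e) from e

    try:
        stage("agreement")
        region_names = [r for r in regions.groups if r != "SWM"]
        ncbf_means = np.array([stats["nCBF"].mean_of(r) for r in region_names])
        ri_means = np.array([stats["R_I"].mean_of(r) for r in region_names])
        rp_means = np.array([stats["R_P"].mean_of(r) for r in region_names])
        ba_ri = agreement_stats.bland_altman(ri_means, ncbf_means)
        ba_rp = agreement_stats.bland_altman(rp_means, ncbf_means)
        for tag, ba in (("RI_vs_nCBF", ba_ri), ("RP_vs_nCBF", ba_rp)):
            log[f"bland_altman_{tag}"] = {
                "bias": ba.bias, "sd": ba.sd_diff,
                "loa": [ba.loa_low, ba.loa_high], "n": ba.n,
            }
            agreement_stats.bland_altman_plot(ba, out / f"bland_altman_{tag}.png", tag)
    except Exception as e:
        raise StageError("agreement", e) from e

    with open(out / "workflow_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=float)

    return {
        "log": log,
        "stats": stats,
        "gray_white_ratio": log["gray_white_ratio"],
        "delay_dispersion": (log["delay_s"], log["dispersion_tau_s"]),
        "bland_altman": {"RI_vs_nCBF": ba_ri, "RP_vs_nCBF": ba_rp},
        "maps": {"CBF": cbf, "nCBF": ncbf, "R_I": srtm_maps["R_I"], "R_P": rp},
        "labels": {"water": labels_water, "fddnp": labels_fddnp},
    }


# ---------------------------------------------------------------------------
# Phantom input bundle
# ---------------------------------------------------------------------------

def write_phantom_bundle(
    outdir,
    seed: int = 0,
    noise_percent: float = 5.0,
    shape=(128, 128),
    with_lesion: bool = True,
    deform_amplitude: float = 5.0,
    rigid_shift=(3.0, -2.0),
) -> dict:
    """Generate and write every input file one workflow run consumes.

    The template is the phantom at rest; the subject structural image is the
    template pushed through a known smooth deformation (plus an optional
    focal lesion); the dynamic PET volumes live on a grid rigidly shifted
    from the subject structural grid.  Returns the paths dict plus the
    ground-truth objects so tests can close the loop.
    """
    from . import phantom as ph
    from .registration import RigidTransform, warp_image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = ph.default_spec(shape=shape, noise_percent=noise_percent, seed=seed)
    atlas, template = ph.make_phantom(spec)
    geom = atlas.geometry

    # subject anatomy: template pushed through a known diffeomorphism
    field, landmarks = ph.make_deformation(geom, deform_amplitude, seed=seed + 1)
    subject = warp_image(template, field)
    subject_labels = warp_image(atlas.labels, field, interp="nearest")
    lesion_mask = np.zeros(geom.shape, dtype=np.int32)
    if with_lesion:
        center = [0.32 * (s - 1) for s in geom.shape]
        radii = [0.08 * s for s in geom.shape]
        subject, lm = ph.insert_lesion(subject, center, radii, intensity=300.0)
        lesion_mask = lm.astype(np.int32)

    # dynamic PET on a rigidly shifted grid: PET(x) = subject-scene(x + shift)
    rigid_true = RigidTransform((0.0,) * (1 if geom.ndim == 2 else 3), tuple(rigid_shift))
    subject_label_vol = atlas_roi.LabelVolume(subject_labels.astype(np.int32), geom,
                                              dict(atlas.table))
    pet_labels = warp_image(subject_labels, rigid_true, interp="nearest")
    pet_label_vol = atlas_roi.LabelVolume(pet_labels.astype(np.int32), geom,
                                          dict(atlas.table))

    true_input = ph.default_input()
    measured = ph.degrade_input(true_input, water_kinetics.DelayDispersion(6.0, 5.0),
                                noise_percent=0.0, seed=seed + 2)
    water_dyn = ph.simulate_dynamic(pet_label_vol, spec, "water", true_input,
                                    core_io.WATER_FRAME_SCHEDULE,
                                    noise_percent=noise_percent, seed=seed + 3)
    fddnp_dyn = ph.simulate_dynamic(pet_label_vol, spec, "fddnp", true_input,
                                    core_io.FDDNP_FRAME_SCHEDULE,
                                    noise_percent=noise_percent, seed=seed + 4)

    region_set = RegionSet({name: frozenset({r.label})
                            for name, r in spec.regions.items() if name != "VENT"})

    paths = {
        "template": outdir / "template.nii.gz",
        "template_labels": outdir / "template_labels.nii.gz",
        "label_table": outdir / "label_table.tsv",
        "region_set": outdir / "region_set.tsv",
        "subject_mr": outdir / "subject_mr.nii.gz",
        "water_image": outdir / "water_dyn.nii.gz",
        "water_timing": outdir / "water_timing.tsv",
        "fddnp_image": outdir / "fddnp_dyn.nii.gz",
        "fddnp_timing": outdir / "fddnp_timing.tsv",
        "blood": outdir / "blood.tsv",
    }
    core_io.save_volume(template, geom, paths["template"])
    core_io.save_volume(atlas.labels, geom, paths["template_labels"])
    atlas_roi.save_label_table(atlas.table, paths["label_table"])
    atlas_roi.save_region_set(region_set, paths["region_set"])
    core_io.save_volume(subject, geom, paths["subject_mr"])
    core_io.save_volume(water_dyn.data, geom, paths["water_image"])
    core_io.save_frame_schedule(water_dyn.schedule, paths["water_timing"])
    core_io.save_volume(fddnp_dyn.data, geom, paths["fddnp_image"])
    core_io.save_frame_schedule(fddnp_dyn.schedule, paths["fddnp_timing"])
    core_io.save_blood_curve(measured, paths["blood"], unit="min")
    if with_lesion:
        paths["lesion_mask"] = outdir / "lesion_mask.nii.gz"
        core_io.save_volume(lesion_mask, geom, paths["lesion_mask"])

    config = {
        "paths": {k: str(Path(v).name) for k, v in paths.items()},
        "output_dir": "results",
        "parameters": {},
        "seed": seed,
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh)

    return {
        "paths": paths,
        "config": outdir / "config.yaml",
        "spec": spec,
        "true_field": field,
        "landmarks": landmarks,
        "true_rigid": rigid_true,
        "true_input": true_input,
        "measured_blood": measured,
        "subject_labels": subject_label_vol,
        "pet_labels": pet_label_vol,
        "lesion_mask": lesion_mask.astype(bool),
    }
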