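"""End-to-end orchestration: simulate -> decompose -> denoise -> project ->
register -> quantify -> analyze.

Per-stage seeds derive from the global seed through a counter scheme
(``SeedSequence(seed).spawn``), so any stage can be re-run independently
yet reproducibly.  Every intermediate is persisted in standard formats and
listed in the run manifest together with per-stage wall times and QC
events.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .attenuation import AttenuationModel
from .decomp import DecompositionMatrix, decompose_image_domain, epl_to_abmd
from .denoise import DenoiseConfig, DictionaryConfig, denoise_pipeline
from .phantom import (
    ScoutAcquisition,
    generate_cohort,
    label_value,
)
from .projector import ScoutGeometry, forward_project, project_mask
from .quantify import build_cohort_table, vertebra_abmd, vertebra_vbmd
from .register import RegistrationConfig, RegistrationError, apply_transform, register_2d
from .stats import run_cohort_analysis

__all__ = ["PipelineConfig", "RunManifest", "run_end_to_end", "process_member", "run_cohort"]

log = logging.getLogger("sdexa")


class ConfigError(ValueError):
    """Raised when a pipeline configuration fails validation."""


@dataclass(frozen=True)
class CohortConfig:
    n: int = 2
    vbmd_range: tuple = (40.0, 200.0)
    n_vertebrae: int = 2
    voxel_spacing: tuple = (2.0, 2.0, 2.0)
    anatomy_jitter: float = 1.0


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = CohortConfig()
    acquisition: ScoutAcquisition = ScoutAcquisition()
    geometry: ScoutGeometry = ScoutGeometry()
    denoise: DenoiseConfig | None = DenoiseConfig()
    coverage_fraction: float = 0.25
    registration: RegistrationConfig | None = RegistrationConfig()
    seed: int = 0
    output_dir: str = "sdexa_run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")

        def build(klass, section):
            if section is None:
                return None
            if not isinstance(section, dict):
                raise ConfigError(f"section for {klass.__name__} must be a mapping")
            names = {f.name for f in dataclasses.fields(klass)}
            bad = set(section) - names
            if bad:
                raise ConfigError(f"unknown fields in {klass.__name__}: {sorted(bad)}")
            coerced = {
                k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
            }
            if klass is DenoiseConfig and "dictionary" in coerced:
                coerced["dictionary"] = DictionaryConfig(**coerced["dictionary"])
            return klass(**coerced)

        kwargs = {}
        for name, klass in (
            ("cohort", CohortConfig),
            ("acquisition", ScoutAcquisition),
            ("geometry", ScoutGeometry),
            ("registration", RegistrationConfig),
        ):
            if name in raw:
                kwargs[name] = build(klass, raw[name])
        if "denoise" in raw:
            kwargs["denoise"] = build(DenoiseConfig, raw["denoise"])
        for name in ("coverage_fraction", "seed", "output_dir"):
            if name in raw:
                kwargs[name] = raw[name]
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: dict = field(default_factory=dict)
    qc: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def process_member(
    member,
    geometry: ScoutGeometry,
    model: AttenuationModel,
    denoise_cfg: DenoiseConfig | None,
    coverage_fraction: float = 0.25,
    registration: RegistrationConfig | None = RegistrationConfig(),
):
    """Measure one synthetic patient.

    Returns per-vertebra measurement rows plus a QC record.  The chain per
    patient: image-domain decomposition of the CT volumes (vBMD), optional
    scout denoising, projection-domain decomposition (measured aBMD),
    AP/lateral forward projections of the vBMD volume (projected aBMD),
    2D trabecular masks in both views, and registration of the projected
    AP map onto the measured scout to carry the mask across.
    """
    vol = member.volume
    qc = {"patient_id": member.patient_id}

    matrix = DecompositionMatrix.from_model(model)
    materials = decompose_image_domain(member.volumes_ct, matrix)
    qc["negative_vbmd_fraction"] = materials.negative_fraction

    scout = member.scout
    if denoise_cfg is not None:
        scout, den_report = denoise_pipeline(scout, denoise_cfg, model=model)
        qc["denoise"] = den_report.as_dict()
    measured = epl_to_abmd(
        scout, model, provenance="measured_scout", denoised=denoise_cfg is not None
    )

    ap_geo = geometry.with_view(0.0)
    lat_geo = geometry.with_view(90.0)
    vbmd_gml = vol.hydroxyapatite_density / 1000.0
    proj = {}
    masks = {}
    trab_labels = {
        v.label: label_value(v.label, "trabecular") for v in member.spec.vertebrae
    }
    for name, geo in (("projected_AP", ap_geo), ("projected_lateral", lat_geo)):
        pm = forward_project(vbmd_gml, vol.voxel_spacing, geo)
        proj[name] = pm
        mask2d, _ = project_mask(
            vol.labels,
            vol.voxel_spacing,
            geo,
            label_values=list(trab_labels.values()),
            coverage_fraction=coverage_fraction,
        )
        masks[name] = mask2d

    # carry the AP trabecular mask onto the measured scout
    measured_mask = masks["projected_AP"]
    if registration is not None:
        try:
            transform, _, metric = register_2d(proj["projected_AP"].values, measured.abmd, registration)
            measured_mask = apply_transform(masks["projected_AP"], transform)
            qc["registration_metric"] = metric
            qc["registration"] = transform.as_dict()
        except RegistrationError as exc:
            qc["registration_error"] = str(exc)
            log.warning("registration failed for %s: %s", member.patient_id, exc)

    rows = []
    for vname, lv in trab_labels.items():
        vbmd = vertebra_vbmd(materials, vol.labels, lv)
        row = {
            "patient_id": member.patient_id,
            "vertebra": vname,
            "vbmd": vbmd,
            "vbmd_true": member.truth["vbmd_per_vertebra"][vname],
        }
        flags = []
        try:
            val, npix, fl = vertebra_abmd(measured, measured_mask, lv)
            row["abmd_measured_ap"] = val
            row["mask_pixel_count"] = npix
            flags += fl
        except Exception as exc:  # empty registered mask is a QC event
            log.warning("measured aBMD failed for %s %s: %s", member.patient_id, vname, exc)
            row["abmd_measured_ap"] = np.nan
            row["mask_pixel_count"] = 0
            flags.append("measured_abmd_failed")
        for name, key in (
            ("projected_AP", "abmd_projected_ap"),
            ("projected_lateral", "abmd_projected_lateral"),
        ):
            from .decomp import ABMDMap

            amap = ABMDMap(
                abmd=proj[name].values,
                pixel_spacing=proj[name].pixel_spacing,
                provenance=name,
            )
            val, npix, fl = vertebra_abmd(amap, masks[name], lv)
            row[key] = val
            flags += [f"{name}:{x}" for x in fl]
        row["qc_flags"] = ";".join(flags)
        rows.append(row)
    return rows, qc


def run_cohort(config: PipelineConfig, model: AttenuationModel | None = None):
    """In-memory cohort run: simulate, measure, tabulate, analyze."""
    model = model or AttenuationModel.from_tabulation()
    seeds = _stage_seeds(config.seed, 2)
    acq = dataclasses.replace(config.acquisition, seed=seeds[0])
    members = generate_cohort(
        config.cohort.n,
        config.cohort.vbmd_range,
        config.geometry.with_view(0.0),
        acq,
        seed=seeds[1],
        n_vertebrae=config.cohort.n_vertebrae,
        voxel_spacing=config.cohort.voxel_spacing,
        anatomy_jitter=config.cohort.anatomy_jitter,
        model=model,
    )
    all_rows, qcs = [], []
    for member in members:
        rows, qc = process_member(
            member,
            config.geometry,
            model,
            config.denoise,
            config.coverage_fraction,
            config.registration,
        )
        all_rows += rows
        qcs.append(qc)
    table = build_cohort_table(all_rows)
    analysis = run_cohort_analysis(table)
    return members, table, analysis, qcs


def run_end_to_end(config: PipelineConfig) -> RunManifest:
    """Full pipeline with persistence of every intermediate.

    Writes phantom NIfTI trios, scout TIFFs, aBMD maps, the cohort CSV and
    the analysis JSON under ``config.output_dir`` and returns the manifest.
    """
    from . import io as sio

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(), version=__version__, seed=config.seed
    )

    t0 = time.perf_counter()
    model = AttenuationModel.from_tabulation()
    members, table, analysis, qcs = run_cohort(config, model=model)
    manifest.stages["simulate_and_measure"] = {"wall_time_s": time.perf_counter() - t0}

    t0 = time.perf_counter()
    paths = {}
    for member in members:
        pdir = out / member.patient_id
        sio.save_labeled_volume(member.volume, pdir)
        sio.save_projection_pair(member.scout, pdir / "scout.tiff")
        paths[member.patient_id] = str(pdir)
    sio.save_cohort_table(table, out / "cohort.csv")
    (out / "analysis.json").write_text(json.dumps(analysis.as_dict(), indent=2))
    (out / "qc.json").write_text(json.dumps(qcs, indent=2, default=float))
    manifest.stages["persist"] = {"wall_time_s": time.perf_counter() - t0, "paths": paths}

    for qc in qcs:
        if "registration_error" in qc:
            manifest.qc.append({qc["patient_id"]: qc["registration_error"]})
        den = qc.get("denoise")
        if den:
            manifest.qc.append(
                {qc["patient_id"]: {"denoised": not den["passthrough"]}}
            )
    manifest.stages["analysis"] = {
        "denoised": config.denoise is not None,
        "outputs": [str(out / "cohort.csv"), str(out / "analysis.json")],
    }
    (out / "manifest.json").write_text(json.dumps(manifest.as_dict(), indent=2, default=float))
    return manifest
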