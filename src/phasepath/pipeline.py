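"""Pipeline orchestration: simulate -> extract -> stats -> classify.

A run is driven by a single configuration mapping (YAML/JSON-friendly) with a
global seed.  Stage seeds are derived from the global seed by hashing the
stage name, so any stage can be re-run independently yet reproducibly; every
output CSV carries a provenance header (config hash, seed, package version).
Identical configurations therefore produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import tifffile

from . import __version__
from .discrimination import ClassifierSpec, error_report
from .features import (
    AcquisitionConfig,
    extract_features,
    intensity_to_phase,
)
from .phantoms import (
    MANIFEST_COLUMNS,
    default_fixture_specs,
    generate_feature_cohort,
    reference_cohort_spec,
    write_fixture_set,
)
from .reference import MAGNIFICATIONS, TISSUES
from .significance import significance_table, summary_frame, group_summary, worked_difference_report

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "acquisition": {"wavelength_um": 0.55, "thickness_um": 6.0, "mean_index": 1.35},
    "phantoms": {
        "shape": [256, 256],
        "gain": 400.0,
        "offset": 2048.0,
        "noise_sd": 2.0,
        "tissues": list(TISSUES),
    },
    "extract": {"calibration": "recorded", "af_form": "outer_square", "fd_method": "spectral"},
    "cohort": {"tissues": list(TISSUES), "magnifications": list(MAGNIFICATIONS), "n_per_group": 100},
    "stats": {"alpha": 0.005},
    "classify": {"classifiers": "all", "folds": 10, "repeats": 5},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % 2**31


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, config: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# phasepath {__version__}\n")
        fh.write(f"# config_hash: {config_hash(config)}\n")
        fh.write(f"# seed: {config.get('seed', 0)}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the provenance header."""
    return pd.read_csv(path, comment="#")


def validate_manifest(path: str | Path) -> list[str]:
    """Check a manifest CSV; returns a list of human-readable errors (empty = valid)."""
    path = Path(path)
    errors: list[str] = []
    if not path.exists():
        return [f"manifest not found: {path}"]
    try:
        manifest = read_csv(path)
    except Exception as exc:  # malformed CSV
        return [f"cannot parse manifest: {exc}"]
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        errors.append(f"missing required columns: {missing}")
        return errors
    for i, row in manifest.iterrows():
        if row["state"] not in ("healthy", "tumoral"):
            errors.append(
                f"row {i}: unknown state {row['state']!r} (allowed: healthy, tumoral)"
            )
        if row["magnification"] not in ("10x", "20x", "40x"):
            errors.append(
                f"row {i}: unknown magnification {row['magnification']!r} (allowed: 10x, 20x, 40x)"
            )
        img = path.parent / str(row["path"])
        if not img.exists():
            errors.append(f"row {i}: image file not found: {img}")
    return errors


def simulate_stage(config: dict, out_dir: Path) -> pd.DataFrame:
    ph = {**DEFAULT_CONFIG["phantoms"], **config.get("phantoms", {})}
    acq = {**DEFAULT_CONFIG["acquisition"], **config.get("acquisition", {})}
    specs = default_fixture_specs(
        base_seed=stage_seed(config.get("seed", 0), "simulate"),
        shape=tuple(ph["shape"]),
        tissues=tuple(ph["tissues"]),
    )
    manifest = write_fixture_set(
        specs,
        out_dir,
        thickness_um=acq["thickness_um"],
        wavelength_um=acq["wavelength_um"],
        gain=ph["gain"],
        offset=ph["offset"],
        noise_sd=ph["noise_sd"],
        overwrite=True,
    )
    logger.info("simulate: wrote %d phantom images to %s", len(manifest), out_dir)
    return manifest


def extract_stage(config: dict, manifest_path: Path, out_path: Path) -> pd.DataFrame:
    ex = {**DEFAULT_CONFIG["extract"], **config.get("extract", {})}
    acq_cfg = {**DEFAULT_CONFIG["acquisition"], **config.get("acquisition", {})}
    ph = {**DEFAULT_CONFIG["phantoms"], **config.get("phantoms", {})}
    manifest = read_csv(manifest_path)
    rows = []
    n_warn = 0
    for _, row in manifest.iterrows():
        counts = tifffile.imread(manifest_path.parent / str(row["path"]))
        calibration = ex["calibration"]
        if calibration == "relative":
            phase, relative = intensity_to_phase(
                counts, pixel_size=float(row["pixel_size_um"]), normalized=True
            )
        else:
            gain, offset = (
                (ph["gain"], ph["offset"])
                if calibration == "recorded"
                else calibration  # (gain, offset) pair
            )
            phase, relative = intensity_to_phase(
                counts, gain=gain, offset=offset, pixel_size=float(row["pixel_size_um"])
            )
        acq = AcquisitionConfig(
            pixel_size=float(row["pixel_size_um"]),
            magnification=str(row["magnification"]),
            wavelength=float(row.get("wavelength_um", acq_cfg["wavelength_um"])),
            thickness=float(row.get("thickness_um", acq_cfg["thickness_um"])),
            mean_index=acq_cfg["mean_index"],
            k0_convention=ex.get("k0_convention", "vacuum"),
        )
        vec = extract_features(
            phase,
            acq,
            af_form=ex["af_form"],
            fd_method=ex["fd_method"],
            relative_scale=relative,
        )
        if vec.warnings:
            n_warn += 1
        rows.append(
            {
                "path": row["path"],
                "tissue": row["tissue"],
                "state": row["state"],
                "magnification": row["magnification"],
                **vec.to_dict(),
            }
        )
    features = pd.DataFrame(rows)
    _write_csv(features, out_path, config)
    logger.info(
        "extract: %d images -> %s (%d with warnings)", len(features), out_path, n_warn
    )
    return features


def cohort_stage(config: dict, out_path: Path) -> pd.DataFrame:
    co = {**DEFAULT_CONFIG["cohort"], **config.get("cohort", {})}
    seed = stage_seed(config.get("seed", 0), "cohort")
    frames = []
    for i, tissue in enumerate(co["tissues"]):
        for j, mag in enumerate(co["magnifications"]):
            spec = reference_cohort_spec(
                tissue, mag, n_per_group=co["n_per_group"], seed=seed + 101 * i + j
            )
            frames.append(generate_feature_cohort(spec))
    cohort = pd.concat(frames, ignore_index=True)
    _write_csv(cohort, out_path, config)
    return cohort


def stats_stage(config: dict, cohort: pd.DataFrame, out_dir: Path) -> dict[str, pd.DataFrame]:
    st = {**DEFAULT_CONFIG["stats"], **config.get("stats", {})}
    rename = {"riv": "riv", "sc_rad2_per_mm": "sc", "os_um": "os"}
    cohort = cohort.rename(columns=rename)
    summary = summary_frame(group_summary(cohort))
    anova = significance_table(cohort, alpha=st["alpha"])
    worked = worked_difference_report(cohort)
    _write_csv(summary, out_dir / "group_summary.csv", config)
    _write_csv(anova, out_dir / "anova.csv", config)
    _write_csv(worked, out_dir / "mean_differences.csv", config)
    logger.info(
        "stats: %d ANOVA cells, %d significant at alpha=%g (no multiplicity correction over %d tests)",
        len(anova),
        int(anova.significant.sum()),
        st["alpha"],
        anova.attrs.get("n_tests", len(anova)),
    )
    return {"summary": summary, "anova": anova, "mean_differences": worked}


def classify_stage(config: dict, cohort: pd.DataFrame, out_dir: Path) -> pd.DataFrame:
    cl = {**DEFAULT_CONFIG["classify"], **config.get("classify", {})}
    seed = stage_seed(config.get("seed", 0), "classify")
    names = cl["classifiers"]
    if names == "all":
        from .discrimination import ALGORITHMS

        names = list(ALGORITHMS)
    specs = [ClassifierSpec(algorithm=a, seed=seed) for a in names]
    rename = {"sc_rad2_per_mm": "sc", "os_um": "os"}
    cohort = cohort.rename(columns=rename)
    report = error_report(
        cohort, specs, folds=cl["folds"], repeats=cl["repeats"], seed=seed
    )
    _write_csv(report, out_dir / "classification_report.csv", config)
    summary = {
        "n_cells": int(len(report)),
        "n_flagged": int(report.flagged.sum()),
        "seed": seed,
    }
    (out_dir / "classification_summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("classify: %d cells, %d flagged (total error < 0.1)", len(report), summary["n_flagged"])
    return report


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the stages named by the config sections present.

    Stage order: ``phantoms`` (simulate images + manifest), ``extract``
    (features CSV from the manifest), ``cohort`` (synthetic feature cohort
    from the reference statistics), ``stats`` (summaries, worked differences,
    ANOVA table), ``classify`` (full error report).  ``stats``/``classify``
    run on the synthetic cohort when present, otherwise on the extracted
    features.  Returns the in-memory stage outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if "phantoms" in config:
        results["manifest"] = simulate_stage(config, out)
    if "extract" in config:
        manifest_path = out / "manifest.csv"
        if not manifest_path.exists():
            raise FileNotFoundError(
                f"extract stage needs a manifest at {manifest_path}; run the phantoms stage first"
            )
        results["features"] = extract_stage(config, manifest_path, out / "features.csv")
    if "cohort" in config:
        results["cohort"] = cohort_stage(config, out / "cohort.csv")

    analysis = results.get("cohort", results.get("features"))
    if "stats" in config:
        if analysis is None:
            raise ValueError("stats stage needs a cohort or extracted features")
        results.update(stats_stage(config, analysis, out))
    if "classify" in config:
        if analysis is None:
            raise ValueError("classify stage needs a cohort or extracted features")
        results["classification"] = classify_stage(config, analysis, out)
    return results


__all__ = [
    "DEFAULT_CONFIG",
    "stage_seed",
    "config_hash",
    "read_csv",
    "validate_manifest",
    "run_pipeline",
    "simulate_stage",
    "extract_stage",
    "cohort_stage",
    "stats_stage",
    "classify_stage",
]
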