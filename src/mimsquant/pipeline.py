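"""Configuration-driven orchestration of figure-style analyses.

A single JSON/YAML config describes a run: simulate a scene (or load a
stack), compute enrichment images, segment compartments, and execute an
ordered list of analyses, writing every table and image under the output
directory with deterministic filenames and a JSON manifest of all artifacts.
Identical config + seed reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import logging
from pathlib import Path

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.image as mpimg

from . import io as mio
from . import rois as mroi
from . import stats as mstats
from .hotspots import colocalize_hotspots, detect_hotspots, hotspot_overlay, hotspot_table
from .ratios import (
    DEFAULT_MIN_DENOMINATOR,
    TRACERS,
    HSIRenderSpec,
    RatioDefinition,
    enrichment_image,
    pooled_roi_ratio,
    render_hsi,
)
from .scene import (
    COMPARTMENTS,
    SceneSpec,
    build_scene,
    default_scene_spec,
    sample_counts,
    scene_truth_summary,
    spec_to_dict,
)

logger = logging.getLogger("mimsquant")

__all__ = ["ConfigError", "StageError", "RunConfig", "run", "CONFIG_SCHEMA", "ANALYSES"]

ANALYSES = (
    "dispersion",
    "nucleolus_fold",
    "line_profile",
    "laminar_area",
    "hotspot_coloc",
    "pixel_correlation",
    "top_percentile",
    "pulse_chase",
    "condition_contrast",
)

#: Printable schema: field -> (type, default, doc).  All analysis defaults
#: live here so a config echo is self-documenting.
CONFIG_SCHEMA = {
    "mode": ("str", "simulate+analyze", "simulate | analyze | simulate+analyze"),
    "seed": ("int", 0, "master seed for all randomness"),
    "output_dir": ("str", "mimsquant_out", "directory for all artifacts"),
    "stack": ("str|null", None, "path to a saved stack (analyze mode)"),
    "scene": ("dict", {}, "SceneSpec field overrides for simulation"),
    "tracers": ("list[str]", ["15N_RNA", "13C_DNA"], "tracer ratio definitions to analyze"),
    "analyses": ("list[str]", ["dispersion"], f"ordered subset of {list(ANALYSES)}"),
    "hsi": ("dict", {"lower_pct": 0.0, "upper_pct": 300.0}, "hue-scale bounds per render"),
    "params": (
        "dict",
        {
            "min_denominator": DEFAULT_MIN_DENOMINATOR,
            "hotspot_window_px": 4,
            "hotspot_top_n": 20,
            "nucleolus_fold_threshold": 2.0,
            "nucleolus_min_diameter_um": 1.0,
            "nucleolus_max_diameter_um": 3.0,
            "top_percentile_pct": 5.0,
            "margin_threshold_pct": 30.0,
            "margin_smooth_sigma": 1.5,
            "line_width_px": 3,
            "segmentation_strategy": "P_threshold",
        },
        "analysis parameters",
    ),
    "pulse_chase": (
        "dict",
        {
            "n_cells": 3,
            "timepoints": [
                {"label": "pulse_15min", "nucleoplasm_rna": 0.3, "cytoplasm_rna": 0.1},
                {"label": "pulse_60min", "nucleoplasm_rna": 0.8, "cytoplasm_rna": 0.25},
                {"label": "pulse_120min", "nucleoplasm_rna": 1.2, "cytoplasm_rna": 0.4},
            ],
        },
        "timepoint multipliers for the pulse-chase analysis",
    ),
    "conditions": (
        "dict",
        {
            "n_cells": 4,
            "reference": "ctrl",
            "groups": {"ctrl": 1.0, "stim": 1.5},
        },
        "per-condition RNA multiplier scale factors",
    ),
}


class ConfigError(ValueError):
    """The run configuration is invalid."""


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _defaults() -> dict:
    return {k: json.loads(json.dumps(v[1])) for k, v in CONFIG_SCHEMA.items()}


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration (see :data:`CONFIG_SCHEMA` for fields)."""

    mode: str
    seed: int
    output_dir: Path
    stack: str | None
    scene: dict
    tracers: list
    analyses: list
    hsi: dict
    params: dict
    pulse_chase: dict
    conditions: dict

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = _defaults()
        unknown = set(raw) - set(cfg)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, value in raw.items():
            if isinstance(cfg[key], dict) and isinstance(value, dict):
                cfg[key] = {**cfg[key], **value}
            else:
                cfg[key] = value
        if cfg["mode"] not in ("simulate", "analyze", "simulate+analyze"):
            raise ConfigError(f"invalid mode {cfg['mode']!r}")
        if cfg["mode"] != "simulate" and not cfg["analyses"]:
            raise ConfigError("at least one analysis is required")
        bad = [a for a in cfg["analyses"] if a not in ANALYSES]
        if bad:
            raise ConfigError(f"unknown analyses {bad}; choose from {list(ANALYSES)}")
        for t in cfg["tracers"]:
            if t not in TRACERS:
                raise ConfigError(f"unknown tracer {t!r}; known: {sorted(TRACERS)}")
        if cfg["mode"] == "analyze" and not cfg["stack"]:
            raise ConfigError("analyze mode requires a stack path")
        return cls(
            mode=cfg["mode"],
            seed=int(cfg["seed"]),
            output_dir=Path(cfg["output_dir"]),
            stack=cfg["stack"],
            scene=cfg["scene"],
            tracers=list(cfg["tracers"]),
            analyses=list(cfg["analyses"]),
            hsi=cfg["hsi"],
            params=cfg["params"],
            pulse_chase=cfg["pulse_chase"],
            conditions=cfg["conditions"],
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _with_companions(path: Path) -> list:
    """A written artifact plus its JSON sidecar / mask companion, if any."""
    out = [path]
    side = path.with_suffix(".json")
    if side != path and side.exists():
        out.append(side)
    mask = path.with_name(path.stem + "_mask" + path.suffix)
    if mask != path and mask.exists():
        out.append(mask)
    return out


def _write_tsv(df, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def _scene_from_config(cfg: RunConfig, seed_offset: int = 0, **extra) -> SceneSpec:
    overrides = dict(cfg.scene)
    overrides.update(extra)
    # JSON/YAML configs carry geometry/texture as plain mappings; coerce them
    from .scene import ChromatinTexture, Disc, Ellipse

    if isinstance(overrides.get("nucleus"), dict):
        d = overrides["nucleus"]
        overrides["nucleus"] = Ellipse(
            tuple(d["center"]), tuple(d["semi_axes"]), d.get("orientation_deg", 0.0)
        )
    if overrides.get("nucleoli") and isinstance(overrides["nucleoli"][0], dict):
        overrides["nucleoli"] = [Disc(tuple(d["center"]), d["radius"]) for d in overrides["nucleoli"]]
    if isinstance(overrides.get("chromatin_texture"), dict):
        overrides["chromatin_texture"] = ChromatinTexture(**overrides["chromatin_texture"])
    spec = default_scene_spec(**overrides)
    spec.seed = (cfg.seed + seed_offset) % (2**31)
    spec.tracers = tuple(cfg.tracers)
    return spec


class _RunContext:
    """Mutable state shared between stages of one run."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.stack = None
        self.truth = None
        self.enr = {}        # tracer -> EnrichmentImage
        self.nucleus = None
        self.cytoplasm = None
        self.nucleoli = []

    def ensure_analysis_inputs(self):
        p = self.cfg.params
        for t in self.cfg.tracers:
            if t not in self.enr:
                self.enr[t] = enrichment_image(self.stack, TRACERS[t], p["min_denominator"])
        if self.nucleus is None:
            self.nucleus = mroi.segment_nucleus(self.stack, p["segmentation_strategy"])
            try:
                cell = mroi.segment_nucleus(self.stack, "S_contour")
                self.cytoplasm = mroi.cytoplasm_roi(cell, self.nucleus)
            except (mroi.SegmentationError, ValueError):
                self.cytoplasm = None
            if "15N_RNA" in self.enr:
                self.nucleoli = mroi.nucleolus_detect(
                    self.enr["15N_RNA"],
                    self.nucleus,
                    self.stack.pixel_size_nm,
                    p["nucleolus_min_diameter_um"],
                    p["nucleolus_max_diameter_um"],
                    p["nucleolus_fold_threshold"],
                )

    @property
    def nucleolar_mask(self) -> np.ndarray:
        mask = np.zeros(self.stack.shape, dtype=bool)
        for roi in self.nucleoli:
            mask |= roi.mask
        return mask


# ---------------------------------------------------------------- stages

def _stage_simulate(ctx: _RunContext, out: Path) -> list:
    spec = _scene_from_config(ctx.cfg)
    ctx.truth = build_scene(spec)
    ctx.stack = sample_counts(ctx.truth, seed=ctx.cfg.seed)
    ctx.stack.metadata["scene_spec"] = spec_to_dict(spec)
    files = [
        mio.save_stack(ctx.stack, out / "stack.tif"),
        mio.save_compartment_map(ctx.truth.compartment_map, COMPARTMENTS, out / "compartments.tif"),
        _write_tsv(scene_truth_summary(ctx.truth), out / "scene_truth_summary.tsv"),
    ]
    return files


def _stage_dispersion(ctx: _RunContext, out: Path) -> list:
    import pandas as pd

    rows, dumps = [], []
    for tracer, enr in ctx.enr.items():
        vals = enr.valid_values(ctx.nucleus.mask)
        d = mstats.dispersion(vals)
        rows.append(
            {
                "tracer": tracer,
                "roi": ctx.nucleus.label,
                "n_pixels": d.n,
                "median_pct": d.median,
                "mad_pct": d.mad,
                "mean_pct": d.mean,
                "sd_pct": d.sd,
                "cov": d.cov,
            }
        )
        dumps.append(
            _write_tsv(
                pd.DataFrame({"pixel_id": np.arange(vals.size), "enrichment_pct": vals}),
                out / f"pixels_{tracer}.tsv",
            )
        )
    return [_write_tsv(pd.DataFrame(rows), out / "dispersion.tsv")] + dumps


def _stage_nucleolus_fold(ctx: _RunContext, out: Path) -> list:
    import pandas as pd

    enr = ctx.enr["15N_RNA"]
    rows = []
    for roi in ctx.nucleoli:
        fold = mroi.fold_enrichment(roi, ctx.nucleus, enr)
        rows.append(
            {
                "nucleolus": roi.label,
                "area_px": roi.area_px,
                "area_um2": roi.area_um2(ctx.stack.pixel_size_nm),
                "fold_vs_nucleus": fold,
            }
        )
    return [_write_tsv(pd.DataFrame(rows), out / "nucleolus_fold.tsv")]


def _stage_line_profile(ctx: _RunContext, out: Path) -> list:
    import pandas as pd

    rows_idx = np.where(ctx.nucleus.mask.any(axis=1))[0]
    r = int(rows_idx.mean())
    cols = np.where(ctx.nucleus.mask[r])[0]
    margin = 8
    c0 = max(int(cols[0]) - margin, 0)
    c1 = min(int(cols[-1]) + margin, ctx.stack.shape[1] - 1)
    prof = mroi.line_profile(
        {t: e for t, e in ctx.enr.items()},
        [(r, c0), (r, c1)],
        width_px=ctx.cfg.params["line_width_px"],
        pixel_size_nm=ctx.stack.pixel_size_nm,
    )
    df = pd.DataFrame({"position_px": prof.positions_px, **prof.samples})
    return [_write_tsv(df, out / "line_profile.tsv")]


def _stage_laminar_area(ctx: _RunContext, out: Path) -> list:
    import pandas as pd

    p = ctx.cfg.params
    dna_tracer = next(t for t in ctx.cfg.tracers if t != "15N_RNA")
    dna_roi = mroi.roi_from_enrichment_threshold(
        ctx.enr[dna_tracer], p["margin_threshold_pct"], p["margin_smooth_sigma"], label="dna_guided"
    )
    rna_roi = mroi.roi_from_enrichment_threshold(
        ctx.enr["15N_RNA"], p["margin_threshold_pct"], p["margin_smooth_sigma"], label="rna_guided"
    )
    pct = mroi.unlabeled_margin_fraction(dna_roi, rna_roi)
    df = pd.DataFrame(
        [
            {
                "dna_area_px": dna_roi.area_px,
                "rna_area_px": rna_roi.area_px,
                "threshold_pct": p["margin_threshold_pct"],
                "unlabeled_margin_pct": pct,
            }
        ]
    )
    return [_write_tsv(df, out / "laminar_area.tsv")]


def _stage_hotspot_coloc(ctx: _RunContext, out: Path) -> list:
    p = ctx.cfg.params
    excl = ctx.nucleolar_mask
    excl_mask = excl if excl.any() else None
    files = []
    pairs = [(t, o) for t in ctx.cfg.tracers for o in ctx.cfg.tracers if t != o]
    for primary, other in pairs:
        hs = detect_hotspots(
            ctx.stack,
            TRACERS[primary],
            window=p["hotspot_window_px"],
            top_n=p["hotspot_top_n"],
            search_mask=ctx.nucleus.mask,
            exclusion_mask=excl_mask,
        )
        hs, nuclear_mean = colocalize_hotspots(hs, TRACERS[other], ctx.stack, ctx.nucleus.mask)
        files.append(_write_tsv(hotspot_table(hs, nuclear_mean), out / f"hotspots_{primary}.tsv"))
        spec = HSIRenderSpec(ctx.cfg.hsi["lower_pct"], ctx.cfg.hsi["upper_pct"])
        base = render_hsi(ctx.enr[other], spec)
        overlay = hotspot_overlay(hs, base)
        png = out / f"hotspots_{primary}_on_{other}.png"
        mpimg.imsave(png, np.clip(overlay, 0, 1))
        files.append(png)
    for tracer, enr in ctx.enr.items():
        spec = HSIRenderSpec(ctx.cfg.hsi["lower_pct"], ctx.cfg.hsi["upper_pct"])
        png = out / f"hsi_{tracer}.png"
        mpimg.imsave(png, np.clip(render_hsi(enr, spec), 0, 1))
        files.append(png)
    return files


def _stage_pixel_correlation(ctx: _RunContext, out: Path) -> list:
    import pandas as pd

    dna_tracer = next(t for t in ctx.cfg.tracers if t != "15N_RNA")
    mask = ctx.nucleus.mask & ~ctx.nucleolar_mask
    fit = mstats.pixel_regression(ctx.enr[dna_tracer], ctx.enr["15N_RNA"], mask, cell_id="cell_1")
    df = pd.DataFrame(
        [
            {
                "cell_id": fit.cell_id,
                "x": dna_tracer,
                "y": "15N_RNA",
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
                "n_pixels": fit.n,
            }
        ]
    )
    return [_write_tsv(df, out / "pixel_correlation.tsv")]


def _stage_top_percentile(ctx: _RunContext, out: Path) -> list:
    import pandas as pd

    p = ctx.cfg.params
    dna_tracer = next(t for t in ctx.cfg.tracers if t != "15N_RNA")
    res = mstats.top_percentile_subset(
        ctx.enr[dna_tracer],
        ctx.nucleus.mask & ~ctx.nucleolar_mask,
        pct=p["top_percentile_pct"],
        stack=ctx.stack,
        companion_rd=TRACERS["15N_RNA"],
    )
    df = pd.DataFrame(
        [
            {
                "density_tracer": dna_tracer,
                "pct": res.pct,
                "cutoff_density_pct": res.cutoff,
                "n_subset_px": res.n_subset,
                "companion_pooled_enrichment_pct": res.companion_pooled_enrichment_pct,
                "companion_pixel_mean_enrichment_pct": res.companion_pixel_mean_enrichment_pct,
                "background_reference_scaled": res.background_reference_scaled,
            }
        ]
    )
    return [_write_tsv(df, out / "top_percentile.tsv")]


def _per_cell_enrichments(ctx: _RunContext, rna_multipliers: dict, n_cells: int, seed_base: int):
    """Simulate n cells with overridden RNA multipliers; pooled nuclear/cytoplasmic enrichment."""
    records = []
    for i in range(n_cells):
        spec = _scene_from_config(ctx.cfg, seed_offset=seed_base + i)
        ce = {c: dict(m) for c, m in spec.compartment_enrichment.items()}
        for comp, mult in rna_multipliers.items():
            ce.setdefault(comp, {})["15N_RNA"] = mult
        spec.compartment_enrichment = ce
        truth = build_scene(spec)
        stack = sample_counts(truth, seed=(seed_base + i) % (2**31))
        rd = TRACERS["15N_RNA"]
        nuc = pooled_roi_ratio(stack, truth.nucleus_mask, rd)
        cyt = pooled_roi_ratio(stack, truth.compartment_mask("cytoplasm"), rd)
        records.append((f"cell_{i + 1}", nuc.enrichment_pct, cyt.enrichment_pct))
    return records


def _stage_pulse_chase(ctx: _RunContext, out: Path) -> list:
    cfgpc = ctx.cfg.pulse_chase
    records = []
    for j, tp in enumerate(cfgpc["timepoints"]):
        mult = {"nucleoplasm": tp["nucleoplasm_rna"], "cytoplasm": tp["cytoplasm_rna"]}
        cells = _per_cell_enrichments(ctx, mult, cfgpc["n_cells"], seed_base=ctx.cfg.seed + 1000 * (j + 1))
        for cell_id, nuc_pct, cyt_pct in cells:
            records.append((cell_id, tp["label"], "nucleus", nuc_pct))
            records.append((cell_id, tp["label"], "cytoplasm", cyt_pct))
    table = mstats.pulse_chase_table(records)
    return [_write_tsv(table, out / "pulse_chase.tsv")]


def _stage_condition_contrast(ctx: _RunContext, out: Path) -> list:
    cfgc = ctx.cfg.conditions
    groups = {}
    for j, (name, scale) in enumerate(sorted(cfgc["groups"].items())):
        base = _scene_from_config(ctx.cfg)
        rna = base.compartment_enrichment["nucleoplasm"]["15N_RNA"] * scale
        cells = _per_cell_enrichments(
            ctx, {"nucleoplasm": rna}, cfgc["n_cells"], seed_base=ctx.cfg.seed + 5000 * (j + 1)
        )
        groups[name] = [nuc for _, nuc, _ in cells]
    table = mstats.condition_contrast(groups, cfgc["reference"])
    return [_write_tsv(table, out / "condition_contrast.tsv")]


_STAGE_FUNCS = {
    "dispersion": _stage_dispersion,
    "nucleolus_fold": _stage_nucleolus_fold,
    "line_profile": _stage_line_profile,
    "laminar_area": _stage_laminar_area,
    "hotspot_coloc": _stage_hotspot_coloc,
    "pixel_correlation": _stage_pixel_correlation,
    "top_percentile": _stage_top_percentile,
    "pulse_chase": _stage_pulse_chase,
    "condition_contrast": _stage_condition_contrast,
}


def run(config: RunConfig | dict) -> dict:
    """Execute a configured run; returns (and writes) the artifact manifest.

    Stages run in order; a failure aborts the run with :class:`StageError`
    (the manifest is still written, with the failing stage marked FAILED and
    partial outputs retained).
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    ctx = _RunContext(cfg)
    manifest = {
        "seed": cfg.seed,
        "mode": cfg.mode,
        "tracers": cfg.tracers,
        "params": cfg.params,
        "stages": [],
    }

    stages = []
    if cfg.mode in ("simulate", "simulate+analyze"):
        stages.append(("simulate", _stage_simulate))
    elif cfg.stack:
        def _load(ctx, out):
            ctx.stack = mio.load_stack(cfg.stack)
            return []

        stages.append(("load_stack", _load))
    if cfg.mode != "simulate":
        stages += [(name, _STAGE_FUNCS[name]) for name in cfg.analyses]

    failed = None
    for name, fn in stages:
        t0 = time.perf_counter()
        entry = {"stage": name, "outputs": [], "status": "OK"}
        try:
            if name not in ("simulate", "load_stack"):
                ctx.ensure_analysis_inputs()
            files = fn(ctx, out)
            entry["outputs"] = [
                {"path": str(g.relative_to(out)), "sha256": _sha256(g)}
                for f in files
                for g in _with_companions(Path(f))
            ]
        except Exception as exc:  # noqa: BLE001 - stage isolation boundary
            entry["status"] = "FAILED"
            entry["error"] = str(exc)
            failed = StageError(name, exc)
        entry["wall_s"] = round(time.perf_counter() - t0, 4)
        logger.info("stage=%s status=%s wall_s=%.3f seed=%d", name, entry["status"], entry["wall_s"], cfg.seed)
        manifest["stages"].append(entry)
        if failed:
            break

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if failed:
        raise failed
    return manifest
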