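"""End-to-end demo: simulate a two-condition study, run every analysis,
write all tables plus a manifest.

The demo mirrors the full study workflow at desk scale: a control and an
LED-"treated" cohort differ only by the generator parameters the config
states (faster persistent migration, faster gap closure, higher
marker-positive fraction, planted expression fold changes); every stage's
output is a CSV under the configured output directory, and the manifest
records the config echo, seed, per-stage outputs and wall time.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .config import RunConfig
from .dosimetry import LEDChannel, PulseSpec, compute_dose
from .errors import PbmQuantError
from .io import configure_logging, logger, write_table
from .morphometrics import adhesion_metrics, count_positive_nuclei
from .motility import FitPolicy, MotilityModel
from .qpcr import fold_changes
from .synthetic import (
    CtSceneParams,
    FluorescenceSceneParams,
    MotilityModelParams,
    ScratchSceneParams,
    render_fluorescence_field,
    render_scratch_frames,
    simulate_ct_table,
    simulate_tracks,
)
from .wound import SegmentationParams, closure_kinetics


@dataclass
class RunManifest:
    """What a demo run produced: config echo, seed, outputs, timings."""

    seed: int
    version: str
    config_echo: dict
    outputs: dict = field(default_factory=dict)      # stage -> [paths]
    wall_time_s: dict = field(default_factory=dict)  # stage -> seconds

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "pbmquant_version": self.version,
            "seed": self.seed,
            "config": self.config_echo,
            "outputs": {k: [str(p) for p in v] for k, v in self.outputs.items()},
            "wall_time_s": {k: round(v, 3) for k, v in self.wall_time_s.items()},
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")

    def all_outputs(self) -> list[Path]:
        return [Path(p) for paths in self.outputs.values() for p in paths]


def _stage(manifest: RunManifest, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s ...", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            manifest.wall_time_s[name] = time.perf_counter() - self.t0
            if exc is not None:
                raise PbmQuantError(f"stage {name!r} failed: {exc}") from exc

    return _Timer()


def run_demo(config: RunConfig) -> RunManifest:
    """Run the full synthetic study; returns the manifest (also written
    to ``<outdir>/manifest.yaml``)."""
    configure_logging(config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        seed=config.seed,
        version=__version__,
        config_echo=yaml.safe_load(config.model_dump_json()),
    )

    # --- motility -----------------------------------------------------
    with _stage(manifest, "motility"):
        mb = config.motility
        cohorts = {}
        for i, (cond, cp) in enumerate(
            (("control", mb.control), ("treated", mb.treated))
        ):
            cohorts[cond] = simulate_tracks(
                MotilityModelParams(
                    model=cp.model,
                    step_sigma=cp.step_sigma,
                    speed=cp.speed,
                    persistence_time=cp.persistence_time,
                    delta_t=mb.delta_t_min,
                    n_steps=mb.n_steps,
                    n_tracks=cp.n_tracks,
                    seed=config.seed * 4 + i,
                )
            )
        res = MotilityModel(
            cohorts,
            FitPolicy(max_lag_frac=mb.fit_max_lag_frac, min_lags=mb.fit_min_lags),
        ).fit()
        paths = []
        for name, df in (
            ("motility_per_track.csv", res.per_track),
            ("motility_by_condition.csv", res.by_condition),
            ("motility_lag_curves.csv", res.lag_table()),
        ):
            write_table(df, out / name)
            paths.append(out / name)
        for cond, table in cohorts.items():
            p = out / f"tracks_{cond}.csv"
            write_table(table.df, p)
            paths.append(p)
        manifest.outputs["motility"] = paths

    # --- wound closure ------------------------------------------------
    with _stage(manifest, "wound"):
        wb = config.wound
        paths = []
        for i, (cond, fractions) in enumerate(
            (("control", wb.control_fractions), ("treated", wb.treated_fractions))
        ):
            stack, masks = render_scratch_frames(
                ScratchSceneParams(
                    height=wb.height,
                    width=wb.width,
                    wound_fraction_per_frame=tuple(fractions),
                    noise_sigma=wb.noise_sigma,
                    seed=config.seed * 4 + i,
                )
            )
            series = closure_kinetics(
                stack,
                wb.times_h,
                SegmentationParams(
                    variance_window=wb.variance_window,
                    closing_radius=wb.closing_radius,
                ),
            )
            exact = closure_kinetics(stack, wb.times_h, masks=masks)
            p1 = out / f"closure_{cond}_segmented.csv"
            p2 = out / f"closure_{cond}_planted.csv"
            write_table(series.to_frame(), p1)
            write_table(exact.to_frame(), p2)
            paths += [p1, p2]
        manifest.outputs["wound"] = paths

    # --- morphometrics ------------------------------------------------
    with _stage(manifest, "morphometrics"):
        fb = config.morphometrics
        paths = []
        rows = []
        for i, (cond, pos_frac) in enumerate(
            (
                ("control", fb.control_positive_fraction),
                ("treated", fb.treated_positive_fraction),
            )
        ):
            stack, truth = render_fluorescence_field(
                FluorescenceSceneParams(
                    height=fb.height,
                    width=fb.width,
                    n_nuclei=fb.n_nuclei,
                    positive_fraction=pos_frac,
                    n_puncta=fb.n_puncta,
                    puncta_axis_ratio=fb.puncta_axis_ratio,
                    noise_sigma=fb.noise_sigma,
                    seed=config.seed * 4 + i,
                )
            )
            quant = count_positive_nuclei(stack.frame(0, 0), stack.frame(0, 1))
            morpho = adhesion_metrics(
                np.ones((fb.height, fb.width), dtype=bool),
                {"puncta": stack.frame(0, 2)},
                adhesion_channels=("puncta",),
            )
            rows.append(
                {
                    "condition": cond,
                    "n_total": quant.n_total,
                    "n_positive": quant.n_positive,
                    "positive_pct": quant.positive_pct,
                    "adhesion_count": morpho.adhesion_count,
                    "mean_adhesion_area": morpho.mean_adhesion_area,
                    "mean_adhesion_elongation": morpho.mean_adhesion_elongation,
                }
            )
            p = out / f"fluorescence_truth_{cond}.csv"
            write_table(truth, p)
            paths.append(p)
        import pandas as pd

        p = out / "morphometrics_by_condition.csv"
        write_table(pd.DataFrame(rows), p)
        paths.append(p)
        manifest.outputs["morphometrics"] = paths

    # --- qPCR ---------------------------------------------------------
    with _stage(manifest, "qpcr"):
        qb = config.qpcr
        ct, truth = simulate_ct_table(
            CtSceneParams(
                genes=tuple(qb.genes),
                reference_gene=qb.reference_gene,
                true_log2_fold=tuple(qb.true_log2_fold),
                ct_noise_sd=qb.ct_noise_sd,
                n_replicates=qb.n_replicates,
                n_samples=qb.n_samples,
                seed=config.seed,
            )
        )
        res = fold_changes(ct, qb.reference_gene, qb.calibrator_condition)
        paths = []
        for name, df in (
            ("ct_table.csv", ct.df),
            ("ct_truth.csv", truth),
            ("fold_changes_per_sample.csv", res.per_sample),
            ("fold_changes_by_condition.csv", res.by_condition),
        ):
            write_table(df, out / name)
            paths.append(out / name)
        manifest.outputs["qpcr"] = paths

    # --- dosimetry ------------------------------------------------------
    with _stage(manifest, "dose"):
        db = config.dose
        dose = compute_dose(
            [LEDChannel(c.wavelength_nm, c.power_mw) for c in db.channels],
            PulseSpec(db.on_time_us, db.off_time_us),
            duration_s=db.duration_min * 60.0,
            area_cm2=db.area_cm2,
        )
        summary = dose.per_channel.copy()
        p = out / "dose_per_channel.csv"
        write_table(summary, p)
        (out / "dose_summary.txt").write_text(dose.summary() + "\n", encoding="utf-8")
        manifest.outputs["dose"] = [p, out / "dose_summary.txt"]

    manifest.to_yaml(out / "manifest.yaml")
    missing = [p for p in manifest.all_outputs() if not p.exists()]
    if missing:
        raise PbmQuantError(f"manifest lists missing outputs: {missing}")
    return manifest
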