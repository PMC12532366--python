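"""End-to-end pipeline: simulate -> reconstruct -> metrics -> classify ->
stats -> image quantification -> report.

All randomness flows from one global seed through per-stage derived
streams (numpy SeedSequence.spawn), so individual stages rerun
reproducibly.  Every stage writes its outputs (CSV/JSON with metadata
sidecars) before the next stage begins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import group_stats as gs
from . import image_quant as iq
from .io import config_hash, spots_to_frame, write_counts_table, write_metadata_sidecar
from .metrics import summarize
from .simulate import (
    STRAIN_PAIRS,
    SpotMeasurement,
    SyntheticCohortConfig,
    random_plaque_ground_truth,
    simulate_cohort,
    simulate_plaque_image,
    simulate_tomography_set,
)
from .source import SourceParams
from .states import make_werner_state
from .tomography import MLEConvergenceError, linear_inversion, mle_reconstruct

__all__ = ["PipelineConfig", "run_pipeline", "measure_tomographies", "measure_cohort"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run, serializable to YAML."""

    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    reconstruction: str = "mle"  # "mle" | "linear"
    subtract_accidentals: bool = False
    features: tuple[str, ...] = clf.FEATURES_2D
    c_grid: tuple[float, ...] = clf.DEFAULT_C_GRID
    n_folds: int = 5
    image_regions: int = 8
    plaques_max: int = 12
    image_shape: tuple[int, int] = (256, 256)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {})
        source_raw = cohort_raw.pop("source", {})
        groups_raw = cohort_raw.pop("groups", None)
        from .simulate import DEFAULT_GROUPS, GroupSpec

        groups = (
            tuple(GroupSpec(**g) for g in groups_raw)
            if groups_raw is not None
            else tuple(DEFAULT_GROUPS)
        )
        cohort = SyntheticCohortConfig(
            groups=groups, source=SourceParams(**source_raw), **cohort_raw
        )
        for key in ("features", "c_grid", "image_shape"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(cohort=cohort, **raw)


def _reconstruct(ts, method: str, subtract_hz: float | None):
    if method == "linear":
        return linear_inversion(ts, subtract_accidentals_hz=subtract_hz)
    try:
        return mle_reconstruct(ts, subtract_accidentals_hz=subtract_hz)
    except MLEConvergenceError as exc:
        logger.warning("using best MLE iterate for %s", ts.metadata.get("spot_id"))
        return exc.best_rho


def measure_tomographies(
    tomography_sets,
    method: str = "mle",
    subtract_accidentals_hz: float | None = None,
    bell: str = "phi_plus",
) -> pd.DataFrame:
    """Reconstruct each tomography set and tabulate the metric panel.

    Returns one row per individual measurement with the cohort labels
    carried through from the set metadata.
    """
    rows = []
    for ts in tomography_sets:
        rho = _reconstruct(ts, method, subtract_accidentals_hz)
        summ = summarize(rho, bell=bell)
        row = {
            "spot_id": ts.metadata.get("spot_id"),
            "strain": ts.metadata.get("strain"),
            "region": ts.metadata.get("region"),
            "replicate_id": ts.metadata.get("replicate"),
            "repeat": ts.metadata.get("repeat"),
            "label": ts.metadata.get("label"),
            "tangle": summ.tangle,
            "linear_entropy": summ.linear_entropy,
            "concurrence": summ.concurrence,
            "purity": summ.purity,
            "werner_p_hat": summ.werner_p_hat,
            "ts_deviation": summ.ts_deviation,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def measure_cohort(
    spots: list[SpotMeasurement],
    method: str = "mle",
    subtract_accidentals_hz: float | None = None,
    bell: str = "phi_plus",
) -> pd.DataFrame:
    """Metrics table for a simulated cohort (one row per repeat)."""
    sets = [ts for spot in spots for ts in spot.tomographies]
    return measure_tomographies(sets, method, subtract_accidentals_hz, bell)


def _image_stage(config: PipelineConfig, outdir: Path, seed_seq) -> pd.DataFrame:
    """Coupled burden/decoherence stage: regions with more plaque area get

    higher Werner p, emulating better entanglement preservation in
    plaque-dense tissue.  Returns per-region burden and mean metrics."""
    rng = np.random.default_rng(seed_seq)
    rows = []
    source = config.cohort.source
    for i in range(config.image_regions):
        n = int(rng.integers(1, config.plaques_max + 1))
        gt = random_plaque_ground_truth(n, shape=config.image_shape, rng=rng)
        img, gt = simulate_plaque_image(gt, rng=rng)
        quant = iq.analyze_image(img)
        # couple Werner p to the true burden (scaled to [0.7, 0.98])
        max_fraction = config.plaques_max * np.pi * 14.0**2 / (
            config.image_shape[0] * config.image_shape[1]
        )
        p = 0.7 + 0.28 * min(gt.area_fraction / max_fraction, 1.0)
        rho = make_werner_state(p)
        metrics = []
        for _ in range(5):
            ts = simulate_tomography_set(rho, source, rng=rng)
            rho_hat = _reconstruct(ts, config.reconstruction, None)
            metrics.append(summarize(rho_hat))
        rows.append(
            {
                "region_id": i,
                "true_count": gt.count,
                "true_area_percent": 100.0 * gt.area_fraction,
                "count": quant.count,
                "area_percent": quant.area_percent,
                "true_p": p,
                "mean_tangle": float(np.mean([m.tangle for m in metrics])),
                "mean_linear_entropy": float(
                    np.mean([m.linear_entropy for m in metrics])
                ),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and write per-stage outputs under ``outdir``.

    Returns a dict of stage result objects and output paths.  Rerunning
    with the same config reproduces all seeded outputs byte-identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config.to_dict())
    meta = {"seed": config.seed, "config_hash": chash}
    (outdir / "run_metadata.json").write_text(
        json.dumps({**meta, "config": config.to_dict()}, indent=1, default=str)
    )
    seeds = np.random.SeedSequence(config.seed).spawn(3)

    stage = "simulate"
    try:
        cohort_cfg = SyntheticCohortConfig(
            **{**asdict_shallow(config.cohort), "seed": config.seed}
        )
        spots = simulate_cohort(cohort_cfg)
        counts = spots_to_frame(spots)
        write_counts_table(counts, outdir / "counts.csv", metadata=meta)

        stage = "reconstruct+metrics"
        subtract = (
            cohort_cfg.source.accidental_rate if config.subtract_accidentals else None
        )
        measurements = measure_cohort(
            spots, config.reconstruction, subtract, config.cohort.bell.label
        )
        measurements.to_csv(outdir / "metrics.csv", index=False)
        write_metadata_sidecar(outdir / "metrics.csv", meta)

        stage = "classify"
        split_frames = []
        for transgenic, control in STRAIN_PAIRS.items():
            for region in sorted(measurements["region"].dropna().unique()):
                records = clf.assemble_features(
                    measurements, (transgenic, control), region
                )
                if records.empty or records["label"].nunique() < 2:
                    continue
                results = clf.leave_one_replicate_out(
                    records,
                    features=config.features,
                    C_grid=config.c_grid,
                    n_folds=config.n_folds,
                    seed=config.seed,
                )
                frame = clf.split_results_frame(results)
                frame.insert(0, "pair", f"{transgenic}-{control}")
                frame.insert(1, "region", region)
                split_frames.append(frame)
        splits = (
            pd.concat(split_frames, ignore_index=True)
            if split_frames
            else pd.DataFrame()
        )
        splits.to_csv(outdir / "classification.csv", index=False)
        write_metadata_sidecar(outdir / "classification.csv", meta)

        stage = "stats"
        stat_rows = []
        for transgenic, control in STRAIN_PAIRS.items():
            for region in sorted(measurements["region"].dropna().unique()):
                sub = measurements[measurements["region"] == region]
                a = sub.loc[sub["strain"] == transgenic]
                b = sub.loc[sub["strain"] == control]
                if len(a) < 3 or len(b) < 3:
                    continue
                for feature in ("tangle", "linear_entropy"):
                    comp = gs.run_comparison(
                        a[feature], b[feature], feature=feature,
                        name_a=transgenic, name_b=control, ci_seed=config.seed,
                    )
                    row = {"pair": f"{transgenic}-{control}", "region": region}
                    row.update(vars(comp))
                    row["stars"] = comp.stars
                    stat_rows.append(row)
        stats = pd.DataFrame(stat_rows)
        stats.to_csv(outdir / "group_stats.csv", index=False)
        write_metadata_sidecar(outdir / "group_stats.csv", meta)

        stage = "image"
        burden = _image_stage(config, outdir, seeds[2])
        burden.to_csv(outdir / "plaque_burden.csv", index=False)
        write_metadata_sidecar(outdir / "plaque_burden.csv", meta)
        corr_t = iq.correlate_burden(burden["area_percent"], burden["mean_tangle"])
        corr_s = iq.correlate_burden(
            burden["area_percent"], burden["mean_linear_entropy"]
        )

        stage = "report"
        report = {
            "seed": config.seed,
            "config_hash": chash,
            "n_spots": len(spots),
            "n_measurements": len(measurements),
            "min_split_metric": float(
                splits[["precision", "recall", "sensitivity", "specificity", "f1"]]
                .min()
                .min()
            )
            if not splits.empty
            else None,
            "burden_vs_tangle_r": corr_t["r"],
            "burden_vs_linear_entropy_r": corr_s["r"],
        }
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {
        "spots": spots,
        "measurements": measurements,
        "classification": splits,
        "stats": stats,
        "burden": burden,
        "report": report,
        "outdir": outdir,
    }


def asdict_shallow(obj) -> dict:
    """dataclasses.asdict without recursing into nested dataclasses."""
    return {f: getattr(obj, f) for f in obj.__dataclass_fields__}
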