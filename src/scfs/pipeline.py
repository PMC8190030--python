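"""Orchestration: the end-to-end synthetic study and the analysis-only run.

A *study* mirrors the experimental design: for every cell-cell pairing the
velocity series is simulated at the control force scale, and every
treatment regime is simulated at the base velocity; each design cell is a
set of force maps that are detected, pooled and summarised, followed by the
velocity trends and the control/vehicle/drug comparisons.  All randomness
descends deterministically from one top-level seed, so a run is exactly
reproducible from its config echo.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .constants import CONDITIONS, TREATMENTS, VELOCITIES_UM_PER_S
from .datamodel import ConditionDataset, RuptureEvent, pool_condition
from .detection import DetectionParams, process_curve
from .errors import DataError, ScfsError
from .io import read_curve, write_curve, write_event_table
from .presets import preset_condition
from .simulate import simulate_force_map
from .stats import (
    ComparisonResult,
    ConditionSummary,
    build_summary_table,
    compare_treatments,
    summarize,
    velocity_trend,
)

__all__ = ["PipelineConfig", "StudyResult", "run_full_synthetic_study", "run_analyze", "version_and_provenance"]

logger = logging.getLogger("scfs")


@dataclass
class PipelineConfig:
    """Serializable configuration of a study or analysis run."""

    out_dir: str = "study_out"
    seed: int = 0
    conditions: tuple[str, ...] = CONDITIONS
    velocities: tuple[float, ...] = VELOCITIES_UM_PER_S
    treatments: tuple[str, ...] = TREATMENTS
    n_maps: int = 2
    n_curves: int = 24
    detection: DetectionParams = field(default_factory=DetectionParams)
    bin_width_pN: float = 10.0
    write_curves: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        d["velocities"] = list(self.velocities)
        d["treatments"] = list(self.treatments)
        return d


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def version_and_provenance(config: PipelineConfig) -> dict:
    """Run manifest: tool version, config hash, seed.  Identical configs
    produce identical manifests."""
    return {"tool": "scfs", "version": __version__, "seed": config.seed, "config_hash": config_hash(config)}


@dataclass
class StudyResult:
    datasets: dict[tuple[str, str, float], ConditionDataset]
    summaries: dict[tuple[str, str, float], ConditionSummary]
    trends: dict[str, object]
    comparisons: dict[str, dict[tuple[str, str], ComparisonResult]]
    events: list[RuptureEvent]
    n_jump_free_curves: dict[tuple[str, str, float], int]
    out_dir: Path


def _cell_seed(seed: int, cell: str) -> int:
    ss = np.random.SeedSequence([int(seed), zlib.crc32(cell.encode("utf-8"))])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _design_cells(config: PipelineConfig):
    """(condition, treatment, velocity) cells: velocity series for controls,
    treatments at the base velocity."""
    base_v = config.velocities[0]
    cells = []
    for cond in config.conditions:
        for v in config.velocities:
            cells.append((cond, "none", float(v)))
        for treat in config.treatments:
            if treat != "none":
                cells.append((cond, treat, float(base_v)))
    return cells


def _simulate_and_detect_cell(
    cond: str, treat: str, v: float, config: PipelineConfig, curves_dir: Path | None
):
    preset_name = cond if treat == "none" else f"{cond}-{treat}"
    cell = f"{cond}_{treat}_{v:g}"
    events: list[RuptureEvent] = []
    n_jump_free = 0
    n_curves_total = 0
    for j in range(config.n_maps):
        cfg = preset_condition(preset_name, velocity=v, seed=_cell_seed(config.seed, cell))
        fmap, _truth = simulate_force_map(cfg, n_curves=config.n_curves, map_id=f"{cell}_m{j}")
        for curve in fmap.curves:
            _, evts = process_curve(curve, config.detection)
            events.extend(evts)
            n_curves_total += 1
            if not any(e.event_class == "jump" for e in evts):
                n_jump_free += 1
            if curves_dir is not None:
                write_curve(curve, curves_dir / f"{curve.metadata.curve_id}.tsv")
    dataset = pool_condition(events, cond, treat, v, n_maps=config.n_maps)
    dataset.n_curves = n_curves_total
    return dataset, events, n_jump_free


def run_full_synthetic_study(config: PipelineConfig) -> StudyResult:
    """Simulate, detect, summarise and compare the full design grid."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    logger.info("study start: %d conditions, %d velocities, seed %d", len(config.conditions), len(config.velocities), config.seed)

    curves_dir = None
    if config.write_curves:
        curves_dir = out_dir / "curves"
        curves_dir.mkdir(exist_ok=True)

    datasets: dict[tuple[str, str, float], ConditionDataset] = {}
    summaries: dict[tuple[str, str, float], ConditionSummary] = {}
    jump_free: dict[tuple[str, str, float], int] = {}
    all_events: list[RuptureEvent] = []
    for cond, treat, v in _design_cells(config):
        try:
            ds, events, nfree = _simulate_and_detect_cell(cond, treat, v, config, curves_dir)
        except ScfsError as exc:
            raise type(exc)(f"stage simulate/detect, cell ({cond}, {treat}, {v}): {exc}") from exc
        key = (cond, treat, v)
        datasets[key] = ds
        summaries[key] = summarize(ds, bin_width=config.bin_width_pN)
        jump_free[key] = nfree
        all_events.extend(events)
        logger.info("cell %s/%s @%g um/s: %d curves, %d jump forces", cond, treat, v, ds.n_curves, ds.n)

    trends = {}
    for cond in config.conditions:
        series = [summaries[(cond, "none", float(v))] for v in config.velocities]
        if sum(1 for s in series if s.n > 0) >= 3:
            trends[cond] = velocity_trend(series)

    base_v = float(config.velocities[0])
    comparisons: dict[str, dict[tuple[str, str], ComparisonResult]] = {}
    for cond in config.conditions:
        for drug in ("cytochalasinD", "ML7"):
            key_c = (cond, "none", base_v)
            key_v = (cond, "DMSO", base_v)
            key_d = (cond, drug, base_v)
            if all(k in datasets and datasets[k].n > 0 for k in (key_c, key_v, key_d)):
                comparisons[f"{cond}:{drug}"] = compare_treatments(
                    datasets[key_c], datasets[key_v], datasets[key_d], drug_label=drug
                )

    _write_study_outputs(out_dir, config, summaries, trends, comparisons, all_events, jump_free)
    logger.info("study done: %d events total", len(all_events))
    return StudyResult(
        datasets=datasets,
        summaries=summaries,
        trends=trends,
        comparisons=comparisons,
        events=all_events,
        n_jump_free_curves=jump_free,
        out_dir=out_dir,
    )


def _setup_logging(out_dir: Path) -> None:
    if not any(isinstance(h, logging.FileHandler) and Path(getattr(h, "baseFilename", "")) == (out_dir / "run.log").resolve() for h in logger.handlers):
        fh = logging.FileHandler(out_dir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
    if logger.level == logging.NOTSET:
        logger.setLevel(logging.INFO)


def _write_study_outputs(out_dir, config, summaries, trends, comparisons, events, jump_free) -> None:
    write_event_table(events, out_dir / "events.tsv")
    table = build_summary_table(summaries.values())
    table.to_csv(out_dir / "table.tsv", sep="\t", index=False, float_format="%.6g")

    payload = {
        "summaries": [s.to_dict() for _, s in sorted(summaries.items())],
        "jump_free_curves": {f"{c}:{t}:{v:g}": n for (c, t, v), n in sorted(jump_free.items())},
        "velocity_trends": {
            cond: {
                "velocities_um_per_s": [float(x) for x in tr.velocities],
                "medians_pN": [float(x) for x in tr.medians],
                "slope_pN_per_um_s": tr.slope,
                "intercept_pN": tr.intercept,
                "spearman_rho": tr.spearman_rho,
            }
            for cond, tr in sorted(trends.items())
        },
    }
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)

    with open(out_dir / "comparisons.tsv", "w", encoding="utf-8") as fh:
        fh.write("condition\tcontrast\tgroup_a\tgroup_b\tU\tp_value\tstars\tmethod\n")
        for name in sorted(comparisons):
            for (la, lb), res in comparisons[name].items():
                fh.write(
                    f"{name.split(':')[0]}\t{name.split(':')[1]}\t{la}\t{lb}\t"
                    f"{res.u_statistic:.6g}\t{res.p_value:.6g}\t{res.stars}\t{res.method}\n"
                )

    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(version_and_provenance(config), fh, indent=2, sort_keys=True)
    with open(out_dir / "config.json", "w", encoding="utf-8") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)


def run_analyze(input_dir: str | Path, config: PipelineConfig) -> StudyResult:
    """Detection and summaries for a directory of curve TSVs (no simulation).

    Unreadable curves are skipped with a logged warning; more than 20%
    skipped, or an empty directory, is a hard error.
    """
    input_dir = Path(input_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)

    paths = sorted(p for p in input_dir.glob("*.tsv") if p.name not in ("truth.tsv", "events.tsv"))
    if not paths:
        raise DataError(f"no curve files found in {input_dir}")
    groups: dict[tuple[str, str, float], list[RuptureEvent]] = {}
    n_curves: dict[tuple[str, str, float], int] = {}
    jump_free: dict[tuple[str, str, float], int] = {}
    all_events: list[RuptureEvent] = []
    n_skipped = 0
    for path in paths:
        try:
            curve = read_curve(path)
            _, evts = process_curve(curve, config.detection)
        except ScfsError as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            n_skipped += 1
            continue
        meta = curve.metadata
        key = (meta.condition_label, meta.treatment_label, float(meta.velocity_v))
        groups.setdefault(key, []).extend(evts)
        n_curves[key] = n_curves.get(key, 0) + 1
        jump_free[key] = jump_free.get(key, 0) + (0 if any(e.event_class == "jump" for e in evts) else 1)
        all_events.extend(evts)
    if n_skipped > 0.2 * len(paths):
        raise DataError(f"{n_skipped} of {len(paths)} curves unreadable (> 20%)")

    datasets = {}
    summaries = {}
    for key, evts in groups.items():
        cond, treat, v = key
        ds = pool_condition(evts, cond, treat, v)
        ds.n_curves = n_curves[key]
        datasets[key] = ds
        summaries[key] = summarize(ds, bin_width=config.bin_width_pN)

    _write_study_outputs(out_dir, config, summaries, {}, {}, all_events, jump_free)
    return StudyResult(
        datasets=datasets,
        summaries=summaries,
        trends={},
        comparisons={},
        events=all_events,
        n_jump_free_curves=jump_free,
        out_dir=out_dir,
    )
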