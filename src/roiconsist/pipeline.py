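"""Configuration-driven orchestration of the full analysis.

A :class:`PipelineConfig` selects either file input (4-D NIfTI plus a
label volume) or in-package synthetic generation, the preprocessing
toggles, and the analysis parameters. :func:`run_pipeline` executes

    read/generate -> low-power filter -> detrend -> (smoothing variants)
    -> ROI averaging -> consistency + distributions + permutation test
    -> pair table + identity-bound check -> adjacency + thresholding
    -> consistency-centrality relation

writing one set of TSV/JSON outputs per smoothing FWHM plus a run
manifest (config hash, seed, package versions, warnings, timings).
Every random draw derives from the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consistency import (
    consistency_vs_size,
    roi_consistencies,
    within_between_distributions,
)
from .cross_roi import build_pair_table, identity_bound_check, relation_binned
from .exceptions import PipelineError, ValidationError
from .io import filter_low_power_voxels, read_4d_image, read_label_volume
from .network import (
    DEFAULT_DENSITY_GRID,
    build_adjacency,
    consistency_centrality_relation,
)
from .signal import SmoothingKernel, detrend_linear, roi_average, smooth_spatial
from .synthetic import SyntheticSpec, generate_parcellation, generate_voxel_timeseries

__all__ = ["PipelineConfig", "run_pipeline", "pool_consistency_tables"]


@dataclass
class PipelineConfig:
    """Validated description of one pipeline run."""

    output_dir: str
    mode: str = "synthetic"  # "synthetic" | "files"
    synthetic_spec: SyntheticSpec | None = None
    image_path: str | None = None
    labels_path: str | None = None
    mask_path: str | None = None
    detrend: bool = True
    power_filter_fraction: float | None = 0.02
    smoothing_fwhm_mm: tuple[float, ...] = (0.0,)
    density_grid: tuple[float, ...] = DEFAULT_DENSITY_GRID
    size_bins: int = 10
    relation_bins: int = 10
    n_permutations: int = 10_000
    pair_cap: int = 10_000_000
    bound_tolerance: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValidationError("mode must be 'synthetic' or 'files'")
        if self.mode == "synthetic" and self.synthetic_spec is None:
            raise ValidationError("synthetic mode requires a synthetic_spec")
        if self.mode == "files" and (
            self.image_path is None or self.labels_path is None
        ):
            raise ValidationError("files mode requires image_path and labels_path")
        if self.power_filter_fraction is not None and not (
            0.0 < self.power_filter_fraction < 1.0
        ):
            raise ValidationError("power_filter_fraction must lie in (0, 1)")
        if any(f < 0 for f in self.smoothing_fwhm_mm):
            raise ValidationError("smoothing FWHM must be nonnegative")
        if not self.smoothing_fwhm_mm:
            raise ValidationError("at least one smoothing FWHM (0 = none)")
        if any(not 0.0 < d <= 1.0 for d in self.density_grid):
            raise ValidationError("densities must lie in (0, 1]")
        if self.size_bins < 1 or self.relation_bins < 1:
            raise ValidationError("bin counts must be >= 1")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic_spec is not None:
            d["synthetic_spec"] = json.loads(self.synthetic_spec.to_json())
        d["smoothing_fwhm_mm"] = list(self.smoothing_fwhm_mm)
        d["density_grid"] = list(self.density_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic_spec") is not None:
            d["synthetic_spec"] = SyntheticSpec.from_json(
                json.dumps(d["synthetic_spec"])
            )
        for key in ("smoothing_fwhm_mm", "density_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text)
        return cls.from_dict(d)


def _hash_config(config: PipelineConfig) -> str:
    d = config.to_dict()
    d.pop("output_dir")  # hash the scientific config, not where it lands
    canon = json.dumps(d, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage(report: dict, name: str):
    """Context manager recording stage timing and wrapping failures."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            report["timings"][name] = round(time.perf_counter() - self.t0, 4)
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all outputs.

    Returns the run report (also written as ``manifest.json``): config
    hash, seed, versions, per-stage timings, collected warnings, and the
    headline numbers of each stage.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": _hash_config(config),
        "seed": config.seed,
        "versions": {"roiconsist": __version__, "numpy": np.__version__},
        "timings": {},
        "warnings": [],
        "stages": {},
    }
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        with _stage(report, "input"):
            if config.mode == "synthetic":
                spec = config.synthetic_spec
                parc = generate_parcellation(spec)
                vts = generate_voxel_timeseries(spec, parc)
            else:
                vts = read_4d_image(config.image_path, config.mask_path)
                parc = read_label_volume(config.labels_path, vts)
            report["stages"]["input"] = {
                "n_voxels": vts.n_voxels,
                "n_timepoints": vts.n_timepoints,
                "n_rois": parc.n_rois,
            }

        if config.power_filter_fraction is not None:
            with _stage(report, "power_filter"):
                vts, removal = filter_low_power_voxels(
                    vts, config.power_filter_fraction
                )
                removal.to_csv(out / "removed_voxels.tsv", sep="\t", index=False)
                report["stages"]["power_filter"] = {
                    "n_removed": len(removal),
                    "threshold": float(removal["threshold"].iloc[0])
                    if len(removal)
                    else None,
                }

        if config.detrend:
            with _stage(report, "detrend"):
                vts = detrend_linear(vts)

        for fwhm in config.smoothing_fwhm_mm:
            tag = f"fwhm{fwhm:g}"
            with _stage(report, f"analysis_{tag}"):
                v = (
                    smooth_spatial(vts, SmoothingKernel(fwhm))
                    if fwhm > 0
                    else vts
                )
                stage_report = _analyze_variant(v, parc, config, out, tag)
                report["stages"][f"analysis_{tag}"] = stage_report

    report["warnings"] = sorted({str(w.message) for w in caught})
    (out / "manifest.json").write_text(json.dumps(report, indent=1))
    return report


def _analyze_variant(
    vts, parc, config: PipelineConfig, out: Path, tag: str
) -> dict:
    """Consistency, pair, and network analyses for one smoothing variant."""
    stage: dict = {}
    records = roi_consistencies(vts, parc)
    pd.DataFrame(
        {
            "roi_id": [r.roi_id for r in records],
            "size": [r.size for r in records],
            "phi": [r.phi for r in records],
        }
    ).to_csv(out / f"consistency_{tag}.tsv", sep="\t", index=False)
    defined = [r for r in records if r.defined]
    stage["mean_phi"] = float(np.mean([r.phi for r in defined])) if defined else None

    summary = within_between_distributions(
        vts,
        parc,
        pair_cap=config.pair_cap,
        seed=config.seed,
        n_permutations=config.n_permutations,
    )
    (out / f"distributions_{tag}.json").write_text(
        json.dumps(summary.to_dict(), indent=1)
    )
    stage["within_mean"] = summary.within_mean
    stage["between_mean"] = summary.between_mean
    stage["t"] = summary.t_statistic
    stage["p"] = summary.p_value

    size_table, r_size, p_size = consistency_vs_size(records, config.size_bins)
    size_table.to_csv(out / f"size_bins_{tag}.tsv", sep="\t", index=False)
    stage["r_size_phi"] = r_size
    stage["p_size_phi"] = p_size

    rts = roi_average(vts, parc)
    rts.to_tsv(out / f"roi_timeseries_{tag}.tsv")
    pair_table, pair_summary = build_pair_table(
        vts, rts, parc, records, pair_budget=config.pair_cap, seed=config.seed
    )
    pair_table.to_csv(out / f"pair_table_{tag}.tsv", sep="\t", index=False)
    (out / f"pair_summary_{tag}.json").write_text(json.dumps(pair_summary, indent=1))
    violations = identity_bound_check(pair_table, config.bound_tolerance)
    violations.to_csv(out / f"bound_violations_{tag}.tsv", sep="\t", index=False)
    stage["n_bound_violations"] = len(violations)
    relation_binned(
        pair_table, "c_vox", "c_roi", config.relation_bins
    ).to_csv(out / f"relation_cvox_croi_{tag}.tsv", sep="\t", index=False)

    A = build_adjacency(rts)
    cent_summary, cent_binned = consistency_centrality_relation(
        records, A, densities=config.density_grid, n_bins=config.relation_bins
    )
    cent_summary.to_csv(out / f"centrality_{tag}.tsv", sep="\t", index=False)
    cent_binned.to_csv(out / f"centrality_bins_{tag}.tsv", sep="\t", index=False)
    node_rows = []
    for d in config.density_grid:
        row = cent_summary[cent_summary["density"] == d]
        if len(row) and row["status"].iloc[0] != "skipped":
            from .network import degree_and_strength, threshold_to_density

            node_rows.append(degree_and_strength(threshold_to_density(A, d)))
    if node_rows:
        pd.concat(node_rows).to_csv(
            out / f"node_metrics_{tag}.tsv", sep="\t", index=False
        )
    return stage


def pool_consistency_tables(paths: list[str | Path]) -> pd.DataFrame:
    """Subject-average per-ROI consistency tables (one TSV per subject).

    Per-ROI consistencies are averaged across subjects (pair-value
    distributions, by contrast, are pooled raw where needed). Returns
    columns ``roi_id, size, mean_phi, sd_phi, n_subjects``.
    """
    frames = [pd.read_csv(p, sep="\t") for p in paths]
    if not frames:
        raise ValidationError("no tables to pool")
    allrows = pd.concat(frames)
    g = allrows.groupby("roi_id")
    return pd.DataFrame(
        {
            "roi_id": g.size().index,
            "size": g["size"].first().to_numpy(),
            "mean_phi": g["phi"].mean().to_numpy(),
            "sd_phi": g["phi"].std(ddof=1).to_numpy(),
            "n_subjects": g["phi"].count().to_numpy(),
        }
    ).reset_index(drop=True)
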