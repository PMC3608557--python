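"""End-to-end orchestration: preprocess → classify → skeletonize → dispersion → cohort.

One :func:`run_pipeline` call takes a cohort manifest (sample id,
treatment, stack) and produces tidy per-sample/per-class metrics plus the
cohort significance summary. Stage order is fixed — classification is
defined on filled vessel maps, so the fill step cannot be skipped — and
every parameter of a run is serialized next to its outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .caliber import BIN_SETS, CaliberClassifier, CaliberResult
from .cohort import CohortSummary, SampleMetrics, build_significance_table, percent_volume
from .dispersion import HaloDispersion
from .preprocess import IsotropicResampler, RenyiBinarizer, SliceContrastNormalizer
from .skeleton import classify_skeleton, compute_ratios, skeletonize_volume
from .stacks import BinaryVolume, GreyStack, read_stack, write_binary

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "preprocess_stack"]


@dataclass
class RunConfig:
    """All tunables of a pipeline run (defaults follow the standard protocol)."""

    lateral_pitch: float = 0.54  # µm per in-plane pixel
    axial_pitch: float = 1.0  # µm between slices
    bin_set: str = "set1"
    target_fraction: float = 0.90
    min_dynamic_range: int = 30
    min_particle_px: int = 4
    per_slice_threshold: bool = False
    cross_first: bool = True
    integer_norm: bool = False
    dispersion_on: str = "wall"  # "wall" or "skeleton"
    interpolation_order: int = 1
    save_volumes: bool = False
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.bin_set not in BIN_SETS:
            raise ValueError(f"unknown bin set {self.bin_set!r}; choose from {sorted(BIN_SETS)}")
        if self.dispersion_on not in ("wall", "skeleton"):
            raise ValueError("dispersion_on must be 'wall' or 'skeleton'")


@dataclass
class PipelineResult:
    metrics: pd.DataFrame  # sample × class: v_pct, nhv, wall, skeleton, lumen, ratios
    curves: pd.DataFrame  # full fill curves for audit
    summary: CohortSummary | None  # None for single-treatment runs
    config: RunConfig
    caliber_results: dict[str, CaliberResult] = field(repr=False, default_factory=dict)


def preprocess_stack(stack: GreyStack, config: RunConfig) -> BinaryVolume:
    """Isotropic resampling, gated slice contrast, Rényi binarization."""
    iso = IsotropicResampler(order=config.interpolation_order).fit_transform(stack)
    enh = SliceContrastNormalizer(config.min_dynamic_range).fit_transform(iso)
    return RenyiBinarizer(per_slice=config.per_slice_threshold).fit(enh).transform(enh)


def _load(entry, config: RunConfig) -> GreyStack:
    if isinstance(entry, GreyStack):
        return entry
    path = Path(entry)
    if not path.exists():
        raise FileNotFoundError(f"manifest names a missing stack: {path}")
    return read_stack(path, lateral_pitch=config.lateral_pitch, axial_pitch=config.axial_pitch)


def run_pipeline(
    config: RunConfig,
    samples: list[tuple[str, str, "GreyStack | str | Path"]],
) -> PipelineResult:
    """Run the full analysis on a cohort.

    ``samples`` lists ``(sample_id, treatment, stack_or_path)`` triples.
    Per-class dispersion is normalized over *all* per-class volumes in the
    run (the set being co-plotted), using the largest initial foreground
    count among them. Returns tidy metrics, fill curves, and — when at
    least two treatments are present — the pairwise significance summary.
    """
    if not samples:
        raise ValueError("empty cohort manifest")
    bins = BIN_SETS[config.bin_set]
    k = bins.n_classes
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "run_config.yaml").write_text(yaml.safe_dump(asdict(config)))

    classifier = CaliberClassifier(bin_set=config.bin_set, min_particle_px=config.min_particle_px)

    per_sample: dict[str, dict] = {}
    class_volumes_for_dispersion: list[BinaryVolume] = []
    for sample_id, treatment, entry in samples:
        try:
            stack = _load(entry, config)
            binary = preprocess_stack(stack, config)
            result = classifier.fit(binary).transform(binary)
            skel = skeletonize_volume(result.filled)
            skel_counts, skel_unclassified = classify_skeleton(skel, result.caliber_map)
            ratios = compute_ratios(result.volumes, skel_counts)
        except Exception as exc:  # noqa: BLE001 - re-tag with the failing sample
            raise RuntimeError(f"pipeline failed on sample {sample_id!r}: {exc}") from exc
        if config.dispersion_on == "wall":
            class_vols = result.wall_masks
        else:
            labels = result.caliber_map.labels
            class_vols = [
                BinaryVolume(skel.voxels & (labels == c + 1), pitch=binary.pitch)
                for c in range(k)
            ]
        per_sample[sample_id] = {
            "treatment": treatment,
            "result": result,
            "skel_counts": skel_counts,
            "skel_unclassified": skel_unclassified,
            "ratios": ratios,
            "class_vols": class_vols,
        }
        class_volumes_for_dispersion.extend(class_vols)
        if outdir and config.save_volumes:
            for c, wm in enumerate(result.wall_masks, start=1):
                write_binary(wm, outdir / f"{sample_id}_class{c}.tif")

    disp = HaloDispersion(
        target_fraction=config.target_fraction,
        cross_first=config.cross_first,
        integer_norm=config.integer_norm,
    ).fit(class_volumes_for_dispersion)

    rows = []
    curve_frames = []
    cohorts: dict[str, list[SampleMetrics]] = {}
    for sample_id, data in per_sample.items():
        results = disp.transform(data["class_vols"])
        v_pct = np.array([percent_volume(v) for v in data["class_vols"]])
        nhv = np.array([r.nhv for r in results])
        vols = data["result"].volumes
        for c, r in enumerate(results, start=1):
            curve_frames.append(r.curve.to_frame(sample=sample_id, label=str(c)))
            rows.append(
                {
                    "sample": sample_id,
                    "treatment": data["treatment"],
                    "class": c,
                    "label_um2": bins.labels()[c - 1],
                    "initial_count": r.initial_count,
                    "v_pct": v_pct[c - 1],
                    "hv": r.hv,
                    "norm_cycles": r.norm_cycles,
                    "nhv": r.nhv,
                    "filled": int(vols.filled_counts[c - 1]),
                    "wall": int(vols.wall_counts[c - 1]),
                    "lumen": int(vols.lumen_counts[c - 1]),
                    "skeleton": int(data["skel_counts"][c - 1]),
                    "staining_per_length": data["ratios"].staining_per_length[c - 1],
                    "lumen_fraction": data["ratios"].lumen_fraction[c - 1],
                }
            )
        cohorts.setdefault(data["treatment"], []).append(
            SampleMetrics(
                sample=sample_id,
                treatment=data["treatment"],
                v_pct=v_pct,
                nhv=nhv,
                wall_counts=vols.wall_counts,
                skeleton_counts=data["skel_counts"],
                lumen_counts=vols.lumen_counts,
            )
        )

    metrics = pd.DataFrame(rows)
    curves = pd.concat(curve_frames, ignore_index=True)
    summary = build_significance_table(cohorts) if len(cohorts) >= 2 else None

    if outdir:
        metrics.to_csv(outdir / "metrics.csv", index=False)
        curves.to_csv(outdir / "fill_curves.csv", index=False)
        if summary is not None:
            summary.medians.to_csv(outdir / "cohort_medians.csv", index=False)
            summary.pairwise.to_csv(outdir / "significance.csv", index=False)
            summary.fits.to_csv(outdir / "quadratic_fits.csv", index=False)

    return PipelineResult(
        metrics=metrics,
        curves=curves,
        summary=summary,
        config=config,
        caliber_results={s: d["result"] for s, d in per_sample.items()},
    )
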