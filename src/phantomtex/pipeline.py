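"""End-to-end orchestration: simulate/read -> preprocess -> extract -> test.

The default simulated study mirrors the four acquisition assessments of the
phantom experiment, with the published slice counts per group:

* magnet strength: 1.5 T (n=80) vs 3 T (n=61), platform A, 30 deg, NEX 1,
  256 x 192 matrix;
* flip angle: 2, 5, 10, 15, 20, 25 deg (n=36 each) and 30 deg (n=44) on
  platform B at 1.5 T;
* NEX: 1 (n=36) vs 4 (n=44), platform B, 30 deg, 256 x 160 matrix;
* platform: A (n=83) vs B (n=36), 1.5 T, 30 deg, NEX 1, 256 x 160 matrix.

Each series gets one automatic whole-phantom contour (from its first slice),
every slice is partial-volume corrected and globally normalized, the 41
features are extracted per slice, and each contrast is tested with its own
Benjamini-Hochberg family.  A run log records every parameter so a run is
reproducible from its log.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Hashable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .dicom_io import auto_mask, load_mask, read_series
from .preprocess import NormalizationParams, normalize_global, partial_volume_correct
from .sensitivity_stats import ComparisonResult, results_to_frame, run_contrast
from .synth_phantom import NoiseModel, PhantomConfig, simulate_series
from .texture_features import EXTRA_NAMES, FEATURE_NAMES, FeatureConfig, extract_all
from .types import AcquisitionParams, ImageSlice, ROIMask

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "default_study",
    "extract_features_table",
    "run_pipeline",
    "render_table",
]

#: (contrast, level, acquisition overrides, slice count) for the default study.
_STUDY_DESIGN: List[Tuple[str, Hashable, Dict, int]] = (
    [("field_strength", fs, dict(field_strength=fs, platform="A"), n)
     for fs, n in ((1.5, 80), (3.0, 61))]
    + [("flip_angle", fa, dict(flip_angle=float(fa), platform="B"), 44 if fa == 30 else 36)
       for fa in (2, 5, 10, 15, 20, 25, 30)]
    + [("nex", nx, dict(nex=nx, platform="B"), n) for nx, n in ((1, 36), (4, 44))]
    + [("platform", pf, dict(platform=pf), n) for pf, n in (("A", 83), ("B", 36))]
)

#: Contrasts whose series use the DCE matrix rather than the T1 one.
_DCE_CONTRASTS = ("nex", "platform")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and series."""


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    mode: str = "simulate"  # "simulate" | "dicom_dir"
    dicom_dir: Optional[str] = None
    mask_path: Optional[str] = None
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    norm: NormalizationParams = field(default_factory=NormalizationParams)
    n_gray_levels: int = 256
    contrasts: Tuple[str, ...] = ("field_strength", "flip_angle", "nex", "platform")
    alpha: float = 0.05
    output_dir: str = "phantomtex_out"
    seed: int = 0
    matrix_t1: Tuple[int, int] = (256, 192)
    matrix_dce: Tuple[int, int] = (256, 160)
    group_size_scale: float = 1.0  # shrink group sizes for quick runs

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.mode not in ("simulate", "dicom_dir"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "dicom_dir" and not self.dicom_dir:
            raise ValueError("dicom_dir mode requires a directory")

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["phantom"]["field_of_view"] = list(self.phantom.field_of_view)
        return d

    @classmethod
    def from_dict(cls, data: Dict) -> "PipelineConfig":
        data = dict(data)
        for key, typ in (("phantom", PhantomConfig), ("noise", NoiseModel),
                         ("norm", NormalizationParams)):
            if key in data and isinstance(data[key], dict):
                data[key] = typ(**data[key])
        for key in ("contrasts", "matrix_t1", "matrix_dce"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        if "phantom" in data and isinstance(data["phantom"], PhantomConfig):
            fov = data["phantom"].field_of_view
            data["phantom"].field_of_view = tuple(fov)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def default_study(
    config: PipelineConfig,
) -> List[Tuple[str, Hashable, AcquisitionParams, int]]:
    """Expand the study design into per-series acquisition parameters."""
    study = []
    for contrast, level, overrides, n in _STUDY_DESIGN:
        if contrast not in config.contrasts:
            continue
        matrix = config.matrix_dce if contrast in _DCE_CONTRASTS else config.matrix_t1
        n_slices = max(2, int(round(n * config.group_size_scale)))
        params = AcquisitionParams(matrix=matrix, n_slices=n_slices, **overrides)
        study.append((contrast, level, params, n_slices))
    return study


def _slice_features(
    slice_: ImageSlice,
    mask: ROIMask,
    norm: NormalizationParams,
    fconfig: FeatureConfig,
    apply_pvc: bool = True,
) -> Dict[str, float]:
    corrected = partial_volume_correct(slice_, mask) if apply_pvc else mask
    normalized = normalize_global(slice_.pixels, norm)
    return extract_all(
        ImageSlice(
            pixels=normalized,
            pixel_spacing=slice_.pixel_spacing,
            params=slice_.params,
            series_id=slice_.series_id,
            instance_index=slice_.instance_index,
        ),
        corrected,
        fconfig,
    )


def extract_features_table(
    slices: Sequence[ImageSlice],
    mask: Optional[ROIMask],
    config: PipelineConfig,
    extra_columns: Optional[Dict[str, Hashable]] = None,
    apply_pvc: bool = True,
) -> pd.DataFrame:
    """Preprocess and extract features for a series; one row per slice.

    ``mask=None`` derives one automatic contour from the first slice and
    reuses it for the whole series (one mask per series).  With
    ``apply_pvc=False`` the given mask is treated as already
    partial-volume corrected and used verbatim.
    """
    if not slices:
        raise ValueError("no slices to extract")
    series_mask = mask if mask is not None else auto_mask(slices[0])
    fconfig = FeatureConfig(n_gray_levels=config.n_gray_levels)
    rows = []
    for s in slices:
        values = _slice_features(s, series_mask, config.norm, fconfig, apply_pvc)
        values["series_id"] = s.series_id
        values["instance_index"] = s.instance_index
        if extra_columns:
            values.update(extra_columns)
        rows.append(values)
    return pd.DataFrame(rows)


def _simulate_contrast_table(
    config: PipelineConfig, contrast: str, seeds: Dict[Tuple[str, Hashable], int]
) -> pd.DataFrame:
    """Simulate all series of one contrast and extract their features.

    One analysis mask is shared across every series of the contrast (contour
    plus partial-volume correction computed once, on the first slice of the
    first group): the compared groups must differ in acquisition physics, not
    in segmentation, so mask derivation is deliberately kept out of the
    between-group variance.
    """
    tables = []
    shared_mask: Optional[ROIMask] = None
    for c, level, params, _n in default_study(config):
        if c != contrast:
            continue
        noise = replace(config.noise, rng_seed=seeds[(c, level)])
        slices = simulate_series(config.phantom, params, noise)
        if shared_mask is None:
            shared_mask = partial_volume_correct(slices[0], auto_mask(slices[0]))
        tables.append(
            extract_features_table(
                slices, shared_mask, config,
                extra_columns={contrast: level}, apply_pvc=False,
            )
        )
    return pd.concat(tables, ignore_index=True)


def _dicom_contrast_tables(config: PipelineConfig) -> Dict[str, pd.DataFrame]:
    root = Path(config.dicom_dir)
    if not root.is_dir():
        raise PipelineError(f"stage=read: input directory not found: {root}")
    series_dirs = sorted(p for p in root.iterdir() if p.is_dir()) or [root]
    tables = []
    for sdir in series_dirs:
        slices = read_series(sdir)
        mask = (
            load_mask(config.mask_path, slices[0].pixels.shape)
            if config.mask_path
            else None
        )
        table = extract_features_table(slices, mask, config)
        for attr in ("field_strength", "flip_angle", "nex", "platform"):
            table[attr] = [getattr(s.params, attr) for s in slices]
        tables.append(table)
    all_rows = pd.concat(tables, ignore_index=True)
    return {contrast: all_rows for contrast in config.contrasts}


def run_pipeline(config: PipelineConfig) -> Dict[str, List[ComparisonResult]]:
    """Run the full study and write feature tables, result tables, and a log.

    Returns the per-contrast comparison results; files are written under
    ``config.output_dir``: features_<contrast>.csv, results_<contrast>.csv,
    results_<contrast>.md, and run_log.yaml.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.mode == "simulate":
        study = default_study(config)
        children = np.random.SeedSequence(config.seed).spawn(len(study))
        seeds = {
            (c, level): int(child.generate_state(1, np.uint32)[0])
            for (c, level, _p, _n), child in zip(study, children)
        }
        contrast_tables = {}
        for contrast in config.contrasts:
            try:
                contrast_tables[contrast] = _simulate_contrast_table(
                    config, contrast, seeds
                )
            except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
                raise PipelineError(f"stage=simulate/extract contrast={contrast}: {exc}") from exc
    else:
        contrast_tables = _dicom_contrast_tables(config)

    all_results: Dict[str, List[ComparisonResult]] = {}
    for contrast, table in contrast_tables.items():
        table.to_csv(outdir / f"features_{contrast}.csv", index=False)
        try:
            results = run_contrast(table, contrast, alpha=config.alpha)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage=compare contrast={contrast}: {exc}") from exc
        all_results[contrast] = results
        (outdir / f"results_{contrast}.csv").write_text(render_table(results, "csv"))
        (outdir / f"results_{contrast}.md").write_text(render_table(results, "markdown"))

    log = {
        "config": config.to_dict(),
        "feature_names": FEATURE_NAMES,
        "extra_names": EXTRA_NAMES,
        "provenance": {
            "t_test": "pooled-variance Student, two-tailed",
            "multi_group_test": "one-way ANOVA (flip-angle contrast)",
            "fdr": "Benjamini-Hochberg step-up, one family per contrast",
            "gray_levels": config.n_gray_levels,
            "laws_kernels": "3x3 outer products of L3/E3/S3",
        },
    }
    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)
    return all_results


def render_table(results: Sequence[ComparisonResult], style: str = "markdown") -> str:
    """Format comparison results as CSV or Markdown (significant rows starred)."""
    if not results:
        raise ValueError("no results to render")
    frame = results_to_frame(results)
    if style == "csv":
        return frame.to_csv(index=False)
    if style == "markdown":
        show = frame.copy()
        for col in show.columns:
            if show[col].dtype.kind == "f":
                show[col] = show[col].map(lambda v: f"{v:.4g}")
        show["significant"] = ["*" if s else "" for s in frame["significant"]]
        header = "| " + " | ".join(show.columns) + " |"
        sep = "|" + "|".join("---" for _ in show.columns) + "|"
        body = "\n".join("| " + " | ".join(map(str, row)) + " |"
                         for row in show.itertuples(index=False))
        return "\n".join([header, sep, body]) + "\n"
    raise ValueError(f"unknown style {style!r}")
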