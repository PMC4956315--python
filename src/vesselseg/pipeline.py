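"""End-to-end segmentation pipeline and batch harness.

Stage order: green channel -> CLAHE -> modified top-hat (dark-vessel
polarity, which inverts the residue) -> Hessian vesselness at the thin
and wide scales -> global Otsu on the wide image -> fusion of the
wide-vessel mask into the thin image -> two-valued region threshold map
around a second Otsu split of the fused image -> classification -> area
filter.  Each stage's output can be captured in a trace for inspection;
errors are re-raised tagged with the stage that produced them.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from vesselseg import enhancement, hessian, io, postprocess, thresholding
from vesselseg.evaluation import (
    MetricsRecord,
    aggregate,
    compute_metrics,
    confusion_counts,
    records_to_frame,
)

__all__ = ["PipelineConfig", "StageError", "segment", "run_dataset", "STAGES"]

logger = logging.getLogger("vesselseg")

STAGES = (
    "green",
    "clahe",
    "tophat",
    "thin_enhanced",
    "wide_enhanced",
    "wide_binary",
    "fused",
    "local_binary",
    "final",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters, serializable to one flat YAML file."""

    clahe_clip_limit: float = 0.01
    clahe_tile_grid: tuple[int, int] = (8, 8)
    tophat_radius: int = 8
    sigma_thin: float = 1.0
    sigma_wide: float = 2.5
    histogram_levels: int = 256
    region_offset: float = 0.05
    neighborhood_radius: int = 8
    min_component_keep: int = 31
    connectivity: int = 8
    eval_region: str = "fov"
    save_intermediates: bool = False

    def __post_init__(self) -> None:
        if self.eval_region not in ("fov", "full"):
            raise ValueError("eval_region must be 'fov' or 'full'")
        if self.min_component_keep < 1:
            raise ValueError("min_component_keep must be >= 1")
        # delegate detailed validation to the stage parameter types
        self.clahe_tile_grid = tuple(self.clahe_tile_grid)  # type: ignore[assignment]
        enhancement.ClaheParams(self.clahe_clip_limit, self.clahe_tile_grid)
        hessian.ScalePair(self.sigma_thin, self.sigma_wide)

    def to_yaml(self, path: str | os.PathLike) -> None:
        data = asdict(self)
        data["clahe_tile_grid"] = list(self.clahe_tile_grid)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "clahe_tile_grid" in data:
            data["clahe_tile_grid"] = tuple(data["clahe_tile_grid"])
        return cls(**data)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(name, exc) from exc
            logger.info("stage %s: done", name)
            return out

        return wrapped

    return deco


def segment(
    img: np.ndarray,
    fov: np.ndarray | None = None,
    cfg: PipelineConfig | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray] | None]:
    """Segment the vasculature of a fundus image.

    Parameters
    ----------
    img
        ``(H, W, 3)`` color fundus image in [0,1], or an ``(H, W)``
        grayscale image already representing the green band.
    fov
        Optional binary field-of-view mask; estimated from the image
        luminance when omitted.
    cfg
        Pipeline parameters; defaults throughout when omitted.

    Returns
    -------
    (mask, trace)
        The final binary vessel mask, and a dict of the nine named stage
        images when ``cfg.save_intermediates`` is set (else ``None``).
    """
    cfg = cfg or PipelineConfig()
    img = np.asarray(img, dtype=np.float64)

    green = (
        _stage("green")(io.extract_green)(img) if img.ndim == 3 else img
    )
    if fov is None:
        fov = io.estimate_fov_mask(img)
    fov = np.asarray(fov).astype(np.uint8)
    if fov.shape != green.shape:
        raise StageError("green", ValueError("fov shape does not match image"))

    params = enhancement.ClaheParams(cfg.clahe_clip_limit, cfg.clahe_tile_grid)
    equalized = _stage("clahe")(enhancement.clahe)(green, params)

    se = enhancement.StructuringElement(cfg.tophat_radius)
    tophat = _stage("tophat")(
        lambda im: enhancement.modified_top_hat(im, se, se, polarity="dark")
    )(equalized)

    thin = _stage("thin_enhanced")(hessian.enhance_at_scale)(
        tophat, cfg.sigma_thin, fov=fov
    )
    wide = _stage("wide_enhanced")(hessian.enhance_at_scale)(
        tophat, cfg.sigma_wide, fov=fov
    )

    def _wide_binary(wide_img):
        hist = thresholding.build_histogram(wide_img, fov=fov, levels=cfg.histogram_levels)
        t_star, _ = thresholding.otsu_threshold(hist)
        t_global = thresholding.level_to_intensity(t_star, cfg.histogram_levels)
        return thresholding.apply_threshold(wide_img, t_global, fov=fov), t_global

    wide_mask, t_global = _stage("wide_binary")(_wide_binary)(wide)

    fused = _stage("fused")(thresholding.fuse_wide_into_thin)(thin, wide_mask)

    def _local_binary(fused_img):
        # second Otsu pass: the local thresholds modulate the fused image's
        # own global split, not the wide image's
        hist = thresholding.build_histogram(
            fused_img, fov=fov, levels=cfg.histogram_levels
        )
        t_fused_star, _ = thresholding.otsu_threshold(hist)
        t_fused = thresholding.level_to_intensity(t_fused_star, cfg.histogram_levels)
        tmap = thresholding.region_threshold_map(
            t_fused, wide_mask, cfg.region_offset, cfg.neighborhood_radius
        )
        mask = thresholding.classify_pixels(fused_img, tmap, wide_mask)
        return (mask * fov).astype(np.uint8)

    local = _stage("local_binary")(_local_binary)(fused)

    final = _stage("final")(postprocess.area_filter)(
        local, cfg.min_component_keep - 1, cfg.connectivity
    )

    trace = None
    if cfg.save_intermediates:
        trace = {
            "green": green,
            "clahe": equalized,
            "tophat": tophat,
            "thin_enhanced": thin,
            "wide_enhanced": wide,
            "wide_binary": wide_mask,
            "fused": fused,
            "local_binary": local,
            "final": final,
        }
    return final, trace


_IMAGE_EXTS = (".png", ".tif", ".tiff", ".ppm", ".gif", ".jpg", ".jpeg")


def _find_by_stem(directory: Path, stem: str) -> Path | None:
    for ext in _IMAGE_EXTS:
        cand = directory / f"{stem}{ext}"
        if cand.exists():
            return cand
    matches = sorted(directory.glob(f"{stem}.*"))
    return matches[0] if matches else None


def run_dataset(
    image_dir: str | os.PathLike,
    truth_dir: str | os.PathLike | None = None,
    fov_dir: str | os.PathLike | None = None,
    cfg: PipelineConfig | None = None,
    out_dir: str | os.PathLike = "out",
):
    """Segment every image in a DRIVE/STARE-layout folder.

    Images are paired with ground-truth and FOV files by filename stem.
    Writes one mask PNG per image into *out_dir*, and — when a truth
    directory is given — per-image metric rows plus an unweighted average
    row as ``metrics.csv`` and ``metrics.json``.  Returns the metrics as
    a DataFrame (empty when no truths were found).
    """
    cfg = cfg or PipelineConfig()
    image_dir = Path(image_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = sorted(
        p for p in image_dir.iterdir()
        if p.suffix.lower() in _IMAGE_EXTS
    )
    if not files:
        raise FileNotFoundError(f"no images found in {image_dir}")

    records: list[MetricsRecord] = []
    for path in files:
        img = io.read_image(path)
        fov = None
        if fov_dir is not None:
            fov_path = _find_by_stem(Path(fov_dir), path.stem)
            if fov_path is not None:
                fov = (io.read_image(fov_path) > 0.5).astype(np.uint8)
        if fov is None:
            fov = io.estimate_fov_mask(img)
        mask, _ = segment(img, fov=fov, cfg=cfg)
        io.write_binary(mask, out_dir / f"{path.stem}_mask.png")

        if truth_dir is not None:
            truth_path = _find_by_stem(Path(truth_dir), path.stem)
            if truth_path is None:
                logger.warning("no ground truth for %s; skipping metrics", path.stem)
                continue
            truth = (io.read_image(truth_path) > 0.5).astype(np.uint8)
            counts = confusion_counts(
                mask, truth, fov=fov if cfg.eval_region == "fov" else None
            )
            records.append(
                compute_metrics(counts, image_id=path.stem, eval_region=cfg.eval_region)
            )

    if records:
        table = records_to_frame(records + [aggregate(records)])
        table.to_csv(out_dir / "metrics.csv", index=False)
        (out_dir / "metrics.json").write_text(
            json.dumps(table.to_dict(orient="records"), indent=2)
        )
        return table
    return records_to_frame([])
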