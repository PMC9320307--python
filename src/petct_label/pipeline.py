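"""Series-level orchestration: enhance -> register -> fuse -> segment -> export.

PET/CT partners are discovered by the shared numeric suffix of their file
names after natural sort (``pet_3.png`` pairs with ``ct_3.png``); an
optional ``points_<index>.csv`` supplies landmark pairs for the
least-squares refinement on top of the frame pre-alignment.  Clicks are
supplied up front as ``(image index, x, y, label)`` rows so a run is a
pure, repeatable function of its inputs.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .enhance import EnhanceConfig, enhance_pet
from .errors import PairingError, ValidationError
from .fuse import FusionWeights, WaveletConfig, fuse_images, pseudocolor
from .image_io import (GrayImage, LabelRecord, export_labels,
                       read_control_points, read_gray_image, write_gray_image,
                       write_rgb_image)
from .lesion import (GrowConfig, bounding_rect, map_region_to_ct, refine_seed,
                     region_grow, trace_boundary)
from .register import (AffineParams, apply_affine, compute_residuals,
                       fit_affine_ls, frame_prealign, compose)

log = logging.getLogger("petct_label")

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".dcm", ".dicom", ".ima")
_INDEX_RE = re.compile(r"(\d+)$")

DEFAULT_SWEEP = ((30, 70), (40, 60), (50, 50), (60, 40), (70, 30))


@dataclass
class PipelineConfig:
    pet_dir: str = "."
    ct_dir: str = "."
    out_dir: str = "out"
    points_dir: str | None = None
    enhance: EnhanceConfig = field(default_factory=EnhanceConfig)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    weights: FusionWeights = field(default_factory=FusionWeights)
    grow: GrowConfig = field(default_factory=GrowConfig)
    prealign: bool = True
    keep_intermediates: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("pet_dir", "ct_dir", "out_dir", "points_dir",
                    "prealign", "keep_intermediates", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "enhance" in raw:
            enh = dict(raw["enhance"])
            if "target_size" in enh:
                enh["target_size"] = tuple(enh["target_size"])
            kwargs["enhance"] = EnhanceConfig(**enh)
        if "wavelet" in raw:
            kwargs["wavelet"] = WaveletConfig(**raw["wavelet"])
        if "weights" in raw:
            kwargs["weights"] = FusionWeights(**raw["weights"])
        if "grow" in raw:
            kwargs["grow"] = GrowConfig(**raw["grow"])
        return cls(**kwargs)


def _index_of(path: Path) -> int | None:
    m = _INDEX_RE.search(path.stem)
    return int(m.group(1)) if m else None


def discover_pairs(pet_dir, ct_dir) -> list[tuple[int, Path, Path]]:
    """Pair PET_i with CT_i by shared trailing number, natural order."""

    def scan(d):
        out = {}
        for p in sorted(Path(d).iterdir()):
            if p.suffix.lower() in _IMAGE_SUFFIXES:
                idx = _index_of(p)
                if idx is not None:
                    out[idx] = p
        return out

    pets, cts = scan(pet_dir), scan(ct_dir)
    pairs = []
    for idx in sorted(set(pets) | set(cts)):
        if idx not in pets:
            raise PairingError(f"CT index {idx} has no PET partner")
        if idx not in cts:
            raise PairingError(f"PET index {idx} has no CT partner")
        pairs.append((idx, pets[idx], cts[idx]))
    return pairs


@dataclass
class PipelineResult:
    records: list
    labels_path: Path
    fused_paths: dict  # index -> Path of the fused grayscale PNG
    transforms: dict   # index -> AffineParams (PET -> CT)


def _register_pair(enhanced: GrayImage, ct: GrayImage,
                   points_path: Path | None,
                   prealign: bool) -> AffineParams:
    pre = frame_prealign(enhanced, ct) if prealign else AffineParams.identity()
    if points_path is not None and points_path.is_file():
        points = read_control_points(points_path)
        from .image_io import ControlPointSet
        moved = ControlPointSet(pre.apply(points.source), points.target)
        return compose(fit_affine_ls(moved), pre)
    return pre


def run_pipeline(cfg: PipelineConfig, clicks=()) -> PipelineResult:
    """Run the full labeling pipeline over a numbered series.

    ``clicks`` is an iterable of ``(image_index, x, y, label_text)``; each
    click yields one label record grown on the registered enhanced PET.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = discover_pairs(cfg.pet_dir, cfg.ct_dir)
    clicks = list(clicks)
    known = {idx for idx, _, _ in pairs}
    for c in clicks:
        if c[0] not in known:
            log.warning("click %s refers to an image index with no pair; "
                        "skipped", c)

    records: list[LabelRecord] = []
    fused_paths: dict[int, Path] = {}
    transforms: dict[int, AffineParams] = {}
    run_log = {
        "enhance": {"target_size": list(cfg.enhance.target_size),
                    "pet_min": cfg.enhance.pet_min},
        "wavelet": vars(cfg.wavelet).copy(),
        "weights": {"pet_pct": cfg.weights.pet_pct,
                    "ct_pct": cfg.weights.ct_pct},
        "grow": vars(cfg.grow).copy(),
        "prealign": cfg.prealign,
        "pairs": [],
    }

    for idx, pet_path, ct_path in pairs:
        log.info("pair %d: %s / %s", idx, pet_path.name, ct_path.name)
        pet = read_gray_image(pet_path, "PET")
        ct = read_gray_image(ct_path, "CT")
        enh_cfg = EnhanceConfig(target_size=(ct.width, ct.height),
                                pet_min=cfg.enhance.pet_min)
        enhanced = enhance_pet(pet, enh_cfg)
        points_path = (Path(cfg.points_dir) / f"points_{idx}.csv"
                       if cfg.points_dir else None)
        transform = _register_pair(enhanced, ct, points_path, cfg.prealign)
        transforms[idx] = transform
        registered = apply_affine(enhanced, transform, (ct.width, ct.height))
        fused = fuse_images(registered, ct, cfg.weights, cfg.wavelet)

        fused_path = out_dir / f"fused_{idx}.png"
        write_gray_image(fused, fused_path)
        write_rgb_image(pseudocolor(fused), out_dir / f"fused_{idx}_color.png")
        fused_paths[idx] = fused_path
        if cfg.keep_intermediates:
            write_gray_image(enhanced, out_dir / f"enhanced_{idx}.png")
            write_gray_image(registered, out_dir / f"registered_{idx}.png")

        lesion_id = 0
        for click in clicks:
            if click[0] != idx:
                continue
            _, x, y, label_text = click
            lesion_id += 1
            seed, value_min = refine_seed(registered, (int(x), int(y)),
                                          cfg.grow)
            region = region_grow(registered, seed, value_min, cfg.grow)
            region_ct = map_region_to_ct(region, AffineParams.identity())
            records.append(LabelRecord(
                image_id=ct_path.stem,
                lesion_id=lesion_id,
                polygon=list(region_ct.boundary),
                bbox=bounding_rect(region_ct),
                label_text=str(label_text),
                seed=region_ct.seed,
                suv_class="unknown",
            ))
        run_log["pairs"].append({
            "index": idx,
            "pet": str(pet_path), "ct": str(ct_path),
            "transform": list(transform.as_tuple()),
            "n_clicks": lesion_id,
        })

    labels_path = out_dir / "labels.json"
    export_labels(records, labels_path)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)
    return PipelineResult(records=records, labels_path=labels_path,
                          fused_paths=fused_paths, transforms=transforms)


def sweep_ratios(pet: GrayImage, ct: GrayImage, ratios=None,
                 cfg: WaveletConfig | None = None) -> list[tuple[FusionWeights, GrayImage]]:
    """Fuse one registered pair at each candidate PET:CT ratio (default
    30:70, 40:60, 50:50, 60:40, 70:30) for visual selection of the blend."""
    cfg = cfg or WaveletConfig()
    if ratios is None:
        ratios = [FusionWeights(a, b) for a, b in DEFAULT_SWEEP]
    else:
        ratios = [r if isinstance(r, FusionWeights) else FusionWeights(*r)
                  for r in ratios]
    return [(w, fuse_images(pet, ct, w, cfg)) for w in ratios]
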