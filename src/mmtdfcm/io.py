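"""Image reading/writing, run manifests, and the paired-comparison driver."""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, is_dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .engine import FcmConfig, SegmentationResult, init_centers, segment
from .metrics import MetricsReport, evaluate_result, reconstruction
from .synthetic import NoiseSpec, PhantomSpec, make_phantom

__all__ = [
    "RunManifest",
    "read_gray_image",
    "write_gray_image",
    "write_outputs",
    "compare_experiment",
]

logger = logging.getLogger(__name__)

_SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff"}


def read_gray_image(path) -> np.ndarray:
    """Read an 8-bit grayscale PNG/TIFF as a uint8 array.

    Multi-channel images are converted by luminance with a logged
    warning; bit depths above 8 are rejected.
    """
    p = Path(path)
    if not p.is_file():
        raise IOError(f"cannot read image: no such file {p}")
    try:
        img = Image.open(p)
    except Exception as exc:  # pragma: no cover - PIL error text varies
        raise IOError(f"cannot read image {p}: {exc}") from exc
    if img.mode in {"I", "I;16", "I;16B", "I;16L", "F"}:
        raise ValueError(f"{p}: bit depth > 8 is not supported")
    if img.mode != "L":
        logger.warning("%s: %s image converted to grayscale by luminance", p, img.mode)
        img = img.convert("L")
    return np.asarray(img, dtype=np.uint8)


def write_gray_image(path, image) -> Path:
    """Write a uint8 2-D array as grayscale PNG or TIFF (by suffix)."""
    p = Path(path)
    if p.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ValueError(f"unsupported image suffix {p.suffix!r} (use PNG or TIFF)")
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.dtype != np.uint8:
        raise ValueError("expected a 2-D uint8 array")
    p.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr, mode="L").save(p)
    return p


@dataclass
class RunManifest:
    """Everything needed to reproduce one run: input, config, noise, output.

    Exactly one of ``input_path`` / ``phantom`` must be set.  ``noise``
    may be a single :class:`NoiseSpec`, a list of them (one comparison
    condition each), or ``None``.
    """

    config: FcmConfig
    input_path: str | None = None
    phantom: PhantomSpec | None = None
    noise: object = None
    output_dir: str = "mmtdfcm_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.phantom is None):
            raise ValueError("exactly one of input_path / phantom must be given")

    def noise_specs(self) -> list[NoiseSpec]:
        if self.noise is None:
            return []
        if isinstance(self.noise, NoiseSpec):
            return [self.noise]
        return list(self.noise)

    def load_input(self):
        """Return (image, truth-labels-or-None)."""
        if self.phantom is not None:
            return make_phantom(self.phantom)
        return read_gray_image(self.input_path), None

    def to_dict(self) -> dict:
        def conv(v):
            if is_dataclass(v) and not isinstance(v, type):
                return {k: conv(x) for k, x in asdict(v).items()}
            if isinstance(v, (list, tuple)):
                return [conv(x) for x in v]
            if isinstance(v, Path):
                return str(v)
            return v

        return {
            "input_path": self.input_path,
            "phantom": conv(self.phantom),
            "config": conv(self.config),
            "noise": conv(self.noise),
            "output_dir": str(self.output_dir),
            "log_level": self.log_level,
        }


def write_outputs(
    result: SegmentationResult,
    report: MetricsReport,
    manifest: RunManifest,
    stem: str = "segmentation",
) -> dict:
    """Write label map, reconstruction, metrics, and manifest to disk.

    The label map is rendered with labels mapped to evenly spaced grays
    (0 .. 255) so it is viewable; the reconstruction replaces each pixel
    by its (rounded) cluster center.  Returns a dict of written paths.
    """
    outdir = Path(manifest.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    c = result.memberships.shape[0]
    spacing = 255.0 / (c - 1) if c > 1 else 0.0
    label_img = np.rint(result.labels * spacing).astype(np.uint8)
    paths = {
        "labels": write_gray_image(outdir / f"{stem}_labels.png", label_img),
        "reconstruction": write_gray_image(
            outdir / f"{stem}_reconstruction.png",
            reconstruction(result.labels, result.centers),
        ),
    }
    metrics_path = outdir / f"{stem}_metrics.yaml"
    payload = dict(report.to_dict())
    payload.update(
        n_iter=result.n_iter,
        converged=bool(result.converged),
        centers=[float(v) for v in result.centers],
    )
    metrics_path.write_text(yaml.safe_dump(payload, sort_keys=True))
    paths["metrics"] = metrics_path
    manifest_path = outdir / f"{stem}_manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest.to_dict(), sort_keys=True))
    paths["manifest"] = manifest_path
    return paths


def compare_experiment(manifest: RunManifest, peak: float | None = None) -> list[dict]:
    """Paired FCM vs MMTDFCM sweep over clean and noisy conditions.

    For each condition (the clean input plus one per noise spec) both
    variants are run from the SAME initial centers; every run yields one
    row with PSNR against the clean reference, vpc, vpe, and — when the
    input is a phantom with known truth — the misclassification rate.
    """
    from dataclasses import replace

    image, truth = manifest.load_input()
    conditions = [("clean", image)]
    for ns in manifest.noise_specs():
        tag = {"salt_pepper": "salt_pepper", "gaussian": "gaussian"}[ns.kind]
        conditions.append((f"{tag}_{ns.level:g}", ns.apply(image)))

    rows = []
    for name, cond_image in conditions:
        centers0 = init_centers(cond_image, manifest.config)
        for variant in ("fcm", "mmtdfcm"):
            cfg = replace(manifest.config, variant=variant)
            result = segment(cond_image, cfg, initial_centers=centers0)
            report = evaluate_result(result, reference=image, truth=truth, peak=peak)
            row = {"condition": name, "algorithm": variant}
            row.update(report.to_dict())
            row.update(n_iter=result.n_iter, converged=bool(result.converged))
            rows.append(row)
    return rows
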