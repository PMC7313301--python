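"""End-to-end orchestration: segment the CC, then parcellate it.

``run_pipeline`` chains normalization, anisotropic diffusion, PNN clustering
with automatic class-count selection, CC isolation, ROI-restricted SLIC,
and the superpixel + geometric parcellations, writing every stage artifact
plus a manifest (config, seed, per-file SHA-256) to the output directory.
Runs are deterministic given (input, config); re-running from a manifest's
config reproduces every artifact bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import cc_isolation, clustering, evaluation, image_io, parcellation, preprocess, slic

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline settings, validated before any computation.

    Keys mirror the per-module configuration (dotted names in YAML):
    ``adf.*`` diffusion, ``cluster.*`` classification and model selection,
    ``slic.*`` superpixels, ``parcel.*`` parcellation, ``eval.*`` metrics.
    ``adf.kappa`` is on the normalized [0, 1] intensity scale because the
    pipeline normalizes before diffusing.
    """

    adf_iterations: int = 10
    adf_kappa: float = 0.10
    adf_lambda: float = 0.25
    adf_conductance: str = "exponential"
    cluster_k_min: int = 2
    cluster_k_max: int = 5
    cluster_sigma: float | None = None
    slic_n_superpixels: int = 200
    slic_compactness: float = 0.5
    slic_iters: int = 10
    slic_intensity_mode: str = "absolute"
    slic_distance_mode: str = "standard"
    parcel_schemes: tuple[str, ...] = ("slic", "witelson", "hofer")
    flip_anterior: bool = False
    eval_roi_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        # Delegate validation to the module-level parameter types.
        preprocess.ADFParams(
            iterations=self.adf_iterations,
            kappa=self.adf_kappa,
            lam=self.adf_lambda,
            conductance=self.adf_conductance,
        )
        if not (2 <= self.cluster_k_min <= self.cluster_k_max <= 10):
            raise ValueError(
                f"cluster class-count range invalid: "
                f"[{self.cluster_k_min}, {self.cluster_k_max}]"
            )
        if self.cluster_sigma is not None and self.cluster_sigma <= 0:
            raise ValueError("cluster.sigma must be positive")
        slic.SlicParams(
            n_superpixels=self.slic_n_superpixels,
            compactness=self.slic_compactness,
            max_iters=self.slic_iters,
            intensity_mode=self.slic_intensity_mode,
            distance_mode=self.slic_distance_mode,
        )
        bad = set(self.parcel_schemes) - {"slic", "witelson", "hofer"}
        if bad or not self.parcel_schemes:
            raise ValueError(f"unknown parcellation schemes: {sorted(bad)}")

    # -- (de)serialization ---------------------------------------------------
    def to_dotted(self) -> dict:
        d = dataclasses.asdict(self)
        out = {}
        for key, val in d.items():
            dotted = key.replace("_", ".", 1) if key.split("_")[0] in (
                "adf", "cluster", "slic", "parcel", "eval"
            ) else key
            out[dotted] = list(val) if isinstance(val, tuple) else val
        return out

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        kwargs = {}
        fields = {f.name for f in dataclasses.fields(cls)}
        for key, val in mapping.items():
            name = key.replace(".", "_")
            if name not in fields:
                raise ValueError(f"unknown configuration key: {key}")
            if name == "parcel_schemes":
                val = tuple(val)
            kwargs[name] = val
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_scaled_gray(img: np.ndarray, path: Path) -> None:
    """Store a float image as 16-bit PNG (min-max scaled; for inspection)."""
    lo, hi = float(img.min()), float(img.max())
    span = hi - lo if hi > lo else 1.0
    image_io.write_label_map(
        np.round((img - lo) / span * 65535).astype(np.int64), path
    )


def run_pipeline(
    input_image,
    config: PipelineConfig | None = None,
    out_dir: Path | str | None = None,
    truth_parcels=None,
    slice_index: int | None = None,
) -> dict:
    """Run the full pipeline; returns stage results and writes artifacts.

    ``input_image`` may be a file path (PNG/TIFF/NIfTI) or a 2-D array.
    ``truth_parcels`` (optional) is a ground-truth five-parcel label map; if
    given, metric reports and the pairwise Dice table are produced.
    """
    config = config or PipelineConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def save_labels(name: str, labels: np.ndarray) -> None:
        if out is None:
            return
        path = out / f"{name}.png"
        image_io.write_label_map(np.asarray(labels, dtype=np.int64), path)
        artifacts[name] = path

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    if isinstance(input_image, (str, Path)):
        img = stage("read", image_io.read_gray, input_image, slice_index)
        input_desc = str(input_image)
    else:
        img = image_io.validate_gray(input_image)
        input_desc = "<array>"

    norm = stage("normalize", image_io.normalize_intensity, img)
    adf = stage(
        "adf",
        preprocess.anisotropic_diffuse,
        norm,
        preprocess.ADFParams(
            iterations=config.adf_iterations,
            kappa=config.adf_kappa,
            lam=config.adf_lambda,
            conductance=config.adf_conductance,
        ),
    )
    if out is not None:
        _write_scaled_gray(adf, out / "filtered.png")
        artifacts["filtered"] = out / "filtered.png"

    cmap = stage(
        "clustering",
        clustering.select_num_classes,
        adf,
        (config.cluster_k_min, config.cluster_k_max),
        config.seed,
        config.cluster_sigma,
    )
    save_labels("cluster_map", cmap.labels)

    cc = stage("cc_isolation", cc_isolation.isolate_cc, cmap, adf)
    save_labels("cc_mask", cc.mask.astype(np.int64))
    contour = stage("contour", cc_isolation.trace_contour, cc)
    if out is not None:
        path = out / "contour.csv"
        np.savetxt(path, contour.points, fmt="%d", delimiter=",", header="row,col")
        artifacts["contour"] = path

    sp = stage(
        "slic",
        slic.slic_segment,
        adf,
        slic.SlicParams(
            n_superpixels=min(config.slic_n_superpixels, cc.area),
            compactness=config.slic_compactness,
            max_iters=config.slic_iters,
            intensity_mode=config.slic_intensity_mode,
            distance_mode=config.slic_distance_mode,
        ),
        cc,
    )
    save_labels("superpixels", sp.labels)

    parcels: dict[str, parcellation.ParcelMap] = {}
    for scheme in config.parcel_schemes:
        if scheme == "slic":
            pm = stage(
                "parcellation",
                parcellation.slic_parcellate,
                sp,
                cc,
                config.flip_anterior,
            )
        else:
            gs = parcellation.WITELSON if scheme == "witelson" else parcellation.HOFER
            pm = stage(
                "parcellation", parcellation.geometric_parcellate, cc, gs,
                config.flip_anterior,
            )
        parcels[scheme] = pm
        save_labels(f"parcels_{scheme}", pm.labels)

    reports = {}
    pairwise = None
    if truth_parcels is not None:
        for scheme, pm in parcels.items():
            reports[scheme] = evaluation.metric_report(
                pm, truth_parcels, roi_only=config.eval_roi_only
            )
            if out is not None:
                path = out / f"metrics_{scheme}.csv"
                reports[scheme].to_csv(path)
                artifacts[f"metrics_{scheme}"] = path
        named = dict(parcels)
        named["truth"] = truth_parcels
        pairwise = evaluation.pairwise_dice_table(
            named, roi_only=config.eval_roi_only
        )
        if out is not None:
            path = out / "pairwise_dice.csv"
            pairwise.to_csv(path)
            artifacts["pairwise_dice"] = path

    manifest = None
    if out is not None:
        manifest = {
            "input": input_desc,
            "slice_index": slice_index,
            "seed": config.seed,
            "config": config.to_dotted(),
            "artifacts": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in artifacts.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "filtered": adf,
        "cluster_map": cmap,
        "cc_mask": cc,
        "contour": contour,
        "superpixels": sp,
        "parcels": parcels,
        "reports": reports,
        "pairwise_dice": pairwise,
        "manifest": manifest,
    }
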