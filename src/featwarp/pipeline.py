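"""End-to-end registration: detect → describe → match → filter → TPS.

Orchestrates the three stages of the method — gradient-based feature
detection on both images, SIFT-style descriptor association with the
κ-ratio test plus bidirectional filtering, and thin-plate-spline
interpolation of the matched control points into a dense displacement
field — as one deterministic call, logging the stage counts.

2-D inputs (single-slice images) are detected automatically and switch
the descriptor to its 32-component planar mode; mixing a 2-D and a 3-D
input is an error.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field

from .core_io import DisplacementField, VolumeImage
from .feature_detection import DetectionConfig, detect_feature_points
from .matching import (MatchConfig, MatchPair, bidirectional_filter,
                       match_forward, matches_to_landmarks)
from .sift_descriptor import compute_descriptors
from .tps import TPSModel, fit_tps, tps_to_field, warp_image

__all__ = ["PipelineConfig", "RegistrationResult", "RegistrationError",
           "run_registration"]

logger = logging.getLogger(__name__)


class RegistrationError(RuntimeError):
    """Raised when the pipeline cannot produce a transformation."""


@dataclass
class PipelineConfig:
    """All knobs of a registration run, serialisable to/from a dict."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    matching: MatchConfig = field(default_factory=MatchConfig)
    tps_kernel: str = "r2logr2"
    tps_ridge: float = 0.0
    direction: str = "backward"  # fit source=target landmarks (no-holes warp)
    hist_weight: str = "magnitude"
    normalize_descriptors: bool = False
    fill_value: float | None = None
    compute_field: bool = True
    compute_warped: bool = True

    def __post_init__(self) -> None:
        if self.direction not in ("backward", "forward"):
            raise ValueError("direction must be 'backward' or 'forward'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        det = doc.pop("detection", {})
        mat = doc.pop("matching", {})
        if isinstance(det.get("intensity_window"), list):
            det["intensity_window"] = tuple(det["intensity_window"])
        return cls(
            detection=DetectionConfig(**det),
            matching=MatchConfig(**mat),
            **doc,
        )


@dataclass
class RegistrationResult:
    """Field, warped template, surviving pairs, TPS model and run log."""

    field: DisplacementField | None
    warped: VolumeImage | None
    pairs: list[MatchPair]
    model: TPSModel
    log: dict


def run_registration(
    template: VolumeImage,
    target: VolumeImage,
    config: PipelineConfig | None = None,
) -> RegistrationResult:
    """Register the template onto the target image.

    Runs detection on both images, descriptor matching with bidirectional
    filtering, and a TPS fit of the surviving control points; by default
    the dense target→template displacement field and the backward-warped
    template are also produced.  Deterministic for identical inputs and
    config; every effective parameter is echoed in the run log.
    """
    if config is None:
        config = PipelineConfig()
    if template.is_2d != target.is_2d:
        raise RegistrationError(
            "cannot mix 2-D and 3-D inputs: template is "
            f"{'2-D' if template.is_2d else '3-D'} and target is "
            f"{'2-D' if target.is_2d else '3-D'}"
        )
    log: dict = {"config": config.to_dict(), "stages": {}}
    t0 = time.perf_counter()

    tpl_points = detect_feature_points(template, config.detection)
    tgt_points = detect_feature_points(target, config.detection)
    log["stages"]["detected_template"] = len(tpl_points)
    log["stages"]["detected_target"] = len(tgt_points)
    logger.info("detected %d template / %d target feature points",
                len(tpl_points), len(tgt_points))
    if not tpl_points or not tgt_points:
        raise RegistrationError(
            "no feature points detected; widen the intensity window or "
            "lower the saliency threshold"
        )

    kw = dict(weight=config.hist_weight, normalize=config.normalize_descriptors)
    tpl_desc = compute_descriptors(template, tpl_points, **kw)
    tgt_desc = compute_descriptors(target, tgt_points, **kw)

    forward = match_forward(tpl_desc, tgt_desc, config.matching)
    survivors = bidirectional_filter(forward, tpl_desc, tgt_desc, config.matching)
    log["stages"]["forward_matches"] = len(forward)
    log["stages"]["surviving_matches"] = len(survivors)
    logger.info("%d forward matches, %d survive bidirectional filtering",
                len(forward), len(survivors))

    dim = 2 if template.is_2d else 3
    if len(survivors) < dim + 1:
        raise RegistrationError(
            f"only {len(survivors)} control-point pairs survived but the TPS "
            f"needs at least {dim + 1}: relax the kappa threshold or lower "
            "the detection saliency threshold"
        )
    tpl_lm, tgt_lm = matches_to_landmarks(survivors)
    if config.direction == "backward":
        model = fit_tps(tgt_lm, tpl_lm, dim=dim, kernel=config.tps_kernel,
                        ridge=config.tps_ridge)
        grid = target
    else:
        model = fit_tps(tpl_lm, tgt_lm, dim=dim, kernel=config.tps_kernel,
                        ridge=config.tps_ridge)
        grid = template

    dvf = tps_to_field(model, grid) if config.compute_field else None
    warped = None
    if config.compute_warped:
        if dvf is None:
            raise RegistrationError("compute_warped requires compute_field")
        warped = warp_image(template, dvf, fill=config.fill_value)

    log["stages"]["n_control_points"] = len(survivors)
    log["elapsed_s"] = time.perf_counter() - t0
    return RegistrationResult(field=dvf, warped=warped, pairs=survivors,
                              model=model, log=log)
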