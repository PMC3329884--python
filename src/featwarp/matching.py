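"""Descriptor matching with the κ-ratio test and bidirectional filtering.

For every template feature point the descriptor difference S is computed
against every eligible target feature point; the two smallest values give
S₁ and S₂, and the pair is associated only when the ratio κ = S₁/S₂ falls
below a threshold (default 50%), which rejects ambiguous, unphysical
matches.  A bidirectional consistency pass then re-matches each associated
target point back into the template set and deletes every pair whose
reverse match does not return the original template point, leaving mutual
best matches only.

Candidates are the detected target feature points (not every voxel), which
keeps the search tractable and mirrors symmetric detection on both images.
Outputs are deterministic: ties for S₁/S₂ are broken by the smaller
lexicographic target voxel index, and the degenerate cases S₁ = 0 or
S₂ = 0 define κ = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core_io import LandmarkSet
from .feature_detection import FeaturePoint
from .sift_descriptor import SiftDescriptor

__all__ = ["MatchPair", "MatchConfig", "match_forward",
           "bidirectional_filter", "matches_to_landmarks"]

logger = logging.getLogger(__name__)

_CHUNK = 1024


@dataclass
class MatchPair:
    """An associated template/target pair with its matching diagnostics."""

    template_point: FeaturePoint
    target_point: FeaturePoint
    s1: float
    s2: float
    kappa: float
    template_idx: int  # position in the template descriptor list
    target_idx: int  # position in the target descriptor list

    def __post_init__(self) -> None:
        if self.s1 > self.s2 + 1e-12:
            raise ValueError(f"S1 ={self.s1} must be <= S2 ={self.s2}")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must be in [0, 1], got {self.kappa}")

    @property
    def displacement(self) -> np.ndarray:
        """Target position minus template position (mm)."""
        return np.asarray(self.target_point.position) - np.asarray(
            self.template_point.position
        )


@dataclass
class MatchConfig:
    """κ threshold (default 50%) and optional physical search radius (mm)."""

    kappa_threshold: float = 0.5
    search_radius: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.kappa_threshold <= 1.0:
            raise ValueError("kappa_threshold must be in (0, 1]")
        if self.search_radius is not None and self.search_radius <= 0:
            raise ValueError("search_radius must be positive when set")


def _stack(descs: list[SiftDescriptor], name: str):
    if not descs:
        raise ValueError(f"{name} descriptor list is empty")
    mode = descs[0].mode
    if any(d.mode != mode for d in descs):
        raise ValueError(f"{name} descriptors mix 2-D and 3-D modes")
    values = np.stack([d.values for d in descs])
    indices = np.asarray([d.point.index for d in descs], dtype=np.int64)
    positions = np.asarray([d.point.position for d in descs])
    return values, indices, positions, mode


def match_forward(
    template_desc: list[SiftDescriptor],
    target_desc: list[SiftDescriptor],
    config: MatchConfig | None = None,
) -> list[MatchPair]:
    """Associate template points to target points by the κ-ratio rule.

    Each template descriptor is compared against every eligible target
    descriptor (all of them, or those within ``search_radius`` of the
    template point).  A :class:`MatchPair` is emitted iff κ = S₁/S₂ is below
    the threshold; template points with fewer than two eligible candidates
    are skipped (with a logged count).  One-to-many matches onto a single
    target point are permitted here; injectivity is the bidirectional
    filter's job.
    """
    if config is None:
        config = MatchConfig()
    a_vals, a_idx, a_pos, a_mode = _stack(template_desc, "template")
    b_vals, b_idx, b_pos, b_mode = _stack(target_desc, "target")
    if a_mode != b_mode:
        raise ValueError(f"descriptor mode mismatch: {a_mode} vs {b_mode}")

    # sort targets lexicographically by voxel index so that argmin's
    # first-occurrence rule breaks S ties toward the smaller index
    order = np.lexsort((b_idx[:, 2], b_idx[:, 1], b_idx[:, 0]))
    b_vals = b_vals[order]
    b_pos_sorted = b_pos[order]

    pairs: list[MatchPair] = []
    n_skipped = 0
    rows = np.arange(0, len(a_vals))
    for start in range(0, len(a_vals), _CHUNK):
        sl = slice(start, min(start + _CHUNK, len(a_vals)))
        D = cdist(a_vals[sl], b_vals, metric="sqeuclidean")
        if config.search_radius is not None:
            geo = cdist(a_pos[sl], b_pos_sorted)
            D[geo > config.search_radius] = np.inf
        eligible = np.sum(np.isfinite(D), axis=1)
        for local, row in enumerate(rows[sl]):
            if eligible[local] < 2:
                n_skipped += 1
                continue
            d = D[local]
            i1 = int(np.argmin(d))
            s1 = float(d[i1])
            d = d.copy()
            d[i1] = np.inf
            i2 = int(np.argmin(d))
            s2 = float(d[i2])
            kappa = 0.0 if s1 == 0.0 else s1 / s2
            if kappa < config.kappa_threshold:
                tgt = int(order[i1])
                pairs.append(
                    MatchPair(
                        template_point=template_desc[row].point,
                        target_point=target_desc[tgt].point,
                        s1=s1,
                        s2=s2,
                        kappa=kappa,
                        template_idx=int(row),
                        target_idx=tgt,
                    )
                )
    if n_skipped:
        logger.info("match_forward: skipped %d template points with < 2 "
                    "eligible candidates", n_skipped)
    return pairs


def bidirectional_filter(
    forward: list[MatchPair],
    template_desc: list[SiftDescriptor],
    target_desc: list[SiftDescriptor],
    config: MatchConfig | None = None,
) -> list[MatchPair]:
    """Keep forward pairs whose reverse match returns the template point.

    The matched target points are inversely coregistered into the template
    set with the same κ rule; a pair survives iff that reverse match exists
    and lands exactly on its template point.  The result is a subset of the
    input in which every surviving pair is a mutual best match; applying the
    filter twice equals applying it once.
    """
    if not forward:
        return []
    if config is None:
        config = MatchConfig()
    uniq = sorted({p.target_idx for p in forward})
    reverse = match_forward(
        [target_desc[t] for t in uniq], template_desc, config
    )
    rev_map = {uniq[p.template_idx]: p.target_idx for p in reverse}
    survivors = [
        p for p in forward if rev_map.get(p.target_idx) == p.template_idx
    ]
    logger.info(
        "bidirectional_filter: %d of %d forward matches survive",
        len(survivors), len(forward),
    )
    return survivors


def matches_to_landmarks(
    pairs: list[MatchPair],
) -> tuple[LandmarkSet, LandmarkSet]:
    """Convert matched pairs to index-aligned control-point landmark sets.

    Returns ``(template_set, target_set)`` in physical millimetres, in pair
    order, ready for the TPS fit.
    """
    if not pairs:
        raise ValueError(
            "no matched pairs: relax the kappa threshold or lower the "
            "detection saliency threshold to obtain control points"
        )
    labels = [f"pair{i:05d}" for i in range(len(pairs))]
    template = LandmarkSet(
        np.asarray([p.template_point.position for p in pairs]), labels=list(labels)
    )
    target = LandmarkSet(
        np.asarray([p.target_point.position for p in pairs]), labels=list(labels)
    )
    return template, target
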