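"""Leakage-safe data bookkeeping.

Field crops descend from parent photographs; if crops of the same parent end
up on both sides of a calibration/test split, thresholds leak.  This module
provides the three safeguards the protocol needs:

* parent-image reconstruction by one-to-one minimum-cost assignment of crop
  thumbnails to source-image thumbnails;
* a stratified 70/15/15 split of the source domain;
* a grouped, approximately class-stratified calibration split of the target
  domain that keeps every parent group on one side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "AssignmentResult",
    "SplitManifest",
    "thumbnail_vector",
    "match_crops_to_sources",
    "stratified_source_split",
    "grouped_calibration_split",
]

THUMBNAIL_SIDE = 32

ROLES = ("train", "val", "test", "field_calib", "field_test", "unknown_eval")


@dataclass
class AssignmentResult:
    """One-to-one crop-to-source matching with unmatched leftovers."""

    pairs: list[tuple[int, int]]
    total_cost: float
    unmatched_crops: list[int]


@dataclass
class SplitManifest:
    """Role assignment per sample with parent-group provenance."""

    sample_id: np.ndarray
    role: np.ndarray
    parent_id: np.ndarray
    seed: int
    setting: str = "B"

    def __post_init__(self) -> None:
        if not (len(self.sample_id) == len(self.role) == len(self.parent_id)):
            raise ValueError("manifest columns must have equal length")
        bad = set(np.unique(self.role)) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {bad}")

    def ids_with_role(self, role: str) -> np.ndarray:
        return self.sample_id[self.role == role]

    def parent_disjoint(self, role_a: str, role_b: str) -> bool:
        pa = set(self.parent_id[self.role == role_a])
        pb = set(self.parent_id[self.role == role_b])
        return not (pa & pb)


def thumbnail_vector(image) -> np.ndarray:
    """Flatten an RGB image to a length-3072 vector via a 32x32 bilinear resize.

    Accepts a PIL image or an array (uint8 in [0,255] or float in [0,1]);
    output is channel-last flattened and scaled to [0, 1].
    """
    if isinstance(image, Image.Image):
        arr = np.asarray(image.convert("RGB"), dtype=np.float64) / 255.0
    else:
        arr = np.asarray(image, dtype=np.float64)
        if arr.size == 0:
            raise ValueError("empty image")
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError("expected an H x W x 3 RGB image")
        if arr.max() > 1.0:
            arr = arr / 255.0
    if arr.shape[0] == 0 or arr.shape[1] == 0:
        raise ValueError("zero-sized image")
    if arr.shape[:2] != (THUMBNAIL_SIDE, THUMBNAIL_SIDE):
        # per-channel float resize: no uint8 quantization on the way down
        chans = []
        for c in range(3):
            im = Image.fromarray(arr[..., c].astype(np.float32), mode="F")
            im = im.resize((THUMBNAIL_SIDE, THUMBNAIL_SIDE), Image.BILINEAR)
            chans.append(np.asarray(im, dtype=np.float64))
        arr = np.stack(chans, axis=-1)
    return np.clip(arr, 0.0, 1.0).reshape(-1)


def match_crops_to_sources(
    crop_vectors: np.ndarray, source_vectors: np.ndarray
) -> AssignmentResult:
    """Minimum-total-cost one-to-one matching on pairwise Euclidean distances.

    When crops outnumber sources the excess crops are returned unmatched (they
    are to be dropped from the protocol, never imputed).  Ties between
    equidistant sources resolve to the lowest index, which is logged.
    """
    crop_vectors = np.atleast_2d(np.asarray(crop_vectors, dtype=np.float64))
    source_vectors = np.atleast_2d(np.asarray(source_vectors, dtype=np.float64))
    if crop_vectors.shape[0] == 0 or source_vectors.shape[0] == 0:
        raise ValueError("need at least one crop and one source")
    if crop_vectors.shape[1] != source_vectors.shape[1]:
        raise ValueError("crop and source vectors have different dimensions")
    cost = cdist(crop_vectors, source_vectors)
    rows, cols = linear_sum_assignment(cost)
    pairs = sorted(zip(rows.tolist(), cols.tolist()))
    total = float(cost[rows, cols].sum())
    matched = set(rows.tolist())
    unmatched = [i for i in range(crop_vectors.shape[0]) if i not in matched]
    if unmatched:
        logger.info("dropping %d unmatched crops: %s", len(unmatched), unmatched)
    return AssignmentResult(pairs=pairs, total_cost=total, unmatched_crops=unmatched)


def stratified_source_split(
    labels,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> np.ndarray:
    """Per-class stratified assignment to train/val/test.

    Within each class, counts follow the fractions by largest-remainder
    rounding (floor, then spill in train/val/test order of descending
    fractional part), so every role count is within one sample of exact.
    """
    labels = np.asarray(labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    roles = np.empty(len(labels), dtype=object)
    for k in np.unique(labels):
        idx = np.flatnonzero(labels == k)
        n = len(idx)
        if n < 3:
            raise ValueError(f"class {k} has {n} samples, cannot fill three roles")
        raw = np.array(fractions) * n
        counts = np.floor(raw).astype(int)
        rem = raw - counts
        for j in np.argsort(-rem, kind="stable")[: n - counts.sum()]:
            counts[j] += 1
        # guarantee every role is populated
        for j in range(3):
            if counts[j] == 0:
                counts[np.argmax(counts)] -= 1
                counts[j] += 1
        perm = rng.permutation(idx)
        roles[perm[: counts[0]]] = "train"
        roles[perm[counts[0] : counts[0] + counts[1]]] = "val"
        roles[perm[counts[0] + counts[1] :]] = "test"
    return roles


def grouped_calibration_split(
    sample_id,
    parent_id,
    labels,
    calib_fraction: float = 0.10,
    seed: int = 0,
) -> SplitManifest:
    """Split target known samples into field_calib / field_test by whole
    parent groups, approximately class-stratified.

    Per class, parent groups are shuffled by seed and added to the
    calibration side until the class calibration fraction first reaches
    ``calib_fraction``; parent disjointness is guaranteed by construction.
    """
    sample_id = np.asarray(sample_id, dtype=object)
    parent_id = np.asarray(parent_id, dtype=object)
    labels = np.asarray(labels)
    if not 0.0 < calib_fraction < 1.0:
        raise ValueError("calib_fraction must lie in (0, 1)")
    if np.any(parent_id == ""):
        raise ValueError("every sample needs a parent_id")
    rng = np.random.default_rng(seed)
    role = np.full(len(sample_id), "field_test", dtype=object)
    for k in np.unique(labels):
        idx = np.flatnonzero(labels == k)
        groups: dict[str, list[int]] = {}
        for i in idx:
            groups.setdefault(parent_id[i], []).append(i)
        if len(groups) < 2:
            raise ValueError(
                f"class {k} has a single parent group and cannot be split"
            )
        names = sorted(groups)
        rng.shuffle(names)
        n_class = len(idx)
        taken = 0
        for name in names:
            if taken / n_class >= calib_fraction:
                break
            for i in groups[name]:
                role[i] = "field_calib"
            taken += len(groups[name])
    manifest = SplitManifest(
        sample_id=sample_id, role=role, parent_id=parent_id, seed=seed, setting="B"
    )
    assert manifest.parent_disjoint("field_calib", "field_test")
    return manifest
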