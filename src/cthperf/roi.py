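"""Lesion-mask filtering, partial-volume handling, and ROI summaries.

Implements the mask-processing rules applied before any perfusion metric is
averaged: a minimum lesion size (three voxels, with an in-plane
cross-section of at least 3 mm in two contiguous slices), nearest-neighbor
partial-volume downsampling of 1 mm lesion masks onto the 3 mm DSC grid
with a 50 % retention rule, exclusion of the highest-CBV voxels (large
vessels), normalization of CBF/CBV to a deep NAWM control region, and
per-ROI means with full exclusion bookkeeping.  RTH is always averaged as
the mean of voxelwise CTH/MTT ratios, never as a ratio of means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .deconv import ConfigurationError, PerfusionMaps

MASK_LABELS = {
    "ms_t2flair",
    "ms_t1",
    "unspecific_t2flair",
    "nawm_control",
    "nagm_region",
    "wml_exclusion",
}

#: ROI metrics reported in summaries, in table order.
METRICS = ("rcbf", "rcbv", "mtt_s", "cth_s", "rth", "pto2_mmHg")

_MAP_OF_METRIC = {
    "rcbf": "rcbf",
    "rcbv": "rcbv",
    "mtt_s": "mtt",
    "cth_s": "cth",
    "rth": "rth",
    "pto2_mmHg": "pto2",
}


@dataclass(frozen=True)
class HighResMask:
    """Binary mask on the high-resolution (structural) grid."""

    data: np.ndarray  # bool, 3-D
    voxel_mm: tuple[float, float, float]
    label: str

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ConfigurationError("mask must be a 3-D volume")
        if data.dtype != bool:
            uniq = np.unique(data)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ConfigurationError("mask must be binary")
            data = data.astype(bool)
        object.__setattr__(self, "data", data)
        if len(self.voxel_mm) != 3 or any(not v > 0 for v in self.voxel_mm):
            raise ConfigurationError("voxel size metadata must be three positive floats")
        if self.label not in MASK_LABELS:
            raise ConfigurationError(
                f"unknown mask label {self.label!r}; expected one of {sorted(MASK_LABELS)}"
            )


@dataclass
class RoiSummary:
    """Per-subject, per-ROI metric means with exclusion bookkeeping."""

    subject: str
    roi: str
    means: dict[str, float] = field(default_factory=dict)
    n_voxels_total: int = 0
    n_voxels_used: int = 0
    n_excluded_vessel: int = 0
    n_excluded_pve: int = 0
    n_invalid: int = 0
    missing: bool = False

    def to_row(self) -> dict:
        row = {"subject": self.subject, "roi": self.roi}
        for m in METRICS:
            row[m] = self.means.get(m, np.nan)
        row.update(
            n_voxels_total=self.n_voxels_total,
            n_voxels_used=self.n_voxels_used,
            n_excluded_vessel=self.n_excluded_vessel,
            n_excluded_pve=self.n_excluded_pve,
            n_invalid=self.n_invalid,
            missing=self.missing,
        )
        return row


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def filter_lesions_by_size(
    mask: HighResMask, min_voxels: int = 3, min_extent_mm: float = 3.0,
    min_contiguous_slices: int = 2, connectivity: int = 26,
) -> HighResMask:
    """Drop lesion components that are too small to survive partial-volume
    averaging on the DSC grid.

    A connected component (26-connectivity by default) is retained only if
    it has at least ``min_voxels`` voxels AND, in at least
    ``min_contiguous_slices`` contiguous slices (third axis), its in-plane
    extent along some axis reaches ``min_extent_mm``.  Idempotent.
    """
    if connectivity == 26:
        struct = _STRUCT_26
    elif connectivity == 6:
        struct = ndimage.generate_binary_structure(3, 1)
    else:
        raise ConfigurationError("connectivity must be 6 or 26")
    labels, n = ndimage.label(mask.data, structure=struct)
    keep = np.zeros_like(mask.data)
    vx, vy, _ = mask.voxel_mm
    for comp in range(1, n + 1):
        coords = np.argwhere(labels == comp)
        if coords.shape[0] < min_voxels:
            continue
        ok_slices = []
        for z in np.unique(coords[:, 2]):
            sl = coords[coords[:, 2] == z]
            ext_x = (sl[:, 0].max() - sl[:, 0].min() + 1) * vx
            ext_y = (sl[:, 1].max() - sl[:, 1].min() + 1) * vy
            if max(ext_x, ext_y) >= min_extent_mm:
                ok_slices.append(int(z))
        ok_slices.sort()
        runs = 1
        best = 1 if ok_slices else 0
        for a, b in zip(ok_slices, ok_slices[1:]):
            runs = runs + 1 if b == a + 1 else 1
            best = max(best, runs)
        if best >= min_contiguous_slices:
            keep[labels == comp] = True
    return HighResMask(data=keep, voxel_mm=mask.voxel_mm, label=mask.label)


def downsample_mask_to_dsc(
    mask: HighResMask, factor: tuple[int, int, int], threshold: float = 0.5
):
    """Partial-volume-aware downsampling onto the DSC grid.

    ``factor`` is the integer refinement of the DSC grid along each axis
    (high-res shape must be an exact multiple).  Returns ``(dsc_mask,
    fraction)`` where ``fraction`` is the share of constituent high-res
    cells inside the lesion and a DSC voxel is retained iff
    ``fraction >= threshold`` (inclusive at the boundary: the exclusion rule
    omits voxels with *less than* 50 % lesion).
    """
    f = tuple(int(v) for v in factor)
    if any(v < 1 for v in f):
        raise ConfigurationError("refinement factors must be >= 1")
    shape = mask.data.shape
    if any(s % v != 0 for s, v in zip(shape, f)):
        raise ConfigurationError(
            f"high-res shape {shape} is not an integer refinement (factor {f}) of the DSC grid"
        )
    coarse = tuple(s // v for s, v in zip(shape, f))
    blocks = mask.data.reshape(coarse[0], f[0], coarse[1], f[1], coarse[2], f[2])
    fraction = blocks.mean(axis=(1, 3, 5))
    return fraction >= threshold, fraction


def exclude_high_cbv(cbv: np.ndarray, valid: np.ndarray, fraction: float = 0.08):
    """Vessel-exclusion mask: the upper ``fraction`` of valid voxels by CBV.

    Excludes exactly ``ceil(fraction * N)`` voxels; ties at the cut are
    broken by lexicographic voxel index so the result is deterministic.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("exclusion fraction must lie strictly inside (0, 1)")
    valid = np.asarray(valid, dtype=bool)
    out = np.zeros(valid.shape, dtype=bool)
    flat_idx = np.flatnonzero(valid.ravel())
    n = flat_idx.size
    if n == 0:
        return out
    n_excl = math.ceil(fraction * n)
    vals = np.asarray(cbv).ravel()[flat_idx]
    # lexsort: last key is primary -> sort by descending cbv, then ascending index
    order = np.lexsort((flat_idx, -vals))
    out.ravel()[flat_idx[order[:n_excl]]] = True
    return out


def normalize_to_control(maps: PerfusionMaps, control: np.ndarray) -> PerfusionMaps:
    """Add rCBF and rCBV: CBF and CBV divided by their control-region means.

    The control mask must already have vessel-excluded and invalid voxels
    removed.  MTT, CTH, RTH and PtO2 stay absolute.
    """
    control = np.asarray(control, dtype=bool)
    sel = control & maps.valid
    if not np.any(sel):
        raise ConfigurationError("control region is empty after validity filtering")
    cbf_ref = float(np.mean(maps.cbf[sel]))
    cbv_ref = float(np.mean(maps.cbv[sel]))
    if not (cbf_ref > 0 and cbv_ref > 0):
        raise ConfigurationError("control-region mean CBF/CBV must be positive")
    maps.rcbf = maps.cbf / cbf_ref
    maps.rcbv = maps.cbv / cbv_ref
    return maps


def summarize_roi(
    maps: PerfusionMaps,
    roi: np.ndarray,
    subject: str = "",
    label: str = "",
    vessel_excluded: np.ndarray | None = None,
    pve_retained: np.ndarray | None = None,
) -> RoiSummary:
    """Metric means over usable ROI voxels with exclusion bookkeeping.

    Usable = in-ROI, valid fit, partial-volume retained, not vessel
    excluded.  Counts satisfy
    n_total = n_used + n_invalid + n_excluded_pve + n_excluded_vessel.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != maps.shape:
        raise ConfigurationError("ROI mask is not on the DSC grid")
    vessel = (
        np.zeros(maps.shape, dtype=bool)
        if vessel_excluded is None
        else np.asarray(vessel_excluded, dtype=bool)
    )
    retained = (
        np.ones(maps.shape, dtype=bool)
        if pve_retained is None
        else np.asarray(pve_retained, dtype=bool)
    )
    n_total = int(roi.sum())
    invalid = roi & ~maps.valid
    pve_out = roi & maps.valid & ~retained
    vessel_out = roi & maps.valid & retained & vessel
    used = roi & maps.valid & retained & ~vessel
    summary = RoiSummary(
        subject=subject,
        roi=label,
        n_voxels_total=n_total,
        n_voxels_used=int(used.sum()),
        n_excluded_vessel=int(vessel_out.sum()),
        n_excluded_pve=int(pve_out.sum()),
        n_invalid=int(invalid.sum()),
    )
    if summary.n_voxels_used == 0:
        summary.missing = True
        return summary
    for metric, attr in _MAP_OF_METRIC.items():
        vol = getattr(maps, attr)
        if vol is None:
            continue
        summary.means[metric] = float(np.mean(vol[used]))
    return summary


def build_normal_appearing_masks(
    wm: np.ndarray, gm: np.ndarray, lesion_masks, auto_wml: np.ndarray | None = None
):
    """Normal-appearing compartments: tissue minus every lesion mask.

    ``lesion_masks`` is an iterable of binary arrays on the same grid (the
    manually drawn lesion categories); ``auto_wml`` is the automatically
    segmented white-matter-lesion mask, also used purely as an exclusion.
    Returns ``{"nawm": ..., "nagm": ...}``.
    """
    wm = np.asarray(wm, dtype=bool)
    gm = np.asarray(gm, dtype=bool)
    excl = np.zeros(wm.shape, dtype=bool)
    for m in lesion_masks:
        m = np.asarray(m, dtype=bool)
        if m.shape != wm.shape:
            raise ConfigurationError("lesion mask grid does not match tissue masks")
        excl |= m
    if auto_wml is not None:
        auto_wml = np.asarray(auto_wml, dtype=bool)
        if auto_wml.shape != wm.shape:
            raise ConfigurationError("auto WML mask grid does not match tissue masks")
        excl |= auto_wml
    if gm.shape != wm.shape:
        raise ConfigurationError("gm/wm masks are on different grids")
    return {"nawm": wm & ~excl, "nagm": gm & ~excl}
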