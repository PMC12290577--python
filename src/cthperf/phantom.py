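"""Synthetic digital phantom and cohort generator with known ground truth.

Everything the pipeline consumes can be generated here: voxelwise DSC
signal curves (gamma-variate transit-time kinetics convolved with a
gamma-variate arterial bolus, optional unidirectional leakage, Gaussian
signal noise at a configurable baseline SNR), high-resolution lesion masks
deliberately misaligned with the coarser DSC grid, tissue compartments, and
whole cohorts whose class-level hemodynamics reproduce the directional
contrasts between MS lesions, unspecific lesions and normal-appearing
tissue.

Class truths are expressed as multipliers on a normal-appearing white
matter base state, so scaling every multiplier to 1 yields an exact null
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .deconv import (
    AcquisitionParams,
    Aif,
    concentration_to_signal,
    tissue_forward_model,
)
from .oxygen import OxygenTransportParams, solve_pto2_batch
from .roi import HighResMask
from .transit import TransitTimeDistribution

#: Absolute-CBF anchor: the NAWM-mean relative CBF maps to this many
#: mL/100 mL/min when solving for tissue oxygen tension.
NAWM_CBF_ANCHOR = 22.0


@dataclass(frozen=True)
class TissueClassSpec:
    """Ground-truth hemodynamics of one tissue class."""

    label: str
    cbf_rel: float  # relative flow, NAWM = 1
    d: TransitTimeDistribution
    k_leak: float = 0.0  # 1/s; only the enhancing T1-lesion class leaks
    fraction: float = 0.0  # share of the phantom volume

    def __post_init__(self) -> None:
        if self.k_leak > 0 and self.label != "ms_t1":
            raise ValueError("only the ms_t1 class may have contrast leakage")


#: NAWM base state and per-class multipliers on (cbf_rel, mtt, cth).
#: The multipliers encode the directional truth of the MS-lesion contrast
#: pattern (lesions: heterogeneity and vasodilation markers up, relative
#: heterogeneity and oxygen tension down vs unspecific lesions).
NAWM_BASE = {"cbf_rel": 1.0, "mtt_s": 1.6, "cth_s": 1.4}
CLASS_MULTIPLIERS = {
    "nawm_control": {"cbf_rel": 1.0, "mtt_s": 1.0, "cth_s": 1.0},
    "nagm_region": {"cbf_rel": 2.0, "mtt_s": 0.75, "cth_s": 0.5714},
    "unspecific_t2flair": {"cbf_rel": 1.10, "mtt_s": 0.84375, "cth_s": 0.6786},
    "ms_t2flair": {"cbf_rel": 0.80, "mtt_s": 1.50, "cth_s": 1.1071},
    "ms_t1": {"cbf_rel": 0.90, "mtt_s": 1.25, "cth_s": 0.8214},
}
DEFAULT_FRACTIONS = {
    "nawm_control": 0.70,
    "nagm_region": 0.15,
    "ms_t2flair": 0.08,
    "unspecific_t2flair": 0.04,
    "ms_t1": 0.03,
}
DEFAULT_K_LEAK = {"ms_t1": 0.01}


def class_params(label: str, effect_scale: float = 1.0) -> dict:
    """Class hemodynamics = NAWM base x multipliers^effect_scale.

    ``effect_scale`` interpolates the class deviation geometrically:
    0 -> identical to NAWM (null), 1 -> the full directional truth.
    """
    m = CLASS_MULTIPLIERS[label]
    return {
        key: NAWM_BASE[key] * m[key] ** effect_scale
        for key in ("cbf_rel", "mtt_s", "cth_s")
    }


def default_classes() -> list[TissueClassSpec]:
    out = []
    for label, frac in DEFAULT_FRACTIONS.items():
        prm = class_params(label)
        out.append(
            TissueClassSpec(
                label=label,
                cbf_rel=prm["cbf_rel"],
                d=TransitTimeDistribution.from_moments(prm["mtt_s"], prm["cth_s"]),
                k_leak=DEFAULT_K_LEAK.get(label, 0.0),
                fraction=frac,
            )
        )
    return out


@dataclass(frozen=True)
class AifParams:
    """Gamma-variate arterial bolus Ca(t) = A (t-t0)^shape exp(-(t-t0)/scale)."""

    t0: float = 12.0  # bolus arrival, s
    shape: float = 2.0
    scale: float = 0.6  # s; compact first-pass bolus
    amplitude: float = 170.0  # concentration units

    def peak_time(self) -> float:
        return self.t0 + self.shape * self.scale


def make_aif(params: AifParams, times) -> Aif:
    times = np.asarray(times, dtype=float)
    u = times - params.t0
    conc = np.where(
        u > 0, params.amplitude * np.clip(u, 0, None) ** params.shape * np.exp(-u / params.scale), 0.0
    )
    return Aif(times=times, conc=conc)


DEFAULT_ACQ = AcquisitionParams(te=0.040, dt=1.2, baseline=(0, 8))
#: Bolus arrival delay of tissue relative to the AIF, seconds.
DEFAULT_DELAY = 2.0


def simulate_voxel(
    cls: TissueClassSpec,
    aif: Aif,
    acq: AcquisitionParams,
    snr: float,
    seed: int | np.random.Generator,
    s0: float = 100.0,
    delay: float = DEFAULT_DELAY,
):
    """Noisy DSC signal curve for one voxel of a tissue class.

    Concentration from the leakage-augmented forward model, converted to
    signal at baseline ``s0`` and degraded with additive Gaussian noise of
    standard deviation ``s0 / snr`` (pass ``snr=inf`` for noiseless).
    Returns ``(signal, truth)`` where ``truth`` records the exact
    generating parameters.
    """
    if not snr > 0:
        raise ValueError("snr must be positive (use inf for noiseless)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conc = tissue_forward_model(cls.cbf_rel, cls.d, cls.k_leak, delay, aif)
    signal = concentration_to_signal(conc, s0, acq)
    if np.isfinite(snr):
        signal = signal + rng.normal(0.0, s0 / snr, signal.shape)
    truth = {
        "label": cls.label,
        "cbf": cls.cbf_rel,
        "alpha": cls.d.alpha,
        "beta": cls.d.beta,
        "mtt_s": cls.d.mean,
        "cth_s": cls.d.std,
        "k_leak": cls.k_leak,
        "delay_s": delay,
    }
    return signal, truth


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of the digital phantom."""

    dsc_shape: tuple[int, int, int] = (12, 12, 4)
    dsc_voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    refinement: int = 3  # high-res grid = DSC grid x refinement (1 mm default)
    acq: AcquisitionParams = DEFAULT_ACQ
    n_frames: int = 100
    aif: AifParams = field(default_factory=AifParams)
    snr: float = 50.0
    classes: tuple[TissueClassSpec, ...] = field(
        default_factory=lambda: tuple(default_classes())
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.refinement < 2:
            raise ValueError("refinement factor must be >= 2 to exercise PVE rules")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        total = sum(c.fraction for c in self.classes)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class fractions must sum to 1, got {total}")


@dataclass
class Phantom:
    """Realized phantom: signal, masks, truth, and provenance."""

    spec: PhantomSpec
    signal4d: np.ndarray  # (x, y, z, t)
    aif: Aif
    hires_labels: np.ndarray  # int class index on the high-res grid
    class_names: list[str]
    dsc_labels: np.ndarray  # majority class per DSC voxel
    truth: dict[str, np.ndarray]  # per-DSC-voxel generating parameters
    hires_voxel_mm: tuple[float, float, float]

    def hires_mask(self, label: str) -> HighResMask:
        idx = self.class_names.index(label)
        return HighResMask(
            data=self.hires_labels == idx,
            voxel_mm=self.hires_voxel_mm,
            label=label,
        )


def _place_blob(rng, free, center, n_target):
    """Pick the n_target free cells nearest to center (ellipsoidal blob)."""
    coords = np.argwhere(free)
    if coords.shape[0] < n_target:
        raise RuntimeError("phantom volume exhausted while placing blobs")
    stretch = rng.uniform(0.7, 1.4, size=3)
    dist = np.sum(((coords - center) * stretch) ** 2, axis=1)
    order = np.argsort(dist, kind="stable")
    return coords[order[:n_target]]


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Realize a phantom: high-res label field, DSC signal, truth maps.

    The lesion layout guarantees, by construction, one sub-minimum-size
    lesion component (2 voxels) and one DSC voxel with lesion fraction
    strictly below 50 %, so the mask filters downstream always have
    something to remove.
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.refinement
    hshape = tuple(s * r for s in spec.dsc_shape)
    n_h = int(np.prod(hshape))
    names = [c.label for c in spec.classes]
    by_label = {c.label: i for i, c in enumerate(spec.classes)}
    if "nawm_control" not in by_label:
        raise ValueError("phantom requires a nawm_control background class")

    labels = np.full(hshape, by_label["nawm_control"], dtype=np.int16)
    assigned = np.zeros(hshape, dtype=bool)

    # NAGM as a deterministic slab of exactly the target count (crude
    # anatomy: a cortical band along the first axis).
    if "nagm_region" in by_label:
        n_gm = round(spec.classes[by_label["nagm_region"]].fraction * n_h)
        flat = np.arange(n_h).reshape(hshape)
        sel = flat < n_gm
        labels[sel] = by_label["nagm_region"]
        assigned |= sel

    lesion_order = [
        lbl for lbl in ("ms_t2flair", "ms_t1", "unspecific_t2flair") if lbl in by_label
    ]
    for lbl in lesion_order:
        cls = spec.classes[by_label[lbl]]
        n_target = round(cls.fraction * n_h)
        remaining = n_target
        idx = by_label[lbl]
        free = ~assigned
        if lbl == "ms_t2flair" and remaining > 30:
            # (a) a 2-voxel speck that the size filter must remove
            base = np.array([hshape[0] - 2, hshape[1] - 2, hshape[2] - 1])
            speck = np.array([base, base - [1, 0, 0]])
            labels[tuple(speck.T)] = idx
            assigned[tuple(speck.T)] = True
            remaining -= 2
            # (b) a DSC voxel covered at strictly less than 50 % lesion:
            # fill floor(r^3/2) - 1 cells of one DSC block
            bx, by_, bz = spec.dsc_shape[0] - 2, 1, spec.dsc_shape[2] - 1
            block = np.argwhere(np.ones((r, r, r))) + np.array([bx * r, by_ * r, bz * r])
            n_half = r**3 // 2 - 1
            part = block[:n_half]
            labels[tuple(part.T)] = idx
            assigned[tuple(part.T)] = True
            remaining -= n_half
        # main blobs
        free = ~assigned
        while remaining > 0:
            n_blob = min(remaining, max(3 * r**3, remaining // 2))
            center = rng.integers(0, np.array(hshape))
            cells = _place_blob(rng, free, center, n_blob)
            labels[tuple(cells.T)] = idx
            assigned[tuple(cells.T)] = True
            free[tuple(cells.T)] = False
            remaining -= n_blob

    # DSC-grid majority class
    blocks = labels.reshape(
        spec.dsc_shape[0], r, spec.dsc_shape[1], r, spec.dsc_shape[2], r
    ).transpose(0, 2, 4, 1, 3, 5).reshape(*spec.dsc_shape, -1)
    n_classes = len(spec.classes)
    counts = np.stack([(blocks == i).sum(axis=-1) for i in range(n_classes)], axis=-1)
    dsc_labels = counts.argmax(axis=-1).astype(np.int16)  # ties -> lowest index

    times = np.arange(spec.n_frames) * spec.acq.dt
    aif = make_aif(spec.aif, times)

    signal4d = np.empty((*spec.dsc_shape, spec.n_frames))
    truth = {
        k: np.empty(spec.dsc_shape)
        for k in ("cbf", "cbv", "mtt_s", "cth_s", "rth", "alpha", "beta", "k_leak")
    }
    noiseless = {}
    for i_cls, cls in enumerate(spec.classes):
        conc = tissue_forward_model(cls.cbf_rel, cls.d, cls.k_leak, DEFAULT_DELAY, aif)
        noiseless[i_cls] = concentration_to_signal(conc, 100.0, spec.acq)
    for i, j, k in np.ndindex(spec.dsc_shape):
        cls = spec.classes[dsc_labels[i, j, k]]
        signal4d[i, j, k] = noiseless[dsc_labels[i, j, k]]
        truth["cbf"][i, j, k] = cls.cbf_rel
        truth["mtt_s"][i, j, k] = cls.d.mean
        truth["cth_s"][i, j, k] = cls.d.std
        truth["rth"][i, j, k] = cls.d.std / cls.d.mean
        truth["cbv"][i, j, k] = cls.cbf_rel * cls.d.mean
        truth["alpha"][i, j, k] = cls.d.alpha
        truth["beta"][i, j, k] = cls.d.beta
        truth["k_leak"][i, j, k] = cls.k_leak
    if np.isfinite(spec.snr):
        signal4d = signal4d + rng.normal(0.0, 100.0 / spec.snr, signal4d.shape)

    hires_mm = tuple(v / r for v in spec.dsc_voxel_mm)
    return Phantom(
        spec=spec,
        signal4d=signal4d,
        aif=aif,
        hires_labels=labels,
        class_names=names,
        dsc_labels=dsc_labels,
        truth=truth,
        hires_voxel_mm=hires_mm,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a synthetic study cohort.

    ``effect_scale`` geometrically scales every class deviation from NAWM
    (1 = the directional truth, 0 = exact null cohort).  Disease-course
    severities additionally scale the MS-lesion deviation.
    """

    n_ms: int = 50
    n_sc: int = 10
    course_counts: tuple[tuple[str, int], ...] = (
        ("CIS", 5), ("RIS", 7), ("RRMS", 31), ("PPMS", 7)
    )
    n_ms_with_t2_roi: int = 48
    n_ms_with_leakage: int = 16
    n_ms_with_unspecific: int = 31
    between_subject_sigma: float = 0.06  # log-normal SD of class parameters
    within_roi_sigma: float = 0.10  # log-normal SD across voxel draws in an ROI
    n_voxel_draws: int = 12
    effect_scale: float = 1.0
    course_severity: tuple[tuple[str, float], ...] = (
        ("CIS", 0.75), ("RIS", 0.75), ("RRMS", 1.0), ("PPMS", 1.25)
    )
    age_mean_sd: tuple[tuple[str, float, float], ...] = (
        ("MS", 39.3, 10.7), ("SC", 43.3, 12.3)
    )
    female_fraction: tuple[tuple[str, float], ...] = (("MS", 0.58), ("SC", 0.90))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ms < 0 or self.n_sc < 0:
            raise ValueError("cohort sizes must be nonnegative")
        if sum(n for _, n in self.course_counts) != self.n_ms:
            raise ValueError("disease-course counts must sum to n_ms")


def _lognormal(rng, sigma, size=None):
    return np.exp(rng.normal(0.0, sigma, size=size))


def simulate_cohort(
    cspec: CohortSpec, oxygen_params: OxygenTransportParams | None = None
) -> pd.DataFrame:
    """Draw a cohort of subjects with per-ROI summary metrics (fast mode).

    Each subject's ROI is represented by ``n_voxel_draws`` voxel-level
    parameter draws around the subject's class state (log-normal
    between-subject and within-ROI variation).  Metrics are averaged over
    the draws exactly as the imaging pipeline would: RTH as the mean of
    voxelwise CTH/MTT ratios, relative CBF/CBV against the subject's own
    NAWM control mean, and PtO2 solved per voxel draw with the NAWM-anchored
    absolute-flow scale.  Fully reproducible from the seed.
    """
    from .oxygen import default_transport_params

    if oxygen_params is None:
        oxygen_params = default_transport_params()
    rng = np.random.default_rng(cspec.seed)
    severity = dict(cspec.course_severity)
    ages = dict((g, (m, s)) for g, m, s in cspec.age_mean_sd)
    p_female = dict(cspec.female_fraction)

    courses = [c for c, n in cspec.course_counts for _ in range(n)]
    subjects = []
    for i in range(cspec.n_ms):
        subjects.append((f"ms{i:03d}", "MS", courses[i]))
    for i in range(cspec.n_sc):
        subjects.append((f"sc{i:03d}", "SC", "none"))

    # availability flags mirror the study structure
    ms_ids = [s for s, g, _ in subjects if g == "MS"]
    has_t2 = set(ms_ids[: cspec.n_ms_with_t2_roi])
    has_leak = set(ms_ids[: cspec.n_ms_with_leakage])
    has_unspec = set(ms_ids[-cspec.n_ms_with_unspecific:]) if cspec.n_ms_with_unspecific else set()

    records = []  # per-ROI rows; pto2 solved in one batch at the end
    batch = {"cbf_abs": [], "alpha": [], "beta": [], "rowidx": []}

    for subj, group, course in subjects:
        age = float(np.clip(rng.normal(*ages[group]), 19.0, 75.0))
        sex = "F" if rng.random() < p_female[group] else "M"
        leak = subj in has_leak
        if group == "MS":
            vol = float(np.exp(rng.normal(np.log(1.2) + 0.5 * (severity[course] - 1.0), 1.0)))
        else:
            vol = 0.0

        rois = ["nawm_control", "nagm_region"]
        if group == "SC":
            rois.append("unspecific_t2flair")
        else:
            if subj in has_t2:
                rois.append("ms_t2flair")
            if subj in has_unspec:
                rois.append("unspecific_t2flair")
            if leak:
                rois.append("ms_t1")

        # subject-level NAWM state (the normalization reference)
        subj_jitter = {
            roi: _lognormal(rng, cspec.between_subject_sigma, size=3) for roi in rois
        }
        draws = {}
        for roi in rois:
            scale = cspec.effect_scale
            if roi in ("ms_t2flair", "ms_t1") and group == "MS":
                scale = scale * severity[course]
            prm = class_params(roi, effect_scale=scale)
            j = subj_jitter[roi]
            vox = _lognormal(rng, cspec.within_roi_sigma, size=(cspec.n_voxel_draws, 3))
            cbf = prm["cbf_rel"] * j[0] * vox[:, 0]
            mtt = prm["mtt_s"] * j[1] * vox[:, 1]
            cth = prm["cth_s"] * j[2] * vox[:, 2]
            draws[roi] = (cbf, mtt, cth)

        nawm_cbf_mean = float(np.mean(draws["nawm_control"][0]))
        nawm_cbv_mean = float(np.mean(draws["nawm_control"][0] * draws["nawm_control"][1]))
        cbf_scale = NAWM_CBF_ANCHOR / nawm_cbf_mean

        for roi in rois:
            cbf, mtt, cth = draws[roi]
            alpha = (mtt / cth) ** 2
            beta = cth**2 / mtt
            row = {
                "subject": subj,
                "group": group,
                "disease_course": course,
                "age": age,
                "sex": sex,
                "bbb_leakage": leak,
                "t2_lesion_volume_ml": vol,
                "roi": roi,
                "rcbf": float(np.mean(cbf)) / nawm_cbf_mean,
                "rcbv": float(np.mean(cbf * mtt)) / nawm_cbv_mean,
                "mtt_s": float(np.mean(mtt)),
                "cth_s": float(np.mean(cth)),
                "rth": float(np.mean(cth / mtt)),
                "pto2_mmHg": np.nan,
                "n_voxels_used": cspec.n_voxel_draws,
            }
            batch["rowidx"].append(len(records))
            batch["cbf_abs"].append(cbf * cbf_scale)
            batch["alpha"].append(alpha)
            batch["beta"].append(beta)
            records.append(row)

    if records:
        cbf_abs = np.concatenate(batch["cbf_abs"])
        alpha = np.concatenate(batch["alpha"])
        beta = np.concatenate(batch["beta"])
        pto2, _, _ = solve_pto2_batch(cbf_abs, alpha, beta, oxygen_params)
        m = cspec.n_voxel_draws
        for pos, ridx in enumerate(batch["rowidx"]):
            records[ridx]["pto2_mmHg"] = float(np.mean(pto2[pos * m : (pos + 1) * m]))

    return pd.DataFrame.from_records(records)
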