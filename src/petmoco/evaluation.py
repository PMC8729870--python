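"""Assessment machinery: MI curves, histogram-AUC deltas, AUC and CMRGlc
percentage differences, dataset splitting, and the two simulated-motion
experiments (interframe and intraframe)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import phantom as ph
from .core import DynamicPETSeries, InputFunction, MotionVector
from .idif import PostprocessConfig, VesselROI, curve_auc, postprocess_idif, pvc_iterative
from .kinetics import PatlakConfig, cmrglc, patlak_fit, plasma_blood_ratio
from .registration import (
    RegistrationConfig,
    correct_series,
    mutual_information,
    moco_cgan,
    moco_none,
    moco_oracle,
    moco_standard,
    register_rigid,
)


# --------------------------------------------------------------------------- #
# Elementary metrics
# --------------------------------------------------------------------------- #


def split_datasets(
    n: int, train_fraction: float = 0.7, seed: int = 0
) -> tuple[list[int], list[int]]:
    """Random disjoint, exhaustive train/test split of dataset ids 0..n-1.

    ``n=20, fraction=0.7`` reproduces the study's 14-scan training / 6-scan
    test split.
    """
    if n < 2:
        raise ValueError("need >= 2 datasets to split")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = rng.permutation(n)
    n_train = int(round(n * train_fraction))
    return sorted(int(i) for i in ids[:n_train]), sorted(int(i) for i in ids[n_train:])


def percent_abs_diff(a: float, b: float) -> float:
    """|a - b| / |b| * 100 — the study's |%Δ| metric (b is the reference)."""
    if b == 0:
        raise ValueError("reference value must be nonzero")
    return abs((a - b) / b) * 100.0


def hist_auc_delta(
    image: np.ndarray,
    reference: np.ndarray,
    bins: int = 64,
    background_fraction: float = 0.02,
) -> float:
    """|%Δ| of the intensity-weighted histogram areas of ``image`` vs
    ``reference``.

    Both histograms share absolute-intensity bin edges spanning the reference
    range; bins below ``background_fraction`` of the reference dynamic range
    (air around the head) are excluded, otherwise the metric is degenerate.
    The area integrates counts weighted by bin intensity, which makes the
    statistic sensitive to the intensity-scale relationship between the two
    images (halving all intensities halves the area) while remaining a pure
    voxel-multiset property — rigid subject motion leaves it unchanged up to
    interpolation.
    """
    reference = np.asarray(reference, dtype=float)
    image = np.asarray(image, dtype=float)
    lo, hi = float(reference.min()), float(reference.max())
    if hi <= lo:
        raise ValueError("constant reference image")
    edges = np.linspace(lo, hi, bins + 1)
    thresh = lo + background_fraction * (hi - lo)
    centres = 0.5 * (edges[:-1] + edges[1:])
    keep = centres >= thresh
    if not np.any(keep):
        raise ValueError("all bins below the background threshold")
    h_img, _ = np.histogram(np.clip(image, lo, hi), bins=edges)
    h_ref, _ = np.histogram(np.clip(reference, lo, hi), bins=edges)
    if h_ref[keep].sum() == 0:
        raise ValueError("all reference voxels in the background bin")
    area_img = float(np.trapezoid(h_img[keep] * centres[keep], centres[keep]))
    area_ref = float(np.trapezoid(h_ref[keep] * centres[keep], centres[keep]))
    return percent_abs_diff(area_img, area_ref)


def gradient_sharpness(volume: np.ndarray) -> float:
    """Sum of gradient magnitudes — an edge-sharpness index for summed images."""
    gx, gy, gz = np.gradient(np.asarray(volume, dtype=float))
    return float(np.sum(np.sqrt(gx**2 + gy**2 + gz**2)))


# --------------------------------------------------------------------------- #
# Report container
# --------------------------------------------------------------------------- #


@dataclass
class EvaluationReport:
    """Per-run rows plus aggregated mean ± SD per method (Table-style)."""

    runs: pd.DataFrame
    aggregates: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "runs": self.runs.to_dict(orient="list"),
            "aggregates": self.aggregates.to_dict(orient="list"),
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EvaluationReport":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            runs=pd.DataFrame(payload["runs"]),
            aggregates=pd.DataFrame(payload["aggregates"]),
            metadata=payload["metadata"],
        )

    def to_csv(self, runs_path, aggregates_path) -> None:
        self.runs.to_csv(runs_path, index=False)
        self.aggregates.to_csv(aggregates_path, index=False)


def aggregate_runs(runs: pd.DataFrame, metrics: Sequence[str]) -> pd.DataFrame:
    """mean ± SD per method over per-run metric values."""
    rows = []
    for method, grp in runs.groupby("method"):
        row = {"method": method, "n_runs": len(grp)}
        for m in metrics:
            row[f"{m}_mean"] = float(grp[m].mean())
            row[f"{m}_sd"] = float(grp[m].std(ddof=1)) if len(grp) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# IDIF + CMRGlc evaluation of one corrected series
# --------------------------------------------------------------------------- #


def evaluate_series(
    series: DynamicPETSeries,
    truth: ph.GroundTruth,
    spec: ph.PhantomSpec,
    estimates,
    patlak: PatlakConfig | None = None,
    postprocess: PostprocessConfig = PostprocessConfig(),
) -> dict:
    """AUC |%Δ| of the IDIF vs the true AIF, and GM CMRGlc |%Δ| between the
    two input functions, for one series + motion-estimate set."""
    if patlak is None:
        patlak = PatlakConfig(plasma_glucose=truth.plasma_glucose)
    roi = VesselROI(truth.region_masks["vessel"], 2 * spec.vessel_radius_mm)
    tac, pvc_ok = pvc_iterative(series, roi, spec.psf_fwhm, estimates)
    r0, r_inf, tau_r = spec.plasma_ratio
    idif, diag = postprocess_idif(
        tac,
        truth.true_aif,
        postprocess,
        plasma_ratio_fn=lambda t: plasma_blood_ratio(t, r0, r_inf, tau_r),
    )
    t1 = series.schedule.total_duration
    auc_delta = percent_abs_diff(curve_auc(idif, 0, t1), truth.true_aif.auc(0, t1))

    # GM CMRGlc from the motion-corrected series, with AIF vs IDIF input
    corrected = correct_series(series, estimates)
    gm = truth.region_masks["gm"]
    gm_tac = np.array([corrected.frame(i)[gm].mean() for i in range(series.n_frames)])
    slope_aif, _ = patlak_fit(gm_tac, truth.true_aif, patlak, series.schedule)
    slope_idif, _ = patlak_fit(gm_tac, idif, patlak, series.schedule)
    cmr_aif = cmrglc(slope_aif, patlak)
    cmr_idif = cmrglc(slope_idif, patlak)
    return {
        "auc_pct_delta": auc_delta,
        "cmrglc_aif": cmr_aif,
        "cmrglc_idif": cmr_idif,
        "cmrglc_pct_delta": percent_abs_diff(cmr_idif, cmr_aif),
        "idif_delay_s": diag["delay_s"],
        "pvc_converged": bool(pvc_ok),
    }


def motion_errors(estimates, truth: ph.GroundTruth, frames: Sequence[int]) -> pd.DataFrame:
    rows = []
    for i in frames:
        est = estimates[i].vector
        true = truth.applied_motion[i]
        rows.append(
            {
                "frame": i,
                "trans_err_mm": float(
                    np.abs(est.translation - true.translation).max()
                ),
                "rot_err_deg": float(
                    np.abs(est.rotation_deg - true.rotation_deg).max()
                ),
                "converged": estimates[i].converged,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# Training-set assembly
# --------------------------------------------------------------------------- #


def train_frame_mappings(
    base_spec: ph.PhantomSpec,
    frame_indices: Sequence[int],
    n_subjects: int = 8,
    config=None,
    seed: int = 0,
    schedule=None,
    pooled: bool = False,
) -> dict[int, object]:
    """Simulate ``n_subjects`` motion-free phantom subjects and train cGAN
    mappings (low-count frame -> that subject's measured reference frame).

    Per-index training (the full-scale protocol: one mapping per frame)
    by default; with ``pooled`` a single mapping is trained on pairs pooled
    across all requested frame indices and shared between them — the
    desk-scale shortcut, registered under the middle index.
    """
    from .cgan import CGANConfig, train_mapping

    if config is None:
        config = CGANConfig()
    if schedule is None:
        schedule = ph.make_schedule(ph.DEFAULT_FRAME_PATTERN)
    datasets = [
        ph.make_dataset(
            ph.random_subject_spec(base_spec, seed + 1000 + s),
            schedule,
            seed=seed + 2000 + s,
        )
        for s in range(n_subjects)
    ]
    if pooled:
        pairs = [
            (d.noisy.data[..., fi], d.noisy.data[..., d.noisy.reference_index])
            for d in datasets
            for fi in frame_indices
        ]
        anchor = sorted(frame_indices)[len(frame_indices) // 2]
        model = train_mapping(pairs, config, frame_index=anchor)
        return {anchor: model}
    models = {}
    for fi in frame_indices:
        pairs = [
            (d.noisy.data[..., fi], d.noisy.data[..., d.noisy.reference_index])
            for d in datasets
        ]
        models[fi] = train_mapping(pairs, config, frame_index=fi)
    return models


# --------------------------------------------------------------------------- #
# Experiments
# --------------------------------------------------------------------------- #


def run_interframe_experiment(
    base_datasets: Sequence[ph.PhantomDataset],
    models: Mapping[int, object],
    repetitions: int = 10,
    methods: Sequence[str] = ("cgan", "standard", "none", "oracle"),
    seed: int = 0,
    reg_config: RegistrationConfig = RegistrationConfig(),
    eval_frames: Sequence[int] | None = None,
) -> EvaluationReport:
    """The interframe simulated-motion experiment.

    For each base dataset x repetition: inject the random interframe-motion
    protocol, run each correction method, extract the IDIF, quantify CMRGlc
    with the true AIF and with the IDIF, and tabulate AUC and CMRGlc |%Δ|
    (study protocol: 6 base datasets x 10 repetitions = 60 evaluated
    datasets).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for d_idx, ds in enumerate(base_datasets):
        sch = ds.noisy.schedule
        if eval_frames is None:
            frames = [
                i
                for i in range(len(sch))
                if sch.mid_times[i] > 120.0 and i != ds.noisy.reference_index
            ]
        else:
            frames = list(eval_frames)
        for rep in range(repetitions):
            motion_seed = int(rng.integers(2**31))
            moved, truth = ph.inject_interframe_motion(ds.noisy, ds.truth, motion_seed)
            for method in methods:
                if method == "cgan":
                    ests = moco_cgan(moved, models, reg_config, frames=frames)
                elif method == "standard":
                    ests = moco_standard(moved, frames=frames)
                elif method == "none":
                    ests = moco_none(moved)
                elif method == "oracle":
                    ests = moco_oracle(moved, truth)
                else:
                    raise ValueError(f"unknown method {method!r}")
                try:
                    metrics = evaluate_series(moved, truth, ds.spec, ests)
                    err = motion_errors(ests, truth, frames)
                    row = {
                        "dataset": d_idx,
                        "repetition": rep,
                        "method": method,
                        "motion_seed": motion_seed,
                        "mean_trans_err_mm": float(err.trans_err_mm.mean()),
                        "mean_rot_err_deg": float(err.rot_err_deg.mean()),
                        "frac_recovered": float(
                            ((err.trans_err_mm <= 3.0) & (err.rot_err_deg <= 0.5)).mean()
                        ),
                        "failed": False,
                        **metrics,
                    }
                except Exception as exc:  # propagate per-run, aggregate flagged
                    row = {
                        "dataset": d_idx,
                        "repetition": rep,
                        "method": method,
                        "motion_seed": motion_seed,
                        "failed": True,
                        "error": str(exc),
                    }
                rows.append(row)
    runs = pd.DataFrame(rows)
    good = runs[~runs["failed"]]
    aggregates = aggregate_runs(
        good, ["auc_pct_delta", "cmrglc_pct_delta", "mean_trans_err_mm", "frac_recovered"]
    )
    meta = {
        "n_base": len(base_datasets),
        "repetitions": repetitions,
        "n_evaluated": int(len(base_datasets) * repetitions),
        "seed": seed,
        "methods": list(methods),
    }
    return EvaluationReport(runs=runs, aggregates=aggregates, metadata=meta)


def run_intraframe_experiment(
    dataset: ph.PhantomDataset,
    model,
    subframe_duration_s: float = 15.0,
    seed: int = 0,
    reg_config: RegistrationConfig = RegistrationConfig(),
    move_fraction: float = 0.5,
) -> EvaluationReport:
    """The intraframe simulated-motion experiment.

    Partition the (noise-free) reference frame into short Poisson subframes
    (300 s -> 20 x 15 s or 10 x 30 s), inject random rigid motion into a
    subset, then correct the subframes with and without cGAN preprocessing,
    sum, and compare MI with the reference and edge sharpness of the summed
    images.
    """
    from .cgan import apply_mapping

    sub = ph.partition_reference_frame(dataset.clean, dataset.spec, subframe_duration_s, seed)
    moved, vectors = ph.inject_intraframe_motion(
        sub, dataset.clean.voxel_size, seed + 1, move_fraction
    )
    reference = dataset.clean.data[..., dataset.clean.reference_index]
    vs = dataset.clean.voxel_size
    # cGAN arm registers in mapped appearance space (see moco_cgan)
    mapped_ref = apply_mapping(model, reference) if model is not None else reference

    sum_uncorrected = np.mean(moved, axis=0)
    rows = []
    corrected = {"standard": [], "cgan": []}
    for i, sf in enumerate(moved):
        mapped = apply_mapping(model, sf) if model is not None else sf
        for method, img, target in (
            ("standard", sf, reference), ("cgan", mapped, mapped_ref)
        ):
            est = register_rigid(img, target, vs, reg_config)
            fixed = (
                sf
                if est.vector.is_identity()
                else ph.apply_motion(sf, est.vector.invert(), vs)
            )
            corrected[method].append(fixed)
            true = vectors[i]
            rows.append(
                {
                    "subframe": i,
                    "method": method,
                    "mi_raw": mutual_information(sf, reference),
                    "mi_processed": mutual_information(img, reference),
                    "trans_err_mm": float(
                        np.abs(est.vector.translation - true.translation).max()
                    ),
                    "rot_err_deg": float(
                        np.abs(est.vector.rotation_deg - true.rotation_deg).max()
                    ),
                }
            )
    runs = pd.DataFrame(rows)
    sums = {m: np.mean(v, axis=0) for m, v in corrected.items()}
    meta = {
        "n_subframes": len(sub),
        "subframe_duration_s": subframe_duration_s,
        "seed": seed,
        "sharpness_uncorrected": gradient_sharpness(sum_uncorrected),
        "sharpness_standard": gradient_sharpness(sums["standard"]),
        "sharpness_cgan": gradient_sharpness(sums["cgan"]),
        "sharpness_no_motion": gradient_sharpness(np.mean(sub, axis=0)),
    }
    aggregates = aggregate_runs(runs, ["mi_raw", "mi_processed", "trans_err_mm", "rot_err_deg"])
    return EvaluationReport(runs=runs, aggregates=aggregates, metadata=meta)
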