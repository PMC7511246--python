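"""Semisynthetic ROC evaluation of correction pipelines.

Each iteration draws a noise scan for one condition (rest, breath-hold with
jittered stimuli, breath-hold with time-locked stimuli), injects a canonical
evoked response into a random half of the long-distance channels at a fixed
CNR, runs one correction/estimation pipeline, and records the per-channel
p-values against the known truth labels.  Pooled over iterations these give
ROC curves, AUC and partial AUC (FPR <= 0.05), DeLong AUC comparisons,
bootstrap pAUC tests, and type-I calibration curves (empirical FPR on
noise-only channels versus the nominal p threshold).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics

from . import superficial_filters as sf
from .glm_engine import (
    DesignMatrix,
    ar_irls_fit,
    build_ss_design,
    build_task_design,
    hotelling_joint,
    me_ar_irls_fit,
    ols_fit,
)
from .probe_signal import CHROMOPHORES, HemoScan, ProbeGeometry, bandpass, default_probe
from .synthetic_data import (
    CONDITIONS,
    EventSet,
    NoiseSpec,
    SimulationSpec,
    generate_noise_scan,
    inject_response,
    make_events,
)

__all__ = [
    "PipelineSpec",
    "ROCCurve",
    "CalibrationCurve",
    "run_iteration",
    "roc_curve",
    "partial_auc",
    "delong_test",
    "pauc_bootstrap_test",
    "calibration_curve",
    "run_benchmark",
    "benchmark_grid",
    "GLM_VARIANTS",
]

logger = logging.getLogger(__name__)

PREFILTERS = ("none", "pca", "bpca", "ss_projection", "ss_image")
SOLVERS = ("ols", "ar_irls", "me_ar_irls")

#: The five GLM variants of the benchmark grid: (solver, ss_mode) pairs.
GLM_VARIANTS = (
    ("ols", "none"),
    ("ols", "both"),
    ("ar_irls", "none"),
    ("ar_irls", "both"),
    ("me_ar_irls", "both"),
)


@dataclass(frozen=True)
class PipelineSpec:
    """One processing pipeline: condition, prefilter, solver and SS usage.

    ``ss_mode`` selects the chromophores of the SS channels used by whichever
    stage consumes them (the SS prefilters or the SS regression inside the
    GLM); 'none' disables SS regression in the solver.  ``n_nearest`` of
    ``None`` uses all SS channels.
    """

    condition: str = "rest"
    prefilter: str = "none"
    solver: str = "ar_irls"
    ss_mode: str = "none"
    n_nearest: int | None = None
    bandpass: tuple = (None, None)
    cnr: float = 0.7
    variance_fraction: float = 0.8

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.prefilter not in PREFILTERS:
            raise ValueError(f"prefilter must be one of {PREFILTERS}")
        if self.solver not in SOLVERS:
            raise ValueError(f"solver must be one of {SOLVERS}")
        if self.ss_mode not in ("none", "HbO2", "Hb", "both"):
            raise ValueError("ss_mode must be none|HbO2|Hb|both")
        if self.solver == "me_ar_irls" and self.ss_mode == "none":
            raise ValueError("the mixed-effects solver requires SS regressors")
        if self.cnr < 0:
            raise ValueError("cnr must be non-negative")

    @property
    def name(self) -> str:
        parts = [self.condition, self.prefilter, self.solver]
        if self.ss_mode != "none":
            nn = "all" if self.n_nearest is None else str(self.n_nearest)
            parts.append(f"ss[{self.ss_mode},n={nn}]")
        return "+".join(parts)


@dataclass
class ROCCurve:
    """Pooled (p, truth) pairs with the derived TPR/FPR sweep."""

    p: np.ndarray
    truth: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def pauc(self, fpr_max: float = 0.05, normalized: bool = True) -> float:
        return partial_auc(self, fpr_max=fpr_max, normalized=normalized)


@dataclass
class CalibrationCurve:
    """Empirical false-positive rate on noise-only channels as a function of
    the nominal p threshold (p-hat).  The identity line is ideal."""

    p_hat: np.ndarray
    fpr: np.ndarray

    def max_deviation(self) -> float:
        return float(np.max(np.abs(self.fpr - self.p_hat)))

    def fpr_at(self, p_hat: float) -> float:
        return float(np.interp(p_hat, self.p_hat, self.fpr))


def _derived_seeds(seed: int, n: int = 4):
    """Independent child seeds for the stages of one iteration."""
    return np.random.SeedSequence(seed).spawn(n)


def _apply_prefilter(
    scan: HemoScan,
    pipeline: PipelineSpec,
    geometry: ProbeGeometry,
    noise: NoiseSpec,
    baseline_seed,
) -> HemoScan:
    """Apply the pipeline's prefilter to the full probe scan and return the
    scan used downstream (still full-probe; LD selection happens later)."""
    if pipeline.prefilter == "none":
        return scan
    if pipeline.prefilter == "pca":
        return sf.pca_filter(scan, variance_fraction=pipeline.variance_fraction)
    if pipeline.prefilter == "bpca":
        baseline_events = EventSet(
            stim=make_events("rest", noise.duration, 0).stim, bh_onsets=np.zeros(0)
        )
        baseline = generate_noise_scan(noise, baseline_events, baseline_seed, geometry)
        return sf.pca_filter(scan, baseline, variance_fraction=pipeline.variance_fraction)
    mode = pipeline.ss_mode if pipeline.ss_mode != "none" else "both"
    if pipeline.prefilter == "ss_projection":
        xshort, _ = build_ss_design(scan, geometry, mode=mode, decorrelate=True)
        filtered_ld = sf.ss_projection_filter(scan.select(geometry.ld_indices()), xshort)
        out = scan.copy(provenance=filtered_ld.provenance)
        out.hbo[:, geometry.ld_indices()] = filtered_ld.hbo
        out.hbr[:, geometry.ld_indices()] = filtered_ld.hbr
        return out
    if pipeline.prefilter == "ss_image":
        skin = sf.build_skin_model(geometry)
        return sf.ss_image_filter(scan, skin)
    raise AssertionError(pipeline.prefilter)


def run_iteration(
    sim: SimulationSpec,
    pipeline: PipelineSpec,
    seed: int,
    noise: NoiseSpec | None = None,
    geometry: ProbeGeometry | None = None,
    chromophores=CHROMOPHORES,
) -> pd.DataFrame:
    """One ROC iteration: simulate, inject, correct, fit, and report.

    Returns a tidy frame with one row per LD channel per chromophore (plus a
    'joint' Hotelling row when both chromophores are fit) carrying the
    p-value, t/T2 statistic, and truth label.  Fully deterministic given
    ``seed``.
    """
    geometry = geometry or default_probe()
    noise = noise or NoiseSpec()
    s_events, s_noise, s_inject, s_baseline = _derived_seeds(seed)
    events = make_events(pipeline.condition, noise.duration, s_events)
    scan = generate_noise_scan(noise, events, s_noise, geometry)
    scan, truth = inject_response(
        scan, events, sim.cnr, s_inject, geometry, truth_fraction=sim.truth_fraction
    )
    lo, hi = pipeline.bandpass
    if lo is not None or hi is not None:
        scan = bandpass(scan, lo, hi)
    scan = _apply_prefilter(scan, pipeline, geometry, noise, s_baseline)

    ld_idx = geometry.ld_indices()
    ld_scan = scan.select(ld_idx)
    xtask, task_labels = build_task_design(events.stim, scan.n_time, scan.fs)

    use_ss_regression = pipeline.ss_mode != "none"
    if use_ss_regression and pipeline.n_nearest is not None:
        xshorts = [
            build_ss_design(
                scan, geometry, ld_channel=int(ch), mode=pipeline.ss_mode,
                n_nearest=pipeline.n_nearest, decorrelate=True,
            )[0]
            for ch in ld_idx
        ]
    elif use_ss_regression:
        xs, _ = build_ss_design(scan, geometry, mode=pipeline.ss_mode, decorrelate=True)
        xshorts = [xs] * len(ld_idx)
    else:
        xshorts = None

    if pipeline.solver == "me_ar_irls":
        zshort = xshorts[0] if pipeline.n_nearest is None else xshorts
        results, _ = me_ar_irls_fit(
            ld_scan, xtask, zshort, fs=scan.fs, task_labels=task_labels,
            chromophores=chromophores,
        )
    elif xshorts is not None and pipeline.n_nearest is not None:
        # per-channel nuisance blocks: fit channel by channel
        results = {c: [] for c in chromophores}
        fit = ols_fit if pipeline.solver == "ols" else ar_irls_fit
        for k in range(len(ld_idx)):
            dm = DesignMatrix(
                xtask=xtask, task_labels=task_labels, fs=scan.fs,
                xshort=xshorts[k], short_labels=[f"SS_pc{i}" for i in range(xshorts[k].shape[1])],
            )
            sub = fit(ld_scan.select([k]), dm, chromophores=chromophores)
            for chrom in chromophores:
                res = sub[chrom][0]
                res.channel = k
                results[chrom].append(res)
    else:
        short_labels = (
            [f"SS_pc{i}" for i in range(xshorts[0].shape[1])] if xshorts else []
        )
        dm = DesignMatrix(
            xtask=xtask, task_labels=task_labels, fs=scan.fs,
            xshort=xshorts[0] if xshorts else None, short_labels=short_labels,
        )
        fit = ols_fit if pipeline.solver == "ols" else ar_irls_fit
        results = fit(ld_scan, dm, chromophores=chromophores)

    rows = []
    for chrom in chromophores:
        for k, res in enumerate(results[chrom]):
            rows.append(
                dict(
                    channel=int(ld_idx[k]),
                    chromophore=chrom,
                    p=float(res.p[0]),
                    stat=float(res.t[0]),
                    truth=bool(truth[ld_idx[k]]),
                    seed=seed,
                )
            )
    if "HbO2" in chromophores and "Hb" in chromophores:
        for k in range(len(ld_idx)):
            t2, p = hotelling_joint(results["HbO2"][k], results["Hb"][k])
            rows.append(
                dict(
                    channel=int(ld_idx[k]),
                    chromophore="joint",
                    p=float(p),
                    stat=float(t2),
                    truth=bool(truth[ld_idx[k]]),
                    seed=seed,
                )
            )
    return pd.DataFrame(rows)


def roc_curve(p, truth) -> ROCCurve:
    """ROC curve from pooled p-values and truth labels, ranking by 1 - p.

    AUC is the trapezoidal area, identical to the Mann-Whitney probability
    that a random positive outranks a random negative.
    """
    p = np.asarray(p, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or (~truth).all():
        raise ValueError("need both positive and negative channels for a ROC curve")
    fpr, tpr, thr = skmetrics.roc_curve(truth.astype(int), 1.0 - p)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(p=p, truth=truth, fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def partial_auc(curve: ROCCurve, fpr_max: float = 0.05, normalized: bool = True) -> float:
    """Trapezoidal ROC area restricted to FPR in [0, fpr_max], linearly
    interpolated at the cut; normalised value divides by fpr_max."""
    if not (0 < fpr_max <= 1):
        raise ValueError("fpr_max must be in (0, 1]")
    fpr, tpr = curve.fpr, curve.tpr
    if fpr_max < fpr[-1]:
        tpr_cut = float(np.interp(fpr_max, fpr, tpr))
        keep = fpr < fpr_max
        fpr = np.concatenate([fpr[keep], [fpr_max]])
        tpr = np.concatenate([tpr[keep], [tpr_cut]])
    raw = float(np.trapezoid(tpr, fpr))
    return raw / fpr_max if normalized else raw


def _midrank_placements(scores: np.ndarray, truth: np.ndarray):
    """DeLong placement values via midranks.  Returns (auc, v_pos, v_neg)."""
    pos = scores[truth]
    neg = scores[~truth]
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    r_all = stats.rankdata(all_scores)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v_pos = (r_all[:m] - r_pos) / n  # P(pos_i > random neg), with ties at 1/2
    v_neg = 1.0 - (r_all[m:] - r_neg) / m
    auc = float(v_pos.mean())
    return auc, v_pos, v_neg


def delong_test(p_a, p_b, truth):
    """DeLong comparison of two correlated AUCs measured on the same channels.

    Scores are 1 - p.  Returns ``(auc_a, auc_b, z, p_value)`` with a
    two-sided normal p-value for the AUC difference.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or (~truth).all():
        raise ValueError("need both classes for a DeLong test")
    auc_a, va_pos, va_neg = _midrank_placements(1.0 - p_a, truth)
    auc_b, vb_pos, vb_neg = _midrank_placements(1.0 - p_b, truth)
    m, n = len(va_pos), len(va_neg)
    s_pos = np.cov(np.vstack([va_pos, vb_pos]))
    s_neg = np.cov(np.vstack([va_neg, vb_neg]))
    var = (s_pos[0, 0] + s_pos[1, 1] - 2 * s_pos[0, 1]) / m + (
        s_neg[0, 0] + s_neg[1, 1] - 2 * s_neg[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        return auc_a, auc_b, 0.0, 1.0
    z = diff / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return auc_a, auc_b, float(z), p


def pauc_bootstrap_test(
    p_a,
    p_b,
    truth,
    n_boot: int = 1000,
    fpr_max: float = 0.05,
    seed: int = 0,
    iteration_ids=None,
):
    """Bootstrap test of the partial-AUC difference between two pipelines.

    Units are resampled with replacement (iterations when ``iteration_ids``
    is given, individual channels otherwise), the pAUC difference is
    recomputed per resample, and the observed difference is referred to the
    bootstrap spread with a Student-t tail.

    Returns the two-sided p-value.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    rng = np.random.default_rng(seed)
    if iteration_ids is not None:
        ids = np.asarray(iteration_ids)
        groups = [np.flatnonzero(ids == u) for u in np.unique(ids)]
    else:
        groups = [np.array([i]) for i in range(len(truth))]
    observed = partial_auc(roc_curve(p_a, truth), fpr_max) - partial_auc(
        roc_curve(p_b, truth), fpr_max
    )
    diffs = np.empty(n_boot)
    n_groups = len(groups)
    for b in range(n_boot):
        pick = rng.integers(0, n_groups, n_groups)
        idx = np.concatenate([groups[i] for i in pick])
        tr = truth[idx]
        if tr.all() or (~tr).all():
            diffs[b] = np.nan
            continue
        diffs[b] = partial_auc(roc_curve(p_a[idx], tr), fpr_max) - partial_auc(
            roc_curve(p_b[idx], tr), fpr_max
        )
    diffs = diffs[np.isfinite(diffs)]
    sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
    if sd == 0:
        warnings.warn("degenerate bootstrap variance; p set to 1")
        return 1.0
    t_stat = observed / sd
    return float(2.0 * stats.t.sf(abs(t_stat), df=len(diffs) - 1))


def calibration_curve(p_null, grid=None) -> CalibrationCurve:
    """Empirical FPR(p-hat) on noise-only channels over a fixed threshold
    grid; a well-calibrated test tracks the identity line."""
    p_null = np.asarray(p_null, dtype=float)
    if len(p_null) < 100:
        raise ValueError("need at least 100 noise-only p-values")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, dtype=float)
    fpr = np.array([np.mean(p_null <= g) for g in grid])
    return CalibrationCurve(p_hat=grid, fpr=fpr)


def benchmark_grid(
    conditions=CONDITIONS,
    prefilters=("none", "pca", "bpca", "ss_projection"),
    glm_variants=GLM_VARIANTS,
    cnr: float = 0.7,
) -> list:
    """Expand the full pipeline grid (3 conditions x 4 preprocessings x 5 GLM
    variants = 60 combinations by default)."""
    grid = []
    for cond in conditions:
        for pre in prefilters:
            for solver, ss_mode in glm_variants:
                grid.append(
                    PipelineSpec(
                        condition=cond, prefilter=pre, solver=solver,
                        ss_mode=ss_mode, cnr=cnr,
                    )
                )
    return grid


def type_one_error_study(
    n_iterations: int = 200,
    master_seed: int = 0,
    noise: NoiseSpec | None = None,
    geometry: ProbeGeometry | None = None,
):
    """Null (no injected response) type-I error study on resting-like noise.

    Each iteration draws a resting-condition scan plus jittered stimulus
    timing, then fits three models to the HbO2 long-distance channels: plain
    OLS, AR-IRLS without SS regressors, and AR-IRLS with all SS channels of
    both chromophores appended (PCA-decorrelated).  Returns a dict mapping
    solver name to the pooled null p-value array, plus the decision count.
    """
    noise = noise or NoiseSpec()
    geometry = geometry or default_probe()
    pooled = {"ols": [], "ar_irls": [], "ar_irls_ss": []}
    for it in range(n_iterations):
        seed = master_seed + it
        s_events, s_noise, _, _ = _derived_seeds(seed)
        events = make_events("rest", noise.duration, s_events)
        scan = generate_noise_scan(noise, events, s_noise, geometry)
        ld = scan.select(geometry.ld_indices())
        xtask, labels = build_task_design(events.stim, scan.n_time, scan.fs)
        dm = DesignMatrix(xtask=xtask, task_labels=labels, fs=scan.fs)
        pooled["ols"] += [r.p[0] for r in ols_fit(ld, dm, chromophores=("HbO2",))["HbO2"]]
        pooled["ar_irls"] += [
            r.p[0] for r in ar_irls_fit(ld, dm, chromophores=("HbO2",))["HbO2"]
        ]
        xs, slab = build_ss_design(scan, geometry, mode="both", decorrelate=True)
        dm_ss = DesignMatrix(
            xtask=xtask, task_labels=labels, fs=scan.fs, xshort=xs, short_labels=slab
        )
        pooled["ar_irls_ss"] += [
            r.p[0] for r in ar_irls_fit(ld, dm_ss, chromophores=("HbO2",))["HbO2"]
        ]
    return {k: np.asarray(v) for k, v in pooled.items()}


def null_auc_study(
    n_iterations: int = 100,
    master_seed: int = 0,
    noise: NoiseSpec | None = None,
    geometry: ProbeGeometry | None = None,
):
    """Pooled AUC with CNR = 0: truth labels are drawn for half the LD
    channels as usual but no response is injected, so the AUC must sit at
    chance.  Returns ``(auc, n_decisions)`` over HbO2 channel decisions."""
    noise = noise or NoiseSpec()
    geometry = geometry or default_probe()
    ps, truths = [], []
    for it in range(n_iterations):
        seed = master_seed + it
        s_events, s_noise, s_inject, _ = _derived_seeds(seed)
        events = make_events("rest", noise.duration, s_events)
        scan = generate_noise_scan(noise, events, s_noise, geometry)
        scan, truth = inject_response(scan, events, 0.0, s_inject, geometry)
        ld_idx = geometry.ld_indices()
        ld = scan.select(ld_idx)
        xtask, labels = build_task_design(events.stim, scan.n_time, scan.fs)
        dm = DesignMatrix(xtask=xtask, task_labels=labels, fs=scan.fs)
        res = ar_irls_fit(ld, dm, chromophores=("HbO2",))["HbO2"]
        ps += [r.p[0] for r in res]
        truths += list(truth[ld_idx])
    curve = roc_curve(np.asarray(ps), np.asarray(truths))
    return curve.auc, len(ps)


def run_benchmark(
    pipelines,
    n_iterations: int = 200,
    master_seed: int = 0,
    noise: NoiseSpec | None = None,
    geometry: ProbeGeometry | None = None,
    fpr_max: float = 0.05,
    chromophores=("HbO2", "Hb", "joint"),
):
    """Run every pipeline over ``n_iterations`` simulated iterations and pool
    the per-channel decisions.

    Per-iteration seeds are ``master_seed + iteration index``.  Failed
    iterations are logged, excluded and counted, never imputed.

    Returns ``(summary, curves, calibrations, pooled)`` where ``summary`` is
    a tidy frame (pipeline x chromophore: AUC, raw/normalised pAUC, empirical
    FPR at p < fpr_max, iteration counts), ``curves`` and ``calibrations``
    map ``(pipeline_name, chromophore)`` to their curve objects, and
    ``pooled`` holds every (p, truth) decision.
    """
    noise = noise or NoiseSpec()
    geometry = geometry or default_probe()
    summary_rows = []
    curves: dict = {}
    calibrations: dict = {}
    pooled_frames = []
    for pipeline in pipelines:
        sim = SimulationSpec(condition=pipeline.condition, cnr=pipeline.cnr,
                             seed=master_seed, n_iterations=n_iterations)
        frames = []
        n_failed = 0
        for it in range(n_iterations):
            seed = master_seed + it
            try:
                df = run_iteration(sim, pipeline, seed, noise=noise, geometry=geometry)
            except Exception:  # noqa: BLE001 - harness isolates iteration failures
                logger.exception("iteration %d (seed %d) failed for %s", it, seed, pipeline.name)
                n_failed += 1
                continue
            df["iteration"] = it
            frames.append(df)
        if not frames:
            raise RuntimeError(f"all iterations failed for pipeline {pipeline.name}")
        pooled = pd.concat(frames, ignore_index=True)
        pooled["pipeline"] = pipeline.name
        pooled_frames.append(pooled)
        for chrom in chromophores:
            sub = pooled[pooled.chromophore == chrom]
            curve = roc_curve(sub.p.to_numpy(), sub.truth.to_numpy())
            null_p = sub.p[~sub.truth].to_numpy()
            cal = calibration_curve(null_p) if len(null_p) >= 100 else None
            curves[(pipeline.name, chrom)] = curve
            calibrations[(pipeline.name, chrom)] = cal
            summary_rows.append(
                dict(
                    pipeline=pipeline.name,
                    condition=pipeline.condition,
                    prefilter=pipeline.prefilter,
                    solver=pipeline.solver,
                    ss_mode=pipeline.ss_mode,
                    chromophore=chrom,
                    cnr=pipeline.cnr,
                    auc=curve.auc,
                    pauc_raw=partial_auc(curve, fpr_max, normalized=False),
                    pauc_norm=partial_auc(curve, fpr_max, normalized=True),
                    fpr_at_thresh=float(np.mean(null_p < fpr_max)),
                    n_iterations=n_iterations - n_failed,
                    n_failed=n_failed,
                )
            )
    summary = pd.DataFrame(summary_rows)
    pooled_all = pd.concat(pooled_frames, ignore_index=True)
    return summary, curves, calibrations, pooled_all
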