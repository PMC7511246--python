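"""Prefilters that remove superficial systemic physiology before statistics.

Four spatial filters, all linear operators on the channel dimension:

* PCA filter — remove the leading principal components of the channel-space
  covariance (systemic physiology is assumed to dominate the spatial
  covariance); components can be fit on the task file itself (``pca``) or on
  a separate baseline-only file (``bpca``).  The number of components
  removed is the smallest count explaining at least 80% of the spatial
  covariance by default.
* Short-separation unconstrained projection — project the span of the SS
  nuisance time courses out of the long-distance data, ignoring spatial
  relationships.
* Short-separation image-reconstruction filter — use an (approximate)
  optical forward model of skin sensitivity to reconstruct and subtract the
  superficial signal, with a smooth spatial basis and Tikhonov
  regularisation.

All filters operate per chromophore and never share components across
HbO2/Hb.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .probe_signal import CHROMOPHORES, HemoScan, ProbeGeometry

__all__ = [
    "SpatialDecomposition",
    "SkinModel",
    "fit_spatial_components",
    "pca_filter",
    "ss_projection_filter",
    "build_skin_model",
    "ss_image_filter",
]


@dataclass
class SpatialDecomposition:
    """SVD of a (time-centred) scan block: U S V^T, with the removal count
    implied by the cumulative squared-singular-value rule."""

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray  # channel x component, orthonormal columns
    n_removed: int
    variance_fraction: float

    def removed_components(self) -> np.ndarray:
        return self.V[:, : self.n_removed]


@dataclass
class SkinModel:
    """Approximate skin-layer forward model for the image-reconstruction
    filter: L maps skin nodes to measurements, Sbasis smooths the skin."""

    L: np.ndarray  # channel x node sensitivity
    Sbasis: np.ndarray  # node x basis, unit-norm smooth kernels
    lam: float
    nodes: np.ndarray  # node positions (mm), for inspection


def _n_removed_from_shares(s: np.ndarray, variance_fraction: float) -> int:
    """Smallest n with cumulative squared-singular-value share >= fraction."""
    if variance_fraction <= 0:
        return 0
    total = float(np.sum(s**2))
    shares = np.cumsum(s**2) / total
    return int(np.searchsorted(shares, variance_fraction - 1e-12) + 1)


def fit_spatial_components_2d(y: np.ndarray, variance_fraction: float = 0.8) -> SpatialDecomposition:
    """Spatial SVD of one time x channel block (centred over time)."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("need a time x channel block with >= 2 channels")
    yc = y - y.mean(axis=0, keepdims=True)
    if not np.any(yc):
        raise ValueError("degenerate (all-zero after centring) data")
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    return SpatialDecomposition(
        U=u,
        S=s,
        V=vt.T,
        n_removed=_n_removed_from_shares(s, variance_fraction),
        variance_fraction=variance_fraction,
    )


def fit_spatial_components(scan: HemoScan, variance_fraction: float = 0.8) -> dict:
    """Per-chromophore spatial decomposition of a scan.

    Returns ``{chromophore: SpatialDecomposition}``; HbO2 and Hb are always
    decomposed separately since their physiological contributions differ.
    """
    return {
        chrom: fit_spatial_components_2d(scan.chrom(chrom), variance_fraction)
        for chrom in CHROMOPHORES
    }


def pca_filter(
    task: HemoScan,
    baseline: HemoScan | None = None,
    variance_fraction: float = 0.8,
) -> HemoScan:
    """Remove leading spatial principal components from a task scan.

    Components are fit on ``baseline`` when given (baseline-derived PCA),
    else on the task scan itself.  Per chromophore the filtered data is
    ``Y - sum_i (Y v_i) v_i^T`` over the removed components, applied to the
    time-centred data (the temporal mean is restored afterwards).
    """
    if baseline is not None and baseline.n_channels != task.n_channels:
        raise ValueError("baseline and task scans must share the channel layout")
    src = "bpca" if baseline is not None else "pca"
    out = task.copy(provenance=f"filtered:{src}")
    for chrom in CHROMOPHORES:
        fit_on = (baseline or task).chrom(chrom)
        dec = fit_spatial_components_2d(fit_on, variance_fraction)
        v = dec.removed_components()
        y = task.chrom(chrom)
        mean = y.mean(axis=0, keepdims=True)
        yc = y - mean
        filtered = yc - (yc @ v) @ v.T + mean
        if chrom == "HbO2":
            out.hbo = filtered
        else:
            out.hbr = filtered
    return out


def ss_projection_filter(long: HemoScan, xshort: np.ndarray) -> HemoScan:
    """Unconstrained projection of the SS nuisance span out of LD data:
    ``Yf = (I - Xs (Xs^T Xs)^-1 Xs^T) Ylong``.

    The residual is orthogonal to every column of ``xshort``; the same
    projector (built once from the nuisance block) is applied to both
    chromophores.
    """
    xs = np.atleast_2d(np.asarray(xshort, dtype=float))
    if xs.shape[0] != long.n_time:
        raise ValueError("xshort must share the time axis with the scan")
    if np.linalg.matrix_rank(xs) < xs.shape[1]:
        raise ValueError(
            "rank-deficient xshort; decorrelate the SS block first "
            "(build_ss_design(..., decorrelate=True))"
        )
    out = long.copy(provenance="filtered:ss_projection")
    coef_hbo, *_ = np.linalg.lstsq(xs, long.hbo, rcond=None)
    coef_hbr, *_ = np.linalg.lstsq(xs, long.hbr, rcond=None)
    out.hbo = long.hbo - xs @ coef_hbo
    out.hbr = long.hbr - xs @ coef_hbr
    return out


def build_skin_model(
    geometry: ProbeGeometry,
    kernel_width_mm: float = 15.0,
    lam: float | None = None,
    grid_spacing_mm: float = 10.0,
    basis_spacing_mm: float = 30.0,
    pad_mm: float = 20.0,
    sensitivity_width_mm: float = 10.0,
    ss_factor: float = 1.0,
    ld_factor: float = 0.3,
) -> SkinModel:
    """Analytic skin-sensitivity model for the image-reconstruction filter.

    Skin nodes form a regular lattice over the probe's bounding box (padded).
    A channel's sensitivity to a node is a Gaussian in the node-to-midpoint
    distance, scaled by a partial-pathlength factor: short-separation
    channels see the skin at full weight, long channels at a reduced weight
    (most of their pathlength is deeper tissue).  ``Sbasis`` holds unit-norm
    Gaussian smoothing kernels of width ``kernel_width_mm`` centred on a
    coarser lattice (``basis_spacing_mm``) — the low-spatial-frequency basis
    of the reconstruction.

    ``lam`` defaults to 0.01 x the largest eigenvalue of ``(L S)^T (L S)``.
    """
    if kernel_width_mm <= 0 or grid_spacing_mm <= 0 or sensitivity_width_mm <= 0:
        raise ValueError("kernel and grid scales must be positive")
    if basis_spacing_mm <= 0:
        raise ValueError("basis spacing must be positive")
    if lam is not None and lam <= 0:
        raise ValueError("lam must be positive")
    optodes = np.vstack([geometry.sources, geometry.detectors])
    lo = optodes[:, :2].min(axis=0) - pad_mm
    hi = optodes[:, :2].max(axis=0) + pad_mm

    def _lattice(spacing, lo_, hi_):
        gx = np.arange(lo_[0], hi_[0] + 0.5 * spacing, spacing)
        gy = np.arange(lo_[1], hi_[1] + 0.5 * spacing, spacing)
        xx, yy = np.meshgrid(gx, gy, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()])

    nodes = _lattice(grid_spacing_mm, lo, hi)
    # basis centres stay on the unpadded probe footprint: fewer, smoother
    # kernels than skin nodes (a genuinely low-spatial-frequency basis)
    centers = _lattice(basis_spacing_mm, lo + pad_mm, hi - pad_mm)

    mids = geometry.midpoints()[:, :2]
    d2 = ((mids[:, None, :] - nodes[None, :, :]) ** 2).sum(axis=2)
    l_mat = np.exp(-d2 / (2.0 * sensitivity_width_mm**2))
    factors = np.where(geometry.is_short(), ss_factor, ld_factor)
    l_mat = l_mat * factors[:, None]

    nd2 = ((nodes[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    sbasis = np.exp(-nd2 / (2.0 * kernel_width_mm**2))
    sbasis = sbasis / np.linalg.norm(sbasis, axis=0, keepdims=True)

    if lam is None:
        a = l_mat @ sbasis
        lam = 0.01 * float(np.linalg.eigvalsh(a.T @ a)[-1])
    return SkinModel(L=l_mat, Sbasis=sbasis, lam=float(lam), nodes=nodes)


def ss_image_filter(scan: HemoScan, skin: SkinModel) -> HemoScan:
    """Image-reconstruction superficial filter:
    ``Yf^T = [I - A (A^T A + lam I)^-1 A^T] Y^T`` with ``A = L Sbasis``.

    As lam -> infinity the operator approaches the identity; as lam -> 0 any
    data lying in span(A) is annihilated.  The scan must contain all probe
    channels (SS and LD) since L has one row per channel.
    """
    a = skin.L @ skin.Sbasis
    if scan.n_channels != a.shape[0]:
        raise ValueError(
            f"scan has {scan.n_channels} channels but the skin model expects {a.shape[0]}"
        )
    gram = a.T @ a + skin.lam * np.eye(a.shape[1])
    proj = a @ np.linalg.solve(gram, a.T)  # channel x channel, symmetric
    f_op = np.eye(a.shape[0]) - proj
    out = scan.copy(provenance="filtered:ss_image")
    out.hbo = scan.hbo @ f_op.T
    out.hbr = scan.hbr @ f_op.T
    return out
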