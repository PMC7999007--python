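"""Segmentation-overlap, confusion-rate and full-reference image-quality metrics.

Overlap: Dice similarity coefficient DSC = 2TP / (2TP + FP + FN), its error
complement SVD = 1 - DSC, and the symmetric Hausdorff distance between mask
boundaries.  Confusion rates: sensitivity, specificity, PPV, NPV.  Image
quality: the nine full-reference indices AD, IQI, LMSE, MD, MSE, NAE, NK,
SC and SSIM, whose ideal values on identical images are (0, 1, 0, 0, 0, 0,
1, 1, 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.metrics import structural_similarity

from .volume_io import Volume

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "dice",
    "svd",
    "hausdorff",
    "confusion_rates",
    "confusion_from_labels",
    "quality_indices",
    "full_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    """Named collection of metrics for one comparison; absent = None.

    A rate whose denominator is zero is reported as None (an explicit
    undefined marker) rather than NaN.
    """

    dsc: float | None = None
    svd: float | None = None
    hd_mm: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    ad: float | None = None
    iqi: float | None = None
    lmse: float | None = None
    md: float | None = None
    mse: float | None = None
    nae: float | None = None
    nk: float | None = None
    sc: float | None = None
    ssim: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def merged(self, other: "MetricReport") -> "MetricReport":
        out = MetricReport(**self.to_dict())
        for k, v in other.to_dict().items():
            if v is not None:
                setattr(out, k, v)
        return out


def _check_same_grid(a: Volume, b: Volume, need_spacing: bool = False) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if need_spacing and a.spacing != b.spacing:
        raise ValueError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


def dice(a: Volume, b: Volume) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|).

    Two empty masks are in perfect agreement: DSC = 1 by convention.
    """
    _check_same_grid(a, b)
    ma, mb = a.mask_array(), b.mask_array()
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / denom


def svd(a: Volume, b: Volume) -> float:
    """Symmetric volume difference, the Dice error complement 1 - DSC."""
    return 1.0 - dice(a, b)


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask)
    return np.argwhere(mask & ~eroded)


def hausdorff(a: Volume, b: Volume, units: str = "mm") -> float:
    """Symmetric Hausdorff distance between the two mask boundaries.

    ``max(h(A, B), h(B, A))`` with the directed distance
    ``h(A, B) = max_{p in A} min_{q in B} ||p - q||``, Euclidean over
    boundary voxel centers.  ``units`` selects world mm (spacing applied)
    or raw voxel indices.
    """
    if units not in ("mm", "voxels"):
        raise ValueError(f"units must be 'mm' or 'voxels', got {units!r}")
    _check_same_grid(a, b, need_spacing=(units == "mm"))
    ma, mb = a.mask_array(), b.mask_array()
    if not ma.any() or not mb.any():
        raise ValueError("Hausdorff distance undefined for an empty mask")
    pa = _boundary_voxels(ma).astype(float)
    pb = _boundary_voxels(mb).astype(float)
    if units == "mm":
        pa *= np.asarray(a.spacing)
        pb *= np.asarray(b.spacing)
    h_ab = cKDTree(pb).query(pa)[0].max()
    h_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(h_ab, h_ba))


def _rate(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_rates(counts: ConfusionCounts) -> MetricReport:
    """Sensitivity, specificity, PPV and NPV from confusion counts."""
    return MetricReport(
        sensitivity=_rate(counts.tp, counts.tp + counts.fn),
        specificity=_rate(counts.tn, counts.tn + counts.fp),
        ppv=_rate(counts.tp, counts.tp + counts.fp),
        npv=_rate(counts.tn, counts.tn + counts.fn),
    )


def confusion_from_labels(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int | None = None
) -> MetricReport:
    """Multiclass confusion rates, one-vs-rest and macro-averaged.

    Each class is reduced to a binary problem (this class vs the rest); the
    four rates are averaged over classes, skipping classes whose rate is
    undefined (zero denominator).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have the same shape")
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    acc: dict[str, list[float]] = {k: [] for k in
                                   ("sensitivity", "specificity", "ppv", "npv")}
    for c in range(n_classes):
        t, p = y_true == c, y_pred == c
        counts = ConfusionCounts(
            tp=int((t & p).sum()), fp=int((~t & p).sum()),
            fn=int((t & ~p).sum()), tn=int((~t & ~p).sum()),
        )
        rep = confusion_rates(counts)
        for k in acc:
            v = getattr(rep, k)
            if v is not None:
                acc[k].append(v)
    return MetricReport(
        **{k: (float(np.mean(v)) if v else None) for k, v in acc.items()}
    )


def _laplacian6(f: np.ndarray) -> np.ndarray:
    """Discrete 6-neighbor 3D Laplacian on interior voxels."""
    return (
        f[:-2, 1:-1, 1:-1] + f[2:, 1:-1, 1:-1]
        + f[1:-1, :-2, 1:-1] + f[1:-1, 2:, 1:-1]
        + f[1:-1, 1:-1, :-2] + f[1:-1, 1:-1, 2:]
        - 6.0 * f[1:-1, 1:-1, 1:-1]
    )


def quality_indices(ref: Volume, test: Volume) -> MetricReport:
    """The nine full-reference image-quality indices, reference first.

    AD = mean(ref - test); MD = max |ref - test|; MSE = mean((ref - test)^2);
    NAE = sum|ref - test| / sum|ref|; NK = sum(ref * test) / sum(ref^2);
    SC = sum(ref^2) / sum(test^2); LMSE uses the 6-neighbor Laplacian on
    interior voxels; IQI is the universal quality index over a single global
    window; SSIM uses uniform 7-voxel sliding windows with the standard
    stabilizing constants (0.01 L)^2 and (0.03 L)^2, L the data range.
    Ratios with zero denominator are reported as None.
    """
    _check_same_grid(ref, test)
    r = ref.data.astype(np.float64)
    t = test.data.astype(np.float64)
    d = r - t

    ad = float(d.mean())
    md = float(np.abs(d).max())
    mse = float((d**2).mean())
    sum_abs_r = float(np.abs(r).sum())
    nae = float(np.abs(d).sum() / sum_abs_r) if sum_abs_r > 0 else None
    sum_r2 = float((r**2).sum())
    nk = float((r * t).sum() / sum_r2) if sum_r2 > 0 else None
    sum_t2 = float((t**2).sum())
    sc = float(sum_r2 / sum_t2) if sum_t2 > 0 else None

    lmse: float | None = None
    if min(r.shape) >= 3:
        lr, lt = _laplacian6(r), _laplacian6(t)
        denom = float((lr**2).sum())
        lmse = float(((lr - lt) ** 2).sum() / denom) if denom > 0 else None

    # universal quality index, single global window
    mr, mt = r.mean(), t.mean()
    vr, vt = r.var(), t.var()
    cov = ((r - mr) * (t - mt)).mean()
    iqi_den = (vr + vt) * (mr**2 + mt**2)
    iqi = float(4 * cov * mr * mt / iqi_den) if iqi_den > 0 else None

    data_range = float(max(r.max(), t.max()) - min(r.min(), t.min()))
    if data_range == 0:
        ssim = 1.0 if np.array_equal(r, t) else None
    else:
        win = min(7, min(s - (s + 1) % 2 for s in r.shape))  # odd, fits grid
        ssim = float(
            structural_similarity(
                r, t, win_size=win, data_range=data_range,
                gaussian_weights=False,
            )
        )
    return MetricReport(
        ad=ad, iqi=iqi, lmse=lmse, md=md, mse=mse, nae=nae, nk=nk, sc=sc,
        ssim=ssim,
    )


def full_report(
    truth: Volume, pred: Volume, hd_units: str = "mm"
) -> MetricReport:
    """Overlap + voxelwise confusion + quality battery for two mask volumes."""
    _check_same_grid(truth, pred)
    mt, mp = truth.mask_array(), pred.mask_array()
    counts = ConfusionCounts(
        tp=int((mt & mp).sum()), fp=int((~mt & mp).sum()),
        fn=int((mt & ~mp).sum()), tn=int((~mt & ~mp).sum()),
    )
    rep = confusion_rates(counts).merged(quality_indices(truth, pred))
    rep.dsc = dice(truth, pred)
    rep.svd = 1.0 - rep.dsc
    if mt.any() and mp.any():
        rep.hd_mm = hausdorff(truth, pred, units=hd_units)
    return rep
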