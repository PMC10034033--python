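"""Map fidelity, surrogate lesion segmentation and agreement statistics.

Fidelity is MSE/PSNR on normalized maps.  Lesions are segmented with a
deterministic threshold rule standing in for manual raters: the ischemic
core is low CBV relative to the brain median, the total hypoperfused
territory is long TTP or low CBF, and the penumbra is their mismatch.
Agreement between paired volume series is summarized with Pearson r,
Bland-Altman limits, the coefficient of repeatability (1.96 x sd of the
paired differences), ICC (one-way random, average measures) and, across
three or more series, the Friedman test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy import stats

from .core import LesionMasks, ParamMaps

__all__ = [
    "SegmentationThresholds",
    "AgreementReport",
    "map_mse",
    "map_psnr",
    "segment_lesions",
    "dice",
    "lesion_volume",
    "bland_altman",
    "coefficient_of_repeatability",
    "icc_1k",
    "agreement_stats",
    "bland_altman_plot",
]


# ---------------------------------------------------------------------------
# fidelity

def map_mse(pred_map, gt_map, mask=None) -> float:
    """Mean squared difference of two normalized maps over ``mask``."""
    pred_map = np.asarray(pred_map, dtype=float)
    gt_map = np.asarray(gt_map, dtype=float)
    if pred_map.shape != gt_map.shape:
        raise ValueError("maps must share a shape")
    if mask is None:
        mask = np.ones(pred_map.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty evaluation mask")
    d = pred_map[mask] - gt_map[mask]
    return float(np.mean(d * d))


def map_psnr(mse: float) -> float:
    """PSNR in dB for unit-range maps: 10 log10(1 / MSE); inf for MSE = 0."""
    if mse < 0:
        raise ValueError("MSE cannot be negative")
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(1.0 / mse))


# ---------------------------------------------------------------------------
# segmentation surrogate

@dataclass
class SegmentationThresholds:
    core_cbv_frac: float = 0.6      # core: CBV below this fraction of median
    hypo_cbf_frac: float = 0.6      # hypoperfusion: CBF below this fraction
    hypo_ttp_delta_s: float = 2.0   # ... or TTP above median by this much
    min_size_voxels: int = 32       # remove smaller connected components
    erode_mask_voxels: int = 1      # drop partial-volume brain-edge voxels


def _drop_small_components(mask, min_size):
    labeled, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labeled.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labeled]


def segment_lesions(maps: ParamMaps, brain_mask,
                    thresholds: SegmentationThresholds | None = None,
                    voxel_spacing=(1.0, 1.0, 1.0)) -> LesionMasks:
    """Threshold-surrogate segmentation of core and hypoperfused territory.

    Thresholds are relative to the median over the brain mask, so the rule
    transfers across subjects with different absolute perfusion levels.
    """
    th = thresholds or SegmentationThresholds()
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("empty brain mask")
    if th.erode_mask_voxels > 0:
        # partial-volume voxels at the brain edge read low on smoothed maps
        # and would otherwise segment as a spurious rim lesion
        structure = np.zeros((3, 3, 3), dtype=bool)
        structure[:, :, 1] = True  # in-plane erosion only (thick slices)
        eroded = ndi.binary_erosion(brain_mask, structure=structure,
                                    iterations=th.erode_mask_voxels)
        if eroded.any():
            brain_mask = eroded
    cbv, cbf, ttp = maps["cbv"], maps["cbf"], maps["ttp"]
    med_cbv = np.median(cbv[brain_mask])
    med_cbf = np.median(cbf[brain_mask])
    med_ttp = np.median(ttp[brain_mask])

    core = brain_mask & (cbv < th.core_cbv_frac * med_cbv)
    hypo = brain_mask & ((ttp > med_ttp + th.hypo_ttp_delta_s)
                         | (cbf < th.hypo_cbf_frac * med_cbf))
    if th.min_size_voxels > 1:
        core = _drop_small_components(core, th.min_size_voxels)
        hypo = _drop_small_components(hypo, th.min_size_voxels)
    hypo |= core  # the core is by definition hypoperfused
    n_brain = brain_mask.sum()
    if hypo.sum() in (0, n_brain):
        warnings.warn("degenerate segmentation: all-normal or all-lesion")
    return LesionMasks(core=core, hypoperfused=hypo,
                       voxel_spacing=voxel_spacing)


def dice(mask_a, mask_b) -> float:
    """Dice similarity 2|A&B| / (|A|+|B|); two empty masks count as 1.0."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def lesion_volume(mask, spacing) -> float:
    """Mask volume in cm^3 (voxel count x voxel volume)."""
    spacing = [float(s) for s in spacing]
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    voxel_mm3 = spacing[0] * spacing[1] * spacing[2]
    return float(np.asarray(mask, dtype=bool).sum() * voxel_mm3 / 1000.0)


# ---------------------------------------------------------------------------
# agreement statistics

@dataclass
class AgreementReport:
    pearson_r: float
    pearson_p: float
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    cr: float
    icc: float | None = None
    icc_ci: tuple | None = None
    friedman_stat: float | None = None
    friedman_p: float | None = None
    n: int = 0


def bland_altman(vols_a, vols_b):
    """(mean difference, sd of differences, lower LoA, upper LoA)."""
    a = np.asarray(vols_a, dtype=float)
    b = np.asarray(vols_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equally long 1-D series")
    d = a - b
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return (mean_diff, sd_diff,
            mean_diff - 1.96 * sd_diff, mean_diff + 1.96 * sd_diff)


def coefficient_of_repeatability(vols_a, vols_b) -> float:
    """CR = 1.96 x sd of the paired differences."""
    _, sd_diff, _, _ = bland_altman(vols_a, vols_b)
    return 1.96 * sd_diff


def icc_1k(series) -> tuple:
    """One-way random, average-measures ICC (ICC1k) with its 95% CI.

    ``series`` is a sequence of equally long rating vectors (one per
    method/rater).  Returns (icc, (ci_low, ci_high)).
    """
    import pingouin as pg
    series = [np.asarray(s, dtype=float) for s in series]
    n = series[0].size
    long = pd.DataFrame({
        "targets": np.tile(np.arange(n), len(series)),
        "raters": np.repeat(np.arange(len(series)), n),
        "scores": np.concatenate(series),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(data=long, targets="targets",
                                 raters="raters", ratings="scores")
    sel = res[res["Type"].isin(["ICC1k", "ICC(1,k)"])]  # name varies by version
    row = sel.iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    return float(row["ICC"]), tuple(np.asarray(row[ci_col], dtype=float))


def agreement_stats(vols_a, vols_b, extra_series=None) -> AgreementReport:
    """Full agreement battery between two paired volume series.

    ``extra_series``: optional additional series; when the total number of
    series is >= 3 a Friedman test across all of them is included, and the
    ICC is computed over all series rather than just the first two.
    """
    a = np.asarray(vols_a, dtype=float)
    b = np.asarray(vols_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need paired series with n >= 3")

    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant series: Pearson r undefined")
        r, p = float("nan"), float("nan")
    else:
        r, p = stats.pearsonr(a, b)
    mean_diff, sd_diff, lo, hi = bland_altman(a, b)
    cr = 1.96 * sd_diff

    series = [a, b] + [np.asarray(s, dtype=float) for s in (extra_series or [])]
    icc, ci = icc_1k(series)
    fr_stat = fr_p = None
    if len(series) >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fr_stat, fr_p = stats.friedmanchisquare(*series)
        if np.isnan(fr_stat):  # fully tied ranks (identical methods)
            fr_stat, fr_p = 0.0, 1.0
        fr_stat, fr_p = float(fr_stat), float(fr_p)

    return AgreementReport(pearson_r=float(r), pearson_p=float(p),
                           mean_diff=mean_diff, sd_diff=sd_diff,
                           loa_low=lo, loa_high=hi, cr=cr,
                           icc=icc, icc_ci=ci,
                           friedman_stat=fr_stat, friedman_p=fr_p,
                           n=int(a.size))


def bland_altman_plot(vols_a, vols_b, path, title=""):
    """Write a Bland-Altman plot (PNG/SVG chosen by file extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(vols_a, dtype=float)
    b = np.asarray(vols_b, dtype=float)
    mean_diff, sd_diff, lo, hi = bland_altman(a, b)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2.0, a - b, s=18)
    for yv, style in ((mean_diff, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(yv, color="k", linestyle=style, linewidth=0.8)
    ax.set_xlabel("mean of methods (cm$^3$)")
    ax.set_ylabel("difference (cm$^3$)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
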