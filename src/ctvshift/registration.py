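"""Intensity-based rigid matching: the clinical grey-value comparator.

Estimates the in-plane translation between a reference (planning) and a
moving (pretreatment) image by exhaustively searching integer-pixel
translations that maximize the correlation ratio of intensities within a
region of interest (typically the CTV plus a 5 mm margin), followed by
quadratic sub-pixel refinement.  This mirrors soft-tissue "grey value
match" registration on clinical IGRT systems and serves as the comparator
the feature-based predictions are measured against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Contour
from .raster import Image2D, fill_mask


def correlation_ratio(reference: np.ndarray, moving: np.ndarray) -> float:
    """eta^2 of reference intensities explained by moving-intensity classes.

    eta^2 = 1 - E[Var(ref | moving level)] / Var(ref); 1 means the
    reference is a deterministic function of the moving intensities.
    """
    ref = np.asarray(reference, dtype=float).ravel()
    mov = np.asarray(moving, dtype=float).ravel()
    if ref.size != mov.size or ref.size == 0:
        raise ValueError("intensity arrays must be non-empty and equal-sized")
    total_var = ref.var()
    if total_var <= 0:
        return 1.0
    _, inverse = np.unique(mov, return_inverse=True)
    n_groups = inverse.max() + 1
    counts = np.bincount(inverse, minlength=n_groups)
    sums = np.bincount(inverse, weights=ref, minlength=n_groups)
    sq_sums = np.bincount(inverse, weights=ref * ref, minlength=n_groups)
    within = sq_sums - sums * sums / counts
    return float(1.0 - within.sum() / (ref.size * total_var))


@dataclass
class MatchResult:
    si: float
    ap: float
    score: float
    score_grid: np.ndarray
    offsets_px: np.ndarray


def grey_value_match(reference: Image2D, moving: Image2D, roi: Contour,
                     search_mm: float = 15.0) -> MatchResult:
    """Estimate the (si, ap) translation of ``moving`` relative to ``reference``.

    Both images must share pixel size and grid origin.  For each candidate
    translation t the moving image is resampled at x - t and compared with
    the reference inside the ROI, so the returned shift is the anatomy's
    displacement: if the moving image is the reference translated by t,
    the estimate is t.  Ties prefer the smallest |shift|; the integer
    optimum is refined per axis by a parabola through its neighbors unless
    the match is already perfect there.
    """
    if reference.pixel_size_mm != moving.pixel_size_mm:
        raise ValueError("images must share a pixel size")
    if (reference.origin.a, reference.origin.s) != (moving.origin.a, moving.origin.s) \
            or reference.shape != moving.shape:
        raise ValueError("images must share a grid (origin and shape)")
    px = reference.pixel_size_mm
    r = int(round(search_mm / px))
    mask = fill_mask(roi, reference)
    rows, cols = np.where(mask)
    if rows.size == 0:
        raise ValueError("ROI covers no pixels")
    if (rows.min() - r < 0 or cols.min() - r < 0
            or rows.max() + r >= reference.shape[0]
            or cols.max() + r >= reference.shape[1]):
        raise ValueError("ROI plus search range exceeds the image; enlarge padding")
    ref_vals = reference.pixels[rows, cols]
    offsets = np.arange(-r, r + 1)
    scores = np.empty((offsets.size, offsets.size))
    for ii, ds in enumerate(offsets):        # row offset: SI, pixels
        for jj, da in enumerate(offsets):    # col offset: AP, pixels
            mov_vals = moving.pixels[rows + ds, cols + da]
            scores[ii, jj] = correlation_ratio(ref_vals, mov_vals)
    # best score, ties broken toward the smallest shift magnitude
    flat = scores.ravel()
    best = flat.max()
    cand = np.flatnonzero(flat >= best - 1e-12)
    ci, cj = np.unravel_index(cand, scores.shape)
    norms = offsets[ci] ** 2 + offsets[cj] ** 2
    pick = cand[np.argmin(norms)]
    bi, bj = np.unravel_index(pick, scores.shape)

    def refine(idx: int, axis_scores: np.ndarray) -> float:
        if axis_scores[idx] >= 1.0 - 1e-12 or idx == 0 or idx == len(axis_scores) - 1:
            return 0.0
        lo, mid, hi = axis_scores[idx - 1], axis_scores[idx], axis_scores[idx + 1]
        denom = lo - 2.0 * mid + hi
        if abs(denom) < 1e-15:
            return 0.0
        return float(np.clip(0.5 * (lo - hi) / denom, -0.5, 0.5))

    ds_px = offsets[bi] + refine(bi, scores[:, bj])
    da_px = offsets[bj] + refine(bj, scores[bi, :])
    # moving sampled at x - t matches reference when t = anatomy shift,
    # and sampling at x - t means indexing at +t: recover t directly.
    return MatchResult(si=float(ds_px * px), ap=float(da_px * px),
                       score=float(best), score_grid=scores,
                       offsets_px=offsets)
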