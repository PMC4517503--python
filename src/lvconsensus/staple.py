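"""STAPLE label fusion of multi-reader contour masks.

Simultaneous Truth and Performance Level Estimation: an EM algorithm that
fuses R binary rater masks into a consensus probability map W (the
conditional probability that a cell is foreground given the rater
decisions) while estimating each rater's sensitivity p_j and specificity
q_j.  The voting map initializes W; a scalar prior (the ROI mean of the
voting map) replaces the usual spatial prior; EM alternates

  M-step:  p_j = sum_i W_i D_ij / sum_i W_i
           q_j = sum_i (1-W_i)(1-D_ij) / sum_i (1-W_i)
  E-step:  W_i = a_i / (a_i + b_i),
           a_i = prior * prod_j p_j^D_ij (1-p_j)^(1-D_ij)
           b_i = (1-prior) * prod_j (1-q_j)^D_ij q_j^(1-D_ij)

until the mean absolute change in W drops below tolerance.  Computation is
restricted to a region of interest (union of rater masks dilated by a
physical margin): an unbounded background otherwise inflates specificity
toward one and washes out the sensitivity weighting.

Internally the EM runs over the distinct reader-decision patterns (at most
2^R of them) with cell-count weights; this is an exact reformulation of
the per-cell iteration, since cells with identical decision vectors share
W, and it makes the cost independent of grid size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .contour_model import (
    BinaryMask,
    Contour,
    SliceGeometry,
    extract_contour,
    rasterize,
)

_EPS = 1e-6


@dataclass
class StapleParams:
    """EM controls: prior choice, convergence tolerance, ROI margin."""

    prior_mode: Union[str, float] = "voting_mean"
    convergence_tol: float = 1e-6
    max_iter: int = 100
    roi_margin_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.roi_margin_mm < 0:
            raise ValueError("roi_margin_mm must be >= 0")
        if isinstance(self.prior_mode, str):
            if self.prior_mode != "voting_mean":
                raise ValueError(f"unknown prior_mode {self.prior_mode!r}")
        elif not (0.0 < float(self.prior_mode) < 1.0):
            raise ValueError("fixed prior must lie in (0, 1)")


@dataclass
class StapleResult:
    """Fusion output: consensus probabilities, rater performance, trace."""

    W: np.ndarray
    p: np.ndarray
    q: np.ndarray
    n_iter: int
    converged: bool
    trace: np.ndarray
    prior: float
    roi: np.ndarray
    reader_ids: list = field(default_factory=list)
    consensus_contour: Optional[Contour] = None


def majority_vote(masks: Sequence[BinaryMask]) -> np.ndarray:
    """Per-cell fraction of masks marking the cell foreground."""
    if len(masks) < 1:
        raise ValueError("need at least one mask")
    shape = masks[0].grid.shape
    for m in masks[1:]:
        if m.grid.shape != shape or m.factor != masks[0].factor:
            raise ValueError("masks must share an identical grid")
    stack = np.stack([m.grid for m in masks]).astype(float)
    return stack.mean(axis=0)


def _clamped_log(v: np.ndarray) -> np.ndarray:
    return np.log(np.clip(v, _EPS, 1.0 - _EPS))


def _posterior(D, p, q, prior):
    """log a_i, log b_i for decision matrix D (R, n)."""
    D = np.asarray(D, dtype=float)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    log_a = (np.log(np.clip(prior, _EPS, 1 - _EPS))
             + D.T @ _clamped_log(p) + (1.0 - D).T @ _clamped_log(1.0 - p))
    log_b = (np.log(np.clip(1.0 - prior, _EPS, 1 - _EPS))
             + D.T @ _clamped_log(1.0 - q) + (1.0 - D).T @ _clamped_log(q))
    return log_a, log_b


def e_step(D: np.ndarray, p: np.ndarray, q: np.ndarray, prior: float) -> np.ndarray:
    """Consensus probability per cell given rater decisions and (p, q).

    ``D`` has shape (R, n_cells); degenerate p, q are clamped to
    [eps, 1-eps] so perfectly agreeing raters do not produce log(0).
    """
    log_a, log_b = _posterior(D, p, q, prior)
    m = np.maximum(log_a, log_b)
    ea, eb = np.exp(log_a - m), np.exp(log_b - m)
    return ea / (ea + eb)


def m_step(D: np.ndarray, W: np.ndarray,
           weights: Optional[np.ndarray] = None) -> tuple[np.ndarray, np.ndarray]:
    """Sensitivity and specificity of each rater given consensus weights W.

    ``weights`` (optional, per-cell multiplicities) supports the
    pattern-compressed EM; omitted means unit weight per cell.
    """
    D = np.asarray(D, dtype=float)
    W = np.asarray(W, dtype=float)
    w = np.ones_like(W) if weights is None else np.asarray(weights, dtype=float)
    fg = W * w
    bg = (1.0 - W) * w
    denom_fg = fg.sum()
    denom_bg = bg.sum()
    if denom_fg <= 0:
        warnings.warn("no consensus foreground mass; sensitivity clamped")
        p = np.full(D.shape[0], 1.0 - _EPS)
    else:
        p = (D @ fg) / denom_fg
    if denom_bg <= 0:
        warnings.warn("no consensus background mass; specificity clamped")
        q = np.full(D.shape[0], 1.0 - _EPS)
    else:
        q = ((1.0 - D) @ bg) / denom_bg
    return p, q


def _log_likelihood(D, p, q, prior, weights) -> float:
    log_a, log_b = _posterior(D, p, q, prior)
    return float(np.sum(weights * np.logaddexp(log_a, log_b)))


def _roi_from_union(union: np.ndarray, geometry: SliceGeometry, factor: int,
                    margin_mm: float) -> np.ndarray:
    """Union of rater masks dilated by a physical margin (exact EDT)."""
    if margin_mm == 0:
        return union.copy()
    dx, dy = geometry.pixel_size_mm
    ch, cw = dy / factor, dx / factor
    rows = np.flatnonzero(union.any(axis=1))
    cols = np.flatnonzero(union.any(axis=0))
    pad_r = int(np.ceil(margin_mm / ch)) + 1
    pad_c = int(np.ceil(margin_mm / cw)) + 1
    r0 = max(0, rows[0] - pad_r)
    r1 = min(union.shape[0], rows[-1] + pad_r + 1)
    c0 = max(0, cols[0] - pad_c)
    c1 = min(union.shape[1], cols[-1] + pad_c + 1)
    sub = union[r0:r1, c0:c1]
    dist = ndimage.distance_transform_edt(~sub, sampling=(ch, cw))
    roi = np.zeros_like(union)
    roi[r0:r1, c0:c1] = dist <= margin_mm
    return roi


def staple_fuse(masks: Sequence[BinaryMask],
                params: Optional[StapleParams] = None,
                geometry: Optional[SliceGeometry] = None) -> StapleResult:
    """Fuse >= 2 rater masks on identical grids into a StapleResult.

    ``geometry`` is needed only to express the ROI margin in mm; without it
    the margin is interpreted with unit cells of 1 mm.
    """
    params = params or StapleParams()
    if len(masks) < 2:
        raise ValueError("need at least two masks to fuse")
    shape = masks[0].grid.shape
    factor = masks[0].factor
    for m in masks[1:]:
        if m.grid.shape != shape or m.factor != factor:
            raise ValueError("masks must share an identical grid")
    grids = np.stack([np.asarray(m.grid, dtype=bool) for m in masks])
    R = len(masks)
    union = grids.any(axis=0)
    if not union.any():
        # no rater marked anything: empty consensus, vacuous performance
        return StapleResult(
            W=np.zeros(shape), p=np.full(R, 1.0 - _EPS), q=np.full(R, 1.0 - _EPS),
            n_iter=0, converged=True, trace=np.array([]), prior=_EPS,
            roi=np.zeros(shape, dtype=bool),
        )
    if geometry is not None:
        roi = _roi_from_union(union, geometry, factor, params.roi_margin_mm)
    else:
        unit = SliceGeometry((1.0, 1.0), 1.0, 1.0, shape[0], shape[1], 1)
        roi = _roi_from_union(union, unit, 1, params.roi_margin_mm)

    D_cells = grids[:, roi]  # (R, n_roi)
    codes = np.zeros(D_cells.shape[1], dtype=np.uint64)
    for j in range(R):
        codes |= D_cells[j].astype(np.uint64) << np.uint64(j)
    uniq, inverse, counts = np.unique(codes, return_inverse=True, return_counts=True)
    bits = (uniq[:, None] >> np.arange(R, dtype=np.uint64)) & np.uint64(1)
    D = bits.T.astype(float)  # (R, n_patterns)
    weights = counts.astype(float)
    n_cells = weights.sum()

    W = D.mean(axis=0)  # voting initialization, per pattern
    if params.prior_mode == "voting_mean":
        prior = float(np.clip(np.average(W, weights=weights), _EPS, 1.0 - _EPS))
    else:
        prior = float(params.prior_mode)

    trace: list[float] = []
    converged = False
    n_iter = 0
    p = q = np.full(R, 0.5)
    for n_iter in range(1, params.max_iter + 1):
        p, q = m_step(D, W, weights=weights)
        W_new = e_step(D, p, q, prior)
        trace.append(_log_likelihood(D, p, q, prior, weights))
        delta = float(np.sum(weights * np.abs(W_new - W)) / n_cells)
        W = W_new
        if delta < params.convergence_tol:
            converged = True
            break

    W_grid = np.zeros(shape, dtype=float)
    W_grid[roi] = W[inverse]
    return StapleResult(
        W=W_grid, p=np.asarray(p), q=np.asarray(q), n_iter=n_iter,
        converged=converged, trace=np.asarray(trace), prior=prior, roi=roi,
    )


def consensus_for_slice(
    contours_by_reader: Mapping[str, Contour],
    geometry: SliceGeometry,
    params: Optional[StapleParams] = None,
    factor: int = 4,
    min_readers: int = 4,
    threshold: float = 0.5,
) -> Optional[tuple[Optional[Contour], StapleResult]]:
    """STAPLE consensus for one (frame, slice, surface) key.

    Returns None when fewer than ``min_readers`` readers contoured the
    slice (the most-of-the-readers rule); otherwise the extracted consensus
    contour together with the fusion diagnostics.
    """
    if len(contours_by_reader) < min_readers:
        return None
    reader_ids = list(contours_by_reader)
    contours = [contours_by_reader[r] for r in reader_ids]
    key = contours[0].key
    for c in contours[1:]:
        if c.key != key:
            raise ValueError(f"contours on mixed keys: {c.key} vs {key}")
    masks = [rasterize(c, geometry, factor) for c in contours]
    result = staple_fuse(masks, params, geometry=geometry)
    result.reader_ids = reader_ids
    frame, s, surface = key
    result.consensus_contour = extract_contour(
        result.W, geometry, factor=factor, threshold=threshold,
        frame=frame, slice_index=s, surface=surface,
    )
    return result.consensus_contour, result


@dataclass
class FusionOutput:
    """Per-case consensus set plus per-slice diagnostics and skipped keys."""

    consensus: "StudyContourSet"
    diagnostics: pd.DataFrame
    skipped: list


def fuse_contour_sets(
    reader_sets: Sequence,
    params: Optional[StapleParams] = None,
    factor: int = 4,
    min_readers: int = 4,
    threshold: float = 0.5,
) -> FusionOutput:
    """Fuse all slice keys of one case across readers, independently per key.

    Keys contoured by fewer than ``min_readers`` readers are skipped and
    listed; the consensus set carries source_id "consensus".
    """
    from .contour_model import StudyContourSet  # local import avoids cycle

    if len(reader_sets) < 2:
        raise ValueError("need at least two reader sets")
    geometry = reader_sets[0].geometry
    case_id = reader_sets[0].case_id
    for rs in reader_sets[1:]:
        if rs.geometry != geometry or rs.case_id != case_id:
            raise ValueError("reader sets must share case and geometry")
    all_keys = sorted({k for rs in reader_sets for k in rs.contours})
    consensus = StudyContourSet(case_id=case_id, source_id="consensus",
                                geometry=geometry)
    rows = []
    skipped = []
    for key in all_keys:
        frame, s, surface = key
        present = {rs.source_id: rs.contours[key]
                   for rs in reader_sets if key in rs.contours}
        fused = consensus_for_slice(present, geometry, params=params,
                                    factor=factor, min_readers=min_readers,
                                    threshold=threshold)
        if fused is None or fused[0] is None:
            skipped.append(key)
            continue
        contour, result = fused
        consensus.add(contour)
        row = {"case_id": case_id, "frame": frame, "slice_index": s,
               "surface": surface, "n_readers": len(present),
               "n_iter": result.n_iter, "converged": result.converged}
        for rid, pj, qj in zip(result.reader_ids, result.p, result.q):
            row[f"p_{rid}"] = pj
            row[f"q_{rid}"] = qj
        rows.append(row)
    diagnostics = pd.DataFrame(rows)
    return FusionOutput(consensus=consensus, diagnostics=diagnostics,
                        skipped=skipped)
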