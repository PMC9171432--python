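"""Mechano-regulation statistics on surface remodeling events.

The substrate of every statistic is the *surface event table*: one row per
eligible surface voxel of an interval, carrying its anatomical region, its
density band, its normalized effective strain at the interval's start
(stimulus precedes response) and the observed event -- formation,
quiescence or resorption.  Effective strain is normalized to the 99th
percentile over the whole simulation region, so roughly 1% of voxels
exceed 1.

Three readouts quantify mechano-regulation:

* conditional probability of each event as a function of the normalized
  effective strain bin (the empirical "mechano-stat" curve);
* ROC AUC of strain as a score for formation (and, among quiescent bone
  voxels, for mineralization), where 0.5 means no association;
* the two-threshold correct-classification-rate (CCR) sweep: strain at or
  below a lower threshold predicts resorption, at or above an upper
  threshold predicts formation, in between quiescence.  CCR is the
  unweighted mean of the three per-class recalls (balanced accuracy), so
  its chance level is 33% regardless of class imbalance.

`MechanoregulationModel` bundles the three readouts behind a fit() /
results / summary() interface; the underlying functions remain available
for direct use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .images import BandedImage, RegionMasks
from .microfe import StrainField
from .remodeling import RemodelingMap, surface_candidates

__all__ = [
    "build_event_table",
    "conditional_probability",
    "roc_auc",
    "ccr_sweep",
    "per_band_summary",
    "ConditionalProbabilityCurve",
    "ROCResult",
    "CCRMatrix",
    "MechanoregulationModel",
    "MechanoregulationResults",
]

_REGION_CODE_TO_NAME = {1: "cortical", 2: "medullary", 3: "peripheral"}


def build_event_table(
    strain: StrainField,
    remodel: RemodelingMap,
    masks: RegionMasks,
    banded_prev: BandedImage,
    *,
    exclude: Optional[np.ndarray] = None,
    interval: Optional[tuple[int, int]] = None,
    subject: Optional[str] = None,
) -> pd.DataFrame:
    """One row per eligible surface voxel at the interval's start.

    Surface voxels are formation candidates (soft tissue face-adjacent to
    bone) and resorption candidates (bone with a non-bone face
    neighbour).  ``eps_norm`` is effective strain over the 99th percentile
    of the simulation region (optionally excluding e.g. the cap plate).
    Candidates without an observed event are recorded as quiescence.
    """
    shape = banded_prev.shape
    if strain.shape != shape or remodel.state.shape != shape or masks.label.shape != shape:
        raise ValueError("strain, remodeling map, masks and banded image must be aligned")
    eps = np.asarray(strain.effective_strain, dtype=float)
    region_sel = masks.label != RegionMasks.OUTSIDE
    if exclude is not None:
        region_sel &= ~np.asarray(exclude, dtype=bool)
    ref = eps[region_sel]
    p99 = float(np.percentile(ref, 99)) if ref.size else 0.0
    eps_norm = eps / p99 if p99 > 0 else np.zeros_like(eps)

    bone = banded_prev.bone_mask()
    form_cand, res_cand = surface_candidates(bone)
    surface = (form_cand | res_cand) & region_sel
    if not surface.any():
        warnings.warn("empty eligible surface set; returning empty table", stacklevel=2)
    idx = np.flatnonzero(surface)

    state = remodel.state.ravel()[idx]
    event = np.full(idx.size, "quiescence", dtype=object)
    event[(form_cand.ravel()[idx]) & (state == RemodelingMap.FORMATION)] = "formation"
    event[(res_cand.ravel()[idx]) & (state == RemodelingMap.RESORPTION)] = "resorption"

    band_prev = np.asarray(banded_prev.band_index).ravel()[idx]
    band_curr = np.asarray(remodel.band_curr).ravel()[idx]
    quiescent_bone = (band_prev >= 1) & (state == RemodelingMap.QUIESCENCE)
    mineralized = np.where(quiescent_bone, band_curr > band_prev, np.nan)

    region = np.array(
        [_REGION_CODE_TO_NAME.get(c, "outside") for c in masks.label.ravel()[idx]],
        dtype=object,
    )
    # band for density stratification: formed voxels are attributed to the
    # band they appear in, everything else to its band at the start
    band = np.where(event == "formation", band_curr, band_prev)
    table = pd.DataFrame(
        {
            "voxel": idx,
            "region": region,
            "band_prev": band_prev.astype(int),
            "band_curr": band_curr.astype(int),
            "band": band.astype(int),
            "eps_norm": eps_norm.ravel()[idx],
            "event": event,
            "mineralized": mineralized,
        }
    )
    if interval is not None:
        table["interval"] = [interval] * len(table)
    if subject is not None:
        table["subject"] = subject
    return table


@dataclass
class ConditionalProbabilityCurve:
    """p(formation / quiescence / resorption | strain bin)."""

    bin_edges: np.ndarray  # len n_bins + 1; last bin is the overflow > 1
    p_form: np.ndarray
    p_quiesc: np.ndarray
    p_res: np.ndarray
    counts: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def occupied(self) -> np.ndarray:
        """Bins with at least one observation (others hold NaN, not interpolated)."""
        return self.counts > 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
                "p_form": self.p_form,
                "p_quiesc": self.p_quiesc,
                "p_res": self.p_res,
            }
        )


def conditional_probability(
    table: pd.DataFrame, n_bins: int = 50, overflow: bool = True
) -> ConditionalProbabilityCurve:
    """Empirical event probabilities per normalized-strain bin.

    Bins cover [0, 1] uniformly; an overflow bin collects the ~1% of
    voxels with strain above the normalization percentile.  Per occupied
    bin the three probabilities sum to one exactly; empty bins are NaN.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if table.empty:
        raise ValueError("event table is empty")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    if overflow:
        hi = max(float(table["eps_norm"].max()), 1.0) + 1e-9
        edges = np.append(edges, hi)
    x = table["eps_norm"].to_numpy(dtype=float)
    which = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
    n_total = len(edges) - 1
    counts = np.bincount(which, minlength=n_total)
    out = {}
    for name in ("formation", "quiescence", "resorption"):
        sel = (table["event"] == name).to_numpy()
        with np.errstate(invalid="ignore"):
            out[name] = np.where(
                counts > 0, np.bincount(which[sel], minlength=n_total) / np.maximum(counts, 1), np.nan
            )
    return ConditionalProbabilityCurve(
        bin_edges=edges,
        p_form=out["formation"],
        p_quiesc=out["quiescence"],
        p_res=out["resorption"],
        counts=counts,
    )


@dataclass
class ROCResult:
    """ROC of normalized effective strain as a score for a binary event."""

    event_type: str  # "formation" | "mineralization"
    auc: float
    n_pos: int
    n_neg: int
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    stratum: dict = field(default_factory=dict)

    @property
    def auc_se(self) -> float:
        """Hanley-McNeil standard error of the AUC."""
        a, m, n = self.auc, self.n_pos, self.n_neg
        if m == 0 or n == 0 or not np.isfinite(a):
            return float("nan")
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        var = (a * (1 - a) + (m - 1) * (q1 - a * a) + (n - 1) * (q2 - a * a)) / (m * n)
        return float(np.sqrt(max(var, 0.0)))


def roc_auc(
    table: pd.DataFrame,
    event_type: str = "formation",
    stratum: Optional[dict] = None,
) -> Optional[ROCResult]:
    """AUC of strain for formation, or mineralization among quiescent bone.

    Ties are handled by the midpoint-rank (Mann-Whitney) convention.
    Returns None for single-class strata, where the AUC is undefined.
    """
    sub = table
    stratum = stratum or {}
    for key, val in stratum.items():
        sub = sub[sub[key] == val]
    if event_type == "formation":
        y = (sub["event"] == "formation").to_numpy()
        score = sub["eps_norm"].to_numpy(dtype=float)
    elif event_type == "mineralization":
        sub = sub[sub["mineralized"].notna()]
        y = sub["mineralized"].to_numpy(dtype=float) > 0.5
        score = sub["eps_norm"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown event_type {event_type!r}")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    auc = float(roc_auc_score(y, score))
    fpr, tpr, thr = roc_curve(y, score)
    return ROCResult(
        event_type=event_type, auc=auc, n_pos=n_pos, n_neg=n_neg,
        fpr=fpr, tpr=tpr, thresholds=thr, stratum=dict(stratum),
    )


@dataclass
class CCRMatrix:
    """Balanced correct-classification rate over all two-threshold pairs.

    ``ccr[i, j]`` is the rate at lower threshold ``grid[i]`` and upper
    threshold ``grid[j]``; cells with a lower threshold above the upper
    one are NaN.  The rate is the unweighted mean of per-class recalls
    over the classes present in the table, so the chance level for three
    classes is 1/3.
    """

    grid: np.ndarray
    ccr: np.ndarray  # (n_grid, n_grid), percent-free fraction in [0, 1]
    max_ccr: float
    argmax: tuple[float, float]  # (t_low, t_high)
    classes: tuple[str, ...]

    @property
    def max_ccr_percent(self) -> float:
        return 100.0 * self.max_ccr


def ccr_sweep(table: pd.DataFrame, n_grid: int = 100) -> CCRMatrix:
    """Sweep (lower, upper) strain threshold pairs for F/Q/R prediction.

    Prediction rule: strain >= upper threshold -> formation; else strain
    <= lower threshold -> resorption; else quiescence.  The grid spans
    [0, max strain] with ``n_grid`` points per axis.
    """
    if n_grid < 2:
        raise ValueError("n_grid must be at least 2")
    if table.empty:
        raise ValueError("event table is empty")
    x = table["eps_norm"].to_numpy(dtype=float)
    grid = np.linspace(0.0, float(x.max()), n_grid)
    class_names = ("resorption", "quiescence", "formation")
    present = [c for c in class_names if (table["event"] == c).any()]
    if not present:
        raise ValueError("no event classes present")

    recalls = np.zeros((len(present), n_grid, n_grid))
    for ci, cname in enumerate(present):
        e = np.sort(x[(table["event"] == cname).to_numpy()])
        n_c = e.size
        above = n_c - np.searchsorted(e, grid, side="left")  # #(e >= t)
        below = np.searchsorted(e, grid, side="right")  # #(e <= t)
        exact = below - np.searchsorted(e, grid, side="left")  # #(e == t)
        pred_f = np.broadcast_to(above[None, :], (n_grid, n_grid)).copy()
        pred_r = np.broadcast_to(below[:, None], (n_grid, n_grid)).copy()
        # on the diagonal the formation rule wins ties at the threshold
        np.fill_diagonal(pred_r, below - exact)
        pred_q = n_c - pred_f - pred_r
        if cname == "formation":
            correct = pred_f
        elif cname == "resorption":
            correct = pred_r
        else:
            correct = pred_q
        recalls[ci] = correct / n_c
    ccr = recalls.mean(axis=0)
    low_idx, high_idx = np.meshgrid(np.arange(n_grid), np.arange(n_grid), indexing="ij")
    ccr[low_idx > high_idx] = np.nan
    flat = np.nanargmax(ccr)
    i, j = np.unravel_index(flat, ccr.shape)
    return CCRMatrix(
        grid=grid,
        ccr=ccr,
        max_ccr=float(ccr[i, j]),
        argmax=(float(grid[i]), float(grid[j])),
        classes=tuple(present),
    )


def per_band_summary(
    table: pd.DataFrame,
    n_bands: int,
    *,
    n_grid: int = 100,
    regions: Sequence[str] = ("cortical", "medullary", "peripheral", "all"),
) -> pd.DataFrame:
    """Tidy long-format metrics per (subject, interval, region, band).

    'all' metrics are computed on pooled rows, never by averaging the
    region-wise results.  AUC entries are NaN where a stratum has a
    single class; CCR is swept within each stratum.
    """
    keys = [k for k in ("subject", "interval") if k in table.columns]
    rows = []
    grouped = table.groupby(keys, sort=False) if keys else [((), table)]
    for group_key, sub in grouped:
        if keys and not isinstance(group_key, tuple):
            group_key = (group_key,)
        base = dict(zip(keys, group_key))
        for region in regions:
            rsub = sub if region == "all" else sub[sub["region"] == region]
            for band in range(1, n_bands + 1):
                bsub = rsub[rsub["band"] == band]
                rec = dict(base, region=region, band=band, n_rows=len(bsub))
                if len(bsub):
                    roc = roc_auc(bsub, "formation")
                    rec["auc_formation"] = roc.auc if roc else np.nan
                    rocm = roc_auc(bsub, "mineralization")
                    rec["auc_mineralization"] = rocm.auc if rocm else np.nan
                    if bsub["event"].nunique() >= 2:
                        rec["max_ccr"] = ccr_sweep(bsub, n_grid).max_ccr
                    else:
                        rec["max_ccr"] = np.nan
                else:
                    rec["auc_formation"] = np.nan
                    rec["auc_mineralization"] = np.nan
                    rec["max_ccr"] = np.nan
                rows.append(rec)
    long = pd.DataFrame(rows)
    return long.melt(
        id_vars=keys + ["region", "band", "n_rows"],
        value_vars=["auc_formation", "auc_mineralization", "max_ccr"],
        var_name="metric",
        value_name="value",
    )


class MechanoregulationModel:
    """Mechano-regulation readouts of a surface event table.

    Parameters
    ----------
    table:
        Surface event table from `build_event_table` (rows may be pooled
        over intervals and subjects).
    n_bins:
        Strain bins for the conditional-probability curve (default 50
        over [0, 1], i.e. 2% of the maximum strain per bin, plus an
        overflow bin).
    n_grid:
        Grid resolution per axis of the two-threshold CCR sweep.
    """

    def __init__(self, table: pd.DataFrame, n_bins: int = 50, n_grid: int = 100):
        if table.empty:
            raise ValueError("event table is empty")
        self.table = table
        self.n_bins = n_bins
        self.n_grid = n_grid

    @classmethod
    def from_images(
        cls,
        strain: StrainField,
        remodel: RemodelingMap,
        masks: RegionMasks,
        banded_prev: BandedImage,
        **kwargs,
    ) -> "MechanoregulationModel":
        table = build_event_table(strain, remodel, masks, banded_prev)
        return cls(table, **kwargs)

    def fit(self) -> "MechanoregulationResults":
        curve = conditional_probability(self.table, self.n_bins)
        auc_form = roc_auc(self.table, "formation")
        auc_min = roc_auc(self.table, "mineralization")
        ccr = (
            ccr_sweep(self.table, self.n_grid)
            if self.table["event"].nunique() >= 2
            else None
        )
        return MechanoregulationResults(
            model=self,
            prob_curve=curve,
            auc_formation=auc_form,
            auc_mineralization=auc_min,
            ccr=ccr,
        )


@dataclass
class MechanoregulationResults:
    """Fitted mechano-regulation estimates with uncertainties."""

    model: MechanoregulationModel
    prob_curve: ConditionalProbabilityCurve
    auc_formation: Optional[ROCResult]
    auc_mineralization: Optional[ROCResult]
    ccr: Optional[CCRMatrix]

    @property
    def event_rates(self) -> pd.Series:
        return self.model.table["event"].value_counts(normalize=True)

    def per_band_summary(self, n_bands: int, **kwargs) -> pd.DataFrame:
        return per_band_summary(self.model.table, n_bands, n_grid=self.model.n_grid, **kwargs)

    def summary(self) -> str:
        t = self.model.table
        lines = [
            "Mechano-regulation summary",
            "=" * 60,
            f"surface voxels: {len(t)}",
        ]
        rates = self.event_rates
        lines.append(
            "event rates: "
            + ", ".join(f"{k} {100 * rates.get(k, 0.0):.1f}%" for k in ("formation", "quiescence", "resorption"))
        )
        for roc in (self.auc_formation, self.auc_mineralization):
            if roc is None:
                continue
            lines.append(
                f"AUC ({roc.event_type}): {roc.auc:.3f} +/- {roc.auc_se:.3f} "
                f"(n_pos={roc.n_pos}, n_neg={roc.n_neg}; 0.5 = no association)"
            )
        if self.ccr is not None:
            tl, th = self.ccr.argmax
            lines.append(
                f"max CCR: {self.ccr.max_ccr_percent:.1f}% at thresholds "
                f"(lower={tl:.3f}, upper={th:.3f}); chance level 33.3%"
            )
        return "\n".join(lines)
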