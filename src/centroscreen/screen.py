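"""Plate-level statistics for arrayed imaging screens.

Per-cell features are QC-filtered (dysmorphic nuclei with solidity < 0.85 or
micronucleus-like area < 30 um^2 are dropped), averaged per well, normalized
per plate by the B-score method (two-way median polish on the library wells,
residuals scaled by 1.4826 x MAD), standardized across plates with a robust
Z-score against the library-well population, and averaged over biological
replicates. Hits are perturbations whose mean Z-score exceeds +-2.5 on spot
count or clustering score, after excluding cytotoxic perturbations
(cell-number Z < -2.5) and perturbations whose replicate scores are
inconsistent (|mean Z| smaller than the replicate SD).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "QCParams",
    "HitCallParams",
    "qc_filter_cells",
    "aggregate_wells",
    "bscore_normalize",
    "robust_z",
    "merge_replicates",
    "call_hits",
    "categorize_hits",
    "analyze_screen",
]

METRICS = ("clustering_score", "spot_count", "mean_norm_radial",
           "area_um2")
#: metrics on which hits are called
HIT_METRICS = ("clustering_score", "spot_count")

MAD_CONSISTENCY = 1.4826  # makes MAD estimate SD for normal data


@dataclass(frozen=True)
class QCParams:
    min_solidity: float = 0.85
    min_area_um2: float = 30.0


@dataclass(frozen=True)
class HitCallParams:
    hit_abs_z: float = 2.5
    cytotox_z: float = -2.5
    max_qc_fail_frac: float = 0.5


# --------------------------------------------------------------------------
# QC and aggregation
# --------------------------------------------------------------------------

def qc_filter_cells(cell_table: pd.DataFrame,
                    params: QCParams | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop dysmorphic and micronucleus-like cells.

    Exclusion is by strict inequality — solidity < ``min_solidity`` or area
    < ``min_area_um2`` — so cells exactly at a threshold are retained.
    Returns (filtered table, per-well exclusion counts with reasons).
    """
    params = params or QCParams()
    for col in ("solidity", "area_um2"):
        if col not in cell_table.columns:
            raise ValueError(f"cell_table is missing required column {col!r}")
    low_sol = cell_table["solidity"] < params.min_solidity
    low_area = cell_table["area_um2"] < params.min_area_um2
    keep = ~(low_sol | low_area)
    group_keys = [k for k in ("plate", "row", "col", "replicate")
                  if k in cell_table.columns]
    if group_keys:
        counts = (
            pd.DataFrame({
                "n_total": 1,
                "n_low_solidity": low_sol.astype(int),
                "n_low_area": low_area.astype(int),
                "n_excluded": (~keep).astype(int),
            }, index=cell_table.index)
            .join(cell_table[group_keys])
            .groupby(group_keys, as_index=False).sum()
        )
    else:
        counts = pd.DataFrame({
            "n_total": [len(cell_table)],
            "n_low_solidity": [int(low_sol.sum())],
            "n_low_area": [int(low_area.sum())],
            "n_excluded": [int((~keep).sum())],
        })
    return cell_table.loc[keep].copy(), counts


def aggregate_wells(cell_table: pd.DataFrame, plate_map: pd.DataFrame,
                    metrics: tuple = METRICS, agg: str = "mean",
                    ) -> pd.DataFrame:
    """Average per-cell metrics per well.

    ``cell_table`` should already be QC-filtered; every cell must map onto a
    well present in ``plate_map`` (orphans raise, listing offenders). Wells
    with zero passing cells appear with missing means and a flag. ``agg`` is
    "mean" (default, the screen's convention) or "median".
    """
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")
    keys = ["plate", "row", "col"]
    pm = plate_map.drop_duplicates(subset=keys)
    merged = cell_table.merge(pm[keys + ["perturbation", "control_class"]],
                              on=keys, how="left", suffixes=("", "_map"))
    orphan = merged["perturbation" if "perturbation" not in cell_table.columns
                    else "perturbation_map"].isna()
    if orphan.any():
        bad = merged.loc[orphan, keys].drop_duplicates()
        raise ValueError(
            "cells mapped to no well in the plate map: "
            + ", ".join(str(tuple(r)) for r in bad.itertuples(index=False)))
    group = keys + (["replicate"] if "replicate" in merged.columns else [])
    present = [m for m in metrics if m in merged.columns]
    aggfun = {m: agg for m in present}
    summaries = merged.groupby(group, as_index=False).agg(
        **{f"mean_{m}": (m, agg) for m in present},
        n_cells_pass_qc=(present[0], "size"),
    )
    reps = (sorted(merged["replicate"].unique())
            if "replicate" in merged.columns else [None])
    full = []
    for rep in reps:
        f = pm[keys + ["well", "perturbation", "control_class"]].copy()
        if rep is not None:
            f["replicate"] = rep
        full.append(f)
    full = pd.concat(full, ignore_index=True)
    out = full.merge(summaries, on=group, how="left")
    out["n_cells_pass_qc"] = out["n_cells_pass_qc"].fillna(0).astype(int)
    out["empty_well_flag"] = out["n_cells_pass_qc"] == 0
    return out


# --------------------------------------------------------------------------
# B-score (two-way median polish)
# --------------------------------------------------------------------------

def bscore_normalize(plate: np.ndarray, library_mask: np.ndarray,
                     max_iter: int = 10, tol: float = 1e-6,
                     return_scale: bool = False):
    """B-score normalization of one plate of well means.

    The plate is centred on the median of the library wells, then a two-way
    median polish removes row and column effects; at each sweep the row and
    column medians are computed over library wells only, so extreme control
    wells never drive the fit (they still receive scores). Residuals are
    scaled by ``1.4826 x MAD`` of the library-well residuals (SD fallback
    when the MAD is zero; a fully constant plate is degenerate and raises).
    Missing wells (NaN) are carried through untouched.
    """
    x = np.array(plate, dtype=float)
    lib = np.asarray(library_mask, dtype=bool)
    if x.shape != lib.shape:
        raise ValueError("plate and library_mask must share a shape")
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("plate must be at least 2x2")
    lib_valid = lib & ~np.isnan(x)
    if lib_valid.sum() < 2:
        raise ValueError("plate has fewer than 2 usable library wells")
    if not (lib_valid.any(axis=1).sum() >= 2
            and lib_valid.any(axis=0).sum() >= 2):
        raise ValueError("library wells must span >= 2 rows and 2 columns")
    x -= np.nanmedian(x[lib_valid])
    masked = np.where(lib_valid, x, np.nan)
    for _ in range(max_iter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rm = np.nanmedian(masked, axis=1)
        rm = np.nan_to_num(rm)
        x -= rm[:, None]
        masked = np.where(lib_valid, x, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cm = np.nanmedian(masked, axis=0)
        cm = np.nan_to_num(cm)
        x -= cm[None, :]
        masked = np.where(lib_valid, x, np.nan)
        if max(np.abs(rm).max(initial=0.0), np.abs(cm).max(initial=0.0)) < tol:
            break
    resid = x[lib_valid]
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = MAD_CONSISTENCY * mad
    # a MAD at float-epsilon level (most residuals exactly polished away)
    # is as degenerate as an exact zero
    if scale <= 1e-12 * max(1.0, float(np.abs(resid).max())):
        scale = 0.0
    if scale == 0.0:
        sd = resid.std(ddof=1) if len(resid) > 1 else 0.0
        if sd == 0.0:
            raise ValueError("degenerate plate: zero spread in library "
                             "residuals")
        log.warning("library residual MAD is 0; falling back to SD")
        scale = sd
    b = x / scale
    return (b, scale) if return_scale else b


# --------------------------------------------------------------------------
# robust Z
# --------------------------------------------------------------------------

def robust_z(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Robust Z-score: (x - median(ref)) / (1.4826 x MAD(ref)).

    Falls back to the reference SD (with a warning) when the MAD is zero.
    """
    ref = np.asarray(reference, dtype=float)
    ref = ref[~np.isnan(ref)]
    if len(ref) < 8:
        raise ValueError("robust_z needs at least 8 reference wells")
    med = np.median(ref)
    mad = np.median(np.abs(ref - med))
    scale = MAD_CONSISTENCY * mad
    if scale == 0.0:
        sd = ref.std(ddof=1)
        if sd == 0.0:
            raise ValueError("degenerate reference: zero spread")
        warnings.warn("reference MAD is 0; falling back to SD",
                      stacklevel=2)
        scale = sd
    return (np.asarray(values, dtype=float) - med) / scale


# --------------------------------------------------------------------------
# replicate merging and hit calling
# --------------------------------------------------------------------------

def merge_replicates(z_tables: list[pd.DataFrame],
                     metrics: tuple = HIT_METRICS + ("n_cells",),
                     ) -> pd.DataFrame:
    """Merge per-replicate Z tables into mean Z and replicate SD per gene.

    Each input table has one row per perturbation with ``z_<metric>``
    columns. For two replicates the SD equals ``|z1 - z2| / sqrt(2)``; with
    a single replicate the SD is flagged missing (NaN). Mismatched
    perturbation keys raise, listing the difference.
    """
    if not z_tables:
        raise ValueError("no replicate tables given")
    keysets = [set(t["perturbation"]) for t in z_tables]
    common = keysets[0]
    for ks in keysets[1:]:
        if ks != common:
            diff = sorted(common ^ ks)
            raise ValueError(
                f"replicate tables disagree on perturbations: {diff[:10]}")
    base = z_tables[0][["perturbation"]].copy()
    if "control_class" in z_tables[0].columns:
        base["control_class"] = z_tables[0]["control_class"].values
    for metric in metrics:
        col = f"z_{metric}"
        if col not in z_tables[0].columns:
            continue
        stack = np.stack([
            t.set_index("perturbation")[col].reindex(
                base["perturbation"]).to_numpy()
            for t in z_tables
        ])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            base[f"mean_z_{metric}"] = np.nanmean(stack, axis=0)
        if len(z_tables) >= 2:
            base[f"z_sd_{metric}"] = np.nanstd(stack, axis=0, ddof=1)
        else:
            base[f"z_sd_{metric}"] = np.nan
    return base


def call_hits(ztable: pd.DataFrame,
              params: HitCallParams | None = None,
              qc_fail_frac: pd.Series | None = None) -> pd.DataFrame:
    """Call and annotate hits from a merged Z table.

    Exclusions are applied first: *cytotoxic* when the cell-number mean Z is
    below ``cytotox_z``; *dysmorphic-excess* when the perturbation's fraction
    of QC-failing nuclei (if provided) exceeds ``max_qc_fail_frac``;
    *inconsistent*, per metric, when |mean Z| is smaller than the replicate
    SD. Surviving perturbations are hits when |mean Z| >= ``hit_abs_z`` on
    either clustering score or spot count; the direction is recorded per
    metric from the sign.
    """
    params = params or HitCallParams()
    out = ztable.copy()
    n = len(out)
    reasons = [[] for _ in range(n)]
    cytotox = np.zeros(n, dtype=bool)
    if "mean_z_n_cells" in out.columns:
        cytotox = out["mean_z_n_cells"].to_numpy() < params.cytotox_z
        for i in np.nonzero(cytotox)[0]:
            reasons[i].append("cytotoxic")
    if qc_fail_frac is not None:
        frac = out["perturbation"].map(qc_fail_frac).to_numpy(float)
        dys = frac > params.max_qc_fail_frac
        for i in np.nonzero(dys)[0]:
            reasons[i].append("dysmorphic-excess")
        cytotox = cytotox | dys
    for metric in HIT_METRICS:
        mz = out[f"mean_z_{metric}"].to_numpy(float)
        sd = out[f"z_sd_{metric}"].to_numpy(float)
        with np.errstate(invalid="ignore"):
            inconsistent = np.abs(mz) < sd
            large = np.abs(mz) >= params.hit_abs_z
        inconsistent = np.where(np.isnan(sd), False, inconsistent)
        hit = large & ~inconsistent & ~cytotox & ~np.isnan(mz)
        out[f"hit_{metric}"] = hit
        out[f"inconsistent_{metric}"] = inconsistent
        for i in np.nonzero(large & inconsistent)[0]:
            reasons[i].append(f"inconsistent:{metric}")
        if metric == "clustering_score":
            out["clustering_direction"] = np.select(
                [hit & (mz > 0), hit & (mz < 0)],
                ["clustered", "unclustered"], default="none")
        else:
            out["count_direction"] = np.select(
                [hit & (mz > 0), hit & (mz < 0)],
                ["higher", "lower"], default="none")
    out["excluded"] = [len(r) > 0 for r in reasons]
    out["exclusion_reasons"] = [";".join(r) for r in reasons]
    out["is_hit"] = (out[[f"hit_{m}" for m in HIT_METRICS]].any(axis=1)
                     & ~out["excluded"])
    # exclusion voids hit flags entirely
    for metric in HIT_METRICS:
        out.loc[out["excluded"], f"hit_{metric}"] = False
    out.loc[out["excluded"], "is_hit"] = False
    return out


#: labels for the both-metric phenotype combinations
BOTH_METRIC_CATEGORIES = {
    ("clustered", "lower"): "higher overall clustering",
    ("unclustered", "higher"): "overall dispersion",
    ("unclustered", "lower"):
        "global dispersion, local clustering into fewer larger clusters",
    ("clustered", "higher"): "more numerous local clusters",
}


def categorize_hits(hit_table: pd.DataFrame) -> pd.DataFrame:
    """Assign each hit exactly one phenotype category.

    Hits on a single metric are "clustering-only" or "count-only"; hits on
    both metrics map through the sign combination: increased clustering with
    fewer spots means higher overall clustering, the opposite signs mean
    overall dispersion, and both-decreased means global dispersion with
    local clustering into fewer, larger clusters.
    """
    out = hit_table.copy()
    cats = []
    for rec in out.itertuples(index=False):
        if not rec.is_hit:
            cats.append("not a hit")
            continue
        hc = rec.hit_clustering_score
        hn = rec.hit_spot_count
        if hc and hn:
            cats.append(BOTH_METRIC_CATEGORIES[
                (rec.clustering_direction, rec.count_direction)])
        elif hc:
            cats.append("clustering-only")
        else:
            cats.append("count-only")
    out["category"] = cats
    return out


# --------------------------------------------------------------------------
# end-to-end convenience
# --------------------------------------------------------------------------

def _per_replicate_z(well_summaries: pd.DataFrame, rows: int, cols: int,
                     metrics: tuple) -> pd.DataFrame:
    """B-score each plate then robust-Z across plates for one replicate."""
    ws = well_summaries
    zcols = {}
    for metric in metrics:
        col = f"mean_{metric}" if metric != "n_cells" else "n_cells_pass_qc"
        bvals = pd.Series(np.nan, index=ws.index)
        for plate in sorted(ws["plate"].unique()):
            sel = ws["plate"] == plate
            mat = np.full((rows, cols), np.nan)
            libmask = np.zeros((rows, cols), dtype=bool)
            sub = ws.loc[sel]
            mat[sub["row"], sub["col"]] = sub[col].to_numpy(float)
            is_lib = (sub["control_class"] == "library").to_numpy()
            libmask[sub["row"].to_numpy()[is_lib],
                    sub["col"].to_numpy()[is_lib]] = True
            b = bscore_normalize(mat, libmask)
            bvals.loc[sel] = b[sub["row"], sub["col"]]
        ref = bvals[(ws["control_class"] == "library")
                    & ~bvals.isna()].to_numpy()
        zcols[f"z_{metric}"] = robust_z(bvals.to_numpy(float), ref)
    out = ws[["perturbation", "control_class"]].copy()
    for k, v in zcols.items():
        out[k] = v
    return out


def analyze_screen(cell_table: pd.DataFrame, plate_map: pd.DataFrame,
                   rows: int, cols: int,
                   qc: QCParams | None = None,
                   hit_params: HitCallParams | None = None,
                   metrics: tuple = HIT_METRICS) -> dict:
    """Run QC -> well aggregation -> B-score -> robust Z -> replicate merge
    -> hit calling -> categorization on a per-cell feature table.

    Returns a dict with the intermediate tables: ``cells_qc``,
    ``qc_counts``, ``well_summaries``, ``z_replicates``, ``z_merged``,
    ``hits``.
    """
    qc = qc or QCParams()
    cells_qc, qc_counts = qc_filter_cells(cell_table, qc)
    ws = aggregate_wells(cells_qc, plate_map)
    all_metrics = tuple(metrics) + ("n_cells",)
    reps = sorted(ws["replicate"].unique()) if "replicate" in ws.columns \
        else [None]
    ztabs = []
    for rep in reps:
        sub = ws if rep is None else ws[ws["replicate"] == rep]
        ztabs.append(_per_replicate_z(sub.reset_index(drop=True),
                                      rows, cols, all_metrics))
    merged = merge_replicates(ztabs, metrics=all_metrics)
    # dysmorphic-excess fraction per perturbation, averaged over replicates
    qc_join = cell_table.copy()
    low = (qc_join["solidity"] < qc.min_solidity) \
        | (qc_join["area_um2"] < qc.min_area_um2)
    qc_join = qc_join.merge(
        plate_map[["plate", "row", "col", "perturbation"]],
        on=["plate", "row", "col"], how="left",
        suffixes=("", "_map"))
    pert_col = ("perturbation_map" if "perturbation_map" in qc_join.columns
                else "perturbation")
    fail_frac = low.groupby(qc_join[pert_col]).mean()
    library = merged[merged["control_class"] == "library"].reset_index(
        drop=True)
    hits = call_hits(library, hit_params, qc_fail_frac=fail_frac)
    hits = categorize_hits(hits)
    return {
        "cells_qc": cells_qc, "qc_counts": qc_counts,
        "well_summaries": ws, "z_replicates": ztabs, "z_merged": merged,
        "hits": hits,
    }
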