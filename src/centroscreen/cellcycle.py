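"""Cell-cycle phase assignment from integrated DAPI and EdU intensities.

The DNA content of a G2/M cell is twice that of a G1 cell, so on a log2
scale the two EdU-negative subpopulations sit one unit apart. ``fit_gates``
locates the two modes (two-component Gaussian mixture by default, histogram
valley as an alternative) and sets an EdU-positivity threshold by two-class
separation on log2 EdU. ``assign_phases`` then labels every cell:
EdU-positive cells are S phase; EdU-negative cells inside the G1 or G2/M
window get that label; cells below the G1 window (subG1 debris) or above the
G2/M window (>4N) are excluded from analysis; EdU-negative cells between the
windows are left unassigned by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from sklearn.mixture import GaussianMixture

__all__ = ["PhaseGates", "fit_gates", "assign_phases"]


@dataclass(frozen=True)
class PhaseGates:
    """Fitted gates on log2 intensity scales.

    ``log2_dapi_g1_center`` and ``log2_dapi_g2_center`` are the 2N and 4N
    mode locations (the latter ~1 log2 unit above the former); windows are
    half-widths around each centre; ``edu_threshold`` separates detectable
    from background EdU on the log2 scale. ``edu_available`` is False when
    the table had no EdU channel, in which case S phase cannot be assigned.
    """

    log2_dapi_g1_center: float
    log2_dapi_g2_center: float
    g1_window: float
    g2_window: float
    edu_threshold: float
    method: str = "gmm2"
    edu_available: bool = True

    def __post_init__(self) -> None:
        if self.log2_dapi_g2_center <= self.log2_dapi_g1_center:
            raise ValueError("g2_center must exceed g1_center")
        if self.g1_window <= 0 or self.g2_window <= 0:
            raise ValueError("windows must be positive")


def _fit_two_modes_gmm(x: np.ndarray, seed: int) -> tuple[float, float,
                                                          float, float]:
    gm = GaussianMixture(n_components=2, covariance_type="spherical",
                         n_init=3, random_state=seed)
    gm.fit(x[:, None])
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    return float(means[0]), float(means[1]), float(sds[0]), float(sds[1])


def _fit_two_modes_valley(x: np.ndarray) -> tuple[float, float, float,
                                                  float]:
    split = threshold_otsu(x)
    lo, hi = x[x <= split], x[x > split]
    if len(lo) < 5 or len(hi) < 5:
        raise ValueError("valley split produced a degenerate mode")
    return (float(np.median(lo)), float(np.median(hi)),
            float(lo.std()), float(hi.std()))


def fit_gates(cell_table: pd.DataFrame, method: str = "gmm2",
              window_scale: float = 3.0, g2_tolerance: float = 0.35,
              seed: int = 0) -> PhaseGates:
    """Fit phase gates from a table with ``dapi_integrated`` (and optionally
    ``edu_integrated``) columns.

    The two DAPI modes are fitted on log2 intensities of EdU-negative cells
    (all cells when no EdU channel is present); the fitted mode separation
    must be 1 log2 unit within ``g2_tolerance``, otherwise the population is
    considered unimodal/mis-gated and an error is raised with a diagnostic.
    Windows are ``window_scale`` times each fitted component scale. The EdU
    threshold is an Otsu two-class split on log2 EdU.
    """
    if "dapi_integrated" not in cell_table.columns:
        raise ValueError("cell_table must have a dapi_integrated column")
    if len(cell_table) < 200:
        warnings.warn(
            f"only {len(cell_table)} cells: gate fits below ~200 cells are "
            "unstable", stacklevel=2)
    dapi = np.log2(np.clip(cell_table["dapi_integrated"].to_numpy(float),
                           1e-12, None))
    edu_available = "edu_integrated" in cell_table.columns
    if edu_available:
        edu = np.log2(np.clip(cell_table["edu_integrated"].to_numpy(float),
                              1e-12, None))
        edu_threshold = float(threshold_otsu(edu))
        dapi_fit = dapi[edu <= edu_threshold]
        if len(dapi_fit) < 20:
            dapi_fit = dapi
    else:
        edu_threshold = np.inf
        dapi_fit = dapi
    if method == "gmm2":
        g1, g2, s1, s2 = _fit_two_modes_gmm(dapi_fit, seed)
    elif method == "valley":
        g1, g2, s1, s2 = _fit_two_modes_valley(dapi_fit)
    else:
        raise ValueError(f"unknown gating method {method!r}")
    sep = g2 - g1
    if abs(sep - 1.0) > g2_tolerance:
        raise ValueError(
            f"DAPI does not resolve into 2N/4N modes one log2 unit apart "
            f"(fitted separation {sep:.3f}); population may be unimodal or "
            f"the intensity scale is wrong")
    # floor the window on a plausible CV so near-delta components still gate
    s1 = max(s1, 0.02)
    s2 = max(s2, 0.02)
    return PhaseGates(
        log2_dapi_g1_center=g1, log2_dapi_g2_center=g2,
        g1_window=window_scale * s1, g2_window=window_scale * s2,
        edu_threshold=edu_threshold, method=method,
        edu_available=edu_available)


def assign_phases(cell_table: pd.DataFrame, gates: PhaseGates,
                  intermediate: str = "unassigned") -> pd.Series:
    """Label every cell as G1, S, G2M, excluded or unassigned.

    EdU-positive cells are S. EdU-negative cells inside the G1 (resp. G2/M)
    window are G1 (resp. G2M); below the lower edge of the G1 window
    (subG1) or above the upper edge of the G2/M window (>4N) they are
    excluded. EdU-negative cells between the windows follow ``intermediate``
    ("unassigned" or "nearest": snap to the closer window centre).
    """
    dapi = np.log2(np.clip(cell_table["dapi_integrated"].to_numpy(float),
                           1e-12, None))
    if gates.edu_available and "edu_integrated" in cell_table.columns:
        edu = np.log2(np.clip(cell_table["edu_integrated"].to_numpy(float),
                              1e-12, None))
        edu_pos = edu > gates.edu_threshold
    else:
        edu_pos = np.zeros(len(cell_table), dtype=bool)
    g1_lo = gates.log2_dapi_g1_center - gates.g1_window
    g1_hi = gates.log2_dapi_g1_center + gates.g1_window
    g2_lo = gates.log2_dapi_g2_center - gates.g2_window
    g2_hi = gates.log2_dapi_g2_center + gates.g2_window
    labels = np.full(len(cell_table), "unassigned", dtype=object)
    labels[(dapi < g1_lo) | (dapi > g2_hi)] = "excluded"
    in_g1 = (dapi >= g1_lo) & (dapi <= min(g1_hi, g2_lo))
    in_g2 = (dapi >= max(g2_lo, g1_hi)) & (dapi <= g2_hi)
    labels[in_g1] = "G1"
    labels[in_g2] = "G2M"
    if intermediate == "nearest":
        mid = labels == "unassigned"
        nearer_g1 = np.abs(dapi - gates.log2_dapi_g1_center) \
            <= np.abs(dapi - gates.log2_dapi_g2_center)
        labels[mid & nearer_g1] = "G1"
        labels[mid & ~nearer_g1] = "G2M"
    # EdU positivity overrides the DAPI windows except for excluded outliers
    s_mask = edu_pos & (labels != "excluded")
    labels[s_mask] = "S"
    return pd.Series(labels, index=cell_table.index, name="phase")
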