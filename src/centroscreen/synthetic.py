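"""Ground-truthed synthetic data: nuclei, spot patterns, images, cell-cycle
populations and whole multi-plate arrayed screens.

Every generator takes an explicit seed and returns both the artifact and a
ground-truth record, so downstream stages (segmentation, spot detection,
spatial statistics, gating, hit calling) can be tested end to end without any
external data. Defaults emulate the acquisition and assay conditions the
pipeline targets: 0.108 um pixels, diffraction-limited centromere foci, a
~40-spot diploid-like G1 count that doubles by G2/M, 384-well plates with
scrambled / non-expressed-gene / essential-gene / condensin-II control wells
and two biological replicates.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon
from skimage.measure import label as cc_label, regionprops

from .spatial import sample_csr_in_mask, points_in_mask

__all__ = [
    "NucleusShapeParams",
    "SpotProcessParams",
    "CellCycleMixtureParams",
    "ScreenDesignConfig",
    "generate_nucleus_mask",
    "sample_spots",
    "render_cell_image",
    "simulate_cell_cycle_population",
    "design_screen",
    "simulate_screen",
    "DEFAULT_PIXEL_SIZE_UM",
]

#: effective pixel size of the targeted acquisition setup (60x, sCMOS)
DEFAULT_PIXEL_SIZE_UM = 0.108


# --------------------------------------------------------------------------
# nucleus masks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleusShapeParams:
    """Shape controls for one synthetic nucleus.

    ``equivalent_radius_um`` sets the area (pi r^2); ``eccentricity`` in
    [0, 1) elongates the base ellipse at constant area; ``boundary_roughness``
    is the SD of a smooth random radial perturbation as a fraction of the
    radius; ``concavity_count`` cuts deep notches into the boundary to create
    dysmorphic, low-solidity shapes (depth controlled by
    ``concavity_depth``, a fraction of the local radius).
    """

    equivalent_radius_um: float = 6.0
    eccentricity: float = 0.0
    boundary_roughness: float = 0.0
    concavity_count: int = 0
    concavity_depth: float = 0.6

    def __post_init__(self) -> None:
        if self.equivalent_radius_um <= 0:
            raise ValueError("equivalent_radius_um must be positive")
        if not 0.0 <= self.eccentricity < 1.0:
            raise ValueError("eccentricity must lie in [0, 1)")
        if self.boundary_roughness < 0:
            raise ValueError("boundary_roughness must be non-negative")
        if self.concavity_count < 0:
            raise ValueError("concavity_count must be non-negative")
        if not 0.0 <= self.concavity_depth < 1.0:
            raise ValueError("concavity_depth must lie in [0, 1)")


@dataclass
class NucleusGroundTruth:
    nucleus_id: int
    params: NucleusShapeParams
    seed: int
    pixel_size_um: float
    area_um2: float
    solidity: float
    centroid_um: np.ndarray
    equivalent_radius_um: float


def generate_nucleus_mask(params: NucleusShapeParams, pixel_size_um: float,
                          seed: int, nucleus_id: int = 0,
                          margin_um: float = 1.0,
                          ) -> tuple[np.ndarray, NucleusGroundTruth]:
    """Rasterize one nucleus mask and return it with its ground truth.

    The boundary is a star-shaped radial function: an equal-area ellipse,
    multiplied by (1 + roughness * smooth harmonic field) and by Gaussian
    notch factors for each concavity. Exact area/solidity are recomputed from
    the raster so downstream recovery tests compare against the raster truth,
    not the analytic intent.
    """
    if params.equivalent_radius_um < 3 * pixel_size_um:
        raise ValueError(
            "equivalent_radius_um must be at least 3 pixels for a "
            "meaningful raster")
    rng = np.random.default_rng(seed)
    r_eq = params.equivalent_radius_um
    e = params.eccentricity
    # equal-area ellipse semi-axes: a*b = r_eq^2, b = a*sqrt(1-e^2)
    a = r_eq / (1.0 - e**2) ** 0.25
    b = r_eq * (1.0 - e**2) ** 0.25
    theta = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    radius = a * b / np.sqrt((b * np.cos(theta)) ** 2
                             + (a * np.sin(theta)) ** 2)
    if params.boundary_roughness > 0:
        pert = np.zeros_like(theta)
        for k in range(2, 7):
            pert += rng.normal() * np.cos(k * theta) \
                 + rng.normal() * np.sin(k * theta)
        pert /= max(pert.std(), 1e-12)
        radius *= 1.0 + params.boundary_roughness * pert
    if params.concavity_count > 0:
        width = 0.18  # rad; narrow enough that notches stay distinct
        base = rng.uniform(0.0, 2.0 * np.pi)
        for k in range(params.concavity_count):
            center = base + 2.0 * np.pi * k / params.concavity_count \
                + rng.uniform(-0.15, 0.15)
            dtheta = np.angle(np.exp(1j * (theta - center)))
            radius *= 1.0 - params.concavity_depth * np.exp(
                -0.5 * (dtheta / width) ** 2)
    radius = np.maximum(radius, 0.1 * r_eq)

    orientation = rng.uniform(0.0, np.pi)
    ys = radius * np.sin(theta + orientation)
    xs = radius * np.cos(theta + orientation)
    half = max(np.abs(ys).max(), np.abs(xs).max()) + margin_um
    size = int(math.ceil(2.0 * half / pixel_size_um))
    c0 = size / 2.0
    rr, cc = draw_polygon(ys / pixel_size_um + c0, xs / pixel_size_um + c0,
                          shape=(size, size))
    mask = np.zeros((size, size), dtype=bool)
    mask[rr, cc] = True
    lab = cc_label(mask)
    if lab.max() > 1:  # keep the largest component; deep notches can pinch
        counts = np.bincount(lab.ravel())[1:]
        mask = lab == (1 + int(np.argmax(counts)))
    props = regionprops(mask.astype(np.uint8))[0]
    truth = NucleusGroundTruth(
        nucleus_id=nucleus_id,
        params=params,
        seed=seed,
        pixel_size_um=pixel_size_um,
        area_um2=float(props.area) * pixel_size_um**2,
        solidity=float(props.solidity),
        centroid_um=(np.asarray(props.centroid) + 0.5) * pixel_size_um,
        equivalent_radius_um=float(
            np.sqrt(props.area / np.pi) * pixel_size_um),
    )
    return mask, truth


# --------------------------------------------------------------------------
# spot point processes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpotProcessParams:
    """One of three point processes inside a nuclear mask.

    ``csr`` draws uniform points (the null model); ``cluster`` is a
    Thomas-type process (Gaussian offspring of standard deviation
    ``cluster_sigma_um`` around uniform parents, truncated to the mask by
    resampling); ``regular`` is hard-core sequential inhibition with minimum
    spacing ``inhibition_radius_um``.
    """

    process: str = "csr"
    n_spots: int = 40
    n_parents: int | None = None
    cluster_sigma_um: float | None = None
    inhibition_radius_um: float | None = None

    def __post_init__(self) -> None:
        if self.process not in ("csr", "cluster", "regular"):
            raise ValueError(f"unknown process {self.process!r}")
        if self.n_spots < 1:
            raise ValueError("n_spots must be positive")
        if self.process == "cluster":
            if self.cluster_sigma_um is None or self.cluster_sigma_um <= 0:
                raise ValueError("cluster process requires cluster_sigma_um")
            if self.n_parents is None or self.n_parents < 1:
                raise ValueError("cluster process requires n_parents")
        else:
            if self.cluster_sigma_um is not None:
                raise ValueError("cluster_sigma_um only valid for cluster")
        if self.process == "regular":
            if (self.inhibition_radius_um is None
                    or self.inhibition_radius_um <= 0):
                raise ValueError(
                    "regular process requires inhibition_radius_um")
        elif self.inhibition_radius_um is not None:
            raise ValueError("inhibition_radius_um only valid for regular")


def sample_spots(mask: np.ndarray, params: SpotProcessParams,
                 pixel_size_um: float, seed: int,
                 max_tries_per_spot: int = 2000,
                 ) -> tuple[np.ndarray, dict]:
    """Sample spot coordinates (um, (y, x)) inside the mask.

    Returns (coordinates, ground truth dict). All points lie strictly inside
    the raster support. The regular process raises after a bounded retry
    budget when the requested hard-core packing is infeasible.
    """
    if np.count_nonzero(mask) == 0:
        raise ValueError("cannot sample spots in an empty mask")
    rng = np.random.default_rng(seed)
    n = params.n_spots
    if params.process == "csr":
        pts = sample_csr_in_mask(mask, n, pixel_size_um, rng)
    elif params.process == "cluster":
        parents = sample_csr_in_mask(mask, params.n_parents, pixel_size_um,
                                     rng)
        pts = np.empty((n, 2))
        for i in range(n):
            parent = parents[rng.integers(0, len(parents))]
            for _ in range(max_tries_per_spot):
                cand = parent + rng.normal(0.0, params.cluster_sigma_um, 2)
                if points_in_mask(cand[None, :], mask, pixel_size_um)[0]:
                    pts[i] = cand
                    break
            else:  # vanishing acceptance region: collapse onto the parent
                pts[i] = parent
    else:  # regular / hard-core
        pts_list: list[np.ndarray] = []
        budget = max_tries_per_spot * n
        tries = 0
        while len(pts_list) < n:
            if tries >= budget:
                raise RuntimeError(
                    f"hard-core packing infeasible: placed {len(pts_list)} "
                    f"of {n} spots with spacing "
                    f"{params.inhibition_radius_um} um in "
                    f"{budget} tries")
            tries += 1
            cand = sample_csr_in_mask(mask, 1, pixel_size_um, rng)[0]
            if pts_list:
                d = np.hypot(*(np.asarray(pts_list) - cand).T)
                if d.min() < params.inhibition_radius_um:
                    continue
            pts_list.append(cand)
        pts = np.asarray(pts_list)
    truth = {"process": params.process, "params": params, "seed": seed,
             "n_spots": n}
    return pts, truth


# --------------------------------------------------------------------------
# image rendering
# --------------------------------------------------------------------------

def render_cell_image(mask: np.ndarray, spots_um: np.ndarray,
                      pixel_size_um: float, psf_sigma_um: float = 0.15,
                      snr: float = 20.0, seed: int = 0,
                      spot_amplitude: float = 1000.0,
                      background: float = 100.0,
                      dapi_level: float = 500.0,
                      ) -> tuple[np.ndarray, dict]:
    """Render a two-channel (DAPI, spot) image of one cell.

    The DAPI channel is the filled mask at ``dapi_level``; the spot channel
    is ``background`` plus one isotropic Gaussian of SD ``psf_sigma_um`` and
    peak ``spot_amplitude`` per spot. Additive Gaussian noise of SD
    ``spot_amplitude / snr`` is applied to both channels (``snr=inf`` for a
    noiseless render). The ground truth carries a merged-spot flag whenever
    two spots are closer than ``2 * psf_sigma_um``: below that separation the
    summed profile of two equal Gaussians has a single maximum, so the pair
    is analytically unresolvable.
    """
    if psf_sigma_um < pixel_size_um / 2:
        raise ValueError("psf_sigma_um must be at least half a pixel")
    rng = np.random.default_rng(seed)
    spots = np.atleast_2d(np.asarray(spots_um, dtype=float)) \
        if len(spots_um) else np.empty((0, 2))
    h, w = mask.shape
    yy = (np.arange(h) + 0.5) * pixel_size_um
    xx = (np.arange(w) + 0.5) * pixel_size_um
    spot_chan = np.full((h, w), background, dtype=float)
    for sy, sx in spots:
        gy = np.exp(-0.5 * ((yy - sy) / psf_sigma_um) ** 2)
        gx = np.exp(-0.5 * ((xx - sx) / psf_sigma_um) ** 2)
        spot_chan += spot_amplitude * np.outer(gy, gx)
    dapi_chan = np.where(mask, dapi_level, background).astype(float)
    noise_sd = 0.0 if np.isinf(snr) else spot_amplitude / snr
    if noise_sd > 0:
        spot_chan = spot_chan + rng.normal(0.0, noise_sd, (h, w))
        dapi_chan = dapi_chan + rng.normal(0.0, noise_sd, (h, w))
    image = np.stack([dapi_chan, spot_chan]).astype(np.float32)

    merged = False
    if len(spots) >= 2:
        from scipy.spatial.distance import pdist
        merged = bool(pdist(spots).min() < 2.0 * psf_sigma_um)
    truth = {
        "spots_um": spots, "pixel_size_um": pixel_size_um,
        "psf_sigma_um": psf_sigma_um, "snr": snr,
        "spot_amplitude": spot_amplitude, "background": background,
        "noise_sd": noise_sd, "merged_spot_flag": merged, "seed": seed,
    }
    return image, truth


# --------------------------------------------------------------------------
# cell-cycle mixtures
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CellCycleMixtureParams:
    """DAPI/EdU intensity mixture for a G1/S/G2M population.

    G2/M DAPI is constructed as exactly twice the 2N mean; S-phase DAPI is
    uniform between the 2N and 4N means (DNA replicating); true spot counts
    double from G1 to G2/M with S in between. ``f_subg1`` / ``f_over4n``
    plant debris/polyploid outliers (taken proportionally out of the three
    phase fractions) for exclusion-logic tests.
    """

    fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    dapi_2n_mean: float = 1.0e5
    dapi_cv: float = 0.06
    edu_pos_mean: float = 5.0e4
    edu_neg_mean: float = 2.0e3
    edu_log_sd: float = 0.35
    spot_count_g1: int = 40
    f_subg1: float = 0.0
    f_over4n: float = 0.0

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if (f < 0).any():
            raise ValueError("fractions must be non-negative")
        if self.dapi_2n_mean <= 0 or self.dapi_cv <= 0:
            raise ValueError("dapi_2n_mean and dapi_cv must be positive")
        if self.edu_pos_mean <= self.edu_neg_mean:
            raise ValueError("edu_pos_mean must exceed edu_neg_mean")
        if self.spot_count_g1 < 1:
            raise ValueError("spot_count_g1 must be positive")
        if self.f_subg1 < 0 or self.f_over4n < 0 \
                or self.f_subg1 + self.f_over4n >= 1:
            raise ValueError("outlier fractions must be small and >= 0")

    @property
    def dapi_modes_separable(self) -> bool:
        """Whether the 2N/4N log2-DAPI modes are >= 3 SD apart each side."""
        sd_log2 = self.dapi_cv / math.log(2)
        return 1.0 >= 6.0 * sd_log2


def simulate_cell_cycle_population(params: CellCycleMixtureParams,
                                   n_cells: int, seed: int) -> pd.DataFrame:
    """Simulate integrated DAPI/EdU intensities with per-cell ground truth.

    Returns a DataFrame with columns ``dapi_integrated``, ``edu_integrated``,
    ``true_phase`` in {G1, S, G2M, subG1, over4N} and ``true_spot_count``.
    The frame's ``attrs`` record the parameters and a ``separability_warning``
    flag when ``dapi_cv`` is large enough that the 2N and 4N log2 modes
    overlap.
    """
    rng = np.random.default_rng(seed)
    f = np.asarray(params.fractions, dtype=float)
    f_out = params.f_subg1 + params.f_over4n
    probs = np.concatenate([f * (1.0 - f_out),
                            [params.f_subg1, params.f_over4n]])
    phases = np.array(["G1", "S", "G2M", "subG1", "over4N"])
    which = rng.choice(5, size=n_cells, p=probs)
    m = params.dapi_2n_mean
    cv = params.dapi_cv
    dapi = np.empty(n_cells)
    spot = np.empty(n_cells, dtype=int)
    is_g1 = which == 0
    is_s = which == 1
    is_g2 = which == 2
    is_sub = which == 3
    is_4n = which == 4
    dapi[is_g1] = m * (1.0 + cv * rng.standard_normal(is_g1.sum()))
    # S phase: DNA content uniform between 2N and 4N as replication proceeds
    s_progress = rng.uniform(0.0, 1.0, is_s.sum())
    dapi[is_s] = m * (1.0 + s_progress) \
        * (1.0 + cv * rng.standard_normal(is_s.sum()))
    dapi[is_g2] = 2.0 * m * (1.0 + cv * rng.standard_normal(is_g2.sum()))
    dapi[is_sub] = 0.4 * m * (1.0 + cv * rng.standard_normal(is_sub.sum()))
    # >4N population modelled as 8N doublets/polyploid debris
    dapi[is_4n] = 4.0 * m * (1.0 + cv * rng.standard_normal(is_4n.sum()))
    dapi = np.clip(dapi, 1.0, None)
    spot[is_g1] = params.spot_count_g1
    spot[is_s] = np.rint(params.spot_count_g1 * (1.0 + s_progress)
                         ).astype(int)
    spot[is_g2] = 2 * params.spot_count_g1
    spot[is_sub] = max(1, params.spot_count_g1 // 2)
    spot[is_4n] = 3 * params.spot_count_g1

    edu = np.where(
        is_s,
        params.edu_pos_mean,
        params.edu_neg_mean,
    ) * np.exp(rng.normal(0.0, params.edu_log_sd, n_cells))
    out = pd.DataFrame({
        "dapi_integrated": dapi,
        "edu_integrated": edu,
        "true_phase": phases[which],
        "true_spot_count": spot,
    })
    out.attrs["params"] = params
    out.attrs["seed"] = seed
    out.attrs["separability_warning"] = not params.dapi_modes_separable
    return out


# --------------------------------------------------------------------------
# arrayed screens
# --------------------------------------------------------------------------

CONTROL_CLASSES = ("scrambled", "neutral", "lethal", "clustering")

_ROW_LETTERS = string.ascii_uppercase


@dataclass
class ScreenDesignConfig:
    """Layout and effect model of a simulated arrayed CRISPR screen.

    ``gene_to_well`` maps gene -> (plate, row, col) with 0-based row/col;
    ``control_wells`` maps control class -> list of (plate, row, col).
    Planted effects are (d_clustering, d_spot_count, d_cell_count) per gene,
    expressed in units of the expected robust SD of neutral well means, so a
    planted +4 shift corresponds to an expected downstream robust Z of ~+4.
    Plate artifacts are additive row/column offsets on the per-cell feature
    scale, drawn per plate with SD ``artifact_sd`` (same robust-SD units).
    """

    n_plates: int
    rows: int
    cols: int
    gene_to_well: dict
    control_wells: dict
    planted_effects: dict = field(default_factory=dict)
    artifact_sd: float = 0.0
    n_replicates: int = 2
    seed: int = 0
    cells_per_well: float = 200.0
    # baseline per-cell feature model
    clustering_mean: float = 0.0
    clustering_cell_sd: float = 1.0
    clustering_well_sd: float = 0.08
    spot_count_mean: float = 40.0
    spot_count_cell_sd: float = 6.0
    spot_count_well_sd: float = 0.5
    radial_mean: float = 0.66
    radial_cell_sd: float = 0.05
    area_mean_um2: float = 110.0
    area_cell_sd: float = 20.0
    qc_fail_frac: float = 0.02
    lethal_cell_fraction: float = 0.05

    def __post_init__(self) -> None:
        seen: dict = {}
        for gene, well in self.gene_to_well.items():
            if well in seen:
                raise ValueError(
                    f"duplicated well assignment {well}: {seen[well]} and "
                    f"{gene}")
            seen[well] = gene
        for cls, wells in self.control_wells.items():
            if cls not in CONTROL_CLASSES:
                raise ValueError(f"unknown control class {cls!r}")
            for well in wells:
                if well in seen:
                    raise ValueError(
                        f"duplicated well assignment {well}: {seen[well]} "
                        f"and control {cls}")
                seen[well] = cls
        for gene in self.planted_effects:
            if gene not in self.gene_to_well:
                raise ValueError(
                    f"planted effect references unknown gene {gene!r}")

    def well_mean_sd(self, cell_sd: float, well_sd: float) -> float:
        """Expected SD of a neutral well mean (between-well + sampling)."""
        return math.sqrt(well_sd**2 + cell_sd**2 / self.cells_per_well)


def design_screen(n_genes: int = 1064, rows: int = 16, cols: int = 24,
                  n_hits: int = 0, hit_effect: float = 4.0,
                  artifact_sd: float = 0.0, n_replicates: int = 2,
                  cells_per_well: float = 200.0, seed: int = 0,
                  controls_per_class: int = 4) -> ScreenDesignConfig:
    """Build a default multi-plate 384-well screen design.

    Controls occupy column 0 of every plate (``controls_per_class`` wells per
    class); library genes fill the remaining wells row-major across as many
    plates as needed. ``n_hits`` genes are planted with effects of magnitude
    ``hit_effect`` (robust-SD units), assigned round-robin to
    clustering-only, count-only and both-metric phenotypes with random signs.
    """
    rng = np.random.default_rng(seed)
    if controls_per_class * len(CONTROL_CLASSES) > rows:
        raise ValueError("control column cannot hold all control wells")
    control_wells: dict = {cls: [] for cls in CONTROL_CLASSES}
    lib_per_plate = rows * (cols - 1)
    n_plates = math.ceil(n_genes / lib_per_plate)
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    gene_to_well: dict = {}
    g = 0
    for plate in range(n_plates):
        for i, cls in enumerate(CONTROL_CLASSES):
            for k in range(controls_per_class):
                control_wells[cls].append(
                    (plate, i * controls_per_class + k, 0))
        for r in range(rows):
            for c in range(1, cols):
                if g < n_genes:
                    gene_to_well[genes[g]] = (plate, r, c)
                    g += 1
    planted: dict = {}
    if n_hits > 0:
        hit_genes = rng.choice(genes, size=n_hits, replace=False)
        for i, gene in enumerate(hit_genes):
            s1 = float(rng.choice([-1.0, 1.0]))
            s2 = float(rng.choice([-1.0, 1.0]))
            kind = i % 3
            if kind == 0:
                planted[str(gene)] = (s1 * hit_effect, 0.0, 0.0)
            elif kind == 1:
                planted[str(gene)] = (0.0, s2 * hit_effect, 0.0)
            else:
                planted[str(gene)] = (s1 * hit_effect, s2 * hit_effect, 0.0)
    return ScreenDesignConfig(
        n_plates=n_plates, rows=rows, cols=cols,
        gene_to_well=gene_to_well, control_wells=control_wells,
        planted_effects=planted, artifact_sd=artifact_sd,
        n_replicates=n_replicates, seed=seed,
        cells_per_well=cells_per_well)


def _well_name(row: int, col: int) -> str:
    return f"{_ROW_LETTERS[row]}{col + 1:02d}"


def plate_map_frame(config: ScreenDesignConfig) -> pd.DataFrame:
    """Plate map as a tidy frame (plate, row, col, well, perturbation,
    control_class)."""
    recs = []
    for gene, (plate, r, c) in config.gene_to_well.items():
        recs.append((plate, r, c, _well_name(r, c), gene, "library"))
    for cls, wells in config.control_wells.items():
        for (plate, r, c) in wells:
            # each control well is its own perturbation instance
            recs.append((plate, r, c, _well_name(r, c),
                         f"ctrl_{cls}_p{plate}_{_well_name(r, c)}", cls))
    return pd.DataFrame(
        recs, columns=["plate", "row", "col", "well", "perturbation",
                       "control_class"]
    ).sort_values(["plate", "row", "col"]).reset_index(drop=True)


def simulate_screen(config: ScreenDesignConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate per-cell feature tables for a whole multi-replicate screen.

    Returns ``(cells, plate_map, truth)``:

    * ``cells`` — one row per cell with plate/row/col/replicate/perturbation
      keys and per-cell features (clustering_score, spot_count,
      mean_norm_radial, area_um2, solidity).
    * ``plate_map`` — the tidy well layout.
    * ``truth`` — one row per perturbation with the planted effect sizes and
      hit direction per metric.

    Neutral library genes and scrambled/neutral controls draw from the
    baseline distribution; planted effects shift the per-cell mean by
    effect x (expected robust SD of neutral well means); lethal-control
    wells draw cell counts at ``lethal_cell_fraction`` of baseline; the
    clustering control receives a fixed +4 clustering shift. Row/column
    artifacts are additive per plate and replicate.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    pm = plate_map_frame(cfg)
    s_clu = cfg.well_mean_sd(cfg.clustering_cell_sd, cfg.clustering_well_sd)
    s_cnt = cfg.well_mean_sd(cfg.spot_count_cell_sd, cfg.spot_count_well_sd)
    s_ncell = math.sqrt(cfg.cells_per_well)  # Poisson SD of cell counts

    effects = {}
    for gene, (d_clu, d_cnt, d_nc) in cfg.planted_effects.items():
        effects[gene] = (d_clu * s_clu, d_cnt * s_cnt, d_nc * s_ncell)

    frames = []
    for rep in range(1, cfg.n_replicates + 1):
        row_art = {}
        col_art = {}
        for plate in range(cfg.n_plates):
            row_art[plate] = (rng.normal(0.0, cfg.artifact_sd, cfg.rows)
                              if cfg.artifact_sd > 0 else np.zeros(cfg.rows))
            col_art[plate] = (rng.normal(0.0, cfg.artifact_sd, cfg.cols)
                              if cfg.artifact_sd > 0 else np.zeros(cfg.cols))
        for rec in pm.itertuples(index=False):
            plate, r, c = rec.plate, rec.row, rec.col
            pert, cls = rec.perturbation, rec.control_class
            lam = cfg.cells_per_well
            d_clu = d_cnt = 0.0
            if cls == "lethal":
                lam = cfg.cells_per_well * cfg.lethal_cell_fraction
            elif cls == "clustering":
                d_clu = 4.0 * s_clu
            elif cls == "library" and pert in effects:
                e_clu, e_cnt, e_nc = effects[pert]
                d_clu, d_cnt = e_clu, e_cnt
                lam = max(1.0, lam + e_nc)
            n_cells = max(1, int(rng.poisson(lam)))
            art = (row_art[plate][r] + col_art[plate][c])
            clu_shift = d_clu + art * s_clu \
                + rng.normal(0.0, cfg.clustering_well_sd)
            cnt_shift = d_cnt + art * s_cnt \
                + rng.normal(0.0, cfg.spot_count_well_sd)
            clu = cfg.clustering_mean + clu_shift \
                + rng.normal(0.0, cfg.clustering_cell_sd, n_cells)
            cnt = np.rint(np.clip(
                cfg.spot_count_mean + cnt_shift
                + rng.normal(0.0, cfg.spot_count_cell_sd, n_cells),
                1.0, None)).astype(int)
            rad = np.clip(rng.normal(cfg.radial_mean, cfg.radial_cell_sd,
                                     n_cells), 0.0, 1.0)
            area = np.clip(rng.normal(cfg.area_mean_um2, cfg.area_cell_sd,
                                      n_cells), 5.0, None)
            solidity = np.clip(rng.normal(0.96, 0.015, n_cells), 0.0, 1.0)
            fail = rng.random(n_cells) < cfg.qc_fail_frac
            # dysmorphic or micronucleus-like cells for the QC filter
            solidity[fail] = rng.uniform(0.5, 0.84, fail.sum())
            micro = fail & (rng.random(n_cells) < 0.5)
            area[micro] = rng.uniform(8.0, 28.0, micro.sum())
            frames.append(pd.DataFrame({
                "plate": plate, "row": r, "col": c,
                "well": _well_name(r, c), "replicate": rep,
                "perturbation": pert, "control_class": cls,
                "clustering_score": clu, "spot_count": cnt,
                "mean_norm_radial": rad, "area_um2": area,
                "solidity": solidity,
            }))
    cells = pd.concat(frames, ignore_index=True)

    truth_recs = []
    for gene in cfg.gene_to_well:
        d_clu, d_cnt, d_nc = cfg.planted_effects.get(gene, (0.0, 0.0, 0.0))
        truth_recs.append({
            "perturbation": gene,
            "effect_clustering": d_clu,
            "effect_spot_count": d_cnt,
            "effect_cell_count": d_nc,
            "is_hit": (d_clu != 0.0) or (d_cnt != 0.0),
            "clustering_direction": ("clustered" if d_clu > 0 else
                                     "unclustered" if d_clu < 0 else "none"),
            "count_direction": ("higher" if d_cnt > 0 else
                                "lower" if d_cnt < 0 else "none"),
        })
    truth = pd.DataFrame(truth_recs)
    return cells, pm, truth
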