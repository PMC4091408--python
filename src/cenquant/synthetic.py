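"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be produced here: 3D image
stacks of cells whose entire fluorophore pool is known photon-by-photon,
mitotic sister-centromere intensity tables produced by binomial partitioning,
quantitative-immunoblot dilution series with a linear mass response, bead
stacks for axial-oversampling calibration, and nucleosome-resolution
read-count profiles. The generators emit a ground-truth record alongside each
artifact so that downstream recovery is always tested against the generating
truth rather than against hard-coded numbers.

The defaults emulate the measured regime of a diploid human epithelial cell
line in which all CENP-A is fluorescent: 46 centromeres of ~400 molecules
each against a total cellular pool of ~91,000 molecules (a per-centromere
fraction of ~0.44%), sister-centromere partitioning of ~75 segregating units,
and a ~300 kb neocentromere with ~1,100 discrete nucleosome positions of
heterogeneous occupancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stack import ImageStack

__all__ = [
    "CellSimSpec",
    "CellGroundTruth",
    "PartitionSimSpec",
    "PartitionGroundTruth",
    "BlotSimSpec",
    "ProfileSimSpec",
    "make_cell_stack",
    "make_sister_pairs",
    "make_blot_series",
    "make_occupancy_profile",
    "make_bead_stack",
    "neocentromere_weights",
]


# ---------------------------------------------------------------------------
# cell image stacks
# ---------------------------------------------------------------------------

@dataclass
class CellSimSpec:
    """Parameters of a synthetic 3D cell stack.

    The fluorophore channel contains a diffuse pool plus ``n_centromeres``
    diffraction-limited foci inside the nucleus; an exclusion-stain channel is
    bright in the medium and dark inside cells; a nuclear-marker channel is
    bright inside the nucleus. An optional second, label-free cell carries
    autofluorescence only (the negative control used for autofluorescence
    subtraction).

    All physical quantities are in nm / fluorescence units; ``noise_model`` is
    one of ``"none"``, ``"poisson"`` or ``"gaussian"`` (with ``gaussian_sd``).
    """

    n_centromeres: int = 46
    molecules_per_centromere: int = 400
    total_molecules: int = 91_000
    brightness_per_molecule: float = 40.0
    psf_sigma_xy: float = 100.0      # nm, high-NA oil objective
    psf_sigma_z: float = 350.0       # nm
    pixel_size: float = 160.0        # nm
    z_step: float = 500.0            # nm; imaging at 500 nm axial sampling
    background_level: float = 20.0   # camera/medium offset, everywhere
    noise_model: str = "poisson"
    gaussian_sd: float = 0.0
    autofluorescence_per_voxel: float = 5.0
    seed: int = 0
    shape: tuple = (24, 256, 320)    # (Z, Y, X)
    include_negative_cell: bool = True
    nucleus_scale: float = 0.75      # nuclear semi-axes relative to the cell
    nuclear_pool_fraction: float = 0.5   # share of the diffuse pool in the nucleus
    exclusion_level: float = 600.0
    nuclear_marker_level: float = 400.0
    min_spot_xy_separation: float = 6.0  # px, in the lateral plane

    def validate(self) -> None:
        if self.n_centromeres < 1:
            raise ValueError("n_centromeres must be >= 1")
        if self.total_molecules < self.n_centromeres * self.molecules_per_centromere:
            raise ValueError(
                "total_molecules must be >= n_centromeres * molecules_per_centromere"
            )
        for name in ("brightness_per_molecule", "psf_sigma_xy", "psf_sigma_z",
                     "pixel_size", "z_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_model not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if not 0.0 <= self.nuclear_pool_fraction <= 1.0:
            raise ValueError("nuclear_pool_fraction must be in [0, 1]")


@dataclass
class CellGroundTruth:
    """What the generator actually deposited (fluorescence units = photons)."""

    spot_coords: np.ndarray          # (n, 3) float (z, y, x) voxel coordinates
    spot_photons: np.ndarray         # (n,) photons per centromeric focus
    total_photons: float             # entire labelled pool, foci + diffuse
    nuclear_photons: float           # labelled pool inside the nucleus
    fraction_per_centromere: float   # spot_photons / total_photons
    nuclear_fraction_per_centromere: float
    cell_mask: np.ndarray            # bool (Z, Y, X)
    nucleus_mask: np.ndarray
    negative_mask: np.ndarray | None
    autofluorescence_per_voxel: float
    background_level: float


def _ellipsoid(shape, center, radii) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    rz, ry, rx = radii
    return (
        ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    ) <= 1.0


def _gauss_kernel_1d(center: float, sigma: float, lo: int, hi: int) -> np.ndarray:
    idx = np.arange(lo, hi)
    return np.exp(-0.5 * ((idx - center) / sigma) ** 2)


def _render_point_source(img: np.ndarray, coord, sigma_z: float, sigma_xy: float,
                         photons: float) -> None:
    """Add a separable 3D Gaussian with total mass ``photons`` (conserved)."""
    z, y, x = coord
    nz, ny, nx = img.shape
    hz = max(int(np.ceil(4 * sigma_z)), 1)
    hxy = max(int(np.ceil(4 * sigma_xy)), 1)
    z0, z1 = max(int(z) - hz, 0), min(int(z) + hz + 1, nz)
    y0, y1 = max(int(y) - hxy, 0), min(int(y) + hxy + 1, ny)
    x0, x1 = max(int(x) - hxy, 0), min(int(x) + hxy + 1, nx)
    kz = _gauss_kernel_1d(z, sigma_z, z0, z1)
    ky = _gauss_kernel_1d(y, sigma_xy, y0, y1)
    kx = _gauss_kernel_1d(x, sigma_xy, x0, x1)
    kernel = kz[:, None, None] * ky[None, :, None] * kx[None, None, :]
    kernel *= photons / kernel.sum()
    img[z0:z1, y0:y1, x0:x1] += kernel


def _place_spots(rng, spec: CellSimSpec, center, radii, margins,
                 max_tries: int = 20_000) -> np.ndarray:
    """Rejection-sample focus centres inside an eroded ellipsoid.

    Enforces a minimum lateral (xy) separation so that foci stay resolvable
    in a maximum-intensity projection.
    """
    cz, cy, cx = center
    rz, ry, rx = (max(r - m, 0.5) for r, m in zip(radii, margins))
    coords = []
    tries = 0
    while len(coords) < spec.n_centromeres:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not place all centromeric foci with the requested "
                "min_spot_xy_separation; relax min_spot_xy_separation, shrink "
                "n_centromeres, or enlarge shape/nucleus_scale"
            )
        u = rng.uniform(-1, 1, size=3)
        if (u ** 2).sum() > 1.0:
            continue
        cand = np.array([cz + u[0] * rz, cy + u[1] * ry, cx + u[2] * rx])
        ok = all(
            np.hypot(cand[1] - p[1], cand[2] - p[2]) >= spec.min_spot_xy_separation
            for p in coords
        )
        if ok:
            coords.append(cand)
    return np.array(coords)


def _apply_noise(rng, img: np.ndarray, model: str, gaussian_sd: float) -> np.ndarray:
    if model == "none":
        return img
    if model == "poisson":
        return rng.poisson(np.clip(img, 0, None)).astype(float)
    if model == "gaussian":
        return img + rng.normal(0.0, gaussian_sd, size=img.shape)
    raise ValueError(f"unknown noise model {model!r}")


def make_cell_stack(spec: CellSimSpec) -> tuple[ImageStack, CellGroundTruth]:
    """Generate a three-channel cell stack plus its ground truth.

    Channels: ``"fluor"`` (labelled pool + foci + autofluorescence +
    background), ``"exclusion"`` (medium bright, cells dark) and ``"nuclear"``
    (marker bright inside the nucleus). Fixed ``spec.seed`` gives bit-identical
    output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape

    # geometry: a positive (labelled) cell, optionally a label-free neighbour
    cell_center = (nz / 2 - 0.5, ny / 2 - 0.5, nx * 0.34)
    cell_radii = (nz * 0.375, ny * 0.2, ny * 0.2)
    cell = _ellipsoid(spec.shape, cell_center, cell_radii)
    nuc_radii = tuple(r * spec.nucleus_scale for r in cell_radii)
    nucleus = _ellipsoid(spec.shape, cell_center, nuc_radii)

    negative = None
    if spec.include_negative_cell:
        neg_center = (nz / 2 - 0.5, ny / 2 - 0.5, nx * 0.79)
        neg_radii = (nz * 0.33, ny * 0.16, ny * 0.16)
        negative = _ellipsoid(spec.shape, neg_center, neg_radii)

    b = spec.brightness_per_molecule
    centromeric = spec.n_centromeres * spec.molecules_per_centromere
    pool = spec.total_molecules - centromeric
    pool_nuc = pool * spec.nuclear_pool_fraction
    pool_cyto = pool - pool_nuc

    fluor = np.full(spec.shape, float(spec.background_level))
    fluor[cell] += spec.autofluorescence_per_voxel
    if negative is not None:
        fluor[negative] += spec.autofluorescence_per_voxel

    cyto = cell & ~nucleus
    if cyto.sum() == 0:  # nucleus fills the cell: keep the whole pool nuclear
        pool_nuc, pool_cyto = pool, 0.0
    fluor[nucleus] += pool_nuc * b / nucleus.sum()
    if pool_cyto > 0:
        fluor[cyto] += pool_cyto * b / cyto.sum()

    # centromeric foci, inside the nucleus with a PSF-sized safety margin
    sigma_xy_px = spec.psf_sigma_xy / spec.pixel_size
    sigma_z_pl = spec.psf_sigma_z / spec.z_step
    margins = (np.ceil(4 * sigma_z_pl), np.ceil(4 * sigma_xy_px) + 1,
               np.ceil(4 * sigma_xy_px) + 1)
    coords = _place_spots(rng, spec, cell_center, nuc_radii, margins)
    spot_photons = np.full(spec.n_centromeres,
                           spec.molecules_per_centromere * b, dtype=float)
    for coord, ph in zip(coords, spot_photons):
        _render_point_source(fluor, coord, sigma_z_pl, sigma_xy_px, ph)

    exclusion = np.full(spec.shape, spec.exclusion_level)
    inside = cell if negative is None else (cell | negative)
    exclusion[inside] = 0.05 * spec.exclusion_level
    nuclear = np.full(spec.shape, 0.02 * spec.nuclear_marker_level)
    nuclear[nucleus] = spec.nuclear_marker_level

    fluor = _apply_noise(rng, fluor, spec.noise_model, spec.gaussian_sd)
    exclusion = _apply_noise(rng, exclusion, spec.noise_model, spec.gaussian_sd)
    nuclear = _apply_noise(rng, nuclear, spec.noise_model, spec.gaussian_sd)

    stack = ImageStack(
        voxels=np.stack([fluor, exclusion, nuclear]),
        channels=["fluor", "exclusion", "nuclear"],
        pixel_size_nm=spec.pixel_size,
        z_step_nm=spec.z_step,
    )
    total_photons = spec.total_molecules * b
    nuclear_photons = (centromeric + pool_nuc) * b
    truth = CellGroundTruth(
        spot_coords=coords,
        spot_photons=spot_photons,
        total_photons=total_photons,
        nuclear_photons=nuclear_photons,
        fraction_per_centromere=spec.molecules_per_centromere
        / spec.total_molecules,
        nuclear_fraction_per_centromere=spot_photons[0] / nuclear_photons,
        cell_mask=cell,
        nucleus_mask=nucleus,
        negative_mask=negative,
        autofluorescence_per_voxel=spec.autofluorescence_per_voxel,
        background_level=spec.background_level,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# bead stacks (axial oversampling calibration)
# ---------------------------------------------------------------------------

def make_bead_stack(psf_sigma_z: float = 350.0, z_step: float = 500.0,
                    n_beads: int = 25, psf_sigma_xy: float = 100.0,
                    pixel_size: float = 160.0, n_planes: int = 25,
                    brightness: float = 10_000.0, seed: int = 0) -> ImageStack:
    """Isolated sub-diffraction beads on a grid, sampled at ``z_step``.

    Bead z-centres are drawn uniformly within one central z-step so the stack
    samples all phases of the axial PSF relative to the plane grid, exactly as
    a bead slide does.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    rng = np.random.default_rng(seed)
    spacing = 14
    per_row = int(np.ceil(np.sqrt(n_beads)))
    side = per_row * spacing + spacing
    img = np.zeros((n_planes, side, side))
    sigma_xy_px = psf_sigma_xy / pixel_size
    sigma_z_pl = psf_sigma_z / z_step
    zc = (n_planes - 1) / 2
    for i in range(n_beads):
        r, c = divmod(i, per_row)
        y = spacing + r * spacing
        x = spacing + c * spacing
        z = zc + rng.uniform(-0.5, 0.5)
        _render_point_source(img, (z, y, x), sigma_z_pl, sigma_xy_px, brightness)
    return ImageStack(voxels=img[None], channels=["beads"],
                      pixel_size_nm=pixel_size, z_step_nm=z_step)


# ---------------------------------------------------------------------------
# sister-centromere partitioning
# ---------------------------------------------------------------------------

@dataclass
class PartitionSimSpec:
    """Binomial partitioning of segregating units onto sister centromeres.

    Each centromere carries ``N_i`` segregating units (mean ``units_mean``,
    lognormal across centromeres with coefficient of variation
    ``units_dispersion``); replication splits them Binomial(N_i, 1/2) onto the
    two sisters, each unit contributing ``unit_brightness`` fluorescence.
    """

    n_centromeres_per_cell: int = 46
    n_cells: int = 20
    units_mean: float = 75.4
    units_dispersion: float = 0.25   # CV of per-centromere totals
    unit_brightness: float = 100.0
    measurement_noise_sd: float = 0.0
    seed: int = 0
    experiment_id: str = "exp1"

    def validate(self) -> None:
        if self.units_mean < 1:
            raise ValueError("units_mean must be >= 1")
        if self.units_dispersion < 0:
            raise ValueError("units_dispersion must be >= 0")
        if self.n_centromeres_per_cell < 1 or self.n_cells < 1:
            raise ValueError("n_centromeres_per_cell and n_cells must be >= 1")


@dataclass
class PartitionGroundTruth:
    units_per_pair: np.ndarray       # true N_i for every pair
    unit_brightness: float
    truncated_draws: int             # negative noise draws floored at 0


def make_sister_pairs(spec: PartitionSimSpec) -> tuple[pd.DataFrame, PartitionGroundTruth]:
    """Simulate a sister-pair intensity table.

    Returns a table with columns ``experiment_id, cell_id, pair_id, i1, i2``
    (sister identity preserved: ``i1``/``i2`` are the two sisters of the same
    centromere) plus the ground truth of per-centromere unit totals.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_centromeres_per_cell * spec.n_cells
    if spec.units_dispersion > 0:
        sigma2 = np.log1p(spec.units_dispersion ** 2)
        mu = np.log(spec.units_mean) - sigma2 / 2
        totals = rng.lognormal(mu, np.sqrt(sigma2), size=n)
        totals = np.maximum(np.rint(totals).astype(int), 1)
    else:
        totals = np.full(n, int(round(spec.units_mean)))
    x = rng.binomial(totals, 0.5)
    i1 = x * spec.unit_brightness
    i2 = (totals - x) * spec.unit_brightness
    truncated = 0
    if spec.measurement_noise_sd > 0:
        i1 = i1 + rng.normal(0, spec.measurement_noise_sd, size=n)
        i2 = i2 + rng.normal(0, spec.measurement_noise_sd, size=n)
        truncated = int((i1 < 0).sum() + (i2 < 0).sum())
        i1 = np.clip(i1, 0, None)
        i2 = np.clip(i2, 0, None)
    table = pd.DataFrame(
        {
            "experiment_id": spec.experiment_id,
            "cell_id": np.repeat(np.arange(spec.n_cells), spec.n_centromeres_per_cell),
            "pair_id": np.arange(n),
            "i1": i1.astype(float),
            "i2": i2.astype(float),
        }
    )
    truth = PartitionGroundTruth(
        units_per_pair=totals.astype(float),
        unit_brightness=spec.unit_brightness,
        truncated_draws=truncated,
    )
    return table, truth


# ---------------------------------------------------------------------------
# quantitative immunoblot series
# ---------------------------------------------------------------------------

@dataclass
class BlotSimSpec:
    """A linear signal-vs-mass immunoblot with a cellular sample lane.

    Default standards span a 32-fold mass range; the default sample mass is
    the CENP-A content of 150,000 cells at 9.1e4 molecules per cell and a
    16 kDa molar mass (~0.363 ng).
    """

    standard_masses: tuple = (0.1, 0.2, 0.4, 0.8, 1.6, 3.2)  # ng
    slope: float = 1000.0       # signal per ng
    intercept: float = 50.0     # signal
    noise_sd: float = 0.0       # signal
    sample_mass: float = 0.3626  # ng
    n_cells: int = 150_000
    molar_mass: float = 16_000.0  # Da
    seed: int = 0

    def validate(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if any(m < 0 for m in self.standard_masses) or self.sample_mass < 0:
            raise ValueError("masses must be >= 0")


def make_blot_series(spec: BlotSimSpec) -> pd.DataFrame:
    """Standards plus one sample lane as a ``(lane, mass_ng, signal, is_sample)`` table."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    masses = np.asarray(spec.standard_masses, dtype=float)
    signals = spec.slope * masses + spec.intercept
    sample_signal = spec.slope * spec.sample_mass + spec.intercept
    if spec.noise_sd > 0:
        signals = signals + rng.normal(0, spec.noise_sd, size=masses.size)
        sample_signal = sample_signal + rng.normal(0, spec.noise_sd)
    rows = [
        {"lane": i, "mass_ng": m, "signal": s, "is_sample": False}
        for i, (m, s) in enumerate(zip(masses, signals))
    ]
    rows.append(
        {"lane": len(rows), "mass_ng": np.nan, "signal": float(sample_signal),
         "is_sample": True}
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nucleosome-occupancy read profiles
# ---------------------------------------------------------------------------

def neocentromere_weights(n_positions: int = 1113, n_nucleosomes: float = 216.0,
                          max_occupancy: float = 0.8, min_occupancy: float = 0.005,
                          shape: float = 0.32, seed: int = 0) -> np.ndarray:
    """Heavy-tailed per-position occupancy weights with a bounded range.

    Draws gamma-distributed weights and iterates clipping + renormalization so
    that the implied occupancies ``n_nucleosomes * w / sum(w)`` span roughly
    ``[min_occupancy, max_occupancy]``: occupancy probabilities are per-cell
    fractions, every identified position is occupied in at least a small
    share of cells, and no probability can exceed 1 for a consistent
    absolute count. Returns the occupancies themselves as weights (their sum
    is ~``n_nucleosomes``, but only ratios matter downstream).
    """
    rng = np.random.default_rng(seed)
    raw = rng.gamma(shape, 1.0, size=n_positions)
    occ = n_nucleosomes * raw / raw.sum()
    for _ in range(200):
        clipped = np.clip(occ, min_occupancy, max_occupancy)
        clipped *= n_nucleosomes / clipped.sum()
        if np.allclose(clipped, occ, rtol=1e-12, atol=0):
            break
        occ = clipped
    return np.clip(occ, min_occupancy, max_occupancy)


@dataclass
class ProfileSimSpec:
    """A read-count profile concentrated on discrete nucleosome positions."""

    n_positions: int = 1113
    locus_length: int = 300_000          # bp
    occupancy_weights: np.ndarray | None = None  # default: heavy-tailed draw
    read_depth: int = 500_000
    read_length: int = 147               # bp footprint per read
    position_jitter_sd: float = 20.0     # bp, read-centre scatter around a position
    seed: int = 0
    positions: np.ndarray | None = None  # explicit bp positions (optional)

    def validate(self) -> None:
        if self.n_positions < 1:
            raise ValueError("n_positions must be >= 1")
        if self.locus_length <= 0 or self.read_length <= 0:
            raise ValueError("locus_length and read_length must be > 0")
        if self.occupancy_weights is not None:
            w = np.asarray(self.occupancy_weights, dtype=float)
            if w.size != self.n_positions:
                raise ValueError("occupancy_weights length must equal n_positions")
            if np.any(w < 0) or not np.isfinite(w.sum()) or w.sum() <= 0:
                raise ValueError("weights must be nonnegative with a positive finite sum")
        if self.positions is not None:
            p = np.asarray(self.positions)
            if p.size != self.n_positions:
                raise ValueError("positions length must equal n_positions")
            if p.min() < 0 or p.max() >= self.locus_length:
                raise ValueError("positions must lie within the locus")


def make_occupancy_profile(spec: ProfileSimSpec):
    """Place reads on nucleosome positions proportionally to their weights.

    Returns ``(profile, truth)`` where ``profile`` is a
    :class:`cenquant.occupancy.ReadProfile` of per-bp counts and ``truth`` is a
    dict with the generating positions, weights and per-position read counts.
    A zero ``read_depth`` yields an all-zero profile with a warning.
    """
    from .occupancy import ReadProfile  # local import to avoid a cycle

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.positions is not None:
        positions = np.asarray(spec.positions, dtype=int)
    else:
        margin = spec.read_length
        span = spec.locus_length - 2 * margin
        base = np.linspace(margin, margin + span, spec.n_positions, endpoint=False)
        step = span / spec.n_positions
        jitter = rng.uniform(-0.2 * step, 0.2 * step, size=spec.n_positions)
        positions = np.clip((base + jitter).astype(int), 0, spec.locus_length - 1)
    if spec.occupancy_weights is not None:
        weights = np.asarray(spec.occupancy_weights, dtype=float)
    else:
        weights = neocentromere_weights(spec.n_positions, seed=spec.seed)
    weights = np.asarray(weights, dtype=float)

    counts_per_bp = np.zeros(spec.locus_length)
    if spec.read_depth == 0:
        warnings.warn("read_depth is 0: emitting an all-zero profile")
        reads = np.zeros(spec.n_positions, dtype=int)
    else:
        reads = rng.multinomial(spec.read_depth, weights / weights.sum())
        half = spec.read_length // 2
        centers = np.repeat(positions, reads)
        if spec.position_jitter_sd > 0 and centers.size:
            centers = centers + np.rint(
                rng.normal(0, spec.position_jitter_sd, size=centers.size)
            ).astype(int)
        lo = np.clip(centers - half, 0, spec.locus_length)
        hi = np.clip(lo + spec.read_length, 0, spec.locus_length)
        diff = np.zeros(spec.locus_length + 1)
        np.add.at(diff, lo, 1.0)
        np.add.at(diff, hi, -1.0)
        counts_per_bp = np.cumsum(diff)[: spec.locus_length]
    profile = ReadProfile(start=0, counts=counts_per_bp, chrom="neoCEN")
    truth = {"positions": positions, "weights": weights, "reads": reads}
    return profile, truth
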