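"""Synthetic OCT B-scan phantoms with class-specific Beer-Lambert decay.

A forward-viewing endoscopic OCT probe images tissue through a GRIN relay
lens whose distal surface shows up as a saturated bright line at the top of
every B-scan.  Below the tissue surface the ensemble-mean intensity follows
the Beer-Lambert law

    I(z) = I0 * exp(-2 * mu * z),

where ``mu`` (mm^-1) is the attenuation coefficient and ``z`` the physical
depth below the tissue surface.  Individual pixels are drawn as fully
developed speckle: intensity is exponentially distributed around the local
ensemble mean, i.e. multiplicative unit-mean noise.  Because
``E[log Exp(m)] = log m - gamma`` the speckle shifts the log-intensity by a
depth-independent constant and leaves the log-slope (hence the estimated
``mu``) asymptotically unbiased.

Six renal phenotypes are modelled: cortex and medulla (homogeneous, medulla
less attenuating so it images deeper), calyx (alternating bright/dark strata,
modelled as a sinusoidal depth-modulation of ``mu``), fat (dark, with sparse
bright circular inclusions standing in for adipocytes), pelvis (a fluid-
filled space with no tissue signal below the lens surface) and tumor (the
brightest and most strongly attenuating class, so it has the shallowest
imaging depth).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "TissuePhenotype",
    "BScan",
    "PhantomDataset",
    "default_phenotypes",
    "render_bscan",
    "generate_dataset",
    "render_from_manifest_row",
]

#: Default image geometry: 650 lateral A-scans x 1050 depth pixels at
#: 2 um/px, i.e. a 1.30 mm x 2.10 mm field of view.
N_LATERAL = 650
N_DEPTH = 1050
PIXEL_PITCH_MM = 0.002

#: Intensity written into the saturated GRIN-lens surface band (rows 0-2).
SURFACE_BAND_INTENSITY = 20000.0
SURFACE_BAND_ROWS = 3

#: Fixed scale used when quantizing float intensities to 16-bit TIFF.
TIFF_SCALE = 1.0


@dataclass(frozen=True)
class TissuePhenotype:
    """Generative parameters for one tissue class.

    Parameters
    ----------
    name
        Tissue label (``cortex``, ``medulla``, ``calyx``, ``fat``,
        ``pelvis`` or ``tumor`` in the default configuration).
    mu
        Attenuation coefficient in mm^-1.
    i0
        Mean backscatter intensity at the tissue surface (arbitrary units).
    surface_row
        Depth-pixel index of the tissue surface.
    stripe_period_px
        Depth period (pixels) of the sinusoidal ``mu`` modulation producing
        the layered calyx appearance; 0 disables it.
    stripe_contrast
        Relative modulation amplitude of ``mu`` in [0, 1).
    dot_density
        Bright circular inclusions per mm^2 (fat only; 0 disables).
    dot_intensity_gain
        Multiplicative brightness of the inclusions.
    has_tissue_signal
        False for the pelvis: only the lens-surface band and the noise
        floor are emitted.
    """

    name: str
    mu: float
    i0: float
    surface_row: int = 5
    stripe_period_px: float = 0.0
    stripe_contrast: float = 0.0
    dot_density: float = 0.0
    dot_intensity_gain: float = 3.0
    has_tissue_signal: bool = True

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if self.has_tissue_signal and self.i0 <= 0:
            raise ValueError("i0 must be > 0 for a phenotype with tissue signal")
        if not 0.0 <= self.stripe_contrast < 1.0:
            raise ValueError("stripe_contrast must lie in [0, 1)")
        if self.surface_row < 0 or self.surface_row >= N_DEPTH:
            raise ValueError("surface_row outside the image depth range")
        if self.dot_density < 0:
            raise ValueError("dot_density must be >= 0")


@dataclass
class BScan:
    """One OCT cross-sectional image: ``pixels[depth, lateral]``, all >= 0."""

    pixels: np.ndarray
    lateral_pitch_mm: float = PIXEL_PITCH_MM
    axial_pitch_mm: float = PIXEL_PITCH_MM
    subject_id: str = ""
    label: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array (depth x lateral)")
        if self.lateral_pitch_mm <= 0 or self.axial_pitch_mm <= 0:
            raise ValueError("invalid geometry: pixel pitch must be positive")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def n_depth(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_lateral(self) -> int:
        return self.pixels.shape[1]

    def to_tiff(self, path: str | Path) -> None:
        """Write as 16-bit grayscale TIFF at the fixed scale ``TIFF_SCALE``."""
        counts = np.clip(np.rint(self.pixels * TIFF_SCALE), 0, 65535)
        tifffile.imwrite(str(path), counts.astype(np.uint16))


def default_phenotypes() -> dict[str, TissuePhenotype]:
    """Default generative parameters for the six renal tissue classes.

    The attenuation ordering (tumor highest; medulla lowest among the
    signal-bearing classes, hence deepest penetration) and the qualitative
    texture of each class follow the published appearance of endoscopic OCT
    kidney images; the numeric values themselves are free simulator
    parameters, since no quantitative mu scale is available for this probe.
    """
    return {
        "cortex": TissuePhenotype(name="cortex", mu=2.5, i0=800.0),
        "medulla": TissuePhenotype(name="medulla", mu=1.5, i0=700.0),
        "calyx": TissuePhenotype(
            name="calyx", mu=3.0, i0=750.0, stripe_period_px=40.0, stripe_contrast=0.35
        ),
        "fat": TissuePhenotype(
            name="fat", mu=2.0, i0=300.0, dot_density=8.0, dot_intensity_gain=4.0
        ),
        "pelvis": TissuePhenotype(name="pelvis", mu=0.0, i0=0.0, has_tissue_signal=False),
        "tumor": TissuePhenotype(name="tumor", mu=8.0, i0=1200.0),
    }


def _mean_image(
    phenotype: TissuePhenotype,
    noise_floor: float,
    shape: tuple[int, int],
    axial_pitch_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Ensemble-mean intensity before speckle is applied."""
    n_depth, n_lateral = shape
    mean = np.full(shape, noise_floor, dtype=np.float64)

    if phenotype.has_tissue_signal and phenotype.surface_row < n_depth:
        rows = np.arange(n_depth - phenotype.surface_row)
        if phenotype.stripe_period_px > 0 and phenotype.stripe_contrast > 0:
            mu_profile = phenotype.mu * (
                1.0
                + phenotype.stripe_contrast
                * np.sin(2.0 * np.pi * rows / phenotype.stripe_period_px)
            )
            # left-Riemann cumulative optical path, exact for constant mu
            atten = np.concatenate(([0.0], np.cumsum(mu_profile[:-1]))) * axial_pitch_mm
        else:
            atten = phenotype.mu * rows * axial_pitch_mm
        decay = phenotype.i0 * np.exp(-2.0 * atten)
        mean[phenotype.surface_row :, :] += decay[:, None]

        if phenotype.dot_density > 0:
            _add_dots(mean, phenotype, axial_pitch_mm, rng)

    mean[:SURFACE_BAND_ROWS, :] = SURFACE_BAND_INTENSITY
    return mean


def _add_dots(
    mean: np.ndarray,
    phenotype: TissuePhenotype,
    axial_pitch_mm: float,
    rng: np.random.Generator,
    radius_px: int = 3,
) -> None:
    """Superpose bright circular inclusions (adipocyte-like dots) in place."""
    n_depth, n_lateral = mean.shape
    depth_extent = n_depth - phenotype.surface_row
    area_mm2 = (n_lateral * axial_pitch_mm) * (depth_extent * axial_pitch_mm)
    n_dots = rng.poisson(phenotype.dot_density * area_mm2)
    if n_dots == 0:
        return
    centers_r = rng.integers(phenotype.surface_row, n_depth, size=n_dots)
    centers_c = rng.integers(0, n_lateral, size=n_dots)
    rr, cc = np.ogrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    disk = (rr**2 + cc**2) <= radius_px**2
    for r, c in zip(centers_r, centers_c):
        r0, r1 = max(r - radius_px, 0), min(r + radius_px + 1, n_depth)
        c0, c1 = max(c - radius_px, 0), min(c + radius_px + 1, n_lateral)
        sub = disk[
            r0 - (r - radius_px) : disk.shape[0] - ((r + radius_px + 1) - r1),
            c0 - (c - radius_px) : disk.shape[1] - ((c + radius_px + 1) - c1),
        ]
        region = mean[r0:r1, c0:c1]
        region[sub] *= phenotype.dot_intensity_gain


def render_bscan(
    phenotype: TissuePhenotype,
    noise_floor: float = 0.0,
    seed: int = 0,
    *,
    shape: tuple[int, int] = (N_DEPTH, N_LATERAL),
    lateral_pitch_mm: float = PIXEL_PITCH_MM,
    axial_pitch_mm: float = PIXEL_PITCH_MM,
    speckle: bool = True,
    speckle_looks: float = 1.0,
    axial_blur_um: float = 0.0,
    subject_id: str = "",
) -> BScan:
    """Render one labeled B-scan for a tissue phenotype.

    Rows 0-2 carry the saturated GRIN-lens surface band.  Below
    ``phenotype.surface_row`` the ensemble mean decays as
    ``i0 * exp(-2 mu dz) + noise_floor``; with ``speckle`` enabled each pixel
    is drawn independently from an exponential distribution with that mean
    (``speckle_looks > 1`` switches to gamma speckle of that many looks,
    keeping the mean).  Phenotypes without tissue signal (pelvis) emit only
    the surface band on top of the noise floor.

    Parameters
    ----------
    noise_floor
        Additive mean background intensity; 0 reproduces the published
        pelvis behaviour where pixels below the lens surface are zero.
    axial_blur_um
        Optional Gaussian axial blur (1-sigma, micrometres) emulating finite
        axial resolution; off by default.
    """
    if noise_floor < 0:
        raise ValueError("noise_floor must be >= 0")
    if lateral_pitch_mm <= 0 or axial_pitch_mm <= 0:
        raise ValueError("invalid geometry: pixel pitch must be positive")
    if speckle_looks <= 0:
        raise ValueError("speckle_looks must be > 0")

    rng = np.random.default_rng(seed)
    mean = _mean_image(phenotype, noise_floor, shape, axial_pitch_mm, rng)

    if speckle:
        body = mean[SURFACE_BAND_ROWS:, :]
        if speckle_looks == 1.0:
            speckled = rng.exponential(body)
        else:
            speckled = rng.gamma(speckle_looks, body / speckle_looks)
        pixels = mean.copy()
        pixels[SURFACE_BAND_ROWS:, :] = speckled
    else:
        pixels = mean

    if axial_blur_um > 0:
        from scipy.ndimage import gaussian_filter1d

        sigma_px = axial_blur_um / (axial_pitch_mm * 1000.0)
        pixels = gaussian_filter1d(pixels, sigma_px, axis=0, mode="nearest")

    return BScan(
        pixels=pixels,
        lateral_pitch_mm=lateral_pitch_mm,
        axial_pitch_mm=axial_pitch_mm,
        subject_id=subject_id,
        label=phenotype.name,
        seed=seed,
    )


@dataclass
class PhantomDataset:
    """A collection of labeled B-scans plus a complete generation manifest.

    ``manifest`` holds one row per scan (scan_id, subject_id, label, seed and
    the full phenotype parameters actually used), so any scan can be
    regenerated bit-exactly with :func:`render_from_manifest_row`.
    Subject ids are the unit of the cross-testing splits.
    """

    scans: list[BScan] = field(default_factory=list)
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)
    noise_floor: float = 0.0

    def __len__(self) -> int:
        return len(self.scans)

    def save(self, outdir: str | Path, *, images: bool = True, archive: bool = False) -> None:
        """Write manifest.csv plus per-scan TIFFs and/or a bundled .npz."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.manifest.to_csv(outdir / "manifest.csv", index=False)
        if images:
            for scan_id, scan in zip(self.manifest["scan_id"], self.scans):
                scan.to_tiff(outdir / f"{scan_id}.tiff")
        if archive:
            arrays = {
                str(scan_id): scan.pixels
                for scan_id, scan in zip(self.manifest["scan_id"], self.scans)
            }
            np.savez_compressed(outdir / "scans.npz", **arrays)


_MANIFEST_PHENOTYPE_COLS = (
    "mu",
    "i0",
    "surface_row",
    "stripe_period_px",
    "stripe_contrast",
    "dot_density",
    "dot_intensity_gain",
    "has_tissue_signal",
)


def render_from_manifest_row(
    row: pd.Series | dict,
    noise_floor: float = 0.0,
    **render_kwargs,
) -> BScan:
    """Re-render a scan bit-exactly from its manifest record."""
    phenotype = TissuePhenotype(
        name=str(row["label"]),
        **{k: row[k] for k in _MANIFEST_PHENOTYPE_COLS},
    )
    return render_bscan(
        phenotype,
        noise_floor=noise_floor,
        seed=int(row["seed"]),
        subject_id=str(row["subject_id"]),
        **render_kwargs,
    )


def _jitter_phenotype(
    phenotype: TissuePhenotype, jitter: float, rng: np.random.Generator
) -> TissuePhenotype:
    """Subject-level variation: mu and i0 scaled by independent U(1-j, 1+j)."""
    if not phenotype.has_tissue_signal or jitter == 0:
        return phenotype
    return dataclasses.replace(
        phenotype,
        mu=phenotype.mu * rng.uniform(1.0 - jitter, 1.0 + jitter),
        i0=phenotype.i0 * rng.uniform(1.0 - jitter, 1.0 + jitter),
    )


def generate_dataset(
    config: dict[str, TissuePhenotype] | None = None,
    n_subjects: int = 5,
    n_per_class_per_subject: int = 10,
    seed: int = 0,
    *,
    subject_jitter: float = 0.15,
    noise_floor: float = 0.0,
    shape: tuple[int, int] = (N_DEPTH, N_LATERAL),
    speckle: bool = True,
    speckle_looks: float = 1.0,
) -> PhantomDataset:
    """Generate a labeled multi-subject phantom dataset.

    Per subject, each class's phenotype parameters are drawn once (mu and i0
    jittered by ``subject_jitter``, default +/-15%) to give genuine
    between-subject variance, mirroring a multi-kidney study design; the
    requested number of scans per class is then rendered with fresh per-scan
    seeds.  Fully reproducible from ``seed``; every scan is recorded in the
    manifest with the exact parameters and seed used.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (subjects are the split unit)")
    if config is None:
        config = default_phenotypes()
    if not config:
        raise ValueError("configuration error: empty class list")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    scans: list[BScan] = []
    records: list[dict] = []
    for s in range(n_subjects):
        subject_id = f"subject{s:02d}"
        for label in config:
            phen = _jitter_phenotype(config[label], subject_jitter, rng)
            for i in range(n_per_class_per_subject):
                scan_seed = int(rng.integers(0, 2**31))
                scan = render_bscan(
                    phen,
                    noise_floor=noise_floor,
                    seed=scan_seed,
                    shape=shape,
                    speckle=speckle,
                    speckle_looks=speckle_looks,
                    subject_id=subject_id,
                )
                scans.append(scan)
                rec = {
                    "scan_id": f"{subject_id}_{label}_{i:04d}",
                    "subject_id": subject_id,
                    "label": label,
                    "seed": scan_seed,
                }
                rec.update({k: getattr(phen, k) for k in _MANIFEST_PHENOTYPE_COLS})
                records.append(rec)
    return PhantomDataset(
        scans=scans, manifest=pd.DataFrame.from_records(records), noise_floor=noise_floor
    )
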