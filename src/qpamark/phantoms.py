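"""Digital phantoms for fluence-marker absorption recovery studies.

Three families of 2D phantoms are generated, all with a central "fluence
marker" — a chromophore whose absorption coefficient is known a priori
(e.g. arterial blood):

* a nine-level absorption phantom on a 20 mm square with scored inclusions
  at several depths, for comparing recovery algorithms;
* a two-concentric-disc spectral phantom whose background and "unknown
  chromophore" absorption vary over five wavelengths, for spectral
  coloring/decoloring studies;
* a carotid-artery cross-section (24 mm, 0.15 mm pixels) with literature
  tissue absorption values at 930 nm, where lipid absorption peaks.

Phantom generation is fully deterministic: the same arguments always yield
bit-identical maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fem import GridSpec, OpticalMap


@dataclass
class RegionLabelMap:
    """Integer label map plus a legend of (name, ground-truth mu_a) per label.

    Label 0 is the background. For multi-wavelength phantoms the legend
    truth is a tuple of per-wavelength values; otherwise a scalar.
    """

    labels: np.ndarray
    legend: dict[int, tuple[str, float | tuple[float, ...]]]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels without a legend entry: {sorted(missing)}")

    def pixels(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class MarkerPrior:
    """The fluence-marker constraint: pixel mask plus known absorption.

    ``mu_a_marker`` is the marker's absorption coefficient in mm^-1 — a
    scalar, or one value per wavelength for spectral datasets.
    """

    mask: np.ndarray
    mu_a_marker: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("marker mask is empty")
        if not np.all(np.asarray(self.mu_a_marker) > 0):
            raise ValueError("mu_a_marker must be positive")

    @property
    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(im, jm) row/column pixel indices of the marker."""
        return np.nonzero(self.mask)


def _disc(grid: GridSpec, cx: float, cy: float, radius: float) -> np.ndarray:
    X, Y = grid.pixel_centers()
    return (X - cx) ** 2 + (Y - cy) ** 2 <= radius**2


def _optical(grid: GridSpec, mu_a: np.ndarray, mu_s_prime: float) -> OpticalMap:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # phantom values are intentional
        return OpticalMap(grid, mu_a, np.full(grid.shape, mu_s_prime))


# ---------------------------------------------------------------------------
# Nine-region phantom (20 mm x 20 mm, default 0.2 mm pixels)
# ---------------------------------------------------------------------------

#: Layout at the design extent of 20 mm: (label, name, mu_a mm^-1, cx, cy, radius).
#: Scored regions 1-3 are shallow (5 mm from the nearest boundary) at distinct
#: bearings; region 4 is deep (13.5 mm below the top surface), laterally offset
#: from the marker shadow; region 5 is a background-level patch directly below
#: the marker, inside its shadow. Labels 6-9 are unscored inclusions completing
#: the nine absorption levels spanning 0.001 to 0.2 mm^-1.
NINE_REGION_LAYOUT = (
    (1, "region1", 0.020, 5.0, 5.0, 1.5),
    (2, "region2", 0.075, 15.0, 5.0, 1.5),
    (3, "region3", 0.150, 5.0, 15.0, 1.5),
    (4, "region4", 0.075, 13.5, 13.5, 1.5),
    (5, "region5", 0.001, 10.0, 15.0, 1.5),
    (6, "inclusion_a", 0.005, 4.0, 10.0, 1.0),
    (7, "inclusion_b", 0.010, 16.0, 10.0, 1.0),
    (8, "inclusion_c", 0.050, 10.0, 3.0, 1.0),
    (9, "inclusion_d", 0.100, 16.0, 16.0, 1.0),
)

NINE_REGION_BACKGROUND = 0.001
NINE_REGION_MARKER_MU_A = 0.2
NINE_REGION_MARKER_RADIUS = 2.0  # mm at the design extent
NINE_REGION_MU_S_PRIME = 2.0
MARKER_LABEL = 10


def default_nine_region_grid() -> GridSpec:
    return GridSpec(100, 100, 0.2)


def make_nine_region_phantom(
    grid: GridSpec | None = None, marker_error: float = 0.0
) -> tuple[OpticalMap, RegionLabelMap, MarkerPrior]:
    """Nine absorption levels in [0.001, 0.2] mm^-1 around a central marker disc.

    The geometry is designed on a 20 mm square and scaled with the grid
    extent; scored inclusions keep their depth classes. ``marker_error``
    perturbs only the *prior* marker value handed to the inversion (e.g.
    +0.1 for a +10% misestimated marker) — the ground-truth map is unchanged.
    """
    if grid is None:
        grid = default_nine_region_grid()
    if grid.nx != grid.ny:
        raise ValueError("nine-region phantom requires a square grid")
    extent = grid.nx * grid.h
    scale = extent / 20.0
    if NINE_REGION_MARKER_RADIUS * scale < 2 * grid.h:
        raise ValueError(
            f"grid too small to fit the documented geometry: marker radius "
            f"{NINE_REGION_MARKER_RADIUS * scale:.3g} mm < 2 pixels"
        )

    mu_a = np.full(grid.shape, NINE_REGION_BACKGROUND)
    labels = np.zeros(grid.shape, dtype=np.int16)
    legend: dict[int, tuple[str, float]] = {0: ("background", NINE_REGION_BACKGROUND)}

    for label, name, value, cx, cy, radius in NINE_REGION_LAYOUT:
        mask = _disc(grid, cx * scale, cy * scale, radius * scale)
        if not mask.any():
            raise ValueError(f"grid too small to resolve inclusion '{name}'")
        mu_a[mask] = value
        labels[mask] = label
        legend[label] = (name, value)

    marker_mask = _disc(grid, 10.0 * scale, 10.0 * scale,
                        NINE_REGION_MARKER_RADIUS * scale)
    mu_a[marker_mask] = NINE_REGION_MARKER_MU_A
    labels[marker_mask] = MARKER_LABEL
    legend[MARKER_LABEL] = ("marker", NINE_REGION_MARKER_MU_A)

    optics = _optical(grid, mu_a, NINE_REGION_MU_S_PRIME)
    marker = MarkerPrior(marker_mask, NINE_REGION_MARKER_MU_A * (1.0 + marker_error))
    return optics, RegionLabelMap(labels, legend), marker


# ---------------------------------------------------------------------------
# Spectral phantom (20 mm x 20 mm, 0.2 mm pixels, five wavelengths)
# ---------------------------------------------------------------------------

N_WAVELENGTHS = 5

#: Synthetic absorption spectra (mm^-1) at the five wavelengths: the unknown
#: chromophore has a unimodal spectrum peaking at wavelength 3; the background
#: absorption increases monotonically with wavelength, which colors the
#: apparent spectrum of everything beneath it. The marker is spectrally flat.
UNKNOWN_SPECTRUM = (0.030, 0.055, 0.080, 0.060, 0.035)
BACKGROUND_SPECTRUM = (0.005, 0.010, 0.016, 0.024, 0.034)
SPECTRAL_MARKER_MU_A = 0.2
SPECTRAL_MU_S_PRIME = 2.0

#: Annulus geometry at the 20 mm design extent (mm): marker disc and the
#: surrounding unknown-chromophore ring, with three scored sub-regions —
#: one beside the marker (same depth), one above it, one below it.
SPECTRAL_MARKER_RADIUS = 2.0
SPECTRAL_ANNULUS_OUTER = 4.5
SPECTRAL_SUBREGIONS = (
    (1, "side", 13.25, 10.0, 0.8),
    (2, "above", 10.0, 6.75, 0.8),
    (3, "below", 10.0, 13.25, 0.8),
)
SPECTRAL_ANNULUS_LABEL = 4


def default_spectral_grid() -> GridSpec:
    return GridSpec(100, 100, 0.2)


def make_spectral_phantom(
    wavelength_index: int, grid: GridSpec | None = None, marker_error: float = 0.0
) -> tuple[OpticalMap, RegionLabelMap, MarkerPrior]:
    """Two concentric discs: a spectrally flat marker inside an "unknown
    chromophore" annulus, in a wavelength-dependent background.

    ``wavelength_index`` is 1-based (1..5).
    """
    if not 1 <= wavelength_index <= N_WAVELENGTHS:
        raise ValueError(
            f"wavelength_index must be in 1..{N_WAVELENGTHS}, got {wavelength_index}"
        )
    if grid is None:
        grid = default_spectral_grid()
    extent = min(grid.extent)
    scale = extent / 20.0
    w = wavelength_index - 1
    cx = grid.nx * grid.h / 2.0
    cy = grid.ny * grid.h / 2.0

    mu_a = np.full(grid.shape, BACKGROUND_SPECTRUM[w])
    labels = np.zeros(grid.shape, dtype=np.int16)

    annulus = _disc(grid, cx, cy, SPECTRAL_ANNULUS_OUTER * scale) & ~_disc(
        grid, cx, cy, SPECTRAL_MARKER_RADIUS * scale
    )
    mu_a[annulus] = UNKNOWN_SPECTRUM[w]
    labels[annulus] = SPECTRAL_ANNULUS_LABEL

    legend: dict[int, tuple[str, tuple[float, ...]]] = {
        0: ("background", BACKGROUND_SPECTRUM),
        SPECTRAL_ANNULUS_LABEL: ("unknown_chromophore", UNKNOWN_SPECTRUM),
    }
    for label, name, sx, sy, radius in SPECTRAL_SUBREGIONS:
        mask = _disc(grid, sx * scale, sy * scale, radius * scale) & annulus
        labels[mask] = label
        legend[label] = (name, UNKNOWN_SPECTRUM)

    marker_mask = _disc(grid, cx, cy, SPECTRAL_MARKER_RADIUS * scale)
    mu_a[marker_mask] = SPECTRAL_MARKER_MU_A
    labels[marker_mask] = MARKER_LABEL
    legend[MARKER_LABEL] = ("marker", (SPECTRAL_MARKER_MU_A,) * N_WAVELENGTHS)

    optics = _optical(grid, mu_a, SPECTRAL_MU_S_PRIME)
    marker = MarkerPrior(marker_mask, SPECTRAL_MARKER_MU_A * (1.0 + marker_error))
    return optics, RegionLabelMap(labels, legend), marker


def make_spectral_series(
    grid: GridSpec | None = None, marker_error: float = 0.0
) -> list[tuple[OpticalMap, RegionLabelMap, MarkerPrior]]:
    """The spectral phantom at all five wavelengths."""
    return [make_spectral_phantom(w, grid, marker_error)
            for w in range(1, N_WAVELENGTHS + 1)]


# ---------------------------------------------------------------------------
# Carotid-plaque phantom (24 mm x 24 mm, default 0.15 mm pixels, 930 nm)
# ---------------------------------------------------------------------------

#: Tissue absorption coefficients (mm^-1) at 930 nm.
CAROTID_MU_A = {
    "blood": 0.650,
    "lipid": 0.013,
    "muscle": 0.050,
    "superficial_tissue": 0.040,
    "background_tissue": 0.040,
    "background": 0.008,
}
CAROTID_MU_S_PRIME = 2.0
CAROTID_LABELS = {
    "superficial_tissue": 1,
    "muscle": 2,
    "lipid": 3,
    "blood": 4,
    "background_tissue": 5,
}


def default_carotid_grid() -> GridSpec:
    return GridSpec(160, 160, 0.15)


def make_carotid_phantom(
    grid: GridSpec | None = None, marker_error: float = 0.0
) -> tuple[OpticalMap, RegionLabelMap, MarkerPrior]:
    """Carotid cross-section: superficial tissue and muscle layers at the top,
    a blood-filled lumen (the fluence marker) ringed by lipid plaque at
    mid-depth, and a background-tissue structure near 15 mm depth.

    Geometry is designed on a 24 mm square and scaled with the grid extent.
    ``marker_error`` perturbs only the prior marker absorption (e.g. +-0.1
    for the +-10% robustness study), never the ground-truth map.
    """
    if grid is None:
        grid = default_carotid_grid()
    extent = min(grid.extent)
    scale = extent / 24.0
    if 2.2 * scale < 2 * grid.h:
        raise ValueError("grid too small to resolve the arterial lumen")

    X, Y = grid.pixel_centers()
    mu_a = np.full(grid.shape, CAROTID_MU_A["background"])
    labels = np.zeros(grid.shape, dtype=np.int16)

    st = Y <= 2.5 * scale
    mu_a[st] = CAROTID_MU_A["superficial_tissue"]
    labels[st] = CAROTID_LABELS["superficial_tissue"]

    muscle = (Y > 2.5 * scale) & (Y <= 6.5 * scale)
    mu_a[muscle] = CAROTID_MU_A["muscle"]
    labels[muscle] = CAROTID_LABELS["muscle"]

    lumen_c = (12.0 * scale, 11.0 * scale)
    lipid = _disc(grid, *lumen_c, 3.4 * scale) & ~_disc(grid, *lumen_c, 2.2 * scale)
    mu_a[lipid] = CAROTID_MU_A["lipid"]
    labels[lipid] = CAROTID_LABELS["lipid"]

    blood = _disc(grid, *lumen_c, 2.2 * scale)
    mu_a[blood] = CAROTID_MU_A["blood"]
    labels[blood] = CAROTID_LABELS["blood"]

    bt = _disc(grid, 12.0 * scale, 16.5 * scale, 1.8 * scale)
    mu_a[bt] = CAROTID_MU_A["background_tissue"]
    labels[bt] = CAROTID_LABELS["background_tissue"]

    legend = {0: ("background", CAROTID_MU_A["background"])}
    for name, label in CAROTID_LABELS.items():
        legend[label] = (name, CAROTID_MU_A[name])

    optics = _optical(grid, mu_a, CAROTID_MU_S_PRIME)
    marker = MarkerPrior(blood, CAROTID_MU_A["blood"] * (1.0 + marker_error))
    return optics, RegionLabelMap(labels, legend), marker


# ---------------------------------------------------------------------------
# Two-layer Beer-Lambert fixture
# ---------------------------------------------------------------------------


def make_two_layer_phantom(
    mu_a_unknown: float, mu_a_marker: float, thickness_r: float, phi0: float = 1.0
) -> tuple[float, float]:
    """Scalar absorbed-energy pair for a homogeneous unknown layer of
    thickness ``thickness_r`` (mm) above a fluence marker.

    Under Beer–Lambert attenuation with surface fluence ``phi0``:

        H_unknown = mu_a_unknown * phi0
        H_marker  = mu_a_marker * phi0 * exp(-mu_a_unknown * thickness_r)
    """
    if mu_a_unknown < 0 or mu_a_marker <= 0 or phi0 <= 0:
        raise ValueError("optical coefficients and phi0 must be positive")
    if thickness_r < 0:
        raise ValueError("layer thickness must be nonnegative")
    h_unknown = mu_a_unknown * phi0
    h_marker = mu_a_marker * phi0 * np.exp(-mu_a_unknown * thickness_r)
    return float(h_unknown), float(h_marker)
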