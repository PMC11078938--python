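"""Nucleus and smFISH spot detection via multi-threshold candidate trees.

The image is binarised at a ladder of intensity levels; connected components
at each level form candidate regions, and containment across levels links
them into a forest (a component tree).  Rule-based selection then keeps, per
nesting chain, the largest candidate that satisfies area, peak-intensity and
(for nuclei) circularity criteria, using the tree to suppress conflicting
ancestors/descendants.  Diffraction-limited RNA spots are detected with the
same machinery under different hyper-parameters and without the circularity
rule.

Default parameter values are the published ones: nucleus area in
[1200, 12000] px with circularity >= 0.8 and an automatically determined
brightness threshold; spot area in [30, 500] px with a 0.2 peak-intensity
threshold on the [0, 1] scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import threshold_otsu

from ._geometry import ellipse_interior

__all__ = [
    "CandidateRegion",
    "CandidateTree",
    "NucleusParams",
    "SpotParams",
    "EllipseRegion",
    "CellRegions",
    "extract_candidates",
    "select_nuclei",
    "fit_ellipse",
    "expand_cytosol",
    "build_cell_regions",
    "segment_cells",
    "detect_spots",
]


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class NucleusParams:
    """Selection rules for nucleus candidates."""

    min_area: int = 1200
    max_area: int = 12000
    circularity_min: float = 0.8
    #: "auto" resolves to Otsu's threshold on the image at segmentation time
    peak_intensity_threshold: Union[float, str] = "auto"
    n_threshold_levels: int = 32

    def __post_init__(self) -> None:
        if not 0 < self.min_area < self.max_area:
            raise ValueError("need 0 < min_area < max_area")
        if not 0 < self.circularity_min <= 1:
            raise ValueError("circularity_min must be in (0, 1]")
        if self.n_threshold_levels < 2:
            raise ValueError("n_threshold_levels must be >= 2")

    def resolve(self, image: np.ndarray) -> "NucleusParams":
        """Replace an "auto" peak threshold by Otsu's threshold on the image."""
        if self.peak_intensity_threshold != "auto":
            return self
        return replace(self, peak_intensity_threshold=float(threshold_otsu(image)))


@dataclass(frozen=True)
class SpotParams:
    """Selection rules for smFISH spot candidates (no circularity rule)."""

    min_area: int = 30
    max_area: int = 500
    peak_intensity_threshold: float = 0.2
    n_threshold_levels: int = 32

    def __post_init__(self) -> None:
        if not 0 < self.min_area < self.max_area:
            raise ValueError("need 0 < min_area < max_area")
        if not 0 < self.peak_intensity_threshold < 1:
            raise ValueError("peak_intensity_threshold must be in (0, 1)")
        if self.n_threshold_levels < 2:
            raise ValueError("n_threshold_levels must be >= 2")


# ---------------------------------------------------------------------------
# candidate tree


@dataclass
class CandidateRegion:
    """One connected component at one threshold level."""

    level: int
    threshold: float
    slice: tuple[slice, slice]
    mask: np.ndarray  # boolean crop within `slice`
    area: int
    peak_intensity: float
    centroid: tuple[float, float]
    parent: int | None = None  # index into CandidateTree.regions
    children: list[int] = field(default_factory=list)
    _circularity: float | None = None

    @property
    def circularity(self) -> float:
        """4*pi*A/P^2 with P the 8-connected boundary contour length.

        Computed lazily (it is the one expensive per-region property, and
        rule-based selection only needs it for candidates that already pass
        the cheap area and peak filters).
        """
        if self._circularity is None:
            self._circularity = _circularity(self.area, measure.perimeter(self.mask))
        return self._circularity

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.slice] = self.mask
        return out


@dataclass
class CandidateTree:
    """Forest of candidate regions ordered by threshold level (ascending)."""

    shape: tuple[int, int]
    thresholds: np.ndarray
    regions: list[CandidateRegion]

    def __len__(self) -> int:
        return len(self.regions)


def _threshold_levels(image: np.ndarray, n_levels: int) -> np.ndarray:
    """Evenly spaced intensity levels spanning the nonzero pixel range.

    Spanning intensity values (rather than quantiles) keeps levels between
    the background and the peaks even when foreground pixels are a tiny
    fraction of the image, as in smFISH spot images.
    """
    if np.ptp(image) == 0:  # constant image: thresholding is meaningless
        return np.empty(0)
    vals = image[image > 0]
    if vals.size == 0:
        return np.empty(0)
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:  # binary image: the single foreground level
        return np.array([lo])
    return np.unique(np.linspace(lo, hi, n_levels))


def _circularity(area: float, perimeter: float) -> float:
    if perimeter <= 0:  # degenerate 1-px-scale region
        return 1.0
    return 4.0 * math.pi * area / perimeter**2


def extract_candidates(image: np.ndarray, n_levels: int = 32) -> CandidateTree:
    """Build the candidate forest of an image.

    Components are 8-connected; the parent of a region at level k is the
    level k-1 component containing it (masks at a higher threshold are
    subsets of masks at a lower one, so the parent is unique).  A constant
    image yields an empty tree.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    img = np.asarray(image, dtype=float)
    levels = _threshold_levels(img, n_levels)
    regions: list[CandidateRegion] = []
    prev_label: np.ndarray | None = None
    prev_index: dict[int, int] = {}
    for k, t in enumerate(levels):
        lab = measure.label(img >= t, connectivity=2)
        n = int(lab.max())
        if n == 0:
            prev_label, prev_index = lab, {}
            continue
        ids = np.arange(1, n + 1)
        objects = ndi.find_objects(lab)
        areas = np.bincount(lab.ravel())[1:]
        peaks = ndi.maximum(img, labels=lab, index=ids)
        coms = ndi.center_of_mass(np.ones_like(img), labels=lab, index=ids)
        index: dict[int, int] = {}
        for i in range(n):
            sl = objects[i]
            crop = lab[sl] == ids[i]
            parent = None
            if prev_label is not None and prev_index:
                first = int(np.argmax(crop))  # first True pixel of the crop
                r0, c0 = divmod(first, crop.shape[1])
                parent = prev_index[int(prev_label[sl][r0, c0])]
            reg = CandidateRegion(
                level=k,
                threshold=float(t),
                slice=sl,
                mask=crop,
                area=int(areas[i]),
                peak_intensity=float(peaks[i]),
                centroid=(float(coms[i][0]), float(coms[i][1])),
                parent=parent,
            )
            idx = len(regions)
            regions.append(reg)
            index[int(ids[i])] = idx
            if parent is not None:
                regions[parent].children.append(idx)
        prev_label, prev_index = lab, index
    return CandidateTree(shape=img.shape, thresholds=levels, regions=regions)


def _greedy_select(tree: CandidateTree, qualifying: list[CandidateRegion]) -> list[CandidateRegion]:
    """Greedy maximum-area selection with pixel-overlap conflict removal.

    Candidates are visited by descending area (ties: higher peak intensity,
    then lexicographic centroid) and accepted when disjoint from everything
    accepted so far.  Because regions of a component tree are either nested
    or disjoint, this realises "largest qualifying candidate per chain".
    """
    order = sorted(
        qualifying,
        key=lambda r: (-r.area, -r.peak_intensity, r.centroid[0], r.centroid[1]),
    )
    taken = np.zeros(tree.shape, dtype=bool)
    accepted: list[CandidateRegion] = []
    for r in order:
        window = taken[r.slice]
        if (window & r.mask).any():
            continue
        window |= r.mask
        accepted.append(r)
    return accepted


def select_nuclei(tree: CandidateTree, params: NucleusParams) -> list[np.ndarray]:
    """Apply the nucleus rules to a candidate tree; returns full-image masks.

    ``params.peak_intensity_threshold`` must already be numeric (use
    ``params.resolve(image)`` or ``segment_cells`` for the automatic
    threshold).  An image with no qualifying candidate yields ``[]``.
    """
    thr = params.peak_intensity_threshold
    if not isinstance(thr, (int, float)):
        raise ValueError(
            "peak_intensity_threshold is 'auto'; call params.resolve(image) first"
        )
    qualifying = [
        r
        for r in tree.regions
        if params.min_area <= r.area <= params.max_area
        and r.peak_intensity >= thr
        and r.circularity >= params.circularity_min  # lazy, checked last
    ]
    accepted = _greedy_select(tree, qualifying)
    # stable, geometry-based ordering for downstream cell ids
    accepted.sort(key=lambda r: (r.centroid[0], r.centroid[1]))
    return [r.full_mask(tree.shape) for r in accepted]


# ---------------------------------------------------------------------------
# ellipse fitting and cytosol rings


@dataclass(frozen=True)
class EllipseRegion:
    """Moment-equivalent ellipse of a pixel region."""

    centroid: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float  # radians in [0, pi), angle from +row axis

    def mask(self, shape: tuple[int, int],
             expand: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
        return ellipse_interior(
            shape,
            self.centroid,
            self.semi_major + expand[0],
            self.semi_minor + expand[1],
            self.orientation,
        )


def fit_ellipse(mask: np.ndarray) -> EllipseRegion:
    """Fit the moment-equivalent ellipse of a binary region.

    The centroid is the mask centroid; semi-axes and orientation come from
    the eigen-decomposition of the second central moment matrix (with the
    1/12 unit-pixel variance added, so even a single pixel has positive
    axes).  A rotationally symmetric region reports orientation 0.
    """
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("cannot fit an ellipse to an empty mask")
    r0, c0 = ys.mean(), xs.mean()
    dr, dc = ys - r0, xs - c0
    cov = np.array(
        [
            [dr @ dr / ys.size + 1.0 / 12.0, dr @ dc / ys.size],
            [dr @ dc / ys.size, dc @ dc / ys.size + 1.0 / 12.0],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(cov)
    lam_minor, lam_major = float(eigvals[0]), float(eigvals[1])
    if lam_major - lam_minor <= 1e-9 * max(lam_major, 1e-30):
        theta = 0.0  # symmetric region: tie-break
    else:
        v = eigvecs[:, 1]
        theta = math.atan2(v[1], v[0]) % math.pi
    return EllipseRegion(
        centroid=(float(r0), float(c0)),
        semi_major=2.0 * math.sqrt(lam_major),
        semi_minor=2.0 * math.sqrt(lam_minor),
        orientation=theta,
    )


def expand_cytosol(
    nucleus: EllipseRegion,
    nucleus_mask: np.ndarray,
    image_shape: tuple[int, int],
    occupied: np.ndarray | None = None,
    expand: tuple[float, float] = (25.0, 15.0),
) -> np.ndarray:
    """Elliptical cytosol ring around one nucleus.

    Pixels inside the fitted ellipse grown by ``expand`` (major, minor) px,
    minus the nucleus mask and minus ``occupied`` pixels, clipped to the
    image bounds.  Joint nearest-centroid arbitration between neighbouring
    cells lives in ``build_cell_regions``.
    """
    ring = nucleus.mask(image_shape, expand=expand)
    ring &= ~nucleus_mask
    if occupied is not None:
        ring &= ~occupied
    return ring


@dataclass
class CellRegions:
    """Per-cell nucleus masks N_i, cytosol rings C_i and fitted ellipses.

    Stored as two label images (ids 1..n, 0 = unassigned), which makes the
    pairwise-disjointness invariants true by construction.
    """

    nucleus_labels: np.ndarray
    cytosol_labels: np.ndarray
    ellipses: list[EllipseRegion]

    @property
    def n_cells(self) -> int:
        return len(self.ellipses)

    @property
    def cell_ids(self) -> list[int]:
        return list(range(1, self.n_cells + 1))

    def nucleus_mask(self, cell_id: int) -> np.ndarray:
        return self.nucleus_labels == cell_id

    def cytosol_mask(self, cell_id: int) -> np.ndarray:
        return self.cytosol_labels == cell_id

    def centroids(self) -> np.ndarray:
        return np.array([e.centroid for e in self.ellipses]).reshape(-1, 2)

    def border_flags(self) -> np.ndarray:
        """True for cells whose nucleus or cytosol touches the image edge."""
        flags = np.zeros(self.n_cells, dtype=bool)
        for lab in (self.nucleus_labels, self.cytosol_labels):
            edge = np.concatenate(
                [lab[0], lab[-1], lab[:, 0], lab[:, -1]]
            )
            for v in np.unique(edge):
                if v > 0:
                    flags[v - 1] = True
        return flags


def build_cell_regions(
    nucleus_masks: list[np.ndarray],
    image_shape: tuple[int, int],
    expand: tuple[float, float] = (25.0, 15.0),
) -> CellRegions:
    """Fit ellipses and assign disjoint cytosol rings for a set of nuclei.

    Contested expansion pixels (claimed by the grown ellipses of several
    cells) go to the cell with the nearer nucleus centroid; exact distance
    ties stay with the lower cell id.  Pixels of any nucleus are excluded
    from every cytosol.
    """
    ellipses = [fit_ellipse(m) for m in nucleus_masks]
    owner = np.full(image_shape, -1, dtype=np.int32)
    best_d2 = np.full(image_shape, np.inf)
    nucleus_labels = np.zeros(image_shape, dtype=np.int32)
    for i, (e, m) in enumerate(zip(ellipses, nucleus_masks)):
        nucleus_labels[m] = i + 1
        ring = e.mask(image_shape, expand=expand)
        rr, cc = np.nonzero(ring)
        d2 = (rr - e.centroid[0]) ** 2 + (cc - e.centroid[1]) ** 2
        closer = d2 < best_d2[rr, cc]
        owner[rr[closer], cc[closer]] = i + 1
        best_d2[rr[closer], cc[closer]] = d2[closer]
    owner[nucleus_labels > 0] = 0
    return CellRegions(
        nucleus_labels=nucleus_labels,
        cytosol_labels=np.maximum(owner, 0).astype(np.int32),
        ellipses=ellipses,
    )


def segment_cells(
    image: np.ndarray,
    params: NucleusParams | None = None,
    expand: tuple[float, float] = (25.0, 15.0),
) -> CellRegions:
    """Nucleus detection + ellipse fitting + cytosol rings in one call."""
    params = (params or NucleusParams()).resolve(image)
    tree = extract_candidates(image, params.n_threshold_levels)
    masks = select_nuclei(tree, params)
    return build_cell_regions(masks, image.shape, expand=expand)


# ---------------------------------------------------------------------------
# spots


def detect_spots(image: np.ndarray, params: SpotParams | None = None) -> pd.DataFrame:
    """Detect diffraction-limited spots; returns (row, col, area, peak) rows.

    Same candidate-tree machinery as nucleus detection, with the spot size
    range and an absolute peak-intensity threshold; circularity is not
    applied to spots.
    """
    params = params or SpotParams()
    tree = extract_candidates(image, params.n_threshold_levels)
    qualifying = [
        r
        for r in tree.regions
        if params.min_area <= r.area <= params.max_area
        and r.peak_intensity >= params.peak_intensity_threshold
    ]
    accepted = _greedy_select(tree, qualifying)
    accepted.sort(key=lambda r: (r.centroid[0], r.centroid[1]))
    return pd.DataFrame(
        [
            {
                "row": r.centroid[0],
                "col": r.centroid[1],
                "area": r.area,
                "peak": r.peak_intensity,
            }
            for r in accepted
        ],
        columns=["row", "col", "area", "peak"],
    )
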