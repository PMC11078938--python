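"""Synthetic multi-cycle imaging experiments with complete ground truth.

The generator emulates the raw data of a cyclic immunofluorescence run on
fixed cells: elliptical nuclei with per-cell nuclear-stain brightness,
per-cell per-marker mean intensities, integer stage drift between cycles,
a slowly accumulating residual background in the erased images, additive
Gaussian camera noise, and Poisson-distributed diffraction-limited RNA
spots rendered as isotropic Gaussian blobs.  Every random draw is governed
by a single seed, so a configuration fully determines the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from ._geometry import ellipse_interior
from .stack import Cycle, CycleStack, MarkerChannel

__all__ = ["SynthConfig", "GroundTruth", "make_experiment", "make_spot_images"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic experiment.

    Defaults describe a mid-size run: nuclei whose areas fall inside the
    detector's [1200, 12000] px envelope, 5 % of dynamic range camera noise,
    a few pixels of inter-cycle drift, and a slight background accumulation
    per cycle in the erased images.
    """

    image_height: int = 640
    image_width: int = 640
    n_cells: int = 30
    n_cycles: int = 3
    markers_per_cycle: int = 2
    #: semi-axis range in px; (22, 34) gives nucleus areas ~1500-3600 px
    nucleus_axis_range: tuple[float, float] = (22.0, 34.0)
    #: per-cell per-marker mean intensity range (arbitrary [0, 1] units)
    intensity_range: tuple[float, float] = (0.2, 0.8)
    #: per-cell nuclear-stain brightness range
    reference_intensity_range: tuple[float, float] = (0.55, 0.9)
    #: additive Gaussian noise sd, fraction of the [0, 1] range
    noise_sd: float = 0.05
    #: maximum absolute integer drift per axis between cycles
    drift_max: int = 5
    #: residual background of the first cycle's erased image
    background_base: float = 0.05
    #: background added per extra cycle (units/cycle)
    background_accumulation_rate: float = 0.01
    spot_genes: int = 4
    #: expected RNA spots per cell per gene (Poisson mean)
    spot_rate: float = 3.0
    #: isotropic blob sd in px (diffraction-limited spot width)
    spot_sigma: float = 2.0
    #: blob peak amplitude; set below 0.2 to emulate sub-threshold spots
    spot_peak: float = 0.6
    spot_background: float = 0.05
    spot_noise_sd: float = 0.01
    #: minimum centre-to-centre distance between spots of one gene; ~8 x
    #: spot_sigma keeps neighbouring blobs from merging into one connected
    #: component even through unlucky noise at the saddle between them
    spot_min_separation: float = 16.0
    #: when False, spots are placed without any separation constraint, so
    #: coincident/merged spots become possible (an undercounting scenario)
    enforce_spot_separation: bool = True
    #: extra clearance kept between a nucleus and the image border
    placement_margin: int = 8
    max_placement_tries: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("image_height", "image_width", "n_cells", "n_cycles",
                     "markers_per_cycle", "spot_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.drift_max < 0:
            raise ValueError("drift_max must be >= 0")
        lo, hi = self.nucleus_axis_range
        if not (0 < lo <= hi):
            raise ValueError("nucleus_axis_range must satisfy 0 < min <= max")
        if self.noise_sd < 0 or self.spot_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.spot_rate < 0:
            raise ValueError("spot_rate must be >= 0")

    @property
    def n_markers(self) -> int:
        return self.n_cycles * self.markers_per_cycle

    def marker_names(self) -> list[str]:
        return [f"M{j + 1:02d}" for j in range(self.n_markers)]

    def gene_names(self) -> list[str]:
        return [f"G{g + 1:02d}" for g in range(self.spot_genes)]

    def with_(self, **kwargs) -> "SynthConfig":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Everything a downstream test needs to score the pipeline."""

    #: int32 mask at the cycle-1 (unshifted) frame; 0 = background, i = cell i
    label_image: np.ndarray
    #: per-cell centroid/semi-axes/orientation (one row per cell, id = cell)
    ellipses: pd.DataFrame
    #: cells x markers matrix of true mean intensities
    true_intensity: pd.DataFrame
    #: per-cycle integer (dy, dx); cycle 1 is (0, 0)
    true_shift: list[tuple[int, int]]
    #: one row per RNA spot: gene, cell, row, col
    true_spots: pd.DataFrame
    #: per-cell nuclear-stain brightness, used for the reference channel
    reference_intensity: pd.Series = field(default_factory=pd.Series)

    def spot_counts(self) -> pd.DataFrame:
        """Cells x genes table of true spot counts."""
        if self.true_spots.empty:
            genes = []
        else:
            genes = sorted(self.true_spots["gene"].unique())
        cells = self.ellipses["cell"].tolist()
        out = pd.DataFrame(0, index=pd.Index(cells, name="cell"), columns=genes)
        for (gene, cell), grp in self.true_spots.groupby(["gene", "cell"]):
            out.loc[cell, gene] = len(grp)
        return out


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    """Deterministic sub-stream of the experiment seed."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def _place_nuclei(config: SynthConfig, rng: np.random.Generator):
    """Rejection-sample non-overlapping elliptical nuclei.

    A 2 px dilation of each candidate is tested against the already-placed
    mask so nuclei keep at least a 2 px gap and never merge at the lowest
    binarisation thresholds.  Fails loudly when the field is too crowded.
    """
    h, w = config.image_height, config.image_width
    lo, hi = config.nucleus_axis_range
    label = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)
    rows = []
    struct = ndi.generate_binary_structure(2, 2)
    for i in range(1, config.n_cells + 1):
        for _ in range(config.max_placement_tries):
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, hi)
            if a < b:
                a, b = b, a
            theta = rng.uniform(0.0, math.pi)
            margin = config.placement_margin + config.drift_max + a + 1
            if 2 * margin >= min(h, w):
                raise ValueError("image too small for the requested nuclei")
            r0 = rng.uniform(margin, h - margin)
            c0 = rng.uniform(margin, w - margin)
            mask = ellipse_interior((h, w), (r0, c0), a, b, theta)
            grown = ndi.binary_dilation(mask, structure=struct, iterations=2)
            if not (grown & occupied).any():
                label[mask] = i
                occupied |= mask
                rows.append((i, r0, c0, a, b, theta))
                break
        else:
            raise RuntimeError(
                f"could not place cell {i} after {config.max_placement_tries} tries; "
                "reduce n_cells or nucleus size"
            )
    ellipses = pd.DataFrame(
        rows, columns=["cell", "row", "col", "semi_major", "semi_minor", "orientation"]
    )
    return label, ellipses


def _sample_spots(config: SynthConfig, label: np.ndarray,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Poisson spot counts per cell per gene, with per-gene spot separation.

    With separation enforced, a spot that cannot be placed after the retry
    budget is dropped rather than placed in violation, so the recorded truth
    always matches the separated-spot contract (crowded cells truncate the
    Poisson draw slightly).  With ``enforce_spot_separation=False`` spots are
    placed unconditionally and may coincide.
    """
    records: list[tuple[str, int, float, float]] = []
    cell_pixels = {}
    for i in range(1, config.n_cells + 1):
        ys, xs = np.nonzero(label == i)
        cell_pixels[i] = (ys, xs)
    min_d2 = config.spot_min_separation**2
    for gene in config.gene_names():
        placed: list[tuple[float, float]] = []
        for i in range(1, config.n_cells + 1):
            n = int(rng.poisson(config.spot_rate))
            ys, xs = cell_pixels[i]
            for _ in range(n):
                for _attempt in range(200):
                    k = int(rng.integers(len(ys)))
                    r = ys[k] + rng.uniform(-0.5, 0.5)
                    c = xs[k] + rng.uniform(-0.5, 0.5)
                    ok = (not config.enforce_spot_separation) or all(
                        (r - pr) ** 2 + (c - pc) ** 2 >= min_d2
                        for pr, pc in placed
                    )
                    if ok:
                        placed.append((r, c))
                        records.append((gene, i, r, c))
                        break
    return pd.DataFrame(records, columns=["gene", "cell", "row", "col"])


def _translate_int(image: np.ndarray, dy: int, dx: int, fill: float = 0.0) -> np.ndarray:
    out = np.full_like(image, fill)
    h, w = image.shape
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ysrc = slice(max(-dy, 0), h + min(-dy, 0))
    xsrc = slice(max(-dx, 0), w + min(-dx, 0))
    if ys.start < ys.stop and xs.start < xs.stop:
        out[ys, xs] = image[ysrc, xsrc]
    return out


def make_experiment(config: SynthConfig) -> tuple[CycleStack, GroundTruth]:
    """Generate a full multi-cycle stack plus its ground truth.

    Per cycle the stack holds one noisy nuclear-stain reference and one
    stained/erased pair per marker.  The clean erased image of cycle c is the
    uniform residual background ``base + rate * (c - 1)``; the clean stained
    image adds each cell's true marker intensity inside its nucleus mask, so
    on noise-free data the background-subtracted nucleus mean recovers the
    true intensity exactly.  All images of cycle c are translated by the
    cycle's true integer shift with zero fill.
    """
    h, w = config.image_height, config.image_width
    rng = _rng(config, 0)
    label, ellipses = _place_nuclei(config, rng)

    ref_levels = rng.uniform(*config.reference_intensity_range, size=config.n_cells)
    intensity = rng.uniform(
        *config.intensity_range, size=(config.n_cells, config.n_markers)
    )
    markers = config.marker_names()
    true_intensity = pd.DataFrame(
        intensity, index=pd.Index(range(1, config.n_cells + 1), name="cell"),
        columns=markers,
    )

    shifts: list[tuple[int, int]] = [(0, 0)]
    for _ in range(1, config.n_cycles):
        dy = int(rng.integers(-config.drift_max, config.drift_max + 1))
        dx = int(rng.integers(-config.drift_max, config.drift_max + 1))
        shifts.append((dy, dx))

    # per-cell lookup tables (index 0 = background)
    ref_lut = np.concatenate(([0.0], ref_levels))
    ref_clean = ref_lut[label]

    noise_rng = _rng(config, 3)

    def _noisy(img: np.ndarray) -> np.ndarray:
        if config.noise_sd > 0:
            img = img + noise_rng.normal(0.0, config.noise_sd, size=img.shape)
        return np.clip(img, 0.0, 1.0)

    cycles = []
    for c in range(config.n_cycles):
        bg = config.background_base + config.background_accumulation_rate * c
        dy, dx = shifts[c]
        reference = _translate_int(_noisy(ref_clean + bg), dy, dx)
        channels = []
        for k in range(config.markers_per_cycle):
            j = c * config.markers_per_cycle + k
            sig_lut = np.concatenate(([0.0], intensity[:, j]))
            stained_clean = bg + sig_lut[label]
            erased_clean = np.full((h, w), bg)
            stained = _translate_int(_noisy(stained_clean), dy, dx)
            erased = _translate_int(_noisy(erased_clean), dy, dx)
            channels.append(MarkerChannel(markers[j], stained, erased))
        cycles.append(Cycle(c, reference, channels))

    spots = _sample_spots(config, label, _rng(config, 1))
    truth = GroundTruth(
        label_image=label,
        ellipses=ellipses,
        true_intensity=true_intensity,
        true_shift=shifts,
        true_spots=spots,
        reference_intensity=pd.Series(
            ref_levels, index=pd.Index(range(1, config.n_cells + 1), name="cell")
        ),
    )
    return CycleStack(cycles), truth


def make_spot_images(config: SynthConfig, truth: GroundTruth) -> dict[str, np.ndarray]:
    """Render one smFISH image per gene from the ground-truth spot table.

    Each spot becomes an isotropic Gaussian blob of spread ``spot_sigma`` and
    peak ``spot_peak`` on a uniform background, plus optional camera noise.
    """
    h, w = config.image_height, config.image_width
    rng = _rng(config, 2)
    images: dict[str, np.ndarray] = {}
    ext = int(math.ceil(4 * config.spot_sigma))
    for gene in config.gene_names():
        img = np.full((h, w), config.spot_background, dtype=float)
        sel = truth.true_spots[truth.true_spots["gene"] == gene]
        for _, row in sel.iterrows():
            r0, c0 = float(row["row"]), float(row["col"])
            rlo = max(int(r0) - ext, 0)
            rhi = min(int(r0) + ext + 1, h)
            clo = max(int(c0) - ext, 0)
            chi = min(int(c0) + ext + 1, w)
            rr = np.arange(rlo, rhi, dtype=float)[:, None] - r0
            cc = np.arange(clo, chi, dtype=float)[None, :] - c0
            img[rlo:rhi, clo:chi] += config.spot_peak * np.exp(
                -(rr**2 + cc**2) / (2 * config.spot_sigma**2)
            )
        if config.spot_noise_sd > 0:
            img = img + rng.normal(0.0, config.spot_noise_sd, size=img.shape)
        images[gene] = np.clip(img, 0.0, 1.0)
    return images
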