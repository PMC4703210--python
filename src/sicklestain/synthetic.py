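"""Synthetic blood-stain rendering with known ground truth.

Every downstream stage (detection, indices, classification, evaluation) is
exercised on images produced here, so the generator encodes the physics of
the assay at the level the scorer sees it, not the level of fluid transport:

* A droplet of blood diluted in hemoglobin solubility buffer deposits a
  total hemoglobin mass proportional to ``hb_conc * droplet_volume /
  (1 + dilution_ratio)`` (only the blood fraction of the droplet carries Hb).
* Insoluble, polymerized HbS stays in a center disk of radius
  ``r_center_mm``; soluble hemoglobins wick into an annulus out to
  ``r_outer_mm``.  Small leak fractions exchange material between the
  compartments: ``leak_center`` of the soluble Hb is retained in the center
  and ``leak_ring`` of the HbS escapes to the ring, conserving total mass.
* Each compartment is rendered as a uniform intensity equal to its Hb mass
  divided by its (pixel-counted) area, times a fixed optical gain; the whole
  field is smoothed with a Gaussian of 0.2 mm, background and per-pixel
  Gaussian noise are added, and the result is clipped to [0, 255] and
  quantized to 8 bits.  Only the Blue channel carries signal
  (``B = 255 - intensity``), matching the analyzer's intensity definition.
* The outer radius spreads with the square root of
  ``droplet_volume * dilution_ratio`` relative to the 20 uL, 1:10 reference
  (two-dimensional spreading), so metering-jitter experiments (1:8-1:12
  ratios, 16-24 uL droplets) change the rendered geometry as well as the
  deposited mass.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DomainError, LayoutError, SaturationError
from .genotypes import Genotype, PERCENT_HBS_BANDS, band_contains
from .imaging import StainImage, px_per_mm

#: Reference metering: a 20 uL droplet of blood mixed 1:10 with buffer.
REFERENCE_DROPLET_UL = 20.0
REFERENCE_DILUTION = 10.0
#: Gaussian edge-smoothing scale in mm.
EDGE_SIGMA_MM = 0.2


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of one rendered stain.

    Parameters
    ----------
    percent_hbs
        Fraction of total hemoglobin that is HbS, in percent (0-100).
    hb_conc
        Total hemoglobin concentration of the blood sample, g/dL
        (6-17 g/dL is the plausible clinical range).
    dilution_ratio
        Buffer volumes per blood volume; 10.0 means blood:buffer = 1:10.
    droplet_volume
        Deposited droplet volume of the mixture, uL.
    dpi
        Rendering resolution, dots per inch.
    r_center_mm, r_outer_mm
        Nominal center-spot and outer stain radii at the reference metering.
    leak_center
        Fraction of soluble Hb retained in the center spot (epsilon).
    leak_ring
        Fraction of HbS escaping into the peripheral ring (delta).
    background
        Baseline paper intensity on the 0-255 scale.
    noise_sd
        SD of additive per-pixel Gaussian noise, intensity units.
    gain
        Optical gain converting Hb surface density (g/dL * uL / mm^2) to
        intensity units; the default keeps the full clinical range well
        below saturation.
    seed
        Seed of the stain's pseudo-random stream (noise).
    margin_mm
        Blank border around the stain in single-stain renders.
    """

    percent_hbs: float
    hb_conc: float = 14.0
    dilution_ratio: float = 10.0
    droplet_volume: float = 20.0
    dpi: float = 300.0
    r_center_mm: float = 2.5
    r_outer_mm: float = 7.5
    leak_center: float = 0.15
    leak_ring: float = 0.05
    background: float = 10.0
    noise_sd: float = 3.0
    gain: float = 150.0
    seed: int = 0
    margin_mm: float = 2.0

    def validate(self) -> None:
        if not 0.0 <= self.percent_hbs <= 100.0:
            raise DomainError("percent_hbs must be in [0, 100]")
        if self.hb_conc <= 0:
            raise DomainError("hb_conc must be positive")
        if self.dilution_ratio <= 0 or self.droplet_volume <= 0:
            raise DomainError("dilution_ratio and droplet_volume must be positive")
        if not (0.0 <= self.leak_center < 1.0 and 0.0 <= self.leak_ring < 1.0):
            raise DomainError("leak fractions must be in [0, 1)")
        if not 0.0 < self.r_center_mm < self.r_outer_mm:
            raise DomainError("require 0 < r_center_mm < r_outer_mm")
        if self.noise_sd < 0 or self.background < 0:
            raise DomainError("noise_sd and background must be non-negative")
        if self.dpi <= 0:
            raise DomainError("dpi must be positive")

    @property
    def spread_scale(self) -> float:
        """Outer-radius scale factor from metering, relative to 20 uL at 1:10."""
        return float(
            np.sqrt(
                (self.droplet_volume * self.dilution_ratio)
                / (REFERENCE_DROPLET_UL * REFERENCE_DILUTION)
            )
        )

    @property
    def r_outer_eff_mm(self) -> float:
        return self.r_outer_mm * self.spread_scale

    @property
    def hb_mass(self) -> float:
        """Deposited hemoglobin mass proxy: g/dL * uL of blood in the droplet."""
        return self.hb_conc * self.droplet_volume / (1.0 + self.dilution_ratio)

    def compartment_shares(self) -> tuple[float, float]:
        """Mass fractions landing in (center, ring); they sum to 1."""
        p = self.percent_hbs / 100.0
        center = (1.0 - self.leak_ring) * p + self.leak_center * (1.0 - p)
        ring = (1.0 - self.leak_center) * (1.0 - p) + self.leak_ring * p
        return center, ring


@dataclass(frozen=True)
class GroundTruthRecord:
    """Per-stain truth implied by the generator parameters."""

    stain_id: str
    genotype_label: Genotype | None
    percent_hbs: float
    hb_conc: float
    center_xy: tuple[float, float]
    params: GeneratorParams

    def __post_init__(self) -> None:
        if self.genotype_label is not None and not band_contains(
            self.genotype_label, self.percent_hbs
        ):
            raise DomainError(
                f"percent_hbs={self.percent_hbs} outside the "
                f"{self.genotype_label} band {PERCENT_HBS_BANDS[self.genotype_label]}"
            )


@dataclass(frozen=True)
class SheetLayout:
    """Grid layout for a multi-stain sheet (row-major placement)."""

    rows: int
    cols: int
    pitch_mm: float = 25.0
    margin_mm: float = 12.0
    jitter_mm: float = 0.5

    def validate(self) -> None:
        if self.rows < 1 or self.cols < 1 or self.pitch_mm <= 0:
            raise DomainError("layout needs positive rows, cols and pitch")
        if self.jitter_mm < 0 or self.margin_mm <= 0:
            raise DomainError("margin must be positive and jitter non-negative")


def infer_genotype(percent_hbs: float) -> Genotype | None:
    """Genotype implied by a %HbS value when it falls in exactly one band."""
    if percent_hbs == 0.0:
        return Genotype.AA
    matches = [
        g
        for g in (Genotype.AS, Genotype.SS)
        if band_contains(g, percent_hbs)
    ]
    return matches[0] if len(matches) == 1 else None


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _stain_field(
    params: GeneratorParams, shape: tuple[int, int], center_xy: tuple[float, float]
) -> np.ndarray:
    """Noiseless, unblurred intensity field (above background) for one stain."""
    ppmm = px_per_mm(params.dpi)
    cx, cy = center_xy
    h, w = shape
    y = np.arange(h, dtype=np.float64)[:, None] - cy
    x = np.arange(w, dtype=np.float64)[None, :] - cx
    r = np.hypot(y, x) / ppmm

    mask_c = r <= params.r_center_mm
    mask_r = (r > params.r_center_mm) & (r <= params.r_outer_eff_mm)
    n_c, n_r = int(mask_c.sum()), int(mask_r.sum())
    if n_c == 0 or n_r == 0:
        raise DomainError("stain radii too small for the pixel grid")
    # Areas measured on the pixel grid so mass bookkeeping is exact.
    area_c = n_c / ppmm**2
    area_r = n_r / ppmm**2
    share_c, share_r = params.compartment_shares()
    amp_c = params.gain * share_c * params.hb_mass / area_c
    amp_r = params.gain * share_r * params.hb_mass / area_r

    field_arr = np.zeros(shape, dtype=np.float64)
    field_arr[mask_c] = amp_c
    field_arr[mask_r] = amp_r

    # Refuse renderings whose noiseless field would clip >1% of stain pixels.
    if max(amp_c, amp_r) + params.background > 255.0:
        stain_px = n_c + n_r
        over = int(np.count_nonzero(field_arr + params.background > 255.0))
        if over / stain_px > 0.01:
            raise SaturationError(
                f"amplitudes (center {amp_c:.1f}, ring {amp_r:.1f}) would saturate "
                f"{100 * over / stain_px:.1f}% of stain pixels"
            )
    return field_arr


def _render(field_arr: np.ndarray, params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    """Blur, add background and noise, clip, quantize, and build RGB planes."""
    ppmm = px_per_mm(params.dpi)
    blurred = ndimage.gaussian_filter(field_arr, sigma=EDGE_SIGMA_MM * ppmm, mode="constant")
    intensity = blurred + params.background
    if params.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, params.noise_sd, size=intensity.shape)
    intensity = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)
    rgb = np.empty(intensity.shape + (3,), dtype=np.uint8)
    rgb[:, :, 0] = 255
    rgb[:, :, 1] = np.clip(255 - intensity.astype(np.int16) // 2, 0, 255).astype(np.uint8)
    rgb[:, :, 2] = 255 - intensity
    return rgb


def generate_stain(
    params: GeneratorParams, genotype_label: Genotype | None = None
) -> tuple[StainImage, GroundTruthRecord]:
    """Render one stain centred in its own image.

    Deterministic given ``params`` (including ``params.seed``).  Raises
    :class:`SaturationError` when the requested amplitudes would clip more
    than 1% of stain pixels at 255, which would break index linearity.
    """
    params.validate()
    ppmm = px_per_mm(params.dpi)
    half = int(np.ceil((params.r_outer_eff_mm + params.margin_mm) * ppmm))
    size = 2 * half + 1
    center = (float(half), float(half))
    field_arr = _stain_field(params, (size, size), center)
    rng = np.random.default_rng(params.seed)
    rgb = _render(field_arr, params, rng)
    label = genotype_label if genotype_label is not None else infer_genotype(params.percent_hbs)
    image = StainImage(pixels=rgb, dpi=params.dpi, source_id=f"synthetic:seed={params.seed}")
    record = GroundTruthRecord(
        stain_id=f"stain_{params.seed}",
        genotype_label=label,
        percent_hbs=params.percent_hbs,
        hb_conc=params.hb_conc,
        center_xy=center,
        params=params,
    )
    return image, record


def generate_sheet(
    samples: list[GeneratorParams],
    layout: SheetLayout,
    seed: int,
    genotype_labels: list[Genotype | None] | None = None,
    source_id: str = "synthetic-sheet",
) -> tuple[StainImage, list[GroundTruthRecord]]:
    """Render a sheet with stains on a jittered grid, row-major.

    All samples must share dpi, background and noise_sd (one scanner pass).
    Raises :class:`LayoutError` when stains could overlap or the grid is too
    small.  Deterministic given (samples, layout, seed).
    """
    layout.validate()
    if len(samples) > layout.rows * layout.cols:
        raise LayoutError(
            f"{len(samples)} stains do not fit a {layout.rows}x{layout.cols} grid"
        )
    if genotype_labels is not None and len(genotype_labels) != len(samples):
        raise DomainError("genotype_labels length must match samples")

    base = samples[0] if samples else GeneratorParams(percent_hbs=0.0)
    for p in samples:
        p.validate()
        if (p.dpi, p.background, p.noise_sd) != (base.dpi, base.background, base.noise_sd):
            raise DomainError("all sheet samples must share dpi, background and noise_sd")
    max_r = max((p.r_outer_eff_mm for p in samples), default=base.r_outer_mm)
    if 2 * max_r + 2 * layout.jitter_mm > layout.pitch_mm:
        raise LayoutError(
            f"outer diameter {2 * max_r:.1f} mm plus jitter exceeds pitch {layout.pitch_mm} mm"
        )
    if layout.margin_mm < max_r + layout.jitter_mm + 1.0:
        raise LayoutError("sheet margin too small for the outer stain radius")

    ppmm = px_per_mm(base.dpi)
    width_mm = 2 * layout.margin_mm + (layout.cols - 1) * layout.pitch_mm
    height_mm = 2 * layout.margin_mm + (layout.rows - 1) * layout.pitch_mm
    w = int(np.ceil(width_mm * ppmm))
    h = int(np.ceil(height_mm * ppmm))
    canvas = np.zeros((h, w), dtype=np.float64)

    rng = np.random.default_rng(seed)
    records: list[GroundTruthRecord] = []
    for i, p in enumerate(samples):
        row, col = divmod(i, layout.cols)
        jx, jy = rng.uniform(-layout.jitter_mm, layout.jitter_mm, size=2)
        cx = (layout.margin_mm + col * layout.pitch_mm + jx) * ppmm
        cy = (layout.margin_mm + row * layout.pitch_mm + jy) * ppmm
        reach = int(np.ceil((p.r_outer_eff_mm + 1.0) * ppmm))
        x0, x1 = int(cx) - reach, int(cx) + reach + 1
        y0, y1 = int(cy) - reach, int(cy) + reach + 1
        local = _stain_field(p, (y1 - y0, x1 - x0), (cx - x0, cy - y0))
        canvas[y0:y1, x0:x1] += local
        label = (
            genotype_labels[i]
            if genotype_labels is not None
            else infer_genotype(p.percent_hbs)
        )
        records.append(
            GroundTruthRecord(
                stain_id=f"{source_id}:{i:03d}",
                genotype_label=label,
                percent_hbs=p.percent_hbs,
                hb_conc=p.hb_conc,
                center_xy=(cx, cy),
                params=p,
            )
        )
    rgb = _render(canvas, base, rng)
    return StainImage(pixels=rgb, dpi=base.dpi, source_id=source_id), records


# ---------------------------------------------------------------------------
# Cohorts and dilution series
# ---------------------------------------------------------------------------

#: Genotype-appropriate total-Hb ranges (g/dL) for cohort draws.  SS (and
#: S-beta+) subjects are anemic and draw low; the union spans the 6.2-16.5
#: g/dL range observed clinically.
DEFAULT_HB_RANGES: dict[Genotype, tuple[float, float]] = {
    Genotype.AA: (11.5, 16.5),
    Genotype.AS: (12.0, 16.0),
    Genotype.SS: (6.2, 11.0),
    Genotype.SC: (8.0, 11.0),
    Genotype.SBETA: (6.2, 11.0),
}

#: %HbS draw bands per genotype (SBETA drawn strictly above 60).
DEFAULT_HBS_BANDS: dict[Genotype, tuple[float, float]] = {
    **PERCENT_HBS_BANDS,
    Genotype.SBETA: (62.0, 93.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a simulated study cohort.

    Defaults mirror a validation cohort of 18 HbAA, 17 HbAS and 20 HbSS
    subjects; %HbS is drawn uniformly inside each genotype's band and total
    Hb uniformly inside a genotype-appropriate range.
    """

    n_aa: int = 18
    n_as: int = 17
    n_ss: int = 20
    n_sc: int = 0
    n_sbeta: int = 0
    hb_ranges: dict[Genotype, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_HB_RANGES)
    )
    hbs_bands: dict[Genotype, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_HBS_BANDS)
    )
    template: GeneratorParams = field(
        default_factory=lambda: GeneratorParams(percent_hbs=0.0)
    )

    def counts(self) -> list[tuple[Genotype, int]]:
        out = [
            (Genotype.AA, self.n_aa),
            (Genotype.AS, self.n_as),
            (Genotype.SS, self.n_ss),
            (Genotype.SC, self.n_sc),
            (Genotype.SBETA, self.n_sbeta),
        ]
        for g, n in out:
            if n < 0:
                raise DomainError(f"negative count for {g}")
        return out


def draw_cohort_params(
    spec: CohortSpec, seed: int
) -> tuple[list[GeneratorParams], list[Genotype]]:
    """Draw per-subject generator parameters for a cohort, deterministically."""
    rng = np.random.default_rng(seed)
    params: list[GeneratorParams] = []
    labels: list[Genotype] = []
    for genotype, n in spec.counts():
        lo_p, hi_p = spec.hbs_bands[genotype]
        lo_h, hi_h = spec.hb_ranges[genotype]
        for _ in range(n):
            p = float(rng.uniform(lo_p, hi_p)) if hi_p > lo_p else lo_p
            hb = float(rng.uniform(lo_h, hi_h))
            stain_seed = int(rng.integers(0, 2**31 - 1))
            params.append(
                dataclasses.replace(
                    spec.template, percent_hbs=p, hb_conc=hb, seed=stain_seed
                )
            )
            labels.append(genotype)
    return params, labels


def generate_cohort(
    spec: CohortSpec, seed: int
) -> tuple[list[StainImage], list[GroundTruthRecord]]:
    """Render one single-stain image per cohort subject."""
    params, labels = draw_cohort_params(spec, seed)
    images: list[StainImage] = []
    records: list[GroundTruthRecord] = []
    for i, (p, g) in enumerate(zip(params, labels)):
        img, rec = generate_stain(p, genotype_label=g)
        rec = dataclasses.replace(rec, stain_id=f"{g}_{i:03d}")
        images.append(img)
        records.append(rec)
    return images, records


def mix_dilution_series(
    percent_hbs_ss: float, fractions: list[float] | np.ndarray
) -> list[float]:
    """%HbS of SS blood mixed with matched AA blood at given volume fractions.

    With the donor bloods matched for total hemoglobin concentration, %HbS is
    linear in the SS volume fraction, so the result is simply
    ``fraction * percent_hbs_ss``.
    """
    if not 0.0 <= percent_hbs_ss <= 100.0:
        raise DomainError("percent_hbs_ss must be in [0, 100]")
    out: list[float] = []
    for f in np.asarray(fractions, dtype=np.float64):
        if not 0.0 <= f <= 1.0:
            raise DomainError("mixing fractions must be in [0, 1]")
        out.append(float(f) * percent_hbs_ss)
    return out


__all__ = [
    "GeneratorParams",
    "GroundTruthRecord",
    "SheetLayout",
    "CohortSpec",
    "DEFAULT_HB_RANGES",
    "DEFAULT_HBS_BANDS",
    "generate_stain",
    "generate_sheet",
    "generate_cohort",
    "draw_cohort_params",
    "mix_dilution_series",
    "infer_genotype",
    "EDGE_SIGMA_MM",
]
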