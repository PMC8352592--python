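"""Chromatin condensation from histone-fluorescence stacks.

Histone-GFP intensity in a confocal stack tracks local nucleosome
density, so binning voxel intensities into white (open interband), gray
(moderately condensed) and black (heterochromatic) classes and counting
class volumes measures chromosome condensation in living nuclei.
Combining the measured volume fractions with the genomic fraction each
class occupies gives per-class DNA densities and pairwise condensation
ratios.  A companion set of operations converts base pairs into the
length of an extended 11 nm nucleosomal fiber (packing ratio 6.8:1) and
compares it with observed fragment lengths and cylinder volumes to
express fold-compaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import AnalysisError, ValidationError
from .synthetic import BACKGROUND_LABEL, CHROMATIN_CLASSES, CLASS_LABELS

# 8-bit class windows: background 0-82, white 83-148, gray 149-224,
# black 225-255.
DEFAULT_THRESHOLDS = (83, 149, 225)

# Genomic composition of the fly genome by chromatin class: ~5 %
# promoters/regulatory (white), ~25 % active genes (gray), ~70 %
# heterochromatin (black).
DEFAULT_GENOMIC_FRACTIONS = {"white": 0.05, "gray": 0.25, "black": 0.70}


@dataclass(frozen=True)
class ClassScheme:
    """Intensity class boundaries on the 8-bit working range.

    ``thresholds = (t_white, t_gray, t_black)`` are the lowest
    intensities of the white, gray and black classes; everything below
    ``t_white`` is background.  The four windows are contiguous and
    cover 0-255.
    """

    thresholds: tuple[int, int, int] = DEFAULT_THRESHOLDS

    def __post_init__(self):
        t = self.thresholds
        if len(t) != 3:
            raise ValidationError("thresholds must have three entries")
        if not (0 < t[0] < t[1] < t[2] <= 255):
            raise ValidationError(
                "thresholds must be strictly increasing within (0, 255]"
            )

    def classify(self, stack: np.ndarray) -> np.ndarray:
        """Label every voxel: 0 background, 1 white, 2 gray, 3 black."""
        arr = np.asarray(stack)
        if np.issubdtype(arr.dtype, np.floating):
            arr = np.rint(arr)
        return np.digitize(arr, bins=self.thresholds).astype(np.uint8)


@dataclass(frozen=True)
class ClassVolumeResult:
    """Chromatin class volumes pooled across nuclei.

    Fractions are over chromatin voxels only (background excluded);
    ``per_nucleus`` retains each nucleus' own fractions so a
    between-nucleus SD can be reported alongside the pooled values.
    """

    counts: dict
    fractions: dict
    per_nucleus: list
    sd: dict
    n_nuclei: int
    n_slices: int

    def __post_init__(self):
        total = sum(self.fractions.values())
        if self.counts and abs(total - 1.0) > 1e-9:
            raise ValidationError("class fractions must sum to 1")


@dataclass(frozen=True)
class GenomicComposition:
    """Fraction of genomic DNA in each chromatin class."""

    white: float = DEFAULT_GENOMIC_FRACTIONS["white"]
    gray: float = DEFAULT_GENOMIC_FRACTIONS["gray"]
    black: float = DEFAULT_GENOMIC_FRACTIONS["black"]

    def __post_init__(self):
        vals = (self.white, self.gray, self.black)
        if any(v < 0 for v in vals):
            raise ValidationError("genomic fractions must be >= 0")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValidationError("genomic fractions must sum to 1")

    def as_dict(self) -> dict:
        return {"white": self.white, "gray": self.gray, "black": self.black}


@dataclass(frozen=True)
class FiberModel:
    """Physical constants of the extended 11 nm nucleosomal fiber.

    ``nm_per_bp`` is the B-DNA contour length per base pair;
    ``packing_ratio`` is the DNA-length-to-fiber-length ratio of an
    extended 11 nm nucleosomal array (6.8:1).
    """

    nm_per_bp: float = 0.34
    packing_ratio: float = 6.8

    def __post_init__(self):
        if not (self.nm_per_bp > 0 and self.packing_ratio > 0):
            raise ValidationError("nm_per_bp and packing_ratio must be > 0")


@dataclass(frozen=True)
class FragmentMeasurement:
    """In vivo measurements of a chromosomal fragment.

    ``lengths_um`` are replicate apparent lengths across nuclei;
    diameter and genomic size are optional (needed for cylinder-volume
    comparisons).
    """

    lengths_um: tuple
    diameter_um: float | None = None
    dna_bp: float | None = None
    name: str = ""

    def __post_init__(self):
        lengths = tuple(float(x) for x in self.lengths_um)
        object.__setattr__(self, "lengths_um", lengths)
        if not lengths:
            raise ValidationError("lengths_um must contain at least one value")
        if any(x <= 0 for x in lengths):
            raise ValidationError("lengths_um entries must be > 0")
        if self.diameter_um is not None and self.diameter_um <= 0:
            raise ValidationError("diameter_um must be > 0")
        if self.dna_bp is not None and self.dna_bp < 0:
            raise ValidationError("dna_bp must be >= 0")

    @property
    def mean_length_um(self) -> float:
        return float(np.mean(self.lengths_um))

    @property
    def sd_length_um(self) -> float:
        if len(self.lengths_um) < 2:
            return 0.0
        return float(np.std(self.lengths_um, ddof=1))

    @property
    def volume_um3(self) -> float:
        if self.diameter_um is None:
            raise ValidationError("diameter_um required for a cylinder volume")
        return math.pi * (self.diameter_um / 2.0) ** 2 * self.mean_length_um


# ---------------------------------------------------------------------------
# Intensity rescaling and voxel classification
# ---------------------------------------------------------------------------


def rescale_to_full_range(
    stack: np.ndarray,
    p_low: float = 0.35,
    p_high: float = 99.65,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Auto-brightness: map the [p_low, p_high] percentile window to 0-255.

    Mirrors the common auto-adjust convention (0.35 % saturation at
    either end).  Percentiles are computed over ``mask`` when given,
    otherwise over the whole stack.  Output dtype is uint8.
    """
    arr = np.asarray(stack, dtype=float)
    sample = arr[mask] if mask is not None else arr
    lo, hi = np.percentile(sample, [p_low, p_high])
    if hi <= lo:
        raise AnalysisError("zero dynamic range: image is constant")
    scaled = (arr - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


def classify_voxels(
    stack: np.ndarray, scheme: ClassScheme | None = None
) -> np.ndarray:
    """Assign every voxel of a rescaled 8-bit stack to an intensity class."""
    return (scheme or ClassScheme()).classify(stack)


def volume_fractions(label_maps) -> ClassVolumeResult:
    """Pool chromatin class volumes across nuclei.

    ``label_maps`` is an iterable of per-nucleus label arrays (as from
    :func:`classify_voxels` or a phantom ground truth).  Nucleolus
    labels, if present, are ignored along with background.  Headline
    fractions pool all voxels; per-nucleus fractions supply the SD.
    """
    label_maps = list(label_maps)
    if not label_maps:
        raise ValidationError("need at least one nucleus")
    pooled = {c: 0 for c in CHROMATIN_CLASSES}
    per_nucleus = []
    n_slices = 0
    for labels in label_maps:
        labels = np.asarray(labels)
        n_slices += labels.shape[0] if labels.ndim == 3 else 1
        counts = {
            c: int((labels == CLASS_LABELS[c]).sum()) for c in CHROMATIN_CLASSES
        }
        total = sum(counts.values())
        if total == 0:
            raise AnalysisError("a nucleus contains no chromatin voxels")
        per_nucleus.append({c: counts[c] / total for c in CHROMATIN_CLASSES})
        for c in CHROMATIN_CLASSES:
            pooled[c] += counts[c]
    grand = sum(pooled.values())
    fractions = {c: pooled[c] / grand for c in CHROMATIN_CLASSES}
    sd = {
        c: float(np.std([p[c] for p in per_nucleus], ddof=1))
        if len(per_nucleus) > 1
        else 0.0
        for c in CHROMATIN_CLASSES
    }
    return ClassVolumeResult(
        counts=pooled,
        fractions=fractions,
        per_nucleus=per_nucleus,
        sd=sd,
        n_nuclei=len(label_maps),
        n_slices=n_slices,
    )


# ---------------------------------------------------------------------------
# Condensation arithmetic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CondensationResult:
    """Per-class DNA densities and pairwise condensation ratios.

    ``density[c] = genomic_fraction[c] / volume_fraction[c]`` is the
    relative DNA amount per unit chromosome volume;
    ``ratio[(c1, c2)] = density[c1] / density[c2]`` says how many fold
    more condensed class ``c1`` is than class ``c2``.
    """

    density: dict
    ratios: dict
    flags: list = field(default_factory=list)


def relative_condensation(
    genome: GenomicComposition, volumes: ClassVolumeResult | dict
) -> CondensationResult:
    """Per-class densities and all pairwise condensation ratios.

    ``volumes`` may be a :class:`ClassVolumeResult` or a plain
    ``{class: fraction}`` mapping.  A zero volume fraction yields an
    infinite density, reported with a flag rather than raising.
    """
    vol = volumes.fractions if isinstance(volumes, ClassVolumeResult) else dict(volumes)
    gen = genome.as_dict()
    if set(vol) != set(gen):
        raise ValidationError("genomic and volume class sets must match")
    density = {}
    flags = []
    for c in CHROMATIN_CLASSES:
        if vol[c] == 0:
            density[c] = math.inf
            flags.append(f"zero volume fraction for {c}: density is infinite")
        else:
            density[c] = gen[c] / vol[c]
    ratios = {}
    for c1 in CHROMATIN_CLASSES:
        for c2 in CHROMATIN_CLASSES:
            if c1 == c2:
                continue
            d1, d2 = density[c1], density[c2]
            ratios[(c1, c2)] = d1 / d2 if d2 not in (0.0,) else math.inf
    return CondensationResult(density=density, ratios=ratios, flags=flags)


# ---------------------------------------------------------------------------
# Fiber-model compaction
# ---------------------------------------------------------------------------


def extended_fiber_length(dna_bp: float, model: FiberModel | None = None) -> float:
    """Length (μm) of ``dna_bp`` base pairs packaged into an extended
    11 nm nucleosomal fiber."""
    if dna_bp < 0:
        raise ValidationError("dna_bp must be >= 0")
    m = model or FiberModel()
    return dna_bp * m.nm_per_bp / m.packing_ratio / 1000.0


@dataclass(frozen=True)
class LinearCompaction:
    fold: float
    fold_sd: float
    extended_um: float
    observed_um: float
    observed_sd_um: float
    n: int


def fold_compaction_linear(
    extended_um: float, measurement: FragmentMeasurement
) -> LinearCompaction:
    """Fold-compaction of a fragment versus its extended fiber length.

    ``fold = extended / mean(observed)``; the uncertainty is first-order
    propagated from the replicate SD of the observed lengths
    (``sd_fold = fold * sd_len / (mean_len * sqrt(n))`` would be the SEM
    version; the replicate-SD version is reported, matching how spreads
    of per-nucleus measurements are usually quoted).
    """
    if extended_um < 0:
        raise ValidationError("extended_um must be >= 0")
    mean_len = measurement.mean_length_um
    fold = extended_um / mean_len
    sd_fold = fold * measurement.sd_length_um / mean_len
    return LinearCompaction(
        fold=float(fold),
        fold_sd=float(sd_fold),
        extended_um=float(extended_um),
        observed_um=float(mean_len),
        observed_sd_um=float(measurement.sd_length_um),
        n=len(measurement.lengths_um),
    )


def fold_compaction_volumetric(
    frag_a: FragmentMeasurement, frag_b: FragmentMeasurement
) -> float:
    """Relative volumetric condensation of fragment a versus fragment b.

    Each fragment is modelled as a cylinder; the comparison is the ratio
    of DNA densities ``(bp / volume)``: values > 1 mean fragment a packs
    its DNA more tightly.
    """
    for frag in (frag_a, frag_b):
        if frag.dna_bp is None or frag.diameter_um is None:
            raise ValidationError(
                "both fragments need dna_bp and diameter_um for a volumetric comparison"
            )
    dens_a = frag_a.dna_bp / frag_a.volume_um3
    dens_b = frag_b.dna_bp / frag_b.volume_um3
    return float(dens_a / dens_b)


# ---------------------------------------------------------------------------
# Line scans
# ---------------------------------------------------------------------------


def line_scan_profile(
    image: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    spacing: float = 0.5,
) -> np.ndarray:
    """Bilinear intensity profile along a segment, as percent of image max.

    ``image`` is a single 2D channel (call once per channel); ``start``
    and ``end`` are (row, col) endpoints inside the image.  Samples are
    taken every ``spacing`` pixels; the profile is scaled so the
    image-wide maximum equals 100 %.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("line_scan_profile expects a single 2D channel")
    for pt in (start, end):
        if not (0 <= pt[0] <= arr.shape[0] - 1 and 0 <= pt[1] <= arr.shape[1] - 1):
            raise ValidationError("line endpoints must lie inside the image")
    peak = arr.max()
    if peak <= 0:
        raise AnalysisError("image maximum is zero; cannot express percent of max")
    n = max(int(np.hypot(end[0] - start[0], end[1] - start[1]) / spacing), 1)
    rows = np.linspace(start[0], end[0], n + 1)
    cols = np.linspace(start[1], end[1], n + 1)
    prof = map_coordinates(arr, np.vstack([rows, cols]), order=1)
    return 100.0 * prof / peak
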