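"""Synthetic FRAP/FLIP curves and banded-nucleus image phantoms.

Every generator is a pure function of its specification and an explicit
integer seed, so downstream fitting and classification code can be
validated against known ground truth.  The forward models are the exact
counterparts of what the analysis modules fit:

* FRAP: an instantaneous bleach at frame ``n_pre`` removing a fraction
  ``bleach_depth`` of the ROI signal, followed by a double-exponential
  recovery ``F(t) = a (1 - e^{-k1 t}) + b (1 - e^{-k2 t})`` of the
  normalized fluorescence, where ``a + b`` is the mobile fraction.
* FLIP-FRAP: two well-mixed nuclear compartments exchanging mobile
  fluorophore, with total fluorescence conserved after the bleach.
* Phantom: an ellipsoidal nucleus containing a banded "chromosome" of
  white/gray/black chromatin classes plus a spherical nucleolar void,
  convolved with a Gaussian PSF and degraded with Poisson shot noise
  and Gaussian read noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .curves import TimeSeriesCurve
from .errors import ValidationError

# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionSpec:
    """Frame counts, timing, bleach depth and curve-level noise.

    Defaults follow the salivary-gland protocol (10 pre-bleach and 250
    post-bleach frames at 648 ms); the S2-cell protocol is 20 pre / 200
    post frames at 70 ms.
    """

    n_pre: int = 10
    n_post: int = 250
    interval: float = 0.648
    bleach_depth: float = 0.7
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pre < 1:
            raise ValidationError("n_pre must be >= 1")
        if self.n_post < 2:
            raise ValidationError("n_post must be >= 2")
        if not self.interval > 0:
            raise ValidationError("interval must be > 0")
        if not (0 < self.bleach_depth <= 1):
            raise ValidationError("bleach_depth must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.n_pre + self.n_post

    def time_axis(self) -> np.ndarray:
        """Absolute frame times; the bleach sits between frames n_pre-1 and n_pre."""
        return np.arange(self.n_frames, dtype=float) * self.interval


@dataclass(frozen=True)
class KineticParams:
    """Double-exponential recovery parameters.

    ``F(t) = a (1 - e^{-k1 t}) + b (1 - e^{-k2 t})``; mobile fraction is
    ``a + b`` and the half-time solves ``F(t½) = (a + b) / 2``.
    """

    a: float
    b: float = 0.0
    k1: float = 1.0
    k2: float = 0.0

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise ValidationError("a and b must be >= 0")
        if self.a + self.b > 1 + 1e-12:
            raise ValidationError("a + b (mobile fraction) must be <= 1")
        if not (self.k1 >= self.k2 >= 0):
            raise ValidationError("rates must satisfy k1 >= k2 >= 0")

    @property
    def mobile_fraction(self) -> float:
        return self.a + self.b

    def recovery(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a * -np.expm1(-self.k1 * t) + self.b * -np.expm1(-self.k2 * t)


@dataclass(frozen=True)
class TwoCompartmentSpec:
    """Half-nucleus FLIP-FRAP exchange model.

    Two well-mixed compartments of volumes ``v1`` (bleached) and ``v2``
    (unbleached) exchange mobile fluorophore with volumetric rate
    ``k_ex``; concentrations relax with rate ``k_ex (1/v1 + 1/v2)``.
    ``immobile_fraction`` of the fluorophore in each compartment never
    exchanges.
    """

    v1: float = 1.0
    v2: float = 1.0
    k_ex: float = 0.02
    bleach_fraction: float = 0.9
    immobile_fraction: float = 0.0

    def __post_init__(self):
        if not (self.v1 > 0 and self.v2 > 0):
            raise ValidationError("v1 and v2 must be > 0")
        if self.k_ex < 0:
            raise ValidationError("k_ex must be >= 0")
        if not (0 <= self.bleach_fraction <= 1):
            raise ValidationError("bleach_fraction must be in [0, 1]")
        if not (0 <= self.immobile_fraction <= 1):
            raise ValidationError("immobile_fraction must be in [0, 1]")

    @property
    def relaxation_rate(self) -> float:
        return self.k_ex * (1.0 / self.v1 + 1.0 / self.v2)

    @property
    def equilibration_t_half(self) -> float:
        if self.relaxation_rate == 0:
            return math.inf
        return math.log(2.0) / self.relaxation_rate


def k_ex_for_half_time(t_half: float, v1: float = 1.0, v2: float = 1.0) -> float:
    """Volumetric exchange rate giving the requested equilibration half-time."""
    if not t_half > 0:
        raise ValidationError("t_half must be > 0")
    return math.log(2.0) / (t_half * (1.0 / v1 + 1.0 / v2))


# Chromatin classes, ordered by increasing condensation.
CHROMATIN_CLASSES = ("white", "gray", "black")
BACKGROUND_LABEL = 0
NUCLEOLUS_LABEL = 4
CLASS_LABELS = {"white": 1, "gray": 2, "black": 3}


@dataclass(frozen=True)
class PhantomSpec:
    """Banded-nucleus phantom geometry, intensities and noise.

    The nucleus is an axis-aligned ellipsoid filling most of the field;
    a spherical nucleolar void is carved out, and the remaining
    chromatin voxels are split into bands stacked along y with target
    volume fractions honoured exactly (largest-remainder rounding on the
    sorted voxel list).  Default volume fractions are the measured
    white/gray/black chromosome volumes (52/43/5 %); default class
    intensities sit inside the printed 8-bit class windows, well apart
    so a one-voxel Gaussian PSF does not move band cores across the
    class thresholds.
    """

    shape: tuple[int, int, int] = (9, 128, 128)
    voxel_size: tuple[float, float, float] = (0.5, 0.1, 0.1)
    class_fractions: dict = field(
        default_factory=lambda: {"white": 0.52, "gray": 0.43, "black": 0.05}
    )
    class_intensity: dict = field(
        default_factory=lambda: {
            "background": 0.0,
            "nucleolus": 30.0,
            "white": 115.0,
            "gray": 190.0,
            "black": 255.0,
        }
    )
    psf_sigma: float | tuple[float, float, float] = (0.3, 1.0, 1.0)
    shot_noise: bool = True
    read_noise_sd: float = 2.0
    nucleolus_radius_frac: float = 0.18
    n_bands: int = 9
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValidationError("shape must be three positive dimensions")
        if any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel_size entries must be > 0")
        fr = self.class_fractions
        if set(fr) != set(CHROMATIN_CLASSES):
            raise ValidationError("class_fractions must cover white/gray/black")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValidationError("class_fractions must sum to 1")
        inten = self.class_intensity
        for key in ("background", "white", "gray", "black"):
            if key not in inten:
                raise ValidationError(f"class_intensity missing {key}")
            if not (0 <= inten[key] <= 255):
                raise ValidationError(f"class_intensity[{key}] outside 8-bit range")
        if not (
            inten["background"] < inten["white"] < inten["gray"] < inten["black"]
        ):
            raise ValidationError(
                "class_intensity must be ordered background < white < gray < black"
            )
        sigma = self.psf_sigma
        if np.isscalar(sigma):
            if sigma < 0:
                raise ValidationError("psf_sigma must be >= 0")
        else:
            if len(sigma) != 3 or any(s < 0 for s in sigma):
                raise ValidationError(
                    "psf_sigma must be a scalar or three non-negative values"
                )
        if self.read_noise_sd < 0:
            raise ValidationError("read_noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Curve generators
# ---------------------------------------------------------------------------


def _assemble_curve(
    acq: AcquisitionSpec,
    post_expect,
    whole_decay_rate: float = 0.0,
    meta: dict | None = None,
) -> TimeSeriesCurve:
    """Build a TimeSeriesCurve from a noiseless post-bleach expectation.

    ``post_expect`` maps time-since-bleach to the noiseless normalized
    ROI signal.  Optional linear observational bleaching multiplies both
    ROI and whole-nucleus channels by ``1 - whole_decay_rate * t_abs``
    so the normalization stage's correction can be exercised.
    """
    t_abs = acq.time_axis()
    roi = np.ones(acq.n_frames)
    roi[acq.n_pre :] = post_expect(t_abs[acq.n_pre :] - t_abs[acq.n_pre])
    whole = np.ones(acq.n_frames)
    if whole_decay_rate:
        decay = np.clip(1.0 - whole_decay_rate * t_abs, 0.05, None)
        roi = roi * decay
        whole = whole * decay
    if acq.noise_sd > 0:
        rng = np.random.default_rng(acq.seed)
        roi = roi + rng.normal(0.0, acq.noise_sd, size=roi.shape)
    return TimeSeriesCurve(
        time=t_abs,
        roi=roi,
        whole=whole,
        background=np.zeros(acq.n_frames),
        n_pre=acq.n_pre,
        meta=meta or {},
    )


def simulate_frap_curve(
    params: KineticParams,
    acq: AcquisitionSpec,
    whole_decay_rate: float = 0.0,
) -> TimeSeriesCurve:
    """Forward-simulate a FRAP trace with double-exponential recovery.

    The noiseless expectation is ``1 - bleach_depth * (1 - F(t))`` with
    ``F`` the normalized recovery model, so the first post-bleach frame
    equals ``1 - bleach_depth``.
    """
    return _assemble_curve(
        acq,
        lambda t: 1.0 - acq.bleach_depth * (1.0 - params.recovery(t)),
        whole_decay_rate=whole_decay_rate,
        meta={"model": "double_exponential", "params": params},
    )


def simulate_slow_recovery(
    plateau: float, k: float, acq: AcquisitionSpec
) -> TimeSeriesCurve:
    """Single-exponential recovery toward a partial plateau.

    Emulates slow histone exchange: normalized recovery
    ``F(t) = plateau (1 - e^{-k t})`` over multi-minute time bases.
    """
    if not (0 <= plateau <= 1):
        raise ValidationError("plateau must be in [0, 1]")
    if k < 0:
        raise ValidationError("k must be >= 0")
    params = KineticParams(a=plateau, b=0.0, k1=k, k2=0.0)
    return _assemble_curve(
        acq,
        lambda t: 1.0 - acq.bleach_depth * (1.0 - params.recovery(t)),
        meta={"model": "single_exponential", "params": params},
    )


def simulate_biphasic_curve(
    fast_amp: float,
    fast_k: float,
    slope: float,
    acq: AcquisitionSpec,
) -> TimeSeriesCurve:
    """Fast exponential phase followed by a slow linear phase.

    Emulates RNA-polymerase-like recovery: promoter-exchange burst plus
    an elongation ramp.  Noiseless normalized expectation is
    ``min(1, fast_amp (1 - e^{-fast_k t}) + slope t)``.
    """
    if fast_amp < 0 or fast_k < 0 or slope < 0:
        raise ValidationError("fast_amp, fast_k and slope must be >= 0")

    def recovery(t):
        return np.minimum(1.0, fast_amp * -np.expm1(-fast_k * t) + slope * t)

    return _assemble_curve(
        acq,
        lambda t: 1.0 - acq.bleach_depth * (1.0 - recovery(t)),
        meta={"model": "biphasic", "fast_amp": fast_amp, "fast_k": fast_k, "slope": slope},
    )


def two_compartment_solution(
    spec: TwoCompartmentSpec, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless post-bleach intensities of both compartments.

    Pre-bleach concentration is 1 everywhere.  At t=0 compartment 1
    loses ``bleach_fraction`` of its fluorescence; the mobile pools then
    relax exponentially toward equal concentration while immobile pools
    stay put.  Returns ``(I1, I2)`` mean intensities (amount / volume).
    """
    t = np.asarray(t, dtype=float)
    f_im = spec.immobile_fraction
    keep = 1.0 - spec.bleach_fraction
    # Immobile amounts (bleached compartment scaled by the bleach).
    i1 = f_im * spec.v1 * keep
    i2 = f_im * spec.v2
    # Mobile concentrations.
    c1_0 = (1.0 - f_im) * keep
    c2_0 = 1.0 - f_im
    lam = spec.relaxation_rate
    v_tot = spec.v1 + spec.v2
    c_eq = (c1_0 * spec.v1 + c2_0 * spec.v2) / v_tot
    decay = np.exp(-lam * t) if lam > 0 else np.ones_like(t)
    c1 = c_eq + (c1_0 - c_eq) * decay
    c2 = c_eq + (c2_0 - c_eq) * decay
    return c1 + i1 / spec.v1, c2 + i2 / spec.v2


def simulate_flip_frap(
    spec: TwoCompartmentSpec, acq: AcquisitionSpec
) -> tuple[TimeSeriesCurve, TimeSeriesCurve]:
    """Simulate paired (bleached, unbleached) half-nucleus traces.

    The noiseless model conserves total fluorescence after the bleach;
    ``acq.bleach_depth`` is ignored (the bleach is set by
    ``spec.bleach_fraction``).
    """
    t_abs = acq.time_axis()
    t_post = t_abs[acq.n_pre :] - t_abs[acq.n_pre]
    i1, i2 = two_compartment_solution(spec, t_post)
    curves = []
    for j, post in enumerate((i1, i2)):
        roi = np.ones(acq.n_frames)
        roi[acq.n_pre :] = post
        if acq.noise_sd > 0:
            rng = np.random.default_rng(acq.seed + j)
            roi = roi + rng.normal(0.0, acq.noise_sd, size=roi.shape)
        total = np.ones(acq.n_frames)
        total[acq.n_pre :] = (i1 * spec.v1 + i2 * spec.v2) / (spec.v1 + spec.v2)
        curves.append(
            TimeSeriesCurve(
                time=t_abs,
                roi=roi,
                whole=total,
                background=np.zeros(acq.n_frames),
                n_pre=acq.n_pre,
                meta={"compartment": "bleached" if j == 0 else "unbleached",
                      "spec": spec},
            )
        )
    return curves[0], curves[1]


# ---------------------------------------------------------------------------
# Image phantom
# ---------------------------------------------------------------------------


def _largest_remainder_counts(n: int, fractions: dict) -> dict:
    """Integer class counts summing to n, closest to the target fractions."""
    raw = {c: n * fractions[c] for c in CHROMATIN_CLASSES}
    counts = {c: int(math.floor(raw[c])) for c in CHROMATIN_CLASSES}
    short = n - sum(counts.values())
    # Hand leftover voxels to the largest fractional remainders.
    order = sorted(CHROMATIN_CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in order[:short]:
        counts[c] += 1
    return counts


def render_nucleus_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a banded-nucleus phantom.

    Returns ``(image, labels)``: an 8-bit image stack and the
    ground-truth label map (0 background, 1 white, 2 gray, 3 black,
    4 nucleolus).  Chromatin voxel counts match ``class_fractions``
    exactly before PSF blur; the image is the class-intensity map
    convolved with a Gaussian PSF plus Poisson shot noise and Gaussian
    read noise, clipped to [0, 255].
    """
    nz, ny, nx = spec.shape
    zc, yc, xc = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    rz, ry, rx = max(nz / 2.0 - 0.5, 0.5), ny / 2.0 - 2.0, nx / 2.0 - 2.0
    z, y, x = np.ogrid[:nz, :ny, :nx]
    inside = (
        ((z - zc) / rz) ** 2 + ((y - yc) / ry) ** 2 + ((x - xc) / rx) ** 2
    ) <= 1.0

    # Spherical nucleolar void, offset from center so it does not sit on
    # the black band.
    r_nucleolus = spec.nucleolus_radius_frac * min(ry, rx)
    nucleolus = (
        (z - zc) ** 2 + (y - (yc - 0.45 * ry)) ** 2 + (x - (xc + 0.35 * rx)) ** 2
    ) <= r_nucleolus**2
    nucleolus &= inside

    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[nucleolus] = NUCLEOLUS_LABEL

    chromatin = inside & ~nucleolus
    counts = _largest_remainder_counts(int(chromatin.sum()), spec.class_fractions)

    # Stack bands along y: voxels sorted by y then z then x, partitioned
    # into contiguous runs.  Band order interleaves the classes so black
    # sits in the interior flanked by gray, echoing a banded chromosome.
    zz, yy, xx = np.nonzero(chromatin)
    order = np.lexsort((xx, zz, yy))
    zz, yy, xx = zz[order], yy[order], xx[order]

    band_order = _band_sequence(counts, spec.n_bands)
    start = 0
    for cls, n_vox in band_order:
        sel = slice(start, start + n_vox)
        labels[zz[sel], yy[sel], xx[sel]] = CLASS_LABELS[cls]
        start += n_vox

    intensity_of = {
        BACKGROUND_LABEL: spec.class_intensity["background"],
        NUCLEOLUS_LABEL: spec.class_intensity.get(
            "nucleolus", spec.class_intensity["background"]
        ),
        CLASS_LABELS["white"]: spec.class_intensity["white"],
        CLASS_LABELS["gray"]: spec.class_intensity["gray"],
        CLASS_LABELS["black"]: spec.class_intensity["black"],
    }
    image = np.zeros(spec.shape, dtype=float)
    for lab, val in intensity_of.items():
        image[labels == lab] = val

    if np.any(np.asarray(spec.psf_sigma) > 0):
        image = ndimage.gaussian_filter(image, sigma=spec.psf_sigma)

    rng = np.random.default_rng(spec.seed)
    if spec.shot_noise:
        image = rng.poisson(np.clip(image, 0, None)).astype(float)
    if spec.read_noise_sd > 0:
        image = image + rng.normal(0.0, spec.read_noise_sd, size=image.shape)

    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return image, labels


def _band_sequence(counts: dict, n_bands: int) -> list[tuple[str, int]]:
    """Split class voxel counts into a banded ordering along the stack axis.

    White and gray bands alternate; the single black band is embedded in
    the middle gray band so it is flanked by gray on both sides (the
    natural condensation gradient).  Counts are preserved exactly.
    """
    n_white = max(1, (n_bands + 1) // 2)
    n_gray = max(1, n_bands - n_white)
    white_parts = _split_count(counts["white"], n_white)
    gray_parts = _split_count(counts["gray"], n_gray)
    seq: list[tuple[str, int]] = []
    for i in range(max(n_white, n_gray)):
        if i < n_white:
            seq.append(("white", white_parts[i]))
        if i < n_gray:
            seq.append(("gray", gray_parts[i]))
    if counts["black"] > 0:
        gray_idx = [j for j, (c, _) in enumerate(seq) if c == "gray"]
        mid = gray_idx[len(gray_idx) // 2]
        g = seq[mid][1]
        seq[mid : mid + 1] = [
            ("gray", g - g // 2),
            ("black", counts["black"]),
            ("gray", g // 2),
        ]
    return [(c, n) for c, n in seq if n > 0]


def _split_count(total: int, parts: int) -> list[int]:
    base = total // parts
    rem = total - base * parts
    return [base + (1 if i < rem else 0) for i in range(parts)]
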