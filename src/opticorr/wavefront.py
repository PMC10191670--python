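"""Zernike wavefronts, Fourier-optics PSFs, and spectrally weighted kernels.

A sphero-cylindrical prescription is converted to second-order Zernike
coefficients through the power-vector representation (M, J0, J45).  The pupil
wavefront W(x, y) built from those coefficients defines a complex pupil
function P = A * exp(i * 2*pi * W / lambda); the monochromatic point spread
function is |FFT(P)|^2, normalised to unit energy.  Per-primary PSFs are
spectrally weighted sums of monochromatic PSFs over the display primary's
emission spectrum, and the LMS kernel additionally weights each wavelength by
the cone sensitivity, producing a rank-4 stack indexed
``[primary, y, x, cone]`` whose per-(primary, cone) mass equals the
corresponding RGB->LMS matrix entry.

The same wavefront (in micrometres) is reused at every wavelength; wavelength
enters only through the 2*pi/lambda phase scaling and diffraction.  Ocular
longitudinal chromatic aberration is not modelled.

Geometry conventions: PSFs are sampled on a uniform angular grid of
``grid_px`` pixels with pitch ``field_extent / grid_px`` radians.  The
astigmatism axis follows the ophthalmic TABO convention (0 deg = horizontal,
counter-clockwise seen from the observer).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import SamplingError, ValidationError
from .spectra import ConeFundamentals, DisplaySpectra, LMSMatrix, SpectralCurve, compute_lms_matrix

__all__ = [
    "Prescription",
    "ZernikeCoefficients",
    "OpticalConfig",
    "PSFStack",
    "LMSKernel",
    "HUMAN_DEFAULT",
    "CAMERA_TESTBED",
    "zernike_value",
    "osa_index",
    "osa_to_nm",
    "prescription_to_zernike",
    "pupil_wavefront",
    "psf_for_wavelength",
    "psf_for_primary",
    "build_psf_stack",
    "build_lms_kernel",
    "delta_lms_kernel",
    "psf_second_moment",
]


@dataclass(frozen=True)
class Prescription:
    """Refractive error: sphere and cylinder in diopters, axis in degrees.

    The axis is wrapped into [0, 180).  Negative sphere models myopia,
    positive hyperopia; a nonzero cylinder models astigmatism.
    """

    sphere_D: float
    cylinder_D: float = 0.0
    axis_deg: float = 0.0

    def __post_init__(self):
        for name in ("sphere_D", "cylinder_D", "axis_deg"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        object.__setattr__(self, "axis_deg", float(self.axis_deg) % 180.0)


class ZernikeCoefficients:
    """Sparse map from OSA/ANSI single index j to a coefficient in micrometres.

    Coefficients are defined over the pupil radius stated at construction
    time; absent indices are zero.  Supports addition and scalar access.
    """

    def __init__(self, coeffs: dict[int, float] | None = None):
        coeffs = coeffs or {}
        for j, c in coeffs.items():
            if j < 0 or int(j) != j:
                raise ValidationError(f"OSA index must be a nonnegative integer, got {j}")
            if not math.isfinite(c):
                raise ValidationError(f"coefficient c[{j}] must be finite")
        self._c = {int(j): float(c) for j, c in coeffs.items() if c != 0.0}

    def __getitem__(self, j: int) -> float:
        return self._c.get(j, 0.0)

    def get_nm(self, n: int, m: int) -> float:
        """Access by double index (radial order n, azimuthal frequency m)."""
        return self[osa_index(n, m)]

    def items(self):
        return self._c.items()

    def __len__(self):
        return len(self._c)

    def __add__(self, other: "ZernikeCoefficients") -> "ZernikeCoefficients":
        out = dict(self._c)
        for j, c in other.items():
            out[j] = out.get(j, 0.0) + c
        return ZernikeCoefficients(out)

    def __eq__(self, other):
        return isinstance(other, ZernikeCoefficients) and self._c == other._c

    def __repr__(self):
        return f"ZernikeCoefficients({self._c!r})"

    @classmethod
    def from_double_index(cls, coeffs: dict[tuple[int, int], float]) -> "ZernikeCoefficients":
        return cls({osa_index(n, m): c for (n, m), c in coeffs.items()})


def osa_index(n: int, m: int) -> int:
    """OSA/ANSI single index j = (n(n+2) + m) / 2."""
    _check_nm(n, m)
    return (n * (n + 2) + m) // 2


def osa_to_nm(j: int) -> tuple[int, int]:
    """Invert the OSA single index to (n, m)."""
    if j < 0:
        raise ValidationError("OSA index must be >= 0")
    n = int(math.ceil((-3 + math.sqrt(9 + 8 * j)) / 2))
    m = 2 * j - n * (n + 2)
    return n, m


def _check_nm(n: int, m: int) -> None:
    if n < 0 or abs(m) > n or (n - abs(m)) % 2 != 0:
        raise ValidationError(
            f"invalid Zernike indices (n={n}, m={m}): need |m| <= n and n - |m| even"
        )


def zernike_value(n: int, m: int, rho, theta):
    """ANSI-normalised Zernike polynomial Z_n^m at polar pupil coordinates.

    rho is the unit-disc radius in [0, 1], theta the azimuth in radians.
    Normalisation is such that the RMS over the unit disc is 1, e.g.
    Z(2, 0) = sqrt(3) * (2 rho^2 - 1).
    """
    _check_nm(n, m)
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(rho < -1e-12) or np.any(rho > 1 + 1e-12):
        raise ValidationError("rho must lie in [0, 1]")
    am = abs(m)
    radial = np.zeros_like(rho, dtype=float)
    for s in range((n - am) // 2 + 1):
        coef = (
            (-1) ** s
            * math.factorial(n - s)
            / (
                math.factorial(s)
                * math.factorial((n + am) // 2 - s)
                * math.factorial((n - am) // 2 - s)
            )
        )
        radial = radial + coef * rho ** (n - 2 * s)
    norm = math.sqrt(2 * (n + 1) / (1 + (1 if m == 0 else 0)))
    if m > 0:
        ang = np.cos(am * theta)
    elif m < 0:
        ang = np.sin(am * theta)
    else:
        ang = np.ones_like(theta)
    return norm * radial * ang


def prescription_to_zernike(rx: Prescription, pupil_diameter_mm: float) -> ZernikeCoefficients:
    """Convert a sphero-cylindrical prescription to second-order Zernikes.

    Uses the power-vector decomposition M = S + C/2, J0 = -(C/2) cos 2a,
    J45 = -(C/2) sin 2a, then the standard mapping to ANSI coefficients over
    pupil radius r (metres), returned in micrometres::

        c(2, 0)  = -M   r^2 / (4 sqrt(3))
        c(2, 2)  = -J0  r^2 / (2 sqrt(6))
        c(2,-2)  = -J45 r^2 / (2 sqrt(6))
    """
    if pupil_diameter_mm <= 0:
        raise ValidationError("pupil diameter must be > 0")
    r_m = pupil_diameter_mm * 1e-3 / 2.0
    ax = math.radians(rx.axis_deg)
    M = rx.sphere_D + rx.cylinder_D / 2.0
    J0 = -(rx.cylinder_D / 2.0) * math.cos(2 * ax)
    J45 = -(rx.cylinder_D / 2.0) * math.sin(2 * ax)
    um = 1e6
    return ZernikeCoefficients.from_double_index(
        {
            (2, 0): -M * r_m**2 / (4 * math.sqrt(3)) * um,
            (2, 2): -J0 * r_m**2 / (2 * math.sqrt(6)) * um,
            (2, -2): -J45 * r_m**2 / (2 * math.sqrt(6)) * um,
        }
    )


# ---------------------------------------------------------------------------
# optical configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalConfig:
    """Sampling geometry for PSF simulation.

    ``field_extent_deg`` is the full angular width of the PSF grid; the pixel
    pitch is ``field_extent / grid_px`` radians.  The default human-eye
    preset uses a 4 mm photopic pupil and a field wide enough that a 1.5 D
    defocus blur disc occupies at most a quarter of the grid.  ``pad_factor``
    oversizes the internal pupil-plane FFT for accuracy; the internal
    angular sampling is additionally refined so the aperture's intensity
    spectrum is Nyquist-sampled at the shortest wavelength.
    """

    pupil_diameter_mm: float = 4.0
    grid_px: int = 128
    field_extent_deg: float = 1.375
    wavelength_start_nm: float = 400.0
    wavelength_end_nm: float = 700.0
    wavelength_step_nm: float = 1.0
    pad_factor: int = 2

    def __post_init__(self):
        if self.pupil_diameter_mm <= 0:
            raise ValidationError("pupil diameter must be > 0")
        if self.grid_px < 32 or self.grid_px % 2 != 0:
            raise ValidationError("grid_px must be even and >= 32")
        if self.field_extent_deg <= 0:
            raise ValidationError("field extent must be > 0")
        if self.pad_factor < 1:
            raise ValidationError("pad_factor must be >= 1")
        if not (0 < self.wavelength_start_nm < self.wavelength_end_nm):
            raise ValidationError("invalid wavelength range")

    @property
    def pixel_pitch_rad(self) -> float:
        return math.radians(self.field_extent_deg) / self.grid_px

    @property
    def wavelength_grid(self) -> np.ndarray:
        n = int(round((self.wavelength_end_nm - self.wavelength_start_nm) / self.wavelength_step_nm)) + 1
        return self.wavelength_start_nm + self.wavelength_step_nm * np.arange(n)

    def with_(self, **kwargs) -> "OpticalConfig":
        return replace(self, **kwargs)


#: Human-eye default: photopic 4 mm pupil.
HUMAN_DEFAULT = OpticalConfig()

#: Camera testbed preset: f/1.8 capture optics with a 13 mm aperture.
CAMERA_TESTBED = OpticalConfig(pupil_diameter_mm=13.0, field_extent_deg=0.45)


@dataclass(frozen=True)
class PSFStack:
    """Per-primary PSFs, each nonnegative and summing to 1."""

    psfs: np.ndarray  # (3, N, N), order R, G, B
    pixel_pitch_rad: float

    def __post_init__(self):
        p = np.asarray(self.psfs, dtype=float)
        if p.ndim != 3 or p.shape[0] != 3 or p.shape[1] != p.shape[2]:
            raise ValidationError(f"PSF stack must be (3, N, N), got {p.shape}")
        if np.any(p < -1e-12):
            raise ValidationError("PSFs must be nonnegative")
        sums = p.sum(axis=(1, 2))
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValidationError(f"each PSF slice must sum to 1, got sums {sums}")
        object.__setattr__(self, "psfs", p)


@dataclass(frozen=True)
class LMSKernel:
    """Rank-4 spectrally weighted kernel indexed ``[primary, y, x, cone]``.

    For every (primary c, cone k) the spatial sum of ``data[c, :, :, k]``
    equals ``matrix.entries[k, c]``: the kernel redistributes exactly the
    energy the RGB->LMS matrix assigns to that pathway.
    """

    data: np.ndarray  # (3, N, N, 3)
    matrix: LMSMatrix
    pixel_pitch_rad: float
    mode: str = "resolved"

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 4 or d.shape[0] != 3 or d.shape[3] != 3 or d.shape[1] != d.shape[2]:
            raise ValidationError(f"LMS kernel must be (3, N, N, 3), got {d.shape}")
        if np.any(d < -1e-12):
            raise ValidationError("LMS kernel must be nonnegative")
        mass = d.sum(axis=(1, 2))  # (primary, cone)
        expect = self.matrix.entries.T  # entries[k, c] -> [c, k]
        if np.any(np.abs(mass - expect) > 1e-9):
            raise ValidationError(
                "kernel mass does not match the LMS matrix "
                f"(max deviation {np.abs(mass - expect).max():.3e})"
            )
        object.__setattr__(self, "data", d)

    @property
    def size_px(self) -> int:
        return self.data.shape[1]

    def fingerprint(self) -> str:
        """Stable content hash, used to tie surrogate models to a kernel."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.data).tobytes())
        return h.hexdigest()[:16]


def delta_lms_kernel(matrix: LMSMatrix, size_px: int = 1, pixel_pitch_rad: float = 1.0) -> LMSKernel:
    """Aberration-free kernel: a centred delta scaled by each matrix entry."""
    if size_px < 1:
        raise ValidationError("size_px must be >= 1")
    data = np.zeros((3, size_px, size_px, 3))
    c = size_px // 2
    for ci in range(3):
        for k in range(3):
            data[ci, c, c, k] = matrix.entries[k, ci]
    return LMSKernel(data, matrix, pixel_pitch_rad, mode="delta")


# ---------------------------------------------------------------------------
# PSF synthesis
# ---------------------------------------------------------------------------

def _internal_sampling(cfg: OpticalConfig) -> tuple[int, float, int]:
    """Choose the internal FFT geometry.

    Returns (fft_size, internal_pitch_rad, bin_factor).  The internal pitch
    refines the output pitch by an integer factor so that the aperture's
    intensity spectrum is Nyquist-sampled at the shortest wavelength
    (pitch <= lambda_min / (2 D)), and the FFT grid is ``pad_factor`` times
    the binned output size for field headroom.
    """
    D = cfg.pupil_diameter_mm * 1e-3
    lam_min = cfg.wavelength_start_nm * 1e-9
    nyq = lam_min / (2.0 * D)
    B = max(1, int(math.ceil(cfg.pixel_pitch_rad / nyq - 1e-12)))
    pitch = cfg.pixel_pitch_rad / B
    fft_size = cfg.grid_px * B * cfg.pad_factor
    return fft_size, pitch, B


def _wavefront_um(coeffs: ZernikeCoefficients, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    w = np.zeros_like(rho)
    for j, c in coeffs.items():
        n, m = osa_to_nm(j)
        w = w + c * zernike_value(n, m, rho, theta)
    return w


def psf_for_wavelength(
    coeffs: ZernikeCoefficients,
    wavelength_nm: float,
    cfg: OpticalConfig = HUMAN_DEFAULT,
    _check_containment: bool = True,
) -> np.ndarray:
    """Monochromatic PSF by Fourier transform of the complex pupil function.

    Returns a ``(grid_px, grid_px)`` nonnegative array summing to 1, sampled
    at ``cfg.pixel_pitch_rad`` per pixel.  Raises :class:`SamplingError`
    when less than 99% of the diffracted energy falls inside the grid.
    """
    if not (cfg.wavelength_start_nm <= wavelength_nm <= cfg.wavelength_end_nm):
        raise ValidationError(
            f"wavelength {wavelength_nm} nm outside configured range "
            f"[{cfg.wavelength_start_nm}, {cfg.wavelength_end_nm}]"
        )
    from scipy.fft import fft2, fftshift, ifftshift

    M, pitch, B = _internal_sampling(cfg)
    lam = wavelength_nm * 1e-9
    D = cfg.pupil_diameter_mm * 1e-3
    dx = lam / (M * pitch)            # pupil-plane sample pitch (m)
    rp = (D / 2.0) / dx               # aperture radius in pupil samples

    # evaluate the pupil only inside the aperture's bounding box
    h = min(int(np.ceil(rp)) + 2, M // 2)
    sub = slice(M // 2 - h, M // 2 + h)
    idx = (np.arange(M) - M // 2)[sub].astype(float)
    r_px = np.hypot(idx[:, None], idx[None, :])
    # area-antialiased aperture edge
    aperture = np.clip(rp - r_px + 0.5, 0.0, 1.0)
    if len(coeffs):
        inside = aperture > 0
        rho = np.minimum(r_px / rp, 1.0)
        theta = np.arctan2(idx[:, None], idx[None, :])
        w_um = np.zeros_like(rho)
        w_um[inside] = _wavefront_um(coeffs, rho[inside], theta[inside])
        phase = 2.0 * np.pi * (w_um * 1e3) / wavelength_nm
        block = aperture * np.exp(1j * phase)
    else:
        block = aperture.astype(complex)
    pupil = np.zeros((M, M), dtype=complex)
    pupil[sub, sub] = block

    field = fftshift(fft2(ifftshift(pupil)))
    intensity = np.abs(field) ** 2
    total = intensity.sum()

    # bin B x B to the output pitch, then crop the central grid_px window;
    # roll by B/2 first so each bin is centred on its output pixel (the
    # optical axis at sample M/2 must land in the middle of a bin, not on
    # its edge, or a near-delta PSF would be split across two pixels)
    n_binned = M // B
    if B > 1:
        intensity = np.roll(intensity, (B // 2, B // 2), axis=(0, 1))
    intensity = intensity.reshape(n_binned, B, n_binned, B).sum(axis=(1, 3))
    start = (n_binned - cfg.grid_px) // 2
    psf = intensity[start : start + cfg.grid_px, start : start + cfg.grid_px]
    contained = psf.sum() / total
    if _check_containment and contained < 0.99:
        raise SamplingError(
            f"only {contained:.1%} of PSF energy lies inside the {cfg.grid_px}px grid; "
            "enlarge grid_px or field_extent_deg",
            contained_energy=float(contained),
        )
    return psf / psf.sum()


def psf_for_primary(
    primary: SpectralCurve,
    coeffs: ZernikeCoefficients,
    cfg: OpticalConfig = HUMAN_DEFAULT,
) -> np.ndarray:
    """Spectrally weighted PSF for one display primary.

    The monochromatic PSFs over the configured wavelength grid are averaged
    with weights proportional to the primary's emission intensity,
    renormalised to sum to 1 (per primary), so the output again sums to 1.
    """
    grid = cfg.wavelength_grid
    if primary.wavelengths_nm.shape != grid.shape or not np.allclose(primary.wavelengths_nm, grid):
        raise ValidationError("primary spectrum must be sampled on cfg.wavelength_grid")
    w = np.clip(primary.values, 0.0, None)
    if w.sum() <= 0:
        raise ValidationError("primary spectrum is identically zero")
    w = w / w.sum()
    out = np.zeros((cfg.grid_px, cfg.grid_px))
    for lam_nm, weight in zip(grid, w):
        if weight == 0.0:
            continue
        out += weight * psf_for_wavelength(coeffs, lam_nm, cfg)
    return out / out.sum()


def build_psf_stack(
    display: DisplaySpectra,
    coeffs: ZernikeCoefficients,
    cfg: OpticalConfig = HUMAN_DEFAULT,
) -> PSFStack:
    """Per-primary PSFs for all three display primaries (shared lambda loop)."""
    stack, _ = _accumulate_spectral(display, None, coeffs, cfg)
    return stack


def build_kernels(
    display: DisplaySpectra,
    cones: ConeFundamentals,
    coeffs: ZernikeCoefficients,
    cfg: OpticalConfig = HUMAN_DEFAULT,
    mode: str = "resolved",
) -> tuple[PSFStack, LMSKernel]:
    """Per-primary PSF stack and LMS kernel from a single wavelength pass.

    Equivalent to calling :func:`build_psf_stack` and
    :func:`build_lms_kernel` separately, at half the cost; the comparison
    harness builds both for every refractive condition.
    """
    if mode == "aggregated":
        stack = build_psf_stack(display, coeffs, cfg)
        return stack, build_lms_kernel(display, cones, coeffs, cfg, mode=mode)
    matrix = compute_lms_matrix(
        display.on_common_grid(cfg.wavelength_grid),
        cones.on_common_grid(cfg.wavelength_grid),
    )
    stack, raw = _accumulate_spectral(display, cones, coeffs, cfg)
    kernel = _finalize_resolved(raw, matrix, cfg, mode)
    return stack, kernel


def _finalize_resolved(raw: np.ndarray, matrix: LMSMatrix, cfg: OpticalConfig, mode: str) -> LMSKernel:
    data = raw * matrix.scale
    # pin each slice's mass exactly (FFT round-off is ~1e-15)
    mass = data.sum(axis=(1, 2), keepdims=True)
    expect = matrix.entries.T[:, None, None, :]
    safe = np.where(mass > 0, mass, 1.0)
    data = data * (expect / safe)
    return LMSKernel(data, matrix, cfg.pixel_pitch_rad, mode=mode)


def build_lms_kernel(
    display: DisplaySpectra,
    cones: ConeFundamentals,
    coeffs: ZernikeCoefficients,
    cfg: OpticalConfig = HUMAN_DEFAULT,
    mode: str = "resolved",
) -> LMSKernel:
    """Assemble the rank-4 LMS kernel.

    ``mode="resolved"`` weights each monochromatic PSF by the product of the
    primary emission and the cone sensitivity at that wavelength — the
    physically consistent form.  ``mode="aggregated"`` applies the aggregated
    RGB->LMS matrix to the already spectrally averaged per-primary PSFs; the
    two coincide exactly when the PSF is wavelength-independent.  Either way
    the per-(primary, cone) kernel mass equals the matching matrix entry.
    """
    if mode not in ("resolved", "aggregated"):
        raise ValidationError(f"mode must be 'resolved' or 'aggregated', got {mode!r}")
    matrix = compute_lms_matrix(
        display.on_common_grid(cfg.wavelength_grid),
        cones.on_common_grid(cfg.wavelength_grid),
    )
    if mode == "aggregated":
        stack = build_psf_stack(display, coeffs, cfg)
        data = np.einsum("cij,kc->cijk", stack.psfs, matrix.entries)
        return LMSKernel(data, matrix, cfg.pixel_pitch_rad, mode=mode)
    _, raw = _accumulate_spectral(display, cones, coeffs, cfg)
    return _finalize_resolved(raw, matrix, cfg, mode)


def _accumulate_spectral(
    display: DisplaySpectra,
    cones: ConeFundamentals | None,
    coeffs: ZernikeCoefficients,
    cfg: OpticalConfig,
) -> tuple[PSFStack, np.ndarray | None]:
    """One pass over the wavelength grid accumulating primary PSFs and,
    when cones are given, the raw (unnormalised) resolved LMS kernel."""
    grid = cfg.wavelength_grid
    disp = display.on_common_grid(grid)
    P = np.stack([np.clip(c.values, 0.0, None) for c in disp])  # (3, L)
    if np.any(P.sum(axis=1) <= 0):
        raise ValidationError("a primary spectrum is identically zero on the grid")
    Pw = P / P.sum(axis=1, keepdims=True)
    C = None
    if cones is not None:
        con = cones.on_common_grid(grid)
        C = np.stack([np.clip(c.values, 0.0, None) for c in con])  # (3, L)

    N = cfg.grid_px
    stack = np.zeros((3, N, N))
    kernel = np.zeros((3, N, N, 3)) if C is not None else None
    dlam = cfg.wavelength_step_nm
    for i, lam_nm in enumerate(grid):
        if P[:, i].max() == 0.0:
            continue
        psf = psf_for_wavelength(coeffs, lam_nm, cfg)
        for ci in range(3):
            if Pw[ci, i] != 0.0:
                stack[ci] += Pw[ci, i] * psf
            if kernel is not None and P[ci, i] != 0.0:
                for k in range(3):
                    if C[k, i] != 0.0:
                        kernel[ci, :, :, k] += dlam * P[ci, i] * C[k, i] * psf
    stack = stack / stack.sum(axis=(1, 2), keepdims=True)
    return PSFStack(stack, cfg.pixel_pitch_rad), kernel


def pupil_wavefront(coeffs: ZernikeCoefficients, grid_px: int = 128) -> np.ndarray:
    """Evaluate the wavefront map (micrometres) on the unit pupil disc.

    Points outside the disc are NaN.
    """
    if grid_px < 32:
        raise ValidationError("grid_px must be >= 32")
    x = np.linspace(-1.0, 1.0, grid_px)
    X, Y = np.meshgrid(x, x, indexing="xy")
    rho = np.hypot(X, Y)
    theta = np.arctan2(Y, X)
    out = np.full((grid_px, grid_px), np.nan)
    inside = rho <= 1.0
    out[inside] = _wavefront_um(coeffs, rho[inside], theta[inside])
    return out


def psf_second_moment(psf: np.ndarray, pixel_pitch_rad: float = 1.0) -> float:
    """Radial second moment of a normalised PSF about its centroid (rad^2)."""
    psf = np.asarray(psf, dtype=float)
    n = psf.shape[0]
    idx = (np.arange(n) - n // 2) * pixel_pitch_rad
    X, Y = np.meshgrid(idx, idx, indexing="xy")
    total = psf.sum()
    cx = (psf * X).sum() / total
    cy = (psf * Y).sum() / total
    return float((psf * ((X - cx) ** 2 + (Y - cy) ** 2)).sum() / total)
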