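"""Display emission spectra, cone fundamentals, and colour-space transforms.

A display is characterised by the emission spectra of its three colour
primaries; the human retina by the sensitivity functions of the L, M and S
cones.  Integrating each primary's spectrum against each cone fundamental
yields a 3x3 matrix that converts linear RGB pixel values into cone
activations (LMS space)::

    [I_L, I_M, I_S]^T = A . [I_R, I_G, I_B]^T
    A[k, c] = sum_lambda cone_k(lambda) * primary_c(lambda) * d_lambda

All spectra are relative (dimensionless, peak-normalised to 1); absolute
radiometric calibration is out of scope.  The default evaluation grid is
400-700 nm at 1 nm, the visible range over which both display primaries and
cone fundamentals carry essentially all of their mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .exceptions import DegenerateInputError, ValidationError

__all__ = [
    "DEFAULT_GRID",
    "SpectralCurve",
    "DisplaySpectra",
    "ConeFundamentals",
    "LMSMatrix",
    "SpectrumSamples",
    "fit_spectrum",
    "resample",
    "compute_lms_matrix",
    "rgb_to_lms",
    "lms_to_opponency",
    "opponency_to_lms",
    "opponency_matrix",
    "synth_display_spectra",
    "builtin_cone_fundamentals",
    "read_display_spectra_csv",
    "read_cone_fundamentals_csv",
    "write_display_spectra_csv",
    "write_cone_fundamentals_csv",
]

#: Default wavelength grid: 400..700 nm inclusive at 1 nm (301 samples).
DEFAULT_GRID = np.arange(400.0, 701.0, 1.0)


def _as_grid(grid_start_nm: float, grid_end_nm: float, grid_step_nm: float) -> np.ndarray:
    if grid_step_nm <= 0:
        raise ValidationError(f"grid step must be > 0, got {grid_step_nm}")
    if grid_end_nm <= grid_start_nm:
        raise ValidationError("grid end must exceed grid start")
    n = int(round((grid_end_nm - grid_start_nm) / grid_step_nm)) + 1
    return grid_start_nm + grid_step_nm * np.arange(n)


@dataclass(frozen=True)
class SpectralCurve:
    """A relative spectrum sampled on a strictly increasing wavelength grid."""

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.ndim != 1 or v.ndim != 1 or w.size != v.size:
            raise ValidationError("wavelengths and values must be 1-D and the same length")
        if w.size == 0:
            raise ValidationError("spectral curve must be non-empty")
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(v)):
            raise ValidationError("spectral curve contains non-finite entries")
        if np.any(np.diff(w) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "values", v)

    def normalized(self) -> "SpectralCurve":
        """Clip to >= 0 and scale so the peak equals 1."""
        v = np.clip(self.values, 0.0, None)
        peak = v.max()
        if peak <= 0:
            raise ValidationError("cannot normalize an all-zero spectrum")
        return SpectralCurve(self.wavelengths_nm, v / peak)

    def integral(self) -> float:
        """Trapezoidal integral over the support, in value * nm."""
        return float(np.trapezoid(self.values, self.wavelengths_nm))

    @property
    def step_nm(self) -> float:
        steps = np.diff(self.wavelengths_nm)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
            raise ValidationError("curve is not on a uniform grid")
        return float(steps[0])


@dataclass(frozen=True)
class DisplaySpectra:
    """Emission spectra of the red, green and blue display primaries."""

    red: SpectralCurve
    green: SpectralCurve
    blue: SpectralCurve

    def __iter__(self):
        return iter((self.red, self.green, self.blue))

    def on_common_grid(self, grid: np.ndarray | None = None) -> "DisplaySpectra":
        grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
        return DisplaySpectra(*(resample(c, grid) for c in self))


@dataclass(frozen=True)
class ConeFundamentals:
    """L, M and S cone sensitivity functions."""

    l: SpectralCurve
    m: SpectralCurve
    s: SpectralCurve

    def __post_init__(self):
        peaks = [c.wavelengths_nm[np.argmax(c.values)] for c in (self.l, self.m, self.s)]
        if not (peaks[0] > peaks[1] > peaks[2]):
            raise ValidationError(
                f"cone peak ordering must be L > M > S in wavelength, got {peaks}"
            )
        for c in (self.l, self.m, self.s):
            if np.any(c.values < 0):
                raise ValidationError("cone fundamentals must be nonnegative")

    def __iter__(self):
        return iter((self.l, self.m, self.s))

    def on_common_grid(self, grid: np.ndarray | None = None) -> "ConeFundamentals":
        grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
        return ConeFundamentals(*(resample(c, grid) for c in self))


@dataclass(frozen=True)
class LMSMatrix:
    """RGB -> LMS conversion matrix (rows L,M,S; columns R,G,B).

    ``entries`` is the working, normalised matrix: the raw spectral-overlap
    matrix scaled by a single scalar so that a full-white pixel (1,1,1) maps
    to LMS activations with maximum 1.  Only ratios matter for the
    precorrection loss, so the scale is a convention; ``raw`` retains the
    unscaled d_lambda-weighted overlap integrals for oracle work.
    """

    entries: np.ndarray
    raw: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        e = np.asarray(self.entries, dtype=float)
        if e.shape != (3, 3):
            raise ValidationError(f"LMS matrix must be 3x3, got {e.shape}")
        if np.any(e < -1e-15):
            raise ValidationError("LMS matrix entries must be nonnegative")
        object.__setattr__(self, "entries", np.clip(e, 0.0, None))
        raw = e if self.raw is None else np.asarray(self.raw, dtype=float)
        object.__setattr__(self, "raw", raw)

    @property
    def scale(self) -> float:
        """Scalar mapping raw -> entries."""
        nz = self.raw != 0
        if not nz.any():
            return 1.0
        return float(np.median(self.entries[nz] / self.raw[nz]))


@dataclass(frozen=True)
class SpectrumSamples:
    """Raw spectrometer readings: discrete wavelengths and intensities."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or v.ndim != 1 or w.size != v.size:
            raise ValidationError("wavelengths and intensities must be 1-D, same length")
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(v)):
            raise ValidationError("spectrometer readings contain non-finite values")
        if np.unique(w).size < 4:
            raise DegenerateInputError(
                f"need at least 4 distinct wavelengths, got {np.unique(w).size}"
            )
        order = np.argsort(w, kind="stable")
        object.__setattr__(self, "wavelengths_nm", w[order])
        object.__setattr__(self, "intensities", v[order])


# ---------------------------------------------------------------------------
# fitting & resampling
# ---------------------------------------------------------------------------

def fit_spectrum(
    samples: SpectrumSamples,
    grid_start_nm: float = 400.0,
    grid_end_nm: float = 700.0,
    grid_step_nm: float = 1.0,
    backend: str = "spline",
    seed: int = 0,
) -> SpectralCurve:
    """Fit a smooth, peak-normalised curve through raw spectrometer samples.

    The default backend is a shape-preserving piecewise-cubic (PCHIP)
    interpolant: deterministic, monotone-safe between samples, and free of
    ringing, so the mean absolute error at the sample wavelengths is zero by
    construction.  ``backend="mlp"`` fits a small multilayer perceptron
    (one hidden layer of 64 tanh units) as a general function
    approximator; it meets the same
    fit-quality contract on smooth spectra but is slower.  The MLP is
    trained with L-BFGS: full-batch quasi-Newton is far more reliable than
    stochastic updates on a few dozen samples.

    Both backends return the curve evaluated on the uniform
    ``[grid_start_nm, grid_end_nm]`` grid, clipped to >= 0 and scaled to
    peak 1; wavelengths outside the sampled support evaluate to 0.
    """
    grid = _as_grid(grid_start_nm, grid_end_nm, grid_step_nm)
    w, v = samples.wavelengths_nm, samples.intensities
    # collapse duplicate wavelengths by averaging
    uw, inv = np.unique(w, return_inverse=True)
    if uw.size != w.size:
        uv = np.zeros_like(uw)
        counts = np.zeros_like(uw)
        np.add.at(uv, inv, v)
        np.add.at(counts, inv, 1.0)
        w, v = uw, uv / counts
    if w[-1] < grid_start_nm or w[0] > grid_end_nm:
        raise ValidationError("samples do not overlap the requested grid")

    if backend == "spline":
        if np.allclose(v, v[0]):
            fitted = np.full_like(grid, v[0])
        else:
            interp = PchipInterpolator(w, v, extrapolate=False)
            fitted = interp(grid)
            fitted = np.where(np.isnan(fitted), 0.0, fitted)
    elif backend == "mlp":
        fitted = _fit_mlp(w, v, grid, seed=seed)
        fitted[(grid < w[0]) | (grid > w[-1])] = 0.0
    else:
        raise ValidationError(f"unknown fit backend {backend!r}")

    return SpectralCurve(grid, fitted).normalized()


def _fit_mlp(w: np.ndarray, v: np.ndarray, grid: np.ndarray, seed: int) -> np.ndarray:
    from sklearn.neural_network import MLPRegressor

    # standardize wavelength; scale intensities to [0,1]
    mu, sd = w.mean(), w.std()
    vmax = np.abs(v).max()
    vmax = vmax if vmax > 0 else 1.0
    x = ((w - mu) / sd).reshape(-1, 1)
    # one hidden layer of 64 tanh units; quasi-Newton training because the
    # sample sets are tiny and the contract is interpolation quality
    model = MLPRegressor(
        hidden_layer_sizes=(64,),
        activation="tanh",
        solver="lbfgs",
        max_iter=5000,
        tol=1e-10,
        random_state=seed,
    )
    model.fit(x, v / vmax)
    xg = ((grid - mu) / sd).reshape(-1, 1)
    return model.predict(xg) * vmax


def resample(curve: SpectralCurve, grid: np.ndarray) -> SpectralCurve:
    """Linearly interpolate a curve onto ``grid``; outside support -> 0."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("resample grid is empty")
    vals = np.interp(grid, curve.wavelengths_nm, curve.values, left=0.0, right=0.0)
    return SpectralCurve(grid, vals)


# ---------------------------------------------------------------------------
# RGB -> LMS -> opponency
# ---------------------------------------------------------------------------

def compute_lms_matrix(
    display: DisplaySpectra,
    cones: ConeFundamentals,
    normalize: bool = True,
) -> LMSMatrix:
    """Build the RGB -> LMS matrix by integrating primaries against cones.

    Each entry is a d_lambda-weighted Riemann sum, so the result is invariant
    under refinement of the wavelength grid; on the default 1 nm grid the
    weight is 1 and the entry reduces to the bare sum over sampled
    wavelengths.  All six curves must share one uniform grid.
    """
    grids = [c.wavelengths_nm for c in display] + [c.wavelengths_nm for c in cones]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise ValidationError(
                "display and cone curves must share one wavelength grid; "
                "resample them first"
            )
    dlam = display.red.step_nm
    P = np.stack([c.values for c in display])   # (3 primaries, n_lambda)
    C = np.stack([c.values for c in cones])     # (3 cones, n_lambda)
    raw = dlam * (C @ P.T)                      # raw[k, c]
    if not normalize:
        return LMSMatrix(raw, raw=raw)
    white = raw.sum(axis=1)                     # LMS of a (1,1,1) pixel
    peak = white.max()
    if peak <= 0:
        raise ValidationError("display/cone overlap is identically zero")
    return LMSMatrix(raw / peak, raw=raw)


def rgb_to_lms(image: np.ndarray, a: LMSMatrix | np.ndarray) -> np.ndarray:
    """Per-pixel matrix-vector product mapping linear RGB to cone space."""
    mat = a.entries if isinstance(a, LMSMatrix) else np.asarray(a, dtype=float)
    image = np.asarray(image, dtype=float)
    if image.shape[-1] != 3:
        raise ValidationError(f"expected trailing channel axis of size 3, got {image.shape}")
    return np.einsum("kc,...c->...k", mat, image)


def opponency_matrix(third_channel: str = "mean") -> np.ndarray:
    """Linear LMS -> colour-opponency transform.

    Channels: (M+S)-L, (L+S)-M, and an achromatic combination of L, M and S.
    The achromatic channel is the arithmetic mean by default (``"sum"``
    selects L+M+S); either choice keeps the transform exactly invertible.
    """
    if third_channel == "mean":
        third = [1 / 3, 1 / 3, 1 / 3]
    elif third_channel == "sum":
        third = [1.0, 1.0, 1.0]
    else:
        raise ValidationError(f"third_channel must be 'mean' or 'sum', got {third_channel!r}")
    return np.array([[-1.0, 1.0, 1.0], [1.0, -1.0, 1.0], third])


def lms_to_opponency(image: np.ndarray, third_channel: str = "mean") -> np.ndarray:
    """Map an LMS image to colour-opponency channels (exactly linear)."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValidationError("LMS image contains non-finite values")
    return np.einsum("oc,...c->...o", opponency_matrix(third_channel), image)


def opponency_to_lms(image: np.ndarray, third_channel: str = "mean") -> np.ndarray:
    """Exact inverse of :func:`lms_to_opponency`."""
    inv = np.linalg.inv(opponency_matrix(third_channel))
    return np.einsum("co,...o->...c", inv, np.asarray(image, dtype=float))


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

def synth_display_spectra(
    peaks_nm: tuple[float, float, float] = (620.0, 530.0, 460.0),
    widths_nm: tuple[float, float, float] = (15.0, 15.0, 15.0),
    seed: int | None = None,
    jitter_nm: float = 0.0,
    grid: np.ndarray | None = None,
) -> DisplaySpectra:
    """Generate narrowband Gaussian display primaries on the 1 nm grid.

    Peak wavelengths default to 620/530/460 nm with 15 nm standard
    deviation — representative of LED-backlit panel primaries.  With
    ``jitter_nm > 0`` a seeded generator perturbs each peak and width by a
    uniform offset in ``[-jitter_nm, +jitter_nm]``; the same seed always
    yields the same spectra.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    peaks = np.asarray(peaks_nm, dtype=float)
    widths = np.asarray(widths_nm, dtype=float)
    if np.any(widths <= 0):
        raise ValidationError("widths must be > 0")
    if jitter_nm > 0:
        rng = np.random.default_rng(seed)
        peaks = peaks + rng.uniform(-jitter_nm, jitter_nm, size=3)
        widths = np.clip(widths + rng.uniform(-jitter_nm, jitter_nm, size=3), 1.0, None)
    if np.any(peaks <= grid[0]) or np.any(peaks >= grid[-1]):
        raise ValidationError(
            f"primary peaks {peaks} must lie strictly inside ({grid[0]}, {grid[-1]})"
        )
    curves = [
        SpectralCurve(grid, np.exp(-0.5 * ((grid - p) / s) ** 2)).normalized()
        for p, s in zip(peaks, widths)
    ]
    return DisplaySpectra(*curves)


def builtin_cone_fundamentals(grid: np.ndarray | None = None) -> ConeFundamentals:
    """Smooth built-in L/M/S cone sensitivity curves.

    Each fundamental is an asymmetric Gaussian lobe (broader on the
    long-wavelength side, as real cone fundamentals are), peaking near
    565, 540 and 445 nm for L, M and S.  These are synthetic stand-ins with
    the right qualitative shape and overlap structure; for fidelity work,
    load measured fundamentals via :func:`read_cone_fundamentals_csv`.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)

    def lobe(peak, sigma_left, sigma_right):
        sigma = np.where(grid < peak, sigma_left, sigma_right)
        return SpectralCurve(grid, np.exp(-0.5 * ((grid - peak) / sigma) ** 2)).normalized()

    return ConeFundamentals(
        l=lobe(565.0, 45.0, 38.0),
        m=lobe(540.0, 40.0, 33.0),
        s=lobe(445.0, 25.0, 22.0),
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path}: malformed CSV: {exc}") from exc


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce").to_numpy()
    bad = np.nonzero(~np.isfinite(vals))[0]
    if bad.size:
        # +2: header line plus 1-based indexing
        raise ValidationError(
            f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}"
        )
    return vals


def read_display_spectra_csv(path) -> DisplaySpectra:
    """Read display primaries from CSV.

    Accepts either a three-primary file with columns
    ``wavelength_nm,intensity,primary`` (primary in R|G|B) or a single-primary
    file ``wavelength_nm,intensity`` — in the latter case pass three paths to
    :func:`read_display_spectra_csv_triplet` instead.
    """
    df = _read_csv(path)
    required = {"wavelength_nm", "intensity", "primary"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    curves = {}
    for name in ("R", "G", "B"):
        sub = df[df["primary"] == name]
        if sub.empty:
            raise ValidationError(f"{path}: no rows for primary {name!r}")
        w = _numeric(sub, "wavelength_nm", path)
        v = _numeric(sub, "intensity", path)
        order = np.argsort(w)
        curves[name] = SpectralCurve(w[order], v[order]).normalized()
    return DisplaySpectra(curves["R"], curves["G"], curves["B"])


def read_display_spectra_csv_triplet(red_path, green_path, blue_path) -> DisplaySpectra:
    """Read one ``wavelength_nm,intensity`` CSV per primary."""
    curves = []
    for path in (red_path, green_path, blue_path):
        df = _read_csv(path)
        if not {"wavelength_nm", "intensity"}.issubset(df.columns):
            raise ValidationError(
                f"{path}: expected columns ['wavelength_nm', 'intensity'], "
                f"got {list(df.columns)}"
            )
        w = _numeric(df, "wavelength_nm", path)
        v = _numeric(df, "intensity", path)
        order = np.argsort(w)
        curves.append(SpectralCurve(w[order], v[order]).normalized())
    return DisplaySpectra(*curves)


def read_cone_fundamentals_csv(path) -> ConeFundamentals:
    """Read cone fundamentals from a ``wavelength_nm,L,M,S`` CSV."""
    df = _read_csv(path)
    required = {"wavelength_nm", "L", "M", "S"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    w = _numeric(df, "wavelength_nm", path)
    order = np.argsort(w)
    curves = {
        k: SpectralCurve(w[order], _numeric(df, k, path)[order]).normalized()
        for k in ("L", "M", "S")
    }
    return ConeFundamentals(curves["L"], curves["M"], curves["S"])


def write_display_spectra_csv(display: DisplaySpectra, path) -> None:
    frames = []
    for name, curve in zip("RGB", display):
        frames.append(
            pd.DataFrame(
                {
                    "wavelength_nm": curve.wavelengths_nm,
                    "intensity": curve.values,
                    "primary": name,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_cone_fundamentals_csv(cones: ConeFundamentals, path) -> None:
    grid = cones.l.wavelengths_nm
    for c in (cones.m, cones.s):
        if c.wavelengths_nm.shape != grid.shape or not np.allclose(c.wavelengths_nm, grid):
            raise ValidationError("cone curves must share a grid to be written together")
    pd.DataFrame(
        {
            "wavelength_nm": grid,
            "L": cones.l.values,
            "M": cones.m.values,
            "S": cones.s.values,
        }
    ).to_csv(path, index=False)
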