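"""Pixelwise temporal-frequency analysis of attenuation image stacks.

Two complementary per-pixel summaries of temporal fluctuation are computed
from the magnitude spectrum of each pixel's mean-subtracted trace:

* the power-law log slope ``beta`` of ``I(f) ~ f**-beta`` fitted by
  ordinary least squares in log10-log10 coordinates (``beta ~ 1`` diffuse
  Brownian motion, ``beta ~ 2`` advective motion), and
* a first-harmonic phasor ``(g, s)`` of the normalized spectral decay over
  the retained frequency axis; distance from the origin grows with
  fluctuation strength and with spectral concentration at low frequency
  (i.e. with ``beta``), and a temporally constant pixel maps to (0, 0).

Frequencies below ``f_min`` (default 0.1 Hz) are excluded from both
analyses; the spectrum runs from the first retained bin to Nyquist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

DEFAULT_F_MIN = 0.1  # Hz; low-frequency exclusion below which the log-log model fails
_ZERO_ENERGY_TOL = 1e-12


@dataclass(frozen=True)
class PixelSpectrum:
    """Positive-frequency magnitude response of one pixel trace."""

    frequencies: np.ndarray  # Hz, strictly increasing, DC excluded, <= Nyquist
    magnitude: np.ndarray  # attenuation units

    def __post_init__(self):
        f = self.frequencies
        if f.ndim != 1 or f.size == 0 or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be 1-D and strictly increasing")
        if f[0] <= 0:
            raise ValueError("DC must be excluded")
        if self.magnitude.shape != f.shape:
            raise ValueError("magnitude and frequency grids differ")


@dataclass
class DynamicMaps:
    """Per-pixel phasor g, phasor s, power-law slope beta and fit r^2.

    Arrays share the stack's spatial shape; pixels outside the analysis
    mask are NaN.
    """

    g: np.ndarray
    s: np.ndarray
    beta: np.ndarray
    r2: np.ndarray
    frame_rate: float
    f_min: float = DEFAULT_F_MIN

    @property
    def gs(self) -> np.ndarray:
        """Product g*s, the scalar used to visualize phasor activity."""
        return self.g * self.s

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.beta)


def pixel_spectrum(trace: np.ndarray, frame_rate: float) -> PixelSpectrum:
    """Magnitude spectrum of the mean-subtracted trace (DC excluded)."""
    trace = np.asarray(trace, dtype=np.float64)
    if trace.size < 8:
        raise ValueError("trace length must be >= 8")
    spec = np.fft.rfft(trace - trace.mean())
    freqs = np.fft.rfftfreq(trace.size, d=1.0 / frame_rate)
    return PixelSpectrum(freqs[1:], np.abs(spec[1:]))


def fit_power_law(spectrum: PixelSpectrum, f_min: float = DEFAULT_F_MIN):
    """OLS fit of ``log10 I`` vs ``log10 f`` over ``[f_min, Nyquist]``.

    Returns ``(beta, r2)`` with beta the positive decay exponent
    (``-slope``).  Bins with zero magnitude are dropped; if fewer than two
    nonzero bins remain, ``(nan, nan)`` is returned.
    """
    keep = spectrum.frequencies >= f_min
    f = spectrum.frequencies[keep]
    m = spectrum.magnitude[keep]
    nz = m > 0
    f, m = f[nz], m[nz]
    if f.size < 2:
        return float("nan"), float("nan")
    x, y = np.log10(f), np.log10(m)
    slope, _, r, _, _ = stats.linregress(x, y)
    return float(-slope), float(r * r)


def phasor(spectrum: PixelSpectrum, f_min: float = DEFAULT_F_MIN):
    """First-harmonic phasor of the normalized spectral decay curve.

    The retained frequency axis is mapped to ``x = (f - f_min) /
    (f_nyq - f_min)`` and the spectrum acts as a weight::

        g = sum I(f) cos(2 pi x) / sum I(f)
        s = sum I(f) sin(2 pi x) / sum I(f)

    A constant trace (zero spectral energy) maps to (0, 0); a spectrum
    concentrated entirely at the lowest retained frequency maps to (1, 0).
    """
    keep = spectrum.frequencies >= f_min
    f = spectrum.frequencies[keep]
    m = spectrum.magnitude[keep]
    if f.size == 0:
        return 0.0, 0.0
    total = m.sum()
    if total < _ZERO_ENERGY_TOL:
        return 0.0, 0.0
    f_nyq = f[-1]
    x = (f - f_min) / (f_nyq - f_min) if f_nyq > f_min else np.zeros_like(f)
    g = float(np.sum(m * np.cos(2 * np.pi * x)) / total)
    s = float(np.sum(m * np.sin(2 * np.pi * x)) / total)
    return g, s


def _batch_spectra(traces: np.ndarray, frame_rate: float):
    """Magnitude spectra of rows of ``traces`` (``(n_pix, T)``), DC excluded."""
    traces = traces - traces.mean(axis=1, keepdims=True)
    mags = np.abs(np.fft.rfft(traces, axis=1))[:, 1:]
    freqs = np.fft.rfftfreq(traces.shape[1], d=1.0 / frame_rate)[1:]
    return freqs, mags


def _batch_fit_power_law(freqs, mags, f_min):
    """Vectorized log-log OLS over rows of ``mags``; zero bins excluded per row."""
    keep = freqs >= f_min
    f = freqs[keep]
    m = mags[:, keep]
    x = np.log10(f)
    valid = m > 0
    n = valid.sum(axis=1).astype(float)
    with np.errstate(divide="ignore"):
        y = np.where(valid, np.log10(np.where(valid, m, 1.0)), 0.0)
    xs = np.where(valid, x[None, :], 0.0)
    sx = xs.sum(axis=1)
    sy = y.sum(axis=1)
    sxx = (xs * xs).sum(axis=1)
    sxy = (xs * y).sum(axis=1)
    syy = (y * y).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = n * sxx - sx * sx
        slope = (n * sxy - sx * sy) / denom
        ss_tot = syy - sy * sy / n
        ss_res = ss_tot - slope * (sxy - sx * sy / n)
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)
    bad = n < 2
    slope = np.where(bad, np.nan, slope)
    r2 = np.where(bad, np.nan, r2)
    return -slope, r2


def _batch_phasor(freqs, mags, f_min):
    keep = freqs >= f_min
    f = freqs[keep]
    m = mags[:, keep]
    f_nyq = f[-1]
    x = (f - f_min) / (f_nyq - f_min) if f_nyq > f_min else np.zeros_like(f)
    total = m.sum(axis=1)
    safe = np.where(total < _ZERO_ENERGY_TOL, 1.0, total)
    g = (m * np.cos(2 * np.pi * x)).sum(axis=1) / safe
    s = (m * np.sin(2 * np.pi * x)).sum(axis=1) / safe
    zero = total < _ZERO_ENERGY_TOL
    g[zero] = 0.0
    s[zero] = 0.0
    return g, s


def dynamic_maps(stack: np.ndarray, mask: np.ndarray, frame_rate: float,
                 f_min: float = DEFAULT_F_MIN) -> DynamicMaps:
    """Compute g, s, beta and r^2 for every pixel where ``mask`` is nonzero.

    ``stack`` is ``(T, H, W)``; ``mask`` any integer/boolean image of the
    same spatial shape.  Unmasked pixels are NaN in every output map.
    """
    if stack.ndim != 3:
        raise ValueError("stack must be (T, H, W)")
    if mask.shape != stack.shape[1:]:
        raise ValueError("mask and stack are not congruent")
    sel = np.asarray(mask) > 0
    shape = stack.shape[1:]
    out = {k: np.full(shape, np.nan) for k in ("g", "s", "beta", "r2")}
    if sel.any():
        traces = stack[:, sel].T.astype(np.float64)
        freqs, mags = _batch_spectra(traces, frame_rate)
        beta, r2 = _batch_fit_power_law(freqs, mags, f_min)
        g, s = _batch_phasor(freqs, mags, f_min)
        out["g"][sel] = g
        out["s"][sel] = s
        out["beta"][sel] = beta
        out["r2"][sel] = r2
    return DynamicMaps(out["g"], out["s"], out["beta"], out["r2"], frame_rate, f_min)


def _pixel_entropy(values: np.ndarray, bins: int = 32) -> float:
    """Shannon entropy (bits) of a histogram of pixelwise values."""
    if values.size == 0:
        return float("nan")
    hist, _ = np.histogram(values, bins=bins)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def aggregate_cell_dynamics(maps: DynamicMaps, cell_mask: np.ndarray,
                            nucleus_mask: np.ndarray) -> dict:
    """Cellwise summary of the dynamic maps.

    Mean g, s, beta and g*s for the whole cell and for the nucleus and
    cytoplasm compartments, plus distribution summaries of the pixelwise
    values (skewness, histogram entropy) and box-counting texture of the
    thresholded g and s maps, used as dynamic features.  An empty nucleus
    sets the nuclear fields to NaN and ``nucleus_flag``.
    """
    from .features import box_counting_dimension

    cell = np.asarray(cell_mask) > 0
    nucleus = np.asarray(nucleus_mask) > 0
    if np.any(nucleus & ~cell):
        raise ValueError("nucleus mask must lie inside the cell mask")
    cyto = cell & ~nucleus
    out: dict = {"nucleus_flag": bool(nucleus.sum() == 0)}
    planes = {"g": maps.g, "s": maps.s, "beta": maps.beta, "gs": maps.gs}
    for comp_name, comp in (("cell", cell), ("nucleus", nucleus), ("cyto", cyto)):
        for name, plane in planes.items():
            vals = plane[comp]
            vals = vals[np.isfinite(vals)]
            out[f"{comp_name}_mean_{name}"] = float(vals.mean()) if vals.size else float("nan")
    def _skew(vals):
        if vals.size < 3 or vals.std() == 0:
            return 0.0 if vals.size else float("nan")
        return float(stats.skew(vals))

    beta_vals = maps.beta[cell]
    beta_vals = beta_vals[np.isfinite(beta_vals)]
    out["beta_skew"] = _skew(beta_vals)
    out["beta_entropy"] = _pixel_entropy(beta_vals)
    for name in ("g", "s"):
        plane = planes[name]
        vals = plane[cell]
        finite = vals[np.isfinite(vals)]
        out[f"{name}_skew"] = _skew(finite)
        out[f"{name}_entropy"] = _pixel_entropy(finite)
        if finite.size:
            thresh = np.nanmedian(finite)
            binary = np.zeros_like(cell)
            binary[cell] = np.where(np.isfinite(vals), vals > thresh, False)
            out[f"{name}_fractal"] = box_counting_dimension(binary)
        else:
            out[f"{name}_fractal"] = float("nan")
    return out


def compare_groups(values_a, values_b):
    """Two-sample equal-variance Student's t test (two-sided).

    Returns ``(t, p)``; two identical zero-variance groups give (0, 1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


_BLUE = np.array([0.0, 0.0, 1.0])
_RED = np.array([1.0, 0.0, 0.0])


def pseudocolor(map_: np.ndarray, value_range=(1.0, 2.0),
                mask: np.ndarray | None = None) -> np.ndarray:
    """Linear blue-to-red pseudo-colorization of an activity map.

    Blue encodes low activity and red high activity; values outside
    ``value_range`` are clipped, NaN or unmasked pixels render black.
    Default range [1, 2] matches the displayed span of the power-law slope.
    """
    lo, hi = value_range
    if not hi > lo:
        raise ValueError("degenerate value_range")
    frac = np.clip((np.asarray(map_, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    valid = np.isfinite(frac)
    if mask is not None:
        valid &= np.asarray(mask) > 0
    frac = np.where(valid, frac, 0.0)
    rgb = (1.0 - frac[..., None]) * _BLUE + frac[..., None] * _RED
    rgb[~valid] = 0.0
    return rgb


class LineProfile(NamedTuple):
    profile: np.ndarray
    short_flag: bool  # cell shorter than the 10-row window


def line_profile(map_: np.ndarray, cell_mask: np.ndarray, n_rows: int = 10) -> LineProfile:
    """Mean activity over the central horizontal rows of a cell.

    Averages over the ``n_rows`` rows bracketing the centroid row,
    restricted to mask pixels, over the cell's bounding-box columns.
    Cells shorter than ``n_rows`` use every available row and set
    ``short_flag``.
    """
    cell = np.asarray(cell_mask) > 0
    if not cell.any():
        raise ValueError("empty cell mask")
    rows_idx, cols_idx = np.nonzero(cell)
    r0, r1 = rows_idx.min(), rows_idx.max()
    c0, c1 = cols_idx.min(), cols_idx.max()
    height = r1 - r0 + 1
    short = height < n_rows
    centroid = int(round(rows_idx.mean()))
    half = n_rows // 2
    lo = max(r0, centroid - half)
    hi = min(r1 + 1, lo + n_rows)
    lo = max(r0, hi - n_rows)
    band = np.asarray(map_, dtype=float)[lo:hi, c0:c1 + 1].copy()
    band[~cell[lo:hi, c0:c1 + 1]] = np.nan
    with np.errstate(invalid="ignore"):
        profile = np.nanmean(band, axis=0)
    return LineProfile(profile, short)


def truncate_stack(stack: np.ndarray, n_frames: int) -> np.ndarray:
    """Keep the first ``n_frames`` frames (shorter-acquisition emulation)."""
    if n_frames < 8:
        raise ValueError("n_frames must be >= 8")
    if n_frames > stack.shape[0]:
        raise ValueError("n_frames exceeds stack length")
    return stack[:n_frames]


def degrade_resolution(stack: np.ndarray, factor: int = 2):
    """Blur and downsample each frame by ``factor`` (resolution degradation).

    Gaussian blur with sigma = factor/2 px, then subsampling every
    ``factor`` pixels; emulates halving the lateral resolution.  Returns
    the degraded stack; callers should scale pixel_size by ``factor``.
    """
    from scipy.ndimage import gaussian_filter

    if int(factor) != factor or factor < 2:
        raise ValueError("factor must be an integer >= 2")
    factor = int(factor)
    if stack.shape[1] // factor < 16 or stack.shape[2] // factor < 16:
        raise ValueError("degraded frame would be smaller than 16 px")
    blurred = gaussian_filter(stack.astype(np.float64), sigma=(0.0, factor / 2.0, factor / 2.0))
    return blurred[:, ::factor, ::factor]
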