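"""Synthetic deep-UV scene and time-series generation with known ground truth.

Emulates the statistical structure of label-free deep-UV (255 nm) T cell
imaging: static scenes containing activated, quiescent and dead phenotypes,
and dynamic image stacks in which per-pixel attenuation traces follow
power-law magnitude spectra ``I(f) ~ f**-beta``.  The generator is the
ground-truth source for every downstream operator (segmentation, feature
extraction, frequency analysis, classification), so each cell carries an
explicit specification of its geometry, compartment attenuations and
compartment dynamic parameters.

Attenuation is unitless in [0, 1]; 255 nm targets nucleic acids, so nuclei
are drawn with higher attenuation than cytoplasm.  Dynamic defaults place
both subtypes inside the displayed [1, 2] slope range with the CD4-like
cytoplasm more active (higher beta, 1.5x amplitude) and the nuclei of both
subtypes identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLASSES = ("activated", "quiescent", "dead", "cd4", "cd8")

#: per-class geometry and attenuation defaults (pixels / unitless attenuation)
CLASS_PARAMS = {
    #               radius  nuc_frac  nuc_att  cyto_att  texture  boundary_irregularity
    "activated": dict(radius=16.0, radius_sd=1.5, nucleus_frac=0.58, nucleus_att=0.75,
                      cyto_att=0.45, texture=0.35, irregularity=0.04),
    "quiescent": dict(radius=9.0, radius_sd=0.8, nucleus_frac=0.62, nucleus_att=0.65,
                      cyto_att=0.35, texture=0.08, irregularity=0.03),
    "dead":      dict(radius=11.0, radius_sd=1.5, nucleus_frac=0.50, nucleus_att=0.50,
                      cyto_att=0.15, texture=0.15, irregularity=0.10),
    "cd4":       dict(radius=14.0, radius_sd=1.2, nucleus_frac=0.58, nucleus_att=0.72,
                      cyto_att=0.42, texture=0.25, irregularity=0.04),
    "cd8":       dict(radius=14.0, radius_sd=1.2, nucleus_frac=0.58, nucleus_att=0.72,
                      cyto_att=0.42, texture=0.25, irregularity=0.04),
}

#: compartment dynamic defaults: spectral exponent beta and fluctuation
#: amplitude (std of the attenuation fluctuation).  CD4-like cytoplasm is
#: assigned higher beta and 1.5x the amplitude of CD8-like cytoplasm; the
#: nuclei of both subtypes share identical parameters.
DYNAMIC_PARAMS = {
    "cd4": dict(beta_cyto=1.7, amp_cyto=0.0375, beta_nuc=1.15, amp_nuc=0.015),
    "cd8": dict(beta_cyto=1.3, amp_cyto=0.025, beta_nuc=1.15, amp_nuc=0.015),
    # static phenotypes get mild, subtype-neutral dynamics if a stack is rendered
    "activated": dict(beta_cyto=1.5, amp_cyto=0.03, beta_nuc=1.15, amp_nuc=0.015),
    "quiescent": dict(beta_cyto=1.2, amp_cyto=0.015, beta_nuc=1.1, amp_nuc=0.01),
    "dead": dict(beta_cyto=0.5, amp_cyto=0.004, beta_nuc=0.5, amp_nuc=0.004),
}

BACKGROUND_ATTENUATION = 0.02
#: white detector noise on rendered stacks.  Must sit well below the
#: f**-beta magnitudes across the fitted band (its flat DFT floor is
#: ~sd*sqrt(n_frames) per bin) or the power-law structure is masked; 2e-5
#: leaves fitted beta unbiased at the default fluctuation amplitudes.
DETECTOR_NOISE_SD = 2e-5


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of one synthetic field of view.

    ``class_mix`` gives proportions over the five phenotypes; they must sum
    to 1.  ``frame_rate``/``n_frames`` follow the stated acquisition
    (~8 Hz over 500 frames).
    """

    image_height: int = 256
    image_width: int = 256
    pixel_size: float = 0.3  # micrometres per pixel
    n_cells: int = 10
    class_mix: dict = field(default_factory=lambda: {"activated": 0.4, "quiescent": 0.4, "dead": 0.2})
    seed: int = 0
    frame_rate: float = 8.0  # Hz
    n_frames: int = 500

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix proportions must sum to 1, got {total}")
        unknown = set(self.class_mix) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in class_mix: {sorted(unknown)}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        return cls(**d)


@dataclass
class GroundTruth:
    """Label mask, nucleus mask and per-cell specification table.

    ``label_mask``: int array, 0 background, k>0 cell k.  ``nucleus_mask``
    carries the same labels restricted to nuclear pixels.  ``cells`` has one
    row per cell: center, radii, compartment attenuations, class label and
    compartment dynamic parameters.
    """

    label_mask: np.ndarray
    nucleus_mask: np.ndarray
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        if np.any((self.nucleus_mask > 0) & (self.nucleus_mask != self.label_mask)):
            raise ValueError("nucleus mask must be a subset of the cell mask")


class PlacementError(RuntimeError):
    """Raised when non-overlapping cell placement fails (density limit)."""


def _irregular_disc(shape, center, radius, irregularity, rng, n_modes=6):
    """Boolean mask of a disc with sinusoidal radial boundary perturbation."""
    h, w = shape
    cy, cx = center
    pad = int(np.ceil(radius * (1 + irregularity * n_modes))) + 2
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r_bound = np.full_like(theta, radius)
    if irregularity > 0:
        amps = rng.normal(0.0, irregularity * radius, size=n_modes)
        phases = rng.uniform(0, 2 * np.pi, size=n_modes)
        for k in range(n_modes):
            r_bound = r_bound + amps[k] * np.cos((k + 2) * theta + phases[k])
    inside = r <= r_bound
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = inside
    return mask


def _smooth_noise(shape, rng, sigma=2.0):
    """Unit-std spatially smoothed Gaussian field (simple texture source)."""
    from scipy.ndimage import gaussian_filter

    g = gaussian_filter(rng.standard_normal(shape), sigma)
    sd = g.std()
    return g / sd if sd > 0 else g


def make_scene(config: SceneConfig):
    """Render a static attenuation frame plus ground truth.

    Cells are placed by rejection sampling with a bounded retry budget;
    activated cells are larger with stronger internal texture than quiescent
    ones, and dead cells have a distinct (lower) mean attenuation and an
    irregular boundary.  Returns ``(frame, GroundTruth)`` with ``frame`` in
    [0, 1] attenuation units (noise-free; detector noise is added by
    :func:`render_stack`).
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height, config.image_width
    frame = np.full((h, w), BACKGROUND_ATTENUATION, dtype=np.float64)
    label_mask = np.zeros((h, w), dtype=np.int32)
    nucleus_mask = np.zeros((h, w), dtype=np.int32)

    # assign classes from the mix (deterministic counts via multinomial)
    names = sorted(config.class_mix)
    probs = np.array([config.class_mix[n] for n in names])
    counts = rng.multinomial(config.n_cells, probs)
    classes = [n for n, c in zip(names, counts) for _ in range(c)]
    rng.shuffle(classes)

    rows = []
    margin = 4
    max_tries = 200
    for idx, cls in enumerate(classes, start=1):
        p = CLASS_PARAMS[cls]
        radius = max(4.0, rng.normal(p["radius"], p["radius_sd"]))
        placed = False
        for _ in range(max_tries):
            cy = rng.uniform(radius + margin, h - radius - margin)
            cx = rng.uniform(radius + margin, w - radius - margin)
            cell = _irregular_disc((h, w), (cy, cx), radius, p["irregularity"], rng)
            # require clear separation from existing cells
            from scipy.ndimage import binary_dilation

            if not (binary_dilation(cell, iterations=3) & (label_mask > 0)).any():
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cell {idx} ({cls}) without overlap after "
                f"{max_tries} tries; scene density limit reached for "
                f"{config.n_cells} cells in {h}x{w}"
            )
        nuc_radius = radius * p["nucleus_frac"]
        nucleus = _irregular_disc((h, w), (cy, cx), nuc_radius, 0.0, rng) & cell

        label_mask[cell] = idx
        nucleus_mask[nucleus] = idx
        cyto = cell & ~nucleus
        frame[cyto] = p["cyto_att"]
        frame[nucleus] = p["nucleus_att"]
        if p["texture"] > 0:
            tex = _smooth_noise((h, w), rng, sigma=1.5)
            frame[cyto] *= 1.0 + p["texture"] * tex[cyto]
            frame[nucleus] *= 1.0 + 0.5 * p["texture"] * tex[nucleus]

        dyn = DYNAMIC_PARAMS[cls]
        rows.append(
            dict(
                cell_id=idx, label=cls, center_y=cy, center_x=cx,
                cell_radius=radius, nucleus_radius=nuc_radius,
                nucleus_attenuation=p["nucleus_att"], cyto_attenuation=p["cyto_att"],
                beta_cyto=dyn["beta_cyto"], amp_cyto=dyn["amp_cyto"],
                beta_nuc=dyn["beta_nuc"], amp_nuc=dyn["amp_nuc"],
            )
        )

    np.clip(frame, 0.0, 1.0, out=frame)
    columns = ["cell_id", "label", "center_y", "center_x", "cell_radius",
               "nucleus_radius", "nucleus_attenuation", "cyto_attenuation",
               "beta_cyto", "amp_cyto", "beta_nuc", "amp_nuc"]
    cells = pd.DataFrame(rows, columns=columns)
    return frame, GroundTruth(label_mask, nucleus_mask, cells)


def synth_trace(beta: float, amplitude: float, n: int, frame_rate: float,
                rng=None, baseline: float = 0.0) -> np.ndarray:
    """Synthesize a 1-D time series with power-law magnitude spectrum.

    The discrete Fourier magnitudes of the (mean-subtracted) trace are
    proportional to ``f**-beta`` at the positive frequencies, with
    independent uniform random phases; the fluctuation standard deviation is
    scaled to ``amplitude`` and ``baseline`` is added.  With ``beta=0`` the
    fluctuation is white; with ``amplitude=0`` the trace is constant.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if n < 8:
        raise ValueError("n must be >= 8")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if amplitude == 0.0:
        return np.full(n, baseline, dtype=np.float64)

    freqs = np.fft.rfftfreq(n, d=1.0 / frame_rate)
    mags = np.zeros_like(freqs)
    mags[1:] = freqs[1:] ** (-beta)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    spectrum = mags * np.exp(1j * phases)
    spectrum[0] = 0.0
    if n % 2 == 0:
        # Nyquist bin must be real for a real-valued signal
        spectrum[-1] = mags[-1] * np.sign(np.cos(phases[-1]))
    trace = np.fft.irfft(spectrum, n=n)
    sd = trace.std()
    if sd > 0:
        trace *= amplitude / sd
    return trace + baseline


def synth_traces(beta, amplitude: float, n: int, frame_rate: float,
                 n_traces: int, rng, baseline: float = 0.0) -> np.ndarray:
    """Vectorized batch of :func:`synth_trace`; returns ``(n_traces, n)``.

    ``beta`` may be a scalar (shared exponent) or an array of length
    ``n_traces`` (one exponent per trace).
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0) or amplitude < 0:
        raise ValueError("beta and amplitude must be >= 0")
    if n < 8:
        raise ValueError("n must be >= 8")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if amplitude == 0.0:
        return np.full((n_traces, n), baseline, dtype=np.float64)
    freqs = np.fft.rfftfreq(n, d=1.0 / frame_rate)
    mags = np.zeros((n_traces, freqs.size))
    mags[:, 1:] = freqs[None, 1:] ** (-np.broadcast_to(beta, (n_traces,))[:, None])
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_traces, freqs.size))
    spectrum = mags * np.exp(1j * phases)
    spectrum[:, 0] = 0.0
    if n % 2 == 0:
        spectrum[:, -1] = mags[:, -1] * np.sign(np.cos(phases[:, -1]))
    traces = np.fft.irfft(spectrum, n=n, axis=1)
    sd = traces.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    traces *= amplitude / sd
    return traces + baseline


def render_stack(config: SceneConfig, frame: np.ndarray, truth: GroundTruth,
                 noise_sd: float = DETECTOR_NOISE_SD,
                 beta_pixel_sd: float = 0.08) -> np.ndarray:
    """Render a ``(n_frames, H, W)`` dynamic stack from a static scene.

    Each masked pixel receives an independent power-law fluctuation with
    exponent drawn around its compartment's beta (``beta_pixel_sd``
    heterogeneity, clipped to [0, 3], giving pixelwise slope histograms a
    realistic spread) and the compartment's amplitude, around the static
    frame value; background pixels are static.  White detector noise of
    ``noise_sd`` is added to every pixel of every frame, so frame 0 equals
    the static frame plus noise.
    """
    if frame.shape != truth.label_mask.shape:
        raise ValueError("frame and ground-truth mask shapes differ")
    t = config.n_frames
    if t < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 917]))
    stack = np.repeat(frame[None, :, :].astype(np.float32), t, axis=0)

    for row in truth.cells.itertuples():
        cell = truth.label_mask == row.cell_id
        nucleus = truth.nucleus_mask == row.cell_id
        for comp_mask, beta, amp in (
            (cell & ~nucleus, row.beta_cyto, row.amp_cyto),
            (nucleus, row.beta_nuc, row.amp_nuc),
        ):
            n_pix = int(comp_mask.sum())
            if n_pix == 0 or amp == 0:
                continue
            betas = np.clip(rng.normal(beta, beta_pixel_sd, size=n_pix), 0.0, 3.0) \
                if beta_pixel_sd > 0 else beta
            fluct = synth_traces(betas, amp, t, config.frame_rate, n_pix, rng)
            stack[:, comp_mask] += fluct.T.astype(np.float32)

    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, size=stack.shape).astype(np.float32)
    np.clip(stack, 0.0, 1.0, out=stack)
    return stack


def make_stack(config: SceneConfig, noise_sd: float = DETECTOR_NOISE_SD):
    """Convenience: scene + stack in one call; returns (stack, frame, truth)."""
    frame, truth = make_scene(config)
    stack = render_stack(config, frame, truth, noise_sd=noise_sd)
    return stack, frame, truth
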