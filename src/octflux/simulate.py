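"""Synthetic OCT capillary time-trace simulator.

A red blood cell (RBC) passing through an OCT voxel produces a transient
intensity peak.  A trace of duration ``T`` at flux ``F`` (RBC/s) therefore
contains ``N = round(F * T)`` Gaussian pulses whose heights, widths and
spacings follow a hierarchical statistical model:

* the per-trace *mean* peak height is beta-distributed around a
  flux-dependent mean (high-flux traces have smaller peaks),
* individual heights within a trace are beta-distributed around that mean,
* widths follow the analogous two-level gamma model (high flux implies
  faster RBCs, hence narrower pulses),
* inter-peak gaps are gamma-distributed with mean ``1/F`` and a
  coefficient of variation that exceeds the Poisson (exponential) value of
  1 at low flux and approaches it at high flux.

On top of the clean pulse train the simulator adds coherent speckle noise
(``I = S + |N|^2 + 2 S |N| cos(phi)`` with ``N`` a zero-mean complex
circular Gaussian) and a slow sinusoidal baseline from static scattering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateTraceError, InfeasibleRecipeError

__all__ = [
    "TimeTrace",
    "TraceRecipe",
    "HierarchicalDistConfig",
    "TraceDataset",
    "sample_trace_recipe",
    "render_clean_trace",
    "add_speckle_noise",
    "add_slow_component",
    "normalize_trace",
    "synthesize_trace",
    "generate_dataset",
]

#: FWHM of a Gaussian = _FWHM_FACTOR * sigma
_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

DEFAULT_DT = 1.5e-3  # s, per-sample interval of repeated B-scans
DEFAULT_N_SAMPLES = 512
DEFAULT_T = DEFAULT_DT * DEFAULT_N_SAMPLES  # 0.768 s


@dataclass(frozen=True)
class TimeTrace:
    """A 1D intensity record sampled at fixed ``dt``."""

    samples: np.ndarray
    dt: float
    normalized: bool = False

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("trace must be a 1D array with at least 2 samples")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


@dataclass(frozen=True)
class TraceRecipe:
    """Latent ground truth of one simulated trace.

    ``flux_label`` is always ``n_peaks / duration`` exactly, so the label is
    self-consistent with the rendered content rather than with the flux that
    was originally requested.
    """

    flux_label: float
    peak_times: np.ndarray  # s, strictly increasing, within [0, T)
    peak_heights: np.ndarray  # normalized intensity in (0, 1]
    peak_fwhms: np.ndarray  # s
    noise_amplitude: float  # per-component std of the complex noise field
    sine_freq: float  # Hz
    sine_amp: float
    sine_phase: float  # rad
    duration: float  # s
    dt: float  # s

    def __post_init__(self):
        for name in ("peak_times", "peak_heights", "peak_fwhms"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        n = self.peak_times.size
        if self.peak_heights.size != n or self.peak_fwhms.size != n:
            raise ValueError("peak arrays must have equal length")
        if n != round(self.flux_label * self.duration):
            raise ValueError("peak count inconsistent with flux label")
        if n:
            if np.any(np.diff(self.peak_times) <= 0):
                raise ValueError("peak times must be strictly increasing")
            if self.peak_times[0] < 0 or self.peak_times[-1] >= self.duration:
                raise ValueError("peak times must lie in [0, T)")
            if np.any(self.peak_heights <= 0) or np.any(self.peak_heights > 1):
                raise ValueError("peak heights must lie in (0, 1]")
            if np.any(self.peak_fwhms <= 0):
                raise ValueError("peak widths must be positive")
        if self.noise_amplitude < 0:
            raise ValueError("noise amplitude must be non-negative")

    @property
    def n_peaks(self) -> int:
        return int(self.peak_times.size)


@dataclass(frozen=True)
class HierarchicalDistConfig:
    """Flux-conditional parameters of the hierarchical trace model.

    Defaults encode the qualitative trends of experimental OCT capillary
    data: mean peak height and mean width decrease with flux, the spread of
    the mean width shrinks with flux, inter-peak times are overdispersed
    relative to a Poisson process at low flux, and both speckle-noise
    amplitude and the prevalence of a slow sinusoidal baseline are
    flux-dependent.
    """

    # mean peak height declines linearly with flux between these anchors
    height_mean_lo_flux: float = 10.0
    height_mean_hi_flux: float = 120.0
    height_mean_at_lo: float = 0.95
    height_mean_at_hi: float = 0.55
    height_mean_concentration: float = 20.0  # beta concentration of trace means
    height_within_concentration: float = 10.0  # beta concentration within a trace
    # per-trace mean FWHM ~ gamma(shape, mean = clip(duty/flux, floor, cap)):
    # the pulse width tracks the RBC transit time, so width x flux — the
    # fraction of time the voxel is occupied — stays roughly constant and
    # pulses remain resolvable at high flux
    width_mean_floor: float = 4e-3  # s
    width_mean_cap: float = 50e-3  # s
    width_duty: float = 0.45  # mean FWHM x flux (dimensionless occupancy)
    width_mean_shape: float = 9.0
    width_within_shape: float = 16.0  # gamma shape of widths within a trace
    # inter-peak gap CV: c(f) = 1 + cv_excess / (1 + f / cv_flux_scale)
    interpeak_cv_excess: float = 1.0
    interpeak_cv_flux_scale: float = 30.0  # RBC/s
    # optional uniform sampling of per-trace means (rare-instance balancing)
    uniform_mean_sampling: bool = False
    height_mean_range: tuple[float, float] = (0.3, 0.98)
    width_mean_range: tuple[float, float] = (4e-3, 40e-3)  # s
    # flux-conditional speckle-noise amplitude ranges
    noise_low_flux_edge: float = 15.0  # RBC/s
    noise_high_flux_edge: float = 100.0  # RBC/s
    noise_range_low: tuple[float, float] = (0.02, 0.1)
    noise_range_mid: tuple[float, float] = (0.05, 0.6)
    noise_range_high: tuple[float, float] = (0.3, 1.0)
    # slow sinusoidal baseline: always present below the low-flux edge
    # (centered on 1.5 Hz / 0.3 amplitude), otherwise present with
    # probability `sine_prob` over broad uniform ranges
    sine_low_flux_freq_range: tuple[float, float] = (0.5, 2.5)  # Hz
    sine_low_flux_amp_range: tuple[float, float] = (0.2, 0.4)
    sine_freq_range: tuple[float, float] = (0.0, 16.0)  # Hz
    sine_amp_range: tuple[float, float] = (0.0, 0.5)
    sine_prob: float = 0.5
    # speckle model: cross term as printed in the heterodyne intensity
    # expansion ("printed": 2*S*|N|*cos phi) or with sqrt(S) ("sqrt")
    noise_cross_term: str = "printed"
    # flux categories used only for balanced dataset generation
    category_edges: tuple[float, ...] = tuple(float(x) for x in range(0, 130, 10))

    def __post_init__(self):
        if self.noise_cross_term not in ("printed", "sqrt"):
            raise ValueError("noise_cross_term must be 'printed' or 'sqrt'")
        edges = np.asarray(self.category_edges, dtype=float)
        if edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("category edges must be strictly increasing")
        for v in (
            self.height_mean_concentration,
            self.height_within_concentration,
            self.width_mean_shape,
            self.width_within_shape,
        ):
            if v <= 0:
                raise ValueError("distribution parameters must be strictly positive")

    # -- flux-conditional laws -------------------------------------------------
    def mean_height(self, flux: float) -> float:
        f0, f1 = self.height_mean_lo_flux, self.height_mean_hi_flux
        h0, h1 = self.height_mean_at_lo, self.height_mean_at_hi
        t = np.clip((flux - f0) / (f1 - f0), 0.0, 1.0)
        return float(h0 + (h1 - h0) * t)

    def mean_width(self, flux: float) -> float:
        if flux <= 0:
            return self.width_mean_cap
        return float(np.clip(self.width_duty / flux, self.width_mean_floor,
                             self.width_mean_cap))

    def interpeak_cv(self, flux: float) -> float:
        return float(1.0 + self.interpeak_cv_excess / (1.0 + flux / self.interpeak_cv_flux_scale))

    def noise_range(self, flux: float) -> tuple[float, float]:
        if flux < self.noise_low_flux_edge:
            return self.noise_range_low
        if flux <= self.noise_high_flux_edge:
            return self.noise_range_mid
        return self.noise_range_high


def _sample_beta_mean_conc(rng: np.random.Generator, mean: float, conc: float, size=None):
    """Beta draw parameterized by mean in (0,1) and concentration alpha+beta."""
    mean = float(np.clip(mean, 1e-3, 1.0 - 1e-3))
    a = mean * conc
    b = (1.0 - mean) * conc
    return rng.beta(a, b, size=size)


def sample_interpeak_gaps(
    flux: float, n: int, config: HierarchicalDistConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` inter-peak gaps with mean ``1/flux`` and CV ``c(flux)``.

    Gamma-distributed: shape ``1/c^2``, scale ``c^2/flux``.  At high flux the
    CV tends to 1 and the gaps become exponential (Poisson process); at low
    flux the gaps are overdispersed.
    """
    if flux <= 0:
        raise ValueError("flux must be positive to sample gaps")
    cv = config.interpeak_cv(flux)
    shape = 1.0 / cv**2
    scale = cv**2 / flux
    gaps = rng.gamma(shape, scale, size=n)
    return np.maximum(gaps, 1e-9)


def sample_trace_recipe(
    flux: float,
    config: HierarchicalDistConfig | None = None,
    rng: np.random.Generator | None = None,
    duration: float = DEFAULT_T,
    dt: float = DEFAULT_DT,
) -> TraceRecipe:
    """Draw the latent parameters of one simulated trace at the given flux.

    The number of peaks is ``N = round(flux * duration)`` and the recorded
    label is the exact ``N / duration``.  Raises
    :class:`~octflux.errors.InfeasibleRecipeError` when N pulses of at least
    the minimal resolvable width cannot fit in the window.
    """
    if flux < 0:
        raise ValueError("flux must be non-negative")
    config = config or HierarchicalDistConfig()
    rng = rng if rng is not None else np.random.default_rng()

    n = int(round(flux * duration))
    label = n / duration
    min_width = 2.0 * dt
    if n * min_width > duration:
        raise InfeasibleRecipeError(
            f"{n} peaks of minimal width {min_width:g}s exceed window {duration:g}s"
        )

    noise_lo, noise_hi = config.noise_range(label)
    noise_amplitude = float(rng.uniform(noise_lo, noise_hi))

    if label < config.noise_low_flux_edge:
        sine_freq = float(rng.uniform(*config.sine_low_flux_freq_range))
        sine_amp = float(rng.uniform(*config.sine_low_flux_amp_range))
    elif rng.uniform() < config.sine_prob:
        sine_freq = float(rng.uniform(*config.sine_freq_range))
        sine_amp = float(rng.uniform(*config.sine_amp_range))
    else:
        sine_freq, sine_amp = 0.0, 0.0
    sine_phase = float(rng.uniform(0.0, 2.0 * np.pi))

    if n == 0:
        empty = np.empty(0)
        return TraceRecipe(
            flux_label=label,
            peak_times=empty,
            peak_heights=empty.copy(),
            peak_fwhms=empty.copy(),
            noise_amplitude=noise_amplitude,
            sine_freq=sine_freq,
            sine_amp=sine_amp,
            sine_phase=sine_phase,
            duration=duration,
            dt=dt,
        )

    # hierarchical heights: trace mean, then per-peak draws around it
    if config.uniform_mean_sampling:
        mean_h = float(rng.uniform(*config.height_mean_range))
    else:
        mean_h = float(
            _sample_beta_mean_conc(rng, config.mean_height(label), config.height_mean_concentration)
        )
    heights = _sample_beta_mean_conc(rng, mean_h, config.height_within_concentration, size=n)
    heights = np.clip(heights, 1e-3, 1.0)

    # hierarchical widths: gamma trace mean, gamma within trace
    if config.uniform_mean_sampling:
        mean_w = float(rng.uniform(*config.width_mean_range))
    else:
        mu_w = config.mean_width(label)
        mean_w = float(rng.gamma(config.width_mean_shape, mu_w / config.width_mean_shape))
    k_w = config.width_within_shape
    fwhms = rng.gamma(k_w, max(mean_w, min_width) / k_w, size=n)
    fwhms = np.maximum(fwhms, min_width)

    # gamma gaps with mean 1/flux, rescaled so all N peaks fit in [0, T)
    gaps = sample_interpeak_gaps(label, n + 1, config, rng)
    positions = np.cumsum(gaps[:n])
    span = positions[-1] + gaps[n]  # leave a trailing gap before the window edge
    times = positions / span * duration
    times = np.sort(times)
    # enforce strict increase at machine resolution
    for i in range(1, n):
        if times[i] <= times[i - 1]:
            times[i] = np.nextafter(times[i - 1], np.inf)
    times = np.clip(times, 0.0, np.nextafter(duration, 0.0))

    return TraceRecipe(
        flux_label=label,
        peak_times=times,
        peak_heights=heights,
        peak_fwhms=fwhms,
        noise_amplitude=noise_amplitude,
        sine_freq=sine_freq,
        sine_amp=sine_amp,
        sine_phase=sine_phase,
        duration=duration,
        dt=dt,
    )


def render_clean_trace(
    recipe: TraceRecipe, n_samples: int | None = None, dt: float | None = None
) -> TimeTrace:
    """Render the noiseless pulse train: a sum of Gaussian pulses on a zero baseline."""
    dt = recipe.dt if dt is None else dt
    if n_samples is None:
        n_samples = int(round(recipe.duration / dt))
    if abs(n_samples * dt - recipe.duration) > 0.5 * dt:
        raise ValueError(
            f"n_samples*dt = {n_samples * dt:g}s does not match recipe duration {recipe.duration:g}s"
        )
    t = np.arange(n_samples) * dt
    y = np.zeros(n_samples)
    for t_i, h_i, w_i in zip(recipe.peak_times, recipe.peak_heights, recipe.peak_fwhms):
        sigma = w_i / _FWHM_FACTOR
        y += h_i * np.exp(-((t - t_i) ** 2) / (2.0 * sigma**2))
    return TimeTrace(y, dt=dt, normalized=False)


def add_speckle_noise(
    trace: TimeTrace,
    noise_amplitude: float,
    rng: np.random.Generator | None = None,
    cross_term: str = "printed",
    modulus_mode: str = "per_sample",
) -> TimeTrace:
    """Corrupt a non-negative signal S with coherent speckle noise.

    Per sample, ``I = S + |N|^2 + 2*S*|N|*cos(phi)`` where ``N`` is a
    zero-mean complex circular Gaussian with per-component standard
    deviation ``noise_amplitude`` and ``phi ~ Uniform[0, 2pi)``, independent
    across samples.  ``cross_term="sqrt"`` replaces ``2*S*|N|`` by the
    heterodyne form ``2*sqrt(S)*|N|``.

    ``modulus_mode`` controls the temporal correlation of the speckle
    modulus: ``"per_sample"`` (default) draws an independent ``|N|`` for
    every sample — a speckle field that decorrelates faster than the
    sampling interval — while ``"per_trace"`` draws a single ``|N|``
    realization for the whole record, the fully-coherent limit in which
    only the relative phase varies between samples.  With amplitude 0 the
    input is returned bit-for-bit.
    """
    if noise_amplitude < 0:
        raise ValueError("noise amplitude must be non-negative")
    if cross_term not in ("printed", "sqrt"):
        raise ValueError("cross_term must be 'printed' or 'sqrt'")
    if modulus_mode not in ("per_sample", "per_trace"):
        raise ValueError("modulus_mode must be 'per_sample' or 'per_trace'")
    if noise_amplitude == 0:
        return trace
    rng = rng if rng is not None else np.random.default_rng()
    s = trace.samples
    size = s.size if modulus_mode == "per_sample" else 1
    n_mod = noise_amplitude * np.hypot(
        rng.standard_normal(size), rng.standard_normal(size)
    )
    phi = rng.uniform(0.0, 2.0 * np.pi, size=s.size)
    sig = s if cross_term == "printed" else np.sqrt(np.maximum(s, 0.0))
    i = s + n_mod**2 + 2.0 * sig * n_mod * np.cos(phi)
    return TimeTrace(i, dt=trace.dt, normalized=False)


def add_slow_component(
    trace: TimeTrace, freq: float, amplitude: float, phase: float = 0.0
) -> TimeTrace:
    """Add the static-scattering baseline ``amplitude * sin(2 pi freq t + phase)``."""
    if freq < 0 or amplitude < 0:
        raise ValueError("frequency and amplitude must be non-negative")
    if amplitude == 0:
        return trace
    y = trace.samples + amplitude * np.sin(2.0 * np.pi * freq * trace.times + phase)
    return TimeTrace(y, dt=trace.dt, normalized=False)


def normalize_trace(trace: TimeTrace, robust: bool = True) -> TimeTrace:
    """Affinely rescale a trace to [0, 1].

    Robust mode (default) uses the 1st/99th percentiles as the 0/1
    references and clips, so isolated speckle spikes do not compress the
    rest of the trace.  Already-normalized traces are returned unchanged
    (idempotence).  Constant traces raise
    :class:`~octflux.errors.DegenerateTraceError`.
    """
    if trace.normalized:
        return trace
    y = trace.samples
    if robust:
        lo, hi = np.percentile(y, [1.0, 99.0])
    else:
        lo, hi = float(np.min(y)), float(np.max(y))
    if hi - lo < 1e-12:
        raise DegenerateTraceError("cannot normalize a constant trace")
    z = np.clip((y - lo) / (hi - lo), 0.0, 1.0)
    return TimeTrace(z, dt=trace.dt, normalized=True)


def synthesize_trace(
    recipe: TraceRecipe,
    n_samples: int,
    rng: np.random.Generator,
    config: HierarchicalDistConfig | None = None,
) -> TimeTrace:
    """Full pipeline: render pulses, add speckle noise, add the slow sine, normalize."""
    config = config or HierarchicalDistConfig()
    trace = render_clean_trace(recipe, n_samples=n_samples)
    trace = add_speckle_noise(
        trace, recipe.noise_amplitude, rng=rng, cross_term=config.noise_cross_term
    )
    trace = add_slow_component(trace, recipe.sine_freq, recipe.sine_amp, recipe.sine_phase)
    return normalize_trace(trace)


@dataclass
class TraceDataset:
    """A labeled collection of simulated traces with their generating recipes."""

    traces: np.ndarray  # (n_traces, n_samples) float32, normalized
    labels: np.ndarray  # (n_traces,) RBC/s
    recipes: list[TraceRecipe] = field(repr=False)
    dt: float = DEFAULT_DT
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.traces.shape[0])

    @property
    def duration(self) -> float:
        return self.traces.shape[1] * self.dt


def _category_peak_count_range(lo: float, hi: float, duration: float) -> tuple[int, int]:
    """Integer peak counts N whose exact label N/duration falls in [lo, hi)."""
    n_lo = int(np.ceil(lo * duration - 1e-9))
    n_hi = int(np.ceil(hi * duration - 1e-9)) - 1
    return n_lo, max(n_hi, n_lo)


def generate_dataset(
    config: HierarchicalDistConfig | None = None,
    per_category: int = 100,
    n_samples: int = DEFAULT_N_SAMPLES,
    dt: float = DEFAULT_DT,
    rng: np.random.Generator | int | None = None,
    max_retries: int = 20,
) -> TraceDataset:
    """Generate a flux-category-balanced labeled dataset.

    For each flux category (config bin edges) the peak count N is drawn
    uniformly over the integers whose exact label ``N/T`` falls inside the
    bin, guaranteeing every stored label lies within its category.  Each
    trace gets an independent substream derived from the top-level seed, so
    identical seeds reproduce identical datasets.
    """
    if per_category < 1:
        raise ValueError("per_category must be >= 1")
    config = config or HierarchicalDistConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    duration = n_samples * dt
    edges = np.asarray(config.category_edges, dtype=float)

    traces, labels, recipes = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        n_lo, n_hi = _category_peak_count_range(lo, hi, duration)
        for _ in range(per_category):
            sub = np.random.default_rng(rng.integers(0, 2**63 - 1))
            recipe = None
            for _attempt in range(max_retries):
                n_peaks = int(sub.integers(n_lo, n_hi + 1))
                try:
                    recipe = sample_trace_recipe(
                        n_peaks / duration, config=config, rng=sub, duration=duration, dt=dt
                    )
                    break
                except InfeasibleRecipeError:
                    continue
            if recipe is None:
                raise InfeasibleRecipeError(
                    f"could not sample a feasible recipe in category [{lo}, {hi}) "
                    f"after {max_retries} attempts"
                )
            trace = synthesize_trace(recipe, n_samples, rng=sub, config=config)
            traces.append(trace.samples.astype(np.float32))
            labels.append(recipe.flux_label)
            recipes.append(recipe)

    return TraceDataset(
        traces=np.stack(traces),
        labels=np.asarray(labels, dtype=np.float64),
        recipes=recipes,
        dt=dt,
        meta={"per_category": per_category, "category_edges": tuple(edges)},
    )


def smooth_trace(trace: TimeTrace, sigma_seconds: float) -> TimeTrace:
    """Gaussian smoothing in time (sigma given in seconds)."""
    if sigma_seconds < 0:
        raise ValueError("sigma must be non-negative")
    if sigma_seconds == 0:
        return trace
    y = ndimage.gaussian_filter1d(trace.samples, sigma=sigma_seconds / trace.dt)
    return TimeTrace(y, dt=trace.dt, normalized=trace.normalized)
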