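"""Synthetic-data generators for every pipeline stage.

These stand in for the animal recordings: a uni-planar machine (actuator
side-arm) angular-velocity impulse, a triaxial skull response at roughly half
the machine peak and about twice its duration with delayed off-axis motion,
cohorts of paired traces with log-normal between-animal variation, and H-DAB
micrographs with known bulb counts and IgG extravasation fractions.

Pulse geometry is parameterized by (peak, FWHM, time-to-peak) rather than by
base duration: FWHM is the field's duration metric, so calibration is direct.
Each shape keeps an exact closed form — a half-sine of base duration T has
FWHM = 2T/3, a sine-squared pulse has FWHM = T/2 — even when an asymmetric
rise/fall split is used to hit a requested time-to-peak.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .errors import InvalidSpecError
from .ihc_quant import FIELD_SIZE_UM, IHCField, StainMatrix, mix_stains
from .traces import AngularRateTrace, TriaxialTrace

PULSE_SHAPES = ("half_sine", "sine_squared")

#: Rise-threshold convention used to convert a requested time-to-peak into a
#: rise duration (matches the analysis side's 5% rise definition).
RISE_FRACTION = 0.05


def _rise_duration(shape: str, time_to_peak_ms: float) -> float:
    """Rise (quarter-wave) duration whose 5%-rise time-to-peak is as requested."""
    if shape == "half_sine":
        frac = 1.0 - (2.0 / np.pi) * np.arcsin(RISE_FRACTION)
    else:  # sine_squared
        frac = 1.0 - (2.0 / np.pi) * np.arcsin(np.sqrt(RISE_FRACTION))
    return time_to_peak_ms / frac


@dataclass
class PulseSpec:
    """One angular-velocity impulse.

    ``fwhm_ms`` fixes the base duration through the shape's closed form
    (half-sine: T = 1.5 x FWHM; sine-squared: T = 2 x FWHM).  When
    ``time_to_peak_ms`` is given, the rise and fall quarter-waves get unequal
    durations so the 5%-rise time-to-peak matches it exactly while the FWHM
    closed form is preserved; when omitted the pulse is symmetric.
    """

    peak_velocity: float
    fwhm_ms: float
    time_to_peak_ms: float | None = None
    shape: str = "half_sine"
    polarity: int = 1

    def __post_init__(self):
        if self.peak_velocity <= 0:
            raise InvalidSpecError("peak_velocity must be positive")
        if self.fwhm_ms <= 0:
            raise InvalidSpecError("fwhm must be positive")
        if self.shape not in PULSE_SHAPES:
            raise InvalidSpecError(f"shape must be one of {PULSE_SHAPES}")
        if self.polarity not in (1, -1):
            raise InvalidSpecError("polarity must be +1 or -1")
        if self.time_to_peak_ms is not None and self.time_to_peak_ms <= 0:
            raise InvalidSpecError("time_to_peak must be positive")
        if self.rise_ms >= self.base_ms:
            raise InvalidSpecError(
                "time_to_peak too long for the requested FWHM (fall duration <= 0)"
            )

    @property
    def base_ms(self) -> float:
        """Base (support) duration T implied by FWHM and shape."""
        return 1.5 * self.fwhm_ms if self.shape == "half_sine" else 2.0 * self.fwhm_ms

    @property
    def rise_ms(self) -> float:
        if self.time_to_peak_ms is None:
            return self.base_ms / 2.0
        return _rise_duration(self.shape, self.time_to_peak_ms)

    @property
    def fall_ms(self) -> float:
        return self.base_ms - self.rise_ms

    def evaluate(self, t_ms: np.ndarray, onset_ms: float) -> np.ndarray:
        """Noise-free pulse samples at times ``t_ms`` with onset ``onset_ms``."""
        tau = np.asarray(t_ms, dtype=float) - onset_ms
        tr, tf = self.rise_ms, self.fall_ms
        y = np.zeros_like(tau)
        rise = (tau >= 0) & (tau <= tr)
        fall = (tau > tr) & (tau <= tr + tf)
        phase_r = np.pi * tau[rise] / (2.0 * tr)
        phase_f = np.pi * (tau[fall] - tr) / (2.0 * tf)
        if self.shape == "half_sine":
            y[rise] = np.sin(phase_r)
            y[fall] = np.cos(phase_f)
        else:
            y[rise] = np.sin(phase_r) ** 2
            y[fall] = np.cos(phase_f) ** 2
        return self.polarity * self.peak_velocity * y

    @property
    def peak_offset_ms(self) -> float:
        """Time of the analytic peak after pulse onset."""
        return self.rise_ms


def default_machine_spec() -> PulseSpec:
    """The emulated machine regime: ~250 rad/s peak, 5.82 ms FWHM, 6.45 ms TTP."""
    return PulseSpec(peak_velocity=250.68, fwhm_ms=5.82, time_to_peak_ms=6.45)


@dataclass
class SpikeArtifactSpec:
    count: int = 1
    amplitude: float = 400.0
    width_samples: int = 1

    def __post_init__(self):
        if self.count < 0 or self.width_samples < 1:
            raise InvalidSpecError("invalid spike artifact spec")


@dataclass
class SkullResponseSpec:
    """Phenomenological skull response to the machine impulse.

    Defaults are calibrated to the observed regime: the coronal peak reaches
    ~51% of the machine peak over ~1.91x its duration, and delayed sagittal /
    axial components reach 55 / 62 rad/s after the coronal peak.
    Multiplanar motion follows the coronal deceleration, so
    ``offaxis_delay_ms`` is anchored at the coronal half-max down-crossing
    (scaling with each pulse's own decay) rather than at the peak; the
    sagittal component peaks ``offaxis_delay_ms`` after that crossing, the
    axial a further ``offaxis_stagger_ms`` later.  With the defaults the
    off-axis support never overlaps the crossing itself, so the resultant
    FWHM tracks the broadened coronal FWHM.
    """

    transfer_ratio: float = 0.51
    broadening: float = 1.91
    offaxis_peaks: tuple = (55.0, 62.0)
    offaxis_delay_ms: float = 4.0
    offaxis_fwhm_ms: float = 4.0
    offaxis_stagger_ms: float = 3.0
    noise_sd: float = 1.0
    spike_spec: SpikeArtifactSpec | None = None

    def __post_init__(self):
        if not 0 < self.transfer_ratio <= 1:
            raise InvalidSpecError("transfer_ratio must be in (0, 1]")
        if self.broadening < 1:
            raise InvalidSpecError("broadening must be >= 1")
        if min(self.offaxis_peaks) < 0 or self.offaxis_delay_ms <= 0:
            raise InvalidSpecError("off-axis peaks must be >= 0 and delay positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")


def _time_grid(sampling_rate: float, duration_ms: float) -> np.ndarray:
    n = int(round(duration_ms * 1e-3 * sampling_rate)) + 1
    return np.arange(n) / sampling_rate


def _check_rate(sampling_rate: float) -> None:
    if sampling_rate < 1000.0:
        raise InvalidSpecError("sampling_rate must be at least 1 kHz")


def simulate_machine_trace(
    spec: PulseSpec,
    sampling_rate: float = 25_000.0,
    seed: int | np.random.Generator = 0,
    noise_sd: float = 0.0,
    lead_ms: float = 15.0,
    duration_ms: float = 60.0,
) -> AngularRateTrace:
    """Single-axis machine-sensor trace: one pulse after a quiet lead-in."""
    _check_rate(sampling_rate)
    if lead_ms < 10.0:
        raise InvalidSpecError("leading quiet segment must be at least 10 ms")
    if noise_sd < 0:
        raise InvalidSpecError("noise_sd must be non-negative")
    t = _time_grid(sampling_rate, duration_ms)
    if lead_ms + spec.base_ms > duration_ms:
        raise InvalidSpecError("duration too short for lead-in plus pulse")
    omega = spec.evaluate(t * 1e3, lead_ms)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        omega = omega + rng.normal(0.0, noise_sd, omega.size)
    return AngularRateTrace(t, omega, "machine")


def simulate_skull_trace(
    machine_spec: PulseSpec,
    response: SkullResponseSpec | None = None,
    sampling_rate: float = 50_000.0,
    seed: int | np.random.Generator = 0,
    lead_ms: float = 15.0,
    duration_ms: float = 60.0,
) -> TriaxialTrace:
    """Triaxial skull-sensor trace driven by the machine impulse.

    The coronal channel scales the machine pulse by ``transfer_ratio`` and
    broadens its FWHM by ``broadening`` while keeping the machine's rise
    duration (the skull tracks the drive on the way up; the decay is what
    broadens).  Sagittal and axial half-sine components peak after the
    coronal peak.  Optional single-/few-sample rectangular spike artifacts
    are injected into the coronal channel.
    """
    _check_rate(sampling_rate)
    response = response or SkullResponseSpec()
    rng = np.random.default_rng(seed)
    t = _time_grid(sampling_rate, duration_ms)
    t_ms = t * 1e3

    cor_fwhm = machine_spec.fwhm_ms * response.broadening
    cor_base = 1.5 * cor_fwhm if machine_spec.shape == "half_sine" else 2.0 * cor_fwhm
    cor_ttp = machine_spec.time_to_peak_ms
    if cor_ttp is not None and _rise_duration(machine_spec.shape, cor_ttp) >= cor_base:
        cor_ttp = None  # fall back to a symmetric pulse
    coronal_spec = PulseSpec(
        peak_velocity=machine_spec.peak_velocity * response.transfer_ratio,
        fwhm_ms=cor_fwhm,
        time_to_peak_ms=cor_ttp,
        shape=machine_spec.shape,
        polarity=machine_spec.polarity,
    )
    coronal = coronal_spec.evaluate(t_ms, lead_ms)
    t_peak_ms = lead_ms + coronal_spec.peak_offset_ms
    # analytic half-max down-crossing of the coronal fall quarter-wave
    fall = coronal_spec.fall_ms
    half_decay_ms = 2.0 * fall / 3.0 if machine_spec.shape == "half_sine" else fall / 2.0
    t_anchor_ms = t_peak_ms + half_decay_ms

    def offaxis(peak: float, center_ms: float) -> np.ndarray:
        if peak == 0:
            return np.zeros_like(t_ms)
        p = PulseSpec(peak, response.offaxis_fwhm_ms, shape="half_sine")
        return p.evaluate(t_ms, center_ms - p.peak_offset_ms)

    sagittal = offaxis(response.offaxis_peaks[0], t_anchor_ms + response.offaxis_delay_ms)
    axial = offaxis(
        response.offaxis_peaks[1],
        t_anchor_ms + response.offaxis_delay_ms + response.offaxis_stagger_ms,
    )

    if response.noise_sd > 0:
        coronal = coronal + rng.normal(0.0, response.noise_sd, t.size)
        sagittal = sagittal + rng.normal(0.0, response.noise_sd, t.size)
        axial = axial + rng.normal(0.0, response.noise_sd, t.size)

    if response.spike_spec is not None and response.spike_spec.count > 0:
        ss = response.spike_spec
        lo = int(np.searchsorted(t_ms, lead_ms))
        hi = int(np.searchsorted(t_ms, lead_ms + cor_base))
        # isolated positions: keep spikes at least 3 widths apart
        positions: list[int] = []
        for _ in range(1000 * ss.count):
            if len(positions) >= ss.count:
                break
            cand = int(rng.integers(lo, max(lo + 1, hi)))
            if all(abs(cand - p) > 3 * ss.width_samples for p in positions):
                positions.append(cand)
        if len(positions) < ss.count:
            raise InvalidSpecError("could not place isolated spike artifacts")
        for p in positions:
            coronal[p : p + ss.width_samples] += ss.amplitude

    return TriaxialTrace(
        AngularRateTrace(t, coronal, "coronal"),
        AngularRateTrace(t.copy(), sagittal, "sagittal"),
        AngularRateTrace(t.copy(), axial, "axial"),
    )


@dataclass
class CohortSpec:
    """A cohort of animals exposed to the same targeted impulse.

    ``between_animal_cv`` (percent) is applied as independent mean-preserving
    log-normal variation to the skull transfer ratio and broadening;
    ``machine_cv`` likewise jitters the achieved machine peak around its
    target.  Defaults mirror the observed cohort dispersions (skull peak COV
    ~8.9%, machine peak COV ~1.1%).
    """

    n_animals: int = 9
    between_animal_cv: float = 8.9
    machine_cv: float = 1.1
    seed: int = 0

    def __post_init__(self):
        if self.n_animals < 1:
            raise InvalidSpecError("n_animals must be >= 1")
        if self.between_animal_cv < 0 or self.machine_cv < 0:
            raise InvalidSpecError("coefficients of variation must be non-negative")


def _lognormal_factor(rng: np.random.Generator, cv_pct: float) -> float:
    """Mean-preserving log-normal multiplier with the given CV (percent)."""
    if cv_pct == 0:
        return 1.0
    cv = cv_pct / 100.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


@dataclass
class AnimalSim:
    animal_id: str
    machine: AngularRateTrace
    skull: TriaxialTrace
    params: dict


@dataclass
class CohortSim:
    animals: list
    manifest: dict

    def manifest_json(self) -> str:
        return json.dumps(self.manifest, indent=2, sort_keys=True)


def simulate_cohort(
    cohort: CohortSpec,
    machine_spec: PulseSpec | None = None,
    response: SkullResponseSpec | None = None,
    machine_sampling_rate: float = 25_000.0,
    skull_sampling_rate: float = 50_000.0,
    machine_noise_sd: float = 0.5,
    label: str = "exp",
) -> CohortSim:
    """Paired (machine, skull) traces for ``n_animals`` with a full manifest.

    Per-animal parameter draws and noise seeds derive deterministically from
    ``cohort.seed`` via spawned seed sequences, so a fixed cohort seed gives
    bit-identical traces across runs.
    """
    machine_spec = machine_spec or default_machine_spec()
    response = response or SkullResponseSpec()
    root = np.random.SeedSequence(cohort.seed)
    children = root.spawn(cohort.n_animals)
    animals = []
    manifest_animals = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        m_factor = _lognormal_factor(rng, cohort.machine_cv)
        t_factor = _lognormal_factor(rng, cohort.between_animal_cv)
        b_factor = _lognormal_factor(rng, cohort.between_animal_cv)
        machine_seed = int(rng.integers(0, 2**31))
        skull_seed = int(rng.integers(0, 2**31))
        m_spec = PulseSpec(
            peak_velocity=machine_spec.peak_velocity * m_factor,
            fwhm_ms=machine_spec.fwhm_ms,
            time_to_peak_ms=machine_spec.time_to_peak_ms,
            shape=machine_spec.shape,
            polarity=machine_spec.polarity,
        )
        resp_i = SkullResponseSpec(
            transfer_ratio=min(1.0, response.transfer_ratio * t_factor),
            broadening=max(1.0, response.broadening * b_factor),
            offaxis_peaks=response.offaxis_peaks,
            offaxis_delay_ms=response.offaxis_delay_ms,
            offaxis_fwhm_ms=response.offaxis_fwhm_ms,
            offaxis_stagger_ms=response.offaxis_stagger_ms,
            noise_sd=response.noise_sd,
            spike_spec=response.spike_spec,
        )
        animal_id = f"{label}_{i + 1:02d}"
        machine = simulate_machine_trace(
            m_spec, machine_sampling_rate, machine_seed, noise_sd=machine_noise_sd
        )
        skull = simulate_skull_trace(m_spec, resp_i, skull_sampling_rate, skull_seed)
        params = {
            "animal_id": animal_id,
            "machine_peak": m_spec.peak_velocity,
            "machine_fwhm_ms": m_spec.fwhm_ms,
            "transfer_ratio": resp_i.transfer_ratio,
            "broadening": resp_i.broadening,
            "machine_seed": machine_seed,
            "skull_seed": skull_seed,
        }
        animals.append(AnimalSim(animal_id, machine, skull, params))
        manifest_animals.append(params)
    manifest = {
        "cohort": asdict(cohort),
        "machine_spec": asdict(machine_spec),
        "response": {
            k: (asdict(v) if isinstance(v, SpikeArtifactSpec) else v)
            for k, v in asdict(response).items()
        },
        "machine_sampling_rate": machine_sampling_rate,
        "skull_sampling_rate": skull_sampling_rate,
        "machine_noise_sd": machine_noise_sd,
        "animals": manifest_animals,
    }
    return CohortSim(animals, manifest)


@dataclass
class IHCFieldSpec:
    """Synthetic H-DAB field with known ground truth.

    Bulbs are disjoint DAB-stained disks (resampled on overlap, capped
    retries) on a uniform hematoxylin background; IgG extravasation is an
    irregular DAB-positive region covering ``igg_fraction`` of the pixels.
    Stains compose through Beer-Lambert optical density with the configured
    stain vectors; noise is Gaussian in 8-bit intensity space.
    """

    field_size_um: tuple = FIELD_SIZE_UM
    microns_per_pixel: float = 2.0
    n_bulbs: int = 12
    bulb_diameter_range_um: tuple = (5.0, 15.0)
    dab_od: float = 0.8
    background_od: float = 0.25
    igg_fraction: float = 0.0
    noise_sd: float = 2.0
    seed: int = 0
    max_retries_per_bulb: int = 200

    def __post_init__(self):
        if self.microns_per_pixel <= 0:
            raise InvalidSpecError("microns_per_pixel must be positive")
        if self.n_bulbs < 0:
            raise InvalidSpecError("n_bulbs must be non-negative")
        if not 0 <= self.igg_fraction <= 1:
            raise InvalidSpecError("igg_fraction must be in [0, 1]")
        if self.dab_od <= 0 or self.background_od < 0 or self.noise_sd < 0:
            raise InvalidSpecError("optical densities / noise must be valid")
        lo, hi = self.bulb_diameter_range_um
        if lo <= 0 or hi < lo:
            raise InvalidSpecError("invalid bulb diameter range")


def simulate_ihc_field(spec: IHCFieldSpec, stains: StainMatrix | None = None) -> IHCField:
    """Render a synthetic stained field; ground truth rides in ``field.truth``."""
    stains = stains or StainMatrix.hdab()
    rng = np.random.default_rng(spec.seed)
    w_px = int(round(spec.field_size_um[0] / spec.microns_per_pixel))
    h_px = int(round(spec.field_size_um[1] / spec.microns_per_pixel))
    yy, xx = np.mgrid[0:h_px, 0:w_px]

    bulb_mask = np.zeros((h_px, w_px), dtype=bool)
    placed: list[tuple[float, float, float]] = []  # (cy, cx, r_px)
    lo_um, hi_um = spec.bulb_diameter_range_um
    for _ in range(spec.n_bulbs):
        for attempt in range(spec.max_retries_per_bulb):
            r_px = rng.uniform(lo_um, hi_um) / 2.0 / spec.microns_per_pixel
            cy = rng.uniform(r_px + 1, h_px - r_px - 1)
            cx = rng.uniform(r_px + 1, w_px - r_px - 1)
            # 2 px clearance so rasterized disks stay 8-disconnected
            if all(np.hypot(cy - py, cx - px) >= r_px + pr + 2.0 for py, px, pr in placed):
                placed.append((cy, cx, r_px))
                bulb_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
                break
        else:
            raise InvalidSpecError(
                "could not place disjoint bulbs; reduce n_bulbs or diameters"
            )

    igg_mask = np.zeros((h_px, w_px), dtype=bool)
    if spec.igg_fraction >= 1.0:
        igg_mask[:] = True
    elif spec.igg_fraction > 0:
        blob = ndimage.gaussian_filter(rng.standard_normal((h_px, w_px)), sigma=8.0)
        k = int(round(spec.igg_fraction * blob.size))
        if k > 0:
            thr = np.partition(blob.ravel(), blob.size - k)[blob.size - k]
            igg_mask = blob >= thr

    conc = np.zeros((h_px, w_px, 3))
    conc[..., 0] = spec.background_od  # hematoxylin
    conc[..., 1] = np.where(bulb_mask | igg_mask, spec.dab_od, 0.0)  # DAB
    rgb = mix_stains(conc, stains)
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, rgb.shape)
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    truth = {
        "n_bulbs": spec.n_bulbs,
        "bulb_mask": bulb_mask,
        "igg_mask": igg_mask,
        "igg_fraction": spec.igg_fraction,
        "bulbs": [
            {"cy": cy, "cx": cx, "radius_px": r} for cy, cx, r in placed
        ],
    }
    return IHCField(rgb, spec.microns_per_pixel, spec.field_size_um, truth)
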