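"""Synthetic transmission-fluence cohorts with injected 3D couch shifts.

The generator emulates an arc-delivery transmission measurement: a rigid
head-like phantom is placed at isocenter, the gantry sweeps two partial
arcs (240deg -> 120deg clockwise through gantry zero, and back counter-
clockwise), and at each control angle the beam is shaped by a smoothly
modulated aperture, attenuated exponentially along its path through the
phantom, and integrated on a fixed imager whose row axis is the SI
patient axis and whose column axis is the in-plane axis perpendicular to
the beam.

The phantom is an analytic composition of ellipsoids (a head-shaped body
plus internal heterogeneities), so the exponential path integral of each
ray has a closed form (attenuation times chord length).  Rigidly shifting
the phantom by ``(lr, si, ap)`` mm therefore shifts the projection at
gantry angle ``theta`` by exactly

    du = M * (lr*cos(theta) - ap*sin(theta))   (in-plane imager axis)
    dz = M * si                                (SI imager axis)

with ``M`` the geometric magnification.  Summed over the arc, the SI
component displaces the integrated image coherently while the LR/AP
components are modulated by cos/sin of the gantry angle and partially
self-cancel — the geometric reason SI shifts are the easiest to detect
and LR shifts the hardest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DEFAULT_PITCH_MM, FRACTION_DOSE_CGY, ErrorVector, FluenceMap
from .labeling import SERIAL_TABLE, LabelSet, assign_labels


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    ``noise_sigma_frac`` is the standard deviation of the additive
    Gaussian detector noise as a fraction of the map maximum.
    ``magnification`` is the imager-plane displacement per mm of couch
    shift (1.0 = shift maps one-to-one onto the imager).
    """

    n_patients: int = 40
    image_size: int = 600
    pitch_mm: float = DEFAULT_PITCH_MM
    magnification: float = 1.0
    noise_sigma_frac: float = 0.005
    master_seed: int = 0
    angular_step_deg: float = 5.0
    open_field_dose_cgy: float = FRACTION_DOSE_CGY

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        if self.noise_sigma_frac < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.angular_step_deg <= 0:
            raise ValueError("angular step must be positive")


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid with constant linear attenuation (per mm).

    ``center`` and ``semi_axes`` are in patient coordinates (x=LR, y=AP,
    z=SI), in mm.  ``mu`` may be negative for a component carved out of a
    denser body (an air cavity), as long as the summed attenuation of the
    phantom stays non-negative everywhere.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    mu: float


@dataclass(frozen=True)
class PhantomModel:
    """Analytic head phantom: an ellipsoidal body plus heterogeneities."""

    components: tuple[Ellipsoid, ...]
    structure_seed: int
    voxel_mm: float = 2.0

    def bounding_radii_mm(self) -> tuple[float, float]:
        """(in-plane radius, SI half-extent) of the phantom, in mm."""
        r_xy = 0.0
        r_z = 0.0
        for c in self.components:
            cx, cy, cz = c.center
            a, b, cc = c.semi_axes
            r_xy = max(r_xy, math.hypot(cx, cy) + max(a, b))
            r_z = max(r_z, abs(cz) + cc)
        return r_xy, r_z

    def attenuation_grid(self, voxel_mm: float | None = None) -> np.ndarray:
        """Rasterize the phantom onto a voxel grid of linear attenuation.

        The grid covers the full phantom extent (hence the beam's-eye view
        at every gantry angle); values are clipped at zero so carved-out
        cavities never go negative.
        """
        v = voxel_mm or self.voxel_mm
        r_xy, r_z = self.bounding_radii_mm()
        half = (r_xy + v, r_xy + v, r_z + v)
        n = [max(int(np.ceil(2 * h / v)), 2) for h in half]
        ax = [np.linspace(-h, h, k) for h, k in zip(half, n)]
        x, y, z = np.meshgrid(*ax, indexing="ij")
        grid = np.zeros_like(x)
        for c in self.components:
            q = (
                ((x - c.center[0]) / c.semi_axes[0]) ** 2
                + ((y - c.center[1]) / c.semi_axes[1]) ** 2
                + ((z - c.center[2]) / c.semi_axes[2]) ** 2
            )
            grid[q <= 1.0] += c.mu
        return np.maximum(grid, 0.0)


@dataclass(frozen=True)
class ArcSegment:
    """One partial arc: gantry sweep with a fixed angular step."""

    start_deg: float
    stop_deg: float
    clockwise: bool
    step_deg: float = 5.0

    def angles(self) -> np.ndarray:
        """Gantry angles (deg, mod 360) visited by the arc, inclusive.

        A clockwise 240->120 arc passes through gantry zero (the top),
        never through the 120-180-240 range under the couch.
        """
        if self.step_deg <= 0:
            raise ValueError("angular step must be positive")
        start, stop = self.start_deg % 360.0, self.stop_deg % 360.0
        if self.clockwise:
            span = (stop - start) % 360.0
        else:
            span = -((start - stop) % 360.0)
        n = int(round(abs(span) / self.step_deg))
        return (start + np.sign(span) * self.step_deg * np.arange(n + 1)) % 360.0


@dataclass(frozen=True)
class PlanModel:
    """Two partial arcs plus the seed driving the aperture modulation.

    ``open_aperture`` replaces the modulated masks with a fully open
    field — useful for isolating the pure projection geometry (e.g. a
    coherent-displacement check for SI shifts).
    """

    arcs: tuple[ArcSegment, ArcSegment]
    aperture_seed: int
    open_aperture: bool = False

    def __post_init__(self) -> None:
        if len(self.arcs) != 2:
            raise ValueError("a plan has exactly two partial arcs")


def default_plan(
    aperture_seed: int, step_deg: float = 5.0, open_aperture: bool = False
) -> PlanModel:
    """The study's plan geometry: 240->120 CW then 120->240 CCW."""
    return PlanModel(
        arcs=(
            ArcSegment(240.0, 120.0, clockwise=True, step_deg=step_deg),
            ArcSegment(120.0, 240.0, clockwise=False, step_deg=step_deg),
        ),
        aperture_seed=aperture_seed,
        open_aperture=open_aperture,
    )


def generate_phantom(patient_seed: int, config: SimulationConfig) -> PhantomModel:
    """Build a patient-specific head phantom from a seed.

    The body is an ellipsoid of water-like attenuation; 3-6 internal
    ellipsoidal heterogeneities (denser inclusions and air-like cavities)
    give each synthetic patient a distinct fluence signature.  The phantom
    is sized to stay inside the field of view for all cohort shifts.
    """
    rng = np.random.default_rng(patient_seed)
    mu_body = rng.uniform(0.0045, 0.0055)  # ~water at MV energies, per mm
    head = Ellipsoid(
        center=(0.0, 0.0, 0.0),
        semi_axes=(
            60.0 + rng.uniform(-3, 3),
            70.0 + rng.uniform(-3, 3),
            70.0 + rng.uniform(-3, 3),
        ),
        mu=mu_body,
    )
    comps = [head]
    n_hetero = int(rng.integers(3, 7))
    for _ in range(n_hetero):
        # centers well inside the body so cavities never poke out of it
        frac = rng.uniform(-0.55, 0.55, size=3)
        center = tuple(f * s for f, s in zip(frac, head.semi_axes))
        semi = tuple(rng.uniform(6.0, 16.0, size=3))
        # bone-like (+) or air-like (-) contrast; never drives total below 0
        delta = rng.uniform(-0.9 * mu_body, 0.9 * mu_body)
        comps.append(Ellipsoid(center=center, semi_axes=semi, mu=delta))
    return PhantomModel(components=tuple(comps), structure_seed=int(patient_seed))


def _sigmoid_edge(x: np.ndarray, lo: float, hi: float, penumbra_mm: float) -> np.ndarray:
    """Smooth rectangular profile: ~1 inside [lo, hi], soft penumbra edges."""
    a = 1.0 / (1.0 + np.exp(-(x - lo) / penumbra_mm))
    b = 1.0 / (1.0 + np.exp((x - hi) / penumbra_mm))
    return a * b


class FluenceSimulator:
    """Per-patient projector with cached attenuation and aperture stacks.

    Precomputes, once per (phantom, plan, config): the open-beam
    transmission image exp(-line integral) at every unique gantry angle,
    and the combined (both-arc) aperture mask at every angle.  Each error
    map is then a per-angle sub-pixel shift of the transmission stack,
    masked and summed over the arcs — exactly the integral a moving-
    aperture arc delivery records.
    """

    def __init__(self, phantom: PhantomModel, plan: PlanModel, config: SimulationConfig):
        self.phantom = phantom
        self.plan = plan
        self.config = config
        n = config.image_size
        half = (n - 1) / 2.0
        # imager coordinates, mm; rows = SI (+SI with increasing row)
        self._u = (np.arange(n) - half) * config.pitch_mm
        self._z = (np.arange(n) - half) * config.pitch_mm
        self._build_stacks()

    # -- geometry ---------------------------------------------------------
    def _build_stacks(self) -> None:
        cfg = self.config
        m = cfg.magnification
        arc_angle_lists = [arc.angles() for arc in self.plan.arcs]
        angles = np.unique(np.concatenate(arc_angle_lists))
        self._angles = angles
        self._n_projections = sum(len(a) for a in arc_angle_lists)

        u_p = self._u / m  # patient-plane coordinates sampled by each ray
        z_p = self._z / m
        n = cfg.image_size
        trans = np.empty((len(angles), n, n), dtype=np.float32)
        for k, ang in enumerate(angles):
            th = math.radians(ang)
            sin_t, cos_t = math.sin(th), math.cos(th)
            total = np.zeros((n, n), dtype=np.float64)
            for comp in self.phantom.components:
                cx, cy, cz = comp.center
                a, b, c = comp.semi_axes
                # ray origin along the in-plane axis u_hat=(cos t, -sin t, 0),
                # direction d=(-sin t, -cos t, 0); closed-form chord length
                qx = u_p * cos_t - cx
                qy = -u_p * sin_t - cy
                qz = z_p - cz
                big_a = (sin_t / a) ** 2 + (cos_t / b) ** 2
                big_b = (-sin_t) * qx / a**2 + (-cos_t) * qy / b**2
                cu = (qx / a) ** 2 + (qy / b) ** 2
                czq = (qz / c) ** 2
                disc = (big_b**2 - big_a * (cu - 1.0))[None, :] - big_a * czq[:, None]
                np.maximum(disc, 0.0, out=disc)
                total += (2.0 * comp.mu / big_a) * np.sqrt(disc)
            trans[k] = np.exp(-total, dtype=np.float64).astype(np.float32)
        self._transmission = trans
        self._masks = self._build_masks(angles, arc_angle_lists)

    def _build_masks(
        self, angles: np.ndarray, arc_angle_lists: list[np.ndarray]
    ) -> np.ndarray:
        """Combined (summed over arcs) separable aperture mask per angle."""
        cfg = self.config
        n = cfg.image_size
        rng = np.random.default_rng(self.plan.aperture_seed)
        if self.plan.open_aperture:
            n_arcs = len(arc_angle_lists)
            return np.full((len(angles), n, n), float(n_arcs), dtype=np.float32)
        masks = np.zeros((len(angles), n, n), dtype=np.float32)
        index = {round(float(a), 6): i for i, a in enumerate(angles)}
        for arc_angles in arc_angle_lists:
            # low-order Fourier modulation of the aperture centre and size
            # over the arc mimics VMAT-like smooth aperture motion
            phase = rng.uniform(0, 2 * np.pi, size=8)
            amp_c = rng.uniform(2.0, 7.0, size=4)
            hw_u0 = rng.uniform(30.0, 40.0)
            hw_z0 = rng.uniform(30.0, 40.0)
            amp_w = rng.uniform(2.0, 6.0, size=2)
            for ang in arc_angles:
                th = math.radians(float(ang))
                cu = amp_c[0] * math.sin(th + phase[0]) + amp_c[1] * math.sin(2 * th + phase[1])
                cz = amp_c[2] * math.sin(th + phase[2]) + amp_c[3] * math.sin(2 * th + phase[3])
                hw_u = hw_u0 + amp_w[0] * math.sin(th + phase[4])
                hw_z = hw_z0 + amp_w[1] * math.sin(2 * th + phase[5])
                mu_1d = _sigmoid_edge(self._u, cu - hw_u, cu + hw_u, 1.5)
                mz_1d = _sigmoid_edge(self._z, cz - hw_z, cz + hw_z, 1.5)
                masks[index[round(float(ang), 6)]] += np.outer(
                    mz_1d, mu_1d
                ).astype(np.float32)
        return masks

    # -- shifting ---------------------------------------------------------
    @staticmethod
    def _shift_axis(img: np.ndarray, shift_px: float, axis: int) -> np.ndarray:
        """Sample ``img`` at coordinates displaced by ``-shift_px`` along
        ``axis`` (linear interpolation, edge clamp): features move by
        ``+shift_px``."""
        if shift_px == 0.0:
            return img
        n = img.shape[axis]
        pos = np.arange(n, dtype=np.float64) - shift_px
        i0 = np.clip(np.floor(pos).astype(np.intp), 0, n - 2)
        frac = np.clip(pos - i0, 0.0, 1.0).astype(img.dtype)
        lo = np.take(img, i0, axis=axis)
        hi = np.take(img, i0 + 1, axis=axis)
        if axis == 0:
            frac = frac[:, None]
        return lo * (1 - frac) + hi * frac

    def check_in_fov(self, error: ErrorVector) -> None:
        cfg = self.config
        half_fov = cfg.image_size * cfg.pitch_mm / 2.0
        r_xy, r_z = self.phantom.bounding_radii_mm()
        m = cfg.magnification
        if m * (r_xy + math.hypot(error.lr_mm, error.ap_mm)) > half_fov or m * (
            r_z + abs(error.si_mm)
        ) > half_fov:
            raise ValueError(
                f"error {error.as_tuple()} mm pushes the phantom outside the "
                f"{2 * half_fov:.1f} mm field of view"
            )

    def simulate(self, error: ErrorVector, noise_seed: int) -> FluenceMap:
        """Integrated fluence map for one phantom position."""
        cfg = self.config
        self.check_in_fov(error)
        m = cfg.magnification
        dz_px = m * error.si_mm / cfg.pitch_mm
        total = np.zeros((cfg.image_size, cfg.image_size), dtype=np.float32)
        for k, ang in enumerate(self._angles):
            th = math.radians(float(ang))
            du_px = m * (error.lr_mm * math.cos(th) - error.ap_mm * math.sin(th)) / cfg.pitch_mm
            t = self._shift_axis(self._transmission[k], du_px, axis=1)
            t = self._shift_axis(t, dz_px, axis=0)
            total += self._masks[k] * t
        # both arcs revisit each unique angle; masks are already summed over
        # arcs, so the open-field normalisation uses the projection count
        dose = total * np.float32(cfg.open_field_dose_cgy / self._n_projections)
        if cfg.noise_sigma_frac > 0:
            rng = np.random.default_rng(noise_seed)
            sigma = cfg.noise_sigma_frac * float(dose.max())
            dose = dose + rng.normal(0.0, sigma, size=dose.shape).astype(np.float32)
            np.maximum(dose, 0.0, out=dose)
        return FluenceMap(
            pixels=dose,
            pitch_mm=cfg.pitch_mm,
            error=error,
            meta={"noise_seed": int(noise_seed), "magnification": m},
            validate=cfg.image_size >= 512,
        )


def simulate_fluence(
    phantom: PhantomModel,
    plan: PlanModel,
    error: ErrorVector,
    config: SimulationConfig,
    noise_seed: int,
) -> FluenceMap:
    """One-shot convenience wrapper around :class:`FluenceSimulator`."""
    return FluenceSimulator(phantom, plan, config).simulate(error, noise_seed)


# -- cohort generation -----------------------------------------------------

@dataclass
class CohortRecord:
    """One acquired map with its provenance and labels."""

    map: FluenceMap
    serial: int
    role: str  # "baseline" | "error"
    labels: LabelSet | None
    noise_seed: int
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.patient_id = self.patient_id or self.map.patient_id


def _derive_seed(*key: int) -> int:
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0] % (2**31))


def iter_patients(config: SimulationConfig):
    """Yield ``(patient_id, [CohortRecord, ...])`` one patient at a time.

    Streaming counterpart of :func:`generate_cohort`: per-patient stacks
    are released as soon as the patient's 28 maps are produced.
    """
    for i in range(config.n_patients):
        pid = f"P{i:03d}"
        phantom_seed = _derive_seed(config.master_seed, i, 0)
        aperture_seed = _derive_seed(config.master_seed, i, 1)
        phantom = generate_phantom(phantom_seed, config)
        plan = default_plan(aperture_seed, step_deg=config.angular_step_deg)
        sim = FluenceSimulator(phantom, plan, config)
        records: list[CohortRecord] = []

        def _record(serial: int, error: ErrorVector, role: str) -> CohortRecord:
            noise_seed = _derive_seed(config.master_seed, i, 2, serial)
            fm = sim.simulate(error, noise_seed)
            fm.patient_id = pid
            labels = None if role == "baseline" else assign_labels(error)
            return CohortRecord(
                map=fm, serial=serial, role=role, labels=labels, noise_seed=noise_seed
            )

        records.append(_record(1, ErrorVector(0, 0, 0), "baseline"))
        for serial, _group, (lr, si, ap) in SERIAL_TABLE:
            records.append(_record(serial, ErrorVector(lr, si, ap), "error"))
        yield pid, records


def generate_cohort(config: SimulationConfig) -> list[CohortRecord]:
    """Generate the full labeled cohort: 28 maps per patient.

    Per patient: one baseline acquisition plus one map for each of the 27
    error positions of {0,2,4}^3 mm — including a re-acquisition of the
    unshifted position with a fresh noise seed (serial 2), so the cohort
    contains the no-error class as a genuinely independent measurement.
    """
    out: list[CohortRecord] = []
    for _pid, records in iter_patients(config):
        out.extend(records)
    return out
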