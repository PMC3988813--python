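"""Transverse-relaxivity enhancement maps for SPIO-loaded mesoporous
constructs.

An elemental (EDX-like) iron image locates super-paramagnetic iron
oxide nanoparticle (SPIO) clusters inside a mesoporous silicon particle
(SiMP).  The chain is:

    raster -> pixel-scale SPIO density -> pore-scale density (mass
    conserved) -> per-pore SPIO count -> representative confinement
    fraction theta_bar -> theta(X, Y) map -> D(X, Y) via the scaling law
    -> outer-sphere enhancement En = (v/D) / (v_B/D_B) and its
    SPIO-weighted average.

Outer-sphere relaxation theory makes r2 proportional to v/D (SPIO
volume fraction over water diffusivity), so the enhancement ratio is
prefactor-free.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .confinement_volume import cpt_correct
from .scaling_law import ScalingLaw, predict_D

logger = logging.getLogger(__name__)

__all__ = [
    "EDXScene",
    "EnhancementMap",
    "generate_synthetic_edx",
    "pixel_density",
    "local_density",
    "pore_scale_density",
    "representative_theta",
    "theta_map",
    "volume_fraction_map",
    "relaxivity",
    "enhancement_map",
    "analyze_scene",
]


@dataclass
class EDXScene:
    """A label image of SPIO clusters plus the construct's geometry.

    image : nonnegative raster, intensity proportional to local iron.
    A_pix : pixel area, nm^2.
    A_SiMP : construct cross-section area, nm^2.
    A_p : representative pore cross-section area, nm^2.
    pore_diameter, h : pore diameter and construct height, nm.
    N_SPIO : total SPIO count in the construct.
    spio_radius : SPIO core radius, nm.
    c_fill : fraction of pore height effectively occupied.
    delta : confinement length around one SPIO, nm.
    """

    image: np.ndarray
    A_pix: float
    A_SiMP: float
    A_p: float
    pore_diameter: float
    h: float
    N_SPIO: int
    spio_radius: float
    c_fill: float = 1.0
    delta: float = 0.5

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2 or np.any(self.image < 0):
            raise ValueError("image must be a 2-D nonnegative raster")
        if not (0 < self.A_pix <= self.A_p <= self.A_SiMP):
            raise ValueError("require 0 < A_pix <= A_p <= A_SiMP")
        if not (0 < self.c_fill <= 1):
            raise ValueError("c_fill must be in (0, 1]")
        if min(self.pore_diameter, self.h, self.spio_radius, self.delta) < 0:
            raise ValueError("geometry lengths must be nonnegative")

    @property
    def pixel_size(self) -> float:
        return math.sqrt(self.A_pix)


@dataclass
class EnhancementMap:
    rho_SPIO: np.ndarray  # count / nm^2
    theta_map: np.ndarray
    D_map: np.ndarray  # m^2/s
    En_map: np.ndarray
    En_avg: float
    theta_bar: float = float("nan")
    clamp_fraction: float = 0.0
    excluded: np.ndarray | None = None


def generate_synthetic_edx(
    shape: tuple[int, int] = (128, 128),
    n_clusters: int = 12,
    cluster_size: float = 2.5,
    seed: int = 0,
    pixel_size: float = 10.0,
    N_SPIO: int = 1_000_000,
    pore_diameter: float = 40.0,
    h: float = 400.0,
    spio_radius: float = 2.565,
    c_fill: float = 1.0,
    delta: float = 0.5,
    intensity: float = 100.0,
) -> EDXScene:
    """Synthetic iron map: Gaussian-blob SPIO clusters on a dark field.

    Defaults emulate a discoidal mesoporous silicon construct (~1000 nm
    across, 400 nm tall, 40 nm pores) loaded with ~5.1 nm SPIOs; the
    image covers the construct cross-section at *pixel_size* nm/pixel.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    img = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for _ in range(n_clusters):
        cy = rng.uniform(0.15, 0.85) * shape[0]
        cx = rng.uniform(0.15, 0.85) * shape[1]
        amp = intensity * rng.uniform(0.5, 1.5)
        img += amp * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * cluster_size**2)
        )
    img[img < 1e-3 * intensity] = 0.0  # sparse background, like a label map
    A_pix = pixel_size**2
    A_SiMP = shape[0] * shape[1] * A_pix
    A_p = math.pi * (pore_diameter / 2.0) ** 2
    return EDXScene(
        image=img,
        A_pix=A_pix,
        A_SiMP=A_SiMP,
        A_p=A_p,
        pore_diameter=pore_diameter,
        h=h,
        N_SPIO=N_SPIO,
        spio_radius=spio_radius,
        c_fill=c_fill,
        delta=delta,
    )


def pixel_density(scene: EDXScene) -> np.ndarray:
    """Pixel-scale SPIO areal density (count/nm^2).

    rho_areal = N_SPIO f(X,Y) / (sum f * A_pix); integrates back to
    N_SPIO exactly.
    """
    total = scene.image.sum()
    if total <= 0:
        raise ValueError("EDX image carries no signal")
    return scene.N_SPIO * scene.image / (total * scene.A_pix)


def local_density(scene: EDXScene, bandwidth: float | None = None) -> np.ndarray:
    """Kernel-smoothed density of the non-zero pixels, unit integral.

    *bandwidth* is the Gaussian sigma in pixels; it defaults to the pore
    diameter expressed in pixels, so that the density lives on the pore
    scale rather than the (instrumental) pixel scale.
    """
    if bandwidth is None:
        bandwidth = scene.pore_diameter / scene.pixel_size
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    indicator = (scene.image > 0).astype(float)
    smoothed = gaussian_filter(indicator, sigma=bandwidth, mode="constant")
    total = smoothed.sum() * scene.A_pix
    if total <= 0:
        raise ValueError("no non-zero pixels in the image")
    return smoothed / total


def pore_scale_density(
    scene: EDXScene, rho_point: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale rho_point so total SPIO mass is conserved.

    Returns (rho_SPIO, per-pore SPIO count map N_p = rho_SPIO * A_p).
    """
    integral = rho_point.sum() * scene.A_pix
    if integral <= 0:
        raise ValueError("rho_point has zero integral")
    C = scene.N_SPIO / integral
    rho_spio = C * rho_point
    return rho_spio, rho_spio * scene.A_p


def representative_theta(scene: EDXScene, n_p_spio: float) -> float:
    """Confinement fraction of a representative pore holding n_p_spio SPIOs.

    V_in stacks spherical influence shells of thickness delta around each
    SPIO; V_w is the filled pore water volume minus the SPIO cores.  The
    overlap-corrected, clamped ratio is returned.
    """
    if n_p_spio < 0:
        raise ValueError("n_p_spio must be >= 0")
    r = scene.spio_radius
    shell = 4.0 * math.pi / 3.0 * ((r + scene.delta) ** 3 - r**3)
    core = 4.0 * math.pi / 3.0 * r**3
    V_in = n_p_spio * shell
    V_w = scene.c_fill * scene.A_p * scene.h - n_p_spio * core
    if V_w <= 0:
        raise ValueError(
            f"pore overfilled: {n_p_spio:.1f} SPIOs leave no water volume"
        )
    theta = cpt_correct(V_in / V_w, overlap=True)
    return float(np.clip(theta, 0.0, 1.0))


def theta_map(
    scene: EDXScene,
    rho_spio: np.ndarray,
    theta_bar: float,
    occupied_threshold: float = 0.0,
) -> np.ndarray:
    """Scale rho_SPIO into a theta raster.

    theta(X,Y) = C' rho_SPIO(X,Y), with C' fixed so the rho_SPIO-weighted
    mean of theta over occupied pixels (rho above *occupied_threshold*
    times the max) equals *theta_bar*.  Values are clamped to [0, 1];
    the clamped mass fraction is logged.
    """
    if not (0.0 <= theta_bar <= 1.0):
        raise ValueError("theta_bar must lie in [0, 1]")
    rho = np.asarray(rho_spio, dtype=float)
    if rho.max() <= 0:
        raise ValueError("rho_SPIO is identically zero")
    occ = rho > occupied_threshold * rho.max()
    w = rho[occ]
    c_prime = theta_bar * w.sum() / np.sum(w * w)
    theta = c_prime * rho
    over = theta > 1.0
    if over.any():
        frac = float(rho[over].sum() / rho.sum())
        logger.warning("theta map clamped on %.2f%% of SPIO mass", 100 * frac)
    return np.clip(theta, 0.0, 1.0)


def volume_fraction_map(scene: EDXScene, rho_spio: np.ndarray) -> np.ndarray:
    """Local SPIO volume fraction: core volume per pore-slab volume.

    v(X,Y) = rho_SPIO * (4/3) pi r^3 / (h c_fill) -- the SPIO volume
    under a pixel over the water-column volume under the same pixel.
    """
    core = 4.0 * math.pi / 3.0 * scene.spio_radius**3
    return np.asarray(rho_spio, dtype=float) * core / (scene.h * scene.c_fill)


def relaxivity(T2: float, T0w: float, M_Fe: float) -> float:
    """Transverse relaxivity r2 = (1/T2 - 1/T0w)/M_Fe in mM^-1 s^-1.

    T2, T0w in ms (bulk water T0w ~ 2800 ms); M_Fe in mM.
    """
    if min(T2, T0w, M_Fe) <= 0:
        raise ValueError("T2, T0w and M_Fe must be positive")
    return (1000.0 / T2 - 1000.0 / T0w) / M_Fe


def enhancement_map(
    theta: np.ndarray,
    vol_fraction: np.ndarray,
    law: ScalingLaw,
    v_bulk: float,
    rho_spio: np.ndarray | None = None,
) -> EnhancementMap:
    """Outer-sphere relaxivity enhancement En = (v/D)/(v_B/D_B).

    D(X,Y) follows the scaling law from theta(X,Y).  Pixels where D = 0
    (total confinement with D_C = 0) are excluded from the average with
    a warning.  En_avg weights En by the normalized SPIO distribution
    f_SPIO (defaulting to the volume-fraction map when *rho_spio* is not
    given, to which it is proportional).
    """
    theta = np.asarray(theta, dtype=float)
    vol_fraction = np.asarray(vol_fraction, dtype=float)
    if theta.shape != vol_fraction.shape:
        raise ValueError("theta and volume-fraction maps must share a shape")
    if v_bulk <= 0:
        raise ValueError("v_bulk must be positive")
    D = predict_D(theta, law)
    D = np.asarray(D, dtype=float)
    valid = D > 0
    if not valid.all():
        logger.warning(
            "%d pixels with D=0 excluded from the enhancement average",
            int((~valid).sum()),
        )
    En = np.zeros_like(theta)
    En[valid] = (vol_fraction[valid] / D[valid]) / (v_bulk / law.D_B)
    weights = np.asarray(
        rho_spio if rho_spio is not None else vol_fraction, dtype=float
    )
    wsum = weights[valid].sum()
    if wsum <= 0:
        raise ValueError("no SPIO mass on valid pixels")
    en_avg = float(np.sum(En[valid] * weights[valid]) / wsum)
    return EnhancementMap(
        rho_SPIO=weights,
        theta_map=theta,
        D_map=D,
        En_map=En,
        En_avg=en_avg,
        excluded=~valid,
    )


def analyze_scene(
    scene: EDXScene,
    law: ScalingLaw = ScalingLaw(),
    bandwidth: float | None = None,
    occupied_threshold: float = 0.05,
) -> EnhancementMap:
    """Full chain from an EDX scene to the enhancement map and average.

    The bulk reference volume fraction v_B is the construct-average SPIO
    volume fraction (same SPIOs uniformly dispersed in the same water
    column), which makes En = 1 for a perfectly uniform, unconfined
    distribution.
    """
    rho_point = local_density(scene, bandwidth)
    rho_spio, n_p = pore_scale_density(scene, rho_point)
    # representative pore: the mean per-pore count over occupied pores
    occ = rho_spio > occupied_threshold * rho_spio.max()
    n_rep = float(np.average(n_p[occ], weights=rho_spio[occ]))
    t_bar = representative_theta(scene, n_rep)
    tmap = theta_map(scene, rho_spio, t_bar, occupied_threshold)
    vmap = volume_fraction_map(scene, rho_spio)
    core = 4.0 * math.pi / 3.0 * scene.spio_radius**3
    v_bulk = scene.N_SPIO * core / (
        scene.A_SiMP * scene.h * scene.c_fill
    )
    out = enhancement_map(tmap, vmap, law, v_bulk, rho_spio=rho_spio)
    out.theta_bar = t_bar
    return out
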