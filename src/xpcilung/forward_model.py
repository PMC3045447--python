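"""In-line phase-contrast projection imaging of a refractive-index volume.

The simulated instrument is an idealized synchrotron microtomography
station: a parallel, monochromatic plane wave traverses the object, picks
up the transmission factor ``exp(-mu/2 + i*phi)`` where

    mu  = (4*pi/lambda) * integral of beta  along the ray   (attenuation)
    phi = -(2*pi/lambda) * integral of delta along the ray  (phase, <= 0)

and then propagates in free space over a distance z to the detector, where
Fresnel diffraction converts phase gradients into intensity fringes (edge
enhancement).  Two propagators are provided:

* ``propagate_angular_spectrum`` — the exact free-space (Fresnel transfer
  function) propagator, used by default and as the oracle;
* ``propagate_weak_object`` — the linearized weak-object transfer function,
  F{I} = delta(u,v) - M(u,v) + 2*pi*lambda*z*(u^2+v^2)*Phi(u,v),
  with (u,v) in cycles per micrometre, valid for weakly absorbing, slowly
  varying objects.

Geometry defaults follow the emulated experiment: 18 keV, z = 1.2 m,
13 µm detector pixels, 1296 projections over 180 degrees, with the object
rotating about the vertical (z) image axis.

Sampling rules enforced (not assumed): the propagation grid pitch must not
exceed detector_pitch/2 nor sqrt(lambda*z)/4 (a quarter of the first
Fresnel-zone width), so the fringes the method lives on are resolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.ndimage as ndi

from .phantom import RefractiveVolume

__all__ = [
    "HC_KEV_ANGSTROM",
    "BeamGeometry",
    "PhaseAbsorptionMaps",
    "ProjectionSet",
    "energy_to_wavelength",
    "project_mu_phi",
    "transmission",
    "propagate_angular_spectrum",
    "propagate_weak_object",
    "bin_to_detector",
    "acquire_ct",
]

# CODATA hc product
HC_KEV_ANGSTROM = 12.398419843320026


def energy_to_wavelength(energy_keV: float) -> float:
    """X-ray wavelength in Angstrom for a photon energy in keV."""
    if energy_keV <= 0:
        raise ValueError("photon energy must be positive")
    return HC_KEV_ANGSTROM / energy_keV


@dataclass(frozen=True)
class BeamGeometry:
    """Acquisition geometry of the parallel-beam in-line setup."""

    energy_keV: float = 18.0
    z_m: float = 1.2                      # propagation (sample-detector) distance
    detector_pitch_um: float = 13.0
    n_angles: int = 1296
    angular_range_deg: float = 180.0
    photons_per_pixel: float = 1.0e4      # flat-field photon count

    def __post_init__(self) -> None:
        if self.energy_keV <= 0 or self.z_m < 0 or self.detector_pitch_um <= 0:
            raise ValueError("invalid beam geometry")
        if self.angular_range_deg != 180.0:
            raise ValueError("only a 180 degree parallel-beam scan is supported")

    @property
    def wavelength_angstrom(self) -> float:
        return energy_to_wavelength(self.energy_keV)

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_angstrom * 1.0e-4

    @property
    def z_um(self) -> float:
        return self.z_m * 1.0e6

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_angles) * (self.angular_range_deg / self.n_angles)

    def max_sim_pitch_um(self) -> float:
        """Largest admissible propagation-grid pitch (enforced in acquire)."""
        fresnel = np.sqrt(self.wavelength_um * self.z_um) / 4.0 if self.z_m > 0 else np.inf
        return min(self.detector_pitch_um / 2.0, fresnel)


@dataclass
class PhaseAbsorptionMaps:
    """Line-integral attenuation mu and phase shift phi for one view."""

    mu: np.ndarray             # dimensionless, >= 0
    phi: np.ndarray            # radians, <= 0 (delta >= 0 retards the phase)
    pitch_um: float
    angle_deg: float

    def __post_init__(self) -> None:
        if self.mu.shape != self.phi.shape:
            raise ValueError("mu and phi grids must share a shape")


@dataclass
class ProjectionSet:
    """Recorded per-angle detector images plus the flat field."""

    images: np.ndarray         # (n_angles, n_rows, n_cols) intensities
    angles_deg: np.ndarray
    flat: np.ndarray           # (n_rows, n_cols), strictly positive
    geometry: BeamGeometry
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.images.ndim != 3 or self.flat.shape != self.images.shape[1:]:
            raise ValueError("projection stack and flat field shapes disagree")
        if np.any(self.images < 0):
            raise ValueError("intensities must be non-negative")
        if np.any(self.flat <= 0):
            raise ValueError("flat field must be strictly positive")
        a = np.asarray(self.angles_deg, dtype=float)
        if np.any(np.diff(a) <= 0) or a[0] < 0 or a[-1] >= 180.0:
            raise ValueError("angles must increase strictly within [0, 180)")


# ---------------------------------------------------------------------------
# projection


def project_mu_phi(
    volume: RefractiveVolume,
    angle_deg: float,
    geometry: BeamGeometry,
) -> PhaseAbsorptionMaps:
    """Parallel-beam line integrals of beta and delta at one view angle.

    The volume (indexed ``[z, y, x]``) is rotated about the vertical z axis
    by ``angle_deg`` with bilinear interpolation and summed along y; a point
    at (y, x) then lands on detector column
    ``c + (x - c) cos(theta) + (y - c) sin(theta)`` with ``c`` the rotation
    center ``(n - 1) / 2`` — the convention the reconstruction module
    matches.  Output maps are at the volume pitch; ``mu = (4 pi/lambda)
    ∫ beta dl`` and ``phi = -(2 pi/lambda) ∫ delta dl``.
    """
    if not 0.0 <= angle_deg < 180.0:
        raise ValueError("angle must lie in [0, 180)")
    lam = geometry.wavelength_um
    pitch = volume.pitch_um
    combo = (volume.beta + 1j * volume.delta).astype(np.complex64)
    if angle_deg != 0.0:
        combo = ndi.rotate(
            combo, angle_deg, axes=(1, 2), reshape=False, order=1, prefilter=False
        )
    integral = combo.sum(axis=1) * pitch          # (z, x), µm-weighted
    mu = (4.0 * np.pi / lam) * integral.real
    phi = -(2.0 * np.pi / lam) * integral.imag
    return PhaseAbsorptionMaps(
        mu=np.ascontiguousarray(mu, dtype=np.float64),
        phi=np.ascontiguousarray(phi, dtype=np.float64),
        pitch_um=pitch,
        angle_deg=float(angle_deg),
    )


def transmission(maps: PhaseAbsorptionMaps) -> np.ndarray:
    """Complex exit wavefield exp(-mu/2 + i*phi) for a unit incident wave."""
    return np.exp(-maps.mu / 2.0 + 1j * maps.phi)


# ---------------------------------------------------------------------------
# propagators


def _check_pitch(pitch_um: float, lam_um: float, z_um: float) -> None:
    if z_um <= 0:
        return
    limit = np.sqrt(lam_um * z_um) / 4.0
    if pitch_um > limit:
        raise ValueError(
            f"grid pitch {pitch_um:.3g} µm undersamples the Fresnel fringes; "
            f"the required pitch at this wavelength and distance is "
            f"<= {limit:.3g} µm"
        )


def _pad_edge(field: np.ndarray) -> Tuple[np.ndarray, Tuple[slice, slice]]:
    """Pad each dimension to 2x with edge replication; return crop slices."""
    ny, nx = field.shape
    py, px = ny // 2, nx // 2
    padded = np.pad(field, ((py, ny - py), (px, nx - px)), mode="edge")
    return padded, (slice(py, py + ny), slice(px, px + nx))


def propagate_angular_spectrum(
    wavefield: np.ndarray,
    wavelength_um: float,
    z_um: float,
    pitch_um: float,
) -> np.ndarray:
    """Exact free-space propagation; returns the detector-plane intensity.

    Uses the Fresnel transfer function H(u,v) = exp(-i pi lambda z (u^2+v^2))
    on a 2x edge-replicated grid (wrap-around suppression), then crops.
    Total intensity over the cropped frame is conserved for compact objects.
    """
    if z_um == 0.0:
        return np.abs(wavefield) ** 2
    _check_pitch(pitch_um, wavelength_um, z_um)
    padded, crop = _pad_edge(np.asarray(wavefield, dtype=np.complex128))
    fy = np.fft.fftfreq(padded.shape[0], d=pitch_um)
    fx = np.fft.fftfreq(padded.shape[1], d=pitch_um)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    kernel = np.exp(-1j * np.pi * wavelength_um * z_um * f2)
    out = np.fft.ifft2(np.fft.fft2(padded) * kernel)
    return np.abs(out[crop]) ** 2


def propagate_weak_object(
    maps: PhaseAbsorptionMaps,
    wavelength_um: float,
    z_um: float,
    pitch_um: Optional[float] = None,
) -> np.ndarray:
    """Linearized (weak-object transfer function) detector intensity.

    Implements F{I} = delta(u,v) - M(u,v) + 2 pi lambda z (u^2+v^2) Phi(u,v)
    with frequencies in cycles/µm.  Valid when max(mu) << 1 and phi varies
    slowly over a Fresnel-zone width; outside that regime accuracy degrades
    gracefully (no error is raised).
    """
    pitch = maps.pitch_um if pitch_um is None else pitch_um
    mu_pad, crop = _pad_edge(np.asarray(maps.mu, dtype=float))
    phi_pad, _ = _pad_edge(np.asarray(maps.phi, dtype=float))
    fy = np.fft.fftfreq(mu_pad.shape[0], d=pitch)
    fx = np.fft.fftfreq(mu_pad.shape[1], d=pitch)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    contrast = np.fft.ifft2(
        2.0 * np.pi * wavelength_um * z_um * f2 * np.fft.fft2(phi_pad)
    ).real
    intensity = 1.0 - mu_pad + contrast
    return intensity[crop]


# ---------------------------------------------------------------------------
# detector


def _overlap_matrix(n_in: int, pitch_in: float, n_out: int, pitch_out: float,
                    offset: float) -> np.ndarray:
    """Row-stochastic area-overlap weights mapping n_in bins to n_out bins."""
    w = np.zeros((n_out, n_in))
    edges_in = np.arange(n_in + 1) * pitch_in
    for j in range(n_out):
        lo = offset + j * pitch_out
        hi = lo + pitch_out
        i0 = max(int(np.floor(lo / pitch_in)), 0)
        i1 = min(int(np.ceil(hi / pitch_in)), n_in)
        for i in range(i0, i1):
            ov = min(hi, edges_in[i + 1]) - max(lo, edges_in[i])
            if ov > 0:
                w[j, i] = ov
    norm = w.sum(axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return w / norm


def bin_to_detector(
    image: np.ndarray, pitch_in_um: float, pitch_out_um: float
) -> Tuple[np.ndarray, Tuple[float, float]]:
    """Area-weighted binning from simulation pitch to detector pitch.

    The output grid is centered on the input extent, so the rotation axis
    (input center) stays at output index (n_out - 1)/2.  Returns the binned
    image and the (row, col) world offsets of the output grid origin.
    """
    if pitch_out_um < pitch_in_um:
        raise ValueError("detector pitch must not be finer than the simulation pitch")
    ny, nx = image.shape
    out_shapes, offsets, mats = [], [], []
    for n in (ny, nx):
        length = n * pitch_in_um
        n_out = max(int(np.floor(length / pitch_out_um)), 1)
        offset = (length - n_out * pitch_out_um) / 2.0
        out_shapes.append(n_out)
        offsets.append(offset)
        mats.append(_overlap_matrix(n, pitch_in_um, n_out, pitch_out_um, offset))
    binned = mats[0] @ image @ mats[1].T
    return binned, (offsets[0], offsets[1])


def _resample_maps(maps: PhaseAbsorptionMaps, factor: int) -> PhaseAbsorptionMaps:
    """Bilinear upsampling by an integer factor, center-aligned, pitch-exact."""
    if factor == 1:
        return maps
    ny, nx = maps.mu.shape
    pitch_out = maps.pitch_um / factor
    rows = (np.arange(ny * factor) + 0.5) / factor - 0.5
    cols = (np.arange(nx * factor) + 0.5) / factor - 0.5
    coords = np.meshgrid(rows, cols, indexing="ij")
    grid = np.stack([c.ravel() for c in coords])
    mu = ndi.map_coordinates(maps.mu, grid, order=1, mode="nearest").reshape(
        ny * factor, nx * factor
    )
    phi = ndi.map_coordinates(maps.phi, grid, order=1, mode="nearest").reshape(
        ny * factor, nx * factor
    )
    return PhaseAbsorptionMaps(mu=mu, phi=phi, pitch_um=pitch_out,
                               angle_deg=maps.angle_deg)


# ---------------------------------------------------------------------------
# acquisition


def acquire_ct(
    volume: RefractiveVolume,
    geometry: BeamGeometry,
    seed: int = 0,
    propagator: str = "exact",
    flat_frames: int = 20,
    progress: bool = False,
) -> ProjectionSet:
    """Simulate a full tomographic scan of the refractive volume.

    For each of ``geometry.n_angles`` equally spaced angles in [0, 180):
    project beta/delta to (mu, phi), upsample to a propagation grid that
    satisfies the sampling rules, apply the transmission function, propagate
    (exact angular-spectrum propagator by default, or the weak-object
    linearization), bin area-weighted to the detector pitch, and draw
    Poisson counts at the configured flat-field photon level.  The flat
    field is recorded the same way with no object.  Identical inputs and
    seed give bit-identical stacks.
    """
    if propagator not in ("exact", "weak"):
        raise ValueError("propagator must be 'exact' or 'weak'")
    lam = geometry.wavelength_um
    z = geometry.z_um
    noise = geometry.photons_per_pixel > 0
    if not noise:
        warnings.warn("photon count <= 0: Poisson noise disabled")
    rng = np.random.default_rng(seed)

    factor = max(int(np.ceil(volume.pitch_um / geometry.max_sim_pitch_um())), 1)
    sim_pitch = volume.pitch_um / factor

    images = []
    offsets = None
    for i, angle in enumerate(geometry.angles_deg):
        maps = project_mu_phi(volume, float(angle), geometry)
        maps = _resample_maps(maps, factor)
        if propagator == "exact":
            intensity = propagate_angular_spectrum(transmission(maps), lam, z, sim_pitch)
        else:
            intensity = propagate_weak_object(maps, lam, z, sim_pitch)
            np.clip(intensity, 0.0, None, out=intensity)
        binned, offsets = bin_to_detector(intensity, sim_pitch, geometry.detector_pitch_um)
        if noise:
            binned = rng.poisson(
                np.clip(binned, 0.0, None) * geometry.photons_per_pixel
            ).astype(np.float64)
        else:
            binned = binned * max(geometry.photons_per_pixel, 1.0)
        images.append(binned.astype(np.float32))
        if progress and (i % 50 == 0):
            print(f"  projection {i + 1}/{geometry.n_angles}")

    # flat field: mean of several no-object frames, the usual practice that
    # keeps flat-field noise from imprinting ring artifacts
    flat_exact = np.full_like(images[0], float(max(geometry.photons_per_pixel, 1.0)))
    if noise:
        frames = rng.poisson(flat_exact[None, :, :], size=(max(flat_frames, 1),)
                             + flat_exact.shape)
        flat = frames.mean(axis=0).astype(np.float32)
        flat[flat <= 0] = 1.0
    else:
        flat = flat_exact
    meta = {
        "seed": int(seed),
        "propagator": propagator,
        "sim_pitch_um": sim_pitch,
        "detector_offset_um": offsets,
        "volume_pitch_um": volume.pitch_um,
        "noise": bool(noise),
    }
    return ProjectionSet(
        images=np.stack(images),
        angles_deg=geometry.angles_deg,
        flat=flat,
        geometry=geometry,
        meta=meta,
    )
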