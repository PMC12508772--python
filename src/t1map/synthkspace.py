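"""Digital phantoms and the multi-TI acquisition forward model.

This module generates everything the reconstruction and fitting stages
need without access to scanner data: a sphere phantom with known T1 and
proton density per compartment (emulating a NiCl2-doped calibration
phantom), smooth complex coil sensitivities, variable-density random
undersampling masks with an elliptical k-space shutter, and the SENSE-type
forward model

    y_n = D_n F (S x_n) + noise,

where ``x_n`` is the complex image at inversion time TI_n, ``S`` the coil
sensitivities, ``F`` the orthonormal 3D DFT (k-space centre at the array
centre), and ``D_n`` the per-TI sampling mask over the (ky, kz)
phase-encode plane; the readout direction kx is always fully sampled.

Array conventions
-----------------
Images and k-space are indexed ``(TI, coil, kx|x, ky|y, kz|z)``; sampling
masks are ``(TI, ky, kz)`` and broadcast along the readout axis.  All
generators are deterministic under a fixed integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

__all__ = [
    "AcquisitionSpec",
    "DigitalPhantom",
    "CoilMaps",
    "SamplingMask",
    "KSpaceData",
    "ImageSeries",
    "make_ti_schedule",
    "make_sphere_phantom",
    "ir_signal",
    "simulate_image_series",
    "make_synthetic_coil_maps",
    "make_sampling_mask",
    "forward_model",
    "adjoint_model",
    "add_noise",
    "fft3",
    "ifft3",
]

# width of the always-sampled central (ky, kz) autocalibration block
CENTRE_BLOCK = 4
# additive floor of the variable-density law, keeps outer k-space reachable
DENSITY_FLOOR = 0.05


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition protocol for a multi-TI inversion-recovery scan.

    Parameters
    ----------
    ti_list : tuple of float
        Inversion times in ms, strictly increasing, all below ``tr``.
    tr : float
        Repetition time in ms.
    matrix_dims : tuple of int
        Image matrix ``(nx, ny, nz)``; ``nx`` is the readout direction.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    undersampling_factor : float
        Acceleration R >= 1 applied in the (ky, kz) plane.
    n_coils : int
        Number of receive coils.
    noise_sigma : float
        SD of the circular complex k-space noise (sqrt(E|n|^2)), in the
        arbitrary units of the simulated signal.
    """

    ti_list: tuple[float, ...] = (50.0, 91.0, 166.0, 302.0, 549.0, 999.0)
    tr: float = 1500.0
    matrix_dims: tuple[int, int, int] = (72, 88, 58)
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 3.5)
    undersampling_factor: float = 4.0
    n_coils: int = 8
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        ti = np.asarray(self.ti_list, dtype=float)
        if ti.size == 0 or np.any(np.diff(ti) <= 0):
            raise ValueError("ti_list must be non-empty and strictly increasing")
        if np.any(ti >= self.tr):
            raise ValueError("every TI must be smaller than TR")
        if len(self.matrix_dims) != 3 or any(d <= 0 for d in self.matrix_dims):
            raise ValueError("matrix_dims must be three positive integers")
        if self.undersampling_factor < 1:
            raise ValueError("undersampling factor R must be >= 1")
        if self.n_coils < 1:
            raise ValueError("n_coils must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def n_ti(self) -> int:
        return len(self.ti_list)


@dataclass
class DigitalPhantom:
    """Label volume plus per-label tissue parameters.

    ``label_volume`` holds one integer label per voxel (0 = background);
    ``t1``/``pd``/``concentration`` map each nonzero label to its
    longitudinal relaxation time (ms), proton density (a.u.) and optional
    NiCl2 concentration (mM).  ``background_phase`` is a smooth per-voxel
    phase field in radians, and ``inversion_efficiency`` the simulated
    inversion efficiency eta in (0, 1].
    """

    label_volume: np.ndarray
    t1: dict[int, float]
    pd: dict[int, float]
    concentration: dict[int, float] = field(default_factory=dict)
    background_phase: np.ndarray | None = None
    inversion_efficiency: float = 1.0

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        labels = set(np.unique(self.label_volume)) - {0}
        for lab in labels:
            if lab not in self.t1 or self.t1[lab] <= 0:
                raise ValueError(f"label {lab} needs t1 > 0")
            if self.pd.get(lab, -1.0) < 0:
                raise ValueError(f"label {lab} needs pd >= 0")
        if self.background_phase is None:
            self.background_phase = np.zeros(self.label_volume.shape)
        elif self.background_phase.shape != self.label_volume.shape:
            raise ValueError("background_phase must cover the full grid")
        if not (0 < self.inversion_efficiency <= 1):
            raise ValueError("inversion_efficiency must lie in (0, 1]")

    def parameter_volume(self, table: dict[int, float]) -> np.ndarray:
        """Expand a per-label table to a full voxel map (0 outside labels)."""
        out = np.zeros(self.label_volume.shape)
        for lab, val in table.items():
            out[self.label_volume == lab] = val
        return out

    def save(self, labels_path: str | Path, sidecar_path: str | Path,
             voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
        """Write the label volume as NIfTI plus a JSON parameter sidecar."""
        affine = np.diag(list(voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(self.label_volume.astype(np.int16), affine),
                 str(labels_path))
        side = {
            str(lab): {
                "t1_ms": self.t1[lab],
                "pd": self.pd[lab],
                "concentration_mM": self.concentration.get(lab),
            }
            for lab in sorted(set(np.unique(self.label_volume)) - {0})
        }
        Path(sidecar_path).write_text(json.dumps(side, indent=2))


@dataclass
class CoilMaps:
    """Complex receive sensitivities, root-sum-of-squares normalised.

    ``maps`` has shape ``(n_coils, nx, ny, nz)``; on the object support the
    RSS across coils equals 1.
    """

    maps: np.ndarray
    support: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("coil maps must be finite everywhere")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


@dataclass
class SamplingMask:
    """Per-TI binary sampling pattern over the (ky, kz) phase-encode plane.

    Zero everywhere outside the elliptical shutter; the central
    ``CENTRE_BLOCK`` x ``CENTRE_BLOCK`` block is always sampled.
    """

    mask: np.ndarray          # (n_ti, ny, nz), uint8
    shutter: np.ndarray       # (ny, nz), bool
    seed: int

    def density(self, ti_index: int | None = None) -> float:
        """Sampled fraction inside the shutter, per TI or averaged."""
        m = self.mask if ti_index is None else self.mask[ti_index:ti_index + 1]
        return float(m[:, self.shutter].mean())


@dataclass
class ImageSeries:
    """One complex volume per TI, shape ``(n_ti, nx, ny, nz)``."""

    data: np.ndarray
    spec: AcquisitionSpec

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        expected = (self.spec.n_ti, *self.spec.matrix_dims)
        if self.data.shape != expected:
            raise ValueError(
                f"image series shape {self.data.shape} != expected {expected}")


@dataclass
class KSpaceData:
    """Undersampled multi-coil k-space, shape ``(n_ti, n_coils, nx, ny, nz)``.

    Entries where the attached mask is zero are exactly zero.
    """

    data: np.ndarray
    mask: SamplingMask
    spec: AcquisitionSpec

    def __post_init__(self) -> None:
        expected = (self.spec.n_ti, self.spec.n_coils, *self.spec.matrix_dims)
        if self.data.shape != expected:
            raise ValueError(
                f"k-space shape {self.data.shape} != expected {expected}")

    def save_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("kspace", data=self.data.astype(np.complex64))
            f.create_dataset("mask", data=self.mask.mask.astype(np.uint8))
            f.attrs["ti_list_ms"] = np.asarray(self.spec.ti_list)
            f.attrs["tr_ms"] = self.spec.tr
            f.attrs["voxel_size_mm"] = np.asarray(self.spec.voxel_size)
            f.attrs["seed"] = self.mask.seed

    @classmethod
    def load_hdf5(cls, path: str | Path) -> "KSpaceData":
        with h5py.File(path, "r") as f:
            for name in ("kspace", "mask"):
                if name not in f:
                    raise KeyError(f"missing dataset '/{name}' in {path}")
            data = f["kspace"][...].astype(np.complex128)
            mask = f["mask"][...].astype(np.uint8)
            ti = tuple(float(t) for t in f.attrs["ti_list_ms"])
            tr = float(f.attrs["tr_ms"])
            vox = tuple(float(v) for v in f.attrs["voxel_size_mm"])
            seed = int(f.attrs.get("seed", 0))
        n_ti, n_coils, nx, ny, nz = data.shape
        shutter = _elliptical_shutter(ny, nz)
        frac = mask[:, shutter].mean() if shutter.any() else 1.0
        spec = AcquisitionSpec(ti_list=ti, tr=tr, matrix_dims=(nx, ny, nz),
                               voxel_size=vox, n_coils=n_coils,
                               undersampling_factor=max(1.0, 1.0 / max(frac, 1e-12)))
        return cls(data=data, mask=SamplingMask(mask, shutter, seed), spec=spec)


# ---------------------------------------------------------------------------
# FFT convention: orthonormal, k-space centre at the array centre
# ---------------------------------------------------------------------------

_AXES = (-3, -2, -1)


def fft3(x: np.ndarray) -> np.ndarray:
    """Centred orthonormal 3D DFT over the last three axes."""
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(x, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES)


def ifft3(k: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft3`."""
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(k, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def make_ti_schedule(t_min: float, t_max: float, n: int) -> list[int]:
    """Logarithmically spaced inversion times, rounded to integer ms.

    Returns the geometric progression from ``t_min`` to ``t_max`` with
    ``n`` terms; endpoints are preserved.  The protocol default
    ``make_ti_schedule(50, 999, 6)`` gives ``[50, 91, 166, 302, 549, 999]``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if t_min <= 0 or t_max <= 0 or t_min > t_max:
        raise ValueError("need 0 < t_min <= t_max")
    if n == 1 and t_min != t_max:
        raise ValueError("a single TI requires t_min == t_max")
    return [int(round(t)) for t in np.geomspace(t_min, t_max, n)]


def make_sphere_phantom(
    grid: tuple[int, int, int],
    spheres: list[tuple[tuple[float, float, float], float, float, float, float | None]],
) -> DigitalPhantom:
    """Build a sphere phantom on ``grid``.

    ``spheres`` is a list of ``(centre, radius, t1_ms, pd, concentration)``
    tuples in voxel coordinates.  Labels are assigned in list order
    starting at 1; where spheres overlap the later-listed sphere wins.
    A sphere larger than the grid is clipped (so a sufficiently large
    sphere labels every voxel); a centre outside the grid is an error.
    """
    labels = np.zeros(grid, dtype=np.int16)
    t1: dict[int, float] = {}
    pd: dict[int, float] = {}
    conc: dict[int, float] = {}
    coords = np.indices(grid).astype(float)
    for i, (centre, radius, t1_ms, pd_val, c) in enumerate(spheres, start=1):
        if radius <= 0:
            raise ValueError("sphere radius must be positive")
        for ax in range(3):
            if not (0 <= centre[ax] <= grid[ax] - 1):
                raise ValueError(f"sphere {i} centre lies outside the grid")
        d2 = sum((coords[ax] - centre[ax]) ** 2 for ax in range(3))
        inside = d2 <= radius ** 2
        labels[inside] = i                      # later sphere wins ties
        t1[i], pd[i] = float(t1_ms), float(pd_val)
        if c is not None:
            conc[i] = float(c)
    return DigitalPhantom(label_volume=labels, t1=t1, pd=pd, concentration=conc)


def ir_signal(ti, t1, pd=1.0, eta: float = 1.0, tr: float = np.inf):
    """Inversion-recovery signal at inversion time ``ti``.

    S(TI) = PD * (1 - (1 + eta) * exp(-TI/T1) + exp(-TR/T1)),

    with ``eta`` the inversion efficiency (eta = 1 and TR -> inf is ideal
    inversion recovery).  Monotonically increasing in TI for T1 > 0.
    Accepts scalars or broadcastable arrays.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be positive")
    ti = np.asarray(ti, dtype=float)
    if np.any(ti < 0):
        raise ValueError("ti must be >= 0")
    out = pd * (1.0 - (1.0 + eta) * np.exp(-ti / t1) + np.exp(-tr / t1))
    return out if out.shape else float(out)


def simulate_image_series(phantom: DigitalPhantom, spec: AcquisitionSpec) -> ImageSeries:
    """Noiseless complex image per TI from the phantom's tissue parameters.

    Each labelled voxel follows :func:`ir_signal`; the smooth background
    phase multiplies every TI identically; background voxels are zero.
    """
    if phantom.label_volume.shape != tuple(spec.matrix_dims):
        raise ValueError("phantom grid does not match the acquisition matrix")
    t1_vol = phantom.parameter_volume(phantom.t1)
    pd_vol = phantom.parameter_volume(phantom.pd)
    inside = phantom.label_volume > 0
    data = np.zeros((spec.n_ti, *spec.matrix_dims), dtype=np.complex128)
    phase = np.exp(1j * phantom.background_phase[inside])
    for n, ti in enumerate(spec.ti_list):
        s = ir_signal(ti, t1_vol[inside], pd_vol[inside],
                      eta=phantom.inversion_efficiency, tr=spec.tr)
        data[n][inside] = s * phase
    return ImageSeries(data=data, spec=spec)


def make_synthetic_coil_maps(n_coils: int, grid: tuple[int, int, int],
                             seed: int = 0) -> CoilMaps:
    """Smooth complex coil sensitivities, RSS-normalised to 1 everywhere.

    Gaussian magnitude lobes are placed on a ring around the (x, y)
    field-of-view (mimicking a receive array surrounding the head), each
    with a coil-specific linear phase ramp.  With a single coil the
    normalised map has unit magnitude everywhere.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    nx, ny, nz = grid
    rng = np.random.default_rng(seed)
    x, y, z = np.indices(grid).astype(float)
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    sigma = 0.6 * max(grid)
    maps = np.empty((n_coils, nx, ny, nz), dtype=np.complex128)
    for c in range(n_coils):
        theta = 2 * np.pi * c / n_coils + rng.uniform(-0.1, 0.1)
        px = cx + 0.7 * nx * np.cos(theta) / 2
        py = cy + 0.7 * ny * np.sin(theta) / 2
        d2 = (x - px) ** 2 + (y - py) ** 2 + 0.5 * (z - cz) ** 2
        mag = np.exp(-d2 / (2 * sigma ** 2))
        gx, gy, gz = rng.uniform(-np.pi, np.pi, size=3) / max(grid)
        phase = gx * (x - cx) + gy * (y - cy) + gz * (z - cz) + rng.uniform(0, 2 * np.pi)
        maps[c] = mag * np.exp(1j * phase)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= rss
    return CoilMaps(maps=maps, support=np.ones(grid, dtype=bool))


def _elliptical_shutter(ny: int, nz: int) -> np.ndarray:
    """Boolean elliptical support in the (ky, kz) plane, centred like fftshift."""
    ky, kz = np.indices((ny, nz)).astype(float)
    u = (ky - ny // 2) / (ny / 2)
    v = (kz - nz // 2) / (nz / 2)
    return u ** 2 + v ** 2 <= 1.0


def _centre_block(ny: int, nz: int) -> np.ndarray:
    blk = np.zeros((ny, nz), dtype=bool)
    cy, cz = ny // 2, nz // 2
    h = CENTRE_BLOCK // 2
    blk[max(cy - h, 0):cy + h, max(cz - h, 0):cz + h] = True
    return blk


def make_sampling_mask(spec: AcquisitionSpec, seed: int) -> SamplingMask:
    """Variable-density random sampling with an elliptical k-space shutter.

    Sampling probability decays with the normalised elliptical radius r as
    ``(1 - r)^2 + DENSITY_FLOOR``.  Exactly ``round(n_shutter / R)`` points
    are drawn per TI (weighted, without replacement), so the realised
    density inside the shutter matches 1/R up to rounding; the central
    4 x 4 block is always included; the masks are drawn independently per
    TI and are reproducible under the seed.
    """
    _, ny, nz = spec.matrix_dims
    R = spec.undersampling_factor
    shutter = _elliptical_shutter(ny, nz)
    centre = _centre_block(ny, nz) & shutter
    n_shutter = int(shutter.sum())
    n_target = int(round(n_shutter / R))
    n_centre = int(centre.sum())
    if n_target < n_centre:
        raise ValueError(
            f"R = {R} not achievable: target {n_target} samples < "
            f"{n_centre} forced centre samples")
    ky, kz = np.indices((ny, nz)).astype(float)
    r = np.sqrt(((ky - ny // 2) / (ny / 2)) ** 2 + ((kz - nz // 2) / (nz / 2)) ** 2)
    weights = (1.0 - np.clip(r, 0, 1)) ** 2 + DENSITY_FLOOR
    candidates = np.flatnonzero(shutter & ~centre)
    w = weights.ravel()[candidates]
    w = w / w.sum()
    mask = np.zeros((spec.n_ti, ny, nz), dtype=np.uint8)
    for n in range(spec.n_ti):
        rng = np.random.default_rng([seed, n])
        m = centre.copy()
        n_extra = n_target - n_centre
        if n_extra > 0:
            chosen = rng.choice(candidates, size=min(n_extra, candidates.size),
                                replace=False, p=w)
            m.ravel()[chosen] = True
        mask[n] = m.astype(np.uint8)
    return SamplingMask(mask=mask, shutter=shutter, seed=seed)


def forward_model(images: ImageSeries, maps: CoilMaps,
                  mask: SamplingMask) -> KSpaceData:
    """Apply the acquisition operator: per TI and coil, ``mask * F(S_c x_n)``.

    Unsampled k-space entries are exactly zero.
    """
    x = images.data
    spec = images.spec
    if maps.maps.shape[1:] != x.shape[1:]:
        raise ValueError("coil maps do not match the image grid")
    if mask.mask.shape != (spec.n_ti, x.shape[2], x.shape[3]):
        raise ValueError("mask shape does not match (n_ti, ny, nz)")
    if maps.n_coils != spec.n_coils:
        spec = dataclasses.replace(spec, n_coils=maps.n_coils)
    ksp = np.empty((spec.n_ti, maps.n_coils, *x.shape[1:]), dtype=np.complex128)
    for n in range(spec.n_ti):
        weighted = maps.maps * x[n][None]          # (coil, x, y, z)
        ksp[n] = fft3(weighted) * mask.mask[n][None, None]
    return KSpaceData(data=ksp, mask=mask, spec=spec)


def adjoint_model(ksp: KSpaceData, maps: CoilMaps) -> ImageSeries:
    """Adjoint of :func:`forward_model`: ``sum_c conj(S_c) F^H (mask * y)``."""
    # mask is (n_ti, ny, nz); broadcast along coil and kx
    y = ksp.data * ksp.mask.mask[:, None, None, :, :]
    imgs = np.sum(np.conj(maps.maps)[None] * ifft3(y), axis=1)
    return ImageSeries(data=imgs, spec=ksp.spec)


def add_noise(ksp: KSpaceData, sigma: float, seed: int) -> KSpaceData:
    """Add i.i.d. circular complex Gaussian noise at sampled locations only.

    ``sigma`` is the complex SD, i.e. sqrt(E|n|^2); each real and imaginary
    component has SD ``sigma / sqrt(2)``.  With ``sigma = 0`` the input is
    returned unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return ksp
    rng = np.random.default_rng(seed)
    sampled = ksp.mask.mask[:, None, None, :, :].astype(bool)
    sampled = np.broadcast_to(sampled, ksp.data.shape)
    n_samp = int(sampled.sum())
    noise = (rng.standard_normal(n_samp) + 1j * rng.standard_normal(n_samp))
    noise *= sigma / np.sqrt(2.0)
    data = ksp.data.copy()
    data[sampled] += noise
    return KSpaceData(data=data, mask=ksp.mask, spec=ksp.spec)
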