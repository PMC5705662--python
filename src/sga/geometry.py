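"""Voxel geometry: camera pixel size, magnification and z-step.

All image-space computation in this package runs in voxel units with 0-based
(z, y, x) coordinates; physical micrometres enter only through this module,
at I/O boundaries and when volumes are reported.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical geometry of one imaging voxel.

    Parameters
    ----------
    camera_pixel_um
        Edge length of one camera pixel on the chip, in micrometres.
    magnification
        Total optical magnification (dimensionless).
    z_step_um
        Axial spacing between consecutive z-planes, in micrometres.

    The lateral sample-space pixel size is ``camera_pixel_um / magnification``
    and the voxel volume is ``lateral² × z_step``.
    """

    camera_pixel_um: float
    magnification: float
    z_step_um: float

    def __post_init__(self) -> None:
        for name in ("camera_pixel_um", "magnification", "z_step_um"):
            value = getattr(self, name)
            if not (value > 0):
                raise ValueError(f"{name} must be positive, got {value!r}")

    @property
    def lateral_um(self) -> float:
        """Lateral voxel edge in sample space (µm)."""
        return self.camera_pixel_um / self.magnification

    @property
    def voxel_volume_um3(self) -> float:
        """Volume of one voxel (µm³)."""
        return self.lateral_um**2 * self.z_step_um

    def sigma_um_to_voxels(self, sigma_lateral_um: float, sigma_axial_um: float) -> tuple[float, float, float]:
        """Convert an anisotropic PSF sigma (lateral, axial) in µm to (z, y, x) voxels."""
        return (
            sigma_axial_um / self.z_step_um,
            sigma_lateral_um / self.lateral_um,
            sigma_lateral_um / self.lateral_um,
        )

    @property
    def z_aspect(self) -> float:
        """Ratio of axial to lateral voxel size; used to scale z-distances."""
        return self.z_step_um / self.lateral_um


#: Geometry of the back-illuminated CCD / 100x oil objective setup the method
#: was developed on: 13 µm camera pixels, 100x, 0.5 µm z-steps.
DEFAULT_GEOMETRY = VoxelGeometry(camera_pixel_um=13.0, magnification=100.0, z_step_um=0.5)


def voxel_volume(geometry: VoxelGeometry) -> float:
    """Voxel volume in µm³ (lateral² × z-step)."""
    return geometry.voxel_volume_um3


def format_voxel_volume(geometry: VoxelGeometry, sig_figs: int = 2) -> str:
    """Two-significant-figure scientific rendering, e.g. ``'8.5 × 10⁻³'``."""
    v = geometry.voxel_volume_um3
    exponent = 0
    mantissa = v
    while mantissa < 1:
        mantissa *= 10
        exponent -= 1
    while mantissa >= 10:
        mantissa /= 10
        exponent += 1
    mantissa = round(mantissa, sig_figs - 1)
    if mantissa >= 10:  # rounding can carry over
        mantissa /= 10
        exponent += 1
    superscript = str(exponent).translate(str.maketrans("-0123456789", "⁻⁰¹²³⁴⁵⁶⁷⁸⁹"))
    return f"{mantissa:g} × 10{superscript}"
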