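"""Registered two-channel 3D volumes and their TIFF + sidecar layout.

A :class:`SnarfVolume` holds one acquisition timepoint: a 3D intensity array
per Raman shift (2850 and 2930 cm^-1), the physical voxel size and the
nominal interval between repeated acquisitions. Axis order is fixed as
(z, y, x) with z increasing with depth below the pial surface.

On disk a volume directory contains one multi-page TIFF per channel per
timepoint (``t{tp}_ch{wavenumber}.tif``, pages = z slices) plus a YAML
sidecar ``volume_meta.yaml`` recording voxel size and channel identities, so
no voxel-unit number crosses a file boundary without its physical scale.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import tifffile
import yaml

#: Raman shifts (cm^-1) of the two SRS channels.
WAVENUMBERS = (2850, 2930)

SIDECAR_NAME = "volume_meta.yaml"


class RegistrationError(ValueError):
    """Raised when two volumes expected to be co-registered disagree in shape."""


@dataclasses.dataclass
class SnarfVolume:
    """Two-channel 3D intensity volume at one timepoint.

    Parameters
    ----------
    channels
        Mapping wavenumber (cm^-1) -> 3D float array, axis order (z, y, x).
    voxel_size
        Physical voxel edge lengths in µm, ordered (z, y, x).
    timepoint
        Acquisition index (1-based).
    acquisition_interval
        Nominal minutes between repeated acquisitions of the same volume.
    """

    channels: dict[int, np.ndarray]
    voxel_size: tuple[float, float, float]
    timepoint: int = 1
    acquisition_interval: float = 15.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel required")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel arrays differ in shape: {shapes}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        for wn, arr in self.channels.items():
            if arr.ndim != 3:
                raise ValueError(f"channel {wn} is not 3D")
            if np.any(arr < 0):
                raise ValueError(f"channel {wn} has negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, wavenumber: int) -> np.ndarray:
        return self.channels[wavenumber]

    def mean_channel(self) -> np.ndarray:
        """Voxelwise mean over the two channels (used for generic intensity gates)."""
        stack = np.stack(list(self.channels.values()))
        return stack.mean(axis=0)

    def check_registered(self, other: "SnarfVolume") -> None:
        if self.shape != other.shape:
            raise RegistrationError(
                f"volumes not co-registered: {self.shape} vs {other.shape}"
            )

    # ------------------------------------------------------------------ I/O

    def save(self, outdir: str | Path) -> None:
        """Write one TIFF per channel plus (or updating) the YAML sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for wn, arr in self.channels.items():
            write_stack(outdir / f"t{self.timepoint}_ch{wn}.tif", arr.astype(np.float32))
        meta_path = outdir / SIDECAR_NAME
        meta = {}
        if meta_path.exists():
            meta = yaml.safe_load(meta_path.read_text()) or {}
        meta.update(
            {
                "voxel_size_um": [float(v) for v in self.voxel_size],
                "channels_cm-1": sorted(int(w) for w in self.channels),
                "acquisition_interval_min": float(self.acquisition_interval),
            }
        )
        tps = set(meta.get("timepoints", []))
        tps.add(int(self.timepoint))
        meta["timepoints"] = sorted(tps)
        meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))

    @classmethod
    def load(cls, indir: str | Path, timepoint: int = 1) -> "SnarfVolume":
        indir = Path(indir)
        meta = yaml.safe_load((indir / SIDECAR_NAME).read_text())
        channels = {}
        for wn in meta["channels_cm-1"]:
            path = indir / f"t{timepoint}_ch{wn}.tif"
            if not path.exists():
                raise FileNotFoundError(path)
            channels[int(wn)] = tifffile.imread(path)
        return cls(
            channels=channels,
            voxel_size=tuple(meta["voxel_size_um"]),
            timepoint=timepoint,
            acquisition_interval=float(meta.get("acquisition_interval_min", 15.0)),
        )


def write_stack(path: str | Path, arr: np.ndarray) -> None:
    """Write a 3D array as a multi-page TIFF (pages = z slices), deterministically."""
    tifffile.imwrite(Path(path), np.asarray(arr), photometric="minisblack")


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))
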