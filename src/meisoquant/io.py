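"""Standard-format I/O: calibrated TIFF images, CSV force curves and tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .afm import ForceCurve
from .images import IntensityImage

__all__ = ["load_image", "save_image", "read_force_curve", "write_force_curve"]

_ACCEPTED = (".tif", ".tiff")


def _pixel_size_from_tags(page: "tifffile.TiffPage") -> float | None:
    """Pixel size in µm from TIFF resolution tags, if present and sane."""
    tags = page.tags
    xres = tags.get("XResolution")
    unit = tags.get("ResolutionUnit")
    if xres is None:
        return None
    num, den = xres.value
    if num == 0:
        return None
    pixels_per_unit = num / den
    unit_val = getattr(unit, "value", None)
    unit_val = getattr(unit_val, "value", unit_val)  # enum -> int
    if unit_val == 3:  # centimetre
        return 1e4 / pixels_per_unit
    if unit_val == 2:  # inch
        return 2.54e4 / pixels_per_unit
    return None


def load_image(
    path: str | Path,
    pixel_size_um: float | None = None,
    channel: int | None = None,
) -> IntensityImage:
    """Read a single-channel 8/16-bit TIFF as an :class:`IntensityImage`.

    The pixel size is taken from the ``pixel_size_um`` argument when given
    (it always wins), else from the TIFF resolution tags; if neither is
    available the call fails. Multi-channel files require ``channel``.
    """
    path = Path(path)
    if path.suffix.lower() not in _ACCEPTED:
        raise ValueError(
            f"unsupported format {path.suffix!r}: accepted formats are {_ACCEPTED}"
        )
    with tifffile.TiffFile(path) as tf:
        values = tf.asarray()
        tag_px = _pixel_size_from_tags(tf.pages[0])
        bit_depth = tf.pages[0].bitspersample
    if values.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path.name} has {values.shape} samples; pass channel= to select one"
            )
        values = values[channel] if values.shape[0] <= 4 else values[..., channel]
    if values.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {values.shape}")
    px = pixel_size_um if pixel_size_um is not None else tag_px
    if px is None:
        raise ValueError(
            f"{path.name}: no pixel size in TIFF tags and none supplied"
        )
    return IntensityImage(values, px, bit_depth=bit_depth)


def save_image(path: str | Path, img: IntensityImage) -> None:
    """Write a 16-bit TIFF with resolution tags encoding the pixel size."""
    path = Path(path)
    values = img.values
    if np.allclose(values, np.round(values)) and values.max() <= 65535:
        data = values.astype(np.uint16)
    else:
        data = values.astype(np.float32)
    pixels_per_cm = 1e4 / img.pixel_size_um
    tifffile.imwrite(
        path, data, resolution=(pixels_per_cm, pixels_per_cm), resolutionunit="CENTIMETER"
    )


def read_force_curve(path: str | Path, k_n_per_m: float | None = None) -> ForceCurve:
    """Read a two-column CSV/TSV force curve.

    Columns: ``height_nm`` plus either ``force_nN`` or ``deflection_nm``
    (the latter requires the cantilever stiffness to convert, F = k·d).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower().strip(): c for c in df.columns}
    if "height_nm" not in cols:
        raise ValueError(f"{path.name}: expected a 'height_nm' column, got {list(df.columns)}")
    z = df[cols["height_nm"]].to_numpy(float)
    if "force_nn" in cols:
        return ForceCurve(z, df[cols["force_nn"]].to_numpy(float), k_n_per_m)
    if "deflection_nm" in cols:
        if k_n_per_m is None:
            raise ValueError(f"{path.name}: deflection data needs the cantilever stiffness")
        return ForceCurve.from_deflection(z, df[cols["deflection_nm"]].to_numpy(float), k_n_per_m)
    raise ValueError(f"{path.name}: need a 'force_nN' or 'deflection_nm' column")


def write_force_curve(path: str | Path, curve: ForceCurve) -> None:
    pd.DataFrame({"height_nm": curve.z_nm, "force_nN": curve.force_nN}).to_csv(
        path, index=False
    )
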