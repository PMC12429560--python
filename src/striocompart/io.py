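"""File formats: single-channel TIFF (16-bit) / PNG (8-bit) for section
channels, indexed PNG with a documented palette for label maps, tidy CSV
for records, YAML for configs."""
from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .types import LabelMap, SectionImage, LABEL_PALETTE, VESSEL


def save_channel(path: str | Path, channel: np.ndarray, bit_depth: int = 8) -> None:
    """Write one gray-level channel; .tif gets 16-bit, .png 8-bit."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        scale = (2**16 - 1) / (2**bit_depth - 1)
        tifffile.imwrite(path, np.clip(channel * scale, 0, 2**16 - 1).astype(np.uint16))
    else:
        from PIL import Image

        arr = np.clip(channel, 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(path)


def load_channel(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path).astype(np.float32)
        return arr * (255.0 / (2**16 - 1))
    from PIL import Image

    return np.asarray(Image.open(path).convert("L"), dtype=np.float32)


def save_section(prefix: str | Path, section: SectionImage, fmt: str = "png") -> tuple[Path, Path]:
    prefix = Path(prefix)
    ref = prefix.with_name(prefix.name + f"_ref.{fmt}")
    tgt = prefix.with_name(prefix.name + f"_target.{fmt}")
    save_channel(ref, section.reference_channel, section.bit_depth)
    save_channel(tgt, section.target_channel, section.bit_depth)
    return ref, tgt


def save_labelmap(path: str | Path, labels: LabelMap) -> None:
    """Indexed PNG; palette entries follow :data:`LABEL_PALETTE`."""
    from PIL import Image

    img = Image.fromarray(labels.labels.astype(np.uint8), mode="P")
    palette = []
    for code in range(VESSEL + 1):
        palette.extend(LABEL_PALETTE[code])
    img.putpalette(palette)
    img.save(path)


def load_labelmap(path: str | Path) -> LabelMap:
    from PIL import Image

    img = Image.open(path)
    if img.mode != "P":
        img = img.convert("L")
    return LabelMap(np.asarray(img, dtype=np.uint8))


def save_config(path: str | Path, config) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
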