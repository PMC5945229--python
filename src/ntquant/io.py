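"""Reading and writing of label stacks, tables and models.

Label images and intensity channels travel together as multi-page TIFF: the
first page is the integer label image, subsequent pages the named channels.
Channel names are stored in the TIFF ImageDescription as JSON, so a stack
round-trips without a sidecar; an explicit channel map passed by the caller
overrides the embedded names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["write_label_stack", "load_label_stack", "StackFormatError"]


class StackFormatError(ValueError):
    """A TIFF stack does not match the expected label + channels layout."""


def write_label_stack(path, label_image: np.ndarray,
                      channels: dict[str, np.ndarray]) -> None:
    """Write a label image plus named channels as one multi-page TIFF."""
    path = Path(path)
    names = list(channels)
    pages = [np.asarray(label_image)]
    for n in names:
        ch = np.asarray(channels[n])
        if ch.shape != pages[0].shape:
            raise StackFormatError(f"channel {n!r} shape {ch.shape} != label "
                                   f"shape {pages[0].shape}")
        pages.append(ch)
    description = json.dumps({"pages": ["label"] + names})
    # pages are independent planes, never RGB components
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack",
                     description=description)


def load_label_stack(path, channel_names: list[str] | None = None):
    """Load a multi-page TIFF written by :func:`write_label_stack`.

    Returns ``(label_image, channels, metadata)``.  ``channel_names``, when
    given, overrides the embedded page names (and must cover every non-label
    page).  Fails with a page report when the label page is not
    integer-typed or a requested channel is missing.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        description = tif.pages[0].description
    if pages.ndim == 2:
        pages = pages[None]
    meta = {}
    try:
        meta = json.loads(description) if description else {}
    except json.JSONDecodeError:
        meta = {}
    names = meta.get("pages")
    if channel_names is not None:
        names = ["label"] + list(channel_names)
    if names is None or len(names) != len(pages):
        raise StackFormatError(
            f"{path}: {len(pages)} pages but page names are {names!r}")
    label = pages[0]
    if not np.issubdtype(label.dtype, np.integer):
        raise StackFormatError(
            f"{path}: label page has dtype {label.dtype}, expected integer "
            f"(pages: {names})")
    channels = {n: pages[i] for i, n in enumerate(names) if i > 0}
    return label, channels, {"pages": names, "path": str(path)}
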