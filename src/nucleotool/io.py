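"""Gzip-transparent text I/O.

Readers sniff the gzip magic bytes so ``.gz`` and plain files are
interchangeable regardless of their extension; writers compress when the
target path ends in ``.gz``.
"""

from __future__ import annotations

from pathlib import Path
from typing import IO, Union

import gzip

GZIP_MAGIC = b"\x1f\x8b"

PathLike = Union[str, Path]


def xopen(path: PathLike, mode: str = "rt") -> IO:
    """Open ``path`` for text I/O, transparently handling gzip.

    For read modes the file content decides (magic bytes), for write modes
    the ``.gz`` suffix decides.
    """
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == GZIP_MAGIC:
            return gzip.open(path, mode)
        return open(path, mode)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)
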