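"""Small shared helpers: chromosome ordering and atomic file writes."""

from __future__ import annotations

import os
from typing import Tuple


def chrom_sort_key(chrom: str) -> Tuple[int, int, str]:
    """Total order on chromosome names: numeric first (1..22), then X, Y, MT,
    then anything else lexicographically. 'chr' prefixes are ignored."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if name.upper() in special:
        return (0, special[name.upper()], "")
    return (1, 0, name)


def atomic_write_text(path: str, text: str) -> None:
    """Write text via a .partial temp file so failures never leave a
    truncated file under the final name."""
    tmp = f"{path}.partial"
    with open(tmp, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)
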