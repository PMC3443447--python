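"""Tissue color-phenotype map.

The map assigns a pigment color (red / yellow / black) to every hybridized
tissue, i.e. to each (wing, morph, section) combination.  It is shipped as an
editable YAML table so that a different cross or race panel can be analyzed
by swapping the file, without touching code.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

COLORS = ("red", "yellow", "black")


@lru_cache(maxsize=4)
def load_phenotype_map(path: str | None = None) -> dict:
    """Load the (wing, morph, section) -> color table.

    Parameters
    ----------
    path
        Optional path to a YAML override; by default the packaged table is
        used.

    Returns
    -------
    dict
        Nested mapping ``{wing: {morph: {section: color}}}``.
    """
    if path is None:
        text = resources.files("wingarray.data").joinpath("phenotype_map.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    pmap = yaml.safe_load(text)
    for wing, morphs in pmap.items():
        for morph, sections in morphs.items():
            for section, color in sections.items():
                if color not in COLORS:
                    raise ValueError(
                        f"phenotype map entry ({wing}, {morph}, {section}) has "
                        f"unknown color {color!r}; expected one of {COLORS}"
                    )
    return pmap


def tissue_color(wing: str, morph: str, section: str, pmap: dict | None = None) -> str:
    """Color of one tissue; pure function of (wing, morph, section)."""
    if pmap is None:
        pmap = load_phenotype_map()
    try:
        return pmap[wing][morph][section]
    except KeyError as exc:
        raise KeyError(f"no phenotype entry for ({wing}, {morph}, {section})") from exc
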