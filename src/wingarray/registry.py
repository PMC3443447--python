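"""Closed registry of pairwise comparisons, per analysis family.

Every contrast the pipeline can test is enumerated here with a canonical
``comparison_id``, so that downstream filtering (which comparisons count for
FDR, which feed the red-consistency score) is done by id against a closed
list rather than by ad-hoc string matching.

Families
--------
``section``   forewing wing-section pairs within each stage, morphs pooled
              (the proximal-distal analysis).
``color``     red/yellow/black pairs within each stage on the combined
              forewing + hindwing data.
``pairwise``  tissue pairs within each stage, per wing: forewing tissues are
              (morph, section) cells compared either between sections within
              a morph or between morphs for the same section; hindwing
              tissues are the three races.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd
import yaml

from .config import (
    FOREWING_MORPHS,
    FOREWING_SECTIONS,
    HINDWING_RACES,
    STAGES,
)
from .phenotypes import COLORS


@dataclass(frozen=True)
class Comparison:
    """One two-group contrast: samples matching ``a`` vs samples matching ``b``.

    ``a`` and ``b`` are dicts of design-column -> required value.
    """

    comparison_id: str
    stage: str
    a: tuple[tuple[str, str], ...]
    b: tuple[tuple[str, str], ...]

    def masks(self, design: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
        ma = pd.Series(True, index=design.index)
        for col, val in self.a:
            ma &= design[col] == val
        mb = pd.Series(True, index=design.index)
        for col, val in self.b:
            mb &= design[col] == val
        return ma, mb


def _cmp(comp_id, stage, a: dict, b: dict) -> Comparison:
    return Comparison(comp_id, stage, tuple(sorted(a.items())), tuple(sorted(b.items())))


def section_comparisons() -> list[Comparison]:
    """Forewing section pairs within stage, morphs pooled (3 x 5 = 15)."""
    out = []
    for stage in STAGES:
        for s1, s2 in combinations(FOREWING_SECTIONS, 2):
            out.append(_cmp(
                f"sec:{stage}:{s1}_vs_{s2}", stage,
                {"wing": "forewing", "stage": stage, "section": s1},
                {"wing": "forewing", "stage": stage, "section": s2},
            ))
    return out


def color_comparisons() -> list[Comparison]:
    """Color pairs within stage on the combined dataset (3 x 5 = 15)."""
    out = []
    for stage in STAGES:
        for c1, c2 in combinations(COLORS, 2):
            out.append(_cmp(
                f"color:{stage}:{c1}_vs_{c2}", stage,
                {"stage": stage, "color": c1},
                {"stage": stage, "color": c2},
            ))
    return out


def pairwise_comparisons(wing: str) -> list[Comparison]:
    """Within-stage tissue pairs for one wing.

    Forewing: between sections within a morph (6) plus the same section
    between morphs (3) per stage -> 45.  Hindwing: race pairs, 3 per
    stage -> 15.
    """
    out = []
    if wing == "forewing":
        for stage in STAGES:
            for morph in FOREWING_MORPHS:
                for s1, s2 in combinations(FOREWING_SECTIONS, 2):
                    out.append(_cmp(
                        f"pw:{stage}:{morph}.{s1}_vs_{morph}.{s2}", stage,
                        {"wing": "forewing", "stage": stage, "morph": morph, "section": s1},
                        {"wing": "forewing", "stage": stage, "morph": morph, "section": s2},
                    ))
            m1, m2 = FOREWING_MORPHS
            for sec in FOREWING_SECTIONS:
                out.append(_cmp(
                    f"pw:{stage}:{m1}.{sec}_vs_{m2}.{sec}", stage,
                    {"wing": "forewing", "stage": stage, "morph": m1, "section": sec},
                    {"wing": "forewing", "stage": stage, "morph": m2, "section": sec},
                ))
    elif wing == "hindwing":
        for stage in STAGES:
            for r1, r2 in combinations(HINDWING_RACES, 2):
                out.append(_cmp(
                    f"pw:{stage}:{r1}_vs_{r2}", stage,
                    {"wing": "hindwing", "stage": stage, "morph": r1},
                    {"wing": "hindwing", "stage": stage, "morph": r2},
                ))
    else:
        raise ValueError(f"unknown wing {wing!r}")
    return out


#: The eight tissue pairs in which a truly red-specific gene must show
#: differential expression: red-vs-black and red-vs-yellow hindwing races,
#: section pairs within each forewing morph that cross a red boundary, and
#: the same-section morph pairs whose colors differ because of red.  Pairs
#: of two black tissues or yellow-vs-black pairs are excluded.
RED_CONSISTENCY_PAIRS = (
    ("hindwing", ("emma",), ("amphitrite",)),          # red vs black HW
    ("hindwing", ("emma",), ("favorinus",)),           # red vs yellow HW
    ("forewing", ("hybrid", "proximal"), ("hybrid", "medial")),        # red vs yellow
    ("forewing", ("hybrid", "proximal"), ("hybrid", "distal")),        # red vs black
    ("forewing", ("petiverana", "proximal"), ("petiverana", "medial")),  # black vs red
    ("forewing", ("petiverana", "medial"), ("petiverana", "distal")),    # red vs black
    ("forewing", ("petiverana", "proximal"), ("hybrid", "proximal")),    # black vs red
    ("forewing", ("petiverana", "medial"), ("hybrid", "medial")),        # red vs yellow
)


def red_consistency_set(stages: tuple[str, ...] = STAGES) -> list[str]:
    """Comparison ids of the red-consistency set: 8 tissue pairs x stages."""
    ids = []
    for stage in stages:
        for wing, a, b in RED_CONSISTENCY_PAIRS:
            if wing == "hindwing":
                ids.append(f"pw:{stage}:{a[0]}_vs_{b[0]}")
            else:
                ids.append(f"pw:{stage}:{a[0]}.{a[1]}_vs_{b[0]}.{b[1]}")
    return ids


def registry_to_yaml(path: str) -> None:
    """Write the full comparison registry (all families) as YAML."""
    doc = {
        "section": [c.comparison_id for c in section_comparisons()],
        "color": [c.comparison_id for c in color_comparisons()],
        "pairwise_forewing": [c.comparison_id for c in pairwise_comparisons("forewing")],
        "pairwise_hindwing": [c.comparison_id for c in pairwise_comparisons("hindwing")],
        "red_consistency": red_consistency_set(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
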