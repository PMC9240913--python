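"""Active/inactive conformation calls from two C-terminal contact regions.

Active nuclear-receptor LBD conformations pack the C-terminal helices (HX,
H12) against the body of the domain, which shows up in the contact map as
two dense blocks absent from inactive conformations:

* region 1 — contacts (i, j) with 300 < i < 340 and j > 475
  (helices H3–H4 against HX–H12);
* region 2 — contacts with 470 < i < 495, i < j and j > 490
  (HX against H12).

A structure is called ACTIVE when the combined count in the two regions
reaches the cutoff (default 60; 60 and above is active).  All inequalities
are strict and each unordered pair is counted once with i the smaller index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .contacts import ContactMatrix

ACTIVITY_CUTOFF = 60

REGION1 = dict(i_lo=300, i_hi=340, j_min=475)  # 300 < i < 340, j > 475
REGION2 = dict(i_lo=470, i_hi=495, j_min=490)  # 470 < i < 495, i < j, j > 490

# The two i-ranges (300,340) and (470,495) are disjoint, so no contact can be
# counted in both regions.
assert REGION1["i_hi"] <= REGION2["i_lo"]


@dataclass(frozen=True)
class ActivityCall:
    structure_id: str
    region1_count: int
    region2_count: int
    label: str  # "ACTIVE" | "INACTIVE"
    cutoff_used: int

    @property
    def total(self) -> int:
        return self.region1_count + self.region2_count


def _in_region1(i: int, j: int) -> bool:
    return REGION1["i_lo"] < i < REGION1["i_hi"] and j > REGION1["j_min"]


def _in_region2(i: int, j: int) -> bool:
    return REGION2["i_lo"] < i < REGION2["i_hi"] and i < j and j > REGION2["j_min"]


def region_contact_counts(m: ContactMatrix) -> tuple[int, int]:
    """Counts of contacts falling in region 1 and region 2.

    The matrix window must reach the C-terminus; when it stops before
    residue 476 no region-1 contact can exist and the structure will look
    inactive purely for lack of coordinates (entries with an unresolved
    C-terminus have exactly this artefact), so a warning is emitted and the
    counts are computed over the available indices.
    """
    if m.hi < REGION1["j_min"] + 1:
        warnings.warn(
            f"contact-map window ends at {m.hi} < 476: region counts computed on "
            "available residues only; the INACTIVE call may be an artefact of an "
            "unresolved C-terminus",
            stacklevel=2,
        )
    r1 = r2 = 0
    for i, j in m.contact_pairs():  # i < j by construction
        if _in_region1(i, j):
            r1 += 1
        elif _in_region2(i, j):
            r2 += 1
    return r1, r2


def classify_activity(m: ContactMatrix, cutoff: int = ACTIVITY_CUTOFF) -> ActivityCall:
    """ACTIVE iff region1 + region2 contact count ≥ cutoff."""
    r1, r2 = region_contact_counts(m)
    label = "ACTIVE" if r1 + r2 >= cutoff else "INACTIVE"
    return ActivityCall(
        structure_id=m.structure_id,
        region1_count=r1,
        region2_count=r2,
        label=label,
        cutoff_used=cutoff,
    )


def classify_ensemble(maps: list[ContactMatrix], cutoff: int = ACTIVITY_CUTOFF) -> list[ActivityCall]:
    return [classify_activity(m, cutoff=cutoff) for m in maps]


def calls_to_tsv(calls: list[ActivityCall]) -> str:
    lines = ["structure_id\tregion1\tregion2\ttotal\tlabel"]
    lines += [
        f"{c.structure_id}\t{c.region1_count}\t{c.region2_count}\t{c.total}\t{c.label}"
        for c in calls
    ]
    return "\n".join(lines) + "\n"
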