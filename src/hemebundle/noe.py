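"""NOE intensity calibration, restraint bookkeeping and isomer assignment.

Cross-peak intensities follow the inverse-sixth-power distance law
I ∝ r⁻⁶, so a single reference pair (d_ref, I_ref) converts intensities
into distance upper limits d = d_ref · (I_ref/I)^(1/6) (CALIBA-style
single-curve calibration; per-class reference pairs can be supplied via
config).  Restraints are classed by sequence separation, and rule tables
encode how the porphyrin-contact patterns identify the regioisomer
(which propionate anchors which chain) and the Δ/Λ diastereomer (which
face of the porphyrin the proximal chain occupies).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AmbiguityError,
    UndeterminedError,
    ValidationError,
)
from .structure_io import PorphyrinTopology

__all__ = [
    "NOEPeak",
    "DistanceRestraint",
    "ContactPattern",
    "RestraintCounts",
    "calibrate_noe",
    "classify_sequence_separation",
    "count_restraint_classes",
    "assign_regioisomer",
    "assign_diastereomer",
    "read_peak_list",
    "write_upper_limits",
]

AtomId = tuple[str, int, str]  # (chain, residue number, atom name)

BOUND_FLOOR = 1.8   # Å, van der Waals contact
BOUND_CAP = 7.0     # Å, longest usable NOE upper limit


@dataclass(frozen=True)
class NOEPeak:
    """One assigned dipolar connectivity with its NOESY intensity."""

    atom_a: AtomId
    atom_b: AtomId
    intensity: float

    def __post_init__(self):
        if self.intensity <= 0:
            raise ValidationError(
                f"peak {self.atom_a}-{self.atom_b}: intensity must be > 0"
            )
        if self.atom_a == self.atom_b:
            raise ValidationError("peak assigned to a single proton")


@dataclass(frozen=True)
class DistanceRestraint:
    atom_a: AtomId
    atom_b: AtomId
    upper_bound: float
    seq_class: str          # intraresidue | sequential | medium | long
    raw_bound: float        # pre-clamp value, for round-trip checks


def classify_sequence_separation(
    atom_a: AtomId,
    atom_b: AtomId,
    porphyrin_chains: frozenset[str] = frozenset({"X"}),
) -> str:
    """Sequence-separation class of an atom pair.

    Same chain: |i−j| = 0 intraresidue, 1 sequential, 2–4 medium-range.
    |i−j| ≥ 5, inter-chain, and peptide↔porphyrin contacts are all
    long-range (inter-moiety contacts carry the fold information).
    """
    ca, ra, _ = atom_a
    cb, rb, _ = atom_b
    if ca != cb or ca in porphyrin_chains or cb in porphyrin_chains:
        return "long"
    sep = abs(ra - rb)
    if sep == 0:
        return "intraresidue"
    if sep == 1:
        return "sequential"
    if sep <= 4:
        return "medium"
    return "long"


def calibrate_noe(
    peaks: Sequence[NOEPeak],
    reference: tuple[float, float],
    floor: float = BOUND_FLOOR,
    cap: float = BOUND_CAP,
    porphyrin_chains: Iterable[str] = ("X",),
) -> list[DistanceRestraint]:
    """Convert NOE intensities into distance upper limits.

    ``reference`` is ``(d_ref, I_ref)``: a proton pair of known distance
    and its intensity.  Bounds are d_ref·(I_ref/I)^(1/6), clamped to
    [floor, cap]; multiplying every intensity and I_ref by a common
    factor leaves the bounds unchanged.
    """
    d_ref, i_ref = reference
    if i_ref <= 0:
        raise ValidationError("reference intensity must be > 0")
    if not (BOUND_FLOOR <= d_ref <= 5.5):
        raise ValidationError(f"reference distance {d_ref} outside [1.8, 5.5] Å")
    pc = frozenset(porphyrin_chains)
    out = []
    for p in peaks:
        raw = d_ref * (i_ref / p.intensity) ** (1.0 / 6.0)
        out.append(
            DistanceRestraint(
                atom_a=p.atom_a,
                atom_b=p.atom_b,
                upper_bound=float(np.clip(raw, floor, cap)),
                seq_class=classify_sequence_separation(p.atom_a, p.atom_b, pc),
                raw_bound=float(raw),
            )
        )
    return out


@dataclass(frozen=True)
class RestraintCounts:
    intraresidue: int
    sequential: int
    medium: int
    long: int
    peptide_porphyrin: int   # separate inter-moiety tally (subset of long)
    total: int
    n_residues: int
    per_residue: int         # nearest-integer
    per_residue_raw: float   # unrounded, always reported alongside


def count_restraint_classes(
    restraints: Sequence[DistanceRestraint],
    n_residues: int,
    porphyrin_chains: Iterable[str] = ("X",),
) -> RestraintCounts:
    """Tally restraints per sequence-separation class.

    Peptide↔porphyrin restraints are counted inside ``long`` and also
    reported as their own inter-moiety tally.  ``per_residue`` is the
    nearest integer of total/n_residues; the raw ratio is kept too.
    """
    if n_residues < 1:
        raise ValidationError("n_residues must be >= 1")
    pc = frozenset(porphyrin_chains)
    counts = {"intraresidue": 0, "sequential": 0, "medium": 0, "long": 0}
    pp = 0
    for r in restraints:
        counts[r.seq_class] += 1
        if r.atom_a[0] in pc or r.atom_b[0] in pc:
            pp += 1
    total = sum(counts.values())
    raw = total / n_residues
    return RestraintCounts(
        intraresidue=counts["intraresidue"],
        sequential=counts["sequential"],
        medium=counts["medium"],
        long=counts["long"],
        peptide_porphyrin=pp,
        total=total,
        n_residues=n_residues,
        per_residue=int(round(raw)),
        per_residue_raw=raw,
    )


# ---------------------------------------------------------------------------
# Isomer assignment rule tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactPattern:
    """Porphyrin contacts of one anchor proton (e.g. the Dab9 side-chain
    amide NHδ, or the Leu5 side chain of the proximal helix)."""

    anchor: str
    contacts: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def make(cls, anchor: str, contacts: Iterable[str]) -> "ContactPattern":
        return cls(anchor=anchor, contacts=frozenset(str(c) for c in contacts))


_POSITION_RE = re.compile(r"^(?:propionyl-)?(\d+)")


def _ring_position(label: str) -> int:
    """Ring position encoded in a contact label: '3CH3' -> 3,
    'propionyl-2' -> 2, '15H' -> 15."""
    m = _POSITION_RE.match(str(label).strip())
    if not m:
        raise ValidationError(f"cannot read a ring position from '{label}'")
    return int(m.group(1))


def assign_regioisomer(
    pattern: ContactPattern, topology: PorphyrinTopology
) -> str:
    """Which propionate anchors the proximal (TD) chain.

    The distal-chain position-9 side-chain amine proton sits next to its
    *own* anchoring propionate: contacts to the propionyl at ring
    position 2 mean the TD chain occupies position 18 (isomer_1), and
    contacts to propionyl-18 mean the TD chain is at position 2
    (isomer_2).
    """
    if not pattern.contacts:
        raise UndeterminedError(
            f"anchor {pattern.anchor}: empty contact set, isomer undetermined"
        )
    positions = {_ring_position(c) for c in pattern.contacts}
    bad = positions - set(topology.propionyl_attachment)
    if bad:
        raise ValidationError(
            f"contacts reference non-propionyl positions {sorted(bad)}"
        )
    if positions == {2}:
        return "isomer_1"
    if positions == {18}:
        return "isomer_2"
    raise AmbiguityError(
        f"anchor {pattern.anchor}: contacts to both propionyls {sorted(positions)}"
    )


# ring positions flanking the two faces the proximal Leu5 can contact:
# the 3..10 side and the 12..17 side of the macrocycle
_SIDE_A = frozenset(range(3, 11))     # 3CH3, 5H, 7CH3, 8H, 10H
_SIDE_B = frozenset(range(12, 18))    # 12CH3, 13H, 15H, 17CH3


def assign_diastereomer(
    leu5_contacts: ContactPattern,
    td_anchor_position: int,
    helix_handedness: str = "right",
) -> str:
    """Δ/Λ call from the proximal Leu5↔porphyrin contact side.

    For right-handed helices: a TD chain anchored at propionate 18 whose
    Leu5 contacts the 3–10 side of the ring sits *above* the porphyrin
    plane (Δ); anchored at 2 with contacts on the 12–17 side it sits
    *below*, which is again Δ.  The two mirrored combinations give Λ.
    Left-handed helices invert every call.
    """
    if td_anchor_position not in (2, 18):
        raise ValidationError("td_anchor_position must be 2 or 18")
    if helix_handedness not in ("right", "left"):
        raise ValidationError("helix_handedness must be 'right' or 'left'")
    if not leu5_contacts.contacts:
        raise UndeterminedError("empty Leu5 contact set")
    positions = {_ring_position(c) for c in leu5_contacts.contacts}
    on_a = positions & _SIDE_A
    on_b = positions & _SIDE_B
    if on_a and on_b:
        raise AmbiguityError(
            f"Leu5 contacts span both ring sides: {sorted(positions)}"
        )
    if not (on_a or on_b):
        raise UndeterminedError(
            f"Leu5 contacts {sorted(positions)} touch neither diagnostic side"
        )
    side = "A" if on_a else "B"
    delta = (td_anchor_position == 18) == (side == "A")
    if helix_handedness == "left":
        delta = not delta
    return "Delta" if delta else "Lambda"


# ---------------------------------------------------------------------------
# Peak-list and restraint I/O
# ---------------------------------------------------------------------------

PEAK_COLUMNS = ["chain_a", "res_a", "atom_a", "chain_b", "res_b", "atom_b",
                "intensity"]


def read_peak_list(path: str | Path) -> list[NOEPeak]:
    """Read a tabular peak list (TSV with the documented seven columns)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"peak list missing columns {missing}")
    return [
        NOEPeak(
            atom_a=(str(r.chain_a), int(r.res_a), str(r.atom_a)),
            atom_b=(str(r.chain_b), int(r.res_b), str(r.atom_b)),
            intensity=float(r.intensity),
        )
        for r in df.itertuples(index=False)
    ]


def write_upper_limits(
    restraints: Sequence[DistanceRestraint], path: str | Path
) -> None:
    """Write a CYANA-style flat upper-limit file.

    Columns: residue number, residue placeholder, atom name for each
    partner, then the upper bound in Å.  Chain is prepended to the
    residue field as ``<chain>:<number>`` since the bundle has two
    peptide chains plus the porphyrin.
    """
    lines = []
    for r in restraints:
        (ca, ra, na), (cb, rb, nb) = r.atom_a, r.atom_b
        lines.append(
            f"{ca}:{ra:<4d} {na:<5s} {cb}:{rb:<4d} {nb:<5s} {r.upper_bound:6.2f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
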