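"""Coarse-grained hydrogen-bond descriptors of a backbone conformation.

A backbone hydrogen bond is detected purely geometrically (the representation
carries no hydrogens): donor N(i) to acceptor carbonyl O(j) with N..O distance
below a cutoff (default 3.5 A, appropriate for N..O), both flanking angles
C(j)-O(j)..N(i) and O(j)..N(i)-CA(i) above a minimum (default 100 degrees),
and sequence separation |i - j| >= 2. Each carbonyl forms at most one bond;
among competing donors the smallest distance wins.

The 8-integer network descriptor partitions the residues by the bonding state
of their carbonyl: three counts of unbonded residues by their own
secondary-structure label (H, E, C) and five counts of bonded residues by the
unordered label pair of the two partners (H-H, E-E, C-C, H-C, E-C; the rare
H-E pair is tallied with E-C). The eight counts always sum to the chain
length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .geometry import Conformation

#: Descriptor category names, in storage order.
CATEGORIES = ("s_H", "s_E", "s_C", "b_HH", "b_EE", "b_CC", "b_HC", "b_EC")

_LABEL_CODE = {"H": 0, "E": 1, "C": 2}


@dataclass(frozen=True)
class HBond:
    """One backbone hydrogen bond (indices 1-based)."""

    donor_residue: int
    acceptor_residue: int
    distance: float


def _labels_to_codes(labels) -> np.ndarray:
    try:
        return np.array([_LABEL_CODE[l] for l in labels], dtype=np.int8)
    except KeyError as e:
        raise ValueError(f"label outside {{H, E, C}}: {e.args[0]!r}") from None


def detect_hbonds(conformation: Conformation, cutoff: float = 3.5,
                  min_angle: float = 100.0, min_sep: int = 2) -> list[HBond]:
    """All backbone hydrogen bonds of a conformation (deterministic)."""
    arrs = (conformation.n, conformation.ca, conformation.c, conformation.o)
    if any(not np.all(np.isfinite(a)) for a in arrs):
        raise ValueError("conformation is missing backbone atoms (non-finite coordinates)")
    donor_of, dist_of = K.assign_hbonds(*arrs, cutoff, min_angle, min_sep)
    return [HBond(int(donor_of[j]) + 1, j + 1, float(dist_of[j]))
            for j in range(len(conformation)) if donor_of[j] >= 0]


def categorize(hbonds: list[HBond], labels) -> np.ndarray:
    """8-category descriptor from a bond list and per-residue {H,E,C} labels.

    Counting is per residue at its carbonyl, so the counts partition the chain.
    """
    codes = _labels_to_codes(labels)
    L = codes.shape[0]
    donor_of = np.full(L, -1, dtype=np.int64)
    for hb in hbonds:
        donor_of[hb.acceptor_residue - 1] = hb.donor_residue - 1
    return K.hbond_descriptor_from_assignment(donor_of, codes)


def hbond_descriptor(conformation: Conformation, labels, cutoff: float = 3.5,
                     min_angle: float = 100.0, min_sep: int = 2) -> np.ndarray:
    """Fused detection + categorization (the coarse map used in sampling)."""
    codes = _labels_to_codes(labels)
    donor_of, _ = K.assign_hbonds(conformation.n, conformation.ca,
                                  conformation.c, conformation.o,
                                  cutoff, min_angle, min_sep)
    return K.hbond_descriptor_from_assignment(donor_of, codes)
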