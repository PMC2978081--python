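"""Embedded study sequences and the native-like hydrogen-bond target fixture.

The two chains used throughout are ubiquitin (76 residues, PDB 1UBQ) and the
B1 domain of streptococcal protein G (56 residues, PDB 2GB1). No structure
files are required: the default 8-category hydrogen-bond target is derived
from the idealized protein-G topology (one alpha-helix packed against a
four-stranded mixed beta-sheet) by applying the same carbonyl-based
categorization rules used for sampled conformations to the topology's
canonical bond pattern (helix i -> i+4 bonds; antiparallel registers for the
two hairpins; a parallel register between the terminal strands). This is a
synthetic stand-in for counts measured on the experimental structure; any
user-supplied 8-vector may replace it.
"""

from __future__ import annotations

import numpy as np

from .geometry import Sequence
from .hbonds import HBond, categorize

UBIQUITIN_1UBQ = Sequence(
    "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYNIQKESTLHLVLRLRGG"
)

PROTEIN_G_2GB1 = Sequence(
    "MTYKLILNGKTLKGETTTEAVDAATAEKVFKQYANDNGVDGEWTYDDATKTFTVTE"
)

#: Secondary-structure segments of the protein-G fold (1-based, inclusive).
PROTEIN_G_SEGMENTS = {
    "E": [(2, 8), (13, 20), (42, 46), (51, 55)],
    "H": [(23, 36)],
}


def get_sequence(name: str) -> Sequence:
    table = {"ubiquitin": UBIQUITIN_1UBQ, "protein_g": PROTEIN_G_2GB1}
    try:
        return table[name]
    except KeyError:
        raise ValueError(
            f"unknown sequence name {name!r}; known: {sorted(table)}") from None


def protein_g_labels() -> list[str]:
    """Per-residue {H,E,C} labels of the idealized protein-G topology."""
    labels = ["C"] * len(PROTEIN_G_2GB1)
    for lab, segments in PROTEIN_G_SEGMENTS.items():
        for lo, hi in segments:
            for i in range(lo, hi + 1):
                labels[i - 1] = lab
    return labels


def _topology_bond_pairs() -> list[tuple[int, int]]:
    """(carbonyl residue, donor residue) pairs of the idealized fold, 1-based."""
    pairs: list[tuple[int, int]] = []
    # helix i -> i+4 carbonyl bonds
    for i in range(23, 33):
        pairs.append((i, i + 4))
    # antiparallel hairpin beta1(2-8) <-> beta2(13-20), register i <-> 22-i
    for i in (2, 4, 6, 8, 20, 18, 16, 14):
        pairs.append((i, 22 - i))
    # antiparallel hairpin beta3(42-46) <-> beta4(51-55), register i <-> 97-i
    for i in (42, 44, 46, 55, 53, 51):
        pairs.append((i, 97 - i))
    # parallel pairing of the terminal strands beta1 <-> beta4
    pairs += [(3, 52), (5, 54)]
    # a few capping / turn contacts involving coil residues
    pairs += [(21, 25), (37, 33),    # coil carbonyl, helix donor
              (12, 18), (47, 44),    # coil carbonyl, strand donor
              (10, 40), (39, 49)]    # coil-coil contacts
    return pairs


def protein_g_native_target_counts() -> np.ndarray:
    """8-category counts of the idealized native protein-G fold (sum = 56)."""
    labels = protein_g_labels()
    bonds = [HBond(donor, acceptor, 2.9) for acceptor, donor in _topology_bond_pairs()]
    return categorize(bonds, labels)
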