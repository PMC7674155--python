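"""Synthetic reference proteins for the pMMO subunit screen.

These are synthetic stand-in references, generated deterministically, not
database sequences. The canonical PmoC reference is built so that the
copper-coordinating catalytic triad (Asp156, His160, His173 in reference
numbering, 1-based) sits at the canonical positions; all residue-site
checks are defined against this numbering. PmoA and PmoB stand-ins exist
only so the "no pmoA/pmoB nearby" confirmation has something to search
against.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# 1-based positions of the copper-binding triad on the canonical reference
CATALYTIC_SITES: tuple[int, ...] = (156, 160, 173)
CATALYTIC_RESIDUES: tuple[str, ...] = ("D", "H", "H")

PMOC_LENGTH = 260
PMOA_LENGTH = 247
PMOB_LENGTH = 414


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@lru_cache(maxsize=1)
def canonical_pmoc() -> str:
    """The canonical synthetic PmoC reference (defines site numbering)."""
    rng = np.random.default_rng(20160501)
    seq = list(_random_protein(PMOC_LENGTH, rng))
    for pos, res in zip(CATALYTIC_SITES, CATALYTIC_RESIDUES):
        seq[pos - 1] = res
    return "".join(seq)


@lru_cache(maxsize=1)
def canonical_pmoa() -> str:
    return _random_protein(PMOA_LENGTH, np.random.default_rng(20160502))


@lru_cache(maxsize=1)
def canonical_pmob() -> str:
    return _random_protein(PMOB_LENGTH, np.random.default_rng(20160503))


def pmoc_references() -> dict[str, str]:
    return {"PmoC_ref": canonical_pmoc()}


def pmoab_references() -> dict[str, str]:
    return {"PmoA_ref": canonical_pmoa(), "PmoB_ref": canonical_pmob()}
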