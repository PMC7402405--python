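"""Window extraction around lysine sites with mirror padding at the termini.

Each candidate lysine is described by two fixed-width windows cut from the
per-residue profiles: a 7-row structural window (flank 3) and a 41-row
evolutionary window (flank 20).  Near a protein terminus the missing rows
are filled by the mirror effect: indices are reflected back into the
protein, so every window row is a copy of a real profile row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ProteinRecord, PssmProfile, SiteLabel, StructuralProfile

#: Default flank of the structural window (2*3 + 1 = 7 rows).
FLANK_STRUCT: int = 3
#: Default flank of the evolutionary window (2*20 + 1 = 41 rows).
FLANK_PSSM: int = 20


@dataclass
class Segment:
    """One lysine site's windowed profile submatrices."""

    site: SiteLabel
    structural_window: np.ndarray  # (2*f_struct+1) x 8
    pssm_window: np.ndarray  # (2*f_pssm+1) x 20
    source_indices_structural: list[int]  # 1-based source positions
    source_indices_pssm: list[int]


def find_lysines(protein: ProteinRecord) -> list[int]:
    """All 1-based positions of 'K' in the sequence, ascending."""
    return [i + 1 for i, aa in enumerate(protein.sequence) if aa == "K"]


def mirror_indices(
    center: int, flank: int, length: int, mode: str = "exclusive"
) -> list[int]:
    """Source positions of a window of width ``2*flank + 1`` around ``center``.

    Nominal indices ``center - flank .. center + flank`` that fall outside
    ``[1, length]`` are reflected back in, iteratively until in range.

    ``mode='exclusive'`` reflects about the terminal residue without
    repeating it (index 0 -> 2, index -1 -> 3; index L+1 -> L-1), the usual
    reading of the mirror effect.  ``mode='inclusive'`` reflects about the
    protein boundary, repeating the terminal residue (index 0 -> 1,
    index L+1 -> L).
    """
    if mode not in ("exclusive", "inclusive"):
        raise ValueError(f"unknown mirror mode {mode!r}")
    if not 1 <= center <= length:
        raise ValueError(
            f"center {center} outside protein of length {length}"
        )
    if length == 1 and mode == "exclusive" and flank > 0:
        raise ValueError(
            "cannot mirror-pad a single-residue protein (no neighbor to "
            "reflect to); use mode='inclusive' or a zero flank"
        )
    out: list[int] = []
    for i in range(center - flank, center + flank + 1):
        while i < 1 or i > length:
            if mode == "exclusive":
                i = 2 - i if i < 1 else 2 * length - i
            else:
                i = 1 - i if i < 1 else 2 * length + 1 - i
        out.append(i)
    return out


def extract_segment(
    site: SiteLabel,
    pssm: PssmProfile,
    struct: StructuralProfile,
    f_struct: int = FLANK_STRUCT,
    f_pssm: int = FLANK_PSSM,
    mirror: str = "exclusive",
) -> Segment:
    """Cut the structural and evolutionary windows for one site."""
    if pssm.protein_id != site.protein_id or struct.protein_id != site.protein_id:
        raise ValueError(
            f"profile/site protein mismatch: site {site.protein_id}, "
            f"pssm {pssm.protein_id}, structural {struct.protein_id}"
        )
    if pssm.length != struct.length:
        raise ValueError(
            f"protein {site.protein_id}: PSSM has {pssm.length} rows but "
            f"structural profile has {struct.length}"
        )
    L = pssm.length
    if not 1 <= site.position <= L:
        raise ValueError(
            f"site position {site.position} outside protein "
            f"{site.protein_id} of length {L}"
        )
    idx_s = mirror_indices(site.position, f_struct, L, mode=mirror)
    idx_p = mirror_indices(site.position, f_pssm, L, mode=mirror)
    return Segment(
        site=site,
        structural_window=struct.values[np.asarray(idx_s) - 1],
        pssm_window=pssm.matrix[np.asarray(idx_p) - 1],
        source_indices_structural=idx_s,
        source_indices_pssm=idx_p,
    )
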