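"""Per-site feature construction: 56 structural values + 400 profile-bigram
transition features, concatenated into the 456-dimensional vector.

The profile bigram of a row-stochastic window M (41 x 20) is the 20 x 20
matrix

    B[p, q] = sum_k M[k, p] * M[k + 1, q],    k over consecutive row pairs,

which conserves total mass: sum(B) equals the number of consecutive pairs
(40 for a 41-row window) when the rows of M each sum to 1.  B is flattened
row-major (p-major) into 400 features; the structural 7 x 8 window is
flattened position-major into 56 features and placed first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import (
    ALPHABET,
    STRUCTURAL_COLUMNS,
    FeatureTable,
    PssmProfile,
    SiteLabel,
    StructuralProfile,
)
from .segmentation import FLANK_PSSM, FLANK_STRUCT, Segment, extract_segment


@dataclass
class BigramMatrix:
    """20 x 20 amino-acid-pair transition matrix from a profile window."""

    B: np.ndarray
    source_rows: int

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        if self.B.shape != (20, 20):
            raise ValueError(f"bigram matrix must be 20x20, got {self.B.shape}")


def profile_bigram(M: np.ndarray) -> BigramMatrix:
    """Transition bigram of a profile matrix.

    ``B[p, q] = sum_{k=1}^{rows-1} M[k, p] * M[k+1, q]`` (1-based).  For a
    row-stochastic M the entries of B sum to ``rows - 1``.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[1] != 20:
        raise ValueError(f"expected an L x 20 matrix, got shape {M.shape}")
    if M.shape[0] < 2:
        raise ValueError("profile bigram needs at least 2 rows")
    if np.any(M < 0):
        raise ValueError("profile entries must be nonnegative")
    B = M[:-1].T @ M[1:]
    return BigramMatrix(B=B, source_rows=M.shape[0])


def flatten_bigram(bigram: BigramMatrix) -> np.ndarray:
    """p-major flattening: element ``20*(p-1) + q`` (1-based) holds B[p, q]."""
    return bigram.B.reshape(400).copy()


def flatten_structural(W: np.ndarray, f_struct: int = FLANK_STRUCT) -> np.ndarray:
    """Position-major flattening of the structural window.

    Row 1's eight properties come first, then row 2's, and so on.
    """
    W = np.asarray(W, dtype=float)
    expected = (2 * f_struct + 1, 8)
    if W.shape != expected:
        raise ValueError(
            f"structural window must be {expected[0]}x8, got {W.shape}"
        )
    return W.reshape(expected[0] * 8).copy()


def build_feature_vector(seg: Segment) -> np.ndarray:
    """Concatenate [structural 56, bigram 400] for one segment (456 total)."""
    f_struct = (seg.structural_window.shape[0] - 1) // 2
    struct_part = flatten_structural(seg.structural_window, f_struct=f_struct)
    bigram_part = flatten_bigram(profile_bigram(seg.pssm_window))
    return np.concatenate([struct_part, bigram_part])


def feature_names(f_struct: int = FLANK_STRUCT) -> list[str]:
    """Column names: structural block then bigram block.

    Structural: ``struct_pos{offset}_{property}`` for offsets
    ``-f_struct .. +f_struct``; bigram: ``bigram_{p}_{q}`` over the PSSM
    amino-acid alphabet, p-major.
    """
    names = [
        f"struct_pos{off:+d}_{prop}"
        for off in range(-f_struct, f_struct + 1)
        for prop in STRUCTURAL_COLUMNS
    ]
    names += [f"bigram_{p}_{q}" for p in ALPHABET for q in ALPHABET]
    return names


def featurize_dataset(
    sites: Sequence[SiteLabel],
    pssms: Mapping[str, PssmProfile] | Iterable[PssmProfile],
    structs: Mapping[str, StructuralProfile] | Iterable[StructuralProfile],
    f_struct: int = FLANK_STRUCT,
    f_pssm: int = FLANK_PSSM,
    mirror: str = "exclusive",
) -> FeatureTable:
    """One feature row per site, in input order."""
    if not isinstance(pssms, Mapping):
        pssms = {p.protein_id: p for p in pssms}
    if not isinstance(structs, Mapping):
        structs = {s.protein_id: s for s in structs}
    missing = sorted(
        {s.protein_id for s in sites}
        - (set(pssms.keys()) & set(structs.keys()))
    )
    if missing:
        raise ValueError(
            f"missing PSSM or structural profile for protein(s): {missing}"
        )
    rows = np.empty((len(sites), 8 * (2 * f_struct + 1) + 400), dtype=float)
    for i, site in enumerate(sites):
        seg = extract_segment(
            site,
            pssms[site.protein_id],
            structs[site.protein_id],
            f_struct=f_struct,
            f_pssm=f_pssm,
            mirror=mirror,
        )
        rows[i] = build_feature_vector(seg)
    return FeatureTable(
        X=rows,
        labels=np.array([s.label for s in sites], dtype=int),
        site_ids=[(s.protein_id, s.position) for s in sites],
        column_names=feature_names(f_struct),
    )
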