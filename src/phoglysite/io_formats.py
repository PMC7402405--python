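"""Readers and writers for every external representation the pipeline touches.

All downstream modules consume only the in-memory types defined here:
:class:`ProteinRecord`, :class:`PssmProfile`, :class:`StructuralProfile`,
:class:`SiteLabel` and :class:`FeatureTable`.

External dialects
-----------------
* multi-record FASTA for protein sequences;
* PSI-BLAST ``-out_ascii_pssm`` layout for evolutionary profiles — three
  header lines, one row per residue with 40 numeric columns (20 log-odds,
  then 20 substitution percentages), then a trailer.  Only the second
  (linear-probability) block is used; the log-odds block is parsed and
  discarded;
* a SPIDER2-style whitespace table for per-residue structural predictions
  with columns ``pos aa ss asa phi psi theta tau pc pe ph``;
* 3-column TSV for site labels; CSV with a header row for feature tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Amino-acid column order of the PSSM matrices — the PSI-BLAST column order.
ALPHABET: str = "ARNDCQEGHILKMFPSTWYV"

#: Canonical column order of a structural profile.
STRUCTURAL_COLUMNS: tuple[str, ...] = (
    "asa", "pc", "pe", "ph", "phi", "psi", "theta", "tau",
)

#: Tolerance on pc+pe+ph deviating from 1 in structural profiles.
SS_PROB_SUM_TOL: float = 0.05

_VALID_RESIDUES = frozenset(ALPHABET + "X")


class FormatError(ValueError):
    """A file did not match its declared dialect or violated an invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20-letter alphabet plus ``X``."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid protein id: {self.id!r}")
        if not self.sequence:
            raise FormatError(f"protein {self.id}: empty sequence")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise FormatError(
                f"protein {self.id}: invalid residues {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PssmProfile:
    """L x 20 row-stochastic substitution-probability matrix.

    Rows follow sequence positions (1-based externally); columns follow
    :data:`ALPHABET`.  Element ``matrix[i, j]`` is the probability of
    observing amino acid ``ALPHABET[j]`` at position ``i + 1``.
    """

    protein_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise FormatError(
                f"PSSM for {self.protein_id}: expected L x 20 matrix, "
                f"got shape {self.matrix.shape}"
            )
        if np.any(self.matrix < 0) or np.any(self.matrix > 1):
            raise FormatError(
                f"PSSM for {self.protein_id}: probabilities outside [0, 1]"
            )
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise FormatError(
                f"PSSM for {self.protein_id}: row sums deviate from 1 "
                f"(max deviation {np.abs(sums - 1.0).max():.3g})"
            )

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


@dataclass
class StructuralProfile:
    """L x 8 per-residue structural table in canonical column order.

    Columns: ``asa`` (accessible surface area, A^2, >= 0), ``pc``/``pe``/
    ``ph`` (coil/strand/helix probabilities, summing to ~1), and the
    backbone angles ``phi``, ``psi``, ``theta``, ``tau`` in degrees.
    """

    protein_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in STRUCTURAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(
                f"structural profile for {self.protein_id}: missing "
                f"column(s) {missing}"
            )
        self.table = (
            self.table.loc[:, list(STRUCTURAL_COLUMNS)]
            .astype(float)
            .reset_index(drop=True)
        )
        t = self.table
        for col in ("pc", "pe", "ph"):
            if ((t[col] < 0) | (t[col] > 1)).any():
                raise FormatError(
                    f"structural profile for {self.protein_id}: {col} "
                    "outside [0, 1]"
                )
        ss_sum = t["pc"] + t["pe"] + t["ph"]
        if ((ss_sum - 1.0).abs() > SS_PROB_SUM_TOL).any():
            row = int((ss_sum - 1.0).abs().idxmax())
            raise FormatError(
                f"structural profile for {self.protein_id}: pc+pe+ph = "
                f"{ss_sum[row]:.4g} at row {row + 1} (tolerance "
                f"{SS_PROB_SUM_TOL})"
            )
        if (t["asa"] < 0).any():
            raise FormatError(
                f"structural profile for {self.protein_id}: negative ASA"
            )
        angles = t[["phi", "psi", "theta", "tau"]].to_numpy()
        if np.any(angles < -180.0) or np.any(angles > 180.0):
            raise FormatError(
                f"structural profile for {self.protein_id}: angle outside "
                "[-180, 180]"
            )

    @property
    def length(self) -> int:
        return len(self.table)

    @property
    def values(self) -> np.ndarray:
        """The table as an L x 8 float array in canonical column order."""
        return self.table.to_numpy(dtype=float)


@dataclass(frozen=True)
class SiteLabel:
    """One candidate lysine site: protein id, 1-based position, 0/1 label."""

    protein_id: str
    position: int
    label: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(
                f"site {self.protein_id}:{self.position}: positions are "
                "1-based"
            )
        if self.label not in (0, 1):
            raise FormatError(
                f"site {self.protein_id}:{self.position}: label must be 0 "
                f"or 1, got {self.label!r}"
            )


@dataclass
class FeatureTable:
    """Aligned per-site feature vectors, labels and site identities."""

    X: np.ndarray
    labels: np.ndarray
    site_ids: list[tuple[str, int]]
    column_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        n, d = self.X.shape
        if len(self.labels) != n or len(self.site_ids) != n:
            raise ValueError("labels/site_ids not aligned with rows")
        if len(self.column_names) != d:
            raise ValueError(
                f"{len(self.column_names)} column names for {d} columns"
            )
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be 0/1")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self) - self.labels.sum())

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        """Row subset by boolean mask or integer index array."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return FeatureTable(
            X=self.X[idx],
            labels=self.labels[idx],
            site_ids=[self.site_ids[i] for i in idx],
            column_names=list(self.column_names),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.column_names)
        df.insert(0, "position", [p for _, p in self.site_ids])
        df.insert(0, "protein_id", [pid for pid, _ in self.site_ids])
        df["label"] = self.labels
        return df


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file.

    Sequences are uppercased and a trailing ``*`` terminator is stripped.
    Duplicate ids raise :class:`FormatError`.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate protein id in {path}: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().rstrip("*")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, p.length, 60):
                fh.write(p.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM


def read_pssm(
    path: str | Path,
    protein_id: str | None = None,
    expected_length: int | None = None,
) -> PssmProfile:
    """Parse a PSI-BLAST ASCII PSSM file.

    The second 20-column block (amino-acid linear probabilities, printed as
    percentages) is authoritative; each row is divided by 100 and then
    renormalized to sum exactly to 1, since rounding in the file makes raw
    row sums approximate.  The log-odds block is skipped.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if not tokens[0].lstrip("-").isdigit():
                continue  # header or trailer line
            if len(tokens) < 42:
                # trailer statistics lines can start with a number; a data
                # row always has index + residue + 40 values
                continue
            try:
                values = [float(t) for t in tokens[2:42]]
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric cell in PSSM row "
                    f"({exc})"
                ) from None
            rows.append(values[20:40])
    if not rows:
        raise FormatError(f"{path}: no PSSM data rows found")
    if expected_length is not None and len(rows) != expected_length:
        raise FormatError(
            f"{path}: {len(rows)} rows but protein has "
            f"{expected_length} residues"
        )
    m = np.asarray(rows, dtype=float) / 100.0
    sums = m.sum(axis=1)
    if np.any(sums <= 0):
        raise FormatError(f"{path}: PSSM row with zero probability mass")
    m = m / sums[:, None]
    return PssmProfile(protein_id=protein_id, matrix=m)


def write_pssm(
    profile: PssmProfile, path: str | Path, sequence: str | None = None
) -> None:
    """Write a profile in the PSI-BLAST ASCII layout.

    The percentage block is written at full float precision (not rounded to
    integers as PSI-BLAST itself does) so that parsing recovers the matrix
    losslessly.  The log-odds block is filled with zeros; it is ignored on
    read.
    """
    m = profile.matrix
    seq = sequence if sequence is not None else "X" * profile.length
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted, "
            "synthetic profile\n"
        )
        fh.write(
            "            "
            + "  ".join(ALPHABET)
            + "   "
            + "  ".join(ALPHABET)
            + "\n"
        )
        for i in range(profile.length):
            logodds = " ".join("0" for _ in range(20))
            probs = " ".join(repr(float(100.0 * v)) for v in m[i])
            fh.write(f"{i + 1:5d} {seq[i]} {logodds}  {probs}\n")
        fh.write("\n")


# ---------------------------------------------------------------------------
# SPIDER2-style structural table

_STRUCT_FILE_COLUMNS = (
    "pos", "aa", "ss", "asa", "phi", "psi", "theta", "tau", "pc", "pe", "ph",
)


def read_structural(
    path: str | Path, protein_id: str | None = None
) -> StructuralProfile:
    """Parse a SPIDER2-style whitespace-delimited per-residue table.

    The file carries columns ``pos aa ss asa phi psi theta tau pc pe ph``
    (one header line, ``#``-prefixed or not); the result is reordered into
    the canonical :data:`STRUCTURAL_COLUMNS` order.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    with open(path) as fh:
        header_line = fh.readline()
        names = header_line.lstrip("#").split()
        lowered = [n.lower() for n in names]
        missing = [c for c in _STRUCT_FILE_COLUMNS if c not in lowered]
        if missing:
            raise FormatError(
                f"{path}: missing structural column(s) {missing} in header"
            )
        df = pd.read_csv(
            fh, sep=r"\s+", names=lowered, comment="#",
            float_precision="round_trip",
        )
    if df.empty:
        raise FormatError(f"{path}: no structural data rows")
    return StructuralProfile(protein_id=protein_id, table=df)


def write_structural(
    profile: StructuralProfile,
    path: str | Path,
    sequence: str | None = None,
) -> None:
    t = profile.table
    seq = sequence if sequence is not None else "X" * profile.length
    ss_letters = np.array(["C", "E", "H"])
    ss = ss_letters[t[["pc", "pe", "ph"]].to_numpy().argmax(axis=1)]
    with open(path, "w") as fh:
        fh.write("# " + " ".join(_STRUCT_FILE_COLUMNS) + "\n")
        for i in range(profile.length):
            r = t.iloc[i]
            fields = [str(i + 1), seq[i], ss[i]] + [
                repr(float(r[c]))
                for c in ("asa", "phi", "psi", "theta", "tau", "pc", "pe", "ph")
            ]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Site labels


def read_sites(
    path: str | Path,
    proteins: Mapping[str, ProteinRecord] | Sequence[ProteinRecord] | None = None,
) -> list[SiteLabel]:
    """Read a 3-column TSV of (protein_id, 1-based position, label).

    If ``proteins`` is given, each position is checked to fall inside the
    protein and to point at a lysine; all offending sites are reported in
    one error.
    """
    by_id: Mapping[str, ProteinRecord] | None
    if proteins is None:
        by_id = None
    elif isinstance(proteins, Mapping):
        by_id = proteins
    else:
        by_id = {p.id: p for p in proteins}
    sites: list[SiteLabel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
                )
            pid, pos_s, label_s = parts
            try:
                sites.append(
                    SiteLabel(pid, position=int(pos_s), label=int(label_s))
                )
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer position or label"
                ) from None
    if by_id is not None:
        bad: list[str] = []
        for s in sites:
            prot = by_id.get(s.protein_id)
            if prot is None:
                bad.append(f"{s.protein_id}:{s.position} (unknown protein)")
            elif not 1 <= s.position <= prot.length:
                bad.append(f"{s.protein_id}:{s.position} (outside protein)")
            elif prot.sequence[s.position - 1] != "K":
                bad.append(
                    f"{s.protein_id}:{s.position} "
                    f"(residue {prot.sequence[s.position - 1]!r}, not 'K')"
                )
        if bad:
            raise FormatError(
                "site(s) not at a lysine: " + "; ".join(bad)
            )
    return sites


def write_sites(sites: Iterable[SiteLabel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.protein_id}\t{s.position}\t{s.label}\n")


# ---------------------------------------------------------------------------
# Feature tables


def write_features(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV: site id columns, features, label."""
    table.to_frame().to_csv(path, index=False)


def read_features(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("protein_id", "position", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    feature_cols = [
        c for c in df.columns if c not in ("protein_id", "position", "label")
    ]
    return FeatureTable(
        X=df[feature_cols].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=int),
        site_ids=list(zip(df["protein_id"], df["position"].astype(int))),
        column_names=feature_cols,
    )
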