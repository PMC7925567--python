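"""Alignment data model, I/O, sequence weighting and column statistics.

The central object is :class:`MSA`, a rectangular multiple sequence
alignment with an explicit query row.  Sequence redundancy is handled by
the standard coupling-analysis reweighting: each sequence receives weight
1/(number of alignment members within ``theta`` identity of it), and the
effective alignment depth ``N_eff`` is the sum of those weights.

Pairwise identity is defined as the number of matching letters divided by
the number of columns where *both* sequences are non-gap.  This symmetric
definition is used consistently for reweighting, paralog exclusion and
species pairing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO

from .errors import DegenerateInputError, EmptyInputError, FormatError, ParameterError

#: canonical amino acids, the statistics alphabet
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Potts-model alphabet: gap state first, then the 20 canonical residues
DEFAULT_ALPHABET = "-" + AMINO_ACIDS

GAP = "-"


@dataclass
class MSA:
    """A rectangular alignment with an explicit query row.

    ``weights`` and ``n_eff`` are ``None`` until :func:`compute_weights`
    has been applied.
    """

    ids: list[str]
    seqs: list[str]
    species: list[str | None] = field(default=None)  # type: ignore[assignment]
    query_index: int = 0
    weights: np.ndarray | None = None
    n_eff: float | None = None

    def __post_init__(self) -> None:
        if not self.seqs:
            raise EmptyInputError("alignment has no sequences")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        if len(self.ids) != len(self.seqs):
            raise FormatError("ids and seqs differ in length")
        if self.species is None:
            self.species = [None] * len(self.seqs)
        if not (0 <= self.query_index < len(self.seqs)):
            raise ParameterError(f"query_index {self.query_index} out of range")
        if set(self.seqs[self.query_index]) <= {GAP, "."}:
            raise DegenerateInputError("query row is gap-only")

    @property
    def L(self) -> int:
        return len(self.seqs[0])

    @property
    def n_rows(self) -> int:
        return len(self.seqs)

    def char_matrix(self) -> np.ndarray:
        """(n_rows, L) uint8 view of the alignment characters."""
        return np.frombuffer("".join(self.seqs).encode("ascii"), dtype=np.uint8).reshape(
            self.n_rows, self.L
        )

    def subset(self, rows: Sequence[int]) -> "MSA":
        rows = list(rows)
        new_query = rows.index(self.query_index) if self.query_index in rows else 0
        return MSA(
            ids=[self.ids[r] for r in rows],
            seqs=[self.seqs[r] for r in rows],
            species=[self.species[r] for r in rows],
            query_index=new_query,
        )


@dataclass
class ColumnStats:
    """Per-column gap fraction and conservation, plus the coverage verdict."""

    gap_fraction: np.ndarray
    conservation: np.ndarray
    coverage_pass: bool


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _strip_a2m_inserts(records: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Drop a2m insert states (lowercase letters and '.') from every row."""
    out = []
    for name, seq in records:
        out.append((name, "".join(c for c in seq if not (c.islower() or c == "."))))
    lengths = {len(s) for _, s in out}
    if len(lengths) > 1:
        raise FormatError("a2m rows disagree in match-column count")
    return out


def read_alignment(path: str | Path, format: str = "fasta", query_id: str | None = None) -> MSA:
    """Read an alignment file into an :class:`MSA`.

    Residues are uppercased, '.' is normalized to '-'.  For ``a2m`` input,
    lowercase insert states are removed from every row before validation.
    The query row defaults to the first row unless ``query_id`` is given.
    """
    path = Path(path)
    if format not in {"fasta", "a2m", "stockholm"}:
        raise ParameterError(f"unknown alignment format {format!r}")
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path} is empty")

    if format == "stockholm":
        aln = AlignIO.read(str(path), "stockholm")
        records = [(rec.id, str(rec.seq)) for rec in aln]
    else:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise EmptyInputError(f"{path} contains no sequences")

    if format == "a2m":
        records = _strip_a2m_inserts(records)

    ids = [r[0] for r in records]
    seqs = [r[1].upper().replace(".", GAP) for r in records]
    qidx = 0
    if query_id is not None:
        try:
            qidx = ids.index(query_id)
        except ValueError:
            raise ParameterError(f"query id {query_id!r} not in alignment") from None
    return MSA(ids=ids, seqs=seqs, query_index=qidx)


def write_fasta(msa: MSA, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(msa.ids, msa.seqs):
            fh.write(f">{name}\n{seq}\n")


def to_fasta_string(msa: MSA) -> str:
    buf = io.StringIO()
    for name, seq in zip(msa.ids, msa.seqs):
        buf.write(f">{name}\n{seq}\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Identity and weighting
# ---------------------------------------------------------------------------

def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """matches / columns where both sequences are non-gap (0 if none)."""
    a = np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode("ascii"), dtype=np.uint8)
    if a.shape != b.shape:
        raise ParameterError("sequences differ in length")
    gap = ord(GAP)
    both = (a != gap) & (b != gap)
    denom = int(both.sum())
    if denom == 0:
        return 0.0
    return float(((a == b) & both).sum() / denom)


def identity_matrix(msa: MSA, chunk: int = 256) -> np.ndarray:
    """All-vs-all pairwise identity (n x n), computed in row chunks."""
    X = msa.char_matrix()
    n = X.shape[0]
    nongap = X != ord(GAP)
    out = np.empty((n, n), dtype=np.float64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        blk = X[start:stop]  # (c, L)
        both = nongap[start:stop, None, :] & nongap[None, :, :]  # (c, n, L)
        matches = (blk[:, None, :] == X[None, :, :]) & both
        denom = both.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident = matches.sum(axis=2) / denom
        ident[denom == 0] = 0.0
        out[start:stop] = ident
    return out


def identities_to_query(msa: MSA) -> np.ndarray:
    """Identity of every row to the query row."""
    q = msa.seqs[msa.query_index]
    return np.array([pairwise_identity(q, s) for s in msa.seqs])


def compute_weights(msa: MSA, theta: float = 0.8) -> MSA:
    """Redundancy-reweight the alignment at identity level ``theta``.

    Each sequence s gets weight 1/|{t : identity(s,t) >= theta}| with the
    self-comparison included, and ``n_eff`` is the sum of weights.
    """
    if not 0 < theta <= 1:
        raise ParameterError(f"theta must be in (0, 1], got {theta}")
    ident = identity_matrix(msa)
    neighbors = (ident >= theta).sum(axis=1)  # self always counted
    weights = 1.0 / neighbors
    out = replace(msa, weights=weights, n_eff=float(weights.sum()))
    return out


# ---------------------------------------------------------------------------
# Column statistics and conservation
# ---------------------------------------------------------------------------

def conservation(frequencies: np.ndarray) -> float:
    """Column conservation C = 1 - H / log2(20).

    ``frequencies`` are amino-acid frequencies over the 20 canonical
    residues (gap and nonstandard mass excluded).  They are renormalized
    to sum to one; an all-gap column (zero total mass) returns NaN.
    """
    f = np.asarray(frequencies, dtype=float)
    if np.any(f < 0):
        raise ParameterError("negative frequency")
    total = f.sum()
    if total == 0:
        return float("nan")
    f = f / total
    nz = f[f > 0]
    H = -np.sum(nz * np.log2(nz))
    return float(1.0 - H / np.log2(20.0))


def column_stats(msa: MSA, coverage_min_fraction: float = 0.8, max_col_gap: float = 0.5) -> ColumnStats:
    """Per-column gap fraction and conservation, unweighted counts.

    ``coverage_pass`` is true iff at least ``coverage_min_fraction`` of
    columns have gap fraction below ``max_col_gap``.
    """
    X = msa.char_matrix()
    n = X.shape[0]
    gap_fraction = (X == ord(GAP)).sum(axis=0) / n

    aa_codes = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)
    counts = np.stack([(X == c).sum(axis=0) for c in aa_codes], axis=1)  # (L, 20)
    cons = np.array([conservation(counts[j]) for j in range(msa.L)])

    good = gap_fraction < max_col_gap
    coverage_pass = bool(good.sum() >= coverage_min_fraction * msa.L)
    return ColumnStats(gap_fraction=gap_fraction, conservation=cons, coverage_pass=coverage_pass)


def column_stats_frame(stats: ColumnStats):
    """Column statistics as a DataFrame (1-based column index), for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "column": np.arange(1, len(stats.gap_fraction) + 1),
            "gap_fraction": stats.gap_fraction,
            "conservation": stats.conservation,
        }
    )


# ---------------------------------------------------------------------------
# Filters and eligibility
# ---------------------------------------------------------------------------

def filter_gappy_rows(msa: MSA, max_gap: float = 0.5) -> MSA:
    """Remove rows whose gap fraction exceeds ``max_gap`` (query kept)."""
    X = msa.char_matrix()
    frac = (X == ord(GAP)).sum(axis=1) / msa.L
    keep = [r for r in range(msa.n_rows) if frac[r] <= max_gap or r == msa.query_index]
    if not keep:
        raise DegenerateInputError("gap filter would empty the alignment")
    if len(keep) == msa.n_rows:
        return msa
    return msa.subset(keep)


def select_best_alignment(candidates: Iterable[MSA]) -> MSA | None:
    """Pick, among coverage-passing candidates, the one with maximal N_eff.

    Candidates come from homology searches at a ladder of bit-score
    thresholds; weights must be precomputed.  Returns ``None`` when no
    candidate passes column coverage.
    """
    candidates = list(candidates)
    if not candidates:
        raise ParameterError("no candidate alignments")
    best: MSA | None = None
    for cand in candidates:
        if cand.n_eff is None:
            raise ParameterError("candidate alignment lacks computed weights")
        if not column_stats(cand).coverage_pass:
            continue
        if best is None or cand.n_eff > best.n_eff:
            best = cand
    return best


def monomer_eligibility(msa: MSA, min_neff_per_l: float = 2.5) -> bool:
    """Monomer alignment eligible iff coverage passes and N_eff/L >= 2.5."""
    if msa.n_eff is None:
        raise ParameterError("weights not computed")
    return column_stats(msa).coverage_pass and (msa.n_eff / msa.L) >= min_neff_per_l
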