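"""Per-site conservation scoring from a multiple sequence alignment.

The MSAC score of a site is C = r * (1 - 0.95**N), where N is the number of
aligned sequences and r the fraction of them carrying the residue of
interest at the site.  The 1 - 0.95**N term is the probability that a
column of N sequences drawn uniformly over the 20 residues shows any given
residue at least once; it discounts apparent conservation in small
alignments (a single sequence is "conserved" only trivially, C = 0.05 at
r = 1).

Alignments are read with Biopython (aligned FASTA or Clustal).  The module
also filters homology-search hit tables down to the best hit per species
below an E-value cutoff, the pre-processing used before aligning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO

from .property_space import ALPHABET, GAP, _check_residue

GAP_POLICIES = ("all-rows", "ungapped-rows")


class ConservationError(ValueError):
    """Invalid alignment, position or formula input."""


class ReferenceMismatchError(ConservationError):
    """The supplied reference residue disagrees with the query row."""


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped sequences with a designated reference (query) row."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.ids or len(self.ids) != len(self.seqs):
            raise ConservationError("alignment needs at least one (id, sequence) row")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ConservationError(f"unequal row lengths in alignment: {sorted(lengths)}")
        if self.reference_id not in self.ids:
            raise ConservationError(f"reference id {self.reference_id!r} not in alignment")
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "seqs", tuple(s.upper() for s in self.seqs))

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def reference_row(self) -> str:
        return self.seqs[self.ids.index(self.reference_id)]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], reference_id: str | None = None) -> "Alignment":
        pairs = list(pairs)
        ids = tuple(p[0] for p in pairs)
        seqs = tuple(p[1] for p in pairs)
        return cls(ids, seqs, reference_id if reference_id is not None else ids[0])


def read_alignment(path: str, fmt: str = "auto", reference_id: str | None = None) -> Alignment:
    """Read an aligned FASTA or Clustal file.

    ``fmt='auto'`` sniffs the first non-blank character ('>' means FASTA).
    The reference row defaults to the first record.
    """
    if fmt == "auto":
        with open(path) as fh:
            head = fh.read(64).lstrip()
        fmt = "fasta" if head.startswith(">") else "clustal"
    msa = AlignIO.read(path, fmt)
    pairs = [(rec.id, str(rec.seq)) for rec in msa]
    return Alignment.from_pairs(pairs, reference_id)


@dataclass(frozen=True)
class SiteConservation:
    """Conservation of one residue at one alignment column."""

    column: int              # 0-based alignment column
    residue: str
    n_sequences: int
    match_fraction: float    # r
    score: float             # C = r * (1 - 0.95**N)
    reference_mismatch: bool = False


def msac_formula(n_sequences: int, match_fraction: float) -> float:
    """C = r * (1 - 0.95**N).

    Strictly increasing in N for r > 0 and in r for fixed N; approaches r
    as N grows.
    """
    n = int(n_sequences)
    if n < 1:
        raise ConservationError(f"n_sequences must be >= 1, got {n_sequences}")
    r = float(match_fraction)
    if not 0.0 <= r <= 1.0:
        raise ConservationError(f"match_fraction must be in [0, 1], got {r}")
    return r * (1.0 - 0.95 ** n)


def column_for_position(aln: Alignment, position: int) -> int:
    """0-based alignment column of the ``position``-th (1-based) ungapped
    residue of the reference row."""
    if position < 1:
        raise ConservationError(f"position must be >= 1, got {position}")
    seen = 0
    for col, ch in enumerate(aln.reference_row):
        if ch != GAP:
            seen += 1
            if seen == position:
                return col
    raise ConservationError(
        f"position {position} beyond ungapped reference length {seen}"
    )


def position_for_column(aln: Alignment, column: int) -> int:
    """Inverse of :func:`column_for_position` on non-gap reference columns."""
    row = aln.reference_row
    if not 0 <= column < len(row):
        raise ConservationError(f"column {column} out of range")
    if row[column] == GAP:
        raise ConservationError(f"reference row is gapped at column {column}")
    return sum(1 for ch in row[: column + 1] if ch != GAP)


def msac_score(
    aln: Alignment,
    position: int,
    residue: str | None = None,
    gap_policy: str = "all-rows",
    strict: bool = False,
) -> SiteConservation:
    """Score conservation of ``residue`` at the reference's ``position``.

    ``residue`` defaults to the reference row's own residue there.  Under
    the default ``all-rows`` policy N counts every alignment row and gaps
    count as mismatches; under ``ungapped-rows`` gapped rows are dropped
    from both N and the match count.

    A supplied residue that disagrees with the reference row is flagged
    (``reference_mismatch``), or raised under ``strict``.
    """
    if gap_policy not in GAP_POLICIES:
        raise ConservationError(f"unknown gap policy {gap_policy!r}; choose from {GAP_POLICIES}")
    col = column_for_position(aln, position)
    ref_char = aln.reference_row[col]
    residue = _check_residue(residue) if residue is not None else ref_char
    mismatch = residue != ref_char
    if mismatch and strict:
        raise ReferenceMismatchError(
            f"reference residue at position {position} is {ref_char}, not {residue}"
        )
    chars = [s[col] for s in aln.seqs]
    if gap_policy == "ungapped-rows":
        chars = [c for c in chars if c != GAP]
    n = len(chars)
    r = sum(1 for c in chars if c == residue) / n
    return SiteConservation(col, residue, n, r, msac_formula(n, r), mismatch)


@dataclass(frozen=True)
class HomologHit:
    """One homology-search hit: species label, E-value, ungapped sequence."""

    species: str
    evalue: float
    sequence: str = ""

    def __post_init__(self) -> None:
        if float(self.evalue) < 0:
            raise ConservationError(f"E-value must be >= 0, got {self.evalue}")


def filter_hits(hits: Sequence[HomologHit], evalue_threshold: float = 0.01) -> list[HomologHit]:
    """Keep the single best (lowest-E-value) hit per species at or below the
    threshold, returned in ascending E-value order.

    Ties within a species keep the first hit by input order; the output
    sort is stable on input order as well, so the result is deterministic.
    """
    if evalue_threshold <= 0:
        raise ConservationError(f"evalue_threshold must be > 0, got {evalue_threshold}")
    best: dict[str, tuple[float, int, HomologHit]] = {}
    for idx, hit in enumerate(hits):
        if hit.evalue > evalue_threshold:
            continue
        cur = best.get(hit.species)
        if cur is None or hit.evalue < cur[0]:
            best[hit.species] = (hit.evalue, idx, hit)
    return [h for _, _, h in sorted(best.values(), key=lambda t: (t[0], t[1]))]


def read_hits_tsv(path: str) -> list[HomologHit]:
    """Read a hits table (TSV with columns species, evalue, sequence)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"species", "evalue"}
    if not needed <= set(df.columns):
        raise ConservationError(f"hits TSV needs columns {sorted(needed)}, got {list(df.columns)}")
    seqs = df["sequence"] if "sequence" in df.columns else [""] * len(df)
    return [
        HomologHit(str(sp), float(ev), str(sq) if not pd.isna(sq) else "")
        for sp, ev, sq in zip(df["species"], df["evalue"], seqs)
    ]
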