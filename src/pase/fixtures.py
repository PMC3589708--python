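"""Synthetic alignments and substitution sets with known conservation.

The generator builds gapless alignments in which the per-column fraction of
rows carrying the reference residue is controlled exactly: at column j with
target fraction r_j and N rows, exactly round(r_j * N) rows carry the
reference residue and the rest draw uniformly from the other 19 residues.
Realized conservation therefore recovers the closed-form MSAC score with no
sampling noise, which keeps scoring tests deterministic.  A stochastic mode
(Bernoulli per row) exists for tolerance-based property tests.

No gaps, no phylogenetic structure and no substitution-matrix realism are
simulated; real homolog sets differ in all three respects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .property_space import ALPHABET, Substitution
from .conservation import Alignment, ConservationError


@dataclass(frozen=True)
class ConservationSpec:
    """Target shape of a synthetic alignment.

    One target match fraction per column; ``seed`` makes generation
    reproducible.
    """

    n_sequences: int
    length: int
    match_fractions: tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ConservationError("n_sequences must be >= 1")
        if self.length < 1:
            raise ConservationError("length must be >= 1")
        fr = tuple(float(r) for r in self.match_fractions)
        if len(fr) != self.length:
            raise ConservationError(
                f"need one match fraction per column: {len(fr)} != {self.length}"
            )
        if any(not 0.0 <= r <= 1.0 for r in fr):
            raise ConservationError("match fractions must be in [0, 1]")
        object.__setattr__(self, "match_fractions", fr)

    def realized_fraction(self, column: int) -> float:
        """The match fraction actually realized at a column: round(r*N)/N."""
        n = self.n_sequences
        return round(self.match_fractions[column] * n) / n


def random_protein(length: int, seed: int = 0) -> str:
    """Uniform random canonical protein sequence."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(ALPHABET), size=length))


def make_alignment(
    spec: ConservationSpec,
    reference: str | None = None,
    stochastic: bool = False,
) -> Alignment:
    """Build a gapless alignment realizing the spec's conservation targets.

    The first row ("query") carries the reference residue wherever the
    realized match count is at least one; where the target rounds to zero
    matches every row, the query included, draws a non-reference residue.
    With ``stochastic=True`` each row matches independently with
    probability r_j instead of hitting the count exactly.
    """
    rng = np.random.default_rng(spec.seed)
    if reference is None:
        reference = "".join(rng.choice(list(ALPHABET), size=spec.length))
    else:
        reference = reference.upper()
        if len(reference) != spec.length:
            raise ConservationError(
                f"reference length {len(reference)} != spec length {spec.length}"
            )
    n = spec.n_sequences
    cols = []
    for j, r in enumerate(spec.match_fractions):
        ref_res = reference[j]
        others = [a for a in ALPHABET if a != ref_res]
        if stochastic:
            match = rng.random(n) < r
        else:
            k = round(r * n)
            if k == 0 and r > 0:
                warnings.warn(
                    f"column {j}: target fraction {r} rounds to 0 matches of {n} rows",
                    stacklevel=2,
                )
            match = np.zeros(n, bool)
            if k >= 1:
                match[0] = True  # query row keeps its residue
                if k > 1:
                    match[1 + rng.choice(n - 1, size=k - 1, replace=False)] = True
        col = np.where(match, ref_res, None)
        draws = rng.choice(others, size=n)
        cols.append([c if c is not None else d for c, d in zip(col, draws)])
    rows = ["".join(col[i] for col in cols) for i in range(n)]
    ids = ["query"] + [f"hom_{i:03d}" for i in range(1, n)]
    return Alignment(tuple(ids), tuple(rows), "query")


def make_substitutions(sequence: str, count: int, seed: int = 0) -> list[Substitution]:
    """Sample ``count`` substitutions at distinct positions of ``sequence``;
    the reference residue always matches the sequence, the alternate is
    uniform over the other 19."""
    sequence = sequence.upper()
    if count > len(sequence):
        raise ConservationError(
            f"cannot draw {count} distinct positions from length {len(sequence)}"
        )
    rng = np.random.default_rng(seed)
    positions = sorted(rng.choice(len(sequence), size=count, replace=False) + 1)
    subs = []
    for pos in positions:
        ref = sequence[pos - 1]
        alt = rng.choice([a for a in ALPHABET if a != ref])
        subs.append(Substitution(int(pos), ref, str(alt)))
    return subs


def write_aligned_fasta(aln: Alignment, path: str) -> None:
    with open(path, "w") as fh:
        for rid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{rid}\n{seq}\n")
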