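"""Physicochemical property space for amino acid substitutions.

A substitution's physicochemical impact (its PASE score) is the Euclidean
distance between the two residues in a seven-dimensional space of AAindex
property vectors, scaled so that the most dissimilar residue pair scores
exactly 1.  This module loads the property vectors from AAindex1 flat-file
text (or a plain TSV), builds the scaled space, and computes scores.

The packaged default uses seven AAindex entries covering hydrophobicity
(RADA880102, CHAM820102), steric bulk (FAUJ880103, DAWD720101),
electrostatics (ZIMJ680104), polarity (GRAR740102) and secondary-structure
propensity (CRAJ730103).  The scaling scheme and the seventh entry are both
configurable; see :func:`normalize`.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical one-letter residue codes, in the fixed AAindex I-record order.
ALPHABET = "ARNDCQEGHILKMFPSTWYV"

GAP = "-"

#: Accessions of the packaged seven-property table, calibrated so that the
#: published worked-example scores are reproduced at 2-decimal display.
PACKAGED_ACCESSIONS = (
    "RADA880102",  # transfer free energy, octanol -> water
    "FAUJ880103",  # normalized van der Waals volume
    "ZIMJ680104",  # isoelectric point
    "GRAR740102",  # polarity
    "CRAJ730103",  # normalized frequency of turn
    "DAWD720101",  # residue size
    "CHAM820102",  # free energy of solution in water
)

#: Documented alternative for the sixth slot: Crawford's helix propensity.
ALPHA_HELIX_ALTERNATIVE = "CRAJ730101"

#: Supported distance-scaling schemes.
#:
#: ``raw-global-max``    -- Euclidean distance on the raw property values,
#:                          divided by the largest pairwise distance
#:                          (the calibrated default).
#: ``minmax-global-max`` -- distance on per-property min-max rescaled values,
#:                          divided by the largest pairwise distance.
#: ``minmax-sqrt7``      -- distance on min-max rescaled values divided by
#:                          sqrt(7), the ceiling when every coordinate
#:                          difference is at most 1.
SCHEMES = ("raw-global-max", "minmax-global-max", "minmax-sqrt7")
DEFAULT_SCHEME = "raw-global-max"

N_PROPERTIES = 7


class PropertySpaceError(ValueError):
    """Invalid property table, residue code or scaling request."""


class AAindexParseError(PropertySpaceError):
    """Malformed or incomplete AAindex1 flat-file input."""


def _check_residue(code: str) -> str:
    if not isinstance(code, str) or len(code) != 1 or code.upper() not in ALPHABET:
        raise PropertySpaceError(
            f"non-canonical residue code {code!r}; expected one of {ALPHABET}"
        )
    return code.upper()


@dataclass(frozen=True)
class Substitution:
    """One amino acid substitution on the ungapped query protein.

    ``position`` is 1-based, following protein convention; ``ref`` and
    ``alt`` are canonical one-letter codes.
    """

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if int(self.position) < 1:
            raise PropertySpaceError(
                f"substitution position must be >= 1, got {self.position}"
            )
        object.__setattr__(self, "position", int(self.position))
        object.__setattr__(self, "ref", _check_residue(self.ref))
        object.__setattr__(self, "alt", _check_residue(self.alt))

    def __str__(self) -> str:
        return f"{self.ref}{self.position}{self.alt}"


@dataclass(frozen=True)
class PropertyTable:
    """Seven AAindex property vectors over the 20 canonical residues.

    ``values`` maps ``(accession, residue)`` to the raw, property-specific
    value; ``descriptions`` carries the AAindex D-line per accession when
    available.
    """

    accessions: tuple[str, ...]
    values: Mapping[tuple[str, str], float]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        accs = tuple(self.accessions)
        if len(accs) != N_PROPERTIES:
            raise PropertySpaceError(
                f"expected exactly {N_PROPERTIES} accessions, got {len(accs)}"
            )
        if len(set(accs)) != len(accs):
            raise PropertySpaceError("duplicate accession in property table")
        for acc in accs:
            for res in ALPHABET:
                v = self.values.get((acc, res))
                if v is None or not math.isfinite(float(v)):
                    raise PropertySpaceError(
                        f"missing or non-finite value for ({acc}, {res})"
                    )
        object.__setattr__(self, "accessions", accs)

    def vector(self, accession: str) -> np.ndarray:
        """Raw 20-vector of one property, in ALPHABET order."""
        if accession not in self.accessions:
            raise PropertySpaceError(f"accession not found: {accession}")
        return np.array([self.values[(accession, r)] for r in ALPHABET], float)

    def matrix(self) -> np.ndarray:
        """Raw 7 x 20 matrix, rows in accession order, columns in ALPHABET order."""
        return np.vstack([self.vector(a) for a in self.accessions])

    def to_aaindex_text(self) -> str:
        """Serialize back to AAindex1 flat-file text (H/D/I records)."""
        chunks = []
        for acc in self.accessions:
            v = self.vector(acc)
            row1 = "".join(f"{x:8.3f}" for x in v[:10])
            row2 = "".join(f"{x:8.3f}" for x in v[10:])
            desc = self.descriptions.get(acc, "")
            chunks.append(
                f"H {acc}\n"
                + (f"D {desc}\n" if desc else "")
                + "I    A/L     R/K     N/M     D/F     C/P     Q/S"
                "     E/T     G/W     H/Y     I/V\n"
                + row1
                + "\n"
                + row2
                + "\n//\n"
            )
        return "".join(chunks)


def parse_aaindex(flat_file_text: str, wanted_accessions: Sequence[str]) -> PropertyTable:
    """Parse AAindex1 flat-file text into a :class:`PropertyTable`.

    Entries are separated by ``//``; the H record names the accession and the
    I record carries 20 values in ALPHABET order split across two lines.
    Only ``wanted_accessions`` are retained, in the given order.

    Raises
    ------
    AAindexParseError
        If a wanted accession is absent, appears twice, or its I record has
        fewer than 20 numeric values.
    """
    wanted = list(wanted_accessions)
    found: dict[str, list[float]] = {}
    descriptions: dict[str, str] = {}

    for entry in flat_file_text.split("//"):
        lines = entry.splitlines()
        acc = None
        desc = ""
        numbers: list[float] = []
        in_i = False
        for line in lines:
            if line.startswith("H "):
                acc = line[2:].strip()
                in_i = False
            elif line.startswith("D "):
                desc = line[2:].strip()
                in_i = False
            elif line.startswith("I"):
                in_i = True  # header line; values follow on continuation lines
            elif in_i and (line.startswith(" ") or line.startswith("-")):
                for tok in line.split():
                    try:
                        numbers.append(float(tok))
                    except ValueError:
                        numbers.append(float("nan"))
            elif line[:1].isalpha():
                in_i = False
        if acc is None or acc not in wanted:
            continue
        if acc in found:
            raise AAindexParseError(f"duplicate AAindex entry for {acc}")
        if len(numbers) < len(ALPHABET):
            raise AAindexParseError(
                f"malformed I record for {acc}: found {len(numbers)} values, need 20"
            )
        found[acc] = numbers[: len(ALPHABET)]
        descriptions[acc] = desc

    missing = [a for a in wanted if a not in found]
    if missing:
        raise AAindexParseError(f"accession not found: {', '.join(missing)}")

    values = {
        (acc, res): found[acc][i]
        for acc in wanted
        for i, res in enumerate(ALPHABET)
    }
    return PropertyTable(tuple(wanted), values, descriptions)


def packaged_aaindex_text() -> str:
    """The vendored AAindex1 flat-file text shipped with the package."""
    return (
        resources.files("pase").joinpath("data/aaindex_pase.txt").read_text("utf-8")
    )


def load_packaged_table(seventh_accession: str | None = None) -> PropertyTable:
    """Load the packaged seven-property table.

    ``seventh_accession`` replaces the size entry (DAWD720101) with an
    alternative vendored entry, e.g. :data:`ALPHA_HELIX_ALTERNATIVE`.
    """
    accs = list(PACKAGED_ACCESSIONS)
    if seventh_accession and seventh_accession != "DAWD720101":
        accs[accs.index("DAWD720101")] = seventh_accession
    return parse_aaindex(packaged_aaindex_text(), accs)


def table_from_tsv(text_or_path: str) -> PropertyTable:
    """Read a property table from TSV: an ``accession`` column plus one
    column per residue letter."""
    if "\t" in text_or_path or "\n" in text_or_path:
        df = pd.read_csv(io.StringIO(text_or_path), sep="\t")
    else:
        df = pd.read_csv(text_or_path, sep="\t")
    df = df.set_index(df.columns[0])
    missing = [r for r in ALPHABET if r not in df.columns]
    if missing:
        raise PropertySpaceError(f"TSV lacks residue columns: {missing}")
    values = {
        (str(acc), res): float(df.loc[acc, res])
        for acc in df.index
        for res in ALPHABET
    }
    return PropertyTable(tuple(str(a) for a in df.index), values)


@dataclass(frozen=True)
class NormalizedPropertyTable:
    """A property table prepared for distance computation.

    ``norm_values`` always holds the per-property min-max rescaled values
    (each property spans exactly [0, 1] over the 20 residues).  Distances
    are computed in the coordinate space selected by ``scheme`` and divided
    by ``scale_factor`` so that scores fall in [0, 1].
    """

    source: PropertyTable
    norm_values: Mapping[tuple[str, str], float]
    scale_factor: float
    scheme: str = DEFAULT_SCHEME
    _distances: np.ndarray = field(repr=False, default=None)

    def distance(self, a: str, b: str) -> float:
        """Unscaled Euclidean distance between two residues."""
        i, j = ALPHABET.index(_check_residue(a)), ALPHABET.index(_check_residue(b))
        return float(self._distances[i, j])

    def score(self, a: str, b: str) -> float:
        """Scaled distance in [0, 1]."""
        return self.distance(a, b) / self.scale_factor


def _pairwise_distances(space: np.ndarray) -> np.ndarray:
    n = space.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = space[:, i] - space[:, j]
            d[i, j] = d[j, i] = math.sqrt(float(np.dot(diff, diff)))
    return d


def normalize(table: PropertyTable, scheme: str = DEFAULT_SCHEME) -> NormalizedPropertyTable:
    """Prepare a property table for scoring under the given scheme.

    Every property is min-max rescaled to [0, 1] regardless of scheme (a
    constant property is an error: it carries no information and cannot be
    rescaled).  ``scale_factor`` is the largest pairwise distance in the
    scheme's coordinate space, except under ``minmax-sqrt7`` where it is the
    analytic ceiling sqrt(7).
    """
    if scheme not in SCHEMES:
        raise PropertySpaceError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    raw = table.matrix()
    lo = raw.min(axis=1, keepdims=True)
    hi = raw.max(axis=1, keepdims=True)
    flat = np.nonzero((hi - lo).ravel() == 0)[0]
    if flat.size:
        bad = ", ".join(table.accessions[i] for i in flat)
        raise PropertySpaceError(f"property constant across residues, cannot rescale: {bad}")
    norm = (raw - lo) / (hi - lo)
    norm_values = {
        (acc, res): float(norm[i, j])
        for i, acc in enumerate(table.accessions)
        for j, res in enumerate(ALPHABET)
    }
    space = raw if scheme == "raw-global-max" else norm
    dists = _pairwise_distances(space)
    scale = math.sqrt(N_PROPERTIES) if scheme == "minmax-sqrt7" else float(dists.max())
    return NormalizedPropertyTable(table, norm_values, scale, scheme, dists)


def raw_distance(a: str, b: str, ntable: NormalizedPropertyTable) -> float:
    """Euclidean distance between residues ``a`` and ``b`` over the seven
    properties, in the (unscaled) coordinate space of ``ntable``."""
    return ntable.distance(a, b)


def pase_score(sub: Substitution, ntable: NormalizedPropertyTable) -> float:
    """Physicochemical impact score of a substitution, in [0, 1].

    0 iff the residue is substituted by itself; 1 for the single most
    dissimilar residue pair (under global-max scaling).
    """
    return ntable.score(sub.ref, sub.alt)


def distance_matrix(ntable: NormalizedPropertyTable) -> pd.DataFrame:
    """20 x 20 symmetric matrix of substitution scores, residues as labels."""
    m = ntable._distances / ntable.scale_factor
    return pd.DataFrame(m, index=list(ALPHABET), columns=list(ALPHABET))
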