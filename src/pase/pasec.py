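"""Combined scoring (PASEC = PASE x MSAC) and threshold-enrichment summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd

from .property_space import Substitution


class PasecError(ValueError):
    """Out-of-range score inputs or empty summaries."""


def combine(pase: float, msac: float) -> float:
    """Product of the physicochemical and conservation scores.

    Both scores live in [0, 1]; so does the product, which is bounded by
    the smaller factor.  0 is neutral; larger values predict a stronger
    functional effect.
    """
    p, c = float(pase), float(msac)
    if not 0.0 <= p <= 1.0:
        raise PasecError(f"pase score out of [0, 1]: {p}")
    if not 0.0 <= c <= 1.0:
        raise PasecError(f"msac score out of [0, 1]: {c}")
    return p * c


def format_score(value: float | None, decimals: int = 2) -> str:
    """Display formatting: fixed decimals, half-up; empty string for absent."""
    if value is None:
        return ""
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScoreRecord:
    """One scored substitution.

    ``pasec`` is derived at full precision (pase * msac) whenever a
    conservation score is present; rounding happens only at serialization.
    ``annotation`` carries any external label (e.g. a tolerated/deleterious
    call from another tool) through untouched.
    """

    substitution: Substitution
    pase: float
    msac: float | None = None
    pasec: float | None = field(default=None)
    flags: tuple[str, ...] = ()
    annotation: str | None = None

    def __post_init__(self) -> None:
        if self.msac is not None and self.pasec is None:
            object.__setattr__(self, "pasec", combine(self.pase, self.msac))

    def as_row(self) -> dict:
        s = self.substitution
        return {
            "id": str(s),
            "position": s.position,
            "ref": s.ref,
            "alt": s.alt,
            "PASE": format_score(self.pase),
            "MSAC": format_score(self.msac),
            "PASEC": format_score(self.pasec),
            "flags": ",".join(self.flags),
        }


def summarize_by_threshold(
    scores: Sequence[float],
    labels: Sequence[bool],
    bounds: Sequence[float],
    cumulative: bool = True,
) -> pd.DataFrame:
    """Enrichment of positive labels among high-scoring records.

    For each bound b the cumulative reading (default) takes all records
    with score >= b and reports the percentage carrying a positive label;
    with ``cumulative=False`` each bound owns the half-open interval up to
    the next bound.  Empty bins report NaN, not zero.

    Returns a DataFrame with columns bound, count, positive, percent.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    if scores.size == 0 or scores.shape != labels.shape:
        raise PasecError("need equally many scores and labels, at least one record")
    bounds = [float(b) for b in bounds]
    if sorted(bounds) != bounds or len(set(bounds)) != len(bounds):
        raise PasecError("bounds must be strictly increasing")
    rows = []
    for i, b in enumerate(bounds):
        mask = scores >= b
        if not cumulative and i + 1 < len(bounds):
            mask &= scores < bounds[i + 1]
        n = int(mask.sum())
        pos = int(labels[mask].sum())
        pct = 100.0 * pos / n if n else float("nan")
        rows.append({"bound": b, "count": n, "positive": pos, "percent": pct})
    return pd.DataFrame(rows)


def records_to_frame(records: Sequence[ScoreRecord]) -> pd.DataFrame:
    """Tabular (display-rounded) view of score records."""
    return pd.DataFrame([r.as_row() for r in records])


def write_report(
    records: Sequence[ScoreRecord],
    path: str,
    header_lines: Sequence[str] = (),
) -> None:
    """Write the TSV score report, with '#'-prefixed provenance header."""
    df = records_to_frame(records)
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
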