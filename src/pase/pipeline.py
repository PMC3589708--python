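"""End-to-end scoring workflow: configuration, input parsing, report writing.

The flow mirrors how the scores are meant to be used: a query protein and a
substitution list always yield PASE scores; when an alignment containing
the query is supplied, each substitution site also gets an MSAC
conservation score and the combined PASEC product.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, asdict, replace

from Bio import SeqIO

from . import __version__
from .property_space import (
    ALPHABET,
    DEFAULT_SCHEME,
    SCHEMES,
    PropertySpaceError,
    Substitution,
    load_packaged_table,
    normalize,
    parse_aaindex,
    pase_score,
    table_from_tsv,
)
from .conservation import (
    GAP_POLICIES,
    Alignment,
    ConservationError,
    msac_score,
    read_alignment,
)
from .pasec import ScoreRecord, write_report


class PipelineError(ValueError):
    """Invalid configuration, inputs or strict-mode violation."""


_SUB_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


def parse_substitution(token: str) -> Substitution:
    """Parse compact substitution notation, e.g. 'W45S'."""
    m = _SUB_RE.match(token.strip())
    if not m:
        raise PipelineError(f"malformed substitution token: {token!r}")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    try:
        return Substitution(pos, ref, alt)
    except PropertySpaceError as exc:
        raise PipelineError(f"invalid substitution {token!r}: {exc}") from exc


def read_substitution_list(path: str) -> list[Substitution]:
    """One token per line; '#' starts a comment; commas also separate tokens."""
    subs = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            for token in re.split(r"[,\s]+", line):
                if token:
                    subs.append(parse_substitution(token))
    return subs


@dataclass(frozen=True)
class RunConfig:
    """Scoring run configuration; round-trips losslessly through JSON."""

    property_source: str = "packaged"        # 'packaged' or a file path
    seventh_accession: str | None = None     # override for the packaged table
    scheme: str = DEFAULT_SCHEME
    gap_policy: str = "all-rows"
    evalue_threshold: float = 0.01
    strict: bool = False
    skip_invalid: bool = False               # skip-with-warning for bad records
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise PipelineError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")
        if self.gap_policy not in GAP_POLICIES:
            raise PipelineError(
                f"unknown gap policy {self.gap_policy!r}; choose from {GAP_POLICIES}"
            )
        if self.evalue_threshold <= 0:
            raise PipelineError("evalue_threshold must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def digest(self) -> str:
        """Short stable hash of the configuration, for report provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_table(config: RunConfig):
    """Resolve the property table named by the configuration."""
    if config.property_source == "packaged":
        return load_packaged_table(config.seventh_accession)
    with open(config.property_source) as fh:
        text = fh.read()
    if text.lstrip().startswith("H "):
        accessions = re.findall(r"^H\s+(\S+)", text, re.M)
        return parse_aaindex(text, accessions)
    return table_from_tsv(text)


def read_query(path: str) -> tuple[str, str]:
    """First record of a FASTA file as (id, ungapped sequence)."""
    for rec in SeqIO.parse(path, "fasta"):
        return rec.id, str(rec.seq).upper().replace("-", "")
    raise PipelineError(f"no FASTA record found in {path}")


def score_substitutions(
    subs: list[Substitution],
    query: str,
    config: RunConfig,
    aln: Alignment | None = None,
) -> list[ScoreRecord]:
    """Score each substitution against the query (PASE), plus MSAC/PASEC
    when an alignment is available.

    Flags: ``ref_mismatch`` when the stated reference residue disagrees
    with the query sequence (a hard error in strict mode), and
    ``out_of_range`` for positions beyond the query (never scored; a hard
    error unless ``skip_invalid``).
    """
    ntable = normalize(load_table(config), config.scheme)
    records: list[ScoreRecord] = []
    for sub in subs:
        flags: list[str] = []
        if sub.position > len(query):
            if not config.skip_invalid:
                raise PipelineError(
                    f"{sub}: position beyond query length {len(query)}"
                )
            records.append(ScoreRecord(sub, 0.0, flags=("out_of_range", "skipped")))
            continue
        if query[sub.position - 1] != sub.ref:
            if config.strict:
                raise PipelineError(
                    f"{sub}: query has {query[sub.position - 1]} at position "
                    f"{sub.position}, not {sub.ref}"
                )
            flags.append("ref_mismatch")
        p = pase_score(sub, ntable)
        c = None
        if aln is not None:
            site = msac_score(
                aln, sub.position, sub.ref,
                gap_policy=config.gap_policy, strict=False,
            )
            c = site.score
            if site.reference_mismatch and "ref_mismatch" not in flags:
                flags.append("ref_mismatch")
        records.append(ScoreRecord(sub, p, c, flags=tuple(flags)))
    return records


def run_score(
    config: RunConfig,
    query_path: str,
    subs_path: str,
    msa_path: str | None = None,
    out_path: str = "pase_report.tsv",
) -> str:
    """Full scoring run from files to a TSV report; returns the report path."""
    query_id, query = read_query(query_path)
    subs = read_substitution_list(subs_path)
    aln = None
    if msa_path is not None:
        aln = read_alignment(msa_path)
        if query_id in aln.ids:
            aln = replace(aln, reference_id=query_id)
        else:
            raise PipelineError(f"query {query_id!r} not found in alignment {msa_path}")
    records = score_substitutions(subs, query, config, aln)
    header = [
        f"pase {__version__}",
        f"config {config.digest()} scheme={config.scheme} gap_policy={config.gap_policy}",
        f"query {query_id} length={len(query)} n_substitutions={len(subs)}"
        + (f" msa_rows={aln.n_rows}" if aln else " msa=none"),
    ]
    write_report(records, out_path, header)
    return out_path
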