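"""Sequence, hit-table and metadata I/O plus the pipeline configuration.

Sequences travel as :class:`GenomeRecord` / :class:`ReadRecord`; pairwise
alignment results as :class:`HitRecord` in the NCBI 12-column tabular
convention (qseqid sseqid pident length mismatch gapopen qstart qend sstart
send evalue bitscore).  Tabular coordinates are 1-based inclusive; all
internal interval arithmetic is 0-based half-open and converts only at
(de)serialization.  Every numeric threshold of the analysis lives in
:class:`PipelineConfig`.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .errors import DuplicateIdError, ParameterError, ParseError

logger = logging.getLogger("podovirome")

_NT_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_NT = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_NT_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """One phage genome with its clade label."""

    genome_id: str
    sequence: str
    clade: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ParameterError(f"genome {self.genome_id!r}: empty sequence")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadRecord:
    """One metagenomic read attributed to a sample."""

    read_id: str
    sequence: str
    sample_id: str = ""

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HitRecord:
    """One alignment hit in 12-column tabular convention (1-based inclusive).

    ``s_start > s_end`` means the subject was hit on the reverse strand.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if self.q_start > self.q_end:
            raise ParameterError(
                f"hit {self.query_id}->{self.subject_id}: q_start > q_end"
            )
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ParameterError(
                f"hit {self.query_id}->{self.subject_id}: pct_identity outside [0,100]"
            )

    @property
    def strand(self) -> str:
        return "-" if self.s_start > self.s_end else "+"

    def subject_interval(self) -> tuple[int, int]:
        """Subject interval as 0-based half-open forward-strand coordinates."""
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi

    def query_span(self) -> int:
        return self.q_end - self.q_start + 1


@dataclass
class SampleMeta:
    """Per-sample metadata: depth layer, dataset size and environmental variables."""

    sample_id: str
    layer: str = "SRF"  # SRF, DCM or MIX
    depth_m: float = 0.0
    dataset_gb: float = 1.0
    site: str | None = None  # shared by the SRF and DCM/MIX samples of one station
    env: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.dataset_gb <= 0:
            raise ParameterError(f"sample {self.sample_id!r}: dataset_gb must be > 0")
        if self.layer not in ("SRF", "DCM", "MIX"):
            raise ParameterError(f"sample {self.sample_id!r}: unknown layer {self.layer!r}")
        if self.site is None:
            self.site = self.sample_id


@dataclass
class PipelineConfig:
    """Every numeric threshold of the analysis, with the published defaults.

    Read recruitment keeps a hit when e-value < ``evalue_max`` (strict),
    percent identity >= ``read_identity_min_pct`` (inclusive) and the aligned
    fraction of the read > ``read_coverage_min`` (strict).  A genome with
    coverage breadth below ``breadth_presence_min`` is called absent (KPKG 0);
    a sample whose best clade-level KPKG falls below ``kpkg_sample_min`` is
    omitted.  Orthology uses reciprocal best hits at ``rbh_evalue_max`` and
    ``rbh_coverage_min`` of the shorter gene; populations are single-linkage
    components at ``ani_population_threshold_pct``.
    """

    evalue_max: float = 1e-5
    read_identity_min_pct: float = 95.0
    read_coverage_min: float = 0.90
    breadth_presence_min: float = 0.40
    kpkg_sample_min: float = 0.001
    ani_population_threshold_pct: float = 95.0
    rbh_evalue_max: float = 1e-5
    rbh_coverage_min: float = 0.75
    mantel_permutations: int = 999
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("read_coverage_min", "breadth_presence_min", "rbh_coverage_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be a fraction in [0,1], got {v}")
        for name in ("read_identity_min_pct", "ani_population_threshold_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 101.0:
                raise ParameterError(f"{name} out of range: {v}")
        if self.evalue_max <= 0 or self.rbh_evalue_max <= 0:
            raise ParameterError("e-value cutoffs must be positive")
        if self.mantel_permutations < 1:
            raise ParameterError("mantel_permutations must be >= 1")


_CONFIG_FIELDS = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat ``key = value`` config file; keys are PipelineConfig fields."""
    values: dict[str, float | int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"expected 'key = value', got {line!r}", lineno)
            key, _, val = (t.strip() for t in line.partition("="))
            if key not in _CONFIG_FIELDS:
                raise ParseError(f"unknown configuration key {key!r}", lineno)
            try:
                values[key] = (
                    int(val) if key in ("mantel_permutations", "rng_seed") else float(val)
                )
            except ValueError as exc:
                raise ParseError(f"cannot parse value for {key!r}: {val!r}", lineno) from exc
    return PipelineConfig(**values)


# ---------------------------------------------------------------------------
# sequence I/O


def _normalize_sequence(seq: str, ident: str, line: int | None) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _VALID_NT
    if bad:
        raise ParseError(
            f"record {ident!r}: ambiguity codes other than N are not supported "
            f"({', '.join(sorted(bad))})",
            line,
        )
    return seq


def read_sequences(
    path: str | Path,
    format: str = "fasta",
    *,
    as_reads: bool = False,
    sample_id: str = "",
) -> list[GenomeRecord] | list[ReadRecord]:
    """Parse a FASTA or FASTQ file into records, preserving file order.

    Sequences are upper-cased and U is mapped to T; ambiguity codes other
    than N are rejected.  Duplicate identifiers raise
    :class:`~podovirome.errors.DuplicateIdError`.
    """
    if format not in ("fasta", "fastq"):
        raise ParameterError(f"unsupported format {format!r}")
    records: list = []
    seen: set[str] = set()
    lines_per_record = 4 if format == "fastq" else None
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), format)):
            approx_line = 1 + i * lines_per_record if lines_per_record else None
            seq = _normalize_sequence(str(rec.seq), rec.id, approx_line)
            if not seq:
                raise ParseError(f"record {rec.id!r}: empty sequence", approx_line)
            if rec.id in seen:
                raise DuplicateIdError(f"duplicate identifier {rec.id!r}", approx_line)
            seen.add(rec.id)
            if as_reads:
                records.append(ReadRecord(rec.id, seq, sample_id=sample_id))
            else:
                records.append(GenomeRecord(rec.id, seq))
    except ValueError as exc:  # biopython signals malformed records this way
        raise ParseError(
            f"malformed {format} record #{len(records) + 1}: {exc}",
            (1 + len(records) * lines_per_record) if lines_per_record else None,
        ) from exc
    return records


def write_fasta(records: Iterable[GenomeRecord | ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            ident = getattr(rec, "genome_id", None) or getattr(rec, "read_id")
            fh.write(f">{ident}\n{rec.sequence}\n")


def write_fastq(records: Iterable[ReadRecord], path: str | Path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{quality_char * rec.length_bp}\n")


# ---------------------------------------------------------------------------
# tabular hit I/O

_HIT_COLUMNS = (
    "query_id subject_id pct_identity aln_length mismatches gap_opens "
    "q_start q_end s_start s_end evalue bitscore"
).split()


def parse_hits(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tabular hit file; '#' comment lines are skipped."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(f"expected 12 tab-separated fields, got {len(fields)}", lineno)
            try:
                hits.append(
                    HitRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"unparseable numeric field: {exc}", lineno) from exc
    return hits


def write_hits(hits: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits in the 12-column tabular convention (no header, '#' comments allowed)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t{h.aln_length}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.q_start}\t{h.q_end}\t"
                f"{h.s_start}\t{h.s_end}\t{h.evalue:.3g}\t{h.bitscore:.6g}\n"
            )


# ---------------------------------------------------------------------------
# generic result tables


def write_table(records, path: str | Path, sort_by: Sequence[str] | None = None) -> None:
    """Write dataclass records or a DataFrame as headered TSV, deterministically ordered."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r) for r in records]
        df = pd.DataFrame(rows)
    if sort_by and not df.empty:
        df = df.sort_values(list(sort_by), kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read a sample-metadata TSV; non-reserved columns become env variables."""
    df = read_table(path)
    reserved = {"sample_id", "layer", "depth_m", "dataset_gb", "site"}
    metas = []
    for _, row in df.iterrows():
        env = {
            c: float(row[c]) for c in df.columns if c not in reserved and pd.notna(row[c])
        }
        metas.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                layer=str(row.get("layer", "SRF")),
                depth_m=float(row.get("depth_m", 0.0)),
                dataset_gb=float(row.get("dataset_gb", 1.0)),
                site=str(row["site"]) if "site" in df.columns and pd.notna(row["site"]) else None,
                env=env,
            )
        )
    return metas


def write_sample_meta(metas: Iterable[SampleMeta], path: str | Path) -> None:
    rows = []
    for m in metas:
        row = {
            "sample_id": m.sample_id,
            "layer": m.layer,
            "depth_m": m.depth_m,
            "dataset_gb": m.dataset_gb,
            "site": m.site,
        }
        row.update(m.env)
        rows.append(row)
    write_table(pd.DataFrame(rows), path, sort_by=["sample_id"])
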