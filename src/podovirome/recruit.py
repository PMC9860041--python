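"""Fragment-recruitment quantification of clade abundance (KPKG).

Read hits pass three filters — e-value < 1e-5 (strict), percent identity
>= 95 (inclusive) and aligned fraction of the read > 0.90 (strict) — and each
surviving read is assigned to the single genome with the highest bitscore
(exact ties broken by lexicographically smallest genome id).  Per genome and
sample, abundance is KPKG: kilobases of recruited read alignment per kilobase
of genome per gigabase of dataset.  A genome covered over less than 40% of
its positions (coverage breadth) is called absent and forced to KPKG 0; a
sample whose best clade-level KPKG is below 0.001 is omitted.  Clade
abundances are sums of member-genome KPKG, optionally pooled per depth layer,
and depth contrasts are reported as log10(KPKG + 1) pairs for sites sampled
at both the surface and depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import GenomeIndex, ScoringScheme, map_read, nucleotide_scheme
from .errors import ParameterError
from .seqio import GenomeRecord, HitRecord, PipelineConfig, ReadRecord, SampleMeta


@dataclass(frozen=True)
class RecruitedRead:
    read_id: str
    genome_id: str
    aligned_nt: int  # alignment length on the read (q_end - q_start + 1)
    pct_identity: float
    bitscore: float
    s_interval: tuple[int, int]  # 0-based half-open on the genome


@dataclass(frozen=True)
class KPKGRecord:
    sample_id: str
    genome_id: str
    recruited_kb: float
    genome_kb: float
    dataset_gb: float
    breadth: float
    present: bool
    kpkg: float


@dataclass(frozen=True)
class CladeAbundance:
    sample_id: str
    clade: str
    kpkg_sum: float
    proportion: float  # NaN when the sample recruited nothing


def filter_hits(
    hits: list[HitRecord], read_lengths: dict[str, int], cfg: PipelineConfig
) -> list[HitRecord]:
    """Apply the e-value, identity and read-coverage recruitment filters.

    Boundary semantics follow the printed inequalities: e-value strictly
    below the cutoff, read coverage strictly above, identity inclusive.
    """
    kept = []
    for h in hits:
        if h.query_id not in read_lengths:
            raise ParameterError(f"hit references unknown read {h.query_id!r}")
        read_len = read_lengths[h.query_id]
        if (
            h.evalue < cfg.evalue_max
            and h.pct_identity >= cfg.read_identity_min_pct
            and h.query_span() / read_len > cfg.read_coverage_min
        ):
            kept.append(h)
    return kept


def assign_reads(filtered: list[HitRecord]) -> list[RecruitedRead]:
    """One genome per read: highest bitscore, ties to the smallest genome id."""
    best: dict[str, HitRecord] = {}
    for h in filtered:
        prev = best.get(h.query_id)
        if (
            prev is None
            or h.bitscore > prev.bitscore
            or (h.bitscore == prev.bitscore and h.subject_id < prev.subject_id)
        ):
            best[h.query_id] = h
    return [
        RecruitedRead(
            read_id=h.query_id,
            genome_id=h.subject_id,
            aligned_nt=h.query_span(),
            pct_identity=h.pct_identity,
            bitscore=h.bitscore,
            s_interval=h.subject_interval(),
        )
        for h in sorted(best.values(), key=lambda h: h.query_id)
    ]


def genome_breadth(intervals: list[tuple[int, int]], genome_length: int) -> float:
    """Fraction of genome positions covered by >= 1 interval (merged union)."""
    if not intervals:
        return 0.0
    for lo, hi in intervals:
        if lo < 0 or hi > genome_length or lo >= hi:
            raise ParameterError(f"interval ({lo}, {hi}) outside genome of {genome_length} bp")
    arr = sorted(intervals)
    covered = 0
    cur_lo, cur_hi = arr[0]
    for lo, hi in arr[1:]:
        if lo > cur_hi:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    covered += cur_hi - cur_lo
    return covered / genome_length


def compute_kpkg(
    assigned: list[RecruitedRead],
    genome: GenomeRecord,
    meta: SampleMeta,
    breadth: float,
    cfg: PipelineConfig,
) -> KPKGRecord:
    """KPKG = recruited kb / (genome kb * dataset Gb); 0 when breadth < 40%."""
    own = [r for r in assigned if r.genome_id == genome.genome_id]
    recruited_kb = sum(r.aligned_nt for r in own) / 1000.0
    genome_kb = genome.length_bp / 1000.0
    kpkg_raw = recruited_kb / (genome_kb * meta.dataset_gb)
    present = breadth >= cfg.breadth_presence_min
    return KPKGRecord(
        sample_id=meta.sample_id,
        genome_id=genome.genome_id,
        recruited_kb=recruited_kb,
        genome_kb=genome_kb,
        dataset_gb=meta.dataset_gb,
        breadth=breadth,
        present=present,
        kpkg=kpkg_raw if present else 0.0,
    )


def clade_kpkg(records: list[KPKGRecord], clade_map: dict[str, str]) -> dict[str, float]:
    """Clade-level KPKG for one sample: sum over member genomes."""
    sums: dict[str, float] = {}
    for r in records:
        clade = clade_map[r.genome_id]
        sums[clade] = sums.get(clade, 0.0) + r.kpkg
    return sums


def sample_gate(
    records: list[KPKGRecord], clade_map: dict[str, str], cfg: PipelineConfig
) -> bool:
    """Keep a sample iff its best clade-level KPKG reaches the 0.001 floor."""
    sums = clade_kpkg(records, clade_map)
    return bool(sums) and max(sums.values()) >= cfg.kpkg_sample_min


def clade_abundance(
    records: list[KPKGRecord],
    clade_map: dict[str, str],
    included_samples: set[str] | None = None,
) -> list[CladeAbundance]:
    """Per-sample clade KPKG sums and proportions over the included samples."""
    by_sample: dict[str, list[KPKGRecord]] = {}
    for r in records:
        if included_samples is None or r.sample_id in included_samples:
            by_sample.setdefault(r.sample_id, []).append(r)
    clades = sorted({clade_map[r.genome_id] for r in records})
    out: list[CladeAbundance] = []
    for sample_id in sorted(by_sample):
        sums = clade_kpkg(by_sample[sample_id], clade_map)
        total = sum(sums.values())
        for clade in clades:
            s = sums.get(clade, 0.0)
            out.append(
                CladeAbundance(
                    sample_id=sample_id,
                    clade=clade,
                    kpkg_sum=s,
                    proportion=s / total if total > 0 else math.nan,
                )
            )
    return out


def layer_proportions(
    abundances: list[CladeAbundance],
    metas: dict[str, SampleMeta],
    method: str = "pooled",
) -> pd.DataFrame:
    """Clade proportions per depth layer.

    ``pooled`` (default) sums clade KPKG over the layer's samples before
    normalizing; ``mean`` averages the per-sample proportions instead.
    """
    if method not in ("pooled", "mean"):
        raise ParameterError(f"unknown pooling method {method!r}")
    rows = []
    for a in abundances:
        layer = metas[a.sample_id].layer
        rows.append((layer, a.clade, a.kpkg_sum, a.proportion))
    df = pd.DataFrame(rows, columns=["layer", "clade", "kpkg_sum", "proportion"])
    out = []
    for layer, sub in df.groupby("layer"):
        if method == "pooled":
            sums = sub.groupby("clade")["kpkg_sum"].sum()
            total = sums.sum()
            props = sums / total if total > 0 else sums * math.nan
        else:
            props = sub.dropna(subset=["proportion"]).groupby("clade")["proportion"].mean()
        for clade, p in props.items():
            out.append({"layer": layer, "clade": clade, "proportion": p})
    return pd.DataFrame(out, columns=["layer", "clade", "proportion"])


def depth_contrast(
    records: list[KPKGRecord],
    metas: dict[str, SampleMeta],
    clade_map: dict[str, str],
    included_samples: set[str] | None = None,
) -> pd.DataFrame:
    """Paired log10(KPKG+1) per (site, clade) for sites with SRF and DCM/MIX.

    DCM and MIX both count as the deep member of the pair.  When a site has
    several samples in one layer their clade KPKG is summed before the
    transform.
    """
    rows = []
    for r in records:
        if included_samples is not None and r.sample_id not in included_samples:
            continue
        meta = metas[r.sample_id]
        stratum = "SRF" if meta.layer == "SRF" else "DEEP"
        rows.append((meta.site, stratum, clade_map[r.genome_id], r.kpkg))
    if not rows:
        return pd.DataFrame(columns=["site", "clade", "srf_log10_kpkg", "deep_log10_kpkg"])
    df = (
        pd.DataFrame(rows, columns=["site", "stratum", "clade", "kpkg"])
        .groupby(["site", "stratum", "clade"], as_index=False)["kpkg"]
        .sum()
    )
    wide = df.pivot_table(index=["site", "clade"], columns="stratum", values="kpkg")
    if "SRF" not in wide.columns or "DEEP" not in wide.columns:
        return pd.DataFrame(columns=["site", "clade", "srf_log10_kpkg", "deep_log10_kpkg"])
    wide = wide.dropna(subset=["SRF", "DEEP"]).reset_index()
    wide["srf_log10_kpkg"] = np.log10(wide["SRF"] + 1.0)
    wide["deep_log10_kpkg"] = np.log10(wide["DEEP"] + 1.0)
    return wide[["site", "clade", "srf_log10_kpkg", "deep_log10_kpkg"]].sort_values(
        ["site", "clade"], ignore_index=True
    )


# ---------------------------------------------------------------------------
# orchestration


def recruit_sample(
    reads: list[ReadRecord],
    genomes: list[GenomeRecord],
    meta: SampleMeta,
    cfg: PipelineConfig,
    index: GenomeIndex | None = None,
    scheme: ScoringScheme | None = None,
    hits: list[HitRecord] | None = None,
    min_seed_count: int = 8,
) -> tuple[list[KPKGRecord], list[RecruitedRead]]:
    """Map (or ingest), filter, assign, and quantify one sample end to end.

    Precomputed 12-column hits may be passed instead of running the internal
    mapper.  If hits are supplied without the reads themselves, each read's
    length is taken as its largest aligned query coordinate — a lower bound
    that makes the read-coverage filter permissive rather than lossy.
    """
    scheme = scheme or nucleotide_scheme()
    read_lengths = {r.read_id: r.length_bp for r in reads}
    if hits is not None and not read_lengths:
        for h in hits:
            read_lengths[h.query_id] = max(read_lengths.get(h.query_id, 0), h.q_end)
    if hits is None:
        index = index or GenomeIndex(genomes)
        hits = []
        for read in reads:
            hits.extend(map_read(read, index, scheme, min_seed_count=min_seed_count))
    filtered = filter_hits(hits, read_lengths, cfg)
    assigned = assign_reads(filtered)
    by_genome: dict[str, list[RecruitedRead]] = {}
    for r in assigned:
        by_genome.setdefault(r.genome_id, []).append(r)
    records = []
    for genome in genomes:
        own = by_genome.get(genome.genome_id, [])
        breadth = genome_breadth([r.s_interval for r in own], genome.length_bp)
        records.append(compute_kpkg(own, genome, meta, breadth, cfg))
    return records, assigned


def kpkg_table(records: list[KPKGRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    return df.sort_values(["sample_id", "genome_id"], ignore_index=True)
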