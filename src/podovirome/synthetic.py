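"""Clade-structured synthetic genomes, proteomes, viromes and environment tables.

The generator emulates the structure of a cyanopodovirus study population:

* genomes evolve by per-site substitution (no indels) from a single root,
  through one ancestor per clade, giving controlled within-clade (~0–5%) and
  between-clade (~10–60%) divergence;
* gene complements combine core families present in every genome,
  clade-specific families, and Poisson-distributed strain-specific genes;
* viromes draw reads from genomes at known clade mixing proportions with a
  substitution error model, plus uniform-random background reads that cannot
  pass a 95% identity filter;
* environmental tables are linear functions of a clade's true abundance with
  Gaussian noise, so downstream Mantel tests have a known answer.

Every operation is a pure function of (spec, seed).  Ground truth (per-read
source, gene-family membership) is always returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AA_ALPHABET, NT_ALPHABET
from .errors import ParameterError
from .seqio import GenomeRecord, ReadRecord, SampleMeta

_NT = np.array(list("ACGT"))
_AA = np.array(list(AA_ALPHABET[:-1]))  # 20 standard residues, no X


@dataclass(frozen=True)
class CladeSpec:
    """One clade: genome count and divergence to the clade ancestor / root."""

    clade_id: str
    n_genomes: int
    within_clade_divergence: float = 0.02
    to_root_divergence: float = 0.15

    def __post_init__(self):
        if not 0.0 <= self.within_clade_divergence <= 0.5:
            raise ParameterError("within_clade_divergence must lie in [0, 0.5]")
        if not 0.0 <= self.to_root_divergence <= 0.75:
            raise ParameterError("to_root_divergence must lie in [0, 0.75]")
        if self.n_genomes > 1 and self.within_clade_divergence >= max(
            self.to_root_divergence, 1e-9
        ):
            raise ParameterError(
                "clades must be separable: within_clade_divergence < to_root_divergence"
            )
        if self.n_genomes < 1:
            raise ParameterError("n_genomes must be >= 1")


@dataclass(frozen=True)
class GenePoolSpec:
    """Gene-family layout: core, clade-specific and strain-specific genes."""

    n_core: int = 9
    n_clade_specific_per_clade: int = 3
    n_strain_specific_mean: float = 2.0
    gene_length_aa: int = 120
    within_family_divergence: float = 0.02   # aa substitutions genome vs clade copy
    between_clade_divergence: float = 0.10   # aa substitutions clade copy vs root copy

    def __post_init__(self):
        if self.n_core < 0 or self.n_clade_specific_per_clade < 0:
            raise ParameterError("gene counts must be non-negative")
        if self.gene_length_aa < 1:
            raise ParameterError("gene_length_aa must be positive")


@dataclass(frozen=True)
class ViromeSpec:
    """A simulated sample: clade mixing proportions, read count and error rate."""

    proportions: dict[str, float]  # clade_id -> fraction; may include "background"
    n_reads: int = 50_000
    read_length_bp: int = 150
    substitution_error_rate: float = 0.01
    dataset_gb: float | None = None  # default: n_reads * read_length / 1e9

    def __post_init__(self):
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.proportions.values()):
            raise ParameterError("proportions must be non-negative")
        if not 0.0 <= self.substitution_error_rate <= 0.1:
            raise ParameterError("substitution_error_rate must lie in [0, 0.1]")
        if self.n_reads < 1 or self.read_length_bp < 1:
            raise ParameterError("n_reads and read_length_bp must be positive")


@dataclass
class ViromeTruth:
    """Ground truth of a simulated virome: per-read source and intended mix."""

    read_source: dict[str, str]          # read_id -> genome_id or "background"
    clade_proportions: dict[str, float]  # the intended mixing proportions
    read_clade: dict[str, str] = field(default_factory=dict)

    def clade_read_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for clade in self.read_clade.values():
            counts[clade] = counts.get(clade, 0) + 1
        return counts


def _mutate_nt(seq_codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution; a substituted base is one of the 3 alternatives."""
    if rate == 0.0:
        return seq_codes.copy()
    mask = rng.random(seq_codes.shape[0]) < rate
    shifts = rng.integers(1, 4, size=int(mask.sum()))
    out = seq_codes.copy()
    out[mask] = (out[mask] + shifts) % 4
    return out


def _mutate_aa(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return seq
    arr = np.array(list(seq))
    mask = rng.random(arr.shape[0]) < rate
    for i in np.flatnonzero(mask):
        choices = _AA[_AA != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return "".join(arr)


def simulate_clade_genomes(
    clades: list[CladeSpec], genome_length_bp: int = 30_000, seed: int = 0
) -> list[GenomeRecord]:
    """Evolve one root sequence into labelled clade members by substitution only."""
    if genome_length_bp < 1000:
        raise ParameterError("genome_length_bp must be >= 1000")
    if not clades:
        raise ParameterError("at least one CladeSpec is required")
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, genome_length_bp).astype(np.int8)
    genomes: list[GenomeRecord] = []
    for spec in clades:
        ancestor = _mutate_nt(root, spec.to_root_divergence, rng)
        for i in range(spec.n_genomes):
            codes = _mutate_nt(ancestor, spec.within_clade_divergence, rng)
            genomes.append(
                GenomeRecord(
                    genome_id=f"{spec.clade_id}_g{i + 1:02d}",
                    sequence="".join(_NT[codes]),
                    clade=spec.clade_id,
                )
            )
    return genomes


def simulate_gene_complements(
    genomes: list[GenomeRecord], pool: GenePoolSpec, seed: int = 0
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Generate per-genome protein complements with a gene-family truth table.

    Returns ``(proteomes, truth)`` where ``proteomes`` maps genome_id to a
    list of (gene_id, aa_sequence) and ``truth`` has columns genome_id,
    gene_id, family, category (core / clade / strain).
    """
    if not genomes:
        raise ParameterError("genomes must be non-empty")
    rng = np.random.default_rng(seed)
    clades = sorted({g.clade for g in genomes})

    def new_protein() -> str:
        return "".join(_AA[rng.integers(0, 20, pool.gene_length_aa)])

    core_roots = [new_protein() for _ in range(pool.n_core)]
    # one ancestor copy of each core family per clade, mirroring genome structure
    core_clade_copies = {
        c: [_mutate_aa(p, pool.between_clade_divergence, rng) for p in core_roots]
        for c in clades
    }
    clade_families = {
        c: [new_protein() for _ in range(pool.n_clade_specific_per_clade)] for c in clades
    }
    proteomes: dict[str, list[tuple[str, str]]] = {}
    rows = []
    for g in genomes:
        genes: list[tuple[str, str]] = []
        for fam_i, clade_copy in enumerate(core_clade_copies[g.clade]):
            gene_id = f"{g.genome_id}_core{fam_i:03d}"
            genes.append((gene_id, _mutate_aa(clade_copy, pool.within_family_divergence, rng)))
            rows.append((g.genome_id, gene_id, f"core{fam_i:03d}", "core"))
        for fam_i, proto in enumerate(clade_families[g.clade]):
            gene_id = f"{g.genome_id}_clade{fam_i:03d}"
            genes.append((gene_id, _mutate_aa(proto, pool.within_family_divergence, rng)))
            rows.append((g.genome_id, gene_id, f"{g.clade}_clade{fam_i:03d}", "clade"))
        n_strain = int(rng.poisson(pool.n_strain_specific_mean))
        for s_i in range(n_strain):
            gene_id = f"{g.genome_id}_strain{s_i:03d}"
            genes.append((gene_id, new_protein()))
            rows.append((g.genome_id, gene_id, f"{g.genome_id}_strain{s_i:03d}", "strain"))
        proteomes[g.genome_id] = genes
    truth = pd.DataFrame(rows, columns=["genome_id", "gene_id", "family", "category"])
    return proteomes, truth


def true_pan_core(truth: pd.DataFrame) -> tuple[int, int]:
    """Pan/core family counts implied by a gene-family truth table."""
    genomes = truth["genome_id"].unique()
    by_family = truth.groupby("family")["genome_id"].nunique()
    return int(len(by_family)), int((by_family == len(genomes)).sum())


def simulate_virome(
    genomes: list[GenomeRecord],
    spec: ViromeSpec,
    seed: int = 0,
    sample_id: str = "sample1",
    layer: str = "SRF",
    depth_m: float = 5.0,
    site: str | None = None,
) -> tuple[list[ReadRecord], ViromeTruth, SampleMeta]:
    """Draw reads from genomes at the spec's clade proportions, plus background."""
    by_clade: dict[str, list[GenomeRecord]] = {}
    for g in genomes:
        by_clade.setdefault(g.clade, []).append(g)
    unknown = set(spec.proportions) - set(by_clade) - {"background"}
    if unknown:
        raise ParameterError(f"proportions name unknown clades: {sorted(unknown)}")
    for g in genomes:
        if spec.read_length_bp > g.length_bp:
            raise ParameterError(
                f"read_length_bp {spec.read_length_bp} exceeds genome {g.genome_id}"
            )
    rng = np.random.default_rng(seed)
    keys = sorted(spec.proportions)
    probs = np.array([spec.proportions[k] for k in keys])
    choices = rng.choice(len(keys), size=spec.n_reads, p=probs)
    reads: list[ReadRecord] = []
    truth = ViromeTruth(read_source={}, clade_proportions=dict(spec.proportions))
    for i, ci in enumerate(choices):
        clade = keys[int(ci)]
        read_id = f"{sample_id}_r{i:06d}"
        if clade == "background":
            seq = "".join(_NT[rng.integers(0, 4, spec.read_length_bp)])
            truth.read_source[read_id] = "background"
        else:
            members = by_clade[clade]
            g = members[int(rng.integers(0, len(members)))]
            start = int(rng.integers(0, g.length_bp - spec.read_length_bp + 1))
            fragment = g.sequence[start : start + spec.read_length_bp]
            codes = np.array([("ACGT".index(c)) for c in fragment], dtype=np.int8)
            codes = _mutate_nt(codes, spec.substitution_error_rate, rng)
            seq = "".join(_NT[codes])
            if rng.random() < 0.5:  # either strand, as in real libraries
                seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            truth.read_source[read_id] = g.genome_id
        truth.read_clade[read_id] = clade
        reads.append(ReadRecord(read_id, seq, sample_id=sample_id))
    dataset_gb = (
        spec.dataset_gb
        if spec.dataset_gb is not None
        else spec.n_reads * spec.read_length_bp / 1e9
    )
    meta = SampleMeta(
        sample_id=sample_id, layer=layer, depth_m=depth_m, dataset_gb=dataset_gb, site=site
    )
    return reads, truth, meta


def simulate_env_table(
    samples: list[SampleMeta],
    true_abundance: dict[str, float],
    driver: dict[str, tuple[float, float]],
    seed: int = 0,
) -> list[SampleMeta]:
    """Fill env variables as slope * true_abundance + Gaussian(0, sd) per sample.

    ``driver`` maps variable name to (slope, noise_sd); slope 0 gives a
    variable independent of abundance.
    """
    if len(samples) < 3:
        raise ParameterError("at least 3 samples are required")
    missing = [s.sample_id for s in samples if s.sample_id not in true_abundance]
    if missing:
        raise ParameterError(f"true_abundance missing samples: {missing}")
    rng = np.random.default_rng(seed)
    out = []
    for s in samples:
        env = dict(s.env)
        for var in sorted(driver):
            slope, sd = driver[var]
            env[var] = slope * true_abundance[s.sample_id] + rng.normal(0.0, sd)
        out.append(
            SampleMeta(
                sample_id=s.sample_id,
                layer=s.layer,
                depth_m=s.depth_m,
                dataset_gb=s.dataset_gb,
                site=s.site,
                env=env,
            )
        )
    return out
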