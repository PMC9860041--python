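"""Fragment-based average nucleotide identity and >=95% population clustering.

Each genome is cut into consecutive 1020 bp windows; every fragment is
locally aligned to the partner genome (k-mer seeded, affine-gap extension).
A fragment is accepted when the alignment covers >= 70% of the fragment at
>= 30% identity; ANI in one direction is the mean identity over accepted
fragments, and the reported value is the arithmetic mean of the two
directions.  Genome pairs with no accepted fragments get NaN (absence of
alignment is not identity zero) and contribute no clustering edge.

Populations are single-linkage connected components of the graph whose edges
join genomes at ANI >= threshold (default 95%), the conventional viral
population definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .align import GenomeIndex, ScoringScheme, map_read, nucleotide_scheme
from .errors import ParameterError
from .seqio import GenomeRecord

DEFAULT_FRAGMENT_LEN = 1020
FRAGMENT_COVERAGE_MIN = 0.70
FRAGMENT_IDENTITY_MIN = 30.0


@dataclass(frozen=True)
class ANIResult:
    genome_a: str
    genome_b: str
    ani_pct: float          # NaN when no fragment aligned in either direction
    aligned_fraction: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ani_pct)


@dataclass
class ANIMatrix:
    genome_ids: list[str]
    values: np.ndarray  # symmetric, diagonal 100, NaN where undefined

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genome_ids, columns=self.genome_ids)

    def get(self, a: str, b: str) -> float:
        return float(
            self.values[self.genome_ids.index(a), self.genome_ids.index(b)]
        )


def fragment_genome(genome: GenomeRecord, fragment_len: int = DEFAULT_FRAGMENT_LEN) -> list[str]:
    """Consecutive non-overlapping windows; a terminal piece survives if >= len/2."""
    if fragment_len < 100:
        raise ParameterError("fragment_len must be >= 100")
    seq = genome.sequence
    fragments = [seq[i : i + fragment_len] for i in range(0, len(seq), fragment_len)]
    if fragments and len(fragments[-1]) < fragment_len:
        if len(fragments[-1]) < fragment_len / 2:
            fragments.pop()
    return fragments


def _directed_ani(
    query: GenomeRecord,
    subject_index: GenomeIndex,
    scheme: ScoringScheme,
    fragment_len: int,
) -> tuple[float, int, int]:
    """Mean identity over accepted fragments of query vs subject; (ani, n_ok, bases)."""
    identities = []
    accepted_bases = 0
    for frag in fragment_genome(query, fragment_len):
        hits = map_read(frag, subject_index, scheme, pad=60)
        if not hits:
            continue
        best = hits[0]
        if best.query_span() < FRAGMENT_COVERAGE_MIN * len(frag):
            continue
        if best.pct_identity < FRAGMENT_IDENTITY_MIN:
            continue
        identities.append(best.pct_identity)
        accepted_bases += len(frag)
    if not identities:
        return math.nan, 0, 0
    return float(np.mean(identities)), len(identities), accepted_bases


def compute_ani(
    a: GenomeRecord,
    b: GenomeRecord,
    scheme: ScoringScheme | None = None,
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
    _indexes: dict[str, GenomeIndex] | None = None,
) -> ANIResult:
    """Symmetrized fragment ANI between two genomes."""
    scheme = scheme or nucleotide_scheme()
    if a.sequence == b.sequence:
        return ANIResult(a.genome_id, b.genome_id, 100.0, 1.0)
    _indexes = _indexes if _indexes is not None else {}
    for g in (a, b):
        if g.genome_id not in _indexes:
            _indexes[g.genome_id] = GenomeIndex([g])
    ani_ab, _, bases_ab = _directed_ani(a, _indexes[b.genome_id], scheme, fragment_len)
    ani_ba, _, bases_ba = _directed_ani(b, _indexes[a.genome_id], scheme, fragment_len)
    directed = [v for v in (ani_ab, ani_ba) if not math.isnan(v)]
    ani = float(np.mean(directed)) if directed else math.nan
    aligned_fraction = (bases_ab + bases_ba) / (a.length_bp + b.length_bp)
    return ANIResult(a.genome_id, b.genome_id, ani, aligned_fraction)


def ani_matrix(
    genomes: list[GenomeRecord],
    scheme: ScoringScheme | None = None,
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
) -> ANIMatrix:
    """All-vs-all symmetric ANI matrix (diagonal fixed at 100)."""
    n = len(genomes)
    values = np.full((n, n), math.nan)
    np.fill_diagonal(values, 100.0)
    indexes: dict[str, GenomeIndex] = {}
    for i in range(n):
        for j in range(i + 1, n):
            res = compute_ani(genomes[i], genomes[j], scheme, fragment_len, _indexes=indexes)
            values[i, j] = values[j, i] = res.ani_pct
    return ANIMatrix([g.genome_id for g in genomes], values)


def cluster_populations(matrix: ANIMatrix, threshold_pct: float = 95.0) -> list[list[str]]:
    """Single-linkage populations at ANI >= threshold; NaN never forms an edge.

    Returned as a partition: each population sorted, populations ordered
    lexicographically by their smallest member.
    """
    graph = nx.Graph()
    graph.add_nodes_from(matrix.genome_ids)
    n = len(matrix.genome_ids)
    for i in range(n):
        for j in range(i + 1, n):
            v = matrix.values[i, j]
            if not math.isnan(v) and v >= threshold_pct:
                graph.add_edge(matrix.genome_ids[i], matrix.genome_ids[j])
    populations = [sorted(c) for c in nx.connected_components(graph)]
    populations.sort(key=lambda pop: pop[0])
    return populations


def population_table(populations: list[list[str]]) -> pd.DataFrame:
    rows = [
        {"genome_id": g, "population_id": f"pop{idx + 1:03d}"}
        for idx, pop in enumerate(populations)
        for g in pop
    ]
    return pd.DataFrame(rows, columns=["genome_id", "population_id"])
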