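"""Reciprocal-best-hit orthology, PSSM rescue, and pan/core accumulation curves.

Gene families are built in three steps: (1) all-vs-all local protein
alignment between genomes; (2) reciprocal best hits (RBH) accepted at
e-value <= 1e-5 with the alignment covering >= 75% of the shorter gene;
(3) connected components of the RBH graph, with at most one representative
per genome per family (supernumerary genes are demoted to singletons by
summed-bitscore rank).  A position-specific scoring step then offers
singleton genes a second chance to join a family whose profile they match —
a deliberately simplified, ungapped stand-in for a profile-HMM rescue of
divergent orthologs.

Pan and core genome sizes are counted over families; accumulation curves
average pan/core counts over random genome orderings.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .align import ScoringScheme, evalue, local_align, protein_scheme
from .errors import ParameterError
from .seqio import HitRecord

PSSM_TAU_BITS = 1.0
_BG_FREQ = 0.05  # uniform background over the 20 standard residues


@dataclass(frozen=True)
class ProteinRecord:
    genome_id: str
    gene_id: str
    aa_sequence: str

    def __post_init__(self):
        if not self.aa_sequence:
            raise ParameterError(f"gene {self.gene_id!r}: empty sequence")


@dataclass
class OrthologGroup:
    group_id: str
    members: set[tuple[str, str]]  # (genome_id, gene_id)

    @property
    def genomes_present(self) -> set[str]:
        return {g for g, _ in self.members}

    @property
    def gene_ids(self) -> set[str]:
        return {x for _, x in self.members}


@dataclass
class PanCoreCurve:
    n_genomes: np.ndarray
    mean_pan: np.ndarray
    sd_pan: np.ndarray
    mean_core: np.ndarray
    sd_core: np.ndarray
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_genomes": self.n_genomes,
                "mean_pan": self.mean_pan,
                "sd_pan": self.sd_pan,
                "mean_core": self.mean_core,
                "sd_core": self.sd_core,
            }
        )


def all_vs_all_protein_hits(
    proteins: list[ProteinRecord], scheme: ScoringScheme | None = None
) -> list[HitRecord]:
    """Best local alignment for every cross-genome ordered gene pair.

    Hits with non-positive local score are omitted.  The e-value search space
    is the total residue count of all proteomes.
    """
    scheme = scheme or protein_scheme()
    genomes = sorted({p.genome_id for p in proteins})
    if len(genomes) < 2:
        return []
    db_len = sum(len(p.aa_sequence) for p in proteins)
    by_genome: dict[str, list[ProteinRecord]] = {g: [] for g in genomes}
    for p in proteins:
        by_genome[p.genome_id].append(p)
    hits: list[HitRecord] = []
    for gq in genomes:
        for gs in genomes:
            if gq == gs:
                continue
            for query in by_genome[gq]:
                for subject in by_genome[gs]:
                    aln = local_align(query.aa_sequence, subject.aa_sequence, scheme)
                    if aln is None:
                        continue
                    hits.append(
                        HitRecord(
                            query_id=query.gene_id,
                            subject_id=subject.gene_id,
                            pct_identity=aln.pct_identity,
                            aln_length=aln.aln_length,
                            mismatches=aln.n_mismatches,
                            gap_opens=aln.n_gap_opens,
                            q_start=aln.q_start + 1,
                            q_end=aln.q_end,
                            s_start=aln.s_start + 1,
                            s_end=aln.s_end,
                            evalue=evalue(aln.bitscore, len(query.aa_sequence), db_len),
                            bitscore=aln.bitscore,
                        )
                    )
    return hits


def rbh_pairs(
    hits: list[HitRecord],
    lengths: dict[str, int],
    genome_of: dict[str, str],
    evalue_max: float = 1e-5,
    coverage_min: float = 0.75,
) -> tuple[set[tuple[str, str]], dict[frozenset, float]]:
    """Reciprocal best hits between genomes.

    A pair (x, y) is accepted iff each is the other's highest-bitscore hit in
    the partner genome (bitscore ties broken by lexicographic gene id) and
    both directed hits pass e-value <= evalue_max and alignment length >=
    coverage_min * min(len(x), len(y)).  Returns the accepted pairs (as
    sorted tuples) and the mean directed bitscore per pair.
    """
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        key = (h.query_id, genome_of[h.subject_id])
        prev = best.get(key)
        if (
            prev is None
            or h.bitscore > prev.bitscore
            or (h.bitscore == prev.bitscore and h.subject_id < prev.subject_id)
        ):
            best[key] = h
    pairs: set[tuple[str, str]] = set()
    scores: dict[frozenset, float] = {}
    for (x, _), h in best.items():
        y = h.subject_id
        back = best.get((y, genome_of[x]))
        if back is None or back.subject_id != x:
            continue
        min_len = min(lengths[x], lengths[y])
        if h.evalue > evalue_max or back.evalue > evalue_max:
            continue
        if h.aln_length < coverage_min * min_len or back.aln_length < coverage_min * min_len:
            continue
        pair = tuple(sorted((x, y)))
        pairs.add(pair)
        scores[frozenset(pair)] = (h.bitscore + back.bitscore) / 2.0
    return pairs, scores


def build_groups(
    pairs: set[tuple[str, str]],
    genes: list[tuple[str, str]],
    pair_scores: dict[frozenset, float] | None = None,
) -> list[OrthologGroup]:
    """Connected components of the RBH graph, one representative per genome.

    ``genes`` lists every (genome_id, gene_id) so that unpaired genes become
    singleton groups and the result partitions the input.  When a component
    holds several genes of one genome, only the gene with the highest summed
    pair bitscore to the rest of the component is kept; the others are
    demoted to singletons.
    """
    pair_scores = pair_scores or {}
    genome_of = {gene: genome for genome, gene in genes}
    graph = nx.Graph()
    graph.add_nodes_from(gene for _, gene in genes)
    for x, y in pairs:
        if genome_of[x] == genome_of[y]:
            raise ParameterError(f"RBH pair within one genome: {x}, {y}")
        graph.add_edge(x, y)
    families: list[set[str]] = []
    for component in nx.connected_components(graph):
        members_by_genome: dict[str, list[str]] = {}
        for gene in component:
            members_by_genome.setdefault(genome_of[gene], []).append(gene)
        kept: set[str] = set()
        for genome, members in members_by_genome.items():
            if len(members) == 1:
                kept.add(members[0])
                continue

            def summed_score(gene: str) -> float:
                return sum(
                    pair_scores.get(frozenset((gene, other)), 0.0)
                    for other in component
                    if other != gene
                )

            ranked = sorted(members, key=lambda g: (-summed_score(g), g))
            kept.add(ranked[0])
            families.extend({g} for g in ranked[1:])
        families.append(kept)
    families.sort(key=lambda fam: sorted(fam)[0])
    return [
        OrthologGroup(
            group_id=f"OG{idx + 1:04d}",
            members={(genome_of[g], g) for g in fam},
        )
        for idx, fam in enumerate(families)
    ]


# ---------------------------------------------------------------------------
# PSSM rescue of divergent orthologs


def _best_offset(a: str, b: str) -> tuple[int, int]:
    """Offset of a relative to b maximizing exact matches (ungapped scan)."""
    best_off, best_matches = 0, -1
    for off in range(-(len(a) - 1), len(b)):
        matches = sum(
            1
            for i in range(max(0, -off), min(len(a), len(b) - off))
            if a[i] == b[i + off]
        )
        if matches > best_matches:
            best_matches, best_off = matches, off
    return best_off, best_matches


def _group_pssm(member_seqs: list[str]) -> np.ndarray | None:
    """Ungapped log-odds profile (length x 20, bits) from a center-star layout."""
    from .align import AA_ALPHABET

    aa_index = {ch: i for i, ch in enumerate(AA_ALPHABET[:-1])}
    if len(member_seqs) < 2:
        return None
    # center = member with the most total matches to the others
    totals = []
    for i, seq in enumerate(member_seqs):
        total = sum(
            _best_offset(other, seq)[1] for j, other in enumerate(member_seqs) if j != i
        )
        totals.append((total, -len(seq), i))
    center = member_seqs[max(totals)[2]]
    counts = np.zeros((len(center), 20))
    for seq in member_seqs:
        off, _ = _best_offset(seq, center)
        for i in range(max(0, -off), min(len(seq), len(center) - off)):
            code = aa_index.get(seq[i])
            if code is not None:
                counts[i + off, code] += 1
    freqs = (counts + 1.0) / (counts.sum(axis=1, keepdims=True) + 20.0)
    return np.log2(freqs / _BG_FREQ)


def _score_against_pssm(seq: str, pssm: np.ndarray, min_overlap_frac: float = 0.7) -> float:
    """Best mean per-position log-odds over all ungapped offsets."""
    from .align import AA_ALPHABET

    aa_index = {ch: i for i, ch in enumerate(AA_ALPHABET[:-1])}
    L = pssm.shape[0]
    n = len(seq)
    min_overlap = max(1, int(np.ceil(min_overlap_frac * min(n, L))))
    best = -np.inf
    for off in range(-(n - min_overlap), L - min_overlap + 1):
        lo, hi = max(0, -off), min(n, L - off)
        if hi - lo < min_overlap:
            continue
        total = 0.0
        for i in range(lo, hi):
            code = aa_index.get(seq[i])
            total += pssm[i + off, code] if code is not None else 0.0
        best = max(best, total / (hi - lo))
    return best


def pssm_rescue(
    groups: list[OrthologGroup],
    orphans: list[ProteinRecord],
    proteins: dict[str, str],
    tau: float = PSSM_TAU_BITS,
) -> list[OrthologGroup]:
    """Let orphan genes join the best-matching multi-member family.

    ``proteins`` maps gene_id to amino-acid sequence for all group members.
    An orphan joins the family with the highest mean per-position log-odds if
    that score exceeds ``tau`` (bits) and the family has no member from the
    orphan's genome; each orphan joins at most one family, and its singleton
    group (if present) is dissolved.
    """
    multi = [g for g in groups if len(g.members) >= 2]
    pssms = [
        (g, _group_pssm([proteins[gene] for _, gene in sorted(g.members)])) for g in multi
    ]
    joined: dict[str, OrthologGroup] = {}
    for orphan in sorted(orphans, key=lambda p: p.gene_id):
        best_group, best_score = None, -np.inf
        for group, pssm in pssms:
            if pssm is None or orphan.genome_id in group.genomes_present:
                continue
            score = _score_against_pssm(orphan.aa_sequence, pssm)
            if score > best_score:
                best_score, best_group = score, group
        if best_group is not None and best_score > tau:
            best_group.members.add((orphan.genome_id, orphan.gene_id))
            joined[orphan.gene_id] = best_group
    out = []
    for g in groups:
        if len(g.members) == 1:
            (_, gene), = g.members
            if gene in joined:
                continue  # singleton dissolved into its rescue family
        out.append(g)
    return out


# ---------------------------------------------------------------------------
# counting


def pan_core_counts(groups: list[OrthologGroup], genome_ids: set[str]) -> tuple[int, int]:
    """(pan, core) family counts over the given genome set."""
    if not genome_ids:
        raise ParameterError("genome set must be non-empty")
    genome_ids = set(genome_ids)
    pan = sum(1 for g in groups if g.genomes_present & genome_ids)
    core = sum(1 for g in groups if g.genomes_present >= genome_ids)
    return pan, core


def accumulation_curves(
    groups: list[OrthologGroup],
    genome_ids: list[str],
    n_permutations: int = 100,
    seed: int = 0,
) -> PanCoreCurve:
    """Permutation-averaged pan/core gene accumulation curves."""
    if len(genome_ids) < 2:
        raise ParameterError("at least 2 genomes are required")
    rng = np.random.default_rng(seed)
    group_sets = {
        gid: {g.group_id for g in groups if gid in g.genomes_present} for gid in genome_ids
    }
    n = len(genome_ids)
    pans = np.zeros((n_permutations, n))
    cores = np.zeros((n_permutations, n))
    for p in range(n_permutations):
        order = rng.permutation(n)
        union: set[str] = set()
        inter: set[str] | None = None
        for step, gi in enumerate(order):
            gs = group_sets[genome_ids[gi]]
            union |= gs
            inter = set(gs) if inter is None else inter & gs
            pans[p, step] = len(union)
            cores[p, step] = len(inter)
    return PanCoreCurve(
        n_genomes=np.arange(1, n + 1),
        mean_pan=pans.mean(axis=0),
        sd_pan=pans.std(axis=0),
        mean_core=cores.mean(axis=0),
        sd_core=cores.std(axis=0),
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# orchestration


def build_pangenome(
    proteins: list[ProteinRecord],
    scheme: ScoringScheme | None = None,
    evalue_max: float = 1e-5,
    coverage_min: float = 0.75,
    rescue: bool = True,
    tau: float = PSSM_TAU_BITS,
) -> list[OrthologGroup]:
    """Full family construction: all-vs-all, RBH, components, PSSM rescue."""
    hits = all_vs_all_protein_hits(proteins, scheme)
    lengths = {p.gene_id: len(p.aa_sequence) for p in proteins}
    genome_of = {p.gene_id: p.genome_id for p in proteins}
    pairs, scores = rbh_pairs(hits, lengths, genome_of, evalue_max, coverage_min)
    groups = build_groups(pairs, [(p.genome_id, p.gene_id) for p in proteins], scores)
    if rescue:
        orphans = [
            p
            for p in proteins
            if any(len(g.members) == 1 and (p.genome_id, p.gene_id) in g.members for g in groups)
        ]
        seqs = {p.gene_id: p.aa_sequence for p in proteins}
        groups = pssm_rescue(groups, orphans, seqs, tau)
    return groups
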