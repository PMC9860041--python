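"""Self-contained pairwise local alignment and read mapping.

The workhorse is an affine-gap Smith–Waterman (Gotoh) kernel compiled with
numba.  A gap of length L costs ``gap_open + L * gap_extend``.  Bitscores and
e-values follow the Karlin–Altschul convention with published constants for
the two default scoring schemes, so the e-value filter of the recruitment
stage behaves like the one applied by standard alignment tools.

Read recruitment uses exact k-mer seeding (default k = 11) on both strands:
seeds voting for the same genome diagonal define a window of the subject that
is then aligned with the full affine-gap kernel, yielding one best tabular
hit per genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numba import njit

from .errors import ParameterError
from .seqio import GenomeRecord, HitRecord, ReadRecord, reverse_complement

NT_ALPHABET = "ACGTN"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"


def _encode_table(alphabet: str) -> np.ndarray:
    table = np.full(128, -1, dtype=np.int8)
    for i, ch in enumerate(alphabet):
        table[ord(ch)] = i
    return table

_NT_TABLE = _encode_table(NT_ALPHABET)
_AA_TABLE = _encode_table(AA_ALPHABET)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and Karlin–Altschul constants."""

    alphabet: str
    matrix: np.ndarray          # (k, k) int32
    gap_open: int               # positive penalty
    gap_extend: int             # positive penalty
    ka_lambda: float
    ka_k: float
    ambiguous_code: int         # N for nucleotides, X for proteins; never an identity

    @property
    def is_protein(self) -> bool:
        return self.alphabet is AA_ALPHABET or len(self.alphabet) > 5

    def encode(self, seq: str) -> np.ndarray:
        table = _AA_TABLE if self.is_protein else _NT_TABLE
        codes = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        if (codes < 0).any():
            bad = sorted({seq[i] for i in np.flatnonzero(codes < 0)[:5]})
            raise ParameterError(f"sequence contains letters outside the alphabet: {bad}")
        return codes


@lru_cache(maxsize=None)
def nucleotide_scheme(
    match: int = 2, mismatch: int = -3, gap_open: int = 5, gap_extend: int = 2
) -> ScoringScheme:
    """Default blastn-like scheme: +2/-3, gap 5/2; lambda/K from the BLAST tables."""
    m = np.full((5, 5), mismatch, dtype=np.int32)
    np.fill_diagonal(m, match)
    m[4, :] = mismatch  # N never matches, not even itself
    m[:, 4] = mismatch
    m.setflags(write=False)
    return ScoringScheme(NT_ALPHABET, m, gap_open, gap_extend, 0.625, 0.41, 4)


@lru_cache(maxsize=None)
def protein_scheme(gap_open: int = 11, gap_extend: int = 1) -> ScoringScheme:
    """BLOSUM62 with gap 11/1; X is tolerated and scored 0 against everything."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    k = len(AA_ALPHABET)
    m = np.zeros((k, k), dtype=np.int32)
    for i, a in enumerate(AA_ALPHABET[:-1]):
        for j, b in enumerate(AA_ALPHABET[:-1]):
            m[i, j] = int(blosum[a][b])
    m[k - 1, :] = 0
    m[:, k - 1] = 0
    m.setflags(write=False)
    return ScoringScheme(AA_ALPHABET, m, gap_open, gap_extend, 0.267, 0.041, k - 1)


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment; coordinates are 0-based half-open on the inputs."""

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    raw_score: int
    bitscore: float
    n_identities: int
    n_mismatches: int
    aln_length: int
    n_gap_opens: int
    strand: str = "+"

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.n_identities / self.aln_length


@njit(cache=True)
def _gotoh_kernel(q, s, sub, gap_open, gap_ext, ambig):  # pragma: no cover - jitted
    n = q.shape[0]
    m = s.shape[0]
    NEG = -(10 ** 9)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = E[i, j - 1] - gap_ext
            e2 = H[i, j - 1] - gap_open - gap_ext
            if e2 > e:
                e = e2
            E[i, j] = e
            f = F[i - 1, j] - gap_ext
            f2 = H[i - 1, j] - gap_open - gap_ext
            if f2 > f:
                f = f2
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[qi, s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:  # strict > keeps the smallest (i, j) end cell
                best = h
                bi = i
                bj = j
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0, 0, 0
    # traceback from (bi, bj), preferring diagonal, then gap-in-subject, then gap-in-query
    i = bi
    j = bj
    n_id = 0
    n_mm = 0
    n_cols = 0
    n_go = 0
    state = 0  # 0 = H, 1 = E (gap in query), 2 = F (gap in subject)
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]:
                if q[i - 1] == s[j - 1] and q[i - 1] != ambig:
                    n_id += 1
                else:
                    n_mm += 1
                n_cols += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = 2
            else:
                state = 1
        elif state == 2:  # gap in subject: consume query
            n_cols += 1
            if F[i, j] == H[i - 1, j] - gap_open - gap_ext:
                n_go += 1
                i -= 1
                state = 0
            else:
                i -= 1
        else:  # gap in query: consume subject
            n_cols += 1
            if E[i, j] == H[i, j - 1] - gap_open - gap_ext:
                n_go += 1
                j -= 1
                state = 0
            else:
                j -= 1
    return best, i, bi, j, bj, n_id, n_mm, n_cols, n_go


def bitscore(raw_score: float, scheme: ScoringScheme) -> float:
    return (scheme.ka_lambda * raw_score - math.log(scheme.ka_k)) / math.log(2.0)


def evalue(bits: float, query_len: int, subject_total_len: int) -> float:
    """Karlin–Altschul expect value: E = m * n * 2**(-bitscore)."""
    if query_len <= 0 or subject_total_len <= 0:
        raise ParameterError("sequence lengths must be positive")
    return float(query_len) * float(subject_total_len) * math.pow(2.0, -bits)


def local_align(query: str, subject: str, scheme: ScoringScheme) -> LocalAlignment | None:
    """Maximum-scoring affine-gap local alignment, or None if no positive score."""
    if not query or not subject:
        raise ParameterError("sequences must be non-empty")
    q = scheme.encode(query)
    s = scheme.encode(subject)
    return _align_encoded(q, s, scheme)


def _align_encoded(q: np.ndarray, s: np.ndarray, scheme: ScoringScheme) -> LocalAlignment | None:
    score, qs, qe, ss, se, n_id, n_mm, n_cols, n_go = _gotoh_kernel(
        q, s, scheme.matrix, scheme.gap_open, scheme.gap_extend, scheme.ambiguous_code
    )
    if score <= 0:
        return None
    return LocalAlignment(
        q_start=qs,
        q_end=qe,
        s_start=ss,
        s_end=se,
        raw_score=int(score),
        bitscore=bitscore(score, scheme),
        n_identities=n_id,
        n_mismatches=n_mm,
        aln_length=n_cols,
        n_gap_opens=n_go,
    )


# ---------------------------------------------------------------------------
# k-mer indexed read mapping


class GenomeIndex:
    """Exact k-mer index over the forward strands of a genome collection.

    Queries search both the read and its reverse complement, which is
    equivalent to indexing both strands.
    """

    def __init__(self, genomes: list[GenomeRecord], k: int = 11):
        if k < 4 or k > 15:
            raise ParameterError(f"seed length k={k} outside the supported range 4..15")
        self.k = k
        self.genomes = list(genomes)
        self.encoded = [nucleotide_scheme().encode(g.sequence) for g in self.genomes]
        self.total_bp = sum(g.length_bp for g in self.genomes)
        codes_parts = []
        gidx_parts = []
        pos_parts = []
        for gi, enc in enumerate(self.encoded):
            codes, positions = _kmer_codes(enc, k)
            codes_parts.append(codes)
            gidx_parts.append(np.full(len(codes), gi, dtype=np.int32))
            pos_parts.append(positions)
        codes = np.concatenate(codes_parts) if codes_parts else np.empty(0, dtype=np.int64)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._gidx = np.concatenate(gidx_parts)[order] if codes_parts else np.empty(0, np.int32)
        self._pos = np.concatenate(pos_parts)[order] if codes_parts else np.empty(0, np.int32)

    def lookup(self, query_codes: np.ndarray, query_pos: np.ndarray):
        """Return (genome_idx, genome_pos, query_pos) for every exact seed match."""
        lo = np.searchsorted(self._codes, query_codes, side="left")
        hi = np.searchsorted(self._codes, query_codes, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            empty = np.empty(0, dtype=np.int32)
            return empty, empty, empty
        out_g = np.empty(total, dtype=np.int32)
        out_p = np.empty(total, dtype=np.int32)
        out_q = np.empty(total, dtype=np.int32)
        at = 0
        for i in np.flatnonzero(counts):
            n = counts[i]
            out_g[at : at + n] = self._gidx[lo[i] : hi[i]]
            out_p[at : at + n] = self._pos[lo[i] : hi[i]]
            out_q[at : at + n] = query_pos[i]
            at += n
        return out_g, out_p, out_q


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 codes of all k-mers free of N, with their start positions."""
    if len(enc) < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int32)
    windows = np.lib.stride_tricks.sliding_window_view(enc, k).astype(np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    valid = (windows < 4).all(axis=1)
    codes = windows @ powers
    positions = np.flatnonzero(valid).astype(np.int32)
    return codes[valid], positions


def map_read(
    read: ReadRecord | str,
    index: GenomeIndex,
    scheme: ScoringScheme | None = None,
    *,
    pad: int = 30,
    min_seed_count: int = 2,
) -> list[HitRecord]:
    """Map one read against the indexed genomes; at most one hit per genome.

    Seeds sharing a (genome, strand, diagonal) vote for a candidate locus; the
    best-supported diagonal per genome and strand defines a subject window
    which is aligned with the affine-gap kernel.  Hits are returned sorted by
    descending bitscore (ties by genome id).  A read shorter than k yields no
    hits.
    """
    scheme = scheme or nucleotide_scheme()
    if isinstance(read, ReadRecord):
        read_id, seq = read.read_id, read.sequence
    else:
        read_id, seq = "query", read
    L = len(seq)
    if L < index.k:
        return []
    enc_fwd = scheme.encode(seq)
    enc_rev = scheme.encode(reverse_complement(seq))
    best_per_genome: dict[int, tuple[int, HitRecord]] = {}
    for strand, enc in (("+", enc_fwd), ("-", enc_rev)):
        codes, qpos = _kmer_codes(enc, index.k)
        if len(codes) == 0:
            continue
        gidx, gpos, qp = index.lookup(codes, qpos)
        if len(gidx) == 0:
            continue
        diag = gpos.astype(np.int64) - qp
        # one combined key per (genome, diagonal); pick the modal diagonal per genome
        key = gidx.astype(np.int64) * (2 * L + 2 * index.total_bp) + (diag + L)
        uniq, counts = np.unique(key, return_counts=True)
        genome_of = (uniq // (2 * L + 2 * index.total_bp)).astype(np.int64)
        for gi in np.unique(genome_of):
            mask = genome_of == gi
            if counts[mask].max() < min_seed_count:
                continue
            # modal diagonal; np.unique sorts keys, so ties take the smallest diagonal
            best_key = uniq[mask][np.argmax(counts[mask])]
            d = int(best_key % (2 * L + 2 * index.total_bp)) - L
            genome = index.genomes[gi]
            w_lo = max(0, d - pad)
            w_hi = min(genome.length_bp, d + L + pad)
            if w_hi <= w_lo:
                continue
            aln = _align_encoded(enc, index.encoded[gi][w_lo:w_hi], scheme)
            if aln is None:
                continue
            hit = _to_hit_record(read_id, genome, aln, strand, w_lo, L, index.total_bp, scheme)
            prev = best_per_genome.get(int(gi))
            if prev is None or aln.raw_score > prev[0]:
                best_per_genome[int(gi)] = (aln.raw_score, hit)
    hits = [h for _, h in best_per_genome.values()]
    hits.sort(key=lambda h: (-h.bitscore, h.subject_id))
    return hits


def _to_hit_record(
    read_id: str,
    genome: GenomeRecord,
    aln: LocalAlignment,
    strand: str,
    window_start: int,
    read_len: int,
    db_len: int,
    scheme: ScoringScheme,
) -> HitRecord:
    s_lo = window_start + aln.s_start  # 0-based half-open on the genome
    s_hi = window_start + aln.s_end
    if strand == "+":
        q_start, q_end = aln.q_start + 1, aln.q_end
        s_start, s_end = s_lo + 1, s_hi
    else:
        # alignment coordinates refer to the reverse-complemented read
        q_start, q_end = read_len - aln.q_end + 1, read_len - aln.q_start
        s_start, s_end = s_hi, s_lo + 1
    return HitRecord(
        query_id=read_id,
        subject_id=genome.genome_id,
        pct_identity=aln.pct_identity,
        aln_length=aln.aln_length,
        mismatches=aln.n_mismatches,
        gap_opens=aln.n_gap_opens,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        evalue=evalue(aln.bitscore, read_len, db_len),
        bitscore=aln.bitscore,
    )
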