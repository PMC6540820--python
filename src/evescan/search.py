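"""Translated local-alignment search.

Implements the two search directions the screening pipeline needs:

* :func:`search_tblastn_like` — protein queries against the six-frame
  translation of genome scaffolds (how candidate endogenous viral
  elements are first located);
* :func:`search_blastx_like` — a translated nucleotide query against a
  mixed protein database (the reciprocal step that decides whether a
  candidate's closest relative really is viral).

Both use the same core: seed-and-extend over 3-mer neighborhood words
with a two-hit diagonal rule and an ungapped X-drop pre-filter,
followed by exact affine-gap Smith–Waterman over the triggered windows.
Small problems skip the heuristics and run Smith–Waterman directly, so
the optimum is exact there.  E-values follow Karlin–Altschul statistics
(see :mod:`evescan.scoring`).

An adapter (:func:`external_engine_adapter`) reads the conventional
12(+1)-column tabular hit format so screens can be driven by an
external search engine while the rest of the pipeline is unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq
from numba import njit

from .scoring import AA_INDEX, ScoringScheme, encode_aa

FRAMES = (1, 2, 3, -1, -2, -3)

_IUPAC_NT = set("ACGTUNRYSWKMBDHV")


@dataclass
class ProteinRecord:
    """A protein database entry with screening metadata.

    ``is_viral`` and the clade / protein-class labels drive the
    reciprocal best-hit classification; for records parsed from FASTA
    they come from ``key=value`` tokens in the description
    (``viral=1 clade=Mono-Chu class=Glycoprotein``).
    """

    id: str
    description: str
    seq: str
    is_viral: bool = False
    clade: str | None = None
    protein_class: str | None = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - set("ACDEFGHIKLMNPQRSTVWYX*")
        if bad:
            raise ValueError(f"protein {self.id}: non-amino-acid symbols {sorted(bad)}")

    @classmethod
    def from_fasta(cls, rid: str, description: str, seq: str) -> "ProteinRecord":
        meta = {}
        for tok in description.split():
            if "=" in tok:
                k, _, v = tok.partition("=")
                meta[k] = v
        return cls(
            id=rid,
            description=description,
            seq=seq,
            is_viral=meta.get("viral", "0") in ("1", "true", "True"),
            clade=meta.get("clade"),
            protein_class=meta.get("class"),
        )

    def to_description(self) -> str:
        toks = [self.description] if self.description else []
        if "viral=" not in self.description:
            toks.append(f"viral={1 if self.is_viral else 0}")
            if self.clade:
                toks.append(f"clade={self.clade}")
            if self.protein_class:
                toks.append(f"class={self.protein_class}")
        return " ".join(toks)


@dataclass
class SearchHit:
    """One local alignment between a protein and a nucleotide sequence.

    Coordinates follow one convention in both search directions: the
    ``subject_nt_*`` fields are 0-based half-open positions on the
    *nucleotide* sequence (forward strand, regardless of frame sign)
    and the ``query_aa_*`` fields are 0-based half-open positions on
    the *protein*.  For the tblastn-like direction the nucleotide side
    is the genome scaffold named by ``subject_id``; for the blastx-like
    direction the nucleotide side is the query and ``subject_id`` names
    the database protein.
    """

    query_id: str
    subject_id: str
    frame: int
    subject_nt_start: int
    subject_nt_end: int
    query_aa_start: int
    query_aa_end: int
    raw_score: int
    bit_score: float
    evalue: float
    aligned_query: str
    aligned_subject: str

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def six_frame_translate(seq: str) -> list[tuple[int, str]]:
    """Translate ``seq`` in all six frames with the standard code.

    Returns ``[(frame, peptide), ...]`` for frames +1..+3 then -1..-3.
    Stops are rendered ``*``; codons containing N (or other ambiguity
    codes) translate to ``X``; the trailing 1-2 nt of each frame are
    dropped.  Non-IUPAC symbols raise ``ValueError``.
    """
    s = seq.upper()
    if len(s) < 3:
        raise ValueError("sequence shorter than one codon")
    bad = set(s) - _IUPAC_NT
    if bad:
        raise ValueError(f"non-IUPAC nucleotide symbols: {sorted(bad)}")
    out = []
    rc = revcomp(s)
    for frame in FRAMES:
        src = s if frame > 0 else rc
        off = abs(frame) - 1
        sub = src[off : off + 3 * ((len(src) - off) // 3)]
        out.append((frame, str(Seq(sub).translate())))
    return out


def frame_to_forward_nt(frame: int, aa_start: int, aa_end: int, seq_len: int) -> tuple[int, int]:
    """Map an aa span [aa_start, aa_end) in a frame to forward-strand nt."""
    off = abs(frame) - 1
    lo, hi = off + 3 * aa_start, off + 3 * aa_end
    if frame > 0:
        return lo, hi
    return seq_len - hi, seq_len - lo


# ---------------------------------------------------------------------------
# Smith-Waterman core (affine gaps; gap of length k costs open + k*extend)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sw_fill(q, s, mat, gap_open, gap_extend):  # pragma: no cover - numba
    n = q.shape[0]
    m = s.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), -10**8, dtype=np.int32)
    F = np.full((n + 1, m + 1), -10**8, dtype=np.int32)
    ph = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop,1 diag,2 E,3 F
    pe = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 = extended
    pf = np.zeros((n + 1, m + 1), dtype=np.uint8)
    go = gap_open + gap_extend
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - go
            e_ext = E[i, j - 1] - gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                pe[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] - go
            f_ext = F[i - 1, j] - gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                pf[i, j] = 1
            else:
                F[i, j] = f_open
            diag = H[i - 1, j - 1] + mat[qi, s[j - 1]]
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ph[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ph, pe, pf


@dataclass
class LocalAlignment:
    raw_score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    aligned_q: str
    aligned_s: str


def local_align(
    q_codes: np.ndarray,
    s_codes: np.ndarray,
    scheme: ScoringScheme,
    q_str: str | None = None,
    s_str: str | None = None,
    min_score: int = 1,
) -> LocalAlignment | None:
    """Optimal local alignment of two encoded amino-acid sequences.

    Exact affine-gap Smith-Waterman with full traceback; returns None
    when the best local score is below ``min_score``.
    """
    if len(q_codes) == 0 or len(s_codes) == 0:
        return None
    best, bi, bj, ph, pe, pf = _sw_fill(
        q_codes, s_codes, scheme.matrix, scheme.gap_open, scheme.gap_extend
    )
    if best <= 0 or best < min_score:
        return None
    alpha = "ACDEFGHIKLMNPQRSTVWYX*"
    qs = q_str if q_str is not None else "".join(alpha[c] for c in q_codes)
    ss = s_str if s_str is not None else "".join(alpha[c] for c in s_codes)
    i, j = bi, bj
    aq: list[str] = []
    asu: list[str] = []
    state = 0  # 0 = H
    while True:
        if state == 0:
            p = ph[i, j]
            if p == 0:
                break
            if p == 1:
                aq.append(qs[i - 1])
                asu.append(ss[j - 1])
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:  # E: gap in query, consume subject
            ext = pe[i, j]
            aq.append("-")
            asu.append(ss[j - 1])
            j -= 1
            if not ext:
                state = 0
        else:  # F: gap in subject, consume query
            ext = pf[i, j]
            aq.append(qs[i - 1])
            asu.append("-")
            i -= 1
            if not ext:
                state = 0
    aq.reverse()
    asu.reverse()
    return LocalAlignment(int(best), i, bi, j, bj, "".join(aq), "".join(asu))


def _region_hsps(
    q_codes: np.ndarray,
    s_codes: np.ndarray,
    scheme: ScoringScheme,
    min_raw: int,
    s_offset: int = 0,
) -> list[LocalAlignment]:
    """All non-overlapping (in subject) HSPs with raw score >= min_raw.

    Recursively re-searches the subject flanks left and right of each
    optimal alignment, so several distinct matches in one window are
    all reported.
    """
    if len(s_codes) < scheme.word_size:
        return []
    aln = local_align(q_codes, s_codes, scheme, min_score=min_raw)
    if aln is None:
        return []
    out = [
        LocalAlignment(
            aln.raw_score,
            aln.q_start,
            aln.q_end,
            aln.s_start + s_offset,
            aln.s_end + s_offset,
            aln.aligned_q,
            aln.aligned_s,
        )
    ]
    out.extend(_region_hsps(q_codes, s_codes[: aln.s_start], scheme, min_raw, s_offset))
    out.extend(
        _region_hsps(q_codes, s_codes[aln.s_end :], scheme, min_raw, s_offset + aln.s_end)
    )
    return out


# ---------------------------------------------------------------------------
# Seed-and-extend machinery
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ungapped_extend_batch(q, s, qpos_arr, spos_arr, w, mat, xdrop):  # pragma: no cover - numba
    out = np.empty(qpos_arr.shape[0], dtype=np.int32)
    for k in range(qpos_arr.shape[0]):
        qpos = qpos_arr[k]
        spos = spos_arr[k]
        score = 0
        for t in range(w):
            score += mat[q[qpos + t], s[spos + t]]
        best = score
        cur = score
        i = qpos + w
        j = spos + w
        while i < q.shape[0] and j < s.shape[0]:
            cur += mat[q[i], s[j]]
            if cur > best:
                best = cur
            if best - cur > xdrop:
                break
            i += 1
            j += 1
        right_gain = best - score
        best2 = 0
        cur = 0
        i = qpos - 1
        j = spos - 1
        while i >= 0 and j >= 0:
            cur += mat[q[i], s[j]]
            if cur > best2:
                best2 = cur
            if best2 - cur > xdrop:
                break
            i -= 1
            j -= 1
        out[k] = score + right_gain + best2
    return out


class _QueryWords:
    """Neighborhood word expansion of one encoded protein query."""

    def __init__(self, q_codes: np.ndarray, scheme: ScoringScheme):
        w = scheme.word_size
        B = scheme.matrix[:20, :20]
        thresh = scheme.neighborhood_threshold
        cache: dict[tuple, np.ndarray] = {}
        qpos_all: list[np.ndarray] = []
        words_all: list[np.ndarray] = []
        for i in range(len(q_codes) - w + 1):
            trip = tuple(int(c) for c in q_codes[i : i + w])
            if any(c >= 20 for c in trip):
                continue
            if trip not in cache:
                sc = (
                    B[trip[0]][:, None, None]
                    + B[trip[1]][None, :, None]
                    + B[trip[2]][None, None, :]
                )
                cache[trip] = np.flatnonzero(sc.ravel() >= thresh).astype(np.int32)
            words = cache[trip]
            if len(words):
                qpos_all.append(np.full(len(words), i, dtype=np.int32))
                words_all.append(words)
        if qpos_all:
            self.qpos = np.concatenate(qpos_all)
            self.words = np.concatenate(words_all)
        else:
            self.qpos = np.zeros(0, dtype=np.int32)
            self.words = np.zeros(0, dtype=np.int32)


class _SubjectIndex:
    """Sorted 3-mer word index over an encoded subject sequence."""

    def __init__(self, s_codes: np.ndarray, word_size: int = 3):
        n = len(s_codes) - word_size + 1
        if n <= 0:
            self.order = np.zeros(0, dtype=np.int64)
            self.sorted_codes = np.zeros(0, dtype=np.int32)
            return
        c = s_codes.astype(np.int32)
        codes = c[:n] * 400 + c[1 : n + 1] * 20 + c[2 : n + 2]
        valid = (c[:n] < 20) & (c[1 : n + 1] < 20) & (c[2 : n + 2] < 20)
        codes = np.where(valid, codes, -1)
        self.order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[self.order]

    def lookup(self, words: np.ndarray, qpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (qpos, spos) pairs of all word matches."""
        lo = np.searchsorted(self.sorted_codes, words, side="left")
        hi = np.searchsorted(self.sorted_codes, words, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            z = np.zeros(0, dtype=np.int64)
            return z, z
        qp = np.repeat(qpos.astype(np.int64), counts)
        idx = np.repeat(lo - np.cumsum(counts) + counts, counts) + np.arange(total)
        sp = self.order[idx]
        return qp, sp


def _candidate_seeds(
    qw: _QueryWords,
    index: _SubjectIndex,
    q_codes: np.ndarray,
    s_codes: np.ndarray,
    scheme: ScoringScheme,
) -> list[int]:
    """Subject positions of seeds that survive two-hit + ungapped filter."""
    qp, sp = index.lookup(qw.words, qw.qpos)
    if len(qp) == 0:
        return []
    diag = sp - qp
    order = np.lexsort((sp, diag))
    diag_s, sp_s, qp_s = diag[order], sp[order], qp[order]
    same = diag_s[1:] == diag_s[:-1]
    close = (sp_s[1:] - sp_s[:-1]) <= scheme.two_hit_window
    pair = same & close
    if len(q_codes) < scheme.two_hit_window:
        cand = np.arange(len(sp_s))  # short queries: single-hit seeding
    else:
        cand = np.flatnonzero(pair)
    keep: list[int] = []
    seen_diag_upto: dict[int, int] = {}
    for k in cand:
        d = int(diag_s[k])
        s_pos = int(sp_s[k])
        if seen_diag_upto.get(d, -1) >= s_pos:
            continue
        # sparsify: one extension per two_hit_window stretch of a diagonal
        seen_diag_upto[d] = s_pos + scheme.two_hit_window
        keep.append(int(k))
    if not keep:
        return []
    keep_arr = np.asarray(keep)
    scores = _ungapped_extend_batch(
        q_codes,
        s_codes,
        qp_s[keep_arr].astype(np.int64),
        sp_s[keep_arr].astype(np.int64),
        scheme.word_size,
        scheme.matrix,
        scheme.ungapped_xdrop,
    )
    return [int(sp_s[k]) for k, sc in zip(keep_arr, scores) if sc >= scheme.ungapped_trigger]


def _find_hsps_aa(
    q_codes: np.ndarray,
    s_codes: np.ndarray,
    scheme: ScoringScheme,
    min_raw: int,
    index: _SubjectIndex | None = None,
    qwords: _QueryWords | None = None,
) -> list[LocalAlignment]:
    """HSPs of one protein query against one amino-acid subject."""
    if len(q_codes) * len(s_codes) <= scheme.sw_fallback_cells:
        return _region_hsps(q_codes, s_codes, scheme, min_raw)
    if qwords is None:
        qwords = _QueryWords(q_codes, scheme)
    if index is None:
        index = _SubjectIndex(s_codes, scheme.word_size)
    seeds = _candidate_seeds(qwords, index, q_codes, s_codes, scheme)
    if not seeds:
        return []
    pad = len(q_codes) + 32
    seeds.sort()
    regions: list[list[int]] = []
    for s_pos in seeds:
        lo, hi = max(0, s_pos - pad), min(len(s_codes), s_pos + pad)
        if regions and lo <= regions[-1][1]:
            regions[-1][1] = max(regions[-1][1], hi)
        else:
            regions.append([lo, hi])
    out: list[LocalAlignment] = []
    for lo, hi in regions:
        out.extend(_region_hsps(q_codes, s_codes[lo:hi], scheme, min_raw, lo))
    return out


def min_raw_for_evalue(scheme: ScoringScheme, m: int, n: int, evalue_max: float) -> int:
    """Smallest raw score whose E-value is <= evalue_max."""
    s = (math.log(scheme.karlin_K) + math.log(m) + math.log(n) - math.log(evalue_max))
    return max(1, math.ceil(s / scheme.karlin_lambda))


# ---------------------------------------------------------------------------
# Public search operations
# ---------------------------------------------------------------------------

def search_tblastn_like(
    queries: Sequence[ProteinRecord],
    genome: Sequence,
    scheme: ScoringScheme | None = None,
    evalue_max: float = 1e-20,
) -> list[SearchHit]:
    """Search protein queries against six-frame-translated scaffolds.

    ``genome`` is a sequence of objects with ``id`` and ``seq``
    attributes (:class:`evescan.genome.Scaffold`).  Every returned hit
    satisfies ``evalue <= evalue_max``; hits are sorted by scaffold id
    then forward-strand position.
    """
    if scheme is None:
        scheme = ScoringScheme()
    if not queries:
        raise ValueError("empty query set")
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    genome = list(genome)
    if not genome:
        return []
    translations = {sc.id: six_frame_translate(sc.seq) for sc in genome if len(sc.seq) >= 3}
    n_space = sum(len(aa) for frames in translations.values() for _, aa in frames)
    if n_space == 0:
        return []
    q_codes = {q.id: encode_aa(q.seq) for q in queries}
    q_words = {q.id: _QueryWords(q_codes[q.id], scheme) for q in queries}
    hits: list[SearchHit] = []
    for sc in genome:
        if sc.id not in translations:
            continue
        for frame, aa in translations[sc.id]:
            s_codes = encode_aa(aa)
            index = None
            for q in queries:
                qc = q_codes[q.id]
                m = len(qc)
                if m == 0:
                    continue
                min_raw = min_raw_for_evalue(scheme, m, n_space, evalue_max)
                if index is None and m * len(s_codes) > scheme.sw_fallback_cells:
                    index = _SubjectIndex(s_codes, scheme.word_size)
                for aln in _find_hsps_aa(
                    qc, s_codes, scheme, min_raw, index=index, qwords=q_words[q.id]
                ):
                    ev = scheme.evalue(aln.raw_score, m, n_space)
                    if ev > evalue_max:
                        continue
                    nt_lo, nt_hi = frame_to_forward_nt(
                        frame, aln.s_start, aln.s_end, len(sc.seq)
                    )
                    hits.append(
                        SearchHit(
                            query_id=q.id,
                            subject_id=sc.id,
                            frame=frame,
                            subject_nt_start=nt_lo,
                            subject_nt_end=nt_hi,
                            query_aa_start=aln.q_start,
                            query_aa_end=aln.q_end,
                            raw_score=aln.raw_score,
                            bit_score=scheme.bit_score(aln.raw_score),
                            evalue=ev,
                            aligned_query=aln.aligned_q,
                            aligned_subject=aln.aligned_s,
                        )
                    )
    hits.sort(key=lambda h: (h.subject_id, h.subject_nt_start, h.subject_nt_end, h.query_id))
    return hits


def rank_hits(hits: Iterable[SearchHit]) -> list[SearchHit]:
    """Deterministic 'best hit first' ordering.

    Ascending E-value, ties broken by descending bit score, then
    lexical subject id.
    """
    return sorted(hits, key=lambda h: (h.evalue, -h.bit_score, h.subject_id))


class BlastxDatabase:
    """A protein database prepared for repeated translated queries.

    Records are concatenated (separated by runs of stop characters, so
    no alignment can bridge two proteins) and indexed once; each query
    frame is then seeded against the single concatenated subject.
    """

    _SEP = 24  # stop-character separator length between records

    def __init__(self, db: Sequence[ProteinRecord], scheme: ScoringScheme | None = None):
        if scheme is None:
            scheme = ScoringScheme()
        self.scheme = scheme
        self.records = list(db)
        self.by_id = {p.id: p for p in self.records}
        sep = np.full(self._SEP, AA_INDEX["*"], dtype=np.int8)
        parts: list[np.ndarray] = []
        starts: list[int] = []
        pos = 0
        for p in self.records:
            starts.append(pos)
            codes = encode_aa(p.seq)
            parts.append(codes)
            pos += len(codes)
            parts.append(sep)
            pos += self._SEP
        self.codes = np.concatenate(parts) if parts else np.zeros(0, dtype=np.int8)
        self.starts = np.array(starts, dtype=np.int64)
        self.lengths = np.array([len(p.seq) for p in self.records], dtype=np.int64)
        self.n_space = int(self.lengths.sum())
        self.index = _SubjectIndex(self.codes, scheme.word_size)

    def locate(self, s_start: int, s_end: int) -> tuple[int, int, int] | None:
        """Map a concatenated-subject span to (record idx, local start, local end)."""
        k = int(np.searchsorted(self.starts, s_start, side="right")) - 1
        lo = s_start - int(self.starts[k])
        hi = s_end - int(self.starts[k])
        if hi > int(self.lengths[k]):  # crosses a separator: not a real match
            return None
        return k, lo, hi


def search_blastx_like(
    query_nt: str,
    db: Sequence[ProteinRecord] | BlastxDatabase,
    scheme: ScoringScheme | None = None,
    evalue_max: float = 1e-3,
    query_id: str = "query",
) -> list[SearchHit]:
    """Search a translated nucleotide query against a protein database.

    Returns at most one hit per database protein (its best HSP over all
    six frames), ranked best-first (see :func:`rank_hits`).  In the
    returned hits ``subject_id`` names the database protein, the
    ``subject_nt_*`` coordinates lie on the nucleotide query, and the
    ``query_aa_*`` coordinates lie on the database protein.  Pass a
    prepared :class:`BlastxDatabase` when querying the same database
    repeatedly.
    """
    if len(query_nt) < 3:
        raise ValueError("query shorter than one codon")
    if isinstance(db, BlastxDatabase):
        prepared = db
        if scheme is None:
            scheme = prepared.scheme
    else:
        if not db:
            return []
        if scheme is None:
            scheme = ScoringScheme()
        prepared = BlastxDatabase(db, scheme)
    n_space = prepared.n_space
    if n_space == 0:
        return []
    best: dict[str, SearchHit] = {}
    for frame, aa in six_frame_translate(query_nt):
        f_codes = encode_aa(aa)
        m = len(f_codes)
        if m == 0:
            continue
        min_raw = min_raw_for_evalue(scheme, m, n_space, evalue_max)
        qwords = _QueryWords(f_codes, scheme)
        seeds = _candidate_seeds(qwords, prepared.index, f_codes, prepared.codes, scheme)
        if not seeds:
            continue
        pad = m + 32
        seeds.sort()
        regions: list[list[int]] = []
        for s_pos in seeds:
            lo, hi = max(0, s_pos - pad), min(len(prepared.codes), s_pos + pad)
            if regions and lo <= regions[-1][1]:
                regions[-1][1] = max(regions[-1][1], hi)
            else:
                regions.append([lo, hi])
        for lo, hi in regions:
            for aln in _region_hsps(f_codes, prepared.codes[lo:hi], scheme, min_raw, lo):
                ev = scheme.evalue(aln.raw_score, m, n_space)
                if ev > evalue_max:
                    continue
                located = prepared.locate(aln.s_start, aln.s_end)
                if located is None:
                    continue
                k, p_lo, p_hi = located
                prot = prepared.records[k]
                nt_lo, nt_hi = frame_to_forward_nt(
                    frame, aln.q_start, aln.q_end, len(query_nt)
                )
                hit = SearchHit(
                    query_id=query_id,
                    subject_id=prot.id,
                    frame=frame,
                    subject_nt_start=nt_lo,
                    subject_nt_end=nt_hi,
                    query_aa_start=p_lo,
                    query_aa_end=p_hi,
                    raw_score=aln.raw_score,
                    bit_score=scheme.bit_score(aln.raw_score),
                    evalue=ev,
                    aligned_query=aln.aligned_q,
                    aligned_subject=aln.aligned_s,
                )
                prev = best.get(prot.id)
                if prev is None or (hit.evalue, -hit.bit_score) < (prev.evalue, -prev.bit_score):
                    best[prot.id] = hit
    return rank_hits(best.values())


# ---------------------------------------------------------------------------
# Tabular interchange (conventional 12(+1)-column hit tables)
# ---------------------------------------------------------------------------

_TAB_COLS = 12


def write_hits_tabular(hits: Sequence[SearchHit], path: str | Path) -> None:
    """Write hits in the conventional 12-column format plus a frame column.

    Output coordinates are 1-based inclusive; on the minus strand the
    nucleotide start/end columns are swapped, as external engines do.
    """
    with open(path, "w") as fh:
        for h in hits:
            ident = _percent_identity(h)
            if h.frame > 0:
                s1, s2 = h.subject_nt_start + 1, h.subject_nt_end
            else:
                s1, s2 = h.subject_nt_end, h.subject_nt_start + 1
            row = [
                h.query_id,
                h.subject_id,
                f"{ident:.2f}",
                str(len(h.aligned_query)),
                str(_mismatches(h)),
                str(_gap_opens(h)),
                str(h.query_aa_start + 1),
                str(h.query_aa_end),
                str(s1),
                str(s2),
                f"{h.evalue:.3g}",
                f"{h.bit_score:.1f}",
                str(h.frame),
            ]
            fh.write("\t".join(row) + "\n")


def _percent_identity(h: SearchHit) -> float:
    same = sum(a == b and a != "-" for a, b in zip(h.aligned_query, h.aligned_subject))
    return 100.0 * same / max(1, len(h.aligned_query))


def _mismatches(h: SearchHit) -> int:
    return sum(
        a != b and a != "-" and b != "-"
        for a, b in zip(h.aligned_query, h.aligned_subject)
    )


def _gap_opens(h: SearchHit) -> int:
    n = 0
    for s in (h.aligned_query, h.aligned_subject):
        prev = False
        for c in s:
            if c == "-" and not prev:
                n += 1
            prev = c == "-"
    return n


def external_engine_adapter(path: str | Path, scheme: ScoringScheme | None = None) -> list[SearchHit]:
    """Read a 12(+1)-column tabular hit table into :class:`SearchHit` s.

    Columns: query, subject, identity, length, mismatches, gapopens,
    qstart, qend, sstart, send, evalue, bitscore [, frame].  Subject
    coordinates with sstart > send encode the minus strand; all
    coordinates are normalized to the internal 0-based half-open
    forward-strand convention.  Raw scores are recovered from the bit
    score under ``scheme``; alignment strings are not recoverable from
    this format and are left empty.
    """
    if scheme is None:
        scheme = ScoringScheme()
    hits: list[SearchHit] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (_TAB_COLS, _TAB_COLS + 1):
                raise ValueError(
                    f"{path}: line {ln}: expected {_TAB_COLS} or {_TAB_COLS + 1} "
                    f"columns, got {len(parts)}"
                )
            try:
                qstart, qend = int(parts[6]), int(parts[7])
                sstart, send = int(parts[8]), int(parts[9])
                ev = float(parts[10])
                bits = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"{path}: line {ln}: {exc}") from exc
            if len(parts) == _TAB_COLS + 1:
                frame = int(parts[12])
            else:
                frame = 1 if sstart <= send else -1
            if sstart <= send:
                nt_lo, nt_hi = sstart - 1, send
            else:
                nt_lo, nt_hi = send - 1, sstart
            raw = round((bits * math.log(2) + math.log(scheme.karlin_K)) / scheme.karlin_lambda)
            hits.append(
                SearchHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    frame=frame,
                    subject_nt_start=nt_lo,
                    subject_nt_end=nt_hi,
                    query_aa_start=qstart - 1,
                    query_aa_end=qend,
                    raw_score=int(raw),
                    bit_score=bits,
                    evalue=ev,
                    aligned_query="",
                    aligned_subject="",
                )
            )
    return hits
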