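"""From raw translated-search hits to classified EVE calls.

The calling stage mirrors a conservative homology screen: nearby hits
on the same scaffold and strand are merged into candidate loci, each
locus is re-searched against a mixed viral/non-viral protein database
and kept only when its best match is viral and not annotated as a
hypothetical protein, and colinear fragments of one source protein are
concatenated into a single call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .scoring import ScoringScheme
from .search import (
    BlastxDatabase,
    ProteinRecord,
    SearchHit,
    revcomp,
    search_blastx_like,
)

logger = logging.getLogger(__name__)

#: case-insensitive keywords that mark a best hit as uninformative
DEFAULT_HYPOTHETICAL_KEYWORDS = (
    "hypothetical",
    "uncharacterized",
    "unknown function",
    "predicted protein",
)

RETAINED = "retained"
DISCARDED_NONVIRAL = "discarded_nonviral"
DISCARDED_HYPOTHETICAL = "discarded_hypothetical"


@dataclass
class MergedHit:
    """A cluster of neighboring same-strand hits on one scaffold."""

    scaffold_id: str
    strand: str
    nt_start: int
    nt_end: int
    source_hits: list[SearchHit]
    source_query_ids: set[str] = field(default_factory=set)


@dataclass
class EveCall:
    """A classified candidate endogenous viral element."""

    eve_id: str
    scaffold_id: str
    strand: str
    segments: list[tuple[int, int, int]]  # (nt_start, nt_end, frame), genomic order
    best_protein: ProteinRecord | None
    best_evalue: float
    clade: str | None
    protein_class: str | None
    peptide: str
    status: str
    best_hit: SearchHit | None = None
    source_query_ids: set[str] = field(default_factory=set)

    @property
    def nt_start(self) -> int:
        return min(s for s, _, _ in self.segments)

    @property
    def nt_end(self) -> int:
        return max(e for _, e, _ in self.segments)


def merge_hits(hits: Sequence[SearchHit], merge_gap: int) -> list[MergedHit]:
    """Merge hits whose intervals lie within ``merge_gap`` bp.

    Two hits merge iff they share scaffold and strand and the gap
    between their nucleotide intervals is at most ``merge_gap``
    (overlapping intervals always merge); merging is the transitive
    closure of that relation.  Frames may differ within one merged
    hit — frameshift-degraded elements produce adjacent hits in
    different frames.
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    groups: dict[tuple[str, str], list[SearchHit]] = {}
    for h in hits:
        groups.setdefault((h.subject_id, h.strand), []).append(h)
    merged: list[MergedHit] = []
    for (scaffold, strand), hs in groups.items():
        hs = sorted(hs, key=lambda h: (h.subject_nt_start, h.subject_nt_end))
        cur: list[SearchHit] = [hs[0]]
        cur_end = hs[0].subject_nt_end
        for h in hs[1:]:
            if h.subject_nt_start - cur_end <= merge_gap:
                cur.append(h)
                cur_end = max(cur_end, h.subject_nt_end)
            else:
                merged.append(_make_merged(scaffold, strand, cur))
                cur = [h]
                cur_end = h.subject_nt_end
        merged.append(_make_merged(scaffold, strand, cur))
    merged.sort(key=lambda m: (m.scaffold_id, m.nt_start, m.nt_end))
    return merged


def _make_merged(scaffold: str, strand: str, hits: list[SearchHit]) -> MergedHit:
    return MergedHit(
        scaffold_id=scaffold,
        strand=strand,
        nt_start=min(h.subject_nt_start for h in hits),
        nt_end=max(h.subject_nt_end for h in hits),
        source_hits=list(hits),
        source_query_ids={h.query_id for h in hits},
    )


# ---------------------------------------------------------------------------
# Segment-wise translation
# ---------------------------------------------------------------------------

def _frame_align(start: int, end: int, frame: int, seq_len: int) -> tuple[int, int]:
    """Clip [start, end) to whole codons of the given frame."""
    off = abs(frame) - 1
    anchor = off if frame > 0 else (seq_len - off) % 3
    start = start + ((anchor - start) % 3)
    end = start + 3 * max(0, (end - start) // 3)
    return start, end


def segments_from_hits(
    hits: Sequence[SearchHit], scaffold_seq: str
) -> tuple[list[tuple[int, int, int]], str]:
    """Disjoint frame-tagged segments and the segment-wise peptide.

    Overlapping source hits are resolved by truncating the later hit
    (genomic order); each segment is clipped to whole codons of its own
    frame and translated in that frame.  The peptide concatenates
    segment translations in protein order (genomic order on the plus
    strand, reverse genomic order on the minus strand).
    """
    L = len(scaffold_seq)
    segs: list[tuple[int, int, int]] = []
    prev_end = 0
    for h in sorted(hits, key=lambda h: (h.subject_nt_start, h.subject_nt_end)):
        s = max(h.subject_nt_start, prev_end)
        e = h.subject_nt_end
        s, e = _frame_align(s, e, h.frame, L)
        if e <= s:
            continue
        segs.append((s, e, h.frame))
        prev_end = e
    return segs, translate_segments(segs, scaffold_seq)


def translate_segments(segs: Sequence[tuple[int, int, int]], scaffold_seq: str) -> str:
    """Segment-wise translation, chunks concatenated in protein order."""
    chunks = []
    for s, e, frame in segs:
        sub = scaffold_seq[s:e]
        if frame < 0:
            sub = revcomp(sub)
        chunks.append(str(Seq(sub).translate()))
    if segs and segs[0][2] < 0:
        chunks.reverse()
    return "".join(chunks)


def clip_segments(
    segs: Sequence[tuple[int, int, int]], lo: int, hi: int, seq_len: int
) -> list[tuple[int, int, int]]:
    """Intersect frame-tagged segments with the interval [lo, hi)."""
    out = []
    for s, e, frame in segs:
        s2, e2 = _frame_align(max(s, lo), min(e, hi), frame, seq_len)
        if e2 > s2:
            out.append((s2, e2, frame))
    return out


def reciprocal_classify(
    merged: MergedHit,
    scaffold_seqs: Mapping[str, str],
    db: Sequence[ProteinRecord] | BlastxDatabase,
    scheme: ScoringScheme | None = None,
    blastx_evalue: float = 1e-3,
    hypothetical_keywords: Sequence[str] = DEFAULT_HYPOTHETICAL_KEYWORDS,
) -> EveCall:
    """Classify a merged locus by its best hit in a mixed database.

    The merged nucleotide region is searched (translated) against
    ``db``; the call is retained only when the top-ranked hit is viral
    and its description contains none of the hypothetical keywords.
    The clade and protein class of a retained call come from that
    reciprocal best hit, not from the original screening query; the
    call's segments and peptide are likewise trimmed to the extent of
    that alignment, so the reported peptide is the fragment actually
    homologous to the best protein (forward-search alignments can
    overshoot slightly into flanking sequence).
    """
    seq = scaffold_seqs[merged.scaffold_id]
    region = seq[merged.nt_start : merged.nt_end]
    ranked = search_blastx_like(
        region, db, scheme=scheme, evalue_max=blastx_evalue,
        query_id=f"{merged.scaffold_id}:{merged.nt_start}-{merged.nt_end}",
    )
    segments, peptide = segments_from_hits(merged.source_hits, seq)
    best_prot = None
    best_hit = None
    if not ranked:
        status = DISCARDED_NONVIRAL
        logger.info(
            "%s:%d-%d: no reciprocal hit at E<=%g; discarded",
            merged.scaffold_id, merged.nt_start, merged.nt_end, blastx_evalue,
        )
    else:
        best_hit = ranked[0]
        by_id = db.by_id if isinstance(db, BlastxDatabase) else {p.id: p for p in db}
        best_prot = by_id[best_hit.subject_id]
        desc = best_prot.description.lower()
        if not best_prot.is_viral:
            status = DISCARDED_NONVIRAL
        elif any(k.lower() in desc for k in hypothetical_keywords):
            status = DISCARDED_HYPOTHETICAL
        else:
            status = RETAINED
    retained = status == RETAINED
    if retained:
        # trim to the reciprocal alignment's extent on the scaffold
        lo = merged.nt_start + best_hit.subject_nt_start
        hi = merged.nt_start + best_hit.subject_nt_end
        trimmed = clip_segments(segments, lo, hi, len(seq))
        if trimmed:
            segments = trimmed
            peptide = translate_segments(segments, seq)
    return EveCall(
        eve_id="",
        scaffold_id=merged.scaffold_id,
        strand=merged.strand,
        segments=segments,
        best_protein=best_prot,
        best_evalue=best_hit.evalue if best_hit else float("nan"),
        clade=best_prot.clade if retained else None,
        protein_class=best_prot.protein_class if retained else None,
        peptide=peptide,
        status=status,
        best_hit=best_hit,
        source_query_ids=set(merged.source_query_ids),
    )


# ---------------------------------------------------------------------------
# Fragment concatenation
# ---------------------------------------------------------------------------

def _can_concat(a: EveCall, b: EveCall, max_gap: int) -> bool:
    if a.scaffold_id != b.scaffold_id:
        return False
    if a.best_protein is None or b.best_protein is None:
        return False
    if a.best_protein.id != b.best_protein.id:
        return False
    gap = max(a.nt_start, b.nt_start) - min(a.nt_end, b.nt_end)
    if gap > max_gap:
        return False
    # protein-coordinate intervals of the two fragments must not overlap
    a0, a1 = a.best_hit.query_aa_start, a.best_hit.query_aa_end
    b0, b1 = b.best_hit.query_aa_start, b.best_hit.query_aa_end
    return a1 <= b0 or b1 <= a0


def concatenate_fragments(calls: Sequence[EveCall], concat_max_gap: int) -> list[EveCall]:
    """Join colinear fragments of one source protein into single calls.

    Applies the transitive closure of the pairwise rule (same scaffold
    and best protein, genomic gap within ``concat_max_gap``,
    non-overlapping protein-coordinate intervals) to retained calls;
    discarded calls pass through unchanged.  The concatenated peptide
    follows protein order, not genomic order.
    """
    retained = [c for c in calls if c.status == RETAINED]
    others = [c for c in calls if c.status != RETAINED]
    parent = list(range(len(retained)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(retained)):
        for j in range(i + 1, len(retained)):
            if _can_concat(retained[i], retained[j], concat_max_gap):
                parent[find(i)] = find(j)
    groups: dict[int, list[EveCall]] = {}
    for i, c in enumerate(retained):
        groups.setdefault(find(i), []).append(c)
    out: list[EveCall] = []
    for members in groups.values():
        if len(members) == 1:
            out.append(members[0])
            continue
        members.sort(key=lambda c: c.best_hit.query_aa_start)
        segs = sorted(
            (s for c in members for s in c.segments), key=lambda t: (t[0], t[1])
        )
        peptide = "".join(c.peptide for c in members)
        first = min(members, key=lambda c: c.best_evalue)
        out.append(
            EveCall(
                eve_id="",
                scaffold_id=first.scaffold_id,
                strand=first.strand,
                segments=segs,
                best_protein=first.best_protein,
                best_evalue=first.best_evalue,
                clade=first.clade,
                protein_class=first.protein_class,
                peptide=peptide,
                status=RETAINED,
                best_hit=first.best_hit,
                source_query_ids=set().union(*(c.source_query_ids for c in members)),
            )
        )
    out.extend(others)
    out.sort(key=lambda c: (c.scaffold_id, c.nt_start if c.segments else 0))
    return out


def assign_eve_ids(calls: Sequence[EveCall], species_tag: str, scaffold_order: Sequence[str]) -> None:
    """Number retained calls '<tag> EVE<k>' by scaffold order then position."""
    rank = {sid: i for i, sid in enumerate(scaffold_order)}
    ordered = sorted(
        calls,
        key=lambda c: (rank.get(c.scaffold_id, len(rank)), c.nt_start if c.segments else 0),
    )
    k = j = 0
    for c in ordered:
        if c.status == RETAINED:
            k += 1
            c.eve_id = f"{species_tag} EVE{k}"
        else:
            j += 1
            c.eve_id = f"{species_tag} cand{j}"


def scaffold_context_summary(
    calls: Sequence[EveCall],
    gene_map: Mapping[str, list[tuple[int, int]]],
    scaffold_lengths: Mapping[str, int],
    long_threshold: int = 30_000,
) -> tuple[float, float]:
    """Fractions of EVE-bearing scaffolds that are long / gene-bearing.

    Over the distinct scaffolds carrying at least one retained call:
    the fraction strictly longer than ``long_threshold`` bp, and the
    fraction with at least one annotated gene.
    """
    scaffolds = {c.scaffold_id for c in calls if c.status == RETAINED}
    if not scaffolds:
        raise ValueError("no retained calls: scaffold context fractions undefined")
    missing = scaffolds - set(scaffold_lengths)
    if missing:
        raise ValueError(f"scaffolds missing from length map: {sorted(missing)}")
    n = len(scaffolds)
    n_long = sum(scaffold_lengths[s] > long_threshold for s in scaffolds)
    n_gene = sum(bool(gene_map.get(s)) for s in scaffolds)
    return n_long / n, n_gene / n
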