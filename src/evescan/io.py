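"""Readers and writers for the formats the pipeline touches.

FASTA (genomes and protein databases), GFF3 gene annotations, Newick
trees, and small TSV tables.  Genomic coordinates are 0-based
half-open internally; every emitted table uses 1-based inclusive
coordinates.

The FASTA reader is a small validating scanner rather than a library
call because the pipeline's error contract requires parse errors that
name the offending line, and duplicate-id tolerance with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import dendropy

logger = logging.getLogger(__name__)


@dataclass
class FastaRecord:
    id: str
    description: str
    seq: str


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read FASTA records, preserving order and ids verbatim.

    Residues are uppercased.  Duplicate ids are tolerated with a
    warning (downstream keys include the record ordinal).  Content
    before the first header, an empty header, or an empty record raise
    ``ValueError`` naming the line.
    """
    records: list[FastaRecord] = []
    seen: set[str] = set()
    rid = None
    desc = ""
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if rid is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ValueError(f"{path}: line {header_line}: record {rid!r} has no sequence")
        if rid in seen:
            logger.warning("%s: duplicate FASTA id %r (kept)", path, rid)
        seen.add(rid)
        records.append(FastaRecord(rid, desc, seq.upper()))

    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise ValueError(f"{path}: line {ln}: empty FASTA header")
                rid, _, desc = header.partition(" ")
                chunks = []
                header_line = ln
            else:
                stripped = line.strip()
                if not stripped:
                    continue
                if rid is None:
                    raise ValueError(f"{path}: line {ln}: sequence before first '>' header")
                chunks.append(stripped)
    flush()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path: str | Path, width: int = 70) -> None:
    """Write (id, description, seq) triples or FastaRecords as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, tuple):
                rec = FastaRecord(*rec)
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_gff_genes(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Extract gene intervals from a GFF3 file.

    Only rows whose type column is ``gene`` are used.  Returns
    ``{scaffold_id: [(start, end), ...]}`` with 1-based inclusive
    coordinates, sorted by start within each scaffold.
    """
    genes: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}: line {ln}: not a GFF3 row ({len(parts)} columns)")
            if parts[2] != "gene":
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}: line {ln}: bad coordinates: {exc}") from exc
            genes.setdefault(parts[0], []).append((start, end))
    for iv in genes.values():
        iv.sort()
    return genes


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a single rooted Newick tree.

    ``source`` may be a path or a Newick string.  Duplicate tip labels
    raise ``ValueError`` (the association statistics key on tips).
    """
    text = None
    p = Path(str(source))
    try:
        if p.exists():
            text = p.read_text()
    except OSError:
        pass
    if text is None:
        text = str(source)
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise ValueError(f"failed to parse Newick tree: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(labels) != len(set(labels)):
        dups = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dups}")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True)
    )


def tip_state_map_from_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column (tip, state) TSV into a dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {ln}: expected 2 columns")
            if ln == 1 and parts[0].lower() in ("tip", "label", "eve"):
                continue
            out[parts[0]] = parts[1]
    if not out:
        raise ValueError(f"{path}: empty tip-state map")
    return out
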