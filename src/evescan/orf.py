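"""Stop-codon analysis and the potential-functionality criterion.

An element's translated peptide is scanned for internal stop codons;
an element with none has an intact open reading frame.  An intact
element is called potentially functional when its length is within a
tolerance (default 75 aa) of the exogenous viral protein it most
closely resembles — i.e. it is close to full length, suggesting either
recent acquisition or preservation by selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .calling import RETAINED, EveCall
from .search import ProteinRecord


@dataclass
class OrfReport:
    eve_id: str
    n_internal_stops: int
    intact: bool
    eve_len_aa: int
    ref_len_aa: int
    len_diff_aa: int
    functional: bool


def scan_stops(call: EveCall) -> int:
    """Count internal stop codons in a call's segment-wise peptide.

    A stop at the very end of the final segment is the natural
    terminator of a complete reading frame and is not counted.
    """
    pep = call.peptide
    if not pep:
        raise ValueError(f"{call.eve_id or call.scaffold_id}: empty peptide")
    n = pep.count("*")
    if pep.endswith("*"):
        n -= 1
    return n


def classify_functional(eve_len_aa: int, ref_len_aa: int, intact: bool, tol: int = 75) -> bool:
    """Potentially functional: intact and within ``tol`` aa of the
    reference protein length (inclusive bound)."""
    if eve_len_aa <= 0 or ref_len_aa <= 0:
        raise ValueError("lengths must be positive")
    return intact and abs(eve_len_aa - ref_len_aa) <= tol


def orf_report(call: EveCall, ref_len_aa: int, tol: int = 75) -> OrfReport:
    n_stops = scan_stops(call)
    intact = n_stops == 0
    eve_len = len(call.peptide.rstrip("*"))
    return OrfReport(
        eve_id=call.eve_id,
        n_internal_stops=n_stops,
        intact=intact,
        eve_len_aa=eve_len,
        ref_len_aa=ref_len_aa,
        len_diff_aa=abs(eve_len - ref_len_aa),
        functional=classify_functional(eve_len, ref_len_aa, intact, tol),
    )


def functionality_table(
    calls: Sequence[EveCall],
    protein_db: Sequence[ProteinRecord] | Mapping[str, ProteinRecord],
    tol: int = 75,
) -> tuple[pd.DataFrame, dict]:
    """Per-call ORF reports plus the intact/functional summary.

    The reference length for each call is the length of its
    classification best hit.  Returns a DataFrame (rows ordered by
    eve_id) and a summary dict with ``n_total``, ``n_intact``,
    ``pct_intact`` (one decimal) and ``n_functional``.
    """
    if not isinstance(protein_db, Mapping):
        protein_db = {p.id: p for p in protein_db}
    rows = []
    for call in calls:
        if call.status != RETAINED:
            continue
        if call.best_protein is None or call.best_protein.id not in protein_db:
            raise ValueError(f"{call.eve_id}: best protein not resolvable in database")
        ref = protein_db[call.best_protein.id]
        rep = orf_report(call, len(ref.seq.rstrip("*")), tol)
        rows.append(
            {
                "eve_id": rep.eve_id,
                "similar_protein": ref.id,
                "clade": call.clade,
                "protein_class": call.protein_class,
                "n_internal_stops": rep.n_internal_stops,
                "intact": rep.intact,
                "eve_len_aa": rep.eve_len_aa,
                "ref_len_aa": rep.ref_len_aa,
                "len_diff_aa": rep.len_diff_aa,
                "functional": rep.functional,
            }
        )
    df = pd.DataFrame(rows).sort_values("eve_id").reset_index(drop=True) if rows else pd.DataFrame(
        columns=[
            "eve_id", "similar_protein", "clade", "protein_class",
            "n_internal_stops", "intact", "eve_len_aa", "ref_len_aa",
            "len_diff_aa", "functional",
        ]
    )
    summary = summarize_intact(
        n_intact=int(df["intact"].sum()) if len(df) else 0,
        n_total=len(df),
        n_functional=int(df["functional"].sum()) if len(df) else 0,
    )
    return df, summary


def summarize_intact(n_intact: int, n_total: int, n_functional: int | None = None) -> dict:
    """Intact-ORF summary; ``pct_intact`` is rounded to one decimal."""
    pct = round(100.0 * n_intact / n_total, 1) if n_total else float("nan")
    out = {"n_total": n_total, "n_intact": n_intact, "pct_intact": pct}
    if n_functional is not None:
        out["n_functional"] = n_functional
    return out
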