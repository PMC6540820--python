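"""Synthetic inputs with known ground truth.

Everything the screening pipeline consumes can be generated here:
multi-scaffold genomes with a broad (log-normal) scaffold length
distribution, a clade-structured viral protein database plus non-viral
decoys (a fraction annotated as hypothetical proteins, emulating a
mixed reference database), genomes with planted reverse-translated
viral protein fragments degraded by substitutions, frameshifting
indels and premature stops, and host/element tree pairs grown under
controlled co-divergence and host-switching.

Plants are recorded in :class:`PlantTruth` rows so recovery
(sensitivity/precision) can be scored automatically.  All sampling
flows from per-stage substreams of one seed, so e.g. changing the
number of plants does not perturb scaffold generation.

What this emulates — and does not: the generator reproduces the
*structure* of a real screen (clade-related proteins, degraded
fragments, decoys, short junk scaffolds) but not real genome
composition: no repeats, no codon-usage bias (reverse translation
draws synonymous codons uniformly), no assembly error beyond scaffold
length variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .genome import Scaffold
from .io import write_fasta
from .search import ProteinRecord, revcomp

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"

# stage ids for per-stage RNG substreams
_STAGE_GENOME, _STAGE_PROTEINS, _STAGE_PLANTS, _STAGE_TREES = 0, 1, 2, 3

_CLADE_NAMES = [
    "Mono-Chu", "Bunya-Arena", "Toti-Chryso", "Partiti-Picobirna",
    "Hepe-Virga", "Qinvirus", "Narna-Levi", "Parvoviridae",
]
_CLASS_NAMES = ["Glycoprotein", "RdRP", "Nucleoprotein", "Capsid", "Coat"]
_DECOY_NAMES = [
    "actin-related protein", "cytochrome oxidase subunit",
    "ribosomal protein L7", "heat shock protein 70", "tubulin beta chain",
    "elongation factor 1-alpha", "histone H3", "ATP synthase subunit",
]


@dataclass
class SimConfig:
    """Generator parameters; defaults are the standard study conditions."""

    n_scaffolds: int = 30
    #: natural-log mean/sd of the scaffold length distribution (bp)
    scaffold_len_distribution: tuple[float, float] = (math.log(20_000), 1.2)
    gc_content: float = 0.38
    n_viral_clades: int = 4
    proteins_per_clade: int = 4
    #: within-clade per-residue divergence from the clade ancestor
    clade_divergence: float = 0.15
    n_host_decoys: int = 40
    hypothetical_fraction: float = 0.3
    n_plants: int = 25
    plant_len_aa: tuple[int, int] = (60, 300)
    substitution_rate: float = 0.05
    indel_rate: float = 0.005
    premature_stop_prob: float = 0.3
    #: plants are only placed on scaffolds at least this long, and kept
    #: at least plant_min_separation bp apart
    plant_min_scaffold_len: int = 10_000
    plant_min_separation: int = 3_000
    tree_n_hosts: int = 12
    eve_per_host: int = 1
    host_switch_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gc_content", "hypothetical_fraction", "substitution_rate",
            "indel_rate", "premature_stop_prob", "host_switch_prob",
            "clade_divergence",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.tree_n_hosts < 3:
            raise ValueError("tree_n_hosts must be >= 3")


@dataclass
class PlantTruth:
    """Ground-truth record of one planted viral fragment."""

    scaffold_id: str
    nt_start: int
    nt_end: int
    strand: str
    frame: int
    protein_id: str
    clade: str
    protein_class: str
    fragment_aa_start: int
    fragment_aa_end: int
    n_substitutions: int
    n_indels: int
    stop_introduced: bool


def _rng(config: SimConfig, stage: int, seed: int | None) -> np.random.Generator:
    return np.random.default_rng([seed if seed is not None else config.seed, stage])


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA20), size=length))


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = _AA20.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def simulate_protein_db(
    config: SimConfig, seed: int | None = None
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Viral proteins (clade-structured) and non-viral decoys.

    Clade members derive from a shared random ancestor by i.i.d.
    substitutions at ``clade_divergence``, so within-clade identity
    exceeds between-clade identity.  A ``hypothetical_fraction`` of
    decoys get hypothetical-protein descriptions.
    """
    rng = _rng(config, _STAGE_PROTEINS, seed)
    viral: list[ProteinRecord] = []
    for ci in range(config.n_viral_clades):
        clade = _CLADE_NAMES[ci % len(_CLADE_NAMES)]
        length = int(rng.integers(250, 601))
        ancestor = _random_protein(rng, length)
        for pi in range(config.proteins_per_clade):
            pclass = _CLASS_NAMES[pi % len(_CLASS_NAMES)]
            seq = ancestor if config.proteins_per_clade == 1 else _mutate_protein(
                rng, ancestor, config.clade_divergence
            )
            viral.append(
                ProteinRecord(
                    id=f"vp_c{ci}_{pi}",
                    description=f"{clade} virus {pclass} viral=1 clade={clade} class={pclass}",
                    seq=seq,
                    is_viral=True,
                    clade=clade,
                    protein_class=pclass,
                )
            )
    decoys: list[ProteinRecord] = []
    for di in range(config.n_host_decoys):
        length = int(rng.integers(150, 501))
        hypothetical = rng.random() < config.hypothetical_fraction
        name = (
            f"hypothetical protein HP{di}"
            if hypothetical
            else f"{_DECOY_NAMES[di % len(_DECOY_NAMES)]} {di}"
        )
        decoys.append(
            ProteinRecord(
                id=f"host_{di}",
                description=f"{name} viral=0",
                seq=_random_protein(rng, length),
                is_viral=False,
            )
        )
    return viral, decoys


def simulate_genome(config: SimConfig, seed: int | None = None) -> list[Scaffold]:
    """Random multi-scaffold genome with the configured GC content."""
    rng = _rng(config, _STAGE_GENOME, seed)
    mu, sigma = config.scaffold_len_distribution
    p = np.array([
        (1 - config.gc_content) / 2, config.gc_content / 2,
        config.gc_content / 2, (1 - config.gc_content) / 2,
    ])
    scaffolds = []
    for i in range(config.n_scaffolds):
        length = int(np.clip(rng.lognormal(mu, sigma), 1_000, 2_000_000))
        seq = "".join(np.array(list(_NT))[rng.choice(4, size=length, p=p)])
        scaffolds.append(Scaffold(id=f"scaffold_{i}", seq=seq))
    return scaffolds


_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
_STOP_CODONS = sorted(standard_dna_table.stop_codons)


def reverse_translate(rng: np.random.Generator, peptide: str) -> str:
    """Reverse-translate with uniformly drawn synonymous codons."""
    parts = []
    for aa in peptide:
        codons = _CODONS_FOR.get(aa) or _STOP_CODONS
        parts.append(codons[rng.integers(len(codons))])
    return "".join(parts)


def _degrade(
    rng: np.random.Generator, nt: str, sub_rate: float, indel_rate: float
) -> tuple[str, int, int]:
    out: list[str] = []
    n_sub = n_indel = 0
    for base in nt:
        r = rng.random()
        if r < indel_rate:
            n_indel += 1
            if rng.random() < 0.5:
                continue  # deletion
            out.append(base)
            out.append(_NT[rng.integers(4)])  # insertion
        elif r < indel_rate + sub_rate:
            n_sub += 1
            out.append(_NT.replace(base, "")[rng.integers(3)])
        else:
            out.append(base)
    return "".join(out), n_sub, n_indel


def plant_eves(
    genome: Sequence[Scaffold],
    viral_db: Sequence[ProteinRecord],
    config: SimConfig,
    seed: int | None = None,
) -> tuple[list[Scaffold], list[PlantTruth]]:
    """Overwrite genome regions with degraded viral protein fragments.

    Each plant samples a viral protein and a fragment of it, reverse
    translates it, optionally replaces one internal codon with a stop
    (``premature_stop_prob``), applies substitutions and 1-nt
    frameshifting indels at the configured per-site rates, and writes
    it over a uniformly chosen position and strand of an eligible
    scaffold.  Plants never overlap and keep ``plant_min_separation``
    bp apart; positions are recorded exactly in the truth rows.
    """
    rng = _rng(config, _STAGE_PLANTS, seed)
    seqs = {s.id: list(s.seq) for s in genome}
    occupied: dict[str, list[tuple[int, int]]] = {s.id: [] for s in genome}
    lo, hi = config.plant_len_aa
    eligible = [s.id for s in genome if len(s) >= max(config.plant_min_scaffold_len, 3 * hi + 2 * config.plant_min_separation)]
    if not eligible:
        raise ValueError("no scaffold long enough to hold a plant")
    truths: list[PlantTruth] = []
    sep = config.plant_min_separation
    for _ in range(config.n_plants):
        prot = viral_db[rng.integers(len(viral_db))]
        flen = int(min(rng.integers(lo, hi + 1), len(prot.seq)))
        a0 = int(rng.integers(0, len(prot.seq) - flen + 1))
        fragment = prot.seq[a0 : a0 + flen]
        nt = reverse_translate(rng, fragment)
        stop_introduced = False
        if flen > 2 and rng.random() < config.premature_stop_prob:
            ci = int(rng.integers(1, flen - 1))
            nt = nt[: 3 * ci] + _STOP_CODONS[rng.integers(3)] + nt[3 * ci + 3 :]
            stop_introduced = True
        nt, n_sub, n_indel = _degrade(rng, nt, config.substitution_rate, config.indel_rate)
        strand = "+" if rng.random() < 0.5 else "-"
        insert = nt if strand == "+" else revcomp(nt)
        placed = False
        for _try in range(400):
            sid = eligible[rng.integers(len(eligible))]
            slen = len(seqs[sid])
            if slen < len(insert) + 2:
                continue
            pos = int(rng.integers(0, slen - len(insert)))
            end = pos + len(insert)
            if any(pos - sep < e and s < end + sep for s, e in occupied[sid]):
                continue
            seqs[sid][pos:end] = list(insert)
            occupied[sid].append((pos, end))
            L = slen
            frame = (pos % 3) + 1 if strand == "+" else -(((L - end) % 3) + 1)
            truths.append(
                PlantTruth(
                    scaffold_id=sid,
                    nt_start=pos,
                    nt_end=end,
                    strand=strand,
                    frame=frame,
                    protein_id=prot.id,
                    clade=prot.clade or "",
                    protein_class=prot.protein_class or "",
                    fragment_aa_start=a0,
                    fragment_aa_end=a0 + flen,
                    n_substitutions=n_sub,
                    n_indels=n_indel,
                    stop_introduced=stop_introduced,
                )
            )
            placed = True
            break
        if not placed:
            raise ValueError("genome too small for the requested number of plants")
    new_genome = [Scaffold(id=s.id, seq="".join(seqs[s.id])) for s in genome]
    return new_genome, truths


# ---------------------------------------------------------------------------
# Host / element tree pairs
# ---------------------------------------------------------------------------

class _SimNode:
    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None):
        self.label = label
        self.children: list[_SimNode] = []

    def newick(self) -> str:
        if not self.children:
            return self.label or ""
        return "(" + ",".join(c.newick() for c in self.children) + ")"


def simulate_tree_pair(
    config: SimConfig, seed: int | None = None
) -> tuple[dendropy.Tree, dendropy.Tree, dict[str, str]]:
    """Grow a host tree (Yule) and an element tree tracking host lineages.

    One founding element lineage follows host speciations
    (co-divergence: the lineage splits with its host); before each
    speciation every element lineage jumps to a uniformly chosen other
    host lineage with probability ``host_switch_prob``.  After the run,
    each surviving lineage is expanded into ``eve_per_host`` copies on
    its final host (a ladder of recent within-host duplications — how
    real elements come to occur in multi-copy host-specific clusters).
    Returns both trees and the element-tip -> host-tip map.
    """
    rng = _rng(config, _STAGE_TREES, seed)
    host_root = _SimNode()
    host_lineages = [host_root]
    founder = _SimNode()
    eve_lineages = [(founder, 0)]  # (node, host lineage index)
    while len(host_lineages) < config.tree_n_hosts:
        # host switches in the interval before this speciation
        if len(host_lineages) > 1:
            for k, (node, hidx) in enumerate(eve_lineages):
                if rng.random() < config.host_switch_prob:
                    others = [i for i in range(len(host_lineages)) if i != hidx]
                    eve_lineages[k] = (node, others[int(rng.integers(len(others)))])
        split = int(rng.integers(len(host_lineages)))
        parent = host_lineages[split]
        left, right = _SimNode(), _SimNode()
        parent.children = [left, right]
        host_lineages[split] = left
        host_lineages.append(right)
        new_idx = len(host_lineages) - 1
        next_eves = []
        for node, hidx in eve_lineages:
            if hidx == split:
                a, b = _SimNode(), _SimNode()
                node.children = [a, b]
                next_eves.append((a, split))
                next_eves.append((b, new_idx))
            else:
                next_eves.append((node, hidx))
        eve_lineages = next_eves
    for i, leaf in enumerate(host_lineages):
        leaf.label = f"H{i + 1}"
    tip_to_host: dict[str, str] = {}
    k_copies = max(1, config.eve_per_host)
    counter = 0
    for node, hidx in eve_lineages:
        host_label = host_lineages[hidx].label
        tips: list[_SimNode] = []
        for _ in range(k_copies):
            counter += 1
            tip = _SimNode(f"EVE{counter}")
            tip_to_host[tip.label] = host_label
            tips.append(tip)
        if k_copies == 1:
            node.label = tips[0].label
        else:  # terminal duplication ladder
            sub = tips[0]
            for t in tips[1:]:
                joint = _SimNode()
                joint.children = [sub, t]
                sub = joint
            node.children = sub.children if sub.children else []
            if sub.children:
                node.label = None
            else:
                node.label = sub.label
    host_tree = dendropy.Tree.get(data=host_root.newick() + ";", schema="newick")
    eve_tree = dendropy.Tree.get(data=founder.newick() + ";", schema="newick")
    host_tree.is_rooted = True
    eve_tree.is_rooted = True
    return host_tree, eve_tree, tip_to_host


def random_yule_tree(n_tips: int, seed: int, prefix: str = "T") -> dendropy.Tree:
    """A random rooted binary tree by repeated cherry joining."""
    rng = np.random.default_rng(seed)
    nodes = [f"{prefix}{i + 1}" for i in range(n_tips)]
    while len(nodes) > 1:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes))))
        nodes.append(f"({a},{b})")
    tree = dendropy.Tree.get(data=nodes[0] + ";", schema="newick")
    tree.is_rooted = True
    return tree


def codivergence_study_config(seed: int) -> SimConfig:
    """Standard pure-co-divergence tree regime: every element lineage
    tracks its host faithfully, with two recent within-host copies per
    lineage (so host states recur and the association test is
    non-degenerate)."""
    return SimConfig(tree_n_hosts=12, eve_per_host=2, host_switch_prob=0.0, seed=seed)


def host_switch_study_config(seed: int) -> SimConfig:
    """Standard pure-host-switch tree regime: single-copy lineages that
    jump to a random host before every speciation, erasing host
    structure."""
    return SimConfig(tree_n_hosts=12, eve_per_host=1, host_switch_prob=1.0, seed=seed)


# ---------------------------------------------------------------------------
# Bundled dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedData:
    genome: list[Scaffold]
    viral: list[ProteinRecord]
    decoys: list[ProteinRecord]
    truth: list[PlantTruth]
    host_tree: dendropy.Tree
    eve_tree: dendropy.Tree
    tip_to_host: dict[str, str]
    config: SimConfig = field(repr=False, default=None)


def simulate_dataset(config: SimConfig) -> SimulatedData:
    """Generate every pipeline input from one configuration."""
    viral, decoys = simulate_protein_db(config)
    genome = simulate_genome(config)
    genome, truth = plant_eves(genome, viral, config)
    host_tree, eve_tree, tip_to_host = simulate_tree_pair(config)
    return SimulatedData(genome, viral, decoys, truth, host_tree, eve_tree, tip_to_host, config)


def write_dataset(data: SimulatedData, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset in the formats the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fasta",
        "viral": out / "viral_proteins.fasta",
        "decoys": out / "decoy_proteins.fasta",
        "truth": out / "truth.tsv",
        "host_tree": out / "host.nwk",
        "eve_tree": out / "eve.nwk",
        "tip_map": out / "tip_to_host.tsv",
    }
    write_fasta(((s.id, "", s.seq) for s in data.genome), paths["genome"])
    write_fasta(((p.id, p.to_description(), p.seq) for p in data.viral), paths["viral"])
    write_fasta(((p.id, p.to_description(), p.seq) for p in data.decoys), paths["decoys"])
    cols = [
        "scaffold_id", "nt_start", "nt_end", "strand", "frame", "protein_id",
        "clade", "protein_class", "fragment_aa_start", "fragment_aa_end",
        "n_substitutions", "n_indels", "stop_introduced",
    ]
    with open(paths["truth"], "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in data.truth:
            fh.write("\t".join(str(getattr(t, c)) for c in cols) + "\n")
    paths["host_tree"].write_text(
        data.host_tree.as_string(schema="newick", suppress_rooting=True)
    )
    paths["eve_tree"].write_text(
        data.eve_tree.as_string(schema="newick", suppress_rooting=True)
    )
    with open(paths["tip_map"], "w") as fh:
        fh.write("tip\thost\n")
        for tip, host in data.tip_to_host.items():
            fh.write(f"{tip}\t{host}\n")
    return paths
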