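"""Run configuration: the pipeline's thresholds in one place.

The defaults are the screening parameters of the analysis this package
implements: a 10 kb scaffold-length floor, a 1e-20 E-value cutoff for
the forward translated search, 0.001 for the reciprocal protein search,
a 10 bp neighbor-merge gap, a 75 aa length tolerance for calling an
intact element potentially functional, 1000 tip-label permutations for
the association index and 100 host-map randomizations for the
reconciliation null, with event costs co-divergence 0 and duplication /
host switch / loss / failure-to-diverge 1 each.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

DEFAULT_EVENT_COSTS = {
    "codivergence": 0,
    "duplication": 1,
    "host_switch": 1,
    "loss": 1,
    "failure_to_diverge": 1,
}


@dataclass
class RunConfig:
    min_scaffold_len: int = 10_000
    tblastn_evalue: float = 1e-20
    blastx_evalue: float = 1e-3
    merge_gap: int = 10
    concat_max_gap: int = 5_000
    functional_len_tol: int = 75
    ai_permutations: int = 1_000
    reconcile_permutations: int = 100
    event_costs: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_EVENT_COSTS))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_scaffold_len", "merge_gap", "concat_max_gap",
            "functional_len_tol", "ai_permutations", "reconcile_permutations",
        ):
            if getattr(self, name) < (0 if name == "merge_gap" else 1):
                raise ValueError(f"{name} must be positive")
        for name in ("tblastn_evalue", "blastx_evalue"):
            v = getattr(self, name)
            if not (0 < v < float("inf")):
                raise ValueError(f"{name} must be in (0, inf)")
        unknown = set(self.event_costs) - set(DEFAULT_EVENT_COSTS)
        if unknown:
            raise ValueError(f"unknown event cost keys: {sorted(unknown)}")

    # -- flat key=value serialization ------------------------------------

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "event_costs":
                for k, c in sorted(v.items()):
                    lines.append(f"event_cost.{k} = {c}")
            else:
                lines.append(f"{f.name} = {v!r}" if isinstance(v, float) else f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        known = {f.name: f.type for f in fields(cls) if f.name != "event_costs"}
        kwargs: dict = {}
        costs = dict(DEFAULT_EVENT_COSTS)
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {ln}: expected 'key = value'")
            key, _, val = (p.strip() for p in line.partition("="))
            if key.startswith("event_cost."):
                event = key[len("event_cost."):]
                if event not in DEFAULT_EVENT_COSTS:
                    raise ValueError(f"{path}: line {ln}: unknown event {event!r}")
                costs[event] = int(val)
            elif key in known:
                typ = known[key]
                kwargs[key] = float(val) if "float" in str(typ) else int(val)
            else:
                raise ValueError(f"{path}: line {ln}: unknown config key {key!r}")
        return cls(event_costs=costs, **kwargs)
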