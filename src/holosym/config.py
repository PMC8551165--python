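"""Run configuration: every tunable of the pipeline in one place.

A ``RunConfig`` can be loaded from a simple ``key = value`` text file and is
echoed to the run log so that every threshold used in an analysis is on
record.  Unknown keys are rejected rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

log = logging.getLogger("holosym")


@dataclass
class RunConfig:
    # holobiont partition
    min_aln_len: int = 100          # bp, minimum alignment length of a kept hit
    min_pident: float = 80.0        # %, minimum sequence identity of a kept hit
    silva_min_aln_len: int = 100    # rRNA screen thresholds (same defaults)
    silva_min_pident: float = 80.0
    min_contig_len: int = 500       # bp, contigs shorter than this are dropped
    # clone detection
    min_depth: int = 10             # per-sample depth required at a kept SNP
    min_qual: float = 30.0          # site QUAL required at a kept SNP
    tau: float = 0.25               # clone call: d <= tau * median pairwise distance
    # expression
    min_total_counts: int = 10      # gene kept if row sum >= this
    fdr_level: float = 0.1          # DE significance cutoff on BH-adjusted p
    n_perm: int = 9999              # PERMANOVA permutations
    # enrichment
    enrich_min_size: int = 5        # smallest testable class
    enrich_max_frac: float = 0.1    # largest testable class, fraction of genes
    alpha: float = 0.05             # per-class significance for cross-taxa overlap
    jaccard_threshold: float = 0.75 # optional class merging similarity
    # randomness
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a ``key = value`` config file; unknown keys raise ValueError."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, value = (t.strip() for t in line.partition("="))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            typ = fields[key].type
            caster = {"int": int, "float": float, "str": str}.get(str(typ), None)
            if caster is None:
                caster = typ if callable(typ) else str
            kwargs[key] = caster(value)
        return cls(**kwargs)

    def log_all(self) -> None:
        """Echo every tunable into the run log."""
        for f in dataclasses.fields(self):
            log.info("config %s = %r", f.name, getattr(self, f.name))
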