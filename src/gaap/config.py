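"""Pipeline configuration.

All tunable parameters of the scaffolder live in one dataclass so that a run
is fully described by (inputs, config, seed).  Values can be overridden from
a YAML file; unknown keys are rejected so typos do not silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

logger = logging.getLogger("gaap")


@dataclass
class GaapConfig:
    """Parameters of segment identification, indexing and local scaffolding.

    Attributes
    ----------
    min_seg_len:
        Minimal number of consecutive core genes that constitutes a cGOF
        segment.  Two is the smallest meaningful value: a single gene carries
        no order information.
    min_identity, min_coverage:
        Acceptance thresholds for a core-gene alignment hit on a contig
        (fraction of identical bases over the aligned region; fraction of the
        gene covered by the alignment).  Conventional values for intra-species
        core genes.
    link_cutoff:
        A paired-end link between two contig ends is trusted only when
        strictly more than this many read pairs support it; screens out
        links caused by sporadic mismapping.
    alpha:
        Weight of the cGOF-permutation term relative to the read-link term in
        the edge confidence c = alpha * permutation + (1 - alpha) * link.
    l_sat:
        Link count at which the read-link term saturates at 1.0.
    end_window:
        A mate supports a contig-end link only when it lies within this many
        bases of the end it points off.  ``None`` means: estimate the mean
        insert size from pairs with both mates on one contig (fallback 500).
    repeat_depth_factor:
        A contig may be reused at several junctions (repeat behaviour) when
        its read depth is at least this multiple of the median contig depth.
    repeat_min_edges:
        ...and it has at least this many disjoint high-confidence edges.
    max_repeat_copies:
        Upper bound on how many times one repeat contig may be placed.
    min_gap / max_gap:
        Bounds on estimated gap sizes written into the pseudo-genome; gaps
        created purely by the guiding permutation get at least ``min_gap`` N.
    default_gap:
        Gap used for junctions supported only by read pairs, where no
        reference coordinates are available.
    seed:
        Seed for every stochastic component (only the simulator is
        stochastic; the scaffolder itself is deterministic).
    """

    min_seg_len: int = 2
    min_identity: float = 0.90
    min_coverage: float = 0.80
    ambiguity_margin: float = 0.01
    link_cutoff: int = 5
    alpha: float = 0.5
    l_sat: int = 10
    end_window: int | None = None
    repeat_depth_factor: float = 1.5
    repeat_min_edges: int = 2
    repeat_min_conf: float = 0.5
    max_repeat_copies: int = 4
    min_gap: int = 100
    max_gap: int = 10_000
    default_gap: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.l_sat < 1:
            raise ValueError(f"l_sat must be >= 1, got {self.l_sat}")
        if self.link_cutoff < 0:
            raise ValueError("link_cutoff must be >= 0")
        if self.min_seg_len < 2:
            raise ValueError("min_seg_len must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "GaapConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def log_parameters(self) -> None:
        for field in dataclasses.fields(self):
            logger.info("config %s = %r", field.name, getattr(self, field.name))
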