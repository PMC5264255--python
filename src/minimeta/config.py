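"""Pipeline configuration: every tunable threshold with its default.

The config file is a flat YAML mapping of dotted keys to values. Unknown
keys are rejected so typos fail loudly. Each default carries a provenance
tag: ``published`` when the value is printed in the method description the
pipeline follows, ``internal`` when it is this package's own choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .formats import ConfigError

# key -> (default, provenance)
DEFAULTS = {
    # contig connection graph
    "ccg.min_overlap": (40, "published"),          # k-1 for a k=41 assembly
    "ccg.plink_min_support": (3, "internal"),
    "ccg.w_conv": (400, "published"),              # convergence bound, bp
    "partition.strict_gt2": (False, "internal"),   # literal 'out-degree > 2'
    "em.max_iter": (200, "internal"),
    "em.tol": (1e-6, "internal"),
    "em.insert_sd_floor": (1.0, "internal"),
    "em.depth_sd_floor": (0.5, "internal"),
    # binning
    "baf.min_len": (1000, "internal"),
    "baf.cluster_cutoff": (3500.0, "internal"),    # footrule cut, fixture-calibrated
    "baf.metric": ("footrule", "internal"),
    "baf.anchor_k": (31, "internal"),
    "baf.anchor_fraction": (0.5, "internal"),
    "baf.end_overlap": (40, "published"),
    "baf.max_path_len": (10000, "internal"),
    # recovery (increase / decrease / connection)
    "mga.min_contig": (300, "published"),
    "mga.min_positive": (5, "internal"),
    "mga.negative_rule": ("mean2sd", "internal"),  # or 'literal' (d > 2*sd)
    "mga.svm_c": (1.0, "internal"),
    "mga.orf_frame": (False, "internal"),
    "mga.svm_gamma": ("scale", "internal"),
    "mga.seed_coverage": (0.9, "internal"),
    "mga.depth_sd": (2.0, "published"),
    "mga.step_limit": (30, "internal"),
    "mga.span_limit": (15000, "internal"),
    "mga.max_tip_nodes": (3, "internal"),
    "mga.max_tip_len": (1000, "internal"),
    "mga.identity": (0.95, "published"),
    "mga.max_bubble_walks": (16, "internal"),      # enumeration safety cap
    "mga.scaffold_min_gap": (10, "internal"),
    # variation
    "variation.max_walks": (3, "published"),
    "variation.min_walk_depth": (2.0, "published"),
    "variation.lr": (0.5, "internal"),
    "variation.gd_iters": (5000, "internal"),
    # simulator
    "sim.n_genomes": (20, "internal"),
    "sim.genome_length": (200000, "internal"),
    "sim.n_strain_pairs": (2, "internal"),
    "sim.ani": (0.98, "internal"),
    "sim.repeat_count": (60, "internal"),
    "sim.repeat_length": (150, "internal"),
    "sim.depth_min": (5.0, "published"),
    "sim.depth_max": (128.0, "published"),
    "sim.power_exponent": (1.5, "internal"),
    "sim.k": (41, "published"),
    "sim.error_rate": (0.02, "published"),
    "sim.insert_mean": (200.0, "published"),
    "sim.insert_sd": (20.0, "internal"),
    "sim.read_len": (100, "published"),
    "sim.seed_fraction": (0.4, "published"),       # 40% of contigs as seeds
    "sim.min_seed_coverage": (0.3, "published"),   # recommended initial coverage
    "seed": (0, "internal"),
}


@dataclass
class PipelineConfig:
    """Flat key/value configuration with validated, typed access."""

    values: dict

    @classmethod
    def default(cls) -> "PipelineConfig":
        return cls({k: v for k, (v, _) in DEFAULTS.items()})

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: config must be a flat mapping")
        cfg = cls.default()
        for key, value in user.items():
            cfg.set(key, value)
        return cfg

    def set(self, key: str, value) -> None:
        if key not in DEFAULTS:
            raise ConfigError(f"unknown config key {key!r}")
        default = DEFAULTS[key][0]
        if isinstance(default, bool):
            value = bool(value)
        elif isinstance(default, int) and not isinstance(value, bool):
            value = int(value)
        elif isinstance(default, float):
            value = float(value)
        if isinstance(default, (int, float)) and not isinstance(default, bool):
            if value <= 0 and key not in ("seed",):
                raise ConfigError(f"config key {key!r} must be positive")
        self.values[key] = value

    def __getitem__(self, key: str):
        if key not in DEFAULTS:
            raise ConfigError(f"unknown config key {key!r}")
        return self.values[key]

    def provenance(self, key: str) -> str:
        return DEFAULTS[key][1]

    def snapshot(self) -> dict:
        return dict(self.values)
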