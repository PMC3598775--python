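"""Pipeline configuration.

A single :class:`RunConfig` carries every tunable parameter of the pipeline
together with the one global seed from which all stage-level random streams
are derived (see :mod:`bistrat._rng`). Configurations round-trip through
YAML; CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # global
    seed: int = 0

    # biclustering
    k_biclusters: int = 44
    min_samples: int = 10
    max_samples: int = 60
    min_genes: int = 15
    max_genes: int = 200
    target_samples: int = 20
    target_genes: int = 60
    lambda_size: float = 0.3
    lambda_overlap: float = 0.5
    anneal_t0: float = 0.05
    anneal_cooling: float = 0.995
    iters_per_bicluster: int = 2000
    n_sweeps: int = 8
    extreme_z: float = 1.5
    activity_threshold: float = 0.8
    gene_margin: float = 1.4
    lambda_activation: float = 0.5

    # preprocessing
    noise_threshold: float | None = None  # None -> 20th percentile of the matrix
    min_expressed_fraction: float = 0.10

    # survival / separation test
    n_randomizations: int = 20
    survival_gene_p: float = 0.01

    # differential expression / volcano
    de_p_cut: float = 0.05
    de_fc_cut: float = 2.0

    # prediction
    correlation_threshold: float = 0.9
    early_cutoff_years: float = 2.0
    late_cutoff_years: float = 8.0
    n_cv_splits: int = 50
    test_fraction: float = 0.2
    split_alpha: float = 0.05
    tree_trim_level: float = 0.5
    tree_min_leaf: int = 7
    tree_n_permutations: int = 9999
    ridge_n_folds: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if not self.early_cutoff_years < self.late_cutoff_years:
            raise ValueError("early_cutoff_years must be < late_cutoff_years")
        if self.k_biclusters < 1:
            raise ValueError("k_biclusters must be >= 1")
        if not (0 < self.min_samples <= self.max_samples):
            raise ValueError("invalid sample-size bounds")
        if not (0 < self.min_genes <= self.max_genes):
            raise ValueError("invalid gene-size bounds")
        if not 0 < self.anneal_cooling < 1:
            raise ValueError("anneal_cooling must be in (0, 1)")
        if self.anneal_t0 <= 0:
            raise ValueError("anneal_t0 must be > 0")
        if not 0 < self.min_expressed_fraction <= 1:
            raise ValueError("min_expressed_fraction must be in (0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **overrides) -> "RunConfig":
        d = asdict(self)
        d.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig.from_dict(d)


def load_config(path=None, **cli_overrides) -> RunConfig:
    """Load a RunConfig from YAML (if given) and apply CLI overrides.

    Overrides equal to None are ignored so that unset CLI flags do not
    clobber file values.
    """
    cfg = RunConfig.from_yaml(path) if path else RunConfig()
    return cfg.replace(**cli_overrides)
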