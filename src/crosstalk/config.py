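"""Run configuration: one YAML file drives the whole pipeline.

Every constant the analysis depends on is surfaced here with its default:
the top-scoring fraction (0.02), the dual-score shift threshold (0.1), the
per-group centrality depth (top 5), the minimum seed count (2) and the
propagation parameters. The master ``rng_seed`` is mandatory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .propagation import PropagationParams
from .synthetic import PhenotypeSpec, default_phenotype_specs


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic fixture (see :mod:`crosstalk.synthetic`)."""

    n_nodes: int = 1000
    attach_m: int = 3
    preset: str = "headline"
    module_size: int = 40
    module_density: float = 0.3
    seed_fraction: float = 0.4
    inter_category_overlap: float = 0.1
    n_bridges: int = 10
    n_decoy_sets: int = 20
    decoy_set_size: int = 30

    def specs(self) -> list[PhenotypeSpec]:
        base = default_phenotype_specs(self.preset)
        return [
            PhenotypeSpec(s.phenotype_id, s.category, self.module_size)
            for s in base
        ]


@dataclass(frozen=True)
class InputPaths:
    """External input files for a run on real (non-synthetic) data."""

    edges: Path
    seeds: Path
    categories: Path
    gene_sets: Path | None = None

    def validate(self) -> None:
        for name in ("edges", "seeds", "categories", "gene_sets"):
            path = getattr(self, name)
            if path is not None and not Path(path).is_file():
                raise FileNotFoundError(f"{name} file not found: {path}")


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of one pipeline run."""

    rng_seed: int
    out_dir: Path
    synthetic: SyntheticConfig | None = None
    inputs: InputPaths | None = None
    fraction: float = 0.02
    delta_threshold: float = 0.1
    top_k: int = 5
    min_seeds: int = 2
    pairing: str = "all"
    n_top_candidates: int = 3
    edge_mode: str = "union"
    max_linkers: int | None = None
    propagation: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError(
                "configure exactly one of 'synthetic' or 'inputs'"
            )
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must lie in (0, 1]")
        if self.delta_threshold <= 0:
            raise ValueError("delta_threshold must be > 0")
        if self.top_k < 1 or self.n_top_candidates < 1:
            raise ValueError("top_k and n_top_candidates must be >= 1")
        if self.inputs is not None:
            self.inputs.validate()

    def propagation_params(self, rng_seed: int) -> PropagationParams:
        return PropagationParams(rng_seed=rng_seed, **dict(self.propagation))

    @classmethod
    def from_dict(cls, payload: Mapping[str, Any], base_dir: Path | None = None) -> "RunConfig":
        payload = dict(payload)
        base = Path(base_dir) if base_dir is not None else Path.cwd()

        def resolve(p: str | None) -> Path | None:
            if p is None:
                return None
            path = Path(p)
            return path if path.is_absolute() else base / path

        synthetic = payload.pop("synthetic", None)
        inputs = payload.pop("inputs", None)
        if synthetic is not None:
            synthetic = SyntheticConfig(**synthetic)
        if inputs is not None:
            inputs = InputPaths(
                edges=resolve(inputs["edges"]),
                seeds=resolve(inputs["seeds"]),
                categories=resolve(inputs["categories"]),
                gene_sets=resolve(inputs.get("gene_sets")),
            )
        out_dir = resolve(payload.pop("out_dir", "crosstalk_run"))
        return cls(
            out_dir=out_dir, synthetic=synthetic, inputs=inputs, **payload
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with path.open() as handle:
            payload = yaml.safe_load(handle)
        if not isinstance(payload, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(payload, base_dir=path.parent)

    def to_manifest_dict(self) -> dict:
        """JSON-serializable echo of the configuration for the run manifest."""
        out: dict[str, Any] = {
            "rng_seed": self.rng_seed,
            "out_dir": str(self.out_dir),
            "fraction": self.fraction,
            "delta_threshold": self.delta_threshold,
            "top_k": self.top_k,
            "min_seeds": self.min_seeds,
            "pairing": self.pairing,
            "n_top_candidates": self.n_top_candidates,
            "edge_mode": self.edge_mode,
            "max_linkers": self.max_linkers,
            "propagation": dict(self.propagation),
        }
        if self.synthetic is not None:
            out["synthetic"] = {
                k: getattr(self.synthetic, k)
                for k in (
                    "n_nodes", "attach_m", "preset", "module_size",
                    "module_density", "seed_fraction", "inter_category_overlap",
                    "n_bridges", "n_decoy_sets", "decoy_set_size",
                )
            }
        if self.inputs is not None:
            out["inputs"] = {
                "edges": str(self.inputs.edges),
                "seeds": str(self.inputs.seeds),
                "categories": str(self.inputs.categories),
                "gene_sets": (
                    str(self.inputs.gene_sets)
                    if self.inputs.gene_sets is not None else None
                ),
            }
        return out
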