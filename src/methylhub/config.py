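"""Simulation and pipeline configuration objects.

Defaults reflect the study conditions the pipeline targets: 21 matched
tumor/normal pairs profiled on both platforms, a promoter DMP-count
distribution dominated by single-DMP genes, planted effect sizes of
|delta beta| = 0.3 and |log2 FC| = 2, and a scale-free interaction network
with four planted hubs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml


def _config_error(name: str, msg: str):
    return ValueError(f"invalid SimConfig field {name!r}: {msg}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic paired methylation/expression study.

    ``beta_shift`` and ``expr_log2fc`` are magnitudes: planted EI genes get a
    tumor beta shift of -|beta_shift| with +|expr_log2fc| expression, planted
    ES genes the converse.
    """

    n_pairs: int = 21
    n_genes: int = 2000
    probes_per_promoter_dist: dict = field(
        default_factory=lambda: {1: 0.55, 2: 0.25, 3: 0.12, 4: 0.08}
    )
    n_ei_planted: int = 10
    n_es_planted: int = 10
    beta_shift: float = 0.3
    expr_log2fc: float = 2.0
    noise_sd_beta: float = 0.05
    noise_sd_expr: float = 0.5
    ppi_n_nodes: int = 2000
    ppi_attach_m: int = 3
    n_hubs_planted: int = 4
    hub_ei_frac: float = 0.5
    censor_rate: float = 0.2
    hazard_ratio: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise _config_error("n_pairs", "need >= 2 matched pairs")
        if self.n_genes < 1:
            raise _config_error("n_genes", "need >= 1 gene")
        if self.n_ei_planted < 0 or self.n_es_planted < 0:
            raise _config_error("n_ei_planted/n_es_planted", "must be >= 0")
        if self.n_ei_planted + self.n_es_planted > self.n_genes:
            raise _config_error(
                "n_ei_planted", "n_ei_planted + n_es_planted exceeds n_genes"
            )
        dist = self.probes_per_promoter_dist
        if not dist or any(k < 1 or k > 10 for k in dist):
            raise _config_error(
                "probes_per_promoter_dist", "support must lie in {1..10}"
            )
        if any(v < 0 for v in dist.values()) or abs(sum(dist.values()) - 1.0) > 1e-9:
            raise _config_error("probes_per_promoter_dist", "probabilities must sum to 1")
        if abs(self.beta_shift) > 1:
            raise _config_error("beta_shift", "must lie in [-1, 1]")
        if self.noise_sd_beta < 0 or self.noise_sd_expr < 0:
            raise _config_error("noise_sd_beta/noise_sd_expr", "must be >= 0")
        if self.ppi_n_nodes < self.n_genes:
            raise _config_error("ppi_n_nodes", "must be >= n_genes")
        if self.ppi_attach_m < 1 or self.ppi_attach_m >= self.ppi_n_nodes:
            raise _config_error("ppi_attach_m", "need 1 <= m < ppi_n_nodes")
        if self.n_hubs_planted < 0:
            raise _config_error("n_hubs_planted", "must be >= 0")
        if not 0.0 <= self.hub_ei_frac <= 1.0:
            raise _config_error("hub_ei_frac", "must lie in [0, 1]")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise _config_error("censor_rate", "must lie in [0, 1]")
        if self.hazard_ratio <= 0:
            raise _config_error("hazard_ratio", "must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        if "probes_per_promoter_dist" in raw:
            raw["probes_per_promoter_dist"] = {
                int(k): float(v) for k, v in raw["probes_per_promoter_dist"].items()
            }
        return cls(**raw)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and modes for an end-to-end run (defaults as published)."""

    alpha_deg: float = 0.05
    lfc_min: float = 1.0
    alpha_dmp: float = 0.05
    alpha_corr: float = 0.05
    fdr_max: float = 0.05
    min_hits: int = 5
    na_frac_max: float = 0.70
    k_knn: int = 10
    upstream: int = 1500
    downstream: int = 500
    j_min: float = 0.5
    corr_method: str = "spearman"
    hub_label_set: str = "both"  # {"EI", "ES", "both"}
    hub_alternative: str = "greater"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in [
            ("alpha_deg", 0, 1),
            ("alpha_dmp", 0, 1),
            ("alpha_corr", 0, 1),
            ("fdr_max", 0, 1),
            ("na_frac_max", 0, 1),
            ("j_min", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"invalid PipelineConfig field {name!r}: must be in [{lo},{hi}]")
        if self.min_hits < 0 or self.k_knn < 1:
            raise ValueError("invalid PipelineConfig field 'min_hits'/'k_knn'")
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("invalid PipelineConfig field 'upstream'/'downstream'")
        if self.corr_method not in {"spearman", "pearson"}:
            raise ValueError(f"invalid PipelineConfig field 'corr_method': {self.corr_method!r}")
        if self.hub_label_set not in {"EI", "ES", "both"}:
            raise ValueError(f"invalid PipelineConfig field 'hub_label_set': {self.hub_label_set!r}")
        if self.hub_alternative not in {"greater", "two-sided"}:
            raise ValueError(
                f"invalid PipelineConfig field 'hub_alternative': {self.hub_alternative!r}"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown PipelineConfig fields: {sorted(unknown)}")
        return cls(**raw)
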