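"""Synthetic pipeline inputs with known ground truth.

Every downstream stage (tolerance screening, DEG/DAM filtering, network
recovery) can be exercised without external data: the generator plants a
latent tolerance gradient across accessions, per-group differential
features, and latent-factor-linked metabolite-gene pairs, and records the
truth for recovery checks. A single integer seed drives one explicit
generator object; identical configs give identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .tolerance import CONDITIONS, TRAITS

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_trait_trial",
    "simulate_feature_stats",
    "simulate_abundance_matrices",
]

_DEFAULT_TRAIT_MEANS = {"PHt": 25.0, "FW": 8.0, "DW": 1.2}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for all three generators; invalid fields raise ValueError
    naming the field."""

    n_accessions: int = 8
    replicates: int = 3
    trait_means: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TRAIT_MEANS)
    )
    tolerance_effect_range: tuple[float, float] = (0.1, 1.0)
    noise_sd: float = 0.05
    n_genes: int = 200
    n_metabolites: int = 50
    n_samples: int = 12
    de_fraction: float = 0.1
    effect_log2fc: float = 2.0
    r_target: float = 0.9
    seed: int = 0

    def __post_init__(self):
        for name in ("n_accessions", "replicates", "n_genes", "n_metabolites",
                     "n_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name}: must be >= 1, got {getattr(self, name)}")
        lo, hi = self.tolerance_effect_range
        if not (0 < lo <= hi <= 1):
            raise ValueError(
                f"tolerance_effect_range: must satisfy 0 < low <= high <= 1, "
                f"got {self.tolerance_effect_range}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd: must be >= 0, got {self.noise_sd}")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError(f"de_fraction: must be in [0, 1], got {self.de_fraction}")
        if not 0 < self.r_target <= 1:
            raise ValueError(f"r_target: must be in (0, 1], got {self.r_target}")
        if set(self.trait_means) != set(TRAITS):
            raise ValueError(
                f"trait_means: must provide exactly {TRAITS}, "
                f"got {sorted(self.trait_means)}"
            )
        if any(v <= 0 for v in self.trait_means.values()):
            raise ValueError("trait_means: all means must be > 0")


@dataclass
class GroundTruth:
    """Bookkeeping of what the generator planted."""

    tolerance_rank: list = field(default_factory=list)
    tolerance_factors: dict = field(default_factory=dict)
    true_de_features: dict = field(default_factory=dict)
    linked_pairs: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload["true_de_features"] = {
            k: sorted(v) for k, v in self.true_de_features.items()
        }
        payload["linked_pairs"] = [list(p) for p in self.linked_pairs]
        path.write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            tolerance_rank=payload.get("tolerance_rank", []),
            tolerance_factors=payload.get("tolerance_factors", {}),
            true_de_features={
                k: set(v) for k, v in payload.get("true_de_features", {}).items()
            },
            linked_pairs=[tuple(p) for p in payload.get("linked_pairs", [])],
        )


def _accession_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"A{i + 1:0{width}d}" for i in range(n)]


def simulate_trait_trial(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Trait screen with a planted tolerance gradient.

    Each accession gets a latent retained-fraction t drawn uniformly from
    ``tolerance_effect_range``; control replicate values are the trait means
    and salt replicate values their product with t, both under multiplicative
    log-normal noise of relative scale ``noise_sd`` (traits stay positive).
    The truth ranks accessions by t descending.
    """
    rng = np.random.default_rng(config.seed)
    ids = _accession_ids(config.n_accessions)
    lo, hi = config.tolerance_effect_range
    t = rng.uniform(lo, hi, config.n_accessions)

    rows = []
    for i, accession in enumerate(ids):
        for trait in TRAITS:
            base = config.trait_means[trait]
            for condition in CONDITIONS:
                expectation = base if condition == "control" else base * t[i]
                noise = (
                    np.exp(rng.normal(0.0, config.noise_sd, config.replicates))
                    if config.noise_sd > 0
                    else np.ones(config.replicates)
                )
                for rep, value in enumerate(expectation * noise, start=1):
                    rows.append((accession, trait, condition, rep, value))

    table = pd.DataFrame(
        rows, columns=["accession", "trait", "condition", "replicate", "value"]
    )
    order = sorted(range(len(ids)), key=lambda i: (-t[i], ids[i]))
    truth = GroundTruth(
        tolerance_rank=[ids[i] for i in order],
        tolerance_factors={ids[i]: float(t[i]) for i in range(len(ids))},
    )
    return table, truth


def simulate_feature_stats(
    config: SimulationConfig,
    group_labels: Sequence[str],
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-feature comparison statistics for one or more groups.

    A ``de_fraction`` of features per group is planted with
    |log2FC| = ``effect_log2fc`` (random sign, small additive jitter) and a
    near-zero adjusted p; null features get log2FC near 0 and uniform p.
    Metabolites carry VIP scores (> 1 when planted, < 1 otherwise); genes
    report VIP as NaN.
    """
    if not list(group_labels):
        raise ValueError("group_labels: at least one label required")
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    metab_ids = [f"M{i + 1:05d}" for i in range(config.n_metabolites)]

    frames = []
    true_de: dict[str, set] = {}
    for label in group_labels:
        planted_ids: set = set()
        for kind, ids in (("gene", gene_ids), ("metabolite", metab_ids)):
            n = len(ids)
            n_planted = int(round(config.de_fraction * n))
            planted = rng.choice(n, size=n_planted, replace=False)
            is_planted = np.zeros(n, dtype=bool)
            is_planted[planted] = True

            log2fc = rng.normal(0.0, 0.25, n)
            signs = rng.choice([-1.0, 1.0], size=n_planted)
            jitter = rng.normal(0.0, 0.05, n_planted)
            log2fc[planted] = signs * (config.effect_log2fc + jitter)

            adj_p = rng.uniform(0.0, 1.0, n)
            adj_p[planted] = rng.beta(0.5, 400.0, n_planted)

            vip = np.full(n, np.nan)
            if kind == "metabolite":
                vip = rng.uniform(0.1, 0.95, n)
                vip[planted] = rng.uniform(1.0, 2.5, n_planted)

            frames.append(
                pd.DataFrame(
                    {
                        "feature": ids,
                        "kind": kind,
                        "group": label,
                        "log2fc": log2fc,
                        "adj_p": adj_p,
                        "vip": vip,
                    }
                )
            )
            planted_ids |= {ids[i] for i in planted}
        true_de[label] = planted_ids

    stats = pd.concat(frames, ignore_index=True)
    return stats, GroundTruth(true_de_features=true_de)


def simulate_abundance_matrices(
    config: SimulationConfig,
    n_linked: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Metabolite and gene abundance matrices with planted correlated pairs.

    ``n_linked`` metabolite-gene pairs share a standard-normal latent factor
    so their population correlation is +/- ``r_target`` (exactly +/-1 when
    ``r_target == 1``); all other features are independent noise. Defaults
    to ``round(de_fraction * min(n_genes, n_metabolites))`` linked pairs.

    Returns ``(metabolite_matrix, gene_matrix, truth)`` where matrices are
    features x samples DataFrames sharing ordered sample columns.
    """
    if config.n_samples < 4:
        raise ValueError(
            f"n_samples: need >= 4 for meaningful correlations, got {config.n_samples}"
        )
    if n_linked is None:
        n_linked = int(round(config.de_fraction * min(config.n_genes,
                                                      config.n_metabolites)))
    if n_linked > min(config.n_genes, config.n_metabolites):
        raise ValueError(
            f"n_linked ({n_linked}) exceeds available features "
            f"({min(config.n_genes, config.n_metabolites)})"
        )
    rng = np.random.default_rng(config.seed)
    samples = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    metab_ids = [f"M{i + 1:05d}" for i in range(config.n_metabolites)]
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]

    metab = rng.normal(size=(config.n_metabolites, config.n_samples))
    genes = rng.normal(size=(config.n_genes, config.n_samples))

    r = config.r_target
    pairs = []
    for i in range(n_linked):
        z = rng.normal(size=config.n_samples)
        eps = rng.normal(size=config.n_samples)
        sign = float(rng.choice([-1.0, 1.0]))
        metab[i] = z
        genes[i] = sign * (r * z + np.sqrt(1.0 - r**2) * eps)
        pairs.append((metab_ids[i], gene_ids[i], "positive" if sign > 0 else "negative"))

    metab_df = pd.DataFrame(metab, index=metab_ids, columns=samples)
    gene_df = pd.DataFrame(genes, index=gene_ids, columns=samples)
    return metab_df, gene_df, GroundTruth(linked_pairs=pairs)
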