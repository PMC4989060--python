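"""Synthetic paired-condition expression data with planted structure.

The generator emulates the statistical structure the downstream
analysis assumes:

* blocks of co-regulated genes — each planted module shares one latent
  factor per condition, so two module genes with loading ``sqrt(rho)``
  have expected Pearson correlation ``rho``;
* condition-dependent differential expression — a configurable fraction
  of modules has its disease-condition mean shifted up or down on the
  log2 scale;
* planted biomarkers ("rewired" genes) whose loading on the module
  factor is negated (correlation sign flips) or zeroed (correlation
  vanishes) in the disease condition only;
* a functional-association network whose edges preferentially connect
  within-module genes, with STRING-like integer combined scores.

Everything is driven by one ``SimulationConfig`` and is reproducible
bit-for-bit from its seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, FunctionalNetwork, GeneSetCollection, gene_pair
from .errors import ConfigurationError

BACKGROUND = "background"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a small two-cohort microarray-like study: 300
    genes, 8 planted modules of 8-15 genes, 200 samples per condition,
    within-module correlation 0.7, three of eight modules shifted by
    3 log2 units in the disease condition, and 2 rewired (planted
    biomarker) genes per differential module.
    """

    n_genes: int = 300
    n_modules: int = 8
    module_size_range: tuple[int, int] = (8, 15)
    n_samples_normal: int = 200
    n_samples_cancer: int = 200
    within_module_correlation: float = 0.7
    de_module_fraction: float = 0.375
    de_log2_shift: float = 3.0
    n_rewired_genes_per_de_module: int = 2
    background_edge_probability: float = 0.005
    in_module_edge_probability: float = 0.9
    score_range_in_module: tuple[int, int] = (601, 1000)
    score_range_background: tuple[int, int] = (50, 700)
    noise_sd: float = 1.0
    baseline_log2_mean: float = 8.0
    rewire_mode: str = "flip"  # "flip" (sign reversal) or "zero" (correlation vanishes)
    seed: int = 0

    def validate(self) -> None:
        def bad(name: str, why: str) -> ConfigurationError:
            return ConfigurationError(f"{name}: {why}")

        if self.n_genes < 1:
            raise bad("n_genes", "must be a positive integer")
        if self.n_modules < 0:
            raise bad("n_modules", "must be >= 0")
        lo, hi = self.module_size_range
        if not (1 <= lo <= hi):
            raise bad("module_size_range", f"invalid interval ({lo}, {hi})")
        if self.n_modules * hi > self.n_genes:
            raise bad(
                "module_size_range",
                f"{self.n_modules} modules of up to {hi} genes cannot fit in "
                f"{self.n_genes} genes",
            )
        if self.n_samples_normal < 3 or self.n_samples_cancer < 3:
            raise bad("n_samples_normal/n_samples_cancer", "need >= 3 samples per condition")
        if not 0.0 < self.within_module_correlation < 1.0:
            raise bad("within_module_correlation", "must lie in (0, 1)")
        if not 0.0 <= self.de_module_fraction <= 1.0:
            raise bad("de_module_fraction", "must lie in [0, 1]")
        if self.de_log2_shift < 0:
            raise bad("de_log2_shift", "must be >= 0")
        if self.n_rewired_genes_per_de_module < 0:
            raise bad("n_rewired_genes_per_de_module", "must be >= 0")
        if self.n_rewired_genes_per_de_module > lo:
            raise bad(
                "n_rewired_genes_per_de_module",
                "cannot exceed the smallest possible module size",
            )
        for name in ("background_edge_probability", "in_module_edge_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise bad(name, "must lie in [0, 1]")
        for name in ("score_range_in_module", "score_range_background"):
            a, b = getattr(self, name)
            if not (0 <= a <= b <= 1000):
                raise bad(name, f"invalid score interval ({a}, {b})")
        if self.noise_sd <= 0:
            raise bad("noise_sd", "must be > 0")
        if self.rewire_mode not in ("flip", "zero"):
            raise bad("rewire_mode", "must be 'flip' or 'zero'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = dict(d)
        for k in ("module_size_range", "score_range_in_module", "score_range_background"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """What was planted: module membership, shifted modules, rewired genes."""

    module_membership: dict[str, str]  # gene -> module id or "background"
    de_modules: dict[str, str]  # module id -> "up" | "down"
    rewired_genes: set[str]

    @property
    def module_ids(self) -> list[str]:
        ids = {m for m in self.module_membership.values() if m != BACKGROUND}
        return sorted(ids)

    def genes_of(self, module_id: str) -> list[str]:
        return sorted(
            g for g, m in self.module_membership.items() if m == module_id
        )

    @property
    def genes(self) -> list[str]:
        return sorted(self.module_membership)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_membership": self.module_membership,
            "de_modules": self.de_modules,
            "rewired_genes": sorted(self.rewired_genes),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            module_membership=payload["module_membership"],
            de_modules=payload["de_modules"],
            rewired_genes=set(payload["rewired_genes"]),
        )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Generate paired normal/cancer expression matrices plus ground truth.

    Module gene ``g`` in condition ``c`` is modelled on the log2 scale as

    ``x_gs = baseline_g + shift_gc + noise_sd * (l_gc * f_cs + sqrt(1 - rho) * e_gs)``

    with module factor ``f_cs ~ N(0,1)`` per sample, loading
    ``l_gc = +-sqrt(rho)`` (negated, or zeroed with compensating noise,
    for rewired genes in the cancer condition) and independent noise
    ``e_gs ~ N(0,1)``, so the expected within-module Pearson correlation
    is ``rho = within_module_correlation``. Background genes are pure
    independent noise around their baseline.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    genes = _gene_ids(config.n_genes)
    rho = config.within_module_correlation
    load = np.sqrt(rho)
    resid = np.sqrt(1.0 - rho)

    # plant modules over a leading block of genes (ids are arbitrary labels)
    sizes = rng.integers(
        config.module_size_range[0], config.module_size_range[1] + 1, config.n_modules
    )
    membership: dict[str, str] = {g: BACKGROUND for g in genes}
    module_genes: dict[str, list[str]] = {}
    cursor = 0
    for i, size in enumerate(sizes, start=1):
        mid = f"P{i}"
        module_genes[mid] = genes[cursor : cursor + int(size)]
        for g in module_genes[mid]:
            membership[g] = mid
        cursor += int(size)

    # differential modules and their directions
    n_de = int(round(config.de_module_fraction * config.n_modules))
    de_ids = [f"P{i + 1}" for i in sorted(rng.choice(config.n_modules, n_de, replace=False))] if n_de else []
    de_modules = {
        mid: ("up" if rng.random() < 0.5 else "down") for mid in de_ids
    }

    # rewired genes live inside differential modules
    rewired: set[str] = set()
    for mid in de_ids:
        members = module_genes[mid]
        k = min(config.n_rewired_genes_per_de_module, len(members))
        picked = rng.choice(len(members), k, replace=False)
        rewired |= {members[j] for j in sorted(picked)}

    baseline = rng.normal(config.baseline_log2_mean, 0.5, config.n_genes)

    def build(n_samples: int, condition: str) -> np.ndarray:
        values = np.empty((config.n_genes, n_samples))
        noise = rng.normal(0.0, 1.0, size=(config.n_genes, n_samples))
        factors = {mid: rng.normal(0.0, 1.0, n_samples) for mid in module_genes}
        for gi, g in enumerate(genes):
            mid = membership[g]
            if mid == BACKGROUND:
                signal = noise[gi]
            else:
                loading = load
                extra = 0.0
                if condition == "cancer" and g in rewired:
                    if config.rewire_mode == "flip":
                        loading = -load
                    else:  # zero the loading, keep unit variance
                        loading = 0.0
                        extra = load * rng.normal(0.0, 1.0, n_samples)
                signal = loading * factors[mid] + resid * noise[gi] + extra
            shift = 0.0
            if condition == "cancer" and mid in de_modules:
                shift = config.de_log2_shift * (1.0 if de_modules[mid] == "up" else -1.0)
            values[gi] = baseline[gi] + shift + config.noise_sd * signal
        return values

    normal_values = build(config.n_samples_normal, "normal")
    cancer_values = build(config.n_samples_cancer, "cancer")

    normal = ExpressionMatrix(
        pd.DataFrame(
            normal_values,
            index=genes,
            columns=[f"N{j:04d}" for j in range(1, config.n_samples_normal + 1)],
        ),
        condition="normal",
    )
    cancer = ExpressionMatrix(
        pd.DataFrame(
            cancer_values,
            index=genes,
            columns=[f"C{j:04d}" for j in range(1, config.n_samples_cancer + 1)],
        ),
        condition="cancer",
    )
    truth = GroundTruth(
        module_membership=membership, de_modules=de_modules, rewired_genes=rewired
    )
    return normal, cancer, truth


def simulate_functional_network(
    truth: GroundTruth, config: SimulationConfig
) -> FunctionalNetwork:
    """STRING-dialect functional network matching the planted modules.

    Within-module pairs receive an edge with ``in_module_edge_probability``
    and a combined score uniform over ``score_range_in_module``; all
    other pairs with ``background_edge_probability`` and
    ``score_range_background``. No self-edges, no duplicate pairs.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    genes = truth.genes
    index = {g: i for i, g in enumerate(genes)}
    same_module = np.zeros(len(genes), dtype=int)
    for mi, mid in enumerate(truth.module_ids, start=1):
        for g in truth.genes_of(mid):
            same_module[index[g]] = mi

    iu, ju = np.triu_indices(len(genes), k=1)
    within = (same_module[iu] == same_module[ju]) & (same_module[iu] > 0)
    p = np.where(within, config.in_module_edge_probability, config.background_edge_probability)
    keep = rng.random(iu.size) < p
    lo_in, hi_in = config.score_range_in_module
    lo_bg, hi_bg = config.score_range_background
    scores_in = rng.integers(lo_in, hi_in + 1, iu.size)
    scores_bg = rng.integers(lo_bg, hi_bg + 1, iu.size)
    scores = np.where(within, scores_in, scores_bg)

    edges: dict[tuple[str, str], int] = {}
    for k in np.nonzero(keep)[0]:
        pair = gene_pair(genes[iu[k]], genes[ju[k]])
        edges[pair] = int(scores[k])
    return FunctionalNetwork(edges)


def simulate_gene_sets(
    truth: GroundTruth, n_extra_sets: int = 0, seed: int = 0
) -> GeneSetCollection:
    """One gene set per planted module (exact membership) plus random decoys."""
    rng = np.random.default_rng([seed, 2])
    genes = truth.genes
    sets: dict[str, set[str]] = {}
    for mid in truth.module_ids:
        sets[f"SET_{mid}"] = set(truth.genes_of(mid))
    for i in range(1, n_extra_sets + 1):
        size = int(rng.integers(5, 21))
        members = rng.choice(len(genes), min(size, len(genes)), replace=False)
        sets[f"RANDOM_{i:03d}"] = {genes[j] for j in members}
    return GeneSetCollection(sets=sets, universe=set(genes))


def simulate_to_dir(config: SimulationConfig, outdir: str | Path, n_extra_sets: int = 5) -> dict[str, Path]:
    """Write a complete synthetic fixture (expression, network, GMT, truth).

    Byte-identical output for identical config; returns the file map.
    """
    from . import io  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    normal, cancer, truth = simulate_expression(config)
    network = simulate_functional_network(truth, config)
    sets = simulate_gene_sets(truth, n_extra_sets=n_extra_sets, seed=config.seed)

    paths = {
        "normal": outdir / "expression_normal.tsv",
        "cancer": outdir / "expression_cancer.tsv",
        "network": outdir / "functional_network.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "truth": outdir / "ground_truth.json",
        "config": outdir / "simulation_config.json",
    }
    io.write_expression(normal, paths["normal"])
    io.write_expression(cancer, paths["cancer"])
    io.write_string_network(network, paths["network"])
    io.write_gmt(sets, paths["gene_sets"])
    truth.to_json(paths["truth"])
    paths["config"].write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return paths
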