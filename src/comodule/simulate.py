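"""Synthetic expression datasets with planted co-expression modules.

The generator emulates a two-group microarray study of liver fibrosis
severity: ``n0`` mild and ``n1`` advanced samples, a handful of planted
modules whose latent eigengenes carry known correlation with the binary
trait, a hub-to-periphery loading gradient within each module, unstructured
background genes, and an optional set of mean-shifted (differentially
expressed) genes.

Generative model, per sample ``s``:

* trait z-score ``t_s`` = standardised group code (0/1 centred and scaled);
* module ``m`` eigengene ``e_ms = rho_m * t_s + sqrt(1 - rho_m^2) * eta_s``
  with ``eta_s ~ N(0, 1)``, so ``cor(e_m, t) -> rho_m``;
* gene ``i`` of module ``m``:
  ``x_is = baseline + noise_sd * (a_i * e_ms + sqrt(1 - a_i^2) * eps_is)``
  with loading ``a_i`` uniform on ``loading_range`` and
  ``eps ~ N(0, 1)``, hence expected within-module Pearson correlation
  ``a_i * a_j`` and expected gene-trait correlation ``a_i * rho_m``;
* background genes are pure noise around the baseline;
* DEG genes additionally gain ``deg_effect`` log2 units in group 1.

Each module draws from its own RNG sub-stream so datasets are reproducible
gene-block by gene-block regardless of how many other blocks exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .palette import MODULE_PALETTE

BASELINE = 8.0  # log2-intensity baseline added to every gene


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-module generative model.

    Defaults mirror the design the pipeline targets: 40 mild vs 32
    advanced samples, seven planted modules spanning 40-600 genes among
    roughly three thousand genes, eigengene-trait correlations from 0 to
    0.7, and a broad hub-to-periphery loading gradient.
    """

    n_samples_group0: int = 40
    n_samples_group1: int = 32
    module_sizes: tuple[int, ...] = (600, 400, 250, 150, 100, 60, 40)
    module_trait_cor: tuple[float, ...] = (0.2, 0.5, -0.3, 0.6, 0.7, 0.0, 0.4)
    loading_range: tuple[float, float] = (0.4, 0.95)
    n_background: int = 1400
    n_deg: int = 150
    deg_effect: float = 1.0
    noise_sd: float = 1.0
    deg_in_modules: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.module_trait_cor) != len(self.module_sizes):
            raise ValueError("module_trait_cor and module_sizes must have equal length")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if any(abs(r) > 1 for r in self.module_trait_cor):
            raise ValueError("module_trait_cor entries must lie in [-1, 1]")
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("loading_range must satisfy 0 < lower <= upper <= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        pool = self.n_background if not self.deg_in_modules else self.n_total_genes
        if self.n_deg > pool:
            raise ValueError(
                f"n_deg={self.n_deg} exceeds the available gene pool ({pool})"
            )

    @property
    def n_samples(self) -> int:
        return self.n_samples_group0 + self.n_samples_group1

    @property
    def n_total_genes(self) -> int:
        return sum(self.module_sizes) + self.n_background

    @property
    def module_labels(self) -> tuple[str, ...]:
        return tuple(MODULE_PALETTE[i] for i in range(len(self.module_sizes)))


@dataclass
class SyntheticDataset:
    """A generated dataset plus its ground truth."""

    expr: pd.DataFrame  # genes x samples, log2 scale
    trait: pd.Series  # 0/1 per sample
    truth: pd.Series  # gene -> planted module label ("grey" = background)
    deg_truth: frozenset[str] = field(default_factory=frozenset)
    eigengene_truth: pd.DataFrame | None = None  # module x sample

    @property
    def module_labels(self) -> list[str]:
        return [m for m in self.truth.unique() if m != "grey"]


def _standardized_trait(n0: int, n1: int) -> np.ndarray:
    code = np.concatenate([np.zeros(n0), np.ones(n1)])
    return (code - code.mean()) / code.std(ddof=1)


def _module_block(
    rng: np.random.Generator,
    size: int,
    rho: float,
    t: np.ndarray,
    loading_range: tuple[float, float],
    noise_sd: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (expression block, loadings, eigengene) for one module."""
    n = t.size
    eta = rng.standard_normal(n)
    e = rho * t + np.sqrt(1.0 - rho * rho) * eta
    a = rng.uniform(*loading_range, size=size)
    eps = rng.standard_normal((size, n))
    block = noise_sd * (a[:, None] * e[None, :] + np.sqrt(1.0 - a * a)[:, None] * eps)
    return BASELINE + block, a, e


def generate_dataset(
    config: SyntheticConfig,
    *,
    _loadings: Sequence[np.ndarray] | None = None,
    _scramble: frozenset[str] = frozenset(),
    _stream_offset: int = 0,
) -> SyntheticDataset:
    """Draw one dataset from the planted-module model.

    Same config (same seed) gives bit-identical output.  The private
    keyword arguments are used by :func:`generate_preserved_pair` to share
    per-gene loadings across the pair and to regenerate selected modules
    as structure-free noise.
    """
    labels = config.module_labels
    unknown = _scramble - set(labels)
    if unknown:
        raise ValueError(f"unknown module label(s): {sorted(unknown)}")

    ss = np.random.SeedSequence(config.seed)
    # one child stream per module, one for background, one for noise draws
    # of the paired dataset (offset shifts into a disjoint range)
    children = ss.spawn(2 * (len(labels) + 2))
    t = _standardized_trait(config.n_samples_group0, config.n_samples_group1)
    n = config.n_samples

    blocks: list[np.ndarray] = []
    gene_ids: list[str] = []
    truth: list[str] = []
    eigengenes = np.empty((len(labels), n))

    for m, (label, size, rho) in enumerate(
        zip(labels, config.module_sizes, config.module_trait_cor)
    ):
        rng = np.random.default_rng(children[2 * m + _stream_offset])
        if label in _scramble:
            # structure-free replacement: independent noise, no eigengene
            block = BASELINE + config.noise_sd * rng.standard_normal((size, n))
            eigengenes[m] = np.nan
        elif _loadings is not None:
            n_samp = t.size
            eta = rng.standard_normal(n_samp)
            e = rho * t + np.sqrt(1.0 - rho * rho) * eta
            a = np.asarray(_loadings[m])
            eps = rng.standard_normal((size, n_samp))
            block = BASELINE + config.noise_sd * (
                a[:, None] * e[None, :] + np.sqrt(1.0 - a * a)[:, None] * eps
            )
            eigengenes[m] = e
        else:
            block, _, e = _module_block(
                rng, size, rho, t, config.loading_range, config.noise_sd
            )
            eigengenes[m] = e
        blocks.append(block)
        gene_ids.extend(f"{label}_{i:04d}" for i in range(size))
        truth.extend([label] * size)

    bg_rng = np.random.default_rng(children[2 * len(labels) + _stream_offset])
    bg = BASELINE + config.noise_sd * bg_rng.standard_normal((config.n_background, n))
    blocks.append(bg)
    gene_ids.extend(f"bg_{i:05d}" for i in range(config.n_background))
    truth.extend(["grey"] * config.n_background)

    values = np.vstack(blocks)
    sample_ids = [f"S{j:03d}" for j in range(n)]
    expr = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    trait = pd.Series(
        np.concatenate(
            [
                np.zeros(config.n_samples_group0, dtype=int),
                np.ones(config.n_samples_group1, dtype=int),
            ]
        ),
        index=sample_ids,
        name="code",
    )

    # mean-shifted genes: by default the first n_deg background genes,
    # optionally spread across the whole matrix
    deg_rng = np.random.default_rng(children[2 * len(labels) + 2 + _stream_offset])
    if config.deg_in_modules:
        deg_idx = deg_rng.choice(len(gene_ids), size=config.n_deg, replace=False)
        deg_genes = [gene_ids[i] for i in sorted(deg_idx)]
    else:
        bg_ids = [g for g, lab in zip(gene_ids, truth) if lab == "grey"]
        deg_genes = bg_ids[: config.n_deg]
    mask = trait.to_numpy() == 1
    expr.loc[deg_genes, expr.columns[mask]] += config.deg_effect

    return SyntheticDataset(
        expr=expr,
        trait=trait,
        truth=pd.Series(truth, index=gene_ids, name="module"),
        deg_truth=frozenset(deg_genes),
        eigengene_truth=pd.DataFrame(eigengenes, index=list(labels), columns=sample_ids),
    )


def generate_preserved_pair(
    config: SyntheticConfig, scramble_modules: Sequence[str] = ()
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Draw a reference/test pair from the same generative parameters.

    Per-gene loadings are shared between the two datasets (the hub
    structure replicates); the noise is independent.  In the test dataset
    every module named in ``scramble_modules`` is regenerated as
    independent noise — ground truth "not preserved".
    """
    scramble = frozenset(scramble_modules)
    unknown = scramble - set(config.module_labels)
    if unknown:
        raise ValueError(f"unknown module label(s): {sorted(unknown)}")

    # draw loadings once, from a stream independent of the noise streams
    load_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x10ad)))
    loadings = [
        load_rng.uniform(*config.loading_range, size=s) for s in config.module_sizes
    ]
    ref = generate_dataset(config, _loadings=loadings, _stream_offset=0)
    test = generate_dataset(
        config, _loadings=loadings, _scramble=scramble, _stream_offset=1
    )
    return ref, test


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write expression, trait and truth tables as TSV; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "trait": out / "trait.tsv",
        "truth": out / "truth_modules.tsv",
    }
    dataset.expr.to_csv(paths["expression"], sep="\t", index_label="gene")
    dataset.trait.rename_axis("sample").to_csv(paths["trait"], sep="\t")
    dataset.truth.rename_axis("gene").to_csv(paths["truth"], sep="\t")
    return paths


def config_from_dict(d: dict) -> SyntheticConfig:
    """Build a config from a plain dict (e.g. parsed YAML), listy fields coerced."""
    kwargs = dict(d)
    for key in ("module_sizes", "module_trait_cor", "loading_range"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return SyntheticConfig(**kwargs)
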