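"""Seeded synthetic-data generators for the whole pipeline.

Three generators emulate the study design end to end:

* :func:`simulate_expression_study` — a two-condition (WT vs KO)
  microarray-like study on the log2 scale, 3 samples per condition by
  default (each standing for a pool of biological replicates), with a
  planted set of over/under-expressed genes. Noise is additive Gaussian
  on the log2 scale, the standard variance-stabilised approximation for
  intensity arrays, so every planted log2 difference has a closed-form
  expectation.
* :func:`simulate_signature_collection` — a collection of microglial
  population signatures (neurodevelopment-like vs disease/ageing-like
  blocks by default) with exact planted cosine structure: block base
  directions and per-population perturbations are drawn from an
  orthonormal basis, and the mixing weights are solved from the target
  within/between-block cosines, so the pre-noise population cosines hit
  the targets exactly.
* :func:`simulate_qpcr_plate` — a Ct plate (gene x animal x technical
  replicate x group) where a planted linear fold ``f`` maps to
  ``ddCt = -log2(f)`` in expectation; a per-animal offset shared across
  genes mimics RNA-input variation and cancels in dCt.

All generators draw from named substreams of a single seed, so adding a
component never perturbs another's draws.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .diffexpr import ExpressionMatrix
from .signatures import SignatureSet

#: Microarray-style planted folds for the study's marker genes (KO vs WT).
DEFAULT_ARRAY_FOLDS: dict[str, float] = {
    "Spp1": 600.0,
    "Gpnmb": 90.0,
    "Itgax": 70.0,
    "Atp6v0d2": 30.0,
    "Cd68": 25.0,
    "Igf1": 12.0,
    "Lgals3": 8.0,
    "ApoE": 4.0,
    "Trem2": 3.0,
}

#: qPCR-style planted folds (KO vs WT); Rn18s is the reference gene.
DEFAULT_QPCR_FOLDS: dict[str, float] = {
    "Spp1": 535.0,
    "Gpnmb": 300.0,
    "Itgax": 200.0,
    "Igf1": 12.0,
    "Cd68": 8.0,
    "Lgals3": 6.0,
    "ApoE": 3.0,
    "Trem2": 2.5,
    "Rn18s": 1.0,
}

#: Default population roster: neurodevelopment-linked vs disease/ageing-linked.
DEFAULT_SIGNATURE_BLOCKS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("neurodevelopment", ("AQP4-CC", "AQP4-AC", "CD11c", "PAM", "ATM")),
    ("disease_ageing", ("DAM1", "DAM2", "MGnD", "LDAM", "APP", "Aged")),
)


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class StudySimConfig:
    """Two-condition expression study with planted fold changes."""

    n_genes: int
    n_samples_per_condition: int = 3
    planted_up: Mapping[str, float] = field(default_factory=dict)
    planted_down: Mapping[str, float] = field(default_factory=dict)
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    noise_sd_log2: float = 0.25
    reference_label: str = "WT"
    test_label: str = "KO"
    seed: int = 0

    def __post_init__(self) -> None:
        _check_positive("n_genes", self.n_genes)
        if self.n_samples_per_condition < 2:
            raise ValueError("need at least 2 samples per condition")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        for name, fold in self.planted_up.items():
            if not fold > 1:
                raise ValueError(f"planted_up fold for {name!r} must be > 1, got {fold}")
        for name, fold in self.planted_down.items():
            if not 0 < fold < 1:
                raise ValueError(f"planted_down fold for {name!r} must be in (0, 1), got {fold}")
        planted = list(self.planted_up) + list(self.planted_down)
        if len(set(planted)) != len(planted):
            raise ValueError("planted gene roles must be unique across up/down")
        if len(planted) > self.n_genes:
            raise ValueError(f"{len(planted)} planted genes exceed n_genes={self.n_genes}")


def simulate_expression_study(cfg: StudySimConfig) -> ExpressionMatrix:
    """Simulate the study; planted genes have E[log2 KO - log2 WT] = log2(fold)."""
    rng = substream(cfg.seed, "expression-study")
    planted = {**cfg.planted_up, **cfg.planted_down}
    filler = [f"Gene{i:05d}" for i in range(cfg.n_genes - len(planted))]
    genes = list(planted) + filler
    effect = np.zeros(cfg.n_genes)
    effect[: len(planted)] = np.log2(list(planted.values()))

    m = cfg.n_samples_per_condition
    samples = [f"{cfg.reference_label}_{i + 1}" for i in range(m)] + [
        f"{cfg.test_label}_{i + 1}" for i in range(m)
    ]
    is_test = np.array([0.0] * m + [1.0] * m)
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
    values = (
        baseline[:, None]
        + effect[:, None] * is_test[None, :]
        + rng.normal(0.0, cfg.noise_sd_log2, (cfg.n_genes, 2 * m))
        if cfg.noise_sd_log2 > 0
        else baseline[:, None] + effect[:, None] * is_test[None, :] + np.zeros((cfg.n_genes, 2 * m))
    )
    frame = pd.DataFrame(values, index=genes, columns=samples)
    condition = {s: (cfg.test_label if is_test[i] else cfg.reference_label) for i, s in enumerate(samples)}
    return ExpressionMatrix(values=frame, condition=condition)


@dataclass(frozen=True)
class SignatureSimConfig:
    """Block-correlated population signature collection."""

    n_genes: int = 500
    blocks: Sequence[tuple[str, Sequence[str]]] = DEFAULT_SIGNATURE_BLOCKS
    within_block_cosine: float = 0.9
    between_block_cosine: float = 0.2
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        _check_positive("n_genes", self.n_genes)
        if not 0 < self.within_block_cosine <= 1:
            raise ValueError("within_block_cosine must be in (0, 1]")
        if not 0 <= self.between_block_cosine < 1:
            raise ValueError("between_block_cosine must be in [0, 1)")
        if self.within_block_cosine <= self.between_block_cosine:
            raise ValueError("within_block_cosine must exceed between_block_cosine")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        pops = [p for _, members in self.blocks for p in members]
        if len(set(pops)) != len(pops):
            raise ValueError("population names must be unique across blocks")
        if not pops:
            raise ValueError("blocks must contain at least one population")
        need = 1 + len(list(self.blocks)) + len(pops)
        if self.n_genes < need:
            raise ValueError(f"n_genes={self.n_genes} too small for exact cosine "
                             f"construction; need >= {need}")

    @property
    def block_of(self) -> dict[str, str]:
        return {p: name for name, members in self.blocks for p in members}


def simulate_signature_collection(cfg: SignatureSimConfig) -> SignatureSet:
    """Simulate signatures with planted within/between-block cosine structure.

    Unit population vectors are ``v_p = b*u_block + sqrt(1-b^2)*e_p`` with
    ``b^2 = within_block_cosine`` and block directions ``u`` mixed from a
    shared direction so that ``u.u' = between/within``, which puts the
    population-level between-block cosine exactly at the target before
    noise. Gaussian noise of total expected magnitude ``noise_sd``
    (relative to the unit signal) is then added entrywise.
    """
    rng = substream(cfg.seed, "signature-collection")
    block_names = [name for name, _ in cfg.blocks]
    pops = [p for _, members in cfg.blocks for p in members]
    n_basis = 1 + len(block_names) + len(pops)
    raw = rng.normal(size=(cfg.n_genes, n_basis))
    q, _ = np.linalg.qr(raw)
    shared = q[:, 0]
    block_noise = q[:, 1 : 1 + len(block_names)]
    pop_noise = q[:, 1 + len(block_names) :]

    alpha2 = cfg.between_block_cosine / cfg.within_block_cosine
    u = {
        name: np.sqrt(alpha2) * shared + np.sqrt(1 - alpha2) * block_noise[:, b]
        for b, name in enumerate(block_names)
    }
    beta = np.sqrt(cfg.within_block_cosine)
    rows = []
    block_of = cfg.block_of
    for p_idx, pop in enumerate(pops):
        v = beta * u[block_of[pop]] + np.sqrt(1 - beta**2) * pop_noise[:, p_idx]
        if cfg.noise_sd > 0:
            v = v + rng.normal(0.0, cfg.noise_sd / np.sqrt(cfg.n_genes), cfg.n_genes)
        rows.append(v)
    genes = [f"Gene{i:05d}" for i in range(cfg.n_genes)]
    return SignatureSet(values=pd.DataFrame(rows, index=pops, columns=genes))


@dataclass(frozen=True)
class QpcrSimConfig:
    """qPCR Ct plate with planted KO-vs-WT fold changes."""

    true_fold_changes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_QPCR_FOLDS)
    )
    reference_gene: str = "Rn18s"
    n_animals_per_group: int = 6
    n_technical_replicates: int = 3
    ct_noise_sd: float = 0.3
    animal_offset_sd: float = 0.15
    reference_base_ct: float = 12.0
    target_base_ct: float = 25.0
    calibrator_group: str = "WT"
    test_group: str = "KO"
    seed: int = 0

    def __post_init__(self) -> None:
        _check_positive("n_animals_per_group", self.n_animals_per_group)
        _check_positive("n_technical_replicates", self.n_technical_replicates)
        if self.ct_noise_sd < 0 or self.animal_offset_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.reference_gene not in self.true_fold_changes:
            raise ValueError(f"reference gene {self.reference_gene!r} must appear in true_fold_changes")
        if self.true_fold_changes[self.reference_gene] != 1:
            raise ValueError("reference gene must have fold change 1")
        for gene, fold in self.true_fold_changes.items():
            if not fold > 0:
                raise ValueError(f"fold for {gene!r} must be > 0, got {fold}")


def simulate_qpcr_plate(cfg: QpcrSimConfig) -> pd.DataFrame:
    """Simulate a CtTable (columns gene, group, animal, replicate, ct)."""
    rng = substream(cfg.seed, "qpcr-plate")
    records = []
    for group in (cfg.calibrator_group, cfg.test_group):
        for a in range(cfg.n_animals_per_group):
            animal = f"{group}{a + 1}"
            offset = rng.normal(0.0, cfg.animal_offset_sd) if cfg.animal_offset_sd > 0 else 0.0
            for gene, fold in cfg.true_fold_changes.items():
                base = cfg.reference_base_ct if gene == cfg.reference_gene else cfg.target_base_ct
                mean_ct = base + offset
                if group == cfg.test_group:
                    mean_ct -= np.log2(fold)
                for rep in range(cfg.n_technical_replicates):
                    noise = rng.normal(0.0, cfg.ct_noise_sd) if cfg.ct_noise_sd > 0 else 0.0
                    records.append((gene, group, animal, rep + 1, mean_ct + noise))
    table = pd.DataFrame(records, columns=["gene", "group", "animal", "replicate", "ct"])
    bad = table[(table["ct"] <= 0) | (table["ct"] >= 40)]
    if len(bad):
        raise ValueError(
            f"{len(bad)} simulated Ct value(s) fall outside (0, 40); "
            "adjust base Ct, folds or noise"
        )
    return table


def make_gene_sets(
    planted_genes: Sequence[str],
    universe: Sequence[str],
    n_random_sets: int = 10,
    random_set_size: int = 50,
    seed: int = 0,
) -> list:
    """A planted 'microglial activation' set plus size-matched random sets."""
    from .enrichment import GeneSet

    rng = substream(seed, "gene-sets")
    sets = [GeneSet(name="MICROGLIAL_ACTIVATION", genes=frozenset(planted_genes))]
    pool = np.array(list(universe))
    for i in range(n_random_sets):
        pick = rng.choice(pool, size=min(random_set_size, len(pool)), replace=False)
        sets.append(GeneSet(name=f"RANDOM_SET_{i + 1:02d}", genes=frozenset(pick.tolist())))
    return sets
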