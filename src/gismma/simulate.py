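"""Seeded synthetic inputs with the structure the predictor assumes.

The generator plants a shared community structure: small molecules and
miRNAs are each partitioned into the same number of blocks, pairwise
similarity is high within a block and low between blocks (plus truncated
Gaussian noise, clipped back into [0, 1]), and known associations are
drawn preferentially between a small molecule and a miRNA whose blocks
match.  Links therefore correlate with *both* similarity networks, so each
side of the model carries recoverable signal; a decoupling switch breaks
the correlation on one side to probe one-sided prediction.  A configurable
fraction of entities is kept association-free, emulating datasets that mix
annotated entities with completely new ones.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources

import numpy as np

from .errors import ValidationError
from .model import AssociationMatrix, ScoreMatrix
from .similarity import SimilarityMatrix


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the block-structured generator.

    Defaults describe the standard simulation used throughout the test
    suite: 30 small molecules and 60 miRNAs in 3 matched blocks, strong
    block contrast in both similarity networks (0.8 within vs 0.2 between,
    noise sd 0.1), and 90 associations of which ~90% fall within matched
    blocks.
    """

    n_sm: int = 30
    n_mirna: int = 60
    n_blocks: int = 3
    within_block_similarity: float = 0.8
    between_block_similarity: float = 0.2
    similarity_noise_sd: float = 0.1
    n_associations: int = 90
    within_block_association_prob: float = 0.9
    fraction_new_sm: float = 0.0
    fraction_new_mirna: float = 0.0
    #: None, "sm" or "mirna": the named side's blocks are scrambled before
    #: placing associations, decoupling that network from the labels.
    decouple_side: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_sm < 1 or self.n_mirna < 1 or self.n_blocks < 1:
            raise ValidationError("entity and block counts must be positive")
        if not (0 <= self.between_block_similarity <= 1
                and 0 <= self.within_block_similarity <= 1):
            raise ValidationError("block similarities must lie in [0, 1]")
        if self.within_block_similarity <= self.between_block_similarity:
            raise ValidationError(
                "within-block similarity must exceed between-block similarity"
            )
        if self.similarity_noise_sd < 0:
            raise ValidationError("noise sd must be non-negative")
        if not 0 <= self.within_block_association_prob <= 1:
            raise ValidationError("association probability must lie in [0, 1]")
        if not (0 <= self.fraction_new_sm < 1 and 0 <= self.fraction_new_mirna < 1):
            raise ValidationError("new-entity fractions must lie in [0, 1)")
        if self.decouple_side not in (None, "sm", "mirna"):
            raise ValidationError("decouple_side must be None, 'sm' or 'mirna'")
        if self.n_associations > self.n_sm * self.n_mirna:
            raise ValidationError("more associations requested than pairs exist")


def _blocks(n: int, n_blocks: int) -> np.ndarray:
    """Contiguous near-equal block assignment."""
    return np.repeat(np.arange(n_blocks), np.diff(np.linspace(0, n, n_blocks + 1).astype(int)))


def _block_similarity(
    blocks: np.ndarray, cfg: GeneratorConfig, rng: np.random.Generator, ids
) -> SimilarityMatrix:
    n = len(blocks)
    base = np.where(
        blocks[:, None] == blocks[None, :],
        cfg.within_block_similarity,
        cfg.between_block_similarity,
    ).astype(float)
    if cfg.similarity_noise_sd > 0:
        noise = rng.normal(0.0, cfg.similarity_noise_sd, size=(n, n))
        noise = np.triu(noise, k=1)
        base = base + noise + noise.T
    base = np.clip(base, 0.0, 1.0)
    np.fill_diagonal(base, 1.0)
    return SimilarityMatrix(ids, base)


def generate(config: GeneratorConfig | None = None):
    """Draw one synthetic dataset.

    Returns ``(sm_similarity, mirna_similarity, associations, truth)``
    where ``truth`` records the block assignments and the index lists of
    association-free ("new") entities.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sm_ids = tuple(f"sm{i:03d}" for i in range(cfg.n_sm))
    mirna_ids = tuple(f"mir{j:03d}" for j in range(cfg.n_mirna))
    sm_blocks = _blocks(cfg.n_sm, cfg.n_blocks)
    mirna_blocks = _blocks(cfg.n_mirna, cfg.n_blocks)
    sm_sim = _block_similarity(sm_blocks, cfg, rng, sm_ids)
    mirna_sim = _block_similarity(mirna_blocks, cfg, rng, mirna_ids)

    n_new_sm = int(round(cfg.fraction_new_sm * cfg.n_sm))
    n_new_mirna = int(round(cfg.fraction_new_mirna * cfg.n_mirna))
    new_sm = rng.choice(cfg.n_sm, size=n_new_sm, replace=False) if n_new_sm else np.array([], dtype=int)
    new_mirna = (
        rng.choice(cfg.n_mirna, size=n_new_mirna, replace=False)
        if n_new_mirna else np.array([], dtype=int)
    )
    eligible_sm = np.setdiff1d(np.arange(cfg.n_sm), new_sm)
    eligible_mirna = np.setdiff1d(np.arange(cfg.n_mirna), new_mirna)

    sm_labels = sm_blocks.copy()
    mirna_labels = mirna_blocks.copy()
    if cfg.decouple_side == "sm":
        sm_labels = rng.permutation(sm_labels)
    elif cfg.decouple_side == "mirna":
        mirna_labels = rng.permutation(mirna_labels)

    matched = sm_labels[eligible_sm][:, None] == mirna_labels[eligible_mirna][None, :]
    within_pool = np.argwhere(matched)
    cross_pool = np.argwhere(~matched)
    total = len(within_pool) + len(cross_pool)
    if cfg.n_associations > total:
        raise ValidationError(
            f"{cfg.n_associations} associations requested but only {total} "
            "pairs remain after excluding new entities"
        )
    n_within = int(rng.binomial(cfg.n_associations, cfg.within_block_association_prob))
    n_within = min(n_within, len(within_pool))
    n_cross = cfg.n_associations - n_within
    if n_cross > len(cross_pool):
        n_cross = len(cross_pool)
        n_within = cfg.n_associations - n_cross
    chosen = []
    if n_within:
        chosen.append(within_pool[rng.choice(len(within_pool), n_within, replace=False)])
    if n_cross:
        chosen.append(cross_pool[rng.choice(len(cross_pool), n_cross, replace=False)])
    pairs = np.concatenate(chosen) if chosen else np.empty((0, 2), dtype=int)

    a = np.zeros((cfg.n_sm, cfg.n_mirna), dtype=np.int8)
    a[eligible_sm[pairs[:, 0]], eligible_mirna[pairs[:, 1]]] = 1
    associations = AssociationMatrix(sm_ids, mirna_ids, a)
    truth = {
        "sm_blocks": sm_blocks.tolist(),
        "mirna_blocks": mirna_blocks.tolist(),
        "new_sm_indices": sorted(int(i) for i in new_sm),
        "new_mirna_indices": sorted(int(j) for j in new_mirna),
        "n_within_block": int(n_within),
        "config": asdict(cfg),
    }
    return sm_sim, mirna_sim, associations, truth


def permute_associations(
    associations: AssociationMatrix, seed: int
) -> AssociationMatrix:
    """Destroy the association signal by relocating the 1-entries uniformly
    at random (same count, same shape).  Used for null-distribution checks."""
    rng = np.random.default_rng(seed)
    flat = np.zeros(associations.values.size, dtype=np.int8)
    flat[rng.choice(flat.size, associations.n_known, replace=False)] = 1
    return AssociationMatrix(
        associations.sm_ids,
        associations.mirna_ids,
        flat.reshape(associations.values.shape),
    )


@dataclass(frozen=True)
class ToyFixture:
    """Frozen miniature worked example with precomputed expected values.

    The expected tensors, features and scores were computed once with the
    brute-force auxiliary-assignment oracle (independent of the vectorized
    production path) and stored in the packaged JSON golden file.
    """

    sm_similarity: SimilarityMatrix
    mirna_similarity: SimilarityMatrix
    associations: AssociationMatrix
    expected_norm_sm: np.ndarray
    expected_norm_mirna: np.ndarray
    expected_scores: ScoreMatrix


def toy_fixture() -> ToyFixture:
    """Load the frozen 3x3 worked example used by hand-unroll tests."""
    payload = json.loads(
        resources.files("gismma.data").joinpath("toy_fixture.json").read_text()
    )
    sm_sim = SimilarityMatrix(
        tuple(payload["sm_ids"]), np.array(payload["sm_similarity"])
    )
    mirna_sim = SimilarityMatrix(
        tuple(payload["mirna_ids"]), np.array(payload["mirna_similarity"])
    )
    associations = AssociationMatrix(
        sm_sim.entity_ids, mirna_sim.entity_ids, np.array(payload["associations"])
    )
    return ToyFixture(
        sm_similarity=sm_sim,
        mirna_similarity=mirna_sim,
        associations=associations,
        expected_norm_sm=np.array(payload["expected_norm_sm"]),
        expected_norm_mirna=np.array(payload["expected_norm_mirna"]),
        expected_scores=ScoreMatrix(
            sm_sim.entity_ids,
            mirna_sim.entity_ids,
            np.array(payload["expected_scores"]),
        ),
    )
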