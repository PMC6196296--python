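"""Similarity networks and their integration.

A similarity network is a labeled, symmetric, weighted graph over one class
of entities — small molecules or miRNAs — with edge weights in [0, 1].  In
practice several similarity measures are available per entity class (for
small molecules: side-effect, target-gene functional, chemical-structure and
indication-phenotype similarity; for miRNAs: functional and phenotype
similarity).  The model consumes a single integrated network per side,
obtained as a weighted mean of the individual measures,

    S(s, t) = sum_i w_i * M_i(s, t) / sum_i w_i,

with all weights defaulting to 1 (a plain average).  The integration is
n-ary: any number of input matrices may be supplied.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, ValidationError

#: Largest tolerated asymmetry |M - M.T| before a matrix is rejected.
SYMMETRY_TOL = 1e-8


@dataclass(frozen=True)
class SimilarityMatrix:
    """A validated symmetric similarity matrix over named entities.

    Parameters
    ----------
    entity_ids
        Ordered, unique string identifiers, one per row/column.
    values
        Square array of similarities in [0, 1].  Small asymmetries (below
        :data:`SYMMETRY_TOL`) are symmetrized on construction; larger ones
        raise :class:`~gismma.errors.ValidationError`.
    """

    entity_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        ids = tuple(str(e) for e in self.entity_ids)
        if len(set(ids)) != len(ids):
            dupes = sorted({e for e in ids if ids.count(e) > 1})
            raise ValidationError(f"duplicate entity ids: {dupes}")
        v = np.asarray(self.values, dtype=float)
        n = len(ids)
        if v.shape != (n, n):
            raise ValidationError(
                f"matrix shape {v.shape} does not match {n} entity ids"
            )
        if not np.all(np.isfinite(v)):
            r, c = np.argwhere(~np.isfinite(v))[0]
            raise ValidationError(
                f"non-finite similarity at ({ids[r]!r}, {ids[c]!r})"
            )
        if v.size and (v.min() < 0.0 or v.max() > 1.0):
            bad = np.argwhere((v < 0.0) | (v > 1.0))[0]
            r, c = bad
            raise ValidationError(
                f"similarity {v[r, c]!r} at ({ids[r]!r}, {ids[c]!r}) "
                "outside [0, 1]"
            )
        asym = np.abs(v - v.T)
        if asym.size and asym.max() > SYMMETRY_TOL:
            r, c = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValidationError(
                f"asymmetric similarity: ({ids[r]!r}, {ids[c]!r}) differs "
                f"from its transpose by {asym[r, c]:.3g}"
            )
        v = (v + v.T) / 2.0
        v.flags.writeable = False
        object.__setattr__(self, "entity_ids", ids)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.entity_ids)

    def index_of(self, entity_id: str) -> int:
        try:
            return self.entity_ids.index(entity_id)
        except ValueError:
            raise KeyError(entity_id) from None


def integrate_similarities(
    matrices: Sequence[SimilarityMatrix],
    weights: Sequence[float] | None = None,
) -> SimilarityMatrix:
    """Combine several similarity matrices into one by a weighted mean.

    All matrices must share identical ``entity_ids`` in identical order;
    use :func:`align_entities` first when they do not.  ``weights`` default
    to all ones (plain average); they must be non-negative with a strictly
    positive sum.  The output diagonal is set to 1 (an entity is maximally
    similar to itself); the diagonal never enters graphlet counting.
    """
    if not matrices:
        raise ValidationError("no similarity matrices supplied")
    if weights is None:
        weights = [1.0] * len(matrices)
    w = np.asarray(list(weights), dtype=float)
    if w.ndim != 1 or len(w) != len(matrices):
        raise ValidationError(
            f"{len(w)} weights supplied for {len(matrices)} matrices"
        )
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise ValidationError("weights must be finite and non-negative")
    if w.sum() <= 0:
        raise ValidationError("weights sum to zero; at least one must be positive")
    ref = matrices[0].entity_ids
    for k, m in enumerate(matrices[1:], start=1):
        if m.entity_ids != ref:
            extra = sorted(set(m.entity_ids) ^ set(ref))
            raise AlignmentError(
                f"matrix {k} entity ids disagree with matrix 0 "
                f"(mismatched or reordered: {extra[:10] or 'same set, different order'})"
            )
    stacked = np.stack([m.values for m in matrices])
    combined = np.tensordot(w, stacked, axes=1) / w.sum()
    np.fill_diagonal(combined, 1.0)
    return SimilarityMatrix(ref, combined)


def align_entities(
    matrix: SimilarityMatrix,
    target_ids: Sequence[str],
    *,
    fill_offdiag: float = 0.0,
    fill_diag: float = 1.0,
) -> SimilarityMatrix:
    """Reorder a matrix to ``target_ids``, adding absent entities.

    Entities in ``target_ids`` but not in the matrix are filled with
    ``fill_offdiag`` off the diagonal and ``fill_diag`` on it — by default
    "no similarity information" (0) and "self-similarity" (1).  Entities of
    the matrix absent from ``target_ids`` are dropped.
    """
    target = tuple(str(e) for e in target_ids)
    if len(set(target)) != len(target):
        dupes = sorted({e for e in target if target.count(e) > 1})
        raise ValidationError(f"duplicate target ids: {dupes}")
    n = len(target)
    out = np.full((n, n), fill_offdiag, dtype=float)
    np.fill_diagonal(out, fill_diag)
    pos = {e: k for k, e in enumerate(matrix.entity_ids)}
    present = [k for k, e in enumerate(target) if e in pos]
    src = [pos[target[k]] for k in present]
    out[np.ix_(present, present)] = matrix.values[np.ix_(src, src)]
    return SimilarityMatrix(target, out)
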