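"""Association scoring: isomer features, regression weights, two-side fusion.

For a candidate pair (small molecule i, miRNA j) the miRNA-side feature
vector sums, over the miRNAs p already known to associate with i, the
normalized isomer counts of the interaction p -> j in the miRNA network:

    X_m[k, (i, j)] = sum_{p in P(i), p != j} norm(N_pj(I_k))

and symmetrically on the small-molecule side over the small molecules q
known to associate with j, using interactions q -> i in the small-molecule
network.  Each side's score is a weighted sum of its 28 features,
S = X^T V, with the 28 isomer weights V fitted by ordinary least squares
against the known-association indicator over all pairs (known pairs 1,
all other pairs 0 — the closed-world convention).  The final score is the
plain average of the two sides.

A pair whose small molecule has no known miRNAs gets a zero miRNA-side
feature column (and vice versa): a *new* entity is still scoreable through
the opposite side's network, but a pair that is new on both sides scores 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, ValidationError
from .graphlets import InteractionTensor, counted_and_normalized
from .similarity import SimilarityMatrix

#: Condition-number threshold above which the normal equations are treated
#: as ill-conditioned (minimum-norm least squares is used either way).
ILL_CONDITIONED = 1e12


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary known-association adjacency: small molecules x miRNAs."""

    sm_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        sm = tuple(str(s) for s in self.sm_ids)
        mi = tuple(str(m) for m in self.mirna_ids)
        for name, ids in (("sm", sm), ("mirna", mi)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate {name} ids")
        v = np.asarray(self.values)
        if v.shape != (len(sm), len(mi)):
            raise ValidationError(
                f"association shape {v.shape} does not match "
                f"{len(sm)} x {len(mi)} ids"
            )
        if not np.isin(v, (0, 1)).all():
            raise ValidationError("association entries must be 0 or 1")
        v = v.astype(np.int8)
        v.flags.writeable = False
        object.__setattr__(self, "sm_ids", sm)
        object.__setattr__(self, "mirna_ids", mi)
        object.__setattr__(self, "values", v)

    @property
    def n_known(self) -> int:
        return int(self.values.sum())

    def known_pairs(self) -> list[tuple[str, str]]:
        return [
            (self.sm_ids[i], self.mirna_ids[j])
            for i, j in np.argwhere(self.values == 1)
        ]

    def with_pairs_removed(self, pairs) -> "AssociationMatrix":
        """Copy with the given (sm index, mirna index) entries set to 0."""
        v = self.values.copy()
        for i, j in pairs:
            v[i, j] = 0
        return AssociationMatrix(self.sm_ids, self.mirna_ids, v)


@dataclass(frozen=True)
class ScoreMatrix:
    """Predicted association scores, same shape/ids as the adjacency."""

    sm_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sm_ids), len(self.mirna_ids)):
            raise ValidationError("score shape does not match ids")
        if not np.all(np.isfinite(v)):
            raise ValidationError("non-finite score")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class IsomerWeights:
    """Fitted per-isomer regression weights plus conditioning diagnostics."""

    values: np.ndarray
    residual: float
    condition_number: float

    @property
    def ill_conditioned(self) -> bool:
        return self.condition_number > ILL_CONDITIONED


def _check_tensor(tensor: InteractionTensor, what: str) -> np.ndarray:
    if tensor.normalized is None:
        raise ValidationError(f"{what} tensor has not been normalized")
    return tensor.normalized


def _feature_cube_mirna(norm_m: np.ndarray, a: np.ndarray) -> np.ndarray:
    """(n_sm, n_mirna, K) cube of miRNA-side features for every pair.

    The p = j self-term drops out automatically because the tensor diagonal
    norm(N_jj) is identically zero.
    """
    return np.einsum("ip,pjk->ijk", a.astype(float), norm_m, optimize=True)


def _feature_cube_sm(norm_s: np.ndarray, a: np.ndarray) -> np.ndarray:
    """(n_sm, n_mirna, K) cube of small-molecule-side features."""
    return np.einsum("qj,qik->ijk", a.astype(float), norm_s, optimize=True)


def _resolve_pairs(associations: AssociationMatrix, pairs) -> tuple[np.ndarray, np.ndarray]:
    sm_pos = {s: k for k, s in enumerate(associations.sm_ids)}
    mi_pos = {m: k for k, m in enumerate(associations.mirna_ids)}
    try:
        rows = np.array([sm_pos[s] for s, _ in pairs], dtype=int)
        cols = np.array([mi_pos[m] for _, m in pairs], dtype=int)
    except KeyError as exc:
        raise AlignmentError(f"unknown entity id {exc.args[0]!r}") from None
    return rows, cols


def build_features_mirna_side(
    tensor: InteractionTensor,
    associations: AssociationMatrix,
    pairs=None,
) -> np.ndarray:
    """Feature matrix (28 x n_pairs) from the miRNA-network tensor.

    ``pairs`` is a list of (sm_id, mirna_id); by default every pair of the
    association matrix, in row-major order.
    """
    norm = _check_tensor(tensor, "miRNA")
    if tensor.entity_ids != associations.mirna_ids:
        raise AlignmentError("tensor entity ids do not match mirna_ids")
    cube = _feature_cube_mirna(norm, associations.values)
    if pairs is None:
        return cube.reshape(-1, cube.shape[2]).T
    rows, cols = _resolve_pairs(associations, pairs)
    return cube[rows, cols, :].T


def build_features_sm_side(
    tensor: InteractionTensor,
    associations: AssociationMatrix,
    pairs=None,
) -> np.ndarray:
    """Feature matrix (28 x n_pairs) from the small-molecule-network tensor."""
    norm = _check_tensor(tensor, "small-molecule")
    if tensor.entity_ids != associations.sm_ids:
        raise AlignmentError("tensor entity ids do not match sm_ids")
    cube = _feature_cube_sm(norm, associations.values)
    if pairs is None:
        return cube.reshape(-1, cube.shape[2]).T
    rows, cols = _resolve_pairs(associations, pairs)
    return cube[rows, cols, :].T


def fit_weights(features: np.ndarray, targets: np.ndarray) -> IsomerWeights:
    """Least-squares isomer weights solving X^T V ~= targets.

    Uses minimum-norm least squares, which coincides with the normal-
    equation solution V = (X X^T)^{-1} X targets when X has full row rank
    and remains well defined when it does not.  An all-zero feature matrix
    yields zero weights with a warning.
    """
    x = np.asarray(features, dtype=float)
    t = np.asarray(targets, dtype=float).ravel()
    if x.ndim != 2:
        raise ValidationError("features must be a 2-D array (n_isomers x n_pairs)")
    if x.shape[1] != t.size:
        raise ValidationError(
            f"{x.shape[1]} feature columns but {t.size} targets"
        )
    if x.shape[1] == 0:
        raise ValidationError("cannot fit weights with zero training pairs")
    if not np.any(x):
        warnings.warn(
            "all-zero feature matrix: returning zero isomer weights",
            RuntimeWarning,
            stacklevel=2,
        )
        return IsomerWeights(np.zeros(x.shape[0]), float(np.linalg.norm(t)), np.inf)
    v, _, rank, sv = np.linalg.lstsq(x.T, t, rcond=None)
    cond = float(sv[0] / sv[rank - 1]) if rank > 0 else np.inf
    residual = float(np.linalg.norm(x.T @ v - t))
    return IsomerWeights(v, residual, cond)


def score_side(features: np.ndarray, weights: IsomerWeights | np.ndarray) -> np.ndarray:
    """Per-pair scores: the weighted sum of isomer features, X^T V."""
    v = weights.values if isinstance(weights, IsomerWeights) else np.asarray(weights)
    x = np.asarray(features, dtype=float)
    if x.shape[0] != v.shape[0]:
        raise ValidationError(
            f"{x.shape[0]} feature rows but {v.shape[0]} weights"
        )
    return x.T @ v


def combine_scores(sm_side: ScoreMatrix, mirna_side: ScoreMatrix) -> ScoreMatrix:
    """Entrywise average of the two per-network score matrices."""
    if (
        sm_side.sm_ids != mirna_side.sm_ids
        or sm_side.mirna_ids != mirna_side.mirna_ids
    ):
        raise AlignmentError("score matrices have mismatched entity ids")
    return ScoreMatrix(
        sm_side.sm_ids,
        sm_side.mirna_ids,
        (sm_side.values + mirna_side.values) / 2.0,
    )


@dataclass(frozen=True)
class FittedModel:
    """Both fitted weight vectors plus the combined score matrix."""

    scores: ScoreMatrix
    weights_mirna_side: IsomerWeights
    weights_sm_side: IsomerWeights


def fit_predict_from_tensors(
    tensor_sm: InteractionTensor,
    tensor_mirna: InteractionTensor,
    associations: AssociationMatrix,
) -> np.ndarray:
    """Train both sides on an association matrix and score every pair.

    Returns the combined (n_sm x n_mirna) score array.  Split out from
    :func:`predict` so that cross-validation can reuse precomputed tensors
    (which depend only on the similarity networks, never on associations).
    """
    return _fit_from_tensors(tensor_sm, tensor_mirna, associations).scores.values


def _fit_from_tensors(
    tensor_sm: InteractionTensor,
    tensor_mirna: InteractionTensor,
    associations: AssociationMatrix,
) -> FittedModel:
    a = associations.values
    if associations.n_known == 0:
        warnings.warn(
            "association matrix has no known pairs: scores are degenerate zeros",
            RuntimeWarning,
            stacklevel=2,
        )
    norm_m = _check_tensor(tensor_mirna, "miRNA")
    norm_s = _check_tensor(tensor_sm, "small-molecule")
    if tensor_mirna.entity_ids != associations.mirna_ids:
        raise AlignmentError("miRNA tensor ids do not match association mirna_ids")
    if tensor_sm.entity_ids != associations.sm_ids:
        raise AlignmentError("small-molecule tensor ids do not match sm_ids")
    targets = a.astype(float).ravel()
    xm = _feature_cube_mirna(norm_m, a).reshape(-1, norm_m.shape[2]).T
    xs = _feature_cube_sm(norm_s, a).reshape(-1, norm_s.shape[2]).T
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vm = fit_weights(xm, targets)
        vs = fit_weights(xs, targets)
    sm_scores = score_side(xm, vm).reshape(a.shape)
    ss_scores = score_side(xs, vs).reshape(a.shape)
    combined = combine_scores(
        ScoreMatrix(associations.sm_ids, associations.mirna_ids, ss_scores),
        ScoreMatrix(associations.sm_ids, associations.mirna_ids, sm_scores),
    )
    return FittedModel(combined, vm, vs)


def predict(
    sm_similarity: SimilarityMatrix,
    mirna_similarity: SimilarityMatrix,
    associations: AssociationMatrix,
) -> ScoreMatrix:
    """End-to-end pipeline: count and normalize graphlet interactions on
    both similarity networks, build features, fit isomer weights on the
    known associations, score every pair on each side and average.

    Deterministic: identical inputs give identical scores.
    """
    if sm_similarity.entity_ids != associations.sm_ids:
        raise AlignmentError(
            "small-molecule similarity ids do not match association sm_ids"
        )
    if mirna_similarity.entity_ids != associations.mirna_ids:
        raise AlignmentError(
            "miRNA similarity ids do not match association mirna_ids"
        )
    tensor_sm = counted_and_normalized(sm_similarity)
    tensor_mirna = counted_and_normalized(mirna_similarity)
    fitted = _fit_from_tensors(tensor_sm, tensor_mirna, associations)
    return fitted.scores


def fit_predict(
    sm_similarity: SimilarityMatrix,
    mirna_similarity: SimilarityMatrix,
    associations: AssociationMatrix,
) -> FittedModel:
    """Like :func:`predict` but also returns both fitted weight vectors."""
    tensor_sm = counted_and_normalized(sm_similarity)
    tensor_mirna = counted_and_normalized(mirna_similarity)
    return _fit_from_tensors(tensor_sm, tensor_mirna, associations)


def rank_predictions(scores: ScoreMatrix, associations: AssociationMatrix):
    """All pairs sorted by descending score, ties broken lexicographically.

    Yields (sm_id, mirna_id, score, rank, is_known) tuples, the layout of
    the ranked-prediction table.
    """
    rows = []
    for i, s in enumerate(scores.sm_ids):
        for j, m in enumerate(scores.mirna_ids):
            rows.append(
                (s, m, float(scores.values[i, j]), bool(associations.values[i, j]))
            )
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return [
        (s, m, sc, rank, known)
        for rank, (s, m, sc, known) in enumerate(rows, start=1)
    ]
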